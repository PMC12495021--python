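"""Holland-Leinhardt P1 model: density, reciprocity, and per-node
expansiveness/attractiveness effects for a binary directed graph.

Dyads are independent.  For an unordered pair {i, j} the four dyad states
have probabilities proportional to::

    null:    1
    i -> j:  exp(theta + alpha_i + beta_j)
    j -> i:  exp(theta + alpha_j + beta_i)
    mutual:  exp(2*theta + rho + alpha_i + alpha_j + beta_i + beta_j)

``theta`` controls overall density, ``rho`` reciprocity, ``alpha_i`` the
node's propensity to send edges (expansiveness) and ``beta_j`` its
propensity to receive them (attractiveness).  The sufficient statistics are
the in/out degree sequences, the edge total, and the mutual-dyad count; the
maximum-likelihood fit solves the corresponding moment equations by damped
iterative proportional scaling.  Identification fixes the finite alpha and
beta to sum to zero.

Nodes with out-degree 0 (or n-1) have alpha hat = -inf (+inf), and likewise
for beta with in-degree; such parameters are reported as infinite sentinels,
held at a large finite surrogate during the iteration, and excluded from the
zero-sum normalization and from rankings.  A graph with no incoming edges on
some node therefore fits cleanly rather than failing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError, ParameterError

logger = logging.getLogger(__name__)

_SENTINEL_MAG = 40.0  # exp(-40) ~ 4e-18: numerically exact zero/one probabilities


@dataclass
class DyadCensus:
    mutual: int
    asymmetric: int
    null: int

    @property
    def total(self) -> int:
        return self.mutual + self.asymmetric + self.null


def dyad_census(adj: pd.DataFrame) -> DyadCensus:
    """Classify every unordered pair as mutual, asymmetric, or null."""
    a = adj.to_numpy().astype(bool)
    n = a.shape[0]
    if n < 2:
        raise ParameterError("need n >= 2")
    if np.diag(a).any():
        raise ParameterError("adjacency must have a zero diagonal")
    upper = np.triu_indices(n, k=1)
    fwd = a[upper]
    bwd = a.T[upper]
    mutual = int((fwd & bwd).sum())
    asym = int((fwd ^ bwd).sum())
    return DyadCensus(mutual=mutual, asymmetric=asym, null=n * (n - 1) // 2 - mutual - asym)


@dataclass
class P1Fit:
    theta: float
    rho: float
    alpha: pd.Series  # expansiveness; +/-inf where the out-degree is degenerate
    beta_attr: pd.Series  # attractiveness; +/-inf where the in-degree is degenerate
    converged: bool
    n_iter: int
    loglik: float
    fitted_edge_probs: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.alpha,
                "beta_attr": self.beta_attr,
                "alpha_finite": np.isfinite(self.alpha),
                "beta_finite": np.isfinite(self.beta_attr),
            }
        )


def _expectations(theta, rho, a, b, n):
    """P(edge i->j) matrix and P(mutual dyad) matrix from current parameters."""
    la = theta + a[:, None] + b[None, :]  # log weight of the arc i->j
    lm = 2 * theta + rho + a[:, None] + a[None, :] + b[:, None] + b[None, :]
    cap = np.maximum.reduce([np.zeros_like(la), la, la.T, lm])
    w0 = np.exp(-cap)
    wa = np.exp(la - cap)
    wm = np.exp(lm - cap)
    denom = w0 + wa + wa.T + wm
    p_edge = (wa + wm) / denom
    p_mut = wm / denom
    np.fill_diagonal(p_edge, 0.0)
    np.fill_diagonal(p_mut, 0.0)
    return p_edge, p_mut


def p1_loglik(adj_bool: np.ndarray, theta, rho, a, b) -> float:
    n = adj_bool.shape[0]
    la = theta + a[:, None] + b[None, :]
    lm = 2 * theta + rho + a[:, None] + a[None, :] + b[:, None] + b[None, :]
    cap = np.maximum.reduce([np.zeros_like(la), la, la.T, lm])
    log_denom = cap + np.log(
        np.exp(-cap) + np.exp(la - cap) + np.exp(la.T - cap) + np.exp(lm - cap)
    )
    ll = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if adj_bool[i, j] and adj_bool[j, i]:
                ll += lm[i, j]
            elif adj_bool[i, j]:
                ll += la[i, j]
            elif adj_bool[j, i]:
                ll += la[j, i]
            ll -= log_denom[i, j]
    return float(ll)


def fit_p1(adj: pd.DataFrame, tol: float = 1e-6, max_iter: int = 500) -> P1Fit:
    """Maximum-likelihood P1 fit by damped iterative scaling.

    Converges when every moment condition (expected out-degree and in-degree
    per node with finite parameters, expected edge total, expected mutual
    count) is matched within ``tol``.
    """
    ab = adj.to_numpy().astype(bool)
    n = ab.shape[0]
    if n < 3:
        raise ParameterError("need n >= 3")
    if np.diag(ab).any():
        raise ParameterError("adjacency must have a zero diagonal")
    out_obs = ab.sum(axis=1).astype(float)
    in_obs = ab.sum(axis=0).astype(float)
    m_obs = float(ab.sum())
    census = dyad_census(adj)
    mut_obs = float(census.mutual)
    n_dyads = n * (n - 1) / 2

    a = np.zeros(n)
    b = np.zeros(n)
    a_lo = out_obs == 0
    a_hi = out_obs == n - 1
    b_lo = in_obs == 0
    b_hi = in_obs == n - 1
    a[a_lo], a[a_hi] = -_SENTINEL_MAG, _SENTINEL_MAG
    b[b_lo], b[b_hi] = -_SENTINEL_MAG, _SENTINEL_MAG
    a_free = ~(a_lo | a_hi)
    b_free = ~(b_lo | b_hi)
    if a_lo.any() or b_lo.any() or a_hi.any() or b_hi.any():
        logger.info(
            "P1 fit: %d degenerate expansiveness and %d degenerate attractiveness "
            "parameters held at infinite sentinels",
            int((~a_free).sum()), int((~b_free).sum()),
        )
    theta = math.log(max(m_obs, 0.5) / max(n * (n - 1) - m_obs, 0.5))
    rho_fixed_low = mut_obs == 0
    rho_fixed_high = mut_obs == n_dyads
    rho = -_SENTINEL_MAG if rho_fixed_low else (_SENTINEL_MAG if rho_fixed_high else 0.0)
    rho_free = not (rho_fixed_low or rho_fixed_high)
    if m_obs == 0 or m_obs == n * (n - 1):
        raise EstimationError("P1 fit undefined for an empty or complete graph")

    damp = 0.5
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p_edge, p_mut = _expectations(theta, rho, a, b, n)
        e_out = p_edge.sum(axis=1)
        e_in = p_edge.sum(axis=0)
        e_m = float(p_edge.sum())
        e_mut = float(np.triu(p_mut, 1).sum())
        viol = [
            np.max(np.abs(e_out[a_free] - out_obs[a_free]), initial=0.0),
            np.max(np.abs(e_in[b_free] - in_obs[b_free]), initial=0.0),
            abs(e_m - m_obs),
            abs(e_mut - mut_obs) if rho_free else 0.0,
        ]
        if max(viol) < tol:
            converged = True
            break
        a[a_free] += damp * np.log(out_obs[a_free] / e_out[a_free])
        p_edge, _ = _expectations(theta, rho, a, b, n)
        e_in = p_edge.sum(axis=0)
        b[b_free] += damp * np.log(in_obs[b_free] / e_in[b_free])
        p_edge, _ = _expectations(theta, rho, a, b, n)
        theta += damp * math.log(m_obs / float(p_edge.sum()))
        if rho_free:
            _, p_mut = _expectations(theta, rho, a, b, n)
            rho += damp * math.log(mut_obs / float(np.triu(p_mut, 1).sum()))

    # identification: finite effects sum to zero, shift absorbed into theta
    sh_a = a[a_free].mean() if a_free.any() else 0.0
    sh_b = b[b_free].mean() if b_free.any() else 0.0
    a[a_free] -= sh_a
    b[b_free] -= sh_b
    theta += sh_a + sh_b
    p_edge, _ = _expectations(theta, rho, a, b, n)
    ll = p1_loglik(ab, theta, rho, a, b)

    alpha = np.where(a_lo, -np.inf, np.where(a_hi, np.inf, a))
    beta = np.where(b_lo, -np.inf, np.where(b_hi, np.inf, b))
    if not converged:
        logger.warning("P1 fit did not converge in %d iterations", max_iter)
    return P1Fit(
        theta=float(theta),
        rho=float(rho) if rho_free else (-math.inf if rho_fixed_low else math.inf),
        alpha=pd.Series(alpha, index=adj.index),
        beta_attr=pd.Series(beta, index=adj.index),
        converged=converged,
        n_iter=it,
        loglik=ll,
        fitted_edge_probs=pd.DataFrame(p_edge, index=adj.index, columns=adj.columns),
    )


def rank_expansive_attractive(
    fit: P1Fit, k: int = 5
) -> tuple[list[tuple[int, float]], list[tuple[int, float]]]:
    """Top-k finite expansiveness and attractiveness coefficients, descending.

    Ties are broken by node label; asking for more than the number of finite
    coefficients returns a shorter list with a logged warning.
    """
    if not fit.converged:
        raise EstimationError("fit did not converge; rankings unavailable")

    def top(series: pd.Series) -> list[tuple[int, float]]:
        finite = series[np.isfinite(series)]
        if k > len(finite):
            logger.warning("requested top %d but only %d finite coefficients", k, len(finite))
        order = sorted(finite.items(), key=lambda kv: (-kv[1], kv[0]))
        return [(node, float(v)) for node, v in order[:k]]

    return top(fit.alpha), top(fit.beta_attr)
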