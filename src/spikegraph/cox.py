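"""Cox-method inference of directed functional connectivity between spike trains.

The target train is modelled as a modulated renewal process: the hazard of
its next spike at age ``u`` (backward recurrence time since its last spike)
is

    lambda(t) = lambda0(u) * exp( sum_j beta_j * Z_j(t) )

with an unspecified baseline hazard ``lambda0`` and one influence covariate
``Z_j(t) = exp(-(t - s_j(t)) / tau)`` per reference train, where ``s_j(t)``
is the reference's latest spike at or before ``t`` (``Z_j = 0`` before its
first spike).  The coefficients ``beta_j`` are estimated by Cox partial
likelihood on the target's inter-spike intervals: each ISI is one
observation whose "survival time" is the ISI length, the leading and
trailing partial intervals are right-censored, and the risk set at elapsed
time ``u`` contains every observation of length >= ``u``, with covariates
evaluated at that observation's own absolute time (interval start + u).
Ties are handled by the Breslow convention.

A reference train is called an influence (a directed edge reference ->
target) when its two-sided Wald confidence interval excludes zero.  Fitting
all references jointly (the default) conditions each influence on every
other simultaneously recorded train; a pairwise mode is available for
comparison with classical two-train analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, ParameterError
from .spike_trains import SpikeTrainSet

logger = logging.getLogger(__name__)

_MAX_RISK_MATRIX_BYTES = 2_000_000_000


@dataclass(frozen=True)
class InfluenceKernel:
    """Exponential-decay influence covariate with time constant ``tau_s``."""

    form: str = "exp_decay"
    tau_s: float = 0.01

    def __post_init__(self) -> None:
        if self.form != "exp_decay":
            raise ParameterError(f"unknown kernel form {self.form!r}")
        if self.tau_s <= 0:
            raise ParameterError("tau_s must be positive")


def influence_covariates(
    ref_spikes: np.ndarray, eval_times: np.ndarray, kernel: InfluenceKernel
) -> np.ndarray:
    """Evaluate ``Z(t) = exp(-(t - s(t))/tau)`` at each eval time.

    ``s(t)`` is the latest reference spike at or before ``t``; before the
    first reference spike the covariate is zero.
    """
    ref_spikes = np.asarray(ref_spikes, dtype=float)
    eval_times = np.asarray(eval_times, dtype=float)
    idx = np.searchsorted(ref_spikes, eval_times, side="right")
    z = np.zeros(eval_times.shape)
    seen = idx > 0
    if ref_spikes.size:
        z[seen] = np.exp(-(eval_times[seen] - ref_spikes[idx[seen] - 1]) / kernel.tau_s)
    return z


def build_risk_sets(
    target_spikes: np.ndarray,
    duration_s: float,
    split_at: np.ndarray | None = None,
) -> pd.DataFrame:
    """Turn a target train into renewal observations (start_s, length_s, event).

    Each inter-spike interval is one observation ending in an event; the
    leading interval (session start to first spike) and trailing interval
    (last spike to session end) are right-censored.  If ``split_at`` gives
    trial-boundary times, observations crossing a boundary are censored at
    the boundary (the portion after the boundary is discarded).
    """
    t = np.asarray(target_spikes, dtype=float)
    if t.size < 2:
        raise EstimationError("insufficient events: need >= 2 target spikes")
    starts = np.concatenate([[0.0], t])
    ends = np.concatenate([t, [duration_s]])
    event = np.ones(starts.size, dtype=bool)
    event[0] = False
    event[-1] = False
    if split_at is not None and len(split_at):
        split_at = np.sort(np.asarray(split_at, dtype=float))
        # censor each observation at the first boundary strictly inside it
        k = np.searchsorted(split_at, starts, side="right")
        has_boundary = (k < split_at.size) & (split_at[np.minimum(k, split_at.size - 1)] < ends)
        new_ends = np.where(has_boundary, split_at[np.minimum(k, split_at.size - 1)], ends)
        event = event & ~has_boundary
        ends = new_ends
    lengths = ends - starts
    keep = lengths > 0
    return pd.DataFrame(
        {"start_s": starts[keep], "length_s": lengths[keep], "event": event[keep]}
    ).reset_index(drop=True)


class PartialLikelihood:
    """Precomputed design for the Cox partial likelihood of one target.

    Risk-set membership and the covariate matrix do not depend on beta, so
    they are built once (vectorized over all event x at-risk-observation
    pairs) and every Newton iteration is dense linear algebra.
    """

    def __init__(
        self,
        observations: pd.DataFrame,
        ref_spike_trains: list[np.ndarray],
        kernel: InfluenceKernel,
    ):
        obs = observations.sort_values("length_s", kind="stable").reset_index(drop=True)
        lengths = obs["length_s"].to_numpy()
        starts = obs["start_s"].to_numpy()
        is_event = obs["event"].to_numpy(dtype=bool)
        n_obs = len(obs)
        event_pos = np.flatnonzero(is_event)
        if event_pos.size == 0:
            raise EstimationError("insufficient events: no complete inter-spike interval")
        self.n_events = int(event_pos.size)
        self.n_obs = n_obs
        p = len(ref_spike_trains)
        self.n_refs = p

        # risk set of event e = sorted observations with length >= its length
        risk_start = np.searchsorted(lengths, lengths[event_pos], side="left")
        seg_len = n_obs - risk_start
        offsets = np.concatenate([[0], np.cumsum(seg_len)[:-1]])
        total_rows = int(seg_len.sum())
        if total_rows * max(p, 1) * 8 > _MAX_RISK_MATRIX_BYTES:
            raise EstimationError(
                f"risk-set design too large ({total_rows} rows x {p} refs); "
                "reduce the duration or the number of events"
            )
        row_obs = np.concatenate([np.arange(s, n_obs) for s in risk_start])
        row_time = starts[row_obs] + np.repeat(lengths[event_pos], seg_len)
        self.offsets = offsets
        self.seg_id = np.repeat(np.arange(self.n_events), seg_len)
        self.event_rows = offsets + (event_pos - risk_start)
        self.X = np.empty((total_rows, p))
        for j, ref in enumerate(ref_spike_trains):
            self.X[:, j] = influence_covariates(ref, row_time, kernel)

    def loglik(self, beta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        """Partial log-likelihood with analytic gradient and Hessian."""
        beta = np.asarray(beta, dtype=float)
        X = self.X
        eta = X @ beta if X.shape[1] else np.zeros(X.shape[0])
        m = np.maximum.reduceat(eta, self.offsets)
        w = np.exp(eta - m[self.seg_id])
        s0 = np.add.reduceat(w, self.offsets)
        value = float(eta[self.event_rows].sum() - (m + np.log(s0)).sum())
        if not X.shape[1]:
            return value, np.zeros(0), np.zeros((0, 0))
        wX = w[:, None] * X
        mu = np.add.reduceat(wX, self.offsets, axis=0) / s0[:, None]
        grad = X[self.event_rows].sum(axis=0) - mu.sum(axis=0)
        h1 = X.T @ (X * (w / s0[self.seg_id])[:, None])
        hess = -(h1 - mu.T @ mu)
        return value, grad, hess


def cox_partial_loglik(
    observations: pd.DataFrame,
    ref_spike_trains: list[np.ndarray],
    kernel: InfluenceKernel,
    beta: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """One-shot evaluation of the partial likelihood (value, gradient, Hessian)."""
    return PartialLikelihood(observations, ref_spike_trains, kernel).loglik(beta)


@dataclass
class CoxFit:
    """Joint influence fit for one target train."""

    target_id: int
    reference_ids: list[int]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    loglik: float
    converged: bool
    n_events: int
    n_iter: int
    alpha_level: float
    dropped_refs: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reference": self.reference_ids,
                "beta": self.beta,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_value": self.p_values,
                "called": (self.ci_low > 0) | (self.ci_high < 0),
            }
        )


def _newton(pl: PartialLikelihood, tol: float, max_iter: int) -> tuple[np.ndarray, float, np.ndarray, bool, int]:
    p = pl.n_refs
    beta = np.zeros(p)
    f, g, h = pl.loglik(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-h, g)
        except np.linalg.LinAlgError:
            return beta, f, h, False, it
        if not np.all(np.isfinite(step)):
            return beta, f, h, False, it
        # step halving keeps the concave objective increasing monotonically
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            f2, g2, h2 = pl.loglik(cand)
            if np.isfinite(f2) and f2 >= f - 1e-10:
                break
            scale *= 0.5
        else:
            return beta, f, h, False, it
        beta, f, g, h = cand, f2, g2, h2
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    return beta, f, h, converged, it


def fit_target(
    target_id: int,
    spikes: SpikeTrainSet,
    kernel: InfluenceKernel,
    alpha_level: float = 0.05,
    min_events: int = 30,
    reference_ids: list[int] | None = None,
    split_at: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Fit all reference influences on one target train jointly.

    Newton-Raphson from beta = 0 with step halving; standard errors from
    the inverse observed information; two-sided Wald intervals at level
    ``1 - alpha_level``.  References with no spikes or a degenerate
    (constant) covariate are dropped with a logged warning.
    """
    if target_id not in spikes.spikes:
        raise ParameterError(f"unknown target channel {target_id}")
    if reference_ids is None:
        reference_ids = [ch for ch in spikes.channel_ids if ch != target_id]
    obs = build_risk_sets(spikes.spikes[target_id], spikes.duration_s, split_at=split_at)
    n_events = int(obs["event"].sum())
    if n_events < min_events:
        raise EstimationError(
            f"target {target_id}: {n_events} events < required minimum {min_events}"
        )

    refs, dropped = [], []
    for ch in reference_ids:
        if spikes.spikes[ch].size == 0:
            logger.warning("target %s: reference %s has no spikes; dropped", target_id, ch)
            dropped.append(ch)
        else:
            refs.append(ch)
    pl = PartialLikelihood(obs, [spikes.spikes[ch] for ch in refs], kernel)
    # degenerate (constant) covariates carry no information and break the fit
    keep_cols = []
    for j, ch in enumerate(refs):
        if np.ptp(pl.X[:, j]) < 1e-12:
            logger.warning("target %s: reference %s has constant covariate; dropped", target_id, ch)
            dropped.append(ch)
        else:
            keep_cols.append(j)
    if len(keep_cols) != len(refs):
        pl.X = pl.X[:, keep_cols]
        pl.n_refs = len(keep_cols)
        refs = [refs[j] for j in keep_cols]

    beta, f, h, converged, n_iter = _newton(pl, tol, max_iter)
    info = -h
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        converged = False
        se = np.full(len(refs), np.nan)
    z = stats.norm.ppf(1 - alpha_level / 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = np.where(se > 0, beta / se, np.nan)
        p_values = 2 * stats.norm.sf(np.abs(wald))
    if not converged:
        logger.warning("target %s: Newton-Raphson did not converge; no edges called", target_id)
    return CoxFit(
        target_id=target_id,
        reference_ids=refs,
        beta=beta,
        se=se,
        ci_low=beta - z * se,
        ci_high=beta + z * se,
        p_values=p_values,
        loglik=f,
        converged=converged,
        n_events=n_events,
        n_iter=n_iter,
        alpha_level=alpha_level,
        dropped_refs=dropped,
    )


def estimate_connectivity(
    spikes: SpikeTrainSet,
    kernel: InfluenceKernel | None = None,
    alpha_level: float = 0.05,
    correction: str = "none",
    min_events: int = 30,
    split_at: np.ndarray | None = None,
    pairwise: bool = False,
) -> tuple[pd.DataFrame, dict[int, CoxFit]]:
    """Estimate the binary directed connectivity matrix among all channels.

    One joint fit per target (or one per reference in ``pairwise`` mode);
    entry ``a[i, j] = 1`` iff reference i's interval in target j's fit
    excludes zero after the configured multiple-testing correction
    (``none``, ``bonferroni``, or ``bh`` = Benjamini-Hochberg).  Rows are
    sources, columns are targets, the diagonal is forced to zero, and
    failed targets yield empty columns with a logged warning.
    """
    if spikes.n_channels < 3:
        raise ParameterError("need at least 3 channels")
    if correction not in ("none", "bonferroni", "bh"):
        raise ParameterError(f"unknown correction {correction!r}")
    kernel = kernel or InfluenceKernel()
    labels = list(spikes.channel_ids)
    fits: dict[int, CoxFit] = {}
    pvals: dict[tuple[int, int], float] = {}
    for target in labels:
        refs = [ch for ch in labels if ch != target]
        try:
            if pairwise:
                parts = [
                    fit_target(
                        target, spikes, kernel, alpha_level, min_events,
                        reference_ids=[r], split_at=split_at,
                    )
                    for r in refs
                ]
                merged = CoxFit(
                    target_id=target,
                    reference_ids=[r for f in parts for r in f.reference_ids],
                    beta=np.concatenate([f.beta for f in parts]),
                    se=np.concatenate([f.se for f in parts]),
                    ci_low=np.concatenate([f.ci_low for f in parts]),
                    ci_high=np.concatenate([f.ci_high for f in parts]),
                    p_values=np.concatenate([f.p_values for f in parts]),
                    loglik=float(sum(f.loglik for f in parts)),
                    converged=all(f.converged for f in parts),
                    n_events=parts[0].n_events,
                    n_iter=max(f.n_iter for f in parts),
                    alpha_level=alpha_level,
                    dropped_refs=[d for f in parts for d in f.dropped_refs],
                )
                fits[target] = merged
                for f in parts:
                    if f.converged:
                        for r, pv in zip(f.reference_ids, f.p_values):
                            if np.isfinite(pv):
                                pvals[(r, target)] = float(pv)
            else:
                fit = fit_target(
                    target, spikes, kernel, alpha_level, min_events,
                    reference_ids=refs, split_at=split_at,
                )
                fits[target] = fit
                if fit.converged:
                    for r, pv in zip(fit.reference_ids, fit.p_values):
                        if np.isfinite(pv):
                            pvals[(r, target)] = float(pv)
        except EstimationError as exc:
            logger.warning("target %s skipped: %s", target, exc)

    adj = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    if pvals:
        pairs = list(pvals)
        p = np.array([pvals[k] for k in pairs])
        if correction == "none":
            called = p < alpha_level
        elif correction == "bonferroni":
            called = p < alpha_level / p.size
        else:
            called = stats.false_discovery_control(p) < alpha_level
        for (src, tgt), c in zip(pairs, called):
            if c:
                adj.loc[src, tgt] = 1
    np.fill_diagonal(adj.values, 0)
    return adj, fits
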