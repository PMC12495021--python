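"""Three-node structural motif census with degree-preserving null ensembles.

A structural motif is the isomorphism class of the induced subgraph on a
weakly-connected node triple.  For directed graphs without self-loops there
are exactly 13 such classes; they are numbered 1-13 in the ordering that is
standard in the brain-connectivity literature, which coincides with the
classical triad-census ordering by increasing edge count:

====  =====  =========================================
ID    triad  representative edges (nodes a, b, c)
====  =====  =========================================
 1    021D   b->a, b->c          (divergence)
 2    021U   a->b, c->b          (convergence)
 3    021C   a->b, b->c          (chain)
 4    111D   a<->b, c->a
 5    111U   a<->b, a->c
 6    030T   a->b, a->c, b->c    (feed-forward triangle)
 7    030C   a->b, b->c, c->a    (cycle)
 8    201    a<->b, a<->c
 9    120D   a<->b, c->a, c->b
10    120U   a<->b, a->c, b->c
11    120C   a<->b, a->c, c->b
12    210    a<->b, a<->c, b->c
13    300    a<->b, a<->c, b<->c (complete)
====  =====  =========================================

Counting is structural (each triple is classified by its full induced
subgraph); a functional mode that also counts every connected sub-pattern
of each triple is available for comparison.  Significance of each class is
assessed against an ensemble of degree-preserving randomizations of the
observed graph (edge switching), with one-sided empirical enrichment
p-values and z-scores.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

logger = logging.getLogger(__name__)

N_MOTIF_CLASSES = 13

#: representative edge sets on nodes (0, 1, 2), indexed by motif ID
MOTIF_REPRESENTATIVES: dict[int, frozenset[tuple[int, int]]] = {
    1: frozenset({(1, 0), (1, 2)}),
    2: frozenset({(0, 1), (2, 1)}),
    3: frozenset({(0, 1), (1, 2)}),
    4: frozenset({(0, 1), (1, 0), (2, 0)}),
    5: frozenset({(0, 1), (1, 0), (0, 2)}),
    6: frozenset({(0, 1), (0, 2), (1, 2)}),
    7: frozenset({(0, 1), (1, 2), (2, 0)}),
    8: frozenset({(0, 1), (1, 0), (0, 2), (2, 0)}),
    9: frozenset({(0, 1), (1, 0), (2, 0), (2, 1)}),
    10: frozenset({(0, 1), (1, 0), (0, 2), (1, 2)}),
    11: frozenset({(0, 1), (1, 0), (0, 2), (2, 1)}),
    12: frozenset({(0, 1), (1, 0), (0, 2), (2, 0), (1, 2)}),
    13: frozenset({(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)}),
}

_PAIRS = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
_PERMS = list(itertools.permutations(range(3)))


def _code(edges: frozenset[tuple[int, int]]) -> int:
    return sum(1 << k for k, pr in enumerate(_PAIRS) if pr in edges)


def _permute(edges: frozenset[tuple[int, int]], perm: tuple[int, ...]) -> frozenset:
    return frozenset((perm[i], perm[j]) for i, j in edges)


def _weakly_connected(edges: frozenset[tuple[int, int]]) -> bool:
    touched = {i for e in edges for i in e}
    if touched != {0, 1, 2}:
        return False
    und = {frozenset(e) for e in edges}
    # 3 nodes: weakly connected iff >= 2 distinct undirected pairs are linked
    return len(und) >= 2


def _build_lookup() -> np.ndarray:
    """Map each of the 64 edge configurations to a motif ID (0 = disconnected)."""
    lut = np.zeros(64, dtype=int)
    for motif_id, rep in MOTIF_REPRESENTATIVES.items():
        for perm in _PERMS:
            lut[_code(_permute(rep, perm))] = motif_id
    return lut


_LOOKUP = _build_lookup()


def triad_class(adj3: np.ndarray) -> int | None:
    """Motif ID (1-13) of a 3-node induced subgraph, or None if disconnected."""
    adj3 = np.asarray(adj3)
    if adj3.shape != (3, 3):
        raise ParameterError("triad_class expects a 3x3 adjacency")
    if np.diag(adj3).any():
        raise ParameterError("self-loops are not allowed")
    code = sum(1 << k for k, (i, j) in enumerate(_PAIRS) if adj3[i, j])
    motif = int(_LOOKUP[code])
    return motif if motif else None


def motif_counts(adj: pd.DataFrame, mode: str = "structural") -> np.ndarray:
    """Counts of motif classes 1..13 over all weakly-connected triples.

    ``structural`` classifies each triple once by its induced subgraph;
    ``functional`` credits every connected sub-pattern of each triple.
    """
    if mode not in ("structural", "functional"):
        raise ParameterError(f"unknown counting mode {mode!r}")
    a = adj.to_numpy().astype(bool)
    n = a.shape[0]
    if n < 3:
        raise ParameterError("need n >= 3")
    if np.diag(a).any():
        raise ParameterError("adjacency must have a zero diagonal")
    trip = np.array(list(itertools.combinations(range(n), 3)))
    i, j, k = trip[:, 0], trip[:, 1], trip[:, 2]
    code = (
        a[i, j] * 1
        + a[j, i] * 2
        + a[i, k] * 4
        + a[k, i] * 8
        + a[j, k] * 16
        + a[k, j] * 32
    )
    if mode == "structural":
        counts = np.bincount(_LOOKUP[code], minlength=N_MOTIF_CLASSES + 1)
    else:
        counts = np.zeros(N_MOTIF_CLASSES + 1, dtype=int)
        for c in code[code > 0]:
            for sub in _sub_patterns(int(c)):
                counts[sub] += 1
    return counts[1:]


def _sub_patterns(code: int) -> list[int]:
    """Motif IDs of all connected sub-edge-sets of a triple (functional counting)."""
    present = [k for k in range(6) if code & (1 << k)]
    out = []
    for r in range(2, len(present) + 1):
        for combo in itertools.combinations(present, r):
            sub = sum(1 << k for k in combo)
            m = _LOOKUP[sub]
            if m:
                out.append(int(m))
    return out


def degree_preserving_randomize(
    adj: pd.DataFrame, swap_factor: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Randomize a digraph by edge switching, preserving every in/out degree.

    Attempts ``swap_factor * m`` swaps of edge pairs (a->b, c->d) ->
    (a->d, c->b), rejecting any swap that would create a self-loop or a
    duplicate edge.
    """
    a = adj.to_numpy().astype(bool).copy()
    edges = np.argwhere(a)
    m = len(edges)
    if m < 2:
        logger.warning("graph has < 2 edges; returned unchanged")
        return adj.copy()
    rng = np.random.default_rng(seed)
    n_attempts = swap_factor * m
    pick = rng.integers(0, m, size=(n_attempts, 2))
    for e1, e2 in pick:
        if e1 == e2:
            continue
        s1, t1 = edges[e1]
        s2, t2 = edges[e2]
        if s1 == t2 or s2 == t1 or s1 == s2 or t1 == t2:
            continue
        if a[s1, t2] or a[s2, t1]:
            continue
        a[s1, t1] = a[s2, t2] = False
        a[s1, t2] = a[s2, t1] = True
        edges[e1] = (s1, t2)
        edges[e2] = (s2, t1)
    return pd.DataFrame(a.astype(int), index=adj.index, columns=adj.columns)


@dataclass
class MotifCensus:
    counts: np.ndarray  # observed counts, classes 1..13
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray  # NaN where the null SD is zero
    p_empirical: np.ndarray  # one-sided enrichment, add-one corrected
    significant: np.ndarray
    n_null: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif_id": np.arange(1, N_MOTIF_CLASSES + 1),
                "count": self.counts,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "z": self.z,
                "p": self.p_empirical,
                "significant": self.significant,
            }
        )


def motif_significance(
    adj: pd.DataFrame,
    n_null: int = 1000,
    swap_factor: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    mode: str = "structural",
) -> MotifCensus:
    """Motif census with significance against a degree-preserving ensemble.

    For each class, ``z = (count - null mean) / null SD`` and the empirical
    enrichment p-value is ``(1 + #{null >= observed}) / (n_null + 1)``.
    A class is flagged significant when p < ``alpha``.
    """
    if n_null < 100:
        raise ParameterError("n_null must be >= 100")
    observed = motif_counts(adj, mode=mode)
    rng = np.random.default_rng(seed)
    null_counts = np.empty((n_null, N_MOTIF_CLASSES), dtype=int)
    for b in range(n_null):
        null = degree_preserving_randomize(
            adj, swap_factor=swap_factor, seed=int(rng.integers(0, 2**31 - 1))
        )
        null_counts[b] = motif_counts(null, mode=mode)
    mean = null_counts.mean(axis=0)
    sd = null_counts.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (observed - mean) / sd, np.nan)
    p = (1 + (null_counts >= observed[None, :]).sum(axis=0)) / (n_null + 1)
    significant = p < alpha
    return MotifCensus(
        counts=observed,
        null_mean=mean,
        null_sd=sd,
        z=z,
        p_empirical=p,
        significant=significant,
        n_null=n_null,
        seed=seed,
    )
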