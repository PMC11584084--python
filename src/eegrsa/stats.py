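"""Group-level inference: sign-flip permutation tests with TFCE.

Per analysis unit (a time point or a searchlight cluster), encoding scores
across subjects are tested against chance level 0 with a one-sample t
statistic.  Threshold-free cluster enhancement (TFCE) integrates cluster
extent and height over all thresholds, boosting contiguous signal without
a fixed cluster-forming threshold; enhancement is one-tailed, so
non-positive t values enhance to 0.  The null distribution is built by
randomly flipping each subject's sign across all units jointly (valid when
the null is symmetric about zero), recomputing t and TFCE, and recording
the maximum enhanced value per permutation; comparing every unit's
observed enhancement against this max-null distribution controls the
family-wise error rate by design.

TFCE parameters default to the canonical E = 0.5, H = 2, dh = 0.1.  Sign
assignments are enumerated exhaustively when 2**n_subjects <= 4096,
otherwise 1024 random draws are used by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix

from .errors import InvalidConfigError, InvalidInputError

EXHAUSTIVE_LIMIT = 4096


@dataclass
class AdjacencyGraph:
    """Undirected adjacency over analysis units."""

    n_nodes: int
    edges: np.ndarray  # (n_edges, 2) int
    node_ids: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if self.edges.size:
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise InvalidInputError("adjacency must not contain self-edges")
            if self.edges.min() < 0 or self.edges.max() >= self.n_nodes:
                raise InvalidInputError("edge endpoint out of range")
        if self.node_ids is not None and len(self.node_ids) != self.n_nodes:
            raise InvalidInputError("node_ids length mismatch")

    def to_csr(self) -> csr_matrix:
        n = self.n_nodes
        if not self.edges.size:
            return csr_matrix((n, n))
        r = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        c = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        return csr_matrix((np.ones(r.size), (r, c)), shape=(n, n))


def build_adjacency(
    kind: str,
    n_times: Optional[int] = None,
    clusters=None,
    montage=None,
    neighbor_distance_mm: float = 40.0,
) -> AdjacencyGraph:
    """Adjacency for TFCE.

    ``temporal_chain`` connects consecutive time points.
    ``searchlight_spatiotemporal`` connects clusters that share a time
    window and whose center electrodes are at most ``neighbor_distance_mm``
    apart, plus same-center clusters in consecutive windows.
    """
    if kind == "temporal_chain":
        if n_times is None or n_times < 1:
            raise InvalidConfigError("temporal_chain requires n_times >= 1")
        idx = np.arange(n_times - 1)
        return AdjacencyGraph(n_times, np.column_stack([idx, idx + 1]))
    if kind == "searchlight_spatiotemporal":
        if clusters is None or montage is None:
            raise InvalidConfigError(
                "searchlight adjacency requires clusters and montage"
            )
        centers = [montage.index(cl.center_channel) for cl in clusters]
        dist = montage.distance_matrix()
        windows = sorted({cl.window_ms for cl in clusters})
        w_rank = {w: k for k, w in enumerate(windows)}
        edges: List[Tuple[int, int]] = []
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                wa = w_rank[clusters[a].window_ms]
                wb = w_rank[clusters[b].window_ms]
                if wa == wb:
                    if dist[centers[a], centers[b]] <= neighbor_distance_mm:
                        edges.append((a, b))
                elif abs(wa - wb) == 1 and centers[a] == centers[b]:
                    edges.append((a, b))
        node_ids = tuple(cl.cluster_id for cl in clusters)
        return AdjacencyGraph(len(clusters), np.asarray(edges), node_ids)
    raise InvalidConfigError(f"unknown adjacency kind '{kind}'")


def subgraph(adjacency: AdjacencyGraph, keep: np.ndarray) -> AdjacencyGraph:
    """Induced subgraph on the units flagged in the boolean mask ``keep``."""
    keep = np.asarray(keep, dtype=bool)
    if keep.shape != (adjacency.n_nodes,):
        raise InvalidInputError("mask length must equal adjacency.n_nodes")
    new_index = np.cumsum(keep) - 1
    edges = adjacency.edges
    if edges.size:
        both = keep[edges[:, 0]] & keep[edges[:, 1]]
        edges = new_index[edges[both]]
    node_ids = (
        tuple(np.asarray(adjacency.node_ids, dtype=object)[keep])
        if adjacency.node_ids is not None
        else None
    )
    return AdjacencyGraph(int(keep.sum()), edges, node_ids)


def one_sample_t(scores: np.ndarray) -> np.ndarray:
    """Per-unit one-sample t against 0 (sd with n-1 denominator).

    Units with zero variance across subjects get t = 0 with a warning:
    such a unit can never reach significance.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2:
        raise InvalidInputError("scores must be (subjects, units)")
    n = x.shape[0]
    if n < 3:
        raise InvalidInputError("need at least 3 subjects")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("non-finite scores")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} unit(s) with zero variance across subjects; "
            "t set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[zero] = 0.0
    return t


def _find_root(parent: np.ndarray, a: int) -> int:
    root = a
    while parent[root] != root:
        root = parent[root]
    while parent[a] != root:  # path compression
        parent[a], a = root, parent[a]
    return root


def _roots_of(parent: np.ndarray, idx: np.ndarray) -> np.ndarray:
    roots = parent[idx]
    while True:
        nxt = parent[roots]
        if np.array_equal(nxt, roots):
            return roots
        roots = nxt


def tfce(
    t_map: np.ndarray,
    adjacency: AdjacencyGraph,
    E: float = 0.5,
    H: float = 2.0,
    dh: float = 0.1,
) -> np.ndarray:
    """One-tailed threshold-free cluster enhancement of a statistic map.

    enhanced(u) = sum over thresholds h = dh, 2dh, ... <= max(t) of
    extent(u, h)**E * h**H * dh, where extent(u, h) is the size of u's
    connected component among units with t >= h.  Negative t contributes
    nothing.

    Thresholds are processed from the highest down with an incremental
    union-find, so each node and edge is merged exactly once across the
    whole sweep (this matters inside permutation loops).
    """
    if dh <= 0:
        raise InvalidConfigError("dh must be positive")
    t = np.asarray(t_map, dtype=float)
    if t.ndim != 1 or t.shape[0] != adjacency.n_nodes:
        raise InvalidInputError("t_map length must equal adjacency.n_nodes")
    if not np.all(np.isfinite(t)):
        raise InvalidInputError("non-finite t map")
    n = t.shape[0]
    out = np.zeros_like(t)
    tmax = t.max(initial=0.0)
    if tmax < dh:
        return out
    n_levels = int(np.floor(tmax / dh + 1e-9))
    # node is supra-threshold at level k (h = k*dh) iff node_level >= k
    node_level = np.clip(np.floor(t / dh + 1e-9), 0, n_levels).astype(int)
    node_order = np.argsort(-node_level, kind="stable")
    edges = adjacency.edges
    if edges.size:
        edge_level = np.minimum(node_level[edges[:, 0]], node_level[edges[:, 1]])
        edge_order = np.argsort(-edge_level, kind="stable")
        edge_level = edge_level[edge_order]
        edges = edges[edge_order]
    parent = np.arange(n)
    comp_size = np.ones(n, dtype=int)
    ei = ni = 0
    for k in range(n_levels, 0, -1):
        while ei < len(edges) and edges.size and edge_level[ei] >= k:
            ra = _find_root(parent, int(edges[ei, 0]))
            rb = _find_root(parent, int(edges[ei, 1]))
            if ra != rb:
                if comp_size[ra] < comp_size[rb]:
                    ra, rb = rb, ra
                parent[rb] = ra
                comp_size[ra] += comp_size[rb]
            ei += 1
        while ni < n and node_level[node_order[ni]] >= k:
            ni += 1
        active = node_order[:ni]
        roots = _roots_of(parent, active)
        h = k * dh
        out[active] += comp_size[roots].astype(float) ** E * h**H * dh
    return out


@dataclass
class GroupStatResult:
    """Observed statistics, TFCE map and family-wise corrected p-values."""

    t: np.ndarray
    tfce: np.ndarray
    p: np.ndarray
    n_permutations: int
    alpha: float = 0.05
    node_ids: Optional[Tuple[str, ...]] = None

    @property
    def significant(self) -> np.ndarray:
        return self.p < self.alpha

    def to_frame(self) -> pd.DataFrame:
        units = (
            list(self.node_ids)
            if self.node_ids is not None
            else list(range(len(self.t)))
        )
        return pd.DataFrame(
            {
                "unit": units,
                "t": self.t,
                "tfce": self.tfce,
                "p": self.p,
                "significant": self.significant,
            }
        )


def _sign_matrix(n_subjects: int, n_permutations: int, seed: int) -> np.ndarray:
    if 2**n_subjects <= EXHAUSTIVE_LIMIT:
        bits = np.arange(2**n_subjects)
        signs = ((bits[:, None] >> np.arange(n_subjects)[None, :]) & 1) * 2 - 1
        return signs.astype(float)
    rng = np.random.default_rng(seed)
    return rng.choice([-1.0, 1.0], size=(n_permutations, n_subjects))


def sign_flip_permutation_test(
    scores: np.ndarray,
    adjacency: AdjacencyGraph,
    n_permutations: int = 1024,
    seed: int = 0,
    E: float = 0.5,
    H: float = 2.0,
    dh: float = 0.1,
    alpha: float = 0.05,
) -> GroupStatResult:
    """One-tailed one-sample permutation test with TFCE and max-null
    family-wise correction.

    corrected p(u) = (1 + #{perm max >= observed enhanced(u)}) /
    (1 + n_permutations); the +1 smoothing keeps p strictly positive.
    Deterministic given ``seed``; exhaustive enumeration replaces random
    draws when 2**n_subjects <= 4096.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise InvalidInputError("scores must be (>=3 subjects, units)")
    if n_permutations < 100:
        raise InvalidConfigError("n_permutations must be >= 100")
    if x.shape[1] != adjacency.n_nodes:
        raise InvalidInputError("unit count must match adjacency")

    n_sub = x.shape[0]
    t_obs = one_sample_t(x)
    tfce_obs = tfce(t_obs, adjacency, E=E, H=H, dh=dh)

    signs = _sign_matrix(n_sub, n_permutations, seed)
    n_perm = signs.shape[0]
    # sign flips leave per-unit sums of squares unchanged, so all permuted
    # t maps follow from one matrix product
    means = (signs @ x) / n_sub
    ssq = (x**2).sum(axis=0)
    var = (ssq[None, :] - n_sub * means**2) / (n_sub - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_null = means / np.sqrt(var / n_sub)
    t_null[var == 0] = 0.0

    null_max = np.empty(n_perm)
    for p in range(n_perm):
        null_max[p] = tfce(t_null[p], adjacency, E=E, H=H, dh=dh).max(initial=0.0)
    null_sorted = np.sort(null_max)
    n_ge = n_perm - np.searchsorted(null_sorted, tfce_obs, side="left")
    p_corr = (1.0 + n_ge) / (1.0 + n_perm)
    return GroupStatResult(
        t=t_obs,
        tfce=tfce_obs,
        p=p_corr,
        n_permutations=n_perm,
        alpha=alpha,
        node_ids=adjacency.node_ids,
    )


def paired_difference_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    adjacency: AdjacencyGraph,
    **kwargs,
) -> GroupStatResult:
    """One-tailed test of model A > model B via the per-subject differences."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("paired score matrices must share a shape")
    return sign_flip_permutation_test(a - b, adjacency, **kwargs)
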