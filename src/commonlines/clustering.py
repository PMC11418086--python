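"""Clustering discretely heterogeneous common lines into homogeneous sets.

Four images drawn from one molecule yield an 8x4 common-lines submatrix
that can be scaled to satisfy the rank-3 and quadratic constraints;
four images spanning different molecules cannot (their cross blocks are
geometrically meaningless).  The algorithm scores many random 4-subsets
by running the denoise (IRLS-ADMM) + Sinkhorn pipeline on the submatrix
and recording the residual quadratic-constraint error, views the scored
subsets as a weighted 4-uniform hypergraph, flattens it to a weighted
graph (pair weight = -log of the smallest error over hyperedges holding
both images), and extracts communities with the local-fitness method of
Lancichinetti, Fortunato and Kertesz (LFK).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .constraints import quadratic_error, rank3_gap
from .denoise import AdmmParams, irls_admm, normalize_blocks
from .geometry import CommonLinesMatrix
from .scaling import sinkhorn

__all__ = [
    "ClusterParams",
    "ClusterResult",
    "RejectReason",
    "SampleScore",
    "WeightedGraph",
    "build_adjacency",
    "cluster_common_lines",
    "lfk_communities",
    "sample_and_score",
    "score_sample",
]


class RejectReason(str, Enum):
    NONE = "none"
    DIVERGED = "diverged"
    NO_RANK3_GAP = "no_rank3_gap"


@dataclass
class SampleScore:
    quadruple: tuple[int, int, int, int]
    error: float
    accepted: bool
    reject_reason: RejectReason = RejectReason.NONE


@dataclass
class WeightedGraph:
    n_nodes: int
    weights: np.ndarray  # symmetric, >= 0, zero diagonal
    covered: np.ndarray  # symmetric bool: pair seen by an accepted sample


@dataclass
class ClusterResult:
    partition: np.ndarray  # community id per image index
    n_samples_used: int
    per_sample: list[SampleScore]
    communities: list[set[int]] = field(default_factory=list)


@dataclass
class ClusterParams:
    """Configuration of the sampling / scoring / community pipeline.

    The solver caps are much lighter than the standalone denoiser
    defaults: the 8x4 subproblems converge (or visibly stall) quickly,
    and tens of thousands of them are solved per dataset.
    """

    budget: int | None = None  # default 50 * n
    alpha: float = 1.0  # LFK resolution parameter
    gap_threshold: float = 0.1  # max sigma4/sigma3 for numerical rank 3
    tau_floor: float = 0.2  # reject fits with vanishing block scales
    error_floor: float = 1e-12
    keep_frac: float = 1.0  # retain this fraction of accepted samples (best first)
    admm: AdmmParams = field(
        default_factory=lambda: AdmmParams(
            outer_iters=5, admm_iters=25, inner_iters=5, tol=1e-9
        )
    )
    sinkhorn_iters: int = 150
    sinkhorn_tol: float = 1e-12
    # shift pair weights by the median accepted log-error so that the
    # background (inconsistent-sample) level sits at zero; without it a
    # noise floor common to all pairs swamps the community structure
    background_calibration: bool = True


def _submatrix(A: CommonLinesMatrix, S: tuple[int, ...]) -> CommonLinesMatrix:
    idx = np.asarray(S)
    blocks = A.blocks()[np.ix_(idx, idx)]
    return CommonLinesMatrix.from_blocks(blocks, check=False)


def score_sample(
    A: CommonLinesMatrix, S, params: ClusterParams | None = None
) -> SampleScore:
    """Constraint-satisfaction score of one 4-subset of images."""
    if params is None:
        params = ClusterParams()
    S = tuple(int(s) for s in S)
    if len(S) != 4 or len(set(S)) != 4:
        raise ValueError("sample must contain 4 distinct indices")
    if min(S) < 0 or max(S) >= A.n:
        raise ValueError("sample index out of range")
    sub = _submatrix(A, S)
    den = irls_admm(sub, params.admm)
    if den.diverged:
        return SampleScore(S, np.inf, False, RejectReason.DIVERGED)
    # vanishing block scales: an inconsistent image can be "explained"
    # by shrinking all its blocks to zero, faking a consistent sample;
    # such degenerate fits are discarded, like vanishing Sinkhorn scales
    toff = np.abs(den.T[~np.eye(sub.n, dtype=bool)])
    if toff.min() < params.tau_floor * np.median(toff):
        return SampleScore(S, np.inf, False, RejectReason.DIVERGED)
    # numerical-rank-3 test on the data scaled by the fitted per-block
    # scales: "can these common lines be scaled to rank 3 at all?"
    sub_unit = normalize_blocks(sub)
    scaled_data = CommonLinesMatrix.from_blocks(
        den.T[:, :, None] * sub_unit.blocks(), check=False
    )
    s3, s4 = rank3_gap(scaled_data)
    if s3 <= 0 or s4 / s3 > params.gap_threshold:
        return SampleScore(S, np.inf, False, RejectReason.NO_RANK3_GAP)
    scaled, state = sinkhorn(den.X, params.sinkhorn_iters, params.sinkhorn_tol)
    if state.diverged:
        return SampleScore(S, np.inf, False, RejectReason.DIVERGED)
    err = quadratic_error(scaled)
    return SampleScore(S, err, True, RejectReason.NONE)


def sample_and_score(
    A: CommonLinesMatrix,
    budget: int,
    seed: int,
    params: ClusterParams | None = None,
) -> list[SampleScore]:
    """Score ``budget`` i.i.d. uniform 4-subsets (deterministic per seed)."""
    if params is None:
        params = ClusterParams()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(budget):
        S = tuple(sorted(rng.choice(A.n, size=4, replace=False).tolist()))
        out.append(score_sample(A, S, params))
    return out


def build_adjacency(
    samples: list[SampleScore], n: int, error_floor: float = 1e-12
) -> WeightedGraph:
    """Flatten scored 4-subsets to pair weights -log(min error over samples)."""
    weights = np.zeros((n, n))
    covered = np.zeros((n, n), dtype=bool)
    best = np.full((n, n), np.inf)
    for s in samples:
        if not s.accepted:
            continue
        e = max(s.error, error_floor)
        q = s.quadruple
        for a in range(4):
            for b in range(a + 1, 4):
                i, j = q[a], q[b]
                covered[i, j] = covered[j, i] = True
                if e < best[i, j]:
                    best[i, j] = best[j, i] = e
    mask = np.isfinite(best)
    weights[mask] = np.clip(-np.log(best[mask]), 0.0, None)
    np.fill_diagonal(weights, 0.0)
    np.fill_diagonal(covered, False)
    return WeightedGraph(n_nodes=n, weights=weights, covered=covered)


def _fitness(W: np.ndarray, members: np.ndarray, alpha: float) -> float:
    """LFK community fitness s_in / (s_in + s_out)^alpha on edge strengths."""
    sub = W[np.ix_(members, members)]
    s_in = float(sub.sum())  # each internal edge counted twice
    s_tot = float(W[members].sum())  # internal (twice) + boundary
    s_out = s_tot - s_in
    if s_in + s_out == 0.0:
        return 0.0
    return s_in / (s_in + s_out) ** alpha


def _grow_community(W: np.ndarray, seed_node: int, alpha: float) -> set[int]:
    """Grow one natural community by greedy fitness ascent with pruning.

    Incremental bookkeeping: for a member set C, the fitness is
    s_in / s_tot^alpha where s_in sums internal weights (both
    directions) and s_tot the total strength of the members; adding v
    changes them by 2 w(v, C) and strength(v).
    """
    n = W.shape[0]
    strength = W.sum(axis=1)
    mask = np.zeros(n, dtype=bool)
    mask[seed_node] = True
    wC = W[:, seed_node].copy()  # each node's total weight into C
    s_in = 0.0
    s_tot = strength[seed_node]

    def fit(si, st):
        return si / st**alpha if st > 0 else 0.0

    # cap guards against add/prune oscillation on near-tied fitness
    for _ in range(4 * n):
        fC = fit(s_in, s_tot)
        cand = (~mask) & (wC > 0)
        if not np.any(cand):
            break
        f_new = np.where(
            cand, (s_in + 2 * wC) / np.maximum(s_tot + strength, 1e-300) ** alpha, -np.inf
        )
        v = int(np.argmax(f_new))
        if f_new[v] <= fC + 1e-15:
            break
        mask[v] = True
        s_in += 2 * wC[v]
        s_tot += strength[v]
        wC = wC + W[:, v]
        # prune members whose node fitness went negative
        for _ in range(2 * n):
            if mask.sum() <= 1:
                break
            fC = fit(s_in, s_tot)
            members = np.where(mask)[0]
            f_without = (s_in - 2 * wC[members]) / np.maximum(
                s_tot - strength[members], 1e-300
            ) ** alpha
            node_fit = fC - f_without
            worst = int(np.argmin(node_fit))
            if node_fit[worst] >= -1e-15 or members[worst] == v:
                break
            u = members[worst]
            mask[u] = False
            s_in -= 2 * wC[u]
            s_tot -= strength[u]
            wC = wC - W[:, u]
    return set(np.where(mask)[0].tolist())


def lfk_communities(G: WeightedGraph, alpha: float = 1.0) -> list[set[int]]:
    """LFK natural communities; raw output may overlap.

    Seeds are taken in order of decreasing node strength among nodes not
    yet assigned to any community; zero-strength nodes become singletons.
    """
    W = G.weights
    strength = W.sum(axis=0)
    unassigned = set(range(G.n_nodes))
    communities: list[set[int]] = []
    while unassigned:
        seed_node = max(unassigned, key=lambda v: (strength[v], -v))
        if strength[seed_node] == 0.0:
            communities.append({seed_node})
            unassigned.discard(seed_node)
            continue
        C = _grow_community(W, seed_node, alpha)
        communities.append(C if C else {seed_node})
        # the seed counts as visited even if pruning removed it
        unassigned -= C | {seed_node}
    return communities


def _resolve_overlaps(
    communities: list[set[int]], W: np.ndarray, alpha: float, n: int
) -> np.ndarray:
    """Hard partition: each node goes to the community where its node
    fitness is largest; ties break toward the lower community id."""
    partition = np.full(n, -1, dtype=int)
    membership: dict[int, list[int]] = {}
    for cid, C in enumerate(communities):
        for v in C:
            membership.setdefault(v, []).append(cid)
    for v in range(n):
        cids = membership.get(v, [])
        if not cids:  # pruned out of every community: singleton
            partition[v] = len(communities) + v
            continue
        if len(cids) == 1:
            partition[v] = cids[0]
            continue
        best_fit, best_cid = -np.inf, None
        for cid in sorted(cids):
            members = np.fromiter(communities[cid], dtype=int)
            rest = members[members != v]
            fit = _fitness(W, members, alpha) - (
                _fitness(W, rest, alpha) if len(rest) else 0.0
            )
            if fit > best_fit + 1e-15:
                best_fit, best_cid = fit, cid
        partition[v] = best_cid
    # compact ids
    _, partition = np.unique(partition, return_inverse=True)
    return partition


def _refine_partition(partition: np.ndarray, W: np.ndarray, alpha: float, sweeps: int = 2) -> np.ndarray:
    """Local refinement: move each node to the community where its node
    fitness is largest.  Rescues nodes whose own community membership is
    supported by few sampled quadruples."""
    part = partition.copy()
    n = len(part)
    for _ in range(sweeps):
        moved = False
        for v in range(n):
            best_fit, best_c = -np.inf, part[v]
            for c in np.unique(part):
                members = np.where(part == c)[0]
                with_v = members if v in members else np.append(members, v)
                without_v = members[members != v]
                fit = _fitness(W, with_v, alpha) - (
                    _fitness(W, without_v, alpha) if len(without_v) else 0.0
                )
                if fit > best_fit + 1e-15:
                    best_fit, best_c = fit, c
            if best_c != part[v]:
                part[v] = best_c
                moved = True
        if not moved:
            break
    _, part = np.unique(part, return_inverse=True)
    return part


def cluster_common_lines(
    A: CommonLinesMatrix,
    params: ClusterParams | None = None,
    seed: int = 0,
    warn_coverage: float = 0.8,
) -> ClusterResult:
    """Full heterogeneity-clustering pipeline on a common-lines matrix."""
    import warnings

    if params is None:
        params = ClusterParams()
    if A.n < 5:
        raise ValueError("clustering needs n >= 5")
    budget = params.budget if params.budget is not None else 50 * A.n
    samples = sample_and_score(A, budget, seed, params)
    accepted = sorted(
        (s for s in samples if s.accepted), key=lambda s: s.error
    )
    kept = accepted[: max(1, int(np.ceil(params.keep_frac * len(accepted))))]
    G = build_adjacency(kept, A.n, params.error_floor)
    if params.background_calibration and kept:
        bg = float(np.median([s.error for s in kept]))
        W = G.weights.copy()
        W[W > 0] = np.maximum(0.0, W[W > 0] + np.log(max(bg, params.error_floor)))
        G = WeightedGraph(G.n_nodes, W, G.covered)
    frac = G.covered.sum() / max(A.n * (A.n - 1), 1)
    if frac < warn_coverage:
        warnings.warn(
            f"only {100 * frac:.0f}% of pairs covered by accepted samples; "
            "consider a larger budget"
        )
    communities = lfk_communities(G, params.alpha)
    partition = _resolve_overlaps(communities, G.weights, params.alpha, A.n)
    partition = _refine_partition(partition, G.weights, params.alpha)
    return ClusterResult(
        partition=partition,
        n_samples_used=len(kept),
        per_sample=samples,
        communities=communities,
    )
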