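"""Spatial analysis of molecular variance (SAMOVA).

Populations are partitioned into K groups so as to maximise the
among-group fixation index Phi_CT.  Initial partitions are geographic:
K seed populations are drawn at random and every other population joins
its nearest seed by great-circle distance, so starting configurations
are made of geographically adjacent populations.  A simulated-annealing
search then proposes single-population moves between groups (a move is
valid only if the donor group stays non-empty), accepting by the
Metropolis rule on the change in Phi_CT with geometric cooling.
Contiguity is encouraged by the initialisation but not enforced during
the search.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, InputError
from .amova import _components
from .haplotypes import DistanceMatrix
from .spatial import great_circle_km

__all__ = ["SamovaResult", "samova", "samova_scan", "fct_plateau"]


@dataclass
class SamovaResult:
    k: int
    partition: list[list[str]]      # groups of population labels
    fct: float
    n_starts: int
    seed: int | None = None
    start_fcts: list[float] = field(default_factory=list)

    def group_map(self) -> dict[str, str]:
        return {p: f"G{i + 1}" for i, grp in enumerate(self.partition) for p in grp}


def _fct_of_partition(group_of: np.ndarray, W: np.ndarray, B: np.ndarray,
                      n_k: np.ndarray) -> float:
    try:
        phi = _components(W, B, n_k, group_of)["phi"]["FCT"]
    except AnalysisError:
        return float("nan")
    return phi


def _geographic_seeding(pop_names, coords, k, rng) -> np.ndarray:
    P = len(pop_names)
    seeds = rng.choice(P, size=k, replace=False)
    group_of = np.empty(P, dtype=int)
    for i, p in enumerate(pop_names):
        lat, lon = coords[p]
        dists = [great_circle_km(lat, lon, *coords[pop_names[s]]) for s in seeds]
        group_of[i] = int(np.argmin(dists))
    for g, s in enumerate(seeds):  # seeds always belong to their own group
        group_of[s] = g
    # guarantee non-empty groups (possible collisions for coincident coordinates)
    for g in range(k):
        if not np.any(group_of == g):
            donors = [i for i in range(P) if np.sum(group_of == group_of[i]) > 1]
            group_of[rng.choice(donors)] = g
    return group_of


def samova(
    table_counts,
    dist,
    coords: dict[str, tuple[float, float]],
    k: int,
    n_starts: int = 100,
    n_proposals: int = 10_000,
    cooling: float = 0.95,
    cool_every: int = 100,
    seed: int | None = None,
) -> SamovaResult:
    """Search the best K-group partition of populations by Phi_CT.

    ``table_counts`` is a population × haplotype count DataFrame (e.g.
    ``HaplotypeTable.counts``), ``dist`` the matching haplotype distance
    matrix and ``coords`` population -> (lat, lon) decimal degrees.
    The defaults (100 restarts of 10,000 proposals, initial temperature
    calibrated so roughly half of early proposals accept, cooling 0.95
    every 100 proposals) are deliberately generous; small problems are
    solved exactly long before the schedule ends.
    """
    counts = np.asarray(table_counts, dtype=float)
    pop_names = list(table_counts.index)
    P = len(pop_names)
    if not 2 <= k <= P:
        raise InputError(f"K={k} out of range for {P} populations")
    missing = [p for p in pop_names if p not in coords]
    if missing:
        raise InputError(f"populations without coordinates: {missing}")
    d2 = dist.matrix if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    n_k = counts.sum(axis=1)
    # expand counts back to aggregates
    B = counts @ d2 @ counts.T
    W = np.diag(B) / 2.0

    if k == P:
        group_of = np.arange(P)
        fct = _fct_of_partition(group_of, W, B, n_k)
        return SamovaResult(k, [[p] for p in pop_names], fct, n_starts=0, seed=seed)

    rng = np.random.default_rng(seed)
    best_fct = -math.inf
    best_group = None
    start_fcts = []
    for _ in range(n_starts):
        group_of = _geographic_seeding(pop_names, coords, k, rng)
        cur = _fct_of_partition(group_of, W, B, n_k)
        if math.isnan(cur):
            cur = -math.inf
        # calibrate temperature from a sample of proposal deltas
        deltas = []
        for _ in range(25):
            move = _propose(group_of, k, rng)
            if move is None:
                continue
            p_i, g_new, g_old = move
            group_of[p_i] = g_new
            nxt = _fct_of_partition(group_of, W, B, n_k)
            group_of[p_i] = g_old
            if not math.isnan(nxt) and cur > -math.inf:
                deltas.append(abs(nxt - cur))
        t = max(float(np.median(deltas)) if deltas else 1e-3, 1e-9) / math.log(2.0)

        local_best, local_best_group = cur, group_of.copy()
        for step in range(n_proposals):
            move = _propose(group_of, k, rng)
            if move is None:
                break
            p_i, g_new, g_old = move
            group_of[p_i] = g_new
            nxt = _fct_of_partition(group_of, W, B, n_k)
            accept = False
            if not math.isnan(nxt):
                delta = nxt - (cur if cur > -math.inf else nxt - 1.0)
                if delta >= 0 or rng.random() < math.exp(delta / t):
                    accept = True
            if accept:
                cur = nxt
                if cur > local_best:
                    local_best, local_best_group = cur, group_of.copy()
            else:
                group_of[p_i] = g_old
            if (step + 1) % cool_every == 0:
                t = max(t * cooling, 1e-12)
        start_fcts.append(local_best)
        if local_best > best_fct:
            best_fct, best_group = local_best, local_best_group

    if best_group is None:
        raise AnalysisError("SAMOVA found no valid partition (zero variance?)")
    partition = [[pop_names[i] for i in np.where(best_group == g)[0]] for g in range(k)]
    partition = [grp for grp in partition if grp]
    return SamovaResult(k, partition, best_fct, n_starts=n_starts, seed=seed,
                        start_fcts=start_fcts)


def _propose(group_of: np.ndarray, k: int, rng) -> tuple[int, int, int] | None:
    """Pick a population whose group keeps >= 1 member after the move."""
    sizes = np.bincount(group_of, minlength=k)
    movable = np.where(sizes[group_of] > 1)[0]
    if movable.size == 0:
        return None
    p_i = int(rng.choice(movable))
    g_old = int(group_of[p_i])
    g_new = int(rng.integers(k - 1))
    if g_new >= g_old:
        g_new += 1
    return p_i, g_new, g_old


def samova_scan(table_counts, dist, coords, k_range=range(2, 11), **kwargs) -> dict[int, SamovaResult]:
    """Run :func:`samova` over a contiguous range of K values."""
    return {k: samova(table_counts, dist, coords, k, **kwargs) for k in k_range}


def fct_plateau(trajectory: dict[int, float], tol: float = 0.01) -> int:
    """Smallest K whose Phi_CT is within ``tol`` (relative) of the
    running maximum over all larger-or-equal K.

    A strictly increasing trajectory with no plateau returns the largest
    K with a warning; a constant trajectory returns the smallest K.
    """
    ks = sorted(trajectory)
    if not ks:
        raise InputError("empty trajectory")
    fcts = [trajectory[k] for k in ks]
    # M_K = max Phi_CT over K' >= K
    tail_max = list(np.maximum.accumulate(fcts[::-1]))[::-1]
    for i, (k, f, m) in enumerate(zip(ks, fcts, tail_max)):
        if f >= m - tol * abs(m):
            if i == len(ks) - 1 and len(ks) > 1 and all(
                fcts[j] < fcts[j + 1] for j in range(len(ks) - 1)
            ):
                warnings.warn("Phi_CT increases up to the largest K; no plateau detected")
            return k
    # unreachable (the largest K always satisfies f == M), kept for safety
    warnings.warn("Phi_CT increases up to the largest K; no plateau detected")
    return ks[-1]
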