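"""Coalescent-style synthetic data with known parameters.

A compact structured-coalescent simulator used for calibration and
recovery tests: Kingman coalescent within demes, island-model migration
between demes, piecewise-constant population size (constant or a sudden
expansion from theta0 to theta1), and infinite-sites mutations dropped
on branches and placed at distinct alignment columns.

Scaling conventions (documented rather than configurable):

* time is measured in units of 2*N_present generations, so a pair of
  lineages in one deme coalesces at rate 1 (times the inverse relative
  deme size);
* mutations arrive on each lineage at rate theta/2 per unit time, so a
  pair separated for the whole stationary history carries theta
  differences on average and Watterson's E[S] = theta * a1 holds;
* for a sudden expansion the size drops from relative size 1 to
  theta0/theta1 at scaled time tau/theta1 in the past, which is the
  event horizon tau mutational units before the present;
* the island-model ``migration`` parameter is the per-lineage rate of
  moving to a uniformly chosen other deme, per unit coalescent time.

The simulator is intentionally minimal (no recombination, no selection)
and is cross-checked against msprime in an integration test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, InputError
from .io import Alignment, Population, PopulationMap

__all__ = [
    "SimSpec",
    "simulate_dataset",
    "simulate_sudden_expansion",
    "simulate_genealogy",
    "simulate_mismatch_counts",
    "simulate_sample_stats",
]


@dataclass
class SimSpec:
    """Parameters of a simulated multi-population dataset.

    ``theta`` is the per-deme, per-locus scaled mutation rate; with
    ``expansion=(tau, theta0)`` the present theta plays the role of
    theta1 in the sudden-expansion model.
    """

    sample_sizes: list[int]
    theta: float = 5.0
    migration: float = 1.0
    L: int = 1000
    expansion: tuple[float, float] | None = None  # (tau, theta0)
    pop_labels: list[str] | None = None
    grid_origin: tuple[float, float] = (29.0, 92.0)
    grid_step_deg: float = 1.0

    def __post_init__(self) -> None:
        if not self.sample_sizes or any(s < 1 for s in self.sample_sizes):
            raise InputError("sample_sizes must be positive")
        if self.theta < 0 or self.migration < 0 or self.L < 1:
            raise InputError("rates must be non-negative and L >= 1")
        if len(self.sample_sizes) > 1 and self.migration <= 0:
            raise InputError("multiple demes need a positive migration rate")
        if self.pop_labels is None:
            self.pop_labels = [f"P{i + 1}" for i in range(len(self.sample_sizes))]


@dataclass
class _Genealogy:
    n: int
    masks: list[int]       # leaf bitmask per branch (descendants of the child node)
    lengths: list[float]   # branch length in scaled time units


def simulate_genealogy(
    sample_sizes: list[int],
    migration: float,
    rng: np.random.Generator,
    size_change: tuple[float, float] | None = None,
) -> _Genealogy:
    """Simulate a structured-coalescent genealogy.

    ``size_change=(t_event, rel_size)`` switches the relative deme size
    from 1 to ``rel_size`` at scaled time ``t_event`` looking backward.
    Returns one mask + accumulated length per branch of the tree.
    """
    n_demes = len(sample_sizes)
    n = sum(sample_sizes)
    lineages: list[tuple[int, int]] = []  # (leaf mask, deme)
    idx = 0
    for d, size in enumerate(sample_sizes):
        for _ in range(size):
            lineages.append((1 << idx, d))
            idx += 1
    t = 0.0
    rel_size = 1.0
    t_event = math.inf
    if size_change is not None:
        t_event, later_size = size_change
    masks: list[int] = []
    lengths: list[float] = []
    birth: dict[int, float] = {m: 0.0 for m, _ in lineages}

    while len(lineages) > 1:
        per_deme: dict[int, int] = {}
        for _, d in lineages:
            per_deme[d] = per_deme.get(d, 0) + 1
        coal_rate = sum(k * (k - 1) / 2.0 for k in per_deme.values()) / rel_size
        mig_rate = migration * len(lineages) if n_demes > 1 else 0.0
        total = coal_rate + mig_rate
        if total <= 0:
            raise AnalysisError("lineages cannot coalesce (no migration between demes)")
        wait = rng.exponential(1.0 / total)
        if t < t_event <= t + wait:
            t = t_event
            rel_size = later_size
            t_event = math.inf
            continue
        t += wait
        if rng.random() < coal_rate / total:
            # choose a deme weighted by its pair count, then a pair in it
            demes, weights = zip(*[(d, k * (k - 1) / 2.0) for d, k in per_deme.items() if k >= 2])
            d = demes[rng.choice(len(demes), p=np.asarray(weights) / sum(weights))]
            members = [i for i, (_, dd) in enumerate(lineages) if dd == d]
            i, j = rng.choice(len(members), size=2, replace=False)
            a, b = members[i], members[j]
            (ma, _), (mb, _) = lineages[a], lineages[b]
            for m in (ma, mb):
                masks.append(m)
                lengths.append(t - birth.pop(m))
            merged = ma | mb
            lineages = [l for x, l in enumerate(lineages) if x not in (a, b)]
            lineages.append((merged, d))
            birth[merged] = t
        else:
            x = int(rng.integers(len(lineages)))
            m, d = lineages[x]
            d_new = int(rng.integers(n_demes - 1))
            if d_new >= d:
                d_new += 1
            lineages[x] = (m, d_new)
    return _Genealogy(n=n, masks=masks, lengths=lengths)


def _drop_mutations(gen: _Genealogy, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Infinite-sites genotypes: n x S 0/1 matrix (columns in mutation order)."""
    cols = []
    for mask, length in zip(gen.masks, gen.lengths):
        k = rng.poisson(theta / 2.0 * length)
        if k:
            col = np.array([(mask >> i) & 1 for i in range(gen.n)], dtype=np.int8)
            cols.extend([col] * k)
    if not cols:
        return np.zeros((gen.n, 0), dtype=np.int8)
    return np.column_stack(cols)


def _pairwise_diff_matrix(geno: np.ndarray) -> np.ndarray:
    g = geno.astype(np.int32)
    ones = 1 - g
    return g @ ones.T + ones @ g.T


def _genotypes_to_alignment(geno: np.ndarray, L: int, ids: list[str],
                            rng: np.random.Generator) -> Alignment:
    n, S = geno.shape
    if S > L:
        raise AnalysisError(f"{S} mutations exceed {L} sites; raise L or lower theta")
    bases = np.array(list("ACGT"))
    ancestral = rng.integers(4, size=L)
    positions = rng.choice(L, size=S, replace=False)
    seq_idx = np.tile(ancestral, (n, 1))
    for s, pos in enumerate(positions):
        alt = (ancestral[pos] + 1 + rng.integers(3)) % 4
        seq_idx[geno[:, s] == 1, pos] = alt
    seqs = ["".join(bases[row]) for row in seq_idx]
    return Alignment(list(ids), seqs)


def simulate_dataset(spec: SimSpec, seed: int | None = None) -> tuple[Alignment, PopulationMap]:
    """Simulate an aligned sample under the island model.

    Population coordinates are laid out on a lat/lon grid purely so the
    spatial machinery (SAMOVA seeding, Mantel) has something to chew on.
    """
    rng = np.random.default_rng(seed)
    size_change = None
    if spec.expansion is not None:
        tau, theta0 = spec.expansion
        if spec.theta <= 0:
            raise InputError("expansion needs theta > 0")
        size_change = (tau / spec.theta, theta0 / spec.theta)
    gen = simulate_genealogy(spec.sample_sizes, spec.migration, rng, size_change)
    geno = _drop_mutations(gen, spec.theta, rng)
    ids = []
    assignments = {}
    populations = {}
    side = math.ceil(math.sqrt(len(spec.sample_sizes)))
    for p, (label, size) in enumerate(zip(spec.pop_labels, spec.sample_sizes)):
        lat = spec.grid_origin[0] + (p // side) * spec.grid_step_deg
        lon = spec.grid_origin[1] + (p % side) * spec.grid_step_deg
        populations[label] = Population(label, lat, lon)
        for i in range(size):
            ind = f"{label}_{i + 1:02d}"
            ids.append(ind)
            assignments[ind] = label
    aln = _genotypes_to_alignment(geno, spec.L, ids, rng)
    return aln, PopulationMap(assignments, populations)


def simulate_sudden_expansion(n: int, L: int, tau: float, theta0: float,
                              theta1: float, seed: int | None = None) -> Alignment:
    """Single-population coalescent under a stepwise size change.

    theta1 is the present-day scaled mutation rate, theta0 the ancestral
    one; the change sits tau mutational units in the past.  tau = 0 or
    theta0 = theta1 reduce to the constant-size coalescent.
    """
    if tau < 0 or theta0 < 0 or theta1 <= 0:
        raise InputError("need tau >= 0, theta0 >= 0, theta1 > 0")
    rng = np.random.default_rng(seed)
    size_change = (tau / theta1, theta0 / theta1) if tau > 0 or theta0 != theta1 else None
    if size_change is not None and size_change[1] <= 0:
        size_change = (size_change[0], 1e-9)  # theta0 = 0: essentially instant ancestral coalescence
    gen = simulate_genealogy([n], 0.0, rng, size_change)
    geno = _drop_mutations(gen, theta1, rng)
    ids = [f"I{i + 1:03d}" for i in range(n)]
    return _genotypes_to_alignment(geno, L, ids, rng)


def simulate_mismatch_counts(n: int, tau: float, theta0: float, theta1: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Pairwise difference counts (length n(n-1)/2) under sudden expansion.

    Sequence-free fast path for the parametric bootstrap: mutations are
    dropped on the genealogy and only the pairwise Hamming counts kept.
    """
    theta0 = max(theta0, 0.0)
    size_change = (tau / theta1, max(theta0 / theta1, 1e-9)) if tau > 0 or theta0 != theta1 else None
    gen = simulate_genealogy([n], 0.0, rng, size_change)
    geno = _drop_mutations(gen, theta1, rng)
    dm = _pairwise_diff_matrix(geno)
    iu = np.triu_indices(n, k=1)
    return dm[iu].astype(int)


def simulate_sample_stats(n: int, theta: float,
                          rng: np.random.Generator) -> tuple[float, int, int]:
    """(mean pairwise differences, number of distinct alleles, S) for one
    constant-size neutral sample -- the ingredients of the neutrality tests."""
    gen = simulate_genealogy([n], 0.0, rng, None)
    geno = _drop_mutations(gen, theta, rng)
    S = geno.shape[1]
    if S == 0:
        return 0.0, 1, 0
    dm = _pairwise_diff_matrix(geno)
    iu = np.triu_indices(n, k=1)
    k_hat = float(dm[iu].mean())
    alleles = len({row.tobytes() for row in geno})
    return k_hat, alleles, S
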