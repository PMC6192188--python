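"""Gene diversity, nucleotide diversity, and PERMUT-style differentiation.

Per-population and species-level statistics follow Nei's unbiased
estimators:

    h  = n/(n-1) * (1 - sum p_i^2)
    pi = n/(n-1) * sum_{i != j} p_i p_j d_ij / L

Differentiation among populations follows the Pons & Petit framework:
HS is the (unweighted, by default) mean of per-population unbiased gene
diversities, HT the total diversity computed from the unweighted mean
haplotype frequencies with a harmonic-mean sample-size correction, and
GST = 1 - HS/HT.  vS, vT and NST are the ordered-allele analogues in
which every term is weighted by the inter-haplotype distance d_ij;
NST > GST indicates phylogeographic structure (closely related
haplotypes co-occurring in the same area), tested by permuting haplotype
identities over the distance matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .haplotypes import DistanceMatrix, HaplotypeTable

__all__ = [
    "gene_diversity",
    "nucleotide_diversity",
    "diversity_table",
    "DifferentiationResult",
    "permut_statistics",
    "nst_gst_test",
]


def gene_diversity(counts) -> tuple[float, float]:
    """Unbiased gene (haplotype) diversity h and its standard deviation.

    ``counts`` are haplotype counts for one sampling unit.  The SD comes
    from Nei's (1987) sampling variance of heterozygosity:

        V(h) = 2/(n(n-1)) * { 2(n-2) [ sum p^3 - (sum p^2)^2 ]
                              + sum p^2 - (sum p^2)^2 }
    """
    c = np.asarray([x for x in np.ravel(counts) if x > 0], dtype=float)
    n = c.sum()
    if n < 2:
        raise AnalysisError("gene diversity needs at least 2 sequences")
    p = c / n
    sum2 = float(np.sum(p**2))
    sum3 = float(np.sum(p**3))
    h = n / (n - 1.0) * (1.0 - sum2)
    var = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (sum3 - sum2**2) + sum2 - sum2**2)
    return h, math.sqrt(max(var, 0.0))


def nucleotide_diversity(counts, dist, L: float) -> tuple[float, float]:
    """Unbiased nucleotide diversity (per site) and an approximate SD.

    ``dist`` is the haplotype DistanceMatrix (or a plain array) aligned
    with ``counts``.  The SD uses the no-recombination variance
    approximation (Nei 1987, eq. 10.7):

        V(pi) = (n+1)/(3(n-1)L) * pi  +  2(n^2+n+3)/(9n(n-1)) * pi^2
    """
    if L <= 0:
        raise AnalysisError("alignment length must be positive")
    c = np.asarray(np.ravel(counts), dtype=float)
    d = dist.matrix if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    n = c.sum()
    if n < 2:
        raise AnalysisError("nucleotide diversity needs at least 2 sequences")
    p = c / n
    mean_pair = float(p @ d @ p)  # sum over ordered pairs i != j (diagonal is 0)
    pi = n / (n - 1.0) * mean_pair / L
    var = (n + 1.0) / (3.0 * (n - 1.0) * L) * pi + 2.0 * (n**2 + n + 3.0) / (
        9.0 * n * (n - 1.0)
    ) * pi**2
    return pi, math.sqrt(max(var, 0.0))


def diversity_table(table: HaplotypeTable, dist: DistanceMatrix | None = None,
                    L: float | None = None) -> pd.DataFrame:
    """One row per population plus a pooled 'Total' row: N, h, h_sd[, pi, pi_sd]."""
    rows = {}
    units = [(p, table.counts.loc[p].to_numpy()) for p in table.populations]
    units.append(("Total", table.total_counts.to_numpy()))
    for name, counts in units:
        n = int(counts.sum())
        if n >= 2:
            h, h_sd = gene_diversity(counts)
        else:
            h, h_sd = float("nan"), float("nan")
        row = {"N": n, "h": h, "h_sd": h_sd}
        if dist is not None and L is not None and n >= 2:
            pi, pi_sd = nucleotide_diversity(counts, dist, L)
            row.update(pi=pi, pi_sd=pi_sd)
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class DifferentiationResult:
    """Pons & Petit differentiation statistics, optionally with the
    NST > GST permutation p-value."""

    hs: float
    ht: float
    gst: float
    vs: float | None = None
    vt: float | None = None
    nst: float | None = None
    ht_uncorrected: float | None = None
    gst_uncorrected: float | None = None
    p_value: float | None = None
    n_perm: int | None = None
    seed: int | None = None
    flags: tuple[str, ...] = ()


def _pons_petit(counts: np.ndarray, weight: np.ndarray, weighted_mean: bool,
                estimator: str) -> tuple[float, float, float, float]:
    """Core HS/HT (or vS/vT) machinery.

    ``weight`` is the matrix applied to frequency cross-products: the
    all-ones-off-diagonal matrix yields the unordered statistics, the
    distance matrix the ordered ones.  Returns (HS, HT_corrected,
    HT_uncorrected, GST-denominator-choice applied by caller).
    """
    n_k = counts.sum(axis=1)
    if np.any(n_k < 2):
        raise AnalysisError("every population needs at least 2 sequences")
    P = counts.shape[0]
    if P < 2:
        raise AnalysisError("differentiation needs at least 2 populations")
    freqs = counts / n_k[:, None]
    within = np.einsum("ki,ij,kj->k", freqs, weight, freqs)
    h_k = n_k / (n_k - 1.0) * within
    if weighted_mean:
        hs = float(np.average(h_k, weights=n_k))
    else:
        hs = float(np.mean(h_k))
    pbar = freqs.mean(axis=0)
    ht_plugin = float(pbar @ weight @ pbar)
    n_harm = P / np.sum(1.0 / n_k)
    ht_corr = ht_plugin + hs / (n_harm * P)
    return hs, ht_corr, ht_plugin, n_harm


def permut_statistics(
    table: HaplotypeTable,
    dist: DistanceMatrix | np.ndarray | None = None,
    weighted_hs: bool = False,
    estimator: str = "corrected",
) -> DifferentiationResult:
    """HS, HT, GST and (if ``dist`` given) vS, vT, NST point estimates.

    ``estimator`` selects which HT/vT enters GST/NST: "corrected"
    (Nei–Chesser correction from unweighted mean frequencies and the
    harmonic mean sample size; default) or "uncorrected" (plain
    1 - sum(pbar^2)).  Both HT variants are always reported.
    """
    if estimator not in ("corrected", "uncorrected"):
        raise AnalysisError(f"unknown estimator {estimator!r}")
    counts = table.counts.to_numpy(dtype=float)
    k = counts.shape[1]
    ones = 1.0 - np.eye(k)
    hs, ht_corr, ht_plain, _ = _pons_petit(counts, ones, weighted_hs, estimator)
    ht = ht_corr if estimator == "corrected" else ht_plain
    flags = []
    if ht > 0:
        gst = 1.0 - hs / ht
    else:
        gst = float("nan")
        flags.append("HT=0: GST undefined")
    gst_plain = 1.0 - hs / ht_plain if ht_plain > 0 else float("nan")

    vs = vt = nst = None
    if dist is not None:
        d = dist.matrix if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
        vs, vt_corr, vt_plain, _ = _pons_petit(counts, d, weighted_hs, estimator)
        vt = vt_corr if estimator == "corrected" else vt_plain
        if vt > 0:
            nst = 1.0 - vs / vt
        else:
            nst = float("nan")
            flags.append("vT=0: NST undefined")
    return DifferentiationResult(
        hs=hs, ht=ht, gst=gst, vs=vs, vt=vt, nst=nst,
        ht_uncorrected=ht_plain, gst_uncorrected=gst_plain, flags=tuple(flags),
    )


def nst_gst_test(
    table: HaplotypeTable,
    dist: DistanceMatrix | np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    weighted_hs: bool = False,
    estimator: str = "corrected",
) -> DifferentiationResult:
    """Permutation test of phylogeographic structure (NST > GST).

    The null distribution is built by randomly relabelling haplotype
    identities on the distance matrix (simultaneous row/column
    permutation of d_ij) and recomputing NST - GST; the one-sided
    p-value uses the +1 convention, p = (1 + #{perm >= obs}) / (B + 1).
    """
    d = dist.matrix if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    k = d.shape[0]
    if k < 2:
        raise AnalysisError("NST/GST test needs at least 2 distinct haplotypes")
    if n_perm < 1:
        raise AnalysisError("n_perm must be >= 1")
    obs = permut_statistics(table, d, weighted_hs=weighted_hs, estimator=estimator)
    observed = obs.nst - obs.gst
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        res = permut_statistics(table, d[np.ix_(perm, perm)],
                                weighted_hs=weighted_hs, estimator=estimator)
        if res.nst - res.gst >= observed - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return DifferentiationResult(
        hs=obs.hs, ht=obs.ht, gst=obs.gst, vs=obs.vs, vt=obs.vt, nst=obs.nst,
        ht_uncorrected=obs.ht_uncorrected, gst_uncorrected=obs.gst_uncorrected,
        p_value=p, n_perm=n_perm, seed=seed, flags=obs.flags,
    )
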