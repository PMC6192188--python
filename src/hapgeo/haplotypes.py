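"""Haplotype collapsing, distances and the population × haplotype table.

Sequences are collapsed into haplotypes (or ITS ribotypes) the way
DnaSP defines them: sites containing gaps or missing/ambiguous bases are
removed alignment-wide, and two sequences share a haplotype iff they are
identical at every retained column.  The pairwise distance ``d_ij``
between haplotypes is the Hamming distance of their representatives over
the retained columns, so it is a metric and is bounded by the number of
segregating sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, InputError
from .io import Alignment, PopulationMap

__all__ = [
    "DistanceMatrix",
    "HaplotypeCollapse",
    "HaplotypeTable",
    "collapse_haplotypes",
    "tabulate_by_population",
]

_UNAMBIGUOUS = frozenset("ACGTU")
_GAPLIKE = frozenset("-.?")


@dataclass
class DistanceMatrix:
    """Pairwise substitution counts between haplotype representatives.

    ``seg_sites`` holds the original (0-based) alignment columns that
    are polymorphic among the retained columns.
    """

    ids: list[str]
    matrix: np.ndarray
    seg_sites: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.ids)
        if self.matrix.shape != (k, k):
            raise InputError("distance matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise InputError("distance matrix has nonzero diagonal")
        if np.any(self.matrix < 0):
            raise InputError("distances must be non-negative")

    @property
    def n_segregating(self) -> int:
        return len(self.seg_sites)

    def submatrix(self, ids: list[str]) -> np.ndarray:
        idx = [self.ids.index(i) for i in ids]
        return self.matrix[np.ix_(idx, idx)]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


@dataclass
class HaplotypeCollapse:
    """Result of collapsing an alignment: who carries which haplotype."""

    assignment: pd.Series          # record id -> haplotype label
    representatives: dict[str, str]  # haplotype label -> full-length sequence
    distances: DistanceMatrix
    retained_columns: list[int]

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.representatives)

    @property
    def counts(self) -> pd.Series:
        return self.assignment.value_counts().reindex(self.haplotype_ids).astype(int)

    def indices(self) -> np.ndarray:
        """Per-individual integer index into the distance matrix."""
        lookup = {h: i for i, h in enumerate(self.haplotype_ids)}
        return np.array([lookup[h] for h in self.assignment], dtype=int)

    def representatives_to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for hap, seq in self.representatives.items():
                fh.write(f">{hap}\n{seq}\n")


def _retained_columns(aln: Alignment, gap_policy: str, treat_ambiguity_as_missing: bool) -> list[int]:
    if gap_policy == "pairwise_complete":
        return list(range(aln.L))
    bad_chars = set(_GAPLIKE) | {"N"}
    if treat_ambiguity_as_missing:
        # anything that is not an unambiguous base is dropped
        keep_set = _UNAMBIGUOUS
        return [
            j for j in range(aln.L)
            if all(s[j] in keep_set for s in aln.seqs)
        ]
    return [
        j for j in range(aln.L)
        if all(s[j] not in bad_chars for s in aln.seqs)
    ]


def collapse_haplotypes(
    aln: Alignment,
    gap_policy: str = "exclude_columns",
    treat_ambiguity_as_missing: bool = True,
    label_prefix: str = "H",
) -> HaplotypeCollapse:
    """Collapse aligned sequences into haplotypes and compute ``d_ij``.

    gap_policy
        ``"exclude_columns"`` (default, DnaSP-style): any column holding
        a gap, N, or (if ``treat_ambiguity_as_missing``) an IUPAC
        ambiguity code in *any* record is removed before haplotype
        definition and distance computation.  ``"pairwise_complete"``:
        all columns are kept, haplotypes are defined by full-string
        identity, and each pairwise distance ignores columns where
        either representative carries a gap/ambiguous base (no longer
        guaranteed to be a metric).

    Haplotypes are labelled ``H1, H2, ...`` in order of first appearance.
    """
    if gap_policy not in ("exclude_columns", "pairwise_complete"):
        raise InputError(f"unknown gap policy {gap_policy!r}")
    retained = _retained_columns(aln, gap_policy, treat_ambiguity_as_missing)
    if not retained:
        raise AnalysisError("no alignment columns retained under the gap policy")

    keys = ["".join(s[j] for j in retained) for s in aln.seqs]
    labels: dict[str, str] = {}
    representatives: dict[str, str] = {}
    assignment = {}
    for rid, seq, key in zip(aln.ids, aln.seqs, keys):
        if key not in labels:
            labels[key] = f"{label_prefix}{len(labels) + 1}"
            representatives[labels[key]] = seq
        assignment[rid] = labels[key]

    hap_ids = list(representatives)
    reps_kept = [k for k in labels]  # retained-column strings, discovery order
    k = len(hap_ids)
    dist = np.zeros((k, k))
    if gap_policy == "pairwise_complete":
        full = [representatives[h] for h in hap_ids]
        for a in range(k):
            for b in range(a + 1, k):
                d = sum(
                    1
                    for x, y in zip(full[a], full[b])
                    if x in _UNAMBIGUOUS and y in _UNAMBIGUOUS and x != y
                )
                dist[a, b] = dist[b, a] = d
    else:
        arr = np.array([list(r) for r in reps_kept])
        for a in range(k):
            for b in range(a + 1, k):
                d = int(np.sum(arr[a] != arr[b]))
                dist[a, b] = dist[b, a] = d

    # segregating sites: retained columns polymorphic across the sample
    seg = []
    for pos, j in enumerate(retained):
        states = {s[j] for s in aln.seqs}
        states &= _UNAMBIGUOUS if gap_policy == "exclude_columns" else set(states)
        if gap_policy == "pairwise_complete":
            states = {c for c in states if c in _UNAMBIGUOUS}
        if len(states) > 1:
            seg.append(j)

    dm = DistanceMatrix(hap_ids, dist, seg_sites=seg)
    return HaplotypeCollapse(
        assignment=pd.Series(assignment, name="haplotype"),
        representatives=representatives,
        distances=dm,
        retained_columns=retained,
    )


@dataclass
class HaplotypeTable:
    """Population × haplotype count matrix (the machine form of a
    frequency table with per-population sample sizes)."""

    counts: pd.DataFrame  # index: populations, columns: haplotype ids
    representatives: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise InputError("haplotype counts must be non-negative")
        if (self.counts.sum(axis=0) < 1).any():
            empty = list(self.counts.columns[self.counts.sum(axis=0) < 1])
            raise InputError(f"haplotypes with zero total count: {empty}")

    @property
    def populations(self) -> list[str]:
        return list(self.counts.index)

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def n_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def total_counts(self) -> pd.Series:
        """Pooled species-level haplotype counts."""
        return self.counts.sum(axis=0)

    def monomorphic_populations(self) -> list[str]:
        """Populations fixed for a single haplotype."""
        return [p for p in self.populations if (self.counts.loc[p] > 0).sum() == 1]

    def presence(self, haplotype: str) -> int:
        """Number of populations in which ``haplotype`` occurs."""
        return int((self.counts[haplotype] > 0).sum())

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "N", self.sample_sizes)
        out.to_csv(path, sep="\t", index_label="population")


def tabulate_by_population(collapse: HaplotypeCollapse, popmap: PopulationMap) -> HaplotypeTable:
    """Cross-tabulate haplotype assignments by population (popmap order)."""
    missing = [i for i in collapse.assignment.index if i not in popmap.assignments]
    if missing:
        raise InputError(
            f"{len(missing)} individuals lack a population assignment: {missing[:5]}"
        )
    pops = popmap.population_order
    haps = collapse.haplotype_ids
    counts = pd.DataFrame(0, index=pops, columns=haps, dtype=int)
    for ind, hap in collapse.assignment.items():
        counts.loc[popmap.assignments[ind], hap] += 1
    return HaplotypeTable(counts, representatives=dict(collapse.representatives))
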