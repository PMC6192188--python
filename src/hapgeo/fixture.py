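"""Deterministic study-shaped fixture datasets.

The original sequences behind the published per-population haplotype
frequency table are not deposited anywhere, so this module rebuilds a
dataset with exactly the published shape: 16 populations, 253
individuals, a 1531-bp chloroplast-like locus whose 7 segregating sites
define 6 haplotypes, and a 606-column ITS-like locus whose 4
substitution sites define 6 ribotypes with 2 additional indel columns
(raw sequence lengths 604-606).  Per-population haplotype counts,
coordinates (as printed, degree/minute/second) and elevations are the
published ones.

The haplotype sequences themselves are a constructed, versioned
stand-in (the publication never lists them): site patterns are chosen so
that H3 and H6 are one substitution apart and form a clade at least two
substitutions from every other haplotype, H1 is two steps from the
widespread H2, and ribotype R2 is the most divergent ribotype --
matching the qualitative clade statements the frequency table came
with.  Every statistic that depends on the actual inter-haplotype
distances (pi, NST, AMOVA percentages, tau) is therefore
fixture-conditional, not a reproduction of the published value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .io import Alignment, PopulationMap, population_map_from_text

__all__ = ["FixtureData", "make_study_fixture", "SAMPLING_TABLE"]

_FIXTURE_SEED = 20181016  # fixed: fixtures are versioned data, not simulations

# Published sampling table: population, province, locality, elevation (m),
# latitude, longitude (as printed, including two entries whose
# seconds field overflows 60), cpDNA haplotype counts, ITS ribotype counts.
SAMPLING_TABLE = [
    ("DML", "XZ", "Demula Mt.", 4900.0, "29°18′36″N", "97°00′59″E",
     [("H2", 20)], [("R1", 20)]),
    ("DQ", "XZ", "Dingqing", 4959.0, "31°41′34″N", "94°55′31″E",
     [("H2", 20)], [("R1", 20)]),
    ("DD-1", "XZ", "Dongda Mt.", 5080.0, "29°42′46″N", "97°57′43″E",
     [("H1", 18), ("H2", 1)], [("R1", 19)]),
    ("DD-2", "XZ", "Dongda Mt.", 5080.0, "29°42′46″N", "97°57′43″E",
     [("H1", 14)], [("R1", 14)]),
    ("JCL", "XZ", "Jiacuola Mt.", 5505.5, "28°57′28″N", "87°23′37″E",
     [("H3", 16)], [("R3", 16)]),
    ("ML", "XZ", "Mila Mt.", 5225.0, "29°50′02″N", "92°20′02″E",
     [("H5", 3), ("H4", 16), ("H2", 1)], [("R1", 7), ("R3", 2), ("R4", 11)]),
    ("SJL-1", "XZ", "Sejila Mt.", 4728.0, "29°33′62″N", "94°34′58″E",
     [("H3", 12)], [("R1", 12)]),
    ("SJL-2", "XZ", "Sejila Mt.", 4728.0, "29°33′62″N", "94°34′42″E",
     [("H3", 10)], [("R1", 10)]),
    ("XL", "XZ", "Xiala Mt.", 5068.0, "31°22′58″N", "93°46′32″E",
     [("H2", 19)], [("R1", 9), ("R6", 10)]),
    ("QE-1", "SC", "Que'er Mt.", 4845.0, "31°56′05″N", "98°55′43″E",
     [("H2", 17)], [("R1", 11), ("R5", 6)]),
    ("QE-2", "SC", "Que'er Mt.", 4700.0, "31°56′02″N", "98°56′02″E",
     [("H2", 10)], [("R1", 10)]),
    ("QE-3", "SC", "Que'er Mt.", 4823.0, "31°48′79″N", "98°34′78″E",
     [("H6", 3), ("H2", 13)], [("R1", 16)]),
    ("XC", "SC", "Xiangcheng", 4780.0, "29°08′23″N", "100°03′24″E",
     [("H2", 18)], [("R1", 6), ("R2", 12)]),
    ("HS-1", "YN", "Hongshan Mt.", 4365.0, "28°07′43″N", "99°53′51″E",
     [("H2", 20)], [("R1", 18), ("R2", 2)]),
    ("HS-2", "YN", "Hongshan Mt.", 4342.0, "28°07′08″N", "99°54′02″E",
     [("H2", 12)], [("R1", 12)]),
    ("HS-3", "YN", "Hongshan Mt.", 4342.0, "28°07′08″N", "99°54′02″E",
     [("H2", 10)], [("R1", 10)]),
]

# Constructed site patterns over the segregating sites (0 = ancestral-like
# state, 1 = derived).  cpDNA: 7 sites; H2 widespread/central, H1 two
# steps away, H4-H5 an adjacent pair, H3-H6 the divergent clade.
CP_PATTERNS = {
    "H1": "1100000",
    "H2": "0000000",
    "H3": "0000110",
    "H4": "0010000",
    "H5": "0011000",
    "H6": "0000111",
}
# ITS: 4 substitution sites, R2 most divergent (first-diverging lineage).
ITS_PATTERNS = {
    "R1": "0000",
    "R2": "1111",
    "R3": "0100",
    "R4": "0010",
    "R5": "0001",
    "R6": "0110",
}
# indel columns (0-based within the gap-column set): ribotype -> gapped columns
ITS_GAPS = {"R2": (0, 1), "R6": (0,)}

_CP_LENGTH = 1531
_ITS_LENGTH = 606


@dataclass
class FixtureData:
    kind: str
    alignment: Alignment
    popmap: PopulationMap
    true_assignment: dict[str, str]      # record id -> constructed haplotype label
    haplotype_sequences: dict[str, str]  # constructed label -> aligned sequence

    def write(self, out_dir) -> tuple[str, str]:
        import os

        os.makedirs(out_dir, exist_ok=True)
        fasta = os.path.join(out_dir, f"{self.kind.lower()}_alignment.fasta")
        tsv = os.path.join(out_dir, f"{self.kind.lower()}_popmap.tsv")
        self.alignment.to_fasta(fasta)
        with open(tsv, "w") as fh:
            fh.write(_popmap_text(self.kind))
        return fasta, tsv


def _haplotype_sequences(kind: str) -> dict[str, str]:
    rng = np.random.default_rng(_FIXTURE_SEED)
    bases = "ACGT"
    if kind == "cpDNA":
        L, patterns, gaps = _CP_LENGTH, CP_PATTERNS, {}
        n_var = 7
        n_gap = 0
    else:
        L, patterns, gaps = _ITS_LENGTH, ITS_PATTERNS, ITS_GAPS
        n_var = 4
        n_gap = 2
    background = "".join(bases[i] for i in rng.integers(4, size=L))
    special = sorted(rng.choice(L, size=n_var + n_gap, replace=False))
    var_cols, gap_cols = special[:n_var], special[n_var:]
    states = {}
    for j in var_cols:
        anc = background[j]
        alt = bases[(bases.index(anc) + 1 + int(rng.integers(3))) % 4]
        states[j] = (anc, alt)
    seqs = {}
    for hap, pattern in patterns.items():
        seq = list(background)
        for bit, j in zip(pattern, var_cols):
            seq[j] = states[j][int(bit)]
        for g_idx, j in enumerate(gap_cols):
            if g_idx in gaps.get(hap, ()):
                seq[j] = "-"
        seqs[hap] = "".join(seq)
    return seqs


def _popmap_text(kind: str) -> str:
    lines = ["individual\tpopulation\tlat\tlon\televation"]
    for pop, _prov, _loc, elev, lat, lon, cp, its in SAMPLING_TABLE:
        counts = cp if kind == "cpDNA" else its
        i = 0
        for _hap, c in counts:
            for _ in range(c):
                i += 1
                lines.append(f"{pop}_{i:02d}\t{pop}\t{lat}\t{lon}\t{elev:g}")
    return "\n".join(lines) + "\n"


def make_study_fixture(kind: str = "cpDNA") -> FixtureData:
    """Build the deterministic fixture dataset for one locus.

    ``kind`` is ``"cpDNA"`` or ``"ITS"``.  Two invocations produce
    byte-identical data (the construction runs from a fixed seed).
    """
    if kind not in ("cpDNA", "ITS"):
        raise InputError(f"unknown fixture kind {kind!r}")
    hap_seqs = _haplotype_sequences(kind)
    ids, seqs = [], []
    true_assignment = {}
    for pop, _prov, _loc, _elev, _lat, _lon, cp, its in SAMPLING_TABLE:
        counts = cp if kind == "cpDNA" else its
        i = 0
        for hap, c in counts:
            for _ in range(c):
                i += 1
                rid = f"{pop}_{i:02d}"
                ids.append(rid)
                seqs.append(hap_seqs[hap])
                true_assignment[rid] = hap
    alignment = Alignment(ids, seqs)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # the printed table contains seconds >= 60; the parser's warning is
        # expected and not useful every time the fixture is built
        _warnings.simplefilter("ignore")
        popmap = population_map_from_text(_popmap_text(kind), alignment=alignment)
    return FixtureData(kind, alignment, popmap, true_assignment, hap_seqs)
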