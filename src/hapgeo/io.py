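"""Alignment and population-map input.

An :class:`Alignment` is a rectangular block of aligned sequences over
{A, C, G, T, N, -, IUPAC ambiguity codes}; a :class:`PopulationMap`
assigns each sequenced individual to a sampled population and carries
per-population coordinates (decimal degrees) and elevation.

Coordinates may be given either as decimal degrees or as printed
degree/minute/second strings (``29°18′36″N``); DMS values are converted
with deg + min/60 + sec/3600.  Field tables occasionally print seconds
(or minutes) ≥ 60; these are converted arithmetically with a warning
rather than rejected, so published tables can be used verbatim.
"""

from __future__ import annotations

import io as _io
import re
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import AlignmentError, InputError

__all__ = [
    "Alignment",
    "Population",
    "PopulationMap",
    "read_alignment",
    "read_population_map",
    "parse_coordinate",
]

_VALID_CHARS = set("ACGTUNRYSWKMBDHV-.?")


@dataclass
class Alignment:
    """A multiple sequence alignment kept as parallel id / sequence lists."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("alignment contains no records")
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise InputError(f"duplicate record ids: {dupes}")
        self.seqs = [s.upper() for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"sequences have unequal lengths {sorted(lengths)}")
        if self.L == 0:
            raise AlignmentError("alignment has zero columns")
        for rid, s in zip(self.ids, self.seqs):
            bad = set(s) - _VALID_CHARS
            if bad:
                raise AlignmentError(f"record {rid!r} contains invalid characters {sorted(bad)}")

    @property
    def L(self) -> int:
        """Alignment length in columns (bp)."""
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        return len(self.ids)

    def column(self, j: int) -> str:
        return "".join(s[j] for s in self.seqs)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, s in zip(self.ids, self.seqs):
                fh.write(f">{rid}\n{s}\n")


def read_alignment(path) -> Alignment:
    """Read a FASTA alignment, preserving record order and uppercasing bases.

    Raises :class:`AlignmentError` for unequal record lengths or an empty
    file, :class:`InputError` for duplicate ids.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


# --- population map ---------------------------------------------------------

_DMS_RE = re.compile(
    r"""^\s*(\d+(?:\.\d+)?)\s*[°º]
        \s*(?:(\d+(?:\.\d+)?)\s*[′'’])?
        \s*(?:(\d+(?:\.\d+)?)\s*[″”"'’]*)?
        \s*([NSEWnsew])?\s*$""",
    re.VERBOSE,
)


def parse_coordinate(text: str | float, kind: str = "lat") -> float:
    """Parse a coordinate given as decimal degrees or a DMS string.

    ``kind`` ("lat" or "lon") sets the admissible range.  Hemisphere
    letters S and W negate; a bare DMS string is taken as N/E.  Minutes
    or seconds ≥ 60 trigger a warning but are converted arithmetically
    (printed tables sometimes contain such values).
    """
    if isinstance(text, (int, float)):
        value = float(text)
    else:
        s = str(text).strip()
        m = _DMS_RE.match(s)
        if m and "°" in s or (m and "º" in s):
            deg = float(m.group(1))
            minutes = float(m.group(2) or 0.0)
            seconds = float(m.group(3) or 0.0)
            if minutes >= 60 or seconds >= 60:
                warnings.warn(
                    f"coordinate {s!r} has minutes/seconds >= 60; converting arithmetically",
                    stacklevel=2,
                )
            value = deg + minutes / 60.0 + seconds / 3600.0
            hemi = (m.group(4) or "").upper()
            if hemi in ("S", "W"):
                value = -value
        else:
            try:
                value = float(s)
            except ValueError as exc:
                raise InputError(f"cannot parse coordinate {text!r}") from exc
    limit = 90.0 if kind == "lat" else 180.0
    if not -limit <= value <= limit:
        raise InputError(f"coordinate {text!r} outside [-{limit}, {limit}]")
    return value


@dataclass
class Population:
    name: str
    latitude: float | None = None
    longitude: float | None = None
    elevation: float | None = None

    @property
    def has_coordinates(self) -> bool:
        return self.latitude is not None and self.longitude is not None


@dataclass
class PopulationMap:
    """individual → population assignment plus per-population metadata."""

    assignments: dict[str, str]
    populations: dict[str, Population] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop in set(self.assignments.values()):
            self.populations.setdefault(pop, Population(pop))

    @property
    def population_order(self) -> list[str]:
        return list(self.populations)

    def individuals_of(self, pop: str) -> list[str]:
        return [ind for ind, p in self.assignments.items() if p == pop]

    def sample_sizes(self) -> dict[str, int]:
        sizes = {p: 0 for p in self.populations}
        for p in self.assignments.values():
            sizes[p] += 1
        return sizes

    def coordinates(self) -> dict[str, tuple[float, float]]:
        """(lat, lon) for every population that has them."""
        return {
            name: (pop.latitude, pop.longitude)
            for name, pop in self.populations.items()
            if pop.has_coordinates
        }

    def missing_coordinates(self) -> list[str]:
        """Populations without coordinates (spatial analyses unavailable)."""
        return [name for name, pop in self.populations.items() if not pop.has_coordinates]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("individual\tpopulation\tlat\tlon\televation\n")
            for ind, popname in self.assignments.items():
                pop = self.populations[popname]
                lat = "" if pop.latitude is None else repr(pop.latitude)
                lon = "" if pop.longitude is None else repr(pop.longitude)
                elev = "" if pop.elevation is None else repr(pop.elevation)
                fh.write(f"{ind}\t{popname}\t{lat}\t{lon}\t{elev}\n")


def read_population_map(path, alignment: Alignment | None = None) -> PopulationMap:
    """Read a TSV population map (columns: individual, population, lat, lon[, elevation]).

    Coordinates are parsed per :func:`parse_coordinate`; the first row
    mentioning a population fixes its metadata.  If ``alignment`` is
    given, individuals absent from it are collected into a warning.
    Duplicate individual rows raise :class:`InputError`.
    """
    if hasattr(path, "read"):
        fh = path
        close = False
    else:
        fh = open(path)
        close = True
    try:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name.strip().lower(): i for i, name in enumerate(header)}
        for required in ("individual", "population", "lat", "lon"):
            if required not in cols:
                raise InputError(f"population map is missing column {required!r}")
        assignments: dict[str, str] = {}
        populations: dict[str, Population] = {}
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            ind = fields[cols["individual"]].strip()
            popname = fields[cols["population"]].strip()
            if ind in assignments:
                raise InputError(f"individual {ind!r} mapped twice")
            assignments[ind] = popname
            if popname not in populations:
                lat_s = fields[cols["lat"]].strip()
                lon_s = fields[cols["lon"]].strip()
                lat = parse_coordinate(lat_s, "lat") if lat_s else None
                lon = parse_coordinate(lon_s, "lon") if lon_s else None
                elev = None
                if "elevation" in cols and len(fields) > cols["elevation"]:
                    elev_s = fields[cols["elevation"]].strip()
                    elev = float(elev_s) if elev_s else None
                populations[popname] = Population(popname, lat, lon, elev)
    finally:
        if close:
            fh.close()
    pm = PopulationMap(assignments, populations)
    if alignment is not None:
        missing = [ind for ind in assignments if ind not in set(alignment.ids)]
        if missing:
            warnings.warn(
                f"{len(missing)} mapped individuals absent from the alignment: "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}",
                stacklevel=2,
            )
    return pm


def population_map_from_text(text: str, alignment: Alignment | None = None) -> PopulationMap:
    """Parse a population map from an in-memory TSV string."""
    return read_population_map(_io.StringIO(text), alignment=alignment)
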