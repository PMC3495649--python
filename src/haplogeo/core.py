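"""Data model and I/O for multi-population haplotype datasets.

The central container is a :class:`Dataset`: a set of distinct haplotypes
(state vectors over the coded polymorphic sites of an alignment) together
with per-population gene-copy counts and geographic coordinates.  Datasets
are built either from an aligned FASTA plus a population map, or from the
packaged study fixtures (see :mod:`haplogeo.fixtures`).

Indels are treated as substitutions: a gap run shared across sequences is
collapsed to a single coded presence/absence site, so a 5-bp deletion counts
as one mutational step, and the effective alignment length shrinks by
``run_length - 1`` per multi-column run.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = set("ACGTN-")

__all__ = [
    "AlignmentError",
    "CodingError",
    "SiteAlignment",
    "HaplotypeSet",
    "PopulationSample",
    "Dataset",
    "parse_dm_coordinate",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "read_popmap",
    "write_popmap",
    "collapse_indel_sites",
    "call_haplotypes",
]


class AlignmentError(ValueError):
    """Raised for ragged or otherwise malformed alignments."""


class CodingError(ValueError):
    """Raised when indel runs cannot be collapsed consistently."""


def parse_dm_coordinate(text: str) -> float:
    """Parse a degrees-minutes coordinate such as ``24°45´N`` to decimal degrees.

    Southern and western hemispheres are signed negative.  Minutes must be
    below 60.
    """
    m = re.match(r"\s*(\d+)\s*[°d]\s*(\d+(?:\.\d+)?)\s*[´'′m]?\s*([NSEW]?)\s*$",
                 text.strip())
    if not m:
        raise ValueError(f"cannot parse degrees-minutes coordinate: {text!r}")
    deg, minutes, hemi = int(m.group(1)), float(m.group(2)), m.group(3)
    if minutes >= 60:
        raise ValueError(f"minutes field out of range in {text!r}")
    value = deg + minutes / 60.0
    if hemi in ("S", "W"):
        value = -value
    return value


@dataclass
class SiteAlignment:
    """A rectangular multiple sequence alignment over {A,C,G,T,N,-}."""

    sequence_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        for sid, seq in zip(self.sequence_ids, self.sequences):
            bad = set(seq.upper()) - VALID_CHARS
            if bad:
                raise AlignmentError(f"invalid characters {sorted(bad)} in {sid}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def column(self, j: int) -> str:
        return "".join(s[j] for s in self.sequences)


def read_alignment_fasta(path) -> SiteAlignment:
    """Read an aligned multi-FASTA; record order is preserved."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return SiteAlignment([r.id for r in records], [str(r.seq) for r in records])


def write_alignment_fasta(alignment: SiteAlignment, path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="")
               for i, s in zip(alignment.sequence_ids, alignment.sequences)]
    SeqIO.write(records, str(path), "fasta")


def read_popmap(path):
    """Read a population map TSV.

    Four tab-separated columns: sample_id, population, latitude, longitude.
    Coordinates may be decimal degrees or degrees-minutes strings; lines
    starting with ``#`` are comments.  Returns ``(sample_to_pop,
    pop_coordinates)``.
    """
    sample_to_pop: dict[str, str] = {}
    coords: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"popmap line needs 4 columns: {line!r}")
            sid, pop, lat, lon = parts
            sample_to_pop[sid] = pop
            coords[pop] = (_coord(lat), _coord(lon))
    if not sample_to_pop:
        raise ValueError(f"empty popmap: {path}")
    return sample_to_pop, coords


def _coord(text: str) -> float:
    try:
        return float(text)
    except ValueError:
        return parse_dm_coordinate(text)


def write_popmap(path, sample_to_pop, coords) -> None:
    with open(path, "w") as fh:
        fh.write("# sample_id\tpopulation\tlatitude\tlongitude\n")
        for sid, pop in sample_to_pop.items():
            lat, lon = coords[pop]
            fh.write(f"{sid}\t{pop}\t{lat:.6f}\t{lon:.6f}\n")


def collapse_indel_sites(alignment: SiteAlignment):
    """Collapse shared gap runs to single coded sites.

    Adjacent columns with an identical gap pattern across sequences form one
    indel run; each run becomes a single coded site whose states are the
    run's sequence content ("present" rows keep their bases concatenated,
    absent rows the gap symbol).  Substitution columns pass through.

    Returns ``(coded_columns, positions, effective_length)`` where
    ``coded_columns`` is a list of per-sequence state strings, ``positions``
    are 1-based alignment coordinates of each coded site (run start for
    indel runs) and ``effective_length = alignment_length - sum(run-1)``.

    Raises :class:`CodingError` when the base content of a "present" row
    varies inside a run in a way that differs between sequences sharing the
    run (inconsistent run boundaries).
    """
    L = alignment.alignment_length
    cols = [alignment.column(j) for j in range(L)]
    gap_pattern = [tuple(c == "-" for c in col) for col in cols]

    coded: list[tuple[str, ...]] = []
    positions: list[int] = []
    effective = 0
    j = 0
    while j < L:
        if not any(gap_pattern[j]):
            coded.append(tuple(cols[j]))
            positions.append(j + 1)
            effective += 1
            j += 1
            continue
        # extend the run while the gap pattern is identical
        k = j
        while k + 1 < L and gap_pattern[k + 1] == gap_pattern[j]:
            k += 1
        run_cols = cols[j:k + 1]
        states = []
        for si in range(alignment.n_sequences):
            segment = "".join(c[si] for c in run_cols)
            states.append("-" if set(segment) == {"-"} else segment)
        present = {s for s in states if s != "-"}
        if len(run_cols) > 1 and len(present) > 1:
            raise CodingError(
                f"inconsistent gap run at columns {j + 1}-{k + 1}: "
                f"present-state variants {sorted(present)}")
        coded.append(tuple(states))
        positions.append(j + 1)
        effective += 1
        j = k + 1
    return coded, positions, effective


@dataclass
class HaplotypeSet:
    """Distinct haplotype state vectors over the coded polymorphic sites."""

    haplotype_ids: list[str]
    state_matrix: list[tuple[str, ...]]   # one tuple of states per haplotype
    site_positions: list[int]             # 1-based alignment coordinates
    effective_length: int

    def __post_init__(self) -> None:
        if len({tuple(r) for r in self.state_matrix}) != len(self.state_matrix):
            raise ValueError("duplicate haplotype state vectors")
        for row in self.state_matrix:
            if len(row) != self.n_polymorphic_sites:
                raise ValueError("ragged state matrix")

    @property
    def n_polymorphic_sites(self) -> int:
        return len(self.site_positions)

    def index(self, hap_id: str) -> int:
        return self.haplotype_ids.index(hap_id)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise mutational steps: each differing coded site adds one."""
        n = len(self.haplotype_ids)
        d = np.zeros((n, n), dtype=float)
        for i in range(n):
            for j in range(i + 1, n):
                steps = sum(a != b for a, b in
                            zip(self.state_matrix[i], self.state_matrix[j]))
                d[i, j] = d[j, i] = steps
        return d


@dataclass
class PopulationSample:
    code: str
    latitude: float
    longitude: float
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -90 <= self.latitude <= 90 or not -180 <= self.longitude <= 180:
            raise ValueError(f"coordinates out of range for {self.code}")
        if self.n <= 0:
            raise ValueError(f"population {self.code} has no gene copies")

    @property
    def n(self) -> int:
        return sum(self.counts.values())


@dataclass
class Dataset:
    locus_name: str
    inheritance_mode: str  # "maternal-haploid" | "biparental-diploid"
    haplotypes: HaplotypeSet
    populations: list[PopulationSample]

    def __post_init__(self) -> None:
        known = set(self.haplotypes.haplotype_ids)
        for pop in self.populations:
            unknown = set(pop.counts) - known
            if unknown:
                raise ValueError(
                    f"population {pop.code} counts unknown haplotypes {sorted(unknown)}")

    @property
    def n_total(self) -> int:
        return sum(p.n for p in self.populations)

    def total_counts(self) -> dict[str, int]:
        out: dict[str, int] = {h: 0 for h in self.haplotypes.haplotype_ids}
        for pop in self.populations:
            for h, c in pop.counts.items():
                out[h] += c
        return out

    def population(self, code: str) -> PopulationSample:
        for pop in self.populations:
            if pop.code == code:
                return pop
        raise KeyError(code)

    def count_matrix(self) -> np.ndarray:
        """Populations x haplotypes gene-copy counts."""
        idx = {h: i for i, h in enumerate(self.haplotypes.haplotype_ids)}
        m = np.zeros((len(self.populations), len(idx)))
        for r, pop in enumerate(self.populations):
            for h, c in pop.counts.items():
                m[r, idx[h]] = c
        return m

    def coordinates(self) -> np.ndarray:
        return np.array([[p.latitude, p.longitude] for p in self.populations])

    # ---- serialization -------------------------------------------------
    def to_json(self) -> str:
        obj = {
            "locus_name": self.locus_name,
            "inheritance_mode": self.inheritance_mode,
            "haplotypes": {
                "ids": self.haplotypes.haplotype_ids,
                "state_matrix": [list(r) for r in self.haplotypes.state_matrix],
                "site_positions": self.haplotypes.site_positions,
                "effective_length": self.haplotypes.effective_length,
            },
            "populations": [
                {"code": p.code, "latitude": p.latitude,
                 "longitude": p.longitude, "counts": p.counts}
                for p in self.populations
            ],
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Dataset":
        obj = json.loads(text)
        h = obj["haplotypes"]
        return cls(
            locus_name=obj["locus_name"],
            inheritance_mode=obj["inheritance_mode"],
            haplotypes=HaplotypeSet(
                h["ids"], [tuple(r) for r in h["state_matrix"]],
                h["site_positions"], h["effective_length"]),
            populations=[
                PopulationSample(p["code"], p["latitude"], p["longitude"],
                                 {k: int(v) for k, v in p["counts"].items()})
                for p in obj["populations"]
            ],
        )

    def haplotype_table_csv(self) -> str:
        """Haplotype table: id, per-site states, per-population counts."""
        buf = io.StringIO()
        pops = [p.code for p in self.populations]
        buf.write("haplotype," +
                  ",".join(str(p) for p in self.haplotypes.site_positions) +
                  "," + ",".join(pops) + "\n")
        for i, hid in enumerate(self.haplotypes.haplotype_ids):
            states = ",".join(self.haplotypes.state_matrix[i])
            counts = ",".join(str(p.counts.get(hid, 0)) for p in self.populations)
            buf.write(f"{hid},{states},{counts}\n")
        return buf.getvalue()


def call_haplotypes(alignment: SiteAlignment,
                    sample_to_pop: dict[str, str],
                    coords: dict[str, tuple[float, float]] | None = None,
                    locus_name: str = "locus",
                    inheritance_mode: str = "maternal-haploid",
                    ambiguous: str = "drop",
                    hap_prefix: str = "HAP") -> Dataset:
    """Call distinct haplotypes from an alignment and tally them per population.

    Indel runs are collapsed first; monomorphic coded columns are dropped.
    Haplotypes are numbered in order of first appearance.  Sequences with an
    ``N`` at a polymorphic site are dropped (``ambiguous="drop"``) or raise
    (``ambiguous="error"``).
    """
    missing = [s for s in alignment.sequence_ids if s not in sample_to_pop]
    if missing:
        raise ValueError(f"sequences missing from popmap: {missing[:5]}")
    coded, positions, effective = collapse_indel_sites(alignment)

    # polymorphic columns (ignoring N when deciding polymorphism)
    poly = []
    for ci, col in enumerate(coded):
        states = {s for s in col if s != "N"}
        if len(states) > 1:
            poly.append(ci)

    hap_ids: list[str] = []
    matrix: list[tuple[str, ...]] = []
    seen: dict[tuple[str, ...], str] = {}
    per_pop: dict[str, dict[str, int]] = {}
    for si, sid in enumerate(alignment.sequence_ids):
        vec = tuple(coded[ci][si] for ci in poly)
        if "N" in vec:
            if ambiguous == "error":
                raise ValueError(f"ambiguous state in {sid} at a polymorphic site")
            continue
        if vec not in seen:
            name = f"{hap_prefix}{len(seen) + 1}"
            seen[vec] = name
            hap_ids.append(name)
            matrix.append(vec)
        pop = sample_to_pop[sid]
        per_pop.setdefault(pop, {})
        per_pop[pop][seen[vec]] = per_pop[pop].get(seen[vec], 0) + 1

    hapset = HaplotypeSet(hap_ids, matrix, [positions[ci] for ci in poly],
                          effective)
    populations = []
    for pop, counts in per_pop.items():
        lat, lon = (coords or {}).get(pop, (0.0, 0.0))
        populations.append(PopulationSample(pop, lat, lon, counts))
    return Dataset(locus_name, inheritance_mode, hapset, populations)
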