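"""Packaged study fixtures: the published data tables as a :class:`Dataset`.

The fixtures transcribe the printed tables of the source study of wild tea
tree (*Camellia taliensis*) populations in Yunnan: 21 populations with
degrees-minutes coordinates and sample sizes; 12 chloroplast *rpl32-trnL*
haplotypes ("chlorotypes") over 18 polymorphic sites of an 858-bp alignment
(including one 5-bp and one 9-bp indel, each coded as a single site, so the
effective length is 846); and 17 nuclear *PAL* haplotypes over 18
substitution sites of a 627-bp alignment, with per-population gene-copy
counts (183 chloroplast copies; 274 phased nuclear copies from 137 diploid
individuals).

:func:`fixture_alignment` rebuilds a synthetic per-gene-copy alignment and
population map from the haplotype tables (monomorphic columns are filler),
which closes the loop with the FASTA/popmap readers: calling haplotypes on
the reconstruction reproduces the tables exactly.
"""

from __future__ import annotations

import csv
from importlib import resources

from .core import (Dataset, HaplotypeSet, PopulationSample, SiteAlignment,
                   parse_dm_coordinate)

CP = "rpl32-trnL"
PAL = "PAL"

_EFFECTIVE_LENGTH = {CP: 846, PAL: 627}
_ALIGNED_LENGTH = {CP: 858, PAL: 627}
_MODE = {CP: "maternal-haploid", PAL: "biparental-diploid"}
_STEM = {CP: "rpl32_trnL", PAL: "pal"}

# Indel layout of the chloroplast alignment frame used by the synthetic
# reconstruction.  Exact run coordinates are not recoverable from the source
# tables; only the run lengths (1, 5, 1, 1, 9) matter for the analysis.
_CP_INDELS = {11: ("indel", 1), 102: ("indel", 5), 163: ("indel", 1),
              251: ("indel", 1), 789: ("indel", 9)}
_PRESENT_BASE = {11: "T", 102: "T", 163: "A", 251: "T", 789: "G"}


def _normalize(locus: str) -> str:
    key = locus.strip().lower().replace("_", "-")
    if key in ("rpl32-trnl", "cp", "cpdna", "chloroplast"):
        return CP
    if key in ("pal", "nrdna", "nuclear"):
        return PAL
    raise ValueError(f"unknown locus {locus!r}; expected 'rpl32-trnL' or 'PAL'")


def _read_csv(name: str):
    with resources.files("haplogeo").joinpath("data", name).open() as fh:
        return list(csv.reader(fh))


def load_populations() -> dict[str, dict]:
    """The 21 sampled populations: coordinates and per-locus sample sizes."""
    rows = _read_csv("populations.csv")
    out = {}
    for code, lat, lon, n_cp, n_ind in rows[1:]:
        out[code] = {
            "latitude": parse_dm_coordinate(lat),
            "longitude": parse_dm_coordinate(lon),
            "n_rpl32_trnL": int(n_cp),
            "n_pal_individuals": int(n_ind),
        }
    return out


def load_study_fixture(locus: str) -> Dataset:
    """Return the transcribed dataset for ``"rpl32-trnL"`` or ``"PAL"``."""
    locus = _normalize(locus)
    stem = _STEM[locus]
    hap_rows = _read_csv(f"{stem}_haplotypes.csv")
    positions = [int(p) for p in hap_rows[0][1:]]
    hap_ids = [r[0] for r in hap_rows[1:]]
    matrix = [tuple(r[1:]) for r in hap_rows[1:]]
    hapset = HaplotypeSet(hap_ids, matrix, positions, _EFFECTIVE_LENGTH[locus])

    pops_meta = load_populations()
    counts: dict[str, dict[str, int]] = {}
    for pop, hap, c in _read_csv(f"{stem}_counts.csv")[1:]:
        counts.setdefault(pop, {})[hap] = int(c)
    populations = [
        PopulationSample(code, meta["latitude"], meta["longitude"], counts[code])
        for code, meta in pops_meta.items()
    ]
    return Dataset(locus, _MODE[locus], hapset, populations)


def fixture_alignment(locus: str):
    """Synthetic per-copy alignment + popmap reconstructed from the tables.

    Returns ``(SiteAlignment, sample_to_pop, coords)``.  One sequence per
    gene copy; monomorphic columns are constant filler, polymorphic columns
    carry the tabulated states, and the chloroplast indel runs are laid out
    as gap runs of the published lengths.
    """
    locus = _normalize(locus)
    ds = load_study_fixture(locus)
    L = _ALIGNED_LENGTH[locus]
    positions = ds.haplotypes.site_positions

    def render(state_vec) -> str:
        seq = ["A"] * L
        for pos, state in zip(positions, state_vec):
            j = pos - 1
            if locus == CP and pos in _CP_INDELS:
                run = _CP_INDELS[pos][1]
                seg = "-" * run if state == "-" else _PRESENT_BASE[pos] * run
                seq[j:j + run] = list(seg)
            else:
                seq[j] = state
        return "".join(seq)

    rendered = {h: render(ds.haplotypes.state_matrix[i])
                for i, h in enumerate(ds.haplotypes.haplotype_ids)}
    ids, seqs, sample_to_pop, coords = [], [], {}, {}
    for pop in ds.populations:
        coords[pop.code] = (pop.latitude, pop.longitude)
        copy = 0
        for hap in ds.haplotypes.haplotype_ids:
            for _ in range(pop.counts.get(hap, 0)):
                copy += 1
                sid = f"{pop.code}-{copy:02d}"
                ids.append(sid)
                seqs.append(rendered[hap])
                sample_to_pop[sid] = pop.code
    return SiteAlignment(ids, seqs), sample_to_pop, coords
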