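"""Orchestration: run the full analysis chain and render tabular reports."""

from __future__ import annotations

import io
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .core import Dataset, read_alignment_fasta, read_popmap, call_haplotypes
from .differentiation import amova, ibd_for_dataset, nst_gst_test
from .diversity import per_population_summaries, neutrality_tests
from .geo import geographic_distance_matrix
from .ncpa import run_ncpa
from .network import build_parsimony_network, nest_clades

log = logging.getLogger("haplogeo")


@dataclass
class AnalysisReport:
    provenance: dict
    diversity: list = field(default_factory=list)
    neutrality: dict | None = None
    differentiation: dict | None = None
    amova: dict | None = None
    ibd: dict | None = None
    nesting: dict | None = None
    ncpa: dict | None = None
    errors: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.provenance:
            raise ValueError("report lacks a provenance block")

    def to_json(self) -> str:
        self.validate()
        return json.dumps(asdict(self), indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(type(x).__name__)


def dataset_from_files(alignment_path, popmap_path,
                       locus_name="locus",
                       inheritance_mode="maternal-haploid") -> Dataset:
    aln = read_alignment_fasta(alignment_path)
    sample_to_pop, coords = read_popmap(popmap_path)
    return call_haplotypes(aln, sample_to_pop, coords,
                           locus_name=locus_name,
                           inheritance_mode=inheritance_mode)


def run_full_analysis(dataset: Dataset, n_perm: int = 10_000,
                      seed: int = 0) -> AnalysisReport:
    """Diversity -> neutrality -> differentiation -> network/NCPA.

    Stage failures are recorded in ``report.errors`` and later stages still
    run where their inputs allow; every stochastic result records its seed
    and permutation count in the provenance block.
    """
    report = AnalysisReport(provenance={
        "package": "haplogeo", "version": __version__,
        "locus": dataset.locus_name, "n_copies": dataset.n_total,
        "n_populations": len(dataset.populations),
        "seed": seed, "n_permutations": n_perm,
        "timestamp": "deterministic-output",
    })

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
            log.info("%s finished in %.2fs", name, time.perf_counter() - t0)
            return out
        except Exception as exc:          # partial report on stage failure
            log.warning("stage %s failed: %s", name, exc)
            report.errors[name] = str(exc)
            return None

    divs = stage("diversity", lambda: per_population_summaries(dataset))
    if divs:
        report.diversity = [asdict(d) for d in divs]
    neut = stage("neutrality", lambda: neutrality_tests(dataset))
    if neut:
        report.neutrality = asdict(neut)
    diff = stage("differentiation",
                 lambda: nst_gst_test(dataset, n_perm=n_perm, seed=seed))
    if diff:
        report.differentiation = asdict(diff)
    am = stage("amova", lambda: amova(dataset, n_perm=min(n_perm, 1000),
                                      seed=seed))
    if am:
        report.amova = asdict(am)
    ibd = stage("ibd", lambda: ibd_for_dataset(dataset, n_perm=n_perm, seed=seed))
    if ibd:
        report.ibd = asdict(ibd)

    def _ncpa():
        net = build_parsimony_network(dataset)
        design = nest_clades(net, dataset)
        stats, outcomes = run_ncpa(design, dataset, n_perm=n_perm, seed=seed)
        return design, stats, outcomes

    ncpa_out = stage("ncpa", _ncpa)
    if ncpa_out:
        design, stats, outcomes = ncpa_out
        report.nesting = {
            "levels": [
                [{"label": c.label, "observed": c.observed_haplotypes,
                  "is_tip": c.is_tip} for c in tier]
                for tier in design.levels
            ],
        }
        report.ncpa = {
            "clade_stats": [asdict(s) for s in stats],
            "inferences": [asdict(o) for o in outcomes],
        }
    return report


def render_tables(report: AnalysisReport, fmt: str = "tsv") -> dict[str, str]:
    """Render the report as named text documents (``tsv`` or ``json``)."""
    if fmt == "json":
        return {"report.json": report.to_json()}
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}")
    out = {}
    buf = io.StringIO()
    buf.write("unit\tS\tn\th\tpi\tK\n")
    for d in report.diversity:
        buf.write(f"{d['unit']}\t{d['S']}\t{d['n']}\t{d['h']:.5f}"
                  f"\t{d['pi']:.5f}\t{d['K']:.5f}\n")
    out["diversity.tsv"] = buf.getvalue()
    if report.amova:
        a = report.amova
        buf = io.StringIO()
        buf.write("source\tdf\tSS\tvariance\tpercent\n")
        buf.write(f"among\t{a['df_among']}\t{a['SS_among']:.3f}"
                  f"\t{a['sigma2_among']:.5f}\t{a['pct_among']:.2f}\n")
        buf.write(f"within\t{a['df_within']}\t{a['SS_within']:.3f}"
                  f"\t{a['sigma2_within']:.5f}\t{a['pct_within']:.2f}\n")
        out["amova.tsv"] = buf.getvalue()
    if report.errors:
        out["errors.tsv"] = "".join(f"{k}\t{v}\n" for k, v in report.errors.items())
    return out
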