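"""Nested clade phylogeographic analysis: clade and nested-clade distances,
permutation tests of geographic association, and an encoded inference key.

For every clade in a nested design, the clade distance Dc is the
frequency-weighted mean great-circle distance of the clade's observations
from the clade's own geographic centre (a weighted spherical centroid), and
the nested-clade distance Dn is the same quantity measured from the centre
of the clade one nesting level up.  Within each nesting group the
interior-vs-tip contrasts (I-T Dc, I-T Dn) are computed from network
topology.  Significance is assessed by permuting, within each nesting
clade, the assignment of observations to subclades against their sampling
locations; Dc/Dn values in the smallest or largest 5% tail of the
permutation distribution are flagged.

Significant patterns are interpreted by walking an inference key encoded as
a data table (``data/inference_key.json``): an explicit decision tree whose
questions are answered from the flag pattern, returning a conclusion
category (restricted gene flow with isolation by distance, allopatric
fragmentation, contiguous range expansion, long-distance colonization, or
inconclusive) together with the full chain of answered steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .core import Dataset
from .geo import haversine_km, mean_distance_to, weighted_centroid
from .network import Clade, NestedDesign

__all__ = [
    "CladeGeoStats", "InferenceOutcome", "clade_distances",
    "ncpa_permutation_test", "apply_inference_key", "run_ncpa",
]


@dataclass
class CladeGeoStats:
    clade: str
    level: int
    nested_in: str | None
    interior: bool
    n_obs: int
    Dc: float
    Dn: float
    p_dc_small: float | None = None
    p_dc_large: float | None = None
    p_dn_small: float | None = None
    p_dn_large: float | None = None

    @property
    def significant(self) -> bool:
        ps = [self.p_dc_small, self.p_dc_large, self.p_dn_small, self.p_dn_large]
        return any(p is not None and p <= 0.05 for p in ps)


@dataclass
class InferenceOutcome:
    clade: str
    chain: list[str]
    conclusion: str


def _observations(dataset: Dataset, hap_ids: list[str]):
    """(lat, lon, weight) rows for every population where the haplotypes occur."""
    rows = []
    for pop in dataset.populations:
        w = sum(pop.counts.get(h, 0) for h in hap_ids)
        if w > 0:
            rows.append((pop.latitude, pop.longitude, w))
    return rows


def _dc(rows) -> float:
    coords = np.array([(r[0], r[1]) for r in rows])
    w = np.array([r[2] for r in rows], float)
    centre = weighted_centroid(coords, w)
    return mean_distance_to(coords, w, centre)


def _dn(rows, centre) -> float:
    coords = np.array([(r[0], r[1]) for r in rows])
    w = np.array([r[2] for r in rows], float)
    return mean_distance_to(coords, w, centre)


def _levels_with_zero(design: NestedDesign, dataset: Dataset):
    """All clade tiers, including haplotypes as 0-step clades."""
    hs = dataset.haplotypes
    zero = [Clade(h, 0, [h], [h]) for h in hs.haplotype_ids]
    # a haplotype is a network tip if its node has degree <= 1
    g = design.network.graph
    for c in zero:
        c.is_tip = (g.degree(c.label) <= 1) if c.label in g else True
    return [zero] + design.levels


def clade_distances(design: NestedDesign, dataset: Dataset) -> list[CladeGeoStats]:
    """Dc/Dn for every clade at every tier of the design.

    Clades with no observations (inferred intermediates only) are excluded.
    Dn is computed relative to the nesting clade one level up; the top
    (total cladogram) clade has Dn = Dc.
    """
    tiers = _levels_with_zero(design, dataset)
    out: list[CladeGeoStats] = []
    for li, tier in enumerate(tiers):
        parents = tiers[li + 1] if li + 1 < len(tiers) else None
        for clade in tier:
            if not clade.observed_haplotypes:
                continue
            rows = _observations(dataset, clade.observed_haplotypes)
            if not rows:
                continue
            parent = None
            if parents is not None:
                for p in parents:
                    if set(clade.observed_haplotypes) <= set(p.observed_haplotypes):
                        parent = p
                        break
            if parent is not None:
                prows = _observations(dataset, parent.observed_haplotypes)
                pcoords = np.array([(r[0], r[1]) for r in prows])
                pw = np.array([r[2] for r in prows], float)
                centre = weighted_centroid(pcoords, pw)
                dn = _dn(rows, centre)
            else:
                dn = _dc(rows)
            out.append(CladeGeoStats(
                clade=clade.label, level=clade.level,
                nested_in=parent.label if parent is not None else None,
                interior=not clade.is_tip,
                n_obs=sum(r[2] for r in rows),
                Dc=_dc(rows), Dn=dn))
    return out


def ncpa_permutation_test(design: NestedDesign, dataset: Dataset,
                          n_perm: int = 10_000,
                          seed: int = 0) -> list[CladeGeoStats]:
    """Permutation significance for every nested Dc/Dn.

    Within each nesting clade, the subclade labels of the individual gene
    copies are shuffled against their sampling locations, holding both the
    per-location totals and the subclade sizes fixed; each observed Dc/Dn
    is then placed in its null distribution (one-tailed small and large).
    """
    rng = np.random.default_rng(seed)
    stats = {s.clade: s for s in clade_distances(design, dataset)}
    tiers = _levels_with_zero(design, dataset)
    label_to_clade = {c.label: c for tier in tiers for c in tier}

    for li in range(1, len(tiers)):
        for nest in tiers[li]:
            subs = [label_to_clade[s] for s in _subclades(nest, tiers[li - 1])]
            subs = [s for s in subs if s.observed_haplotypes]
            if len(subs) < 2:
                continue
            # expand observations: (location index, subclade index) per copy
            locs, sub_idx = [], []
            coords = []
            for si, sub in enumerate(subs):
                for pop in dataset.populations:
                    w = sum(pop.counts.get(h, 0) for h in sub.observed_haplotypes)
                    if w > 0:
                        coords.append((pop.latitude, pop.longitude))
                        locs.extend([len(coords) - 1] * w)
                        sub_idx.extend([si] * w)
            locs = np.array(locs)
            sub_idx = np.array(sub_idx)
            coords = np.array(coords)
            nrows = _observations(dataset, nest.observed_haplotypes)
            ncentre = weighted_centroid(
                np.array([(r[0], r[1]) for r in nrows]),
                np.array([r[2] for r in nrows], float))

            def dcdn(sub_assign):
                vals = []
                for si in range(len(subs)):
                    mask = sub_assign == si
                    if not mask.any():
                        vals.append((np.nan, np.nan))
                        continue
                    pts = coords[locs[mask]]
                    w = np.ones(mask.sum())
                    centre = weighted_centroid(pts, w)
                    vals.append((mean_distance_to(pts, w, centre),
                                 mean_distance_to(pts, w, ncentre)))
                return vals

            obs = dcdn(sub_idx)
            ge_c = np.zeros(len(subs)); le_c = np.zeros(len(subs))
            ge_n = np.zeros(len(subs)); le_n = np.zeros(len(subs))
            valid = np.zeros(len(subs))
            work = sub_idx.copy()
            for _ in range(n_perm):
                rng.shuffle(work)
                perm = dcdn(work)
                for si in range(len(subs)):
                    if np.isnan(perm[si][0]):
                        continue
                    valid[si] += 1
                    ge_c[si] += perm[si][0] >= obs[si][0] - 1e-12
                    le_c[si] += perm[si][0] <= obs[si][0] + 1e-12
                    ge_n[si] += perm[si][1] >= obs[si][1] - 1e-12
                    le_n[si] += perm[si][1] <= obs[si][1] + 1e-12
            for si, sub in enumerate(subs):
                if sub.label not in stats or valid[si] == 0:
                    continue
                s = stats[sub.label]
                s.p_dc_large = (ge_c[si] + 1) / (valid[si] + 1)
                s.p_dc_small = (le_c[si] + 1) / (valid[si] + 1)
                s.p_dn_large = (ge_n[si] + 1) / (valid[si] + 1)
                s.p_dn_small = (le_n[si] + 1) / (valid[si] + 1)
    return list(stats.values())


def _subclades(nest: Clade, lower_tier: list[Clade]) -> list[str]:
    out = []
    members = set(nest.members)
    for c in lower_tier:
        cm = set(c.members)
        if cm <= members:
            out.append(c.label)
    return out


# ---------------------------------------------------------------------------
# Inference key
# ---------------------------------------------------------------------------

def _load_key() -> dict:
    with resources.files("haplogeo").joinpath("data", "inference_key.json").open() as fh:
        return json.load(fh)


@dataclass
class CladePattern:
    """Aggregate significance pattern for one nesting group, the input
    alphabet of the inference key."""

    clade: str
    any_significant: bool = False
    tip_dc_small: bool = False
    tip_dc_large: bool = False
    interior_dc_small: bool = False
    interior_dc_large: bool = False
    tip_dn_small: bool = False
    tip_dn_large: bool = False
    interior_dn_small: bool = False
    interior_dn_large: bool = False
    it_dc_large: bool = False
    it_dn_large: bool = False
    ranges_disjoint: bool = False
    per_clade: list[dict] = field(default_factory=list)

    def validate(self) -> None:
        for rec in self.per_clade:
            for stat in ("dc", "dn"):
                if rec.get(f"{stat}_small") and rec.get(f"{stat}_large"):
                    raise ValueError(
                        f"contradictory flags for {rec.get('clade')}: "
                        f"{stat} marked both small and large")


_PREDICATES = {
    "any_significant": lambda p: p.any_significant,
    "restricted_dc": lambda p: (p.tip_dc_small or p.interior_dc_large
                                or p.it_dc_large),
    "reversed_dn": lambda p: p.tip_dn_large or p.interior_dn_small,
    "ranges_disjoint": lambda p: p.ranges_disjoint,
    "long_distance_dn": lambda p: p.tip_dn_large or p.it_dn_large,
    "expansion_dc": lambda p: p.interior_dc_small or p.tip_dc_large,
    "ranges_contiguous": lambda p: not p.ranges_disjoint,
}


def apply_inference_key(pattern: CladePattern) -> InferenceOutcome:
    """Walk the encoded inference key for one nesting group's pattern."""
    pattern.validate()
    key = _load_key()
    node = key["root"]
    chain: list[str] = []
    while True:
        step = key["steps"][node]
        answer = _PREDICATES[step["question"]](pattern)
        chain.append(f"{node}:{'yes' if answer else 'no'}")
        nxt = step["yes"] if answer else step["no"]
        if isinstance(nxt, dict):
            return InferenceOutcome(pattern.clade, chain, nxt["conclusion"])
        node = nxt


def pattern_from_stats(nest_label: str,
                       stats: list[CladeGeoStats],
                       design: NestedDesign,
                       dataset: Dataset,
                       alpha: float = 0.05) -> CladePattern:
    """Build the key's input pattern for one nesting clade from tested stats."""
    tiers = _levels_with_zero(design, dataset)
    nest = None
    for tier in tiers:
        for c in tier:
            if c.label == nest_label:
                nest = c
    if nest is None:
        raise KeyError(nest_label)
    subs = {s.clade: s for s in stats if s.nested_in == nest_label}
    p = CladePattern(clade=nest_label)
    pops_by_sub = []
    for s in subs.values():
        sig_small_dc = s.p_dc_small is not None and s.p_dc_small <= alpha
        sig_large_dc = s.p_dc_large is not None and s.p_dc_large <= alpha
        sig_small_dn = s.p_dn_small is not None and s.p_dn_small <= alpha
        sig_large_dn = s.p_dn_large is not None and s.p_dn_large <= alpha
        if any([sig_small_dc, sig_large_dc, sig_small_dn, sig_large_dn]):
            p.any_significant = True
        kind = "interior" if s.interior else "tip"
        if sig_small_dc:
            setattr(p, f"{kind}_dc_small", True)
        if sig_large_dc:
            setattr(p, f"{kind}_dc_large", True)
        if sig_small_dn:
            setattr(p, f"{kind}_dn_small", True)
        if sig_large_dn:
            setattr(p, f"{kind}_dn_large", True)
        p.per_clade.append({"clade": s.clade,
                            "dc_small": sig_small_dc, "dc_large": sig_large_dc,
                            "dn_small": sig_small_dn, "dn_large": sig_large_dn})
        # population footprint, for range overlap
        label_clades = [c for tier in tiers for c in tier if c.label == s.clade]
        haps = label_clades[0].observed_haplotypes
        pops_by_sub.append({pop.code for pop in dataset.populations
                            if any(pop.counts.get(h, 0) for h in haps)})
    if len(pops_by_sub) >= 2:
        overlap = False
        for i in range(len(pops_by_sub)):
            for j in range(i + 1, len(pops_by_sub)):
                if pops_by_sub[i] & pops_by_sub[j]:
                    overlap = True
        p.ranges_disjoint = not overlap
    return p


def run_ncpa(design: NestedDesign, dataset: Dataset,
             n_perm: int = 10_000, seed: int = 0):
    """Full NCPA: permutation tests plus a key inference per nesting group.

    Returns ``(stats, outcomes)``; outcomes cover every nesting clade with
    at least two observed subclades.
    """
    stats = ncpa_permutation_test(design, dataset, n_perm=n_perm, seed=seed)
    outcomes = []
    nests = sorted({s.nested_in for s in stats if s.nested_in is not None})
    for nest_label in nests:
        pat = pattern_from_stats(nest_label, stats, design, dataset)
        outcomes.append(apply_inference_key(pat))
    return stats, outcomes
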