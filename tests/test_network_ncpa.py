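"""Parsimony networks, clade nesting, geographic clade statistics and the
inference key."""

import itertools

import networkx as nx
import numpy as np
import pytest

from haplogeo.core import Dataset, HaplotypeSet, PopulationSample
from haplogeo.geo import haversine_km
from haplogeo.ncpa import (CladePattern, apply_inference_key, clade_distances,
                           ncpa_permutation_test)
from haplogeo.network import (build_parsimony_network, nest_clades,
                              parsimony_connection_limit,
                              parsimony_probability)


def _limit_oracle(m, conf=0.95):
    """Independent cumulative-product evaluation of the step probability."""
    j = 1
    while True:
        p, nxt = 1.0, j + 1
        for i in range(1, nxt):
            p *= 1 - i / (2 * m)
        if p <= conf:
            return j
        j += 1


def test_connection_limit_values_and_monotonicity():
    assert parsimony_connection_limit(627) == _limit_oracle(627) == 11
    assert parsimony_connection_limit(858) == _limit_oracle(858) == 13
    assert parsimony_connection_limit(50) >= 1
    limits = [parsimony_connection_limit(m) for m in (100, 400, 900, 1600)]
    assert limits == sorted(limits)
    assert parsimony_probability(1, 500) == 1.0


def test_cp_limit_exceeds_max_observed_distance(cp_dataset):
    d = cp_dataset.haplotypes.distance_matrix()
    assert parsimony_connection_limit(cp_dataset.haplotypes.effective_length) \
        >= d.max()


def _mst_weight(dataset):
    d = dataset.haplotypes.distance_matrix()
    g = nx.Graph()
    ids = dataset.haplotypes.haplotype_ids
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            g.add_edge(a, b, weight=d[ids.index(a), ids.index(b)])
    return sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))


def test_networks_attain_parsimony_bound(cp_dataset, pal_dataset):
    """With mutually compatible sites the network length equals the number
    of mutations (one per coded binary split), which cannot exceed the
    minimum-spanning-tree weight over observed haplotypes."""
    for ds in (cp_dataset, pal_dataset):
        net = build_parsimony_network(ds)
        assert net.n_components == 1
        n_splits = 0
        hs = ds.haplotypes
        for j in range(hs.n_polymorphic_sites):
            n_splits += len({r[j] for r in hs.state_matrix}) - 1
        assert net.total_steps == n_splits
        assert net.total_steps <= _mst_weight(ds)
        # tree over nodes: every edge spans exactly one step
        assert net.graph.number_of_edges() == net.graph.number_of_nodes() - 1


def test_network_shortest_paths_bound_distances(cp_dataset):
    net = build_parsimony_network(cp_dataset)
    d = cp_dataset.haplotypes.distance_matrix()
    hs = cp_dataset.haplotypes
    for a, b in itertools.combinations(hs.haplotype_ids, 2):
        sp = nx.shortest_path_length(net.graph, a, b)
        assert sp >= d[hs.index(a), hs.index(b)]


def test_two_haplotypes_one_step_edge():
    hs = HaplotypeSet(["A", "B"], [("C",), ("T",)], [5], 100)
    ds = Dataset("toy", "maternal-haploid", hs,
                 [PopulationSample("P1", 20, 100, {"A": 3, "B": 2})])
    net = build_parsimony_network(ds)
    assert net.graph.has_edge("A", "B")
    assert net.total_steps == 1


def test_pal_h3_adjacent_to_h1_and_h6(pal_dataset):
    net = build_parsimony_network(pal_dataset)
    assert net.graph.has_edge("H3", "H1")
    assert net.graph.has_edge("H3", "H6")


def test_observed_frequencies_sum_to_total(cp_dataset):
    net = build_parsimony_network(cp_dataset)
    total = sum(a["frequency"] for _, a in net.graph.nodes(data=True))
    assert total == cp_dataset.n_total


def test_disconnection_beyond_limit(cp_dataset):
    net = build_parsimony_network(cp_dataset, connection_limit=2)
    assert net.n_components > 1


# ---- nesting --------------------------------------------------------------

def test_star_of_three_is_single_one_step_clade():
    hs = HaplotypeSet(["A", "B", "C", "D"],
                      [("C", "C", "C"), ("T", "C", "C"),
                       ("C", "T", "C"), ("C", "C", "T")],
                      [1, 2, 3], 100)
    ds = Dataset("toy", "maternal-haploid", hs,
                 [PopulationSample("P1", 20, 100,
                                   {"A": 5, "B": 1, "C": 1, "D": 1})])
    design = nest_clades(build_parsimony_network(ds), ds)
    assert design.n_clades(1) == 1
    assert design.clades(1)[0].observed_haplotypes == ["A", "B", "C", "D"]


def test_nesting_is_exhaustive_and_exclusive(cp_dataset, pal_dataset):
    for ds in (cp_dataset, pal_dataset):
        net = build_parsimony_network(ds)
        design = nest_clades(net, ds)
        nodes = set(net.graph.nodes())
        for lvl in range(1, design.n_levels + 1):
            seen = []
            for c in design.clades(lvl):
                seen.extend(c.members)
            assert sorted(seen) == sorted(nodes)          # partition
        # strict nesting: every clade is inside one clade of the next level
        for lvl in range(1, design.n_levels):
            for c in design.clades(lvl):
                parents = [p for p in design.clades(lvl + 1)
                           if set(c.members) <= set(p.members)]
                assert len(parents) == 1


def test_nesting_partition_on_random_networks():
    from haplogeo.simulate import SimulationConfig, simulate_island_model
    checked = 0
    for seed in range(60):
        ds, _, _, _ = simulate_island_model(SimulationConfig(
            n_pops=4, copies_per_pop=6, theta=2.0, migration=2.0,
            sequence_length=1200, seed=500 + seed))
        net = build_parsimony_network(ds)
        if net.n_components != 1 or net.graph.number_of_nodes() < 3:
            continue
        design = nest_clades(net, ds)
        nodes = set(net.graph.nodes())
        for lvl in range(1, design.n_levels + 1):
            seen = [m for c in design.clades(lvl) for m in c.members]
            assert sorted(seen) == sorted(nodes)
        checked += 1
    assert checked >= 30


def test_fixture_clade_structure(cp_dataset, pal_dataset):
    cp_design = nest_clades(build_parsimony_network(cp_dataset), cp_dataset)
    # published: seven 1-step and three 2-step clades
    assert cp_design.n_clades(1) == 7
    assert cp_design.n_clades(2) == 3
    # stated memberships (labels matched by membership, not string)
    one_step = [set(c.observed_haplotypes) for c in cp_design.clades(1)]
    assert {"C3", "C10", "C11"} in one_step
    assert {"C1", "C4", "C5", "C6", "C8"} in one_step
    two_step = [set(c.observed_haplotypes) for c in cp_design.clades(2)]
    assert {"C2", "C12"} in two_step

    pal_design = nest_clades(build_parsimony_network(pal_dataset), pal_dataset)
    assert pal_design.n_clades(2) == 3
    # five observed one-step clades (plus one inferred-intermediate unit)
    assert pal_design.n_clades(1, observed_only=True) == 5


# ---- clade geographic statistics ------------------------------------------

def test_single_population_clade_has_zero_dc(cp_dataset):
    design = nest_clades(build_parsimony_network(cp_dataset), cp_dataset)
    stats = {s.clade: s for s in clade_distances(design, cp_dataset)}
    # C3 occurs only in population MD
    assert stats["C3"].Dc == pytest.approx(0.0, abs=1e-9)


def test_two_equal_observations_dc_is_half_separation():
    hs = HaplotypeSet(["A", "B"], [("C",), ("T",)], [1], 100)
    ds = Dataset("toy", "maternal-haploid", hs, [
        PopulationSample("P1", 24.0, 100.0, {"A": 5}),
        PopulationSample("P2", 24.0, 101.0, {"A": 5, "B": 5}),
    ])
    design = nest_clades(build_parsimony_network(ds), ds)
    stats = {s.clade: s for s in clade_distances(design, ds)}
    sep = haversine_km(24.0, 100.0, 24.0, 101.0)
    assert stats["A"].Dc == pytest.approx(sep / 2, rel=1e-4)


def test_dc_dn_match_brute_force_oracle(cp_dataset):
    """Dc recomputed from expanded per-copy observation lists."""
    design = nest_clades(build_parsimony_network(cp_dataset), cp_dataset)
    stats = {s.clade: s for s in clade_distances(design, cp_dataset)}
    for clade in design.clades(1):
        if not clade.observed_haplotypes:
            continue
        pts = []
        for pop in cp_dataset.populations:
            for h in clade.observed_haplotypes:
                pts.extend([(pop.latitude, pop.longitude)] *
                           pop.counts.get(h, 0))
        pts = np.array(pts)
        # oracle: spherical centroid by normalized vector mean of all copies
        lat, lon = np.radians(pts[:, 0]), np.radians(pts[:, 1])
        v = np.column_stack([np.cos(lat) * np.cos(lon),
                             np.cos(lat) * np.sin(lon), np.sin(lat)]).mean(0)
        v /= np.linalg.norm(v)
        c_lat = np.degrees(np.arcsin(v[2]))
        c_lon = np.degrees(np.arctan2(v[1], v[0]))
        oracle = np.mean([haversine_km(p[0], p[1], c_lat, c_lon) for p in pts])
        assert stats[clade.label].Dc == pytest.approx(oracle, abs=1e-6)


def test_permutation_significance_is_seed_stable(pal_dataset):
    design = nest_clades(build_parsimony_network(pal_dataset), pal_dataset)
    a = ncpa_permutation_test(design, pal_dataset, n_perm=100, seed=7)
    b = ncpa_permutation_test(design, pal_dataset, n_perm=100, seed=7)
    pa = {s.clade: s.p_dc_small for s in a}
    pb = {s.clade: s.p_dc_small for s in b}
    assert pa == pb


# ---- inference key --------------------------------------------------------

def test_key_no_significant_is_inconclusive():
    out = apply_inference_key(CladePattern(clade="x", any_significant=False))
    assert "inconclusive" in out.conclusion
    assert out.chain == ["1:no"]


def test_key_fragmentation_chain():
    """The significance pattern reported for the western chloroplast clade
    (tips with restricted Dc, disjoint ranges) walks to fragmentation."""
    pattern = CladePattern(clade="1-1", any_significant=True,
                           tip_dc_small=True, ranges_disjoint=True)
    out = apply_inference_key(pattern)
    assert out.conclusion == "allopatric fragmentation"
    assert out.chain == ["1:yes", "2:yes", "3:no", "4:yes", "9:yes"]


def test_key_restricted_gene_flow_with_ibd():
    """Restricted Dc with overlapping ranges: the nuclear total cladogram."""
    pattern = CladePattern(clade="total", any_significant=True,
                           tip_dc_small=True, interior_dc_large=True,
                           ranges_disjoint=False)
    out = apply_inference_key(pattern)
    assert out.conclusion == "restricted gene flow with isolation by distance"


def test_key_contiguous_range_expansion():
    pattern = CladePattern(clade="2-3", any_significant=True,
                           interior_dc_small=True, tip_dc_large=True,
                           ranges_disjoint=False)
    out = apply_inference_key(pattern)
    assert out.conclusion == "contiguous range expansion"


def test_key_rejects_contradictory_flags():
    pattern = CladePattern(clade="x", any_significant=True, tip_dc_small=True)
    pattern.per_clade.append({"clade": "c", "dc_small": True, "dc_large": True})
    with pytest.raises(ValueError):
        apply_inference_key(pattern)
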