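"""Differentiation estimators, AMOVA, pairwise F_ST, Mantel IBD."""

import itertools
import math

import numpy as np
import pytest

from haplogeo.core import Dataset, HaplotypeSet, PopulationSample
from haplogeo.differentiation import (amova, gst_nst, ibd_for_dataset,
                                      linearized_fst, mantel_ibd, nst_gst_test,
                                      pairwise_fst, slatkin_m)
from haplogeo.geo import geographic_distance_matrix, haversine_km


def _toy_dataset(counts_by_pop, states=None):
    haps = sorted({h for c in counts_by_pop.values() for h in c})
    if states is None:
        states = {h: (h,) for h in haps}   # all pairwise distance 1
    hs = HaplotypeSet(haps, [tuple(states[h]) for h in haps],
                      list(range(1, len(next(iter(states.values()))) + 1)), 100)
    pops = [PopulationSample(code, 20.0 + i, 100.0 + i, c)
            for i, (code, c) in enumerate(counts_by_pop.items())]
    return Dataset("toy", "maternal-haploid", hs, pops)


def test_gst_nst_fixture_values(cp_dataset, pal_dataset):
    cp = gst_nst(cp_dataset)
    pal = gst_nst(pal_dataset)
    # printed: cp 0.988 / 0.989, PAL 0.222 / 0.301 (estimator variant of the
    # original program unpublished; agreement to ~0.005/0.01)
    assert cp.G_ST == pytest.approx(0.988, abs=0.005)
    assert cp.N_ST == pytest.approx(0.989, abs=0.005)
    assert pal.G_ST == pytest.approx(0.222, abs=0.005)
    assert pal.N_ST == pytest.approx(0.301, abs=0.01)
    assert pal.N_ST > pal.G_ST


def test_identical_frequencies_give_zero_gst():
    ds = _toy_dataset({"P1": {"a": 5, "b": 5}, "P2": {"a": 5, "b": 5}})
    s = gst_nst(ds)
    assert s.G_ST <= 0.0 + 1e-12   # only the sampling correction below zero


def test_equal_distances_make_nst_equal_gst(cp_dataset):
    k = len(cp_dataset.haplotypes.haplotype_ids)
    s = gst_nst(cp_dataset, distance_matrix=1.0 - np.eye(k))
    assert s.N_ST == pytest.approx(s.G_ST, abs=1e-12)


def test_nst_invariant_under_distance_scaling(pal_dataset):
    d = pal_dataset.haplotypes.distance_matrix()
    assert gst_nst(pal_dataset, d * 7.5).N_ST == \
        pytest.approx(gst_nst(pal_dataset, d).N_ST, abs=1e-12)


def test_permutation_test_is_seed_reproducible(pal_dataset):
    a = nst_gst_test(pal_dataset, n_perm=200, seed=42)
    b = nst_gst_test(pal_dataset, n_perm=200, seed=42)
    c = nst_gst_test(pal_dataset, n_perm=200, seed=43)
    assert (a.U, a.p_value) == (b.U, b.p_value)
    assert a.p_value != c.p_value or a.U != c.U


def test_nst_test_flags_low_permutations(pal_dataset):
    r = nst_gst_test(pal_dataset, n_perm=50, seed=1)
    assert r.notes


def test_equal_distance_permutation_null(cp_dataset):
    """With all off-diagonal distances equal, N_ST == G_ST exactly and the
    permutation p-value is non-significant."""
    k = len(cp_dataset.haplotypes.haplotype_ids)
    r = nst_gst_test(cp_dataset, distance_matrix=1.0 - np.eye(k),
                     n_perm=200, seed=3)
    assert r.N_ST == pytest.approx(r.G_ST, abs=1e-12)
    assert r.p_value > 0.2


# ---- AMOVA ----------------------------------------------------------------

def test_amova_reproduces_published_tables(cp_dataset, pal_dataset):
    cp = amova(cp_dataset)
    assert cp.SS_among == pytest.approx(75.668, abs=5e-3)
    assert cp.SS_within == pytest.approx(0.889, abs=5e-3)
    assert cp.SS_total == pytest.approx(76.557, abs=5e-3)
    assert cp.sigma2_among == pytest.approx(0.43397, abs=5e-5)
    assert cp.sigma2_within == pytest.approx(0.00549, abs=5e-5)
    assert cp.pct_among == pytest.approx(98.75, abs=0.01)
    assert cp.F_ST == pytest.approx(0.9875, abs=5e-4)
    assert cp.df_among == 20 and cp.df_within == 162
    pal = amova(pal_dataset)
    assert pal.SS_among == pytest.approx(31.327, abs=5e-3)
    assert pal.SS_within == pytest.approx(82.841, abs=5e-3)
    assert pal.pct_among == pytest.approx(22.51, abs=0.01)
    assert pal.pct_within == pytest.approx(77.49, abs=0.01)
    assert pal.F_ST == pytest.approx(0.225, abs=5e-4)
    assert pal.df_among == 20 and pal.df_within == 253


def test_amova_percentages_sum_to_100(cp_dataset, pal_dataset):
    for ds in (cp_dataset, pal_dataset):
        for metric in ("identity", "steps"):
            a = amova(ds, metric=metric)
            assert a.pct_among + a.pct_within == pytest.approx(100.0, abs=1e-9)


def test_amova_identical_populations_nonpositive_among():
    ds = _toy_dataset({"P1": {"a": 5, "b": 5}, "P2": {"a": 5, "b": 5}})
    a = amova(ds)
    assert a.sigma2_among <= 0
    assert a.pct_among <= 0


def test_amova_permutation_p(cp_dataset):
    a = amova(cp_dataset, n_perm=200, seed=9)
    assert a.p_value <= 0.01
    b = amova(cp_dataset, n_perm=200, seed=9)
    assert a.p_value == b.p_value


# ---- pairwise F_ST --------------------------------------------------------

def test_pairwise_fst_fixed_and_identical():
    ds = _toy_dataset({"P1": {"a": 8}, "P2": {"b": 8}, "P3": {"a": 8}})
    f = pairwise_fst(ds)
    assert f[0, 1] == pytest.approx(1.0)
    assert math.isnan(f[0, 2])   # same fixed haplotype: undefined (0/0)


def test_pairwise_fst_against_two_pop_oracle(cp_dataset):
    """CNB {8 C1 + 1 C2} vs BD {8 C1}: direct variance-component oracle."""
    # oracle on the expanded copies, identity metric
    def oracle(c1, c2):
        pops = [c1, c2]
        ns = [sum(c.values()) for c in pops]
        N = sum(ns)
        def ssd(c):
            n = sum(c.values())
            pairs_diff = 0
            items = list(c.items())
            for i, (h1, x1) in enumerate(items):
                for h2, x2 in items[i + 1:]:
                    pairs_diff += x1 * x2
            return pairs_diff / n
        allc = {}
        for c in pops:
            for h, x in c.items():
                allc[h] = allc.get(h, 0) + x
        sst, ssw = ssd(allc), sum(ssd(c) for c in pops)
        s2w = (sst - ssw) and None  # placeholder to keep names distinct
        ssa = sst - ssw
        s2w = ssw / (N - 2)
        nprime = (N - sum(n * n for n in ns) / N) / 1
        s2a = (ssa / 1 - s2w) / nprime
        return s2a / (s2a + s2w)

    f = pairwise_fst(cp_dataset)
    codes = [p.code for p in cp_dataset.populations]
    i, j = codes.index("CNB"), codes.index("BD")
    expect = oracle({"C1": 8, "C2": 1}, {"C1": 8})
    assert f[i, j] == pytest.approx(expect, abs=1e-12)


# ---- geography ------------------------------------------------------------

def test_haversine_arc_minute():
    # one arc-minute of latitude at fixed longitude
    d = haversine_km(24.0, 100.0, 24.0 + 1 / 60, 100.0)
    assert d == pytest.approx(1.853, abs=2e-3)


def test_haversine_against_law_of_cosines_oracle():
    lat1, lon1 = 21 + 50 / 60, 100.1     # BD
    lat2, lon2 = 24.75, 99 + 47 / 60     # CNB
    p1, p2 = math.radians(lat1), math.radians(lat2)
    oracle = 6371.0088 * math.acos(
        math.sin(p1) * math.sin(p2)
        + math.cos(p1) * math.cos(p2) * math.cos(math.radians(lon2 - lon1)))
    assert haversine_km(lat1, lon1, lat2, lon2) == pytest.approx(oracle, abs=0.1)


def test_distance_matrix_zero_diagonal(cp_dataset):
    g = geographic_distance_matrix(cp_dataset.coordinates())
    assert np.allclose(np.diag(g), 0)
    assert haversine_km(24.0, 100.0, 24.0, 100.0) == 0.0


# ---- Mantel ---------------------------------------------------------------

def test_mantel_self_correlation_is_one():
    rng = np.random.default_rng(2)
    f = rng.uniform(0.05, 0.6, size=(6, 6))
    f = (f + f.T) / 2
    np.fill_diagonal(f, 0)
    km = np.exp(linearized_fst(f))    # geo distance whose log IS the transform
    r = mantel_ibd(f, km, n_perm=0)
    assert r.mantel_r == pytest.approx(1.0, abs=1e-9)


def test_mantel_r_invariant_under_affine_geo_rescaling():
    rng = np.random.default_rng(3)
    f = rng.uniform(0.05, 0.6, size=(7, 7)); f = (f + f.T) / 2
    np.fill_diagonal(f, 0)
    km = rng.uniform(10, 500, size=(7, 7)); km = (km + km.T) / 2
    np.fill_diagonal(km, 0)
    a = mantel_ibd(f, km, n_perm=0).mantel_r
    b = mantel_ibd(f, km * 3.0, n_perm=0).mantel_r   # ln(c*d) = ln c + ln d
    assert a == pytest.approx(b, abs=1e-9)


def test_slatkin_transforms_cap_extremes():
    assert slatkin_m(np.array([0.0]))[0] == pytest.approx((1 / 0.0025 - 1) / 2)
    assert slatkin_m(np.array([1.0]))[0] == 0.0
    assert np.isfinite(linearized_fst(np.array([1.0]))[0])


def test_ibd_fixture_values(cp_dataset, pal_dataset):
    pal = ibd_for_dataset(pal_dataset, n_perm=500, seed=4)
    assert pal.mantel_r == pytest.approx(0.234, abs=0.01)
    assert pal.p_value < 0.05
    cp = ibd_for_dataset(cp_dataset, n_perm=500, seed=4)
    assert cp.p_value > 0.02     # no clear signal at the chloroplast locus
    assert cp.n_pairs == 189     # 21 identical fixed pairs excluded
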