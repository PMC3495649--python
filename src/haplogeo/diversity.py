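"""Within-unit diversity and neutrality statistics.

Implements the DnaSP-style summary statistics for haplotype samples:
haplotype (gene) diversity *h* with the unbiased n/(n-1) correction, the
mean number of pairwise differences *K*, nucleotide diversity per site
pi = K / L_eff, the number of segregating coded sites *S*, Tajima's *D*,
Fu & Li's *D\\**, and the Hudson–Kaplan minimum number of recombination
events *Rm* (four-gamete interval algorithm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Dataset

__all__ = [
    "DiversitySummary", "NeutralityResult",
    "haplotype_diversity", "mean_pairwise_differences", "nucleotide_diversity",
    "segregating_sites", "diversity_summary", "per_population_summaries",
    "tajimas_d", "tajimas_d_band", "fu_li_dstar",
    "min_recombination_events", "neutrality_tests",
]


@dataclass
class DiversitySummary:
    unit: str
    S: int
    n: int
    h: float
    pi: float
    K: float


@dataclass
class NeutralityResult:
    tajima_D: float
    tajima_band: str
    fu_li_Dstar: float
    fu_li_band: str
    eta: int
    eta_s: int
    Rm: int


def haplotype_diversity(counts: dict[str, int]) -> float:
    """Nei's unbiased gene diversity h = n/(n-1) (1 - sum p_i^2)."""
    n = sum(counts.values())
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2 gene copies")
    return n / (n - 1) * (1.0 - sum((c / n) ** 2 for c in counts.values()))


def mean_pairwise_differences(counts: dict[str, int],
                              dataset: Dataset) -> float:
    """K: average mutational differences over all n(n-1)/2 sequence pairs."""
    n = sum(counts.values())
    if n < 2:
        raise ValueError("K needs n >= 2 gene copies")
    d = dataset.haplotypes.distance_matrix()
    idx = {h: i for i, h in enumerate(dataset.haplotypes.haplotype_ids)}
    total = 0.0
    items = list(counts.items())
    for a in range(len(items)):
        ha, xa = items[a]
        for b in range(a + 1, len(items)):
            hb, xb = items[b]
            total += xa * xb * d[idx[ha], idx[hb]]
    return total / (n * (n - 1) / 2)


def nucleotide_diversity(K: float, effective_length: int) -> float:
    if effective_length <= 0:
        raise ValueError("effective_length must be positive")
    return K / effective_length


def segregating_sites(counts: dict[str, int], dataset: Dataset) -> int:
    """Coded sites polymorphic among the haplotypes present in ``counts``."""
    present = [dataset.haplotypes.index(h) for h, c in counts.items() if c > 0]
    S = 0
    for j in range(dataset.haplotypes.n_polymorphic_sites):
        if len({dataset.haplotypes.state_matrix[i][j] for i in present}) > 1:
            S += 1
    return S


def diversity_summary(dataset: Dataset, unit: str = "Total",
                      counts: dict[str, int] | None = None) -> DiversitySummary:
    counts = dataset.total_counts() if counts is None else counts
    counts = {h: c for h, c in counts.items() if c > 0}
    n = sum(counts.values())
    K = mean_pairwise_differences(counts, dataset)
    return DiversitySummary(
        unit=unit,
        S=segregating_sites(counts, dataset),
        n=n,
        h=haplotype_diversity(counts),
        pi=nucleotide_diversity(K, dataset.haplotypes.effective_length),
        K=K,
    )


def per_population_summaries(dataset: Dataset) -> list[DiversitySummary]:
    out = [diversity_summary(dataset, pop.code, pop.counts)
           for pop in dataset.populations]
    out.append(diversity_summary(dataset, "Total"))
    return out


# ---------------------------------------------------------------------------
# Neutrality tests
# ---------------------------------------------------------------------------

def _harmonics(n: int):
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    return a1, a2


def tajimas_d(n: int, S: int, K: float) -> float:
    """Tajima's D from sample size, segregating sites and mean differences."""
    if S < 1:
        raise ValueError("Tajima's D is undefined for S = 0")
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (K - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def tajimas_d_band(n: int, D: float) -> str:
    """Significance band from the rescaled-beta approximation to D's null.

    D is assumed to range between its theoretical extremes with mean 0 and
    variance 1; the band is reported DnaSP-style (e.g. ``"P > 0.10"``),
    not as an exact p-value.
    """
    a1, _ = _harmonics(n)
    e2 = _tajima_e2(n)
    dmin = (2.0 / n - 1.0 / a1) / math.sqrt(e2)
    dmax = ((n + 1) / (2.0 * n) - 1.0 / a1) / math.sqrt(e2)
    alpha = -(1 + dmin * dmax) * dmax / (dmax - dmin)
    beta = (1 + dmin * dmax) * dmin / (dmax - dmin)
    x = (D - dmin) / (dmax - dmin)
    x = min(max(x, 1e-12), 1 - 1e-12)
    cdf = stats.beta.cdf(x, beta, alpha)
    p_two = 2 * min(cdf, 1 - cdf)
    return _band(p_two)


def _tajima_e2(n: int) -> float:
    a1, a2 = _harmonics(n)
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    return c2 / (a1 ** 2 + a2)


def _band(p: float) -> str:
    for cut in (0.001, 0.01, 0.02, 0.05, 0.10):
        if p < cut:
            return f"P < {cut:g}"
    return "P > 0.1"


def fu_li_dstar(n: int, eta: int, eta_s: int) -> float:
    """Fu & Li's D* from total mutations eta and singleton mutations eta_s.

    Uses the corrected closed-form variance coefficients (the version
    standard population-genetics software applies).
    """
    if eta < 1:
        raise ValueError("D* is undefined for eta = 0")
    if n < 3:
        raise ValueError("D* needs n >= 3")
    an = sum(1.0 / i for i in range(1, n))
    an1 = an + 1.0 / n
    bn = sum(1.0 / i ** 2 for i in range(1, n))
    cn = 2.0 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (cn + (n - 2) / (n - 1) ** 2
          + 2.0 / (n - 1) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n))
    v = ((n / (n - 1.0)) ** 2 * bn + an ** 2 * dn
         - 2 * (n * an * (an + 1)) / ((n - 1.0) ** 2)) / (an ** 2 + bn)
    u = (n / (n - 1.0)) * (an - n / (n - 1.0)) - v
    return ((n / (n - 1.0)) * eta - an * eta_s) / math.sqrt(u * eta + v * eta ** 2)


def fu_li_dstar_band(n: int, Dstar: float) -> str:
    """Conservative band for D*: the +/-1.7 / +/-2.1 envelope brackets the
    2% and 5% critical points across the sample sizes used here."""
    if abs(Dstar) < 1.7:
        return "P > 0.1"
    if abs(Dstar) < 2.1:
        return "P < 0.05"
    return "P < 0.02"


def _binary_site_matrix(dataset: Dataset, counts: dict[str, int] | None = None):
    """Haplotype x site 0/1 matrix over biallelic coded sites (among the
    haplotypes present), plus per-haplotype copy numbers."""
    counts = dataset.total_counts() if counts is None else counts
    present = [h for h, c in counts.items() if c > 0]
    rows = [dataset.haplotypes.state_matrix[dataset.haplotypes.index(h)]
            for h in present]
    cols = []
    for j in range(dataset.haplotypes.n_polymorphic_sites):
        states = sorted({r[j] for r in rows})
        if len(states) == 2:
            cols.append([states.index(r[j]) for r in rows])
    mat = np.array(cols, dtype=int).T if cols else np.zeros((len(rows), 0), int)
    weights = np.array([counts[h] for h in present])
    return mat, weights


def min_recombination_events(site_matrix: np.ndarray) -> int:
    """Hudson–Kaplan Rm: maximum number of non-overlapping site intervals
    whose endpoints fail the four-gamete test.

    ``site_matrix`` is haplotypes x biallelic sites (0/1); rows are weighted
    implicitly by presence (copy numbers do not matter for gamete types).
    """
    n_sites = site_matrix.shape[1]
    intervals = []
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            gametes = {(a, b) for a, b in zip(site_matrix[:, i], site_matrix[:, j])}
            if len(gametes) == 4:
                intervals.append((i, j))
                break  # nearest incompatible partner suffices for the scan
    # greedy interval scheduling on open intervals (i, j)
    intervals.sort(key=lambda iv: iv[1])
    rm, last_end = 0, -1
    for i, j in intervals:
        if i >= last_end:
            rm += 1
            last_end = j
    return rm


def neutrality_tests(dataset: Dataset) -> NeutralityResult:
    """Tajima's D, Fu & Li's D* and Rm for the pooled dataset.

    eta is taken as the number of segregating coded sites (no multiple hits
    at these divergence levels); eta_s counts sites where the rarer state
    is carried by exactly one gene copy.
    """
    counts = dataset.total_counts()
    n = sum(counts.values())
    S = segregating_sites(counts, dataset)
    K = mean_pairwise_differences(counts, dataset)
    mat, w = _binary_site_matrix(dataset, counts)
    eta_s = 0
    for j in range(mat.shape[1]):
        tallies = (w[mat[:, j] == 1].sum(), w[mat[:, j] == 0].sum())
        if min(tallies) == 1:
            eta_s += 1
    D = tajimas_d(n, S, K)
    Dstar = fu_li_dstar(n, S, eta_s)
    return NeutralityResult(
        tajima_D=D, tajima_band=tajimas_d_band(n, D),
        fu_li_Dstar=Dstar, fu_li_band=fu_li_dstar_band(n, Dstar),
        eta=S, eta_s=eta_s,
        Rm=min_recombination_events(mat),
    )
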