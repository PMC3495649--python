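"""Among-population structure: G_ST/N_ST, AMOVA, pairwise F_ST, and
isolation by distance.

Two families of estimators are provided:

* Frequency/distance diversity partitioning in the Pons–Petit style.
  ``G_ST = 1 - h_S/h_T`` uses the 0/1 haplotype mismatch indicator;
  ``N_ST`` is the same construction with pairwise mutational distances, so
  ``N_ST > G_ST`` indicates phylogeographic structure (closely related
  haplotypes co-occur).  ``h_S`` is the sample-size-weighted mean of the
  per-population unbiased diversities and ``h_T`` the diversity of the
  unweighted mean haplotype frequencies across populations.  The published
  HAPLONST internals are not fully specified; this variant reproduces the
  study's printed values most closely (see docs/methods.md).

* One-level AMOVA (Excoffier): sums of squared inter-individual distances
  partitioned among/within populations, variance components by the moment
  equations with the weighted average sample size n', F_ST and a
  permutation p-value.  The default metric is haplotype identity (0/1),
  which is what reproduces the study's printed AMOVA table; any distance
  matrix (e.g. mutational steps) may be supplied instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import Dataset
from .geo import geographic_distance_matrix

__all__ = [
    "DifferentiationSummary", "AMOVAResult", "IBDResult",
    "gst_nst", "nst_gst_test", "amova", "pairwise_fst", "mantel_ibd",
    "slatkin_m", "linearized_fst",
]


@dataclass
class DifferentiationSummary:
    h_S: float
    h_T: float
    v_S: float
    v_T: float
    G_ST: float
    N_ST: float
    U: float | None = None
    p_value: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    notes: list[str] = field(default_factory=list)


@dataclass
class AMOVAResult:
    df_among: int
    df_within: int
    SS_among: float
    SS_within: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    F_ST: float
    p_value: float | None = None
    n_permutations: int | None = None
    seed: int | None = None

    @property
    def SS_total(self) -> float:
        return self.SS_among + self.SS_within


@dataclass
class IBDResult:
    mantel_r: float
    p_value: float | None
    transform_genetic: str
    transform_geo: str
    n_pairs: int
    n_permutations: int | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# G_ST / N_ST
# ---------------------------------------------------------------------------

def _freqs_and_sizes(dataset: Dataset):
    counts = dataset.count_matrix()
    ns = counts.sum(axis=1)
    small = [p.code for p, n in zip(dataset.populations, ns) if n < 2]
    if small:
        raise ValueError(f"populations with n < 2: {small}")
    return counts / ns[:, None], ns


def _diversity_partition(X: np.ndarray, ns: np.ndarray, D: np.ndarray):
    """(within, total) diversity for frequency matrix X under metric D."""
    plug = np.einsum("ki,ij,kj->k", X, D, X)
    unbiased = ns / (ns - 1) * plug
    h_S = float((ns * unbiased).sum() / ns.sum())
    xbar = X.mean(axis=0)
    h_T = float(xbar @ D @ xbar)
    return h_S, h_T


def gst_nst(dataset: Dataset,
            distance_matrix: np.ndarray | None = None) -> DifferentiationSummary:
    """Unordered (G_ST) and ordered (N_ST) differentiation across populations."""
    X, ns = _freqs_and_sizes(dataset)
    D = dataset.haplotypes.distance_matrix() if distance_matrix is None \
        else np.asarray(distance_matrix, float)
    identity = 1.0 - np.eye(X.shape[1])
    h_S, h_T = _diversity_partition(X, ns, identity)
    v_S, v_T = _diversity_partition(X, ns, D)
    return DifferentiationSummary(
        h_S=h_S, h_T=h_T, v_S=v_S, v_T=v_T,
        G_ST=1.0 - h_S / h_T, N_ST=1.0 - v_S / v_T,
    )


def nst_gst_test(dataset: Dataset,
                 distance_matrix: np.ndarray | None = None,
                 n_perm: int = 10_000,
                 seed: int = 0) -> DifferentiationSummary:
    """Permutation test of N_ST > G_ST.

    The null keeps haplotype frequencies fixed and permutes haplotype
    identities in the distance matrix (rows and columns jointly), which
    destroys any association between relatedness and geography.  ``U`` is
    the permutation-standardized difference ``(N_ST - G_ST) / SE_perm`` and
    ``p`` the one-tailed exceedance probability of the observed difference.
    """
    summary = gst_nst(dataset, distance_matrix)
    if n_perm < 100:
        summary.notes.append(f"n_perm={n_perm} is low; p-value is coarse")
    X, ns = _freqs_and_sizes(dataset)
    D = dataset.haplotypes.distance_matrix() if distance_matrix is None \
        else np.asarray(distance_matrix, float)
    rng = np.random.default_rng(seed)
    obs = summary.N_ST - summary.G_ST
    null = np.empty(n_perm)
    k = D.shape[0]
    for b in range(n_perm):
        perm = rng.permutation(k)
        v_S, v_T = _diversity_partition(X, ns, D[np.ix_(perm, perm)])
        null[b] = (1.0 - v_S / v_T) - summary.G_ST
    se = float(null.std(ddof=1))
    summary.U = (obs - float(null.mean())) / se if se > 0 else math.inf
    summary.p_value = float((np.sum(null >= obs) + 1) / (n_perm + 1))
    summary.n_permutations = n_perm
    summary.seed = seed
    return summary


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _amova_components(counts: np.ndarray, D2: np.ndarray):
    """Variance components from population x haplotype counts and squared
    distances D2 between haplotypes."""
    ns = counts.sum(axis=1)
    N = ns.sum()
    K = counts.shape[0]
    pooled = counts.sum(axis=0)
    sst = 0.5 * pooled @ D2 @ pooled / N
    ssw = sum(0.5 * counts[k] @ D2 @ counts[k] / ns[k] for k in range(K))
    ssa = sst - ssw
    df_a, df_w = K - 1, int(N) - K
    s2w = ssw / df_w
    nprime = (N - (ns ** 2).sum() / N) / df_a
    s2a = (ssa / df_a - s2w) / nprime
    return ssa, ssw, s2a, s2w, df_a, df_w


def amova(dataset: Dataset,
          distance_matrix: np.ndarray | None = None,
          metric: str = "identity",
          n_perm: int = 0,
          seed: int = 0) -> AMOVAResult:
    """One-level AMOVA (among / within populations).

    ``metric="identity"`` (default) scores each pair of distinct haplotypes
    as one squared difference — the conventional haplotype-frequency F_ST.
    ``metric="steps"`` uses squared distance = mutational steps, or pass an
    explicit ``distance_matrix`` of squared distances.  Negative variance
    components are reported as computed.  The permutation p-value reassigns
    gene copies to populations (sample sizes fixed).
    """
    counts = dataset.count_matrix()
    if distance_matrix is not None:
        D2 = np.asarray(distance_matrix, float)
    elif metric == "identity":
        D2 = 1.0 - np.eye(counts.shape[1])
    elif metric == "steps":
        D2 = dataset.haplotypes.distance_matrix()
    else:
        raise ValueError(f"unknown metric {metric!r}")
    ssa, ssw, s2a, s2w, df_a, df_w = _amova_components(counts, D2)
    total = s2a + s2w
    fst = s2a / total if total != 0 else 0.0
    result = AMOVAResult(
        df_among=df_a, df_within=df_w, SS_among=ssa, SS_within=ssw,
        sigma2_among=s2a, sigma2_within=s2w,
        pct_among=100 * s2a / total, pct_within=100 * s2w / total,
        F_ST=fst,
    )
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        ns = counts.sum(axis=1).astype(int)
        # expand the copy list; shuffling it reassigns copies to populations
        copies = []
        for k in range(counts.shape[0]):
            for j in range(counts.shape[1]):
                copies.extend([j] * int(counts[k, j]))
        copies = np.array(copies)
        bounds = np.cumsum(ns)[:-1]
        exceed = 0
        for _ in range(n_perm):
            rng.shuffle(copies)
            groups = np.split(copies, bounds)
            perm_counts = np.zeros_like(counts)
            for k, g in enumerate(groups):
                np.add.at(perm_counts[k], g, 1)
            _, _, ps2a, ps2w, _, _ = _amova_components(perm_counts, D2)
            ptot = ps2a + ps2w
            pf = ps2a / ptot if ptot != 0 else 0.0
            if pf >= fst:
                exceed += 1
        result.p_value = (exceed + 1) / (n_perm + 1)
        result.n_permutations = n_perm
        result.seed = seed
    return result


def pairwise_fst(dataset: Dataset,
                 distance_matrix: np.ndarray | None = None,
                 metric: str = "identity") -> np.ndarray:
    """Two-population AMOVA F_ST for every population pair.

    Pairs where both populations are fixed for the same haplotype have no
    variance to partition; their F_ST is NaN (undefined).
    """
    counts = dataset.count_matrix()
    if distance_matrix is not None:
        D2 = np.asarray(distance_matrix, float)
    elif metric == "identity":
        D2 = 1.0 - np.eye(counts.shape[1])
    else:
        D2 = dataset.haplotypes.distance_matrix()
    K = counts.shape[0]
    out = np.zeros((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            sub = counts[[a, b]]
            ssa, ssw, s2a, s2w, _, _ = _amova_components(sub, D2)
            total = s2a + s2w
            f = np.nan if (ssa + ssw) == 0 else (s2a / total if total != 0 else 0.0)
            out[a, b] = out[b, a] = f
    return out


# ---------------------------------------------------------------------------
# Isolation by distance
# ---------------------------------------------------------------------------

F_MIN = 0.0025   # cap for non-positive / saturated F_ST in the transforms
F_MAX = 1.0 - F_MIN


def slatkin_m(fst: np.ndarray) -> np.ndarray:
    """Slatkin's island-model gene-flow measure M = (1/F_ST - 1)/2.

    F_ST is clipped to [F_MIN, 1] so that undifferentiated pairs map to the
    finite cap M = (1/F_MIN - 1)/2 instead of infinity.
    """
    f = np.clip(np.asarray(fst, float), F_MIN, 1.0)
    return (1.0 / f - 1.0) / 2.0


def linearized_fst(fst: np.ndarray) -> np.ndarray:
    """Slatkin's linearized genetic distance F_ST / (1 - F_ST), with F_ST
    clipped to [F_MIN, F_MAX] to keep fixed pairs finite."""
    f = np.clip(np.asarray(fst, float), F_MIN, F_MAX)
    return f / (1.0 - f)


def mantel_ibd(fst_matrix: np.ndarray,
               km_matrix: np.ndarray,
               n_perm: int = 10_000,
               seed: int = 0,
               transform: str = "linearized_fst") -> IBDResult:
    """Mantel test of isolation by distance.

    Correlates a transform of pairwise F_ST with ln(geographic distance in
    km) over all population pairs.  Pairs with undefined F_ST (NaN: both
    populations fixed for the same haplotype) and pairs at zero geographic
    distance are excluded.  Significance comes from jointly permuting the
    rows/columns of the genetic matrix; the p-value is one-tailed for the
    observed sign of r.

    ``transform="linearized_fst"`` (default) uses F/(1-F), a genetic
    distance expected to INCREASE with distance under isolation by
    distance; ``transform="slatkin_m"`` uses the gene-flow measure
    M = (1/F-1)/2, expected to DECREASE.
    """
    F = np.asarray(fst_matrix, float)
    G = np.asarray(km_matrix, float)
    if F.shape != G.shape:
        raise ValueError("matrix shapes differ")
    tf = {"linearized_fst": linearized_fst, "slatkin_m": slatkin_m}[transform]
    K = F.shape[0]
    iu = np.triu_indices(K, 1)

    def stat(Fm):
        gen = tf(Fm[iu])
        geo = G[iu]
        keep = np.isfinite(Fm[iu]) & (geo > 0)
        return float(np.corrcoef(gen[keep], np.log(geo[keep]))[0, 1]), int(keep.sum())

    r_obs, n_pairs = stat(F)
    p = None
    if n_perm and n_perm >= 1:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(K)
            r_p, _ = stat(F[np.ix_(perm, perm)])
            if (r_p >= r_obs) if r_obs >= 0 else (r_p <= r_obs):
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    return IBDResult(mantel_r=r_obs, p_value=p,
                     transform_genetic=transform, transform_geo="ln(km)",
                     n_pairs=n_pairs, n_permutations=n_perm or None,
                     seed=seed if n_perm else None)


def ibd_for_dataset(dataset: Dataset, n_perm: int = 10_000, seed: int = 0,
                    transform: str = "linearized_fst") -> IBDResult:
    """Convenience: pairwise F_ST + great-circle distances + Mantel test."""
    F = pairwise_fst(dataset)
    G = geographic_distance_matrix(dataset.coordinates())
    return mantel_ibd(F, G, n_perm=n_perm, seed=seed, transform=transform)
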