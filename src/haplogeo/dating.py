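"""Kimura two-parameter distances, net between-clade divergence, and
divergence dating with a substitution-rate range.

Divergence times follow T = d_A / (2 mu): the net divergence per site
between two clades, d_A = d_XY - (d_X + d_Y)/2, accumulates on both
branches, so halving by 2 mu (substitutions per site per year) converts it
to years since the split.  Indel-coded sites are excluded from K2P, which
is defined for nucleotide substitutions only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Dataset

__all__ = ["DivergenceEstimate", "k2p_distance", "net_divergence",
           "divergence_time", "clade_divergence"]

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass
class DivergenceEstimate:
    clade_pair: tuple[str, str]
    d_A: float
    mu_low: float
    mu_high: float
    T_low_mya: float | None
    T_high_mya: float | None
    estimable: bool = True


def _classify(a: str, b: str) -> str | None:
    """'ts' (transition), 'tv' (transversion) or None (not a substitution)."""
    if a == b:
        return None
    if a in _PURINES and b in _PURINES:
        return "ts"
    if a in _PYRIMIDINES and b in _PYRIMIDINES:
        return "ts"
    if (a in _PURINES and b in _PYRIMIDINES) or \
       (a in _PYRIMIDINES and b in _PURINES):
        return "tv"
    return None   # gap / indel state: excluded


def k2p_distance(seq_a, seq_b, length: int) -> float:
    """Kimura two-parameter distance per site.

    ``seq_a``/``seq_b`` are equal-length state sequences; ``length`` is the
    number of substitution-eligible sites (sites not compared, e.g. the
    monomorphic remainder of an alignment, count as identical).  Raises on
    saturation (log argument <= 0).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    ts = tv = 0
    for a, b in zip(seq_a, seq_b):
        kind = _classify(a.upper() if isinstance(a, str) else a,
                         b.upper() if isinstance(b, str) else b)
        if kind == "ts":
            ts += 1
        elif kind == "tv":
            tv += 1
    P, Q = ts / length, tv / length
    w1, w2 = 1.0 - 2 * P - Q, 1.0 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("K2P distance saturated (log argument <= 0)")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def _substitution_length(dataset: Dataset) -> int:
    """Sites usable by K2P: effective length minus indel-coded sites."""
    hs = dataset.haplotypes
    n_indel = 0
    for j in range(hs.n_polymorphic_sites):
        states = {r[j] for r in hs.state_matrix}
        if any(_classify(a, b) is None for a in states for b in states if a != b):
            n_indel += 1
    return hs.effective_length - n_indel


def net_divergence(dataset: Dataset,
                   clade_x: list[str], clade_y: list[str],
                   weighted: bool = True) -> float:
    """Net K2P divergence per site: d_A = d_XY - (d_X + d_Y)/2.

    Within- and between-clade mean distances weight haplotypes by observed
    frequency by default (``weighted=False`` treats haplotypes uniformly).
    """
    if not clade_x or not clade_y:
        raise ValueError("both clades must be non-empty")
    hs = dataset.haplotypes
    counts = dataset.total_counts()
    L = _substitution_length(dataset)

    def w(h):
        return counts.get(h, 0) if weighted else 1.0

    def mean_between(A, B):
        tot = sw = 0.0
        for a in A:
            for b in B:
                d = k2p_distance(hs.state_matrix[hs.index(a)],
                                 hs.state_matrix[hs.index(b)], L)
                tot += w(a) * w(b) * d
                sw += w(a) * w(b)
        return tot / sw if sw else 0.0

    def mean_within(A):
        tot = sw = 0.0
        for i, a in enumerate(A):
            for b in A[i + 1:]:
                d = k2p_distance(hs.state_matrix[hs.index(a)],
                                 hs.state_matrix[hs.index(b)], L)
                tot += w(a) * w(b) * d
                sw += w(a) * w(b)
        # mean over unordered pairs incl. self-pairs contributes 0; use
        # frequency-weighted mean over distinct-copy pairs
        n = sum(w(a) for a in A)
        pairs = n * (n - 1) / 2.0
        return tot / pairs if pairs else 0.0

    return mean_between(clade_x, clade_y) - 0.5 * (mean_within(clade_x)
                                                   + mean_within(clade_y))


def divergence_time(d_A: float, mu_low: float, mu_high: float,
                    clade_pair=("X", "Y")) -> DivergenceEstimate:
    """T = d_A / (2 mu) in MYA; the fast rate gives T_low."""
    if mu_low <= 0 or mu_high <= 0:
        raise ValueError("substitution rates must be positive")
    if d_A < 0:
        return DivergenceEstimate(tuple(clade_pair), d_A, mu_low, mu_high,
                                  None, None, estimable=False)
    t_low = d_A / (2 * mu_high) / 1e6
    t_high = d_A / (2 * mu_low) / 1e6
    return DivergenceEstimate(tuple(clade_pair), d_A, mu_low, mu_high,
                              t_low, t_high)


def clade_divergence(dataset: Dataset, clades: dict[str, list[str]],
                     mu_low: float = 1.0e-9, mu_high: float = 3.0e-9,
                     weighted: bool = True) -> list[DivergenceEstimate]:
    """Net divergence and dating for every pair of named clades."""
    labels = sorted(clades)
    out = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            dA = net_divergence(dataset, clades[a], clades[b], weighted=weighted)
            out.append(divergence_time(dA, mu_low, mu_high, (a, b)))
    return out
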