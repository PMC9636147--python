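"""Diversity indices, AMOVA and haplogroup-composition homogeneity.

AMOVA follows the Excoffier sums-of-squares partition of squared
molecular distances (here: counts of differing substitution sites) into
among-group and within-group components, with Φ_ST tested by label
permutation. Variance components can legitimately be negative and are
reported as-is.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import EmptyGroupError
from .reference import HotspotList
from .variants import MT_LENGTH, VariantProfile, pairwise_differences


@dataclass(frozen=True)
class DiversitySummary:
    n: int
    k: int                       # distinct haplotypes
    haplotype_diversity: float   # H in [0, 1]
    nucleotide_diversity: float  # pi, per site
    segregating_sites: int
    mean_pairwise_differences: float
    flags: Tuple[str, ...] = ()


def diversity(profiles: Sequence[VariantProfile],
              hotspots: Optional[HotspotList] = None,
              callable_sites: Optional[int] = None) -> DiversitySummary:
    """Molecular diversity summary of a panel.

    H = n/(n−1)·(1 − Σ pᵢ²) over haplotype frequencies; π = mean
    pairwise substitution differences per callable site.
    """
    n = len(profiles)
    hs = hotspots.positions if hotspots else frozenset()
    L = callable_sites if callable_sites is not None else MT_LENGTH - len(hs)
    keys = [p.haplotype_key(hs) for p in profiles]
    counts = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    k_distinct = len(counts)

    flags: Tuple[str, ...] = ()
    if n < 2:
        return DiversitySummary(n=n, k=k_distinct, haplotype_diversity=float("nan"),
                                nucleotide_diversity=0.0, segregating_sites=0,
                                mean_pairwise_differences=0.0,
                                flags=("undefined_n_lt_2",))

    freqs = np.array(list(counts.values())) / n
    H = n / (n - 1) * (1.0 - float(np.sum(freqs ** 2)))

    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += pairwise_differences(profiles[i], profiles[j], hs)
    n_pairs = n * (n - 1) // 2
    mpd = total / n_pairs

    seg = set()
    all_states = [p.substitution_state(hs) for p in profiles]
    union_pos = set().union(*(set(s) for s in all_states)) if all_states else set()
    for pos in union_pos:
        alleles = {s.get(pos) for s in all_states}
        if len(alleles) > 1:
            seg.add(pos)

    return DiversitySummary(n=n, k=k_distinct, haplotype_diversity=H,
                            nucleotide_diversity=mpd / L,
                            segregating_sites=len(seg),
                            mean_pairwise_differences=mpd, flags=flags)


# ---------------------------------------------------------------------------
# AMOVA

@dataclass(frozen=True)
class AmovaResult:
    groups: Tuple[str, ...]
    group_sizes: Tuple[int, ...]
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    percent_among: float
    percent_within: float
    phi_st: float
    p_value: float
    n_permutations: int
    seed: Optional[int]


def distance_matrix(profiles: Sequence[VariantProfile],
                    hotspots: Optional[HotspotList] = None) -> np.ndarray:
    """Pairwise substitution-difference matrix (symmetric, zero diagonal)."""
    hs = hotspots.positions if hotspots else frozenset()
    n = len(profiles)
    D = np.zeros((n, n))
    states = [p.substitution_state(hs) for p in profiles]
    missing = [set(p.missing_positions) for p in profiles]
    for i in range(n):
        for j in range(i + 1, n):
            skip = missing[i] | missing[j]
            si = {p: a for p, a in states[i].items() if p not in skip}
            sj = {p: a for p, a in states[j].items() if p not in skip}
            d = sum(1 for pos in set(si) | set(sj) if si.get(pos) != sj.get(pos))
            D[i, j] = D[j, i] = d
    return D


def _amova_components(D2: np.ndarray, labels: np.ndarray
                      ) -> Tuple[float, float, float, float, float]:
    """(ss_among, ss_within, sigma2_among, sigma2_within, phi_st) on a
    squared-distance matrix and integer group labels."""
    N = len(labels)
    groups = np.unique(labels)
    k = len(groups)
    ss_total = D2.sum() / (2 * N)
    ss_within = 0.0
    sizes = []
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sizes.append(len(idx))
        if len(idx) > 1:
            ss_within += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_among = ss_total - ss_within
    df_among = k - 1
    df_within = N - k
    sizes = np.array(sizes, dtype=float)
    n_c = (N - (sizes ** 2).sum() / N) / df_among
    sigma2_within = ss_within / df_within if df_within > 0 else 0.0
    ms_among = ss_among / df_among
    sigma2_among = (ms_among - sigma2_within) / n_c
    total_var = sigma2_among + sigma2_within
    phi = sigma2_among / total_var if total_var != 0 else 0.0
    return ss_among, ss_within, sigma2_among, sigma2_within, phi


def amova(groups: Mapping[str, Sequence[VariantProfile]],
          hotspots: Optional[HotspotList] = None,
          n_permutations: int = 999, seed: Optional[int] = None,
          distances: Optional[np.ndarray] = None) -> AmovaResult:
    """One-level AMOVA across the given groups.

    Distances are squared before partitioning (Excoffier convention).
    The permutation p-value is (#{Φ_perm ≥ Φ_obs} + 1)/(n_perm + 1),
    reproducible under ``seed``. Groups of size 1 are allowed with a
    warning.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise EmptyGroupError("AMOVA requires at least two groups")
    profiles: List[VariantProfile] = []
    labels: List[int] = []
    for gi, name in enumerate(names):
        members = list(groups[name])
        if not members:
            raise EmptyGroupError(f"group {name!r} is empty")
        if len(members) == 1:
            warnings.warn(f"group {name!r} has a single member")
        profiles.extend(members)
        labels.extend([gi] * len(members))
    labels_arr = np.array(labels)

    D = distances if distances is not None else distance_matrix(profiles, hotspots)
    if D.shape != (len(profiles), len(profiles)):
        raise ValueError("distance matrix shape does not match profiles")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    D2 = D.astype(float) ** 2

    ss_a, ss_w, s2a, s2w, phi = _amova_components(D2, labels_arr)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels_arr)
        *_, phi_perm = _amova_components(D2, perm)
        if phi_perm >= phi - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)

    total_var = s2a + s2w
    pct_a = 100.0 * s2a / total_var if total_var != 0 else 0.0
    return AmovaResult(
        groups=tuple(names),
        group_sizes=tuple(len(groups[n]) for n in names),
        ss_among=ss_a, ss_within=ss_w,
        df_among=len(names) - 1, df_within=len(profiles) - len(names),
        sigma2_among=s2a, sigma2_within=s2w,
        percent_among=pct_a, percent_within=100.0 - pct_a,
        phi_st=phi, p_value=p,
        n_permutations=n_permutations, seed=seed)


def pairwise_phist(groups: Mapping[str, Sequence[VariantProfile]],
                   hotspots: Optional[HotspotList] = None,
                   n_permutations: int = 999, seed: Optional[int] = None
                   ) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Pairwise Φ_ST matrix with permutation p-values.

    Each pair's Φ_ST is the among-group proportion of a two-group AMOVA
    on that pair. Returns (phi_matrix, p_matrix, group_names).
    """
    names = sorted(groups)
    k = len(names)
    phi = np.zeros((k, k))
    pvals = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = amova({names[i]: groups[names[i]], names[j]: groups[names[j]]},
                        hotspots=hotspots, n_permutations=n_permutations,
                        seed=seed)
            phi[i, j] = phi[j, i] = res.phi_st
            pvals[i, j] = pvals[j, i] = res.p_value
    return phi, pvals, names


# ---------------------------------------------------------------------------
# Haplogroup-composition homogeneity

@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    dropped_rows: Tuple[int, ...] = ()
    dropped_cols: Tuple[int, ...] = ()
    low_expected_warning: bool = False


def composition_chi2(counts) -> Chi2Result:
    """Pearson χ² homogeneity test on a groups × categories table.

    Zero-margin rows/columns are dropped with a warning; expected counts
    below 5 set ``low_expected_warning``.
    """
    table = np.asarray(counts, dtype=float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("contingency table must hold nonnegative integers")
    drop_r = tuple(int(i) for i in np.flatnonzero(table.sum(axis=1) == 0))
    drop_c = tuple(int(j) for j in np.flatnonzero(table.sum(axis=0) == 0))
    if drop_r or drop_c:
        warnings.warn(f"dropping zero-margin rows {drop_r} / columns {drop_c}")
        keep_r = [i for i in range(table.shape[0]) if i not in drop_r]
        keep_c = [j for j in range(table.shape[1]) if j not in drop_c]
        table = table[np.ix_(keep_r, keep_c)]
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    return Chi2Result(statistic=float(chi2), df=int(df), p_value=float(p),
                      expected=expected, dropped_rows=drop_r, dropped_cols=drop_c,
                      low_expected_warning=bool((expected < 5).any()))
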