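"""Clade age estimation with the ρ statistic.

ρ is the mean number of substitution differences between each sequence
of a clade and the clade's root haplotype; its standard error σ follows
the genealogy-weighted estimator (for a star genealogy, σ = √(ρ/n)).
Ages in years are obtained from a molecular clock μ (substitutions per
site per year) over L callable sites, either as the transparent linear
conversion t = ρ/(μ·L) or with a purifying-selection correction in which
young clades carry a transient excess of mildly deleterious
substitutions: the instantaneous rate multiplier is r(t) = 1 + a·e^(−t/τ)
so E[ρ](t) = μ·L·(t + a·τ·(1 − e^(−t/τ))), inverted numerically. The
correction coefficients ship as a replaceable JSON data file.

Hotspot positions and indels never enter ρ.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
from scipy.optimize import brentq

from .errors import MtFounderError
from .founders import FounderLineage
from .reference import HotspotList
from .variants import MT_LENGTH, Variant, VariantProfile, pairwise_differences

DEFAULT_MU = 2.355e-8  # substitutions per site per year
CORRECTION_NONE = "none"
CORRECTION_PURIFYING = "purifying_selection"


def _load_correction_coefficients() -> Dict[str, float]:
    src = resources.files("mtfounder.data").joinpath("selection_correction.json")
    with src.open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class CladeAgeEstimate:
    rho: float
    sigma: float
    n_sequences: int
    root_profile: Optional[VariantProfile]
    mu: float
    L: int
    age_years: float
    age_sigma_years: float
    correction: str
    label: str = ""
    flags: Tuple[str, ...] = ()

    @property
    def age_kya(self) -> float:
        """Age in thousands of years, rounded to one decimal."""
        return round(self.age_years / 1000.0, 1)

    @property
    def sigma_kya(self) -> float:
        return round(self.age_sigma_years / 1000.0, 1)


def infer_root_profile(clade: Sequence[VariantProfile],
                       outgroup: Optional[VariantProfile] = None,
                       hotspots: Optional[HotspotList] = None
                       ) -> VariantProfile:
    """Strict-consensus root: the substitutions present in every clade
    member (hotspots and indels excluded). An explicit ``outgroup``
    profile, when given, is returned as the root instead."""
    if not clade:
        raise MtFounderError("cannot infer a root for an empty clade")
    if outgroup is not None:
        return outgroup
    hs = hotspots.positions if hotspots else frozenset()
    states = [set(p.substitution_state(hs).items()) for p in clade]
    shared = set.intersection(*states)
    variants = tuple(Variant(pos, None, alt) for pos, alt in sorted(shared))
    return VariantProfile(sample_id="root", variants=variants,
                          population=clade[0].population)


def rho_sigma(clade: Sequence[VariantProfile], root: VariantProfile,
              exclusions: Optional[HotspotList] = None,
              genealogy: Optional[nx.DiGraph] = None
              ) -> Tuple[float, float]:
    """Compute (ρ, σ) for a clade against its root haplotype.

    Without a ``genealogy`` the star approximation is used:
    σ = √(Σdᵢ)/n = √(ρ/n). With a rooted ``genealogy`` (networkx DiGraph,
    edge attribute ``mutations``, leaves named by sample_id) the
    branch-weighted estimator σ² = (1/n²)·Σ_branches nᵢ²·ℓᵢ applies.

    A root substitution absent from a member at a non-missing site means
    the root is not strictly ancestral there; the site is excluded with
    a warning.
    """
    if not clade:
        raise MtFounderError("rho_sigma requires at least one sequence")
    exclude = set(exclusions.positions) if exclusions else set()

    # ancestrality check on the root's own substitutions
    root_states = root.substitution_state(exclude)
    for pos, alt in sorted(root_states.items()):
        for p in clade:
            if pos in p.missing_positions:
                continue
            if p.substitution_state().get(pos) != alt:
                warnings.warn(
                    f"root variant {pos}{alt} absent from {p.sample_id}; "
                    f"site {pos} excluded from rho")
                exclude.add(pos)
                break

    distances = [pairwise_differences(p, root, exclude) for p in clade]
    n = len(clade)
    rho = sum(distances) / n

    if genealogy is None:
        sigma = math.sqrt(sum(distances)) / n
    else:
        rho_tree, sigma = rho_sigma_from_genealogy(genealogy)
        rho = rho_tree
    return rho, sigma


def rho_sigma_from_genealogy(genealogy: nx.DiGraph) -> Tuple[float, float]:
    """(ρ, σ) from an explicit rooted genealogy.

    Edges carry a ``mutations`` attribute; leaves are nodes with no
    out-edges. ρ = (1/n)·Σ nᵢ·ℓᵢ and σ² = (1/n²)·Σ nᵢ²·ℓᵢ, where nᵢ is
    the number of leaves below branch i of length ℓᵢ mutations.
    """
    roots = [v for v in genealogy if genealogy.in_degree(v) == 0]
    if len(roots) != 1:
        raise MtFounderError(f"genealogy must have exactly one root, got {roots}")
    leaves = [v for v in genealogy if genealogy.out_degree(v) == 0]
    n = len(leaves)
    below: Dict[object, int] = {}

    def count(v) -> int:
        if v in below:
            return below[v]
        kids = list(genealogy.successors(v))
        below[v] = 1 if not kids else sum(count(k) for k in kids)
        return below[v]

    count(roots[0])
    total = 0.0
    var = 0.0
    for u, v, data in genealogy.edges(data=True):
        length = float(data.get("mutations", 0))
        total += below[v] * length
        var += below[v] ** 2 * length
    return total / n, math.sqrt(var) / n


def _corrected_rho_of_t(t: float, mu: float, L: float,
                        a: float, tau: float) -> float:
    return mu * L * (t + a * tau * (1.0 - math.exp(-t / tau)))


def rho_to_years(rho: float, sigma: float, mu: float = DEFAULT_MU,
                 L: int = MT_LENGTH, correction: str = CORRECTION_NONE,
                 n_sequences: int = 0,
                 root_profile: Optional[VariantProfile] = None,
                 label: str = "", flags: Tuple[str, ...] = ()
                 ) -> CladeAgeEstimate:
    """Convert (ρ, σ) to years under the chosen clock.

    ``correction="none"`` is the linear clock t = ρ/(μ·L);
    ``"purifying_selection"`` inverts the time-dependent rate curve and
    converts σ by the local slope dt/dρ.
    """
    if mu <= 0 or L <= 0:
        raise MtFounderError("mu and L must be positive")
    if rho < 0:
        raise MtFounderError("rho cannot be negative")

    if correction == CORRECTION_NONE or rho == 0.0:
        age = rho / (mu * L)
        age_sigma = sigma / (mu * L)
    elif correction == CORRECTION_PURIFYING:
        coef = _load_correction_coefficients()
        a, tau = float(coef["a"]), float(coef["tau_years"])
        upper = rho / (mu * L) * 1.001 + 1.0  # uncorrected age bounds the root
        age = brentq(lambda t: _corrected_rho_of_t(t, mu, L, a, tau) - rho,
                     0.0, upper)
        slope = mu * L * (1.0 + a * math.exp(-age / tau))  # drho/dt
        age_sigma = sigma / slope
    else:
        raise MtFounderError(f"unknown correction {correction!r}")

    return CladeAgeEstimate(rho=rho, sigma=sigma, n_sequences=n_sequences,
                            root_profile=root_profile, mu=mu, L=L,
                            age_years=age, age_sigma_years=age_sigma,
                            correction=correction, label=label, flags=flags)


def date_clade(clade: Sequence[VariantProfile],
               root: Optional[VariantProfile] = None,
               hotspots: Optional[HotspotList] = None,
               mu: float = DEFAULT_MU, L: Optional[int] = None,
               correction: str = CORRECTION_NONE,
               genealogy: Optional[nx.DiGraph] = None,
               label: str = "") -> CladeAgeEstimate:
    """End-to-end clade dating: root inference, ρ/σ, clock conversion."""
    if root is None:
        root = infer_root_profile(clade, hotspots=hotspots)
    rho, sigma = rho_sigma(clade, root, hotspots, genealogy)
    callable_sites = L if L is not None else MT_LENGTH - (
        len(hotspots) if hotspots else 0)
    flags: Tuple[str, ...] = ()
    if len(clade) == 1:
        flags = ("low_confidence_n1",)
    return rho_to_years(rho, sigma, mu, callable_sites, correction,
                        n_sequences=len(clade), root_profile=root,
                        label=label, flags=flags)


def date_founder_lineages(lineages: Sequence[FounderLineage],
                          profiles: Sequence[VariantProfile],
                          hotspots: Optional[HotspotList] = None,
                          mu: float = DEFAULT_MU,
                          correction: str = CORRECTION_NONE,
                          comparative: Mapping[str, Sequence[VariantProfile]] = None
                          ) -> List[CladeAgeEstimate]:
    """One age estimate per lineage; ``comparative`` may add extra
    profiles (e.g. other study groups) to a lineage's clade by label."""
    by_id = {p.sample_id: p for p in profiles}
    estimates = []
    for lineage in lineages:
        clade = [by_id[s] for s in lineage.carriers if s in by_id]
        if comparative and lineage.label in comparative:
            clade = clade + list(comparative[lineage.label])
        estimates.append(date_clade(clade, hotspots=hotspots, mu=mu,
                                    correction=correction,
                                    label=lineage.label))
    return estimates


def write_ages_tsv(estimates: Sequence[CladeAgeEstimate], path) -> None:
    import pandas as pd

    rows = [{"lineage": e.label, "n": e.n_sequences,
             "rho": round(e.rho, 4), "sigma": round(e.sigma, 4),
             "age_kya": e.age_kya, "sigma_kya": e.sigma_kya,
             "correction": e.correction,
             "flags": ",".join(e.flags)} for e in estimates]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
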