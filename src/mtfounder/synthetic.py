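"""Two-population synthetic mitogenome panels with planted ground truth.

The generator emulates the design of a founder-effect mitogenome study:
a bottlenecked *study* population carrying founder clades of known
haplogroup, carrier count, age and variant signature, against a *host*
(reference) population without them, plus admixed study individuals who
copy reference haplotypes, hotspot noise and a pathogenicity score table
in which non-founder variation is, by construction, more deleterious.

Founder clades are star genealogies by default (the ρ/σ closed forms
apply exactly); a random bifurcating mode exercises the structured-
genealogy σ path. Every emitted sample is described exactly by the
returned manifest, and identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dating import DEFAULT_MU
from .errors import ConfigError
from .haplogroups import Haplotree, load_haplotree
from .mito_io import PanelRecord, apply_variants
from .pathogenicity import annotate_coding
from .reference import HotspotList, ReferenceGenome, default_hotspots, load_reference
from .variants import MT_LENGTH, SUBSTITUTION, Variant, VariantProfile

_BASES = "ACGT"


@dataclass(frozen=True)
class FounderSpec:
    haplogroup: str          # backbone node the clade hangs off
    carriers: int
    age_years: float
    signature_length: int = 2
    planted_in_reference: int = 0   # exclusivity violations, for tests


@dataclass
class SimulationConfig:
    seed: int = 0
    study_n: int = 144
    reference_n: int = 200
    founders: Tuple[FounderSpec, ...] = ()
    mu: float = DEFAULT_MU
    L: int = MT_LENGTH
    hotspot_noise_rate: float = 0.0
    admixture_fraction: Optional[float] = None  # default: fill non-founder rest
    missing_rate: float = 0.0
    genealogy: str = "star"                     # star | bifurcating
    reference_haplogroups: Tuple[str, ...] = (
        "H1", "H3", "H7a1", "J1c1", "J2b1", "K1a4", "T2", "U3b1", "V", "W", "X")
    reference_private_mean: float = 3.0
    regions: Tuple[str, ...] = ("north", "south", "east", "west")
    region_proportions: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.study_n < 0 or self.reference_n < 0:
            raise ConfigError("panel sizes must be nonnegative")
        for frac in (self.hotspot_noise_rate, self.missing_rate):
            if not 0 <= frac <= 1:
                raise ConfigError("rates must lie in [0, 1]")
        if self.admixture_fraction is not None and not (
                0 <= self.admixture_fraction <= 1):
            raise ConfigError("admixture_fraction must lie in [0, 1]")
        if self.genealogy not in ("star", "bifurcating"):
            raise ConfigError(f"unknown genealogy mode {self.genealogy!r}")


@dataclass
class SimulatedPanel:
    records: List[PanelRecord]
    manifest: Dict
    score_table: pd.DataFrame
    config: SimulationConfig

    def write(self, out_dir) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fasta = out / "panel.fasta"
        meta = out / "metadata.tsv"
        manifest = out / "manifest.json"
        scores = out / "scores.tsv"
        with open(fasta, "w") as fh:
            for r in self.records:
                fh.write(f">{r.sample_id}\n")
                for i in range(0, len(r.sequence), 70):
                    fh.write(r.sequence[i:i + 70] + "\n")
        pd.DataFrame(
            [{"sample_id": r.sample_id, "population": r.population,
              "region": r.region} for r in self.records]
        ).to_csv(meta, sep="\t", index=False)
        with open(manifest, "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
        self.score_table.to_csv(scores, sep="\t", index=False)
        return {"fasta": fasta, "metadata": meta, "manifest": manifest,
                "scores": scores}


class _PositionPool:
    """Draw globally unique non-hotspot, non-backbone positions."""

    def __init__(self, rng: np.random.Generator, reserved: set) -> None:
        candidates = np.array(
            [p for p in range(50, MT_LENGTH - 50) if p not in reserved])
        self._order = rng.permutation(candidates)
        self._next = 0

    def draw(self, k: int) -> List[int]:
        if self._next + k > len(self._order):
            raise ConfigError("position pool exhausted; reduce panel size "
                              "or private-variant rates")
        out = self._order[self._next:self._next + k]
        self._next += k
        return [int(p) for p in out]


def _alt_for(rng: np.random.Generator, ref_base: str) -> str:
    choices = [b for b in _BASES if b != ref_base]
    return choices[int(rng.integers(len(choices)))]


def _variant(reference: ReferenceGenome, rng: np.random.Generator,
             pos: int) -> Variant:
    ref = reference.base_at(pos)
    return Variant(pos, ref, _alt_for(rng, ref), SUBSTITUTION)


def simulate_profiles(config: SimulationConfig,
                      reference: Optional[ReferenceGenome] = None,
                      tree: Optional[Haplotree] = None,
                      hotspots: Optional[HotspotList] = None
                      ) -> Tuple[List[VariantProfile], Dict]:
    """Generate the panel as in-memory variant profiles plus the
    ground-truth manifest (no sequence materialisation or score table —
    the fast path for simulation studies)."""
    rng = np.random.default_rng(config.seed)
    reference = reference or load_reference()
    tree = tree or load_haplotree()
    hotspots = hotspots or default_hotspots()

    for spec in config.founders:
        if spec.haplogroup not in tree.nodes:
            raise ConfigError(f"founder haplogroup {spec.haplogroup!r} "
                              f"not in the haplotree")
    backbone_positions = set()
    for node in tree:
        backbone_positions.update(node.cumulative)
    pool = _PositionPool(rng, reserved=backbone_positions | set(hotspots.positions))

    mu_l = config.mu * config.L
    samples: Dict[str, dict] = {}        # manifest per sample
    lineages: Dict[str, dict] = {}
    profiles: List[VariantProfile] = []

    def cumulative_variants(hg: str) -> List[Variant]:
        node = tree[hg]
        return [Variant(pos, reference.base_at(pos), alt, SUBSTITUTION)
                for pos, alt in sorted(node.cumulative.items())]

    def fmt(v: Variant) -> str:
        return f"{v.ref_allele}{v.position}{v.alt_allele}"

    def draw_variants(count: int) -> List[Variant]:
        return [_variant(reference, rng, p) for p in pool.draw(count)]

    def bifurcating_tips(n: int, age: float) -> List[List[Variant]]:
        """Random bifurcating genealogy of depth ``age``: mutations on
        shared branches are shared between the tips below them."""

        def build(tips: List[int], t: float) -> Dict[int, List[Variant]]:
            if len(tips) == 1:
                return {tips[0]: draw_variants(int(rng.poisson(mu_l * t)))}
            split_t = float(rng.uniform(0, t))
            k = int(rng.integers(1, len(tips)))
            out: Dict[int, List[Variant]] = {}
            for side in (tips[:k], tips[k:]):
                stem = draw_variants(int(rng.poisson(mu_l * (t - split_t))))
                for tip, vs in build(side, split_t).items():
                    out[tip] = stem + vs
            return out

        resolved = build(list(range(n)), age)
        return [resolved[i] for i in range(n)]

    # ---- reference (host) population ------------------------------------
    ref_profiles: List[VariantProfile] = []
    hg_pool = list(config.reference_haplogroups)
    for i in range(config.reference_n):
        sid = f"REF{i + 1:04d}"
        hg = hg_pool[int(rng.integers(len(hg_pool)))]
        variants = cumulative_variants(hg)
        n_priv = int(rng.poisson(config.reference_private_mean))
        priv = [_variant(reference, rng, p) for p in pool.draw(n_priv)]
        prof = VariantProfile(sample_id=sid,
                              variants=tuple(variants + priv),
                              population="reference")
        ref_profiles.append(prof)
        samples[sid] = {"population": "reference", "haplogroup": hg,
                        "founder_lineage": None,
                        "planted_variants": [fmt(v) for v in prof.variants]}

    # ---- founder clades ---------------------------------------------------
    study_profiles: List[VariantProfile] = []
    founder_slots = config.study_n
    if config.admixture_fraction is not None:
        n_admixed_target = round(config.admixture_fraction * config.study_n)
        founder_slots = config.study_n - n_admixed_target
    sid_counter = 0
    for spec in config.founders:
        take = min(spec.carriers, founder_slots - sum(
            l["n_carriers"] for l in lineages.values()))
        if take <= 0:
            continue
        signature = [_variant(reference, rng, p)
                     for p in pool.draw(spec.signature_length)]
        base = cumulative_variants(spec.haplogroup) + signature
        label = f"{spec.haplogroup}+" + "-".join(fmt(v) for v in signature)
        carriers = []
        if config.genealogy == "star":
            counts = rng.poisson(mu_l * spec.age_years, size=take)
            private_per_tip = [draw_variants(int(c)) for c in counts]
        else:
            private_per_tip = bifurcating_tips(take, spec.age_years)
        for priv in private_per_tip:
            sid_counter += 1
            sid = f"IBR{sid_counter:04d}"
            prof = VariantProfile(sample_id=sid,
                                  variants=tuple(base + priv),
                                  population="study")
            study_profiles.append(prof)
            carriers.append(sid)
            samples[sid] = {"population": "study",
                            "haplogroup": spec.haplogroup,
                            "founder_lineage": label,
                            "planted_variants": [fmt(v) for v in prof.variants]}
        lineages[label] = {
            "haplogroup": spec.haplogroup,
            "signature": [fmt(v) for v in signature],
            "carriers": carriers,
            "n_carriers": len(carriers),
            "age_years": spec.age_years,
        }
        # optional exclusivity violations planted into the host panel
        for j in range(spec.planted_in_reference):
            vid = f"REFV{len(ref_profiles) + 1:04d}"
            prof = VariantProfile(sample_id=vid, variants=tuple(base),
                                  population="reference")
            ref_profiles.append(prof)
            samples[vid] = {"population": "reference",
                            "haplogroup": spec.haplogroup,
                            "founder_lineage": label,
                            "planted_variants": [fmt(v) for v in prof.variants]}

    # ---- admixed study samples (copies of host haplotypes) ---------------
    n_founder_emitted = len(study_profiles)
    n_admixed = config.study_n - n_founder_emitted
    true_hosts = [p for p in ref_profiles if not p.sample_id.startswith("REFV")]
    for _ in range(n_admixed):
        sid_counter += 1
        sid = f"IBR{sid_counter:04d}"
        if true_hosts:
            donor = true_hosts[int(rng.integers(len(true_hosts)))]
            prof = VariantProfile(sample_id=sid, variants=donor.variants,
                                  population="study")
            samples[sid] = {"population": "study",
                            "haplogroup": samples[donor.sample_id]["haplogroup"],
                            "founder_lineage": None,
                            "admixed_copy_of": donor.sample_id,
                            "planted_variants": [fmt(v) for v in prof.variants]}
        else:
            # no host pool: draw a fresh backbone haplotype instead
            hg = hg_pool[int(rng.integers(len(hg_pool)))]
            variants = cumulative_variants(hg) + draw_variants(
                int(rng.poisson(config.reference_private_mean)))
            prof = VariantProfile(sample_id=sid, variants=tuple(variants),
                                  population="study")
            samples[sid] = {"population": "study", "haplogroup": hg,
                            "founder_lineage": None,
                            "planted_variants": [fmt(v) for v in prof.variants]}
        study_profiles.append(prof)

    # ---- hotspot noise and regions ---------------------------------------
    hotspot_list = sorted(hotspots.positions)
    all_profiles = study_profiles + ref_profiles
    noisy_profiles: List[VariantProfile] = []
    props = (config.region_proportions
             or tuple(1 / len(config.regions) for _ in config.regions))
    for prof in all_profiles:
        variants = list(prof.variants)
        if config.hotspot_noise_rate and rng.random() < config.hotspot_noise_rate:
            pos = hotspot_list[int(rng.integers(len(hotspot_list)))]
            if all(v.position != pos for v in variants):
                v = _variant(reference, rng, pos)
                variants.append(v)
                samples[prof.sample_id].setdefault("hotspot_noise", []).append(fmt(v))
        missing: set = set()
        if config.missing_rate:
            n_miss = int(rng.binomial(MT_LENGTH, config.missing_rate))
            missing = {int(p) for p in rng.integers(1, MT_LENGTH + 1, size=n_miss)}
            missing -= {v.position for v in variants}
            samples[prof.sample_id]["missing_positions"] = sorted(missing)
        region = config.regions[int(rng.choice(len(config.regions), p=props))]
        samples[prof.sample_id]["region"] = region
        noisy_profiles.append(VariantProfile(
            sample_id=prof.sample_id, variants=tuple(variants),
            population=prof.population, region=region,
            missing_positions=frozenset(missing)))

    founder_sids = {s for l in lineages.values() for s in l["carriers"]}
    manifest = {
        "config": {
            "seed": config.seed, "study_n": config.study_n,
            "reference_n": config.reference_n, "mu": config.mu, "L": config.L,
            "genealogy": config.genealogy,
            "hotspot_noise_rate": config.hotspot_noise_rate,
            "admixture_fraction": config.admixture_fraction,
        },
        "samples": samples,
        "lineages": lineages,
        "expected_founder_fraction": (
            len(founder_sids) / config.study_n if config.study_n else 0.0),
    }
    return noisy_profiles, manifest


def simulate_panel(config: SimulationConfig,
                   reference: Optional[ReferenceGenome] = None,
                   tree: Optional[Haplotree] = None,
                   hotspots: Optional[HotspotList] = None) -> SimulatedPanel:
    """Generate a full panel: FASTA-ready records, metadata, manifest and
    the pathogenicity score table."""
    reference = reference or load_reference()
    noisy_profiles, manifest = simulate_profiles(config, reference, tree, hotspots)
    rng = np.random.default_rng(config.seed + 2_000_003)  # score-table stream
    lineages = manifest["lineages"]

    # ---- pathogenicity score table ----------------------------------------
    founder_sids = {s for l in lineages.values() for s in l["carriers"]}
    founder_keys = set()
    all_keys: Dict[tuple, dict] = {}
    for prof in noisy_profiles:
        is_founder = prof.sample_id in founder_sids
        for cons in annotate_coding(prof, reference):
            if cons.is_synonymous:
                continue
            key = (cons.gene, cons.codon_number, cons.alt_aa)
            if key not in all_keys:
                all_keys[key] = {"gene": cons.gene, "codon": cons.codon_number,
                                 "ref_aa": cons.ref_aa, "alt_aa": cons.alt_aa,
                                 "position": cons.variant.position}
            if is_founder:
                founder_keys.add(key)
    rows = []
    for key in sorted(all_keys):
        row = dict(all_keys[key])
        # founder variation drawn mild, everything else more deleterious
        if key in founder_keys:
            row["score"] = round(float(rng.beta(2, 6)), 4)
        else:
            row["score"] = round(float(rng.beta(6, 2)), 4)
        rows.append(row)
    score_table = pd.DataFrame(
        rows, columns=["gene", "codon", "ref_aa", "alt_aa", "position", "score"])
    for row in rows:
        key = (row["gene"], row["codon"], row["alt_aa"])
        # record scores in the manifest for oracle use
        all_keys[key]["score"] = row["score"]

    records = [PanelRecord(sample_id=p.sample_id,
                           sequence=apply_variants(reference, p),
                           population=p.population, region=p.region)
               for p in noisy_profiles]

    manifest = dict(manifest)
    manifest["variant_consequences"] = [
        {**v, "key": f"{k[0]}:{k[1]}:{k[2]}"} for k, v in sorted(all_keys.items())]
    return SimulatedPanel(records=records, manifest=manifest,
                          score_table=score_table, config=config)


# ---------------------------------------------------------------------------
# Presets

_ROMA_LIKE_FOUNDERS = (
    # two South Asian founder clades (20 carriers, 13.9% of 144) and seven
    # West Eurasian ones (74 carriers, 51.4%), ages in years
    FounderSpec("M5a1b1a1", 14, 1800.0, 2),
    FounderSpec("M18", 6, 1500.0, 2),
    FounderSpec("U3b1", 35, 2100.0, 3),
    FounderSpec("J2b1c", 9, 1200.0, 3),
    FounderSpec("J1b3a", 7, 1500.0, 2),
    FounderSpec("J1c1b", 6, 400.0, 3),
    FounderSpec("H7a1", 6, 1000.0, 2),
    FounderSpec("H88a", 6, 900.0, 2),
    FounderSpec("H3g1", 5, 2500.0, 2),
)


def emulate_study_shape(preset: str = "roma-like", seed: int = 0,
                        reference_n: Optional[int] = None) -> SimulationConfig:
    """Ready-made configs mirroring published study dimensions.

    ``roma-like``: 144 study mitogenomes, 1,066 host mitogenomes, nine
    founder lineages (two South Asian + seven West Eurasian) whose
    carrier counts give an expected founder fraction of 94/144 ≈ 0.653.
    ``reference_n`` can shrink the host panel for quick runs.
    """
    if preset != "roma-like":
        raise ConfigError(f"unknown preset {preset!r}")
    return SimulationConfig(
        seed=seed,
        study_n=144,
        reference_n=reference_n if reference_n is not None else 1066,
        founders=_ROMA_LIKE_FOUNDERS,
        admixture_fraction=None,  # non-founder remainder is admixed
    )
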