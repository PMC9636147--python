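"""End-to-end study workflow.

Runs the stages in dependency order — variant calling, haplogroup
classification, founder scan (study and reference), lineage dating,
per-lineage networks, diversity/AMOVA/χ², pathogenicity load — and
assembles a machine-readable report. The AMOVA between populations is
repeated with all founder-lineage carriers removed, quantifying how much
of the between-population variance the founder lineages explain.

Every stage writes its own artifact into the output directory, a fixed
seed makes the whole run reproducible, and optional stages (network
rendering, pathogenicity) degrade gracefully with logged warnings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from . import __version__
from .dating import (CORRECTION_NONE, DEFAULT_MU, CladeAgeEstimate,
                     date_founder_lineages, write_ages_tsv)
from .errors import ConfigError, MtFounderError
from .founders import (ScanConfig, detect_founder_lineages, exclusive_lineages,
                       founder_fraction_summary, founder_membership,
                       scan_reference_population, write_lineages_tsv)
from .haplogroups import (classify_panel, load_haplotree, load_macrogroup_table,
                          write_calls_tsv)
from .mito_io import call_panel, read_fasta_panel
from .network import build_mj_network, extract_parsimony_tree, render_network
from .pathogenicity import (PathogenicityTable, lineage_load_comparison,
                            write_load_tsv)
from .popgen import amova, composition_chi2, diversity
from .reference import default_hotspots, load_hotspots, load_reference
from .variants import VariantProfile, write_profiles_json

log = logging.getLogger("mtfounder")


@dataclass
class RunConfig:
    fasta: str
    metadata: str
    out_dir: str
    reference_fasta: Optional[str] = None       # rCRS; packaged synthetic if None
    tree: Optional[str] = None                  # packaged mini-tree if None
    hotspots: Optional[str] = None              # packaged default if None
    scores: Optional[str] = None                # pathogenicity table TSV
    study_population: str = "study"
    min_carriers: int = 4
    min_relative_frequency: Optional[float] = None  # default: min_carriers/study_n
    mu: float = DEFAULT_MU
    correction: str = CORRECTION_NONE
    n_permutations: int = 999
    seed: int = 0
    build_networks: bool = True
    exclude_haplogroups: Tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "exclude_haplogroups" in raw:
            raw["exclude_haplogroups"] = tuple(raw["exclude_haplogroups"])
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _diversity_dict(profiles) -> dict:
    d = diversity(profiles)
    return {"n": d.n, "k": d.k,
            "haplotype_diversity": (None if d.haplotype_diversity != d.haplotype_diversity
                                    else round(d.haplotype_diversity, 6)),
            "nucleotide_diversity": round(d.nucleotide_diversity, 8),
            "segregating_sites": d.segregating_sites,
            "mean_pairwise_differences": round(d.mean_pairwise_differences, 4)}


def _amova_dict(res) -> dict:
    return {"groups": list(res.groups), "group_sizes": list(res.group_sizes),
            "percent_among": round(res.percent_among, 4),
            "percent_within": round(res.percent_within, 4),
            "phi_st": round(res.phi_st, 6), "p_value": res.p_value,
            "n_permutations": res.n_permutations}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the study report (also written
    to ``out_dir/report.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("inputs")
        reference = load_reference(config.reference_fasta)
        tree = load_haplotree(config.tree)
        hotspots = (load_hotspots(config.hotspots) if config.hotspots
                    else default_hotspots())
        macro = load_macrogroup_table()
        records = read_fasta_panel(config.fasta, config.metadata)
    except MtFounderError as exc:
        raise MtFounderError(f"stage 'inputs' failed: {exc}") from exc

    stage("variants")
    profiles = call_panel(records, reference)
    write_profiles_json(profiles, out / "profiles.json")
    study = [p for p in profiles if p.population == config.study_population]
    host = [p for p in profiles if p.population != config.study_population]
    if not study:
        raise MtFounderError(
            f"stage 'variants' failed: no samples with population "
            f"{config.study_population!r}")

    stage("classify")
    calls = classify_panel(profiles, tree, hotspots)
    write_calls_tsv(calls, out / "calls.tsv")

    stage("founder scan")
    min_freq = (config.min_relative_frequency
                if config.min_relative_frequency is not None
                else config.min_carriers / len(study))
    scan_cfg = ScanConfig(min_carriers=config.min_carriers,
                          min_relative_frequency=min_freq,
                          hotspots=hotspots, reference_panel=host)
    lineages = detect_founder_lineages(study, calls, scan_cfg,
                                       macro_table=macro)
    write_lineages_tsv(lineages, out / "founders.tsv")
    founders = exclusive_lineages(lineages)
    membership = founder_membership(lineages)
    study_summary = founder_fraction_summary(lineages, study)

    host_summary = None
    if host:
        host_cfg = ScanConfig(min_carriers=config.min_carriers,
                              min_relative_frequency=min_freq,
                              hotspots=hotspots, reference_panel=study)
        host_lineages = scan_reference_population(
            host, calls, host_cfg,
            exclude_haplogroups=config.exclude_haplogroups, macro_table=macro)
        host_summary = founder_fraction_summary(host_lineages, host)

    stage("dating")
    ages = date_founder_lineages(founders, study, hotspots=hotspots,
                                 mu=config.mu, correction=config.correction)
    write_ages_tsv(ages, out / "ages.tsv")
    age_by_label = {e.label: e for e in ages}

    stage("networks")
    if config.build_networks and founders:
        net_dir = out / "networks"
        net_dir.mkdir(exist_ok=True)
        by_id = {p.sample_id: p for p in profiles}
        for lineage in founders:
            try:
                clade = [by_id[s] for s in lineage.carriers]
                network = build_mj_network(clade, hotspots=hotspots)
                from .dating import infer_root_profile
                root = infer_root_profile(clade, hotspots=hotspots)
                ptree = extract_parsimony_tree(network, root, hotspots)
                safe = lineage.haplogroup.replace("/", "_")
                render_network(network, gml_path=net_dir / f"{safe}.gml")
                render_network(ptree, newick_path=net_dir / f"{safe}.nwk",
                               figure_path=net_dir / f"{safe}.png")
            except Exception as exc:  # optional stage: degrade gracefully
                warnings.warn(f"network rendering for {lineage.label} "
                              f"failed: {exc}")

    stage("stats")
    pops = sorted({p.population for p in profiles})
    diversity_report = {pop: _diversity_dict(
        [p for p in profiles if p.population == pop]) for pop in pops}
    regional = {}
    for pop in pops:
        members = [p for p in profiles if p.population == pop]
        regions = sorted({p.region for p in members if p.region})
        regional[pop] = {r: _diversity_dict(
            [p for p in members if p.region == r]) for r in regions}

    composition: Dict[str, Dict[str, int]] = {}
    for p in profiles:
        hg = calls[p.sample_id].haplogroup
        composition.setdefault(p.population, {})
        composition[p.population][hg] = composition[p.population].get(hg, 0) + 1

    amova_report: Dict[str, Optional[dict]] = {}
    seed = config.seed
    if host:
        res = amova({"study": study, "host": host}, hotspots=hotspots,
                    n_permutations=config.n_permutations, seed=seed)
        amova_report["between_populations"] = _amova_dict(res)
        study_nf = [p for p in study if p.sample_id not in membership]
        if study_nf:
            res_nf = amova({"study": study_nf, "host": host}, hotspots=hotspots,
                           n_permutations=config.n_permutations, seed=seed + 1)
            amova_report["between_populations_without_founders"] = _amova_dict(res_nf)
        else:
            amova_report["between_populations_without_founders"] = None
    for pop, key in ((config.study_population, "among_study_regions"),
                     ("__host__", "among_host_regions")):
        members = (study if key == "among_study_regions" else host)
        groups = {}
        for p in members:
            if p.region:
                groups.setdefault(p.region, []).append(p)
        if len(groups) >= 2 and all(len(v) >= 1 for v in groups.values()):
            res = amova(groups, hotspots=hotspots,
                        n_permutations=config.n_permutations, seed=seed + 2)
            amova_report[key] = _amova_dict(res)
        else:
            amova_report[key] = None

    # χ² homogeneity of class composition across study regions
    chi2_report = None
    class_of = {}
    for p in study:
        label = membership.get(p.sample_id)
        if label is None:
            cls = "non-founder"
        else:
            cls = next(l.ancestry_class for l in lineages if l.label == label)
            cls = f"founder ({cls})"
        class_of[p.sample_id] = cls
    regions = sorted({p.region for p in study if p.region})
    classes = sorted(set(class_of.values()))
    if len(regions) >= 2 and len(classes) >= 2:
        table = [[sum(1 for p in study
                      if p.region == r and class_of[p.sample_id] == c)
                  for c in classes] for r in regions]
        chi = composition_chi2(table)
        chi2_report = {"statistic": round(chi.statistic, 4), "df": chi.df,
                       "p_value": chi.p_value, "regions": regions,
                       "classes": classes,
                       "low_expected_warning": chi.low_expected_warning}

    stage("pathogenicity")
    load_report = None
    if config.scores and membership:
        try:
            table = PathogenicityTable.from_tsv(config.scores)
            lineage_classes = {l.label: l.ancestry_class for l in lineages}
            comparisons = lineage_load_comparison(
                study, membership, table, reference,
                lineage_classes=lineage_classes)
            write_load_tsv(comparisons, out / "load.tsv")
            load_report = [{
                "group_a": c.group_a, "group_b": c.group_b,
                "n_a": len(c.scores_a), "n_b": len(c.scores_b),
                "mean_a": round(c.mean_a, 4), "mean_b": round(c.mean_b, 4),
                "U": c.u_statistic, "p_value": c.p_value,
                "method": c.method, "higher_mean": c.direction,
            } for c in comparisons]
        except Exception as exc:
            warnings.warn(f"pathogenicity stage skipped: {exc}")

    stage("report")
    report = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "inputs": {"fasta": _sha256(config.fasta),
                       "metadata": _sha256(config.metadata),
                       **({"scores": _sha256(config.scores)}
                          if config.scores else {})},
        },
        "diversity": {"by_population": diversity_report,
                      "by_region": regional},
        "haplogroup_composition": composition,
        "founder_lineages": [{
            "label": l.label, "haplogroup": l.haplogroup,
            "signature": "-".join(f"{p}{a}" for p, a in l.shared_variants),
            "carrier_count": l.carrier_count,
            "relative_frequency": round(l.relative_frequency, 6),
            "exclusivity": l.exclusivity,
            "ancestry_class": l.ancestry_class,
            **({"age_kya": age_by_label[l.label].age_kya,
                "sigma_kya": age_by_label[l.label].sigma_kya,
                "rho": round(age_by_label[l.label].rho, 4),
                "sigma": round(age_by_label[l.label].sigma, 4)}
               if l.label in age_by_label else {}),
        } for l in lineages],
        "founder_summary": {
            "study": {k: v for k, v in study_summary.items() if k != "membership"},
            "host": ({k: v for k, v in host_summary.items() if k != "membership"}
                     if host_summary else None),
        },
        "amova": amova_report,
        "composition_chi2": chi2_report,
        "pathogenicity": load_report,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    with open(out / "run_config.yml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)
    report_render(report, out / "report.md", out / "founder_fractions.png")
    return report


# ---------------------------------------------------------------------------
# Report rendering and schema validation

def report_render(report: dict, md_path=None, figure_path=None) -> str:
    """Human-readable summary; the founder/non-founder chart fractions are
    taken verbatim from the report."""
    lines = ["# Founder-lineage study report", ""]
    lines.append("## Diversity")
    for pop, d in sorted(report["diversity"]["by_population"].items()):
        lines.append(f"- {pop}: n={d['n']}, haplotypes={d['k']}, "
                     f"H={d['haplotype_diversity']}, "
                     f"pi={d['nucleotide_diversity']}")
    lines.append("")
    lines.append("## Founder lineages")
    for l in report["founder_lineages"]:
        age = (f", TMRCA {l['age_kya']} kya (sigma {l['sigma_kya']})"
               if "age_kya" in l else "")
        lines.append(f"- {l['label']} [{l['ancestry_class']}]: "
                     f"{l['carrier_count']} carriers "
                     f"({100 * l['relative_frequency']:.1f}%), "
                     f"{l['exclusivity']}{age}")
    lines.append("")
    summary = report["founder_summary"]
    lines.append("## Founder vs non-founder fractions")
    fractions: Dict[str, Dict[str, float]] = {}
    for pop_key in ("study", "host"):
        s = summary.get(pop_key)
        if s:
            fractions[pop_key] = dict(s["fractions"])
            lines.append(f"- {pop_key}: founder fraction "
                         f"{100 * s['founder_fraction']:.1f}%")
    lines.append("")
    if report.get("amova"):
        lines.append("## AMOVA")
        for key, a in sorted(report["amova"].items()):
            if a:
                lines.append(f"- {key}: {a['percent_among']:.2f}% among "
                             f"(p = {a['p_value']})")
        lines.append("")
    if report.get("pathogenicity"):
        lines.append("## Pathogenicity load")
        for c in report["pathogenicity"]:
            lines.append(f"- {c['group_a']} vs {c['group_b']}: higher mean in "
                         f"{c['higher_mean']} (U={c['U']}, p={c['p_value']:.3g})")
    text = "\n".join(lines) + "\n"
    if md_path is not None:
        with open(md_path, "w") as fh:
            fh.write(text)
    if figure_path is not None and fractions:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        classes = sorted({c for f in fractions.values() for c in f})
        pops = list(fractions)
        fig, ax = plt.subplots(figsize=(5, 4))
        bottoms = [0.0] * len(pops)
        for cls in classes:
            vals = [fractions[p].get(cls, 0.0) for p in pops]
            ax.bar(pops, vals, bottom=bottoms, label=cls)
            bottoms = [b + v for b, v in zip(bottoms, vals)]
        ax.set_ylabel("fraction of population")
        ax.set_ylim(0, 1)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(figure_path, dpi=120)
        plt.close(fig)
    return text


def load_report_schema() -> dict:
    src = resources.files("mtfounder.data").joinpath("report_schema.json")
    with src.open() as fh:
        return json.load(fh)


def validate_report(report: dict, schema: Optional[dict] = None) -> List[str]:
    """Check a report against the shipped schema (supports the subset of
    JSON Schema the schema uses). Returns a list of problems, empty when
    valid."""
    schema = schema or load_report_schema()
    problems: List[str] = []

    def type_ok(value, expected) -> bool:
        types = expected if isinstance(expected, list) else [expected]
        for t in types:
            if t == "object" and isinstance(value, dict):
                return True
            if t == "array" and isinstance(value, list):
                return True
            if t == "string" and isinstance(value, str):
                return True
            if t == "number" and isinstance(value, (int, float)) \
                    and not isinstance(value, bool):
                return True
            if t == "boolean" and isinstance(value, bool):
                return True
            if t == "null" and value is None:
                return True
        return False

    def walk(value, sch, path):
        if "type" in sch and not type_ok(value, sch["type"]):
            problems.append(f"{path}: expected {sch['type']}, "
                            f"got {type(value).__name__}")
            return
        if isinstance(value, dict):
            for key in sch.get("required", []):
                if key not in value:
                    problems.append(f"{path}: missing required key {key!r}")
            for key, sub in sch.get("properties", {}).items():
                if key in value:
                    walk(value[key], sub, f"{path}.{key}")
        if isinstance(value, list) and "items" in sch:
            for i, item in enumerate(value):
                walk(item, sch["items"], f"{path}[{i}]")

    walk(report, schema, "report")
    return problems
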