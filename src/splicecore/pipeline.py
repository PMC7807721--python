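"""End-to-end orchestration with reproducible, checksummed outputs.

``run_all`` executes the stages in order -- (optional) simulate ->
landscape -> core sets -> controls -> ORF impact -> variation partition ->
splice features -> set statistics -- writing one output directory per
stage and a ``manifest.json`` holding a parameter hash and the sha256 of
every output file.  All numeric output uses fixed decimal formatting so a
rerun with the same seed and configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .as_landscape import (AsCallParams, PanAsParams, detect_panas,
                           percent_as_genes, strong_as_genes)
from .core_sets import (CoreSetCall, GeParams, StressAsParams, TissueAsParams,
                        as_nr_set, common_controls, genome_background, members,
                        set_overlaps, stress_as_core, stress_ge_core,
                        tissue_as_core, tissue_ge_core)
from .coverage_qc import CoverageRule
from .io_formats import (read_design, read_expression_table,
                         read_gene_annotation, read_gene_models,
                         read_psi_table)
from .orf_impact import classify_impact, impact_profile, utr5_enrichment, uorf_enrichment
from .set_stats import event_type_shift
from .splice_features import build_pwms, gene_min_site_scores
from .synthetic_data import SyntheticConfig, generate
from .variation_partition import partition_variation, partition_summary, partitions_frame

log = logging.getLogger(__name__)

FLOAT_FMT = "%.4f"


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    simulate: SyntheticConfig | None = None
    psi_path: Path | None = None
    expression_path: Path | None = None
    design_path: Path | None = None
    gtf_path: Path | None = None
    fasta_path: Path | None = None
    annotations_path: Path | None = None
    coverage: CoverageRule = field(default_factory=CoverageRule)
    as_call: AsCallParams = field(default_factory=AsCallParams)
    panas: PanAsParams = field(default_factory=PanAsParams)
    stress_as: StressAsParams = field(default_factory=StressAsParams)
    tissue_as: TissueAsParams = field(default_factory=TissueAsParams)
    ge: GeParams = field(default_factory=GeParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {"outdir": Path(raw.get("outdir", "splicecore_out")),
                        "seed": int(raw.get("seed", 0))}
        if "simulate" in raw:
            sim = dict(raw["simulate"] or {})
            sim.setdefault("seed", kwargs["seed"])
            if "tissue_types" in sim:
                sim["tissue_types"] = tuple(sim["tissue_types"])
            kwargs["simulate"] = SyntheticConfig(**sim)
        for key, attr in (("psi", "psi_path"), ("expression", "expression_path"),
                          ("design", "design_path"), ("gtf", "gtf_path"),
                          ("fasta", "fasta_path"), ("annotations", "annotations_path")):
            if key in raw:
                kwargs[attr] = Path(raw[key])
        params = raw.get("params", {})
        for key, klass, attr in (("coverage", CoverageRule, "coverage"),
                                 ("as_call", AsCallParams, "as_call"),
                                 ("panas", PanAsParams, "panas"),
                                 ("stress_as", StressAsParams, "stress_as"),
                                 ("tissue_as", TissueAsParams, "tissue_as"),
                                 ("ge", GeParams, "ge")):
            if key in params:
                kwargs[attr] = klass(**params[key])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float) + "\n")


def _calls_frame(calls: list[CoreSetCall]) -> pd.DataFrame:
    rows = [{"item_id": c.item_id, "set": c.set_name,
             "direction": c.direction or "NA",
             "target_tissue": c.target_tissue or "NA",
             "ambiguous": int(c.ambiguous),
             "supporting_contrasts": ";".join(
                 f"{e}:{v:.2f}" for e, v in c.supporting_contrasts)}
            for c in calls]
    return pd.DataFrame(rows, columns=["item_id", "set", "direction",
                                       "target_tissue", "ambiguous",
                                       "supporting_contrasts"])


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def record(stage: str, *paths: Path):
        manifest["stages"].setdefault(stage, {})
        for p in paths:
            manifest["stages"][stage][p.name] = _sha256(p)

    def stage_dir(name: str) -> Path:
        d = outdir / name
        d.mkdir(exist_ok=True)
        return d

    # ---- inputs -----------------------------------------------------------
    try:
        if config.simulate is not None:
            dataset = generate(config.simulate)
            paths = dataset.write(stage_dir("inputs"))
            record("inputs", *paths.values())
            table, expr, design = dataset.psi, dataset.expression, dataset.design
            models = dataset.models
            annotations = dataset.annotations
        else:
            for attr in ("psi_path", "expression_path", "design_path"):
                p = getattr(config, attr)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"missing input {attr}: {p}")
            table = read_psi_table(config.psi_path)
            expr = read_expression_table(config.expression_path)
            design = read_design(config.design_path)
            models = None
            if config.gtf_path is not None:
                for attr in ("gtf_path", "fasta_path"):
                    p = getattr(config, attr)
                    if p is None or not Path(p).exists():
                        raise FileNotFoundError(f"missing input {attr}: {p}")
                models = read_gene_models(config.gtf_path, config.fasta_path)
            annotations = (read_gene_annotation(config.annotations_path)
                           if config.annotations_path else None)
    except Exception as e:
        raise StageError(f"[inputs] {e}") from e

    rule = config.coverage
    tissue_samples = [s for ss in design.tissue_samples().values() for s in ss]
    tissue_table = table.subset_samples(tissue_samples)

    # ---- landscape --------------------------------------------------------
    try:
        d = stage_dir("landscape")
        res = percent_as_genes(table, config.as_call, rule)
        strong = strong_as_genes(table, rule=rule)
        panas = detect_panas(tissue_table, config.panas, rule)
        by_type = pd.Series(res["by_type"], name="n_as_events").sort_index()
        by_type.rename_axis("event_type").to_frame().to_csv(
            d / "as_events_by_type.tsv", sep="\t")
        _write_json({"percent_as_genes": res["percent"],
                     "n_as_genes": res["n_as_genes"], "n_genes": res["n_genes"],
                     "n_strong_as_genes": len(strong),
                     "n_panas_events": len(panas)}, d / "landscape.json")
        pd.Series(sorted(panas), name="event_id").to_csv(
            d / "panas_events.tsv", sep="\t", index=False)
        record("landscape", d / "as_events_by_type.tsv", d / "landscape.json",
               d / "panas_events.tsv")
    except Exception as e:
        raise StageError(f"[landscape] {e}") from e

    # ---- core sets --------------------------------------------------------
    try:
        d = stage_dir("cores")
        calls: dict[str, list[CoreSetCall]] = {}
        for cls in ("abiotic", "biotic"):
            calls[f"{cls}_AS"] = stress_as_core(table, design, cls,
                                                config.stress_as, rule)
            calls[f"{cls}_GE"] = stress_ge_core(expr, design, cls, config.ge)
        calls["tissue_AS"] = tissue_as_core(table, design, config.tissue_as, rule)
        calls["tissue_GE"] = tissue_ge_core(expr, design, config.ge)
        summary = {}
        for name, cs in calls.items():
            _calls_frame(cs).to_csv(d / f"{name}.tsv", sep="\t", index=False)
            mem = members(cs)
            summary[name] = {
                "n_members": len(mem),
                "n_ambiguous": sum(1 for c in cs if c.ambiguous),
                "n_up": sum(1 for c in cs if c.direction == "up"),
                "n_down": sum(1 for c in cs if c.direction == "down")}
            if name.endswith("_AS"):
                types = table.events.loc[sorted(mem), "event_type"]
                summary[name]["by_type"] = types.value_counts().to_dict()
        _write_json(summary, d / "core_summary.json")
        record("cores", *[d / f"{n}.tsv" for n in calls], d / "core_summary.json")
    except Exception as e:
        raise StageError(f"[cores] {e}") from e

    # ---- controls ---------------------------------------------------------
    try:
        d = stage_dir("controls")
        contexts = ("abiotic", "biotic", "tissue")
        genome_sets = {c: genome_background(table, design, c, config.stress_as,
                                            config.tissue_as, rule)
                       for c in contexts}
        nr_sets = {c: as_nr_set(table, design, c, as_params=config.stress_as,
                                tissue_params=config.tissue_as, rule=rule)
                   for c in contexts}
        as_cores = {c: members(calls[f"{c}_AS"]) for c in contexts}
        common_genome, common_nr = common_controls(genome_sets, nr_sets, as_cores)
        for name, sets in (("genome", genome_sets), ("as_nr", nr_sets)):
            for c, s in sets.items():
                pd.Series(sorted(s), name="event_id").to_csv(
                    d / f"{name}_{c}.tsv", sep="\t", index=False)
        pd.Series(sorted(common_genome), name="event_id").to_csv(
            d / "genome_common.tsv", sep="\t", index=False)
        pd.Series(sorted(common_nr), name="event_id").to_csv(
            d / "as_nr_common.tsv", sep="\t", index=False)
        gene_map = table.events["gene_id"].to_dict()
        _write_json(set_overlaps(as_cores, gene_map), d / "core_overlaps.json")
        record("controls", *sorted(d.glob("*.tsv")), d / "core_overlaps.json")
    except Exception as e:
        raise StageError(f"[controls] {e}") from e

    # ---- ORF impact -------------------------------------------------------
    impacts = {}
    if models is not None:
        try:
            d = stage_dir("impact")
            rows = []
            for eid in table.event_ids:
                imp = classify_impact(table.event(eid), models)
                impacts[eid] = imp
                rows.append({"event_id": eid, "category": imp.category,
                             "nmd_predicted": int(imp.nmd_predicted),
                             "truncation_fraction": (FLOAT_FMT % imp.truncation_fraction
                                                     if imp.truncation_fraction is not None
                                                     else "NA"),
                             "truncated_aa": (imp.truncated_aa
                                              if imp.truncated_aa is not None else "NA"),
                             "introduces_frameshift": int(imp.introduces_frameshift),
                             "introduces_stop": int(imp.introduces_stop)})
            pd.DataFrame(rows).to_csv(d / "orf_impact.tsv", sep="\t", index=False)
            outputs = [d / "orf_impact.tsv"]
            enr = {}
            for c in contexts:
                core = sorted(as_cores[c])
                genome = sorted(genome_sets[c])
                if core and genome:
                    profile = impact_profile(core, table.events, impacts)
                    profile.to_csv(d / f"profile_{c}.tsv", sep="\t", index=False,
                                   float_format=FLOAT_FMT)
                    outputs.append(d / f"profile_{c}.tsv")
                    enr[f"utr5_{c}"] = utr5_enrichment(core, genome, impacts)
                    if annotations is not None and "uorf" in annotations.columns:
                        uorf_genes = set(annotations.index[annotations["uorf"] == 1])
                        core_genes = sorted({gene_map[e] for e in core})
                        genome_genes = sorted({gene_map[e] for e in genome})
                        enr[f"uorf_{c}"] = uorf_enrichment(core_genes, genome_genes,
                                                           uorf_genes)
            _write_json(enr, d / "enrichment.json")
            outputs.append(d / "enrichment.json")
            record("impact", *outputs)
        except Exception as e:
            raise StageError(f"[impact] {e}") from e

    # ---- variation partition ---------------------------------------------
    try:
        d = stage_dir("partition")
        parts = partition_variation(table, design, rule)
        frame = partitions_frame(parts)
        frame.to_csv(d / "variation_partition.tsv", sep="\t", index=False,
                     float_format=FLOAT_FMT)
        outputs = [d / "variation_partition.tsv"]
        for name, grid in partition_summary(parts).items():
            grid.to_csv(d / f"grid_{name}.tsv", sep="\t")
            outputs.append(d / f"grid_{name}.tsv")
        record("partition", *outputs)
    except Exception as e:
        raise StageError(f"[partition] {e}") from e

    # ---- splice features ----------------------------------------------------
    if models is not None:
        try:
            d = stage_dir("features")
            donor, acceptor = build_pwms(models)
            donor.to_frame().to_csv(d / "pwm_donor.tsv", sep="\t",
                                    float_format="%.6f")
            acceptor.to_frame().to_csv(d / "pwm_acceptor.tsv", sep="\t",
                                       float_format="%.6f")
            scores = gene_min_site_scores(models, donor, acceptor)
            scores.sort_index().to_csv(d / "gene_min_site_scores.tsv", sep="\t",
                                       float_format=FLOAT_FMT)
            record("features", d / "pwm_donor.tsv", d / "pwm_acceptor.tsv",
                   d / "gene_min_site_scores.tsv")
        except Exception as e:
            raise StageError(f"[features] {e}") from e

    # ---- set statistics ----------------------------------------------------
    try:
        d = stage_dir("stats")
        shifts = {}
        for c in contexts:
            core, nr = as_cores[c], nr_sets[c]
            if core and nr:
                res = event_type_shift(core, nr, table.events["event_type"])
                shifts[c] = {etype: {"odds_ratio": r.odds_ratio,
                                     "p_two_sided": r.p_two_sided}
                             for etype, r in res.items()}
        _write_json(shifts, d / "event_type_shifts.json")
        record("stats", d / "event_type_shifts.json")
    except Exception as e:
        raise StageError(f"[stats] {e}") from e

    manifest["param_hash"] = hashlib.sha256(
        repr((config.seed, config.coverage, config.as_call, config.panas,
              config.stress_as, config.tissue_as, config.ge,
              config.simulate)).encode()).hexdigest()
    _write_json(manifest, outdir / "manifest.json")
    return manifest
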