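"""End-to-end orchestration: synthetic world -> phenotype calls -> pan-genome
-> alleleome -> strain models -> validation -> report.

Each stage reads its inputs from, and persists its outputs to, the run
directory, so stages are individually re-runnable and every number in the
final report is recomputable from persisted intermediates.  A fixed seed
makes the whole run byte-reproducible.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alleleome as alle
from . import pangenome as pg
from . import strains as sm
from .errors import ConfigError
from .fba import GROWTH_TOLERANCE, apply_gapfill, gapfill
from .network import Medium, MetabolicNetwork, load_json, save_json
from .orthology import bbh_map
from .phenotype import CallConfig, CompoundGroup, GrowthCallMatrix, call_growth, group_activity
from .synth import WorldConfig, generate_world, load_plates_csv, stream_rng, write_world

logger = logging.getLogger(__name__)

STAGES = ("simulate", "call", "pangenome", "alleleome", "derive", "gapfill", "validate", "report")


@dataclass
class PipelineConfig:
    outdir: Path
    world: WorldConfig | None = None  # synthetic mode
    input_dir: Path | None = None  # pre-existing inputs laid out like write_world's output
    call: CallConfig = field(default_factory=CallConfig)
    identity_threshold: float = pg.DEFAULT_IDENTITY
    bbh_cutoff: float = 60.0
    bbh_dropout: float = 0.0  # fraction of strain genes hidden from BBH (robustness experiments)
    uptake: float = 10.0
    growth_tolerance: float = GROWTH_TOLERANCE
    core_frequency: float = sm.CORE_FREQUENCY
    rare_frequency: float = sm.RARE_FREQUENCY
    n_blocks: int = 6
    n_mca_axes: int = 2
    glucose_exchange: str = "EX_sub01_e"
    reference_counts: dict[str, int] | None = None  # genes/reactions/metabolites of a reference model
    seed: int = 0

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if (self.world is None) == (self.input_dir is None):
            raise ConfigError("exactly one of a synthetic WorldConfig or an input directory must be supplied")
        for name in ("identity_threshold", "bbh_dropout"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0 <= self.bbh_cutoff <= 100:
            raise ConfigError("bbh_cutoff is a percent identity in [0, 100]")
        if not 0 <= self.rare_frequency <= self.core_frequency <= 1:
            raise ConfigError("need 0 <= rare_frequency <= core_frequency <= 1")

    @property
    def data_dir(self) -> Path:
        return self.input_dir if self.input_dir is not None else self.outdir / "world"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "world" in raw and raw["world"] is not None:
            raw["world"] = WorldConfig(**raw["world"])
        if "call" in raw and raw["call"] is not None:
            raw["call"] = CallConfig(**raw["call"])
        raw.update(overrides)
        return cls(**raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        d["input_dir"] = None if self.input_dir is None else str(self.input_dir)
        return d


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.ndarray,)):
        return x.tolist()
    if isinstance(x, Path):
        return str(x)
    raise TypeError(f"not JSON-serialisable: {type(x)}")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig):
    if cfg.world is None:
        raise ConfigError("simulate stage requires a synthetic WorldConfig")
    world = generate_world(cfg.world)
    out = cfg.outdir / "world"
    out.mkdir(parents=True, exist_ok=True)
    write_world(world, out)
    logger.info("simulate: %d strains, %d families, %d substrates", len(world.strains), len(world.families), len(world.substrates))
    return world


def stage_call(cfg: PipelineConfig) -> GrowthCallMatrix:
    plates = load_plates_csv(cfg.data_dir / "plates.csv")
    calls = call_growth(plates, cfg.call)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    calls.to_frame().to_csv(cfg.outdir / "calls.csv", index=False, float_format="%.17g")
    groups = [CompoundGroup("all substrates", calls.substrates)]
    profile = group_activity(calls, groups)
    profile.fractions.to_csv(cfg.outdir / "activity_fractions.csv", float_format="%.17g")
    profile.index.rename("metabolic_activity_index").to_csv(cfg.outdir / "activity_index.csv", float_format="%.17g")
    logger.info("call: %d strains x %d substrates, %d growth calls", len(calls.strains), len(calls.substrates), int(calls.calls.to_numpy().sum()))
    return calls


def load_calls(cfg: PipelineConfig) -> GrowthCallMatrix:
    df = pd.read_csv(cfg.outdir / "calls.csv")
    calls = df.pivot(index="strain", columns="substrate", values="call") == "growth"
    return GrowthCallMatrix.from_bool(calls)


def stage_pangenome(cfg: PipelineConfig):
    fastas = sorted((cfg.data_dir / "proteomes").glob("*.faa"))
    records = pg.read_proteomes_fasta(fastas)
    strains = sorted({r.strain for r in records})
    families = pg.cluster_gene_families(records, cfg.identity_threshold)
    matrix = pg.build_presence_matrix(families, strains)
    ordering = pg.order_strains_by_shared(matrix)
    curve = pg.core_genome_curve(matrix, ordering)
    pg.families_table(families).to_csv(cfg.outdir / "families.tsv", sep="\t", index=False, float_format="%.17g")
    matrix.matrix.to_csv(cfg.outdir / "presence_matrix.csv")
    pd.DataFrame({"strain": curve.ordering, "core_size": curve.sizes}).to_csv(cfg.outdir / "core_curve.csv", index=False)
    n_blocks = min(cfg.n_blocks, len(strains))
    blocks = pg.cluster_strain_blocks(matrix, n_blocks)
    pd.Series(blocks, name="block").rename_axis("strain").to_csv(cfg.outdir / "strain_blocks.csv")
    logger.info("pangenome: %d families, core %d, pan %d", len(families), matrix.core_size(), matrix.pan_size())
    return families, matrix, curve, blocks


def stage_alleleome(cfg: PipelineConfig, families=None):
    if families is None:
        families, _, _, _ = stage_pangenome(cfg)
    table = alle.build_allele_table(families)
    n_strains = len({m.strain for f in families for m in f.members})
    table.to_frame().to_csv(cfg.outdir / "alleles.tsv", sep="\t", index=False)
    dom = alle.dominant_alleles(table, n_strains)
    pd.DataFrame(
        [{"family_id": fid, "allele": a.name, "strain_count": a.strain_count} for fid, a in dom]
    ).to_csv(cfg.outdir / "dominant_alleles.tsv", sep="\t", index=False)
    clade_rows = []
    newick_dir = cfg.outdir / "allele_trees"
    newick_dir.mkdir(parents=True, exist_ok=True)
    for fid, alleles in table.alleles.items():
        if len(alleles) < 3:
            continue
        split = alle.allele_tree(alleles)
        (newick_dir / f"{fid}.nwk").write_text(split.newick + "\n")
        clade_rows.append(
            {"family_id": fid, "n_alleles": len(alleles), "major_fraction": split.major_fraction}
        )
    clades = pd.DataFrame(clade_rows, columns=["family_id", "n_alleles", "major_fraction"])
    clades.to_csv(cfg.outdir / "clade_summary.csv", index=False, float_format="%.17g")
    logger.info("alleleome: %d families, %d with clade splits", len(table.alleles), len(clades))
    return table, dom, clades


def _load_pan_inputs(cfg: PipelineConfig):
    from Bio import SeqIO

    pan_net = load_json(cfg.data_dir / "universal_model.json")
    pan_proteins = {}
    for rec in SeqIO.parse(str(cfg.data_dir / "pan_proteins.faa"), "fasta"):
        _, _, fam = rec.id.partition("|")
        pan_proteins[fam or rec.id] = str(rec.seq)
    return pan_net, pan_proteins


def stage_derive(cfg: PipelineConfig) -> list[sm.StrainModel]:
    pan_net, pan_proteins = _load_pan_inputs(cfg)
    fastas = sorted((cfg.data_dir / "proteomes").glob("*.faa"))
    records = pg.read_proteomes_fasta(fastas)
    by_strain: dict[str, dict[str, str]] = {}
    for r in records:
        by_strain.setdefault(r.strain, {})[r.gene] = r.sequence
    rng = stream_rng(cfg.seed, "dropout")
    models_dir = cfg.outdir / "models"
    models_dir.mkdir(parents=True, exist_ok=True)
    models = []
    for strain in sorted(by_strain):
        proteome = by_strain[strain]
        if cfg.bbh_dropout > 0:
            kept = {g: s for g, s in proteome.items() if rng.random() >= cfg.bbh_dropout}
            proteome = kept or dict(list(proteome.items())[:1])
        bbh = bbh_map(proteome, pan_proteins, cfg.bbh_cutoff)
        bbh.to_csv(models_dir / f"{strain}_bbh.tsv", sep="\t", index=False, float_format="%.17g")
        model = sm.derive_strain_model(pan_net, bbh, strain)
        save_json(model.network, models_dir / f"{strain}.json")
        models.append(model)
    logger.info("derive: %d strain models from %d pan genes", len(models), len(pan_net.genes))
    return models


def stage_gapfill(cfg: PipelineConfig, models: list[sm.StrainModel] | None = None) -> list[sm.StrainModel]:
    """Ensure every strain model grows on the reference carbon source."""
    pan_net, _ = _load_pan_inputs(cfg)
    if models is None:
        models = _load_models(cfg)
    report = {}
    for model in models:
        result = gapfill(
            model.network, pan_net, cfg.glucose_exchange, cfg.growth_tolerance, Medium(), cfg.uptake
        )
        if result.added:
            model.network = apply_gapfill(model.network, pan_net, result.added)
            model.gapfilled_reactions.extend(result.added)
            save_json(model.network, cfg.outdir / "models" / f"{model.strain}.json")
        report[model.strain] = {"added": result.added, "objective": result.objective_after}
    _write_json(cfg.outdir / "gapfill_report.json", report)
    n_filled = sum(1 for v in report.values() if v["added"])
    logger.info("gapfill: %d/%d models needed additions on %s", n_filled, len(models), cfg.glucose_exchange)
    return models


def _load_models(cfg: PipelineConfig) -> list[sm.StrainModel]:
    models = []
    for path in sorted((cfg.outdir / "models").glob("*.json")):
        if path.name.endswith("_bbh.tsv"):
            continue
        net = load_json(path)
        models.append(sm.StrainModel(path.stem, net))
    return models


def stage_validate(cfg: PipelineConfig, models: list[sm.StrainModel] | None = None) -> dict:
    """Score predictions against the observed calls; refine by gap-filling.

    For every observed-growth cell the model misses, a minimal gap-fill
    against the pan network on that substrate is attempted, echoing the
    phenotype-driven curation loop; accuracy is reported before and after.
    """
    pan_net, _ = _load_pan_inputs(cfg)
    if models is None:
        models = _load_models(cfg)
    observed = load_calls(cfg)
    substrates = observed.substrates
    exchange_of = {s: f"EX_{s}_e" for s in substrates}

    def predict(mods):
        mat = sm.predict_growth_matrix(mods, list(exchange_of.values()), Medium(), cfg.uptake, cfg.growth_tolerance)
        mat.calls.columns = pd.Index(substrates, name="substrate")
        return mat

    before = predict(models)
    score_before = sm.score_predictions(before, observed)

    refined = 0
    for model in models:
        for s in substrates:
            if bool(observed.calls.loc[model.strain, s]) and not bool(before.calls.loc[model.strain, s]):
                try:
                    result = gapfill(
                        model.network, pan_net, exchange_of[s], cfg.growth_tolerance, Medium(), cfg.uptake
                    )
                except Exception:  # genuinely unfillable cell stays a false negative
                    continue
                if result.added:
                    model.network = apply_gapfill(model.network, pan_net, result.added)
                    model.gapfilled_reactions.extend(result.added)
                    save_json(model.network, cfg.outdir / "models" / f"{model.strain}.json")
                    refined += 1
    after = predict(models)
    score_after = sm.score_predictions(after, observed)
    validation = {
        "before": score_before.as_dict(),
        "after": score_after.as_dict(),
        "cells_refined": refined,
    }
    _write_json(cfg.outdir / "validation.json", validation)
    logger.info(
        "validate: accuracy %.3f -> %.3f (%d cells gap-filled)",
        score_before.accuracy,
        score_after.accuracy,
        refined,
    )
    return validation


def compute_model_deltas(model_counts: dict[str, int], reference_counts: dict[str, int]) -> dict[str, dict[str, int]]:
    """Absolute and rounded-percent increases per category vs a reference model."""
    out = {}
    for key in ("genes", "reactions", "metabolites"):
        new, ref = int(model_counts[key]), int(reference_counts[key])
        if ref <= 0:
            raise ValueError(f"reference count for {key} must be positive")
        delta = new - ref
        out[key] = {"new": new, "reference": ref, "delta": delta, "percent": round(100.0 * delta / ref)}
    return out


def stage_report(cfg: PipelineConfig, models: list[sm.StrainModel] | None = None) -> dict:
    pan_net, _ = _load_pan_inputs(cfg)
    if models is None:
        models = _load_models(cfg)
    classification = sm.classify_reactions(models, cfg.core_frequency, cfg.rare_frequency)
    mca = sm.mca_strains(models, cfg.n_mca_axes)
    mca.coordinates.to_csv(cfg.outdir / "mca_coordinates.csv", float_format="%.17g")
    classification.frequency.rename("frequency").to_frame().assign(cls=classification.classes).to_csv(
        cfg.outdir / "reaction_classes.csv", float_format="%.17g"
    )
    curve = pd.read_csv(cfg.outdir / "core_curve.csv")
    activity = pd.read_csv(cfg.outdir / "activity_index.csv", index_col=0)
    validation = json.loads((cfg.outdir / "validation.json").read_text())
    report = {
        "config": cfg.echo(),
        "pan_model_counts": pan_net.counts(),
        "core_curve": {
            "first": int(curve["core_size"].iloc[0]),
            "final": int(curve["core_size"].iloc[-1]),
            "n_strains": int(len(curve)),
        },
        "activity_index": {k: float(v) for k, v in activity.iloc[:, 0].items()},
        "validation": validation,
        "reaction_classes": classification.counts(),
        "mca_inertia": [float(x) for x in mca.inertia],
    }
    if cfg.reference_counts is not None:
        report["model_deltas"] = compute_model_deltas(pan_net.counts(), cfg.reference_counts)
    _write_json(cfg.outdir / "report.json", report)
    return report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order and return the final report."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    _write_json(cfg.outdir / "run_config.json", cfg.echo())
    if cfg.world is not None:
        stage_simulate(cfg)
    stage_call(cfg)
    families, _, _, _ = stage_pangenome(cfg)
    stage_alleleome(cfg, families)
    models = stage_derive(cfg)
    models = stage_gapfill(cfg, models)
    stage_validate(cfg, models)
    return stage_report(cfg, models)
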