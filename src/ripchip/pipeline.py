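"""End-to-end orchestration: simulate (or read) -> normalize -> filter ->
targetome -> specific targets -> seed scan -> gene-set enrichment -> report.

A single global seed is fanned out to per-stage child seeds through
:func:`stage_seed` (a ``numpy.random.SeedSequence`` keyed on the stage
name), so any stage can be re-run in isolation and still reproduce the full
pipeline's randomness.
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

from . import arrays, gsea, seeds, targetome
from .errors import ConfigError, UsageError
from .simulate import RipChipSimConfig, generate_ripchip, generate_utrs

logger = logging.getLogger("ripchip")

MIR155_5P = "UUAAUGCUAAUCGUGAUAGGGGU"

_STAGES = ("simulate", "utrs", "gsea")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic child seed for a named stage (< 2**31)."""
    if stage not in _STAGES:
        raise UsageError(f"unknown stage {stage!r}; stages are {_STAGES}")
    ss = np.random.SeedSequence([int(global_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, serializable to/from YAML."""

    simulation: RipChipSimConfig = field(default_factory=RipChipSimConfig)
    normalize: bool = True
    detection_quantile: float = 0.10
    max_dye_fold: float = 2.0
    min_detected_fraction: float = 0.5
    min_ratio: float = 2.0
    min_ratio_fold: float = 2.0
    test_construct: str = "overexpression"
    ref_construct: str = "control"
    mirna_name: str = "hsa-miR-155-5p"
    mirna_sequence: str = MIR155_5P
    site_types: tuple[str, ...] = ("6mer", "8mer")
    gsea_n_perm: int = 1000
    gsea_n_decoy_sets: int = 49
    gsea_top_k: int = 20
    gsea_weight_p: float = 1.0
    rng_seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        self.simulation.validate()
        if not 0 < self.detection_quantile < 1:
            raise ConfigError(f"detection_quantile must be in (0,1), got {self.detection_quantile}")
        for name in ("max_dye_fold", "min_ratio", "min_ratio_fold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0 <= self.min_detected_fraction <= 1:
            raise ConfigError(
                f"min_detected_fraction must be in [0,1], got {self.min_detected_fraction}"
            )
        if self.test_construct == self.ref_construct:
            raise ConfigError("test_construct and ref_construct must differ")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["constructs"] = list(self.simulation.constructs)
        if self.simulation.target_fold_range is not None:
            d["simulation"]["target_fold_range"] = list(self.simulation.target_fold_range)
        d["site_types"] = list(self.site_types)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            if "constructs" in sim:
                sim["constructs"] = tuple(sim["constructs"])
            if sim.get("target_fold_range") is not None:
                sim["target_fold_range"] = tuple(sim["target_fold_range"])
            sim = RipChipSimConfig(**sim)
        if "site_types" in d:
            d["site_types"] = tuple(d["site_types"])
        return cls(simulation=sim, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunReport:
    """Machine-readable per-stage summary of one pipeline run."""

    payload: dict

    def to_json(self) -> str:
        return json.dumps(self.payload, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> RunReport:
    """Execute the full analysis on a simulated experiment.

    Writes per-stage outputs under ``output_dir`` when given (signals/,
    targetome/, seedscan/, gsea/, report.json, run.log) and returns the
    report.  Deterministic under ``config.rng_seed``.
    """
    config.validate()
    outdir = Path(output_dir or config.output_dir) if (output_dir or config.output_dir) else None
    handler = None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)

    try:
        return _run(config, outdir)
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()


def _run(config: PipelineConfig, outdir: Path | None) -> RunReport:
    report: dict = {"config": config.to_dict()}
    sim_cfg = dataclasses.replace(
        config.simulation, rng_seed=stage_seed(config.rng_seed, "simulate")
    )

    logger.info("stage=simulate n_genes=%d n_planted_targets=%d seed=%d",
                sim_cfg.n_genes, sim_cfg.n_planted_targets, sim_cfg.rng_seed)
    experiment = generate_ripchip(sim_cfg)
    matrix, design = experiment.signal_matrix, experiment.design

    logger.info("stage=detect detection_quantile=%g", config.detection_quantile)
    matrix = arrays.detect_calls(matrix, threshold_quantile=config.detection_quantile)
    if config.normalize:
        logger.info("stage=normalize method=quantile")
        matrix = arrays.quantile_normalize(matrix)
    logger.info("stage=filter max_dye_fold=%g min_detected_fraction=%g",
                config.max_dye_fold, config.min_detected_fraction)
    filtered, filter_report = arrays.filter_probes(
        matrix, design,
        max_dye_fold=config.max_dye_fold,
        min_detected_fraction=config.min_detected_fraction,
    )
    averaged = arrays.average_dye_replicates(filtered, design)
    report["filter"] = filter_report.summary()

    logger.info("stage=targetome min_ratio=%g min_ratio_fold=%g",
                config.min_ratio, config.min_ratio_fold)
    table = targetome.compute_ratios(averaged, min_ratio=config.min_ratio)
    cell_line = sim_cfg.cell_line
    specific_probes = targetome.call_specific_targets(
        table, cell_line, config.test_construct, config.ref_construct,
        min_ratio=config.min_ratio, min_ratio_fold=config.min_ratio_fold,
    )
    collapse, specific_genes = targetome.collapse_to_genes(
        table, experiment.probe_annotation, cell_line, config.test_construct,
        specific_probes=specific_probes,
    )
    member = table.member[(cell_line, config.test_construct)]
    report["targetome"] = {
        "n_probes_retained": int(len(table.probes)),
        "ip_enriched_probe_fraction": float(member.mean()),
        "n_specific_probes": int(len(specific_probes)),
        "n_specific_genes": int(len(specific_genes)),
        "n_unannotated_specific_probes": int(
            sum(1 for p in specific_probes
                if experiment.probe_annotation.get(p, "") in ("", None))
        ),
    }

    truth = set(experiment.truth_targets)
    if truth or not specific_genes:
        tp = len(specific_genes & truth)
        recall = tp / len(truth) if truth else float("nan")
        precision = tp / len(specific_genes) if specific_genes else float("nan")
        report["truth"] = {
            "n_planted_targets": len(truth),
            "recall": recall,
            "precision": precision,
        }

    logger.info("stage=seedscan mirna=%s site_types=%s", config.mirna_name, config.site_types)
    mirna = seeds.MatureMiRNA(config.mirna_name, config.mirna_sequence)
    catalog = seeds.derive_sites(mirna)
    utr_rng = np.random.default_rng(stage_seed(config.rng_seed, "utrs"))
    utrs = generate_utrs(experiment, catalog, sim_cfg, rng=utr_rng)
    hits = seeds.scan_sequences(utrs, catalog, site_types=tuple(config.site_types))
    seed_summary = {}
    if specific_genes:
        content = seeds.summarize_site_content(hits, sorted(specific_genes))
        seed_summary = {
            st: {"k": int(row["k"]), "n": int(row["n"]), "fraction": float(row["fraction"])}
            for st, row in content.iterrows()
        }
    report["seedscan"] = seed_summary

    logger.info("stage=gsea n_perm=%d n_decoy_sets=%d", config.gsea_n_perm, config.gsea_n_decoy_sets)
    ranked = gsea.rank_genes(collapse.gene_ratio)
    collection, motif_flags = _build_synthetic_collection(
        ranked, truth, config, rng_seed=stage_seed(config.rng_seed, "gsea")
    )
    result = gsea.permutation_test(
        ranked, collection, is_motif_set=motif_flags,
        n_perm=config.gsea_n_perm, weight_p=config.gsea_weight_p,
        rng_seed=stage_seed(config.rng_seed, "gsea"),
    )
    motif_name = _motif_set_name(config)
    fraction_motif, motif_rank = (float("nan"), None)
    if motif_name in collection:
        top_k = min(config.gsea_top_k, len(result.table))
        fraction_motif, motif_rank = gsea.motif_set_summary(result, top_k=top_k, named_set=motif_name)
    report["gsea"] = {
        "n_sets": len(collection),
        "motif_set_rank": motif_rank,
        "fraction_motif_in_top_k": fraction_motif,
    }

    run_report = RunReport(payload=report)
    if outdir is not None:
        _write_outputs(outdir, config, experiment, filtered, filter_report, table,
                       specific_probes, specific_genes, collapse, utrs, hits, result, run_report)
    return run_report


def _motif_set_name(config: PipelineConfig) -> str:
    return f"{config.mirna_name.upper()}_SITE_MOTIF"


def _build_synthetic_collection(
    ranked: gsea.RankedGeneList, truth: set, config: PipelineConfig, rng_seed: int
) -> tuple[dict[str, set], dict[str, bool]]:
    """Planted motif set (the true targets) plus random decoy sets."""
    rng = np.random.default_rng(rng_seed)
    universe = list(ranked.genes)
    collection: dict[str, set] = {}
    flags: dict[str, bool] = {}
    motif_members = truth & set(universe)
    if motif_members and len(motif_members) < len(universe):
        name = _motif_set_name(config)
        collection[name] = motif_members
        flags[name] = True
    size = max(len(motif_members), 10)
    for i in range(config.gsea_n_decoy_sets):
        name = f"RANDOM_SET_{i:03d}"
        members = set(rng.choice(universe, size=min(size, len(universe) - 1), replace=False))
        collection[name] = members
        flags[name] = False
    return collection, flags


def _write_outputs(outdir, config, experiment, filtered, filter_report, table,
                   specific_probes, specific_genes, collapse, utrs, hits, gsea_result, run_report):
    for sub in ("signals", "targetome", "seedscan", "gsea"):
        (outdir / sub).mkdir(exist_ok=True)
    arrays.write_signal_table(experiment.signal_matrix, outdir / "signals" / "raw_signals.tsv")
    arrays.write_design(experiment.design, outdir / "signals" / "design.tsv")
    experiment.probe_annotation.rename("gene_id").to_csv(
        outdir / "signals" / "probe_annotation.tsv", sep="\t", index_label="probe_id"
    )
    filter_report.removal_reason.rename("reason").to_csv(
        outdir / "signals" / "filter_report.tsv", sep="\t", index_label="probe_id"
    )
    flat = table.ratios.copy()
    flat.columns = [f"{cl}.{construct}" for cl, construct in flat.columns]
    flat.to_csv(outdir / "targetome" / "ip_t_ratios.tsv", sep="\t", index_label="probe_id")
    (outdir / "targetome" / "specific_probes.txt").write_text(
        "\n".join(sorted(specific_probes)) + "\n" if len(specific_probes) else ""
    )
    (outdir / "targetome" / "specific_genes.txt").write_text(
        "\n".join(sorted(specific_genes)) + "\n" if specific_genes else ""
    )
    (outdir / "targetome" / "truth_targets.txt").write_text(
        "\n".join(sorted(experiment.truth_targets)) + "\n" if experiment.truth_targets else ""
    )
    with open(outdir / "seedscan" / "utrs.fasta", "w") as fh:
        for gene, seq in sorted(utrs.items()):
            fh.write(f">{gene}\n{seq}\n")
    hits.counts.to_csv(outdir / "seedscan" / "site_counts.tsv", sep="\t")
    gsea_result.table.to_csv(outdir / "gsea" / "enrichment.tsv", sep="\t")
    config.to_yaml(outdir / "effective_config.yaml")
    (outdir / "report.json").write_text(run_report.to_json() + "\n")


# ---------------------------------------------------------------------------
# Fixture presets
# ---------------------------------------------------------------------------

PRESETS: dict[str, PipelineConfig] = {}


def _register_presets() -> None:
    PRESETS["paper-like"] = PipelineConfig(
        simulation=RipChipSimConfig(
            n_genes=8000, n_planted_targets=54, target_fold_range=(2.0, 12.6),
            noise_sd_log2=0.25,
        ),
    )
    PRESETS["zero-noise"] = PipelineConfig(
        simulation=RipChipSimConfig(
            n_genes=2000, n_planted_targets=20, ip_enrichment_fold_targets=4.0,
            noise_sd_log2=0.0, dye_effect_sd_log2=0.0, detection_dropout_rate=0.0,
        ),
    )
    PRESETS["null"] = PipelineConfig(
        simulation=RipChipSimConfig(n_genes=2000, n_planted_targets=0, noise_sd_log2=0.25),
    )
    PRESETS["sponge-weak"] = PipelineConfig(
        simulation=RipChipSimConfig(
            n_genes=8000, n_planted_targets=54, target_fold_range=(2.0, 12.6),
            noise_sd_log2=0.25,
            constructs=("control", "sponge"),
            # a weak sponge removes only 20% of the miRNA's target loading
            construct_attenuation={"control": 1.0, "sponge": 0.8},
        ),
        test_construct="control",
        ref_construct="sponge",
    )


_register_presets()


def get_preset(name: str, rng_seed: int = 0) -> PipelineConfig:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg = PipelineConfig.from_dict(PRESETS[name].to_dict())
    cfg.rng_seed = rng_seed
    return cfg


def make_fixture(preset: str, output_dir: str | Path, rng_seed: int = 0) -> Path:
    """Write a complete miniature input bundle for a named preset.

    Produces the signal table, design, probe annotation, UTR FASTA, truth
    gene lists, a gene-set GMT, and the effective config under
    ``output_dir``.
    """
    config = get_preset(preset, rng_seed=rng_seed)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim_cfg = dataclasses.replace(config.simulation, rng_seed=stage_seed(rng_seed, "simulate"))
    experiment = generate_ripchip(sim_cfg)
    mirna = seeds.MatureMiRNA(config.mirna_name, config.mirna_sequence)
    catalog = seeds.derive_sites(mirna)
    utrs = generate_utrs(
        experiment, catalog, sim_cfg, rng=np.random.default_rng(stage_seed(rng_seed, "utrs"))
    )

    arrays.write_signal_table(experiment.signal_matrix, outdir / "signals.tsv")
    arrays.write_design(experiment.design, outdir / "design.tsv")
    experiment.probe_annotation.rename("gene_id").to_csv(
        outdir / "probe_annotation.tsv", sep="\t", index_label="probe_id"
    )
    with open(outdir / "utrs.fasta", "w") as fh:
        for gene, seq in sorted(utrs.items()):
            fh.write(f">{gene}\n{seq}\n")
    (outdir / "truth_targets.txt").write_text(
        "\n".join(sorted(experiment.truth_targets)) + "\n" if experiment.truth_targets else ""
    )
    (outdir / "truth_site_genes.txt").write_text(
        "\n".join(sorted(experiment.truth_site_genes)) + "\n" if experiment.truth_site_genes else ""
    )
    motif_name = _motif_set_name(config)
    collection = {motif_name: set(experiment.truth_targets)} if experiment.truth_targets else {}
    rng = np.random.default_rng(stage_seed(rng_seed, "gsea"))
    genes = sorted(set(experiment.probe_annotation))
    for i in range(10):
        collection[f"RANDOM_SET_{i:03d}"] = set(
            rng.choice(genes, size=max(len(experiment.truth_targets), 10), replace=False)
        )
    gsea.write_gmt(collection, outdir / "gene_sets.gmt")
    config.to_yaml(outdir / "config.yaml")
    return outdir
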