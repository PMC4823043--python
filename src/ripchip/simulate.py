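"""Synthetic RIP-Chip experiments and GFP-competition assays with recorded
ground truth.

The generator emulates the paired design of an Ago2-RIP-Chip study: for each
construct (e.g. empty-vector control vs miRNA overexpression) it produces a
total-RNA (T) and an immunoprecipitated (IP) fraction, each hybridized with
Cy3 and Cy5 dye replicates.  A planted subset of genes receives an elevated
IP signal in the construct(s) where the miRNA is active, so that downstream
targetome calls can be scored against truth.

Signals are simulated on the linear fluorescence scale as
``2 ** (log2 baseline + effects + noise)`` with per-probe baseline
log2-intensities drawn from Normal(10, 1.5), reproducing the lognormal
behavior of array data without modeling scanner physics.  Detection dropout
sets a boolean flag rather than zeroing the signal, mirroring
feature-extraction "detected" flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrays import DYES, FRACTIONS, ExperimentDesign, SignalMatrix
from .errors import ConfigError

BASELINE_LOG2_MEAN = 10.0
BASELINE_LOG2_SD = 1.5


@dataclass(frozen=True)
class RipChipSimConfig:
    """Parameters of a synthetic RIP-Chip experiment.

    ``ip_enrichment_fold_targets`` is the linear IP/T multiplier applied to
    planted targets in the miRNA-active construct; if ``target_fold_range``
    is set, per-target folds are instead drawn uniformly from that interval.
    ``construct_attenuation`` maps each construct to the fraction of the
    target enrichment it expresses (1.0 = full enrichment, 0.0 = none);
    a weak miRNA sponge, for example, is a construct with attenuation just
    below that of its control.
    """

    n_genes: int = 8000
    probes_per_gene: int = 1
    n_planted_targets: int = 54
    ip_enrichment_fold_targets: float = 4.0
    target_fold_range: tuple[float, float] | None = None
    ip_enrichment_fold_background: float = 1.0
    noise_sd_log2: float = 0.25
    dye_effect_sd_log2: float = 0.05
    detection_dropout_rate: float = 0.02
    utr_length: int = 1000
    site_plant_rate_targets: float = 1.0
    site_plant_rate_background: float = 0.05
    rng_seed: int = 0
    cell_line: str = "SIM"
    constructs: tuple[str, ...] = ("control", "overexpression")
    construct_attenuation: dict[str, float] = field(
        default_factory=lambda: {"control": 0.0, "overexpression": 1.0}
    )

    def validate(self) -> None:
        def _positive(name: str) -> None:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")

        def _nonneg(name: str) -> None:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative, got {getattr(self, name)}")

        def _prob(name: str) -> None:
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be a probability in [0,1], got {getattr(self, name)}")

        for name in ("n_genes", "probes_per_gene", "utr_length"):
            _positive(name)
        if self.n_planted_targets < 0:
            raise ConfigError(f"n_planted_targets must be non-negative, got {self.n_planted_targets}")
        if self.n_planted_targets > self.n_genes:
            raise ConfigError(
                f"n_planted_targets ({self.n_planted_targets}) exceeds n_genes ({self.n_genes})"
            )
        for name in ("ip_enrichment_fold_targets", "ip_enrichment_fold_background"):
            _positive(name)
        if self.target_fold_range is not None:
            lo, hi = self.target_fold_range
            if not (0 < lo <= hi):
                raise ConfigError(f"target_fold_range must satisfy 0 < lo <= hi, got {self.target_fold_range}")
        for name in ("noise_sd_log2", "dye_effect_sd_log2"):
            _nonneg(name)
        for name in ("detection_dropout_rate", "site_plant_rate_targets", "site_plant_rate_background"):
            _prob(name)
        if len(self.constructs) < 1:
            raise ConfigError("constructs must name at least one construct")
        for c in self.constructs:
            if c not in self.construct_attenuation:
                raise ConfigError(f"construct_attenuation missing entry for construct {c!r}")


@dataclass
class SyntheticExperiment:
    """A complete simulated experiment with its ground truth."""

    signal_matrix: SignalMatrix
    design: ExperimentDesign
    probe_annotation: pd.Series  # probe id -> gene id ("" for unannotated probes)
    utr_sequences: dict[str, str]
    truth_targets: frozenset[str]
    truth_site_genes: frozenset[str]
    target_folds: pd.Series  # gene id -> planted IP/T fold (targets only)
    config: RipChipSimConfig


def generate_ripchip(config: RipChipSimConfig) -> SyntheticExperiment:
    """Simulate a full RIP-Chip experiment.

    Planted targets receive the IP enrichment multiplier scaled by each
    construct's attenuation; all other effects (noise, dye offsets, dropout)
    are drawn independently per probe and channel.  Fully reproducible from
    ``config.rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    probes, probe_gene = [], []
    for g in genes:
        for k in range(config.probes_per_gene):
            probes.append(f"{g}_P{k}")
            probe_gene.append(g)
    annotation = pd.Series(probe_gene, index=pd.Index(probes, name="probe_id"), name="gene_id")

    target_idx = rng.choice(config.n_genes, size=config.n_planted_targets, replace=False)
    targets = [genes[i] for i in sorted(target_idx)]
    if config.target_fold_range is not None:
        lo, hi = config.target_fold_range
        folds = rng.uniform(lo, hi, size=len(targets))
    else:
        folds = np.full(len(targets), config.ip_enrichment_fold_targets)
    target_folds = pd.Series(folds, index=pd.Index(targets, name="gene_id"), name="ip_fold")

    # per-gene log2 IP enrichment at full strength
    log2_enrich = pd.Series(np.log2(config.ip_enrichment_fold_background), index=genes)
    log2_background = log2_enrich.copy()
    log2_enrich[targets] = np.log2(folds)

    baseline = rng.normal(BASELINE_LOG2_MEAN, BASELINE_LOG2_SD, size=len(probes))

    columns, design_rows = [], []
    signal = {}
    detected = {}
    for construct in config.constructs:
        atten = config.construct_attenuation[construct]
        gene_effect = log2_background + atten * (log2_enrich - log2_background)
        probe_effect = gene_effect.loc[probe_gene].to_numpy()
        for fraction in FRACTIONS:
            for dye in DYES:
                ch = f"{config.cell_line}.{construct}.{fraction}.{dye}"
                columns.append(ch)
                design_rows.append(
                    {
                        "sample_channel_id": ch,
                        "cell_line": config.cell_line,
                        "construct": construct,
                        "fraction": fraction,
                        "dye": dye,
                        "replicate": "r1",
                    }
                )
                log2 = baseline.copy()
                if fraction == "IP":
                    log2 = log2 + probe_effect
                if config.dye_effect_sd_log2 > 0:
                    log2 = log2 + rng.normal(0, config.dye_effect_sd_log2, size=len(probes))
                if config.noise_sd_log2 > 0:
                    log2 = log2 + rng.normal(0, config.noise_sd_log2, size=len(probes))
                signal[ch] = np.exp2(log2)
                detected[ch] = rng.random(len(probes)) >= config.detection_dropout_rate

    signal_df = pd.DataFrame(signal, index=annotation.index)
    detected_df = pd.DataFrame(detected, index=annotation.index)
    matrix = SignalMatrix(signal=signal_df, detected=detected_df, state="raw")
    design = ExperimentDesign(pd.DataFrame(design_rows))

    experiment = SyntheticExperiment(
        signal_matrix=matrix,
        design=design,
        probe_annotation=annotation,
        utr_sequences={},
        truth_targets=frozenset(targets),
        truth_site_genes=frozenset(),
        target_folds=target_folds,
        config=config,
    )
    return experiment


def generate_utrs(
    experiment: SyntheticExperiment,
    site_catalog,
    config: RipChipSimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Attach random UTR sequences, planting one 8mer seed site per selected gene.

    Planted targets are selected at ``site_plant_rate_targets``, background
    genes at ``site_plant_rate_background``.  Insertion guarantees exactly
    one 8mer occurrence per planted sequence (the sequence is re-drawn on
    accidental extra matches).  Updates ``experiment.utr_sequences`` and
    ``experiment.truth_site_genes`` and returns the sequence mapping.
    """
    config = config or experiment.config
    site = site_catalog.sites["8mer"]
    if config.utr_length < len(site):
        raise ConfigError(
            f"utr_length ({config.utr_length}) is shorter than the 8mer site ({len(site)} nt)"
        )
    rng = rng or np.random.default_rng(config.rng_seed + 1)
    alphabet = np.array(list("ACGT"))

    genes = sorted(set(experiment.probe_annotation) - {""})
    utrs: dict[str, str] = {}
    site_genes: list[str] = []
    for g in genes:
        is_target = g in experiment.truth_targets
        rate = config.site_plant_rate_targets if is_target else config.site_plant_rate_background
        plant = rng.random() < rate
        while True:
            seq = "".join(rng.choice(alphabet, size=config.utr_length))
            if plant:
                pos = int(rng.integers(0, config.utr_length - len(site) + 1))
                seq = seq[:pos] + site + seq[pos + len(site):]
                if seq.count(site) != 1:
                    continue  # accidental extra occurrence: re-draw
            else:
                if site in seq:
                    continue  # background sequence must not carry the site by chance
            break
        utrs[g] = seq
        if plant:
            site_genes.append(g)

    experiment.utr_sequences = utrs
    experiment.truth_site_genes = frozenset(site_genes)
    return utrs


# ---------------------------------------------------------------------------
# GFP competition assay
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthSimConfig:
    """Parameters of a synthetic GFP-competition assay.

    ``growth_advantage_per_day`` is the difference in the daily slope of the
    relative GFP+ percentage between the test and control constructs; the
    control's expected relative value stays at 1.  Days follow a roughly
    twice-weekly three-week monitoring schedule by default.
    """

    n_replicates: int = 3
    days: tuple[int, ...] = (4, 8, 11, 15, 18, 22)
    baseline_gfp_pct: float = 30.0
    growth_advantage_per_day: float = 0.0
    replicate_sd: float = 0.05
    residual_sd: float = 0.05
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ConfigError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if len(self.days) < 2 or any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ConfigError(f"days must be a strictly increasing list of >= 2 days, got {self.days}")
        if not 0 < self.baseline_gfp_pct < 100:
            raise ConfigError(f"baseline_gfp_pct must be in (0,100), got {self.baseline_gfp_pct}")
        for name in ("replicate_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative, got {getattr(self, name)}")


def generate_growth(config: GrowthSimConfig) -> pd.DataFrame:
    """Simulate a two-arm GFP competition assay.

    Returns a long table with columns ``construct, replicate, day, gfp_pct``.
    The first measured day is the baseline: its relative value is 1 by
    construction.  Post-baseline relative values are
    ``1 + advantage*(day - day0) [test arm] + replicate shift + residual``,
    converted to percentages and clipped to (0, 100).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    day0 = config.days[0]
    rows = []
    for construct, advantage in (("control", 0.0), ("test", config.growth_advantage_per_day)):
        for r in range(config.n_replicates):
            rep = f"{construct}_rep{r + 1}"
            rep_shift = rng.normal(0, config.replicate_sd) if config.replicate_sd > 0 else 0.0
            for day in config.days:
                if day == day0:
                    rel = 1.0
                else:
                    eps = rng.normal(0, config.residual_sd) if config.residual_sd > 0 else 0.0
                    rel = 1.0 + advantage * (day - day0) + rep_shift + eps
                gfp = float(np.clip(config.baseline_gfp_pct * rel, 1e-6, 99.9999))
                rows.append({"construct": construct, "replicate": rep, "day": day, "gfp_pct": gfp})
    return pd.DataFrame(rows)
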