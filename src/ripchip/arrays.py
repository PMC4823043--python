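"""Two-color array preprocessing: signal tables, quantile normalization,
detection and dye-consistency filtering, and dye-replicate averaging.

The expected experimental layout mirrors an Ago2-RIP-Chip design: for every
(cell_line, construct, fraction) sample there is one Cy3 and one Cy5 channel
(technical dye replicates of the same hybridized RNA).  Fractions are ``T``
(total RNA) and ``IP`` (Ago2-immunoprecipitated RNA); the downstream IP/T
ratio is formed on the dye-averaged signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError, FormatError

DESIGN_COLUMNS = ["sample_channel_id", "cell_line", "construct", "fraction", "dye", "replicate"]
FRACTIONS = ("T", "IP")
DYES = ("Cy3", "Cy5")

#: floor (linear fluorescence units) applied before forming dye ratios so a
#: zero signal cannot produce an infinite inconsistency ratio
DYE_RATIO_FLOOR = 1.0


@dataclass
class ExperimentDesign:
    """Per-channel sample metadata.

    ``table`` has one row per sample channel with columns
    ``sample_channel_id, cell_line, construct, fraction, dye, replicate``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"design table missing columns: {missing}")
        ids = self.table["sample_channel_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise DesignError(f"duplicate sample_channel_ids: {dups}")

    @property
    def channel_ids(self) -> list[str]:
        return list(self.table["sample_channel_id"])

    def groups(self) -> pd.core.groupby.DataFrameGroupBy:
        """Group channels by (cell_line, construct, fraction)."""
        return self.table.groupby(["cell_line", "construct", "fraction"], sort=True)

    def dye_pairs(self, require_pairing: bool = True) -> list[tuple[tuple[str, str, str], str, str]]:
        """Return [(group_key, cy3_channel, cy5_channel), ...].

        Groups with a single channel are returned as ``(key, ch, ch)`` only
        when ``require_pairing`` is False; otherwise they raise
        :class:`DesignError`.
        """
        pairs = []
        for key, sub in self.groups():
            by_dye = {d: list(sub.loc[sub["dye"] == d, "sample_channel_id"]) for d in DYES}
            if len(sub) == 1 and not require_pairing:
                ch = sub["sample_channel_id"].iloc[0]
                pairs.append((key, ch, ch))
                continue
            if len(by_dye["Cy3"]) != 1 or len(by_dye["Cy5"]) != 1:
                raise DesignError(
                    f"group {key} does not have exactly one Cy3 and one Cy5 channel "
                    f"(found {dict((d, len(v)) for d, v in by_dye.items())})"
                )
            pairs.append((key, by_dye["Cy3"][0], by_dye["Cy5"][0]))
        return pairs


@dataclass
class SignalMatrix:
    """Probe x sample-channel fluorescence with optional detection flags.

    ``signal`` is linear-scale, non-negative; ``detected`` (same shape,
    boolean) is ``None`` until flags are read from file or derived by
    :func:`detect_calls`.  ``state`` is ``"raw"`` or ``"normalized"``.
    """

    signal: pd.DataFrame
    detected: pd.DataFrame | None = None
    state: str = "raw"

    def __post_init__(self) -> None:
        if (self.signal.to_numpy() < 0).any():
            raise FormatError("signal matrix contains negative values")
        if self.detected is not None:
            if not self.detected.index.equals(self.signal.index) or not self.detected.columns.equals(
                self.signal.columns
            ):
                raise FormatError("detection flags do not align with the signal matrix")

    @property
    def probes(self) -> pd.Index:
        return self.signal.index

    @property
    def channels(self) -> pd.Index:
        return self.signal.columns


@dataclass
class FilterReport:
    """Accounting of the probe-QC filter.

    Reasons are assigned in fixed order: a probe failing both rules is
    counted under ``detection``.
    """

    n_probes_input: int
    n_removed_detection: int
    n_removed_consistency: int
    n_probes_retained: int
    removal_reason: pd.Series = field(repr=False)  # probe -> "detection"|"consistency"|"retained"

    def summary(self) -> dict:
        return {
            "n_probes_input": self.n_probes_input,
            "n_removed_detection": self.n_removed_detection,
            "n_removed_consistency": self.n_removed_consistency,
            "n_probes_retained": self.n_probes_retained,
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FLAG_SUFFIX = ".detected"


def write_signal_table(matrix: SignalMatrix, path: str | Path) -> None:
    """Write a tab-separated signal table (probe-id first column).

    Detection flags, when present, are written as 0/1 columns named
    ``<channel>.detected`` after the signal columns.
    """
    out = matrix.signal.copy()
    if matrix.detected is not None:
        for ch in matrix.signal.columns:
            out[ch + _FLAG_SUFFIX] = matrix.detected[ch].astype(int)
    out.to_csv(path, sep="\t", index_label="probe_id")


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> ExperimentDesign:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return ExperimentDesign(table)


def read_signal_table(path: str | Path, design_path: str | Path) -> tuple[SignalMatrix, ExperimentDesign]:
    """Read a signal table and its companion design file.

    The table must contain exactly the channels declared in the design plus,
    optionally, one ``<channel>.detected`` flag column per channel.  A missing
    flag block leaves ``detected`` as ``None`` (provisional; resolved later by
    :func:`detect_calls`).
    """
    design = read_design(design_path)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    channels = design.channel_ids
    flag_cols = {c for c in raw.columns if c.endswith(_FLAG_SUFFIX)}
    signal_cols = [c for c in raw.columns if c not in flag_cols]

    unknown = sorted(set(signal_cols) - set(channels))
    missing = sorted(set(channels) - set(signal_cols))
    if unknown or missing:
        raise FormatError(
            f"signal table / design mismatch: unknown columns {unknown}, missing channels {missing}"
        )
    unknown_flags = sorted(c for c in flag_cols if c[: -len(_FLAG_SUFFIX)] not in set(channels))
    if unknown_flags:
        raise FormatError(f"flag columns for undeclared channels: {unknown_flags}")

    signal = raw[channels]
    bad = signal.columns[~signal.apply(lambda s: pd.to_numeric(s, errors="coerce").notna().all())]
    if len(bad):
        for col in bad:
            coerced = pd.to_numeric(signal[col], errors="coerce")
            row = signal.index[coerced.isna()][0]
            raise FormatError(f"non-numeric signal at probe {row!r}, column {col!r}")
    signal = signal.astype(float)

    detected = None
    if flag_cols:
        expected_flags = {ch + _FLAG_SUFFIX for ch in channels}
        if flag_cols != expected_flags:
            raise FormatError(
                f"incomplete detection-flag block: missing {sorted(expected_flags - flag_cols)}"
            )
        detected = raw[[ch + _FLAG_SUFFIX for ch in channels]].astype(int).astype(bool)
        detected.columns = channels
    return SignalMatrix(signal=signal, detected=detected, state="raw"), design


# ---------------------------------------------------------------------------
# Normalization and QC
# ---------------------------------------------------------------------------


def quantile_normalize(matrix: SignalMatrix) -> SignalMatrix:
    """Quantile-normalize all channels jointly.

    Every output column's sorted values equal the cross-column mean of order
    statistics; ties within a column receive the mean of the normalized
    values of the tied ranks.  Detection flags pass through unchanged.
    """
    values = matrix.signal.to_numpy(dtype=float)
    n, k = values.shape
    if k < 2:
        raise ConfigError("quantile normalization requires at least 2 channels")
    reference = np.sort(values, axis=0).mean(axis=1)

    out = np.empty_like(values)
    for j in range(k):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n)
        mapped[order] = reference
        # average normalized values over tied input values
        ties = pd.Series(mapped).groupby(pd.Series(col), sort=False).transform("mean")
        out[:, j] = ties.to_numpy()

    signal = pd.DataFrame(out, index=matrix.signal.index, columns=matrix.signal.columns)
    return SignalMatrix(signal=signal, detected=matrix.detected, state="normalized")


def detect_calls(matrix: SignalMatrix, threshold_quantile: float = 0.10) -> SignalMatrix:
    """Resolve detection flags.

    Where flags are absent, a probe is called detected in a channel iff its
    signal strictly exceeds that channel's ``threshold_quantile`` quantile
    (so a constant channel detects nothing).  Flags already present are never
    overwritten.
    """
    if not 0 < threshold_quantile < 1:
        raise ConfigError(f"threshold_quantile must be in (0,1), got {threshold_quantile}")
    if matrix.detected is not None:
        return matrix
    thresholds = matrix.signal.quantile(threshold_quantile, axis=0)
    detected = matrix.signal.gt(thresholds, axis=1)
    return replace(matrix, detected=detected)


def filter_probes(
    matrix: SignalMatrix,
    design: ExperimentDesign,
    max_dye_fold: float = 2.0,
    min_detected_fraction: float = 0.5,
    allow_single_channel: bool = False,
) -> tuple[SignalMatrix, FilterReport]:
    """Apply the two probe-QC rules.

    A probe is removed when (a) it is detected in fewer than
    ``min_detected_fraction`` of the sample channels (detected fraction
    exactly at the boundary is retained — the literal reading of "not
    detected in more than half"), or (b) its Cy3 and Cy5 signals differ by
    more than ``max_dye_fold`` in any (cell_line, construct, fraction) dye
    pair.  Signals are floored at ``DYE_RATIO_FLOOR`` before the ratio.
    """
    if matrix.detected is None:
        raise DesignError("detection flags unresolved; run detect_calls first")
    pairs = design.dye_pairs(require_pairing=not allow_single_channel)

    detected_fraction = matrix.detected.mean(axis=1)
    fail_detection = detected_fraction < min_detected_fraction

    floored = matrix.signal.clip(lower=DYE_RATIO_FLOOR)
    fail_consistency = pd.Series(False, index=matrix.probes)
    for _key, cy3, cy5 in pairs:
        if cy3 == cy5:  # declared single-channel group: nothing to compare
            continue
        a, b = floored[cy3], floored[cy5]
        ratio = np.maximum(a, b) / np.minimum(a, b)
        fail_consistency |= ratio > max_dye_fold

    reason = pd.Series("retained", index=matrix.probes)
    reason[fail_consistency] = "consistency"
    reason[fail_detection] = "detection"  # detection takes precedence

    keep = reason == "retained"
    report = FilterReport(
        n_probes_input=len(matrix.probes),
        n_removed_detection=int((reason == "detection").sum()),
        n_removed_consistency=int((reason == "consistency").sum()),
        n_probes_retained=int(keep.sum()),
        removal_reason=reason,
    )
    filtered = SignalMatrix(
        signal=matrix.signal.loc[keep],
        detected=matrix.detected.loc[keep],
        state=matrix.state,
    )
    return filtered, report


def average_dye_replicates(matrix: SignalMatrix, design: ExperimentDesign) -> pd.DataFrame:
    """Average the two dye channels of every sample on the linear scale.

    Returns a probe x sample frame whose columns are a MultiIndex
    (cell_line, construct, fraction); single-channel groups pass through.
    """
    pairs = design.dye_pairs(require_pairing=False)
    data = {}
    for key, cy3, cy5 in pairs:
        if cy3 == cy5:
            data[key] = matrix.signal[cy3]
        else:
            data[key] = (matrix.signal[cy3] + matrix.signal[cy5]) / 2.0
    out = pd.DataFrame(data)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["cell_line", "construct", "fraction"])
    return out
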