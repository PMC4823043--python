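"""Tests of signal-table I/O, quantile normalization, and probe QC."""

import numpy as np
import pandas as pd
import pytest

from conftest import paired_design, small_matrix
from ripchip import arrays
from ripchip.errors import ConfigError, DesignError, FormatError
from ripchip.simulate import RipChipSimConfig, generate_ripchip


class TestSignalTableIO:
    def test_round_trip_is_bit_identical(self, tmp_path, rng):
        design = paired_design()
        channels = design.channel_ids
        signal = pd.DataFrame(
            rng.lognormal(7, 1, size=(100, len(channels))),
            index=pd.Index([f"P{i:03d}" for i in range(100)], name="probe_id"),
            columns=channels,
        )
        detected = pd.DataFrame(
            rng.random(size=signal.shape) > 0.1, index=signal.index, columns=channels
        )
        matrix = arrays.SignalMatrix(signal=signal, detected=detected)
        arrays.write_signal_table(matrix, tmp_path / "sig.tsv")
        arrays.write_design(design, tmp_path / "design.tsv")
        back, design_back = arrays.read_signal_table(tmp_path / "sig.tsv", tmp_path / "design.tsv")
        pd.testing.assert_frame_equal(back.signal, signal)
        pd.testing.assert_frame_equal(back.detected, detected)
        pd.testing.assert_frame_equal(design_back.table, design.table)

    def test_unknown_column_is_named_in_error(self, tmp_path):
        design = paired_design()
        signal = pd.DataFrame(
            np.ones((5, len(design.channel_ids))),
            index=[f"P{i}" for i in range(5)],
            columns=design.channel_ids,
        )
        signal["mystery_channel"] = 1.0
        signal.to_csv(tmp_path / "sig.tsv", sep="\t", index_label="probe_id")
        arrays.write_design(design, tmp_path / "design.tsv")
        with pytest.raises(FormatError, match="mystery_channel"):
            arrays.read_signal_table(tmp_path / "sig.tsv", tmp_path / "design.tsv")

    def test_non_numeric_signal_reports_position(self, tmp_path):
        design = paired_design()
        signal = pd.DataFrame(
            np.ones((3, len(design.channel_ids))),
            index=["P0", "P1", "P2"],
            columns=design.channel_ids,
            dtype=object,
        )
        signal.iloc[1, 2] = "oops"
        signal.to_csv(tmp_path / "sig.tsv", sep="\t", index_label="probe_id")
        arrays.write_design(design, tmp_path / "design.tsv")
        with pytest.raises(FormatError, match="P1"):
            arrays.read_signal_table(tmp_path / "sig.tsv", tmp_path / "design.tsv")

    def test_missing_flag_block_leaves_flags_provisional(self, tmp_path):
        design = paired_design()
        signal = pd.DataFrame(
            np.ones((4, len(design.channel_ids))),
            index=[f"P{i}" for i in range(4)],
            columns=design.channel_ids,
        )
        signal.to_csv(tmp_path / "sig.tsv", sep="\t", index_label="probe_id")
        arrays.write_design(design, tmp_path / "design.tsv")
        matrix, _ = arrays.read_signal_table(tmp_path / "sig.tsv", tmp_path / "design.tsv")
        assert matrix.detected is None


class TestQuantileNormalize:
    def test_worked_example(self):
        matrix = small_matrix({"a": [1, 2, 3], "b": [6, 4, 5]})
        out = arrays.quantile_normalize(matrix)
        assert np.allclose(out.signal["a"], [2.5, 3.5, 4.5])
        assert np.allclose(out.signal["b"], [4.5, 2.5, 3.5])
        assert out.state == "normalized"

    def test_identical_columns_are_a_fixed_point(self):
        matrix = small_matrix({"a": [3, 1, 2], "b": [3, 1, 2]})
        out = arrays.quantile_normalize(matrix)
        pd.testing.assert_frame_equal(out.signal, matrix.signal)

    def test_sorted_columns_identical_and_idempotent(self, rng):
        signal = pd.DataFrame(
            rng.lognormal(6, 2, size=(50, 4)), columns=list("abcd"),
            index=[f"P{i}" for i in range(50)],
        )
        once = arrays.quantile_normalize(arrays.SignalMatrix(signal=signal))
        sorted_cols = np.sort(once.signal.to_numpy(), axis=0)
        for j in range(1, 4):
            assert np.allclose(sorted_cols[:, 0], sorted_cols[:, j])
        twice = arrays.quantile_normalize(arrays.SignalMatrix(signal=once.signal))
        assert np.allclose(once.signal, twice.signal, atol=1e-12)

    def test_rank_preservation_within_columns(self, rng):
        signal = pd.DataFrame(
            rng.random(size=(40, 3)), columns=list("xyz"), index=[f"P{i}" for i in range(40)]
        )
        out = arrays.quantile_normalize(arrays.SignalMatrix(signal=signal))
        for c in signal:
            assert (signal[c].rank() == out.signal[c].rank()).all()

    def test_ties_get_mean_of_tied_ranks(self):
        # in column b the two tied values share the mean of the two
        # normalized values their ranks would receive
        matrix = small_matrix({"a": [1, 2, 3, 4], "b": [5, 5, 7, 8]})
        out = arrays.quantile_normalize(matrix)
        assert out.signal["b"].iloc[0] == out.signal["b"].iloc[1]
        ref = np.sort(out.signal.to_numpy(), axis=0)[:, 0]
        assert np.isclose(out.signal["b"].iloc[0], (ref[0] + ref[1]) / 2)

    def test_single_column_is_an_error(self):
        with pytest.raises(ConfigError):
            arrays.quantile_normalize(small_matrix({"a": [1, 2, 3]}))


class TestDetectCalls:
    def test_existing_flags_untouched(self):
        matrix = small_matrix({"a": [1, 2, 3]}, flags={"a": [False, False, False]})
        out = arrays.detect_calls(matrix)
        assert not out.detected.any().any()

    def test_constant_column_detects_nothing(self):
        matrix = small_matrix({"a": [5.0] * 10, "b": list(range(10))})
        out = arrays.detect_calls(matrix, threshold_quantile=0.10)
        assert not out.detected["a"].any()

    def test_rank_count_matches_quantile(self, rng):
        values = rng.permutation(1000).astype(float)
        matrix = arrays.SignalMatrix(
            signal=pd.DataFrame({"a": values}, index=[f"P{i}" for i in range(1000)])
        )
        out = arrays.detect_calls(matrix, threshold_quantile=0.10)
        # distinct values: everything strictly above the 10% quantile
        expected = (values > np.quantile(values, 0.10)).sum()
        assert out.detected["a"].sum() == expected
        assert abs(expected - 0.9 * 1000) <= 1

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_threshold_domain(self, bad):
        with pytest.raises(ConfigError):
            arrays.detect_calls(small_matrix({"a": [1, 2]}), threshold_quantile=bad)


class TestFilterProbes:
    def _matrix_and_design(self, rng, n=500):
        design = paired_design()
        channels = design.channel_ids
        signal = pd.DataFrame(
            rng.lognormal(7, 1, size=(n, len(channels))),
            index=[f"P{i:04d}" for i in range(n)],
            columns=channels,
        )
        detected = pd.DataFrame(
            rng.random(size=signal.shape) > 0.4, index=signal.index, columns=channels
        )
        return arrays.SignalMatrix(signal=signal, detected=detected), design

    def test_boundary_half_detected_is_retained(self):
        design = paired_design()
        channels = design.channel_ids
        signal = pd.DataFrame({ch: [100.0] for ch in channels}, index=["P0"])
        flags = {ch: [i < 4] for i, ch in enumerate(channels)}  # 4 of 8 detected
        matrix = arrays.SignalMatrix(signal=signal, detected=pd.DataFrame(flags, index=["P0"]))
        filtered, report = arrays.filter_probes(matrix, design)
        assert list(filtered.probes) == ["P0"]
        assert report.n_removed_detection == 0

    def test_dye_fold_just_above_two_is_removed(self):
        design = paired_design()
        channels = design.channel_ids
        row = {ch: 100.0 for ch in channels}
        row["CL.control.T.Cy5"] = 201.0
        matrix = arrays.SignalMatrix(
            signal=pd.DataFrame(row, index=["P0"]),
            detected=pd.DataFrame({ch: [True] for ch in channels}, index=["P0"]),
        )
        filtered, report = arrays.filter_probes(matrix, design)
        assert len(filtered.probes) == 0
        assert report.n_removed_consistency == 1

    def test_matches_brute_force_oracle(self, rng):
        matrix, design = self._matrix_and_design(rng)
        filtered, report = arrays.filter_probes(matrix, design)

        expected = []
        for probe in matrix.probes:
            frac = matrix.detected.loc[probe].mean()
            if frac < 0.5:
                continue
            bad = False
            for _key, cy3, cy5 in design.dye_pairs():
                a = max(matrix.signal.loc[probe, cy3], 1.0)
                b = max(matrix.signal.loc[probe, cy5], 1.0)
                if max(a, b) / min(a, b) > 2.0:
                    bad = True
            if not bad:
                expected.append(probe)
        assert list(filtered.probes) == expected
        assert (
            report.n_probes_input
            == report.n_removed_detection + report.n_removed_consistency + report.n_probes_retained
        )

    def test_order_independent(self, rng):
        matrix, design = self._matrix_and_design(rng, n=200)
        shuffled = arrays.SignalMatrix(
            signal=matrix.signal.sample(frac=1, random_state=0),
            detected=matrix.detected.sample(frac=1, random_state=0),
        )
        a, _ = arrays.filter_probes(matrix, design)
        b, _ = arrays.filter_probes(shuffled, design)
        assert set(a.probes) == set(b.probes)

    def test_unpaired_design_is_an_error(self):
        design = paired_design()
        broken = arrays.ExperimentDesign(design.table.iloc[:-1].copy())
        matrix = small_matrix(
            {ch: [1.0] for ch in broken.channel_ids},
            flags={ch: [True] for ch in broken.channel_ids},
        )
        with pytest.raises(DesignError):
            arrays.filter_probes(matrix, broken)


class TestAverageDyeReplicates:
    def test_arithmetic_mean(self):
        design = paired_design()
        row = {ch: 100.0 for ch in design.channel_ids}
        row["CL.control.T.Cy5"] = 300.0
        matrix = arrays.SignalMatrix(signal=pd.DataFrame(row, index=["P0"]))
        out = arrays.average_dye_replicates(matrix, design)
        assert out.loc["P0", ("CL", "control", "T")] == 200.0
        assert out.loc["P0", ("CL", "control", "IP")] == 100.0

    def test_column_count_equals_sample_groups(self, noisy_experiment):
        out = arrays.average_dye_replicates(noisy_experiment.signal_matrix, noisy_experiment.design)
        n_groups = len(noisy_experiment.design.table.groupby(["cell_line", "construct", "fraction"]))
        assert out.shape[1] == n_groups

    def test_zero_noise_pipeline_recovers_planted_signals(self, zero_noise_experiment):
        exp = zero_noise_experiment
        matrix = arrays.detect_calls(exp.signal_matrix)
        filtered, report = arrays.filter_probes(matrix, exp.design)
        assert report.n_probes_retained == len(exp.signal_matrix.probes)
        averaged = arrays.average_dye_replicates(filtered, exp.design)
        # all dye channels identical at zero noise: average == raw channel
        cl = exp.config.cell_line
        for construct in exp.config.constructs:
            for fraction in ("T", "IP"):
                raw = exp.signal_matrix.signal[f"{cl}.{construct}.{fraction}.Cy3"]
                assert np.array_equal(averaged[(cl, construct, fraction)].to_numpy(), raw.to_numpy())
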