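"""Container invariants, CSV round-trips and cohort assembly."""

import numpy as np
import pandas as pd
import pytest

from circaseason import (GeneratorConfig, assemble_cohort, read_actigraphy,
                         simulate_cohort, simulate_recording, write_actigraphy)
from circaseason.series import ActigraphyError
from conftest import make_series


class TestActigraphySeries:
    def test_channel_length_mismatch_rejected(self):
        with pytest.raises(ActigraphyError):
            make_series({"activity": np.zeros(10), "light": np.zeros(9)})

    def test_negative_counts_rejected_where_valid(self):
        with pytest.raises(ActigraphyError):
            make_series({"light": np.array([1.0, -2.0, 3.0])})

    def test_negative_allowed_when_masked(self):
        s = make_series({"light": np.array([1.0, -2.0, 3.0])},
                        mask=np.array([True, False, True]))
        assert s.coverage() == pytest.approx(2 / 3)

    def test_clock_hours_wrap(self):
        s = make_series({"light": np.zeros(1440)}, start="2024-01-01 23:00")
        ch = s.clock_hours()
        assert ch[0] == 23.0
        assert ch[60] == 0.0
        assert ch[-1] == pytest.approx(22.0 + 59 / 60)


class TestActigraphyCSV:
    def test_well_formed_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        s = make_series({"activity": rng.gamma(2.0, 50.0, 10080),
                         "light": rng.lognormal(3.0, 1.0, 10080),
                         "blue": rng.lognormal(0.0, 1.0, 10080),
                         "wrist_temp": rng.normal(34.0, 1.0, 10080)})
        path = tmp_path / "rec.csv"
        write_actigraphy(s, path)
        back = read_actigraphy(path, participant_id="P01", season="winter")
        assert back.n_minutes == 10080
        assert back.mask.all()
        for ch in s.channels:
            np.testing.assert_array_equal(back.channel(ch), s.channel(ch))

    def test_simulated_roundtrip_bit_identical(self, tmp_path):
        s, _ = simulate_recording(GeneratorConfig(), seed=1, pidx=0, season="summer")
        path = tmp_path / "sim.csv"
        write_actigraphy(s, path)
        back = read_actigraphy(path, participant_id=s.participant_id, season=s.season)
        assert back.start == s.start
        np.testing.assert_array_equal(back.mask, s.mask)
        for ch in s.channels:
            np.testing.assert_array_equal(back.channel(ch), s.channel(ch))

    def test_missing_minutes_masked_not_dropped(self, tmp_path):
        s = make_series({"light": np.arange(10080, dtype=float)})
        frame = s.to_frame().rename(columns={"light": "lux"})
        frame = frame.drop(index=range(100, 160))
        frame.to_csv(tmp_path / "gap.csv", index=False)
        back = read_actigraphy(tmp_path / "gap.csv")
        assert back.n_minutes == 10080
        assert not back.mask[100:160].any()
        assert back.mask.sum() == 10080 - 60

    def test_out_of_order_rows_sorted(self, tmp_path):
        s = make_series({"light": np.arange(200, dtype=float)})
        frame = s.to_frame().rename(columns={"light": "lux"})
        frame.iloc[::-1].to_csv(tmp_path / "rev.csv", index=False)
        back = read_actigraphy(tmp_path / "rev.csv")
        np.testing.assert_array_equal(back.channel("light"), np.arange(200.0))

    def test_duplicate_timestamp_hard_error(self, tmp_path):
        frame = make_series({"light": np.ones(10)}).to_frame()
        frame = pd.concat([frame, frame.iloc[[3]]])
        frame.rename(columns={"light": "lux"}).to_csv(tmp_path / "dup.csv", index=False)
        with pytest.raises(ActigraphyError, match="duplicate"):
            read_actigraphy(tmp_path / "dup.csv")

    def test_empty_file_hard_error(self, tmp_path):
        (tmp_path / "empty.csv").write_text("timestamp,lux\n")
        with pytest.raises(ActigraphyError):
            read_actigraphy(tmp_path / "empty.csv")

    def test_non_numeric_cell_masks_minute(self, tmp_path):
        frame = make_series({"light": np.ones(10)}).to_frame()
        frame = frame.astype({"light": object})
        frame.loc[4, "light"] = "oops"
        frame.rename(columns={"light": "lux"}).to_csv(tmp_path / "bad.csv", index=False)
        back = read_actigraphy(tmp_path / "bad.csv")
        assert not back.mask[4]
        assert back.mask.sum() == 9


class TestAssembleCohort:
    @staticmethod
    def _meta(ids):
        return pd.DataFrame({"participant_id": ids, "age": 30.0, "sex": "F",
                             "bmi": 25.0, "population": "native"})

    def test_full_grid(self):
        expr = pd.DataFrame({
            "participant_id": np.repeat(["P1", "P2", "P3"], 4),
            "season": ["winter", "spring", "summer", "autumn"] * 3,
            "cq_target": 25.0, "cq_reference": 20.0})
        out = assemble_cohort(expr, self._meta(["P1", "P2", "P3"]))
        assert len(out) == 12
        assert not out.duplicated(["participant_id", "season"]).any()

    def test_partial_grid_keeps_single_row(self):
        expr = pd.DataFrame({"participant_id": ["P1"], "season": ["winter"],
                             "cq_target": [25.0], "cq_reference": [20.0]})
        out = assemble_cohort(expr, self._meta(["P1", "P2"]))
        assert len(out) == 1

    def test_missing_metrics_stay_nan(self):
        expr = pd.DataFrame({"participant_id": ["P1", "P2"], "season": "winter",
                             "cq_target": 25.0, "cq_reference": 20.0})
        metrics = pd.DataFrame({"participant_id": ["P1"], "season": ["winter"],
                                "light_mesor": [200.0]})
        out = assemble_cohort(expr, self._meta(["P1", "P2"]), metrics)
        assert out["light_mesor"].isna().sum() == 1

    def test_orphan_expression_hard_error(self):
        expr = pd.DataFrame({"participant_id": ["P9"], "season": ["winter"],
                             "cq_target": [25.0], "cq_reference": [20.0]})
        with pytest.raises(ValueError, match="no metadata"):
            assemble_cohort(expr, self._meta(["P1"]))

    def test_duplicate_key_hard_error(self):
        expr = pd.DataFrame({"participant_id": ["P1", "P1"], "season": "winter",
                             "cq_target": 25.0, "cq_reference": 20.0})
        with pytest.raises(ValueError, match="duplicate"):
            assemble_cohort(expr, self._meta(["P1"]))

    def test_order_independence(self):
        expr = pd.DataFrame({
            "participant_id": np.repeat(["P1", "P2"], 2),
            "season": ["winter", "summer"] * 2,
            "cq_target": [25.0, 24.0, 23.0, 22.0], "cq_reference": 20.0})
        a = assemble_cohort(expr, self._meta(["P1", "P2"]))
        b = assemble_cohort(expr.sample(frac=1, random_state=3),
                            self._meta(["P2", "P1"]))
        pd.testing.assert_frame_equal(a, b[a.columns])

    def test_synthetic_cohort_row_count_by_construction(self):
        # 29 participants with 29/22/25/21 seasonal availability -> 97 rows
        cohort = simulate_cohort(GeneratorConfig(), seed=1, channels=(),
                                 keep_recordings=False)
        assert len(cohort.truth) == 97
        out = assemble_cohort(cohort.expression, cohort.meta)
        assert len(out) == 97
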