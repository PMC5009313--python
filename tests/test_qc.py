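import numpy as np
import pandas as pd
import pytest

from arraybsa.errors import DegenerateBackgroundError, NormalizationError
from arraybsa.io import FeatureAnnotation, SpotMeasurement
from arraybsa.qc import (
    QCConfig,
    apply_qc_flags,
    build_fingerprint,
    compute_snr,
    snr_detection_filter,
    spike_in_normalize,
    subtraction_efficiency,
)

from conftest import make_matrix


class TestSNR:
    def test_conventional_definition(self):
        assert compute_snr(SpotMeasurement("A", 150, 50, 10)) == 10.0

    def test_signal_equals_background(self):
        assert compute_snr(SpotMeasurement("A", 50, 50, 10)) == 0.0

    def test_zero_background_sd(self):
        with pytest.raises(DegenerateBackgroundError):
            compute_snr(SpotMeasurement("A", 150, 50, 0))


def _detection_matrix(snrs_by_feature, layout=None):
    """One bulk, one bio rep, six tech reps."""
    if layout is None:
        layout = [
            FeatureAnnotation(f, "subtracted") for f in snrs_by_feature
        ] + [FeatureAnnotation("SPIKE1", "spike_in")]
    values = {}
    for j in range(6):
        values[f"h{j}"] = [snrs_by_feature[f][j] for f in snrs_by_feature] + [50.0]
    design = {
        "target": ["DN1"] * 6,
        "biological_replicate": [1] * 6,
        "technical_replicate": list(range(1, 7)),
    }
    return make_matrix(values, layout, design)


class TestDetectionFilter:
    @pytest.mark.parametrize(
        "snrs,expected",
        [
            ([7.1, 7.1, 7.1, 7.1, 2, 2], True),   # 4/6 strictly above
            ([8, 8, 8, 2, 2, 2], False),          # exactly half is not enough
            ([7.0] * 6, False),                   # threshold is strict
        ],
    )
    def test_more_than_half_rule(self, snrs, expected):
        m = _detection_matrix({"F1": snrs})
        retained, dropped = snr_detection_filter(m, QCConfig())
        assert ("F1" in retained) is expected

    def test_any_group_aggregation(self):
        # absent in SD but present in DN1: retained (candidate marker)
        layout = [FeatureAnnotation("F1", "subtracted"),
                  FeatureAnnotation("SPIKE1", "spike_in")]
        values, design = {}, {"target": [], "biological_replicate": [], "technical_replicate": []}
        for b, level in (("DN1", 20.0), ("SD", 1.0)):
            for j in range(6):
                values[f"{b}_{j}"] = [level, 50.0]
                design["target"].append(b)
                design["biological_replicate"].append(1)
                design["technical_replicate"].append(j + 1)
        m = make_matrix(values, layout, design)
        retained, _ = snr_detection_filter(m)
        assert retained == ["F1"]

    def test_lower_threshold_never_shrinks_retained_set(self):
        rng = np.random.default_rng(3)
        snrs = {f"F{i}": rng.uniform(0, 15, 6).tolist() for i in range(30)}
        m = _detection_matrix(snrs)
        previous: set = set()
        for thr in (12.0, 9.0, 7.0, 4.0, 1.0):
            retained, _ = snr_detection_filter(m, QCConfig(snr_threshold=thr))
            assert previous <= set(retained)
            previous = set(retained)


class TestFlags:
    def test_negative_control_masked_everywhere(self, two_bulk_matrix):
        m = apply_qc_flags(two_bulk_matrix)
        assert m.mask.loc["NEG1"].all()

    def test_single_bad_cell_masked(self, two_bulk_matrix):
        two_bulk_matrix.flags.loc["FS1", "DN1_b1_t1"] = "bad"
        m = apply_qc_flags(two_bulk_matrix)
        assert m.mask.loc["FS1", "DN1_b1_t1"]
        assert m.mask.loc["FS1"].sum() == 1

    def test_all_good_matrix_only_masks_negative_controls(self, two_bulk_matrix):
        m = apply_qc_flags(two_bulk_matrix)
        assert m.mask.drop(index="NEG1").to_numpy().sum() == 0


class TestSpikeInNormalize:
    def test_identity_when_already_equal(self, two_bulk_matrix):
        m = spike_in_normalize(two_bulk_matrix)
        np.testing.assert_allclose(m.values, two_bulk_matrix.values)

    def test_half_reference_doubles(self, two_bulk_matrix):
        col = "DN1_b1_t1"
        two_bulk_matrix.values[col] /= 2  # spike-in now at half the reference
        m = spike_in_normalize(two_bulk_matrix)
        # after normalization the column is scaled by ref / (50/2)
        ref = np.mean([50.0] * 7 + [25.0]) / 50 * 50
        expected = two_bulk_matrix.values[col] * ref / 25.0
        np.testing.assert_allclose(m.values[col], expected)

    def test_masked_spike_in_is_error(self, two_bulk_matrix):
        two_bulk_matrix.mask.loc["SPIKE1", "SD_b2_t2"] = True
        with pytest.raises(NormalizationError, match="SD_b2_t2"):
            spike_in_normalize(two_bulk_matrix)

    def test_idempotent(self, two_bulk_matrix):
        two_bulk_matrix.values["DN1_b1_t1"] *= 3.7
        once = spike_in_normalize(two_bulk_matrix)
        twice = spike_in_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)


class TestFingerprint:
    def _matrix(self, tech1, tech2):
        layout = [FeatureAnnotation("F1", "subtracted"),
                  FeatureAnnotation("SPIKE1", "spike_in")]
        values, design = {}, {"target": [], "biological_replicate": [], "technical_replicate": []}
        for i, reps in ((1, tech1), (2, tech2)):
            for j, v in enumerate(reps):
                values[f"b{i}_t{j}"] = [v, 50.0]
                design["target"].append("DN1")
                design["biological_replicate"].append(i)
                design["technical_replicate"].append(j + 1)
        return make_matrix(values, layout, design)

    def test_mean_of_technical_then_biological(self):
        m = self._matrix([1, 2, 3, 4, 5, 6], [2, 3, 4, 5, 6, 7])
        fp = build_fingerprint(m, "DN1")
        assert fp.values["F1"] == pytest.approx(4.0)

    def test_single_biological_replicate(self):
        m = self._matrix([1, 2, 3, 4, 5, 6], [])
        fp = build_fingerprint(m, "DN1")
        assert fp.values["F1"] == pytest.approx(3.5)

    def test_masked_replicate_excluded(self):
        m = self._matrix([1, 2, 3, 4, 5, 600], [2, 3, 4, 5, 6, 7])
        m.mask.loc["F1", "b1_t5"] = True  # drops the 600 outlier
        fp = build_fingerprint(m, "DN1")
        expected_bio1 = (1 + 2 + 3 + 4 + 5) / 5
        assert fp.values["F1"] == pytest.approx((expected_bio1 + 4.5) / 2)

    def test_scaling_a_bulk_scales_its_fingerprint(self, two_bulk_matrix):
        fp0 = build_fingerprint(two_bulk_matrix, "DN1")
        scaled = two_bulk_matrix.copy()
        for col in scaled.columns_for("DN1"):
            scaled.values[col] *= 2.5
        fp1 = build_fingerprint(scaled, "DN1")
        np.testing.assert_allclose(fp1.values, 2.5 * fp0.values)


class TestSubtractionEfficiency:
    def _driver_fp(self, n_total, n_detected):
        idx = pd.Index([f"FS{i:03d}" for i in range(n_total)])
        vals = pd.Series(1.0, index=idx)
        vals.iloc[:n_detected] = 20.0
        return vals

    def test_three_of_290_rounds_to_99(self):
        r = subtraction_efficiency(self._driver_fp(290, 3), threshold=7.0)
        assert r.n_detected == 3
        assert r.efficiency_percent == pytest.approx(100 * 287 / 290)
        assert r.efficiency_percent_rounded == 99
        assert len(r.detected_ids) == 3
        # removing the driver-detected features leaves the analysis set
        assert r.n_total - r.n_detected == 287

    def test_none_detected(self):
        r = subtraction_efficiency(self._driver_fp(290, 0))
        assert r.efficiency_percent == 100.0

    def test_all_detected(self):
        r = subtraction_efficiency(self._driver_fp(10, 10))
        assert r.efficiency_percent == 0.0
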