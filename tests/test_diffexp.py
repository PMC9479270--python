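"""Fold-change/t-test statistics and the four-part expression filter."""

import math

import numpy as np
import pytest
from scipy import stats

from lncnet.diffexp import (Contrast, DEThresholds, contrast_statistics,
                            filter_de)
from lncnet.exceptions import DataError, DesignError, ParameterError
from lncnet.synthetic import SimulationConfig, simulate_study
from tests.conftest import build_study


def welch_oracle(a, b):
    """Independently coded Welch t-test: statistic and df by hand."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2.0 * stats.t.sf(abs(t), df)


class TestContrastStatistics:
    def test_exact_fold_change_and_direction(self):
        study = build_study({"T_up": [8.0] * 4 + [2.0] * 4 + [2.0] * 4,
                             "T_ref": [4.0] * 12})
        res = contrast_statistics(study, Contrast("c", "Control", "CIA"))
        row = res.set_index("transcript_id").loc["T_up"]
        assert row["fc_magnitude"] == pytest.approx(4.0)
        assert row["direction"] == "Up"

    def test_identical_groups_null_case(self):
        study = build_study({"T0": [5.0, 6.0, 7.0, 8.0] * 3})
        res = contrast_statistics(study, Contrast("c", "CIA", "Control"))
        row = res.set_index("transcript_id").loc["T0"]
        assert row["fc_magnitude"] == 1.0
        assert row["direction"] is None
        assert row["p_value"] == 1.0

    def test_matches_independent_welch_oracle(self):
        a = [10.1, 9.9, 10.0, 10.2]
        b = [8.0, 8.2, 7.9, 8.1]
        study = build_study({"T0": [2.0 ** v for v in b + a + a]})
        res = contrast_statistics(study, Contrast("c", "CIA", "Control"))
        p = res.set_index("transcript_id").loc["T0", "p_value"]
        assert p == pytest.approx(welch_oracle(a, b), abs=1e-12)

    def test_antisymmetry_under_contrast_swap(self, toy_study):
        c = Contrast("fwd", "CIA", "Control")
        fwd = contrast_statistics(toy_study, c).set_index("transcript_id")
        rev = contrast_statistics(toy_study, c.swapped()).set_index("transcript_id")
        assert np.allclose(fwd["fc_magnitude"], rev["fc_magnitude"])
        assert np.allclose(fwd["p_value"], rev["p_value"], atol=1e-12)
        flip = {"Up": "Down", "Down": "Up", None: None}
        assert all(rev.loc[t, "direction"] == flip[fwd.loc[t, "direction"]]
                   for t in fwd.index)

    def test_scale_equivariance(self, toy_study):
        c = Contrast("c", "BZXD", "CIA")
        base = contrast_statistics(toy_study, c).set_index("transcript_id")
        scaled = toy_study.matrix.copy()
        scaled.loc["T2"] *= 37.5
        study2 = build_study({t: scaled.loc[t].tolist() for t in scaled.index})
        after = contrast_statistics(study2, c).set_index("transcript_id")
        assert after.loc["T2", "p_value"] == pytest.approx(
            base.loc["T2", "p_value"], abs=1e-12)
        assert after.loc["T2", "fc_magnitude"] == pytest.approx(
            base.loc["T2", "fc_magnitude"], rel=1e-12)

    def test_missing_group_is_design_error(self, toy_study):
        with pytest.raises(DesignError):
            contrast_statistics(toy_study, Contrast("c", "Nope", "CIA"))

    def test_same_group_contrast_rejected(self):
        with pytest.raises(ParameterError):
            Contrast("c", "CIA", "CIA")


class TestFilterDe:
    def test_empty_results_empty_set(self, toy_study):
        res = contrast_statistics(toy_study, Contrast("c", "CIA", "Control"))
        assert filter_de(res.iloc[0:0], toy_study, DEThresholds()) == {}

    def test_raising_min_fc_never_enlarges(self, small_study):
        study, _ = small_study
        res = contrast_statistics(study, Contrast("c", "CIA", "Control"))
        prev = None
        for fc in (1.5, 2.0, 3.0, 5.0):
            kept = set(filter_de(res, study, DEThresholds(min_fc=fc)))
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_lowering_max_p_never_enlarges(self, small_study):
        study, _ = small_study
        res = contrast_statistics(study, Contrast("c", "CIA", "Control"))
        prev = None
        for p in (0.1, 0.05, 0.01, 0.001):
            kept = set(filter_de(res, study, DEThresholds(max_p=p)))
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_length_and_intensity_criteria(self):
        high = [4096.0] * 4 + [1024.0] * 8     # fc 4, bright
        dim = [40.0] * 4 + [10.0] * 8          # fc 4, below 200 in both groups
        study = build_study({"T_ok": high, "T_long": high, "T_dim": dim},
                            lengths={"T_ok": 1000, "T_long": 3500, "T_dim": 1000})
        res = contrast_statistics(study, Contrast("c", "Control", "CIA"))
        kept = filter_de(res, study, DEThresholds())
        assert set(kept) == {"T_ok"}
        assert kept["T_ok"] == "Up"

    def test_strict_vs_inclusive_fold_threshold(self):
        exactly2 = [2048.0] * 4 + [1024.0] * 8
        study = build_study({"T2": exactly2})
        res = contrast_statistics(study, Contrast("c", "Control", "CIA"))
        assert "T2" in filter_de(res, study, DEThresholds(min_fc=2.0))
        assert "T2" not in filter_de(res, study,
                                     DEThresholds(min_fc=2.0, strict_fc=True))

    def test_recovers_exactly_the_planted_set_at_low_noise(self):
        """Near-noiseless planting at fc 4: the filter returns the planted
        transcripts and nothing else."""
        cfg = SimulationConfig(n_lncrna=40, n_mrna=160, n_reversal_lncrna=4,
                               targets_per_lncrna=2, n_reversal_mrna=4,
                               noise_log2_sd=0.05, latent_sd=0.05,
                               coupling_sd=0.01, low_intensity_fraction=0.0,
                               seed=21)
        study, truth = simulate_study(cfg)
        res = contrast_statistics(study, Contrast("c", "CIA", "Control"))
        kept = filter_de(res, study, DEThresholds())
        assert set(kept) == set(truth.de_disease)
        assert kept == truth.de_disease

    def test_missing_annotation_is_data_error(self, toy_study):
        res = contrast_statistics(toy_study, Contrast("c", "CIA", "Control"))
        study2 = build_study({t: toy_study.matrix.loc[t].tolist()
                              for t in toy_study.matrix.index})
        study2.annotation.drop(index="T0", inplace=True)
        with pytest.raises(DataError, match="T0"):
            filter_de(res, study2, DEThresholds())
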