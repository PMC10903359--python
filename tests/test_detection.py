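import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import surveycost as sc
from surveycost.detection import SeparationWarning


def records_frame(cells):
    """Build a records DataFrame from {(site, method): (n_detected, n_total)}."""
    rows = []
    for (site, method), (hit, total) in cells.items():
        for i in range(total):
            rows.append((site, method, f"{site}-{method}-{i}", int(i < hit)))
    return pd.DataFrame(rows, columns=["site_id", "method", "sample_id", "detected"])


class TestInverseLogit:
    def test_symmetry_at_zero(self):
        assert sc.inverse_logit(0.0) == 0.5

    def test_rare_case_seine_coefficients(self):
        # low-detection site: logistic intercept 1.08 minus site effect 2.2
        gamma = float(sc.inverse_logit(1.08 - 2.2))
        assert gamma == pytest.approx(0.246, abs=5e-4)
        assert round(gamma, 2) == 0.25

    def test_saturates_at_extremes(self):
        assert float(sc.inverse_logit(-20.0)) == pytest.approx(2.06e-9, rel=1e-2)
        assert 0.0 < float(sc.inverse_logit(-50.0)) < 1e-20

    @given(p=st.floats(0.001, 0.999))
    @settings(derandomize=True)
    def test_round_trip(self, p):
        assert float(sc.inverse_logit(sc.logit(p))) == pytest.approx(p, abs=1e-12)


class TestDetectionGLM:
    def test_single_cell_half_detected(self):
        frame = records_frame({("s", "m"): (10, 20)})
        (est,) = sc.fit_detection_glm(frame)
        assert est.gamma == pytest.approx(0.5, abs=1e-9)
        assert est.coefficient == pytest.approx(0.0, abs=1e-8)
        assert est.ci_low < 0.5 < est.ci_high

    def test_matches_closed_form_empirical_logits(self):
        # counts constructed so the empirical cell odds are exactly
        # multiplicative (odds 1, 2, 3, 6): the additive logit model can then
        # attain the saturated fit, and MLE cell probabilities must equal the
        # empirical proportions
        N = 84
        cells = {
            ("s1", "m1"): (42, N),   # p = 1/2
            ("s1", "m2"): (56, N),   # p = 2/3
            ("s2", "m1"): (63, N),   # p = 3/4
            ("s2", "m2"): (72, N),   # p = 6/7
        }
        model = sc.DetectionModel().fit(records_frame(cells))
        for (site, method), (hit, total) in cells.items():
            est = model.estimate_for(site, method)
            assert est.gamma == pytest.approx(hit / total, abs=1e-6)

    def test_separation_warned_and_flagged(self):
        frame = records_frame({("ormond", "qPCR"): (18, 18), ("scr", "qPCR"): (15, 20)})
        with pytest.warns(SeparationWarning, match="ormond"):
            estimates = sc.fit_detection_glm(frame)
        by_site = {e.site_id: e for e in estimates}
        assert by_site["ormond"].separation
        assert not by_site["scr"].separation
        assert by_site["scr"].gamma == pytest.approx(0.75, abs=1e-6)

    def test_requires_both_outcomes(self):
        with pytest.raises(ValueError, match="non-detection"):
            sc.fit_detection_glm(records_frame({("s", "m"): (5, 5)}))

    def test_reference_levels_respected(self):
        frame = records_frame({("a", "x"): (5, 20), ("a", "y"): (12, 20),
                               ("b", "x"): (9, 20), ("b", "y"): (15, 20)})
        model = sc.DetectionModel(reference_method="y", reference_site="b").fit(frame)
        assert model.method_levels_[0] == "y"
        assert model.site_levels_[0] == "b"
        # predictions are invariant to the chosen reference level
        other = sc.DetectionModel(reference_method="x", reference_site="a").fit(frame)
        grid = pd.DataFrame({"site_id": ["a", "a", "b"], "method": ["x", "y", "y"]})
        np.testing.assert_allclose(
            model.predict_proba(grid), other.predict_proba(grid), atol=1e-6
        )


class TestCumulativeDetection:
    def test_five_edna_samples_exceed_99_percent(self, rare_case):
        cum = sc.cumulative_detection(rare_case["metabarcode"], n=1, k=5)
        assert cum.d > 0.99
        assert cum.d == pytest.approx(0.99207, abs=1e-5)

    def test_single_sample_equals_gamma(self, rare_case):
        est = rare_case["seine"]
        cum = sc.cumulative_detection(est, n=1, k=1)
        assert cum.d == pytest.approx(est.gamma)
        assert (cum.ci_low, cum.ci_high) == (est.ci_low, est.ci_high)

    def test_undetectable_species_stays_undetected(self):
        assert sc.cumulative_detection(0.0, n=5, k=20).d == 0.0

    def test_seine_ten_sites(self):
        assert sc.cumulative_detection(0.25, n=1, k=10).d == pytest.approx(0.94369, abs=1e-5)

    def test_ci_ordering_preserved(self, rare_case):
        for est in rare_case.values():
            for k in (1, 3, 10, 25):
                cum = sc.cumulative_detection(est, n=1, k=k)
                assert cum.ci_low <= cum.d <= cum.ci_high

    @given(
        gamma=st.floats(0.01, 0.99),
        nk1=st.integers(0, 100),
        nk2=st.integers(0, 100),
    )
    @settings(derandomize=True)
    def test_monotone_in_effort(self, gamma, nk1, nk2):
        lo, hi = sorted((nk1, nk2))
        assert (
            sc.cumulative_detection(gamma, n=1, k=hi).d
            >= sc.cumulative_detection(gamma, n=1, k=lo).d
        )

    @given(g1=st.floats(0.01, 0.99), g2=st.floats(0.01, 0.99), nk=st.integers(1, 50))
    @settings(derandomize=True)
    def test_monotone_in_gamma(self, g1, g2, nk):
        lo, hi = sorted((g1, g2))
        assert (
            sc.cumulative_detection(hi, n=1, k=nk).d
            >= sc.cumulative_detection(lo, n=1, k=nk).d
        )

    def test_approaches_one(self):
        assert sc.cumulative_detection(0.05, n=1, k=1000).d == pytest.approx(1.0, abs=1e-12)


class TestMinSamples:
    @pytest.mark.parametrize(
        "gamma, target, expected",
        [(0.62, 0.99, 5), (0.25, 0.99, 17), (0.999999, 0.99, 1), (0.5, 0.5, 1)],
    )
    def test_known_counts(self, gamma, target, expected):
        m = sc.min_samples(gamma, target)
        assert m == expected
        # boundary verification: m works, m-1 does not
        assert 1 - (1 - gamma) ** m >= target
        if m > 1:
            assert 1 - (1 - gamma) ** (m - 1) < target

    def test_zero_gamma_has_no_solution(self):
        with pytest.raises(ValueError, match="no solution"):
            sc.min_samples(0.0, 0.99)

    @given(gamma=st.floats(0.01, 0.99), target=st.floats(0.01, 0.999))
    @settings(derandomize=True)
    def test_minimality(self, gamma, target):
        m = sc.min_samples(gamma, target)
        assert (1.0 - gamma) ** m <= 1.0 - target
        if m > 1:
            assert (1.0 - gamma) ** (m - 1) > 1.0 - target


class TestRareCase:
    def test_shared_edna_gamma(self, rare_case):
        assert rare_case["qPCR"].gamma == rare_case["metabarcode"].gamma == 0.62
        assert rare_case["seine"].gamma == 0.25
        assert (rare_case["qPCR"].ci_low, rare_case["qPCR"].ci_high) == (0.42, 0.78)
        assert (rare_case["seine"].ci_low, rare_case["seine"].ci_high) == (0.12, 0.43)
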