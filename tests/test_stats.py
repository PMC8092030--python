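"""Wilson intervals, Newcombe difference CIs and Pearson chi-square,
cross-checked against independent library implementations."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency
from statsmodels.stats.proportion import proportion_confint

from emovista.intensity import IntensityProfile
from emovista.plutchik import EMOTIONS
from emovista.stats import (ProportionSample, chisq_two_proportions,
                            compare_intensity_profiles,
                            newcombe_difference_ci, wilson_interval)

FIRST = {"anger": 13.84, "sadness": 31.36, "disgust": 9.81, "fear": 17.58,
         "joy": 16.94, "surprise": 1.32, "trust": 6.56, "anticipation": 2.59}
SECOND = {"anger": 15.97, "sadness": 31.01, "disgust": 12.06, "fear": 19.66,
          "joy": 12.56, "surprise": 0.74, "trust": 5.63, "anticipation": 2.37}
N1, N2 = 36_317, 10_604


def _profile(phase, pct, n):
    raw = {e: pct[e] for e in EMOTIONS}
    return IntensityProfile(phase=phase, raw=raw, normalized=dict(pct),
                            n_observations=n)


class TestWilson:
    def test_half_at_n100(self):
        lo, hi = wilson_interval(0.5, 100)
        assert lo == pytest.approx(0.4038, abs=5e-5)
        assert hi == pytest.approx(0.5962, abs=5e-5)

    def test_degenerate_bounds_exact(self):
        assert wilson_interval(0.0, 10)[0] == pytest.approx(0.0, abs=1e-12)
        assert wilson_interval(1.0, 10)[1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("p,n", [(0.05, 40), (0.3, 200), (0.77, 1234),
                                     (0.999, 10_000)])
    def test_matches_reference_implementation(self, p, n):
        """Oracle: statsmodels' Wilson proportion interval."""
        lo, hi = wilson_interval(p, n)
        ref_lo, ref_hi = proportion_confint(round(p * n), n, method="wilson")
        p_exact = round(p * n) / n
        lo2, hi2 = wilson_interval(p_exact, n)
        assert lo2 == pytest.approx(ref_lo, abs=1e-10)
        assert hi2 == pytest.approx(ref_hi, abs=1e-10)
        assert 0.0 <= lo <= p <= hi <= 1.0

    def test_width_shrinks_with_n(self):
        widths = [hi - lo for lo, hi in
                  (wilson_interval(0.3, n) for n in (10, 100, 1000))]
        assert widths[0] > widths[1] > widths[2]


class TestNewcombe:
    @pytest.mark.parametrize("emotion,diff,lo,hi", [
        ("anger", 2.13, 1.3567, 2.9218),
        ("sadness", 0.35, -0.6563, 1.3461),
        ("disgust", 2.25, 1.5691, 2.9518),
        ("fear", 2.08, 1.2365, 2.9399),
        ("joy", 4.38, 3.6308, 5.1097),
        ("surprise", 0.58, 0.3662, 0.7708),
        ("trust", 0.93, 0.4108, 1.4260),
        ("anticipation", 0.22, -0.1257, 0.5406),
    ])
    def test_published_lockdown_intervals(self, emotion, diff, lo, hi):
        """Feeding the printed intensities and n's reproduces the printed
        95% CIs to four decimals."""
        s1 = ProportionSample(FIRST[emotion] / 100, N1)
        s2 = ProportionSample(SECOND[emotion] / 100, N2)
        d, ci_lo, ci_hi = newcombe_difference_ci(s1, s2)
        assert d == pytest.approx(diff, abs=0.005)
        assert ci_lo == pytest.approx(lo, abs=2e-4)
        assert ci_hi == pytest.approx(hi, abs=2e-4)

    def test_equal_samples_symmetric_about_zero(self):
        s = ProportionSample(0.3, 500)
        d, lo, hi = newcombe_difference_ci(s, s)
        assert d == 0.0
        assert lo == pytest.approx(-hi)

    def test_interval_contains_difference(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s1 = ProportionSample(float(rng.uniform(0, 1)),
                                  int(rng.integers(5, 5000)))
            s2 = ProportionSample(float(rng.uniform(0, 1)),
                                  int(rng.integers(5, 5000)))
            d, lo, hi = newcombe_difference_ci(s1, s2)
            assert lo <= d <= hi

    def test_empirical_coverage(self):
        """95% CI covers the true (zero) difference in ≥93% of 2,000
        simulated equal-proportion two-sample draws."""
        rng = np.random.default_rng(17)
        covered = total = 0
        for p in (0.05, 0.15, 0.3):
            for n in (500, 5000):
                for _ in range(334):
                    x1 = rng.binomial(n, p) / n
                    x2 = rng.binomial(n, p) / n
                    _, lo, hi = newcombe_difference_ci(
                        ProportionSample(x1, n), ProportionSample(x2, n))
                    covered += lo <= 0.0 <= hi
                    total += 1
        assert total >= 2000
        assert covered / total >= 0.93


class TestChiSquare:
    def test_hand_computed_example(self):
        chi2, p = chisq_two_proportions(ProportionSample(0.1, 100),
                                        ProportionSample(0.2, 100))
        assert chi2 == pytest.approx(3.9216, abs=5e-5)
        assert 0.04 < p < 0.05

    def test_equal_proportions_give_zero(self):
        chi2, p = chisq_two_proportions(ProportionSample(0.25, 400),
                                        ProportionSample(0.25, 800))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_published_sadness_row_not_significant(self):
        _chi2, p = chisq_two_proportions(ProportionSample(0.3136, N1),
                                         ProportionSample(0.3101, N2))
        assert round(p, 2) == 0.49

    @pytest.mark.parametrize("p1,n1,p2,n2", [
        (0.1, 100, 0.2, 100), (0.3136, 36317, 0.3101, 10604),
        (0.05, 2000, 0.07, 500),
    ])
    def test_matches_scipy_contingency(self, p1, n1, p2, n2):
        """Oracle: scipy's chi-square on the same 2×2 table, uncorrected."""
        chi2, p = chisq_two_proportions(ProportionSample(p1, n1),
                                        ProportionSample(p2, n2))
        a, c = round(p1 * n1), round(p2 * n2)
        ref = chi2_contingency([[a, n1 - a], [c, n2 - c]], correction=False)
        assert chi2 == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)


class TestCompareProfiles:
    def test_published_significance_pattern(self):
        """All negative emotions except sadness significantly higher in the
        second lockdown; among positives only anticipation is not
        significantly different."""
        results = compare_intensity_profiles(
            _profile("first_lockdown", FIRST, N1),
            _profile("second_lockdown", SECOND, N2))
        by_emotion = {r.emotion: r for r in results}
        not_significant = {e for e, r in by_emotion.items()
                           if not r.significant}
        assert not_significant == {"sadness", "anticipation"}
        assert 0.15 < by_emotion["anticipation"].p_value < 0.25
        for e in ("anger", "disgust", "fear", "joy", "surprise", "trust"):
            assert by_emotion[e].p_value < 0.001
        assert by_emotion["joy"].ci_low == pytest.approx(3.6308, abs=2e-4)

    def test_identical_profiles_nothing_significant(self):
        prof = _profile("a", FIRST, N1)
        results = compare_intensity_profiles(prof, prof)
        assert not any(r.significant for r in results)
        assert all(r.diff == 0.0 for r in results)

    def test_ci_brackets_difference(self):
        results = compare_intensity_profiles(
            _profile("a", FIRST, N1), _profile("b", SECOND, N2))
        for r in results:
            assert r.ci_low <= r.diff <= r.ci_high
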