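"""Prediction-error statistics, chi-squared comparison, aligned profiles."""

import numpy as np
import pytest

from wsnuc import (
    DyadSet,
    ErrorDistribution,
    ScoreProfile,
    UndefinedScoreError,
    aligned_average_profile,
    compare_distributions,
    error_distribution,
    format_report,
    prediction_error,
    score_profile,
    symmetrize,
)
from wsnuc.synthetic import PlantSpec, plant_nucleosomes, random_genome


def make_profile(scores, offset=0, name="c"):
    return ScoreProfile(sequence_name=name, offset=offset, scores=np.asarray(scores))


class TestPredictionError:
    def test_unique_maximum_at_dyad(self):
        profile = make_profile([0, 1, 2, 3, 4, 9, 4, 3, 2, 1, 0])
        assert prediction_error(profile, 5) == 0

    def test_monotone_window_pins_boundary(self):
        profile = make_profile(list(range(11)))
        assert prediction_error(profile, 5) == 5

    def test_undefined_window_raises(self):
        profile = make_profile(list(range(11)))
        with pytest.raises(UndefinedScoreError):
            prediction_error(profile, 4)  # needs positions -1..9

    def test_nearest_tie_break_prefers_dyad_then_negative(self):
        flat = make_profile([7] * 11)
        assert prediction_error(flat, 5, tie_break="nearest") == 0
        two = make_profile([0, 0, 0, 0, 9, 0, 9, 0, 0, 0, 0])
        assert prediction_error(two, 5, tie_break="nearest") == -1

    def test_uniform_tie_break_is_deterministic_and_valid(self):
        profile = make_profile([3, 0, 3, 0, 3, 0, 3, 0, 3, 0, 3])
        picks = {prediction_error(profile, 5) for _ in range(10)}
        assert len(picks) == 1 and picks.pop() in (-5, -3, -1, 1, 3, 5)

    def test_unknown_tie_break_rejected(self):
        with pytest.raises(ValueError):
            prediction_error(make_profile([0] * 11), 5, tie_break="bogus")

    def test_agrees_with_exhaustive_argmax_on_planted_signal(self, rng):
        # strong planted signal, fixed seed: compare against an independent
        # per-dyad exhaustive argmax over the +/-5 window
        dyads = [100 + 200 * i for i in range(30)]
        seq = random_genome(100 + 200 * 30, 0.5, 7)
        seq, truth = plant_nucleosomes(seq, PlantSpec(dyads=dyads, strength=0.95, seed=7))
        profile = score_profile(seq)
        errors = []
        for _, d, _ in truth:
            e = prediction_error(profile, d)
            window = {k: profile.score_at(d + k) for k in range(-5, 6)}
            assert window[e] == max(window.values())
            errors.append(e)
        assert sum(e == 0 for e in errors) / len(errors) >= 0.9


class TestErrorDistribution:
    def test_all_exact(self):
        dist = ErrorDistribution.from_errors([0] * 10)
        assert dist.percentages[5] == 100.0
        assert dist.fraction_within(0) == 1.0

    def test_counting_and_fractions(self):
        dist = ErrorDistribution.from_errors([0, 0, 1, -1])
        pct = dict(zip(dist.errors, dist.percentages))
        assert pct[0] == 50.0 and pct[1] == 25.0 and pct[-1] == 25.0
        assert dist.fraction_within(2) == 1.0

    def test_percentages_always_sum_to_100(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 50, size=11)
            if counts.sum() == 0:
                counts[0] = 1
            dist = ErrorDistribution(counts=counts)
            assert np.isclose(dist.percentages.sum(), 100.0)

    def test_out_of_range_error_rejected(self):
        with pytest.raises(ValueError):
            ErrorDistribution.from_errors([6])

    def test_excluded_dyads_counted_not_dropped(self):
        profile = score_profile("ACGT" * 100, sequence_name="c")
        # one evaluable dyad, one too near the end, one on a missing sequence
        dyads = DyadSet.from_positions([("c", 200), ("c", 75), ("other", 200)])
        dist = error_distribution(profile, dyads)
        assert dist.n_total == 1
        assert dist.n_excluded == 2

    def test_report_format_carries_headline_fractions(self):
        dist = ErrorDistribution.from_errors([0, 0, 1, -1, 5])
        text = format_report(dist)
        assert "# fraction_within_2\t0.8000" in text
        assert text.count("\n") >= 12


class TestChiSquared:
    def test_identical_distributions(self):
        a = ErrorDistribution(counts=[3, 4, 5, 9, 12, 30, 12, 9, 5, 4, 3])
        result = compare_distributions(a, a)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.pvalue == pytest.approx(1.0)

    def test_opposite_concentrations_strongly_rejected(self):
        # one sample all at 0, the other uniform, n = 110 each
        concentrated = ErrorDistribution(counts=[0] * 5 + [110] + [0] * 5)
        uniform = ErrorDistribution(counts=[10] * 11)
        result = compare_distributions(concentrated, uniform)
        assert result.pvalue < 0.001

    def test_argument_symmetry(self):
        a = ErrorDistribution(counts=[1, 2, 3, 4, 5, 6, 5, 4, 3, 2, 1])
        b = ErrorDistribution(counts=[4, 4, 4, 4, 4, 4, 4, 4, 4, 4, 4])
        r1 = compare_distributions(a, b)
        r2 = compare_distributions(b, a)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_sparse_categories_pooled(self):
        a = ErrorDistribution(counts=[1, 0, 0, 0, 0, 50, 0, 0, 0, 0, 1])
        b = ErrorDistribution(counts=[0, 1, 0, 0, 0, 50, 0, 0, 0, 0, 1])
        result = compare_distributions(a, b)
        assert result.n_categories < 11
        assert result.dof == result.n_categories - 1

    def test_empty_distribution_rejected(self):
        empty = ErrorDistribution(counts=[0] * 11)
        full = ErrorDistribution(counts=[1] * 11)
        with pytest.raises(ValueError):
            compare_distributions(empty, full)


class TestAlignedProfile:
    def test_symmetrize_is_exact_and_idempotent(self, rng):
        x = rng.normal(size=141)
        s = symmetrize(x)
        assert np.array_equal(s, s[::-1])
        assert np.array_equal(symmetrize(s), s)

    def test_single_dyad_equals_symmetrized_window(self):
        seq = "ACGT" * 100
        profile = score_profile(seq, sequence_name="c")
        dyads = DyadSet.from_positions([200], chrom="c")
        aligned = aligned_average_profile(profile, dyads, half_width=20)
        lo = 200 - 20 - profile.offset
        window = profile.scores[lo : lo + 41].astype(float)
        assert np.array_equal(aligned.mean_score, symmetrize(window))
        assert aligned.n_contributing[0] == 1

    def test_planted_signal_peaks_at_dyad_with_helical_period(self):
        dyads = [100 + 200 * i for i in range(50)]
        seq = random_genome(100 + 200 * 50, 0.5, 3)
        seq, truth = plant_nucleosomes(seq, PlantSpec(dyads=dyads, strength=1.0, seed=3))
        aligned = aligned_average_profile(score_profile(seq, sequence_name="synthetic"), truth, half_width=30)
        mid = aligned.half_width
        assert aligned.mean_score[mid] == aligned.mean_score.max()
        # autocorrelation of the mean-removed profile recovers ~10-11 bp
        x = aligned.mean_score - aligned.mean_score.mean()
        ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
        period = int(np.argmax(ac[6:16])) + 6
        assert 9 <= period <= 12

    def test_amplitude_grows_with_signal_strength(self):
        dyads = [100 + 200 * i for i in range(60)]
        length = 100 + 200 * 60
        amplitudes = []
        for strength in (0.2, 0.6, 1.0):
            seq = random_genome(length, 0.5, 11)
            seq, truth = plant_nucleosomes(
                seq, PlantSpec(dyads=dyads, strength=strength, seed=11)
            )
            aligned = aligned_average_profile(score_profile(seq, sequence_name="synthetic"), truth, half_width=30)
            amplitudes.append(aligned.amplitude())
        assert amplitudes[0] < amplitudes[1] < amplitudes[2]

    def test_partially_covered_dyads_excluded(self):
        profile = score_profile("ACGT" * 60, sequence_name="c")  # 240 bp
        dyads = DyadSet.from_positions([80, 120], chrom="c")
        aligned = aligned_average_profile(profile, dyads, half_width=40)
        assert aligned.n_excluded == 1  # dyad 80 needs scores from position 40
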