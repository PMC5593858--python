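import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aquaspec as aq
from aquaspec.sampling import equidistant_split, format_summary, random_split, summarize_split


class TestEquidistantSplit:
    def test_90_samples_ratio_4_gives_72_18(self, rng):
        w = rng.uniform(0.32, 0.75, size=90)
        s = equidistant_split(w, ratio=4)
        assert len(s.calibration_idx) == 72 and len(s.validation_idx) == 18

    def test_two_blocks_of_five(self):
        # w already sorted: validation = sorted positions {4, 9} at offset 4
        w = np.linspace(0.3, 0.7, 10)
        s = equidistant_split(w, ratio=4, offset=4)
        assert np.array_equal(np.sort(s.validation_idx), [4, 9])

    def test_leftover_partial_block_goes_to_calibration(self):
        w = np.linspace(0.3, 0.7, 11)
        s = equidistant_split(w, ratio=4, offset=0)
        assert np.array_equal(np.sort(s.validation_idx), [0, 5])
        assert len(s.calibration_idx) == 9

    def test_sorting_is_by_water_content_not_position(self, rng):
        w = rng.permutation(np.linspace(0.3, 0.7, 10))
        s = equidistant_split(w, ratio=4, offset=4)
        # offset = last of each sorted block: block maxima
        expected = {np.argsort(w, kind="stable")[4], np.argsort(w, kind="stable")[9]}
        assert set(s.validation_idx) == expected

    def test_offset_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            equidistant_split(np.linspace(0.3, 0.7, 10), ratio=4, offset=5)

    def test_random_start_reproducible(self, rng):
        w = rng.uniform(0.3, 0.7, size=30)
        a = equidistant_split(w, ratio=4, offset="random", seed=3)
        b = equidistant_split(w, ratio=4, offset="random", seed=3)
        assert np.array_equal(a.validation_idx, b.validation_idx)
        assert 0 <= a.offset <= 4

    def test_validation_interleaves_calibration(self, rng):
        """Each complete sorted block contributes exactly one validation sample,
        so every validation value lies within the span of its source block."""
        w = rng.uniform(0.32, 0.75, size=90)
        s = equidistant_split(w, ratio=4, offset=2)
        order = np.argsort(w, kind="stable")
        sorted_w = w[order]
        val_set = set(s.validation_idx)
        for b in range(90 // 5):
            block = order[b * 5 : (b + 1) * 5]
            picked = [i for i in block if i in val_set]
            assert len(picked) == 1
            assert sorted_w[b * 5] <= w[picked[0]] <= sorted_w[b * 5 + 4]

    @given(n=st.integers(6, 120), offset=st.integers(0, 4), seed=st.integers(0, 1000))
    @settings(max_examples=60, derandomize=True)
    def test_partition_property(self, n, offset, seed):
        w = np.random.default_rng(seed).uniform(0.3, 0.8, size=n)
        s = equidistant_split(w, ratio=4, offset=offset)
        assert len(s.validation_idx) == n // 5
        # disjointness/coverage enforced by the SplitResult constructor
        assert len(set(s.calibration_idx) | set(s.validation_idx)) == n


class TestRandomSplit:
    def test_seeded_reproducibility(self):
        a = random_split(90, n_val=18, seed=11)
        b = random_split(90, n_val=18, seed=11)
        assert np.array_equal(a.validation_idx, b.validation_idx)
        assert len(a.validation_idx) == 18 and len(a.calibration_idx) == 72

    def test_singleton_calibration_warns(self):
        with pytest.warns(UserWarning, match="single sample"):
            random_split(5, n_val=4, seed=0)

    @pytest.mark.parametrize("n_val", [0, 90, 95])
    def test_bad_sizes_rejected(self, n_val):
        with pytest.raises(ValueError):
            random_split(90, n_val=n_val, seed=0)

    def test_uniform_inclusion_frequency(self):
        """Monte-Carlo: each sample's validation frequency approximates
        n_val / n = 0.2."""
        counts = np.zeros(90)
        n_seeds = 1000
        for seed in range(n_seeds):
            counts[random_split(90, n_val=18, seed=seed).validation_idx] += 1
        freq = counts / n_seeds
        assert np.all(np.abs(freq - 0.2) < 0.05)


class TestSummary:
    def _summary_row(self, values):
        w = np.asarray(values)
        n = w.size
        s = random_split(n, n_val=max(1, n // 5), seed=0)
        return summarize_split(s, w)

    def test_cv_is_sd_over_mean(self, rng):
        w = rng.uniform(0.32, 0.75, size=90)
        summary = self._summary_row(w)
        for row in summary.index:
            assert summary.loc[row, "cv"] == pytest.approx(
                summary.loc[row, "std_dev"] / summary.loc[row, "mean"]
            )
            assert summary.loc[row, "min"] <= summary.loc[row, "mean"] <= summary.loc[row, "max"]
        assert summary.loc["Calibration", "n"] + summary.loc["Validation", "n"] == 90

    @pytest.mark.parametrize(
        "mean, sd, expected_cv_pct",
        [(0.525, 0.087, 16.6), (0.527, 0.093, 17.6), (0.526, 0.086, 16.3)],
    )
    def test_printed_cv_consistency(self, mean, sd, expected_cv_pct):
        """CV recomputed from a table's printed mean and SD matches its printed
        percent value at 1 d.p."""
        assert round(100 * sd / mean, 1) == expected_cv_pct

    def test_constant_subset_has_zero_spread(self):
        summary = self._summary_row(np.full(10, 0.5))
        assert summary.loc["Validation", "std_dev"] == 0.0
        assert summary.loc["Validation", "cv"] == 0.0

    def test_percent_rendering(self, rng):
        w = rng.uniform(0.32, 0.75, size=90)
        table = format_summary(self._summary_row(w))
        assert list(table.columns) == ["N", "Max (%)", "Min (%)", "Mean (%)", "Std Dev", "CV (%)"]
        assert 30 < table.loc["Total", "Mean (%)"] < 80


def test_equidistant_balances_better_than_random():
    """Across many synthetic campaigns the calibration/validation mean gap is
    smaller under systematic response-ordered sampling — the polarization
    random hold-outs suffer from."""
    gaps = {"equidistant": [], "random": []}
    for seed in range(500):
        w = aq.generate_water_contents(aq.SpectralSimConfig(), np.random.default_rng(seed))
        for method, split in (
            ("equidistant", equidistant_split(w, ratio=4)),
            ("random", random_split(90, n_val=18, seed=seed)),
        ):
            gaps[method].append(
                abs(w[split.calibration_idx].mean() - w[split.validation_idx].mean())
            )
    assert np.mean(gaps["equidistant"]) < np.mean(gaps["random"])
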