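"""Ratio-trace computation, peak quantification, and null-based calls."""

import numpy as np
import pytest

from nemoresponse.calcium import (
    CalciumTrace,
    NullModel,
    RatioTrace,
    categorize_response,
    classify_cohort,
    cohort_mean_sem,
    compute_ratio_trace,
    default_response_window,
    fit_air_null,
    order_for_heatmap,
    peak_amplitudes,
)
from nemoresponse.errors import DataError, DegenerateNullWarning, InvalidArgumentError
from nemoresponse.synthetic import CalciumGroundTruth, simulate_calcium_cohort, simulate_calcium_trace


def make_trace(protocol, donor, acceptor, animal_id="a0", group="g"):
    t = protocol.times()
    donor = np.broadcast_to(np.asarray(donor, dtype=float), t.shape).copy()
    acceptor = np.broadcast_to(np.asarray(acceptor, dtype=float), t.shape).copy()
    return CalciumTrace(animal_id, "sim", group, t, donor, acceptor, protocol)


def make_ratio(protocol, dr_pct, animal_id="a0", group="g"):
    t = protocol.times()
    dr = np.broadcast_to(np.asarray(dr_pct, dtype=float), t.shape).copy()
    r0 = 2.0
    return RatioTrace(animal_id, "sim", group, t, r0 * (1 + dr / 100), r0, dr, protocol)


class TestComputeRatioTrace:
    def test_constant_channels_zero_dr(self, imaging_protocol):
        rt = compute_ratio_trace(make_trace(imaging_protocol, 1.0, 2.0))
        assert rt.r0 == pytest.approx(2.0)
        assert np.allclose(rt.r, 2.0)
        assert np.allclose(rt.dr_pct, 0.0)

    def test_common_gain_cancels(self, imaging_protocol, rng):
        donor = 100 * (1 + 0.01 * rng.standard_normal(imaging_protocol.n_frames))
        acceptor = 210 * (1 + 0.01 * rng.standard_normal(imaging_protocol.n_frames))
        a = compute_ratio_trace(make_trace(imaging_protocol, donor, acceptor))
        b = compute_ratio_trace(make_trace(imaging_protocol, 7 * donor, 7 * acceptor))
        assert np.allclose(a.dr_pct, b.dr_pct)

    def test_simulated_excitatory_peak(self, imaging_protocol):
        tr = simulate_calcium_trace(
            imaging_protocol, CalciumGroundTruth("excitatory", 20.0), noise_sd=0, seed=0
        )
        rt = compute_ratio_trace(tr)
        mx, _ = peak_amplitudes(rt)
        assert mx == pytest.approx(20.0, rel=0.05)

    def test_window_overlapping_pulse_rejected(self, imaging_protocol):
        with pytest.raises(InvalidArgumentError):
            compute_ratio_trace(make_trace(imaging_protocol, 1.0, 2.0), baseline_window=(10, 30))

    def test_window_outside_recording_rejected(self, imaging_protocol):
        with pytest.raises(InvalidArgumentError):
            compute_ratio_trace(make_trace(imaging_protocol, 1.0, 2.0), baseline_window=(-5, 10))

    def test_nonpositive_channel_rejected(self, imaging_protocol):
        donor = np.ones(imaging_protocol.n_frames)
        donor[5] = 0.0
        with pytest.raises(DataError):
            make_trace(imaging_protocol, donor, 2.0)


class TestPeakAmplitudes:
    def test_flat_trace(self, imaging_protocol):
        assert peak_amplitudes(make_ratio(imaging_protocol, 0.0)) == (0.0, 0.0)

    def test_direct_extrema(self, imaging_protocol):
        dr = np.zeros(imaging_protocol.n_frames)
        # place values inside the response window [20, 110)
        idx = np.searchsorted(imaging_protocol.times(), [30, 40, 50, 60])
        dr[idx] = [0, 5, -3, 1]
        rt = make_ratio(imaging_protocol, dr)
        assert peak_amplitudes(rt) == (5.0, -3.0)

    def test_half_open_excludes_end_frame(self, imaging_protocol):
        dr = np.zeros(imaging_protocol.n_frames)
        t = imaging_protocol.times()
        dr[t == 50.0] = 99.0
        rt = make_ratio(imaging_protocol, dr)
        mx, _ = peak_amplitudes(rt, response_window=(20.0, 50.0))
        assert mx == 0.0  # frame at end_s is excluded
        mx2, _ = peak_amplitudes(rt, response_window=(50.0, 60.0))
        assert mx2 == 99.0  # frame at start_s is included

    def test_empty_window_rejected(self, imaging_protocol):
        with pytest.raises(InvalidArgumentError):
            peak_amplitudes(make_ratio(imaging_protocol, 0.0), response_window=(20.0, 20.0))


class TestFitAirNull:
    def test_two_point_sample_sd(self, imaging_protocol):
        # extremum statistics {+1, -1}: sample SD = sqrt(2)
        a = make_ratio(imaging_protocol, 0.0, "a")
        b = make_ratio(imaging_protocol, 0.0, "b")
        t = imaging_protocol.times()
        a.dr_pct[np.searchsorted(t, 40.0)] = 1.0
        b.dr_pct[np.searchsorted(t, 40.0)] = -1.0
        null = fit_air_null([a, b], statistic="extremum")
        assert null.sd == pytest.approx(np.sqrt(2))
        assert null.n_controls == 2

    def test_identical_traces_degenerate_warning(self, imaging_protocol):
        traces = [make_ratio(imaging_protocol, 0.0, f"a{i}") for i in range(3)]
        with pytest.warns(DegenerateNullWarning):
            null = fit_air_null(traces)
        assert null.sd == 0.0

    def test_fewer_than_two_rejected(self, imaging_protocol):
        with pytest.raises(InvalidArgumentError):
            fit_air_null([make_ratio(imaging_protocol, 0.0)])

    def test_sd_matches_monte_carlo_oracle(self, imaging_protocol, rng):
        """SD of the fitted null approaches the extremum-statistic SD."""
        window = default_response_window(imaging_protocol)
        t = imaging_protocol.times()
        n_frames = imaging_protocol.n_frames
        mask = (t >= window[0]) & (t < window[1])

        # vectorized Monte-Carlo of the signed window extremum of iid noise
        g = np.random.default_rng(42)
        noise = 1.5 * g.standard_normal((20_000, int(mask.sum())))
        draws = np.take_along_axis(
            noise, np.argmax(np.abs(noise), axis=1)[:, None], axis=1
        ).ravel()
        oracle_sd = np.std(draws, ddof=1)
        traces = []
        for i in range(10_000):
            dr = 1.5 * rng.standard_normal(n_frames)
            traces.append(
                RatioTrace(f"a{i}", "sim", "air", t, 2 * (1 + dr / 100), 2.0, dr, imaging_protocol)
            )
        null = fit_air_null(traces, statistic="extremum")
        assert null.sd == pytest.approx(oracle_sd, rel=0.02)


class TestCategorize:
    NULL = NullModel("extremum", 2.0, 10, (20.0, 110.0))

    @pytest.mark.parametrize("mx,mn,expected", [
        (10, -1, "excitatory"),   # 10 > 3*2
        (1, -1, "silent"),        # inside threshold
        (2, -9, "inhibitory"),    # 9 > 6 and 9 > 2
        (7, -7, "excitatory"),    # tie above threshold -> excitatory
        (6, -1, "silent"),        # boundary: not strictly greater
    ])
    def test_rule(self, mx, mn, expected):
        assert categorize_response((mx, mn), self.NULL, k=3) == expected

    def test_monotone_in_k(self):
        calls = [categorize_response((5.0, -1.0), self.NULL, k=k) for k in (1, 2, 3, 4, 5)]
        nonsilent = [c != "silent" for c in calls]
        assert nonsilent == sorted(nonsilent, reverse=True)

    def test_degenerate_null_everything_nonsilent(self):
        null = NullModel("extremum", 0.0, 5, (20.0, 110.0))
        assert categorize_response((0.001, 0.0), null) == "excitatory"
        assert categorize_response((0.0, 0.0), null) == "silent"

    def test_invalid_k_rejected(self):
        with pytest.raises(InvalidArgumentError):
            categorize_response((1, -1), self.NULL, k=0)


class TestClassifyCohort:
    def test_counting_table(self, imaging_protocol):
        traces, _ = simulate_calcium_cohort(
            imaging_protocol, (10 / 16, 0.0, 6 / 16), n=16, seed=4,
            noise_sd=0.001, amplitude_dist={"kind": "fixed", "value": 25.0},
        )
        air, _ = simulate_calcium_cohort(
            imaging_protocol, (0, 0, 1.0), n=8, seed=5, noise_sd=0.001
        )
        calls, table = classify_cohort(traces, air)
        n_exc = sum(c.response_class == "excitatory" for c in calls)
        row = table[(table["group"] == "sim") & (table["response_class"] == "excitatory")]
        assert int(row["count"].iloc[0]) == n_exc
        assert float(row["pct"].iloc[0]) == pytest.approx(100 * n_exc / 16)
        assert table.groupby("group")["pct"].sum().iloc[0] == pytest.approx(100.0)

    def test_empty_cohort_rejected(self, imaging_protocol):
        air, _ = simulate_calcium_cohort(imaging_protocol, (0, 0, 1.0), n=4, seed=0)
        with pytest.raises(InvalidArgumentError):
            classify_cohort([], air)


class TestCohortMeanSem:
    def test_identical_traces(self, imaging_protocol):
        traces = [make_ratio(imaging_protocol, 5.0, f"a{i}") for i in range(4)]
        df = cohort_mean_sem(traces)
        assert np.allclose(df["mean_pct"], 5.0)
        assert np.all(df["sem_pct"] == 0.0)

    def test_two_point_sem(self, imaging_protocol):
        a = make_ratio(imaging_protocol, 0.0, "a")
        b = make_ratio(imaging_protocol, 2.0, "b")
        df = cohort_mean_sem([a, b])
        assert np.allclose(df["mean_pct"], 1.0)
        assert np.allclose(df["sem_pct"], 1.0)  # SD sqrt(2), / sqrt(2)

    def test_mean_trace_covers_noise_free_kernel(self, imaging_protocol):
        """Across repetitions, ~99% of frames have |mean - kernel| <= 3 SEM."""
        from nemoresponse.synthetic import (
            CalciumGroundTruth,
            response_kernel,
            simulate_calcium_trace,
        )

        truth = CalciumGroundTruth("excitatory", 20.0)
        kernel_pct = 100 * response_kernel(imaging_protocol.times(), truth, imaging_protocol)
        inside = []
        for rep in range(30):
            traces = [
                compute_ratio_trace(
                    simulate_calcium_trace(
                        imaging_protocol, truth, noise_sd=0.01, seed=1000 * rep + i
                    )
                )
                for i in range(10)
            ]
            df = cohort_mean_sem(traces)
            ok = np.abs(df["mean_pct"] - kernel_pct) <= 3 * np.maximum(df["sem_pct"], 1e-12)
            inside.append(np.mean(ok))
        assert np.mean(inside) >= 0.98

    def test_mismatched_grids_rejected(self, imaging_protocol, behavior_protocol):
        a = make_ratio(imaging_protocol, 0.0)
        b = make_ratio(behavior_protocol, 0.0)
        with pytest.raises(InvalidArgumentError):
            cohort_mean_sem([a, b])


class TestHeatmapOrdering:
    def test_distinct_animal_at_an_end(self, imaging_protocol, rng):
        base = rng.normal(0, 0.1, imaging_protocol.n_frames)
        traces = [make_ratio(imaging_protocol, base + rng.normal(0, 0.01, base.size), f"a{i}")
                  for i in range(3)]
        traces.append(make_ratio(imaging_protocol, base + 50.0, "outlier"))
        order = order_for_heatmap(traces)
        assert order[0] == 3 or order[-1] == 3

    def test_two_traces_identity_order(self, imaging_protocol):
        traces = [make_ratio(imaging_protocol, float(i), f"a{i}") for i in range(2)]
        assert list(order_for_heatmap(traces)) == [0, 1]

    def test_adjacency_invariant_under_permutation(self, imaging_protocol, rng):
        # three well-separated clusters; adjacency structure must survive
        # relabeling of the input order (up to reversal)
        traces = []
        for c, level in enumerate((0.0, 30.0, 60.0)):
            for i in range(3):
                traces.append(
                    make_ratio(imaging_protocol,
                               level + rng.normal(0, 0.1, imaging_protocol.n_frames),
                               f"c{c}i{i}")
                )
        order1 = order_for_heatmap(traces)
        perm = rng.permutation(len(traces))
        traces2 = [traces[i] for i in perm]
        order2 = order_for_heatmap(traces2)
        ids1 = [traces[i].animal_id for i in order1]
        ids2 = [traces2[i].animal_id for i in order2]
        pairs1 = {frozenset(p) for p in zip(ids1, ids1[1:])}
        clusters1 = ["".join(sorted(i[1] for i in ids1[j:j+3])) for j in (0, 3, 6)]
        clusters2 = ["".join(sorted(i[1] for i in ids2[j:j+3])) for j in (0, 3, 6)]
        # cluster blocks are contiguous in both orderings
        assert sorted(clusters1) == sorted(clusters2)

    def test_nan_rejected(self, imaging_protocol):
        a = make_ratio(imaging_protocol, 0.0, "a")
        b = make_ratio(imaging_protocol, 0.0, "b")
        c = make_ratio(imaging_protocol, 0.0, "c")
        c.dr_pct[3] = np.nan
        with pytest.raises(DataError):
            order_for_heatmap([a, b, c])
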