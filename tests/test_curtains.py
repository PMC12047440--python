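"""Curtain event statistics: per-DNA counts, colocalization, position and
sequence tracks, survival analysis and kymograms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rnpq import curtains
from rnpq.curtains import (
    GenomeTrack,
    at_content_track,
    build_kymogram,
    colocalization_fraction,
    events_per_dna,
    find_motif_sites,
    kaplan_meier,
    mean_event_amplitude,
    normalize_per_rna,
    position_enrichment_test,
    position_histogram,
    reverse_complement,
    survival_at,
    weighted_average,
)
from rnpq.simulate import gen_curtain_events


def _table(rows):
    defaults = dict(experiment_id=0, fov_id=0, dna_id=0, event_id=0, position_kbp=1.0,
                    t_start_s=0.0, t_end_s=10.0, censored=False, channel="green",
                    amplitude=100.0, partner_event_id=-1)
    recs = []
    for i, r in enumerate(rows):
        rec = dict(defaults, event_id=i)
        rec.update(r)
        recs.append(rec)
    return pd.DataFrame(recs)


class TestEventsPerDna:
    def test_single_experiment_arithmetic(self):
        table = _table([{} for _ in range(30)])
        counts = pd.DataFrame({"experiment_id": [0], "fov_id": [0], "n_dna": [10]})
        per_exp, mean, sem = events_per_dna(table, counts)
        assert mean == 3.0 and sem == 0.0

    def test_mean_and_sem_across_experiments(self):
        rows = ([{"experiment_id": 0}] * 2 + [{"experiment_id": 1}] * 3
                + [{"experiment_id": 2}] * 4)
        counts = pd.DataFrame({"experiment_id": [0, 1, 2], "fov_id": 0, "n_dna": 1})
        _, mean, sem = events_per_dna(_table(rows), counts)
        assert mean == pytest.approx(3.0)
        assert sem == pytest.approx(0.5774, abs=1e-3)

    def test_zero_events_experiment(self):
        table = pd.DataFrame({"experiment_id": pd.Series(dtype=int),
                              "fov_id": pd.Series(dtype=int)})
        counts = pd.DataFrame({"experiment_id": [0], "fov_id": [0], "n_dna": [5]})
        _, mean, sem = events_per_dna(table, counts)
        assert mean == 0.0 and sem == 0.0

    def test_missing_fov_counts_rejected(self):
        table = _table([{"fov_id": 1}])
        counts = pd.DataFrame({"experiment_id": [0], "fov_id": [0], "n_dna": [5]})
        with pytest.raises(ValueError, match="missing dna_counts"):
            events_per_dna(table, counts)

    def test_invariant_to_fov_split(self):
        whole = _table([{} for _ in range(12)])
        counts_whole = pd.DataFrame({"experiment_id": [0], "fov_id": [0], "n_dna": [6]})
        split = whole.copy()
        split.loc[6:, "fov_id"] = 1
        counts_split = pd.DataFrame({"experiment_id": [0, 0], "fov_id": [0, 1],
                                     "n_dna": [3, 3]})
        assert events_per_dna(whole, counts_whole)[1] == events_per_dna(split, counts_split)[1]


class TestNormalizationAndAveraging:
    def test_per_rna_division(self):
        assert normalize_per_rna(3.0, 0.03) == pytest.approx(100.0)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            normalize_per_rna(3.0, 0.0)

    def test_equal_weights_is_plain_mean(self):
        assert weighted_average([1.0, 2.0, 6.0], [2, 2, 2]) == pytest.approx(3.0)

    def test_hand_weighted_example(self):
        assert weighted_average([10.0, 2.0], [1, 3]) == pytest.approx(4.0)


class TestColocalization:
    def test_perfect_duplication_gives_unity(self):
        rows = []
        for i in range(10):
            rows.append({"dna_id": i, "position_kbp": float(i), "channel": "green"})
            rows.append({"dna_id": i, "position_kbp": float(i), "channel": "red"})
        frac, _ = colocalization_fraction(_table(rows))
        assert frac == 1.0

    def test_disjoint_dna_molecules_give_zero(self):
        rows = [{"dna_id": i, "channel": "green"} for i in range(5)]
        rows += [{"dna_id": 100 + i, "channel": "red"} for i in range(5)]
        frac, _ = colocalization_fraction(_table(rows))
        assert frac == 0.0

    def test_symmetric_under_channel_swap(self):
        rng = np.random.default_rng(0)
        rows = [{"dna_id": int(rng.integers(5)), "position_kbp": float(rng.uniform(0, 10)),
                 "channel": rng.choice(["green", "red"])} for _ in range(60)]
        table = _table(rows)
        swapped = table.assign(channel=table["channel"].map({"green": "red", "red": "green"}))
        assert colocalization_fraction(table)[0] == colocalization_fraction(swapped)[0]

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            colocalization_fraction(_table([{}, {}]))


class TestPositionHistogram:
    def test_all_events_in_first_bin(self):
        hist = position_histogram(_table([{"position_kbp": 1.0} for _ in range(7)]))
        assert hist.counts[0] == 7 and hist.counts[1:].sum() == 0

    def test_boundary_goes_to_upper_bin(self):
        hist = position_histogram(np.array([2.0]))
        assert hist.counts[1] == 1

    def test_structure_and_conservation(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 50, size=1000)
        hist = position_histogram(pos)
        assert hist.bin_edges_kbp.size == 25
        assert np.allclose(np.diff(hist.bin_edges_kbp), 2.0)
        assert hist.counts.sum() + hist.n_out_of_range == 1000

    def test_agrees_with_brute_force_binning(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 48, size=500)
        hist = position_histogram(pos)
        brute = np.zeros(24, dtype=int)
        for p in pos:
            brute[int(p // 2)] += 1
        assert np.array_equal(hist.counts, brute)

    def test_uniform_events_nearly_flat(self):
        rng = np.random.default_rng(3)
        hist = position_histogram(rng.uniform(0, 48, size=100000))
        assert hist.counts.max() / hist.counts.min() < 1.2


class TestMotifScan:
    def test_overlapping_forward_hits(self):
        assert find_motif_sites("TTTTTAATTTTTAA", "TTTTTAA", "forward") == [(1, "+"), (8, "+")]

    def test_reverse_complement_hit(self):
        assert find_motif_sites("TTAAAAA", "TTTTTAA", "both") == [(1, "-")]

    def test_forward_policy_ignores_reverse(self):
        assert find_motif_sites("TTAAAAA", "TTTTTAA", "forward") == []

    def test_palindromic_motif_not_double_counted(self):
        assert find_motif_sites("AATT", "AATT", "both") == [(1, "+")]

    def test_agrees_with_naive_scan_on_random_sequence(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        motif = "TTTAA"
        rc = reverse_complement(motif)
        naive = sorted(
            [(i + 1, "+") for i in range(len(seq) - len(motif) + 1) if seq[i:i + 5] == motif]
            + [(i + 1, "-") for i in range(len(seq) - len(rc) + 1) if seq[i:i + 5] == rc])
        assert find_motif_sites(seq, motif, "both") == naive

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            find_motif_sites("ACGTN", "TTTTTAA")
        with pytest.raises(ValueError):
            find_motif_sites("ACGT", "TTN")


class TestAtContent:
    def test_all_at_sequence(self):
        track = at_content_track("A" * 100, window_bp=10, step_bp=10)
        assert np.allclose(track["at_fraction"], 1.0)

    def test_balanced_window(self):
        track = at_content_track("ATGC", window_bp=4)
        assert track["at_fraction"].tolist() == [0.5]

    def test_alternating_blocks(self):
        seq = ("AT" * 50 + "GC" * 50) * 3
        track = at_content_track(seq, window_bp=100, step_bp=100)
        assert track["at_fraction"].tolist() == [1.0, 0.0] * 3

    def test_agrees_with_naive_windows(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        track = at_content_track(seq, window_bp=150, step_bp=70)
        for _, row in track.iterrows():
            start = int(row["start_bp"]) - 1
            window = seq[start:start + 150]
            naive = sum(c in "AT" for c in window) / 150
            assert row["at_fraction"] == pytest.approx(naive, abs=1e-12)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            at_content_track("ACGT", window_bp=0)


class TestEnrichmentTest:
    def test_extreme_positions_reach_minimum_p(self, small_track):
        best = small_track.at_content.nlargest(1, "at_fraction")["center_bp"].iloc[0]
        positions = np.full(50, best / 1000.0)
        _, p = position_enrichment_test(positions, small_track, n_permutations=500, seed=0)
        assert p == pytest.approx(1 / 501)

    def test_null_positions_give_uniform_p(self, small_track):
        from scipy.stats import kstest

        rng = np.random.default_rng(6)
        ps = []
        for i in range(200):
            pos = rng.uniform(0, small_track.length_bp / 1000.0, size=30)
            _, p = position_enrichment_test(pos, small_track, n_permutations=199, seed=i)
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_detects_at_weighted_binding(self):
        # genome with genuine A/T-content structure (alternating rich/poor
        # blocks, as on the lambda substrate); base-level weighting only
        # shifts window scores when windows actually differ
        rng = np.random.default_rng(12)
        blocks = []
        for k in range(20):
            p_at = 0.75 if k % 2 == 0 else 0.25
            blocks.append("".join(rng.choice(list("ATGC"), size=500,
                                             p=[p_at / 2, p_at / 2, (1 - p_at) / 2, (1 - p_at) / 2])))
        track = GenomeTrack("".join(blocks), at_window_bp=200, at_step_bp=100)
        table, _ = gen_curtain_events(track, n_dna=25, events_per_dna_mean=20.0,
                                      dwell_mean_s=10.0, movie_length_s=100.0,
                                      position_bias="at_weighted", bias_weight=3.0, seed=7)
        _, p = position_enrichment_test(table["position_kbp"].to_numpy()[:500],
                                        track, n_permutations=999, seed=1)
        assert p < 0.01

    def test_empty_positions_rejected(self, small_track):
        with pytest.raises(ValueError):
            position_enrichment_test([], small_track)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        curve = kaplan_meier([1.0, 2.0, 3.0], [False, True, False], n_bootstrap=100, seed=0)
        assert survival_at(curve, 0.0) == 1.0
        assert survival_at(curve, 1.0) == pytest.approx(2 / 3)
        assert survival_at(curve, 2.0) == pytest.approx(2 / 3)
        assert survival_at(curve, 3.0) == pytest.approx(0.0)

    @given(st.lists(st.floats(min_value=0.1, max_value=100), min_size=3, max_size=30))
    def test_no_censoring_equals_empirical_survival(self, lifetimes):
        lifetimes = np.round(np.asarray(lifetimes), 3)
        curve = kaplan_meier(lifetimes, np.zeros(len(lifetimes), bool),
                             n_bootstrap=100, seed=0)
        for t in np.unique(lifetimes):
            assert survival_at(curve, t) == pytest.approx(np.mean(lifetimes > t), abs=1e-12)

    def test_agrees_with_lifelines_under_censoring(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(8)
        life = rng.exponential(750.0, 120)
        censored = life > 600.0
        life = np.minimum(life, 600.0)
        curve = kaplan_meier(life, censored, n_bootstrap=100, seed=0)
        km = KaplanMeierFitter().fit(life, event_observed=~censored)
        for t in (100.0, 300.0, 500.0):
            assert survival_at(curve, t) == pytest.approx(
                float(km.predict(t)), abs=1e-10)

    def test_bootstrap_band_contains_point_estimate(self):
        rng = np.random.default_rng(9)
        life = rng.exponential(100.0, 80)
        curve = kaplan_meier(life, np.zeros(80, bool), n_bootstrap=200, seed=1)
        assert np.all(curve.ci_lower <= curve.survival + 1e-12)
        assert np.all(curve.survival <= curve.ci_upper + 1e-12)

    def test_exponential_truth_within_band(self):
        rng = np.random.default_rng(10)
        life = rng.exponential(750.0, 300)
        censored = life > 600.0
        life = np.minimum(life, 600.0)
        curve = kaplan_meier(life, censored, n_bootstrap=500, seed=2)
        idx = np.searchsorted(curve.time_s, 300.0, side="right") - 1
        truth = np.exp(-300.0 / 750.0)
        assert curve.ci_lower[idx] <= truth <= curve.ci_upper[idx]

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([1.0, 2.0], [True, True], n_bootstrap=100)


class TestAmplitudes:
    def test_constant_amplitude(self):
        per_event, summary = mean_event_amplitude(_table([{"amplitude": 100.0}] * 5))
        assert np.allclose(per_event, 100.0)
        assert summary["mean"].iloc[0] == 100.0

    def test_condition_ratio_recovered(self, small_track):
        tables = []
        for cond, amp in (("lo", 100.0), ("hi", 200.0)):
            t, _ = gen_curtain_events(small_track, n_dna=100, events_per_dna_mean=5.0,
                                      dwell_mean_s=10.0, movie_length_s=100.0,
                                      amplitude=(amp, 10.0), seed=11)
            t = t.assign(condition=cond, event_id=t["event_id"].astype(str) + cond)
            tables.append(t)
        _, summary = mean_event_amplitude(pd.concat(tables), condition_col="condition")
        ratio = summary.loc["hi", "mean"] / summary.loc["lo", "mean"]
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_single_frame_event(self):
        frames = pd.DataFrame({"event_id": [0], "amplitude": [42.0]})
        per_event, _ = mean_event_amplitude(frames)
        assert per_event.iloc[0] == 42.0


class TestKymogram:
    def test_static_event_is_constant_stripe(self):
        traces = pd.DataFrame({"frame": range(10), "position_kbp": 10.0, "intensity": 5.0})
        kymo, missing = build_kymogram(traces, n_frames=10, n_position_bins=48)
        row = int(10.0 / 48.5 * 48)
        assert np.allclose(kymo[row], 5.0)
        assert kymo.sum() == pytest.approx(50.0)
        assert missing == []

    def test_event_appearing_mid_movie(self):
        traces = pd.DataFrame({"frame": range(4, 10), "position_kbp": 10.0, "intensity": 1.0})
        kymo, missing = build_kymogram(traces, n_frames=10, n_position_bins=48)
        row = int(10.0 / 48.5 * 48)
        assert np.allclose(kymo[row, 4:], 1.0) and np.allclose(kymo[row, :4], 0.0)
        assert missing == [0, 1, 2, 3]

    def test_two_events_two_stripes(self):
        traces = pd.concat([
            pd.DataFrame({"frame": range(10), "position_kbp": 5.0, "intensity": 1.0}),
            pd.DataFrame({"frame": range(10), "position_kbp": 40.0, "intensity": 2.0})])
        kymo, _ = build_kymogram(traces, n_frames=10, n_position_bins=48)
        occupied = np.flatnonzero(kymo.sum(axis=1))
        assert occupied.size == 2


class TestGenomeTrack:
    def test_annotations_consistent(self, small_track):
        for start, strand in small_track.motif_sites:
            window = small_track.sequence[start - 1:start - 1 + len(small_track.motif)]
            expected = small_track.motif if strand == "+" else reverse_complement(small_track.motif)
            assert window == expected
        assert small_track.at_content["at_fraction"].between(0, 1).all()

    def test_invalid_sequence_rejected(self):
        with pytest.raises(ValueError):
            GenomeTrack("ACGTX")
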