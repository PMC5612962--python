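"""Rule-based scoring, IS assignment, state/transition statistics and the
behavioural-episode detector (checked against a brute-force span oracle)."""

import numpy as np
import pandas as pd
import pytest

import spindleca as sc
from spindleca.core import ValidationError
from spindleca.scoring import _high

from conftest import score_pipeline


def make_bp(swa, theta, sigma):
    """Minimal scoring-band table: swa/sigma on EEG-FF, theta on EEG-FP."""
    n = len(swa)
    cols = {
        ("EEG-FF", "swa"): np.asarray(swa, float),
        ("EEG-FF", "theta"): np.zeros(n),
        ("EEG-FF", "sigma"): np.asarray(sigma, float),
        ("EEG-FP", "swa"): np.asarray(swa, float),
        ("EEG-FP", "theta"): np.asarray(theta, float),
        ("EEG-FP", "sigma"): np.asarray(sigma, float),
    }
    table = pd.DataFrame(cols)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["channel", "band"])
    return sc.BandPowerTable(table=table, scheme=sc.BandScheme(sc.SCORING_BANDS))


class TestScoreEpochs:
    def test_zero_emg_max_swa_scores_all_nrem(self):
        bp = make_bp(swa=np.full(20, 5.0), theta=np.zeros(20), sigma=np.zeros(20))
        h = sc.score_epochs(bp, np.zeros(20))
        assert (h.labels == "NREM").all()

    def test_high_emg_high_parietal_theta_scores_aw(self):
        rng = np.random.default_rng(0)
        n = 100  # 35 active-wake-like epochs, 65 quiet
        hi = np.arange(n) < 35
        theta = np.where(hi, 10.0, 1.0) + rng.uniform(0, 0.1, n)
        emg = np.where(hi, 20.0, 1.0) + rng.uniform(0, 0.1, n)
        bp = make_bp(swa=rng.uniform(0, 0.1, n), theta=theta, sigma=rng.uniform(0, 0.1, n))
        h = sc.score_epochs(bp, emg)
        assert (h.labels[hi] == "AW").all()
        # low-EMG epochs are never active wake
        assert not (h.labels[~hi] == "AW").any()

    def test_misaligned_inputs_rejected(self):
        bp = make_bp(np.ones(10), np.ones(10), np.ones(10))
        with pytest.raises(ValidationError):
            sc.score_epochs(bp, np.ones(9))

    def test_recovers_generator_hypnogram(self, sim_2h, sim_2h_bandpower):
        scored = score_pipeline(
            sim_2h, sim_2h_bandpower["scoring"], sim_2h_bandpower["emg"]
        )
        true = np.where(sim_2h.hypnogram.labels == "IS", "NREM", sim_2h.hypnogram.labels)
        pred = np.where(scored.labels == "IS", "NREM", scored.labels)
        assert (true == pred).mean() >= 0.90

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rem_never_scored_in_high_emg_epochs(self, seed):
        rec = sc.simulate_recording(sc.SimConfig(seed=seed, duration_s=3600))
        emg_idx = rec.eeg.labels.index("EMG")
        emg = (sc.slice_epochs(rec.eeg, 4.0)[:, emg_idx, :] ** 2).mean(axis=1)
        scored = score_pipeline(rec, emg=emg)
        emg_hi = _high(emg, 60.0, ties_high=False)
        assert not np.any((scored.labels == "REM") & emg_hi)

    def test_deterministic_and_channel_order_invariant(self, sim_2h, sim_2h_bandpower):
        bp = sim_2h_bandpower["scoring"]
        emg = sim_2h_bandpower["emg"]
        a = sc.score_epochs(bp, emg)
        b = sc.score_epochs(bp, emg)
        assert (a.labels == b.labels).all()
        # permute column order in the table; lookups are by name
        perm = sc.BandPowerTable(
            table=bp.table[bp.table.columns[::-1]], scheme=bp.scheme
        )
        c = sc.score_epochs(perm, emg)
        assert (a.labels == c.labels).all()


class TestISRule:
    def make_hyp(self, labels):
        return sc.Hypnogram(np.array(labels))

    def test_five_epoch_run_after_nrem_not_is(self):
        labels = ["NREM"] * 5 + ["NREM"] * 5 + ["REM"] * 3
        cand = [False] * 5 + [True] * 5 + [False] * 3
        out = sc.enforce_is_rule(self.make_hyp(labels), cand)
        assert not (out.labels == "IS").any()

    def test_six_epoch_run_after_nrem_is(self):
        labels = ["NREM"] * 5 + ["NREM"] * 6 + ["REM"] * 3
        cand = [False] * 5 + [True] * 6 + [False] * 3
        out = sc.enforce_is_rule(self.make_hyp(labels), cand)
        assert (out.labels[5:11] == "IS").all()
        assert (out.labels[:5] == "NREM").all()

    def test_run_after_rem_not_is(self):
        labels = ["REM"] * 4 + ["QW"] * 8 + ["AW"] * 2
        cand = [False] * 4 + [True] * 8 + [False] * 2
        out = sc.enforce_is_rule(self.make_hyp(labels), cand)
        assert not (out.labels == "IS").any()

    def test_run_at_recording_start_not_is(self):
        labels = ["NREM"] * 10
        cand = [True] * 6 + [False] * 4
        out = sc.enforce_is_rule(self.make_hyp(labels), cand)
        assert not (out.labels == "IS").any()


class TestStateStatistics:
    def test_all_nrem(self):
        h = sc.Hypnogram(np.array(["NREM"] * 100))
        stats = sc.state_statistics(h)
        assert stats.loc["NREM", "percent"] == pytest.approx(100.0)
        assert stats.loc["NREM", "n_bouts"] == 1
        assert stats.loc["NREM", "mean_bout_s"] == pytest.approx(400.0)

    def test_alternating_singles_have_no_bouts(self):
        h = sc.Hypnogram(np.array(["AW", "QW"] * 30))
        stats = sc.state_statistics(h)
        assert stats.loc["AW", "n_bouts"] == 0
        assert stats.loc["QW", "n_bouts"] == 0
        assert np.isnan(stats.loc["AW", "mean_bout_s"])

    def test_crafted_run_lengths_match_brute_force(self):
        # runs: NREM 7, AW 6, NREM 3, QW 10, AW 2
        labels = ["NREM"] * 7 + ["AW"] * 6 + ["NREM"] * 3 + ["QW"] * 10 + ["AW"] * 2
        h = sc.Hypnogram(np.array(labels))
        stats = sc.state_statistics(h)
        # brute-force run-length encoding oracle
        runs = []
        cur, count = labels[0], 0
        for lab in labels:
            if lab == cur:
                count += 1
            else:
                runs.append((cur, count))
                cur, count = lab, 1
        runs.append((cur, count))
        for s in ("NREM", "AW", "QW"):
            lens = [c for lab, c in runs if lab == s and c > 5]
            assert stats.loc[s, "n_bouts"] == len(lens)
            if lens:
                assert stats.loc[s, "mean_bout_s"] == pytest.approx(4 * np.mean(lens))
        assert stats["percent"].sum() == pytest.approx(100.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            sc.state_statistics(sc.Hypnogram(np.array([], dtype="U4")))


class TestTransitionStatistics:
    def test_is_always_to_rem(self):
        labels = (["NREM"] * 6 + ["IS"] * 6 + ["REM"] * 3) * 3
        out = sc.transition_statistics(sc.Hypnogram(np.array(labels)), "IS")
        assert out["REM"] == pytest.approx(100.0)

    def test_hand_counted_distribution(self):
        seq = []
        for nxt in ("NREM", "NREM", "REM", "QW"):
            seq += ["NREM"] * 6 + ["IS"] * 6 + [nxt] * 6
        out = sc.transition_statistics(sc.Hypnogram(np.array(seq)), "IS")
        assert out["NREM"] == pytest.approx(50.0)
        assert out["REM"] == pytest.approx(25.0)
        assert out["QW"] == pytest.approx(25.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_percentages_sum_to_100(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice(["AW", "QW", "NREM", "REM"], size=300)
        out = sc.transition_statistics(sc.Hypnogram(labels), "NREM")
        assert out.sum() == pytest.approx(100.0)

    def test_absent_state_rejected(self):
        with pytest.raises(ValidationError):
            sc.transition_statistics(sc.Hypnogram(np.array(["AW"] * 5)), "IS")


def episodes_oracle(labels, min_epochs=13, max_interruption=0.30):
    """Independent O(n^2) enumeration of the episode rules."""
    pooled = [sc.pool_state(s) for s in labels]
    n = len(labels)
    out = []
    i = 0
    while i < n:
        s = pooled[i]
        if s is None:
            i += 1
            continue
        best = None
        for j in range(i, n):
            if pooled[j] != s:
                continue
            span = labels[i : j + 1]
            bad = sum(1 for lab in span if sc.pool_state(lab) != s)
            if bad / len(span) <= max_interruption:
                best = j
        if best is not None and best - i + 1 >= min_epochs:
            out.append((s, i, best))
            i = best + 1
        else:
            i += 1
    return out


class TestDetectEpisodes:
    def wrap(self, labels):
        return sc.detect_episodes(sc.Hypnogram(np.array(labels)))

    def test_twelve_epoch_run_rejected(self):
        eps = self.wrap(["REM"] * 5 + ["NREM"] * 12 + ["REM"] * 5)
        assert all(e.state != "SWS" for e in eps)

    def test_thirteen_epoch_run_is_shortest_accepted(self):
        # short wake flanks cannot form episodes of their own (< 13)
        for k in range(10, 16):
            eps = self.wrap(["AW"] * 5 + ["NREM"] * k + ["AW"] * 5)
            sws = [e for e in eps if e.state == "SWS"]
            if k < 13:
                assert not sws
            else:
                assert len(sws) == 1
                assert sws[0].duration_s() == k * 4.0
        eps = self.wrap(["AW"] * 5 + ["NREM"] * 13 + ["AW"] * 5)
        sws = [e for e in eps if e.state == "SWS"][0]
        assert sws.duration_s() == pytest.approx(52.0)

    def test_thirty_percent_interruption_boundary(self):
        # 20-epoch span, 6 wake intrusions in the middle = 30% -> accepted
        span = ["NREM"] * 7 + ["AW"] * 6 + ["NREM"] * 7
        eps = self.wrap(["REM"] * 20 + span + ["REM"] * 20)
        sws = [e for e in eps if e.state == "SWS"]
        assert len(sws) == 1 and sws[0].n_epochs == 20
        # 7 intrusions = 35% -> the full span is rejected/shortened
        span = ["NREM"] * 7 + ["AW"] * 7 + ["NREM"] * 6
        eps = self.wrap(["REM"] * 20 + span + ["REM"] * 20)
        sws = [e for e in eps if e.state == "SWS"]
        assert all(e.n_epochs < 20 for e in sws)

    def test_matches_exhaustive_span_oracle_on_random_hypnograms(self):
        rng = np.random.default_rng(0)
        states = np.array(["AW", "QW", "NREM", "IS", "REM"])
        for _ in range(300):
            # run-structured random hypnograms (runs of 1-15 epochs)
            labels = []
            while len(labels) < 60:
                labels += [rng.choice(states)] * int(rng.integers(1, 16))
            labels = labels[:60]
            got = [
                (e.state, e.start_epoch, e.end_epoch)
                for e in sc.detect_episodes(sc.Hypnogram(np.array(labels)))
            ]
            assert got == episodes_oracle(labels), labels

    def test_every_episode_satisfies_printed_rules(self, sim_2h):
        labels = sim_2h.hypnogram.labels
        for e in sc.detect_episodes(sim_2h.hypnogram):
            span = labels[e.start_epoch : e.end_epoch + 1]
            bad = sum(1 for lab in span if sc.pool_state(lab) != e.state)
            assert len(span) >= 13
            assert bad / len(span) <= 0.30
            assert sc.pool_state(span[0]) == e.state
            assert sc.pool_state(span[-1]) == e.state
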