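"""Cue classification, event-locked epoching and light-response extraction."""

import numpy as np
import pytest

import oracles
from conftest import toy_schedule
from pupilmw.epochs import (
    CONTROL,
    EMOTIONAL_NONTRIGGER,
    EXCLUDED,
    MW_TRIGGER,
    classify_cues,
    cue_placement_check,
    epoch_cue_aligned,
    epoch_probe_aligned,
    extract_light_responses,
)
from pupilmw.preprocess import GRID_TIMES, CleanSession
from pupilmw.pupil import PupilGenParams, pupil_kernel
from pupilmw.states import ProbeReport


def report(k, category, spontaneity="not_applicable", trigger="none", word=None):
    return ProbeReport(
        probe_index=k,
        category=category,
        spontaneity=spontaneity,
        trigger_type=trigger,
        trigger_word_id=word,
    )


@pytest.fixture()
def labelled_session():
    sched = toy_schedule(
        n_trials=30,
        cues={2: "neutral", 5: "positive", 10: "negative", 22: "negative", 25: "positive"},
        probes=(8, 20, 28),
    )
    reports = [
        report(0, "mw_spontaneous", "spontaneous", "cue_word", "w005"),
        report(1, "on_task"),
        report(2, "mw_intentional", "deliberate", "cue_word", "w025"),
    ]
    return sched, reports


class TestClassifyCues:
    def test_three_way_labels(self, labelled_session):
        sched, reports = labelled_session
        by_word = {l.word_id: l.label for l in classify_cues(sched, reports)}
        # neutral cue; the next probe reports MW triggered by a *different* word
        assert by_word["w002"] == CONTROL
        # positive cue named as the trigger of a later spontaneous-MW report
        assert by_word["w005"] == MW_TRIGGER
        # negative cue, unnamed, nearest following probe on-task
        assert by_word["w010"] == EMOTIONAL_NONTRIGGER
        # emotional cue preceded (not followed) by an on-task probe
        assert by_word["w022"] == EXCLUDED
        # trigger of an intentional-MW report
        assert by_word["w025"] == EXCLUDED

    def test_labels_partition_cue_occurrences(self, labelled_session):
        sched, reports = labelled_session
        labels = classify_cues(sched, reports)
        assert len(labels) == len(sched.cue_indices)
        assert {l.label for l in labels} <= {
            MW_TRIGGER, EMOTIONAL_NONTRIGGER, CONTROL, EXCLUDED,
        }

    def test_unknown_trigger_word_is_warned_and_ignored(self, labelled_session, caplog):
        sched, _ = labelled_session
        reports = [report(0, "mw_spontaneous", "spontaneous", "cue_word", "w999"),
                   report(1, "on_task"), report(2, "on_task")]
        with caplog.at_level("WARNING"):
            labels = classify_cues(sched, reports)
        assert "w999" in caplog.text
        assert all(l.label != MW_TRIGGER for l in labels)


def make_clean(subject_id, traces, excluded=None):
    traces = np.asarray(traces, dtype=float)
    n = traces.shape[0]
    excl = np.zeros(n, bool) if excluded is None else np.asarray(excluded, bool)
    return CleanSession(subject_id, traces, excl, np.where(excl, 1.0, 0.0))


class TestCueAligned:
    def test_constant_session_gives_zero_summaries(self, labelled_session):
        sched, reports = labelled_session
        clean = make_clean("t01", np.full((30, 40), 4.0))
        labels = classify_cues(sched, reports)
        epochs, summ = epoch_cue_aligned(clean, labels)
        assert len(epochs) == 3  # the three non-excluded cues
        assert np.allclose(summ["value_mm"], 0.0)
        assert sorted(summ["position"].unique()) == [0.0, 1.0, 2.0]

    def test_epoch_dropped_when_following_trial_excluded(self, labelled_session):
        sched, reports = labelled_session
        excl = np.zeros(30, bool)
        excl[7] = True  # trial 2 after the cue on trial 5
        clean = make_clean("t01", np.full((30, 40), 4.0), excl)
        epochs, _ = epoch_cue_aligned(clean, classify_cues(sched, reports))
        assert all(e.reference_id != "w005" for e in epochs)

    def test_baseline_identity(self, labelled_session):
        sched, reports = labelled_session
        rng = np.random.default_rng(0)
        clean = make_clean("t01", rng.normal(4, 0.3, (30, 40)))
        epochs, _ = epoch_cue_aligned(clean, classify_cues(sched, reports))
        for ep in epochs:
            assert abs(ep.corrected[0].mean()) < 1e-10

    def test_programmed_ramp_appears_in_position_summaries(self, labelled_session):
        """A 0.1 mm dilation ramping over the first post-cue trial then held:
        position-2 summary reads +0.1 mm against the cue-trial baseline."""
        sched, reports = labelled_session
        delta = 0.1
        traces = np.full((30, 40), 4.0)
        traces[6] = 4.0 + delta * GRID_TIMES / 2.0  # ramp during trial 1 after w005
        traces[7] = 4.0 + delta
        clean = make_clean("t01", traces)
        _, summ = epoch_cue_aligned(clean, classify_cues(sched, reports))
        s = summ[summ["reference_id"] == "w005"].set_index("position")["value_mm"]
        assert s[0.0] == pytest.approx(0.0, abs=1e-12)
        assert s[1.0] == pytest.approx(0.75 * delta, abs=1e-12)
        assert s[2.0] == pytest.approx(delta, abs=1e-12)


class TestProbeAligned:
    @pytest.fixture()
    def probe_session(self):
        sched = toy_schedule(n_trials=30, probes=(10, 20, 28))
        reports = [
            report(0, "mw_spontaneous", "spontaneous", "own_thoughts"),
            report(1, "on_task"),
            report(2, "mw_intentional", "deliberate"),
        ]
        return sched, reports

    def test_conditions_and_positions(self, probe_session):
        sched, reports = probe_session
        clean = make_clean("t01", np.full((30, 40), 4.0))
        epochs, summ = epoch_probe_aligned(clean, sched, reports)
        assert {e.condition for e in epochs} == {"MW", "OT", "other"}
        assert sorted(summ["position"].unique()) == [1.0, 2.0, 3.0]
        assert np.allclose(summ["value_mm"], 0.0)
        # intentional MW is "other", never MW
        other = [e for e in epochs if e.reference_id == "probe02"]
        assert other[0].condition == "other"

    def test_probe_with_short_history_dropped(self, probe_session):
        sched, reports = probe_session
        excl = np.zeros(30, bool)
        excl[8] = True  # third trial before the first probe
        clean = make_clean("t01", np.full((30, 40), 4.0), excl)
        epochs, _ = epoch_probe_aligned(clean, sched, reports)
        assert all(e.reference_id != "probe00" for e in epochs)

    def test_baseline_is_last_trial_before_probe(self, probe_session):
        sched, reports = probe_session
        rng = np.random.default_rng(1)
        clean = make_clean("t01", rng.normal(4, 0.2, (30, 40)))
        epochs, _ = epoch_probe_aligned(clean, sched, reports)
        for ep in epochs:
            # position 1 (the last trial) is the reference: corrected mean 0
            assert abs(ep.corrected[list(ep.positions).index(1)].mean()) < 1e-10


class TestLightResponses:
    def test_flat_trace_gives_zero_constriction(self):
        sched = toy_schedule(n_trials=12, probes=(5, 10))
        reports = [report(0, "mw_spontaneous", "spontaneous"), report(1, "on_task")]
        clean = make_clean("t01", np.full((12, 40), 4.0))
        out = extract_light_responses(clean, sched, reports)
        assert len(out) == 2
        assert np.allclose(out["constriction_mm"], 0.0)

    def test_cue_on_trial_or_predecessor_excludes_candidate(self):
        sched = toy_schedule(
            n_trials=12, cues={5: "neutral", 9: "positive"}, probes=(5, 10)
        )
        reports = [report(0, "mw_spontaneous", "spontaneous"), report(1, "on_task")]
        clean = make_clean("t01", np.full((12, 40), 4.0))
        out = extract_light_responses(clean, sched, reports)
        # probe 0's trial carries a cue; probe 1's predecessor does
        assert len(out) == 0

    def test_noiseless_bar_constriction_matches_kernel_quadrature(self):
        """The measured constriction equals the analytic kernel response
        pushed through reference implementations of the cleaning chain."""
        amp = 0.3
        params = PupilGenParams(bar_constriction_mm=amp, word_constriction_mm=0.0)
        raw_t = (np.arange(60) + 0.5) / 30.0
        # analytic 30 Hz trace for one mid-session trial: own onset plus the
        # tails of the four preceding trials' responses
        trace30 = 4.0 - amp * sum(
            pupil_kernel(raw_t + 2.0 * k, params) for k in range(5)
        )
        keep = oracles.brute_force_central_mask(trace30, np.ones(60, bool))
        grid = np.interp(GRID_TIMES, raw_t[keep], trace30[keep])
        expected = np.mean(grid[10:20] - np.mean(grid[:5]))

        traces = np.tile(grid, (12, 1))
        sched = toy_schedule(n_trials=12, probes=(5, 10))
        reports = [report(0, "mw_spontaneous", "spontaneous"), report(1, "on_task")]
        out = extract_light_responses(make_clean("t01", traces), sched, reports)
        assert np.allclose(out["constriction_mm"], expected, atol=1e-12)
        # and the pure window-quadrature of the kernel is close by
        pure = -amp * (
            np.mean(pupil_kernel(GRID_TIMES[10:20], params))
            - np.mean(pupil_kernel(GRID_TIMES[:5], params))
        )
        assert expected == pytest.approx(pure, abs=0.05 * amp)

    def test_target_mode_pairs_targets_with_preceding_nontargets(self):
        sched = toy_schedule(n_trials=20, targets=(8, 15))
        clean = make_clean("t01", np.full((20, 40), 4.0))
        out = extract_light_responses(clean, sched, [], mode="target_vs_nontarget")
        assert set(out["group"]) == {"target", "nontarget"}
        assert sorted(out.loc[out.group == "target", "trial_index"]) == [8, 15]
        assert sorted(out.loc[out.group == "nontarget", "trial_index"]) == [7, 14]

    def test_unknown_mode_raises(self):
        sched = toy_schedule(n_trials=5)
        clean = make_clean("t01", np.full((5, 40), 4.0))
        with pytest.raises(ValueError, match="mode"):
            extract_light_responses(clean, sched, [], mode="nope")


class TestCuePlacement:
    def test_hand_counted_toy_fixture(self):
        # probes after trials 10, 20, 30, 40, 50, 58; cues sit on the 4th
        # trial before probes 0, 2 and 4 only
        sched = toy_schedule(
            n_trials=60,
            cues={7: "neutral", 27: "positive", 47: "negative"},
            probes=(10, 20, 30, 40, 50, 58),
        )
        reports = [
            report(0, "mw_spontaneous", "spontaneous"),  # cue at 7  -> hit
            report(1, "mw_spontaneous", "spontaneous"),  # 17: no cue
            report(2, "on_task"),                        # 27 -> hit
            report(3, "on_task"),                        # 37: no cue
            report(4, "task_related"),                   # 47 -> hit
            report(5, "task_related"),                   # 55: no cue
        ]
        out = cue_placement_check([(sched, reports)]).set_index("category")
        assert out.loc["MW", "mean"] == pytest.approx(0.5)
        assert out.loc["OT", "mean"] == pytest.approx(0.5)
        assert out.loc["other", "mean"] == pytest.approx(0.5)

    def test_all_or_nothing_placements(self):
        sched = toy_schedule(n_trials=30, cues={7: "neutral", 17: "positive"},
                             probes=(10, 20))
        reports = [report(0, "on_task"), report(1, "on_task")]
        out = cue_placement_check([(sched, reports)]).set_index("category")
        assert out.loc["OT", "mean"] == pytest.approx(1.0)
        no_cues = toy_schedule(n_trials=30, probes=(10, 20))
        out = cue_placement_check([(no_cues, reports)]).set_index("category")
        assert out.loc["OT", "mean"] == pytest.approx(0.0)
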