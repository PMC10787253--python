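"""One-vs-rest metrics, majority voting, validation schedule, early stopping."""

import math

import numpy as np
import pandas as pd
import pytest

from histotile import (
    EarlyStopState,
    early_stop_update,
    majority_vote,
    slide_prediction_table,
    tile_metrics,
    validation_schedule,
)
from histotile.errors import EarlyStopStateError


def _table(truth, preds, slides=None):
    n = len(truth)
    return pd.DataFrame(
        {
            "slide_id": slides if slides is not None else ["s0"] * n,
            "tile_id": range(n),
            "true_label": truth,
            "predicted_label": preds,
        }
    )


class TestTileMetrics:
    def test_two_class_hand_computed_example(self):
        """truth (A,A,B,B), preds (A,B,B,B): class A has TP=1 FN=1 FP=0 TN=2."""
        report = tile_metrics(_table(list("AABB"), list("ABBB")), ["A", "B"])
        assert report.accuracy == pytest.approx(0.75)
        a = report.per_class["A"]
        assert a.sensitivity == pytest.approx(0.5)
        assert a.specificity == pytest.approx(1.0)
        assert a.precision == pytest.approx(1.0)
        assert a.f1 == pytest.approx(2 / 3)

    def test_perfect_predictions(self):
        report = tile_metrics(_table(list("ABAB"), list("ABAB")), ["A", "B"])
        assert report.accuracy == 1.0
        for m in report.per_class.values():
            assert (m.sensitivity, m.specificity, m.precision, m.f1) == (1, 1, 1, 1)

    def test_class_absent_from_truth_has_nan_sensitivity(self):
        report = tile_metrics(_table(list("AA"), list("AA")), ["A", "B"])
        assert math.isnan(report.per_class["B"].sensitivity)
        # macro mean excludes the undefined entry
        assert report.macro_sensitivity == pytest.approx(1.0)

    def test_prediction_outside_classes_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            tile_metrics(_table(["A"], ["C"]), ["A", "B"])

    def test_confusion_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        labels = list("ABC")
        t = _table(rng.choice(labels, 50).tolist(), rng.choice(labels, 50).tolist())
        report = tile_metrics(t, labels)
        assert report.confusion.to_numpy().sum() == 50

    def test_agrees_with_sklearn_on_random_tables(self):
        """Independent cross-check against scikit-learn's per-class rates."""
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(17)
        for trial in range(10):
            k = int(rng.integers(2, 7))
            labels = [f"c{i}" for i in range(k)]
            n = int(rng.integers(10, 200))
            truth = rng.choice(labels, n).tolist()
            preds = rng.choice(labels, n).tolist()
            report = tile_metrics(_table(truth, preds), labels)
            prec, rec, f1, _ = precision_recall_fscore_support(
                truth, preds, labels=labels, zero_division=np.nan
            )
            for i, c in enumerate(labels):
                m = report.per_class[c]
                for mine, ref in ((m.precision, prec[i]), (m.sensitivity, rec[i])):
                    if math.isnan(ref):
                        assert math.isnan(mine)
                    else:
                        assert mine == pytest.approx(ref)
                # F1 is undefined here (NaN) when either rate is undefined
                # or both are zero; sklearn reports 0 instead — compare
                # only where the conventions coincide
                if not (
                    math.isnan(prec[i])
                    or math.isnan(rec[i])
                    or (prec[i] == 0 and rec[i] == 0)
                ):
                    assert m.f1 == pytest.approx(f1[i])
            assert report.accuracy == pytest.approx(np.mean(np.array(truth) == np.array(preds)))


class TestMajorityVote:
    def test_clear_majority(self):
        votes = majority_vote(_table(list("AAA"), ["A", "A", "B"]))
        v = votes["s0"]
        assert v.label == "A" and v.vote_counts == {"A": 2, "B": 1} and not v.tie_flag

    def test_tie_without_probabilities_lexicographic(self):
        v = majority_vote(_table(list("AA"), ["B", "A"]))["s0"]
        assert v.label == "A" and v.tie_flag

    def test_tie_with_probabilities_highest_sum_wins(self):
        t = _table(list("AA"), ["A", "B"])
        t["p_A"] = [0.6, 0.4]
        t["p_B"] = [0.4, 0.6]
        t.loc[1, ["p_A", "p_B"]] = [0.1, 0.9]
        v = majority_vote(t)["s0"]
        assert v.label == "B" and v.tie_flag  # summed 0.7 vs 1.3

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        slides = [f"s{i % 5}" for i in range(60)]
        t = _table(rng.choice(list("AB"), 60).tolist(), rng.choice(list("AB"), 60).tolist(), slides)
        base = majority_vote(t)
        shuffled = majority_vote(t.sample(frac=1, random_state=1))
        assert {k: v.label for k, v in base.items()} == {
            k: v.label for k, v in shuffled.items()
        }

    def test_matches_exhaustive_counting(self):
        rng = np.random.default_rng(8)
        slides = [f"s{i % 7}" for i in range(140)]
        preds = rng.choice(list("ABC"), 140).tolist()
        t = _table(["A"] * 140, preds, slides)
        votes = majority_vote(t)
        for sid in set(slides):
            sub = [p for s, p in zip(slides, preds) if s == sid]
            counts = {c: sub.count(c) for c in set(sub)}
            best = max(counts.values())
            winners = sorted(c for c, v in counts.items() if v == best)
            assert votes[sid].label == winners[0]
            assert votes[sid].vote_counts == counts
            assert votes[sid].tie_flag == (len(winners) > 1)

    def test_slide_level_report_from_votes(self):
        """Voting then metrics reproduces a hand-computed slide-level report."""
        slides = ["s0"] * 3 + ["s1"] * 3 + ["s2"] * 3
        truth = ["A"] * 3 + ["A"] * 3 + ["B"] * 3
        preds = ["A", "A", "B", "B", "B", "A", "B", "B", "B"]
        slide_table = slide_prediction_table(_table(truth, preds, slides))
        report = tile_metrics(slide_table, ["A", "B"])
        # s0 -> A (correct), s1 -> B (wrong), s2 -> B (correct)
        assert report.accuracy == pytest.approx(2 / 3)
        assert report.per_class["A"].sensitivity == pytest.approx(0.5)
        assert report.per_class["B"].sensitivity == pytest.approx(1.0)


class TestValidationSchedule:
    @pytest.mark.parametrize(
        "steps,k,expected",
        [
            (80, 8, [10, 20, 30, 40, 50, 60, 70, 80]),
            (10, 8, [1, 2, 3, 5, 6, 7, 8, 10]),
            (8, 8, [1, 2, 3, 4, 5, 6, 7, 8]),
        ],
    )
    def test_examples(self, steps, k, expected):
        assert validation_schedule(steps, k) == expected

    def test_strictly_increasing_and_ends_at_epoch(self):
        for steps in (8, 13, 100, 999):
            sched = validation_schedule(steps, 8)
            assert all(b > a for a, b in zip(sched, sched[1:]))
            assert sched[-1] == steps

    def test_k_larger_than_steps_rejected(self):
        with pytest.raises(ValueError):
            validation_schedule(5, 8)


class TestEarlyStopping:
    def _run(self, scores, **kw):
        state = EarlyStopState(**kw)
        history = []
        for s in scores:
            state = early_stop_update(state, s)
            history.append(state)
        return history

    def test_stops_exactly_after_five_flat_scores(self):
        history = self._run([1, 2, 3, 3, 3, 3, 3, 3])
        assert [h.stopped for h in history] == [False] * 7 + [True]
        assert history[-1].non_improving == 5

    def test_strictly_increasing_never_stops(self):
        history = self._run(list(range(20)))
        assert not history[-1].stopped and history[-1].non_improving == 0

    def test_equal_score_counts_as_non_improvement(self):
        history = self._run([1.0, 1.0])
        assert history[-1].non_improving == 1

    def test_min_delta_requires_margin(self):
        history = self._run([1.0, 1.05, 1.2], min_delta=0.1)
        assert history[0].best_score == 1.0
        assert history[1].non_improving == 1  # +0.05 below the margin
        assert history[2].best_score == 1.2

    def test_update_after_stop_is_an_error(self):
        state = EarlyStopState(patience=1)
        state = early_stop_update(state, 1.0)
        state = early_stop_update(state, 0.5)
        assert state.stopped
        with pytest.raises(EarlyStopStateError):
            early_stop_update(state, 2.0)

    def test_fuzzed_sequences_stop_after_exact_patience(self):
        """In any score sequence, stopping happens exactly at the first run of
        `patience` consecutive non-improvements."""
        rng = np.random.default_rng(10)
        for _ in range(30):
            patience = int(rng.integers(1, 7))
            scores = rng.uniform(0, 1, size=40)
            state = EarlyStopState(patience=patience)
            best, run, expected_stop = -math.inf, 0, None
            for i, s in enumerate(scores):
                if s > best:
                    best, run = s, 0
                else:
                    run += 1
                if run == patience:
                    expected_stop = i
                    break
            stopped_at = None
            state = EarlyStopState(patience=patience)
            for i, s in enumerate(scores):
                state = early_stop_update(state, float(s))
                if state.stopped:
                    stopped_at = i
                    break
            assert stopped_at == expected_stop
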