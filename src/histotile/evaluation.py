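"""Tile-level metrics, tile-to-slide majority voting, and early stopping.

A tile classifier is evaluated at two granularities.  At the tile level,
standard one-vs-rest metrics are computed per class (every other class
counts as negative): sensitivity TP/(TP+FN), specificity TN/(TN+FP),
precision TP/(TP+FP), and F1 — the harmonic mean of sensitivity and
precision.  At the slide level, each slide (= patient) receives the most
frequent predicted label among its tiles (majority voting); ties are
broken by the highest summed class probability when probabilities are
available, else by the lexicographically smallest label, and flagged
either way.

Aggregate numbers use macro (unweighted) averaging over classes; a rate
whose denominator is zero (e.g. sensitivity of a class absent from the
truth) is reported as NaN and excluded from the macro mean with a logged
note.

Also here: the intra-epoch validation schedule (validate k times per
epoch, because with very large tile sets a full epoch moves the weights
too far for end-of-epoch early stopping to react) and the early-stopping
state machine that halts after ``patience`` consecutive validation checks
without improvement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EarlyStopStateError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("slide_id", "tile_id", "true_label", "predicted_label")


def validate_prediction_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a prediction table's schema and probability normalisation.

    Expected columns: slide_id, tile_id, true_label, predicted_label and
    optionally one ``p_<class>`` column per class (row-normalised to 1).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"prediction table missing columns: {missing}")
    prob_cols = [c for c in table.columns if c.startswith("p_")]
    if prob_cols:
        sums = table[prob_cols].sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-6
        if bad.any():
            raise ValueError(
                f"per-row probabilities must sum to 1; first bad row index "
                f"{table.index[bad][0]} sums to {sums[bad].iloc[0]:.8f}"
            )
    return table


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest rates for a single class (NaN where undefined)."""

    sensitivity: float
    specificity: float
    precision: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and aggregate classification metrics."""

    accuracy: float
    per_class: dict[str, ClassMetrics]
    macro_sensitivity: float
    macro_specificity: float
    macro_f1: float
    confusion: pd.DataFrame  # rows = true, cols = predicted
    n_rows: int

    def to_frame(self) -> pd.DataFrame:
        """Per-class metrics as a tidy DataFrame (one row per class)."""
        return pd.DataFrame(
            {
                "class": list(self.per_class),
                "sensitivity": [m.sensitivity for m in self.per_class.values()],
                "specificity": [m.specificity for m in self.per_class.values()],
                "precision": [m.precision for m in self.per_class.values()],
                "f1": [m.f1 for m in self.per_class.values()],
            }
        )


def _safe_ratio(num: int, den: int, what: str, cls: str) -> float:
    if den == 0:
        logger.info("%s undefined for class %r (zero denominator)", what, cls)
        return math.nan
    return num / den


def tile_metrics(table: pd.DataFrame, classes: Sequence[str]) -> MetricsReport:
    """Compute tile-level one-vs-rest metrics over ``classes``.

    Every predicted and true label must belong to ``classes``.  Undefined
    ratios (zero denominators) are NaN and excluded from macro averages.
    """
    validate_prediction_table(table)
    if len(table) == 0:
        raise ValueError("prediction table is empty")
    classes = list(classes)
    for col in ("predicted_label", "true_label"):
        unknown = set(table[col]) - set(classes)
        if unknown:
            raise ValueError(f"{col} values outside the class set: {sorted(unknown)}")
    truth = table["true_label"].to_numpy()
    pred = table["predicted_label"].to_numpy()
    n = len(table)
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(truth, pred):
        confusion.loc[t, p] += 1
    accuracy = float((truth == pred).sum() / n)
    per_class: dict[str, ClassMetrics] = {}
    for c in classes:
        tp = int(confusion.loc[c, c])
        fn = int(confusion.loc[c].sum() - tp)
        fp = int(confusion[c].sum() - tp)
        tn = n - tp - fn - fp
        sens = _safe_ratio(tp, tp + fn, "sensitivity", c)
        spec = _safe_ratio(tn, tn + fp, "specificity", c)
        prec = _safe_ratio(tp, tp + fp, "precision", c)
        if math.isnan(sens) or math.isnan(prec) or (sens + prec) == 0:
            f1 = math.nan
            logger.info("F1 undefined for class %r", c)
        else:
            f1 = 2 * sens * prec / (sens + prec)
        per_class[c] = ClassMetrics(sens, spec, prec, f1, tp, fp, fn, tn)

    def macro(values: list[float]) -> float:
        finite = [v for v in values if not math.isnan(v)]
        return sum(finite) / len(finite) if finite else math.nan

    return MetricsReport(
        accuracy=accuracy,
        per_class=per_class,
        macro_sensitivity=macro([m.sensitivity for m in per_class.values()]),
        macro_specificity=macro([m.specificity for m in per_class.values()]),
        macro_f1=macro([m.f1 for m in per_class.values()]),
        confusion=confusion,
        n_rows=n,
    )


@dataclass(frozen=True)
class VoteResult:
    """Outcome of majority voting for one slide."""

    label: str
    vote_counts: dict[str, int]
    tie_flag: bool


def majority_vote(table: pd.DataFrame) -> dict[str, VoteResult]:
    """Aggregate tile predictions to one label per slide.

    The slide label is the most frequent ``predicted_label`` among its
    tiles.  On a tie the winner is the tied label with the highest summed
    probability (when ``p_<class>`` columns exist) or the
    lexicographically smallest tied label otherwise; ``tie_flag`` is set
    in both cases so downstream reporting can surface ambiguous slides.
    """
    validate_prediction_table(table)
    out: dict[str, VoteResult] = {}
    for sid, group in table.groupby("slide_id", sort=False):
        counts = group["predicted_label"].value_counts().to_dict()
        top = max(counts.values())
        tied = sorted(label for label, c in counts.items() if c == top)
        if len(tied) == 1:
            out[str(sid)] = VoteResult(tied[0], counts, tie_flag=False)
            continue
        prob_cols = {lab: f"p_{lab}" for lab in tied}
        if all(col in group.columns for col in prob_cols.values()):
            sums = {lab: float(group[col].sum()) for lab, col in prob_cols.items()}
            winner = max(tied, key=lambda lab: (sums[lab], ))
        else:
            winner = tied[0]  # lexicographically smallest
        out[str(sid)] = VoteResult(winner, counts, tie_flag=True)
    return out


def slide_prediction_table(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a tile table to one row per slide via majority voting.

    The returned frame has columns slide_id, tile_id (=0), true_label,
    predicted_label, and feeds straight back into :func:`tile_metrics`
    for slide-level reports.  Requires each slide's tiles to share one
    true label.
    """
    votes = majority_vote(table)
    rows = []
    for sid, group in table.groupby("slide_id", sort=False):
        true = group["true_label"].unique()
        if len(true) != 1:
            raise ValueError(f"slide {sid!r} has multiple true labels: {sorted(true)}")
        rows.append(
            {
                "slide_id": sid,
                "tile_id": 0,
                "true_label": true[0],
                "predicted_label": votes[str(sid)].label,
            }
        )
    return pd.DataFrame(rows)


def validation_schedule(steps_per_epoch: int, k: int = 8) -> list[int]:
    """Step indices at which to run validation, k times per epoch.

    Returns ``floor(i * steps_per_epoch / k)`` for i = 1..k — strictly
    increasing, ending exactly at ``steps_per_epoch``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > steps_per_epoch:
        raise ValueError(
            f"cannot validate {k} times in an epoch of {steps_per_epoch} steps"
        )
    return [(i * steps_per_epoch) // k for i in range(1, k + 1)]


@dataclass(frozen=True)
class EarlyStopState:
    """Immutable early-stopping state; thread through validation checks."""

    best_score: float = -math.inf
    non_improving: int = 0
    patience: int = 5
    min_delta: float = 0.0
    stopped: bool = False

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError(f"patience must be >= 1, got {self.patience}")
        if self.min_delta < 0:
            raise ValueError(f"min_delta must be >= 0, got {self.min_delta}")
        if self.non_improving > self.patience:
            raise ValueError("non_improving cannot exceed patience")


def early_stop_update(state: EarlyStopState, score: float) -> EarlyStopState:
    """Advance the early-stopping state with a new validation score.

    Improvement is strict: ``score > best + min_delta`` resets the
    counter; anything else (including an exact tie at min_delta 0) counts
    as a non-improvement.  ``stopped`` becomes true when the counter
    reaches ``patience`` consecutive non-improvements.
    """
    if state.stopped:
        raise EarlyStopStateError("early stopping already triggered; no further updates")
    if score > state.best_score + state.min_delta:
        return replace(state, best_score=score, non_improving=0)
    count = state.non_improving + 1
    return replace(state, non_improving=count, stopped=count >= state.patience)
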