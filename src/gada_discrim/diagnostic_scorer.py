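"""Apply a discriminant model artifact to records and evaluate accuracy."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .cohort_model import Cohort, Group, encode_value
from .discriminant import FisherScore, ModelArtifact, fisher_classify
from .errors import DomainError, EncodingError


@dataclass
class ConfusionSummary:
    """2x2 classification counts with GADA+ as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.fp + self.tn)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


@dataclass
class ScoringResult:
    #: (record index, FisherScore) for every scoreable record, input order
    scores: list
    #: (record index, reason) for records lacking a needed field
    skipped: list

    @property
    def predictions(self) -> list:
        return [score.predicted for _, score in self.scores]


def score_cohort(artifact: ModelArtifact, cohort: Cohort) -> ScoringResult:
    """Encode and classify every record; report unscoreable records."""
    if len(cohort) == 0:
        raise DomainError("cannot score an empty cohort")
    scores, skipped = [], []
    for idx, rec in enumerate(cohort.records):
        try:
            x = [encode_value(rec, name, artifact.cutoffs) for name in artifact.variables]
        except EncodingError as exc:
            skipped.append((idx, str(exc)))
            continue
        scores.append((idx, fisher_classify(artifact.fisher, x)))
    return ScoringResult(scores=scores, skipped=skipped)


def evaluate(predictions: Sequence, truths: Sequence) -> ConfusionSummary:
    """Confusion counts for aligned prediction/truth label lists."""
    if len(predictions) != len(truths):
        raise DomainError(
            f"length mismatch: {len(predictions)} predictions vs {len(truths)} truths"
        )
    counts = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
    for pred, truth in zip(predictions, truths):
        pred, truth = Group(pred), Group(truth)
        if truth is Group.GADA_POS:
            counts["tp" if pred is Group.GADA_POS else "fn"] += 1
        else:
            counts["fp" if pred is Group.GADA_POS else "tn"] += 1
    return ConfusionSummary(**counts)


def resubstitution_summary(artifact: ModelArtifact, cohort: Cohort) -> ConfusionSummary:
    """Score a labeled cohort and evaluate against its own labels."""
    result = score_cohort(artifact, cohort)
    truths = []
    preds = []
    for idx, score in result.scores:
        truth = cohort.records[idx].group
        if truth is None:
            raise DomainError(f"record {idx} has no group label; cannot evaluate")
        truths.append(truth)
        preds.append(score.predicted)
    return evaluate(preds, truths)
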