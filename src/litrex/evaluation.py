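"""Scoring: contingency counts, precision/recall/F1, run aggregation.

Positive means "the relation holds".  Zero denominators follow the
conservative convention P = R = 0 (logged when triggered); F1 = 0 when
P + R = 0.  Aggregation over repeated runs reports per-metric mean and
sample (n-1) standard deviation, matching the mean ± std presentation
convention, with std = 0 for a single run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .types import Prediction, RelationInstance

logger = logging.getLogger(__name__)

METRIC_NAMES = ("precision", "recall", "f1")


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    parse_failures: int
    run_id: str = ""

    @property
    def n_instances(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def metric(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    if tp + fp == 0:
        logger.debug("no positive predictions; precision set to 0")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def score_predictions(
    predictions: Sequence[Prediction],
    instances: Sequence[RelationInstance],
    run_id: str = "",
    exclude_unparseable: bool = False,
) -> MetricsReport:
    """Score one prediction per instance against gold labels.

    Unparseable outputs enter the contingency under their default label
    (and are tallied) unless ``exclude_unparseable``, which drops them
    from the counts entirely.
    """
    if len(predictions) != len(instances):
        raise ValueError(
            f"{len(predictions)} predictions for {len(instances)} instances"
        )
    tp = fp = fn = tn = parse_failures = 0
    for pred, inst in zip(predictions, instances):
        if pred.instance.key != inst.key:
            raise ValueError(f"prediction/instance mismatch at {inst.key}")
        if pred.parse_status == "unparseable":
            parse_failures += 1
            if exclude_unparseable:
                continue
        gold_pos = inst.gold == "positive"
        pred_pos = pred.predicted == "positive"
        if gold_pos and pred_pos:
            tp += 1
        elif gold_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
    precision, recall, f1 = _prf(tp, fp, fn)
    return MetricsReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=precision, recall=recall, f1=f1,
        parse_failures=parse_failures, run_id=run_id,
    )


@dataclass(frozen=True)
class RunAggregate:
    """Mean and sample standard deviation per metric over n runs."""

    n: int
    mean: dict[str, float]
    std: dict[str, float]
    reports: tuple[MetricsReport, ...]

    def describe(self) -> str:
        return ", ".join(
            f"{m}={self.mean[m]:.4f}±{self.std[m]:.4f}" for m in METRIC_NAMES
        )


def aggregate_runs(reports: Sequence[MetricsReport]) -> RunAggregate:
    if not reports:
        raise ValueError("cannot aggregate zero runs")
    n = len(reports)
    mean: dict[str, float] = {}
    std: dict[str, float] = {}
    for m in METRIC_NAMES:
        values = [r.metric(m) for r in reports]
        mu = sum(values) / n
        mean[m] = mu
        std[m] = math.sqrt(sum((v - mu) ** 2 for v in values) / (n - 1)) if n > 1 else 0.0
    return RunAggregate(n=n, mean=mean, std=std, reports=tuple(reports))
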