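"""Confusion-matrix performance metrics and group summary statistics.

Metrics follow the usual diagnostic definitions on cumulative dataset-level
counts; a zero denominator yields NaN (an undefined marker), never zero or a
crash, and undefined values are excluded from group summaries with their
count logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import UNDEFINED, ConfusionSummary, is_defined, mean_iou

logger = logging.getLogger(__name__)

METRIC_NAMES = [
    "errors",
    "mean_iou",
    "sensitivity",
    "specificity",
    "accuracy",
    "precision",
    "f1",
]


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


@dataclass(frozen=True)
class MetricsReport:
    annotator_id: str
    session: str
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float
    errors: int
    mean_iou: float

    def value(self, metric: str) -> float:
        return float(getattr(self, metric))

    def as_dict(self) -> dict[str, float]:
        return {m: self.value(m) for m in METRIC_NAMES}


def compute_metrics(summary: ConfusionSummary) -> MetricsReport:
    """Sensitivity, specificity, accuracy, precision and F1 from cumulative
    TP/FP/FN/TN counts, plus the error count (FP+FN) and pooled mean IoU."""
    sens = _ratio(summary.tp, summary.tp + summary.fn)
    prec = _ratio(summary.tp, summary.tp + summary.fp)
    if is_defined(sens) and is_defined(prec) and (sens + prec) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    elif is_defined(sens) and is_defined(prec):
        f1 = 0.0
    else:
        f1 = UNDEFINED
    return MetricsReport(
        annotator_id=summary.annotator_id,
        session=summary.session,
        sensitivity=sens,
        specificity=_ratio(summary.tn, summary.tn + summary.fp),
        accuracy=_ratio(summary.tp + summary.tn, summary.tp + summary.tn + summary.fp + summary.fn),
        precision=prec,
        f1=f1,
        errors=summary.errors,
        mean_iou=mean_iou(summary),
    )


@dataclass
class MetricSummary:
    """Distributional summary of one metric across annotators."""

    metric: str
    n: int
    n_undefined: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float


@dataclass
class GroupSummary:
    group_label: str
    n: int
    metrics: dict[str, MetricSummary] = field(default_factory=dict)


def summarize_group(reports: list[MetricsReport], label: str) -> GroupSummary:
    """Per-metric mean, sample SD (n−1), median and IQR (linear-interpolation
    quantiles) across annotators.  Undefined values are dropped per metric
    and their count logged; a single defined value has undefined SD."""
    if not reports:
        raise ValueError("summarize_group requires at least one report")
    out = GroupSummary(group_label=label, n=len(reports))
    for metric in METRIC_NAMES:
        values = np.array([r.value(metric) for r in reports], dtype=float)
        defined = values[~np.isnan(values)]
        n_undef = int(np.isnan(values).sum())
        if n_undef:
            logger.info("group %s: %d undefined %s values excluded", label, n_undef, metric)
        if defined.size == 0:
            out.metrics[metric] = MetricSummary(metric, 0, n_undef, UNDEFINED, UNDEFINED, UNDEFINED, UNDEFINED, UNDEFINED)
            continue
        q1, med, q3 = np.percentile(defined, [25, 50, 75])
        out.metrics[metric] = MetricSummary(
            metric=metric,
            n=int(defined.size),
            n_undefined=n_undef,
            mean=float(defined.mean()),
            sd=float(defined.std(ddof=1)) if defined.size > 1 else UNDEFINED,
            median=float(med),
            q1=float(q1),
            q3=float(q3),
        )
    return out


def improvement(pre: MetricsReport, post: MetricsReport) -> dict[str, float]:
    """Per-metric post − pre delta for one annotator.

    Positive deltas mean the metric rose after training; for the error count
    an improvement therefore shows as a negative delta.  NaN propagates when
    either side is undefined.
    """
    if pre.annotator_id != post.annotator_id:
        raise ValueError(
            f"improvement requires the same annotator on both sides "
            f"(got {pre.annotator_id!r} vs {post.annotator_id!r})"
        )
    return {m: post.value(m) - pre.value(m) for m in METRIC_NAMES}
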