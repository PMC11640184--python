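"""Comparison framings, confusion matrices and diagnostic test metrics.

Three framings define the negative class for a target diagnosis:

``target_vs_nat``
    the target's own normal adjacent tissues only;
``all_tumors``
    primary tumors of every other diagnosis (no normals);
``all_samples``
    every other sample — other tumors plus all normals, including the
    target's own.

The positive class is always the target's primary tumors.  Metrics are
the standard five (sensitivity, specificity, accuracy, PPV, NPV) with
exact Clopper-Pearson 95% confidence intervals; percentages render with
one decimal, round-half-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .calling import PanelCallSet
from .errors import ConfigurationError, DataError, ValidationError
from .types import (
    NEGATIVE,
    POSITIVE,
    SampleRecord,
    TISSUE_NORMAL,
    TISSUE_TUMOR,
    UNDETERMINED,
)

FRAMINGS = ("target_vs_nat", "all_tumors", "all_samples")
METRICS = ("sensitivity", "specificity", "accuracy", "ppv", "npv")


def format_percent(x: float) -> str:
    """Render a fraction as a percentage with one decimal, round-half-up.

    11/14 -> '78.6%'; 13/16 -> '81.3%' (81.25 rounds up, not to even).
    """
    if not 0.0 <= x <= 1.0:
        raise ValidationError(f"fraction {x} outside [0, 1]")
    # Round away float noise well below the half-up decision point first.
    snapped = Decimal(repr(round(x * 100.0, 9)))
    return f"{snapped.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)}%"


@dataclass(frozen=True)
class ComparisonFrame:
    """Positive and negative sample ids for one framing of one target."""

    framing: str
    target: str
    positives: tuple[str, ...]
    negatives: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValidationError(
                f"samples in both classes: {sorted(overlap)[:5]}"
            )


def frame_comparison(
    framing: str, target: str, sheet: Sequence[SampleRecord]
) -> ComparisonFrame:
    """Build the positive/negative sample sets for one framing."""
    if framing not in FRAMINGS:
        raise ConfigurationError(
            f"unknown framing {framing!r}; expected one of {FRAMINGS}"
        )
    positives = [
        r.sample_id
        for r in sheet
        if r.diagnosis == target and r.tissue == TISSUE_TUMOR
    ]
    if not positives:
        raise DataError(f"sheet has no {target} tumor samples")
    if framing == "target_vs_nat":
        negatives = [
            r.sample_id
            for r in sheet
            if r.diagnosis == target and r.tissue == TISSUE_NORMAL
        ]
    elif framing == "all_tumors":
        negatives = [
            r.sample_id
            for r in sheet
            if r.diagnosis != target and r.tissue == TISSUE_TUMOR
        ]
    else:  # all_samples
        negatives = [
            r.sample_id
            for r in sheet
            if r.tissue == TISSUE_NORMAL
            or (r.diagnosis != target and r.tissue == TISSUE_TUMOR)
        ]
    return ComparisonFrame(
        framing=framing,
        target=target,
        positives=tuple(positives),
        negatives=tuple(negatives),
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """The 2x2 table, plus undetermined calls excluded from it."""

    tp: int
    fn: int
    fp: int
    tn: int
    undetermined_positives: int = 0
    undetermined_negatives: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn",
                     "undetermined_positives", "undetermined_negatives"):
            if getattr(self, name) < 0:
                raise ValidationError(f"negative confusion count {name}")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(calls: PanelCallSet, frame: ComparisonFrame) -> ConfusionCounts:
    """Cross the panel calls with a comparison frame."""

    def split(ids: tuple[str, ...]) -> tuple[int, int, int]:
        pos = neg = undet = 0
        for sample_id in ids:
            if sample_id not in calls.calls.index:
                raise DataError(
                    f"frame sample {sample_id!r} has no panel call"
                )
            call = calls.calls[sample_id]
            if call == POSITIVE:
                pos += 1
            elif call == NEGATIVE:
                neg += 1
            else:
                undet += 1
        return pos, neg, undet

    tp, fn, undet_pos = split(frame.positives)
    fp, tn, undet_neg = split(frame.negatives)
    return ConfusionCounts(
        tp=tp, fn=fn, fp=fp, tn=tn,
        undetermined_positives=undet_pos,
        undetermined_negatives=undet_neg,
    )


@dataclass(frozen=True)
class MetricEstimate:
    """One proportion metric: exact ratio, point value and exact CI."""

    numerator: int
    denominator: int
    ci_low: float | None
    ci_high: float | None

    @property
    def value(self) -> float | None:
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    @property
    def percent(self) -> str:
        return "NA" if self.value is None else format_percent(self.value)

    def to_dict(self) -> dict:
        return {
            "numerator": self.numerator,
            "denominator": self.denominator,
            "value": self.value,
            "percent": self.percent,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def _estimate(numerator: int, denominator: int, level: float) -> MetricEstimate:
    if denominator == 0:
        return MetricEstimate(numerator, denominator, None, None)
    low, high = proportion_confint(
        numerator, denominator, alpha=1.0 - level, method="beta"
    )
    # statsmodels returns NaN at the boundary counts; the exact interval
    # endpoint there is 0 or 1.
    low = 0.0 if pd.isna(low) else float(low)
    high = 1.0 if pd.isna(high) else float(high)
    return MetricEstimate(numerator, denominator, low, high)


def metrics(c: ConfusionCounts, level: float = 0.95) -> dict[str, MetricEstimate]:
    """The five diagnostic metrics with exact Clopper-Pearson CIs.

    A metric whose denominator is zero is reported as undefined (value
    None, rendered 'NA'), never as an exception.
    """
    return {
        "sensitivity": _estimate(c.tp, c.tp + c.fn, level),
        "specificity": _estimate(c.tn, c.tn + c.fp, level),
        "accuracy": _estimate(c.tp + c.tn, c.n, level),
        "ppv": _estimate(c.tp, c.tp + c.fp, level),
        "npv": _estimate(c.tn, c.tn + c.fn, level),
    }


@dataclass(frozen=True)
class FramingResult:
    """Confusion counts and metrics for one framing."""

    frame: ComparisonFrame
    counts: ConfusionCounts
    metrics: Mapping[str, MetricEstimate]

    def to_dict(self) -> dict:
        return {
            "framing": self.frame.framing,
            "target": self.frame.target,
            "n_positives": len(self.frame.positives),
            "n_negatives": len(self.frame.negatives),
            "confusion": {
                "tp": self.counts.tp,
                "fn": self.counts.fn,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
                "undetermined_positives": self.counts.undetermined_positives,
                "undetermined_negatives": self.counts.undetermined_negatives,
            },
            "metrics": {k: v.to_dict() for k, v in self.metrics.items()},
        }


@dataclass(frozen=True)
class DiagnosticReport:
    """Per-framing diagnostic performance of one panel on one cohort."""

    panel_name: str
    target: str
    cohort: str | None
    framings: Mapping[str, FramingResult]

    def percent_table(self) -> pd.DataFrame:
        """Metric x framing table of formatted percent strings."""
        cols = [f for f in FRAMINGS if f in self.framings]
        data = {
            f: [self.framings[f].metrics[m].percent for m in METRICS]
            for f in cols
        }
        return pd.DataFrame(data, index=list(METRICS))

    def to_dict(self) -> dict:
        return {
            "panel": self.panel_name,
            "target": self.target,
            "cohort": self.cohort,
            "framings": {f: r.to_dict() for f, r in self.framings.items()},
        }


def diagnostic_report(
    calls: PanelCallSet,
    sheet: Sequence[SampleRecord],
    target: str,
    framings: Sequence[str] = FRAMINGS,
    cohort: str | None = None,
    level: float = 0.95,
) -> DiagnosticReport:
    """Evaluate a panel call set under one or more framings."""
    results: dict[str, FramingResult] = {}
    for framing in framings:
        frame = frame_comparison(framing, target, sheet)
        counts = confusion(calls, frame)
        results[framing] = FramingResult(frame, counts, metrics(counts, level))
    return DiagnosticReport(
        panel_name=calls.panel_name,
        target=target,
        cohort=cohort,
        framings=results,
    )
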