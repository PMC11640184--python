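"""Model/results interface over the panel-evaluation pipeline.

`PanelDiagnostics` is constructed from data (a beta or call matrix, a
panel and a sample sheet); `fit()` runs calling, framing, metric and ROC
computation and returns a `PanelDiagnosticsResults` carrying the point
estimates, their exact confidence intervals and a printable summary, in
the spirit of statsmodels' model/results pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .calling import PanelCallSet, apply_panel
from .diagnostics import (
    DiagnosticReport,
    FRAMINGS,
    METRICS,
    diagnostic_report,
    frame_comparison,
)
from .errors import ValidationError
from .roc import RocResult, roc_analysis
from .types import BetaMatrix, CallMatrix, PanelDefinition, SampleRecord


class PanelDiagnostics:
    """Diagnostic evaluation of one methylation panel on one cohort.

    Parameters
    ----------
    matrix
        Beta values (binarized at the panel cutoff) or precomputed
        per-probe calls.
    panel
        Panel definition: probes, target diagnosis, cutoff.
    sheet
        Validated sample records covering the matrix samples.
    framings
        Which negative-class framings to evaluate (default: all three).
    """

    def __init__(
        self,
        matrix: BetaMatrix | CallMatrix,
        panel: PanelDefinition,
        sheet: Sequence[SampleRecord],
        framings: Sequence[str] = FRAMINGS,
        cohort: str | None = None,
        strict_cutoff: bool = False,
    ) -> None:
        unknown = [f for f in framings if f not in FRAMINGS]
        if unknown:
            raise ValidationError(f"unknown framings {unknown}")
        self.matrix = matrix
        self.panel = panel
        self.sheet = list(sheet)
        self.framings = tuple(framings)
        self.cohort = cohort
        self.strict_cutoff = strict_cutoff

    @classmethod
    def from_beta(cls, beta: BetaMatrix, panel: PanelDefinition,
                  sheet: Sequence[SampleRecord], **kw) -> "PanelDiagnostics":
        return cls(beta, panel, sheet, **kw)

    @classmethod
    def from_calls(cls, calls: CallMatrix, panel: PanelDefinition,
                   sheet: Sequence[SampleRecord], **kw) -> "PanelDiagnostics":
        return cls(calls, panel, sheet, **kw)

    def fit(
        self, ci_level: float = 0.95, score: str = "binary"
    ) -> "PanelDiagnosticsResults":
        """Run calling, metrics and ROC; return the results object."""
        callset = apply_panel(
            self.matrix, self.panel, self.sheet, strict=self.strict_cutoff
        )
        report = diagnostic_report(
            callset,
            self.sheet,
            target=self.panel.target_diagnosis,
            framings=self.framings,
            cohort=self.cohort,
            level=ci_level,
        )
        roc: dict[str, RocResult] = {}
        beta = self.matrix if isinstance(self.matrix, BetaMatrix) else None
        for framing in self.framings:
            frame = frame_comparison(
                framing, self.panel.target_diagnosis, self.sheet
            )
            roc[framing] = roc_analysis(
                callset, frame, score=score, beta=beta, level=ci_level
            )
        return PanelDiagnosticsResults(
            model=self, callset=callset, report=report, roc=roc,
            ci_level=ci_level, score=score,
        )


@dataclass(frozen=True)
class PanelDiagnosticsResults:
    """Fitted panel evaluation: calls, metrics with CIs, ROC, summary."""

    model: PanelDiagnostics
    callset: PanelCallSet
    report: DiagnosticReport
    roc: Mapping[str, RocResult]
    ci_level: float
    score: str

    def metrics_frame(self) -> pd.DataFrame:
        """Long-format metric table: framing, metric, ratio, value, CI."""
        rows = []
        for framing, result in self.report.framings.items():
            for metric in METRICS:
                est = result.metrics[metric]
                rows.append(
                    {
                        "framing": framing,
                        "metric": metric,
                        "numerator": est.numerator,
                        "denominator": est.denominator,
                        "value": est.value,
                        "percent": est.percent,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary of the fitted evaluation."""
        lines = [
            f"Panel diagnostics: {self.model.panel.name} "
            f"(target {self.model.panel.target_diagnosis}, "
            f"cutoff {self.model.panel.cutoff:g}, score {self.score})",
            f"Samples called: {len(self.callset.calls)}"
            + (f"  cohort: {self.model.cohort}" if self.model.cohort else ""),
            "",
        ]
        pct = self.report.percent_table()
        lines.append(pct.to_string())
        lines.append("")
        for framing, res in self.roc.items():
            ci = f"[{res.ci_low:.4f}, {res.ci_high:.4f}]"
            p = "indeterminate" if res.p_value is None else f"{res.p_value:.3g}"
            flag = "  (degenerate)" if res.degenerate else ""
            lines.append(
                f"ROC {framing}: AUC {res.auc:.4f}  "
                f"{int(self.ci_level * 100)}% CI {ci}  p {p}{flag}"
            )
        return "\n".join(lines)
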