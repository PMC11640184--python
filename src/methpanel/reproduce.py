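"""End-to-end orchestration: published-results reproduction and runs.

`reproduce_published` regenerates, from the embedded count fixtures, the
published group-count tables, the per-framing diagnostic percent tables
and the MS-HRM binary-call AUCs, and emits a machine-readable comparison
of every printed percent cell against its recomputation.  A handful of
printed cells are not arithmetically consistent with the published
counts (see docs/methods.md); those rows carry ``match = False``.

`run_pipeline` drives simulate/ingest -> call -> evaluate -> ROC from a
single validated config with one seed.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .calling import apply_panel, tabulate_counts
from .diagnostics import FRAMINGS
from .errors import ConfigurationError, MethPanelError, ValidationError
from .evaluation import PanelDiagnostics
from .io import (
    read_beta_matrix,
    read_call_matrix,
    read_panel,
    read_sample_sheet,
    write_beta_matrix,
    write_report,
    write_sample_sheet,
)
from .published import (
    COHORTS,
    PANELS,
    PUBLISHED_AUC,
    PUBLISHED_METRICS,
    published_group_counts,
)
from .roc import SCORE_MODES
from .synthetic import FixtureSpec, GroupGenSpec, fixture_from_counts, generate_cohort

logger = logging.getLogger(__name__)


def comparison_table() -> pd.DataFrame:
    """Printed vs recomputed percent cells for both panels, all cohorts.

    Columns: panel, cohort, framing, metric, printed, recomputed, match.
    Recomputed values come from running the count fixtures through the
    full calling/metrics pipeline.
    """
    rows = []
    for panel_name, panel in PANELS.items():
        for cohort in COHORTS:
            counts = published_group_counts(panel_name, cohort)
            matrix, records = fixture_from_counts(
                FixtureSpec(counts=counts, panel=panel)
            )
            results = PanelDiagnostics(
                matrix, panel, records, cohort=cohort
            ).fit()
            for framing in FRAMINGS:
                framing_idx = FRAMINGS.index(framing)
                res = results.report.framings[framing]
                for metric in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
                    printed = PUBLISHED_METRICS[panel_name][cohort][metric][framing_idx]
                    recomputed = res.metrics[metric].percent
                    rows.append(
                        {
                            "panel": panel_name,
                            "cohort": cohort,
                            "framing": framing,
                            "metric": metric,
                            "printed": printed,
                            "recomputed": recomputed,
                            "match": printed == recomputed,
                        }
                    )
    return pd.DataFrame(rows)


def reproduce_published(outdir: str | Path | None = None) -> dict:
    """Recompute the published tables and AUCs from embedded fixtures.

    Returns a bundle: per panel/cohort GroupCounts and DiagnosticReport,
    MS-HRM RocResults, and the printed-vs-recomputed comparison table.
    Writes TSV/JSON artifacts when ``outdir`` is given.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    bundle: dict = {"counts": {}, "reports": {}, "roc": {}, }
    for panel_name, panel in PANELS.items():
        for cohort in COHORTS:
            counts = published_group_counts(panel_name, cohort)
            matrix, records = fixture_from_counts(
                FixtureSpec(counts=counts, panel=panel)
            )
            results = PanelDiagnostics(matrix, panel, records, cohort=cohort).fit()
            callset = results.callset
            tallied = tabulate_counts(callset, records)
            bundle["counts"][(panel_name, cohort)] = tallied
            bundle["reports"][(panel_name, cohort)] = results.report
            if cohort == "MS-HRM":
                bundle["roc"][panel_name] = results.roc["all_samples"]
            if out is not None:
                stem = f"{panel_name.lower()}_{cohort.lower().replace('-', '')}"
                write_report(tallied, out / f"counts_{stem}.tsv", "tsv")
                write_report(results.report, out / f"metrics_{stem}.tsv", "tsv")
                write_report(results.report, out / f"metrics_{stem}.json", "json")
                if cohort == "MS-HRM":
                    (out / f"roc_{panel_name.lower()}_mshrm.json").write_text(
                        json.dumps(results.roc["all_samples"].to_dict(), indent=2)
                        + "\n"
                    )

    comparison = comparison_table()
    bundle["comparison"] = comparison
    bundle["auc"] = {
        name: {
            "published": PUBLISHED_AUC[name],
            "recomputed": round(bundle["roc"][name].auc, 4),
            "match": round(bundle["roc"][name].auc, 4) == PUBLISHED_AUC[name],
        }
        for name in PANELS
    }
    if out is not None:
        comparison.to_csv(out / "comparison.csv", index=False, lineterminator="\n")
        (out / "auc_comparison.json").write_text(
            json.dumps(bundle["auc"], indent=2) + "\n"
        )
    return bundle


# --------------------------------------------------------------------------
# Configured pipeline runs


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: inputs (or a simulation), panel, outputs, seed."""

    panel_path: str | None = None
    panel_name: str | None = None  # builtin panel ('GAC' or 'LUAD')
    beta_path: str | None = None
    calls_path: str | None = None
    sheet_path: str | None = None
    simulate: Sequence[GroupGenSpec] = field(default_factory=tuple)
    probes: Sequence[str] = field(default_factory=tuple)
    cutoff: float | None = None
    strict_cutoff: bool = False
    framings: Sequence[str] = tuple(FRAMINGS)
    score: str = "binary"
    outdir: str = "methpanel_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff is not None and not 0.0 < self.cutoff < 1.0:
            raise ValidationError(f"cutoff {self.cutoff} not in (0, 1)")
        if self.score not in SCORE_MODES:
            raise ValidationError(f"unknown score mode {self.score!r}")
        bad = [f for f in self.framings if f not in FRAMINGS]
        if bad:
            raise ValidationError(f"unknown framings {bad}")
        if self.panel_path is None and self.panel_name is None:
            raise ConfigurationError("config needs a panel (path or builtin name)")
        if self.panel_name is not None and self.panel_name not in PANELS:
            raise ConfigurationError(
                f"unknown builtin panel {self.panel_name!r}; "
                f"choose from {sorted(PANELS)}"
            )
        has_data = self.beta_path or self.calls_path
        if has_data and not self.sheet_path:
            raise ConfigurationError("matrix input requires a sample sheet")
        if not has_data and not self.simulate:
            raise ConfigurationError(
                "config needs either input data or simulation group specs"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigurationError(f"config {path} is not a key-value document")
        sim_specs = tuple(
            GroupGenSpec(**{str(k): v for k, v in g.items()})
            for g in doc.get("simulate", [])
        )
        return cls(
            panel_path=doc.get("panel_path"),
            panel_name=doc.get("panel_name"),
            beta_path=doc.get("beta_path"),
            calls_path=doc.get("calls_path"),
            sheet_path=doc.get("sheet_path"),
            simulate=sim_specs,
            probes=tuple(doc.get("probes", [])),
            cutoff=doc.get("cutoff"),
            strict_cutoff=bool(doc.get("strict_cutoff", False)),
            framings=tuple(doc.get("framings", FRAMINGS)),
            score=doc.get("score", "binary"),
            outdir=doc.get("outdir", "methpanel_run"),
            seed=int(seed if seed is not None else doc.get("seed", 0)),
        )


def run_pipeline(config: RunConfig) -> dict:
    """simulate/ingest -> call -> evaluate -> roc, all outputs written.

    Deterministic given the config seed.  Any stage failure removes the
    partially written output directory and re-raises with a stage tag.
    """
    outdir = Path(config.outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _track(path: Path) -> Path:
        written.append(path)
        return path

    stage = "setup"
    try:
        stage = "ingest"
        if config.panel_path:
            panel = read_panel(config.panel_path)
        else:
            panel = PANELS[config.panel_name]
        if config.cutoff is not None:
            panel = type(panel)(
                name=panel.name,
                target_diagnosis=panel.target_diagnosis,
                probes=panel.probes,
                cutoff=config.cutoff,
                probe_gene_map=panel.probe_gene_map,
            )
        if config.simulate:
            stage = "simulate"
            probes = tuple(config.probes) or panel.probes
            matrix, sheet = generate_cohort(config.simulate, probes, config.seed)
            write_beta_matrix(matrix, _track(outdir / "simulated_betas.tsv"))
            write_sample_sheet(sheet, _track(outdir / "simulated_sheet.tsv"))
        else:
            sheet = read_sample_sheet(config.sheet_path)
            if config.beta_path:
                matrix = read_beta_matrix(config.beta_path)
            else:
                matrix = read_call_matrix(config.calls_path)

        stage = "call"
        callset = apply_panel(matrix, panel, sheet, strict=config.strict_cutoff)
        write_call_matrix_like = pd.DataFrame(
            {"panel_call": callset.calls}
        )
        write_call_matrix_like.to_csv(
            _track(outdir / "panel_calls.tsv"), sep="\t",
            index_label="sample_id", lineterminator="\n",
        )
        counts = tabulate_counts(callset, sheet)
        write_report(counts, _track(outdir / "group_counts.tsv"), "tsv")

        stage = "evaluate"
        results = PanelDiagnostics(
            matrix, panel, sheet, framings=config.framings,
            strict_cutoff=config.strict_cutoff,
        ).fit(score=config.score)
        write_report(results.report, _track(outdir / "diagnostics.tsv"), "tsv")
        write_report(results.report, _track(outdir / "diagnostics.json"), "json")

        stage = "roc"
        roc_payload = {f: r.to_dict() for f, r in results.roc.items()}
        _track(outdir / "roc.json").write_text(json.dumps(roc_payload, indent=2) + "\n")
        _track(outdir / "summary.txt").write_text(results.summary() + "\n")
        return {
            "panel": panel,
            "sheet": sheet,
            "callset": callset,
            "counts": counts,
            "results": results,
        }
    except MethPanelError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        raise type(exc)(f"[stage {stage}] {exc}") from exc
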