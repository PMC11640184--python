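"""Probe binarization at the methylation cutoff and OR-rule panel calls.

A probe is called methylated when its beta value reaches the cutoff
(inclusive by default: a sample melting at or above the 30%-methylated
control is labeled methylated).  A panel is positive when at least one of
its probes is methylated, negative when at least one probe is determined
and none is methylated, and undetermined only when every probe call is
undetermined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ValidationError
from .types import (
    BetaMatrix,
    CallMatrix,
    GroupCounts,
    METHYLATED,
    NEGATIVE,
    PanelDefinition,
    POSITIVE,
    SampleRecord,
    UNDETERMINED,
    UNMETHYLATED,
    canonical_sort_key,
)

logger = logging.getLogger(__name__)


def binarize_probe(beta: float | None, cutoff: float, strict: bool = False) -> str:
    """Call one beta value at ``cutoff``.

    ``strict`` switches to a strictly-greater comparison; the default is
    inclusive (>=), the operational rule used against the 30% control.
    Missing values (None/NaN) yield ``undetermined``.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValidationError(f"cutoff {cutoff} not in (0, 1)")
    if beta is None or (isinstance(beta, float) and np.isnan(beta)):
        return UNDETERMINED
    if not 0.0 <= beta <= 1.0:
        raise ValidationError(f"beta value {beta} outside [0, 1]")
    hit = beta > cutoff if strict else beta >= cutoff
    return METHYLATED if hit else UNMETHYLATED


def binarize_matrix(
    matrix: BetaMatrix, cutoff: float, strict: bool = False
) -> CallMatrix:
    """Vectorized `binarize_probe` over a whole beta matrix."""
    if not 0.0 < cutoff < 1.0:
        raise ValidationError(f"cutoff {cutoff} not in (0, 1)")
    arr = matrix.values.to_numpy(dtype=float)
    hit = arr > cutoff if strict else arr >= cutoff
    out = np.where(np.isnan(arr), UNDETERMINED, np.where(hit, METHYLATED, UNMETHYLATED))
    return CallMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    )


def call_panel(probe_calls: Sequence[str]) -> str:
    """OR-aggregate per-probe calls into one panel call."""
    if len(probe_calls) == 0:
        raise ValidationError("call_panel requires at least one probe call")
    if METHYLATED in probe_calls:
        return POSITIVE
    if all(c == UNDETERMINED for c in probe_calls):
        return UNDETERMINED
    return NEGATIVE


@dataclass(frozen=True)
class PanelCallSet:
    """Panel-level calls per sample, with the supporting probe calls."""

    panel_name: str
    cutoff: float
    calls: pd.Series  # sample_id -> positive/negative/undetermined
    probe_calls: pd.DataFrame  # samples x (available panel probes)

    def counts(self) -> dict[str, int]:
        return self.calls.value_counts().to_dict()


def apply_panel(
    matrix: BetaMatrix | CallMatrix,
    panel: PanelDefinition,
    sheet: Sequence[SampleRecord],
    strict: bool = False,
) -> PanelCallSet:
    """Call ``panel`` on every sample shared by ``matrix`` and ``sheet``.

    Beta input is binarized at the panel cutoff first; call-matrix input
    is used as-is (the cutoff does not apply).  Panel probes absent from
    the matrix and matrix samples absent from the sheet are dropped with
    a warning; zero probe overlap is a configuration error.
    """
    if isinstance(matrix, BetaMatrix):
        call_matrix = binarize_matrix(matrix, panel.cutoff, strict=strict)
    else:
        call_matrix = matrix

    available = [p for p in panel.probes if p in call_matrix.values.columns]
    missing = [p for p in panel.probes if p not in call_matrix.values.columns]
    if not available:
        raise ConfigurationError(
            f"panel {panel.name!r}: none of its probes {list(panel.probes)} "
            "are present in the matrix"
        )
    if missing:
        logger.warning(
            "panel %s: probes %s absent from matrix; calling on %s",
            panel.name, missing, available,
        )

    sheet_ids = {r.sample_id for r in sheet}
    keep = [s for s in call_matrix.values.index if s in sheet_ids]
    dropped = [s for s in call_matrix.values.index if s not in sheet_ids]
    if dropped:
        logger.warning(
            "dropping %d matrix sample(s) absent from the sample sheet: %s",
            len(dropped), dropped[:5],
        )

    sub = call_matrix.values.loc[keep, available]
    arr = sub.to_numpy(dtype=object)
    any_meth = (arr == METHYLATED).any(axis=1)
    all_undet = (arr == UNDETERMINED).all(axis=1)
    panel_calls = np.where(any_meth, POSITIVE, np.where(all_undet, UNDETERMINED, NEGATIVE))
    return PanelCallSet(
        panel_name=panel.name,
        cutoff=panel.cutoff,
        calls=pd.Series(panel_calls, index=sub.index, name=panel.name),
        probe_calls=sub,
    )


def tabulate_counts(
    calls: PanelCallSet, sheet: Sequence[SampleRecord]
) -> GroupCounts:
    """Tally panel calls per (cohort, diagnosis, tissue).

    Positive calls count as methylated, negative as unmethylated;
    undetermined calls are tallied separately and belong to neither.
    """
    by_id = {r.sample_id: r for r in sheet}
    unknown = [s for s in calls.calls.index if s not in by_id]
    if unknown:
        raise DataError(
            f"panel call(s) for sample(s) absent from the sheet: {unknown[:5]}"
        )
    tallies: dict[tuple[str, str, str], list[int]] = {}
    for sample_id, call in calls.calls.items():
        rec = by_id[sample_id]
        key = (rec.cohort, rec.diagnosis, rec.tissue)
        row = tallies.setdefault(key, [0, 0, 0])
        if call == POSITIVE:
            row[0] += 1
        elif call == NEGATIVE:
            row[1] += 1
        else:
            row[2] += 1
    keys = sorted(tallies, key=lambda k: canonical_sort_key(*k))
    return GroupCounts.from_rows([(*k, *tallies[k]) for k in keys])


def tabulate_probe_counts(
    matrix: BetaMatrix | CallMatrix,
    panel: PanelDefinition,
    sheet: Sequence[SampleRecord],
    strict: bool = False,
) -> dict[str, GroupCounts]:
    """Per-probe tallies (one GroupCounts per panel probe).

    Diagnostic companion to `tabulate_counts` for probe-level behavior
    of a panel on beta input.
    """
    if isinstance(matrix, BetaMatrix):
        call_matrix = binarize_matrix(matrix, panel.cutoff, strict=strict)
    else:
        call_matrix = matrix
    out: dict[str, GroupCounts] = {}
    for probe in panel.probes:
        if probe not in call_matrix.values.columns:
            continue
        single = PanelDefinition(
            name=f"{panel.name}:{probe}",
            target_diagnosis=panel.target_diagnosis,
            probes=(probe,),
            cutoff=panel.cutoff,
        )
        out[probe] = tabulate_counts(apply_panel(call_matrix, single, sheet), sheet)
    return out
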