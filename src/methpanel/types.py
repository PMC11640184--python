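"""Domain types for methylation-panel diagnostics.

The vocabulary follows clinical methylation studies: samples are primary
solid tumors (``TP``) or normal adjacent tissues (``NAT``); probes are
cg-identified CpG loci whose methylation fraction (beta value, in [0, 1])
is thresholded into a binary call; a panel is a named probe set with a
single cutoff, positive when any member probe is methylated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

# --------------------------------------------------------------------------
# Controlled vocabularies

#: Tissue classes: primary solid tumor and normal adjacent tissue.
TISSUE_TUMOR = "TP"
TISSUE_NORMAL = "NAT"
TISSUES = (TISSUE_TUMOR, TISSUE_NORMAL)

#: Per-probe call states.
METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
UNDETERMINED = "undetermined"
PROBE_CALLS = (METHYLATED, UNMETHYLATED, UNDETERMINED)

#: Panel-level call states.
POSITIVE = "positive"
NEGATIVE = "negative"
PANEL_CALLS = (POSITIVE, NEGATIVE, UNDETERMINED)

# Extensible diagnosis registry, seeded with the six adenocarcinoma
# entities this pipeline was built around.  Insertion order is the
# canonical display order for tabulated output.
_DIAGNOSIS_REGISTRY: dict[str, str] = {
    "HCC": "hepatocellular carcinoma",
    "CCA": "cholangiocarcinoma",
    "CRC": "colorectal carcinoma",
    "PDAC": "pancreatic adenocarcinoma",
    "GAC": "gastric adenocarcinoma",
    "LUAD": "lung adenocarcinoma",
}


def register_diagnosis(code: str, description: str = "") -> None:
    """Add a diagnosis code to the registry (idempotent)."""
    if not code or not code.strip():
        raise ValidationError("diagnosis code must be a non-empty string")
    _DIAGNOSIS_REGISTRY.setdefault(code, description)


def known_diagnoses() -> tuple[str, ...]:
    """Registered diagnosis codes, in canonical display order."""
    return tuple(_DIAGNOSIS_REGISTRY)


def is_known_diagnosis(code: str) -> bool:
    return code in _DIAGNOSIS_REGISTRY


# --------------------------------------------------------------------------
# Sample sheet


@dataclass(frozen=True)
class SampleRecord:
    """One sample's identity: diagnosis, tissue class and cohort label.

    ``pair_id`` optionally links a tumor with its matched normal tissue;
    at most one TP and one NAT may share a pair id within a sheet.
    """

    sample_id: str
    diagnosis: str
    tissue: str
    cohort: str
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not is_known_diagnosis(self.diagnosis):
            raise ValidationError(
                f"unknown diagnosis {self.diagnosis!r} for sample "
                f"{self.sample_id!r}; known: {', '.join(known_diagnoses())}"
            )
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"unknown tissue {self.tissue!r} for sample "
                f"{self.sample_id!r}; expected one of {TISSUES}"
            )


def validate_sheet(records: Sequence[SampleRecord]) -> None:
    """Enforce sheet-level invariants: unique ids, well-formed pairs."""
    seen: set[str] = set()
    for rec in records:
        if rec.sample_id in seen:
            raise ValidationError(f"duplicate sample_id {rec.sample_id!r}")
        seen.add(rec.sample_id)
    pairs: dict[str, set[str]] = {}
    for rec in records:
        if rec.pair_id is None:
            continue
        tissues = pairs.setdefault(rec.pair_id, set())
        if rec.tissue in tissues:
            raise ValidationError(
                f"pair_id {rec.pair_id!r} has more than one {rec.tissue} sample"
            )
        tissues.add(rec.tissue)


def sheet_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Sample sheet as a DataFrame (row order preserved)."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "diagnosis": [r.diagnosis for r in records],
            "tissue": [r.tissue for r in records],
            "cohort": [r.cohort for r in records],
            "pair_id": [r.pair_id for r in records],
        }
    )


# --------------------------------------------------------------------------
# Matrices


def _check_axes(df: pd.DataFrame, what: str) -> None:
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids in {what}: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate probe ids in {what}: {dupes}")


@dataclass(frozen=True)
class BetaMatrix:
    """Samples x probes matrix of methylation fractions in [0, 1].

    Missing values (NaN) are allowed and propagate to undetermined
    probe calls downstream.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_axes(self.values, "beta matrix")
        arr = self.values.to_numpy(dtype=float)
        bad = np.argwhere(~np.isnan(arr) & ((arr < 0.0) | (arr > 1.0)))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at sample "
                f"{self.values.index[i]!r}, probe {self.values.columns[j]!r}"
            )

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def probes(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


@dataclass(frozen=True)
class CallMatrix:
    """Samples x probes matrix of per-probe binary methylation calls."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_axes(self.values, "call matrix")
        flat = self.values.to_numpy(dtype=object).ravel()
        bad = [v for v in flat if v not in PROBE_CALLS]
        if bad:
            raise ValidationError(
                f"invalid call value {bad[0]!r}; expected one of {PROBE_CALLS}"
            )

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def probes(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


# --------------------------------------------------------------------------
# Panels


@dataclass(frozen=True)
class PanelDefinition:
    """A named probe set targeting one diagnosis, with a call cutoff.

    The default cutoff of 0.30 corresponds to the 30%-methylated control
    used to dichotomize melt-curve and array measurements.
    """

    name: str
    target_diagnosis: str
    probes: tuple[str, ...]
    cutoff: float = 0.30
    probe_gene_map: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.probes:
            raise ValidationError(f"panel {self.name!r} has no probes")
        if len(set(self.probes)) != len(self.probes):
            raise ValidationError(f"panel {self.name!r} has duplicate probes")
        if not 0.0 < self.cutoff < 1.0:
            raise ValidationError(
                f"panel {self.name!r} cutoff {self.cutoff} not in (0, 1)"
            )
        if not is_known_diagnosis(self.target_diagnosis):
            raise ValidationError(
                f"panel {self.name!r} targets unknown diagnosis "
                f"{self.target_diagnosis!r}"
            )
        object.__setattr__(self, "probes", tuple(self.probes))


# --------------------------------------------------------------------------
# Group counts (the published count-table shape)

_COUNT_COLUMNS = (
    "cohort",
    "diagnosis",
    "tissue",
    "n_methylated",
    "n_unmethylated",
    "n_undetermined",
)


@dataclass(frozen=True)
class GroupCounts:
    """Methylated/unmethylated tallies per (cohort, diagnosis, tissue)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"GroupCounts missing columns {missing}")
        df = df.loc[:, list(_COUNT_COLUMNS)].reset_index(drop=True)
        for col in _COUNT_COLUMNS[3:]:
            vals = df[col].to_numpy()
            if (vals < 0).any():
                raise ValidationError(f"negative count in column {col!r}")
            df[col] = vals.astype(int)
        keys = list(zip(df["cohort"], df["diagnosis"], df["tissue"]))
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (cohort, diagnosis, tissue) rows")
        object.__setattr__(self, "table", df)

    @classmethod
    def from_rows(
        cls,
        rows: Iterable[tuple[str, str, str, int, int] | tuple[str, str, str, int, int, int]],
    ) -> "GroupCounts":
        """Build from (cohort, diagnosis, tissue, n_meth, n_unmeth[, n_undet])."""
        norm = [tuple(r) + (0,) * (6 - len(r)) for r in rows]
        return cls(pd.DataFrame(norm, columns=list(_COUNT_COLUMNS)))

    def as_dict(self) -> dict[tuple[str, str, str], tuple[int, int, int]]:
        """Order-insensitive view keyed by (cohort, diagnosis, tissue)."""
        return {
            (r.cohort, r.diagnosis, r.tissue): (
                r.n_methylated,
                r.n_unmethylated,
                r.n_undetermined,
            )
            for r in self.table.itertuples()
        }

    def get(self, cohort: str, diagnosis: str, tissue: str) -> tuple[int, int, int]:
        return self.as_dict()[(cohort, diagnosis, tissue)]

    def total_samples(self) -> int:
        return int(
            self.table[["n_methylated", "n_unmethylated", "n_undetermined"]]
            .to_numpy()
            .sum()
        )

    def same_counts(self, other: "GroupCounts") -> bool:
        """Exact equality of tallies, ignoring row order."""
        return self.as_dict() == other.as_dict()


# Display-order helper shared by tabulation and report writers.
def canonical_sort_key(cohort: str, diagnosis: str, tissue: str) -> tuple:
    diag_order = {d: i for i, d in enumerate(known_diagnoses())}
    tissue_order = {TISSUE_TUMOR: 0, TISSUE_NORMAL: 1}
    return (
        cohort,
        diag_order.get(diagnosis, len(diag_order)),
        diagnosis,
        tissue_order.get(tissue, 2),
    )
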