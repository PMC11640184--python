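"""Synthetic cohorts with the statistical structure the pipeline assumes.

Two generators:

* `generate_cohort` draws beta values from a two-component mixture per
  sample and probe: with probability pi the value comes from a
  high-methylation beta component (mean above the cutoff), otherwise
  from a low-methylation component (mean below it).  Components are
  parameterized by (mean, concentration), the natural reading for
  methylation data; internally mean m and concentration k map to a
  Beta(m*k, (1-m)*k) distribution.  Probes are independent.

* `fixture_from_counts` deterministically materializes per-sample panel
  calls from published group tallies, so count-only results can be
  pushed through the full pipeline.  `builtin_cohort_fixtures` embeds
  the six published panel x cohort count tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .errors import ValidationError
from .published import (
    COHORTS,
    PANELS,
    published_group_counts,
)
from .types import (
    BetaMatrix,
    CallMatrix,
    GroupCounts,
    METHYLATED,
    PanelDefinition,
    SampleRecord,
    TISSUE_NORMAL,
    TISSUE_TUMOR,
    UNMETHYLATED,
    validate_sheet,
)

# Default component shapes: unmethylated loci sit near zero with little
# spread, as in normalized array data; hypermethylated loci center around
# 0.7 with wider spread (tumor cellularity, partial methylation).
DEFAULT_M_LO = 0.08
DEFAULT_KAPPA_LO = 30.0
DEFAULT_M_HI = 0.70
DEFAULT_KAPPA_HI = 15.0


def _component_params(mean: float, kappa: float) -> tuple[float, float]:
    if not 0.0 < mean < 1.0:
        raise ValidationError(f"component mean {mean} not in (0, 1)")
    if kappa <= 0.0:
        raise ValidationError(f"component concentration {kappa} must be > 0")
    return mean * kappa, (1.0 - mean) * kappa


@dataclass(frozen=True)
class GroupGenSpec:
    """Generator settings for one (cohort, diagnosis, tissue) group.

    ``pi`` is the per-probe probability that a value is drawn from the
    high-methylation component; a scalar applies to every probe, a
    mapping sets it per probe (missing probes fall back to 0).
    """

    diagnosis: str
    tissue: str
    cohort: str
    n: int
    pi: float | Mapping[str, float]
    m_hi: float = DEFAULT_M_HI
    kappa_hi: float = DEFAULT_KAPPA_HI
    m_lo: float = DEFAULT_M_LO
    kappa_lo: float = DEFAULT_KAPPA_LO
    cutoff: float = 0.30

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError("group size n must be >= 0")
        if not 0.0 < self.cutoff < 1.0:
            raise ValidationError(f"cutoff {self.cutoff} not in (0, 1)")
        if not self.cutoff < self.m_hi <= 1.0:
            raise ValidationError(
                f"high-component mean {self.m_hi} must lie in (cutoff, 1]"
            )
        if not 0.0 <= self.m_lo < self.cutoff:
            raise ValidationError(
                f"low-component mean {self.m_lo} must lie in [0, cutoff)"
            )
        _component_params(self.m_hi, self.kappa_hi)
        _component_params(self.m_lo, self.kappa_lo)
        for p in self._pi_values():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"mixture weight pi={p} not in [0, 1]")

    def _pi_values(self) -> tuple[float, ...]:
        if isinstance(self.pi, Mapping):
            return tuple(float(v) for v in self.pi.values())
        return (float(self.pi),)

    def pi_for(self, probe: str) -> float:
        if isinstance(self.pi, Mapping):
            return float(self.pi.get(probe, 0.0))
        return float(self.pi)


def exceedance_probability(spec: GroupGenSpec, probe: str) -> float:
    """P(beta >= cutoff) under the group's mixture, in closed form."""
    a_hi, b_hi = _component_params(spec.m_hi, spec.kappa_hi)
    a_lo, b_lo = _component_params(spec.m_lo, spec.kappa_lo)
    pi = spec.pi_for(probe)
    return float(
        pi * beta_dist.sf(spec.cutoff, a_hi, b_hi)
        + (1.0 - pi) * beta_dist.sf(spec.cutoff, a_lo, b_lo)
    )


def panel_positive_probability(spec: GroupGenSpec, probes: Sequence[str]) -> float:
    """P(any probe >= cutoff) under independence across probes."""
    miss = 1.0
    for probe in probes:
        miss *= 1.0 - exceedance_probability(spec, probe)
    return 1.0 - miss


def generate_cohort(
    specs: Sequence[GroupGenSpec],
    probes: Sequence[str],
    seed: int,
) -> tuple[BetaMatrix, list[SampleRecord]]:
    """Draw a reproducible beta-value cohort from group specs.

    Sample ids are '<cohort>_<diagnosis>_<tissue>_<k>'; identical
    (specs, probes, seed) yield identical output.
    """
    if not probes:
        raise ValidationError("generate_cohort requires at least one probe")
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    records: list[SampleRecord] = []
    for spec in specs:
        a_hi, b_hi = _component_params(spec.m_hi, spec.kappa_hi)
        a_lo, b_lo = _component_params(spec.m_lo, spec.kappa_lo)
        pis = np.array([spec.pi_for(p) for p in probes])
        use_hi = rng.random((spec.n, len(probes))) < pis
        hi = rng.beta(a_hi, b_hi, size=(spec.n, len(probes)))
        lo = rng.beta(a_lo, b_lo, size=(spec.n, len(probes)))
        rows.append(np.where(use_hi, hi, lo))
        for k in range(1, spec.n + 1):
            records.append(
                SampleRecord(
                    sample_id=f"{spec.cohort}_{spec.diagnosis}_{spec.tissue}_{k:04d}",
                    diagnosis=spec.diagnosis,
                    tissue=spec.tissue,
                    cohort=spec.cohort,
                )
            )
    validate_sheet(records)
    values = np.vstack(rows) if rows else np.empty((0, len(probes)))
    matrix = BetaMatrix(
        pd.DataFrame(
            values, index=[r.sample_id for r in records], columns=list(probes)
        )
    )
    return matrix, records


# --------------------------------------------------------------------------
# Deterministic count fixtures


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for materializing per-sample calls from group tallies."""

    counts: GroupCounts
    panel: PanelDefinition
    pair_balanced_groups: bool = True
    id_width: int = 3


def fixture_from_counts(
    spec: FixtureSpec,
) -> tuple[CallMatrix, list[SampleRecord]]:
    """Materialize exactly the given tallies as panel-level probe calls.

    Per group, the methylated block comes first, ids are zero-padded so
    lexicographic order matches construction order.  A panel-positive
    sample carries a methylated call on the panel's first probe and
    unmethylated elsewhere (the fixtures encode the panel call, not a
    probe-level pattern).  When ``pair_balanced_groups`` is set,
    diagnoses whose tumor and normal blocks are the same size get pair
    ids linking the k-th tumor with the k-th normal.
    """
    probes = list(spec.panel.probes)
    width = spec.id_width
    records: list[SampleRecord] = []
    call_rows: list[list[str]] = []

    table = spec.counts.table
    sizes: dict[tuple[str, str, str], int] = {
        (r.cohort, r.diagnosis, r.tissue): r.n_methylated + r.n_unmethylated
        for r in table.itertuples()
    }
    for row in table.itertuples():
        key = (row.cohort, row.diagnosis, row.tissue)
        other = (
            row.cohort,
            row.diagnosis,
            TISSUE_NORMAL if row.tissue == TISSUE_TUMOR else TISSUE_TUMOR,
        )
        paired = (
            spec.pair_balanced_groups
            and other in sizes
            and sizes[other] == sizes[key]
        )
        total = row.n_methylated + row.n_unmethylated
        for k in range(1, total + 1):
            methylated = k <= row.n_methylated
            records.append(
                SampleRecord(
                    sample_id=f"{row.cohort}_{row.diagnosis}_{row.tissue}_{k:0{width}d}",
                    diagnosis=row.diagnosis,
                    tissue=row.tissue,
                    cohort=row.cohort,
                    pair_id=(
                        f"{row.cohort}_{row.diagnosis}_pair{k:0{width}d}"
                        if paired
                        else None
                    ),
                )
            )
            call_rows.append(
                [METHYLATED if methylated and i == 0 else UNMETHYLATED
                 for i in range(len(probes))]
            )
    validate_sheet(records)
    matrix = CallMatrix(
        pd.DataFrame(
            call_rows, index=[r.sample_id for r in records], columns=probes
        )
    )
    return matrix, records


def builtin_cohort_fixtures() -> dict[str, tuple[CallMatrix, list[SampleRecord], PanelDefinition]]:
    """Embedded fixtures for the six published panel x cohort tables.

    Keys: 'gac-mshrm', 'gac-geo', 'gac-tcga', 'luad-mshrm', 'luad-geo',
    'luad-tcga'.  Tabulating each fixture recovers the published counts
    exactly.
    """
    out: dict[str, tuple[CallMatrix, list[SampleRecord], PanelDefinition]] = {}
    for panel_name, panel in PANELS.items():
        for cohort in COHORTS:
            key = f"{panel_name.lower()}-{cohort.lower().replace('-', '')}"
            counts = published_group_counts(panel_name, cohort)
            matrix, records = fixture_from_counts(
                FixtureSpec(counts=counts, panel=panel)
            )
            out[key] = (matrix, records, panel)
    return out


FIXTURE_KEYS = tuple(
    f"{p.lower()}-{c.lower().replace('-', '')}" for p in PANELS for c in COHORTS
)
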