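"""Mann-Whitney AUC with midrank ties and the DeLong variance estimator.

The AUC is the probability that a randomly chosen positive sample scores
above a randomly chosen negative one, ties counted half.  Its sampling
variance comes from the nonparametric structural-components (placement
value) estimator: with positives X_1..X_m and negatives Y_1..Y_n,

    V10_i = mean_j [ X_i > Y_j ] + 1/2 [ X_i = Y_j ]
    V01_j = mean_i [ X_i > Y_j ] + 1/2 [ X_i = Y_j ]
    var(AUC) = S10 / m + S01 / n

where S10, S01 are the sample variances of the placement values.  The
confidence interval is the normal approximation truncated to [0, 1], and
the test of AUC != 0.5 is a two-sided Z-test.  For a binary 0/1 score the
AUC reduces exactly to (sensitivity + specificity) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .errors import DataError, ValidationError

_DEGENERATE_VAR = 1e-300


@dataclass(frozen=True)
class RocResult:
    """AUC point estimate with DeLong variance, CI and Z-test p-value."""

    auc: float
    variance: float
    ci_low: float
    ci_high: float
    p_value: float | None
    n_pos: int
    n_neg: int
    level: float = 0.95
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "variance": self.variance,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "level": self.level,
            "degenerate": self.degenerate,
        }


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be 1-D and equal length")
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise DataError(
            "AUC undefined: need at least one positive and one negative sample"
        )
    return pos, neg


def _placements(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and per-sample placement values via midranks (O(n log n))."""
    pos, neg = _split(scores, labels)
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    return float(auc), v10, v01


def auc_mann_whitney(scores, labels) -> float:
    """Midrank Mann-Whitney AUC (ties counted half)."""
    auc, _, _ = _placements(scores, labels)
    return auc


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance).  Requires >= 2 samples per class."""
    auc, v10, v01 = _placements(scores, labels)
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise DataError(
            "DeLong variance needs at least two samples in each class"
        )
    s10 = float(np.var(v10, ddof=1))
    s01 = float(np.var(v01, ddof=1))
    return auc, s10 / m + s01 / n


def auc_z_test(auc: float, variance: float, null_auc: float = 0.5) -> float:
    """Two-sided p-value for AUC != null_auc under normal approximation."""
    if variance <= 0.0:
        raise DataError("Z-test undefined for zero AUC variance")
    z = (auc - null_auc) / np.sqrt(variance)
    return float(2.0 * norm.sf(abs(z)))


def delong_ci(scores, labels, level: float = 0.95) -> RocResult:
    """AUC with DeLong normal-approximation CI and Z-test vs 0.5.

    A zero variance (perfectly separated or constant scores) is flagged
    degenerate: the CI collapses to the point and the p-value is None.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"confidence level {level} not in (0, 1)")
    auc, variance = delong_variance(scores, labels)
    pos, neg = _split(scores, labels)
    if variance <= _DEGENERATE_VAR:
        return RocResult(
            auc=auc, variance=0.0, ci_low=auc, ci_high=auc, p_value=None,
            n_pos=len(pos), n_neg=len(neg), level=level, degenerate=True,
        )
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(variance)
    return RocResult(
        auc=auc,
        variance=variance,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        p_value=auc_z_test(auc, variance),
        n_pos=len(pos),
        n_neg=len(neg),
        level=level,
    )


# --------------------------------------------------------------------------
# Scores from panel calls

SCORE_MODES = ("binary", "probe-count", "max-beta")


def scores_from_calls(
    callset,
    frame,
    score: str = "binary",
    beta=None,
) -> tuple[np.ndarray, np.ndarray]:
    """(scores, labels) arrays for a comparison frame.

    ``binary`` scores the panel call 0/1 (the published analysis);
    ``probe-count`` scores the number of methylated panel probes;
    ``max-beta`` scores the maximum beta over panel probes and requires
    the beta matrix.  Undetermined panel calls are dropped.
    """
    from .types import BetaMatrix, METHYLATED, POSITIVE, UNDETERMINED

    if score not in SCORE_MODES:
        raise ValidationError(
            f"unknown score mode {score!r}; expected one of {SCORE_MODES}"
        )
    if score == "max-beta":
        if not isinstance(beta, BetaMatrix):
            raise ValidationError("score mode 'max-beta' requires a beta matrix")
        probes = [p for p in callset.probe_calls.columns if p in beta.values.columns]
        per_sample = beta.values.loc[:, probes].max(axis=1)

    scores_out: list[float] = []
    labels_out: list[bool] = []
    for label, ids in ((True, frame.positives), (False, frame.negatives)):
        for sample_id in ids:
            if sample_id not in callset.calls.index:
                raise DataError(f"frame sample {sample_id!r} has no panel call")
            call = callset.calls[sample_id]
            if call == UNDETERMINED:
                continue
            if score == "binary":
                value = 1.0 if call == POSITIVE else 0.0
            elif score == "probe-count":
                value = float(
                    (callset.probe_calls.loc[sample_id] == METHYLATED).sum()
                )
            else:
                value = float(per_sample.loc[sample_id])
            scores_out.append(value)
            labels_out.append(label)
    return np.asarray(scores_out), np.asarray(labels_out, dtype=bool)


def roc_analysis(
    callset, frame, score: str = "binary", beta=None, level: float = 0.95
) -> RocResult:
    """DeLong ROC analysis of a panel call set under one framing."""
    scores, labels = scores_from_calls(callset, frame, score=score, beta=beta)
    return delong_ci(scores, labels, level=level)
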