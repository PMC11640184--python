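"""Mann-Whitney AUC, DeLong variance and the Z-test against 0.5."""

import subprocess
import sys
import textwrap

import numpy as np
import pytest
from scipy.stats import norm

import methpanel as mp


def pairwise_auc(scores, labels):
    """Exhaustive O(n^2) pair-counting oracle."""
    pos = scores[labels]
    neg = scores[~labels]
    diff = pos[:, None] - neg[None, :]
    return ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg))


def placement_variance(scores, labels):
    """Direct placement-value (structural components) oracle."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    v10 = np.array([((x > neg).sum() + 0.5 * (x == neg).sum()) / n for x in pos])
    v01 = np.array([((pos > y).sum() + 0.5 * (pos == y).sum()) / m for y in neg])
    return np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n


def random_instance(rng):
    n = rng.integers(6, 200)
    m = rng.integers(2, n - 2 + 1)
    labels = np.zeros(n, dtype=bool)
    labels[:m] = True
    rng.shuffle(labels)
    if rng.random() < 0.5:  # heavy ties, including binary scores
        scores = rng.integers(0, rng.integers(2, 6), size=n).astype(float)
    else:
        scores = rng.normal(size=n) + labels
    return scores, labels


def test_midrank_auc_equals_pair_counting():
    rng = np.random.default_rng(7)
    for _ in range(30):
        scores, labels = random_instance(rng)
        assert mp.auc_mann_whitney(scores, labels) == pytest.approx(
            pairwise_auc(scores, labels), abs=1e-12
        )


def test_delong_variance_equals_placement_oracle():
    rng = np.random.default_rng(8)
    for _ in range(30):
        scores, labels = random_instance(rng)
        auc, var = mp.delong_variance(scores, labels)
        assert var == pytest.approx(placement_variance(scores, labels), abs=1e-12)


def test_label_swap_antisymmetry():
    rng = np.random.default_rng(9)
    for _ in range(10):
        scores, labels = random_instance(rng)
        a = mp.auc_mann_whitney(scores, labels)
        b = mp.auc_mann_whitney(scores, ~labels)
        assert a + b == pytest.approx(1.0, abs=1e-12)


def test_delong_variance_invariant_under_monotone_transform():
    rng = np.random.default_rng(10)
    scores, labels = random_instance(rng)
    _, v1 = mp.delong_variance(scores, labels)
    _, v2 = mp.delong_variance(np.exp(3 * scores), labels)
    assert v1 == pytest.approx(v2, abs=1e-12)


def test_binary_auc_is_mean_of_sensitivity_and_specificity(cohort_fixtures):
    for key, (matrix, records, panel) in cohort_fixtures.items():
        calls = mp.apply_panel(matrix, panel, records)
        frame = mp.frame_comparison("all_samples", panel.target_diagnosis, records)
        scores, labels = mp.scores_from_calls(calls, frame)
        auc = mp.auc_mann_whitney(scores, labels)
        c = mp.confusion(calls, frame)
        sens = c.tp / (c.tp + c.fn)
        spec = c.tn / (c.tn + c.fp)
        assert auc == pytest.approx((sens + spec) / 2, abs=1e-12), key


def test_trivial_aucs():
    assert mp.auc_mann_whitney([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
    assert mp.auc_mann_whitney([5, 5, 5, 5], [1, 0, 1, 0]) == 0.5


def test_single_class_input_is_an_error():
    with pytest.raises(mp.DataError):
        mp.auc_mann_whitney([1.0, 2.0], [True, True])


def test_z_test_values():
    assert mp.auc_z_test(0.5, 0.01) == pytest.approx(1.0)
    variance = ((0.6 - 0.5) / 1.959963984540054) ** 2
    assert mp.auc_z_test(0.6, variance) == pytest.approx(0.05, abs=1e-9)
    with pytest.raises(mp.DataError):
        mp.auc_z_test(0.7, 0.0)


def test_perfect_separation_is_flagged_degenerate():
    scores = np.array([0.0, 0.1, 0.9, 1.0])
    labels = np.array([False, False, True, True])
    res = mp.delong_ci(scores, labels)
    assert res.degenerate and res.variance == 0.0
    assert (res.ci_low, res.ci_high) == (1.0, 1.0)
    assert res.p_value is None


def test_ci_brackets_auc_on_gac_fixture(gac_mshrm):
    matrix, records, panel = gac_mshrm
    calls = mp.apply_panel(matrix, panel, records)
    frame = mp.frame_comparison("all_samples", "GAC", records)
    res = mp.roc_analysis(calls, frame)
    assert res.ci_low < res.auc < res.ci_high
    assert not res.degenerate
    z = norm.ppf(0.975)
    assert res.ci_high - res.ci_low == pytest.approx(
        2 * z * np.sqrt(res.variance), abs=1e-12
    )


def test_probe_count_and_max_beta_scores():
    import pandas as pd

    df = pd.DataFrame(
        {"cg_a": [0.9, 0.4, 0.1, 0.05], "cg_b": [0.8, 0.1, 0.2, 0.02]},
        index=["p1", "p2", "n1", "n2"],
    )
    beta = mp.BetaMatrix(df)
    sheet = [
        mp.SampleRecord("p1", "GAC", "TP", "c"),
        mp.SampleRecord("p2", "GAC", "TP", "c"),
        mp.SampleRecord("n1", "GAC", "NAT", "c"),
        mp.SampleRecord("n2", "GAC", "NAT", "c"),
    ]
    panel = mp.PanelDefinition("p", "GAC", ("cg_a", "cg_b"))
    calls = mp.apply_panel(beta, panel, sheet)
    frame = mp.frame_comparison("target_vs_nat", "GAC", sheet)
    s_count, _ = mp.scores_from_calls(calls, frame, score="probe-count")
    assert list(s_count) == [2.0, 1.0, 0.0, 0.0]
    s_max, _ = mp.scores_from_calls(calls, frame, score="max-beta", beta=beta)
    assert list(s_max) == [0.9, 0.4, 0.2, 0.05]


def test_delong_matches_independent_r_implementation(tmp_path):
    """Cross-check AUC, variance-based CI and p-value against pROC."""
    rng = np.random.default_rng(42)
    scores = np.round(rng.normal(size=40) + np.r_[np.ones(15), np.zeros(25)], 2)
    labels = np.r_[np.ones(15), np.zeros(25)].astype(bool)
    ours = mp.delong_ci(scores, labels)

    script = tmp_path / "roc.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(pROC))
        scores <- c({', '.join(map(str, scores))})
        labels <- c({', '.join('1' if l else '0' for l in labels)})
        r <- roc(labels, scores, quiet=TRUE, direction="<")
        ci <- ci.auc(r, method="delong")
        cat(sprintf("%.12f %.12f %.12f %.12f\\n",
            as.numeric(auc(r)), ci[1], ci[3], sqrt(var(r, method="delong"))))
    """))
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    )
    r_auc, r_lo, r_hi, r_sd = map(float, out.stdout.split())
    assert ours.auc == pytest.approx(r_auc, abs=1e-10)
    assert np.sqrt(ours.variance) == pytest.approx(r_sd, abs=1e-10)
    assert ours.ci_low == pytest.approx(r_lo, abs=1e-9)
    assert ours.ci_high == pytest.approx(r_hi, abs=1e-9)
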