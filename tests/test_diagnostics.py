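"""Comparison framings, confusion matrices, metrics and formatting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import methpanel as mp
from methpanel.diagnostics import _estimate


def test_frame_sizes_on_the_mshrm_cohort(mshrm_sheet):
    f = mp.frame_comparison("all_samples", "GAC", mshrm_sheet)
    assert (len(f.positives), len(f.negatives)) == (14, 164)
    f = mp.frame_comparison("target_vs_nat", "GAC", mshrm_sheet)
    assert (len(f.positives), len(f.negatives)) == (14, 14)
    f = mp.frame_comparison("all_tumors", "LUAD", mshrm_sheet)
    assert (len(f.positives), len(f.negatives)) == (15, 74)


def test_all_samples_negatives_include_target_normals(mshrm_sheet):
    frame = mp.frame_comparison("all_samples", "GAC", mshrm_sheet)
    gac_nats = {
        r.sample_id for r in mshrm_sheet
        if r.diagnosis == "GAC" and r.tissue == "NAT"
    }
    assert gac_nats <= set(frame.negatives)


def test_unknown_framing_rejected(mshrm_sheet):
    with pytest.raises(mp.ConfigurationError):
        mp.frame_comparison("versus", "GAC", mshrm_sheet)


def test_confusion_on_gac_fixture_target_vs_nat(gac_mshrm):
    matrix, records, panel = gac_mshrm
    calls = mp.apply_panel(matrix, panel, records)
    frame = mp.frame_comparison("target_vs_nat", "GAC", records)
    c = mp.confusion(calls, frame)
    assert (c.tp, c.fn, c.fp, c.tn) == (11, 3, 1, 13)


def test_confusion_on_luad_fixture_all_samples(luad_mshrm):
    matrix, records, panel = luad_mshrm
    calls = mp.apply_panel(matrix, panel, records)
    frame = mp.frame_comparison("all_samples", "LUAD", records)
    c = mp.confusion(calls, frame)
    assert (c.fp, c.tn) == (36, 127)


@pytest.mark.parametrize(
    "confusion_counts, expected",
    [
        # published MS-HRM target-vs-normal columns for both panels
        ((11, 3, 1, 13), ("78.6%", "92.9%", "85.7%", "91.7%", "81.3%")),
        ((14, 1, 2, 13), ("93.3%", "86.7%", "90.0%", "87.5%", "92.9%")),
    ],
)
def test_metrics_match_published_cells(confusion_counts, expected):
    tp, fn, fp, tn = confusion_counts
    m = mp.metrics(mp.ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn))
    got = tuple(
        m[k].percent for k in ("sensitivity", "specificity", "accuracy", "ppv", "npv")
    )
    assert got == expected


def test_empty_positive_class_gives_undefined_sensitivity():
    m = mp.metrics(mp.ConfusionCounts(tp=0, fn=0, fp=0, tn=10))
    assert m["sensitivity"].value is None and m["sensitivity"].percent == "NA"
    assert m["specificity"].percent == "100.0%"
    m = mp.metrics(mp.ConfusionCounts(tp=0, fn=0, fp=0, tn=0))
    assert all(v.value is None for v in m.values())


@pytest.mark.parametrize(
    "fraction, expected",
    [
        (11 / 14, "78.6%"),
        (0.0, "0.0%"),
        (1.0, "100.0%"),
        (1 / 68, "1.5%"),
        (13 / 16, "81.3%"),  # 81.25 rounds half-up, not to even
        (11 / 21, "52.4%"),
        (0.8666666666, "86.7%"),
    ],
)
def test_format_percent(fraction, expected):
    assert mp.format_percent(fraction) == expected


_counts = st.integers(min_value=0, max_value=400)


@given(tp=_counts, fn=_counts, fp=_counts, tn=_counts)
def test_accuracy_is_prevalence_weighted_average(tp, fn, fp, tn):
    c = mp.ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)
    m = mp.metrics(c)
    if c.n == 0:
        assert m["accuracy"].value is None
        return
    acc = m["accuracy"].value
    p, n = tp + fn, fp + tn
    sens, spec = m["sensitivity"].value, m["specificity"].value
    weighted = ((sens or 0.0) * p + (spec or 0.0) * n) / (p + n)
    assert acc == pytest.approx(weighted, abs=1e-12)
    assert acc == pytest.approx((tp + tn) / c.n, abs=1e-12)


@given(num=st.integers(0, 200), den=st.integers(1, 200))
def test_ci_brackets_point_estimate_within_unit_interval(num, den):
    num = min(num, den)
    est = _estimate(num, den, 0.95)
    assert 0.0 <= est.ci_low <= est.value <= est.ci_high <= 1.0


@pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
def test_ci_width_shrinks_with_sample_size(p):
    widths = []
    for n in (14, 89, 500):
        est = _estimate(round(p * n), n, 0.95)
        widths.append(est.ci_high - est.ci_low)
    assert widths[0] > widths[1] > widths[2]


def test_diagnostic_report_table_shape(gac_mshrm):
    matrix, records, panel = gac_mshrm
    calls = mp.apply_panel(matrix, panel, records)
    report = mp.diagnostic_report(calls, records, target="GAC", cohort="MS-HRM")
    table = report.percent_table()
    assert list(table.columns) == list(mp.FRAMINGS)
    assert table.loc["sensitivity", "target_vs_nat"] == "78.6%"
    payload = report.to_dict()
    assert payload["framings"]["target_vs_nat"]["confusion"]["tp"] == 11
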