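"""Probe binarization, OR-rule panel calls and group tabulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import methpanel as mp


@pytest.mark.parametrize(
    "beta, strict, expected",
    [
        (0.30, False, "methylated"),  # inclusive rule at the control level
        (0.30, True, "unmethylated"),
        (0.0, False, "unmethylated"),
        (1.0, False, "methylated"),
        (0.29999, False, "unmethylated"),
        (None, False, "undetermined"),
        (float("nan"), False, "undetermined"),
    ],
)
def test_binarize_probe(beta, strict, expected):
    assert mp.binarize_probe(beta, 0.30, strict=strict) == expected


def test_binarize_probe_rejects_bad_inputs():
    with pytest.raises(mp.ValidationError):
        mp.binarize_probe(1.2, 0.3)
    with pytest.raises(mp.ValidationError):
        mp.binarize_probe(0.5, 1.5)


@pytest.mark.parametrize(
    "calls, expected",
    [
        (("unmethylated", "methylated", "unmethylated"), "positive"),
        (("unmethylated", "unmethylated", "unmethylated"), "negative"),
        (("undetermined", "undetermined", "methylated"), "positive"),
        (("undetermined", "undetermined", "undetermined"), "undetermined"),
        (("undetermined", "unmethylated"), "negative"),
        (("methylated",), "positive"),
    ],
)
def test_call_panel_or_rule(calls, expected):
    assert mp.call_panel(calls) == expected


def test_call_panel_requires_probes():
    with pytest.raises(mp.ValidationError):
        mp.call_panel(())


def test_apply_panel_reproduces_published_gac_tumor_counts(gac_mshrm):
    matrix, records, panel = gac_mshrm
    counts = mp.tabulate_counts(mp.apply_panel(matrix, panel, records), records)
    assert counts.get("MS-HRM", "GAC", "TP")[:2] == (11, 3)


def test_tabulate_reproduces_published_luad_rows(luad_mshrm):
    matrix, records, panel = luad_mshrm
    counts = mp.tabulate_counts(mp.apply_panel(matrix, panel, records), records)
    assert counts.get("MS-HRM", "LUAD", "TP")[:2] == (14, 1)
    assert counts.get("MS-HRM", "GAC", "TP")[:2] == (5, 9)


def test_partial_probe_overlap_equals_single_probe_calls():
    df = pd.DataFrame(
        {"cg_a": [0.1, 0.4, np.nan, 0.31]},
        index=[f"s{i}" for i in range(4)],
    )
    matrix = mp.BetaMatrix(df)
    sheet = [mp.SampleRecord(f"s{i}", "GAC", "TP", "c") for i in range(4)]
    panel = mp.PanelDefinition("p", "GAC", ("cg_a", "cg_b", "cg_c"), cutoff=0.3)
    calls = mp.apply_panel(matrix, panel, sheet)
    for sample_id, beta in df["cg_a"].items():
        single = mp.binarize_probe(None if pd.isna(beta) else beta, 0.3)
        expected = {
            "methylated": "positive",
            "unmethylated": "negative",
            "undetermined": "undetermined",
        }[single]
        assert calls.calls[sample_id] == expected


def test_zero_probe_overlap_is_configuration_error():
    matrix = mp.BetaMatrix(pd.DataFrame({"cg_x": [0.5]}, index=["s0"]))
    sheet = [mp.SampleRecord("s0", "GAC", "TP", "c")]
    with pytest.raises(mp.ConfigurationError, match="GAC"):
        mp.apply_panel(matrix, mp.GAC_PANEL, sheet)


def test_samples_missing_from_sheet_are_dropped(caplog):
    matrix = mp.BetaMatrix(
        pd.DataFrame({"cg_a": [0.5, 0.1]}, index=["known", "stray"])
    )
    sheet = [mp.SampleRecord("known", "GAC", "TP", "c")]
    panel = mp.PanelDefinition("p", "GAC", ("cg_a",))
    with caplog.at_level("WARNING"):
        calls = mp.apply_panel(matrix, panel, sheet)
    assert list(calls.calls.index) == ["known"]
    assert any("stray" in m for m in caplog.messages)


def test_tabulate_rejects_calls_for_unknown_samples(gac_mshrm):
    matrix, records, panel = gac_mshrm
    calls = mp.apply_panel(matrix, panel, records)
    with pytest.raises(mp.DataError, match="absent from the sheet"):
        mp.tabulate_counts(calls, records[100:])


def test_undetermined_samples_counted_separately():
    df = pd.DataFrame({"cg_a": [np.nan, 0.9, 0.1]}, index=["u", "m", "n"])
    sheet = [mp.SampleRecord(s, "GAC", "TP", "c") for s in ("u", "m", "n")]
    panel = mp.PanelDefinition("p", "GAC", ("cg_a",))
    counts = mp.tabulate_counts(mp.apply_panel(mp.BetaMatrix(df), panel, sheet), sheet)
    assert counts.get("c", "GAC", "TP") == (1, 1, 1)


def test_call_matrix_input_ignores_cutoff(gac_mshrm):
    matrix, records, panel = gac_mshrm
    low = mp.PanelDefinition("GAC", "GAC", panel.probes, cutoff=0.05)
    high = mp.PanelDefinition("GAC", "GAC", panel.probes, cutoff=0.95)
    c1 = mp.apply_panel(matrix, low, records)
    c2 = mp.apply_panel(matrix, high, records)
    assert c1.calls.equals(c2.calls)


_betas = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    min_size=1,
    max_size=6,
)


@given(betas=_betas, bump_index=st.integers(min_value=0, max_value=5),
       bump=st.floats(min_value=0.0, max_value=1.0))
def test_raising_a_beta_never_flips_positive_to_negative(betas, bump_index, bump):
    i = bump_index % len(betas)
    raised = list(betas)
    raised[i] = min(1.0, raised[i] + bump)
    calls = [mp.binarize_probe(b, 0.3) for b in betas]
    raised_calls = [mp.binarize_probe(b, 0.3) for b in raised]
    before, after = mp.call_panel(calls), mp.call_panel(raised_calls)
    assert not (before == "positive" and after == "negative")


@given(betas=_betas, c1=st.floats(min_value=0.01, max_value=0.99),
       c2=st.floats(min_value=0.01, max_value=0.99))
def test_lowering_cutoff_never_loses_positives(betas, c1, c2):
    lo, hi = min(c1, c2), max(c1, c2)
    pos_lo = mp.call_panel([mp.binarize_probe(b, lo) for b in betas]) == "positive"
    pos_hi = mp.call_panel([mp.binarize_probe(b, hi) for b in betas]) == "positive"
    assert pos_lo or not pos_hi


@given(betas=_betas, extra=st.floats(min_value=0.0, max_value=1.0))
def test_adding_a_probe_never_decreases_positivity(betas, extra):
    before = mp.call_panel([mp.binarize_probe(b, 0.3) for b in betas])
    after = mp.call_panel([mp.binarize_probe(b, 0.3) for b in betas + [extra]])
    assert not (before == "positive" and after != "positive")
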