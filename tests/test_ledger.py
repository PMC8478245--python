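"""Cost-ledger construction, time pricing, and arm-level aggregation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecdeval as e
from ecdeval.ledger import LedgerError, breakdown_record

amounts = st.floats(0, 1e6, allow_nan=False, allow_infinity=False)


def _line(amount, category="personnel", perspective="provider_direct", arm="group_only"):
    return e.CostLine(
        label="x",
        category=category,
        perspective=perspective,
        arm=arm,
        amount_usd=amount,
    )


@pytest.mark.parametrize(
    "hours, wage, expected",
    [
        (0.0, 0.58, 0.0),
        (156.0, 0.19, 29.64),  # 1 h/week over 3 years at the mother wage
        (18.5, 0.58, 10.73),  # extra home-visit delivery time per CHV
    ],
)
def test_price_time(hours, wage, expected):
    assert e.price_time(hours, wage) == pytest.approx(expected)


@pytest.mark.parametrize("hours, wage", [(-1.0, 0.5), (1.0, -0.5)])
def test_price_time_rejects_negative(hours, wage):
    with pytest.raises(LedgerError):
        e.price_time(hours, wage)


def test_mother_session_hours_group_only():
    """64% attendance x 16 sessions x (1.5 h + 0.66 h travel) = 22.12 h."""
    sched = e.default_schedules()["group_only"]
    assert e.mother_session_hours(sched) == pytest.approx(22.1184)


def test_mother_session_hours_mixed_and_zero_attendance():
    """Home visits add their duration but no mother travel time."""
    sched = e.default_schedules()["mixed"]
    expected = 0.74 * (12 * (1.5 + 0.66) + 4 * 1.0)
    assert e.mother_session_hours(sched) == pytest.approx(expected)
    none = e.ArmSchedule(
        n_group_sessions=16, n_home_visit_sessions=0, attendance_rate=0.0
    )
    assert e.mother_session_hours(none) == 0.0


def test_mother_opportunity_cost_attendance_switch():
    sched = e.default_schedules()["group_only"]
    params = e.TimeUseParams()
    full = e.mother_opportunity_cost(sched, params)
    scaled = e.mother_opportunity_cost(sched, params, attendance_scaled_behavior=True)
    assert scaled < full
    assert full == pytest.approx(400 * (22.1184 + 156.0) * 0.19)


def test_aggregate_reproduces_program_accounts(breakdowns):
    g, m = breakdowns["group_only"], breakdowns["mixed"]
    assert (g.direct_provider, g.indirect_provider) == (42693, 4730)
    assert g.societal_present == 8748
    assert g.total == 56171
    assert g.per_child_total == pytest.approx(140.4275)
    assert (m.direct_provider, m.indirect_provider) == (43940, 4730)
    assert m.societal_present == 9433
    assert m.total == 58103
    assert m.per_child_total == pytest.approx(145.2575)


def test_provider_totals_exclude_societal_lines(ledger_lines):
    provider_only = [ln for ln in ledger_lines if ln.perspective != "societal"]
    g = e.aggregate(provider_only, "group_only", 400)
    m = e.aggregate(provider_only, "mixed", 400)
    assert g.total == 47423 == e.aggregate(ledger_lines, "group_only", 400).total_provider
    assert m.total == 48670 == e.aggregate(ledger_lines, "mixed", 400).total_provider


def test_aggregate_empty_ledger_is_zero():
    b = e.aggregate([], "group_only", 400)
    assert (b.direct_provider, b.indirect_provider, b.societal_present) == (0, 0, 0)
    assert b.total == 0.0


def test_shared_lines_count_in_both_arms():
    shared = _line(100.0, arm="both")
    for arm in ("group_only", "mixed"):
        assert e.aggregate([shared], arm, 10).direct_provider == 100.0


def test_unknown_category_and_perspective_rejected():
    with pytest.raises(LedgerError, match="category"):
        e.CostLine(label="bad", category="catering", perspective="societal", arm="both")
    with pytest.raises(LedgerError, match="perspective"):
        e.CostLine(label="bad", category="venue", perspective="donor", arm="both")
    with pytest.raises(LedgerError, match="arm"):
        e.aggregate([], "control", 10)


@given(st.lists(amounts, min_size=1, max_size=12), st.randoms())
@settings(max_examples=50, deadline=None)
def test_aggregate_is_permutation_invariant(vals, rnd):
    lines = [
        _line(v, perspective=p)
        for v, p in zip(
            vals,
            ["provider_direct", "provider_indirect", "societal"] * len(vals),
        )
    ]
    base = e.aggregate(lines, "group_only", 7)
    shuffled = lines[:]
    rnd.shuffle(shuffled)
    assert e.aggregate(shuffled, "group_only", 7) == base


@given(amounts, st.floats(0.0, 1.0))
@settings(max_examples=50, deadline=None)
def test_splitting_a_line_preserves_the_breakdown(total, frac):
    whole = [_line(total)]
    parts = [_line(total * frac), _line(total * (1.0 - frac))]
    a = e.aggregate(whole, "group_only", 5)
    b = e.aggregate(parts, "group_only", 5)
    assert b.direct_provider == pytest.approx(a.direct_provider, abs=1e-9)
    assert b.total == pytest.approx(a.total, abs=1e-9)


@given(st.lists(amounts, max_size=8))
@settings(max_examples=50, deadline=None)
def test_all_monetary_outputs_nonnegative(vals):
    lines = [_line(v, perspective="societal") for v in vals]
    b = e.aggregate(lines, "group_only", 3)
    rec = breakdown_record(b)
    assert all(v >= 0 for k, v in rec.items() if k != "arm")


def test_amount_override_beats_unit_cost_times_quantity():
    line = e.CostLine(
        label="venue",
        category="venue",
        perspective="societal",
        arm="group_only",
        unit_cost=5.0,
        quantity=100.0,
        amount_usd=1652.0,
    )
    assert line.amount == 1652.0
    plain = e.CostLine(
        label="venue",
        category="venue",
        perspective="societal",
        arm="group_only",
        unit_cost=5.0,
        quantity=100.0,
    )
    assert plain.amount == 500.0


def test_ledger_file_roundtrip(tmp_path, ledger_lines, breakdowns):
    """YAML and CSV ledgers load to identical aggregates."""
    records = [
        {
            "label": ln.label,
            "category": ln.category,
            "perspective": ln.perspective,
            "arm": ln.arm,
            "amount_usd": ln.amount,
        }
        for ln in ledger_lines
    ]
    import yaml

    path = tmp_path / "ledger.yaml"
    path.write_text(yaml.safe_dump(records))
    again = e.read_ledger(path)
    assert e.aggregate(again, "mixed", 400) == breakdowns["mixed"]


def test_read_ledger_reports_offending_record(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "label,category,perspective,arm,unit_cost_usd,quantity,amount_usd\n"
        "ok,venue,societal,both,5,2,\n"
        "bad,nonsense,societal,both,1,1,\n"
    )
    with pytest.raises(LedgerError, match="record 2"):
        e.read_ledger(path)


def test_write_breakdowns_json(tmp_path, breakdowns):
    import json

    path = tmp_path / "costs.json"
    e.ledger.write_breakdowns(list(breakdowns.values()), path)
    rows = json.loads(path.read_text())
    assert rows[0]["total_costs"] == 56171
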