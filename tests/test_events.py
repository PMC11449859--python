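import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import brute_extremum_events, brute_run_events
from pepxai import (
    TimeSeriesDataset,
    extract_all,
    extract_extremum_events,
    extract_run_events,
    extract_series_events,
)
from pepxai.errors import SeriesTooShortError

# mixed integer/float values encourage plateaus and exact ties
series_strategy = st.lists(
    st.one_of(st.integers(-3, 3), st.floats(-3, 3, allow_nan=False, width=32)),
    min_size=2,
    max_size=30,
)


def as_tuples(run_events):
    return [(e.t_start, e.dura, e.grad_avg) for e in run_events]


def ex_tuples(extremum_events):
    return [(e.time, e.value) for e in extremum_events]


@pytest.mark.parametrize(
    "series, kind, expected",
    [
        ([5, 5, 5, 5], "increasing", []),
        ([0, 1, 2, 3], "increasing", [(0, 3, 1.0)]),
        ([0, 2, 1, 3, 3], "increasing", [(0, 1, 2.0), (2, 1, 2.0)]),
        ([0, 2, 1, 3, 3], "decreasing", [(1, 1, -1.0)]),
        ([3, 2, 1, 0], "decreasing", [(0, 3, -1.0)]),
    ],
)
def test_run_extraction_examples(series, kind, expected):
    assert as_tuples(extract_run_events(series, kind)) == expected


@pytest.mark.parametrize(
    "series, kind, expected",
    [
        ([0, 1, 2, 3], "local_max", []),
        ([0, 1, 2, 3], "local_min", []),
        ([0, 2, 1, 3, 0], "local_max", [(1, 2.0), (3, 3.0)]),
        ([0, 2, 1, 3, 0], "local_min", [(2, 1.0)]),
        ([0, 3, 3, 0], "local_max", [(1, 3.0)]),  # plateau anchored at onset
        ([0, 3, 3, 0], "local_min", []),
        ([1, 0], "local_max", []),  # too short: no error, no events
    ],
)
def test_extremum_extraction_examples(series, kind, expected):
    assert ex_tuples(extract_extremum_events(series, kind)) == expected


def test_too_short_series_raises_for_runs():
    with pytest.raises(SeriesTooShortError):
        extract_run_events([1.0], "increasing")


def test_single_triangle_series_all_kinds():
    inst = extract_series_events([0, 1, 0])
    assert as_tuples(inst.events["increasing"]) == [(0, 1, 1.0)]
    assert as_tuples(inst.events["decreasing"]) == [(1, 1, -1.0)]
    assert ex_tuples(inst.events["local_max"]) == [(1, 1.0)]
    assert inst.events["local_min"] == []


def test_min_dura_and_min_abs_grad_filters():
    series = [0, 1, 2, 1.95, 3]
    assert len(extract_run_events(series, "increasing")) == 2
    assert len(extract_run_events(series, "increasing", min_dura=2)) == 1
    assert len(extract_run_events(series, "decreasing", min_abs_grad=0.1)) == 0


@given(series_strategy)
def test_runs_match_brute_force(series):
    for kind in ("increasing", "decreasing"):
        got = as_tuples(extract_run_events(series, kind))
        want = brute_run_events([float(v) for v in series], kind)
        assert [(t, d) for t, d, _ in got] == [(t, d) for t, d, _ in want]
        np.testing.assert_allclose(
            [g for _, _, g in got], [g for _, _, g in want], rtol=1e-12, atol=0
        )


@given(series_strategy)
def test_extrema_match_brute_force(series):
    for kind in ("local_max", "local_min"):
        got = ex_tuples(extract_extremum_events(series, kind))
        want = brute_extremum_events([float(v) for v in series], kind)
        assert got == want


@given(series_strategy)
def test_mirror_symmetry(series):
    neg = [-float(v) for v in series]
    inc_of_neg = as_tuples(extract_run_events(neg, "increasing"))
    dec = as_tuples(extract_run_events(series, "decreasing"))
    assert [(t, d) for t, d, _ in inc_of_neg] == [(t, d) for t, d, _ in dec]
    np.testing.assert_allclose(
        [g for _, _, g in inc_of_neg], [-g for _, _, g in dec], rtol=1e-12, atol=0
    )
    assert ex_tuples(extract_extremum_events(neg, "local_max")) == [
        (t, -v) for t, v in ex_tuples(extract_extremum_events(series, "local_min"))
    ]


@given(series_strategy)
def test_runs_partition_difference_indices(series):
    x = np.asarray(series, dtype=float)
    inc = extract_run_events(x, "increasing")
    dec = extract_run_events(x, "decreasing")
    covered = set()
    for ev in inc + dec:
        span = set(range(ev.t_start, ev.t_start + ev.dura))
        assert not span & covered, "run events overlap"
        covered |= span
    zeros = {i for i in range(len(x) - 1) if x[i + 1] == x[i]}
    assert covered | zeros == set(range(len(x) - 1))
    assert not covered & zeros


@given(series_strategy, st.integers(-5, 5))
def test_translation_invariance(series, shift):
    # integer shifts keep first differences exactly representable, so the
    # structural claim is testable without float sign flips near zero
    x = [float(v) for v in series]
    shifted = [v + shift for v in x]
    base_runs = as_tuples(extract_run_events(x, "increasing"))
    moved_runs = as_tuples(extract_run_events(shifted, "increasing"))
    assert [(t, d) for t, d, _ in base_runs] == [(t, d) for t, d, _ in moved_runs]
    np.testing.assert_allclose(
        [g for *_, g in base_runs], [g for *_, g in moved_runs], rtol=0, atol=1e-9
    )
    base = ex_tuples(extract_extremum_events(x, "local_max"))
    moved = ex_tuples(extract_extremum_events(shifted, "local_max"))
    assert [t for t, _ in base] == [t for t, _ in moved]
    np.testing.assert_allclose(
        [v for _, v in moved], [v + shift for _, v in base], rtol=0, atol=1e-9
    )


@given(st.lists(st.floats(-3, 3, allow_nan=False), min_size=3, max_size=30))
def test_extrema_alternate_on_plateau_free_series(series):
    x = [float(v) for v in series]
    if any(x[i + 1] == x[i] for i in range(len(x) - 1)):
        return  # plateau: alternation not claimed
    maxima = [(t, "max") for t, _ in ex_tuples(extract_extremum_events(x, "local_max"))]
    minima = [(t, "min") for t, _ in ex_tuples(extract_extremum_events(x, "local_min"))]
    merged = sorted(maxima + minima)
    for (_, a), (_, b) in zip(merged, merged[1:]):
        assert a != b
    assert abs(len(maxima) - len(minima)) <= 1


def test_extract_all_composes_per_series_extraction(tiny_dataset):
    all_events = extract_all(tiny_dataset)
    assert [e.instance_id for e in all_events] == ["a", "b", "c"]
    for i, inst in enumerate(all_events):
        solo = extract_series_events(tiny_dataset.values[i])
        for kind, evs in solo.events.items():
            assert len(inst.events[kind]) == len(evs)


def test_extract_all_constant_dataset_has_no_events():
    ds = TimeSeriesDataset(values=np.full((3, 6), 2.0))
    for inst in extract_all(ds):
        assert all(len(v) == 0 for v in inst.events.values())


def test_extract_all_reports_offending_instance():
    # dataset invariants forbid length-1 series, so exercise the per-series path
    with pytest.raises(SeriesTooShortError):
        extract_series_events([1.0], instance_id="bad")
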