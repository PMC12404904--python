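"""Query parsing/rendering round trips and scan-matching semantics,
checked against an independent brute-force filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sstlab.formula_mass import ToleranceSpec
from sstlab.massql_engine import (
    ConditionSpec,
    QueryAST,
    QueryParseError,
    evaluate_query,
    parse_query,
    render_query,
)

from conftest import make_run, make_scan

WORKED_EXAMPLE = (
    "QUERY scansum(MS1DATA) WHERE MS1MZ=249.1888 AND TOLERANCEPPM=10 "
    "AND RTMIN=4.13 AND RTMAX=4.46"
)


# -- independent oracle: literal scan-by-scan, peak-by-peak filter ----------

def brute_force(run, ast):
    rows = []
    for scan in run.scans:
        if ast.source == "MS1DATA" and scan.ms_level != 1:
            continue
        if ast.source == "MS2DATA" and scan.ms_level < 2:
            continue
        lo, hi = ast.rt_window
        if lo is not None and scan.rt_minutes < lo:
            continue
        if hi is not None and scan.rt_minutes > hi:
            continue
        ok = True
        matched_idx = None
        first_vals = None
        for cond in ast.conditions:
            if cond.kind in ("RTMIN", "RTMAX"):
                continue
            if cond.kind == "MS2PREC":
                if scan.precursor_mz is None:
                    ok = False
                    break
                if ast.tolerance.mode == "ppm":
                    err = abs(scan.precursor_mz - cond.value) / cond.value * 1e6
                    if err > ast.tolerance.value:
                        ok = False
                        break
                elif abs(scan.precursor_mz - cond.value) > ast.tolerance.value:
                    ok = False
                    break
                continue
            if cond.kind in ("MS1MZ", "MS2PROD"):
                vals = scan.mz_array
            else:  # MS2NL
                if scan.precursor_mz is None:
                    ok = False
                    break
                vals = scan.precursor_mz - scan.mz_array
            idx = []
            for i, v in enumerate(vals):
                if ast.tolerance.mode == "ppm":
                    hit = abs(v - cond.value) / cond.value * 1e6 <= ast.tolerance.value
                else:
                    hit = abs(v - cond.value) <= ast.tolerance.value
                if hit:
                    idx.append(i)
            if not idx:
                ok = False
                break
            if matched_idx is None:
                matched_idx = set(idx)
                first_vals = (vals, list(idx))
            else:
                matched_idx |= set(idx)
        if not ok:
            continue
        if matched_idx is None:
            if scan.tic <= 0:
                continue
            rows.append((scan.scan_id, scan.rt_minutes, scan.tic))
            continue
        total = sum(scan.intensity_array[i] for i in matched_idx)
        if total <= 0:
            continue
        vals, idx = first_vals
        w = [scan.intensity_array[i] for i in idx]
        obs = sum(vals[i] * wi for i, wi in zip(idx, w)) / sum(w)
        rows.append((scan.scan_id, scan.rt_minutes, total, obs))
    return rows


class TestParse:
    def test_worked_example_ast(self):
        ast = parse_query(WORKED_EXAMPLE)
        assert ast.action == "scansum"
        assert ast.source == "MS1DATA"
        assert ast.conditions == (
            ConditionSpec("MS1MZ", 249.1888),
            ConditionSpec("RTMIN", 4.13),
            ConditionSpec("RTMAX", 4.46),
        )
        assert ast.tolerance == ToleranceSpec("ppm", 10.0)

    def test_ms2_product_query(self):
        ast = parse_query("QUERY scaninfo(MS2DATA) WHERE MS2PROD=85.0284 AND TOLERANCEPPM=10")
        assert ast.action == "scaninfo"
        assert ast.source == "MS2DATA"
        assert ast.conditions == (ConditionSpec("MS2PROD", 85.0284),)

    def test_default_tolerance_is_ten_ppm(self):
        ast = parse_query("QUERY scansum(MS1DATA) WHERE MS1MZ=100.0")
        assert ast.tolerance == ToleranceSpec("ppm", 10.0)

    def test_case_and_whitespace_insensitive(self):
        a = parse_query("query SCANSUM( ms1data )  where ms1mz = 100.0 and rtmin=1")
        b = parse_query("QUERY scansum(MS1DATA) WHERE MS1MZ=100.0 AND RTMIN=1")
        assert a == b

    @pytest.mark.parametrize(
        "bad, match",
        [
            ("QUERY scansum(MS1DATA) WHERE BOGUS=1", "BOGUS"),
            ("QUERY scanavg(MS1DATA) WHERE MS1MZ=1", "action"),
            ("QUERY scansum(MS3DATA) WHERE MS1MZ=1", "source"),
            ("QUERY scansum(MS1DATA) WHERE MS1MZ=abc", "abc"),
            ("QUERY scansum(MS1DATA) WHERE MS1MZ", "="),
            ("QUERY scansum(MS2DATA) WHERE MS1MZ=100", "MS1DATA"),
            ("QUERY scansum(MS1DATA) WHERE MS2PROD=100", "MS2DATA"),
            ("QUERY scansum(MS1DATA) WHERE MS1MZ=1 AND RTMIN=5 AND RTMAX=2", "RTMIN"),
            ("QUERY scansum(MS1DATA) WHERE MS1MZ=1 AND RTMIN=1 AND RTMIN=2", "RTMIN"),
            ("QUERY scansum(MS1DATA) WHERE MS1MZ=1 AND TOLERANCEPPM=5 AND TOLERANCEMZ=0.1", "tolerance"),
            ("", "empty"),
        ],
    )
    def test_parse_errors_name_the_problem(self, bad, match):
        with pytest.raises(QueryParseError, match=match):
            parse_query(bad)


asts = st.builds(
    QueryAST,
    action=st.sampled_from(["scansum", "scaninfo"]),
    source=st.just("MS1DATA"),
    conditions=st.lists(
        st.builds(
            ConditionSpec,
            kind=st.just("MS1MZ"),
            value=st.floats(min_value=50, max_value=2000).map(lambda v: round(v, 4)),
        ),
        max_size=2,
    ).map(tuple),
    tolerance=st.builds(
        ToleranceSpec,
        mode=st.sampled_from(["ppm", "absolute_mz"]),
        value=st.floats(min_value=0.001, max_value=50).map(lambda v: round(v, 3)),
    ),
)


class TestRender:
    def test_round_trip_of_worked_example(self):
        ast = parse_query(WORKED_EXAMPLE)
        assert parse_query(render_query(ast)) == ast

    def test_no_rt_tokens_without_window(self):
        text = render_query(parse_query("QUERY scansum(MS1DATA) WHERE MS1MZ=100"))
        assert "RTMIN" not in text and "RTMAX" not in text

    @settings(max_examples=150, derandomize=True)
    @given(ast=asts)
    def test_random_ast_round_trip(self, ast):
        assert parse_query(render_query(ast)) == ast


def _random_run(rng, n_scans=30, ms2=False):
    scans = []
    for i in range(n_scans):
        n_peaks = rng.integers(0, 20)
        mz = np.sort(rng.uniform(80, 500, n_peaks))
        mz = np.unique(np.round(mz, 4))
        peaks = list(zip(mz, rng.uniform(1, 1e5, len(mz))))
        level = 2 if (ms2 and i % 2) else 1
        scans.append(
            make_scan(
                scan_id=f"s{i}",
                ms_level=level,
                rt=i * 0.1,
                peaks=peaks or [(100.0, 0.0)],
                precursor_mz=float(rng.uniform(200, 300)) if level == 2 else None,
            )
        )
    return make_run(scans)


class TestEvaluate:
    def test_exact_synthetic_match_inside_window(self):
        scans = [
            make_scan(scan_id=f"s{i}", rt=4.0 + i * 0.05, peaks=[(249.1888, 100.0)])
            for i in range(12)
        ]
        run = make_run(scans)
        out = evaluate_query(run, parse_query(WORKED_EXAMPLE))
        assert ((out["rt_minutes"] >= 4.13) & (out["rt_minutes"] <= 4.46)).all()
        assert len(out) == 7  # rts 4.15 .. 4.45 (window boundaries inclusive)
        assert (out["observed_mz"] == 249.1888).all()
        assert (out["ppm_error"] == 0).all()

    def test_no_match_yields_empty_table(self):
        run = make_run([make_scan(peaks=[(249.1888, 100.0)])])
        out = evaluate_query(
            run, parse_query("QUERY scansum(MS1DATA) WHERE MS1MZ=500.0")
        )
        assert out.empty and list(out.columns) == [
            "run_id", "scan_id", "rt_minutes", "matched_intensity",
            "observed_mz", "ppm_error",
        ]

    def test_two_peaks_in_tolerance_are_summed(self):
        run = make_run(
            [make_scan(peaks=[(249.1880, 40.0), (249.1896, 60.0)])]
        )
        out = evaluate_query(
            run, parse_query("QUERY scansum(MS1DATA) WHERE MS1MZ=249.1888 AND TOLERANCEPPM=10")
        )
        assert len(out) == 1
        assert out["matched_intensity"].iloc[0] == pytest.approx(100.0)
        # intensity-weighted mean of the two matched peaks
        expected = (249.1880 * 40 + 249.1896 * 60) / 100
        assert out["observed_mz"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_neutral_loss_uses_recorded_precursor(self):
        scan = make_scan(
            ms_level=2,
            peaks=[(85.0284, 80.0), (148.0684, 20.0)],
            precursor_mz=207.1419,
        )
        out = evaluate_query(
            make_run([scan]),
            parse_query("QUERY scaninfo(MS2DATA) WHERE MS2NL=59.0735 AND TOLERANCEPPM=10"),
        )
        assert len(out) == 1
        assert out["matched_intensity"].iloc[0] == pytest.approx(20.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_oracle_equivalence_on_random_runs(self, seed):
        rng = np.random.default_rng(seed)
        run = _random_run(rng, n_scans=40, ms2=(seed % 2 == 0))
        queries = [
            "QUERY scansum(MS1DATA) WHERE MS1MZ=250.0 AND TOLERANCEMZ=5.0",
            "QUERY scansum(MS1DATA) WHERE MS1MZ=250.0 AND TOLERANCEPPM=10000 AND RTMIN=0.5 AND RTMAX=2.5",
            "QUERY scaninfo(MS2DATA) WHERE MS2PROD=150.0 AND TOLERANCEMZ=20.0",
            "QUERY scaninfo(MS2DATA) WHERE MS2PREC=250.0 AND TOLERANCEMZ=30.0",
            "QUERY scaninfo(MS2DATA) WHERE MS2NL=100.0 AND TOLERANCEMZ=10.0",
        ]
        for q in queries:
            ast = parse_query(q)
            got = evaluate_query(run, ast)
            expected = brute_force(run, ast)
            assert len(got) == len(expected), q
            for row, exp in zip(got.itertuples(index=False), expected):
                assert row.scan_id == exp[0]
                assert row.matched_intensity == pytest.approx(exp[2])
                if len(exp) > 3:
                    assert row.observed_mz == pytest.approx(exp[3])

    def test_result_invariant_to_scan_storage_order(self):
        rng = np.random.default_rng(7)
        run = _random_run(rng, n_scans=20)
        shuffled = make_run(list(reversed(run.scans)))
        ast = parse_query("QUERY scansum(MS1DATA) WHERE MS1MZ=250.0 AND TOLERANCEMZ=20.0")
        a = evaluate_query(run, ast).reset_index(drop=True)
        b = evaluate_query(shuffled, ast).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_monotonicity_in_tolerance_and_window(self):
        rng = np.random.default_rng(11)
        run = _random_run(rng, n_scans=30)
        tight = evaluate_query(
            run, parse_query("QUERY scansum(MS1DATA) WHERE MS1MZ=250.0 AND TOLERANCEMZ=2.0")
        )
        loose = evaluate_query(
            run, parse_query("QUERY scansum(MS1DATA) WHERE MS1MZ=250.0 AND TOLERANCEMZ=10.0")
        )
        assert set(tight["scan_id"]) <= set(loose["scan_id"])
        narrow = evaluate_query(
            run,
            parse_query(
                "QUERY scansum(MS1DATA) WHERE MS1MZ=250.0 AND TOLERANCEMZ=10.0 AND RTMIN=1.0 AND RTMAX=2.0"
            ),
        )
        assert set(narrow["scan_id"]) <= set(loose["scan_id"])
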