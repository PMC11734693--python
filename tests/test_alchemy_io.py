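"""Window-table and fepout parsing: round trips, conservation, errors."""

import io

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rnafep import alchemy_io
from rnafep.alchemy_io import (
    FepoutParseError,
    parse_fep_output,
    read_ti_profile,
    read_window_table,
    write_ti_profile,
    write_window_table,
)
from rnafep.synthetic import StudySpec, gen_study, gen_ti_profile
from rnafep.types import Direction, StepId


def make_fepout(windows, n_fields=6):
    """Render windows [(l1, l2, [du...])] in the legacy dialect."""
    lines = ["# some preamble", "#SOME OTHER COMMENT"]
    for l1, l2, samples in windows:
        lines.append(f"#NEW FEP WINDOW: LAMBDA SET TO {l1} LAMBDA2 {l2}")
        for i, du in enumerate(samples):
            pad = " ".join(str(float(i + j)) for j in range(n_fields - 1))
            lines.append(f"FepEnergy: {pad} {du!r} 0.0")
    return "\n".join(lines) + "\n"


class TestParseFepout:
    def test_counts_and_bounds_preserved(self):
        text = make_fepout([(0.0, 0.5, [0.1, 0.2, 0.3]), (0.5, 1.0, [0.4, -0.1, 0.0])])
        leg = parse_fep_output(text, "forward", 298.0)
        assert leg.n_windows == 2
        assert [w.n_samples for w in leg.windows] == [3, 3]
        assert [(w.lambda_start, w.lambda_end) for w in leg.windows] == [
            (0.0, 0.5),
            (0.5, 1.0),
        ]
        np.testing.assert_allclose(leg.windows[0].delta_u, [0.1, 0.2, 0.3])

    def test_delta_u_field_position_is_configurable(self):
        text = make_fepout([(0.0, 1.0, [1.5, 2.5])], n_fields=8)
        leg = parse_fep_output(text, "forward", 300.0, delta_u_field=8)
        # field 8 holds the planted dU; field 3 holds the pad counter
        np.testing.assert_allclose(leg.windows[0].delta_u, [1.5, 2.5])
        leg3 = parse_fep_output(text, "forward", 300.0, delta_u_field=3)
        np.testing.assert_allclose(leg3.windows[0].delta_u, [2.0, 3.0])

    def test_discard_fraction_recorded_not_applied(self):
        text = make_fepout([(0.0, 1.0, list(range(10)))])
        leg = parse_fep_output(text, "forward", 298.0, discard_fraction=0.2)
        assert leg.windows[0].n_samples == 10
        assert leg.windows[0].retained().size == 8

    @pytest.mark.parametrize(
        "bad_text,match",
        [
            ("#NEW FEP WINDOW: LAMBDA SET TO oops\n", "malformed"),
            (make_fepout([(0.0, 0.5, [])]) + "#NEW FEP WINDOW: LAMBDA SET TO 0.5 LAMBDA2 1\nFepEnergy: 1 2 3 4 5 6\n", "no FepEnergy"),
            ("FepEnergy: 1 2 3 4 5 6\n", "precedes any window header"),
            (make_fepout([(0.0, 0.4, [1.0]), (0.8, 1.0, [1.0]), (0.4, 0.8, [1.0])]), "non-monotone"),
        ],
    )
    def test_malformed_streams_raise(self, bad_text, match):
        with pytest.raises(FepoutParseError, match=match):
            parse_fep_output(io.StringIO(bad_text), "forward", 298.0)


class TestWindowTable:
    def test_round_trip_from_fepout(self, tmp_path):
        text = make_fepout(
            [(0.0, 0.5, [0.123456789012345, -2.5]), (0.5, 1.0, [1e-8, 3.14159])]
        )
        leg = parse_fep_output(text, "forward", 298.0)
        path = tmp_path / "w.csv"
        write_window_table([leg], path)
        (leg2,) = read_window_table(path)
        assert leg2.step_id == leg.step_id
        for w, w2 in zip(leg.windows, leg2.windows):
            assert (w.lambda_start, w.lambda_end) == (w2.lambda_start, w2.lambda_end)
            np.testing.assert_array_equal(w.delta_u, w2.delta_u)

    def test_study_round_trip_is_identity(self, tmp_path, small_study):
        rep = small_study.replicates[0]
        legs = [leg for pair in rep.fep_legs.values() for leg in pair]
        path = tmp_path / "study.csv"
        write_window_table(legs, path)
        back = read_window_table(path)
        assert len(back) == len(legs)
        by_key = {(l.step_id, l.direction): l for l in back}
        for leg in legs:
            twin = by_key[(leg.step_id, leg.direction)]
            assert twin.n_windows == leg.n_windows
            for w, w2 in zip(leg.windows, twin.windows):
                assert w.lambda_start == w2.lambda_start
                np.testing.assert_array_equal(w.delta_u, w2.delta_u)

    def test_deterministic_output(self, tmp_path, small_study):
        rep = small_study.replicates[0]
        legs = [leg for pair in rep.fep_legs.values() for leg in pair]
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_window_table(legs, p1)
        write_window_table(legs, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_inputs(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_window_table([], path)
        assert read_window_table(path) == []

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("step_id,direction\nstep1,forward\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_window_table(path)

    def test_mixed_temperature_leg_raises(self, tmp_path):
        path = tmp_path / "mixed.csv"
        rows = [
            "step1,bulk,forward,0.0,0.5,0,1.0,298.0",
            "step1,bulk,forward,0.5,1.0,0,1.0,310.0",
        ]
        path.write_text(
            ",".join(alchemy_io.WINDOW_TABLE_COLUMNS) + "\n" + "\n".join(rows) + "\n"
        )
        with pytest.raises(ValueError, match="mixes temperatures"):
            read_window_table(path)

    @given(
        samples=st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=1, max_size=20
        )
    )
    def test_sample_values_survive_round_trip(self, tmp_path_factory, samples):
        text = make_fepout([(0.0, 1.0, samples)])
        leg = parse_fep_output(text, "forward", 298.0)
        path = tmp_path_factory.mktemp("rt") / "w.csv"
        write_window_table([leg], path)
        (leg2,) = read_window_table(path)
        np.testing.assert_array_equal(leg2.windows[0].delta_u, np.asarray(samples))


class TestTIProfile:
    def test_round_trip(self, tmp_path):
        prof, _ = gen_ti_profile(10.0, 0.5, np.linspace(0, 1, 11), 0.01, seed=4)
        path = tmp_path / "ti.csv"
        write_ti_profile(prof, path)
        back = read_ti_profile(path)
        np.testing.assert_array_equal(back.lambda_grid, prof.lambda_grid)
        np.testing.assert_array_equal(back.mean_dudl, prof.mean_dudl)
        np.testing.assert_array_equal(back.n_samples, prof.n_samples)

    def test_grid_validation(self, tmp_path):
        path = tmp_path / "ti.csv"
        path.write_text(
            "lambda,mean_dudl_kcal_mol,sem_dudl_kcal_mol,n_samples\n"
            "0.0,1.0,0.1,10\n0.5,1.0,0.1,10\n"
        )
        with pytest.raises(ValueError, match="end at 1"):
            read_ti_profile(path)
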