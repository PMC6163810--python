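import numpy as np
import pytest

from protongate.state_energetics import (
    InsufficientDataError,
    MissingTermError,
    MissingVoltageError,
    ProtonationState,
    StateEnergyTable,
    TiedStatesError,
    crossing_point,
    decomposition_delta,
    min_energy_state,
)
from protongate.synthetic_data import (
    CLOSED_STATE_LABEL,
    OPEN_STATE_LABEL,
    gen_energy_table,
)


class TestProtonationState:
    def test_label_round_trip(self):
        st = ProtonationState.from_label("Y266:-,R300:+,E183:0")
        assert st.charge_of("Y266") == "-"
        assert ProtonationState.from_label(st.label) == st

    def test_duplicate_residues_rejected(self):
        with pytest.raises(ValueError):
            ProtonationState((("Y266", "-"), ("Y266", "0")))

    def test_invalid_tag_rejected(self):
        with pytest.raises(ValueError):
            ProtonationState.from_label("Y266:2")


class TestMinEnergyState:
    def test_planted_all_neutral_lowest_when_hyperpolarized(self):
        table, manifest = gen_energy_table(seed=0)
        assert min_energy_state(table, -70.0) == manifest.truths["closed_state"]
        assert ProtonationState.from_label(min_energy_state(table, -70.0)).as_dict() == {
            "Y266": "0", "R300": "0", "E183": "0"
        }

    def test_single_state_table(self):
        table = StateEnergyTable.from_records([("only:0", 0.0, 5.0)])
        assert min_energy_state(table, 0.0) == "only:0"

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        records = [
            (f"s{k}:0", v, float(rng.normal(0, 20)))
            for k in range(10)
            for v in (-70.0, 0.0, 70.0)
        ]
        table = StateEnergyTable.from_records(records)
        for v in (-70.0, 0.0, 70.0):
            rows = [(lbl, e) for lbl, vv, e in records if vv == v]
            expected = min(rows, key=lambda r: r[1])[0]
            assert min_energy_state(table, v) == expected

    def test_missing_voltage_is_error(self):
        table = StateEnergyTable.from_records([("a:0", 0.0, 1.0)])
        with pytest.raises(MissingVoltageError):
            min_energy_state(table, -35.0)

    def test_ties_are_reported(self):
        table = StateEnergyTable.from_records([("a:0", 0.0, 1.0), ("b:0", 0.0, 1.0)])
        with pytest.raises(TiedStatesError, match="a:0"):
            min_energy_state(table, 0.0)

    def test_invariant_under_constant_shift(self):
        table, _ = gen_energy_table(seed=5)
        shifted = StateEnergyTable.from_records(
            [
                (r.state_label, r.voltage_mV, r.energy_kJ_mol + 123.4)
                for r in table.df.itertuples()
            ]
        )
        for v in table.voltages:
            assert min_energy_state(table, v) == min_energy_state(shifted, v)


class TestCrossingPoint:
    def test_symmetric_lines_cross_at_zero(self):
        table = StateEnergyTable.from_records(
            [("a:0", v, float(v)) for v in (-70.0, 0.0, 70.0)]
            + [("b:0", v, float(-v)) for v in (-70.0, 0.0, 70.0)]
        )
        cp = crossing_point(table, "a:0", "b:0")
        assert cp.voltage_mv == pytest.approx(0.0)

    def test_planted_crossing_recovered_exactly(self):
        table, manifest = gen_energy_table(crossing=(-20.0, 60.0), seed=1)
        cp = crossing_point(table, CLOSED_STATE_LABEL, OPEN_STATE_LABEL)
        assert cp.voltage_mv == pytest.approx(manifest.truths["crossing_voltage_mV"], abs=1e-9)
        assert cp.height_kj_mol == pytest.approx(manifest.truths["crossing_height_kJ_mol"], abs=1e-9)

    def test_crossing_symmetric_in_states(self):
        table, _ = gen_energy_table(seed=2)
        cp_ab = crossing_point(table, CLOSED_STATE_LABEL, OPEN_STATE_LABEL, CLOSED_STATE_LABEL)
        cp_ba = crossing_point(table, OPEN_STATE_LABEL, CLOSED_STATE_LABEL, CLOSED_STATE_LABEL)
        assert cp_ab.voltage_mv == pytest.approx(cp_ba.voltage_mv)
        assert cp_ab.height_kj_mol == pytest.approx(cp_ba.height_kj_mol)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_grid_scan(self, seed):
        rng = np.random.default_rng(seed)
        grid = np.array([-70.0, -35.0, 0.0, 35.0, 70.0])
        ea = 2.0 * grid + float(rng.normal(0, 5))
        eb = -1.0 * grid + float(rng.normal(0, 5))
        table = StateEnergyTable.from_records(
            [("a:0", v, e) for v, e in zip(grid, ea)]
            + [("b:0", v, e) for v, e in zip(grid, eb)]
        )
        cp = crossing_point(table, "a:0", "b:0")
        dense = np.linspace(-70, 70, 1400001)
        diff = np.interp(dense, grid, ea) - np.interp(dense, grid, eb)
        v_scan = dense[np.argmin(np.abs(diff))]
        assert cp.voltage_mv == pytest.approx(v_scan, abs=0.1)

    def test_no_crossing_is_distinguished_from_error(self):
        table = StateEnergyTable.from_records(
            [("a:0", -70.0, 0.0), ("a:0", 70.0, 0.0),
             ("b:0", -70.0, 10.0), ("b:0", 70.0, 10.0)]
        )
        assert crossing_point(table, "a:0", "b:0") is None

    def test_single_common_voltage_insufficient(self):
        table = StateEnergyTable.from_records(
            [("a:0", 0.0, 1.0), ("b:0", 0.0, 2.0), ("b:0", 70.0, 0.0)]
        )
        with pytest.raises(InsufficientDataError):
            crossing_point(table, "a:0", "b:0")


class TestDecompositionDelta:
    def test_planted_xc_values(self):
        table, manifest = gen_energy_table(seed=0)
        delta = decomposition_delta(table, CLOSED_STATE_LABEL, OPEN_STATE_LABEL, 0.0)
        assert delta == pytest.approx(96.0 - 25.2)
        assert delta == pytest.approx(manifest.truths["xc_delta_kJ_mol"])

    def test_identical_rows_give_zero(self):
        table = StateEnergyTable.from_records([("a:0", 0.0, 1.0, 7.0), ("b:0", 0.0, 2.0, 7.0)])
        assert decomposition_delta(table, "a:0", "b:0", 0.0) == 0.0

    def test_missing_term_is_error(self):
        table = StateEnergyTable.from_records([("a:0", 0.0, 1.0), ("b:0", 0.0, 2.0)])
        with pytest.raises(MissingTermError):
            decomposition_delta(table, "a:0", "b:0", 0.0, term="nonexistent")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_lookup(self, seed):
        table, _ = gen_energy_table(seed=seed)
        xc = {
            (r.state_label, r.voltage_mV): r.xc_kJ_mol for r in table.df.itertuples()
        }
        for v in (-70.0, 0.0, 70.0):
            expected = xc[(CLOSED_STATE_LABEL, v)] - xc[(OPEN_STATE_LABEL, v)]
            assert decomposition_delta(
                table, CLOSED_STATE_LABEL, OPEN_STATE_LABEL, v
            ) == pytest.approx(expected)


class TestTableIO:
    def test_csv_round_trip(self, tmp_path):
        table, _ = gen_energy_table(seed=9)
        path = tmp_path / "energies.csv"
        table.to_csv(path)
        back = StateEnergyTable.from_csv(path)
        assert back.states == table.states
        np.testing.assert_allclose(
            back.df["energy_kJ_mol"], table.df["energy_kJ_mol"]
        )

    def test_duplicate_state_voltage_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            StateEnergyTable.from_records([("a:0", 0.0, 1.0), ("a:0", 0.0, 2.0)])
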