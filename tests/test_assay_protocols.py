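import io
from dataclasses import replace

import numpy as np
import pytest

from appki.analytic_models import mm_rate
from appki.assay_protocols import (
    AssayProtocol,
    RateTable,
    preincubate,
    run_inhibition_assay,
    vary_fixed_substrate,
)
from appki.ki_estimation import cornish_bowden_kiu, dixon_kic
from appki.mechanism_library import case_spec

UM = 1e-6
NM = 1e-9
PM = 1e-12


class TestProtocolValidation:
    def test_defaults(self):
        p = AssayProtocol()
        assert p.detection_time == 60.0
        assert p.initiation == "co_start"
        assert p.velocity_mode == "instantaneous"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"detection_time": 0.0},
            {"initiation": "quench"},
            {"velocity_mode": "endpoint"},
            {"max_consumption": 1.5},
        ],
    )
    def test_invalid_fields(self, kwargs):
        with pytest.raises(ValueError):
            AssayProtocol(**kwargs)


class TestPreincubate:
    def test_no_inhibitor_all_free(self):
        net = case_spec("slow").network
        eq = preincubate(net, 100 * PM, 0.0)
        assert eq["E"] == pytest.approx(100 * PM) and eq["EI"] == 0.0

    def test_excess_inhibitor_half_bound_at_kd(self):
        # E0=100 pM, I0=1 uM = Kd: bound fraction 0.5 in the I >> E regime
        net = case_spec("slow").network
        eq = preincubate(net, 100 * PM, 1 * UM)
        assert eq["EI"] / (100 * PM) == pytest.approx(0.5, rel=1e-3)

    def test_tight_regime_matches_numeric_root(self):
        # E0 = 1 nM, I0 = 1 nM, Kd = 0.01 nM
        net = case_spec("slow", {"koff": 1e-5, "Kd_I": 0.01 * NM}).network
        E0, I0, kd = 1 * NM, 1 * NM, 0.01 * NM
        eq = preincubate(net, E0, I0)
        # independent oracle: numeric root of EI^2 - (E0+I0+Kd)EI + E0*I0
        roots = np.roots([1.0, -(E0 + I0 + kd), E0 * I0])
        bound = float(min(r for r in roots if 0 <= r <= min(E0, I0) * (1 + 1e-9)))
        assert eq["EI"] == pytest.approx(bound, rel=1e-9)

    def test_substrate_present_rejected(self):
        net = case_spec("slow").network.with_conc0(S=1 * UM)
        with pytest.raises(ValueError, match="substrate"):
            preincubate(net, 100 * PM, 1 * UM)

    def test_nonpositive_e0_rejected(self):
        with pytest.raises(ValueError):
            preincubate(case_spec("slow").network, 0.0, 1 * UM)


class TestRunAssay:
    def test_tight_uninhibited_series_matches_mm(self):
        spec = case_spec("tight", {"E0": 1 * PM, "I_grid": [0.0]})
        table = run_inhibition_assay(spec)
        km = (50.0 + 50.0) / 2e7
        for _, row in table.df.iterrows():
            expected = mm_rate(50.0 * 1 * PM, km, row["substrate"])
            assert row["velocity"] == pytest.approx(expected, rel=0.01)

    def test_slow_preincubated_velocities_reflect_trapped_enzyme(self):
        # koff = 1e-5/s: the preincubation equilibrium is frozen; velocities
        # are far below what the free-inhibitor steady state would allow
        spec = case_spec("slow", {"E0": 1 * PM, "S_grid": [1e-4], "I_grid": [0.0, 2e-5]})
        table = run_inhibition_assay(spec)
        v0 = table.df[table.df["inhibitor"] == 0]["velocity"].iloc[0]
        v = table.df[table.df["inhibitor"] > 0]["velocity"].iloc[0]
        km = (1.0 + 1000.0) / 1e8
        s = 1e-4
        # classical competitive prediction with free [I] = total [I]
        v_classical = v0 * (km + s) / (km * (1 + 2e-5 / 1e-6) + s)
        assert v < 0.1 * v0          # trapped: ~1/21 of activity
        assert v < 0.5 * v_classical  # far below the equilibrium-free prediction

    def test_monotonicity_invariant(self):
        spec = case_spec("tight")
        table = run_inhibition_assay(spec)
        table.validate()

    def test_chord_close_to_instantaneous_without_depletion(self):
        # fast-equilibrating case at negligible substrate consumption
        base = {"E0": 1 * PM, "i_over_e": 1e4}
        inst = run_inhibition_assay(case_spec("tight", base))
        spec_c = case_spec("tight", base)
        spec_c.protocol = replace(spec_c.protocol, velocity_mode="chord")
        chord = run_inhibition_assay(spec_c)
        ratio = chord.df["velocity"].to_numpy() / inst.df["velocity"].to_numpy()
        assert np.allclose(ratio, 1.0, rtol=0.01)

    def test_chord_differs_for_slow_dissociation_co_start(self):
        # co-started slow-binding assay: onset delay makes the chord velocity
        # materially exceed the instantaneous rate at 60 s
        # koff = 1e-2/s, kon = 1e4: onset time constant ~17 s at [I] = 5 uM,
        # so inhibition develops inside the 60 s detection window
        ov = {"E0": 1 * PM, "koff": 1e-2, "S_grid": [1e-5], "I_grid": [5e-6]}
        spec_i = case_spec("slow", ov)
        spec_i.protocol = replace(spec_i.protocol, initiation="co_start", velocity_mode="instantaneous")
        spec_c = case_spec("slow", ov)
        spec_c.protocol = replace(spec_c.protocol, initiation="co_start", velocity_mode="chord")
        v_i = run_inhibition_assay(spec_i).df["velocity"].iloc[0]
        v_c = run_inhibition_assay(spec_c).df["velocity"].iloc[0]
        assert v_c > 1.2 * v_i

    def test_depletion_guard_caps_enzyme_load(self):
        spec = case_spec("ordered_bibi")
        table = vary_fixed_substrate(spec, 25 * UM)
        e0 = table.metadata["E0_effective"]
        assert e0 < spec.params["E0"]
        assert e0 <= 0.02 * 2.5 * UM / (100.0 * 60.0) * (1 + 1e-12)


class TestVaryFixedSubstrate:
    def test_one_table_per_a_value(self):
        spec = case_spec("ordered_bibi", {"B_grid": [5e-6, 2e-5, 1e-4], "I_grid": [0.0, 5e-9]})
        for a in (1 * UM, 100 * UM):
            table = vary_fixed_substrate(spec, a)
            assert set(table.df["co_substrate"]) == {a}

    def test_saturating_limit_reaches_kcat(self):
        spec = case_spec("ordered_bibi", {"E0": 1 * PM, "B_grid": [2e-3], "I_grid": [0.0]})
        table = vary_fixed_substrate(spec, 5e-3)  # A = 5 mM >> Ks
        v = table.df["velocity"].iloc[0]
        assert v == pytest.approx(100.0 * 1 * PM, rel=0.05)

    def test_non_bibi_rejected(self):
        with pytest.raises(ValueError, match="two-substrate"):
            vary_fixed_substrate(case_spec("tight"), 1 * UM)

    def test_nonpositive_a_rejected(self):
        with pytest.raises(ValueError):
            vary_fixed_substrate(case_spec("ordered_bibi"), 0.0)


class TestRateTableCsv:
    def test_round_trip(self):
        spec = case_spec("tight", {"E0": 1 * PM, "S_grid": [1e-5, 3e-5, 1e-4], "I_grid": [0.0, 5e-11, 2e-10]})
        table = run_inhibition_assay(spec)
        buf = io.StringIO()
        table.to_csv(buf)
        buf.seek(0)
        back = RateTable.from_csv(buf)
        assert np.allclose(back.df["velocity"], table.df["velocity"])
        assert np.allclose(back.df["substrate"], table.df["substrate"])
        assert back.case_id == "tight"
        assert back.metadata["varied"] == "S"

    def test_bibi_round_trip_keeps_co_substrate(self, tmp_path):
        spec = case_spec("ordered_bibi", {"B_grid": [5e-6, 2e-5, 1e-4], "I_grid": [0.0, 5e-9, 1e-8]})
        table = vary_fixed_substrate(spec, 25 * UM)
        path = tmp_path / "t.csv"
        table.to_csv(path)
        back = RateTable.from_csv(path)
        assert np.allclose(back.df["co_substrate"], 25 * UM)
        header = path.read_text().splitlines()[1]
        assert header.split(",") == ["case_id", "B_M", "A_M", "I_M", "v_M_per_s"]
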