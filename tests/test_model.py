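import numpy as np
import pytest
from scipy.linalg import expm

from ceqpbpk import (
    ChemicalParams,
    ConcentrationTimeSeries,
    DosingRegimen,
    SimulationError,
    auc,
    build_rhs,
    simulate,
    system_matrix,
)
from ceqpbpk.model import DEPOT_FAST, DEPOT_SLOW, N_AMOUNTS, N_STATES, VEN


class TestRightHandSide:
    def test_zero_state_is_stationary(self, phys, chem):
        rhs = build_rhs(phys, chem)
        assert np.allclose(rhs(np.zeros(N_STATES)), 0.0)

    def test_closed_system_conserves_mass(self, phys, chem):
        """With clearances off, body + depot derivatives sum to zero."""
        closed = chem.evolve(KbileC=0.0, KurineC=0.0)
        rhs = build_rhs(phys, closed)
        rng = np.random.default_rng(42)
        for _ in range(5):
            state = np.abs(rng.normal(size=N_STATES))
            assert abs(rhs(state)[:N_AMOUNTS].sum()) < 1e-10 * state.sum()

    def test_depot_chain_matches_hand_written_linear_system(self, phys, chem):
        """Depot slow -> fast -> venous reduces to a hand-expandable
        3-state chain when tissue flows are negligible."""
        quiet = phys.evolve(QMC=1e-14, QLC=1e-14, QKC=1e-14, QRC=1e-14, QCC=1e-12)
        rhs = build_rhs(quiet, chem)
        state = np.zeros(N_STATES)
        state[DEPOT_SLOW], state[DEPOT_FAST], state[VEN] = 5.0, 45.0, 2.0
        d = rhs(state)
        assert d[DEPOT_SLOW] == pytest.approx(-chem.Kdiss * 5.0)
        assert d[DEPOT_FAST] == pytest.approx(chem.Kdiss * 5.0 - chem.Kim * 45.0)
        assert d[VEN] == pytest.approx(chem.Kim * 45.0, rel=1e-9)


class TestSimulate:
    def test_zero_dose_gives_zero_traces(self, phys, chem):
        s = simulate(phys, chem, DosingRegimen(0.0), 12.0)
        for name in s.compartments:
            assert np.all(s.trace(name) == 0.0)

    def test_mass_balance_with_clearances(self, phys, chem, single_dose):
        """Administered = body burden + depots + urine + bile at all times."""
        s = simulate(phys, chem, single_dose, 120.0)
        assert s.administered_mg == pytest.approx(50.0)
        assert s.mass_balance_error() < 1e-6

    def test_mass_balance_multidose_lsoda(self, phys, chem):
        reg = DosingRegimen(2.0, interval_h=12.0, n_doses=3)
        s = simulate(phys, chem, reg, 48.0, dt=0.5, method="lsoda")
        assert s.mass_balance_error() < 1e-6

    def test_states_nonnegative(self, phys, chem, single_dose):
        s = simulate(phys, chem, single_dose, 48.0)
        assert s.states[:, :N_AMOUNTS].min() >= 0.0

    def test_t_end_before_last_dose_rejected(self, phys, chem):
        reg = DosingRegimen(2.0, interval_h=24.0, n_doses=3)
        with pytest.raises(SimulationError):
            simulate(phys, chem, reg, 24.0)

    def test_lung_if_flagged_free_and_plasma_total(self, phys, chem, single_dose):
        s = simulate(phys, chem, single_dose, 6.0)
        assert s.free["lung_if"] and s.free["plasma_free"]
        assert not s.free["plasma"]
        assert np.allclose(s.trace("plasma_free"),
                           (1.0 - chem.PB) * s.trace("plasma"))

    def test_csv_round_trip_schema(self, phys, chem, single_dose, tmp_path):
        import pandas as pd
        s = simulate(phys, chem, single_dose, 2.0, dt=0.5)
        path = tmp_path / "sim.csv"
        s.to_csv(path)
        df = pd.read_csv(path)
        assert set(df.columns) == {"time_h", "compartment", "concentration",
                                   "units", "free_or_total"}
        assert set(df["compartment"]) == set(s.compartments)


class TestLinearSystemOracles:
    def test_lsoda_matches_matrix_exponential_oracle(self, phys, chem, single_dose):
        """Between dose events the system is linear time-invariant, so the
        stiff solver must agree with exp(A t) x0 evaluated directly."""
        s = simulate(phys, chem, single_dose, 10.0, dt=1.0, method="lsoda")
        A = system_matrix(phys, chem)
        x0 = np.zeros(N_STATES)
        x0[DEPOT_SLOW] = chem.Frac * 50.0
        x0[DEPOT_FAST] = (1 - chem.Frac) * 50.0
        for i, t in enumerate(s.time[1:], start=1):
            ref = expm(A * t) @ x0
            scale = np.abs(ref).max()
            assert np.abs(s.states[i] - ref).max() / scale < 1e-5

    def test_expm_engine_matches_lsoda_engine(self, phys, chem, single_dose):
        fast = simulate(phys, chem, single_dose, 24.0, dt=0.5, method="expm")
        slow = simulate(phys, chem, single_dose, 24.0, dt=0.5, method="lsoda")
        ref = np.abs(fast.trace("plasma")).max()
        for name in ("plasma", "lung_if", "kidney"):
            denom = np.abs(fast.trace(name)).max()
            assert np.abs(fast.trace(name) - slow.trace(name)).max() / denom < 1e-5
        assert ref > 0

    def test_superposition_of_identical_doses(self, phys, chem):
        """Linearity: the 3-dose solution equals the sum of time-shifted
        single-dose solutions."""
        reg3 = DosingRegimen(2.0, interval_h=12.0, n_doses=3)
        multi = simulate(phys, chem, reg3, 48.0)
        single = simulate(phys, chem, DosingRegimen(2.0), 48.0)
        t, c1 = single.time, single.trace("plasma")
        combo = np.zeros_like(multi.trace("plasma"))
        for shift in (0.0, 12.0, 24.0):
            shifted = np.where(multi.time >= shift - 1e-12,
                               np.interp(multi.time - shift, t, c1, left=0.0), 0.0)
            combo += shifted
        scale = combo.max()
        assert np.abs(multi.trace("plasma") - combo).max() / scale < 1e-6

    def test_equilibrium_tissue_blood_ratios_reach_partition(self, phys, chem):
        """With clearances and lung exchange off, every flow-limited tissue
        equilibrates to C_T / C_art = P_T."""
        inert = chem.evolve(KbileC=0.0, KurineC=0.0, KBI=0.0, KIB=0.0,
                            KIT=0.0, KTI=0.0)
        s = simulate(phys, inert, DosingRegimen(2.0), 3000.0, dt=10.0)
        c_art = s.trace("arterial")[-1]
        for name, p in [("muscle", chem.PM), ("liver", chem.PL),
                        ("kidney", chem.PK), ("rest", chem.PR)]:
            assert s.trace(name)[-1] / c_art == pytest.approx(p, rel=1e-6)


class TestAUC:
    def _series(self, t, c):
        n = len(t)
        return ConcentrationTimeSeries(
            time=np.asarray(t, float),
            concentrations={"x": np.asarray(c, float)},
            free={"x": False}, cumulative_auc={},
            states=np.zeros((n, N_STATES)), administered_mg=0.0)

    def test_constant_concentration(self):
        s = self._series(np.linspace(0, 24, 49), np.ones(49))
        assert auc(s, "x", 0, 24) == pytest.approx(24.0)

    def test_zero_trace(self):
        s = self._series(np.linspace(0, 24, 49), np.zeros(49))
        assert auc(s, "x") == 0.0

    def test_monoexponential_matches_closed_form(self):
        """C0 e^{-kt} integrates to C0/k; trapezoid on a fine grid."""
        t = np.linspace(0, 60, 60001)
        s = self._series(t, 10.0 * np.exp(-0.5 * t))
        assert auc(s, "x", 0, 60) == pytest.approx(20.0, rel=1e-4)

    def test_accumulator_agrees_with_trapezoid(self, phys, chem, single_dose):
        s = simulate(phys, chem, single_dose, 24.0)
        trapz = np.trapezoid(s.trace("kidney"), s.time)
        assert auc(s, "kidney", 0, 24) == pytest.approx(trapz, rel=1e-3)

    def test_unknown_compartment_raises(self, phys, chem, single_dose):
        s = simulate(phys, chem, single_dose, 2.0, dt=0.5)
        with pytest.raises(KeyError):
            auc(s, "spleen")
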