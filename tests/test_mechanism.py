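"""Mechanism core: free-protease partitioning, rate laws, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect

from raskinetics.mechanism import (AssayDesign, KineticParameters,
                                   SpeciesState, equilibrium_state,
                                   free_protease, mechanism_rhs,
                                   simulate_progress)


class TestFreeProtease:
    def test_no_ligands_returns_total(self):
        assert free_protease(100e-9, 0.0, 0.0, 1e-6, 1e-6) == 100e-9

    def test_saturating_ligand_drives_free_toward_zero(self):
        P = free_protease(100e-9, 20e-6, 0.0, 1e-9, 1e-6)
        assert 0 <= P <= 1e-9

    def test_matches_bisection_oracle(self):
        ptot, rt, r1t, ks, kp = 100e-9, 1e-6, 1e-6, 1e-6, 1e-6

        def residual(P):
            return P * (1 + rt / (ks + P) + r1t / (kp + P)) - ptot

        oracle = bisect(residual, 0.0, ptot, xtol=1e-25)
        P = free_protease(ptot, rt, r1t, ks, kp)
        assert P == pytest.approx(oracle, rel=1e-10)

    @pytest.mark.parametrize("bad", [
        dict(protease_total=-1e-9), dict(ras_intact_total=np.nan),
        dict(K_S=0.0), dict(K_P=-1e-6)])
    def test_invalid_inputs_raise(self, bad):
        kw = dict(protease_total=1e-7, ras_intact_total=1e-6,
                  r1_total=0.0, K_S=1e-6, K_P=1e-6)
        kw.update(bad)
        with pytest.raises(ValueError):
            free_protease(**kw)

    @given(ptot=st.floats(1e-10, 1e-5), rt=st.floats(0, 1e-4),
           r1t=st.floats(0, 1e-4), ks=st.floats(1e-9, 1e-3),
           kp=st.floats(1e-9, 1e-3))
    @settings(max_examples=50, deadline=None)
    def test_conservation_residual_tiny(self, ptot, rt, r1t, ks, kp):
        P = free_protease(ptot, rt, r1t, ks, kp)
        assert 0 <= P <= ptot
        recon = P * (1 + rt / (ks + P) + r1t / (kp + P))
        assert recon == pytest.approx(ptot, rel=1e-10)


class TestMechanismRhs:
    def test_zero_protease_freezes_everything(self, quick_params):
        design = AssayDesign(protease_total=0.0, ras_total=5e-6,
                             reporter_total=1e-6,
                             time_grid=np.array([0.0, 1.0]))
        state = SpeciesState(R=5e-6, P=0, RP=0, Pr1=0, S=1e-6,
                             r1=0, r2=0, AMC=0)
        for mode in ("rapid_equilibrium", "mass_action"):
            d = mechanism_rhs(state, quick_params, design, mode)
            assert all(v == 0 for v in d.as_array())

    def test_zero_acylation_conserves_intact_ras(self, short_design):
        params = KineticParameters(K_S=10e-6, k_2=1e-12, K_P=0.5e-6,
                                   k_rep=1e4)
        state = equilibrium_state(5e-6, 0.2e-6, 1e-6, 0.0,
                                  short_design.protease_total, params)
        d = mechanism_rhs(state, params, short_design)
        assert d.R + d.RP == pytest.approx(0.0, abs=1e-18)
        assert d.S < 0 and d.AMC > 0

    def test_unknown_mode_rejected(self, short_design, quick_params):
        state = SpeciesState(R=0, P=1e-7, RP=0, Pr1=0, S=1e-6,
                             r1=0, r2=0, AMC=0)
        with pytest.raises(ValueError, match="mode"):
            mechanism_rhs(state, quick_params, short_design, "exact")

    @pytest.mark.parametrize("mode", ["rapid_equilibrium", "mass_action"])
    def test_conservation_groups_sum_to_zero(self, short_design,
                                             quick_params, mode):
        state = equilibrium_state(4e-6, 0.5e-6, 0.8e-6, 0.2e-6,
                                  short_design.protease_total, quick_params)
        d = mechanism_rhs(state, quick_params, short_design, mode)
        assert d.P + d.RP + d.Pr1 == pytest.approx(0.0, abs=1e-15)
        assert d.R + d.RP + d.r1 + d.Pr1 == pytest.approx(0.0, abs=1e-15)
        assert d.S + d.AMC == pytest.approx(0.0, abs=1e-15)

    def test_rhs_matches_finite_difference_of_trajectory(self, quick_params):
        """d/dt of simulated pools agrees with the reported rate laws."""
        design = AssayDesign(protease_total=100e-9, ras_total=5e-6,
                             reporter_total=1e-6, r1_initial=0.0,
                             time_grid=np.linspace(0.0, 400.0, 4001))
        _, traj = simulate_progress(design, quick_params)
        t = traj["time_s"].to_numpy()
        i = 2000
        h = t[1] - t[0]
        state = SpeciesState.from_array(
            traj.loc[i, ["R", "P", "RP", "Pr1", "S", "r1", "r2", "AMC"]]
            .to_numpy())
        d = mechanism_rhs(state, quick_params, design)
        for pool, cols, deriv in [
                ("intact", ["R", "RP"], d.R + d.RP),
                ("cleaved", ["r1", "Pr1"], d.r1),
                ("reporter", ["S"], d.S),
                ("amc", ["AMC"], d.AMC)]:
            series = traj[cols].sum(axis=1).to_numpy()
            fd = (series[i + 1] - series[i - 1]) / (2 * h)
            assert deriv == pytest.approx(fd, rel=1e-6, abs=1e-16), pool

    def test_mass_action_rhs_matches_finite_difference(self, quick_params):
        design = AssayDesign(protease_total=100e-9, ras_total=5e-6,
                             reporter_total=1e-6, r1_initial=0.0,
                             time_grid=np.linspace(0.0, 40.0, 4001))
        params = quick_params.with_k_on(1e7)
        _, traj = simulate_progress(design, params, mode="mass_action")
        t = traj["time_s"].to_numpy()
        i, h = 2000, t[1] - t[0]
        state = SpeciesState.from_array(
            traj.loc[i, ["R", "P", "RP", "Pr1", "S", "r1", "r2", "AMC"]]
            .to_numpy())
        d = mechanism_rhs(state, params, design, "mass_action").as_array()
        for j, name in enumerate(("R", "P", "RP", "Pr1", "S", "r1", "r2",
                                  "AMC")):
            series = traj[name].to_numpy()
            fd = (series[i + 1] - series[i - 1]) / (2 * h)
            assert d[j] == pytest.approx(fd, rel=1e-5, abs=1e-15), name


class TestSimulateProgress:
    def test_starts_at_zero_and_monotone(self, short_design, quick_params):
        curve, traj = simulate_progress(short_design, quick_params)
        assert curve.amc[0] == 0.0
        assert traj["S"].iloc[0] == pytest.approx(
            short_design.reporter_total, rel=1e-12)
        assert np.all(np.diff(curve.amc) >= -1e-15)

    def test_ras_free_matches_single_exponential(self, quick_params):
        design = AssayDesign(protease_total=100e-9, ras_total=0.0,
                             reporter_total=1e-6,
                             time_grid=np.linspace(0.0, 2300.0, 201))
        curve, _ = simulate_progress(design, quick_params)
        exact = design.reporter_total * (
            1 - np.exp(-quick_params.k_rep * design.protease_total
                       * design.time_grid))
        np.testing.assert_allclose(curve.amc[1:], exact[1:], rtol=1e-6)

    def test_modes_agree_at_fast_on_rate(self, truth_active,
                                         active_suite_noiseless):
        params9 = truth_active.with_k_on(1e9)
        for design in active_suite_noiseless.designs:
            c_re, _ = simulate_progress(design, truth_active)
            c_ma, _ = simulate_progress(design, params9, mode="mass_action")
            disc = np.max(np.abs(c_re.amc - c_ma.amc))
            assert disc < 5e-3 * design.reporter_total

    def test_mode_discrepancy_shrinks_with_on_rate(self, truth_active,
                                                   active_suite_noiseless):
        design = active_suite_noiseless.designs[4]
        c_re, _ = simulate_progress(design, truth_active)
        discs = []
        for kon in (1e7, 1e8, 1e9):
            c_ma, _ = simulate_progress(design, truth_active.with_k_on(kon),
                                        mode="mass_action")
            discs.append(np.max(np.abs(c_re.amc - c_ma.amc)))
        assert discs[0] > discs[1] > discs[2]

    def test_amc_nonincreasing_in_ras_and_r1(self, quick_params):
        grid = np.linspace(0.0, 1000.0, 51)
        base = dict(protease_total=100e-9, reporter_total=1e-6,
                    time_grid=grid)
        prev = None
        for ras in (0.0, 2e-6, 10e-6, 20e-6):
            c, _ = simulate_progress(
                AssayDesign(ras_total=ras, **base), quick_params)
            if prev is not None:
                assert np.all(c.amc <= prev + 1e-12)
            prev = c.amc
        prev = None
        for r1 in (0.0, 0.2e-6, 1e-6, 3.3e-6):
            c, _ = simulate_progress(
                AssayDesign(ras_total=0.0, r1_initial=r1, **base),
                quick_params)
            if prev is not None:
                assert np.all(c.amc <= prev + 1e-12)
            prev = c.amc

    def test_higher_specificity_cleaves_faster(self):
        """With parameters differing only in k_2/K_S, the cleaved-RAS
        fraction at every t > 0 is larger for the more specific enzyme."""
        grid = np.linspace(0.0, 1000.0, 51)
        design = AssayDesign(protease_total=100e-9, ras_total=5e-6,
                             reporter_total=1e-6, time_grid=grid)
        lo = KineticParameters(K_S=10e-6, k_2=0.01, K_P=0.5e-6, k_rep=1e4)
        hi = KineticParameters(K_S=10e-6, k_2=0.10, K_P=0.5e-6, k_rep=1e4)
        _, tlo = simulate_progress(design, lo)
        _, thi = simulate_progress(design, hi)
        cleaved_lo = tlo["r1"] + tlo["Pr1"]
        cleaved_hi = thi["r1"] + thi["Pr1"]
        assert np.all(cleaved_hi.to_numpy()[1:] > cleaved_lo.to_numpy()[1:])


class TestConservation:
    @given(ptot=st.floats(1e-9, 1e-6), ras=st.one_of(st.just(0.0), st.floats(1e-9, 2e-5)),
           r1=st.one_of(st.just(0.0), st.floats(1e-9, 3.3e-6)),
           ks=st.floats(1e-7, 1e-4), k2=st.floats(1e-3, 1.0),
           kp=st.floats(1e-8, 1e-5), krep=st.floats(1e3, 1e5))
    @settings(max_examples=30, deadline=None)
    def test_mass_action_conservation_under_random_designs(
            self, ptot, ras, r1, ks, k2, kp, krep):
        params = KineticParameters(K_S=ks, k_2=k2, K_P=kp, k_rep=krep)
        t_end = np.log(10.0) / (krep * ptot)
        design = AssayDesign(protease_total=ptot, ras_total=ras,
                             reporter_total=1e-6, r1_initial=r1,
                             time_grid=np.linspace(0.0, t_end, 21))
        _, traj = simulate_progress(design, params, mode="mass_action")
        groups = {
            "protease": (traj["P"] + traj["RP"] + traj["Pr1"], ptot),
            "ras": (traj["R"] + traj["RP"] + traj["r1"] + traj["Pr1"],
                    ras + r1),
            "reporter": (traj["S"] + traj["AMC"], 1e-6),
        }
        for name, (series, ref) in groups.items():
            if ref > 0:
                drift = np.max(np.abs(series.to_numpy() - ref)) / ref
                assert drift < 1e-6, name
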