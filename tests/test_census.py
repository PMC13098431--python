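import numpy as np
import pytest

from sdrcensus import synthetic
from sdrcensus.census import (
    ContactSpec,
    census,
    contact_census,
    default_sdr_criteria,
    evaluate_frame,
    fold_change,
    hydride_angle_stats,
    specific_activity,
    turnover_number,
)
from sdrcensus.errors import (
    ConfigurationError,
    EmptyInputError,
    EmptySelectionError,
    UndefinedFractionError,
)
from sdrcensus.model_io import Frame, Selection

from conftest import make_topology, make_trajectory


@pytest.fixture
def site():
    """A tiny hand-placed active site with controllable criterion distances."""
    topo = make_topology(
        [
            ("OH", "TYR", 164),
            ("OG1", "THR", 124),
            ("NZ", "LYS", 168),
            ("O2D", "NAD", 401),
            ("O3D", "NAD", 401),
            ("C4N", "NAD", 401),
            ("C2", "SUG", 402),
            ("H2", "SUG", 402),
            ("O2", "SUG", 402),
        ]
    )
    bindings = {
        "tyr_oh": Selection(resid=164, name="OH"),
        "thr_og": Selection(resid=124, name="OG1"),
        "lys_nz": Selection(resid=168, name="NZ"),
        "ribose_oh": Selection(resname="NAD", name="O?D"),
        "nad_c4": Selection(resname="NAD", name="C4N"),
        "sugar_c2": Selection(resname="SUG", name="C2"),
        "sugar_o2": Selection(resname="SUG", name="O2"),
    }

    def frame(d_tyr, d_thr, d_lys, d_hyd):
        xyz = np.zeros((9, 3))
        xyz[8] = [0, 0, 0]                    # O2
        xyz[0] = [0, d_tyr, 0]                # Tyr OH
        xyz[1] = [0, -d_thr, 0]               # Thr OG1
        xyz[3] = [-5, 5, 0]                   # ribose O2D
        xyz[4] = [-5, 1, 0]                   # ribose O3D (4 A away)
        xyz[2] = [-5, 5 + d_lys, 0]           # Lys NZ (nearest to O2D)
        xyz[6] = [2, 0, 0]                    # sugar C2
        xyz[7] = [2, 0, 1.09]                 # H2
        xyz[5] = [2 + d_hyd, 0, 0]            # nicotinamide C4
        return Frame(0, xyz)

    return topo, bindings, frame


class TestDefaultCriteria:
    def test_four_criteria_all_cutoff_3p5(self, site):
        _, bindings, _ = site
        cs = default_sdr_criteria(bindings)
        assert len(cs.criteria) == 4
        assert all(c.cutoff == 3.5 for c in cs.criteria)
        by_label = {c.label: c for c in cs.criteria}
        assert by_label["lys_nz-ribose_oh"].reduction == "min-over-pairs"

    def test_missing_binding_names_role(self, site):
        _, bindings, _ = site
        del bindings["lys_nz"]
        with pytest.raises(ConfigurationError, match="lys_nz"):
            default_sdr_criteria(bindings)

    def test_cutoff_override_echoed(self, site):
        _, bindings, _ = site
        cs = default_sdr_criteria(bindings, cutoffs={"nad_c4-sugar_c2": 4.0})
        by_label = {c.label: c.cutoff for c in cs.criteria}
        assert by_label["nad_c4-sugar_c2"] == 4.0
        assert by_label["tyr_oh-sugar_o2"] == 3.5


class TestEvaluateFrame:
    def test_triad_3_hydride_3p4_is_plausible(self, site):
        # the reported plausible-pose geometry: triad <= 3.0 A, hydride 3.4 A
        topo, bindings, frame = site
        cs = default_sdr_criteria(bindings)
        v = evaluate_frame(frame(3.0, 3.0, 3.0, 3.4), cs, topo)
        assert v.plausible

    def test_distant_tyr_vetoes(self, site):
        topo, bindings, frame = site
        cs = default_sdr_criteria(bindings)
        v = evaluate_frame(frame(4.8, 3.0, 3.0, 3.0), cs, topo)
        assert not v.plausible
        assert not v.passes["tyr_oh-sugar_o2"]
        assert v.passes["thr_og-sugar_o2"]

    def test_boundary_exactly_at_cutoff_passes(self, site):
        topo, bindings, frame = site
        cs = default_sdr_criteria(bindings)
        v = evaluate_frame(frame(3.5, 3.5, 3.5, 3.5), cs, topo)
        assert v.plausible

    def test_min_over_pairs_uses_nearest_ribose_hydroxyl(self, site):
        topo, bindings, frame = site
        cs = default_sdr_criteria(bindings)
        f = frame(3.0, 3.0, 3.2, 3.0)
        v = evaluate_frame(f, cs, topo)
        # NZ sits 3.2 from O2D but 7.2 from O3D; either-suffices semantics
        assert v.distances["lys_nz-ribose_oh"] == pytest.approx(3.2)
        assert v.plausible

    def test_both_hydroxyls_reading_is_stricter(self, site):
        topo, bindings, frame = site
        strict = default_sdr_criteria(bindings, lys_requires_both=True)
        v = evaluate_frame(frame(3.0, 3.0, 3.2, 3.0), strict, topo)
        assert not v.plausible


class TestCensus:
    def _traj_with_flags(self, site, flags):
        topo, bindings, frame = site
        frames = []
        for ok in flags:
            d = 3.0 if ok else 5.0
            frames.append(frame(d, 3.0, 3.0, 3.0).coordinates)
        return make_trajectory(topo, np.array(frames)), default_sdr_criteria(bindings)

    def test_no_frame_passes(self, site):
        traj, cs = self._traj_with_flags(site, [False] * 10)
        res = census(traj, cs)
        assert res.fraction == 0.0
        assert res.ci_low == 0.0

    def test_fraction_and_ci(self, site):
        traj, cs = self._traj_with_flags(site, [True] * 3 + [False] * 7)
        res = census(traj, cs)
        assert res.fraction == pytest.approx(0.3)
        assert res.ci_low < 0.3 < res.ci_high

    def test_brute_force_equivalence(self, site):
        topo, bindings, frame = site
        cs = default_sdr_criteria(bindings)
        rng = np.random.default_rng(17)
        frames = [
            frame(*rng.uniform(2.5, 5.0, 4)) for _ in range(100)
        ]
        traj = make_trajectory(topo, np.array([f.coordinates for f in frames]))
        res = census(traj, cs)
        # independent brute-force loop over frames x criteria
        resolved = cs.resolve(topo)
        n_pass = 0
        for f in traj:
            ok = True
            for crit, pi, ti in resolved:
                dmin = min(
                    np.linalg.norm(f.coordinates[a] - f.coordinates[b])
                    for a in pi
                    for b in ti
                )
                if dmin > crit.cutoff:
                    ok = False
            n_pass += ok
        assert res.n_plausible == n_pass
        assert res.fraction == n_pass / 100

    def test_monotone_in_cutoff(self, site):
        topo, bindings, frame = site
        rng = np.random.default_rng(23)
        traj = make_trajectory(
            topo,
            np.array([frame(*rng.uniform(2.5, 5.5, 4)).coordinates for _ in range(200)]),
        )
        fractions = []
        for cut in (3.0, 3.5, 4.0, 4.5, 5.0):
            cs = default_sdr_criteria(
                bindings, cutoffs={"tyr_oh-sugar_o2": cut}
            )
            fractions.append(census(traj, cs).fraction)
        assert all(a <= b for a, b in zip(fractions, fractions[1:]))

    def test_conjunction_bounded_by_marginals(self, site):
        topo, bindings, frame = site
        rng = np.random.default_rng(29)
        traj = make_trajectory(
            topo,
            np.array([frame(*rng.uniform(2.5, 5.5, 4)).coordinates for _ in range(300)]),
        )
        res = census(traj, default_sdr_criteria(bindings))
        assert res.fraction <= min(res.marginals.values()) + 1e-12


class TestContactCensus:
    def test_always_satisfied_under_both_denominators(self, site):
        topo, bindings, frame = site
        traj = make_trajectory(
            topo, np.array([frame(3.0, 3.0, 3.0, 3.0).coordinates] * 5)
        )
        spec = ContactSpec(
            label="thr-o2",
            probe=Selection(resid=124, name="OG1"),
            target=Selection(resname="SUG", name="O2"),
            cutoff=3.5,
        )
        res = contact_census(traj, spec)
        assert res.fraction == 1.0
        verdicts = census(traj, default_sdr_criteria(bindings)).verdicts
        from dataclasses import replace

        res2 = contact_census(
            traj, replace(spec, denominator="plausible-frames"), verdicts
        )
        assert res2.fraction == 1.0

    def test_empty_denominator_is_an_error_not_zero(self, site):
        topo, bindings, frame = site
        traj = make_trajectory(
            topo, np.array([frame(5.0, 3.0, 3.0, 3.0).coordinates] * 4)
        )
        verdicts = census(traj, default_sdr_criteria(bindings)).verdicts
        spec = ContactSpec(
            label="x",
            probe=Selection(resid=124, name="OG1"),
            target=Selection(resname="SUG", name="O2"),
            denominator="plausible-frames",
        )
        with pytest.raises(UndefinedFractionError):
            contact_census(traj, spec, verdicts)

    def test_planted_probability_recovered(self):
        cfg = synthetic.preset("cdp-man-like", n_frames=4000, seed=41)
        from dataclasses import replace

        cfg = replace(
            cfg,
            contacts=(synthetic.ContactPlant("val_o-c3o", "OV", "O3", 0.10, 3.5),),
        )
        traj, truth = synthetic.generate_ensemble(cfg)
        spec = synthetic.default_contact_specs(cfg)[0]
        res = contact_census(traj, spec)
        se = np.sqrt(0.1 * 0.9 / 4000)
        assert abs(res.fraction - 0.10) < 3 * se


class TestHydrideAngle:
    def test_collinear_gives_180(self, site):
        topo, bindings, frame = site
        xyz = frame(3.0, 3.0, 3.0, 3.0).coordinates.copy()
        xyz[7] = [2, 0, 1.09]
        xyz[6] = [2, 0, 2.09]     # C2 directly above H2
        xyz[5] = [2, 0, -1.0]     # C4 directly below
        traj = make_trajectory(topo, xyz[None])
        res = hydride_angle_stats(
            traj,
            Selection(resname="SUG", name="C2"),
            Selection(resname="SUG", name="H2"),
            Selection(resname="NAD", name="C4N"),
        )
        assert res.mean == pytest.approx(180.0)

    def test_missing_hydrogen_is_explicit_error(self, site):
        topo, bindings, frame = site
        traj = make_trajectory(topo, frame(3, 3, 3, 3).coordinates[None])
        with pytest.raises(EmptySelectionError, match="[Hh]ydrogen"):
            hydride_angle_stats(
                traj,
                Selection(resname="SUG", name="C2"),
                Selection(resname="SUG", name="H9"),
                Selection(resname="NAD", name="C4N"),
            )

    def test_normal_sample_mean_recovered(self):
        cfg = synthetic.preset("cdp-man-like", n_frames=3000, seed=5)
        traj, truth = synthetic.generate_ensemble(cfg)
        res = hydride_angle_stats(
            traj,
            Selection(resname="SUG", name="C2"),
            Selection(resname="SUG", name="H2"),
            Selection(resname="NAD", name="C4N"),
        )
        np.testing.assert_allclose(res.series, truth.hydride_angle, atol=1e-9)
        se = res.sd / np.sqrt(res.n)
        assert abs(res.mean - truth.hydride_angle.mean()) < 1e-9
        assert abs(res.mean - 135.0) < 3 * se + 0.5  # truncation shifts slightly

    def test_restrict_to_plausible(self):
        cfg = synthetic.preset("cdp-man-like", n_frames=2000, seed=6)
        traj, truth = synthetic.generate_ensemble(cfg)
        res = hydride_angle_stats(
            traj,
            Selection(resname="SUG", name="C2"),
            Selection(resname="SUG", name="H2"),
            Selection(resname="NAD", name="C4N"),
            restrict_to=truth.plausible,
        )
        assert res.n == int(truth.plausible.sum())


class TestActivityArithmetic:
    def test_wildtype_vs_q205a_is_12_fold(self):
        fc = fold_change(23.1, 1.9)
        assert fc.display == 12

    def test_lyx_vs_man_is_14_fold(self):
        fc = fold_change(500.0, 36.0)
        assert fc.display == 14

    def test_equal_activities(self):
        assert fold_change(5.0, 5.0).ratio == 1.0

    def test_zero_reference_is_nd(self):
        with pytest.raises(ZeroDivisionError):
            fold_change(1.0, 0.0)

    def test_ctp_corrected_activity(self):
        # a 3.4-fold decrease from the 23.1 mU/mg reference leaves 6.8 mU/mg
        corrected = 23.1 / 3.4
        assert round(corrected, 1) == 6.8
        assert fold_change(23.1, corrected).display == pytest.approx(3.4)

    def test_linear_timecourse_unit_arithmetic(self):
        t = np.arange(10, dtype=float)
        product = 0.01 * t + 0.2  # mM, slope 0.01 mM/min
        res = specific_activity(np.column_stack([t, product]), enzyme_conc=0.4)
        assert res.specific_activity == pytest.approx(25.0)
        assert res.slope == pytest.approx(0.01)

    def test_zero_slope(self):
        t = np.arange(5, dtype=float)
        res = specific_activity(np.column_stack([t, np.ones(5)]), enzyme_conc=1.0)
        assert res.specific_activity == pytest.approx(0.0, abs=1e-12)

    def test_window_restricts_fit(self):
        t = np.arange(10, dtype=float)
        y = np.where(t < 5, 0.02 * t, 0.1)  # linear then saturating
        res = specific_activity(
            np.column_stack([t, y]), enzyme_conc=1.0, linear_window=(0, 5)
        )
        assert res.slope == pytest.approx(0.02)

    def test_too_few_points(self):
        with pytest.raises(EmptyInputError):
            specific_activity(np.array([[0, 0], [1, 1]]), enzyme_conc=1.0)

    def test_turnover_number_back_calculates_k(self):
        # 500 mU/mg at 39.2 kDa -> 19.6 per minute
        assert turnover_number(500.0, 39200.0) == pytest.approx(19.6)
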