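"""Phantom generators and experiment drivers."""

import numpy as np
import pytest

from isingtcp import (
    BoostPhantomSpec,
    MCMCConfig,
    boost_dose_sweep,
    boost_phantom,
    boost_volume_sweep,
    dose_response_sweep,
    homogeneous_phantom,
    logistic_tcp_voxel,
    phase_diagram,
)
from isingtcp.phantoms import DELTA_D_ORIGIN, delta_tcp_table

SMALL = (5, 5, 5)  # cheap phantom for MCMC-backed driver tests
FAST = MCMCConfig(n_sweeps=3000, seed=17)


class TestHomogeneousPhantom:
    def test_default_geometry(self):
        grid = homogeneous_phantom(dose=97.0)
        assert grid.n == 1000
        assert grid.voxel_edge == 0.1270
        assert np.all(grid.dose == 97.0)

    def test_delta_d_convention(self):
        """Absolute dose = 87 Gy + dD; dD = -22.5 Gy gives 64.5 Gy."""
        assert DELTA_D_ORIGIN - 22.5 == pytest.approx(64.5)
        grid = homogeneous_phantom(dose=DELTA_D_ORIGIN - 22.5)
        assert grid.dose[0] == pytest.approx(64.5)

    def test_single_voxel(self):
        grid = homogeneous_phantom((1, 1, 1), 0.127, 80.0)
        assert grid.n == 1

    def test_lattice_spacing(self):
        grid = homogeneous_phantom((4, 3, 2), 0.2, 50.0)
        assert grid.n == 24
        d = np.linalg.norm(grid.positions[1] - grid.positions[0])
        assert d == pytest.approx(0.2)


class TestBoostPhantom:
    def test_quarter_boost_doses(self):
        """25% of voxels boosted by 45 Gy on a 57 Gy base -> 102 Gy inside."""
        grid, mask = boost_phantom(BoostPhantomSpec(boost_delta=45.0, boost_fraction=0.25))
        assert mask.sum() == 250
        assert np.all(grid.dose[mask] == 102.0)
        assert np.all(grid.dose[~mask] == 57.0)

    @pytest.mark.parametrize("fraction, expected_dose", [(0.0, 57.0), (1.0, 97.0)])
    def test_degenerate_fractions_are_homogeneous(self, fraction, expected_dose):
        grid, mask = boost_phantom(BoostPhantomSpec(boost_fraction=fraction))
        assert np.all(grid.dose == expected_dose)
        assert mask.sum() == round(fraction * grid.n)

    def test_slab_is_contiguous_planes(self):
        grid, mask = boost_phantom(BoostPhantomSpec(boost_fraction=0.30))
        x = grid.positions[:, 0]
        assert x[mask].max() < x[~mask].min() + 1e-12

    def test_centered_box_is_compact(self):
        spec = BoostPhantomSpec(boost_fraction=0.20, boost_geometry="centered-box")
        grid, mask = boost_phantom(spec)
        center = grid.positions.mean(axis=0)
        r_in = np.linalg.norm(grid.positions[mask] - center, axis=1)
        r_out = np.linalg.norm(grid.positions[~mask] - center, axis=1)
        assert np.median(r_in) < np.median(r_out)

    def test_tiny_fraction_rejected(self):
        with pytest.raises(ValueError):
            boost_phantom(BoostPhantomSpec(shape=(2, 2, 2), boost_fraction=0.01))

    def test_mask_cardinality_rounds(self):
        grid, mask = boost_phantom(BoostPhantomSpec(boost_fraction=0.333))
        assert mask.sum() == round(0.333 * grid.n)


class TestDoseResponseSweep:
    def test_closed_form_midpoint_and_shoulder(self, params):
        dd_mid = params.d50 - DELTA_D_ORIGIN  # dose = D50
        df = dose_response_sweep([dd_mid, 10.0], [0.0], cfg=FAST, shape=SMALL)
        by_dd = df.set_index("control").tcp_avg
        assert by_dd[dd_mid] == pytest.approx(0.5, abs=1e-12)
        assert by_dd[10.0] == pytest.approx(
            logistic_tcp_voxel(97.0, params), abs=1e-12
        )  # ~0.9987

    def test_rows_sorted_and_closed_form_is_exact(self):
        df = dose_response_sweep([-5.0, -15.0, 0.0], [0.0], cfg=FAST, shape=SMALL)
        assert list(df.control) == sorted(df.control)
        assert np.all(df.stderr == 0.0)

    def test_interactions_shift_midpoint_left_and_steepen(self):
        """The transition moves to lower dose and sharpens when couplings
        are on (collective sterilization)."""
        dd = np.arange(-25.0, 0.1, 2.5)
        df = dose_response_sweep(dd, [0.0, 0.30], cfg=FAST, shape=SMALL)
        free = df[df.lam_cm == 0.0].set_index("control").tcp_avg
        coup = df[df.lam_cm == 0.30].set_index("control").tcp_avg
        cross_free = np.interp(0.5, free.values, free.index.values)
        cross_coup = np.interp(0.5, coup.values, coup.index.values)
        assert cross_coup < cross_free - 2.0
        slope_free = np.max(np.diff(free.values)) / 2.5
        slope_coup = np.max(np.diff(coup.values)) / 2.5
        assert slope_coup > slope_free

    def test_monotone_in_dose_within_noise(self):
        dd = np.arange(-25.0, 0.1, 5.0)
        df = dose_response_sweep(dd, [0.15], cfg=FAST, shape=SMALL)
        sub = df.sort_values("control")
        drops = np.diff(sub.tcp_avg.values)
        noise = 3 * np.sqrt(sub.stderr.values[1:] ** 2 + sub.stderr.values[:-1] ** 2)
        assert np.all(drops >= -noise)

    def test_closed_form_agrees_with_sampler_at_lambda_zero(self, params):
        """Engine cross-check: an explicit J0=0 MCMC run reproduces the
        closed-form non-interacting row."""
        from isingtcp import metropolis_run

        grid = homogeneous_phantom(SMALL, 0.127, 80.0)
        r = metropolis_run(grid, params, None, MCMCConfig(n_sweeps=20_000, seed=5))
        expected = logistic_tcp_voxel(80.0, params)
        assert r.tcp_avg == pytest.approx(expected, abs=3 * r.tcp_avg_stderr)


class TestPhaseDiagram:
    def test_extreme_doses_classified(self):
        labels, tcp = phase_diagram([-60.0, 40.0], [0.0, 0.15], cfg=FAST, shape=SMALL)
        assert list(labels[:, 0]) == ["uncontrolled"] * 2
        assert list(labels[:, 1]) == ["controlled"] * 2

    def test_disordered_band_shrinks_with_interaction_range(self):
        """The partially-sterilized band narrows as couplings lengthen."""
        dd = np.arange(-27.5, 5.1, 2.5)
        labels, _ = phase_diagram(dd, [0.0, 0.30], cfg=FAST, shape=SMALL)
        width_free = (labels[0] == "disordered").sum()
        width_coup = (labels[1] == "disordered").sum()
        assert width_coup <= width_free

    def test_eps_validation(self):
        with pytest.raises(ValueError):
            phase_diagram([0.0], [0.0], eps=0.6, cfg=FAST, shape=SMALL)


class TestBoostDoseSweep:
    def test_lambda0_unboosted_invariant_and_saturation(self, params):
        """Without couplings the unboosted region never feels the boost, and
        the whole-structure TCP saturates at fraction + (1-fraction)*TCP(57)."""
        df = boost_dose_sweep([0.0, 25.0, 45.0], [0.0], cfg=FAST)
        unb = df[(df.region == "unboosted")].tcp_avg
        assert unb.nunique() == 1
        assert unb.iloc[0] == pytest.approx(logistic_tcp_voxel(57.0, params), abs=1e-12)
        top = df[(df.region == "all") & (df.control == 45.0)].tcp_avg.iloc[0]
        assert top == pytest.approx(
            0.25 * logistic_tcp_voxel(102.0, params) + 0.75 * logistic_tcp_voxel(57.0, params),
            abs=1e-12,
        )

    def test_biological_penumbra(self):
        """With lambda = 0.30 cm a large boost raises the unboosted region's
        TCP well above its non-interacting value."""
        df = boost_dose_sweep([40.0], [0.0, 0.30], cfg=FAST)
        unb = df[df.region == "unboosted"].set_index("lam_cm")
        gain = unb.loc[0.30, "tcp_avg"] - unb.loc[0.0, "tcp_avg"]
        assert gain > 3 * unb.loc[0.30, "stderr"]
        assert gain > 0.1

    def test_delta_tcp_table(self):
        df = boost_dose_sweep([0.0, 45.0], [0.0], cfg=FAST)
        wide = delta_tcp_table(df)
        expected = (wide.boosted - wide.unboosted).values
        np.testing.assert_allclose(wide.delta_tcp.values, expected)


class TestBoostVolumeSweep:
    def test_lambda0_tracks_boost_fraction(self, params):
        """Without couplings TCP_avg = f*TCP(97) + (1-f)*TCP(57) ~ f."""
        fracs = [0.2, 0.5, 0.8, 1.0]
        df = boost_volume_sweep(fracs, [0.0], cfg=FAST)
        lo, hi = logistic_tcp_voxel(57.0, params), logistic_tcp_voxel(97.0, params)
        for f in fracs:
            got = df[df.control == f].tcp_avg.iloc[0]
            assert got == pytest.approx(f * hi + (1 - f) * lo, abs=1e-12)
            assert got == pytest.approx(f, abs=0.02)

    def test_interactions_dominate_partial_coverage(self):
        """lambda = 0.30 cm reaches near-total sterilization well before full
        coverage; the coupled curve lies above the non-interacting one."""
        fracs = [0.25, 0.5, 0.75]
        df = boost_volume_sweep(fracs, [0.0, 0.30], cfg=FAST)
        free = df[df.lam_cm == 0.0].set_index("control").tcp_avg
        coup = df[df.lam_cm == 0.30].set_index("control").tcp_avg
        assert np.all(coup.values >= free.values)
        assert coup[0.75] > 0.99


class TestSurfaceEffect:
    def test_surface_voxels_lag_the_bulk_above_the_transition(self, params):
        """Voxels on the open boundary incur fewer bystander couplings, so
        just above the collective transition they remain less sterilized than
        interior voxels; they account for the extra dose needed for complete
        sterilization on a finite phantom."""
        from isingtcp import BystanderParams, build_interaction_linearized, metropolis_run

        grid = homogeneous_phantom(dose=87.0 - 22.5)  # just above the coupled transition
        J = build_interaction_linearized(grid, params, BystanderParams(2.0, 0.30))
        r = metropolis_run(grid, params, J, MCMCConfig(n_sweeps=6000, seed=31))
        a = grid.voxel_edge
        idx = np.round(grid.positions / a).astype(int)
        on_surface = (idx == idx.min(0)).any(axis=1) | (idx == idx.max(0)).any(axis=1)
        surf, bulk = r.tcp_map[on_surface].mean(), r.tcp_map[~on_surface].mean()
        se = np.sqrt(
            np.sum(r.tcp_stderr[on_surface] ** 2) / on_surface.sum() ** 2
            + np.sum(r.tcp_stderr[~on_surface] ** 2) / (~on_surface).sum() ** 2
        )
        assert surf < bulk - 3 * se
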