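"""2D FTCS engine: heterogeneous diffusion, masks, reporters."""

import numpy as np
import pytest

from rootniche import (
    ConfigError,
    ModelParams,
    ModelSpec,
    Params2D,
    StabilityError,
    State2D,
    build_field_maps,
    ftcs_run,
    heterogeneous_laplacian,
    reduced_variant_run,
    transverse_profile,
)
from rootniche.sim2d import load_state_h5, save_state_h5


MIXED2D = dict(
    alpha=1.0, k_B=0.1, beta=1.0, k_Z=1.0, gamma=1.0, k_W=5.0, h=1.0,
    c=1.0, lam=1.0, d_B=0.1, d_W=0.1, d_Z=0.01, alpha_0=0.02,
)
P2D = Params2D(D_cyt={"B": 0.3, "W": 1.0, "Z": 1.0}, D_wall={"B": 0.0, "W": 0.02, "Z": 0.8})


def mixed_spec(genotype="wt"):
    return ModelSpec("mixed", "hill", wox5_self_repression=True,
                     basal_vi_production=True, genotype=genotype)


class TestLaplacian:
    def test_uniform_field_has_zero_laplacian(self):
        D = np.random.default_rng(0).random((12, 14)) + 0.1
        u = np.full((12, 14), 3.7)
        np.testing.assert_allclose(heterogeneous_laplacian(u, D), 0.0, atol=1e-12)

    def test_hot_pixel_reproduces_five_point_stencil(self):
        u = np.zeros((9, 9))
        u[4, 4] = 1.0
        lap = heterogeneous_laplacian(u, np.ones((9, 9)))
        expected = np.zeros((9, 9))
        expected[4, 4] = -4.0
        expected[3, 4] = expected[5, 4] = expected[4, 3] = expected[4, 5] = 1.0
        np.testing.assert_allclose(lap, expected)

    def test_flux_form_conserves_mass_on_any_map(self):
        rng = np.random.default_rng(1)
        D = rng.random((20, 30))
        D[0, :] = D[-1, :] = D[:, 0] = D[:, -1] = 0.0  # zero-D border
        u0 = rng.random((20, 30))
        u = u0.copy()
        for _ in range(50):
            u += 0.1 * heterogeneous_laplacian(u, D)
        assert abs(u.sum() - u0.sum()) < 1e-10 * u0.sum()

    def test_negative_diffusivity_rejected(self):
        with pytest.raises(ConfigError):
            heterogeneous_laplacian(np.zeros((4, 4)), -np.ones((4, 4)))

    def test_harmonic_face_average_conserves_and_gates_harder(self):
        """The optional harmonic face mean also conserves mass and lets
        less flux through a low-D wall than the arithmetic mean."""
        D = np.ones((5, 9))
        D[:, 4] = 0.01  # thin low-diffusivity wall
        u0 = np.zeros((5, 9))
        u0[:, :4] = 1.0
        ua = u0.copy()
        uh = u0.copy()
        for _ in range(100):
            ua += 0.2 * heterogeneous_laplacian(ua, D)
            uh += 0.2 * heterogeneous_laplacian(uh, D, face_average="harmonic")
        assert ua.sum() == pytest.approx(u0.sum(), rel=1e-12)
        assert uh.sum() == pytest.approx(u0.sum(), rel=1e-12)
        assert uh[:, 5:].sum() < ua[:, 5:].sum()


class TestFieldMaps:
    def test_wall_and_outside_rules(self, tiny_layout):
        _, lay, _ = tiny_layout
        maps = build_field_maps(lay, P2D)
        outside = ~lay.root_mask
        for name, D in maps.Dmap.items():
            assert np.all(D[outside] == 0.0), name
        assert np.all(maps.Dmap["B"][lay.wall_mask] == 0.0)
        assert np.all(maps.Dmap["W"][lay.wall_mask] == P2D.D_wall["W"])
        # production masks live on cell pixels only
        for m in (maps.gamma_mask, maps.alpha_mask, maps.basal_mask):
            assert not (m & ~lay.cell_mask).any()

    def test_csc_not_among_activating_types(self, tiny_layout):
        _, lay, _ = tiny_layout
        maps = build_field_maps(lay, P2D)
        assert not (maps.alpha_mask & lay.type_mask("CSC")).any()
        assert not (maps.alpha_mask & lay.type_mask("CC", "LRC")).any()
        assert (maps.alpha_mask & lay.type_mask("VI")).any()

    def test_missing_qc_rejected(self, tiny_layout):
        _, lay, _ = tiny_layout
        import copy

        bald = copy.deepcopy(lay)
        bald.cell_types = {k: ("V" if v == "QC" else v) for k, v in lay.cell_types.items()}
        with pytest.raises(ConfigError, match="QC"):
            build_field_maps(bald, P2D)

    def test_wall_diffusion_cannot_exceed_cytoplasmic(self):
        with pytest.raises(ConfigError):
            Params2D(D_cyt={"B": 0.3, "W": 0.1, "Z": 1.0}, D_wall={"B": 0.0, "W": 0.5, "Z": 0.1})

    def test_bravo_wall_diffusion_must_vanish(self):
        with pytest.raises(ConfigError):
            Params2D(D_wall={"B": 0.1, "W": 0.02, "Z": 0.15})


class TestFTCS:
    def test_stability_guard(self, tiny_layout):
        _, lay, _ = tiny_layout
        maps = build_field_maps(lay, P2D)
        with pytest.raises(StabilityError):
            ftcs_run(maps, ModelParams(**MIXED2D), mixed_spec(), p2d=P2D, dt=0.5, t_end=1.0)

    def test_diffusion_only_mass_conserved_and_confined(self, tiny_layout):
        _, lay, _ = tiny_layout
        maps = build_field_maps(lay, P2D)
        p0 = ModelParams(alpha=0, beta=0, gamma=0, lam=0, c=0, d_B=0, d_W=0, d_Z=0, alpha_0=0)
        st0 = State2D.zeros(lay.shape)
        rng = np.random.default_rng(5)
        blob = np.where(lay.cell_mask, rng.random(lay.shape), 0.0)
        st0.fields["W"] = blob.copy()
        out = ftcs_run(maps, p0, mixed_spec(), p2d=P2D, state0=st0, dt=0.1, t_end=100.0)
        assert out["W"].sum() == pytest.approx(blob.sum(), rel=1e-12)
        assert np.all(out["W"][~lay.root_mask] == 0.0)

    def test_reactions_confined_to_cell_pixels(self, tiny_layout):
        """With all diffusion off, production can only appear on cell
        pixels; walls and outside stay exactly zero."""
        _, lay, _ = tiny_layout
        p2d = Params2D(
            D_cyt={"B": 0.0, "W": 0.0, "Z": 0.0},
            D_wall={"B": 0.0, "W": 0.0, "Z": 0.0},
            D_GFP_cyt=0.0, D_GFP_wall=0.0,
        )
        maps = build_field_maps(lay, p2d)
        out = ftcs_run(maps, ModelParams(**MIXED2D), mixed_spec(), p2d=p2d, dt=0.1, t_end=20.0)
        for name, u in out.fields.items():
            assert np.all(u[~lay.cell_mask] == 0.0), name
        assert out["W"].max() > 0

    def test_mutant_keeps_reporter_but_not_protein(self, tiny_layout):
        _, lay, _ = tiny_layout
        maps = build_field_maps(lay, P2D)
        out = ftcs_run(maps, ModelParams(**MIXED2D), mixed_spec("bravo"), p2d=P2D, dt=0.1, t_end=60.0)
        assert np.all(out["B"] == 0.0)
        assert out["B_GFP"].max() > 0.0

    def test_state_h5_round_trip(self, tmp_path, tiny_layout):
        _, lay, _ = tiny_layout
        maps = build_field_maps(lay, P2D)
        out = ftcs_run(maps, ModelParams(**MIXED2D), mixed_spec(), p2d=P2D, dt=0.1, t_end=5.0)
        save_state_h5(tmp_path / "run.h5", out, lay)
        back = load_state_h5(tmp_path / "run.h5")
        assert back.t == out.t
        np.testing.assert_array_equal(back["W"], out["W"])


class TestTransverseProfile:
    def test_uniform_field_counts_root_pixels(self, tiny_layout):
        _, lay, _ = tiny_layout
        prof = transverse_profile(np.ones(lay.shape), lay)
        np.testing.assert_allclose(prof, lay.root_mask.sum(axis=1))

    def test_single_pixel(self, tiny_layout):
        _, lay, _ = tiny_layout
        ys, xs = np.nonzero(lay.cell_mask)
        field = np.zeros(lay.shape)
        field[ys[0], xs[0]] = 2.5
        prof = transverse_profile(field, lay)
        assert prof[ys[0]] == 2.5
        assert prof.sum() == 2.5

    def test_partition_identity(self, tiny_layout):
        _, lay, _ = tiny_layout
        rng = np.random.default_rng(2)
        field = np.where(lay.root_mask, rng.random(lay.shape), 0.0)
        assert transverse_profile(field, lay).sum() == pytest.approx(field.sum())


class TestReducedVariants:
    def test_fully_decoupled_wt_equals_mutant(self, tiny_layout):
        """With both lambda = 0 and c = 0 BRAVO influences nothing, so every
        other field (and the BRAVO reporter) is identical across genotypes."""
        _, lay, _ = tiny_layout
        maps = build_field_maps(lay, P2D)
        wt, mut = reduced_variant_run(
            maps, ModelParams(**MIXED2D), mixed_spec(),
            overrides={"lambda": 0.0, "c": 0.0}, p2d=P2D, dt=0.1, t_end=40.0,
        )
        for name in ("W", "Z", "B_GFP", "W_GFP", "Z_GFP"):
            np.testing.assert_array_equal(wt[name], mut[name])

    def test_mutant_reporter_identical_across_c_and_lambda_overrides(self, tiny_layout):
        _, lay, _ = tiny_layout
        maps = build_field_maps(lay, P2D)
        p = ModelParams(**MIXED2D)
        runs = {}
        for tag, ov in [("mixed", None), ("c0", {"c": 0.0}), ("lam0", {"lambda": 0.0})]:
            _, mut = reduced_variant_run(maps, p, mixed_spec(), overrides=ov, p2d=P2D, dt=0.1, t_end=30.0)
            runs[tag] = mut
        np.testing.assert_array_equal(runs["mixed"]["B_GFP"], runs["c0"]["B_GFP"])
        np.testing.assert_array_equal(runs["mixed"]["B_GFP"], runs["lam0"]["B_GFP"])

    def test_unknown_override_rejected(self, tiny_layout):
        _, lay, _ = tiny_layout
        maps = build_field_maps(lay, P2D)
        with pytest.raises(ConfigError):
            reduced_variant_run(maps, ModelParams(**MIXED2D), mixed_spec(), overrides={"zeta": 1.0})
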