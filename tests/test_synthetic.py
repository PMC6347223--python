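"""Tests for the synthetic cohort generator and damage operators."""

import math

import numpy as np
import pandas as pd
import pytest

from cryoactin.metrics import FilamentSet, cell_metrics, circular_std
from cryoactin.synthetic import (
    GeneratorConfig,
    StratumParams,
    apply_buckling,
    apply_cracking,
    apply_depolymerization,
    generate_annexin_pixels,
    generate_cell_filaments,
    generate_cohort,
    sample_orientations,
)


class TestSampleOrientations:
    def test_zero_dispersion_is_constant(self):
        assert np.allclose(sample_orientations(5, 37.0, 0.0, seed=1), 37.0)

    def test_same_seed_reproduces(self):
        a = sample_orientations(100, 90.0, 0.3, seed=11)
        b = sample_orientations(100, 90.0, 0.3, seed=11)
        assert np.array_equal(a, b)

    def test_outputs_folded_to_half_turn(self):
        a = sample_orientations(10_000, 170.0, 0.6, seed=3)
        assert np.all((a >= 0) & (a < 180))

    def test_circular_sd_of_unfolded_draws_matches_sigma(self):
        # R = exp(-sigma^2/2) identity: nu of the raw wrapped-normal draws
        # equals sigma; checked through the metrics module
        gen = np.random.default_rng(5)
        draws = 90.0 + np.rad2deg(gen.normal(0.0, 0.3, 100_000))
        assert circular_std(draws) == pytest.approx(0.3, abs=0.01)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            sample_orientations(-1, 0.0, 0.1, seed=0)
        with pytest.raises(ValueError):
            sample_orientations(5, 0.0, -0.1, seed=0)


class TestGenerateCellFilaments:
    def test_degenerate_count_range(self):
        cfg = GeneratorConfig(filament_count_range=(40, 40))
        fs = generate_cell_filaments(cfg, seed=0)
        assert fs.n == 40

    def test_fixed_seed_reproduces(self):
        cfg = GeneratorConfig()
        a = generate_cell_filaments(cfg, seed=9)
        b = generate_cell_filaments(cfg, seed=9)
        assert np.array_equal(a.lengths_um, b.lengths_um)
        assert np.array_equal(a.thetas_deg, b.thetas_deg)

    def test_centroids_inside_cell_ellipse(self):
        cfg = GeneratorConfig(cell_semi_axes_um=(25.0, 15.0))
        fs = generate_cell_filaments(cfg, seed=4)
        assert np.all((fs.x_um / 25.0) ** 2 + (fs.y_um / 15.0) ** 2 <= 1.0 + 1e-9)

    def test_degenerate_widths_factorize_F(self):
        # widths concentrated at w => F = w * sum(l)
        cfg = GeneratorConfig(mu_width_um=0.4, sigma_width_um=1e-9)
        fs = generate_cell_filaments(cfg, seed=2)
        m = cell_metrics(fs)
        assert m.F_um2 == pytest.approx(0.4 * fs.lengths_um.sum(), rel=1e-6)


def _toy_set(n=50, seed=0):
    rng = np.random.default_rng(seed)
    return FilamentSet(lengths_um=rng.uniform(2, 12, n), widths_um=rng.uniform(0.2, 0.6, n),
                       thetas_deg=rng.uniform(0, 180, n),
                       x_um=rng.uniform(-20, 20, n), y_um=rng.uniform(-15, 15, n))


class TestBuckling:
    def test_zero_fraction_is_identity(self):
        fs = _toy_set()
        out = apply_buckling(fs, 0.0, 3, 10.0, seed=1)
        assert np.array_equal(out.lengths_um, fs.lengths_um)
        assert np.array_equal(out.thetas_deg, fs.thetas_deg)

    def test_full_buckling_triples_count_preserves_F(self):
        fs = _toy_set()
        out = apply_buckling(fs, 1.0, 3, 0.0, seed=1)
        assert out.n == 3 * fs.n
        m0, m1 = cell_metrics(fs), cell_metrics(out)
        assert m1.F_um2 == pytest.approx(m0.F_um2, rel=1e-9)   # widths kept, lengths partitioned
        assert m1.L_um == pytest.approx(m0.L_um / 3, rel=1e-9)

    def test_sub_segment_centroids_on_parent_axis(self):
        fs = FilamentSet(lengths_um=[10.0], widths_um=[0.5], thetas_deg=[30.0],
                         x_um=[2.0], y_um=[-1.0])
        out = apply_buckling(fs, 1.0, 4, 0.0, seed=3)
        ux, uy = math.cos(math.radians(30)), math.sin(math.radians(30))
        # each centroid lies on the parent line through (2,-1) at angle 30
        for x, y in zip(out.x_um, out.y_um):
            cross = (x - 2.0) * uy - (y + 1.0) * ux
            assert abs(cross) < 1e-9

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            apply_buckling(_toy_set(), 0.5, 1, 0.0, seed=0)

    def test_jitter_raises_nu_across_cells(self):
        # 200 cells: measured nu rises for nearly all after jittered buckling
        cfg = GeneratorConfig()
        up = 0
        for i in range(200):
            fs = generate_cell_filaments(cfg, seed=1000 + i)
            out = apply_buckling(fs, 1.0, 3, 20.0, seed=2000 + i)
            up += cell_metrics(out).nu_rad > cell_metrics(fs).nu_rad
        assert up >= 0.95 * 200


class TestDepolymerization:
    def test_identity_with_zero_removal(self):
        fs = _toy_set()
        out = apply_depolymerization(fs, 0.0, seed=1)
        assert out.n == fs.n

    def test_full_removal_empties_set(self):
        out = apply_depolymerization(_toy_set(), 1.0, seed=1)
        assert out.n == 0 and cell_metrics(out).F_um2 == 0.0

    def test_holes_delete_filaments_inside_disc(self):
        fs = FilamentSet(lengths_um=[5, 5], widths_um=[0.4, 0.4],
                         thetas_deg=[0, 0], x_um=[0.0, 10.0], y_um=[0.0, 0.0])
        out = apply_depolymerization(fs, 0.0, hole_centers=[(0.0, 0.0)],
                                     hole_radius_um=2.0, seed=0)
        assert out.n == 1 and out.x_um[0] == 10.0

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            apply_depolymerization(_toy_set(), 0.1, [(0, 0)], -1.0, seed=0)

    def test_thinning_expectation_minus_30_percent(self):
        cfg = GeneratorConfig()
        deltas = []
        for i in range(200):
            fs = generate_cell_filaments(cfg, seed=i)
            out = apply_depolymerization(fs, 0.3, seed=10_000 + i)
            deltas.append(100 * (cell_metrics(out).F_um2 / cell_metrics(fs).F_um2 - 1))
        mean = np.mean(deltas)
        se = np.std(deltas, ddof=1) / math.sqrt(len(deltas))
        assert abs(mean - (-30.0)) < 4 * se + 0.5


class TestCracking:
    def test_no_cracks_is_identity(self):
        fs = _toy_set()
        out = apply_cracking(fs, [], 1.0)
        assert out.n == fs.n
        assert np.allclose(out.lengths_um, fs.lengths_um)

    def test_midpoint_crack_geometry_by_hand(self):
        # horizontal filament of length 10 crossed at its midpoint, gap 2
        fs = FilamentSet(lengths_um=[10.0], widths_um=[0.4], thetas_deg=[0.0],
                         x_um=[0.0], y_um=[0.0])
        out = apply_cracking(fs, [((0.0, -5.0), (0.0, 5.0))], gap_um=2.0)
        assert out.n == 2
        assert np.allclose(sorted(out.lengths_um), [4.0, 4.0])
        assert np.allclose(out.thetas_deg, 0.0)

    def test_short_pieces_dropped(self):
        fs = FilamentSet(lengths_um=[10.0], widths_um=[0.4], thetas_deg=[0.0],
                         x_um=[0.0], y_um=[0.0])
        # crack near one end: the 0.3 um remnant is below the minimum
        out = apply_cracking(fs, [((-4.5, -5.0), (-4.5, 5.0))], gap_um=0.4,
                             min_piece_um=0.5)
        assert out.n == 1
        assert out.lengths_um[0] == pytest.approx(10 - 0.5 - 0.2, abs=1e-9)

    def test_cracking_never_increases_mean_length(self):
        rng = np.random.default_rng(8)
        for trial in range(50):
            fs = _toy_set(seed=trial)
            cracks = [((rng.uniform(-20, 20), rng.uniform(-15, 15)),
                       (rng.uniform(-20, 20), rng.uniform(-15, 15)))
                      for _ in range(3)]
            out = apply_cracking(fs, cracks, gap_um=rng.uniform(0, 2))
            if out.n:
                assert cell_metrics(out).L_um <= cell_metrics(fs).L_um + 1e-9

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            apply_cracking(_toy_set(), [], -0.1)


class TestAnnexinPixels:
    def test_zero_sd_is_constant(self):
        px = generate_annexin_pixels(False, 0.0, 50, seed=1)
        assert np.ptp(px) == 0.0

    def test_sample_sd_matches_target(self):
        for target in (100.0, 6500.0):
            px = generate_annexin_pixels(True, target, 500, seed=2)
            assert np.std(px, ddof=0) == pytest.approx(target, rel=1e-9)

    def test_gate_polarity_from_drawn_targets(self):
        from cryoactin.classify import apoptosis_gate
        pos = generate_annexin_pixels(True, None, 200, seed=3)
        neg = generate_annexin_pixels(False, None, 200, seed=4)
        assert apoptosis_gate(float(np.std(pos)))
        assert not apoptosis_gate(float(np.std(neg)))

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError):
            generate_annexin_pixels(True, 100.0, 1, seed=0)


class TestGenerateCohort:
    def test_design_arithmetic(self, default_cohort):
        # 4 conditions x 3 times x 3 replicates x 15 cells
        assert len(default_cohort.manifest) == 540
        pre_cells = default_cohort.filament_table.query("stage == 'pre'")["cell_id"].nunique()
        assert pre_cells == 540

    def test_determinism_bit_identical(self):
        cfg = GeneratorConfig(conditions=("control", "slow_1C"),
                              recovery_times_min=(0,), n_replicates=2,
                              n_cells_per_replicate=5)
        a = generate_cohort(cfg, seed=7)
        b = generate_cohort(cfg, seed=7)
        pd.testing.assert_frame_equal(a.filament_table, b.filament_table)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)

    def test_forced_detachment_stratum(self):
        cfg = GeneratorConfig(
            conditions=("control", "vitrified"), recovery_times_min=(0,),
            n_replicates=2, n_cells_per_replicate=5,
            damage_params={("vitrified", 0): StratumParams(0.5, 0.5, 1.0)})
        cohort = generate_cohort(cfg, seed=3)
        vit = cohort.manifest.query("condition == 'vitrified'")
        assert vit["detached"].all()
        post = cohort.filament_table.query("stage == 'post'")
        assert not post["cell_id"].isin(vit["cell_id"]).any()

    def test_planted_margin_from_boundaries(self, default_cohort):
        gt = default_cohort.ground_truth.dropna(subset=["delta_T"])
        man = default_cohort.manifest.set_index("cell_id")
        apop = man.loc[gt["cell_id"], "annexin_sd"] > 6000
        dt = gt.loc[apop.to_numpy(), "delta_T"]
        for boundary in (10.0, 20.0):
            assert (abs(dt - boundary) >= 2.0).all()

    def test_planted_labels_recovered_by_pipeline(self, default_cohort):
        from cryoactin.pipeline import alterations_from_tables

        alt = alterations_from_tables(default_cohort.filament_table,
                                      default_cohort.manifest)
        merged = alt.merge(default_cohort.manifest[["cell_id", "planted_class"]],
                           on="cell_id")
        assert (merged["assigned_class"] == merged["planted_class"]).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(filament_count_range=(10, 5)).validate()
        with pytest.raises(ValueError):
            StratumParams(p_damaged=1.5)
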