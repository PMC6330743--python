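"""Tests for the synthetic vasculature and angiogram renderer."""

import math
from dataclasses import replace

import numpy as np
import pytest

from octaquant import pipeline, synth
from octaquant.errors import InvalidParameterError, UnsupportedModalityError

from conftest import make_tree


class TestGrowVesselTree:
    def test_no_branching_gives_single_path(self):
        params = synth.GrowthParams(branch_prob=0.0, n_steps=10)
        tree = synth.grow_vessel_tree(params, n_sprouts=1, seed=4)
        assert len(tree) == 10
        # an unbranched path: segment k's parent is k-1
        parents = [s.parent for s in tree.segments]
        assert parents == [None] + list(range(9))

    def test_same_seed_same_tree(self):
        params = synth.GrowthParams(branch_prob=0.3, n_steps=15)
        t1 = synth.grow_vessel_tree(params, n_sprouts=3, seed=11)
        t2 = synth.grow_vessel_tree(params, n_sprouts=3, seed=11)
        assert t1.segments == t2.segments

    def test_different_seed_differs(self):
        params = synth.GrowthParams(branch_prob=0.3, n_steps=15)
        t1 = synth.grow_vessel_tree(params, n_sprouts=3, seed=11)
        t2 = synth.grow_vessel_tree(params, n_sprouts=3, seed=12)
        assert t1.segments != t2.segments

    @pytest.mark.parametrize("seed", [7, 19, 101])
    def test_segment_count_matches_independent_replay(self, seed):
        """Segment count equals a straight-line re-simulation of the growth
        loop that tracks only tip counts and the Bernoulli branch stream."""
        params = synth.GrowthParams(branch_prob=0.3, n_steps=20)
        tree = synth.grow_vessel_tree(params, n_sprouts=5, seed=seed)

        branch = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
        tips = 5
        total = 0
        for _ in range(params.n_steps):
            new = 0
            for _tip in range(tips):
                total += 1
                if float(branch.uniform()) < params.branch_prob:
                    if tips + new < params.max_tips:
                        new += 1
            tips += new
        assert len(tree) == total

    def test_tree_invariants(self):
        params = synth.GrowthParams(branch_prob=0.25, n_steps=18)
        tree = synth.grow_vessel_tree(params, n_sprouts=4, seed=2)
        for seg in tree.segments:
            assert seg.radius_um > 0
            assert 0.0 <= seg.depth_um <= params.depth_max_um
            if seg.parent is not None:
                parent = tree.segments[seg.parent]
                assert parent.end == seg.start
                assert seg.radius_um <= parent.radius_um + 1e-12

    def test_roots_start_on_border(self):
        tree = synth.grow_vessel_tree(synth.GrowthParams(), n_sprouts=6, seed=0)
        roots = [s for s in tree.segments if s.parent is None]
        assert len(roots) == 6
        for s in roots:
            x, y = s.start
            assert min(x, y, 1 - x, 1 - y) == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_sprouts": 0},
            {"params": synth.GrowthParams(step_len=0.0)},
            {"params": synth.GrowthParams(branch_prob=1.5)},
        ],
    )
    def test_invalid_parameters(self, kwargs):
        params = kwargs.get("params", synth.GrowthParams())
        n = kwargs.get("n_sprouts", 2)
        with pytest.raises(InvalidParameterError):
            synth.grow_vessel_tree(params, n_sprouts=n, seed=0)


class TestGroundTruthDensity:
    def test_empty_tree_zero(self):
        tree = make_tree([])
        assert synth.ground_truth_density(tree, (20, 20), 10.0) == 0.0

    def test_full_coverage_hundred(self):
        tree = make_tree([(None, (0.0, 0.5), (1.0, 0.5), 5000.0, 100.0)])
        assert synth.ground_truth_density(tree, (16, 16), 10.0) == 100.0

    def test_rectangular_vessel_direct_count(self):
        # full-height vertical tube, radius 22 um = 2.2 px: covers 5 of 20
        # columns over all 10 rows -> 50 / 200 pixels = 25 %
        tree = make_tree([(None, (0.225, 0.0), (0.225, 1.0), 22.0, 100.0)])
        assert synth.ground_truth_density(tree, (10, 20), 10.0) == 25.0

    def test_depth_window_filters_segments(self):
        tree = make_tree(
            [
                (None, (0.1, 0.3), (0.9, 0.3), 30.0, 100.0),
                (None, (0.1, 0.7), (0.9, 0.7), 30.0, 300.0),
            ]
        )
        full = synth.ground_truth_density(tree, (40, 40), 10.0)
        shallow = synth.ground_truth_density(
            tree, (40, 40), 10.0, depth_window=(0.0, 200.0)
        )
        deep = synth.ground_truth_density(
            tree, (40, 40), 10.0, depth_window=(200.0, 400.0)
        )
        assert shallow > 0 and deep > 0
        assert shallow + deep == pytest.approx(full)
        # window is half-open: a segment exactly at the upper edge is excluded
        assert synth.ground_truth_density(
            tree, (40, 40), 10.0, depth_window=(0.0, 100.0)
        ) == 0.0

    def test_empty_window_rejected(self):
        tree = make_tree([])
        with pytest.raises(InvalidParameterError):
            synth.ground_truth_density(tree, (20, 20), 10.0, depth_window=(50.0, 50.0))

    def test_adding_segment_never_decreases_density(self):
        tree = synth.grow_vessel_tree(
            synth.GrowthParams(branch_prob=0.2, n_steps=12), 2, seed=5
        )
        dens = synth.ground_truth_density(tree, (64, 64), 10.0)
        bigger = tree.with_segment(
            synth.VesselSegment(None, (0.5, 0.1), (0.5, 0.9), 25.0, 200.0)
        )
        assert synth.ground_truth_density(bigger, (64, 64), 10.0) >= dens


class TestRenderEnface:
    def test_empty_tree_no_noise_all_zero(self, noise_free_profile):
        profile = replace(noise_free_profile, background_level=0.0)
        img = synth.render_enface(make_tree([]), profile, (32, 32), 10.0, seed=0)
        assert img.scale == "uint8"
        assert not img.pixels.any()

    def test_tube_density_matches_analytic_area(self, sharp_profile):
        # capsule: rectangle L x 2r plus two half-discs of radius r
        r_um, px = 30.0, 10.0
        tree = make_tree([(None, (0.25, 0.5), (0.75, 0.5), r_um, 150.0)])
        img = synth.render_enface(tree, sharp_profile, (60, 60), px, seed=1)
        mid = synth.VESSEL_LEVEL * 255 / 2
        mask = img.pixels > mid
        length_px = 0.5 * 60
        r_px = r_um / px
        analytic = (length_px * 2 * r_px + math.pi * r_px**2) / (60 * 60) * 100
        measured = 100 * mask.mean()
        # 1 blurred-pixel band around the capsule perimeter
        perimeter_px = 2 * length_px + 2 * math.pi * r_px
        assert abs(measured - analytic) <= 100 * perimeter_px / (60 * 60)

    def test_deterministic_per_seed(self, single_tube_tree):
        a = synth.render_enface(
            single_tube_tree, synth.OMAG_PROFILE, (48, 48), 10.0, seed=3
        )
        b = synth.render_enface(
            single_tube_tree, synth.OMAG_PROFILE, (48, 48), 10.0, seed=3
        )
        assert np.array_equal(a.pixels, b.pixels)

    def test_motion_lines_reproducible_and_present(self, single_tube_tree):
        profile = replace(
            synth.OMAG_PROFILE, motion_line_rate=2.0, speckle_shape=None
        )
        imgs = [
            synth.render_enface(single_tube_tree, profile, (48, 48), 10.0, seed=9)
            for _ in range(2)
        ]
        assert np.array_equal(imgs[0].pixels, imgs[1].pixels)
        line_level = round(synth.MOTION_LINE_LEVEL * 255)
        full_rows = (imgs[0].pixels == line_level).all(axis=1).sum()
        full_cols = (imgs[0].pixels == line_level).all(axis=0).sum()
        assert full_rows + full_cols >= 1


class TestRenderVolume:
    def test_icga_rejected(self, single_tube_tree):
        with pytest.raises(UnsupportedModalityError):
            synth.render_volume(
                single_tube_tree, synth.ICGA_PROFILE, (32, 32, 8), 50.0, 10.0, seed=0
            )

    def test_no_projection_deep_slabs_background_only(self, single_tube_tree):
        profile = replace(
            synth.OMAG_PROFILE,
            projection_strength=0.0,
            speckle_shape=None,
            motion_line_rate=0.0,
        )
        vol = synth.render_volume(
            single_tube_tree, profile, (32, 32, 8), 50.0, 10.0, seed=0
        )
        bg = round(profile.background_level * 255)
        # vessel at 150 um lives in slice 3; slices 4.. carry only background
        deep = vol.voxels[:, :, 4:]
        assert (deep == bg).all()

    def test_full_projection_decays_exponentially(self, sharp_profile):
        profile = replace(
            sharp_profile,
            name="SSADA",
            supports_volume=True,
            projection_strength=1.0,
            projection_decay_um=200.0,
        )
        tree = make_tree([(None, (0.2, 0.5), (0.8, 0.5), 30.0, 25.0)])
        vol = synth.render_volume(tree, profile, (40, 40, 6), 50.0, 10.0, seed=0)
        base = vol.voxels[:, :, 0].max() / 255.0
        footprint = vol.voxels[:, :, 0] > 128
        for k in range(1, 6):
            expected = base * math.exp(-k * 50.0 / 200.0)
            got = vol.voxels[:, :, k].astype(float)[footprint].max() / 255.0
            assert got == pytest.approx(expected, abs=2 / 255)

    def test_deterministic_per_seed(self, single_tube_tree):
        a = synth.render_volume(
            single_tube_tree, synth.SSADA_PROFILE, (32, 32, 6), 50.0, 10.0, seed=5
        )
        b = synth.render_volume(
            single_tube_tree, synth.SSADA_PROFILE, (32, 32, 6), 50.0, 10.0, seed=5
        )
        assert np.array_equal(a.voxels, b.voxels)

    def test_deep_enface_density_monotone_in_projection_strength(
        self, single_tube_tree
    ):
        densities = []
        for strength in (0.0, 0.4, 0.8):
            profile = replace(
                synth.SSADA_PROFILE,
                projection_strength=strength,
                speckle_shape=None,
                motion_line_rate=0.0,
            )
            vol = synth.render_volume(
                single_tube_tree, profile, (40, 40, 8), 50.0, 10.0, seed=2
            )
            # density of the deepest slab's raw footprint above background
            bg = round(profile.background_level * 255)
            densities.append((vol.voxels[:, :, 7] > bg + 5).mean())
        assert densities == sorted(densities)


class TestProfiles:
    def test_default_profiles_follow_device_character(self):
        assert synth.SSADA_PROFILE.psf_fwhm_um == 15.0
        assert synth.OMAG_PROFILE.psf_fwhm_um == 20.0
        assert synth.SSADA_PROFILE.projection_strength > 0
        assert synth.OMAG_PROFILE.projection_strength == 0
        assert synth.OMAG_PROFILE.motion_line_rate > synth.SSADA_PROFILE.motion_line_rate
        assert not synth.ICGA_PROFILE.supports_volume

    def test_profile_validation(self):
        with pytest.raises(InvalidParameterError):
            replace(synth.SSADA_PROFILE, projection_strength=1.5)
        with pytest.raises(InvalidParameterError):
            replace(synth.SSADA_PROFILE, psf_fwhm_um=0.0)
        with pytest.raises(UnsupportedModalityError):
            synth.default_profile("FA")
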