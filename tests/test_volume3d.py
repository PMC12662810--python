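import numpy as np
import pytest

from octmargin.phantom import (PRESETS, PassRecord, Region, SceneSpec,
                               synth_bscan, synth_pass_stacks)
from octmargin.volume3d import (VolumeStack, attenuation_volume, classify_color,
                                classify_volume, deinterleave, extract_surface,
                                interleave_passes, render_volume,
                                surface_matrix)


def _labeled_pass(labels, direction, index):
    """Tiny 1x1 'slices' carrying an integer label, for order bookkeeping."""
    slices = [np.full((1, 1), v, dtype=np.uint8) for v in labels]
    return PassRecord(index=index, direction=direction, slices=slices,
                      positions_mm=[], truths=[])


class TestInterleave:
    def test_single_pass_identity(self):
        rec = _labeled_pass([1, 2, 3], "forward", 0)
        stack = interleave_passes([rec], 0.1)
        assert [int(s) for s in stack.slices[:, 0, 0]] == [1, 2, 3]
        assert stack.slice_spacing_mm == pytest.approx(0.1)

    def test_backward_pass_normalized_then_woven(self):
        # pass0 stores A0,A1,A2; pass1 (backward) stores B2,B1,B0
        p0 = _labeled_pass([10, 11, 12], "forward", 0)
        p1 = _labeled_pass([22, 21, 20], "backward", 1)
        stack = interleave_passes([p0, p1], 0.1)
        assert [int(s) for s in stack.slices[:, 0, 0]] == [10, 20, 11, 21, 12, 22]
        assert stack.slice_spacing_mm == pytest.approx(0.05)

    def test_ten_pass_spacing_claim(self):
        passes = [_labeled_pass(list(range(5)), "backward" if p % 2 else "forward", p)
                  for p in range(10)]
        stack = interleave_passes(passes, 0.187)
        assert stack.slice_spacing_mm == pytest.approx(0.0187, abs=1e-12)
        assert stack.slice_spacing_mm * 10 == pytest.approx(0.187, abs=1e-15)

    def test_provenance_inversion_round_trip(self, tiny_geom):
        scene = SceneSpec(geometry=tiny_geom,
                          regions=(Region(0, tiny_geom.n_cols,
                                          PRESETS["all_glioma"], mu=5.0),),
                          standoff_mm=0.5, seed=21)
        passes = synth_pass_stacks(scene, 3, 4)
        stack = interleave_passes(passes, 0.1)
        restored = deinterleave(stack, 3)
        for rec, back in zip(passes, restored):
            for a, b in zip(rec.slices, back):
                assert np.array_equal(a, b)

    def test_ragged_passes_error(self):
        p0 = _labeled_pass([1, 2, 3], "forward", 0)
        p1 = _labeled_pass([1, 2], "forward", 1)
        with pytest.raises(ValueError, match="ragged"):
            interleave_passes([p0, p1], 0.1)


class TestExtractSurface:
    def test_clean_step(self):
        img = np.zeros((30, 12), dtype=np.uint8)
        img[10:] = 200
        surf = extract_surface(img)
        assert np.all(surf == 10)

    def test_all_background_undefined(self):
        img = np.zeros((30, 12), dtype=np.uint8)
        assert np.all(np.isnan(extract_surface(img)))

    def test_opening_removes_isolated_speck(self):
        img = np.zeros((15, 5), dtype=np.uint8)
        img[10:] = 200
        img[3, 2] = 255                      # lone bright speck above the tissue
        surf = extract_surface(img)
        assert np.all(surf == 10)

    def test_subthreshold_noise_invariance(self, rng):
        img = np.zeros((40, 20), dtype=np.uint8)
        img[25:] = 200
        noisy = img.copy()
        noise = rng.integers(0, 70, size=img.shape).astype(np.uint8)
        noisy[img == 0] = noise[img == 0]    # arbitrary sub-threshold values
        assert np.array_equal(extract_surface(img), extract_surface(noisy))

    def test_raising_a_block_never_deepens_surface(self):
        img = np.zeros((40, 20), dtype=np.uint8)
        img[25:] = 200
        before = extract_surface(img)
        raised = img.copy()
        raised[10:13, 5:8] = 200             # supra-threshold block above surface
        after = extract_surface(raised)
        assert np.all(after <= before)


class TestAttenuationVolume:
    def _uniform_stack(self, geom, mu, n_slices=3):
        scene = SceneSpec(geometry=geom,
                          regions=(Region(0, geom.n_cols, PRESETS["all_glioma"],
                                          mu=mu),),
                          surface_roughness_mm=0.0, noise=False,
                          standoff_mm=1.0, seed=0)
        img, _ = synth_bscan(scene)
        slices = np.stack([img] * n_slices)
        return VolumeStack(slices=slices, slice_spacing_mm=0.1,
                           positions_mm=np.arange(n_slices) * 0.1)

    def test_uniform_phantom_recovery(self, geom):
        stack = self._uniform_stack(geom, 5.0)
        att = attenuation_volume(stack)
        good = np.abs(att.mu - 5.0) <= 0.2
        assert att.defined_fraction >= 0.99
        assert good[np.isfinite(att.mu)].mean() >= 0.99

    def test_blank_volume_all_undefined(self):
        stack = VolumeStack(slices=np.zeros((2, 64, 8), dtype=np.uint8),
                            slice_spacing_mm=0.1, positions_mm=np.arange(2) * 0.1)
        att = attenuation_volume(stack)
        assert np.all(np.isnan(att.mu))


class TestClassifyColor:
    @pytest.mark.parametrize("mu,zone", [
        (4.5, "red"),        # tumor-probable
        (5.5, "yellow"),     # boundary
        (0.0, "red"), (5.0, "yellow"), (6.0, "green"), (11.0, "green"),
        (8.0, "green"),
    ])
    def test_zone_ownership(self, mu, zone):
        assert classify_color(mu)[0] == zone

    @pytest.mark.parametrize("mu", [float("nan"), -0.1, 11.01, None])
    def test_undefined_renders_white(self, mu):
        zone, rgb = classify_color(mu)
        assert zone == "white" and rgb == (255, 255, 255)

    def test_ramp_monotone_within_zones(self):
        reds = [classify_color(m)[1][0] for m in np.linspace(0, 4.99, 25)]
        greens = [classify_color(m)[1][1] for m in np.linspace(6, 11, 25)]
        assert all(a <= b for a, b in zip(reds, reds[1:])) and reds[0] < reds[-1]
        assert all(a <= b for a, b in zip(greens, greens[1:])) and greens[0] < greens[-1]

    def test_zone_partition_no_white_leaks(self):
        """Every defined mu in [0, 11] maps to exactly one colored zone."""
        for mu in np.linspace(0.0, 11.0, 2201):
            zone, rgb = classify_color(float(mu))
            assert zone in ("red", "yellow", "green")
            assert rgb != (255, 255, 255)

    def test_classify_volume_shape(self):
        from octmargin.volume3d import AttenuationVolume

        mu = np.array([[4.0, np.nan], [5.5, 7.0]])
        rgb = classify_volume(AttenuationVolume(mu=mu))
        assert rgb.shape == (2, 2, 3)
        assert tuple(rgb[0, 1]) == (255, 255, 255)


class TestRenderVolume:
    def _stack(self, geom, scene_kwargs=None, n_slices=2):
        kwargs = dict(surface_roughness_mm=0.0, noise=False,
                      standoff_mm=1.0, seed=5)
        kwargs.update(scene_kwargs or {})
        scene = SceneSpec(geometry=geom, **kwargs)
        slices, truths = [], []
        for noise_seed in range(1, n_slices + 1):
            img, t = synth_bscan(scene, noise_seed=noise_seed)
            slices.append(img)
            truths.append(t)
        stack = VolumeStack(slices=np.stack(slices), slice_spacing_mm=0.1,
                            positions_mm=np.arange(n_slices) * 0.1)
        return stack, truths

    def test_uniform_scene_renders_all_red(self, tiny_geom):
        regions = (Region(0, tiny_geom.n_cols, PRESETS["all_glioma"], mu=4.0),)
        stack, _ = self._stack(tiny_geom, {"regions": regions,
                                           "standoff_mm": 0.25})
        att = attenuation_volume(stack)
        surf = surface_matrix(stack)
        render = render_volume(att, surf, stack, tiny_geom.lateral_pitch_mm,
                               tiny_geom.axial_pitch_mm)
        assert len(render.vertices) > 0
        assert np.all(render.vertex_colors[:, 1] == 0)   # pure red zone
        assert np.all(render.vertex_colors[:, 0] > 0)

    def test_split_scene_zones(self, geom):
        regions = (Region(0, 256, PRESETS["all_glioma"], mu=4.8),
                   Region(256, 512, PRESETS["peritumoral_all"], mu=6.4))
        stack, _ = self._stack(geom, {"regions": regions})
        att = attenuation_volume(stack)
        zones = [classify_color(m)[0] for m in att.mu[0]]
        assert set(zones[:250]) == {"red"}
        assert set(zones[262:]) == {"green"}
        assert "yellow" not in zones[:250] + zones[262:]

    def test_mesh_heights_match_generator_surface(self, geom):
        regions = (Region(0, geom.n_cols, PRESETS["all_glioma"], mu=5.0),)
        stack, truths = self._stack(geom, {"regions": regions,
                                           "surface_roughness_mm": 0.15})
        att = attenuation_volume(stack)
        surf = surface_matrix(stack)
        render = render_volume(att, surf, stack, geom.lateral_pitch_mm,
                               geom.axial_pitch_mm)
        true_rows = truths[0].surface_row
        mesh_rows = surf[0]
        ok = np.isfinite(mesh_rows)
        assert ok.mean() > 0.95
        assert np.max(np.abs(mesh_rows[ok] - true_rows[ok])) <= 1.0

    def test_side_faces_shapes_and_blanking(self, tiny_geom):
        regions = (Region(0, tiny_geom.n_cols, PRESETS["all_glioma"], mu=4.0),)
        stack, truths = self._stack(tiny_geom, {"regions": regions})
        att = attenuation_volume(stack)
        surf = surface_matrix(stack)
        render = render_volume(att, surf, stack, tiny_geom.lateral_pitch_mm,
                               tiny_geom.axial_pitch_mm)
        front = render.side_faces["front"]
        assert front.shape == (tiny_geom.n_rows, tiny_geom.n_cols, 3)
        # voxels above the surface are blanked white
        surface_row = int(truths[0].surface_row[0])
        assert np.all(front[:surface_row] == 255)

    def test_no_tissue_errors(self):
        stack = VolumeStack(slices=np.zeros((2, 16, 8), dtype=np.uint8),
                            slice_spacing_mm=0.1, positions_mm=np.arange(2) * 0.1)
        att = attenuation_volume(stack)
        surf = surface_matrix(stack)
        with pytest.raises(ValueError, match="no tissue"):
            render_volume(att, surf, stack, 0.01, 0.024445)
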