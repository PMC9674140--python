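"""Lean morphometrics: profiles, boundary detection, regional volumes,
chambers and body size."""

import numpy as np
import pytest

from fishct.compartments import Compartment
from fishct.errors import BoundaryUndetectableError, EmptyBodyError, FishCTError
from fishct.morphometrics import (
    body_measures,
    body_size,
    chamber_lengths,
    csa_profile,
    detect_swimbladder_boundary,
    lean_profile,
    regional_lean_volumes,
)
from fishct.phantom import generate_phantom
from fishct.segmentation import segment_tissues

from conftest import NOISE_LOW, scaled_spec
from helpers import make_segmentation


def _cuboid_seg(n_ap=10, h=6, w=4):
    labels = np.zeros((n_ap, h + 6, w + 8), dtype=np.uint8)
    labels[:, 3:3 + h, 4:4 + w] = Compartment.LEAN
    return make_segmentation(labels)


class TestProfile:
    def test_cuboid_constant_profile(self):
        seg = _cuboid_seg(h=6, w=4)
        area = csa_profile(seg, "lean")
        expected = 6 * 4 * 21.0 * 21.0 * 1e-6
        assert np.allclose(area, expected)

    def test_empty_compartment_zero_profile(self):
        seg = _cuboid_seg()
        assert np.all(csa_profile(seg, "bone") == 0)

    def test_unknown_compartment(self):
        with pytest.raises(KeyError):
            csa_profile(_cuboid_seg(), "muscle")

    def test_adipose_counts_toward_lean(self):
        labels = np.zeros((4, 8, 8), dtype=np.uint8)
        labels[:, 2:4, 2:4] = Compartment.LEAN
        labels[:, 4:6, 2:4] = Compartment.ADIPOSE
        seg = make_segmentation(labels)
        assert np.allclose(csa_profile(seg, "lean"), 8 * 21.0 * 21.0 * 1e-6)

    def test_profile_integrates_to_lean_volume(self, noisy_phantom, noisy_seg):
        _, _, _, truth = noisy_phantom
        prof = lean_profile(noisy_seg)
        integral = prof.lean_mm2.sum() * prof.slice_thickness_um / 1000.0
        assert integral == pytest.approx(truth.regional_lean_mm3[0], rel=0.05)


class TestBoundary:
    def test_phantom_boundary_within_one_slice(self, noisy_phantom, noisy_seg):
        _, volume, _, truth = noisy_phantom
        b = detect_swimbladder_boundary(noisy_seg, volume.data)
        assert abs(b - truth.boundary_slice) <= 1

    def test_explicit_override_returned(self, noisy_phantom, noisy_seg):
        _, volume, _, _ = noisy_phantom
        assert detect_swimbladder_boundary(noisy_seg, volume.data, override=123) == 123

    def test_single_chamber_undetectable(self):
        labels = np.zeros((30, 16, 16), dtype=np.uint8)
        labels[2:28, 2:14, 2:14] = Compartment.LEAN
        labels[10:20, 6:10, 6:10] = Compartment.ADIPOSE  # one air cavity
        seg = make_segmentation(labels)
        data = np.where(labels == Compartment.LEAN, 120, 0).astype(np.int32)
        with pytest.raises(BoundaryUndetectableError):
            detect_swimbladder_boundary(seg, data, min_voxels=10)

    def test_boundary_within_one_slice_over_random_specs(self):
        """Detection error <= 1 slice across varied geometries (subsampled
        from the 50-spec invariant for runtime)."""
        rng = np.random.default_rng(99)
        for k in range(12):
            spec = scaled_spec(
                0.7,
                noise_sd=NOISE_LOW,
                seed=int(rng.integers(2**31)),
                sb_boundary_frac=float(rng.uniform(0.40, 0.50)),
                sb_anterior_length=float(rng.uniform(1900, 2400)),
                sb_posterior_length=float(rng.uniform(2600, 3100)),
            )
            volume, _, truth = generate_phantom(spec)
            seg = segment_tissues(volume)
            b = detect_swimbladder_boundary(seg, volume.data)
            assert abs(b - truth.boundary_slice) <= 1, f"spec {k}"


class TestRegionalVolumes:
    def test_uniform_profile_midpoint_split(self):
        seg = _cuboid_seg(n_ap=10)
        prof = lean_profile(seg)
        trunk, ant, post = regional_lean_volumes(prof, boundary=5)
        assert ant == pytest.approx(post)
        assert trunk == pytest.approx(ant + post)

    def test_boundary_at_trunk_start(self):
        seg = _cuboid_seg(n_ap=10)
        prof = lean_profile(seg)
        trunk, ant, post = regional_lean_volumes(prof, boundary=0)
        assert ant == 0
        assert post == pytest.approx(trunk)

    def test_boundary_outside_range(self):
        prof = lean_profile(_cuboid_seg(n_ap=10))
        with pytest.raises(FishCTError):
            regional_lean_volumes(prof, boundary=3, trunk_range=(5, 9))

    def test_regional_volumes_reproduce_total_lean(self, noisy_seg, noisy_phantom):
        _, volume, _, _ = noisy_phantom
        prof = lean_profile(noisy_seg, volume.data)
        trunk, ant, post = regional_lean_volumes(prof)
        assert trunk == pytest.approx(ant + post, abs=1e-12)
        assert trunk == pytest.approx(noisy_seg.lean_volume_mm3, rel=1e-12)

    def test_phantom_split_recovered(self, noisy_phantom, noisy_seg):
        _, volume, _, truth = noisy_phantom
        prof = lean_profile(noisy_seg, volume.data)
        _, ant, post = regional_lean_volumes(prof, boundary=truth.boundary_slice)
        _, t_ant, t_post = truth.regional_lean_mm3
        assert ant == pytest.approx(t_ant, rel=0.05)
        assert post == pytest.approx(t_post, rel=0.05)


class TestChambers:
    def test_phantom_chambers_within_one_voxel(self, noisy_phantom, noisy_seg):
        spec, volume, _, truth = noisy_phantom
        ant, post = chamber_lengths(noisy_seg, volume.data)
        assert ant == pytest.approx(truth.chamber_lengths[0], abs=spec.voxel_size)
        assert post == pytest.approx(truth.chamber_lengths[1], abs=spec.voxel_size)

    def test_equal_chambers_equal_lengths(self):
        labels = np.zeros((40, 16, 16), dtype=np.uint8)
        labels[2:38, 2:14, 2:14] = Compartment.LEAN
        labels[5:15, 6:10, 6:10] = Compartment.ADIPOSE
        labels[25:35, 6:10, 6:10] = Compartment.ADIPOSE
        seg = make_segmentation(labels)
        data = np.where(labels == Compartment.LEAN, 120, 0).astype(np.int32)
        ant, post = chamber_lengths(seg, data, min_voxels=10)
        assert ant == post

    def test_no_cavities_error(self):
        seg = _cuboid_seg()
        data = np.where(seg.labels > 0, 120, 0).astype(np.int32)
        with pytest.raises(BoundaryUndetectableError):
            chamber_lengths(seg, data)


class TestBodySize:
    def test_fineness_arithmetic(self):
        seg = _cuboid_seg(n_ap=40, h=10)  # SL 40 vox, height 10 vox
        m = body_size(seg)
        assert m.fineness_ratio == pytest.approx(4.0)

    def test_empty_mask(self):
        labels = np.zeros((5, 5, 5), dtype=np.uint8)
        with pytest.raises(EmptyBodyError):
            body_size(make_segmentation(labels))

    def test_phantom_sl_within_two_voxels(self, noisy_phantom, noisy_seg):
        spec, _, _, truth = noisy_phantom
        m = body_size(noisy_seg)
        assert m.standard_length_um == pytest.approx(
            truth.standard_length, abs=2 * spec.voxel_size)
        assert m.dorsoventral_height_um == pytest.approx(
            truth.height, abs=2 * spec.voxel_size)

    def test_fineness_invariant_to_voxel_size(self):
        """The same fish digitized at two resolutions has the same fineness
        ratio within 2%."""
        vals = []
        for vx in (21.0, 42.0):
            spec = scaled_spec(0.7, noise_sd=0).replace(voxel_size=vx)
            volume, _, _ = generate_phantom(spec)
            seg = segment_tissues(volume)
            vals.append(body_size(seg).fineness_ratio)
        assert vals[0] == pytest.approx(vals[1], rel=0.02)

    def test_full_record(self, noisy_phantom, noisy_seg):
        _, volume, _, truth = noisy_phantom
        m = body_measures(noisy_seg, volume.data)
        assert m.trunk_lean_mm3 == pytest.approx(
            m.anterior_trunk_lean_mm3 + m.posterior_trunk_lean_mm3)
        assert abs(m.boundary_slice - truth.boundary_slice) <= 1
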