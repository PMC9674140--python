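"""Vertebra labeling, element partition, local thickness, arch geometry and
phenome assembly."""

import numpy as np
import pandas as pd
import pytest

from fishct.compartments import Compartment, Element
from fishct.errors import FishCTError, FusionError, GeometryError
from fishct.phantom import generate_phantom
from fishct.segmentation import segment_tissues
from fishct.vertebrae import (
    TMDCalibration,
    assemble_phenome,
    centrum_length,
    label_vertebrae,
    local_thickness,
    measure_element,
    neural_arch_geometry,
    partition_elements,
)

from conftest import scaled_spec
from helpers import local_thickness_bruteforce, make_segmentation

VX = 21.0


def _cylinder_labels(shape, centre, radius_vox, ap_range):
    labels = np.zeros(shape, dtype=np.uint8)
    jj, kk = np.mgrid[0:shape[1], 0:shape[2]]
    disc = (jj - centre[0]) ** 2 + (kk - centre[1]) ** 2 <= radius_vox ** 2
    labels[ap_range[0]:ap_range[1], disc] = Compartment.BONE
    return labels


class TestLabeling:
    def test_phantom_has_24_ordered_vertebrae(self, clean_labeling, clean_phantom):
        _, _, truth = clean_phantom
        assert clean_labeling.n_vertebrae == 24
        centroids = [np.argwhere(clean_labeling.labels == i)[:, 0].mean()
                     for i in range(1, 25)]
        assert np.all(np.diff(centroids) > 0)  # anterior to posterior
        # labels agree with the generator's vertebra identities
        overlap = (clean_labeling.labels == truth.vertebra_labels)[truth.vertebra_labels > 0]
        assert overlap.mean() > 0.99

    def test_empty_bone_mask(self):
        seg = make_segmentation(np.zeros((10, 10, 10), dtype=np.uint8))
        with pytest.raises(FishCTError):
            label_vertebrae(seg)

    def test_fused_pair_reported(self):
        # five centra, two of them bridged into one long component
        labels = np.zeros((120, 24, 24), dtype=np.uint8)
        for i in range(5):
            labels |= _cylinder_labels(labels.shape, (12, 12), 5,
                                       (5 + 20 * i, 15 + 20 * i))
        labels |= _cylinder_labels(labels.shape, (12, 12), 2, (15, 25))  # bridge
        seg = make_segmentation(labels)
        with pytest.raises(FusionError) as err:
            label_vertebrae(seg, clean_radius=0)
        assert err.value.component_ids  # names the offending component


class TestPartition:
    def test_element_agreement_with_truth(self, clean_labeling, clean_phantom):
        _, _, truth = clean_phantom
        bone = truth.vertebra_labels > 0
        agree = (clean_labeling.element_labels == truth.element_labels)[bone].mean()
        assert agree >= 0.95

    def test_arch_free_vertebra_is_all_centrum(self):
        labels = _cylinder_labels((40, 24, 24), (12, 12), 6, (5, 35))
        seg = make_segmentation(labels)
        lab = partition_elements(label_vertebrae(seg))
        assert lab.element_mask(1, Element.CENTRUM).sum() == (labels > 0).sum()
        assert lab.element_mask(1, Element.NEURAL_ARCH).sum() == 0
        assert lab.element_mask(1, Element.HAEMAL_ARCH).sum() == 0

    def test_symmetric_arches_have_similar_volumes(self, clean_labeling):
        vv = np.prod(clean_labeling.voxel_size) * 1e-9
        for i in (1, 12, 24):
            nv = clean_labeling.element_mask(i, Element.NEURAL_ARCH).sum() * vv
            hv = clean_labeling.element_mask(i, Element.HAEMAL_ARCH).sum() * vv
            assert nv == pytest.approx(hv, rel=0.10)

    def test_partition_conserves_vertebra_volume(self, clean_labeling):
        for i in (1, 10, 24):
            total = clean_labeling.vertebra_mask(i).sum()
            parts = sum(clean_labeling.element_mask(i, e).sum()
                        for e in (Element.CENTRUM, Element.NEURAL_ARCH,
                                  Element.HAEMAL_ARCH))
            assert parts == total


class TestThickness:
    def test_slender_cylinder_thickness_is_diameter(self):
        labels = _cylinder_labels((64, 16, 16), (8, 8), 3.2, (2, 62))
        mask = labels > 0
        lt = local_thickness(mask, VX)
        mean_th = lt[mask].mean()
        assert mean_th == pytest.approx(2 * 3.2 * VX, abs=VX)

    @pytest.mark.parametrize("builder", ["plate", "rod"])
    def test_equals_bruteforce_inscribed_sphere_oracle(self, builder):
        if builder == "plate":
            mask = np.zeros((6, 20, 20), dtype=bool)
            mask[1:5, 2:18, 2:18] = True  # plate of thickness 4
        else:
            mask = _cylinder_labels((30, 14, 14), (7, 7), 3.0, (2, 28)) > 0
        ours = local_thickness(mask, VX)
        oracle = local_thickness_bruteforce(mask, VX)
        assert np.allclose(ours[mask], oracle[mask], atol=1e-6)

    def test_phantom_element_vs_oracle(self, clean_labeling):
        """On a real (sub-40^3) centrum the operator matches the exhaustive
        maximal-inscribed-sphere oracle."""
        mask = clean_labeling.element_mask(5, Element.CENTRUM)
        ours = local_thickness(mask, VX)
        oracle = local_thickness_bruteforce(mask, VX)
        assert np.allclose(ours[mask], oracle[mask], atol=1e-6)


class TestMeasures:
    def test_uniform_intensity_tmd_exact(self):
        labels = _cylinder_labels((20, 16, 16), (8, 8), 4, (2, 18))
        mask = labels > 0
        intens = np.where(mask, 640.0, 0.0)
        calib = TMDCalibration(slope=0.5, intercept=100.0)
        vol, th, tmd = measure_element(mask, intens, VX, calib)
        assert tmd == pytest.approx(0.5 * 640.0 + 100.0)
        assert vol == pytest.approx(mask.sum() * VX**3 * 1e-9)

    def test_empty_element(self):
        with pytest.raises(FishCTError):
            measure_element(np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4)), VX)

    def test_calibration_needs_positive_slope(self):
        with pytest.raises(FishCTError):
            TMDCalibration(slope=-1.0)

    def test_single_slice_centrum_length(self):
        labels = _cylinder_labels((9, 16, 16), (8, 8), 4, (4, 5))
        lab = partition_elements(label_vertebrae(make_segmentation(labels),
                                                 clean_radius=0))
        assert centrum_length(lab, 1) == pytest.approx(VX / 1000.0)


class TestArchGeometry:
    def test_angle_recovered_within_2_degrees(self, clean_labeling, clean_spec):
        angles = [neural_arch_geometry(clean_labeling, i)[1] for i in (1, 8, 16, 24)]
        for a in angles:
            assert a == pytest.approx(clean_spec.neural_arch_angle_true, abs=2.0)

    @pytest.mark.parametrize("theta", [24.0, 45.0])
    def test_angle_parametrized(self, theta):
        """Apex-angle recovery on resolvable arches (leg length well above
        the ~15-row resolution floor)."""
        from fishct.phantom import PhantomSpec

        # only the neural angle varies: a narrower haemal arch would grow
        # ventrally into the swim bladder
        spec = PhantomSpec(noise_sd=0, neural_arch_angle_true=theta)
        volume, _, _ = generate_phantom(spec)
        lab = partition_elements(label_vertebrae(segment_tissues(volume)))
        _, angle = neural_arch_geometry(lab, 6)
        assert angle == pytest.approx(theta, abs=2.0)

    def test_missing_arch_is_geometry_error(self):
        labels = _cylinder_labels((40, 24, 24), (12, 12), 6, (5, 35))
        lab = partition_elements(label_vertebrae(make_segmentation(labels)))
        with pytest.raises(GeometryError):
            neural_arch_geometry(lab, 1)

    def test_arch_symmetric_about_sagittal_plane(self, clean_labeling):
        m = clean_labeling.element_mask(3, Element.NEURAL_ARCH)
        w = np.argwhere(m)
        (_, _), (az, bz) = clean_labeling.axis_fit
        rel_z = (w[:, 2] + 0.5) * VX - (az * (w[:, 0] + 0.5) * VX + bz)
        assert abs(rel_z.mean()) < VX / 2


class TestPhenome:
    def test_shape_and_finiteness(self, clean_labeling, clean_phantom):
        volume, _, _ = clean_phantom
        table = assemble_phenome(clean_labeling, volume.data)
        assert table.shape == (20, 12)
        assert np.isfinite(table.to_numpy()).all()

    def test_recovery_of_truth(self, clean_labeling, clean_phantom):
        """Volumes and lengths within 5%, TMD exact (noiseless, identity
        calibration), arch angle within 2 degrees."""
        volume, _, truth = clean_phantom
        table = assemble_phenome(clean_labeling, volume.data)
        tr = truth.vertebrae.loc[1:20]
        for col in ("Cent.Vol", "Neur.Vol", "Haem.Vol", "Cent.Le", "Neur.Le"):
            assert np.allclose(table[col], tr[col], rtol=0.05), col
        for col in ("Cent.TMD", "Neur.TMD", "Haem.TMD"):
            assert np.allclose(table[col], tr[col]), col
        assert np.allclose(table["Neur.Angle"], tr["Neur.Angle"], atol=2.0)

    def test_too_few_vertebrae_raises(self, clean_labeling, clean_phantom):
        volume, _, _ = clean_phantom
        with pytest.raises(FishCTError):
            assemble_phenome(clean_labeling, volume.data, n_vertebrae=30)

    def test_pipeline_deterministic_and_translation_invariant(self):
        """Same spec, same seed: identical phenome; shifting the fish within
        the field of view (more padding) changes nothing."""
        tables = []
        for pad in (3, 3, 7):
            spec = scaled_spec(0.7, noise_sd=0).replace(pad_voxels=pad)
            volume, _, _ = generate_phantom(spec)
            lab = partition_elements(label_vertebrae(segment_tissues(volume)))
            tables.append(assemble_phenome(lab, volume.data, n_vertebrae=12))
        pd.testing.assert_frame_equal(tables[0], tables[1])  # determinism
        pd.testing.assert_frame_equal(tables[0], tables[2])  # translation

    def test_centrum_length_monotone_under_cohort_effect(self):
        """A cohort built with shorter centra measures shorter centra."""
        base = scaled_spec(0.7, noise_sd=8.0, seed=21)
        short = base.replace(centrum_length=0.85 * base.centrum_length, seed=22)
        lengths = []
        for spec in (base, short):
            volume, _, _ = generate_phantom(spec)
            lab = partition_elements(label_vertebrae(segment_tissues(volume)))
            table = assemble_phenome(lab, volume.data, n_vertebrae=12)
            lengths.append(table["Cent.Le"].mean())
        assert lengths[1] < lengths[0]
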