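import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tubesta import (
    DensityVolume,
    NoiseModel,
    VolumeSource,
    average_particles,
    binary_wedge,
    build_wmd_stack,
    class_purity,
    matrix_to_euler,
    pca_classify,
    render_motif,
    scree_is_flat,
    simulate_subtomogram,
    soft_sphere_mask,
    wedge_masked_difference,
)
from tubesta.classification import WMDStack, total_masked_variance
from tubesta.errors import ValidationError
from tubesta.io_formats import new_particle_table
from tubesta.simulator import _splat

BOX, VOXEL = 32, 8.0


def motif_box(variant="default", rotation=None):
    m = render_motif(VOXEL, variant)
    vol = np.zeros((BOX,) * 3)
    _splat(vol, m.data.astype(float), np.eye(3) if rotation is None else rotation,
           (BOX / 2.0,) * 3)
    return DensityVolume(vol.astype(np.float32), VOXEL)


def two_class_stack(n_per_class=40, snr=0.5, seed=17):
    """Wedge-affected noisy copies of two motif variants at random poses."""
    wedge = binary_wedge((BOX,) * 3, -60, 60)
    center = {"pos_x": BOX // 2, "pos_y": BOX // 2, "pos_z": BOX // 2}
    table = new_particle_table(2 * n_per_class)
    vols = {}
    truth = {}
    for i in range(2 * n_per_class):
        variant = "default" if i < n_per_class else "short_leg"
        truth[i] = 0 if i < n_per_class else 1
        r = Rotation.random(random_state=seed * 1000 + i).as_matrix()
        clean = motif_box(variant, rotation=r)
        vols[i] = simulate_subtomogram(
            clean, {**center, "particle_id": i}, BOX, wedge, NoiseModel(snr, seed=seed)
        )
        table.loc[i, ["phi", "theta", "psi"]] = matrix_to_euler(r).as_tuple()
        table.loc[i, "cc_score"] = 0.5
    return table, VolumeSource(vols, wedge), truth


class TestWMD:
    def test_self_difference_is_negligible(self):
        """A particle generated from the reference itself (no noise) leaves
        essentially zero difference."""
        wedge = binary_wedge((BOX,) * 3, -60, 60)
        ref = motif_box()
        center = {"pos_x": 16, "pos_y": 16, "pos_z": 16, "particle_id": 0}
        particle = simulate_subtomogram(ref, center, BOX, wedge, NoiseModel(np.inf))
        rec = new_particle_table(1).iloc[0].copy()
        rec["cc_score"] = 0.9
        mask = soft_sphere_mask(BOX, radius_vox=11, edge_vox=2)
        d = wedge_masked_difference(particle, ref, rec, wedge, mask)
        assert np.linalg.norm(d) < 0.05 * np.linalg.norm(particle.data)

    def test_variant_difference_concentrates_in_altered_region(self):
        """Particle from the short-leg variant: over half the difference
        power falls inside the known altered-leg region."""
        wedge = binary_wedge((BOX,) * 3, -60, 60)
        ref = motif_box("default")
        variant = motif_box("short_leg")
        center = {"pos_x": 16, "pos_y": 16, "pos_z": 16, "particle_id": 0}
        particle = simulate_subtomogram(variant, center, BOX, wedge, NoiseModel(np.inf))
        rec = new_particle_table(1).iloc[0].copy()
        rec["cc_score"] = 0.9
        mask = soft_sphere_mask(BOX, radius_vox=12, edge_vox=2)
        d = wedge_masked_difference(particle, ref, rec, wedge, mask)
        region = np.abs(ref.data - variant.data) > 0.1 * float(
            np.abs(ref.data - variant.data).max()
        )
        power_in = float((d[region] ** 2).sum())
        assert power_in > 0.5 * float((d**2).sum())

    def test_wedge_masking_shrinks_the_difference(self):
        """For wedge-affected noise-free particles the difference against the
        wedge-filtered reference is strictly smaller than against the raw
        reference — the motivation for WMDs."""
        from tubesta.fourier_filters import allpass

        wedge = binary_wedge((BOX,) * 3, -60, 60)
        ref = motif_box()
        center = {"pos_x": 16, "pos_y": 16, "pos_z": 16, "particle_id": 0}
        particle = simulate_subtomogram(ref, center, BOX, wedge, NoiseModel(np.inf))
        rec = new_particle_table(1).iloc[0].copy()
        rec["cc_score"] = 0.9
        mask = soft_sphere_mask(BOX, radius_vox=11, edge_vox=2)
        with_mask = wedge_masked_difference(particle, ref, rec, wedge, mask)
        without = wedge_masked_difference(particle, ref, rec, allpass((BOX,) * 3), mask)
        assert np.linalg.norm(with_mask) < np.linalg.norm(without)

    def test_unaligned_particle_rejected(self):
        ref = motif_box()
        rec = new_particle_table(1).iloc[0].copy()  # cc_score NaN
        with pytest.raises(ValidationError):
            wedge_masked_difference(ref, ref, rec, binary_wedge((BOX,) * 3, -60, 60),
                                    soft_sphere_mask(BOX))


class TestPCAClassify:
    def test_two_class_recovery(self):
        """Mixed-variant particles at SNR 0.5 separate by WMD-PCA + k-means
        (the full-size two-class recovery runs in the acceptance suite)."""
        table, source, truth = two_class_stack(n_per_class=40, snr=0.5)
        ref = average_particles(table, source).mean_map
        mask = soft_sphere_mask(BOX, radius_vox=12, edge_vox=2)
        stack = build_wmd_stack(table, source, ref, mask)
        result = pca_classify(stack, n_components=5, k_classes=2, seed=0)
        import pandas as pd

        purity = class_purity(result.labels, pd.Series(truth))
        assert purity >= 0.9

    def test_single_class_scree_is_flat(self):
        """With one underlying structure no component dominates: the 'no
        classes' diagnostic."""
        table, source, truth = two_class_stack(n_per_class=40, snr=0.5)
        single = table.iloc[:40]
        ref = average_particles(single, source).mean_map
        mask = soft_sphere_mask(BOX, radius_vox=12, edge_vox=2)
        stack = build_wmd_stack(single, source, ref, mask)
        result = pca_classify(stack, n_components=6, k_classes=2, seed=0)
        assert scree_is_flat(result.explained_variance, ratio=3.0)

    def test_deterministic_for_fixed_seed(self):
        table, source, _ = two_class_stack(n_per_class=15, snr=1.0)
        ref = average_particles(table, source).mean_map
        mask = soft_sphere_mask(BOX, radius_vox=12, edge_vox=2)
        stack = build_wmd_stack(table, source, ref, mask)
        a = pca_classify(stack, 4, 2, seed=3)
        b = pca_classify(stack, 4, 2, seed=3)
        assert np.array_equal(a.labels.to_numpy(), b.labels.to_numpy())
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_variance_accounting_and_monotonicity(self, rng):
        diffs = rng.standard_normal((30, 12, 12, 12)).astype(np.float32)
        mask = np.ones((12, 12, 12), dtype=np.float32)
        stack = WMDStack(diffs, np.arange(30), mask)
        result = pca_classify(stack, n_components=29, k_classes=2, seed=0)
        ev = result.explained_variance
        assert np.all(np.diff(ev) <= 1e-9)
        assert ev.sum() == pytest.approx(total_masked_variance(stack), rel=1e-6)

    def test_invariant_to_global_intensity_scale(self):
        table, source, truth = two_class_stack(n_per_class=20, snr=1.0)
        ref = average_particles(table, source).mean_map
        mask = soft_sphere_mask(BOX, radius_vox=12, edge_vox=2)
        stack = build_wmd_stack(table, source, ref, mask)
        scaled = WMDStack(5.0 * stack.diffs, stack.particle_ids, stack.real_mask)
        a = pca_classify(stack, 4, 2, seed=1)
        b = pca_classify(scaled, 4, 2, seed=1)
        same = (a.labels.to_numpy() == b.labels.to_numpy()).mean()
        assert same in (0.0, 1.0) or same > 0.95  # up to label swap

    def test_opposite_handedness_motifs_separate(self):
        """Left- vs right-handed arch variants are distinguished — the
        desk-scale analogue of classification revealing arch asymmetry."""
        import pandas as pd

        wedge = binary_wedge((BOX,) * 3, -60, 60)
        center = {"pos_x": 16, "pos_y": 16, "pos_z": 16}
        table = new_particle_table(80)
        vols, truth = {}, {}
        for i in range(80):
            variant = "short_leg" if i < 40 else "short_leg_mirror"
            truth[i] = int(i >= 40)
            r = Rotation.random(random_state=900 + i).as_matrix()
            clean = motif_box(variant, rotation=r)
            vols[i] = simulate_subtomogram(
                clean, {**center, "particle_id": i}, BOX, wedge, NoiseModel(0.5, seed=2)
            )
            table.loc[i, ["phi", "theta", "psi"]] = matrix_to_euler(r).as_tuple()
            table.loc[i, "cc_score"] = 0.5
        source = VolumeSource(vols, wedge)
        ref = average_particles(table, source).mean_map
        mask = soft_sphere_mask(BOX, radius_vox=12, edge_vox=2)
        stack = build_wmd_stack(table, source, ref, mask)
        result = pca_classify(stack, 5, 2, seed=0)
        assert class_purity(result.labels, pd.Series(truth)) >= 0.85

    def test_validation_errors(self, rng):
        diffs = rng.standard_normal((5, 8, 8, 8)).astype(np.float32)
        stack = WMDStack(diffs, np.arange(5), np.ones((8, 8, 8), dtype=np.float32))
        with pytest.raises(ValidationError):
            pca_classify(stack, 2, 1, seed=0)
        with pytest.raises(ValidationError):
            pca_classify(stack, 10, 2, seed=0)
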