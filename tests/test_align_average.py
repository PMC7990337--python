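import numpy as np
import pandas as pd
import pytest

from tubesta import (
    AngularGrid,
    DensityVolume,
    EulerTriplet,
    IterationSpec,
    NoiseModel,
    RefinementSchedule,
    VolumeSource,
    align_particle,
    average_particles,
    binary_wedge,
    composite_particle_mask,
    constrained_cc,
    ctf_amplitude_profile,
    dose_symmetric_scheme,
    euler_to_matrix,
    matrix_to_euler,
    render_motif,
    rotation_geodesic_deg,
    simulate_subtomogram,
    soft_sphere_mask,
)
from tubesta.errors import DegenerateInputError, ValidationError
from tubesta.fourier_filters import allpass
from tubesta.io_formats import new_particle_table
from tubesta.simulator import _splat


def motif_in_box(box=32, voxel=8.0, rotation=None, pos=None):
    motif = render_motif(voxel)
    vol = np.zeros((box,) * 3)
    r = np.eye(3) if rotation is None else rotation
    p = (box / 2.0,) * 3 if pos is None else pos
    _splat(vol, motif.data.astype(float), r, p)
    return DensityVolume(vol.astype(np.float32), voxel)


def brute_force_cc_map(a, b, max_shift):
    """O(n^3 * shifts) normalized circular correlation oracle."""
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    n = a.size
    out = {}
    for dx in range(-max_shift, max_shift + 1):
        for dy in range(-max_shift, max_shift + 1):
            for dz in range(-max_shift, max_shift + 1):
                rolled = np.roll(b, (dz, dy, dx), axis=(0, 1, 2))
                out[(dx, dy, dz)] = float((a * rolled).sum() / n)
    return out


class TestConstrainedCC:
    def test_self_correlation_is_one(self):
        v = motif_in_box()
        cc, shift = constrained_cc(v, v, None, subvoxel=False)
        assert cc == pytest.approx(1.0, abs=1e-6)
        assert shift == pytest.approx([0, 0, 0], abs=1e-9)

    def test_recovers_constructed_translation(self):
        ref = motif_in_box(box=32)
        sub = motif_in_box(box=32, pos=(19.0, 14.0, 17.0))  # shift (3,-2,1)
        cc, shift = constrained_cc(sub, ref, None, max_shift_vox=6)
        assert shift == pytest.approx([3.0, -2.0, 1.0], abs=0.25)
        assert cc > 0.9

    def test_matches_brute_force_oracle(self, rng):
        """All-pass mask on box 16: FFT correlation equals the direct
        real-space normalized correlation at every integer shift."""
        from scipy import fft as sfft

        a = rng.standard_normal((16,) * 3)
        b = rng.standard_normal((16,) * 3)
        oracle = brute_force_cc_map(a, b, 2)
        an = (a - a.mean()) / a.std()
        bn = (b - b.mean()) / b.std()
        cc = sfft.fftshift(
            sfft.irfftn(sfft.rfftn(an) * np.conj(sfft.rfftn(bn)), s=a.shape)
        ) / a.size
        c = 8
        for (dx, dy, dz), val in oracle.items():
            assert cc[c + dz, c + dy, c + dx] == pytest.approx(val, abs=1e-6)
        # and the public op returns the oracle's maximum value over the same
        # (Euclidean) shift ball; ties between nearly-equal noise correlations
        # may break to different shifts
        in_ball = {k: v for k, v in oracle.items() if sum(s * s for s in k) <= 4}
        best = max(in_ball, key=in_ball.get)
        peak, shift = constrained_cc(
            DensityVolume(a.astype(np.float32), 4.0),
            DensityVolume(b.astype(np.float32), 4.0),
            None, max_shift_vox=2, subvoxel=False,
        )
        assert peak == pytest.approx(oracle[best], abs=1e-6)
        assert oracle[tuple(int(s) for s in shift)] == pytest.approx(peak, abs=1e-6)

    def test_wedge_compensation_raises_cc(self):
        """Masking the reference with the particle's wedge must on average beat
        correlating against the unmasked reference — the point of the method."""
        ref = motif_in_box(box=32)
        wedge = binary_wedge((32,) * 3, -60, 60)
        rec = {"pos_x": 16, "pos_y": 16, "pos_z": 16}
        gains = []
        for pid in range(20):
            noisy = simulate_subtomogram(
                ref, {**rec, "particle_id": pid}, 32, wedge, NoiseModel(0.7, seed=5)
            )
            with_mask, _ = constrained_cc(noisy, ref, wedge, max_shift_vox=2)
            without, _ = constrained_cc(noisy, ref, None, max_shift_vox=2)
            gains.append(with_mask - without)
        assert np.mean(gains) > 0

    def test_zero_variance_rejected(self):
        flat = DensityVolume(np.zeros((16,) * 3, dtype=np.float32), 4.0)
        v = motif_in_box(16)
        with pytest.raises(DegenerateInputError):
            constrained_cc(flat, v, None)


class TestAngularGrid:
    def test_identity_first_and_always_included(self):
        for grid in (AngularGrid(0, 0, 0, 0), AngularGrid(8, 4, 8, 4)):
            offs = grid.offsets()
            assert np.allclose(offs[0], np.eye(3))

    def test_neighbor_spacing_bounded(self):
        grid = AngularGrid(12, 4, 0, 0)
        offs = grid.offsets()
        zaxes = np.array([o @ [0, 0, 1.0] for o in offs])
        # every grid point has a neighbor within 1.5 x step
        for i, z in enumerate(zaxes):
            angles = np.degrees(
                np.arccos(np.clip(zaxes @ z, -1, 1))
            )
            angles[i] = np.inf
            assert angles.min() <= 1.5 * 4 + 1e-9

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValidationError):
            AngularGrid(-1, 4, 0, 0)
        with pytest.raises(ValidationError):
            AngularGrid(8, 0, 0, 0)


@pytest.fixture(scope="module")
def reference():
    return motif_in_box(box=32)


class TestAlignParticle:

    def _record(self, e: EulerTriplet):
        rec = new_particle_table(1).iloc[0].copy()
        rec["phi"], rec["theta"], rec["psi"] = e.as_tuple()
        return rec

    def test_identity_grid_refines_only_shift(self, reference):
        sub = motif_in_box(box=32, pos=(18.0, 16.0, 16.0))
        rec = self._record(EulerTriplet(0, 0, 0))
        out = align_particle(rec, sub, reference, AngularGrid(0, 0, 0, 0),
                             None, max_shift_vox=4)
        assert (out["phi"], out["theta"], out["psi"]) == (0, 0, 0)
        assert out["shift_x"] == pytest.approx(2.0, abs=0.25)

    def test_parameter_recovery_under_wedge_and_noise(self, rng):
        """Known pose perturbed by ~10°, cone 12°/step 4°: ≥90% of 20 noisy
        particles recover within 4° and 0.5 voxel at SNR 0.5."""
        from scipy.spatial.transform import Rotation

        box = 48
        scheme = dose_symmetric_scheme()
        wedge = binary_wedge((box,) * 3, -60, 60)
        mask = composite_particle_mask(wedge, ctf_amplitude_profile(4.0), scheme, 8.0)
        real_mask = soft_sphere_mask(box, radius_vox=10.0, edge_vox=2.0)
        ref = motif_in_box(box=box)
        ok = 0
        for pid in range(20):
            r_true = Rotation.random(random_state=100 + pid).as_matrix()
            particle = motif_in_box(box=box, rotation=r_true)
            noisy = simulate_subtomogram(
                particle, {"pos_x": 24, "pos_y": 24, "pos_z": 24, "particle_id": pid},
                box, mask, NoiseModel(0.5, seed=6),
            )
            pert = Rotation.from_rotvec(
                np.deg2rad(np.random.default_rng(pid).normal(0, 5.5, 3))
            ).as_matrix()
            rec = self._record(matrix_to_euler(r_true @ pert))
            out = align_particle(rec, noisy, ref, AngularGrid(12, 4, 12, 4),
                                 mask, real_mask, max_shift_vox=3)
            r_got = euler_to_matrix(EulerTriplet(out["phi"], out["theta"], out["psi"]))
            ang = rotation_geodesic_deg(r_got, r_true)
            shift = np.array([out["shift_x"], out["shift_y"], out["shift_z"]])
            if ang <= 4.0 and np.linalg.norm(shift) <= 0.5:
                ok += 1
        assert ok >= 18

    def test_tie_break_is_first_in_grid_order(self, reference):
        """A featureless-in-angle particle (sphere) gives numerically equal CC
        at many grid points; the identity offset (first in order) must win."""
        n = 32
        zz, yy, xx = np.meshgrid(*[np.arange(n) - 16] * 3, indexing="ij")
        sphere = DensityVolume(
            np.exp(-(xx**2 + yy**2 + zz**2) / 32.0).astype(np.float32), 8.0
        )
        rec = self._record(EulerTriplet(0, 0, 0))
        out = align_particle(rec, sphere, sphere, AngularGrid(8, 8, 8, 8),
                             None, max_shift_vox=1)
        r_got = euler_to_matrix(EulerTriplet(out["phi"], out["theta"], out["psi"]))
        assert rotation_geodesic_deg(r_got, np.eye(3)) < 1.0


class TestAveraging:
    def test_single_identity_particle_returns_itself(self):
        v = motif_in_box(box=32)
        table = new_particle_table(1)
        src = VolumeSource({0: v}, None)
        avg = average_particles(table, src, normalize_output=False)
        assert avg.n_particles == 1
        assert np.allclose(avg.mean_map.data, v.data, atol=1e-4)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            average_particles(new_particle_table(0), VolumeSource({}, None))

    def test_wedge_sum_is_linear_in_particles(self):
        v = motif_in_box(box=16, voxel=8.0)
        wedge = binary_wedge((16,) * 3, -60, 60)
        table = new_particle_table(4)
        src = VolumeSource({i: v for i in range(4)}, wedge)
        avg = average_particles(table, src, normalize_output=False)
        assert np.allclose(avg.wedge_sum, 4.0 * wedge.weights, atol=1e-6)

    def test_order_invariance(self):
        """Summation runs in particle_id order, so table row order is moot."""
        rng = np.random.default_rng(3)
        vols = {i: DensityVolume(
            rng.standard_normal((16,) * 3).astype(np.float32), 8.0) for i in range(5)}
        table = new_particle_table(5)
        table.loc[:, ["phi", "theta", "psi"]] = rng.uniform(-90, 90, (5, 3))
        src = VolumeSource(vols, None)
        a = average_particles(table, src, normalize_output=False)
        b = average_particles(table.iloc[::-1], src, normalize_output=False)
        assert np.array_equal(a.mean_map.data, b.mean_map.data)

    def test_inplane_diversity_fills_the_wedge(self):
        """Wedge-affected copies at many in-plane angles about an axis
        orthogonal to the wedge axis average back to the phantom."""
        box = 32
        phantom = motif_in_box(box=box)
        wedge = binary_wedge((box,) * 3, -60, 60)
        n_copies = 100
        table = new_particle_table(n_copies)
        vols = {}
        rng = np.random.default_rng(11)
        for i in range(n_copies):
            # particle orientation: rotation about the x (tube circumference)
            # axis, i.e. the missing wedge sweeps around as on a tube surface
            ang = np.deg2rad(rng.uniform(0, 360))
            r = np.array([
                [1, 0, 0],
                [0, np.cos(ang), -np.sin(ang)],
                [0, np.sin(ang), np.cos(ang)],
            ])
            rotated = motif_in_box(box=box, rotation=r)
            masked = simulate_subtomogram(
                rotated, {"pos_x": 16, "pos_y": 16, "pos_z": 16, "particle_id": i},
                box, wedge, NoiseModel(np.inf),
            )
            vols[i] = masked
            table.loc[i, ["phi", "theta", "psi"]] = matrix_to_euler(r).as_tuple()
        src = VolumeSource(vols, wedge)
        avg = average_particles(table, src, normalize_output=False)
        # correlate inside the inscribed sphere (corners carry boundary fill)
        zz2, yy2, xx2 = np.meshgrid(*[np.arange(box) - box // 2] * 3, indexing="ij")
        core = xx2**2 + yy2**2 + zz2**2 <= (box // 2 - 1) ** 2
        a = avg.mean_map.data[core] - avg.mean_map.data[core].mean()
        b = phantom.data[core] - phantom.data[core].mean()
        cc = float(a @ b / np.sqrt((a @ a) * (b @ b)))
        assert cc > 0.95


class TestSchedule:
    def test_monotonic_constraints_enforced(self):
        mk = lambda step, lp: IterationSpec(AngularGrid(8, step, 4, 4), 4.0, lp)
        RefinementSchedule([mk(8, 40), mk(4, 40), mk(4, 32)])
        with pytest.raises(ValidationError):
            RefinementSchedule([mk(4, 40), mk(8, 40)])
        with pytest.raises(ValidationError):
            RefinementSchedule([mk(8, 32), mk(4, 40)])
        with pytest.raises(ValidationError):
            RefinementSchedule([])
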