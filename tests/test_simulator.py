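import numpy as np
import pytest

from tubesta import (
    DensityVolume,
    NoiseModel,
    binary_wedge,
    dose_symmetric_scheme,
    load_fixture,
    make_fixture,
    render_motif,
    simulate_subtomogram,
    simulate_tilt_series_tomogram,
)
from tubesta.errors import ExtractionError, ValidationError
from tubesta.fourier_filters import allpass
from tubesta.simulator import _splat, extract_crop, realized_snr

from conftest import make_lattice


class TestGroundTruth:
    def test_unit_count_follows_ring_arithmetic(self):
        """axial rise 80 Å, 800 Å tube, 12 per turn -> 120 units."""
        spec, (table, vol) = make_lattice(
            length_vox=100.0, shape=(116, 128, 116), units_per_turn=12
        )
        assert len(table) == 10 * 12

    def test_zero_tilt_units_point_along_the_normal(self):
        from tubesta.lattice import arch_tilt_stats

        spec, (table, vol) = make_lattice(tilt_deg=0.0)
        stats = arch_tilt_stats(table, [spec.tube], spec.voxel_size_A)
        assert stats.tilt_mean_deg == pytest.approx(0.0, abs=1e-6)

    def test_reproducible_from_seed(self):
        _, (t1, v1) = make_lattice(jitter_A=5.0, jitter_deg=3.0, seed=11)
        _, (t2, v2) = make_lattice(jitter_A=5.0, jitter_deg=3.0, seed=11)
        assert t1.equals(t2)
        assert np.array_equal(v1.data, v2.data)
        _, (t3, _) = make_lattice(jitter_A=5.0, jitter_deg=3.0, seed=12)
        assert not t1[["pos_x", "pos_y", "pos_z"]].equals(t3[["pos_x", "pos_y", "pos_z"]])

    def test_motif_variants_differ_where_stated(self):
        full = render_motif(8.0, "default")
        short = render_motif(8.0, "short_leg")
        mirror = render_motif(8.0, "short_leg_mirror")
        assert full.data.shape == short.data.shape
        assert not np.allclose(full.data, short.data)
        assert not np.allclose(short.data, mirror.data)
        # the mirrored variant's lobes are the x-negated short-leg lobes
        from tubesta.simulator import arch_motif_lobes

        for (c_m, s_m, a_m), (c_d, s_d, a_d) in zip(
            arch_motif_lobes("short_leg_mirror"), arch_motif_lobes("short_leg")
        ):
            assert c_m[0] == pytest.approx(-c_d[0], abs=1e-9)
            assert c_m[1:] == pytest.approx(c_d[1:], abs=1e-9)
            assert s_m == pytest.approx(s_d) and a_m == a_d


class TestSubtomogramSurrogate:
    @pytest.fixture(scope="class")
    def truth(self):
        spec, (table, vol) = make_lattice()
        return spec, table, vol

    def test_allpass_no_noise_equals_crop(self, truth):
        spec, table, vol = truth
        rec = table.iloc[5]
        out = simulate_subtomogram(vol, rec, 32, allpass((32,) * 3), NoiseModel(np.inf))
        crop = extract_crop(vol, rec[["pos_x", "pos_y", "pos_z"]].to_numpy(float), 32)
        assert np.allclose(out.data, crop.data, atol=1e-4)

    def test_wedge_zeroes_unsampled_frequencies(self, truth):
        spec, table, vol = truth
        rec = table.iloc[5]
        wedge = binary_wedge((32,) * 3, -60, 60)
        out = simulate_subtomogram(vol, rec, 32, wedge, NoiseModel(np.inf))
        f = np.abs(np.fft.fftshift(np.fft.fftn(out.data)))
        assert f[wedge.weights == 0].max() < 1e-6 * f.max()

    def test_realized_snr_matches_request(self, truth):
        """Over 50 particles the realized SNR must sit within 10%."""
        spec, table, vol = truth
        wedge = binary_wedge((32,) * 3, -60, 60)
        snrs = []
        for _, rec in table.head(50).iterrows():
            clean = simulate_subtomogram(vol, rec, 32, wedge, NoiseModel(np.inf))
            noisy = simulate_subtomogram(vol, rec, 32, wedge, NoiseModel(1.0, seed=4))
            snrs.append(realized_snr(noisy.data, clean.data))
        assert np.mean(snrs) == pytest.approx(1.0, abs=0.1)

    def test_noise_reproducible_and_independent(self, truth):
        spec, table, vol = truth
        wedge = binary_wedge((32,) * 3, -60, 60)
        a = simulate_subtomogram(vol, table.iloc[3], 32, wedge, NoiseModel(0.5, seed=9))
        b = simulate_subtomogram(vol, table.iloc[3], 32, wedge, NoiseModel(0.5, seed=9))
        c = simulate_subtomogram(vol, table.iloc[4], 32, wedge, NoiseModel(0.5, seed=9))
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_out_of_bounds_crop_rejected(self, truth):
        spec, table, vol = truth
        rec = table.iloc[0].copy()
        rec["pos_x"] = 2.0
        with pytest.raises(ExtractionError):
            simulate_subtomogram(vol, rec, 32, allpass((32,) * 3), NoiseModel(np.inf))


def blob_phantom(n=48, voxel=8.0):
    zz, yy, xx = np.meshgrid(*[np.arange(n) - n // 2] * 3, indexing="ij")
    data = np.exp(-((xx - 3) ** 2 + (yy + 2) ** 2 + (zz - 1) ** 2) / 18.0)
    data += 0.7 * np.exp(-((xx + 6) ** 2 + (yy - 5) ** 2 + (zz + 4) ** 2) / 8.0)
    return DensityVolume(data.astype(np.float32), voxel)


class TestTiltSeries:
    def test_single_view_matches_direct_backprojection(self):
        """One 0° tilt: reconstruction equals the ramp-filtered z-sum smeared
        back along z, computed here independently with plain FFTs."""
        from tubesta.io_formats import TiltScheme

        vol = blob_phantom(32)
        scheme = TiltScheme([0.0], [0], [0.0])
        rec = simulate_tilt_series_tomogram(vol, scheme, NoiseModel(np.inf),
                                            apply_exposure=False)
        proj = vol.data.sum(axis=0)
        ramp = np.abs(np.fft.fftfreq(32))
        filtered = np.fft.ifft(np.fft.fft(proj, axis=1) * ramp[None, :], axis=1).real
        oracle = np.broadcast_to(filtered[None], vol.data.shape) * (np.pi / 2.0)
        assert np.allclose(rec.data, oracle, atol=1e-4 * np.abs(oracle).max() + 1e-6)

    def test_ideal_coverage_recovers_phantom(self):
        """±90° fine sampling: weighted backprojection correlates > 0.95."""
        vol = blob_phantom(48)
        scheme = dose_symmetric_scheme(tilt_max_deg=90.0, n_tilts=61,
                                       total_dose_eA2=0.0)
        rec = simulate_tilt_series_tomogram(vol, scheme, NoiseModel(np.inf),
                                            apply_exposure=False)
        core = (slice(8, 40),) * 3  # ignore corner artefacts
        a, b = rec.data[core].ravel(), vol.data[core].ravel()
        cc = np.corrcoef(a, b)[0, 1]
        assert cc > 0.95

    def test_wedge_surrogate_agrees_with_tilt_series(self):
        """A crop from the projected/backprojected tomogram correlates > 0.8
        with the Fourier-mask surrogate of the same particle (no noise)."""
        from tubesta.fourier_filters import composite_particle_mask

        n = 64
        zz, yy, xx = np.meshgrid(*[np.arange(n) - n // 2] * 3, indexing="ij")
        data = np.exp(-((xx - 2) ** 2 + (yy + 3) ** 2 + zz**2) / 24.0)
        data += 0.6 * np.exp(-((xx + 7) ** 2 + (yy - 4) ** 2 + (zz - 6) ** 2) / 10.0)
        vol = DensityVolume(data.astype(np.float32), 8.0)
        scheme = dose_symmetric_scheme(total_dose_eA2=0.0)
        rec = simulate_tilt_series_tomogram(vol, scheme, NoiseModel(np.inf),
                                            apply_exposure=False)
        box = 48
        center = {"pos_x": 32.0, "pos_y": 32.0, "pos_z": 32.0, "particle_id": 0}
        wedge = binary_wedge((box,) * 3, -60, 60)
        surrogate = simulate_subtomogram(vol, center, box, wedge, NoiseModel(np.inf))
        crop = extract_crop(rec, (32.0, 32.0, 32.0), box)
        a = (crop.data - crop.data.mean()).ravel()
        b = (surrogate.data - surrogate.data.mean()).ravel()
        cc = float(a @ b / np.sqrt((a @ a) * (b @ b)))
        assert cc > 0.8

    def test_out_of_range_angles_rejected(self):
        from tubesta.io_formats import TiltScheme

        vol = blob_phantom(16)
        with pytest.raises(ValidationError):
            simulate_tilt_series_tomogram(
                vol, TiltScheme([120.0], [0], [1.0]), NoiseModel(np.inf)
            )


class TestFixtures:
    def test_tiny_bundle_contents(self, tmp_path):
        manifest = make_fixture("tiny", 3, tmp_path / "fx")
        assert len(manifest["tomograms"]) == 1
        bundle = load_fixture(tmp_path / "fx")
        assert len(bundle.tubes) == 1
        assert len(bundle.truth) > 0
        assert bundle.tomograms[0].data.shape == (64, 64, 64)

    def test_refuses_to_overwrite(self, tmp_path):
        make_fixture("tiny", 3, tmp_path / "fx")
        with pytest.raises(ValidationError):
            make_fixture("tiny", 3, tmp_path / "fx")
        make_fixture("tiny", 4, tmp_path / "fx", overwrite=True)

    def test_same_seed_gives_identical_truth(self, tmp_path):
        make_fixture("tiny", 5, tmp_path / "a")
        make_fixture("tiny", 5, tmp_path / "b")
        assert (tmp_path / "a" / "truth_particles.tsv").read_bytes() == (
            tmp_path / "b" / "truth_particles.tsv"
        ).read_bytes()

    def test_classes_preset_has_two_motifs(self, tmp_path):
        manifest = make_fixture("classes", 2, tmp_path / "fx")
        assert manifest["lattice"]["variants"] == ["default", "short_leg"]
        bundle = load_fixture(tmp_path / "fx")
        assert set(bundle.truth["class_id"].dropna().unique()) == {0, 1}


class TestSplat:
    def test_splat_places_motif_at_position(self):
        motif = render_motif(8.0)
        vol = np.zeros((64, 64, 64))
        _splat(vol, motif.data.astype(float), np.eye(3), (20.0, 30.0, 40.0))
        zz, yy, xx = np.meshgrid(*[np.arange(64)] * 3, indexing="ij")
        m = vol.sum()
        com = ((vol * xx).sum() / m, (vol * yy).sum() / m, (vol * zz).sum() / m)
        assert com == pytest.approx((20.0, 30.0, 40.0), abs=0.3)
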