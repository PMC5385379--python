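"""Phantom generator: rasterisation, forward signal model, noise, seeds."""

import numpy as np
import pytest
from scipy import stats

from endoprofile import phantom
from endoprofile.protocol import ImagingProtocol, functional_cine_protocol
from endoprofile.t1map import spgr_signal

from conftest import straight_tube_geometry


class TestProtocolValidation:
    def test_voxel_size(self):
        p = functional_cine_protocol()
        assert p.voxel_mm == pytest.approx((30 / 256, 30 / 256, 5 / 30))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(tr_ms=-1),
            dict(fov_mm=(30, 30, 0)),
            dict(matrix=(256, 256, 0)),
            dict(flip_angles_deg=(0.0,)),
            dict(flip_angles_deg=(95.0,)),
            dict(flip_angles_deg=(30.0, 20.0)),
            dict(n_frames=0),
        ],
    )
    def test_invalid_protocols_rejected(self, kwargs):
        base = dict(
            tr_ms=10.0,
            te_ms=1.1,
            fov_mm=(30.0, 30.0, 4.0),
            matrix=(64, 64, 4),
            flip_angles_deg=(2.0, 30.0),
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            ImagingProtocol(**base)


class TestRasterize:
    def test_cylinder_volume_matches_analytic(self):
        # straight cylinder, voxel ~0.117 mm: count vs pi r^2 L / voxel volume
        p = functional_cine_protocol().with_matrix((256, 256, 10))
        g = straight_tube_geometry(p, radius_mm=1.0)
        labels = phantom.rasterize_phantom(g, p)
        count = int((labels == phantom.BLOOD).sum())
        vr, vc, dz = p.voxel_mm
        expected = np.pi * 1.0**2 * p.fov_mm[2] / (vr * vc * dz)
        assert count == pytest.approx(expected, rel=0.02)

    def test_identity_dilation_gives_identical_labels(self, cine_protocol_small):
        g = phantom.bifurcating_geometry(cine_protocol_small, dilation_factor=1.0)
        pre = phantom.rasterize_phantom(g, cine_protocol_small, frame=0, state="pre")
        post = phantom.rasterize_phantom(g, cine_protocol_small, frame=0, state="post")
        assert np.array_equal(pre, post)

    def test_dilation_scales_lumen_count(self):
        p = functional_cine_protocol().with_matrix((256, 256, 10))
        g = straight_tube_geometry(p, radius_mm=1.0, dilation_factor=0.8)
        pre = phantom.rasterize_phantom(g, p, state="pre")
        post = phantom.rasterize_phantom(g, p, state="post")
        ratio = (post == phantom.BLOOD).sum() / (pre == phantom.BLOOD).sum()
        assert ratio == pytest.approx(0.80, rel=0.02)

    def test_compartment_counts_conserve_voxels(self, cine_protocol_small):
        g = phantom.bifurcating_geometry(cine_protocol_small)
        for frame, state in [(0, "pre"), (3, "post")]:
            labels = phantom.rasterize_phantom(g, cine_protocol_small, frame, state)
            counts = np.bincount(labels.ravel(), minlength=4)
            assert counts.sum() == labels.size
            assert (counts[1:] > 0).all()

    def test_dilation_monotonically_increases_lumen(self, cine_protocol_small):
        counts = []
        for d in (0.8, 1.0, 1.2):
            g = phantom.bifurcating_geometry(cine_protocol_small, dilation_factor=d)
            labels = phantom.rasterize_phantom(g, cine_protocol_small, state="post")
            counts.append((labels == phantom.BLOOD).sum())
        assert counts[0] < counts[1] < counts[2]

    def test_geometry_leaving_fov_raises(self, cine_protocol_small):
        g = phantom.bifurcating_geometry(cine_protocol_small, radius_mm=14.0)
        with pytest.raises(ValueError, match="FOV"):
            phantom.rasterize_phantom(g, cine_protocol_small)

    def test_bad_frame_rejected(self, cine_protocol_small, geometry_small):
        with pytest.raises(ValueError, match="frame"):
            phantom.rasterize_phantom(
                geometry_small, cine_protocol_small, frame=99, state="pre"
            )


class TestVfaSimulation:
    def test_noiseless_signal_matches_forward_model(self, vfa_protocol_small, tissue):
        labels = np.full((2, 8, 8), phantom.BLOOD, dtype=np.uint8)
        series = phantom.simulate_vfa_series(
            labels, tissue, vfa_protocol_small, "pre", seed=0
        )
        for vol, alpha in zip(series.volumes, series.flip_angles_deg):
            expected = spgr_signal(
                tissue.blood.m0,
                tissue.blood.t1_pre_ms,
                vfa_protocol_small.tr_ms,
                alpha,
            )
            assert np.allclose(vol, expected)

    def test_zero_leak_keeps_rim_unchanged(self, vfa_protocol_small):
        g = phantom.bifurcating_geometry(vfa_protocol_small)
        labels = phantom.rasterize_phantom(g, vfa_protocol_small)
        tis = phantom.TissueParams.default(leak_fraction=0.0)
        pre = phantom.simulate_vfa_series(labels, tis, vfa_protocol_small, "pre", 1)
        post = phantom.simulate_vfa_series(labels, tis, vfa_protocol_small, "post", 1)
        rim = labels == phantom.PERIVASCULAR
        assert np.allclose(pre.volumes[:, rim], post.volumes[:, rim])

    def test_full_leak_changes_every_rim_voxel(self, vfa_protocol_small):
        g = phantom.bifurcating_geometry(vfa_protocol_small)
        labels = phantom.rasterize_phantom(g, vfa_protocol_small)
        rim_count = int((labels == phantom.PERIVASCULAR).sum())
        t1_post = phantom.t1_ground_truth(
            labels, phantom.TissueParams.default(leak_fraction=1.0), "post", seed=5
        )
        changed = (labels == phantom.PERIVASCULAR) & (t1_post == 500.0)
        assert int(changed.sum()) == rim_count

    @pytest.mark.parametrize("fraction", [0.0, 0.25, 0.5, 1.0])
    def test_leak_count_is_rounded_fraction(self, vfa_protocol_small, fraction):
        g = phantom.bifurcating_geometry(vfa_protocol_small)
        labels = phantom.rasterize_phantom(g, vfa_protocol_small)
        rim_count = int((labels == phantom.PERIVASCULAR).sum())
        mask = phantom.leaky_rim_mask(labels, fraction, seed=2)
        assert int(mask.sum()) == round(fraction * rim_count)
        assert not np.any(mask & (labels != phantom.PERIVASCULAR))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            phantom.add_rician_noise(np.zeros(3), -1.0, np.random.default_rng(0))

    def test_single_angle_rejected(self, tissue):
        p = ImagingProtocol(10.0, 1.1, (30, 30, 4), (16, 16, 2), (30.0,))
        labels = np.full((2, 16, 16), phantom.BLOOD, dtype=np.uint8)
        with pytest.raises(ValueError, match="two flip angles"):
            phantom.simulate_vfa_series(labels, tissue, p, "pre", seed=0)


class TestCineSimulation:
    def test_identity_dilation_noiseless_pre_equals_post(
        self, cine_protocol_small, tissue
    ):
        g = phantom.bifurcating_geometry(cine_protocol_small, dilation_factor=1.0)
        pre, post = phantom.simulate_cine(g, tissue, cine_protocol_small, seed=3)
        assert np.array_equal(pre.intensities, post.intensities)

    def test_blood_hyperintense_against_background(self, cine_protocol_small, tissue):
        g = phantom.bifurcating_geometry(cine_protocol_small)
        pre, _ = phantom.simulate_cine(g, tissue, cine_protocol_small, seed=3)
        labels = phantom.rasterize_phantom(g, cine_protocol_small, frame=0)
        frame = pre.frame(0)
        assert frame[labels == phantom.BLOOD].mean() > 3 * frame[
            labels == phantom.BACKGROUND
        ].mean()

    def test_seed_contract_bit_reproducible(self, cine_protocol_small):
        g = phantom.bifurcating_geometry(cine_protocol_small)
        tis = phantom.TissueParams.default(noise_sigma=3.0)
        a = phantom.simulate_cine(g, tis, cine_protocol_small, seed=11)
        b = phantom.simulate_cine(g, tis, cine_protocol_small, seed=11)
        c = phantom.simulate_cine(g, tis, cine_protocol_small, seed=12)
        assert np.array_equal(a[0].intensities, b[0].intensities)
        assert np.array_equal(a[1].intensities, b[1].intensities)
        assert not np.array_equal(a[0].intensities, c[0].intensities)

    def test_diastolic_frame_has_minimal_lumen_radius(self, cine_protocol_small):
        g = phantom.bifurcating_geometry(cine_protocol_small)
        scales = [
            g.pulsation_scale(f, cine_protocol_small.n_frames)
            for f in range(cine_protocol_small.n_frames)
        ]
        assert int(np.argmin(scales)) == g.diastolic_frame
        assert scales[g.diastolic_frame] == pytest.approx(1.0)

    def test_background_noise_is_rayleigh(self):
        # Rician noise on zero signal is Rayleigh; KS goodness of fit at 1%
        rng = np.random.default_rng(202)
        sigma = 3.0
        noisy = phantom.add_rician_noise(np.zeros(10_000), sigma, rng)
        _, p = stats.kstest(noisy, "rayleigh", args=(0, sigma))
        assert p > 0.01


class TestGeometryValidation:
    def test_branch_must_attach_interior(self, cine_protocol_small):
        g = phantom.bifurcating_geometry(cine_protocol_small)
        bad_branch = g.branch_centerline_mm.copy()
        bad_branch[:, 0] -= 100.0  # move branch before the main vessel start
        import dataclasses

        with pytest.raises(ValueError, match="interior"):
            dataclasses.replace(g, branch_centerline_mm=bad_branch)

    @pytest.mark.parametrize(
        "kwargs", [dict(pulsation_amplitude=0.6), dict(dilation_factor=0.0)]
    )
    def test_invalid_parameters_rejected(self, cine_protocol_small, kwargs):
        with pytest.raises(ValueError):
            phantom.bifurcating_geometry(cine_protocol_small, **kwargs)

    def test_tissue_t1_must_not_increase_post_contrast(self):
        with pytest.raises(ValueError, match="shortening"):
            phantom.CompartmentParams(1000.0, 1500.0, 100.0, 10.0)
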