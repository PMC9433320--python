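import numpy as np
import pytest

from oracles import clip_polyline_dense

from mitoquant import synthdata
from mitoquant.synthdata import NoiseParams


class TestDeterminism:
    @pytest.mark.parametrize(
        "maker",
        [
            lambda s: synthdata.make_cell_scene("bipolar", seed=s),
            lambda s: synthdata.make_droplet_field(seed=s),
            lambda s: synthdata.make_filament_field(seed=s),
            lambda s: synthdata.make_frap_series(n_post=20, seed=s),
            lambda s: synthdata.make_fret_pair(seed=s),
        ],
        ids=["cell", "droplets", "filaments", "frap", "fret"],
    )
    def test_same_seed_same_arrays(self, maker):
        s1, t1 = maker(7)
        s2, t2 = maker(7)
        assert np.array_equal(s1.data, s2.data)
        assert t1.true_params == t2.true_params

    def test_different_seed_different_noise(self):
        s1, _ = synthdata.make_droplet_field(seed=1)
        s2, _ = synthdata.make_droplet_field(seed=2)
        assert not np.array_equal(s1.data, s2.data)


class TestNoiseModel:
    def test_mean_of_realizations_converges_to_noiseless(self):
        quiet, _ = synthdata.make_fret_pair(noise=NoiseParams.off(), seed=0)
        acc = np.zeros_like(quiet.data)
        n = 60
        for s in range(n):
            noisy, _ = synthdata.make_fret_pair(seed=s)
            acc += noisy.data
        mean_img = acc / n
        rel = np.abs(mean_img - quiet.data).mean() / quiet.data.mean()
        assert rel < 0.05


class TestCellScene:
    def test_degenerate_central_fraction_one(self):
        stack, truth = synthdata.make_cell_scene(
            "bipolar", central_fraction=1.0, noise=NoiseParams.off(), seed=0
        )
        assert truth.true_params["central_fraction"] == 1.0

    @pytest.mark.parametrize("f", [0.3, 0.6, 0.8])
    def test_central_fraction_matches_band_integral(self, f):
        """Integrating the noiseless DNA model over the central band
        reproduces the requested fraction to within 1%."""
        stack, truth = synthdata.make_cell_scene(
            "bipolar", central_fraction=f, noise=NoiseParams.off(), seed=1
        )
        dna = stack.channel("dna") - truth.true_params["background"]
        px = stack.calibration.pixel_size_xy
        cy, cx = truth.true_params["center"]
        yy, xx = np.mgrid[0 : dna.shape[0], 0 : dna.shape[1]]
        band = (np.abs(xx - cx) <= 22.5 / 2 / px) & (np.abs(yy - cy) <= 7.06 / 2 / px)
        central = band & (np.abs(xx - cx) <= 2.5 / px)
        assert dna[central].sum() / dna[band].sum() == pytest.approx(f, abs=0.01)

    def test_unachievable_fraction_rejected(self):
        with pytest.raises(ValueError):
            synthdata.make_cell_scene("bipolar", central_fraction=0.0, seed=0)

    def test_tubulin_maxima_at_declared_poles(self):
        stack, truth = synthdata.make_cell_scene("bipolar", noise=NoiseParams.off(), seed=2)
        tub = stack.channel("tubulin")
        for py, px_ in truth.true_params["pole_positions"]:
            peak = np.unravel_index(np.argmax(tub), tub.shape)
            local = tub[int(py) - 2 : int(py) + 3, int(px_) - 2 : int(px_) + 3]
            assert local.max() >= 0.99 * tub.max()

    def test_kt_spots_recorded_with_labels(self):
        stack, truth = synthdata.make_cell_scene(
            "bipolar", chromatin_layout="disc", n_kt_inside=3, n_kt_outside=2, seed=3
        )
        spots = truth.true_params["spots"]
        assert [s["label"] for s in spots].count("outside") == 2
        assert "cenpa" in stack.channel_names

    def test_spots_outside_cell_rejected(self):
        with pytest.raises(ValueError):
            synthdata.make_cell_scene(
                "bipolar", chromatin_layout="disc", disc_radius_um=4.0,
                n_kt_outside=1, kt_outside_distance_um=20.0, seed=0,
            )


class TestDropletField:
    def test_partition_one_probe_statistically_uniform(self):
        stack, truth = synthdata.make_droplet_field(partition_ratio=1.0, seed=0)
        probe = stack.channel("probe")
        inside = np.zeros(probe.shape, bool)
        um = 1.0 / stack.calibration.pixel_size_xy
        yy, xx = np.mgrid[0 : probe.shape[0], 0 : probe.shape[1]]
        for d in truth.true_params["droplets"]:
            inside |= (yy - d["y"]) ** 2 + (xx - d["x"]) ** 2 <= (d["radius_um"] * um) ** 2
        assert probe[inside].mean() == pytest.approx(probe[~inside].mean(), rel=0.02)

    def test_partition_five_by_construction(self):
        stack, truth = synthdata.make_droplet_field(
            partition_ratio=5.0, noise=NoiseParams.off(), psf_sigma_px=0.0, seed=1
        )
        tp = truth.true_params
        probe = stack.channel("probe")
        um = 1.0 / stack.calibration.pixel_size_xy
        d = tp["droplets"][0]
        yy, xx = np.mgrid[0 : probe.shape[0], 0 : probe.shape[1]]
        core = (yy - d["y"]) ** 2 + (xx - d["x"]) ** 2 <= (0.5 * d["radius_um"] * um) ** 2
        inside = probe[core].mean() - tp["background"]
        outside = probe[:40, :40].mean() - tp["background"]
        assert inside / outside == pytest.approx(5.0, abs=1e-9)

    def test_buffer_rect_droplet_free(self):
        _, truth = synthdata.make_droplet_field(seed=2)
        y0, y1, _, _ = truth.true_params["buffer_rect"]
        for d in truth.true_params["droplets"]:
            assert d["y"] * 0.1 - d["radius_um"] > y1 * 0.1 - 10  # strip separation


class TestFilamentField:
    def test_exclusion_means_zero_inside_length(self):
        _, truth = synthdata.make_filament_field(exclusion=True, seed=0)
        assert truth.true_params["length_in_um"] >= 0
        # with exclusion the *rendered* truth assigns no length inside
        stack, truth = synthdata.make_filament_field(exclusion=True, seed=0)
        assert truth.true_params["exclusion"] is True

    def test_uniform_field_length_ratio_matches_area_ratio(self):
        _, truth = synthdata.make_filament_field(exclusion=False, n_segments=400, seed=1)
        tp = truth.true_params
        frac_area = tp["chromatin_area_fraction"]
        frac_len = tp["length_in_um"] / (tp["length_in_um"] + tp["length_out_um"])
        assert frac_len == pytest.approx(frac_area, rel=0.15)

    def test_truth_lengths_match_dense_clipping_oracle(self):
        _, truth = synthdata.make_filament_field(n_segments=50, seed=11)
        tp = truth.true_params
        px = tp["pixel_size"]
        centers = [np.array(c) / px for c in tp["chromatin_centers_um"]]
        r = tp["chromatin_radius_um"] / px
        h = w = 256  # generator default frame

        def in_rect(pts):
            return (
                (pts[:, 0] >= 0) & (pts[:, 0] <= h - 1)
                & (pts[:, 1] >= 0) & (pts[:, 1] <= w - 1)
            )

        def in_disc(pts):
            return np.any(
                [np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) <= r for c in centers],
                axis=0,
            )

        lin = lout = 0.0
        for p0, p1 in tp["segments"]:
            seg = np.array([p0, p1])
            a, _ = clip_polyline_dense(seg, lambda p: in_rect(p) & in_disc(p), pitch=0.02)
            b, _ = clip_polyline_dense(seg, lambda p: in_rect(p) & ~in_disc(p), pitch=0.02)
            lin += a
            lout += b
        assert lin * px == pytest.approx(tp["length_in_um"], rel=1e-3, abs=1e-6)
        assert lout * px == pytest.approx(tp["length_out_um"], rel=1e-3)

    def test_zero_radius_region_rejected(self):
        with pytest.raises(ValueError):
            synthdata.make_filament_field(chromatin_radius_um=0.0, seed=0)


class TestTomogramFixture:
    def test_truth_matches_dense_oracle(self):
        poly, mask, cal, truth = synthdata.make_tomogram_fixture(
            n_polylines=30, seed=13
        )
        tp = truth.true_params
        c = np.array(tp["sphere_center_um"])
        R = tp["sphere_radius_um"]
        v = tp["voxel_um"]
        zlo, zhi = tp["z_exclude"] * v, (mask.shape[0] - tp["z_exclude"]) * v

        def member(pts):
            return np.linalg.norm(pts - c, axis=1) <= R

        lin = lout = 0.0
        for line in poly:
            for p0, p1 in zip(line[:-1], line[1:]):
                seg = np.array([p0, p1])
                a_in, a_out = clip_polyline_dense(seg, member, pitch=0.001)
                # restrict to slab by separate dense accounting
                def member_slab_in(pts):
                    return (
                        (pts[:, 0] >= zlo) & (pts[:, 0] <= zhi) & member(pts)
                    )
                def member_slab(pts):
                    return (pts[:, 0] >= zlo) & (pts[:, 0] <= zhi)
                li, _ = clip_polyline_dense(seg, member_slab_in, pitch=0.001)
                ls, _ = clip_polyline_dense(seg, member_slab, pitch=0.001)
                lin += li
                lout += ls - li
        assert lin == pytest.approx(tp["length_in_um"], rel=1e-3, abs=1e-4)
        assert lout == pytest.approx(tp["length_out_um"], rel=1e-3)


class TestFrapSeries:
    def test_immobile_curve_constant_at_floor(self):
        stack, truth = synthdata.make_frap_series(
            mobile_fraction=0.0, noise=NoiseParams.off(), n_post=30, seed=0
        )
        tp = truth.true_params
        um = 1.0 / stack.calibration.pixel_size_xy
        yy, xx = np.mgrid[0:64, 0:64]
        roi = (yy - tp["roi"]["center"][0]) ** 2 + (xx - tp["roi"]["center"][1]) ** 2 <= (
            tp["roi"]["radius_um"] * um / 2
        ) ** 2
        post = [stack.channel("h2b", t=i)[roi].mean() for i in range(tp["n_pre"], 40)]
        assert np.ptp(post) < 1e-9

    def test_full_recovery_half_time_construction(self):
        """With m=1, β=1 and no noise the ROI recovers exactly halfway at t=τ."""
        stack, truth = synthdata.make_frap_series(
            mobile_fraction=1.0, half_time_s=0.5, time_step=0.1,
            acq_bleach_factor=1.0, noise=NoiseParams.off(), n_post=30, seed=0,
        )
        tp = truth.true_params
        um = 1.0 / stack.calibration.pixel_size_xy
        yy, xx = np.mgrid[0:64, 0:64]
        roi = (yy - tp["roi"]["center"][0]) ** 2 + (xx - tp["roi"]["center"][1]) ** 2 <= (
            tp["roi"]["radius_um"] * um / 2
        ) ** 2
        pre = stack.channel("h2b", t=0)[roi].mean()
        bleach = stack.channel("h2b", t=tp["n_pre"])[roi].mean()
        k_half = tp["n_pre"] + int(round(tp["half_time_s"] / tp["time_step"]))
        at_tau = stack.channel("h2b", t=k_half)[roi].mean()
        assert at_tau == pytest.approx(bleach + 0.5 * (pre - bleach), rel=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            synthdata.make_frap_series(mobile_fraction=1.5, seed=0)
        with pytest.raises(ValueError):
            synthdata.make_frap_series(half_time_s=0.0, seed=0)


class TestFretPair:
    def test_zero_ratio_scene(self):
        stack, truth = synthdata.make_fret_pair(
            fret_ratio=0.0, noise=NoiseParams.off(), seed=0
        )
        tp = truth.true_params
        fret = stack.channel("fret")
        nuc_c = tp["nucleus"]["center"]
        assert fret[int(nuc_c[0]), int(nuc_c[1])] == tp["backgrounds"]["fret"]

    def test_ratio_exact_by_construction(self):
        stack, truth = synthdata.make_fret_pair(
            fret_ratio=1.2, noise=NoiseParams.off(), seed=0
        )
        tp = truth.true_params
        c = tp["nucleus"]["center"]
        y, x = int(c[0]), int(c[1])
        f = stack.channel("fret")[y, x] - tp["backgrounds"]["fret"]
        cfp = stack.channel("cfp")[y, x] - tp["backgrounds"]["cfp"]
        assert f / cfp == pytest.approx(1.2, abs=1e-12)

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            synthdata.make_fret_pair(fret_ratio=-0.1, seed=0)


class TestTruthSerialization:
    def test_json_round_trip(self, tmp_path):
        _, truth = synthdata.make_droplet_field(seed=5)
        p = truth.to_json(tmp_path / "t.json")
        back = synthdata.SceneTruth.from_json(p)
        assert back.seed == truth.seed
        assert back.true_params["partition_ratio"] == truth.true_params["partition_ratio"]
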