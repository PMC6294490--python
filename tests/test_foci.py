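"""Detection, intensity measurement, tracking and trace assembly, validated
against injected ground truth and brute-force oracles."""

import numpy as np
import pytest

import forktime as ft
from forktime import foci


def make_volume(shape=(12, 64, 64), background=0.0):
    return np.full(shape, background, dtype=float)


def inject_spot(vol, center, peak, sigmas=(0.5, 1.0, 1.0)):
    """Additive 3D Gaussian with given peak amplitude (point-sampled)."""
    zz, yy, xx = np.indices(vol.shape)
    cz, cy, cx = center
    sz, sy, sx = sigmas
    vol += peak * np.exp(
        -0.5 * (((zz - cz) / sz) ** 2 + ((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2)
    )
    return vol


@pytest.fixture
def params():
    return foci.DetectionParams(sigma_z_vox=0.5, sigma_xy_vox=1.0)


class TestDetectSpots:
    def test_blank_noise_rarely_triggers(self, params):
        """Pure Gaussian noise at k_sigma = 5 yields no detections in >= 99%
        of seeds.  Oracle: the false-positive rate of 5-sigma thresholding is
        at most ~N x Phi(-5) ~ 0.4% per 12x32x32 volume."""
        empty = 0
        n_seeds = 100
        for seed in range(n_seeds):
            vol = np.random.default_rng(seed).normal(0, 1, (12, 32, 32))
            if not foci.detect_spots(vol, params):
                empty += 1
        assert empty >= 99

    def test_single_spot_found_at_true_center(self, params):
        """One spot at SNR 10: exactly one detection within 1 voxel of the
        argmax of the noiseless volume."""
        rng = np.random.default_rng(0)
        clean = inject_spot(make_volume(shape=(12, 32, 32)), (6.0, 22.0, 15.0), peak=10.0)
        true_center = np.unravel_index(np.argmax(clean), clean.shape)
        vol = clean + rng.normal(0, 1.0, clean.shape)
        dets = foci.detect_spots(vol, params)
        assert len(dets) == 1
        assert np.all(np.abs(np.array(dets[0].position) - true_center) <= 1.0)

    def test_two_separated_spots(self, params):
        rng = np.random.default_rng(1)
        vol = make_volume(shape=(12, 32, 32))
        inject_spot(vol, (6.0, 16.0, 11.0), peak=10.0)
        inject_spot(vol, (6.0, 16.0, 21.0), peak=10.0)
        vol += rng.normal(0, 1.0, vol.shape)
        assert len(foci.detect_spots(vol, params)) == 2

    def test_sister_foci_merged_with_summed_response(self, params):
        vol = make_volume()
        inject_spot(vol, (6.0, 20.0, 20.0), peak=10.0)
        inject_spot(vol, (6.0, 20.0, 22.0), peak=10.0)  # within merge radius
        dets = foci.detect_spots(vol, params)
        assert len(dets) == 1

    def test_requires_finite_3d_input(self, params):
        with pytest.raises(ValueError):
            foci.detect_spots(np.zeros((5, 5)), params)
        bad = np.zeros((4, 8, 8))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            foci.detect_spots(bad, params)
        with pytest.raises(ValueError):
            foci.DetectionParams(sigma_z_vox=0.0, sigma_xy_vox=1.0)

    def test_recall_and_localization_at_snr_8(self, params):
        """>= 95% recall and < 1 voxel xy localization error over 200 spots
        at SNR >= 8."""
        found, err_xy = 0, []
        n_spots = 200
        rng = np.random.default_rng(42)
        for _ in range(n_spots):
            vol = make_volume(shape=(12, 48, 48))
            c = (
                rng.uniform(3, 8),
                rng.uniform(10, 38),
                rng.uniform(10, 38),
            )
            inject_spot(vol, c, peak=8.0)
            vol += rng.normal(0, 1.0, vol.shape)
            dets = foci.detect_spots(vol, params)
            if len(dets) >= 1:
                best = min(
                    dets, key=lambda d: np.hypot(d.position[1] - c[1], d.position[2] - c[2])
                )
                e = np.hypot(best.position[1] - c[1], best.position[2] - c[2])
                if e <= 3.0:
                    found += 1
                    err_xy.append(e)
        assert found / n_spots >= 0.95
        assert np.mean(err_xy) < 1.0


class TestMeasureIntensity:
    ip = foci.IntensityParams(z_step=0.7, pixel_size=0.15)

    def test_zero_volume_measures_zero(self):
        val, clipped = foci.measure_intensity(make_volume(), (6.0, 32.0, 32.0), self.ip)
        assert val == 0.0
        assert not clipped

    def test_matches_direct_core_sum_minus_background(self):
        """Noiseless spot on constant background b: value equals the direct
        core sum minus b x core voxel count (oracle: direct arithmetic)."""
        b = 50.0
        vol = make_volume(background=b)
        inject_spot(vol, (6.0, 32.0, 32.0), peak=200.0)
        val, clipped = foci.measure_intensity(vol, (6.0, 32.0, 32.0), self.ip)
        # oracle: same aperture arithmetic done directly
        scale = np.array([0.7, 0.15, 0.15])
        zz, yy, xx = np.indices(vol.shape)
        dist = np.sqrt(
            ((zz - 6.0) * scale[0]) ** 2
            + ((yy - 32.0) * scale[1]) ** 2
            + ((xx - 32.0) * scale[2]) ** 2
        )
        core = dist <= self.ip.r_core
        expect = vol[core].sum() - b * core.sum()
        # the shell median sees the spot's Gaussian tail (< 1e-3 of the peak),
        # so agreement is to that tail level, not machine precision
        assert val == pytest.approx(expect, rel=1e-4)
        assert not clipped

    def test_linearity_in_amplitude(self):
        vals = []
        for peak in (100.0, 200.0):
            vol = make_volume(background=10.0)
            inject_spot(vol, (6.0, 32.0, 32.0), peak=peak)
            v, _ = foci.measure_intensity(vol, (6.0, 32.0, 32.0), self.ip)
            vals.append(v)
        assert vals[1] / vals[0] == pytest.approx(2.0, rel=0.01)

    def test_edge_measurement_flagged(self):
        vol = make_volume()
        _, clipped = foci.measure_intensity(vol, (0.0, 1.0, 1.0), self.ip)
        assert clipped


def det(frame, pos, channel="green", intensity=100.0):
    return foci.SpotDetection(
        frame=frame, channel=channel, position=pos, raw_score=1.0, intensity=intensity
    )


class TestLinkTracks:
    def test_stationary_spot_single_track(self):
        dets = [det(f, (6.0, 20.0, 20.0)) for f in range(5)]
        tracks = foci.link_tracks(dets, max_displacement=0.5)
        assert len(tracks) == 1
        assert tracks[0].frames == [0, 1, 2, 3, 4]
        assert tracks[0].gaps == []

    def test_gap_closing_records_missing_frame(self):
        dets = [det(f, (6.0, 20.0, 20.0)) for f in (0, 1, 2, 4)]
        tracks = foci.link_tracks(dets, max_displacement=0.5, max_gap=1)
        assert len(tracks) == 1
        assert tracks[0].gaps == [3]

    def test_gap_beyond_limit_splits_track(self):
        dets = [det(f, (6.0, 20.0, 20.0)) for f in (0, 1, 5, 6)]
        tracks = foci.link_tracks(dets, max_displacement=0.5, max_gap=1)
        assert len(tracks) == 2

    def test_converging_spots_keep_identity_like_optimal_matching(self):
        """Greedy assignment equals brute-force minimal-cost matching for
        two converging spots when max_displacement < their spacing."""
        a0 = [det(0, (6.0, 20.0, 10.0)), det(0, (6.0, 20.0, 30.0))]
        a1 = [det(1, (6.0, 20.0, 12.0)), det(1, (6.0, 20.0, 28.0))]
        tracks = foci.link_tracks(a0 + a1, max_displacement=1.0)
        oracle = foci.brute_force_link(a0, a1, max_displacement=1.0)
        assert len(tracks) == 2
        greedy_pairs = sorted(
            (a0.index(t.detections[0]), a1.index(t.detections[1])) for t in tracks
        )
        assert greedy_pairs == oracle

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_small_random_frames(self, seed):
        """Frame-to-frame assignment equals exhaustive minimal matching on
        up to 3 well-separated spots."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 4))
        base = rng.uniform(5, 40, size=(n, 2))
        # keep spots >> max_displacement apart so the optimum is unique
        while n > 1 and np.min(
            [np.linalg.norm(base[i] - base[j]) * 0.25 for i in range(n) for j in range(i)]
        ) < 3.0:
            base = rng.uniform(5, 40, size=(n, 2))
        f0 = [det(0, (6.0, y, x)) for y, x in base]
        jitter = rng.uniform(-1.5, 1.5, size=(n, 2))
        f1 = [det(1, (6.0, y + dy, x + dx)) for (y, x), (dy, dx) in zip(base, jitter)]
        tracks = foci.link_tracks(f0 + f1, max_displacement=1.0)
        oracle = foci.brute_force_link(f0, f1, max_displacement=1.0)
        greedy_pairs = sorted(
            (f0.index(t.detections[0]), f1.index(t.detections[1]))
            for t in tracks
            if len(t.detections) == 2
        )
        assert greedy_pairs == oracle


class TestAssembleTraces:
    def test_nearby_pair_forms_one_trace(self):
        tg = foci.Track("green", [det(f, (6.0, 20.0, 20.0), "green") for f in range(5)])
        tr = foci.Track("red", [det(f, (6.0, 20.0, 22.0), "red") for f in range(5)])
        traces, unpaired = foci.assemble_cell_traces([tg], [tr], n_frames=5)
        assert len(traces) == 1 and not unpaired
        assert np.all(np.isfinite(traces[0].intensity_green))

    def test_distant_tracks_stay_unpaired(self):
        tg = foci.Track("green", [det(f, (6.0, 10.0, 10.0), "green") for f in range(5)])
        tr = foci.Track("red", [det(f, (6.0, 10.0, 40.0), "red") for f in range(5)])  # 7.5 µm
        traces, unpaired = foci.assemble_cell_traces(
            [tg], [tr], pairing_radius=2.0, n_frames=5
        )
        assert traces == []
        assert len(unpaired) == 2

    def test_missing_frames_become_nan_not_interpolated(self):
        tg = foci.Track("green", [det(f, (6.0, 20.0, 20.0), "green") for f in (0, 1, 3, 4)])
        tr = foci.Track("red", [det(f, (6.0, 20.0, 22.0), "red") for f in range(5)])
        traces, _ = foci.assemble_cell_traces([tg], [tr], n_frames=5)
        assert np.isnan(traces[0].intensity_green[2])


class TestSimulatedMoviePipeline:
    def run_pipeline(self, movie):
        acq = movie.config
        params = foci.DetectionParams(
            sigma_z_vox=acq.psf_sigma_z / acq.z_step,
            sigma_xy_vox=acq.psf_sigma_xy / acq.pixel_size,
        )
        ip = foci.IntensityParams(z_step=acq.z_step, pixel_size=acq.pixel_size)
        per_chan = {c: [] for c in foci.CHANNELS}
        for f in range(acq.n_frames):
            for c, chan in enumerate(foci.CHANNELS):
                vol = movie.data[f, c]
                dets = foci.detect_spots(vol, params, frame=f, channel=chan)
                for d in dets:
                    d.intensity, d.clipped = foci.measure_intensity(vol, d.position, ip)
                per_chan[chan].extend(dets)
        tracks = {
            c: foci.link_tracks(per_chan[c], max_displacement=0.8, min_length=5)
            for c in foci.CHANNELS
        }
        return foci.assemble_cell_traces(
            tracks["green"], tracks["red"], n_frames=acq.n_frames,
            frame_interval=acq.frame_interval,
        )

    def test_ten_cell_movie_recovers_all_cells(self, nominal):
        """A simulated 10-cell movie yields 10 paired traces whose positions
        match the simulator's ground-truth spot table."""
        rng = np.random.default_rng(5)
        acq = ft.AcquisitionConfig(n_frames=40, ny=96, nx=96)
        gts = ft.sample_cell_kinetics(
            nominal, ft.ScenarioConfig(n_cells=10, seed=5, firing_time_mean=15), rng
        )
        movie, truth = ft.render_movie(gts, nominal, acq, rng=rng)
        traces, unpaired = self.run_pipeline(movie)
        assert len(traces) == 10
        true_pos = truth[(truth.frame == 0) & (truth.channel == "green")]
        matched = set()
        for tr in traces:
            y, x = tr.position_um
            d = np.hypot(true_pos.y * acq.pixel_size - y, true_pos.x * acq.pixel_size - x)
            cid = true_pos.cell_id.iloc[int(np.argmin(d))]
            assert d.min() < 1.0
            matched.add(cid)
        assert len(matched) == 10

    def test_measured_trace_tracks_ground_truth_intensity(self, nominal):
        """Pearson r >= 0.95 between the measured trace and the rendered
        ground-truth amplitude time course at default noise."""
        rng = np.random.default_rng(6)
        acq = ft.AcquisitionConfig(n_frames=60, ny=48, nx=48)
        gts = ft.sample_cell_kinetics(
            nominal, ft.ScenarioConfig(n_cells=1, seed=6, firing_time_mean=15), rng
        )
        movie, truth = ft.render_movie(gts, nominal, acq, rng=rng)
        traces, _ = self.run_pipeline(movie)
        assert len(traces) == 1
        for chan, meas in (("green", traces[0].intensity_green),
                           ("red", traces[0].intensity_red)):
            amp = truth[truth.channel == chan].sort_values("frame").amplitude.to_numpy()
            keep = np.isfinite(meas)
            r = np.corrcoef(meas[keep], amp[keep])[0, 1]
            assert r >= 0.95

    def test_frame_order_statelessness(self, params):
        """Detection is per-frame stateless: processing order is irrelevant."""
        rng = np.random.default_rng(7)
        vols = [
            inject_spot(make_volume(), (6.0, 20.0, 20.0), peak=10.0)
            + rng.normal(0, 1, (12, 64, 64))
            for _ in range(4)
        ]
        fwd = [foci.detect_spots(v, params, frame=i) for i, v in enumerate(vols)]
        rev = [foci.detect_spots(v, params, frame=i) for i, v in reversed(list(enumerate(vols)))]
        fwd_pos = [[d.position for d in dets] for dets in fwd]
        rev_pos = [[d.position for d in dets] for dets in rev][::-1]
        assert fwd_pos == rev_pos
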