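import numpy as np
import pytest

import centrotrack as ct
from centrotrack import AmbiguousCellError, SpotObservation
from centrotrack.tracking import link_pair


def _spot(x, y, q=1.0):
    return SpotObservation(x=x, y=y, quality=q)


class TestDetectSpots:
    def test_blank_image_empty(self):
        assert ct.detect_spots(np.zeros((32, 32)), 0.1426, 0.65, 1.0) == []

    def test_under_resolved_diameter_rejected(self):
        with pytest.raises(ValueError, match="under-resolved"):
            ct.detect_spots(np.zeros((32, 32)), pixel_size=0.5, expected_diameter=0.65)

    def test_snr10_recovery_within_quarter_pixel(self):
        movie, truth = ct.make_centriole_movie(n_frames=10, snr=10, seed=2)
        errs = []
        for t in range(10):
            spots = ct.detect_spots(movie.channel("centriole")[t], movie.pixel_size,
                                    0.65, quality_threshold=20.0)
            assert len(spots) >= 2
            got = sorted([(s.x, s.y) for s in spots[:2]])
            want = sorted([tuple(truth.positions_a[t]), tuple(truth.positions_b[t])])
            errs += [np.hypot(g[0] - w[0], g[1] - w[1]) / movie.pixel_size
                     for g, w in zip(got, want)]
        assert np.sqrt(np.mean(np.square(errs))) < 0.25

    def test_puncta_at_cohesive_distance_resolved(self):
        # 0.7 um apart with a 0.2-um PSF must appear as two spots
        movie, _ = ct.make_centriole_movie(
            n_frames=1, cohesive_distance=0.7, snr=10, seed=3
        )
        spots = ct.detect_spots(movie.channel("centriole")[0], movie.pixel_size,
                                0.65, quality_threshold=20.0)
        assert len(spots) == 2

    def test_quality_sorted_descending(self, noiseless_pair):
        movie, _ = noiseless_pair
        spots = ct.detect_spots(movie.channel("centriole")[0], movie.pixel_size, 0.65, 1.0)
        qualities = [s.quality for s in spots]
        assert qualities == sorted(qualities, reverse=True)


class TestLinkPair:
    def test_stationary_spots_constant_identity(self):
        frames = [[_spot(1.0, 1.0), _spot(3.0, 1.0)] for _ in range(10)]
        track = link_pair(frames, frame_interval=6.0)
        assert len(track) == 10
        np.testing.assert_allclose(track.distances, 2.0)
        np.testing.assert_allclose(track.pos_a, np.tile(track.pos_a[0], (10, 1)))

    def test_gap_of_three_bridged_gap_of_four_ends(self):
        def frames_with_gap(n_missing):
            fr = [[_spot(1.0, 1.0), _spot(3.0, 1.0)] for _ in range(5)]
            fr += [[_spot(1.0, 1.0)] for _ in range(n_missing)]
            fr += [[_spot(1.0, 1.0), _spot(3.0, 1.0)] for _ in range(5)]
            return fr

        bridged = link_pair(frames_with_gap(3), gap_size=3)
        assert len(bridged) == 13  # continues through the gap
        ended = link_pair(frames_with_gap(4), gap_size=3)
        assert len(ended) <= 9  # track terminated at the gap

    def test_crowded_frame_rejected(self):
        frames = [[_spot(float(i), 0.0) for i in range(5)]]
        with pytest.raises(AmbiguousCellError):
            link_pair(frames)

    def test_identity_swap_never_changes_distance(self):
        rng = np.random.default_rng(5)
        frames = []
        a, b = np.array([2.0, 2.0]), np.array([4.0, 3.0])
        for _ in range(20):
            a = a + rng.normal(0, 0.1, 2)
            b = b + rng.normal(0, 0.1, 2)
            pair = [_spot(*a, q=rng.random()), _spot(*b, q=rng.random())]
            rng.shuffle(pair)
            frames.append(pair)
        fwd = link_pair(frames)
        swapped = link_pair([list(reversed(f)) for f in frames])
        np.testing.assert_allclose(fwd.distances, swapped.distances, atol=1e-12)


class TestDistanceSeries:
    def test_known_pair_distance(self):
        track = link_pair([[_spot(0.0, 0.0), _spot(0.8, 0.0)]], frame_interval=6.0)
        series = ct.distance_series(track)
        assert series[0, 1] == pytest.approx(0.8)

    def test_time_is_frame_times_interval(self):
        frames = [[_spot(0.0, 0.0), _spot(1.0, 0.0)] for _ in range(4)]
        series = ct.distance_series(link_pair(frames, frame_interval=15.0))
        np.testing.assert_allclose(series[:, 0], [0, 15, 30, 45])

    def test_missing_frames_omitted_not_interpolated(self):
        frames = [
            [_spot(0.0, 0.0), _spot(1.0, 0.0)],
            [_spot(0.0, 0.0)],
            [_spot(0.0, 0.0), _spot(1.0, 0.0)],
        ]
        series = ct.distance_series(link_pair(frames, frame_interval=1.0))
        np.testing.assert_allclose(series[:, 0], [0, 2])

    def test_empty_track_empty_series(self):
        track = link_pair([[], []])
        assert ct.distance_series(track).shape == (0, 2)


class TestEndToEndRecovery:
    def test_scripted_fracture_distance_recovered(self, fracture_movie):
        movie, truth = fracture_movie
        track = ct.track_centriole_pair(movie)
        series = ct.distance_series(track)
        ok = np.isfinite(track.distances)
        err = series[:, 1] - truth.distances[track.frames[ok]]
        assert np.sqrt(np.mean(err**2)) < 0.1

    def test_distance_series_rigid_motion_invariant(self, noiseless_pair):
        movie, _ = noiseless_pair
        frame = movie.channel("centriole")[0]
        base = ct.detect_spots(frame, movie.pixel_size, 0.65, 1.0)
        rotated = ct.detect_spots(np.rot90(frame), movie.pixel_size, 0.65, 1.0)
        shifted = ct.detect_spots(np.roll(frame, (3, 5), axis=(0, 1)),
                                  movie.pixel_size, 0.65, 1.0)

        def dist(spots):
            (a, b) = spots[:2]
            return np.hypot(a.x - b.x, a.y - b.y)

        assert dist(rotated) == pytest.approx(dist(base), abs=1e-3)
        assert dist(shifted) == pytest.approx(dist(base), abs=1e-3)


class TestMigrationStats:
    def test_straight_track(self):
        pos = np.column_stack([np.zeros(6), np.arange(6) * 5.0])
        times = np.arange(6) * 60.0
        speed, accum, direc = ct.track_migration_stats(pos, times)
        assert speed == pytest.approx(5.0)
        assert accum == pytest.approx(25.0)
        assert direc == pytest.approx(1.0)

    def test_back_and_forth_directionality_zero(self):
        pos = np.array([[0.0, 0.0], [0.0, 5.0], [0.0, 0.0]])
        _, _, direc = ct.track_migration_stats(pos, np.array([0.0, 60.0, 120.0]))
        assert direc == pytest.approx(0.0)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            ct.track_migration_stats(np.array([[0.0, 0.0]]), np.array([0.0]))


class TestCometStats:
    def test_mean_speed(self):
        # 1 um per 5-s frame = 0.2 um/s
        tracks = [np.column_stack([np.arange(5), np.arange(5) * 1.0, np.zeros(5)])]
        comets = ct.CometTrackSet(tracks=tracks, frame_interval=5.0)
        stats = ct.comet_stats(comets, anchors=[[0.0, 0.0]], origin_radius=2.0)
        assert stats["mean_comet_speed"] == pytest.approx(0.2)

    def test_origin_attribution_to_scripted_anchors(self):
        anchors = np.array([[0.0, 0.0], [10.0, 10.0]])
        tracks = []
        for ax, ay in anchors:
            for k in range(3):
                tracks.append(np.column_stack(
                    [np.arange(4) + k, ax + 0.3 + np.arange(4.0), np.full(4, ay)]))
        comets = ct.CometTrackSet(tracks=tracks, frame_interval=5.0)
        stats = ct.comet_stats(comets, anchors, origin_radius=1.0)
        assert stats["n_active_anchors"] == 2
        np.testing.assert_array_equal(stats["anchor_origin_counts"], [3, 3])

    def test_no_origin_in_radius_zero_rate(self):
        tracks = [np.column_stack([np.arange(3), np.full(3, 50.0), np.full(3, 50.0)])]
        comets = ct.CometTrackSet(tracks=tracks, frame_interval=5.0)
        stats = ct.comet_stats(comets, anchors=[[0.0, 0.0]], origin_radius=1.0)
        assert stats["nucleation_rate_per_cell"] == 0.0

    def test_gapped_track_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            ct.CometTrackSet(
                tracks=[np.array([[0, 0.0, 0.0], [3, 1.0, 1.0]])], frame_interval=1.0
            )
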