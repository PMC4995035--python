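"""Skeleton tracing, segment fitting and fiber merging."""

import numpy as np
import pytest

from actintrace.extract import (
    Fiber,
    FixedLengthSegment,
    MergeConfig,
    extract_fibers,
    fit_segments,
    merge_fibers,
    overlap_endpoints,
    skeletonize_and_trace,
)
from actintrace.synthetic import FilamentSpec, rasterize_filaments


def chain_at(angle_deg, length, origin=(100.0, 100.0)):
    """Integer pixel chain approximating a straight line."""
    t = np.deg2rad(angle_deg)
    k = np.arange(length, dtype=float)
    rows = np.round(origin[0] - k * np.sin(t)).astype(int)
    cols = np.round(origin[1] + k * np.cos(t)).astype(int)
    pts = np.stack([rows, cols], axis=1)
    _, idx = np.unique(pts, axis=0, return_index=True)
    return pts[np.sort(idx)]


class TestTracing:
    def test_bar_traces_to_single_chain(self):
        m = np.zeros((20, 120), bool)
        m[9:12, 10:110] = True
        chains = skeletonize_and_trace(m)
        assert len(chains) == 1
        assert abs(len(chains[0]) - 100) <= 3
        # ordered: consecutive pixels are 8-adjacent
        steps = np.abs(np.diff(chains[0], axis=0)).max(axis=1)
        assert (steps == 1).all()

    def test_empty_mask_gives_no_chains(self):
        assert skeletonize_and_trace(np.zeros((32, 32), bool)) == []

    def test_crossing_bars_split_at_junction(self):
        m = np.zeros((60, 60), bool)
        m[29:32, 5:55] = True
        m[5:55, 29:32] = True
        chains = skeletonize_and_trace(m)
        assert len(chains) == 4
        # every skeleton pixel belongs to exactly one chain
        allpix = np.vstack(chains)
        assert len(np.unique(allpix, axis=0)) == len(allpix)

    def test_all_skeleton_pixels_covered(self):
        from skimage.morphology import skeletonize

        img, mask = rasterize_filaments(
            [
                FilamentSpec(center=(40, 60), angle_deg=20, length_px=80),
                FilamentSpec(center=(70, 60), angle_deg=130, length_px=70),
            ],
            (128, 128),
        )
        chains = skeletonize_and_trace(mask)
        skel = skeletonize(mask)
        covered = np.vstack(chains)
        assert len(covered) == int(skel.sum())
        assert len(np.unique(covered, axis=0)) == len(covered)


class TestFitSegments:
    def test_straight_chain_yields_one_segment_at_its_angle(self):
        segs = fit_segments(chain_at(30.0, 100), L=30)
        assert len(segs) == 1
        assert segs[0].theta_deg == pytest.approx(30.0, abs=1.0)
        assert segs[0].length_px >= 90

    def test_short_chain_is_discarded(self):
        assert fit_segments(chain_at(10.0, 20), L=30) == []

    def test_right_angle_elbow_splits_into_two_segments(self):
        a = np.array([[50, c] for c in range(0, 50)])
        b = np.array([[r, 49] for r in range(50, 100)])
        segs = fit_segments(np.vstack([a, b]), L=30)
        assert len(segs) == 2
        d = abs(segs[0].theta_deg - segs[1].theta_deg) % 180
        assert min(d, 180 - d) == pytest.approx(90.0, abs=2.0)

    def test_fitted_segments_stay_within_perpendicular_error(self):
        rng = np.random.default_rng(5)
        # gently wavy chain: every fitted segment must be quasi-straight
        cols = np.arange(200)
        rows = (60 + 4 * np.sin(cols / 25.0)).round().astype(int)
        chain = np.stack([rows, cols], axis=1)
        for seg in fit_segments(chain, L=30):
            pts = seg.pixels.astype(float)
            c = pts.mean(axis=0)
            d = pts - c
            cov = d.T @ d / len(pts)
            lam = np.linalg.eigvalsh(cov)[0]
            assert np.sqrt(max(lam, 0)) <= 1.0 + 1e-9


class TestOverlapEndpoints:
    def test_shared_endpoint_overlaps(self):
        a = FixedLengthSegment.from_pixels(chain_at(0.0, 40))
        b = FixedLengthSegment.from_pixels(chain_at(0.0, 40, origin=(100.0, 139.0)))
        assert overlap_endpoints(a, b, 2.0)

    def test_distant_parallel_segments_do_not_overlap(self):
        a = FixedLengthSegment.from_pixels(chain_at(0.0, 40))
        b = FixedLengthSegment.from_pixels(chain_at(0.0, 40, origin=(150.0, 100.0)))
        assert not overlap_endpoints(a, b, 2.0)

    def test_boundary_distance_is_inclusive(self):
        a = FixedLengthSegment.from_pixels(chain_at(0.0, 40))
        # endpoint exactly 2 px (perpendicular) from the other chain
        b = FixedLengthSegment.from_pixels(chain_at(0.0, 40, origin=(102.0, 120.0)))
        assert overlap_endpoints(a, b, 2.0)
        assert not overlap_endpoints(a, b, 1.9)


class TestMergeFibers:
    def test_collinear_overlapping_segments_merge_at_zero_tolerance(self):
        a = FixedLengthSegment.from_pixels(np.array([[50, c] for c in range(0, 41)]))
        b = FixedLengthSegment.from_pixels(np.array([[50, c] for c in range(40, 91)]))
        fibers = merge_fibers([a, b], MergeConfig(T_theta=0))
        assert len(fibers) == 1
        assert fibers[0].theta_deg == pytest.approx(40 % 180 * 0, abs=1e-9)
        assert fibers[0].length_px == pytest.approx(90, abs=3)

    def test_weighted_orientation_formula(self):
        s1 = FixedLengthSegment(
            pixels=np.array([[50, c] for c in range(40, 51)]),
            theta_deg=0.0, endpoints=((50, 40), (50, 50)), length_px=10.0,
        )
        px = [
            [50 - int(round(k * np.tan(np.deg2rad(4)))), 50 + k]
            for k in range(0, 31)
        ]
        s2 = FixedLengthSegment(
            pixels=np.array(px), theta_deg=4.0,
            endpoints=(tuple(px[0]), tuple(px[-1])), length_px=30.0,
        )
        fibers = merge_fibers([s1, s2], MergeConfig(T_theta=4))
        assert len(fibers) == 1
        # (10*0 + 30*4) / 40 = 3.0
        assert fibers[0].theta_deg == pytest.approx(3.0, abs=1e-9)

    def test_angle_gap_beyond_tolerance_prevents_merge(self):
        a = FixedLengthSegment.from_pixels(chain_at(0.0, 41))
        b = FixedLengthSegment.from_pixels(chain_at(10.0, 41, origin=(100.0, 140.0)))
        fibers = merge_fibers([a, b], MergeConfig(T_theta=2))
        assert len(fibers) == 2

    def test_wraparound_angles_merge(self):
        # 179 and 1 degrees are 2 degrees apart circularly; a signed
        # comparison would wrongly see 178
        a = FixedLengthSegment.from_pixels(chain_at(179.0, 41))
        b = FixedLengthSegment.from_pixels(chain_at(1.0, 41, origin=(99.0, 60.0)))
        a.theta_deg, b.theta_deg = 179.0, 1.0
        fibers = merge_fibers([a, b], MergeConfig(T_theta=2))
        assert len(fibers) == 1
        # the length-weighted mean respects the wraparound: near 0/180
        d = min(fibers[0].theta_deg, 180 - fibers[0].theta_deg)
        assert d <= 1.1

    def test_idempotence(self):
        segs = [
            FixedLengthSegment.from_pixels(chain_at(0.0, 41)),
            FixedLengthSegment.from_pixels(chain_at(1.0, 41, origin=(100.0, 140.0))),
            FixedLengthSegment.from_pixels(chain_at(90.0, 41, origin=(30.0, 30.0))),
        ]
        cfg = MergeConfig(T_theta=2)
        once = merge_fibers(segs, cfg)
        again = merge_fibers(
            [
                FixedLengthSegment(
                    pixels=f.pixels, theta_deg=f.theta_deg,
                    endpoints=f.endpoints, length_px=f.length_px,
                )
                for f in once
            ],
            cfg,
        )
        assert len(again) == len(once)
        for f1, f2 in zip(once, again):
            assert np.array_equal(f1.pixels, f2.pixels)
            assert f1.theta_deg == pytest.approx(f2.theta_deg, abs=1e-9)

    def test_fiber_count_non_increasing_in_tolerance(self):
        rng = np.random.default_rng(0)
        segs = []
        for i in range(8):
            ang = rng.uniform(0, 180)
            segs.append(
                FixedLengthSegment.from_pixels(
                    chain_at(ang, 45, origin=(100.0 + 3 * i, 100.0 + 2 * i))
                )
            )
        counts = [
            len(merge_fibers(segs, MergeConfig(T_theta=t))) for t in (0, 1, 2, 4)
        ]
        assert all(c2 <= c1 for c1, c2 in zip(counts, counts[1:]))

    def test_pixel_conservation(self):
        segs = [
            FixedLengthSegment.from_pixels(chain_at(0.0, 41)),
            FixedLengthSegment.from_pixels(chain_at(2.0, 41, origin=(100.0, 140.0))),
        ]
        source = np.unique(np.vstack([s.pixels for s in segs]), axis=0)
        fibers = merge_fibers(segs, MergeConfig(T_theta=2))
        out = np.vstack([f.pixels for f in fibers])
        assert len(np.unique(out, axis=0)) == len(out)  # no duplicates
        src_set = {tuple(p) for p in source}
        assert all(tuple(p) in src_set for p in out)  # no invented pixels


class TestRecovery:
    def test_well_separated_fibers_recovered_one_to_one(self):
        from actintrace.synthetic import random_scene

        scene = random_scene(
            n_fibers=10, shape=(256, 256), seed=21, length_range=(70.0, 110.0),
            width_range=(2.0, 4.0), min_separation=12.0, n_blobs=0,
            noise_sigma=0.0,
        )
        fibers, _ = extract_fibers(scene.truth_mask, MergeConfig(T_theta=2))
        matched = 0
        for spec in scene.truth_fibers:
            best = None
            for f in fibers:
                d = abs(f.theta_deg - spec.angle_deg) % 180
                d = min(d, 180 - d)
                mid = f.pixels.mean(axis=0)
                if (
                    d <= 2.0
                    and abs(f.length_px - spec.length_px) / spec.length_px <= 0.15
                    and np.hypot(*(mid - np.array(spec.center))) < 20
                ):
                    best = f
                    break
            if best is not None:
                matched += 1
        assert matched >= 0.8 * len(scene.truth_fibers)
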