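"""Patch-to-body matching: frames, disc-segment geometry, body partition,
exclusion rules, and the pixel-level brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flyopto import hitdetect as hd
from flyopto.synthetic_fly import FlyBodyModel


def _pose(centroid=(0.0, 0.0), heading=0.0, limbs=None, model=None):
    if limbs is None:
        limbs = (model or FlyBodyModel()).rest_offsets
    centroid = np.asarray(centroid, dtype=float)
    ch, sh = np.cos(heading), np.sin(heading)
    R = np.array([[ch, -sh], [sh, ch]])
    ground = limbs @ R.T + centroid
    return centroid, heading, ground


class TestBodyFrame:
    def test_centroid_maps_to_origin(self):
        bf = hd.to_body_frame((3.0, 4.0), (3.0, 4.0), 1.2)
        np.testing.assert_allclose(bf, [0.0, 0.0], atol=1e-12)

    def test_point_ahead_on_heading_axis(self):
        bf = hd.to_body_frame((1.0, 0.0), (0.0, 0.0), 0.0)
        np.testing.assert_allclose(bf, [1.0, 0.0], atol=1e-12)

    def test_left_of_fly_has_positive_y(self):
        # heading +x; the fly's left is +y in a right-handed frame
        bf = hd.to_body_frame((0.0, 1.0), (0.0, 0.0), 0.0)
        np.testing.assert_allclose(bf, [0.0, 1.0], atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        px=st.floats(-10, 10), py=st.floats(-10, 10),
        cx=st.floats(-10, 10), cy=st.floats(-10, 10),
        h=st.floats(-10, 10),
    )
    def test_roundtrip_identity(self, px, py, cx, cy, h):
        bf = hd.to_body_frame((px, py), (cx, cy), h)
        back = hd.from_body_frame(bf, (cx, cy), h)
        np.testing.assert_allclose(back, [px, py], atol=1e-10)


class TestBodyPartition:
    def test_from_model_boundaries(self, model, partition):
        assert partition.semi_major_mm == pytest.approx(1.25)
        assert partition.semi_minor_mm == pytest.approx(0.5)
        # head occupies the front 25% of the body axis
        assert partition.head_boundary_mm == pytest.approx(1.25 - 0.25 * 2.5)
        assert partition.abdomen_boundary_mm == pytest.approx(-1.25 + 0.4 * 2.5)

    def test_region_lookup(self, partition):
        assert partition.region_of(1.0) == "head"
        assert partition.region_of(0.0) == "thorax"
        assert partition.region_of(-0.5) == "abdomen"

    def test_side_lookup_with_midline_band(self, partition):
        assert partition.side_of(0.3) == "left"
        assert partition.side_of(-0.3) == "right"
        assert partition.side_of(0.02) == "midline"

    def test_region_frequencies_match_area_fractions(self, partition, rng):
        # uniform points over the ellipse vs geometric area fractions
        n = 40_000
        pts = rng.uniform([-1.25, -0.5], [1.25, 0.5], size=(n, 2))
        inside = (pts[:, 0] / 1.25) ** 2 + (pts[:, 1] / 0.5) ** 2 <= 1.0
        pts = pts[inside]
        regions = np.array([partition.region_of(x) for x in pts[:, 0]])
        # area fraction of an ellipse slice x > c: via the circular segment
        def slice_frac(c):
            u = c / 1.25
            return (np.arccos(u) - u * np.sqrt(1 - u * u)) / np.pi
        f_head = slice_frac(partition.head_boundary_mm)
        f_abd = slice_frac(-partition.abdomen_boundary_mm)
        assert (regions == "head").mean() == pytest.approx(f_head, abs=0.01)
        assert (regions == "abdomen").mean() == pytest.approx(f_abd, abs=0.01)


class TestDetectHits:
    RADIUS = 0.215

    def test_patch_on_limb_tip_hits_that_limb(self, model, partition):
        pose = _pose(model=model)
        tip = pose[2][4]  # R2 tip, outside the body ellipse
        assert hd.detect_limb_hits(tip, self.RADIUS, pose, partition) == [4]

    def test_patch_on_centroid_hits_no_limb(self, model, partition):
        pose = _pose(model=model)
        assert hd.detect_limb_hits(pose[0], self.RADIUS, pose, partition) == []

    def test_limb_tip_inside_body_is_unreachable(self, model, partition):
        limbs = model.rest_offsets.copy()
        limbs[0] = [0.5, 0.1]  # retract L1 inside the ellipse
        pose = _pose(limbs=limbs, model=model)
        assert hd.detect_limb_hits(pose[2][0], self.RADIUS, pose, partition) == []

    def test_body_hit_regions(self, model, partition):
        pose = _pose(model=model)
        assert hd.detect_body_hit((1.0, 0.0), self.RADIUS, pose, partition) == \
            ("head", "midline")
        assert hd.detect_body_hit((0.0, 0.2), self.RADIUS, pose, partition) == \
            ("thorax", "left")
        assert hd.detect_body_hit((-0.8, -0.1), self.RADIUS, pose, partition) == \
            ("abdomen", "right")

    def test_patch_outside_ellipse_no_body_hit(self, model, partition):
        pose = _pose(model=model)
        assert hd.detect_body_hit((0.0, 0.6), self.RADIUS, pose, partition) is None

    def test_rotation_invariance(self, model, partition, rng):
        """Rotating the whole scene preserves target class and side."""
        base = _pose(model=model)
        for _ in range(50):
            patch = rng.uniform(-1.8, 1.8, 2)
            ev0 = hd.classify_patches([patch], self.RADIUS, base, partition,
                                      "f", 0, 0.0)
            th = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            rot_pose = (R @ base[0], base[1] + th, base[2] @ R.T)
            ev1 = hd.classify_patches([R @ patch], self.RADIUS, rot_pose,
                                      partition, "f", 0, 0.0)
            if ev0 is None:
                assert ev1 is None
            else:
                assert ev1.target_class == ev0.target_class
                assert ev1.side == ev0.side


class TestClassifyPatches:
    RADIUS = 0.215

    def test_single_forelimb_patch(self, model, partition):
        pose = _pose(model=model)
        ev = hd.classify_patches([pose[2][0]], self.RADIUS, pose, partition,
                                 "fly0", 10, 0.1)
        assert ev.target_class == "forelimb" and ev.side == "left"
        assert not ev.excluded and ev.limb_index == 0

    def test_two_limbs_excluded_multi_limb(self, model, partition):
        pose = _pose(model=model)
        ev = hd.classify_patches([pose[2][0], pose[2][1]], self.RADIUS, pose,
                                 partition, "fly0", 10, 0.1)
        assert ev.excluded and ev.exclusion_reason == "multi_limb"

    def test_limb_plus_body_excluded(self, model, partition):
        pose = _pose(model=model)
        ev = hd.classify_patches([pose[2][0], np.array([0.0, 0.0])],
                                 self.RADIUS, pose, partition, "fly0", 10, 0.1)
        assert ev.excluded and ev.exclusion_reason == "limb_and_body"

    def test_no_hit_returns_none(self, model, partition):
        pose = _pose(model=model)
        assert hd.classify_patches([np.array([10.0, 10.0])], self.RADIUS,
                                   pose, partition, "fly0", 10, 0.1) is None

    def test_equidistant_patch_between_two_limbs_is_multi_limb(self, partition):
        # two limbs symmetric about the patch, both within radius
        limbs = np.array([[1.6, 0.1], [1.6, -0.1], [0.0, 1.1],
                          [-0.8, 0.95], [0.0, -1.1], [-0.8, -0.95]])
        pose = _pose(limbs=limbs)
        ev = hd.classify_patches([np.array([1.6, 0.0])], self.RADIUS, pose,
                                 partition, "fly0", 0, 0.0)
        assert ev.excluded and ev.exclusion_reason == "multi_limb"

    def test_event_validation(self):
        with pytest.raises(ValueError, match="exclusion reason"):
            hd.ActivationEvent("f", 0, 0.0, (0, 0), "head", "left",
                               excluded=True)


class TestSymmetrize:
    def test_left_event_passes_through(self):
        tr = {"v_rot": np.array([1.0, -2.0]), "v_perp": np.array([0.5, 0.5])}
        side, out = hd.symmetrize("left", tr)
        np.testing.assert_array_equal(out["v_rot"], tr["v_rot"])

    def test_right_event_flips_signed_traces(self):
        tr = {"v_rot": np.array([1.0, -2.0]), "fold_vpar": np.array([0.9])}
        _, out = hd.symmetrize("right", tr)
        np.testing.assert_array_equal(out["v_rot"], [-1.0, 2.0])
        np.testing.assert_array_equal(out["fold_vpar"], [0.9])

    def test_midline_unchanged(self):
        tr = {"v_rot": np.array([1.0])}
        side, out = hd.symmetrize("midline", tr)
        assert side == "midline"
        np.testing.assert_array_equal(out["v_rot"], [1.0])

    def test_mirrored_population_mean_doubles(self, rng):
        """Equal-and-mirrored left/right effects cancel raw, add mirrored."""
        f = rng.normal(size=20)
        left = ("left", {"v_rot": f})
        right = ("right", {"v_rot": -f})
        raw_mean = (left[1]["v_rot"] + right[1]["v_rot"]) / 2
        sym = [hd.symmetrize(s, t)[1]["v_rot"] for s, t in (left, right)]
        sym_mean = (sym[0] + sym[1]) / 2
        np.testing.assert_allclose(raw_mean, 0.0, atol=1e-12)
        np.testing.assert_allclose(sym_mean, f, atol=1e-12)


# --------------------------------------------------------------- oracle

def rasterized_limb_hits(patch_center, radius, pose, partition,
                         step_mm=0.01) -> list:
    """Brute-force reference: sample each centroid->tip segment densely,
    discard samples inside the body ellipse, and test whether any surviving
    sample falls within the patch disc.  Independent of the exact geometric
    clipping and projection used by the implementation."""
    centroid, heading, limbs = pose
    patch_bf = hd.to_body_frame(patch_center, centroid, heading)
    hits = []
    for l in range(6):
        tip_bf = hd.to_body_frame(limbs[l], centroid, heading)
        length = np.hypot(*tip_bf)
        n = max(int(np.ceil(length / step_mm)), 2)
        s = np.linspace(0.0, 1.0, n + 1)
        pts = s[:, None] * tip_bf[None, :]
        outside = ((pts[:, 0] / partition.semi_major_mm) ** 2
                   + (pts[:, 1] / partition.semi_minor_mm) ** 2) > 1.0
        pts = pts[outside]
        if len(pts) and np.min(np.hypot(pts[:, 0] - patch_bf[0],
                                        pts[:, 1] - patch_bf[1])) <= radius:
            hits.append(l)
    return hits


def random_configurations(rng, n, model):
    """Random pose + patch configurations concentrated around the fly."""
    rest = model.rest_offsets
    for _ in range(n):
        centroid = rng.uniform(-2, 2, 2)
        heading = rng.uniform(0, 2 * np.pi)
        limbs_bf = rest + rng.normal(0, 0.35, (6, 2))
        ch, sh = np.cos(heading), np.sin(heading)
        R = np.array([[ch, -sh], [sh, ch]])
        limbs = limbs_bf @ R.T + centroid
        patch = centroid + rng.uniform(-2.2, 2.2, 2)
        yield (centroid, heading, limbs), patch


def test_limb_hit_oracle_equivalence(model, partition, rng):
    """Geometric disc-segment test vs dense-sampling brute force on random
    configurations; disagreements may occur only at boundary distances
    below the sampling resolution."""
    n = 2000
    agree = 0
    for pose, patch in random_configurations(rng, n, model):
        geo = hd.detect_limb_hits(patch, 0.215, pose, partition)
        ref = rasterized_limb_hits(patch, 0.215, pose, partition)
        if geo == ref:
            agree += 1
    assert agree / n >= 0.995


def test_exclusion_bookkeeping_is_complete(model, partition, rng):
    """Every classified pulse yields exactly one event per fly, excluded
    events carry reasons, and reason counts add up."""
    pose = _pose(model=model)
    events = []
    for _ in range(400):
        centers = rng.uniform(-2.0, 2.0, size=(rng.poisson(3), 2))
        ev = hd.classify_patches(centers, 0.215, pose, partition, "f", 0, 0.0)
        if ev is not None:
            events.append(ev)
    df = hd.events_to_frame(events)
    assert len(df) == len(events)
    n_excl = df["excluded"].sum()
    assert (df.loc[df["excluded"], "exclusion_reason"] != "none").all()
    assert (df.loc[~df["excluded"], "exclusion_reason"] == "none").all()
    assert df["exclusion_reason"].value_counts().sum() == len(events)
    assert 0 < n_excl < len(events)
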