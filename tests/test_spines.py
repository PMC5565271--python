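"""Tests for spine detection, extraction, splitting and declumping."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from spinetrace import spines as sp
from oracles import brute_distance_map, brute_watershed


def scene_with_protrusions(protrusions, h=48, w=64, bar_rows=(30, 38)):
    """Foreground = dendrite bar + rectangular protrusions on top of it.

    ``protrusions``: list of (col_lo, col_hi, height).
    Returns (fg, dendrite).
    """
    dendrite = np.zeros((h, w), bool)
    dendrite[bar_rows[0] : bar_rows[1], 2 : w - 2] = True
    fg = dendrite.copy()
    for c0, c1, ph in protrusions:
        fg[bar_rows[0] - ph : bar_rows[0], c0:c1] = True
    return fg, dendrite


class TestDistanceMap:
    def test_diagonal_neighbor_is_sqrt2(self):
        dendrite = np.zeros((8, 8), bool)
        dendrite[4, 4] = True
        fg = np.ones((8, 8), bool)
        dmap = sp.compute_distance_map(fg, dendrite)
        assert dmap[3, 3] == pytest.approx(math.sqrt(2))
        assert dmap[4, 4] == 0.0

    def test_matches_brute_force(self, rng):
        fg = rng.random((16, 16)) > 0.3
        dendrite = (rng.random((16, 16)) > 0.8) & fg
        if not dendrite.any():
            dendrite[8, 8] = fg[8, 8] = True
        dmap = sp.compute_distance_map(fg, dendrite)
        assert np.allclose(dmap, brute_distance_map(fg, dendrite))

    def test_empty_dendrite_rejected(self):
        with pytest.raises(ValueError):
            sp.compute_distance_map(np.ones((4, 4), bool), np.zeros((4, 4), bool))


class TestContourTracing:
    def test_rectangle_perimeter_ordered_and_closed(self):
        mask = np.zeros((12, 12), bool)
        mask[3:9, 2:10] = True
        contour = sp.trace_contour(mask)
        expected = {
            (r, c)
            for r in range(3, 9)
            for c in range(2, 10)
            if r in (3, 8) or c in (2, 9)
        }
        assert set(contour) == expected
        for p, q in zip(contour, contour[1:] + contour[:1]):
            assert max(abs(p[0] - q[0]), abs(p[1] - q[1])) == 1

    def test_single_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert sp.trace_contour(mask) == [(2, 2)]


class TestSeeds:
    def test_one_protrusion_one_seed_at_tip(self):
        fg, dendrite = scene_with_protrusions([(20, 26, 10)])
        dmap = sp.compute_distance_map(fg, dendrite)
        contour = sp.trace_contour(fg)
        seeds = sp.detect_spine_seeds(dmap, contour, 3.0)
        assert len(seeds) == 1
        idx, height = seeds[0]
        assert height == pytest.approx(10.0)
        assert contour[idx][0] == 20  # top row of the protrusion

    def test_two_protrusions_two_seeds(self):
        fg, dendrite = scene_with_protrusions([(10, 16, 9), (40, 46, 11)])
        dmap = sp.compute_distance_map(fg, dendrite)
        seeds = sp.detect_spine_seeds(dmap, sp.trace_contour(fg), 3.0)
        assert len(seeds) == 2

    def test_smooth_dendrite_has_no_seeds(self):
        fg, dendrite = scene_with_protrusions([])
        dmap = sp.compute_distance_map(fg, dendrite)
        assert sp.detect_spine_seeds(dmap, sp.trace_contour(fg), 3.0) == []

    def test_seed_detection_commutes_with_90_degree_rotation(self):
        fg, dendrite = scene_with_protrusions([(20, 26, 10)])
        dmap = sp.compute_distance_map(fg, dendrite)
        seeds = sp.detect_spine_seeds(dmap, sp.trace_contour(fg), 3.0)
        fg_r, dendrite_r = np.rot90(fg), np.rot90(dendrite)
        dmap_r = sp.compute_distance_map(fg_r, dendrite_r)
        seeds_r = sp.detect_spine_seeds(dmap_r, sp.trace_contour(fg_r), 3.0)
        assert len(seeds_r) == len(seeds) == 1
        h, w = fg.shape
        (i, v), (ir, vr) = seeds[0], seeds_r[0]
        assert vr == pytest.approx(v)
        r, c = sp.trace_contour(fg)[i]
        rr, cc = sp.trace_contour(fg_r)[ir]
        assert (rr, cc) == (w - 1 - c, r)


class TestExtraction:
    def test_rectangular_protrusion_recovered(self):
        fg, dendrite = scene_with_protrusions([(20, 23, 8)])  # 3 wide, 8 tall
        dmap = sp.compute_distance_map(fg, dendrite)
        contour = sp.trace_contour(fg)
        seeds = sp.detect_spine_seeds(dmap, contour, 3.0)
        seg = sp.extract_spine(seeds[0][0], contour, dmap, dendrite, fg.astype(float))
        assert seg is not None
        assert seg.height == pytest.approx(8.0, abs=1.0)
        assert seg.width == pytest.approx(3.0, abs=1.5)
        truth = np.zeros_like(fg)
        truth[22:30, 20:23] = True
        assert (seg.mask & truth).sum() / truth.sum() >= 0.8

    def test_shallow_seed_discarded_as_degenerate(self):
        fg, dendrite = scene_with_protrusions([(20, 21, 1)])
        dmap = sp.compute_distance_map(fg, dendrite)
        contour = sp.trace_contour(fg)
        # force the shallow tip in as a seed
        tip = max(range(len(contour)), key=lambda i: dmap[contour[i]])
        seg = sp.extract_spine(tip, contour, dmap, dendrite, fg.astype(float))
        assert seg is None or seg.area <= 4

    def test_semicircular_bump_area(self):
        h, w = 40, 60
        dendrite = np.zeros((h, w), bool)
        dendrite[25:33, 2:58] = True
        rr, cc = np.mgrid[0:h, 0:w]
        bump = ((rr - 25) ** 2 + (cc - 30) ** 2 <= 10**2) & (rr < 25)
        fg = dendrite | bump
        dmap = sp.compute_distance_map(fg, dendrite)
        contour = sp.trace_contour(fg)
        seeds = sp.detect_spine_seeds(dmap, contour, 3.0)
        seg = sp.extract_spine(seeds[0][0], contour, dmap, dendrite, fg.astype(float))
        half_disk = math.pi * 10**2 / 2
        assert seg.area == pytest.approx(half_disk, rel=0.2)


class TestSplitting:
    def _merged_pair(self, valley_height):
        fg, dendrite = scene_with_protrusions(
            [(16, 22, 8), (22, 28, valley_height), (28, 34, 8)]
        )
        dmap = sp.compute_distance_map(fg, dendrite)
        contour = sp.trace_contour(fg)
        seeds = sp.detect_spine_seeds(dmap, contour, 3.0)
        seg = sp.extract_spine(seeds[0][0], contour, dmap, dendrite, fg.astype(float))
        return seg, dmap, dendrite, fg

    def test_deep_valley_splits_in_two(self):
        seg, dmap, dendrite, fg = self._merged_pair(valley_height=3)
        pieces = sp.split_touching_spines(seg, dmap, dendrite, fg.astype(float))
        assert len(pieces) == 2
        assert not (pieces[0].mask & pieces[1].mask).any()

    def test_shallow_valley_not_split(self):
        seg, dmap, dendrite, fg = self._merged_pair(valley_height=6)
        pieces = sp.split_touching_spines(seg, dmap, dendrite, fg.astype(float))
        assert len(pieces) == 1

    def test_single_bump_unchanged(self):
        fg, dendrite = scene_with_protrusions([(20, 26, 8)])
        dmap = sp.compute_distance_map(fg, dendrite)
        contour = sp.trace_contour(fg)
        seeds = sp.detect_spine_seeds(dmap, contour, 3.0)
        seg = sp.extract_spine(seeds[0][0], contour, dmap, dendrite, fg.astype(float))
        pieces = sp.split_touching_spines(seg, dmap, dendrite, fg.astype(float))
        assert len(pieces) == 1


def _two_blob_segment():
    """One merged mask holding two Gaussian intensity blobs stacked
    perpendicular to a horizontal dendrite."""
    h, w = 48, 40
    dendrite = np.zeros((h, w), bool)
    dendrite[40:46, :] = True
    mask = np.zeros((h, w), bool)
    mask[8:40, 14:26] = True
    rr, cc = np.mgrid[0:h, 0:w]
    intensity = (
        np.exp(-(((rr - 14) ** 2 + (cc - 20) ** 2)) / 30.0)
        + np.exp(-(((rr - 32) ** 2 + (cc - 20) ** 2)) / 30.0)
    )
    dmap = ndi.distance_transform_edt(~dendrite)
    r, c = np.nonzero(mask)
    seg = sp.SpineSegment(
        spine_id=0,
        frame_index=0,
        mask=mask,
        seed=(8, 20),
        base_endpoints=((39.0, 14.0), (39.0, 25.0)),
        area=float(mask.sum()),
        height=float(dmap[mask].max()),
        width=11.0,
        mean_structure_intensity=1.0,
    )
    return seg, intensity, dendrite


class TestDeclumping:
    def test_two_stacked_blobs_split_between_centers(self):
        seg, intensity, dendrite = _two_blob_segment()
        children = sp.declump_watershed(seg, intensity, dendrite, prominence=0.05)
        assert len(children) == 2
        tops = sorted(c.centroid[0] for c in children)
        assert tops[0] < 23 < tops[1]
        union = children[0].mask | children[1].mask
        assert union.sum() <= seg.mask.sum()

    def test_uniform_blob_unchanged(self):
        seg, intensity, dendrite = _two_blob_segment()
        flat = np.ones_like(intensity)
        children = sp.declump_watershed(seg, flat, dendrite, prominence=0.05)
        assert len(children) == 1

    def test_matches_priority_flood_oracle(self):
        seg, intensity, dendrite = _two_blob_segment()
        children = sp.declump_watershed(seg, intensity, dendrite, prominence=0.05)
        # oracle: flood the same composite from the two blob maxima
        smooth = sp._masked_smooth(intensity, seg.mask)
        composite = np.full(seg.mask.shape, 127, np.uint8)
        composite[~seg.mask] = 0
        markers = np.zeros(seg.mask.shape, int)
        markers[14, 20] = 1
        markers[32, 20] = 2
        composite[markers > 0] = 255
        labels = brute_watershed(
            (255 - composite).astype(float), markers, seg.mask
        )
        for child in children:
            overlaps = [
                (labels == lab)[child.mask].mean() for lab in (1, 2)
            ]
            assert max(overlaps) >= 0.9  # each child is one oracle basin


class TestFullSegmentation:
    def test_spineless_dendrite_yields_nothing(self):
        fg, dendrite = scene_with_protrusions([])
        assert sp.segment_spines(fg, dendrite, fg.astype(float)) == []

    def test_masks_disjoint_and_off_dendrite(self, six_spine_run):
        _, _, result = six_spine_run
        for t, segments in enumerate(result.segments_per_frame):
            dendrite = result.dendrites[t].mask
            union = np.zeros_like(dendrite)
            for seg in segments:
                assert not (seg.mask & dendrite).any()
                assert not (seg.mask & union).any()
                union |= seg.mask
                assert seg.mask[seg.seed]

    def test_adjacent_spines_separated(self):
        fg, dendrite = scene_with_protrusions([(16, 21, 9), (23, 28, 9)])
        # 2 px gap at the base merges the contour arcs of both spines
        segments = sp.segment_spines(
            fg, dendrite, fg.astype(float), min_prominence=3.0, min_area=4
        )
        assert len(segments) == 2
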