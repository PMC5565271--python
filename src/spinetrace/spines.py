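"""Spine detection, segmentation, splitting and declumping.

Spines are protrusions of the foreground away from the dendrite shaft. The
distance of every foreground pixel to the nearest dendrite pixel peaks at
spine tips, so regional maxima of that distance along the foreground contour
seed the detections. Each seed claims the connected stretch of contour closer
to it than to the dendrite; the arc's endpoints are joined by a straight base
line -- the spine/dendrite boundary -- and the closed curve is filled.

Merged detections are repaired in two stages: spines touching at the base
are split where the contour's distance profile dips below half of a flanking
peak, and severely overlapping spines are declumped by a marker-controlled
watershed built from intensity extrema inside the merged mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import draw, segmentation

__all__ = [
    "SpineSegment",
    "compute_distance_map",
    "trace_contour",
    "seed_height_threshold",
    "detect_spine_seeds",
    "extract_spine",
    "split_touching_spines",
    "declump_watershed",
    "segment_spines",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
_FULL = np.ones((3, 3), bool)


@dataclass
class SpineSegment:
    """One spine in one frame."""

    spine_id: int
    frame_index: int
    mask: np.ndarray
    seed: tuple[int, int]
    base_endpoints: tuple[tuple[float, float], tuple[float, float]]
    area: float
    height: float
    width: float
    mean_structure_intensity: float
    contour_arc: list[tuple[int, int]] = field(default_factory=list, repr=False)

    @property
    def centroid(self) -> tuple[float, float]:
        r, c = np.nonzero(self.mask)
        return float(r.mean()), float(c.mean())


# ---------------------------------------------------------------------------
# distance map and contour


def compute_distance_map(fg: np.ndarray, dendrite: np.ndarray) -> np.ndarray:
    """Euclidean distance of each foreground pixel to the nearest dendrite
    pixel; zero on the dendrite and outside the foreground."""
    fg = np.asarray(fg, bool)
    dendrite = np.asarray(dendrite, bool)
    if not dendrite.any():
        raise ValueError("dendrite mask is empty")
    dmap = ndi.distance_transform_edt(~dendrite)
    dmap[~fg] = 0.0
    return dmap


_CW = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def trace_contour(mask: np.ndarray) -> list[tuple[int, int]]:
    """Ordered outer boundary of a connected mask (Moore-neighbor tracing).

    Returns boundary pixels in traversal order; pixels on 1 px wide
    protrusions appear once per side visited. Single-pixel masks return one
    point.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return []
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    start = (int(rows.min()), int(cols[rows == rows.min()].min()))
    contour = [start]
    backtrack = (start[0], start[1] - 1)
    p = start
    init_state = None
    while True:
        i0 = _CW.index((backtrack[0] - p[0], backtrack[1] - p[1]))
        nxt = None
        for k in range(1, 9):
            idx = (i0 + k) % 8
            q = (p[0] + _CW[idx][0], p[1] + _CW[idx][1])
            if padded[q]:
                nxt = q
                backtrack = (p[0] + _CW[(idx - 1) % 8][0], p[1] + _CW[(idx - 1) % 8][1])
                break
        if nxt is None:  # isolated pixel
            break
        p = nxt
        state = (p, backtrack)
        if init_state is None:
            init_state = state
        elif state == init_state:
            break
        contour.append(p)
        if len(contour) > 8 * padded.size:  # safety net
            break
    if len(contour) > 1 and contour[-1] == start:
        contour.pop()
    return [(r - 1, c - 1) for r, c in contour]


# ---------------------------------------------------------------------------
# 1D profile extrema with plateau merging


def _runs(vals: np.ndarray) -> list[tuple[int, int, float]]:
    """Run-length encode (start, length, value)."""
    runs = []
    start = 0
    for i in range(1, len(vals) + 1):
        if i == len(vals) or vals[i] != vals[start]:
            runs.append((start, i - start, float(vals[start])))
            start = i
    return runs


def _circular_regional_maxima(vals: np.ndarray) -> list[int]:
    """Indices (plateau midpoints) of regional maxima of a circular profile."""
    n = len(vals)
    if n == 0 or np.ptp(vals) == 0:
        return []
    # rotate so position 0 is at a value change, keeping plateaus contiguous
    change = int(np.nonzero(vals != vals[0])[0][0])
    rot = np.roll(vals, -change)
    runs = _runs(rot)
    out = []
    m = len(runs)
    for i, (start, length, value) in enumerate(runs):
        prev_v = runs[(i - 1) % m][2]
        next_v = runs[(i + 1) % m][2]
        if value > prev_v and value > next_v:
            mid = start + (length - 1) // 2
            out.append((mid + change) % n)
    return sorted(out)


def _open_extrema(vals: np.ndarray):
    """Interior regional maxima and minima (plateau midpoints) of an open
    profile. Returns (max_indices, min_indices)."""
    runs = _runs(np.asarray(vals, float))
    maxima, minima = [], []
    for i in range(1, len(runs) - 1):
        start, length, value = runs[i]
        prev_v, next_v = runs[i - 1][2], runs[i + 1][2]
        mid = start + (length - 1) // 2
        if value > prev_v and value > next_v:
            maxima.append(mid)
        elif value < prev_v and value < next_v:
            minima.append(mid)
    return maxima, minima


# ---------------------------------------------------------------------------
# detection and extraction


def seed_height_threshold(
    profile: np.ndarray, min_spine_height: float = 3.0, min_prominence: float = 5.0
) -> float:
    """Minimum distance-to-dendrite for a contour pixel to seed a spine.

    Most of the contour runs along the shaft at the halo clearance the
    foreground threshold leaves around the dendrite, so the profile median
    estimates that baseline; a seed must rise ``min_prominence`` above it
    (and never below the absolute ``min_spine_height`` floor).
    """
    baseline = float(np.median(profile)) if len(profile) else 0.0
    return max(min_spine_height, baseline + min_prominence)


def detect_spine_seeds(
    dmap: np.ndarray,
    contour: list[tuple[int, int]],
    min_spine_height: float = 3.0,
    min_prominence: float = 5.0,
) -> list[tuple[int, int]]:
    """Spine seeds: regional maxima of the distance-to-dendrite profile along
    the ordered contour, rising above the shaft-clearance baseline (see
    :func:`seed_height_threshold`).

    Returns ``(contour_index, value)`` pairs sorted by descending height.
    """
    if not contour:
        return []
    profile = np.array([dmap[p] for p in contour])
    thresh = seed_height_threshold(profile, min_spine_height, min_prominence)
    idx = _circular_regional_maxima(profile)
    seeds = [(i, profile[i]) for i in idx if profile[i] >= thresh]
    seeds.sort(key=lambda t: -t[1])
    return [(i, float(v)) for i, v in seeds]


def _arc_around(
    contour: list[tuple[int, int]],
    seed_idx: int,
    dmap: np.ndarray,
    profile: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Contiguous contour stretch around ``seed_idx`` belonging to the spine.

    The spine's contour runs from where it leaves the dendrite, over the
    tip, to where it rejoins: walking from the seed in both directions, the
    arc ends once the distance-to-dendrite profile descends to the contour's
    dendrite-adjacent baseline (median clearance plus one pixel, at least
    1.5 px -- the median is dominated by shaft contour, so it absorbs the
    halo the foreground threshold leaves around the dendrite). Pixels closer
    to the dendrite than to the seed beyond three seed heights are cut off
    as a safety radius. Two spines merged at the base stay on one arc, which
    is what the half-rule splitting operates on."""
    n = len(contour)
    seed = np.asarray(contour[seed_idx], float)
    if profile is None:
        profile = np.array([dmap[p] for p in contour])
    stop_level = max(1.5, 1.0 + float(np.median(profile)))
    radius_cap = 3.0 * float(dmap[contour[seed_idx]])

    def ok(i: int) -> bool:
        p = contour[i % n]
        return profile[i % n] > stop_level and math.dist(p, seed) < radius_cap

    lo = seed_idx
    while lo > seed_idx - n + 1 and ok(lo - 1):
        lo -= 1
    hi = seed_idx
    while hi < lo + n - 1 and ok(hi + 1):
        hi += 1
    # include the dendrite-adjacent pixel on each side as the base corner
    if hi - lo < n - 1:
        lo -= 1
        hi = min(hi + 1, lo + n - 1)
    return [contour[i % n] for i in range(lo, hi + 1)]


def _segment_from_mask(
    mask: np.ndarray,
    dmap: np.ndarray,
    intensity: np.ndarray,
    frame_index: int,
    spine_id: int,
    contour_arc=None,
    base_endpoints=None,
) -> SpineSegment | None:
    """Assemble a SpineSegment from a mask, measuring morphology scalars."""
    if not mask.any():
        return None
    r, c = np.nonzero(mask)
    inside = dmap[r, c]
    tip = int(np.argmax(inside))
    seed = (int(r[tip]), int(c[tip]))
    height = float(inside.max())
    if base_endpoints is None:
        # base = widest pair among pixels nearest the dendrite
        near = inside <= max(inside.min() + 1.5, 2.5)
        pts = np.column_stack([r[near], c[near]]).astype(float)
        if len(pts) >= 2:
            d2 = ((pts[:, None] - pts[None]) ** 2).sum(-1)
            i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
            base_endpoints = (tuple(pts[i]), tuple(pts[j]))
        else:
            base_endpoints = (tuple(pts[0]), tuple(pts[0]))
    width = float(math.dist(*base_endpoints))
    return SpineSegment(
        spine_id=spine_id,
        frame_index=frame_index,
        mask=mask,
        seed=seed,
        base_endpoints=base_endpoints,
        area=float(mask.sum()),
        height=max(height, 1.0),
        width=max(width, 1.0),
        mean_structure_intensity=float(intensity[mask].mean()),
        contour_arc=list(contour_arc) if contour_arc else [],
    )


def extract_spine(
    seed_idx: int,
    contour: list[tuple[int, int]],
    dmap: np.ndarray,
    dendrite: np.ndarray,
    intensity: np.ndarray,
    frame_index: int = 0,
    spine_id: int = 0,
) -> SpineSegment | None:
    """Segment the spine owning the contour seed at ``seed_idx``.

    The spine's contour arc is closed with a straight base line between its
    endpoints (the spine/dendrite boundary), filled, and clipped away from
    the dendrite. Arcs shorter than 3 pixels are degenerate and discarded.
    """
    arc = _arc_around(contour, seed_idx, dmap)
    if len(arc) < 3:
        return None
    canvas = np.zeros(dmap.shape, bool)
    rr, cc = zip(*arc)
    canvas[list(rr), list(cc)] = True
    e0, e1 = arc[0], arc[-1]
    lr, lc = draw.line(e0[0], e0[1], e1[0], e1[1])
    canvas[lr, lc] = True
    filled = ndi.binary_fill_holes(canvas, structure=_CROSS)
    mask = filled & ~np.asarray(dendrite, bool)
    labels, n = ndi.label(mask, structure=_FULL)
    if n > 1:
        seed_px = contour[seed_idx]
        lab = labels[seed_px]
        if lab == 0:
            sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
            lab = 1 + int(np.argmax(sizes))
        mask = labels == lab
    if mask.sum() < 3:
        return None
    return _segment_from_mask(
        mask,
        dmap,
        intensity,
        frame_index,
        spine_id,
        contour_arc=arc,
        base_endpoints=(tuple(map(float, e0)), tuple(map(float, e1))),
    )


# ---------------------------------------------------------------------------
# splitting (half-rule) and declumping (marker watershed)


def _nearest_dendrite_px(p, dendrite_idx) -> tuple[int, int]:
    r, c = p
    return int(dendrite_idx[0][r, c]), int(dendrite_idx[1][r, c])


def split_touching_spines(
    segment: SpineSegment,
    dmap: np.ndarray,
    dendrite: np.ndarray,
    intensity: np.ndarray,
    dendrite_idx=None,
) -> list[SpineSegment]:
    """Split spines merged at the base using the half-rule.

    The distance-to-dendrite profile along the spine's contour arc is traced;
    an interior regional minimum flanked by two maxima triggers a split when
    it is below half of either flanking maximum. The dividing line runs from
    the minimum to its nearest dendrite pixel and is excluded from both
    children. Applied recursively.
    """
    if len(segment.contour_arc) < 5:
        return [segment]
    if dendrite_idx is None:
        _, dendrite_idx = ndi.distance_transform_edt(
            ~np.asarray(dendrite, bool), return_indices=True
        )
    profile = np.array([dmap[p] for p in segment.contour_arc])
    maxima, minima = _open_extrema(profile)
    split_at = None
    for m in sorted(minima, key=lambda i: profile[i]):
        left = [i for i in maxima if i < m]
        right = [i for i in maxima if i > m]
        if not left or not right:
            continue
        lmax = profile[left[-1]]
        rmax = profile[right[0]]
        if profile[m] < 0.5 * lmax or profile[m] < 0.5 * rmax:
            split_at = m
            break
    if split_at is None:
        return [segment]
    p = segment.contour_arc[split_at]
    q = _nearest_dendrite_px(p, dendrite_idx)
    lr, lc = draw.line(p[0], p[1], q[0], q[1])
    divider = np.zeros_like(segment.mask)
    divider[lr, lc] = True
    divider = ndi.binary_dilation(divider, structure=_CROSS)
    remaining = segment.mask & ~divider
    labels, n = ndi.label(remaining, structure=_FULL)
    if n < 2:
        return [segment]
    arc_sets = [set(), set()]
    children = []
    order = np.argsort(
        ndi.sum_labels(remaining, labels, index=np.arange(1, n + 1))
    )[::-1][:2]
    for child_i, lab in enumerate(order + 1):
        child_mask = labels == lab
        sub_arc = [pt for pt in segment.contour_arc if child_mask[pt]]
        child = _segment_from_mask(
            child_mask,
            dmap,
            intensity,
            segment.frame_index,
            segment.spine_id,
            contour_arc=sub_arc,
        )
        if child is not None:
            children.append(child)
    if len(children) < 2:
        return [segment]
    out = []
    for child in children:
        out.extend(
            split_touching_spines(child, dmap, dendrite, intensity, dendrite_idx)
        )
    return out


def _masked_smooth(intensity: np.ndarray, mask: np.ndarray, sigma: float = 1.0):
    """Gaussian smoothing restricted to ``mask`` (normalized convolution)."""
    m = mask.astype(float)
    num = ndi.gaussian_filter(intensity * m, sigma)
    den = ndi.gaussian_filter(m, sigma)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 1e-9)
    return out


def _local_tangent(dendrite: np.ndarray, point, radius: int = 20) -> np.ndarray:
    """Dominant direction of dendrite pixels near ``point`` (PCA)."""
    r0 = max(int(point[0]) - radius, 0)
    c0 = max(int(point[1]) - radius, 0)
    sub = dendrite[r0 : int(point[0]) + radius + 1, c0 : int(point[1]) + radius + 1]
    r, c = np.nonzero(sub)
    if len(r) < 2:
        return np.array([0.0, 1.0])
    pts = np.column_stack([r, c]).astype(float)
    pts -= pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    return vt[0]


def declump_watershed(
    segment: SpineSegment,
    intensity: np.ndarray,
    dendrite: np.ndarray,
    dmap: np.ndarray | None = None,
    tangent: np.ndarray | None = None,
    parallel_tol: float = 30.0,
    prominence: float = 0.1,
) -> list[SpineSegment]:
    """Declump severely overlapping spines with a marker-controlled watershed.

    Intensity regional maxima and minima inside the mask act as markers;
    extrema shallower than ``prominence`` (intensity fraction) are ignored so
    a single smooth bump is never cut on interpolation ripple.
    Maxima pairs whose axis is not parallel to the local dendrite direction
    (angle > ``parallel_tol`` degrees) are connected by a straight line that
    must avoid minima regions, merging markers that belong to one spine;
    minima pairs are connected likewise avoiding maxima. A composite image
    (background/minima 0, maxima 255, rest 127) is inverted and flooded from
    the maxima; the watershed line splits the mask.
    """
    mask = segment.mask
    if not mask.any():
        return [segment]
    smooth = _masked_smooth(intensity, mask)
    lowest = smooth[mask].min()
    highest = smooth[mask].max()
    if highest - lowest <= prominence:  # essentially flat: one plateau
        return [segment]
    from skimage.morphology import h_maxima, h_minima, local_maxima, local_minima

    inside = np.where(mask, smooth, lowest - 1.0)
    inside_min = np.where(mask, smooth, highest + 1.0)
    if prominence > 0:
        maxima = h_maxima(inside, prominence).astype(bool) & mask
        minima = h_minima(inside_min, prominence).astype(bool) & mask
    else:
        maxima = local_maxima(inside).astype(bool) & mask
        minima = local_minima(inside_min).astype(bool) & mask
    max_labels, n_max = ndi.label(maxima, structure=_FULL)
    if n_max < 2:
        return [segment]
    if tangent is None:
        base_mid = np.mean(np.asarray(segment.base_endpoints), axis=0)
        tangent = _local_tangent(np.asarray(dendrite, bool), base_mid)
    centroids = ndi.center_of_mass(maxima, max_labels, index=np.arange(1, n_max + 1))
    tangent = np.asarray(tangent, float)
    tangent /= max(np.linalg.norm(tangent), 1e-12)

    def connect(src: np.ndarray, avoid: np.ndarray, pairs, check_angle: bool,
                bright: bool):
        out = src.copy()
        for (i, pi), (j, pj) in pairs:
            axis = np.asarray(pj, float) - np.asarray(pi, float)
            norm = np.linalg.norm(axis)
            if norm < 1e-9:
                continue
            if check_angle:
                cosang = abs(float(axis @ tangent)) / norm
                ang = math.degrees(math.acos(np.clip(cosang, 0, 1)))
                if ang <= parallel_tol:
                    continue  # pair parallel to the dendrite: separate spines
            lr, lc = draw.line(
                int(round(pi[0])), int(round(pi[1])), int(round(pj[0])), int(round(pj[1]))
            )
            if not (mask[lr, lc].all() and not avoid[lr, lc].any()):
                continue
            # the line must stay on its own intensity level: a ridge line
            # between maxima may not dip into a valley, a valley line between
            # minima may not climb over a ridge
            ends = (smooth[lr[0], lc[0]], smooth[lr[-1], lc[-1]])
            line_vals = smooth[lr, lc]
            if bright and line_vals.min() < min(ends) - prominence:
                continue
            if not bright and line_vals.max() > max(ends) + prominence:
                continue
            out[lr, lc] = True
        return out

    max_pairs = [
        ((i, centroids[i]), (j, centroids[j]))
        for i in range(n_max)
        for j in range(i + 1, n_max)
    ]
    connected_max = connect(maxima, minima, max_pairs, check_angle=True, bright=True)
    min_labels, n_min = ndi.label(minima, structure=_FULL)
    if n_min >= 2:
        min_centroids = ndi.center_of_mass(
            minima, min_labels, index=np.arange(1, n_min + 1)
        )
        min_pairs = [
            ((i, min_centroids[i]), (j, min_centroids[j]))
            for i in range(n_min)
            for j in range(i + 1, n_min)
        ]
        connected_min = connect(
            minima, connected_max, min_pairs, check_angle=False, bright=False
        )
    else:
        connected_min = minima
    composite = np.full(mask.shape, 127, dtype=np.uint8)
    composite[~mask] = 0
    composite[connected_min & mask] = 0
    composite[connected_max & mask] = 255
    markers, n_markers = ndi.label(composite == 255, structure=_FULL)
    if n_markers < 2:
        return [segment]
    ws = segmentation.watershed(
        255 - composite.astype(np.int32), markers=markers, mask=mask, watershed_line=True
    )
    labels_present = np.unique(ws[ws > 0])
    if len(labels_present) < 2:
        return [segment]
    if dmap is None:
        dmap = ndi.distance_transform_edt(~np.asarray(dendrite, bool))
    children = []
    for lab in labels_present:
        child_mask = ws == lab
        comp_labels, n_comp = ndi.label(child_mask, structure=_FULL)
        if n_comp > 1:
            sizes = ndi.sum_labels(child_mask, comp_labels, index=np.arange(1, n_comp + 1))
            child_mask = comp_labels == (1 + int(np.argmax(sizes)))
        if child_mask.sum() < 3:
            continue
        sub_arc = [pt for pt in segment.contour_arc if child_mask[pt]]
        child = _segment_from_mask(
            child_mask,
            dmap,
            intensity,
            segment.frame_index,
            segment.spine_id,
            contour_arc=sub_arc,
        )
        if child is not None:
            children.append(child)
    return children if len(children) >= 2 else [segment]


# ---------------------------------------------------------------------------
# per-frame driver


def segment_spines(
    fg: np.ndarray,
    dendrite: np.ndarray,
    structure_frame: np.ndarray,
    frame_index: int = 0,
    min_spine_height: float = 3.0,
    min_prominence: float = 5.0,
    min_area: int = 16,
    declump: bool = True,
    parallel_tol: float = 30.0,
    prominence: float = 0.1,
    tangent_fn=None,
) -> list[SpineSegment]:
    """Full per-frame spine segmentation.

    Seed detection, extraction, base splitting and watershed declumping, in
    that order. Returned masks are pairwise disjoint, disjoint from the
    dendrite, and each satisfies ``height >= min_spine_height``.
    """
    fg = np.asarray(fg, bool)
    dendrite = np.asarray(dendrite, bool)
    if not fg.any() or not dendrite.any():
        return []
    labels, n = ndi.label(fg, structure=_FULL)
    if n > 1:
        sizes = ndi.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    dmap = compute_distance_map(fg, dendrite)
    contour = trace_contour(fg)
    profile = np.array([dmap[p] for p in contour]) if contour else np.zeros(0)
    height_floor = seed_height_threshold(profile, min_spine_height, min_prominence)
    seeds = detect_spine_seeds(dmap, contour, min_spine_height, min_prominence)
    _, dendrite_idx = ndi.distance_transform_edt(~dendrite, return_indices=True)
    claimed = np.zeros_like(fg)
    segments: list[SpineSegment] = []
    next_id = 0
    for seed_idx, _height in seeds:
        if claimed[contour[seed_idx]]:
            continue
        seg = extract_spine(
            seed_idx, contour, dmap, dendrite, structure_frame, frame_index, next_id
        )
        if seg is None:
            continue
        seg_mask = seg.mask & ~claimed
        if seg_mask.sum() < min_area:
            continue
        if seg_mask.sum() != seg.mask.sum():
            seg = _segment_from_mask(
                seg_mask,
                dmap,
                structure_frame,
                frame_index,
                next_id,
                contour_arc=[p for p in seg.contour_arc if seg_mask[p]],
            )
            if seg is None:
                continue
        claimed |= seg.mask
        pieces = split_touching_spines(
            seg, dmap, dendrite, structure_frame, dendrite_idx
        )
        if declump:
            declumped = []
            for piece in pieces:
                tangent = tangent_fn(piece) if tangent_fn is not None else None
                declumped.extend(
                    declump_watershed(
                        piece,
                        structure_frame,
                        dendrite,
                        dmap=dmap,
                        tangent=tangent,
                        parallel_tol=parallel_tol,
                        prominence=prominence,
                    )
                )
            pieces = declumped
        for piece in pieces:
            if piece.height >= height_floor and piece.area >= min_area:
                segments.append(replace(piece, spine_id=next_id))
                next_id += 1
    return segments
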