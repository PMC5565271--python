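"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (per-pixel loops, exhaustive search)
and shares no code with the package.
"""

from __future__ import annotations

import heapq
import math

import numpy as np


def brute_opening(img: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening by a disk: erosion then dilation, per-pixel loops."""
    offsets = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    h, w = img.shape

    def erode(a):
        out = np.empty_like(a)
        for r in range(h):
            for c in range(w):
                vals = [
                    a[r + dr, c + dc]
                    for dr, dc in offsets
                    if 0 <= r + dr < h and 0 <= c + dc < w
                ]
                out[r, c] = min(vals)
        return out

    def dilate(a):
        out = np.empty_like(a)
        for r in range(h):
            for c in range(w):
                vals = [
                    a[r + dr, c + dc]
                    for dr, dc in offsets
                    if 0 <= r + dr < h and 0 <= c + dc < w
                ]
                out[r, c] = max(vals)
        return out

    return dilate(erode(img))


def brute_median3(img: np.ndarray) -> np.ndarray:
    """3x3 median with edge replication."""
    h, w = img.shape
    out = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            vals = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr = min(max(r + dr, 0), h - 1)
                    cc = min(max(c + dc, 0), w - 1)
                    vals.append(img[rr, cc])
            out[r, c] = sorted(vals)[4]
    return out


def brute_otsu(img: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold by exhaustive between-class-variance maximization."""
    hist, edges = np.histogram(img.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = hist.sum()
    best_var, best_t = -1.0, centers[0]
    for k in range(1, nbins):
        w0 = hist[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:k] * centers[:k]).sum() / w0
        mu1 = (hist[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[k - 1]
    return float(best_t)


def brute_distance_map(fg: np.ndarray, dendrite: np.ndarray) -> np.ndarray:
    """Min-over-all-dendrite-pixels Euclidean distance, zero outside fg."""
    dpix = list(zip(*np.nonzero(dendrite)))
    out = np.zeros(fg.shape, float)
    for r in range(fg.shape[0]):
        for c in range(fg.shape[1]):
            if fg[r, c] and not dendrite[r, c]:
                out[r, c] = min(math.dist((r, c), p) for p in dpix)
    return out


def brute_uniform_lbp(img: np.ndarray) -> np.ndarray:
    """59-bin uniform LBP histogram; independent pattern enumeration."""
    neighbors = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]

    def transitions(bits):
        return sum(bits[i] != bits[(i + 1) % 8] for i in range(8))

    uniform_patterns = sorted(
        p
        for p in range(256)
        if transitions([(p >> i) & 1 for i in range(8)]) <= 2
    )
    index = {p: i for i, p in enumerate(uniform_patterns)}
    hist = np.zeros(59)
    h, w = img.shape
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            code = 0
            for bit, (dr, dc) in enumerate(neighbors):
                if img[r + dr, c + dc] >= img[r, c]:
                    code |= 1 << bit
            hist[index.get(code, 58)] += 1
    return hist


def brute_directional_fill(mask: np.ndarray, starts, offsets) -> np.ndarray:
    """Set-based BFS reachability with a restricted step set."""
    h, w = mask.shape
    seen = {s for s in starts if mask[s]}
    frontier = list(seen)
    while frontier:
        nxt = []
        for r, c in frontier:
            for dr, dc in offsets:
                q = (r + dr, c + dc)
                if 0 <= q[0] < h and 0 <= q[1] < w and mask[q] and q not in seen:
                    seen.add(q)
                    nxt.append(q)
        frontier = nxt
    out = np.zeros_like(mask)
    for p in seen:
        out[p] = True
    return out


def brute_watershed(surface: np.ndarray, markers: np.ndarray, mask: np.ndarray):
    """Priority-flood watershed with watershed lines (label 0).

    Floods ``surface`` from the labelled ``markers`` inside ``mask``; pixels
    reached by two different labels become boundary (0).
    """
    h, w = surface.shape
    labels = np.where(mask, -1, -2)  # -1 unvisited, -2 outside
    heap = []
    counter = 0
    for r, c in zip(*np.nonzero(markers)):
        labels[r, c] = markers[r, c]
        heapq.heappush(heap, (surface[r, c], counter, r, c))
        counter += 1
    while heap:
        _, _, r, c = heapq.heappop(heap)
        lab = labels[r, c]
        if lab <= 0:
            continue
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w):
                    continue
                if labels[rr, cc] == -1:
                    labels[rr, cc] = lab
                    heapq.heappush(heap, (surface[rr, cc], counter, rr, cc))
                    counter += 1
                elif labels[rr, cc] > 0 and labels[rr, cc] != lab:
                    pass  # already claimed by another basin
    labels[labels < 0] = 0
    return labels
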