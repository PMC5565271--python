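"""Ground-truthed synthetic two-channel videos of spiny dendrites.

The generator emulates the kind of data produced by wide-field fluorescence
time-lapse imaging of cultured hippocampal neurons: a curved dendrite bearing
spines of the three common morphological classes (stubby, thin, mushroom),
imaged in a structural channel (cell fill) and a protein channel whose spine
intensity follows a prescribed time course. Frames include background haze,
multiplicative photobleaching and additive Gaussian shot-noise surrogate;
spines sway about their base from frame to frame.

Geometry is defined at the native camera resolution (128x128 by default) in
pixel units. All randomness flows from ``SceneSpec.rng_seed``; identical
specs render bit-identical videos.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate

from .video import FluoVideo, write_video

__all__ = [
    "SpineSpec",
    "SceneSpec",
    "GroundTruth",
    "render_scene",
    "write_ground_truth",
    "ramp",
    "constant",
    "example_scene",
    "generate_track_dataset",
]

SHAPE_CLASSES = ("stubby", "thin", "mushroom")

#: Structural-channel amplitude of in-focus structures (fraction of full scale).
SIGNAL_LEVEL = 0.75
#: Protein-channel level inside the dendrite shaft.
DENDRITE_PROTEIN_LEVEL = 0.30


def constant(level: float = 0.5) -> Callable[[float], float]:
    """Protein density profile that stays at ``level`` for the whole video."""
    return lambda tau: level


def ramp(start: float, stop: float) -> Callable[[float], float]:
    """Linear protein density profile from ``start`` (tau=0) to ``stop`` (tau=1)."""
    return lambda tau: start + (stop - start) * tau


@dataclass
class SpineSpec:
    """Geometry and protein dynamics of one spine.

    ``base_arclength`` is the fractional position (0..1) of the spine base
    along the dendrite curve; the base always lies on the curve. Lengths are
    native-resolution pixels. ``sway_amplitude`` is the peak rotation of the
    spine about its base, in degrees; the sway follows one sine period over
    the video. ``side`` selects which side of the dendrite the spine grows
    from (+1 or -1).
    """

    base_arclength: float
    shape_class: str
    neck_length: float
    neck_width: float
    head_diameter: float
    sway_amplitude: float = 6.0
    side: int = 1
    protein_density_profile: Callable[[float], float] = field(default_factory=constant)

    def validate(self) -> None:
        if self.shape_class not in SHAPE_CLASSES:
            raise ValueError(f"unknown shape class {self.shape_class!r}")
        if not 0.0 <= self.base_arclength <= 1.0:
            raise ValueError(
                f"spine base at arclength {self.base_arclength} is off the "
                "dendrite curve (must be in [0, 1])"
            )
        if self.shape_class == "mushroom" and self.head_diameter <= self.neck_width:
            raise ValueError("a mushroom spine needs head_diameter > neck_width")
        if self.shape_class == "stubby" and self.neck_length > 1.5:
            raise ValueError("a stubby spine has essentially no neck")
        if self.shape_class == "thin" and self.neck_length <= self.head_diameter:
            raise ValueError("a thin spine needs neck_length > head_diameter")


@dataclass
class SceneSpec:
    """Complete description of a synthetic recording."""

    image_size: tuple[int, int] = (128, 128)
    n_frames: int = 20
    frame_interval: float = 180.0
    dendrite_control_points: Sequence[tuple[float, float]] | None = None
    dendrite_width: float = 7.0
    spines: Sequence[SpineSpec] = field(default_factory=list)
    background_level: float = 0.05
    noise_sigma: float = 0.02
    bleach_rate: float = 0.98
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.dendrite_width < 3:
            raise ValueError("dendrite_width must be at least 3 px")
        for spine in self.spines:
            spine.validate()

    def control_points(self) -> np.ndarray:
        if self.dendrite_control_points is not None:
            return np.asarray(self.dendrite_control_points, dtype=float)
        h, w = self.image_size
        # default: gentle S-curve spanning the field of view
        cols = np.linspace(0.1 * w, 0.9 * w, 5)
        rows = h / 2 + 0.12 * h * np.sin(np.linspace(0, 2 * np.pi, 5))
        return np.column_stack([rows, cols])


@dataclass
class GroundTruth:
    """Noise-free reference data accompanying a rendered scene.

    ``dendrite_masks`` is (T, H, W); ``spine_masks`` is (T, S, H, W) with
    spines pairwise disjoint and disjoint from the dendrite. ``density`` is
    the (S, T) noise-free protein integrated density of each spine.
    """

    dendrite_masks: np.ndarray
    spine_masks: np.ndarray
    labels: list[str]
    density: np.ndarray

    @property
    def n_spines(self) -> int:
        return self.spine_masks.shape[1]


# ---------------------------------------------------------------------------
# curve and rasterization helpers


def _dense_curve(points: np.ndarray, step: float = 0.5):
    """Resample an interpolating spline through ``points`` at ~step px spacing.

    Returns (samples (M,2), unit tangents (M,2), total arclength).
    """
    if len(points) < 2:
        raise ValueError("need at least two control points")
    k = min(3, len(points) - 1)
    tck, _ = interpolate.splprep(points.T, s=0, k=k)
    u = np.linspace(0, 1, 2048)
    xy = np.column_stack(interpolate.splev(u, tck))
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    n = max(int(total / step), 2)
    target = np.linspace(0, total, n)
    rows = np.interp(target, arclen, xy[:, 0])
    cols = np.interp(target, arclen, xy[:, 1])
    samples = np.column_stack([rows, cols])
    tangents = np.gradient(samples, axis=0)
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1, keepdims=True), 1e-12)
    return samples, tangents, total


def _dist_to_points(shape: tuple[int, int], pts: np.ndarray) -> np.ndarray:
    """Distance from every pixel center to the nearest of ``pts`` (rows, cols)."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    grid = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    # chunk to bound memory
    out = np.full(h * w, np.inf)
    for i in range(0, len(pts), 512):
        chunk = pts[i : i + 512]
        d = np.sqrt(
            (grid[:, None, 0] - chunk[None, :, 0]) ** 2
            + (grid[:, None, 1] - chunk[None, :, 1]) ** 2
        ).min(axis=1)
        np.minimum(out, d, out=out)
    return out.reshape(h, w)


def _capsule_mask(shape, p0, p1, radius) -> np.ndarray:
    """Pixels within ``radius`` of segment p0-p1."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    p = np.stack([rr, cc], axis=-1).astype(float)
    d = np.asarray(p1, float) - np.asarray(p0, float)
    L2 = float(d @ d)
    if L2 < 1e-12:
        dist = np.linalg.norm(p - p0, axis=-1)
    else:
        t = np.clip(((p - p0) @ d) / L2, 0.0, 1.0)
        proj = np.asarray(p0, float) + t[..., None] * d
        dist = np.linalg.norm(p - proj, axis=-1)
    return dist <= radius


def _disk_mask(shape, center, radius) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _rotate(v: np.ndarray, deg: float) -> np.ndarray:
    a = math.radians(deg)
    r, c = v
    return np.array([r * math.cos(a) - c * math.sin(a), r * math.sin(a) + c * math.cos(a)])


def _spine_mask(shape, base, direction, spine: SpineSpec, half_width: float) -> np.ndarray:
    """Rasterize one spine growing from ``base`` along unit ``direction``."""
    base = np.asarray(base, float)
    u = np.asarray(direction, float)
    neck_end = base + u * (half_width + spine.neck_length)
    mask = _capsule_mask(shape, base, neck_end, spine.neck_width / 2.0)
    head_center = neck_end + u * (0.4 * spine.head_diameter)
    mask |= _disk_mask(shape, head_center, spine.head_diameter / 2.0)
    return mask


# ---------------------------------------------------------------------------
# rendering


def render_scene(spec: SceneSpec) -> tuple[FluoVideo, GroundTruth]:
    """Render a scene to a two-channel video plus noise-free ground truth.

    The structure channel is the rasterized dendrite-plus-spines geometry at
    ``SIGNAL_LEVEL``; the protein channel shares the geometry but weights each
    spine by its ``protein_density_profile`` evaluated at tau = t/(T-1). Both
    channels are scaled by ``bleach_rate**t``, offset by ``background_level``
    (also bleached, emulating autofluorescent haze) and perturbed with
    i.i.d. Gaussian noise of ``noise_sigma``, then clipped to [0, 1].
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(spec.image_size)
    T = spec.n_frames
    samples, tangents, total = _dense_curve(spec.control_points())
    arclen = np.linspace(0, 1, len(samples))

    dendrite = _dist_to_points(shape, samples) <= spec.dendrite_width / 2.0

    structure = np.zeros((T,) + shape)
    protein = np.zeros((T,) + shape)
    S = len(spec.spines)
    spine_masks = np.zeros((T, S) + shape, dtype=bool)
    density = np.zeros((S, T))

    half_width = spec.dendrite_width / 2.0
    for t in range(T):
        tau = t / (T - 1) if T > 1 else 0.0
        struct_sig = np.where(dendrite, SIGNAL_LEVEL, 0.0)
        prot_sig = np.where(dendrite, DENDRITE_PROTEIN_LEVEL, 0.0)
        claimed = dendrite.copy()
        for s, spine in enumerate(spec.spines):
            idx = int(round(spine.base_arclength * (len(samples) - 1)))
            base = samples[idx]
            tan = tangents[idx]
            normal = np.array([-tan[1], tan[0]]) * spine.side
            sway = spine.sway_amplitude * math.sin(2 * math.pi * t / T)
            direction = _rotate(normal, sway)
            raw = _spine_mask(shape, base, direction, spine, half_width)
            gt_mask = raw & ~claimed
            claimed |= raw
            spine_masks[t, s] = gt_mask
            level = float(spine.protein_density_profile(tau))
            struct_sig = np.where(gt_mask, SIGNAL_LEVEL, struct_sig)
            prot_sig = np.where(gt_mask, level, prot_sig)
            density[s, t] = level * gt_mask.sum() * spec.bleach_rate**t
        decay = spec.bleach_rate**t
        structure[t] = (struct_sig + spec.background_level) * decay
        protein[t] = (prot_sig + spec.background_level) * decay
    if spec.noise_sigma > 0:
        structure += rng.normal(0, spec.noise_sigma, structure.shape)
        protein += rng.normal(0, spec.noise_sigma, protein.shape)
    np.clip(structure, 0.0, 1.0, out=structure)
    np.clip(protein, 0.0, 1.0, out=protein)

    video = FluoVideo(structure, protein, frame_interval=spec.frame_interval)
    truth = GroundTruth(
        dendrite_masks=np.repeat(dendrite[None], T, axis=0),
        spine_masks=spine_masks,
        labels=[sp.shape_class for sp in spec.spines],
        density=density,
    )
    return video, truth


def write_ground_truth(truth: GroundTruth, out_dir: str | os.PathLike) -> Path:
    """Write per-frame label PNGs and a CSV manifest; returns the manifest path.

    Label images encode dendrite as 1 and spine ``s`` as ``s + 2``.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    T = truth.dendrite_masks.shape[0]
    for t in range(T):
        labels = truth.dendrite_masks[t].astype(np.uint8)
        for s in range(truth.n_spines):
            mask = truth.spine_masks[t, s]
            labels[mask] = s + 2
            if mask.any():
                r, c = np.nonzero(mask)
                rows.append(
                    dict(
                        frame=t,
                        spine_id=s,
                        shape_class=truth.labels[s],
                        centroid_row=float(r.mean()),
                        centroid_col=float(c.mean()),
                        area=int(mask.sum()),
                        integrated_density=float(truth.density[s, t]),
                    )
                )
        iio.imwrite(out / f"labels_{t:03d}.png", labels)
    manifest = out / "ground_truth.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def simulate_to_dir(spec: SceneSpec, out_dir: str | os.PathLike) -> None:
    """Render a scene and write video TIFFs plus ground truth to ``out_dir``."""
    video, truth = render_scene(spec)
    write_video(video, out_dir)
    write_ground_truth(truth, Path(out_dir) / "ground_truth")


# ---------------------------------------------------------------------------
# canonical study scenes


def _standard_spines(profiles=None) -> list[SpineSpec]:
    """Six spines, two per shape class, spread along the dendrite."""
    geoms = [
        (0.14, "stubby", 0.0, 4.5, 5.5, -1),
        (0.30, "thin", 8.0, 2.5, 3.0, 1),
        (0.44, "mushroom", 4.0, 2.5, 6.0, -1),
        (0.58, "stubby", 0.0, 4.0, 5.0, 1),
        (0.72, "thin", 9.0, 2.5, 3.5, -1),
        (0.86, "mushroom", 5.0, 2.5, 6.5, 1),
    ]
    spines = []
    for i, (s, cls, nl, nw, hd, side) in enumerate(geoms):
        profile = profiles[i] if profiles is not None else constant(0.5)
        spines.append(
            SpineSpec(
                base_arclength=s,
                shape_class=cls,
                neck_length=nl,
                neck_width=nw,
                head_diameter=hd,
                sway_amplitude=5.0,
                side=side,
                protein_density_profile=profile,
            )
        )
    return spines


def example_scene(name: str, seed: int = 0, **overrides) -> SceneSpec:
    """Canonical scenes used throughout the test-bench.

    ``six_spine``     gentle S-curve dendrite with 6 spines (2 per class).
    ``six_spine_noisy`` same geometry at 5%-of-full-scale noise.
    ``u_shape``       strongly curved (U-shaped) dendrite, no spines.
    ``flux``          noise- and bleach-free scene whose spines carry linear
                      protein ramps, half up (0.2 -> 0.8) and half down.
    ``bare``          straight spineless dendrite.
    """
    if name == "six_spine":
        spec = SceneSpec(
            n_frames=12,
            spines=_standard_spines(),
            noise_sigma=0.0,
            bleach_rate=1.0,
            background_level=0.0,
            rng_seed=seed,
        )
    elif name == "six_spine_noisy":
        spec = SceneSpec(
            n_frames=12,
            spines=_standard_spines(),
            noise_sigma=0.05,
            bleach_rate=0.99,
            background_level=0.05,
            rng_seed=seed,
        )
    elif name == "u_shape":
        spec = SceneSpec(
            n_frames=4,
            dendrite_control_points=[
                (20, 30),
                (64, 18),
                (105, 45),
                (105, 85),
                (64, 110),
                (20, 98),
            ],
            spines=[],
            noise_sigma=0.0,
            bleach_rate=1.0,
            background_level=0.0,
            rng_seed=seed,
        )
    elif name == "flux":
        profiles = [
            ramp(0.2, 0.8),
            ramp(0.8, 0.2),
            ramp(0.2, 0.8),
            ramp(0.8, 0.2),
            ramp(0.2, 0.8),
            ramp(0.8, 0.2),
        ]
        spines = _standard_spines(profiles)
        for sp in spines:
            sp.sway_amplitude = 2.0
        spec = SceneSpec(
            n_frames=10,
            spines=spines,
            noise_sigma=0.0,
            bleach_rate=1.0,
            background_level=0.0,
            rng_seed=seed,
        )
    elif name == "bare":
        spec = SceneSpec(
            n_frames=6,
            dendrite_control_points=[(64, 10), (64, 64), (64, 118)],
            spines=[],
            noise_sigma=0.0,
            bleach_rate=1.0,
            background_level=0.0,
            rng_seed=seed,
        )
    else:
        raise ValueError(f"unknown example scene {name!r}")
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# classification benchmark tracks

#: Geometry ranges (pixels at analysis scale) per shape class, used by the
#: classification benchmark: (neck_length, neck_width, head_diameter).
CLASS_GEOMETRY_RANGES = {
    "stubby": ((0.0, 1.0), (8.0, 14.0), (10.0, 16.0)),
    "thin": ((18.0, 30.0), (3.0, 5.0), (4.0, 7.0)),
    "mushroom": ((6.0, 14.0), (4.0, 7.0), (12.0, 18.0)),
}


def _render_track_spine(canvas, base, direction, up, nl, nw, hd):
    """Spine mask clipped at the base plane (the dendrite boundary)."""
    base = np.asarray(base, float)
    u = np.asarray(direction, float)
    neck_end = base + u * nl
    mask = _capsule_mask(canvas, base, neck_end, nw / 2.0)
    head_center = neck_end + u * (0.4 * hd)
    mask |= _disk_mask(canvas, head_center, hd / 2.0)
    rr, cc = np.mgrid[0 : canvas[0], 0 : canvas[1]]
    above = (rr - base[0]) * up[0] + (cc - base[1]) * up[1] >= -0.5
    return mask & above


def generate_track_dataset(
    n_per_class: int = 60,
    n_frames: int = 12,
    seed: int = 0,
    canvas: int = 64,
    boundary_flip: float = 0.08,
):
    """Simulate spine tracks for the shape-classification benchmark.

    Each track is one spine of a random geometry drawn from
    ``CLASS_GEOMETRY_RANGES``, rendered over ``n_frames`` frames with sway
    about its base, a random in-scene orientation and per-frame boundary
    noise (each boundary pixel flips with probability ``boundary_flip``).

    Returns ``(tracks, labels)`` where each track is a list of
    :class:`~spinetrace.spines.SpineSegment` (one per frame).
    """
    from .spines import SpineSegment

    rng = np.random.default_rng(seed)
    shape = (canvas, canvas)
    tracks, labels = [], []
    for cls in SHAPE_CLASSES:
        (nl_lo, nl_hi), (nw_lo, nw_hi), (hd_lo, hd_hi) = CLASS_GEOMETRY_RANGES[cls]
        for _ in range(n_per_class):
            nl = rng.uniform(nl_lo, nl_hi)
            nw = rng.uniform(nw_lo, nw_hi)
            hd = rng.uniform(hd_lo, hd_hi)
            orient = rng.uniform(0, 360)
            amp = rng.uniform(3.0, 10.0)
            base = np.array([canvas / 2.0, canvas / 2.0])
            u0 = _rotate(np.array([-1.0, 0.0]), orient)
            segs = []
            for t in range(n_frames):
                sway = amp * math.sin(2 * math.pi * t / n_frames) + rng.normal(0, 1.0)
                u = _rotate(u0, sway)
                mask = _render_track_spine(shape, base, u, u0, nl, nw, hd)
                if boundary_flip > 0:
                    from scipy import ndimage as ndi

                    interior = ndi.binary_erosion(mask)
                    boundary = mask & ~interior
                    outer = ndi.binary_dilation(mask) & ~mask
                    flips = rng.random(shape) < boundary_flip
                    mask = (mask & ~(boundary & flips)) | (outer & flips)
                    mask = ndi.binary_fill_holes(mask)
                # base line: extent of the mask across the base, perp to u
                perp = np.array([-u0[1], u0[0]])
                r, c = np.nonzero(mask)
                pts = np.column_stack([r, c]).astype(float) - base
                along = pts @ perp
                across = pts @ u0
                near_base = np.abs(across) <= 1.5
                if near_base.sum() < 2:
                    near_base = across <= np.percentile(across, 10)
                lo, hi = along[near_base].min(), along[near_base].max()
                e0 = base + perp * lo
                e1 = base + perp * hi
                height = float(across.max())
                segs.append(
                    SpineSegment(
                        spine_id=len(tracks),
                        frame_index=t,
                        mask=mask,
                        seed=(int(r[np.argmax(across)]), int(c[np.argmax(across)])),
                        base_endpoints=(tuple(e0), tuple(e1)),
                        area=float(mask.sum()),
                        height=max(height, 1.0),
                        width=float(hi - lo),
                        mean_structure_intensity=float(
                            np.clip(rng.normal(0.55, 0.05), 0, 1)
                        ),
                    )
                )
            tracks.append(segs)
            labels.append(cls)
    return tracks, labels
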