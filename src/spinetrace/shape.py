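"""Spine shape classification from Spine Energy Images.

A Spine Energy Image (SEI) summarizes a spine track: every binary spine mask
is rotated so its spine/dendrite base line lies along the bottom edge,
cropped, resized to 10x10 and re-binarized; the SEI is the pixelwise mean of
those aligned masks. Gray level encodes positional occupancy over time, so
the SEI captures both shape (stubby / thin / mushroom silhouettes) and
temporal sway -- the same construction as the gait energy image used for
human gait recognition.

The raw 10x10 SEI is a 100-dimensional vector; a uniform local binary
pattern (LBP) histogram reduces it to 59 dimensions (the 58 rotation-variant
uniform 8-bit patterns plus one pooled bin for the non-uniform rest). The
final feature vector appends the spine's area, height, width and mean
intensity -- 63 dimensions -- and is fed to a discriminant-analysis, k-NN
(k=5) or pairwise-SVM ECOC classifier under repeated stratified 10-fold
cross-validation. A decision-tree cascade on raw height/width measurements
serves as the classical baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import transform
from sklearn.compose import ColumnTransformer
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.multiclass import OneVsOneClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .spines import SpineSegment

__all__ = [
    "SpineEnergyImage",
    "align_and_resize",
    "compute_sei",
    "uniform_lbp_histogram",
    "build_feature_vector",
    "track_features",
    "train_classifier",
    "crossvalidate",
    "decision_tree_baseline",
    "measure_spine_profile",
    "N_LBP_BINS",
    "FEATURE_DIM",
]

SEI_SIZE = 10
N_LBP_BINS = 59
N_MORPHOLOGY = 4
FEATURE_DIM = N_LBP_BINS + N_MORPHOLOGY
CLASSIFIER_KINDS = ("DA", "KNN", "ECOC")


@dataclass
class SpineEnergyImage:
    """10x10 occupancy image of an aligned spine track; values in [0, 1]."""

    pixels: np.ndarray
    n_frames: int


# ---------------------------------------------------------------------------
# alignment and SEI


def align_mask(segment: SpineSegment) -> np.ndarray:
    """Native-resolution binary spine mask rotated base-down and cropped.

    The mask is rotated so the base line (spine/dendrite boundary) is
    horizontal with the spine body above it, then cropped to its bounding
    box. Coincident base endpoints fall back to orienting by the mask's
    base-to-centroid axis.
    """
    mask = np.asarray(segment.mask, bool)
    if not mask.any():
        raise ValueError("cannot align an empty mask")
    (r0, c0), (r1, c1) = segment.base_endpoints
    base_vec = np.array([r1 - r0, c1 - c0], float)
    base_mid = np.array([(r0 + r1) / 2.0, (c0 + c1) / 2.0])
    r, c = np.nonzero(mask)
    pts = np.column_stack([r, c]).astype(float)
    if np.linalg.norm(base_vec) < 1e-9:
        # degenerate base: orient by the base->centroid axis instead
        up = pts.mean(axis=0) - base_mid
        base_vec = np.array([-up[1], up[0]])
        if np.linalg.norm(base_vec) < 1e-9:
            base_vec = np.array([0.0, 1.0])
    base_dir = base_vec / np.linalg.norm(base_vec)
    normal = np.array([-base_dir[1], base_dir[0]])
    # orient so the spine body ends up at negative (upward) rows
    if float(((pts - base_mid) @ normal).mean()) > 0:
        normal = -normal
    # rotate: base_dir -> +col axis, normal -> +row axis (body up at
    # negative rows); then sample the source mask over the rotated bounding
    # box by inverse mapping, which leaves no rotation holes
    rot = np.array([normal, base_dir])  # rows: new-row axis, new-col axis
    rel = (pts - base_mid) @ rot.T
    rmin, rmax = rel[:, 0].min(), rel[:, 0].max()
    cmin, cmax = rel[:, 1].min(), rel[:, 1].max()
    h = max(int(math.ceil(rmax - rmin)) + 1, 1)
    w = max(int(math.ceil(cmax - cmin)) + 1, 1)
    ii, jj = np.mgrid[0:h, 0:w]
    src = (
        base_mid[None, None, :]
        + (ii + rmin)[..., None] * normal[None, None, :]
        + (jj + cmin)[..., None] * base_dir[None, None, :]
    )
    sr = np.clip(np.round(src[..., 0]).astype(int), 0, mask.shape[0] - 1)
    sc = np.clip(np.round(src[..., 1]).astype(int), 0, mask.shape[1] - 1)
    inside = (
        (np.round(src[..., 0]) >= 0)
        & (np.round(src[..., 0]) < mask.shape[0])
        & (np.round(src[..., 1]) >= 0)
        & (np.round(src[..., 1]) < mask.shape[1])
    )
    return mask[sr, sc] & inside


def align_and_resize(segment: SpineSegment, out_size: int = SEI_SIZE) -> np.ndarray:
    """Aligned spine mask resized to 10x10 and re-binarized at 0.5.

    Aspect ratio is preserved (silhouette convention): the crop is scaled to
    fit, pasted base-down and horizontally centered.
    """
    grid = align_mask(segment).astype(float)
    h, w = grid.shape
    scale = out_size / max(h, w)
    nh = max(int(round(h * scale)), 1)
    nw = max(int(round(w * scale)), 1)
    small = transform.resize(
        grid, (nh, nw), order=1, mode="edge", anti_aliasing=False,
        preserve_range=True,
    ) >= 0.5
    out = np.zeros((out_size, out_size), bool)
    c0 = (out_size - nw) // 2
    out[out_size - nh :, c0 : c0 + nw] = small
    return out


def compute_sei(aligned_masks: np.ndarray) -> SpineEnergyImage:
    """Pixelwise mean of a (N, 10, 10) stack of aligned binary masks."""
    stack = np.asarray(aligned_masks, float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] < 1:
        raise ValueError("a spine energy image needs at least one mask")
    return SpineEnergyImage(stack.mean(axis=0), n_frames=stack.shape[0])


# ---------------------------------------------------------------------------
# uniform LBP

# neighbor offsets in circular order (P=8, R=1, square neighborhood)
_LBP_OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def _transitions(pattern: int) -> int:
    bits = [(pattern >> i) & 1 for i in range(8)]
    return sum(bits[i] != bits[(i + 1) % 8] for i in range(8))


def _build_uniform_lookup() -> np.ndarray:
    """Map each 8-bit pattern to its bin: 58 uniform bins + 1 pooled."""
    uniform = [p for p in range(256) if _transitions(p) <= 2]
    lut = np.full(256, len(uniform), dtype=np.int64)  # pooled bin = 58
    for i, p in enumerate(uniform):
        lut[p] = i
    return lut


_UNIFORM_LUT = _build_uniform_lookup()
assert int((_UNIFORM_LUT < 58).sum()) == 58


def uniform_lbp_histogram(sei: SpineEnergyImage | np.ndarray) -> np.ndarray:
    """59-bin uniform LBP histogram of a (gray-valued) SEI.

    For every interior pixel the 8 radius-1 neighbors are compared to the
    center (neighbor >= center -> 1), giving an 8-bit pattern; patterns with
    at most 2 circular bit transitions get their own bin (58 of them), all
    others share one pooled bin. The histogram sums to the interior pixel
    count (64 for a 10x10 image).
    """
    img = sei.pixels if isinstance(sei, SpineEnergyImage) else np.asarray(sei, float)
    h, w = img.shape
    codes = np.zeros((h - 2, w - 2), dtype=np.int64)
    center = img[1:-1, 1:-1]
    for bit, (dr, dc) in enumerate(_LBP_OFFSETS):
        nb = img[1 + dr : h - 1 + dr, 1 + dc : w - 1 + dc]
        codes |= (nb >= center).astype(np.int64) << bit
    bins = _UNIFORM_LUT[codes]
    return np.bincount(bins.ravel(), minlength=N_LBP_BINS).astype(float)


# ---------------------------------------------------------------------------
# features


def build_feature_vector(sei: SpineEnergyImage | np.ndarray, stats) -> np.ndarray:
    """Concatenate the LBP histogram with (area, height, width, intensity).

    ``stats`` is (area, height, width, mean_intensity) or an object with
    those attributes. The morphology block is z-scored later, inside the
    classifier pipeline, using training-set statistics.
    """
    if hasattr(stats, "area"):
        stats = (stats.area, stats.height, stats.width, stats.mean_structure_intensity)
    stats = np.asarray(stats, float)
    if stats.shape != (N_MORPHOLOGY,):
        raise ValueError("stats must provide area, height, width, mean intensity")
    if not np.isfinite(stats).all():
        raise ValueError("morphology stats must be finite")
    vec = np.concatenate([uniform_lbp_histogram(sei), stats])
    assert vec.shape == (FEATURE_DIM,)
    return vec


def track_features(track_segments: list[SpineSegment]):
    """Per-frame feature vectors for one track (shared SEI + frame stats).

    Returns ``(features (N, 63), sei)``. The SEI is a track-level summary;
    the per-frame morphology lets individual segmentations be classified.
    """
    aligned = np.stack([align_and_resize(s) for s in track_segments])
    sei = compute_sei(aligned)
    lbp = uniform_lbp_histogram(sei)
    feats = np.stack(
        [
            np.concatenate(
                [lbp, [s.area, s.height, s.width, s.mean_structure_intensity]]
            )
            for s in track_segments
        ]
    )
    return feats, sei


# ---------------------------------------------------------------------------
# classifiers


def _make_estimator(kind: str):
    if kind == "DA":
        clf = LinearDiscriminantAnalysis()
    elif kind == "KNN":
        clf = KNeighborsClassifier(n_neighbors=5)
    elif kind == "ECOC":
        clf = OneVsOneClassifier(SVC(kernel="linear", C=1.0))
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; use one of {CLASSIFIER_KINDS}")
    scaler = ColumnTransformer(
        [("morphology", StandardScaler(), slice(N_LBP_BINS, FEATURE_DIM))],
        remainder="passthrough",
    )
    return Pipeline([("scale", scaler), ("clf", clf)])


def train_classifier(features: np.ndarray, labels, kind: str = "KNN"):
    """Fit a DA, KNN (k=5) or pairwise-SVM ECOC classifier.

    Morphology features are z-scored with training-set statistics inside the
    returned pipeline; the LBP histogram passes through unscaled.
    """
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if kind == "KNN" and counts.min() < 5:
        warnings.warn("a class has fewer samples than k=5 neighbors", stacklevel=2)
    model = _make_estimator(kind)
    model.fit(features, labels)
    return model


def n_binary_learners(model) -> int:
    """Number of binary learners inside a fitted ECOC model."""
    clf = model.named_steps["clf"]
    if not isinstance(clf, OneVsOneClassifier):
        raise TypeError("not an ECOC model")
    return len(clf.estimators_)


def crossvalidate(
    features: np.ndarray,
    labels,
    kind: str = "KNN",
    folds: int = 10,
    repeats: int = 20,
    seed: int = 0,
) -> tuple[float, float]:
    """Accuracy mean and std over repeated stratified k-fold CV.

    Every fold of every repeat is tested once; the dataset is reshuffled
    between repeats. Returns (mean, std) over the repeats x folds accuracies.
    """
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    n = len(labels)
    _, class_counts = np.unique(labels, return_counts=True)
    max_folds = min(n, int(class_counts.min()))
    if folds > max_folds:
        warnings.warn(
            f"reducing folds from {folds} to {max_folds} (stratified folds "
            "cannot exceed the smallest class)",
            stacklevel=2,
        )
        folds = max_folds
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    accs = []
    for train_idx, test_idx in cv.split(features, labels):
        model = _make_estimator(kind)
        model.fit(features[train_idx], labels[train_idx])
        accs.append(float(np.mean(model.predict(features[test_idx]) == labels[test_idx])))
    accs = np.asarray(accs)
    return float(accs.mean()), float(accs.std())


# ---------------------------------------------------------------------------
# decision-tree baseline


def measure_spine_profile(mask: np.ndarray, base_endpoints=None) -> dict:
    """Classical per-spine measurements from an aligned (base-down) mask.

    Per-row widths of the mask give: total height, base width, head width
    (widest row in the upper part), neck width (narrowest row between head
    and base) and neck length (rows below the head).
    """
    mask = np.asarray(mask, bool)
    rows = np.nonzero(mask.any(axis=1))[0]
    if len(rows) == 0:
        raise ValueError("empty mask")
    widths = []
    for r in range(rows.min(), rows.max() + 1):
        cols = np.nonzero(mask[r])[0]
        widths.append(cols.max() - cols.min() + 1 if len(cols) else 0)
    widths = np.asarray(widths, float)  # index 0 = top (tip side)
    height = float(len(widths))
    upper = widths[: max(int(0.6 * len(widths)), 1)]
    head_row = int(np.argmax(upper))
    head_width = float(widths[head_row])
    between = widths[head_row:-1]
    neck_width = float(between.min()) if len(between) else float(widths[-1])
    neck_length = float(len(widths) - 1 - head_row)
    return dict(
        height=height,
        width=float(widths.max()),
        head_width=head_width,
        neck_width=max(neck_width, 1.0),
        neck_length=neck_length,
    )


def decision_tree_baseline(
    measurements: dict,
    stubby_ratio: float = 1.0,
    mushroom_head_ratio: float = 2.0,
) -> str:
    """Classical rule cascade on height/width measurements.

    height/width < ``stubby_ratio``            -> stubby
    head_width/neck_width > ``mushroom_head_ratio`` -> mushroom
    otherwise                                   -> thin
    """
    try:
        height = measurements["height"]
        width = measurements["width"]
        head = measurements["head_width"]
        neck = measurements["neck_width"]
    except KeyError as exc:
        raise ValueError(f"missing measurement: {exc}") from exc
    if width > 0 and height / width < stubby_ratio:
        return "stubby"
    if neck > 0 and head / neck > mushroom_head_ratio:
        return "mushroom"
    return "thin"
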