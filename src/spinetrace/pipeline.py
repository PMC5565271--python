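"""End-to-end orchestration: video in, spine tracks and reports out.

The pipeline mirrors the three-subsystem design of the analysis: (1)
segmentation -- preprocess the structure channel, enhance with the temporal
maximum projection, extract foreground, dendrite and spines per frame; (2)
protein motility -- associate spines over time and measure integrated
density and flux on the protein channel; (3) shape analysis -- build spine
energy images and classify each track as stubby, thin or mushroom.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dendrite as dendrite_mod
from . import enhance as enhance_mod
from . import shape as shape_mod
from . import spines as spines_mod
from . import tracking as tracking_mod
from .preprocess import preprocess_video
from .video import FluoVideo

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "upscale_mask"]


@dataclass
class PipelineConfig:
    """All tunable parameters of an end-to-end run."""

    tophat_radius: int = 50
    upscale: int = 4
    otsu_multiplier: float = 0.3  # useful range 0.2-0.4
    min_component_area: int = 20
    seed_deviation: float = 15.0  # piecewise-linear threshold d
    trim_length: int = 40
    contour_keep_fraction: float = 0.02
    min_spine_height: float = 3.0
    min_spine_prominence: float = 5.0
    min_spine_area: int = 16
    declump: bool = True
    parallel_tol: float = 30.0
    declump_prominence: float = 0.1
    new_track_threshold: float = 0.1
    reuse_frame0_seeds: bool = False
    classifier: str = "KNN"
    classify: bool = False
    folds: int = 10
    repeats: int = 20
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    config: PipelineConfig
    processed: FluoVideo
    tmip: enhance_mod.TMIP
    foregrounds: list[np.ndarray]
    dendrites: list[dendrite_mod.DendriteModel]
    segments_per_frame: list[list[spines_mod.SpineSegment]]
    tracks: list[tracking_mod.SpineTrack]
    flux_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    seis: dict[int, shape_mod.SpineEnergyImage] = field(default_factory=dict)


def upscale_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbor upscaling of a boolean mask by an integer factor."""
    return np.kron(np.asarray(mask, bool), np.ones((factor, factor), bool))


def _snap_to_mask(point, mask: np.ndarray):
    r, c = np.nonzero(mask)
    i = int(np.argmin((r - point[0]) ** 2 + (c - point[1]) ** 2))
    return (int(r[i]), int(c[i]))


def _classify_tracks(tracks, config: PipelineConfig) -> None:
    """Label tracks with a classifier trained on the synthetic shape library."""
    from .synthetic import generate_track_dataset

    lib_tracks, lib_labels = generate_track_dataset(
        n_per_class=60, seed=config.rng_seed
    )
    feats, labels = [], []
    for segs, lab in zip(lib_tracks, lib_labels):
        f, _ = shape_mod.track_features(segs)
        feats.append(f)
        labels.extend([lab] * len(f))
    model = shape_mod.train_classifier(
        np.concatenate(feats), labels, kind=config.classifier
    )
    for track in tracks:
        segs = [track.segments[t] for t in track.frames]
        if not segs:
            continue
        f, _ = shape_mod.track_features(segs)
        pred = model.predict(f)
        values, counts = np.unique(pred, return_counts=True)
        track.class_label = str(values[np.argmax(counts)])


def run_pipeline(
    video: FluoVideo,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run segmentation, tracking, flux and (optionally) classification."""
    config = config or PipelineConfig()
    processed = preprocess_video(
        video, tophat_radius=config.tophat_radius, upscale=config.upscale
    )
    tmip = enhance_mod.compute_tmip(processed.structure)
    foregrounds, dendrites, segments_per_frame = [], [], []
    frame0_seeds = None
    for t in range(processed.n_frames):
        enhanced = enhance_mod.enhance_frame(processed.structure[t], tmip)
        fg = enhance_mod.segment_foreground(
            enhanced, config.otsu_multiplier, config.min_component_area
        )
        if not fg.any():
            foregrounds.append(fg)
            dendrites.append(None)
            segments_per_frame.append([])
            continue
        if config.reuse_frame0_seeds and frame0_seeds is not None:
            seeds = [_snap_to_mask(s, fg) for s in frame0_seeds]
            region = np.zeros_like(fg)
            for p, q in zip(seeds[:-1], seeds[1:]):
                region |= dendrite_mod.directional_kernel_region(fg, p, q)
            dmask = dendrite_mod.smooth_dendrite_contour(
                region, config.contour_keep_fraction, clip_to=fg
            )
            dmodel = dendrite_mod.DendriteModel(
                mask=dmask, skeleton=np.zeros_like(fg), seeds=seeds
            )
        else:
            dmodel = dendrite_mod.segment_dendrite(
                fg,
                d=config.seed_deviation,
                trim_length=config.trim_length,
                keep_fraction=config.contour_keep_fraction,
            )
            if frame0_seeds is None:
                frame0_seeds = dmodel.seeds
        segments = spines_mod.segment_spines(
            fg,
            dmodel.mask,
            processed.structure[t],
            frame_index=t,
            min_spine_height=config.min_spine_height,
            min_prominence=config.min_spine_prominence,
            min_area=config.min_spine_area,
            declump=config.declump,
            parallel_tol=config.parallel_tol,
            prominence=config.declump_prominence,
            tangent_fn=lambda seg, dm=dmodel: dm.tangent_at(
                np.mean(np.asarray(seg.base_endpoints), axis=0)
            ),
        )
        foregrounds.append(fg)
        dendrites.append(dmodel)
        segments_per_frame.append(segments)
    tracks = tracking_mod.track_video(
        segments_per_frame, processed.protein, config.new_track_threshold
    )
    if config.classify:
        _classify_tracks(tracks, config)
    flux_table = tracking_mod.summarize_flux(tracks)
    seis = {}
    for track in tracks:
        segs = [track.segments[t] for t in track.frames]
        try:
            aligned = np.stack([shape_mod.align_and_resize(s) for s in segs])
            seis[track.track_id] = shape_mod.compute_sei(aligned)
        except ValueError:
            continue
    result = PipelineResult(
        config=config,
        processed=processed,
        tmip=tmip,
        foregrounds=foregrounds,
        dendrites=dendrites,
        segments_per_frame=segments_per_frame,
        tracks=tracks,
        flux_table=flux_table,
        seis=seis,
    )
    if out_dir is not None:
        write_report(result, out_dir)
    return result


# ---------------------------------------------------------------------------
# reporting


def _spine_rows(result: PipelineResult):
    for t, segments in enumerate(result.segments_per_frame):
        for seg in segments:
            cr, cc = seg.centroid
            yield dict(
                frame=t,
                spine_id=seg.spine_id,
                centroid_row=round(cr, 2),
                centroid_col=round(cc, 2),
                area=seg.area,
                height=round(seg.height, 3),
                width=round(seg.width, 3),
                base_r0=round(seg.base_endpoints[0][0], 1),
                base_c0=round(seg.base_endpoints[0][1], 1),
                base_r1=round(seg.base_endpoints[1][0], 1),
                base_c1=round(seg.base_endpoints[1][1], 1),
                mean_structure_intensity=round(seg.mean_structure_intensity, 5),
            )


def write_report(result: PipelineResult, out_dir: str | Path) -> None:
    """Write spine/track CSVs, SEI images, overlays and a JSON summary."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(list(_spine_rows(result))).to_csv(out / "spines.csv", index=False)
    track_rows = []
    for track in result.tracks:
        flux = tracking_mod.compute_flux(track)
        frames = track.frames
        for i, frame in enumerate(frames):
            track_rows.append(
                dict(
                    track_id=track.track_id,
                    frame=frame,
                    integrated_density=round(track.density.get(frame, float("nan")), 5),
                    inward_flux=round(float(flux[i - 1]), 5) if 0 < i <= len(flux) else "",
                    class_label=track.class_label or "",
                )
            )
    pd.DataFrame(track_rows).to_csv(out / "tracks.csv", index=False)
    if len(result.flux_table):
        result.flux_table.to_csv(out / "flux_summary.csv", index=False)
    sei_dir = out / "sei"
    sei_dir.mkdir(exist_ok=True)
    for tid, sei in result.seis.items():
        iio.imwrite(
            sei_dir / f"track_{tid:03d}.png",
            (sei.pixels * 255).round().astype(np.uint8),
        )
    overlay_dir = out / "overlays"
    overlay_dir.mkdir(exist_ok=True)
    for t in range(result.processed.n_frames):
        iio.imwrite(overlay_dir / f"frame_{t:03d}.png", render_overlay(result, t))
    summary = dict(
        config=result.config.to_dict(),
        n_frames=result.processed.n_frames,
        n_tracks=len(result.tracks),
        n_spine_detections=sum(len(s) for s in result.segments_per_frame),
        class_counts=pd.Series(
            [t.class_label for t in result.tracks if t.class_label]
        ).value_counts().to_dict(),
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=2))


def render_overlay(result: PipelineResult, frame: int) -> np.ndarray:
    """RGB overlay: foreground contour green, dendrite red, spines blue."""
    img = result.processed.structure[frame]
    lo, hi = img.min(), img.max()
    gray = ((img - lo) / (hi - lo) * 255 if hi > lo else img * 0).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    fg = result.foregrounds[frame]
    if fg.any():
        rgb[enhance_mod.foreground_contour(fg)] = (0, 255, 0)
    dmodel = result.dendrites[frame]
    if dmodel is not None and dmodel.mask.any():
        rgb[enhance_mod.foreground_contour(dmodel.mask)] = (255, 0, 0)
    for seg in result.segments_per_frame[frame]:
        rgb[enhance_mod.foreground_contour(seg.mask)] = (80, 120, 255)
    return rgb
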