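"""Shared fixtures: canonical scenes run once per session through the full
pipeline, plus the shape-classification benchmark."""

from __future__ import annotations

import numpy as np
import pytest

import spinetrace as st
from spinetrace.pipeline import upscale_mask


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def _run(name, **cfg):
    spec = st.example_scene(name)
    video, truth = st.render_scene(spec)
    result = st.run_pipeline(video, st.PipelineConfig(**cfg))
    return video, truth, result


@pytest.fixture(scope="session")
def six_spine_run():
    return _run("six_spine")


@pytest.fixture(scope="session")
def noisy_run():
    return _run("six_spine_noisy")


@pytest.fixture(scope="session")
def u_shape_run():
    return _run("u_shape")


@pytest.fixture(scope="session")
def flux_run():
    return _run("flux")


@pytest.fixture(scope="session")
def benchmark_tracks():
    from spinetrace.synthetic import generate_track_dataset

    return generate_track_dataset(n_per_class=60, seed=0)


@pytest.fixture(scope="session")
def benchmark_features(benchmark_tracks):
    from spinetrace import shape

    tracks, labels = benchmark_tracks
    feats = []
    for segs in tracks:
        f, _ = shape.track_features(segs)
        feats.append(f.mean(axis=0))
    return np.array(feats), np.array(labels)


def detection_scores(truth, result, factor=4):
    """Aggregate detection precision/recall over all frames of a run."""
    from spinetrace import metrics

    n_det = n_truth = n_pred = 0
    for t, segments in enumerate(result.segments_per_frame):
        preds = [s.mask for s in segments]
        trues = [
            upscale_mask(truth.spine_masks[t, s], factor)
            for s in range(truth.n_spines)
            if truth.spine_masks[t, s].any()
        ]
        m = metrics.detection_metrics(preds, trues)
        n_det += m["n_detected"]
        n_truth += m["n_truth"]
        n_pred += m["n_predicted"]
    return dict(
        recall=n_det / n_truth if n_truth else float("nan"),
        precision=n_det / n_pred if n_pred else float("nan"),
    )
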