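# spinetrace

Automated analysis of dendritic spines and tagged-protein trafficking in
two-channel fluorescence time-lapse videos of cultured neurons.

Dendritic spines — the micron-scale protrusions that carry excitatory
synapses — are remodeled by actin-regulating proteins such as cofilin.
Experiments that image a cell-fill label (e.g. tdTomato) alongside a
GFP-tagged protein produce short, low-resolution, noisy videos
(128×128 px, tens of frames, 0.5–3 min intervals) in which spines must be
found, followed over time, measured and classified before any biology can
be read off. `spinetrace` is a library plus command-line tool that does
this end to end, for experimentalists and image-analysis researchers who
need a reproducible, scriptable alternative to manual ROI work.

## Method

The pipeline has three subsystems.

**Segmentation** (structure channel). Each frame is cleaned with a disk
top-hat (radius 50 px), a 3×3 median and histogram matching against frame 0
(photobleach correction), then upscaled ×4 bicubically. The *temporal
maximum intensity projection* T(x,y) = maxₜ I(x,y,t), min–max normalized,
weights each frame — structures that fluoresced at any time are enhanced,
out-of-focus haze is suppressed — and a scaled Otsu threshold
(multiplier 0.2–0.4) yields the foreground. The dendrite shaft is isolated
by skeletonizing the foreground, anchoring a piecewise-linear backbone
between the two geodesically farthest skeleton points (new seed wherever
the skeleton deviates > d = 15 px from the chord), sweeping each seed pair
with a pair of complementary directional 3×3 kernels (region growth within
±45° of the flow, intersected), and low-passing the resulting contour with
truncated Fourier descriptors. Spines are seeded at regional maxima of the
distance-to-dendrite profile along the foreground contour, extracted as
filled contour arcs closed by a straight base line (the spine/dendrite
boundary), split at deep profile valleys (valley < ½ × flanking peak), and
declumped with a marker-controlled watershed on intensity extrema.

**Protein motility** (protein channel, never TMIP-weighted). Spines are
associated over time by mask overlap — they are anchored to the dendrite,
so no motion model is needed. For each track the *integrated density*
ρᵢ(t) = Σ_{(x,y)∈Sᵢ(t)} i(x,y,t) measures the amount of tagged protein;
treating it as a conserved fluid with the spine neck as the only boundary,
the signed flux through the neck is Δρᵢ/Δt per frame interval: positive
means protein moved in, negative out.

**Shape analysis.** Every spine mask is rotated base-down, resized to
10×10 and averaged over the track into a *spine energy image*
S(x,y) = (1/N) Σₜ Bₜ(x,y) — a gray-valued silhouette that also encodes
sway. A uniform local binary pattern histogram (8 neighbors, radius 1;
58 uniform patterns + 1 pooled bin = 59 features) plus area, height, width
and mean intensity (63 features total) feed a discriminant-analysis, k-NN
(k = 5) or pairwise-SVM ECOC classifier that labels each track stubby,
thin or mushroom under repeated stratified 10-fold cross-validation. A
height/width decision-tree cascade serves as the classical baseline.

Because no public dataset of this kind exists, the package ships a
first-class synthetic-scene generator (`spinetrace.synthetic`): curved
dendrites bearing swaying spines of the three shape classes, protein ramps,
background haze, photobleaching and Gaussian noise — with exact ground
truth for every mask and density series.

## Worked example

```python
import spinetrace as st
from spinetrace import tracking

spec = st.example_scene("six_spine", seed=0)      # 6 spines, 2 per class
video, truth = st.render_scene(spec)
result = st.run_pipeline(video, st.PipelineConfig(classify=True))

print(f"{video.n_frames} frames, "
      f"{sum(len(s) for s in result.segments_per_frame)} spine detections, "
      f"{len(result.tracks)} tracks")
for tr in result.tracks:
    flux = tracking.compute_flux(tr)
    print(f"track {tr.track_id}: {len(tr.frames)} frames, "
          f"class={tr.class_label}, net flux={flux.sum():+.1f}")
print(result.flux_table.to_string(index=False))
```

prints

```
12 frames, 72 spine detections, 6 tracks
track 0: 12 frames, class=mushroom, net flux=+22.8
track 1: 12 frames, class=mushroom, net flux=-10.1
track 2: 12 frames, class=mushroom, net flux=+3.2
track 3: 12 frames, class=mushroom, net flux=-25.4
track 4: 12 frames, class=stubby, net flux=-10.3
track 5: 12 frames, class=stubby, net flux=+21.1
shape_class  n_in_steps  n_out_steps  n_zero_steps  fraction_in
   mushroom          22           22             0          0.5
     stubby          11           11             0          0.5
```

All six simulated spines are recovered as one track each over all 12
frames (72 detections = 6 spines × 12 frames, no false positives on this
noise-free scene). Net flux is the telescoped density change ρ(last) −
ρ(first) in intensity units: here the spines carry constant protein
levels, so small positive and negative drifts cancel and each class shows
a balanced in/out step ratio (`fraction_in` = 0.5). Classification is done
by a k-NN model trained on the synthetic shape library; thin spines swaying
with larger heads can be mistaken for mushrooms at this scale, as seen in
tracks 1–3.

The same run from a shell:

```
spinetrace simulate --config scene.yaml --out sim/ --seed 0
spinetrace run --structure sim/structure.tif --protein sim/protein.tif --out results/
```

where `scene.yaml` can be as short as `example: six_spine`. Reports land
in `results/` as CSV tables (per-spine morphology, per-track density and
flux), SEI and overlay PNGs, and a JSON summary.

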