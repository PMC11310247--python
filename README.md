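# ccvtrack

Quantification of clathrin-coated-vesicle (CCV) dynamics and distribution in
fluorescence microscopy of cultured cells.

Clathrin-mediated endocytosis packages receptor-bound cargo (EGF,
transferrin-iron) into ~100-nm coated vesicles that appear as
diffraction-limited spots in live-cell movies of GFP-clathrin-expressing
cells. `ccvtrack` turns such movies — and fixed two-channel images of the
same cells — into the standard readouts used to compare conditions such as
normoxia versus hypoxia:

* **Detection** — sub-pixel spot localization by weighted least-squares
  fitting of an isotropic 2-D Gaussian PSF; accepted spots must have a
  fitted amplitude ≥ 5 a.u. above the frame background and a width
  σ ∈ [1, 15] px.
* **Tracking** — greedy nearest-neighbour linking within a 3-px radius,
  gap closing up to 5 frames, minimum track length 5 observed frames.
* **Motion statistics** — per-track mean square displacement
  MSD(τ) = ⟨(x_{t+τ}−x_t)² + (y_{t+τ}−y_t)²⟩; apparent diffusion constant
  D = slope/4 of the first four MSD lags (MSD = 4Dτ in 2-D); turning
  angles α = |atan2(det(v₁,v₂), v₁·v₂)| between consecutive displacements;
  and the asymmetry coefficient AC = freq(α ∈ 180°±30°) / freq(α ≤ 30°) —
  the lower the AC, the more directional the transport (Brownian motion
  gives AC ≈ 1).
* **Colocalization** — rolling-ball background subtraction (radius 50 px,
  no smoothing) and the Manders overlap coefficient
  MOC = Σ RᵢGᵢ / √(Σ Rᵢ² Σ Gᵢ²) with Costes automatic thresholding.
* **Radial distribution** — cell segmentation (rolling ball → intensity
  window [3, 30] → Gaussian blur σ = 5 → Otsu, border cells discarded),
  speckle enhancement (white top-hat, feature size 20), vesicle
  identification with watershed declumping, child–parent centroid
  distances, the area-corrected distance index (mean distance / √area)
  and 4-bin fraction-at-distance radial profiles.
* **Simulation** — every stage is validated against a built-in generator of
  movies and scenes with exact ground truth (Brownian/directed motion,
  blinking, Poisson + read noise, controllable channel overlap and radial
  vesicle placement).

## Worked example

Simulate a movie of 15 vesicles undergoing weakly directed transport
(D = 0.05 px²/frame, drift 0.4 px/frame), then run the full chain:

```
ccvtrack simulate --kind directed -D 0.05 -v 0.4 --n-tracks 15 \
    --n-frames 60 --shape 256 256 --seed 11 --out demo
ccvtrack detect demo/movie.tif --out demo/detections.csv
ccvtrack link demo/detections.csv --out demo/tracks.csv
ccvtrack stats demo/tracks.csv --pixel-size 0.1083 --frame-interval 1.0 \
    --out demo/metrics.csv --summary demo/summary.json
```

`demo/summary.json` then reads (abridged):

```json
{
  "n_tracks": 15,
  "asymmetry_coefficient": 0.1978,
  "mean_msd_at": {"1": 0.3815, "2": 1.0776, "3": 2.1030, "4": 3.4516},
  "mean_track_length": 56.07,
  "median_diffusion_px2_per_frame": 0.2542
}
```

All 15 simulated particles are recovered. The mean MSD at lags 1–4 matches
the theoretical 4Dτ + (vτ)² = 0.36, 1.04, 2.04, 3.36 px²; the fitted
apparent D (0.25 px²/frame) exceeds the thermal D because the drift term
steepens the early MSD slope, and the AC of 0.20 ≪ 1 flags the motion as
directional. With the 60×-objective calibration (0.1083 µm/px, 1 s/frame)
the same quantities are reported in µm²/s.

The same library surface is available in Python:

```python
from ccvtrack import MotionModel, OpticsModel, simulate_tracks, render_movie
from ccvtrack import detect_movie, link_tracks, summarize_field

truth = simulate_tracks(MotionModel(kind="brownian", D=0.05), 20, 100)
movie = render_movie(truth, OpticsModel(poisson_noise=True), seed=1)
tracks = link_tracks(detect_movie(movie))
print(summarize_field(tracks).to_dict())
```

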