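# mitotrack

Single-cell analysis of mitotic progression in 2D+t chromatin movies.

Live-cell imaging of fluorescently labelled chromatin (e.g. H2B-mCherry in
HeLa cells) records hundreds of cells passing through mitosis: chromatin
condenses at prophase, aligns into the metaphase plate, the sister
chromatin masses separate at anaphase onset, and the daughter nuclei
decondense back toward interphase during telophase and early G1.
`mitotrack` turns such movies into quantitative, temporally aligned
single-cell measurements without any trained classifier:

1. **Detection** — nucleus centroids per frame via multi-scale
   Laplacian-of-Gaussian filtering (scale-normalized response
   `-σ²∇²G * I`, local maxima merged within `σ√2`).
2. **Tracking** — time-reversed linking: the detections of frame *t* and
   the tracked objects of frame *t+1* are clustered jointly with Ward's
   linkage; the dendrogram is cut at a distance cutoff (default: half the
   average distance of each object to its eight nearest neighbours).  Two
   successors for one predecessor annotate a cell division; complete
   mitotic trajectories covering 30 frames before and 60 frames after the
   division (90 and 180 minutes at 3 min/frame) are extracted.
3. **Segmentation** — per tracked cell a square patch is cropped and the
   central cell segmented by 5×5 median filtering, a modified Otsu
   threshold `T = (T_otsu + min_center)/2` (protecting dim central cells),
   and a seeded watershed on the inverted Euclidean distance map.
   Externally produced instance labels (e.g. from a CNN segmenter) can be
   merged instead, with the classical pipeline as fallback.
4. **Features** — area, axes, orientation, circularity `4πA/P²`, intensity
   statistics; 13 Haralick statistics from 64-level co-occurrence matrices
   with background transitions removed, averaged over the offsets
   (0,1), (1,0), (1,1), (−1,1); spindle-channel statistics on
   dilated/eroded/toroidal regions around the chromatin mask; sister
   centroid distance and metaphase-plate rotation readouts.
5. **Synchronization** — each trajectory frame gets a state label
   (1 interphase, 2 prophase…early anaphase, 3 late anaphase/telophase).
   The IP anchor is found by temporally constrained two-cluster splitting
   (TC3) of (area, circularity, mean intensity, intensity std.), the MA
   anchor as the first frame whose sister distance exceeds a threshold.
   Any per-frame classifier can be plugged in through a state-probability
   table decoded by Viterbi over an HMM that only allows 1→2→3 (or all-0).
   Manual two-click annotations (CSV) override either, and are copied to
   the sibling cell.
6. **Analysis** — event-anchored normalization, recovery percentages
   (100% = all selected features back at their interphase means), windowed
   regression slopes, metadata/feature-range selection, fold-change
   feature ranking with an HTML report, grouped statistics (two-sample t,
   ANOVA, Wilcoxon rank-sum, Kruskal–Wallis, two-way treatment×time ANOVA)
   and aligned heatmap/mean±sd/violin/box/histogram plots.

A **synthetic movie generator** (`mitotrack.simulate`) renders all of
these dynamics with complete ground truth, so the entire pipeline is
testable offline; see `docs/methods.md` for the model and its limits.

## Worked example

```python
import numpy as np
from mitotrack import SimParams, generate_movie, run_pipeline
from mitotrack.report import fold_change_table

params = SimParams(image_size=(340, 340), n_frames=100, n_cells=5,
                   n_divisions=2, division_schedule=[(1, 36), (2, 34)],
                   seed=7)
movie, truth = generate_movie(params)
project = run_pipeline(movie)

print(f"cells extracted:      {project.n_cells}")
print(f"synchronized:         {int(project.valid.sum())}")
print(f"IP anchors (frames):  {project.ip.tolist()}")
print(f"MA anchors (frames):  {project.ma.tolist()}")
table = fold_change_table(project).set_index("feature")
print(f"mean_int fold at IP:  {table.loc['mean_int'].fold_ip:.3f}")
print(f"area fold at IP:      {table.loc['area'].fold_ip:.3f}")
rec = project.ts["derived/recovery"]
print(f"recovery at +60 min:  {np.nanmean(rec[:, 50]):.1f} %")
```

prints

```
cells extracted:      4
synchronized:         4
IP anchors (frames):  [20, 20, 20, 20]
MA anchors (frames):  [30, 30, 30, 30]
mean_int fold at IP:  1.346
area fold at IP:      0.360
recovery at +60 min:  98.3 %
```

Both divisions yield a sister pair (4 cells).  Each trajectory window
starts 30 frames before the division, so the IP anchor at frame 20 means
chromatin condensed 10 frames (30 minutes) before anaphase onset — exactly
the generator's configured prophase length.  The intensity fold change at
the IP transition (1.346) recovers the simulated condensation gain (1.4,
diluted by the constant image background), the area fold (0.360) equals
the configured shrink factor squared (0.6² = 0.36), and one hour after
anaphase onset the daughters' recovery score is ~98%, i.e. area, minor
axis, mean intensity and intensity std. have returned to their interphase
means.

The same analysis is available from the shell:

```sh
mitotrack simulate --out movie/ --n-cells 5 --n-frames 100 --seed 7
mitotrack run --chromatin 'movie/chromatin_t*.tif' \
              --second 'movie/second_t*.tif' \
              --meta treatment=Scrambled --out project.h5
mitotrack export --project project.h5 --out tables/
mitotrack report --project project.h5 --out report/
```

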