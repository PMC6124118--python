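# trabspec

Simulated k-space texture analysis of trabecular bone.

Osteoporosis thins the struts (trabeculae) of cancellous bone and widens the
marrow spaces between them, long before a fracture reveals it. High-resolution
micro-CT can measure these changes ex vivo, but an MR acquisition that probes
*individual spatial frequencies* of the tissue — one k-value per excitation,
magnitude only — could detect them in vivo, fast and motion-robustly.
`trabspec` is the in-silico validation workbench for that idea: it simulates
such band-limited k-space measurements on 3D binary bone volumes and asks how
well a tiny set of spectral samples separates healthy from degraded
microarchitecture.

It is aimed at researchers in quantitative bone imaging and MR sequence design
who want a reproducible, fully synthetic test bed — the pipeline runs end to
end from generated microstructure, with no proprietary histomorphometry
software and no access to scanner hardware.

## The metric

A cubic volume of interest (VOI, default $(5\,\mathrm{mm})^3$) is divided into
25 prisms of $1 \times 1 \times 5$ mm. Each prism is collapsed (averaged) over
its cross-section to a 1D occupancy signal $s(x)$ along the analysis
direction; the magnitude of its DFT, $|\hat s(k)|$ (DC excluded), is averaged
across prisms. With mean spectral magnitude $\bar S(k)$, the diagnostic
**ratio metric** is

$$ R \;=\; \log_{10} \frac{\langle \bar S \rangle_{k \in [1.0,\,1.8]\ \mathrm{mm}^{-1}}}
                          {\langle \bar S \rangle_{k \in [3.8,\,7.4]\ \mathrm{mm}^{-1}}} $$

The low band sits at the trabecular-*spacing* scale (wavelengths 0.56–1 mm)
and the high band at the trabecular-*thickness* scale (0.13–0.26 mm); at the
5 mm nominal analysis length they contain 5 and 19 k-values respectively — few
enough to acquire directly. $R$ is invariant to signal scale and offset. Bone
degradation is simulated by 3D morphological erosion (cubic kernel, despeckle
cleanup), and a one-feature linear max-margin classifier on $R$ is scored by
sensitivity/specificity under stratified five-fold cross-validation repeated
50 times.

## Worked example

```sh
# a synthetic trabecular volume: 25 x 5 x 5 mm at 0.04 mm voxels, BV/TV 16%
trabspec generate --seed 4 --shape 625 125 125 --voxel-size 0.04 --out bone.tif
# simulate disease: erode one voxel layer (~40 um) off every surface
trabspec preprocess bone.tif --no-otsu --erode-radius 1 --out eroded.tif
# per-VOI ratio metrics (5 VOIs per condition)
trabspec measure bone.tif   --condition baseline --out base.csv
trabspec measure eroded.tif --condition eroded   --out eroded.csv
```

`generate` prints `wrote bone.tif (BV/TV 0.1600)` — the quantile threshold
pins the bone volume fraction exactly; erosion drops it to `0.0145`. The
metric records look like

```
voi_id,analysis_axis,condition,metric
voi_0000,0,baseline,0.7916111492439386
voi_0000,0,eroded,0.6465183031752912
```

— erosion *lowers* the metric on this microstructure (the baseline VOIs sit
near 0.79, eroded ones near 0.65). Concatenating both CSVs and classifying:

```sh
trabspec classify --train all.csv --repeats 5
```

```json
{
  "decision_boundary": 0.7185567263468962,
  "diseased_above": false,
  "sensitivity_mean": 1.0,
  "specificity_mean": 1.0,
  ...
}
```

i.e. a threshold at $R = 0.719$ separates the two conditions perfectly on
this small, well-separated example. `trabspec sweep bone.tif eroded.tif
--seed 2 --out sweep.csv` repeats the evaluation using only the first $m$
prisms ($m = 1..25$, i.e. 1–25 mm² of acquired cross-section) and shows the
accuracy cost of acquiring less tissue. `trabspec histomorph` reports Tb.Th,
Tb.Sp, Tb.N and BV/TV of any binary volume via a largest-inscribed-sphere
local-thickness map.

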