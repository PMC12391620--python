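# Methods

## Scope and design

`dropscreen` models the computational side of an image-activated droplet
screening experiment: droplet generation and loading statistics, image
formation, detection, CNN counting, feature-based gating, sorting, and
population statistics. Hardware physics (chip fabrication, fluidics,
dielectrophoresis, camera timing) is out of scope; where it touches the
computation it is abstracted into explicit stochastic error terms.

## Encapsulation statistics

A droplet of diameter *d* µm holds `V = πd³/6` µm³ = `πd³/6000` pL
(80 µm → 268 pL ≈ 270 pL at two significant figures). Cell loading is
Poisson per cell type with mean `λ = c·V`; the defaults, 3×10⁶ effector and
6×10⁶ target cells mL⁻¹, give `λ_eff = 0.80`, `λ_tgt = 1.61` — an average
1:2 effector:target ratio. `equivalent_bulk_concentration` inverts the
volume relation (one cell per 80 µm droplet ≡ 3.7×10⁶ cells mL⁻¹).

## Killing model

Each effector independently receives a phenotype from
`(non_killer, single_killer, serial_killer)` with default probabilities
(0.65, 0.26, 0.09). A killer eliminates live targets sequentially with
independent `Exp(kill_rate)` waiting times (default 0.5 h⁻¹) until its
capacity (1, or `serial_capacity = 3`) is spent, no live target remains, or
it dies itself. All cells also face baseline exponential death:
0.003 h⁻¹ for targets (high spontaneous viability) and 0.01 h⁻¹ for
effectors. The effector rate deserves a note: encapsulated NK viability is
essentially intact through 6 h and visibly reduced only toward the end of
an 8 h window, which a constant hazard can only approximate; 0.01 h⁻¹
(≈94% viable at 6 h, ≈92% at 8 h) reproduces that late, mild decline,
whereas a substantially larger constant rate would flood the 6 h
serial-killer gate with "one kill + effector died" look-alikes and distort
the sort purities the model is meant to study. Only the 9% serial fraction
is anchored to observed parent populations; all rates are config-exposed.

Kill times, baseline death times and victim choices are drawn per droplet;
a target's death time is the minimum of its baseline and kill times, with
attribution (`killed_by`) kept for the winner only. Per-timepoint
live/dead counts follow deterministically, so `live + dead` always equals
the encapsulated count.

## Image formation

Default scale is 1.0 µm/pixel; an 80 µm droplet spans 80 px inside a
96×96 px crop (tiled fields use the same 96 px pitch). Cells draw uniform
diameters from 8–14 µm and are rejection-placed uniformly in the droplet
disk; a pair may overlap by at most 30% of the smaller radius by default
(raising the cap produces the clustered, hard-to-count droplets used in the
degradation tests). Channel semantics: brightfield carries a dark rim ring
and dim cell disks on a bright background (20,000 counts, rim 8,000);
lineage stains light every cell of their type at 4,000 counts over a
400-count background; the apoptosis channel lights dead cells of either
type co-located with their lineage disk. Gaussian blur (σ = 1 px) and
Gaussian read noise (σ = 60 counts) finish the image; all channels are
16-bit. The three artifact classes are rendered as: a bright disk occluding
part of the droplet (bubble), the droplet centre moved to within the crop
radius of the image border (edge cut-off), and 3× blur (double emulsion
layer).

The generator reproduces the features the analysis relies on — stoichiometry
statistics, co-localised death staining, boundary/area geometry, artifact
appearance — but not real-microscope physics: no point-spread-function
model, vignetting, stage drift, droplet shrinkage or motion blur, and
cells are re-placed independently at each rendered timepoint. Passing
tests therefore validate the algorithms under controlled conditions, not
performance on any particular microscope's data.

## Detection

Brightfield frames are percentile-normalised, edged with Canny (σ = 2),
and voted into a circle-Hough accumulator over radii 0.8–1.2× nominal in
2 px steps. Normalised peaks must collect ≥50% of the theoretical
perimeter votes; greedy non-maximum suppression (score-descending, ties by
discovery order) forbids two centres closer than `r_min`. On clean fields
this yields ≥99% recall and precision at 5 px tolerance; crops are padded
with the channel background where they cross the field edge and flagged
`edge_truncated`.

## Count models

Both classifiers are small convolutional networks written directly in
NumPy (im2col 3×3 convolutions, ReLU, 2×2 max-pool, global average
pooling, linear softmax heads, Adam, cross-entropy averaged over heads).
Inputs are average-pooled 2× (96→48 px) and standardised per channel with
fixed constants tied to the 16-bit rendering scale (brightfield
(x−0.30)/0.05, fluorescence (x−0.010)/0.012 after division by 65535) —
deliberately *not* per-image statistics, so absolute intensity remains
informative. Augmentation is right-angle rotations and flips only, since
droplet crops have no canonical orientation.

The outlier model reads brightfield alone and classifies usable vs
artifact. The count model reads all four channels into one shared trunk
(10/20/40 filters) with four parallel classification heads over classes
0–"5+" (live/dead × effector/target); a config switch
(`shared_trunk=False`) instantiates fully separate per-head trunks at
higher cost. With defaults (12 epochs, batch 64, lr 2×10⁻³, seed-fixed),
training 8,000 crops takes ~6 minutes on one CPU and reaches ≥95% exact
count accuracy per head on held-out synthetic droplets; accuracy is highest
for low cell counts and degrades as the rendered overlap cap rises.
Training is bit-reproducible for a fixed seed on a given platform.

## Gating and sorting

Fluorescence frames are thresholded strictly (`> t`); the default manual
threshold is the midpoint of the configured background and signal levels,
with Otsu available as the automatic alternative. Features are computed
over the whole droplet disk (not per component): `area` = foreground pixel
count, `contour` = foreground pixels with a background 4-neighbour (pixels
beyond the image edge count as background). Polygon gates are evaluated by
ray casting with configurable boundary inclusion, winding normalised on
load; all gates of a strategy AND together and set the exclusive trigger.

Gate calibration takes a labelled droplet split, trims each count-class
feature cloud at 3.5 robust (MAD) z-units, and wraps the requested classes'
convex hull, expanded outward by a margin (default 6 feature units);
degenerate clouds — e.g. the empty-apoptosis class collapsing onto the
origin — fall back to a padded bounding box. Open-ended "≥ k cells"
criteria use a lower-left box whose corner sits midway between the
(k−1)-class cloud's 95th percentile and the ≥k cloud's 5th percentile in
each feature dimension.

The sorter's timing-error model has two terms: with
`frame_drop_probability` (default 0.005) a droplet passes unimaged and
follows the default (negative) electrode state; with
`misroute_probability` (default 0.01) the trigger window is mis-synchronised
by one droplet period, so the droplet is routed by its *predecessor's*
trigger. The window-shift form matters: it makes wrongly collected
droplets scale with the positive rate (about one misrouted droplet per
hundred sorted, in rare-positive and common-positive sorts alike), which is
how a tuned delay/trigger-length system actually fails; a symmetric
per-droplet flip at the same rate would swamp rare-positive sorts with
false positives out of all proportion to the device behaviour being
modelled.

Purity is always scored against ground truth — the in-silico analogue of
re-imaging the sorted emulsion. For the non-cytotoxic sort the scored
predicate is "no kill occurred in the droplet": the gate itself carries no
effector criterion, so effector-free droplets can be collected, and judging
them "impure" would say nothing about gating quality. The serial-mode
predicate is "exactly one effector, and it killed ≥2 targets over the full
assay window". The serial sort's purity ceiling is set by biology rather
than optics: a single killer whose one victim *plus its own death* yields
two apoptotic cells is indistinguishable from a serial event in any
apoptosis-count gate, which keeps serial purities in the 60–75% range under
the default rates.

## Statistics

All statistics skip outlier-flagged droplets and accept predicted or
ground-truth counts interchangeably (they agree exactly under perfect
prediction). Kills are counted as dead targets in the droplet — the
apoptosis reporter cannot attribute cause — with optional baseline
correction (off by default) that subtracts the expected spontaneous death
measured from target-only single-cell droplets. Dead effectors never count
as kills; droplets whose effector died are retained. Kill counts bucket at
"3+", mirroring the count model's "5+" cap. Droplet identity across
timepoints uses nearest-centre matching within 0.5 radius (static
observation chamber), a documented helper rather than a motion tracker.

## Problem sizes and reproducibility

The shipped benchmarks use 9,000 crops (8,000 train / 1,000 test) for the
count model and 5,000-droplet streams with 1,500 calibration droplets for
each sort simulation; the test suite exercises the same code paths at
reduced sizes chosen to keep a full run comfortably on one CPU. Every
stochastic stage draws from a named child stream of one master seed
(CRC-mixed through `numpy.random.SeedSequence`), so stages are individually
reproducible and identical config + seed reproduces CSV/JSON artifacts byte
for byte.

## Known limitations

- Constant-hazard baseline death only approximates late-onset NK mortality;
  a time-varying hazard would need data the generator does not model.
- The renderer's simplified optics make the counting task cleaner than real
  microscopy; reported accuracies are upper bounds for real data.
- Gates are calibrated per simulated dataset; no attempt is made to model
  day-to-day drift that manual gate placement absorbs in practice.
- The sorter abstracts all timing physics into two probabilities; it cannot
  reproduce throughput-dependent effects (droplet spacing, multi-droplet
  windows).
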