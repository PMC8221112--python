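# Methods

## Overview

`histocyte` implements a quantitative "cells-as-cytometry-events" analysis of
multispectral fluorescence images of secondary lymphoid tissue, together with
a ground-truthed synthetic scene simulator that makes every stage of the
analysis verifiable without external data. The analysis chain is

    render/load → spillover compensation → (MIP) → nuclear segmentation →
    per-cell features → compartment mapping → thresholds → hierarchical
    gating → quantification → (RNAscope spot analysis)

All randomness derives from a single integer seed; identical configuration
and seed reproduce identical outputs bit for bit.

## The synthetic tissue model

A scene is a 2D field (µm frame) containing elliptical B-cell follicles in
an extrafollicular (EF) space. Each follicle consists of a mantle zone (MZ)
ring around a concentric germinal center (GC) ellipse whose area is
`gc_fraction` of the follicle; the dark zone (DZ) is a sub-ellipse of the GC
(area `dz_fraction` of the GC, offset toward one pole), and the light zone
(LZ) is the GC remainder. Defaults for the reference scenes: 9 follicles
with semi-major axes 110–160 µm in a 1.1 × 1.1 mm field, `gc_fraction`
0.45, `dz_fraction` 0.45.

Follicles are laid out on a jittered grid (one follicle per randomly chosen
grid cell, center uniformly jittered within the clearance the cell allows);
this guarantees non-overlap with a configurable inter-follicle margin for
any feasible geometry and any seed, where rejection sampling fails
sporadically at the reference packing density.

Cells are placed by hard-core (Poisson-disk) sampling with minimum spacing
0.8 × (2 × mean nucleus radius); nucleus radii are normal (3.0 ± 0.35 µm,
clipped). Per-compartment cell counts are `density × compartment area`
(10 000 cells/mm² in the reference scenes — chosen as a plausible density
for dense lymphoid tissue; no published figure constrains it, and the
recovery targets are composition ratios that do not depend on it). Each
cell draws a phenotype from the compartment's composition (multinomial) and
a true expression level per marker from a log-normal with the phenotype
profile's mean and CV (0.25 throughout). Expression levels encode
hi/dim/negative modes (e.g. CD20: 220 / 60 / 0), which gives the
thresholdable multimodality of real immunofluorescence.

Rendering: nuclear markers (Ki67, Bcl-6, FoxP3, Helios, pH2Ax, and the DNA
stain) paint a soft-edged disk over the nucleus; surface/cytoplasmic markers
paint a thin shell from 0.85 × r to r + 0.6 µm, **clipped to the cell's
territory** (nearest-nucleus/Voronoi region). The clipping encodes the fact
that in packed tissue the membrane of one cell lies at the midline to its
neighbour — without it, the rim of a bright B cell would paint the nuclear
area of an adjacent T cell and no threshold could separate the populations.
The FDC meshwork is a random dendritic skeleton dilated to ~1 px and
confined to GC ellipses; vRNA puncta are soft dots of radius 0.5 µm placed
on a cytoplasmic ring around vRNA+ cells or on the mesh (FDC-bound), with a
minimum spacing of 2.2 punctum radii so that the dots are resolvable —
matching the discrete-dot signal model of tyramide-amplified in situ
hybridization.

The optical model is linear: observed = Mᵀ·true per pixel for a spillover
matrix M with unit diagonal (block structure mirrors sequential-excitation
grouping: spillover only within groups of 2–3 spectrally adjacent
fluorophores, 0.03–0.12 off-diagonal), plus constant autofluorescence
(2 counts), Gaussian PSF blur (σ 0.4 µm), Poisson shot noise and Gaussian
read noise (σ 1.5), clipped to the bit depth. A thin z-stack mode spreads
the 2D render over 3–5 slices with triangular weights for testing maximum
intensity projection.

What the simulator does **not** emulate: 3D optics and depth-dependent PSF,
photobleaching, tile stitching seams, antibody off-target binding,
cell-shape irregularity (nuclei are disks), spatially structured
autofluorescence, and biological gradients within a compartment
(compositions are homogeneous per compartment). Passing recovery tests
therefore demonstrates correctness of the computational chain under a
linear, geometrically idealized image-formation model — not performance on
real tissue sections.

## Spillover estimation and compensation

M is estimated from single-stain renders (one fluorophore expressed at a
time, identical optics). For fluorophore f, foreground pixels are those
above the 0.98 quantile of f's own channel; after subtracting each
channel's background (median over non-foreground), entry [f, g] is the
median of per-pixel ratios channel-g / channel-f over the foreground.
Median-of-ratios was chosen over least squares because it ignores
autofluorescence and noise outliers; least squares is available as an
option. Compensation solves Mᵀ·true = observed per pixel and clamps
negative solutions to zero (downstream gating assumes non-negative
intensities). The estimate is scale-invariant and accurate to well under
±0.02 per entry at the reference noise level.

## Segmentation and features

Nuclei are segmented on the DNA channel: Gaussian smoothing (0.4 µm),
Otsu threshold, hole filling, and a distance-transform watershed whose
seeds are distance-map maxima at least 1.5 µm apart. Components outside
[min_area, max_area] are dropped (defaults: area of a 2 µm-radius circle;
4 × the median component area). These defaults were calibrated on the
simulator's ground truth to keep count error within a few percent at
reference packing; they are all exposed in the fixture configs.

Features per cell: mean intensity per channel over the label's pixels
(an optional erosion margin is supported but the shipped configs use the
full label), centroid in µm with the pixel-center (index + 0.5) convention,
area = pixel count × pixel_size², and circularity 4πA/P² with the Crofton
perimeter (less pixelation bias than boundary counting). Area and
circularity are exported under the column names `volume` and `sphericity`
to match the vocabulary of cytometry-style spreadsheets (downstream gates
such as `Volume^hi` use these names).

## Compartment mapping

Follicles are detected on the **B-cell occupancy field**: pixels above
3.5% of the CD20 channel's bright level (p99.9) are binarized and smoothed
at 10 µm, giving the local areal fraction of CD20⁺ staining. This weighs
CD20^dim mantle B cells and CD20^hi light-zone B cells equally — an
intensity-weighted density bulges at the bright LZ and recedes over the dim
MZ, distorting the follicle outline. The follicle mask is occupancy > 0.40
of the plateau (97th percentile), majority-smoothed at 3 µm, filled, with
components under 8 000 µm² discarded. On reference scenes this recovers
follicle outlines with Jaccard ≈ 0.88 against the true ellipses.

Within each follicle, the GC is the smoothed-Ki67-dense region above 0.06
of the follicle's Ki67 amplitude, morphologically opened (2 µm) and then
closed (8 µm, distance-transform implementation), largest component kept;
the DZ is the largest connected sub-region above 0.5 of the amplitude;
LZ = GC \ DZ, MZ = follicle \ GC. The closing step matters for unbiased
composition readouts: pockets of Ki67-negative cells (T cells, macrophages,
DCs) dent the proliferation-density mask, and without reclaiming those bays
the GC mask excludes non-B cells preferentially (in development this biased
GC T-cell fractions low by ~20% relative). Marker polarity is configurable:
the RNAscope panel detects
follicles as CD3-occupancy *minima* (T-cell-poor islands), without GC
subdivision (no proliferation marker in that panel).

Cells are assigned the region and follicle instance at their centroid pixel
(unambiguous for boundary-straddling cells). The T-cell zone used for
regulatory T-cell denominators is CD4-dense EF (smoothed CD4 above 30% of
the EF amplitude) — the source analyses report "T cell zone" frequencies
without a formal definition, so this one is the package's own.

## Thresholding and gating

Cutpoints are derived per channel on log1p mean intensities:

- `gmm` — Gaussian mixture, cuts at posterior-equality points between
  adjacent components (the textbook choice; used when modes are clean).
- `gmm_edge` — same fit, cut at `k_sigma` (default 2.2) SDs below the upper
  component's mean, never below the inter-mode midpoint. Robust when the
  negative bulk has heavy non-Gaussian tails (residual spillover, blur
  bleed-through from adjacent bright cells): the gate hugs the positive
  population rather than the background. `n_components` may exceed the
  number of levels so surplus low components absorb the bleed-over shoulder
  (CD20 uses 4 components for 3 levels). This mirrors how a cytometrist
  places a gate at the edge of the positive cloud.
- `gmm_valley` — cut at the empirical density minimum between modes.
- `background` — median + k·MAD robust-background cut.
- `quantile`, `fixed` — explicit cuts.

Rare-marker channels (FoxP3, CD25, IL-10, Helios, CD68, CD163, MPO, CD11c,
CD123, CLEC9A, CD138, pH2Ax, GrzB, FasL, CD57) use `gmm_edge` with 3
components: on reference scenes this yields essentially zero false-positive
rate at 0–4% false-negative rate even for populations of a few dozen cells,
which matters because several reported populations are below 0.5%.

Gate trees are conjunctions of (channel, level) terms per node, applied
with full ancestor chains; `+`/`hi/dim` means above the first cut, `hi`
above the last, `dim` between, ties to the upper level. Feature terms
(`volume`, `sphericity`) gate on CellRecord fields; `Volume^hi` defaults to
the population median. The eight shipped panel fixtures transcribe the
published gating strategies (GC reactivity; Treg/Tfr; B cell; CD8; 
inflammation; structure; DC; RNAscope). The CD4/CD8 lineage gates use the
lineage marker alone (no `CD20⁻` co-gate): the edge-placed CD4 cut already
excludes B cells, while a CD20⁻ co-gate would discard the T cells that sit
against bright B-cell rims inside GCs and bias follicular T-cell
denominators low.

Quantification reports counts, relative frequencies (scope-total, parent,
or named-population denominators; a zero denominator yields a missing
frequency) and densities per mm² of tissue (nuclear-density support area).

## RNAscope

Spots are detected by Laplacian-of-Gaussian over σ 0.35–0.9 µm with
threshold 15 on the background-subtracted vRNA channel and non-maximum
suppression at 0.6 µm (parameters calibrated on the simulator's punctum
signal model and exposed in config). A spot over a nuclear label dilated by
1.5 µm (cytoplasmic rim — vRNA is cytoplasmic, nuclei are what is
segmented) is cell-associated, taking precedence over the FDC^hi mask;
remaining spots on the FDC^hi mask (dilated 1 µm to absorb centroid
localization error against the thin mesh) are FDC-bound virions, attributed
to the nearest detected follicle. A cell is vRNA+ iff it has
at least one assigned spot (an intensity-gate mode is also provided; the
spot criterion is the default because tyramide amplification makes per-spot
presence the robust readout).

## Problem sizes

Reference acceptance scenes are 1.1 × 1.1 mm at 0.5 µm/px with ≈ 12 000
cells and 9 follicles, five seeds per fixture — sized so that the binomial
standard error of the rarest reported frequency is comfortably below its
comparison tolerance. The test suite runs the same pipeline on ~0.5 mm
scenes (≈ 2 500 cells, 2 follicles), which keeps the whole suite in the
minutes range while leaving every recovery check at 3σ-level power.

## Known limitations

- Compartment sub-zone boundaries (LZ/DZ) are intensity-threshold
  constructs; cells within a PSF-and-smoothing length of a boundary can be
  assigned to the adjacent sub-zone (~4% of follicular cells at reference
  settings). Coarse F/EF/GC assignment agreement is ≈ 96%.
- Surface-marker mean intensities over nuclear labels are attenuated
  (~25% of the rim amplitude) and carry residual bleed from adjacent cells;
  gating absorbs this through the edge-placed cuts, but absolute intensity
  values are not calibrated to expression units.
- The spillover estimator assumes one emitting fluorophore per single-stain
  image and block-diagonal-dominant mixing; it is not a spectral unmixing
  of arbitrary lambda stacks.
- Threshold derivation is per-scene; no cross-specimen batch normalization
  is attempted.
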