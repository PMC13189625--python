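# Methods

This note documents the models, defaults and numerical choices behind
`synprox`, and what the synthetic-data validation does and does not show.

## Spectral-count simulation

`simulate_count_table` draws one protein × sample matrix from a
Gamma–Poisson (negative binomial) law with mean μ and variance
μ + φμ² (`dispersion` = φ). Background proteins share the same mean
(`background_mean`, default 5 spectra) in bait and control; a fraction
`frac_true` (default 5%) of proteins is planted as true interactors whose
bait mean is multiplied by `fold_true` (default 6). `dropout_ctrl` lets a
true interactor vanish from individual control samples, emulating
bait-only hits. The default design is two bait and two control samples —
the whole pull-down performed twice.

**Default dispersion is 0 (the Poisson limit).** The interaction scorer's
count likelihood is Poisson, and the generator's default emulates the model
under which that score is calibrated; low-abundance spectral counts are
close to Poisson in practice. Overdispersion is a first-class parameter for
robustness studies: identifiability of a 6-fold enrichment from 2 + 2
replicates degrades quickly as φ grows (at φ ≥ 0.05 even the oracle
likelihood-ratio classifier can no longer hold sensitivity and precision at
0.8 simultaneously for this design), which is a property of the design, not
of the estimator.

All randomness in a simulation call flows from one `numpy` generator seeded
by the config, so identical config + seed reproduces the table bit for bit.

## Interaction scoring

The mean ratio uses a pseudocount (default 0.5) in numerator and
denominator because bait-only hits (control mean 0) are common and
informative; the threshold is applied strictly (ratio > 3 by the mouse
convention, > 2 for the zebrafish arm — both exposed, species presets set
the default). The score is the replicate-averaged two-component posterior
described in the README with prior π = 0.1 and the true-component rate
floored at `min_fold_constraint` × λ_F (default 1.0) so a depleted protein
can never invert the components; equal evidence scores exactly π, which
pins the score's scale. Note the score is *not* monotone in a single bait
count: raising one replicate raises λ_T (the bait mean) and can lower the
other replicates' posteriors. The monotone quantity is the per-replicate
posterior at fixed rates, which is what the property suite asserts.

Candidate lists are sorted by descending ratio with protein id as a
deterministic tie-break. Cross-species conservation counts a candidate as
shared when any orthologue appears in the other species' list; the Jaccard
index is n_shared / (n_A + n_B − n_shared) over the two lists.

## Image simulation

`simulate_puncta_image` emulates an Airyscan-style acquisition of synaptic
puncta: a 512 × 512 field at 50 nm pixels (25.6 µm square), seven slices
spanning 1.08 µm (0.18 µm step). Punctum counts per channel are Poisson
with intensity `density × area` (default 0.08 µm⁻² per channel); radii are
normal (0.15 ± 0.03 µm, floored at a third of the mean); each punctum is a
hard disk with a Gaussian axial profile of sd = one slice, rendered
additively, blurred laterally with a Gaussian PSF (σ = 0.08 µm), scaled to
photons (`photon_scale` = 200 at unit amplitude over a flat background of
0.005), Poisson-sampled and read-noise-corrupted (σ = 1 ADU), and stored as
16-bit. `photon_scale=None` disables the noise model for geometric tests.

`round(coloc_fraction × n_cand)` candidate puncta are planted on randomly
chosen reference puncta with the center displaced uniformly inside a disk
of radius 0.5 (r_ref + r_cand), which guarantees the ground-truth disks
intersect (clipping at the field boundary can only shrink the
displacement); the planted candidate also inherits its host's z position.
The remaining candidates are uniform, so at `coloc_fraction = 0` the two
channels are independent (checked against complete spatial randomness via
the nearest-neighbour distance distribution).

What the simulator does **not** model: retinal lamination (flat fields
only), anisotropic or depth-varying PSFs, chromatic offsets between
channels, autofluorescent structures, or intensity correlation between
truly colocalized partners beyond spatial overlap. Passing tests therefore
show that the measurement chain is unbiased and calibrated under a clean
punctate model, not that it is robust to structured background in real
tissue.

## Segmentation

The Triangle (Zack) threshold is computed on the histogram pooled over the
entire z-stack of a channel at native integer resolution (no rebinning).
The dialect is pinned: the histogram is mirrored first if the peak is
nearer the bright end; the line runs from the peak bin to the last nonzero
bin; the threshold is the bin maximizing perpendicular distance to that
line over bins strictly after the peak, first index on ties, mapped back
through the mirroring; foreground is strictly above the threshold. This
construction is verified bin-exactly against an exhaustive scan and loosely
(± 3 bins) against scikit-image's independent implementation.

Particle analysis runs in 2D after a maximum-intensity projection (a
per-slice-OR mode is available); connected components use 8-connectivity by
default; objects outside `[min_area_px, max_area_px]` are dropped. The
config default is no size filter, but every noisy-image analysis in the
test and acceptance suites passes `min_area_px = 12` (≈ 0.03 µm², about
half the area of the smallest credible punctum) to reject single-pixel shot
noise — the standard minimum-size setting of any particle-analysis
workflow. ROI membership is by centroid in the half-open box
[origin, origin + extent), so tiled ROIs never double-count; the default
ROI extent is 20.07 × 32.91 µm², the sublayer-sized sampling box.

## Colocalization and its nulls

A reference punctum is colocalized when it satisfies the overlap rule
against the candidate mask: ≥ 1 shared pixel (default), centroid inside the
candidate mask, or ≥ k shared pixels. Candidate objects larger than
`size_criterion_px2` (default 10,000 px² = 100² pixels, i.e. 25 µm² at
50 nm pixels) are excluded first — a guard against confluent aggregates
that would trivially overlap everything. The flip control mirrors the
reference mask about the image's vertical midline (whole-image mirror, so
the candidate channel keeps its context), re-derives objects and
re-measures; the flip is an involution and mirror-symmetric candidate masks
give exactly equal original and flipped percentages, both asserted exactly.

As an internal cross-check (not part of the headline statistic),
`expected_chance_overlap` reports the Boolean-model approximation
100 (1 − exp(−λ_c A_dil)) — λ_c the candidate object density, A_dil the
mean candidate area dilated by the mean reference radius, floored by the
candidate coverage fraction where the Poisson-disk model breaks down — next
to a Monte-Carlo estimate over ≥ 1000 toroidal translations of the
reference labels, with its standard error. The flipped percentage sits at
this chance level on unplanted scenes.

ROIs with zero reference puncta have an undefined percentage and are
flagged and excluded from aggregation. The paired original-vs-flipped test
requires ≥ 3 pairs; normality of the differences must pass **both** the
Anderson–Darling and D'Agostino–Pearson tests at α = 0.05 to use the paired
t-test, otherwise the Wilcoxon signed-rank test is used (scipy's exact
null for small tie-free samples). Below 8 pairs the D'Agostino–Pearson
statistic is undefined and the Wilcoxon branch is always taken. All-zero
differences return the degenerate p = 1.

## Group comparisons

The unit of analysis is the ROI (matching a 22–32-ROIs-per-analysis
design); there is no mixed-effects nesting by animal, which is a known
limitation — ROI-level inference overstates precision when ROIs within an
animal are correlated. Two genotypes are compared by the two-tailed
Mann–Whitney U (exact enumeration for small tie-free samples, midranks
with normal approximation and continuity correction otherwise, via scipy);
more than two groups route to one-way ANOVA. Groups need ≥ 3 ROIs.

The power analyses use lognormal ROI-to-ROI variability with σ = 0.35 on
the log scale — a coefficient of variation of ~36%, typical of puncta
densities re-measured across sampling boxes — and a planted 40% knockout
reduction; at 25 ROIs per group the Mann–Whitney test has power ≈ 1 and
the label-permutation null rejects at the nominal 5%.

## Problem sizes and determinism

The validation suites run the proteomics arm at 2000 proteins × 20 seeds
and the imaging arm at the default 512 × 512 field over 20 seeds × 4
planted fractions, with 2000-replicate null calibrations and 500-replicate
power runs; the full test suite and the acceptance script each complete in
about a minute on one CPU. Every simulation is reproducible bit for bit
from its config and seed; the pipeline manifest records SHA-256 hashes of
every output so reruns are verifiable.
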