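# Methods

This note records the models implemented in `merscreen`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical choices a maintainer would want to know.

## Codebooks

A codebook is a set of length-*n* binary codewords of constant Hamming
weight *w* with all pairwise Hamming distances ≥ *d* = 4. Constant weight
equalizes per-round signal density; distance 4 gives unique single-bit
error correction because radius-1 Hamming spheres around codewords are
disjoint.

**Construction.** Weight-*w* words are partitioned by Σ(set-bit positions)
mod *n*. Two distinct words at distance 2 differ by moving one bit from
position *i* to *j*, changing the class key by *j* − *i* ≢ 0 (mod *n*);
therefore words sharing a class are at distance ≥ 4. The largest class
holds at least ⌊C(n,w)/n⌋ words (285 for n=21, w=4; ≥ 1031 for n=18,
w=6), so the platform sizes (209 genes, 456 barcodes) are always
attainable. The class is then greedily augmented from the remaining words
in a seeded shuffled order, accepting a word when its maximum overlap with
every accepted word is ≤ w − d/2. At (21, 4, 4) the construction already
yields 285 = A(21, 4, 4) words, the known optimum; at (18, 6, 4) it
reaches 1044. Generation is deterministic given the seed; distances of
every generated code are re-verified exhaustively (O(K²n) via overlap
matrices).

**Decoding.** Exact match → distance 0; otherwise a call is made only if
exactly one codeword lies within the correction radius (0 or 1); distance
ties are never broken arbitrarily — they are no-calls. Blank codewords
(codewords never assigned a target, default 10% of the assigned count)
decode like coding words but are flagged, which is what makes the
misidentification estimate possible downstream. Scheduling assigns bits
consecutively to (round, channel) slots, ⌈n/colors⌉ rounds at 3 colors per
round by default.

## Padlock probe design

Each 60-nt target window splits into two 30-nt halves. The donor
(5′-phosphorylated) arm is the reverse complement of the left half, the
acceptor (3′) arm of the right half; on hybridization the acceptor's 3′
end abuts the donor's 5′ end and the nick is sealed by ligation. The
donor's 5′ base therefore pairs with target position start+29, and
windows whose donor 5′ base is G or C are excluded (nick-sealing ligases
discriminate poorly there). Which transcript half is "donor" is a
convention; coordinates are stored so the opposite convention is
reconstructable.

**Filters** (all must pass, per arm where applicable): GC ∈ [0.30, 0.70];
Tm ∈ [60, 80] °C; gene specificity index ∈ [0.75, 1]; isoform specificity
index ∈ [0.7, 1]; longest exact match to rRNA/tRNA ≤ 15 nt; junction base
∉ {G, C}. Emitted probes re-pass the filters idempotently.

**Tm model.** Nearest-neighbor thermodynamics (SantaLucia unified
parameters, via Biopython) with the entropy salt correction at 300 mM
monovalent salt and 25 nM strand concentrations, plus a linear formamide
correction of −0.6 °C/%. The design filter evaluates Tm at 0% formamide:
the 60–80 °C window refers to the standard-condition duplex stability, and
a 30% formamide correction (−18 °C) would place no 30-mer arm inside it.
Coefficients live in the function signature, not hidden constants.

**Specificity indices.** Defined here as unique-k-mer fractions at k = 15
(matching the 15-nt contaminant-homology rule): the gene index is the
fraction of the window's 15-mers occurring in no other gene; the isoform
index the fraction occurring in no other isoform of the same gene.
Abundance weighting is deliberately omitted. Contaminant homology is the
exact longest common substring against both strands of the rRNA/tRNA set,
found by binary search over substring length.

**Assembly.** Liberated probe = donor arm (30) + RCA primer site (20) +
one 15-nt readout complement per codeword on-bit + acceptor arm (30):
140 nt for weight-4 gene probes, 170 nt for weight-6 barcode probes, both
inside the intended ~140–170 nt envelope (a 23-nt primer site is also
provided as a constant; the 20-nt default keeps weight-6 probes inside
the envelope). PCR handles carrying BciVI (left) and BccI (right)
recognition sites flank the probe; the probe body is checked free of both
motifs on either strand, and candidate windows whose arms would introduce
one are rejected during design. Readout sequences are seeded random
15-mers with 33–67% GC, no homopolymer > 3, and no liberation-enzyme
motifs.

**Probe-set selection.** Windows are tiled at a 5-nt step. Among passing
candidates, an earliest-end greedy first establishes the maximum number of
mutually non-overlapping sites; when supply exceeds the budget (8 probes
per gene, 3 per 185-mer barcode), sites are chosen nearest to evenly
spaced anchors, maximizing spread along the transcript. Undersupply is a
warning, never an error. A 185-mer barcode admits three 60-nt windows only
under near-exact tiling, so barcodes are *designed*, not found:
`design_random_barcode` draws seeded candidates until one supports all
three probes, mirroring how barcode sequences are chosen in practice.

## Synthetic screens

The generator fixes the study conditions; its defaults are the conditions
every downstream guarantee is tested under.

* **Tissue.** Cells sit on a jittered grid (jitter 0.15 spacings; disk
  radius 0.9 × (0.5 − jitter) × spacing, so masks are exact and disjoint
  by construction). The zonal coordinate is z = d_cv/(d_cv + d_pv) against
  planted central-vein (lobule centers) and portal (lobule corners) point
  sets; subtypes Hep1–Hep6 are the sextiles of z, Hep1 most pericentral.
* **Transduction.** Per-cell guide count ~ Poisson(MOI), identities
  uniform over the library; MOI defaults to 0.3, inside the 10–30%
  infection range targeted for single-guide screens. Optional clonal
  patches copy a neighbor's guide multiset; patch statistics are a free
  parameter (left at 0 by default) since they are not constrained by any
  quantitative description.
* **Library.** 202 targeted genes × 2 guides + 50 negative controls = 454
  entries. Effect templates cycle 8:1:1 over target depletion only
  (factor 0.2, emulating nonsense-mediated decay of frameshifted
  transcripts), stress-set induction (2× on a 10-gene set), and zonal
  shift (δz = ±0.25 applied to the zonal-factor argument). Controls carry
  the identity effect.
* **Counts.** Per-cell, per-gene mean = baseline × exp(slope·(z − ½)) ×
  perturbation fold-changes, baselines log-normal and scaled to a
  300-molecule mean library size (inside the 25–1500 filter window);
  counts are negative-binomial with dispersion 0.25 (the noise model is a
  package choice; no specific model is prescribed by the assay).
  The 23 zonation marker genes are always present with the correct slope
  signs.
* **Images.** 2-D rendering, one plane per bit (the real assay images
  10-plane z-stacks; a single focal plane is the desk-scale choice).
  Each molecule is a Gaussian spot (σ 0.3 μm at 0.25 μm pixels) with a
  shared log-normal brightness in every on-bit plane after per-bit flips
  (p₁→₀ = 0.04, p₀→₁ = 0.01), over folded-normal background. Spurious
  blank-codeword molecules can be injected at a configurable rate
  (default 0: blank calls arise from bit errors, which is the mechanism
  the filter targets). For ≥10⁴-molecule runs, `simulate_spot_intensities`
  produces the per-spot intensity vectors directly — the spot-detection
  stage is exercised end-to-end on smaller rendered fields.
* **Flex tables.** Transcriptome UMIs are binomial thinnings (capture
  0.5); each true guide's probe receives ~Poisson(50) UMIs, all other
  guide probes Poisson(0.05) ambient counts, reproducing the bimodal
  histograms that make thresholded sgRNA calling work.

Passing tests on these simulations demonstrates the pipeline's logic —
error correction, filter calibration, statistical control, parameter
recovery — not robustness to optical registration error, segmentation
error, PSF anisotropy, batch chemistry effects, or ambient RNA beyond the
models above, all of which the generator deliberately omits.

## Decoding and misidentification filtering

Spots are local maxima of the across-bit maximum projection
(non-maximum suppression at 3 px, threshold 0.3); per-bit intensity is the
plane maximum within a 2-px disk. Intensities are normalized by each bit's
90th percentile over detected spots and binarized at 0.5 (neither constant
is prescribed by the assay; both are recorded here). Decoding uses the
radius-1 rule above.

The misidentification filter is a gradient-boosted tree classifier
(100 trees, depth 3) on five quality features — mean on-bit intensity,
mean off-bit intensity, their ratio, Hamming distance, spot area — with
blank-assigned molecules as negatives and coding-assigned as positives,
trained with 5-fold cross-fitting so every score comes from a model not
trained on that molecule. The retained set is the largest score-suffix
whose blank-based estimate m(c) = (blanks/blank codewords) ÷
(coding/coding codewords) stays ≤ 5%; candidate cutoffs sit on
distinct-score boundaries so the export is exactly {score ≥ cutoff} under
ties. Blank-assigned molecules are never exported. When decoding is so
clean that no blanks are called, the filter is degenerate and the whole
coding set is exported with m = 0.

## Calling and filters

Imaging barcodes: a guide is called iff its per-cell molecule count is
strictly greater than 3 (the boundary count of exactly 3 is not called).
Sequencing sgRNAs: a guide is called iff its probe UMI count reaches its
threshold, inclusive; the strict-vs-inclusive choice at exact equality is
a convention, fixed here as inclusive and documented. The default sequencing threshold is
max(5, ⌈95th percentile of ambient counts⌉ + 1), ambient meaning every
count that is not its cell's argmax; per-guide thresholds are accepted.
Only cells with exactly one called guide enter perturbation analyses.
Cell filtering (totals in [25, 1500], boundaries kept) precedes gene
filtering (expressed in ≥ 3 remaining cells), and that order is fixed.

## Statistics

* **Normalization.** Counts are scaled to 10,000 per cell and
  log1p-transformed. Optional covariates (cell area, molecule count) are
  removed per gene by least squares. z-scores use the control-cell mean
  and sd per gene, computed within batch and concatenated; zero-variance
  genes in controls are excluded and listed.
* **Energy distance.** E(X,Y) = 2 E d(X,Y) − E d(X,X′) − E d(Y,Y′) with
  squared Euclidean distance on the first 20 PCs (configurable to
  Euclidean; the convention is recorded in the output). Means are taken
  over all ordered pairs (V-statistic), so identical sets give exactly 0
  and with squared Euclidean the statistic equals twice the squared
  mean shift. PCA is fitted per comparison on the pooled perturbed +
  control cells, so each test's feature space reflects its own comparison. The null permutes the group/control split 1,000 times
  (vectorized as mask-matrix products against the precomputed distance
  matrix); p = (1 + #{perm ≥ obs})/(n + 1); Holm–Šídák across groups at
  α = 0.05.
* **Differential expression.** Two-sided Mann–Whitney per gene on
  tp10k-log values (mid-rank ties, normal approximation with continuity
  correction), Benjamini–Hochberg adjusted; pseudobulk log2 fold-changes
  are ratios of linear tp10k means.
* **Pseudobulk profiles.** Mean z per guide over the top 250 (or 1,000)
  control-expressed genes; Pearson correlations between guides.
* **Scores.** Gene-set score = mean z over the set, per guide; zonation
  score = Σz(7 periportal markers) − Σz(16 pericentral markers), per cell
  or per guide, with the two partial sums available separately.
  Intensity effects z-score each channel against control cells within
  imaging sample. Score and intensity tests are Mann–Whitney vs controls
  with Benjamini–Yekutieli correction (the conservative choice under
  dependence); DE uses BH; the energy-distance family uses Holm–Šídák.

## Zonation segmentation

Per replicate: 2-D histograms of Hep1+Hep2 and Hep5+Hep6 cell counts at
50 μm resolution, Gaussian-blurred with σ = 0.5 (in bin units, matching
the histogram pipeline), each normalized by its own maximum, and each bin
labeled by the larger normalized density. Ties break toward pericentral
(a convention, logged in code). Zone-occupancy enrichment per guide is a
two-sided Fisher exact test of the guide's pericentral/periportal counts
against control counts, BH-adjusted — the test is a package choice since
none is named for this comparison. Per-replicate maps with pooled counts
are used when multiple replicates exist.

## Problem sizes and degenerate inputs

Test and acceptance runs use desk-scale sizes chosen as the smallest that
make each guarantee sharp: exhaustive code verification at full size
(285/1044 words), 50,000-molecule decoding runs, 50 × 100-cell null
groups with 1,000 permutations, 10⁵–10⁶-cell Poisson populations, and
9–16-cell rendered fields for exact end-to-end identities. Degenerate
inputs are handled explicitly: zero-total cells are an error in
normalization; single-class classifier input raises; a single-codeword
code reports its minimum distance as undefined; infeasible code requests
report the best size achieved; empty filter results are allowed.

## Known limitations

The decoder is spot-based, appropriate for well-separated RCA amplicons
but not for dense single-molecule FISH where pixel-based decoding is
needed. Images are single-plane and registration-free. Cell segmentation
is consumed as exact masks; segmentation error propagation is out of
scope. The specificity indices are k-mer stand-ins for
expression-weighted indices used in production probe design. Sequencing
guide thresholds are data-driven rather than optimized against on-target
knockdown, which requires real targets.
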