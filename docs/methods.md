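# Methods

## Model

Shed-cell fractions (washes) and tissue biopsies sample the same gene
pool with different cell-state weights: the wash weights each state by
its abundance *times* its shedding (death) rate, the biopsy by abundance
alone. On log-log axes the two bulk profiles are therefore highly
correlated, and the informative signal is the deviation from the fitted
line.

**Shedding residuals.** Counts of each wash/biopsy sample are divided by
the sample's total (sum normalization). Per-gene medians are taken across
samples *on the linear scale*; a pseudocount is then added and logs
taken, giving `y_i = log10(median_wash_i + p)` and
`x_i = log10(median_biopsy_i + p)` with `p = 1e-5`. OLS with an intercept
of `y` on `x` yields residuals `R_i = y_i − (a + b·x_i)`. The operator
order — median first, then pseudo, then log — is fixed; the alternative
(median of logs) is explicitly rejected by a unit test. The regression
direction (wash on the y axis) is likewise fixed because flipping it
flips every residual sign: positive residuals are genes overrepresented
among shed cells.

**Turnover score.** A cell or pixel with expression sum-normalized over
the residual table's included genes scores
`Σ_i R_i · E_i`. Because the weights `E_i` are non-negative and sum to 1,
every defined score lies in `[min R, max R]`; a cell detecting zero panel
genes gets an undefined (NaN) score rather than 0, since 0 is a
meaningful score. Normalizing the weights over the panel (rather than all
genes) keeps scores convex combinations and comparable across
observations; normalization over all genes remains available by passing a
different gene subset to `sum_normalize`.

**Gene-set exclusion.** `turnover_score_excluding` removes a gene set
(e.g. an apoptosis program), refits the regression on the remaining
genes, renormalizes expression over them, and rescores; both score
columns are returned. A `refit=False` flag keeps the original residuals
for sensitivity analysis — under that flag, excluding genes with zero
weight provably cannot change any score, which the tests exploit.

**Tip score.** `Σ tip-marker expression / (Σ tip + Σ bottom)` — a
zonation coordinate in [0, 1], NaN when neither marker set is detected.

## Statistical conventions

- QC boundaries follow the quoted rules literally: "more than N" and
  "above x" strict, "below x" strict, "ranging from a to b" inclusive.
  Defaults: bulk samples > 10,000 UMIs; cells 1,500–10,000 UMIs with
  mitochondrial fraction < 0.5; pixels > 20 UMIs (> 100 for the
  neighborhood analysis).
- Marker selection: target-group mean expression ≥ 1e-5 and
  pseudocounted fold change `(target + 1e-5)/(off + 1e-5)` ≥ 1.5, with
  the off-target reference the *maximum* over competitor groups (the
  strictest notion of specificity; `mean` available). Cell types with
  < 300 cells are dropped from marker selection unless excepted; score
  summaries flag groups with < 15 observations.
- Differential expression: two-sided Mann–Whitney rank-sum on
  sum-normalized expression (Welch t on logs as an option), genes tested
  when the larger group mean exceeds 1e-5, BH correction across tested
  genes, significance at q < 0.05 plus symmetric fold change
  `max(FC, 1/FC) ≥ 1.5` so depletion counts too. `M = log2 FC`;
  `A = mean of log10 pseudocounted means` (the pseudocount keeps A
  finite for half-zero genes).
- Quantile splits (top/bottom 33%, top 2% vs rest) are rank-based with
  ties broken deterministically by observation id; floor(n·fraction)
  observations per side, a `keep_ties` mode includes boundary ties.
- Spatial neighborhoods: Euclidean center-to-center distance, "up to
  70 µm" inclusive; pixels within radius of both the high and low focal
  sets are assigned to the high side (a `closest` policy is available).
- Box summaries: linear-interpolation quartiles, whiskers at the most
  extreme values within 1.5·IQR of the box.
- Panel representation summaries take log10 of per-class mean expression
  over panel genes that are nonzero in at least one compared class;
  genes at exactly zero within a class are dropped from that class's
  mean/SEM (reported via `n_nonzero`) because their log is undefined.
  SEM is the sample standard deviation over genes divided by √n, and 0
  for a single gene.

## Synthetic world

`make_zonated_truth` builds a 6-zone epithelium over 1,000 genes: each
gene peaks at a uniform position along the crypt–villus axis with a
log-normal magnitude and a Gaussian profile of width 1 zone
(`zonation_sharpness`); zone programs are the profiles evaluated at bin
centers, normalized to probability vectors. Zone z sheds at relative
rate `gradient^z` (gradient 1 = null world). Tissue abundance is uniform
across zones by default.

- **Bulks** (`simulate_wash_biopsy`): biopsy mixture = abundance-weighted
  zone programs; wash mixture = abundance×shedding-weighted. Each sample
  perturbs its mixture with a Dirichlet draw (concentration 1e4,
  a moderate sample-to-sample biological variability) and draws 1e6
  multinomial reads — a typical bulk RNA-seq depth.
- **Cells** (`simulate_cells`): each cell draws a zone by abundance, a
  *continuous* position uniform within the zone's bin, a log-normal UMI
  depth (median 4,000, σ=0.3 — the middle of the 1,500–10,000 QC
  window), and multinomial counts from the program evaluated at its
  position. The continuous position is what gives per-zone score
  distributions realistic width and overlap; truths without continuous
  parameters (hand-built, or modified by `with_spike`, whose
  zone-specific fold has no continuous representation) fall back to
  sampling the binned programs.
- **Shed cells** (`simulate_shed_cells`): zone probabilities proportional
  to abundance × shedding, optional apoptosis-program spike.
- **Spatial grid** (`simulate_spatial_grid`): a 8-µm lattice of repeating
  crypt units — inter-crypt surface epithelium, crypt wall/bottom
  columns, lamina propria, muscularis bands — with stromal compartments
  drawing from their own log-normal programs. A random 2% of inter-crypt
  pixels is designated high-shedding and draws the top-zone program
  (other surface pixels draw the next zone down); lamina pixels within
  70 µm of a high-shedding pixel receive a 3× spike of 20
  microenvironment genes drawn from the 200 best-expressed lamina genes,
  so the spike is detectable at the ~300-UMI pixel depth typical of 8-µm
  bins passing QC.

What a green test establishes: that the regression/scoring/DE machinery
recovers the orderings and gene sets the generative model encodes, at
realistic depths and noise. What it does not establish: robustness to
features the generator omits — ambient RNA, doublets, batch effects,
post-shedding transcriptional change, compositional shifts in disease,
non-multinomial overdispersion within cells, or histology-realistic
geometry.

## Numerical choices and edge cases

- The OLS solve uses `numpy.linalg.lstsq` on the `[1, x]` design matrix;
  tests verify slope, intercept and residuals against an independent
  closed-form normal-equations solver at 1e-10 and the zero-sum residual
  property at 1e-8.
- Benjamini–Hochberg is delegated to statsmodels (`fdr_bh`); tests
  compare against a hand-written textbook step-up at relative 1e-12 (the
  two evaluate `p·m/rank` in different floating-point orders, so
  agreement is to rounding, not bitwise).
- Observations with zero counts on a normalization subset are flagged
  and masked (NaN), never silently divided or dropped; callers decide.
- Fewer than 3 genes, zero variance in the biopsy log medians, gene-set
  mismatches between a residual table and the matrix it scores,
  overlapping DE groups, and empty gate intersections are all hard
  errors rather than warnings.
- Radius queries use a KD-tree with the radius padded by a 1e-12
  relative epsilon so pixels at exactly the stated distance are included
  regardless of floating-point wobble; tests pin the boundary at 70 µm
  inclusive vs 70.1 µm excluded and compare whole neighbor sets against
  brute-force all-pairs distances.

## Known limitations

- Residuals are relative within one wash/biopsy pairing; scores are not
  comparable across organs or cohorts without a shared fit, and they are
  not absolute lifetimes.
- The rank-sum default for DE is a convention choice; on heavily tied
  sparse genes its p-values are conservative.
- The simulator's geometric shedding gradient is a stand-in for
  empirical tip-biased shedding; analyses should rely only on its
  monotonicity, not its functional form.
- Marker panels depend on the composition of the reference; the package
  reproduces selection rules, not any published panel's gene list.
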