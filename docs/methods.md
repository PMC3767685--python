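# Methods

`germomics` re-implements, as a tested library, the statistical workflow of
a dual proteome/transcriptome time-course study of *Streptomyces
coelicolor* spore germination: 13 sampling points (dormant spores, then
0–5.5 h at 30-min intervals), three measurement modalities per time point
(Sypro-Ruby-stained 2DE gels, pulse-radiolabeled 2DE gels, and two-channel
microarrays with a pooled all-time-points reference), and a downstream
analysis built on principal kinetic trends. This note records the models,
the numerical conventions, and the design choices made where the published
procedure left the design open.

## Normalization models

**2DE gels.** Spot intensities are first divided by the total protein
loaded per gel. Distribution matching assumes log intensities on the
stained (accumulative) gels are normal around a common mean: with
m_g the mean natural log of gel g's positive spots and M the grand mean of
the m_g, each gel gets the multiplicative factor f_g = exp(M − m_g).
Natural logs are used; the base cancels in exp(M − m_g), so the choice is
cosmetic but fixed for reproducibility. Zero/missing spots are excluded
from m_g rather than floored — pseudocounts would distort the sparse early
gels. The stained-gel factors are transferred to the radiolabeled image of
the same gel: early radiolabeled gels carry only a handful of spots, and
normalizing them by their own cumulative signal would inflate the earliest
time points. Replicate CV uses the sample (n−1) standard deviation, suited
to the 3–5 replicates per time point.

**Two-channel arrays.** Log2Ratio = log2(sample α / reference β) per cell;
a non-positive β flags the cell invalid, a zero α becomes missing rather
than −∞. Each array is centered to median 0 and scaled to MAD 1 (plain
median absolute deviation, no 1.4826 consistency constant — the constant
would rescale all arrays identically). The most extreme ratios are trimmed
symmetrically at the 0.02 quantile per tail. Replicate pools per gene and
time point are screened with Dixon's Q (r10 ratio, two-sided, 95 %
critical values, one removal per pool) for 3–9 values and Peirce's
criterion (Gould's iterative procedure; mean and SD taken from the full
pool, the assumed outlier count k incremented until the flagged set
stabilizes) for 10 or more; the boundary case n = 10, unassigned in the
source procedure, goes to Peirce. Survivors are averaged in the log2
domain and exponentiated (a geometric mean), giving ratio-scale profiles.
Single internal gaps with observed neighbors are linearly interpolated in
time-index space (the dormant point has no numeric hour; spacing is
uniform anyway); leading/trailing gaps and runs of ≥ 2 stay missing.

**Low-expression floor.** Per gene, the median of all raw α-channel
measurements is taken; genes whose log2 median falls below the first
quartile of that distribution are dropped. The published analysis rescued
single-peak genes "individually", without a stated rule; here a gene is
rescued when exactly one time point exceeds the mean of the remaining
points by more than 3 of their standard deviations and that point's raw
replicate median clears the floor. Both the quartile and the peak margin
are parameters.

## PCA, correlation and alignment

Profiles are row-standardized (mean 0, SD 1; population 1/n SD — the
convention is invisible to downstream correlations) and decomposed by
eigendecomposition of the time-domain second-moment matrix XᵀX/n of the
standardized rows, *without* column centering: with row-standardized
follower profiles the planted trends are then exact eigenvectors in the
noise-free limit, which column centering would destroy. Eigenvector signs
are fixed so each loading's largest-magnitude element is positive.
Variance fractions cover all min(n_time, n_entities) components regardless
of how many loadings are returned.

Standardization is performed on the ratio scale by default, matching the
exponentiated profiles the normalization emits. For component-recovery
analyses the package standardizes log2-transformed profiles instead
(`log_scale=True`): the generative model is affine in the planted trend on
that scale and multiplicative noise is homoscedastic there, so planted
loadings are exactly recoverable; on the ratio scale the exponential
transform alone costs ≈ 2 % of correlation noise-free and under noise
introduces a systematic heteroscedastic rotation of the closely spaced
components.

Gene–trend association uses Pearson r with the two-sided p-value from
t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom; a gene "follows" a
loading when p ≤ 0.05 *and* r > 0 (negative correlates are reported, not
flagged). Cross-dataset alignment correlates the first k loadings of two
decompositions over their shared time labels (the 12-point radiolabeled
grid aligns against the 13-point grids on the 12 shared labels), matches
components greedily by descending |r|, and detects a constant index shift
by maximizing the mean |r| over pairs (i, i+s) for s ∈ [−2, 2]. A
candidate shift must rest on at least two matched pairs: a mean over a
single pair is not statistically comparable to a mean over three, and the
single-pair candidates at the window edges otherwise win spuriously
whenever two planted shapes happen to resemble each other.

## Enrichment and utilization

Group over-representation uses a 2×2 chi-square per functional group
(in-group vs. out, selected vs. not) against the full set, without Yates
correction, at raw p ≤ 0.05 — a per-group test matches per-group
significance statements better than a single 27-cell goodness-of-fit.
Expected counts below 5 are flagged; Benjamini–Hochberg adjusted p-values
are emitted as an extra column but play no role in the default call. Fold
over-representation is (n_subset/subset_size)/(n_full/full_size).

Absolute-expression analyses use the α channel alone. Per-gene abundance
is the median over all measurements; the log2-median distribution is cut
at its quartiles and 95th percentile (linear interpolation between order
statistics), a gene landing in the highest partition whose lower boundary
it reaches. The utilization threshold is a single global quantile (default
0.75) of the pooled distribution of *all* α signals — per-time-point
thresholds are deliberately not used; a gene counts as highly expressed at
a time point when the geometric mean of its replicates strictly exceeds
the threshold (ties excluded). Relative series divide each group's counts
by the all-group total and scale by 100. Tiny groups are kept in the
output; threshold-robustness summaries exclude them because counts of a
handful of genes are binomial-noise dominated.

## Synthetic data generator

The generator is the test bed: every planted feature is recoverable.

* **Latent structure.** Orthonormal, mean-zero component profiles over the
  grid; defaults are three germination-like shapes (dip-then-rise, 1-h
  peak, high-start/late-rise). A follower gene's log2 α/β ratio is exactly
  amplitude × profile; amplitudes are N(1.2, 0.3) log2 units, clipped at
  0.3 (peak fold changes ≈ 2–4×, typical of arrays).
* **Population mix.** Default loading fractions (0.25, 0.15, 0.10):
  planted variance shares in ratio 0.5 : 0.3 : 0.2, with half the genes
  unstructured. The unstructured bulk is not decoration — median/MAD array
  centering estimates its correction from the bulk, and a population that
  is 100 % structured violates the assumption of the very method the data
  feed. Real germinating-spore data are similar: the three follower sets
  together cover roughly half the expressed genes.
* **Abundance and noise.** Lognormal baselines (ln-mean 7, ln-SD 1.5,
  ≈ 3 decades); lognormal multiplicative cell noise with CV 0.2
  (multiplicative because fluorescence is positive and the pipeline is
  log-domain throughout); ×10 outlier spikes at rate 0.005 (large enough
  that Dixon/Peirce removal is consequential); missing cells at 0.01.
* **Technical artifacts.** Arrays carry a per-array additive Log2Ratio
  offset (SD 0.3) and gain (lognormal SD 0.15) — exactly what median/MAD
  centering removes; gels carry a per-gel brightness factor (ln-SD 0.4)
  shared by the stained and radiolabeled image of the same gel — exactly
  what factor transfer removes.
* **Gel dataset.** Spots are sampled without replacement with probability
  ∝ abundance^bias, emulating gels detecting mostly abundant proteins; the
  radiolabeled channel omits the dormant point (dormant spores cannot be
  pulse-labeled). `plant_pc_shift` prepends a stored-protein consumption
  profile (strict decline over the first four intervals, then constant)
  with 40 % of the structured population, shrinking the original
  components proportionally, so alignment against the source transcriptome
  must detect a unit shift. Gel followers take sign-symmetric amplitudes
  (spots are consumed as well as accumulated), which also keeps the
  per-gel mean log free of a structured trend that factor matching would
  otherwise subtract from every spot.

What the generator does **not** emulate: spot detection and matching
errors, saturation, dye-specific (intensity-dependent) bias, sequence
effects, correlated replicates, and any real biological covariance between
functional annotation and kinetics (group labels are assigned at random in
genome-wide proportions). Passing tests therefore demonstrate the
correctness and statistical behavior of the pipeline under its own model
assumptions, not the biological fidelity of conclusions drawn from real
gels or arrays.

## Validation experiments and problem sizes

The canned experiments (`germomics.experiments`) use 2000 genes × 13 time
points × 3 replicates with variance shares 0.5/0.3/0.2 and noise CV 0.2;
gel datasets use 600 spots with abundance bias 5. Recovery experiments
plant no array artifacts and skip centering — they isolate recovery under
measurement noise, while artifact removal is verified by its own exact
checks (centering cancels planted offset/gain bit-for-bit in the
noise-free limit). Shift detection is assessed over 20 seeded runs. These
sizes keep the full validation under a minute on one CPU while leaving the
statistical margins (loading recovery ≥ 0.95, follower fraction within 5
percentage points, ≥ 19/20 shift detections) comfortably clear.

## Known limitations

* Median/MAD centering on data whose structured fraction approaches 100 %
  subtracts a signal-bearing profile; component recovery through the
  centering step degrades as the unstructured bulk shrinks. This is a
  property of the published procedure itself, reproduced faithfully.
* The Dixon critical values are the standard two-tailed r10 table at
  90/95/99 %; other confidence levels raise an error rather than
  interpolate.
* The single-peak rescue rule is this package's formalization of a step
  the source described only as manual curation.
* Quantile conventions (linear interpolation) shift partition boundaries
  by at most one rank relative to other conventions.
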