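# Methods

This note documents the models, estimators and numerical choices behind
`alosaedna`, and what the synthetic-data generator does and does not
emulate.

## In-silico assay screen

A candidate template is gap-stripped and scanned on both strands for the
forward primer and the reverse complement of the reverse primer. Primer
matching is Hamming distance on equal-length windows: primers are short
(18 nt) and assay specificity arguments are mismatch-count based, so
indel alignment would add nothing but ambiguity. IUPAC ambiguity codes
in the reference count as a match when the primer base belongs to the
code's set. Among all placements with each primer within `max_mm`
(default 3) mismatches and amplicon length ≤ 200 bp, the pair minimizing
total mismatches wins; equal-score ties are reported with an ambiguity
flag rather than silently resolved. Coordinates are 1-based inclusive
throughout, so "amplicon bp 104" means the 104th base counting the first
forward-primer base as 1.

The probe is a molecular beacon: a hairpin whose 5'/3' arms
(CGCGAT…ATCGCG, 6 nt each) hybridize to each other, not to the target.
Mismatch counting therefore uses only the loop between the arms. The
exact stem/loop boundary of the published beacon is not stated anywhere
we could consult; 6+6 is the default reading of the arm sequences and is
exposed as `AssayOligos.stem` so a user with better information can
override it. The loop is slid over the amplicon interior in both
orientations and the minimum mismatch count is reported.

Diagnostic SNPs between two species are amplicon columns where every
sequence of one species carries one base and every sequence of the other
a different base. All sequences must yield equal-length amplicons (the
assay's amplicon is indel-free among the taxa of interest); anything
else is an error rather than a guess.

## qPCR quantification

The standard curve is ordinary least squares of Cq on log₁₀(copies) over
the plate's own dilution series (five levels from 300,000 to 30 copies
in duplicate; zero-copy blanks are excluded from the fit). Curves are
fitted per plate and never pooled — between-plate drift is exactly what
the per-plate series exists to absorb. Plate QC fails when r² < 0.98,
when any nonzero standard fails to amplify, or when any no-template
control or cooler blank crosses threshold. Copy estimates invert the
curve: copies = 10^((Cq − intercept)/slope); amplification efficiency is
10^(−1/slope) − 1.

Detection requires at least two of three replicates with Cq **strictly**
below 39.0 ("below 39" is read literally; a replicate at exactly 39.0
does not count). Fewer than three replicates are accepted with a warning,
the ≥2 rule unchanged. The per-sample copy number is the arithmetic mean
of the copy estimates from replicates below the cutoff; non-amplifying
replicates are excluded from the mean by default
(`mean_mode="detected"`), with `mean_mode="all"` available to count them
as zeros — the published figures say "mean mtDNA copies" without
resolving which, so both are implemented and the default is the reading
that does not mix detection and abundance.

Inhibition is flagged from a spiked control (a 300,000-copy standard
plus 1 µl of the sample extract): delta Cq = spiked − baseline, inhibited
when delta ≥ 3 cycles, with a non-amplifying spike reported as complete
inhibition (infinite delta). The baseline is the mean Cq of the plate's
own duplicate 300,000-copy standards — an assumption, since the
protocol does not say which wells anchor the comparison. Inhibited
samples are flagged and retained, never dropped; downstream statistics
can filter on the flag.

Volume standardization: adjusted = (1000 mL / filtered volume) ×
reaction copies. With the whole 1 L sample eluted into 100 µl and 4 µl
loaded per reaction, one reaction represents 40 mL of source water; the
helper `reaction_volume_equivalent` makes that arithmetic explicit.

The raw fluorescence → Cq step (single-threshold calling at the
instrument) is upstream instrument behaviour; the pipeline ingests Cq
values and the simulator generates them directly.

## Peak-height apportionment

At the diagnostic SNP the T and C peak heights estimate the species
mixture, after base-specific normalization: each base's correction
factor is the mean height of that base at the monomorphic flanking
positions within ±`window` bp of the SNP where it is the called base.
The window defaults to 8 (the method is described for 6–10 flanking
bases; 8 is the midpoint) and is validated to that range. Mean is the
default aggregator with median available — the original description
does not say which estimator the correction uses, so the least-assuming
one is the default and both are exposed. A base never called on either
flank falls back to the mean of the observed factors with a warning.

The corrected ratio p̂ = (h_T/f_T)/(h_T/f_T + h_C/f_C) is read as the
alewife proportion (T = alewife, C = blueback, asserted against the
called-base column; sequencing is assumed to be in the forward
direction). Calls: p̂ ≥ 0.95 → alewife, p̂ ≤ 0.05 → blueback, otherwise
both. The 0.05 minor-allele floor is a free parameter — no threshold is
published for when a minor peak stops being noise — and is exposed as
`minor_floor`. Copies split proportionally and conserve the total
exactly.

Sequenced amplicons are also checked against the reference panel by
ungapped sliding identity; a best match below 98% identity against both
river herring is called `other` (this is the route by which look-alike
hickory shad amplifications are caught).

## Field statistics

- **Phi** is computed from the closed form (ad − bc)/√(row/col margin
  product) and equals Pearson correlation of the 0/1 codings (tested to
  1e-12 against an expansion oracle). Zero margins are an error, not a 0.
- **Fisher exact** (two-sided, sum of hypergeometric probabilities ≤
  observed) is delegated to scipy; this matches R's `fisher.test`.
- **Spearman with permutation null**: rho is Pearson on average ranks.
  The analytic p uses exact enumeration of rank permutations for n ≤ 9
  tie-free data and the t-approximation otherwise. The permutation p
  shuffles one margin and applies the add-one rule
  (1 + #{|ρ*| ≥ |ρ|})/(n_perm + 1), so it is never exactly zero; the
  null draws are returned for plotting. Permutations are vectorised, so
  10⁵ permutations cost milliseconds.
- **Marascuilo**: pair (i,j) differs when |p_i − p_j| exceeds
  √χ²₁₋α,k₋₁ · √(p_i q_i/n_i + p_j q_j/n_j); all k(k−1)/2 comparisons
  are returned with their critical ranges. With k = 2 the decision
  coincides with a χ²-based two-proportion test.
- **Seasonal split**: per species, a two-sided Mann-Whitney (tie
  corrected) compares detected copy numbers on-or-before April 15
  against after. The boundary date is placed in the early period —
  the published period labels overlap at April 15, so the choice is a
  convention, exposed as `split_date`.
- **Log-log regression** drops nonpositive pairs by default (zeros
  carry no information on the log scale); a +1 offset mode is available.

The pipeline applies Marascuilo to inhibition proportions by river when
plate data are available (the survey file format carries no inhibition
column); the standalone stats layer falls back to detection proportions
by river, and the report records which basis was used.

## Synthetic-data generator

The generator is the package's study system. Its defaults describe a
spring season (Mar 1 – May 31, weekly visits) over 12 named tributaries
(3 eastern-shore, 9 western-shore; four sites each) with:

- **Occupancy** Bernoulli per site-visit: 0.33 eastern / 0.18 western,
  mirroring the observed shore-level detection rates.
- **Species** drawn per occupied visit: alewife-biased on the eastern
  shore (0.75) and blueback-biased on the western (0.40 alewife), with
  an 18% chance of a mixed (both-species) signal whose alewife fraction
  is uniform on [0.15, 0.85].
- **Copy abundance** lognormal with median 1,771 per-reaction copies
  and σ = 1.5 natural-log units, multiplied by a Gaussian run curve in
  date (alewife peak Mar 25, blueback peak May 1, width 14 days). The
  marginal distribution of detected copies then spans roughly 1–10⁵,
  the seasonal factor contributing part of the spread; the site-level σ
  is deliberately below the marginal spread for that reason. The
  blueback peak sits at May 1 because observed blueback detections
  concentrate in the mid-April-to-mid-May window; the 14-day width
  reproduces month-scale species windows and gives the early/late
  Mann-Whitney split roughly the (near-total) power seen on real data.
  At wider widths or an April peak the split test has little power for
  blueback, because the April 15 boundary falls inside the blueback
  rise.
- **Detection** runs through the real machinery: plates are simulated
  (Cq = intercept + slope·log₁₀(copies) + N(0, 0.2), censored to NO_AMP
  past cycle 39) and quantified by `alosaedna.qpcr.quantify`, so the
  2-of-3 rule, plate QC and volume adjustment act exactly as in the
  analysis. Default curve: slope −3.3219 (100% efficiency), intercept
  38.0.
- **Inhibition** Bernoulli by stream type (coastal 0.55, piedmont 0.15,
  mixed 0.35 — averaging near the observed 38% overall), shifting the
  sample's unknown and spiked wells by 3 + Exp(2) cycles, with 10% of
  inhibited samples completely suppressed. Uninhibited samples get a
  small N(0, 0.3) spike jitter.
- **Ichthyoplankton** negative binomial with mean 0.05·copies^0.8 and
  dispersion 0.6 at occupied visits; unoccupied visits are structural
  zeros except for a 2% contamination rate of look-alike eggs (1 +
  Poisson(2) counts).
- **Adults** Bernoulli: 0.45 given occupancy, 0.03 otherwise — a
  noisier presence signal than the counts, which is what makes the
  eDNA–ichthyoplankton Phi exceed the eDNA–adult Phi.
- **Chromatograms** put each called base's peak at 1000 × bias ×
  lognormal noise (default bias A/C/G/T = 1.0/0.8/1.1/1.2, CV 10%);
  focal heights are h_T ∝ p·f_T and h_C ∝ (1−p)·f_C, the exact model
  the corrected-ratio estimator inverts.

All draws flow from a single explicitly passed `numpy` Generator; the
same config and seed give byte-identical outputs.

**What passing tests do not show.** The generator omits eDNA transport
and decay, temperature effects, site-level persistence of occupancy
across visits, spatial autocorrelation, imperfect species assignment of
eggs, and raw fluorescence curves. Recovery on synthetic data therefore
demonstrates that the estimators invert their own assumed models under
realistic noise — not that those models capture every property of field
samples.

## Problem sizes and numerical choices

Stochastic calibration checks use fixed seeds and the following sizes,
chosen to exercise the estimators well inside a few minutes of CPU:
mock-mixture regression over 500 series of 7 levels; permutation-test
type-I error over 1,000 simulations of n = 100 with 1,000 permutations
each; standard-curve slope recovery over 1,000 plates; survey-level
structure (Phi ordering) over 120 seeded seasons and seasonal phenology
over 20. Degenerate inputs are errors, not silent numbers: constant
vectors for rho, zero margins for Phi, all-identical standards (slope 0
curves are representable but refuse to convert Cq to copies), both focal
peaks zero. A constant response in any OLS helper returns r² = 0 rather
than NaN. Ties in detection calling cannot occur (the rule counts strict
inequalities); ties in ranks use average ranks.

## Known limitations

- The reference panel shipped for tests is synthetic (clearly labelled
  so): it reproduces the assay's geometry — amplicon length, mismatch
  ordering among species, the three diagnostic SNPs — but not real CO1
  phylogenetic structure. Real analyses should load their own FASTA.
- Only two-species mixtures are apportioned; three-way mixtures at the
  focal SNP are out of scope.
- The peak-table route assumes chromatogram peaks have already been
  extracted; binary AB1 trace decoding is deliberately not implemented.
- No occupancy modelling with a detection submodel, and no spatial
  covariate modelling; the statistics here are the descriptive layer.
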