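# Methods

This note documents the models implemented in `methcanyon`, the synthetic
data they are validated on, the numerical choices, and the limitations a
user should know before trusting a number.

## Read-level filters and pileup

Three technical biases of paired-end bisulfite libraries are handled before
any methylation ratio is computed.

* **M-bias / end-repair trimming.** The end-repair step of library
  construction fills in overhangs with unmethylated cytosines, biasing
  calls near one read end. Each `ReadObservation` carries a flag naming the
  repaired end in read orientation ('5p'/'3p'); `mbias_trim` removes base
  calls within `n_bases` (default 3) of that end and shrinks the read span
  accordingly, so the downstream mate-overlap logic sees the trimmed
  extent. In real data the trim length is chosen from an M-bias plot; here
  it is a parameter.
* **Clonal (PCR-duplicate) filtering.** With total read count `N` over
  genome length `G`, the expected reads per start position is λ = N/G. The
  duplicate cap is the smallest `k` with Poisson upper tail
  `P(X ≥ k+1) < 1e-5`; at most `k` reads are kept per (chrom, start,
  strand), first by input order. The key choice (start + strand) follows
  the common duplicate definition; the cap can be overridden (ChIP
  libraries conventionally use 2).
* **Mate-overlap single counting.** Where the two mates of a fragment
  overlap, their CpG calls describe the same molecule; calls inside the
  overlap of the trimmed spans are taken from the first mate only.

The pileup pools plus- and minus-strand calls per CpG (reported on the
plus-strand C, 0-based half-open coordinates). Zero-coverage sites are
flagged as missing, never imputed as 0.

## Segmentation into UMRs and canyons

A two-state HMM runs over the ordered per-CpG counts of each chromosome.
Emissions are binomial, `m_i ~ Binom(t_i, p_s)` with state-specific
methylation probabilities; the binomial coefficient is state-independent
and drops out of the posterior. Parameters are re-estimated by EM
(initialisation p = 0.05/0.75, stay probability 0.99, at most 50
iterations, relative log-likelihood tolerance 1e-4, no random restarts —
fits are exactly reproducible). Decoding is by posterior probability with a
0.5 threshold on the low state; a tie goes to the high state, the
conservative direction. On the simulated methylomes EM converges in a
handful of iterations and the forward–backward pass (numba-compiled) takes
about a second for 3·10⁵ CpGs.

Candidate segments are maximal low-state runs, split wherever consecutive
CpGs are more than `max_cpg_gap` = 2000 bp apart (CpG deserts carry no
evidence and should not be bridged). A candidate is kept when its
count-weighted mean methylation is ≤ `max_region_meth` = 0.10 — the "< 10%
methylation" rule is applied to the region mean, not per CpG, since HMM
decoding already enforces per-CpG consistency. Genomic extent is the
CpG-to-CpG span: the data cannot locate a boundary inside CpG-free flanking
sequence. Length classes: segments shorter than 1 kb are dropped, 1–3.5 kb
is a UMR, ≥ 3.5 kb a canyon; a canyon edge is the 2-kb interval abutting
each boundary, truncated at chromosome ends.

## Credible-difference DMC/DMR calling

The methylation difference between two samples at one CpG is summarised by
the *credible difference*: with independent posteriors
`p_j ~ Beta(m_j + α, t_j − m_j + β)` (uniform prior α = β = 1), take the
equal-tailed credible interval of `p₂ − p₁` at level 0.95 and report the
bound nearer zero, or 0 when the interval spans zero. This is a
reimplementation choice validated against brute-force grid integration of
the difference-of-betas distribution, not a bit-level reproduction of any
particular tool.

The interval is computed by Monte Carlo with 20,000 posterior draws and a
fixed seed. Three implementation details matter:

* **Canonical draw order.** The per-site sampling order is canonicalised on
  the count tuple, so swapping the two samples flips the sign of every
  value exactly (antisymmetry holds to the bit, not just statistically).
* **Deduplication.** Posterior-sample pools are drawn once per distinct
  (m, t) marginal; a site's interval uses the pooled difference. Results
  depend only on the counts present and the seed, not on site order or
  multiplicity.
* **Prescreen for genome-scale calling.** Sites whose normal-approximation
  posterior interval spans zero by more than one posterior-sd margin beyond
  the nominal quantiles are assigned 0 without Monte Carlo — the exact
  answer for any interval spanning zero, and far outside the approximation
  error. Every site near or beyond the decision boundary takes the exact
  path. The prescreen is used by `call_dmcs`; the plain function computes
  everything exactly.

Monte-Carlo resolution: at 20,000 draws the statistic carries a quantile
sampling error of ~0.005 (worst at 3 reads). The oracle-equivalence checks
therefore evaluate the statistic at 100,000 draws, where the maximum
deviation from grid integration over a coverage-3-to-100 count grid is
≈ 0.005; calling keeps the cheaper 20,000-draw resolution, which is
irrelevant at the 0.2 decision boundary except for counts whose true value
sits within ~0.01 of the cutoff.

DMCs require ≥ 3 reads in *both* samples (the stricter reading of "at
least three reads") and `|cdif| ≥ 0.2`. DMRs are maximal runs of ≥ 4
same-direction DMCs ("more than three" read strictly) with adjacent
spacing ≤ 300 bp; intervening non-DMC CpGs do not break a run — only
opposite-direction DMCs and the spacing rule do.

**Power.** By exact enumeration with the grid oracle, the probability of
detecting a true methylation difference of 0.5 at 30× coverage is 0.900 at
the most favorable proportion pair (0 → 0.5, fixed coverage 30) and ≈ 0.85
under Poisson(30) coverage or for central pairs such as 0.25 → 0.75
(≈ 0.65). This is a property of the conservative interval bound itself:
detection requires the *lower* 95% bound, not the point estimate, to clear
0.2. The test suite asserts agreement between the empirical detection rate
and this enumeration rather than a round-number target. The null error
rate at 30× (p = 0.75 in both samples) is below 10⁻³ by a wide margin.

## Occupancy processing

Tracks are fixed-width binned signal (10-bp default for differential
scores; the simulator uses 50 bp). Normalisation scales ChIP and input to
a common tag total, subtracts input bin-wise and floors at zero (occupancy
cannot be negative). This is a deliberate simplification of full
fragment-aware pipelines: the quantities exercised here depend only on
depth, input and spike-in handling. Spike-in scaling multiplies a track by
`reference_tags / sample_spike_tags`; factors compose multiplicatively and
depth normalisation is idempotent.

Window statistics tile each chromosome into 1-kb windows and exclude
windows overlapping a satellite interval by ≥ 1 bp, windows with no
WGBS-covered CpG, and windows with zero input signal. Feature classes
(proximal promoter TSS ± 500 bp, distal promoter 500–3000 bp upstream
strand-aware, canyon, canyon edge, …) are assigned by window-midpoint
containment and may overlap; enrichment is the class mean over the
included-window mean, reported also on log2 scale. The all-windows class
is exactly 1 — a conservation check in the suite.

The differential-occupancy score per bin is `sign(A − ref)·|log₁₀ P|`,
with `P` the upper-tail Poisson probability of the larger value given the
smaller as mean (regularised incomplete gamma, smooth in non-integer
values, exact at integers). Treating min/max symmetrically makes the score
exactly antisymmetric; equal bins score 0; `|log₁₀ P|` is capped at 300 to
avoid infinities. This Poisson formulation is a documented stand-in for
the original tooling's unpublished test and is validated for sign,
magnitude at integer counts, and antisymmetry.

## Landscape measures

* **Scaled-region profiles** resample each region body to 100 bins by
  linear interpolation and sample flanks at 50-bp resolution (5-kb flanks
  for canyons, 3-kb for gene bodies by convention; both parameters), so
  every region contributes equal weight regardless of length. A constant
  track yields an exactly flat profile — no resampling artifacts.
* **TSS matrices** are strand-oriented (minus-strand rows reversed);
  positions beyond chromosome ends are missing, excluded from means.
* **Density profiles** rank included 1-kb windows by CpG density and cut
  them into equal-count bins (rank-based, matching "ranked by density"
  semantics; populations equal within one window). The crossing point of
  two tracks is located by linear interpolation of the mean-signal
  difference between adjacent bin centres.
* **Peak coordinates** map genomic position to `u` with 0 at the peak
  centre and ±1 at the edges, linear beyond; the map is invertible within
  1 bp. DMR midpoints map to the peak with the nearest centre (ties to the
  lower coordinate). TSS-associated peaks are those whose centre lies
  within 1 kb of a TSS (configurable; the threshold is a convention).
* **Promoter CpG density** counts CpGs in the strand-oriented
  [TSS − 1 kb, TSS + 0.5 kb) window per 100 bp; windows truncated at
  chromosome ends use the truncated length.

## Clustering

`TssKMeans` concatenates per-track TSS profiles into one feature vector
per gene and runs k-means (k = 5, 10 restarts, tolerance 1e-6, fixed
seed). Genes are sorted by id before clustering, so input order cannot
change the result. Labels G1…Gk are assigned in descending order of the
cluster-centre mean over the central bins of the first track; empty
clusters are flagged and skipped in numbering. `ExpressionPatternKMeans`
log-transforms FPKM (log2(x+1)), standardises each gene across conditions
(zero mean, unit variance; constant genes are excluded with a warning) and
runs k-means with k = 7. Labels C1…C7 order clusters by their shift
pattern relative to the reference condition, comparing the last condition
first, so the "up in both knockouts, additive" cluster is C1. Both label
conventions are artifact conventions — they make labels invariant to
k-means centre permutation, nothing more. Annotation loading selects the
longest isoform per gene where multiple are present.

## The synthetic-data generator

The generator plants every structure the analyses measure, under one
seeded generator with per-chromosome sub-streams.

* **Genome.** CpG placement is an inhomogeneous Bernoulli-per-bp process.
  Each 1-kb block draws its background rate from a lognormal around
  `background_cpg_rate` (1 CpG/100 bp, spread 0.5 in log units), giving a
  continuous density gradient across windows; island intervals override
  with `island_cpg_rate` (8/100 bp). Planted regions (UMRs 1–3.5 kb,
  canyons 3.5–10 kb) are CpG islands; extra "knockout-only" regions
  (2× UMRs, 4× canyons relative to baseline — the direction and rough
  magnitude of the published knockout counts) are islands that stay
  methylated in wild type. Promoter island status follows the binding
  archetype: TET1-bound groups (G2, G3) are CpG-dense, others carry a
  low background island rate — the same promoter-density-by-group
  structure the group summaries measure. The density field is held at the
  background rate within ±5 kb of TSSs and planted regions are placed
  clear of TSS neighbourhoods, so promoter binding profiles and
  canyon-edge structure remain separable signals rather than being
  confounded by random density texture. A configurable fraction of 1-kb
  windows is flagged satellite.
* **Methylome.** Coverage is Poisson(`coverage_mean` = 30); methylated
  counts are beta-binomial around a piecewise mean field — background 0.75,
  planted regions 0.03 — with dispersion 0.02 (0 recovers the binomial).
  Dnmt3aKO/DKO lower the background by 0.15, extend active regions by
  500 bp per side and activate the knockout-only regions. Tet1KO/DKO add
  +0.15 methylation in the 2-kb flanks of planted regions (the gain is a
  free parameter; no published magnitude exists).
* **Occupancy.** TET1 follows a thresholded Hill response to local CpG
  density, `f(d) = d⁴/(d⁴ + d₀⁴)` above an activation floor, with
  `d₀ = crossing_density` = 1.5 CpG/100 bp; DNMT3A1 carries the
  complementary response `1 − f(d)` plus Gaussian bumps centred 1 kb
  outside canyon boundaries (σ = 800 bp) and archetype-specific TSS bumps;
  with equal baselines and amplitudes the two density responses cross
  exactly at d₀. "Local density" is the tiled 1-kb window count — the same
  quantity the window analysis measures, which keeps the planted crossing
  identifiable instead of being blurred by a definition mismatch. A
  protein is flat baseline in its own knockout; Tet1KO multiplies the
  DNMT3A1 bumps over former TET1 peaks in height and width (defaults 2×);
  Dnmt3aKO modestly raises TET1 peak height (height only — no width
  expansion, the published asymmetry). Noise is multiplicative lognormal;
  depth factors scale both the track and its spike-in tag count.
* **Expression.** Seven response archetypes over (WT, Dnmt3aKO, Tet1KO,
  DKO) in units of a log2 effect (default 2): up/down shared-additive
  (C1/C5, DKO = 2× single-KO), knockout-specific up/down (C2/C3/C4/C6),
  and a compensated class down in Dnmt3aKO but restored in DKO (C7).
  Non-archetype genes have exchangeable condition means.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: raw sequencing reads and alignment artifacts
beyond the three modelled filters, non-CpG methylation, fragment-size
effects in ChIP signal, copy-number and mappability structure, biological
replicate variability, and any coupling between methylation and expression
beyond the planted archetypes. Recovery rates on this generator are upper
bounds on real-data performance.

## Validation scales

The bundled checks run at desk scale, chosen to keep the full suite around
a minute while exercising genome-scale code paths: a 20-Mb, two-chromosome
methylome at 30× (≈ 3.4·10⁵ CpGs) for region recovery; 10-Mb genomes for
the landscape and clustering recoveries; 10⁴ CpG sites for error-rate and
power measurements; exhaustive enumeration up to 6 DMCs for merge
combinatorics. `scripts/acceptance.py --seed N --out results.json`
recomputes all of it from scratch in roughly half a minute.
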