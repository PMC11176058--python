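# Methods

This note records the models, parameter choices and numerical conventions
behind `chromfiber`, and what the synthetic-data validation does and does
not establish.

## Data model and conventions

A *fiber* is one aligned single molecule with per-base modification
probabilities: m6dA on adenines (the accessibility channel, deposited on
accessible DNA by a non-specific adenine methyltransferase) and m5dC on
CpG dyads (endogenous methylation). Probabilities travel in the standard
SAM MM/ML optional fields; the ML byte b decodes to b/256 and encoding
takes the floor, so a decode–encode round trip is the identity to within
1/256. MM payloads are written in implicit-unmodified mode (no `?` flag):
bases skipped by the delta encoding count as unmodified, matching common
modification-caller output. Coordinates are 0-based half-open everywhere;
m6dA probabilities are stored at sequenced-strand adenine offsets and CpG
probabilities once per dyad at the top-strand C. Parsing goes through
pysam's modified-bases machinery; the encoder is ours because pysam has no
writer for these tags.

The empiric read quality is computed from alignment event counts as
−10·log10(1 − n_matches/(n_matches+n_mismatches+n_del+n_ins)), i.e. a
Phred-scaled error fraction, with a configurable cap (default Q60) for
reads without any variation. The bare −log10 form is available behind
`phred=False`; the Phred scale is the default because it is the scale on
which read-quality figures are conventionally read (Q20 ≈ 99% accuracy).

Barcode demultiplexing decodes each molecule end to its unique nearest
barcode within `max_dist` substitutions and assigns a sample only when both
ends agree (concordance). A minimum pairwise Hamming distance of 4, as used
for the 8-nt hairpin barcodes modeled here, makes single-substitution
errors perfectly correctable (max_dist = ⌊(4−1)/2⌋ = 1), which the tests
verify by exhaustive corruption.

## Footprint HMM

Observations are binarized methylation calls (probability > 0.5) at adenine
positions. The chain has two states — accessible and protected — with
Bernoulli emissions and is homogeneous in adenine index; it deliberately
ignores inter-adenine distances. This is the simplest model consistent
with a two-state segmentation of the accessibility channel; physical
distances re-enter when decoded runs are converted to nucleotide spans
(boundaries at midpoints between flanking adenines, clipped at fiber
edges). The cost of the simplification is that a linker containing no
adenine cannot be resolved: two nucleosomes separated by such a linker
merge into one di-nucleosome-sized footprint. At the ~25% adenine density
of natural sequence this is rare (P ≈ 0.75^38 per 38-nt linker) and the
merged calls are in any case how real multi-nucleosome footprints present.

Estimation is Baum–Welch over all molecules (scaled forward–backward,
numba-compiled inner loops), initialized at emissions (0.8, 0.1), self-
transitions 0.95, uniform start; max 100 iterations, log-likelihood
tolerance 1e-4. State identifiability is enforced by relabeling so the
accessible state has the larger emission probability. Degenerate input
(all calls identical) returns boundary emissions with a warning. Decoding
is Viterbi with ties broken toward the protected state (the conservative
call for footprinting). Footprints spanning fewer than 30 nt are discarded
by default — small enough to retain transcription-factor-scale (~35–50 nt)
footprints while suppressing single-adenine flickers. Fibers whose
methylated-call fraction is below 0.05 are flagged unmethylated (enzyme
never reached them) and excluded from clustering; the threshold is a stated
default, not a claim about any particular dataset's artifact rate.

## Fiber typing

Decoded adenine states are broadcast to a per-nt binary track (midpoint
boundaries) so that autocorrelation lags are in nucleotides. Molecules
shorter than 1 kb are excluded; zero-variance tracks are marked invalid and
dropped as artifactual. The autocorrelation uses the standard FFT
estimator with global mean/variance normalization, lags 1–500 nt — at
least two repeats of any NRL ≤ 250 on a 1-kb molecule.

Clustering is Leiden (RBConfiguration) on a symmetrized Euclidean kNN
graph, k = 15, deterministic given the seed. The resolution default is
0.1: on mixtures of planted fiber types this recovers the planted
partition exactly, while resolution 1.0 fragments even a homogeneous
population into several communities (a known property of modularity-like
objectives on kNN graphs of a single blob) which the downstream <10%
cluster filter then partially discards. Because disconnected groups can
never be merged by the objective, the low resolution coarsens within
populations without blurring between them. Clusters holding strictly less
than 10% of clustered fibers are filtered; survivors are relabeled by
decreasing size.

A cluster's NRL estimate is the lag of the highest sufficiently prominent
local maximum of its mean autocorrelation within 120–250 nt after a 10-nt
running mean. The prominence threshold is 0.25. This value was set by
measuring both regimes the estimator must separate: regular arrays
(planted NRL 170–210, realistic emission noise) produce band peaks of
prominence 0.7–1.0, while irregular arrays — exponential linkers with a
hard-core 147-nt nucleosome, which as a renewal process still carries a
weak bump at its typical spacing — produce 0.07–0.18. A threshold far
below that bump (e.g. 0.05) would assign spurious repeat lengths to
irregular chromatin; 0.25 sits between the regimes with a ≥ 2.8× margin on
both sides. Clusters with no qualifying peak are reported as irregular
(estimate = none).

## Profiles

The 5′-aligned meta-profile averages binary accessibility over the first
1 kb of molecules (shorter molecules contribute as missing). The
periodicity detector first detrends with a 201-nt running mean, then
requires two conditions before reporting a period: an autocorrelation peak
of prominence ≥ 0.25 at a lag in 120–250 nt, and an absolute oscillation
size — RMS of the detrended profile ≥ 0.5× the profile mean. The second
condition exists because the autocorrelation is scale-free: n molecules
with random phases leave a residual oscillation of amplitude ∝ 1/√n that
never vanishes from the normalized autocorrelation, yet is biologically
meaningless. Under the simulator's study conditions the in situ profile
has relative RMS ≈ 1.4 and the ex situ profile ≈ 0.1, so the 0.5 cut
separates them with wide margins.

Motif matrices take one row per (molecule, anchor) pair whose molecule
fully spans the 750-nt anchor-centered window, column-reversed for
minus-strand anchors. For clustering, rows with > 20% missing cells are
dropped and remaining missing cells are mean-imputed per column (with
full-span rows this is vacuous, but the path is kept for partial-window
use). Insertion preference tabulates fragment ends in 5-kb windows around
anchors, smooths the meta-profile with a 100-nt running mean, and reports
the in-window fraction of ends plus its ratio to the fraction expected if
ends were uniform over the mappable span (windows merged before counting
so overlapping anchors do not double-count). The uniform background is a
stated assumption — no mappability correction is applied. CpG binning uses
strictly-greater thresholds: density > 10 CpG/kb is high, mean score > 0.5
is high; ties go to "low" on both axes, and fibers with zero CpGs are
excluded. Track correlation is Pearson's r of log(x + 1) aggregates over
shared regions; AUC is the rank statistic (Mann–Whitney normalization,
ties averaged).

## Statistics

Fisher's one-sided test reports the sample odds ratio (a·d)/(b·c) —
infinite when b·c = 0 with a·d > 0 — and the hypergeometric upper tail
P(X ≥ a) at fixed margins (via scipy, verified exactly against exhaustive
enumeration for all tables with n ≤ 30). Tables with a zero margin are
vacuous: p = 1 and an undefined odds ratio. Replicates are pooled before
testing.

Storey's q-values estimate π0 on the grid λ ∈ {0.05, …, 0.95}: for m ≥ 100
p-values a cubic smoother is read out at the largest λ, precision-weighted
by √(1−λ) because the tail estimates carry the most sampling noise; for
m < 100 the fixed λ = 0.5 estimate is used. π0 is clipped to (0, 1]. With
π0 = 1 the q-values coincide exactly with Benjamini–Hochberg step-up, which
the tests assert on random inputs. The estimator's sampling spread at
m = 1000 is roughly ±0.15, so individual draws below 0.8 on truly uniform
p-values occur; the validation therefore checks the cross-draw mean as well
as a fixed draw.

Differential fiber usage models, per (fiber type, domain) pair, the
replicate-level in-domain usage of that type as a binomial response —
successes = depth-normalized count of the type in the domain, trials = the
type's normalized total across domains — with case status as the sole
predictor, fitted by IRLS (statsmodels GLM). Depth normalization is
median-of-medians: each replicate's scale is the median of its nonzero
stratum counts, the global scale is the median of replicate scales, and
weights are count × global/replicate scale; doubling one replicate's depth
leaves the fitted effect unchanged. The case coefficient is a natural-log
odds ratio; it is divided by ln 2 and reported as Δ, a log2 fold change in
usage odds (not a ratio of proportions). Significance is a Wald normal
test on the coefficient, Storey-corrected, with q ≤ 0.05 as the cutoff.
Complete separation (a case with zero or full usage) is flagged
non-estimable rather than fitted. The case coding is explicit
(`case_levels=(baseline, case)`) so the sign of Δ is never an accident of
label sort order.

## Simulator

The simulator is the package's ground-truth oracle. Fiber kinds:

* **regular** — nucleosomes of 147 nt tiled with linkers ~
  Normal(NRL−147, sd) truncated at ≥ 5 nt (sd default 5 nt); a terminal
  nucleosome clipped by the fiber end is kept only if at least half fits,
  keeping the protected fraction near 147/NRL;
* **irregular** — exponential linkers (mean NRL−147), i.e. a renewal array
  with no stable repeat;
* **hyperaccessible** — long exponential linkers with placement capped so
  nucleosomes never cover more than 20% of the fiber;
* **ctcf_bound** — a central 45-nt motif footprint with phased nucleosomes
  tiled outward on both flanks, and locally depressed CpG methylation
  within ±50 nt of the motif.

Interior linkers are occluded (emitted as protected) with probability
1 − `linker_accessible_prob` (default 0.85), producing the di-/tri-
nucleosome footprint modes seen on real single-molecule data; the planted
truth "footprints" are the maximal protected runs after this merging.
Emission noise is Beta-distributed around state means (accessible 0.9,
protected 0.05, concentration 10; CpG high/low means 0.85/0.15); a
concentration of ∞ is the noiseless limit. Sequences are random at GC 0.41
with CpG density steered to ~5/kb (depleted background) or ~33/kb
(island-like), so both CpG classes exist.

Tagmentation draws Poisson-many insertion sites — `tn5_density` per
eligible kb — from accessible positions only (in situ) or uniformly (ex
situ). Each insertion carries a 9-bp target-site duplication, so
consecutive fragments share a duplicated 9-nt junction; only internal
fragments (both ends transposase-made) are emitted, fragments under 500 nt
are dropped by default (mirroring a size-selection cleanup), and both ends
receive the parent fiber's sample barcode with a small discordance rate
(default 0.001). Datasets are written as SAM/BAM + BED + TSV and are
byte-identical across runs at a fixed seed.

What the simulator does *not* emulate: sequencing errors and kinetics, the
upstream neural-network modification caller (probabilities are emitted
directly), mappability structure, copy-number variation, and any coupling
between accessibility and sequence. Passing the validation therefore shows
that the analysis recovers planted structure through the full IO path under
calibrated noise — not that any particular biological dataset will behave
this way.

## Validation scales

The shipped validation runs at desk scale, chosen to finish in minutes on
one CPU: footprint recovery on 200 fibers of 5 kb; fiber typing on 800
fibers of 4 kb (200 per planted type); insertion-model discrimination on
40 fibers of 20 kb per mode; differential-usage calibration with 5
replicates per case at ~10⁴ fibers per replicate and 1,000 null
simulations; statistical primitives against exhaustive oracles (all 2×2
tables with n ≤ 30; brute-force AUC at n ≤ 100).

## Known limitations

* The HMM has geometric state durations; no explicit nucleosome-length
  prior (no semi-Markov modeling) and no joint m6dA/m5dC decoding.
* NRL estimation reports a single dominant repeat per cluster; mixtures
  within a cluster are not decomposed.
* The insertion background is uniform over the mappable span; real Tn5
  sequence bias and mappability are not modeled.
* Cluster count depends on the Leiden resolution; it is a tunable, not a
  contract.
* Fisher tests pool replicates; there is no hierarchical/mixed-effects
  variant of the differential model.
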