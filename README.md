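# chromfiber

Single-molecule chromatin fiber analysis for long-read accessibility
footprinting. `chromfiber` takes aligned single molecules that carry
per-base modification probabilities — exogenous m6dA marking accessible
DNA and endogenous CpG m5dC — in the standard SAM/BAM MM/ML tag
convention, and turns them into footprints, fiber types, CpG classes,
domain-enrichment statistics and differential fiber-usage calls. It is
aimed at people developing or analyzing single-molecule adenine-methylation
footprinting assays (tagmentation-based long-read chromatin profiling in
particular), and it ships a ground-truth simulator so that every stage of
the analysis can be exercised and validated without external data.

## What it computes

**Footprints.** Per-adenine m6dA probabilities are binarized at 0.5 and
modeled with a two-state hidden Markov chain over adenine positions with
Bernoulli emissions: an accessible state (high P(methylated)) and a
protected state (low P(methylated)). Parameters are estimated by
Baum–Welch; molecules are decoded by Viterbi. Maximal protected runs become
footprints, with boundaries at midpoints between flanking adenines —
mono-nucleosomes appear near 147 nt, di-nucleosomes near 2×147 + linker.

**Fiber types and NRL.** Each molecule ≥ 1 kb contributes the Pearson
autocorrelation r(ℓ) of its per-nt binary accessibility track for lags
ℓ = 1..500 nt. Molecules are clustered by Leiden community detection on a
k-nearest-neighbor graph of their autocorrelation vectors; clusters below
10% of fibers are filtered. A cluster's nucleosome repeat length (NRL) is
the lag of the dominant prominent peak of its mean autocorrelation in the
120–250 nt band; clusters without a sufficiently prominent peak are called
irregular.

**Profiles.** 5′-aligned meta-accessibility over the first kilobase of
molecules; motif-centered single-molecule matrices (750-nt windows) with
Leiden clustering and per-cluster CpG-methylation overlays; insertion
preference of fragment ends around anchors (FRITSS/FRICBS — the fraction of
ends within 5-kb windows — and fold enrichment over a uniform background);
CpG binning of fibers (density > 10/kb = high; mean score > 0.5 = high);
rank-based AUC for methylation-call classification.

**Statistics.** Enrichment of fiber type A in feature B uses the 2×2 table
(A∩B, A∩B′, A′∩B, A′∩B′) with a one-sided Fisher's exact test and Storey's
q-value correction. Differential fiber usage between two conditions fits,
per (fiber type, domain), a binomial logistic regression of in-domain usage
on case status with median-of-medians depth-normalized replicate counts;
the case coefficient divided by ln 2 is the reported Δ (a log2 odds ratio)
with a Wald two-sided p and Storey q (significant at q ≤ 0.05).

**Simulator.** `chromfiber.simulate` plants nucleosome arrays with chosen
repeat lengths (regular, irregular, hyperaccessible, CTCF-bound fiber
kinds), emits Beta-noise modification probabilities, and fragments fibers
with an in situ (accessible-linker-only) or ex situ (uniform) transposase
insertion model with 9-bp target-site duplications and barcoded hairpin
adapters. Every output carries its ground truth.

## Worked example

`python examples/03_fiber_types.py` simulates 480 molecules from four
planted fiber types, decodes them with the HMM and clusters their
accessibility autocorrelation:

```
480 molecules clustered; 0 in filtered small clusters
cluster 0:  120 fibers, NRL = irregular (planted type: IR)
cluster 1:  120 fibers, NRL = 208 nt (planted type: NRL208)
cluster 2:  120 fibers, NRL = 173 nt (planted type: NRL172)
cluster 3:  120 fibers, NRL = 186 nt (planted type: NRL185)
```

Each cluster is pure for one planted type; the regular clusters' NRL
estimates land within 1 nt of the planted repeat lengths, and the
exponential-linker population is correctly reported as irregular rather
than being assigned a spurious repeat length. The other examples cover
dataset simulation (`01`), footprint calling and the footprint size
distribution (`02`), motif-centered accessibility/CpG clustering and
insertion preference (`04`), and enrichment plus differential usage (`05`).

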