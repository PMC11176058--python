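"""Motif-centered single-molecule views: accessibility states and CpG overlay.

Simulates fibers covering CTCF motifs in three chromatin states (bound,
hyperaccessible, nucleosome-occupied), builds the motif-centered
accessibility matrix, clusters its rows, and overlays per-cluster CpG
methylation -- the joint accessibility/methylation readout at binding sites.
Also scores the transposase insertion preference around the motifs.
"""

import numpy as np
import pandas as pd

from chromfiber import FiberTypeSpec, NoiseModel, simulate_fiber
from chromfiber.hmm import accessibility_track, decode_accessibility, fit_hmm
from chromfiber.io import GenomicInterval
from chromfiber.profiles import (
    cluster_cpg_overlay,
    cluster_motif_matrix,
    insertion_preference,
    motif_matrix,
)

rng = np.random.default_rng(17)
specs = [
    FiberTypeSpec("bound", "ctcf_bound", nrl_mean=185.0),
    FiberTypeSpec("open", "hyperaccessible", nrl_mean=185.0),
    FiberTypeSpec("nucleosomal", "regular", nrl_mean=185.0),
]
fibers, anchors = [], []
k = 0
for spec in specs:
    for i in range(120):
        start = k * 5000
        fb, _ = simulate_fiber(spec, 2000, NoiseModel(), rng,
                               molecule_id=f"{spec.label}_{i:03d}", start=start,
                               cpg_island=True, cpg_methylated=True)
        fibers.append(fb)
        anchors.append(GenomicInterval("chrS", start + 990, start + 1010, f"a{k}", "+"))
        k += 1

params, _ = fit_hmm(fibers[:100])
tracks = [accessibility_track(f, decode_accessibility(f, params)) for f in fibers]
matrix = motif_matrix(fibers, tracks, anchors, window=750)
labels = cluster_motif_matrix(matrix, seed=0)
overlay = cluster_cpg_overlay(matrix, labels, {f.molecule_id: f for f in fibers})

print(f"{matrix.data.shape[0]} motif-spanning molecules in {len(set(labels[labels >= 0]))} clusters")
truth = np.array([m.rsplit("_", 1)[0] for m in matrix.molecule_ids])
for label in sorted(set(labels[labels >= 0])):
    sel = labels == label
    dominant = np.unique(truth[sel])[np.argmax(np.unique(truth[sel], return_counts=True)[1])]
    central_acc = matrix.data[sel, 350:400].mean()
    central_cpg = np.nanmean(overlay[label][300:450])
    print(f"cluster {label}: n={sel.sum():3d} dominant={dominant:12s} "
          f"central accessibility={central_acc:.2f} central CpG methylation={central_cpg:.2f}")

# insertion preference: fragment ends biased toward motifs vs a uniform control
span = 2_000_000
sites = [GenomicInterval("chrG", c - 10, c + 10, f"s{i}", "+")
         for i, c in enumerate(range(100_000, 1_900_000, 100_000))]
near = rng.choice([s.center for s in sites], 3000) + rng.integers(-1500, 1500, 3000)
biased = pd.DataFrame({"chrom": "chrG", "pos": np.concatenate(
    [near, rng.integers(0, span, 7000)])})
uniform = pd.DataFrame({"chrom": "chrG", "pos": rng.integers(0, span, 10_000)})
for name, ends in (("motif-biased", biased), ("uniform control", uniform)):
    prof = insertion_preference(ends, sites, mappable_span_nt=span)
    print(f"{name}: fraction of ends within 5 kb of a motif = {prof.frit_score:.3f} "
          f"({prof.fold_enrichment:.2f}-fold over uniform background)")
print(
    "Bound-motif fibers show the central accessibility dip and locally depressed\n"
    "CpG methylation; nucleosome-occupied fibers stay methylated at the motif."
)
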