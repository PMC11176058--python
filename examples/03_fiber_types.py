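"""Cluster single molecules into fiber types and estimate repeat lengths.

Simulates a mixture of regular arrays (repeat lengths 172/185/208 nt) and
irregular fibers, computes each molecule's accessibility autocorrelation,
partitions the molecules with Leiden clustering, and reads the nucleosome
repeat length (NRL) off each cluster's mean autocorrelation.
"""

import numpy as np

from chromfiber import FiberTypeSpec, NoiseModel, simulate_fiber
from chromfiber import accessibility_autocorrelation, assign_fiber_types
from chromfiber.hmm import accessibility_track, decode_accessibility, fit_hmm
from chromfiber.fibertypes import FILTERED, estimate_nrl

rng = np.random.default_rng(17)
specs = [
    FiberTypeSpec("NRL172", "regular", nrl_mean=172.0, mixture_weight=0.3),
    FiberTypeSpec("NRL185", "regular", nrl_mean=185.0, mixture_weight=0.3),
    FiberTypeSpec("NRL208", "regular", nrl_mean=208.0, mixture_weight=0.2),
    FiberTypeSpec("IR", "irregular", nrl_mean=250.0, mixture_weight=0.2),
]
fibers = []
for spec in specs:
    for i in range(120):
        fb, _ = simulate_fiber(spec, 4000, NoiseModel(), rng,
                               molecule_id=f"{spec.label}_{i:03d}")
        fibers.append(fb)

params, _ = fit_hmm(fibers[:100])
vectors = [
    accessibility_autocorrelation(
        accessibility_track(f, decode_accessibility(f, params)),
        max_lag=500, molecule_id=f.molecule_id,
    )
    for f in fibers
]
table, mean_acfs = assign_fiber_types(vectors, seed=0)

print(f"{len(table)} molecules clustered; "
      f"{(table['cluster_label'] == FILTERED).sum()} in filtered small clusters")
for label, mean_acf in sorted(mean_acfs.items()):
    members = table[table["cluster_label"] == label]
    nrl = estimate_nrl(mean_acf)
    dominant = members["molecule_id"].str.rsplit("_", n=1).str[0].mode()[0]
    print(f"cluster {label}: {len(members):4d} fibers, "
          f"NRL = {'irregular' if nrl is None else f'{nrl:.0f} nt'} "
          f"(planted type: {dominant})")
print(
    "Each regular cluster's repeat-length estimate lands on its planted NRL;\n"
    "the exponential-linker population shows no sufficiently prominent\n"
    "autocorrelation peak and is reported as irregular."
)
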