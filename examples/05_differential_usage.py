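"""Domain enrichment and differential fiber usage between two conditions.

Builds replicate-level counts of fiber types across epigenomic domains for
a primary and a metastatic condition with one planted shift, runs the
one-sided Fisher enrichment suite on pooled fibers, then the weighted
logistic differential-usage model with Storey-q correction.
"""

import numpy as np
import pandas as pd

from chromfiber import run_differential_suite, run_enrichment_suite

rng = np.random.default_rng(17)

# pooled per-fiber labels for enrichment: one type over-represented in one domain
n = 20_000
domains = rng.choice(["Het", "TssA", "TxWk"], n, p=[0.3, 0.2, 0.5])
types = np.where(
    (domains == "Het") & (rng.random(n) < 0.40), "IR",
    rng.choice(["IR", "NRL185", "NRL208"], n, p=[0.2, 0.45, 0.35]),
)
enrich = run_enrichment_suite(types, domains)
hit = enrich.sort_values("q_value").iloc[0]
print("strongest enrichment:", hit["fiber_type"], "in", hit["feature"],
      f"OR={hit['odds_ratio']:.2f} q={hit['q_value']:.2e}")

# replicate counts for the differential model: IR usage of Het doubles in odds
rows = []
for case, p_het in (("primary", 0.30), ("metastatic", 0.46)):
    for r in range(5):
        total = rng.poisson(10_000)
        k = rng.binomial(total, p_het)
        rows.append((f"{case}_{r}", case, "IR", "Het", k))
        rows.append((f"{case}_{r}", case, "IR", "other", total - k))
        total2 = rng.poisson(12_000)
        k2 = rng.binomial(total2, 0.30)
        rows.append((f"{case}_{r}", case, "NRL185", "Het", k2))
        rows.append((f"{case}_{r}", case, "NRL185", "other", total2 - k2))
counts = pd.DataFrame(rows, columns=["replicate", "case", "fiber_type", "domain", "count"])

diff = run_differential_suite(counts, case_levels=("primary", "metastatic"))
print(diff[["fiber_type", "domain", "delta", "q_value", "significant"]].to_string(index=False))
print(
    "delta is the case-status coefficient on a log2 scale (a log2 odds ratio,\n"
    "metastatic vs primary): the planted IR-in-heterochromatin gain is called\n"
    "significant while the unchanged NRL185 usage is not."
)
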