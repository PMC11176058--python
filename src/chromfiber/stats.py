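"""Domain-enrichment and differential fiber-usage statistics.

Enrichment of a fiber type in a genomic feature is tested on the 2x2 table
of fiber counts (type membership x feature membership) with a one-sided
Fisher's exact test; the resulting p-values are adjusted with Storey's
q-value.  Differential fiber usage between two conditions is modeled per
(fiber type, domain) pair with a binomial logistic regression of in-domain
usage on case status, using median-of-medians depth-normalized counts;
the case coefficient, divided by ln 2, is reported as a log2 fold change
(a log2 odds ratio) and tested with a Wald test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact

LN2 = float(np.log(2.0))


@dataclass
class ContingencyTable:
    """Fiber counts: a=|A∩B|, b=|A∩B'|, c=|A'∩B|, d=|A'∩B'| where A is
    fiber-type membership and B feature membership."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    fiber_type: str
    feature: str
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")


@dataclass
class DifferentialResult:
    fiber_type: str
    domain: str
    delta: float  # log2 fold change (case-status coefficient / ln 2)
    wald_p: float
    q_value: float = float("nan")
    estimable: bool = True

    @property
    def significant(self) -> bool:
        return self.q_value <= 0.05


def build_table(a_membership, b_membership) -> ContingencyTable:
    a_mask = np.asarray(a_membership, dtype=bool)
    b_mask = np.asarray(b_membership, dtype=bool)
    if len(a_mask) != len(b_mask):
        raise ValueError("membership vectors must have equal length")
    return ContingencyTable(
        a=int(np.sum(a_mask & b_mask)),
        b=int(np.sum(a_mask & ~b_mask)),
        c=int(np.sum(~a_mask & b_mask)),
        d=int(np.sum(~a_mask & ~b_mask)),
    )


def fisher_one_sided(table: ContingencyTable) -> tuple[float, float]:
    """Sample odds ratio and one-sided (greater) Fisher exact p.

    The odds ratio is (a*d)/(b*c), infinite when b*c = 0 with a*d > 0 and
    nan when both products vanish; a zero margin makes the test vacuous
    (p = 1, odds ratio nan).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return float("nan"), 1.0
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    # hypergeometric upper tail P(X >= a) at fixed margins
    p = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
    return odds, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Storey's q-value
# ---------------------------------------------------------------------------


def estimate_pi0(p_values: np.ndarray, lambda_grid: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0.

    For m >= 100 p-values, pi0(lambda) is evaluated over the grid and a
    precision-weighted cubic smoother (weights ~ sqrt(1 - lambda), since
    the tail estimates carry the most sampling noise) is read out at the
    largest lambda; smaller inputs fall back to the fixed lambda = 0.5
    estimate.  The estimate is clipped to (0, 1].
    """
    p = np.asarray(p_values, dtype=np.float64)
    m = len(p)
    if m == 0:
        return 1.0
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    if m < 100:
        lam = 0.5
        pi0 = np.mean(p > lam) / (1 - lam)
    else:
        pi0_lam = np.array([np.mean(p > lam) / (1 - lam) for lam in lambda_grid])
        coeffs = np.polyfit(lambda_grid, pi0_lam, 3, w=np.sqrt(1 - lambda_grid))
        pi0 = float(np.polyval(coeffs, lambda_grid.max()))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_q(
    p_values,
    lambda_grid: np.ndarray | None = None,
    pi0: float | None = None,
) -> np.ndarray:
    """Storey q-values; with ``pi0=1`` this reduces exactly to the
    Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p_values, dtype=np.float64)
    m = len(p)
    if m == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p, lambda_grid)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


# ---------------------------------------------------------------------------
# Enrichment suite
# ---------------------------------------------------------------------------


def run_enrichment_suite(type_labels, feature_labels) -> pd.DataFrame:
    """One-sided enrichment of every fiber type in every feature, with
    Storey q over the full result set (replicates pooled)."""
    types = np.asarray(type_labels)
    feats = np.asarray(feature_labels)
    if len(types) != len(feats):
        raise ValueError("type and feature labels must align per fiber")
    results: list[EnrichmentResult] = []
    for t in sorted(pd.unique(types)):
        for f in sorted(pd.unique(feats)):
            odds, p = fisher_one_sided(build_table(types == t, feats == f))
            results.append(EnrichmentResult(str(t), str(f), odds, p))
    q = storey_q(np.array([r.p_value for r in results]))
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return pd.DataFrame(
        {
            "fiber_type": [r.fiber_type for r in results],
            "feature": [r.feature for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "significant": [r.q_value <= 0.05 for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Differential fiber usage
# ---------------------------------------------------------------------------


def median_of_medians_weights(counts: pd.DataFrame) -> pd.DataFrame:
    """Depth-normalize replicate counts with a median-of-medians scheme.

    ``counts`` needs columns (replicate, fiber_type, domain, count).  Each
    replicate's scale is the median of its nonzero stratum counts; the
    global scale is the median of replicate scales; weights are
    ``count * global / replicate_scale``.  Replicates with zero scale are
    excluded with a warning.
    """
    required = {"replicate", "fiber_type", "domain", "count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    if not (counts["count"] > 0).any():
        raise ValueError("all-zero counts table")
    scales = (
        counts[counts["count"] > 0].groupby("replicate")["count"].median().rename("replicate_scale")
    )
    out = counts.merge(scales, on="replicate", how="left")
    dead = out["replicate_scale"].isna() | (out["replicate_scale"] <= 0)
    if dead.any():
        warnings.warn(
            f"excluding replicates with zero scale: {sorted(out.loc[dead, 'replicate'].unique())}"
        )
        out = out[~dead].copy()
    global_scale = float(scales[scales > 0].median())
    out["weight"] = out["count"] * global_scale / out["replicate_scale"]
    return out.drop(columns="replicate_scale")


def differential_usage(
    weighted: pd.DataFrame,
    fiber_type: str,
    domain: str,
    case_levels: tuple[str, str] | None = None,
) -> DifferentialResult:
    """Weighted logistic model of in-domain usage for one (type, domain).

    For each replicate the successes are the (depth-normalized) count of
    ``fiber_type`` in ``domain`` and the trials are that type's total across
    domains; case status (0/1) is the predictor.  ``case_levels`` fixes the
    coding as (baseline, case) -- e.g. ("primary", "metastatic") reports
    metastatic-versus-primary; by default the levels are taken in sorted
    order.  The case coefficient is reported as a log2 odds ratio with a
    Wald (normal) two-sided p-value.  Complete separation (a case with
    all-zero or all-full usage) is flagged non-estimable.
    """
    required = {"replicate", "case", "fiber_type", "domain", "weight"}
    if not required.issubset(weighted.columns):
        raise ValueError(f"weighted table needs columns {sorted(required)}")
    sub = weighted[weighted["fiber_type"] == fiber_type]
    rows = []
    for (rep, case), grp in sub.groupby(["replicate", "case"], sort=True):
        trials = grp["weight"].sum()
        succ = grp.loc[grp["domain"] == domain, "weight"].sum()
        rows.append((rep, case, succ, trials))
    frame = pd.DataFrame(rows, columns=["replicate", "case", "succ", "trials"])
    cases = sorted(frame["case"].unique())
    if len(cases) != 2 or (frame.groupby("case")["trials"].sum() <= 0).any():
        raise ValueError("both cases must be present with nonzero totals")
    if case_levels is not None:
        if set(case_levels) != set(cases):
            raise ValueError(f"case_levels {case_levels} do not match observed cases {cases}")
        cases = list(case_levels)
    case_num = (frame["case"] == cases[1]).astype(float)
    per_case_succ = frame.groupby("case")["succ"].sum()
    per_case_fail = (frame["trials"] - frame["succ"]).groupby(frame["case"]).sum()
    if (per_case_succ <= 0).any() or (per_case_fail <= 0).any():
        return DifferentialResult(fiber_type, domain, float("nan"), float("nan"), estimable=False)
    endog = np.column_stack([frame["succ"], frame["trials"] - frame["succ"]])
    exog = sm.add_constant(case_num.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer binomial counts are expected here
        fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    return DifferentialResult(
        fiber_type,
        domain,
        delta=float(fit.params[1] / LN2),
        wald_p=float(fit.pvalues[1]),
    )


def run_differential_suite(
    counts: pd.DataFrame, case_levels: tuple[str, str] | None = None
) -> pd.DataFrame:
    """Differential usage over all observed (fiber type, domain) pairs.

    ``counts`` needs columns (replicate, case, fiber_type, domain, count);
    weights are median-of-medians normalized, every pair is modeled, and
    Wald p-values are Storey-adjusted; ``significant`` marks q <= 0.05.
    """
    if "case" not in counts.columns:
        raise ValueError("counts table needs a 'case' column")
    weighted = median_of_medians_weights(counts)
    results: list[DifferentialResult] = []
    for ft in sorted(weighted["fiber_type"].unique()):
        for dom in sorted(weighted["domain"].unique()):
            try:
                results.append(differential_usage(weighted, ft, dom, case_levels=case_levels))
            except ValueError:
                results.append(
                    DifferentialResult(ft, dom, float("nan"), float("nan"), estimable=False)
                )
    estimable = [r for r in results if r.estimable]
    if estimable:
        q = storey_q(np.array([r.wald_p for r in estimable]))
        for r, qv in zip(estimable, q):
            r.q_value = float(qv)
    return pd.DataFrame(
        {
            "fiber_type": [r.fiber_type for r in results],
            "domain": [r.domain for r in results],
            "delta": [r.delta for r in results],
            "wald_p": [r.wald_p for r in results],
            "q_value": [r.q_value for r in results],
            "significant": [r.estimable and r.q_value <= 0.05 for r in results],
            "estimable": [r.estimable for r in results],
        }
    )
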