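"""Group-comparison statistics used throughout the pipeline.

One-sided Wilcoxon rank-sum (exact for small tie-free samples, normal
approximation with tie and continuity correction otherwise), the 2x2
Pearson chi-square without continuity correction, and a convenience wrapper
comparing a per-gene value map between two gene sets.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _ss

#: total sample size at or below which the rank-sum p is exact (tie-free)
EXACT_LIMIT = 10


@dataclass
class GroupComparison:
    """Result of a one-sided two-sample comparison."""

    n_a: int
    n_b: int
    median_a: float
    median_b: float
    statistic: float
    p_value: float
    alternative: str
    method: str = ""
    n_dropped: int = 0


def wilcoxon_one_sided(a, b, alternative: str = "a_greater") -> GroupComparison:
    """One-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``alternative`` is ``a_greater`` or ``b_greater``.  For tie-free inputs
    with n+m <= 10 the p-value is exact (equals full enumeration over all
    rank assignments); otherwise the normal approximation with tie
    correction and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("a_greater", "b_greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = _ss.mannwhitneyu(
        a,
        b,
        alternative="greater" if alternative == "a_greater" else "less",
        method=method,
        use_continuity=True,
    )
    return GroupComparison(
        n_a=int(a.size),
        n_b=int(b.size),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        method=method,
    )


@dataclass
class Chi2Result:
    statistic: float
    p_value: float
    dof: int = 1


def chi2_2x2(table) -> Chi2Result:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be >= 0")
    if (t.sum(axis=0) <= 0).any() or (t.sum(axis=1) <= 0).any():
        raise ValueError("both margins must be positive")
    stat, p, dof, _ = _ss.chi2_contingency(t, correction=False)
    return Chi2Result(float(stat), float(p), int(dof))


def compare_gene_sets(values, set_a, set_b, alternative: str = "a_greater") -> GroupComparison:
    """Apply the one-sided rank-sum test to per-gene values of two gene sets.

    Genes lacking a (finite) value are dropped and counted in
    ``n_dropped``.  Used for dN/dS, expression-level, tau and centrality
    comparisons between gene classes.
    """
    def _collect(genes):
        vals, dropped = [], 0
        for g in sorted(genes):
            v = values.get(g)
            if v is None or not np.isfinite(v):
                dropped += 1
            else:
                vals.append(float(v))
        return vals, dropped

    va, da = _collect(set_a)
    vb, db = _collect(set_b)
    if not va or not vb:
        raise ValueError("a gene set has no genes with values")
    out = wilcoxon_one_sided(va, vb, alternative)
    out.n_dropped = da + db
    return out
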