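"""Cytotoxicity quantification and exact nonparametric statistics.

Complement-dependent and cell-mediated killing assays report gated dead or
dead/dying cell fractions per replicate; specific cytotoxicity is

    cytotoxicity% = (experimental - baseline) / (maximum - baseline) * 100,

where baseline is spontaneous death (isotype/no-antibody control) and
maximum is total lysis. Small replicate groups (N = 3-4 independent
experiments) are compared with an exact two-tailed Mann-Whitney test by
full enumeration of all rank assignments — the convention that yields
P = 2/70 = 0.0286 for complete separation of two groups of four, and
P = 2/20 = 0.10 for two groups of three, the smallest attainable
two-tailed levels at those sizes. Multi-group comparison uses the
Kruskal-Wallis H test (chi-square approximation, tie-corrected) followed
by Dunn's pairwise z tests with family-wise adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import chi2, norm, rankdata
from statsmodels.stats.multitest import multipletests


@dataclass
class CytotoxicityTable:
    """Replicate (experimental, baseline, maximum) death fractions for one
    condition; fractions in [0, 1], maximum > baseline per replicate."""

    condition: str
    replicates: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        for exp, base, mx in self.replicates:
            for v in (exp, base, mx):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{self.condition}: fraction {v} outside [0, 1]")
            if mx <= base:
                raise ValueError(f"{self.condition}: maximum death must exceed baseline")

    def cytotoxicity(self) -> list[float]:
        return [cytotoxicity_percent(e, b, m) for e, b, m in self.replicates]


def cytotoxicity_percent(experimental: float, baseline: float, maximum: float) -> float:
    """Specific cytotoxicity in percent; negative values (experimental below
    baseline) are reported as-is."""
    if maximum <= baseline:
        raise ValueError("maximum cell death must exceed baseline cell death")
    return (experimental - baseline) / (maximum - baseline) * 100.0


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    exact: bool = False
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# exact Mann-Whitney


def _u_statistic(ranks_x: np.ndarray, n1: int, n2: int) -> float:
    return float(np.sum(ranks_x)) - n1 * (n1 + 1) / 2.0


def exact_mann_whitney(x: Sequence[float], y: Sequence[float],
                       max_exact_n: int = 20) -> TestResult:
    """Two-tailed Mann-Whitney U test, exact by full enumeration.

    All C(n1+n2, n1) assignments of the pooled mid-ranks to the first
    sample are enumerated (the observed tie pattern is kept fixed), giving
    the exact permutation distribution of U. The two-tailed p-value is the
    doubled smaller tail, capped at 1. Above ``max_exact_n`` combined
    observations, the tie-corrected normal approximation is used and the
    result is flagged exact=False.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)          # mid-ranks under ties
    u_obs = _u_statistic(ranks[:n1], n1, n2)

    if n1 + n2 <= max_exact_n:
        total = math.comb(n1 + n2, n1)
        n_le = n_ge = 0
        eps = 1e-9
        for idx in combinations(range(n1 + n2), n1):
            u = _u_statistic(ranks[list(idx)], n1, n2)
            if u <= u_obs + eps:
                n_le += 1
            if u >= u_obs - eps:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return TestResult(u_obs, p, "Mann-Whitney (exact enumeration)", exact=True,
                          detail={"n_le": n_le, "n_ge": n_ge, "n_total": total})

    # tie-corrected normal approximation for larger samples
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = (u_obs - mu) / math.sqrt(sigma2) if sigma2 > 0 else 0.0
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return TestResult(u_obs, p, "Mann-Whitney (normal approximation)", exact=False,
                      detail={"z": z})


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn's test


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from the chi-square
    approximation (the 'Gaussian approximated' p of common stats packages)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = [len(g) for g in groups]
    if any(s == 0 for s in sizes):
        raise ValueError("each group must be non-empty")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    if np.allclose(pooled, pooled[0]):
        return TestResult(0.0, 1.0, "Kruskal-Wallis (chi-square approximation)",
                          detail={"df": len(groups) - 1})
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for s in sizes:
        h += np.sum(ranks[start:start + s]) ** 2 / s
        start += s
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    if correction > 0:
        h /= correction
    df = len(groups) - 1
    return TestResult(float(h), float(chi2.sf(h, df)),
                      "Kruskal-Wallis (chi-square approximation)",
                      detail={"df": df, "tie_correction": correction})


def dunns_test(
    groups: Sequence[Sequence[float]],
    adjustment: str = "bonferroni",
    labels: Sequence[str] | None = None,
) -> dict[tuple[str, str], TestResult]:
    """Dunn's post-hoc pairwise comparisons on pooled mean ranks.

    z_ij = (mean_rank_i - mean_rank_j) / sqrt(V (1/n_i + 1/n_j)) with the
    tie-corrected pooled variance V = N(N+1)/12 - sum(t^3 - t)/(12(N-1));
    two-sided normal p-values adjusted family-wise over all pairs
    (any method accepted by statsmodels' multipletests, Bonferroni by
    default, matching common practice after Kruskal-Wallis).
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    labels = list(labels) if labels is not None else [f"group{i + 1}" for i in range(k)]
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    ranks = rankdata(pooled)
    mean_ranks = []
    start = 0
    for s in sizes:
        mean_ranks.append(float(np.mean(ranks[start:start + s])))
        start += s
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    variance = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1)) if n > 1 else 0.0

    pairs = list(combinations(range(k), 2))
    zs, raw_ps = [], []
    for i, j in pairs:
        if variance <= 0:
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(
                variance * (1.0 / sizes[i] + 1.0 / sizes[j]))
        zs.append(z)
        raw_ps.append(min(1.0, 2.0 * norm.sf(abs(z))))
    adjusted = multipletests(raw_ps, method=adjustment)[1] if pairs else []
    out = {}
    for (i, j), z, raw, adj in zip(pairs, zs, raw_ps, adjusted):
        out[(labels[i], labels[j])] = TestResult(
            float(z), float(min(1.0, adj)), f"Dunn ({adjustment})",
            detail={"p_unadjusted": float(raw),
                    "mean_rank_diff": mean_ranks[i] - mean_ranks[j]})
    return out


def compare_to_control(
    treated: CytotoxicityTable,
    control: CytotoxicityTable,
) -> TestResult:
    """Exact Mann-Whitney comparison of treated vs control cytotoxicity%."""
    return exact_mann_whitney(treated.cytotoxicity(), control.cytotoxicity())
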