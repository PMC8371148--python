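"""Single-cell heterogeneity statistics.

Implements the ratio metrics (F-ratio, IF-ratio), robust spread measures
(quartiles with linear interpolation, IQR, coefficient of quartile variation),
Pearson's moment coefficient of skew, fold changes of medians, Spearman rank
correlation, QQ-based distribution assessment against normal or gamma
families, and thin wrappers for the nonparametric group tests (Mann–Whitney,
Kruskal–Wallis with Dunn–Šidák post hoc).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "f_ratio",
    "if_ratio",
    "quartiles",
    "iqr",
    "cqv",
    "pearson_skew",
    "fold_change_of_medians",
    "spearman",
    "cv_of_medians",
    "DistAssessment",
    "assess_distribution",
    "rank_tests",
    "dunn_sidak",
]


def f_ratio(F, G):
    """F/(F+G): the fraction of actin in filamentous (complex) form, in [0, 1].

    Accepts scalars or arrays; raises when F + G is zero (undefined ratio) or
    either input is negative.
    """
    F = np.asarray(F, float)
    G = np.asarray(G, float)
    if np.any(F < 0) or np.any(G < 0):
        raise ValueError("AFU values must be >= 0")
    tot = F + G
    if np.any(tot == 0):
        raise ZeroDivisionError("F + G = 0: ratio undefined")
    out = F / tot
    return float(out) if out.ndim == 0 else out


def if_ratio(IF, VIM_monomer):
    """IF/(IF + VIM_monomer): fraction of vimentin in intermediate filaments."""
    return f_ratio(IF, VIM_monomer)


def quartiles(values) -> tuple[float, float]:
    """(Q1, Q3) with linear interpolation between order statistics."""
    v = np.asarray(values, float)
    if v.size < 4:
        raise ValueError("need n >= 4 for quartiles")
    q1, q3 = np.percentile(v, [25, 75], method="linear")
    return float(q1), float(q3)


def iqr(values) -> float:
    q1, q3 = quartiles(values)
    return q3 - q1


def cqv(values) -> float:
    """Coefficient of quartile variation (Q3 − Q1)/(Q3 + Q1): a spread measure
    robust to the heavy right tails of gamma-like expression distributions."""
    q1, q3 = quartiles(values)
    if q1 + q3 == 0:
        raise ZeroDivisionError("Q1 + Q3 = 0: CQV undefined")
    return (q3 - q1) / (q3 + q1)


def pearson_skew(values) -> float:
    """Pearson's moment coefficient of skew: E[((X − μ)/σ)³] over the sample
    (population σ)."""
    v = np.asarray(values, float)
    if v.size < 3:
        raise ValueError("need n >= 3 for skew")
    mu = v.mean()
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance: skew undefined")
    return float(np.mean(((v - mu) / sd) ** 3))


def fold_change_of_medians(a, b) -> float:
    """median(a) / median(b); the fold-change arithmetic used for treated vs
    control comparisons."""
    mb = float(np.median(np.asarray(b, float)))
    if mb <= 0:
        raise ValueError("median of the denominator sample must be > 0")
    return float(np.median(np.asarray(a, float))) / mb


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, float)
    if x.size < 3:
        raise ValueError("need n >= 3 for correlation")
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


def cv_of_medians(medians, ddof: int = 0) -> float:
    """Coefficient of variation across replicate medians (population sd by
    default, which is the convention that matches reporting CV of a small,
    fixed set of device medians)."""
    m = np.asarray(medians, float)
    mean = m.mean()
    if mean == 0:
        raise ZeroDivisionError("mean of medians is zero")
    return float(m.std(ddof=ddof) / mean)


@dataclass
class DistAssessment:
    family: str
    params: dict
    theoretical: np.ndarray
    empirical: np.ndarray
    linearity: float  # squared correlation of the QQ points


def assess_distribution(values, family: str = "normal") -> DistAssessment:
    """QQ assessment of a sample against a fitted normal or gamma.

    Normal is fitted by sample mean/sd; gamma by method of moments
    (shape = mean²/var, scale = var/mean), the stable choice at modest n.
    Theoretical quantiles are evaluated at plotting positions (i − 0.5)/n;
    ``linearity`` is the squared Pearson correlation of the QQ point pairs
    (1.0 = the sample is exactly a linear transform of the family quantiles).
    """
    v = np.sort(np.asarray(values, float))
    n = v.size
    if n < 20:
        raise ValueError("need n >= 20 to assess a distribution")
    if v.std(ddof=0) == 0:
        raise ValueError("degenerate (constant) sample")
    p = (np.arange(1, n + 1) - 0.5) / n
    if family == "normal":
        mu, sd = v.mean(), v.std(ddof=1)
        theo = sps.norm.ppf(p, loc=mu, scale=sd)
        params = {"mean": float(mu), "sd": float(sd)}
    elif family == "gamma":
        if np.any(v <= 0):
            raise ValueError("gamma assessment requires strictly positive values")
        mean, var = v.mean(), v.var(ddof=1)
        shape = mean**2 / var
        scale = var / mean
        theo = sps.gamma.ppf(p, shape, scale=scale)
        params = {"shape": float(shape), "scale": float(scale)}
    else:
        raise ValueError(f"unknown family {family!r}")
    r = np.corrcoef(theo, v)[0, 1]
    return DistAssessment(family=family, params=params, theoretical=theo,
                          empirical=v, linearity=float(r**2))


def dunn_sidak(groups: dict[str, np.ndarray]) -> list[dict]:
    """Dunn's pairwise rank comparisons after Kruskal–Wallis, with Šidák
    family-wise correction.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)·(1/n_i + 1/n_j)) on the pooled
    ranks, with the standard tie correction T = Σ(t³ − t)/(12(N − 1));
    adjusted p = 1 − (1 − p)^m over the m pairwise comparisons.
    """
    names = list(groups)
    sizes = {k: len(np.asarray(groups[k])) for k in names}
    pooled = np.concatenate([np.asarray(groups[k], float) for k in names])
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    mean_rank = {}
    start = 0
    for k in names:
        mean_rank[k] = ranks[start : start + sizes[k]].mean()
        start += sizes[k]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    out = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out.append(
            dict(group_a=a, group_b=b, z=float(z), p_unadjusted=float(p),
                 p_adjusted=float(min(1.0, 1.0 - (1.0 - min(p, 1.0)) ** m)))
        )
    return out


def rank_tests(groups: dict[str, np.ndarray]) -> dict:
    """Two-sided Mann–Whitney for 2 groups; Kruskal–Wallis plus Dunn–Šidák
    pairwise comparisons for more."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for k, v in groups.items():
        if len(np.asarray(v)) == 0:
            raise ValueError(f"group {k!r} is empty")
    names = list(groups)
    if len(names) == 2:
        stat, p = sps.mannwhitneyu(groups[names[0]], groups[names[1]], alternative="two-sided")
        return {"test": "mann-whitney", "U": float(stat), "p": float(p)}
    stat, p = sps.kruskal(*[groups[k] for k in names])
    return {
        "test": "kruskal-wallis",
        "H": float(stat),
        "p": float(p),
        "posthoc": dunn_sidak(groups),
    }
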