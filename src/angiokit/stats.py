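"""Assumption-gated group comparisons with all four omnibus/post-hoc routes.

Small-sample group measurements (n = 3-6 gels per condition is typical for
this kind of experiment) are tested through a 2x2 decision tree:

    normality (Shapiro-Wilk, per group) x homoscedasticity
    (Bartlett when normal, median-centred Levene / Brown-Forsythe
    otherwise)

    normal,     homoscedastic   -> one-way ANOVA        + Tukey HSD
    normal,     heteroscedastic -> Welch ANOVA          + Games-Howell
    non-normal, homoscedastic   -> Kruskal-Wallis       + Dunn
    non-normal, heteroscedastic -> trimmed-means Welch F + Games-Howell

Welch ANOVA, the Games-Howell test, Dunn's test (with tie correction) and
the heteroscedastic F test on trimmed means with Winsorized variances are
implemented here directly; the classical ANOVA, Kruskal-Wallis and Tukey
HSD pieces come from scipy. With groups of n = 3 the Shapiro-Wilk gate has
negligible power; the router records a low-power warning rather than
refusing to test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupData",
    "StatRoutingResult",
    "gate_assumptions",
    "route_and_test",
    "welch_anova",
    "games_howell",
    "trimmed_welch_f",
    "dunn_posthoc",
    "anova_tukey",
]

ROUTES = {
    (True, True): ("anova", "tukey"),
    (True, False): ("welch_anova", "games_howell"),
    (False, True): ("kruskal_wallis", "dunn"),
    (False, False): ("trimmed_welch", "games_howell"),
}


@dataclass
class GroupData:
    """Group label → numeric measurements, with metric name and units."""

    groups: dict[str, np.ndarray]
    metric: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.groups = {
            str(k): np.asarray(v, dtype=float).ravel()
            for k, v in self.groups.items()
        }
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        for k, v in self.groups.items():
            if v.size < 2:
                raise ValueError(f"group {k!r} has fewer than 2 observations")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"group {k!r} contains non-finite values")

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    def arrays(self) -> list[np.ndarray]:
        return list(self.groups.values())

    @property
    def k(self) -> int:
        return len(self.groups)


@dataclass
class OmnibusResult:
    name: str
    statistic: float
    df: tuple[float, ...]
    pvalue: float

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": list(self.df),
            "pvalue": self.pvalue,
        }


@dataclass
class StatRoutingResult:
    normality_pvalues: dict[str, float]
    normal: bool
    variance_test: str
    variance_pvalue: float
    homoscedastic: bool
    omnibus: OmnibusResult
    posthoc_name: str
    posthoc: pd.DataFrame
    alpha: float
    warnings: list[str] = field(default_factory=list)
    forced: bool = False

    def to_dict(self) -> dict:
        return {
            "normality_pvalues": self.normality_pvalues,
            "normal": self.normal,
            "variance_test": self.variance_test,
            "variance_pvalue": self.variance_pvalue,
            "homoscedastic": self.homoscedastic,
            "omnibus": self.omnibus.to_dict(),
            "posthoc_name": self.posthoc_name,
            "posthoc": self.posthoc.to_dict(orient="records"),
            "alpha": self.alpha,
            "warnings": self.warnings,
            "forced": self.forced,
        }


# --------------------------------------------------------------------------
# assumption gate
# --------------------------------------------------------------------------

def gate_assumptions(data: GroupData, alpha: float = 0.05):
    """Shapiro-Wilk per group, then Bartlett (if normal) or Brown-Forsythe.

    Returns ``(normal, homoscedastic, evidence)``. Bartlett's test assumes
    normality, so it is only consulted when the normality gate passes;
    otherwise the median-centred Levene variant is used.
    """
    norm_p: dict[str, float] = {}
    warnings: list[str] = []
    for label, vals in data.groups.items():
        if vals.size < 3:
            raise ValueError(
                f"group {label!r}: Shapiro-Wilk needs at least 3 observations"
            )
        if np.ptp(vals) == 0:
            raise ValueError(f"group {label!r} is constant; normality undefined")
        norm_p[label] = float(sps.shapiro(vals).pvalue)
    if min(v.size for v in data.groups.values()) < 8:
        warnings.append(
            "small groups: the Shapiro-Wilk normality gate has low power"
        )
    normal = all(p > alpha for p in norm_p.values())
    if normal:
        var_name = "bartlett"
        var_stat = sps.bartlett(*data.arrays())
    else:
        var_name = "levene_median"
        var_stat = sps.levene(*data.arrays(), center="median")
    var_p = float(var_stat.pvalue)
    homoscedastic = var_p > alpha
    evidence = {
        "normality_pvalues": norm_p,
        "variance_test": var_name,
        "variance_pvalue": var_p,
        "warnings": warnings,
    }
    return normal, homoscedastic, evidence


# --------------------------------------------------------------------------
# omnibus tests
# --------------------------------------------------------------------------

def anova_omnibus(data: GroupData) -> OmnibusResult:
    arrays = data.arrays()
    res = sps.f_oneway(*arrays)
    n = sum(a.size for a in arrays)
    return OmnibusResult(
        "anova", float(res.statistic), (data.k - 1, n - data.k), float(res.pvalue)
    )


def welch_anova(data: GroupData) -> OmnibusResult:
    """Welch's heteroscedasticity-robust one-way ANOVA.

    With two groups the statistic reduces exactly to the square of the
    Welch t statistic and yields the identical p-value.
    """
    arrays = data.arrays()
    k = len(arrays)
    n = np.array([a.size for a in arrays], float)
    m = np.array([a.mean() for a in arrays])
    v = np.array([a.var(ddof=1) for a in arrays])
    if np.any(v == 0):
        raise ValueError("Welch ANOVA undefined for a zero-variance group")
    w = n / v
    bigw = w.sum()
    mw = (w * m).sum() / bigw
    a_num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    tail = ((1 - w / bigw) ** 2 / (n - 1)).sum()
    b_den = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * tail
    f = a_num / b_den
    df1 = k - 1.0
    df2 = (k**2 - 1.0) / (3.0 * tail)
    p = float(sps.f.sf(f, df1, df2))
    return OmnibusResult("welch_anova", float(f), (df1, float(df2)), p)


def kruskal_omnibus(data: GroupData, method: str = "auto") -> OmnibusResult:
    """Kruskal-Wallis H with tie correction.

    ``method='exact'`` (or ``'auto'`` with small samples) computes the
    p-value by exhaustive enumeration of all group assignments of the
    pooled ranks — e.g. 1680 partitions for n = (3, 3, 3) — instead of the
    chi-square approximation, which is unreliable at these sizes.
    """
    res = sps.kruskal(*data.arrays())
    h_obs = float(res.statistic)
    sizes = [a.size for a in data.arrays()]
    n_part = _n_partitions(sizes)
    use_exact = method == "exact" or (method == "auto" and n_part <= 20_000)
    if not use_exact:
        return OmnibusResult("kruskal_wallis", h_obs, (data.k - 1,), float(res.pvalue))
    pooled = np.concatenate(data.arrays())
    ranks = sps.rankdata(pooled)
    n = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - ((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
    if tie_corr == 0:
        raise ValueError("all observations identical")

    def h_from_rank_sums(rank_sums):
        h = (12.0 / (n * (n + 1))) * sum(
            r * r / m for r, m in zip(rank_sums, sizes)
        ) - 3 * (n + 1)
        return h / tie_corr

    hits = 0
    total = 0
    for assignment in _partitions(tuple(range(n)), sizes):
        rank_sums = [ranks[list(g)].sum() for g in assignment]
        total += 1
        hits += h_from_rank_sums(rank_sums) >= h_obs - 1e-12
    return OmnibusResult("kruskal_wallis", h_obs, (data.k - 1,), hits / total)


def _n_partitions(sizes) -> int:
    n = sum(sizes)
    total = 1
    for s in sizes:
        total *= math.comb(n, s)
        n -= s
    return total


def _partitions(indices: tuple, sizes):
    """Yield all splits of ``indices`` into consecutive groups of ``sizes``."""
    if len(sizes) == 1:
        yield (indices,)
        return
    first, rest_sizes = sizes[0], sizes[1:]
    for chosen in combinations(indices, first):
        chosen_set = set(chosen)
        rest = tuple(i for i in indices if i not in chosen_set)
        for tail in _partitions(rest, rest_sizes):
            yield (chosen,) + tail


def _trim_counts(n: int, trim: float) -> tuple[int, int]:
    g = int(math.floor(trim * n))
    h = n - 2 * g
    return g, h


def _winsorized_variance(x: np.ndarray, g: int) -> float:
    xs = np.sort(x)
    w = xs.copy()
    if g > 0:
        w[:g] = xs[g]
        w[-g:] = xs[-g - 1]
    return float(np.var(w, ddof=1))


def trimmed_welch_f(data: GroupData, trim: float = 0.2) -> OmnibusResult:
    """Heteroscedastic F test on trimmed means with Winsorized variances.

    Each group's mean is replaced by its ``trim``-trimmed mean and its
    squared standard error by the Winsorized variance scaled to the
    effective (post-trim) sample size h_i; the Welch construction is then
    applied with h_i in place of n_i. ``trim=0`` reduces to ordinary Welch
    ANOVA exactly.
    """
    if not (0.0 <= trim < 0.5):
        raise ValueError("trim proportion must lie in [0, 0.5)")
    arrays = data.arrays()
    k = len(arrays)
    tmeans, d, h_eff = [], [], []
    for a in arrays:
        g, h = _trim_counts(a.size, trim)
        if h < 2:
            raise ValueError("over-trimming: fewer than 2 observations remain")
        xs = np.sort(a)
        tmeans.append(float(xs[g : a.size - g].mean()))
        sw2 = _winsorized_variance(a, g)
        if sw2 == 0:
            raise ValueError("zero Winsorized variance in a group")
        d.append((a.size - 1) * sw2 / (h * (h - 1)))
        h_eff.append(h)
    tmeans = np.array(tmeans)
    d = np.array(d)
    h_eff = np.array(h_eff, float)
    w = 1.0 / d
    u = w.sum()
    xt = (w * tmeans).sum() / u
    a_num = (w * (tmeans - xt) ** 2).sum() / (k - 1)
    tail = ((1 - w / u) ** 2 / (h_eff - 1)).sum()
    f = a_num / (1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * tail)
    df1 = k - 1.0
    df2 = 1.0 / (3.0 / (k**2 - 1.0) * tail)
    p = float(sps.f.sf(f, df1, df2))
    return OmnibusResult("trimmed_welch", float(f), (df1, float(df2)), p)


# --------------------------------------------------------------------------
# post-hoc tests
# --------------------------------------------------------------------------

def anova_tukey(data: GroupData) -> pd.DataFrame:
    """Tukey HSD pairwise table (p-values are family-wise by construction)."""
    arrays = data.arrays()
    labels = data.labels
    res = sps.tukey_hsd(*arrays)
    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        rows.append(
            {
                "group1": labels[i],
                "group2": labels[j],
                "statistic": float(res.statistic[i, j]),
                "df": float(sum(a.size for a in arrays) - len(arrays)),
                "p_raw": float(res.pvalue[i, j]),
                "p_adj": float(res.pvalue[i, j]),
            }
        )
    return pd.DataFrame(rows)


def games_howell(data: GroupData) -> pd.DataFrame:
    """Games-Howell pairwise comparisons for unequal variances.

    For each pair, a Welch t statistic with Welch-Satterthwaite degrees of
    freedom is referred to the studentized-range distribution with
    q = t * sqrt(2) and the full number of groups k, which controls the
    family-wise error without assuming equal variances. The returned
    p-values are inherently multiplicity-adjusted.
    """
    labels = data.labels
    arrays = data.arrays()
    k = len(arrays)
    rows = []
    for i, j in combinations(range(k), 2):
        a, b = arrays[i], arrays[j]
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va == 0 and vb == 0:
            raise ValueError(
                f"both groups {labels[i]!r}, {labels[j]!r} have zero variance"
            )
        se2a, se2b = va / a.size, vb / b.size
        se = math.sqrt(se2a + se2b)
        t = (a.mean() - b.mean()) / se
        df = (se2a + se2b) ** 2 / (
            se2a**2 / (a.size - 1) + se2b**2 / (b.size - 1)
        )
        q = abs(t) * math.sqrt(2.0)
        p = float(sps.studentized_range.sf(q, k, df))
        p = min(1.0, max(0.0, p))
        rows.append(
            {
                "group1": labels[i],
                "group2": labels[j],
                "statistic": float(t),
                "df": float(df),
                "p_raw": p,
                "p_adj": p,
            }
        )
    return pd.DataFrame(rows)


def dunn_posthoc(data: GroupData, adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based pairwise test after Kruskal-Wallis, tie-corrected.

    z statistics use the pooled-rank variance N(N+1)/12 reduced by the tie
    term sum(t^3 - t)/(12(N-1)); two-sided normal p-values are adjusted by
    Holm (default), Bonferroni, or left raw.
    """
    if adjust not in ("holm", "bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    labels = data.labels
    arrays = data.arrays()
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    if np.ptp(pooled) == 0:
        raise ValueError("all observations identical; ranks fully tied")
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        se = math.sqrt(var_base * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = float(2.0 * sps.norm.sf(abs(z)))
        rows.append(
            {
                "group1": labels[i],
                "group2": labels[j],
                "statistic": float(z),
                "df": float("nan"),
                "p_raw": min(1.0, p),
            }
        )
    table = pd.DataFrame(rows)
    if adjust == "none":
        table["p_adj"] = table["p_raw"]
    else:
        table["p_adj"] = multipletests(table["p_raw"], method=adjust)[1]
    return table


# --------------------------------------------------------------------------
# router
# --------------------------------------------------------------------------

_OMNIBUS = {
    "anova": anova_omnibus,
    "welch_anova": welch_anova,
    "kruskal_wallis": kruskal_omnibus,
    "trimmed_welch": trimmed_welch_f,
}


def route_and_test(
    data: GroupData,
    alpha: float = 0.05,
    force_route: tuple[bool, bool] | None = None,
    trim: float = 0.2,
    dunn_adjust: str = "holm",
    posthoc: bool = True,
) -> StatRoutingResult:
    """Gate assumptions, pick the matching omnibus + post-hoc pair, run both.

    ``force_route`` overrides the gate with an explicit ``(normal,
    homoscedastic)`` verdict, for reproducing a stated test choice.
    ``posthoc=False`` runs the gate and omnibus only (e.g. for calibration
    simulations where only the omnibus decision matters).
    """
    normal, homo, evidence = gate_assumptions(data, alpha=alpha)
    forced = force_route is not None
    if forced:
        normal, homo = force_route
    omni_name, post_name = ROUTES[(normal, homo)]
    if omni_name == "trimmed_welch":
        omnibus = trimmed_welch_f(data, trim=trim)
    else:
        omnibus = _OMNIBUS[omni_name](data)
    if not posthoc:
        posthoc_table = pd.DataFrame(
            columns=["group1", "group2", "statistic", "df", "p_raw", "p_adj"]
        )
    elif post_name == "tukey":
        posthoc_table = anova_tukey(data)
    elif post_name == "games_howell":
        posthoc_table = games_howell(data)
    else:
        posthoc_table = dunn_posthoc(data, adjust=dunn_adjust)
    return StatRoutingResult(
        normality_pvalues=evidence["normality_pvalues"],
        normal=normal,
        variance_test=evidence["variance_test"],
        variance_pvalue=evidence["variance_pvalue"],
        homoscedastic=homo,
        omnibus=omnibus,
        posthoc_name=post_name,
        posthoc=posthoc_table,
        alpha=alpha,
        warnings=evidence["warnings"],
        forced=forced,
    )
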