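"""Trial statistics for the screening design.

Fixed-effects two-factor RCBD ANOVA (replicate = block, genotype crossed
with salinity), Fisher's protected LSD, simple-regression R^2 and the
percentile box-whisker summaries used to display trait distributions by
treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .traits import TREATMENTS

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_code(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else NS."""
    if not np.isfinite(p):
        return "NS"
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "NS"


class UnbalancedDesignError(ValueError):
    """Raised when the RCBD decomposition is requested on incomplete data."""


@dataclass
class AnovaTable:
    """Fixed-effects RCBD decomposition for one trait.

    ``table`` rows: block, genotype, salinity, genotype:salinity, error,
    total; columns: df, ss, ms, F, p, stars.  F and p are NaN for error,
    total, and (by convention) the block row when requested, and stars
    are NS whenever F is not computable (zero error variance with zero
    effect variance).
    """

    trait: str
    table: pd.DataFrame
    n_genotypes: int
    n_treatments: int
    n_blocks: int

    def __getitem__(self, source: str) -> pd.Series:
        return self.table.loc[source]

    @property
    def mse(self) -> float:
        return float(self.table.loc["error", "ms"])

    @property
    def df_error(self) -> int:
        return int(self.table.loc["error", "df"])

    def star_row(self) -> dict[str, str]:
        return {src: self.table.loc[src, "stars"]
                for src in ("salinity", "genotype", "genotype:salinity")}


def _anova_from_cube(y: np.ndarray) -> dict[str, tuple[int, float]]:
    """SS/df for a balanced g x s x r response cube (genotype, salinity, block)."""
    g, s, r = y.shape
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_block = float(g * s * ((y.mean(axis=(0, 1)) - grand) ** 2).sum())
    ss_geno = float(s * r * ((y.mean(axis=(1, 2)) - grand) ** 2).sum())
    ss_sal = float(g * r * ((y.mean(axis=(0, 2)) - grand) ** 2).sum())
    cell = y.mean(axis=2)
    inter = cell - y.mean(axis=(1, 2))[:, None] - y.mean(axis=(0, 2))[None, :] + grand
    ss_int = float(r * (inter ** 2).sum())
    ss_err = ss_total - ss_block - ss_geno - ss_sal - ss_int
    if ss_err < 0:  # roundoff on near-perfect fits
        ss_err = max(ss_err, 0.0) if abs(ss_err) < 1e-10 * max(ss_total, 1.0) else ss_err
    df_err = (g * s * r - 1) - (r - 1) - (g - 1) - (s - 1) - (g - 1) * (s - 1)
    return {
        "block": (r - 1, ss_block),
        "genotype": (g - 1, ss_geno),
        "salinity": (s - 1, ss_sal),
        "genotype:salinity": ((g - 1) * (s - 1), ss_int),
        "error": (df_err, ss_err),
        "total": (g * s * r - 1, ss_total),
    }


def rcbd_anova(table: pd.DataFrame, trait: str) -> AnovaTable:
    """Two-factor RCBD ANOVA for one trait of a long-format trial table.

    Requires balanced complete data: every genotype x treatment x
    replicate cell present exactly once for the trait.  F-ratios use the
    pooled error mean square; p-values come from the F distribution;
    star codes use the 0.001/0.01/0.05 thresholds.
    """
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise KeyError(f"trait {trait!r} absent from the table")

    genotypes = sorted(sub["genotype"].unique())
    treatments = [t for t in TREATMENTS if t in set(sub["treatment"])]
    reps = sorted(sub["replicate"].unique())
    g, s, r = len(genotypes), len(treatments), len(reps)
    if len(sub) != g * s * r:
        raise UnbalancedDesignError(
            f"trait {trait!r}: {len(sub)} observations for a {g}x{s}x{r} design "
            f"({g * s * r} expected); consult the missing-cell report of aggregate_means")

    pivot = sub.set_index(["genotype", "treatment", "replicate"])["value"]
    try:
        y = pivot.to_numpy().reshape(-1)
        full = pd.MultiIndex.from_product([genotypes, treatments, reps],
                                          names=["genotype", "treatment", "replicate"])
        y = pivot.reindex(full).to_numpy().reshape(g, s, r)
    except Exception as exc:  # pragma: no cover - defensive
        raise UnbalancedDesignError(str(exc)) from exc
    if np.isnan(y).any():
        raise UnbalancedDesignError(
            f"trait {trait!r}: missing genotype x treatment x replicate cells; "
            "consult the missing-cell report of aggregate_means")

    parts = _anova_from_cube(y)
    rows = []
    mse = parts["error"][1] / parts["error"][0] if parts["error"][0] > 0 else np.nan
    for src in ("block", "genotype", "salinity", "genotype:salinity", "error", "total"):
        df_, ss = parts[src]
        ms = ss / df_ if df_ > 0 else np.nan
        if src in ("error", "total"):
            F = p = np.nan
            stars = ""
        else:
            if np.isfinite(mse) and mse > 0:
                F = ms / mse
                p = float(sps.f.sf(F, df_, parts["error"][0]))
            else:
                F = p = np.nan  # zero error variance: F not computable
            stars = star_code(p)
        rows.append((src, df_, ss, ms, F, p, stars))
    tbl = pd.DataFrame(rows, columns=["source", "df", "ss", "ms", "F", "p", "stars"]
                       ).set_index("source")
    return AnovaTable(trait=trait, table=tbl, n_genotypes=g, n_treatments=s, n_blocks=r)


def anova_star_matrix(table: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Traits x sources matrix of significance stars (screening overview)."""
    rows = {t: rcbd_anova(table, t).star_row() for t in traits}
    return pd.DataFrame(rows).T[["salinity", "genotype", "genotype:salinity"]]


@dataclass
class LsdResult:
    """Fisher's protected LSD for one factor's means."""

    lsd: float
    alpha: float
    comparisons_performed: bool  # False when the protecting F-test was NS
    significant_pairs: list[tuple[str, str]] = field(default_factory=list)
    pairs: dict[tuple[str, str], bool] = field(default_factory=dict)


def fisher_lsd(anova: AnovaTable, means: pd.Series, r: int,
               alpha: float = 0.05, factor: str = "salinity") -> LsdResult:
    """Protected pairwise comparisons of factor-level means.

    LSD = t(1 - alpha/2, df_error) * sqrt(2 MSE / r), where r is the
    number of observations behind each mean.  A pair is flagged iff the
    absolute mean difference exceeds the LSD — but only when the
    protecting omnibus F-test for ``factor`` is significant at alpha;
    otherwise no pair is flagged and ``comparisons_performed`` is False.
    """
    if r <= 0:
        raise ValueError(f"replication r must be positive, got {r}")
    mse = anova.mse
    if not np.isfinite(mse) or mse < 0:
        raise ValueError(f"error mean square must be >= 0, got {mse}")
    p_protect = anova[factor]["p"]
    lsd = float(sps.t.ppf(1 - alpha / 2, anova.df_error) * np.sqrt(2 * mse / r))

    protected_ok = bool(np.isfinite(p_protect) and p_protect <= alpha)
    pairs: dict[tuple[str, str], bool] = {}
    sig: list[tuple[str, str]] = []
    for a, b in combinations(means.index, 2):
        flag = bool(protected_ok and abs(means[a] - means[b]) > lsd)
        pairs[(a, b)] = flag
        if flag:
            sig.append((a, b))
    return LsdResult(lsd=lsd, alpha=alpha, comparisons_performed=protected_ok,
                     significant_pairs=sig, pairs=pairs)


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r2: float


def regression_r2(x, y) -> RegressionFit:
    """Ordinary least squares of y on x with the coefficient of determination.

    Constant x raises (slope undefined); constant y returns r2 = 0 by
    convention (no variance to explain).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return RegressionFit(slope=float(slope), intercept=float(intercept), r2=0.0)
    resid = y - (slope * x + intercept)
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
    return RegressionFit(slope=float(slope), intercept=float(intercept), r2=r2)


@dataclass
class BoxplotSummary:
    """Percentile box-whisker summary for one group.

    Box spans Q1-Q3 with the median inside; whiskers sit at the 5th and
    95th percentiles (linear-interpolation quantiles); observations
    outside the whiskers are listed as outliers.
    """

    p5: float
    q1: float
    median: float
    q3: float
    p95: float
    outliers: list[float] = field(default_factory=list)


def boxplot_summary(values_by_group: dict[str, np.ndarray] | pd.Series) -> dict[str, BoxplotSummary]:
    """Five-number percentile summaries per group (e.g. per treatment).

    Accepts a mapping group -> values or a Series with a group level in
    its index (grouped on the first index level).
    """
    if isinstance(values_by_group, pd.Series):
        groups = {str(k): v.to_numpy() for k, v in values_by_group.groupby(level=0)}
    else:
        groups = {str(k): np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    out: dict[str, BoxplotSummary] = {}
    for name, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {name!r} is empty")
        p5, q1, med, q3, p95 = np.percentile(vals, [5, 25, 50, 75, 95])
        outliers = sorted(float(v) for v in vals[(vals < p5) | (vals > p95)])
        out[name] = BoxplotSummary(p5=float(p5), q1=float(q1), median=float(med),
                                   q3=float(q3), p95=float(p95), outliers=outliers)
    return out
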