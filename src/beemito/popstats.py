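"""Population summaries over haplotype call tables.

Implements the descriptive and inferential statistics used for regional
mitotype monitoring: stratified frequency tables (per haplotype, or collapsed
to the C1 / C2(+C2c) / M / A groups used in gel-era reporting), the haplotype
diversity statistic

    H = 1 - sum_i x_i**2            (optionally multiplied by N/(N-1)),

the probability that two randomly sampled bees carry different mitotypes, a
Fisher exact test of differentiation across strata (exact enumeration for 2x2
tables, conditional Monte Carlo with the table-probability criterion for
larger tables), and a logistic regression of mitotype presence/absence on
longitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "PROVINCES",
    "FrequencyTable",
    "DiversityResult",
    "TestResult",
    "LogisticResult",
    "lineage_group",
    "frequency_table",
    "haplotype_diversity",
    "fisher_exact_mc",
    "logistic_presence_vs_longitude",
]

#: administrative province codes of the sampled region
PROVINCES = ("PC", "PR", "RE", "MO", "BO", "FE", "RA", "FC", "RN")

#: reporting groups used in the collapsed frequency tables
LINEAGE_GROUPS = ("C1", "C2", "M", "A")


@dataclass(frozen=True)
class FrequencyTable:
    strata: tuple
    categories: tuple
    counts: np.ndarray  # shape (len(strata), len(categories))

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.strata), len(self.categories)):
            raise ValueError("counts shape does not match strata/categories")
        if (counts < 0).any():
            raise ValueError("negative counts")

    @property
    def N(self) -> int:
        return int(np.asarray(self.counts).sum())

    def to_frame(self, frequencies: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            np.asarray(self.counts), index=list(self.strata), columns=list(self.categories)
        )
        if frequencies:
            return df.div(df.sum(axis=1), axis=0)
        return df

    def category_totals(self) -> dict:
        totals = np.asarray(self.counts).sum(axis=0)
        return dict(zip(self.categories, (int(t) for t in totals)))


@dataclass(frozen=True)
class DiversityResult:
    H: float
    N: int
    corrected: bool
    k: int


@dataclass(frozen=True)
class TestResult:
    statistic: float | None
    p_value: float
    method: str
    n_resamples: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class LogisticResult:
    slope: float | None
    intercept: float | None
    chi2: float | None
    p_value: float | None
    n: int
    separation: bool = False
    converged: bool = True

    @property
    def statistic(self) -> float | None:
        return self.chi2


def lineage_group(haplotype: str, lineage: str) -> str:
    """Collapse a haplotype call to the C1/C2/M/A reporting group.

    C2 includes C2c; M and A collect every haplotype of those lineages.
    """
    if haplotype == "C1":
        return "C1"
    if lineage == "C":
        return "C2"
    if lineage in ("M", "A"):
        return lineage
    raise ValueError(f"no reporting group for lineage {lineage!r}")


def frequency_table(records, by: str = "year", level: str = "haplotype") -> FrequencyTable:
    """Counts per stratum.

    ``records`` is a DataFrame (or iterable of mappings/dataclasses) with at
    least ``haplotype``, ``lineage`` and the stratum column ``by`` (``year``
    or ``province``).  ``level`` is ``haplotype`` or ``lineage-grouped``.
    """
    df = _as_frame(records)
    if len(df) == 0:
        raise ValueError("no records")
    if by not in df.columns:
        raise ValueError(f"unknown stratum field {by!r}")
    if level == "haplotype":
        cat = df["haplotype"]
        categories = tuple(pd.unique(cat))
    elif level == "lineage-grouped":
        cat = [lineage_group(h, l) for h, l in zip(df["haplotype"], df["lineage"])]
        categories = tuple(g for g in LINEAGE_GROUPS if g in set(cat))
    else:
        raise ValueError(f"unknown category level {level!r}")
    tab = pd.crosstab(df[by], pd.Series(list(cat), index=df.index, name="category"))
    tab = tab.reindex(columns=list(categories), fill_value=0)
    return FrequencyTable(
        strata=tuple(tab.index),
        categories=categories,
        counts=tab.to_numpy(),
    )


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for r in records:
        if hasattr(r, "__dataclass_fields__"):
            rows.append({k: getattr(r, k) for k in r.__dataclass_fields__})
        else:
            rows.append(dict(r))
    return pd.DataFrame(rows)


def haplotype_diversity(counts, corrected: bool = False) -> DiversityResult:
    """Probability that two randomly drawn samples carry different haplotypes.

    With ``corrected=True`` the small-sample factor N/(N-1) is applied.
    """
    counts = np.asarray(list(counts), dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    n = counts.sum()
    if n <= 0:
        raise ValueError("at least one positive count required")
    x = counts / n
    h = 1.0 - float(np.sum(x**2))
    if corrected:
        if n < 2:
            raise ValueError("corrected H requires N >= 2")
        h *= n / (n - 1.0)
    return DiversityResult(H=h, N=int(n), corrected=corrected, k=int((counts > 0).sum()))


# ---------------------------------------------------------------------------
# Fisher exact test


def _log_table_prob(table: np.ndarray, lgf: np.ndarray) -> float:
    """Log null (multivariate hypergeometric) probability of an r x c table."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(lgf[r].sum() + lgf[c].sum() - lgf[n] - lgf[table].sum())


def _exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher p by full enumeration of the 2x2 table family."""
    r0, r1 = table.sum(axis=1)
    c0, c1 = table.sum(axis=0)
    n = table.sum()
    lgf = gammaln(np.arange(n + 2) + 1.0)
    lo, hi = max(0, r0 - c1), min(r0, c0)

    def logp(a: int) -> float:
        t = np.array([[a, r0 - a], [c0 - a, r1 - (c0 - a)]])
        return _log_table_prob(t, lgf)

    obs = logp(int(table[0, 0]))
    total = 0.0
    for a in range(lo, hi + 1):
        lp = logp(a)
        if lp <= obs + 1e-9:
            total += np.exp(lp)
    return min(1.0, total)


def fisher_exact_mc(
    table,
    n_resamples: int = 100_000,
    seed: int | None = None,
    method: str = "auto",
) -> TestResult:
    """Fisher exact test of independence for an r x c contingency table.

    2x2 tables (``method='auto'``) are enumerated exactly.  Larger tables use
    conditional Monte Carlo: tables are drawn with both margins fixed and a
    resample counts as at least as extreme when its null hypergeometric
    probability does not exceed the observed table's, with the add-one
    correction p = (1 + #extreme) / (n_resamples + 1).  Zero rows/columns are
    dropped with a warning.
    """
    if hasattr(table, "counts"):
        table = table.counts
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2:
        raise ValueError("table must be two-dimensional")
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero rows/columns from the contingency table")
        table = table[keep_r][:, keep_c]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping zero margins")

    if method == "exact" or (method == "auto" and table.shape == (2, 2)):
        return TestResult(
            statistic=None, p_value=_exact_2x2(table), method="fisher-exact"
        )

    if n_resamples < 10_000:
        raise ValueError("n_resamples must be at least 10,000")
    if seed is None:
        raise ValueError("Monte-Carlo Fisher requires an explicit seed")
    rng = np.random.default_rng(seed)
    n = int(table.sum())
    lgf = gammaln(np.arange(n + 2) + 1.0)
    obs = _log_table_prob(table, lgf)
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    extreme = 0
    for _ in range(n_resamples):
        remaining = col_sums.copy()
        t = np.empty_like(table)
        for i, r in enumerate(row_sums[:-1]):
            draw = rng.multivariate_hypergeometric(remaining, int(r))
            t[i] = draw
            remaining -= draw
        t[-1] = remaining
        if _log_table_prob(t, lgf) <= obs + 1e-9:
            extreme += 1
    p = (1 + extreme) / (n_resamples + 1)
    return TestResult(
        statistic=None,
        p_value=p,
        method="fisher-mc",
        n_resamples=n_resamples,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Logistic regression of presence/absence on longitude


def logistic_presence_vs_longitude(records, target: str) -> LogisticResult:
    """Likelihood-ratio test of mitotype presence against longitude.

    ``target`` may name a haplotype or a lineage; each record is coded 1 when
    it carries the target.  The model (intercept + slope on longitude) is fit
    by IRLS; the statistic is the 1-df likelihood-ratio chi-square against the
    intercept-only model.  Complete separation is flagged instead of fitted.
    """
    import statsmodels.api as sm

    df = _as_frame(records)
    if df["longitude"].isna().any():
        raise ValueError("every record needs a longitude")
    y = (
        (df["haplotype"] == target) | (df["lineage"] == target)
    ).to_numpy(dtype=float)
    x = df["longitude"].to_numpy(dtype=float)
    n = len(y)
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
        return LogisticResult(
            slope=None, intercept=None, chi2=None, p_value=None, n=n, separation=True
        )
    X = sm.add_constant(x)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-10)
    null = sm.GLM(y, np.ones((n, 1)), family=sm.families.Binomial()).fit()
    chi2 = 2.0 * (fit.llf - null.llf)
    chi2 = max(chi2, 0.0)
    return LogisticResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        chi2=float(chi2),
        p_value=float(chi2_dist.sf(chi2, df=1)),
        n=n,
        converged=bool(fit.converged),
    )
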