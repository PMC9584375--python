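"""Roost-use statistics from the site and occurrence tables.

Covers the tabular analyses of the study: per-period occurrence totals,
per-site species richness, tie-aware Spearman rank correlations (cave
length vs population size / diversity; species abundance vs tourist
passes), Friedman tests with Kendall's W effect size, pairwise Wilcoxon
signed-rank comparisons, and a binomial GLM on the spot variables (height,
distance from entrance, spot temperature) with VIF-based collinearity
elimination followed by backward AIC selection.

Site tables are keyed by site NAME. The Meziad cave's two levels are
summed into one site for all inter-site statistics (correlations run over
ten sites); species absent from a site in a period are coded 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import rankdata

PERIOD_CODES = ("SO", "NM", "AM")

_COUNT_COLS = {"SO": "so_total", "NM": "nm_total", "AM": "am_total"}
_PASS_COLS = {"SO": "so_max_passes", "NM": "nm_max_passes", "AM": "am_max_passes"}


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1 - 1e-9 <= self.rho <= 1 + 1e-9:
            raise ValueError("rho out of [-1, 1]")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p out of [0, 1]")


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p_value: float
    kendalls_W: float

    def __post_init__(self) -> None:
        if self.chi2 < 0 or not 0 <= self.kendalls_W <= 1 + 1e-9:
            raise ValueError("invalid Friedman result")


@dataclass
class StepwiseGLMResult:
    retained: list[str]
    coefficients: pd.Series
    z_values: pd.Series
    p_values: pd.Series
    aic_trace: list[float]
    vif_table: pd.Series
    dropped_by_vif: list[str] = field(default_factory=list)
    dropped_by_aic: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# packaged table fixtures
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("speleosdm").joinpath("data", name)


def load_site_table() -> pd.DataFrame:
    """Site metadata table (one row per site, keyed by name)."""
    with resources.as_file(_data_path("sites.csv")) as p:
        df = pd.read_csv(p)
    if df["name"].duplicated().any():
        raise ValueError("site names must be unique")
    if (df["cave_length_m"] <= 0).any():
        raise ValueError("cave lengths must be positive")
    return df


def load_occurrence_table() -> pd.DataFrame:
    """Occurrence counts per site, level, species and activity period."""
    with resources.as_file(_data_path("occurrences.csv")) as p:
        df = pd.read_csv(p)
    count_cols = [c for c in df.columns if c.endswith(("_total", "_visit", "_passes"))]
    if (df[count_cols] < 0).any().any():
        raise ValueError("counts and passes must be non-negative")
    return df


def load_passes_reference() -> pd.DataFrame:
    """Published abundance-vs-passes correlation matrix (reference values)."""
    with resources.as_file(_data_path("passes_correlations.csv")) as p:
        return pd.read_csv(p)


# ---------------------------------------------------------------------------
# totals and richness
# ---------------------------------------------------------------------------


def _period_col(period: str, cols: Mapping[str, str]) -> str:
    code = period.code if hasattr(period, "code") else str(period)
    if code not in cols:
        raise ValueError(f"unknown activity period {code!r}")
    return cols[code]


def site_period_totals(table: pd.DataFrame, period: str) -> int:
    """Total occurrences over all species, sites and levels for one period."""
    if len(table) == 0:
        return 0
    return int(table[_period_col(period, _COUNT_COLS)].sum())


def site_abundance(
    table: pd.DataFrame, period: str, species: str | None = None
) -> pd.Series:
    """Per-site occurrence totals for one period (levels merged).

    With ``species`` given, sites where the species was absent are coded 0.
    """
    col = _period_col(period, _COUNT_COLS)
    sub = table if species is None else table[table["species"] == species]
    sites = table["site"].unique()
    totals = sub.groupby("site")[col].sum()
    return totals.reindex(sites, fill_value=0).astype(int)


def species_richness(table: pd.DataFrame, period: str) -> pd.Series:
    """Number of species with a positive count per site (levels merged)."""
    col = _period_col(period, _COUNT_COLS)
    present = table[table[col] > 0]
    counts = present.groupby("site")["species"].nunique()
    return counts.reindex(table["site"].unique(), fill_value=0).astype(int)


def site_passes(table: pd.DataFrame, period: str) -> pd.Series:
    """Maximum tourist passes per site for one period."""
    col = _period_col(period, _PASS_COLS)
    return table.groupby("site")[col].max().reindex(table["site"].unique())


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------


def midranks(x: Sequence[float]) -> np.ndarray:
    """Average (mid) ranks with ties sharing their mean rank."""
    return rankdata(np.asarray(x, dtype=float), method="average")


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Tie-aware Spearman rank correlation: Pearson correlation of midranks,
    with a t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    rx, ry = midranks(x), midranks(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("degenerate: zero variance in ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if abs(rho) >= 1.0 - 1e-15:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho, p, n)


def abundance_passes_matrix(
    table: pd.DataFrame,
    species_list: Sequence[str] | None = None,
    periods: Sequence[str] = PERIOD_CODES,
) -> pd.DataFrame:
    """Spearman correlations of per-site species abundance vs tourist passes.

    One row per species, one (rho, p, n) triple per period; all sites enter
    each correlation with absent species coded 0. Species with zero variance
    in abundance are reported as undefined (NaN).
    """
    if species_list is None:
        species_list = sorted(table["species"].unique())
    rows = {}
    for sp in species_list:
        row = {}
        for per in periods:
            ab = site_abundance(table, per, species=sp)
            passes = site_passes(table, per).reindex(ab.index)
            try:
                res = spearman(ab.to_numpy(), passes.to_numpy())
                row[f"{per}_rho"] = res.rho
                row[f"{per}_p"] = res.p_value
            except ValueError:
                row[f"{per}_rho"] = np.nan
                row[f"{per}_p"] = np.nan
        rows[sp] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def friedman_test(matrix: np.ndarray) -> FriedmanResult:
    """Friedman rank test over a blocks x treatments matrix with tie
    correction, and Kendall's W = chi2 / (n_blocks * (k - 1))."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 blocks and >= 2 treatments")
    n, k = m.shape
    ranks = np.vstack([midranks(row) for row in m])
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3 * n * (k + 1)
    # tie correction
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * (k**3 - k))
    if correction <= 0:
        return FriedmanResult(0.0, k - 1, 1.0, 0.0)
    chi2 = chi2 / correction
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    w = float(chi2 / (n * (k - 1)))
    return FriedmanResult(float(chi2), k - 1, p, min(w, 1.0))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 15
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test: zero differences excluded, tied
    absolute differences midranked; exact sign-flip enumeration for small n,
    normal approximation (with tie correction) above.

    Returns ``(W_plus, p_two_sided)``.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("degenerate: all paired differences are zero")
    r = midranks(np.abs(d))
    w_plus = float(r[d > 0].sum())
    mu = n * (n + 1) / 4.0
    if n <= exact_max_n:
        # enumerate all 2^n sign assignments of the midranks
        totals = np.zeros(1)
        for ri in r:
            totals = np.concatenate([totals, totals + ri])
        dev = np.abs(totals - mu)
        p = float(np.mean(dev >= abs(w_plus - mu) - 1e-12))
    else:
        _, counts = np.unique(r, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_plus - mu) / sigma
        p = float(2 * stats.norm.sf(abs(z)))
    return w_plus, min(p, 1.0)


def wilcoxon_pairwise(
    vectors: Mapping[str, Sequence[float]]
) -> dict[tuple[str, str], float]:
    """All pairwise paired Wilcoxon tests among named period vectors."""
    out = {}
    for a, b in itertools.combinations(vectors, 2):
        try:
            _, p = wilcoxon_signed_rank(vectors[a], vectors[b])
        except ValueError:
            p = np.nan
        out[(a, b)] = p
    return out


# ---------------------------------------------------------------------------
# stepwise binomial GLM on the spot variables
# ---------------------------------------------------------------------------


def _vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors via auxiliary OLS R-squared."""
    out = {}
    for col in X.columns:
        others = X.drop(columns=[col])
        A = sm.add_constant(others)
        r2 = sm.OLS(X[col], A).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def stepwise_binomial_glm(
    response: Sequence[int],
    predictors: pd.DataFrame,
    vif_threshold: float = 10.0,
) -> StepwiseGLMResult:
    """Binomial GLM with VIF elimination then backward AIC selection.

    While any predictor's VIF exceeds ``vif_threshold`` the worst offender
    is dropped. Backward elimination then removes, one at a time, the
    predictor whose removal lowers the AIC most, stopping when no removal
    improves it. The accepted-model AIC trace is non-increasing.
    """
    y = np.asarray(response, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: response must have both classes")
    X = predictors.astype(float).copy()
    if len(X) < 10:
        raise ValueError("need at least 10 rows")

    dropped_vif = []
    while X.shape[1] > 1:
        vifs = _vif(X)
        worst = vifs.idxmax()
        if vifs[worst] > vif_threshold:
            X = X.drop(columns=[worst])
            dropped_vif.append(worst)
        else:
            break
    vif_table = _vif(X) if X.shape[1] > 1 else pd.Series({X.columns[0]: 1.0})

    def fit(cols):
        model = sm.GLM(y, sm.add_constant(X[list(cols)]), family=sm.families.Binomial())
        return model.fit()

    cols = list(X.columns)
    res = fit(cols)
    aic_trace = [float(res.aic)]
    dropped_aic = []
    while len(cols) > 1:
        best_aic, best_drop, best_res = aic_trace[-1], None, None
        for col in cols:
            cand = [c for c in cols if c != col]
            r = fit(cand)
            if r.aic < best_aic:
                best_aic, best_drop, best_res = float(r.aic), col, r
        if best_drop is None:
            break
        cols.remove(best_drop)
        dropped_aic.append(best_drop)
        aic_trace.append(best_aic)
        res = best_res

    params = res.params.drop("const", errors="ignore")
    tvals = res.tvalues.drop("const", errors="ignore")
    pvals = res.pvalues.drop("const", errors="ignore")
    return StepwiseGLMResult(
        retained=cols,
        coefficients=params,
        z_values=tvals,
        p_values=pvals,
        aic_trace=aic_trace,
        vif_table=vif_table,
        dropped_by_vif=dropped_vif,
        dropped_by_aic=dropped_aic,
    )
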