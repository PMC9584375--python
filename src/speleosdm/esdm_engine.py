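"""Presence/background ensemble species distribution modelling.

Seven base-learner families — classification trees (CTA), multivariate
adaptive regression splines (MARS), logistic GLM, single-hidden-layer
neural networks (ANN), spline-basis GAM, RBF support vector machines and a
Maxent-style L1-regularised presence/background logistic regression — are
fitted on the five temperature statistics, each scored by its training
ROC AUC, and stacked into one AUC-weighted ensemble projection. Evaluation
follows the standard SDM toolbox: rank-based AUC, Cohen's kappa,
ten-percentile training-presence omission, permutation/Pearson variable
contributions and global Moran's I as a clustering diagnostic. Binary maps
(TSS-maximising threshold by default) are summed with equal weights into
multi-species richness/sensitivity maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cave_geometry import GridSpec
from .microclimate import ActivityPeriod

LEARNER_FAMILIES = ("CTA", "MARS", "GLM", "ANN", "GAM", "SVM", "MAXENT_LIKE")

FEATURE_NAMES = ("Tmin", "Tmax", "Tmean", "Trange", "Tstd")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class OccurrenceSet:
    """Presence records for one species in one activity period."""

    species: str
    period: ActivityPeriod
    records: pd.DataFrame  # columns: site_id, level_index, x, y, count (+spot)

    def __post_init__(self) -> None:
        req = {"site_id", "level_index", "x", "y", "count"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"occurrence records missing columns {sorted(missing)}")
        if (self.records["count"] < 1).any():
            raise ValueError("occurrence counts must be >= 1")

    @property
    def n_occurrences(self) -> int:
        return int(self.records["count"].sum())

    def positions(self) -> np.ndarray:
        return self.records[["x", "y"]].to_numpy(dtype=float)

    def expanded_positions(self) -> np.ndarray:
        """Positions with counts > 1 expanded to repeated presence rows."""
        reps = self.records["count"].to_numpy(dtype=int)
        return np.repeat(self.positions(), reps, axis=0)


@dataclass(frozen=True)
class FilterPolicy:
    min_occurrences: int = 25

    def __post_init__(self) -> None:
        if self.min_occurrences < 1:
            raise ValueError("min_occurrences must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class BaseLearnerSpec:
    family: str
    hyperparameters: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in LEARNER_FAMILIES:
            raise ValueError(f"unknown learner: {self.family!r}")


@dataclass
class FittedLearner:
    family: str
    predict: Callable[[np.ndarray], np.ndarray]  # features -> suitability [0,1]
    training_auc: float = np.nan


@dataclass
class EnsembleModel:
    species: str
    period: ActivityPeriod | None
    models: list[FittedLearner]
    weights: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    dropped: list[FittedLearner] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.models) == 0:
            raise ValueError("ensemble empty: no base model retained")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros(len(X))
        for w, m in zip(self.weights, self.models):
            out += w * np.clip(m.predict(X), 0.0, 1.0)
        return out


@dataclass
class ModelEvaluation:
    AUC: float
    kappa: float
    omission10: float
    variable_contributions: dict[str, float]

    def __post_init__(self) -> None:
        if not 0 <= self.AUC <= 1:
            raise ValueError("AUC out of [0, 1]")
        if not -1 <= self.kappa <= 1:
            raise ValueError("kappa out of [-1, 1]")
        if not 0 <= self.omission10 <= 1:
            raise ValueError("omission out of [0, 1]")
        total = sum(self.variable_contributions.values())
        if self.variable_contributions and not np.isclose(total, 100.0):
            raise ValueError("variable contributions must sum to 100")


@dataclass
class AutocorrelationReport:
    morans_I: float
    z_score: float
    n: int
    expected_I: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("Moran's I needs at least 3 analysis units")


@dataclass
class BinaryMap:
    grid: GridSpec
    values: np.ndarray  # 0/1 inside, NaN outside
    threshold: float
    method: str
    provenance: dict = field(default_factory=dict)


@dataclass
class RichnessMap:
    grid: GridSpec
    values: np.ndarray  # small integers inside, NaN outside
    provenance: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# occurrence handling
# ---------------------------------------------------------------------------


def filter_occurrences(
    sets: Iterable[OccurrenceSet], policy: FilterPolicy = FilterPolicy()
) -> tuple[list[OccurrenceSet], list[dict]]:
    """Retain species x period sets with at least ``min_occurrences`` records.

    The threshold is inclusive (a set with exactly the minimum is kept).
    Excluded sets are logged with their counts.
    """
    retained, excluded = [], []
    for s in sets:
        n = s.n_occurrences
        if n >= policy.min_occurrences:
            retained.append(s)
        else:
            excluded.append(
                {"species": s.species, "period": s.period.code, "n": n}
            )
    return retained, excluded


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------


def morans_i_from_weights(
    values: np.ndarray, W: np.ndarray, row_standardize: bool = True
) -> AutocorrelationReport:
    """Global Moran's I for arbitrary spatial weights, z-score under the
    normality expectation E[I] = -1/(n-1)."""
    x = np.asarray(values, dtype=float)
    W = np.asarray(W, dtype=float).copy()
    n = len(x)
    if n < 3:
        raise ValueError("Moran's I needs at least 3 analysis units")
    z = x - x.mean()
    if np.allclose(z, 0):
        raise ValueError("degenerate variance: all values identical")
    np.fill_diagonal(W, 0.0)
    if row_standardize:
        rs = W.sum(axis=1)
        rs[rs == 0] = 1.0
        W = W / rs[:, None]
    s0 = W.sum()
    I = (n / s0) * float(z @ W @ z) / float(z @ z)
    e_i = -1.0 / (n - 1)

    s1 = 0.5 * np.sum((W + W.T) ** 2)
    s2 = np.sum((W.sum(axis=1) + W.sum(axis=0)) ** 2)
    b2 = n * np.sum(z**4) / (np.sum(z**2) ** 2)
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    den = (n - 1) * (n - 2) * (n - 3) * s0**2
    var_i = num / den - e_i**2
    z_score = (I - e_i) / np.sqrt(var_i) if var_i > 0 else np.nan
    return AutocorrelationReport(float(I), float(z_score), n, e_i)


def morans_i(
    positions: np.ndarray,
    grid: GridSpec,
    agg_cell_size_m: float = 2.0,
    counts: np.ndarray | None = None,
) -> AutocorrelationReport:
    """Moran's I of occurrence counts over occupied aggregation cells.

    Occurrences are tallied into square aggregation cells of
    ``agg_cell_size_m`` laid over the inside mask; the analysis units are
    the OCCUPIED cells (count > 0) — clustered colonies then show as
    smoothly varying counts among mutually close cells. Weights are inverse
    distance between cell centers, row-standardised.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if counts is None:
        counts = np.ones(len(positions))
    counts = np.asarray(counts, dtype=float)

    f = max(1, int(round(agg_cell_size_m / grid.cell_size_m)))
    nr, nc = -(-grid.n_rows // f), -(-grid.n_cols // f)

    tally = np.zeros((nr, nc))
    cs = grid.cell_size_m
    for (x, y), w in zip(positions, counts):
        r, c = grid.xy_to_rc(x, y)
        r, c = min(max(r, 0), grid.n_rows - 1), min(max(c, 0), grid.n_cols - 1)
        tally[r // f, c // f] += w

    rows, cols = np.nonzero(tally > 0)
    if len(rows) < 3:
        raise ValueError("Moran's I needs at least 3 occupied analysis units")
    vals = tally[rows, cols]
    # aggregation-cell center coordinates
    xs = grid.origin[0] + (cols * f + f / 2) * cs
    ys = grid.origin[1] + (grid.n_rows - rows * f - f / 2) * cs
    pts = np.column_stack([xs, ys])
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    # inverse distance within the standard ensure-a-neighbour threshold:
    # the smallest radius at which every unit has at least one neighbour
    np.fill_diagonal(d, np.inf)
    cutoff = float(d.min(axis=1).max()) * (1 + 1e-9)
    with np.errstate(divide="ignore"):
        W = np.where(d <= cutoff, 1.0 / d, 0.0)
    np.fill_diagonal(W, 0.0)
    return morans_i_from_weights(vals, W, row_standardize=True)


# ---------------------------------------------------------------------------
# background sampling and data split
# ---------------------------------------------------------------------------


def sample_background(
    grid: GridSpec,
    n: int,
    seed: int,
    exclude_cells: set[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Uniform random inside-cell centers as pseudo-absence points.

    Sampling is without replacement while possible; if ``n`` exceeds the
    number of available cells, sampling falls back to with-replacement and a
    warning is emitted.
    """
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(grid.inside_mask)
    if len(rows) == 0:
        raise ValueError("no domain: empty inside mask")
    if exclude_cells:
        keep = [i for i in range(len(rows)) if (rows[i], cols[i]) not in exclude_cells]
        rows, cols = rows[keep], cols[keep]
        if len(rows) == 0:
            raise ValueError("no domain: every inside cell excluded")
    if n <= len(rows):
        pick = rng.choice(len(rows), size=n, replace=False)
    else:
        warnings.warn(
            f"background n={n} exceeds {len(rows)} available cells; "
            "sampling with replacement"
        )
        pick = rng.choice(len(rows), size=n, replace=True)
    cs = grid.cell_size_m
    x = grid.origin[0] + (cols[pick] + 0.5) * cs
    y = grid.origin[1] + (grid.n_rows - rows[pick] - 0.5) * cs
    return np.column_stack([x, y])


def split_train_test(records, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint exhaustive train/test partition of record indices.

    ``|train| = round(train_fraction * n)``; returns index arrays usable on
    any row-aligned container.
    """
    n = len(records)
    if n < 4:
        raise ValueError("too few records: need at least 4 to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = int(round(spec.train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


# ---------------------------------------------------------------------------
# base learners
# ---------------------------------------------------------------------------


def _hinge_features(X: np.ndarray, knots: list[np.ndarray]) -> np.ndarray:
    cols = []
    for j in range(X.shape[1]):
        for k in knots[j]:
            cols.append(np.maximum(X[:, j] - k, 0.0))
            cols.append(np.maximum(k - X[:, j], 0.0))
    return np.column_stack(cols) if cols else np.empty((len(X), 0))


def _quantile_knots(X: np.ndarray, qs=(0.25, 0.5, 0.75)) -> list[np.ndarray]:
    return [np.unique(np.quantile(X[:, j], qs)) for j in range(X.shape[1])]


class _MarsModel:
    """Small forward/backward MARS: greedy hinge-term selection by SSE,
    backward pruning by generalised cross-validation, linear output clipped
    to [0, 1]."""

    def __init__(self, max_terms: int = 15, seed: int = 0):
        self.max_terms = max_terms

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_MarsModel":
        self.knots_ = _quantile_knots(X, qs=(0.1, 0.25, 0.5, 0.75, 0.9))
        H = _hinge_features(X, self.knots_)
        n, p = H.shape
        selected: list[int] = []
        resid = y - y.mean()
        # forward: add the hinge column most correlated with the residual
        for _ in range(min(self.max_terms, p)):
            scores = np.abs(H.T @ resid)
            scores[selected] = -np.inf
            j = int(np.argmax(scores))
            if scores[j] <= 1e-12:
                break
            selected.append(j)
            A = np.column_stack([np.ones(n), H[:, selected]])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ beta
        # backward: prune terms while GCV improves
        best = list(selected)
        best_gcv = self._gcv(H, y, best)
        improved = True
        while improved and len(best) > 1:
            improved = False
            for j in list(best):
                cand = [k for k in best if k != j]
                g = self._gcv(H, y, cand)
                if g < best_gcv:
                    best, best_gcv, improved = cand, g, True
                    break
        self.selected_ = best
        A = np.column_stack([np.ones(n), H[:, best]])
        self.beta_, *_ = np.linalg.lstsq(A, y, rcond=None)
        return self

    @staticmethod
    def _gcv(H: np.ndarray, y: np.ndarray, cols: list[int]) -> float:
        n = len(y)
        A = np.column_stack([np.ones(n), H[:, cols]])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(np.sum((y - A @ beta) ** 2))
        c = 1 + 2 * len(cols)  # effective parameters with hinge penalty
        denom = (1 - min(c / n, 0.99)) ** 2
        return rss / (n * denom)

    def predict(self, X: np.ndarray) -> np.ndarray:
        H = _hinge_features(X, self.knots_)
        A = np.column_stack([np.ones(len(X)), H[:, self.selected_]])
        return np.clip(A @ self.beta_, 0.0, 1.0)


def _poly2(X: np.ndarray) -> np.ndarray:
    return np.column_stack([X, X**2])


class _SvmPlatt:
    """RBF SVC scored through a Platt-style logistic calibration of the
    decision values (fitted on the training data)."""

    def __init__(self, seed: int):
        self.svc = make_pipeline(
            StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="scale")
        )
        self.platt = LogisticRegression(C=1e6, max_iter=1000)

    def fit(self, X, y):
        self.svc.fit(X, y)
        d = self.svc.decision_function(X)
        self.platt.fit(d[:, None], y)
        return self

    def predict(self, X):
        d = self.svc.decision_function(X)
        return self.platt.predict_proba(d[:, None])[:, 1]


def fit_base_learner(
    spec: BaseLearnerSpec, X: np.ndarray, y: np.ndarray, seed: int = 0
) -> FittedLearner:
    """Fit one base-learner family on presence(1)/background(0) data.

    Returns a probability-like suitability scorer bounded in [0, 1],
    deterministic for a given seed, annotated with its training AUC.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: both classes required")
    hp = dict(spec.hyperparameters)
    fam = spec.family

    if fam == "CTA":
        model = DecisionTreeClassifier(
            max_depth=hp.get("max_depth", 4), random_state=seed
        ).fit(X, y)
        predict = lambda Z: model.predict_proba(np.asarray(Z, float))[:, 1]
    elif fam == "MARS":
        model = _MarsModel(max_terms=hp.get("max_terms", 15), seed=seed).fit(
            X, y.astype(float)
        )
        predict = lambda Z: model.predict(np.asarray(Z, float))
    elif fam == "GLM":
        model = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=hp.get("C", 1e4), max_iter=2000),
        ).fit(_poly2(X), y)
        predict = lambda Z: model.predict_proba(_poly2(np.asarray(Z, float)))[:, 1]
    elif fam == "GAM":
        model = make_pipeline(
            SplineTransformer(n_knots=hp.get("n_knots", 4), degree=3),
            LogisticRegression(C=hp.get("C", 1e3), max_iter=2000),
        ).fit(X, y)
        predict = lambda Z: model.predict_proba(np.asarray(Z, float))[:, 1]
    elif fam == "ANN":
        model = make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(hp.get("hidden_units", 8),),
                max_iter=hp.get("max_iter", 500),
                random_state=seed,
            ),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        predict = lambda Z: model.predict_proba(np.asarray(Z, float))[:, 1]
    elif fam == "SVM":
        model = _SvmPlatt(seed).fit(X, y)
        predict = lambda Z: model.predict(np.asarray(Z, float))
    elif fam == "MAXENT_LIKE":
        knots = _quantile_knots(X)

        def expand(Z):
            Z = np.asarray(Z, float)
            return np.column_stack([Z, Z**2, _hinge_features(Z, knots)])

        # saga leaves the intercept unpenalised, so regularization -> inf
        # collapses the prediction to the observed prevalence
        model = make_pipeline(
            StandardScaler(),
            LogisticRegression(
                l1_ratio=1.0,
                C=hp.get("C", 1.0),
                solver="saga",
                max_iter=2000,
                tol=1e-3,
                random_state=seed,
            ),
        ).fit(expand(X), y)
        predict = lambda Z: model.predict_proba(expand(Z))[:, 1]
    else:  # pragma: no cover - guarded by BaseLearnerSpec
        raise ValueError(f"unknown learner: {fam!r}")

    scores = predict(X)
    auc = compute_auc(scores[y == 1], scores[y == 0])
    return FittedLearner(fam, predict, auc)


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------


def compute_auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) ROC AUC; ties counted one half."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if len(sp) == 0 or len(sb) == 0:
        raise ValueError("empty class: both score sets must be non-empty")
    ranks = rankdata(np.concatenate([sp, sb]))
    u = ranks[: len(sp)].sum() - len(sp) * (len(sp) + 1) / 2
    return float(u / (len(sp) * len(sb)))


def cohens_kappa(predictions: np.ndarray, truth: np.ndarray) -> float:
    """Chance-corrected agreement of binary predictions with observations."""
    p = np.asarray(predictions, dtype=int)
    t = np.asarray(truth, dtype=int)
    if len(p) == 0 or len(p) != len(t):
        raise ValueError("predictions and truth must be equal-length, non-empty")
    n = len(p)
    po = float(np.mean(p == t))
    pe = float(
        (np.mean(p == 1) * np.mean(t == 1)) + (np.mean(p == 0) * np.mean(t == 0))
    )
    if np.isclose(pe, 1.0):
        return 0.0
    return (po - pe) / (1 - pe)


def ten_percentile_omission(
    train_presence_scores: np.ndarray, test_presence_scores: np.ndarray
) -> float:
    """Fraction of test presences scored strictly below the 10th percentile
    of training-presence suitability (linear-interpolation percentile)."""
    tr = np.asarray(train_presence_scores, dtype=float)
    te = np.asarray(test_presence_scores, dtype=float)
    if len(tr) == 0 or len(te) == 0:
        raise ValueError("empty class: both score sets must be non-empty")
    thr = float(np.percentile(tr, 10))
    return float(np.mean(te < thr))


def build_ensemble(
    models: Sequence[FittedLearner],
    auc_floor: float = 0.5,
    species: str = "",
    period: ActivityPeriod | None = None,
) -> EnsembleModel:
    """AUC-weighted stack of base learners; models below the floor dropped."""
    kept = [m for m in models if m.training_auc >= auc_floor]
    dropped = [m for m in models if m.training_auc < auc_floor]
    if not kept:
        raise ValueError("ensemble empty: no model reaches the AUC floor")
    aucs = np.array([m.training_auc for m in kept])
    return EnsembleModel(species, period, kept, aucs / aucs.sum(), dropped=dropped)


def variable_contribution(
    ensemble: EnsembleModel,
    X: np.ndarray,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> dict[str, float]:
    """Permutation/Pearson variable contributions (percentages summing to 100).

    Each feature column is permuted in turn; the contribution is
    ``1 - r`` (floored at 0) where r is the Pearson correlation between the
    permuted-feature and intact ensemble scores, normalised across features.
    """
    X = np.asarray(X, dtype=float)
    names = list(feature_names or ensemble.feature_names)[: X.shape[1]]
    rng = np.random.default_rng(seed)
    base = ensemble.predict(X)
    if np.std(base) < 1e-12:
        raise ValueError("degenerate predictions: ensemble scores are constant")
    raw = []
    for j in range(X.shape[1]):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        scores = ensemble.predict(Xp)
        if np.std(scores) < 1e-12:
            r = 0.0
        else:
            r = float(np.corrcoef(base, scores)[0, 1])
        raw.append(max(1.0 - r, 0.0))
    raw = np.asarray(raw)
    if raw.sum() <= 0:
        raw = np.ones_like(raw)
    pct = 100.0 * raw / raw.sum()
    return dict(zip(names, pct))


# ---------------------------------------------------------------------------
# binarization and stacking
# ---------------------------------------------------------------------------


def _tss(thr, sp, sb):
    sens = np.mean(sp >= thr)
    spec = np.mean(sb < thr)
    return sens + spec - 1.0


def find_threshold(
    presence_scores: np.ndarray,
    background_scores: np.ndarray,
    method: str = "tss",
) -> float:
    """Suitability threshold for binarization.

    Methods: ``tss`` (maximise sensitivity + specificity - 1),
    ``kappa`` (maximise Cohen's kappa), ``tenth_percentile`` (10th
    percentile of presence scores). Ties resolved toward the highest
    threshold (most conservative map).
    """
    sp = np.asarray(presence_scores, dtype=float)
    sb = np.asarray(background_scores, dtype=float)
    if method == "tenth_percentile":
        return float(np.percentile(sp, 10))
    if method not in ("tss", "kappa"):
        raise ValueError(f"unknown binarization method {method!r}")
    cands = np.unique(np.concatenate([sp, sb]))
    y = np.concatenate([np.ones(len(sp), int), np.zeros(len(sb), int)])
    s = np.concatenate([sp, sb])
    best_thr, best_val = cands[0], -np.inf
    for thr in cands:
        if method == "tss":
            val = _tss(thr, sp, sb)
        else:
            val = cohens_kappa((s >= thr).astype(int), y)
        if val >= best_val - 1e-12:
            if val > best_val + 1e-12 or thr > best_thr:
                best_thr, best_val = float(thr), float(val)
    return best_thr


def binarize(
    suitability: np.ndarray,
    grid: GridSpec,
    presence_scores: np.ndarray,
    background_scores: np.ndarray,
    method: str = "tss",
    provenance: dict | None = None,
) -> BinaryMap:
    """Threshold a suitability field into a 0/1 habitat map."""
    thr = find_threshold(presence_scores, background_scores, method)
    field2d = np.asarray(suitability, dtype=float)
    values = np.where(np.isnan(field2d), np.nan, (field2d >= thr).astype(float))
    values[~grid.inside_mask] = np.nan
    prov = dict(provenance or {})
    prov["threshold"] = thr
    prov["method"] = method
    return BinaryMap(grid, values, thr, method, prov)


def sum_binary_maps(
    maps: Sequence[BinaryMap], grid: GridSpec | None = None
) -> RichnessMap:
    """Equal-weight cellwise sum of binary habitat maps.

    NaN propagates only where every input is NaN; an empty list yields an
    all-zero map over the supplied grid's mask.
    """
    if not maps:
        if grid is None:
            raise ValueError("grid required to sum an empty map list")
        values = np.where(grid.inside_mask, 0.0, np.nan)
        return RichnessMap(grid, values, [])
    grid = maps[0].grid
    shp = (grid.n_rows, grid.n_cols)
    for m in maps:
        if m.values.shape != shp or m.grid is not grid and (
            m.grid.n_rows != grid.n_rows
            or m.grid.n_cols != grid.n_cols
            or m.grid.cell_size_m != grid.cell_size_m
        ):
            raise ValueError("grid mismatch: binary maps on different grids")
    stack = np.stack([m.values for m in maps])
    all_nan = np.all(np.isnan(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        total = np.nansum(stack, axis=0)
    total[all_nan] = np.nan
    prov = [m.provenance for m in maps]
    return RichnessMap(grid, total, prov)


# ---------------------------------------------------------------------------
# high-level fit/evaluate for one species x period
# ---------------------------------------------------------------------------

DEFAULT_LEARNERS = tuple(BaseLearnerSpec(f) for f in LEARNER_FAMILIES)


def background_size(n_presence: int, n_inside_cells: int) -> int:
    """Default pseudo-absence count: 10x presences, at least 100, capped at
    the number of inside cells."""
    return min(max(10 * n_presence, 100), n_inside_cells)


def fit_evaluate_ensemble(
    X_presence: np.ndarray,
    X_background: np.ndarray,
    seed: int,
    learners: Sequence[BaseLearnerSpec] = DEFAULT_LEARNERS,
    split: SplitSpec | None = None,
    species: str = "",
    period: ActivityPeriod | None = None,
) -> tuple[EnsembleModel, ModelEvaluation, dict]:
    """Fit the AUC-weighted ensemble on a 75/25 presence split and evaluate.

    Background points are used in full for calibration and evaluation
    contrast. Returns the ensemble, its evaluation (test AUC, kappa at the
    TSS threshold, ten-percentile omission, variable contributions) and a
    details dict with train/test scores.
    """
    split = split or SplitSpec(seed=seed)
    Xp = np.asarray(X_presence, dtype=float)
    Xb = np.asarray(X_background, dtype=float)
    tr_idx, te_idx = split_train_test(Xp, split)
    Xp_tr, Xp_te = Xp[tr_idx], Xp[te_idx]
    btr_idx, bte_idx = split_train_test(Xb, SplitSpec(split.train_fraction, split.seed + 1))
    Xb_tr, Xb_te = Xb[btr_idx], Xb[bte_idx]

    X_tr = np.vstack([Xp_tr, Xb_tr])
    y_tr = np.concatenate([np.ones(len(Xp_tr), int), np.zeros(len(Xb_tr), int)])

    models = [
        fit_base_learner(spec, X_tr, y_tr, seed=seed + k)
        for k, spec in enumerate(learners)
    ]
    ensemble = build_ensemble(models, species=species, period=period)

    sp_tr = ensemble.predict(Xp_tr)
    sb_tr = ensemble.predict(Xb_tr)
    sp_te = ensemble.predict(Xp_te)
    sb_te = ensemble.predict(Xb_te)

    auc = compute_auc(sp_te, sb_te)
    thr = find_threshold(sp_tr, sb_tr, "tss")
    preds = np.concatenate([sp_te, sb_te]) >= thr
    truth = np.concatenate([np.ones(len(sp_te), int), np.zeros(len(sb_te), int)])
    kappa = cohens_kappa(preds.astype(int), truth)
    omission = ten_percentile_omission(sp_tr, sp_te)
    contrib = variable_contribution(ensemble, np.vstack([Xp_tr, Xb_tr]), seed=seed)
    evaluation = ModelEvaluation(auc, kappa, omission, contrib)
    details = {
        "train_presence_scores": sp_tr,
        "test_presence_scores": sp_te,
        "train_background_scores": sb_tr,
        "test_background_scores": sb_te,
        "tss_threshold": thr,
        "base_aucs": {m.family: m.training_auc for m in ensemble.models},
    }
    return ensemble, evaluation, details
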