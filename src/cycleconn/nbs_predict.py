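"""Cross-validated network-based edge selection and penalized prediction.

The pipeline identifies functional connectivity related to an outcome
(hormonal-contraceptive use, estradiol, or progesterone) by embedding
connected-component edge selection inside a repeated cross-validation
loop:

1. per training fold, residualize each edge (and, for hormone outcomes,
   the outcome) against nuisance covariates — mean framewise
   displacement and optionally HC use — with coefficients fitted on the
   training rows only;
2. compute a connection-wise F test between each residualized edge and
   the outcome (for a binary outcome this is the two-group one-way
   ANOVA F) and keep edges with p below the edge threshold;
3. reduce the suprathreshold edges to their largest connected component
   (the component with the most edges in which every involved region
   reaches every other directly or indirectly);
4. fit an L2-penalized model (logistic for HC use, ridge for hormones)
   on the component edges, choosing the penalty α by inner cross-
   validation, and score it on the held-out fold (accuracy, or Spearman
   ρ between actual and predicted hormone levels).

Repeating this over many random fold assignments yields a weighted
network: each edge accumulates the mean held-out performance of the
iterations in which it was *stably* selected (present in the component
of every training fold of that iteration), divided by the total number
of iterations.  Thresholding the positive edges of this network gives
the final connectivity pattern, which is refit on the full discovery
study and transferred to an independent study to measure
generalizability.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.model_selection import KFold

from .core import Study, edge_index, n_edges

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "WeightedNetwork",
    "FittedModel",
    "TransferResult",
    "residualize_confounds",
    "edgewise_association",
    "largest_connected_component",
    "fit_component_model",
    "run_discovery",
    "threshold_network",
    "train_final_model",
    "transfer_predict",
    "drop_cycle_window",
]

OUTCOMES = ("hc", "e2", "p4")
_DEFAULT_ALPHA_GRID = tuple(np.logspace(-4, 1, 20))


@dataclass
class CVConfig:
    """Configuration of the discovery cross-validation loop.

    ``covariates`` lists nuisance regressors removed from each edge (and
    from hormone outcomes) within each training fold: ``"fd"`` is mean
    framewise displacement, ``"hc"`` contraceptive use.  ``fold_
    aggregation`` controls which edges an iteration contributes to the
    weighted network: ``"all"`` (default) requires an edge to sit in the
    selected component of every training fold of the iteration (a
    stability criterion that keeps the weighted network sparse),
    ``"any"`` requires a single fold.
    """

    outcome: str
    n_folds: int = 5
    n_iterations: int = 1000
    p_threshold: float = 0.05
    retain_fraction: float = 0.5
    alpha_grid: tuple = _DEFAULT_ALPHA_GRID
    covariates: tuple = ("fd",)
    inner_folds: int = 3
    fold_aggregation: str = "all"
    scale_outcome: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if not 0 < self.retain_fraction <= 1:
            raise ValueError("retain_fraction must lie in (0, 1]")
        if self.fold_aggregation not in {"all", "any"}:
            raise ValueError("fold_aggregation must be 'all' or 'any'")
        if any(a <= 0 for a in self.alpha_grid):
            raise ValueError("alpha grid values must be positive")

    @classmethod
    def for_outcome(cls, outcome: str, **overrides) -> "CVConfig":
        """Default configuration for an outcome.

        HC-use models residualize edges on FD only; hormone models
        additionally remove HC use from both edges and outcome.
        """
        if "covariates" not in overrides:
            overrides["covariates"] = ("fd",) if outcome == "hc" else ("fd", "hc")
        return cls(outcome=outcome, **overrides)

    @property
    def family(self) -> str:
        return "logistic" if self.outcome == "hc" else "linear"


@dataclass
class WeightedNetwork:
    """Performance-weighted edge-selection average for one outcome."""

    outcome: str
    labels: list[str]
    edge_weights: np.ndarray
    performance: np.ndarray  # per-iteration held-out performance
    n_iterations: int

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def matrix(self) -> np.ndarray:
        iu, ju = edge_index(self.n_regions)
        m = np.zeros((self.n_regions, self.n_regions))
        m[iu, ju] = self.edge_weights
        m[ju, iu] = self.edge_weights
        return m

    @property
    def performance_mean(self) -> float:
        return float(np.mean(self.performance))

    @property
    def performance_sd(self) -> float:
        return float(np.std(self.performance, ddof=1))


@dataclass
class FittedModel:
    """A trained component model with everything needed for transfer."""

    outcome: str
    family: str
    labels: list[str]
    edge_indices: list[int]
    beta: list[float]
    intercept: float
    alpha: float
    covariates: list[str]
    edge_resid_coef: list[list[float]] | None  # (k+1) × n_edges
    outcome_resid_coef: list[float] | None  # length k+1
    feature_mean: list[float]
    feature_std: list[float]
    scale_outcome: bool = True

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class TransferResult:
    """Out-of-sample predictions and performance on an external study."""

    outcome: str
    predictions: np.ndarray
    actual: np.ndarray
    performance: float  # accuracy for hc; Spearman rho for hormones
    mse: float
    n_sessions: int
    n_dropped: int


# ---------------------------------------------------------------------------
# Building blocks


def _minmax_by_dataset(values: np.ndarray, dataset: np.ndarray) -> np.ndarray:
    out = np.full_like(values, np.nan, dtype=float)
    for d in np.unique(dataset):
        m = dataset == d
        v = values[m]
        lo, hi = np.nanmin(v), np.nanmax(v)
        out[m] = 0.0 if hi - lo <= 0 else (v - lo) / (hi - lo)
    return out


def _covariate_matrix(sessions: pd.DataFrame, covariates) -> np.ndarray:
    cols = []
    for c in covariates:
        if c == "fd":
            cols.append(sessions["mean_fd"].to_numpy(dtype=float))
        elif c == "hc":
            cols.append(sessions["hc_use"].to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown covariate {c!r}")
    if not cols:
        return np.empty((len(sessions), 0))
    return np.column_stack(cols)


def _prepare(study: Study, config: CVConfig):
    """Edge matrix, outcome vector and covariates, missing outcomes dropped."""
    E = study.edge_matrix()
    sessions = study.sessions
    if config.outcome == "hc":
        y = sessions["hc_use"].to_numpy(dtype=float)
    else:
        raw = sessions[config.outcome].to_numpy(dtype=float)
        if config.scale_outcome:
            y = _minmax_by_dataset(raw, sessions["dataset_id"].to_numpy())
        else:
            y = raw
    keep = ~np.isnan(y)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropping %d session(s) with missing %s", n_dropped, config.outcome
        )
    C = _covariate_matrix(sessions, config.covariates)
    return E[keep], y[keep], C[keep], n_dropped


def residualize_confounds(
    X: np.ndarray,
    covariates: np.ndarray,
    train_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove covariate effects from columns of ``X`` without leakage.

    An ordinary-least-squares fit (with intercept) of each column of
    ``X`` on the covariates uses the training rows only; residuals are
    produced for *all* rows with those training-fitted coefficients.
    Covariate columns constant on the training rows are dropped with a
    warning.  Returns ``(residuals, coefficients)`` where coefficients
    has one row per retained design column (intercept first).
    """
    X = np.asarray(X, dtype=float)
    one_d = X.ndim == 1
    if one_d:
        X = X[:, None]
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    S = X.shape[0]
    keep_cols = [
        k for k in range(covariates.shape[1])
        if np.ptp(covariates[train_idx, k]) > 0
    ]
    if len(keep_cols) < covariates.shape[1]:
        warnings.warn(
            "dropping covariate column(s) constant on the training rows",
            stacklevel=2,
        )
    D = np.column_stack([np.ones(S), covariates[:, keep_cols]])
    coef, *_ = np.linalg.lstsq(D[train_idx], X[train_idx], rcond=None)
    resid = X - D @ coef
    if one_d:
        return resid[:, 0], coef
    return resid, coef


def edgewise_association(
    edges: np.ndarray, outcome: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Single-predictor F statistic and p-value for every edge.

    The F statistic of the linear association between each edge and the
    outcome, ``F = r² (n − 2) / (1 − r²)``; for a binary outcome this
    equals the classical two-group one-way ANOVA F.  p-values come from
    the F(1, n − 2) distribution.  Constant edges get F = 0, p = 1.
    """
    edges = np.asarray(edges, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 sessions for edgewise F tests")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; F tests undefined")
    Ec = edges - edges.mean(axis=0)
    yc = y - y.mean()
    se = np.sqrt((Ec**2).sum(axis=0))
    sy = math.sqrt(float((yc**2).sum()))
    ok = se > 0
    r = np.zeros(edges.shape[1])
    r[ok] = (Ec[:, ok].T @ yc) / (se[ok] * sy)
    r2 = np.clip(r**2, 0.0, 1.0 - 1e-15)
    F = np.where(ok, r2 * (n - 2) / (1.0 - r2), 0.0)
    p = np.where(ok, stats.f.sf(F, 1, n - 2), 1.0)
    return F, p


def _lcc_indices(
    p_values: np.ndarray, threshold: float, n_regions: int
) -> np.ndarray:
    """Edge indices of the largest connected suprathreshold component."""
    iu, ju = edge_index(n_regions)
    hit = np.flatnonzero(np.asarray(p_values) < threshold)
    if hit.size == 0:
        return np.empty(0, dtype=int)
    G = nx.Graph()
    for k in hit:
        G.add_edge(int(iu[k]), int(ju[k]), idx=int(k))
    best: set[int] | None = None
    best_key = None
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        key = (sub.number_of_edges(), -min(comp))  # ties: smallest node wins
        if best_key is None or key > best_key:
            best_key = key
            best = comp
    sub = G.subgraph(best)
    return np.array(sorted(d["idx"] for *_, d in sub.edges(data=True)), dtype=int)


def largest_connected_component(
    p_values: np.ndarray, threshold: float, n_regions: int
) -> list[tuple[int, int]]:
    """Edges (i, j) of the largest connected component of suprathreshold
    connections — the component in which every involved region reaches
    every other directly or indirectly, maximal in edge count.  Empty
    when no edge passes the threshold.
    """
    iu, ju = edge_index(n_regions)
    idx = _lcc_indices(p_values, threshold, n_regions)
    return [(int(iu[k]), int(ju[k])) for k in idx]


def _standardize(F: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = F.mean(axis=0)
    std = F.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    return (F - mean) / std, mean, std


def _fit_single(family: str, X: np.ndarray, y: np.ndarray, alpha: float):
    if family == "logistic":
        m = LogisticRegression(C=1.0 / alpha, solver="liblinear")
        m.fit(X, y.astype(int))
        return m.coef_[0].copy(), float(m.intercept_[0])
    m = Ridge(alpha=alpha)
    m.fit(X, y)
    return m.coef_.copy(), float(m.intercept_)


def _predict_linear(beta, intercept, X):
    return X @ np.asarray(beta) + intercept


def _predict_logistic_prob(beta, intercept, X):
    return 1.0 / (1.0 + np.exp(-(X @ np.asarray(beta) + intercept)))


def fit_component_model(
    features: np.ndarray,
    outcome: np.ndarray,
    family: str,
    alpha_grid=_DEFAULT_ALPHA_GRID,
    inner_folds: int = 3,
    seed: int = 0,
):
    """Fit an L2-penalized model on component edges with inner-CV α tuning.

    Features are standardized on the provided (training) rows.  The L2
    coefficient α is chosen from ``alpha_grid`` by inner K-fold
    cross-validated performance (accuracy for logistic, negative mean
    squared error for ridge); the first best value in grid order wins,
    making the choice deterministic.  Returns ``(beta, intercept,
    alpha, mean, std)`` on the standardized-feature scale.
    """
    X, mean, std = _standardize(np.asarray(features, dtype=float))
    y = np.asarray(outcome, dtype=float)
    n = y.size
    k = min(inner_folds, n)
    if k >= 2 and len(alpha_grid) > 1:
        kf = KFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
        scores = np.zeros(len(alpha_grid))
        for tr, te in kf.split(X):
            if family == "logistic" and len(np.unique(y[tr])) < 2:
                continue
            for a, alpha in enumerate(alpha_grid):
                beta, icpt = _fit_single(family, X[tr], y[tr], alpha)
                if family == "logistic":
                    pred = _predict_logistic_prob(beta, icpt, X[te]) > 0.5
                    scores[a] += float(np.mean(pred == y[te].astype(bool)))
                else:
                    pred = _predict_linear(beta, icpt, X[te])
                    scores[a] -= float(np.mean((pred - y[te]) ** 2))
        alpha = float(alpha_grid[int(np.argmax(scores))])
    else:
        alpha = float(alpha_grid[0])
    beta, intercept = _fit_single(family, X, y, alpha)
    return beta, intercept, alpha, mean, std


def _fold_performance(family: str, y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if family == "logistic":
        return float(np.mean((y_pred > 0.5) == y_true.astype(bool)))
    if y_true.size < 2 or np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        return 0.0
    rho = stats.spearmanr(y_true, y_pred).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def _chance_performance(family: str) -> float:
    return 0.5 if family == "logistic" else 0.0


# ---------------------------------------------------------------------------
# Discovery loop


def run_discovery(study: Study, config: CVConfig) -> WeightedNetwork:
    """Repeated cross-validated component selection and prediction.

    Each iteration reshuffles the sessions into ``n_folds`` folds with a
    fresh derived seed.  Every fold in turn serves as the held-out set:
    residualization, F tests, component selection, standardization and α
    tuning all use the training rows only, and the fitted model is
    scored on the held-out fold.  The iteration's performance is the
    mean across its folds, and the edges it contributes are those
    selected in every fold (``config.fold_aggregation``).  The returned
    network weights each edge by the summed performance of contributing
    iterations divided by the total iteration count, so never-selected
    edges are exactly 0.
    """
    E, y, C, _ = _prepare(study, config)
    S, ne_total = E.shape
    if S < 10:
        raise ValueError("need at least 10 sessions with the outcome present")
    n = len(study.labels)
    family = config.family
    weights = np.zeros(ne_total)
    perfs = np.zeros(config.n_iterations)
    for it in range(config.n_iterations):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed % (2**31), it])
        )
        order = rng.permutation(S)
        folds = np.array_split(order, config.n_folds)
        fold_sets: list[set[int]] = []
        fold_perfs = []
        for f, test in enumerate(folds):
            train = np.concatenate([folds[g] for g in range(len(folds)) if g != f])
            sel, perf = _run_fold(
                E, y, C, train, test, config, family, n,
                seed=(config.seed % (2**31)) * 31 + it * config.n_folds + f,
            )
            fold_sets.append(sel)
            fold_perfs.append(perf)
        iter_perf = float(np.mean(fold_perfs))
        if config.fold_aggregation == "all":
            selected = set.intersection(*fold_sets) if fold_sets else set()
        else:
            selected = set.union(*fold_sets) if fold_sets else set()
        if selected:
            weights[sorted(selected)] += iter_perf
        perfs[it] = iter_perf
    weights /= config.n_iterations
    return WeightedNetwork(
        outcome=config.outcome,
        labels=study.labels,
        edge_weights=weights,
        performance=perfs,
        n_iterations=config.n_iterations,
    )


def _run_fold(E, y, C, train, test, config, family, n_regions, seed):
    """One train/test fold: returns (selected edge-index set, performance)."""
    if C.shape[1] > 0:
        E_res, _ = residualize_confounds(E, C, train)
        if family == "linear":
            y_res, _ = residualize_confounds(y, C, train)
        else:
            y_res = y
    else:
        E_res, y_res = E, y
    y_tr = y_res[train]
    if np.ptp(y_tr) == 0 or (family == "logistic" and len(np.unique(y[train])) < 2):
        return set(), _chance_performance(family)
    _, p = edgewise_association(E_res[train], y_tr)
    comp = _lcc_indices(p, config.p_threshold, n_regions)
    if comp.size == 0:
        logger.debug("empty component; recording chance-level performance")
        return set(), _chance_performance(family)
    beta, icpt, _, mean, std = fit_component_model(
        E_res[np.ix_(train, comp)],
        y[train] if family == "logistic" else y_res[train],
        family,
        alpha_grid=config.alpha_grid,
        inner_folds=config.inner_folds,
        seed=seed,
    )
    X_te = (E_res[np.ix_(test, comp)] - mean) / std
    if family == "logistic":
        pred = _predict_logistic_prob(beta, icpt, X_te)
        perf = _fold_performance(family, y[test], pred)
    else:
        pred = _predict_linear(beta, icpt, X_te)
        perf = _fold_performance(family, y_res[test], pred)
    return set(int(k) for k in comp), perf


def threshold_network(
    network: WeightedNetwork, retain_fraction: float = 0.5
) -> np.ndarray:
    """Edge indices of the retained (most positively weighted) edges.

    Keeps the top ``ceil(retain_fraction × n_positive)`` positive-weight
    edges by weight; ties are broken by canonical edge index (lower
    index first).  Returns a sorted index array; empty (with a warning)
    when the network has no positive edge.
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain_fraction must lie in (0, 1]")
    w = network.edge_weights
    pos = np.flatnonzero(w > 0)
    if pos.size == 0:
        warnings.warn("weighted network has no positive edges", stacklevel=2)
        return np.empty(0, dtype=int)
    k = math.ceil(retain_fraction * pos.size)
    order = pos[np.lexsort((pos, -w[pos]))]  # weight desc, then index asc
    return np.sort(order[:k])


def train_final_model(
    study: Study, edge_indices: np.ndarray, config: CVConfig
) -> FittedModel:
    """Refit the retained connectivity pattern on the full discovery study.

    Residualization coefficients, feature standardization statistics, β,
    the intercept and α are all fitted on the entire study and stored so
    the model can be applied unchanged to an external study.
    """
    edge_indices = np.asarray(edge_indices, dtype=int)
    if edge_indices.size == 0:
        raise ValueError("edge set is empty")
    E, y, C, _ = _prepare(study, config)
    train = np.arange(E.shape[0])
    family = config.family
    E_sub = E[:, edge_indices]
    if C.shape[1] > 0:
        E_sub, edge_coef = residualize_confounds(E_sub, C, train)
        if family == "linear":
            y_fit, y_coef = residualize_confounds(y, C, train)
        else:
            y_fit, y_coef = y, None
    else:
        edge_coef, y_coef, y_fit = None, None, y
    beta, intercept, alpha, mean, std = fit_component_model(
        E_sub, y if family == "logistic" else y_fit, family,
        alpha_grid=config.alpha_grid, inner_folds=config.inner_folds,
        seed=config.seed,
    )
    return FittedModel(
        outcome=config.outcome,
        family=family,
        labels=list(study.labels),
        edge_indices=[int(k) for k in edge_indices],
        beta=[float(b) for b in beta],
        intercept=float(intercept),
        alpha=float(alpha),
        covariates=list(config.covariates),
        edge_resid_coef=None if edge_coef is None else edge_coef.tolist(),
        outcome_resid_coef=None if y_coef is None else np.asarray(y_coef).ravel().tolist(),
        feature_mean=[float(v) for v in mean],
        feature_std=[float(v) for v in std],
        scale_outcome=config.scale_outcome,
    )


def transfer_predict(model: FittedModel, study: Study) -> TransferResult:
    """Apply a trained model to an independent study.

    External edges are residualized with the model's stored coefficients
    (fitted on the discovery study — nothing is refit here), then
    standardized with the stored statistics and passed through the
    model.  For hormone outcomes the removed covariate contribution is
    added back so predictions live on the outcome scale, and the actual
    hormone levels are min-max scaled within the external dataset before
    comparison.  Performance is classification accuracy for HC use and
    Spearman ρ for hormones; mean squared error is reported on the same
    scale (predicted probability vs. 0/1 label for HC use).
    """
    if list(study.labels) != list(model.labels):
        raise ValueError("external study has a different region set")
    sessions = study.sessions
    E = study.edge_matrix()[:, model.edge_indices]
    if model.outcome == "hc":
        y = sessions["hc_use"].to_numpy(dtype=float)
    else:
        raw = sessions[model.outcome].to_numpy(dtype=float)
        if model.scale_outcome:
            y = _minmax_by_dataset(raw, sessions["dataset_id"].to_numpy())
        else:
            y = raw
    keep = ~np.isnan(y)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d external session(s) with missing outcome", n_dropped)
    E, y = E[keep], y[keep]
    C = _covariate_matrix(sessions, model.covariates)[keep]
    if model.edge_resid_coef is not None:
        D = np.column_stack([np.ones(E.shape[0]), C])
        E = E - D @ np.asarray(model.edge_resid_coef)
    X = (E - np.asarray(model.feature_mean)) / np.asarray(model.feature_std)
    if model.family == "logistic":
        prob = _predict_logistic_prob(model.beta, model.intercept, X)
        performance = float(np.mean((prob > 0.5) == y.astype(bool)))
        mse = float(np.mean((prob - y) ** 2))
        predictions = prob
    else:
        pred = _predict_linear(model.beta, model.intercept, X)
        if model.outcome_resid_coef is not None:
            D = np.column_stack([np.ones(E.shape[0]), C])
            pred = pred + D @ np.asarray(model.outcome_resid_coef)
        performance = _fold_performance("linear", y, pred)
        mse = float(np.mean((pred - y) ** 2))
        predictions = pred
    return TransferResult(
        outcome=model.outcome,
        predictions=predictions,
        actual=y,
        performance=performance,
        mse=mse,
        n_sessions=int(keep.sum()),
        n_dropped=n_dropped,
    )


def drop_cycle_window(study: Study, day_low: int, day_high: int) -> Study:
    """Remove sessions whose cycle day falls in the closed window.

    Used for sensitivity analyses that exclude ovulatory-peak days.
    Sessions with a missing cycle day are retained with a warning.
    """
    days = study.sessions["cycle_day"]
    missing = days.isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} session(s) lack a cycle day and are retained",
            stacklevel=2,
        )
    drop = (~missing) & (days >= day_low) & (days <= day_high)
    logger.info(
        "dropping %d of %d sessions in cycle-day window [%d, %d]",
        int(drop.sum()), len(days), day_low, day_high,
    )
    return study.subset(~drop.to_numpy())
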