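"""Cross-validated regression battery linking sparsity and features to ratings.

Five model families relate per-image predictors to beauty scores:

1. ``sparsity_per_layer`` — one univariate OLS per layer (sparsity of
   that layer only);
2. ``sparsity_all`` — one ridge model on the sparsities of all layers;
3. ``pc_per_layer`` — one ridge model per layer on its retained
   principal-component scores (80%-variance rule);
4. ``pc_all3`` — one global ridge model on the first three PCs of every
   layer (3 x n_layers predictors, 45 for the 15-layer default set);
5. ``combined`` — first three PCs plus sparsity of every layer
   (4 x n_layers predictors, 60 for the default set).

Every model is scored by repeated k-fold cross-validation (default
10-fold, 100 repeats): R2 = 1 - SSE/SST is computed between held-out
truth and prediction on each test fold (SST centered on the test-fold
mean; negative values retained), then averaged over folds and repeats.
The ridge penalty is chosen from a log-spaced grid by nested inner CV
on each training fold, so penalty selection never sees test data.
Significance is assessed by a seeded permutation test on the
cross-validated R2.

All randomness (fold assignment, permutations) derives from the
configuration seed, making result tables bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, DomainError
from .features import FeatureMatrix, first_k_scores, pca_retain, zscore_columns

__all__ = [
    "CVConfig",
    "RegressionResult",
    "BatteryResult",
    "make_folds",
    "fit_univariate",
    "fit_ridge",
    "permutation_pvalue",
    "run_model_battery",
]

MODEL_FAMILIES = (
    "sparsity_per_layer",
    "sparsity_all",
    "pc_per_layer",
    "pc_all3",
    "combined",
)


def _default_lambda_grid() -> np.ndarray:
    return np.logspace(-4, 4, 50)


@dataclass
class CVConfig:
    """Cross-validation and significance-testing configuration.

    Parameters
    ----------
    folds, repeats
        Outer k-fold structure; defaults 10 folds repeated 100 times.
    seed
        Master seed; every fold assignment and permutation is derived
        from it deterministically.
    lambda_grid
        Candidate ridge penalties (positive, ascending); default 50
        log-spaced values in [1e-4, 1e4] on z-scored predictors.
    permutations
        Permutation count B for p-values (default 10,000).
    inner_folds
        Inner CV folds for penalty selection (default 5).
    lambda_selection
        ``"nested"`` (default): penalty re-selected inside every outer
        training fold.  ``"global"``: selected once on the full data.
    preprocess
        ``"full"`` (default): z-scores/PCA fit on the full dataset
        before CV, replicating the standard full-dataset workflow.
        ``"fold"``: preprocessing refit inside each training fold
        (leak-free variant).
    """

    folds: int = 10
    repeats: int = 100
    seed: int = 0
    lambda_grid: np.ndarray = field(default_factory=_default_lambda_grid)
    permutations: int = 10_000
    inner_folds: int = 5
    lambda_selection: str = "nested"
    preprocess: str = "full"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigurationError(f"folds must be >= 2, got {self.folds}")
        if self.repeats < 1:
            raise ConfigurationError(f"repeats must be >= 1, got {self.repeats}")
        grid = np.asarray(self.lambda_grid, dtype=np.float64)
        if grid.size == 0 or np.any(grid <= 0):
            raise ConfigurationError("lambda_grid must be non-empty and positive")
        self.lambda_grid = np.sort(grid)
        if self.lambda_selection not in ("nested", "global"):
            raise ConfigurationError(
                f"lambda_selection must be 'nested' or 'global', "
                f"got {self.lambda_selection!r}")
        if self.preprocess not in ("full", "fold"):
            raise ConfigurationError(
                f"preprocess must be 'full' or 'fold', got {self.preprocess!r}")


@dataclass
class RegressionResult:
    """Cross-validated fit summary for one model."""

    model_family: str
    r2: float  # mean held-out R2 over folds then repeats
    r2_adjusted: float | None  # adjusted variant (multivariate families)
    coefficients: np.ndarray | None  # full-data fit, z-scored predictor scale
    intercept: float | None
    p_value: float | None  # permutation significance of r2
    per_fold_scores: np.ndarray | None  # (repeats, folds)
    n_predictors: int
    lambda_full: float | None = None  # penalty used for the full-data fit


# ---------------------------------------------------------------------------
# fold construction

def make_folds(n: int, cfg: CVConfig, repeat_index: int) -> np.ndarray:
    """Deterministic k-fold partition for one repeat.

    Returns an integer array of fold labels (0..folds-1) of length
    ``n``, fully determined by ``(cfg.seed, repeat_index)``; fold sizes
    differ by at most one.
    """
    if n < cfg.folds:
        raise DomainError(f"cannot split n={n} samples into {cfg.folds} folds")
    rng = np.random.default_rng([cfg.seed, 7, repeat_index])
    perm = rng.permutation(n)
    fold_id = np.empty(n, dtype=np.intp)
    for f, chunk in enumerate(np.array_split(perm, cfg.folds)):
        fold_id[chunk] = f
    return fold_id


def _heldout_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Prediction R2 = 1 - SSE/SST with SST centered on the test-fold mean."""
    sse = float(np.sum((y_true - y_pred) ** 2))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0.0:
        return np.nan
    return 1.0 - sse / sst


def _adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R2 with n = total samples and p = predictor count.

    Applied to the CV-averaged R2; undefined (NaN) when n <= p + 1.
    """
    if n - p - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


# ---------------------------------------------------------------------------
# per-fold preprocessing transformers (leak-free mode)

class IdentityTransformer:
    def fit(self, X: np.ndarray) -> "IdentityTransformer":
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return X


class ZScoreTransformer:
    """Column z-scoring with statistics taken from the training split."""

    def fit(self, X: np.ndarray) -> "ZScoreTransformer":
        X = np.atleast_2d(np.asarray(X, dtype=np.float64).T).T
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=1)
        if np.any(self.sd_ == 0):
            raise DegenerateInputError("constant predictor in training fold")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.sd_


class PCAScoresTransformer:
    """Training-fold PCA followed by z-scoring of the PC scores.

    ``n_components``: a fixed leading count (e.g. 3) or ``None`` to use
    the variance-target retention rule on the training fold.
    """

    def __init__(self, n_components: int | None = None,
                 variance_target: float = 0.80, layer_id: str = ""):
        self.n_components = n_components
        self.variance_target = variance_target
        self.layer_id = layer_id

    def fit(self, X: np.ndarray) -> "PCAScoresTransformer":
        fm = pca_retain(X, self.variance_target, self.layer_id,
                        keep_all_scores=True)
        k = self.n_components if self.n_components is not None else fm.k
        if k > fm.scores.shape[1]:
            raise DegenerateInputError(
                f"layer {self.layer_id!r}: only {fm.scores.shape[1]} components "
                f"available, {k} requested")
        self.fm_ = fm
        self.k_ = k
        scores = fm.scores[:, :k]
        self.score_mean_ = scores.mean(axis=0)
        self.score_sd_ = scores.std(axis=0, ddof=1)
        if np.any(self.score_sd_ == 0):
            raise DegenerateInputError(
                f"layer {self.layer_id!r}: degenerate PC score column")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        proj = (X - self.fm_.mean) @ self.fm_.components[: self.k_].T
        return (proj - self.score_mean_) / self.score_sd_


class BlockTransformer:
    """Apply independent transformers to horizontal column blocks."""

    def __init__(self, blocks: list[tuple[slice, object]]):
        self.blocks = blocks

    def fit(self, X: np.ndarray) -> "BlockTransformer":
        for sl, t in self.blocks:
            t.fit(X[:, sl])
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.hstack([t.transform(X[:, sl]) for sl, t in self.blocks])


# ---------------------------------------------------------------------------
# ridge machinery: full regularization path from one SVD per training set

def _ridge_path(X: np.ndarray, y: np.ndarray,
                lambdas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ridge solutions for every penalty in ``lambdas`` at once.

    Minimizes ||y - Xw - b||^2 + lam ||w||^2 with an unpenalized
    intercept, via SVD of the column-centered design.  Returns
    ``(coefs, intercepts)`` with coefs of shape (len(lambdas), p).
    """
    mu = X.mean(axis=0)
    Xc = X - mu
    ybar = y.mean()
    yc = y - ybar
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    Uty = U.T @ yc
    shrink = s[None, :] / (s[None, :] ** 2 + np.asarray(lambdas)[:, None])
    coefs = (shrink * Uty[None, :]) @ Vt
    intercepts = ybar - coefs @ mu
    return coefs, intercepts


def _select_lambda(X: np.ndarray, y: np.ndarray, cfg: CVConfig,
                   key: tuple[int, ...]) -> float:
    """Pick the penalty minimizing inner-CV squared error.

    Ties on the error curve go to the larger penalty (more shrinkage).
    """
    n = X.shape[0]
    grid = cfg.lambda_grid
    if n < cfg.inner_folds:
        return float(grid[len(grid) // 2])
    rng = np.random.default_rng([cfg.seed, 11, *key])
    perm = rng.permutation(n)
    sse = np.zeros(grid.size)
    for chunk in np.array_split(perm, cfg.inner_folds):
        mask = np.ones(n, dtype=bool)
        mask[chunk] = False
        coefs, b0 = _ridge_path(X[mask], y[mask], grid)
        pred = X[chunk] @ coefs.T + b0
        sse += ((pred - y[chunk, None]) ** 2).sum(axis=0)
    best = grid.size - 1 - int(np.argmin(sse[::-1]))
    return float(grid[best])


def _make_transformer_or_identity(factory) -> object:
    return factory() if factory is not None else IdentityTransformer()


def fit_ridge(
    X: np.ndarray,
    y: np.ndarray,
    cfg: CVConfig,
    model_family: str = "sparsity_all",
    make_transformer: Callable[[], object] | None = None,
    full_fit: bool = True,
) -> RegressionResult:
    """Repeated k-fold cross-validated ridge regression.

    The penalty is selected from ``cfg.lambda_grid``: with
    ``cfg.lambda_selection == "nested"`` (default) by inner CV on each
    outer training fold, with ``"global"`` once on the full data.
    ``make_transformer``, if given, builds a fresh preprocessing object
    (fit on each training fold) mapping raw columns to model predictors.
    Reported coefficients come from a full-data fit at a full-data
    selected penalty (fold-wise coefficients are not uniquely defined).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[0]
    if y.shape[0] != n:
        raise DomainError("X and y disagree on sample count")

    global_lam = None
    if cfg.lambda_selection == "global":
        t = _make_transformer_or_identity(make_transformer).fit(X)
        global_lam = _select_lambda(t.transform(X), y, cfg, (0, 0, 2))

    scores = np.empty((cfg.repeats, cfg.folds))
    for r in range(cfg.repeats):
        fold_id = make_folds(n, cfg, r)
        for f in range(cfg.folds):
            te = fold_id == f
            tr = ~te
            t = _make_transformer_or_identity(make_transformer).fit(X[tr])
            Xtr, Xte = t.transform(X[tr]), t.transform(X[te])
            lam = (global_lam if global_lam is not None
                   else _select_lambda(Xtr, y[tr], cfg, (r, f, 0)))
            coefs, b0 = _ridge_path(Xtr, y[tr], np.array([lam]))
            pred = Xte @ coefs[0] + b0[0]
            scores[r, f] = _heldout_r2(y[te], pred)

    r2 = float(scores.mean())
    coef = intercept = lam_full = None
    p = X.shape[1]
    if full_fit:
        t = _make_transformer_or_identity(make_transformer).fit(X)
        Xz = t.transform(X)
        p = Xz.shape[1]
        lam_full = (global_lam if global_lam is not None
                    else _select_lambda(Xz, y, cfg, (0, 0, 1)))
        coefs, b0 = _ridge_path(Xz, y, np.array([lam_full]))
        coef, intercept = coefs[0], float(b0[0])
    return RegressionResult(
        model_family=model_family,
        r2=r2,
        r2_adjusted=_adjusted_r2(r2, n, p),
        coefficients=coef,
        intercept=intercept,
        p_value=None,
        per_fold_scores=scores,
        n_predictors=p,
        lambda_full=lam_full,
    )


def fit_univariate(
    x: np.ndarray,
    y: np.ndarray,
    cfg: CVConfig,
    model_family: str = "sparsity_per_layer",
    make_transformer: Callable[[], object] | None = None,
    full_fit: bool = True,
) -> RegressionResult:
    """Cross-validated simple linear regression of scores on one predictor.

    OLS is fit on each training fold and scored on the held-out fold;
    the reported coefficient comes from a full-data fit.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    n = x.size
    if y.size != n:
        raise DomainError("x and y disagree on sample count")
    if n < 10:
        raise DomainError(f"univariate fit needs n >= 10, got {n}")
    if np.std(x) == 0:
        raise DegenerateInputError("zero-variance predictor")

    scores = np.empty((cfg.repeats, cfg.folds))
    for r in range(cfg.repeats):
        fold_id = make_folds(n, cfg, r)
        for f in range(cfg.folds):
            te = fold_id == f
            tr = ~te
            if make_transformer is not None:
                t = make_transformer().fit(x[tr, None])
                xtr = t.transform(x[tr, None]).ravel()
                xte = t.transform(x[te, None]).ravel()
            else:
                xtr, xte = x[tr], x[te]
            xm, ym = xtr.mean(), y[tr].mean()
            sxx = float(((xtr - xm) ** 2).sum())
            slope = float(((xtr - xm) @ (y[tr] - ym)) / sxx)
            pred = ym + slope * (xte - xm)
            scores[r, f] = _heldout_r2(y[te], pred)

    r2 = float(scores.mean())
    coef = intercept = None
    if full_fit:
        if make_transformer is not None:
            t = make_transformer().fit(x[:, None])
            xf = t.transform(x[:, None]).ravel()
        else:
            xf = x
        xm, ym = xf.mean(), y.mean()
        slope = float(((xf - xm) @ (y - ym)) / ((xf - xm) ** 2).sum())
        coef = np.array([slope])
        intercept = float(ym - slope * xm)
    return RegressionResult(
        model_family=model_family,
        r2=r2,
        r2_adjusted=None,
        coefficients=coef,
        intercept=intercept,
        p_value=None,
        per_fold_scores=scores,
        n_predictors=1,
    )


def permutation_pvalue(
    X: np.ndarray,
    y: np.ndarray,
    cfg: CVConfig,
    model_family: str = "univariate",
    make_transformer: Callable[[], object] | None = None,
    observed: float | None = None,
) -> float:
    """Permutation p-value for the cross-validated R2.

    ``p = (1 + #{permuted CV R2 >= observed}) / (1 + B)`` with ``B =
    cfg.permutations`` seeded permutations of ``y``; the permuted
    statistic is computed with exactly the same CV procedure as the
    observed one, so the test is exchangeability-exact up to Monte
    Carlo error.  Deterministic given the seed.
    """
    if cfg.permutations < 99:
        raise ConfigurationError("permutations must be >= 99 for a usable p-value")
    fit = fit_univariate if model_family == "univariate" else fit_ridge
    y = np.asarray(y, dtype=np.float64).ravel()
    if observed is None:
        observed = fit(X, y, cfg, make_transformer=make_transformer,
                       full_fit=False).r2
    rng = np.random.default_rng([cfg.seed, 13])
    count = 0
    for _ in range(cfg.permutations):
        yp = y[rng.permutation(y.size)]
        stat = fit(X, yp, cfg, make_transformer=make_transformer,
                   full_fit=False).r2
        if stat >= observed:
            count += 1
    return (1 + count) / (1 + cfg.permutations)


# ---------------------------------------------------------------------------
# the model battery

@dataclass
class BatteryResult:
    """All five model families fit on one dataset."""

    results: dict  # family -> RegressionResult | list[RegressionResult]
    battery_table: pd.DataFrame  # one row per family
    per_layer_table: pd.DataFrame  # per-layer R2 / coefficient / p-value


def run_model_battery(
    sparsity: pd.DataFrame,
    features: Mapping[str, FeatureMatrix] | None,
    y: np.ndarray,
    cfg: CVConfig,
    activations: Mapping[str, np.ndarray] | None = None,
    permute_univariate: bool = True,
    permute_multivariate: bool = False,
) -> BatteryResult:
    """Fit the five-family model battery.

    Parameters
    ----------
    sparsity
        n_images x n_layers sparsity table (columns = layer ids).
    features
        Per-layer :class:`FeatureMatrix` (required unless
        ``cfg.preprocess == "fold"`` with ``activations`` given).
    y
        Rescaled beauty scores, length n_images.
    activations
        Raw per-layer activation matrices (n_images x d); required for
        the leak-free ``"fold"`` preprocessing mode, where PCA and
        z-scoring are refit inside every training fold.
    permute_univariate, permute_multivariate
        Whether to compute permutation p-values (B = cfg.permutations)
        for the per-layer univariate family (cheap) and for the
        multivariate families (expensive).
    """
    layer_ids = list(sparsity.columns)
    n_layers = len(layer_ids)
    S = sparsity.to_numpy(dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if S.shape[0] != y.size:
        raise ConfigurationError("sparsity table and scores disagree on n_images")
    fold_mode = cfg.preprocess == "fold"
    if fold_mode and activations is None:
        raise ConfigurationError(
            "preprocess='fold' requires raw per-layer activation matrices")
    if not fold_mode and features is None:
        raise ConfigurationError("features (per-layer PCA) required")
    if features is not None:
        missing = [l for l in layer_ids if l not in features]
        if missing:
            raise ConfigurationError(
                f"features missing for layers {missing}: layer sets must match")

    def _udata(j):  # (x, factory) for univariate family, layer j
        if fold_mode:
            return S[:, j], ZScoreTransformer
        return zscore_columns(S[:, j]), None

    def _sparsity_all_data():
        if fold_mode:
            return S, ZScoreTransformer
        return zscore_columns(S, labels=layer_ids), None

    def _pc_layer_data(lid):
        if fold_mode:
            return (activations[lid],
                    lambda: PCAScoresTransformer(None, 0.80, lid))
        fm = features[lid]
        return zscore_columns(fm.scores[:, : fm.k]), None

    def _global_data(include_sparsity: bool):
        if fold_mode:
            mats, blocks, start = [], [], 0
            for lid in layer_ids:
                A = np.asarray(activations[lid], dtype=np.float64)
                mats.append(A)
                blocks.append((slice(start, start + A.shape[1]),
                               PCAScoresTransformer(3, 0.80, lid)))
                start += A.shape[1]
            if include_sparsity:
                mats.append(S)
                blocks.append((slice(start, start + n_layers),
                               ZScoreTransformer()))
            Xraw = np.hstack(mats)
            return Xraw, lambda: BlockTransformer(
                [(sl, type(t)(*_t_args(t))) for sl, t in blocks])
        cols = [zscore_columns(first_k_scores(features[lid], 3))
                for lid in layer_ids]
        if include_sparsity:
            cols.append(zscore_columns(S, labels=layer_ids))
        return np.hstack(cols), None

    def _t_args(t):
        if isinstance(t, PCAScoresTransformer):
            return (t.n_components, t.variance_target, t.layer_id)
        return ()

    results: dict = {}

    # family 1: per-layer univariate sparsity
    fam1 = []
    for j, lid in enumerate(layer_ids):
        x, factory = _udata(j)
        res = fit_univariate(x, y, cfg, "sparsity_per_layer",
                             make_transformer=factory)
        if permute_univariate and cfg.permutations:
            res.p_value = permutation_pvalue(
                x, y, cfg, "univariate", make_transformer=factory,
                observed=res.r2)
        fam1.append(res)
    results["sparsity_per_layer"] = fam1

    # family 2: all-layer ridge on sparsity
    X2, f2 = _sparsity_all_data()
    res2 = fit_ridge(X2, y, cfg, "sparsity_all", make_transformer=f2)
    results["sparsity_all"] = res2

    # family 3: per-layer ridge on retained PCs
    fam3 = []
    for lid in layer_ids:
        Xl, fl = _pc_layer_data(lid)
        fam3.append(fit_ridge(Xl, y, cfg, "pc_per_layer", make_transformer=fl))
    results["pc_per_layer"] = fam3

    # families 4 and 5: global models
    X4, f4 = _global_data(include_sparsity=False)
    res4 = fit_ridge(X4, y, cfg, "pc_all3", make_transformer=f4)
    results["pc_all3"] = res4
    X5, f5 = _global_data(include_sparsity=True)
    res5 = fit_ridge(X5, y, cfg, "combined", make_transformer=f5)
    results["combined"] = res5

    if permute_multivariate and cfg.permutations:
        for fam, (Xf, ff) in (("sparsity_all", (X2, f2)),
                              ("pc_all3", (X4, f4)),
                              ("combined", (X5, f5))):
            results[fam].p_value = permutation_pvalue(
                Xf, y, cfg, "ridge", make_transformer=ff,
                observed=results[fam].r2)

    n = y.size
    rows = [
        {
            "model_family": "sparsity_per_layer",
            "n_predictors": 1,
            "r2": float(np.mean([r.r2 for r in fam1])),
            "r2_adjusted": np.nan,
            "p_value": np.nan,
        },
        {
            "model_family": "sparsity_all",
            "n_predictors": res2.n_predictors,
            "r2": res2.r2,
            "r2_adjusted": res2.r2_adjusted,
            "p_value": res2.p_value if res2.p_value is not None else np.nan,
        },
        {
            "model_family": "pc_per_layer",
            "n_predictors": float(np.mean([r.n_predictors for r in fam3])),
            "r2": float(np.mean([r.r2 for r in fam3])),
            "r2_adjusted": float(np.mean(
                [_adjusted_r2(r.r2, n, r.n_predictors) for r in fam3])),
            "p_value": np.nan,
        },
        {
            "model_family": "pc_all3",
            "n_predictors": res4.n_predictors,
            "r2": res4.r2,
            "r2_adjusted": res4.r2_adjusted,
            "p_value": res4.p_value if res4.p_value is not None else np.nan,
        },
        {
            "model_family": "combined",
            "n_predictors": res5.n_predictors,
            "r2": res5.r2,
            "r2_adjusted": res5.r2_adjusted,
            "p_value": res5.p_value if res5.p_value is not None else np.nan,
        },
    ]
    battery_table = pd.DataFrame(rows)

    ridge_coef = res2.coefficients
    per_layer_table = pd.DataFrame(
        {
            "layer_id": layer_ids,
            "r2_sparsity": [r.r2 for r in fam1],
            "coef_sparsity": [float(r.coefficients[0]) for r in fam1],
            "coef_sparsity_ridge_all": (ridge_coef if ridge_coef is not None
                                        else [np.nan] * n_layers),
            "p_sparsity": [r.p_value if r.p_value is not None else np.nan
                           for r in fam1],
            "r2_pc": [r.r2 for r in fam3],
            "n_pc": [r.n_predictors for r in fam3],
        }
    )
    return BatteryResult(results=results, battery_table=battery_table,
                         per_layer_table=per_layer_table)
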