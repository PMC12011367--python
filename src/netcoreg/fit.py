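"""Solve the embedded Lasso problem per target gene.

The embedded system has N rows (one per candidate TF), not M, so the Lasso
objective ``1/(2N) ||y~ - X~ c||^2 + alpha ||c||_1`` is exactly what
scikit-learn's coordinate-descent Lasso minimizes with ``n_samples = N``.

When ``alpha="cv"``, k-fold cross-validation partitions the N embedded rows.
Because those rows are a nearly noise-free compression of the normal
equations, the minimum-CV-MSE rule degenerates toward alpha -> 0 (selecting
almost every TF); the default selection rule is therefore the
one-standard-error rule: the largest alpha whose CV error is within one
standard error of the minimum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from netcoreg.embedding import (
    EmbeddingSpace,
    ExpressionMatrix,
    TargetVector,
    build_A,
    build_E,
    standardize,
    svd_embed,
)
from netcoreg.ppin import CandidateSet, PPINetwork, subset_and_complete

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Hyperparameters:
    """Knobs of the network-regularized fit.

    beta
        Network prior strength (> 0). Higher values pull coefficients of
        PPI-connected TFs together.
    alpha
        Lasso sparsity penalty (>= 0), or the string ``"cv"`` for k-fold
        cross-validated selection.
    cv_rule
        ``"1se"`` (default) or ``"min"`` — how the CV alpha is picked.
    eta
        Artificial weight for missing PPI edges.
    """

    beta: float = 1.0
    alpha: float | str = 0.1
    cv_folds: int = 5
    cv_rule: str = "1se"
    n_alphas: int = 100
    alpha_min_ratio: float = 1e-4
    intercept: bool = False
    eta: float = 0.01
    tol_svd: float = 1e-6
    max_iter: int = 10_000
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not (self.alpha == "cv" or (isinstance(self.alpha, (int, float)) and self.alpha >= 0)):
            raise ValueError(f"alpha must be >= 0 or 'cv', got {self.alpha!r}")
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.cv_rule not in ("1se", "min"):
            raise ValueError(f"cv_rule must be '1se' or 'min', got {self.cv_rule!r}")


@dataclass
class FitResult:
    """Coefficients and fit quality for one target gene."""

    tg: str
    tf_order: tuple[str, ...]
    c_star: np.ndarray
    alpha_used: float
    mse_train: float
    mse_test: float | None = None
    intercept: float = 0.0
    embedding: EmbeddingSpace | None = None

    @property
    def selected(self) -> tuple[str, ...]:
        """The N* TFs with nonzero coefficient."""
        return tuple(t for t, c in zip(self.tf_order, self.c_star) if c != 0)

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.c_star))

    @property
    def ranks(self) -> dict[str, int]:
        """Rank 1 = largest |c*| among selected TFs; ties broken by TF name."""
        sel = [(abs(c), t) for t, c in zip(self.tf_order, self.c_star) if c != 0]
        sel.sort(key=lambda p: (-p[0], p[1]))
        return {t: i + 1 for i, (_, t) in enumerate(sel)}


def _alpha_grid(X_tilde: np.ndarray, y_tilde: np.ndarray, hp: Hyperparameters) -> np.ndarray:
    n = X_tilde.shape[0]
    alpha_max = np.max(np.abs(X_tilde.T @ y_tilde)) / n
    if alpha_max <= 0:
        alpha_max = 1.0
    return alpha_max * np.logspace(0, np.log10(hp.alpha_min_ratio), hp.n_alphas)


def _cv_alpha(X_tilde: np.ndarray, y_tilde: np.ndarray, hp: Hyperparameters) -> float:
    """Pick alpha by k-fold CV over the N embedded rows."""
    n = X_tilde.shape[0]
    folds = min(hp.cv_folds, n)
    if folds < hp.cv_folds:
        logger.warning("cv_folds reduced to %d (only %d embedded rows)", folds, n)
    alphas = _alpha_grid(X_tilde, y_tilde, hp)
    kf = KFold(n_splits=folds, shuffle=True, random_state=hp.seed)
    errs = np.empty((folds, len(alphas)))
    for f, (tr, te) in enumerate(kf.split(X_tilde)):
        _, coefs, _ = lasso_path(
            X_tilde[tr], y_tilde[tr], alphas=alphas, max_iter=hp.max_iter, tol=hp.tol
        )
        resid = y_tilde[te, None] - X_tilde[te] @ coefs
        errs[f] = np.mean(resid**2, axis=0)
    mean = errs.mean(axis=0)
    j_min = int(np.argmin(mean))
    if hp.cv_rule == "min":
        return float(alphas[j_min])
    se = errs.std(axis=0, ddof=1) / np.sqrt(folds)
    within = np.where(mean <= mean[j_min] + se[j_min])[0]
    return float(alphas[within.min()])  # alphas descend: smallest index = largest alpha


def fit_lasso_embedded(
    emb: EmbeddingSpace,
    hp: Hyperparameters,
    tg: str = "TG",
) -> FitResult:
    """Solve the embedded Lasso and package the solution.

    Training MSE is computed downstream in :func:`fit_one_tg` where the
    original (X, y) are available; here it is filled with the embedded-space
    residual as a placeholder when called stand-alone.
    """
    X_t, y_t = emb.X_tilde, emb.y_tilde
    if hp.alpha == "cv":
        alpha = _cv_alpha(X_t, y_t, hp)
    else:
        alpha = float(hp.alpha)

    model = Lasso(
        alpha=max(alpha, np.finfo(float).tiny),
        fit_intercept=hp.intercept,
        max_iter=hp.max_iter,
        tol=hp.tol,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(X_t, y_t)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            gap = getattr(model, "dual_gap_", None)
            warnings.warn(
                f"Lasso did not converge for {tg} (duality gap {gap}); "
                "result returned as-is",
                ConvergenceWarning,
                stacklevel=2,
            )
    c = model.coef_.copy()
    mse_emb = float(np.mean((y_t - X_t @ c - (model.intercept_ if hp.intercept else 0.0)) ** 2))
    return FitResult(
        tg=tg,
        tf_order=emb.tf_order,
        c_star=c,
        alpha_used=alpha,
        mse_train=mse_emb,
        intercept=float(model.intercept_) if hp.intercept else 0.0,
        embedding=emb,
    )


def fit_one_tg(
    X_raw: np.ndarray,
    y_raw: np.ndarray,
    net: PPINetwork,
    cand: CandidateSet,
    hp: Hyperparameters = Hyperparameters(),
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
) -> FitResult:
    """Run the full per-TG pipeline on raw (unstandardized) expression.

    ``X_raw`` columns must follow ``cand.tfs`` order. Held-out data, when
    provided, is standardized with the training means/sds before scoring.
    """
    ppin = subset_and_complete(net, cand, eta=hp.eta)
    X_std, y_std = standardize(X_raw, y_raw, tf_order=cand.tfs)
    A = build_A(ppin)
    E = build_E(X_std, A, hp.beta)
    emb = svd_embed(E, X_std, y_std, beta=hp.beta, tol=hp.tol_svd)
    res = fit_lasso_embedded(emb, hp, tg=cand.tg)

    yhat = X_std.X @ res.c_star + res.intercept
    res.mse_train = float(np.mean((yhat - y_std.y) ** 2))
    if X_test is not None and y_test is not None:
        Xt = X_std.transform(X_test)
        yt = y_std.transform(y_test)
        res.mse_test = float(np.mean((Xt @ res.c_star + res.intercept - yt) ** 2))
    return res


def fit_all_tgs(
    expression,
    tg_list: list[str],
    net: PPINetwork,
    tf_list: list[str] | None = None,
    prior_grn=None,
    hp: Hyperparameters = Hyperparameters(),
    expression_test=None,
) -> list[FitResult]:
    """Fit every TG in ``tg_list`` against a pandas expression frame (cells x genes).

    Candidates come from ``prior_grn`` (columns TF, TG) when given, otherwise
    from ``tf_list`` (minus the TG itself). Failures on individual TGs are
    logged and skipped rather than aborting the run.
    """
    import pandas as pd  # local import keeps numpy-only paths light

    if not tg_list:
        raise ValueError("empty TG list")
    expression = pd.DataFrame(expression)
    if tf_list is None and prior_grn is None:
        raise ValueError("either tf_list or prior_grn must be provided")

    prior_map: dict[str, list[str]] = {}
    if prior_grn is not None:
        pg = pd.DataFrame(prior_grn)
        cols = {c.lower(): c for c in pg.columns}
        tf_col, tg_col = cols.get("tf", pg.columns[0]), cols.get("tg", pg.columns[1])
        for tg, grp in pg.groupby(tg_col):
            prior_map[str(tg)] = list(dict.fromkeys(grp[tf_col].astype(str)))

    results: list[FitResult] = []
    for tg in tg_list:
        try:
            if tg not in expression.columns:
                raise KeyError(f"TG {tg!r} absent from expression data")
            tfs = prior_map.get(tg, tf_list) if prior_grn is not None else tf_list
            if tfs is None or not tfs:
                raise ValueError(f"no candidate TFs for TG {tg!r}")
            cand = CandidateSet.for_tg(tg, list(tfs))
            missing = [t for t in cand.tfs if t not in expression.columns]
            if missing:
                raise KeyError(f"candidate TFs missing from expression data: {missing}")
            X_raw = expression[list(cand.tfs)].to_numpy(dtype=float)
            y_raw = expression[tg].to_numpy(dtype=float)
            X_te = y_te = None
            if expression_test is not None:
                X_te = expression_test[list(cand.tfs)].to_numpy(dtype=float)
                y_te = expression_test[tg].to_numpy(dtype=float)
            results.append(fit_one_tg(X_raw, y_raw, net, cand, hp, X_te, y_te))
        except Exception as exc:  # per-TG failures are not fatal
            logger.warning("skipping TG %s: %s", tg, exc)
    return results
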