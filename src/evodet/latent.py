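"""Latent-variable regression: PLS and PCR with CV component selection.

Both methods project the standardized predictor matrix X onto a small number
of orthogonal-score components and regress the (centred) response on the
scores.  PCR takes the leading principal axes of X; PLS extracts components
whose scores maximise covariance with the response (classical single-response
NIPALS with deflation, which is exact for one response).  The number of
components is chosen by seeded 10-fold cross-validation with the
one-standard-error rule.  Two variable-importance views are derived: VIP
scores from the PLS weights and a per-variable share of explained response
variance from the PCR loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class LatentModelError(ValueError):
    pass


@dataclass
class LatentModel:
    """Fitted PCR or PLS state.

    ``weights`` (PLS only) are unit-norm X-weight columns; ``loadings`` are
    X-loadings (orthonormal for PCR); ``scores`` the training score matrix
    with mutually orthogonal columns; ``q`` the per-component response
    coefficients; ``ss`` each component's share of training response variance
    (non-negative, additive because scores are orthogonal); ``coef`` the
    regression coefficients collapsed back to the original variable space.
    """

    method: str
    n_components: int
    variable_names: list[str]
    loadings: np.ndarray
    scores: np.ndarray
    q: np.ndarray
    ss: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray
    weights: np.ndarray | None = None

    @property
    def training_r2(self) -> float:
        return float(self.ss.sum())

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_components": self.n_components,
            "variable_names": self.variable_names,
            "coef": self.coef.tolist(),
            "ss": self.ss.tolist(),
            "y_mean": self.y_mean,
        }


@dataclass
class ComponentSelection:
    """Cross-validated error curve and the component count it selects."""

    rmsep: np.ndarray  # indexed by A = 0..max_A
    se: np.ndarray
    selected: int
    n_folds: int
    seed: int
    fold_rmsep: np.ndarray = field(repr=False, default=None)


@dataclass
class FitMetrics:
    """Holdout (or training) fit quality: RMSE and pseudo-R^2.

    variance_explained = 1 - MSE(y, yhat) / var(y) with the population (1/n)
    variance, so predicting the mean gives exactly 0; it can be negative.
    """

    rmse: float
    variance_explained: float


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _check_xy(X: np.ndarray, y: np.ndarray, A: int) -> None:
    n, p = X.shape
    if y.shape != (n,):
        raise LatentModelError(f"y has shape {y.shape}, expected ({n},)")
    if np.isnan(X).any() or np.isnan(y).any():
        raise LatentModelError("X and y must be complete (impute/drop first)")
    if not 1 <= A <= min(n - 1, p):
        raise LatentModelError(f"n_components {A} outside [1, min(n-1, p)={min(n - 1, p)}]")
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise LatentModelError("zero-variance column in X; preprocess must drop these")


def fit_pls(X, y, n_components: int) -> LatentModel:
    """Single-response PLS by sequential covariance-maximising deflation.

    Each round takes the unit weight vector w_a proportional to X'y (which
    maximises the covariance of the score t_a = X w_a with y), then deflates
    X by the loading projection t_a p_a'.  Scores come out mutually
    orthogonal, so each component's share of response variance ss_a is
    additive.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    _check_xy(Xm, y, n_components)
    x_mean = Xm.mean(axis=0)
    y_mean = float(y.mean())
    Xa = Xm - x_mean
    yc = y - y_mean
    ss_total = float(yc @ yc)
    if ss_total == 0:
        raise LatentModelError("response has zero variance")
    p = Xm.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((len(y), n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = Xa.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14:  # X exhausted w.r.t. y
            W, P, T, q = W[:, :a], P[:, :a], T[:, :a], q[:a]
            n_components = a
            break
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        pa = Xa.T @ t / tt
        qa = float(yc @ t / tt)
        Xa = Xa - np.outer(t, pa)
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
    if n_components == 0:
        raise LatentModelError("no usable PLS component (X'y vanishes)")
    ss = q**2 * (T**2).sum(axis=0) / ss_total
    coef = W @ np.linalg.solve(P.T @ W, q)
    return LatentModel(
        method="PLS",
        n_components=n_components,
        variable_names=names,
        loadings=P,
        scores=T,
        q=q,
        ss=ss,
        x_mean=x_mean,
        y_mean=y_mean,
        coef=coef,
        weights=W,
    )


def fit_pcr(X, y, n_components: int) -> LatentModel:
    """Principal-components regression: regress y on the leading A score columns.

    Components are the leading right singular vectors of centred X
    (eigenvectors of its covariance in descending eigenvalue order); loadings
    are orthonormal and scores orthogonal by construction.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    _check_xy(Xm, y, n_components)
    x_mean = Xm.mean(axis=0)
    y_mean = float(y.mean())
    Xc = Xm - x_mean
    yc = y - y_mean
    ss_total = float(yc @ yc)
    if ss_total == 0:
        raise LatentModelError("response has zero variance")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    P = Vt[:n_components].T
    T = U[:, :n_components] * S[:n_components]
    tt = (T**2).sum(axis=0)
    # components beyond numerical rank carry no signal; their q is set to 0
    rank_ok = S[:n_components] > S[0] * 1e-12 if S[0] > 0 else np.zeros(n_components, bool)
    q = np.where(rank_ok, np.divide(yc @ T, tt, out=np.zeros_like(tt), where=tt > 0), 0.0)
    ss = q**2 * tt / ss_total
    coef = P @ q
    return LatentModel(
        method="PCR",
        n_components=n_components,
        variable_names=names,
        loadings=P,
        scores=T,
        q=q,
        ss=ss,
        x_mean=x_mean,
        y_mean=y_mean,
        coef=coef,
    )


def predict_response(model: LatentModel, X_new) -> np.ndarray:
    """Predict the response for new (already standardized) predictor rows.

    DataFrame input is aligned to the training variables by name; a plain
    array must match the training column order.
    """
    if isinstance(X_new, pd.DataFrame):
        missing = [v for v in model.variable_names if v not in X_new.columns]
        extra = [v for v in X_new.columns if v not in model.variable_names]
        if missing or extra:
            raise LatentModelError(
                f"column mismatch with training variables: missing={missing}, extra={extra}"
            )
        Xm = X_new[model.variable_names].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X_new, dtype=float)
        if Xm.shape[1] != len(model.variable_names):
            raise LatentModelError(
                f"X_new has {Xm.shape[1]} columns, model was trained on {len(model.variable_names)}"
            )
    return model.y_mean + (Xm - model.x_mean) @ model.coef


def score_predictions(y, y_hat) -> FitMetrics:
    """RMSE and pseudo-R^2 (1 - MSE / population variance of y)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise LatentModelError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size < 2:
        raise LatentModelError("need at least 2 observations to score")
    mse = float(np.mean((y - y_hat) ** 2))
    var = float(np.var(y))  # population (1/n) variance: yhat=mean(y) scores exactly 0
    return FitMetrics(rmse=float(np.sqrt(mse)), variance_explained=1.0 - mse / var)


# ---------------------------------------------------------------------------
# cross-validated component selection


def one_se_select(rmsep: np.ndarray, se: np.ndarray) -> int:
    """Smallest A whose RMSEP is within one SE of the minimum's RMSEP."""
    rmsep = np.asarray(rmsep, dtype=float)
    se = np.asarray(se, dtype=float)
    amin = int(np.argmin(rmsep))
    threshold = rmsep[amin] + se[amin]
    return int(np.nonzero(rmsep <= threshold)[0][0])


def _bounds(n: int, n_folds: int, k: int) -> slice:
    sizes = np.full(n_folds, n // n_folds)
    sizes[: n % n_folds] += 1
    starts = np.concatenate([[0], np.cumsum(sizes)])
    return slice(starts[k], starts[k + 1])


def _pls_path_predict(X_tr, y_tr, X_te, max_A: int) -> np.ndarray:
    """Test predictions for every component count 0..max_A from one PLS fit."""
    x_mean = X_tr.mean(axis=0)
    y_mean = y_tr.mean()
    Xa = X_tr - x_mean
    yc = y_tr - y_mean
    Ea = X_te - x_mean
    preds = np.empty((max_A + 1, len(X_te)))
    preds[0] = y_mean
    yhat = np.full(len(X_te), y_mean)
    for a in range(1, max_A + 1):
        w = Xa.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            preds[a:] = yhat
            return preds
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        pa = Xa.T @ t / tt
        qa = float(yc @ t / tt)
        Xa = Xa - np.outer(t, pa)
        t_new = Ea @ w
        Ea = Ea - np.outer(t_new, pa)
        yhat = yhat + qa * t_new
        preds[a] = yhat
    return preds


def _pcr_path_predict(X_tr, y_tr, X_te, max_A: int) -> np.ndarray:
    x_mean = X_tr.mean(axis=0)
    y_mean = y_tr.mean()
    Xc = X_tr - x_mean
    yc = y_tr - y_mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    A = min(max_A, len(S))
    T = U[:, :A] * S[:A]
    tt = (T**2).sum(axis=0)
    ok = S[:A] > (S[0] * 1e-12 if S[0] > 0 else np.inf)
    q = np.where(ok, np.divide(yc @ T, tt, out=np.zeros_like(tt), where=tt > 0), 0.0)
    T_new = (X_te - x_mean) @ Vt[:A].T
    preds = np.empty((max_A + 1, len(X_te)))
    preds[0] = y_mean
    yhat = np.full(len(X_te), y_mean)
    for a in range(1, max_A + 1):
        if a <= A:
            yhat = yhat + q[a - 1] * T_new[:, a - 1]
        preds[a] = yhat
    return preds


def select_components(
    X,
    y,
    max_A: int | None = None,
    n_folds: int = 10,
    seed: int = 0,
    method: str = "pls",
) -> ComponentSelection:
    """Choose the number of components by seeded K-fold CV and the one-SE rule.

    RMSEP(A) is evaluated for A = 0..max_A (A=0 is the intercept-only model);
    the selected A is the smallest whose pooled RMSEP lies within one standard
    error (over folds, at the argmin) of the minimum.  Under a pure-noise
    response this degenerates to selecting 0 components.
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n < n_folds:
        raise LatentModelError(f"n={n} smaller than n_folds={n_folds}")
    max_fold = -(-n // n_folds)
    hard_cap = max(1, min(n - max_fold - 1, p))
    if max_A is None:
        max_A = min(n - 1, p, 100)
    if max_A < 1:
        raise LatentModelError("max_A must be >= 1")
    max_A = min(max_A, hard_cap)
    path = _pls_path_predict if method.lower() == "pls" else _pcr_path_predict
    folds = [np.random.default_rng(seed).permutation(n)[_bounds(n, n_folds, k)] for k in range(n_folds)]
    sq_err = np.zeros((max_A + 1, n))
    fold_rmsep = np.zeros((n_folds, max_A + 1))
    for k, test_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        preds = path(Xm[mask], y[mask], Xm[test_idx], max_A)
        err = (preds - y[test_idx]) ** 2
        sq_err[:, test_idx] = err
        fold_rmsep[k] = np.sqrt(err.mean(axis=1))
    rmsep = np.sqrt(sq_err.mean(axis=1))
    se = fold_rmsep.std(axis=0, ddof=1) / np.sqrt(n_folds)
    selected = one_se_select(rmsep, se)
    return ComponentSelection(
        rmsep=rmsep, se=se, selected=selected, n_folds=n_folds, seed=seed, fold_rmsep=fold_rmsep
    )


# ---------------------------------------------------------------------------
# variable importance


def vip_scores(model: LatentModel) -> pd.Series:
    """Variable importance in projection for a fitted PLS model.

    VIP_j = sqrt( p * sum_a ss_a w_ja^2 / sum_a ss_a ) with unit-norm weight
    columns w_a and ss_a the component's share of training response variance.
    The mean of VIP^2 over variables is exactly 1; variables below 1 are
    conventionally considered removable.
    """
    if model.method != "PLS" or model.weights is None:
        raise LatentModelError("VIP is defined for PLS models only")
    if model.n_components < 1:
        raise LatentModelError("VIP requires at least one component")
    W = model.weights
    norms = np.linalg.norm(W, axis=0)
    Wn = W / norms
    p = W.shape[0]
    ss = model.ss
    vip = np.sqrt(p * (Wn**2 @ ss) / ss.sum())
    return pd.Series(vip, index=model.variable_names, name="vip")


def pcr_variance_decomposition(model: LatentModel) -> pd.Series:
    """Percent of response variance attributed to each variable by a PCR model.

    Each component's explained share ss_a is distributed over variables by
    its squared (orthonormal) loadings: contribution_j = sum_a p_ja^2 ss_a,
    reported in percent.  The contributions sum to the training R^2 (x100).
    """
    if model.method != "PCR":
        raise LatentModelError("variance decomposition is defined for PCR models only")
    if model.n_components < 1:
        raise LatentModelError("decomposition requires at least one component")
    P = model.loadings
    gram = P.T @ P
    if not np.allclose(gram, np.eye(P.shape[1]), atol=1e-8):
        raise LatentModelError("PCR loadings are not orthonormal (internal corruption)")
    pct = 100.0 * (P**2 @ model.ss)
    return pd.Series(pct, index=model.variable_names, name="pct_variance")
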