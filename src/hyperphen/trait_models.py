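"""Trait prediction and classification from hyperspectral index tables.

The modeling workflow mirrors common practice in spectroscopy-based
phenotyping: linear stepwise regression (forward entry / backward removal
on partial-F p-values) selects a handful of indices from the 1,541
candidates to predict a manually measured trait (dry weight, green leaf
area, chlorophyll), and k-fold cross-validation reports held-out R2 and
absolute-percentage-error statistics:

    MAPE   = (1/n) * sum_i |(Y_i - y_i) / Y_i| * 100%
    SD_APE = standard deviation of the per-sample absolute percentage errors

with Y_i the manual measurement and y_i the model prediction.  A
correlation screen tallies, per wavelength, how many indices correlate with
a trait beyond a threshold, and a stepwise (Wilks' lambda) linear
discriminant classifier separates growth stages or subspecies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spectral_indices import feature_wavelength

__all__ = [
    "StepwiseModel",
    "CVReport",
    "stepwise_lsr",
    "kfold_cv",
    "mape",
    "correlation_screen",
    "discriminant_classify",
]

# candidates whose residual variance falls below this fraction of their raw
# variance are treated as collinear with the current model and skipped
_COLLINEARITY_TOL = 1e-8


@dataclass
class StepwiseModel:
    """A fitted stepwise linear model: selected features and coefficients."""

    features: list[str]
    coef: pd.Series  # indexed by feature name
    intercept: float
    r2: float
    n: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.features:
            return (
                X[self.features].to_numpy(dtype=float) @ self.coef.to_numpy()
                + self.intercept
            )
        return np.full(len(X), self.intercept)


def _ols(Xm: np.ndarray, y: np.ndarray):
    """Least squares with intercept; returns (beta, resid, p-values of slopes)."""
    n, p = Xm.shape
    design = np.column_stack([np.ones(n), Xm])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = n - p - 1
    if dof <= 0:
        raise ValueError(f"n={n} too small for {p} features")
    s2 = resid @ resid / dof
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.maximum(s2 * np.diag(xtx_inv), 1e-300))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    return beta, resid, pvals[1:]


def stepwise_lsr(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    max_features: int | None = None,
) -> StepwiseModel:
    """Forward-entry / backward-removal linear stepwise regression.

    At each forward step the candidate with the smallest partial-F p-value
    enters if it is below ``alpha_enter`` (ties broken by the
    lexicographically smallest feature name); after each entry, included
    features whose p-value exceeds ``alpha_remove`` are removed, worst
    first.  Candidates collinear with the current model are skipped.  The
    procedure is deterministic and independent of column order when all
    p-values are distinct.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != len(X):
        raise ValueError("X and y length mismatch")
    if n < 3:
        raise ValueError(f"n={n} too small to fit any predictor")
    cols = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    col_var = Xa.var(axis=0)
    candidates = [c for c, v in zip(cols, col_var) if v > 0]
    if len(candidates) < len(cols):
        warnings.warn(
            f"{len(cols) - len(candidates)} zero-variance candidates skipped",
            stacklevel=2,
        )
    col_idx = {c: cols.index(c) for c in candidates}
    col_ss = {c: float(((Xa[:, col_idx[c]] - Xa[:, col_idx[c]].mean()) ** 2).sum())
              for c in candidates}

    selected: list[str] = []
    visited: set[frozenset] = set()
    if max_features is None:
        max_features = n - 2

    while True:
        state = frozenset(selected)
        if state in visited:
            break  # cycle guard
        visited.add(state)

        # ---- forward: partial F via residualization against current model
        entered = False
        remaining = [c for c in candidates if c not in selected]
        if remaining and len(selected) < max_features:
            design = np.column_stack(
                [np.ones(n)] + [Xa[:, col_idx[c]] for c in selected]
            )
            Q, _ = np.linalg.qr(design)
            ry = y - Q @ (Q.T @ y)
            rss_cur = float(ry @ ry)
            Xr = Xa[:, [col_idx[c] for c in remaining]]
            RX = Xr - Q @ (Q.T @ Xr)
            ssx = (RX**2).sum(axis=0)
            dof2 = n - len(selected) - 2
            best: tuple[float, str] | None = None
            if dof2 > 0 and rss_cur > 0:
                num = RX.T @ ry
                for j, c in enumerate(remaining):
                    if ssx[j] <= _COLLINEARITY_TOL * col_ss[c]:
                        continue  # collinear with current model
                    ss_expl = num[j] ** 2 / ssx[j]
                    rss_new = max(rss_cur - ss_expl, 0.0)
                    if rss_new <= 0:
                        p = 0.0
                    else:
                        F = ss_expl / (rss_new / dof2)
                        p = float(stats.f.sf(F, 1, dof2))
                    if best is None or (p, c) < best:
                        best = (p, c)
            if best is not None and best[0] < alpha_enter:
                selected.append(best[1])
                selected.sort(key=candidates.index)
                entered = True

        # ---- backward: drop worst included feature above alpha_remove
        removed = False
        while selected:
            _, _, pvals = _ols(Xa[:, [col_idx[c] for c in selected]], y)
            order = sorted(
                range(len(selected)), key=lambda i: (-pvals[i], selected[i])
            )
            worst = order[0]
            if pvals[worst] > alpha_remove:
                selected.pop(worst)
                removed = True
            else:
                break

        if not entered and not removed:
            break

    if selected:
        beta, resid, _ = _ols(Xa[:, [col_idx[c] for c in selected]], y)
        intercept = float(beta[0])
        coef = pd.Series(beta[1:], index=selected)
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
    else:
        intercept = float(y.mean())
        coef = pd.Series(dtype=float)
        r2 = 0.0
    return StepwiseModel(selected, coef, intercept, r2, n)


def mape(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Mean absolute percentage error, in percent.

    Scale-invariant: multiplying observed and predicted jointly by any
    nonzero constant leaves it unchanged.  Observations equal to zero are
    undefined and must be excluded by the caller.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if np.any(observed == 0):
        raise ValueError("MAPE undefined for zero observations")
    return float(np.mean(np.abs((observed - predicted) / observed)) * 100.0)


@dataclass
class CVReport:
    """Cross-validation summary for one trait model."""

    fold_r2: list[float]
    fold_mape: list[float]
    fold_sd_ape: list[float]
    mape: float           # over all held-out samples
    sd_ape: float         # SD (ddof=0) of per-sample absolute % errors
    n_per_fold: list[int]
    seed: int
    k: int
    models: list[StepwiseModel] = field(default_factory=list)


def kfold_cv(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    k: int = 5,
    seed: int = 0,
    fit=None,
) -> CVReport:
    """k-fold cross-validation of a trait model.

    Folds are a seeded uniform permutation of the samples split into k
    near-equal parts.  ``fit`` is a callable ``(X_train, y_train) -> model``
    with a ``predict`` method; by default a stepwise model with the standard
    entry/removal thresholds is refit on every training split.  Held-out
    samples with Y_i = 0 are excluded from the percentage errors with a
    warning.
    """
    if fit is None:
        fit = stepwise_lsr
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k < 2 or k > n:
        raise ValueError(f"k={k} invalid for n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    fold_r2, fold_mape, fold_sd, n_per_fold, models = [], [], [], [], []
    all_ape: list[np.ndarray] = []
    for test_idx in folds:
        train_idx = np.setdiff1d(order, test_idx)
        model = fit(X.iloc[train_idx], y[train_idx])
        pred = model.predict(X.iloc[test_idx])
        obs = y[test_idx]
        sst = float(((obs - obs.mean()) ** 2).sum())
        ssr = float(((obs - pred) ** 2).sum())
        fold_r2.append(1.0 - ssr / sst if sst > 0 else np.nan)
        nonzero = obs != 0
        if not nonzero.all():
            warnings.warn(
                f"{int((~nonzero).sum())} zero observations excluded from MAPE",
                stacklevel=2,
            )
        ape = np.abs((obs[nonzero] - pred[nonzero]) / obs[nonzero]) * 100.0
        fold_mape.append(float(ape.mean()))
        fold_sd.append(float(ape.std()))
        all_ape.append(ape)
        n_per_fold.append(len(test_idx))
        models.append(model)
    pooled = np.concatenate(all_ape)
    return CVReport(
        fold_r2, fold_mape, fold_sd,
        mape=float(pooled.mean()), sd_ape=float(pooled.std()),
        n_per_fold=n_per_fold, seed=seed, k=k, models=models,
    )


def correlation_screen(
    index_table: pd.DataFrame,
    trait: np.ndarray | pd.Series,
    r_threshold: float = 0.3,
    wavelengths: np.ndarray | None = None,
) -> pd.Series:
    """Per-wavelength count of indices correlated with a trait.

    For every catalog feature the absolute Pearson correlation with the
    trait is computed; features with |r| > ``r_threshold`` are tallied at
    their wavelength (band-wise features at their band center,
    characteristic features at their window center), giving the wavelength
    frequency distribution used to locate trait-informative spectral
    regions.  Returns counts indexed by wavelength (nm, rounded).
    """
    trait = np.asarray(trait, dtype=float)
    if len(trait) < 3:
        raise ValueError("need at least 3 samples")
    if trait.std() == 0:
        raise ValueError("zero-variance trait")
    if wavelengths is None:
        from .cube_io import default_wavelengths

        wavelengths = default_wavelengths()
    meta_cols = {"accession", "stage", "S"}
    counts: dict[int, int] = {}
    values = index_table.drop(columns=[c for c in meta_cols
                                       if c in index_table.columns])
    arr = values.to_numpy(dtype=float)
    tc = trait - trait.mean()
    denom_t = np.sqrt((tc**2).sum())
    ac = arr - arr.mean(axis=0)
    denom_a = np.sqrt((ac**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac.T @ tc) / (denom_a * denom_t)
    for name, ri in zip(values.columns, r):
        if np.isfinite(ri) and abs(ri) > r_threshold:
            nm = int(round(feature_wavelength(name, wavelengths)))
            counts[nm] = counts.get(nm, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def _wilks_lambda(X: np.ndarray, labels: np.ndarray) -> float:
    """Wilks' lambda det(W)/det(T) for features X under class labels."""
    xc = X - X.mean(axis=0)
    T = xc.T @ xc
    W = np.zeros_like(T)
    for g in np.unique(labels):
        xg = X[labels == g]
        xg = xg - xg.mean(axis=0)
        W += xg.T @ xg
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        return np.nan  # singular scatter
    return float(np.exp(logdet_w - logdet_t))


def discriminant_classify(
    X: pd.DataFrame,
    labels,
    cv: int = 5,
    alpha_enter: float = 0.05,
    max_features: int | None = None,
    seed: int = 0,
):
    """Stepwise linear discriminant classification.

    Features enter by the partial F of the Wilks' lambda ratio (candidates
    with singular within-class scatter are skipped); the selected set feeds
    a linear discriminant classifier evaluated with stratified k-fold
    cross-validation.  Returns ``(accuracy, selected_features,
    confusion_matrix)`` where the confusion matrix is a DataFrame over the
    sorted class labels.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.metrics import confusion_matrix
    from sklearn.model_selection import StratifiedKFold, cross_val_predict

    labels = np.asarray(labels)
    classes, class_counts = np.unique(labels, return_counts=True)
    g = len(classes)
    if g < 2:
        raise ValueError("need at least two classes")
    if class_counts.min() < cv:
        raise ValueError(
            f"smallest class has {class_counts.min()} samples, fewer than "
            f"cv={cv} folds"
        )
    n = len(labels)
    cols = [c for c in X.columns if X[c].std() > 0]
    Xa = X[cols].to_numpy(dtype=float)
    if max_features is None:
        max_features = min(len(cols), max(1, n - g - 2))

    selected: list[int] = []
    lam_cur = 1.0
    while len(selected) < max_features:
        p = len(selected)
        dof2 = n - g - p
        if dof2 <= 0:
            break
        best = None
        for j in range(len(cols)):
            if j in selected:
                continue
            lam_new = _wilks_lambda(Xa[:, selected + [j]], labels)
            if not np.isfinite(lam_new) or lam_new <= 0:
                continue
            ratio = lam_new / lam_cur
            ratio = min(ratio, 1.0)
            F = dof2 / (g - 1) * (1 - ratio) / max(ratio, 1e-300)
            pval = float(stats.f.sf(F, g - 1, dof2))
            if best is None or (pval, cols[j]) < (best[0], cols[best[1]]):
                best = (pval, j, lam_new)
        if best is None or best[0] >= alpha_enter:
            break
        selected.append(best[1])
        lam_cur = best[2]

    if not selected:  # fall back to the single best-separating feature
        lams = [(_wilks_lambda(Xa[:, [j]], labels), cols[j], j) for j in range(len(cols))]
        lams = [t for t in lams if np.isfinite(t[0])]
        if not lams:
            raise ValueError("no usable features")
        selected = [min(lams)[2]]

    feats = [cols[j] for j in selected]
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    pred = cross_val_predict(
        LinearDiscriminantAnalysis(), Xa[:, selected], labels, cv=skf
    )
    acc = float(np.mean(pred == labels))
    cm = pd.DataFrame(
        confusion_matrix(labels, pred, labels=classes),
        index=classes, columns=classes,
    )
    return acc, feats, cm
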