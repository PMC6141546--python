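"""Explain vulnerability from structure: PCA, univariate fits, random forest.

Predictors are the 14 topological features plus D_ER and D_BA (dissimilarity
to the matched Erdős–Rényi / Barabási–Albert ensembles); the response is the
network vulnerability.  Univariate linear fits and the random forest (1000
trees, p/3 features per split) are scored by five-fold cross-validated test
mean squared error with seeded, shuffled, size-balanced folds.  The forest
uses the 14 features only; importances are the mean decrease in MSE.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .topology import FEATURE_NAMES

PREDICTOR_NAMES = tuple(FEATURE_NAMES) + ("D_ER", "D_BA")
RESPONSE = "vulnerability"


def build_feature_matrix(features: pd.DataFrame, d_er, d_ba,
                         vulnerability) -> pd.DataFrame:
    """Assemble the 16-predictor matrix plus the response column.

    ``features`` is indexed by network (14 columns); ``d_er``, ``d_ba`` and
    ``vulnerability`` are mappings/Series over the same networks.
    """
    df = features.loc[:, list(FEATURE_NAMES)].copy()
    df["D_ER"] = pd.Series(d_er)
    df["D_BA"] = pd.Series(d_ba)
    df[RESPONSE] = pd.Series(vulnerability)
    if df.isna().any().any():
        missing = df.columns[df.isna().any()].tolist()
        raise ValueError(f"feature matrix has missing values in {missing}")
    return df


def pca_features(matrix: pd.DataFrame, standardize=True, columns=None):
    """PCA of (standardized) feature columns.

    Constant columns are dropped with a warning.  Loadings are signed so the
    largest-magnitude loading of each component is positive; variance
    fractions sum to 1.  Returns (scores, loadings, variance_fractions).
    """
    if columns is None:
        columns = [c for c in matrix.columns if c != RESPONSE]
    x = matrix.loc[:, columns].to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("PCA needs at least 3 rows")
    keep = x.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(columns, keep) if not k]
        warnings.warn(f"dropping constant columns before PCA: {dropped}")
        columns = [c for c, k in zip(columns, keep) if k]
        x = x[:, keep]
    if standardize:
        x = (x - x.mean(axis=0)) / x.std(axis=0)
    pca = PCA()
    scores = pca.fit_transform(x)
    loadings = pca.components_
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[0])]
    return (pd.DataFrame(scores, index=matrix.index, columns=comp_names),
            pd.DataFrame(loadings, index=comp_names, columns=columns),
            pca.explained_variance_ratio_)


def _cv_folds(n, k_folds, seed):
    if n < k_folds:
        raise ValueError(f"{n} rows cannot be split into {k_folds} folds")
    return KFold(n_splits=k_folds, shuffle=True, random_state=seed)


def fit_univariate(matrix: pd.DataFrame, predictor: str, k_folds=5, seed=0):
    """Cross-validated simple linear regression vulnerability ~ predictor."""
    x = matrix[predictor].to_numpy(dtype=float)
    y = matrix[RESPONSE].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError(f"constant predictor: {predictor!r}")
    def _ols(xi, yi):
        # closed-form simple regression; a fold-constant predictor falls
        # back to the intercept-only fit
        vx = np.var(xi)
        b = np.cov(xi, yi, bias=True)[0, 1] / vx if vx > 0 else 0.0
        return b, float(np.mean(yi) - b * np.mean(xi))

    kf = _cv_folds(len(y), k_folds, seed)
    mses = []
    for train, test in kf.split(x):
        b, a = _ols(x[train], y[train])
        mses.append(float(np.mean((y[test] - (a + b * x[test])) ** 2)))
    b_full, a_full = _ols(x, y)
    return {"predictor": predictor, "cv_mse": float(np.mean(mses)),
            "slope": float(b_full), "intercept": float(a_full),
            "fold_mse": mses}


def univariate_scan(matrix: pd.DataFrame, predictors=None, k_folds=5, seed=0):
    """Univariate CV MSE for every predictor, sorted best-first."""
    if predictors is None:
        predictors = [c for c in PREDICTOR_NAMES if c in matrix.columns]
    usable = [p for p in predictors if np.std(matrix[p].to_numpy(dtype=float)) > 0]
    skipped = sorted(set(predictors) - set(usable))
    if skipped:
        warnings.warn(f"skipping constant predictor(s): {skipped}")
    rows = [fit_univariate(matrix, p, k_folds=k_folds, seed=seed)
            for p in usable]
    df = pd.DataFrame(rows).drop(columns="fold_mse")
    return df.sort_values("cv_mse", kind="stable").reset_index(drop=True)


def fit_random_forest(matrix: pd.DataFrame, n_trees=1000, k_folds=5, seed=0,
                      predictors=None):
    """Cross-validated random-forest regression on the 14 topological features.

    Importances (impurity-based mean decrease in MSE) come from the forest
    fitted on all rows; CV follows the same fold protocol as the univariate
    fits.  Deterministic given seed.
    """
    if predictors is None:
        predictors = [c for c in FEATURE_NAMES if c in matrix.columns]
    x = matrix.loc[:, predictors].to_numpy(dtype=float)
    y = matrix[RESPONSE].to_numpy(dtype=float)
    kf = _cv_folds(len(y), k_folds, seed)
    mses = []
    for i, (train, test) in enumerate(kf.split(x)):
        rf = RandomForestRegressor(n_estimators=n_trees, max_features=1.0 / 3,
                                   random_state=seed + i, n_jobs=1)
        rf.fit(x[train], y[train])
        mses.append(float(np.mean((y[test] - rf.predict(x[test])) ** 2)))
    rf_full = RandomForestRegressor(n_estimators=n_trees, max_features=1.0 / 3,
                                    random_state=seed, n_jobs=1)
    rf_full.fit(x, y)
    importances = pd.Series(rf_full.feature_importances_, index=predictors)
    return {"cv_mse": float(np.mean(mses)), "fold_mse": mses,
            "importances": importances.sort_values(ascending=False)}


def cv_mse_spread(matrix: pd.DataFrame, predictor: str, k_folds=5,
                  n_seeds=20, base_seed=0):
    """CV MSE across seed repetitions (small panels make single splits noisy)."""
    vals = [fit_univariate(matrix, predictor, k_folds=k_folds,
                           seed=base_seed + s)["cv_mse"]
            for s in range(n_seeds)]
    return {"predictor": predictor, "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)), "values": vals}
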