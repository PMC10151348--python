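"""Missing-data imputation and principal component analysis of the feature
table.

Fundamental-frequency features can fail to measure on noisy syllables; the
missing cells are imputed per species by regularized iterative PCA (riPCA): an
EM-style loop that alternates a low-rank reconstruction with shrunk singular
values and refilling of the missing cells, so imputation respects both the
similarity between a species' syllables and the correlations between features.

The PCA itself is computed on the correlation matrix (features standardized):
the 21 measures mix Hz, seconds and unitless quantities, and unstandardized
PCA would let the Hz-scale features dominate. Components are retained by the
Kaiser-Guttman rule (eigenvalue > 1) and a feature's loading on a component
counts as significant when |loading| >= L_crit = sqrt(1/f), f the number of
raw features.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acoustic_features import FEATURE_NAMES, FUND_FEATURES, ID_COLUMNS

__all__ = [
    "PCModel",
    "ripca_impute",
    "impute_diagnostic",
    "pca_fit",
    "significant_loadings",
    "loading_criterion",
]


def loading_criterion(f: int) -> float:
    """L_crit = sqrt(1/f): the significance threshold for |loading|."""
    if f < 1:
        raise ValueError("f must be a positive feature count")
    return float(np.sqrt(1.0 / f))


@dataclass
class PCModel:
    """Fitted principal components of a standardized feature table."""

    loadings: pd.DataFrame        # features x components, unit-norm columns
    eigenvalues: np.ndarray       # nonincreasing
    scores: pd.DataFrame          # rows x components (pc1..pcK)
    feature_means: pd.Series
    feature_sds: pd.Series
    f: int = 0                    # number of raw features
    l_crit: float = 0.0
    retained: list = field(default_factory=list)

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def to_json(self, path) -> None:
        payload = {
            "loadings": self.loadings.to_dict(),
            "eigenvalues": self.eigenvalues.tolist(),
            "f": self.f,
            "l_crit": self.l_crit,
            "retained": list(self.retained),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _ripca_block(x: np.ndarray, ncp: int, max_iter: int, tol: float) -> tuple[np.ndarray, int, bool]:
    """Regularized iterative PCA completion of one (standardized) block.

    Missing cells start at column means; each sweep reconstructs the centered
    block at rank ``ncp`` with singular values shrunk by the estimated noise
    variance ((d_l^2 - sigma2)/d_l) and refills only the missing cells.
    """
    mask = np.isnan(x)
    n, p = x.shape
    col_mean = np.nanmean(x, axis=0)
    filled = np.where(mask, col_mean[None, :], x)
    prev = filled[mask].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = filled.mean(axis=0)
        c = filled - mu[None, :]
        u, d, vt = np.linalg.svd(c, full_matrices=False)
        # residual variance from the discarded directions
        tail = d[ncp:] ** 2
        denom = n * p - p - n * ncp - p * ncp + ncp**2 + ncp
        sigma2 = tail.sum() / denom if denom > 0 and tail.size else 0.0
        d_shrunk = np.where(d[:ncp] > 0, (d[:ncp] ** 2 - sigma2) / np.where(d[:ncp] > 0, d[:ncp], 1.0), 0.0)
        d_shrunk = np.maximum(d_shrunk, 0.0)
        recon = (u[:, :ncp] * d_shrunk[None, :]) @ vt[:ncp] + mu[None, :]
        filled[mask] = recon[mask]
        change = np.sqrt(np.mean((filled[mask] - prev) ** 2)) if mask.any() else 0.0
        prev = filled[mask].copy()
        if change < tol:
            converged = True
            break
    return filled, it, converged


def ripca_impute(
    table: pd.DataFrame,
    ncp: int = 2,
    max_iter: int = 500,
    tol: float = 1e-8,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Impute missing cells per species with regularized iterative PCA.

    Missingness must be confined to the fundamental-frequency columns (raised
    otherwise by the table validator upstream); observed cells are untouched.
    A species whose missing column has no observed value at all is an error.
    Non-convergence warns with the iteration count.
    """
    features = list(feature_names) if feature_names is not None else FEATURE_NAMES
    out = table.copy()
    if not out[features].isna().any().any():
        return out
    for species, block in out.groupby("species", sort=False):
        x = block[features].to_numpy(dtype=float)
        mask = np.isnan(x)
        if not mask.any():
            continue
        all_missing = [features[j] for j in range(x.shape[1]) if mask[:, j].all()]
        if all_missing:
            raise ValueError(f"species {species!r}: column(s) entirely missing: {all_missing}")
        # standardize on observed cells so mixed units share a scale
        mu = np.nanmean(x, axis=0)
        sd = np.nanstd(x, axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        z = (x - mu[None, :]) / sd[None, :]
        filled, n_iter, converged = _ripca_block(z, min(ncp, min(x.shape) - 1), max_iter, tol)
        if not converged:
            warnings.warn(f"riPCA for species {species!r} did not converge in {n_iter} iterations")
        restored = filled * sd[None, :] + mu[None, :]
        x[mask] = restored[mask]
        out.loc[block.index, features] = x
    return out


def impute_diagnostic(
    complete: pd.DataFrame,
    incomplete: pd.DataFrame,
    n_components: int = 3,
    feature_names: list[str] | None = None,
) -> float:
    """Congruence between the PCA dimensions of the imputed table and those of
    the incomplete table's complete cases.

    Returns the mean absolute correlation between matched leading loading
    vectors, in [0, 1]; values near 1 mean imputation did not distort the
    principal structure.
    """
    features = list(feature_names) if feature_names is not None else FEATURE_NAMES
    a = pca_fit(complete, feature_names=features)
    cc = incomplete.dropna(subset=features)
    b = pca_fit(cc, feature_names=features)
    k = min(n_components, a.loadings.shape[1], b.loadings.shape[1])
    cors = []
    for i in range(k):
        la = a.loadings.iloc[:, i].to_numpy()
        lb = b.loadings.iloc[:, i].to_numpy()
        cors.append(abs(float(np.corrcoef(la, lb)[0, 1])))
    return float(np.mean(cors))


def pca_fit(table: pd.DataFrame, feature_names: list[str] | None = None) -> PCModel:
    """Correlation-matrix PCA of the feature table.

    Loadings are unit-norm eigenvectors with each column oriented so its
    largest-magnitude entry is positive; scores are the projections of the
    standardized data. Retained components follow Kaiser-Guttman
    (eigenvalue > 1).
    """
    features = list(feature_names) if feature_names is not None else FEATURE_NAMES
    x = table[features].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("PCA requires a complete table; impute first")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = [features[j] for j in range(len(features)) if sd[j] == 0]
    if zero:
        raise ValueError(f"constant feature column(s): {zero}")
    z = (x - mu[None, :]) / sd[None, :]
    corr = np.corrcoef(z, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.maximum(vals[order], 0.0), vecs[:, order]
    # orient: largest-|.| entry of each loading column positive
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    comp_names = [f"pc{i + 1}" for i in range(len(vals))]
    loadings = pd.DataFrame(vecs, index=features, columns=comp_names)
    scores = pd.DataFrame(z @ vecs, columns=comp_names, index=table.index)
    f = len(features)
    retained = [i for i, v in enumerate(vals) if v > 1.0]
    return PCModel(
        loadings=loadings,
        eigenvalues=vals,
        scores=scores,
        feature_means=pd.Series(mu, index=features),
        feature_sds=pd.Series(sd, index=features),
        f=f,
        l_crit=loading_criterion(f),
        retained=retained,
    )


def significant_loadings(model: PCModel, component: int) -> list[str]:
    """Features whose |loading| on the (0-based) component meets L_crit.

    Boundary convention: a loading exactly at the threshold is included (a
    tiny tolerance keeps the inclusive rule robust to floating-point rounding
    of the eigenvectors).
    """
    col = model.loadings.iloc[:, component]
    return list(col.index[np.abs(col.to_numpy()) >= model.l_crit - 1e-12])
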