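"""Species hypervolumes in PC space: one-class SVM boundaries, Monte Carlo
volume estimation, and pairwise overlap indices.

Each species' occupied region of 3-D component space is delimited by a
one-class SVM (RBF kernel). The inclusion threshold is set at the minimum
decision value over the training points, so the fitted region always encloses
every training syllable regardless of the nu parameter. Volumes and overlaps
are estimated by uniform sampling inside a margin-padded bounding box; overlap
uses one joint sample per species pair so the set identities
(Jaccard <= both directionals) hold exactly in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import OneClassSVM

__all__ = [
    "VolumeModel",
    "OverlapIndices",
    "fit_boundary",
    "estimate_volume",
    "overlap_indices",
    "symmetry_test",
]


@dataclass
class VolumeModel:
    """One species' fitted one-class boundary and padded bounding box."""

    species: str
    svm: OneClassSVM
    threshold: float          # minimum decision value over training points
    box_lo: np.ndarray
    box_hi: np.ndarray

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Inclusion test: decision value >= the training minimum."""
        return self.svm.decision_function(np.atleast_2d(points)) >= self.threshold

    @property
    def box_volume(self) -> float:
        return float(np.prod(self.box_hi - self.box_lo))


@dataclass
class OverlapIndices:
    """Pairwise hypervolume overlap: symmetric Jaccard and asymmetric
    directional indices (entry [X, Y] = proportion of X's volume inside Y)."""

    jaccard: pd.DataFrame
    directional: pd.DataFrame
    iterations: int


def fit_boundary(
    points: np.ndarray,
    species: str = "",
    nu: float = 0.01,
    gamma: float = 0.5,
    margin: float = 0.10,
) -> VolumeModel:
    """Fit a one-class boundary that encloses all training points.

    The bounding box is the per-dimension data extent expanded by ``margin``
    (proportion of the extent) on each side. Degenerate (collinear/coplanar)
    point sets are rejected with advice to jitter.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 10:
        raise ValueError("need >= 10 points in a 2-D array (points x dims)")
    extents = pts.max(axis=0) - pts.min(axis=0)
    if np.any(extents <= 0):
        raise ValueError("degenerate point set (zero extent in some dimension); add jitter")
    svm = OneClassSVM(nu=nu, gamma=gamma)
    svm.fit(pts)
    threshold = float(svm.decision_function(pts).min())
    pad = margin * extents
    return VolumeModel(
        species=species,
        svm=svm,
        threshold=threshold,
        box_lo=pts.min(axis=0) - pad,
        box_hi=pts.max(axis=0) + pad,
    )


def estimate_volume(
    model: VolumeModel, n_samples: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte Carlo volume of the enclosed region: (volume, standard error)."""
    rng = np.random.default_rng(int(seed))
    dims = model.box_lo.size
    pts = rng.uniform(model.box_lo, model.box_hi, size=(n_samples, dims))
    inside = model.contains(pts)
    frac = inside.mean()
    se = np.sqrt(frac * (1 - frac) / n_samples)
    v = model.box_volume
    return float(frac * v), float(se * v)


def _pair_overlap(mx: VolumeModel, my: VolumeModel, n_samples: int, rng) -> tuple[float, float, float]:
    """Joint-sample Jaccard and the two directionals for one species pair."""
    lo = np.minimum(mx.box_lo, my.box_lo)
    hi = np.maximum(mx.box_hi, my.box_hi)
    pts = rng.uniform(lo, hi, size=(n_samples, lo.size))
    in_x = mx.contains(pts)
    in_y = my.contains(pts)
    n_x, n_y = in_x.sum(), in_y.sum()
    n_both = np.logical_and(in_x, in_y).sum()
    n_union = np.logical_or(in_x, in_y).sum()
    jac = n_both / n_union if n_union > 0 else 0.0
    dxy = n_both / n_x if n_x > 0 else np.nan  # share of X inside Y
    dyx = n_both / n_y if n_y > 0 else np.nan
    return float(jac), float(dxy), float(dyx)


def overlap_indices(
    models: dict[str, VolumeModel],
    n_samples: int = 100_000,
    iterations: int = 100,
    seed: int = 0,
) -> OverlapIndices:
    """Pairwise overlap indices averaged over ``iterations`` fresh Monte Carlo
    samples. Diagonals are 1 by definition; an undefined directional entry
    (zero focal volume) is NaN with a warning."""
    names = list(models)
    k = len(names)
    jac = np.eye(k)
    dire = np.eye(k)
    rng = np.random.default_rng(int(seed))
    for i in range(k):
        for j in range(i + 1, k):
            js, dxys, dyxs = [], [], []
            for _ in range(iterations):
                a, b, c = _pair_overlap(models[names[i]], models[names[j]], n_samples, rng)
                js.append(a)
                dxys.append(b)
                dyxs.append(c)
            jac[i, j] = jac[j, i] = float(np.mean(js))
            dire[i, j] = float(np.nanmean(dxys))
            dire[j, i] = float(np.nanmean(dyxs))
            if np.isnan(dire[i, j]) or np.isnan(dire[j, i]):
                warnings.warn(f"zero focal volume for pair ({names[i]}, {names[j]})")
    return OverlapIndices(
        jaccard=pd.DataFrame(jac, index=names, columns=names),
        directional=pd.DataFrame(dire, index=names, columns=names),
        iterations=iterations,
    )


def symmetry_test(directional: pd.DataFrame) -> tuple[float, float, int]:
    """Spearman rank correlation between directional(X, Y) and directional(Y, X)
    over the C(k, 2) unordered heterospecific pairs: (r_s, p, N)."""
    d = directional.to_numpy()
    k = d.shape[0]
    if k < 3:
        raise ValueError("need >= 3 species")
    xy, yx = [], []
    for i in range(k):
        for j in range(i + 1, k):
            xy.append(d[i, j])
            yx.append(d[j, i])
    res = stats.spearmanr(xy, yx)
    return float(res.statistic), float(res.pvalue), len(xy)
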