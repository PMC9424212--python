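"""Centred, SVD-based principal component analysis.

The model follows the smartpca-family convention used throughout the
framework: columns are centred by their mean (no variance scaling by
default), components come from the singular value decomposition of the
centred matrix, and eigenvalues use the sample (n-1) normalisation.  The
component sign is fixed deterministically by flipping each component so its
largest-magnitude loading is positive; axis flips carry no information and
downstream comparisons are made up to rotation/reflection anyway.

Held-out samples are mapped into a fitted basis one at a time.  A sample
with missing features is projected using only its observed features: the
centring vector and loadings are restricted to the observed columns and each
coordinate is rescaled by p/p_obs so score magnitudes stay comparable across
samples with different missingness.  No shrinkage correction is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pcaudit.colors import Dataset

__all__ = ["PCA", "PCAResults"]


class PCA:
    """Principal component analysis model for a complete Dataset.

    Parameters
    ----------
    data : Dataset or (n, p) array
        Training data; must contain no missing entries (collapse windowed
        data first, see :mod:`pcaudit.robustness`).
    normalize : bool, default False
        If True, scale each centred column by its sample SD before the SVD.
        Off by default to match the centring-only convention.

    Examples
    --------
    >>> model = PCA(cohort)
    >>> res = model.fit()
    >>> res.explained_variance(2)
    0.889...
    """

    def __init__(self, data: Dataset | np.ndarray, normalize: bool = False):
        if isinstance(data, Dataset):
            if data.has_missing:
                raise ValueError(
                    "dataset contains missing entries; PCA requires complete data "
                    "— aggregate windows first (pcaudit.robustness.collapse_windows) "
                    "or project held-out samples with PCAResults.project_with_missing"
                )
            X = data.values
            labels = np.asarray(data.sample_labels, dtype=object)
        else:
            X = np.asarray(data, dtype=float)
            if np.isnan(X).any():
                raise ValueError("data contains NaN entries; PCA requires complete data")
            labels = np.array([f"s{i}" for i in range(X.shape[0])], dtype=object)
        if X.ndim != 2:
            raise ValueError("data must be 2-D")
        n, p = X.shape
        if n < 2:
            raise ValueError(f"PCA requires n >= 2 samples, got {n}")
        if p < 1:
            raise ValueError("PCA requires at least one feature")
        self.X = X
        self.labels = labels
        self.normalize = bool(normalize)

    def fit(self, n_components: int | None = None) -> "PCAResults":
        X = self.X
        n, p = X.shape
        center = X.mean(axis=0)
        Xc = X - center
        scale = np.ones(p)
        if self.normalize:
            sd = Xc.std(axis=0, ddof=1)
            scale = np.where(sd > 0, sd, 1.0)
            Xc = Xc / scale
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        r_full = min(n - 1, p)
        eigenvalues = (s**2) / (n - 1)
        total_var = float(eigenvalues.sum())
        r = r_full if n_components is None else min(int(n_components), r_full)
        loadings = Vt[:r].T.copy()
        eigenvalues = eigenvalues[:r].copy()
        # deterministic sign: largest-|loading| entry of each component positive
        for j in range(r):
            i_max = int(np.argmax(np.abs(loadings[:, j])))
            if loadings[i_max, j] < 0:
                loadings[:, j] = -loadings[:, j]
        scores = Xc @ loadings
        explained = eigenvalues / total_var if total_var > 0 else np.zeros(r)
        return PCAResults(
            model=self,
            center=center,
            scale=scale,
            loadings=loadings,
            eigenvalues=eigenvalues,
            total_variance=total_var,
            explained_fraction=explained,
            scores=scores,
            r=r,
            sample_labels=self.labels,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, feature_columns=None, **kw) -> "PCA":
        if feature_columns is None:
            feature_columns = [c for c in df.columns if c not in ("sample_id", "label")]
        X = df[feature_columns].to_numpy(dtype=float)
        model = cls(X, **kw)
        if "label" in df.columns:
            model.labels = df["label"].to_numpy(dtype=object)
        return model


@dataclass
class PCAResults:
    """Fitted PCA basis: centring vector, orthonormal loadings, eigenvalues,
    per-component explained-variance fractions and training scores."""

    model: PCA
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # p x r, orthonormal columns
    eigenvalues: np.ndarray  # length r, nonincreasing
    total_variance: float
    explained_fraction: np.ndarray
    scores: np.ndarray  # n x r
    r: int
    sample_labels: np.ndarray

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def explained_variance(self, k: int) -> float:
        """Fraction of total variance captured by the first k components."""
        if not (1 <= k <= self.r):
            raise ValueError(f"k must be in [1, {self.r}], got {k}")
        return float(self.explained_fraction[:k].sum())

    def explained_percent(self, k: int, digits: int | None = 0) -> float:
        """Explained variance as a percentage; rounded half away from zero
        to integer percent by default (the display convention)."""
        pct = 100.0 * self.explained_variance(k)
        if digits is None:
            return pct
        shifted = pct * 10**digits
        return float(np.floor(shifted + 0.5) / 10**digits)

    def transform(self, data: Dataset | np.ndarray, k: int | None = None) -> np.ndarray:
        """Map complete samples into the fitted basis: (X - center) @ loadings."""
        if isinstance(data, Dataset):
            if data.has_missing:
                raise ValueError(
                    "data has missing entries; use project_with_missing per sample"
                )
            X = data.values
        else:
            X = np.atleast_2d(np.asarray(data, dtype=float))
        if X.shape[1] != self.p:
            raise ValueError(f"feature mismatch: model p={self.p}, data p={X.shape[1]}")
        k = self.r if k is None else int(k)
        if not (1 <= k <= self.r):
            raise ValueError(f"k must be in [1, {self.r}], got {k}")
        return ((X - self.center) / self.scale) @ self.loadings[:, :k]

    def project_with_missing(
        self,
        sample: np.ndarray,
        missing_mask: np.ndarray | None = None,
        k: int | None = None,
        rescale: bool = True,
    ) -> np.ndarray:
        """Project one held-out sample using only its observed features.

        The centring vector and loadings are restricted to the observed
        columns; each coordinate is then rescaled by p/p_obs (``rescale=True``)
        so samples with heavy missingness keep comparable score magnitudes.
        Samples are projected one at a time, never jointly.
        """
        x = np.asarray(sample, dtype=float).ravel()
        if x.shape[0] != self.p:
            raise ValueError(f"feature mismatch: model p={self.p}, sample p={x.shape[0]}")
        if missing_mask is None:
            missing_mask = np.isnan(x)
        obs = ~np.asarray(missing_mask, dtype=bool).ravel()
        k = self.r if k is None else int(k)
        p_obs = int(obs.sum())
        if p_obs < k:
            raise ValueError(
                f"sample observes only {p_obs} features but k={k} components requested"
            )
        score = ((x[obs] - self.center[obs]) / self.scale[obs]) @ self.loadings[obs, :k]
        if rescale:
            score = score * (self.p / p_obs)
        return score

    def project_dataset(
        self, data: Dataset, k: int | None = None, rescale: bool = True
    ) -> np.ndarray:
        """Project every sample of a (possibly missing) dataset one at a time."""
        k = self.r if k is None else int(k)
        out = np.empty((data.n, k))
        for i in range(data.n):
            out[i] = self.project_with_missing(
                data.values[i], data.missing_mask[i], k=k, rescale=rescale
            )
        return out

    def reconstruct(self, k: int | None = None) -> np.ndarray:
        """Training-data reconstruction from the first k components."""
        k = self.r if k is None else int(k)
        return (self.scores[:, :k] @ self.loadings[:, :k].T) * self.scale + self.center

    # -- reporting -------------------------------------------------------
    def scores_frame(self, k: int | None = None) -> pd.DataFrame:
        k = self.r if k is None else int(k)
        df = pd.DataFrame(
            self.scores[:, :k], columns=[f"PC{j + 1}" for j in range(k)]
        )
        df.insert(0, "label", [str(x) for x in self.sample_labels])
        df.insert(0, "sample_id", [f"s{i}" for i in range(self.n)])
        return df

    def summary(self) -> str:
        lines = [
            "PCA results",
            "===========",
            f"samples: {self.n}   features: {self.p}   components: {self.r}",
            f"normalized columns: {self.model.normalize}",
            "",
            f"{'component':>10} {'eigenvalue':>14} {'explained':>10} {'cumulative':>11}",
        ]
        cum = 0.0
        for j in range(self.r):
            cum += self.explained_fraction[j]
            lines.append(
                f"{'PC' + str(j + 1):>10} {self.eigenvalues[j]:>14.6g} "
                f"{100 * self.explained_fraction[j]:>9.2f}% {100 * cum:>10.2f}%"
            )
        return "\n".join(lines)

    # -- plain-text persistence -----------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialise the basis (center, scale, loadings, eigenvalues) to a
        plain-text JSON bundle so projections are reproducible across runs."""
        bundle = {
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "total_variance": self.total_variance,
            "normalize": self.model.normalize,
        }
        Path(path).write_text(json.dumps(bundle, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PCAResults":
        bundle = json.loads(Path(path).read_text())
        center = np.asarray(bundle["center"], dtype=float)
        loadings = np.asarray(bundle["loadings"], dtype=float)
        eigenvalues = np.asarray(bundle["eigenvalues"], dtype=float)
        total = float(bundle["total_variance"])
        model = PCA.__new__(PCA)
        model.X = np.zeros((2, center.shape[0]))
        model.labels = np.array(["s0", "s1"], dtype=object)
        model.normalize = bool(bundle["normalize"])
        return cls(
            model=model,
            center=center,
            scale=np.asarray(bundle["scale"], dtype=float),
            loadings=loadings,
            eigenvalues=eigenvalues,
            total_variance=total,
            explained_fraction=eigenvalues / total if total > 0 else 0 * eigenvalues,
            scores=np.zeros((0, loadings.shape[1])),
            r=loadings.shape[1],
            sample_labels=np.array([], dtype=object),
        )
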