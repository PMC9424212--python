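"""Marker-robustness machinery: windows, missingness and noise markers.

Colour components are expanded into SNP-like markers by replicating each
component value across a window of features (default 200, i.e. 600 "SNPs"
from 3 components).  Missingness is injected entry-wise, and structure is
recovered by the reverse operation: a missing-aware mean over each
component's observed window features.  Replication-plus-mean (rather than
dividing the value across the window) keeps per-feature variance equal to
the component variance, so heavy missingness merely thins the replicates
and recovery error scales as noise/sqrt(observed window count).

Noise markers are i.i.d. uniform [0,1] features appended to the matrix;
they dilute the explained variance of the leading components and, in large
numbers, drown the structure entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from pcaudit.clustering import homogeneity
from pcaudit.colors import Dataset
from pcaudit.distances import configuration_agreement
from pcaudit.pca import PCA

__all__ = [
    "WindowMap",
    "expand_windows",
    "inject_missingness",
    "collapse_windows",
    "add_noise_markers",
    "add_uniform_noise",
    "structure_retention",
    "RetentionReport",
]


@dataclass(frozen=True)
class WindowMap:
    """Mapping from expanded features back to their source components."""

    window_size: int
    component_of: tuple[int, ...]  # length p_expanded
    source_feature_ids: tuple[str, ...]

    @property
    def n_components(self) -> int:
        return len(self.source_feature_ids)


def expand_windows(data: Dataset, window_size: int = 200) -> tuple[Dataset, WindowMap]:
    """Replicate each component value across a window of features.

    3 colour components with window_size=200 yield a 600-"SNP" dataset.
    Requires complete input.
    """
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    if data.has_missing:
        raise ValueError("cannot expand a dataset with missing entries")
    window_size = int(window_size)
    p = data.p
    values = np.repeat(data.values, window_size, axis=1)
    component_of = tuple(int(c) for c in np.repeat(np.arange(p), window_size))
    feature_ids = [
        f"{data.feature_ids[c]}_w{w}" for c in range(p) for w in range(window_size)
    ]
    expanded = Dataset(
        values=values,
        sample_labels=data.sample_labels.copy(),
        feature_ids=feature_ids,
        feature_class=["window-snp"] * (p * window_size),
    )
    wmap = WindowMap(
        window_size=window_size,
        component_of=component_of,
        source_feature_ids=tuple(data.feature_ids),
    )
    return expanded, wmap


def inject_missingness(data: Dataset, rate: float, seed: int) -> Dataset:
    """Nullify a uniform random subset of exactly round(rate*n*p) entries.

    Raises if any sample would be left with no observed feature.
    """
    if not (0 <= rate < 1):
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    out = data.copy()
    if rate == 0:
        return out
    n, p = data.n, data.p
    m = int(round(rate * n * p))
    rng = np.random.default_rng(int(seed))
    flat = rng.choice(n * p, size=m, replace=False)
    mask = out.missing_mask.copy()
    mask[np.unravel_index(flat, (n, p))] = True
    fully = np.flatnonzero(mask.all(axis=1))
    if fully.size:
        raise ValueError(
            f"missingness rate {rate} leaves sample(s) {fully.tolist()} fully missing"
        )
    out.missing_mask = mask
    return out


def collapse_windows(data: Dataset, wmap: WindowMap) -> Dataset:
    """Recover components as the missing-aware mean over each component's
    observed window features.  A component with zero observed features is
    missing in the output."""
    n = data.n
    comp = np.asarray(wmap.component_of)
    if comp.shape[0] != data.p:
        raise ValueError("WindowMap does not match dataset width")
    n_comp = wmap.n_components
    values = np.zeros((n, n_comp))
    mask = np.zeros((n, n_comp), dtype=bool)
    for c in range(n_comp):
        cols = comp == c
        sub = data.values[:, cols]
        obs = ~data.missing_mask[:, cols]
        cnt = obs.sum(axis=1)
        with np.errstate(invalid="ignore"):
            means = np.where(cnt > 0, (sub * obs).sum(axis=1) / np.maximum(cnt, 1), 0.0)
        values[:, c] = means
        mask[:, c] = cnt == 0
    return Dataset(
        values=values,
        sample_labels=data.sample_labels.copy(),
        feature_ids=list(wmap.source_feature_ids),
        feature_class=["color-component"] * n_comp,
        missing_mask=mask,
    )


def add_noise_markers(data: Dataset, m: int, seed: int) -> Dataset:
    """Append m noise markers, each entry an independent uniform [0,1] draw."""
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    if m == 0:
        return data.copy()
    rng = np.random.default_rng(int(seed))
    noise = Dataset(
        values=rng.random((data.n, int(m))),
        sample_labels=data.sample_labels.copy(),
        feature_ids=[f"noise{j}" for j in range(int(m))],
        feature_class=["noise-marker"] * int(m),
    )
    return data.concat_features(noise)


def add_uniform_noise(data: Dataset, magnitude: float, seed: int) -> Dataset:
    """Add low-level uniform noise in [0, magnitude) to every observed entry."""
    if magnitude < 0:
        raise ValueError("magnitude must be nonnegative")
    rng = np.random.default_rng(int(seed))
    out = data.copy()
    out.values = out.values + rng.random(out.values.shape) * magnitude
    return out


@dataclass
class RetentionReport:
    """How much of the reference population structure a perturbed dataset keeps."""

    disagreement: float  # Procrustes disparity between centroid configurations
    pct_individuals_homogeneous_ref: float
    pct_individuals_homogeneous_perturbed: float

    @property
    def homogeneity_delta(self) -> float:
        return (
            self.pct_individuals_homogeneous_perturbed
            - self.pct_individuals_homogeneous_ref
        )


def structure_retention(
    data_ref: Dataset, data_perturbed: Dataset, k: int = 2, seed: int = 0
) -> RetentionReport:
    """Fit PCA independently on reference and perturbed datasets and compare
    the top-k centroid configurations (Procrustes) plus cluster homogeneity."""
    if data_ref.n != data_perturbed.n or (
        data_ref.sample_labels != data_perturbed.sample_labels
    ).any():
        raise ValueError("sample labels differ between reference and perturbed data")
    res_ref = PCA(data_ref).fit()
    res_pert = PCA(data_perturbed).fit()
    labels = data_ref.labels_in_order()
    lab_arr = data_ref.sample_labels

    def centroid_config(res, kk):
        return np.vstack(
            [res.scores[np.asarray(lab_arr == lab), :kk].mean(axis=0) for lab in labels]
        )

    kk = min(k, res_ref.r, res_pert.r)
    if kk < k:
        warnings.warn(f"k reduced to available rank {kk}", stacklevel=2)
    dis = configuration_agreement(centroid_config(res_ref, kk), centroid_config(res_pert, kk))
    hom_ref = homogeneity(res_ref.scores[:, : min(2, res_ref.r)], lab_arr, seed=seed)
    hom_pert = homogeneity(res_pert.scores[:, : min(2, res_pert.r)], lab_arr, seed=seed)
    return RetentionReport(
        disagreement=dis,
        pct_individuals_homogeneous_ref=hom_ref.pct_individuals_in_homogeneous,
        pct_individuals_homogeneous_perturbed=hom_pert.pct_individuals_in_homogeneous,
    )
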