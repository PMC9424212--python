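"""Synthetic colour-population model.

Each "population" is a point P in RGB space [0,1]^3; an individual drawn
from it is P + R*N where R is a fresh vector of standard-normal deviates and
N a per-population noise scale (SD).  The three colour coordinates play the
role of markers, so the ground-truth geometry of any cohort is known exactly:
population distances are Euclidean distances between the mean colours.

Noise is additive and values are deliberately NOT clipped to [0,1]: clipping
would halve the noise on boundary components (e.g. the 0 components of Red)
and bias every centroid inward.  A multiplicative reading of the noise term
(P_i * R * N) would collapse all zero components to exactly zero, making
Black a single point and Red/Green indistinguishable on their shared zero
coordinates; it is rejected in favour of the additive model.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ColorSpec",
    "CohortConfig",
    "Dataset",
    "CANONICAL_COLORS",
    "generate_population",
    "generate_cohort",
    "era_spec",
    "child_seed",
]

#: Canonical primary/secondary colour directions (unit patterns of 0s and 1s).
CANONICAL_COLORS: dict[str, tuple[float, float, float]] = {
    "Red": (1.0, 0.0, 0.0),
    "Green": (0.0, 1.0, 0.0),
    "Blue": (0.0, 0.0, 1.0),
    "Cyan": (0.0, 1.0, 1.0),
    "Purple": (1.0, 0.0, 1.0),
    "Yellow": (1.0, 1.0, 0.0),
    "White": (1.0, 1.0, 1.0),
    "Black": (0.0, 0.0, 0.0),
}

DEFAULT_NOISE_SD = 0.01


@dataclass(frozen=True)
class ColorSpec:
    """A named ground-truth point in colour space with a noise SD.

    Parameters
    ----------
    name : str
        Population label.
    mean : sequence of 3 floats in [0, 1]
        The true colour (the population "allele frequencies").
    noise_sd : float, default 0.01
        SD of the additive Gaussian noise applied independently to each
        coordinate of every individual.
    """

    name: str
    mean: tuple[float, float, float]
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        mean = tuple(float(m) for m in self.mean)
        if len(mean) != 3:
            raise ValueError(f"mean must have 3 components, got {len(mean)}")
        if any(not (0.0 <= m <= 1.0) for m in mean):
            raise ValueError(f"mean components must lie in [0,1]: {mean}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "noise_sd", float(self.noise_sd))

    @property
    def mean_array(self) -> np.ndarray:
        return np.asarray(self.mean, dtype=float)

    def plot_color(self) -> tuple[float, float, float]:
        """RGB triple usable directly as a matplotlib colour."""
        return tuple(float(np.clip(m, 0.0, 1.0)) for m in self.mean)


@dataclass(frozen=True)
class CohortConfig:
    """An ordered list of (ColorSpec, n) members plus a root seed."""

    members: tuple[tuple[ColorSpec, int], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        members = tuple((spec, int(n)) for spec, n in self.members)
        if not members:
            raise ValueError("CohortConfig requires at least one member")
        for spec, n in members:
            if n < 1:
                raise ValueError(f"member {spec.name!r} has non-positive n={n}")
        object.__setattr__(self, "members", members)

    @property
    def total_n(self) -> int:
        return sum(n for _, n in self.members)

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=int(seed))

    def with_scaled_n(self, scale: float, minimum: int = 1) -> "CohortConfig":
        """Uniformly rescale all sample sizes (used for reduced-size runs)."""
        members = tuple(
            (spec, max(minimum, int(round(n * scale)))) for spec, n in self.members
        )
        return replace(self, members=members)


@dataclass
class Dataset:
    """Labelled sample x feature matrix — the common currency of the pipeline.

    `missing_mask` marks absent entries (True = missing); `feature_class`
    tags each column as one of ``color-component``, ``window-snp``,
    ``noise-marker`` or ``genotype``.  Observed genotype dosages must be in
    {0, 1, 2}.
    """

    values: np.ndarray
    sample_labels: np.ndarray
    feature_ids: list[str]
    feature_class: list[str]
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        self.sample_labels = np.asarray(self.sample_labels, dtype=object)
        if self.sample_labels.shape != (n,):
            raise ValueError(
                f"sample_labels has shape {self.sample_labels.shape}, expected ({n},)"
            )
        self.feature_ids = list(self.feature_ids)
        self.feature_class = list(self.feature_class)
        if len(self.feature_ids) != p or len(self.feature_class) != p:
            raise ValueError("feature metadata length does not match p")
        if self.missing_mask is None:
            self.missing_mask = np.zeros((n, p), dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (n, p):
                raise ValueError("missing_mask shape mismatch")
        if p > 0 and bool(self.missing_mask.all(axis=1).any()):
            bad = int(np.flatnonzero(self.missing_mask.all(axis=1))[0])
            raise ValueError(f"sample {bad} has no observed feature")
        geno = [j for j, c in enumerate(self.feature_class) if c == "genotype"]
        if geno:
            sub = self.values[:, geno]
            obs = ~self.missing_mask[:, geno]
            vals = sub[obs]
            if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
                raise ValueError("observed genotype dosages must be in {0,1,2}")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def labels_in_order(self) -> list[str]:
        """Unique population labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.sample_labels:
            seen.setdefault(str(lab), None)
        return list(seen)

    def label_counts(self) -> dict[str, int]:
        return {lab: int((self.sample_labels == lab).sum()) for lab in self.labels_in_order()}

    def centroid(self, label: str) -> np.ndarray:
        rows = self.sample_labels == label
        if not rows.any():
            raise KeyError(f"unknown population label {label!r}")
        if self.missing_mask[rows].any():
            masked = np.where(self.missing_mask[rows], np.nan, self.values[rows])
            return np.nanmean(masked, axis=0)
        return self.values[rows].mean(axis=0)

    def centroids(self) -> tuple[list[str], np.ndarray]:
        labels = self.labels_in_order()
        return labels, np.vstack([self.centroid(lab) for lab in labels])

    def subset_features(self, keep: Sequence[int] | np.ndarray) -> "Dataset":
        keep = np.asarray(keep, dtype=int)
        return Dataset(
            values=self.values[:, keep].copy(),
            sample_labels=self.sample_labels.copy(),
            feature_ids=[self.feature_ids[j] for j in keep],
            feature_class=[self.feature_class[j] for j in keep],
            missing_mask=self.missing_mask[:, keep].copy(),
        )

    def subset_samples(self, keep: Sequence[int] | np.ndarray) -> "Dataset":
        keep = np.asarray(keep, dtype=int)
        return Dataset(
            values=self.values[keep].copy(),
            sample_labels=self.sample_labels[keep].copy(),
            feature_ids=list(self.feature_ids),
            feature_class=list(self.feature_class),
            missing_mask=self.missing_mask[keep].copy(),
        )

    def features_of_class(self, cls: str) -> "Dataset":
        keep = [j for j, c in enumerate(self.feature_class) if c == cls]
        if not keep:
            raise KeyError(f"no features of class {cls!r}")
        return self.subset_features(keep)

    def concat_features(self, other: "Dataset") -> "Dataset":
        if other.n != self.n:
            raise ValueError("sample counts differ")
        return Dataset(
            values=np.hstack([self.values, other.values]),
            sample_labels=self.sample_labels.copy(),
            feature_ids=self.feature_ids + other.feature_ids,
            feature_class=self.feature_class + other.feature_class,
            missing_mask=np.hstack([self.missing_mask, other.missing_mask]),
        )

    def copy(self) -> "Dataset":
        return Dataset(
            values=self.values.copy(),
            sample_labels=self.sample_labels.copy(),
            feature_ids=list(self.feature_ids),
            feature_class=list(self.feature_class),
            missing_mask=self.missing_mask.copy(),
        )

    # -- text round-trip -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        vals = np.where(self.missing_mask, np.nan, self.values)
        df = pd.DataFrame(vals, columns=self.feature_ids)
        df.insert(0, "label", [str(x) for x in self.sample_labels])
        df.insert(0, "sample_id", [f"s{i}" for i in range(self.n)])
        return df

    def to_tsv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path_or_buf, feature_class: str = "color-component") -> "Dataset":
        df = pd.read_csv(path_or_buf, sep="\t")
        feats = [c for c in df.columns if c not in ("sample_id", "label")]
        vals = df[feats].to_numpy(dtype=float)
        mask = np.isnan(vals)
        return cls(
            values=np.where(mask, 0.0, vals),
            sample_labels=df["label"].to_numpy(dtype=object),
            feature_ids=feats,
            feature_class=[feature_class] * len(feats),
            missing_mask=mask,
        )

    def to_tsv_string(self) -> str:
        buf = io.StringIO()
        self.to_tsv(buf)
        return buf.getvalue()


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def child_seed(root_seed: int, index: int, name: str) -> int:
    """Deterministic per-population seed derived from the cohort root seed.

    Hashing (index, name) rather than advancing one stream means appending a
    population to a cohort never changes the draws of earlier populations,
    which keeps seed-sensitivity experiments controllable.
    """
    digest = hashlib.blake2b(
        f"{int(root_seed)}:{int(index)}:{name}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def generate_population(spec: ColorSpec, n: int, seed: int) -> Dataset:
    """Draw n individuals from a colour population.

    Row i is ``spec.mean + R_i * spec.noise_sd`` with R_i a fresh 3-vector of
    standard-normal deviates; bit-identical for identical (spec, n, seed).
    """
    n = int(n)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(int(seed))
    values = spec.mean_array[None, :] + rng.standard_normal((n, 3)) * spec.noise_sd
    return Dataset(
        values=values,
        sample_labels=np.array([spec.name] * n, dtype=object),
        feature_ids=["R", "G", "B"],
        feature_class=["color-component"] * 3,
    )


def generate_cohort(config: CohortConfig) -> Dataset:
    """Concatenate per-population draws in member order.

    Each member gets a child seed derived from ``config.seed`` via
    :func:`child_seed`, so members are independent and stable under cohort
    edits downstream of them.
    """
    blocks = [
        generate_population(spec, n, child_seed(config.seed, i, spec.name))
        for i, (spec, n) in enumerate(config.members)
    ]
    out = blocks[0]
    for block in blocks[1:]:
        out = Dataset(
            values=np.vstack([out.values, block.values]),
            sample_labels=np.concatenate([out.sample_labels, block.sample_labels]),
            feature_ids=out.feature_ids,
            feature_class=out.feature_class,
            missing_mask=np.vstack([out.missing_mask, block.missing_mask]),
        )
    return out


_ERA_PARAMS = {"ancient": (0.95, 0.05), "modern": (0.6, 0.02)}


def era_spec(base_name: str, era: str) -> ColorSpec:
    """Ancient/modern variant of a canonical colour.

    Ancient populations are modelled as brighter and more diverse (nonzero
    components set to 0.95, SD 0.05); modern ones darker and tighter (0.6,
    SD 0.02).  Zero components stay 0, and the era SD applies to all three
    coordinates.
    """
    if era not in _ERA_PARAMS:
        raise ValueError(f"era must be 'ancient' or 'modern', got {era!r}")
    if base_name not in CANONICAL_COLORS:
        raise KeyError(f"unknown canonical colour {base_name!r}")
    level, sd = _ERA_PARAMS[era]
    base = CANONICAL_COLORS[base_name]
    mean = tuple(level if b != 0 else 0.0 for b in base)
    return ColorSpec(name=f"{era} {base_name}", mean=mean, noise_sd=sd)


def cohort_from_pairs(
    pairs: Iterable[tuple[str, Sequence[float], int]],
    seed: int,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> CohortConfig:
    """Convenience builder: (name, mean, n) triples -> CohortConfig."""
    members = tuple(
        (ColorSpec(name, tuple(mean), noise_sd), n) for name, mean, n in pairs
    )
    return CohortConfig(members=members, seed=seed)
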