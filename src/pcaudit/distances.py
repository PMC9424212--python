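"""Distance-distortion metrics: true-space vs reduced-space geometry.

Because centring plus an orthonormal rotation preserves Euclidean geometry,
pairwise distances over ALL components equal original-space distances; any
discrepancy over the top-k components is pure truncation distortion, and a
truncated projection can only contract distances.  These two facts are the
oracles behind every report here.

pc_distance is always computed on raw (unrescaled) scores.  Min-max
normalisation of the two distance columns (independently) is available for
x = y scatter comparisons.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import procrustes

from pcaudit.colors import Dataset
from pcaudit.pca import PCAResults

__all__ = [
    "DistanceReport",
    "centroid_distances",
    "individual_pair_distances",
    "normalize_report",
    "distortion_summary",
    "configuration_agreement",
]


@dataclass
class DistanceReport:
    """Per-pair records of true-space vs top-k score-space distance.

    ``table`` columns: entity_a, entity_b, kind (population | individual),
    true_distance, pc_distance, and after normalisation true_norm / pc_norm.
    """

    table: pd.DataFrame
    k: int
    normalized: bool = False

    def __post_init__(self) -> None:
        required = {"entity_a", "entity_b", "kind", "true_distance", "pc_distance"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"report table missing columns: {sorted(missing)}")
        if (self.table["true_distance"] < 0).any() or (self.table["pc_distance"] < 0).any():
            raise ValueError("distances must be nonnegative")

    def to_tsv(self, path_or_buf) -> None:
        self.table.to_csv(path_or_buf, sep="\t", index=False, float_format="%.12g")


def _pair_table(names_a, names_b, kind, true_d, pc_d) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "entity_a": names_a,
            "entity_b": names_b,
            "kind": kind,
            "true_distance": np.asarray(true_d, dtype=float),
            "pc_distance": np.asarray(pc_d, dtype=float),
        }
    )


def centroid_distances(data: Dataset, results: PCAResults, k: int) -> DistanceReport:
    """Population-pair Euclidean distances between label centroids, in the
    original feature space and in the top-k score space."""
    labels = data.labels_in_order()
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    cent_true = {lab: data.centroid(lab) for lab in labels}
    scores = results.scores[:, :k]
    cent_pc = {
        lab: scores[np.asarray(data.sample_labels == lab)].mean(axis=0) for lab in labels
    }
    a, b, td, pd_ = [], [], [], []
    for la, lb in itertools.combinations(labels, 2):
        a.append(la)
        b.append(lb)
        td.append(float(np.linalg.norm(cent_true[la] - cent_true[lb])))
        pd_.append(float(np.linalg.norm(cent_pc[la] - cent_pc[lb])))
    return DistanceReport(table=_pair_table(a, b, "population", td, pd_), k=k)


def individual_pair_distances(
    data: Dataset, results: PCAResults, k: int, n_pairs: int, seed: int
) -> DistanceReport:
    """Distances for n_pairs distinct random individual pairs (seeded).

    If n_pairs exceeds the number of distinct pairs it is capped with a
    warning.
    """
    n = data.n
    if n < 2:
        raise ValueError("need at least two samples")
    ii, jj = np.triu_indices(n, 1)
    total = ii.shape[0]
    if n_pairs > total:
        warnings.warn(
            f"n_pairs={n_pairs} exceeds the {total} distinct pairs; capped",
            stacklevel=2,
        )
        n_pairs = total
    rng = np.random.default_rng(int(seed))
    sel = rng.choice(total, size=int(n_pairs), replace=False)
    ii, jj = ii[sel], jj[sel]
    diffs_true = data.values[ii] - data.values[jj]
    scores = results.scores[:, :k]
    diffs_pc = scores[ii] - scores[jj]
    return DistanceReport(
        table=_pair_table(
            [f"s{i}" for i in ii],
            [f"s{j}" for j in jj],
            "individual",
            np.linalg.norm(diffs_true, axis=1),
            np.linalg.norm(diffs_pc, axis=1),
        ),
        k=k,
    )


def normalize_report(report: DistanceReport) -> DistanceReport:
    """Min-max normalise true_distance and pc_distance independently to [0,1]."""
    table = report.table.copy()
    for col, out in (("true_distance", "true_norm"), ("pc_distance", "pc_norm")):
        vals = table[col].to_numpy()
        lo, hi = float(vals.min()), float(vals.max())
        if hi <= lo:
            raise ValueError(f"column {col} is constant; min-max normalisation undefined")
        table[out] = (vals - lo) / (hi - lo)
    return replace(report, table=table, normalized=True)


@dataclass
class DistortionSummary:
    """Summary of how faithfully pair distances survive truncation."""

    n_pairs: int
    frac_within: float  # fraction of pairs with |pc - true| <= tolerance
    tolerance: float
    max_distortion: float
    worst_pair: tuple[str, str]
    per_entity_worst: dict[str, float] = field(default_factory=dict)

    @property
    def pct_within(self) -> float:
        return 100.0 * self.frac_within


def distortion_summary(report: DistanceReport, tolerance: float = 0.05) -> DistortionSummary:
    """Fraction of "correctly projected" pairs (|pc - true| <= tolerance),
    max distortion and per-entity worst pair.  Uses normalised columns when
    present, raw distances otherwise."""
    t = report.table
    if report.normalized:
        true_v, pc_v = t["true_norm"].to_numpy(), t["pc_norm"].to_numpy()
    else:
        true_v, pc_v = t["true_distance"].to_numpy(), t["pc_distance"].to_numpy()
    dist = np.abs(pc_v - true_v)
    i_worst = int(np.argmax(dist))
    per_entity: dict[str, float] = {}
    ea = t["entity_a"].to_numpy()
    eb = t["entity_b"].to_numpy()
    for pos in range(len(t)):
        d = float(dist[pos])
        for e in (str(ea[pos]), str(eb[pos])):
            per_entity[e] = max(per_entity.get(e, 0.0), d)
    return DistortionSummary(
        n_pairs=len(t),
        frac_within=float((dist <= tolerance).mean()),
        tolerance=float(tolerance),
        max_distortion=float(dist[i_worst]),
        worst_pair=(str(t.iloc[i_worst]["entity_a"]), str(t.iloc[i_worst]["entity_b"])),
        per_entity_worst=per_entity,
    )


def configuration_agreement(scores_a: np.ndarray, scores_b: np.ndarray) -> float:
    """Procrustes disagreement between two point configurations.

    Both configurations are centred, scaled to unit norm and optimally
    rotated/reflected onto each other; the returned disparity is the
    residual sum of squares (0 = identical geometry).  Reflections (axis
    flips) are absorbed, so sign-flipped scores agree perfectly.
    """
    a = np.atleast_2d(np.asarray(scores_a, dtype=float))
    b = np.atleast_2d(np.asarray(scores_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if np.allclose(a - a.mean(axis=0), 0) and np.allclose(b - b.mean(axis=0), 0):
        return 0.0
    _, _, disparity = procrustes(a, b)
    return float(disparity)
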