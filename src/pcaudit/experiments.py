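"""Registry of runnable synthetic test cases and the experiment driver.

Every in-scope scenario of the evaluation framework is declared here as an
:class:`ExperimentSpec`: a cohort configuration (colour populations and
sample sizes), an ordered list of pipeline stages, and a seed.  Scenarios
whose published sample sizes are given only as ranges carry
``ambiguous=True`` plus a note quoting the pinned assignment, so the choice
is auditable.

``run_experiment`` executes the stages against a context, collects score
tables, distance/cluster reports and summary metrics, and (optionally)
writes a reproducible artifact bundle: TSV tables, a scatter plot of the
top two PCs drawn in the populations' true colours, and a manifest
recording config, seed and package version.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

import pcaudit
from pcaudit.clustering import homogeneity
from pcaudit.colors import (
    CANONICAL_COLORS,
    CohortConfig,
    ColorSpec,
    Dataset,
    era_spec,
    generate_cohort,
)
from pcaudit.distances import (
    centroid_distances,
    configuration_agreement,
    distortion_summary,
    individual_pair_distances,
    normalize_report,
)
from pcaudit.gwas import CaseControlDesign, adjustment_experiment
from pcaudit.pca import PCA
from pcaudit.robustness import (
    add_noise_markers,
    add_uniform_noise,
    collapse_windows,
    expand_windows,
    inject_missingness,
    structure_retention,
)

__all__ = [
    "ExperimentSpec",
    "ExperimentResult",
    "build_registry",
    "run_experiment",
    "seed_sensitivity",
    "StabilityReport",
]


@dataclass(frozen=True)
class ExperimentSpec:
    id: str
    description: str
    cohort: CohortConfig
    stages: tuple[tuple[str, dict], ...]
    projected_cohort: CohortConfig | None = None
    ambiguous: bool = False
    note: str = ""

    @property
    def seed(self) -> int:
        return self.cohort.seed


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    data: Dataset
    context: dict[str, Any] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def pca(self):
        return self.context.get("pca")


# ---------------------------------------------------------------------------
# stage registry
# ---------------------------------------------------------------------------

STAGES: dict[str, Callable] = {}


def stage(name: str):
    def deco(fn):
        STAGES[name] = fn
        return fn

    return deco


@stage("pca")
def _stage_pca(res: ExperimentResult, normalize: bool = False, **_) -> None:
    res.context["pca"] = PCA(res.context["data"], normalize=normalize).fit()
    res.metrics["explained_pct_top2"] = res.context["pca"].explained_percent(
        min(2, res.context["pca"].r), digits=None
    )
    res.tables["scores"] = res.context["pca"].scores_frame()


@stage("explained")
def _stage_explained(res: ExperimentResult, k: int = 2, **_) -> None:
    res.metrics[f"explained_pct_k{k}"] = res.context["pca"].explained_percent(k, digits=None)


@stage("centroid_distances")
def _stage_cdist(res: ExperimentResult, k: int = 2, **_) -> None:
    rep = centroid_distances(res.context["data"], res.context["pca"], k=k)
    res.context["distance_report"] = rep
    res.tables[f"centroid_distances_k{k}"] = rep.table


@stage("individual_distances")
def _stage_idist(res: ExperimentResult, k: int = 2, n_pairs: int = 2000, **_) -> None:
    rep = individual_pair_distances(
        res.context["data"], res.context["pca"], k=k, n_pairs=n_pairs, seed=res.spec.seed
    )
    res.context["distance_report"] = rep
    res.tables[f"individual_distances_k{k}"] = rep.table


@stage("normalize_distances")
def _stage_norm(res: ExperimentResult, **_) -> None:
    rep = normalize_report(res.context["distance_report"])
    res.context["distance_report"] = rep


@stage("distortion")
def _stage_distortion(res: ExperimentResult, tolerance: float = 0.05, **_) -> None:
    s = distortion_summary(res.context["distance_report"], tolerance=tolerance)
    res.metrics["pct_pairs_within_tolerance"] = s.pct_within
    res.metrics["max_distortion"] = s.max_distortion


@stage("cluster")
def _stage_cluster(res: ExperimentResult, K="auto", restarts: int = 20, **_) -> None:
    pca = res.context["pca"]
    rep = homogeneity(
        pca.scores[:, : min(2, pca.r)],
        res.context["data"].sample_labels,
        K=K,
        seed=res.spec.seed,
        restarts=restarts,
    )
    res.context["cluster_report"] = rep
    res.tables["clusters"] = rep.to_frame()
    res.metrics["pct_homogeneous_clusters"] = rep.pct_homogeneous_clusters
    res.metrics["pct_individuals_in_homogeneous"] = rep.pct_individuals_in_homogeneous


@stage("expand_windows")
def _stage_expand(res: ExperimentResult, window_size: int = 200, **_) -> None:
    data, wmap = expand_windows(res.context["data"], window_size=window_size)
    res.context["data"] = data
    res.context["window_map"] = wmap


@stage("inject_missingness")
def _stage_missing(res: ExperimentResult, rate: float, **_) -> None:
    res.context["data"] = inject_missingness(res.context["data"], rate, seed=res.spec.seed + 17)


@stage("collapse_windows")
def _stage_collapse(res: ExperimentResult, **_) -> None:
    res.context["data"] = collapse_windows(res.context["data"], res.context["window_map"])


@stage("add_noise_markers")
def _stage_noise_markers(res: ExperimentResult, m: int, **_) -> None:
    res.context["data"] = add_noise_markers(res.context["data"], m, seed=res.spec.seed + 29)


@stage("add_uniform_noise")
def _stage_uniform_noise(res: ExperimentResult, magnitude: float = 0.1, **_) -> None:
    res.context["data"] = add_uniform_noise(
        res.context["data"], magnitude, seed=res.spec.seed + 31
    )


@stage("retention")
def _stage_retention(res: ExperimentResult, k: int = 2, **_) -> None:
    rep = structure_retention(res.data, res.context["data"], k=k, seed=res.spec.seed)
    res.metrics["retention_disagreement"] = rep.disagreement
    res.metrics["homogeneity_delta"] = rep.homogeneity_delta


@stage("project")
def _stage_project(res: ExperimentResult, k: int = 2, rescale: bool = True, **_) -> None:
    """Generate the held-out cohort and project it one sample at a time."""
    if res.spec.projected_cohort is None:
        raise ValueError(f"experiment {res.spec.id} has no projected cohort")
    proj_data = generate_cohort(res.spec.projected_cohort)
    pca = res.context["pca"]
    scores = pca.project_dataset(proj_data, k=k, rescale=rescale)
    df = pd.DataFrame(scores, columns=[f"PC{j + 1}" for j in range(k)])
    df.insert(0, "label", [str(x) for x in proj_data.sample_labels])
    res.tables["projected_scores"] = df
    res.context["projected_data"] = proj_data
    res.context["projected_scores"] = scores
    # overlap of shared-population centroids, base vs projected
    base_labels = res.context["data"].labels_in_order()
    shared = [lab for lab in proj_data.labels_in_order() if lab in base_labels]
    if len(shared) >= 3:
        base_cent = np.vstack(
            [
                pca.scores[np.asarray(res.context["data"].sample_labels == lab), :k].mean(axis=0)
                for lab in shared
            ]
        )
        proj_cent = np.vstack(
            [scores[np.asarray(proj_data.sample_labels == lab)].mean(axis=0) for lab in shared]
        )
        res.metrics["projection_centroid_disagreement"] = configuration_agreement(
            base_cent, proj_cent
        )


@stage("separate_pca")
def _stage_separate_pca(res: ExperimentResult, **_) -> None:
    """Fit an independent PCA on the held-out cohort (results presented
    jointly with the base fit, without any projection)."""
    if res.spec.projected_cohort is None:
        raise ValueError(f"experiment {res.spec.id} has no second cohort")
    second = generate_cohort(res.spec.projected_cohort)
    pca2 = PCA(second).fit()
    res.context["second_data"] = second
    res.context["second_pca"] = pca2
    res.tables["second_scores"] = pca2.scores_frame()


@stage("gwas")
def _stage_gwas(res: ExperimentResult, replicates: int = 3, **design_kw) -> None:
    design = CaseControlDesign(seed=res.spec.seed, **design_kw)
    comp = adjustment_experiment(res.context["data"], design, replicates=replicates)
    res.tables["gwas"] = comp.table
    res.tables["gwas_aggregate"] = comp.aggregate()
    agg = comp.aggregate().set_index("n_pcs")
    for q in design.adjust_pcs:
        res.metrics[f"tp_median_pcs{q}"] = float(agg.loc[q, "tp_median"])
        res.metrics[f"fp_median_pcs{q}"] = float(agg.loc[q, "fp_median"])
    res.context["gwas"] = comp


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_experiment(
    spec: ExperimentSpec,
    out_dir: str | Path | None = None,
    scale: float = 1.0,
    plot: bool = False,
) -> ExperimentResult:
    """Execute the stages of a registered experiment.

    ``scale`` uniformly rescales all cohort sample sizes (reduced-size runs
    for continuous testing).  With ``out_dir`` set, score tables, reports, a
    manifest and optionally a scatter plot are written; outputs are
    byte-identical for a fixed seed.
    """
    cohort = spec.cohort if scale == 1.0 else spec.cohort.with_scaled_n(scale)
    data = generate_cohort(cohort)
    res = ExperimentResult(spec=spec, data=data)
    res.context["data"] = data
    for name, params in spec.stages:
        if name not in STAGES:
            raise KeyError(f"stage {name!r} of experiment {spec.id} is not registered")
        try:
            STAGES[name](res, **params)
        except Exception as exc:
            if out_dir is not None:
                _write_bundle(res, Path(out_dir), plot=False)
            raise RuntimeError(f"experiment {spec.id}: stage {name!r} failed") from exc
    if out_dir is not None:
        _write_bundle(res, Path(out_dir), plot=plot)
    return res


def _write_bundle(res: ExperimentResult, out_dir: Path, plot: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, table in res.tables.items():
        table.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, float_format="%.12g")
    manifest = {
        "experiment": res.spec.id,
        "description": res.spec.description,
        "seed": res.spec.seed,
        "ambiguous": res.spec.ambiguous,
        "note": res.spec.note,
        "cohort": [
            {"name": s.name, "mean": list(s.mean), "noise_sd": s.noise_sd, "n": n}
            for s, n in res.spec.cohort.members
        ],
        "stages": [[name, params] for name, params in res.spec.stages],
        "metrics": res.metrics,
        "pcaudit_version": pcaudit.__version__,
        "python": platform.python_version(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    if plot and "pca" in res.context:
        plot_scores(res, out_dir / "scores.png")


def plot_scores(res: ExperimentResult, path: str | Path) -> None:
    """Top-2-PC scatter with samples drawn in their true colours — the
    ground-truth legend of the framework."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pca = res.context["pca"]
    color_of = {s.name: s.plot_color() for s, _ in res.spec.cohort.members}
    if res.spec.projected_cohort is not None:
        color_of.update({s.name: s.plot_color() for s, _ in res.spec.projected_cohort.members})
    fig, ax = plt.subplots(figsize=(5, 5))
    data = res.context["data"]
    k = min(2, pca.r)
    for lab in data.labels_in_order():
        rows = np.asarray(data.sample_labels == lab)
        ax.scatter(
            pca.scores[rows, 0],
            pca.scores[rows, 1] if k > 1 else 0 * pca.scores[rows, 0],
            s=18,
            color=color_of.get(lab, "grey"),
            edgecolors="k",
            linewidths=0.3,
            label=lab,
        )
    if "projected_scores" in res.context:
        pdata = res.context["projected_data"]
        pscores = res.context["projected_scores"]
        for lab in pdata.labels_in_order():
            rows = np.asarray(pdata.sample_labels == lab)
            ax.scatter(
                pscores[rows, 0],
                pscores[rows, 1],
                s=26,
                marker="s",
                color=color_of.get(lab, "grey"),
                edgecolors="k",
                linewidths=0.3,
            )
    ax.set_xlabel(f"PC1 ({100 * pca.explained_fraction[0]:.0f}%)")
    if k > 1:
        ax.set_ylabel(f"PC2 ({100 * pca.explained_fraction[1]:.0f}%)")
    ax.set_title(res.spec.id)
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# seed sensitivity
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    """Per-seed centroid configurations with pairwise Procrustes disagreement."""

    seeds: list[int]
    disagreement: pd.DataFrame  # n_seeds x n_seeds
    nearest_neighbor: pd.DataFrame  # seed, reference, nearest population
    configs: dict[int, np.ndarray]

    def n_distinct_orderings(self) -> int:
        return int(self.nearest_neighbor["nearest"].nunique())


def seed_sensitivity(
    spec: ExperimentSpec,
    n_seeds: int,
    k: int = 2,
    reference_label: str = "Black",
) -> StabilityReport:
    """Re-run cohort generation + PCA varying only the seed, and compare the
    resulting top-k centroid configurations and the nearest neighbour of the
    reference population."""
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    seeds = [spec.seed + i for i in range(n_seeds)]
    configs: dict[int, np.ndarray] = {}
    nn_rows = []
    labels_order: list[str] | None = None
    for s in seeds:
        data = generate_cohort(spec.cohort.with_seed(s))
        pca = PCA(data).fit()
        labels_order = data.labels_in_order()
        kk = min(k, pca.r)
        cent = np.vstack(
            [
                pca.scores[np.asarray(data.sample_labels == lab), :kk].mean(axis=0)
                for lab in labels_order
            ]
        )
        configs[s] = cent
        if reference_label in labels_order:
            i_ref = labels_order.index(reference_label)
            d = np.linalg.norm(cent - cent[i_ref], axis=1)
            d[i_ref] = np.inf
            nn_rows.append(
                {"seed": s, "reference": reference_label, "nearest": labels_order[int(np.argmin(d))]}
            )
    mat = np.zeros((n_seeds, n_seeds))
    for i, si in enumerate(seeds):
        for j, sj in enumerate(seeds):
            if i < j:
                mat[i, j] = mat[j, i] = configuration_agreement(configs[si], configs[sj])
    return StabilityReport(
        seeds=seeds,
        disagreement=pd.DataFrame(mat, index=seeds, columns=seeds),
        nearest_neighbor=pd.DataFrame(nn_rows),
        configs=configs,
    )


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def _spec(name: str, sd: float = 0.01) -> ColorSpec:
    return ColorSpec(name, CANONICAL_COLORS[name], noise_sd=sd)


def _c(name: str, mean, sd: float = 0.01) -> ColorSpec:
    return ColorSpec(name, tuple(mean), noise_sd=sd)


def _cohort(members, seed) -> CohortConfig:
    return CohortConfig(members=tuple(members), seed=seed)


def build_registry(seed: int = 0) -> dict[str, ExperimentSpec]:
    """All in-scope synthetic scenarios, keyed by their figure tag."""
    reg: dict[str, ExperimentSpec] = {}

    def add(spec: ExperimentSpec) -> None:
        reg[spec.id] = spec

    pca_dist = (("pca", {}), ("explained", {"k": 2}), ("centroid_distances", {"k": 2}))
    pca_cluster = (("pca", {}), ("cluster", {}))

    # --- near-perfect simplex -------------------------------------------
    simplex = [(_spec(n), 1) for n in ("Red", "Green", "Blue", "Black")]
    add(
        ExperimentSpec(
            "fig1",
            "Near-perfect case: one sample each of Red/Green/Blue/Black",
            _cohort(simplex, seed),
            pca_dist,
        )
    )
    add(
        ExperimentSpec(
            "fig1D",
            "Simplex with all sample sizes evenly increased to 100",
            _cohort([(_spec(n), 100) for n in ("Red", "Green", "Blue", "Black")], seed),
            pca_dist,
        )
    )

    # --- uneven sample sizes (primaries + Black) ------------------------
    fig4_sizes = {
        "fig4A": (10, 10, 10, 200),
        "fig4B": (10, 10, 5, 200),
        "fig4C": (10, 200, 50, 200),
        "fig4D": (25, 50, 50, 200),
        "fig4E": (300, 200, 300, 300),
        "fig4F": (1000, 2000, 300, 2000),
    }
    for tag, (nr, ng, nb, nk) in fig4_sizes.items():
        members = [
            (_spec("Red"), nr),
            (_spec("Green"), ng),
            (_spec("Blue"), nb),
            (_spec("Black"), nk),
        ]
        add(
            ExperimentSpec(
                tag,
                "Uneven sample sizes distort the primaries/Black geometry",
                _cohort(members, seed),
                pca_dist,
            )
        )

    # --- admixed Cyan ----------------------------------------------------
    fig8_sizes = {
        "fig8A": (100, 100, 100, 200, 100),
        "fig8B": (100, 100, 100, 500, 500),
        "fig8C": (100, 33, 400, 400, 33),
        "fig8D": (100, 33, 33, 100, 33),
    }
    for tag, (nr, ng, nb, nk, nc) in fig8_sizes.items():
        members = [
            (_spec("Red"), nr),
            (_spec("Green"), ng),
            (_spec("Blue"), nb),
            (_spec("Black"), nk),
            (_spec("Cyan"), nc),
        ]
        add(
            ExperimentSpec(
                tag,
                "Primary colours plus admixed Cyan under varied sampling",
                _cohort(members, seed),
                pca_dist,
            )
        )

    # --- multiple mixed colours -----------------------------------------
    mixed = ["Red", "Green", "Blue", "Cyan", "Purple", "Yellow", "Black"]
    pink = _c("Pink", (1, 0.5, 0.5))
    mixed_specs = [_spec(n) for n in mixed] + [pink]
    fig10_sizes = {
        "fig10A": [50] * 8,
        "fig10B": [50, 10, 50, 10, 50, 10, 50, 10],
        "fig10C": [50, 5, 100, 25, 50, 5, 100, 25],
        "fig10D": [100, 25, 50, 5, 25, 100, 5, 50],
    }
    for tag, sizes in fig10_sizes.items():
        add(
            ExperimentSpec(
                tag,
                "Primaries plus multiple mixed colours",
                _cohort(list(zip(mixed_specs, sizes)), seed),
                pca_dist,
                ambiguous=tag in ("fig10C", "fig10D"),
                note="published sizes given only as the set {50, 5, 100, 25}; "
                "assignment pinned here" if tag in ("fig10C", "fig10D") else "",
            )
        )
    add(
        ExperimentSpec(
            "fig10E",
            "Distance-distortion scatter for the fig10D cohort",
            _cohort(list(zip(mixed_specs, fig10_sizes["fig10D"])), seed),
            (
                ("pca", {}),
                ("centroid_distances", {"k": 2}),
                ("distortion", {"tolerance": 0.05}),
            ),
            ambiguous=True,
            note="same pinned sizes as fig10D",
        )
    )

    # --- seed sensitivity ------------------------------------------------
    secondary = [(_spec(n), 50) for n in ("Cyan", "Purple", "Yellow", "Black")]
    add(
        ExperimentSpec(
            "fig11",
            "Seed sensitivity of secondary colours plus Black (n_all = 50)",
            _cohort(secondary, seed),
            pca_dist,
        )
    )
    add(
        ExperimentSpec(
            "fig11W",
            "Seed sensitivity with White added",
            _cohort(secondary + [(_spec("White"), 50)], seed),
            pca_dist,
            ambiguous=True,
            note="published caption lists White as [1,1,0] (Yellow's value); "
            "pinned to the canonical White [1,1,1]",
        )
    )

    # --- GWAS-style reference mismatch ----------------------------------
    test_cyan = _c("test Cyan", (0, 1, 1), sd=0.17)
    refs13 = [
        _c("Yellow", (1, 1, 0), 0.05),
        _c("light Red", (1, 0, 0.5), 0.05),
        _c("Purple", (1, 0, 1), 0.05),
        _c("dark Purple", (0.5, 0, 0.5), 0.05),
        _c("Black", (0, 0, 0), 0.05),
        _c("dark Green", (0, 0.5, 0), 0.05),
        _c("Green", (0, 1, 0), 0.05),
        _c("Blue", (0, 0, 1), 0.05),
    ]
    add(
        ExperimentSpec(
            "fig13A",
            "True distribution of the heterogeneous test population",
            _cohort([(test_cyan, 1000)], seed),
            (("pca", {}),),
        )
    )
    add(
        ExperimentSpec(
            "fig13B",
            "Test population with eight mismatched reference populations",
            _cohort([(test_cyan, 1000)] + [(s, 250) for s in refs13], seed),
            pca_cluster,
            ambiguous=True,
            note="published caption lists Blue as [1,0,0]; pinned to canonical [0,0,1]",
        )
    )
    add(
        ExperimentSpec(
            "fig13C",
            "Test population with the Blue reference alone",
            _cohort([(test_cyan, 1000), (_c("Blue", (0, 0, 1), 0.05), 250)], seed),
            pca_cluster,
        )
    )
    refs13d = [refs13[0], refs13[2], refs13[5], _c("Cyan", (0, 1, 1), 0.05), refs13[4]]
    add(
        ExperimentSpec(
            "fig13D",
            "Test population with five references including matching Cyan",
            _cohort([(test_cyan, 1000)] + [(s, 250) for s in refs13d], seed),
            pca_cluster,
            ambiguous=True,
            note="published caption names only 'five even-sized reference populations "
            "including Cyan'; the other four pinned here",
        )
    )

    # --- projections -----------------------------------------------------
    base17 = [
        (_c("Red", (1, 0, 0), 0.02), 200),
        (_c("Green", (0, 1, 0), 0.02), 10),
        (_c("Blue", (0, 0, 1), 0.02), 200),
        (_c("Purple", (1, 0, 1), 0.02), 10),
    ]
    proj17 = [
        (_c("Red", (1, 0.1, 0.1), 0.02), 200),
        (_c("Green", (0.1, 1, 0.1), 0.02), 200),
        (_c("Blue", (0.1, 0.1, 1), 0.02), 10),
        (_c("Purple", (1, 0.1, 1), 0.02), 10),
    ]
    add(
        ExperimentSpec(
            "fig17A",
            "Projection with matching populations and varied sample sizes",
            _cohort(base17, seed),
            (("pca", {}), ("project", {"k": 2})),
            projected_cohort=_cohort(proj17, seed + 1000),
        )
    )
    fig17_rest = {
        "fig17B": (
            [(_c("Red", (1, 0, 0), 0.02), 100), (_c("Green", (0, 1, 0), 0.02), 150),
             (_c("Blue", (0, 0, 1), 0.02), 50), (_c("Black", (0, 0, 0), 0.02), 100)],
            [(_c("Cyan", (0, 1, 1), 0.02), 100), (_c("Purple", (1, 0, 1), 0.02), 50),
             (_c("Yellow", (1, 1, 0), 0.02), 150)],
        ),
        "fig17C": (
            [(_c("Red", (1, 0, 0), 0.02), 300), (_c("Cyan", (0, 1, 1), 0.02), 20),
             (_c("Grey", (0.5, 0.5, 0.5), 0.02), 100)],
            [(_c("Green", (0, 1, 0), 0.02), 10), (_c("Blue", (0, 0, 1), 0.02), 300),
             (_c("White", (1, 1, 1), 0.02), 50)],
        ),
        "fig17D": (
            [(_c("light Green", (1, 0.2, 1), 0.02), 100), (_c("Yellow", (1, 1, 0), 0.02), 50),
             (_c("Black", (0, 0, 0), 0.02), 200)],
            [(_c("Red", (1, 0, 0), 0.02), 30), (_c("Grey", (0.5, 0.5, 0.5), 0.02), 150),
             (_c("Purple", (1, 0, 1), 0.02), 60)],
        ),
    }
    for tag, (base, proj) in fig17_rest.items():
        add(
            ExperimentSpec(
                tag,
                "Projection with unique populations in the two cohorts",
                _cohort(base, seed),
                (("pca", {}), ("project", {"k": 2})),
                projected_cohort=_cohort(proj, seed + 1000),
                ambiguous=True,
                note="published sizes given only as the range 10 <= n <= 300; pinned here",
            )
        )

    # --- ancient/modern colours -----------------------------------------
    ancient = [era_spec(n, "ancient") for n in ("Red", "Green", "Blue")]
    modern = [era_spec(n, "modern") for n in ("Red", "Green", "Blue", "Cyan", "Yellow", "Purple")]
    modern_black = _c("Black", (0, 0, 0), 0.02)
    add(
        ExperimentSpec(
            "fig19A",
            "Ancient (n=25) and modern (n=75) colours, separate PCAs plotted jointly",
            _cohort([(s, 75) for s in modern] + [(modern_black, 75)], seed),
            (("pca", {}), ("centroid_distances", {"k": 2}), ("separate_pca", {})),
            projected_cohort=_cohort([(s, 25) for s in ancient], seed + 1000),
        )
    )
    add(
        ExperimentSpec(
            "fig19B",
            "Ancient and modern colours with varied sample sizes",
            _cohort(
                [(s, n) for s, n in zip(modern, (75, 40, 10, 25, 60, 15))]
                + [(modern_black, 30)],
                seed,
            ),
            (("pca", {}), ("centroid_distances", {"k": 2}), ("separate_pca", {})),
            projected_cohort=_cohort([(s, n) for s, n in zip(ancient, (25, 10, 18))], seed + 1000),
            ambiguous=True,
            note="published sizes given as ranges (ancient 10-25, modern 10-75); pinned here",
        )
    )
    for tag, n_modern, anc_sizes in (("fig19C", 15, (75, 30, 10)), ("fig19D", 25, (60, 15, 40))):
        add(
            ExperimentSpec(
                tag,
                "Ancient colours projected one at a time onto the modern PCA",
                _cohort([(s, n_modern) for s in modern] + [(modern_black, n_modern)], seed),
                (("pca", {}), ("project", {"k": 2})),
                projected_cohort=_cohort(
                    [(s, n) for s, n in zip(ancient, anc_sizes)], seed + 1000
                ),
                ambiguous=True,
                note="published ancient sizes given as the range 10-75; pinned here",
            )
        )

    # --- missingness and noise -------------------------------------------
    six = [(_spec(n), 50) for n in ("Red", "Green", "Blue", "Cyan", "Yellow", "Black")]
    for tag, rate in (("fig21A", 0.5), ("fig21B", 0.9)):
        add(
            ExperimentSpec(
                tag,
                f"{int(rate * 100)}% missingness on the 600-SNP window expansion",
                _cohort(six, seed),
                (
                    ("expand_windows", {"window_size": 200}),
                    ("inject_missingness", {"rate": rate}),
                    ("collapse_windows", {}),
                    ("pca", {}),
                    ("retention", {"k": 2}),
                ),
            )
        )
    add(
        ExperimentSpec(
            "fig21C",
            "90% missingness plus low-level noise in all markers",
            _cohort(six, seed),
            (
                ("expand_windows", {"window_size": 200}),
                ("add_uniform_noise", {"magnitude": 0.1}),
                ("inject_missingness", {"rate": 0.9}),
                ("collapse_windows", {}),
                ("pca", {}),
                ("retention", {"k": 2}),
            ),
            ambiguous=True,
            note="noise magnitude unstated in the published caption; default 0.1",
        )
    )
    # noise markers are appended to the recovered tri-colour structure: the
    # replicated 600-SNP set carries window-size-fold inflated structure
    # eigenvalues that no amount of uniform noise can drown, whereas the
    # collapsed components reproduce the retained/degraded/lost transition
    for tag, m in (("fig21D", 30), ("fig21E", 300), ("fig21F", 3000)):
        add(
            ExperimentSpec(
                tag,
                f"{m} random noise markers appended to the colour marker set",
                _cohort(six, seed),
                (
                    ("add_noise_markers", {"m": m}),
                    ("pca", {}),
                    ("cluster", {}),
                ),
            )
        )

    # --- single-individual ancestry --------------------------------------
    bright_cyan = _c("bright Cyan", (0, 0.9, 0.8))
    dark_cyan = _c("dark Cyan", (0, 0.9, 0.6))
    het_cyan = _c("heterogeneous Cyan", (0, 0.9, 0.4), 0.25)
    add(
        ExperimentSpec(
            "fig23A",
            "Single light-Green individual with even-sized references",
            _cohort(
                [(_spec("Red"), 37), (_spec("Green"), 37), (bright_cyan, 37),
                 (dark_cyan, 37), (het_cyan, 37), (_c("light Green", (0, 0.5, 0)), 1)],
                seed,
            ),
            pca_dist,
        )
    )
    add(
        ExperimentSpec(
            "fig23B",
            "Single Yellow individual with uneven-sized references",
            _cohort(
                [(_spec("Red"), 15), (_spec("Green"), 15), (bright_cyan, 100),
                 (dark_cyan, 15), (het_cyan, 100), (_spec("Yellow"), 1)],
                seed,
            ),
            pca_dist,
        )
    )
    add(
        ExperimentSpec(
            "fig23C",
            "Single Grey individual with one heterogeneous Cyan population",
            _cohort(
                [(_c("Cyan", (0, 1, 1), 0.25), 300), (_c("Grey", (0.5, 0.5, 0.5)), 1)],
                seed,
            ),
            pca_dist,
        )
    )
    add(
        ExperimentSpec(
            "fig23D",
            "Single Blue individual with Red, Green and a heterogeneous population",
            _cohort(
                [(_spec("Red"), 10), (_spec("Green"), 10),
                 (_c("heterogeneous", (1, 1, 0.5), 0.25), 200), (_spec("Blue"), 1)],
                seed,
            ),
            pca_dist,
        )
    )

    # --- case-control stratification -------------------------------------
    add(
        ExperimentSpec(
            "gwas",
            "Structured case-control cohort: majority Red, minority Blue all controls",
            _cohort([(_spec("Red"), 300), (_spec("Blue"), 20)], seed),
            (
                ("gwas", {
                    "replicates": 3,
                    "labeling": "structured",
                    "minority_label": "Blue",
                    "adjust_pcs": (0, 2, 10),
                }),
            ),
        )
    )
    return reg
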