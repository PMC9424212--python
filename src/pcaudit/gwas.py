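"""Case-control association under population stratification.

The experiment mirrors a GWAS confounded by structure: case/control labels
are laid over a structured cohort (optionally with one minority population
entirely in the control arm), SNP-like markers are simulated with
population-specific allele frequencies derived from the colour structure,
and a per-marker association scan is run with and without principal
component covariates.  The comparison tabulates false positives (null
markers), true positives (causal markers) and the median causal p-value at
each adjustment level.

Marker model
------------
Null markers: dosage ~ Binomial(2, f_pop), where f_pop is a base frequency
shifted along one colour channel by ``freq_spread`` times the population's
deviation from the cohort-mean colour.  Causal markers add a case/control
shift of +/- effect_size/2 on the logit scale, on top of the same
population structure, so stratification and causality are entangled exactly
as in a confounded study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from pcaudit.colors import Dataset, child_seed
from pcaudit.pca import PCA, PCAResults

__all__ = [
    "CaseControlDesign",
    "AssocResult",
    "simulate_labels",
    "simulate_markers",
    "association_scan",
    "cochran_armitage_trend",
    "adjustment_experiment",
    "AdjustmentComparison",
]


@dataclass(frozen=True)
class CaseControlDesign:
    """Configuration of one case-control stratification experiment.

    ``labeling='structured'`` puts the designated minority population
    entirely in the control arm (the remaining labels are drawn at random to
    reach evenly sized arms); ``'random'`` assigns labels uniformly.
    ``adjust_pcs`` lists the PC-covariate counts to compare (0 = unadjusted).
    ``freq_spread`` controls how strongly marker frequencies track the
    colour structure (0 = no structure in the markers).
    """

    labeling: str = "structured"
    minority_label: str | None = None
    n_null_markers: int = 100
    n_causal_markers: int = 20
    effect_size: float = 1.0  # per-allele log-odds between arms
    adjust_pcs: tuple[int, ...] = (0, 2, 10)
    alpha: float = 0.05
    seed: int = 0
    freq_spread: float = 0.6
    base_freq_range: tuple[float, float] = (0.2, 0.8)

    def __post_init__(self) -> None:
        if self.labeling not in ("structured", "random"):
            raise ValueError("labeling must be 'structured' or 'random'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if self.n_null_markers < 0 or self.n_causal_markers < 0:
            raise ValueError("marker counts must be nonnegative")
        object.__setattr__(self, "adjust_pcs", tuple(int(q) for q in self.adjust_pcs))


def simulate_labels(data: Dataset, design: CaseControlDesign, seed: int | None = None) -> np.ndarray:
    """Assign case (True) / control (False) labels with evenly sized arms."""
    n = data.n
    if n % 2:
        raise ValueError("evenly sized arms require an even cohort size")
    rng = np.random.default_rng(design.seed if seed is None else int(seed))
    n_cases = n // 2
    is_case = np.zeros(n, dtype=bool)
    if design.labeling == "random":
        is_case[rng.choice(n, size=n_cases, replace=False)] = True
        return is_case
    minority = design.minority_label
    if minority is None:
        counts = data.label_counts()
        minority = min(counts, key=counts.get)
    member = np.asarray(data.sample_labels == minority)
    if not member.any():
        raise ValueError(f"minority population {minority!r} not present")
    if member.sum() > n - n_cases:
        raise ValueError(
            f"minority population {minority!r} ({int(member.sum())}) exceeds the "
            f"control arm size ({n - n_cases})"
        )
    others = np.flatnonzero(~member)
    is_case[rng.choice(others, size=n_cases, replace=False)] = True
    return is_case


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def simulate_markers(
    data: Dataset,
    labels: np.ndarray,
    design: CaseControlDesign,
    seed: int | None = None,
) -> tuple[Dataset, np.ndarray]:
    """Simulate null and causal {0,1,2} dosages on the structured cohort.

    Returns the genotype Dataset (feature_class ``genotype``) and a boolean
    causal-flag vector.  Frequencies that fall outside (0.01, 0.99) after
    the structure/effect shifts are clipped with a warning.
    """
    rng = np.random.default_rng(design.seed + 1 if seed is None else int(seed))
    labels = np.asarray(labels, dtype=bool)
    n = data.n
    pop_labels, centroids = data.centroids()
    pop_index = {lab: i for i, lab in enumerate(pop_labels)}
    sample_pop = np.array([pop_index[str(lab)] for lab in data.sample_labels])
    global_mean = data.values.mean(axis=0)
    m_total = design.n_null_markers + design.n_causal_markers
    causal = np.zeros(m_total, dtype=bool)
    causal[design.n_null_markers:] = True
    lo, hi = design.base_freq_range
    geno = np.zeros((n, m_total))
    clipped = 0
    n_channels = data.p
    for j in range(m_total):
        c = int(rng.integers(n_channels))
        f0 = rng.uniform(lo, hi)
        f_pop = f0 + design.freq_spread * (centroids[:, c] - global_mean[c])
        f = f_pop[sample_pop]
        if causal[j]:
            shift = np.where(labels, design.effect_size / 2, -design.effect_size / 2)
            safe = np.clip(f, 1e-6, 1 - 1e-6)
            f = _sigmoid(_logit(safe) + shift)
        out_of_range = (f < 0.01) | (f > 0.99)
        clipped += int(out_of_range.sum())
        f = np.clip(f, 0.01, 0.99)
        geno[:, j] = rng.binomial(2, f)
    if clipped:
        warnings.warn(
            f"{clipped} sample-marker frequencies clipped into (0.01, 0.99)",
            stacklevel=2,
        )
    panel = Dataset(
        values=geno,
        sample_labels=data.sample_labels.copy(),
        feature_ids=[f"m{j}" for j in range(m_total)],
        feature_class=["genotype"] * m_total,
    )
    return panel, causal


def cochran_armitage_trend(dosage: np.ndarray, is_case: np.ndarray) -> tuple[float, float]:
    """Cochran-Armitage trend chi-square (scores 0,1,2) and its p-value."""
    dosage = np.asarray(dosage)
    is_case = np.asarray(is_case, dtype=bool)
    t = np.array([0.0, 1.0, 2.0])
    n_i = np.array([(dosage == g).sum() for g in (0, 1, 2)], dtype=float)
    r_i = np.array([(is_case & (dosage == g)).sum() for g in (0, 1, 2)], dtype=float)
    N = n_i.sum()
    R = r_i.sum()
    num = N * (N * (t * r_i).sum() - R * (t * n_i).sum()) ** 2
    den = R * (N - R) * (N * (t**2 * n_i).sum() - (t * n_i).sum() ** 2)
    if den <= 0:
        return 0.0, 1.0
    chi2 = num / den
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class AssocResult:
    """Per-marker association statistics plus the design-level summary."""

    table: pd.DataFrame  # marker, beta, stat, p, trend_stat, trend_p, causal, excluded
    alpha: float
    n_pcs_adjusted: int

    @property
    def false_positive_count(self) -> int:
        t = self.table
        ok = ~t["excluded"] & ~t["causal"]
        return int((t.loc[ok, "p"] < self.alpha).sum())

    @property
    def true_positive_count(self) -> int:
        t = self.table
        ok = ~t["excluded"] & t["causal"]
        return int((t.loc[ok, "p"] < self.alpha).sum())

    @property
    def median_causal_p(self) -> float:
        t = self.table
        ok = ~t["excluded"] & t["causal"]
        vals = t.loc[ok, "p"]
        return float(vals.median()) if len(vals) else float("nan")

    @property
    def n_excluded(self) -> int:
        return int(self.table["excluded"].sum())

    def summary(self) -> str:
        return (
            f"adjustment: {self.n_pcs_adjusted} PCs | "
            f"FP {self.false_positive_count} | TP {self.true_positive_count} | "
            f"median causal p {self.median_causal_p:.3g} | "
            f"excluded {self.n_excluded}"
        )


def association_scan(
    genotypes: Dataset | np.ndarray,
    labels: np.ndarray,
    covariates: np.ndarray | None = None,
    causal_flags: np.ndarray | None = None,
    alpha: float = 0.05,
) -> AssocResult:
    """Per-marker logistic regression of case status on allele dosage.

    ``covariates`` are the top-q PC score columns when adjusting (None for
    the unadjusted scan, which also reports the Cochran-Armitage trend
    statistic as a model-free cross-check).  Markers with separation or a
    failed fit are flagged and excluded from the FP/TP counts.
    """
    G = genotypes.values if isinstance(genotypes, Dataset) else np.asarray(genotypes, dtype=float)
    y = np.asarray(labels, dtype=float)
    n, m = G.shape
    if y.shape[0] != n:
        raise ValueError("labels length does not match genotypes")
    if causal_flags is None:
        causal_flags = np.zeros(m, dtype=bool)
    q = 0
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        q = covariates.shape[1]
    rows = []
    unadjusted = covariates is None
    for j in range(m):
        g = G[:, j]
        X = np.column_stack([np.ones(n), g] if unadjusted else [np.ones(n), g, covariates])
        beta = stat = p = np.nan
        excluded = False
        if np.ptp(g) == 0:
            p = 1.0
            stat = 0.0
            beta = 0.0
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
                beta = float(fit.params[1])
                p = float(fit.pvalues[1])
                stat = float(fit.tvalues[1])
                if not fit.mle_retvals.get("converged", True) or abs(beta) > 30:
                    excluded = True
                    p = stat = np.nan
            except Exception:
                excluded = True
        trend_stat = trend_p = np.nan
        if unadjusted and not excluded:
            trend_stat, trend_p = cochran_armitage_trend(g, labels)
        rows.append(
            {
                "marker": f"m{j}",
                "beta": beta,
                "stat": stat,
                "p": p,
                "trend_stat": trend_stat,
                "trend_p": trend_p,
                "causal": bool(causal_flags[j]),
                "excluded": excluded,
            }
        )
    return AssocResult(table=pd.DataFrame(rows), alpha=float(alpha), n_pcs_adjusted=q)


@dataclass
class AdjustmentComparison:
    """Replicated comparison of association scans across adjustment levels."""

    table: pd.DataFrame  # replicate, n_pcs, fp, tp, median_causal_p, n_excluded
    design: CaseControlDesign
    pca_results: PCAResults = field(repr=False, default=None)  # type: ignore[assignment]

    def aggregate(self) -> pd.DataFrame:
        return (
            self.table.groupby("n_pcs")
            .agg(
                fp_median=("fp", "median"),
                tp_median=("tp", "median"),
                median_causal_p=("median_causal_p", "median"),
                n_replicates=("replicate", "count"),
            )
            .reset_index()
        )

    def sign_test_tp(self, q: int) -> dict:
        """Across replicates, does adjusting with q PCs yield fewer true
        positives than the unadjusted scan?  One-sided sign test."""
        wide = self.table.pivot(index="replicate", columns="n_pcs", values="tp")
        diff = wide[q] - wide[0]
        n_worse = int((diff < 0).sum())
        n_better = int((diff > 0).sum())
        n_eff = n_worse + n_better
        p = (
            float(stats.binomtest(n_worse, n_eff, 0.5, alternative="greater").pvalue)
            if n_eff
            else float("nan")
        )
        return {"n_pcs": q, "n_worse": n_worse, "n_better": n_better, "p": p}

    def summary(self) -> str:
        agg = self.aggregate()
        lines = ["Adjustment comparison (medians across replicates)", ""]
        lines.append(agg.to_string(index=False))
        for q in sorted(set(self.table["n_pcs"])) :
            if q == 0:
                continue
            st = self.sign_test_tp(q)
            lines.append(
                f"TP with {q} PCs < unadjusted in {st['n_worse']}/"
                f"{st['n_worse'] + st['n_better']} informative replicates "
                f"(sign test p = {st['p']:.3g})"
            )
        return "\n".join(lines)


def adjustment_experiment(
    data: Dataset,
    design: CaseControlDesign,
    replicates: int = 1,
) -> AdjustmentComparison:
    """Run the full label/marker/scan pipeline for each replicate and each
    PC-adjustment level in ``design.adjust_pcs``.

    PC covariates are recomputed per replicate from the simulated marker
    panel itself — the standard GWAS practice of adjusting with ancestry
    PCs of the genotyped markers.  (The 3-column colour matrix has rank at
    most 3, so genotype PCs are also what makes a 10-PC adjustment
    meaningful.)
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    res = None
    for rep in range(replicates):
        rep_seed = child_seed(design.seed, rep, "replicate")
        labels = simulate_labels(data, design, seed=rep_seed)
        markers, causal = simulate_markers(data, labels, design, seed=rep_seed + 1)
        res = PCA(markers).fit()
        for q in design.adjust_pcs:
            if q > res.r:
                raise ValueError(f"cannot adjust with {q} PCs; rank is {res.r}")
            cov = res.scores[:, :q] if q > 0 else None
            scan = association_scan(markers, labels, cov, causal, alpha=design.alpha)
            rows.append(
                {
                    "replicate": rep,
                    "n_pcs": q,
                    "fp": scan.false_positive_count,
                    "tp": scan.true_positive_count,
                    "median_causal_p": scan.median_causal_p,
                    "n_excluded": scan.n_excluded,
                }
            )
    return AdjustmentComparison(table=pd.DataFrame(rows), design=design, pca_results=res)
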