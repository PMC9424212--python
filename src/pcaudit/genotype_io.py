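"""Plain-text genotype readers/writers (EIGENSTRAT and PLINK text exports).

These are optional adapters so the same pipeline runs on real dosage
matrices; nothing else in the package depends on them, and tests use the
bundled random-fixture generator rather than downloads.  Dosages are
allelic counts in {0,1,2}; '9' (EIGENSTRAT) and 'NA' (PLINK) mark missing
entries.  Out-of-range dosages raise — they are never silently clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pcaudit.colors import Dataset

__all__ = [
    "GenotypePanel",
    "read_eigenstrat",
    "write_eigenstrat",
    "read_plink_text",
    "write_plink_raw",
    "write_plink_traw",
    "filter_missingness",
    "random_panel",
]


@dataclass
class GenotypePanel:
    """A genotype Dataset plus marker and sample metadata tables."""

    dataset: Dataset  # n samples x p markers, feature_class = genotype
    markers: pd.DataFrame  # id, chrom, pos, ref, alt
    samples: pd.DataFrame  # id, population

    def __post_init__(self) -> None:
        if len(self.markers) != self.dataset.p:
            raise ValueError("marker metadata length does not match marker count")
        if len(self.samples) != self.dataset.n:
            raise ValueError("sample metadata length does not match sample count")

    @property
    def n(self) -> int:
        return self.dataset.n

    @property
    def p(self) -> int:
        return self.dataset.p


def _geno_dataset(dosage: np.ndarray, mask: np.ndarray, labels, marker_ids) -> Dataset:
    return Dataset(
        values=np.where(mask, 0.0, dosage),
        sample_labels=np.asarray(labels, dtype=object),
        feature_ids=list(marker_ids),
        feature_class=["genotype"] * dosage.shape[1],
        missing_mask=mask,
    )


def read_eigenstrat(geno_path, snp_path, ind_path) -> GenotypePanel:
    """Read an EIGENSTRAT triple (.geno/.snp/.ind).

    .geno rows are markers, columns samples, one character per dosage with
    '9' = missing.  Sample population labels come from the .ind group
    column.
    """
    snp_rows = []
    for ln, line in enumerate(Path(snp_path).read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 4:
            raise ValueError(f"{snp_path}:{ln}: expected >=4 fields, got {len(parts)}")
        ref = parts[4] if len(parts) > 4 else "A"
        alt = parts[5] if len(parts) > 5 else "T"
        snp_rows.append(
            {"id": parts[0], "chrom": parts[1], "pos": int(parts[3]), "ref": ref, "alt": alt}
        )
    markers = pd.DataFrame(snp_rows)

    ind_rows = []
    for ln, line in enumerate(Path(ind_path).read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 3:
            raise ValueError(f"{ind_path}:{ln}: expected 3 fields, got {len(parts)}")
        ind_rows.append({"id": parts[0], "sex": parts[1], "population": parts[2]})
    samples = pd.DataFrame(ind_rows)

    n, p = len(samples), len(markers)
    dosage = np.zeros((n, p))
    mask = np.zeros((n, p), dtype=bool)
    lines = [l for l in Path(geno_path).read_text().splitlines() if l.strip()]
    if len(lines) != p:
        raise ValueError(
            f"{geno_path}: {len(lines)} genotype rows but {p} markers in {snp_path}"
        )
    for ln, line in enumerate(lines):
        if len(line) != n:
            raise ValueError(
                f"{geno_path}:{ln + 1}: row has {len(line)} columns, expected {n} samples"
            )
        for i, ch in enumerate(line):
            if ch == "9":
                mask[i, ln] = True
            elif ch in "012":
                dosage[i, ln] = int(ch)
            else:
                raise ValueError(f"{geno_path}:{ln + 1}: invalid character {ch!r}")
    return GenotypePanel(
        dataset=_geno_dataset(dosage, mask, samples["population"], markers["id"]),
        markers=markers,
        samples=samples[["id", "population"]],
    )


def write_eigenstrat(panel: GenotypePanel, prefix: str | Path) -> tuple[Path, Path, Path]:
    prefix = Path(prefix)
    geno_path = prefix.with_suffix(".geno")
    snp_path = prefix.with_suffix(".snp")
    ind_path = prefix.with_suffix(".ind")
    ds = panel.dataset
    lines = []
    for j in range(ds.p):
        chars = [
            "9" if ds.missing_mask[i, j] else str(int(ds.values[i, j])) for i in range(ds.n)
        ]
        lines.append("".join(chars))
    geno_path.write_text("\n".join(lines) + "\n")
    snp_lines = [
        f"{m.id} {m.chrom} 0.0 {m.pos} {m.ref} {m.alt}" for m in panel.markers.itertuples()
    ]
    snp_path.write_text("\n".join(snp_lines) + "\n")
    ind_lines = [f"{s.id} U {s.population}" for s in panel.samples.itertuples()]
    ind_path.write_text("\n".join(ind_lines) + "\n")
    return geno_path, snp_path, ind_path


def read_plink_text(path) -> GenotypePanel:
    """Read a PLINK additive-coding text export (.raw or .traw).

    Orientation is auto-detected from the header dialect: a ``FID IID ...``
    header is samples x markers (.raw); a ``CHR SNP ...`` header is
    markers x samples (.traw).  'NA' marks missing dosages.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
    if not header:
        raise ValueError(f"{path}: empty file")
    if header[:2] == ["FID", "IID"]:
        df = pd.read_csv(path, sep=r"\s+")
        meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        marker_cols = [c for c in df.columns if c not in meta_cols]
        dosage = df[marker_cols].to_numpy(dtype=float)
        mask = np.isnan(dosage)
        marker_ids = [c.rsplit("_", 1)[0] for c in marker_cols]
        samples = pd.DataFrame({"id": df["IID"].astype(str), "population": df["FID"].astype(str)})
        markers = pd.DataFrame(
            {"id": marker_ids, "chrom": "0", "pos": 0, "ref": "A", "alt": "T"}
        )
        labels = samples["population"]
    elif header[0] == "CHR" and header[1] == "SNP":
        df = pd.read_csv(path, sep="\t")
        meta_cols = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]
        sample_cols = [c for c in df.columns if c not in meta_cols]
        dosage = df[sample_cols].to_numpy(dtype=float).T
        mask = np.isnan(dosage)
        markers = pd.DataFrame(
            {
                "id": df["SNP"].astype(str),
                "chrom": df["CHR"].astype(str),
                "pos": df["POS"].astype(int),
                "ref": df["COUNTED"].astype(str),
                "alt": df["ALT"].astype(str),
            }
        )
        ids = [c.split("_", 1)[1] if "_" in c else c for c in sample_cols]
        pops = [c.split("_", 1)[0] for c in sample_cols]
        samples = pd.DataFrame({"id": ids, "population": pops})
        labels = samples["population"]
    else:
        raise ValueError(f"{path}: unrecognised header {' '.join(header[:4])!r}")
    observed = np.where(mask, 0, dosage)
    if not np.isin(observed, (0.0, 1.0, 2.0)).all():
        raise ValueError(f"{path}: observed dosages outside {{0,1,2}}")
    return GenotypePanel(
        dataset=_geno_dataset(dosage, mask, labels, markers["id"]),
        markers=markers,
        samples=samples,
    )


def write_plink_raw(panel: GenotypePanel, path) -> Path:
    path = Path(path)
    ds = panel.dataset
    cols = [f"{mid}_A" for mid in panel.markers["id"]]
    lines = ["FID IID PAT MAT SEX PHENOTYPE " + " ".join(cols)]
    for i in range(ds.n):
        row = [
            str(panel.samples["population"].iloc[i]),
            str(panel.samples["id"].iloc[i]),
            "0",
            "0",
            "0",
            "-9",
        ]
        for j in range(ds.p):
            row.append("NA" if ds.missing_mask[i, j] else str(int(ds.values[i, j])))
        lines.append(" ".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_plink_traw(panel: GenotypePanel, path) -> Path:
    path = Path(path)
    ds = panel.dataset
    sample_cols = [
        f"{panel.samples['population'].iloc[i]}_{panel.samples['id'].iloc[i]}"
        for i in range(ds.n)
    ]
    lines = ["\t".join(["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"] + sample_cols)]
    for j in range(ds.p):
        m = panel.markers.iloc[j]
        row = [str(m["chrom"]), str(m["id"]), "0", str(int(m["pos"])), str(m["ref"]), str(m["alt"])]
        for i in range(ds.n):
            row.append("NA" if ds.missing_mask[i, j] else str(int(ds.values[i, j])))
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


def filter_missingness(
    panel: GenotypePanel, max_missing_per_sample: int = 5
) -> tuple[GenotypePanel, list[str]]:
    """Drop samples with more than ``max_missing_per_sample`` missing markers.

    Returns the filtered panel and the list of dropped sample ids.
    """
    counts = panel.dataset.missing_mask.sum(axis=1)
    keep = counts <= max_missing_per_sample
    dropped = [str(panel.samples["id"].iloc[i]) for i in np.flatnonzero(~keep)]
    if keep.all():
        return panel, []
    filtered = GenotypePanel(
        dataset=panel.dataset.subset_samples(np.flatnonzero(keep)),
        markers=panel.markers.reset_index(drop=True),
        samples=panel.samples.loc[keep].reset_index(drop=True),
    )
    return filtered, dropped


def random_panel(
    n: int, p: int, seed: int, missing_rate: float = 0.0, n_pops: int = 2
) -> GenotypePanel:
    """Random genotype fixture for tests (never downloaded data)."""
    rng = np.random.default_rng(int(seed))
    freqs = rng.uniform(0.1, 0.9, size=p)
    dosage = rng.binomial(2, freqs, size=(n, p)).astype(float)
    mask = rng.random((n, p)) < missing_rate
    # never leave a row fully missing
    for i in np.flatnonzero(mask.all(axis=1)):
        mask[i, rng.integers(p)] = False
    pops = [f"pop{i % n_pops}" for i in range(n)]
    markers = pd.DataFrame(
        {
            "id": [f"rs{j}" for j in range(p)],
            "chrom": ["1"] * p,
            "pos": np.arange(1, p + 1) * 1000,
            "ref": ["A"] * p,
            "alt": ["T"] * p,
        }
    )
    samples = pd.DataFrame({"id": [f"ind{i}" for i in range(n)], "population": pops})
    return GenotypePanel(
        dataset=_geno_dataset(dosage, mask, pops, markers["id"]),
        markers=markers,
        samples=samples,
    )
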