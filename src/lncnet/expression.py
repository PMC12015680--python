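"""Expression matrices: counts, FPKM conversion, expression filtering, PCA.

FPKM here uses the in-matrix column sum as the "million mapped fragments"
denominator: fpkm[g,s] = counts[g,s] * 1e9 / (length_bp[g] * colsum_s). PCA
sample scores are computed on log2(FPKM+1), gene-centered, by SVD, with each
component's sign fixed so its largest-magnitude gene loading is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneTable

logger = logging.getLogger(__name__)

GROUPS = ("TL", "PROM", "PTB", "PPROM")


def _validate_design(samples, design: pd.Series) -> pd.Series:
    design = design.astype(str)
    missing = [s for s in samples if s not in design.index]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    return design.loc[list(samples)]


@dataclass
class CountMatrix:
    """Genes x samples integer count matrix with a sample->group design."""

    counts: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        self.counts = self.counts.astype(np.int64)
        self.design = _validate_design(self.counts.columns, self.design)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.samples if self.design[s] == group]

    @classmethod
    def from_tsv(cls, counts_path, design_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = read_design(design_path)
        return cls(counts, design)


@dataclass
class FpkmMatrix:
    """Genes x samples FPKM matrix sharing the CountMatrix design."""

    fpkm: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM must be non-negative")
        self.design = _validate_design(self.fpkm.columns, self.design)

    @property
    def genes(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.fpkm.columns)

    def subset(self, gene_ids) -> "FpkmMatrix":
        return FpkmMatrix(self.fpkm.loc[list(gene_ids)], self.design)


def read_design(path_or_buf) -> pd.Series:
    """Two-column TSV (sample_id, group) -> Series indexed by sample_id."""
    df = pd.read_csv(path_or_buf, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("design table needs columns sample_id, group")
    df.columns = ["sample_id", "group"] + list(df.columns[2:])
    return df.set_index("sample_id")["group"].astype(str)


def compute_fpkm(counts: CountMatrix, annotation: GeneTable) -> FpkmMatrix:
    """Fragments per kilobase of transcript per million in-matrix fragments."""
    lengths = annotation.lengths(counts.genes)  # raises on missing genes
    totals = counts.counts.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        bad = [s for s, t in zip(counts.samples, totals) if t == 0]
        raise ValueError(f"samples with zero total counts: {bad}")
    fpkm = counts.counts.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * totals[None, :])
    return FpkmMatrix(pd.DataFrame(fpkm, index=counts.genes, columns=counts.samples), counts.design)


def filter_expressed(
    fpkm: FpkmMatrix, min_fpkm: float = 0.1, min_samples: int = 2
) -> FpkmMatrix:
    """Keep genes with FPKM >= min_fpkm in at least min_samples samples."""
    if min_fpkm < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    keep = (fpkm.fpkm >= min_fpkm).sum(axis=1) >= min_samples
    return FpkmMatrix(fpkm.fpkm.loc[keep], fpkm.design)


def pca_scores(
    fpkm: FpkmMatrix, n_components: int = 2, log_transform: bool = True
) -> pd.DataFrame:
    """Sample scores of a gene-centered PCA of log2(FPKM+1).

    Returns a samples x components DataFrame (columns PC1, PC2, ...). Each
    component's sign is fixed by making the largest-magnitude gene loading
    positive, so scores are deterministic. A constant input yields zero
    scores with a logged warning.
    """
    n_samples = len(fpkm.samples)
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not (0 < n_components < n_samples):
        raise ValueError("need 0 < n_components < number of samples")
    x = fpkm.fpkm.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    x = x - x.mean(axis=1, keepdims=True)  # center each gene
    cols = [f"PC{i + 1}" for i in range(n_components)]
    if not np.any(x):
        logger.warning("constant expression matrix: PCA scores are all zero")
        return pd.DataFrame(0.0, index=fpkm.samples, columns=cols)
    # samples x genes orientation: scores = U * S
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components]
    for j in range(n_components):
        pivot = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, pivot] < 0:
            scores[:, j] = -scores[:, j]
            loadings[j] = -loadings[j]
    return pd.DataFrame(scores, index=fpkm.samples, columns=cols)
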