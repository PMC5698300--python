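"""Expression-atlas tissue assignment and co-expression analysis.

Values are RMA-scale log2 intensities (genes x samples) with per-sample
tissue/condition metadata.  Tissue assignment follows the atlas convention:
a gene is called present in a tissue when its mean log2 intensity over that
tissue's replicate samples reaches log2(256) = 8.  Co-expression uses the
distance ``d = 1 - PCC`` with average-linkage agglomeration and a strict
cut: genes share a cluster only when their merge height is *below* the
threshold (default 0.2, i.e. PCC > 0.8).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ExpressionMatrix",
    "TissueCall",
    "CoexpressionCluster",
    "read_expression_matrix",
    "assign_tissue_ontology",
    "center_relative",
    "coexpression_clusters",
    "neighbors_of",
    "condition_contrast",
    "plot_heatmap",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensities plus sample metadata.

    ``sample_meta`` is indexed by sample id and must carry a ``tissue``
    column; ``condition`` and ``platform`` columns are optional.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("gene and sample labels must be unique")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if "tissue" not in self.sample_meta.columns:
            raise ValueError("sample_meta must have a 'tissue' column")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def tissues(self) -> list[str]:
        return sorted(self.sample_meta.loc[self.samples, "tissue"].unique())

    def samples_of_tissue(self, tissue: str) -> list[str]:
        meta = self.sample_meta.loc[self.samples]
        return list(meta.index[meta["tissue"] == tissue])


def read_expression_matrix(matrix_path, meta_path) -> ExpressionMatrix:
    """Read a tab-delimited genes x samples matrix and sample-metadata TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, meta)


def write_expression_matrix(m: ExpressionMatrix, matrix_path, meta_path) -> None:
    m.values.to_csv(matrix_path, sep="\t")
    m.sample_meta.to_csv(meta_path, sep="\t")


@dataclass(frozen=True)
class TissueCall:
    gene: str
    tissues: frozenset[str]


def assign_tissue_ontology(
    m: ExpressionMatrix,
    threshold_abs: float = 256.0,
    stat: str = "mean",
) -> list[TissueCall]:
    """Assign tissue labels where expression clears the atlas threshold.

    ``threshold_abs`` is on the linear intensity scale (default 256, i.e.
    log2 value 8) and the comparison is inclusive.  The per-tissue summary
    is the mean over that tissue's replicate samples by default
    (``stat="max"`` is available).  Tissues with zero samples are skipped
    with a warning.
    """
    log2_thr = math.log2(threshold_abs)
    calls = []
    summaries = {}
    for tissue in m.tissues():
        samples = m.samples_of_tissue(tissue)
        if not samples:
            warnings.warn(f"tissue {tissue!r} has no samples; skipped")
            continue
        block = m.values[samples]
        summaries[tissue] = block.mean(axis=1) if stat == "mean" else block.max(axis=1)
    for gene in m.genes:
        hit = frozenset(t for t, s in summaries.items() if s[gene] >= log2_thr)
        calls.append(TissueCall(gene, hit))
    return calls


def center_relative(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's row mean: relative expression, row means zero."""
    centered = m.values.sub(m.values.mean(axis=1), axis=0)
    return ExpressionMatrix(centered, m.sample_meta)


@dataclass(frozen=True)
class CoexpressionCluster:
    members: tuple[str, ...]
    max_internal_distance: float  # in 1 - PCC units


def _pcc_distance(values: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """1 - PCC condensed distance over rows, excluding zero-variance rows."""
    sd = values.std(axis=1, ddof=0)
    flat = sd[sd == 0].index
    if len(flat):
        warnings.warn(
            f"excluding zero-variance genes (PCC undefined): {sorted(flat)}"
        )
    kept = values.drop(index=flat).sort_index()
    genes = list(kept.index)
    if len(genes) < 2:
        return genes, np.empty(0)
    corr = np.corrcoef(kept.to_numpy(dtype=float))
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return genes, squareform(dist, checks=False)


def coexpression_clusters(
    m: ExpressionMatrix,
    distance_threshold: float = 0.2,
) -> list[CoexpressionCluster]:
    """Average-linkage clusters cut strictly below the distance threshold.

    Genes are sorted by label before clustering so ties resolve
    deterministically; singletons are dropped.
    """
    if len(m.genes) < 2:
        raise ValueError("need at least 2 genes")
    if len(m.samples) < 3:
        raise ValueError("need at least 3 samples for a meaningful PCC")
    genes, condensed = _pcc_distance(m.values)
    if len(genes) < 2:
        return []
    Z = linkage(condensed, method="average")
    # fcluster's 'distance' criterion is <= t; nudge below for a strict cut
    cut = np.nextafter(distance_threshold, -np.inf)
    labels = fcluster(Z, t=cut, criterion="distance")
    groups: dict[int, list[str]] = {}
    for gene, lab in zip(genes, labels):
        groups.setdefault(int(lab), []).append(gene)
    out = []
    dm = squareform(condensed) if len(condensed) else np.zeros((len(genes), len(genes)))
    index = {g: i for i, g in enumerate(genes)}
    for members in groups.values():
        if len(members) < 2:
            continue
        members = sorted(members)
        idx = [index[g] for g in members]
        sub = dm[np.ix_(idx, idx)]
        out.append(CoexpressionCluster(tuple(members), float(sub.max())))
    out.sort(key=lambda c: c.members)
    return out


def neighbors_of(
    m: ExpressionMatrix,
    gene: str,
    distance_threshold: float = 0.2,
) -> list[tuple[str, float]]:
    """All genes at 1 - PCC distance strictly below the threshold, ascending."""
    if gene not in m.values.index:
        raise KeyError(gene)
    row = m.values.loc[gene].to_numpy(dtype=float)
    if row.std() == 0:
        warnings.warn(f"query {gene!r} has zero variance; PCC undefined")
        return []
    out = []
    for other in m.genes:
        if other == gene:
            continue
        vec = m.values.loc[other].to_numpy(dtype=float)
        if vec.std() == 0:
            continue
        d = 1.0 - float(np.corrcoef(row, vec)[0, 1])
        if d < distance_threshold:
            out.append((other, d))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def condition_contrast(
    m: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.Series:
    """Descriptive per-gene log2 difference: mean(group_a) - mean(group_b)."""
    for s in list(group_a) + list(group_b):
        if s not in m.values.columns:
            raise KeyError(f"unknown sample {s!r}")
    return m.values[list(group_a)].mean(axis=1) - m.values[list(group_b)].mean(axis=1)


def plot_heatmap(m: ExpressionMatrix, path, center: bool = True) -> None:
    """Export a simple genes x samples heat map (PNG/PDF/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = center_relative(m).values if center else m.values
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * len(data.columns)), max(3, 0.2 * len(data.index)))
    )
    im = ax.imshow(data.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(data.columns)))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(data.index)))
    ax.set_yticklabels(data.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="log2 intensity" + (" (centered)" if center else ""))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
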