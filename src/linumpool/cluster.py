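"""Hierarchical clustering of cultivars on their VAF profiles.

Following the analysis this pipeline reproduces, VAFs below 20% are zeroed
(suppressing residual off-target signal), inter-cultivar Euclidean distances
are computed, and agglomeration uses the Ward-D2 criterion — squared
Euclidean distances inside the objective, merge heights reported on the
distance scale (the semantics of R's ``hclust(method="ward.D2")``, which is
also what :func:`scipy.cluster.hierarchy.linkage` computes with
``method="ward"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .calling import CALLER_THRESHOLD, ConsensusCall

__all__ = [
    "VafProfileMatrix",
    "Dendrogram",
    "build_profile",
    "ward_d2",
    "cut_tree",
    "render_heatmap",
]

DEFAULT_ZERO_FLOOR = 0.20


@dataclass
class VafProfileMatrix:
    """Cultivars × variants VAF matrix after zeroing sub-floor values.

    Entries are 0 or in [zero_floor, 1]; missing VAFs become 0 (absence of
    evidence is treated as absence of the allele for distance purposes).
    """

    values: pd.DataFrame  # index cultivar, columns variant labels
    caller_id: str
    genes: tuple[str, ...]
    zero_floor: float

    @property
    def cultivars(self) -> list[str]:
        return list(self.values.index)


@dataclass
class Dendrogram:
    """Ward-D2 merge tree for a set of cultivars.

    ``linkage`` is the scipy linkage matrix: n−1 rows of
    (node_a, node_b, height, size), nodes ≥ n being merged clusters.
    """

    linkage: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        if self.linkage.shape != (len(self.labels) - 1, 4):
            raise ValueError("linkage must have n-1 merges for n leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[int]:
        return list(hierarchy.leaves_list(self.linkage))

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]

    def cophenetic(self) -> np.ndarray:
        """Condensed matrix of cophenetic distances between leaves."""
        from scipy.spatial.distance import squareform

        return hierarchy.cophenet(self.linkage)

    def merges(self) -> list[tuple[int, int, float, int]]:
        return [
            (int(a), int(b), float(h), int(size))
            for a, b, h, size in self.linkage
        ]

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - (node.dist if not node.is_leaf() else 0.0), 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def build_profile(
    calls: list[ConsensusCall],
    caller_id: str = CALLER_THRESHOLD,
    genes: tuple[str, ...] | list[str] | None = None,
    zero_floor: float = DEFAULT_ZERO_FLOOR,
) -> VafProfileMatrix:
    """VAF profile matrix restricted to ``genes`` with sub-floor zeroing."""
    if genes is not None and len(genes) == 0:
        raise ValueError("gene subset must not be empty")
    if not calls:
        raise ValueError("no consensus calls to profile")
    wanted = set(genes) if genes is not None else None
    cultivars = calls[0].cultivars
    columns = {}
    kept_genes: list[str] = []
    for call in calls:
        gene = call.gene_id or "unassigned"
        if wanted is not None and gene not in wanted:
            continue
        vaf = np.nan_to_num(call.vaf[caller_id], nan=0.0)
        vaf = np.where(vaf < zero_floor, 0.0, vaf)
        label = f"{gene}:{call.site.chromosome_id}:{call.site.position}:{call.site.alt_allele}"
        columns[label] = vaf
        if gene not in kept_genes:
            kept_genes.append(gene)
    if not columns:
        raise ValueError("no variants left after gene restriction")
    values = pd.DataFrame(columns, index=pd.Index(cultivars, name="cultivar"))
    return VafProfileMatrix(
        values=values, caller_id=caller_id, genes=tuple(kept_genes),
        zero_floor=zero_floor,
    )


def ward_d2(profile: VafProfileMatrix | pd.DataFrame | np.ndarray,
            labels: list[str] | None = None) -> Dendrogram:
    """Ward-D2 agglomeration of rows on Euclidean distances.

    Deterministic for a given input; exact ties are resolved by scipy's
    nearest-neighbor chain, which is reproducible run to run.
    """
    if isinstance(profile, VafProfileMatrix):
        matrix = profile.values.to_numpy(dtype=float)
        labels = profile.cultivars
    elif isinstance(profile, pd.DataFrame):
        matrix = profile.to_numpy(dtype=float)
        labels = list(profile.index)
    else:
        matrix = np.asarray(profile, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(matrix.shape[0])]
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    linkage = hierarchy.linkage(matrix, method="ward")
    return Dendrogram(linkage=linkage, labels=list(labels))


def cut_tree(dendro: Dendrogram, k: int) -> pd.Series:
    """Cluster labels from cutting the tree into ``k`` clusters.

    Labels are renumbered 1..k by order of first appearance along the
    dendrogram leaf order, so the numbering is stable across runs.
    """
    n = dendro.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = hierarchy.fcluster(dendro.linkage, t=k, criterion="maxclust")
    mapping: dict[int, int] = {}
    for leaf in dendro.leaf_order:
        if raw[leaf] not in mapping:
            mapping[raw[leaf]] = len(mapping) + 1
    labels = np.array([mapping[c] for c in raw])
    return pd.Series(labels, index=pd.Index(dendro.labels, name="cultivar"),
                     name="cluster")


def render_heatmap(
    profile: VafProfileMatrix,
    dendro: Dendrogram,
    phenotypes: pd.DataFrame,
    out_path,
    tsv_path=None,
) -> pd.DataFrame:
    """Heatmap of the VAF profile with fatty-acid annotation tracks.

    Cultivars are ordered by the dendrogram leaves and variant columns are
    grouped by gene.  The plotted numeric matrix (VAF columns followed by
    the five fatty-acid tracks) is returned and optionally written as TSV so
    renders are testable; the figure itself goes to ``out_path``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = dendro.ordered_labels
    values = profile.values.loc[order]
    # group variant columns by gene prefix, preserving within-gene order
    by_gene = sorted(range(len(values.columns)),
                     key=lambda i: values.columns[i].split(":")[0])
    values = values.iloc[:, by_gene]
    pheno = phenotypes.loc[order]
    plotted = pd.concat([values, pheno], axis=1)

    fig, (ax_vaf, ax_fa) = plt.subplots(
        1, 2, figsize=(max(6.0, 0.18 * values.shape[1] + 2), max(4.0, 0.12 * len(order))),
        width_ratios=[max(values.shape[1], 1), 5], sharey=True,
    )
    im = ax_vaf.imshow(values.to_numpy(), aspect="auto", cmap="viridis",
                       vmin=0.0, vmax=1.0, interpolation="nearest")
    ax_vaf.set_xticks(range(values.shape[1]))
    ax_vaf.set_xticklabels(values.columns, rotation=90, fontsize=4)
    ax_vaf.set_yticks(range(len(order)))
    ax_vaf.set_yticklabels(order, fontsize=4)
    ax_vaf.set_title(f"VAF profile ({profile.caller_id})", fontsize=8)
    fig.colorbar(im, ax=ax_vaf, shrink=0.5, label="VAF")

    im2 = ax_fa.imshow(pheno.to_numpy(), aspect="auto", cmap="magma",
                       interpolation="nearest")
    ax_fa.set_xticks(range(pheno.shape[1]))
    ax_fa.set_xticklabels(pheno.columns, rotation=90, fontsize=6)
    ax_fa.set_title("fatty acids (%)", fontsize=8)
    fig.colorbar(im2, ax=ax_fa, shrink=0.5, label="% of oil")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    if tsv_path is not None:
        plotted.rename_axis("cultivar").to_csv(tsv_path, sep="\t")
    return plotted
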