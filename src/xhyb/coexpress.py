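"""Cross-species co-expression of differentially expressed clusters.

Orthologous clusters containing reference-species (e.g. Arabidopsis)
genes are mapped onto probesets of a reference expression compendium;
each probeset's expression vector across the compendium's arrays is
correlated with every other, and probesets are grouped by average-linkage
hierarchical clustering of the dissimilarity d = 1 - r.  Cutting the
tree at a small height (0.05, 0.1 or 0.2) keeps only groups whose
members are very highly co-expressed; smaller heights are stricter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from xhyb.orthology import OrthoClusterSet

COEXPRESSION_THRESHOLDS = (0.05, 0.1, 0.2)


@dataclass
class ExpressionCompendium:
    """Probesets x arrays expression matrix.

    All-constant probeset rows are dropped (their correlation is
    undefined); dropped ids are recorded in ``dropped``.
    """
    matrix: pd.DataFrame
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not np.isfinite(self.matrix.to_numpy()).all():
            raise ValueError("compendium contains non-finite values")
        constant = self.matrix.std(axis=1) == 0
        if constant.any():
            self.dropped = list(self.matrix.index[constant])
            self.matrix = self.matrix[~constant]

    @property
    def probesets(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def arrays(self) -> list[str]:
        return list(self.matrix.columns)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionCompendium":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")


@dataclass
class CoexpressionResult:
    threshold: float
    groups: list[set[str]]
    singletons: set[str]
    r_matrix: pd.DataFrame
    linkage_method: str = "average"


def map_clusters(clusters: OrthoClusterSet,
                 gene_to_probeset_hits: pd.DataFrame,
                 min_identity: float = 80.0,
                 min_length: int = 100) -> tuple[dict[str, set[str]],
                                                 list[str]]:
    """Map each ortholog cluster to reference-array probesets.

    Hits relate reference gene ids (query) to probeset target sequences
    (subject); a cluster maps to the union of probesets hit by any of
    its members above the identity/length thresholds.  Returns the map
    and the list of unmappable cluster ids.
    """
    ok = gene_to_probeset_hits[
        (gene_to_probeset_hits["percent_identity"] >= min_identity)
        & (gene_to_probeset_hits["alignment_length"] >= min_length)]
    gene_to_ps: dict[str, set[str]] = {}
    for q, s in zip(ok["query_id"], ok["subject_id"]):
        gene_to_ps.setdefault(q, set()).add(s)
    mapped: dict[str, set[str]] = {}
    unmappable = []
    for cid in sorted(clusters.clusters):
        probesets: set[str] = set()
        for member in clusters.clusters[cid]:
            probesets |= gene_to_ps.get(member, set())
        if probesets:
            mapped[cid] = probesets
        else:
            unmappable.append(cid)
    return mapped, unmappable


def expression_vectors(comp: ExpressionCompendium,
                       probesets: list[str]
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Expression vectors (rows) for the requested probesets.

    Probesets absent from the compendium are reported, never silently
    skipped.
    """
    present = [p for p in probesets if p in comp.matrix.index]
    missing = [p for p in probesets if p not in comp.matrix.index]
    return comp.matrix.loc[present], missing


def pearson_matrix(vectors: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations; symmetric with unit diagonal."""
    if vectors.shape[1] < 3:
        raise ValueError("need >= 3 arrays to correlate")
    stds = vectors.std(axis=1)
    constant = stds[stds == 0]
    if len(constant):
        raise ValueError(
            f"constant expression vector(s): {list(constant.index)[:5]}")
    r = np.corrcoef(vectors.to_numpy())
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=vectors.index, columns=vectors.index)


def coexpressed_groups(r_matrix: pd.DataFrame, threshold: float = 0.2,
                       linkage_method: str = "average"
                       ) -> CoexpressionResult:
    """Cut the hierarchical tree of d = 1 - r at height ``threshold``.

    Items are clustered on the 1 - r dissimilarity with the given
    linkage and the dendrogram cut at the threshold; groups of size >= 2
    are the co-expressed sets (members correlate at r >= 1 - threshold at
    the linkage level), singletons are reported separately.  Input order
    does not matter: items are put in canonical id order first.
    """
    if not 0 < threshold < 2:
        raise ValueError("threshold must be in (0, 2)")
    ids = sorted(r_matrix.index)
    r = r_matrix.loc[ids, ids].to_numpy()
    if len(ids) == 1:
        return CoexpressionResult(threshold, [], set(ids), r_matrix,
                                  linkage_method)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method=linkage_method)
    labels = fcluster(z, t=threshold, criterion="distance")
    by_label: dict[int, set[str]] = {}
    for pid, lab in zip(ids, labels):
        by_label.setdefault(lab, set()).add(pid)
    groups = sorted((g for g in by_label.values() if len(g) >= 2),
                    key=lambda g: min(g))
    singletons = {next(iter(g)) for g in by_label.values() if len(g) == 1}
    return CoexpressionResult(threshold, groups, singletons,
                              r_matrix.loc[ids, ids], linkage_method)


def groups_to_tsv(results: list[CoexpressionResult], path) -> None:
    rows = []
    for res in results:
        for gid, group in enumerate(res.groups, start=1):
            rows.append({"threshold": res.threshold, "group_id": gid,
                         "members": ",".join(sorted(group))})
    pd.DataFrame(rows, columns=["threshold", "group_id", "members"]).to_csv(
        path, sep="\t", index=False)
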