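"""Fitted clonal-structure model over a multi-biopsy CCF matrix.

``ClonalStructureModel`` bundles the deconvolution thresholds;
``fit()`` runs deconvolution -> classification -> tree reconstruction ->
per-biopsy composition -> inter-lesion distances and returns a
``ClonalStructureResults`` carrying all of it plus a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .ccf import CCFMatrix
from .deconvolution import (
    DEFAULT_ABSENT_THRESHOLD,
    DEFAULT_BANDWIDTH_FLOOR,
    DEFAULT_CLONAL_THRESHOLD,
    DEFAULT_MERGE_TOL,
    DEFAULT_MIN_CLUSTER_SIZE,
    CCFCluster,
    deconvolute,
)
from .phylogeny import (
    DEFAULT_SUM_RULE_TOL,
    CloneTree,
    Composition,
    composition,
    build_tree,
    distance_matrix,
    to_newick,
)


@dataclass
class ClonalStructureModel:
    """Clonal-structure model for a mutation x sample CCF matrix.

    Deconvolution runs on the *raw* (unclamped) CCFs with inverse-variance
    weights; final cluster centers are clipped to [0, 1].
    """

    matrix: CCFMatrix
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
    merge_tol: float = DEFAULT_MERGE_TOL
    bandwidth_floor: float = DEFAULT_BANDWIDTH_FLOOR
    clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD
    absent_threshold: float = DEFAULT_ABSENT_THRESHOLD
    sum_rule_tol: float = DEFAULT_SUM_RULE_TOL

    def fit(self) -> "ClonalStructureResults":
        clusters = deconvolute(
            self.matrix.raw,
            variance=self.matrix.variance,
            min_cluster_size=self.min_cluster_size,
            merge_tol=self.merge_tol,
            bandwidth_floor=self.bandwidth_floor,
            clonal_threshold=self.clonal_threshold,
            absent_threshold=self.absent_threshold,
        )
        tree = build_tree(clusters, sum_rule_tol=self.sum_rule_tol)
        compositions = {
            s: composition(tree, s, absent_threshold=self.absent_threshold)
            for s in self.matrix.samples
        }
        distances = distance_matrix(self.matrix.ccf)
        return ClonalStructureResults(
            model=self,
            clusters=clusters,
            tree=tree,
            compositions=compositions,
            distances=distances,
        )


@dataclass
class ClonalStructureResults:
    """Results object: clusters, clone tree, compositions, distances."""

    model: ClonalStructureModel
    clusters: list[CCFCluster]
    tree: CloneTree
    compositions: dict[str, Composition]
    distances: pd.DataFrame

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_table(self) -> pd.DataFrame:
        samples = self.model.matrix.samples
        rows = []
        for cl in self.clusters:
            row = {
                "cluster": cl.cluster_id,
                "n_mutations": cl.weight,
                "classification": cl.classification,
                "subclonal": cl.subclonal,
                "parent": self.tree.parent.get(cl.cluster_id, ""),
                "forced_root": cl.cluster_id in self.tree.forced_root,
            }
            for s in samples:
                row[f"ccf_{s}"] = cl.centers.get(s, float("nan"))
            rows.append(row)
        return pd.DataFrame(rows)

    def assignment_table(self) -> pd.DataFrame:
        rows = []
        for cl in self.clusters:
            for key in cl.members:
                rows.append((*key, cl.cluster_id, cl.classification))
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "cluster", "classification"]
        ).sort_values(["chrom", "pos"], kind="stable", ignore_index=True)

    def composition_table(self) -> pd.DataFrame:
        return pd.concat(
            [c.to_frame() for c in self.compositions.values()], ignore_index=True
        )

    def newick(self, branch_lengths: bool = True) -> str:
        return to_newick(self.tree, branch_lengths=branch_lengths)

    def summary(self) -> str:
        lines = [
            "Clonal structure fit",
            f"  mutations: {self.model.matrix.n_mutations}  "
            f"samples: {len(self.model.matrix.samples)}  clusters: {self.n_clusters}",
            f"  tree: {self.newick(branch_lengths=False)}",
            "",
            self.cluster_table().to_string(index=False, float_format="%.3f"),
            "",
            "Per-biopsy composition (exclusive cell fractions):",
        ]
        for s, comp in self.compositions.items():
            parts = ", ".join(f"{n}: {f:.1%}" for n, f in sorted(comp.fractions.items()))
            lines.append(f"  {s}: {parts}")
        lines.append("")
        lines.append("Inter-lesion distances (mean |dCCF|):")
        lines.append(self.distances.to_string(float_format="%.3f"))
        return "\n".join(lines)
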