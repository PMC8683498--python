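"""Clone-tree reconstruction from cluster CCFs.

Two constraints order clones into a lineage tree:

* containment — a descendant clone cannot exceed its ancestor's CCF in any
  sample (every cell carrying the child's mutations also carries the
  parent's);
* the pigeonhole sum rule — sibling subclones occupy disjoint cell
  populations, so their CCFs must sum to at most the parent's in every
  sample.

The builder is greedy: clusters are attached in descending total-CCF order,
each to the *deepest* existing node that satisfies both constraints within an
absolute tolerance (default 0.10, sized for binomial noise at ~150x depth),
with deterministic cluster-id tie-breaks.  A cluster with no feasible parent
is attached to the root and flagged rather than aborting the run.

Per-biopsy composition assigns each node the cell fraction it holds
exclusively: its CCF minus its children's, floored at zero.  Inter-lesion
distance is the mean absolute per-mutation CCF difference (an L1 metric;
"normal" is the all-zero pseudo-sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .deconvolution import CCFCluster
from .errors import InputError, ModelAssumptionError

logger = logging.getLogger(__name__)

DEFAULT_SUM_RULE_TOL = 0.10
NORMAL_SAMPLE = "normal"


@dataclass
class CloneTree:
    """Rooted clone tree over CCF clusters."""

    clusters: dict[str, CCFCluster]
    parent: dict[str, str]  # child -> parent
    root_id: str
    forced_root: set[str] = field(default_factory=set)  # attached with warning

    def children(self, node_id: str) -> list[str]:
        return sorted(c for c, p in self.parent.items() if p == node_id)

    def depth(self, node_id: str) -> int:
        d = 0
        while node_id != self.root_id:
            node_id = self.parent[node_id]
            d += 1
        return d

    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.parent.items())

    @property
    def samples(self) -> list[str]:
        return list(self.clusters[self.root_id].centers)

    def ccf(self, node_id: str, sample_id: str) -> float:
        c = self.clusters[node_id].centers.get(sample_id, 0.0)
        return c if np.isfinite(c) else 0.0

    def validate(self, tol: float = DEFAULT_SUM_RULE_TOL) -> None:
        """Post-construction check of containment and the sum rule."""
        for child, parent in self.parent.items():
            if child in self.forced_root:
                continue
            for s in self.samples:
                if self.ccf(child, s) > self.ccf(parent, s) + tol:
                    raise ModelAssumptionError(
                        f"containment violated: {child} > {parent} in {s}"
                    )
        for node in self.clusters:
            kids = [c for c in self.children(node) if c not in self.forced_root]
            for s in self.samples:
                total = sum(self.ccf(c, s) for c in kids)
                if total > self.ccf(node, s) + tol:
                    raise ModelAssumptionError(
                        f"sum rule violated at {node} in {s}: children sum {total:.3f}"
                    )


@dataclass
class Composition:
    """Per-biopsy cellular fractions of the tree nodes."""

    sample_id: str
    fractions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_id, "node": list(self.fractions),
             "fraction": list(self.fractions.values())}
        )


def infer_root(clusters: Sequence[CCFCluster]) -> CCFCluster:
    """The unique clonal-in-all-samples cluster is the most common ancestor."""
    clonal = [c for c in clusters if c.classification == "clonal_all"]
    if len(clonal) != 1:
        raise ModelAssumptionError(
            f"need exactly one clonal_all cluster to root the tree, found {len(clonal)}"
        )
    return clonal[0]


def _feasible(
    tree_parent: dict[str, str],
    clusters: dict[str, CCFCluster],
    samples: Sequence[str],
    child: CCFCluster,
    candidate_id: str,
    tol: float,
) -> bool:
    cand = clusters[candidate_id]

    def ccf(cl: CCFCluster, s: str) -> float:
        v = cl.centers.get(s, 0.0)
        return v if np.isfinite(v) else 0.0

    for s in samples:
        if ccf(child, s) > ccf(cand, s) + tol:
            return False
    siblings = [c for c, p in tree_parent.items() if p == candidate_id]
    for s in samples:
        total = ccf(child, s) + sum(ccf(clusters[c], s) for c in siblings)
        if total > ccf(cand, s) + tol:
            return False
    return True


def build_tree(
    clusters: Sequence[CCFCluster], sum_rule_tol: float = DEFAULT_SUM_RULE_TOL
) -> CloneTree:
    """Greedy-ordered clone-tree reconstruction with backtracking.

    Clusters are attached in descending total-CCF order, preferring the
    deepest feasible parent (ties by cluster id).  When a choice leaves a
    later cluster without a feasible parent the search backtracks, so a
    fully constraint-satisfying tree is found whenever one exists (bounded
    exploration; deterministic).  Only genuinely unplaceable clusters are
    attached to the root with a warning flag.
    """
    clusters = list(clusters)
    for cl in clusters:
        if cl.classification is None:
            from .deconvolution import classify_cluster

            classify_cluster(cl)
    root = infer_root(clusters)
    samples = list(root.centers)
    by_id = {c.cluster_id: c for c in clusters}
    if len(by_id) != len(clusters):
        raise InputError("duplicate cluster ids")

    def total_ccf(cl: CCFCluster) -> float:
        return float(np.nansum([cl.centers.get(s, 0.0) for s in samples]))

    pending = sorted(
        (c for c in clusters if c.cluster_id != root.cluster_id),
        key=lambda c: (-total_ccf(c), c.cluster_id),
    )

    def depth_of(parent: dict[str, str], node_id: str) -> int:
        d = 0
        while node_id != root.cluster_id:
            node_id = parent[node_id]
            d += 1
        return d

    budget = [200_000]  # bound on explored attachments; ample for real data

    def search(i: int, parent: dict[str, str]) -> Optional[dict[str, str]]:
        if i == len(pending):
            return dict(parent)
        cl = pending[i]
        placed = [root.cluster_id] + [c.cluster_id for c in pending[:i]]
        candidates = [
            nid for nid in placed
            if _feasible(parent, by_id, samples, cl, nid, sum_rule_tol)
        ]
        candidates.sort(key=lambda nid: (-depth_of(parent, nid), nid))
        for nid in candidates:
            if budget[0] <= 0:
                return None
            budget[0] -= 1
            parent[cl.cluster_id] = nid
            done = search(i + 1, parent)
            if done is not None:
                return done
            del parent[cl.cluster_id]
        return None

    solution = search(0, {})
    forced: set[str] = set()
    if solution is None:
        # no fully feasible tree: fall back to one-pass greedy, flagging the
        # clusters that cannot be placed
        solution = {}
        for cl in pending:
            placed = [root.cluster_id] + list(solution)
            candidates = [
                nid for nid in placed
                if _feasible(solution, by_id, samples, cl, nid, sum_rule_tol)
            ]
            if candidates:
                best = sorted(
                    candidates, key=lambda nid: (-depth_of(solution, nid), nid)
                )[0]
                solution[cl.cluster_id] = best
            else:
                logger.warning(
                    "cluster %s has no feasible parent; attaching to root with flag",
                    cl.cluster_id,
                )
                solution[cl.cluster_id] = root.cluster_id
                forced.add(cl.cluster_id)

    tree = CloneTree(
        clusters=by_id, parent=solution, root_id=root.cluster_id, forced_root=forced
    )
    tree.validate(sum_rule_tol)
    return tree


def composition(
    tree: CloneTree, sample_id: str, absent_threshold: float = 0.10
) -> Composition:
    """Exclusive cellular fraction per node in one biopsy.

    ``fraction(v) = ccf_s(v) - sum(children ccf_s)``, floored at 0; nodes
    whose CCF is below ``absent_threshold`` in the sample are omitted, as are
    force-rooted clusters (no feasible placement): a clone that cannot be
    placed consistently in the lineage receives no cell mass.
    """
    fractions: dict[str, float] = {}
    for node in tree.clusters:
        if node in tree.forced_root:
            continue
        c = tree.ccf(node, sample_id)
        if c < absent_threshold:
            continue
        kids_total = sum(
            tree.ccf(k, sample_id)
            for k in tree.children(node)
            if k not in tree.forced_root
        )
        fractions[node] = max(0.0, c - kids_total)
    return Composition(sample_id=sample_id, fractions=fractions)


def biopsy_distance(
    ccf: pd.DataFrame, sample_a: str, sample_b: str
) -> float:
    """Mean absolute per-mutation CCF difference between two biopsies.

    ``"normal"`` denotes the all-zero pseudo-sample.  Missing CCFs are
    excluded pairwise; an empty shared universe is an error.
    """
    if len(ccf) == 0:
        raise InputError("empty mutation universe")

    def column(s: str) -> np.ndarray:
        if s == NORMAL_SAMPLE:
            return np.zeros(len(ccf))
        if s not in ccf.columns:
            raise InputError(f"sample {s!r} not in CCF matrix")
        return ccf[s].to_numpy(dtype=float)

    a = column(sample_a)
    b = column(sample_b)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if not ok.any():
        raise InputError("no shared (non-missing) mutations between samples")
    return float(np.mean(np.abs(a[ok] - b[ok])))


def distance_matrix(ccf: pd.DataFrame, include_normal: bool = True) -> pd.DataFrame:
    """Symmetric inter-lesion distance matrix, optionally with the synthetic
    all-zero "normal" baseline of the evolutionary-distance visualization."""
    samples = list(ccf.columns) + ([NORMAL_SAMPLE] if include_normal else [])
    out = pd.DataFrame(0.0, index=samples, columns=samples)
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            d = biopsy_distance(ccf, a, b)
            out.loc[a, b] = out.loc[b, a] = d
    return out


def to_newick(tree: CloneTree, branch_lengths: bool = True) -> str:
    """Newick serialization with cluster ids as labels and branch lengths =
    cluster-private mutation counts; sibling order is canonical (sorted)."""

    def render(node_id: str) -> str:
        kids = tree.children(node_id)
        label = node_id
        if branch_lengths and node_id != tree.root_id:
            label += f":{tree.clusters[node_id].n_private_mutations}"
        if not kids:
            return label
        return "(" + ",".join(render(k) for k in kids) + ")" + label

    return render(tree.root_id) + ";"
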