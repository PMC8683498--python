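"""Subclone deconvolution: mode seeking in CCF space.

Mutations from the same clone pile up around a common per-sample CCF; read
sampling smears each observation binomially.  The deconvolution is a
weighted kernel-density mode search (mean shift with a diagonal Gaussian
kernel): the per-coordinate bandwidth is the median binomial standard
deviation of the CCFs (floored at 0.05), each mutation climbs the density to
its mode, modes closer than ``merge_tol`` in every sample are merged, and
clusters smaller than ``min_cluster_size`` are dissolved into their nearest
neighbor.  Weights are inverse CCF variances.

Cluster centers are weighted means of member CCFs, clipped to [0, 1]; the
caller should pass *unclamped* CCFs so clonal clusters are not biased below 1
by the clamping pile-up.

Classification against per-sample presence:

* ``clonal_all`` — center at or above ``clonal_threshold`` in every sample;
* ``private:<sample>`` — present (center above ``absent_threshold``) in
  exactly one sample; a ``subclonal`` flag is retained when that center is
  below ``clonal_threshold``;
* ``shared_subclonal`` — everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import InputError, ModelAssumptionError

DEFAULT_MIN_CLUSTER_SIZE = 5
DEFAULT_MERGE_TOL = 0.10
DEFAULT_BANDWIDTH_FLOOR = 0.05
DEFAULT_CLONAL_THRESHOLD = 0.85
DEFAULT_ABSENT_THRESHOLD = 0.10


@dataclass
class CCFCluster:
    """A mutation cluster with per-sample CCF centers."""

    cluster_id: str
    centers: dict[str, float]
    members: list[tuple]
    classification: Optional[str] = None
    subclonal: bool = False
    n_private_mutations: int = 0  # alias for weight, used as branch length

    @property
    def weight(self) -> int:
        return len(self.members)

    def center_vector(self, samples: Sequence[str]) -> np.ndarray:
        return np.array([self.centers[s] for s in samples], dtype=float)


def classify_cluster(
    cluster: CCFCluster,
    clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD,
    absent_threshold: float = DEFAULT_ABSENT_THRESHOLD,
) -> str:
    """Total classification function over valid clusters (see module docs).

    Missing centers are treated as absent.  Sets ``cluster.subclonal`` as a
    side effect and returns the label.
    """
    centers = {s: (c if np.isfinite(c) else 0.0) for s, c in cluster.centers.items()}
    present = {s for s, c in centers.items() if c > absent_threshold}
    if centers and all(c >= clonal_threshold for c in centers.values()):
        cluster.subclonal = False
        label = "clonal_all"
    elif len(present) == 1:
        (sample,) = present
        cluster.subclonal = centers[sample] < clonal_threshold
        label = f"private:{sample}"
    else:
        cluster.subclonal = True
        label = "shared_subclonal"
    cluster.classification = label
    return label


def _mean_shift_modes(
    x: np.ndarray, w: np.ndarray, h: np.ndarray, max_iter: int = 200, tol: float = 1e-8
) -> np.ndarray:
    """Shift every point to its weighted-KDE mode (diagonal bandwidth)."""
    pts = x.copy()
    scaled_data = x / h
    for _ in range(max_iter):
        d2 = cdist(pts / h, scaled_data, metric="sqeuclidean")
        k = np.exp(-0.5 * d2) * w
        denom = k.sum(axis=1, keepdims=True)
        new = (k @ x) / denom
        if np.max(np.abs(new - pts)) < tol:
            pts = new
            break
        pts = new
    return pts


def deconvolute(
    ccf: pd.DataFrame,
    variance: Optional[pd.DataFrame] = None,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    merge_tol: float = DEFAULT_MERGE_TOL,
    bandwidth_floor: float = DEFAULT_BANDWIDTH_FLOOR,
    clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD,
    absent_threshold: float = DEFAULT_ABSENT_THRESHOLD,
) -> list[CCFCluster]:
    """Cluster a mutation x sample CCF table into subclones.

    ``ccf`` rows are mutation keys, columns samples; NaN marks missing
    observations (excluded from density estimation; rows with a missing
    coordinate are assigned to the nearest seed over their observed
    coordinates afterwards).  Returns clusters sorted by descending weight
    with deterministic ids C0, C1, ...
    """
    if ccf.shape[1] == 0:
        raise InputError("no samples in CCF matrix")
    samples = list(ccf.columns)
    values = ccf.to_numpy(dtype=float)
    complete = ~np.isnan(values).any(axis=1)
    partial = ~complete & ~np.isnan(values).all(axis=1)
    if complete.sum() == 0:
        raise InputError("all CCFs missing")
    if complete.sum() < min_cluster_size:
        raise InputError(
            f"only {int(complete.sum())} complete mutations; need >= {min_cluster_size}"
        )

    if variance is not None:
        var = variance.to_numpy(dtype=float)
        sd = np.sqrt(np.where(np.isnan(var), np.nan, var))
        # bandwidth = per-sample median binomial SD over *informative*
        # observations; exact-zero SDs (vaf = 0 wells) carry no noise scale
        sd_pos = np.where(sd > 0, sd, np.nan)
        with np.errstate(all="ignore"):
            h = np.nanmedian(sd_pos, axis=0)
        h = np.where(np.isfinite(h), h, 0.0)
        # regularized inverse-variance weights: 1/(var + typical var) keeps
        # exact-zero-variance observations (vaf = 0) finite and bounded
        mean_var = float(np.nanmean(var[var > 0])) if np.any(var > 0) else 1e-4
        w_full = 1.0 / (np.nan_to_num(var, nan=mean_var) + mean_var)
        w = w_full.mean(axis=1)
    else:
        h = np.zeros(len(samples))
        w = np.ones(values.shape[0])
    h = np.maximum(h, bandwidth_floor)

    x = values[complete]
    wx = w[complete]
    modes = _mean_shift_modes(x, wx, h)

    # merge modes into seeds: greedy in descending local density order
    d2 = cdist(modes / h, x / h, metric="sqeuclidean")
    density = (np.exp(-0.5 * d2) * wx).sum(axis=1)
    order = np.argsort(-density, kind="stable")
    seeds: list[np.ndarray] = []
    for idx in order:
        m = modes[idx]
        if not any(np.all(np.abs(m - s) < merge_tol) for s in seeds):
            seeds.append(m)
    seed_arr = np.vstack(seeds)

    assign = np.full(values.shape[0], -1, dtype=int)
    assign[complete] = np.argmin(cdist(x / h, seed_arr / h, metric="sqeuclidean"), axis=1)
    # partial rows: nearest seed over observed coordinates
    for i in np.where(partial)[0]:
        obs = ~np.isnan(values[i])
        d = ((values[i, obs] / h[obs] - seed_arr[:, obs] / h[obs]) ** 2).sum(axis=1)
        assign[i] = int(np.argmin(d))

    # dissolve undersized clusters into the nearest surviving seed
    def counts() -> np.ndarray:
        return np.bincount(assign[assign >= 0], minlength=seed_arr.shape[0])

    alive = set(range(seed_arr.shape[0]))
    while True:
        c = counts()
        small = [k for k in sorted(alive) if 0 < c[k] < min_cluster_size]
        if not small or len(alive) == 1:
            break
        k = min(small, key=lambda q: c[q])
        others = [q for q in alive if q != k]
        d = ((seed_arr[k] / h - seed_arr[others] / h) ** 2).sum(axis=1)
        target = others[int(np.argmin(d))]
        assign[assign == k] = target
        alive.discard(k)
    c = counts()
    if all(c[k] < min_cluster_size for k in alive):
        raise ModelAssumptionError("no cluster reaches min_cluster_size")

    def center_of(member_idx: np.ndarray) -> np.ndarray:
        out = np.empty(len(samples))
        for j in range(len(samples)):
            vals = values[member_idx, j]
            wts = w[member_idx]
            ok = ~np.isnan(vals)
            out[j] = np.average(vals[ok], weights=wts[ok]) if ok.any() else np.nan
        return out

    # iterative center-based merging: clusters whose (weighted-mean, clipped)
    # centers agree within merge_tol in every sample collapse into one,
    # largest first; comparison happens in CCF space [0, 1] so the unclamped
    # upper tail of a clonal cluster cannot hold a satellite apart
    while True:
        groups = {k: np.where(assign == k)[0] for k in sorted(alive)}
        centers_by = {k: np.clip(center_of(idx), 0.0, 1.0) for k, idx in groups.items()}
        merged = False
        for k in sorted(alive, key=lambda q: -groups[q].size):
            for other in sorted(alive, key=lambda q: -groups[q].size):
                if other == k or other not in alive or k not in alive:
                    continue
                diff = np.abs(centers_by[k] - centers_by[other])
                if np.all(np.nan_to_num(diff, nan=0.0) < merge_tol):
                    assign[assign == other] = k
                    alive.discard(other)
                    merged = True
                    break
            if merged:
                break
        if not merged:
            break

    keys = list(ccf.index)
    clusters: list[CCFCluster] = []
    for k in sorted(alive):
        member_idx = np.where(assign == k)[0]
        if member_idx.size == 0:
            continue
        raw_center = center_of(member_idx)
        centers = {
            s: (float(np.clip(raw_center[j], 0.0, 1.0))
                if np.isfinite(raw_center[j]) else float("nan"))
            for j, s in enumerate(samples)
        }
        clusters.append(
            CCFCluster(
                cluster_id="",
                centers=centers,
                members=[keys[i] for i in member_idx],
            )
        )
    clusters.sort(
        key=lambda cl: (-cl.weight, -np.nansum(list(cl.centers.values())))
    )
    for rank, cl in enumerate(clusters):
        cl.cluster_id = f"C{rank}"
        cl.n_private_mutations = cl.weight
        classify_cluster(cl, clonal_threshold, absent_threshold)
    return clusters


def pairwise_clusters(
    ccf: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    variance: Optional[pd.DataFrame] = None,
    **kwargs,
) -> tuple[list[CCFCluster], pd.DataFrame]:
    """Deconvolute the 2-column submatrix of two biopsies.

    Returns the clusters and a per-mutation scatter table
    (ccf_a, ccf_b, cluster, classification) ready for plotting/export.
    """
    for s in (sample_a, sample_b):
        if s not in ccf.columns:
            raise InputError(f"sample {s!r} not in CCF matrix")
    sub = ccf[[sample_a, sample_b]]
    sub = sub[~sub.isna().all(axis=1)]
    var = variance[[sample_a, sample_b]].loc[sub.index] if variance is not None else None
    clusters = deconvolute(sub, var, **kwargs)
    rows = {}
    for cl in clusters:
        for key in cl.members:
            rows[key] = (cl.cluster_id, cl.classification)
    table = pd.DataFrame(
        {
            "ccf_a": sub[sample_a],
            "ccf_b": sub[sample_b],
            "cluster": [rows.get(k, (None, None))[0] for k in sub.index],
            "classification": [rows.get(k, (None, None))[1] for k in sub.index],
        },
        index=sub.index,
    )
    return clusters, table
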