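"""Independent oracles used only by the test suite.

* An EM binomial-mixture fitter with BIC model selection: the reference
  answer for 1-D CCF deconvolution on well-separated components.
* Brute-force enumeration of all parent assignments satisfying containment
  and the pigeonhole sum rule: the reference answer for clone-tree topology
  (and the uniqueness check that makes greedy-vs-oracle comparison fair).

Both are deliberately naive and independent of the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import binom


def _em_binomial(alt, depth, k, p_init, max_iter=500, tol=1e-10):
    alt = np.asarray(alt, dtype=int)
    depth = np.asarray(depth, dtype=int)
    n = alt.size
    pi = np.full(k, 1.0 / k)
    p = np.asarray(p_init, dtype=float).copy()
    last_ll = -np.inf
    for _ in range(max_iter):
        logr = np.log(pi)[None, :] + binom.logpmf(
            alt[:, None], depth[:, None], np.clip(p, 1e-9, 1 - 1e-9)[None, :]
        )
        m = logr.max(axis=1, keepdims=True)
        ll = float(np.sum(m.ravel() + np.log(np.exp(logr - m).sum(axis=1))))
        r = np.exp(logr - m)
        r /= r.sum(axis=1, keepdims=True)
        pi = r.mean(axis=0)
        p = (r * alt[:, None]).sum(axis=0) / np.maximum((r * depth[:, None]).sum(axis=0), 1e-12)
        if abs(ll - last_ll) < tol:
            break
        last_ll = ll
    return ll, pi, p


def em_binomial_mixture_bic(alt, depth, k_max=5):
    """Fit binomial mixtures for k = 1..k_max with deterministic quantile
    initializations, select k by BIC.  Returns (k, success-rate centers in
    VAF space sorted ascending, mixing weights)."""
    alt = np.asarray(alt, dtype=int)
    depth = np.asarray(depth, dtype=int)
    n = alt.size
    vaf = alt / np.maximum(depth, 1)
    best = None
    for k in range(1, k_max + 1):
        inits = [np.quantile(vaf, (np.arange(k) + 0.5) / k)]
        if k > 1:  # second deterministic init: equal spacing over the range
            inits.append(np.linspace(vaf.min() + 1e-3, vaf.max() - 1e-3, k))
        for p0 in inits:
            ll, pi, p = _em_binomial(alt, depth, k, p0)
            n_params = 2 * k - 1
            bic = -2.0 * ll + n_params * np.log(n)
            if best is None or bic < best[0] - 1e-9:
                best = (bic, k, pi, p)
    _, k, pi, p = best
    order = np.argsort(p)
    return k, p[order], pi[order]


def feasible_trees(centers: dict[str, np.ndarray], root_id: str, tol: float):
    """All parent maps rooted at ``root_id`` satisfying containment and the
    sum rule within ``tol``, as a list of frozensets of (child, parent)."""
    ids = sorted(centers)
    others = [i for i in ids if i != root_id]
    valid = []
    for parents in itertools.product(ids, repeat=len(others)):
        pmap = dict(zip(others, parents))
        if any(c == p for c, p in pmap.items()):
            continue
        # rooted-tree check: every node reaches the root without cycling
        ok = True
        for node in others:
            seen = set()
            cur = node
            while cur != root_id:
                if cur in seen or cur not in pmap:
                    ok = False
                    break
                seen.add(cur)
                cur = pmap[cur]
            if not ok:
                break
        if not ok:
            continue
        # containment
        for child, parent in pmap.items():
            if np.any(centers[child] > centers[parent] + tol):
                ok = False
                break
        if not ok:
            continue
        # pigeonhole sum rule
        for node in ids:
            kids = [c for c, p in pmap.items() if p == node]
            if kids:
                total = np.sum([centers[c] for c in kids], axis=0)
                if np.any(total > centers[node] + tol):
                    ok = False
                    break
        if ok:
            valid.append(frozenset(pmap.items()))
    return valid
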