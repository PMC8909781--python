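"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (BFS flood fill, exhaustive
enumeration, direct rule reading) and shares no code with the package paths
it validates.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np

_OFFSETS = {
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    18: None,
    26: None,
}


def _offsets(connectivity: int):
    if connectivity == 6:
        return _OFFSETS[6]
    out = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        if connectivity == 18 and sum(abs(x) for x in d) == 3:
            continue
        out.append(d)
    return out


def bfs_components(binary: np.ndarray, connectivity: int = 26) -> list[set]:
    """Flood-fill partition of True voxels into connected components."""
    binary = np.asarray(binary).astype(bool)
    offsets = _offsets(connectivity)
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for d in offsets:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[i] < binary.shape[i] for i in range(3)):
                    if binary[w] and not seen[w]:
                        seen[w] = True
                        queue.append(w)
        comps.append(comp)
    return comps


def threshold_segments(grid, voi, threshold, connectivity=26, strict=True):
    """Voxel-scan + BFS segmentation oracle; returns a set of frozensets."""
    grid = np.asarray(grid, dtype=float)
    voi = np.asarray(voi).astype(bool)
    supra = (grid > threshold) if strict else (grid >= threshold)
    return {frozenset(c) for c in bfs_components(supra & voi, connectivity)}


def best_overlap_match(pre_sets: dict, post_set: set):
    """Largest-overlap pre lesion for one post voxel set (ties: smaller key)."""
    best_key, best = None, 0
    for key in sorted(pre_sets):
        ov = len(post_set & pre_sets[key])
        if ov > best:
            best_key, best = key, ov
    return best_key


def mpercist_oracle(pre_lesions, post_matched, new_lesions):
    """Direct reading of the four response rules on summary values.

    ``pre_lesions``: list of (suvmax, tv) baseline values; ``post_matched``:
    list of ((suvmax, tv), (suvmax, tv)) matched pairs; ``new_lesions``:
    list of (suvmax, tv) for novel lesions. Whole-body indices aggregate all
    residual lesions, matched and new alike. Written as independent
    predicate checks, not a rule cascade.
    """
    post_all = [p for _, p in post_matched] + list(new_lesions)
    if not post_all:
        return "CR"
    progressive = len(new_lesions) >= 2
    for (s0, v0), (s1, v1) in post_matched:
        if v1 >= 1.3 * v0 or s1 >= 1.3 * s0:
            progressive = True
    wb_s0 = max(s for s, _ in pre_lesions)
    wb_v0 = sum(v for _, v in pre_lesions)
    wb_s1 = max(s for s, _ in post_all)
    wb_v1 = sum(v for _, v in post_all)
    if wb_v1 >= 1.3 * wb_v0 or wb_s1 >= 1.3 * wb_s0:
        progressive = True
    if progressive:
        return "PD"
    responding = wb_s1 < 0.7 * wb_s0 and wb_v1 < 0.7 * wb_v0
    return "PR" if responding else "SD"


# ---------------------------------------------------------------------------
# Exhaustive statistics


def wilcoxon_exact_p(diffs) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign patterns (midranks)."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    r = rankdata(np.abs(d))
    mu = r.sum() / 2.0
    w_obs = r[d > 0].sum()
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(ri for s, ri in zip(signs, r) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / 2**n


def mwu_exact_p(a, b) -> float:
    """Two-sided Mann-Whitney p by enumerating all group assignments.

    U is computed by direct pairwise comparison counts (not via rank sums).
    """
    a = list(map(float, a))
    b = list(map(float, b))
    n_a = len(a)

    def u_of(x, y):
        return sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in x for yi in y)

    pooled = a + b
    mu = n_a * len(b) / 2.0
    u_obs = u_of(a, b)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_of(ga, gb)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


def spearman_exact_p(x, y) -> float:
    """Two-sided exact permutation p for Spearman's rho via n! enumeration."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)

    def rho(u, v):
        u = np.asarray(u, float)
        v = np.asarray(v, float)
        uc, vc = u - u.mean(), v - v.mean()
        return float(uc @ vc / np.sqrt((uc @ uc) * (vc @ vc)))

    obs = abs(rho(rx, ry))
    count = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho(rx, perm)) >= obs - 1e-12:
            count += 1
    return count / total
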