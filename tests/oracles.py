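"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately naive (flood fill, exhaustive pair enumeration,
hill climbing, explicit ranking) and shares no code with the library paths
it checks.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np


def neighbours(connectivity: int):
    """Offsets of the 6/18/26 neighbourhood."""
    offs = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(x) for x in d)
        if (connectivity == 6 and order == 1) or \
           (connectivity == 18 and order <= 2) or connectivity == 26:
            offs.append(d)
    return offs


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Partition of True voxels into connected components via BFS."""
    offs = neighbours(connectivity)
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            comp.add(v)
            for d in offs:
                w = tuple(a + b for a, b in zip(v, d))
                if all(0 <= c < s for c, s in zip(w, mask.shape)) \
                        and mask[w] and not seen[w]:
                    seen[w] = True
                    q.append(w)
        comps.append(frozenset(comp))
    return comps


def steepest_ascent_basin(field: np.ndarray, start, connectivity: int = 26,
                          mask: np.ndarray | None = None):
    """Hill-climb from a voxel to its regional maximum (strict ascent).

    Assumes no ties along the path (the caller constructs separable fields).
    Returns the maximum's coordinates.
    """
    offs = neighbours(connectivity)
    v = tuple(start)
    while True:
        best, best_val = v, field[v]
        for d in offs:
            w = tuple(a + b for a, b in zip(v, d))
            if not all(0 <= c < s for c, s in zip(w, field.shape)):
                continue
            if mask is not None and not mask[w]:
                continue
            if field[w] > best_val:
                best, best_val = w, field[w]
        if best == v:
            return v
        v = best


def lesion_pair_counts(cand: np.ndarray, ref: np.ndarray, connectivity: int):
    """Exhaustive component-pair overlap enumeration -> (tp, fp, fn)."""
    cand_comps = flood_fill_components(cand.astype(bool), connectivity)
    ref_comps = flood_fill_components(ref.astype(bool), connectivity)
    cand_any = cand.astype(bool)
    tp = sum(1 for rc in ref_comps
             if any(cand_any[v] for v in rc))
    fn = len(ref_comps) - tp
    ref_any = ref.astype(bool)
    fp = sum(1 for cc in cand_comps
             if not any(ref_any[v] for v in cc))
    return tp, fp, fn


def spearman_rank_pearson(x, y) -> float:
    """Spearman via explicit average ranks then the Pearson formula."""
    def ranks(a):
        a = np.asarray(a, dtype=float)
        order = np.argsort(a, kind="stable")
        r = np.empty(len(a))
        i = 0
        sorted_a = a[order]
        while i < len(a):
            j = i
            while j + 1 < len(a) and sorted_a[j + 1] == sorted_a[i]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
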