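"""Independent brute-force oracles used by the test-suite.

These deliberately avoid the package's production code paths: the contact
oracle is a plain O(N^2) numpy computation, the image oracle enumerates
all 27 periodic translations, and the component oracle is a hand-written
breadth-first search.
"""

from __future__ import annotations

import numpy as np


def brute_force_min_image(a, b, box) -> float:
    """Minimum distance over the 27 periodic images (coords within the box)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    best = np.inf
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                shift = box * np.array([i, j, k], dtype=float)
                best = min(best, float(np.linalg.norm(a - (b + shift))))
    return best


def all_pairs_contacts(prot_pos, lip_pos, box, threshold) -> set[tuple[int, int]]:
    """O(N^2) periodic contact search: indices into the two position arrays."""
    prot_pos = np.asarray(prot_pos, dtype=float)
    lip_pos = np.asarray(lip_pos, dtype=float)
    box = np.asarray(box, dtype=float)
    delta = prot_pos[:, None, :] - lip_pos[None, :, :]
    delta -= box * np.round(delta / box)
    d2 = np.sum(delta * delta, axis=-1)
    p, l = np.where(d2 < threshold * threshold)
    return set(zip(p.tolist(), l.tolist()))


def bfs_components(nodes, edges) -> list[list]:
    """Connected components by breadth-first search, same ordering contract
    as memlens.network.components (size desc, then smallest node)."""
    adj: dict = {n: set() for n in nodes}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    seen: set = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        queue = [start]
        seen.add(start)
        comp = []
        while queue:
            node = queue.pop(0)
            comp.append(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        comps.append(sorted(comp))
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps
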