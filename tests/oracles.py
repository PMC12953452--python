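"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — O(n²) pairwise loops and
direct transcriptions of textbook formulas — and shares no code with
the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_dbscan(
    points: np.ndarray, eps: float, min_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Reference DBSCAN via explicit pairwise distances.

    Returns ``(labels, roles)`` with labels -1 for noise and roles
    0=noise, 1=border, 2=core.  Core components are connected via
    pairwise distance <= eps; border points attach to the nearest core
    within eps (deterministic tie-break by core index).
    """
    n = len(points)
    labels = np.full(n, -1, dtype=int)
    roles = np.zeros(n, dtype=int)
    if n == 0:
        return labels, roles
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    neighbour_counts = (d <= eps).sum(axis=1)  # includes self
    core = neighbour_counts >= min_samples
    roles[core] = 2

    # connected components of cores (BFS)
    comp = np.full(n, -1, dtype=int)
    next_label = 0
    for start in range(n):
        if not core[start] or comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = next_label
        while stack:
            i = stack.pop()
            for j in range(n):
                if core[j] and comp[j] < 0 and d[i, j] <= eps:
                    comp[j] = next_label
                    stack.append(j)
        next_label += 1
    labels[core] = comp[core]

    for j in range(n):
        if core[j]:
            continue
        best, best_dist = -1, np.inf
        for i in range(n):
            if core[i] and d[i, j] <= eps and d[i, j] < best_dist:
                best, best_dist = i, d[i, j]
        if best >= 0:
            labels[j] = labels[best]
            roles[j] = 1
    return labels, roles


def labels_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two labelings agree up to a permutation of cluster ids."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    if not ((a == -1) == (b == -1)).all():
        return False
    mapping: dict[int, int] = {}
    reverse: dict[int, int] = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(x, y) != y:
            return False
        if reverse.setdefault(y, x) != x:
            return False
    return True


def brute_force_best_assignment(iou_matrix: np.ndarray) -> float:
    """Maximum total IoU over all one-to-one assignments (exhaustive)."""
    nt, nd = iou_matrix.shape
    best = 0.0
    if nt <= nd:
        for cols in itertools.permutations(range(nd), nt):
            best = max(best, sum(iou_matrix[r, c] for r, c in enumerate(cols)))
    else:
        for rows in itertools.permutations(range(nt), nd):
            best = max(best, sum(iou_matrix[r, c] for c, r in enumerate(rows)))
    return best


def precision_oracle(tp: int, fp: int) -> float:
    return tp / (tp + fp) if tp + fp else 1.0


def recall_oracle(tp: int, fn: int) -> float:
    return tp / (tp + fn)


def ap_oracle(points: list[tuple[float, float]]) -> float:
    total = 0.0
    prev = 0.0
    for p, r in points:
        total += p * (r - prev)
        prev = r
    return total


def acc_oracle(y: int, y_hat: int) -> float:
    return (1 - abs(y_hat - y) / y) * 100.0


def r2_oracle(pairs: list[tuple[float, float]]) -> float:
    ys = [p[0] for p in pairs]
    mean = sum(ys) / len(ys)
    ss_res = sum((y - yh) ** 2 for y, yh in pairs)
    ss_tot = sum((y - mean) ** 2 for y in ys)
    return 1 - ss_res / ss_tot
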