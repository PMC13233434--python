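"""Independent oracles used by the test suite.

These deliberately do not share code with the package: the quaternion
superposition follows Horn's closed-form absolute-orientation method, and the
interval matcher enumerates every one-to-one assignment.
"""

from __future__ import annotations

import itertools

import numpy as np


def quaternion_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Least-squares superposition RMSD via Horn's quaternion method."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    Sxx = ac.T @ bc
    N = np.array(
        [
            [Sxx[0, 0] + Sxx[1, 1] + Sxx[2, 2], Sxx[1, 2] - Sxx[2, 1], Sxx[2, 0] - Sxx[0, 2], Sxx[0, 1] - Sxx[1, 0]],
            [Sxx[1, 2] - Sxx[2, 1], Sxx[0, 0] - Sxx[1, 1] - Sxx[2, 2], Sxx[0, 1] + Sxx[1, 0], Sxx[2, 0] + Sxx[0, 2]],
            [Sxx[2, 0] - Sxx[0, 2], Sxx[0, 1] + Sxx[1, 0], -Sxx[0, 0] + Sxx[1, 1] - Sxx[2, 2], Sxx[1, 2] + Sxx[2, 1]],
            [Sxx[0, 1] - Sxx[1, 0], Sxx[2, 0] + Sxx[0, 2], Sxx[1, 2] + Sxx[2, 1], -Sxx[0, 0] - Sxx[1, 1] + Sxx[2, 2]],
        ]
    )
    lam = np.linalg.eigvalsh(N)[-1]
    e0 = (ac**2).sum() + (bc**2).sum()
    msd = max(0.0, (e0 - 2.0 * lam) / len(a))
    return float(np.sqrt(msd))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def interval_iou(a, b) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    return inter / ((a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter)


def optimal_tp_count(predicted, reference, iou_min=0.5) -> int:
    """Brute-force maximum one-to-one matching with IoU >= iou_min.

    Enumerates every injective assignment of predictions to references
    (feasible for <= 6 intervals per side).
    """
    eligible = {
        (i, j)
        for i, p in enumerate(predicted)
        for j, r in enumerate(reference)
        if p[0] == r[0] and interval_iou(p[1:], r[1:]) >= iou_min
    }
    n, m = len(predicted), len(reference)
    best = 0
    for k in range(min(n, m), 0, -1):
        for preds in itertools.combinations(range(n), k):
            for refs in itertools.permutations(range(m), k):
                if all((i, j) in eligible for i, j in zip(preds, refs)):
                    return k
    return best
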