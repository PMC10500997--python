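"""Independent brute-force oracles shared by the test suite.

These deliberately re-derive each quantity from first principles (textbook
formulas, direct enumeration) and never call the implementation paths they
are used to check.
"""

import numpy as np


def lj(r, sigma, eps):
    """Lennard-Jones 12-6 closed form."""
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6**2 - sr6)


def brute_force_dihedral(p0, p1, p2, p3):
    """Signed dihedral (degrees) by direct vector algebra."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    return np.degrees(np.arctan2(y, np.dot(n1, n2)))


def quaternion_rmsd(x, y):
    """Optimal-superposition RMSD via the quaternion eigenvalue method."""
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    R = x.T @ y
    K = np.empty((4, 4))
    K[0, 0] = R[0, 0] + R[1, 1] + R[2, 2]
    K[0, 1] = K[1, 0] = R[1, 2] - R[2, 1]
    K[0, 2] = K[2, 0] = R[2, 0] - R[0, 2]
    K[0, 3] = K[3, 0] = R[0, 1] - R[1, 0]
    K[1, 1] = R[0, 0] - R[1, 1] - R[2, 2]
    K[1, 2] = K[2, 1] = R[0, 1] + R[1, 0]
    K[1, 3] = K[3, 1] = R[0, 2] + R[2, 0]
    K[2, 2] = -R[0, 0] + R[1, 1] - R[2, 2]
    K[2, 3] = K[3, 2] = R[1, 2] + R[2, 1]
    K[3, 3] = -R[0, 0] - R[1, 1] + R[2, 2]
    lam_max = np.linalg.eigvalsh(K)[-1]
    msd = max(((x**2).sum() + (y**2).sum() - 2.0 * lam_max) / x.shape[0], 0.0)
    return np.sqrt(msd)


def brute_force_dbscan(dist, eps, min_samples):
    """Textbook DBSCAN by BFS over core points (precomputed distances)."""
    n = dist.shape[0]
    labels = np.full(n, -1)
    neighbors = [np.flatnonzero(dist[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_samples for nb in neighbors])
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        stack.append(k)
        cluster += 1
    return labels
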