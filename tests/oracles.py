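"""Independent brute-force oracles used across the test suite.

Everything here is deliberately written from first principles (direct
charge sums, two-pass statistics, exhaustive enumeration) and shares no
code with the implementation paths it checks.
"""

import numpy as np


def charge_sum_quadrupole(charges, positions, point):
    """Direct Buckingham sum Θαβ = ½ Σ q (3 aα aβ − |a|² δαβ) about ``point`` (bohr)."""
    total = np.zeros((3, 3))
    for q, r in zip(charges, positions):
        a = np.asarray(r, float) - np.asarray(point, float)
        total += 0.5 * q * (3.0 * np.outer(a, a) - float(a @ a) * np.eye(3))
    return total


def spherical_from_cartesian_matrix(m):
    """(Q20, Q21c, Q21s, Q22c, Q22s) read off a traceless Cartesian matrix."""
    s3 = np.sqrt(3.0)
    return np.array(
        [
            m[2, 2],
            2.0 / s3 * m[0, 2],
            2.0 / s3 * m[1, 2],
            (m[0, 0] - m[1, 1]) / s3,
            2.0 / s3 * m[0, 1],
        ]
    )


def greedy_ward_reference(x):
    """Exhaustive greedy Ward merges computed via the ESS identity.

    ΔESS(A, B) = ESS(A ∪ B) − ESS(A) − ESS(B), with ESS the total squared
    deviation of member rows from their centroid — an algebraically
    different route than the centroid-distance formula used by the
    implementation.  Ties break toward the smallest (a, b) id pair.
    Returns a list of (a, b, height, size) merge records in scipy-style
    id numbering.
    """
    x = np.asarray(x, float)
    n = x.shape[0]

    def ess(rows):
        pts = x[rows]
        c = pts.mean(axis=0)
        return float(((pts - c) ** 2).sum())

    members = {i: [i] for i in range(n)}
    merges = []
    for t in range(n - 1):
        best = None
        for a in sorted(members):
            for b in sorted(members):
                if b <= a:
                    continue
                d = ess(members[a] + members[b]) - ess(members[a]) - ess(members[b])
                if best is None or d < best[0] - 1e-12 * max(1.0, abs(d)):
                    best = (d, a, b)
        d, a, b = best
        members[n + t] = members.pop(a) + members.pop(b)
        merges.append((a, b, d, len(members[n + t])))
    return merges


def two_pass_mean_sd(col):
    """Textbook two-pass population mean / standard deviation."""
    col = np.asarray(col, float)
    m = sum(col) / len(col)
    var = sum((v - m) ** 2 for v in col) / len(col)
    return m, np.sqrt(var)


def pearson_r(x, y):
    """Covariance-formula Pearson correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxy = float(x @ y)
    sxx = float(x @ x)
    syy = float(y @ y)
    num = n * sxy - sx * sy
    den = np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den
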