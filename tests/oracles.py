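"""Independent brute-force reference implementations.

Deliberately naive code paths (plain recursion, explicit per-frame loops,
textbook matrix recursions) kept separate from the package so that
agreement between the two routes is informative.
"""

from __future__ import annotations

import math

import numpy as np


def rdp_reference(points: np.ndarray, epsilon: float) -> list[int]:
    """Recursive RDP returning kept indices; perpendicular distance to the
    chord line, Euclidean distance to the start point when the chord is
    degenerate."""

    def dist(p, a, b):
        ax, ay = b[0] - a[0], b[1] - a[1]
        n = math.hypot(ax, ay)
        if n == 0.0:
            return math.hypot(p[0] - a[0], p[1] - a[1])
        return abs((p[0] - a[0]) * ay - (p[1] - a[1]) * ax) / n

    def rec(i, j):
        if j <= i + 1:
            return []
        dmax, kmax = -1.0, -1
        for k in range(i + 1, j):
            d = dist(points[k], points[i], points[j])
            if d > dmax:
                dmax, kmax = d, k
        if dmax > epsilon:
            return rec(i, kmax) + [kmax] + rec(kmax, j)
        return []

    n = len(points)
    return [0] + rec(0, n - 1) + [n - 1]


def turning_angle_reference(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Signed angle at b via explicit rotation-matrix search is overkill;
    instead rotate the incoming direction into the frame of reference and
    read the heading angle difference, wrapped to [-pi, pi]."""
    t1 = math.atan2(b[1] - a[1], b[0] - a[0])
    t2 = math.atan2(c[1] - b[1], c[0] - b[0])
    d = t2 - t1
    while d > math.pi:
        d -= 2 * math.pi
    while d < -math.pi:
        d += 2 * math.pi
    return d


def turns_per_minute_reference(indicator, window: int) -> float:
    sums = []
    for i in range(len(indicator) - window + 1):
        s = 0
        for j in range(i, i + window):
            s += indicator[j]
        sums.append(s)
    return sum(sums) / len(sums)


def classify_reference(s_prev, s_k, s_next, center) -> str:
    """Direct arccos evaluation of theta1/theta2 against the centre vector."""
    v1 = np.asarray(s_k, float) - np.asarray(s_prev, float)
    v2 = np.asarray(s_next, float) - np.asarray(s_k, float)
    u = np.asarray(center, float) - np.asarray(s_k, float)
    n1, n2, nu = np.linalg.norm(v1), np.linalg.norm(v2), np.linalg.norm(u)
    if n1 == 0 or n2 == 0 or nu == 0:
        return "unclassifiable"
    t1 = math.acos(np.clip(np.dot(v1, u) / (n1 * nu), -1, 1))
    t2 = math.acos(np.clip(np.dot(v2, u) / (n2 * nu), -1, 1))
    return "inward" if t2 < t1 - 1e-12 else "outward"


def kalman_reference(z: np.ndarray, dt: float, process_sd: float, measurement_sd: float):
    """Textbook constant-velocity Kalman recursion (explicit inverses)."""
    F = np.array([[1, 0, dt, 0], [0, 1, 0, dt], [0, 0, 1, 0], [0, 0, 0, 1]], float)
    H = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], float)
    q = process_sd**2
    G = np.array([[dt**2 / 2, 0], [0, dt**2 / 2], [dt, 0], [0, dt]])
    Q = q * G @ G.T
    R = measurement_sd**2 * np.eye(2)
    x = np.array([z[0, 0], z[0, 1], 0.0, 0.0])
    P = np.diag([measurement_sd**2, measurement_sd**2, 1.0, 1.0])
    out = [x[:2].copy()]
    for j in range(1, len(z)):
        x = F @ x
        P = F @ P @ F.T + Q
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        x = x + K @ (z[j] - H @ x)
        P = (np.eye(4) - K @ H) @ P
        out.append(x[:2].copy())
    return np.array(out)


def nearest_patch_reference(layout, point):
    """Exhaustive scan of all patches for the closest centre."""
    dists = [
        math.hypot(point[0] - p.center[0], point[1] - p.center[1]) for p in layout.patches
    ]
    i = int(np.argmin(dists))  # argmin takes the first minimum: lowest index
    return i, dists[i]
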