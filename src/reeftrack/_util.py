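"""Small shared helpers: geodesy, union-find, seeding."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in meters on a spherical Earth (R = 6371 km)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def child_rng(seed: int, *salt) -> np.random.Generator:
    """Deterministic sub-stream derived from an integer seed and a salt tuple.

    Stable across processes and platforms (salts are CRC-hashed, never
    Python-hash-randomized)."""
    import zlib
    salted = [zlib.crc32(repr(s).encode()) & 0x7FFFFFFF for s in salt]
    ss = np.random.SeedSequence([int(seed) % (2**31)] + salted)
    return np.random.default_rng(ss)


def max_pairwise_distance(xy: np.ndarray) -> float:
    """Maximum Euclidean distance between any two rows of an (n, 2) array.

    Uses the convex hull when n is large; the diameter of a point set is
    attained on its hull.
    """
    pts = np.asarray(xy, dtype=float)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 50:
        from scipy.spatial import ConvexHull, QhullError
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear points: fall through to brute force
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))
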