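"""From binary filament network to individual fibers.

The binarized network mask is thinned to a one-pixel skeleton, the
skeleton is traced into junction-free ordered pixel chains, each chain is
partitioned into quasi-straight fixed-length segments by greedy total
least-squares fitting (perpendicular RMS error capped at one pixel, short
segments discarded), and finally segments are merged into individual
fibers: a sweep over an increasing angle tolerance xi = 0..T_theta joins
pairs whose endpoints overlap and whose orientations differ by at most xi,
averaging orientations weighted by segment length and discarding pixels
beyond the connection (intersection) point.

Orientations are degrees in [0, 180) measured counter-clockwise from the
image horizontal axis (see :mod:`actintrace.synthetic`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.morphology import skeletonize

__all__ = [
    "FixedLengthSegment",
    "Fiber",
    "MergeConfig",
    "skeletonize_and_trace",
    "fit_segments",
    "overlap_endpoints",
    "merge_fibers",
    "extract_fibers",
]


def _pca_line(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares line through points.

    Returns (centroid, unit direction, perpendicular RMS error).  The
    direction is the principal axis of the point cloud, which treats row
    and column residuals symmetrically (orientation-unbiased, unlike a
    regression of row on column).
    """
    pts = np.asarray(pts, dtype=float)
    c = pts.mean(axis=0)
    d = pts - c
    cov = d.T @ d / len(pts)
    vals, vecs = np.linalg.eigh(cov)
    direction = vecs[:, -1]  # (d_row, d_col) of largest eigenvalue
    rms = float(np.sqrt(max(vals[0], 0.0)))
    return c, direction, rms


def _theta_from_direction(d_row: float, d_col: float) -> float:
    """Orientation in [0, 180) from a (row, col) direction vector."""
    ang = np.degrees(np.arctan2(-d_row, d_col)) % 180.0
    return float(ang)


@dataclass
class FixedLengthSegment:
    """A quasi-straight run of skeleton pixels with its fitted line."""

    pixels: np.ndarray  # ordered (n, 2) array of (row, col)
    theta_deg: float
    endpoints: tuple[tuple[int, int], tuple[int, int]]
    length_px: float

    @classmethod
    def from_pixels(cls, pixels: np.ndarray) -> "FixedLengthSegment":
        pixels = np.asarray(pixels)
        _, direction, _ = _pca_line(pixels)
        theta = _theta_from_direction(direction[0], direction[1])
        p0, p1 = tuple(pixels[0]), tuple(pixels[-1])
        length = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
        return cls(pixels=pixels, theta_deg=theta, endpoints=(p0, p1), length_px=length)


@dataclass
class Fiber:
    """A merged chain of segments: the framework's principal output."""

    pixels: np.ndarray
    theta_deg: float
    length_px: float
    source_segments: list[int] = field(default_factory=list)

    @property
    def endpoints(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return tuple(self.pixels[0]), tuple(self.pixels[-1])


@dataclass
class MergeConfig:
    """Merging parameters: angle tolerance, endpoint overlap, min length."""

    T_theta: float = 2.0
    overlap_tol_px: float = 2.0
    L: float = 30.0

    def __post_init__(self) -> None:
        if self.T_theta < 0:
            raise ValueError("T_theta must be >= 0")
        if self.overlap_tol_px < 0:
            raise ValueError("overlap_tol_px must be >= 0")


# ---------------------------------------------------------------------------
# Skeleton tracing
# ---------------------------------------------------------------------------

_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def skeletonize_and_trace(u_B: np.ndarray) -> list[np.ndarray]:
    """Thin a binary mask and trace maximal junction-free pixel chains.

    Pixels with three or more skeleton neighbours are junctions; they
    terminate chains and are attached to the first-traced adjacent chain in
    scan order, so every skeleton pixel belongs to exactly one chain.
    """
    u_B = np.asarray(u_B, dtype=bool)
    if not u_B.any():
        return []
    skel = skeletonize(u_B)
    h, w = skel.shape
    pix = {(int(r), int(c)) for r, c in zip(*np.nonzero(skel))}

    def neighbors(p):
        r, c = p
        return [(r + dr, c + dc) for dr, dc in _NEIGH if (r + dr, c + dc) in pix]

    deg = {p: len(neighbors(p)) for p in pix}
    junctions = {p for p, d in deg.items() if d >= 3}
    path_pix = pix - junctions

    def path_neighbors(p):
        return [q for q in neighbors(p) if q in path_pix]

    visited: set = set()
    chains: list[list[tuple[int, int]]] = []

    def walk(start: tuple[int, int]) -> list[tuple[int, int]]:
        chain = [start]
        visited.add(start)
        while True:
            nxt = [q for q in path_neighbors(chain[-1]) if q not in visited]
            if not nxt:
                return chain
            q = min(nxt)  # deterministic scan-order tie-break
            chain.append(q)
            visited.add(q)

    # open chains first (traced end to end from their endpoints), then any
    # remaining cycles, both in scan order for determinism
    endpoints = sorted(p for p in path_pix if len(path_neighbors(p)) <= 1)
    for p in endpoints:
        if p not in visited:
            chains.append(walk(p))
    for p in sorted(path_pix):
        if p not in visited:
            chains.append(walk(p))
    # attach each junction pixel to the first-traced chain whose endpoint is
    # adjacent (scan-order tie-break); otherwise it forms its own chain
    for j in sorted(junctions):
        placed = False
        for chain in chains:
            if max(abs(j[0] - chain[-1][0]), abs(j[1] - chain[-1][1])) == 1:
                chain.append(j)
                placed = True
                break
            if max(abs(j[0] - chain[0][0]), abs(j[1] - chain[0][1])) == 1:
                chain.insert(0, j)
                placed = True
                break
        if not placed:
            chains.append([j])
    return [np.array(c) for c in chains]


# ---------------------------------------------------------------------------
# Fixed-length segment fitting
# ---------------------------------------------------------------------------

def fit_segments(
    chain: np.ndarray, L: float = 30.0, max_err_px: float = 1.0
) -> list[FixedLengthSegment]:
    """Greedy partition of an ordered chain into quasi-straight segments.

    The current segment is extended pixel by pixel while the perpendicular
    RMS error of the total-least-squares line stays within ``max_err_px``;
    on violation the segment closes at the previous pixel and a new one
    starts at the current pixel.  Segments whose endpoint distance falls
    below ``L`` are discarded.
    """
    chain = np.asarray(chain, dtype=float)
    segments: list[FixedLengthSegment] = []
    n = len(chain)
    start = 0
    # incremental second moments for O(1) TLS updates
    while start < n - 1:
        end = start + 1
        s = chain[start : start + 2].sum(axis=0)
        ss = (chain[start : start + 2] ** 2).sum(axis=0)
        sxy = float(chain[start, 0] * chain[start, 1]
                    + chain[start + 1, 0] * chain[start + 1, 1])
        while end + 1 < n:
            cand = chain[end + 1]
            m = end - start + 2
            s2 = s + cand
            ss2 = ss + cand**2
            sxy2 = sxy + cand[0] * cand[1]
            mu = s2 / m
            c_rr = ss2[0] / m - mu[0] ** 2
            c_cc = ss2[1] / m - mu[1] ** 2
            c_rc = sxy2 / m - mu[0] * mu[1]
            tr = c_rr + c_cc
            det = c_rr * c_cc - c_rc**2
            lam_min = tr / 2 - np.sqrt(max(tr**2 / 4 - det, 0.0))
            if np.sqrt(max(lam_min, 0.0)) > max_err_px:
                break
            end += 1
            s, ss, sxy = s2, ss2, sxy2
        pts = chain[start : end + 1]
        if np.hypot(*(pts[-1] - pts[0])) >= L:
            segments.append(FixedLengthSegment.from_pixels(pts.astype(int)))
        start = end + 1
    return segments


# ---------------------------------------------------------------------------
# Fiber merging
# ---------------------------------------------------------------------------

def _circular_diff(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def overlap_endpoints(f_k, f_i, overlap_tol_px: float = 2.0) -> bool:
    """True when an endpoint of one chain lies within tolerance of the other."""
    pk = np.asarray(f_k.pixels, dtype=float)
    pi = np.asarray(f_i.pixels, dtype=float)
    ek = np.array([pk[0], pk[-1]], dtype=float)
    ei = np.array([pi[0], pi[-1]], dtype=float)
    return bool(
        cdist(ek, pi).min() <= overlap_tol_px or cdist(ei, pk).min() <= overlap_tol_px
    )


def _weighted_theta(theta_k: float, len_k: float, theta_i: float, len_i: float) -> float:
    # unwrap theta_i to the representative nearest theta_k before averaging
    cand = min(
        (theta_i, theta_i + 180.0, theta_i - 180.0), key=lambda t: abs(t - theta_k)
    )
    return ((len_k * theta_k + len_i * cand) / (len_k + len_i)) % 180.0


def _trim_beyond_intersection(fk: Fiber, fi: Fiber) -> tuple[np.ndarray, np.ndarray]:
    """Drop pixels located beyond the connection point of the fitted lines.

    For near-parallel lines (< 0.5 degrees) the midpoint of the closest
    endpoint pair serves as the connection point.
    """
    ck, dk, _ = _pca_line(fk.pixels)
    ci, di, _ = _pca_line(fi.pixels)
    if _circular_diff(fk.theta_deg, fi.theta_deg) < 0.5:
        ek = np.array([fk.pixels[0], fk.pixels[-1]], dtype=float)
        ei = np.array([fi.pixels[0], fi.pixels[-1]], dtype=float)
        d = cdist(ek, ei)
        a, b = np.unravel_index(np.argmin(d), d.shape)
        P = (ek[a] + ei[b]) / 2.0
    else:
        # solve ck + t*dk = ci + s*di
        A = np.array([dk, -di]).T
        t, _s = np.linalg.solve(A, ci - ck)
        P = ck + t * dk

    def trim(fiber: Fiber, c: np.ndarray, d: np.ndarray) -> np.ndarray:
        t_pix = (np.asarray(fiber.pixels, dtype=float) - c) @ d
        t_P = float((P - c) @ d)
        ends = np.array([t_pix[0], t_pix[-1]])
        far = ends[np.argmax(np.abs(ends - t_P))]
        sign = np.sign(far - t_P) or 1.0
        keep = (t_pix - t_P) * sign >= -0.5
        if not keep.any():
            keep[np.argmax((t_pix - t_P) * sign)] = True
        return fiber.pixels[keep]

    return trim(fk, ck, dk), trim(fi, ci, di)


def _merge_pair(fk: Fiber, fi: Fiber) -> Fiber:
    theta = _weighted_theta(fk.theta_deg, fk.length_px, fi.theta_deg, fi.length_px)
    keep_k, keep_i = _trim_beyond_intersection(fk, fi)
    pixels = np.vstack([keep_k, keep_i])
    pixels = np.unique(pixels, axis=0)
    # order the merged chain along the merged orientation
    t = np.deg2rad(theta)
    d = np.array([-np.sin(t), np.cos(t)])  # (d_row, d_col)
    order = np.argsort(pixels @ d, kind="stable")
    pixels = pixels[order]
    length = float(np.hypot(*(pixels[-1].astype(float) - pixels[0])))
    return Fiber(
        pixels=pixels,
        theta_deg=theta,
        length_px=length,
        source_segments=fk.source_segments + fi.source_segments,
    )


def merge_fibers(
    segments: list[FixedLengthSegment], cfg: MergeConfig | None = None
) -> list[Fiber]:
    """Merge fixed-length segments into individual fibers.

    For each tolerance ``xi = 0..T_theta`` a single pass over the surviving
    list merges segment ``i`` into the first ``k > i`` whose orientation
    differs by at most ``xi`` (circular difference) and whose endpoints
    overlap; the merged orientation is the length-weighted mean and pixels
    beyond the intersection point are dropped.
    """
    cfg = cfg or MergeConfig()
    fibers: list[Fiber | None] = [
        Fiber(
            pixels=np.asarray(s.pixels),
            theta_deg=s.theta_deg,
            length_px=s.length_px,
            source_segments=[idx],
        )
        for idx, s in enumerate(segments)
    ]
    for xi in range(0, int(np.floor(cfg.T_theta)) + 1):
        for i in range(len(fibers)):
            fi = fibers[i]
            if fi is None:
                continue
            for k in range(i + 1, len(fibers)):
                fk = fibers[k]
                if fk is None:
                    continue
                if _circular_diff(fk.theta_deg, fi.theta_deg) > xi:
                    continue
                if not overlap_endpoints(fk, fi, cfg.overlap_tol_px):
                    continue
                fibers[k] = _merge_pair(fk, fi)
                fibers[i] = None
                break
    return [f for f in fibers if f is not None]


def extract_fibers(
    u_B: np.ndarray, cfg: MergeConfig | None = None, max_err_px: float = 1.0
) -> tuple[list[Fiber], list[FixedLengthSegment]]:
    """Full extraction: thin, trace, fit fixed-length segments, merge."""
    cfg = cfg or MergeConfig()
    segments: list[FixedLengthSegment] = []
    for chain in skeletonize_and_trace(u_B):
        segments.extend(fit_segments(chain, L=cfg.L, max_err_px=max_err_px))
    return merge_fibers(segments, cfg), segments
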