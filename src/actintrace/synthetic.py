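"""Ground-truthed synthetic filament scenes.

Fluorescence micrographs of stained actin cytoskeletons are modelled as a
linear mixture ``f = u + v + eta``: a filament image ``u`` made of
quasi-straight bright strokes, a smooth artifact image ``v`` made of
isotropic blobs (out-of-focus cell body, staining debris), and additive
Gaussian noise ``eta``.  Scenes generated here carry their own ground truth
(per-pixel filament mask and per-fiber geometry), so every downstream stage
of the extraction framework can be scored without external data.

Conventions
-----------
Images are 2-D float arrays indexed ``[row, col]`` with values in [0, 1].
Orientations are degrees in [0, 180), measured counter-clockwise from the
image horizontal axis: a fiber at angle ``theta`` advances by
``(d_col, d_row) = (cos theta, -sin theta)`` per unit arc length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FilamentSpec",
    "SyntheticScene",
    "rasterize_filaments",
    "generate_artifacts",
    "compose_scene",
    "random_scene",
]


@dataclass(frozen=True)
class FilamentSpec:
    """Geometry and brightness of one quasi-straight filament.

    ``curvature`` is an angular drift in degrees per pixel of arc length;
    the total drift over the stroke is kept small (<= 20 degrees) so the
    fiber remains quasi-straight.
    """

    center: tuple[float, float]  # (row, col)
    angle_deg: float
    length_px: float
    width_px: float = 3.0
    intensity: float = 1.0
    curvature: float = 0.0

    def __post_init__(self) -> None:
        if self.length_px < 1:
            raise ValueError("length_px must be >= 1")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")
        if not (0.0 <= self.angle_deg < 180.0):
            raise ValueError("angle_deg must lie in [0, 180)")
        if not (0.0 < self.intensity <= 1.0):
            raise ValueError("intensity must lie in (0, 1]")
        if abs(self.curvature) * self.length_px > 20.0:
            raise ValueError("total angular drift must stay <= 20 degrees")

    def centerline(self, step: float = 0.25) -> np.ndarray:
        """Sample the (possibly gently curved) centerline at ``step`` px.

        Returns an (n, 2) array of (row, col) points.
        """
        n = max(int(np.ceil(self.length_px / step)) + 1, 2)
        s = np.linspace(-self.length_px / 2.0, self.length_px / 2.0, n)
        ang = np.deg2rad(self.angle_deg + self.curvature * s)
        # integrate the direction field; for zero curvature this is exact
        d_col = np.cos(ang)
        d_row = -np.sin(ang)
        ds = np.gradient(s)
        col = np.cumsum(d_col * ds)
        row = np.cumsum(d_row * ds)
        # center the arc on the requested center point
        col = self.center[1] + col - col.mean()
        row = self.center[0] + row - row.mean()
        return np.stack([row, col], axis=1)


@dataclass
class SyntheticScene:
    """A composed scene together with its ground truth."""

    truth_image: np.ndarray
    artifacts_image: np.ndarray
    noise_sigma: float
    composite: np.ndarray
    truth_mask: np.ndarray
    truth_fibers: list[FilamentSpec] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.composite.shape

    def fibers_table(self) -> "np.ndarray":
        """Ground-truth fiber parameters as a structured record array."""
        import pandas as pd

        rows = [
            dict(
                id=i,
                cy=f.center[0],
                cx=f.center[1],
                angle_deg=f.angle_deg,
                length_px=f.length_px,
                width_px=f.width_px,
                intensity=f.intensity,
            )
            for i, f in enumerate(self.truth_fibers)
        ]
        return pd.DataFrame(rows)


def _check_shape(shape: tuple[int, int]) -> tuple[int, int]:
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"image shape must be positive, got {shape}")
    return h, w


def _segment_distance(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Min distance from each query point to a polyline (vectorised)."""
    a = polyline[:-1]  # (m, 2)
    b = polyline[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    # points (n, 2) vs segments (m, 2): n*m distance matrix in blocks
    ap = points[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("nmj,mj->nm", ap, ab) / denom[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return d.min(axis=1)


def rasterize_filaments(
    specs: list[FilamentSpec], shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Render filaments into a truth image and a truth mask.

    The stroke profile is flat across the width with a one-pixel
    anti-aliased ramp at the edges; the mask is the set of pixels whose
    distance to the centerline is at most ``width_px / 2``.
    """
    h, w = _check_shape(shape)
    img = np.zeros((h, w), dtype=float)
    mask = np.zeros((h, w), dtype=bool)
    for spec in specs:
        poly = spec.centerline()
        half = spec.width_px / 2.0
        pad = int(np.ceil(half)) + 2
        r0 = max(int(np.floor(poly[:, 0].min())) - pad, 0)
        r1 = min(int(np.ceil(poly[:, 0].max())) + pad + 1, h)
        c0 = max(int(np.floor(poly[:, 1].min())) - pad, 0)
        c1 = min(int(np.ceil(poly[:, 1].max())) + pad + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
        d = _segment_distance(pts, poly).reshape(rr.shape)
        # flat core, linear anti-aliasing ramp over the outermost pixel
        cov = np.clip(half + 0.5 - d, 0.0, 1.0)
        img[r0:r1, c0:c1] = np.maximum(img[r0:r1, c0:c1], spec.intensity * cov)
        mask[r0:r1, c0:c1] |= d <= half
    return img, mask


def generate_artifacts(
    shape: tuple[int, int],
    n_blobs: int,
    seed: int | np.random.Generator = 0,
    sigma_range: tuple[float, float] = (5.0, 20.0),
    amplitude_range: tuple[float, float] = (0.1, 0.3),
) -> np.ndarray:
    """Smooth blob-like background lacking any line-like geometry.

    Blobs are isotropic Gaussians with scales drawn from ``sigma_range``.
    Centers are re-drawn when they would land closer than the sum of blob
    scales, so that overlapping blobs cannot chain into elongated ridges.
    """
    h, w = _check_shape(shape)
    if n_blobs < 0:
        raise ValueError("n_blobs must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    img = np.zeros((h, w), dtype=float)
    centers: list[tuple[float, float, float]] = []  # (row, col, sigma)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    for _ in range(n_blobs):
        sig = rng.uniform(*sigma_range)
        amp = rng.uniform(*amplitude_range)
        # keep centers away from the border: a clipped blob thresholds to a
        # half-disk whose skeleton is a straight ridge
        mr = min(sig, h / 4.0)
        mc = min(sig, w / 4.0)
        for _attempt in range(200):
            r = rng.uniform(mr, h - mr)
            c = rng.uniform(mc, w - mc)
            if all(np.hypot(r - r2, c - c2) >= (sig + s2) for r2, c2, s2 in centers):
                break
        centers.append((r, c, sig))
        img += amp * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * sig**2))
    return img


def compose_scene(
    specs: list[FilamentSpec],
    shape: tuple[int, int] = (256, 256),
    n_blobs: int = 4,
    noise_sigma: float = 0.04,
    seed: int | np.random.Generator = 0,
    blur_sigma: float = 0.0,
    artifact_kwargs: dict | None = None,
) -> SyntheticScene:
    """Compose ``f = clip(u + v + eta, 0, 1)`` with ground truth attached.

    ``blur_sigma`` optionally blurs the truth image before composition to
    emulate out-of-plane defocus; the noise standard deviation defaults to
    0.04, the regime the extraction framework is designed for.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u, mask = rasterize_filaments(specs, shape)
    if blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        u = gaussian_filter(u, blur_sigma, mode="reflect")
    v = generate_artifacts(shape, n_blobs, seed=rng, **(artifact_kwargs or {}))
    eta = rng.normal(0.0, noise_sigma, size=u.shape) if noise_sigma > 0 else np.zeros_like(u)
    f = np.clip(u + v + eta, 0.0, 1.0)
    return SyntheticScene(
        truth_image=u,
        artifacts_image=v,
        noise_sigma=float(noise_sigma),
        composite=f,
        truth_mask=mask,
        truth_fibers=list(specs),
    )


def random_scene(
    n_fibers: int = 12,
    shape: tuple[int, int] = (256, 256),
    seed: int | np.random.Generator = 0,
    length_range: tuple[float, float] = (60.0, 120.0),
    width_range: tuple[float, float] = (1.0, 8.0),
    intensity_range: tuple[float, float] = (0.6, 1.0),
    min_separation: float = 0.0,
    n_blobs: int = 4,
    noise_sigma: float = 0.04,
    angle_range: tuple[float, float] = (0.0, 180.0),
) -> SyntheticScene:
    """Draw a random scene of straight fibers.

    With ``min_separation > 0`` fibers are placed by rejection so that no
    two centerlines come closer than the given distance, yielding the
    well-separated regime used for fiber-level recovery checks.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    h, w = _check_shape(shape)
    specs: list[FilamentSpec] = []
    polys: list[np.ndarray] = []
    margin = 10.0
    attempts = 0
    while len(specs) < n_fibers and attempts < 200 * n_fibers:
        attempts += 1
        length = rng.uniform(*length_range)
        ang = rng.uniform(*angle_range) % 180.0
        width = rng.uniform(*width_range)
        cy = rng.uniform(margin + length / 2 * 0.2, h - margin - length / 2 * 0.2)
        cx = rng.uniform(margin + length / 2 * 0.2, w - margin - length / 2 * 0.2)
        spec = FilamentSpec(
            center=(cy, cx),
            angle_deg=float(ang),
            length_px=float(length),
            width_px=float(width),
            intensity=float(rng.uniform(*intensity_range)),
        )
        poly = spec.centerline(step=1.0)
        if (
            poly[:, 0].min() < 2
            or poly[:, 0].max() > h - 3
            or poly[:, 1].min() < 2
            or poly[:, 1].max() > w - 3
        ):
            continue
        if min_separation > 0 and polys:
            ok = True
            for other in polys:
                d = np.linalg.norm(poly[:, None, :] - other[None, :, :], axis=2)
                if d.min() < min_separation:
                    ok = False
                    break
            if not ok:
                continue
        specs.append(spec)
        polys.append(poly)
    return compose_scene(
        specs, shape=shape, n_blobs=n_blobs, noise_sigma=noise_sigma, seed=rng
    )
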