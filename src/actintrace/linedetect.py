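"""Multi-scale line response and adaptive binarization.

Each pixel of the enhanced image is scored by how much brighter a short
oriented line element through it is than its surrounding window: the line
response ``R`` at orientation ``theta`` and scale ``s`` is the mean along a
length-``s`` line segment centered at the pixel minus the mean over the
``(2W+1) x (2W+1)`` window, where ``W`` is the expected fiber width.  The
multi-scale response ``u_G`` averages, over scales 1..W, the maximum of
``R`` across a discrete orientation set, optionally adding the pixel's own
intensity as a (W+1)-th term.  ``u_G`` is then binarized by an adaptive
local threshold derived from a median filter (Wellner-style), giving the
filament-network mask ``u_B``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import remove_small_objects

__all__ = [
    "LineResponseConfig",
    "ThresholdConfig",
    "line_offsets",
    "line_response_R",
    "multiscale_response",
    "wellner_binarize",
]


@dataclass
class LineResponseConfig:
    """Settings of the multi-scale line detector.

    ``W`` is the expected fiber width in pixels and doubles as the number
    of scales; ``angle_step_deg`` must divide 180.  When
    ``include_pixel_term`` is set, the pixel's own intensity becomes the
    (W+1)-th averaged term, matching the detector's 1/(W+1) normalization.
    """

    W: int = 4
    angle_step_deg: float = 15.0
    include_pixel_term: bool = True

    def __post_init__(self) -> None:
        if self.W < 1:
            raise ValueError("W must be >= 1")
        if 180.0 % self.angle_step_deg != 0:
            raise ValueError("angle_step_deg must divide 180")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(0.0, 180.0, self.angle_step_deg)


@dataclass
class ThresholdConfig:
    """Wellner-style adaptive threshold settings.

    The local intensity estimate is a ``median_window``-sided median
    filter of ``u_G``.  ``mode`` selects how the retained threshold is
    derived from the estimate: ``"fraction"`` keeps pixels exceeding
    ``b * median`` (the threshold is a percentage b of the estimate),
    while ``"excess"`` keeps pixels exceeding ``median + b`` on the [0, 1]
    response scale.  Both are monotone: a smaller ``b`` retains more
    candidate pixels.
    """

    b: float = 0.1
    median_window: int = 15
    mode: str = "excess"
    min_object_px: int = 5

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be > 0")
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 3")
        if self.mode not in ("fraction", "excess"):
            raise ValueError("mode must be 'fraction' or 'excess'")


def _round_half_up(v: np.ndarray) -> np.ndarray:
    return np.floor(v + 0.5).astype(int)


def line_offsets(theta_deg: float, s: int) -> np.ndarray:
    """Integer (row, col) offsets of a length-``s`` line element.

    Samples are placed at signed arc positions ``j - (s-1)/2`` for
    ``j = 0..s-1`` along direction ``(d_col, d_row) = (cos t, -sin t)`` and
    rounded half-up to the pixel grid.
    """
    t = np.deg2rad(theta_deg)
    k = np.arange(s) - (s - 1) / 2.0
    dr = _round_half_up(k * (-np.sin(t)))
    dc = _round_half_up(k * np.cos(t))
    return np.stack([dr, dc], axis=1)


def _shifted(padded: np.ndarray, pad: int, dr: int, dc: int, shape: tuple[int, int]):
    h, w = shape
    return padded[pad + dr : pad + dr + h, pad + dc : pad + dc + w]


def line_response_R(
    u_E: np.ndarray, x: int, y: int, theta: float, s: int, W: int
) -> float:
    """Line response at a single pixel ``(x, y)`` (col, row).

    Mean of ``u_E`` along the length-``s`` line element at angle ``theta``
    centered on the pixel, minus the mean over the ``(2W+1) x (2W+1)``
    window; off-image samples use mirror (symmetric) padding.
    """
    u_E = np.asarray(u_E, dtype=float)
    h, w = u_E.shape

    def mirror(i: int, n: int) -> int:
        period = 2 * n
        i = i % period
        if i < 0:
            i += period
        return i if i < n else period - 1 - i

    line_sum = 0.0
    for dr, dc in line_offsets(theta, s):
        line_sum += u_E[mirror(y + dr, h), mirror(x + dc, w)]
    win_sum = 0.0
    for dr in range(-W, W + 1):
        for dc in range(-W, W + 1):
            win_sum += u_E[mirror(y + dr, h), mirror(x + dc, w)]
    return line_sum / s - win_sum / (2 * W + 1) ** 2


def multiscale_response(
    u_E: np.ndarray, cfg: LineResponseConfig | None = None, rescale: bool = True
) -> np.ndarray:
    """Multi-scale line response field ``u_G``.

    ``u_G = (1/(W+1)) * sum_{s=1..W} max_theta R(.; theta, s, W)`` plus,
    when configured, the pixel's own intensity as the (W+1)-th term.  With
    ``rescale`` the field is clipped at zero (negative responses carry no
    line evidence) and divided by its maximum.
    """
    cfg = cfg or LineResponseConfig()
    u_E = np.asarray(u_E, dtype=float)
    h, w = u_E.shape
    W = cfg.W
    pad = W + 2
    padded = np.pad(u_E, pad, mode="symmetric")
    window_mean = ndimage.uniform_filter(u_E, size=2 * W + 1, mode="reflect")

    acc = np.zeros_like(u_E)
    for s in range(1, W + 1):
        best = np.full(u_E.shape, -np.inf)
        for theta in cfg.angles:
            offs = line_offsets(theta, s)
            line_mean = np.zeros_like(u_E)
            for dr, dc in offs:
                line_mean += _shifted(padded, pad, int(dr), int(dc), (h, w))
            line_mean /= s
            np.maximum(best, line_mean - window_mean, out=best)
        acc += best
    if cfg.include_pixel_term:
        acc += u_E
    u_G = acc / (W + 1)
    if rescale:
        u_G = np.clip(u_G, 0.0, None)
        m = u_G.max()
        if m > 0:
            u_G = u_G / m
    return u_G


def wellner_binarize(u_G: np.ndarray, cfg: ThresholdConfig | None = None) -> np.ndarray:
    """Adaptive local binarization of the line-response field.

    A median filter provides the local intensity estimate; a pixel is
    foreground when it strictly exceeds the retained threshold derived
    from the estimate and ``b``.  Isolated foreground components smaller
    than ``min_object_px`` pixels are removed.
    """
    cfg = cfg or ThresholdConfig()
    u_G = np.asarray(u_G, dtype=float)
    med = ndimage.median_filter(u_G, size=cfg.median_window, mode="reflect")
    if cfg.mode == "fraction":
        mask = u_G > cfg.b * med
    else:
        mask = u_G > med + cfg.b
    if cfg.min_object_px > 1:
        # drop isolated components of fewer than min_object_px pixels
        mask = remove_small_objects(mask, max_size=cfg.min_object_px - 1)
    return mask
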