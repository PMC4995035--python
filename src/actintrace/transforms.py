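"""Tight-frame transform dictionaries for two-source image separation.

Morphological component analysis separates an image into components that
are each sparse in their own dictionary.  Here the filamentous content is
modelled by a directional multiscale Parseval frame (curvelet-type: dyadic
radial bands split into smooth orientation wedges), and the blob/texture
content by an undecimated wavelet transform (UDWT).

Both dictionaries expose ``analysis`` (image -> list of real coefficient
bands), ``synthesis`` (bands -> image), and per-band white-noise gains used
to equalise thresholds across bands.  Synthesis after analysis reconstructs
the input to machine precision (tight / near-tight frame contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pywt

__all__ = ["TransformDictionary", "udwt_dictionary", "curvelet_dictionary"]


@dataclass
class TransformDictionary:
    """A linear analysis/synthesis operator pair with named bands."""

    name: str
    analysis: Callable[[np.ndarray], list[np.ndarray]]
    synthesis: Callable[[list[np.ndarray], tuple[int, int]], np.ndarray]
    band_noise_gains: Callable[[tuple[int, int]], np.ndarray]
    # labels for diagnostics: list of (scale, orientation-or-None)
    band_info: Callable[[tuple[int, int]], list[tuple[int, float | None]]]


# ---------------------------------------------------------------------------
# Meyer-type smooth transition
# ---------------------------------------------------------------------------

def _meyer_nu(t: np.ndarray) -> np.ndarray:
    """Polynomial Meyer window helper: 0 for t<=0, 1 for t>=1, C^3 ramp.

    Satisfies nu(t) + nu(1 - t) = 1, which makes cos/sin cross-fades built
    from it square-sum to one.
    """
    t = np.clip(t, 0.0, 1.0)
    return t**4 * (35.0 - 84.0 * t + 70.0 * t**2 - 20.0 * t**3)


# ---------------------------------------------------------------------------
# Directional multiscale Parseval frame (curvelet-type)
# ---------------------------------------------------------------------------

def _curvelet_windows(
    shape: tuple[int, int], scales: int, angles: int
) -> tuple[list[np.ndarray], list[tuple[int, float | None]]]:
    """Fourier-domain windows whose squares sum to one everywhere.

    Radial: a coarse low-pass plus ``scales - 1`` dyadic rings, the finest
    ring absorbing everything up to the Nyquist corner.  Angular: each ring
    is multiplied by ``angles`` smooth wedges covering orientation mod 180
    degrees (windows are symmetric under frequency negation, so coefficient
    bands are real for real input).
    """
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    rho = np.hypot(fy, fx)
    # orientation of the frequency vector, folded to [0, pi)
    phi = np.arctan2(fy, fx) % np.pi

    # radial cross-fades: lowpass_k(rho) = 1 below a_k, 0 above 2 a_k
    def lowpass(a: float) -> np.ndarray:
        out = np.ones_like(rho)
        tr = (rho > a) & (rho < 2 * a)
        out[rho >= 2 * a] = 0.0
        out[tr] = np.cos(0.5 * np.pi * _meyer_nu((rho[tr] - a) / a))
        return out

    cuts = [0.25 / 2**j for j in range(scales - 1)]  # finest first
    lows = [lowpass(a) for a in cuts]
    radial: list[np.ndarray] = []
    radial.append(np.sqrt(np.clip(1.0 - lows[0] ** 2, 0.0, None)))  # finest ring
    for j in range(scales - 2):
        radial.append(np.sqrt(np.clip(lows[j] ** 2 - lows[j + 1] ** 2, 0.0, None)))
    coarse = lows[-1]

    # angular wedges: squares of adjacent wedges cross-fade to one
    dphi = np.pi / angles
    wedges = []
    for l in range(angles):
        t = (phi - l * dphi) / dphi
        t = (t + angles / 2) % angles - angles / 2  # wrap to [-angles/2, angles/2)
        win = np.where(np.abs(t) < 1.0, np.cos(0.5 * np.pi * _meyer_nu(np.abs(t))), 0.0)
        wedges.append(win)

    def symmetrize(u: np.ndarray) -> np.ndarray:
        # enforce u(-omega) = u(omega) exactly on the discrete grid (the
        # Nyquist row/column maps onto itself with a different folded
        # angle); averaging squares keeps the partition of unity intact
        neg = np.roll(np.roll(u[::-1, ::-1], 1, axis=0), 1, axis=1)
        return np.sqrt(0.5 * (u**2 + neg**2))

    windows: list[np.ndarray] = []
    info: list[tuple[int, float | None]] = []
    for j, ring in enumerate(radial):
        for l, wedge in enumerate(wedges):
            windows.append(symmetrize(ring * wedge))
            # a line at spatial angle theta concentrates its spectrum along
            # the perpendicular frequency direction 90 - theta
            info.append((j, (90.0 - np.degrees(l * dphi)) % 180.0))
    windows.append(coarse)
    info.append((scales - 1, None))
    return windows, info


class _CurveletFrame:
    """Shape-cached FFT implementation of the directional frame."""

    def __init__(self, scales: int, angles: int):
        if scales < 2:
            raise ValueError("scales must be >= 2")
        if angles < 2:
            raise ValueError("angles per scale must be >= 2")
        self.scales = scales
        self.angles = angles
        self._cache: dict[tuple[int, int], tuple[list[np.ndarray], list]] = {}

    def _windows(self, shape: tuple[int, int]):
        h, w = shape
        if h < 2**self.scales or w < 2**self.scales:
            raise ValueError(
                f"image shape {shape} too small for {self.scales} scales"
            )
        if shape not in self._cache:
            self._cache[shape] = _curvelet_windows(shape, self.scales, self.angles)
        return self._cache[shape]

    def analysis(self, img: np.ndarray) -> list[np.ndarray]:
        img = np.asarray(img, dtype=float)
        windows, _ = self._windows(img.shape)
        F = np.fft.fft2(img)
        return [np.fft.ifft2(F * u).real for u in windows]

    def synthesis(self, bands: list[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
        windows, _ = self._windows(shape)
        acc = np.zeros(shape, dtype=complex)
        for band, u in zip(bands, windows):
            acc += np.fft.fft2(band) * u
        return np.fft.ifft2(acc).real

    def band_noise_gains(self, shape: tuple[int, int]) -> np.ndarray:
        windows, _ = self._windows(shape)
        n = shape[0] * shape[1]
        return np.array([np.sqrt(np.sum(u**2) / n) for u in windows])

    def band_info(self, shape: tuple[int, int]):
        return self._windows(shape)[1]


def curvelet_dictionary(scales: int = 4, angles_per_scale: int = 8) -> TransformDictionary:
    """Directional multiscale Parseval frame for quasi-linear content.

    Elongated, orientation-selective atoms make quasi-straight filaments
    sparse: a straight line concentrates its energy in the few wedges whose
    spatial orientation matches the line.
    """
    frame = _CurveletFrame(scales, angles_per_scale)
    return TransformDictionary(
        name="curvelet",
        analysis=frame.analysis,
        synthesis=frame.synthesis,
        band_noise_gains=frame.band_noise_gains,
        band_info=frame.band_info,
    )


def wedge_energies(d: TransformDictionary, img: np.ndarray, scale: int = 0) -> dict[float, float]:
    """Per-orientation coefficient energy at one scale (diagnostics)."""
    bands = d.analysis(img)
    info = d.band_info(img.shape)
    out: dict[float, float] = {}
    for band, (j, orient) in zip(bands, info):
        if j == scale and orient is not None:
            out[orient] = out.get(orient, 0.0) + float(np.sum(band**2))
    return out


# ---------------------------------------------------------------------------
# Undecimated wavelet transform (UDWT)
# ---------------------------------------------------------------------------

class _UDWT:
    """Shift-invariant wavelet dictionary via the stationary transform.

    Images are symmetrically padded to a multiple of ``2**levels`` (the
    stationary transform requires it) and cropped back after synthesis, so
    the operator pair remains exactly linear and invertible.
    """

    def __init__(self, levels: int, wavelet: str):
        if levels < 1:
            raise ValueError("levels must be >= 1")
        self.levels = levels
        self.wavelet = wavelet
        self._gain_cache: dict[tuple[int, int], np.ndarray] = {}

    def _pad(self, img: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        m = 2**self.levels
        h, w = img.shape
        if h < m or w < m:
            raise ValueError(
                f"image shape {img.shape} too small for {self.levels} levels"
            )
        ph = (-h) % m
        pw = (-w) % m
        if ph or pw:
            img = np.pad(img, ((0, ph), (0, pw)), mode="symmetric")
        return img, (h, w)

    def analysis(self, img: np.ndarray) -> list[np.ndarray]:
        img = np.asarray(img, dtype=float)
        padded, _ = self._pad(img)
        coeffs = pywt.swt2(padded, self.wavelet, level=self.levels,
                           norm=True, trim_approx=True)
        bands = [coeffs[0]]
        for detail in coeffs[1:]:
            bands.extend(detail)
        return bands

    def synthesis(self, bands: list[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
        coeffs: list = [bands[0]]
        i = 1
        for _ in range(self.levels):
            coeffs.append(tuple(bands[i : i + 3]))
            i += 3
        rec = pywt.iswt2(coeffs, self.wavelet, norm=True)
        return rec[: shape[0], : shape[1]]

    def band_noise_gains(self, shape: tuple[int, int]) -> np.ndarray:
        if shape not in self._gain_cache:
            rng = np.random.default_rng(12345)
            noise = rng.normal(size=shape)
            bands = self.analysis(noise)
            self._gain_cache[shape] = np.array([float(np.std(b)) for b in bands])
        return self._gain_cache[shape]

    def band_info(self, shape: tuple[int, int]):
        info: list[tuple[int, float | None]] = [(self.levels, None)]
        for lev in range(self.levels, 0, -1):
            info.extend([(lev, 0.0), (lev, 90.0), (lev, None)])
        return info


def udwt_dictionary(levels: int = 4, wavelet_name: str = "db4") -> TransformDictionary:
    """Undecimated wavelet dictionary for blob/texture artifact content."""
    t = _UDWT(levels, wavelet_name)
    return TransformDictionary(
        name="udwt",
        analysis=t.analysis,
        synthesis=t.synthesis,
        band_noise_gains=t.band_noise_gains,
        band_info=t.band_info,
    )
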