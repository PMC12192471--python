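"""Ensemble noise-power-spectrum estimation and frequency-band comparison.

The estimation chain mirrors the repeated-reconstruction method: subtract
the ensemble mean from each repetition, Fourier-transform every difference
image, average the squared moduli into a 2D power map, sample the map along
18 straight lines through DC (10..180 degrees), average the directional
spectra into an angle-independent curve, and average those curves over
slices into a cohort spectrum.  Band integrals and a relative-improvement
curve with zero-crossing (crossover) detection compare two methods.

Normalization: a difference image d gives |FFT2(d)|^2 * pixel_area /
n_pixels, and the average over the n repetitions is multiplied by n/(n-1)
to undo the variance deficit from subtracting the sample mean.  With this
convention white noise of variance sigma^2 on a grid of pixel size delta
has a flat NPS equal to sigma^2 * delta^2, and per-pixel variance equals
the 2D integral of the NPS over the Nyquist square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .ensemble import NoiseEnsemble

__all__ = [
    "PowerMap",
    "NPSCurve",
    "BandSummary",
    "ensemble_power_map",
    "directional_spectrum",
    "angular_average",
    "cohort_nps",
    "band_integrals",
    "relative_improvement",
    "find_crossovers",
    "DEFAULT_ANGLES",
]

DEFAULT_ANGLES: tuple[float, ...] = tuple(float(a) for a in range(10, 181, 10))


@dataclass(frozen=True)
class PowerMap:
    """DC-centered 2D spectral power of ensemble noise for one slice."""

    values: np.ndarray  # (H, W), HU^2 mm^2, >= 0
    fx_axis: np.ndarray  # 1/mm, ascending, DC at the center bin
    fy_axis: np.ndarray
    pixel_size: float  # mm
    n_rep_used: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("power map must be 2D")
        if np.any(v < 0):
            raise ValueError("power map values must be >= 0")
        object.__setattr__(self, "values", v)

    @property
    def freq_step(self) -> float:
        return float(self.fx_axis[1] - self.fx_axis[0])

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.pixel_size)


@dataclass(frozen=True)
class NPSCurve:
    """1D noise power versus spatial frequency.

    ``kind`` is one of ``directional``, ``angular_mean``, ``cohort_mean``,
    ``relative``.  Relative curves are in percent and may be negative or NaN
    (masked where the reference vanished); all other kinds are >= 0.
    ``support_count[i]`` is the number of samples contributing at
    ``frequencies[i]``.
    """

    frequencies: np.ndarray  # 1/mm, strictly ascending, >= 0
    power: np.ndarray  # HU^2 mm^2, or % for kind == "relative"
    kind: str
    angle: float | None = None
    support_count: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.ndim != 1 or f.shape != p.shape:
            raise ValueError("frequencies and power must be matching 1D arrays")
        if f.size and (f[0] < 0 or np.any(np.diff(f) <= 0)):
            raise ValueError("frequencies must be strictly ascending and start >= 0")
        if self.kind not in {"directional", "angular_mean", "cohort_mean", "relative"}:
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if self.kind != "relative" and np.any(p[np.isfinite(p)] < 0):
            raise ValueError("power must be >= 0 for non-relative curves")
        sc = self.support_count
        sc = np.ones(f.size, dtype=int) if sc is None else np.asarray(sc, dtype=int)
        if sc.shape != f.shape:
            raise ValueError("support_count must match frequencies")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)
        object.__setattr__(self, "support_count", sc)


@dataclass(frozen=True)
class BandSummary:
    """Integrated noise power below/between/above the band boundaries."""

    low_band: float
    mid_band: float
    high_band: float
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_low < self.f_high):
            raise ValueError("band boundaries must satisfy 0 < f_low < f_high")
        for b in (self.low_band, self.mid_band, self.high_band):
            if b < -1e-12:
                raise ValueError("band integrals must be >= 0")

    @property
    def total(self) -> float:
        return self.low_band + self.mid_band + self.high_band


def ensemble_power_map(ens: NoiseEnsemble, slice_index: int = 0) -> PowerMap:
    """2D NPS estimate for one slice from the repeated reconstructions.

    Each repetition minus the ensemble mean is Fourier transformed; the
    squared moduli are scaled by pixel_area/n_pixels, averaged over the
    repetitions and multiplied by n/(n-1) (bias correction for the sample
    mean).  The DC bin carries the residual-mean power, which is ~0.
    """
    n = ens.n_rep
    if n < 2:
        raise ValueError("need n_rep >= 2 to form difference images")
    diffs = ens.images[:, slice_index] - ens.images[:, slice_index].mean(axis=0)
    h, w = diffs.shape[-2:]
    delta = ens.pixel_size
    power = np.zeros((h, w))
    for d in diffs:
        power += np.abs(np.fft.fft2(d)) ** 2
    power *= (delta * delta) / (h * w) / n * (n / (n - 1.0))
    power = np.fft.fftshift(power)
    fy = np.fft.fftshift(np.fft.fftfreq(h, d=delta))
    fx = np.fft.fftshift(np.fft.fftfreq(w, d=delta))
    return PowerMap(values=power, fx_axis=fx, fy_axis=fy, pixel_size=delta, n_rep_used=n)


def _line_length(n: int, center: int, direction: float) -> float:
    """Largest step count j so that center + j*direction stays in [0, n-1]."""
    if abs(direction) < 1e-12:
        return np.inf
    if direction > 0:
        return (n - 1 - center) / direction
    return center / (-direction)


def directional_spectrum(pmap: PowerMap, angle: float) -> NPSCurve:
    """Sample the power map along the line through DC at ``angle`` degrees.

    Bilinear interpolation at steps of one axis-frequency bin, out to the
    map boundary; the reachable maximum frequency therefore grows from the
    axis Nyquist at 90/180 degrees up to sqrt(2) times that on diagonals.
    """
    if not (0.0 < angle <= 180.0):
        raise ValueError("angle must be in (0, 180] degrees")
    vals = pmap.values
    h, w = vals.shape
    if h != w:
        raise ValueError("directional sampling requires a square power map")
    theta = np.deg2rad(angle)
    dx, dy = np.cos(theta), np.sin(theta)
    cy = int(np.argmin(np.abs(pmap.fy_axis)))
    cx = int(np.argmin(np.abs(pmap.fx_axis)))
    jmax = int(np.floor(min(_line_length(w, cx, dx), _line_length(h, cy, dy))))
    j = np.arange(jmax + 1)
    rows = cy + j * dy
    cols = cx + j * dx
    power = map_coordinates(vals, np.vstack([rows, cols]), order=1, mode="nearest")
    freqs = j * pmap.freq_step
    return NPSCurve(frequencies=freqs, power=power, kind="directional", angle=float(angle))


def angular_average(curves: Sequence[NPSCurve]) -> NPSCurve:
    """Average directional spectra into an angle-independent curve.

    The common grid runs from 0 in axis-bin steps up to the longest input
    curve; at each frequency only curves that reach it contribute, and
    ``support_count`` records how many (beyond the axis Nyquist only
    near-diagonal angles survive).
    """
    if not curves:
        raise ValueError("no directional curves given")
    steps = {round(float(c.frequencies[1] - c.frequencies[0]), 12) for c in curves if c.frequencies.size > 1}
    if len(steps) != 1:
        raise ValueError("directional curves are not on a common frequency step")
    df = steps.pop()
    nmax = max(c.frequencies.size for c in curves)
    power = np.zeros(nmax)
    support = np.zeros(nmax, dtype=int)
    for c in curves:
        k = c.frequencies.size
        power[:k] += c.power
        support[:k] += 1
    power /= np.maximum(support, 1)
    freqs = np.arange(nmax) * df
    return NPSCurve(frequencies=freqs, power=power, kind="angular_mean", support_count=support)


def cohort_nps(per_slice_curves: Sequence[NPSCurve]) -> NPSCurve:
    """Unweighted mean of per-slice spectra on a shared frequency grid."""
    if not per_slice_curves:
        raise ValueError("no curves given")
    f0 = per_slice_curves[0].frequencies
    for c in per_slice_curves[1:]:
        if c.frequencies.shape != f0.shape or not np.allclose(c.frequencies, f0):
            raise ValueError("per-slice curves are not on a shared frequency grid")
    power = np.mean([c.power for c in per_slice_curves], axis=0)
    support = np.sum([c.support_count for c in per_slice_curves], axis=0)
    return NPSCurve(
        frequencies=f0.copy(),
        power=power,
        kind="cohort_mean",
        support_count=support,
        meta={"n_slices": len(per_slice_curves)},
    )


def band_integrals(curve: NPSCurve, f_low: float = 0.5088, f_high: float = 1.3084) -> BandSummary:
    """Trapezoidal integrals over [0, f_low], (f_low, f_high], (f_high, fmax].

    Boundary points are inserted by linear interpolation so the three bands
    sum to the total integral to machine precision.
    """
    f = curve.frequencies
    p = curve.power
    if not np.all(np.isfinite(p)):
        raise ValueError("curve power contains non-finite values")
    if not (f[0] <= f_low < f_high <= f[-1]) or f_low <= 0:
        raise ValueError("band boundaries must lie inside the frequency grid")
    grid = np.union1d(f, [f_low, f_high])
    vals = np.interp(grid, f, p)

    def _seg(a: float, b: float) -> float:
        m = (grid >= a) & (grid <= b)
        return float(np.trapezoid(vals[m], grid[m]))

    return BandSummary(
        low_band=_seg(f[0], f_low),
        mid_band=_seg(f_low, f_high),
        high_band=_seg(f_high, f[-1]),
        f_low=f_low,
        f_high=f_high,
    )


def relative_improvement(reference: NPSCurve, test: NPSCurve) -> NPSCurve:
    """Percent noise reduction of ``test`` relative to ``reference``.

    100 * (reference - test) / reference; positive where the test method has
    less noise.  Frequencies where the reference power is <= 0 are masked
    with NaN.
    """
    f = reference.frequencies
    if test.frequencies.shape != f.shape or not np.allclose(test.frequencies, f):
        raise ValueError("curves are not on a common frequency grid")
    ref = reference.power
    if not np.any(ref > 0):
        raise ValueError("reference curve has no positive power")
    rel = np.full(f.shape, np.nan)
    ok = ref > 0
    rel[ok] = 100.0 * (ref[ok] - test.power[ok]) / ref[ok]
    support = np.minimum(reference.support_count, test.support_count)
    return NPSCurve(frequencies=f.copy(), power=rel, kind="relative", support_count=support)


def find_crossovers(rel: NPSCurve) -> list[float]:
    """Zero-crossing frequencies of a relative curve, ascending.

    Linear interpolation between adjacent finite grid points of opposite
    sign; exact-zero grid points are reported once, and runs of consecutive
    exact zeros collapse to their midpoint.
    """
    if rel.kind != "relative":
        raise ValueError("crossover detection expects a relative curve")
    f = rel.frequencies
    p = rel.power
    finite = np.isfinite(p)
    fv, pv = f[finite], p[finite]
    roots: list[float] = []
    i = 0
    while i < pv.size:
        if pv[i] == 0.0:
            j = i
            while j + 1 < pv.size and pv[j + 1] == 0.0:
                j += 1
            roots.append(float(0.5 * (fv[i] + fv[j])))
            i = j + 1
            continue
        if i + 1 < pv.size and pv[i + 1] != 0.0 and pv[i] * pv[i + 1] < 0:
            t = pv[i] / (pv[i] - pv[i + 1])
            roots.append(float(fv[i] + t * (fv[i + 1] - fv[i])))
        i += 1
    return sorted(roots)
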