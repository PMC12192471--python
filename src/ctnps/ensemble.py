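"""Synthesis of repeated-reconstruction noise ensembles.

Emulates the study design in which the same raw data are reconstructed
n_rep times with identical parameters, so that differences between the
repetitions isolate image noise.  Noise fields are generated by spectral
shaping: a white Gaussian field is transformed to the frequency domain,
multiplied by sqrt(NPS_t)/pixel_size and transformed back, which makes the
expected NPS of each field equal the target profile.  Dose reduction follows
the quantum-noise model (variance proportional to 1/dose).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .phantom import ImageStack
from .profiles import MethodProfile

__all__ = ["NoiseEnsemble", "synthesize_ensemble", "simulate_dose_reduction"]


@dataclass(frozen=True)
class NoiseEnsemble:
    """n_rep repeated reconstructions of one slice set.

    ``images`` has shape (n_rep, n_slice, H, W) in HU.  ``provenance``
    records the method/dose labels, the seed and the generating profile.
    """

    images: np.ndarray
    pixel_size: float
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        imgs = np.asarray(self.images, dtype=float)
        if imgs.ndim != 4:
            raise ValueError("images must be 4D (n_rep, n_slice, H, W)")
        if imgs.shape[0] < 2:
            raise ValueError("an ensemble needs n_rep >= 2 repetitions")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "images", imgs)

    @property
    def n_rep(self) -> int:
        return self.images.shape[0]

    @property
    def n_slices(self) -> int:
        return self.images.shape[1]

    def noise_fields(self) -> np.ndarray:
        """Differences from the ensemble mean, shape like ``images``."""
        return self.images - self.images.mean(axis=0, keepdims=True)


def _shaping_filter(shape: tuple[int, int], pixel_size: float, profile: MethodProfile) -> np.ndarray:
    """sqrt(NPS_t)/pixel_size on the unshifted FFT frequency grid."""
    h, w = shape
    fy = np.fft.fftfreq(h, d=pixel_size)
    fx = np.fft.fftfreq(w, d=pixel_size)
    fmag = np.hypot(fy[:, None], fx[None, :])
    return np.sqrt(profile.nps(fmag)) / pixel_size


def _shaped_noise(rng: np.random.Generator, n_fields: int, shape: tuple[int, int], filt: np.ndarray) -> np.ndarray:
    """Zero-mean Gaussian fields with expected NPS equal to the target."""
    out = np.empty((n_fields,) + shape)
    for i in range(n_fields):
        white = rng.standard_normal(shape)
        out[i] = np.fft.ifft2(np.fft.fft2(white) * filt).real
    return out


def synthesize_ensemble(
    phantom: ImageStack,
    profile: MethodProfile,
    n_rep: int = 5,
    seed: int = 0,
) -> NoiseEnsemble:
    """Phantom plus n_rep independent noise fields with the profile's NPS.

    Noise is independent across repetitions and slices and fully reproducible
    from ``seed``.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    n_slice, h, w = phantom.shape
    rng = np.random.default_rng(seed)
    filt = _shaping_filter((h, w), phantom.pixel_size, profile)
    images = np.empty((n_rep, n_slice, h, w))
    for r in range(n_rep):
        images[r] = phantom.values + _shaped_noise(rng, n_slice, (h, w), filt)
    return NoiseEnsemble(
        images,
        phantom.pixel_size,
        provenance={
            "method": profile.method_name,
            "dose_fraction": profile.dose_fraction,
            "seed": int(seed),
            "profile": profile,
        },
    )


def simulate_dose_reduction(
    ens: NoiseEnsemble, fraction: float, seed: int | None = None
) -> NoiseEnsemble:
    """Emulate a lower-dose acquisition by quantum-noise insertion.

    Adds independent noise with the generating profile's spectral shape and
    variance sigma^2 * (1/fraction - 1), so total noise variance scales as
    1/fraction.  ``fraction = 1`` returns the input unchanged.  The added
    noise is seeded deterministically from the ensemble provenance unless an
    explicit ``seed`` is given.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("dose fraction must be in (0, 1]")
    if fraction == 1.0:
        return ens
    profile: MethodProfile | None = ens.provenance.get("profile")
    if profile is None:
        raise ValueError("ensemble provenance lacks the generating profile")
    if seed is None:
        base = int(ens.provenance.get("seed", 0))
        seed_seq = np.random.SeedSequence([base, int(round(fraction * 1_000_000)), 0x0D05])
    else:
        seed_seq = np.random.SeedSequence(int(seed))
    rng = np.random.default_rng(seed_seq)

    # additional NPS: (1/fraction - 1) times the current one
    extra = dataclasses.replace(profile, amplitude=profile.amplitude * (1.0 / fraction - 1.0))
    n_rep, n_slice, h, w = ens.images.shape
    filt = _shaping_filter((h, w), ens.pixel_size, extra)
    images = np.empty_like(ens.images)
    for r in range(n_rep):
        images[r] = ens.images[r] + _shaped_noise(rng, n_slice, (h, w), filt)
    new_fraction = ens.provenance.get("dose_fraction", profile.dose_fraction) * fraction
    prov = dict(ens.provenance)
    prov.update(
        dose_fraction=new_fraction,
        profile=profile.at_dose(max(new_fraction, 1e-12)) if new_fraction <= 1 else profile,
    )
    return NoiseEnsemble(images, ens.pixel_size, provenance=prov)
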