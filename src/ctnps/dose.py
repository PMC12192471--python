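"""Radiation dose bookkeeping: effective dose and cohort summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "HEAD_CONVERSION_K",
    "DoseRecord",
    "effective_dose",
    "cohort_dose_summary",
    "sample_dose_records",
]

#: ICRP conversion coefficient for head CT, mSv per mGy*cm.
HEAD_CONVERSION_K = 0.0021

#: Cohort protocol summaries (mean, SD) used as sampling defaults.
PROTOCOL_DOSE = {"ctdi_vol": (41.9, 2.9), "dlp": (638.4, 65.4), "effective_mas": (401.6, 28.7)}


@dataclass(frozen=True)
class DoseRecord:
    """Dose indices of one examination."""

    ctdi_vol: float  # mGy
    dlp: float  # mGy*cm
    effective_mas: float  # mAs
    conversion_k: float = HEAD_CONVERSION_K  # mSv / (mGy*cm)

    def __post_init__(self) -> None:
        for name in ("ctdi_vol", "dlp", "effective_mas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.conversion_k <= 0:
            raise ValueError("conversion_k must be > 0")

    @property
    def effective_dose(self) -> float:
        return effective_dose(self.dlp, self.conversion_k)


def effective_dose(dlp: float, k: float = HEAD_CONVERSION_K) -> float:
    """Effective dose in mSv: dose-length product times the conversion factor."""
    if dlp < 0:
        raise ValueError("dlp must be >= 0")
    if k <= 0:
        raise ValueError("conversion coefficient must be > 0")
    return dlp * k


def cohort_dose_summary(records: Sequence[DoseRecord]) -> dict[str, dict[str, float]]:
    """Mean +- SD and range per dose field, plus derived effective dose."""
    if not records:
        raise ValueError("no dose records")
    fields = {
        "ctdi_vol": [r.ctdi_vol for r in records],
        "dlp": [r.dlp for r in records],
        "effective_mas": [r.effective_mas for r in records],
        "effective_dose": [r.effective_dose for r in records],
    }
    out = {}
    for name, vals in fields.items():
        x = np.asarray(vals, dtype=float)
        out[name] = {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
            "min": float(x.min()),
            "max": float(x.max()),
            "n": int(x.size),
        }
    return out


def sample_dose_records(n: int = 21, seed: int = 0) -> list[DoseRecord]:
    """Draw a synthetic cohort of dose records around the protocol values."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    recs = []
    for _ in range(n):
        ctdi = max(0.0, rng.normal(*PROTOCOL_DOSE["ctdi_vol"]))
        dlp = max(0.0, rng.normal(*PROTOCOL_DOSE["dlp"]))
        mas = max(0.0, rng.normal(*PROTOCOL_DOSE["effective_mas"]))
        recs.append(DoseRecord(ctdi_vol=ctdi, dlp=dlp, effective_mas=mas))
    return recs
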