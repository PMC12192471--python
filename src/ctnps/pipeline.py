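"""End-to-end orchestration: simulate -> NPS -> compare -> stats -> report.

A single :class:`RunConfig` drives the whole chain: synthesize repeated
reconstruction ensembles for every method and dose fraction, estimate
cohort noise power spectra, integrate frequency bands and locate the
SAFIRE/ADMIRE crossovers, generate and analyze ROI and Likert tables, and
summarize cohort dose.  Identical config and seed give identical numeric
outputs; a manifest records the seed, a config hash and the file list.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .dose import cohort_dose_summary, sample_dose_records
from .ensemble import NoiseEnsemble, synthesize_ensemble
from .nps import (
    DEFAULT_ANGLES,
    NPSCurve,
    angular_average,
    band_integrals,
    cohort_nps,
    directional_spectrum,
    ensemble_power_map,
    find_crossovers,
    relative_improvement,
)
from .phantom import PhantomSpec, make_head_phantom
from .profiles import BAND_HIGH, BAND_LOW, default_method_profiles
from .stats import (
    bonferroni_pairwise,
    oneway_anova,
    paired_t,
    rm_anova_gg,
    summarize_ordinal,
    wilcoxon_signed_rank,
)
from .tables import generate_likert_table, generate_roi_table

log = logging.getLogger("ctnps")

__all__ = ["RunConfig", "run_full", "run_simulate", "run_nps", "run_compare", "run_stats", "trim_dc"]


@dataclass(frozen=True)
class RunConfig:
    """Protocol constants and run parameters for one pipeline execution."""

    mode: str = "full"  # simulate | analyze | full
    methods: tuple[str, ...] = ("FBP", "SAFIRE", "ADMIRE")
    dose_fractions: tuple[float, ...] = (1.0, 0.9, 0.7)
    n_rep: int = 5
    matrix_size: int = 512
    pixel_size: float = 0.429
    n_slices: int = 30
    n_subjects: int = 21
    icc: float = 0.8
    f_low: float = BAND_LOW
    f_high: float = BAND_HIGH
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "results"
    input_dir: str | None = None
    save_ensembles: bool = False

    def __post_init__(self) -> None:
        if self.mode not in {"simulate", "analyze", "full"}:
            raise ValueError("mode must be simulate, analyze or full")
        if not all(0.0 < d <= 1.0 for d in self.dose_fractions):
            raise ValueError("dose fractions must lie in (0, 1]")
        if self.n_rep < 2:
            raise ValueError("n_rep must be >= 2")
        if not (0.0 < self.f_low < self.f_high):
            raise ValueError("band boundaries must satisfy 0 < f_low < f_high")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        for key in ("methods", "dose_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(
            matrix_size=self.matrix_size,
            pixel_size=self.pixel_size,
            n_slices=self.n_slices,
        )


def _dose_tag(dose: float) -> str:
    return f"{int(round(dose * 100)):03d}"


def _child_seeds(config: RunConfig) -> dict[tuple[str, float], int]:
    tasks = [(m, d) for d in config.dose_fractions for m in config.methods]
    state = np.random.SeedSequence(config.seed).generate_state(len(tasks) + 2)
    seeds = {task: int(s & 0x7FFFFFFF) for task, s in zip(tasks, state)}
    seeds[("roi", -1.0)] = int(state[-2] & 0x7FFFFFFF)
    seeds[("dose", -1.0)] = int(state[-1] & 0x7FFFFFFF)
    return seeds


def trim_dc(curve: NPSCurve) -> NPSCurve:
    """Drop the DC bin (residual-mean power) from a curve."""
    if curve.frequencies.size and curve.frequencies[0] == 0.0:
        return NPSCurve(
            frequencies=curve.frequencies[1:],
            power=curve.power[1:],
            kind=curve.kind,
            angle=curve.angle,
            support_count=curve.support_count[1:],
            meta=curve.meta,
        )
    return curve


def estimate_cohort_nps(ens: NoiseEnsemble, angles: Sequence[float] = DEFAULT_ANGLES) -> NPSCurve:
    """Full estimation chain for one ensemble: power maps, 18 directional
    spectra per slice, angular average, cohort mean over slices."""
    per_slice = []
    for s in range(ens.n_slices):
        pmap = ensemble_power_map(ens, s)
        per_slice.append(angular_average([directional_spectrum(pmap, a) for a in angles]))
    return cohort_nps(per_slice)


def _synthesize_all(config: RunConfig) -> dict[tuple[str, float], NoiseEnsemble]:
    phantom, _ = make_head_phantom(config.phantom_spec())
    seeds = _child_seeds(config)
    out = {}
    for dose in config.dose_fractions:
        profiles = default_method_profiles(dose)
        for method in config.methods:
            log.info("synthesizing %s at dose %.0f%%", method, dose * 100)
            out[(method, dose)] = synthesize_ensemble(
                phantom, profiles[method], config.n_rep, seed=seeds[(method, dose)]
            )
    return out


def run_simulate(config: RunConfig) -> list[Path]:
    """Generate all ensembles and write them as NIfTI + sidecars."""
    out_dir = Path(config.out_dir) / "ensembles"
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (method, dose), ens in _synthesize_all(config).items():
        path = out_dir / f"ensemble_{method}_{_dose_tag(dose)}.nii"
        paths.append(cio.write_ensemble_nifti(ens, path))
    _write_manifest(config, paths)
    return paths


def _load_ensembles(config: RunConfig) -> dict[tuple[str, float], NoiseEnsemble]:
    in_dir = Path(config.input_dir or Path(config.out_dir) / "ensembles")
    expected = {
        (m, d): in_dir / f"ensemble_{m}_{_dose_tag(d)}.nii"
        for d in config.dose_fractions
        for m in config.methods
    }
    missing = [str(p) for p in expected.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(
            "analyze mode needs simulated ensembles; missing files:\n  " + "\n  ".join(missing)
        )
    return {task: cio.read_ensemble_nifti(p) for task, p in expected.items()}


def _analyze_nps(
    config: RunConfig, ensembles: dict[tuple[str, float], NoiseEnsemble]
) -> dict[str, Any]:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    curves: dict[tuple[str, float], NPSCurve] = {}
    band_rows = []
    for (method, dose), ens in ensembles.items():
        log.info("estimating NPS for %s at dose %.0f%%", method, dose * 100)
        curve = estimate_cohort_nps(ens)
        curves[(method, dose)] = curve
        cio.write_curve_csv(curve, out_dir / f"nps_{method}_{_dose_tag(dose)}.csv")
        bands = band_integrals(curve, config.f_low, config.f_high)
        band_rows.append(
            {
                "method": method,
                "dose": dose,
                "low_band": bands.low_band,
                "mid_band": bands.mid_band,
                "high_band": bands.high_band,
                "total": bands.total,
            }
        )
    pd.DataFrame(band_rows).to_csv(out_dir / "band_summaries.csv", index=False)

    report: dict[str, Any] = {"crossovers": {}, "fbp_dominates": {}}
    for dose in config.dose_fractions:
        if "SAFIRE" in config.methods and "ADMIRE" in config.methods:
            # drop the DC bin: it holds residual-mean power, not spectral
            # density, and its sign in a difference is arbitrary
            rel = relative_improvement(
                trim_dc(curves[("SAFIRE", dose)]), trim_dc(curves[("ADMIRE", dose)])
            )
            cio.write_curve_csv(rel, out_dir / f"relative_improvement_{_dose_tag(dose)}.csv")
            report["crossovers"][_dose_tag(dose)] = find_crossovers(rel)
        if "FBP" in config.methods:
            fbp = curves[("FBP", dose)].power
            others = [curves[(m, dose)].power for m in config.methods if m != "FBP"]
            if others:
                mask = curves[("FBP", dose)].frequencies > 0
                dominated = bool(np.all([np.all(fbp[mask] > o[mask]) for o in others]))
                report["fbp_dominates"][_dose_tag(dose)] = dominated
    cio.write_json(report, out_dir / "nps_comparison.json")
    return {"curves": curves, "bands": band_rows, "comparison": report}


def run_nps(config: RunConfig) -> dict[str, Any]:
    """Analyze previously simulated ensembles (analyze mode entry point)."""
    return _analyze_nps(config, _load_ensembles(config))


def run_compare(config: RunConfig) -> dict[str, Any]:
    """Recompute band integrals and crossovers from cohort curve CSVs."""
    out_dir = Path(config.out_dir)
    report: dict[str, Any] = {"crossovers": {}}
    for dose in config.dose_fractions:
        saf = cio.read_curve_csv(out_dir / f"nps_SAFIRE_{_dose_tag(dose)}.csv")
        adm = cio.read_curve_csv(out_dir / f"nps_ADMIRE_{_dose_tag(dose)}.csv")
        rel = relative_improvement(trim_dc(saf), trim_dc(adm))
        report["crossovers"][_dose_tag(dose)] = find_crossovers(rel)
    cio.write_json(report, out_dir / "nps_comparison.json")
    return report


def run_stats(config: RunConfig) -> dict[str, Any]:
    """Generate ROI/Likert tables and run the statistical battery on them."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config)

    roi = generate_roi_table(n_subjects=config.n_subjects, seed=seeds[("roi", -1.0)], icc=config.icc)
    roi.to_csv(out_dir / "roi_table.csv", index=False)
    anova_rows, pairwise_rows, paired_rows = [], [], []
    for tissue in sorted(roi["tissue"].unique()):
        for dose in config.dose_fractions:
            sub = roi[(roi["tissue"] == tissue) & (roi["dose"] == dose)]
            groups = {
                m: sub[sub["method"] == m].sort_values("subject")["mean_hu"].to_numpy()
                for m in config.methods
            }
            f, df1, df2, p = oneway_anova(list(groups.values()))
            anova_rows.append({"tissue": tissue, "dose": dose, "F": f, "df1": df1, "df2": df2, "p": p})
            for cmp_ in bonferroni_pairwise(groups, alpha=config.alpha):
                pairwise_rows.append(
                    {
                        "tissue": tissue,
                        "dose": dose,
                        "group_1": cmp_.group_1,
                        "group_2": cmp_.group_2,
                        "mean_difference": cmp_.mean_difference,
                        "ci_low": cmp_.ci_low,
                        "ci_high": cmp_.ci_high,
                        "adjusted_p": cmp_.adjusted_p,
                        "sem": cmp_.sem,
                    }
                )
            if {"SAFIRE", "ADMIRE"} <= set(config.methods):
                t, df, tp = paired_t(groups["ADMIRE"], groups["SAFIRE"])
                paired_rows.append({"tissue": tissue, "dose": dose, "t": t, "df": df, "p": tp})
    pd.DataFrame(anova_rows).to_csv(out_dir / "roi_anova.csv", index=False)
    pd.DataFrame(pairwise_rows).to_csv(out_dir / "roi_pairwise.csv", index=False)
    pd.DataFrame(paired_rows).to_csv(out_dir / "roi_paired_t.csv", index=False)

    likert = generate_likert_table(n_subjects=config.n_subjects)
    likert.to_csv(out_dir / "likert_table.csv", index=False)
    summary_rows, wilcoxon_rows = [], []
    for (category, method), cell in likert.groupby(["category", "method"]):
        by_dose = {
            d: cell[cell["dose"] == d].sort_values("subject")["score"].to_numpy()
            for d in config.dose_fractions
        }
        for d, scores in by_dose.items():
            med, (q1, q3), mean, sd = summarize_ordinal(scores)
            summary_rows.append(
                {
                    "category": category,
                    "method": method,
                    "dose": d,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "mean": mean,
                    "sd": sd,
                }
            )
        for d1, d2 in [(1.0, 0.9), (1.0, 0.7), (0.9, 0.7)]:
            if d1 not in by_dose or d2 not in by_dose:
                continue
            try:
                w, z, p = wilcoxon_signed_rank(by_dose[d1], by_dose[d2])
            except ValueError:
                # fewer than 5 informative pairs: no evidence of a dose effect
                w, z, p = 0.0, 0.0, 1.0
            wilcoxon_rows.append(
                {"category": category, "method": method, "dose_1": d1, "dose_2": d2, "W": w, "Z": z, "p": p}
            )
    pd.DataFrame(summary_rows).to_csv(out_dir / "likert_summary.csv", index=False)
    pd.DataFrame(wilcoxon_rows).to_csv(out_dir / "likert_wilcoxon.csv", index=False)

    # pooled subjective scores: mean over categories per subject x condition
    pooled = (
        likert.groupby(["subject", "method", "dose"])["score"].mean().reset_index()
    )
    wide = pooled.pivot_table(index="subject", columns=["method", "dose"], values="score")
    rm = rm_anova_gg(wide.to_numpy())
    rm_report = {
        "F": rm.F,
        "df1": rm.df1,
        "df2": rm.df2,
        "p": rm.p,
        "epsilon_gg": rm.epsilon_gg,
        "partial_eta_sq": rm.partial_eta_sq,
        "k_conditions": int(wide.shape[1]),
        "n_subjects": int(wide.shape[0]),
    }
    cio.write_json(rm_report, out_dir / "likert_rm_anova.json")

    records = sample_dose_records(config.n_subjects, seed=seeds[("dose", -1.0)])
    dose_summary = cohort_dose_summary(records)
    cio.write_json(dose_summary, out_dir / "dose_summary.json")

    return {
        "roi_anova": anova_rows,
        "roi_pairwise": pairwise_rows,
        "roi_paired_t": paired_rows,
        "likert_summary": summary_rows,
        "likert_wilcoxon": wilcoxon_rows,
        "rm_anova": rm_report,
        "dose_summary": dose_summary,
    }


def _write_manifest(config: RunConfig, paths: Sequence[Path]) -> None:
    from . import __version__

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash,
        "config": config.to_dict(),
        "version": __version__,
        "outputs": sorted(str(p) for p in paths),
    }
    cio.write_json(manifest, out_dir / "manifest.json")


def run_full(config: RunConfig) -> dict[str, Any]:
    """Run the whole pipeline; returns the in-memory report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.mode == "analyze":
        ensembles = _load_ensembles(config)
    else:
        ensembles = _synthesize_all(config)
        if config.save_ensembles:
            ens_dir = out_dir / "ensembles"
            ens_dir.mkdir(exist_ok=True)
            for (method, dose), ens in ensembles.items():
                cio.write_ensemble_nifti(ens, ens_dir / f"ensemble_{method}_{_dose_tag(dose)}.nii")
    nps_report = _analyze_nps(config, ensembles)
    stats_report = run_stats(config)
    _write_manifest(config, sorted(out_dir.glob("*")))
    return {**nps_report, **stats_report}
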