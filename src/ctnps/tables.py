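"""Synthetic ROI and Likert tables with the study's statistical structure.

The generators emulate the observed-data tables of the emulated reading
study: per-patient GM/WM mean Hounsfield units by reconstruction method and
dose (normal model with a shared within-subject offset, since all methods
reconstruct the same scan), and per-patient ordinal 1-10 quality scores
whose per-cell mean and SD match printed "Mdn (IQR) Mean +- SD" summaries
via an exhaustive small-support multiset search.

``TABLE_HU`` and ``TABLE_LIKERT`` hold the published cohort summaries
(n = 21) used as default generator parameters; they define the study
conditions rather than tunable inputs.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "METHODS",
    "DOSES",
    "TISSUES",
    "CATEGORIES",
    "TABLE_HU",
    "TABLE_LIKERT",
    "generate_roi_table",
    "generate_likert_table",
    "find_score_multiset",
]

METHODS = ("FBP", "SAFIRE", "ADMIRE")
DOSES = (1.0, 0.9, 0.7)
TISSUES = ("GM", "WM")
CATEGORIES = ("overall", "detail", "noise", "contrast", "artifacts")

N_SUBJECTS = 21

#: (tissue, method, dose) -> (mean HU, SD HU), cohort of 21 patients.
TABLE_HU: dict[tuple[str, str, float], tuple[float, float]] = {
    ("GM", "FBP", 1.0): (39.916, 1.275),
    ("GM", "SAFIRE", 1.0): (41.254, 1.251),
    ("GM", "ADMIRE", 1.0): (39.967, 1.180),
    ("WM", "FBP", 1.0): (33.452, 1.424),
    ("WM", "SAFIRE", 1.0): (32.913, 1.703),
    ("WM", "ADMIRE", 1.0): (33.542, 1.472),
    ("GM", "FBP", 0.9): (39.795, 1.280),
    ("GM", "SAFIRE", 0.9): (41.182, 1.335),
    ("GM", "ADMIRE", 0.9): (39.870, 1.197),
    ("WM", "FBP", 0.9): (33.339, 1.421),
    ("WM", "SAFIRE", 0.9): (32.847, 1.673),
    ("WM", "ADMIRE", 0.9): (33.444, 1.494),
    ("GM", "FBP", 0.7): (39.815, 1.246),
    ("GM", "SAFIRE", 0.7): (41.176, 1.317),
    ("GM", "ADMIRE", 0.7): (39.843, 1.153),
    ("WM", "FBP", 0.7): (33.325, 1.384),
    ("WM", "SAFIRE", 0.7): (32.843, 1.626),
    ("WM", "ADMIRE", 0.7): (33.417, 1.490),
}

#: (category, method, dose) -> (median, (q1, q3), mean, SD) for the 1-10
#: Likert ratings of the 21 datasets.
TABLE_LIKERT: dict[tuple[str, str, float], tuple[float, tuple[float, float], float, float]] = {
    ("overall", "FBP", 1.0): (4, (4, 5), 4.48, 0.51),
    ("overall", "FBP", 0.9): (4, (4, 4), 3.95, 0.25),
    ("overall", "FBP", 0.7): (3, (2, 3), 2.71, 0.46),
    ("overall", "SAFIRE", 1.0): (8, (7, 8), 7.57, 0.51),
    ("overall", "SAFIRE", 0.9): (8, (8, 8), 7.95, 0.21),
    ("overall", "SAFIRE", 0.7): (7, (7, 7), 6.95, 0.20),
    ("overall", "ADMIRE", 1.0): (9, (9, 9), 8.95, 0.22),
    ("overall", "ADMIRE", 0.9): (9, (9, 9), 8.95, 0.22),
    ("overall", "ADMIRE", 0.7): (8, (8, 8), 7.95, 0.19),
    ("detail", "FBP", 1.0): (4, (3, 4), 3.57, 0.51),
    ("detail", "FBP", 0.9): (3, (3, 3), 2.86, 0.36),
    ("detail", "FBP", 0.7): (2, (2, 2.5), 2.24, 0.44),
    ("detail", "SAFIRE", 1.0): (7, (7, 7), 6.95, 0.21),
    ("detail", "SAFIRE", 0.9): (7, (7, 7), 7.05, 0.22),
    ("detail", "SAFIRE", 0.7): (6, (6, 6), 5.95, 0.23),
    ("detail", "ADMIRE", 1.0): (9, (9, 9), 8.95, 0.18),
    ("detail", "ADMIRE", 0.9): (8, (8, 9), 8.48, 0.51),
    ("detail", "ADMIRE", 0.7): (7, (7, 7), 6.95, 0.22),
    ("noise", "FBP", 1.0): (4, (4, 4), 3.95, 0.22),
    ("noise", "FBP", 0.9): (4, (4, 4), 3.95, 0.23),
    ("noise", "FBP", 0.7): (3, (3, 3), 2.95, 0.22),
    ("noise", "SAFIRE", 1.0): (9, (8, 9), 8.67, 0.48),
    ("noise", "SAFIRE", 0.9): (8, (7.5, 8), 7.76, 0.44),
    ("noise", "SAFIRE", 0.7): (7, (7, 7), 6.95, 0.22),
    ("noise", "ADMIRE", 1.0): (9, (8.5, 9), 8.76, 0.44),
    ("noise", "ADMIRE", 0.9): (8, (8, 8), 8.05, 0.22),
    ("noise", "ADMIRE", 0.7): (6, (6, 6), 6.00, 0.45),
    ("contrast", "FBP", 1.0): (5, (5, 5), 4.95, 0.24),
    ("contrast", "FBP", 0.9): (4, (4, 5), 4.48, 0.51),
    ("contrast", "FBP", 0.7): (3, (3, 3), 2.95, 0.24),
    ("contrast", "SAFIRE", 1.0): (9, (9, 9), 9.05, 0.22),
    ("contrast", "SAFIRE", 0.9): (9, (9, 9), 8.95, 0.22),
    ("contrast", "SAFIRE", 0.7): (8, (8, 8), 7.95, 0.24),
    ("contrast", "ADMIRE", 1.0): (7, (7, 7), 6.95, 0.24),
    ("contrast", "ADMIRE", 0.9): (7, (7, 7), 6.95, 0.22),
    ("contrast", "ADMIRE", 0.7): (6, (6, 6), 5.95, 0.22),
    ("artifacts", "FBP", 1.0): (7, (7, 7), 6.95, 0.22),
    ("artifacts", "FBP", 0.9): (6, (5, 6), 5.48, 0.93),
    ("artifacts", "FBP", 0.7): (5, (5, 5), 4.95, 0.21),
    ("artifacts", "SAFIRE", 1.0): (5, (5, 6), 5.48, 0.51),
    ("artifacts", "SAFIRE", 0.9): (4, (4, 4), 4.19, 0.40),
    ("artifacts", "SAFIRE", 0.7): (4, (4, 4), 3.95, 0.22),
    ("artifacts", "ADMIRE", 1.0): (9, (9, 9), 8.95, 0.22),
    ("artifacts", "ADMIRE", 0.9): (9, (9, 9), 8.95, 0.21),
    ("artifacts", "ADMIRE", 0.7): (8, (8, 8), 7.95, 0.24),
}


def generate_roi_table(
    group_params: Mapping[tuple[str, str, float], tuple[float, float]] | None = None,
    n_subjects: int = N_SUBJECTS,
    seed: int = 0,
    icc: float = 0.8,
) -> pd.DataFrame:
    """Per-patient GM/WM mean HU draws with within-subject correlation.

    Each cell (tissue, method, dose) has its own normal (mean, SD); a
    subject's values across methods and doses share a per-subject-and-tissue
    standard-normal offset weighted by sqrt(icc), because every method and
    dose level is reconstructed from the same scan of the same patient.
    Marginal cell SDs are preserved and the within-subject correlation
    between any two cells of the same tissue equals ``icc``.
    """
    if group_params is None:
        group_params = TABLE_HU
    if n_subjects < 2:
        raise ValueError("need n_subjects >= 2")
    if not (0.0 <= icc < 1.0):
        raise ValueError("icc must be in [0, 1)")
    if any(sd <= 0 for _, sd in group_params.values()):
        raise ValueError("all cell SDs must be > 0")
    rng = np.random.default_rng(seed)
    tissues = sorted({t for t, _, _ in group_params})
    shared = {t: rng.standard_normal(n_subjects) for t in tissues}
    rows = []
    for (tissue, method, dose), (mean, sd) in group_params.items():
        eps = rng.standard_normal(n_subjects)
        vals = mean + sd * (np.sqrt(icc) * shared[tissue] + np.sqrt(1.0 - icc) * eps)
        for s, v in enumerate(vals, start=1):
            rows.append((s, method, dose, tissue, float(v)))
    return pd.DataFrame(rows, columns=["subject", "method", "dose", "tissue", "mean_hu"])


def find_score_multiset(
    mean: float,
    sd: float,
    n: int,
    lo: int = 1,
    hi: int = 10,
    tol: float = 0.05,
) -> tuple[np.ndarray, bool]:
    """Integer score multiset of size n matching a printed mean and SD.

    Exhaustively searches multisets supported on at most three distinct
    values in [lo, hi] and returns the one minimizing the summed squared
    mean/SD error, sorted descending, together with a flag saying whether
    both errors are within ``tol``.  Infeasible summaries yield the nearest
    achievable multiset and a warning.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    values = list(range(lo, hi + 1))
    best: tuple[float, tuple[int, ...], tuple[int, ...]] | None = None

    def consider(vals: tuple[int, ...], counts: tuple[int, ...]) -> None:
        nonlocal best
        total = float(np.dot(counts, vals))
        mu = total / n
        var = float(np.dot(counts, (np.asarray(vals, float) - mu) ** 2)) / (n - 1)
        err = (mu - mean) ** 2 + (np.sqrt(var) - sd) ** 2
        if best is None or err < best[0]:
            best = (err, vals, counts)

    for v in values:
        consider((v,), (n,))
    for a, b in itertools.combinations(values, 2):
        for k in range(1, n):
            consider((a, b), (k, n - k))
    for a, b, c in itertools.combinations(values, 3):
        for ka in range(1, n - 1):
            for kb in range(1, n - ka):
                consider((a, b, c), (ka, kb, n - ka - kb))

    assert best is not None
    _, vals, counts = best
    scores = np.repeat(vals, counts)
    mu = scores.mean()
    s = scores.std(ddof=1)
    feasible = abs(mu - mean) <= tol and abs(s - sd) <= tol
    if not feasible:
        warnings.warn(
            f"no integer multiset on [{lo},{hi}] matches mean={mean}, sd={sd} "
            f"(n={n}) within {tol}; nearest achieves mean={mu:.3f}, sd={s:.3f}",
            stacklevel=2,
        )
    return np.sort(scores)[::-1], feasible


def generate_likert_table(
    cell_summaries: Mapping[tuple[str, str, float], tuple[float, tuple[float, float], float, float]] | None = None,
    n_subjects: int = N_SUBJECTS,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-patient ordinal scores reproducing per-cell Mdn/IQR/mean/SD.

    Each cell's score multiset comes from :func:`find_score_multiset` on the
    printed mean and SD.  Scores are assigned to subjects in a fixed
    descending order, which keeps ratings maximally concordant within a
    subject across methods and doses (a dataset scored high at one dose is
    scored high at the others) - the natural structure for paired dose
    comparisons.  ``seed`` is accepted for interface symmetry; the
    construction itself is deterministic.
    """
    if cell_summaries is None:
        cell_summaries = TABLE_LIKERT
    if n_subjects < 2:
        raise ValueError("need n_subjects >= 2")
    del seed  # deterministic construction; see docstring
    rows = []
    for (category, method, dose), (_, _, mean, sd) in cell_summaries.items():
        scores, _ = find_score_multiset(mean, sd, n_subjects)
        for s, v in enumerate(scores, start=1):
            rows.append((s, category, method, dose, int(v)))
    df = pd.DataFrame(rows, columns=["subject", "category", "method", "dose", "score"])
    if not df["score"].between(1, 10).all():
        raise AssertionError("scores escaped the 1-10 range")
    return df
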