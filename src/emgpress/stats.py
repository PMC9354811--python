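"""Within-subject statistics for the activation table.

Per muscle: Shapiro-Wilk normality screening, a fully-within 2x2x2
repeated-measures ANOVA (factors: load = barbell/machine, position =
front/back, phase = ascending/descending) with partial eta squared,
Bonferroni-adjusted paired contrasts, and Cohen's d effect sizes with
z-based 95% confidence intervals classified on the Hopkins scale.

Every factor has two levels, so each of the seven effects has 1 numerator
df, its error term is the effect-by-subject interaction with n-1 df, and
no sphericity correction exists or is applied. Each 1-df F equals the
squared paired t statistic of the corresponding +-1 contrast of cell
means, a property the test suite exploits as an independent oracle.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spst

from .datatypes import ANALYZED_PHASES, exercise_factors

__all__ = [
    "EFFECTS",
    "shapiro_wilk",
    "cell_table",
    "rm_anova_2x2x2",
    "partial_eta_squared",
    "cohens_d",
    "cohens_d_ci",
    "hopkins_classify",
    "pairwise_contrasts",
    "default_families",
    "analyze_activations",
]

#: The seven within-subject effects, in report order.
EFFECTS = (
    "load",
    "position",
    "phase",
    "load x position",
    "load x phase",
    "position x phase",
    "load x position x phase",
)

#: Cell order used throughout: (load, position, phase), phase fastest.
CELL_ORDER = tuple(
    (load, position, phase)
    for load in ("barbell", "machine")
    for position in ("front", "back")
    for phase in ANALYZED_PHASES
)


def shapiro_wilk(sample: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p for a sample of 3..50 values.

    Screening only: the pipeline never branches on the outcome. Degenerate
    (constant) samples raise, since W is undefined.
    """
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 50:
        raise ValueError(f"Shapiro-Wilk needs 3..50 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = spst.shapiro(x)
    return float(w), float(p)


def cell_table(activations: pd.DataFrame, muscle: str) -> pd.DataFrame:
    """Participants x 8-cell wide table of nRMS for one muscle.

    Columns are a MultiIndex (load, position, phase) in canonical order;
    raises if any participant x cell combination is missing.
    """
    sub = activations[activations["muscle"] == muscle]
    if sub.empty:
        raise ValueError(f"no activation rows for muscle {muscle!r}")
    wide = sub.pivot_table(
        index="participant",
        columns=["load", "position", "phase"],
        values="nrms_percent",
        aggfunc="mean",
    )
    missing = [c for c in CELL_ORDER if c not in wide.columns]
    if missing or wide.isna().any().any():
        raise ValueError(
            f"incomplete cell table for {muscle!r}; missing cells: {missing}"
        )
    return wide[list(CELL_ORDER)]


def _contrast_matrix() -> np.ndarray:
    """7 x 8 matrix of +-1 contrast codes over CELL_ORDER (effects x cells)."""
    codes = np.array(
        [
            [1 if load == "barbell" else -1, 1 if pos == "front" else -1,
             1 if ph == "ascending" else -1]
            for load, pos, ph in CELL_ORDER
        ]
    ).T  # 3 x 8
    a, b, c = codes
    return np.vstack([a, b, c, a * b, a * c, b * c, a * b * c])


_C = _contrast_matrix()


def rm_anova_batch(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 2x2x2 within-subject ANOVA.

    ``values``: (..., n, 8) arrays in CELL_ORDER. Returns (F, p), each of
    shape (..., 7). For every effect, F = MS_effect / MS_(effect x subject)
    on (1, n-1) df.
    """
    y = np.asarray(values, dtype=float)
    n = y.shape[-2]
    if n < 2:
        raise ValueError("need at least 2 participants")
    scores = y @ _C.T / 4.0  # (..., n, 7) per-subject contrast scores
    mean = scores.mean(axis=-2)
    var = scores.var(axis=-2, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = n * mean**2 / var
    f = np.where(var == 0, np.inf, f)
    p = spst.f.sf(f, 1, n - 1)
    return f, p


def rm_anova_2x2x2(cells: pd.DataFrame) -> pd.DataFrame:
    """Three-way repeated-measures ANOVA on one muscle's cell table.

    Returns one row per effect: effect, F, df_num, df_den, p, eta_p_sq.
    """
    y = cells.to_numpy(dtype=float)
    if y.shape[1] != 8:
        raise ValueError("cell table must have exactly 8 condition columns")
    if np.isnan(y).any():
        raise ValueError("cell table contains missing cells")
    n = y.shape[0]
    f, p = rm_anova_batch(y)
    return pd.DataFrame(
        {
            "effect": EFFECTS,
            "F": f,
            "df_num": 1,
            "df_den": n - 1,
            "p": p,
            "eta_p_sq": [partial_eta_squared(fi, 1, n - 1) for fi in f],
        }
    )


def ss_decomposition(cells: pd.DataFrame) -> dict[str, float]:
    """Sum-of-squares decomposition of one muscle's cell table.

    total = subject + sum(effect) + sum(effect x subject); the identity
    holds exactly because the 7 contrasts plus the grand mean form an
    orthogonal basis of the 8 cells.
    """
    y = cells.to_numpy(dtype=float)
    n = y.shape[0]
    grand = y.mean()
    out: dict[str, float] = {
        "total": float(((y - grand) ** 2).sum()),
        "subject": float(8.0 * ((y.mean(axis=1) - grand) ** 2).sum()),
    }
    scores = y @ _C.T / 4.0
    lbar = scores.mean(axis=0)
    for j, eff in enumerate(EFFECTS):
        out[f"effect:{eff}"] = float(2.0 * n * lbar[j] ** 2)
        out[f"error:{eff}"] = float(2.0 * ((scores[:, j] - lbar[j]) ** 2).sum())
    return out


def partial_eta_squared(F: float, df_num: int, df_den: int) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ValueError("F must be non-negative")
    if df_num < 1 or df_den < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return (F * df_num) / (F * df_num + df_den)


def cohens_d(x1: Sequence[float], x2: Sequence[float]) -> float:
    """Cohen's d with pooled SD (n-1 denominators, no small-sample
    correction): (mean1 - mean2) / sqrt((var1 + var2) / 2)."""
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("cohens_d needs two equal-length samples of n >= 2")
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        raise ValueError("pooled SD is zero; d is undefined")
    return float((a.mean() - b.mean()) / pooled)


def cohens_d_ci(
    d: float, n1: int, n2: int, level: float = 0.95
) -> tuple[float, float]:
    """z-based confidence interval for Cohen's d.

    SE = sqrt((n1+n2)/(n1*n2) + d^2 / (2*(n1+n2))), bounds d -/+ z*SE.
    The normal (not noncentral-t) interval is the conventional reporting
    form this package reproduces; it under-covers somewhat at small n,
    which the test suite documents rather than corrects.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    z = spst.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    return (float(d - z * se), float(d + z * se))


#: Hopkins qualitative bands for |d|, left-closed.
_HOPKINS = ((2.0, "very large"), (1.2, "large"), (0.6, "moderate"), (0.2, "small"))


def hopkins_classify(d: float) -> str:
    """Hopkins label for |d|: <0.2 trivial, <0.6 small, <1.2 moderate,
    <2.0 large, >=2.0 very large."""
    if not np.isfinite(d):
        raise ValueError("d must be finite")
    mag = abs(d)
    for cut, label in _HOPKINS:
        if mag >= cut:
            return label
    return "trivial"


def default_families(
    muscle: str, mode: str = "per-phase"
) -> list[tuple[str, list[tuple[str, tuple, tuple]]]]:
    """Bonferroni families of paired contrasts for one muscle.

    per-phase (default): within each phase, the 6 exercise pairs form one
    family (m=6); the 4 ascending-vs-descending contrasts form another
    (m=4). global: all 28 cell pairs in a single family.
    """
    conditions = {
        ("front_BMP",): ("barbell", "front"),
        ("back_BMP",): ("barbell", "back"),
        ("front_MSP",): ("machine", "front"),
        ("back_MSP",): ("machine", "back"),
    }
    exercises = [k[0] for k in conditions]

    def cell(exercise: str, phase: str) -> tuple:
        load, position = exercise_factors(exercise)
        return (load, position, phase)

    if mode == "per-phase":
        families = []
        for phase in ANALYZED_PHASES:
            pairs = [
                (f"{e1} vs {e2} ({phase})", cell(e1, phase), cell(e2, phase))
                for e1, e2 in itertools.combinations(exercises, 2)
            ]
            families.append((f"{muscle}:{phase}:exercise_pairs", pairs))
        phase_pairs = [
            (
                f"{e} ascending vs descending",
                cell(e, "ascending"),
                cell(e, "descending"),
            )
            for e in exercises
        ]
        families.append((f"{muscle}:ascending_vs_descending", phase_pairs))
        return families
    if mode == "global":
        cells = [cell(e, ph) for e in exercises for ph in ANALYZED_PHASES]
        labels = [f"{e} ({ph})" for e in exercises for ph in ANALYZED_PHASES]
        pairs = [
            (f"{labels[i]} vs {labels[j]}", cells[i], cells[j])
            for i, j in itertools.combinations(range(len(cells)), 2)
        ]
        return [(f"{muscle}:all_pairs", pairs)]
    raise ValueError(f"unknown family mode {mode!r}")


def pairwise_contrasts(
    cells: pd.DataFrame,
    families: Iterable[tuple[str, list[tuple[str, tuple, tuple]]]],
) -> pd.DataFrame:
    """Paired t-tests with Bonferroni adjustment within each family.

    ``families``: iterable of (family_id, [(pair_label, colA, colB), ...]).
    Each row carries the mean difference, t, raw and adjusted p, Cohen's d
    with its 95% CI, and the Hopkins label.
    """
    rows = []
    for family_id, pairs in families:
        m = len(pairs)
        for label, col_a, col_b in pairs:
            for col in (col_a, col_b):
                if col not in cells.columns:
                    raise ValueError(f"pair {label!r} references absent cell {col}")
            a = cells[col_a].to_numpy(dtype=float)
            b = cells[col_b].to_numpy(dtype=float)
            diff = a - b
            if np.all(diff == 0):
                t_stat, p_raw = 0.0, 1.0  # identical columns: no difference
            else:
                t_stat, p_raw = spst.ttest_rel(a, b)
            d = cohens_d(a, b) if (a.var(ddof=1) + b.var(ddof=1)) > 0 else 0.0
            lo, hi = cohens_d_ci(d, a.size, b.size)
            rows.append(
                {
                    "family": family_id,
                    "pair": label,
                    "mean_diff": float(np.mean(diff)),
                    "t": float(t_stat),
                    "p_raw": float(p_raw),
                    "p_adj": float(min(1.0, m * p_raw)),
                    "d": float(d),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "hopkins": hopkins_classify(d),
                    "family_size": m,
                }
            )
    return pd.DataFrame(rows)


def analyze_activations(
    activations: pd.DataFrame, family_mode: str = "per-phase"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full statistical layer over an activation table.

    Returns (anova, pairwise, shapiro) DataFrames, one block per muscle.
    """
    anova_rows, pairwise_frames, shapiro_rows = [], [], []
    for muscle in activations["muscle"].unique():
        cells = cell_table(activations, muscle)
        an = rm_anova_2x2x2(cells)
        an.insert(0, "muscle", muscle)
        anova_rows.append(an)
        pw = pairwise_contrasts(cells, default_families(muscle, family_mode))
        pw.insert(0, "muscle", muscle)
        pairwise_frames.append(pw)
        for col in cells.columns:
            try:
                w, p = shapiro_wilk(cells[col].to_numpy())
            except ValueError:
                w, p = float("nan"), float("nan")
            shapiro_rows.append(
                {
                    "muscle": muscle,
                    "cell": "/".join(col),
                    "W": w,
                    "p": p,
                    "degenerate": not np.isfinite(w),
                }
            )
    return (
        pd.concat(anova_rows, ignore_index=True),
        pd.concat(pairwise_frames, ignore_index=True),
        pd.DataFrame(shapiro_rows),
    )
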