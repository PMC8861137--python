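"""Cohort statistics for plate-level calcium concentrations.

Comparisons between healthy and degenerated (DDD) plates:

* two-way fixed-effects ANOVA (condition x vertebral level), Type III
  sums of squares with sum-to-zero contrasts so unbalanced cohorts are
  handled the way mainstream commercial statistics packages do;
* Sidak adjustment for the family of level-wise condition comparisons;
* percent-of-healthy ratios (DDD mean as an integer percentage of the
  healthy mean), the headline effect sizes;
* per-subject superior/inferior plate ratios within a motion segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import DesignError, ParameterError


@dataclass(frozen=True)
class PlateRecord:
    """Relative calcium concentration of one plate."""

    subject: str
    level: str
    side: str  # superior | inferior
    condition: str  # healthy | ddd
    relative_ca: float

    def __post_init__(self) -> None:
        if self.relative_ca <= 0:
            raise ParameterError(f"relative_ca must be > 0, got {self.relative_ca}")


def records_to_frame(records) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    dup = df.duplicated(subset=["subject", "level", "side"])
    if dup.any():
        raise ParameterError(
            f"duplicate (subject, level, side) plates: {df[dup].to_dict('records')}"
        )
    return df


def two_way_anova(records, side: str | None = None) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA of relative_ca on condition x level.

    Type III sums of squares with sum-to-zero contrasts (valid for
    unbalanced cohorts).  Returns a table with sum_sq, df, F and p per
    effect plus the residual row.  Superior and inferior plates are
    analysed separately (pass ``side``) to match the per-side panels the
    ratios are reported on.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if side is not None:
        df = df[df["side"] == side]
    for factor in ("condition", "level"):
        if df[factor].nunique() < 2:
            raise DesignError(f"factor {factor!r} has fewer than 2 levels")
    counts = df.groupby(["condition", "level"], observed=True).size()
    if (counts < 1).any():
        raise DesignError("every nonempty design cell needs >= 1 observation")
    model = smf.ols(
        "relative_ca ~ C(condition, Sum) * C(level, Sum)", data=df
    ).fit()
    table = sm.stats.anova_lm(model, typ=3)
    table = table.rename(
        index={
            "C(condition, Sum)": "condition",
            "C(level, Sum)": "level",
            "C(condition, Sum):C(level, Sum)": "condition:level",
            "Residual": "residual",
        }
    ).drop(index="Intercept")
    return table[["sum_sq", "df", "F", "PR(>F)"]].rename(columns={"PR(>F)": "p"})


def level_wise_condition_tests(records, side: str) -> pd.DataFrame:
    """Welch t-test of ddd vs healthy within each level, Sidak-adjusted.

    The Sidak family is the set of level-wise comparisons run for the
    side (one per level present).
    """
    from scipy import stats

    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df[df["side"] == side]
    rows = []
    for level, grp in df.groupby("level", observed=True):
        h = grp.loc[grp.condition == "healthy", "relative_ca"].to_numpy()
        d = grp.loc[grp.condition == "ddd", "relative_ca"].to_numpy()
        if len(h) < 2 or len(d) < 2:
            continue
        t, p = stats.ttest_ind(d, h, equal_var=False)
        rows.append(
            {
                "level": level,
                "mean_healthy": h.mean(),
                "mean_ddd": d.mean(),
                "percent_of_healthy": percent_of_healthy(d.mean(), h.mean()),
                "t": float(t),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_sidak"] = sidak_adjust(out["p"].to_numpy(), m=len(out))
        out["significant"] = out["p_sidak"] < 0.05
    return out


def sidak_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Sidak multiple-comparison adjustment: p_adj = 1 - (1 - p)^m."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ParameterError(f"family size must be >= 1, got {m}")
    return np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0)


def percent_of_healthy(mean_ddd: float, mean_healthy: float) -> int:
    """DDD mean as an integer percent of the healthy mean.

    Rounded to the nearest integer, halves away from zero — the
    convention that reproduces printed cohort percentages from printed
    means.
    """
    if mean_healthy <= 0:
        raise ParameterError(f"healthy mean must be > 0, got {mean_healthy}")
    x = 100.0 * mean_ddd / mean_healthy
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


@dataclass(frozen=True)
class RatioSummary:
    segment: str
    ratios: tuple  # per-subject inferior(upper)/superior(lower) ratios
    subjects: tuple
    excluded_subjects: tuple
    mean: float
    sd: float  # sample sd (ddof=1); NaN for a single subject


def superior_inferior_ratio(records, segment: str) -> RatioSummary:
    """Per-subject ratio of the plates facing one disc.

    For segment "L4/L5" the ratio is
    relative_ca(inferior plate of L4) / relative_ca(superior plate of L5),
    i.e. the plate cranial to the disc over the plate caudal to it.
    Subjects missing either plate are excluded and reported.
    """
    try:
        upper, lower = segment.split("/")
    except ValueError as exc:
        raise ParameterError(f"segment must look like 'L4/L5', got {segment!r}") from exc
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    inf = df[(df.level == upper) & (df.side == "inferior")].set_index("subject")
    sup = df[(df.level == lower) & (df.side == "superior")].set_index("subject")
    subjects = sorted(set(inf.index) & set(sup.index))
    excluded = sorted((set(inf.index) | set(sup.index)) - set(subjects))
    if not subjects:
        raise DesignError(f"no subject has both plates of segment {segment}")
    ratios = tuple(
        float(inf.loc[s, "relative_ca"] / sup.loc[s, "relative_ca"]) for s in subjects
    )
    arr = np.asarray(ratios)
    return RatioSummary(
        segment=segment,
        ratios=ratios,
        subjects=tuple(subjects),
        excluded_subjects=tuple(excluded),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
    )


__all__ = [
    "PlateRecord",
    "RatioSummary",
    "records_to_frame",
    "two_way_anova",
    "level_wise_condition_tests",
    "sidak_adjust",
    "percent_of_healthy",
    "superior_inferior_ratio",
]
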