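"""Reference oxidation chemistry: peroxide value, UV extinction coefficients,
fatty-acid class sums, and univariate three-way ANOVA with Tukey HSD.

The peroxide value comes from iodometric titration (meq O2 per kg oil); the
specific extinction coefficients K232/K268 from UV absorbance of an oil
solution (conjugated dienes at 232 nm, trienes/carbonyls at 268 nm).  The
three-way ANOVA uses the same cell-mean estimators as the multivariate
decomposition applied to a single column, so the two stay consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from . import asca

__all__ = [
    "TitrationRecord",
    "UvRecord",
    "peroxide_value",
    "extinction_coefficient",
    "load_fa_table",
    "fa_class_sums",
    "threeway_anova",
    "AnovaResult",
]

FA_CLASSES = ("SFA", "MUFA", "PUFA")


@dataclass(frozen=True)
class TitrationRecord:
    """One iodometric titration: thiosulfate volume, normality, oil mass."""

    titrant_volume: float    # mL
    titrant_normality: float  # eq/L
    sample_mass: float       # kg

    def validate(self) -> None:
        if self.titrant_volume < 0:
            raise ValueError("titrant volume must be >= 0")
        if self.titrant_normality <= 0:
            raise ValueError("titrant normality must be > 0")
        if self.sample_mass <= 0:
            raise ValueError("sample mass must be > 0")


@dataclass(frozen=True)
class UvRecord:
    """One UV reading of an oil solution."""

    absorbance: float        # AU
    concentration: float     # g per 100 mL
    path_length: float       # cm

    def validate(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.path_length <= 0:
            raise ValueError("path length must be > 0")


def peroxide_value(t: TitrationRecord) -> float:
    """Peroxide value, meq O2/kg: titrant volume (mL) x normality / mass (kg)."""
    t.validate()
    return t.titrant_volume * t.titrant_normality / t.sample_mass


def extinction_coefficient(u: UvRecord) -> float:
    """Specific extinction K = A / (c * l), c in g/100 mL, l in cm.

    Reported to two decimal places, the convention for K232/K268; rounding is
    applied once, at output.
    """
    u.validate()
    return round(u.absorbance / (u.concentration * u.path_length), 2)


def load_fa_table() -> pd.DataFrame:
    """Fatty-acid composition of cold-pressed hempseed oil (% of total FAME)."""
    with resources.files("oxispec.data").joinpath("hempseed_fatty_acids.csv").open() as fh:
        return pd.read_csv(fh)


def fa_class_sums(table: pd.DataFrame) -> dict:
    """Total percent per saturation class (SFA / MUFA / PUFA)."""
    if len(table) == 0:
        raise ValueError("fatty-acid table is empty")
    unknown = set(table["class"]) - set(FA_CLASSES)
    if unknown:
        raise ValueError(f"unknown fatty-acid class labels: {sorted(unknown)}")
    sums = table.groupby("class")["percent"].sum()
    return {c: float(sums.get(c, 0.0)) for c in FA_CLASSES}


@dataclass
class AnovaResult:
    """Three-way fixed-effects ANOVA with all two-way interactions."""

    table: pd.DataFrame          # effect, ss, df, ms, F, p_value
    tukey: dict                  # factor -> DataFrame of pairwise comparisons
    no_variance: bool = False


def _tukey_factor(
    y: np.ndarray, labels: np.ndarray, mse: float, df_resid: int, alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey HSD over the levels of one factor, pooled MSE from the full model."""
    levels = pd.unique(labels)
    means = {lv: y[labels == lv].mean() for lv in levels}
    n_per = len(y) / len(levels)  # balanced
    se = np.sqrt(mse / n_per)
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            diff = means[a] - means[b]
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, len(levels), df_resid))
            rows.append(
                {"level_a": a, "level_b": b, "mean_diff": diff,
                 "q": q, "p_value": p, "reject": p < alpha}
            )
    return pd.DataFrame(rows)


def threeway_anova(y, design: pd.DataFrame, alpha: float = 0.05) -> AnovaResult:
    """Three-way fixed-effects ANOVA of one response over the storage design.

    Sums of squares come from the single-column multivariate decomposition
    (main effects + all two-way interactions); F statistics test each term
    against the residual, and Tukey HSD compares level pairs within each
    factor at family level ``alpha``.  Requires replication for a residual df.
    """
    y = np.asarray(y, float).ravel()
    d = asca.decompose(y[:, None], design)

    n = len(y)
    n_levels = {f: design[c].nunique() for f, c in asca.FACTOR_COLUMNS.items()}
    df = {f: n_levels[f] - 1 for f in asca.MAIN_EFFECTS}
    for a, b in asca.INTERACTIONS:
        df[f"{a}:{b}"] = (n_levels[a] - 1) * (n_levels[b] - 1)
    df_resid = n - 1 - sum(df.values())
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom: the design has no replication")

    if d.total_ssq <= 0:
        table = pd.DataFrame(
            {"effect": list(asca.EFFECT_NAMES) + ["residual"],
             "ss": 0.0, "df": list(df.values()) + [df_resid],
             "ms": 0.0, "F": np.nan, "p_value": np.nan}
        )
        return AnovaResult(table=table, tukey={}, no_variance=True)

    mse = d.ssq["residual"] / df_resid
    rows = []
    for name in asca.EFFECT_NAMES:
        if df[name] == 0:  # single-level factor: no testable effect
            rows.append({"effect": name, "ss": 0.0, "df": 0, "ms": np.nan,
                         "F": np.nan, "p_value": np.nan})
            continue
        ms = d.ssq[name] / df[name]
        F = ms / mse if mse > 0 else np.inf
        rows.append(
            {"effect": name, "ss": d.ssq[name], "df": df[name], "ms": ms,
             "F": F, "p_value": float(stats.f.sf(F, df[name], df_resid))}
        )
    rows.append(
        {"effect": "residual", "ss": d.ssq["residual"], "df": df_resid,
         "ms": mse, "F": np.nan, "p_value": np.nan}
    )

    tukey = {
        f: _tukey_factor(y, design[c].to_numpy(), mse, df_resid, alpha)
        for f, c in asca.FACTOR_COLUMNS.items()
    }
    return AnovaResult(table=pd.DataFrame(rows), tukey=tukey)
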