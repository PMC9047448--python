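"""Cross-instrument comparison of per-cell lipid ratios.

Per-cell lipid intensities measured on different instruments are first
normalized to a reference lipid (the most abundant differentiating species,
PC 34:1 by default in the workflow), then each non-reference lipid's ratios
are compared across instruments with a one-way (single-factor) ANOVA. A
lipid whose F statistic stays below the critical F at the chosen alpha shows
no significant instrument effect — the profiles are platform-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["RatioTable", "AnovaReport", "normalize_to_reference",
           "anova_per_lipid", "f_critical"]


@dataclass
class RatioTable:
    """Reference-normalized lipid ratios per (instrument, cell)."""

    reference: str
    data: pd.DataFrame = field(repr=False)  # columns: instrument, cell_id, lipid, ratio

    def __post_init__(self) -> None:
        required = {"instrument", "cell_id", "lipid", "ratio"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"ratio table needs columns {sorted(required)}")
        ref = self.data[self.data["lipid"] == self.reference]["ratio"]
        if len(ref) and not np.allclose(ref, 1.0):
            raise ValueError("reference lipid ratios must all equal 1")
        if (self.data["ratio"] < 0).any():
            raise ValueError("ratios must be nonnegative")

    @property
    def lipids(self) -> list[str]:
        return sorted(self.data["lipid"].unique())

    @property
    def instruments(self) -> list[str]:
        return sorted(self.data["instrument"].unique())


@dataclass
class AnovaReport:
    """Per-lipid one-way ANOVA verdicts against a single critical F."""

    alpha: float
    df_between: int
    df_within: int
    critical_f: float
    table: pd.DataFrame = field(repr=False)  # index lipid; columns F, significant

    def all_below_critical(self) -> bool:
        return bool((~self.table["significant"]).all())


def normalize_to_reference(profiles: pd.DataFrame, reference: str) -> RatioTable:
    """Divide each cell profile's intensities by its reference-lipid intensity.

    ``profiles`` is long-form with columns ``instrument, cell_id, lipid,
    intensity``. Every (instrument, cell) profile must contain the reference
    lipid with nonzero intensity.
    """
    required = {"instrument", "cell_id", "lipid", "intensity"}
    if not required.issubset(profiles.columns):
        raise ValueError(f"profiles need columns {sorted(required)}")
    out = []
    for (instrument, cell), grp in profiles.groupby(["instrument", "cell_id"], sort=True):
        ref = grp.loc[grp["lipid"] == reference, "intensity"]
        if ref.empty or float(ref.iloc[0]) == 0.0:
            raise ValueError(
                f"profile (instrument={instrument!r}, cell={cell!r}) lacks a "
                f"nonzero reference intensity for {reference!r}"
            )
        g = grp.copy()
        g["ratio"] = g["intensity"] / float(ref.iloc[0])
        out.append(g[["instrument", "cell_id", "lipid", "ratio"]])
    return RatioTable(reference=reference, data=pd.concat(out, ignore_index=True))


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper-``alpha`` quantile of the F distribution with (df1, df2) df."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(scipy.stats.f.isf(alpha, df1, df2))


def _oneway_f(groups: list[np.ndarray]) -> float:
    """One-way ANOVA F = between-group MS / within-group MS."""
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    if ms_within == 0.0:
        return float("inf") if ms_between > 0 else 0.0
    return float(ms_between / ms_within)


def anova_per_lipid(
    table: RatioTable, alpha: float = 0.05, bonferroni: bool = False
) -> AnovaReport:
    """Single-factor ANOVA of each non-reference lipid's ratios across instruments.

    Each lipid is tested independently against one critical F at ``alpha``
    (optionally Bonferroni-divided by the number of lipids tested). Zero
    within-group variance with nonzero between-group variance reports
    F = +inf.
    """
    instruments = table.instruments
    if len(instruments) < 2:
        raise ValueError("need >= 2 instruments")
    lipids = [l for l in table.lipids if l != table.reference]
    n_total = None
    records = {}
    for lipid in lipids:
        sub = table.data[table.data["lipid"] == lipid]
        groups = [
            sub.loc[sub["instrument"] == ins, "ratio"].to_numpy(float)
            for ins in instruments
        ]
        if any(len(g) < 2 for g in groups):
            raise ValueError(
                f"lipid {lipid!r}: every instrument needs >= 2 replicate cells"
            )
        records[lipid] = (_oneway_f(groups), sum(len(g) for g in groups))
        n_total = records[lipid][1]
    if not records:
        raise ValueError("no non-reference lipids to test")
    df1 = len(instruments) - 1
    df2 = n_total - len(instruments)
    eff_alpha = alpha / len(lipids) if bonferroni else alpha
    crit = f_critical(eff_alpha, df1, df2)
    df = pd.DataFrame(
        {
            "F": {lip: f for lip, (f, _) in records.items()},
            "significant": {lip: f >= crit for lip, (f, _) in records.items()},
        }
    )
    df.index.name = "lipid"
    return AnovaReport(
        alpha=alpha, df_between=df1, df_within=df2, critical_f=crit, table=df
    )
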