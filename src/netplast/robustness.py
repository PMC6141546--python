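"""Robustness statistics from paired error/attack damage curves.

The error-attack deviation Δea is the root mean square gap between a
network's mean error curve e_f and its attack curve a_f over the removal
grid: Δea = sqrt((1/n) Σ_f (e_f − a_f)²).  Small Δea means a targeted
attack hurts little more than random failure — the signature of a
homogeneous, attack-robust network.  Network vulnerability is the mean of
Δea computed on the giant-component curve and on the efficiency curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RobustnessProfile:
    network_name: str
    dea_S: float
    dea_E: float

    def __post_init__(self):
        if self.dea_S < 0 or self.dea_E < 0:
            raise ValueError("error-attack deviations must be non-negative")

    @property
    def vulnerability(self) -> float:
        return vulnerability(self.dea_S, self.dea_E)


def error_attack_deviation(error_curve, attack_curve) -> float:
    """RMS deviation between an error and an attack damage curve."""
    e = np.asarray(error_curve, dtype=float)
    a = np.asarray(attack_curve, dtype=float)
    if e.shape != a.shape or e.ndim != 1 or e.size < 1:
        raise ValueError(
            f"curves must be equal-length 1-d vectors (got {e.shape} vs {a.shape})"
        )
    return float(np.sqrt(np.mean((e - a) ** 2)))


def vulnerability(dea_S: float, dea_E: float) -> float:
    """Mean of the two error-attack deviations (the ranking statistic)."""
    if dea_S < 0 or dea_E < 0:
        raise ValueError("deviations must be non-negative")
    return (dea_S + dea_E) / 2.0


def profile_from_curves(error_curve, attack_curve) -> RobustnessProfile:
    """Build a profile from one network's paired DamageCurves."""
    if not np.array_equal(error_curve.f_grid, attack_curve.f_grid):
        raise ValueError("error and attack curves must share one f grid")
    return RobustnessProfile(
        network_name=error_curve.name or attack_curve.name,
        dea_S=error_attack_deviation(error_curve.S_rel, attack_curve.S_rel),
        dea_E=error_attack_deviation(error_curve.E_rel, attack_curve.E_rel),
    )


def rank_networks(profiles, groups=None) -> pd.DataFrame:
    """Rank networks by vulnerability, most robust (smallest) first.

    Each network gets a leave-one-out z-score against the other networks'
    vulnerability distribution.  With a ``groups`` mapping (name -> label,
    exactly two labels) a two-sided Wilcoxon rank-sum compares the groups'
    vulnerabilities and the p-value is attached to every row.
    """
    if len(profiles) < 2:
        raise ValueError("ranking needs at least two profiles")
    df = pd.DataFrame(
        {
            "network": [p.network_name for p in profiles],
            "dea_S": [p.dea_S for p in profiles],
            "dea_E": [p.dea_E for p in profiles],
            "vulnerability": [p.vulnerability for p in profiles],
        }
    )
    df = df.sort_values(["vulnerability", "network"], kind="stable")
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    v = df["vulnerability"].to_numpy()
    z = np.full(len(v), np.nan)
    for i in range(len(v)):
        rest = np.delete(v, i)
        sd = rest.std(ddof=1)
        if sd > 0:
            z[i] = (v[i] - rest.mean()) / sd
    df["zscore"] = z
    if groups is not None:
        df["group"] = df["network"].map(groups)
        labels = sorted(df["group"].dropna().unique())
        if len(labels) != 2:
            raise ValueError("group comparison needs exactly two group labels")
        a = df.loc[df["group"] == labels[0], "vulnerability"]
        b = df.loc[df["group"] == labels[1], "vulnerability"]
        stat, p = stats.ranksums(a, b)
        df["group_ranksum_stat"] = stat
        df["group_ranksum_p"] = p
    return df
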