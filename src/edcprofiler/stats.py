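"""Dose-response statistics for headline phenotypic features.

Per feature and compound: well values are normalized to the vehicle-control
mean (per biological replicate), a one-way ANOVA is run across the five
dose groups (vehicle + four doses), and — when significant at 0.05 — a
Tukey HSD post-hoc compares each dose against vehicle with family-wise
adjusted p-values, reported as significance tiers
(* p<.05, ** p<.01, *** p<.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .catalogue import HEADLINE_FEATURES
from .plate import COMPOUNDS, DOSES_UM, VEHICLE

ALPHA = 0.05
STAR_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_tier(p_adj: float) -> str:
    """Map an adjusted p-value to its significance tier."""
    if not np.isfinite(p_adj):
        return "ns"
    for thr, stars in STAR_TIERS:
        if p_adj < thr:
            return stars
    return "ns"


def normalize_to_control(
    values: pd.Series, is_control: pd.Series, groups: pd.Series | None = None
) -> pd.Series:
    """Divide each well value by the mean of control wells (per group).

    ``groups`` typically holds the biological-replicate / plate index so
    each plate is anchored to its own controls.  Raises when a group has
    fewer than 2 controls or a zero control mean.
    """
    values = values.astype(float)
    if groups is None:
        groups = pd.Series(0, index=values.index)
    out = pd.Series(index=values.index, dtype=float)
    for g, idx in values.groupby(groups).groups.items():
        ctrl = values.loc[idx][is_control.loc[idx]]
        if len(ctrl) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 control wells")
        m = ctrl.mean()
        if m == 0:
            raise ValueError(f"control mean is zero in group {g!r}")
        out.loc[idx] = values.loc[idx] / m
    return out


@dataclass
class AnovaTukeyResult:
    f_stat: float
    p_value: float
    contrasts: pd.DataFrame  # dose, p_adj, stars (dose vs vehicle)
    flag: str = ""


def anova_tukey(
    values: np.ndarray | pd.Series,
    dose_groups: np.ndarray | pd.Series,
    vehicle_dose: float = 0.0,
    alpha: float = ALPHA,
) -> AnovaTukeyResult:
    """One-way ANOVA over dose groups; Tukey HSD vs vehicle when p < alpha.

    Doses never compared (ANOVA ns) or untestable report adjusted p NaN and
    tier 'ns'.  All-constant, all-equal groups have an undefined F and are
    flagged.
    """
    values = np.asarray(values, dtype=float)
    dose_groups = np.asarray(dose_groups, dtype=float)
    doses = sorted(set(dose_groups.tolist()))
    if vehicle_dose not in doses:
        raise ValueError("vehicle group missing")
    samples = [values[dose_groups == d] for d in doses]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    treat_doses = [d for d in doses if d != vehicle_dose]
    blank = pd.DataFrame(
        {"dose_uM": treat_doses, "p_adj": np.nan, "stars": "ns"}
    )
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        return AnovaTukeyResult(np.nan, np.nan, blank, flag="degenerate: zero variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = sps.f_oneway(*samples)
    if not np.isfinite(p) or p >= alpha:
        return AnovaTukeyResult(float(f), float(p), blank)
    tuk = pairwise_tukeyhsd(values, dose_groups, alpha=alpha)
    tt = pd.DataFrame(
        tuk.summary().data[1:], columns=[str(c) for c in tuk.summary().data[0]]
    )
    rows = []
    for d in treat_doses:
        hit = tt[
            ((tt["group1"].astype(float) == vehicle_dose) & (tt["group2"].astype(float) == d))
            | ((tt["group2"].astype(float) == vehicle_dose) & (tt["group1"].astype(float) == d))
        ]
        p_adj = float(hit["p-adj"].iloc[0]) if len(hit) else np.nan
        rows.append({"dose_uM": d, "p_adj": p_adj, "stars": star_tier(p_adj)})
    return AnovaTukeyResult(float(f), float(p), pd.DataFrame(rows))


def _t_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """t-based CI of the mean; degenerate for n < 2."""
    x = np.asarray(x, dtype=float)
    m = float(x.mean())
    if x.size < 2:
        return m, m
    half = sps.t.ppf(0.5 + level / 2, df=x.size - 1) * sps.sem(x)
    return m - half, m + half


def dose_response_table(
    well_table: pd.DataFrame,
    features: dict[str, str] | list[str] | None = None,
    compounds: tuple[str, ...] = COMPOUNDS,
    doses: tuple[float, ...] = DOSES_UM,
    replicate_col: str | None = "replicate",
) -> pd.DataFrame:
    """Tidy dose-response summary for the requested features.

    One row per (feature, compound, dose incl. vehicle at 0) with the
    control-normalized mean, 95% CI of the mean, Tukey-adjusted p against
    vehicle, and the significance tier.  Vehicle rows carry no contrast.
    """
    if features is None:
        features = HEADLINE_FEATURES
    if isinstance(features, dict):
        features = list(features.values())
    is_control = well_table["compound"] == VEHICLE
    groups = (
        well_table[replicate_col]
        if replicate_col and replicate_col in well_table.columns
        else None
    )
    all_doses = (0.0,) + tuple(doses)
    rows = []
    for feat in features:
        norm = normalize_to_control(well_table[feat], is_control, groups)
        for comp in compounds:
            sel = is_control | (well_table["compound"] == comp)
            vals = norm[sel].to_numpy()
            dose_lab = well_table.loc[sel, "dose_uM"].to_numpy(dtype=float)
            try:
                res = anova_tukey(vals, dose_lab)
            except ValueError as err:  # sparse design (e.g. 1 well per dose)
                res = AnovaTukeyResult(
                    np.nan,
                    np.nan,
                    pd.DataFrame(
                        {"dose_uM": list(doses), "p_adj": np.nan, "stars": "ns"}
                    ),
                    flag=f"untestable: {err}",
                )
            contrasts = res.contrasts.set_index("dose_uM")
            for d in all_doses:
                x = vals[dose_lab == d]
                lo, hi = _t_ci(x)
                if d == 0.0:
                    p_adj, stars = np.nan, ""
                else:
                    p_adj = contrasts.loc[d, "p_adj"] if d in contrasts.index else np.nan
                    stars = contrasts.loc[d, "stars"] if d in contrasts.index else "ns"
                rows.append(
                    {
                        "feature": feat,
                        "compound": comp,
                        "dose_uM": d,
                        "n_wells": int(x.size),
                        "normalized_mean": float(x.mean()) if x.size else np.nan,
                        "ci_low": lo,
                        "ci_high": hi,
                        "anova_F": res.f_stat,
                        "anova_p": res.p_value,
                        "p_adj": p_adj,
                        "stars": stars,
                        "flag": res.flag,
                    }
                )
    return pd.DataFrame(rows)


def shapiro_diagnostic(
    well_table: pd.DataFrame, feature: str, by: tuple[str, ...] = ("compound", "dose_uM")
) -> pd.DataFrame:
    """Shapiro-Wilk normality p per condition group — logged, never gating."""
    rows = []
    for key, grp in well_table.groupby(list(by)):
        x = grp[feature].dropna().to_numpy()
        if 3 <= x.size and np.ptp(x) > 0:
            _, p = sps.shapiro(x)
        else:
            p = np.nan
        rows.append({"condition": key, "n": int(x.size), "shapiro_p": p})
    return pd.DataFrame(rows)
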