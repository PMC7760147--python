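"""Statistics for the functional assays.

Covers the four desk-side analyses that accompany a miRNA perturbation
study: GFP growth-competition trajectories (baseline normalization and a
random-intercept mixed model for the time x construct interaction),
dual-luciferase Renilla/firefly reporter ratios with a paired t-test, qPCR
relative expression (2^-dCp), and Western-blot band quantification relative
to total lane protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf


@dataclass
class GfpSeries:
    """%GFP-positive trajectory for one construct/replicate."""

    construct: str
    replicate: str
    days: np.ndarray
    pct_gfp: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.pct_gfp = np.asarray(self.pct_gfp, dtype=float)
        if self.days.shape != self.pct_gfp.shape:
            raise ValueError("days and pct_gfp must have equal length")
        # raw measurements are percentages, but baseline-normalized values
        # may exceed 100, so only positivity is enforced here
        if (self.pct_gfp <= 0).any():
            raise ValueError("pct_gfp must be positive")


def normalize_gfp(series: GfpSeries, baseline_day: int = 4) -> GfpSeries:
    """Scale a trajectory so the baseline-day value is exactly 100.

    Mirrors the convention of growth-competition assays, where the GFP+
    percentage on the first measured day is set to 100%.  Idempotent.
    """
    at = np.flatnonzero(series.days == baseline_day)
    if len(at) == 0:
        raise ValueError(
            f"baseline day {baseline_day} not observed for "
            f"{series.construct}/{series.replicate}"
        )
    scaled = series.pct_gfp * (100.0 / series.pct_gfp[at[0]])
    return GfpSeries(series.construct, series.replicate, series.days.copy(), scaled)


@dataclass
class GrowthFit:
    """Mixed-model fit of normalized %GFP trajectories.

    ``interaction`` maps each non-reference construct to its time x construct
    slope difference (estimate, standard error, two-sided p-value).
    """

    time_slope: float
    interaction: dict[str, tuple[float, float, float]]
    random_intercept_var: float
    residual_var: float
    n_obs: int
    converged: bool


def _series_frame(all_series: list[GfpSeries], baseline_day: int,
                  normalize: bool, log_scale: bool) -> pd.DataFrame:
    rows = []
    for s in all_series:
        t = normalize_gfp(s, baseline_day) if normalize else s
        value = np.log(t.pct_gfp) if log_scale else t.pct_gfp
        for d, v in zip(t.days, value):
            rows.append(
                {
                    "construct": s.construct,
                    "replicate": f"{s.construct}/{s.replicate}",
                    "t": d - baseline_day,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


def fit_growth_mixed_model(
    all_series: list[GfpSeries],
    reference_construct: str,
    baseline_day: int = 4,
    normalize: bool = True,
    log_scale: bool = False,
    random_slope: bool = False,
    construct_main_effect: bool = True,
    drop_baseline: bool = True,
) -> GrowthFit:
    """REML mixed model for growth-competition assays.

    Fixed effects are time and the time x construct interaction; the
    measurement replicate within construct is a random intercept.  Two
    numerical choices keep the interaction test calibrated at the handful of
    replicates these assays have.  First, after baseline normalization the
    baseline-day rows are identically 100 and are dropped by default: they
    carry no information but would bias the residual variance toward zero.
    Second, a construct main effect is included by default
    (``construct_main_effect``): dividing by the noisy baseline observation
    shifts whole series up or down, and without a main effect those shifts
    leak into the slope contrast and inflate its type-I error.  Interaction
    p-values are two-sided on a t reference with n_obs - n_fixed - n_groups
    degrees of freedom.
    """
    constructs = sorted({s.construct for s in all_series})
    if reference_construct not in constructs:
        raise ValueError(f"reference construct {reference_construct!r} not present")
    if len(constructs) < 2:
        raise ValueError("need at least two constructs")
    df = _series_frame(all_series, baseline_day, normalize, log_scale)
    if df.groupby("construct")["t"].nunique().min() < 3:
        raise ValueError("need >=3 timepoints per construct")
    if df.groupby("construct")["replicate"].nunique().min() < 2:
        raise ValueError("need >=2 replicates per construct")
    if normalize and drop_baseline:
        df = df[df["t"] != 0].copy()

    base = f"C(construct, Treatment('{reference_construct}'))"
    if construct_main_effect:
        formula = f"value ~ t * {base}"
    else:
        formula = f"value ~ t + t:{base}"
    re_formula = "~t" if random_slope else "1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["replicate"],
                                re_formula=re_formula)
            fit = model.fit(reml=True)
        except (np.linalg.LinAlgError, ValueError) as err:
            raise ValueError(f"singular design in mixed-model fit: {err}") from err

    n_groups = df["replicate"].nunique()
    k_fe = len(fit.fe_params)
    ddf = max(len(df) - k_fe - n_groups, 1)
    interaction = {}
    for c in constructs:
        if c == reference_construct:
            continue
        name = f"t:C(construct, Treatment('{reference_construct}'))[T.{c}]"
        est = float(fit.fe_params[name])
        se = float(fit.bse_fe[name])
        if se > 0 and np.isfinite(se):
            p = float(2.0 * stats.t.sf(abs(est) / se, ddf))
        else:  # noiseless/degenerate fit: an exact line has no sampling error
            p = 0.0 if est != 0 else 1.0
        interaction[c] = (est, se, p)
    return GrowthFit(
        time_slope=float(fit.fe_params["t"]),
        interaction=interaction,
        random_intercept_var=float(np.atleast_2d(fit.cov_re)[0, 0]),
        residual_var=float(fit.scale),
        n_obs=len(df),
        converged=bool(fit.converged),
    )


@dataclass
class LuciferaseResult:
    n: int
    mean_ratio_experimental: float
    mean_ratio_control: float
    mean_change: float  # experimental - control, in RL/FL units
    t: float
    p: float


def rl_fl_ratios(arm: pd.DataFrame) -> pd.Series:
    """Per-replicate Renilla/firefly ratio with duplicate wells averaged first.

    ``arm`` is long-format with columns replicate, RL, FL (one row per well).
    """
    if (arm["FL"] <= 0).any():
        raise ValueError("firefly (FL) readings must be positive")
    by_rep = arm.groupby("replicate")[["RL", "FL"]].mean()
    return by_rep["RL"] / by_rep["FL"]


def luciferase_test(exp_arm: pd.DataFrame, ctrl_arm: pd.DataFrame) -> LuciferaseResult:
    """Two-sided paired t-test on per-replicate RL/FL ratios of two arms."""
    r_exp = rl_fl_ratios(exp_arm)
    r_ctrl = rl_fl_ratios(ctrl_arm)
    if sorted(r_exp.index) != sorted(r_ctrl.index):
        raise ValueError("arms are not paired by biological replicate")
    r_ctrl = r_ctrl.reindex(r_exp.index)
    if len(r_exp) < 2:
        raise ValueError("paired t-test needs >=2 biological replicates")
    diff = (r_exp - r_ctrl).to_numpy()
    if np.allclose(diff, 0.0):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(r_exp, r_ctrl)
    return LuciferaseResult(
        n=len(r_exp),
        mean_ratio_experimental=float(r_exp.mean()),
        mean_ratio_control=float(r_ctrl.mean()),
        mean_change=float(diff.mean()),
        t=float(t_stat),
        p=float(p),
    )


def qpcr_relative_expression(cp_mirna: float, cp_housekeeping: float) -> float:
    """Relative qPCR expression 2^-(Cp_miRNA - Cp_housekeeping)."""
    if not (np.isfinite(cp_mirna) and np.isfinite(cp_housekeeping)):
        raise ValueError("Cp values must be finite")
    return float(2.0 ** -(cp_mirna - cp_housekeeping))


def protein_relative_level(
    band_intensity, lane_total_intensity, control_index: int = 0
) -> np.ndarray:
    """Band intensity over total-lane protein, relative to the control lane.

    Each band is first normalized to the total protein of its own lane, then
    divided by the control sample's normalized level (control = 1 exactly).
    """
    band = np.asarray(band_intensity, dtype=float)
    lane = np.asarray(lane_total_intensity, dtype=float)
    if band.shape != lane.shape:
        raise ValueError("band and lane totals must have equal length")
    if (lane <= 0).any():
        raise ValueError("lane totals must be positive")
    level = band / lane
    return level / level[control_index]


def protein_paired_test(
    treated_levels, control_levels, alternative: str = "less"
) -> tuple[float, float]:
    """One-tailed paired t-test on relative protein levels across experiments.

    ``alternative="less"`` tests for a decrease in the treated samples.
    Returns (t, p); identical inputs give t = 0 and one-tailed p = 0.5.
    """
    x = np.asarray(treated_levels, dtype=float)
    y = np.asarray(control_levels, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired vectors of equal length required")
    if len(x) < 2:
        raise ValueError("paired t-test needs >=2 experiments")
    if np.allclose(x - y, 0.0):
        return 0.0, 0.5
    t_stat, p = stats.ttest_rel(x, y, alternative=alternative)
    return float(t_stat), float(p)
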