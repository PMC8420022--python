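"""Indirect-calorimetry energy-expenditure analysis.

Converts gas-exchange traces (VO2/VCO2) into energy expenditure via the Weir
equation and derives the study summaries: resting energy expenditure (REE),
respiratory exchange ratio (RER), cognitive energy expenditure (CEE) and
thermic effect of feeding (TEF) as AUC contrasts against rest, incremental
AUC, mouse light-cycle means, diet-switch deltas, and the mass-adjusted and
age-stratified group statistics.

Units
-----
VO2/VCO2 are canonically mL/min (human metabolic carts); mouse cage data in
mL/h are converted on read.  Energy expenditure is kcal/day.  AUCs integrate
the kcal/day signal over minutes and divide by 1440 min/day, so a constant
1440 kcal/day held for 25 min contributes an AUC of 25 (numerically kcal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .exceptions import DataError, DegenerateInputError, PeriodError

__all__ = [
    "GasExchangeTrace",
    "EnergySummary",
    "weir_ee",
    "rer",
    "apply_steady_state_window",
    "resting_summary",
    "period_auc",
    "cognitive_ee",
    "thermic_effect",
    "summarize_subject",
    "mouse_cycle_summary",
    "diet_delta",
    "carrier_composition",
    "mass_adjusted_group_test",
    "age_stratified_regression",
    "read_gas_exchange",
    "write_summaries",
]

#: Weir-equation coefficients: EE [kcal/day] = 1.44 * (3.94*VO2 + 1.11*VCO2)
#: with VO2/VCO2 in mL/min.
WEIR_SCALE = 1.44
WEIR_VO2 = 3.94
WEIR_VCO2 = 1.11

#: Steady-state buffer excluded from the start of each period (seconds).
STEADY_STATE_BUFFER_S = 300.0

MINUTES_PER_DAY = 1440.0


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------

@dataclass
class GasExchangeTrace:
    """A time-stamped VO2/VCO2 series for one subject or animal.

    ``time`` is seconds from session start, strictly increasing.  ``vo2`` and
    ``vco2`` are mL/min (canonical unit; mouse mL/h inputs are converted by
    :func:`read_gas_exchange`).  Every sample carries a period label: for
    humans ``rest``/``cognitive``/``glucose``; for mice ``light|chow`` style
    ``cycle|diet`` compound labels.  ``activity`` and ``food`` are optional
    parallel series used only by the mouse summaries.
    """

    subject_id: str
    species: str  # "human" | "mouse"
    time: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    period_labels: np.ndarray
    body_mass: float | None = None
    covariates: dict = field(default_factory=dict)
    activity: np.ndarray | None = None
    food: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        self.period_labels = np.asarray(self.period_labels, dtype=object)
        n = self.time.size
        if not (self.vo2.size == self.vco2.size == self.period_labels.size == n):
            raise DataError("time, vo2, vco2 and period_labels must be equal length")
        if n and np.any(np.diff(self.time) <= 0):
            raise DataError("time must be strictly increasing")
        if np.any(self.vo2 < 0) or np.any(self.vco2 < 0):
            raise DataError("vo2 and vco2 must be non-negative")
        if self.species not in ("human", "mouse"):
            raise DataError(f"unknown species {self.species!r}")

    @property
    def periods(self) -> list[str]:
        """Distinct period labels in order of first appearance."""
        seen: list[str] = []
        for lab in self.period_labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def select(self, mask: np.ndarray) -> "GasExchangeTrace":
        """Return a copy restricted to ``mask`` (pure; input unmodified)."""
        return replace(
            self,
            time=self.time[mask],
            vo2=self.vo2[mask],
            vco2=self.vco2[mask],
            period_labels=self.period_labels[mask],
            activity=None if self.activity is None else np.asarray(self.activity)[mask],
            food=None if self.food is None else np.asarray(self.food)[mask],
        )


@dataclass
class EnergySummary:
    """Per-subject energy-expenditure decomposition."""

    subject_id: str
    ree: float            # kcal/day
    rer: float            # dimensionless
    cee: float            # AUC difference, kcal at day-rate
    tef: float            # AUC difference, kcal at day-rate
    auc_by_period: dict
    incremental_auc: float
    n_samples_used: dict


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def weir_ee(vo2, vco2):
    """Energy expenditure (kcal/day) from the abbreviated Weir equation.

    EE = 1.44 * (3.94 * VO2 + 1.11 * VCO2), VO2/VCO2 in mL/min.  Linear and
    homogeneous; accepts scalars or arrays.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise DataError("weir_ee requires non-negative vo2 and vco2")
    out = WEIR_SCALE * (WEIR_VO2 * vo2 + WEIR_VCO2 * vco2)
    return float(out) if out.ndim == 0 else out


def rer(vco2, vo2):
    """Respiratory exchange ratio VCO2/VO2 (dimensionless)."""
    vco2 = np.asarray(vco2, dtype=float)
    vo2 = np.asarray(vo2, dtype=float)
    if np.any(vo2 <= 0):
        raise DegenerateInputError("RER undefined for vo2 <= 0")
    out = vco2 / vo2
    return float(out) if out.ndim == 0 else out


def _period_mask(trace: GasExchangeTrace, period: str) -> np.ndarray:
    mask = trace.period_labels == period
    if not mask.any():
        raise PeriodError(f"period {period!r} not present in trace "
                          f"{trace.subject_id!r}")
    return mask


def apply_steady_state_window(trace: GasExchangeTrace, period: str,
                              buffer_s: float = STEADY_STATE_BUFFER_S,
                              ) -> GasExchangeTrace:
    """Drop the first ``buffer_s`` seconds of a period (steady-state buffer).

    Samples at exactly ``start + buffer_s`` are retained (half-open interval
    ``[start + buffer_s, end)``).  Raises :class:`PeriodError` if the period
    is absent or no samples survive.
    """
    mask = _period_mask(trace, period)
    start = trace.time[mask].min()
    keep = mask & (trace.time >= start + buffer_s)
    if not keep.any():
        raise PeriodError(
            f"period {period!r} shorter than the {buffer_s:.0f} s steady-state "
            f"buffer in trace {trace.subject_id!r}")
    return trace.select(keep)


def _time_weighted_mean(t: np.ndarray, y: np.ndarray) -> float:
    """Trapezoid-weighted mean; reduces to midpoint value for a linear drift."""
    if t.size == 1:
        return float(y[0])
    return float(np.trapezoid(y, t) / (t[-1] - t[0]))


def resting_summary(trace: GasExchangeTrace, *, period: str = "rest",
                    time_weighted: bool = True) -> tuple[float, float]:
    """(REE kcal/day, mean RER) over the steady-state-windowed rest period.

    REE is the mean of per-sample Weir EE; RER the mean of per-sample ratios.
    Means are time-weighted (trapezoid) by default to tolerate irregular
    sampling; ``time_weighted=False`` gives the simple mean.
    """
    view = apply_steady_state_window(trace, period)
    ee = weir_ee(view.vo2, view.vco2)
    ratios = rer(view.vco2, view.vo2)
    ee = np.atleast_1d(ee)
    ratios = np.atleast_1d(ratios)
    if time_weighted:
        return _time_weighted_mean(view.time, ee), _time_weighted_mean(view.time, ratios)
    return float(np.mean(ee)), float(np.mean(ratios))


def period_auc(trace: GasExchangeTrace, period: str, mode: str = "raw",
               baseline: float | None = None, *, window: bool = True) -> float:
    """Trapezoidal AUC of EE over a (windowed) period, in kcal at day-rate.

    The kcal/day EE signal is integrated over minutes and divided by
    1440 min/day, so a constant 1440 kcal/day over 25 min gives 25.
    ``mode="incremental"`` subtracts ``baseline`` (default: the subject's own
    windowed REE) from the signal before integrating.
    """
    if mode not in ("raw", "incremental"):
        raise ValueError(f"unknown AUC mode {mode!r}")
    view = apply_steady_state_window(trace, period) if window else \
        trace.select(_period_mask(trace, period))
    if view.time.size < 2:
        raise DegenerateInputError(
            f"period {period!r} has <2 samples after windowing")
    ee = np.atleast_1d(weir_ee(view.vo2, view.vco2))
    if mode == "incremental":
        if baseline is None:
            baseline, _ = resting_summary(trace)
        ee = ee - baseline
    t_min = view.time / 60.0
    return float(np.trapezoid(ee, t_min) / MINUTES_PER_DAY)


def _auc_contrast(trace: GasExchangeTrace, period: str, *,
                  rest_period: str = "rest") -> float:
    """Raw AUC(period) - raw AUC(rest), rescaled to a common duration.

    If the two windowed periods differ in duration, each AUC is converted to
    a per-minute mean and multiplied by the shorter duration before
    differencing, so the contrast is not confounded by unequal lengths.
    """
    v_p = apply_steady_state_window(trace, period)
    v_r = apply_steady_state_window(trace, rest_period)
    d_p = (v_p.time[-1] - v_p.time[0]) / 60.0
    d_r = (v_r.time[-1] - v_r.time[0]) / 60.0
    if d_p <= 0 or d_r <= 0:
        raise DegenerateInputError("zero-duration period after windowing")
    auc_p = period_auc(trace, period)
    auc_r = period_auc(trace, rest_period)
    if not np.isclose(d_p, d_r):
        common = min(d_p, d_r)
        auc_p = auc_p / d_p * common
        auc_r = auc_r / d_r * common
    return auc_p - auc_r


def cognitive_ee(trace: GasExchangeTrace) -> float:
    """CEE: AUC of EE during the cognitive challenge minus the resting AUC."""
    return _auc_contrast(trace, "cognitive")


def thermic_effect(trace: GasExchangeTrace) -> float:
    """TEF: AUC of EE during the glucose challenge minus the resting AUC."""
    return _auc_contrast(trace, "glucose")


def summarize_subject(trace: GasExchangeTrace) -> EnergySummary:
    """Full per-subject decomposition: REE, RER, CEE, TEF and period AUCs."""
    ree, mean_rer = resting_summary(trace)
    aucs, n_used = {}, {}
    for p in trace.periods:
        aucs[p] = period_auc(trace, p)
        n_used[p] = apply_steady_state_window(trace, p).time.size
    return EnergySummary(
        subject_id=trace.subject_id,
        ree=ree,
        rer=mean_rer,
        cee=cognitive_ee(trace),
        tef=thermic_effect(trace),
        auc_by_period=aucs,
        incremental_auc=period_auc(trace, "glucose", mode="incremental",
                                   baseline=ree),
        n_samples_used=n_used,
    )


# ---------------------------------------------------------------------------
# Mouse cage summaries
# ---------------------------------------------------------------------------

def _split_label(label: str) -> tuple[str, str]:
    cycle, _, diet = str(label).partition("|")
    if not diet:
        raise DataError(f"mouse period label {label!r} is not 'cycle|diet'")
    return cycle, diet


def mouse_cycle_summary(trace: GasExchangeTrace,
                        interval_s: float = 1800.0) -> pd.DataFrame:
    """Per-(cycle, diet) means of EE/VO2/VCO2 (+activity/food) for one animal.

    Samples are first averaged into ``interval_s`` bins (30-min cage
    convention), then bin means are averaged within each cycle x diet cell.
    Dark-cycle rows are retained in the output but the headline analysis
    uses only ``cycle == "light"`` rows.
    """
    cycles_diets = [_split_label(lab) for lab in trace.period_labels]
    cycle = np.array([c for c, _ in cycles_diets], dtype=object)
    diet = np.array([d for _, d in cycles_diets], dtype=object)
    if not (cycle == "light").any():
        raise PeriodError(f"no light-cycle samples in trace {trace.subject_id!r}")
    df = pd.DataFrame({
        "bin": np.floor(trace.time / interval_s).astype(int),
        "cycle": cycle,
        "diet": diet,
        "ee": weir_ee(trace.vo2, trace.vco2),
        "vo2": trace.vo2,
        "vco2": trace.vco2,
    })
    if trace.activity is not None:
        df["activity"] = np.asarray(trace.activity, dtype=float)
    if trace.food is not None:
        df["food"] = np.asarray(trace.food, dtype=float)
    value_cols = [c for c in ("ee", "vo2", "vco2", "activity", "food")
                  if c in df.columns]
    binned = df.groupby(["cycle", "diet", "bin"], sort=True)[value_cols].mean()
    out = binned.groupby(["cycle", "diet"], sort=True).mean().reset_index()
    out.insert(0, "subject_id", trace.subject_id)
    return out


def diet_delta(summary_chow: pd.DataFrame, summary_hcd: pd.DataFrame,
               measures: tuple[str, ...] = ("ee", "vo2", "vco2"),
               alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal diet-induced change in light-cycle means, with per-genotype
    one-sample tests of delta > 0.

    Inputs are per-animal light-cycle summary tables (one row per animal with
    columns ``subject_id``, ``genotype`` and the measures) for the chow and
    high-carbohydrate phases.  Returns ``(deltas, tests)``: the per-animal
    delta table and a per-(genotype, measure) table with the one-sided paired
    t-test p-value and a ``significant_increase`` flag — genotypes whose flag
    is False failed to raise that measure on the carbohydrate diet.
    """
    a = summary_chow.set_index("subject_id")
    b = summary_hcd.set_index("subject_id")
    if set(a.index) != set(b.index):
        raise DataError("chow and HCD summaries cover different animal sets")
    b = b.loc[a.index]
    deltas = pd.DataFrame(index=a.index)
    deltas["genotype"] = a["genotype"]
    for m in measures:
        deltas[m] = b[m] - a[m]
    rows = []
    for geno, sub in deltas.groupby("genotype", sort=True):
        for m in measures:
            x = sub[m].to_numpy(dtype=float)
            if np.ptp(x) == 0.0:
                # zero-variance delta: t undefined; null iff the common value is <= 0
                t_stat, p = 0.0, (1.0 if x[0] <= 0 else 0.0)
            else:
                t_stat, p = scipy.stats.ttest_1samp(x, 0.0,
                                                    alternative="greater")
            rows.append({"genotype": geno, "measure": m,
                         "mean_delta": float(np.mean(x)),
                         "sem": float(scipy.stats.sem(x)) if x.size > 1 else np.nan,
                         "t": float(t_stat), "p": float(p),
                         "significant_increase": bool(p < alpha)})
    return deltas.reset_index(), pd.DataFrame(rows)


def carrier_composition(genotype_counts: dict) -> dict:
    """Carrier / non-carrier arithmetic from per-genotype subject counts.

    A subject is an E4 carrier when either allele is 4 (e.g. ``"E3/E4"``,
    ``"E2/E4"``, ``"E4/E4"``).  Returns carrier, non-carrier and total counts.
    """
    carriers = sum(n for g, n in genotype_counts.items() if "4" in g)
    total = sum(genotype_counts.values())
    return {"carriers": int(carriers),
            "non_carriers": int(total - carriers),
            "total": int(total)}


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def mass_adjusted_group_test(ee, mass, group) -> dict:
    """ANCOVA of EE on group adjusting for body mass.

    Fits ``EE ~ group + mass`` and reports the adjusted group difference with
    its 95% CI and p-value, plus a group x mass interaction (slope
    homogeneity) test from the augmented model.  ``group`` must have exactly
    two levels; the difference is level2 - level1 in order of first
    appearance.
    """
    df = pd.DataFrame({"ee": np.asarray(ee, dtype=float),
                       "mass": np.asarray(mass, dtype=float),
                       "group": np.asarray(group, dtype=object)})
    levels = list(pd.unique(df["group"]))
    if len(levels) != 2:
        raise DataError("mass_adjusted_group_test requires exactly two groups")
    df["group"] = pd.Categorical(df["group"], categories=levels)
    if (df["group"].value_counts() < 3).any():
        raise DataError("need >=3 subjects per group")
    try:
        fit = smf.ols("ee ~ C(group) + mass", data=df).fit()
        fit_int = smf.ols("ee ~ C(group) * mass", data=df).fit()
    except Exception as exc:  # singular design surfaces as LinAlgError
        raise DegenerateInputError(f"singular ANCOVA design: {exc}") from exc
    term = f"C(group)[T.{levels[1]}]"
    ci = fit.conf_int().loc[term]
    inter_term = f"C(group)[T.{levels[1]}]:mass"
    return {
        "group_levels": levels,
        "adjusted_difference": float(fit.params[term]),
        "ci_low": float(ci[0]),
        "ci_high": float(ci[1]),
        "p_group": float(fit.pvalues[term]),
        "mass_slope": float(fit.params["mass"]),
        "p_interaction": float(fit_int.pvalues[inter_term]),
    }


def age_stratified_regression(ree, age, carrier_flag) -> dict:
    """Per-stratum OLS of REE on age, plus a slope-equality test.

    Returns per-stratum slope, intercept and R-squared (strata keyed by the
    values of ``carrier_flag``), and the p-value of the age x stratum
    interaction from the pooled model — the test of whether the age-related
    EE decline differs between carriers and non-carriers.
    """
    df = pd.DataFrame({"ree": np.asarray(ree, dtype=float),
                       "age": np.asarray(age, dtype=float),
                       "stratum": np.asarray(carrier_flag, dtype=object)})
    out: dict = {"strata": {}}
    for level, sub in df.groupby("stratum", sort=True):
        if sub.shape[0] < 3:
            raise DataError(f"stratum {level!r} has <3 subjects")
        if np.isclose(sub["age"].var(ddof=0), 0.0):
            raise DegenerateInputError(f"constant age in stratum {level!r}")
        x = sm.add_constant(sub["age"])
        fit = sm.OLS(sub["ree"], x).fit()
        out["strata"][level] = {
            "slope": float(fit.params["age"]),
            "intercept": float(fit.params["const"]),
            "r_squared": float(fit.rsquared),
            "p_slope": float(fit.pvalues["age"]),
            "n": int(sub.shape[0]),
        }
    levels = sorted(df["stratum"].unique())
    if len(levels) == 2:
        fit_int = smf.ols("ree ~ age * C(stratum)", data=df).fit()
        term = f"age:C(stratum)[T.{levels[1]}]"
        out["p_slope_difference"] = float(fit_int.pvalues[term])
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gas_exchange(path, species: str) -> list[GasExchangeTrace]:
    """Read traces from delimited text.

    Expected columns: ``subject_id, time_s, vo2, vco2, period`` with optional
    ``mass, sex, age, group, activity, food``.  Mouse files carry VO2/VCO2 in
    mL/h and are converted to the canonical mL/min here.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "time_s", "vo2", "vco2", "period"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"missing columns: {sorted(missing)}")
    scale = 1.0 / 60.0 if species == "mouse" else 1.0
    traces = []
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("time_s")
        cov = {}
        for c in ("sex", "age", "group"):
            if c in sub.columns:
                cov[c] = sub[c].iloc[0]
        traces.append(GasExchangeTrace(
            subject_id=str(sid), species=species,
            time=sub["time_s"].to_numpy(dtype=float),
            vo2=sub["vo2"].to_numpy(dtype=float) * scale,
            vco2=sub["vco2"].to_numpy(dtype=float) * scale,
            period_labels=sub["period"].to_numpy(dtype=object),
            body_mass=float(sub["mass"].iloc[0]) if "mass" in sub.columns else None,
            covariates=cov,
            activity=sub["activity"].to_numpy(dtype=float) if "activity" in sub.columns else None,
            food=sub["food"].to_numpy(dtype=float) if "food" in sub.columns else None,
        ))
    return traces


def write_summaries(summaries: list[EnergySummary], path) -> pd.DataFrame:
    """Write a tidy per-subject summary table (CSV); returns the DataFrame."""
    rows = []
    for s in summaries:
        row = {"subject_id": s.subject_id, "ree": s.ree, "rer": s.rer,
               "cee": s.cee, "tef": s.tef,
               "incremental_auc": s.incremental_auc}
        for p, v in s.auc_by_period.items():
            row[f"auc_{p}"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
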