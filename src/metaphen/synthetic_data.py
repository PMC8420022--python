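"""Synthetic-data generators with known ground truth.

Every generator emulates one of the study's five input kinds — human
indirect-calorimetry sessions, mouse cage runs, extracellular-flux plates,
isotopologue spectra, plasma metabolite tables and single-cell count
matrices — with configurable group effects, and returns the ground-truth
parameters alongside the data so every downstream estimator has a
parameter-recovery test surface.

Conventions
-----------
* Identical config + seed => identical output (all randomness flows through
  one ``numpy.random.default_rng(seed)`` per call).
* With all noise terms zero, downstream estimators recover the configured
  truth to numerical tolerance.
* Human gas exchange is simulated in mL/min, mouse in mL/h (converted to the
  canonical mL/min in the returned traces; file writers emit cage-convention
  mL/h).
* Stratum keys are ``"group|sex|age_band"`` strings, e.g. ``"E4+|F|young"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from . import calorimetry as cal
from .exceptions import ConfigError
from .extracellular_flux import FluxTrace
from .isotope_tracing import IsotopologueSpectrum, convolve_natural_abundance
from .metabolomics_stats import MetaboliteTable
from .sc_qc import CellCountMatrix

__all__ = [
    "CohortConfig",
    "MouseIcConfig",
    "FluxPlateConfig",
    "LabelingConfig",
    "PlasmaConfig",
    "CountMatrixConfig",
    "gen_ic_cohort",
    "gen_mouse_ic",
    "gen_flux_plate",
    "gen_labeling_experiment",
    "gen_plasma_table",
    "gen_count_matrix",
    "load_yaml_config",
    "write_ic_cohort",
]

GROUPS = ("E4-", "E4+")
SEXES = ("F", "M")
AGE_BANDS = ("young", "middle")
AFFECTED_STRATUM = ("E4+", "F", "young")  # carries the REE shift


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{fieldname}: {msg}")


def load_yaml_config(path, cls):
    """Instantiate a config dataclass from a YAML mapping."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return cls(**payload)


# ---------------------------------------------------------------------------
# Human indirect-calorimetry cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-design parameters for a simulated human IC cohort.

    ``n_per_group`` is either one count per (group x sex x age-band) stratum
    or a ``{"group|sex|age_band": n}`` mapping.  ``ree_effect`` is the
    additive kcal/day shift applied to the affected stratum (young female
    carriers).  ``tef_gain`` is the fractional EE rise at the post-glucose
    plateau; ``vo2_blunt`` reduces the post-glucose VO2 rise of female
    carriers by that fraction.  ``noise_sd`` is additive measurement noise on
    VO2/VCO2 in mL/min.  The three periods (rest, cognitive, glucose) run
    back to back; within each challenge period the response ramps linearly
    over the first ``ramp_s`` seconds (inside the steady-state buffer) and
    plateaus after, so windowed means sit on the plateau.
    """

    n_per_group: int | dict = 8
    ree_mean: float | dict = 1450.0      # kcal/day per stratum
    ree_effect: float = -150.0           # kcal/day, affected stratum only
    tef_gain: float | dict = 0.15        # fractional post-glucose EE rise
    cog_gain: float = 0.05               # fractional cognitive EE rise
    vo2_blunt: float = 0.0               # of female carriers' VO2 rise
    ree_between_sd: float = 0.0          # kcal/day between-subject SD
    ree_age_slope: dict = field(default_factory=lambda: {"E4-": 0.0, "E4+": 0.0})
    rer: float = 0.85
    noise_sd: float = 0.0                # mL/min on VO2 and VCO2
    sampling_interval: float = 15.0      # s
    period_durations: tuple = (1800.0, 1800.0, 1800.0)
    ramp_s: float = 300.0
    seed: int = 0

    def validate(self) -> None:
        _require(all(d > 0 for d in self.period_durations),
                 "period_durations", "all durations must be > 0")
        _require(self.sampling_interval > 0, "sampling_interval", "must be > 0")
        for d in self.period_durations:
            _require(abs(d % self.sampling_interval) < 1e-9,
                     "sampling_interval", f"must divide period duration {d}")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(0.0 <= self.vo2_blunt <= 1.0, "vo2_blunt", "must be in [0, 1]")
        _require(self.rer > 0, "rer", "must be > 0")
        _require(abs(self.ramp_s % self.sampling_interval) < 1e-9,
                 "ramp_s", "must align to the sampling grid")
        _require(self.ramp_s <= min(self.period_durations),
                 "ramp_s", "must fit inside each period")
        _require(self.ramp_s <= cal.STEADY_STATE_BUFFER_S, "ramp_s",
                 "response ramp must finish inside the steady-state buffer "
                 "so windowed means sit on the plateau")

    def stratum_n(self, stratum: tuple) -> int:
        if isinstance(self.n_per_group, dict):
            return int(self.n_per_group.get("|".join(stratum), 0))
        return int(self.n_per_group)

    def stratum_ree(self, stratum: tuple) -> float:
        if isinstance(self.ree_mean, dict):
            return float(self.ree_mean["|".join(stratum)])
        return float(self.ree_mean)

    def group_tef_gain(self, group: str) -> float:
        if isinstance(self.tef_gain, dict):
            return float(self.tef_gain[group])
        return float(self.tef_gain)


def _vo2_for_ee(ee: float, rer: float) -> float:
    """Invert the Weir equation at a fixed RER (mL/min for kcal/day)."""
    return ee / (cal.WEIR_SCALE * (cal.WEIR_VO2 + cal.WEIR_VCO2 * rer))


def _ramp(t_in_period: np.ndarray, ramp_s: float) -> np.ndarray:
    if ramp_s <= 0:
        return np.ones_like(t_in_period)
    return np.clip(t_in_period / ramp_s, 0.0, 1.0)


def gen_ic_cohort(config: CohortConfig
                  ) -> tuple[pd.DataFrame, list[cal.GasExchangeTrace]]:
    """Simulate a human IC cohort; returns (subject table, traces).

    The subject table carries the per-subject ground truth: ``true_ree``
    (kcal/day), ``true_tef`` and ``true_cee`` (AUC-difference units matching
    :func:`metaphen.calorimetry.thermic_effect`), sex, age and carrier group.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt = config.sampling_interval
    d_rest, d_cog, d_glu = config.period_durations
    starts = (0.0, d_rest, d_rest + d_cog)
    total = sum(config.period_durations)
    t = np.arange(0.0, total, dt)
    labels = np.empty(t.size, dtype=object)
    labels[t < starts[1]] = "rest"
    labels[(t >= starts[1]) & (t < starts[2])] = "cognitive"
    labels[t >= starts[2]] = "glucose"

    buffer_s = max(cal.STEADY_STATE_BUFFER_S, config.ramp_s)

    def _win_minutes(dur: float) -> float:
        # windowed plateau duration (minutes) for the closed-form AUC truths;
        # the last sample in a period sits at dur - dt
        return (dur - dt - buffer_s) / 60.0

    subjects = []
    traces = []
    age_ranges = {"young": (20, 39), "middle": (40, 64)}
    idx = 0
    for group in GROUPS:
        for sex in SEXES:
            for band in AGE_BANDS:
                stratum = (group, sex, band)
                n = config.stratum_n(stratum)
                for _ in range(n):
                    idx += 1
                    sid = f"S{idx:03d}"
                    age = int(rng.integers(age_ranges[band][0],
                                           age_ranges[band][1] + 1))
                    ree = config.stratum_ree(stratum)
                    ree += config.ree_age_slope.get(group, 0.0) * (age - 30.0)
                    if stratum == AFFECTED_STRATUM:
                        ree += config.ree_effect
                    if config.ree_between_sd > 0:
                        ree += rng.normal(0.0, config.ree_between_sd)
                    ree = max(ree, 200.0)

                    tef_gain = config.group_tef_gain(group)
                    blunt = config.vo2_blunt if (group == "E4+" and sex == "F") \
                        else 0.0
                    vo2_rest = _vo2_for_ee(ree, config.rer)
                    vco2_rest = config.rer * vo2_rest

                    vo2 = np.full(t.size, vo2_rest)
                    vco2 = np.full(t.size, vco2_rest)
                    # cognitive challenge: symmetric fractional rise
                    m = labels == "cognitive"
                    r = _ramp(t[m] - starts[1], config.ramp_s)
                    vo2[m] *= 1.0 + config.cog_gain * r
                    vco2[m] *= 1.0 + config.cog_gain * r
                    # glucose challenge: VCO2 rises by tef_gain, VO2 rise
                    # possibly blunted
                    m = labels == "glucose"
                    r = _ramp(t[m] - starts[2], config.ramp_s)
                    vo2[m] *= 1.0 + tef_gain * (1.0 - blunt) * r
                    vco2[m] *= 1.0 + tef_gain * r

                    ee_glu_plateau = cal.weir_ee(
                        vo2_rest * (1.0 + tef_gain * (1.0 - blunt)),
                        vco2_rest * (1.0 + tef_gain))
                    true_tef = (ee_glu_plateau - ree) * \
                        min(_win_minutes(d_glu), _win_minutes(d_rest)) / \
                        cal.MINUTES_PER_DAY
                    true_cee = (ree * config.cog_gain) * \
                        min(_win_minutes(d_cog), _win_minutes(d_rest)) / \
                        cal.MINUTES_PER_DAY

                    if config.noise_sd > 0:
                        vo2 = np.clip(vo2 + rng.normal(0, config.noise_sd,
                                                       t.size), 0, None)
                        vco2 = np.clip(vco2 + rng.normal(0, config.noise_sd,
                                                         t.size), 0, None)

                    traces.append(cal.GasExchangeTrace(
                        subject_id=sid, species="human", time=t.copy(),
                        vo2=vo2, vco2=vco2, period_labels=labels.copy(),
                        covariates={"sex": sex, "age": age, "group": group}))
                    subjects.append({
                        "subject_id": sid, "group": group, "sex": sex,
                        "age_band": band, "age": age,
                        "true_ree": ree, "true_tef": true_tef,
                        "true_cee": true_cee, "true_tef_gain": tef_gain,
                        "vo2_blunt": blunt,
                    })
    return pd.DataFrame(subjects), traces


def write_ic_cohort(traces: list[cal.GasExchangeTrace], path,
                    species: str = "human") -> None:
    """Write traces in the delimited layout :func:`read_gas_exchange` consumes.

    Mouse traces are written in cage-convention mL/h.
    """
    scale = 60.0 if species == "mouse" else 1.0
    frames = []
    for tr in traces:
        df = pd.DataFrame({
            "subject_id": tr.subject_id, "time_s": tr.time,
            "vo2": tr.vo2 * scale, "vco2": tr.vco2 * scale,
            "period": tr.period_labels,
        })
        for key in ("sex", "age", "group"):
            if key in tr.covariates:
                df[key] = tr.covariates[key]
        if tr.body_mass is not None:
            df["mass"] = tr.body_mass
        if tr.activity is not None:
            df["activity"] = tr.activity
        if tr.food is not None:
            df["food"] = tr.food
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Mouse cage runs
# ---------------------------------------------------------------------------

@dataclass
class MouseIcConfig:
    """Cage-run design: light/dark cycling across a chow and a
    high-carbohydrate-diet (HCD) phase.

    Gas rates are configured in mL/h (cage convention).  ``hcd_vo2_gain`` /
    ``hcd_vco2_gain`` are fractional light-cycle increments on the HCD per
    genotype; a genotype with a VO2 gain of 0 models the carrier phenotype
    that fails to raise oxygen consumption on dietary carbohydrate.
    """

    n_per_genotype: dict = field(default_factory=lambda: {"E3": 13, "E4": 20})
    vo2_light_mean: dict = field(default_factory=lambda: {"E3": 95.0, "E4": 85.0})
    rer: float = 0.85
    dark_multiplier: float = 1.25
    hcd_vo2_gain: dict = field(default_factory=lambda: {"E3": 0.10, "E4": 0.0})
    hcd_vco2_gain: dict = field(default_factory=lambda: {"E3": 0.12, "E4": 0.08})
    animal_cv: float = 0.0               # between-animal CV on light-cycle VO2
    noise_sd: float = 0.0                # mL/h, additive per sample
    cycle_hours: float = 12.0
    days_per_phase: int = 2
    sampling_minutes: float = 30.0
    mass_mean_g: float = 25.0
    mass_sd_g: float = 0.0
    mass_ee_slope: float = 0.0           # kcal/day extra EE per g above mean
    activity_light: float = 5.0
    activity_dark: float = 20.0
    food_light: float = 0.05
    food_dark: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        _require(self.sampling_minutes > 0, "sampling_minutes", "must be > 0")
        cycle_s = self.cycle_hours * 3600.0
        dt = self.sampling_minutes * 60.0
        _require(abs(cycle_s % dt) < 1e-9, "sampling_minutes",
                 "light/dark cycle boundary must align to the sampling grid")
        phase_s = self.days_per_phase * 86400.0
        _require(abs(phase_s % dt) < 1e-9, "days_per_phase",
                 "diet-phase boundary must align to the sampling grid")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.dark_multiplier > 0, "dark_multiplier", "must be > 0")


def gen_mouse_ic(config: MouseIcConfig
                 ) -> tuple[pd.DataFrame, list[cal.GasExchangeTrace]]:
    """Simulate mouse cage runs; returns (animal table, traces).

    Traces carry compound ``cycle|diet`` labels and canonical mL/min rates.
    The animal table stores per-animal ground-truth light-cycle means per
    phase: ``true_vo2_light_{chow,hcd}`` (mL/h) and the matching
    ``true_ee_light_*`` (kcal/day).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt = config.sampling_minutes * 60.0
    phase_s = config.days_per_phase * 86400.0
    cycle_s = config.cycle_hours * 3600.0
    t = np.arange(0.0, 2 * phase_s, dt)
    diet = np.where(t < phase_s, "chow", "hcd")
    cycle = np.where((t // cycle_s).astype(int) % 2 == 0, "light", "dark")
    labels = np.array([f"{c}|{d}" for c, d in zip(cycle, diet)], dtype=object)

    animals = []
    traces = []
    idx = 0
    for geno in sorted(config.n_per_genotype):
        for _ in range(int(config.n_per_genotype[geno])):
            idx += 1
            aid = f"M{idx:03d}"
            mass = config.mass_mean_g + (
                rng.normal(0.0, config.mass_sd_g) if config.mass_sd_g > 0 else 0.0)
            vo2_light = config.vo2_light_mean[geno]
            if config.animal_cv > 0:
                vo2_light *= rng.lognormal(0.0, config.animal_cv)
            if config.mass_ee_slope:
                # mass acts on VO2 proportionally to its EE contribution
                extra_ee = config.mass_ee_slope * (mass - config.mass_mean_g)
                vo2_light += _vo2_for_ee(extra_ee, config.rer) * 60.0
            vco2_light = config.rer * vo2_light

            vo2 = np.full(t.size, vo2_light)
            vco2 = np.full(t.size, vco2_light)
            dark = cycle == "dark"
            vo2[dark] *= config.dark_multiplier
            vco2[dark] *= config.dark_multiplier
            hcd = diet == "hcd"
            vo2[hcd] *= 1.0 + config.hcd_vo2_gain[geno]
            vco2[hcd] *= 1.0 + config.hcd_vco2_gain[geno]
            if config.noise_sd > 0:
                vo2 = np.clip(vo2 + rng.normal(0, config.noise_sd, t.size), 0, None)
                vco2 = np.clip(vco2 + rng.normal(0, config.noise_sd, t.size), 0, None)

            activity = np.where(dark, config.activity_dark, config.activity_light)
            food = np.where(dark, config.food_dark, config.food_light)
            if config.noise_sd > 0:
                activity = np.clip(activity * rng.lognormal(0.0, 0.1, t.size), 0, None)
                food = np.clip(food * rng.lognormal(0.0, 0.1, t.size), 0, None)

            traces.append(cal.GasExchangeTrace(
                subject_id=aid, species="mouse", time=t.copy(),
                vo2=vo2 / 60.0, vco2=vco2 / 60.0,  # canonical mL/min
                period_labels=labels.copy(), body_mass=mass,
                covariates={"group": geno},
                activity=activity, food=food))
            row = {"animal_id": aid, "genotype": geno, "mass_g": mass}
            for phase in ("chow", "hcd"):
                gv = config.hcd_vo2_gain[geno] if phase == "hcd" else 0.0
                gc = config.hcd_vco2_gain[geno] if phase == "hcd" else 0.0
                v, c = vo2_light * (1 + gv), vco2_light * (1 + gc)
                row[f"true_vo2_light_{phase}"] = v
                row[f"true_vco2_light_{phase}"] = c
                row[f"true_ee_light_{phase}"] = cal.weir_ee(v / 60.0, c / 60.0)
            animals.append(row)
    return pd.DataFrame(animals), traces


# ---------------------------------------------------------------------------
# Extracellular-flux plates
# ---------------------------------------------------------------------------

@dataclass
class FluxPlateConfig:
    """Plate design: per-group baselines and per-injection response
    multipliers (segment level = baseline x multiplier)."""

    group_baselines: dict = field(default_factory=lambda: {
        "E3": {"ECAR": 5.0, "OCR": 100.0},
        "E4": {"ECAR": 6.0, "OCR": 80.0},
    })
    injections: tuple = ("glucose", "oligomycin", "2-DG")
    multipliers: dict = field(default_factory=lambda: {
        "ECAR": {"glucose": 2.4, "oligomycin": 3.6, "2-DG": 0.4},
        "OCR": {"glucose": 1.1, "oligomycin": 0.5, "2-DG": 0.5},
    })
    wells_per_group: int = 24
    cycles_per_segment: int = 3
    cycle_minutes: float = 6.5
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        _require(self.cycles_per_segment >= 1, "cycles_per_segment",
                 "need at least one measurement cycle per segment")
        _require(self.wells_per_group >= 1, "wells_per_group", "must be >= 1")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        for measure, mult in self.multipliers.items():
            for inj in self.injections:
                _require(inj in mult, "multipliers",
                         f"missing multiplier for {inj!r} ({measure})")


def gen_flux_plate(config: FluxPlateConfig
                   ) -> tuple[pd.DataFrame, list[FluxTrace]]:
    """Simulate a flux plate; returns (ground-truth segment means, traces).

    One ECAR and one OCR trace per well; each segment holds
    ``cycles_per_segment`` cycles.  Truth rows: group, measure, segment,
    true mean.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.cycles_per_segment
    n_seg = 1 + len(config.injections)
    times = np.arange(n_seg * k) * config.cycle_minutes
    inj_list = [(name, (i + 1) * k - 1)
                for i, name in enumerate(config.injections)]
    truth_rows = []
    traces = []
    widx = 0
    for group in sorted(config.group_baselines):
        for measure, baseline in config.group_baselines[group].items():
            levels = [baseline] + [baseline * config.multipliers[measure][inj]
                                   for inj in config.injections]
            for seg_name, level in zip(("baseline",) + tuple(config.injections),
                                       levels):
                truth_rows.append({"group": group, "measure": measure,
                                   "segment": seg_name, "true_mean": level})
        for w in range(config.wells_per_group):
            widx += 1
            wid = f"W{widx:03d}"
            for measure, baseline in config.group_baselines[group].items():
                levels = [baseline] + [
                    baseline * config.multipliers[measure][inj]
                    for inj in config.injections]
                values = np.repeat(levels, k).astype(float)
                if config.noise_sd > 0:
                    values = values + rng.normal(0, config.noise_sd, values.size)
                traces.append(FluxTrace(
                    well_id=wid, group=group, measure=measure,
                    cycle_times=times.copy(), values=values,
                    injections=list(inj_list)))
    return pd.DataFrame(truth_rows), traces


# ---------------------------------------------------------------------------
# Isotope-labeling experiments
# ---------------------------------------------------------------------------

@dataclass
class LabelingConfig:
    """Ground-truth corrected MIDs per metabolite (optionally per group).

    ``true_mid`` maps metabolite name -> simplex vector of length
    n_carbons+1, or -> {group: vector} for planted group contrasts.  Raw
    intensities are the truth convolved with binomial natural 13C abundance,
    times a random per-spectrum scale, times multiplicative log-normal noise
    of CV ``noise_cv``.
    """

    metabolites: tuple = (("lactate", 3), ("pyruvate", 3))
    true_mid: dict = field(default_factory=lambda: {
        "lactate": {"E3": [0.55, 0.03, 0.02, 0.40],
                    "E4": [0.45, 0.03, 0.02, 0.50]},
        "pyruvate": [0.60, 0.03, 0.02, 0.35],
    })
    groups: tuple = ("E3", "E4")
    n_per_group: int = 6
    p_nat: float = 0.0107
    noise_cv: float = 0.0
    scale_mean: float = 1e6
    standard_level: float = 1e5
    seed: int = 0

    def validate(self) -> None:
        _require(0.0 <= self.p_nat < 1.0, "p_nat", "must be in [0, 1)")
        _require(self.noise_cv >= 0, "noise_cv", "must be >= 0")
        for name, n_c in self.metabolites:
            spec = self.true_mid.get(name)
            _require(spec is not None, "true_mid", f"missing metabolite {name!r}")
            mids = spec.values() if isinstance(spec, dict) else [spec]
            for mid in mids:
                mid = np.asarray(mid, dtype=float)
                _require(mid.size == n_c + 1, "true_mid",
                         f"{name}: expected {n_c + 1} fractions, got {mid.size}")
                _require(np.all(mid >= 0), "true_mid", f"{name}: negative fraction")
                _require(abs(mid.sum() - 1.0) < 1e-9, "true_mid",
                         f"{name}: fractions must sum to 1")

    def mid_for(self, name: str, group: str) -> np.ndarray:
        spec = self.true_mid[name]
        vec = spec[group] if isinstance(spec, dict) else spec
        return np.asarray(vec, dtype=float)


def gen_labeling_experiment(config: LabelingConfig
                            ) -> tuple[pd.DataFrame, list[IsotopologueSpectrum]]:
    """Simulate raw isotopologue spectra; returns (truth table, spectra).

    Truth rows: sample_id, group, metabolite, true m+k fractions and the true
    fractional enrichment.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    spectra = []
    truth_rows = []
    sidx = 0
    for group in config.groups:
        for _ in range(config.n_per_group):
            sidx += 1
            sample = f"T{sidx:03d}"
            for name, n_c in config.metabolites:
                true = config.mid_for(name, group)
                raw = convolve_natural_abundance(true, config.p_nat)
                scale = config.scale_mean * rng.lognormal(0.0, 0.25)
                intens = raw * scale
                if config.noise_cv > 0:
                    sigma = np.sqrt(np.log1p(config.noise_cv ** 2))
                    intens = intens * rng.lognormal(0.0, sigma, intens.size)
                spectra.append(IsotopologueSpectrum(
                    metabolite=name, n_carbons=n_c, intensities=intens,
                    sample_id=sample,
                    internal_standard=config.standard_level))
                k = np.arange(n_c + 1)
                truth_rows.append({
                    "sample_id": sample, "group": group, "metabolite": name,
                    **{f"true_m{i}": true[i] for i in range(n_c + 1)},
                    "true_enrichment": float(np.dot(k / n_c, true)),
                })
    return pd.DataFrame(truth_rows), spectra


# ---------------------------------------------------------------------------
# Plasma metabolite tables
# ---------------------------------------------------------------------------

def _default_plasma_metabolites() -> dict:
    names = ["lactate", "pyruvate", "glucose", "alanine", "glycine", "serine",
             "glutamate", "glutamine", "citrate", "succinate", "fumarate",
             "malate", "leucine", "isoleucine", "valine", "proline",
             "threonine", "phenylalanine", "tyrosine", "urea"]
    return {n: (5.0, 0.3) for n in names}


@dataclass
class PlasmaConfig:
    """Plasma-table design: per-metabolite log-normal abundances with planted
    group effects, missingness and a shared internal standard.

    ``group_effects`` maps metabolite -> additive log-effect for the carrier
    group (applied at both timepoints); ``time_effects`` -> log-effect of the
    post-drink timepoint.  ``missing_prob`` is a scalar or a per-metabolite
    mapping.  A per-sample instrument gain multiplies all metabolites and the
    internal standard alike, so standard-normalization removes it exactly.
    """

    metabolites: dict = field(default_factory=_default_plasma_metabolites)
    group_effects: dict = field(default_factory=lambda: {"lactate": 0.5})
    time_effects: dict = field(default_factory=lambda: {"glucose": 0.4})
    missing_prob: float | dict = 0.0
    n_per_group: int = 30
    groups: tuple = ("E4-", "E4+")
    timepoints: tuple = ("pre", "post")
    standard_level: float = 1.0
    gain_sd: float = 0.0                 # log-SD of the per-sample gain
    seed: int = 0

    def validate(self) -> None:
        probs = (self.missing_prob.values()
                 if isinstance(self.missing_prob, dict) else [self.missing_prob])
        for p in probs:
            _require(0.0 <= p <= 1.0, "missing_prob", "must be in [0, 1]")
        for m in list(self.group_effects) + list(self.time_effects):
            _require(m in self.metabolites, "group_effects/time_effects",
                     f"unknown metabolite {m!r}")
        _require(self.standard_level > 0, "standard_level", "must be > 0")

    def p_missing(self, metabolite: str) -> float:
        if isinstance(self.missing_prob, dict):
            return float(self.missing_prob.get(metabolite, 0.0))
        return float(self.missing_prob)


def gen_plasma_table(config: PlasmaConfig
                     ) -> tuple[pd.DataFrame, MetaboliteTable]:
    """Simulate a plasma metabolite table; returns (truth table, table).

    The returned :class:`MetaboliteTable` holds standard-normalized
    abundances with pre/post samples per subject; ``meta`` includes the raw
    internal-standard intensity.  Truth rows list each metabolite's planted
    log group effect and log time effect (0 = null).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = list(config.metabolites)
    rows, meta_rows = [], []
    sidx = 0
    for group in config.groups:
        for _ in range(config.n_per_group):
            sidx += 1
            subject = f"P{sidx:03d}"
            for tp in config.timepoints:
                gain = rng.lognormal(0.0, config.gain_sd) if config.gain_sd > 0 \
                    else 1.0
                standard = config.standard_level * gain
                vals = {}
                for name in names:
                    mu, sd = config.metabolites[name]
                    logv = mu
                    if group == config.groups[1]:
                        logv += config.group_effects.get(name, 0.0)
                    if tp == "post":
                        logv += config.time_effects.get(name, 0.0)
                    if sd > 0:
                        logv += rng.normal(0.0, sd)
                    raw = np.exp(logv) * gain
                    if rng.random() < config.p_missing(name):
                        vals[name] = np.nan
                    else:
                        vals[name] = raw / standard  # internal-standard norm
                rows.append(vals)
                meta_rows.append({"subject": subject, "group": group,
                                  "timepoint": tp,
                                  "internal_standard": standard})
    index = pd.RangeIndex(len(rows))
    table = MetaboliteTable(
        data=pd.DataFrame(rows, index=index, columns=names),
        meta=pd.DataFrame(meta_rows, index=index),
        provenance=["gen_plasma_table"])
    truth = pd.DataFrame({
        "metabolite": names,
        "log_group_effect": [config.group_effects.get(n, 0.0) for n in names],
        "log_time_effect": [config.time_effects.get(n, 0.0) for n in names],
        "missing_prob": [config.p_missing(n) for n in names],
    }).set_index("metabolite")
    return truth, table


# ---------------------------------------------------------------------------
# Single-cell count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountMatrixConfig:
    """Count-matrix design: cell-type expression programs with planted QC
    failures and doublets.

    ``markers`` must be disjoint across types.  Planted failures draw their
    UMI totals outside the QC bounds (or mitochondrial fraction above the
    rule); doublets mix the expression programs of the first two cell types
    and live in their own small cluster.
    """

    n_cells: dict = field(default_factory=lambda: {
        "astrocyte": 500, "microglia": 400, "oligodendrocyte": 300})
    markers: dict = field(default_factory=lambda: {
        "astrocyte": ["Aldoc", "Aqp4", "Gja1", "Aldh1l1"],
        "microglia": ["Tmem119", "P2ry12", "Cx3cr1"],
        "oligodendrocyte": ["Mog", "Mbp", "Plp1"]})
    n_background_genes: int = 60
    n_mito_genes: int = 8
    mito_frac: float = 0.05
    umi_mean: float | dict = 3000.0
    umi_dispersion: float = 10.0
    qc_fail_fractions: dict = field(default_factory=lambda: {
        "low_umi": 0.02, "high_umi": 0.01, "high_mito": 0.02})
    doublet_fraction: float = 0.02
    high_mito_level: float = 0.5
    marker_weight: float = 30.0
    off_marker_weight: float = 0.2
    glycolysis_boost: dict = field(default_factory=dict)  # type -> gene weight
    seed: int = 0

    def validate(self) -> None:
        seen: set = set()
        for cell_type, genes in self.markers.items():
            overlap = seen & set(genes)
            _require(not overlap, "markers",
                     f"marker genes shared across types: {sorted(overlap)}")
            seen |= set(genes)
        for k, v in self.qc_fail_fractions.items():
            _require(0.0 <= v <= 1.0, "qc_fail_fractions",
                     f"{k} must be in [0, 1]")
        _require(0.0 <= self.doublet_fraction <= 1.0, "doublet_fraction",
                 "must be in [0, 1]")
        _require(0.0 <= self.mito_frac < 1.0, "mito_frac", "must be in [0, 1)")
        _require(set(self.n_cells) == set(self.markers), "n_cells",
                 "cell types must match marker map")

    def type_umi_mean(self, cell_type: str) -> float:
        if isinstance(self.umi_mean, dict):
            return float(self.umi_mean[cell_type])
        return float(self.umi_mean)


def _nb_total(rng, mean: float, dispersion: float, lo: int, hi: int) -> int:
    """Negative-binomial UMI total clipped inside the QC-safe band."""
    p = dispersion / (dispersion + mean)
    return int(np.clip(rng.negative_binomial(dispersion, p), lo, hi))


def gen_count_matrix(config: CountMatrixConfig
                     ) -> tuple[pd.DataFrame, CellCountMatrix]:
    """Simulate a sparse genes x cells count matrix; returns (truth, matrix).

    Truth rows per cell: barcode, true type, planted QC-failure reason
    (empty string for clean cells) and a doublet flag.  Cluster labels are
    the true type for singlets and a dedicated ``doublet`` cluster for the
    planted multi-marker cells.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    types = sorted(config.n_cells)
    genes: list[str] = []
    for t in types:
        genes.extend(config.markers[t])
    genes.extend(f"bg{i:03d}" for i in range(config.n_background_genes))
    mito_genes = [f"mt-g{i}" for i in range(config.n_mito_genes)]
    genes.extend(mito_genes)
    gene_arr = np.array(genes, dtype=object)
    mito_mask = np.array([g.startswith("mt-") for g in genes])
    n_genes = gene_arr.size

    def type_probs(cell_type: str, mito_level: float) -> np.ndarray:
        w = np.full(n_genes, 0.0)
        for t in types:
            for g in config.markers[t]:
                w[genes.index(g)] = (config.marker_weight if t == cell_type
                                     else config.off_marker_weight)
        bg0 = len(genes) - config.n_background_genes - config.n_mito_genes
        w[bg0:bg0 + config.n_background_genes] = 1.0
        for g, boost in config.glycolysis_boost.get(cell_type, {}).items():
            if g in genes:
                w[genes.index(g)] += boost
        w[mito_mask] = 0.0
        w = w / w.sum() * (1.0 - mito_level)
        w[mito_mask] = mito_level / config.n_mito_genes
        return w

    probs = {t: type_probs(t, config.mito_frac) for t in types}
    high_mito_probs = {t: type_probs(t, config.high_mito_level) for t in types}

    cols, barcodes, rows_truth, clusters = [], [], [], []
    cidx = 0

    def add_cell(p: np.ndarray, total: int, true_type: str, reason: str,
                 cluster: str, doublet: bool) -> None:
        nonlocal cidx
        cidx += 1
        bc = f"C{cidx:05d}"
        counts = rng.multinomial(total, p)
        cols.append(counts)
        barcodes.append(bc)
        clusters.append(cluster)
        rows_truth.append({"barcode": bc, "true_type": true_type,
                           "planted_fail": reason, "is_doublet": doublet})

    for t in types:
        n = int(config.n_cells[t])
        n_low = int(round(n * config.qc_fail_fractions.get("low_umi", 0.0)))
        n_high = int(round(n * config.qc_fail_fractions.get("high_umi", 0.0)))
        n_mito = int(round(n * config.qc_fail_fractions.get("high_mito", 0.0)))
        n_clean = n - n_low - n_high - n_mito
        _require(n_clean >= 0, "qc_fail_fractions", "fail fractions exceed 1")
        mean = config.type_umi_mean(t)
        for _ in range(n_clean):
            add_cell(probs[t], _nb_total(rng, mean, config.umi_dispersion,
                                         200, 20000), t, "", t, False)
        for _ in range(n_low):
            add_cell(probs[t], int(rng.integers(5, 50)), t, "low_umi", t, False)
        for _ in range(n_high):
            add_cell(probs[t], int(rng.integers(50001, 60001)), t,
                     "high_umi", t, False)
        for _ in range(n_mito):
            add_cell(high_mito_probs[t],
                     _nb_total(rng, mean, config.umi_dispersion, 200, 20000),
                     t, "high_mito", t, False)

    n_total_singlets = cidx
    n_doublets = int(round(n_total_singlets * config.doublet_fraction))
    if n_doublets and len(types) >= 2:
        ta, tb = types[0], types[1]
        p_mix = 0.5 * (probs[ta] + probs[tb])
        mean = 0.5 * (config.type_umi_mean(ta) + config.type_umi_mean(tb))
        for _ in range(n_doublets):
            add_cell(p_mix, _nb_total(rng, mean, config.umi_dispersion,
                                      200, 20000),
                     f"{ta}+{tb}", "", "doublet", True)

    counts = sp.csr_matrix(np.column_stack(cols))
    matrix = CellCountMatrix(
        counts=counts, gene_names=gene_arr, mito_mask=mito_mask,
        barcodes=np.array(barcodes, dtype=object),
        cluster_labels=np.array(clusters, dtype=object))
    return pd.DataFrame(rows_truth), matrix
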