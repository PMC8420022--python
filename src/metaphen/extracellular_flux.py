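"""Extracellular-flux (Seahorse-style) trace parameterization.

Per-well ECAR/OCR series are segmented by injection events; the glycolysis
stress test (glucose -> oligomycin -> 2-DG) yields glycolysis, glycolytic
capacity and glycolytic reserve, and the fuel-flex inhibitor-order design
yields per-fuel dependency, capacity and flexibility percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import DataError, DegenerateInputError, QualityWarning

__all__ = [
    "FluxTrace",
    "GlycoStressResult",
    "FuelFlexResult",
    "segment_means",
    "glycolysis_stress",
    "glyco_stress_table",
    "fuel_flex",
    "group_compare_flux",
    "read_flux_traces",
]


@dataclass
class FluxTrace:
    """One well's measurement-cycle series with ordered injection events.

    ``injections`` is an ordered list of ``(name, after_cycle_index)``: the
    named compound is injected after the 0-based cycle index, so cycles
    ``after_cycle_index + 1 ..`` up to the next injection belong to that
    compound's segment.  Cycles before the first injection are the baseline.
    """

    well_id: str
    group: str
    measure: str  # "ECAR" (mpH/min) | "OCR" (pmol/min)
    cycle_times: np.ndarray  # minutes
    values: np.ndarray
    injections: list

    def __post_init__(self) -> None:
        self.cycle_times = np.asarray(self.cycle_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.cycle_times.size != self.values.size:
            raise DataError("cycle_times and values must be equal length")
        if np.any(np.diff(self.cycle_times) <= 0):
            raise DataError("cycle_times must be increasing")
        n = self.cycle_times.size
        prev = -1
        for name, idx in self.injections:
            if not (0 <= idx < n):
                raise DataError(f"injection {name!r} after_cycle_index {idx} "
                                f"out of range for {n} cycles")
            if idx <= prev:
                raise DataError("injections must be strictly ordered")
            prev = idx


@dataclass
class GlycoStressResult:
    """Glycolysis stress test metrics for one well (same units as ECAR)."""

    well_id: str
    group: str
    baseline_ecar: float
    glycolysis: float           # post-glucose - baseline
    glycolytic_capacity: float  # post-oligomycin - baseline
    glycolytic_reserve: float   # post-oligomycin - post-glucose


@dataclass
class FuelFlexResult:
    """Fuel dependency / capacity / flexibility for one fuel pathway (%)."""

    dependency_pct: float
    capacity_pct: float
    flexibility_pct: float


def segment_means(trace: FluxTrace) -> dict:
    """Mean value per injection segment, keyed ``baseline`` then by injection
    name.  A segment is the cycles strictly after its injection up to (and
    including the cycle at) the next injection's index.
    """
    n = trace.values.size
    bounds = [idx for _, idx in trace.injections]
    names = [name for name, _ in trace.injections]
    out: dict = {}
    first = (bounds[0] + 1) if bounds else n
    if first == 0:
        raise DegenerateInputError("empty baseline segment (no cycles before "
                                   "the first injection)")
    out["baseline"] = float(np.mean(trace.values[:first]))
    for k, name in enumerate(names):
        lo = bounds[k] + 1
        hi = (bounds[k + 1] + 1) if k + 1 < len(bounds) else n
        if lo >= hi:
            raise DegenerateInputError(f"empty segment after injection {name!r}")
        out[name] = float(np.mean(trace.values[lo:hi]))
    return out


_GLYCO_ORDER = ("glucose", "oligomycin", "2-DG")


def glycolysis_stress(trace: FluxTrace) -> GlycoStressResult:
    """Glycolysis stress test metrics from an ECAR well trace.

    glycolysis          = ECAR post-glucose    - baseline ECAR
    glycolytic capacity = ECAR post-oligomycin - baseline ECAR
    glycolytic reserve  = ECAR post-oligomycin - ECAR post-glucose

    so reserve == capacity - glycolysis identically.  Requires the glucose,
    oligomycin, 2-DG injections in that order.  A negative post-2-DG mean
    (instrument drift) is floored at 0 with a warning; it does not enter the
    three metrics.
    """
    if trace.measure != "ECAR":
        raise DataError("glycolysis_stress requires an ECAR trace")
    names = [name for name, _ in trace.injections]
    for required in _GLYCO_ORDER:
        if required not in names:
            raise DataError(f"missing injection {required!r}")
    if [n for n in names if n in _GLYCO_ORDER] != list(_GLYCO_ORDER):
        raise DataError("injections must be ordered glucose, oligomycin, 2-DG")
    seg = segment_means(trace)
    if seg["2-DG"] < 0:
        warnings.warn("negative post-2-DG ECAR floored at 0",
                      QualityWarning, stacklevel=2)
        seg["2-DG"] = 0.0
    glycolysis = seg["glucose"] - seg["baseline"]
    capacity = seg["oligomycin"] - seg["baseline"]
    return GlycoStressResult(
        well_id=trace.well_id, group=trace.group,
        baseline_ecar=seg["baseline"],
        glycolysis=glycolysis,
        glycolytic_capacity=capacity,
        glycolytic_reserve=capacity - glycolysis,
    )


def glyco_stress_table(traces: list[FluxTrace]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-well metric table and per-group mean +/- SEM for a plate."""
    rows = [vars(glycolysis_stress(t)) for t in traces]
    per_well = pd.DataFrame(rows)
    metrics = ["baseline_ecar", "glycolysis", "glycolytic_capacity",
               "glycolytic_reserve"]
    agg = per_well.groupby("group")[metrics].agg(["mean", "sem"])
    return per_well, agg


def fuel_flex(baseline_ocr: float, target_first_ocr: float,
              other_two_first_ocr: float, all_inhibited_ocr: float,
              *, as_printed: bool = False) -> FuelFlexResult:
    """Fuel dependency, capacity and flexibility from inhibitor-order OCR.

    Dependency (%) = (baseline - target-inhibitor-first OCR)
                   / (baseline - all-inhibitors OCR) x 100.

    Capacity uses the complementary arm (the other two fuels inhibited
    first).  The default convention is
    ``capacity = (1 - (baseline - other_two) / (baseline - all)) x 100``
    and ``flexibility = capacity - dependency`` always holds by construction.
    ``as_printed=True`` instead uses the literal reciprocal form
    ``capacity = 1 / ((baseline - other_two) / (baseline - all)) x 100``,
    which is unbounded; the default bounded convention is recommended.
    """
    window = baseline_ocr - all_inhibited_ocr
    if window <= 0:
        raise DegenerateInputError(
            "degenerate mitochondrial window: baseline OCR must exceed the "
            "all-inhibitors OCR")
    dependency = (baseline_ocr - target_first_ocr) / window * 100.0
    ratio = (baseline_ocr - other_two_first_ocr) / window
    if as_printed:
        if ratio == 0:
            raise DegenerateInputError("capacity undefined: other-two arm "
                                       "showed no OCR drop")
        capacity = 1.0 / ratio * 100.0
    else:
        capacity = (1.0 - ratio) * 100.0
    return FuelFlexResult(
        dependency_pct=dependency,
        capacity_pct=capacity,
        flexibility_pct=capacity - dependency,
    )


def group_compare_flux(per_well: pd.DataFrame, metrics: list[str],
                       group_col: str = "group") -> pd.DataFrame:
    """Two-tailed unpaired t-test per metric between two groups of wells.

    Returns one row per metric with group means +/- SEM, t and p.
    """
    levels = list(pd.unique(per_well[group_col]))
    if len(levels) != 2:
        raise DataError("group_compare_flux requires exactly two groups")
    a = per_well[per_well[group_col] == levels[0]]
    b = per_well[per_well[group_col] == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise DataError("need >=2 wells per group")
    rows = []
    for m in metrics:
        x, y = a[m].to_numpy(dtype=float), b[m].to_numpy(dtype=float)
        if np.ptp(np.concatenate([x, y])) == 0.0:
            t_stat, p = 0.0, 1.0  # identical constant wells
        else:
            t_stat, p = scipy.stats.ttest_ind(x, y)
        rows.append({
            "metric": m,
            f"mean_{levels[0]}": float(np.mean(x)),
            f"sem_{levels[0]}": float(scipy.stats.sem(x)),
            f"mean_{levels[1]}": float(np.mean(y)),
            f"sem_{levels[1]}": float(scipy.stats.sem(y)),
            "t": float(t_stat), "p": float(p),
        })
    return pd.DataFrame(rows)


def read_flux_traces(path, injection_map: dict) -> list[FluxTrace]:
    """Read well traces from delimited text.

    Columns: ``well_id, group, measure, cycle_index, time_min, value``.
    ``injection_map`` maps injection name -> after_cycle_index (ordered
    dict / list of pairs), shared across wells.
    """
    df = pd.read_csv(path)
    required = {"well_id", "group", "measure", "cycle_index", "time_min", "value"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"missing columns: {sorted(missing)}")
    injections = list(injection_map.items()) if isinstance(injection_map, dict) \
        else list(injection_map)
    traces = []
    for (wid, measure), sub in df.groupby(["well_id", "measure"], sort=False):
        sub = sub.sort_values("cycle_index")
        traces.append(FluxTrace(
            well_id=str(wid), group=str(sub["group"].iloc[0]), measure=measure,
            cycle_times=sub["time_min"].to_numpy(dtype=float),
            values=sub["value"].to_numpy(dtype=float),
            injections=injections,
        ))
    return traces
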