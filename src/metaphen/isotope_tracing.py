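"""Stable-isotope-resolved metabolomics (13C) enrichment analysis.

Raw isotopologue intensity vectors (m+0 .. m+n for an n-carbon metabolite)
are normalized to mass-isotopologue distributions (MIDs), corrected for
naturally occurring 13C by inverting the binomial convolution matrix, and
summarized as carbon-weighted fractional enrichment, per-metabolite-panel
means, and group contrasts on chosen isotopologue species.

The correction is carbon-only: natural abundance of Si and other
derivatization isotopes is not modelled (``nat_abund_matrix`` is the hook
for a full element matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from scipy.stats import binom

from .exceptions import DataError, DegenerateInputError, QualityWarning

__all__ = [
    "P13C_NATURAL",
    "IsotopologueSpectrum",
    "CorrectedMID",
    "normalize_mid",
    "nat_abund_matrix",
    "convolve_natural_abundance",
    "natural_abundance_correct",
    "fractional_enrichment",
    "panel_enrichment",
    "normalize_abundance",
    "labeled_species_compare",
    "read_isotopologue_table",
    "write_isotopologue_table",
]

#: Natural abundance of 13C.
P13C_NATURAL = 0.0107


@dataclass
class IsotopologueSpectrum:
    """Raw m+0..m+n intensities for one metabolite in one sample."""

    metabolite: str
    n_carbons: int
    intensities: np.ndarray
    sample_id: str = ""
    internal_standard: float | None = None
    protein: float | None = None  # mg, optional second normalizer

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.size != self.n_carbons + 1:
            raise DataError(
                f"{self.metabolite}: expected {self.n_carbons + 1} intensities "
                f"(m+0..m+{self.n_carbons}), got {self.intensities.size}")
        if np.any(self.intensities < 0):
            raise DataError(f"{self.metabolite}: negative intensity")
        if not np.any(self.intensities > 0):
            raise DataError(f"{self.metabolite}: all-zero spectrum")


@dataclass
class CorrectedMID:
    """Natural-abundance-corrected mass-isotopologue distribution."""

    metabolite: str
    n_carbons: int
    fractions: np.ndarray
    fractional_enrichment: float
    sample_id: str = ""
    labeled_pool_size: float | None = None  # normalized abundance x labeled frac


def normalize_mid(spectrum: IsotopologueSpectrum) -> np.ndarray:
    """Intensities divided by their sum (scale-invariant MID)."""
    total = spectrum.intensities.sum()
    if total <= 0:
        raise DegenerateInputError(f"{spectrum.metabolite}: zero-sum spectrum")
    return spectrum.intensities / total


def nat_abund_matrix(n_carbons: int, p_nat: float = P13C_NATURAL) -> np.ndarray:
    """Forward natural-abundance convolution matrix M (lower-triangular).

    M[i, j] = C(n-j, i-j) * p^(i-j) * (1-p)^(n-i) for i >= j: a molecule with
    j tracer-labeled carbons acquires i-j extra mass units when each of its
    n-j unlabeled carbons is independently 13C with probability p.  The
    measured MID is M @ true MID; each column sums to 1.
    """
    if not (0.0 <= p_nat < 1.0):
        raise DataError("p_nat must be in [0, 1)")
    n = n_carbons
    m = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        k = np.arange(n - j + 1)  # extra mass units on the n-j unlabeled carbons
        m[j + k, j] = binom.pmf(k, n - j, p_nat)
    return m


def convolve_natural_abundance(true_mid: np.ndarray,
                               p_nat: float = P13C_NATURAL) -> np.ndarray:
    """Forward-convolve a true MID with natural 13C abundance."""
    true_mid = np.asarray(true_mid, dtype=float)
    return nat_abund_matrix(true_mid.size - 1, p_nat) @ true_mid


def natural_abundance_correct(spectrum: IsotopologueSpectrum,
                              p_nat: float = P13C_NATURAL,
                              *, clamp_tol: float = 1e-6) -> CorrectedMID:
    """Remove natural 13C contributions from a measured spectrum.

    Solves the lower-triangular system M x = measured-MID, clamps small
    negative components to zero (a data-quality warning fires when a
    component is below ``-clamp_tol``), renormalizes to the simplex, and
    reports the carbon-weighted fractional enrichment.  ``p_nat = 0`` is the
    identity correction.
    """
    measured = normalize_mid(spectrum)
    m = nat_abund_matrix(spectrum.n_carbons, p_nat)
    if (1.0 - p_nat) ** spectrum.n_carbons < 1e-12:
        raise DegenerateInputError(
            "correction matrix is numerically singular (p_nat too close to 1)")
    x = scipy.linalg.solve_triangular(m, measured, lower=True)
    if np.any(x < -clamp_tol):
        warnings.warn(
            f"{spectrum.metabolite}: corrected fraction "
            f"{x.min():.3g} < -{clamp_tol:g}; clamped (noisy or misassigned "
            "spectrum?)", QualityWarning, stacklevel=2)
    x = np.clip(x, 0.0, None)
    x = x / x.sum()
    pool = None
    if spectrum.internal_standard is not None:
        pool = normalize_abundance(spectrum) * (1.0 - x[0])
    return CorrectedMID(
        metabolite=spectrum.metabolite, n_carbons=spectrum.n_carbons,
        fractions=x, fractional_enrichment=fractional_enrichment(x),
        sample_id=spectrum.sample_id, labeled_pool_size=pool)


def fractional_enrichment(fractions: np.ndarray) -> float:
    """Carbon-weighted mean labeled fraction: sum_i (i/n) * fraction_i."""
    fractions = np.asarray(fractions, dtype=float)
    n = fractions.size - 1
    if n == 0:
        return 0.0
    return float(np.dot(np.arange(n + 1) / n, fractions))


def panel_enrichment(enrichment: pd.DataFrame,
                     metabolite_set) -> tuple[pd.Series, list[str]]:
    """Mean fractional enrichment over a metabolite panel, per sample.

    ``enrichment`` is a samples x metabolites frame of fractional
    enrichments (NaN where undetected).  Returns the per-sample unweighted
    mean over the detected panel members and the member list used.
    """
    members = [m for m in metabolite_set if m in enrichment.columns]
    if not members:
        raise DataError("no panel member detected in the enrichment table")
    return enrichment[members].mean(axis=1, skipna=True), members


def normalize_abundance(spectrum: IsotopologueSpectrum) -> float:
    """Total intensity / internal standard [/ protein mg when present]."""
    if spectrum.internal_standard is None or spectrum.internal_standard <= 0:
        raise DataError(f"{spectrum.metabolite}: missing or non-positive "
                        "internal-standard intensity")
    out = float(spectrum.intensities.sum() / spectrum.internal_standard)
    if spectrum.protein is not None:
        if spectrum.protein <= 0:
            raise DataError(f"{spectrum.metabolite}: non-positive protein mass")
        out /= spectrum.protein
    return out


def labeled_species_compare(mids: list[CorrectedMID], groups: list[str],
                            species: int, *, use: str = "fraction") -> dict:
    """Two-tailed unpaired t-test on a chosen isotopologue between two groups.

    ``species`` is k of m+k.  ``use="fraction"`` compares the corrected m+k
    fraction; ``use="pool"`` the labeled pool size.  The m+3 lactate contrast
    (fully labeled lactate from U-13C glucose) is the motivating case.
    """
    if len(mids) != len(groups):
        raise DataError("mids and groups must align")
    n_carbons = mids[0].n_carbons
    if not (0 <= species <= n_carbons):
        raise DataError(f"species m+{species} out of range for "
                        f"{n_carbons}-carbon metabolite")
    if use == "fraction":
        values = np.array([m.fractions[species] for m in mids])
    elif use == "pool":
        values = np.array([m.labeled_pool_size for m in mids], dtype=float)
    else:
        raise ValueError(f"unknown use={use!r}")
    groups = np.asarray(groups, dtype=object)
    levels = list(pd.unique(groups))  # first-appearance order
    if len(levels) != 2:
        raise DataError("labeled_species_compare requires exactly two groups")
    x = values[groups == levels[0]]
    y = values[groups == levels[1]]
    if x.size < 2 or y.size < 2:
        raise DataError("need >=2 samples per group")
    if np.ptp(np.concatenate([x, y])) == 0.0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = scipy.stats.ttest_ind(x, y)
    return {"levels": levels, "species": f"m+{species}",
            "mean_a": float(x.mean()), "mean_b": float(y.mean()),
            "difference": float(y.mean() - x.mean()),
            "t": float(t_stat), "p": float(p)}


# ---------------------------------------------------------------------------
# I/O: delimited text, one row per (sample, metabolite)
# ---------------------------------------------------------------------------

def read_isotopologue_table(path) -> list[IsotopologueSpectrum]:
    """Read spectra from CSV with columns
    ``sample_id, metabolite, n_carbons, m0..mN[, standard, protein]``;
    m-columns beyond a metabolite's carbon count are left blank.
    """
    df = pd.read_csv(path)
    spectra = []
    for _, row in df.iterrows():
        n = int(row["n_carbons"])
        intens = [row[f"m{i}"] for i in range(n + 1)]
        spectra.append(IsotopologueSpectrum(
            metabolite=str(row["metabolite"]), n_carbons=n,
            intensities=np.asarray(intens, dtype=float),
            sample_id=str(row["sample_id"]),
            internal_standard=float(row["standard"]) if "standard" in df.columns
            and pd.notna(row["standard"]) else None,
            protein=float(row["protein"]) if "protein" in df.columns
            and pd.notna(row["protein"]) else None,
        ))
    return spectra


def write_isotopologue_table(spectra: list[IsotopologueSpectrum], path) -> pd.DataFrame:
    """Write spectra to the same delimited layout; returns the DataFrame."""
    n_max = max(s.n_carbons for s in spectra)
    rows = []
    for s in spectra:
        row = {"sample_id": s.sample_id, "metabolite": s.metabolite,
               "n_carbons": s.n_carbons}
        for i in range(n_max + 1):
            row[f"m{i}"] = s.intensities[i] if i <= s.n_carbons else np.nan
        row["standard"] = s.internal_standard
        row["protein"] = s.protein
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
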