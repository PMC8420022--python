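"""Plasma-metabolome statistics.

The workflow: keep metabolites measurable in more than 75% of participants,
impute the remaining missing values (random-forest-style iterative
imputation by default), log-transform, test each metabolite for group and/or
timepoint effects with Benjamini-Hochberg FDR control (volcano output), and
score metabolite sets by hypergeometric over-representation of the
significant hits against the measured background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer, KNNImputer
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError, DegenerateInputError

__all__ = [
    "MetaboliteTable",
    "EnrichmentResult",
    "presence_filter",
    "impute_missing",
    "differential_test",
    "set_enrichment",
]


@dataclass
class MetaboliteTable:
    """Samples x metabolites abundances with per-sample metadata.

    ``data`` holds normalized abundances (NaN = not measurable); ``meta`` is
    indexed like ``data`` with at least ``subject`` and ``group`` columns and
    optionally ``timepoint`` ("pre"/"post").  ``provenance`` records the
    processing steps applied.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.meta.index):
            raise DataError("data and meta must share the sample index")
        if (self.data < 0).any().any():
            raise DataError("negative abundances")
        if "timepoint" in self.meta.columns:
            key = self.meta[["subject", "timepoint"]].apply(tuple, axis=1)
            if key.duplicated().any():
                raise DataError("duplicate subject x timepoint samples")


@dataclass
class EnrichmentResult:
    """Over-representation of one metabolite set among the hits."""

    set_name: str
    overlap: int
    set_size: int          # measured members
    background_size: int
    p: float
    q: float = float("nan")


def presence_filter(table: MetaboliteTable,
                    min_frac: float = 0.75) -> MetaboliteTable:
    """Keep metabolites measurable in strictly more than ``min_frac`` of samples.

    The boundary is exclusive: a metabolite present in exactly 75% of
    participants is dropped.  An empty result warns rather than raises.
    """
    if not (0.0 < min_frac <= 1.0):
        raise DataError("min_frac must be in (0, 1]")
    present = table.data.notna().mean(axis=0)
    keep = present > min_frac
    if not keep.any():
        warnings.warn("presence filter removed every metabolite", stacklevel=2)
    return replace(table, data=table.data.loc[:, keep],
                   provenance=table.provenance + [f"presence_filter>{min_frac}"])


def impute_missing(table: MetaboliteTable, method: str = "rf",
                   seed: int = 0, *, n_neighbors: int = 5,
                   max_iter: int = 10) -> MetaboliteTable:
    """Fill missing abundances; observed cells are returned bit-identical.

    ``rf``       iterative chained prediction with extremely-randomized trees
                 (the random-forest-style imputation, seeded, capped at
                 ``max_iter`` rounds);
    ``knn``      k-nearest-neighbour imputation;
    ``half-min`` half of each metabolite's observed minimum.
    """
    x = table.data
    if x.isna().all(axis=0).any():
        bad = x.columns[x.isna().all(axis=0)].tolist()
        raise DataError(f"fully missing metabolites (filter first): {bad}")
    if not x.isna().any().any():
        return replace(table, provenance=table.provenance + [f"impute:{method}:noop"])
    if method == "half-min":
        filled = x.fillna(x.min(axis=0) / 2.0)
    elif method == "knn":
        filled = pd.DataFrame(KNNImputer(n_neighbors=n_neighbors).fit_transform(x),
                              index=x.index, columns=x.columns)
    elif method == "rf":
        est = ExtraTreesRegressor(n_estimators=30, random_state=seed, n_jobs=1)
        imp = IterativeImputer(estimator=est, max_iter=max_iter,
                               random_state=seed, sample_posterior=False,
                               keep_empty_features=False)
        filled = pd.DataFrame(imp.fit_transform(x),
                              index=x.index, columns=x.columns)
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    # imputation must never perturb observed values
    filled = filled.where(x.isna(), x)
    filled = filled.clip(lower=0.0)
    return replace(table, data=filled,
                   provenance=table.provenance + [f"impute:{method}"])


def _log_transform(x: pd.DataFrame) -> pd.DataFrame:
    """Natural log with a half-minimum offset applied only to zeros."""
    x = x.copy()
    for col in x.columns:
        col_min = x[col][x[col] > 0].min()
        offset = (col_min / 2.0) if np.isfinite(col_min) else 1.0
        x[col] = np.log(x[col].where(x[col] > 0, offset))
    return x


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def differential_test(table: MetaboliteTable, design: str = "group",
                      *, timepoint: str | None = None,
                      log_transform: bool = True,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-metabolite tests with BH-FDR; returns a volcano table.

    designs
    -------
    ``group``         Welch t between the two groups (optionally restricted
                      to one ``timepoint``).
    ``paired_time``   paired t of post vs pre within subjects (all groups).
    ``group_by_time`` group contrast on the per-subject post - pre
                      differences (the group x time interaction).

    Output columns: ``effect`` (second-group minus first-group mean on the
    analysis scale, groups in order of first appearance),
    ``log2_fold_change`` (from raw means, same direction), ``p``, ``q``,
    ``significant`` (q < ``alpha``).
    """
    x = table.data
    if x.isna().any().any():
        raise DataError("missing values present; impute first")
    meta = table.meta
    work = _log_transform(x) if log_transform else x

    def two_group(values: pd.DataFrame, labels: pd.Series):
        levels = list(pd.unique(labels))  # first-appearance order
        if len(levels) != 2:
            raise DataError("design requires exactly two groups")
        a = values[labels == levels[0]]
        b = values[labels == levels[1]]
        if len(a) < 2 or len(b) < 2:
            raise DataError("need >=2 samples per group")
        t_stat, p = scipy.stats.ttest_ind(b, a, axis=0, equal_var=False)
        return b.mean(axis=0) - a.mean(axis=0), np.asarray(p)

    if design == "group":
        mask = np.ones(len(x), dtype=bool)
        if timepoint is not None:
            mask = (meta["timepoint"] == timepoint).to_numpy()
        glabels = meta.loc[mask, "group"]
        effect, p = two_group(work[mask], glabels)
        lv = list(pd.unique(glabels))
        raw_a = x[mask][(glabels == lv[0]).to_numpy()]
        raw_b = x[mask][(glabels == lv[1]).to_numpy()]
    elif design in ("paired_time", "group_by_time"):
        if "timepoint" not in meta.columns:
            raise DataError("design needs a timepoint column")
        pre = meta["timepoint"] == "pre"
        post = meta["timepoint"] == "post"
        pre_x = work[pre.to_numpy()].set_index(meta.loc[pre, "subject"])
        post_x = work[post.to_numpy()].set_index(meta.loc[post, "subject"])
        common = pre_x.index.intersection(post_x.index)
        if len(common) < 3:
            raise DataError("need >=3 paired subjects")
        diff = post_x.loc[common] - pre_x.loc[common]
        if design == "paired_time":
            t_stat, p = scipy.stats.ttest_1samp(diff, 0.0, axis=0)
            effect, p = diff.mean(axis=0), np.asarray(p)
            raw_a = x[pre.to_numpy()]
            raw_b = x[post.to_numpy()]
        else:
            subject_group = meta.loc[pre.to_numpy()].set_index("subject")["group"]
            effect, p = two_group(diff, subject_group.loc[common])
            raw_a = x[pre.to_numpy()]
            raw_b = x[post.to_numpy()]
    else:
        raise ValueError(f"unknown design {design!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        l2fc = np.log2(raw_b.mean(axis=0) / raw_a.mean(axis=0))
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance metabolites: no evidence
    q = bh_adjust(p)
    out = pd.DataFrame({
        "metabolite": x.columns,
        "effect": np.asarray(effect, dtype=float),
        "log2_fold_change": np.asarray(l2fc, dtype=float),
        "p": p, "q": q,
        "significant": q < alpha,
    }).set_index("metabolite")
    return out.sort_values("q")


def set_enrichment(hits, background, sets: dict,
                   min_set_overlap: int = 3,
                   alpha: float = 0.05) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation of metabolite sets.

    ``hits`` must be a subset of ``background`` (the measured metabolites).
    Sets with fewer than ``min_set_overlap`` measured members are excluded;
    p-values are BH-adjusted across the remaining sets.
    """
    hits = set(hits)
    background = set(background)
    stray = hits - background
    if stray:
        raise DataError(f"hits not in background: {sorted(stray)}")
    n_bg, n_hits = len(background), len(hits)
    results = []
    for name, members in sets.items():
        measured = set(members) & background
        if len(measured) < min_set_overlap:
            continue
        overlap = len(measured & hits)
        # P(X >= overlap), X ~ Hypergeom(N=n_bg, K=len(measured), n=n_hits)
        p = float(scipy.stats.hypergeom.sf(overlap - 1, n_bg,
                                           len(measured), n_hits))
        results.append(EnrichmentResult(
            set_name=name, overlap=overlap, set_size=len(measured),
            background_size=n_bg, p=min(p, 1.0)))
    if results:
        qs = bh_adjust([r.p for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
    return sorted(results, key=lambda r: r.p)
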