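"""Censored-concentration preprocessing.

Pipeline order for the stimulation analysis:

1. exclude metabolites below the detection limit in >= 80% of samples in
   *both* groups of the contrast (``detection_filter``);
2. replace remaining left-censored cells (``substitute_censored``) — by zero
   (default), by LOD/2, or by the conditional mean below the LOD from a
   reversed Kaplan-Meier fit;
3. subtract the unstimulated baseline cell-wise (``baseline_subtract``),
   keeping negative differences;
4. divide each subject's row by their white-blood-cell count
   (``wbc_normalize``), yielding ng released per 10^6 leukocytes.

Downstream tests are rank-based, so any substitution constant below every
uncensored value of a metabolite leaves single-matrix test results unchanged
— the mechanism behind the equivalence of the zero / half-LOD / KM schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .datatypes import CohortError, ConcentrationMatrix, NetReleaseMatrix, Panel, SampleMeta

logger = logging.getLogger(__name__)

SCHEMES = ("zero", "half_lod", "km")


@dataclass(frozen=True)
class SubstitutionScheme:
    """Named left-censoring substitution scheme: zero, half_lod or km."""

    kind: str = "zero"

    def __post_init__(self) -> None:
        if self.kind not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.kind!r}")


@dataclass(frozen=True)
class FilterReport:
    """Per-metabolite censoring fractions and keep/exclude decisions."""

    table: pd.DataFrame  # index metabolite; columns frac_a, frac_b, kept, reason
    threshold: float
    group_a: str
    group_b: str

    @property
    def kept_ids(self) -> list:
        return list(self.table.index[self.table["kept"]])

    @property
    def excluded_ids(self) -> list:
        return list(self.table.index[~self.table["kept"]])


def detection_filter(
    matrix: ConcentrationMatrix,
    groups: Sequence[str],
    threshold: float = 0.8,
) -> tuple:
    """Exclude metabolites censored in at least ``threshold`` of both groups.

    Parameters
    ----------
    matrix : ConcentrationMatrix
        The matrix the analysis will test (stimulated for the release
        analysis, baseline for the plasma analysis).
    groups : sequence of str
        Group label per row of ``matrix``; exactly two distinct labels.
    threshold : float
        Censoring fraction at which a metabolite is excluded ("at least 80%"
        means the 0.8 boundary itself excludes). In (0, 1].

    Returns
    -------
    (kept_ids, FilterReport)
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    labels = pd.Series(list(groups), index=matrix.values.index)
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    rows = {}
    for g in uniq:
        sel = (labels == g).to_numpy()
        if not sel.any():
            raise ValueError(f"group {g!r} is empty")
        cens = matrix.censored.loc[labels.index[sel]]
        vals = matrix.values.loc[labels.index[sel]]
        measured = vals.notna().sum(axis=0)
        if (measured == 0).any():
            missing = list(measured.index[measured == 0])
            raise ValueError(f"group {g!r}: no measurements for {missing}")
        rows[g] = cens.sum(axis=0) / measured
    frac_a, frac_b = rows[uniq[0]], rows[uniq[1]]
    excluded = (frac_a >= threshold) & (frac_b >= threshold)
    reason = np.where(
        excluded, f"censored fraction >= {threshold:g} in both groups", "kept"
    )
    table = pd.DataFrame(
        {"frac_a": frac_a, "frac_b": frac_b, "kept": ~excluded, "reason": reason}
    )
    table.index.name = "metabolite"
    report = FilterReport(table, threshold, uniq[0], uniq[1])
    return report.kept_ids, report


def km_left_censored(
    values: np.ndarray, censored: np.ndarray, lod: float
) -> tuple:
    """Reversed Kaplan-Meier estimate for left-censored concentrations.

    The sample is flipped (``y = -x``; censored cells become right-censored at
    ``-lod``), the standard product-limit estimator is applied, and the step
    distribution is flipped back. The probability mass the estimator leaves
    below the LOD is unlocated within [0, lod); it is placed at the interval
    midpoint ``lod / 2``, which makes the returned mean well defined and keeps
    every imputed value strictly below the LOD.

    Returns
    -------
    (distribution, mean) : (pandas.DataFrame, float)
        ``distribution`` has columns ``value`` and ``prob`` (atoms of the
        estimated distribution, including the below-LOD atom); ``mean`` is its
        expectation. With no censoring this reduces to the empirical
        distribution and the arithmetic mean.
    """
    x = np.asarray(values, dtype=float)
    cens = np.asarray(censored, dtype=bool)
    if x.shape != cens.shape or x.ndim != 1:
        raise ValueError("values and censored must be aligned 1-D arrays")
    ok = ~np.isnan(x) | cens
    x, cens = x[ok], cens[ok]
    if len(x) == 0 or not (~cens).any():
        raise ValueError("km_left_censored requires at least one uncensored value")
    y = np.where(cens, -lod, -x)
    kmf = KaplanMeierFitter()
    kmf.fit(y, event_observed=~cens)
    surv = kmf.survival_function_.iloc[:, 0]
    times = surv.index.to_numpy(dtype=float)
    s = surv.to_numpy(dtype=float)
    prev = np.concatenate([[1.0], s[:-1]])
    drops = prev - s  # probability mass at each flipped event time
    atoms = [(-t, d) for t, d in zip(times, drops) if d > 0]
    leftover = s[-1]
    if leftover > 1e-12:
        atoms.append((lod / 2.0, leftover))
    dist = pd.DataFrame(atoms, columns=["value", "prob"]).sort_values("value")
    dist = dist.reset_index(drop=True)
    mean = float((dist["value"] * dist["prob"]).sum())
    return dist, mean


def substitute_censored(
    matrix: ConcentrationMatrix, panel: Panel, scheme: SubstitutionScheme
) -> ConcentrationMatrix:
    """Replace censored cells per the scheme; uncensored cells are untouched.

    For ``km`` the replacement is the conditional mean below the LOD of the
    reversed product-limit distribution, computed per metabolite over the
    rows of ``matrix``; a metabolite with every measured cell censored falls
    back to zero (logged).
    """
    values = matrix.values.copy()
    for mid in matrix.metabolite_ids:
        mask = matrix.censored[mid].to_numpy(dtype=bool)
        if not mask.any():
            continue
        lod = panel[mid].lod
        if scheme.kind == "zero":
            sub = 0.0
        elif scheme.kind == "half_lod":
            sub = lod / 2.0
        else:  # km
            col = matrix.values[mid].to_numpy(dtype=float)
            measured = ~np.isnan(col) | mask
            if not (~mask & measured & ~np.isnan(col)).any():
                logger.warning(
                    "%s: all measured cells censored; km falls back to zero", mid
                )
                sub = 0.0
            else:
                dist, _ = km_left_censored(col[measured], mask[measured], lod)
                below = dist[dist["value"] < lod]
                if below["prob"].sum() > 0:
                    sub = float(
                        (below["value"] * below["prob"]).sum() / below["prob"].sum()
                    )
                else:  # no estimated mass below LOD; degenerate, use midpoint
                    sub = lod / 2.0
        col = values[mid].to_numpy(dtype=float)
        col[mask] = sub
        values[mid] = col
    return ConcentrationMatrix(matrix.condition, values, matrix.censored.copy())


def baseline_subtract(
    stimulated: ConcentrationMatrix, baseline: ConcentrationMatrix
) -> pd.DataFrame:
    """Cell-wise stimulated minus baseline; negative differences are kept.

    Censored cells must already be substituted. A cell missing in either
    matrix is missing (NaN) in the result.
    """
    if stimulated.subjects != baseline.subjects or (
        stimulated.metabolite_ids != baseline.metabolite_ids
    ):
        raise CohortError("stimulated and baseline matrices are not aligned")
    return stimulated.values - baseline.values


def wbc_normalize(
    differences: pd.DataFrame, samples: Sequence[SampleMeta], provenance: dict | None = None
) -> NetReleaseMatrix:
    """Divide each subject's row by their WBC count (10^6 cells/ml).

    The result is net release in ng per 10^6 leukocytes; a common positive
    rescaling of all rows leaves downstream rank tests unchanged, so this
    step only matters when leukocyte counts differ between groups (they do:
    asthmatics run higher).
    """
    wbc = pd.Series({s.subject_id: s.wbc for s in samples})
    missing = [sid for sid in differences.index if sid not in wbc.index]
    if missing:
        raise CohortError(f"no metadata for subject(s) {missing}")
    wbc = wbc.loc[differences.index]
    if (wbc <= 0).any():
        raise CohortError("wbc must be > 0 for all subjects")
    prov = dict(provenance or {})
    prov.update({"normalized_by": "wbc", "unit": "ng per 10^6 leukocytes"})
    return NetReleaseMatrix(differences.div(wbc, axis=0), prov)
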