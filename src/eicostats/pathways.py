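"""Pathway-level inference by functional class scoring (FCS).

Metabolite-level permutation p-values are combined within each biosynthesis
pathway with the Tippett combining function (the minimum member p-value) and
calibrated on the *same* joint permutation ensemble used for the metabolite
tests: for every permutation b the member-wise p-values are recomputed by
ranking each member's permuted statistic within the full ensemble ("double
ranking"), and their minimum forms the pathway null distribution. Because the
group labels — not the pathway memberships — are permuted, this is a
self-contained test (null: no member is associated with the grouping) that
preserves the inter-metabolite correlation structure by construction.

Auto-oxidation (AUTOX-only) metabolites are excluded from pathway scoring;
dual-annotated metabolites count in every pathway they carry (a primary-only
mode is available since printed pathway sizes cannot disambiguate this).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import Panel
from .permtest import PermutationEnsemble, stepdown_adjust, _le_counts

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwaySet:
    """One pathway and its kept (post-filter, non-AUTOX) member metabolites."""

    pathway: str
    members: tuple

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.pathway}: empty pathway set")


@dataclass(frozen=True)
class PathwayTestResult:
    """Tippett-combined permutation result for one pathway."""

    pathway: str
    contrast: str
    n_members: int
    tippett_statistic: float  # min member raw permutation p
    raw_p: float
    adj_p: float


def build_pathway_sets(
    panel: Panel, kept_ids: Sequence[str], dual_membership: bool = True
) -> list:
    """Group kept metabolites into per-pathway sets, excluding AUTOX.

    ``dual_membership=True`` (default) puts a dual-annotated metabolite (e.g.
    5-LOX/15-LOX) in every pathway it carries; ``False`` keeps only the first
    label in panel order. Pathways with no kept member are dropped with a log
    line.
    """
    kept = [mid for mid in kept_ids if mid in panel]
    sets: dict = {}
    for mid in kept:
        met = panel[mid]
        labels = sorted(met.pathways - {"AUTOX"})
        if not labels:
            continue  # pure auto-oxidation product: excluded from FCS
        if not dual_membership:
            labels = labels[:1]
        for label in labels:
            sets.setdefault(label, []).append(mid)
    out = []
    order = []
    for m in panel.metabolites:  # deterministic pathway order: first appearance
        for label in sorted(m.pathways - {"AUTOX"}):
            if label not in order:
                order.append(label)
    for label in order:
        if label in sets:
            out.append(PathwaySet(label, tuple(sets[label])))
        else:
            logger.info("pathway %s has no kept members; dropped", label)
    return out


def tippett_statistic(p_values: Sequence[float]) -> float:
    """Tippett combining function: the minimum of the member p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("tippett_statistic requires at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(p.min())


def _member_indices(pset: PathwaySet, ensemble: PermutationEnsemble) -> np.ndarray:
    idx = []
    for mid in pset.members:
        if mid not in ensemble.metabolite_ids:
            raise ValueError(f"{pset.pathway}: member {mid!r} missing from ensemble")
        idx.append(ensemble.metabolite_ids.index(mid))
    return np.asarray(idx, dtype=int)


def pathway_min_counts(
    sets: Sequence[PathwaySet], ensemble: PermutationEnsemble
) -> np.ndarray:
    """(K, n_pathways) integer matrix: per-permutation minimum member p-count.

    ``ensemble.counts[b, j]`` is (B+1) times the permutation p-value member j
    would get at permutation b; the column-wise minimum over a pathway's
    members is (B+1) times its Tippett statistic at permutation b.
    """
    if ensemble.counts is None:
        raise ValueError("ensemble has no statistics; run ensemble_statistics first")
    cols = [ensemble.counts[:, _member_indices(ps, ensemble)].min(axis=1) for ps in sets]
    return np.column_stack(cols)


def pathway_pvalue(
    pset: PathwaySet, ensemble: PermutationEnsemble, contrast_name: str = ""
) -> PathwayTestResult:
    """Permutation p-value for one pathway's Tippett statistic.

    ``p = (1 + #{b >= 1 : min_b <= min_obs}) / (B + 1)`` where ``min_b`` is
    the minimum member p-value recomputed under permutation b. For a
    singleton pathway this reduces exactly to the member's raw permutation
    p-value.
    """
    k = ensemble.assignments.shape[0]
    mins = pathway_min_counts([pset], ensemble)[:, 0]
    obs = mins[0]
    p = float(np.sum(mins <= obs) / k)  # row 0 counts itself: (1 + #{b>=1})/K
    return PathwayTestResult(
        pathway=pset.pathway,
        contrast=contrast_name,
        n_members=len(pset.members),
        tippett_statistic=float(obs / k),
        raw_p=p,
        adj_p=np.nan,
    )


def adjust_pathways(
    results: Sequence[PathwayTestResult],
    sets: Sequence[PathwaySet],
    ensemble: PermutationEnsemble,
    method: str = "minp",
) -> list:
    """Step-down adjustment across the pathway family (same machinery as the
    metabolite stage, driven by the pathway-level min statistics)."""
    if not results:
        raise ValueError("no pathway results to adjust")
    raw = np.array([r.raw_p for r in results])
    if method == "minp":
        mins = pathway_min_counts(sets, ensemble)
        counts = _le_counts(mins)  # smaller min = more extreme
        adj = stepdown_adjust(raw, counts=counts, method="minp")
    else:
        adj = stepdown_adjust(raw, method=method)
    return [
        PathwayTestResult(
            r.pathway, r.contrast, r.n_members, r.tippett_statistic, r.raw_p, float(a)
        )
        for r, a in zip(results, adj)
    ]
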