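"""Per-metabolite two-group permutation inference.

The test statistic is the Wilcoxon rank-sum of group A (midranks over the
pooled sample); two-sided evidence is the centred absolute statistic
``|W - n_A (n + 1) / 2|``. p-values come from a joint permutation ensemble:
one set of B random relabellings (plus the identity, permutation 0) shared by
every metabolite, which preserves inter-metabolite correlation under the null
and feeds both the Westfall-Young step-down minP adjustment and the pathway
scoring. For small samples (total n <= ``exhaustive_max_n``) the ensemble
enumerates all C(n, n_A) assignments and p-values are exact.

p-value convention: ``p = (1 + #{b >= 1 : |T_b - E_b| >= |T_obs - E|}) / (B + 1)``,
which is a valid test (p >= 1/(B+1)); ties with the observed statistic count
as at least as extreme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

ADJUST_METHODS = ("minp", "bh")


@dataclass(frozen=True)
class Selector:
    """Predicate over sample metadata: group label and optional OCS status."""

    group: str
    ocs: bool | None = None

    def matches(self, sample) -> bool:
        if sample.group != self.group:
            return False
        return self.ocs is None or sample.ocs == self.ocs


@dataclass(frozen=True)
class Contrast:
    """A named two-group comparison (A vs B) over the cohort metadata."""

    name: str
    a: Selector
    b: Selector

    def split(self, samples: Sequence) -> tuple:
        """Return (subject ids in A, subject ids in B); checks disjointness."""
        a_ids = [s.subject_id for s in samples if self.a.matches(s)]
        b_ids = [s.subject_id for s in samples if self.b.matches(s)]
        if set(a_ids) & set(b_ids):
            raise ValueError(f"{self.name}: selectors overlap")
        if not a_ids or not b_ids:
            raise ValueError(f"{self.name}: a contrast group is empty")
        return a_ids, b_ids


#: The pairwise comparisons reported for this design: the three severity
#: contrasts plus the OCS stratification of the severe group.
DEFAULT_CONTRASTS = (
    Contrast("ctrl_vs_moderate", Selector("control"), Selector("moderate")),
    Contrast("ctrl_vs_severe", Selector("control"), Selector("severe")),
    Contrast("moderate_vs_severe", Selector("moderate"), Selector("severe")),
    Contrast("ctrl_vs_severe_no_ocs", Selector("control"), Selector("severe", ocs=False)),
    Contrast("ctrl_vs_severe_ocs", Selector("control"), Selector("severe", ocs=True)),
)


@dataclass
class PermutationEnsemble:
    """Shared group-label relabellings plus per-metabolite permuted statistics.

    ``assignments`` is a (B+1, n) boolean matrix (True = assigned to group A);
    row 0 is the observed labelling. In exhaustive mode the rows are all
    C(n, n_A) distinct assignments, reordered so the identity is row 0.
    ``extremity``/``counts`` are filled by :func:`ensemble_statistics`:
    ``counts[b, j] = #{b' : extremity[b', j] >= extremity[b, j]}``, so
    ``counts[0, j] / (B + 1)`` is metabolite j's raw permutation p-value.
    """

    assignments: np.ndarray
    seed: int | None
    exhaustive: bool
    metabolite_ids: list = field(default_factory=list)
    extremity: np.ndarray | None = None
    counts: np.ndarray | None = None

    @property
    def n_perm(self) -> int:
        """B: number of permutations beyond the identity."""
        return self.assignments.shape[0] - 1


def build_ensemble(
    labels: Sequence[bool],
    b: int,
    seed=None,
    exhaustive_max_n: int = 12,
) -> PermutationEnsemble:
    """Build the joint permutation ensemble for a two-group labelling.

    ``labels`` is the observed A-membership per subject. Random mode samples
    ``b`` assignments uniformly (with replacement over the assignment space —
    collisions are negligible at realistic n) and prepends the identity.
    Exhaustive mode (total n <= ``exhaustive_max_n``) enumerates every
    assignment exactly once.
    """
    obs = np.asarray(labels, dtype=bool)
    n = obs.size
    n_a = int(obs.sum())
    if n_a == 0 or n_a == n:
        raise ValueError("both groups must be non-empty")
    if b < 1:
        raise ValueError("b must be >= 1")
    if n <= exhaustive_max_n:
        rows = np.zeros((comb(n, n_a), n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n_a)):
            rows[i, list(idx)] = True
        identity = int(np.flatnonzero((rows == obs).all(axis=1))[0])
        rows[[0, identity]] = rows[[identity, 0]]
        return PermutationEnsemble(rows, seed, True)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(obs, (b, 1)), axis=1)
    return PermutationEnsemble(np.vstack([obs[None, :], perms]), seed, False)


def rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Wilcoxon rank-sum W of group ``x``: sum of its midranks in the pooled
    sample. Two-sided evidence is ``|W - n_x (n + 1) / 2|``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[: x.size].sum())


def _extremity_matrix(
    values: np.ndarray, assignments: np.ndarray
) -> np.ndarray:
    """Centred absolute rank-sum per (permutation, metabolite).

    ``values``: (n, m) float with NaN = missing; ``assignments``: (K, n) bool.
    Missing cells drop the subject for that metabolite only: the permuted
    label vector is re-subset to subjects with data, so per-permutation group
    sizes (and the null centring E_b) follow the available labels.
    """
    k, n = assignments.shape
    m = values.shape[1]
    out = np.empty((k, m), dtype=float)
    a_f = assignments.astype(float)
    complete = ~np.isnan(values).any(axis=0)
    if complete.any():
        ranks = np.apply_along_axis(rankdata, 0, values[:, complete])
        w = a_f @ ranks
        n_a = a_f.sum(axis=1, keepdims=True)
        e = n_a * (n + 1) / 2.0
        out[:, complete.nonzero()[0]] = np.abs(w - e)
    for j in np.flatnonzero(~complete):
        ok = ~np.isnan(values[:, j])
        n_j = int(ok.sum())
        if n_j == 0:
            out[:, j] = 0.0
            continue
        ranks_j = rankdata(values[ok, j])
        a_sub = a_f[:, ok]
        w = a_sub @ ranks_j
        e = a_sub.sum(axis=1) * (n_j + 1) / 2.0
        out[:, j] = np.abs(w - e)
    return out


def _ge_counts(stats: np.ndarray) -> np.ndarray:
    """counts[b, j] = #{b' : stats[b', j] >= stats[b, j]} (integer)."""
    k, m = stats.shape
    out = np.empty((k, m), dtype=np.int64)
    for j in range(m):
        col = stats[:, j]
        srt = np.sort(col)
        out[:, j] = k - np.searchsorted(srt, col, side="left")
    return out


def _le_counts(stats: np.ndarray) -> np.ndarray:
    """counts[b, j] = #{b' : stats[b', j] <= stats[b, j]} (integer)."""
    k, m = stats.shape
    out = np.empty((k, m), dtype=np.int64)
    for j in range(m):
        col = stats[:, j]
        srt = np.sort(col)
        out[:, j] = np.searchsorted(srt, col, side="right")
    return out


def ensemble_statistics(
    ensemble: PermutationEnsemble, values: pd.DataFrame
) -> PermutationEnsemble:
    """Fill the ensemble with per-metabolite permuted statistics and counts."""
    stats = _extremity_matrix(values.to_numpy(dtype=float), ensemble.assignments)
    ensemble.metabolite_ids = list(values.columns)
    ensemble.extremity = stats
    ensemble.counts = _ge_counts(stats)
    return ensemble


def perm_pvalue(observed: float, permuted: Sequence[float]) -> float:
    """p = (1 + #{b >= 1 : permuted_b >= observed}) / (B + 1).

    ``permuted`` holds the B permutation extremities (identity excluded);
    ties count as at least as extreme (conservative).
    """
    permuted = np.asarray(permuted, dtype=float)
    b = permuted.size
    return float((1 + np.sum(permuted >= observed)) / (b + 1))


def stepdown_minp_counts(counts: np.ndarray) -> np.ndarray:
    """Westfall-Young step-down minP adjustment from an integer count matrix.

    ``counts[b, j] / K`` is the permutation p-value hypothesis j would get if
    permutation b's statistic were observed (row 0 = the actual raw p-values).
    Hypotheses are processed from most to least significant; each adjusted p
    is the permutation probability that the minimum p over the remaining
    hypotheses falls at or below the observed one, with monotonicity
    enforced. Comparisons are on integer counts, so ties are exact.
    """
    k, m = counts.shape
    raw = counts[0]
    order = np.argsort(raw, kind="stable")
    ordered = counts[:, order]
    tail_min = np.minimum.accumulate(ordered[:, ::-1], axis=1)[:, ::-1]
    exceed = (tail_min[1:] <= raw[order][None, :]).sum(axis=0)
    adj_ordered = (1 + exceed) / k
    adj_ordered = np.maximum.accumulate(adj_ordered)
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = adj_ordered
    return adjusted


def stepdown_adjust(
    raw_p: Sequence[float],
    counts: np.ndarray | None = None,
    method: str = "minp",
) -> np.ndarray:
    """Adjust raw permutation p-values across the metabolite family.

    method="minp" (default): resampling-based step-down minP on the joint
    permutation ensemble's count matrix (required). method="bh":
    Benjamini-Hochberg step-up, the standard marginal cross-check.
    Both return adjusted p in [raw p, 1].
    """
    raw_p = np.asarray(raw_p, dtype=float)
    if method == "bh":
        adj = multipletests(raw_p, method="fdr_bh")[1]
    elif method == "minp":
        if counts is None:
            raise ValueError("minp adjustment needs the ensemble count matrix")
        if counts.shape[1] != raw_p.size:
            raise ValueError("counts and raw p-values have mismatched dimensions")
        adj = stepdown_minp_counts(counts)
    else:
        raise ValueError(f"method must be one of {ADJUST_METHODS}")
    return np.minimum(1.0, np.maximum(adj, raw_p))


@dataclass(frozen=True)
class MetaboliteTestResult:
    """Permutation Wilcoxon result for one metabolite under one contrast."""

    metabolite: str
    contrast: str
    n_a: int
    n_b: int
    statistic: float  # rank-sum W of group A over the pooled midranks
    raw_p: float
    adj_p: float
    direction: int  # sign of median(A) - median(B)


def run_contrast(
    net_values: pd.DataFrame,
    labels: Sequence[bool],
    contrast_name: str,
    b: int = 10_000,
    seed=None,
    method: str = "minp",
    exhaustive_max_n: int = 12,
) -> tuple:
    """Test every metabolite of ``net_values`` (rows = subjects) for a
    two-group difference, sharing one permutation ensemble.

    Returns ``(results, ensemble)`` where ``results`` is a list of
    :class:`MetaboliteTestResult` and the filled ensemble feeds the pathway
    scoring. Subjects missing a metabolite are dropped pairwise for that
    metabolite (effective n recorded per result).
    """
    obs = np.asarray(labels, dtype=bool)
    if obs.sum() < 2 or (~obs).sum() < 2:
        raise ValueError(f"{contrast_name}: fewer than 2 subjects in a group")
    # canonical subject order: results do not depend on input row order
    order = net_values.index.argsort(kind="stable")
    net_values = net_values.iloc[order]
    obs = obs[order]
    ensemble = build_ensemble(obs, b, seed=seed, exhaustive_max_n=exhaustive_max_n)
    ensemble_statistics(ensemble, net_values)
    k = ensemble.assignments.shape[0]
    raw_p = ensemble.counts[0] / k
    adj_p = stepdown_adjust(raw_p, counts=ensemble.counts, method=method)
    vals = net_values.to_numpy(dtype=float)
    results = []
    for j, mid in enumerate(net_values.columns):
        ok = ~np.isnan(vals[:, j])
        xa = vals[ok & obs, j]
        xb = vals[ok & ~obs, j]
        w = rank_sum(xa, xb) if xa.size and xb.size else np.nan
        med_diff = np.median(xa) - np.median(xb) if xa.size and xb.size else 0.0
        results.append(
            MetaboliteTestResult(
                metabolite=mid,
                contrast=contrast_name,
                n_a=int(xa.size),
                n_b=int(xb.size),
                statistic=w,
                raw_p=float(raw_p[j]),
                adj_p=float(adj_p[j]),
                direction=int(np.sign(med_diff)),
            )
        )
    return results, ensemble
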