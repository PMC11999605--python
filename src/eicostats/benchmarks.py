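"""Simulation studies validating the statistical machinery.

These are the package's operating-characteristic checks, run on synthetic
cohorts from :mod:`eicostats.simulate`:

* :func:`calibration_study` — type-I error of the per-metabolite permutation
  test under a global null;
* :func:`fdp_study` — false-discovery proportion of the step-down minP and
  BH adjustments with a subset of truly shifted metabolites;
* :func:`pathway_selectivity_study` — how often a planted single-pathway
  effect makes that pathway the top-ranked one.

Problem sizes default to desk-scale settings that finish in minutes on one
core; all randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .datatypes import Metabolite, Panel
from .pathways import adjust_pathways, build_pathway_sets, pathway_pvalue
from .permtest import run_contrast
from .preprocess import (
    SubstitutionScheme,
    baseline_subtract,
    substitute_censored,
    wbc_normalize,
)
from .simulate import EffectSpec, SimConfig, generate_cohort


def _flat_panel(n_metabolites: int, lod: float = 1e-9, pathway: str = "COX") -> Panel:
    return Panel(
        tuple(
            Metabolite(f"m{j + 1}", frozenset({pathway}), lod)
            for j in range(n_metabolites)
        )
    )


def _two_group_config(
    panel: Panel, n_per_group: int, seed: int, effects=()
) -> SimConfig:
    ids = panel.ids
    return SimConfig(
        panel=panel,
        n_control=n_per_group,
        n_moderate=n_per_group,
        n_severe=0,
        n_severe_ocs=0,
        baseline_log_median={m: 0.0 for m in ids},
        baseline_log_sd={m: 0.5 for m in ids},
        release_log_median={m: 1.0 for m in ids},
        release_log_sd={m: 1.0 for m in ids},
        wbc={"control": (6.02, 1.46), "moderate": (7.87, 2.61), "severe": (7.87, 2.61)},
        wbc_ref=6.0,
        effects=effects,
        seed=seed,
    )


def net_release_values(ds, scheme: str = "zero"):
    """Full preprocessing to the tested matrix (no detection filter)."""
    sub = SubstitutionScheme(scheme)
    stim = substitute_censored(ds.stimulated, ds.panel, sub)
    base = substitute_censored(ds.baseline, ds.panel, sub)
    return wbc_normalize(baseline_subtract(stim, base), ds.samples).values


def calibration_study(
    n_cohorts: int = 1000,
    n_per_group: int = 20,
    n_metabolites: int = 10,
    b: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Per-metabolite rejection rate of the raw permutation p at ``alpha``
    under the global null (all fold-changes 1). Returns the pooled rate over
    ``n_cohorts * n_metabolites`` tests and the per-test count."""
    panel = _flat_panel(n_metabolites)
    ss = np.random.SeedSequence(seed)
    hits = total = 0
    for rep, child in enumerate(ss.spawn(n_cohorts)):
        s1, s2 = (int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(2))
        ds = generate_cohort(_two_group_config(panel, n_per_group, seed=s1))
        values = net_release_values(ds)
        labels = [s.group == "control" for s in ds.samples]
        results, _ = run_contrast(
            values, labels, "null", b=b, seed=s2, exhaustive_max_n=0
        )
        hits += sum(r.raw_p <= alpha for r in results)
        total += len(results)
    return {"rejection_rate": hits / total, "n_tests": total, "alpha": alpha}


def fdp_study(
    n_replicates: int = 200,
    n_per_group: int = 30,
    n_null: int = 15,
    n_effect: int = 5,
    fold: float = 3.0,
    b: int = 1000,
    q: float = 0.05,
    seed: int = 0,
) -> dict:
    """Mean false-discovery proportion at level ``q`` for both adjustments.

    ``n_effect`` metabolites get a ``fold`` shift of the release median in
    one group; the rest are null. Returns mean FDP, its Monte-Carlo SE and
    mean power per method."""
    m = n_null + n_effect
    panel = _flat_panel(m)
    effect_ids = {f"m{j + 1}" for j in range(n_effect)}
    effects = tuple(EffectSpec(mid, "moderate", fold) for mid in sorted(effect_ids))
    ss = np.random.SeedSequence(seed + 1)
    fdp = {"minp": [], "bh": []}
    power = {"minp": [], "bh": []}
    for child in ss.spawn(n_replicates):
        s1, s2 = (int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(2))
        ds = generate_cohort(_two_group_config(panel, n_per_group, seed=s1, effects=effects))
        values = net_release_values(ds)
        labels = [s.group == "control" for s in ds.samples]
        for method in ("minp", "bh"):
            results, _ = run_contrast(
                values, labels, "fdr", b=b, seed=s2, method=method, exhaustive_max_n=0
            )
            rejected = [r.metabolite for r in results if r.adj_p <= q]
            false = [mid for mid in rejected if mid not in effect_ids]
            fdp[method].append(len(false) / max(1, len(rejected)))
            power[method].append(
                sum(mid in effect_ids for mid in rejected) / n_effect
            )
    out = {"q": q, "n_replicates": n_replicates}
    for method in ("minp", "bh"):
        arr = np.asarray(fdp[method])
        out[f"fdp_{method}"] = float(arr.mean())
        out[f"fdp_{method}_se"] = float(arr.std(ddof=1) / np.sqrt(len(arr)))
        out[f"power_{method}"] = float(np.mean(power[method]))
    return out


def pathway_selectivity_study(
    n_replicates: int = 100,
    n_per_group: int = 30,
    members_per_pathway: int = 5,
    fold: float = 4.0,
    b: int = 999,
    seed: int = 0,
) -> dict:
    """Fraction of replicates where a planted single-pathway effect gives
    that pathway the (strictly) smallest adjusted p among four pathways."""
    pathways = ("COX", "5-LOX", "15-LOX", "CYP")
    mets = []
    for pw in pathways:
        for i in range(members_per_pathway):
            mets.append(Metabolite(f"{pw}_{i + 1}", frozenset({pw}), 1e-9))
    panel = Panel(tuple(mets))
    effects = tuple(
        EffectSpec(f"COX_{i + 1}", "moderate", fold) for i in range(members_per_pathway)
    )
    ss = np.random.SeedSequence(seed + 2)
    hits = 0
    for child in ss.spawn(n_replicates):
        s1, s2 = (int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(2))
        ds = generate_cohort(_two_group_config(panel, n_per_group, seed=s1, effects=effects))
        values = net_release_values(ds)
        labels = [s.group == "control" for s in ds.samples]
        _, ensemble = run_contrast(
            values, labels, "fcs", b=b, seed=s2, exhaustive_max_n=0
        )
        sets = build_pathway_sets(panel, panel.ids)
        raw = [pathway_pvalue(s, ensemble) for s in sets]
        adjusted = adjust_pathways(raw, sets, ensemble)
        by_pathway = {r.pathway: r.adj_p for r in adjusted}
        target = by_pathway.pop("COX")
        hits += all(target < p for p in by_pathway.values())
    return {"top1_rate": hits / n_replicates, "n_replicates": n_replicates}
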