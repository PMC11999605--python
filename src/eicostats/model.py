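"""Model/Results interface tying the pipeline together.

:class:`ReleaseModel` wraps a :class:`~eicostats.datatypes.CohortDataset` and
a set of two-group contrasts; :meth:`ReleaseModel.fit` runs, per contrast:

detection filter -> censoring substitution -> baseline subtraction -> WBC
normalisation -> joint-ensemble permutation Wilcoxon tests -> step-down
adjustment -> Tippett pathway scoring,

and returns a :class:`ReleaseResults` carrying the per-metabolite and
per-pathway tables, the filter reports and a reproducibility manifest.

``mode="plasma"`` analyses the unstimulated baseline concentrations directly
(no subtraction, no WBC normalisation) — the analysis behind the circulating-
eicosanoid comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .datatypes import CohortDataset, NetReleaseMatrix
from .io import metabolite_results_frame, pathway_results_frame, write_results
from .pathways import adjust_pathways, build_pathway_sets, pathway_pvalue
from .permtest import DEFAULT_CONTRASTS, Contrast, run_contrast
from .preprocess import (
    SubstitutionScheme,
    baseline_subtract,
    detection_filter,
    substitute_censored,
    wbc_normalize,
)

P_BANDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Asterisk band for an adjusted p-value (<=0.05/0.01/0.001/0.0001)."""
    for cut, mark in P_BANDS:
        if p <= cut:
            return mark
    return ""


class ReleaseModel:
    """Two-group permutation analysis of eicosanoid release.

    Parameters
    ----------
    dataset : CohortDataset
        Paired baseline/stimulated concentrations with metadata.
    contrasts : sequence of Contrast, optional
        Defaults to the five severity/OCS contrasts of the design.
    mode : {"release", "plasma"}
        "release": test baseline-corrected, WBC-normalised stimulated
        release. "plasma": test baseline plasma concentrations directly.
    """

    def __init__(
        self,
        dataset: CohortDataset,
        contrasts: Sequence[Contrast] = DEFAULT_CONTRASTS,
        mode: str = "release",
    ) -> None:
        if mode not in ("release", "plasma"):
            raise ValueError("mode must be 'release' or 'plasma'")
        self.dataset = dataset
        self.contrasts = tuple(contrasts)
        self.mode = mode

    def fit(
        self,
        b: int = 10_000,
        seed: int | None = None,
        censor: str = "zero",
        detect_threshold: float = 0.8,
        adjust: str = "minp",
        exhaustive_max_n: int = 12,
        dual_membership: bool = True,
    ) -> "ReleaseResults":
        scheme = SubstitutionScheme(censor)
        met_rows: list = []
        path_rows: list = []
        reports: dict = {}
        ss = np.random.SeedSequence(seed if seed is not None else 0)
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(self.contrasts))]
        for contrast, cseed in zip(self.contrasts, child_seeds):
            a_ids, b_ids = contrast.split(self.dataset.samples)
            sub = self.dataset.select_subjects(a_ids + b_ids)
            labels = [sid in set(a_ids) for sid in sub.subject_ids]
            groups = ["A" if flag else "B" for flag in labels]
            tested = sub.stimulated if self.mode == "release" else sub.baseline
            kept, report = detection_filter(tested, groups, detect_threshold)
            reports[contrast.name] = report
            if not kept:
                continue
            if self.mode == "release":
                stim = substitute_censored(sub.stimulated, sub.panel, scheme)
                base = substitute_censored(sub.baseline, sub.panel, scheme)
                diff = baseline_subtract(stim, base)
                net = wbc_normalize(diff, sub.samples, {"scheme": scheme.kind})
            else:
                base = substitute_censored(sub.baseline, sub.panel, scheme)
                net = NetReleaseMatrix(base.values, {"scheme": scheme.kind, "mode": "plasma"})
            values = net.values[kept]
            results, ensemble = run_contrast(
                values,
                labels,
                contrast.name,
                b=b,
                seed=cseed,
                method=adjust,
                exhaustive_max_n=exhaustive_max_n,
            )
            met_rows.extend(results)
            psets = build_pathway_sets(sub.panel, kept, dual_membership=dual_membership)
            if psets:
                praw = [pathway_pvalue(ps, ensemble, contrast.name) for ps in psets]
                path_rows.extend(adjust_pathways(praw, psets, ensemble, method=adjust))
        manifest = {
            "package": "eicostats",
            "version": _pkg_version,
            "mode": self.mode,
            "permutations": b,
            "seed": seed,
            "censor_scheme": scheme.kind,
            "detect_threshold": detect_threshold,
            "adjust_method": adjust,
            "adjust_family": "within-contrast",
            "contrasts": [c.name for c in self.contrasts],
            "n_subjects": len(self.dataset.samples),
            "n_metabolites": len(self.dataset.panel),
            "dual_membership": dual_membership,
        }
        return ReleaseResults(
            self,
            metabolite_results_frame(met_rows),
            pathway_results_frame(path_rows),
            reports,
            manifest,
        )


@dataclass
class ReleaseResults:
    """Fitted results: per-metabolite and per-pathway permutation tables."""

    model: ReleaseModel
    metabolites: pd.DataFrame
    pathways: pd.DataFrame
    filter_reports: dict
    manifest: dict

    def metabolite_table(self, contrast: str) -> pd.DataFrame:
        return self.metabolites[self.metabolites["contrast"] == contrast].reset_index(
            drop=True
        )

    def summary(self, alpha: float = 0.05) -> str:
        """Human-readable per-contrast tables with asterisk banding."""
        lines = [
            f"eicostats {self.manifest['mode']} analysis "
            f"(B={self.manifest['permutations']}, censor={self.manifest['censor_scheme']}, "
            f"adjust={self.manifest['adjust_method']})",
        ]
        for contrast in self.manifest["contrasts"]:
            sub = self.metabolite_table(contrast)
            lines.append("")
            lines.append(f"== {contrast} ==")
            if sub.empty:
                lines.append("  (no metabolites kept)")
                continue
            sub = sub.sort_values(["adj_p", "metabolite"], kind="stable")
            for r in sub.itertuples(index=False):
                mark = stars(r.adj_p)
                lines.append(
                    f"  {r.metabolite:<32s} raw_p={r.raw_p:.4f} adj_p={r.adj_p:.4f} "
                    f"dir={r.direction:+d} {mark}"
                )
            psub = self.pathways[self.pathways["contrast"] == contrast]
            if not psub.empty:
                lines.append("  -- pathways --")
                for r in psub.itertuples(index=False):
                    lines.append(
                        f"  {r.pathway:<8s} members={r.n_members:<3d} "
                        f"p={r.raw_p:.4f} adj_p={r.adj_p:.4f} {stars(r.adj_p)}"
                    )
        return "\n".join(lines)

    def save(self, out_dir) -> dict:
        """Write the result TSVs, filter reports and manifest to ``out_dir``."""
        written = write_results(self.metabolites, self.pathways, out_dir, self.manifest)
        from pathlib import Path

        out = Path(out_dir)
        for name, report in self.filter_reports.items():
            path = out / f"filter_{name}.tsv"
            report.table.to_csv(path, sep="\t")
            written[f"filter_{name}"] = str(path)
        return written
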