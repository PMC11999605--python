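"""Readers and writers for the tabular interchange formats.

Interchange is tidy CSV (RFC-4180, UTF-8, "." decimal):

* panel:          ``metabolite,pathway,lod`` — pathway may hold several
  "/"-separated labels (e.g. ``5-LOX/15-LOX``);
* sample metadata: ``subject_id,group,ocs,wbc``;
* concentrations (one file per condition, long format):
  ``subject_id,metabolite,concentration,censored``.

Outputs are TSV (one metabolite table per contrast, one pathway table) plus a
JSON run manifest recording seed, permutation count, substitution scheme and
adjustment method so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CohortDataset,
    CohortError,
    ConcentrationMatrix,
    Metabolite,
    Panel,
    PanelError,
    SampleMeta,
)

METABOLITE_COLUMNS = [
    "contrast",
    "metabolite",
    "n_a",
    "n_b",
    "statistic",
    "raw_p",
    "adj_p",
    "direction",
]
PATHWAY_COLUMNS = [
    "contrast",
    "pathway",
    "n_members",
    "tippett_statistic",
    "raw_p",
    "adj_p",
]


def _parse_pathways(cell: str) -> frozenset:
    labels = frozenset(p.strip() for p in str(cell).split("/") if p.strip())
    if not labels:
        raise PanelError(f"empty pathway cell: {cell!r}")
    return labels


def read_panel(path) -> Panel:
    """Read a panel definition CSV into a :class:`Panel` (row order kept)."""
    df = pd.read_csv(path, dtype={"metabolite": str, "pathway": str})
    required = {"metabolite", "pathway", "lod"}
    if df.empty:
        raise PanelError(f"{path}: empty panel file")
    if not required.issubset(df.columns):
        raise PanelError(f"{path}: expected columns {sorted(required)}")
    mets = []
    for row in df.itertuples(index=False):
        lod = pd.to_numeric(row.lod, errors="coerce")
        if pd.isna(lod):
            raise PanelError(f"{row.metabolite}: non-numeric lod {row.lod!r}")
        mets.append(Metabolite(row.metabolite, _parse_pathways(row.pathway), float(lod)))
    return Panel(tuple(mets))


def write_panel(panel: Panel, path) -> None:
    rows = [
        {"metabolite": m.id, "pathway": "/".join(sorted(m.pathways)), "lod": m.lod}
        for m in panel.metabolites
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_samples(path) -> tuple:
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    required = {"subject_id", "group", "ocs", "wbc"}
    if not required.issubset(df.columns):
        raise CohortError(f"{path}: expected columns {sorted(required)}")
    samples = []
    for row in df.itertuples(index=False):
        ocs = row.ocs if isinstance(row.ocs, (bool, np.bool_)) else str(row.ocs).lower() in (
            "true",
            "1",
            "yes",
        )
        samples.append(SampleMeta(row.subject_id, row.group, bool(ocs), float(row.wbc)))
    return tuple(samples)


def _long_to_matrix(
    df: pd.DataFrame, condition: str, subject_ids: Sequence[str], panel: Panel, source: str
) -> ConcentrationMatrix:
    unknown = set(df["metabolite"]) - set(panel.ids)
    if unknown:
        raise CohortError(f"{source}: metabolite(s) not in panel: {sorted(unknown)}")
    unknown_subj = set(df["subject_id"]) - set(subject_ids)
    if unknown_subj:
        raise CohortError(f"{source}: subject(s) not in metadata: {sorted(unknown_subj)}")
    cens_raw = df["censored"]
    cens = cens_raw.astype(str).str.lower().isin(("true", "1", "yes")) if cens_raw.dtype == object else cens_raw.astype(bool)
    values = (
        df.assign(censored=cens)
        .pivot(index="subject_id", columns="metabolite", values="concentration")
        .reindex(index=list(subject_ids), columns=panel.ids)
    )
    censored = (
        df.assign(censored=cens)
        .pivot(index="subject_id", columns="metabolite", values="censored")
        .reindex(index=list(subject_ids), columns=panel.ids)
        .astype(float)
        .fillna(0.0)  # absent rows are missing, never censored
        .astype(bool)
    )
    values.index.name = censored.index.name = "subject_id"
    return ConcentrationMatrix(condition, values.astype(float), censored)


def read_cohort(panel: Panel, meta_path, baseline_path, stimulated_path) -> CohortDataset:
    """Assemble a :class:`CohortDataset` from the three tidy CSVs.

    Subjects present in the metadata but without a concentration row for some
    metabolite get NaN (missing), which is distinct from a censored cell.
    """
    samples = read_samples(meta_path)
    sids = [s.subject_id for s in samples]
    frames = {}
    for cond, path in (("baseline", baseline_path), ("stimulated", stimulated_path)):
        df = pd.read_csv(path, dtype={"subject_id": str, "metabolite": str})
        required = {"subject_id", "metabolite", "concentration", "censored"}
        if not required.issubset(df.columns):
            raise CohortError(f"{path}: expected columns {sorted(required)}")
        frames[cond] = _long_to_matrix(df, cond, sids, panel, str(path))
    ds = CohortDataset(panel, samples, frames["baseline"], frames["stimulated"])
    ds.baseline.check_against(panel)
    ds.stimulated.check_against(panel)
    return ds


def _matrix_to_long(matrix: ConcentrationMatrix) -> pd.DataFrame:
    long = matrix.values.stack(future_stack=True).rename("concentration").reset_index()
    cens = matrix.censored.stack(future_stack=True).rename("censored").reset_index()
    out = long.merge(cens, on=["subject_id", "metabolite"])
    return out.dropna(subset=["concentration"])


def write_cohort(dataset: CohortDataset, out_dir) -> dict:
    """Write panel.csv, samples.csv, baseline.csv, stimulated.csv; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": out / "panel.csv",
        "samples": out / "samples.csv",
        "baseline": out / "baseline.csv",
        "stimulated": out / "stimulated.csv",
    }
    write_panel(dataset.panel, paths["panel"])
    dataset.meta_frame.reset_index().to_csv(paths["samples"], index=False)
    for cond in ("baseline", "stimulated"):
        _matrix_to_long(getattr(dataset, cond)).to_csv(paths[cond], index=False)
    return {k: str(v) for k, v in paths.items()}


def metabolite_results_frame(results: Iterable) -> pd.DataFrame:
    rows = [
        {
            "contrast": r.contrast,
            "metabolite": r.metabolite,
            "n_a": r.n_a,
            "n_b": r.n_b,
            "statistic": r.statistic,
            "raw_p": r.raw_p,
            "adj_p": r.adj_p,
            "direction": r.direction,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=METABOLITE_COLUMNS)


def pathway_results_frame(results: Iterable) -> pd.DataFrame:
    rows = [
        {
            "contrast": r.contrast,
            "pathway": r.pathway,
            "n_members": r.n_members,
            "tippett_statistic": r.tippett_statistic,
            "raw_p": r.raw_p,
            "adj_p": r.adj_p,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=PATHWAY_COLUMNS)


def write_results(
    metabolite_results: pd.DataFrame,
    pathway_results: pd.DataFrame,
    out_dir,
    manifest: dict,
) -> dict:
    """Write per-contrast metabolite TSVs, a pathway TSV and the run manifest.

    Column order is fixed and row order is (contrast, metabolite/pathway)
    sorted, so identical inputs yield byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    mr = metabolite_results.reindex(columns=METABOLITE_COLUMNS)
    contrasts = list(dict.fromkeys(mr["contrast"])) if len(mr) else []
    for name in contrasts:
        sub = mr[mr["contrast"] == name].sort_values(["metabolite"], kind="stable")
        path = out / f"metabolites_{name}.tsv"
        sub.to_csv(path, sep="\t", index=False)
        written[f"metabolites_{name}"] = str(path)
    if not contrasts:
        path = out / "metabolites.tsv"
        mr.to_csv(path, sep="\t", index=False)
        written["metabolites"] = str(path)
    pw = pathway_results.reindex(columns=PATHWAY_COLUMNS).sort_values(
        ["contrast", "pathway"], kind="stable"
    )
    path = out / "pathways.tsv"
    pw.to_csv(path, sep="\t", index=False)
    written["pathways"] = str(path)
    mpath = out / "manifest.json"
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["manifest"] = str(mpath)
    return written
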