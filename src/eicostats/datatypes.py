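"""Domain types for targeted eicosanoid panels and whole-blood stimulation cohorts.

The analysis operates on a paired design: for every subject an unstimulated
EDTA-plasma measurement (``baseline``) and a zymosan-stimulated whole-blood
supernatant measurement (``stimulated``) of the same metabolite panel.
Concentrations are in ng/ml; white-blood-cell counts in 10^6 cells/ml; net
release (stimulated minus baseline, divided by WBC) in ng per 10^6 leukocytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: The fixed pathway vocabulary. AUTOX (non-enzymatic auto-oxidation) is a
#: real label so its exclusion from pathway scoring is a downstream filter,
#: not a parse-time drop.
PATHWAYS = frozenset({"COX", "5-LOX", "12-LOX", "15-LOX", "CYP", "AUTOX"})

GROUPS = ("control", "moderate", "severe")

CONDITIONS = ("baseline", "stimulated")


class PanelError(ValueError):
    """Raised for malformed panel definitions."""


class CohortError(ValueError):
    """Raised for inconsistent cohort data."""


@dataclass(frozen=True)
class Metabolite:
    """One analyte of the targeted panel.

    Parameters
    ----------
    id : str
        Short metabolite name, e.g. ``"LTE4"`` or ``"15-HETE"``.
    pathways : frozenset of str
        Biosynthesis pathway assignment(s); dual assignments such as
        ``{"5-LOX", "15-LOX"}`` are permitted.
    lod : float
        Limit of detection in ng/ml, strictly positive.
    unit : str
        Fixed to ``"ng/ml"``.
    """

    id: str
    pathways: frozenset
    lod: float
    unit: str = "ng/ml"

    def __post_init__(self) -> None:
        if not self.id:
            raise PanelError("metabolite id must be non-empty")
        pw = frozenset(self.pathways)
        object.__setattr__(self, "pathways", pw)
        if not pw:
            raise PanelError(f"{self.id}: pathway set must be non-empty")
        unknown = pw - PATHWAYS
        if unknown:
            raise PanelError(f"{self.id}: unknown pathway label(s) {sorted(unknown)}")
        if not np.isfinite(self.lod) or self.lod <= 0:
            raise PanelError(f"{self.id}: lod must be a positive number, got {self.lod}")

    @property
    def is_autox(self) -> bool:
        """True if the metabolite is exclusively an auto-oxidation product."""
        return self.pathways == frozenset({"AUTOX"})


@dataclass(frozen=True)
class Panel:
    """Ordered collection of :class:`Metabolite` with unique ids."""

    metabolites: tuple

    def __post_init__(self) -> None:
        mets = tuple(self.metabolites)
        object.__setattr__(self, "metabolites", mets)
        if not mets:
            raise PanelError("panel is empty")
        ids = [m.id for m in mets]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PanelError(f"duplicate metabolite id(s): {sorted(dupes)}")
        if all(m.is_autox for m in mets):
            raise PanelError("panel contains only auto-oxidation metabolites")

    @property
    def ids(self) -> list:
        return [m.id for m in self.metabolites]

    def __len__(self) -> int:
        return len(self.metabolites)

    def __getitem__(self, metabolite_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == metabolite_id:
                return m
        raise KeyError(metabolite_id)

    def __contains__(self, metabolite_id: str) -> bool:
        return any(m.id == metabolite_id for m in self.metabolites)

    @property
    def lods(self) -> pd.Series:
        return pd.Series({m.id: m.lod for m in self.metabolites}, name="lod")


@dataclass(frozen=True)
class SampleMeta:
    """Per-subject metadata.

    ``ocs`` (permanent oral-corticosteroid use) is meaningful only within the
    severe group; mild-to-moderate patients are OCS-naive by design.
    """

    subject_id: str
    group: str
    ocs: bool
    wbc: float  # 10^6 cells/ml

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortError(
                f"{self.subject_id}: group must be one of {GROUPS}, got {self.group!r}"
            )
        if self.group == "moderate" and self.ocs:
            raise CohortError(f"{self.subject_id}: mild-to-moderate patients are OCS-naive")
        if not np.isfinite(self.wbc) or self.wbc <= 0:
            raise CohortError(f"{self.subject_id}: wbc must be > 0, got {self.wbc}")

    @property
    def stratum(self) -> str:
        """Group refined by OCS status within the severe group."""
        if self.group == "severe":
            return "severe_ocs" if self.ocs else "severe_no_ocs"
        return self.group


@dataclass(frozen=True)
class ConcentrationMatrix:
    """Samples x metabolites concentration matrix with a censoring mask.

    ``values`` is a DataFrame (rows = subject ids, columns = metabolite ids);
    NaN marks a *missing* (not measured) cell, which is distinct from a
    *censored* (measured below LOD) cell. Censored cells carry a sentinel
    concentration strictly below the metabolite's LOD (0 before substitution).
    """

    condition: str
    values: pd.DataFrame
    censored: pd.DataFrame

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise CohortError(f"condition must be one of {CONDITIONS}")
        if not self.values.index.equals(self.censored.index) or not self.values.columns.equals(
            self.censored.columns
        ):
            raise CohortError("values and censored mask are not aligned")
        v = self.values.to_numpy(dtype=float)
        if np.nanmin(v, initial=0.0) < 0:
            raise CohortError("negative concentrations are not allowed")
        if bool((self.censored.to_numpy(dtype=bool) & np.isnan(v)).any()):
            raise CohortError("a cell cannot be both censored and missing")

    @property
    def subjects(self) -> list:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list:
        return list(self.values.columns)

    def check_against(self, panel: Panel) -> None:
        """Verify censored sentinels sit below their metabolite's LOD."""
        for mid in self.metabolite_ids:
            if mid not in panel:
                raise CohortError(f"metabolite {mid!r} not in panel")
            mask = self.censored[mid].to_numpy(dtype=bool)
            if mask.any():
                vals = self.values[mid].to_numpy(dtype=float)[mask]
                if np.any(vals >= panel[mid].lod):
                    raise CohortError(
                        f"{mid}: censored cell at or above LOD {panel[mid].lod}"
                    )

    def select(self, subjects: Iterable[str]) -> "ConcentrationMatrix":
        idx = list(subjects)
        return ConcentrationMatrix(
            self.condition, self.values.loc[idx], self.censored.loc[idx]
        )


@dataclass(frozen=True)
class CohortDataset:
    """Panel + metadata + paired baseline/stimulated concentration matrices."""

    panel: Panel
    samples: tuple
    baseline: ConcentrationMatrix
    stimulated: ConcentrationMatrix

    def __post_init__(self) -> None:
        samples = tuple(self.samples)
        object.__setattr__(self, "samples", samples)
        sids = [s.subject_id for s in samples]
        if len(set(sids)) != len(sids):
            raise CohortError("duplicate subject ids in metadata")
        for mat, name in ((self.baseline, "baseline"), (self.stimulated, "stimulated")):
            if mat.subjects != sids:
                raise CohortError(f"{name} matrix subjects do not match metadata")
            if mat.metabolite_ids != self.panel.ids:
                raise CohortError(f"{name} matrix metabolites do not match panel")
        if self.baseline.condition != "baseline" or self.stimulated.condition != "stimulated":
            raise CohortError("matrix conditions are swapped")

    @property
    def subject_ids(self) -> list:
        return [s.subject_id for s in self.samples]

    @property
    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.samples],
                "group": [s.group for s in self.samples],
                "ocs": [s.ocs for s in self.samples],
                "wbc": [s.wbc for s in self.samples],
            }
        ).set_index("subject_id")

    def select_subjects(self, subject_ids: Iterable[str]) -> "CohortDataset":
        keep = set(subject_ids)
        samples = tuple(s for s in self.samples if s.subject_id in keep)
        sids = [s.subject_id for s in samples]
        return CohortDataset(
            self.panel,
            samples,
            self.baseline.select(sids),
            self.stimulated.select(sids),
        )


@dataclass(frozen=True)
class NetReleaseMatrix:
    """Baseline-corrected, WBC-normalised release values.

    Units: ng per 10^6 leukocytes. Values may be negative (stimulated below
    baseline); NaN marks missing cells. ``provenance`` records the censoring
    substitution scheme and normalisation applied.
    """

    values: pd.DataFrame
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if np.isinf(v).any():
            raise CohortError("net release contains non-finite (infinite) values")
        object.__setattr__(self, "provenance", dict(self.provenance))
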