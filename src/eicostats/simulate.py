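"""Synthetic whole-blood stimulation cohorts.

Generative model, chosen so that every preprocessing step downstream is the
*correct* correction under the model:

* baseline plasma concentration: per-metabolite log-normal (concentrations
  are positive and right-skewed — published SDs often exceed means);
* stimulated concentration = baseline + release, additive on the
  concentration scale, so baseline subtraction exactly removes the basal
  level at fold-change 1;
* release = log-normal draw x stratum fold-change x (WBC / wbc_ref):
  release is proportional to the leukocyte count, so dividing by WBC exactly
  removes the between-group leukocyte difference;
* WBC: truncated normal (> 0.5 x 10^6/ml) with group-specific mean/SD,
  matching mean +- SD reporting;
* censoring: any cell drawn below its metabolite's LOD is flagged censored
  and stored as 0 (the pre-substitution sentinel).

Effects are multiplicative shifts of a stratum's release median (1.0 = null);
within-subject correlation between baseline and stimulated values arises only
through the shared baseline term.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import log, sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from ._reference_panel import REFERENCE_PANEL
from .datatypes import (
    CohortDataset,
    ConcentrationMatrix,
    Metabolite,
    Panel,
    SampleMeta,
)

STRATA = ("control", "moderate", "severe", "severe_ocs", "severe_no_ocs")

#: Lower truncation of the WBC distribution, 10^6 cells/ml.
WBC_FLOOR = 0.5


@dataclass(frozen=True)
class EffectSpec:
    """Multiplicative fold-change on one stratum's stimulated-release median.

    ``stratum`` names the affected subjects (``severe`` covers both OCS
    strata); ``fold = 1.0`` is the null.
    """

    metabolite: str
    stratum: str
    fold: float

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}; one of {STRATA}")
        if not np.isfinite(self.fold) or self.fold <= 0:
            raise ValueError(f"{self.metabolite}: fold must be > 0, got {self.fold}")

    def applies_to(self, sample: SampleMeta) -> bool:
        return sample.stratum == self.stratum or (
            self.stratum == "severe" and sample.group == "severe"
        )


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic cohort.

    Per-metabolite log-medians/log-SDs are on the natural-log scale of ng/ml
    (baseline) and ng/ml at the reference WBC (release); ``wbc`` maps group
    to (mean, sd) in 10^6 cells/ml; ``wbc_ref`` is the leukocyte count at
    which the release log-median is stated.
    """

    panel: Panel
    n_control: int
    n_moderate: int
    n_severe: int
    n_severe_ocs: int
    baseline_log_median: Mapping
    baseline_log_sd: Mapping
    release_log_median: Mapping
    release_log_sd: Mapping
    wbc: Mapping  # group -> (mean, sd)
    wbc_ref: float = 6.0
    effects: tuple = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", tuple(self.effects))
        sizes = (self.n_control, self.n_moderate, self.n_severe)
        compared = [n for n in sizes if n > 0]
        if len(compared) < 2 or any(n < 2 for n in compared):
            raise ValueError("need >= 2 subjects in each of >= 2 groups")
        if not 0 <= self.n_severe_ocs <= self.n_severe:
            raise ValueError("n_severe_ocs must be within [0, n_severe]")
        ids = set(self.panel.ids)
        for name, mapping in (
            ("baseline_log_median", self.baseline_log_median),
            ("baseline_log_sd", self.baseline_log_sd),
            ("release_log_median", self.release_log_median),
            ("release_log_sd", self.release_log_sd),
        ):
            missing = ids - set(mapping)
            if missing:
                raise ValueError(f"{name} missing metabolites {sorted(missing)}")
            if name.endswith("sd") and any(mapping[m] < 0 for m in ids):
                raise ValueError(f"{name} must be >= 0")
        for eff in self.effects:
            if eff.metabolite not in ids:
                raise ValueError(f"effect references unknown metabolite {eff.metabolite!r}")

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "panel": [
                {"metabolite": m.id, "pathway": "/".join(sorted(m.pathways)), "lod": m.lod}
                for m in self.panel.metabolites
            ],
            "n_control": self.n_control,
            "n_moderate": self.n_moderate,
            "n_severe": self.n_severe,
            "n_severe_ocs": self.n_severe_ocs,
            "baseline_log_median": dict(self.baseline_log_median),
            "baseline_log_sd": dict(self.baseline_log_sd),
            "release_log_median": dict(self.release_log_median),
            "release_log_sd": dict(self.release_log_sd),
            "wbc": {g: list(v) for g, v in self.wbc.items()},
            "wbc_ref": self.wbc_ref,
            "effects": [asdict(e) for e in self.effects],
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        from .io import _parse_pathways

        panel = Panel(
            tuple(
                Metabolite(r["metabolite"], _parse_pathways(r["pathway"]), float(r["lod"]))
                for r in d["panel"]
            )
        )
        effects = tuple(EffectSpec(**e) for e in d.get("effects", []))
        return cls(
            panel=panel,
            n_control=int(d["n_control"]),
            n_moderate=int(d["n_moderate"]),
            n_severe=int(d["n_severe"]),
            n_severe_ocs=int(d["n_severe_ocs"]),
            baseline_log_median=dict(d["baseline_log_median"]),
            baseline_log_sd=dict(d["baseline_log_sd"]),
            release_log_median=dict(d["release_log_median"]),
            release_log_sd=dict(d["release_log_sd"]),
            wbc={g: tuple(v) for g, v in d["wbc"].items()},
            wbc_ref=float(d.get("wbc_ref", 6.0)),
            effects=effects,
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw) -> "SimConfig":
        d = {f: getattr(self, f) for f in (
            "panel", "n_control", "n_moderate", "n_severe", "n_severe_ocs",
            "baseline_log_median", "baseline_log_sd", "release_log_median",
            "release_log_sd", "wbc", "wbc_ref", "effects", "seed",
        )}
        d.update(kw)
        return SimConfig(**d)


def _truncnorm_draw(rng, mean, sd, size, floor=WBC_FLOOR):
    if sd == 0:
        return np.full(size, max(mean, floor))
    a = (floor - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: SimConfig, return_latent: bool = False):
    """Draw a :class:`CohortDataset` from the generative model.

    Reproducible: identical configs (including ``seed``) give bit-identical
    datasets. With ``return_latent=True`` also returns the pre-censoring
    baseline/stimulated draws (for diagnostics and calibration checks).
    """
    rng = np.random.default_rng(config.seed)
    samples = []
    wbc_groups = []
    for group, n in (
        ("control", config.n_control),
        ("moderate", config.n_moderate),
        ("severe", config.n_severe),
    ):
        if n == 0:
            continue
        mean, sd = config.wbc[group]
        wbc = _truncnorm_draw(rng, mean, sd, n)
        for i in range(n):
            ocs = group == "severe" and i < config.n_severe_ocs
            samples.append(
                SampleMeta(f"{group[:3]}-{i + 1:03d}", group, ocs, float(wbc[i]))
            )
        wbc_groups.append(wbc)
    samples = tuple(samples)
    n_sub = len(samples)
    mids = config.panel.ids
    m = len(mids)

    mu_b = np.array([config.baseline_log_median[j] for j in mids])
    sd_b = np.array([config.baseline_log_sd[j] for j in mids])
    mu_r = np.array([config.release_log_median[j] for j in mids])
    sd_r = np.array([config.release_log_sd[j] for j in mids])

    log_fold = np.zeros((n_sub, m))
    for eff in config.effects:
        j = mids.index(eff.metabolite)
        for i, s in enumerate(samples):
            if eff.applies_to(s):
                log_fold[i, j] += log(eff.fold)

    baseline = np.exp(mu_b[None, :] + sd_b[None, :] * rng.standard_normal((n_sub, m)))
    wbc_vec = np.array([s.wbc for s in samples])
    release = (
        np.exp(mu_r[None, :] + log_fold + sd_r[None, :] * rng.standard_normal((n_sub, m)))
        * (wbc_vec[:, None] / config.wbc_ref)
    )
    stimulated = baseline + release

    lods = np.array([config.panel[j].lod for j in mids])
    sids = [s.subject_id for s in samples]

    def censor(mat, condition):
        cens = mat < lods[None, :]
        stored = np.where(cens, 0.0, mat)
        return ConcentrationMatrix(
            condition,
            pd.DataFrame(stored, index=pd.Index(sids, name="subject_id"), columns=pd.Index(mids, name="metabolite")),
            pd.DataFrame(cens, index=pd.Index(sids, name="subject_id"), columns=pd.Index(mids, name="metabolite")),
        )

    ds = CohortDataset(config.panel, samples, censor(baseline, "baseline"), censor(stimulated, "stimulated"))
    if return_latent:
        return ds, {"baseline": baseline, "stimulated": stimulated, "release": release}
    return ds


def _lognormal_params(mean: float, sd: float) -> tuple:
    """Moment-match a log-normal to a reported mean +- SD: returns (mu, sigma)
    with mu the log-median."""
    sigma2 = log(1.0 + (sd / mean) ** 2) if sd > 0 else 0.0
    return log(mean) - sigma2 / 2.0, sqrt(sigma2)


#: Fold-changes mimicking the reported direction of each finding: LTE4 and
#: 15-HETE elevated with mild-to-moderate disease, LTE4 elevated in
#: OCS-naive severe disease, and COX-pathway release suppressed under
#: permanent OCS (mildly in OCS-naive severe disease for 12-HHT/11-HETE).
_REFERENCE_EFFECTS = (
    ("LTE4", "moderate", 3.0),
    ("LTE4", "severe_no_ocs", 2.5),
    ("15-HETE", "moderate", 2.0),
    ("PGE2", "severe_ocs", 0.35),
    ("PGA2", "severe_ocs", 0.35),
    ("11-HETE", "severe_ocs", 0.35),
    ("12-HHT", "severe_ocs", 0.35),
    ("TXB2", "severe_ocs", 0.35),
    ("PGF2a", "severe_ocs", 0.35),
    ("6-keto-PGF1a", "severe_ocs", 0.35),
    ("PGF1a", "severe_ocs", 0.35),
    ("11-HETE", "severe_no_ocs", 0.6),
    ("12-HHT", "severe_no_ocs", 0.6),
)

# Synthetic LODs / baseline scale for analytes not detected in plasma: the
# published table reports them as ND, i.e. essentially always below LOD.
_ND_LOD = 0.01
_ND_MEAN = 0.002
_ND_SD = 0.002
# Stimulated release median at the reference WBC, as a multiple of the
# baseline mean: zymosan stimulation releases well above basal plasma levels.
_RELEASE_SCALE = 5.0
_RELEASE_LOG_SD = 1.0

# Of the analytes undetectable in circulation, some are genuinely produced by
# stimulated leukocytes (notably the leukotriene cascade) and become
# detectable in the supernatant; the rest stay below LOD in both matrices.
# 41 plasma-detected + these 10 = 51 analytes detectable after stimulation.
_STIM_INDUCIBLE = frozenset(
    {
        "LTB4",
        "LTC4",
        "LTD4",
        "20-hydroxy-LTB4",
        "20-carboxy-LTB4",
        "12-oxoETE",
        "LXA4",
        "5,15-diHETE",
        "PGD2",
        "11-dhTXB2",
    }
)
_STIM_INDUCIBLE_RELEASE = 0.05  # ng/ml at the reference WBC: well above LOD
_STIM_SILENT_RELEASE = 0.0005  # stays below LOD essentially always


def reference_config(seed: int = 0) -> SimConfig:
    """The packaged study-scale configuration.

    63 healthy controls, 108 mild-to-moderate and 90 severe asthmatics (44 of
    whom use OCS permanently); WBC 6.02 +- 1.46 (controls) and 7.87 +- 2.61
    (asthma) x10^6/ml; the 67-analyte reference panel with plasma baseline
    scale moment-matched to the published control means, and planted effects
    in the reported directions.
    """
    mets, mu_b, sd_b, mu_r, sd_r = [], {}, {}, {}, {}
    from .io import _parse_pathways

    for name, pathway, ctrl_mean, ctrl_sd, _asth_mean, _asth_sd in REFERENCE_PANEL:
        detected = ctrl_mean is not None
        if detected:
            lod = min(ctrl_mean, _asth_mean) / 5.0
            mu, sigma = _lognormal_params(ctrl_mean, ctrl_sd)
        else:
            lod = _ND_LOD
            mu, sigma = _lognormal_params(_ND_MEAN, _ND_SD)
        mets.append(Metabolite(name, _parse_pathways(pathway), lod))
        mu_b[name] = mu
        sd_b[name] = sigma
        if detected:
            release = ctrl_mean * _RELEASE_SCALE
        elif name in _STIM_INDUCIBLE:
            release = _STIM_INDUCIBLE_RELEASE
        else:
            release = _STIM_SILENT_RELEASE
        mu_r[name] = log(release)
        sd_r[name] = _RELEASE_LOG_SD
    return SimConfig(
        panel=Panel(tuple(mets)),
        n_control=63,
        n_moderate=108,
        n_severe=90,
        n_severe_ocs=44,
        baseline_log_median=mu_b,
        baseline_log_sd=sd_b,
        release_log_median=mu_r,
        release_log_sd=sd_r,
        wbc={"control": (6.02, 1.46), "moderate": (7.87, 2.61), "severe": (7.87, 2.61)},
        wbc_ref=6.0,
        effects=tuple(EffectSpec(*e) for e in _REFERENCE_EFFECTS),
        seed=seed,
    )
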