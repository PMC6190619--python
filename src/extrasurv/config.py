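"""Configuration schema, evidence-file IO and run-level validation.

Evidence files (YAML or JSON) use the keys::

    gp_survival: {r, n, t}
    registry_cs: [{t, r, n}, ...]
    gp_cs: {t, r, n}
    hr_pseudo: {t_min, t_max, value, sd}

Run configuration adds the model choice, evidence toggles (any subset may be
active: evidence is designed to be added incrementally), sampler settings,
the integration horizon and a mandatory seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .evidence import (
    ConditionalSurvivalSeries,
    ExternalEvidence,
    GPSurvivalPoint,
    HRPseudoData,
)
from .families import FAMILIES


class ConfigError(ValueError):
    """Configuration failed validation; message names the offending field."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GPSurvivalConfig(_Strict):
    r: int = Field(ge=0)
    n: int = Field(gt=0)
    t: float = Field(gt=0)

    @model_validator(mode="after")
    def _r_le_n(self):
        if self.r > self.n:
            raise ValueError("gp_survival: r must be <= n")
        return self


class CSEntryConfig(_Strict):
    t: float = Field(gt=0)
    r: int = Field(ge=0)
    n: int = Field(gt=0)

    @model_validator(mode="after")
    def _r_le_n(self):
        if self.r > self.n:
            raise ValueError("conditional-survival entry: r must be <= n")
        return self


class HRPseudoConfig(_Strict):
    t_min: float = Field(default=6.0, gt=0)
    t_max: float = Field(default=35.0, gt=0)
    value: float = Field(default=1.0, gt=0)
    sd: float = Field(default=0.1, gt=0)

    @model_validator(mode="after")
    def _range(self):
        if self.t_max < self.t_min:
            raise ValueError("hr_pseudo: t_max must be >= t_min")
        return self


class EvidenceConfig(_Strict):
    gp_survival: Optional[GPSurvivalConfig] = None
    registry_cs: Optional[list[CSEntryConfig]] = None
    gp_cs: Optional[CSEntryConfig] = None
    hr_pseudo: Optional[HRPseudoConfig] = None

    def build(self, toggles: Optional[dict] = None) -> ExternalEvidence:
        """Materialize the evidence objects, optionally masking by toggles."""
        on = toggles or {}

        def active(key):
            return on.get(key, True) and getattr(self, key) is not None

        ev = ExternalEvidence()
        if active("gp_survival"):
            g = self.gp_survival
            ev.gp_survival = GPSurvivalPoint(g.r, g.n, g.t)
        if active("registry_cs"):
            ev.registry_cs = ConditionalSurvivalSeries.from_entries(
                [e.model_dump() for e in self.registry_cs]
            )
        if active("gp_cs"):
            e = self.gp_cs
            ev.gp_cs = ConditionalSurvivalSeries(
                (e.t,), (e.r,), (e.n,), source="general_population"
            )
        if active("hr_pseudo"):
            h = self.hr_pseudo
            times = tuple(float(t) for t in range(int(h.t_min), int(h.t_max) + 1))
            ev.hr_pseudo = HRPseudoData(times, h.value, h.sd)
        return ev


class ModelConfig(_Strict):
    family: str = "spline"
    link: Optional[Literal["PH", "AFT", "FSEA"]] = None

    @model_validator(mode="after")
    def _known(self):
        if self.family != "spline":
            if self.family not in FAMILIES:
                raise ValueError(
                    f"model.family must be 'spline' or one of {sorted(FAMILIES)}, got {self.family!r}"
                )
            if self.link is None:
                raise ValueError("model.link is required for parametric families")
        return self


class KnotConfig(_Strict):
    trial_end: float = Field(default=5.0, gt=0)
    external_end: float = Field(default=40.0, gt=0)
    n_internal_trial: int = Field(default=1, ge=0)
    n_internal_external: int = Field(default=1, ge=0)
    n_internal_treatment: int = Field(default=1, ge=0)

    @model_validator(mode="after")
    def _order(self):
        if self.external_end <= self.trial_end:
            raise ValueError("knots: external_end must be > trial_end")
        return self


class SamplerConfig(_Strict):
    n_walkers: Optional[int] = Field(default=None, ge=4)
    n_steps: int = Field(default=2000, ge=10)
    burn_frac: float = Field(default=0.5, gt=0.0, lt=1.0)


class EvidenceToggles(_Strict):
    gp_survival: bool = True
    registry_cs: bool = True
    gp_cs: bool = True
    hr_pseudo: bool = True


class RunConfig(_Strict):
    model: ModelConfig = ModelConfig(family="spline")
    knots: KnotConfig = KnotConfig()
    sampler: SamplerConfig = SamplerConfig()
    use_evidence: EvidenceToggles = EvidenceToggles()
    horizon: float = Field(default=60.0, gt=0)
    seed: int

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def validate_config(raw) -> RunConfig:
    """Validate a raw mapping (or YAML/JSON path) into a RunConfig.

    Unknown keys and out-of-range values raise :class:`ConfigError` naming
    the offending field.
    """
    if isinstance(raw, (str, Path)):
        raw = yaml.safe_load(Path(raw).read_text()) or {}
    try:
        return RunConfig(**raw)
    except ValidationError as err:
        raise ConfigError(str(err)) from err


def load_evidence_config(path) -> EvidenceConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return EvidenceConfig(**raw)
    except ValidationError as err:
        raise ConfigError(str(err)) from err


def load_evidence(path, toggles: Optional[dict] = None) -> ExternalEvidence:
    """Read an evidence YAML/JSON file into the evidence objects."""
    return load_evidence_config(path).build(toggles)


def save_evidence(evidence: ExternalEvidence, path) -> None:
    """Write evidence objects back to the YAML dialect that load_evidence reads."""
    doc: dict = {}
    if evidence.gp_survival is not None:
        g = evidence.gp_survival
        doc["gp_survival"] = {"r": int(g.r), "n": int(g.n), "t": float(g.t_star)}
    if evidence.registry_cs is not None:
        doc["registry_cs"] = [
            {"t": float(t), "r": int(r), "n": int(n)}
            for t, r, n in zip(evidence.registry_cs.years, evidence.registry_cs.r, evidence.registry_cs.n)
        ]
    if evidence.gp_cs is not None:
        e = evidence.gp_cs
        doc["gp_cs"] = {"t": float(e.years[0]), "r": int(e.r[0]), "n": int(e.n[0])}
    if evidence.hr_pseudo is not None:
        h = evidence.hr_pseudo
        doc["hr_pseudo"] = {
            "t_min": float(min(h.times)), "t_max": float(max(h.times)),
            "value": float(h.value), "sd": float(h.sd),
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
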