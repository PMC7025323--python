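"""Pipeline configuration: one YAML file drives simulate/fit/summarise/validate.

A single global ``seed`` expands deterministically into per-stage seeds:
``stage_seed(seed, stage) = SeedSequence((seed, ord)).generate_state(1)[0]
mod 2**31`` with stage ordinals simulate=0, fit=1, summarise=2, validate=3.
Chains then derive their streams from ``(fit seed, chain index)`` inside
the sampler, so any stage can be rerun independently and reproducibly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .sampler import MCMCSchedule
from .synthetic import GenerativeSettings, SurveyDesign

_STAGE_ORD = {"simulate": 0, "fit": 1, "summarise": 2, "validate": 3}


def stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence((int(seed), _STAGE_ORD[stage]))
               .generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    seed: int = 0
    outcome: str = "prev_diabetes"
    outdir: str = "out"
    sexes: tuple[str, ...] = ("men", "women")
    n_regions: int = 3
    countries_per_region: tuple[int, ...] = (4, 4, 4)
    years: tuple[int, int] = (1980, 2014)
    holdout_countries: tuple[str, ...] = ()
    generator: dict = field(default_factory=dict)      # GenerativeSettings kwargs
    design: dict = field(default_factory=dict)         # SurveyDesign kwargs
    model: dict = field(default_factory=dict)          # estimator kwargs
    mcmc: dict = field(default_factory=dict)           # MCMCSchedule kwargs
    report_years: tuple[int, int] | None = None

    def settings(self) -> GenerativeSettings:
        return GenerativeSettings(**self.generator)

    def survey_design(self, countries: tuple[str, ...]) -> SurveyDesign:
        kwargs = dict(self.design)
        if self.holdout_countries:
            per = kwargs.get("studies_per_country", 10)
            if not isinstance(per, dict):
                per = {c: int(per) for c in countries}
            for c in self.holdout_countries:
                per[c] = 0
            kwargs["studies_per_country"] = per
        return SurveyDesign(**kwargs)

    def schedule(self) -> MCMCSchedule:
        kwargs = dict(self.mcmc)
        kwargs.setdefault("seed", stage_seed(self.seed, "fit"))
        return MCMCSchedule(**kwargs)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sexes", "countries_per_region", "years",
                    "holdout_countries", "report_years"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
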