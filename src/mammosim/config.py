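"""Structured run configuration: one YAML file drives a full analysis.

Top-level keys mirror the model objects (``onset``, ``growth``, ``detection``,
``cohort``) plus a mandatory ``seed``, a list of ``scenarios`` and an
``output_dir``.  Every scenario names a screening policy (start/end age and
interval in years), an attendance mode and a sensitivity scenario (or explicit
beta0/beta1), optionally with a ±percentage perturbation of the sensitivity
parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import yaml

from .natural_history import CohortSpec, DetectionModel, GrowthModel, OnsetModel
from .screening import AttendanceModel, ScreeningPolicy, SensitivityParams

__all__ = ["ScenarioConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    policy: ScreeningPolicy
    attendance: AttendanceModel
    sensitivity: SensitivityParams


@dataclass
class RunConfig:
    seed: int
    onset: OnsetModel = field(default_factory=OnsetModel)
    growth: GrowthModel = field(default_factory=GrowthModel)
    detection: DetectionModel = field(default_factory=DetectionModel)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    scenarios: List[ScenarioConfig] = field(default_factory=list)
    output_dir: str = "mammosim-output"

    def config_hash(self) -> str:
        """Short stable digest of the full configuration (for output headers)."""
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            return o.__dict__
        text = json.dumps(self, default=default, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _onset_from(block: dict) -> OnsetModel:
    kw = dict(block)
    grid = kw.pop("age_grid", None)
    if isinstance(grid, dict):
        kw["age_grid"] = np.arange(grid["start"], grid["stop"] + 1, dtype=float)
    elif grid is not None:
        kw["age_grid"] = np.asarray(grid, dtype=float)
    return OnsetModel(**kw)


def _detection_from(block: dict) -> DetectionModel:
    kw = dict(block)
    if "log_eta" in kw:
        kw["eta"] = float(np.exp(kw.pop("log_eta")))
    return DetectionModel(**kw)


def _scenario_from(block: dict, idx: int) -> ScenarioConfig:
    try:
        pol = block["policy"]
        policy = ScreeningPolicy(
            start_age=pol["start_age"], end_age=pol["end_age"], interval=pol["interval"]
        )
    except KeyError as exc:
        raise ValueError(f"scenario {idx}: missing policy field {exc}") from None
    att = block.get("attendance", "imperfect")
    attendance = AttendanceModel(mode=att) if isinstance(att, str) else AttendanceModel(**att)
    sens = block.get("sensitivity", "moderate")
    perturb = float(block.get("perturb_pct", 0.0))
    if isinstance(sens, str):
        sensitivity = SensitivityParams.from_scenario(sens, perturb_pct=perturb)
    else:
        f = 1.0 + perturb / 100.0
        sensitivity = SensitivityParams(
            beta0=float(sens["beta0"]) * f, beta1=float(sens["beta1"]) * f
        )
    name = block.get("name") or f"scenario_{idx}"
    return ScenarioConfig(name=name, policy=policy, attendance=attendance, sensitivity=sensitivity)


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration; the master seed is mandatory."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError(f"{path}: a master 'seed' is mandatory")
    return RunConfig(
        seed=int(raw["seed"]),
        onset=_onset_from(raw.get("onset", {})),
        growth=GrowthModel(**raw.get("growth", {})),
        detection=_detection_from(raw.get("detection", {})),
        cohort=CohortSpec(**raw.get("cohort", {})),
        scenarios=[_scenario_from(s, i) for i, s in enumerate(raw.get("scenarios", []))],
        output_dir=str(raw.get("output_dir", "mammosim-output")),
    )
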