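"""Planning configuration schema: YAML/JSON loading and validation.

A planning config collects everything one run needs: the scenario
(geometry, arc span, prescription), the machine (beam model, delivery
dynamics, minimum MU), the objective list, and the sequencing schedule.
Validation is strict — unknown keys are rejected with their location —
and a config fingerprint (SHA-256 of the canonical JSON) is embedded in
outputs for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._errors import ConfigurationError
from .arc_sequencing import SequencingConfig
from .beam_physics import BeamModel
from .delivery import DeliveryModel
from .optimize import ObjectiveSet, ObjectiveTerm
from .phantoms import ScenarioSpec, scenario_spec

_SCENARIO_KEYS = {
    "id", "arc_start_deg", "arc_stop_deg", "prescription_gy", "fractions",
    "spacing_mm", "geometry",
}
_MACHINE_KEYS = {
    "energy_min_mev", "energy_max_mev", "energy_step_mev", "sigma_air_mm",
    "min_mu", "rotation_rpm", "spot_switch_s", "layer_switch_s",
    "beam_on_s_per_mu", "static_setup_s",
}
_OBJECTIVE_KEYS = {"roi", "quantity", "sense", "goal", "penalty", "volume_fraction"}
_SEQUENCING_KEYS = {
    "coarse_spacing_deg", "final_spacing_deg", "final_layers_per_cp",
    "lateral_spacing_mm", "layer_spacing_cm", "margin_mm", "max_iterations",
    "tolerance", "influence_cutoff", "renormalize_d95",
}
_TOP_KEYS = {"scenario", "machine", "objectives", "sequencing", "output_dir"}


@dataclass
class PlanningConfig:
    scenario: ScenarioSpec
    beam_model: BeamModel
    delivery_model: DeliveryModel
    objectives: ObjectiveSet
    sequencing: SequencingConfig
    output_dir: str = "."
    raw: dict = field(default_factory=dict)

    @property
    def fingerprint(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _check_keys(section: dict, allowed: set, path: str) -> None:
    for key in section:
        if key not in allowed:
            raise ConfigurationError(
                f"unknown config key {path}.{key!r}; allowed: {sorted(allowed)}"
            )


def _require(section: dict, key: str, path: str):
    if key not in section:
        raise ConfigurationError(f"missing required config key {path}.{key!r}")
    return section[key]


def parse_config(doc: dict) -> PlanningConfig:
    """Validate a parsed config document and build the typed objects."""
    if not isinstance(doc, dict):
        raise ConfigurationError("config root must be a mapping")
    _check_keys(doc, _TOP_KEYS, "<root>")

    sc = _require(doc, "scenario", "<root>")
    _check_keys(sc, _SCENARIO_KEYS, "scenario")
    overrides = {k: v for k, v in sc.items() if k != "id"}
    scenario = scenario_spec(_require(sc, "id", "scenario"), **overrides)

    mc = dict(doc.get("machine", {}))
    _check_keys(mc, _MACHINE_KEYS, "machine")
    beam_kwargs = {}
    if {"energy_min_mev", "energy_max_mev", "energy_step_mev"} & mc.keys():
        lo = float(mc.get("energy_min_mev", 70.0))
        hi = float(mc.get("energy_max_mev", 230.0))
        step = float(mc.get("energy_step_mev", 2.0))
        beam_kwargs["energies_mev"] = np.arange(lo, hi + step / 2, step)
    if "sigma_air_mm" in mc:
        beam_kwargs["sigma_air_mm"] = float(mc["sigma_air_mm"])
    beam_model = BeamModel(**beam_kwargs)
    delivery_model = DeliveryModel(
        rotation_rpm=float(mc.get("rotation_rpm", 1.0)),
        spot_switch_s=float(mc.get("spot_switch_s", 0.002)),
        layer_switch_s=float(mc.get("layer_switch_s", 0.6)),
        beam_on_s_per_mu=float(mc.get("beam_on_s_per_mu", 0.0)),
        static_setup_s=float(mc.get("static_setup_s", 0.0)),
    )

    terms = []
    for i, t in enumerate(doc.get("objectives", [])):
        _check_keys(t, _OBJECTIVE_KEYS, f"objectives[{i}]")
        terms.append(
            ObjectiveTerm(
                roi=_require(t, "roi", f"objectives[{i}]"),
                quantity=_require(t, "quantity", f"objectives[{i}]"),
                sense=_require(t, "sense", f"objectives[{i}]"),
                goal=float(_require(t, "goal", f"objectives[{i}]")),
                penalty=float(_require(t, "penalty", f"objectives[{i}]")),
                volume_fraction=t.get("volume_fraction"),
            )
        )
    objectives = ObjectiveSet(terms) if terms else default_objectives(scenario)

    sq = dict(doc.get("sequencing", {}))
    _check_keys(sq, _SEQUENCING_KEYS, "sequencing")
    seq_kwargs = {k: v for k, v in sq.items()}
    sequencing = SequencingConfig(**seq_kwargs)
    if "min_mu" in mc:
        sequencing.min_mu = float(mc["min_mu"])

    return PlanningConfig(
        scenario=scenario,
        beam_model=beam_model,
        delivery_model=delivery_model,
        objectives=objectives,
        sequencing=sequencing,
        output_dir=str(doc.get("output_dir", ".")),
        raw=doc,
    )


def load_config(path) -> PlanningConfig:
    """Read a YAML (or JSON) planning config from disk."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    return parse_config(doc)


#: packaged default objective sets per scenario — the study conditions.
_DEFAULT_OBJECTIVES = {
    "prostate-like": [
        ("ctv", "dose", "uniform", None, 100.0),
        ("oar_left", "dose", "max", 60.0, 20.0),
        ("oar_right", "dose", "max", 60.0, 20.0),
        ("body", "dose", "max", None, 10.0),
        ("ctv", "letd", "min", 8.0, 60.0),
    ],
    "liver-like": [
        ("ctv", "dose", "uniform", None, 100.0),
        ("normal_liver", "dose", "max", 20.0, 10.0),
        ("body", "dose", "max", None, 10.0),
        ("gtv", "letd", "min", 8.0, 60.0),
    ],
    "brain-like": [
        ("ctv", "dose", "uniform", None, 100.0),
        ("brainstem", "dose", "max", 30.0, 20.0),
        ("chiasm", "dose", "max", 30.0, 20.0),
        ("optic_nerve_left", "dose", "max", 30.0, 20.0),
        ("optic_nerve_right", "dose", "max", 30.0, 20.0),
        ("body", "dose", "max", None, 10.0),
        ("ctv", "letd", "min", 8.0, 60.0),
        ("brainstem", "letd", "max", 1.5, 30.0),
        ("chiasm", "letd", "max", 1.5, 30.0),
        ("optic_nerve_left", "letd", "max", 1.5, 30.0),
        ("optic_nerve_right", "letd", "max", 1.5, 30.0),
    ],
}


def default_objectives(scenario: ScenarioSpec) -> ObjectiveSet:
    """The packaged objective set for a scenario (goals in Gy / keV/um)."""
    try:
        spec = _DEFAULT_OBJECTIVES[scenario.scenario]
    except KeyError:
        raise ConfigurationError(
            f"no default objectives for scenario {scenario.scenario!r}"
        ) from None
    terms = [
        ObjectiveTerm(
            roi, quantity, sense,
            scenario.prescription_gy if goal is None else goal,
            penalty,
        )
        for roi, quantity, sense, goal, penalty in spec
    ]
    return ObjectiveSet(terms)


def config_to_dict(cfg: PlanningConfig) -> dict:
    """Serializable snapshot of a config (for provenance sidecars)."""
    doc = dict(cfg.raw)
    doc.setdefault("scenario", {})
    return {
        "fingerprint": cfg.fingerprint,
        "scenario": asdict(cfg.scenario),
        "sequencing": asdict(cfg.sequencing),
        "objectives": [asdict(t) for t in cfg.objectives.terms],
        "delivery": asdict(cfg.delivery_model),
    }
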