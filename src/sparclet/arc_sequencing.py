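"""Coarse-to-fine arc sequencing and the multi-beam planning path.

A spot-scanning arc plan is built in rounds: control points start at a
coarse angular sampling (default 20 deg), each round optimizes the spot
weights, splits every control point into two children at +/- quarter
spacing (doubling the sampling), partitions the parent's energy layers
between the children, and carries the weights over as a warm start.  At
the final sampling (default 2.5 deg) the energy layers per control point
are reduced to a configured maximum (default 1, for continuous-rotation
deliverability), the weights are re-optimized, and the plan is made
deliverable by enforcing the minimum-MU threshold.

The multi-beam path (plan_impt) uses one control point per beam with its
full layer set and no sequencing; its LET-free variant zeroes the LET
penalties over an identical spot set.

Both paths end with a dose-only renormalization of the weight vector so
the target D95 equals the prescription: per-voxel dose is linear in the
weights and dose-averaged LET is invariant under uniform scaling, so the
renormalization matches coverage across plans without touching LET.
Control points are placed at the centers of equal angular cells, so
refinement (cell halving) never leaves the configured arc span.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._errors import PlanningError
from .beam_physics import BeamModel, EnergyLayer, Spot, place_spots
from .influence import InfluencePair, accumulate_dose, accumulate_letd, compute_influence
from .optimize import (
    ObjectiveSet,
    OptimizerReport,
    deliverable_postprocess,
    init_weights,
    solve_weights,
)
from .phantoms import ROIMask, ScenarioSpec, VoxelPhantom

log = logging.getLogger(__name__)

DEFAULT_SCHEDULE = (20.0, 10.0, 5.0, 2.5)


@dataclass
class ControlPoint:
    """One gantry angle of a plan with its energy layers."""

    angle_deg: float
    layers: list[EnergyLayer] = field(default_factory=list)
    parent_angle_deg: float | None = None


@dataclass
class Plan:
    """An ordered set of control points with spots and final MU weights."""

    mode: str  # 'sparc' or 'impt'
    control_points: list[ControlPoint]
    spots: list[Spot]
    prescription_gy: float
    fractions: int
    scenario: str = ""
    machine: dict = field(default_factory=dict)
    arc_start_deg: float = 0.0
    arc_stop_deg: float = 0.0
    evaluation: object | None = None  # PlanEvaluation, attached after planning

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.spots])

    def set_weights(self, w: np.ndarray) -> None:
        if len(w) != len(self.spots):
            raise PlanningError("weight vector length != spot count")
        self.spots = [replace(s, weight=float(x)) for s, x in zip(self.spots, w)]

    @property
    def total_mu(self) -> float:
        return float(self.weights.sum())

    @property
    def angles_deg(self) -> list[float]:
        return [cp.angle_deg for cp in self.control_points]

    def layer_count(self) -> int:
        return sum(len(cp.layers) for cp in self.control_points)

    def delivered_spot_count(self) -> int:
        return int((self.weights > 0).sum())

    def to_json(self) -> str:
        doc = {
            "mode": self.mode,
            "prescription_gy": self.prescription_gy,
            "fractions": self.fractions,
            "scenario": self.scenario,
            "machine": self.machine,
            "arc_start_deg": self.arc_start_deg,
            "arc_stop_deg": self.arc_stop_deg,
            "control_points": [
                {
                    "angle_deg": cp.angle_deg,
                    "parent_angle_deg": cp.parent_angle_deg,
                    "layers": [
                        {"energy_mev": ly.energy_mev, "spot_indices": ly.spot_indices}
                        for ly in cp.layers
                    ],
                }
                for cp in self.control_points
            ],
            "spots": [
                {
                    "cp_index": s.cp_index,
                    "energy_mev": s.energy_mev,
                    "x_mm": s.x_mm,
                    "y_mm": s.y_mm,
                    "weight_mu": s.weight,
                }
                for s in self.spots
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Plan":
        doc = json.loads(text)
        cps = [
            ControlPoint(
                d["angle_deg"],
                [EnergyLayer(ly["energy_mev"], list(ly["spot_indices"])) for ly in d["layers"]],
                d.get("parent_angle_deg"),
            )
            for d in doc["control_points"]
        ]
        spots = [
            Spot(s["cp_index"], s["energy_mev"], s["x_mm"], s["y_mm"], s["weight_mu"])
            for s in doc["spots"]
        ]
        return cls(
            mode=doc["mode"],
            control_points=cps,
            spots=spots,
            prescription_gy=doc["prescription_gy"],
            fractions=doc["fractions"],
            scenario=doc.get("scenario", ""),
            machine=doc.get("machine", {}),
            arc_start_deg=doc.get("arc_start_deg", 0.0),
            arc_stop_deg=doc.get("arc_stop_deg", 0.0),
        )


def arc_span_deg(start_deg: float, stop_deg: float) -> float:
    """Angular span traversed from start to stop (wrapping through 0)."""
    span = (stop_deg - start_deg) % 360.0
    return 360.0 if span == 0.0 else span


def control_point_angles(
    start_deg: float, stop_deg: float, spacing_deg: float
) -> list[float]:
    """Cell-center angles of an equally sampled arc.

    The span is divided into ``span/spacing`` cells and control points
    sit at cell centers, so later cell-halving refinements always stay
    inside the span.
    """
    span = arc_span_deg(start_deg, stop_deg)
    n = max(1, int(round(span / spacing_deg)))
    if span < spacing_deg:
        warnings.warn(
            f"arc span {span:g} deg below sampling {spacing_deg:g} deg; "
            "falling back to a single control point",
            stacklevel=2,
        )
        n = 1
    cell = span / n
    return [(start_deg + (k + 0.5) * cell) % 360.0 for k in range(n)]


def init_control_points(
    phantom: VoxelPhantom,
    target: ROIMask,
    model: BeamModel,
    arc_start_deg: float,
    arc_stop_deg: float,
    coarse_spacing_deg: float = 20.0,
    lateral_spacing_mm: float = 5.0,
    layer_spacing_cm: float = 0.5,
    margin_mm: float = 5.0,
) -> tuple[list[ControlPoint], list[Spot]]:
    """Coarsely sampled control points with full layer sets per angle."""
    angles = control_point_angles(arc_start_deg, arc_stop_deg, coarse_spacing_deg)
    if len(angles) == 1 and arc_span_deg(arc_start_deg, arc_stop_deg) >= coarse_spacing_deg:
        warnings.warn("arc sampling yields a single control point", stacklevel=2)
    cps: list[ControlPoint] = []
    spots: list[Spot] = []
    for k, ang in enumerate(angles):
        layers, local = place_spots(
            phantom, target, ang, model,
            lateral_spacing_mm=lateral_spacing_mm,
            layer_spacing_cm=layer_spacing_cm,
            margin_mm=margin_mm,
            cp_index=k,
        )
        offset = len(spots)
        for ly in layers:
            ly.spot_indices = [i + offset for i in ly.spot_indices]
        spots.extend(local)
        cps.append(ControlPoint(angle_deg=ang, layers=layers))
    return cps, spots


def _layer_weight(layer: EnergyLayer, spots: Sequence[Spot]) -> float:
    return float(sum(spots[i].weight for i in layer.spot_indices))


def reduce_layers(
    cp: ControlPoint, spots: list[Spot], keep: int
) -> tuple[ControlPoint, list[int]]:
    """Keep the ``keep`` heaviest energy layers of a control point.

    Layers are ranked by summed spot weight; ties break toward the lower
    energy.  Returns the reduced control point and the spot indices of
    removed layers (whose weights the caller must zero before the next
    optimization round).  ``keep >= layer count`` is the identity.
    """
    if keep < 1:
        raise PlanningError("must keep at least one energy layer")
    if keep >= len(cp.layers):
        return cp, []
    ranked = sorted(
        cp.layers, key=lambda ly: (-_layer_weight(ly, spots), ly.energy_mev)
    )
    kept = ranked[:keep]
    removed = ranked[keep:]
    kept_sorted = sorted(kept, key=lambda ly: ly.energy_mev)
    dropped = [i for ly in removed for i in ly.spot_indices]
    return ControlPoint(cp.angle_deg, kept_sorted, cp.parent_angle_deg), dropped


def refine_and_reduce(
    cps: Sequence[ControlPoint],
    spots: Sequence[Spot],
    current_spacing_deg: float,
) -> tuple[list[ControlPoint], list[Spot], float]:
    """Double the angular sampling, partitioning layers between children.

    Each control point splits into children at +/- quarter spacing.  The
    parent's layers, ranked by summed spot weight, are dealt alternately
    to the two children (strongest first, to the lower-angle child), so
    the children's energy sets are disjoint and exhaustive.  Spots of
    each layer are carried verbatim (position and weight), conserving
    total MU exactly.  A parent with a single layer duplicates it into
    both children with the weights halved (logged), which also conserves
    MU.
    """
    new_spacing = current_spacing_deg / 2.0
    quarter = current_spacing_deg / 4.0
    new_cps: list[ControlPoint] = []
    new_spots: list[Spot] = []

    for cp in cps:
        child_angles = [
            (cp.angle_deg - quarter) % 360.0,
            (cp.angle_deg + quarter) % 360.0,
        ]
        ranked = sorted(
            cp.layers, key=lambda ly: (-_layer_weight(ly, spots), ly.energy_mev)
        )
        assignment: list[list[tuple[EnergyLayer, float]]] = [[], []]
        if len(ranked) == 1:
            log.info(
                "cp %.2f deg has one layer; duplicating into both children "
                "with halved weights", cp.angle_deg,
            )
            assignment[0].append((ranked[0], 0.5))
            assignment[1].append((ranked[0], 0.5))
        else:
            for r, ly in enumerate(ranked):
                assignment[r % 2].append((ly, 1.0))

        for child, ang in enumerate(child_angles):
            layers: list[EnergyLayer] = []
            for ly, frac in sorted(assignment[child], key=lambda t: t[0].energy_mev):
                new_layer = EnergyLayer(ly.energy_mev)
                for i in ly.spot_indices:
                    s = spots[i]
                    new_layer.spot_indices.append(len(new_spots))
                    new_spots.append(
                        Spot(len(new_cps), s.energy_mev, s.x_mm, s.y_mm,
                             s.weight * frac)
                    )
                layers.append(new_layer)
            new_cps.append(
                ControlPoint(ang, layers, parent_angle_deg=cp.angle_deg)
            )
    return new_cps, new_spots, new_spacing


@dataclass
class SequencingConfig:
    """Knobs of the arc workflow; defaults follow the packaged schedule."""

    coarse_spacing_deg: float = 20.0
    final_spacing_deg: float = 2.5
    final_layers_per_cp: int = 1
    lateral_spacing_mm: float = 5.0
    layer_spacing_cm: float = 0.5
    margin_mm: float = 5.0
    max_iterations: int = 200
    tolerance: float = 1e-6
    min_mu: float = 0.02
    influence_cutoff: float = 1e-4
    renormalize_d95: bool = True


def _renormalize(
    weights: np.ndarray,
    inf: InfluencePair,
    rois: Mapping[str, ROIMask],
    target_roi: str,
    prescription_gy: float,
    min_mu: float,
) -> np.ndarray:
    """Scale weights so target D95 equals the prescription.

    Uniform scaling leaves every per-voxel LET_d unchanged; nonzero
    weights are floored at the minimum MU to preserve deliverability
    (the floor touches only spots already at the threshold).
    """
    rows = inf.rows_for_mask(rois[target_roi].mask)
    d95 = float(np.percentile((inf.D @ weights)[rows], 5))
    if d95 <= 0:
        raise PlanningError("cannot renormalize a plan with zero target D95")
    scaled = weights * (prescription_gy / d95)
    scaled[weights > 0] = np.maximum(scaled[weights > 0], min_mu)
    return scaled


def _optimize_stage(
    phantom: VoxelPhantom,
    rois: Mapping[str, ROIMask],
    model: BeamModel,
    cps: Sequence[ControlPoint],
    spots: list[Spot],
    objectives: ObjectiveSet,
    target_roi: str,
    prescription_gy: float,
    cfg: SequencingConfig,
    warm: np.ndarray | None,
    two_stage: bool,
) -> tuple[InfluencePair, np.ndarray, OptimizerReport]:
    """Influence assembly + weight optimization for the current spot set.

    ``two_stage`` first solves the dose-only problem and then adds the
    LET terms from that solution — the sequencing used for every fresh
    start; warm-started rounds go straight to the full objective.
    """
    angles = [cp.angle_deg for cp in cps]
    inf = compute_influence(
        phantom, spots, angles, model, cutoff=cfg.influence_cutoff
    )
    if warm is None:
        w = init_weights(inf, rois, target_roi, prescription_gy)
    else:
        w = np.asarray(warm, dtype=float)
    if two_stage:
        w, _ = solve_weights(
            inf, objectives.with_let_penalties_zeroed(), rois, w,
            max_iterations=cfg.max_iterations, tolerance=cfg.tolerance,
        )
    w, report = solve_weights(
        inf, objectives, rois, w,
        max_iterations=cfg.max_iterations, tolerance=cfg.tolerance,
    )
    return inf, w, report


def plan_sparc(
    phantom: VoxelPhantom,
    rois: Mapping[str, ROIMask],
    scenario: ScenarioSpec,
    objectives: ObjectiveSet,
    model: BeamModel | None = None,
    config: SequencingConfig | None = None,
    target_roi: str = "ctv",
    evaluate: bool = True,
) -> Plan:
    """End-to-end arc plan: coarse sampling -> refine -> reduce -> deliver."""
    model = model or BeamModel()
    cfg = config or SequencingConfig()
    roi_map = dict(rois) if not isinstance(rois, Mapping) else rois

    cps, spots = init_control_points(
        phantom, roi_map[target_roi], model,
        scenario.arc_start_deg, scenario.arc_stop_deg,
        coarse_spacing_deg=cfg.coarse_spacing_deg,
        lateral_spacing_mm=cfg.lateral_spacing_mm,
        layer_spacing_cm=cfg.layer_spacing_cm,
        margin_mm=cfg.margin_mm,
    )
    span = arc_span_deg(scenario.arc_start_deg, scenario.arc_stop_deg)
    spacing = span / len(cps)
    warm: np.ndarray | None = None
    traces: list[float] = []

    round_no = 0
    while True:
        round_no += 1
        try:
            inf, w, report = _optimize_stage(
                phantom, roi_map, model, cps, spots, objectives,
                target_roi, scenario.prescription_gy, cfg,
                warm, two_stage=(warm is None),
            )
        except Exception as exc:
            raise PlanningError(
                f"sparc round {round_no} (spacing {spacing:g} deg) failed: {exc}"
            ) from exc
        traces.append(report.objective_trace[-1])
        log.info(
            "sparc round %d: %d cps at %.3g deg, objective %.4e",
            round_no, len(cps), spacing, traces[-1],
        )
        if spacing > cfg.final_spacing_deg * 1.5:
            for s_idx, s in enumerate(spots):
                spots[s_idx] = replace(s, weight=float(w[s_idx]))
            cps, spots, spacing = refine_and_reduce(cps, spots, spacing)
            warm = np.array([s.weight for s in spots])
            continue
        break

    # final sampling reached: reduce layers, drop removed spots, re-optimize
    for s_idx, s in enumerate(spots):
        spots[s_idx] = replace(s, weight=float(w[s_idx]))
    kept_spots: list[Spot] = []
    new_cps: list[ControlPoint] = []
    for cp in cps:
        reduced, _ = reduce_layers(cp, spots, cfg.final_layers_per_cp)
        new_layers = []
        for ly in reduced.layers:
            new_layer = EnergyLayer(ly.energy_mev)
            for i in ly.spot_indices:
                s = spots[i]
                new_layer.spot_indices.append(len(kept_spots))
                kept_spots.append(replace(s, cp_index=len(new_cps)))
            new_layers.append(new_layer)
        new_cps.append(ControlPoint(cp.angle_deg, new_layers, cp.parent_angle_deg))
    cps, spots = new_cps, kept_spots

    try:
        inf, w, report = _optimize_stage(
            phantom, roi_map, model, cps, spots, objectives,
            target_roi, scenario.prescription_gy, cfg,
            warm=np.array([s.weight for s in spots]), two_stage=False,
        )
        w, _ = deliverable_postprocess(
            w, inf, objectives, roi_map, min_mu=cfg.min_mu,
            max_iterations=cfg.max_iterations, tolerance=cfg.tolerance,
        )
    except PlanningError:
        raise
    except Exception as exc:
        raise PlanningError(f"sparc deliverable stage failed: {exc}") from exc
    if cfg.renormalize_d95:
        w = _renormalize(
            w, inf, roi_map, target_roi, scenario.prescription_gy, cfg.min_mu
        )

    plan = Plan(
        mode="sparc",
        control_points=cps,
        spots=spots,
        prescription_gy=scenario.prescription_gy,
        fractions=scenario.fractions,
        scenario=scenario.scenario,
        machine={"min_mu": cfg.min_mu, "final_spacing_deg": cfg.final_spacing_deg},
        arc_start_deg=scenario.arc_start_deg,
        arc_stop_deg=scenario.arc_stop_deg,
    )
    plan.set_weights(w)
    if evaluate:
        from .evaluate import evaluate_plan

        plan.evaluation = evaluate_plan(
            plan, phantom, roi_map, model, influence=inf, weights=w
        )
    return plan


def plan_impt(
    phantom: VoxelPhantom,
    rois: Mapping[str, ROIMask],
    beam_angles_deg: Sequence[float],
    objectives: ObjectiveSet,
    prescription_gy: float,
    fractions: int = 1,
    let_optimization: bool = True,
    model: BeamModel | None = None,
    config: SequencingConfig | None = None,
    target_roi: str = "ctv",
    evaluate: bool = True,
    scenario_id: str = "",
) -> Plan:
    """Multi-beam plan: one control point per beam, full layer sets.

    ``let_optimization=False`` zeroes the LET penalties over the same
    spot set, producing the LET-free comparator with identical geometry.
    """
    if not (1 <= len(beam_angles_deg) <= 8):
        raise PlanningError("plan_impt expects 1-8 beam angles")
    model = model or BeamModel()
    cfg = config or SequencingConfig()
    roi_map = dict(rois) if not isinstance(rois, Mapping) else rois
    objs = objectives if let_optimization else objectives.with_let_penalties_zeroed()

    cps: list[ControlPoint] = []
    spots: list[Spot] = []
    for k, ang in enumerate(beam_angles_deg):
        layers, local = place_spots(
            phantom, roi_map[target_roi], ang, model,
            lateral_spacing_mm=cfg.lateral_spacing_mm,
            layer_spacing_cm=cfg.layer_spacing_cm,
            margin_mm=cfg.margin_mm,
            cp_index=k,
        )
        offset = len(spots)
        for ly in layers:
            ly.spot_indices = [i + offset for i in ly.spot_indices]
        spots.extend(local)
        cps.append(ControlPoint(angle_deg=float(ang), layers=layers))

    try:
        inf, w, _ = _optimize_stage(
            phantom, roi_map, model, cps, spots, objs,
            target_roi, prescription_gy, cfg, warm=None, two_stage=True,
        )
        w, _ = deliverable_postprocess(
            w, inf, objs, roi_map, min_mu=cfg.min_mu,
            max_iterations=cfg.max_iterations, tolerance=cfg.tolerance,
        )
    except PlanningError:
        raise
    except Exception as exc:
        raise PlanningError(f"impt planning failed: {exc}") from exc
    if cfg.renormalize_d95:
        w = _renormalize(w, inf, roi_map, target_roi, prescription_gy, cfg.min_mu)

    plan = Plan(
        mode="impt",
        control_points=cps,
        spots=spots,
        prescription_gy=prescription_gy,
        fractions=fractions,
        scenario=scenario_id,
        machine={"min_mu": cfg.min_mu, "let_optimization": let_optimization},
    )
    plan.set_weights(w)
    if evaluate:
        from .evaluate import evaluate_plan

        plan.evaluation = evaluate_plan(
            plan, phantom, roi_map, model, influence=inf, weights=w
        )
    return plan
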