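"""Plan delivery-time simulation.

Machine dynamics: gantry rotation speed (default one rotation per
minute), per-spot switching time (default 2 ms), energy-layer switching
time (default 0.6 s), an optional per-MU beam-on rate, and an optional
static setup time between fixed beams.

A static beam takes

    t = n_spots * t_spot + (n_layers - 1) * t_layer + MU * rate

Arc delivery models a continuously rotating gantry that slows only when
spot/layer delivery is the bottleneck: the time across each angular
interval is the larger of the gantry travel time and the delivery time
of the control point the interval arrives at, so a trivially light full
arc takes exactly one rotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

from ._errors import ContractViolation
from .arc_sequencing import Plan, arc_span_deg

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeliveryModel:
    rotation_rpm: float = 1.0
    spot_switch_s: float = 0.002
    layer_switch_s: float = 0.6
    beam_on_s_per_mu: float = 0.0
    static_setup_s: float = 0.0

    def __post_init__(self) -> None:
        if self.rotation_rpm <= 0:
            raise ContractViolation("rotation speed must be > 0")
        if min(self.spot_switch_s, self.layer_switch_s,
               self.beam_on_s_per_mu, self.static_setup_s) < 0:
            raise ContractViolation("all delivery times must be >= 0")

    @property
    def deg_per_s(self) -> float:
        return self.rotation_rpm * 360.0 / 60.0


def _cp_stats(plan: Plan, cp_index: int) -> tuple[int, int, float]:
    """(delivered spot count, delivered layer count, total MU) of a control point."""
    cp = plan.control_points[cp_index]
    n_spots = 0
    n_layers = 0
    mu = 0.0
    for layer in cp.layers:
        delivered = [i for i in layer.spot_indices if plan.spots[i].weight > 0]
        if delivered:
            n_layers += 1
            n_spots += len(delivered)
            mu += sum(plan.spots[i].weight for i in delivered)
    return n_spots, n_layers, mu


def beam_delivery_time(plan: Plan, cp_index: int, model: DeliveryModel) -> float:
    """Delivery time (s) of one control point, gantry motion excluded."""
    n_spots, n_layers, mu = _cp_stats(plan, cp_index)
    if n_spots == 0:
        warnings.warn(
            f"control point {cp_index} has no delivered spots", stacklevel=2
        )
        return 0.0
    return (
        n_spots * model.spot_switch_s
        + (n_layers - 1) * model.layer_switch_s
        + mu * model.beam_on_s_per_mu
    )


def plan_delivery_time(
    plan: Plan, model: DeliveryModel | None = None
) -> tuple[float, pd.DataFrame]:
    """Total delivery time (s) and a per-control-point breakdown.

    Static multi-beam plans sum beam times plus setup between fields.
    Arc plans sum, per inter-control-point interval, the maximum of the
    gantry travel time and the arriving control point's delivery time,
    including travel from the arc start to the first control point and
    from the last to the arc stop.
    """
    model = model or DeliveryModel()
    w = plan.weights
    nz = w[w > 0]
    min_mu = float(plan.machine.get("min_mu", 0.0))
    if nz.size and min_mu > 0 and nz.min() < min_mu - 1e-12:
        raise ContractViolation(
            f"plan is not deliverable: weight {nz.min():.4g} MU below "
            f"minimum {min_mu} MU"
        )

    rows = []
    if plan.mode == "impt":
        total = 0.0
        for k in range(len(plan.control_points)):
            bt = beam_delivery_time(plan, k, model)
            setup = model.static_setup_s if k > 0 else 0.0
            total += bt + setup
            n_spots, n_layers, mu = _cp_stats(plan, k)
            rows.append(
                dict(cp=k, angle_deg=plan.control_points[k].angle_deg,
                     spots=n_spots, layers=n_layers, mu=mu,
                     travel_s=setup, delivery_s=bt, interval_s=bt + setup)
            )
    else:
        span = arc_span_deg(plan.arc_start_deg, plan.arc_stop_deg)
        angles = plan.angles_deg
        # unwrapped positions along the arc, measured from the start angle
        pos = [(a - plan.arc_start_deg) % 360.0 for a in angles]
        total = 0.0
        prev = 0.0
        for k, p in enumerate(pos):
            travel = (p - prev) / model.deg_per_s
            n_spots, n_layers, mu = _cp_stats(plan, k)
            # an emptied control point is normal after min-MU removal in an
            # arc; the gantry just rotates through it
            bt = (
                n_spots * model.spot_switch_s
                + (n_layers - 1) * model.layer_switch_s
                + mu * model.beam_on_s_per_mu
            ) if n_spots else 0.0
            step = max(travel, bt)
            total += step
            rows.append(
                dict(cp=k, angle_deg=angles[k], spots=n_spots, layers=n_layers,
                     mu=mu, travel_s=travel, delivery_s=bt, interval_s=step)
            )
            prev = p
        tail = (span - prev) / model.deg_per_s
        total += tail
        rows.append(
            dict(cp=-1, angle_deg=plan.arc_stop_deg, spots=0, layers=0, mu=0.0,
                 travel_s=tail, delivery_s=0.0, interval_s=tail)
        )
    breakdown = pd.DataFrame(rows)
    log.info("delivery time (%s): %.1f s", plan.mode, total)
    return float(total), breakdown
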