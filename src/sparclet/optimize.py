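"""Joint dose + dose-averaged-LET inverse optimization of spot weights.

The objective is the standard quadratic form over per-voxel dose and
LET_d: uniform-dose terms on targets penalize any deviation from the
goal, organ-at-risk terms penalize only overshoot through a Heaviside
gate, and target-LET terms penalize only undershoot:

    Obj(w) = sum_targets   p/N * sum_i (dose_i - D0)^2
           + sum_oars      p/N * sum_i H(dose_i - D0) (dose_i - D0)^2
           + sum_t,LET     p/N * sum_i H(L0 - letd_i) (letd_i - L0)^2
           + sum_oar,LET   p/N * sum_i H(letd_i - L0) (letd_i - L0)^2

with H(x) = 1 iff x > 0, and letd_i the dose-weighted LET ratio.  Each
term is normalized by its ROI voxel count N so penalties are comparable
across structures of different size.

Gradients are exact: dose terms are linear in w; LET terms use the full
quotient rule  d(letd_i)/dw_j = D_ij (L_ij - letd_i) / dose_i,  with the
Heaviside gates held fixed at the evaluation point (one-sided).  LET
terms are evaluated only on voxels with strictly positive dose, where
the ratio (and its derivative) is defined.  The LET ratio makes the
objective nonconvex; the solver is a deterministic bound-constrained
quasi-Newton method, so runs are reproducible but may end in a local
minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize as sciopt
from scipy import sparse

from ._errors import (
    ConfigurationError,
    ContractViolation,
    NumericalError,
    PlanningError,
)
from .influence import InfluencePair
from .phantoms import ROIMask

log = logging.getLogger(__name__)

SENSES = ("uniform", "max", "min", "max_dvh")


@dataclass(frozen=True)
class ObjectiveTerm:
    """One penalty term of the planning objective.

    ``sense='uniform'`` (targets only) penalizes both under- and
    overshoot of the goal; ``'max'`` penalizes overshoot, ``'min'``
    undershoot; ``'max_dvh'`` penalizes the excess voxels above the dose
    level once more than ``volume_fraction`` of the ROI exceeds it.
    """

    roi: str
    quantity: str  # 'dose' (Gy) or 'letd' (keV/um)
    sense: str
    goal: float
    penalty: float
    volume_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.quantity not in ("dose", "letd"):
            raise ConfigurationError(f"unknown quantity {self.quantity!r}")
        if self.sense not in SENSES:
            raise ConfigurationError(f"unknown sense {self.sense!r}")
        if self.goal < 0 or self.penalty < 0:
            raise ConfigurationError("goal and penalty must be >= 0")
        if self.sense == "max_dvh":
            if self.quantity != "dose":
                raise ConfigurationError("max_dvh terms apply to dose only")
            if not (self.volume_fraction is not None and 0 < self.volume_fraction < 1):
                raise ConfigurationError("max_dvh needs volume_fraction in (0, 1)")


@dataclass
class ObjectiveSet:
    """Ordered list of objective terms; requires a dose term on a target."""

    terms: list[ObjectiveTerm]

    def validate(self, rois: Mapping[str, ROIMask], planning: bool = False) -> None:
        """Check ROI bindings; ``planning=True`` additionally requires a
        target dose term (evaluation of partial term sets is legal)."""
        has_target_dose = False
        for t in self.terms:
            if t.roi not in rois:
                raise ConfigurationError(f"objective references unknown ROI {t.roi!r}")
            kind = rois[t.roi].kind
            if t.sense == "uniform" and kind != "target":
                raise ConfigurationError(
                    f"uniform-target sense on non-target ROI {t.roi!r}"
                )
            if t.quantity == "dose" and kind == "target":
                has_target_dose = True
        if planning and not has_target_dose:
            raise ConfigurationError("objective set needs a dose term on a target")

    def with_let_penalties_zeroed(self) -> "ObjectiveSet":
        """The dose-only variant of this objective set (same term list)."""
        return ObjectiveSet(
            [
                ObjectiveTerm(t.roi, t.quantity, t.sense, t.goal, 0.0, t.volume_fraction)
                if t.quantity == "letd"
                else t
                for t in self.terms
            ]
        )

    def scale_let_penalties(self, factor: float) -> "ObjectiveSet":
        return ObjectiveSet(
            [
                ObjectiveTerm(
                    t.roi, t.quantity, t.sense, t.goal, t.penalty * factor,
                    t.volume_fraction,
                )
                if t.quantity == "letd"
                else t
                for t in self.terms
            ]
        )


@dataclass
class OptimizerReport:
    iterations: int
    objective_trace: list[float]
    converged: bool
    term_values: dict[str, float] = field(default_factory=dict)
    message: str = ""


@dataclass
class _CompiledTerm:
    rows: np.ndarray
    quantity: str
    sense: str
    goal: float
    weight: float  # penalty / N
    volume_fraction: float | None
    label: str


def _compile(
    objectives: ObjectiveSet,
    inf: InfluencePair,
    rois: Mapping[str, ROIMask],
    planning: bool = False,
) -> list[_CompiledTerm]:
    objectives.validate(rois, planning=planning)
    compiled = []
    for k, t in enumerate(objectives.terms):
        rows = inf.rows_for_mask(rois[t.roi].mask)
        if rows.size == 0:
            log.warning("objective term on ROI %r scores no voxels", t.roi)
            continue
        compiled.append(
            _CompiledTerm(
                rows, t.quantity, t.sense, t.goal, t.penalty / rows.size,
                t.volume_fraction, f"{k}:{t.roi}/{t.quantity}/{t.sense}",
            )
        )
    return compiled


def _eval(
    w: np.ndarray,
    compiled: Sequence[_CompiledTerm],
    inf: InfluencePair,
    want_grad: bool,
):
    """Objective value, per-term values, and (optionally) the gradient.

    Voxel-space residuals are accumulated into two vectors so the whole
    gradient costs two sparse transpose matvecs regardless of term count:

        grad = D^T (r_dose - v * num / den^2) + (L*D)^T (v / den)

    where v holds the LET-term residuals 2*(p/N)*H*(letd - L0).
    """
    den = inf.D @ w
    need_let = any(t.quantity == "letd" for t in compiled)
    if need_let:
        num = inf.dl @ w
        pos = den > 0.0
        letd = np.where(pos, num / np.where(pos, den, 1.0), 0.0)
    value = 0.0
    terms: dict[str, float] = {}
    r_dose = np.zeros_like(den) if want_grad else None
    v_let = np.zeros_like(den) if want_grad else None

    for t in compiled:
        rows = t.rows
        if t.quantity == "dose":
            resid = den[rows] - t.goal
            if t.sense == "uniform":
                gate = np.ones_like(resid, dtype=bool)
            elif t.sense == "max":
                gate = resid > 0
            elif t.sense == "min":
                gate = resid < 0
            else:  # max_dvh: penalize overshooters closest to the level
                over = np.flatnonzero(resid > 0)
                gate = np.zeros_like(resid, dtype=bool)
                allowed = int(np.floor(t.volume_fraction * rows.size))
                if over.size > allowed:
                    order = over[np.argsort(resid[over])]
                    gate[order[: over.size - allowed]] = True
            tv = t.weight * float(np.sum(resid[gate] ** 2))
            value += tv
            terms[t.label] = tv
            if want_grad:
                contrib = np.zeros_like(resid)
                contrib[gate] = 2.0 * t.weight * resid[gate]
                r_dose[rows] += contrib  # rows are unique within a term
        else:  # letd
            sub_pos = pos[rows]
            lsub = letd[rows]
            resid = lsub - t.goal
            if t.sense == "min":
                gate = (resid < 0) & sub_pos
            elif t.sense == "max":
                gate = (resid > 0) & sub_pos
            else:  # pragma: no cover - blocked by ObjectiveTerm validation
                raise ConfigurationError("uniform sense is dose-only")
            tv = t.weight * float(np.sum(resid[gate] ** 2))
            value += tv
            terms[t.label] = tv
            if want_grad:
                contrib = np.zeros_like(resid)
                contrib[gate] = 2.0 * t.weight * resid[gate]
                v_let[rows] += contrib

    if not want_grad:
        return value, terms, None
    grad_vox_d = r_dose
    if need_let and np.any(v_let):
        safe_den = np.where(den > 0.0, den, 1.0)
        grad = inf.D.T @ (grad_vox_d - v_let * num / safe_den**2) + inf.dl.T @ (
            v_let / safe_den
        )
    else:
        grad = inf.D.T @ grad_vox_d
    return value, terms, grad


def objective_value(
    weights, objectives: ObjectiveSet, inf: InfluencePair, rois: Mapping[str, ROIMask]
) -> float:
    """Evaluate the planning objective at a weight vector."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (inf.n_spots,):
        raise ContractViolation("weight length must equal the spot count")
    if np.any(w < 0):
        raise ContractViolation("weights must be >= 0")
    value, _, _ = _eval(w, _compile(objectives, inf, rois), inf, want_grad=False)
    return value


def objective_gradient(
    weights, objectives: ObjectiveSet, inf: InfluencePair, rois: Mapping[str, ROIMask]
) -> np.ndarray:
    """Exact analytic gradient of :func:`objective_value` w.r.t. the weights."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ContractViolation("weights must be >= 0")
    _, _, grad = _eval(w, _compile(objectives, inf, rois), inf, want_grad=True)
    return grad


def init_weights(
    inf: InfluencePair,
    rois: Mapping[str, ROIMask],
    target_roi: str,
    prescription_gy: float,
) -> np.ndarray:
    """Uniform weights scaled so the mean target dose equals the prescription."""
    rows = inf.rows_for_mask(rois[target_roi].mask)
    if rows.size == 0:
        raise PlanningError(f"target {target_roi!r} scores no voxels")
    ones = np.ones(inf.n_spots)
    mean_dose = float((inf.D @ ones)[rows].mean())
    if mean_dose <= 0:
        raise PlanningError("unit-weight plan deposits no dose in the target")
    return ones * (prescription_gy / mean_dose)


def solve_weights(
    inf: InfluencePair,
    objectives: ObjectiveSet,
    rois: Mapping[str, ROIMask],
    init: np.ndarray,
    lower_bound: float = 0.0,
    max_iterations: int = 200,
    tolerance: float = 1e-6,
) -> tuple[np.ndarray, OptimizerReport]:
    """Bound-constrained quasi-Newton descent (L-BFGS-B) on the objective.

    Deterministic given the initial point and settings; the returned
    objective never exceeds the initial one.
    """
    w0 = np.asarray(init, dtype=float)
    if np.any(w0 < lower_bound - 1e-12):
        raise ContractViolation("initial weights must satisfy the lower bound")
    compiled = _compile(objectives, inf, rois, planning=True)

    trace: list[float] = []
    last: dict = {"w": None, "f": None}

    def fun(w):
        value, _, grad = _eval(w, compiled, inf, want_grad=True)
        if not np.isfinite(value) or not np.all(np.isfinite(grad)):
            raise NumericalError(
                f"non-finite objective at iterate |w|={np.linalg.norm(w):.3e}"
            )
        last["w"], last["f"] = w.copy(), value
        return value, grad

    def on_iterate(wk):
        # the accepted iterate is normally the last point fun evaluated;
        # reuse its value instead of paying an extra objective evaluation
        if last["w"] is not None and np.array_equal(wk, last["w"]):
            trace.append(last["f"])
        else:
            trace.append(_eval(wk, compiled, inf, False)[0])

    f0, _, _ = _eval(w0, compiled, inf, want_grad=False)
    trace.append(f0)

    res = sciopt.minimize(
        fun,
        w0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(lower_bound, None)] * w0.size,
        callback=on_iterate,
        options={"maxiter": max_iterations, "ftol": tolerance, "gtol": 1e-10},
    )
    w_star = np.maximum(res.x, lower_bound)
    f_star, term_values, _ = _eval(w_star, compiled, inf, want_grad=False)
    if f_star > f0:  # line-search pathologies: fall back to the start point
        w_star, f_star = w0, f0
    report = OptimizerReport(
        iterations=int(res.nit),
        objective_trace=trace,
        converged=bool(res.success),
        term_values=term_values,
        message=str(res.message),
    )
    log.info(
        "solve_weights: %d iters, objective %.4e -> %.4e (%s)",
        res.nit, f0, f_star, res.message,
    )
    return w_star, report


def deliverable_postprocess(
    weights: np.ndarray,
    inf: InfluencePair,
    objectives: ObjectiveSet,
    rois: Mapping[str, ROIMask],
    min_mu: float = 0.02,
    max_iterations: int = 100,
    tolerance: float = 1e-6,
) -> tuple[np.ndarray, OptimizerReport]:
    """Enforce the minimum-MU constraint and re-optimize the survivors.

    Spots below ``min_mu`` are removed (weight 0); the remaining spots
    are re-optimized with the lower bound active, so every returned
    weight is either 0 or >= ``min_mu``.
    """
    w = np.asarray(weights, dtype=float)
    keep = w >= min_mu
    if not keep.any():
        raise PlanningError("deliverable post-processing removed every spot")
    f_before = objective_value(w, objectives, inf, rois)

    sub = InfluencePair(
        inf.D[:, keep].tocsc(), inf.L[:, keep].tocsc(), inf.voxel_index, inf.shape
    )
    w_sub, report = solve_weights(
        sub,
        objectives,
        rois,
        init=np.maximum(w[keep], min_mu),
        lower_bound=min_mu,
        max_iterations=max_iterations,
        tolerance=tolerance,
    )
    out = np.zeros_like(w)
    out[keep] = w_sub
    f_after = objective_value(out, objectives, inf, rois)
    log.info(
        "deliverable: kept %d/%d spots, objective %.4e -> %.4e",
        int(keep.sum()), w.size, f_before, f_after,
    )
    report.message = (
        f"deliverable: removed {int((~keep).sum())} spots below {min_mu} MU; "
        f"objective {f_before:.4e} -> {f_after:.4e}"
    )
    return out, report


def tune_let_penalties(
    inf: InfluencePair,
    objectives: ObjectiveSet,
    rois: Mapping[str, ROIMask],
    target_roi: str,
    prescription_gy: float,
    init: np.ndarray,
    schedule: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0),
    d95_degradation: float = 0.01,
    **solver_kwargs,
) -> tuple[float, np.ndarray, OptimizerReport]:
    """Ramp LET penalties until target D95 degrades beyond the allowance.

    Dose penalties stay fixed; LET penalties are scaled by each factor in
    ``schedule`` in turn, and the largest factor whose solution keeps
    target D95 within ``d95_degradation`` of the dose-only solution wins.
    Returns (chosen factor, weights, report).
    """
    rows = inf.rows_for_mask(rois[target_roi].mask)
    w_ref, rep_ref = solve_weights(
        inf, objectives.with_let_penalties_zeroed(), rois, init, **solver_kwargs
    )
    d95_ref = float(np.percentile((inf.D @ w_ref)[rows], 5))
    best = (0.0, w_ref, rep_ref)
    for factor in schedule:
        w_f, rep_f = solve_weights(
            inf, objectives.scale_let_penalties(factor), rois, init, **solver_kwargs
        )
        d95 = float(np.percentile((inf.D @ w_f)[rows], 5))
        if d95 >= d95_ref * (1.0 - d95_degradation):
            best = (factor, w_f, rep_f)
        else:
            break
    log.info("tune_let_penalties: chose factor %.3g", best[0])
    return best
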