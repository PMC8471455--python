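"""Two-stage estimation of PK parameters and IVIVE scaling factors.

Stage 1 fits the systemic parameters (``V_d``, ``k_el`` and, for
extravascular dosing, ``k_a``) to the plasma profile with all scaling
factors held at one — brain and CSF fluxes are a small perturbation of the
plasma balance, so the systemic parameters are essentially plasma-determined.
Stage 2 then fixes the systemic parameters and fits ``SC1``–``SC3`` jointly
to the plasma and brain (and CSF, when present) profiles. The scaling
factors are optimised in natural-log space, which enforces positivity and
matches their roughly multiplicative role; stage 2 uses a seeded multi-start
(log-uniform) because the objective can be multi-modal when efflux and
binding trade off against each other.

Residuals are relative by default (observed profiles span orders of
magnitude between plasma and brain), with log and unweighted alternatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import InvalidInputError
from .neuropk import InVitroPermeability
from .pbpk import (
    DosingMode,
    DrugParams,
    Profile,
    ScalingFactors,
    infer_dosing,
    simulate,
)
from .physiology import DEFAULT_PHYSIOLOGY, Physiology

__all__ = [
    "FitSpec",
    "FitResult",
    "objective",
    "residuals",
    "fit_plasma",
    "fit_scaling_factors",
    "vd_from_human",
    "ka_initial_from_kel",
]

_PK_NAMES = ("v_d", "k_el", "k_a")
_SC_NAMES = ("sc1", "sc2", "sc3")
_SC_LOG_BOUND = 14.0  # |ln SC| bound; covers the observed 0.01 - 2400 range


@dataclass
class FitSpec:
    """What to fit, from where, and how to weight the residuals."""

    free_params: tuple[str, ...]
    initial_values: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    weighting: str = "relative"  # relative | log | uniform
    multi_start: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        known = set(_PK_NAMES) | set(_SC_NAMES)
        for name in self.free_params:
            if name not in known:
                raise InvalidInputError(f"unknown parameter: {name}")
        for name in self.free_params:
            self.initial_values.setdefault(
                name, 1.0 if name in _SC_NAMES else np.nan
            )
            lo, hi = self.bounds.setdefault(
                name,
                (np.exp(-_SC_LOG_BOUND), np.exp(_SC_LOG_BOUND))
                if name in _SC_NAMES
                else (1e-12, np.inf),
            )
            x0 = self.initial_values[name]
            if np.isfinite(x0) and not (lo <= x0 <= hi):
                raise InvalidInputError(f"initial value of {name} outside bounds")
        if self.weighting not in ("relative", "log", "uniform"):
            raise InvalidInputError(f"unknown weighting: {self.weighting}")


@dataclass
class FitResult:
    estimates: dict[str, float]
    objective_value: float
    converged: bool
    residuals: np.ndarray
    message: str = ""
    flags: tuple[str, ...] = ()


def _match(observed: Sequence[Profile], simulated: Mapping) -> list[tuple[Profile, np.ndarray]]:
    pairs = []
    for obs in observed:
        if obs.key not in simulated:
            raise InvalidInputError(f"no simulated counterpart for {obs.key}")
        pairs.append((obs, simulated[obs.key].values))
    return pairs


def residuals(
    params: Mapping[str, float],
    observed: Sequence[Profile],
    drug: DrugParams,
    perm: InVitroPermeability,
    phys: Physiology,
    dosing: DosingMode,
    spec: FitSpec,
) -> np.ndarray:
    """Weighted residual vector (simulation minus observation)."""
    if not observed:
        raise InvalidInputError("empty observation set")
    drug = replace(
        drug,
        v_d=params.get("v_d", drug.v_d),
        k_el=params.get("k_el", drug.k_el),
        k_a=params.get("k_a", drug.k_a),
    )
    sc = ScalingFactors(
        sc1=params.get("sc1", 1.0),
        sc2=params.get("sc2", 1.0),
        sc3=params.get("sc3", 1.0),
    )
    # infusion duration depends on dose/k_0 only, so the dosing mode is fixed
    out = []
    for obs in observed:
        sim = simulate(
            drug, perm, sc, phys, dosing, obs.times, method="analytic"
        )[obs.key]
        pred, y = sim.values, obs.values
        if spec.weighting == "relative":
            floor = 1e-3 * max(float(np.max(y)), 1e-300)
            out.append((pred - y) / np.maximum(y, floor))
        elif spec.weighting == "log":
            floor = 1e-9 * max(float(np.max(y)), 1e-300)
            out.append(np.log(np.maximum(pred, floor))
                       - np.log(np.maximum(y, floor)))
        else:
            out.append(pred - y)
    return np.concatenate(out)


def objective(
    params: Mapping[str, float],
    observed: Sequence[Profile],
    drug: DrugParams,
    perm: InVitroPermeability,
    phys: Physiology,
    dosing: DosingMode,
    spec: FitSpec,
) -> float:
    """Sum of weighted squared residuals over all matched profiles."""
    r = residuals(params, observed, drug, perm, phys, dosing, spec)
    return float(r @ r)


def fit_plasma(
    observed_plasma: Profile,
    drug: DrugParams,
    dosing: DosingMode | None = None,
    spec: FitSpec | None = None,
    perm: InVitroPermeability | None = None,
    phys: Physiology = DEFAULT_PHYSIOLOGY,
) -> tuple[DrugParams, FitResult]:
    """Stage 1: fit (V_d, k_el[, k_a]) to the plasma profile with SCs = 1.

    Initial values default to the drug's nominal parameters; a missing k_a
    initial is seeded as twice the elimination constant (a serviceable rule
    of thumb for absorption-rate starts). Returns the updated DrugParams
    together with the optimiser diagnostics.
    """
    if dosing is None:
        dosing = infer_dosing(drug)
    if spec is None:
        free = ["v_d", "k_el"]
        if drug.k_a is not None:
            free.append("k_a")
        spec = FitSpec(free_params=tuple(free))
    n_free = len(spec.free_params)
    if observed_plasma.times.size < 2 * n_free:
        raise InvalidInputError(
            f"need at least {2 * n_free} plasma points to fit {n_free} parameters"
        )
    if perm is None:
        # plasma-only stage: any positive permeability works since SCs are 1;
        # use a neutral, slow membrane so CNS fluxes stay a perturbation
        perm = InVitroPermeability(papp_ab=1e-6, papp_ba=1e-6, fu_brain=1.0)

    x0 = []
    for name in spec.free_params:
        v = spec.initial_values.get(name, np.nan)
        if not np.isfinite(v):
            v = {
                "v_d": drug.v_d,
                "k_el": drug.k_el,
                "k_a": drug.k_a if drug.k_a is not None
                else ka_initial_from_kel(drug.k_el),
            }[name]
        x0.append(np.log(v))
    lo = [np.log(spec.bounds[n][0]) for n in spec.free_params]
    hi = [np.log(min(spec.bounds[n][1], 1e30)) for n in spec.free_params]

    def fun(logx: np.ndarray) -> np.ndarray:
        params = dict(zip(spec.free_params, np.exp(logx)))
        return residuals(params, [observed_plasma], drug, perm, phys, dosing, spec)

    sol = least_squares(fun, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    estimates = dict(zip(spec.free_params, np.exp(sol.x)))
    fitted = replace(
        drug,
        v_d=estimates.get("v_d", drug.v_d),
        k_el=estimates.get("k_el", drug.k_el),
        k_a=estimates.get("k_a", drug.k_a),
    )
    result = FitResult(
        estimates=estimates,
        objective_value=float(2 * sol.cost),
        converged=bool(sol.success),
        residuals=sol.fun,
        message=sol.message,
    )
    return fitted, result


def fit_scaling_factors(
    observed: Sequence[Profile],
    drug: DrugParams,
    perm: InVitroPermeability,
    phys: Physiology = DEFAULT_PHYSIOLOGY,
    dosing: DosingMode | None = None,
    spec: FitSpec | None = None,
) -> FitResult:
    """Stage 2: fit SC1-SC3 in log-space to plasma + brain (+ CSF) profiles.

    SC3 rescales the homogenate f_u,brain and is cleanly identified only
    when a total-brain observation constrains C_b while an unbound-brain (or
    plasma backflux) observation constrains SC3*f_u*C_b; with purely unbound
    brain data it trades off against SC2 and the fit reports a
    ``"sc3 weakly identified"`` flag.
    """
    if dosing is None:
        dosing = infer_dosing(drug)
    if spec is None:
        spec = FitSpec(free_params=("sc1", "sc2", "sc3"))
    if not any(p.compartment in ("brain", "csf") for p in observed):
        raise InvalidInputError("need at least one brain or CSF profile")

    flags: list[str] = []
    free = list(spec.free_params)
    brain_keys = {p.key for p in observed if p.compartment == "brain"}
    fixed_sc3 = spec.initial_values.get("sc3", 1.0)
    if "sc3" in free and not brain_keys:
        # CSF-only data: the observation model never sees SC3, hold it fixed
        free.remove("sc3")
        flags.append("sc3 held at initial (no brain observation)")
    elif "sc3" in free and ("brain", "total") not in brain_keys:
        warnings.warn("sc3 weakly identified from unbound-only brain data",
                      stacklevel=2)
        flags.append("sc3 weakly identified")

    x0 = np.array([np.log(spec.initial_values.get(n, 1.0)) for n in free])
    lo = np.array([np.log(spec.bounds[n][0]) for n in free])
    hi = np.array([np.log(spec.bounds[n][1]) for n in free])

    def fun(logx: np.ndarray) -> np.ndarray:
        params = dict(zip(free, np.exp(logx)))
        params.setdefault("sc3", fixed_sc3)
        return residuals(params, observed, drug, perm, phys, dosing, spec)

    rng = np.random.default_rng(spec.seed)
    starts = [x0]
    for _ in range(max(0, spec.multi_start - 1)):
        starts.append(rng.uniform(np.log(1e-3), np.log(1e3), size=len(free)))

    best = None
    for start in starts:
        sol = least_squares(fun, start, bounds=(lo, hi), method="trf",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    estimates = dict(zip(free, np.exp(best.x)))
    return FitResult(
        estimates=estimates,
        objective_value=float(2 * best.cost),
        converged=bool(best.success),
        residuals=best.fun,
        message=best.message,
        flags=tuple(flags),
    )


def vd_from_human(vd_per_kg: float, rat_weight: float) -> float:
    """Allometric volume: human V_d in cm^3/kg scaled by rat weight in g."""
    if vd_per_kg <= 0 or rat_weight <= 0:
        raise InvalidInputError("vd_per_kg and rat_weight must be > 0")
    return vd_per_kg * rat_weight / 1000.0


def ka_initial_from_kel(k_el: float) -> float:
    """Absorption-rate starting value: twice the elimination constant."""
    if k_el <= 0:
        raise InvalidInputError("k_el must be > 0")
    return 2.0 * k_el
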