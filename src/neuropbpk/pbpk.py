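"""Semi-physiological plasma / brain / CSF model with IVIVE scaling.

The rat CNS is reduced to three well-stirred compartments — plasma (volume
``V_d``), brain tissue (``V_b``) and CSF (``V_CSF``). Unbound drug exchanges
across the BBB and the BCSFB with permeability-surface products obtained by
scaling the in vitro transwell permeabilities:

    PS_BBB,in   = SC1 * Papp(A->B) * S_BBB
    PS_BCSFB,in = SC1 * Papp(A->B) * S_BCSFB
    PS_BBB,out  = SC2 * Papp(B->A) * S_BBB
    PS_BCSFB,out= SC2 * Papp(B->A) * S_BCSFB

Brain ECF bulk flow ``Q_bulk`` carries unbound drug from tissue to CSF and
CSF drainage ``Q_sink`` returns it to plasma. Unbound concentrations are
``C_u,p = f_u,plasma * C_p`` in plasma and ``C_u,b = SC3 * f_u,brain * C_b``
in brain; CSF drug is treated as entirely unbound. Elimination is first
order from plasma only (``k_el``). Dosing is an IV bolus (initial condition
``C_p(0) = D/V_d``), a zero-order infusion ``k_0`` active for ``D/k_0``
seconds (or the whole window when no total dose is given), or first-order
absorption ``k_a`` from a depot holding the dose.

The resulting ODE system is linear and time-invariant (piecewise across the
infusion switch), so next to the stiff-capable numerical integrator a
matrix-exponential propagator provides machine-precision solutions; the two
are interchangeable and cross-checked in the test-suite.

All quantities are in ng, cm^3 and s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .errors import InvalidInputError, SolverError
from .neuropk import InVitroPermeability
from .physiology import DEFAULT_PHYSIOLOGY, Physiology

__all__ = [
    "DrugParams",
    "ScalingFactors",
    "ClearanceSet",
    "DoseKind",
    "DosingMode",
    "StateVector",
    "Profile",
    "build_clearances",
    "infer_dosing",
    "rhs",
    "system_matrices",
    "simulate",
    "analytic_solution",
]

# State layout: [A_depot, C_p, C_b, C_csf, A_eliminated]
_IDX_DEPOT, _IDX_P, _IDX_B, _IDX_CSF, _IDX_ELIM = range(5)


@dataclass(frozen=True)
class DrugParams:
    """Systemic PK and dosing description of one drug (rat)."""

    name: str
    fu_plasma: float
    v_d: float  # cm^3
    k_el: float  # 1/s
    k_a: float | None = None  # 1/s
    dose: float | None = None  # ng
    k_0: float | None = None  # ng/s
    rat_weight: float | None = None  # g

    def __post_init__(self) -> None:
        if not (0 < self.fu_plasma <= 1):
            raise InvalidInputError("fu_plasma must lie in (0, 1]")
        if self.v_d <= 0 or self.k_el <= 0:
            raise InvalidInputError("v_d and k_el must be > 0")
        if self.dose is None and self.k_0 is None:
            raise InvalidInputError("at least one of dose, k_0 is required")


@dataclass(frozen=True)
class ScalingFactors:
    """Empirical in vitro -> in vivo scaling factors.

    SC1 scales the influx permeability, SC2 the efflux permeability, and SC3
    corrects the homogenate-derived f_u,brain; all were unity before fitting.
    """

    sc1: float = 1.0
    sc2: float = 1.0
    sc3: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sc1, self.sc2, self.sc3) <= 0:
            raise InvalidInputError("scaling factors must be > 0")


@dataclass(frozen=True)
class ClearanceSet:
    """Permeability-surface products (cm^3/s) across the two barriers."""

    ps_bbb_in: float
    ps_bbb_out: float
    ps_bcsfb_in: float
    ps_bcsfb_out: float

    def __post_init__(self) -> None:
        if min(self.ps_bbb_in, self.ps_bbb_out, self.ps_bcsfb_in,
               self.ps_bcsfb_out) <= 0:
            raise InvalidInputError("clearances must be > 0")


class DoseKind(str, Enum):
    IV_BOLUS = "iv_bolus"
    IV_INFUSION = "iv_infusion"
    EXTRAVASCULAR = "extravascular"


@dataclass(frozen=True)
class DosingMode:
    """Administration route; infusion_duration is D/k_0 when the total dose
    is known, else None (infusion active for the whole window)."""

    kind: DoseKind
    infusion_duration: float | None = None


@dataclass(frozen=True)
class StateVector:
    """Amounts/concentrations of the full system at one instant."""

    a_depot: float
    c_p: float
    c_b: float
    c_csf: float
    a_eliminated: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.a_depot, self.c_p, self.c_b, self.c_csf, self.a_eliminated]
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "StateVector":
        return cls(*map(float, y))


@dataclass
class Profile:
    """Concentration-time series for one compartment and observation kind."""

    times: np.ndarray
    values: np.ndarray
    compartment: str  # plasma | brain | csf
    observed_as: str  # total | unbound

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise InvalidInputError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise InvalidInputError("concentrations must be non-negative")

    @property
    def key(self) -> tuple[str, str]:
        return (self.compartment, self.observed_as)


def build_clearances(
    perm: InVitroPermeability,
    sc: ScalingFactors,
    phys: Physiology = DEFAULT_PHYSIOLOGY,
) -> ClearanceSet:
    """Scale in vitro permeabilities to in vivo PS products (cm^3/s)."""
    return ClearanceSet(
        ps_bbb_in=sc.sc1 * perm.papp_ab * phys.s_bbb,
        ps_bcsfb_in=sc.sc1 * perm.papp_ab * phys.s_bcsfb,
        ps_bbb_out=sc.sc2 * perm.papp_ba * phys.s_bbb,
        ps_bcsfb_out=sc.sc2 * perm.papp_ba * phys.s_bcsfb,
    )


def infer_dosing(drug: DrugParams) -> DosingMode:
    """Choose the administration route the drug's parameters imply.

    An absorption constant with a dose means extravascular input; an
    infusion rate means a zero-order infusion (of duration D/k_0 when the
    total dose is also given); a bare dose means an IV bolus.
    """
    if drug.k_a is not None and drug.dose is not None:
        return DosingMode(DoseKind.EXTRAVASCULAR)
    if drug.k_0 is not None:
        duration = None if drug.dose is None else drug.dose / drug.k_0
        return DosingMode(DoseKind.IV_INFUSION, infusion_duration=duration)
    if drug.dose is not None:
        return DosingMode(DoseKind.IV_BOLUS)
    raise InvalidInputError("cannot infer dosing mode from drug parameters")


def system_matrices(
    drug: DrugParams,
    clear: ClearanceSet,
    sc3: float,
    fu_brain: float,
    phys: Physiology,
    dosing: DosingMode,
    *,
    infusing: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Constant-coefficient form dy/dt = M y + b of the model equations.

    ``infusing`` selects whether the zero-order source term is active; the
    depot row is present for every mode (it simply stays zero when unused).
    """
    fu_p = drug.fu_plasma
    fb = sc3 * fu_brain
    m = np.zeros((5, 5))
    b = np.zeros(5)

    if dosing.kind == DoseKind.EXTRAVASCULAR:
        if drug.k_a is None:
            raise InvalidInputError("extravascular dosing requires k_a")
        m[_IDX_DEPOT, _IDX_DEPOT] = -drug.k_a
        m[_IDX_P, _IDX_DEPOT] = drug.k_a / drug.v_d
    elif dosing.kind == DoseKind.IV_INFUSION:
        if drug.k_0 is None:
            raise InvalidInputError("infusion dosing requires k_0")
        if infusing:
            b[_IDX_P] = drug.k_0 / drug.v_d
    elif dosing.kind != DoseKind.IV_BOLUS:
        raise InvalidInputError(f"unknown dosing kind: {dosing.kind}")

    # plasma
    m[_IDX_P, _IDX_P] += (
        -(clear.ps_bbb_in + clear.ps_bcsfb_in) * fu_p / drug.v_d - drug.k_el
    )
    m[_IDX_P, _IDX_B] += clear.ps_bbb_out * fb / drug.v_d
    m[_IDX_P, _IDX_CSF] += (clear.ps_bcsfb_out + phys.q_sink) / drug.v_d
    # brain tissue
    m[_IDX_B, _IDX_P] = clear.ps_bbb_in * fu_p / phys.v_b
    m[_IDX_B, _IDX_B] = -(clear.ps_bbb_out + phys.q_bulk) * fb / phys.v_b
    # CSF
    m[_IDX_CSF, _IDX_P] = clear.ps_bcsfb_in * fu_p / phys.v_csf
    m[_IDX_CSF, _IDX_B] = phys.q_bulk * fb / phys.v_csf
    m[_IDX_CSF, _IDX_CSF] = -(clear.ps_bcsfb_out + phys.q_sink) / phys.v_csf
    # elimination ledger (bookkeeping state, closes the mass balance)
    m[_IDX_ELIM, _IDX_P] = drug.k_el * drug.v_d
    return m, b


def rhs(
    state: StateVector | np.ndarray,
    drug: DrugParams,
    clear: ClearanceSet,
    sc3: float,
    fu_brain: float,
    phys: Physiology,
    dosing: DosingMode,
    t: float = 0.0,
) -> np.ndarray:
    """Time derivative of the state under the given dosing mode."""
    y = state.to_array() if isinstance(state, StateVector) else np.asarray(state)
    infusing = dosing.kind == DoseKind.IV_INFUSION and (
        dosing.infusion_duration is None or t < dosing.infusion_duration
    )
    m, b = system_matrices(drug, clear, sc3, fu_brain, phys, dosing,
                           infusing=infusing)
    return m @ y + b


def _initial_state(drug: DrugParams, dosing: DosingMode) -> np.ndarray:
    y0 = np.zeros(5)
    if dosing.kind == DoseKind.IV_BOLUS:
        if drug.dose is None:
            raise InvalidInputError("bolus dosing requires a dose")
        y0[_IDX_P] = drug.dose / drug.v_d
    elif dosing.kind == DoseKind.EXTRAVASCULAR:
        if drug.dose is None:
            raise InvalidInputError("extravascular dosing requires a dose")
        y0[_IDX_DEPOT] = drug.dose
    return y0


def _segments(times: np.ndarray, dosing: DosingMode) -> list[tuple[float, float, bool]]:
    """Split [0, t_end] at the infusion switch: (t0, t1, infusing) pieces.

    Integration always starts at t=0 (where the initial state is defined),
    regardless of the first requested sample time.
    """
    t0, t1 = 0.0, float(times[-1])
    if dosing.kind != DoseKind.IV_INFUSION:
        return [(t0, t1, False)]
    t_inf = dosing.infusion_duration
    if t_inf is None or t_inf >= t1:
        return [(t0, t1, True)]
    if t_inf <= t0:
        return [(t0, t1, False)]
    return [(t0, t_inf, True), (t_inf, t1, False)]


def _propagate_expm(
    y0: np.ndarray,
    times: np.ndarray,
    drug: DrugParams,
    clear: ClearanceSet,
    sc3: float,
    fu_brain: float,
    phys: Physiology,
    dosing: DosingMode,
) -> np.ndarray:
    """Exact piecewise solution via the exponential of the augmented matrix."""
    out = np.empty((times.size, 5))
    y = y0.copy()
    cursor = 0
    for t0, t1, infusing in _segments(times, dosing):
        m, b = system_matrices(drug, clear, sc3, fu_brain, phys, dosing,
                               infusing=infusing)
        aug = np.zeros((6, 6))
        aug[:5, :5] = m
        aug[:5, 5] = b
        seg_times = times[(times >= t0) & (times <= t1)]
        # walk the sorted sample times inside this segment
        t_prev = t0
        for t in seg_times:
            if t > t_prev:
                phi = expm(aug * (t - t_prev))
                y = phi[:5, :5] @ y + phi[:5, 5]
                t_prev = t
            out[cursor] = y
            cursor += 1
        if t1 > t_prev:  # advance to the segment boundary for the next piece
            phi = expm(aug * (t1 - t_prev))
            y = phi[:5, :5] @ y + phi[:5, 5]
    # duplicate boundary time may appear in both segments; guard by cursor
    if cursor != times.size:
        raise SolverError("internal time bookkeeping error in propagator")
    return out


def _states_to_profiles(
    times: np.ndarray,
    states: np.ndarray,
    drug: DrugParams,
    sc3: float,
    fu_brain: float,
) -> dict[tuple[str, str], Profile]:
    c_p = states[:, _IDX_P]
    c_b = states[:, _IDX_B]
    c_csf = states[:, _IDX_CSF]
    clip = lambda v: np.clip(v, 0.0, None)
    return {
        ("plasma", "total"): Profile(times, clip(c_p), "plasma", "total"),
        ("plasma", "unbound"): Profile(times, clip(drug.fu_plasma * c_p),
                                       "plasma", "unbound"),
        ("brain", "total"): Profile(times, clip(c_b), "brain", "total"),
        ("brain", "unbound"): Profile(times, clip(sc3 * fu_brain * c_b),
                                      "brain", "unbound"),
        ("csf", "total"): Profile(times, clip(c_csf), "csf", "total"),
        ("csf", "unbound"): Profile(times, clip(c_csf), "csf", "unbound"),
    }


def simulate(
    drug: DrugParams,
    perm: InVitroPermeability,
    sc: ScalingFactors,
    phys: Physiology = DEFAULT_PHYSIOLOGY,
    dosing: DosingMode | None = None,
    times: Iterable[float] | None = None,
    *,
    method: str = "ivp",
    rtol: float = 1e-10,
    atol: float | None = None,
    return_states: bool = False,
):
    """Simulate all six concentration profiles at the requested times.

    Parameters
    ----------
    method : {"ivp", "analytic"}
        ``"ivp"`` integrates with a stiff-capable solver (LSODA); the
        ``"analytic"`` path evaluates the exact matrix-exponential solution
        and is preferred inside optimisation loops.
    rtol, atol
        Solver tolerances for the ``"ivp"`` path. ``atol=None`` (default)
        auto-scales the absolute floor to 1e-9 of the dose-derived plasma
        concentration scale, so that even the small CSF compartment is
        resolved to well below 1e-6 relative accuracy.
    return_states : bool
        Also return the raw (n_times, 5) state array.

    Returns
    -------
    dict mapping (compartment, observed_as) to :class:`Profile`, and the
    state array when ``return_states`` is set.
    """
    if dosing is None:
        dosing = infer_dosing(drug)
    if times is None:
        t_end = 5 * np.log(2) / drug.k_el
        times = np.linspace(0.0, t_end, 201)
    times = np.asarray(list(times), dtype=float)
    if times.size < 1 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise InvalidInputError("times must be increasing and start at >= 0")

    clear = build_clearances(perm, sc, phys)
    y0 = _initial_state(drug, dosing)
    if atol is None:
        if drug.dose is not None:
            dose_scale = drug.dose
        else:  # open-ended infusion: amount delivered over the window
            dose_scale = drug.k_0 * max(float(times[-1]), 1.0 / drug.k_el)
        conc_scale = dose_scale / drug.v_d
        atol = np.array([1e-9 * dose_scale] + [1e-9 * conc_scale] * 3
                        + [1e-9 * dose_scale])

    if method == "analytic":
        states = _propagate_expm(y0, times, drug, clear, sc.sc3,
                                 perm.fu_brain, phys, dosing)
    elif method == "ivp":
        states = np.empty((times.size, 5))
        y = y0.copy()
        cursor = 0
        for t0, t1, infusing in _segments(times, dosing):
            m, b = system_matrices(drug, clear, sc.sc3, perm.fu_brain, phys,
                                   dosing, infusing=infusing)
            n_seg = int(np.searchsorted(times, t1, side="right") - cursor)
            seg_times = times[cursor:cursor + n_seg]
            if cursor == 0 and seg_times.size and seg_times[0] == t0:
                states[0] = y  # initial state is exact, no integration needed
                cursor += 1
                seg_times = seg_times[1:]
            t_eval = np.append(seg_times, t1) if (not seg_times.size
                                                  or seg_times[-1] < t1) \
                else seg_times
            if t1 > t0:
                sol = solve_ivp(
                    lambda t, y: m @ y + b,
                    (t0, t1), y,
                    t_eval=t_eval, method="LSODA", rtol=rtol, atol=atol,
                )
                if not sol.success:
                    raise SolverError(f"integration failed: {sol.message}")
                states[cursor:cursor + seg_times.size] = \
                    sol.y[:, :seg_times.size].T
                cursor += seg_times.size
                y = sol.y[:, -1]
        if cursor != times.size:
            raise SolverError("solver did not report all requested times")
    else:
        raise InvalidInputError(f"unknown method: {method}")

    conc = states[:, [_IDX_P, _IDX_B, _IDX_CSF]]
    floor = -1e-9 * max(conc.max(initial=0.0), 1.0)
    if conc.min(initial=0.0) < floor:
        raise SolverError(
            "negative concentrations beyond tolerance; "
            "solver settings need tightening"
        )

    profiles = _states_to_profiles(times, states, drug, sc.sc3, perm.fu_brain)
    if return_states:
        return profiles, states
    return profiles


def analytic_solution(
    drug: DrugParams,
    perm: InVitroPermeability,
    sc: ScalingFactors,
    phys: Physiology = DEFAULT_PHYSIOLOGY,
    dosing: DosingMode | None = None,
    t: float = 0.0,
) -> StateVector:
    """Exact state at time ``t`` via the matrix exponential (test oracle)."""
    if dosing is None:
        dosing = infer_dosing(drug)
    clear = build_clearances(perm, sc, phys)
    y0 = _initial_state(drug, dosing)
    if t == 0:
        return StateVector.from_array(y0)
    times = np.array([0.0, float(t)])
    states = _propagate_expm(y0, times, drug, clear, sc.sc3, perm.fu_brain,
                             phys, dosing)
    return StateVector.from_array(states[-1])


def administered(drug: DrugParams, dosing: DosingMode, t: np.ndarray) -> np.ndarray:
    """Cumulative drug input (ng) up to each time, for mass-balance checks."""
    t = np.asarray(t, dtype=float)
    if dosing.kind in (DoseKind.IV_BOLUS, DoseKind.EXTRAVASCULAR):
        return np.full_like(t, float(drug.dose))
    t_inf = dosing.infusion_duration
    active = t if t_inf is None else np.minimum(t, t_inf)
    return drug.k_0 * active


def total_in_system(
    states: np.ndarray, drug: DrugParams, phys: Physiology
) -> np.ndarray:
    """Total amount (ng) across depot, compartments and elimination ledger."""
    return (
        states[:, _IDX_DEPOT]
        + states[:, _IDX_P] * drug.v_d
        + states[:, _IDX_B] * phys.v_b
        + states[:, _IDX_CSF] * phys.v_csf
        + states[:, _IDX_ELIM]
    )


def with_scaling(drug: DrugParams, **overrides) -> DrugParams:
    """Convenience: copy a DrugParams with selected fields replaced."""
    return replace(drug, **overrides)
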