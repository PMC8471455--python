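"""NeuroPK parameters from transwell permeability assays.

A confluent monolayer (MDCK, MDCK-MDR1 or hCMEC/D3) grown on a transwell
insert separates a donor from a receiver chamber. Under sink conditions the
cumulative amount in the receiver grows linearly in time and the apparent
permeability is

    Papp = (dQ/dt) / (A * C0)          [cm/s]

with A the insert area and C0 the initial donor concentration. Three assay
conditions are used:

* A->B (apical donor): surrogate of the influx clearance through the BBB;
* B->A (basolateral donor): surrogate of the efflux clearance;
* HOM (basolateral donor in brain homogenate): only the unbound fraction can
  cross, so the ratio Papp(B->A)/Papp(HOM) estimates f_u,brain.

From these, the three classical neuroPK parameters follow:

* ``Kp_uu,brain = Papp(A->B) / Papp(B->A)`` — ratio of unbound brain to
  unbound plasma exposure at steady state;
* ``f_u,brain`` — unbound drug fraction in brain tissue;
* ``V_u,brain = V_ECF + V_ICF / f_u,brain`` — apparent unbound brain volume
  of distribution (mL/g brain), 0.2 + 0.6/f_u with the default water spaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import InvalidInputError
from .physiology import DEFAULT_PHYSIOLOGY, Physiology

__all__ = [
    "Condition",
    "TranswellRun",
    "InVitroPermeability",
    "NeuroPKParams",
    "PappResult",
    "papp_from_transwell",
    "kpuu_brain",
    "fu_brain_from_papp",
    "vu_brain",
    "derive_neuropk",
]


class Condition(str, Enum):
    """Transwell assay condition (donor side / donor matrix)."""

    AB = "AB"
    BA = "BA"
    HOM = "HOM"


@dataclass
class TranswellRun:
    """One transwell experiment: cumulative receiver amounts over time.

    ``receiver_amounts`` is shaped (replicates, n_times), in ng; sampling
    times are in seconds and strictly increasing; ``donor_conc_0`` is the
    initial donor concentration in ng/cm^3.
    """

    condition: Condition
    donor_conc_0: float
    effective_area: float
    sample_times: np.ndarray
    receiver_amounts: np.ndarray
    donor_volume: float = 2.0  # cm^3; typical 6-well chamber fill

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.receiver_amounts = np.atleast_2d(
            np.asarray(self.receiver_amounts, dtype=float)
        )
        if self.donor_conc_0 <= 0:
            raise InvalidInputError("donor_conc_0 must be > 0")
        if self.effective_area <= 0:
            raise InvalidInputError("effective_area must be > 0")
        if np.any(np.diff(self.sample_times) <= 0):
            raise InvalidInputError("sample_times must be strictly increasing")
        if np.any(self.receiver_amounts < 0):
            raise InvalidInputError("receiver_amounts must be non-negative")
        if self.receiver_amounts.shape[1] != self.sample_times.size:
            raise InvalidInputError(
                "receiver_amounts second axis must match sample_times"
            )

    @property
    def replicate_count(self) -> int:
        return self.receiver_amounts.shape[0]


@dataclass(frozen=True)
class InVitroPermeability:
    """Apparent permeabilities (cm/s) and brain unbound fraction for one
    drug in one cell line."""

    papp_ab: float
    papp_ba: float
    fu_brain: float
    papp_hom: float | None = None

    def __post_init__(self) -> None:
        if self.papp_ab <= 0 or self.papp_ba <= 0:
            raise InvalidInputError("apparent permeabilities must be > 0")
        if not (0 < self.fu_brain <= 1):
            raise InvalidInputError("fu_brain must lie in (0, 1]")
        if self.papp_hom is not None:
            if self.papp_hom <= 0:
                raise InvalidInputError("papp_hom must be > 0")
            if abs(self.fu_brain - self.papp_ba / self.papp_hom) > 1e-9 * self.fu_brain:
                raise InvalidInputError(
                    "fu_brain inconsistent with papp_ba / papp_hom"
                )


@dataclass(frozen=True)
class NeuroPKParams:
    """The three neuroPK parameters plus the influx-clearance surrogate."""

    kpuu_brain: float
    fu_brain: float
    vu_brain: float
    cl_in: float  # alias of papp_ab (cm/s), the in vitro influx surrogate


@dataclass
class PappResult:
    """Papp estimate with a status flag (``ok`` or a warning reason)."""

    value: float
    status: str = "ok"
    slope: float = field(default=np.nan)
    intercept: float = field(default=np.nan)


def papp_from_transwell(
    run: TranswellRun,
    *,
    per_replicate: bool = False,
    sink_fraction_warn: float = 0.10,
) -> PappResult:
    """Estimate the apparent permeability (cm/s) from one transwell run.

    The cumulative receiver amount, averaged over replicates at each sample
    time (or fitted per replicate and averaged, with ``per_replicate=True``),
    is regressed on time with a free intercept; the slope divided by
    (area x donor concentration) is Papp. A non-positive slope yields a
    flagged zero result rather than an error. A warning is emitted when the
    transported fraction exceeds ``sink_fraction_warn`` of the donor load,
    i.e. when the sink assumption behind the linear model is doubtful.
    """
    t = run.sample_times
    if t.size < 2:
        raise InvalidInputError("need at least 2 sample times for a slope")

    def _slope(q: np.ndarray) -> tuple[float, float]:
        design = np.column_stack([np.ones_like(t), t])
        coef, *_ = np.linalg.lstsq(design, q, rcond=None)
        return float(coef[1]), float(coef[0])

    if per_replicate:
        fits = [_slope(rep) for rep in run.receiver_amounts]
        slope = float(np.mean([s for s, _ in fits]))
        intercept = float(np.mean([b for _, b in fits]))
    else:
        slope, intercept = _slope(run.receiver_amounts.mean(axis=0))

    donor_amount = run.donor_conc_0 * run.donor_volume
    if float(run.receiver_amounts.max(initial=0.0)) > sink_fraction_warn * donor_amount:
        warnings.warn(
            "receiver amounts exceed 10% of the donor load; sink-condition "
            "assumption may be violated",
            stacklevel=2,
        )

    if slope <= 0:
        return PappResult(0.0, status="non-positive slope", slope=slope,
                          intercept=intercept)
    papp = slope / (run.effective_area * run.donor_conc_0)
    return PappResult(papp, slope=slope, intercept=intercept)


def kpuu_brain(papp_ab: float, papp_ba: float) -> float:
    """Unbound brain-to-plasma partition coefficient, Papp(A->B)/Papp(B->A)."""
    if papp_ab <= 0 or papp_ba <= 0:
        raise InvalidInputError("permeabilities must be > 0")
    return papp_ab / papp_ba


def fu_brain_from_papp(papp_ba: float, papp_hom: float) -> float:
    """Unbound brain fraction, Papp(B->A)/Papp(HOM).

    The homogenate condition is expected to be the slower of the two (only
    free drug crosses); the reverse ordering is reported as a warning, not an
    error, since assay noise can invert near-unity ratios.
    """
    if papp_ba <= 0 or papp_hom <= 0:
        raise InvalidInputError("permeabilities must be > 0")
    if papp_ba > papp_hom:
        warnings.warn(
            "papp_ba > papp_hom implies fu_brain > 1; check assay pairing",
            stacklevel=2,
        )
    return papp_ba / papp_hom


def vu_brain(fu_brain: float, physiology: Physiology = DEFAULT_PHYSIOLOGY) -> float:
    """Unbound brain volume of distribution, V_ECF + V_ICF/f_u (mL/g)."""
    if fu_brain <= 0:
        raise InvalidInputError("fu_brain must be > 0")
    return physiology.v_ecf + physiology.v_icf / fu_brain


def derive_neuropk(
    perm: InVitroPermeability, physiology: Physiology = DEFAULT_PHYSIOLOGY
) -> NeuroPKParams:
    """Bundle the three neuroPK parameters for one drug x cell line."""
    return NeuroPKParams(
        kpuu_brain=kpuu_brain(perm.papp_ab, perm.papp_ba),
        fu_brain=perm.fu_brain,
        vu_brain=vu_brain(perm.fu_brain, physiology),
        cl_in=perm.papp_ab,
    )


def mean_papp(runs: Sequence[TranswellRun], **kwargs) -> float:
    """Average Papp over several runs of the same condition."""
    if not runs:
        raise InvalidInputError("no runs given")
    return float(np.mean([papp_from_transwell(r, **kwargs).value for r in runs]))
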