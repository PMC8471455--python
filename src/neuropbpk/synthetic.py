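"""Synthetic study generator: every pipeline input with known ground truth.

Real inputs to this pipeline are (a) transwell sampling data and (b) sparse
rat plasma/brain concentration-time profiles from the literature. Neither is
needed to exercise the code: this module generates both from a chosen ground
truth, so estimators can be validated by recovery.

* Transwell runs follow the sink-condition line Q(t) = Papp*A*C0*t, sampled
  at the assay's standard times (15/30/60/90 min) in triplicate, with
  multiplicative noise per sample.
* In vivo profiles are model simulations at the true parameters, sampled
  sparsely (10 plasma / 8 brain points, log-spaced over five elimination
  half-lives, emulating the density of published rat PK studies) with
  multiplicative noise.

Noise is lognormal by default (mean-one, CV exactly as requested) since
assay error is roughly proportional and concentrations are positive; a
proportional-normal option exists for sensitivity checks. All draws are
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidInputError
from .neuropk import Condition, InVitroPermeability, TranswellRun
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
    "SyntheticStudySpec",
    "STANDARD_TRANSWELL_TIMES",
    "gen_transwell",
    "gen_invivo",
    "default_sampling_times",
]

# 15, 30, 60, 90 min in seconds — the standard transwell sampling scheme
STANDARD_TRANSWELL_TIMES = (900.0, 1800.0, 3600.0, 5400.0)


@dataclass
class SyntheticStudySpec:
    """Ground truth plus sampling/noise design for one synthetic study."""

    truth: dict  # (drug, cell_line) -> dict(drug=DrugParams, perm=..., sc=...)
    sampling_times: dict = field(default_factory=dict)  # compartment -> times
    noise_model: str = "lognormal"
    noise_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise InvalidInputError("noise_cv must be >= 0")
        if self.noise_model not in ("lognormal", "proportional-normal"):
            raise InvalidInputError(f"unknown noise model: {self.noise_model}")


def _noise_factors(
    shape, cv: float, model: str, rng: np.random.Generator
) -> np.ndarray:
    """Mean-one multiplicative factors with coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    if model == "lognormal":
        sigma = np.sqrt(np.log1p(cv**2))
        return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=shape))
    if model == "proportional-normal":
        return 1.0 + rng.normal(0.0, cv, size=shape)
    raise InvalidInputError(f"unknown noise model: {model}")


def gen_transwell(
    papp_true: float,
    area: float = 4.2,
    c0: float = 1e6,
    times: Sequence[float] = STANDARD_TRANSWELL_TIMES,
    replicates: int = 3,
    cv: float = 0.05,
    seed: int = 0,
    condition: Condition = Condition.AB,
    noise_model: str = "lognormal",
) -> TranswellRun:
    """Simulate one transwell run under sink conditions.

    Cumulative receiver amounts lie on Q(t) = Papp*A*C0*t, perturbed
    multiplicatively per replicate and sample. Deterministic given seed.
    """
    if papp_true <= 0:
        raise InvalidInputError("papp_true must be > 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    q = papp_true * area * c0 * t  # ng
    factors = _noise_factors((replicates, t.size), cv, noise_model, rng)
    return TranswellRun(
        condition=condition,
        donor_conc_0=c0,
        effective_area=area,
        sample_times=t,
        receiver_amounts=q[None, :] * factors,
    )


def default_sampling_times(
    drug: DrugParams,
    n_plasma: int = 10,
    n_brain: int = 8,
    dosing: DosingMode | None = None,
) -> dict[str, np.ndarray]:
    """Log-spaced sparse schedules over five elimination half-lives."""
    if dosing is None:
        dosing = infer_dosing(drug)
    t_end = 5.0 * np.log(2.0) / drug.k_el
    if dosing.infusion_duration is not None:
        t_end = max(t_end, 1.2 * dosing.infusion_duration)
    t0 = t_end / 200.0
    return {
        "plasma": np.geomspace(t0, t_end, n_plasma),
        "brain": np.geomspace(t0, t_end, n_brain),
        "csf": np.geomspace(t0, t_end, n_brain),
    }


def gen_invivo(
    truth: Mapping,
    dosing: DosingMode | None = None,
    sampling_times: Mapping[str, Sequence[float]] | None = None,
    noise_model: str = "lognormal",
    cv: float = 0.15,
    seed: int = 0,
    phys: Physiology = DEFAULT_PHYSIOLOGY,
    observed_kinds: Sequence[tuple[str, str]] = (
        ("plasma", "total"),
        ("brain", "total"),
        ("brain", "unbound"),
    ),
) -> list[Profile]:
    """Sparse noisy observations from the model at the true parameters.

    ``truth`` maps "drug" -> DrugParams, "perm" -> InVitroPermeability and
    "sc" -> ScalingFactors. Each requested (compartment, observed_as) pair
    becomes one Profile; noise draws are independent across profiles but
    fully determined by the seed.
    """
    drug: DrugParams = truth["drug"]
    perm: InVitroPermeability = truth["perm"]
    sc: ScalingFactors = truth["sc"]
    if dosing is None:
        dosing = infer_dosing(drug)
    if sampling_times is None:
        sampling_times = default_sampling_times(drug, dosing=dosing)

    rng = np.random.default_rng(seed)
    out: list[Profile] = []
    for compartment, observed_as in observed_kinds:
        times = np.asarray(sampling_times[compartment], dtype=float)
        sim = simulate(drug, perm, sc, phys, dosing, times, method="analytic")
        clean = sim[(compartment, observed_as)].values
        noisy = clean * _noise_factors(clean.shape, cv, noise_model, rng)
        out.append(
            Profile(times, np.clip(noisy, 0.0, None), compartment, observed_as)
        )
    return out
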