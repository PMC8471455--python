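"""Internal validation: exposure metrics and prediction-error percentages.

The model's practical claim is that scaling factors predicted from logP
alone (via the QSPRs) still yield usable brain exposure predictions. The
check replaces each drug's fitted SC1-SC3 with the QSPR-predicted values,
re-simulates the brain profile, and scores the prediction error of brain
C_max and AUC against a reference profile:

    PE% = (reference - predicted) / reference * 100

reported as an absolute value by default (the signed variant is available).
Per-cell-line summaries average the six drugs with equal weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidInputError, UndefinedResultError
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
from .qspr import QSPRModel, predict_sc

__all__ = [
    "ExposureMetrics",
    "ValidationReport",
    "exposure_metrics",
    "pe_percent",
    "internal_validation",
]


@dataclass(frozen=True)
class ExposureMetrics:
    """Peak and cumulative exposure of one concentration profile."""

    cmax: float  # ng/cm^3
    tmax: float  # s
    auc: float  # ng*s/cm^3, trapezoid over the observed window


@dataclass
class ValidationReport:
    """Per-drug and per-cell-line prediction errors for one stage."""

    stage: str  # fitted | simulated
    per_drug: "pd.DataFrame"  # columns: drug, cell_line, pe_cmax, pe_auc
    cell_line_means: "pd.DataFrame"  # columns: cell_line, pe_cmax, pe_auc

    def mean_for(self, cell_line: str, metric: str) -> float:
        row = self.cell_line_means[self.cell_line_means.cell_line == cell_line]
        if row.empty:
            raise KeyError(cell_line)
        return float(row[metric].iloc[0])


def exposure_metrics(profile: Profile) -> ExposureMetrics:
    """C_max, t_max and trapezoidal AUC over the profile's time window.

    Intended for profiles evaluated on a dense simulation grid; no
    extrapolated tail is added beyond the last observation.
    """
    if profile.times.size < 2:
        raise InvalidInputError("need at least 2 points for exposure metrics")
    i = int(np.argmax(profile.values))
    return ExposureMetrics(
        cmax=float(profile.values[i]),
        tmax=float(profile.times[i]),
        auc=float(np.trapezoid(profile.values, profile.times)),
    )


def pe_percent(experimental: float, predicted: float, *, signed: bool = False) -> float:
    """Prediction error percentage relative to the experimental value."""
    if experimental == 0:
        raise UndefinedResultError("experimental value is zero")
    pe = (experimental - predicted) / experimental * 100.0
    return pe if signed else abs(pe)


def _dense_grid(drug: DrugParams, dosing: DosingMode, n: int = 241) -> np.ndarray:
    """Simulation window of five elimination half-lives (covers the infusion
    when one is longer than that)."""
    t_end = 5.0 * np.log(2.0) / drug.k_el
    if dosing.infusion_duration is not None:
        t_end = max(t_end, 1.2 * dosing.infusion_duration)
    return np.linspace(0.0, t_end, n)


def internal_validation(
    drugs: Mapping[str, DrugParams],
    perm_tables: Mapping[tuple[str, str], InVitroPermeability],
    fitted_sc: Mapping[tuple[str, str], ScalingFactors],
    qspr_models: Mapping[tuple[str, str], QSPRModel],
    logp: Mapping[str, float],
    reference_profiles: Mapping[tuple[str, str], Profile] | None = None,
    phys: Physiology = DEFAULT_PHYSIOLOGY,
    *,
    brain_observed_as: str = "total",
    stage: str = "simulated",
    signed: bool = False,
    grid_points: int = 241,
) -> ValidationReport:
    """Score QSPR-predicted scaling factors against reference brain profiles.

    For every (drug, cell line): simulate the brain profile with the SCs
    predicted from the cell line's QSPR models at the drug's logP, extract
    C_max and AUC, and compute PE% against the reference profile — an
    experimental profile when supplied, otherwise the simulation with the
    fitted SCs. Cell-line summaries are unweighted means over the drugs.
    """
    import pandas as pd

    rows = []
    for (drug_name, cell_line), perm in perm_tables.items():
        drug = drugs[drug_name]
        dosing = infer_dosing(drug)
        times = _dense_grid(drug, dosing, grid_points)

        models = {}
        for target in ("sc1", "sc2", "sc3"):
            key = (cell_line, target)
            if key not in qspr_models:
                raise ConfigurationError(f"missing QSPR model for {key}")
            models[target] = qspr_models[key]
        predicted_sc = ScalingFactors(
            **{t: predict_sc(models[t], logp[drug_name]) for t in models}
        )

        if reference_profiles is not None and (drug_name, cell_line) in reference_profiles:
            ref = reference_profiles[(drug_name, cell_line)]
        else:
            ref = simulate(
                drug, perm, fitted_sc[(drug_name, cell_line)], phys, dosing,
                times, method="analytic",
            )[("brain", brain_observed_as)]
        pred = simulate(
            drug, perm, predicted_sc, phys, dosing, ref.times, method="analytic"
        )[("brain", brain_observed_as)]

        m_ref = exposure_metrics(ref)
        m_pred = exposure_metrics(pred)
        rows.append(
            {
                "drug": drug_name,
                "cell_line": cell_line,
                "pe_cmax": pe_percent(m_ref.cmax, m_pred.cmax, signed=signed),
                "pe_auc": pe_percent(m_ref.auc, m_pred.auc, signed=signed),
            }
        )

    per_drug = pd.DataFrame(rows).sort_values(["cell_line", "drug"],
                                              ignore_index=True)
    means = (
        per_drug.groupby("cell_line", as_index=False)[["pe_cmax", "pe_auc"]]
        .mean()
    )
    return ValidationReport(stage=stage, per_drug=per_drug,
                            cell_line_means=means)
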