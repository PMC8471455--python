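"""Tabular I/O, bundled study tables, configuration and the pipeline runner.

All CSV schemas carry units in their column names (e.g.
``papp_ab_1e-6_cm_per_s``); conversion to the internal ng/cm^3/s unit system
happens exactly once, here at the boundary. Cell-line names are normalised
to {MDCK, MDCK-MDR1, hCMEC}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError
from .neuropk import InVitroPermeability
from .pbpk import DrugParams, Profile, ScalingFactors, infer_dosing
from .physiology import Physiology
from .qspr import DEFAULT_FORMS, QSPRModel, fit_qspr
from .validation import internal_validation

__all__ = [
    "CELL_LINES",
    "read_drug_table",
    "read_permeability_table",
    "read_fitted_table",
    "read_descriptor_table",
    "read_profiles",
    "write_profiles",
    "load_drug_table",
    "load_permeability_table",
    "load_fitted_table",
    "load_descriptor_table",
    "StudyConfig",
    "run_pipeline",
]

CELL_LINES = ("MDCK", "MDCK-MDR1", "hCMEC")

_CELL_ALIASES = {
    "mdck": "MDCK",
    "mdck-mdr1": "MDCK-MDR1",
    "mdckmdr1": "MDCK-MDR1",
    "mdck_mdr1": "MDCK-MDR1",
    "hcmec": "hCMEC",
    "hcmec/d3": "hCMEC",
    "hcmec-d3": "hCMEC",
}


def normalise_cell_line(name: str) -> str:
    key = str(name).strip().lower()
    if key not in _CELL_ALIASES:
        raise ConfigurationError(f"unknown cell line: {name!r}")
    return _CELL_ALIASES[key]


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _opt(row, col) -> float | None:
    if col not in row or pd.isna(row[col]):
        return None
    return float(row[col])


def read_drug_table(path) -> dict[str, DrugParams]:
    """Read per-drug PK/dosing parameters.

    Columns: drug, fu_plasma, vd_cm3, kel_per_s and optional ka_per_s,
    dose_ng, k0_ng_per_s, rat_weight_g. Blank optional cells mean "absent",
    which drives dosing-mode inference downstream. A row carrying both an
    absorption constant and an infusion rate is ambiguous and rejected.
    """
    df = _read_csv(path)
    _require(df, ["drug", "fu_plasma", "vd_cm3", "kel_per_s"], path)
    out: dict[str, DrugParams] = {}
    for _, row in df.iterrows():
        name = str(row["drug"]).strip().lower()
        if name in out:
            raise SchemaError(f"{path}: duplicate drug {name!r}")
        k_a, k_0 = _opt(row, "ka_per_s"), _opt(row, "k0_ng_per_s")
        if k_a is not None and k_0 is not None:
            raise SchemaError(
                f"{path}: {name} has both k_a and k_0; route is ambiguous"
            )
        out[name] = DrugParams(
            name=name,
            fu_plasma=float(row["fu_plasma"]),
            v_d=float(row["vd_cm3"]),
            k_el=float(row["kel_per_s"]),
            k_a=k_a,
            dose=_opt(row, "dose_ng"),
            k_0=k_0,
            rat_weight=_opt(row, "rat_weight_g"),
        )
    return out


def read_permeability_table(path) -> dict[tuple[str, str], InVitroPermeability]:
    """Read transwell permeabilities (tabulated in 1e-6 cm/s) and f_u,brain.

    Values are converted to cm/s here; keys are (drug, cell_line).
    """
    df = _read_csv(path)
    _require(
        df,
        ["drug", "cell_line", "papp_ab_1e-6_cm_per_s",
         "papp_ba_1e-6_cm_per_s", "fu_brain"],
        path,
    )
    out: dict[tuple[str, str], InVitroPermeability] = {}
    for _, row in df.iterrows():
        key = (str(row["drug"]).strip().lower(),
               normalise_cell_line(row["cell_line"]))
        if key in out:
            raise SchemaError(f"{path}: duplicate entry for {key}")
        fu = float(row["fu_brain"])
        if not (0 < fu <= 1):
            raise SchemaError(f"{path}: fu_brain outside (0, 1] for {key}")
        out[key] = InVitroPermeability(
            papp_ab=float(row["papp_ab_1e-6_cm_per_s"]) * 1e-6,
            papp_ba=float(row["papp_ba_1e-6_cm_per_s"]) * 1e-6,
            fu_brain=fu,
        )
    return out


def write_permeability_table(perm: dict, path) -> None:
    rows = [
        {
            "drug": drug,
            "cell_line": cell,
            "papp_ab_1e-6_cm_per_s": p.papp_ab * 1e6,
            "papp_ba_1e-6_cm_per_s": p.papp_ba * 1e6,
            "fu_brain": p.fu_brain,
        }
        for (drug, cell), p in perm.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fitted_table(path) -> tuple[dict[str, dict], dict[tuple[str, str], ScalingFactors]]:
    """Read fitted PK parameters and scaling factors (long format).

    Returns (pk, sc): per-drug fitted {v_d, k_el, k_a} and per
    (drug, cell_line) ScalingFactors.
    """
    df = _read_csv(path)
    _require(df, ["drug", "cell_line", "vd_cm3", "kel_per_s",
                  "sc1", "sc2", "sc3"], path)
    pk: dict[str, dict] = {}
    sc: dict[tuple[str, str], ScalingFactors] = {}
    for _, row in df.iterrows():
        drug = str(row["drug"]).strip().lower()
        cell = normalise_cell_line(row["cell_line"])
        pk.setdefault(
            drug,
            {
                "v_d": float(row["vd_cm3"]),
                "k_el": float(row["kel_per_s"]),
                "k_a": _opt(row, "ka_per_s"),
            },
        )
        if (drug, cell) in sc:
            raise SchemaError(f"{path}: duplicate entry for {(drug, cell)}")
        sc[(drug, cell)] = ScalingFactors(
            sc1=float(row["sc1"]), sc2=float(row["sc2"]), sc3=float(row["sc3"])
        )
    return pk, sc


def read_descriptor_table(path) -> dict[str, float]:
    """Read per-drug logP values."""
    df = _read_csv(path)
    _require(df, ["drug", "logp"], path)
    return {
        str(r["drug"]).strip().lower(): float(r["logp"])
        for _, r in df.iterrows()
    }


def read_profiles(path) -> dict[str, list[Profile]]:
    """Read observed concentration-time profiles, grouped per drug.

    Columns: drug, time_s, conc_ng_per_cm3, compartment, observed_as.
    """
    df = _read_csv(path)
    _require(df, ["drug", "time_s", "conc_ng_per_cm3", "compartment",
                  "observed_as"], path)
    out: dict[str, list[Profile]] = {}
    for (drug, comp, kind), g in df.groupby(
        ["drug", "compartment", "observed_as"]
    ):
        g = g.sort_values("time_s")
        out.setdefault(str(drug).strip().lower(), []).append(
            Profile(
                g["time_s"].to_numpy(float),
                g["conc_ng_per_cm3"].to_numpy(float),
                str(comp),
                str(kind),
            )
        )
    return out


def write_profiles(profiles, path, drug: str | None = None) -> None:
    """Write profiles (an iterable or a simulate() mapping) to CSV."""
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    rows = []
    for p in profiles:
        for t, v in zip(p.times, p.values):
            row = {
                "time_s": t,
                "conc_ng_per_cm3": v,
                "compartment": p.compartment,
                "observed_as": p.observed_as,
            }
            if drug is not None:
                row = {"drug": drug, **row}
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _bundled(name: str):
    return resources.files("neuropbpk.data").joinpath(name)


def load_drug_table() -> dict[str, DrugParams]:
    """Bundled systemic PK/dosing table for the six study drugs."""
    return read_drug_table(_bundled("drugs.csv"))


def load_permeability_table() -> dict[tuple[str, str], InVitroPermeability]:
    """Bundled transwell permeabilities, six drugs x three cell lines."""
    return read_permeability_table(_bundled("permeability.csv"))


def load_fitted_table():
    """Bundled fitted PK parameters and scaling factors."""
    return read_fitted_table(_bundled("fitted_params.csv"))


def load_descriptor_table() -> dict[str, float]:
    """Bundled experimental logP values."""
    return read_descriptor_table(_bundled("descriptors_logp.csv"))


def apply_fitted_pk(drugs: dict[str, DrugParams], pk: dict[str, dict]) -> dict[str, DrugParams]:
    """Overlay fitted V_d/k_el/k_a on the nominal drug table (dose, f_u and
    route fields are kept from the nominal table)."""
    from dataclasses import replace

    out = {}
    for name, d in drugs.items():
        if name in pk:
            p = pk[name]
            out[name] = replace(
                d, v_d=p["v_d"], k_el=p["k_el"],
                k_a=p["k_a"] if p["k_a"] is not None else d.k_a,
            )
        else:
            out[name] = d
    return out


@dataclass
class StudyConfig:
    """Paths and options driving :func:`run_pipeline`.

    Any table path left as None falls back to the bundled study tables.
    """

    out_dir: Path
    drug_table: Path | None = None
    permeability_table: Path | None = None
    fitted_table: Path | None = None
    descriptor_table: Path | None = None
    profile_table: Path | None = None
    physiology: Physiology = field(default_factory=Physiology)
    qspr_forms: dict = field(default_factory=lambda: dict(DEFAULT_FORMS))
    seed: int = 0
    grid_points: int = 241

    @classmethod
    def from_toml(cls, path) -> "StudyConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        base = Path(path).parent

        def _p(key):
            return (base / raw[key]).resolve() if key in raw else None

        phys = Physiology(**raw.get("physiology", {}))
        return cls(
            out_dir=(base / raw.get("out_dir", "out")).resolve(),
            drug_table=_p("drug_table"),
            permeability_table=_p("permeability_table"),
            fitted_table=_p("fitted_table"),
            descriptor_table=_p("descriptor_table"),
            profile_table=_p("profile_table"),
            physiology=phys,
            qspr_forms={**DEFAULT_FORMS, **raw.get("qspr_forms", {})},
            seed=int(raw.get("seed", 0)),
            grid_points=int(raw.get("grid_points", 241)),
        )


def fit_all_qsprs(
    sc: dict[tuple[str, str], ScalingFactors],
    logp: dict[str, float],
    forms: dict[str, str] | None = None,
) -> dict[tuple[str, str], QSPRModel]:
    """One QSPR per (cell line, SC index) from a fitted-SC table."""
    forms = {**DEFAULT_FORMS, **(forms or {})}
    cells = sorted({cell for _, cell in sc})
    models: dict[tuple[str, str], QSPRModel] = {}
    for cell in cells:
        drugs = sorted({d for d, c in sc if c == cell})
        x = np.array([logp[d] for d in drugs])
        for target in ("sc1", "sc2", "sc3"):
            y = np.array([getattr(sc[(d, cell)], target) for d in drugs])
            models[(cell, target)] = fit_qspr(
                y, x, forms[target], target=target, cell_line=cell,
                drugs=tuple(drugs),
            )
    return models


def run_pipeline(config: StudyConfig) -> dict:
    """Run the study end to end and write artifacts to ``config.out_dir``.

    Stages: derive neuroPK parameters from the permeability table; overlay
    fitted PK/SC values (refitting from observed profiles is exposed through
    the `fitting` module and CLI rather than this batch path); fit the nine
    QSPRs; run the internal validation. Writes neuropk.csv, fit.json,
    qspr.json, report.csv and run_log.json.
    """
    from .neuropk import derive_neuropk

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    drugs = (read_drug_table(config.drug_table) if config.drug_table
             else load_drug_table())
    perm = (read_permeability_table(config.permeability_table)
            if config.permeability_table else load_permeability_table())
    pk, sc = (read_fitted_table(config.fitted_table)
              if config.fitted_table else load_fitted_table())
    logp = (read_descriptor_table(config.descriptor_table)
            if config.descriptor_table else load_descriptor_table())

    missing = {d for d, _ in perm} - set(logp)
    if missing:
        raise ConfigurationError(f"no logP for drug(s): {sorted(missing)}")

    # stage 1: neuroPK parameters per drug x cell line
    neuro_rows = []
    for (drug, cell), p in sorted(perm.items()):
        np_params = derive_neuropk(p, config.physiology)
        neuro_rows.append(
            {
                "drug": drug,
                "cell_line": cell,
                "kpuu_brain": np_params.kpuu_brain,
                "fu_brain": np_params.fu_brain,
                "vu_brain_ml_per_g": np_params.vu_brain,
                "cl_in_cm_per_s": np_params.cl_in,
            }
        )
    pd.DataFrame(neuro_rows).to_csv(out_dir / "neuropk.csv", index=False)

    # stage 2: fitted parameters (from table or prior fit)
    fitted_drugs = apply_fitted_pk(drugs, pk)
    fit_payload = {
        "pk": {d: {k: v for k, v in p.items()} for d, p in pk.items()},
        "scaling_factors": {
            f"{d}|{c}": {"sc1": s.sc1, "sc2": s.sc2, "sc3": s.sc3}
            for (d, c), s in sorted(sc.items())
        },
    }
    (out_dir / "fit.json").write_text(json.dumps(fit_payload, indent=2))

    # stage 3: QSPRs
    models = fit_all_qsprs(sc, logp, config.qspr_forms)
    qspr_payload = {
        f"{cell}|{target}": {
            "form": m.form,
            "coefficients": m.coefficients.tolist(),
            "r_squared": m.r_squared,
            "n_points": m.n_points,
        }
        for (cell, target), m in sorted(models.items())
    }
    (out_dir / "qspr.json").write_text(json.dumps(qspr_payload, indent=2))

    # stage 4: internal validation
    report = internal_validation(
        fitted_drugs, perm, sc, models, logp, phys=config.physiology,
        grid_points=config.grid_points,
    )
    report_df = report.cell_line_means.assign(stage=report.stage)[
        ["stage", "cell_line", "pe_cmax", "pe_auc"]
    ]
    report_df.to_csv(out_dir / "report.csv", index=False)
    report.per_drug.to_csv(out_dir / "report_per_drug.csv", index=False)

    log = {
        "seed": config.seed,
        "grid_points": config.grid_points,
        "qspr_forms": config.qspr_forms,
        "physiology": {
            k: getattr(config.physiology, k)
            for k in ("v_b", "v_csf", "q_bulk", "q_sink", "s_bbb", "s_bcsfb",
                      "v_ecf", "v_icf")
        },
        "tables": {
            "drug_table": str(config.drug_table or "bundled"),
            "permeability_table": str(config.permeability_table or "bundled"),
            "fitted_table": str(config.fitted_table or "bundled"),
            "descriptor_table": str(config.descriptor_table or "bundled"),
        },
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return {"neuropk": neuro_rows, "qspr": models, "report": report}
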