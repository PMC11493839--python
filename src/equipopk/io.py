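"""Readers and writers: parameter YAML, regimen tables, NONMEM-style CSV.

The study-dataset format follows NONMEM conventions: one row per dose
(``EVID=1``, amount in ``AMT``) or observation (``EVID=0``, concentration in
``DV``), with ``MDV`` marking missing/censored dependent values and a
``BLQ`` flag for records below the lower limit of quantitation.  Extra
columns carry the administration route, salt form, clinical-event
annotations, and subject covariates.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .population import OmegaSpec, ResidualSpec
from .structural_pk import DoseEvent, PKParameters, Regimen

__all__ = [
    "STUDY_COLUMNS",
    "load_table1",
    "read_params_yaml",
    "write_params_yaml",
    "read_regimen",
    "write_regimen",
    "read_study_csv",
    "write_study_csv",
]

#: Canonical column order of the study-dataset CSV.
STUDY_COLUMNS = [
    "ID", "TIME", "AMT", "RATE", "CMT", "EVID", "DV", "MDV",
    "BLQ", "ROUTE", "SALT", "EVENT", "COND", "AGE", "BW", "SEX",
]


def _parse_params(doc: dict) -> tuple[PKParameters, OmegaSpec, ResidualSpec]:
    typ = doc["typical"]
    p = PKParameters(**typ)
    bsv = doc.get("bsv_cv_percent", {})
    correlation = None
    pairs = doc.get("correlation", {}).get("pairs", [])
    omega = OmegaSpec.from_cv_percent(bsv)
    if pairs:
        omega = omega.with_correlation(
            {(pair["a"], pair["b"]): pair["rho"] for pair in pairs}
        )
    res_doc = doc.get("residual", {})
    res = ResidualSpec(
        sigma_prop_iv=res_doc.get("proportional_iv", 0.0),
        sigma_add_iv=res_doc.get("additive_iv", 0.0),
        sigma_prop_po=res_doc.get("proportional_po", 0.0),
        sigma_add_po=res_doc.get("additive_po", 0.0),
    )
    return p, omega, res


def read_params_yaml(path) -> tuple[PKParameters, OmegaSpec, ResidualSpec]:
    """Load typical values, BSV CV%, and residual SDs from a YAML file."""
    with open(path) as fh:
        return _parse_params(yaml.safe_load(fh))


def load_table1(with_correlation: bool = False):
    """The package's bundled population estimates for quinidine in horses.

    Returns ``(PKParameters, OmegaSpec, ResidualSpec)``.  With
    ``with_correlation=True`` the omega matrix includes the reconstructed
    CL–F correlation calibrated to the published percentile bands (see the
    methods note); the default is the diagonal (independent) specification.
    """
    ref = resources.files("equipopk.data").joinpath("table1.yaml")
    doc = yaml.safe_load(ref.read_text())
    if not with_correlation:
        doc = dict(doc)
        doc.pop("correlation", None)
    return _parse_params(doc)


def write_params_yaml(
    path, p: PKParameters, omega: OmegaSpec, res: ResidualSpec
) -> None:
    doc = {
        "typical": {n: float(getattr(p, n)) for n in PKParameters.parameter_names()},
        "bsv_cv_percent": {k: float(v) for k, v in omega.cv_percent().items()},
        "residual": {
            "proportional_iv": float(res.sigma_prop_iv),
            "additive_iv": float(res.sigma_add_iv),
            "proportional_po": float(res.sigma_prop_po),
            "additive_po": float(res.sigma_add_po),
        },
    }
    if omega.correlation is not None:
        pairs = []
        names = omega.names
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rho = float(omega.correlation[i, j])
                if rho != 0.0:
                    pairs.append({"a": names[i], "b": names[j], "rho": rho})
        doc["correlation"] = {"pairs": pairs}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_regimen(path) -> Regimen:
    """Read a dose schedule from CSV (or YAML with a ``doses`` list).

    CSV columns: ``time_h, amount_mg_per_kg, route, salt, infusion_duration_h``.
    """
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        rows = doc["doses"]
        label = doc.get("label", path.stem)
    else:
        frame = pd.read_csv(path)
        rows = frame.to_dict("records")
        label = path.stem
    events = []
    for row in rows:
        duration = row.get("infusion_duration_h")
        if duration is not None and pd.isna(duration):
            duration = None
        events.append(
            DoseEvent(
                time=float(row["time_h"]),
                amount=float(row["amount_mg_per_kg"]),
                route=str(row["route"]),
                salt=str(row.get("salt", "sulfate_dihydrate")),
                infusion_duration=duration,
            )
        )
    return Regimen(events=tuple(events), label=label)


def write_regimen(path, regimen: Regimen) -> None:
    frame = pd.DataFrame(
        {
            "time_h": [e.time for e in regimen.events],
            "amount_mg_per_kg": [e.amount for e in regimen.events],
            "route": [e.route for e in regimen.events],
            "salt": [e.salt for e in regimen.events],
            "infusion_duration_h": [e.infusion_duration for e in regimen.events],
        }
    )
    frame.to_csv(path, index=False)


def read_study_csv(path) -> pd.DataFrame:
    """Read a NONMEM-style study dataset, normalizing missing columns."""
    frame = pd.read_csv(path)
    for col in STUDY_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    return frame[STUDY_COLUMNS]


def write_study_csv(path, frame: pd.DataFrame) -> None:
    cols = [c for c in STUDY_COLUMNS if c in frame.columns]
    frame[cols].to_csv(path, index=False)
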