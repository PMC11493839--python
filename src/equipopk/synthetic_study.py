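"""Virtual study datasets emulating the quinidine study designs.

Two designs are generated:

* a rich healthy-horse study — an IV/PO crossover (5-min IV infusion of
  4.28 mg/kg base, then after a two-week washout a single oral dose of
  20 mg/kg sulfate dihydrate) with dense sampling, plus a twice-daily oral
  arm (20 mg/kg q 6 h x 2);
* a sparse clinical atrial-fibrillation study — repeated oral doses chosen
  by the prescribing clinician (uniform over 9.3–30.6 mg/kg sulfate at 4–6 h
  intervals) with only a handful of samples per horse.

Measurements carry route-specific combined residual error and are censored
at the assay's lower limit of quantitation (0.03 μg/mL).  Conversion to
sinus rhythm and adverse effects are simulated as the first crossing of
subject-specific concentration thresholds; this event model is entirely
synthetic — the source study recorded real clinical events — and exists so
the therapeutic-window derivation has annotated data to work on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import (
    IndividualParameters,
    OmegaSpec,
    ResidualSpec,
    apply_residual_error,
    sample_individuals,
)
from .structural_pk import DoseEvent, PKParameters, Regimen, simulate_profile

__all__ = [
    "AssaySpec",
    "StudyDataset",
    "IV_SAMPLING_TIMES",
    "PO_SINGLE_SAMPLING_TIMES",
    "PO_TWICE_SAMPLING_TIMES",
    "AF_SAMPLING_OFFSETS",
    "generate_rich_study",
    "generate_af_study",
    "blq_censor",
    "therapeutic_window_from_events",
]

#: Washout between the IV and PO occasions of the crossover (h).
CROSSOVER_WASHOUT = 336.0

# Sampling schedules of the source designs (hours post dose). The IV "0 min"
# sample is taken immediately after the 5-min infusion ends; later offsets
# count from the end of infusion.
_IV_END = 5.0 / 60.0
IV_SAMPLING_TIMES = tuple(
    _IV_END + off
    for off in (0.0, 5 / 60, 10 / 60, 20 / 60, 30 / 60, 45 / 60, 1, 2, 3, 4, 6, 8, 12)
)
PO_SINGLE_SAMPLING_TIMES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 7.0, 9.0, 12.0, 24.0)
PO_TWICE_SAMPLING_TIMES = (
    0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 5.8, 6.5, 7.0, 7.5, 8.0, 8.5, 9.0, 12.0, 24.0
)
AF_SAMPLING_OFFSETS = (0.5, 1.0, 2.0, 3.0, 4.0)


@dataclass(frozen=True)
class AssaySpec:
    """Assay quantitation limits (μg/mL)."""

    lloq: float = 0.03
    calibration_range: tuple[float, float] = (0.03, 10.0)

    def __post_init__(self) -> None:
        if self.lloq < 0:
            raise ValueError("LLOQ must be non-negative")


@dataclass
class StudyDataset:
    """A NONMEM-style multi-subject dataset of doses and observations."""

    records: pd.DataFrame
    individuals: list[IndividualParameters] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        df = self.records
        doses = df[df["EVID"] == 1]
        for sid, grp in df.groupby("ID"):
            if (grp["EVID"] == 1).sum() < 1:
                raise ValueError(f"subject {sid} has no dose record")
        if (df["TIME"] < 0).any():
            raise ValueError("record times must be non-negative")
        if (doses["AMT"] < 0).any():
            raise ValueError("dose amounts must be non-negative")

    @property
    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.records["ID"]))

    def observations(self, subject_id=None) -> pd.DataFrame:
        obs = self.records[self.records["EVID"] == 0]
        if subject_id is not None:
            obs = obs[obs["ID"] == subject_id]
        return obs

    def doses(self, subject_id=None) -> pd.DataFrame:
        doses = self.records[self.records["EVID"] == 1]
        if subject_id is not None:
            doses = doses[doses["ID"] == subject_id]
        return doses

    def events(self) -> pd.DataFrame:
        return self.records[self.records["EVENT"].isin(["conversion", "adverse"])]

    def regimen_for(self, subject_id) -> Regimen:
        """The subject's dose schedule as a simulatable regimen."""
        rows = self.doses(subject_id)
        events = tuple(
            DoseEvent(
                time=float(r.TIME),
                amount=float(r.AMT),
                route=str(r.ROUTE),
                salt=str(r.SALT),
                infusion_duration=(
                    float(r.AMT) / float(r.RATE)
                    if r.ROUTE == "IV" and pd.notna(r.RATE) and r.RATE > 0
                    else None
                ),
            )
            for r in rows.itertuples()
        )
        return Regimen(events=events, label=f"subject-{subject_id}")


def _dose_row(sid, t, amount_salt, route, salt, duration, cov) -> dict:
    amount_base = amount_salt / {"sulfate_dihydrate": 1.206,
                                 "hydrochloride_monohydrate": 1.168,
                                 "base": 1.0}[salt]
    return {
        "ID": sid, "TIME": t, "AMT": amount_salt,
        "RATE": amount_salt / duration if duration else np.nan,
        "CMT": 1 if route == "IV" else 0, "EVID": 1, "DV": np.nan, "MDV": 1,
        "BLQ": 0, "ROUTE": route, "SALT": salt, "EVENT": "none", **cov,
    }


def _obs_rows(sid, times, values, route, cov) -> list[dict]:
    return [
        {
            "ID": sid, "TIME": t, "AMT": np.nan, "RATE": np.nan, "CMT": 1,
            "EVID": 0, "DV": v, "MDV": 0, "BLQ": 0, "ROUTE": route,
            "SALT": np.nan, "EVENT": "none", **cov,
        }
        for t, v in zip(times, values)
    ]


def _draw_covariates(rng, condition: str) -> dict:
    return {
        "COND": condition,
        "AGE": float(rng.integers(2, 11 if condition == "AF" else 8)),
        "BW": float(np.round(rng.uniform(430, 563), 0)),
        "SEX": "stallion" if rng.random() < 0.6 else "mare",
    }


def _observe(predictions, res, route, rng):
    return apply_residual_error(predictions, res, route, rng)


def generate_rich_study(
    p: PKParameters,
    omega: OmegaSpec,
    res: ResidualSpec,
    seed: int,
    n_crossover: int = 6,
    n_multi: int = 4,
    assay: AssaySpec | None = None,
) -> StudyDataset:
    """The healthy-horse design: IV/PO crossover plus a twice-q6h oral arm.

    Crossover subjects receive 5 mg/kg IV quinidine hydrochloride
    monohydrate (5-min infusion) at t=0 and 20 mg/kg oral sulfate dihydrate
    after a two-week washout, sampled on the dense schedules; the oral-only
    arm receives 20 mg/kg q 6 h twice.  Pre-dose samples are generated as
    true zeros and then censored at the LLOQ.
    """
    rng = np.random.default_rng(seed)
    assay = assay or AssaySpec()
    n = n_crossover + n_multi
    individuals = sample_individuals(p, omega, n, rng)
    rows: list[dict] = []
    for i, ind in enumerate(individuals):
        sid = ind.subject_id
        cov = _draw_covariates(rng, "healthy")
        if i < n_crossover:
            regimen = Regimen(
                events=(
                    DoseEvent(time=0.0, amount=5.0, route="IV",
                              salt="hydrochloride_monohydrate"),
                    DoseEvent(time=CROSSOVER_WASHOUT, amount=20.0, route="PO",
                              salt="sulfate_dihydrate"),
                ),
                label="crossover",
            )
            rows.append(_dose_row(sid, 0.0, 5.0, "IV", "hydrochloride_monohydrate",
                                  5.0 / 60.0, cov))
            rows.append(_dose_row(sid, CROSSOVER_WASHOUT, 20.0, "PO",
                                  "sulfate_dihydrate", 0.0, cov))
            iv_times = np.array(IV_SAMPLING_TIMES)
            po_times = CROSSOVER_WASHOUT + np.array(PO_SINGLE_SAMPLING_TIMES)
            f_iv = simulate_profile(ind.theta, regimen, iv_times).concentrations
            f_po = simulate_profile(ind.theta, regimen, po_times).concentrations
            y_iv = _observe(f_iv, res, "IV", rng)
            y_po = _observe(f_po, res, "PO", rng)
            rows.extend(_obs_rows(sid, [0.0], [0.0], "IV", cov))  # pre-dose
            rows.extend(_obs_rows(sid, iv_times, y_iv, "IV", cov))
            rows.extend(_obs_rows(sid, [CROSSOVER_WASHOUT], [0.0], "PO", cov))
            rows.extend(_obs_rows(sid, po_times, y_po, "PO", cov))
        else:
            regimen = Regimen(
                events=(
                    DoseEvent(time=0.0, amount=20.0, route="PO",
                              salt="sulfate_dihydrate"),
                    DoseEvent(time=6.0, amount=20.0, route="PO",
                              salt="sulfate_dihydrate"),
                ),
                label="po_twice",
            )
            for t in (0.0, 6.0):
                rows.append(_dose_row(sid, t, 20.0, "PO", "sulfate_dihydrate",
                                      0.0, cov))
            times = np.array(PO_TWICE_SAMPLING_TIMES)
            f = simulate_profile(ind.theta, regimen, times).concentrations
            y = _observe(f, res, "PO", rng)
            rows.extend(_obs_rows(sid, [0.0], [0.0], "PO", cov))
            rows.extend(_obs_rows(sid, times, y, "PO", cov))
    frame = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"],
                                           ascending=[True, True, False])
    ds = StudyDataset(records=frame.reset_index(drop=True),
                      individuals=individuals, seed=seed)
    ds, _ = blq_censor(ds, assay)
    return ds


def generate_af_study(
    p: PKParameters,
    omega: OmegaSpec,
    res: ResidualSpec,
    n: int = 19,
    seed: int = 0,
    n_doses: int = 4,
    conversion_threshold: float | None = 2.0,
    adverse_threshold: float | None = 3.8,
    threshold_cv: float = 0.3,
    sampling_offsets: tuple[float, ...] = AF_SAMPLING_OFFSETS,
    assay: AssaySpec | None = None,
) -> StudyDataset:
    """The sparse clinical design in horses with atrial fibrillation.

    Doses are drawn uniformly from 9.3–30.6 mg/kg sulfate dihydrate, given
    ``n_doses`` times at clinician-style 4–6 h intervals; samples are taken
    pre-dose and at the stated offsets after the first administration.
    Conversion / adverse events are annotated at the first crossing of
    subject-specific log-normal thresholds centred on the stated medians
    (pass ``None`` or ``inf`` to disable a class).
    """
    rng = np.random.default_rng(seed)
    assay = assay or AssaySpec()
    individuals = sample_individuals(p, omega, n, rng)
    rows: list[dict] = []
    for ind in individuals:
        sid = ind.subject_id
        cov = _draw_covariates(rng, "AF")
        dose = float(np.round(rng.uniform(9.3, 30.6), 1))
        intervals = rng.uniform(4.0, 6.0, size=n_doses - 1)
        dose_times = np.concatenate([[0.0], np.cumsum(intervals)])
        events = tuple(
            DoseEvent(time=float(t), amount=dose, route="PO",
                      salt="sulfate_dihydrate")
            for t in dose_times
        )
        regimen = Regimen(events=events, label="af")
        for t in dose_times:
            rows.append(_dose_row(sid, float(t), dose, "PO",
                                  "sulfate_dihydrate", 0.0, cov))
        times = np.array(sampling_offsets, dtype=float)
        f = simulate_profile(ind.theta, regimen, times).concentrations
        y = _observe(f, res, "PO", rng)
        rows.extend(_obs_rows(sid, [0.0], [0.0], "PO", cov))
        rows.extend(_obs_rows(sid, times, y, "PO", cov))
        # first-crossing clinical events on a fine grid of the true curve
        for kind, median in (("conversion", conversion_threshold),
                             ("adverse", adverse_threshold)):
            if median is None or not np.isfinite(median):
                continue
            sd = np.sqrt(np.log1p(threshold_cv**2))
            threshold = median * np.exp(rng.normal(0.0, sd)) if sd > 0 else median
            horizon = dose_times[-1] + 12.0
            fine = np.linspace(1e-3, horizon, int(horizon / 0.05) + 1)
            curve = simulate_profile(ind.theta, regimen, fine).concentrations
            crossed = np.nonzero(curve >= threshold)[0]
            if crossed.size:
                t_event = float(fine[crossed[0]])
                rows.append({
                    "ID": sid, "TIME": t_event, "AMT": np.nan, "RATE": np.nan,
                    "CMT": 1, "EVID": 2, "DV": np.nan, "MDV": 1, "BLQ": 0,
                    "ROUTE": "PO", "SALT": np.nan, "EVENT": kind, **cov,
                })
                # the blood sample drawn when the clinical event was observed
                y_event = _observe(curve[crossed[0]: crossed[0] + 1],
                                   res, "PO", rng)
                rows.extend(_obs_rows(sid, [t_event], y_event, "PO", cov))
    frame = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"],
                                           ascending=[True, True, False])
    ds = StudyDataset(records=frame.reset_index(drop=True),
                      individuals=individuals, seed=seed)
    ds, _ = blq_censor(ds, assay)
    return ds


def blq_censor(
    ds: StudyDataset, assay: AssaySpec | None = None
) -> tuple[StudyDataset, dict]:
    """Flag observations below the limit of quantitation.

    Flagged records keep their raw value but get ``BLQ=1`` and ``MDV=1`` so
    that estimation excludes them.  The report gives the below-quantitation
    fraction among post-dose observations (pre-first-dose samples are
    structurally blank and excluded from the rule); the exclusion approach is
    only appropriate while that fraction is small, so fractions of 5% or more
    trigger a warning.
    """
    assay = assay or AssaySpec()
    df = ds.records.copy()
    obs = df["EVID"] == 0
    below = obs & (df["DV"] < assay.lloq)
    df.loc[obs, "BLQ"] = 0
    df.loc[below, "BLQ"] = 1
    df.loc[below, "MDV"] = 1
    df.loc[obs & ~below, "MDV"] = 0
    first_dose = df[df["EVID"] == 1].groupby("ID")["TIME"].min()
    post = obs & (df["TIME"] > df["ID"].map(first_dose))
    n_obs = int(post.sum())
    n_blq = int((below & post).sum())
    fraction = n_blq / n_obs if n_obs else 0.0
    if fraction >= 0.05:
        warnings.warn(
            f"{100 * fraction:.1f}% of observations are below the LLOQ; "
            "exclusion-based handling may bias the fit"
        )
    report = {"n_observations": n_obs, "n_blq": n_blq, "fraction": fraction}
    return (
        StudyDataset(records=df, individuals=ds.individuals, seed=ds.seed),
        report,
    )


def therapeutic_window_from_events(ds: StudyDataset, lookback: float = 1.0) -> dict:
    """Concentration summaries at clinical events, per event class.

    For every annotated event, quantifiable observed concentrations of the
    same subject within ``lookback`` hours before (and including) the event
    time are pooled; the summary is the median and min–max range per class.
    Classes with no events (or no in-window samples) are reported empty.
    """
    out: dict[str, dict] = {}
    events = ds.events()
    for kind in ("conversion", "adverse"):
        pooled: list[float] = []
        for row in events[events["EVENT"] == kind].itertuples():
            obs = ds.observations(row.ID)
            ok = (
                (obs["TIME"] >= row.TIME - lookback)
                & (obs["TIME"] <= row.TIME)
                & (obs["BLQ"] == 0)
            )
            pooled.extend(obs.loc[ok, "DV"].tolist())
        if pooled:
            arr = np.array(pooled)
            out[kind] = {
                "median": float(np.median(arr)),
                "range": (float(arr.min()), float(arr.max())),
                "n": len(pooled),
            }
        else:
            out[kind] = {"median": None, "range": None, "n": 0}
    return out
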