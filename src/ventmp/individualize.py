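"""Closed-loop individualization of ventilator settings.

The algorithm observes the patient's respiratory-acidosis status
(PaCO2 > 45 mmHg AND pH < 7.35), which selects the objective: acidotic
patients need CO2 clearance, so candidate settings are ordered by
descending minute ventilation (VE = TV × RR); non-acidotic patients are
protected from over-ventilation, so candidates are ordered by ascending
mechanical power. Candidate tidal volumes span a lung-protective
4–8 mL/kg IBW grid; the driving pressure follows from an estimated
respiratory-system compliance (TV = C × ΔP); PEEP is held fixed —
its titration is delegated to a parallel workflow. Candidates are fed,
in objective order, into a frozen mortality model (only the
ventilation-derived features are recomputed) until the prediction flips
to survival; if none flips, the settings are left unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ventmp.metrics import mechanical_power, minute_ventilation

#: Admission-level features recomputed per candidate; everything else in the
#: patient row is frozen during the search.
VENT_FEATURES = ("twa_mp", "twa_mp_ibw", "twa_tv_mlkg", "twa_rr", "twa_dp", "twa_peep")

PACO2_THRESHOLD = 45.0  # mmHg
PH_THRESHOLD = 7.35


@dataclass
class AcidosisState:
    paco2: float
    ph: float
    acidotic: bool


@dataclass
class VentSettings:
    tv_L: float
    rr: float
    dp: float
    peep: float

    @property
    def ve(self) -> float:
        return minute_ventilation(self.tv_L, self.rr)

    @property
    def mp(self) -> float:
        return mechanical_power(self.tv_L, self.rr, self.peep, self.dp)

    def as_dict(self) -> dict:
        d = {**asdict(self), "ve": self.ve, "mp": self.mp}
        return {k: float(v) for k, v in d.items()}


@dataclass
class SearchBounds:
    """Candidate grid and safety envelope.

    Tidal volume is gridded in mL/kg IBW (lung-protective default 4–8,
    step 0.5); respiratory rate 10–35 /min, step 1; the driving pressure
    implied by TV and compliance must stay within ``dp_bounds``.
    """

    tv_mlkg: tuple[float, float] = (4.0, 8.0)
    tv_step_mlkg: float = 0.5
    rr: tuple[float, float] = (10.0, 35.0)
    rr_step: float = 1.0
    dp_bounds: tuple[float, float] = (5.0, 25.0)
    ve_bounds: tuple[float, float] = (2.0, 20.0)


@dataclass
class IndividualizationOutcome:
    admission_id: object
    initial: VentSettings
    final: VentSettings
    objective: str  # "max_VE" | "min_MP"
    initial_pred: str  # "death" | "survival"
    final_pred: str
    flipped: bool
    iterations: int
    note: str = ""

    def as_dict(self) -> dict:
        d = asdict(self)
        d["initial"] = self.initial.as_dict()
        d["final"] = self.final.as_dict()
        return d


def acidosis_status(paco2: float, ph: float) -> AcidosisState:
    """Respiratory acidosis: PaCO2 > 45 mmHg AND pH < 7.35 (both must hold)."""
    if paco2 is None or ph is None or np.isnan(paco2) or np.isnan(ph):
        raise ValueError("paco2 and ph must be observed to assess acidosis")
    return AcidosisState(paco2=paco2, ph=ph,
                         acidotic=bool(paco2 > PACO2_THRESHOLD and ph < PH_THRESHOLD))


def estimate_compliance(vent_series: pd.DataFrame) -> float:
    """Respiratory-system compliance in L/cmH2O as the median of recent
    TV/ΔP sample pairs."""
    wide = vent_series.pivot_table(index="t_min", columns="variable",
                                   values="value", aggfunc="last").ffill()
    if not {"tv_L", "dp"} <= set(wide.columns):
        raise ValueError("series lacks tv_L/dp samples for compliance estimation")
    ratio = (wide["tv_L"] / wide["dp"]).dropna()
    if ratio.empty:
        raise ValueError("no concurrent tv_L/dp samples")
    return float(ratio.median())


def candidate_settings(
    ibw_kg: float,
    compliance_L_per_cmH2O: float,
    peep: float,
    objective: str,
    bounds: SearchBounds | None = None,
) -> list[VentSettings]:
    """Enumerate the feasible (TV, RR, ΔP) grid, ordered by the objective.

    max_VE: descending minute ventilation (ties: lower MP, then lower RR).
    min_MP: ascending mechanical power (ties: lower RR).
    Infeasible combinations (ΔP or VE outside the safety envelope) are
    excluded; the list may be empty.
    """
    if objective not in ("max_VE", "min_MP"):
        raise ValueError(f"unknown objective {objective!r}")
    b = bounds or SearchBounds()
    tv_grid = np.arange(b.tv_mlkg[0], b.tv_mlkg[1] + 1e-9, b.tv_step_mlkg)
    rr_grid = np.arange(b.rr[0], b.rr[1] + 1e-9, b.rr_step)
    out = []
    for mlkg in tv_grid:
        tv = mlkg * ibw_kg / 1000.0
        dp = tv / compliance_L_per_cmH2O
        if not b.dp_bounds[0] <= dp <= b.dp_bounds[1]:
            continue
        for rr in rr_grid:
            s = VentSettings(tv_L=tv, rr=float(rr), dp=dp, peep=peep)
            if not b.ve_bounds[0] <= s.ve <= b.ve_bounds[1]:
                continue
            out.append(s)
    if objective == "max_VE":
        out.sort(key=lambda s: (-s.ve, s.mp, s.rr))
    else:
        out.sort(key=lambda s: (s.mp, s.rr))
    return out


def _apply_settings(row: pd.Series, s: VentSettings, ibw_kg: float) -> pd.Series:
    """Overwrite the ventilation-derived features of a frozen patient row."""
    row = row.copy()
    updates = {
        "twa_mp": s.mp,
        "twa_mp_ibw": s.mp / ibw_kg,
        "twa_tv_mlkg": s.tv_L * 1000.0 / ibw_kg,
        "twa_rr": s.rr,
        "twa_dp": s.dp,
        "twa_peep": s.peep,
    }
    for k, v in updates.items():
        if k in row.index:
            row[k] = v
    return row


def _predict(model, row: pd.Series, threshold: float) -> str:
    """'death' or 'survival' from a frozen model.

    The model may be a sklearn-style classifier with predict_proba over
    the feature columns it was fitted on, or any callable mapping a
    pd.Series to a death probability.
    """
    if callable(model) and not hasattr(model, "predict_proba"):
        p = float(model(row))
    else:
        cols = getattr(model, "feature_names_ventmp_", None)
        x = row[cols].to_frame().T.to_numpy(dtype=float) if cols else \
            row.to_frame().T.to_numpy(dtype=float)
        p = float(model.predict_proba(x)[0, 1])
    return "death" if p >= threshold else "survival"


def individualize(
    patient_row: pd.Series,
    model,
    initial: VentSettings,
    ibw_kg: float,
    compliance_L_per_cmH2O: float,
    paco2: float,
    ph: float,
    bounds: SearchBounds | None = None,
    threshold: float = 0.5,
    ve_tolerance: float = 0.05,
) -> IndividualizationOutcome:
    """Walk the objective-ordered candidate list until the frozen model
    predicts survival.

    The first candidate that flips the prediction wins (it is the best
    feasible setting under the active objective, since the list is sorted).
    The search keeps the desired VE or MP: acidotic candidates may not drop
    minute ventilation below the initial VE minus ``ve_tolerance`` (a
    relative fraction), and non-acidotic candidates may not exceed the
    initial mechanical power. If no candidate flips — or the patient is
    already predicted to survive — the initial settings are returned
    unchanged. Non-ventilation covariates are never mutated.
    """
    adm_id = patient_row.get("admission_id", None)
    state = acidosis_status(paco2, ph)
    objective = "max_VE" if state.acidotic else "min_MP"

    row0 = _apply_settings(patient_row, initial, ibw_kg)
    try:
        pred0 = _predict(model, row0, threshold)
    except Exception as exc:  # noqa: BLE001 - surface as a skipped patient
        return IndividualizationOutcome(
            adm_id, initial, initial, objective, "error", "error",
            flipped=False, iterations=0, note=f"prediction failure: {exc}")
    if pred0 == "survival":
        return IndividualizationOutcome(
            adm_id, initial, initial, objective, pred0, pred0,
            flipped=False, iterations=1, note="already predicted survivor")

    iterations = 1
    for cand in candidate_settings(ibw_kg, compliance_L_per_cmH2O,
                                   initial.peep, objective, bounds):
        if objective == "min_MP" and cand.mp > initial.mp + 1e-9:
            continue
        if objective == "max_VE" and cand.ve < initial.ve * (1 - ve_tolerance):
            continue
        iterations += 1
        pred = _predict(model, _apply_settings(patient_row, cand, ibw_kg), threshold)
        if pred == "survival":
            return IndividualizationOutcome(
                adm_id, initial, cand, objective, pred0, pred,
                flipped=True, iterations=iterations)
    return IndividualizationOutcome(
        adm_id, initial, initial, objective, pred0, "death",
        flipped=False, iterations=iterations, note="no feasible flip")


@dataclass
class CaseStudySummary:
    n_initial: int
    n_flipped: int
    percent: float

    @classmethod
    def from_counts(cls, n_initial: int, n_flipped: int) -> "CaseStudySummary":
        pct = 0.0 if n_initial == 0 else round(100.0 * n_flipped / n_initial, 1)
        return cls(n_initial=n_initial, n_flipped=n_flipped, percent=pct)


def case_study(
    nonsurvivor_rows: pd.DataFrame,
    model,
    per_patient: dict,
    bounds: SearchBounds | None = None,
    threshold: float = 0.5,
) -> tuple[CaseStudySummary, list[IndividualizationOutcome]]:
    """Run the individualizer over model-predicted nonsurvivors.

    ``per_patient`` maps admission_id to a dict with keys ``initial``
    (VentSettings), ``ibw_kg``, ``compliance``, ``paco2``, ``ph``.
    Returns the flip summary (percent to 1 decimal) and per-patient
    outcomes.
    """
    outcomes = []
    for _, row in nonsurvivor_rows.iterrows():
        info = per_patient[row["admission_id"]]
        outcomes.append(individualize(
            row, model, info["initial"], info["ibw_kg"], info["compliance"],
            info["paco2"], info["ph"], bounds=bounds, threshold=threshold))
    usable = [o for o in outcomes if o.initial_pred != "error"]
    summary = CaseStudySummary.from_counts(
        len(usable), sum(o.flipped for o in usable))
    return summary, outcomes
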