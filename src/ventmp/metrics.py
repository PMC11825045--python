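"""Ventilation metrics: ideal body weight, surrogate mechanical power,
minute ventilation, and time-weighted aggregates over 24 h / 48 h windows.

The mechanical power of pressure-controlled ventilation is approximated by
the surrogate

    MP [J/min] = 0.098 · TV [L] · RR [1/min] · (PEEP + ΔPinsp) [cmH2O]

where ΔPinsp is the inspiratory (driving) pressure above PEEP, so
PEEP + ΔPinsp is the peak inspiratory pressure. Time-weighted averages
treat ventilator settings as sample-and-hold signals: each recorded value
is held constant until the next record, and the last value before the
window end is held to the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MP_COEF = 0.098

#: Canonical order of the per-window aggregate columns.
TWA_COLUMNS = [
    "twa_pfr",
    "twa_rr",
    "twa_ti_s",
    "twa_ie",
    "twa_peep",
    "twa_tv_L",
    "twa_tv_mlkg",
    "twa_dp",
    "twa_ppeak",
    "twa_mp",
    "twa_mp_ibw",
    "sd48_mp",
]


def ibw(height_cm: float, sex: str) -> float:
    """Ideal body weight in kg by the Devine formula.

    male:   50.0 + 0.91 * (height_cm - 152.4)
    female: 45.5 + 0.91 * (height_cm - 152.4)

    The result is not rounded; round only at reporting time.
    """
    if height_cm <= 0:
        raise ValueError(f"height must be positive, got {height_cm}")
    if sex == "male":
        base = 50.0
    elif sex == "female":
        base = 45.5
    else:
        raise ValueError(f"unknown sex code {sex!r}; expected 'male' or 'female'")
    return base + 0.91 * (height_cm - 152.4)


def mechanical_power(
    tv_L: float,
    rr: float,
    peep: float,
    dp: float,
    *,
    pressure_mode: str = "sum",
) -> float:
    """Surrogate mechanical power in J/min.

    Computes 0.098 × TV × RR × (PEEP + ΔP). The printed source formula lists
    PEEP and inspiratory pressure with no operator between them; the additive
    reading (total pressure = peak pressure) is the physically consistent one
    and the default. ``pressure_mode="product"`` evaluates the literal
    product variant, retained for audit only.
    """
    for name, v in (("tv_L", tv_L), ("rr", rr), ("peep", peep), ("dp", dp)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if pressure_mode == "sum":
        pressure = peep + dp
    elif pressure_mode == "product":
        pressure = peep * dp
    else:
        raise ValueError(f"unknown pressure_mode {pressure_mode!r}")
    return MP_COEF * tv_L * rr * pressure


def minute_ventilation(tv_L: float, rr: float) -> float:
    """Minute ventilation VE = TV × RR, in L/min."""
    if tv_L < 0 or rr < 0:
        raise ValueError("tv_L and rr must be non-negative")
    return tv_L * rr


def twa(samples, window_min: float) -> float:
    """Time-weighted average of a sample-and-hold signal over [0, window_min].

    Parameters
    ----------
    samples
        Sequence of ``(t_min, value)`` pairs sorted by time. Values are held
        constant until the next sample; the last value before the window end
        is held to the boundary. Samples at or after ``window_min`` are
        ignored. If the first sample falls after t=0, the integral starts at
        that sample and is divided by the covered duration only.
    window_min
        Window length in minutes, > 0.

    Returns
    -------
    float
        The duration-weighted mean; ``nan`` if no sample lies in the window.
    """
    if window_min <= 0:
        raise ValueError("window_min must be positive")
    arr = np.asarray([(t, v) for t, v in samples if 0 <= t < window_min], dtype=float)
    if arr.size == 0:
        return float("nan")
    t = arr[:, 0]
    v = arr[:, 1]
    if np.any(np.diff(t) < 0):
        raise ValueError("samples must be sorted by time")
    edges = np.append(t, window_min)
    durations = np.diff(edges)
    covered = window_min - t[0]
    return float(np.sum(v * durations) / covered)


@dataclass
class TWAFeatures:
    """Per-admission time-weighted aggregates for one window (24 h or 48 h)."""

    admission_id: object
    window_h: int
    twa_pfr: float
    twa_rr: float
    twa_ti_s: float
    twa_ie: float
    twa_peep: float
    twa_tv_L: float
    twa_tv_mlkg: float
    twa_dp: float
    twa_ppeak: float
    twa_mp: float
    twa_mp_ibw: float
    sd48_mp: float  # nan for the 24 h window

    def as_dict(self) -> dict:
        return {
            "admission_id": self.admission_id,
            "window_h": self.window_h,
            **{c: getattr(self, c) for c in TWA_COLUMNS},
        }


def _pivot_series(vent_series: pd.DataFrame) -> pd.DataFrame:
    """Long (admission_id, t_min, variable, value) -> wide per-time frame,
    forward-filled so each row carries the currently-held value of every
    variable."""
    wide = vent_series.pivot_table(
        index="t_min", columns="variable", values="value", aggfunc="last"
    )
    return wide.sort_index().ffill()


def build_twa_features(
    vent_series: pd.DataFrame,
    admission: pd.Series | dict,
    windows_h: tuple[int, ...] = (24, 48),
) -> list[TWAFeatures]:
    """Compute every aggregate for one admission, per window.

    MP is computed per time point from the currently-held settings and then
    time-weighted — never as the product of the individual TWAs, which does
    not commute with averaging. ``sd48_mp`` is the plain standard deviation
    of the per-time-point MP values within the first 48 h (reported on the
    48 h row only).

    Parameters
    ----------
    vent_series
        Long-format frame with columns ``t_min, variable, value`` for ONE
        admission. Recognized variables: tv_L, rr, peep, dp, ti_s, fio2,
        pao2 (others pass through untouched).
    admission
        Mapping with at least ``admission_id``, ``height_cm``, ``sex``.
    """
    adm_id = admission["admission_id"]
    weight = ibw(admission["height_cm"], admission["sex"])
    wide = _pivot_series(vent_series)

    t = wide.index.to_numpy(dtype=float)
    derived = pd.DataFrame(index=wide.index)
    if {"tv_L", "rr", "peep", "dp"} <= set(wide.columns):
        derived["mp"] = MP_COEF * wide["tv_L"] * wide["rr"] * (wide["peep"] + wide["dp"])
        derived["ppeak"] = wide["peep"] + wide["dp"]
    if {"pao2", "fio2"} <= set(wide.columns):
        derived["pfr"] = wide["pao2"] / wide["fio2"]
    if {"ti_s", "rr"} <= set(wide.columns):
        # IE ratio = inspiratory / expiratory time; cycle length is 60/RR s.
        te = 60.0 / wide["rr"] - wide["ti_s"]
        derived["ie"] = wide["ti_s"] / te
    if {"tv_L"} <= set(wide.columns):
        derived["tv_mlkg"] = wide["tv_L"] * 1000.0 / weight

    def _twa(col_frame, col, wmin):
        if col not in col_frame.columns:
            return float("nan")
        vals = col_frame[col].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        return twa(zip(t[ok], vals[ok]), wmin)

    out = []
    mask48 = (t >= 0) & (t < 48 * 60)
    mp48 = derived["mp"].to_numpy(dtype=float)[mask48] if "mp" in derived else np.array([])
    sd48 = float(np.std(mp48[~np.isnan(mp48)])) if mp48.size else float("nan")

    for wh in windows_h:
        wmin = wh * 60.0
        out.append(
            TWAFeatures(
                admission_id=adm_id,
                window_h=wh,
                twa_pfr=_twa(derived, "pfr", wmin),
                twa_rr=_twa(wide, "rr", wmin),
                twa_ti_s=_twa(wide, "ti_s", wmin),
                twa_ie=_twa(derived, "ie", wmin),
                twa_peep=_twa(wide, "peep", wmin),
                twa_tv_L=_twa(wide, "tv_L", wmin),
                twa_tv_mlkg=_twa(derived, "tv_mlkg", wmin),
                twa_dp=_twa(wide, "dp", wmin),
                twa_ppeak=_twa(derived, "ppeak", wmin),
                twa_mp=_twa(derived, "mp", wmin),
                twa_mp_ibw=_twa(derived, "mp", wmin) / weight,
                sd48_mp=sd48 if wh == 48 else float("nan"),
            )
        )
    return out


def twa_feature_table(
    vent_series: pd.DataFrame,
    admissions: pd.DataFrame,
    windows_h: tuple[int, ...] = (24, 48),
) -> pd.DataFrame:
    """Vectorize :func:`build_twa_features` over a cohort.

    Returns one row per admission per window; admissions with no ventilation
    samples are skipped.
    """
    rows = []
    grouped = dict(iter(vent_series.groupby("admission_id")))
    for _, adm in admissions.iterrows():
        series = grouped.get(adm["admission_id"])
        if series is None or series.empty:
            continue
        rows.extend(f.as_dict() for f in build_twa_features(series, adm, windows_h))
    return pd.DataFrame(rows, columns=["admission_id", "window_h", *TWA_COLUMNS])
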