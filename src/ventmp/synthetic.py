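"""Synthetic ICU cohort generator.

The source study database is access-restricted, so this module generates
admission tables and ventilation time series with the statistical
structure the downstream analysis assumes: four hypoxemia strata,
pressure-controlled ventilation settings held piecewise-constant with
occasional changes, laboratory values on the scales of an adult ICU
population, and an ICU-mortality outcome drawn from a configurable
logistic model on the 48 h time-weighted-average mechanical power per kg
ideal body weight (MP/IBW), age, and highest lactate.

The generator's defaults are the study conditions: stratum mix equal to
the printed cohort fractions, 2:1 male sex ratio, heights spanning
150–200 cm with median 175, baseline log-odds set so that marginal ICU
mortality is about 29%. Missingness is inserted completely at random, in
laboratory columns only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ventmp import metrics

STRATA = ["nonhypoxemic", "mild", "moderate", "severe"]

#: Per-stratum sampling bands: (PFR low, PFR high, FiO2 low, FiO2 high,
#: PEEP low, PEEP high). Lower PFR strata get higher FiO2 and PEEP,
#: mirroring how severity and support co-vary in practice.
_STRATUM_BANDS = {
    "nonhypoxemic": (310, 450, 0.25, 0.45, 4, 9),
    "mild": (200, 300, 0.35, 0.55, 5, 11),
    "moderate": (100, 199, 0.45, 0.70, 7, 14),
    "severe": (40, 99, 0.60, 1.00, 9, 18),
}

LAB_COLUMNS = [
    "wbc_highest", "hemoglobin_lowest", "thrombocytes_lowest", "asat_highest",
    "bilirubin_highest", "aptt_highest", "crp_highest", "lactate_highest",
    "creatinine_highest", "urea_highest", "potassium_highest", "sodium_highest",
    "ph_lowest", "pco2_highest", "be_highest",
]

SPECIALTIES = ["cardio_surgery", "cardiology", "neurosurgery", "internal_medicine",
               "trauma", "pulmonology", "other"]


@dataclass
class SynthConfig:
    """Generative settings for one synthetic cohort.

    beta_mp_ibw is the log-odds of ICU death per 1 J/min/kg of 48 h TWA
    MP/IBW (default 1.4 ≈ an odds ratio of 1.02 per J/min at the median
    IBW of 70.57 kg). beta_covariates maps admission-level covariates to
    per-unit log-odds; defaults carry age (per year) and highest lactate
    (per mmol/L). baseline_log_odds centres marginal mortality near 29%.
    """

    n_admissions: int = 500
    seed: int = 0
    group_mix: tuple[float, float, float, float] = (0.263, 0.3148, 0.3593, 0.0629)
    sampling_interval_min: float = 60.0
    horizon_hours: float = 72.0
    beta_mp_ibw: float = 1.4
    beta_covariates: dict = field(
        default_factory=lambda: {"age_years": 0.035, "lactate_highest": 0.1526}
    )
    baseline_log_odds: float = -4.56
    missing_rate: float = 0.05
    compliance_mean_sd: tuple[float, float] = (35.0, 10.0)  # mL/cmH2O
    rr_range: tuple[float, float] = (12.0, 30.0)
    peep_range: tuple[float, float] = (0.0, 20.0)
    dp_range: tuple[float, float] = (8.0, 22.0)
    change_rate_per_h: float = 1.0 / 12.0  # Poisson setting changes

    def __post_init__(self):
        if self.n_admissions < 0:
            raise ValueError("n_admissions must be non-negative")
        if abs(sum(self.group_mix) - 1.0) > 1e-9:
            raise ValueError("group_mix must sum to 1")
        if not 0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5]")
        if self.horizon_hours < 48:
            raise ValueError("horizon_hours must be >= 48")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("group_mix", "compliance_mean_sd", "rr_range", "peep_range", "dp_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticCohort:
    """Generated admissions, long-format ventilation series, and the latent
    truth (death probability, uniform draw, stratum, 48 h TWA MP/IBW)."""

    admissions: pd.DataFrame
    vent_series: pd.DataFrame
    truth: pd.DataFrame
    config: SynthConfig

    def write(self, out_dir) -> None:
        """Emit admissions.csv, vent_series.csv and a seed manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.admissions.to_csv(out / "admissions.csv", index=False)
        self.vent_series.to_csv(out / "vent_series.csv", index=False)
        manifest = {"seed": self.config.seed, "n_admissions": self.config.n_admissions,
                    "generator": "ventmp.synthetic", "version": 1}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _segment_times(rng, horizon_min, rate_per_h) -> np.ndarray:
    """Setting-change times: 0 plus Poisson arrivals over the horizon."""
    times = [0.0]
    t = 0.0
    while True:
        t += rng.exponential(60.0 / rate_per_h)
        if t >= horizon_min:
            break
        times.append(t)
    return np.asarray(times)


def _labs(rng) -> dict:
    """Admission labs on adult-ICU scales (lognormal/normal marginals)."""
    return {
        "wbc_highest": rng.lognormal(np.log(17.0), 0.30),
        "hemoglobin_lowest": np.clip(rng.normal(5.6, 1.2), 2.5, 11.0),
        "thrombocytes_lowest": rng.lognormal(np.log(130.0), 0.55),
        "asat_highest": rng.lognormal(np.log(90.0), 0.90),
        "bilirubin_highest": rng.lognormal(np.log(12.0), 0.55),
        "aptt_highest": rng.lognormal(np.log(60.0), 0.50),
        "crp_highest": rng.lognormal(np.log(95.0), 0.80),
        "lactate_highest": rng.lognormal(np.log(3.9), 0.60),
        "creatinine_highest": rng.lognormal(np.log(115.0), 0.45),
        "urea_highest": rng.lognormal(np.log(9.0), 0.45),
        "potassium_highest": np.clip(rng.normal(4.8, 0.5), 3.0, 8.0),
        "sodium_highest": np.clip(rng.normal(145.0, 4.0), 125.0, 165.0),
        "ph_lowest": np.clip(rng.normal(7.21, 0.07), 6.8, 7.45),
        "pco2_highest": np.clip(rng.normal(55.0, 8.0), 30.0, 110.0),
        "be_highest": rng.normal(7.0, 4.5),
    }


def generate_cohort(config: SynthConfig) -> SyntheticCohort:
    """Draw one cohort; deterministic for a fixed seed.

    Each admission gets a latent hypoxemia stratum, per-admission
    respiratory-system compliance, and a piecewise-constant ventilation
    series over ``horizon_hours`` sampled every ``sampling_interval_min``.
    Tidal volume follows TV = compliance × ΔP (clipped to 0.2–0.9 L). The
    death indicator is Bernoulli(logistic(baseline + β·covariates)) where
    the exposure covariate is the 48 h TWA MP/IBW computed from the
    generated series itself.
    """
    rng = np.random.default_rng(config.seed)
    adm_rows, vent_rows, truth_rows = [], [], []
    horizon_min = config.horizon_hours * 60.0
    sample_t = np.arange(0.0, horizon_min, config.sampling_interval_min)

    for i in range(config.n_admissions):
        adm_id = f"A{i:05d}"
        stratum = STRATA[rng.choice(4, p=np.asarray(config.group_mix))]
        pfr_lo, pfr_hi, fio2_lo, fio2_hi, peep_lo, peep_hi = _STRATUM_BANDS[stratum]

        sex = "male" if rng.random() < 2 / 3 else "female"
        height = float(np.clip(rng.normal(175.0, 10.0), 150.0, 200.0))
        weight = float(np.clip(rng.normal(80.0, 15.0), 40.0, 150.0))
        age = float(np.clip(rng.normal(65.0, 15.0), 16.0, 95.0))
        compliance_ml = float(np.clip(
            rng.normal(*config.compliance_mean_sd), 10.0, 80.0))

        pfr_base = rng.uniform(pfr_lo, pfr_hi)
        peep_base = rng.uniform(peep_lo, peep_hi)

        seg_t = _segment_times(rng, horizon_min, config.change_rate_per_h)
        seg = []
        for _ in seg_t:
            rr = rng.uniform(*config.rr_range)
            peep = float(np.clip(peep_base + rng.normal(0, 1.0), *config.peep_range))
            dp = rng.uniform(*config.dp_range)
            tv = float(np.clip(compliance_ml / 1000.0 * dp, 0.2, 0.9))
            fio2 = float(np.clip(rng.uniform(fio2_lo, fio2_hi), 0.21, 1.0))
            pfr = float(np.clip(pfr_base + rng.normal(0, (pfr_hi - pfr_lo) * 0.05),
                                pfr_lo, pfr_hi))
            pao2 = float(np.clip(pfr * fio2, 20.0, 600.0))
            ti_max = 60.0 / rr - 0.3
            ti = float(np.clip(rng.normal(1.1, 0.15), 0.6, min(2.0, ti_max)))
            paco2 = float(np.clip(rng.normal(45.0, 8.0), 20.0, 90.0))
            ph = float(np.clip(7.68 - 0.007 * paco2 + rng.normal(0, 0.04), 6.9, 7.6))
            seg.append(dict(tv_L=tv, rr=rr, peep=peep, dp=dp, ti_s=ti,
                            fio2=fio2, pao2=pao2, paco2=paco2, ph=ph))

        idx = np.searchsorted(seg_t, sample_t, side="right") - 1
        for t, j in zip(sample_t, idx):
            for var, val in seg[j].items():
                vent_rows.append((adm_id, float(t), var, val))

        # 48 h TWA MP / IBW from the segment structure itself
        mp_seg = [(float(st), metrics.mechanical_power(s["tv_L"], s["rr"],
                                                       s["peep"], s["dp"]))
                  for st, s in zip(seg_t, seg)]
        ibw_kg = metrics.ibw(height, sex)
        mp_ibw_48 = metrics.twa(mp_seg, 48 * 60.0) / ibw_kg

        labs = _labs(rng)
        lin = (config.baseline_log_odds + config.beta_mp_ibw * mp_ibw_48
               + sum(b * (age if c == "age_years" else labs.get(c, 0.0))
                     for c, b in config.beta_covariates.items()))
        p_death = float(_sigmoid(lin))
        u = float(rng.random())
        died = int(u < p_death)

        mv_duration = float(np.clip(rng.lognormal(np.log(130.0), 0.6), 30.0, 1200.0))
        if died:
            followup = float(min(rng.lognormal(np.log(12.0), 0.8), 90.0))
        else:
            followup = float(min(rng.lognormal(np.log(25.0), 0.7), 90.0))

        adm_rows.append({
            "admission_id": adm_id,
            "age_years": age,
            "sex": sex,
            "height_cm": height,
            "weight_kg": weight,
            "urgency": int(rng.random() < 0.55),
            "specialty": SPECIALTIES[rng.choice(len(SPECIALTIES))],
            "sofa_total": int(np.clip(round(rng.normal(7.3, 2.6)), 0, 24)),
            "sofa_resp": int(np.clip(round(rng.normal(1.9, 0.35)), 0, 4)),
            **labs,
            "icu_mortality": died,
            "mv_duration_h": mv_duration,
            "followup_days": followup,
            "event": died,
        })
        truth_rows.append({
            "admission_id": adm_id,
            "stratum": stratum,
            "p_death": p_death,
            "u": u,
            "mp_ibw_48": mp_ibw_48,
        })

    admissions = pd.DataFrame(
        adm_rows,
        columns=["admission_id", "age_years", "sex", "height_cm", "weight_kg",
                 "urgency", "specialty", "sofa_total", "sofa_resp", *LAB_COLUMNS,
                 "icu_mortality", "mv_duration_h", "followup_days", "event"],
    )
    vent_series = pd.DataFrame(
        vent_rows, columns=["admission_id", "t_min", "variable", "value"])
    truth = pd.DataFrame(
        truth_rows, columns=["admission_id", "stratum", "p_death", "u", "mp_ibw_48"])

    if config.missing_rate > 0 and not admissions.empty:
        mask_rng = np.random.default_rng(config.seed + 1_000_003)
        for col in LAB_COLUMNS:
            hole = mask_rng.random(len(admissions)) < config.missing_rate
            admissions.loc[hole, col] = np.nan

    return SyntheticCohort(admissions, vent_series, truth, config)


def inject_mortality_threshold(
    cohort: SyntheticCohort, tau: float, jump: float
) -> SyntheticCohort:
    """Raise the death log-odds by ``jump`` for admissions whose 48 h TWA
    MP/IBW exceeds ``tau``, and re-realize the death indicators against the
    SAME latent uniform draws (so jump=0 is an exact identity).

    ``tau`` outside the observed MP/IBW range leaves the cohort unchanged
    and emits a warning.
    """
    truth = cohort.truth
    if truth.empty:
        return cohort
    mp = truth["mp_ibw_48"].to_numpy()
    if not (mp.min() <= tau <= mp.max()):
        warnings.warn(
            f"tau={tau} outside observed MP/IBW range "
            f"[{mp.min():.3f}, {mp.max():.3f}]; cohort unchanged",
            stacklevel=2,
        )
        return cohort
    p = truth["p_death"].to_numpy()
    logit = np.log(p / (1 - p))
    above = mp > tau
    p_new = np.where(above, _sigmoid(logit + jump), p)
    died = (truth["u"].to_numpy() < p_new).astype(int)

    new_truth = truth.copy()
    new_truth["p_death"] = p_new
    new_adm = cohort.admissions.copy()
    order = new_adm["admission_id"].map(
        dict(zip(truth["admission_id"], range(len(truth)))))
    new_adm["icu_mortality"] = died[order.to_numpy()]
    new_adm["event"] = new_adm["icu_mortality"]
    return SyntheticCohort(new_adm, cohort.vent_series, new_truth, cohort.config)
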