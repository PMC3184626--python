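"""Synthetic cohorts and external samples for the employment-cost pipeline.

The patient-level assessment database behind the analysis is not publicly
deposited, so every downstream stage is exercised on synthetic data whose
statistical structure mirrors the published cohort description: ~77% female,
mean ages ~41 (men) / ~39 (women), right-skewed illness durations, employment
status recorded for ~92% of patients with a ~9% "other" category, and
inventory scores generated from a shared per-patient severity latent so that
fatigue, disability, mood and pain co-vary as they do clinically.

Employment status is drawn from a configurable logistic model over the same
covariate construction the analysis fits (age per decade, sex, duration in
years, the 0-10 rescaled inventory scores, centre and year effects), which
makes parameter-recovery and confidence-interval-coverage tests exact by
construction. The external duration-of-unemployment sample draws each
record's unemployment/illness fraction from a Beta law with configured per-sex
mean and concentration.

All randomness flows from a single :class:`numpy.random.Generator` seeded
once per run; identical ``(config, seed)`` reproduce identical records.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import cohort, employment

CENTRES = ("centre_a", "centre_b", "centre_c", "centre_d", "centre_e")
YEARS = (2006, 2007, 2008, 2009)


def _default_coefficients() -> dict[str, float]:
    # generative log-odds on the analysis covariate scales; magnitudes sit at
    # the published associations (e.g. ~1.3 per decade of age, ~0.7 per
    # 0-10 point of physical function)
    return {
        "intercept": 0.50,
        "age_decade": 0.27,
        "female": -0.27,
        "duration_years": 0.03,
        "chalder": 0.02,
        "sf36_pf": -0.35,
        "hads_anxiety": -0.02,
        "hads_depression": 0.05,
        "vas_pain": 0.0,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters; defaults emulate the study cohort."""

    n_patients: int = 2170
    seed: int = 0
    prob_female: float = 0.769
    age_mean_male: float = 41.4
    age_mean_female: float = 38.6
    age_sd: float = 11.5
    # log-months of illness duration; the severity loading couples duration
    # to the latent that also drives the inventory scores, reproducing the
    # longer durations seen in the discontinued group
    illness_log_mean_male: float = 3.68
    illness_log_mean_female: float = 3.68
    illness_log_sd: float = 1.15
    illness_severity_loading: float = 0.35
    coefficients: Mapping[str, float] = field(default_factory=_default_coefficients)
    centre_effects: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in CENTRES}
    )
    year_effects: Mapping[int, float] = field(
        default_factory=lambda: {y: 0.0 for y in YEARS}
    )
    status_recorded_prob: float = 0.918
    prob_other_given_recorded: float = 0.091
    prob_temporary_given_discontinued: float = 322 / 998
    complete_inventory_prob: float = 0.91
    duration_missing_prob: float = 0.045
    vas_missing_prob: float = 0.045
    status_missing_mnar: bool = False
    unemployment_fraction_mean_male: float = 0.52
    unemployment_fraction_mean_female: float = 0.47
    unemployment_fraction_concentration: float = 2.0
    n_external_male: int = 22
    n_external_female: int = 38
    external_illness_log_mean: float = 3.33
    external_illness_log_sd: float = 1.2

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in (
            "prob_female",
            "status_recorded_prob",
            "prob_other_given_recorded",
            "prob_temporary_given_discontinued",
            "complete_inventory_prob",
            "duration_missing_prob",
            "vas_missing_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "unemployment_fraction_mean_male",
            "unemployment_fraction_mean_female",
        ):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.unemployment_fraction_concentration <= 0:
            raise ValueError("concentration must be positive")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["coefficients"] = dict(payload["coefficients"])
        payload["centre_effects"] = dict(payload["centre_effects"])
        payload["year_effects"] = {int(k): v for k, v in payload["year_effects"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "year_effects" in payload:
            payload["year_effects"] = {
                int(k): float(v) for k, v in payload["year_effects"].items()
            }
        return cls(**payload)


@dataclass(frozen=True)
class TruthSet:
    """The generative parameters a simulation run actually used, exposed so
    recovery tests can compare estimates against them."""

    coefficients: dict[str, float]
    centre_effects: dict[str, float]
    year_effects: dict[int, float]
    unemployment_fraction_mean: dict[str, float]
    unemployment_fraction_concentration: float


def true_parameters(config: SimulationConfig) -> TruthSet:
    """Pure projection of the config onto the quantities estimators target."""
    return TruthSet(
        coefficients=dict(config.coefficients),
        centre_effects=dict(config.centre_effects),
        year_effects=dict(config.year_effects),
        unemployment_fraction_mean={
            "male": config.unemployment_fraction_mean_male,
            "female": config.unemployment_fraction_mean_female,
        },
        unemployment_fraction_concentration=config.unemployment_fraction_concentration,
    )


# ---------------------------------------------------------------------------
# item-response generation: threshold a shared severity latent per patient

_ITEM_MODELS = {
    # inventory -> (n_items, latent loading, item noise sd, location, levels)
    "chalder": (11, 0.45, 0.70, 2.35, np.arange(4)),
    "hadsA": (7, 0.35, 0.80, 1.45, np.arange(4)),
    "hadsD": (7, 0.40, 0.80, 1.35, np.arange(4)),
}


def _draw_items(rng: np.random.Generator, z: np.ndarray, model: str) -> np.ndarray:
    n_items, load, noise, loc, levels = _ITEM_MODELS[model]
    latent = loc + load * z[:, None] + rng.normal(0, noise, (len(z), n_items))
    return np.clip(np.rint(latent), levels[0], levels[-1])


def _draw_sf36(rng: np.random.Generator, z: np.ndarray) -> np.ndarray:
    # items take {0, 5, 10}; higher severity -> lower physical function
    latent = 4.3 - 2.8 * z[:, None] + rng.normal(0, 3.0, (len(z), 10))
    return np.clip(np.rint(latent / 5.0), 0, 2) * 5.0


def _blank_items(
    rng: np.random.Generator, items: np.ndarray, complete_prob: float
) -> np.ndarray:
    """MCAR item missingness: with prob (1-p)/2 one item blanked (adjusted
    total downstream), with prob (1-p)/2 two items blanked (missing total)."""
    n, k = items.shape
    u = rng.random(n)
    p_miss = (1.0 - complete_prob) / 2.0
    n_blank = np.where(u < p_miss, 2, np.where(u < 2 * p_miss, 1, 0))
    out = items.astype(float)
    for count in (1, 2):
        rows = np.flatnonzero(n_blank == count)
        for r in rows:
            cols = rng.choice(k, size=count, replace=False)
            out[r, cols] = np.nan
    return out


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a synthetic assessment cohort as a patient table.

    Covariates are drawn first (sex, age, centre, year, severity latent,
    illness duration, item responses); employment status then follows the
    configured logistic model given those covariates; missingness is applied
    last, independent of the outcome (missing-completely-at-random), unless
    ``status_missing_mnar`` couples status missingness to age and fatigue.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients

    female = rng.random(n) < config.prob_female
    sex = np.where(female, "female", "male")
    age_mean = np.where(female, config.age_mean_female, config.age_mean_male)
    age = rng.normal(age_mean, config.age_sd)
    for _ in range(40):  # resample out-of-window draws; window is 18-64
        bad = (age < cohort.ELIGIBLE_AGE_MIN) | (age > cohort.ELIGIBLE_AGE_MAX)
        if not bad.any():
            break
        age[bad] = rng.normal(age_mean[bad], config.age_sd)
    age = np.clip(np.rint(age), 18, 64).astype(int)

    centre = rng.choice(CENTRES, size=n)
    year = rng.choice(YEARS, size=n)

    z = rng.normal(0, 1, n)
    log_mu = np.where(
        female, config.illness_log_mean_female, config.illness_log_mean_male
    )
    duration = np.exp(
        log_mu + config.illness_severity_loading * z
        + config.illness_log_sd * rng.normal(0, 1, n)
    )
    duration = np.maximum(np.rint(duration), 1.0)

    chalder = _draw_items(rng, z, "chalder")
    sf36 = _draw_sf36(rng, z)
    hads_a = _draw_items(rng, z, "hadsA")
    hads_d = _draw_items(rng, z, "hadsD")
    vas = np.clip(np.rint(50 + 18 * z + rng.normal(0, 20, n)), 0, 100)

    frame = pd.DataFrame(
        {
            "patient_id": [f"p{i:05d}" for i in range(n)],
            "centre": centre,
            "assessment_year": year,
            "age": age,
            "sex": sex,
            "duration_illness": duration,
        }
    )
    frame[list(cohort.CHALDER_ITEMS)] = chalder
    frame[list(cohort.SF36PF_ITEMS)] = sf36
    frame[list(cohort.HADS_A_ITEMS)] = hads_a
    frame[list(cohort.HADS_D_ITEMS)] = hads_d
    frame["vas"] = vas

    # linear predictor on the analysis covariate scales, pre-missingness
    scored = frame.copy()
    scored["chalder_total"] = chalder.sum(axis=1)
    scored["sf36pf_total"] = sf36.sum(axis=1)
    scored["hads_anxiety"] = hads_a.sum(axis=1)
    scored["hads_depression"] = hads_d.sum(axis=1)
    scored["vas_pain"] = vas
    covs = employment.covariate_frame(scored)
    coef = dict(config.coefficients)
    lp = np.full(n, coef.get("intercept", 0.0))
    for name in employment.DEFAULT_COVARIATES:
        lp += coef.get(name, 0.0) * covs[name].to_numpy()
    lp += np.array([config.centre_effects.get(c, 0.0) for c in centre])
    lp += np.array([config.year_effects.get(int(y), 0.0) for y in year])
    discontinued = rng.random(n) < 1.0 / (1.0 + np.exp(-lp))

    if config.status_missing_mnar:
        # missingness rises with age and fatigue, anchored at the configured
        # marginal rate for an average patient
        base = np.log(
            (1 - config.status_recorded_prob) / config.status_recorded_prob
        )
        miss_lp = base + 0.03 * (age - 39) + 0.06 * (scored["chalder_total"] - 26)
        recorded = rng.random(n) >= 1.0 / (1.0 + np.exp(-miss_lp))
    else:
        recorded = rng.random(n) < config.status_recorded_prob
    other = rng.random(n) < config.prob_other_given_recorded
    temporary = rng.random(n) < config.prob_temporary_given_discontinued

    status = np.where(
        ~recorded,
        None,
        np.where(
            other,
            "other",
            np.where(
                discontinued,
                np.where(
                    temporary, "temporarily_discontinued", "indefinitely_discontinued"
                ),
                "currently_employed",
            ),
        ),
    )
    frame["employment_status"] = status

    frame[list(cohort.CHALDER_ITEMS)] = _blank_items(
        rng, chalder, config.complete_inventory_prob
    )
    frame[list(cohort.SF36PF_ITEMS)] = _blank_items(
        rng, sf36, config.complete_inventory_prob
    )
    frame[list(cohort.HADS_A_ITEMS)] = _blank_items(
        rng, hads_a, config.complete_inventory_prob
    )
    frame[list(cohort.HADS_D_ITEMS)] = _blank_items(
        rng, hads_d, config.complete_inventory_prob
    )
    frame.loc[rng.random(n) < config.vas_missing_prob, "vas"] = np.nan
    frame.loc[rng.random(n) < config.duration_missing_prob, "duration_illness"] = np.nan

    return frame[list(cohort.PATIENT_COLUMNS)]


def simulate_external_sample(
    config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Draw the external duration-of-unemployment sample.

    Each record's unemployment/illness fraction follows Beta(m*nu, (1-m)*nu)
    with per-sex mean m and shared concentration nu; the unemployment
    duration is that fraction of a log-normal illness duration.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for sex, count, mean in (
        ("male", config.n_external_male, config.unemployment_fraction_mean_male),
        ("female", config.n_external_female, config.unemployment_fraction_mean_female),
    ):
        nu = config.unemployment_fraction_concentration
        frac = rng.beta(mean * nu, (1.0 - mean) * nu, size=count)
        illness = np.maximum(
            np.rint(
                np.exp(
                    rng.normal(
                        config.external_illness_log_mean,
                        config.external_illness_log_sd,
                        size=count,
                    )
                )
            ),
            1.0,
        )
        for f, d in zip(frac, illness):
            rows.append(
                {
                    "sex": sex,
                    "duration_illness_months": float(d),
                    "duration_unemployment_months": float(f * d),
                }
            )
    return pd.DataFrame(rows)


def write_simulation(config: SimulationConfig, out_dir, seed: int | None = None) -> None:
    """Write the patient table, external sample, economics fixture copy and
    the truth file for one simulation run."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = simulate_cohort(config, seed)
    cohort.write_patient_table(frame, out / "patients.csv")
    simulate_external_sample(config, seed).to_csv(out / "external.csv", index=False)
    cohort.load_economics_table().to_csv(out / "economics.csv", index=False)
    truth = dataclasses.asdict(true_parameters(config))
    truth["year_effects"] = {int(k): v for k, v in truth["year_effects"].items()}
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
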