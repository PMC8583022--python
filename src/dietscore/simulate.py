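"""Synthetic cohort generation.

Emulates the data structure of an eight-wave women's-health survey cohort:
a one-off dietary intake table (FFQ-derived daily equivalents), per-wave
covariates, per-wave condition reports, deaths assigned to between-survey
intervals, response/dropout patterns, and dietary-data completeness flags.

A standardized latent diet-quality factor ``z`` drives correlated intake
fields, so the three indices computed from a generated cohort correlate
positively as real indices do, and a latent socioeconomic factor ``u``
(correlated with ``z`` and with the covariates) creates confounding.
Condition onset at each wave follows logit(p) = baseline + effect * z +
small covariate effects; onset persists for the five enduring conditions,
while depression and anxiety are drawn fresh each wave.  All randomness
flows from one seed; the same config reproduces the same cohort.

Distribution families: gamma for servings and gram amounts, lognormal for
sodium, beta for the water proportion, a zero-inflated gamma for alcohol.
Default magnitudes are plausible for middle-aged women (e.g. sodium median
~2000 mg/day) with no claim of matching any restricted dataset.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .outcomes import (
    CONDITIONS,
    ENDURING_CONDITIONS,
    EPISODIC_CONDITIONS,
    OUTCOME_WAVES,
    WAVES,
    DeathRecord,
)
from .records import IntakeRecord, ValidationError

#: years since S1 at each survey (1996, 1998, then three-yearly to 2016)
WAVE_YEAR_OFFSETS = {1: 0, 2: 2, 3: 5, 4: 8, 5: 11, 6: 14, 7: 17, 8: 20}


def _default_baseline_logits() -> dict[str, float]:
    # per-wave onset log-odds tuned to plausible cumulative burdens over
    # five follow-up waves (~10% DM/CHD/asthma, ~36% HT, ~14% cancer) and
    # ~14% per-wave depression-and/or-anxiety prevalence
    return {
        "DM": -3.89,
        "CHD": -3.79,
        "HT": -2.38,
        "asthma": -3.89,
        "cancer_nonskin": -3.48,
        "depression": -2.20,
        "anxiety": -2.59,
    }


def _default_diet_effects() -> dict[str, float]:
    # protective log-ORs per SD of latent diet quality, direction and rough
    # magnitude of the associations the pipeline is meant to detect
    return {
        "DM": -0.35,
        "CHD": -0.10,
        "HT": -0.15,
        "asthma": -0.15,
        "cancer_nonskin": 0.0,
        "depression": -0.15,
        "anxiety": -0.15,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for one synthetic cohort; serialisable and hashed into outputs."""

    n_participants: int = 2000
    seed: int = 0
    baseline_logits: dict[str, float] = field(default_factory=_default_baseline_logits)
    diet_effects: dict[str, float] = field(default_factory=_default_diet_effects)
    ses_effect: float = -0.2          # log-OR per SD of SES on condition onset
    smoking_effect: float = 0.2       # extra log-odds of onset for current smokers
    ses_diet_loading: float = 0.4     # corr(SES, diet latent)
    dropout_prob: float = 0.04        # absorbing non-response per wave, S4-S8
    intermittent_nonresponse: float = 0.03  # per-wave skip with later return, S4-S8
    early_nonresponse: float = 0.04   # independent non-response at S2/S3
    death_prob: float = 0.008         # per between-survey interval, S3-S4 .. S7-S8
    death_diet_effect: float = -0.1   # log-OR per SD diet quality on death
    ffq_incomplete_rate: float = 0.11
    covariate_missing_rate: float = 0.03

    def __post_init__(self) -> None:
        for name, p in [
            ("dropout_prob", self.dropout_prob),
            ("early_nonresponse", self.early_nonresponse),
            ("intermittent_nonresponse", self.intermittent_nonresponse),
            ("death_prob", self.death_prob),
            ("ffq_incomplete_rate", self.ffq_incomplete_rate),
            ("covariate_missing_rate", self.covariate_missing_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        missing = set(CONDITIONS) - set(self.baseline_logits)
        if missing:
            raise ValidationError(f"baseline_logits missing conditions: {sorted(missing)}")

    def as_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class CohortData:
    """Everything one synthetic cohort produced, plus the latent factors
    (oracle bookkeeping for parameter-recovery checks)."""

    intake: pd.DataFrame
    covariates: pd.DataFrame
    reports: pd.DataFrame
    deaths: list[DeathRecord]
    responded: pd.DataFrame
    ffq_complete: pd.Series
    latent: pd.DataFrame
    config: SimulationConfig


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _gamma(rng, n, mean, shape, loading, z):
    m = mean * np.exp(loading * z)
    return rng.gamma(shape, m / shape, size=n)


#: intake field -> (base mean, gamma shape, loading on diet latent)
_GAMMA_FIELDS = {
    "total_grain_serv": (4.0, 6.0, 0.15),
    "wholegrain_serv": (1.3, 2.5, 0.28),
    "vegetable_serv": (2.4, 4.0, 0.22),
    "legume_serv": (0.35, 1.5, 0.30),
    "fruit_serv": (1.5, 3.0, 0.22),
    "dairy_serv": (1.6, 4.0, 0.10),
    "meat_protein_serv": (1.6, 4.0, 0.05),
    "discretionary_serv": (3.0, 3.0, -0.32),
    "satfat_pct_energy": (12.0, 20.0, -0.16),
    "mufa_pufa_serv": (1.2, 3.0, 0.20),
    "total_sugar_pct_energy": (9.0, 12.0, -0.12),
    "fish_g": (25.0, 1.5, 0.30),
    "mufa_g": (25.0, 8.0, 0.10),
    "pufa_g": (10.0, 6.0, 0.25),
    "sfa_g": (25.0, 8.0, -0.25),
    "nuts_legumes_serv": (0.4, 1.5, 0.25),
    "ssb_juice_serv": (0.6, 1.2, -0.30),
    "red_processed_meat_serv": (1.0, 3.0, -0.22),
    "lc_omega3_mg": (120.0, 1.5, 0.22),
    "pufa_pct_energy": (5.0, 10.0, 0.18),
    "transfat_pct_energy": (1.2, 6.0, -0.22),
}


def _generate_intake(rng: np.random.Generator, ids: pd.Index, z: np.ndarray) -> pd.DataFrame:
    n = len(ids)
    df = pd.DataFrame({"participant_id": ids})
    for col, (mean, shape, loading) in _GAMMA_FIELDS.items():
        df[col] = _gamma(rng, n, mean, shape, loading, z)
    for col in ("satfat_pct_energy", "total_sugar_pct_energy", "pufa_pct_energy",
                "transfat_pct_energy"):
        df[col] = np.minimum(df[col], 100.0)

    def _noise(sd=0.2):
        return rng.lognormal(0.0, sd, size=n)

    # variety sub-servings: noisy shares of the vegetable total
    for col, share in [
        ("veg_green_serv", 0.30),
        ("veg_orange_serv", 0.25),
        ("veg_cruciferous_serv", 0.25),
        ("veg_tuber_bulb_serv", 0.20),
    ]:
        df[col] = df["vegetable_serv"] * share * _noise(0.4)
    df["fruit_variety_count"] = rng.poisson(1.2 * np.exp(0.3 * z))

    # gram amounts consistent with the serving fields (guideline serving sizes)
    df["veg_g"] = df["vegetable_serv"] * 75.0 * _noise()
    df["legume_g"] = df["legume_serv"] * 75.0 * _noise()
    df["fruit_g"] = df["fruit_serv"] * 150.0 * _noise()
    df["cereal_g"] = df["total_grain_serv"] * 40.0 * _noise()
    df["red_processed_meat_g"] = df["red_processed_meat_serv"] * 65.0 * _noise()
    df["dairy_g"] = df["dairy_serv"] * 250.0 * _noise()
    df["wholegrain_g"] = df["wholegrain_serv"] * 40.0 * _noise()

    df["sodium_mg"] = rng.lognormal(np.log(2000.0) - 0.10 * z, 0.35)

    drinker = rng.random(n) > 0.30
    amount = rng.gamma(1.2, 12.0 / 1.2, size=n)
    df["alcohol_g"] = np.where(drinker, amount, 0.0)
    df["std_drinks"] = df["alcohol_g"] / 10.0
    df["drinks_per_day"] = df["std_drinks"]

    mean_logit = 0.4 + 0.4 * z
    mu = _expit(mean_logit)
    conc = 8.0
    df["water_proportion"] = rng.beta(mu * conc, (1 - mu) * conc)
    return df


_AREA = ("urban", "inner_regional", "outer_regional_rural")
_MARITAL = ("not_married", "married_defacto", "sep_div_wid")
_EDUCATION = ("none", "school_certificate", "apprenticeship_diploma", "university")
_SMOKING = ("never", "past", "current")


def _ordered_from_latent(rng, u, categories, probs):
    """Ordinal category increasing in the latent ``u`` plus noise."""
    score = u + rng.normal(0, 1, size=len(u))
    cuts = np.quantile(score, np.cumsum(probs)[:-1])
    idx = np.searchsorted(cuts, score, side="right")
    return np.array(categories, dtype=object)[idx]


def _generate_covariates(
    rng: np.random.Generator, ids: pd.Index, u: np.ndarray, z: np.ndarray,
    responded: pd.DataFrame, config: SimulationConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    n = len(ids)
    age_s1 = rng.uniform(45.0, 50.0, size=n)
    education = _ordered_from_latent(rng, u, _EDUCATION, [0.14, 0.47, 0.20, 0.19])
    area = rng.choice(_AREA, size=n, p=[0.35, 0.41, 0.24])
    marital = rng.choice(_MARITAL, size=n, p=[0.03, 0.82, 0.15])
    p_current = _expit(-1.5 - 0.4 * u)
    r = rng.random(n)
    smoking = np.where(r < p_current, "current", np.where(r < p_current + 0.25, "past", "never"))
    current_smoker = smoking == "current"

    rows = []
    for wave in WAVES:
        met = rng.gamma(1.2, (600.0 * np.exp(0.25 * u + 0.15 * z)) / 1.2)
        activity = np.array(
            ["nil_sedentary", "low", "moderate", "high"], dtype=object
        )[np.searchsorted([40.0, 600.0, 1200.0], met, side="right")]
        frame = pd.DataFrame(
            {
                "participant_id": ids,
                "wave": wave,
                "age": age_s1 + WAVE_YEAR_OFFSETS[wave],
                "area": area,
                "marital": marital,
                "education": education if wave in (1, 6) else np.nan,
                "occupation": np.where(
                    rng.random(n) < _expit(1.0 + 0.3 * u - 0.15 * (wave - 1)),
                    "paid_job",
                    "no_paid_job",
                ),
                "income_manage": np.where(
                    rng.random(n) < _expit(-0.5 - 0.5 * u), "difficult", "easy_not_bad"
                ),
                "smoking": smoking,
                "physical_activity": activity,
                "prescribed_med": np.where(
                    rng.random(n) < _expit(-1.2 + 0.15 * (wave - 3)), "yes", "no"
                ),
                "otc_med": np.where(rng.random(n) < 0.7, "yes", "no"),
            }
        )
        resp = responded[wave].to_numpy()
        value_cols = [c for c in frame.columns if c not in ("participant_id", "wave")]
        # item non-response among respondents; full missingness otherwise
        for col in value_cols:
            if col == "education":
                continue
            miss = rng.random(n) < config.covariate_missing_rate
            frame.loc[miss | ~resp, col] = np.nan
        frame.loc[~resp, "education"] = np.nan
        rows.append(frame)
    panel = pd.concat(rows, ignore_index=True)
    return panel, current_smoker


def generate_cohort(config: SimulationConfig) -> CohortData:
    """Generate one fully reproducible synthetic cohort."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    ids = pd.Index([f"W{i:06d}" for i in range(n)], name="participant_id")

    u = rng.normal(0, 1, size=n)  # socioeconomic latent
    lam = config.ses_diet_loading
    z = lam * u + np.sqrt(1 - lam**2) * rng.normal(0, 1, size=n)  # diet latent

    intake = _generate_intake(rng, ids, z)

    # deaths first (they censor response)
    death_interval = np.full(n, np.inf)
    alive = np.ones(n, dtype=bool)
    for wave in OUTCOME_WAVES:
        p = _expit(
            np.log(config.death_prob / (1 - config.death_prob)) + config.death_diet_effect * z
        )
        dies = alive & (rng.random(n) < p)
        death_interval[dies] = wave
        alive &= ~dies
    deaths = [
        DeathRecord(ids[i], int(death_interval[i]))
        for i in range(n)
        if np.isfinite(death_interval[i])
    ]

    responded = pd.DataFrame(True, index=ids, columns=list(WAVES))
    for wave in (2, 3):
        responded[wave] = rng.random(n) >= config.early_nonresponse
    dropped = np.zeros(n, dtype=bool)
    for wave in OUTCOME_WAVES:
        dropped |= rng.random(n) < config.dropout_prob
        skipped = rng.random(n) < config.intermittent_nonresponse
        responded[wave] = ~dropped & ~skipped & (death_interval > wave)

    panel, current_smoker = _generate_covariates(rng, ids, u, z, responded, config)

    # condition onset: enduring conditions persist, episodic redrawn per wave
    report_rows = []
    onset = {cond: np.zeros(n, dtype=bool) for cond in ENDURING_CONDITIONS}
    for wave in WAVES:
        for cond in ENDURING_CONDITIONS:
            logit = (
                config.baseline_logits[cond]
                + config.diet_effects[cond] * z
                + config.ses_effect * u
                + config.smoking_effect * current_smoker
            )
            new = ~onset[cond] & (rng.random(n) < _expit(logit)) & (death_interval >= wave)
            onset[cond] |= new
            for i in np.flatnonzero(new):
                report_rows.append(
                    {"participant_id": ids[i], "wave": wave, "condition": cond, "reported": 1}
                )
        for cond in EPISODIC_CONDITIONS:
            logit = (
                config.baseline_logits[cond]
                + config.diet_effects[cond] * z
                + config.ses_effect * u
            )
            present = (rng.random(n) < _expit(logit)) & (death_interval >= wave)
            for i in np.flatnonzero(present):
                report_rows.append(
                    {"participant_id": ids[i], "wave": wave, "condition": cond, "reported": 1}
                )
    reports = pd.DataFrame(report_rows, columns=["participant_id", "wave", "condition", "reported"])

    ffq_complete = pd.Series(rng.random(n) >= config.ffq_incomplete_rate, index=ids, name="ffq_complete")

    latent = pd.DataFrame({"participant_id": ids, "diet_z": z, "ses": u}).set_index(
        "participant_id"
    )
    return CohortData(intake, panel, reports, deaths, responded, ffq_complete, latent, config)


def make_worked_profiles() -> dict[str, IntakeRecord]:
    """Canonical fixture intake profiles: index-maximal and index-minimal
    diets and the printed discretionary band edges."""
    profiles = {
        "heifa_max": IntakeRecord(
            participant_id="heifa_max",
            total_grain_serv=6.0,
            wholegrain_serv=3.0,
            vegetable_serv=5.0,
            veg_green_serv=1.0,
            veg_orange_serv=1.0,
            veg_cruciferous_serv=1.0,
            veg_tuber_bulb_serv=1.0,
            legume_serv=0.5,
            fruit_serv=2.0,
            fruit_variety_count=2,
            dairy_serv=2.5,
            meat_protein_serv=2.5,
            discretionary_serv=1.0,
            satfat_pct_energy=9.0,
            mufa_pufa_serv=2.0,
            sodium_mg=1500.0,
            total_sugar_pct_energy=4.0,
            std_drinks=1.0,
            water_proportion=0.6,
        ),
        "heifa_min": IntakeRecord(
            participant_id="heifa_min",
            discretionary_serv=6.0,
            satfat_pct_energy=15.0,
            sodium_mg=3000.0,
            total_sugar_pct_energy=15.0,
            std_drinks=3.0,
            water_proportion=0.0,
        ),
        "mds_best": IntakeRecord(
            participant_id="mds_best",
            veg_g=300.0,
            legume_g=50.0,
            fruit_g=400.0,
            cereal_g=200.0,
            fish_g=60.0,
            mufa_g=40.0,
            pufa_g=20.0,
            sfa_g=15.0,
            red_processed_meat_g=30.0,
            dairy_g=100.0,
            alcohol_g=15.0,
        ),
        "mds_worst": IntakeRecord(
            participant_id="mds_worst",
            veg_g=100.0,
            legume_g=5.0,
            fruit_g=100.0,
            cereal_g=80.0,
            fish_g=5.0,
            mufa_g=10.0,
            pufa_g=5.0,
            sfa_g=30.0,
            red_processed_meat_g=120.0,
            dairy_g=400.0,
            alcohol_g=0.0,
        ),
        "ahei_max": IntakeRecord(
            participant_id="ahei_max",
            vegetable_serv=5.0,
            fruit_serv=4.0,
            wholegrain_g=75.0,
            nuts_legumes_serv=1.0,
            lc_omega3_mg=250.0,
            pufa_pct_energy=10.0,
            ssb_juice_serv=0.0,
            red_processed_meat_serv=0.0,
            transfat_pct_energy=0.4,
            sodium_mg=900.0,
            drinks_per_day=1.0,
        ),
        "ahei_min": IntakeRecord(
            participant_id="ahei_min",
            vegetable_serv=0.0,
            fruit_serv=0.0,
            wholegrain_g=0.0,
            nuts_legumes_serv=0.0,
            lc_omega3_mg=0.0,
            pufa_pct_energy=2.0,
            ssb_juice_serv=1.2,
            red_processed_meat_serv=1.5,
            transfat_pct_energy=4.5,
            sodium_mg=3600.0,
            drinks_per_day=3.0,
        ),
    }
    for servings in (2.4, 3.0, 3.5, 4.4, 4.5, 5.4, 5.5, 6.0):
        name = f"discretionary_{servings:g}serv"
        profiles[name] = IntakeRecord(participant_id=name, discretionary_serv=servings)
    return profiles


def sodium_reference_profiles() -> list[IntakeRecord]:
    """A constructed 20-record sample spanning 1000-2900 mg/day of sodium,
    used to anchor the AHEI decile reference in worked examples: the
    ``ahei_max`` profile (900 mg) falls in its lowest decile and
    ``ahei_min`` (3600 mg) in its highest."""
    return [
        IntakeRecord(participant_id=f"sodium_ref_{i:02d}", sodium_mg=1000.0 + 100.0 * i)
        for i in range(20)
    ]
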