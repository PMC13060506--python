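"""Synthetic trial cohorts.

Generates complete, reproducible trials — participant profiles with latent
truths, adjusting-amount choice records across five sessions, purchase-task
responses, and daily drinking/breath records over three monitoring phases —
so every downstream estimator can be exercised and validated against known
generating parameters without any external data.

Generating model
----------------
* latent discount rates: ln(k) ~ Normal(mean_ln_k, sd_ln_k^2), constant
  across sessions; choices from a softmax on the two options' hyperbolic
  present values with temperature ``noise_sd_choice`` (0 = deterministic).
* purchase responses: exponentiated demand with participant-level latent
  Q0 and alpha (log-normal around the configured means), multiplicative
  log10-normal noise, integer rounding, and the 50-drink cap.
* daily drinking: per-day counts ~ Poisson(participant rate x group-phase
  factor); participant rates Gamma-distributed around
  ``mean_baseline_drinks``.  Days are conditionally independent given the
  participant rate.
* breath samples: up to three per day; sample s of a day with d drinks has
  BrAC max(0, brac_per_drink * d * decay_s + noise), so the daily peak
  increases with drinks; a small heavy-tailed contamination adds occasional
  unexplained positive readings, mimicking drinking outside the reporting
  window.
* missingness: each drink report and each breath sample is independently
  missing with probability sigmoid(phase log-odds + participant propensity).

One master seed fans out to per-participant substreams (SeedSequence.spawn),
so enlarging the cohort never reshuffles earlier participants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .demand import DEFAULT_PRICES, DEFAULT_CAP, exponentiated_demand
from .discounting import TitrationSchedule, run_titration, hyperbolic_value

__all__ = [
    "CohortConfig",
    "ParticipantProfile",
    "CohortData",
    "ConfigError",
    "simulated_chooser",
    "simulate_cohort",
]

PHASES = ("baseline", "monitoring1", "monitoring2")
PHASE_LENGTHS = {"baseline": 7, "monitoring1": 14, "monitoring2": 14}
SESSIONS = ("S1", "S2", "S3", "S4", "S5")

# internal generator constants, not trial conditions
_RATE_GAMMA_SHAPE = 6.25          # drinks/day rate heterogeneity (CV = 0.4)
_LN_Q0_SD = 0.3                   # participant spread of latent demand Q0
_LN_ALPHA_SD = 0.5                # participant spread of latent elasticity
_GEN_K_SPAN = 2.0                 # log10 span used to generate demand data
_BRAC_NOISE_SD = 0.004            # additive BrAC noise (% BrAC)
_BRAC_DECAY = (1.0, 0.6, 0.3)     # later samples catch less of the peak
# occasional unexplained positive readings (drinking outside the reporting
# window, device artifacts): heavy-tailed contamination per sample
_BRAC_ARTIFACT_P = 0.02
_BRAC_ARTIFACT_SCALE = 0.03
# probability that a drinking day's submitted samples all precede the
# drinking episode, yielding negative samples despite a positive report --
# the dominant source of breath/self-report discordance
_P_PREDRINK_SAMPLES = 0.35
_PROPENSITY_SD = 0.3              # participant spread in missingness log-odds


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


def _default_phase_effects() -> dict:
    # EFT drinking declines across phases; CET dips transiently then returns
    return {
        "EFT": {"baseline": 1.0, "monitoring1": 0.75, "monitoring2": 0.55},
        "CET": {"baseline": 1.0, "monitoring1": 0.85, "monitoring2": 1.0},
    }


def _default_missingness() -> dict:
    # submissions get sparser as the study progresses
    return {"baseline": -2.2, "monitoring1": -1.8, "monitoring2": -1.2}


@dataclass
class CohortConfig:
    """Generative parameters for one synthetic trial."""

    n_per_group: int = 32
    mean_ln_k: float = -5.0
    sd_ln_k: float = 2.5
    mean_baseline_drinks: float = 5.5
    phase_effects: dict = field(default_factory=_default_phase_effects)
    demand_Q0_mean: float = 10.0
    demand_alpha_mean: float = 0.003
    noise_sd_choice: float = 20.0
    noise_sd_demand: float = 0.1
    missingness_log_odds: dict = field(default_factory=_default_missingness)
    brac_per_drink: float = 0.012
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        for name in ("sd_ln_k", "noise_sd_choice", "noise_sd_demand"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("mean_baseline_drinks", "demand_Q0_mean",
                     "demand_alpha_mean", "brac_per_drink"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for g in ("EFT", "CET"):
            if g not in self.phase_effects:
                raise ConfigError(f"phase_effects missing group {g}")
            for ph in PHASES:
                f = self.phase_effects[g].get(ph)
                if f is None or f <= 0:
                    raise ConfigError(
                        f"phase_effects[{g}][{ph}] must be a positive rate factor")
        for ph in PHASES:
            if ph not in self.missingness_log_odds:
                raise ConfigError(f"missingness_log_odds missing phase {ph}")


@dataclass
class ParticipantProfile:
    id: str
    group: str
    latent_ln_k: float
    latent_Q0: float
    latent_alpha: float
    baseline_rate: float
    missing_propensity: float
    age: int
    sex: str
    ethnicity: str
    race: str
    education: str
    income: str
    audit_score: int


@dataclass
class CohortData:
    """The four long-format tables of one simulated trial."""

    profiles: pd.DataFrame
    choices: pd.DataFrame
    purchases: pd.DataFrame
    daily: pd.DataFrame
    config: CohortConfig

    def write(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.profiles.to_csv(out / "profiles.csv", index=False)
        self.choices.to_csv(out / "choices.csv", index=False)
        self.purchases.to_csv(out / "purchase.csv", index=False)
        self.daily.to_csv(out / "daily.csv", index=False)


def simulated_chooser(latent_ln_k: float, temperature: float,
                      rng: np.random.Generator | None = None):
    """Choice rule of a hyperbolic discounter with softmax response noise.

    Returns a chooser(ss, ll, delay) -> 'SS'|'LL'.  The SS is chosen with
    probability sigmoid((ss - present value of LL)/temperature); temperature
    0 gives the deterministic value maximizer (ties go to the LL).
    """
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    k = math.exp(latent_ln_k)
    if temperature > 0 and rng is None:
        raise ValueError("a noisy chooser needs an rng")

    def chooser(ss: float, ll: float, delay_days: float) -> str:
        if ss < 0 or ll < 0:
            raise ValueError("amounts must be nonnegative")
        v_ll = hyperbolic_value(ll, k, delay_days)
        if temperature == 0:
            return "SS" if ss > v_ll else "LL"
        p_ss = 1.0 / (1.0 + math.exp(-(ss - v_ll) / temperature))
        return "SS" if rng.random() < p_ss else "LL"

    return chooser


def _recording_chooser(chooser, log: list, participant: str, session: str):
    counters: dict[float, int] = {}

    def wrapped(ss, ll, delay):
        counters[delay] = counters.get(delay, 0) + 1
        choice = chooser(ss, ll, delay)
        log.append({"participant": participant, "session": session,
                    "delay_days": delay, "trial_index": counters[delay],
                    "ss_amount": ss, "choice": choice})
        return choice

    return wrapped


_RACES = ("White", "Black or African American", "Asian",
          "More Than One Race", "Other")
_RACE_P = (0.78, 0.13, 0.02, 0.04, 0.03)
_EDU = ("High School", "College", "Graduate School")
_EDU_P = (0.19, 0.62, 0.19)
_INCOME = ("<5k", "5-25k", "25-50k", "50-75k", "75-100k", ">=100k")
_INCOME_P = (0.11, 0.17, 0.30, 0.13, 0.12, 0.17)


def _draw_profile(pid: str, group: str, cfg: CohortConfig,
                  rng: np.random.Generator) -> ParticipantProfile:
    ln_k = rng.normal(cfg.mean_ln_k, cfg.sd_ln_k)
    q0 = cfg.demand_Q0_mean * math.exp(rng.normal(0.0, _LN_Q0_SD)
                                       - _LN_Q0_SD ** 2 / 2)
    alpha = cfg.demand_alpha_mean * math.exp(rng.normal(0.0, _LN_ALPHA_SD)
                                             - _LN_ALPHA_SD ** 2 / 2)
    rate = rng.gamma(_RATE_GAMMA_SHAPE,
                     cfg.mean_baseline_drinks / _RATE_GAMMA_SHAPE)
    return ParticipantProfile(
        id=pid, group=group, latent_ln_k=float(ln_k), latent_Q0=float(q0),
        latent_alpha=float(alpha), baseline_rate=float(rate),
        missing_propensity=float(rng.normal(0.0, _PROPENSITY_SD)),
        age=int(rng.integers(21, 66)),
        sex=str(rng.choice(("Male", "Female"), p=(0.63, 0.37))),
        ethnicity=str(rng.choice(("Not Hispanic or Latino", "Hispanic or Latino"),
                                 p=(0.94, 0.06))),
        race=str(rng.choice(_RACES, p=_RACE_P)),
        education=str(rng.choice(_EDU, p=_EDU_P)),
        income=str(rng.choice(_INCOME, p=_INCOME_P)),
        audit_score=int(np.clip(round(rng.normal(23.0, 4.0)), 16, 40)),
    )


def simulate_cohort(config: CohortConfig) -> CohortData:
    """Generate one complete synthetic trial.

    Every participant gets five discounting task administrations and five
    purchase tasks (one per session) and 35 daily records spanning the three
    monitoring phases.  Identical config and seed give identical output.
    """
    config.validate()
    n_total = 2 * config.n_per_group
    children = np.random.SeedSequence(config.seed).spawn(n_total)
    schedule = TitrationSchedule()
    prices = np.asarray(DEFAULT_PRICES)

    profiles, choice_rows, purchase_rows, daily_rows = [], [], [], []
    for i in range(n_total):
        rng = np.random.default_rng(children[i])
        group = "EFT" if i % 2 == 0 else "CET"
        pid = f"P{i + 1:03d}"
        prof = _draw_profile(pid, group, config, rng)
        profiles.append(asdict(prof))

        for session in SESSIONS:
            chooser = simulated_chooser(prof.latent_ln_k,
                                        config.noise_sd_choice, rng)
            run_titration(_recording_chooser(chooser, choice_rows, pid, session),
                          schedule, session=session)

            q_true = exponentiated_demand(prices, prof.latent_Q0,
                                          prof.latent_alpha, _GEN_K_SPAN)
            noise = rng.normal(0.0, config.noise_sd_demand, size=prices.size)
            q_obs = np.minimum(np.rint(q_true * 10.0 ** noise), DEFAULT_CAP)
            for price, q in zip(prices, q_obs.astype(int)):
                purchase_rows.append({"participant": pid, "session": session,
                                      "price": float(price), "quantity": int(q)})

        day = 0
        for phase in PHASES:
            factor = config.phase_effects[group][phase]
            p_miss = float(expit(config.missingness_log_odds[phase]
                                 + prof.missing_propensity))
            for _ in range(PHASE_LENGTHS[phase]):
                day += 1
                drinks = int(rng.poisson(prof.baseline_rate * factor))
                sampled_before_drinking = rng.random() < _P_PREDRINK_SAMPLES
                row = {"participant": pid, "day_index": day, "phase": phase,
                       "group": group,
                       "reported_drinks": (np.nan if rng.random() < p_miss
                                           else drinks)}
                peak_clean = (0.0 if sampled_before_drinking
                              else config.brac_per_drink * drinks)
                for s in range(3):
                    if rng.random() < p_miss:
                        row[f"brac_{s + 1}"] = np.nan
                    else:
                        val = peak_clean * _BRAC_DECAY[s] + \
                            rng.normal(0.0, _BRAC_NOISE_SD)
                        if rng.random() < _BRAC_ARTIFACT_P:
                            val += rng.exponential(_BRAC_ARTIFACT_SCALE)
                        row[f"brac_{s + 1}"] = max(0.0, val)
                daily_rows.append(row)

    return CohortData(
        profiles=pd.DataFrame(profiles).rename(columns={"id": "participant"}),
        choices=pd.DataFrame(choice_rows),
        purchases=pd.DataFrame(purchase_rows),
        daily=pd.DataFrame(daily_rows),
        config=config,
    )
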