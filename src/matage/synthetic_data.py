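"""Synthetic individual life histories with known ground-truth rates.

Emulates the rotifer life-table experiment: clonal (all-female) cohorts
established from mothers of age 3, 5, 7 or 9 days, each followed daily
under ad libitum (AL) or chronically restricted (LF, 10% food) rations,
with roughly 70 individuals per maternal-age-by-treatment cell.

The generative model is deliberately minimal but reproduces the features
the analysis is designed to detect:

* mortality: Gompertz hazard ``h(j) = a exp(b j)`` after a juvenile period
  of guaranteed survival (through age 3), scaled by a proportional
  maternal-age factor ``1 + gamma * i`` — the Lansing effect, offspring of
  older mothers dying faster — and, under caloric restriction, by a hazard
  multiplier ``delta < 1`` beyond a threshold age (lifespan extension);
* reproduction: daily offspring are Poisson with a gamma-kernel mean
  schedule ``mu(j) = c (j - alpha)^(kappa-1) exp(-(j - alpha)/theta)``
  (early-peaked, right-skewed), scaled by a linear maternal-age decline
  ``max(1 - d i, 0)`` — reproductive Lansing effect.  Caloric restriction
  delays the schedule (``alpha + delay``) and lowers its scale (``c * rho``),
  the delayed/flattened reproduction seen under restriction;
* right censoring: independent per-day loss probability ``epsilon``.

Default parameters put the ad libitum ground truth at lambda ~ 1.9 and
R0 ~ 20 per day/lifetime, the regime of laboratory rotifer populations.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .data_io import validate_life_histories
from .rate_surfaces import OMEGA, S, RateSurfaces

#: Simulation horizon: individuals still alive here are censored (the
#: Gompertz hazard makes survival this long vanishingly rare).
MAX_DAYS = 29


@dataclass(frozen=True)
class SyntheticParams:
    """Ground-truth parameters of the synthetic experiment.

    Units: ages and maternal ages in days; hazards per day; fertility in
    daughters per day.
    """

    maternal_ages: tuple[int, ...] = (3, 5, 7, 9)
    n_per_cohort: int = 70
    # survival: Gompertz baseline, juvenile plateau, Lansing factor
    hazard_a: float = 0.003
    hazard_b: float = 0.40
    juvenile_age: int = 3  # no mortality through this age
    gamma: float = 0.15  # proportional hazard increase per day of maternal age
    # caloric-restriction survival effect
    lf_hazard_multiplier: float = 0.35
    lf_hazard_age_threshold: int = 3  # LF multiplier applies beyond this age
    # fertility: gamma-kernel schedule and maternal-age decline
    fert_scale: float = 3.5
    fert_alpha: float = 2.2  # reproduction starts after this age
    fert_kappa: float = 3.0
    fert_theta: float = 1.7
    fert_decline: float = 0.042  # linear decline per day of maternal age
    # caloric-restriction fertility effects
    lf_delay: float = 0.15
    lf_scale: float = 0.97
    # right censoring
    censor_prob: float = 0.01

    def __post_init__(self):
        if self.hazard_a <= 0 or self.hazard_b < 0:
            raise ValueError("Gompertz parameters must be positive")
        if not 0 < self.lf_hazard_multiplier <= 1:
            raise ValueError("LF hazard multiplier must lie in (0, 1]")
        if self.fert_scale < 0 or self.fert_theta <= 0 or self.fert_kappa <= 0:
            raise ValueError("fertility kernel parameters must be positive")
        if not 0 <= self.censor_prob < 1:
            raise ValueError("censoring probability must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def _hazard(params: SyntheticParams, treatment: str, ages: np.ndarray,
            maternal_age: int) -> np.ndarray:
    """Daily hazard h(i, j) for one maternal age, over integer ages."""
    h = params.hazard_a * np.exp(params.hazard_b * ages)
    h = np.where(ages <= params.juvenile_age, 0.0, h)
    h = h * (1.0 + params.gamma * maternal_age)
    if treatment == "LF":
        h = np.where(
            ages > params.lf_hazard_age_threshold,
            h * params.lf_hazard_multiplier,
            h,
        )
    return h


def _mean_fertility(params: SyntheticParams, treatment: str, ages: np.ndarray,
                    maternal_age: int) -> np.ndarray:
    """Expected daily offspring mu(i, j) for one maternal age."""
    alpha = params.fert_alpha
    scale = params.fert_scale
    if treatment == "LF":
        alpha = alpha + params.lf_delay
        scale = scale * params.lf_scale
    u = np.clip(ages - alpha, 0.0, None)
    kernel = np.where(
        u > 0, u ** (params.fert_kappa - 1) * np.exp(-u / params.fert_theta), 0.0
    )
    decline = max(1.0 - params.fert_decline * maternal_age, 0.0)
    return scale * kernel * decline


def ground_truth_surfaces(
    params: SyntheticParams = SyntheticParams(),
) -> dict[str, RateSurfaces]:
    """Closed-form rate surfaces implied by the parameters, per treatment.

    Survivorship is ``l(i, j) = exp(-sum_{j' <= j} h(i, j'))`` and daily
    fertility the mean schedule, on the full 19 x 19 grid.
    """
    ages = np.arange(1, OMEGA + 1, dtype=float)
    out = {}
    for treatment in ("AL", "LF"):
        l = np.ones((S, OMEGA + 1))
        m = np.zeros((S, OMEGA))
        for i in range(1, S + 1):
            h = _hazard(params, treatment, ages, i)
            l[i - 1, 1:] = np.exp(-np.cumsum(h))
            m[i - 1] = _mean_fertility(params, treatment, ages, i)
        out[treatment] = RateSurfaces(
            treatment=treatment,
            l=l,
            m=m,
            survival_provenance=["observed"] * S,
            fertility_provenance=["observed"] * S,
            meta={"ground_truth": True, **params.to_dict()},
        ).validate()
    return out


def generate(
    params: SyntheticParams = SyntheticParams(),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate a life-history table for the full 2 x 4 cohort design.

    Each individual lives through daily Bernoulli survival against its
    ground-truth hazard, produces Poisson daily offspring while alive, and
    may be lost (right-censored) with probability ``censor_prob`` each day.
    Deterministic for a fixed seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ages = np.arange(1, MAX_DAYS + 1, dtype=float)
    frames = []
    counter = 0
    for treatment in ("AL", "LF"):
        for maternal_age in params.maternal_ages:
            n = params.n_per_cohort
            h = _hazard(params, treatment, ages, maternal_age)
            q_die = 1.0 - np.exp(-h)  # death probability during each day
            mu = _mean_fertility(params, treatment, ages, maternal_age)

            dies = rng.random((n, MAX_DAYS)) < q_die
            lost = rng.random((n, MAX_DAYS)) < params.censor_prob
            death_day = np.where(
                dies.any(axis=1), dies.argmax(axis=1) + 1, MAX_DAYS + 1
            )
            censor_day = np.where(
                lost.any(axis=1), lost.argmax(axis=1) + 1, MAX_DAYS
            )
            duration = np.minimum(death_day, censor_day)
            died = death_day <= censor_day
            offspring = rng.poisson(np.broadcast_to(mu, (n, MAX_DAYS)))

            # expand to long format: rows 1..duration per individual, the
            # last row terminal (dead/censored, offspring forced to 0)
            ids = np.array(
                [
                    f"{treatment}-m{maternal_age:02d}-{counter + ind:05d}"
                    for ind in range(1, n + 1)
                ],
                dtype=object,
            )
            counter += n
            row_ind = np.repeat(np.arange(n), duration)
            age_day = np.concatenate([np.arange(1, d + 1) for d in duration])
            terminal = age_day == duration[row_ind]
            status = np.where(
                terminal, np.where(died[row_ind], "dead", "censored"), "alive"
            )
            off = offspring[row_ind, age_day - 1]
            off[terminal] = 0
            frames.append(
                pd.DataFrame(
                    {
                        "individual_id": ids[row_ind],
                        "treatment": treatment,
                        "maternal_age": maternal_age,
                        "age_day": age_day,
                        "status": status,
                        "offspring": off,
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    return validate_life_histories(table)
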