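"""Nonparametric vital-rate surfaces on the maternal-age × age grid.

Laboratory cohorts provide daily survival and fertility observations at
maternal ages 3, 5, 7 and 9 days only.  The matrix model needs rates for
every maternal age 1..19, so observed cohort curves are interpolated to
maternal ages 4, 6 and 8 and extrapolated to 10..19:

* Fertility is handled on the *cumulative* scale, where curves must be
  monotone even though daily rates fluctuate.  Missing curves between
  observed maternal ages are pointwise means of the flanking curves; beyond
  maternal age 9 every curve is the previous one scaled by the ratio ``r``
  of total cumulative fertility between maternal ages 9 and 8.  Daily rates
  are recovered by first differences.  Maternal ages 1-2 reuse the maternal
  age 3 curve.
* Survivorship uses the same interpolation, and extrapolation by a single
  multiplier ``k`` fitted (least squares) so that ``k`` times the maternal
  age 8 curve best predicts the observed maternal age 9 curve; ``k`` is then
  applied successively for maternal ages 10..19, holding a 100%-survival
  plateau through age 3 so extrapolation acts from age 4 on.
* Under the low-food treatment, where survivorship at maternal ages 3-7
  does not differ, those cohorts are pooled into one curve applied to
  maternal ages 1-7; maternal age 8 is the mean of the pooled and the
  observed maternal-age-9 curves.

Censoring is handled by Kaplan-Meier product-limit estimation, which
reduces to simple proportions when no one is censored.  The estimator is
implemented directly on per-individual summaries so the whole fitting
pipeline can be re-run cheaply thousands of times by the permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Maximum age class omega and maximum maternal age s, in days.  No
#: individual reproduced after 19 days of age in the laboratory populations.
OMEGA = 19
S = 19

#: All maternal-age survivorship curves keep 100% survival through this age;
#: extrapolation multipliers act from the next age on.
PLATEAU_AGE = 3

OBSERVED_MATERNAL_AGES = (3, 5, 7, 9)


class CohortError(ValueError):
    """A required maternal-age cohort is empty or missing."""


class MonotonicityError(ValueError):
    """An input curve violates its required monotonicity."""


@dataclass(frozen=True)
class RateOptions:
    """Fitting choices for surface construction.

    estimator : ``"km"`` (Kaplan-Meier product-limit) or ``"raw"``
        (deaths over initial cohort size, ignoring censoring).
    pool : how the low-food maternal ages 3/5/7 are pooled -- ``"km"``
        merges the individuals into one risk set, ``"curve_mean"`` averages
        the three cohort curves.
    extrapolate_survival : when False, maternal ages 10..19 are assigned
        the observed maternal-age-9 survivorship curve unchanged (the
        conservative no-extrapolation variant).
    """

    estimator: str = "km"
    pool: str = "km"
    extrapolate_survival: bool = True
    observed_maternal_ages: tuple[int, ...] = OBSERVED_MATERNAL_AGES
    plateau_age: int = PLATEAU_AGE


@dataclass
class IndividualSummaries:
    """Per-individual arrays: the minimal input to the fitting pipeline.

    One entry per individual: observation length (``duration``, the last
    observed age-day), whether that last day was a death (``event``), plus
    dense daily offspring counts and at-risk (alive) indicators over ages
    1..OMEGA.  Shuffling treatment labels (for permutation tests) never
    touches anything but ``treatment``.
    """

    individual_id: np.ndarray
    treatment: np.ndarray
    maternal_age: np.ndarray
    duration: np.ndarray
    event: np.ndarray
    offspring: np.ndarray  # (n, OMEGA) float
    alive: np.ndarray  # (n, OMEGA) bool

    def __len__(self) -> int:
        return len(self.individual_id)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "IndividualSummaries":
        codes, uniques = pd.factorize(table["individual_id"], sort=True)
        n = len(uniques)
        duration = np.zeros(n, dtype=int)
        event = np.zeros(n, dtype=bool)
        treatment = np.empty(n, dtype=object)
        maternal_age = np.zeros(n, dtype=int)
        offspring = np.zeros((n, OMEGA))
        alive = np.zeros((n, OMEGA), dtype=bool)

        age = table["age_day"].to_numpy()
        status = table["status"].to_numpy()
        off = table["offspring"].to_numpy(dtype=float)

        np.maximum.at(duration, codes, age)
        is_dead = status == "dead"
        event[codes[is_dead]] = True
        treatment[codes] = table["treatment"].to_numpy()
        maternal_age[codes] = table["maternal_age"].to_numpy()

        in_grid = (age <= OMEGA) & (status == "alive")
        alive[codes[in_grid], age[in_grid] - 1] = True
        offspring[codes[in_grid], age[in_grid] - 1] = off[in_grid]
        return cls(
            individual_id=np.asarray(uniques),
            treatment=np.asarray(treatment, dtype=object),
            maternal_age=maternal_age,
            duration=duration,
            event=event,
            offspring=offspring,
            alive=alive,
        )

    def select(self, mask: np.ndarray) -> "IndividualSummaries":
        return IndividualSummaries(
            self.individual_id[mask],
            self.treatment[mask],
            self.maternal_age[mask],
            self.duration[mask],
            self.event[mask],
            self.offspring[mask],
            self.alive[mask],
        )

    def with_treatment(self, labels: np.ndarray) -> "IndividualSummaries":
        return replace(self, treatment=np.asarray(labels, dtype=object))


@dataclass
class CohortCurves:
    """Observed curves for one maternal-age cohort (or a pooled set)."""

    treatment: str
    maternal_age: int | tuple[int, ...]
    survivorship: np.ndarray  # ages 0..OMEGA
    fertility: np.ndarray  # ages 1..OMEGA
    n_at_risk: np.ndarray  # alive counts, ages 1..OMEGA
    n: int


@dataclass
class RateSurfaces:
    """Survivorship and daily fertility on the full 19 x 19 grid.

    ``l[i-1, j]`` is the probability that an individual of maternal age
    ``i`` survives from birth to age ``j`` (j = 0..19); ``m[i-1, j-1]`` is
    its expected number of daughters during age-day ``j`` (j = 1..19),
    conditional on being alive.  ``survival_provenance`` and
    ``fertility_provenance`` record, per maternal age, whether the row was
    observed, copied, pooled, interpolated or extrapolated.  ``meta``
    carries the fertility extrapolation ratio ``r`` and the survival
    multiplier ``k``.
    """

    treatment: str
    l: np.ndarray  # (S, OMEGA + 1)
    m: np.ndarray  # (S, OMEGA)
    survival_provenance: list[str] = field(default_factory=list)
    fertility_provenance: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def validate(self, atol: float = 1e-9) -> "RateSurfaces":
        s, omega = self.m.shape
        if self.l.shape != (s, omega + 1):
            raise ValueError("surface shape mismatch")
        if not np.allclose(self.l[:, 0], 1.0):
            raise MonotonicityError("survivorship must start at 1")
        if (self.l < -atol).any() or (self.l > 1 + atol).any():
            raise MonotonicityError("survivorship outside [0, 1]")
        if (np.diff(self.l, axis=1) > atol).any():
            raise MonotonicityError("survivorship must be non-increasing in age")
        if (self.m < -atol).any():
            raise MonotonicityError("daily fertility must be non-negative")
        return self

    def cumulative_fertility(self) -> np.ndarray:
        """Cumulative fertility C(i, j) over ages 0..OMEGA (column 0 is 0)."""
        return np.hstack(
            [np.zeros((self.m.shape[0], 1)), np.cumsum(self.m, axis=1)]
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format export (one row per maternal age x age)."""
        rows = []
        s, omega = self.m.shape
        for i in range(1, s + 1):
            for j in range(1, omega + 1):
                rows.append(
                    {
                        "treatment": self.treatment,
                        "maternal_age": i,
                        "age": j,
                        "survivorship": self.l[i - 1, j],
                        "fertility": self.m[i - 1, j - 1],
                        "survival_provenance": (
                            self.survival_provenance[i - 1]
                            if self.survival_provenance
                            else ""
                        ),
                        "fertility_provenance": (
                            self.fertility_provenance[i - 1]
                            if self.fertility_provenance
                            else ""
                        ),
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort-level estimators
# ---------------------------------------------------------------------------


def km_curve(
    durations: np.ndarray,
    events: np.ndarray,
    omega: int = OMEGA,
    estimator: str = "km",
) -> np.ndarray:
    """Product-limit survivorship at integer ages 0..omega.

    ``durations[i]`` is individual i's last observed age-day and
    ``events[i]`` whether it died then (False = right-censored: the record
    leaves the risk set after that day).  Individuals censored on the same
    day as a death are counted at risk for that death, the standard
    convention.  ``estimator="raw"`` instead returns the plain fraction of
    the initial cohort not yet observed dead, ignoring censoring.
    """
    durations = np.asarray(durations, dtype=int)
    events = np.asarray(events, dtype=bool)
    if durations.size == 0:
        raise CohortError("empty cohort")
    deaths = np.bincount(
        np.clip(durations[events], 0, omega + 1), minlength=omega + 2
    )[1 : omega + 1]
    if estimator == "raw":
        return np.concatenate(
            [[1.0], 1.0 - np.cumsum(deaths) / durations.size]
        )
    ended = np.bincount(np.clip(durations, 0, omega + 1), minlength=omega + 2)
    # at risk during day t: everyone whose record extends to t or beyond
    at_risk = durations.size - np.cumsum(ended)[:omega]
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(at_risk > 0, 1.0 - deaths / at_risk, 1.0)
    return np.concatenate([[1.0], np.cumprod(factors)])


def fertility_curve(
    offspring: np.ndarray, alive: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean daily offspring among individuals alive each day.

    Returns ``(m, n_at_risk)`` over ages 1..OMEGA; ``m`` is 0 where no one
    is at risk.  The mean is per capita over survivors, not the initial
    cohort: survival discounting happens inside the projection matrix.
    """
    if len(offspring) == 0:
        raise CohortError("empty cohort")
    n_at_risk = alive.sum(axis=0)
    total = offspring.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(n_at_risk > 0, total / n_at_risk, 0.0)
    return m, n_at_risk


def cohort_curves(
    summaries: IndividualSummaries,
    treatment: str,
    maternal_ages,
    estimator: str = "km",
) -> CohortCurves:
    """Observed curves for one (treatment, maternal-age[s]) cohort."""
    ages = np.atleast_1d(maternal_ages)
    mask = (summaries.treatment == treatment) & np.isin(
        summaries.maternal_age, ages
    )
    if not mask.any():
        raise CohortError(
            f"no individuals for treatment {treatment!r}, "
            f"maternal age(s) {list(ages)}"
        )
    sub = summaries.select(mask)
    m, n_at_risk = fertility_curve(sub.offspring, sub.alive)
    return CohortCurves(
        treatment=treatment,
        maternal_age=int(ages[0]) if len(ages) == 1 else tuple(int(a) for a in ages),
        survivorship=km_curve(sub.duration, sub.event, estimator=estimator),
        fertility=m,
        n_at_risk=n_at_risk,
        n=len(sub),
    )


def cohort_survivorship(
    table: pd.DataFrame, treatment: str, maternal_age: int, estimator: str = "km"
) -> np.ndarray:
    """Survivorship over ages 0..19 for one observed cohort of a table."""
    summaries = IndividualSummaries.from_table(table)
    return cohort_curves(summaries, treatment, maternal_age, estimator).survivorship


def cohort_fertility(
    table: pd.DataFrame, treatment: str, maternal_age: int
) -> np.ndarray:
    """Mean daily fertility over ages 1..19 for one observed cohort."""
    summaries = IndividualSummaries.from_table(table)
    return cohort_curves(summaries, treatment, maternal_age).fertility


# ---------------------------------------------------------------------------
# Interpolation / extrapolation primitives
# ---------------------------------------------------------------------------


def interpolate_cumulative_fertility(
    c_lower: np.ndarray, c_upper: np.ndarray, atol: float = 1e-9
) -> np.ndarray:
    """Pointwise mean of two flanking cumulative-fertility curves."""
    c_lower = np.asarray(c_lower, dtype=float)
    c_upper = np.asarray(c_upper, dtype=float)
    for c in (c_lower, c_upper):
        if (np.diff(c) < -atol).any():
            raise MonotonicityError("cumulative fertility must be non-decreasing")
    return 0.5 * (c_lower + c_upper)


def fertility_extrapolation_ratio(c8: np.ndarray, c9: np.ndarray) -> float:
    """Ratio r of total cumulative fertility, maternal age 9 over 8.

    Each successive maternal age beyond 9 scales the whole cumulative curve
    by this same factor.
    """
    if c8[-1] <= 0:
        raise ValueError("total cumulative fertility at maternal age 8 is zero")
    r = float(c9[-1] / c8[-1])
    if r > 1:
        warnings.warn(
            f"fertility extrapolation ratio r={r:.4f} > 1: cumulative "
            "fertility increases with maternal age",
            stacklevel=2,
        )
    return r


def extrapolate_cumulative_fertility(
    c9: np.ndarray, r: float, maternal_ages=range(10, S + 1)
) -> dict[int, np.ndarray]:
    """Successive scaling C_{i+1} = r * C_i from maternal age 9 upward."""
    out: dict[int, np.ndarray] = {}
    current = np.asarray(c9, dtype=float)
    for i in maternal_ages:
        current = r * current
        out[i] = current
    return out


def daily_from_cumulative(c: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """First differences of a cumulative curve defined at ages 0..omega."""
    c = np.asarray(c, dtype=float)
    m = np.diff(c)
    if (m < -atol).any():
        raise MonotonicityError("cumulative fertility must be non-decreasing")
    return np.clip(m, 0.0, None)


def interpolate_survivorship(
    l_lower: np.ndarray, l_upper: np.ndarray, atol: float = 1e-9
) -> np.ndarray:
    """Pointwise mean of two flanking survivorship curves."""
    l_lower = np.asarray(l_lower, dtype=float)
    l_upper = np.asarray(l_upper, dtype=float)
    for l in (l_lower, l_upper):
        if (l < -atol).any() or (l > 1 + atol).any() or (np.diff(l) > atol).any():
            raise MonotonicityError("invalid survivorship curve")
    return 0.5 * (l_lower + l_upper)


def fit_survival_extrapolation_multiplier(
    l8: np.ndarray,
    l9: np.ndarray,
    plateau_age: int = PLATEAU_AGE,
    k_max: float = 1.5,
) -> float:
    """Least-squares multiplier predicting the next maternal-age curve.

    Minimises sum over ages j > plateau of ``(k * l8(j) - l9(j))^2``;
    closed form ``k = <l8, l9> / <l8, l8>`` on those ages, clipped to
    ``(0, k_max]``.  Ages in the 100%-survival plateau are excluded since
    extrapolation never alters them.
    """
    l8 = np.asarray(l8, dtype=float)[plateau_age + 1 :]
    l9 = np.asarray(l9, dtype=float)[plateau_age + 1 :]
    denom = float(np.dot(l8, l8))
    if denom <= 0:
        raise ValueError("survivorship is zero everywhere beyond the plateau")
    k = float(np.dot(l8, l9) / denom)
    return float(np.clip(k, np.finfo(float).tiny, k_max))


def extrapolate_survivorship(
    l9: np.ndarray,
    k: float,
    maternal_ages=range(10, S + 1),
    plateau_age: int = PLATEAU_AGE,
) -> dict[int, np.ndarray]:
    """Successive multiplier extrapolation of survivorship curves.

    Each next curve keeps the 100% plateau through ``plateau_age``; beyond
    it entries are ``k`` times the previous curve, clipped to keep every
    curve non-increasing in age.
    """
    if k > 1:
        warnings.warn(
            f"survival extrapolation multiplier k={k:.4f} > 1", stacklevel=2
        )
    out: dict[int, np.ndarray] = {}
    current = np.asarray(l9, dtype=float)
    for i in maternal_ages:
        nxt = current.copy()
        nxt[: plateau_age + 1] = 1.0
        for j in range(plateau_age + 1, len(nxt)):
            nxt[j] = min(max(k * current[j], 0.0), nxt[j - 1])
        out[i] = current = nxt
    return out


# ---------------------------------------------------------------------------
# Full-surface assembly
# ---------------------------------------------------------------------------


def build_rate_surfaces(
    data: pd.DataFrame | IndividualSummaries,
    treatment: str,
    options: RateOptions = RateOptions(),
) -> RateSurfaces:
    """Estimate the full 19 x 19 rate surfaces for one treatment.

    Survivorship, ad libitum: observed maternal ages 3/5/7/9, interpolated
    4/6/8, maternal ages 1-2 copied from 3, extrapolated 10-19.  Low food:
    one pooled 3/5/7 curve applied to maternal ages 1-7, maternal age 8
    interpolated between the pooled and the observed-9 curves, observed 9,
    extrapolated 10-19.  Fertility (both treatments): observed 3/5/7/9,
    interpolated 4/6/8 and extrapolated 10-19 on the cumulative scale,
    maternal ages 1-2 copied from 3.
    """
    if isinstance(data, pd.DataFrame):
        summaries = IndividualSummaries.from_table(data)
    else:
        summaries = data
    obs_ages = options.observed_maternal_ages
    curves = {
        i: cohort_curves(summaries, treatment, i, options.estimator)
        for i in obs_ages
    }

    # --- fertility, on the cumulative scale ---
    cum = {
        i: np.concatenate([[0.0], np.cumsum(curves[i].fertility)])
        for i in obs_ages
    }
    fert_prov = {i: "observed" for i in obs_ages}
    for i in (4, 6, 8):
        cum[i] = interpolate_cumulative_fertility(cum[i - 1], cum[i + 1])
        fert_prov[i] = "interpolated"
    for i in (1, 2):
        cum[i] = cum[3].copy()
        fert_prov[i] = "copied"
    r = fertility_extrapolation_ratio(cum[8], cum[9])
    for i, c in extrapolate_cumulative_fertility(cum[9], r).items():
        cum[i] = c
        fert_prov[i] = "extrapolated"
    m = np.vstack([daily_from_cumulative(cum[i]) for i in range(1, S + 1)])

    # --- survivorship ---
    surv: dict[int, np.ndarray] = {}
    surv_prov: dict[int, str] = {}
    if treatment == "LF":
        if options.pool == "curve_mean":
            pooled = np.mean(
                [curves[i].survivorship for i in (3, 5, 7)], axis=0
            )
        else:
            pooled = cohort_curves(
                summaries, treatment, (3, 5, 7), options.estimator
            ).survivorship
        for i in range(1, 8):
            surv[i] = pooled
            surv_prov[i] = "pooled"
        surv[9] = curves[9].survivorship
        surv_prov[9] = "observed"
        surv[8] = interpolate_survivorship(pooled, surv[9])
        surv_prov[8] = "interpolated"
    else:
        for i in obs_ages:
            surv[i] = curves[i].survivorship
            surv_prov[i] = "observed"
        for i in (4, 6, 8):
            surv[i] = interpolate_survivorship(surv[i - 1], surv[i + 1])
            surv_prov[i] = "interpolated"
        for i in (1, 2):
            surv[i] = surv[3].copy()
            surv_prov[i] = "copied"

    if options.extrapolate_survival:
        k = fit_survival_extrapolation_multiplier(
            surv[8], surv[9], options.plateau_age
        )
        for i, l in extrapolate_survivorship(
            surv[9], k, plateau_age=options.plateau_age
        ).items():
            surv[i] = l
            surv_prov[i] = "extrapolated"
    else:
        k = 1.0
        for i in range(10, S + 1):
            surv[i] = surv[9].copy()
            surv_prov[i] = "copied"

    l = np.vstack([surv[i] for i in range(1, S + 1)])
    surfaces = RateSurfaces(
        treatment=treatment,
        l=l,
        m=m,
        survival_provenance=[surv_prov[i] for i in range(1, S + 1)],
        fertility_provenance=[fert_prov[i] for i in range(1, S + 1)],
        meta={
            "fertility_ratio_r": r,
            "survival_multiplier_k": k,
            "estimator": options.estimator,
            "pool": options.pool,
            "extrapolate_survival": options.extrapolate_survival,
        },
    )
    return surfaces.validate()
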