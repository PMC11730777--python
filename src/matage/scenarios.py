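"""Stationary-population scenarios and single-maternal-age populations.

The laboratory populations grow explosively (lambda close to 2 per day).
To study maternal-age effects in demographically realistic, stationary
populations (lambda near 1), both treatments' models are rescaled by a
*common* constant so the age-specific patterns of treatment and maternal
age are preserved:

* low fertility: divide every fertility entry by the ad libitum net
  reproductive rate, which sets R0(AL) = 1 and hence lambda(AL) = 1 —
  a crowding/competition caricature;
* low survival: multiply the survival matrix U by the constant c that
  solves lambda(c U + F) = 1 for the ad libitum model — a predation
  caricature.

Also provided: hypothetical single-maternal-age populations, where every
individual experiences the rates of one maternal-age row; their lambdas
trace how fitness would change if the whole population carried a given
maternal age.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import scipy.sparse as sp
from scipy.optimize import brentq

from . import matrix_model as mm
from .rate_surfaces import OMEGA, RateSurfaces


def scale_fertility(
    model_al: mm.BlockModel, model_lf: mm.BlockModel
) -> tuple[mm.BlockModel, mm.BlockModel]:
    """Divide both treatments' fertility by the ad libitum R0.

    R0 is linear in a scalar scaling of F, so the scaled ad libitum model
    has R0 = 1 and therefore lambda = 1.
    """
    r0_al = mm.net_reproductive_rate(model_al)
    if r0_al <= 0:
        raise ValueError("ad libitum R0 must be positive")
    return tuple(
        replace(
            m,
            F=(m.F / r0_al).tocsr(),
            f=None if m.f is None else m.f / r0_al,
        )
        for m in (model_al, model_lf)
    )


def solve_survival_multiplier(
    model: mm.BlockModel,
    target_lambda: float = 1.0,
    bracket: tuple[float, float] = (1e-6, 1.0),
    tol: float = 1e-12,
) -> float:
    """Constant c with lambda(c U + F) = target, by bracketed root-finding.

    lambda is strictly increasing in c (adding survival can only help a
    non-negative model), which is verified on the bracket before solving.
    """
    U, F = model.U, model.F

    def lam(c: float) -> float:
        return mm.growth_rate(c * U + F)

    lo, hi = bracket
    f_lo, f_hi = lam(lo) - target_lambda, lam(hi) - target_lambda
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"target lambda {target_lambda} not bracketed: "
            f"lambda({lo})={f_lo + target_lambda:.6f}, "
            f"lambda({hi})={f_hi + target_lambda:.6f}"
        )
    if not f_lo < f_hi:
        raise ValueError("lambda(cU + F) is not increasing on the bracket")
    if f_hi == 0:
        return hi
    c = brentq(lambda c: lam(c) - target_lambda, lo, hi, xtol=tol, rtol=1e-15)
    return float(c)


def _daily_rates_from_entries(f: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Invert the birth-flow map f = (m + p m_next) / 2 for the rates m."""
    m = np.zeros_like(f)
    m[:, -1] = 2 * f[:, -1]
    for j in range(f.shape[1] - 2, -1, -1):
        m[:, j] = 2 * f[:, j] - p[:, j] * m[:, j + 1]
    return np.clip(m, 0.0, None)


def apply_survival_multiplier(
    model_al: mm.BlockModel,
    model_lf: mm.BlockModel,
    c: float,
    rebuild_fertility: bool = False,
) -> tuple[mm.BlockModel, mm.BlockModel]:
    """Scale U by c in both treatments' models, leaving F untouched.

    The multiplier acts on the assembled survival matrix, not on the
    survivorship curves, so by default the birth-flow fertility entries
    (which embed the original p) are deliberately not rebuilt.  With
    ``rebuild_fertility=True`` the daily rates are recovered from the
    entries and the birth-flow coefficients recomputed with the scaled
    survival, as a sensitivity variant.
    """
    if not 0 < c <= 1:
        raise ValueError("survival multiplier must lie in (0, 1]")
    out = []
    for m in (model_al, model_lf):
        scaled = replace(
            m,
            U=(c * m.U).tocsr(),
            p=None if m.p is None else c * m.p,
        )
        if rebuild_fertility:
            if m.p is None or m.f is None:
                raise ValueError(
                    "rebuilding fertility needs the model's vital-rate grids"
                )
            daily = _daily_rates_from_entries(m.f, m.p)
            f_new = mm.fertility_entries(daily, c * m.p, census=m.census)
            n = m.U.shape[0]
            _, _, rows_f, cols_f = mm._block_pattern(m.s, m.omega)
            scaled = replace(
                scaled,
                f=f_new,
                F=sp.csr_matrix(
                    (f_new.T.ravel(), (rows_f, cols_f)), shape=(n, n)
                ),
            )
        out.append(scaled)
    return tuple(out)


def single_maternal_age_model(
    surfaces: RateSurfaces, maternal_age: int, census: str = mm.BIRTH_FLOW
) -> tuple[np.ndarray, float]:
    """Leslie model where everyone carries one maternal age's rates.

    Builds the 19 x 19 age-only Leslie matrix from row ``maternal_age`` of
    the surfaces, with the same birth-flow discretisation as the full
    model, and returns (matrix, lambda).
    """
    if not 1 <= maternal_age <= surfaces.l.shape[0]:
        raise ValueError(f"maternal age {maternal_age} outside the grid")
    i = maternal_age - 1
    p = mm.survival_probabilities(surfaces.l[[i]], census)[0]
    f = mm.fertility_entries(surfaces.m[[i]], p[None, :], census=census)[0]
    a = np.zeros((OMEGA, OMEGA))
    a[0, :] = f
    a[np.arange(1, OMEGA), np.arange(OMEGA - 1)] = p[: OMEGA - 1]
    return a, mm.growth_rate(sp.csr_matrix(a))


def single_maternal_age_lambdas(
    surfaces: RateSurfaces, census: str = mm.BIRTH_FLOW
) -> np.ndarray:
    """lambda for each single-maternal-age population, maternal ages 1..19."""
    return np.array(
        [
            single_maternal_age_model(surfaces, i, census)[1]
            for i in range(1, surfaces.l.shape[0] + 1)
        ]
    )
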