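"""Individual-level permutation tests for feeding-treatment effects.

The unit of resampling is the individual: its entire daily record (survival
and reproduction) is reassigned to a pseudo-treatment, within its
maternal-age cohort, preserving the original per-treatment sample sizes.
For every shuffled data set the full nonparametric pipeline — rate-surface
construction, block-matrix assembly, eigenanalysis — is re-run for both
pseudo-treatments, building null distributions for

* |delta lambda|          (population growth rate),
* |delta R0|              (net reproductive rate),
* ||w_LF - w_AL||_1       (stable population structure).

p-values are the proportion of null statistics at least as extreme as the
observed one; with zero exceedances the result is reported as "< 1/N".
The add-one convention (k+1)/(N+1) is reported alongside, since the plain
proportion is anti-conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from . import matrix_model as mm
from .rate_surfaces import (
    IndividualSummaries,
    RateOptions,
    build_rate_surfaces,
)

STATISTICS = ("lambda", "r0", "structure")


def _pair_statistics(
    summaries: IndividualSummaries,
    options: RateOptions,
    census: str,
    statistics: tuple[str, ...] = STATISTICS,
) -> dict[str, float | np.ndarray]:
    """Run the full pipeline for both treatments of one labelling.

    Only the quantities needed for the requested statistics are computed
    (the R0 solve is skipped when ``"r0"`` is not asked for), which matters
    inside long permutation loops.
    """
    want_r0 = "r0" in statistics
    out = {}
    for treatment in ("AL", "LF"):
        surfaces = build_rate_surfaces(summaries, treatment, options)
        model = mm.assemble(surfaces, census)
        lam, w = mm.dominant_eigenpair(model.A)
        out[treatment] = {
            "lambda": lam,
            "r0": mm.net_reproductive_rate(model) if want_r0 else np.nan,
            "w": w / w.sum(),
        }
    result = {
        "lambda": abs(out["LF"]["lambda"] - out["AL"]["lambda"]),
        "structure": float(np.abs(out["LF"]["w"] - out["AL"]["w"]).sum()),
        "lambda_al": out["AL"]["lambda"],
        "lambda_lf": out["LF"]["lambda"],
    }
    if want_r0:
        result["r0"] = abs(out["LF"]["r0"] - out["AL"]["r0"])
        result["r0_al"] = out["AL"]["r0"]
        result["r0_lf"] = out["LF"]["r0"]
    return result


def shuffled_labels(
    summaries: IndividualSummaries, rng: np.random.Generator
) -> np.ndarray:
    """Permute treatment labels within each maternal-age cohort.

    Per-cohort treatment counts are conserved exactly; individual records
    are never altered.
    """
    labels = summaries.treatment.copy()
    for ma in np.unique(summaries.maternal_age):
        idx = np.flatnonzero(summaries.maternal_age == ma)
        if len(set(labels[idx])) < 2:
            raise ValueError(
                f"maternal-age cohort {ma} has a single treatment; "
                "nothing to shuffle"
            )
        labels[idx] = labels[idx[rng.permutation(len(idx))]]
    return labels


def shuffle_treatments(
    table: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Table-level shuffle: reassign individuals' treatments within cohorts."""
    summaries = IndividualSummaries.from_table(table)
    labels = shuffled_labels(summaries, rng)
    mapping = dict(zip(summaries.individual_id, labels))
    out = table.copy()
    out["treatment"] = out["individual_id"].map(mapping)
    return out


@dataclass
class PermutationResult:
    """Observed statistics, null distributions and p-values.

    ``null[stat]`` has one entry per successful permutation; ``p_values``
    uses the plain proportion (#null >= observed)/N with the string
    ``"< 1/N"`` at zero exceedances, ``p_values_add_one`` the
    (k+1)/(N+1) convention.
    """

    observed: dict[str, float]
    null: dict[str, np.ndarray]
    n_permutations: int
    seed: int
    n_failed: int = 0
    details: dict = field(default_factory=dict)

    @property
    def p_values(self) -> dict[str, float | str]:
        out = {}
        for stat, dist in self.null.items():
            k = int(np.sum(dist >= self.observed[stat]))
            n = len(dist)
            out[stat] = k / n if k > 0 else f"< {1 / n:.6g}"
        return out

    @property
    def p_values_add_one(self) -> dict[str, float]:
        return {
            stat: (int(np.sum(dist >= self.observed[stat])) + 1)
            / (len(dist) + 1)
            for stat, dist in self.null.items()
        }


def permutation_test(
    table: pd.DataFrame | IndividualSummaries,
    n_permutations: int = 4000,
    seed: int = 0,
    statistics: tuple[str, ...] = STATISTICS,
    options: RateOptions = RateOptions(),
    census: str = mm.BIRTH_FLOW,
) -> PermutationResult:
    """Permutation test of the treatment effect on lambda, R0 and structure.

    Each permutation draws its own RNG substream from the seed, so results
    do not depend on execution order.  A pipeline failure on a shuffled
    data set (e.g. a degenerate cohort) is recorded and excluded with a
    warning rather than aborting the test.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    summaries = (
        IndividualSummaries.from_table(table)
        if isinstance(table, pd.DataFrame)
        else table
    )
    observed_full = _pair_statistics(summaries, options, census, statistics)
    observed = {stat: observed_full[stat] for stat in statistics}

    streams = np.random.SeedSequence(seed).spawn(n_permutations)
    null = {stat: [] for stat in statistics}
    n_failed = 0
    for stream in streams:
        rng = np.random.default_rng(stream)
        labels = shuffled_labels(summaries, rng)
        try:
            with warnings.catch_warnings():
                # fit chatter (e.g. a noise-driven extrapolation multiplier
                # slightly above 1) is routine on resampled labels
                warnings.simplefilter("ignore", UserWarning)
                stats = _pair_statistics(
                    summaries.with_treatment(labels), options, census,
                    statistics,
                )
        except Exception as exc:  # degenerate shuffle: record and move on
            n_failed += 1
            warnings.warn(f"permutation failed and was excluded: {exc}")
            continue
        for stat in statistics:
            null[stat].append(stats[stat])

    return PermutationResult(
        observed=observed,
        null={stat: np.array(vals) for stat, vals in null.items()},
        n_permutations=n_permutations,
        seed=seed,
        n_failed=n_failed,
        details={
            k: v
            for k, v in observed_full.items()
            if k in ("lambda_al", "lambda_lf", "r0_al", "r0_lf")
        },
    )
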