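"""End-to-end study orchestration from a single configuration.

One call runs the whole analysis — rate-surface fitting for both
treatments, block-model assembly and eigenanalysis, the stationary
(low-fertility and low-survival) scenarios, LTRE decompositions for all
three settings, single-maternal-age populations, and the permutation test
— and writes every result into a run directory with a manifest carrying
the configuration hash, seed and package versions.  All randomness flows
from the single top-level seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import matrix_model as mm
from . import scenarios as sc
from .data_io import cohort_census, read_life_histories, write_life_histories
from .ltre import ltre_contributions, summarize_ltre
from .permutation import permutation_test
from .rate_surfaces import RateOptions, build_rate_surfaces
from .synthetic_data import SyntheticParams, generate

logger = logging.getLogger("matage")


@dataclass
class StudyConfig:
    """Configuration of one full study run.

    Provide either ``input_csv`` (canonical life-history CSV) or
    ``synthetic`` parameters; the seed drives data generation and the
    permutation test.
    """

    input_csv: str | None = None
    synthetic: SyntheticParams | None = None
    seed: int = 0
    census: str = mm.BIRTH_FLOW
    rate_options: RateOptions = field(default_factory=RateOptions)
    n_permutations: int = 0  # 0 disables the (costly) permutation stage
    projection_days: int = 90
    target_lambda: float = 1.0
    outdir: str = "matage_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = raw["synthetic"]
            if "maternal_ages" in syn:
                syn["maternal_ages"] = tuple(syn["maternal_ages"])
            raw["synthetic"] = SyntheticParams(**syn)
        if "rate_options" in raw:
            raw["rate_options"] = RateOptions(**raw["rate_options"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        return d


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=2, default=default), encoding="utf-8")


def run_study(config: StudyConfig) -> dict:
    """Run every analysis stage and write the result bundle.

    Returns a dict with the in-memory results and the artifact manifest.
    Any stage failure propagates annotated with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    results: dict = {}
    stage = "setup"
    t_start = time.time()

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        artifacts.append(name)
        logger.info("wrote %s (%.2fs elapsed)", path, time.time() - t_start)

    try:
        stage = "data"
        if config.input_csv:
            table = read_life_histories(config.input_csv)
        elif config.synthetic is not None:
            table = generate(config.synthetic, seed=config.seed)
            emit("life_histories.csv", lambda p: write_life_histories(table, p))
        else:
            raise ValueError("config needs input_csv or synthetic parameters")
        results["census"] = cohort_census(table)
        emit("cohort_census.csv",
             lambda p: results["census"].to_csv(p, index=False))

        stage = "rate_surfaces"
        surfaces = {
            t: build_rate_surfaces(table, t, config.rate_options)
            for t in ("AL", "LF")
        }
        results["surfaces"] = surfaces
        emit("rate_surfaces.csv", lambda p: pd.concat(
            [s.to_frame() for s in surfaces.values()]).to_csv(p, index=False))

        stage = "matrix_model"
        models = {t: mm.assemble(s, config.census) for t, s in surfaces.items()}
        eigen = {t: mm.eigen_summary(m) for t, m in models.items()}
        results["models"] = models
        results["eigen"] = eigen
        lam = {t: e.lambda_ for t, e in eigen.items()}
        ratio = (lam["AL"] / lam["LF"]) ** config.projection_days
        results["abundance_ratio"] = ratio
        emit("eigen_summary.json", lambda p: _write_json(p, {
            t: {
                "lambda": e.lambda_,
                "r0": e.r0,
                "stable_structure": e.w,
                "reproductive_value": e.v,
            } for t, e in eigen.items()
        } | {"delta_lambda": lam["LF"] - lam["AL"],
             f"abundance_ratio_{config.projection_days}d": ratio}))

        stage = "single_maternal_age"
        sma = {
            t: sc.single_maternal_age_lambdas(s, config.census)
            for t, s in surfaces.items()
        }
        results["single_maternal_age_lambdas"] = sma
        emit("single_maternal_age_lambdas.csv", lambda p: pd.DataFrame(
            {"maternal_age": np.arange(1, 20),
             "lambda_AL": sma["AL"], "lambda_LF": sma["LF"]}
        ).to_csv(p, index=False))

        stage = "scenarios"
        lowfert = sc.scale_fertility(models["AL"], models["LF"])
        c = sc.solve_survival_multiplier(models["AL"], config.target_lambda)
        lowsurv = sc.apply_survival_multiplier(models["AL"], models["LF"], c)
        scen = {
            "laboratory": (models["AL"], models["LF"]),
            "low_fertility": lowfert,
            "low_survival": lowsurv,
        }
        results["scenario_models"] = scen
        results["survival_multiplier"] = c
        scen_summary = {
            name: {
                "lambda_AL": mm.growth_rate(pair[0]),
                "lambda_LF": mm.growth_rate(pair[1]),
            }
            for name, pair in scen.items()
        }
        scen_summary["survival_multiplier"] = c
        results["scenario_lambdas"] = scen_summary
        emit("scenarios.json", lambda p: _write_json(p, scen_summary))
        # stable structures of all scenario models: the low-fertility world
        # flattens the distribution, the low-survival world concentrates it
        structure_rows = []
        for name, pair in scen.items():
            for treatment, model in zip(("AL", "LF"), pair):
                w = mm.to_grid(mm.stable_structure(model))
                for i in range(w.shape[0]):
                    for j in range(w.shape[1]):
                        structure_rows.append(
                            (name, treatment, i + 1, j + 1, w[i, j])
                        )
        emit("scenario_stable_structures.csv", lambda p: pd.DataFrame(
            structure_rows,
            columns=["scenario", "treatment", "maternal_age", "age", "share"],
        ).to_csv(p, index=False))

        stage = "ltre"
        ltre_results = {
            name: ltre_contributions(pair[1], pair[0])
            for name, pair in scen.items()
        }
        results["ltre"] = ltre_results
        emit("ltre_contributions.csv", lambda p: pd.concat(
            [r.to_frame().assign(scenario=name)
             for name, r in ltre_results.items()]).to_csv(p, index=False))
        emit("ltre_summary.json", lambda p: _write_json(
            p, {name: summarize_ltre(r) for name, r in ltre_results.items()}))

        if config.n_permutations > 0:
            stage = "permutation"
            perm = permutation_test(
                table,
                n_permutations=config.n_permutations,
                seed=config.seed,
                options=config.rate_options,
                census=config.census,
            )
            results["permutation"] = perm
            emit("permutation.json", lambda p: _write_json(p, {
                "observed": perm.observed,
                "p_values": perm.p_values,
                "p_values_add_one": perm.p_values_add_one,
                "n_permutations": perm.n_permutations,
                "n_failed": perm.n_failed,
                "seed": perm.seed,
            }))
            emit("permutation_null.csv", lambda p: pd.DataFrame(
                perm.null).to_csv(p, index=False))
    except Exception as exc:
        raise RuntimeError(f"study stage {stage!r} failed: {exc}") from exc

    stage = "manifest"
    config_json = json.dumps(config.to_jsonable(), sort_keys=True, default=str)
    manifest = {
        "config": config.to_jsonable(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "matage": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "artifacts": artifacts,
        "elapsed_seconds": time.time() - t_start,
    }
    _write_json(outdir / "manifest.json", manifest)
    results["manifest"] = manifest
    return results
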