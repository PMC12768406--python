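"""End-to-end pipeline: simulate or load every table, run every analysis.

A single :class:`PipelineConfig` (built from a dict, JSON or YAML document)
drives the stages; each stage records its result or its error in one
machine-readable report that embeds the config, the master seed and a
schema version, so any report can be rerun exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import pandas as pd

from . import io as ovio
from .choice import (
    bayes_choice_posterior,
    exclude_empty_nights,
    fit_poisson_glmm,
    pearson_chi2,
)
from .simulate import (
    GradientSimConfig,
    TrajectorySimConfig,
    TwoChoiceSimConfig,
    simulate_deafening,
    simulate_gradient,
    simulate_tracks,
    simulate_two_choice,
)
from .spatial import PermutationNullConfig, gradient_test, spatial_density
from .trajectory import assign_sides, count_crossings, fit_occupancy_trend, occupancy_bins

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

SCHEMA_VERSION = 1
log = logging.getLogger("ovisound")


@dataclass
class PipelineConfig:
    """Stage inputs for one pipeline run.

    Each stage takes exactly one input source: either a ``*_path`` to a CSV
    or simulator settings (``*_sim``; an empty dict means defaults).  A
    stage with neither source is skipped.
    """

    seed: int = 0
    output_dir: Optional[str] = None
    nights_path: Optional[str] = None
    two_choice_sim: Optional[Dict[str, Any]] = None
    eggs_path: Optional[str] = None
    gradient_sim: Optional[Dict[str, Any]] = None
    tracks_path: Optional[str] = None
    tracks_sim: Optional[Dict[str, Any]] = None
    deafening_table: Optional[Any] = None
    deafening_sim: Optional[Dict[str, Any]] = None
    n_shuffles: int = 1000
    first_night_only: bool = False
    bin_minutes: int = 30
    bayes_draws: int = 16000

    def __post_init__(self) -> None:
        pairs = [
            ("nights_path", "two_choice_sim"),
            ("eggs_path", "gradient_sim"),
            ("tracks_path", "tracks_sim"),
            ("deafening_table", "deafening_sim"),
        ]
        for a, b in pairs:
            if getattr(self, a) is not None and getattr(self, b) is not None:
                raise ValueError(f"stage has two input sources: {a} and {b}")


def load_config(path) -> PipelineConfig:
    """Read a pipeline config from a JSON or YAML document."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    return PipelineConfig(**doc)


def _stage(report: Dict[str, Any], name: str, fn) -> None:
    try:
        report["stages"][name] = {"ok": True, "result": fn()}
    except Exception as e:  # stage isolation: later stages still run
        log.warning("stage %s failed: %s", name, e)
        report["stages"][name] = {"ok": False, "error": f"{type(e).__name__}: {e}"}


def run_pipeline(config: PipelineConfig) -> Dict[str, Any]:
    """Execute every configured stage and return the report document."""
    if config.output_dir:
        Path(config.output_dir).mkdir(parents=True, exist_ok=True)
    report: Dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    # --- two-choice counts -> exclusion -> Poisson GLMM -> Bayes posterior
    nights = None
    if config.nights_path is not None:
        nights = ovio.read_nights(config.nights_path)
    elif config.two_choice_sim is not None:
        tc = TwoChoiceSimConfig(**{"seed": config.seed, **config.two_choice_sim})
        nights = simulate_two_choice(tc)

    if nights is not None:
        def _fit():
            kept, dropped = exclude_empty_nights(nights)
            log.info("two_choice: %d nights, %d empty nights excluded", len(nights), dropped)
            fit = fit_poisson_glmm(kept, exclude_empty=False)
            return {
                "n_nights": int(len(nights)),
                "n_excluded_empty": dropped,
                "estimate_treatment": float(fit.beta["treatment"]),
                "se_treatment": float(fit.se["treatment"]),
                "p_treatment": float(fit.p["treatment"]),
                "sigma_u": {k: float(v) for k, v in fit.sigma_u.items()},
                "converged": bool(fit.converged),
            }

        _stage(report, "two_choice_glmm", _fit)

        def _bayes():
            kept, _ = exclude_empty_nights(nights)
            choices = pd.DataFrame(
                {
                    "choice01": np.concatenate(
                        [
                            np.ones(int(kept["clusters_treatment"].sum())),
                            np.zeros(int(kept["clusters_control"].sum())),
                        ]
                    ),
                    "n_females": np.concatenate(
                        [
                            np.repeat(kept["n_females"], kept["clusters_treatment"]),
                            np.repeat(kept["n_females"], kept["clusters_control"]),
                        ]
                    ),
                }
            )
            post = bayes_choice_posterior(
                choices, n_draws=config.bayes_draws, seed=config.seed
            )
            return post.summary()

        _stage(report, "bayes_choice", _bayes)

    # --- gradient arena
    eggs = None
    if config.eggs_path is not None:
        eggs = ovio.read_eggs(config.eggs_path)
    elif config.gradient_sim is not None:
        gc = GradientSimConfig(**{"seed": config.seed, **config.gradient_sim})
        eggs = simulate_gradient(gc)

    if eggs is not None:
        def _grad():
            ks = gradient_test(
                eggs,
                PermutationNullConfig(n_shuffles=config.n_shuffles, seed=config.seed),
                first_night_only=config.first_night_only,
            )
            out = {
                "d": ks.d,
                "p": ks.p,
                "p_method": ks.p_method,
                "n_obs": ks.n_obs,
                "n_null": ks.n_null,
                "n_clusters": int(len(eggs)),
            }
            if config.output_dir:
                dens_e = spatial_density(eggs, unit="egg")
                dens_c = spatial_density(eggs, unit="cluster")
                dens = dens_e.rename(columns={"density": "egg_density"})
                dens["cluster_density"] = dens_c["density"]
                dens.to_csv(Path(config.output_dir) / "density.csv", index=False)
            return out

        _stage(report, "gradient_test", _grad)

    # --- trajectories
    tracks = None
    if config.tracks_path is not None:
        tracks = ovio.read_tracks(config.tracks_path)
    elif config.tracks_sim is not None:
        tj = TrajectorySimConfig(**{"seed": config.seed, **config.tracks_sim})
        tracks = simulate_tracks(tj)

    if tracks is not None:
        def _traj():
            series = [assign_sides(tr) for tr in tracks]
            crossings = {s.moth_id: count_crossings(s) for s in series}
            trend = fit_occupancy_trend(series, bin_minutes=config.bin_minutes)
            if config.output_dir:
                tabs = []
                for s in series:
                    tab = occupancy_bins(s, config.bin_minutes)
                    tab.insert(0, "moth_id", s.moth_id)
                    tabs.append(tab)
                pd.concat(tabs, ignore_index=True).to_csv(
                    Path(config.output_dir) / "bins.csv", index=False
                )
            return {
                "crossings": crossings,
                "crossings_mean": float(np.mean(list(crossings.values()))),
                "trend_slope_per_hour": trend.slope,
                "trend_se": trend.se,
                "trend_p": trend.p,
                "trend_converged": trend.converged,
            }

        _stage(report, "trajectory", _traj)

    # --- deafening chi-square
    table = None
    if config.deafening_table is not None:
        table = np.asarray(config.deafening_table, dtype=int)
    elif config.deafening_sim is not None:
        table = simulate_deafening(**{"seed": config.seed, **config.deafening_sim})

    if table is not None:
        def _chi2():
            res = pearson_chi2(table)
            return {"q": res.q, "df": res.df, "p": res.p, "table": table.tolist()}

        _stage(report, "deafening_chi2", _chi2)

    if config.output_dir:
        (Path(config.output_dir) / "report.json").write_text(json.dumps(report, indent=2))
    return report
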