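"""End-to-end orchestration: validate → describe → selection → heritability.

Produces a reproducible report bundle (CSV tables mirroring the analysis
outputs, a machine-readable JSON of every statistic, and a log) from either
a pedigree file on disk or a simulation config.  Identical config + seed
give identical outputs; the resolved configuration and package version are
echoed into the JSON for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .descriptives import length_anova, rs_count_glm, tactic_summary
from .errors import ConfigError, DegenerateDataError, InsufficientDataError, TactqgError
from .heritability import bartlett_test, grid_frame, heritability_grid
from .pedigree import Pedigree, TACTICS, read_pedigree
from .selection import interaction_scan, selection_table
from .simulate import SimConfig, simulate_pedigree

__all__ = ["RunConfig", "run_pipeline"]

ALL_STAGES = ("describe", "selection", "heritability")


@dataclass
class RunConfig:
    """Pipeline configuration: exactly one of ``input_path`` / ``sim`` is set."""

    input_path: Optional[str] = None
    sim: Optional[SimConfig] = None
    alpha_var: float = 0.05
    outdir: str = "tactqg_report"
    seed: Optional[int] = None
    stages: Sequence[str] = ALL_STAGES

    def __post_init__(self):
        if (self.input_path is None) == (self.sim is None):
            raise ConfigError("exactly one of input_path / sim must be set")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ConfigError(f"unknown stages {sorted(bad)}; valid: {ALL_STAGES}")


def _jsonable(obj):
    """Recursively convert to JSON-safe types; NaN becomes None."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not math.isfinite(v) else v
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if obj is pd.NA or (isinstance(obj, float) and math.isnan(obj)):
        return None
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages and write the report bundle to ``cfg.outdir``.

    Files: ``descriptives.csv``, ``table1.csv`` (selection gradients),
    ``table2.csv`` (heritability grid), ``results.json``, ``run.log``.
    Returns the results dictionary (the same content as ``results.json``).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    if cfg.sim is not None:
        sim = cfg.sim
        if cfg.seed is not None:
            sim = SimConfig.from_dict({**sim.to_dict(), "seed": cfg.seed})
        log(f"stage simulate: n_dams={sim.n_dams} n_sires={sim.n_sires} "
            f"n_offspring={sim.n_offspring} seed={sim.seed}")
        ped = simulate_pedigree(sim)
        source = {"kind": "simulated", "sim": sim.to_dict()}
    else:
        log(f"stage read: {cfg.input_path}")
        ped = read_pedigree(cfg.input_path)
        source = {"kind": "file", "path": str(cfg.input_path)}

    n_parent = len(ped.parents)
    log(f"stage validate: {len(ped)} individuals "
        f"({n_parent} parents, {len(ped) - n_parent} offspring)")

    results: dict = {
        "version": __version__,
        "config": {
            "source": source,
            "alpha_var": cfg.alpha_var,
            "seed": cfg.seed,
            "stages": list(cfg.stages),
        },
        "counts": {
            "total": len(ped),
            "parents": n_parent,
            "offspring": len(ped) - n_parent,
            "per_tactic": ped.frame["tactic"].value_counts().to_dict(),
        },
    }

    if "describe" in cfg.stages:
        log("stage describe")
        summary = tactic_summary(ped)
        summary.to_csv(outdir / "descriptives.csv")
        anova = length_anova(ped)
        nb = rs_count_glm(ped, family="negative_binomial")
        results["descriptives"] = {
            "per_tactic": summary.reset_index(),
            "length_anova": {
                "F": anova.F, "df_between": anova.df_between,
                "df_within": anova.df_within, "p": anova.p,
                "tukey": anova.tukey,
            },
            "rs_glm": {
                "family": nb.family, "alpha": nb.alpha, "chi_sq": nb.chi_sq,
                "df": nb.df, "p": nb.p, "group_means": nb.group_means,
            },
        }

    if "selection" in cfg.stages:
        log("stage selection")
        table1 = selection_table(ped)
        table1.to_csv(outdir / "table1.csv", index=False)
        results["selection"] = {"table1": table1}
        try:
            scan = interaction_scan(ped)
            results["selection"]["interaction_scan"] = [t.__dict__ for t in scan]
        except DegenerateDataError as exc:
            log(f"stage selection: interaction scan skipped ({exc})")
            results["selection"]["interaction_scan"] = str(exc)

    if "heritability" in cfg.stages:
        log("stage heritability")
        groups = {t: ped.frame.loc[ped.frame["tactic"].eq(t), "length_mm"].astype(float)
                  for t in TACTICS if (ped.frame["tactic"] == t).any()}
        try:
            var_cmp = bartlett_test(groups)
            variance = {
                "bartlett_k2": var_cmp.bartlett_k2,
                "bartlett_df": var_cmp.bartlett_df,
                "bartlett_p": var_cmp.bartlett_p,
                "pairwise": {f"{a}:{b}": v for (a, b), v in var_cmp.pairwise.items()},
            }
        except TactqgError as exc:
            variance = str(exc)
        grid = heritability_grid(ped, alpha_var=cfg.alpha_var)
        table2 = grid_frame(grid)
        table2.to_csv(outdir / "table2.csv", index=False)
        results["heritability"] = {"variance": variance, "table2": table2}

    results = _jsonable(results)
    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, allow_nan=False)
    log("done")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return results
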