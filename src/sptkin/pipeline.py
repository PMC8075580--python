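"""Configuration-driven end-to-end runs with reproducible JSON reports."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fluctuation, jumplens, kinmodel, trajectories
from .errors import ConfigError, EmptyDatasetError, ParseError

__all__ = ["SptRunConfig", "FluctuationRunConfig", "run_spt", "run_fluctuation"]

log = logging.getLogger("sptkin")


@dataclass
class SptRunConfig:
    input_csv: str
    out_dir: str
    seed: int = 0
    min_photons: float = 20.0
    max_precision: float = 40.0  # nm
    max_jump_link: float = 0.8  # um
    frame_interval: float = 0.02  # s
    n_timepoints: int = 5
    jumps_to_consider: int = 4
    bin_width: float = 0.01  # um
    max_jump_hist: float = 3.0  # um
    dz: float = 0.9  # um
    d_slow_min: float = 0.08  # um^2/s
    n_states_candidates: tuple[int, ...] = (2, 3)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "SptRunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        if not Path(self.input_csv).exists():
            raise ConfigError(f"input file not found: {self.input_csv}")


@dataclass
class FluctuationRunConfig:
    input_csv: str
    out_dir: str
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def validate(self) -> None:
        if not Path(self.input_csv).exists():
            raise ConfigError(f"input file not found: {self.input_csv}")


def _model_to_dict(model: kinmodel.DiffusionModel) -> dict:
    return {
        "fractions": list(model.fractions),
        "diffusion_um2_s": list(model.diffusion),
        "sigma_um": model.sigma,
        "dz_um": model.dz,
    }


def _fit_to_dict(fit: kinmodel.FitResult) -> dict:
    return {
        "model": _model_to_dict(fit.model),
        "rss": fit.rss,
        "n_points": fit.n_points,
        "k_params": fit.k_params,
        "aic": fit.aic,
        "n_states": fit.n_states,
        "converged": fit.converged,
        "f_bound": kinmodel.f_bound(fit),
    }


def run_spt(config: SptRunConfig) -> dict:
    """Filter -> link -> jump histograms -> 2/3-state fits -> AIC selection.

    Writes ``report.json``, per-lag CDF/PDF CSVs and a log; returns the
    report dict. Deterministic given the seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    locs = trajectories.read_locs_csv(config.input_csv)
    kept = trajectories.filter_localizations(
        locs, min_photons=config.min_photons, max_precision=config.max_precision
    )
    log.info("localizations: %d read, %d retained", len(locs), len(kept))
    if not kept:
        raise EmptyDatasetError("no localizations survive the quality filters")

    trajs = trajectories.link_trajectories(kept, max_jump=config.max_jump_link)
    dataset = jumplens.compute_jump_dataset(
        trajs,
        frame_interval=config.frame_interval,
        n_timepoints=config.n_timepoints,
        jumps_to_consider=config.jumps_to_consider,
        bin_width=config.bin_width,
        max_jump=config.max_jump_hist,
    )
    log.info(
        "%d trajectories, %d jumps across %d lags",
        len(trajs), dataset.total_jumps, len(dataset.lag_indices),
    )

    fits = {
        n: kinmodel.fit_model(
            dataset, n_states=n, dz=config.dz,
            d_slow_min=config.d_slow_min, seed=config.seed,
        )
        for n in config.n_states_candidates
    }
    chosen = min(fits.values(), key=lambda f: (f.aic, f.n_states))
    delta_aic = max(f.aic for f in fits.values()) - chosen.aic

    grid = dataset.bin_edges
    for k in dataset.lag_indices:
        if dataset.n_jumps(k) == 0:
            continue
        dt = k * config.frame_interval
        pd.DataFrame(
            {
                "r_um": grid,
                "empirical_cdf": dataset.empirical_cdf(k),
                "model_cdf": kinmodel.model_cdf(
                    chosen.model, dt, grid,
                    jumps_to_consider=config.jumps_to_consider,
                    frame_interval=config.frame_interval,
                ),
                "model_pdf": kinmodel.model_pdf(
                    chosen.model, dt, grid,
                    jumps_to_consider=config.jumps_to_consider,
                    frame_interval=config.frame_interval,
                ),
            }
        ).to_csv(out / f"cdf_lag{k}.csv", index=False)

    report = {
        "config": dataclasses.asdict(config),
        "counts": {
            "localizations_read": len(locs),
            "localizations_retained": len(kept),
            "trajectories": len(trajs),
            "jumps_per_lag": {
                str(k): dataset.n_jumps(k) for k in dataset.lag_indices
            },
        },
        "fits": {str(n): _fit_to_dict(f) for n, f in fits.items()},
        "selected_n_states": chosen.n_states,
        "delta_aic": delta_aic,
        "f_bound": kinmodel.f_bound(chosen),
    }
    _write_report(report, out / "report.json")
    return report


def run_fluctuation(config: FluctuationRunConfig) -> dict:
    """Per-condition Luria-Delbruck rate estimates plus requested fold changes.

    Input CSV columns: culture_id, condition, mutant_count, n_final, efficiency.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    df = pd.read_csv(config.input_csv)
    required = ["culture_id", "condition", "mutant_count", "n_final", "efficiency"]
    for col in required:
        if col not in df.columns:
            raise ParseError(f"missing required column '{col}'")
    for col in ["mutant_count", "n_final", "efficiency"]:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = int(bad.index[bad.isna()][0]) + 2
            raise ParseError(f"non-numeric '{col}' at row {row}")
        df[col] = bad

    estimates = {}
    for cond, grp in df.groupby("condition", sort=True):
        exp = fluctuation.FluctuationExperiment(
            counts=tuple(int(c) for c in grp["mutant_count"]),
            n_final=float(grp["n_final"].iloc[0]),
            plating_efficiency=float(grp["efficiency"].iloc[0]),
            condition=str(cond),
        )
        est = fluctuation.estimate_rate(exp)
        estimates[str(cond)] = est

    folds = {}
    for cond_a, cond_b in config.pairs:
        if cond_a not in estimates or cond_b not in estimates:
            raise ConfigError(
                f"unknown condition pair ({cond_a}, {cond_b}); "
                f"available: {sorted(estimates)}"
            )
        fc = fluctuation.fold_change(estimates[cond_a], estimates[cond_b])
        folds[f"{cond_a}_vs_{cond_b}"] = {
            "ratio": fc.ratio, "ci95": list(fc.ci95),
        }

    report = {
        "config": {
            "input_csv": config.input_csv,
            "out_dir": config.out_dir,
            "pairs": [list(p) for p in config.pairs],
        },
        "rates": {
            cond: {
                "m_hat": est.m_hat,
                "rate": est.rate,
                "rate_ci95": list(est.ci95),
                "m_ci95": list(est.m_ci95),
                "loglik": est.loglik,
                "note": est.note,
            }
            for cond, est in estimates.items()
        },
        "fold_changes": folds,
    }
    _write_report(report, out / "fluctuation_report.json")
    return report


def _write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
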