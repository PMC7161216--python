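"""End-to-end experiment drivers: matching benchmark and tracking benchmark."""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import (
    OSPAParams,
    count_id_switches,
    evaluate_solver,
    ospa_t_average,
)
from .policy import PolicyModel, save_checkpoint
from .simulate import generate_crossing_scenario, generate_mwm
from .tracking import constant_velocity_model, track_sequence
from .training import TrainingConfig, train

__all__ = [
    "MWMExperimentConfig",
    "run_mwm_experiment",
    "TrackingExperimentConfig",
    "run_tracking_experiment",
]


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(name.encode())])
    )


@dataclass
class MWMExperimentConfig:
    sizes: tuple[int, ...] = (15, 20, 25)
    n_train: int = 10_000
    n_test: int = 1_000
    batch_size: int = 64
    n_steps: int | None = None
    learning_rate: float = 1e-3
    baseline_rate: float = 0.1
    temperature: float = 1.0
    epochs: int = 3
    seed: int = 0
    out_dir: Path | None = None


def run_mwm_experiment(config: MWMExperimentConfig) -> dict:
    """Train and evaluate the matching policy at each size; report medians."""
    report: dict = {"sizes": {}, "seed": config.seed}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    for size in config.sizes:
        t0 = time.time()
        train_cfg = TrainingConfig(
            n_samples=config.n_train,
            batch_size=config.batch_size,
            n_steps=config.n_steps,
            learning_rate=config.learning_rate,
            baseline_rate=config.baseline_rate,
            temperature=config.temperature,
            epochs=config.epochs,
            seed=config.seed + size,
            objective_sense="maximize",
        )
        gen = lambda rng: generate_mwm(size, rng).weights
        model, log = train(train_cfg, gen)

        test_rng = _substream(config.seed, f"test-{size}")
        test_set = [generate_mwm(size, test_rng).weights
                    for _ in range(config.n_test)]
        trained = evaluate_solver(test_set, policy=model, sense="maximize")
        untrained = evaluate_solver(
            test_set,
            policy=PolicyModel(
                n_blocks=model.n_blocks, n_channels=model.n_channels,
                kernel_size=model.kernel_size, seed=train_cfg.seed,
                temperature=model.temperature,
            ),
            sense="maximize",
        )
        entry = {
            "median_ratio": trained.median_ratio,
            "mean_ratio": trained.mean_ratio,
            "untrained_median_ratio": untrained.median_ratio,
            "n_test": config.n_test,
            "n_train": config.n_train,
            "steps": train_cfg.n_steps,
            "wall_seconds": time.time() - t0,
        }
        report["sizes"][str(size)] = entry
        if out_dir:
            save_checkpoint(model, out_dir / f"policy_n{size}",
                            extra={"size": size})
            log.write_csv(out_dir / f"training_log_n{size}.csv")
            (out_dir / f"ratios_n{size}.json").write_text(
                json.dumps(list(trained.ratios))
            )
    if out_dir:
        (out_dir / "mwm_report.json").write_text(json.dumps(report, indent=2))
    return report


@dataclass
class TrackingExperimentConfig:
    noise_levels: tuple[float, ...] = (0.01, 0.05, 0.1)
    n_runs: int = 100
    n_targets: int = 5
    n_frames: int = 40
    solver: str = "exact"
    policy: PolicyModel | None = None
    threshold: float | None = None
    patience: int = 2
    ospa: OSPAParams = field(default_factory=OSPAParams)
    seed: int = 0
    out_dir: Path | None = None


def run_tracking_experiment(config: TrackingExperimentConfig) -> dict:
    """Crossing-scenario sweep over measurement noise levels.

    Per run: simulate, track with a Mahalanobis-gated constant-velocity
    Kalman tracker, and score OSPA-T and identity switches against truth.
    """
    report: dict = {"noise_levels": {}, "seed": config.seed,
                    "n_runs": config.n_runs, "solver": config.solver}
    for level in config.noise_levels:
        ospa_vals, idsw_vals = [], []
        for run in range(config.n_runs):
            seed = int(
                np.random.SeedSequence([config.seed, int(level * 1e6), run])
                .generate_state(1)[0]
            )
            scenario = generate_crossing_scenario(
                n_targets=config.n_targets, n_frames=config.n_frames,
                noise_cov=level, seed=seed,
            )
            sigma = float(np.sqrt(level)) if level > 0 else 0.05
            model = constant_velocity_model(sigma_accel=0.005, sigma_meas=sigma)
            # Mahalanobis units: generous gate (no clutter in this scenario)
            tau = config.threshold if config.threshold is not None else 6.0
            tracks = track_sequence(
                scenario.detections_by_frame(), model, threshold=tau,
                solver=config.solver, distance="mahalanobis",
                policy=config.policy, patience=config.patience,
            )
            truth = {
                k: {t: scenario.truth[k, t] for t in range(scenario.n_frames)}
                for k in range(scenario.n_targets)
            }
            estimate = {trk.id: trk.positions() for trk in tracks}
            ospa_vals.append(ospa_t_average(truth, estimate, config.ospa))
            idsw_vals.append(
                count_id_switches(truth, estimate,
                                  match_radius=config.ospa.cutoff)
            )
        report["noise_levels"][str(level)] = {
            "ospa_t_mean": float(np.mean(ospa_vals)),
            "ospa_t_std": float(np.std(ospa_vals)),
            "idsw_mean": float(np.mean(idsw_vals)),
            "idsw_std": float(np.std(idsw_vals)),
            "runs": config.n_runs,
        }
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "tracking_report.json").write_text(json.dumps(report, indent=2))
    return report
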