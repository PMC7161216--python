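"""REINFORCE training of the score network on a fixed set of instances.

Each training step samples a batch from a persistent training set, draws one
assignment per instance from the stochastic policy, and follows the
advantage-weighted score-function gradient

    g = (1/B) sum_i (AC(pi_i | C_i) - b(C_i)) * d log p(pi_i | C_i) / d theta

with an exponential-moving-average baseline per instance,

    b'(C_i) = b(C_i) + alpha * (AC(pi_i | C_i) - b(C_i)),

updated by Adam under a step-decayed learning rate.  Episodes are single
decisions (one matrix in, one permutation out), so no discounting appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .assignment import assignment_cost
from .policy import PolicyModel, decode, decode_batch, normalize_input

__all__ = [
    "TrainingConfig",
    "BaselineStore",
    "TrainingLog",
    "Adam",
    "initialize_baselines",
    "reinforce_gradient",
    "update_baseline",
    "train",
]


@dataclass
class TrainingConfig:
    n_samples: int = 10_000
    batch_size: int = 64
    n_steps: int | None = None       # default: 3 epochs over the training set
    learning_rate: float = 1e-3
    lr_decay_factor: float = 0.96
    lr_decay_every: int = 5_000
    baseline_rate: float = 0.1
    seed: int = 0
    objective_sense: Literal["minimize", "maximize"] = "minimize"
    epochs: int = 3
    temperature: float = 1.0
    n_blocks: int = 3
    n_channels: int = 8
    kernel_size: int = 3
    dtype: str = "float32"  # float32 for throughput; float64 for grad checks
    # Optional annealing: evenly split phases of (sampling temperature,
    # learning rate).  Overrides `temperature`/`learning_rate` per phase;
    # the training set and baselines persist across phases.
    schedule: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.batch_size <= 0:
            raise ValueError("n_samples and batch_size must be positive")
        if not 0 < self.baseline_rate <= 1:
            raise ValueError("baseline_rate must be in (0, 1]")
        if not 0 < self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must be in (0, 1]")
        if self.learning_rate <= 0 or self.temperature <= 0:
            raise ValueError("learning_rate and temperature must be positive")
        if self.n_steps is None:
            steps_per_epoch = -(-self.n_samples // self.batch_size)
            self.n_steps = steps_per_epoch * self.epochs
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")
        if self.schedule is not None:
            if not self.schedule:
                raise ValueError("schedule must be non-empty when given")
            for temp, lr in self.schedule:
                if temp <= 0 or lr <= 0:
                    raise ValueError("schedule temperatures and lrs must be positive")

    def phase_at(self, step: int) -> tuple[float, float]:
        """(temperature, base learning rate) in effect at a step."""
        if self.schedule is None:
            return self.temperature, self.learning_rate
        n_phases = len(self.schedule)
        span = max(1, -(-self.n_steps // n_phases))
        return self.schedule[min(step // span, n_phases - 1)]

    def lr_at(self, step: int) -> float:
        _, base = self.phase_at(step)
        return base * self.lr_decay_factor ** (step // self.lr_decay_every)


class BaselineStore:
    """Per-instance running baseline values ``b(C_i)``."""

    def __init__(self, values: Sequence[float]):
        self.values = np.asarray(values, dtype=float).copy()

    def __getitem__(self, sample_id: int) -> float:
        return float(self.values[sample_id])

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TrainingLog:
    steps: list[int] = field(default_factory=list)
    mean_reward: list[float] = field(default_factory=list)
    mean_baseline: list[float] = field(default_factory=list)
    grad_norm: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)

    def record(self, step, reward, baseline, gnorm, lr) -> None:
        self.steps.append(step)
        self.mean_reward.append(float(reward))
        self.mean_baseline.append(float(baseline))
        self.grad_norm.append(float(gnorm))
        self.learning_rate.append(float(lr))

    def to_rows(self):
        header = ["step", "mean_reward", "mean_baseline", "grad_norm", "lr"]
        rows = zip(self.steps, self.mean_reward, self.mean_baseline,
                   self.grad_norm, self.learning_rate)
        return header, list(rows)

    def write_csv(self, path) -> None:
        header, rows = self.to_rows()
        with open(path, "w") as fh:
            fh.write(",".join(header) + "\n")
            for row in rows:
                fh.write(",".join(str(v) for v in row) + "\n")


class Adam:
    """Standard Adam optimizer over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for key, p in self.params.items():
            g = grads[key]
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            p -= lr * (self.m[key] / b1c) / (np.sqrt(self.v[key] / b2c) + self.eps)


def _stack_normalized(model: PolicyModel, matrices: Sequence[np.ndarray]) -> np.ndarray:
    return np.stack([normalize_input(m, model.normalization) for m in matrices])


def initialize_baselines(
    model: PolicyModel, samples: Sequence[np.ndarray]
) -> BaselineStore:
    """Baseline = cost of the initial model's greedy assignment, per sample."""
    if len(samples) == 0:
        raise ValueError("cannot initialize baselines from an empty sample list")
    values = []
    for start in range(0, len(samples), 256):  # chunked to bound memory
        chunk = samples[start : start + 256]
        scores = model.forward(_stack_normalized(model, chunk), train=False)
        perms, _, _ = decode_batch(scores, mode="greedy",
                                   temperature=model.temperature)
        values.extend(
            assignment_cost(sample, perm) for sample, perm in zip(chunk, perms)
        )
    return BaselineStore(values)


def reinforce_gradient(
    model: PolicyModel,
    batch: Sequence[tuple[np.ndarray, float]],
    rng: np.random.Generator | int | None = None,
    objective_sense: str = "minimize",
    train_mode: bool = True,
) -> tuple[dict[str, np.ndarray], list[tuple[tuple[int, ...], float]]]:
    """One advantage-weighted policy-gradient estimate over a batch.

    Returns the gradient dict (aligned with ``model.parameters()``) and the
    sampled ``(permutation, cost)`` per instance.  The returned gradient is a
    *descent* direction: for ``minimize`` it descends the expected cost, for
    ``maximize`` it ascends the expected weight.
    """
    if len(batch) == 0:
        raise ValueError("empty batch")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    matrices = [m for m, _ in batch]
    baselines = np.array([b for _, b in batch], dtype=float)
    x = _stack_normalized(model, matrices)
    model.zero_grad()
    scores = model.forward(x, train=train_mode)
    sign = 1.0 if objective_sense == "minimize" else -1.0
    perms, _, dlogp = decode_batch(scores, mode="sample", rng=rng,
                                   temperature=model.temperature,
                                   with_grad=True)
    costs = np.array([
        assignment_cost(matrix, perm) for matrix, perm in zip(matrices, perms)
    ])
    advantages = costs - baselines
    dscores = (sign / len(batch)) * advantages[:, None, None] * dlogp
    outcomes = [
        (tuple(int(c) for c in perm), float(cost))
        for perm, cost in zip(perms, costs)
    ]
    model.backward(dscores)
    return {k: v.copy() for k, v in model.gradients().items()}, outcomes


def update_baseline(
    store: BaselineStore, sample_id: int, observed_cost: float, alpha: float
) -> BaselineStore:
    """Exponential-moving-average baseline update (in place; store returned)."""
    if not 0 <= sample_id < len(store):
        raise KeyError(f"unknown sample id {sample_id}")
    store.values[sample_id] += alpha * (observed_cost - store.values[sample_id])
    return store


def train(
    config: TrainingConfig,
    instance_generator: Callable[[np.random.Generator], np.ndarray],
    model: PolicyModel | None = None,
    progress: Callable[[int, TrainingLog], None] | None = None,
) -> tuple[PolicyModel, TrainingLog]:
    """Run the full training procedure and return the trained model + log.

    ``instance_generator(rng)`` must yield one square cost matrix per call;
    the training set of ``config.n_samples`` instances is generated once and
    revisited so per-instance baselines persist.
    """
    root = np.random.default_rng(config.seed)
    data_rng = np.random.default_rng(root.integers(2**63))
    sample_rng = np.random.default_rng(root.integers(2**63))
    batch_rng = np.random.default_rng(root.integers(2**63))

    samples = [np.asarray(instance_generator(data_rng), dtype=float)
               for _ in range(config.n_samples)]
    sizes = {s.shape for s in samples}
    if len(sizes) != 1:
        raise ValueError(f"training batches need one matrix size, got {sizes}")

    if model is None:
        model = PolicyModel(
            n_blocks=config.n_blocks,
            n_channels=config.n_channels,
            kernel_size=config.kernel_size,
            seed=int(root.integers(2**31)),
            temperature=config.temperature,
            dtype=np.dtype(config.dtype).type,
        )
    baselines = initialize_baselines(model, samples)
    optimizer = Adam(model.parameters())
    log = TrainingLog()

    for step in range(config.n_steps):
        model.temperature, _ = config.phase_at(step)
        idx = batch_rng.integers(0, config.n_samples, size=config.batch_size)
        batch = [(samples[i], baselines[i]) for i in idx]
        grads, outcomes = reinforce_gradient(
            model, batch, rng=sample_rng,
            objective_sense=config.objective_sense,
        )
        gnorm = float(np.sqrt(sum(float((g * g).sum()) for g in grads.values())))
        if not np.isfinite(gnorm):
            raise FloatingPointError(
                f"non-finite gradient at step {step}; batch ids {list(idx)}"
            )
        lr = config.lr_at(step)
        optimizer.step(grads, lr)
        costs = [c for _, c in outcomes]
        for i, (_, cost) in zip(idx, outcomes):
            update_baseline(baselines, int(i), cost, config.baseline_rate)
        log.record(step, np.mean(costs), float(np.mean(baselines.values)),
                   gnorm, lr)
        if progress is not None:
            progress(step, log)
    return model, log
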