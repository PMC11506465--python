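"""GA-BP freshness classifier.

A single-hidden-layer feed-forward network (sigmoid units, one-hot
targets, argmax decision) whose initial weights and biases are found by a
real-coded genetic algorithm before backpropagation refines them:

1. fix the layer sizes and flatten all weights and biases into one real
   chromosome;
2. evolve a population of chromosomes — roulette-wheel selection with
   elitism, arithmetic (blend) crossover, per-gene Gaussian mutation —
   scoring each by ``1 / (1 + SSE)`` of the decoded network on the
   training set;
3. decode the best individual into the network's initial parameters;
4. train with full-batch gradient descent on the squared error;
5. predict grades 1/2/3 by the argmax of the three output units.

The GA supplies a good basin for gradient descent; backpropagation does
the fine work. Both stages are deterministic under their seeds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "NetworkSpec",
    "Chromosome",
    "GaConfig",
    "BpConfig",
    "NetworkParams",
    "GabpModel",
    "chromosome_length",
    "encode",
    "decode",
    "forward",
    "fitness",
    "evolve",
    "GaResult",
    "train_bp",
    "predict",
    "fit_gabp",
    "save_model",
    "load_model",
]

GRADES = np.array([1, 2, 3])


@dataclass(frozen=True)
class NetworkSpec:
    """Feed-forward network architecture.

    Defaults match the freshness task: 3 inputs (PCA scores), 10 hidden
    sigmoid units, 3 output units (one per grade) read by argmax.
    """

    n_input: int = 3
    n_hidden: int = 10
    n_output: int = 3
    activation: str = "sigmoid"
    output_rule: str = "argmax"

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise ValueError("all layer sizes must be at least 1")
        if self.activation != "sigmoid":
            raise ValueError(f"unsupported activation {self.activation!r}")
        if self.output_rule != "argmax":
            raise ValueError(f"unsupported output rule {self.output_rule!r}")


def chromosome_length(spec: NetworkSpec) -> int:
    """Genes needed to encode every weight and bias of ``spec``."""
    return (
        spec.n_input * spec.n_hidden
        + spec.n_hidden
        + spec.n_hidden * spec.n_output
        + spec.n_output
    )


@dataclass
class Chromosome:
    """A flat real vector encoding all network weights and biases."""

    genes: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=float)
        if self.genes.ndim != 1:
            raise ValueError("genes must be a flat vector")


@dataclass(frozen=True)
class GaConfig:
    """Genetic-algorithm settings.

    ``gene_bounds`` is both the initialization range and the clip range
    for mutated genes; ``mutation_sd_fraction`` sets the Gaussian
    perturbation scale as a fraction of the bound width.
    """

    population_size: int = 40
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.05
    elitism_count: int = 1
    gene_bounds: tuple[float, float] = (-1.0, 1.0)
    mutation_sd_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if not 0 <= self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")
        if not 0 <= self.crossover_prob <= 1 or not 0 <= self.mutation_prob <= 1:
            raise ValueError("crossover_prob and mutation_prob must be in [0, 1]")
        low, high = self.gene_bounds
        if low >= high:
            raise ValueError(f"degenerate gene_bounds {self.gene_bounds}: low must be < high")
        if self.generations < 0:
            raise ValueError("generations must be nonnegative")


@dataclass(frozen=True)
class BpConfig:
    """Backpropagation settings: full-batch gradient descent with an
    adaptive step size.

    ``learning_rate`` is the initial step size. With ``adaptive=True``
    (the default) the step size grows by ``lr_increase`` after an epoch
    that does not raise the loss by more than ``max_loss_increase`` and
    shrinks by ``lr_decrease`` — with the step rolled back — otherwise;
    the constants are the classical adaptive-gradient-descent ones.
    ``adaptive=False`` gives plain fixed-step gradient descent.
    """

    learning_rate: float = 0.01
    epochs: int = 2000
    adaptive: bool = True
    lr_increase: float = 1.05
    lr_decrease: float = 0.7
    max_loss_increase: float = 1.04

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")


class NetworkParams(NamedTuple):
    """Weight matrices and bias vectors of the two layers."""

    w_hidden: np.ndarray  # (n_hidden, n_input)
    b_hidden: np.ndarray  # (n_hidden,)
    w_output: np.ndarray  # (n_output, n_hidden)
    b_output: np.ndarray  # (n_output,)


def encode(params: NetworkParams, spec: NetworkSpec) -> Chromosome:
    """Flatten parameters into a chromosome.

    Layout: input→hidden weights row-major, hidden biases, hidden→output
    weights row-major, output biases.
    """
    w1, b1, w2, b2 = params
    if (
        w1.shape != (spec.n_hidden, spec.n_input)
        or b1.shape != (spec.n_hidden,)
        or w2.shape != (spec.n_output, spec.n_hidden)
        or b2.shape != (spec.n_output,)
    ):
        raise ValueError("parameter shapes do not match the network spec")
    return Chromosome(np.concatenate([w1.ravel(), b1, w2.ravel(), b2]))


def decode(chromosome: Chromosome | np.ndarray, spec: NetworkSpec) -> NetworkParams:
    """Unflatten a chromosome into weight matrices and bias vectors."""
    genes = chromosome.genes if isinstance(chromosome, Chromosome) else np.asarray(chromosome, float)
    expected = chromosome_length(spec)
    if genes.shape != (expected,):
        raise ValueError(f"chromosome has {genes.shape[0]} genes, spec requires {expected}")
    i = 0
    w1 = genes[i : i + spec.n_input * spec.n_hidden].reshape(spec.n_hidden, spec.n_input)
    i += spec.n_input * spec.n_hidden
    b1 = genes[i : i + spec.n_hidden]
    i += spec.n_hidden
    w2 = genes[i : i + spec.n_hidden * spec.n_output].reshape(spec.n_output, spec.n_hidden)
    i += spec.n_hidden * spec.n_output
    b2 = genes[i:]
    return NetworkParams(w1.copy(), b1.copy(), w2.copy(), b2.copy())


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Network outputs for rows of ``X`` (sigmoid hidden and output layers)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.w_hidden.shape[1]:
        raise ValueError(
            f"input has {X.shape[1]} features, network expects {params.w_hidden.shape[1]}"
        )
    hidden = _sigmoid(X @ params.w_hidden.T + params.b_hidden)
    return _sigmoid(hidden @ params.w_output.T + params.b_output)


def _one_hot(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    T = np.zeros((len(y), len(GRADES)))
    for j, g in enumerate(GRADES):
        T[y == g, j] = 1.0
    if not np.isin(y, GRADES).all():
        raise ValueError("labels must be grades in {1, 2, 3}")
    return T


def fitness(
    chromosome: Chromosome | np.ndarray,
    train_X: np.ndarray,
    train_y: np.ndarray,
    spec: NetworkSpec,
) -> float:
    """GA fitness ``1 / (1 + SSE)`` of the decoded, untrained network.

    SSE is the summed squared error between the network outputs and the
    one-hot grade targets over the whole training set; fitness lies in
    (0, 1], and a network reproducing the targets exactly scores 1.
    """
    if len(train_X) == 0:
        raise ValueError("training set is empty")
    params = decode(chromosome, spec)
    out = forward(params, train_X)
    if not np.isfinite(out).all():
        warnings.warn("non-finite network output; fitness set to 0")
        return 0.0
    sse = float(((out - _one_hot(train_y)) ** 2).sum())
    return 1.0 / (1.0 + sse)


class GaResult(NamedTuple):
    """Best individual found and the per-generation best-fitness trace."""

    best: Chromosome
    best_fitness_trace: np.ndarray


def _roulette_pick(rng: np.random.Generator, cumulative: np.ndarray) -> int:
    return int(np.searchsorted(cumulative, rng.random() * cumulative[-1], side="right"))


def evolve(
    ga_config: GaConfig,
    spec: NetworkSpec,
    train_X: np.ndarray,
    train_y: np.ndarray,
) -> GaResult:
    """Evolve chromosomes toward low training error.

    Each generation: fitness-proportional (roulette-wheel) selection,
    arithmetic blend crossover with probability ``crossover_prob``,
    per-gene Gaussian mutation clipped to ``gene_bounds``, and elitism
    copying the ``elitism_count`` best individuals unchanged — which makes
    the best-so-far fitness trace nondecreasing. Deterministic under the
    config seed.
    """
    rng = np.random.default_rng(ga_config.seed)
    low, high = ga_config.gene_bounds
    length = chromosome_length(spec)
    pop = rng.uniform(low, high, size=(ga_config.population_size, length))
    fits = np.array([fitness(ind, train_X, train_y, spec) for ind in pop])
    trace = [float(fits.max())]
    mut_sd = ga_config.mutation_sd_fraction * (high - low)

    for _ in range(ga_config.generations):
        order = np.argsort(fits)[::-1]
        elite = pop[order[: ga_config.elitism_count]].copy()
        cumulative = np.cumsum(fits)
        children = []
        while len(children) < ga_config.population_size - ga_config.elitism_count:
            i = _roulette_pick(rng, cumulative)
            j = _roulette_pick(rng, cumulative)
            a, b = pop[i].copy(), pop[j].copy()
            if rng.random() < ga_config.crossover_prob:
                alpha = rng.random(length)
                a, b = alpha * a + (1 - alpha) * b, alpha * b + (1 - alpha) * a
            for child in (a, b):
                mask = rng.random(length) < ga_config.mutation_prob
                if mask.any():
                    child[mask] = np.clip(
                        child[mask] + rng.normal(0.0, mut_sd, mask.sum()), low, high
                    )
                children.append(child)
        pop = np.vstack([elite, *children[: ga_config.population_size - ga_config.elitism_count]])
        fits = np.array([fitness(ind, train_X, train_y, spec) for ind in pop])
        trace.append(float(fits.max()))

    best_idx = int(fits.argmax())
    best = Chromosome(pop[best_idx].copy(), fitness=float(fits[best_idx]))
    return GaResult(best=best, best_fitness_trace=np.asarray(trace))


def _bp_loss(out: np.ndarray, targets: np.ndarray) -> float:
    # half the summed squared output error (the quantity the GA fitness uses)
    return float(0.5 * ((out - targets) ** 2).sum())


def train_bp(
    init_params: NetworkParams,
    spec: NetworkSpec,
    train_X: np.ndarray,
    train_y: np.ndarray,
    learning_rate: float = 0.01,
    epochs: int = 2000,
    seed: int | None = None,
    bp_config: BpConfig | None = None,
) -> tuple[NetworkParams, np.ndarray]:
    """Full-batch gradient descent on the squared error from given initials.

    The loss is half the summed squared output error over the training
    set — the same SSE the GA fitness is built on — and gradients are the
    standard sigmoid backpropagation ones. By default the step size
    adapts (see :class:`BpConfig`): it grows while the loss keeps
    falling, and an epoch that raises the loss beyond the tolerance is
    rolled back with a smaller step; this escapes the shallow plateaus
    fixed-step descent can stall on.

    Returns the trained parameters and the loss after each epoch
    (element 0 is the loss at the initial parameters; a rolled-back
    epoch repeats the previous value; ``epochs=0`` returns the initials
    unchanged). ``seed`` is accepted for interface symmetry; full-batch
    training consumes no randomness.
    """
    if bp_config is None:
        bp_config = BpConfig(learning_rate=learning_rate, epochs=epochs)
    lr = bp_config.learning_rate
    X = np.atleast_2d(np.asarray(train_X, dtype=float))
    T = _one_hot(np.asarray(train_y))
    if len(X) == 0:
        raise ValueError("training set is empty")
    w1, b1, w2, b2 = (a.copy() for a in init_params)

    def _forward(w1, b1, w2, b2):
        hidden = _sigmoid(X @ w1.T + b1)
        out = _sigmoid(hidden @ w2.T + b2)
        return hidden, out

    hidden, out = _forward(w1, b1, w2, b2)
    loss = _bp_loss(out, T)
    losses = [loss]
    for _ in range(bp_config.epochs):
        delta_out = (out - T) * out * (1.0 - out)  # (n, n_output)
        delta_hidden = (delta_out @ w2) * hidden * (1.0 - hidden)
        step = (
            lr * delta_hidden.T @ X,
            lr * delta_hidden.sum(axis=0),
            lr * delta_out.T @ hidden,
            lr * delta_out.sum(axis=0),
        )
        new = (w1 - step[0], b1 - step[1], w2 - step[2], b2 - step[3])
        new_hidden, new_out = _forward(*new)
        new_loss = _bp_loss(new_out, T)
        if not bp_config.adaptive:
            w1, b1, w2, b2 = new
            hidden, out, loss = new_hidden, new_out, new_loss
        elif np.isfinite(new_loss) and new_loss <= loss * bp_config.max_loss_increase:
            w1, b1, w2, b2 = new
            hidden, out, loss = new_hidden, new_out, new_loss
            lr *= bp_config.lr_increase
        else:  # reject the step, retry smaller
            lr *= bp_config.lr_decrease
        losses.append(loss)
    return NetworkParams(w1, b1, w2, b2), np.asarray(losses)


def predict(params: NetworkParams, spec: NetworkSpec, X: np.ndarray) -> np.ndarray:
    """Grades 1/2/3 by argmax over the output units (ties go to the lower
    grade)."""
    out = forward(params, np.atleast_2d(np.asarray(X, dtype=float)))
    return GRADES[out.argmax(axis=1)]


@dataclass
class GabpModel:
    """A fitted GA-BP classifier plus its input-scaling transform.

    ``feature_min``/``feature_max`` record the min–max scaling fitted on
    the training features (applied before the network), so the model is
    self-contained at prediction time.
    """

    spec: NetworkSpec
    params: NetworkParams
    feature_min: np.ndarray
    feature_max: np.ndarray
    ga_config: GaConfig
    bp_config: BpConfig
    ga_best_fitness: float
    loss_trace: np.ndarray = field(repr=False)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.feature_max == self.feature_min, 1.0, self.feature_max - self.feature_min)
        return (np.atleast_2d(np.asarray(X, float)) - self.feature_min) / span

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self.params, self.spec, self._scale(X))


def fit_gabp(
    train_X: np.ndarray,
    train_y: np.ndarray,
    ga_config: GaConfig | None = None,
    spec: NetworkSpec | None = None,
    bp_config: BpConfig | None = None,
) -> GabpModel:
    """Run the full GA-BP fit: evolve, decode the best individual, then
    backpropagate from it.

    Features are min–max scaled internally (the scaling is stored on the
    model); labels are grades in {1, 2, 3}.
    """
    X = np.atleast_2d(np.asarray(train_X, dtype=float))
    y = np.asarray(train_y)
    spec = spec if spec is not None else NetworkSpec(n_input=X.shape[1])
    ga_config = ga_config if ga_config is not None else GaConfig()
    bp_config = bp_config if bp_config is not None else BpConfig()
    if X.shape[1] != spec.n_input:
        raise ValueError(f"training data has {X.shape[1]} features, spec expects {spec.n_input}")
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = np.where(hi == lo, 1.0, hi - lo)
    Xs = (X - lo) / span
    ga = evolve(ga_config, spec, Xs, y)
    init = decode(ga.best, spec)
    params, losses = train_bp(init, spec, Xs, y, bp_config=bp_config)
    return GabpModel(
        spec=spec,
        params=params,
        feature_min=lo,
        feature_max=hi,
        ga_config=ga_config,
        bp_config=bp_config,
        ga_best_fitness=float(ga.best.fitness),
        loss_trace=losses,
    )


# ---------------------------------------------------------------------------
# plain-text persistence


def save_model(model: GabpModel, path: str | Path) -> None:
    """Write a model as a plain-text JSON document (config echo + weights)."""
    doc = {
        "format": "enose-gabp-model",
        "spec": model.spec.__dict__,
        "ga_config": {**model.ga_config.__dict__, "gene_bounds": list(model.ga_config.gene_bounds)},
        "bp_config": model.bp_config.__dict__,
        "ga_best_fitness": model.ga_best_fitness,
        "feature_min": model.feature_min.tolist(),
        "feature_max": model.feature_max.tolist(),
        "params": {
            "w_hidden": model.params.w_hidden.tolist(),
            "b_hidden": model.params.b_hidden.tolist(),
            "w_output": model.params.w_output.tolist(),
            "b_output": model.params.b_output.tolist(),
        },
        "final_loss": float(model.loss_trace[-1]),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> GabpModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "enose-gabp-model":
        raise ValueError(f"{path} is not an enose GA-BP model file")
    ga_kwargs = dict(doc["ga_config"])
    ga_kwargs["gene_bounds"] = tuple(ga_kwargs["gene_bounds"])
    params = NetworkParams(
        np.asarray(doc["params"]["w_hidden"]),
        np.asarray(doc["params"]["b_hidden"]),
        np.asarray(doc["params"]["w_output"]),
        np.asarray(doc["params"]["b_output"]),
    )
    return GabpModel(
        spec=NetworkSpec(**doc["spec"]),
        params=params,
        feature_min=np.asarray(doc["feature_min"]),
        feature_max=np.asarray(doc["feature_max"]),
        ga_config=GaConfig(**ga_kwargs),
        bp_config=BpConfig(**doc["bp_config"]),
        ga_best_fitness=doc["ga_best_fitness"],
        loss_trace=np.asarray([doc["final_loss"]]),
    )
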