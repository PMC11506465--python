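"""End-to-end experiment orchestration.

One configuration drives the whole study: for each storage temperature,
generate (or load) a sensor dataset, derive TVB-N grades, min–max
normalize the 10 gas channels, reduce them to 3 principal components,
split 8:2 stratified, fit the GA-BP classifier on the training portion
and evaluate on the held-out portion. Four temperatures yield four
independent models, each with its own report; a combined summary gathers
the per-temperature accuracies. Everything is reproducible from the
config: per-stage seeds are derived deterministically from the
experiment seed, and each report embeds the config hash and the seeds
used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import chemometrics, evaluation, gabp, synthetic_data
from .synthetic_data import SENSOR_CHANNELS, GeneratorConfig, default_config

logger = logging.getLogger("enose")

__all__ = ["PipelineConfig", "load_config", "save_config", "run_experiment"]

_TEMPERATURES = (4, 12, 20, 28)


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of the full multi-temperature experiment.

    ``seed`` is the master seed: the generator at temperature index ``i``
    uses ``seed + i``, the train/test split ``seed + 100 + i``, and the
    genetic algorithm ``seed + 200 + i`` (all far below 2**31 for small
    master seeds).
    """

    temperatures: tuple[int, ...] = _TEMPERATURES
    n_components: int = 3
    train_ratio: float = 0.8
    stratified: bool = True
    n_hidden: int = 10
    population_size: int = 40
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.05
    learning_rate: float = 0.01
    epochs: int = 2000
    noise_sd: float = 0.02
    drift_sd: float = 0.05
    n_rows: dict = field(default_factory=dict)  # optional per-temperature override
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_components <= len(SENSOR_CHANNELS):
            raise ValueError(
                f"n_components must be in [1, {len(SENSOR_CHANNELS)}], got {self.n_components}"
            )
        for t in self.temperatures:
            if int(t) not in synthetic_data.CONDITION_PRESETS:
                raise ValueError(f"unsupported storage temperature {t!r}")

    def generator_config(self, temperature: int) -> GeneratorConfig:
        i = self.temperatures.index(temperature)
        overrides = {}
        if temperature in self.n_rows:
            overrides["n_rows"] = int(self.n_rows[temperature])
        return default_config(
            temperature,
            seed=self.seed + i,
            noise_sd=self.noise_sd,
            drift_sd=self.drift_sd,
            **overrides,
        )


_ALLOWED_KEYS = set(PipelineConfig.__dataclass_fields__)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path} does not contain a mapping")
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "temperatures" in raw:
        raw["temperatures"] = tuple(int(t) for t in raw["temperatures"])
    if "n_rows" in raw:
        raw["n_rows"] = {int(k): int(v) for k, v in raw["n_rows"].items()}
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_dict(config), sort_keys=True))


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["temperatures"] = list(d["temperatures"])
    return d


def config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(_config_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_temperature(config: PipelineConfig, temperature: int) -> dict:
    """Run the pipeline at one storage temperature and return its report."""
    i = config.temperatures.index(temperature)
    gen_config = config.generator_config(temperature)
    logger.info("generating %d rows at %d degC", gen_config.n_rows, temperature)
    sensors, quality, labels = synthetic_data.generate_dataset(gen_config)
    y = labels["label"].to_numpy()
    dist = {int(g): int(c) for g, c in zip(*np.unique(y, return_counts=True))}
    logger.info("label distribution at %d degC: %s", temperature, dist)

    X = sensors[SENSOR_CHANNELS].to_numpy()
    Xn, norm_model = chemometrics.normalize(X)
    pca = chemometrics.fit_pca(Xn, n_components=config.n_components)
    scores = chemometrics.transform(pca, Xn)
    cumvar = chemometrics.cumulative_variance(pca, config.n_components)
    logger.info(
        "PCA at %d degC: %d components keep %.1f%% of variance",
        temperature, config.n_components, 100 * cumvar,
    )

    train_idx, test_idx = evaluation.split_train_test(
        scores, y, ratio=config.train_ratio, seed=config.seed + 100 + i,
        stratified=config.stratified,
    )
    spec = gabp.NetworkSpec(n_input=config.n_components, n_hidden=config.n_hidden)
    ga_config = gabp.GaConfig(
        population_size=config.population_size,
        generations=config.generations,
        crossover_prob=config.crossover_prob,
        mutation_prob=config.mutation_prob,
        seed=config.seed + 200 + i,
    )
    bp_config = gabp.BpConfig(learning_rate=config.learning_rate, epochs=config.epochs)
    model = gabp.fit_gabp(scores[train_idx], y[train_idx], ga_config, spec, bp_config)
    logger.info(
        "GA best fitness %.3g, final training loss %.4g",
        model.ga_best_fitness, model.loss_trace[-1],
    )

    doc = evaluation.report(model, scores[test_idx], y[test_idx])
    doc.update(
        temperature_celsius=int(temperature),
        n_rows=int(gen_config.n_rows),
        n_train=int(len(train_idx)),
        label_distribution=dist,
        cumulative_variance_3pc=cumvar,
        generator_seed=int(gen_config.seed),
        split_seed=int(config.seed + 100 + i),
        ga_seed=int(ga_config.seed),
        config_hash=config_hash(config),
    )
    return doc


def run_experiment(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every configured temperature; optionally write reports to disk.

    Returns the combined summary: per-temperature reports plus the
    overall-accuracy vector and its minimum. With ``outdir`` set, writes
    ``report_<T>C.json``/``.txt`` per temperature and ``summary.json``.
    """
    reports = {}
    for t in config.temperatures:
        try:
            reports[int(t)] = run_temperature(config, t)
        except Exception as exc:  # annotate with the failing stage's condition
            raise RuntimeError(f"pipeline failed at {t} degC: {exc}") from exc
    summary = {
        "config": _config_dict(config),
        "config_hash": config_hash(config),
        "seed": int(config.seed),
        "overall_accuracy_pct": {
            str(t): reports[int(t)]["overall_accuracy_pct"] for t in config.temperatures
        },
        "min_overall_accuracy_pct": min(
            reports[int(t)]["overall_accuracy_pct"] for t in config.temperatures
        ),
        "reports": {str(t): reports[int(t)] for t in config.temperatures},
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for t, doc in reports.items():
            (outdir / f"report_{t}C.json").write_text(json.dumps(doc, indent=1, sort_keys=True))
            (outdir / f"report_{t}C.txt").write_text(evaluation.render_report(doc))
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
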