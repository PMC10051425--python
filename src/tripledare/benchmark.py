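"""The default synthetic adaptation benchmark.

A desk-scale analogue of a coincident lab-to-field study: 2000 windows per
domain over 8 context labels (6 activities + 2 prioceptions) with priors
taken from the scripted / in-the-wild proportion tables, domain shift
magnitude 1, and 30 training epochs.  Architecture and optimization settings
are compact so a full method comparison runs in minutes on one CPU core:
strided CNN stacks, batch size 64, Adam at lr0 = 3e-3 (the published lr of
0.1 remains the library default for TrainConfig; the benchmark documents its
own value).
"""

from __future__ import annotations

import copy

import numpy as np

from .config import GeneratorConfig, ModelConfig, RunConfig, TrainConfig
from .evaluation import MetricsReport, evaluate_model
from .features import featurize_dataset
from .synthetic import generate_dataset
from .training import train

BENCHMARK_LABELS = [
    "jogging", "sitting", "sleeping", "stairs_up", "typing", "walking",
    "phone_in_hand", "phone_in_pocket",
]

#: loss-mask methods used by the standard comparison
BENCHMARK_METHODS = ("tripledare", "dan", "source_only", "ablation-cls+tri")


def benchmark_config(seed: int = 0, epochs: int = 30,
                     shift_magnitude: float = 1.0) -> RunConfig:
    """The default benchmark conditions (see module docstring)."""
    return RunConfig(
        generator=GeneratorConfig(
            n_source=2000, n_target=2000, n_subjects_per_domain=20,
            label_names=list(BENCHMARK_LABELS), shift_magnitude=shift_magnitude,
            target_label_noise=0.05, seed=seed),
        model=ModelConfig(
            cnn_channels=[8, 16, 16], cnn_strides=[2, 2, 2],
            cnn_combined_channels=[16, 16, 32], cnn_combined_strides=[2, 1, 1]),
        train=TrainConfig(epochs=epochs, batch_size=64, lr0=3e-3, seed=seed),
        seed=seed,
    )


def make_benchmark_data(seed: int, config: RunConfig | None = None):
    """Generate and featurize the benchmark's source/target pair for one seed."""
    cfg = copy.deepcopy(config) if config is not None else benchmark_config(seed)
    cfg.generator.seed = seed
    source = generate_dataset(cfg.generator, "source")
    target = generate_dataset(cfg.generator, "target")
    featurize_dataset(source)
    featurize_dataset(target)
    return cfg, source, target


def run_benchmark(methods=BENCHMARK_METHODS, seeds=(1, 2, 3, 4, 5),
                  config: RunConfig | None = None,
                  progress: bool = False) -> list[MetricsReport]:
    """Train every method on every seed's dataset pair; score on the target.

    All methods share, per seed, the same generated data, initialization seed
    and batch schedule, so metric differences isolate the objectives.
    """
    reports: list[MetricsReport] = []
    for seed in seeds:
        cfg, source, target = make_benchmark_data(seed, config)
        for method in methods:
            run_cfg = copy.deepcopy(cfg)
            run_cfg.train.method = method
            run_cfg.train.seed = seed
            model, history = train(source, target, run_cfg)
            report = evaluate_model(model, target, method=method, seed=seed)
            report.extras["best_val_f1"] = history.best_val_f1
            report.extras["final_loss_total"] = history.steps[-1].loss_total
            reports.append(report)
            if progress:  # pragma: no cover - console convenience
                print(f"[seed {seed}] {method:>20s}  target micro-F1 "
                      f"{report.f1_micro:.3f}  silhouette "
                      f"{np.nan if report.silhouette_mean is None else report.silhouette_mean:.3f}")
    return reports
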