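"""Search orchestration: sample -> evaluate -> fit surrogate -> rank pool ->
top-k -> re-evaluate -> select best; plus the matched-budget random-search
baseline.

The surrogate predicts validation RMSE, so selection minimizes the
prediction. The candidate pool is a seeded uniform subsample of the space
(deduplicated against the surrogate's training set); for small enumerable
spaces the whole space can be supplied as the pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np

from .codec import EvaluatedArchitecture, encode
from .space import (
    ArchitectureDescriptor,
    SearchSpace,
    count_options,
    random_descriptor,
    stratified_sample,
    uniform_sample,
)
from .surrogate import (
    RankReport,
    SurrogateConfig,
    fit,
    predict_pool,
    rank_report,
)

__all__ = ["SearchConfig", "SearchReport", "top_k", "run_search",
           "run_random_search"]


@dataclass
class SearchConfig:
    """Knobs of one search run. Defaults: 800 sampled training
    architectures, top k=100 re-evaluated, candidates trained 200 epochs and
    the finalists 300, a 10^6-architecture candidate pool."""

    n_train_archs: int = 800
    k: int = 100
    candidate_epochs: int = 200
    final_epochs: int = 300
    pool_size: int = 1_000_000
    evaluation_backend: Literal["oracle", "cdrp"] = "oracle"
    sampler: Literal["stratified", "uniform"] = "stratified"
    seed: int = 0
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)

    def __post_init__(self) -> None:
        if self.k > self.pool_size:
            raise ValueError("k must not exceed pool_size")


@dataclass
class SearchReport:
    best_descriptor: ArchitectureDescriptor
    best_true_performance: float
    top_k_table: list  # [(descriptor, predicted, true)]
    surrogate_report: Optional[RankReport]
    evaluation_log: list  # [(descriptor canonical hash, stage, value)]
    config: dict
    n_evaluations: int

    def to_json(self) -> dict:
        return {
            "best_descriptor": self.best_descriptor.to_json(),
            "best_true_performance": self.best_true_performance,
            "top_k": [
                {"descriptor": d.to_json(), "predicted": p, "true": t}
                for d, p, t in self.top_k_table
            ],
            "surrogate_report": (
                self.surrogate_report.to_json() if self.surrogate_report else None
            ),
            "evaluation_log": [list(e) for e in self.evaluation_log],
            "config": self.config,
            "n_evaluations": self.n_evaluations,
        }

    @classmethod
    def from_json(cls, obj: dict, space: SearchSpace) -> "SearchReport":
        rep = obj.get("surrogate_report")
        return cls(
            best_descriptor=ArchitectureDescriptor.from_json(
                obj["best_descriptor"], space
            ),
            best_true_performance=obj["best_true_performance"],
            top_k_table=[
                (
                    ArchitectureDescriptor.from_json(row["descriptor"], space),
                    row["predicted"],
                    row["true"],
                )
                for row in obj["top_k"]
            ],
            surrogate_report=(
                RankReport(rep["rmse"], rep["pearson"], rep["kendall_tau"],
                           rep.get("degenerate", False))
                if rep
                else None
            ),
            evaluation_log=[tuple(e) for e in obj["evaluation_log"]],
            config=obj["config"],
            n_evaluations=obj["n_evaluations"],
        )


def top_k(
    predictions: Sequence[tuple[ArchitectureDescriptor, float]], k: int
) -> list[ArchitectureDescriptor]:
    """The k descriptors with the lowest predicted RMSE; ties broken by the
    descriptor's canonical serialization (stable and reproducible)."""
    if k > len(predictions):
        raise ValueError(f"k={k} exceeds pool size {len(predictions)}")
    ranked = sorted(predictions, key=lambda dp: (dp[1], dp[0].canonical()))
    return [d for d, _ in ranked[:k]]


Evaluator = Callable[[ArchitectureDescriptor, int], float]


def _config_json(space: SearchSpace, config: SearchConfig) -> dict:
    sc = config.surrogate
    return {
        "n_train_archs": config.n_train_archs,
        "k": config.k,
        "candidate_epochs": config.candidate_epochs,
        "final_epochs": config.final_epochs,
        "pool_size": config.pool_size,
        "evaluation_backend": config.evaluation_backend,
        "sampler": config.sampler,
        "seed": config.seed,
        "surrogate": {
            "hidden_width": sc.hidden_width,
            "beta": sc.beta,
            "learning_rate": sc.learning_rate,
            "weight_decay": sc.weight_decay,
            "epochs": sc.epochs,
            "batch_size": sc.batch_size,
            "split_fraction": sc.split_fraction,
            "seed": sc.seed,
        },
        "space_q": count_options(space),
    }


def _make_evaluator(config: SearchConfig, oracle=None, dataset=None,
                    split_spec=None) -> Evaluator:
    if config.evaluation_backend == "oracle":
        if oracle is None:
            raise ValueError("oracle backend requires a FitnessOracle")
        from .synthetic import oracle_fitness

        return lambda d, epochs: oracle_fitness(d, oracle)

    if dataset is None:
        raise ValueError("cdrp backend requires a ResponseDataset")
    from .model import SplitSpec, build_model, split, train_eval

    spec = split_spec or SplitSpec(seed=config.seed)
    splits = split(dataset, spec)
    cell_dim = len(dataset.cells[0].features)

    def evaluate(d: ArchitectureDescriptor, epochs: int) -> float:
        model = build_model(d, cell_feature_dim=cell_dim, seed=config.seed)
        metrics = train_eval(model, dataset, splits, epochs=epochs,
                             seed=config.seed)
        return metrics["val_rmse"]

    return evaluate


def _evaluate_all(descriptors, evaluator: Evaluator, epochs: int, stage: str,
                  log: list) -> list[EvaluatedArchitecture]:
    """Evaluate candidates, logging each; failures are logged and skipped,
    never imputed."""
    out = []
    for d in descriptors:
        try:
            perf = evaluator(d, epochs)
        except Exception as exc:  # noqa: BLE001 — candidate-level isolation
            log.append((d.canonical(), f"{stage}:failed", str(exc)))
            continue
        log.append((d.canonical(), stage, perf))
        out.append(EvaluatedArchitecture(d, perf))
    return out


def _draw_pool(space: SearchSpace, config: SearchConfig,
               exclude: set, pool: Optional[Sequence[ArchitectureDescriptor]]):
    if pool is not None:
        return [d for d in pool if d.canonical() not in exclude]
    rng = np.random.default_rng(config.seed + 1)
    drawn: list[ArchitectureDescriptor] = []
    seen = set(exclude)
    attempts = 0
    # bounded rejection: small spaces may not have pool_size fresh descriptors
    while len(drawn) < config.pool_size and attempts < 20 * config.pool_size:
        attempts += 1
        d = random_descriptor(space, rng=rng)
        key = d.canonical()
        if key in seen:
            continue
        seen.add(key)
        drawn.append(d)
    return drawn


def run_search(
    space: SearchSpace,
    config: SearchConfig,
    oracle=None,
    dataset=None,
    split_spec=None,
    pool: Optional[Sequence[ArchitectureDescriptor]] = None,
) -> SearchReport:
    """Full surrogate-guided search; fully reproducible from config.seed.

    ``pool`` overrides the random candidate pool (e.g. the exhaustive space
    for enumerable mini-spaces). Backends: ``oracle`` labels architectures
    with a synthetic fitness; ``cdrp`` trains a candidate model per
    architecture on ``dataset``.
    """
    evaluator = _make_evaluator(config, oracle, dataset, split_spec)
    log: list = []

    if config.sampler == "stratified":
        train_descs = stratified_sample(space, config.n_train_archs,
                                        seed=config.seed)
    else:
        train_descs = uniform_sample(space, config.n_train_archs,
                                     seed=config.seed)
    pairs = _evaluate_all(train_descs, evaluator, config.candidate_epochs,
                          "train", log)
    if len(pairs) < 2:
        raise RuntimeError("fewer than 2 evaluated training architectures")

    surrogate_config = SurrogateConfig(**{**config.surrogate.__dict__,
                                          "seed": config.seed})
    model, history = fit(pairs, space, surrogate_config)
    held_truth = [pairs[i].performance for i in history.test_indices]
    held_graphs = [encode(pairs[i].descriptor, space)
                   for i in history.test_indices]
    surrogate_rep = None
    if len(held_truth) >= 2:
        held_preds = predict_pool(model, held_graphs)
        surrogate_rep = rank_report(held_truth, held_preds.tolist())

    exclude = {p.descriptor.canonical() for p in pairs}
    candidates = _draw_pool(space, config, exclude, pool)
    graphs = [encode(d, space) for d in candidates]
    preds = predict_pool(model, graphs)
    k = min(config.k, len(candidates))
    chosen = top_k(list(zip(candidates, preds.tolist())), k)
    pred_by_key = {d.canonical(): p for d, p in zip(candidates, preds.tolist())}

    finalists = _evaluate_all(chosen, evaluator, config.final_epochs, "topk", log)
    if not finalists:
        raise RuntimeError("no finalist architecture could be evaluated")
    table = sorted(
        [(f.descriptor, pred_by_key[f.descriptor.canonical()], f.performance)
         for f in finalists],
        key=lambda row: (row[2], row[0].canonical()),
    )
    best_desc, _, best_true = table[0]
    return SearchReport(
        best_descriptor=best_desc,
        best_true_performance=best_true,
        top_k_table=table,
        surrogate_report=surrogate_rep,
        evaluation_log=log,
        config=_config_json(space, config),
        n_evaluations=len(pairs) + len(finalists),
    )


def run_random_search(
    space: SearchSpace,
    config: SearchConfig,
    oracle=None,
    dataset=None,
    split_spec=None,
) -> SearchReport:
    """Random-search baseline at matched budget: n_train_archs + k uniform
    descriptors are evaluated and the argmin reported."""
    evaluator = _make_evaluator(config, oracle, dataset, split_spec)
    log: list = []
    rng = np.random.default_rng(config.seed)
    budget = config.n_train_archs + config.k
    descs = [random_descriptor(space, rng=rng) for _ in range(budget)]
    evaluated = _evaluate_all(descs, evaluator, config.candidate_epochs,
                              "random", log)
    if not evaluated:
        raise RuntimeError("no architecture could be evaluated")
    table = sorted(
        [(e.descriptor, float("nan"), e.performance) for e in evaluated],
        key=lambda row: (row[2], row[0].canonical()),
    )
    best_desc, _, best_true = table[0]
    return SearchReport(
        best_descriptor=best_desc,
        best_true_performance=best_true,
        top_k_table=table[: config.k],
        surrogate_report=None,
        evaluation_log=log,
        config=_config_json(space, config),
        n_evaluations=len(evaluated),
    )
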