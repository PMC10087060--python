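"""End-to-end experiment orchestration at desk scale.

One experiment runs, for each random split seed: clean -> derive cluster
scheme -> fan out the test products over the scheme's tokens -> query the
retro model per token -> merge rank-major -> validate with the forward
model -> classify -> evaluate; the unconditioned baseline model is run on
the same test set with the same topN budget (topN = X * topk). Per-model
per-seed reports and a mean +/- standard-error comparison table are
written to the output directory, together with the config and every
intermediate file, so each number in the table can be re-derived.

Models here are the deterministic toy-chemistry oracles; any external
model can be substituted by exporting the fan-out source files
(``retroprompt prepare`` / ``fanout``) and re-importing its predictions
(``retroprompt evaluate``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import clusters, metrics, prompting, toychem
from .data import ReactionRecord, clean_dataset, split_dataset, write_reactions
from .errors import ConfigError

logger = logging.getLogger("retroprompt")


@dataclass
class SchemeSpec:
    """One token-derivation strategy to evaluate."""

    mode: str  # "superclass" | "random-group" | "kmeans"
    x: int
    p: int = 3  # PCA dimension, kmeans mode only
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = f"{self.x}clusters-{self.mode}"


@dataclass
class ExperimentConfig:
    """Fully serializable description of one experiment run."""

    toy: toychem.ToyDatasetParams = field(default_factory=toychem.ToyDatasetParams)
    schemes: list[SchemeSpec] = field(
        default_factory=lambda: [SchemeSpec(mode="superclass", x=4)]
    )
    topk: int = 1
    k_max: int = 0  # 0 -> X * topk of each scheme
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    outdir: str = "experiment-out"

    def to_yaml(self) -> str:
        payload = asdict(self)
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        raw = yaml.safe_load(text)
        toy = toychem.ToyDatasetParams(**_tupled(raw.pop("toy", {})))
        schemes = [SchemeSpec(**s) for s in raw.pop("schemes", [])]
        cfg = cls(toy=toy, schemes=schemes or cls().schemes, **_tupled(raw))
        return cfg


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def _fit_scheme(
    spec: SchemeSpec, train: Sequence[ReactionRecord], seed: int
) -> clusters.ClusterScheme:
    if spec.mode == "superclass":
        scheme = clusters.superclass_scheme()
        scheme.x = spec.x  # toy class codes span 0..T-1, not the full 12
        return scheme
    if spec.mode == "random-group":
        return clusters.random_group_scheme(spec.x, seed)
    if spec.mode == "kmeans":
        return clusters.kmeans_scheme(train, k=spec.x, p=spec.p, seed=seed)
    raise ConfigError(f"unknown scheme mode {spec.mode!r}")


def conditioned_bundle(
    test: Sequence[ReactionRecord], x: int, topk: int
) -> metrics.PredictionBundle:
    """Fan out each test product over ``x`` tokens and merge the oracle
    retro model's per-token predictions rank-major."""
    samples = []
    for rec in test:
        per_token = {
            token: [".".join(p) for p in toychem.oracle_retro(source, topk)]
            for token, source in enumerate(prompting.fan_out(rec.product, x))
        }
        merged = prompting.merge_predictions(per_token, topk)
        samples.append(
            metrics.SamplePrediction(
                product=rec.product,
                target=rec.precursors,
                predictions=[tuple(p.split(".")) for p in merged.predictions],
            )
        )
    return metrics.PredictionBundle(samples=samples)


def baseline_bundle(
    test: Sequence[ReactionRecord], topn: int
) -> metrics.PredictionBundle:
    samples = [
        metrics.SamplePrediction(
            product=rec.product,
            target=rec.precursors,
            predictions=[tuple(p) for p in toychem.baseline_retro(rec.product, topn)],
        )
        for rec in test
    ]
    return metrics.PredictionBundle(samples=samples)


def _evaluate_bundle(
    bundle: metrics.PredictionBundle, k_range: Sequence[int]
) -> metrics.EvaluationReport:
    metrics.mark_validity(bundle, toychem.oracle_forward)
    metrics.mark_classes(bundle, toychem.oracle_classify)
    return metrics.evaluate(bundle, k_range)


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full protocol; returns reports and the comparison table.

    Output directory layout: ``config.yaml``, the cleaned toy corpus, one
    report JSON/CSV per model per seed, and ``comparison.csv`` with
    mean +/- standard error per model at each k.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(config.to_yaml())

    records = toychem.generate_dataset(config.toy)
    cleaned, report = clean_dataset(records)
    logger.info(
        "cleaning: %d in, %d out, removed per rule %s",
        report.n_input,
        report.n_output,
        report.counts_removed_per_rule,
    )
    write_reactions(cleaned, outdir / "cleaned.rxn", outdir / "cleaned.classes")
    (outdir / "cleaning_report.json").write_text(report.to_json() + "\n")

    frames: dict[str, list[pd.DataFrame]] = {}
    reports: dict[tuple[str, int], metrics.EvaluationReport] = {}
    for seed in config.seeds:
        split = split_dataset(cleaned, seed=seed, fractions=config.fractions)
        logger.info(
            "seed %d split: %d train / %d val / %d test",
            seed,
            len(split.train),
            len(split.validation),
            len(split.test),
        )
        model_bundles: dict[str, metrics.PredictionBundle] = {}
        topn_budget = max(s.x for s in config.schemes) * config.topk
        if config.k_max:
            topn_budget = config.k_max
        model_bundles["baseline"] = baseline_bundle(split.test, topn_budget)
        for spec in config.schemes:
            scheme = _fit_scheme(spec, split.train, seed)
            model_bundles[spec.name] = conditioned_bundle(
                split.test, scheme.x, config.topk
            )
            if spec.mode == "kmeans":
                clusters.save_scheme(scheme, outdir / f"scheme-{spec.name}-seed{seed}.json")
        k_range = list(range(1, topn_budget + 1))
        for name, bundle in model_bundles.items():
            rep = _evaluate_bundle(bundle, k_range)
            reports[(name, seed)] = rep
            rep.write(
                outdir / f"report-{name}-seed{seed}.json",
                outdir / f"report-{name}-seed{seed}.csv",
            )
            frames.setdefault(name, []).append(rep.to_frame())

    comparison = pd.concat(
        [metrics.summarize_across_seeds(fr, label=name) for name, fr in frames.items()],
        ignore_index=True,
    )
    comparison.to_csv(outdir / "comparison.csv", index=False)
    final_k = max(r.ks[-1] for r in reports.values())
    table = comparison[comparison["k"] == comparison.groupby("model")["k"].transform("max")]
    (outdir / "comparison_final.json").write_text(
        json.dumps(table.to_dict(orient="records"), indent=2) + "\n"
    )
    logger.info("final-k (%d) comparison:\n%s", final_k, table.to_string(index=False))
    return {"reports": reports, "comparison": comparison, "final_table": table}
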