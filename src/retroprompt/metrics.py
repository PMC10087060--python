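"""Evaluation metrics for single-step retrosynthesis prediction bundles.

For a test set of N target products x_i with target precursors y_i and
ranked predicted precursor sets x_{i,j}, four metrics are computed:

* top-n accuracy — fraction of samples whose canonical predicted precursor
  set equals the canonical target set at some rank <= n. Exact set
  equality over the full precursor set (reactants and reagents), so a
  correct disconnection with different reagents counts as a miss.
* round-trip accuracy RT_k = (1 / (N k)) sum_i sum_{j<=k} v_{i,j}, where
  the validity flag v_{i,j} is 1 iff a forward model applied to the
  prediction recovers the target product. Samples with fewer than k
  predictions contribute 0 for the missing ranks (fixed N*k denominator).
* class diversity CD_k = (1 / N) sum_i |set of predicted classes among the
  valid top-k predictions of sample i| — the average number of distinct
  reaction classes per target, counting only valid predictions. Classes
  come from a classifier applied to the predicted reaction, not from
  ground-truth labels.
* coverage CV_k = fraction of samples with at least one valid prediction
  in the top k.

All molecule/set equality is equality of canonical SMILES sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .data import canonicalize
from .errors import ConfigError, DataError


def canonical_set_key(precursors: Iterable[str]) -> frozenset[str] | None:
    """Canonical-set identity of a precursor set; None if any SMILES fails."""
    try:
        return frozenset(canonicalize(s) for s in precursors)
    except Exception:
        return None


@dataclass
class SamplePrediction:
    """One target with its ranked predictions and per-prediction annotations."""

    product: str
    target: tuple[str, ...]
    predictions: list[tuple[str, ...]]
    validity: list[int] | None = None
    classes: list[int | None] | None = None


@dataclass
class PredictionBundle:
    samples: list[SamplePrediction]

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def max_k(self) -> int:
        return max((len(s.predictions) for s in self.samples), default=0)

    def require_validity(self) -> None:
        if any(s.validity is None for s in self.samples):
            raise DataError("bundle has no validity flags; run mark_validity first")


def mark_validity(
    bundle: PredictionBundle, forward_model: Callable[[tuple[str, ...]], str]
) -> PredictionBundle:
    """Set v_{i,j} = 1 iff the forward model on prediction j recovers product i.

    Unparsable predictions, forward failures and no-reaction sentinels all
    yield validity 0 — never an exception.
    """
    for sample in bundle.samples:
        try:
            product_key = canonicalize(sample.product)
        except Exception:
            product_key = None
        flags = []
        for pred in sample.predictions:
            valid = 0
            if product_key is not None:
                try:
                    forward = forward_model(pred)
                    valid = int(canonicalize(forward) == product_key)
                except Exception:
                    valid = 0
            flags.append(valid)
        sample.validity = flags
    return bundle


def mark_classes(
    bundle: PredictionBundle,
    classifier: Callable[[tuple[str, ...], str], int],
) -> PredictionBundle:
    """Attach a predicted class to every prediction via the classifier model."""
    for sample in bundle.samples:
        sample.classes = []
        for pred in sample.predictions:
            try:
                sample.classes.append(classifier(pred, sample.product))
            except Exception:
                sample.classes.append(None)
    return bundle


def topn_accuracy(bundle: PredictionBundle, n: int) -> float:
    """Fraction of samples with the exact target precursor set in the top n."""
    if n < 1 or n > bundle.max_k:
        raise ConfigError(f"n={n} out of range 1-{bundle.max_k}")
    hits = 0
    for sample in bundle.samples:
        target_key = canonical_set_key(sample.target)
        for pred in sample.predictions[:n]:
            if canonical_set_key(pred) == target_key:
                hits += 1
                break
    return hits / bundle.n


def round_trip_accuracy(bundle: PredictionBundle, k: int) -> float:
    """RT_k with fixed N*k normalization; missing ranks count as invalid."""
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    bundle.require_validity()
    total = sum(sum(s.validity[:k]) for s in bundle.samples)
    return total / (bundle.n * k)


def class_diversity(bundle: PredictionBundle, k: int) -> float:
    """CD_k: mean number of distinct classes among valid top-k predictions."""
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    bundle.require_validity()
    total = 0
    for sample in bundle.samples:
        classes: set[int] = set()
        for j in range(min(k, len(sample.predictions))):
            if sample.validity[j]:
                if sample.classes is None or sample.classes[j] is None:
                    raise DataError(
                        f"valid prediction {j} of product {sample.product!r} has no class"
                    )
                classes.add(sample.classes[j])
        total += len(classes)
    return total / bundle.n


def coverage(bundle: PredictionBundle, k: int) -> float:
    """CV_k: fraction of samples with any valid prediction in the top k."""
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    bundle.require_validity()
    covered = sum(1 for s in bundle.samples if any(s.validity[:k]))
    return covered / bundle.n


@dataclass
class EvaluationReport:
    """All four metrics over a range of k, plus per-sample detail."""

    n: int
    ks: list[int]
    topn: dict[int, float] = field(default_factory=dict)
    round_trip: dict[int, float] = field(default_factory=dict)
    diversity: dict[int, float] = field(default_factory=dict)
    coverage: dict[int, float] = field(default_factory=dict)
    per_sample: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.ks,
                "topn_accuracy": [self.topn[k] for k in self.ks],
                "round_trip_accuracy": [self.round_trip[k] for k in self.ks],
                "class_diversity": [self.diversity[k] for k in self.ks],
                "coverage": [self.coverage[k] for k in self.ks],
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "metrics": self.to_frame().to_dict(orient="records"),
                "per_sample": self.per_sample,
            },
            indent=2,
        )

    def write(self, json_path: str | Path, csv_path: str | Path | None = None) -> None:
        Path(json_path).write_text(self.to_json() + "\n")
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)


def evaluate(bundle: PredictionBundle, k_range: Sequence[int]) -> EvaluationReport:
    """Compute all four metrics for every k in ``k_range``."""
    bundle.require_validity()
    ks = sorted(int(k) for k in k_range)
    report = EvaluationReport(n=bundle.n, ks=ks)
    for k in ks:
        report.topn[k] = topn_accuracy(bundle, min(k, bundle.max_k)) if bundle.max_k else 0.0
        report.round_trip[k] = round_trip_accuracy(bundle, k)
        report.diversity[k] = class_diversity(bundle, k)
        report.coverage[k] = coverage(bundle, k)
    for sample in bundle.samples:
        report.per_sample.append(
            {
                "product": sample.product,
                "n_predictions": len(sample.predictions),
                "n_valid": int(sum(sample.validity or [])),
                "classes": sorted(
                    {
                        c
                        for c, v in zip(sample.classes or [], sample.validity or [])
                        if v and c is not None
                    }
                ),
            }
        )
    return report


def summarize_across_seeds(
    frames: Sequence[pd.DataFrame], label: str = ""
) -> pd.DataFrame:
    """Mean and standard error of each metric across per-seed report frames."""
    stacked = pd.concat(frames, keys=range(len(frames)))
    grouped = stacked.groupby("k")
    mean = grouped.mean()
    sem = grouped.sem(ddof=1) if len(frames) > 1 else grouped.mean() * 0.0
    out = mean.add_suffix("_mean").join(sem.add_suffix("_se")).reset_index()
    if label:
        out.insert(0, "model", label)
    return out


# ---------------------------------------------------------------------------
# prediction file interchange


def write_prediction_table(bundle: PredictionBundle, path: str | Path) -> None:
    """Tabular prediction file: sample_id, rank, predicted precursors SMILES."""
    rows = []
    for i, sample in enumerate(bundle.samples):
        for rank, pred in enumerate(sample.predictions):
            rows.append(
                {
                    "sample_id": i,
                    "rank": rank,
                    "precursors": ".".join(pred),
                    "product": sample.product,
                    "target": ".".join(sample.target),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_prediction_table(path: str | Path) -> PredictionBundle:
    df = pd.read_csv(path, sep="\t")
    samples: dict[int, SamplePrediction] = {}
    for sid, group in df.groupby("sample_id"):
        group = group.sort_values("rank")
        first = group.iloc[0]
        samples[int(sid)] = SamplePrediction(
            product=str(first["product"]),
            target=tuple(str(first["target"]).split(".")),
            predictions=[tuple(str(p).split(".")) for p in group["precursors"]],
        )
    return PredictionBundle(samples=[samples[i] for i in sorted(samples)])
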