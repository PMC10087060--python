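"""Evaluation metrics against an independent brute-force re-computation.

The brute-force oracle below recomputes every metric with naive double
loops straight from the definitions, sharing no code with the package.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from retroprompt.errors import ConfigError, DataError
from retroprompt.metrics import (
    PredictionBundle,
    SamplePrediction,
    class_diversity,
    coverage,
    evaluate,
    mark_classes,
    mark_validity,
    read_prediction_table,
    round_trip_accuracy,
    summarize_across_seeds,
    topn_accuracy,
    write_prediction_table,
)

# small molecule vocabulary with alternate spellings of the same molecules
VOCAB = ["CCO", "OCC", "CC(=O)O", "OC(C)=O", "CCC", "C1CC1", "N", "CS", "SC"]


def _canon_set(precursors):
    return frozenset(Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in precursors)


# ---------------------------------------------------------------------------
# brute-force oracle (independent of the package implementation)


def bf_topn(samples, n):
    hits = 0
    for s in samples:
        hit = False
        for j in range(min(n, len(s.predictions))):
            if _canon_set(s.predictions[j]) == _canon_set(s.target):
                hit = True
        hits += hit
    return hits / len(samples)


def bf_rt(samples, k):
    total = 0
    for s in samples:
        for j in range(k):
            if j < len(s.predictions) and s.validity[j] == 1:
                total += 1
    return total / (len(samples) * k)


def bf_cd(samples, k):
    total = 0
    for s in samples:
        seen = []
        for j in range(min(k, len(s.predictions))):
            if s.validity[j] == 1 and s.classes[j] not in seen:
                seen.append(s.classes[j])
        total += len(seen)
    return total / len(samples)


def bf_cv(samples, k):
    covered = 0
    for s in samples:
        for j in range(min(k, len(s.predictions))):
            if s.validity[j] == 1:
                covered += 1
                break
    return covered / len(samples)


def random_bundle(rng, max_n=50, max_k=24):
    n = int(rng.integers(1, max_n + 1))
    samples = []
    for _ in range(n):
        target = tuple(rng.choice(VOCAB, size=int(rng.integers(1, 3)), replace=False))
        n_pred = int(rng.integers(1, max_k + 1))
        predictions, validity, classes = [], [], []
        for _ in range(n_pred):
            if rng.random() < 0.25:  # sometimes hit the target, re-spelled
                pred = tuple(
                    {"CCO": "OCC", "OCC": "CCO", "CC(=O)O": "OC(C)=O"}.get(s, s)
                    for s in target
                )
            else:
                pred = tuple(
                    rng.choice(VOCAB, size=int(rng.integers(1, 3)), replace=False)
                )
            predictions.append(pred)
            validity.append(int(rng.random() < 0.6))
            classes.append(int(rng.integers(0, 5)))
        samples.append(
            SamplePrediction(
                product="CCOCC",
                target=target,
                predictions=predictions,
                validity=validity,
                classes=classes,
            )
        )
    return PredictionBundle(samples=samples)


class TestAgainstBruteForce:
    def test_randomized_bundles_match_exactly(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            bundle = random_bundle(rng, max_n=20, max_k=12)
            k = int(rng.integers(1, 13))
            n = min(k, bundle.max_k)
            assert topn_accuracy(bundle, n) == bf_topn(bundle.samples, n)
            assert round_trip_accuracy(bundle, k) == bf_rt(bundle.samples, k)
            assert class_diversity(bundle, k) == bf_cd(bundle.samples, k)
            assert coverage(bundle, k) == bf_cv(bundle.samples, k)


class TestFormulaExamples:
    def _bundle(self, validity_rows, classes_rows=None):
        samples = []
        for i, row in enumerate(validity_rows):
            classes = classes_rows[i] if classes_rows else [0] * len(row)
            samples.append(
                SamplePrediction(
                    product="CCOCC",
                    target=("CCO", "BrCC"),
                    predictions=[("CCC",)] * len(row),
                    validity=list(row),
                    classes=list(classes),
                )
            )
        return PredictionBundle(samples=samples)

    def test_round_trip_two_samples(self):
        bundle = self._bundle([(1, 0), (1, 1)])
        assert round_trip_accuracy(bundle, 2) == pytest.approx(3 / 4)

    def test_all_valid_gives_one(self):
        bundle = self._bundle([(1, 1, 1)] * 3)
        assert round_trip_accuracy(bundle, 3) == 1.0

    def test_missing_ranks_padded_invalid(self):
        bundle = self._bundle([(1,)])
        assert round_trip_accuracy(bundle, 4) == pytest.approx(1 / 4)

    def test_five_distinct_classes_give_diversity_five(self):
        bundle = self._bundle([(1,) * 6], [[0, 1, 2, 3, 4, 0]])
        assert class_diversity(bundle, 6) == 5.0

    def test_valid_duplicates_collapse_to_one_class(self):
        bundle = self._bundle([(1,) * 20], [[3] * 20])
        assert class_diversity(bundle, 20) == 1.0

    def test_coverage_counts_any_valid(self):
        bundle = self._bundle([(0, 0), (1, 0)])
        assert coverage(bundle, 1) == pytest.approx(1 / 2)

    def test_ground_truth_at_rank_one_everywhere(self):
        samples = [
            SamplePrediction(
                product="CCOCC",
                target=("CCO", "BrCC"),
                predictions=[("BrCC", "OCC")],  # same set, re-spelled
                validity=[1],
                classes=[2],
            )
        ]
        assert topn_accuracy(PredictionBundle(samples=samples), 1) == 1.0

    def test_reagent_variant_counts_as_miss(self):
        samples = [
            SamplePrediction(
                product="CCOCC",
                target=("CCO", "BrCC", "N"),
                predictions=[("CCO", "BrCC", "CS")],  # different reagent
                validity=[1],
                classes=[2],
            )
        ]
        assert topn_accuracy(PredictionBundle(samples=samples), 1) == 0.0

    def test_valid_prediction_without_class_is_an_error(self):
        bundle = self._bundle([(1,)])
        bundle.samples[0].classes = [None]
        with pytest.raises(DataError):
            class_diversity(bundle, 1)

    def test_k_out_of_range_rejected(self):
        bundle = self._bundle([(1, 0)])
        with pytest.raises(ConfigError):
            round_trip_accuracy(bundle, 0)
        with pytest.raises(ConfigError):
            topn_accuracy(bundle, 3)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), k=st.integers(1, 10))
def test_bounds_and_monotonicity_properties(seed, k):
    """0 <= RT_k <= CV_k <= 1; CD_k <= min(k, #classes); CV/CD/top-n
    non-decreasing in k."""
    rng = np.random.default_rng(seed)
    bundle = random_bundle(rng, max_n=12, max_k=10)
    rt = round_trip_accuracy(bundle, k)
    cv = coverage(bundle, k)
    cd = class_diversity(bundle, k)
    n_classes = len(
        {c for s in bundle.samples for c in s.classes if c is not None}
    )
    assert 0.0 <= rt <= cv <= 1.0
    assert 0.0 <= cd <= min(k, n_classes) + 1e-12
    if k > 1:
        assert coverage(bundle, k) >= coverage(bundle, k - 1)
        assert class_diversity(bundle, k) >= class_diversity(bundle, k - 1)
        n = min(k, bundle.max_k)
        if n > 1:
            assert topn_accuracy(bundle, n) >= topn_accuracy(bundle, n - 1)


class TestMarking:
    def test_forward_recovery_sets_validity(self):
        from retroprompt.toychem import oracle_classify, oracle_forward

        samples = [
            SamplePrediction(
                product="CC(=O)OCC",
                target=("CC(=O)O", "OCC"),
                predictions=[("CC(=O)O", "OCC"), ("CC(=O)OCC",), ("garbage((",)],
            )
        ]
        bundle = mark_validity(PredictionBundle(samples=samples), oracle_forward)
        assert bundle.samples[0].validity == [1, 0, 0]
        mark_classes(bundle, oracle_classify)
        assert bundle.samples[0].classes[0] == 0


class TestReportAndIO:
    def test_evaluate_composes_individual_metrics(self):
        rng = np.random.default_rng(5)
        bundle = random_bundle(rng, max_n=15, max_k=8)
        report = evaluate(bundle, range(1, 9))
        for k in range(1, 9):
            assert report.round_trip[k] == round_trip_accuracy(bundle, k)
            assert report.coverage[k] == coverage(bundle, k)
            assert report.diversity[k] == class_diversity(bundle, k)
        assert report.n == bundle.n
        frame = report.to_frame()
        assert list(frame["k"]) == list(range(1, 9))

    def test_empty_k_range_gives_empty_report(self):
        rng = np.random.default_rng(6)
        report = evaluate(random_bundle(rng, max_n=3, max_k=3), [])
        assert report.ks == [] and report.to_frame().empty

    def test_prediction_table_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        bundle = random_bundle(rng, max_n=5, max_k=4)
        path = tmp_path / "preds.tsv"
        write_prediction_table(bundle, path)
        loaded = read_prediction_table(path)
        assert loaded.n == bundle.n
        for a, b in zip(loaded.samples, bundle.samples):
            assert a.predictions == b.predictions
            assert a.target == b.target

    def test_seed_summary_has_mean_and_se(self):
        rng = np.random.default_rng(8)
        frames = []
        for _ in range(3):
            bundle = random_bundle(rng, max_n=10, max_k=6)
            frames.append(evaluate(bundle, range(1, 7)).to_frame())
        summary = summarize_across_seeds(frames, label="model-a")
        assert {"round_trip_accuracy_mean", "round_trip_accuracy_se"} <= set(
            summary.columns
        )
        assert (summary["model"] == "model-a").all()
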