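"""Derivation of integer prompt tokens for reactions.

Three token-derivation modes are supported, mirroring the usual model
roster for cluster-token prompting:

* ``superclass`` — the leading digit of the reaction-class code (the
  NameRXN-style superclass, 0-11) is the token;
* ``random-group`` — the 12 superclasses are partitioned at random into
  ``n_groups`` balanced groups and the group id is the token;
* ``kmeans`` — reaction fingerprints are projected with PCA and clustered
  with K-means; the cluster id is the token.

Fingerprints come from a pluggable provider. The default provider is a
deterministic structural difference fingerprint: hashed circular
(Morgan) substructure counts of the product minus the summed counts of the
precursors. A learned reaction fingerprint can be registered under another
name and used identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .data import ReactionRecord
from .errors import ConfigError, DimensionalityError, InvalidMoleculeError, LabelError

N_SUPERCLASSES = 12

SUPERCLASS_NAMES: dict[int, str] = {
    0: "unrecognized",
    1: "heteroatom alkylation and arylation",
    2: "acylation and related processes",
    3: "C-C bond formation",
    4: "heterocycle formation",
    5: "protections",
    6: "deprotections",
    7: "reductions",
    8: "oxidations",
    9: "functional group interconversion (FGI)",
    10: "functional group addition (FGA)",
    11: "resolutions",
}


def superclass_token(class_code: str) -> int:
    """Leading integer of a dotted class code; must lie in 0-11."""
    head = class_code.split(".", 1)[0].strip()
    if not head.isdigit():
        raise LabelError(f"non-numeric superclass in class code {class_code!r}")
    value = int(head)
    if value >= N_SUPERCLASSES:
        raise LabelError(f"superclass {value} out of range 0-{N_SUPERCLASSES - 1}")
    return value


def random_grouping(n_groups: int, seed: int) -> dict[int, int]:
    """Random balanced partition of the 12 superclasses into ``n_groups``.

    Surjective onto ``range(n_groups)``; group sizes differ by at most one;
    deterministic given ``seed``.
    """
    if not 1 <= n_groups <= N_SUPERCLASSES:
        raise ConfigError(f"n_groups must be in 1-{N_SUPERCLASSES}, got {n_groups}")
    order = np.random.default_rng(seed).permutation(N_SUPERCLASSES)
    return {int(cls): i % n_groups for i, cls in enumerate(order)}


# ---------------------------------------------------------------------------
# fingerprints

FingerprintFn = Callable[[ReactionRecord], np.ndarray]

DEFAULT_FP_BITS = 256
DEFAULT_FP_RADIUS = 2


@dataclass
class FingerprintMatrix:
    values: np.ndarray  # (n_reactions, d), rows aligned with record order
    provider: str


def _hashed_counts(smiles: str, n_bits: int, radius: int) -> np.ndarray:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetCountFingerprint(mol)
    vec = np.zeros(n_bits, dtype=float)
    for idx, count in fp.GetNonzeroElements().items():
        vec[idx] = count
    return vec


def structural_difference_fingerprint(
    record: ReactionRecord,
    n_bits: int = DEFAULT_FP_BITS,
    radius: int = DEFAULT_FP_RADIUS,
) -> np.ndarray:
    """Product substructure counts minus summed precursor counts.

    Permutation of the precursors leaves the row unchanged (set semantics);
    the hashing is the toolkit's fixed Morgan hash, so rows are fully
    deterministic.
    """
    vec = _hashed_counts(record.product, n_bits, radius)
    for prec in set(record.precursors):
        vec -= _hashed_counts(prec, n_bits, radius)
    return vec


FINGERPRINT_PROVIDERS: dict[str, FingerprintFn] = {
    "structural-diff": structural_difference_fingerprint,
}


def register_fingerprint_provider(name: str, fn: FingerprintFn) -> None:
    FINGERPRINT_PROVIDERS[name] = fn


def compute_fingerprints(
    records: Sequence[ReactionRecord], provider: str = "structural-diff"
) -> FingerprintMatrix:
    """One fingerprint row per record, aligned with record order."""
    try:
        fn = FINGERPRINT_PROVIDERS[provider]
    except KeyError:
        raise ConfigError(
            f"unknown fingerprint provider {provider!r}; "
            f"registered: {sorted(FINGERPRINT_PROVIDERS)}"
        ) from None
    return FingerprintMatrix(
        values=np.array([fn(r) for r in records], dtype=float), provider=provider
    )


# ---------------------------------------------------------------------------
# projection + clustering


@dataclass
class ProjectionModel:
    """Mean-centered PCA projection onto the top-p components."""

    components: np.ndarray  # (p, d)
    mean: np.ndarray  # (d,)
    explained_variance_ratio: np.ndarray  # (p,)
    p: int

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) @ self.components.T

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) @ self.components + self.mean


def fit_projection(fps: FingerprintMatrix | np.ndarray, p: int) -> ProjectionModel:
    """Fit mean-centered PCA and keep the top ``p`` components by variance."""
    x = fps.values if isinstance(fps, FingerprintMatrix) else np.asarray(fps, dtype=float)
    n, d = x.shape
    if p > min(n, d):
        raise DimensionalityError(f"p={p} exceeds min(n, d)={min(n, d)}")
    pca = PCA(n_components=p, svd_solver="full")
    pca.fit(x)
    return ProjectionModel(
        components=pca.components_,
        mean=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        p=p,
    )


@dataclass
class ClusterModel:
    """Fitted K-means model: centroids, training inertia and labels."""

    centroids: np.ndarray  # (k, p)
    inertia: float
    seed: int
    labels: np.ndarray  # training assignments

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def predict(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((points[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


KMEANS_RESTARTS = 10
KMEANS_MAX_ITER = 300
KMEANS_TOL = 1e-6


def fit_kmeans(
    points: np.ndarray,
    k: int,
    seed: int,
    restarts: int = KMEANS_RESTARTS,
) -> ClusterModel:
    """Best-of-``restarts`` K-means by inertia, deterministic given ``seed``."""
    points = np.asarray(points, dtype=float)
    if k > len(points):
        raise ConfigError(f"k={k} exceeds the number of points ({len(points)})")
    km = KMeans(
        n_clusters=k,
        n_init=restarts,
        random_state=seed,
        max_iter=KMEANS_MAX_ITER,
        tol=KMEANS_TOL,
        algorithm="lloyd",
    ).fit(points)
    return ClusterModel(
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
        labels=km.labels_,
    )


@dataclass
class InertiaCurve:
    """Inertia as a function of k, with the discrete-second-difference elbow."""

    ks: list[int]
    inertias: list[float]
    k_opt: int
    elbow_strength: float  # max second difference / total inertia drop

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"k": self.ks, "inertia": self.inertias}).to_csv(path, index=False)


def elbow_select(
    points: np.ndarray,
    k_range: Sequence[int],
    seed: int,
    restarts: int = KMEANS_RESTARTS,
) -> tuple[InertiaCurve, int]:
    """Inertia curve over ``k_range`` and an automatic elbow choice.

    The elbow is the interior k maximizing the discrete second difference
    of the inertia curve (the point where the decrease slackens most); an
    elbow-strength score (second difference over total drop) accompanies
    the choice, and the full curve is returned for visual confirmation.
    """
    ks = sorted(int(k) for k in k_range)
    if len(ks) < 3:
        raise ConfigError("k_range must contain at least 3 values to locate an elbow")
    points = np.asarray(points, dtype=float)
    inertias: list[float] = []
    prev: ClusterModel | None = None
    for k in ks:
        model = fit_kmeans(points, k, seed, restarts)
        if prev is not None and model.inertia > prev.inertia and k == prev.k + 1:
            # adding a centroid can never raise the optimal inertia; warm-start
            # from the previous solution plus its worst-fit point
            d2 = ((points[:, None, :] - prev.centroids[None, :, :]) ** 2).sum(axis=2)
            extra = points[int(d2.min(axis=1).argmax())]
            init = np.vstack([prev.centroids, extra[None, :]])
            km = KMeans(
                n_clusters=k, init=init, n_init=1, max_iter=KMEANS_MAX_ITER, tol=KMEANS_TOL
            ).fit(points)
            if km.inertia_ < model.inertia:
                model = ClusterModel(
                    centroids=km.cluster_centers_,
                    inertia=float(km.inertia_),
                    seed=seed,
                    labels=km.labels_,
                )
        inertias.append(model.inertia)
        prev = model
    second_diff = [
        inertias[i - 1] - 2.0 * inertias[i] + inertias[i + 1] for i in range(1, len(ks) - 1)
    ]
    best = int(np.argmax(second_diff))
    total_drop = inertias[0] - inertias[-1]
    strength = float(second_diff[best] / total_drop) if total_drop > 0 else 0.0
    k_opt = ks[best + 1]
    curve = InertiaCurve(ks=ks, inertias=inertias, k_opt=k_opt, elbow_strength=strength)
    return curve, k_opt


# ---------------------------------------------------------------------------
# cluster schemes

SCHEME_FORMAT_VERSION = 1


@dataclass
class ClusterScheme:
    """Mapping from reactions to integer prompt tokens in ``[0, X)``."""

    mode: str  # "superclass" | "random-group" | "kmeans"
    x: int
    class_to_group: dict[int, int] | None = None
    projection: ProjectionModel | None = None
    kmeans: ClusterModel | None = None
    provider: str = "structural-diff"
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def token_for(self, record: ReactionRecord, fingerprint: np.ndarray | None = None) -> int:
        if self.mode == "superclass":
            if record.class_code is None:
                raise LabelError(f"record {record.id} has no class code")
            return superclass_token(record.class_code)
        if self.mode == "random-group":
            if record.class_code is None:
                raise LabelError(f"record {record.id} has no class code")
            assert self.class_to_group is not None
            return self.class_to_group[superclass_token(record.class_code)]
        if self.mode == "kmeans":
            assert self.projection is not None and self.kmeans is not None
            if fingerprint is None:
                fingerprint = FINGERPRINT_PROVIDERS[self.provider](record)
            z = self.projection.transform(np.atleast_2d(fingerprint))
            return int(self.kmeans.predict(z)[0])
        raise ConfigError(f"unknown scheme mode {self.mode!r}")


def superclass_scheme() -> ClusterScheme:
    return ClusterScheme(mode="superclass", x=N_SUPERCLASSES)


def random_group_scheme(n_groups: int, seed: int) -> ClusterScheme:
    return ClusterScheme(
        mode="random-group",
        x=n_groups,
        class_to_group=random_grouping(n_groups, seed),
        seed=seed,
    )


def kmeans_scheme(
    records: Sequence[ReactionRecord],
    k: int,
    p: int,
    seed: int,
    provider: str = "structural-diff",
    restarts: int = KMEANS_RESTARTS,
) -> ClusterScheme:
    """Fit the fingerprint -> PCA -> K-means token scheme on ``records``."""
    fps = compute_fingerprints(records, provider)
    projection = fit_projection(fps, p)
    model = fit_kmeans(projection.transform(fps.values), k, seed, restarts)
    return ClusterScheme(
        mode="kmeans",
        x=k,
        projection=projection,
        kmeans=model,
        provider=provider,
        seed=seed,
    )


def assign_tokens(
    records: Sequence[ReactionRecord],
    scheme: ClusterScheme,
    fps: FingerprintMatrix | None = None,
) -> list[ReactionRecord]:
    """Return copies of ``records`` with the prompt token filled in.

    For class-based modes, records missing a class code are reported
    together in one error. For kmeans mode, fingerprints are computed with
    the scheme's provider unless ``fps`` is given.
    """
    if scheme.mode in ("superclass", "random-group"):
        missing = [r.id for r in records if r.class_code is None]
        if missing:
            raise LabelError(f"records missing class codes: {missing}")
        return [replace(r, token=scheme.token_for(r)) for r in records]
    if fps is None:
        fps = compute_fingerprints(records, scheme.provider)
    return [
        replace(r, token=scheme.token_for(r, fingerprint=row))
        for r, row in zip(records, fps.values)
    ]


def write_token_file(records: Iterable[ReactionRecord], path: str | Path) -> None:
    Path(path).write_text("".join(f"{r.token}\n" for r in records))


def save_scheme(scheme: ClusterScheme, path: str | Path) -> None:
    """Serialize a scheme (centroids, components, metadata) to one JSON file."""
    payload: dict = {
        "format_version": SCHEME_FORMAT_VERSION,
        "mode": scheme.mode,
        "x": scheme.x,
        "provider": scheme.provider,
        "seed": scheme.seed,
        "metadata": scheme.metadata,
    }
    if scheme.class_to_group is not None:
        payload["class_to_group"] = {str(k): v for k, v in scheme.class_to_group.items()}
    if scheme.projection is not None:
        payload["projection"] = {
            "components": scheme.projection.components.tolist(),
            "mean": scheme.projection.mean.tolist(),
            "explained_variance_ratio": scheme.projection.explained_variance_ratio.tolist(),
            "p": scheme.projection.p,
        }
    if scheme.kmeans is not None:
        payload["kmeans"] = {
            "centroids": scheme.kmeans.centroids.tolist(),
            "inertia": scheme.kmeans.inertia,
            "seed": scheme.kmeans.seed,
        }
    Path(path).write_text(json.dumps(payload))


def load_scheme(path: str | Path) -> ClusterScheme:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != SCHEME_FORMAT_VERSION:
        raise ConfigError(f"unsupported scheme format version in {path}")
    projection = None
    if "projection" in payload:
        pr = payload["projection"]
        projection = ProjectionModel(
            components=np.array(pr["components"], dtype=float),
            mean=np.array(pr["mean"], dtype=float),
            explained_variance_ratio=np.array(pr["explained_variance_ratio"], dtype=float),
            p=int(pr["p"]),
        )
    kmeans = None
    if "kmeans" in payload:
        km = payload["kmeans"]
        kmeans = ClusterModel(
            centroids=np.array(km["centroids"], dtype=float),
            inertia=float(km["inertia"]),
            seed=int(km["seed"]),
            labels=np.array([], dtype=int),
        )
    class_to_group = None
    if "class_to_group" in payload:
        class_to_group = {int(k): int(v) for k, v in payload["class_to_group"].items()}
    return ClusterScheme(
        mode=payload["mode"],
        x=int(payload["x"]),
        class_to_group=class_to_group,
        projection=projection,
        kmeans=kmeans,
        provider=payload.get("provider", "structural-diff"),
        seed=int(payload.get("seed", 0)),
        metadata=payload.get("metadata", {}),
    )
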