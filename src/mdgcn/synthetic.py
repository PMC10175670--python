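"""Synthetic inputs with planted, recoverable structure.

Three generators emulate the shapes and statistics of curated
miRNA-disease data without any download:

* a rooted random ontology whose leaves are the disease terms, so the
  semantic-similarity stage has non-trivial shared-ancestor structure;
* a binary association matrix with a planted low-rank model: latent
  factors ``U`` (miRNAs) and ``V`` (diseases) are sampled from a unit
  normal and the top ``density * n_m * n_d`` cells of ``U @ V.T``
  become the positives — deterministic given the seed, so fold-level
  tests are stable;
* a miRNA functional-similarity matrix derived from the planted ``U``
  (cosine similarity plus bounded uniform noise, partially masked), so
  the "FM exists" fallback path is exercised.

The ``benchmark_shape`` preset matches the scale of the HMDD v2.0 benchmark
snapshot (495 miRNAs x 383 diseases, 5430 positives, ~97.14% sparse);
the ``demo`` preset (200 x 150, rank 5, density 0.03) is sized for
minutes-scale end-to-end runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .ontology import DiseaseOntology
from .types import AssociationMatrix, SimilarityMatrix

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "SyntheticDataset",
    "generate_ontology",
    "generate_associations",
    "generate_functional_similarity",
    "generate_dataset",
]

# exact HMDD v2.0 benchmark density: 5430 positives in a 495 x 383 matrix
_BENCHMARK_DENSITY = 5430 / (495 * 383)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic world; defaults mirror the benchmark scale."""

    n_m: int = 495
    n_d: int = 383
    latent_rank: int = 5
    density: float = _BENCHMARK_DENSITY
    ontology_depth: int = 5
    branching: int = 4
    extra_edge_fraction: float = 0.1
    fm_noise: float = 0.1
    fm_missing: float = 0.1
    nonnegative_factors: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.density < 0.5:
            raise ValueError("density must be in (0, 0.5)")
        if self.latent_rank > min(self.n_m, self.n_d):
            raise ValueError("latent_rank cannot exceed min(n_m, n_d)")
        if self.branching**self.ontology_depth < self.n_d:
            raise ValueError(
                f"ontology with branching {self.branching} and depth "
                f"{self.ontology_depth} has fewer leaves than {self.n_d} diseases"
            )

    @staticmethod
    def benchmark_shape(seed: int = 0) -> "SyntheticSpec":
        return SyntheticSpec(seed=seed)

    @staticmethod
    def demo(seed: int = 0) -> "SyntheticSpec":
        """Small recoverable-signal preset for minutes-scale runs."""
        return SyntheticSpec(
            n_m=200, n_d=150, latent_rank=5, density=0.03,
            ontology_depth=5, branching=3, seed=seed,
        )

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlantedTruth:
    """Ground truth of the planted low-rank association model."""

    u: np.ndarray
    v: np.ndarray
    threshold: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "threshold": self.threshold,
                "u": self.u.tolist(),
                "v": self.v.tolist(),
            }
        )


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    assoc: AssociationMatrix
    ontology: DiseaseOntology
    fm: SimilarityMatrix
    truth: PlantedTruth


def _disease_ids(n_d: int) -> list[str]:
    return [f"D{i:04d}" for i in range(n_d)]


def _mirna_ids(n_m: int) -> list[str]:
    return [f"M{i:04d}" for i in range(n_m)]


def generate_ontology(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> DiseaseOntology:
    """Rooted random DAG whose leaves include every disease id.

    A complete ``branching``-ary tree of the given depth is built, the
    leaves are shuffled, and the first ``n_d`` of them are renamed to the
    disease ids. A fraction of non-root terms then gains one extra parent
    from a strictly shallower level, which keeps the graph acyclic while
    making ancestor DAGs genuinely DAG-shaped.
    """
    rng = rng or np.random.default_rng(spec.seed)
    levels: list[list[str]] = [["ROOT"]]
    edges: list[tuple[str, str]] = []
    counter = 0
    for depth in range(1, spec.ontology_depth + 1):
        level = []
        for parent in levels[-1]:
            for _ in range(spec.branching):
                name = f"T{depth}_{counter}"
                counter += 1
                edges.append((name, parent))
                level.append(name)
        levels.append(level)
    leaves = list(levels[-1])
    order = rng.permutation(len(leaves))
    rename = {leaves[order[i]]: d for i, d in enumerate(_disease_ids(spec.n_d))}
    edges = [(rename.get(c, c), rename.get(p, p)) for c, p in edges]
    # extra cross edges: child at level L -> extra parent at level < L - 1
    level_of = {t: d for d, lvl in enumerate(levels) for t in lvl}
    non_root = [t for t in level_of if level_of[t] >= 2]
    n_extra = int(spec.extra_edge_fraction * len(non_root))
    for t in rng.choice(non_root, size=n_extra, replace=False):
        shallow = [u for u in level_of if level_of[u] < level_of[t] - 1]
        extra_parent = shallow[int(rng.integers(len(shallow)))]
        edges.append((rename.get(t, t), rename.get(extra_parent, extra_parent)))
    return DiseaseOntology(edges, disease_terms=_disease_ids(spec.n_d))


def generate_associations(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[AssociationMatrix, PlantedTruth]:
    """Planted low-rank binary association matrix.

    The top ``floor(density * n_m * n_d)`` cells of ``U @ V.T`` are set
    to 1 (ties broken by cell order); the factors and the threshold are
    returned for recovery tests.
    """
    rng = rng or np.random.default_rng(spec.seed)
    u = rng.standard_normal((spec.n_m, spec.latent_rank))
    v = rng.standard_normal((spec.n_d, spec.latent_rank))
    if spec.nonnegative_factors:
        u, v = np.abs(u), np.abs(v)
    scores = u @ v.T
    q = int(np.floor(spec.density * spec.n_m * spec.n_d))
    flat = scores.ravel()
    top = np.argpartition(flat, -q)[-q:]
    values = np.zeros(spec.n_m * spec.n_d, dtype=np.int8)
    values[top] = 1
    threshold = float(flat[top].min())
    assoc = AssociationMatrix(
        mirna_ids=_mirna_ids(spec.n_m),
        disease_ids=_disease_ids(spec.n_d),
        values=values.reshape(spec.n_m, spec.n_d),
    )
    return assoc, PlantedTruth(u=u, v=v, threshold=threshold, seed=spec.seed)


def generate_functional_similarity(
    truth: PlantedTruth,
    fm_noise: float = 0.1,
    missing_fraction: float = 0.1,
    rng: np.random.Generator | None = None,
) -> SimilarityMatrix:
    """Noisy cosine similarity of the planted miRNA factors.

    Symmetric, diagonal exactly 1, clipped to [0, 1]; a fraction of
    off-diagonal pairs is marked missing (symmetrically), exercising the
    Gaussian-kernel fallback during integration.
    """
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError("missing_fraction must be in [0, 1)")
    rng = rng or np.random.default_rng(truth.seed + 1)
    u = truth.u
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    un = u / norms
    fm = un @ un.T
    n = fm.shape[0]
    noise = rng.uniform(-fm_noise, fm_noise, size=(n, n))
    fm = fm + 0.5 * (noise + noise.T)
    fm = np.clip(fm, 0.0, 1.0)
    fm = 0.5 * (fm + fm.T)
    np.fill_diagonal(fm, 1.0)
    defined = np.ones((n, n), dtype=bool)
    iu = np.triu_indices(n, k=1)
    n_off = len(iu[0])
    n_missing = int(round(missing_fraction * n_off))
    if n_missing:
        drop = rng.choice(n_off, size=n_missing, replace=False)
        defined[iu[0][drop], iu[1][drop]] = False
        defined[iu[1][drop], iu[0][drop]] = False
    return SimilarityMatrix(
        ids=_mirna_ids(n), values=fm, defined=defined
    )


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """All three inputs from one seed (independent sub-streams)."""
    root = np.random.SeedSequence(spec.seed)
    s_onto, s_assoc, s_fm = root.spawn(3)
    assoc, truth = generate_associations(spec, np.random.default_rng(s_assoc))
    ontology = generate_ontology(spec, np.random.default_rng(s_onto))
    fm = generate_functional_similarity(
        truth, spec.fm_noise, spec.fm_missing, np.random.default_rng(s_fm)
    )
    return SyntheticDataset(spec=spec, assoc=assoc, ontology=ontology, fm=fm, truth=truth)
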