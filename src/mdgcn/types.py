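"""Core in-memory containers shared across the pipeline.

The two workhorse containers are :class:`AssociationMatrix` (the binary
miRNA x disease incidence matrix with stable, sorted identifiers) and
:class:`SimilarityMatrix` (a square symmetric similarity over one node
class, with an optional per-entry "defined" mask used by the similarity
integration rules).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "FoldReport",
]


def _check_unique(ids, what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    if not ids:
        raise ValueError(f"empty {what} identifier list")
    return ids


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease association matrix.

    Rows are miRNAs, columns are diseases; ``values[i, j] == 1`` means
    miRNA ``mirna_ids[i]`` is associated with disease ``disease_ids[j]``.
    """

    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.mirna_ids = _check_unique(self.mirna_ids, "miRNA")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError(
                f"association matrix shape {self.values.shape} does not match "
                f"{len(self.mirna_ids)} miRNAs x {len(self.disease_ids)} diseases"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def n_m(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_d(self) -> int:
        return len(self.disease_ids)

    @property
    def n_positive(self) -> int:
        return int(self.values.sum())

    def mirna_index(self, mirna_id: str) -> int:
        try:
            return self._m_index[mirna_id]
        except AttributeError:
            self._m_index = {m: i for i, m in enumerate(self.mirna_ids)}
            return self._m_index[mirna_id]
        except KeyError:
            raise KeyError(f"unknown miRNA id: {mirna_id!r}") from None

    def disease_index(self, disease_id: str) -> int:
        try:
            return self._d_index[disease_id]
        except AttributeError:
            self._d_index = {d: i for i, d in enumerate(self.disease_ids)}
            return self._d_index[disease_id]
        except KeyError:
            raise KeyError(f"unknown disease id: {disease_id!r}") from None

    def positive_pairs(self) -> np.ndarray:
        """All (miRNA index, disease index) pairs with a known association."""
        rows, cols = np.nonzero(self.values)
        return np.column_stack([rows, cols]).astype(np.int64)

    def mask_positives(self, pairs: np.ndarray) -> "AssociationMatrix":
        """Copy with the given positive (m, d) index pairs zeroed out.

        Used to hide test-fold edges from everything derived from the
        training matrix (interaction profiles, features, the graph).
        """
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        values = self.values.copy()
        if pairs.size and not values[pairs[:, 0], pairs[:, 1]].all():
            raise ValueError("mask_positives given a pair that is not a positive")
        values[pairs[:, 0], pairs[:, 1]] = 0
        return AssociationMatrix(self.mirna_ids, self.disease_ids, values)

    def sparsity(self) -> float:
        """Fraction of zero cells, in percent (e.g. 97.14)."""
        total = self.n_m * self.n_d
        return 100.0 * (total - self.n_positive) / total


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity over one node class.

    ``defined`` marks entries that actually exist (e.g. supplied
    functional-similarity pairs, or disease pairs whose semantic
    similarity is computable); undefined entries trigger the Gaussian
    kernel fallback during integration. ``provenance`` is set by the
    integration step: 1 where the averaged branch fired, 0 where the
    kernel fallback was used.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    defined: np.ndarray | None = None
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = _check_unique(self.ids, "node")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            i, j = np.unravel_index(
                np.argmax(np.abs(self.values - self.values.T)), self.values.shape
            )
            raise ValueError(
                f"similarity matrix is asymmetric, worst pair ({self.ids[i]}, {self.ids[j]})"
            )
        if self.defined is None:
            self.defined = np.ones((n, n), dtype=bool)
        else:
            self.defined = np.asarray(self.defined, dtype=bool)
            if self.defined.shape != (n, n):
                raise ValueError("defined mask shape mismatch")

    @property
    def n(self) -> int:
        return len(self.ids)

    def reindex(self, ids) -> "SimilarityMatrix":
        """Align to a new id order; pairs involving absent ids become missing.

        External similarity matrices (e.g. a supplied functional
        similarity) need not cover exactly the nodes of the association
        matrix; absent pairs fall back to the kernel during integration.
        """
        ids = tuple(str(i) for i in ids)
        old = {x: i for i, x in enumerate(self.ids)}
        n = len(ids)
        values = np.zeros((n, n))
        defined = np.zeros((n, n), dtype=bool)
        present = [(j, old[x]) for j, x in enumerate(ids) if x in old]
        if present:
            new_idx, old_idx = map(np.array, zip(*present))
            values[np.ix_(new_idx, new_idx)] = self.values[np.ix_(old_idx, old_idx)]
            defined[np.ix_(new_idx, new_idx)] = self.defined[np.ix_(old_idx, old_idx)]
        return SimilarityMatrix(ids=ids, values=values, defined=defined)


@dataclass
class FoldReport:
    """Metric bundle for one cross-validation fold."""

    auc: float
    aupr: float
    mcc: float
    f1: float
    precision: float
    recall: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "mcc": self.mcc,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
        }
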