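"""Readers and writers for all on-disk formats.

All formats are plain TSV/JSON/YAML:

* association edge list: ``mirna_id<TAB>disease_id`` (header optional);
* ontology: ``child<TAB>parent`` term-id pairs;
* square similarity matrix: id header row and index column, numeric
  cells; empty or ``NA`` cells mark missing (undefined) entries;
* predictions: ``mirna_id<TAB>disease_id<TAB>score`` sorted descending.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ontology import DiseaseOntology
from .types import AssociationMatrix, SimilarityMatrix

__all__ = [
    "read_associations",
    "write_associations",
    "read_ontology",
    "write_ontology",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_predictions",
    "read_config",
    "write_config",
]

logger = logging.getLogger(__name__)

_HEADER_TOKENS = {"mirna", "mirna_id", "disease", "disease_id", "child", "parent",
                  "term", "term_id", "source", "target"}


def _read_edge_rows(path, what: str) -> list[tuple[str, str]]:
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: malformed {what} row: {line!r}")
            if lineno == 1 and parts[0].strip().lower() in _HEADER_TOKENS:
                continue  # optional header
            rows.append((parts[0].strip(), parts[1].strip()))
    if not rows:
        raise ValueError(f"{path}: empty {what} file")
    return rows


def read_associations(path) -> AssociationMatrix:
    """Edge-list TSV -> association matrix with sorted, stable id order."""
    rows = _read_edge_rows(path, "association")
    unique = set(rows)
    if len(unique) != len(rows):
        logger.warning(
            "%s: %d duplicate association edge(s) collapsed", path, len(rows) - len(unique)
        )
    mirnas = tuple(sorted({m for m, _ in unique}))
    diseases = tuple(sorted({d for _, d in unique}))
    m_idx = {m: i for i, m in enumerate(mirnas)}
    d_idx = {d: j for j, d in enumerate(diseases)}
    values = np.zeros((len(mirnas), len(diseases)), dtype=np.int8)
    for m, d in unique:
        values[m_idx[m], d_idx[d]] = 1
    return AssociationMatrix(mirna_ids=mirnas, disease_ids=diseases, values=values)


def write_associations(a: AssociationMatrix, path) -> None:
    pairs = a.positive_pairs()
    with open(path, "w") as fh:
        fh.write("mirna\tdisease\n")
        for i, j in pairs:
            fh.write(f"{a.mirna_ids[i]}\t{a.disease_ids[j]}\n")


def read_ontology(path, disease_map_path=None) -> DiseaseOntology:
    """Parent-edge TSV -> ontology; optional disease->term mapping TSV.

    Without a mapping file, disease ids are assumed to be ontology term
    ids themselves (identity mapping).
    """
    edges = _read_edge_rows(path, "ontology")
    disease_terms = None
    if disease_map_path is not None:
        mapping = _read_edge_rows(disease_map_path, "disease-map")
        disease_terms = [t for _, t in mapping]
    return DiseaseOntology(edges, disease_terms=disease_terms)


def write_ontology(onto: DiseaseOntology, path) -> None:
    with open(path, "w") as fh:
        fh.write("child\tparent\n")
        for child, parent in sorted(onto._graph.edges):
            fh.write(f"{child}\t{parent}\n")


def read_matrix_tsv(path) -> SimilarityMatrix:
    """Square similarity TSV with id header/index; empty or NA = missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    ids = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != ids:
        raise ValueError(f"{path}: row and column ids differ (matrix must be square)")
    raw = df.to_numpy(dtype=object)
    n = len(ids)
    values = np.zeros((n, n))
    defined = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            cell = str(raw[i, j]).strip()
            if cell == "" or cell.upper() == "NA":
                defined[i, j] = False
            else:
                values[i, j] = float(cell)  # raises on garbage
    if np.isnan(values).any():
        raise ValueError(f"{path}: NaN cell in similarity matrix")
    if (defined != defined.T).any():
        raise ValueError(f"{path}: missing-entry mask is not symmetric")
    both = defined & defined.T
    delta = np.abs(np.where(both, values - values.T, 0.0))
    if delta.max() > 1e-9:
        i, j = np.unravel_index(np.argmax(delta), delta.shape)
        raise ValueError(
            f"{path}: asymmetric beyond 1e-9, worst pair ({ids[i]}, {ids[j]})"
        )
    return SimilarityMatrix(ids=ids, values=0.5 * (values + values.T), defined=defined)


def write_matrix_tsv(sim: SimilarityMatrix, path, fmt: str = "%.12g") -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(sim.ids) + "\n")
        for i, row_id in enumerate(sim.ids):
            cells = [
                (fmt % sim.values[i, j]) if sim.defined[i, j] else ""
                for j in range(sim.n)
            ]
            fh.write(row_id + "\t" + "\t".join(cells) + "\n")


def write_provenance_tsv(sim: SimilarityMatrix, path) -> None:
    """0 = kernel fallback, 1 = averaged branch, per pair."""
    if sim.provenance is None:
        raise ValueError("similarity matrix carries no provenance mask")
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(sim.ids) + "\n")
        for i, row_id in enumerate(sim.ids):
            fh.write(row_id + "\t" + "\t".join(str(int(v)) for v in sim.provenance[i]) + "\n")


def write_predictions(records: list[dict], path, anchor: str | None = None) -> None:
    """Ranked candidate records -> TSV (descending score)."""
    with open(path, "w") as fh:
        fh.write("anchor\tcandidate\tscore\tpredicted\n")
        for r in records:
            fh.write(f"{anchor or ''}\t{r['id']}\t{r['score']:.6f}\t{r['predicted']}\n")


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_yaml_safe(cfg), fh, sort_keys=True)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
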