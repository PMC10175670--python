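"""Initial node feature construction.

Each node's basic feature vector fuses its integrated-similarity row with
its association profile:

* disease ``i``: ``[SD row i (n_d) || A column i (n_m)]``
* miRNA ``j``:  ``[SM row j (n_m) || A row j (n_d)]``

Both classes therefore share the feature dimension ``n_m + n_d``, which
lets a single autoencoder architecture serve both. An alternative
``product`` fusion (similarity matrix times association matrix) is kept
behind a flag for comparison; it is not the default.
"""

from __future__ import annotations

import numpy as np

from .types import AssociationMatrix, SimilarityMatrix

__all__ = ["build_disease_features", "build_mirna_features"]


def build_disease_features(
    sd: SimilarityMatrix, a: AssociationMatrix, fusion: str = "concat"
) -> np.ndarray:
    """Per-disease feature matrix, shape (n_d, n_d + n_m) under concat."""
    if sd.ids != a.disease_ids:
        raise ValueError("disease id order mismatch between SD and association matrix")
    if fusion == "concat":
        return np.hstack([sd.values, a.values.T.astype(float)])
    if fusion == "product":
        return sd.values @ a.values.T.astype(float)
    raise ValueError(f"unknown fusion mode {fusion!r}")


def build_mirna_features(
    sm: SimilarityMatrix, a: AssociationMatrix, fusion: str = "concat"
) -> np.ndarray:
    """Per-miRNA feature matrix, shape (n_m, n_m + n_d) under concat."""
    if sm.ids != a.mirna_ids:
        raise ValueError("miRNA id order mismatch between SM and association matrix")
    if fusion == "concat":
        return np.hstack([sm.values, a.values.astype(float)])
    if fusion == "product":
        return sm.values @ a.values.astype(float)
    raise ValueError(f"unknown fusion mode {fusion!r}")
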