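"""Family-level co-existence via the C-score.

The C-score between two families is computed on their site-occupancy
vectors (a family occupies a site when any member species occurs there):
with R_i, R_j occupied-site counts and S shared sites,

    C = (R_i − S)(R_j − S) / (R_i · R_j)

ranging from 0 (full sympatry, one occupancy nested in the other) to 1
(allopatry, disjoint occupancies).  The pairwise matrix feeds the same
patristic-distance regression used for the other dissimilarities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import OccurrenceMatrix

__all__ = ["c_score", "family_cscore_matrix"]


def c_score(occ_i, occ_j) -> float:
    """Checkerboard C-score between two binary site-occupancy vectors."""
    a = np.asarray(occ_i, dtype=bool)
    b = np.asarray(occ_j, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("occupancy vectors differ in length")
    ri, rj = int(a.sum()), int(b.sum())
    if ri == 0 or rj == 0:
        raise ValueError("empty occupancy vector")
    s = int((a & b).sum())
    return float((ri - s) * (rj - s) / (ri * rj))


def family_cscore_matrix(occ: OccurrenceMatrix, families: list[str]) -> pd.DataFrame:
    """Symmetric matrix of pairwise C-scores over the retained families."""
    if len(families) < 2:
        raise ValueError("need >= 2 families")
    vecs = {f: occ.family_occupancy_vector(f).to_numpy() for f in families}
    n = len(families)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = c_score(vecs[families[i]], vecs[families[j]])
    return pd.DataFrame(M, index=families, columns=families)
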