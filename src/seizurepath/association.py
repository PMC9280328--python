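"""Association between pathway dissimilarities and duration differences.

For each subject, Spearman's correlation is computed between the
upper-triangular entries of the pathway dissimilarity and duration
difference matrices.  Because matrix entries are not independent, its
significance is assessed with a Mantel permutation test: one matrix's rows
and columns are permuted jointly (preserving its internal distance
structure), the correlation recomputed for each permutation, and a one-sided
p-value formed with the add-one convention so p is always in (0, 1].  Across
subjects, p-values are corrected with the Benjamini-Hochberg FDR step-up.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .dissimilarity import DissimilarityMatrix

__all__ = ["AssociationResult", "spearman_upper", "mantel_test", "bh_fdr"]


@dataclass
class AssociationResult:
    rho: float
    p_value: float
    n_perm: int
    seed: int | None = None


def _upper_vec(D) -> np.ndarray:
    if isinstance(D, DissimilarityMatrix):
        return D.upper()
    D = np.asarray(D, dtype=float)
    iu = np.triu_indices(D.shape[0], k=1)
    return D[iu]


def _as_matrix(D) -> np.ndarray:
    return D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)


def _check_pair(D1, D2) -> tuple[np.ndarray, np.ndarray]:
    A, B = _as_matrix(D1), _as_matrix(D2)
    if A.shape != B.shape:
        raise ValueError("matrices must have the same shape")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 seizures")
    return A, B


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return math.nan
    return float((xc @ yc) / denom)


def spearman_upper(D1, D2) -> float:
    """Spearman correlation of the two matrices' upper-triangular entries.

    Average ranks are used for ties.  If either entry vector is constant the
    correlation is undefined and NaN is returned.
    """
    A, B = _check_pair(D1, D2)
    x = rankdata(_upper_vec(A))
    y = rankdata(_upper_vec(B))
    return _pearson(x, y)


def mantel_test(
    D1, D2, n_perm: int = 10_000, seed: int | None = None
) -> AssociationResult:
    """One-sided Mantel test of the Spearman matrix correlation.

    The null is built by jointly permuting the rows and columns of the second
    matrix and recomputing the upper-triangular Spearman correlation.
    ``p = (#{rho_perm >= rho_obs} + 1) / (n_perm + 1)``.  When ``s!`` does not
    exceed ``n_perm`` the permutation distribution is enumerated exhaustively
    instead (with the identity included, giving an exact p).
    """
    A, B = _check_pair(D1, D2)
    s = A.shape[0]
    iu = np.triu_indices(s, k=1)
    x = rankdata(A[iu])
    # rank the entries once; joint row/column permutation only reindexes them
    Br = np.zeros_like(B)
    Br[iu] = rankdata(B[iu])
    Br = Br + Br.T
    rho_obs = _pearson(x, Br[iu])
    if math.isnan(rho_obs):
        return AssociationResult(rho=math.nan, p_value=math.nan, n_perm=0, seed=seed)

    if math.factorial(s) <= n_perm:
        warnings.warn(
            f"only {math.factorial(s)} distinct permutations for s={s}; "
            "enumerating exhaustively",
            stacklevel=2,
        )
        rhos = []
        for perm in permutations(range(s)):
            p = np.array(perm)
            rhos.append(_pearson(x, Br[np.ix_(p, p)][iu]))
        rhos = np.array(rhos)
        p_value = float((rhos >= rho_obs - 1e-12).sum() / rhos.size)
        return AssociationResult(rho=rho_obs, p_value=p_value, n_perm=rhos.size, seed=seed)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(s)
        if _pearson(x, Br[np.ix_(p, p)][iu]) >= rho_obs:
            count += 1
    p_value = (count + 1) / (n_perm + 1)
    return AssociationResult(rho=rho_obs, p_value=float(p_value), n_perm=n_perm, seed=seed)


def bh_fdr(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg FDR step-up; returns the boolean rejection mask."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject
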