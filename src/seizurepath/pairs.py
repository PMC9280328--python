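"""Four-way taxonomy of seizure pairs: concordance, elasticity, semblance.

With a pathway-similarity threshold (dissimilarity <= 1) and a
duration-similarity threshold (|ln ratio| <= 0.2, i.e. up to an
e^0.2 ~ 1.22-fold duration increase), every seizure pair falls into exactly
one of four categories:

* ``similar-similar``     — similar pathways, similar durations
* ``different-different`` — different pathways, different durations
* ``elastic``             — similar pathways, different durations (the same
                            route traversed at different speeds)
* ``semblant``            — different pathways, similar durations

Concordant pairs strengthen the within-subject association between pathway
and duration variability; elastic and semblant pairs weaken it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dissimilarity import DissimilarityMatrix

__all__ = [
    "CATEGORIES",
    "PairTaxonomy",
    "classify_pairs",
    "subject_has_category",
    "match_similarity_thresholds",
]

CATEGORIES = ("similar-similar", "different-different", "elastic", "semblant")


@dataclass
class PairTaxonomy:
    """Per-pair category assignment plus counts; categories partition all pairs."""

    categories: np.ndarray  # (s, s) array of category strings, "" on diagonal
    thr_path: float
    thr_dur: float

    @property
    def n(self) -> int:
        return self.categories.shape[0]

    def counts(self) -> dict[str, int]:
        iu = np.triu_indices(self.n, k=1)
        vals = self.categories[iu]
        return {c: int((vals == c).sum()) for c in CATEGORIES}

    def proportions(self) -> dict[str, float]:
        total = self.n * (self.n - 1) // 2
        return {c: k / total for c, k in self.counts().items()}

    def pair_mask(self, category: str) -> np.ndarray:
        return self.categories == category


def _values(D) -> np.ndarray:
    return D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)


def classify_pairs(
    D_path, D_dur, thr_path: float = 1.0, thr_dur: float = 0.2
) -> PairTaxonomy:
    """Assign each seizure pair to one of the four categories.

    Both thresholds are inclusive on the "similar" side: a pair sitting
    exactly at (1.0, 0.2) is similar in both features.
    """
    P, L = _values(D_path), _values(D_dur)
    if P.shape != L.shape:
        raise ValueError("matrices must be aligned")
    if P.shape[0] < 2:
        raise ValueError("need at least 2 seizures")
    sim_path = P <= thr_path
    sim_dur = L <= thr_dur
    cats = np.empty(P.shape, dtype=object)
    cats[sim_path & sim_dur] = "similar-similar"
    cats[~sim_path & ~sim_dur] = "different-different"
    cats[sim_path & ~sim_dur] = "elastic"
    cats[~sim_path & sim_dur] = "semblant"
    np.fill_diagonal(cats, "")
    return PairTaxonomy(categories=cats, thr_path=thr_path, thr_dur=thr_dur)


def subject_has_category(taxonomy: PairTaxonomy, category: str) -> tuple[bool, int]:
    """Whether the subject displays the category at all, and its pair count."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    count = taxonomy.counts()[category]
    return count >= 1, count


def match_similarity_thresholds(
    path_entries: np.ndarray, dur_entries: np.ndarray, thr_path: float = 1.0
) -> float:
    """Quantile-match the duration threshold to the pathway threshold.

    Helper reproducing the calibration in which the global proportion of
    duration-similar pairs is matched to the global proportion of
    pathway-similar pairs: given pooled upper-triangular entries from all
    subjects, returns the duration threshold whose similar-pair proportion
    equals that of ``thr_path`` on the pathway side.  Not applied by default;
    the standard thresholds are (1.0, 0.2).
    """
    path_entries = np.asarray(path_entries, float)
    dur_entries = np.asarray(dur_entries, float)
    prop = (path_entries <= thr_path).mean()
    if prop <= 0:
        return 0.0
    return float(np.quantile(dur_entries, prop))
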