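"""End-to-end orchestration of the pathway-vs-duration analysis.

``run_pipeline`` takes one subject's connectivity series and durations
(either a saved cohort directory or a synthetic generator call), optionally
denoises with stability NMF, and writes every per-subject artefact: the
pathway dissimilarity and duration difference matrices, the Spearman/Mantel
association, the truncation result, the four-way pair taxonomy, the
duration-population report with pathway-cluster agreement, 2-D embedding
coordinates, and a JSON run log (seeds, parameters, exclusions).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from . import io as sio
from .association import mantel_test
from .connectivity import exclude_incomplete_seizures
from .dissimilarity import duration_difference_matrix, pathway_dissimilarity_matrix
from .nmf import concatenate_windows, fit_stability_nmf, reconstruct
from .pairs import classify_pairs
from .populations import cluster_durations, cluster_pathways, partition_agreement
from .embedding import sammon_map
from .synthetic import CohortConfig, generate_cohort
from .truncation import find_truncation_pairs

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the standard analysis values."""

    cohort_dir: str | None = None  # saved cohort; None -> synthetic
    out_dir: str = "results"
    seed: int = 0
    synthetic: CohortConfig = field(default_factory=CohortConfig)
    use_nmf: bool = True
    nmf_rank_range: tuple[int, int] = (1, 8)
    nmf_restarts: int = 8
    thr_path: float = 1.0
    thr_dur: float = 0.2
    truncation_cut: float = 1.0
    truncation_thresh: float = 1.0
    n_perm: int = 10_000
    k_max: int = 10
    gap_n_ref: int = 1000
    run_embedding: bool = True
    embedding_max_windows: int = 400


@dataclass
class PipelineResult:
    out_dir: Path
    D_path: object
    D_dur: object
    association: object
    truncation: object
    taxonomy: object
    duration_partition: object
    agreement: object | None
    excluded: list


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    if cfg.cohort_dir is not None:
        fc, durations, _, _ = sio.load_cohort_fc(cfg.cohort_dir)
    else:
        cohort = generate_cohort(cfg.synthetic, seed=cfg.seed)
        sio.save_cohort(out / "cohort", cohort)
        fc = cohort.fc
        durations = cohort.durations_s

    fc, excluded = exclude_incomplete_seizures(fc)
    durations = {sid: durations[sid] for sid in fc}
    ids = list(fc)
    if len(ids) < 3:
        raise ValueError("fewer than 3 analyzable seizures after exclusions")

    nmf_info = None
    if cfg.use_nmf:
        V, slices = concatenate_windows(fc)
        lo, hi = cfg.nmf_rank_range
        hi = min(hi, min(V.shape))
        model = fit_stability_nmf(
            V, rank_range=range(lo, hi + 1), n_restarts=cfg.nmf_restarts,
            seed=int(rng.integers(2**31 - 1)),
        )
        fc = reconstruct(model, slices, fc)
        nmf_info = {
            "rank": model.rank,
            "stability": model.stability,
            "reconstruction_error": model.reconstruction_error,
        }

    D_path = pathway_dissimilarity_matrix(fc)
    D_dur = duration_difference_matrix(durations)
    sio.write_matrix_csv(out / "pathway_dissimilarity.csv", D_path)
    sio.write_matrix_csv(out / "duration_difference.csv", D_dur)
    sio.write_durations_csv(out / "durations.csv", durations)

    assoc = mantel_test(
        D_path, D_dur, n_perm=cfg.n_perm, seed=int(rng.integers(2**31 - 1))
    )
    sio.write_json(
        out / "association.json",
        {"rho": assoc.rho, "p_value": assoc.p_value, "n_perm": assoc.n_perm},
    )

    trunc = find_truncation_pairs(
        list(fc.values()), D_path, durations,
        cut=cfg.truncation_cut, dissim_thresh=cfg.truncation_thresh,
    )
    sio.write_json(
        out / "truncation.json",
        {
            "proportion": trunc.proportion,
            "n_truncation_pairs": trunc.n_truncation_pairs,
            "group_labels": trunc.group_labels,
            "flagged_group_pairs": trunc.flagged_group_pairs,
        },
    )

    taxonomy = classify_pairs(D_path, D_dur, thr_path=cfg.thr_path, thr_dur=cfg.thr_dur)
    sio.write_json(
        out / "pair_taxonomy.json",
        {
            "thresholds": {"pathway": cfg.thr_path, "duration": cfg.thr_dur},
            "counts": taxonomy.counts(),
            "proportions": taxonomy.proportions(),
        },
    )

    dur_part = cluster_durations(
        durations, k_max=cfg.k_max, n_ref=cfg.gap_n_ref,
        seed=int(rng.integers(2**31 - 1)),
    )
    agreement = None
    report = {"k": dur_part.k, "labels": dur_part.labels}
    if dur_part.k >= 2:
        path_part = cluster_pathways(D_path, dur_part.k)
        agreement = partition_agreement(
            dur_part, path_part, n_perm=cfg.n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        report.update(
            {
                "pathway_labels": path_part.labels,
                "rand_index": agreement.rand_index,
                "adjusted_rand_index": agreement.adjusted_rand_index,
                "p_rand": agreement.p_rand,
                "p_ari": agreement.p_ari,
            }
        )
    sio.write_json(out / "duration_populations.json", report)

    if cfg.run_embedding:
        X = np.vstack([fc[sid].features for sid in ids])
        owner = np.concatenate([[sid] * fc[sid].n_windows for sid in ids])
        if X.shape[0] > cfg.embedding_max_windows:
            sel = np.sort(
                rng.choice(X.shape[0], size=cfg.embedding_max_windows, replace=False)
            )
            X, owner = X[sel], owner[sel]
        emb = sammon_map(
            squareform(pdist(X, metric="cityblock")),
            seed=int(rng.integers(2**31 - 1)),
        )
        pd.DataFrame(
            {
                "seizure_id": owner,
                "x": emb.coordinates[:, 0],
                "y": emb.coordinates[:, 1],
            }
        ).to_csv(out / "embedding.csv", index=False)

    sio.write_json(
        out / "run_log.json",
        {
            "config": dataclasses.asdict(cfg),
            "n_seizures": len(ids),
            "excluded_seizures": excluded,
            "nmf": nmf_info,
        },
    )
    return PipelineResult(
        out_dir=out,
        D_path=D_path,
        D_dur=D_dur,
        association=assoc,
        truncation=trunc,
        taxonomy=taxonomy,
        duration_partition=dur_part,
        agreement=agreement,
        excluded=excluded,
    )
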