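# seizurepath

Within-subject comparison of **seizure pathways** and **seizure durations**
from intracranial EEG (iEEG).

A seizure's electrographic dynamics can be summarised by two features: the
*pathway* it follows through functional-network space (its time-varying
connectivity evolution) and the *duration* it takes to complete that pathway.
These features need not vary together: the same pathway can be traversed at
different speeds ("elasticity"), different pathways can take the same time
("semblance"), and one seizure can be a truncated version of another in both
pathway and duration. `seizurepath` implements the full quantitative pipeline
for separating these cases in per-subject seizure cohorts, together with a
synthetic cohort generator that plants each kind of pair structure with known
ground truth.

The package is aimed at researchers analysing epilepsy-monitoring-unit or
chronic iEEG seizure recordings, and at anyone who wants a tested reference
implementation of the underlying methods.

## Methods at a glance

- **Pathway**: sliding-window (10 s window, 1 s step) band-averaged coherence
  in six canonical bands (δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–80, high-γ
  80–150 Hz), with
  `C_ij = |Σ_f P_ij(f)|² / (Σ_f P_ii(f) · Σ_f P_jj(f))`
  over Welch cross-/auto-spectra (2 s subwindows, 1 s overlap); the
  upper-triangular entries are vectorised and L1-normalised per band, giving
  `6·(n²−n)/2` features per window. Optional stability-NMF denoising
  reconstructs a low-rank approximation used downstream.
- **Pathway dissimilarity**: dynamic time warping aligns two feature series
  to minimise the total L1 distance; the dissimilarity is the average L1
  distance along the optimal alignment, so pure re-timings cost nothing.
- **Duration difference**: `|ln(l_i) − ln(l_j)| = |ln(l_i/l_j)|` — depends
  only on the duration ratio (20 s vs 40 s equals 60 s vs 120 s).
- **Association**: Spearman correlation between the upper triangles of the
  two pairwise matrices, tested one-sided with a Mantel permutation test
  (10 000 joint row/column permutations), BH-FDR across subjects.
- **Pair taxonomy**: with thresholds `d_path ≤ 1` and `d_dur ≤ 0.2` (an
  `e^0.2 ≈ 1.22`-fold duration change), every pair is *similar-similar*,
  *different-different*, *elastic* (similar pathway, different duration) or
  *semblant* (different pathway, similar duration).
- **Truncation pairs**: UPGMA pathway groups (dendrogram cut at 1) are
  scanned for ordered group pairs where one group is strictly shorter in
  duration and smaller in pathway size and its centroid matches a prefix of
  the other group's centroid (partial-pathway DTW scan ≤ 1).
- **Duration populations**: k-means on log durations with the gap statistic
  (uniform reference, firstMaxSE rule); if `k ≥ 2`, agreement between
  duration populations and UPGMA pathway clusters is measured with the Rand
  index / ARI plus permutation nulls.
- **Visualisation**: Sammon mapping of the L1 distances between all window
  connectivity patterns.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from seizurepath import (
    CohortConfig, generate_cohort, pathway_dissimilarity_matrix,
    duration_difference_matrix, mantel_test, classify_pairs,
    find_truncation_pairs, cluster_durations,
)

cohort = generate_cohort(CohortConfig(), seed=42)   # 2 base pathways x 5
print(f"seizures: {cohort.n_seizures}")             # + 2 truncation doublets
D_path = pathway_dissimilarity_matrix(cohort.fc)
D_dur = duration_difference_matrix(cohort.durations_s)
res = mantel_test(D_path, D_dur, n_perm=10_000, seed=0)
print(f"Spearman rho = {res.rho:.3f}, Mantel p = {res.p_value:.4f}")
tax = classify_pairs(D_path, D_dur)
print("pair taxonomy:", tax.counts())
trunc = find_truncation_pairs(list(cohort.fc.values()), D_path, cohort.durations_s)
print(f"truncation pairs: {trunc.n_truncation_pairs} "
      f"(proportion {trunc.proportion:.3f})")
part = cluster_durations(cohort.durations_s, seed=0)
print(f"duration populations: k = {part.k}")
```

prints

```
seizures: 14
Spearman rho = -0.257, Mantel p = 0.9833
pair taxonomy: {'similar-similar': 4, 'different-different': 56, 'elastic': 16, 'semblant': 15}
truncation pairs: 2 (proportion 0.022)
duration populations: k = 1
```

Reading the numbers: this synthetic subject's duration variability is mostly
independent of its pathway variability (durations are sampled independently
per seizure), so the pathway–duration correlation is weak and not
significant. All 16 detected elastic pairs include the 2 planted ones plus
same-pathway pairs whose independently sampled durations happen to differ by
more than the 1.22-fold band; both planted truncation doublets are found
(2 of 91 pairs); the unimodal lognormal duration model yields a single
duration population.

The same analysis is available from the shell:

```bash
seizurepath simulate --seed 42 --out-dir cohort/
seizurepath run-all --cohort cohort/ --out-dir results/ --seed 0
```

which writes the dissimilarity matrices (CSV), association, truncation,
taxonomy and duration-population reports (JSON), embedding coordinates and a
run log.

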