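"""Synthetic seizure cohorts with known pathway/duration ground truth.

The generator emulates the structure the analysis pipeline is built to
detect, without claiming biophysical realism.  Each subject has a dictionary
of latent network *states* (band-specific connectivity templates); a latent
*pathway* is an ordered sequence of states with dwell fractions; a seizure
realises a pathway as a connectivity time series (one window per second
beyond the 10 s window length) or, optionally, as a raw multichannel signal
whose band coherence reflects the active state.  Pair structure is planted
explicitly:

* **elastic pairs** — same pathway, durations differing by more than the
  e^0.2 similarity band, with independently warped dwell times;
* **semblant pairs** — different pathways, near-identical durations;
* **truncation pairs** — a child seizure realises only the leading fraction
  of its parent's pathway with a proportionally shorter duration.

Every one of the s(s-1)/2 seizure pairs carries a construction-time truth
label (``same-pathway`` / ``elastic`` / ``truncated`` / ``semblant`` /
``unrelated``), and generation is bit-reproducible from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.spatial.distance import pdist

from .connectivity import CANONICAL_BANDS, ConnectivityTimeSeries, n_fc_windows
from .recording import SeizureRecording

__all__ = [
    "StateDictionary",
    "LatentPathway",
    "SeizureSpec",
    "DurationModel",
    "CohortConfig",
    "SyntheticCohort",
    "make_dictionary",
    "realize_fc_series",
    "realize_raw_seizure",
    "generate_cohort",
    "inject_dropout",
]

PAIR_LABELS = ("same-pathway", "elastic", "truncated", "semblant", "unrelated")


@dataclass
class StateDictionary:
    """K latent network states as band-specific connectivity templates.

    ``templates`` has shape (K, n_bands, n_pairs); every band row is
    nonnegative and sums to 1, mirroring the per-band L1 normalisation of
    measured connectivity windows.
    """

    n_channels: int
    templates: np.ndarray
    band_names: tuple[str, ...] = tuple(CANONICAL_BANDS)

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        if self.templates.ndim != 3:
            raise ValueError("templates must be (K, n_bands, n_pairs)")
        if (self.templates < 0).any():
            raise ValueError("templates must be nonnegative")
        sums = self.templates.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each band block must sum to 1")

    @property
    def n_states(self) -> int:
        return self.templates.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.templates.shape[2]

    def flat(self, k: int) -> np.ndarray:
        """State k as a band-blocked feature vector (like an FC window)."""
        return self.templates[k].reshape(-1)


@dataclass
class LatentPathway:
    """Ordered state ids with positive dwell fractions summing to one."""

    state_sequence: np.ndarray
    dwell_fractions: np.ndarray

    def __post_init__(self) -> None:
        self.state_sequence = np.asarray(self.state_sequence, dtype=int)
        self.dwell_fractions = np.asarray(self.dwell_fractions, dtype=float)
        if self.state_sequence.size < 1:
            raise ValueError("pathway needs at least one segment")
        if self.state_sequence.shape != self.dwell_fractions.shape:
            raise ValueError("sequence/dwell length mismatch")
        if (self.dwell_fractions <= 0).any():
            raise ValueError("dwell fractions must be positive")
        if abs(self.dwell_fractions.sum() - 1.0) > 1e-9:
            raise ValueError("dwell fractions must sum to 1")

    @property
    def n_segments(self) -> int:
        return self.state_sequence.size

    def warped(self, warp: np.ndarray) -> "LatentPathway":
        """Monotone dwell rescaling: multiply dwell fractions, renormalise."""
        w = np.asarray(warp, dtype=float)
        if w.shape != self.dwell_fractions.shape or (w <= 0).any():
            raise ValueError("warp must be positive, one factor per segment")
        d = self.dwell_fractions * w
        return LatentPathway(self.state_sequence.copy(), d / d.sum())


@dataclass
class SeizureSpec:
    """Recipe for realising one seizure from a latent pathway."""

    pathway_id: int
    duration_s: float
    warp: np.ndarray | None = None
    truncate_fraction: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 10:
            raise ValueError("seizure durations must be at least 10 s")
        if not 0 < self.truncate_fraction <= 1:
            raise ValueError("truncate_fraction must be in (0, 1]")

    @property
    def effective_duration_s(self) -> float:
        """Realised duration: a truncated seizure is proportionally shorter."""
        return self.duration_s * self.truncate_fraction


@dataclass
class DurationModel:
    """Lognormal seizure-duration model, optionally a two-mode mixture.

    Defaults: median 60 s with log-sd 0.5.  In bimodal mode the second
    log-mode sits ``separation_sd`` standard deviations above the first.
    """

    mu: float = float(np.log(60.0))
    sigma: float = 0.5
    bimodal: bool = False
    separation_sd: float = 3.0
    weight2: float = 0.5

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.bimodal:
            comp = rng.random(size) < self.weight2
            mu = np.where(comp, self.mu + self.separation_sd * self.sigma, self.mu)
        else:
            mu = np.full(size, self.mu)
        return np.exp(rng.normal(mu, self.sigma))


@dataclass
class CohortConfig:
    """Study conditions for one synthetic subject."""

    n_channels: int = 16
    n_pathways: int = 2
    seizures_per_pathway: int = 5
    n_states_per_pathway: int = 3
    n_elastic_pairs: int = 2
    n_semblant_pairs: int = 2
    n_truncation_pairs: int = 2
    truncate_fraction: float = 0.4
    noise_sd: float = 5e-4
    duration_model: DurationModel = field(default_factory=DurationModel)
    min_duration_s: float = 15.0
    fade_windows: int = 1
    template_sparsity: float = 0.25
    template_margin: float = 3.0
    elastic_log_ratio: tuple[float, float] = (0.4, 1.0)
    semblant_log_ratio_max: float = 0.05


@dataclass
class SyntheticCohort:
    """Generated seizures plus full construction ground truth."""

    seizure_ids: list[int]
    fc: dict[int, ConnectivityTimeSeries]
    durations_s: dict[int, float]
    pair_labels: np.ndarray  # (s, s) object array; "" on diagonal
    config: CohortConfig
    seed: int
    dictionary: StateDictionary
    pathways: list[LatentPathway]
    specs: list[SeizureSpec]
    true_window_states: dict[int, np.ndarray]

    @property
    def n_seizures(self) -> int:
        return len(self.seizure_ids)

    def durations_array(self) -> np.ndarray:
        return np.array([self.durations_s[i] for i in self.seizure_ids])

    def pairs_with_label(self, label: str) -> list[tuple[int, int]]:
        """Index pairs (i < j) carrying the given truth label."""
        if label not in PAIR_LABELS:
            raise ValueError(f"unknown pair label {label!r}")
        s = self.n_seizures
        return [
            (i, j)
            for i in range(s)
            for j in range(i + 1, s)
            if self.pair_labels[i, j] == label
        ]


def make_dictionary(
    n_channels: int,
    n_states: int,
    seed: int | None = None,
    n_bands: int = 6,
    sparsity: float = 0.25,
    margin: float = 3.0,
    max_retries: int = 200,
) -> StateDictionary:
    """Draw mutually distinguishable sparse connectivity state templates.

    Each band block concentrates mass on a random subset of channel pairs
    (fraction ``sparsity``) and is L1-normalised.  States are redrawn until
    all pairwise cityblock distances between flattened templates exceed
    ``margin``; if that cannot be achieved within ``max_retries`` redraws the
    request is impossible at this margin and an error is raised.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    if n_states < 1:
        raise ValueError("need at least 1 state")
    rng = np.random.default_rng(seed)
    n_pairs = (n_channels * n_channels - n_channels) // 2
    n_active = max(1, int(round(sparsity * n_pairs)))

    def draw_state() -> np.ndarray:
        t = np.zeros((n_bands, n_pairs))
        for b in range(n_bands):
            active = rng.choice(n_pairs, size=n_active, replace=False)
            w = rng.exponential(1.0, size=n_active)
            t[b, active] = w / w.sum()
        return t

    states = [draw_state() for _ in range(n_states)]
    for _ in range(max_retries):
        flats = np.array([s.reshape(-1) for s in states])
        if n_states == 1:
            break
        d = pdist(flats, metric="cityblock")
        if d.min() > margin:
            break
        # redraw one member of the closest pair
        iu = np.triu_indices(n_states, k=1)
        worst = np.argmin(d)
        states[iu[1][worst]] = draw_state()
    else:
        raise RuntimeError(
            f"could not draw {n_states} states with pairwise distance > {margin}"
        )
    return StateDictionary(n_channels=n_channels, templates=np.array(states))


def _segment_boundaries(pathway: LatentPathway) -> np.ndarray:
    return np.concatenate(([0.0], np.cumsum(pathway.dwell_fractions)))


def _template_at(
    dictionary: StateDictionary,
    pathway: LatentPathway,
    tau: float,
    fade_width: float,
) -> tuple[np.ndarray, int]:
    """Template at pathway position tau in [0, 1), with linear cross-fade.

    Within ``fade_width`` of an internal segment boundary the two adjacent
    state templates are blended linearly.  Returns the (n_bands, n_pairs)
    template and the id of the dominant state.
    """
    bounds = _segment_boundaries(pathway)
    seg = int(np.searchsorted(bounds[1:-1], tau, side="right"))
    t = dictionary.templates[pathway.state_sequence[seg]]
    state = int(pathway.state_sequence[seg])
    if fade_width > 0:
        for k in range(1, pathway.n_segments):
            b = bounds[k]
            if abs(tau - b) < fade_width / 2:
                alpha = (tau - (b - fade_width / 2)) / fade_width
                lo = dictionary.templates[pathway.state_sequence[k - 1]]
                hi = dictionary.templates[pathway.state_sequence[k]]
                t = (1 - alpha) * lo + alpha * hi
                state = int(pathway.state_sequence[k if alpha > 0.5 else k - 1])
                break
    return t, state


def realize_fc_series(
    dictionary: StateDictionary,
    pathway: LatentPathway,
    spec: SeizureSpec,
    fade_windows: int = 1,
    return_states: bool = False,
):
    """Render a latent pathway as a connectivity time series.

    The number of windows follows the same rule as measured connectivity,
    ``m = floor(duration) - 9``; window ``w`` samples the pathway at latent
    position ``truncate_fraction * (w + 0.5) / m``, so a truncated seizure
    covers only the leading fraction of the dwell mass at the same rate as
    its parent.  Nonnegative (clipped-Gaussian) noise perturbs each window's
    template before per-band re-normalisation.
    """
    if spec.warp is not None:
        pathway = pathway.warped(spec.warp)
    m = n_fc_windows(spec.effective_duration_s)
    if m < 1:
        raise ValueError(
            f"effective duration {spec.effective_duration_s:.1f}s yields no FC window"
        )
    rng = np.random.default_rng(spec.seed)
    fade_width = fade_windows * spec.truncate_fraction / m
    n_bands, n_pairs = dictionary.templates.shape[1:]
    feats = np.empty((m, n_bands * n_pairs))
    states = np.empty(m, dtype=int)
    for w in range(m):
        tau = spec.truncate_fraction * (w + 0.5) / m
        t, states[w] = _template_at(dictionary, pathway, tau, fade_width)
        if spec.noise_sd > 0:
            t = np.maximum(t + rng.normal(0.0, spec.noise_sd, size=t.shape), 0.0)
            sums = t.sum(axis=1, keepdims=True)
            t = np.divide(t, sums, out=t, where=sums > 0)
        else:
            t = t.copy()
        feats[w] = t.reshape(-1)
    fc = ConnectivityTimeSeries(
        features=feats,
        n_channels=dictionary.n_channels,
        band_names=dictionary.band_names,
        window_times=np.arange(m, dtype=float),
    )
    return (fc, states) if return_states else fc


def _state_loadings(dictionary: StateDictionary) -> np.ndarray:
    """Per-state, per-band channel loadings for the raw-signal model.

    The template's pair weights are arranged as a symmetric matrix whose
    leading eigenvector gives one channel loading per channel: channels
    that the template connects strongly share a large loading on the band's
    common source, so their estimated coherence correlates with the
    template.  Shape (K, n_bands, n_channels).
    """
    K, n_bands, _ = dictionary.templates.shape
    n = dictionary.n_channels
    iu = np.triu_indices(n, k=1)
    G = np.empty((K, n_bands, n))
    for k in range(K):
        for b in range(n_bands):
            M = np.zeros((n, n))
            M[iu] = dictionary.templates[k, b]
            M = M + M.T
            np.fill_diagonal(M, M.max(axis=1))
            vals, vecs = np.linalg.eigh(M)
            v = np.abs(vecs[:, -1]) * np.sqrt(max(vals[-1], 0.0))
            G[k, b] = v / max(v.max(), 1e-12)
    return G


def realize_raw_seizure(
    dictionary: StateDictionary,
    pathway: LatentPathway,
    spec: SeizureSpec,
    fs: float,
    bands: dict[str, tuple[float, float]] | None = None,
    source_gain: float = 1.0,
) -> SeizureRecording:
    """Render a latent pathway as a raw multichannel recording.

    Per band, channels share a narrowband Gaussian source with
    state-dependent loadings (see :func:`_state_loadings`); independent
    white channel noise of standard deviation ``spec.noise_sd`` is added.
    ``fs`` must resolve the highest analysis band (>= 2 x 150 Hz).
    """
    if bands is None:
        bands = dict(CANONICAL_BANDS)
    f_hi = max(b[1] for b in bands.values())
    if fs < 2 * f_hi:
        raise ValueError(f"fs={fs} Hz below Nyquist for the {f_hi} Hz band edge")
    if spec.warp is not None:
        pathway = pathway.warped(spec.warp)
    T = int(round(spec.effective_duration_s * fs))
    rng = np.random.default_rng(spec.seed)
    n = dictionary.n_channels
    G = _state_loadings(dictionary)
    # sample-level dominant state (hard assignment; dwell in tau units)
    taus = spec.truncate_fraction * (np.arange(T) + 0.5) / T
    bounds = _segment_boundaries(pathway)
    segs = np.searchsorted(bounds[1:-1], taus, side="right")
    sample_states = pathway.state_sequence[segs]
    data = np.zeros((n, T))
    for b, (f1, f2) in enumerate(bands.values()):
        white = rng.normal(size=T)
        sos = sps.butter(4, [f1, min(f2, 0.99 * fs / 2)], btype="bandpass",
                         fs=fs, output="sos")
        src = sps.sosfiltfilt(sos, white)
        src = src / max(src.std(), 1e-12)
        data += source_gain * G[sample_states, b, :].T * src[None, :]
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    return SeizureRecording(data=data, fs=fs, onset_sample=0, termination_sample=T)


def inject_dropout(
    rec: SeizureRecording,
    intervals: list[tuple[float, float]] | list[tuple[float, float, list[int] | None]],
    seed: int | None = None,
) -> SeizureRecording:
    """Flatten signal in the given intervals, emulating telemetry dropouts.

    Each interval is ``(start_s, end_s)`` or ``(start_s, end_s, channels)``
    with ``channels=None`` meaning all channels.  Affected samples are held
    at the interval's first sample value (a flat line) and marked missing.
    Overlapping or out-of-range intervals are rejected.  ``seed`` is
    accepted for interface symmetry; the operation is deterministic.
    """
    out = rec.copy_with()
    claimed = np.zeros(rec.data.shape, dtype=bool)
    for iv in intervals:
        start_s, end_s = iv[0], iv[1]
        channels = iv[2] if len(iv) > 2 else None
        s0 = int(round(start_s * rec.fs))
        s1 = int(round(end_s * rec.fs))
        if not 0 <= s0 < s1 <= rec.n_samples:
            raise ValueError(f"dropout interval ({start_s}, {end_s}) out of range")
        chans = range(rec.n_channels) if channels is None else channels
        for ch in chans:
            if not 0 <= ch < rec.n_channels:
                raise ValueError(f"dropout channel {ch} out of range")
            if claimed[ch, s0:s1].any():
                raise ValueError("overlapping dropout intervals")
            claimed[ch, s0:s1] = True
            out.data[ch, s0:s1] = out.data[ch, s0]
            out.missing_mask[ch, s0:s1] = True
    return out


def _prefix_states(pathway: LatentPathway, fraction: float) -> np.ndarray:
    """States visited within the leading ``fraction`` of the dwell mass."""
    bounds = _segment_boundaries(pathway)
    return pathway.state_sequence[bounds[:-1] < fraction]


def _sound_truncation_pathway(
    dictionary: StateDictionary,
    state_block: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> LatentPathway:
    """Pathway whose prefix is strictly smaller than the whole, noiselessly.

    The truncated (prefix) seizure must have a smaller pathway size (max
    cityblock spread of its windows) than its parent; that requires the
    maximum template distance among prefix states to be strictly below the
    maximum over all states.  State order and dwell fractions are resampled
    until this holds.
    """
    flats = np.array([dictionary.flat(k) for k in state_block])
    n = len(state_block)
    full = pdist(flats, metric="cityblock")

    def spread(idx: np.ndarray) -> float:
        if idx.size < 2:
            return 0.0
        return float(pdist(flats[idx], metric="cityblock").max())

    for _ in range(max_retries):
        order = rng.permutation(n)
        dwell = rng.uniform(0.5, 1.5, size=n)
        dwell /= dwell.sum()
        pathway = LatentPathway(state_block[order], dwell)
        prefix = _prefix_states(pathway, fraction)
        pos = {s: i for i, s in enumerate(state_block)}
        pre_idx = np.array([pos[s] for s in prefix])
        if prefix.size < n and spread(pre_idx) < full.max() - 1e-9:
            return pathway
    raise RuntimeError("could not construct a sound truncation pathway")


def generate_cohort(config: CohortConfig, seed: int = 0) -> SyntheticCohort:
    """Generate one subject's seizures with planted pair structure.

    Base pathways each contribute ``seizures_per_pathway`` seizures with
    model-sampled durations.  Elastic pairs are planted on disjoint
    same-pathway seizure pairs (second member re-timed to a log-duration
    ratio inside ``elastic_log_ratio`` and dwell-warped); semblant pairs on
    disjoint cross-pathway pairs (durations matched within
    ``semblant_log_ratio_max``).  Each truncation pair adds a dedicated
    parent/child seizure doublet on its own pathway, the child realising the
    leading ``truncate_fraction`` of the dwell mass at proportionally
    shorter duration.  Requested counts are achieved exactly or generation
    fails with an explanatory error.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    if cfg.n_semblant_pairs > 0 and cfg.n_pathways < 2:
        raise ValueError("semblant pairs require at least two pathways")
    if cfg.n_elastic_pairs > cfg.n_pathways * (cfg.seizures_per_pathway // 2):
        raise ValueError("not enough same-pathway seizures for requested elastic pairs")

    n_states = (cfg.n_pathways + cfg.n_truncation_pairs) * cfg.n_states_per_pathway
    dictionary = make_dictionary(
        cfg.n_channels,
        n_states,
        seed=int(rng.integers(2**31 - 1)),
        sparsity=cfg.template_sparsity,
        margin=cfg.template_margin,
    )

    pathways: list[LatentPathway] = []
    for p in range(cfg.n_pathways):
        block = np.arange(p * cfg.n_states_per_pathway, (p + 1) * cfg.n_states_per_pathway)
        dwell = rng.uniform(0.5, 1.5, size=block.size)
        pathways.append(LatentPathway(block, dwell / dwell.sum()))

    def sample_duration(min_s: float) -> float:
        for _ in range(1000):
            d = float(cfg.duration_model.sample(rng, 1)[0])
            if d >= min_s:
                return d
        raise RuntimeError("duration model cannot reach the minimum duration")

    specs: list[SeizureSpec] = []
    pathway_of: list[int] = []
    for p in range(cfg.n_pathways):
        for _ in range(cfg.seizures_per_pathway):
            specs.append(
                SeizureSpec(
                    pathway_id=p,
                    duration_s=sample_duration(cfg.min_duration_s),
                    noise_sd=cfg.noise_sd,
                    seed=int(rng.integers(2**31 - 1)),
                )
            )
            pathway_of.append(p)

    s_base = len(specs)
    labels_override: dict[tuple[int, int], str] = {}
    used: set[int] = set()

    # elastic: same pathway, re-timed second member plus a dwell warp;
    # planted round-robin across pathways to spread seizure usage
    free_by_pathway = {
        p: [i for i in range(s_base) if pathway_of[i] == p]
        for p in range(cfg.n_pathways)
    }
    planted = 0
    while planted < cfg.n_elastic_pairs:
        order = sorted(free_by_pathway, key=lambda p: -len(free_by_pathway[p]))
        if len(free_by_pathway[order[0]]) < 2:
            raise ValueError("could not plant the requested number of elastic pairs")
        p = order[0]
        i, j = free_by_pathway[p].pop(0), free_by_pathway[p].pop(0)
        r = rng.uniform(*cfg.elastic_log_ratio)
        new_d = specs[i].duration_s * np.exp(r)
        warp = rng.uniform(0.5, 2.0, size=pathways[p].n_segments)
        specs[j] = replace(specs[j], duration_s=float(new_d), warp=warp)
        labels_override[(i, j)] = "elastic"
        used.update((i, j))
        planted += 1

    # semblant: cross-pathway, matched durations; draw from the two
    # pathways with the most unused seizures
    planted = 0
    while planted < cfg.n_semblant_pairs:
        order = sorted(free_by_pathway, key=lambda p: -len(free_by_pathway[p]))
        if len(order) < 2 or not free_by_pathway[order[1]]:
            raise ValueError("could not plant the requested number of semblant pairs")
        pa, pb = order[0], order[1]
        i, j = free_by_pathway[pa].pop(0), free_by_pathway[pb].pop(0)
        u = rng.uniform(-cfg.semblant_log_ratio_max, cfg.semblant_log_ratio_max)
        specs[j] = replace(
            specs[j],
            duration_s=float(max(specs[i].duration_s * np.exp(u), cfg.min_duration_s)),
        )
        labels_override[tuple(sorted((i, j)))] = "semblant"
        used.update((i, j))
        planted += 1

    # truncation: dedicated parent/child doublets on their own pathways
    for t in range(cfg.n_truncation_pairs):
        block = np.arange(
            (cfg.n_pathways + t) * cfg.n_states_per_pathway,
            (cfg.n_pathways + t + 1) * cfg.n_states_per_pathway,
        )
        pathway = _sound_truncation_pathway(
            dictionary, block, cfg.truncate_fraction, rng
        )
        pathways.append(pathway)
        pid = len(pathways) - 1
        parent_d = sample_duration(
            max(cfg.min_duration_s, (cfg.min_duration_s + 1) / cfg.truncate_fraction)
        )
        parent = SeizureSpec(
            pathway_id=pid, duration_s=parent_d, noise_sd=cfg.noise_sd,
            seed=int(rng.integers(2**31 - 1)),
        )
        child = SeizureSpec(
            pathway_id=pid, duration_s=parent_d, truncate_fraction=cfg.truncate_fraction,
            noise_sd=cfg.noise_sd, seed=int(rng.integers(2**31 - 1)),
        )
        specs.extend([parent, child])
        pathway_of.extend([pid, pid])
        labels_override[(len(specs) - 2, len(specs) - 1)] = "truncated"

    s = len(specs)
    fc: dict[int, ConnectivityTimeSeries] = {}
    durations: dict[int, float] = {}
    true_states: dict[int, np.ndarray] = {}
    for i, spec in enumerate(specs):
        series, states = realize_fc_series(
            dictionary, pathways[spec.pathway_id], spec,
            fade_windows=cfg.fade_windows, return_states=True,
        )
        fc[i] = series
        durations[i] = spec.effective_duration_s
        true_states[i] = states

    labels = np.empty((s, s), dtype=object)
    labels[:] = ""
    for i in range(s):
        for j in range(i + 1, s):
            same = pathway_of[i] == pathway_of[j]
            lab = labels_override.get((i, j), "same-pathway" if same else "unrelated")
            labels[i, j] = labels[j, i] = lab

    return SyntheticCohort(
        seizure_ids=list(range(s)),
        fc=fc,
        durations_s=durations,
        pair_labels=labels,
        config=cfg,
        seed=seed,
        dictionary=dictionary,
        pathways=pathways,
        specs=specs,
        true_window_states=true_states,
    )
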