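"""Synthetic dyadic cohort generator.

The study's raw data are undeposited, so this module generates a full
stand-in cohort with the statistical structure the analysis assumes:

* 29 disjoint same-sex pairs (58 subjects), 180 time points at TR = 2 s,
  120 regions;
* each subject's latent inter-regional correlation is a convex mixture of a
  cohort template, a pair-shared component, and an individual component
  (weights ``lambda_pair`` / ``lambda_indiv``), so members of a pair have
  genuinely more similar connectomes than strangers;
* how strongly the two members of a pair diverge is controlled per
  (pair, region) by a "dyadic variability" dial that scales the individual
  component's factor loadings; the dial mixes a pair-level and a
  region-level part, each drawn as a shuffled evenly-spaced grid so every
  cohort spans the similarity continuum;
* observed raw series are AR(1)-in-time, cross-sectionally correlated draws
  from that latent correlation, contaminated with slow drift and leaked
  motion/WM/CSF nuisance that the preprocessing stage must remove;
* pair-level conversational satisfaction carries a controllable linear
  signal from the latent per-region similarity features (sparse, mixed-sign
  weights), wrapped top-down into integer 18-item ratings on the 1–8 scale.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .similarity import build_similarity_matrix

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_template",
    "subject_latent_corr",
    "dyadic_variability_dials",
    "select_signal_regions",
    "sample_timeseries",
    "sample_nuisance",
    "apply_nuisance_leak",
    "plant_satisfaction",
    "make_signal_weights",
    "generate_cohort",
]

N_SATISFACTION_ITEMS = 18
N_SESSIONS = 3
N_TRAITS = 5
N_TRAIT_ITEMS = 12


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the emulated study where it states a value (58 subjects
    in 29 disjoint same-sex pairs, 180 volumes at TR 2 s, 120 regions, 1–8
    satisfaction items); the generative conventions (factor structure,
    mixture weights, AR coefficient, noise levels) are fixed choices
    documented in the methods note.
    """

    n_subjects: int = 58
    n_pairs: int = 29
    n_regions: int = 120
    n_timepoints: int = 180
    tr_seconds: float = 2.0
    lambda_pair: float = 0.5
    lambda_indiv: float = 0.45
    ar_coef: float = 0.3
    n_factors: int = 4
    dyad_var_scale: float = 1.5  # overall dyadic-variability dial range
    dyad_var_pair_frac: float = 0.5  # pair-level share of the dial
    dyad_var_region_amp: tuple = (1.0, 1.0)  # optional region amplitude ramp
    signal_weights: np.ndarray | None = None
    signal_scale: float = 0.0  # SD of the standardized planted component
    n_signal_positive: int = 2
    n_signal_negative: int = 1
    signal_pool: int = 15  # top-variance regions eligible as planted support
    intercept: float = 6.0
    noise_sd: float = 0.2
    subject_jitter_sd: float = 0.3
    item_noise_sd: float = 0.6
    session_effects: tuple = (0.0, 0.0, 0.4)
    session_noise_sd: float = 0.6
    nuisance_leak: float = 0.5
    drift_amplitude: float = 1.0
    drift_freq_hz: float = 0.003
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects != 2 * self.n_pairs:
            raise ValueError("n_subjects must equal 2 * n_pairs")
        for name in ("n_pairs", "n_regions", "n_timepoints"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.lambda_pair <= 1 and 0 <= self.lambda_indiv <= 1):
            raise ValueError("mixture weights must lie in [0, 1]")
        if self.lambda_pair + self.lambda_indiv > 1:
            raise ValueError("lambda_pair + lambda_indiv must not exceed 1")
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must lie in [0, 1)")
        if self.noise_sd < 0 or self.session_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if len(self.session_effects) != N_SESSIONS:
            raise ValueError(f"need {N_SESSIONS} session effects")
        if not 0 <= self.dyad_var_pair_frac <= 1:
            raise ValueError("dyad_var_pair_frac must lie in [0, 1]")

    @classmethod
    def strong_signal(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Strong planted-effect regime: component SD 2.4 on the 1-8 scale."""
        overrides.setdefault("signal_scale", 2.4)
        overrides.setdefault("intercept", 5.5)  # limits ceiling clipping
        return cls(seed=seed, **overrides)

    @classmethod
    def weak_signal(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Weak planted-effect regime: component SD 0.6."""
        overrides.setdefault("signal_scale", 0.6)
        return cls(seed=seed, **overrides)


@dataclass
class SyntheticCohort:
    """Everything the pipeline consumes, plus the planted ground truth."""

    config: SyntheticConfig
    subjects: list
    pairs: list  # (subject_a, subject_b) ids
    pair_sex: list  # 'M' or 'F' per pair (assigned, unused by the pipeline)
    region_labels: list
    timeseries: dict  # subject -> T×N raw (pre-cleaning) series
    motion: dict  # subject -> T×6
    wm: dict  # subject -> T
    csf: dict  # subject -> T
    personality: dict  # subject -> 5×12 integer items
    satisfaction_items: dict  # subject -> 3×18 integer items (session × item)
    signal_weights: np.ndarray  # effective length-N planted weights
    signal_support: np.ndarray  # indices of nonzero planted weights
    latent_similarity: np.ndarray  # P×N ground-truth similarity features
    pair_targets: np.ndarray = field(default=None)  # P×3 pre-item pair scores


def generate_template(n_regions: int, n_factors: int, seed) -> np.ndarray:
    """Random factor-model correlation matrix.

    ``C = rescale(L L' + I)`` with an N×k standard-normal loading matrix L;
    the unit-variance idiosyncratic term keeps C positive definite and the
    rescaling makes it a correlation matrix.  ``n_factors=0`` gives the
    identity.
    """
    if n_regions <= 0:
        raise ValueError("n_regions must be positive")
    if n_factors < 0 or n_factors >= n_regions:
        raise ValueError("need 0 <= n_factors < n_regions")
    if n_factors == 0:
        return np.eye(n_regions)
    rng = _as_rng(seed)
    loadings = rng.normal(size=(n_regions, n_factors))
    cov = loadings @ loadings.T + np.eye(n_regions)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def _nearest_correlation(m: np.ndarray, clip: float = 1e-8) -> np.ndarray:
    """Eigenvalue clipping + unit-diagonal rescale (cheap at N <= 120)."""
    m = (m + m.T) / 2.0
    w = np.linalg.eigvalsh(m)
    if w[0] >= clip:
        np.fill_diagonal(m, 1.0)
        return m
    w, v = np.linalg.eigh(m)
    w = np.clip(w, clip, None)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    return m


def subject_latent_corr(
    template: np.ndarray,
    pair_corr: np.ndarray,
    lambda_pair: float,
    lambda_indiv: float,
    seed,
    n_factors: int = 4,
    indiv_scale: np.ndarray | None = None,
) -> np.ndarray:
    """Subject-level latent correlation matrix.

    Nearest-correlation projection of
    ``(1 - lp - li) * template + lp * pair_corr + li * indiv_corr`` where the
    individual component is drawn fresh per subject (from ``seed``); the two
    members of one pair share ``pair_corr`` but not ``indiv_corr``.

    ``indiv_scale`` (length N, nonnegative) scales the individual
    component's factor loadings per region: regions with a larger scale
    diverge more between the two members of a pair.  Both members share the
    scale vector (it is a property of the dyad), not the loadings.
    """
    if not (0 <= lambda_pair <= 1 and 0 <= lambda_indiv <= 1):
        raise ValueError("mixture weights must lie in [0, 1]")
    if lambda_pair + lambda_indiv > 1:
        raise ValueError("lambda_pair + lambda_indiv must not exceed 1")
    template = np.asarray(template, dtype=float)
    if lambda_pair == 0 and lambda_indiv == 0:
        return template.copy()
    pair_corr = np.asarray(pair_corr, dtype=float)
    if template.shape != pair_corr.shape:
        raise ValueError("template and pair_corr shapes differ")
    n = template.shape[0]
    if indiv_scale is None:
        indiv = generate_template(n, n_factors, seed)
    else:
        indiv_scale = np.asarray(indiv_scale, dtype=float).reshape(-1)
        if indiv_scale.shape[0] != n or np.any(indiv_scale < 0):
            raise ValueError("indiv_scale must be length N and nonnegative")
        rng = _as_rng(seed)
        loadings = rng.normal(size=(n, max(n_factors, 1))) * indiv_scale[:, None]
        cov = loadings @ loadings.T + np.eye(n)
        d = np.sqrt(np.diag(cov))
        indiv = cov / np.outer(d, d)
    mix = (
        (1.0 - lambda_pair - lambda_indiv) * template
        + lambda_pair * pair_corr
        + lambda_indiv * indiv
    )
    return _nearest_correlation(mix)


def dyadic_variability_dials(
    n_pairs: int,
    n_regions: int,
    seed,
    scale: float = 1.5,
    pair_frac: float = 0.5,
    region_amp: tuple = (1.0, 1.0),
) -> np.ndarray:
    """(n_pairs, n_regions) dial matrix controlling within-pair divergence.

    ``dial = scale * amp_j * (pair_frac * G + (1 - pair_frac) * U)`` where
    the pair-level column ``G`` and every region-level column of ``U`` are
    shuffled evenly-spaced grids on (0, 1) — stratified draws, so each
    cohort covers the whole similarity continuum instead of clumping — and
    ``amp_j`` is a shuffled linear ramp over ``region_amp`` giving regions a
    stable hierarchy of dyadic variability (some regions differ a lot
    between partners, others barely at all).
    """
    rng = _as_rng(seed)
    grid = (np.arange(n_pairs) + 0.5) / n_pairs
    g = rng.permutation(grid)
    u = np.column_stack([rng.permutation(grid) for _ in range(n_regions)])
    amp = rng.permutation(np.linspace(region_amp[0], region_amp[1], n_regions))
    return scale * amp[None, :] * (pair_frac * g[:, None] + (1.0 - pair_frac) * u)


def select_signal_regions(
    latent_similarity: np.ndarray, n_signal: int = 3, pool: int = 15
) -> np.ndarray:
    """Pick planted-support regions: decorrelated high-variability columns.

    Candidates are the ``pool`` columns with the largest across-pair SD of
    latent similarity; starting from the most variable one, each next region
    greedily minimizes its maximum |correlation| with those already chosen.
    Deterministic given the similarity matrix.
    """
    s = np.asarray(latent_similarity, dtype=float)
    pool = min(pool, s.shape[1])
    if n_signal > pool:
        raise ValueError("more signal regions requested than pool size")
    cand = np.argsort(s.std(axis=0))[::-1][:pool]
    # prefer candidates with few strongly-correlated siblings anywhere in
    # the feature set: a support region surrounded by near-duplicates could
    # not be singled out by any attribution method
    full_corr = np.corrcoef(s, rowvar=False)
    siblings = np.array(
        [np.sum(np.abs(np.delete(full_corr[c], c)) > 0.6) for c in cand]
    )
    # balance the two demands: high variability (prediction) and few
    # siblings (attribution) via a rank sum
    rank_sd = np.argsort(np.argsort(-s.std(axis=0)[cand]))
    rank_sib = np.argsort(np.argsort(siblings))
    cand = cand[np.argsort(rank_sd + 2 * rank_sib, kind="stable")]
    corr = np.corrcoef(s[:, cand], rowvar=False)
    chosen = [0]
    while len(chosen) < n_signal:
        remaining = [i for i in range(pool) if i not in chosen]
        nxt = min(remaining, key=lambda i: max(abs(corr[i, j]) for j in chosen))
        chosen.append(nxt)
    return cand[chosen]


def sample_timeseries(
    latent_corr: np.ndarray, n_timepoints: int, ar_coef: float, seed
) -> np.ndarray:
    """Stationary AR(1) draws with cross-region correlation ``latent_corr``.

    ``x_t = phi * x_{t-1} + sqrt(1 - phi^2) * e_t`` with ``e_t ~ N(0, C)``,
    initialized from the stationary distribution, so the marginal
    cross-region correlation equals C at every lag-0 slice and the empirical
    correlation converges to C as T grows.
    """
    if not abs(ar_coef) < 1:
        raise ValueError("|ar_coef| must be < 1")
    latent_corr = np.asarray(latent_corr, dtype=float)
    if latent_corr.ndim != 2 or latent_corr.shape[0] != latent_corr.shape[1]:
        raise ValueError("latent_corr must be square")
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be positive")
    rng = _as_rng(seed)
    w, v = np.linalg.eigh((latent_corr + latent_corr.T) / 2.0)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    n = latent_corr.shape[0]
    innovations = rng.normal(size=(n_timepoints, n)) @ root.T
    out = np.empty((n_timepoints, n))
    out[0] = innovations[0]
    scale = np.sqrt(1.0 - ar_coef**2)
    for t in range(1, n_timepoints):
        out[t] = ar_coef * out[t - 1] + scale * innovations[t]
    return out


def sample_nuisance(
    n_timepoints: int,
    seed,
    translation_step_mm: float = 0.02,
    rotation_step_rad: float = 2e-4,
    physio_ar: float = 0.9,
):
    """Motion, white-matter and CSF nuisance series.

    Motion is a cumulative random walk (three translations in mm, three
    rotations in rad); WM and CSF means are unit-variance AR(1) noise.
    Returns ``(motion T×6, wm T, csf T)``.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    rng = _as_rng(seed)
    steps = rng.normal(size=(n_timepoints, 6))
    steps[:, :3] *= translation_step_mm
    steps[:, 3:] *= rotation_step_rad
    motion = np.cumsum(steps, axis=0)

    def ar1(rng, t, phi):
        e = rng.normal(size=t)
        x = np.empty(t)
        x[0] = e[0]
        s = np.sqrt(1 - phi**2)
        for i in range(1, t):
            x[i] = phi * x[i - 1] + s * e[i]
        return x

    wm = ar1(rng, n_timepoints, physio_ar)
    csf = ar1(rng, n_timepoints, physio_ar)
    return motion, wm, csf


def apply_nuisance_leak(
    ts: np.ndarray,
    motion: np.ndarray,
    wm: np.ndarray,
    csf: np.ndarray,
    weight: float,
    seed,
) -> np.ndarray:
    """Mix standardized nuisance series into the signal with random loadings.

    ``weight=0`` returns the series unchanged.
    """
    ts = np.asarray(ts, dtype=float)
    if weight == 0:
        return ts.copy()
    rng = _as_rng(seed)
    z = np.column_stack([motion, np.reshape(wm, (-1, 1)), np.reshape(csf, (-1, 1))])
    sd = z.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (z - z.mean(axis=0)) / sd
    loadings = rng.normal(size=(z.shape[1], ts.shape[1]))
    return ts + weight * (z @ loadings) / np.sqrt(z.shape[1])


def make_signal_weights(
    n_regions: int,
    seed,
    n_positive: int = 3,
    n_negative: int = 4,
) -> np.ndarray:
    """Sparse mixed-sign raw weight pattern (3 positive, 4 negative regions)."""
    rng = _as_rng(seed)
    k = n_positive + n_negative
    if k > n_regions:
        raise ValueError("more signal regions than regions")
    support = rng.choice(n_regions, size=k, replace=False)
    w = np.zeros(n_regions)
    mags = np.abs(rng.normal(loc=1.0, scale=0.25, size=k))
    signs = np.array([1.0] * n_positive + [-1.0] * n_negative)
    w[support] = signs * mags
    return w


def plant_satisfaction(
    similarity_matrix: np.ndarray,
    signal_weights: np.ndarray,
    intercept: float,
    noise_sd: float,
    seed,
    subject_jitter_sd: float = 0.3,
    item_noise_sd: float = 0.6,
):
    """Pair satisfaction targets and per-subject integer item ratings.

    ``y_p = clip(intercept + sum_j w_j s_pj + eps_p, 1, 8)``.  Subject-level
    scores are antithetic jitters ``y_p +/- d_p`` (so the pair mean of the
    two subject targets equals ``y_p`` exactly, before integer rounding of
    the items), and each subject's 18 items are the subject target plus
    rounding noise, clipped to integers in 1..8.

    Returns ``(pair_targets P, items_a P×18, items_b P×18)``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    s = np.asarray(similarity_matrix, dtype=float)
    w = np.asarray(signal_weights, dtype=float).reshape(-1)
    if s.ndim != 2 or s.shape[1] != w.shape[0]:
        raise ValueError("similarity matrix columns must match weight length")
    rng = _as_rng(seed)
    n_pairs = s.shape[0]
    y = intercept + s @ w + rng.normal(0.0, noise_sd, size=n_pairs) if noise_sd > 0 \
        else intercept + s @ w
    y = np.clip(y, 1.0, 8.0)

    jitter = (
        rng.normal(0.0, subject_jitter_sd, size=n_pairs)
        if subject_jitter_sd > 0
        else np.zeros(n_pairs)
    )
    items = []
    for subject_target in (y + jitter, y - jitter):
        target = np.clip(subject_target, 1.0, 8.0)
        noise = (
            rng.normal(0.0, item_noise_sd, size=(n_pairs, N_SATISFACTION_ITEMS))
            if item_noise_sd > 0
            else np.zeros((n_pairs, N_SATISFACTION_ITEMS))
        )
        raw = target[:, None] + noise
        items.append(np.clip(np.round(raw), 1, 8).astype(int))
    return y, items[0], items[1]


def _subject_ids(n_subjects: int):
    width = max(2, len(str(n_subjects)))
    return [f"sub-{i + 1:0{width}d}" for i in range(n_subjects)]


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Generate the full synthetic cohort for one seed.

    Deterministic given ``config.seed``; all randomness flows through named
    substreams so stages are independently reproducible.
    """
    cfg = config or SyntheticConfig()
    seed = cfg.seed
    subjects = _subject_ids(cfg.n_subjects)
    pairs = [(subjects[2 * p], subjects[2 * p + 1]) for p in range(cfg.n_pairs)]
    n_male = (cfg.n_pairs + 1) // 2  # 15 male-male + 14 female-female at 29
    pair_sex = ["M"] * n_male + ["F"] * (cfg.n_pairs - n_male)
    region_labels = [f"region-{j + 1:03d}" for j in range(cfg.n_regions)]

    template = generate_template(
        cfg.n_regions, cfg.n_factors, substream(seed, "template")
    )
    dials = dyadic_variability_dials(
        cfg.n_pairs,
        cfg.n_regions,
        substream(seed, "dial"),
        scale=cfg.dyad_var_scale,
        pair_frac=cfg.dyad_var_pair_frac,
        region_amp=cfg.dyad_var_region_amp,
    )

    timeseries, motion, wm, csf = {}, {}, {}, {}
    latent_rsfc = {}
    t_axis = np.arange(cfg.n_timepoints) * cfg.tr_seconds
    for p, (a, b) in enumerate(pairs):
        pair_corr = generate_template(
            cfg.n_regions, cfg.n_factors, substream(seed, "pair", p)
        )
        for subj in (a, b):
            latent = subject_latent_corr(
                template,
                pair_corr,
                cfg.lambda_pair,
                cfg.lambda_indiv,
                substream(seed, "indiv", subj),
                n_factors=cfg.n_factors,
                indiv_scale=dials[p],
            )
            latent_rsfc[subj] = latent
            ts = sample_timeseries(
                latent, cfg.n_timepoints, cfg.ar_coef, substream(seed, "ts", subj)
            )
            mo, w_, c_ = sample_nuisance(
                cfg.n_timepoints, substream(seed, "nuisance", subj)
            )
            raw = apply_nuisance_leak(
                ts, mo, w_, c_, cfg.nuisance_leak, substream(seed, "leak", subj)
            )
            if cfg.drift_amplitude > 0:
                drift_rng = substream(seed, "drift", subj)
                phases = drift_rng.uniform(0, 2 * np.pi, size=cfg.n_regions)
                raw = raw + cfg.drift_amplitude * np.sin(
                    2 * np.pi * cfg.drift_freq_hz * t_axis[:, None] + phases[None, :]
                )
            timeseries[subj] = raw
            motion[subj], wm[subj], csf[subj] = mo, w_, c_

    latent_similarity = build_similarity_matrix(latent_rsfc, pairs)

    # resolve the planted effect
    if cfg.signal_weights is not None:
        weights = np.asarray(cfg.signal_weights, dtype=float).reshape(-1)
        if weights.shape[0] != cfg.n_regions:
            raise ValueError("signal_weights length must equal n_regions")
        intercept_eff = cfg.intercept
    elif cfg.signal_scale > 0:
        k = cfg.n_signal_positive + cfg.n_signal_negative
        support = select_signal_regions(
            latent_similarity, n_signal=k, pool=cfg.signal_pool
        )
        signs = np.concatenate(
            [np.ones(cfg.n_signal_positive), -np.ones(cfg.n_signal_negative)]
        )
        substream(seed, "weights").shuffle(signs)
        # equalize each support feature's contribution to the planted
        # component: equal raw magnitudes on unequal-variance columns would
        # leave the weakest feature without a detectable association
        col_sd = latent_similarity[:, support].std(axis=0)
        raw_w = np.zeros(cfg.n_regions)
        raw_w[support] = signs / np.where(col_sd == 0, 1.0, col_sd)
        z = latent_similarity @ raw_w
        sd = z.std()
        if sd == 0:
            raise ValueError("degenerate similarity features; cannot scale signal")
        weights = raw_w * (cfg.signal_scale / sd)
        # center the planted component so the intercept stays the scale anchor
        intercept_eff = cfg.intercept - float(z.mean()) * cfg.signal_scale / sd
    else:
        weights = np.zeros(cfg.n_regions)
        intercept_eff = cfg.intercept

    support = np.flatnonzero(weights)

    pair_targets = np.empty((cfg.n_pairs, N_SESSIONS))
    items_by_subject = {s: np.empty((N_SESSIONS, N_SATISFACTION_ITEMS), dtype=int)
                        for s in subjects}
    for sess in range(N_SESSIONS):
        if sess == 0:
            w_sess, icpt, noise = weights, intercept_eff, cfg.noise_sd
        else:
            w_sess = np.zeros(cfg.n_regions)
            icpt = cfg.intercept + cfg.session_effects[sess]
            noise = cfg.session_noise_sd
        y, items_a, items_b = plant_satisfaction(
            latent_similarity,
            w_sess,
            icpt,
            noise,
            substream(seed, "satisfaction", sess),
            subject_jitter_sd=cfg.subject_jitter_sd,
            item_noise_sd=cfg.item_noise_sd,
        )
        pair_targets[:, sess] = y
        for p, (a, b) in enumerate(pairs):
            items_by_subject[a][sess] = items_a[p]
            items_by_subject[b][sess] = items_b[p]

    personality = {}
    for subj in subjects:
        rng = substream(seed, "personality", subj)
        trait_means = rng.normal(4.5, 1.0, size=N_TRAITS)
        items = trait_means[:, None] + rng.normal(
            0.0, 1.0, size=(N_TRAITS, N_TRAIT_ITEMS)
        )
        personality[subj] = np.clip(np.round(items), 1, 7).astype(int)

    return SyntheticCohort(
        config=cfg,
        subjects=subjects,
        pairs=pairs,
        pair_sex=pair_sex,
        region_labels=region_labels,
        timeseries=timeseries,
        motion=motion,
        wm=wm,
        csf=csf,
        personality=personality,
        satisfaction_items=items_by_subject,
        signal_weights=weights,
        signal_support=support,
        latent_similarity=latent_similarity,
        pair_targets=pair_targets,
    )
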