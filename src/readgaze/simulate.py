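"""Synthetic reading-gaze study generator.

Emulates a within-subjects newspaper-reading experiment: 30 participants
each read 18 one-page articles (grouped in three counterbalanced blocks)
while a 60 Hz remote binocular tracker records gaze position and pupil
diameter; after every article the reader rates its comprehensibility and
interest on three 7-point items each.

The generator produces raw sample streams (not event lists), so the whole
downstream pipeline — fixation detection, saccade derivation, filtering,
aggregation, modeling — is exercised end to end. Two standardized latent
appraisals per session (comprehensibility, interest; correlated at
``latent_correlation``) drive session-level multipliers on fixation
duration, regression probability, word-skip rate (hence saccade
amplitude), and pupil drift variance. The latents also generate the
questionnaire items through a common-factor model.

Tracker artifacts are emulated: blinks appear as runs of samples at
position (0, 0) px; one participant loses all gaze data (a software
failure); a handful of sessions are cut short by tracking loss, which
leaves them with too few regression events for higher distribution
moments and therefore with missing feature values downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import eval_hermitenorm
from scipy.stats import norm

CANVAS_W, CANVAS_H = 1280, 1024

# Questionnaire items. ``reverse_coded`` marks semantic differentials whose
# recorded value runs opposite to the construct (left anchor = high on the
# construct), e.g. comprehensible(1)-incomprehensible(7). boring-exciting is
# deliberately the reverse of interesting-uninteresting.
ITEM_DEFINITIONS: dict[str, list[tuple[str, bool]]] = {
    "comprehensibility": [
        ("comp_comprehensible", True),
        ("comp_coherent", True),
        ("comp_easy_to_understand", True),
    ],
    "interest": [
        ("int_interesting", True),
        ("int_boring_exciting", False),
        ("int_read_more", False),
    ],
}

# 7-point response distribution centers; readers on average found the
# articles comprehensible (M ~ 5.3) and moderately interesting (M ~ 4.7).
ITEM_MEANS = {"comprehensibility": 5.3, "interest": 4.7}
ITEM_SD = 1.4

# Per-family gain applied to the latent index before exponentiation. The
# gains compensate for how much session-level sampling noise each feature
# family carries (e.g. session mean saccade amplitude is dominated by
# line-return sweeps, so its channel needs a larger gain to surface at the
# same correlation strength as reading time).
FAMILY_GAINS = {
    "reading_time": 0.75,
    "fixation_duration": 0.75,
    "regression_prob": 2.0,
    "saccade_amplitude": 3.0,
    "pupil_variance": 1.5,
}

DEFAULT_EFFECT_DIRECTIONS = {
    "reading_time": -1,
    "fixation_duration": -1,
    "regression_prob": -1,
    "saccade_amplitude": -1,
    "pupil_variance": -1,
}


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass
class GeneratorConfig:
    n_participants: int = 30
    n_articles: int = 18
    n_blocks: int = 3
    sample_rate: float = 60.0
    latent_correlation: float = 0.466
    effect_directions: dict = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_DIRECTIONS))
    item_intercorrelation: dict = field(
        default_factory=lambda: {"comprehensibility": 0.7356,
                                 "interest": 0.7953})
    effect_size_comprehensibility: float = 0.08
    effect_size_interest: float = 0.04
    blink_rate_per_min: float = 8.0
    dropout_rate: float = 1 / 30
    n_partial_sessions: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_articles", "n_blocks"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be > 0")
        if not -1.0 <= self.latent_correlation <= 1.0:
            raise ConfigurationError("latent_correlation must be in [-1, 1]")
        for scale, rho in self.item_intercorrelation.items():
            if not 0.0 < rho < 1.0:
                raise ConfigurationError(
                    f"item_intercorrelation[{scale!r}] must be in (0, 1)")
        if self.blink_rate_per_min < 0:
            raise ConfigurationError("blink_rate_per_min must be >= 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1]")
        if self.n_partial_sessions < 0:
            raise ConfigurationError("n_partial_sessions must be >= 0")


@dataclass(frozen=True)
class LatentAppraisal:
    """Standardized latent comprehensibility/interest for one session."""

    participant_id: int
    article_id: int
    block_id: int
    comprehensibility: float
    interest: float


@dataclass(frozen=True)
class ArticleLayout:
    """Word-level page layout on a 1280 x 1024 canvas (y grows downward)."""

    title_rect: tuple[float, float, float, float]
    content_rect: tuple[float, float, float, float]
    line_boxes: tuple  # ordered top-to-bottom (x0, y0, x1, y1) per text line
    n_words: int
    word_x: np.ndarray  # word-center x, reading order (title words first)
    word_y: np.ndarray
    n_title_words: int

    @property
    def aois(self) -> dict:
        return {"title": list(self.title_rect),
                "content": list(self.content_rect)}


@dataclass(frozen=True)
class ParticipantProfile:
    """Stable reading traits of one participant, plus slow block-level
    drift (fatigue / familiarity); both are what the participant- and
    block-median normalizations downstream are meant to strip."""

    speed: float = 1.0           # multiplies fixation durations
    pupil_base_left: float = 28.0
    pupil_base_right: float = 28.0
    pupil_scale: float = 1.0     # multiplies pupil drift amplitude
    skip_tendency: float = 1.0
    regression_tendency: float = 1.0
    block_tempo: tuple = (1.0, 1.0, 1.0)
    block_skip: tuple = (1.0, 1.0, 1.0)
    block_regression: tuple = (1.0, 1.0, 1.0)
    block_pupil: tuple = (1.0, 1.0, 1.0)

    def block_factor(self, field_name: str, block_id: int) -> float:
        vals = getattr(self, field_name)
        return vals[block_id % len(vals)]


@dataclass
class SyntheticStudy:
    config: GeneratorConfig
    layouts: dict            # article_id -> ArticleLayout
    latents: pd.DataFrame    # participant, article, block, order, C, I
    ratings: pd.DataFrame    # one row per (participant, article)
    gaze: dict               # (participant, article) -> sample DataFrame
    reverse_coded: dict      # item name -> bool
    dropped_participants: list
    partial_sessions: list


# ---------------------------------------------------------------------------
# Layout


def generate_layout(article_id: int, rng: np.random.Generator,
                    n_words: int | None = None) -> ArticleLayout:
    """Random single-page article layout: one title line plus a text body.

    Word widths emulate proportional text at ~10 px per character; lines
    fill a 1000 px column. Body length varies per article (1,200-character
    truncation in the emulated stimuli corresponds to roughly 140-220
    words).
    """
    x0, x1 = 140.0, 1140.0
    char_w = 10.0
    if n_words is None:
        n_words = 180  # ~1,200-character truncated article
    if n_words <= 0:
        raise ConfigurationError("n_words must be positive")
    n_title = int(rng.integers(4, 9))
    title_rect = (x0, 70.0, x1, 122.0)
    title_y = 96.0

    widths = (rng.integers(3, 9, size=n_words) + 1) * char_w
    line_h, line_box_h, y_top = 46.0, 32.0, 186.0
    word_x, word_y, line_boxes = [], [], []
    cx, line_i = x0, 0
    for w in widths:
        if cx + w > x1:  # wrap
            line_boxes.append((x0, y_top + line_i * line_h,
                               x1, y_top + line_i * line_h + line_box_h))
            line_i += 1
            cx = x0
        word_x.append(cx + w / 2.0)
        word_y.append(y_top + line_i * line_h + line_box_h / 2.0)
        cx += w
    line_boxes.append((x0, y_top + line_i * line_h,
                       x1, y_top + line_i * line_h + line_box_h))

    # title words, centered-ish, read before the body
    t_widths = (rng.integers(4, 10, size=n_title) + 1) * (char_w + 4)
    t_total = float(np.sum(t_widths))
    tx = (x0 + x1) / 2.0 - t_total / 2.0
    tx_centers = []
    for w in t_widths:
        tx_centers.append(tx + w / 2.0)
        tx += w
    wx = np.array(tx_centers + word_x)
    wy = np.array([title_y] * n_title + word_y)

    content_rect = (x0, y_top - 10.0, x1, min(
        float(CANVAS_H), y_top + (line_i + 1) * line_h + 10.0))
    return ArticleLayout(
        title_rect=title_rect, content_rect=content_rect,
        line_boxes=tuple(line_boxes), n_words=n_words,
        word_x=wx, word_y=wy, n_title_words=n_title)


# ---------------------------------------------------------------------------
# Ratings


@lru_cache(maxsize=32)
def _calibrated_latent_rho(rho_target: float, mean: float, sd: float) -> float:
    """Latent normal correlation whose 7-point discretization has Pearson
    correlation ``rho_target``.

    The staircase transform g(x) = 1 + sum_c 1[x > t_c] attenuates
    correlations; its Hermite expansion gives
    corr(g(X), g(Y)) = sum_k a_k^2 r^k / sum_k a_k^2 for latent corr r,
    with a_k = sum_c phi(t_c) He_{k-1}(t_c) / sqrt(k!). The monotone map is
    inverted with Brent's method.
    """
    cuts = np.array([(c + 0.5 - mean) / sd for c in range(1, 7)])
    K = 40
    a = np.zeros(K + 1)
    log_fact = np.cumsum(np.log(np.arange(1, K + 1)))
    for k in range(1, K + 1):
        he = eval_hermitenorm(k - 1, cuts)
        a[k] = float(np.sum(norm.pdf(cuts) * he)) * math.exp(
            -0.5 * log_fact[k - 1])
    a2 = a ** 2
    # exact variance of the discretized variable (the Hermite tail beyond K
    # is not negligible for a staircase, but in the numerator it is damped
    # by r^k and can be truncated)
    edges = np.concatenate(([-np.inf], cuts, [np.inf]))
    probs = np.diff(norm.cdf(edges))
    levels = np.arange(1, 8, dtype=float)
    mu_g = float(probs @ levels)
    denom = float(probs @ (levels - mu_g) ** 2)

    def attenuated(r: float) -> float:
        return float(np.sum(a2[1:] * r ** np.arange(1, K + 1))) / denom

    if attenuated(0.999999) < rho_target:
        raise ConfigurationError(
            "item_intercorrelation unreachable after 7-point discretization")
    return float(brentq(lambda r: attenuated(r) - rho_target,
                        1e-9, 0.999999, xtol=1e-10))


def simulate_item_triplets(n: int, rho: float, rng: np.random.Generator,
                           discretize: bool = False, mean: float = 4.0,
                           sd: float = 1.5) -> np.ndarray:
    """n x 3 equicorrelated standardized responses from a common-factor
    model: x_j = sqrt(rho) F + sqrt(1 - rho) e_j, so every item pair has
    correlation exactly ``rho`` in expectation. With ``discretize`` the
    items are mapped onto a 1-7 response scale (which attenuates the
    correlation; see :func:`_calibrated_latent_rho`)."""
    if not 0.0 < rho < 1.0:
        raise ConfigurationError("rho must be in (0, 1)")
    f = rng.standard_normal((n, 1))
    e = rng.standard_normal((n, 3))
    x = math.sqrt(rho) * f + math.sqrt(1.0 - rho) * e
    if discretize:
        x = np.clip(np.rint(mean + sd * x), 1, 7)
    return x


def generate_ratings(latent: LatentAppraisal, item_intercorrelation: dict,
                     rng: np.random.Generator) -> dict:
    """Three 7-point items per construct from a common-factor model.

    The session's standardized latent appraisal is the common factor; item
    loadings are chosen so that the PAIRWISE correlation of the recorded
    (discretized, polarity-aligned) items equals ``item_intercorrelation``
    in expectation. Reverse-coded differentials are flipped (x -> 8 - x)
    before recording.
    """
    values: dict = {}
    for construct, items in ITEM_DEFINITIONS.items():
        rho = item_intercorrelation[construct]
        rho_lat = _calibrated_latent_rho(rho, ITEM_MEANS[construct], ITEM_SD)
        loading = math.sqrt(rho_lat)
        L = getattr(latent, construct)
        for name, reverse in items:
            xi = loading * L + math.sqrt(1.0 - rho_lat) * rng.standard_normal()
            raw = int(np.clip(round(ITEM_MEANS[construct] + ITEM_SD * xi),
                              1, 7))
            values[name] = 8 - raw if reverse else raw
    return values


def reverse_coding_map() -> dict:
    return {name: rev for items in ITEM_DEFINITIONS.values()
            for name, rev in items}


# ---------------------------------------------------------------------------
# Gaze streams


# base scanpath parameters (defaults chosen to center reading time near 75 s
# for an average article at neutral latents)
BASE_FIX_MEDIAN_MS = 385.0
FIX_SIGMA_LOG = 0.4
BASE_SKIP_PROB = 0.18
BASE_REGRESSION_PROB = 0.10
SESSION_TEMPO_SD = 0.12
FIX_JITTER_PX = 1.5
EYE_OFFSET_PX = 1.5
EYE_NOISE_PX = 0.8
PUPIL_DRIFT_AMP = (0.7, 0.5)
PUPIL_DRIFT_PERIOD_S = (23.0, 7.5)
PUPIL_WHITE_SD = 0.35
BLINK_DUR_RANGE_MS = (100.0, 400.0)

# Stable participant-trait and block-drift variability (log scale). The
# variance split between participants, blocks and sessions is a free
# design choice; it is kept small so that within-subject analyses (and
# their cross-validation) are not dominated by person-level confounds,
# while pupil BASELINES still differ strongly across people (they carry no
# analytic weight because absolute pupil size is excluded downstream).
TRAIT_SD = 0.05
BLOCK_SD = 0.03


def _latent_index(latent: LatentAppraisal, config: GeneratorConfig) -> float:
    return (config.effect_size_comprehensibility * latent.comprehensibility
            + config.effect_size_interest * latent.interest)


def _channel(latent: LatentAppraisal, config: GeneratorConfig,
             family: str) -> float:
    """exp(gain * sign * (beta_C*C + beta_I*I)) session multiplier."""
    sign = config.effect_directions.get(family, 0)
    return math.exp(FAMILY_GAINS[family] * sign * _latent_index(latent, config))


def generate_session(latent: LatentAppraisal, layout: ArticleLayout,
                     config: GeneratorConfig, rng: np.random.Generator,
                     profile: ParticipantProfile | None = None
                     ) -> pd.DataFrame:
    """Render one reading session to raw 60 Hz samples.

    A word-by-word scanpath is drawn over the layout's word slots:
    lognormal fixation durations, Bernoulli word skips, Bernoulli
    regressions (a one-fixation revisit of a recently read word), and
    line-return sweeps implicit in the word geometry. Fixations are
    rendered as runs of samples with sub-dispersion positional jitter;
    saccades as 1-3 interpolated transition samples; blinks as runs of
    (0, 0) samples. Session-level multipliers derived from the latent
    appraisals scale durations, skip rate, regression rate, and pupil
    drift amplitude (signs per ``config.effect_directions``).
    """
    if len(layout.line_boxes) == 0:
        raise ValueError("layout has zero text lines")
    profile = profile or ParticipantProfile()
    dt_ms = 1000.0 / config.sample_rate
    b = latent.block_id

    m_dur = (_channel(latent, config, "fixation_duration")
             * _channel(latent, config, "reading_time")
             * profile.speed * profile.block_factor("block_tempo", b)
             * math.exp(SESSION_TEMPO_SD * rng.standard_normal()))
    p_skip = min(0.6, BASE_SKIP_PROB * profile.skip_tendency
                 * profile.block_factor("block_skip", b)
                 * _channel(latent, config, "saccade_amplitude"))
    p_reg = min(0.5, BASE_REGRESSION_PROB * profile.regression_tendency
                * profile.block_factor("block_regression", b)
                * _channel(latent, config, "regression_prob"))
    m_pupil_var = (_channel(latent, config, "pupil_variance")
                   * profile.block_factor("block_pupil", b)
                   * math.exp(0.1 * rng.standard_normal()))
    # skipping readers save fixations but dwell slightly longer per word
    # (parafoveal preview); this keeps the skip channel from leaking into
    # total reading time
    m_dur *= ((1.0 - BASE_SKIP_PROB) / (1.0 - p_skip)) ** 0.8

    n_total = len(layout.word_x)
    u_skip = rng.random(n_total)
    # title words are always read; body words may be skipped
    fixated = np.flatnonzero(
        (np.arange(n_total) < layout.n_title_words) | (u_skip >= p_skip))
    if len(fixated) == 0:
        fixated = np.array([0])

    # weave in regressions: after reading word k, optionally revisit a word
    # 1-7 positions back before moving on
    u_reg = rng.random(len(fixated))
    back = rng.integers(1, 8, size=len(fixated))
    seq: list[int] = []
    for pos, wi in enumerate(fixated):
        seq.append(int(wi))
        if pos >= 2 and u_reg[pos] < p_reg:
            seq.append(int(fixated[max(0, pos - back[pos])]))
    order = np.asarray(seq)

    fx = layout.word_x[order] + np.clip(
        FIX_JITTER_PX * 2.0 * rng.standard_normal(len(order)), -8, 8)
    fy = layout.word_y[order] + np.clip(
        FIX_JITTER_PX * 2.0 * rng.standard_normal(len(order)), -6, 6)
    dur = (BASE_FIX_MEDIAN_MS * m_dur
           * np.exp(FIX_SIGMA_LOG * rng.standard_normal(len(order))))

    # render to samples: fixations as repeated positions, saccades as 1-3
    # transition samples (count stochastic in amplitude, emulating the
    # main-sequence duration-amplitude relation at a 60 Hz sampling grid)
    m_fix = len(order)
    n_fix_samp = np.maximum(1, np.rint(dur / dt_ms).astype(int))
    amp = np.hypot(np.diff(fx), np.diff(fy))
    n_mid = (1 + (rng.random(m_fix - 1) < np.clip(amp / 900.0, 0, 0.9))
             + (amp > 900)).astype(int)

    block_sizes = n_fix_samp.copy()
    block_sizes[:-1] += n_mid
    block_starts = np.concatenate(([0], np.cumsum(block_sizes)[:-1]))
    n = int(np.sum(block_sizes))
    x = np.empty(n)
    y = np.empty(n)

    fix_owner = np.repeat(np.arange(m_fix), n_fix_samp)
    fix_starts = np.concatenate(([0], np.cumsum(n_fix_samp)[:-1]))
    within = np.arange(len(fix_owner)) - fix_starts[fix_owner]
    fix_pos = block_starts[fix_owner] + within
    x[fix_pos] = fx[fix_owner] + np.clip(
        FIX_JITTER_PX * rng.standard_normal(len(fix_owner)), -4, 4)
    y[fix_pos] = fy[fix_owner] + np.clip(
        FIX_JITTER_PX * rng.standard_normal(len(fix_owner)), -4, 4)

    if m_fix > 1:
        t_owner = np.repeat(np.arange(m_fix - 1), n_mid)
        t_starts = np.concatenate(([0], np.cumsum(n_mid)[:-1]))
        t_within = np.arange(len(t_owner)) - t_starts[t_owner]
        # irregular crossing fractions decouple transit speed from pure
        # amplitude scaling
        frac = ((t_within + 1.0) / (n_mid[t_owner] + 1.0)
                + rng.uniform(-0.15, 0.15, size=len(t_owner)))
        t_pos = block_starts[t_owner] + n_fix_samp[t_owner] + t_within
        x[t_pos] = fx[t_owner] + frac * (fx[t_owner + 1] - fx[t_owner])
        y[t_pos] = fy[t_owner] + frac * (fy[t_owner + 1] - fy[t_owner])
    # sub-millisecond timestamp jitter, as real tracker clocks show; keeps
    # event durations off the exact sample-interval lattice
    t = np.arange(n) * dt_ms + rng.uniform(-0.4, 0.4, size=n)
    t[0] = abs(t[0])

    # pupil: per-eye baseline + slow drift (variance channel) + white noise
    drift = np.zeros(n)
    for a, period in zip(PUPIL_DRIFT_AMP, PUPIL_DRIFT_PERIOD_S):
        phase = rng.uniform(0, 2 * math.pi)
        drift += a * np.sin(2 * math.pi * t / (period * 1000.0) + phase)
    drift *= profile.pupil_scale * math.sqrt(m_pupil_var)
    pl = (profile.pupil_base_left + drift
          + PUPIL_WHITE_SD * rng.standard_normal(n))
    pr = (profile.pupil_base_right + drift
          + PUPIL_WHITE_SD * rng.standard_normal(n))

    lx = x - EYE_OFFSET_PX + EYE_NOISE_PX * rng.standard_normal(n)
    ly = y + EYE_NOISE_PX * rng.standard_normal(n)
    rx = x + EYE_OFFSET_PX + EYE_NOISE_PX * rng.standard_normal(n)
    ry = y + EYE_NOISE_PX * rng.standard_normal(n)

    # blinks: Poisson arrivals, uniform 100-400 ms closures, encoded as
    # (0, 0) positions with zero pupil
    total_min = n * dt_ms / 60000.0
    n_blinks = rng.poisson(config.blink_rate_per_min * total_min)
    for _ in range(n_blinks):
        b_dur = rng.uniform(*BLINK_DUR_RANGE_MS)
        b_start = rng.uniform(0, max(dt_ms, n * dt_ms - b_dur))
        sl = (t >= b_start) & (t < b_start + b_dur)
        lx[sl] = ly[sl] = rx[sl] = ry[sl] = 0.0
        pl[sl] = pr[sl] = 0.0

    return pd.DataFrame({
        "time_ms": t,
        "left_x_px": lx, "left_y_px": ly,
        "right_x_px": rx, "right_y_px": ry,
        "left_pupil_px": pl, "right_pupil_px": pr,
    })


# ---------------------------------------------------------------------------
# Whole study


def _block_design(config: GeneratorConfig, rng: np.random.Generator):
    """Counterbalanced block design: articles are grouped into blocks (by
    emulated topical familiarity); block order rotates across participants;
    article order within a block is randomized per participant."""
    n_art, n_blocks = config.n_articles, config.n_blocks
    per_block = [n_art // n_blocks + (1 if b < n_art % n_blocks else 0)
                 for b in range(n_blocks)]
    blocks = []
    start = 0
    for size in per_block:
        blocks.append(list(range(start, start + size)))
        start += size
    design = {}
    for p in range(config.n_participants):
        order = []
        rotation = [(b + p) % n_blocks for b in range(n_blocks)]
        for b in rotation:
            arts = list(blocks[b])
            rng.shuffle(arts)
            order.extend((a, b) for a in arts)
        design[p] = order  # list of (article, block) in presentation order
    return design


def generate_study(config: GeneratorConfig | None = None,
                   rng_seed: int | None = None) -> SyntheticStudy:
    """Generate a full synthetic study: layouts, latents, gaze streams and
    questionnaire records. Deterministic given the configuration seed.

    Gaze streams are absent for dropout participants (their questionnaire
    records remain), and ``n_partial_sessions`` randomly chosen sessions
    are truncated after ~3 s of tracking.
    """
    config = config or GeneratorConfig()
    if rng_seed is not None:
        config = GeneratorConfig(**{**config.__dict__,
                                    "rng_seed": rng_seed,
                                    "effect_directions":
                                        dict(config.effect_directions),
                                    "item_intercorrelation":
                                        dict(config.item_intercorrelation)})
    rng = np.random.default_rng(config.rng_seed)

    # One page template shared by all articles: the emulated stimuli are
    # identically formatted 1,200-character truncations, and a shared
    # template keeps article identity out of the gaze features (appraisal
    # effects act at the session level).
    template = generate_layout(0, rng)
    layouts = {a: template for a in range(config.n_articles)}
    design = _block_design(config, rng)

    # latent appraisals: standardized bivariate normal per session
    rho = config.latent_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)

    profiles = {}
    nb = config.n_blocks
    ts = TRAIT_SD
    bs = BLOCK_SD
    for p in range(config.n_participants):
        profiles[p] = ParticipantProfile(
            speed=math.exp(ts * rng.standard_normal()),
            pupil_base_left=28.0 + 2.5 * rng.standard_normal(),
            pupil_base_right=28.0 + 2.5 * rng.standard_normal(),
            pupil_scale=math.exp(ts * rng.standard_normal()),
            skip_tendency=math.exp(ts * rng.standard_normal()),
            regression_tendency=math.exp(ts * rng.standard_normal()),
            block_tempo=tuple(np.exp(bs * rng.standard_normal(nb))),
            block_skip=tuple(np.exp(bs * rng.standard_normal(nb))),
            block_regression=tuple(np.exp(bs * rng.standard_normal(nb))),
            block_pupil=tuple(np.exp(bs * rng.standard_normal(nb))),
        )

    n_drop = int(round(config.dropout_rate * config.n_participants))
    dropped = sorted(rng.choice(config.n_participants, size=n_drop,
                                replace=False).tolist()) if n_drop else []

    latent_rows = []
    latents: dict[tuple[int, int], LatentAppraisal] = {}
    for p in range(config.n_participants):
        for order_i, (a, b) in enumerate(design[p]):
            z = chol @ rng.standard_normal(2)
            lat = LatentAppraisal(participant_id=p, article_id=a, block_id=b,
                                  comprehensibility=float(z[0]),
                                  interest=float(z[1]))
            latents[(p, a)] = lat
            latent_rows.append((p, a, b, order_i + 1,
                                lat.comprehensibility, lat.interest))
    latent_df = pd.DataFrame(latent_rows, columns=[
        "participant", "article", "block", "presentation_order",
        "comprehensibility_latent", "interest_latent"])

    eligible = [(p, a) for p in range(config.n_participants)
                if p not in dropped for a, _ in design[p]]
    n_partial = min(config.n_partial_sessions, len(eligible))
    partial_idx = rng.choice(len(eligible), size=n_partial, replace=False)
    partial = sorted(eligible[i] for i in partial_idx)
    partial_cut_s = {key: rng.uniform(2.5, 4.0) for key in partial}

    gaze: dict[tuple[int, int], pd.DataFrame] = {}
    rating_rows = []
    for p in range(config.n_participants):
        for order_i, (a, b) in enumerate(design[p]):
            lat = latents[(p, a)]
            session_rng = np.random.default_rng(
                int(rng.integers(0, 2 ** 31 - 1)))
            items = generate_ratings(lat, config.item_intercorrelation,
                                     session_rng)
            rating_rows.append({"participant": p, "article": a, "block": b,
                                "presentation_order": order_i + 1, **items})
            if p in dropped:
                continue
            stream = generate_session(lat, layouts[a], config, session_rng,
                                      profiles[p])
            if (p, a) in partial_cut_s:
                cut_ms = partial_cut_s[(p, a)] * 1000.0
                stream = stream[stream["time_ms"] < cut_ms].reset_index(
                    drop=True)
            gaze[(p, a)] = stream
    ratings = pd.DataFrame(rating_rows)

    return SyntheticStudy(
        config=config, layouts=layouts, latents=latent_df, ratings=ratings,
        gaze=gaze, reverse_coded=reverse_coding_map(),
        dropped_participants=dropped, partial_sessions=partial)
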