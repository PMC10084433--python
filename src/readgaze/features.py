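"""Session-level feature extraction from detected oculomotor events.

The processing order follows the analysis pipeline: detect events ->
outlier removal per feature over the whole event pool (4 x IQR, anchored
at the second quartile below and the third above) -> area-of-interest
filtering -> per-session aggregation (count, mean, variance, skewness,
kurtosis) -> baseline normalization (median subtraction per participant,
annotated ``_a``, and per participant x block, annotated ``_b``).

Coefficient K (Krejtz et al.) contrasts focal and ambient visual
processing: for each fixation i followed by a non-blink saccade,
K_i = (d_i - mu_d)/sigma_d - (a_{i+1} - mu_a)/sigma_a, standardized by the
participant's own fixation-duration and saccade-amplitude statistics.
K > 0 marks focal (long fixation, short saccade), K < 0 ambient
processing. Because K is already participant-standardized it needs no
baseline subtraction, but re-centered ``_a``/``_b`` variants are emitted
alongside for parity with the other families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import events as ev

logger = logging.getLogger(__name__)

SESSION_KEYS = ["participant", "article"]

#: feature family -> (statistics emitted, units)
FEATURE_FAMILIES = {
    "reading_time": ("value", "s"),
    "fix_dur": ("moments", "ms"),
    "pupil": ("moments", "px"),
    "sac_amp": ("moments", "deg"),
    "sac_dur": ("moments", "ms"),
    "sac_speed": ("moments", "deg/s"),
    "reg_amp": ("moments", "deg"),
    "reg_dur": ("moments", "ms"),
    "reg_speed": ("moments", "deg/s"),
    "k": ("moments", ""),
}


# ---------------------------------------------------------------------------
# Primitive operations


def iqr_filter(values, multiplier: float = 4.0,
               warn_fraction: float = 0.2) -> np.ndarray:
    """Boolean retention mask under the lenient asymmetric IQR rule.

    A value is an outlier when it lies more than ``multiplier`` * IQR below
    the SECOND quartile or above the THIRD quartile (IQR = Q3 - Q1,
    quartiles by linear interpolation). Pools with fewer than 4 finite
    values pass through unfiltered. NaNs are never retained.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        return finite
    q1, q2, q3 = np.percentile(v[finite], [25, 50, 75])
    iqr = q3 - q1
    keep = finite & (v >= q2 - multiplier * iqr) & (v <= q3 + multiplier * iqr)
    removed = 1.0 - keep.sum() / finite.sum()
    if removed > warn_fraction:
        logger.warning("IQR filter removed %.1f%% of values (alarm at %.0f%%)",
                       100 * removed, 100 * warn_fraction)
    return keep


def moments(values) -> dict:
    """count / mean / sample variance / skewness (g1) / excess kurtosis (g2).

    Variance uses the n-1 denominator; g1 and g2 are the third and fourth
    standardized moments without small-sample bias correction (g2 has 3
    subtracted, so a normal distribution scores 0). Statistics whose
    minimum sample size is not met (var 2, skew 3, kurt 4) — or that are
    undefined because the values are constant — come back as NaN.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = len(v)
    out = {"count": n, "mean": np.nan, "var": np.nan,
           "skew": np.nan, "kurt": np.nan}
    if n == 0:
        return out
    mean = float(np.mean(v))
    out["mean"] = mean
    if n >= 2:
        out["var"] = float(np.var(v, ddof=1))
    m2 = float(np.mean((v - mean) ** 2))
    if m2 > 0:
        z = (v - mean) / np.sqrt(m2)
        if n >= 3:
            out["skew"] = float(np.mean(z ** 3))
        if n >= 4:
            out["kurt"] = float(np.mean(z ** 4) - 3.0)
    return out


def reading_time(fixations: pd.DataFrame) -> float:
    """Seconds between the first fixation's onset and the last fixation's
    offset in a session; NaN when the session has no fixations."""
    if len(fixations) == 0:
        return float("nan")
    return float((fixations["offset_ms"].iloc[-1]
                  - fixations["onset_ms"].iloc[0]) / 1000.0)


@dataclass(frozen=True)
class KContext:
    """Participant-level standardization constants for Coefficient K."""

    mu_d: float
    sigma_d: float
    mu_a: float
    sigma_a: float

    @classmethod
    def from_pairs(cls, durations_ms, amplitudes_deg) -> "KContext":
        d = np.asarray(durations_ms, float)
        a = np.asarray(amplitudes_deg, float)
        return cls(mu_d=float(np.mean(d)), sigma_d=float(np.std(d, ddof=1)),
                   mu_a=float(np.mean(a)), sigma_a=float(np.std(a, ddof=1)))

    @property
    def valid(self) -> bool:
        return self.sigma_d > 0 and self.sigma_a > 0


def coefficient_k(durations_ms, amplitudes_deg, ctx: KContext) -> np.ndarray:
    """Per-pair K values: standardized fixation duration minus standardized
    amplitude of the following non-blink saccade."""
    if not ctx.valid:
        raise ValueError("KContext sigmas must be > 0")
    d = np.asarray(durations_ms, float)
    a = np.asarray(amplitudes_deg, float)
    return (d - ctx.mu_d) / ctx.sigma_d - (a - ctx.mu_a) / ctx.sigma_a


def normalize(table: pd.DataFrame, feature_cols, scope_cols) -> pd.DataFrame:
    """Median-baseline normalization: subtract, per feature, the median over
    the sessions sharing ``scope_cols`` (participant for the ``_a``
    variant, participant + block for ``_b``). Medians ignore NaN."""
    g = table.groupby(list(scope_cols), dropna=False)
    out = {}
    for col in feature_cols:
        out[col] = table[col] - g[col].transform("median")
    return pd.DataFrame(out, index=table.index)


# ---------------------------------------------------------------------------
# Event extraction across a study


def extract_study_events(gaze: dict, aois_by_article: dict,
                         blocks: dict | None = None,
                         geometry: ev.ScreenGeometry | None = None,
                         min_duration_ms: float = 80.0,
                         dispersion_deg: float = 1.0,
                         regression_threshold_px: float = 20.0):
    """Detect fixations and saccades for every session and pool them.

    ``gaze`` maps (participant, article) to a raw sample DataFrame;
    ``aois_by_article`` maps article to its AOI rectangles; ``blocks``
    optionally maps (participant, article) to a block id. AOI labels are
    attached here but only APPLIED later, after pool-level IQR filtering,
    preserving the pipeline's stage order.

    Returns (fixation pool, saccade pool, sessions table).
    """
    geometry = geometry or ev.ScreenGeometry()
    fix_parts, sac_parts, session_rows = [], [], []
    for (p, a), stream in gaze.items():
        fix = ev.detect_fixations(stream, geometry, min_duration_ms,
                                  dispersion_deg)
        sac = ev.derive_saccades(fix, stream, geometry,
                                 regression_threshold_px)
        block = blocks.get((p, a), 0) if blocks else 0
        fix_parts.append(fix)
        sac_parts.append(sac)
        session_rows.append((p, a, block, len(fix), len(sac)))
    sessions = pd.DataFrame(
        [r[:3] for r in session_rows],
        columns=["participant", "article", "block"])

    def _pool(parts, counts):
        pool = pd.concat(parts, ignore_index=True) if parts else \
            pd.DataFrame()
        counts = np.asarray(counts)
        for j, col in enumerate(("participant", "article", "block")):
            pool[col] = np.repeat([r[j] for r in session_rows], counts)
        # within-session event index (0..n_i-1 per session)
        offs = np.repeat(np.cumsum(counts) - counts, counts)
        pool["fix_index"] = np.arange(len(pool)) - offs
        return pool

    fixations = _pool(fix_parts, [r[3] for r in session_rows])
    saccades = _pool(sac_parts, [r[4] for r in session_rows]).drop(
        columns="fix_index")

    # AOI labels, vectorized per article
    label = np.full(len(fixations), "none", dtype=object)
    if len(fixations):
        fx = fixations["centroid_x_px"].to_numpy(float)
        fy = fixations["centroid_y_px"].to_numpy(float)
        art = fixations["article"].to_numpy()
        for a, aois in aois_by_article.items():
            in_art = art == a
            if not in_art.any():
                continue
            for name, rect in aois.items():
                x0, y0, x1, y1 = rect
                hit = (in_art & (label == "none")
                       & (fx >= x0) & (fx < x1) & (fy >= y0) & (fy < y1))
                label[hit] = name
    fixations["aoi_label"] = label
    return fixations, saccades, sessions


# ---------------------------------------------------------------------------
# Feature table assembly


def _agg(pool: pd.DataFrame, value_col: str, prefix: str,
         index: pd.MultiIndex) -> pd.DataFrame:
    """Per-session count/mean/var/skew/kurt of one event-value pool.

    Vectorized equivalent of applying :func:`moments` per session group
    (asserted equal in the tests).
    """
    cols = [f"{prefix}_{s}" for s in ("count", "mean", "var", "skew", "kurt")]
    if len(pool) == 0:
        out = pd.DataFrame(index=index, columns=cols, dtype=float)
        out[cols[0]] = 0
        return out
    df = pool[SESSION_KEYS].copy()
    df["v"] = pool[value_col].to_numpy(float)
    gb = df.groupby(SESSION_KEYS)["v"]
    cnt = gb.count()
    mean = gb.mean()
    var = gb.var(ddof=1)
    c = df["v"] - gb.transform("mean")
    df["c2"] = c * c
    df["c3"] = df["c2"] * c
    df["c4"] = df["c2"] * df["c2"]
    s = df.groupby(SESSION_KEYS)[["c2", "c3", "c4"]].sum()
    m2 = s["c2"] / cnt
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = (s["c3"] / cnt) / m2 ** 1.5
        kurt = (s["c4"] / cnt) / (m2 * m2) - 3.0
    skew[(cnt < 3) | (m2 <= 0)] = np.nan
    kurt[(cnt < 4) | (m2 <= 0)] = np.nan
    out = pd.DataFrame({cols[0]: cnt, cols[1]: mean, cols[2]: var,
                        cols[3]: skew, cols[4]: kurt}).reindex(index)
    out[cols[0]] = out[cols[0]].fillna(0).astype(int)
    return out


def build_feature_table(fixations: pd.DataFrame, saccades: pd.DataFrame,
                        sessions: pd.DataFrame,
                        ratings: pd.DataFrame | None = None,
                        iqr_multiplier: float = 4.0):
    """Assemble the sessions x features study table.

    Stage order: pool-level IQR outlier removal per feature family ->
    AOI filtering -> Coefficient K (participant-standardized) -> session
    aggregation -> median-baseline normalization. One row per session with
    gaze data; sessions whose pools are too small for some statistic carry
    NaN there (never silently dropped). When ``ratings`` is given the
    questionnaire scale scores are merged in.

    Returns (table, manifest); the manifest records the emitted feature
    columns (family / statistic / normalization / units) and the event
    counts surviving each stage.
    """
    index = pd.MultiIndex.from_frame(sessions[SESSION_KEYS])
    counts: dict[str, int] = {}

    fix = fixations.copy()
    counts["fixations_detected"] = len(fix)
    fix_keep_dur = iqr_filter(fix["duration_ms"], iqr_multiplier) \
        if len(fix) else np.zeros(0, bool)
    pupil_keep = iqr_filter(fix["mean_pupil_px"], iqr_multiplier) \
        if len(fix) else np.zeros(0, bool)
    counts["fixations_post_iqr"] = int(fix_keep_dur.sum())

    sac = saccades[~saccades["is_blink"]].copy() if len(saccades) else \
        saccades.copy()
    counts["saccades_detected"] = len(sac)
    if len(sac):
        sac_keep = (iqr_filter(sac["amplitude_deg"], iqr_multiplier)
                    & iqr_filter(sac["duration_ms"], iqr_multiplier)
                    & iqr_filter(sac["peak_speed_deg_s"], iqr_multiplier))
    else:
        sac_keep = np.zeros(0, bool)
    counts["saccades_post_iqr"] = int(sac_keep.sum())

    reg = sac[sac["is_regression"]] if len(sac) else sac
    counts["regressions_detected"] = len(reg)
    if len(reg):
        reg_keep = (iqr_filter(reg["amplitude_deg"], iqr_multiplier)
                    & iqr_filter(reg["duration_ms"], iqr_multiplier)
                    & iqr_filter(reg["peak_speed_deg_s"], iqr_multiplier))
    else:
        reg_keep = np.zeros(0, bool)
    counts["regressions_post_iqr"] = int(reg_keep.sum())

    in_aoi = (fix["aoi_label"] != "none").to_numpy() if len(fix) else \
        np.zeros(0, bool)
    fix_final = fix[fix_keep_dur & in_aoi]
    pupil_final = fix[pupil_keep & in_aoi]
    counts["fixations_post_aoi"] = len(fix_final)

    if len(sac):
        # AOI rule: both bounding fixations inside an AOI
        fix_lab = fix[SESSION_KEYS + ["fix_index"]].copy()
        fix_lab["in_aoi"] = in_aoi
        merged = sac[SESSION_KEYS + ["fix_from", "fix_to"]].merge(
            fix_lab.rename(columns={"fix_index": "fix_from",
                                    "in_aoi": "aoi_from"}),
            on=SESSION_KEYS + ["fix_from"], how="left").merge(
            fix_lab.rename(columns={"fix_index": "fix_to",
                                    "in_aoi": "aoi_to"}),
            on=SESSION_KEYS + ["fix_to"], how="left")
        aoi_ok = (merged["aoi_from"].fillna(False)
                  & merged["aoi_to"].fillna(False)).to_numpy(bool)
        sac_final = sac[sac_keep & aoi_ok]
        reg_mask_final = reg_keep & aoi_ok[sac["is_regression"].to_numpy()]
        reg_final = reg[reg_mask_final]
    else:
        sac_final = sac
        reg_final = reg
    counts["saccades_post_aoi"] = len(sac_final)
    counts["regressions_post_aoi"] = len(reg_final)

    k_pool = _k_samples(fix, fix_keep_dur & in_aoi, sac,
                        sac_keep & aoi_ok if len(sac) else sac_keep)
    counts["k_samples"] = len(k_pool)
    if len(k_pool):
        k_keep = iqr_filter(k_pool["k"], iqr_multiplier)
        k_pool = k_pool[k_keep]
    counts["k_samples_post_iqr"] = len(k_pool)

    parts = [
        _agg(fix_final, "duration_ms", "fix_dur", index),
        _agg(pupil_final, "mean_pupil_px", "pupil", index),
        _agg(sac_final, "amplitude_deg", "sac_amp", index),
        _agg(sac_final, "duration_ms", "sac_dur", index),
        _agg(sac_final, "peak_speed_deg_s", "sac_speed", index),
        _agg(reg_final, "amplitude_deg", "reg_amp", index),
        _agg(reg_final, "duration_ms", "reg_dur", index),
        _agg(reg_final, "peak_speed_deg_s", "reg_speed", index),
        _agg(k_pool, "k", "k", index),
    ]
    table = pd.concat(parts, axis=1)

    if len(fix_final):
        g = fix_final.groupby(SESSION_KEYS)
        rt = (g["offset_ms"].max() - g["onset_ms"].min()) / 1000.0
    else:
        rt = pd.Series(dtype=float)
    table["reading_time"] = rt.reindex(index)

    # counts: single count per family; drop the per-statistic duplicates
    table = table.rename(columns={"fix_dur_count": "fixation_count",
                                  "sac_amp_count": "saccade_count",
                                  "reg_amp_count": "regression_count"})
    table = table.drop(columns=[c for c in table.columns
                                if c.endswith("_count")
                                and c not in ("fixation_count",
                                              "saccade_count",
                                              "regression_count")])

    table = table.reset_index()
    table = table.merge(sessions, on=SESSION_KEYS, how="left")

    count_cols = ["fixation_count", "saccade_count", "regression_count"]
    feature_cols = [c for c in table.columns
                    if c not in SESSION_KEYS + ["block"] + count_cols]

    norm_a = normalize(table, feature_cols, ["participant"])
    norm_b = normalize(table, feature_cols, ["participant", "block"])
    for col in feature_cols:
        table[f"{col}_a"] = norm_a[col]
        table[f"{col}_b"] = norm_b[col]
    # absolute pupil size has no cross-person meaning: only the normalized
    # mean is kept (variance/skew/kurtosis stay in all variants)
    table = table.drop(columns=["pupil_mean"])

    manifest = {
        "stage_counts": counts,
        "features": _manifest_columns(table),
        "iqr_multiplier": iqr_multiplier,
        "quantile_convention": "linear interpolation",
        "n_sessions": len(table),
    }

    if ratings is not None:
        from . import models  # late import; models never imports features
        scores, alphas = models.score_scales(ratings)
        table = table.merge(
            scores[SESSION_KEYS + ["comprehensibility", "interest"]],
            on=SESSION_KEYS, how="left")
        manifest["cronbach_alpha"] = alphas
    return table, manifest


def _k_samples(fix: pd.DataFrame, fix_keep: np.ndarray, sac: pd.DataFrame,
               sac_keep: np.ndarray) -> pd.DataFrame:
    """Coefficient-K sample pool: (fixation, following non-blink saccade)
    pairs surviving the filters, standardized per participant by the
    statistics of that participant's own pair pool."""
    if len(fix) == 0 or len(sac) == 0:
        return pd.DataFrame(columns=SESSION_KEYS + ["k"])
    fixk = fix.loc[fix_keep, SESSION_KEYS + ["fix_index", "duration_ms"]]
    sck = sac.loc[sac_keep, SESSION_KEYS + ["fix_from", "amplitude_deg"]]
    pool = sck.merge(
        fixk.rename(columns={"fix_index": "fix_from", "duration_ms": "d"}),
        on=SESSION_KEYS + ["fix_from"], how="inner").rename(
        columns={"amplitude_deg": "a"})
    if len(pool) == 0:
        return pd.DataFrame(columns=SESSION_KEYS + ["k"])
    out = []
    for p, grp in pool.groupby("participant"):
        ctx = KContext.from_pairs(grp["d"], grp["a"])
        if not ctx.valid:
            logger.warning("participant %s has zero-variance K context; "
                           "excluded from K features", p)
            continue
        k = coefficient_k(grp["d"], grp["a"], ctx)
        out.append(pd.DataFrame({"participant": p,
                                 "article": grp["article"].to_numpy(),
                                 "k": k}))
    if not out:
        return pd.DataFrame(columns=SESSION_KEYS + ["k"])
    return pd.concat(out, ignore_index=True)


def _manifest_columns(table: pd.DataFrame) -> dict:
    info = {}
    for col in table.columns:
        if col in SESSION_KEYS + ["block"]:
            continue
        base = col
        normalization = "raw"
        if col.endswith("_a"):
            base, normalization = col[:-2], "participant_median"
        elif col.endswith("_b"):
            base, normalization = col[:-2], "participant_block_median"
        if base in ("fixation_count", "saccade_count", "regression_count"):
            family, stat, units = base.split("_")[0], "count", ""
        elif base == "reading_time":
            family, stat, units = "reading_time", "value", "s"
        else:
            family, _, stat = base.rpartition("_")
            units = FEATURE_FAMILIES.get(family, ("", ""))[1]
        info[col] = {"family": family, "statistic": stat,
                     "normalization": normalization, "units": units}
    return info
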