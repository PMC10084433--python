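import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import readgaze as rg

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> rg.GeneratorConfig:
    """4 readers x 6 articles, one dropout candidate disabled, one
    truncated session — small enough for unit tests, rich enough to hit
    every pipeline branch."""
    return rg.GeneratorConfig(n_participants=4, n_articles=6,
                              dropout_rate=0.0, n_partial_sessions=1,
                              rng_seed=42)


@pytest.fixture(scope="session")
def small_study(small_config) -> rg.SyntheticStudy:
    return rg.generate_study(small_config)


@pytest.fixture(scope="session")
def small_events(small_study):
    aois = {a: lay.aois for a, lay in small_study.layouts.items()}
    blocks = {(r.participant, r.article): r.block
              for r in small_study.latents.itertuples()}
    return rg.extract_study_events(small_study.gaze, aois, blocks=blocks)


@pytest.fixture(scope="session")
def small_table(small_study, small_events):
    fixations, saccades, sessions = small_events
    return rg.build_feature_table(fixations, saccades, sessions,
                                  ratings=small_study.ratings)


@pytest.fixture()
def geometry() -> rg.ScreenGeometry:
    return rg.ScreenGeometry()


def make_stream(segments, dt_ms=1000.0 / 60.0, pupil=25.0):
    """Construct a gaze stream from (x, y, n_samples) segments; (0, 0)
    segments become blink rows (pupil 0)."""
    rows = []
    t = 0.0
    for x, y, n in segments:
        for _ in range(n):
            p = 0.0 if (x == 0 and y == 0) else pupil
            rows.append((t, x, y, x, y, p, p))
            t += dt_ms
    return pd.DataFrame(rows, columns=[
        "time_ms", "left_x_px", "left_y_px", "right_x_px", "right_y_px",
        "left_pupil_px", "right_pupil_px"])


@pytest.fixture()
def stream_factory():
    return make_stream


def idt_oracle(t, x, y, blink, disp_px, min_dur_ms, max_gap_ms):
    """Brute-force dispersion grouping: for each window start, scan forward
    recomputing the bounding-box dispersion from scratch over the whole
    candidate window; emit maximal runs that satisfy the minimum span."""
    out = []
    n = len(t)
    i = 0
    while i < n:
        if blink[i]:
            i += 1
            continue
        j = i
        while j + 1 < n:
            k = j + 1
            if blink[k] or (t[k] - t[j]) > max_gap_ms:
                break
            xs = x[i:k + 1]
            ys = y[i:k + 1]
            if (max(xs) - min(xs)) + (max(ys) - min(ys)) > disp_px:
                break
            j = k
        if t[j] - t[i] >= min_dur_ms:
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


@pytest.fixture()
def fixation_oracle():
    return idt_oracle


def iqr_oracle(values, multiplier=4.0):
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        return finite
    q1, q2, q3 = np.percentile(v[finite], [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q2 - multiplier * iqr, q3 + multiplier * iqr
    return np.array([np.isfinite(val) and lo <= val <= hi for val in v])


@pytest.fixture()
def iqr_brute():
    return iqr_oracle
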