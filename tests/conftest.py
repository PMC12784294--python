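import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ramantag.phantom import PhantomSpec, make_phantom
from ramantag.preprocess import preprocess_cube

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def small_spec(**overrides) -> PhantomSpec:
    """A 40x40 phantom: fast enough for unit tests, same structure as default."""
    base = dict(
        grid_rows=40,
        grid_cols=40,
        cell_ellipse=(20, 20, 16, 17),
        nucleus_ellipse=(20, 19, 6, 7),
        droplet_count=5,
        droplet_radius_px=2.5,
        seed=5,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def phantom_small():
    return make_phantom(small_spec())


@pytest.fixture(scope="session")
def processed_small(phantom_small):
    cube, truth = phantom_small
    processed, report = preprocess_cube(cube)
    return processed, truth, report


def sample_annotation(class_map: np.ndarray, rng: np.random.Generator, frac: float = 0.3):
    """Partial annotation: a seeded random subset of truth labels, 0 elsewhere."""
    ann = np.zeros_like(class_map)
    sel = rng.random(class_map.shape) < frac
    ann[sel] = class_map[sel]
    return ann


def naive_snip(y: np.ndarray, iterations: int) -> np.ndarray:
    """Independent straightforward SNIP oracle (scalar loops, edge clamping)."""
    b = [float(v) for v in y]
    n = len(b)
    for p in range(1, iterations + 1):
        nxt = list(b)
        for i in range(n):
            lo = b[max(i - p, 0)]
            hi = b[min(i + p, n - 1)]
            nxt[i] = min(b[i], 0.5 * (lo + hi))
        b = nxt
    return np.array(b)


def modified_z_scores(x: np.ndarray) -> np.ndarray:
    """Brute-force modified z-scores of first differences, aligned so that
    channel i (i >= 1) owns d_i = x_i - x_{i-1}; channel 0 is never flagged."""
    d = np.diff(np.asarray(x, dtype=float))
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    if mad == 0:
        return np.zeros(x.size)
    z = np.zeros(x.size)
    z[1:] = 0.6745 * (d - med) / mad
    return z
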