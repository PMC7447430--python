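import matplotlib
import numpy as np
import pytest
from hypothesis import settings

matplotlib.use("Agg")

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from recruitkit.synthetic_data import (
    GuvSimSpec,
    RecruitmentKinetics,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def single_ring_spec():
    """One noiseless vesicle with distinct lumen/exterior backgrounds."""
    return GuvSimSpec(
        image_shape=(96, 96),
        vesicles=[(48.0, 48.0, 18.0)],
        membrane_sigma=3.5,
        membrane_amplitude=100.0,
        protein_amplitude=80.0,
        kinetics=RecruitmentKinetics(model="constant", value=1.0),
        lumen_background=1.0,
        exterior_background=3.0,
        noise_sigma=0.0,
        frame_times_min=[0.0],
        seed=0,
    )


def local_contrast_oracle(image: np.ndarray, radius: int) -> np.ndarray:
    """Brute-force sliding-window max-minus-min with a Euclidean disk and
    edge replication, written as explicit loops independent of the
    implementation's filter-based path."""
    h, w = image.shape
    offsets = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    out = np.empty((h, w), dtype=float)
    for i in range(h):
        for j in range(w):
            vals = [
                image[min(max(i + dr, 0), h - 1), min(max(j + dc, 0), w - 1)]
                for dr, dc in offsets
            ]
            out[i, j] = max(vals) - min(vals)
    return out


def otsu_oracle(values: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive scan over all candidate histogram cuts, maximizing the
    between-class variance in exact rational arithmetic (ties resolve to the
    lowest cut).  With weights w0, w1 and first-class mass S0 of total S,
    w0*w1*(mu0-mu1)^2 == (S0*W - S*w0)^2 / (w0*w1), evaluated with Fractions
    so the comparison is exact."""
    from fractions import Fraction

    v = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(v, bins=nbins, range=(v.min(), v.max()))
    centers = [Fraction(c) for c in (0.5 * (edges[:-1] + edges[1:]))]
    n = [int(c) for c in counts]
    total = sum(n)
    mass_total = sum(Fraction(ni) * ci for ni, ci in zip(n, centers))
    best_var, best_k = None, None
    w0, s0 = 0, Fraction(0)
    for k in range(1, nbins):
        w0 += n[k - 1]
        s0 += n[k - 1] * centers[k - 1]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        var = (s0 * total - mass_total * w0) ** 2 / (w0 * w1)
        if best_var is None or var > best_var:
            best_var, best_k = var, k
    return float(edges[best_k])
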