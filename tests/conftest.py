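"""Shared fixtures and independent brute-force oracles.

The filter oracles below are deliberate nested-loop transliterations of the
filter definitions (LoG/Gabor kernel convolution, bilateral and trilateral
windowed means) — independent of the vectorised implementation paths they
check.  Boundary handling is mirror reflection without edge duplication,
matching the package convention.
"""

import numpy as np
import pytest

import mpfusion as mp
from mpfusion.filters import LAPLACIAN_STENCIL, log_kernel, gabor_real


# ---------------------------------------------------------------------------
# brute-force filter oracles


def bf_convolve(image, kernel):
    """Direct-sum 2D convolution with mirror boundary."""
    R = kernel.shape[0] // 2
    padded = np.pad(image, R, mode="reflect")
    H, W = image.shape
    out = np.zeros_like(image, dtype=float)
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for u in range(-R, R + 1):
                for v in range(-R, R + 1):
                    acc += kernel[u + R, v + R] * padded[i - u + R, j - v + R]
            out[i, j] = acc
    return out


def bf_laplacian(image):
    return bf_convolve(image, LAPLACIAN_STENCIL)


def bf_bilateral(image, spec, laplacian_term=False):
    """Nested-loop windowed mean with spatial x range (x Laplacian) weights."""
    half = spec.window_N // 2
    padded = np.pad(image, half, mode="reflect")
    lap = bf_laplacian(image)
    lap_padded = np.pad(lap, half, mode="reflect")
    H, W = image.shape
    out = np.zeros_like(image, dtype=float)
    for i in range(H):
        for j in range(W):
            num = den = 0.0
            for dx in range(-half, half + 1):
                for dy in range(-half, half + 1):
                    I_r = padded[i + dx + half, j + dy + half]
                    w = np.exp(-(dx * dx + dy * dy) / (2 * spec.sigma_S**2))
                    w *= np.exp(-(I_r - image[i, j]) ** 2 / (2 * spec.sigma_R**2))
                    if laplacian_term:
                        L_r = lap_padded[i + dx + half, j + dy + half]
                        w *= np.exp(-(L_r - lap[i, j]) ** 2 / (2 * spec.sigma_L**2))
                    num += w * I_r
                    den += w
            out[i, j] = num / den
    return out


def bf_log(image, spec):
    return bf_convolve(image, log_kernel(spec.sigma))


def bf_gabor(image, spec):
    return bf_convolve(image, gabor_real(spec))


# ---------------------------------------------------------------------------
# shared phantom data


@pytest.fixture(scope="session")
def small_easy_vois():
    """~60 extracted VOIs from a 10-scan easy phantom set."""
    scans, annotations = mp.generate_dataset(10, 6, "easy", seed=7)
    objects = mp.build_consensus(annotations)
    scan_map = {s.scan_id: s for s in scans}
    return [mp.extract_voi(scan_map[o.source_scan], o) for o in objects]


@pytest.fixture(scope="session")
def benchmark():
    """The 604-object easy phantom benchmark with its 70/30 split."""
    scans, annotations = mp.generate_dataset(151, 4, "easy", seed=42)
    objects = mp.build_consensus(annotations)
    scan_map = {s.scan_id: s for s in scans}
    vois = [mp.extract_voi(scan_map[o.source_scan], o) for o in objects]
    train, test = mp.split_dataset(vois, 0.7, seed=0)
    return {"train": train, "test": test, "scans": scans}


@pytest.fixture(scope="session")
def benchmark_runs(benchmark):
    """Three seeded end-to-end fusion fits on the benchmark, with reports."""
    runs = []
    for seed in range(3):
        results = mp.train_mpf(benchmark["train"], seed=seed)
        runs.append({"results": results,
                     "report": results.evaluate(benchmark["test"])})
    return runs
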