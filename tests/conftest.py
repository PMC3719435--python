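import logging

import numpy as np
import pytest

from fibrospect import RunConfig, SyntheticConstructSpec, generate_fiber_image

# the default r_max (200 spectral px) intentionally exceeds the inscribed
# radius of the small test images; silence the per-call clipping notice
logging.getLogger("fibrospect.spectral").setLevel(logging.ERROR)


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def aligned_fiber_image():
    """Noise-free, highly concentrated fiber field at 20°."""
    spec = SyntheticConstructSpec(
        n_slices=1,
        orientation_schedule=[20.0],
        kappa=1e6,
        noise_model="none",
        seed=3,
    )
    img, truth = generate_fiber_image(spec, 0)
    return img, truth


def vonmises_axial_profile(mu_deg: float, kappa: float, n_bins: int = 180) -> np.ndarray:
    """Analytic axial von Mises density evaluated at bin centres, normalized."""
    centers = (np.arange(n_bins) + 0.5) * (180.0 / n_bins)
    w = np.exp(kappa * np.cos(2.0 * np.radians(centers - mu_deg)))
    return w / w.sum()


def brute_force_smallest_arc(weights: np.ndarray, mass_fraction: float):
    """Exhaustive scan over all (start, length) circular arcs; independent
    oracle for the smallest-arc search. Same definition: minimal length,
    then maximal mass, exact ties by start order cyclically from the peak."""
    n = len(weights)
    total = weights.sum()
    target = mass_fraction * total - 1e-12 * total
    peak = int(np.argmax(weights))
    for length in range(1, n + 1):
        candidates = []
        for k in range(n):
            start = (peak + k) % n
            mass = weights[(start + np.arange(length)) % n].sum()
            if mass >= target:
                candidates.append((start, mass))
        if candidates:
            best_mass = max(m for _, m in candidates)
            for start, mass in candidates:  # already in tie-break order
                if mass >= best_mass - 1e-12 * total:
                    return start, length
    return 0, n
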