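import numpy as np
import pytest

from ccvtrack.simulate import OpticsModel


@pytest.fixture
def clean_optics():
    """Noiseless optics on a small field."""
    return OpticsModel(
        psf_sigma=2.0, amplitude=100.0, background=10.0,
        read_noise_sigma=0.0, poisson_noise=False, image_shape=(64, 64),
    )


@pytest.fixture
def noisy_optics():
    """Realistic camera: Poisson shot noise + Gaussian read noise."""
    return OpticsModel(
        psf_sigma=2.0, amplitude=100.0, background=10.0,
        read_noise_sigma=5.0, poisson_noise=True, image_shape=(128, 128),
    )


def brute_force_msd(positions, frames):
    """Independent MSD oracle: double loop over all observed frame pairs."""
    positions = np.asarray(positions, float)
    frames = np.asarray(frames, int)
    sums, counts = {}, {}
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            tau = int(frames[j] - frames[i])
            sq = float(np.sum((positions[j] - positions[i]) ** 2))
            sums[tau] = sums.get(tau, 0.0) + sq
            counts[tau] = counts.get(tau, 0) + 1
    lags = sorted(sums)
    return (np.array(lags),
            np.array([sums[l] / counts[l] for l in lags]),
            np.array([counts[l] for l in lags]))
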