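"""Shared fixtures and independent brute-force oracles used across tests."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ecmorph import synthgen as sg


def angular_profile_oracle(spectrum, r_min, r_max, bin_deg):
    """Per-pixel loop implementation of the angular mean: the reference
    against which the vectorized binning is checked."""
    rows, cols = spectrum.shape
    cy, cx = rows // 2, cols // 2
    n_bins = int(round(180.0 / bin_deg))
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for r in range(rows):
        for c in range(cols):
            dy, dx = r - cy, c - cx
            rad = math.hypot(dy, dx)
            if rad < r_min or rad > r_max:
                continue
            ang = math.degrees(math.atan2(dy, dx)) % 180.0
            b = min(int(ang // bin_deg), n_bins - 1)
            sums[b] += float(spectrum[r, c])
            counts[b] += 1
    return np.array(
        [s / n if n else math.nan for s, n in zip(sums, counts)]
    )


def bh_stepup_oracle(pvals, alpha):
    """Benjamini-Hochberg step-up implemented directly from its definition:
    find the largest k with p_(k) <= alpha*k/m and reject the k smallest."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    kmax = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= alpha * rank / m:
            kmax = rank
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:kmax]] = True
    return rejected


@pytest.fixture
def fiber_map_factory():
    """Height maps with oriented sinusoidal fiber texture."""

    def make(seed=0, theta=45.0, amplitude=30.0, noise_sd=0.0, shape=(128, 128)):
        cfg = sg.SynthConfig(
            seed=seed,
            image_shape=shape,
            fibers=[sg.FiberSpec(theta_deg=theta, period_um=1.25, amplitude_nm=amplitude)]
            if amplitude > 0
            else [],
            noise_sd=noise_sd,
        )
        return sg.make_height_map(cfg)

    return make


@pytest.fixture
def dome_map():
    """256-px map of a 20 µm field with three 200 nm and two 50 nm domes."""
    bumps = [
        sg.BumpSpec((5.0, 5.0), 200.0, 0.5),
        sg.BumpSpec((5.0, 15.0), 200.0, 0.5),
        sg.BumpSpec((15.0, 5.0), 200.0, 0.5),
        sg.BumpSpec((15.0, 15.0), 50.0, 0.5),
        sg.BumpSpec((10.0, 10.0), 50.0, 0.5),
    ]
    cfg = sg.SynthConfig(seed=11, image_shape=(256, 256), pixel_size_um=20.0 / 256, bumps=bumps)
    return sg.make_height_map(cfg)


@pytest.fixture
def spot_image_factory():
    """25 well-separated Gaussian dots at peak SNR ~10 (Poisson background)."""

    def make(seed=0, n_spots=25, amplitude=100.0, background=100.0, poisson=True):
        cfg = sg.SynthConfig(
            seed=seed,
            image_shape=(256, 256),
            spot=sg.SpotSpec(
                n_spots=n_spots,
                sigma_px=2.0,
                amplitude=amplitude,
                min_separation_px=20.0,
                background=background,
                poisson=poisson,
            ),
        )
        return sg.make_spot_image(cfg)

    return make


@pytest.fixture
def triangle_dip_curve():
    """Noiseless curve with a 200 pN deep, 400 nm wide triangular adhesion dip."""
    cfg = sg.SynthConfig(
        seed=2,
        curve=sg.CurveSpec(
            contact_nm=500.0,
            slope_pn_per_nm=0.05,
            dip_depth_pn=200.0,
            dip_width_nm=400.0,
            n_samples=2048,
        ),
    )
    return sg.make_force_curve(cfg)
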