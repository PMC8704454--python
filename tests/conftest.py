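"""Shared fixtures: small feature grids, banks, and the (expensive) demo runs.

The chirped-arc completion protocol and the frequency ablation are computed
once per session and shared by the acceptance-level tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaborlift import (CompletionConfig, build_filter_bank, complete_image,
                       evaluate_completion, make_feature_grid,
                       single_frequency_ablation)
from gaborlift import synth


@pytest.fixture(scope="session")
def small_grid():
    """A light grid for unit tests: K=8, L=3, M=3."""
    return make_feature_grid(8, 3, 3, 1.2, 2.0)


@pytest.fixture(scope="session")
def small_bank(small_grid):
    return build_filter_bank(small_grid, sigma=2.0)


@pytest.fixture(scope="session")
def scaled_grid():
    """The scaled study grid: K=16, L=6, M=5, sigma=2 band [1.4, 2.6]."""
    return make_feature_grid(16, 6, 5, 1.4, 2.6)


@pytest.fixture(scope="session")
def scaled_bank(scaled_grid):
    return build_filter_bank(scaled_grid, sigma=2.0)


@pytest.fixture(scope="session")
def bandlimited_image():
    """64x64 sum of three lattice-commensurate gratings inside [1.4, 2.6]."""
    N = 64
    x, y = np.meshgrid(np.arange(N, dtype=float), np.arange(N, dtype=float),
                       indexing="ij")
    img = (0.5
           + 0.15 * np.cos(2 * np.pi * (15 * x + 4 * y) / N + 0.3)
           + 0.15 * np.cos(2 * np.pi * (0 * x + 20 * y) / N + 1.1)
           + 0.15 * np.cos(2 * np.pi * (18 * x + 18 * y) / N + 2.0))
    return img


@pytest.fixture(scope="session")
def gap_diffusion():
    """Oriented grating with an 8-pixel gap diffused for T=10 (anisotropy demo).

    The gap is filled with the image mean so the measurement isolates the
    directional propagation rather than occluder-edge responses.
    """
    from gaborlift import (DiffusionConfig, build_filter_bank, lift,
                           lift_mask, run_diffusion)

    N = 48
    f_cyc = 0.25
    img = synth.oriented_grating(N, theta=0.0, f=f_cyc)
    mask = np.zeros((N, N), bool)
    mask[20:28, :] = True  # gap cutting every stripe (X1 runs along axis 0)
    corrupted = np.where(mask, img.mean(), img)
    grid = make_feature_grid(8, 3, 5, 1.2, 1.9)
    bank = build_filter_bank(grid, sigma=2.0)
    lifted = lift(corrupted, bank, grid)
    lmask = lift_mask(mask, grid.K, grid.L, grid.M)
    run = run_diffusion(lifted, lmask, grid,
                        DiffusionConfig(mode="exact", dt=0.1, T=10.0))
    return {"grid": grid, "mask": mask, "lifted": lifted, "run": run,
            "k_matched": 0, "k_orthogonal": 4, "l_matched": 1}


@pytest.fixture(scope="session")
def chirp_demo():
    """Chirped-arc completion at 64x64 in both modes (the scaled protocol)."""
    N = 64
    truth = synth.chirped_arcs_image(N)
    mask = synth.occluding_arcs_mask(N)
    corrupted = np.where(mask, 0.0, truth)
    results = {}
    for mode in ("exact", "approximate"):
        cfg = CompletionConfig(mode=mode)
        res = complete_image(corrupted, mask, cfg)
        res.masked_rmse = evaluate_completion(res, truth, mask)
        results[mode] = res
    return {
        "truth": truth, "mask": mask, "corrupted": corrupted,
        "corrupted_rmse": evaluate_completion(corrupted, truth, mask),
        "exact": results["exact"], "approximate": results["approximate"],
    }


@pytest.fixture(scope="session")
def ablation_runs(chirp_demo):
    """Single-frequency completions of the chirp demo at three fixed frequencies."""
    cfg = CompletionConfig()
    f_all = np.linspace(cfg.f_min, cfg.f_max, cfg.n_frequencies)
    runs = {}
    for f in (f_all[0], f_all[1], f_all[3]):
        res = single_frequency_ablation(chirp_demo["corrupted"],
                                        chirp_demo["mask"], float(f), cfg)
        res.masked_rmse = evaluate_completion(res, chirp_demo["truth"],
                                              chirp_demo["mask"])
        runs[float(f)] = res
    return runs
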