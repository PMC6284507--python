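"""Reference synthetic experiments exercising every pipeline stage.

Each runner builds its study conditions from the synthetic generator,
pushes them through the public pipeline, and measures how well the
stage recovers known ground truth (or agrees with an independent
oracle computed by brute force).  The same runners back the
acceptance-style tests and the ``scripts/acceptance.py`` report.

Problem sizes are desk-scale: single 128×128 (or 64×64) nuclei and
cohorts of 10–100 cells, chosen so the full battery runs in minutes on
one CPU.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter
from scipy.signal import convolve2d

from .core import AcquisitionMeta, NucleusMask, TimeLapseMovie
from .filtering import DoGParams, dog_filter
from .io import estimate_split_offset
from .pipeline import process_cell_pair, simulate_cohort
from .population import cluster_by_final_fmr, fmr_ratio, qc_filter
from .synth import (
    ChannelSim,
    KineticParams,
    fast_config,
    simulate_movie,
    small_config,
    standard_config,
)
from .traces import bleach_correct, extract_trace, med_max, rfi, smooth3


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------- medMax


def medmax_oracle_agreement(seed: int, n_inputs: int = 1000) -> dict:
    """Fraction of random inputs where med_max equals a full-sort oracle."""
    rng = np.random.default_rng(seed)
    agree = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # inputs smaller than 20
        for _ in range(n_inputs):
            size = int(rng.integers(5, 501))
            values = rng.uniform(-100, 1000, size)
            oracle = float(np.median(np.sort(values)[-min(20, size):]))
            agree += med_max(values) == oracle
    return {"agreement_percent": 100.0 * agree / n_inputs, "n": n_inputs}


# ------------------------------------------------------------------- DoG


def _dense_dog(frame: np.ndarray, s: float, l: float, truncate: float = 4.0):
    """Direct dense convolution with reflect padding (independent oracle)."""
    parts = []
    for sigma in (s, l):
        radius = int(truncate * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        padded = np.pad(frame, radius, mode="symmetric")
        parts.append(convolve2d(padded, np.outer(k1, k1), mode="valid"))
    return parts[0] - parts[1]


def dog_correctness(seed: int) -> dict:
    """Constant-frame rejection and impulse response vs the dense oracle."""
    level = 500.0
    const_rel = 0.0
    for sigma_large in (1.3, 40.0):  # spatial and FFT evaluation paths
        params = DoGParams(sigma_small=0.6, sigma_large=sigma_large, pixel_size=1.0)
        out = dog_filter(np.full((48, 48), level), params)
        const_rel = max(const_rel, float(np.abs(out).max() / level))
    frame = np.zeros((33, 33))
    frame[16, 16] = 1.0
    params = DoGParams(sigma_small=1.0, sigma_large=6.0, pixel_size=1.0)
    out = dog_filter(frame, params)
    oracle = _dense_dog(frame, 1.0, 6.0)
    impulse_rel = float(np.abs(out - oracle).max() / np.abs(oracle).max())
    return {
        "constant_response_rel": const_rel,
        "impulse_max_rel_err": impulse_rel,
        "n": 33 * 33,
    }


# ------------------------------------------------- bleaching correction


def bleach_recovery(seed: int) -> dict:
    """No-recruitment movie, k_b = 0.002/frame, SNR 10: worst |RFI − 1|."""
    none = KineticParams(0.0, 0.1)
    base = standard_config(n_frames=610, drift=(0.0, 0.0), bleedthrough=0.0)
    cfg = dataclasses.replace(
        base,
        green=dataclasses.replace(base.green, kinetics=none, bleach_rate=0.002),
        red=dataclasses.replace(base.red, kinetics=none, bleach_rate=0.002),
    )
    green, _, _ = simulate_movie(cfg, np.random.default_rng(seed))
    nucleus = NucleusMask.from_ellipse(cfg.shape, cfg.nucleus_center, cfg.nucleus_axes)
    trace = extract_trace(green, cfg.damage_roi, nucleus)
    series, _ = rfi(smooth3(bleach_correct(trace)), cfg.meta)
    return {"max_abs_rfi_deviation": float(np.abs(series - 1.0).max()), "n": cfg.n_frames}


# ---------------------------------------------------------- FMR contract


def _random_kinetics(rng: np.random.Generator) -> KineticParams:
    return KineticParams(
        amplitude=float(rng.uniform(0.3, 2.0)),
        k_on=float(rng.uniform(0.05, 0.5)),
        k_off=float(rng.uniform(0.0, 0.05)),
    )


def fmr_contract(seed: int, n_cells: int = 100) -> dict:
    """FMR normalization contract over random simulated cells.

    Checks: FMR at the post-damage argmax is exactly 1; the pre-damage
    mean FMR is 0 to float precision; FMR is bit-identical under a
    power-of-two gain and invariant to 1e-9 under an arbitrary gain.
    """
    rngs = _spawn(seed, n_cells)
    argmax_dev = 0.0
    pre_mean_dev = 0.0
    pow2_identical = 0
    gain_dev = 0.0
    base = small_config()
    nucleus = NucleusMask.from_ellipse(base.shape, base.nucleus_center, base.nucleus_axes)
    for rng in rngs:
        cfg = dataclasses.replace(
            base,
            green=dataclasses.replace(base.green, kinetics=_random_kinetics(rng)),
        )
        green, _, _ = simulate_movie(cfg, rng)
        rec = process_cell_pair("c", green, green, cfg.damage_roi, nucleus)
        curve = rec.green_curve
        fmr_series = curve.fmr
        post = fmr_series[cfg.damage_frame :]
        argmax_dev = max(argmax_dev, abs(float(post.max()) - 1.0))
        pre_mean_dev = max(pre_mean_dev, abs(float(fmr_series[: cfg.damage_frame].mean())))

        def curve_for(gain: float):
            movie = green.with_frames(green.frames * gain)
            r = process_cell_pair("c", movie, movie, cfg.damage_roi, nucleus)
            return r.green_curve.fmr

        pow2_identical += bool(np.array_equal(curve_for(4.0), fmr_series))
        arbitrary = curve_for(float(rng.uniform(0.3, 3.0)))
        gain_dev = max(gain_dev, float(np.abs(arbitrary - fmr_series).max()))
    return {
        "fmr_argmax_max_abs_dev": argmax_dev,
        "predamage_mean_max_abs_dev": pre_mean_dev,
        "pow2_gain_bit_identical_percent": 100.0 * pow2_identical / n_cells,
        "gain_invariance_max_abs_dev": gain_dev,
        "n": n_cells,
    }


# --------------------------------------------------------- t50 recovery


def t50_recovery(seed: int, n_cells: int = 20) -> dict:
    """Randomized-kinetics cohort: |t50 − true t50| and rank correlation."""
    base = standard_config(n_frames=260)
    nucleus = NucleusMask.from_ellipse(base.shape, base.nucleus_center, base.nucleus_axes)
    rngs = _spawn(seed, n_cells)
    estimates, truths = [], []
    for rng in rngs:
        cfg = dataclasses.replace(
            base, green=dataclasses.replace(base.green, kinetics=_random_kinetics(rng))
        )
        green, red, truth = simulate_movie(cfg, rng)
        rec = process_cell_pair("c", green, red, cfg.damage_roi, nucleus)
        estimates.append(rec.green_curve.t50)
        truths.append(truth.green.t50)
    estimates = np.array(estimates, dtype=float)
    truths = np.array(truths)
    within = int(np.sum(np.abs(estimates - truths) <= 1.0))
    rho = float(stats.spearmanr(truths, estimates).statistic)
    return {"within_1s_count": within, "rank_correlation": rho, "n": n_cells}


# ------------------------------------------------ subpopulation clusters


def subpopulation_clustering(seed: int, n_per_group: int = 10) -> dict:
    """Fast-dissociating vs persistent cells: purity of the rank quartiles."""
    base = standard_config(n_frames=610)
    records = []
    labels = {}
    for tag, k_off in (("fast", 0.02), ("persistent", 0.0)):
        cfg = dataclasses.replace(
            base,
            green=dataclasses.replace(
                base.green, kinetics=KineticParams(1.0, 0.1, k_off)
            ),
        )
        recs, _ = simulate_cohort(
            cfg, n_per_group, seed=seed + (0 if tag == "fast" else 1)
        )
        for i, rec in enumerate(recs):
            rec.cell_id = f"{tag}{i:02d}"
            labels[rec.cell_id] = tag
            records.append(rec)
    clusters = cluster_by_final_fmr(records, "green", k=4)
    top = clusters[0].cell_ids + clusters[1].cell_ids
    bottom = clusters[2].cell_ids + clusters[3].cell_ids
    correct = sum(labels[c] == "persistent" for c in top) + sum(
        labels[c] == "fast" for c in bottom
    )
    return {
        "purity_percent": 100.0 * correct / (len(top) + len(bottom)),
        "n": 2 * n_per_group,
    }


# ----------------------------------------------------- FMR ratio plateau


def ratio_plateau(seed: int, n_cells: int = 20) -> dict:
    """Identical kinetics in both channels: red/green FMR ratio near 1."""
    kinetics = KineticParams(1.0, 0.015, 0.005)
    base = standard_config(n_frames=610)
    cfg = dataclasses.replace(
        base,
        green=dataclasses.replace(base.green, kinetics=kinetics),
        red=dataclasses.replace(base.red, kinetics=kinetics),
    )
    records, _ = simulate_cohort(cfg, n_cells, seed=seed)
    _, mean, _, n = fmr_ratio(records)
    times = records[0].green_trace.time_s
    sel = (times >= 15.0) & (n > 0)
    return {
        "max_abs_ratio_deviation": float(np.abs(mean[sel] - 1.0).max()),
        "n": n_cells,
    }


# -------------------------------------------------- fast-recruiter order


def fast_recruiter_ordering(seed: int, n_cells: int = 50) -> dict:
    """0.1 s imaging, no smoothing, 0.3 s onset shift: t50(A) < t50(B)."""
    base = fast_config()
    cfg = dataclasses.replace(
        base,
        green=dataclasses.replace(
            base.green, kinetics=KineticParams(1.0, 2.0, 0.05, t_damage=0.0)
        ),
        red=dataclasses.replace(
            base.red, kinetics=KineticParams(1.0, 2.0, 0.05, t_damage=0.3)
        ),
    )
    records, _ = simulate_cohort(cfg, n_cells, seed=seed, smooth=False)
    ordered = sum(
        1
        for rec in records
        if rec.green_curve.t50 is not None
        and rec.red_curve.t50 is not None
        and rec.green_curve.t50 < rec.red_curve.t50
    )
    return {"ordered_percent": 100.0 * ordered / n_cells, "n": n_cells}


# ------------------------------------------------------------- QC filter


def qc_agreement(seed: int) -> dict:
    """QC decisions vs an independent predicate on a boundary-straddling grid."""
    from .population import CellRecord
    from .traces import IntensityTrace, compute_curve

    greens = [139.9, 140.0, 140.1, 170.0, 199.9, 200.0, 200.1, 250.0]
    reds = [199.9, 200.0, 200.5, 300.0, 399.9, 400.0, 400.1, 150.0]
    rng = np.random.default_rng(seed)
    pairs = [(g, r) for g in greens for r in reds]
    pairs += [tuple(rng.uniform(100, 450, 2)) for _ in range(100)]

    meta = AcquisitionMeta(0.5, 0.11, 10)
    series = np.ones(20)
    series[10:] = 1.5
    agree = 0
    for i, (g, r) in enumerate(pairs):
        trace_g = IntensityTrace(meta.times(20), series.copy(), np.ones(20), meta)
        trace_r = IntensityTrace(meta.times(20), series.copy(), np.ones(20), meta)
        cell = CellRecord(
            cell_id=f"c{i}",
            green_trace=trace_g,
            red_trace=trace_r,
            green_curve=compute_curve(trace_g, smooth=False),
            red_curve=compute_curve(trace_r, smooth=False),
            i0_raw_green=g,
            i0_raw_red=r,
            nucleus_area_px=3000,
            nucleus_area_um2=36.3,
        )
        passing, _ = qc_filter([cell])
        expected = (140 <= g <= 200) and (200 <= r <= 400) and (r > g)
        agree += (len(passing) == 1) == expected
    return {"agreement_percent": 100.0 * agree / len(pairs), "n": len(pairs)}


# ---------------------------------------------------------- registration


def _splitview_with_offset(rng, offset, noise_sigma=0.0, shape=(64, 64)):
    h, w = shape
    pad = 16
    base = gaussian_filter(rng.normal(0, 1, (h + 2 * pad, w + 2 * pad)), 2.0) * 100 + 500
    dx, dy = offset
    left = base[pad : pad + h, pad : pad + w]
    right = base[pad - dy : pad - dy + h, pad - dx : pad - dx + w]
    frames = np.concatenate([left, right], axis=1)[None].repeat(2, axis=0)
    if noise_sigma:
        frames = frames + rng.normal(0, noise_sigma, frames.shape)
    meta = AcquisitionMeta(0.5, 0.11, damage_frame=1)
    return TimeLapseMovie(np.clip(frames, 0, None), meta)


def registration_recovery(seed: int, n_offsets: int = 50) -> dict:
    """Planted integer split-view offsets: exact recovery (noise-free)
    and worst per-axis error at texture SNR 5."""
    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n_offsets):
        dx, dy = (int(v) for v in rng.integers(-10, 11, 2))
        movie = _splitview_with_offset(rng, (dx, dy))
        exact += estimate_split_offset(movie, max_shift=10) == (dx, dy)
    worst = 0
    for _ in range(n_offsets):
        dx, dy = (int(v) for v in rng.integers(-10, 11, 2))
        movie = _splitview_with_offset(rng, (dx, dy), noise_sigma=20.0)
        ex, ey = estimate_split_offset(movie, max_shift=10)
        worst = max(worst, abs(ex - dx), abs(ey - dy))
    return {
        "exact_recovery_percent": 100.0 * exact / n_offsets,
        "snr5_max_error_px": worst,
        "n": n_offsets,
    }
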