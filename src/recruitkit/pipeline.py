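"""Glue: movies + ROIs → cell records; cohorts of simulated cells;
record reconstruction from trace tables; population summaries.

Stage order is fixed: DoG → extract → bleach correction → smoothing
(standard mode only) → RFI/ΔI → FMR → scalars.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import NucleusMask, RectROI, TimeLapseMovie
from .filtering import DoGParams
from .population import CellRecord
from .synth import GroundTruth, SimConfig, simulate_cells
from .traces import IntensityTrace, compute_curve, curve_stats, extract_trace

PIPELINE_STAGES = (
    "dog_filter",
    "extract",
    "bleach_correct",
    "smooth3",
    "rfi_delta",
    "fmr",
    "scalars",
)


def raw_initial_intensity(movie: TimeLapseMovie, nucleus: NucleusMask) -> float:
    """Pre-damage mean nucleus intensity on the unfiltered frames
    (camera-count scale; what the QC intensity ranges refer to)."""
    pre = movie.frames[: movie.meta.damage_frame]
    return float(pre[:, nucleus.mask].mean())


def process_cell_pair(
    cell_id: str,
    green: TimeLapseMovie,
    red: TimeLapseMovie,
    damage: RectROI,
    nucleus: NucleusMask,
    use_dog: bool = True,
    dog: DoGParams | None = None,
    smooth: bool = True,
    interpolate_t50: bool = False,
) -> CellRecord:
    """Run the full per-cell pipeline on an aligned green/red movie pair."""
    traces = {}
    curves = {}
    for label, movie in (("green", green), ("red", red)):
        trace = extract_trace(movie, damage, nucleus, use_dog=use_dog, dog=dog)
        traces[label] = trace
        curves[label] = compute_curve(
            trace, smooth=smooth, interpolate_t50=interpolate_t50
        )
    return CellRecord(
        cell_id=cell_id,
        green_trace=traces["green"],
        red_trace=traces["red"],
        green_curve=curves["green"],
        red_curve=curves["red"],
        i0_raw_green=raw_initial_intensity(green, nucleus),
        i0_raw_red=raw_initial_intensity(red, nucleus),
        nucleus_area_px=nucleus.area,
        nucleus_area_um2=nucleus.area_um2(green.meta.pixel_size),
    )


def simulate_cohort(
    cfg: SimConfig,
    n_cells: int,
    seed: int,
    use_dog: bool = True,
    dog: DoGParams | None = None,
    smooth: bool = True,
    interpolate_t50: bool = False,
) -> tuple[list[CellRecord], list[GroundTruth]]:
    """Simulate ``n_cells`` and push each through the full pipeline."""
    nucleus = NucleusMask.from_ellipse(cfg.shape, cfg.nucleus_center, cfg.nucleus_axes)
    records: list[CellRecord] = []
    truths: list[GroundTruth] = []
    for i, (green, red, truth) in enumerate(simulate_cells(cfg, n_cells, seed)):
        records.append(
            process_cell_pair(
                f"cell{i:03d}",
                green,
                red,
                cfg.damage_roi,
                nucleus,
                use_dog=use_dog,
                dog=dog,
                smooth=smooth,
                interpolate_t50=interpolate_t50,
            )
        )
        truths.append(truth)
    return records, truths


def truth_table(truths: list[GroundTruth]) -> pd.DataFrame:
    """Ground-truth scalars of a simulated cohort as one tidy table."""
    rows = []
    for i, truth in enumerate(truths):
        for channel in ("green", "red"):
            ch = truth.channel(channel)
            rows.append(
                {
                    "cell_id": f"cell{i:03d}",
                    "channel": channel,
                    "i0": ch.i0,
                    "amplitude": ch.params.amplitude,
                    "k_on": ch.params.k_on,
                    "k_off": ch.params.k_off,
                    "t_damage": ch.params.t_damage,
                    "true_t50": ch.t50,
                    "true_t_max": ch.t_max,
                }
            )
    return pd.DataFrame(rows)


def cells_table(records: list[CellRecord]) -> pd.DataFrame:
    """Per-cell scalar summary (QC inputs and kinetic scalars)."""
    rows = []
    for rec in records:
        row = {
            "cell_id": rec.cell_id,
            "i0_raw_green": rec.i0_raw_green,
            "i0_raw_red": rec.i0_raw_red,
            "nucleus_area_px": rec.nucleus_area_px,
            "nucleus_area_um2": rec.nucleus_area_um2,
            "qc_pass": rec.qc_pass,
            "qc_reason": rec.qc_reason,
        }
        for channel in ("green", "red"):
            curve = rec.curve(channel)
            row[f"i0_{channel}"] = curve.i0 if curve else np.nan
            row[f"max_rfi_{channel}"] = curve.max_rfi if curve else np.nan
            row[f"t_max_{channel}"] = curve.t_max if curve else np.nan
            row[f"t50_{channel}"] = (
                curve.t50 if curve and curve.t50 is not None else np.nan
            )
            row[f"final_fmr_{channel}"] = (
                curve.final_fmr if curve and curve.final_fmr is not None else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_tables(
    traces: pd.DataFrame, cells: pd.DataFrame, meta
) -> list[CellRecord]:
    """Rebuild :class:`CellRecord` objects from traces + cells tables.

    Stored series are taken as-is; scalar kinetics are recomputed from
    them, so a rebuilt record analyses identically to a fresh one.
    """
    from .traces import RecruitmentCurve

    records = []
    for cell_id, cell_rows in traces.groupby("cell_id", sort=True):
        info = cells.loc[cells["cell_id"] == cell_id]
        if info.empty:
            raise ValueError(f"cell {cell_id} missing from cells table")
        info = info.iloc[0]
        tr = {}
        cv = {}
        for channel in ("green", "red"):
            ch = cell_rows[cell_rows["channel"] == channel].sort_values("frame")
            if ch.empty:
                raise ValueError(f"cell {cell_id} missing channel {channel}")
            trace = IntensityTrace(
                time_s=ch["time_s"].to_numpy(),
                raw_medmax=ch["raw_medmax"].to_numpy(),
                nucleus_mean=ch["nucleus_mean"].to_numpy(),
                meta=meta,
                channel_label=channel,
                corrected=ch["corrected"].to_numpy(),
            )
            rfi_series = ch["rfi"].to_numpy()
            fmr_series = ch["fmr"].to_numpy()
            has_fmr = not np.isnan(fmr_series).all()
            max_rfi, t_max, t50, final = curve_stats(
                rfi_series, fmr_series if has_fmr else None, meta
            )
            i0 = float(trace.corrected[: meta.damage_frame].mean())
            cv[channel] = RecruitmentCurve(
                rfi=rfi_series,
                delta=trace.corrected - i0,
                fmr=fmr_series if has_fmr else None,
                i0=i0,
                max_rfi=max_rfi,
                t_max=t_max,
                t50=t50,
                final_fmr=final,
                flags=() if has_fmr else ("no_recruitment",),
            )
            tr[channel] = trace
        records.append(
            CellRecord(
                cell_id=str(cell_id),
                green_trace=tr["green"],
                red_trace=tr["red"],
                green_curve=cv["green"],
                red_curve=cv["red"],
                i0_raw_green=float(info["i0_raw_green"]),
                i0_raw_red=float(info["i0_raw_red"]),
                nucleus_area_px=int(info["nucleus_area_px"]),
                nucleus_area_um2=float(info["nucleus_area_um2"]),
                qc_pass=bool(info["qc_pass"]),
                qc_reason=str(info["qc_reason"]) if pd.notna(info["qc_reason"]) else "",
            )
        )
    return records
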