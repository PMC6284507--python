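import numpy as np
import pytest

from recruitkit.core import AcquisitionMeta
from recruitkit.population import CellRecord
from recruitkit.traces import IntensityTrace, RecruitmentCurve, compute_curve


@pytest.fixture
def meta():
    """Standard-regime metadata: 0.5 s interval, damage after 10 frames."""
    return AcquisitionMeta(frame_interval=0.5, pixel_size=0.11, damage_frame=10)


def make_trace(corrected, meta, channel="green"):
    """Trace whose bleach-corrected series equals ``corrected`` exactly
    (nucleus mean 1 everywhere)."""
    corrected = np.asarray(corrected, dtype=np.float64)
    return IntensityTrace(
        time_s=meta.times(len(corrected)),
        raw_medmax=corrected.copy(),
        nucleus_mean=np.ones_like(corrected),
        meta=meta,
        channel_label=channel,
    )


def make_record(
    cell_id,
    meta,
    green_corrected=None,
    red_corrected=None,
    i0_raw_green=150.0,
    i0_raw_red=300.0,
    nucleus_area_px=3000,
    smooth=False,
    green_scalars=None,
    red_scalars=None,
):
    """CellRecord from synthetic corrected series (no movies involved).

    ``*_scalars`` overrides (t50, final_fmr) on the computed curve, for
    tests that plant exact kinetic values.
    """
    T = 40
    default = np.ones(T)
    default[meta.damage_frame :] = 1.5
    curves = {}
    traces = {}
    for channel, series, scalars in (
        ("green", green_corrected, green_scalars),
        ("red", red_corrected, red_scalars),
    ):
        series = default if series is None else np.asarray(series, dtype=np.float64)
        trace = make_trace(series, meta, channel)
        curve = compute_curve(trace, smooth=smooth)
        if scalars is not None:
            curve = RecruitmentCurve(
                rfi=curve.rfi,
                delta=curve.delta,
                fmr=curve.fmr,
                i0=curve.i0,
                max_rfi=curve.max_rfi,
                t_max=curve.t_max,
                t50=scalars.get("t50", curve.t50),
                final_fmr=scalars.get("final_fmr", curve.final_fmr),
                flags=curve.flags,
            )
        traces[channel] = trace
        curves[channel] = curve
    return CellRecord(
        cell_id=cell_id,
        green_trace=traces["green"],
        red_trace=traces["red"],
        green_curve=curves["green"],
        red_curve=curves["red"],
        i0_raw_green=i0_raw_green,
        i0_raw_red=i0_raw_red,
        nucleus_area_px=nucleus_area_px,
        nucleus_area_um2=nucleus_area_px * 0.11**2,
    )
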