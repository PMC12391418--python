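"""Chrono-sampling arithmetic and time-resolved profile assembly.

A skin-interfaced microfluidic sampler routes sweat through capillary
bursting valves into a train of fixed-volume chambers, so chamber index
maps to collection time. These helpers convert chamber geometry and flow
into sampling intervals and capacities, estimate quasi-dynamic sweat rate
from fill times, and turn per-spectrum concentration predictions into a
chronological profile with replicate dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_N_CHAMBERS = 17
DEFAULT_CHAMBER_VOLUME_UL = 0.5
DEFAULT_FLOW_RATE_UL_MIN = 0.25


@dataclass
class ChamberRecord:
    """One sampling chamber: geometry, fill window, and attached data.

    ``concentration`` is the (simulated or assumed) true inlet label;
    ``predictions`` maps analyte name to the replicate prediction vector
    for spectra measured from this chamber.
    """

    index: int
    volume: float
    fill_start: float
    fill_end: float
    concentration: float | None = None
    predictions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("chamber volume must be positive")
        if self.fill_end < self.fill_start:
            raise ValueError("fill_end must be >= fill_start")

    @property
    def midpoint(self) -> float:
        """Fill-window midpoint (minutes), the profile timestamp."""
        return 0.5 * (self.fill_start + self.fill_end)


def sampling_interval(chamber_volume: float, flow_rate: float) -> float:
    """Minutes to fill one chamber: volume (uL) / flow rate (uL/min).

    At the device's working point — 0.5 uL chambers, 0.25 uL/min sweat
    rate — this is 2 min per chamber.
    """
    if chamber_volume <= 0 or flow_rate <= 0:
        raise ValueError("chamber_volume and flow_rate must be positive")
    return chamber_volume / flow_rate


def patch_capacity(n_chambers: int, chamber_volume: float) -> float:
    """Total sample volume (uL) of the patch: n x chamber volume."""
    if n_chambers < 1:
        raise ValueError("n_chambers must be >= 1")
    if chamber_volume <= 0:
        raise ValueError("chamber_volume must be positive")
    return n_chambers * chamber_volume


def estimate_sweat_rate(
    records: list[ChamberRecord],
    window: float | None = None,
) -> pd.DataFrame:
    """Quasi-dynamic sweat rate from chamber fill times.

    The rate over an interval is the volume collected in it divided by its
    duration. With ``window=None`` each chamber's fill window is one
    interval; otherwise fixed windows of ``window`` minutes are used and
    the volume collected in each is interpolated from cumulative fills.
    The ``overall`` attribute of the returned frame is total volume over
    total elapsed time.
    """
    if not records:
        raise ValueError("no chamber records")
    recs = sorted(records, key=lambda r: r.index)
    t_end = recs[-1].fill_end
    t_start = recs[0].fill_start
    if t_end <= t_start:
        raise ValueError("zero elapsed time")

    if window is None:
        rows = [
            {
                "t_start": r.fill_start,
                "t_end": r.fill_end,
                "rate": r.volume / (r.fill_end - r.fill_start),
            }
            for r in recs
        ]
    else:
        if window <= 0:
            raise ValueError("window must be positive")
        # cumulative volume vs time, linear within each fill window
        times = [t_start] + [r.fill_end for r in recs]
        vols = np.concatenate([[0.0], np.cumsum([r.volume for r in recs])])
        edges = np.arange(t_start, t_end + 1e-9, window)
        if edges[-1] < t_end:
            edges = np.append(edges, t_end)
        cum = np.interp(edges, times, vols)
        rows = [
            {
                "t_start": a,
                "t_end": b,
                "rate": (vb - va) / (b - a),
            }
            for a, b, va, vb in zip(edges[:-1], edges[1:], cum[:-1], cum[1:])
        ]
    out = pd.DataFrame(rows)
    out.attrs["overall"] = sum(r.volume for r in recs) / (t_end - t_start)
    return out


def assemble_profile(
    records: list[ChamberRecord],
    predictions: dict[int, dict[str, np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Chronological concentration profile from per-chamber predictions.

    ``predictions`` maps chamber index to ``{analyte: replicate vector}``;
    if omitted, predictions already attached to the records are used. The
    output is tidy: one row per (chamber, analyte) with the fill-window
    midpoint as timestamp, the replicate mean, and one standard deviation
    as dispersion.
    """
    if not records:
        raise ValueError("no chamber records")
    rows = []
    for rec in sorted(records, key=lambda r: r.index):
        preds = (
            predictions.get(rec.index) if predictions is not None
            else rec.predictions
        )
        if not preds:
            raise ValueError(f"chamber {rec.index} has no predictions")
        for analyte, values in preds.items():
            values = np.asarray(values, dtype=float)
            if values.size == 0:
                raise ValueError(
                    f"chamber {rec.index} has no predictions for {analyte}"
                )
            rows.append(
                {
                    "chamber": rec.index,
                    "time_min": rec.midpoint,
                    "analyte": analyte,
                    "mean": float(values.mean()),
                    "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
                    "n": int(values.size),
                }
            )
    return pd.DataFrame(rows)
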