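"""FRET flow-cytometry biosensor quantification of tau seeding.

Per-cell CFP / YFP / FRET channel intensities are spillover-compensated,
gated against negative controls (a triangular FRET-vs-CFP gate plus an
optional false-FRET exclusion boundary calibrated on YFP-only cells), and
summarized as the integrated FRET density: the percentage of FRET-positive
cells multiplied by the median FRET intensity of those cells.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FlowEventTable",
    "CompensationSpec",
    "GateSpec",
    "SeedingResult",
    "compensate",
    "estimate_spill",
    "calibrate_gate",
    "integrated_fret_density",
    "read_events_csv",
    "write_seeding_tsv",
]


@dataclass
class FlowEventTable:
    """Per-event channel intensities for one sample/replicate."""

    cfp: np.ndarray
    yfp: np.ndarray
    fret: np.ndarray
    sample: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.cfp = np.asarray(self.cfp, dtype=float)
        self.yfp = np.asarray(self.yfp, dtype=float)
        self.fret = np.asarray(self.fret, dtype=float)
        if not (self.cfp.shape == self.yfp.shape == self.fret.shape):
            raise ValueError("channel arrays must share a shape")
        if self.cfp.size == 0:
            raise ValueError("at least one event required")
        for arr in (self.cfp, self.yfp, self.fret):
            if not np.all(np.isfinite(arr)):
                raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return self.cfp.size


@dataclass(frozen=True)
class CompensationSpec:
    """Spillover fractions; donor bleed-through into acceptor channels."""

    spill_cfp_to_yfp: float = 0.0
    spill_cfp_to_fret: float = 0.0
    spill_yfp_to_fret: float = 0.0

    def __post_init__(self) -> None:
        for f in (self.spill_cfp_to_yfp, self.spill_cfp_to_fret, self.spill_yfp_to_fret):
            if not 0.0 <= f < 1.0:
                raise ValueError("spill fractions must be in [0, 1)")


@dataclass
class GateSpec:
    """FRET positivity gate.

    ``fret_gate`` is a triangular region in (CFP, FRET) space given by
    three vertices; ``false_fret_threshold`` is an optional linear boundary
    in (YFP, FRET) space (slope, intercept) below which a cell's FRET
    signal is attributed to YFP emission and the cell excluded.
    """

    fret_gate: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    false_fret_threshold: tuple[float, float] | None = None
    calibration_quantile: float = 0.999

    def __post_init__(self) -> None:
        (x1, y1), (x2, y2), (x3, y3) = self.fret_gate
        area2 = abs((x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1))
        if area2 <= 0:
            raise ValueError("degenerate triangular gate")


@dataclass(frozen=True)
class SeedingResult:
    sample: str
    replicate: str
    n_events: int
    pct_positive: float
    mfi_positive: float
    integrated_fret_density: float


def compensate(events: FlowEventTable, spec: CompensationSpec) -> FlowEventTable:
    """Sequentially subtract CFP bleed-through from YFP and FRET, then YFP
    bleed-through from FRET.  Negative compensated values are permitted."""
    yfp = events.yfp - spec.spill_cfp_to_yfp * events.cfp
    fret = events.fret - spec.spill_cfp_to_fret * events.cfp - spec.spill_yfp_to_fret * yfp
    return FlowEventTable(
        cfp=events.cfp.copy(), yfp=yfp, fret=fret,
        sample=events.sample, replicate=events.replicate,
    )


def estimate_spill(
    single_positive_events: FlowEventTable,
    donor_channel: str,
    acceptor_channel: str,
    donor_floor_quantile: float = 0.1,
    min_events: int = 100,
) -> float:
    """Spill fraction from single-positive controls: the median acceptor/donor
    intensity ratio over events above a donor-intensity floor."""
    channels = {
        "cfp": single_positive_events.cfp,
        "yfp": single_positive_events.yfp,
        "fret": single_positive_events.fret,
    }
    donor = channels[donor_channel]
    acceptor = channels[acceptor_channel]
    floor = np.quantile(donor[donor > 0], donor_floor_quantile) if np.any(donor > 0) else 0.0
    mask = donor > max(floor, 0.0)
    if mask.sum() < min_events:
        raise ValueError(f"too few events above donor floor ({int(mask.sum())} < {min_events})")
    return float(np.median(acceptor[mask] / donor[mask]))


def _in_triangle(x: np.ndarray, y: np.ndarray, verts) -> np.ndarray:
    (x1, y1), (x2, y2), (x3, y3) = verts
    d = (y2 - y3) * (x1 - x3) + (x3 - x2) * (y1 - y3)
    a = ((y2 - y3) * (x - x3) + (x3 - x2) * (y - y3)) / d
    b = ((y3 - y1) * (x - x3) + (x1 - x3) * (y - y3)) / d
    c = 1.0 - a - b
    return (a >= 0) & (b >= 0) & (c >= 0)


def classify_positive(events: FlowEventTable, gate: GateSpec) -> np.ndarray:
    """Boolean FRET-positivity per compensated event."""
    pos = _in_triangle(events.cfp, events.fret, gate.fret_gate)
    if gate.false_fret_threshold is not None:
        slope, intercept = gate.false_fret_threshold
        # exclude cells whose FRET is attributable to YFP emission
        pos &= events.fret > slope * events.yfp + intercept
    return pos


def calibrate_gate(
    negative_events: FlowEventTable,
    quantile: float = 0.999,
    yfp_only_events: FlowEventTable | None = None,
    min_events: int = 1000,
) -> GateSpec:
    """Place the FRET gate from FRET-negative control cells.

    The lower edge of the triangular FRET-vs-CFP gate is a line of the
    negatives' FRET-on-CFP regression slope, raised so that at most
    1 - quantile of negative events fall above it.  The false-FRET boundary
    (if YFP-only cells are given) is the analogous linear quantile boundary
    of their FRET emission against YFP.
    """
    if len(negative_events) < min_events:
        raise ValueError(
            f"insufficient negative-control events ({len(negative_events)} < {min_events})"
        )
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    cfp, fret = negative_events.cfp, negative_events.fret
    slope = float(np.polyfit(cfp, fret, 1)[0]) if np.ptp(cfp) > 0 else 0.0
    resid = fret - slope * cfp
    if quantile == 1.0:
        # the gate edge is inclusive, so sit strictly above the extreme event
        intercept = float(np.nextafter(resid.max(), np.inf) + 1e-9 * abs(resid.max()))
    else:
        intercept = float(np.quantile(resid, quantile, method="higher"))

    # the calibrated lower edge runs across the full CFP range; the apex is
    # placed far above it so the triangle approximates the half-band above
    # the boundary over the observed CFP range
    x_lo = float(min(cfp.min(), 0.0))
    x_hi = float(cfp.max() * 10.0 + 1.0)
    y_top = float(max(abs(fret).max(), abs(intercept) + abs(slope) * x_hi) * 1e4 + 1.0)
    verts = (
        (x_lo, slope * x_lo + intercept),
        (x_hi, slope * x_hi + intercept),
        ((x_lo + x_hi) / 2.0, y_top),
    )

    false_fret = None
    if yfp_only_events is not None:
        yfp, yfret = yfp_only_events.yfp, yfp_only_events.fret
        fslope = float(np.polyfit(yfp, yfret, 1)[0]) if np.ptp(yfp) > 0 else 0.0
        fresid = yfret - fslope * yfp
        if quantile == 1.0:
            fintercept = float(np.nextafter(fresid.max(), np.inf))
        else:
            fintercept = float(np.quantile(fresid, quantile, method="higher"))
        false_fret = (fslope, fintercept)

    return GateSpec(
        fret_gate=verts, false_fret_threshold=false_fret, calibration_quantile=quantile
    )


def integrated_fret_density(events: FlowEventTable, gate: GateSpec) -> SeedingResult:
    """Percent positive, median FRET of positives, and their product."""
    pos = classify_positive(events, gate)
    n = len(events)
    n_pos = int(pos.sum())
    if n_pos == 0:
        return SeedingResult(events.sample, events.replicate, n, 0.0, 0.0, 0.0)
    pct = 100.0 * n_pos / n
    mfi = float(np.median(events.fret[pos]))
    return SeedingResult(events.sample, events.replicate, n, pct, mfi, pct * mfi)


# ---------------------------------------------------------------------------
# I/O

def read_events_csv(path) -> list[FlowEventTable]:
    """Read an events CSV (sample, replicate, cfp_raw, yfp_raw, fret_raw).

    Controls are flagged by sample-label convention: ``neg_*``,
    ``cfp_only``, ``yfp_only``.
    """
    df = pd.read_csv(path)
    required = {"sample", "replicate", "cfp_raw", "yfp_raw", "fret_raw"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    tables = []
    for (sample, rep), grp in df.groupby(["sample", "replicate"], sort=True):
        tables.append(
            FlowEventTable(
                cfp=grp["cfp_raw"].to_numpy(),
                yfp=grp["yfp_raw"].to_numpy(),
                fret=grp["fret_raw"].to_numpy(),
                sample=str(sample),
                replicate=str(rep),
            )
        )
    return tables


def write_events_csv(tables: Sequence[FlowEventTable], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "sample": t.sample,
                "replicate": t.replicate,
                "cfp_raw": t.cfp,
                "yfp_raw": t.yfp,
                "fret_raw": t.fret,
            }
        )
        for t in tables
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_seeding_tsv(results: Sequence[SeedingResult], path) -> None:
    pd.DataFrame([asdict(r) for r in results]).to_csv(path, sep="\t", index=False)


def write_gate_json(gate: GateSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "fret_gate": gate.fret_gate,
                "false_fret_threshold": gate.false_fret_threshold,
                "calibration_quantile": gate.calibration_quantile,
            },
            fh,
            indent=2,
        )
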