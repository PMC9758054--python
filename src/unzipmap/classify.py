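"""Category assignment from called peaks.

Pre-chase traces carry at most a stalled motor at A20 and a bound dCas;
post-chase traces fall into seven categories determined by whether a dCas
clamp signature is present and where the motor peak sits relative to the
dCas target site (the PAM-proximal edge of the protospacer).  A motor
within the collision-competence cutoff of the site — 60 bp for RNAP, 70 bp
for Mfd (the approximate complex footprint) — has collided; the boundary is
inclusive (distance <= cutoff counts as collided).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .construct import UnzipConstruct
from .traces import PeakCall


@dataclass
class ClassifierConfig:
    motor: str = "RNAP"
    collision_cutoff_bp: float | None = None  # 60 RNAP / 70 Mfd when None
    site_tolerance_bp: float = 15.0
    #: tighter window for the dCas clamp itself — the clamp position is known
    #: precisely, and a looser window would swallow motor peaks that invaded
    #: the R-loop after removing the dCas
    dcas_tolerance_bp: float = 6.0
    a20_tolerance_bp: float = 15.0
    #: window past the hybrid within which a lone rise still counts as the
    #: dCas clamp (removal-overlap assessment)
    dcas_footprint_pad_bp: float = 10.0

    def __post_init__(self) -> None:
        if self.motor not in ("RNAP", "Mfd"):
            raise ValueError(f"unknown motor {self.motor!r}")
        if self.collision_cutoff_bp is None:
            self.collision_cutoff_bp = 60.0 if self.motor == "RNAP" else 70.0
        if self.collision_cutoff_bp <= 0 or self.site_tolerance_bp <= 0:
            raise ValueError("cutoff and tolerance must be positive")


@dataclass
class TraceCategory:
    phase: str  # "control" | "chase"
    label: str | None
    motor_pos: float | None = None
    dcas_pos: float | None = None
    flags: list[str] = field(default_factory=list)
    evidence: list[PeakCall] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.label is not None


def _expected_clamp(construct: UnzipConstruct, cfg: ClassifierConfig) -> float:
    if construct.direction == "PAM-proximal-first":
        return construct.pam.end + 3.0
    return construct.protospacer.end - 2.0


def _split_calls(
    calls: list[PeakCall], construct: UnzipConstruct, cfg: ClassifierConfig
) -> tuple[float | None, list[PeakCall], bool]:
    """Separate the dCas clamp rise from motor rises.

    Returns (dcas position or None, motor rise calls, ambiguous).  dCas
    presence requires the clamp rise at its precisely known position
    (within ``dcas_tolerance_bp``); the R-loop dip corroborates but is
    neither required (a colliding motor can mask it) nor sufficient.
    """
    rises = [c for c in calls if c.sign == "rise"]
    clamp = _expected_clamp(construct, cfg)
    near = [c for c in rises if abs(c.position_bp - clamp) <= cfg.dcas_tolerance_bp]

    dcas_pos: float | None = None
    dcas_call: PeakCall | None = None
    if near:
        candidate = min(near, key=lambda c: abs(c.position_bp - clamp))
        dcas_call, dcas_pos = candidate, candidate.position_bp

    motors = [c for c in rises if c is not dcas_call]
    ambiguous = False
    if dcas_call is not None and len(near) > 1:
        # a second rise equally close to the clamp: nearer wins, ties flagged
        second = sorted(near, key=lambda c: abs(c.position_bp - clamp))[1]
        if abs(abs(second.position_bp - clamp) - abs(dcas_call.position_bp - clamp)) < 1e-6:
            ambiguous = True
    return dcas_pos, motors, ambiguous


def classify_prechase(
    calls: list[PeakCall], construct: UnzipConstruct, cfg: ClassifierConfig
) -> TraceCategory:
    """Four-way control-phase label: A20_dCas / A20_only / dCas_only / Nak."""
    dcas_pos, motors, ambiguous = _split_calls(calls, construct, cfg)
    if ambiguous:
        return TraceCategory("control", None, flags=["ambiguous dCas assignment"], evidence=calls)
    a20 = construct.a20_position
    at_a20 = [m for m in motors if abs(m.position_bp - a20) <= cfg.a20_tolerance_bp]
    stray = [m for m in motors if m not in at_a20]
    flags = []
    if stray:
        flags.append(f"{len(stray)} rise(s) matching no pre-chase site")
    motor_pos = at_a20[0].position_bp if at_a20 else None
    if motor_pos is not None and dcas_pos is not None:
        label = "A20_dCas"
    elif motor_pos is not None:
        label = "A20_only"
    elif dcas_pos is not None:
        label = "dCas_only"
    else:
        label = "Nak"
    return TraceCategory("control", label, motor_pos, dcas_pos, flags, calls)


def classify_postchase(
    calls: list[PeakCall], construct: UnzipConstruct, cfg: ClassifierConfig
) -> TraceCategory:
    """Seven-way chase-phase label from dCas presence and motor position."""
    dcas_pos, motors, ambiguous = _split_calls(calls, construct, cfg)
    if ambiguous:
        return TraceCategory("chase", None, flags=["ambiguous dCas assignment"], evidence=calls)
    site = construct.dcas_site
    flags: list[str] = []
    if motors:
        # the translocating motor is the most advanced rise
        motor = max(motors, key=lambda c: c.position_bp)
        pos = motor.position_bp
        if len(motors) > 1:
            flags.append(f"{len(motors) - 1} additional rise(s) ignored")
        upstream = site - pos
        if upstream > cfg.collision_cutoff_bp:
            label = "TEC_up_dCas" if dcas_pos is not None else "TEC_up_only"
        elif upstream >= -cfg.dcas_footprint_pad_bp:
            label = "Coll" if dcas_pos is not None else "dCas_rem"
        else:
            if dcas_pos is not None:
                return TraceCategory(
                    "chase",
                    None,
                    pos,
                    dcas_pos,
                    flags + ["motor downstream of a still-bound dCas"],
                    calls,
                )
            label = "TEC_dn"
        return TraceCategory("chase", label, pos, dcas_pos, flags, calls)
    label = "dCas_only" if dcas_pos is not None else "Nak"
    return TraceCategory("chase", label, None, dcas_pos, flags, calls)


def invasion_statistics(
    classified: pd.DataFrame, construct: UnzipConstruct
) -> pd.DataFrame:
    """Percentile summary of motor peak position relative to the R-loop edge.

    Expects columns condition, label, motor_pos; summarizes Coll and
    dCas_rem traces per condition.  Invasion depth is the overlap of the
    motor peak into the hybrid window (positive = into the R-loop).
    Conditions with no qualifying traces are omitted.
    """
    edge = construct.rloop_upstream_edge
    rows = []
    sub = classified[classified.label.isin(["Coll", "dCas_rem"])]
    for (cond, label), grp in sub.groupby(["condition", "label"], sort=True):
        pos = grp.motor_pos.dropna().to_numpy(dtype=float)
        if pos.size == 0:
            continue
        depth = pos - edge
        rows.append(
            {
                "condition": cond,
                "label": label,
                "n": pos.size,
                "invasion_p25_bp": float(np.percentile(depth, 25)),
                "invasion_median_bp": float(np.percentile(depth, 50)),
                "invasion_p75_bp": float(np.percentile(depth, 75)),
                "invasion_sd_bp": float(depth.std(ddof=1)) if pos.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "condition",
            "label",
            "n",
            "invasion_p25_bp",
            "invasion_median_bp",
            "invasion_p75_bp",
            "invasion_sd_bp",
        ],
    )
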