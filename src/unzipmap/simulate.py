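"""Synthetic chambers and traces from the assay's probabilistic outcome tree.

The generator is outcome-level: each chase trace draws its initial
occupancy state, then motor dissociation, collision competence, spontaneous
Cas loss, and — when a collision-competent motor meets a still-bound Cas —
one of {read-through, removal-then-stall, blocked}.  Read-through (or an
unopposed run) ends at the template end with probability ``p_runoff``
(naked DNA) or as a downstream motor peak otherwise.  Chase time and
translocation rate are metadata: the estimator consumes end-point
categories only.

``expected_fractions`` is the closed-form twin of ``sample_outcomes``; the
estimator inverts it exactly, which is the centerpiece identity the test
suite asserts.

``render_trace`` turns a category label into a full force-extension record
by perturbing the naked-DNA theory baseline with the protein signatures:
a sharp force rise where the fork meets a clamped protein and a force dip
over the R-loop bubble, shifted earlier by thermal breathing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .construct import UnzipConstruct
from .elastic import ElasticParams, ElasticTables
from .estimator import POST_CATEGORIES, PRE_CATEGORIES, ChamberCounts
from .theory import equilibrium_unzip_curve, make_schedule
from .thermo import ThermoParams, junction_energies
from .traces import Trace

_PROB_TOL = 1e-9


@dataclass
class GeneratorConfig:
    """Study conditions for one simulated experiment.

    Defaults mirror the assay: >90 % co-occupancy, ~40 control and ~60
    chase tethers per chamber, 135 s NTP chase for RNAP (480 s ATP chase
    for Mfd, with 80 chase tethers).
    """

    f_A20_dCas: float = 0.90
    f_A20_only: float = 0.04
    f_dCas_only: float = 0.04
    f_nak: float = 0.02
    p_motor_diss: float = 0.05
    p_dcas_diss: float = 0.05
    p_coll_comp: float = 0.85
    p_read_through: float = 0.43
    p_removal_stall: float = 0.10
    p_block: float = 0.47
    p_runoff_given_readthrough: float = 0.5
    motor: str = "RNAP"
    chase_duration_s: float = 135.0
    traces_control: int = 40
    traces_chase: int = 60
    chambers: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            k: getattr(self, k)
            for k in (
                "f_A20_dCas",
                "f_A20_only",
                "f_dCas_only",
                "f_nak",
                "p_motor_diss",
                "p_dcas_diss",
                "p_coll_comp",
                "p_read_through",
                "p_removal_stall",
                "p_block",
                "p_runoff_given_readthrough",
            )
        }
        for k, v in probs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{k} must be in [0, 1], got {v}")
        if abs(self.f_A20_dCas + self.f_A20_only + self.f_dCas_only + self.f_nak - 1) > _PROB_TOL:
            raise ValueError("initial fractions must sum to 1")
        if abs(self.p_read_through + self.p_removal_stall + self.p_block - 1) > _PROB_TOL:
            raise ValueError("collision outcome probabilities must sum to 1")
        if self.motor not in ("RNAP", "Mfd"):
            raise ValueError(f"unknown motor {self.motor!r}")
        if min(self.traces_control, self.traces_chase, self.chambers) < 1:
            raise ValueError("trace and chamber counts must be >= 1")

    def for_mfd(self) -> "GeneratorConfig":
        """Mfd variant: no removal-then-stall population, longer chase."""
        return replace(
            self,
            motor="Mfd",
            chase_duration_s=480.0,
            p_removal_stall=0.0,
            p_block=1.0 - self.p_read_through,
            traces_chase=80,
        )


def expected_fractions(cfg: GeneratorConfig) -> ChamberCounts:
    """Exact leaf probabilities of the outcome tree.

    Pre-chase expectations are the initial fractions themselves; post-chase
    expectations follow the chase tree (motor dissociation -> collision
    competence -> spontaneous Cas loss -> collision outcome -> runoff).
    """
    a, b, c, d = cfg.f_A20_dCas, cfg.f_A20_only, cfg.f_dCas_only, cfg.f_nak
    pm, ps, pcc = cfg.p_motor_diss, cfg.p_dcas_diss, cfg.p_coll_comp
    prt, prem = cfg.p_read_through, cfg.p_removal_stall
    pblock = cfg.p_block
    prun = cfg.p_runoff_given_readthrough

    # motors that run unopposed to the template end (Cas absent or lost),
    # plus read-through motors: split Nak vs TEC_dn by runoff
    through_a = a * (1 - pm) * pcc * (ps + (1 - ps) * prt)
    through_b = b * (1 - pm) * pcc
    through = through_a + through_b

    post = {
        "TEC_up_dCas": a * (1 - pm) * (1 - pcc) * (1 - ps),
        "TEC_up_only": a * (1 - pm) * (1 - pcc) * ps + b * (1 - pm) * (1 - pcc),
        "Coll": a * (1 - pm) * pcc * (1 - ps) * pblock,
        "dCas_rem": a * (1 - pm) * pcc * (1 - ps) * prem,
        "TEC_dn": through * (1 - prun),
        "Nak": d + c * ps + a * pm * ps + b * pm + through * prun,
        "dCas_only": c * (1 - ps) + a * pm * (1 - ps),
    }
    pre = {"A20_dCas": a, "A20_only": b, "dCas_only": c, "Nak": d}
    return ChamberCounts(pre=pre, post=post, chamber_id="expected")


def _post_probs(cfg: GeneratorConfig) -> np.ndarray:
    post = expected_fractions(cfg).post
    return np.array([post[k] for k in POST_CATEGORIES])


def sample_outcomes(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw labelled outcomes for every trace of every chamber.

    Returns a table with columns chamber_id, trace_id, phase
    (control | chase) and category.  Reproducible under a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pre_p = np.array([cfg.f_A20_dCas, cfg.f_A20_only, cfg.f_dCas_only, cfg.f_nak])
    post_p = _post_probs(cfg)
    rows: list[tuple[str, str, str, str]] = []
    for ch in range(cfg.chambers):
        cid = f"chamber{ch:02d}"
        pre_idx = rng.choice(len(PRE_CATEGORIES), size=cfg.traces_control, p=pre_p)
        for t, k in enumerate(pre_idx):
            rows.append((cid, f"{cid}_c{t:03d}", "control", PRE_CATEGORIES[k]))
        post_idx = rng.choice(len(POST_CATEGORIES), size=cfg.traces_chase, p=post_p)
        for t, k in enumerate(post_idx):
            rows.append((cid, f"{cid}_t{t:03d}", "chase", POST_CATEGORIES[k]))
    return pd.DataFrame(rows, columns=["chamber_id", "trace_id", "phase", "category"])


def chamber_counts_from_outcomes(outcomes: pd.DataFrame) -> list[ChamberCounts]:
    """Tally an outcome (or classification) table into per-chamber fractions."""
    out: list[ChamberCounts] = []
    for cid, grp in outcomes.groupby("chamber_id", sort=True):
        pre = grp[grp.phase == "control"].category.value_counts().to_dict()
        post = grp[grp.phase == "chase"].category.value_counts().to_dict()
        out.append(ChamberCounts.from_counts(pre, post, chamber_id=str(cid)))
    return out


# ---------------------------------------------------------------------------
# trace rendering


@dataclass
class TraceSignatureModel:
    """Shapes of protein signatures superposed on the naked-DNA baseline."""

    rise_amp_pN: float = 8.0
    rise_width_bp: float = 8.0
    dip_amp_pN: float = 2.5
    breathing_offset_bp: float = 5.0
    #: Gaussian force noise s.d. per raw 10-kHz sample
    noise_sd_pN: float = 0.75
    #: probability that a bound dCas12a shows the single-rise conformation
    dcas12a_single_rise_weight: float = 0.43
    dcas12a_dual_conformation: bool = False
    #: clamp position for PAM-proximal-first unzipping, bp past the PAM
    pam_proximal_clamp_offset_bp: float = 6.0
    #: motor stall peak offset upstream of the PAM for proximal collisions
    proximal_collision_offset_bp: float = 30.0
    #: motor footprint: stall peak sits this far upstream of the R-loop edge
    motor_footprint_bp: float = 10.0
    #: mean invasion depth into the R-loop for removal-then-stall traces
    invasion_mean_bp: float = 5.0
    invasion_sd_bp: float = 2.0

    def __post_init__(self) -> None:
        if min(self.rise_amp_pN, self.dip_amp_pN, self.rise_width_bp) <= 0:
            raise ValueError("signature amplitudes and widths must be positive")
        if self.breathing_offset_bp < 0 or self.motor_footprint_bp < 0:
            raise ValueError("offsets must be nonnegative")
        if not (0.0 <= self.dcas12a_single_rise_weight <= 1.0):
            raise ValueError("conformation mixture weight must be in [0, 1]")


@dataclass
class TraceTruth:
    """Ground truth attached to a rendered trace."""

    category: str
    motor_pos: float | None
    dcas_present: bool
    rise_positions: list[float] = field(default_factory=list)


def _dcas_clamp_position(construct: UnzipConstruct, sig: TraceSignatureModel) -> float:
    """Unzip-frame position of the dCas clamp rise."""
    if construct.direction == "PAM-proximal-first":
        # fork crosses the PAM then hits tight binding ~6 bp beyond it
        return construct.pam.end + sig.pam_proximal_clamp_offset_bp - 3.0
    # distal-first: tight binding at the PAM-proximal end of the hybrid
    return construct.protospacer.end - 2.0


def _draw_motor_position(
    category: str,
    construct: UnzipConstruct,
    sig: TraceSignatureModel,
    cutoff_bp: float,
    rng: np.random.Generator,
) -> float | None:
    """Motor rise position implied by a category, drawn in the unzip frame."""
    site = construct.dcas_site
    a20 = construct.a20_position
    edge = construct.rloop_upstream_edge
    if category in ("A20_dCas", "A20_only"):
        return a20
    if category in ("TEC_up_dCas", "TEC_up_only"):
        hi = site - cutoff_bp - 5.0
        if hi <= a20:
            return a20
        return float(rng.uniform(a20, hi))
    if category == "Coll":
        if construct.direction == "PAM-proximal-first":
            return construct.pam.start - sig.proximal_collision_offset_bp
        return edge - sig.motor_footprint_bp
    if category == "dCas_rem":
        inv = abs(rng.normal(sig.invasion_mean_bp, sig.invasion_sd_bp))
        return edge + min(inv, construct.protospacer.end - edge - 2.0)
    if category == "TEC_dn":
        lo = construct.pam.end + 15.0
        hi = construct.length - 20.0
        return float(rng.uniform(lo, min(hi, lo + 120.0)))
    return None  # Nak, dCas_only


def _compliance_nm_per_pN(
    construct: UnzipConstruct, j: float, tables: ElasticTables, f_ref: float
) -> float:
    """Differential compliance of arms + 2j released nucleotides at f_ref."""
    fg = tables.f_grid
    dxds = np.gradient(tables.x_ds, fg)
    dxss = np.gradient(tables.x_ss, fg)
    return float(
        construct.arm_bp * np.interp(f_ref, fg, dxds)
        + 2.0 * j * np.interp(f_ref, fg, dxss)
    )


def signature_energies(
    dg: np.ndarray,
    rises: list[float],
    dip_window: tuple[float, float] | None,
    sig: TraceSignatureModel,
    construct: UnzipConstruct,
    elastic: ElasticParams,
    tables: ElasticTables,
    f_ref: float = 15.0,
) -> np.ndarray:
    """Per-bp opening costs (kT) with protein signatures superposed.

    A clamped protein adds a Gaussian barrier; its total energy is sized so
    the equilibrium force rise reaches ~``rise_amp_pN`` against this
    construct's compliance (the fork must charge the stored elastic energy
    ½ C Δf² before it can cross, plus the ssDNA release work across the
    barrier footprint).  The R-loop bubble removes pairing cost over the
    hybrid (the strands are already separated), tapering upstream over the
    breathing offset.
    """
    kT = elastic.kT_pN_nm
    per_pN = 2.0 * tables.ss_at(f_ref) / kT  # kT per bp per pN of force shift
    out = dg.astype(float).copy()
    j = np.arange(out.size)
    sigma = sig.rise_width_bp / 2.355  # FWHM -> s.d.
    for r in rises:
        C = _compliance_nm_per_pN(construct, r, tables, f_ref)
        barrier_kT = (
            0.5 * C * sig.rise_amp_pN**2
            + 2.0 * tables.ss_at(f_ref) * sig.rise_amp_pN * sigma
        ) / kT
        # the stall point (observed force peak) sits slightly upstream of the
        # barrier centroid; center the barrier 1 bp downstream so the called
        # peak lands on the nominal clamp position
        profile = np.exp(-0.5 * ((j - (r + 1.0)) / sigma) ** 2)
        out += barrier_kT * profile / profile.sum()
    if dip_window is not None:
        lo, hi = dip_window
        ramp = np.clip(
            (j - (lo - sig.breathing_offset_bp)) / max(sig.breathing_offset_bp, 1e-6),
            0,
            1,
        )
        bubble = np.where((j >= lo) & (j < hi), 1.0, np.where(j < lo, ramp, 0.0))
        # Boltzmann averaging shallows the equilibrium dip relative to the
        # naive work balance; oversubtract so the rendered dip reaches the
        # requested amplitude
        out -= (1.6 * sig.dip_amp_pN * per_pN) * bubble
        out = np.clip(out, 0.15, None)
    return out


def render_trace(
    category: str,
    construct: UnzipConstruct,
    sig: TraceSignatureModel,
    thermo: ThermoParams,
    elastic: ElasticParams,
    rng: np.random.Generator,
    tables: ElasticTables | None = None,
    schedule: np.ndarray | None = None,
    cutoff_bp: float = 60.0,
    velocity_nm_s: float = 500.0,
    acquisition_rate_hz: float = 10_000.0,
) -> tuple[Trace, TraceTruth]:
    """Render a full (time, force, extension) record for one category.

    The trace is the equilibrium unzipping curve of the construct with the
    category's protein signatures written into the energy landscape
    (clamp barriers as force rises, the R-loop bubble as a force dip with
    its thermal-breathing look-ahead emerging from the Boltzmann average),
    sampled uniformly in extension at the acquisition rate with Gaussian
    force noise.  Naked traces are the unperturbed baseline plus noise.
    """
    if category not in PRE_CATEGORIES and category not in POST_CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    dcas_present = category in ("A20_dCas", "dCas_only", "TEC_up_dCas", "Coll")
    if tables is None:
        tables = ElasticTables(elastic)
    if schedule is None:
        schedule = make_schedule(construct, elastic, n_points=1200)

    motor_pos = _draw_motor_position(category, construct, sig, cutoff_bp, rng)
    rises: list[float] = []
    if motor_pos is not None:
        rises.append(motor_pos)
    dip_window: tuple[float, float] | None = None
    if dcas_present:
        clamp = _dcas_clamp_position(construct, sig)
        rises.append(clamp)
        if construct.direction == "PAM-distal-first":
            dip_window = construct.rloop_window
            if sig.dcas12a_dual_conformation and rng.random() > sig.dcas12a_single_rise_weight:
                rises.append(construct.rloop_window[0] + 2.0)  # distal-end rise

    margin = 2.0 * sig.rise_width_bp
    for r in rises:
        if not (margin <= r <= construct.length - 3.0):
            raise ValueError(
                f"signature at {r:.1f} bp extends beyond the {construct.length}-bp segment"
            )

    dg = junction_energies(construct.sequence, thermo)
    dg_mod = signature_energies(dg, rises, dip_window, sig, construct, elastic, tables)
    curve = equilibrium_unzip_curve(
        construct, thermo, elastic, schedule=schedule, tables=tables, dg_override=dg_mod
    )

    # sample uniformly in extension: constant-velocity acquisition
    dz = velocity_nm_s / acquisition_rate_hz
    ext_u = np.arange(curve.extension_nm[0], curve.extension_nm[-1], dz)
    force_u = np.interp(ext_u, curve.extension_nm, curve.force_pN)
    force_u = force_u + rng.normal(0.0, sig.noise_sd_pN, size=force_u.size)
    time = np.arange(1, ext_u.size + 1) / acquisition_rate_hz
    trace = Trace(
        time_s=time,
        force_pN=force_u,
        extension_nm=ext_u,
        rate_hz=acquisition_rate_hz,
        loading_mode="constant-velocity",
    )
    return trace, TraceTruth(
        category=category,
        motor_pos=motor_pos,
        dcas_present=dcas_present,
        rise_positions=rises,
    )
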