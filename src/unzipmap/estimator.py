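"""Conditional-probability estimator of roadblock read-through and removal.

Per-chamber category fractions measured before and after the chase are
combined with separately measured nuisance probabilities (noncollision
dissociation of the motor and of the Cas complex) to estimate, for the
motors that actually reached the roadblock:

* ``collision_competence`` — P(motor reached the Cas site | it survived),
* ``read_through``         — P(roadblock removed AND motor passed the site),
* ``removal``              — read-through plus removal-then-stall events.

Estimates are plug-in ratios of linear combinations of fractions; sampling
noise can push them slightly outside [0, 1], in which case they are
flagged but never clipped (clipping would bias the cross-chamber mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PRE_CATEGORIES = ("A20_dCas", "A20_only", "dCas_only", "Nak")
POST_CATEGORIES = (
    "TEC_up_dCas",
    "TEC_up_only",
    "Coll",
    "dCas_rem",
    "TEC_dn",
    "Nak",
    "dCas_only",
)

_SUM_TOL = 1e-9


@dataclass
class NuisanceParams:
    """Noncollision dissociation probabilities over the chase interval."""

    p_motor_diss: float = 0.0
    p_dcas_diss: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_motor_diss", "p_dcas_diss"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass
class ChamberCounts:
    """Pre-chase (4) and post-chase (7) category fractions for one chamber."""

    pre: dict[str, float]
    post: dict[str, float]
    pre_total: int | None = None
    post_total: int | None = None
    chamber_id: str = ""

    def __post_init__(self) -> None:
        for names, fr in ((PRE_CATEGORIES, self.pre), (POST_CATEGORIES, self.post)):
            missing = set(names) - set(fr)
            if missing:
                raise ValueError(f"missing category fractions: {sorted(missing)}")
            vals = np.array([fr[k] for k in names], dtype=float)
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError("fractions must lie in [0, 1]")
            if abs(vals.sum() - 1.0) > _SUM_TOL:
                raise ValueError(
                    f"fractions must sum to 1 (got {vals.sum():.12f})"
                )

    @classmethod
    def from_counts(
        cls,
        pre_counts: dict[str, int],
        post_counts: dict[str, int],
        chamber_id: str = "",
    ) -> "ChamberCounts":
        n_pre = sum(pre_counts.get(k, 0) for k in PRE_CATEGORIES)
        n_post = sum(post_counts.get(k, 0) for k in POST_CATEGORIES)
        if n_pre == 0 or n_post == 0:
            raise ValueError("each phase needs at least one classified trace")
        return cls(
            pre={k: pre_counts.get(k, 0) / n_pre for k in PRE_CATEGORIES},
            post={k: post_counts.get(k, 0) / n_post for k in POST_CATEGORIES},
            pre_total=n_pre,
            post_total=n_post,
            chamber_id=chamber_id,
        )


@dataclass
class ChamberEstimate:
    chamber_id: str
    p_coll_comp: float
    p_read_through: float
    p_removal: float
    valid: bool = True
    flags: list[str] = field(default_factory=list)


@dataclass
class EfficiencyResult:
    chambers: list[ChamberEstimate]
    mean_read_through: float
    sem_read_through: float
    mean_removal: float
    sem_removal: float
    mean_coll_comp: float
    sem_coll_comp: float
    n_valid: int
    n_excluded: int


def collision_competence(c: ChamberCounts, nu: NuisanceParams) -> float:
    """P(motor reached the Cas site | motor survived the chase)."""
    denom = (c.pre["A20_dCas"] + c.pre["A20_only"]) * (1.0 - nu.p_motor_diss)
    if denom <= 0.0:
        raise ZeroDivisionError(
            "collision competence undefined: no initial motor-bearing traces "
            f"(denominator {denom:g})"
        )
    return 1.0 - (c.post["TEC_up_dCas"] + c.post["TEC_up_only"]) / denom


def _readthrough_numerator(c: ChamberCounts, nu: NuisanceParams, p_cc: float) -> float:
    pm, pd = nu.p_motor_diss, nu.p_dcas_diss
    reached_or_lost = p_cc * (1.0 - pm) + pm
    return (
        c.post["Nak"]
        + c.post["TEC_dn"]
        - c.pre["Nak"]
        - c.pre["A20_dCas"] * reached_or_lost * pd
        - c.pre["A20_only"] * reached_or_lost
        - c.pre["dCas_only"] * pd
    )


def _denominator(c: ChamberCounts, nu: NuisanceParams, p_cc: float) -> float:
    return (
        c.pre["A20_dCas"]
        * p_cc
        * (1.0 - nu.p_motor_diss)
        * (1.0 - nu.p_dcas_diss)
    )


def read_through(c: ChamberCounts, nu: NuisanceParams, p_cc: float) -> float:
    """P(read-through | collision-competent motor met a still-bound Cas).

    Starts from the post-chase naked + motor-downstream pool and subtracts
    every noncollision pathway that also feeds it.
    """
    denom = _denominator(c, nu, p_cc)
    if denom <= 0.0:
        raise ZeroDivisionError(
            f"read-through undefined: denominator {denom:g} "
            "(no collision-competent co-occupied traces expected)"
        )
    return _readthrough_numerator(c, nu, p_cc) / denom


def removal(c: ChamberCounts, nu: NuisanceParams, p_cc: float) -> float:
    """Like read-through but also crediting removal-then-stall traces."""
    denom = _denominator(c, nu, p_cc)
    if denom <= 0.0:
        raise ZeroDivisionError(
            f"removal undefined: denominator {denom:g}"
        )
    return (_readthrough_numerator(c, nu, p_cc) + c.post["dCas_rem"]) / denom


def estimate_chamber(c: ChamberCounts, nu: NuisanceParams) -> ChamberEstimate:
    flags: list[str] = []
    try:
        p_cc = collision_competence(c, nu)
        p_rt = read_through(c, nu, p_cc)
        p_rem = removal(c, nu, p_cc)
    except ZeroDivisionError as err:
        return ChamberEstimate(
            c.chamber_id, np.nan, np.nan, np.nan, valid=False, flags=[str(err)]
        )
    for name, v in (
        ("p_coll_comp", p_cc),
        ("p_read_through", p_rt),
        ("p_removal", p_rem),
    ):
        if not (0.0 <= v <= 1.0):
            flags.append(f"{name} outside [0,1]: {v:.4f}")
    return ChamberEstimate(c.chamber_id, p_cc, p_rt, p_rem, valid=True, flags=flags)


def aggregate(estimates: list[ChamberEstimate]) -> EfficiencyResult:
    """Unweighted cross-chamber mean and s.e.m. (sample s.d. / sqrt(n))."""
    valid = [e for e in estimates if e.valid]
    if not valid:
        raise ValueError("no valid chambers to aggregate")

    def mean_sem(values: list[float]) -> tuple[float, float]:
        arr = np.array(values, dtype=float)
        mean = float(arr.mean())
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else np.nan
        return mean, sem

    m_rt, s_rt = mean_sem([e.p_read_through for e in valid])
    m_rm, s_rm = mean_sem([e.p_removal for e in valid])
    m_cc, s_cc = mean_sem([e.p_coll_comp for e in valid])
    return EfficiencyResult(
        chambers=estimates,
        mean_read_through=m_rt,
        sem_read_through=s_rt,
        mean_removal=m_rm,
        sem_removal=s_rm,
        mean_coll_comp=m_cc,
        sem_coll_comp=s_cc,
        n_valid=len(valid),
        n_excluded=len(estimates) - len(valid),
    )
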