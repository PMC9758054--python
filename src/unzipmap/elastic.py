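"""Polymer elasticity of the unzipping construct.

ssDNA is modeled as an extensible freely-jointed chain (FJC) and dsDNA as
an extensible worm-like chain (WLC, Marko–Siggia interpolation with a
stretch-modulus term).  Extensions are reported per monomer (nm/nt for
ssDNA, nm/bp for dsDNA); multiply by monomer counts for a whole molecule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq


@dataclass
class ElasticParams:
    """Elastic constants of ssDNA and dsDNA plus the thermal energy.

    Defaults are the standard optical-tweezers values: ssDNA contour
    0.56 nm/nt, Kuhn length 1.5 nm, stretch modulus 800 pN; dsDNA contour
    0.338 nm/bp, persistence length 43 nm, stretch modulus 1200 pN;
    kT = 4.116 pN nm (298.15 K).
    """

    ss_contour_nm: float = 0.56
    ss_kuhn_nm: float = 1.5
    ss_stretch_pN: float = 800.0
    ds_contour_nm: float = 0.338
    ds_persistence_nm: float = 43.0
    ds_stretch_pN: float = 1200.0
    kT_pN_nm: float = 4.116

    def __post_init__(self) -> None:
        for name in (
            "ss_contour_nm",
            "ss_kuhn_nm",
            "ss_stretch_pN",
            "ds_contour_nm",
            "ds_persistence_nm",
            "ds_stretch_pN",
            "kT_pN_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def ssdna_extension(force, p: ElasticParams):
    """Extensible-FJC extension of ssDNA, nm per nucleotide.

    x(f) = Lc [coth(f b / kT) - kT / (f b)] (1 + f / S); x(0) = 0.
    """
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be nonnegative")
    u = f * p.ss_kuhn_nm / p.kT_pN_nm
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        langevin = np.where(
            u < 1e-8, u / 3.0, 1.0 / np.tanh(np.clip(u, 1e-300, 700)) - 1.0 / u
        )
    x = p.ss_contour_nm * langevin * (1.0 + f / p.ss_stretch_pN)
    return x if x.ndim else float(x)


def _ms_force(l: float, p: ElasticParams) -> float:
    """Marko–Siggia force at effective fractional extension l (stretch removed)."""
    return (p.kT_pN_nm / p.ds_persistence_nm) * (
        0.25 / (1.0 - l) ** 2 - 0.25 + l
    )


def dsdna_extension(force, p: ElasticParams):
    """Extensible-WLC extension of dsDNA, nm per base pair.

    Solves f = (kT/P) [1/(4(1-l)^2) - 1/4 + l] for the effective fractional
    extension l = x/Lc - f/S, then x = Lc (l + f/S).
    """
    f = np.atleast_1d(np.asarray(force, dtype=float))
    if np.any(f < 0):
        raise ValueError("force must be nonnegative")
    out = np.empty_like(f)
    for i, fi in enumerate(f):
        if fi == 0.0:
            out[i] = 0.0
            continue
        l = brentq(lambda l: _ms_force(l, p) - fi, 0.0, 1.0 - 1e-9, xtol=1e-12)
        out[i] = p.ds_contour_nm * (l + fi / p.ds_stretch_pN)
    return out if np.asarray(force).ndim else float(out[0])


class ElasticTables:
    """Tabulated extensions and stretching work on a force grid.

    Precomputes x_ss(f), x_ds(f) and their force integrals
    w(f) = ∫_0^f x(f') df' (the Legendre partner of the stretching free
    energy) for fast vectorized evaluation inside the equilibrium curve.
    """

    def __init__(self, p: ElasticParams, f_max: float = 65.0, n: int = 2600):
        self.params = p
        self.f_grid = np.linspace(0.0, f_max, n)
        self.x_ss = ssdna_extension(self.f_grid, p)
        self.x_ds = dsdna_extension(self.f_grid, p)
        self.w_ss = cumulative_trapezoid(self.x_ss, self.f_grid, initial=0.0)
        self.w_ds = cumulative_trapezoid(self.x_ds, self.f_grid, initial=0.0)

    def ss_at(self, force):
        return np.interp(force, self.f_grid, self.x_ss)

    def ds_at(self, force):
        return np.interp(force, self.f_grid, self.x_ds)

    def w_ss_at(self, force):
        return np.interp(force, self.f_grid, self.w_ss)

    def w_ds_at(self, force):
        return np.interp(force, self.f_grid, self.w_ds)
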