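"""Equilibrium unzipping theory curve.

At a controlled total DNA end-to-end extension z the fork position j is in
rapid equilibrium; its Boltzmann weight combines the sequence cost of the
opened base pairs with the stretching free energy of the arms plus 2j
released ssDNA nucleotides held at extension z.  The observable curve is
the weighted mean force and mean fork position versus z; sequence
heterogeneity produces the characteristic sawtooth about the 12–17 pN
plateau and the Boltzmann averaging yields the thermal "breathing"
softening ahead of weakly paired regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .construct import UnzipConstruct
from .elastic import ElasticParams, ElasticTables
from .thermo import ThermoParams, junction_energies

#: Boltzmann-weight truncation threshold (relative to the per-z maximum)
WEIGHT_CUTOFF = 1e-12


@dataclass
class TheoryCurve:
    """Naked-DNA unzipping baseline: force and mean fork position vs z."""

    extension_nm: np.ndarray
    force_pN: np.ndarray
    bp_unzipped: np.ndarray

    def baseline_force(self, bp) -> np.ndarray:
        """Baseline force at a given fork position, by interpolation."""
        order = np.argsort(self.bp_unzipped)
        return np.interp(
            bp, self.bp_unzipped[order], self.force_pN[order]
        )


def make_schedule(
    construct: UnzipConstruct,
    elastic: ElasticParams,
    n_points: int = 1600,
    f_start: float = 6.0,
    f_end: float = 20.0,
) -> np.ndarray:
    """Extension schedule from arms-only (at ``f_start``) to fully unzipped
    (at ``f_end``), linear in z — the constant-velocity loading mode."""
    tables = ElasticTables(elastic)
    z0 = construct.arm_bp * tables.ds_at(f_start)
    z1 = construct.arm_bp * tables.ds_at(f_end) + 2 * construct.length * tables.ss_at(
        f_end
    )
    return np.linspace(z0, z1, n_points)


def equilibrium_unzip_curve(
    construct: UnzipConstruct,
    thermo: ThermoParams,
    elastic: ElasticParams,
    schedule: np.ndarray | None = None,
    tables: ElasticTables | None = None,
    dg_override: np.ndarray | None = None,
) -> TheoryCurve:
    """Boltzmann-weighted equilibrium unzipping curve along an extension schedule.

    For each fork position j the force at extension z solves
    z = N_arm x_ds(f) + 2 j x_ss(f); the stretching (Helmholtz) free energy
    at fixed z is recovered from the tabulated work integrals by Legendre
    back-transform, A(j, z) = f_j z - N_arm w_ds(f_j) - 2 j w_ss(f_j).

    ``dg_override`` replaces the sequence's per-bp opening costs (kT units);
    the trace renderer uses it to superpose protein barriers and the
    pre-opened R-loop bubble on the same equilibrium machinery.
    """
    if schedule is None:
        schedule = make_schedule(construct, elastic)
    z = np.asarray(schedule, dtype=float)
    if tables is None:
        tables = ElasticTables(elastic)
    kT = elastic.kT_pN_nm

    if dg_override is not None:
        dg = np.asarray(dg_override, dtype=float)
        if dg.shape != (construct.length,):
            raise ValueError("dg_override must have one value per base pair")
    else:
        dg = junction_energies(construct.sequence, thermo)  # kT per bp
    L = construct.length
    G = np.concatenate([[0.0], np.cumsum(dg)])  # opened-sequence cost, kT

    f_grid = tables.f_grid
    arm_ext = construct.arm_bp * tables.x_ds  # (nf,)
    z_max = arm_ext[-1] + 2 * L * tables.x_ss[-1]
    if np.any(z > z_max):
        raise ValueError(
            "schedule extension exceeds the fully-unzipped contour at the "
            "maximum tabulated force"
        )

    nj = L + 1
    F = np.empty((nj, z.size))
    A = np.empty((nj, z.size))
    for j in range(nj):
        ext_j = arm_ext + 2 * j * tables.x_ss
        fj = np.interp(z, ext_j, f_grid)
        F[j] = fj
        A[j] = (
            fj * z
            - construct.arm_bp * tables.w_ds_at(fj)
            - 2 * j * tables.w_ss_at(fj)
        )

    logw = -(G[:, None] + A / kT)
    logw -= logw.max(axis=0, keepdims=True)
    w = np.exp(logw)
    w[w < WEIGHT_CUTOFF] = 0.0
    w /= w.sum(axis=0, keepdims=True)

    force = (w * F).sum(axis=0)
    bp = (w * np.arange(nj)[:, None]).sum(axis=0)
    return TheoryCurve(extension_nm=z, force_pN=force, bp_unzipped=bp)


def homopolymer_plateau_force(
    dg_per_bp_kT: float, elastic: ElasticParams, tables: ElasticTables | None = None
) -> float:
    """Two-state work-balance plateau force for a uniform opening cost.

    Solves ΔG_open = 2 ∫_0^{f*} x_ss(f') df' (in kT) for f*.
    """
    if tables is None:
        tables = ElasticTables(elastic)
    target = dg_per_bp_kT * elastic.kT_pN_nm
    vals = 2.0 * tables.w_ss
    if target > vals[-1]:
        raise ValueError("opening cost beyond tabulated force range")
    return float(np.interp(target, vals, tables.f_grid))
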