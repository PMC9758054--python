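"""Nearest-neighbor duplex thermodynamics for unzipping baselines.

Base-pairing free energies are computed per dinucleotide step from a
ΔH/ΔS table (unified parameters at 1 M NaCl), corrected to the working
temperature and monovalent-salt concentration, and mapped onto per-base-pair
opening costs in units of kT. The convention used throughout: pairing free
energies are negative (stabilizing); opening costs are positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: gas constant, kcal / (mol K)
R_KCAL = 1.9872e-3
#: Boltzmann constant, pN nm / K
KB_PN_NM = 1.380649e-2

# Unified nearest-neighbor ΔH (kcal/mol) and ΔS (cal/mol/K) at 1 M NaCl,
# keyed by the ten unique 5'->3' steps.  Complementary steps share values.
NN_DH_DS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _canonical_step(step: str) -> str:
    """Map a dinucleotide step to its table key (step or its reverse complement)."""
    rc = step.translate(_COMPLEMENT)[::-1]
    return step if step in NN_DH_DS else rc


def _default_nn_table(temperature: float) -> dict[str, float]:
    """ΔG(T) = ΔH - T ΔS for the ten unique steps, kcal/mol at 1 M NaCl."""
    return {
        step: dh - temperature * ds * 1e-3 for step, (dh, ds) in NN_DH_DS.items()
    }


@dataclass
class ThermoParams:
    """Duplex stability parameters.

    Parameters
    ----------
    temperature : float
        Working temperature in kelvin.  Defaults to 298.15 K (the trap
        chamber runs slightly warm from local laser heating).
    monovalent_salt : float
        Monovalent cation concentration in molar; the transcription buffer
        carries 100 mM KCl.
    salt_coeff : float
        Free-energy salt correction per base pair (i.e. per phosphate pair),
        kcal/mol per ln(M): ΔG(c) = ΔG(1 M) - salt_coeff * ln(c).
    initiation : float
        Duplex initiation penalty, kcal/mol.  A per-duplex constant; it does
        not enter per-base-pair opening energies and is kept for completeness.
    nn_table : dict
        Pairing free energies (kcal/mol, negative = stabilizing) for the ten
        unique steps at 1 M NaCl and ``temperature``.  Computed from the
        unified ΔH/ΔS table unless overridden.
    """

    temperature: float = 298.15
    monovalent_salt: float = 0.100
    salt_coeff: float = 0.114
    initiation: float = 1.96
    nn_table: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not (0 < self.monovalent_salt):
            raise ValueError("monovalent_salt must be positive")
        if not self.nn_table:
            self.nn_table = _default_nn_table(self.temperature)
        missing = set(NN_DH_DS) - set(self.nn_table)
        if missing:
            raise ValueError(f"nn_table incomplete; missing steps {sorted(missing)}")
        if any(v >= 0 for v in self.nn_table.values()):
            raise ValueError("pairing free energies must be negative (stabilizing)")

    @property
    def kT_pN_nm(self) -> float:
        """Thermal energy in pN nm."""
        return KB_PN_NM * self.temperature

    @property
    def kcal_per_kT(self) -> float:
        """kcal/mol corresponding to one kT."""
        return R_KCAL * self.temperature

    def step_dg_kcal(self, step: str) -> float:
        """Salt-corrected pairing free energy of one step, kcal/mol."""
        dg = self.nn_table[_canonical_step(step)]
        return dg - self.salt_coeff * np.log(self.monovalent_salt)


def junction_energies(seq: str, thermo: ThermoParams) -> np.ndarray:
    """Per-base-pair opening free energies along ``seq``, in kT (positive).

    The nearest-neighbor step energies live on the L-1 junctions of an
    L-mer; they are averaged onto base-pair positions (terminal base pairs
    take their single adjacent step).

    Parameters
    ----------
    seq : str
        The unzipping-segment strand read in the direction of fork
        progression; ACGT alphabet, length >= 2.

    Returns
    -------
    numpy.ndarray
        One opening cost per base pair, ``len(seq)`` values, kT units.
    """
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    for i, base in enumerate(seq):
        if base not in "ACGT":
            raise ValueError(f"non-ACGT character {base!r} at position {i}")
    step_dg = np.array(
        [thermo.step_dg_kcal(seq[i : i + 2]) for i in range(len(seq) - 1)]
    )
    per_bp = np.empty(len(seq))
    per_bp[0] = step_dg[0]
    per_bp[-1] = step_dg[-1]
    if len(seq) > 2:
        per_bp[1:-1] = 0.5 * (step_dg[:-1] + step_dg[1:])
    # opening cost = -pairing free energy, converted from kcal/mol to kT
    return -per_bp / thermo.kcal_per_kT
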