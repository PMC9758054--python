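"""Study conditions for the synthetic roadblock experiments.

Each condition fixes the generator at the occupancies, nuisance
probabilities and chamber/trace scale of the corresponding optical-trap
experiment, with the true read-through (move-through, for Mfd) probability
set to that condition's reported efficiency.  Recovering the truth from
sampled chambers is the package's parameter-recovery benchmark.

Shared settings: initial occupancy fractions (0.90, 0.04, 0.04, 0.02)
(co-occupancy >90 % as measured in the controls), noncollision
dissociation probabilities 0.05 over the chase, collision competence 0.85,
~40 control and ~60 chase tethers per chamber (80 chase for the slower Mfd
reactions), chamber counts per condition as in the experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

from .simulate import GeneratorConfig


@dataclass(frozen=True)
class Condition:
    name: str
    efficiency: float  # true read-through / move-through probability
    chambers: int
    motor: str = "RNAP"
    p_motor_diss: float = 0.05
    p_dcas_diss: float = 0.05
    p_removal_stall: float = 0.10
    traces_control: int = 40
    traces_chase: int = 60


CONDITIONS: dict[str, Condition] = {
    c.name: c
    for c in (
        Condition("dcas9_pam_distal", 0.43, 6),
        Condition("dcas9_pam_distal_greb", 0.70, 6),
        Condition("dcas9_pam_proximal", 0.0, 5, p_removal_stall=0.0),
        Condition("dcas12a_pam_distal", 0.47, 5),
        Condition("dcas12a_pam_distal_greb", 0.73, 5),
        Condition("mismatch_3nt_pam_distal", 0.61, 6, p_dcas_diss=0.15),
        Condition("inverted_repeat_5nt_pam_distal", 0.18, 5),
        Condition("inverted_repeat_6nt_pam_distal", 0.10, 8),
        Condition("inverted_repeat_7nt_pam_distal", 0.10, 8),
        Condition(
            "mfd_pam_distal",
            0.20,
            6,
            motor="Mfd",
            p_motor_diss=0.15,
            p_removal_stall=0.0,
            traces_chase=80,
        ),
    )
}


def condition_config(name: str, seed: int = 0) -> GeneratorConfig:
    """GeneratorConfig for a named condition."""
    c = CONDITIONS[name]
    cfg = GeneratorConfig(
        f_A20_dCas=0.90,
        f_A20_only=0.04,
        f_dCas_only=0.04,
        f_nak=0.02,
        p_motor_diss=c.p_motor_diss,
        p_dcas_diss=c.p_dcas_diss,
        p_coll_comp=0.85,
        p_read_through=c.efficiency,
        p_removal_stall=c.p_removal_stall,
        p_block=1.0 - c.efficiency - c.p_removal_stall,
        motor=c.motor,
        chase_duration_s=480.0 if c.motor == "Mfd" else 135.0,
        traces_control=c.traces_control,
        traces_chase=c.traces_chase,
        chambers=c.chambers,
        seed=seed,
    )
    return cfg
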