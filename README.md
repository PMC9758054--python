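# unzipmap

Analysis pipeline for single-molecule DNA-unzipping mapping of
protein roadblocks to transcription — in particular, how an elongating
motor (RNAP, or the Mfd translocase) collides with a DNA-bound dCas
effector, and how often it reads through or removes it.

In the assay this package models, an optical trap unzips a dsDNA
construct at constant velocity.  Bound proteins resist the fork and
register as rises in the unzipping force above the naked-DNA baseline; the
unpaired DNA bubble of a dCas R-loop registers as a dip below it.  A
chamber of tethers starts with a transcription complex stalled at +20
(A20) and a dCas bound downstream; after a chase that lets the motor
translocate, each re-unzipped tether is classified into one of seven
outcome categories, and per-chamber category fractions are converted into
read-through / removal efficiencies by a conditional-probability estimator
that corrects for imperfect initial occupancy, spontaneous dissociation
and collision-incompetent motors:

    P_coll_comp   = 1 − (F_TECup,dCas_f + F_TECup_only_f)
                        / [(F_A20,dCas_i + F_A20_only_i)(1 − P_motor_diss)]
    P_read-through = [F_Nak_f + F_TECdn_f − F_Nak_i − (noncollision terms)]
                        / [F_A20,dCas_i · P_coll_comp (1 − P_motor_diss)(1 − P_dCas_diss)]
    P_removal      = same, with F_dCas_rem_f added to the numerator

Because no raw traces are publicly deposited for this kind of experiment,
the package ships a first-class synthetic generator: an outcome-level
sampler drawing from the exact probabilistic tree the estimator assumes,
and a physics-level renderer that writes protein signatures into the
sequence energy landscape and produces full (time, force, extension)
records through the same equilibrium theory used for the baseline.  The
estimator provably inverts the generator's expected fractions — exactly —
and the full trace pipeline (decimate → convert to bp → align → call
peaks → classify → estimate) recovers generating efficiencies at the
experimental chamber scale.

Audience: biophysicists analyzing unzipping-mapper data or designing
roadblock experiments, and anyone needing a tested reference
implementation of sequence-dependent unzipping theory plus the
category-fraction efficiency estimator.

## Layout

    src/unzipmap/    library: thermo, elastic, theory, construct,
                     simulate, traces, classify, estimator, conditions,
                     io, pipeline
    analysis/        numbered drivers (01 theory curve … 05 invasion)
    tests/           pytest suite (unit, property, acceptance)
    scripts/         acceptance.py (reproduces the benchmark numbers)
    docs/methods.md  model assumptions, parameters, calibrations, limits

## Worked example

```python
import numpy as np
from unzipmap import *
from unzipmap.elastic import ElasticTables
from unzipmap.pipeline import RunConfig, run_pipeline
from unzipmap.simulate import GeneratorConfig

summary = run_pipeline(RunConfig(
    seed=3,
    generator=GeneratorConfig(chambers=2, traces_control=16,
                              traces_chase=20, seed=3),
    out_dir="results/demo",
))
print(summary["mean_read_through"], summary["classification_accuracy"])
```

This simulates two chambers (truth: read-through 0.43, collision
competence 0.85, 5 % nuisance dissociation), renders every tether as a
full force-extension trace, reprocesses and classifies them, and
estimates the efficiencies.  One run prints

    0.5033603328774969 1.0

i.e. the recovered aggregate read-through is 50.3 % — two chambers of 20
chase tethers each carry that much sampling noise around the 43 % truth —
with all 72 rendered traces classified into their generating category;
the output
directory holds the theory curve, outcome and classification tables, the
confusion matrix, per-chamber efficiencies and a JSON summary.

The numbered drivers tell the same story piecewise, e.g.

    $ python analysis/01_theory_curve.py
    unzipping plateau 15.05 pN (sawtooth s.d. 1.25 pN)
    poly-AT: plateau 9.83 pN, two-state work balance 9.85 pN (0.17% apart)

    $ python analysis/04_recover_efficiencies.py
    ...
    10/10 conditions recovered within 3 s.e.m.

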