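"""End-to-end runner: simulate -> render -> process -> classify -> estimate.

Deterministic given a single seed; every stage writes its artifact under
the output directory and the final report carries per-chamber efficiencies,
the aggregate mean ± s.e.m. and (for synthetic runs) the category
confusion matrix against the generator's ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassifierConfig, classify_postchase, classify_prechase
from .construct import UnzipConstruct, demo_construct
from .elastic import ElasticParams, ElasticTables
from .estimator import NuisanceParams, aggregate, estimate_chamber
from .io import write_table
from .simulate import (
    GeneratorConfig,
    TraceSignatureModel,
    chamber_counts_from_outcomes,
    render_trace,
    sample_outcomes,
)
from .theory import TheoryCurve, equilibrium_unzip_curve
from .thermo import ThermoParams
from .traces import Thresholds, align_to_theory, bp_from_force_extension, call_interactions

log = logging.getLogger("unzipmap")


@dataclass
class RunConfig:
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    signature: TraceSignatureModel = field(default_factory=TraceSignatureModel)
    thermo: ThermoParams = field(default_factory=ThermoParams)
    elastic: ElasticParams = field(default_factory=ElasticParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    classifier: ClassifierConfig | None = None
    nuisance: NuisanceParams | None = None
    construct: UnzipConstruct | None = None
    render_traces: bool = True
    out_dir: str | Path = "results/pipeline"

    def resolved(self) -> "RunConfig":
        if self.classifier is None:
            self.classifier = ClassifierConfig(motor=self.generator.motor)
        if self.nuisance is None:
            self.nuisance = NuisanceParams(
                p_motor_diss=self.generator.p_motor_diss,
                p_dcas_diss=self.generator.p_dcas_diss,
            )
        if self.construct is None:
            self.construct = demo_construct()
        return self


def process_and_classify(
    trace,
    phase: str,
    construct: UnzipConstruct,
    theory: TheoryCurve,
    elastic: ElasticParams,
    tables: ElasticTables,
    thresholds: Thresholds,
    classifier: ClassifierConfig,
):
    """The per-trace measurement chain: decimate, convert, align, call, classify."""
    from .traces import correct_transcript_annealing, decimate

    if trace.rate_hz > 1000.0:
        trace = decimate(trace, 1000.0)
    pt = bp_from_force_extension(trace, elastic, construct, tables=tables)
    pt = align_to_theory(pt, theory)
    if pt.alignment_failed:
        from .classify import TraceCategory

        return TraceCategory(phase, None, flags=["alignment failed"])
    calls = call_interactions(pt, theory, thresholds)
    calls, _ = correct_transcript_annealing(pt, calls, dcas_window=construct.rloop_window)
    if phase == "control":
        return classify_prechase(calls, construct, classifier)
    return classify_postchase(calls, construct, classifier)


def run_pipeline(cfg: RunConfig) -> dict:
    cfg = cfg.resolved()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": cfg.seed}
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    construct = cfg.construct
    theory = equilibrium_unzip_curve(construct, cfg.thermo, cfg.elastic)
    pd.DataFrame(
        {
            "extension_nm": theory.extension_nm,
            "force_pN": theory.force_pN,
            "bp_unzipped": theory.bp_unzipped,
        }
    ).to_csv(out / "theory_curve.tsv", sep="\t", index=False)

    outcomes = sample_outcomes(cfg.generator, rng)
    write_table(outcomes, out / "outcomes.tsv", "categories", meta)
    log.info("simulated %d traces in %d chambers", len(outcomes), cfg.generator.chambers)

    if cfg.render_traces:
        tables = ElasticTables(cfg.elastic)
        from .theory import make_schedule

        schedule = make_schedule(construct, cfg.elastic, n_points=1200)
        records = []
        for row in outcomes.itertuples(index=False):
            trace, truth = render_trace(
                row.category,
                construct,
                cfg.signature,
                cfg.thermo,
                cfg.elastic,
                rng,
                tables=tables,
                schedule=schedule,
                cutoff_bp=cfg.classifier.collision_cutoff_bp,
            )
            cat = process_and_classify(
                trace,
                row.phase,
                construct,
                theory,
                cfg.elastic,
                tables,
                cfg.thresholds,
                cfg.classifier,
            )
            records.append(
                {
                    "chamber_id": row.chamber_id,
                    "trace_id": row.trace_id,
                    "phase": row.phase,
                    "label": cat.label if cat.ok else "FAILED",
                    "motor_pos_bp": cat.motor_pos,
                    "dcas_pos_bp": cat.dcas_pos,
                    "flags": ";".join(cat.flags),
                    "true_category": row.category,
                }
            )
        classified = pd.DataFrame(records)
        write_table(classified, out / "classified.tsv", "classified", meta)
        confusion = pd.crosstab(classified.true_category, classified.label)
        confusion.to_csv(out / "confusion.tsv", sep="\t")
        usable = classified[classified.label != "FAILED"].rename(
            columns={"label": "category"}
        )[["chamber_id", "trace_id", "phase", "category"]]
        counts = chamber_counts_from_outcomes(usable)
        accuracy = float((classified.label == classified.true_category).mean())
        log.info("classification accuracy %.3f", accuracy)
    else:
        counts = chamber_counts_from_outcomes(outcomes)
        confusion = None
        accuracy = None

    estimates = [estimate_chamber(c, cfg.nuisance) for c in counts]
    result = aggregate(estimates)
    per_chamber = pd.DataFrame(
        {
            "chamber_id": [e.chamber_id for e in estimates],
            "p_coll_comp": [e.p_coll_comp for e in estimates],
            "p_read_through": [e.p_read_through for e in estimates],
            "p_removal": [e.p_removal for e in estimates],
            "valid": [e.valid for e in estimates],
            "flags": [";".join(e.flags) for e in estimates],
        }
    )
    per_chamber.to_csv(out / "efficiencies.tsv", sep="\t", index=False)

    summary = {
        "seed": cfg.seed,
        "motor": cfg.generator.motor,
        "n_chambers": cfg.generator.chambers,
        "mean_read_through": result.mean_read_through,
        "sem_read_through": result.sem_read_through,
        "mean_removal": result.mean_removal,
        "sem_removal": result.sem_removal,
        "mean_coll_comp": result.mean_coll_comp,
        "sem_coll_comp": result.sem_coll_comp,
        "n_valid_chambers": result.n_valid,
        "n_excluded_chambers": result.n_excluded,
        "classification_accuracy": accuracy,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
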