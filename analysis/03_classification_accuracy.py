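#!/usr/bin/env python
"""Confusion matrix of the trace pipeline on rendered synthetic traces.

Renders traces for every pre- and post-chase category, runs the full
measurement chain (decimate, convert, align, call, classify) and writes
the confusion matrix to results/confusion.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from unzipmap import (
    ClassifierConfig,
    ElasticParams,
    ThermoParams,
    Thresholds,
    TraceSignatureModel,
    demo_construct,
    equilibrium_unzip_curve,
    render_trace,
)
from unzipmap.elastic import ElasticTables
from unzipmap.estimator import POST_CATEGORIES, PRE_CATEGORIES
from unzipmap.pipeline import process_and_classify
from unzipmap.theory import make_schedule

OUT = Path("results")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=30)
    parser.add_argument("--per-category", type=int, default=15)
    args = parser.parse_args()

    construct = demo_construct()
    thermo, elastic = ThermoParams(), ElasticParams()
    tables = ElasticTables(elastic)
    theory = equilibrium_unzip_curve(construct, thermo, elastic, tables=tables)
    schedule = make_schedule(construct, elastic, n_points=1200)
    sig, clf, thr = TraceSignatureModel(), ClassifierConfig(), Thresholds()
    rng = np.random.default_rng(args.seed)

    rows = []
    for phase, cats in (("control", PRE_CATEGORIES), ("chase", POST_CATEGORIES)):
        for cat in cats:
            for _ in range(args.per_category):
                trace, _ = render_trace(
                    cat, construct, sig, thermo, elastic, rng,
                    tables=tables, schedule=schedule,
                )
                got = process_and_classify(
                    trace, phase, construct, theory, elastic, tables, thr, clf
                )
                rows.append(
                    {"phase": phase, "true": cat, "called": got.label or "FAILED"}
                )
    df = pd.DataFrame(rows)
    confusion = pd.crosstab(df["true"], df["called"])
    OUT.mkdir(exist_ok=True)
    confusion.to_csv(OUT / "confusion.tsv", sep="\t")
    accuracy = (df["true"] == df["called"]).mean()
    per_cat = (df["true"] == df["called"]).groupby(df["true"]).mean()
    print(confusion)
    print(f"\noverall accuracy {accuracy:.3f}; per-category minimum "
          f"{per_cat.min():.3f} ({per_cat.idxmin()})")
    print(f"wrote {OUT / 'confusion.tsv'}")


if __name__ == "__main__":
    main()
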