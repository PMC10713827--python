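#!/usr/bin/env python
"""Classify treated versus control wells with LDA, LightGBM and XGBoost.

Tunes each classifier by 5-fold grid search on the 90% training split,
reports 10-fold cross-validation spread, the held-out confusion matrix and
accuracy, and the ten most important features; everything lands in
results/classification.json.
"""

import json
from pathlib import Path

import pandas as pd

from edcprofiler.pipeline import RunConfig, classification_experiment

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    config = RunConfig()
    table = pd.read_csv(RESULTS / "well_features.csv")
    reports = classification_experiment(config, seed=SEED, table=table)
    out = {k: r.to_dict() for k, r in reports.items()}
    (RESULTS / "classification.json").write_text(json.dumps(out, indent=1))
    for kind, rep in reports.items():
        cv = rep.cv_summary
        print(f"{kind}: 10-fold CV {cv['min']:.2f}-{cv['max']:.2f} "
              f"(median {cv['median']:.2f}); test accuracy {rep.test_accuracy:.2f} "
              f"{rep.confusion}")
        top3 = ", ".join(rep.top10["feature"].head(3))
        print(f"    top features: {top3}")
    figs = ROOT / "scratch" / "figures"
    from edcprofiler.plots import confusion_heatmap, cv_boxplot, importance_barplot

    cv_boxplot(reports, save_to=figs / "cv_boxplot.png")
    for kind, rep in reports.items():
        confusion_heatmap(rep, save_to=figs / f"confusion_{kind}.png")
        importance_barplot(rep, save_to=figs / f"importance_{kind}.png")

    best = max(reports.values(), key=lambda r: r.test_accuracy)
    print(f"best classifier: {best.kind} at {best.test_accuracy:.2f}")


if __name__ == "__main__":
    main()
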