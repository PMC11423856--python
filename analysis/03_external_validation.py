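#!/usr/bin/env python
"""Apply the trained classifier to the independent validation cohort.

Quantifies the external cohort with the same pipeline, predicts subtype
labels with the discovery classifier, compares predicted-subtype survival
(KM + multi-group log-rank), and scores predictions against the planted
truth.  Writes predictions and the survival report to results/validation/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sclc_subtyping import io as sio
from sclc_subtyping.pipeline import load_model, quantify_intensity, run_validation
from sclc_subtyping.survival import subtype_names

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohorts" / "validation"
OUT = ROOT / "results" / "validation"


def main() -> None:
    model = load_model(ROOT / "results" / "discovery" / "classifier_model.pkl")
    intensity = sio.read_intensity(COHORT / "intensity.tsv")
    clinical = sio.read_clinical(COHORT / "clinical.tsv")
    abundance = quantify_intensity(intensity)
    result = run_validation(model, abundance, clinical)

    OUT.mkdir(parents=True, exist_ok=True)
    result.predictions.to_csv(OUT / "predictions.tsv", sep="\t")
    print("predicted subtype sizes:")
    print(result.predictions["predicted"].value_counts().sort_index().to_string())
    if "logrank" in result.survival_report:
        lr = result.survival_report["logrank"]
        print(f"OS log-rank across predicted subtypes: p = {lr['p_value']:.4g}")
        sio.write_json({"logrank": lr}, OUT / "survival_stats.json")

    truth = pd.read_csv(COHORT / "true_labels.tsv", sep="\t")["true_subtype"]
    names = subtype_names(clinical["os_years"], clinical["os_event"], truth.to_numpy())
    truth_named = truth.map(names)
    acc = (result.predictions["predicted"].to_numpy() == truth_named.to_numpy()).mean()
    print(f"agreement with planted truth: {acc:.1%}")


if __name__ == "__main__":
    main()
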