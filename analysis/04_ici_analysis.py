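#!/usr/bin/env python
"""Immunotherapy-benefit analysis on the simulated ICI cohort.

Classifies the checkpoint-inhibitor-treated cohort with the discovery model,
then compares ICI progression-free survival between predicted subtypes among
first-line-treated patients (pairwise log-rank), mirroring the question of
which subtype benefits from first-line immunotherapy.  Results go to
results/ici/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sclc_subtyping import io as sio
from sclc_subtyping.pipeline import load_model, quantify_intensity, run_validation
from sclc_subtyping.survival import ici_analysis

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohorts" / "ici"
OUT = ROOT / "results" / "ici"


def main() -> None:
    model = load_model(ROOT / "results" / "discovery" / "classifier_model.pkl")
    intensity = sio.read_intensity(COHORT / "intensity.tsv")
    clinical = sio.read_clinical(COHORT / "clinical.tsv")
    abundance = quantify_intensity(intensity)
    result = run_validation(model, abundance)
    labels = result.predictions["predicted"].to_numpy()

    print("predicted subtype sizes:")
    print(result.predictions["predicted"].value_counts().sort_index().to_string())
    n_first = int((clinical["ici_line"] == "first").sum())
    print(f"first-line ICI patients entering the PFS comparison: {n_first}")

    pairwise = ici_analysis(clinical, labels)
    print("pairwise first-line ICI-PFS log-rank:")
    print(pairwise.round(4).to_string(index=False))

    OUT.mkdir(parents=True, exist_ok=True)
    result.predictions.to_csv(OUT / "predictions.tsv", sep="\t")
    pairwise.to_csv(OUT / "pfs_pairwise_logrank.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
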