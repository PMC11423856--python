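#!/usr/bin/env python
"""Generate the three study-like synthetic cohorts and write them as TSV.

Produces, under results/cohorts/:

* discovery/   - 75 samples x 7000 proteins, three planted subtypes with
  fold changes (3, 3, 10), subtype-dependent survival and a chemotherapy
  interaction (benefit in the best-prognosis subtype, harm in the middle).
* validation/  - 52 independent samples drawn from the same proteome, used
  to test classifier transfer.
* ici/         - 52 extensive-stage samples treated with immune checkpoint
  inhibitors (roughly 70% first line), with progression-free survival
  planted to favour the intermediate subtype.

Every cohort also gets its planted truth (true_labels.tsv) for later checks.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sclc_subtyping import io as sio
from sclc_subtyping.synthetic import SyntheticConfig, generate_cohort

SEED = 20231
OUT = Path(__file__).resolve().parents[1] / "results" / "cohorts"


def write_cohort(name: str, cfg: SyntheticConfig) -> None:
    intensity, clinical, truth = generate_cohort(cfg)
    out = OUT / name
    out.mkdir(parents=True, exist_ok=True)
    sio.write_intensity(intensity, out / "intensity.tsv")
    sio.write_clinical(clinical, out / "clinical.tsv")
    pd.DataFrame(
        {"sample_id": clinical["sample_id"], "true_subtype": truth.true_labels}
    ).to_csv(out / "true_labels.tsv", sep="\t", index=False)
    n_detected = (intensity.raw_intensity > 0).any(axis=1).sum()
    print(f"{name}: {cfg.n_samples} samples, {n_detected} proteins detected at least once")


def main() -> None:
    discovery = SyntheticConfig(seed=SEED)
    write_cohort("discovery", discovery)

    validation = SyntheticConfig(n_samples=52, seed=SEED + 1, proteome_seed=SEED)
    write_cohort("validation", validation)

    ici = SyntheticConfig(
        n_samples=52,
        seed=SEED + 2,
        proteome_seed=SEED,
        tnm_probs=(0.0, 0.0, 0.0, 1.0),  # extensive-stage patients
        ici_first_line_fraction=0.71,
        ici_later_line_fraction=0.29,
        pfs_hazard_per_subtype=(1.2, 0.6, 1.5),  # intermediate subtype: longest PFS
    )
    write_cohort("ici", ici)


if __name__ == "__main__":
    main()
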