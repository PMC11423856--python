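"""Synthetic SCLC-like proteomic cohort generator.

Emulates the statistical structure of a label-free FFPE proteomic discovery
cohort: ~75 tumours, ~7000 detected proteins with heavy per-sample
missingness, three latent molecular subtypes with planted overexpression
signatures, and subtype-dependent overall survival with a
subtype-by-chemotherapy interaction.  Every downstream stage of the pipeline
(quantification, feature selection, consensus NMF subtyping, classification,
survival analysis) can therefore be exercised against a known ground truth.

Generative model
----------------
* Per-protein baseline: log10 latent intensity ``mu_p ~ N(base_abundance_logmean,
  base_abundance_logsd)``, shared across samples (heavy-tailed, log-normal).
* Subtype signatures: disjoint blocks of proteins; a signature protein of
  subtype k is multiplied by ``signature_fold_change[k]`` in samples of that
  subtype (defaults 3, 3, 10 — mild signatures for the two better-prognosis
  subtypes, a strong one for the worst).
* Sample noise: multiplicative log-normal, log10-sd ``noise_logsd``.
* Dropout: each entry is detected with probability
  ``sigmoid(dropout_slope * (log10 intensity - dropout_midpoint))`` —
  low-abundance proteins go missing more often, as in real MS data.
  ``dropout_slope = 0`` is the degenerate no-dropout switch (detection
  probability forced to 1).
* Survival: exponential event times with hazard
  ``hazard_rate[subtype] * exp(treatment_loghr[subtype] * chemo)``,
  independent exponential censoring, administrative cutoff at
  ``followup_max_years``.

All randomness flows through a single ``numpy.random.Generator`` seeded from
``config.seed``; identical configs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import IntensityTable

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_cohort", "generate_survival"]

_TNM_LEVELS = ("I", "II", "III", "IV")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort; defaults mirror the discovery cohort.

    Proportions default to 28/20/27 of 75, hazards to 5-year overall survival
    of 75% / ~37% / 3.7% per subtype, and the chemotherapy log-hazard-ratio to
    benefit in the best-prognosis subtype, harm in the middle one and no
    effect in the worst.
    """

    n_samples: int = 75
    n_proteins: int = 7000
    n_subtypes: int = 3
    subtype_proportions: tuple[float, ...] = (28 / 75, 20 / 75, 27 / 75)
    signature_size_per_subtype: int | tuple[int, ...] = (450, 400, 50)
    signature_fold_change: tuple[float, ...] = (3.0, 3.0, 10.0)
    base_abundance_logmean: float = 6.0
    base_abundance_logsd: float = 1.2
    signature_abundance_offset: float = 0.0
    signature_activation_sd: float = 0.0
    noise_logsd: float = 0.4
    dropout_midpoint: float = 6.0
    dropout_slope: float = 1.0
    hazard_rate_per_subtype: tuple[float, ...] = (0.0575, 0.2, 0.66)
    treatment_loghr_per_subtype: tuple[float, ...] = (-1.0, 0.7, 0.0)
    censoring_rate: float = 0.05
    followup_max_years: float = 8.0
    chemotherapy_fraction: float = 0.44
    tnm_probs: tuple[float, ...] = (13 / 73, 19 / 73, 28 / 73, 13 / 73)
    ici_first_line_fraction: float = 0.0
    ici_later_line_fraction: float = 0.0
    pfs_hazard_per_subtype: tuple[float, ...] | None = None
    seed: int = 0
    # protein-level properties (baseline abundance, peptide counts) are drawn
    # from their own generator; set the same proteome_seed on two configs to
    # make their cohorts share one proteome, as real discovery/validation
    # cohorts profiling the same organism do (None: derived from seed)
    proteome_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_proteins < 1 or self.n_subtypes < 1:
            raise ValueError("n_samples, n_proteins, n_subtypes must be positive")
        props = np.asarray(self.subtype_proportions, dtype=float)
        if props.shape != (self.n_subtypes,):
            raise ValueError("subtype_proportions length must equal n_subtypes")
        if abs(props.sum() - 1.0) > 1e-12 or (props <= 0).any():
            raise ValueError("subtype_proportions must be positive and sum to 1")
        sizes = self.signature_sizes
        if len(sizes) != self.n_subtypes or any(s < 1 for s in sizes):
            raise ValueError("signature sizes must be positive, one per subtype")
        if sum(sizes) > self.n_proteins:
            raise ValueError(
                f"disjoint signatures need {sum(sizes)} proteins, "
                f"only {self.n_proteins} available"
            )
        for name in ("signature_fold_change", "hazard_rate_per_subtype",
                     "treatment_loghr_per_subtype"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (self.n_subtypes,):
                raise ValueError(f"{name} must have one value per subtype")
        if (np.asarray(self.signature_fold_change) <= 1).any():
            raise ValueError("signature fold changes must exceed 1")
        if (np.asarray(self.hazard_rate_per_subtype) <= 0).any():
            raise ValueError("hazard rates must be strictly positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        tnm = np.asarray(self.tnm_probs, dtype=float)
        if tnm.shape != (4,) or abs(tnm.sum() - 1.0) > 1e-9:
            raise ValueError("tnm_probs must be 4 probabilities summing to 1")

    @property
    def signature_sizes(self) -> tuple[int, ...]:
        """Per-subtype planted signature sizes (scalar broadcast to all)."""
        s = self.signature_size_per_subtype
        if isinstance(s, (int, np.integer)):
            return (int(s),) * self.n_subtypes
        return tuple(int(v) for v in s)


@dataclass
class SyntheticTruth:
    """Planted ground truth of a generated cohort."""

    true_labels: np.ndarray  # integer subtype per sample, 0..n_subtypes-1
    signature_proteins: dict[int, list[str]] = field(default_factory=dict)
    true_hazards: tuple[float, ...] = ()
    true_treatment_loghr: tuple[float, ...] = ()


def _detection_probability(log_abund: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    if config.dropout_slope == 0:
        return np.ones_like(log_abund)
    z = config.dropout_slope * (log_abund - config.dropout_midpoint)
    return 1.0 / (1.0 + np.exp(-z))


def generate_survival(
    labels: np.ndarray,
    treatment: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
    hazards: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Exponential event times with subtype hazards and treatment interaction.

    Hazard for sample i is ``h[label_i] * exp(loghr[label_i] * treatment_i)``.
    Censoring is exponential at ``censoring_rate`` plus an administrative
    cutoff at ``followup_max_years``.  Returns a DataFrame with ``time`` and
    ``event`` columns.
    """
    labels = np.asarray(labels)
    treatment = np.asarray(treatment, dtype=bool)
    if labels.shape != treatment.shape:
        raise ValueError("labels and treatment must have the same length")
    base = np.asarray(
        hazards if hazards is not None else config.hazard_rate_per_subtype, dtype=float
    )
    loghr = np.asarray(config.treatment_loghr_per_subtype, dtype=float)
    h = base[labels] * np.exp(loghr[labels] * treatment)
    event_time = rng.exponential(1.0 / h)
    if config.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / config.censoring_rate, size=labels.shape)
    else:
        censor_time = np.full(labels.shape, np.inf)
    cutoff = np.minimum(censor_time, config.followup_max_years)
    time = np.minimum(event_time, cutoff)
    event = event_time <= cutoff
    return pd.DataFrame({"time": time, "event": event})


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[IntensityTable, pd.DataFrame, SyntheticTruth]:
    """Draw one cohort: intensity table, clinical table, and planted truth.

    The clinical table has one row per sample with columns ``sample_id,
    os_years, os_event, pfs_years, pfs_event, age, gender, smoking, lnm,
    tnm_stage, valg_stage, chemotherapy, ici_line``.  VALG extensive stage
    coincides with TNM IV (metastatic disease); other covariates are drawn
    independently of subtype so that adjusted survival models isolate the
    subtype effect.
    """
    rng = np.random.default_rng(config.seed)
    n, p, k = config.n_samples, config.n_proteins, config.n_subtypes

    protein_ids = [f"P{i:05d}" for i in range(p)]
    sample_ids = [f"S{i:03d}" for i in range(n)]

    labels = rng.choice(k, size=n, p=np.asarray(config.subtype_proportions))

    sizes = config.signature_sizes
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    signature = {
        s: protein_ids[bounds[s] : bounds[s + 1]] for s in range(k)
    }

    base_entropy = config.seed if config.proteome_seed is None else config.proteome_seed
    # distinct stream from the cohort draws even when the integer seed matches
    proteome_rng = np.random.default_rng(np.random.SeedSequence(base_entropy, spawn_key=(1,)))
    mu = proteome_rng.normal(
        config.base_abundance_logmean, config.base_abundance_logsd, size=p
    )
    # signature proteins sit in the abundant, well-detected stratum, as the
    # discriminative panel of a top-N abundance selection necessarily does
    mu[: bounds[-1]] += config.signature_abundance_offset
    peptides = proteome_rng.integers(5, 51, size=p)
    # per-sample activation of the tumour's own programme: emulates variable
    # tumour purity / programme strength diluting the planted signature
    activation = np.ones(n)
    if config.signature_activation_sd > 0:
        activation = np.clip(
            rng.normal(1.0, config.signature_activation_sd, size=n), 0.2, 1.8
        )
    log_fc = np.zeros((p, n))
    for s in range(k):
        rows = slice(bounds[s], bounds[s + 1])
        cols = labels == s
        log_fc[rows, cols] = np.log10(config.signature_fold_change[s]) * activation[cols]
    log_abund = mu[:, None] + log_fc + rng.normal(0.0, config.noise_logsd, size=(p, n))

    detect = rng.random(size=(p, n)) < _detection_probability(log_abund, config)
    raw = np.where(detect, 10.0 ** log_abund, 0.0)

    intensity = IntensityTable(
        raw_intensity=pd.DataFrame(raw, index=protein_ids, columns=sample_ids),
        theoretical_peptides=pd.Series(peptides, index=protein_ids),
    )

    chemo = rng.random(n) < config.chemotherapy_fraction
    surv = generate_survival(labels, chemo, config, rng)

    tnm = rng.choice(np.array(_TNM_LEVELS), size=n, p=np.asarray(config.tnm_probs))
    age = np.clip(rng.normal(60.0, 8.0, size=n), 30.0, 85.0)
    gender = np.where(rng.random(n) < 0.8, "male", "female")
    smoking = rng.random(n) < 0.7
    lnm = rng.random(n) < 0.6

    u = rng.random(n)
    p_first = config.ici_first_line_fraction
    p_later = config.ici_later_line_fraction
    ici_line = np.where(u < p_first, "first", np.where(u < p_first + p_later, "later", "none"))

    pfs_years = np.full(n, np.nan)
    pfs_event = np.full(n, np.nan)
    if config.pfs_hazard_per_subtype is not None:
        on_ici = ici_line != "none"
        pfs = generate_survival(
            labels, np.zeros(n, dtype=bool), config, rng,
            hazards=config.pfs_hazard_per_subtype,
        )
        pfs_years[on_ici] = pfs["time"].to_numpy()[on_ici]
        pfs_event[on_ici] = pfs["event"].to_numpy()[on_ici].astype(float)

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "os_years": surv["time"].to_numpy(),
            "os_event": surv["event"].to_numpy(),
            "pfs_years": pfs_years,
            "pfs_event": pfs_event,
            "age": age,
            "gender": gender,
            "smoking": smoking,
            "lnm": lnm,
            "tnm_stage": tnm,
            "valg_stage": np.where(tnm == "IV", "ES", "LS"),
            "chemotherapy": chemo,
            "ici_line": ici_line,
        }
    )

    truth = SyntheticTruth(
        true_labels=labels,
        signature_proteins=signature,
        true_hazards=tuple(config.hazard_rate_per_subtype),
        true_treatment_loghr=tuple(config.treatment_loghr_per_subtype),
    )
    return intensity, clinical, truth
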