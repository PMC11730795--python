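"""Synthetic paired-measurement generator for tests and demos.

Emulates the structure of a paired diagnostic study: each subject has a true
disease status drawn Bernoulli(prevalence) and, for every candidate test, a
continuous measurement drawn from a class-conditional Gaussian placed so
that dichotomizing at the analysis cutoff attains the target sensitivity and
specificity in expectation.

Two measurement scales are supported:

* ``log_viral_load`` — log10-scale values around a cutoff of 3.0
  (i.e. 1000 copies/mL), resembling viral-load assays; written out as
  copies/mL (10**x).
* ``probability`` — scores in (0, 1) around a cutoff of 0.5, resembling
  classifier output probabilities (a latent Gaussian passed through the
  logistic function; the monotone map preserves the operating point).

Defaults mirror a mid-sized paired accuracy study: 750 subjects at 32%
prevalence with a test of sensitivity 0.90 and specificity 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .contingency import SubjectTable
from .errors import ConfigError

LOG_VL_CUTOFF = 3.0  # log10(1000 copies/mL)
PROBABILITY_CUTOFF = 0.5


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic paired-measurement study.

    ``target_sensitivity``/``target_specificity`` are the operating
    characteristics each simulated test attains in expectation when
    dichotomized at the scale's cutoff. ``sigma`` is the within-class spread
    on the latent (log10 or logit) scale; 0.6 log10 units is a realistic
    between-replicate spread for viral-load assays.
    """

    n_subjects: int = 750
    prevalence: float = 0.32
    target_sensitivity: float = 0.90
    target_specificity: float = 0.95
    n_tests: int = 1
    missing_rate: float = 0.0
    seed: int = 0
    scale: Literal["log_viral_load", "probability"] = "log_viral_load"
    sigma: float = 0.6

    def __post_init__(self) -> None:
        for name in ("prevalence", "target_sensitivity", "target_specificity", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_subjects < 1 or self.n_tests < 1:
            raise ConfigError("n_subjects and n_tests must be >= 1")
        if self.scale not in ("log_viral_load", "probability"):
            raise ConfigError(f"unknown scale {self.scale!r}")

    @property
    def cutoff(self) -> float:
        """Analysis cutoff on the output scale."""
        return 1000.0 if self.scale == "log_viral_load" else PROBABILITY_CUTOFF


def _class_means(spec: SimulationSpec, cutoff: float) -> tuple[float, float]:
    """Latent-scale means putting P(X >= cutoff | D=1) = sens and
    P(X >= cutoff | D=0) = 1 - spec."""
    mu_pos = cutoff - spec.sigma * stats.norm.ppf(1.0 - spec.target_sensitivity)
    mu_neg = cutoff - spec.sigma * stats.norm.ppf(spec.target_specificity)
    return float(mu_pos), float(mu_neg)


def generate_paired_measurements(spec: SimulationSpec) -> SubjectTable:
    """Draw a synthetic subject-level table; deterministic under fixed seed.

    Columns: ``truth`` (the reference measurement, on the same scale and
    meeting the cutoff exactly for diseased subjects), ``test_1..test_k``,
    and ``domain`` (all ones; a placeholder subgroup id).
    """
    if spec.prevalence in (0.0, 1.0):
        import warnings

        warnings.warn(
            "degenerate prevalence: ROC/PR curves will be undefined", stacklevel=2
        )
    rng = np.random.default_rng(spec.seed)
    diseased = rng.random(spec.n_subjects) < spec.prevalence

    latent_cut = LOG_VL_CUTOFF if spec.scale == "log_viral_load" else 0.0
    mu_pos, mu_neg = _class_means(spec, latent_cut)

    def to_output(latent: np.ndarray) -> np.ndarray:
        if spec.scale == "log_viral_load":
            return 10.0 ** latent
        return expit(latent)

    # Reference values sit on the correct side of the cutoff by construction:
    # the truth column is itself a (noise-free at the operating point) assay.
    # The margin keeps negatives strictly below the cutoff after the output
    # transform's rounding (10**x or expit).
    margin = 1e-6
    truth_latent = np.where(
        diseased,
        rng.normal(latent_cut + 2.0 * spec.sigma, spec.sigma, spec.n_subjects).clip(min=latent_cut),
        rng.normal(latent_cut - 2.0 * spec.sigma, spec.sigma, spec.n_subjects).clip(max=latent_cut - margin),
    )
    columns = {"truth": to_output(truth_latent)}
    for k in range(1, spec.n_tests + 1):
        latent = np.where(
            diseased,
            rng.normal(mu_pos, spec.sigma, spec.n_subjects),
            rng.normal(mu_neg, spec.sigma, spec.n_subjects),
        )
        values = to_output(latent)
        if spec.missing_rate > 0:
            values = values.astype(float)
            values[rng.random(spec.n_subjects) < spec.missing_rate] = np.nan
        columns[f"test_{k}"] = values
    columns["domain"] = np.ones(spec.n_subjects, dtype=int)
    frame = pd.DataFrame(columns)
    return SubjectTable(
        data=frame,
        truth_column="truth",
        test_columns=[f"test_{k}" for k in range(1, spec.n_tests + 1)],
        domain_column="domain",
    )
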