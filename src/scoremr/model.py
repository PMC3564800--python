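"""Domain types shared by the simulator and the analysis layers.

The analysis operates on natural-log phenotypes throughout: a regression
coefficient on ln(BMI) or ln(25(OH)D), multiplied by 100, reads as a percent
difference in the raw trait.  Per-allele weights are therefore stored on that
percent scale (effect of one effect-allele copy on 100*ln(phenotype)).

Sign conventions follow the GWAS sources the instruments come from: for BMI
SNPs the effect allele is the BMI-raising allele (weight > 0); for vitamin D
SNPs it is the 25(OH)D-lowering allele (weight < 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigurationError, ModelError

TRAIT_AXES = ("bmi", "vitd_synthesis", "vitd_metabolism")
CONTINENTS = ("europe", "north_america")


@dataclass(frozen=True)
class SnpDef:
    """One instrument SNP: identity, axis, frequency and per-allele weight."""

    rsid: str
    gene_label: str
    trait_axis: str
    effect_allele_freq: float
    weight: float  # percent change in phenotype per effect-allele copy

    def __post_init__(self):
        if self.trait_axis not in TRAIT_AXES:
            raise ConfigurationError(
                f"{self.rsid}: unknown trait_axis {self.trait_axis!r}"
            )
        if not 0.0 < self.effect_allele_freq < 1.0:
            raise ConfigurationError(
                f"{self.rsid}: effect_allele_freq must lie strictly in (0,1)"
            )
        if self.trait_axis == "bmi" and self.weight <= 0:
            raise ConfigurationError(
                f"{self.rsid}: BMI SNP weight must be > 0 (BMI-raising allele)"
            )
        if self.trait_axis != "bmi" and self.weight >= 0:
            raise ConfigurationError(
                f"{self.rsid}: vitamin D SNP weight must be < 0 "
                "(25(OH)D-lowering allele)"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Design of one simulated cohort.

    ``lnbmi_offset``/``lnvitd_offset`` shift the cohort's phenotype means away
    from the collaboration-wide intercepts, reproducing the between-cohort
    spread of geometric means seen in multi-cohort collaborations.
    ``missing_snps`` are SNPs not genotyped in this cohort: their biological
    effect is still simulated, but the column is emitted as missing.
    """

    name: str
    n: int
    prop_female: float = 0.5
    age_mean: float = 50.0
    age_sd: float = 10.0
    continent: str = "europe"
    assay_label: str = "ria"
    missing_snps: frozenset[str] = field(default_factory=frozenset)
    resid_sd_lnbmi: float = 0.15
    resid_sd_lnvitd: float = 0.35
    month_amplitude: float = 0.15
    season_peak_month: int = 7
    lnbmi_offset: float = 0.0
    lnvitd_offset: float = 0.0
    n_pcs: int = 2

    def __post_init__(self):
        if self.n < 30:
            raise ConfigurationError(f"{self.name}: cohort n must be >= 30")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigurationError(f"{self.name}: prop_female outside [0,1]")
        if self.age_sd <= 0 or self.resid_sd_lnbmi <= 0 or self.resid_sd_lnvitd <= 0:
            raise ConfigurationError(f"{self.name}: SDs must be > 0")
        if self.continent not in CONTINENTS:
            raise ConfigurationError(
                f"{self.name}: continent must be one of {CONTINENTS}"
            )
        object.__setattr__(self, "missing_snps", frozenset(self.missing_snps))


@dataclass(frozen=True)
class TrueModel:
    """Structural truth for the two-phenotype system.

    ``gamma_bmi_to_vitd`` is the causal elasticity of ln 25(OH)D with respect
    to ln BMI; ``delta_vitd_to_bmi`` the reverse effect.  The default truth is
    the one-directional scenario the analysis is designed to detect:
    gamma = -0.42, delta = 0 (adiposity lowers vitamin D status; no reverse
    effect), with a shared standard-normal confounder loading 0.3 on both
    ln-phenotypes.  Small age and sex effects make covariate adjustment
    non-trivial without touching instrument validity.
    """

    gamma_bmi_to_vitd: float = -0.42
    delta_vitd_to_bmi: float = 0.0
    confounder_effect_bmi: float = 0.3
    confounder_effect_vitd: float = 0.3
    intercept_lnbmi: float = math.log(26.4)
    intercept_lnvitd: float = math.log(53.0)
    age_effect_lnbmi: float = 0.001   # per year of age
    age_effect_lnvitd: float = -0.002
    female_effect_lnbmi: float = -0.03
    female_effect_lnvitd: float = 0.05

    def __post_init__(self):
        for name in (
            "gamma_bmi_to_vitd",
            "delta_vitd_to_bmi",
            "confounder_effect_bmi",
            "confounder_effect_vitd",
            "intercept_lnbmi",
            "intercept_lnvitd",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"TrueModel.{name} must be finite")

    def reduced_form_det(self) -> float:
        """Determinant 1 - gamma*delta of the simultaneous-equation system."""
        det = 1.0 - self.gamma_bmi_to_vitd * self.delta_vitd_to_bmi
        if abs(self.gamma_bmi_to_vitd * self.delta_vitd_to_bmi) >= 1.0:
            raise ModelError(
                "non-invertible reduced form: |gamma*delta| >= 1 "
                f"(gamma={self.gamma_bmi_to_vitd}, delta={self.delta_vitd_to_bmi})"
            )
        return det
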