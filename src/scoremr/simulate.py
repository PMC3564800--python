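"""Individual-level cohort simulation.

Genotypes are drawn per SNP as Binomial(2, EAF) — Hardy–Weinberg equilibrium
and linkage equilibrium across SNPs.  Phenotypes are generated on the ln scale
from the structural system (deviations from cohort means):

    B* = Z_b + delta * V*          Z_b = genetics_bmi + covariates + c_b*U + e_b
    V* = Z_v + gamma * B*          Z_v = genetics_vitd + season + covariates
                                         + c_v*U + e_v

solved in reduced form B* = (Z_b + delta*Z_v)/(1-gamma*delta),
V* = (Z_v + gamma*Z_b)/(1-gamma*delta).  The seasonal term is a cosine in the
month of blood draw peaking at ``season_peak_month``; months are uniform over
1..12 so the cosine is exactly mean-zero.  SNPs listed in the cohort's
``missing_snps`` still act biologically but their columns are emitted missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .model import CohortSpec, SnpDef, TrueModel

COHORT_BASE_COLUMNS = ("iid", "age", "sex", "month")


def simulate_cohort(
    spec: CohortSpec,
    panel: list[SnpDef],
    truth: TrueModel,
    seed,
) -> pd.DataFrame:
    """Simulate one cohort; returns a table with genotype and phenotype columns.

    Columns: iid, age, sex ("M"/"F"), month (1-12), pc1..pck, bmi, vitd,
    ln_bmi, ln_vitd, then one column per panel rsid with genotype counts 0-2
    (NaN throughout a column the cohort did not genotype).
    """
    if not panel:
        raise ConfigurationError("panel must be non-empty")
    rsids = {s.rsid for s in panel}
    extra = spec.missing_snps - rsids
    if extra:
        raise ConfigurationError(
            f"{spec.name}: missing_snps not in panel: {sorted(extra)}"
        )
    det = truth.reduced_form_det()

    rng = np.random.default_rng(seed)
    n = spec.n
    freqs = np.array([s.effect_allele_freq for s in panel])
    weights = np.array([s.weight for s in panel])
    axes = np.array([s.trait_axis for s in panel])

    genotypes = rng.binomial(2, freqs, size=(n, len(panel))).astype(float)
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, size=n), 16.0, 100.0)
    female = (rng.random(n) < spec.prop_female).astype(float)
    month = rng.integers(1, 13, size=n)
    pcs = rng.normal(size=(n, spec.n_pcs))
    confounder = rng.normal(size=n)
    e_b = rng.normal(scale=spec.resid_sd_lnbmi, size=n)
    e_v = rng.normal(scale=spec.resid_sd_lnvitd, size=n)

    centered = genotypes - 2.0 * freqs
    is_bmi = axes == "bmi"
    g_bmi = centered[:, is_bmi] @ (weights[is_bmi] / 100.0)
    g_vitd = centered[:, ~is_bmi] @ (weights[~is_bmi] / 100.0)
    season = spec.month_amplitude * np.cos(
        2.0 * np.pi * (month - spec.season_peak_month) / 12.0
    )

    z_b = (
        g_bmi
        + truth.age_effect_lnbmi * (age - spec.age_mean)
        + truth.female_effect_lnbmi * (female - spec.prop_female)
        + truth.confounder_effect_bmi * confounder
        + e_b
    )
    z_v = (
        g_vitd
        + season
        + truth.age_effect_lnvitd * (age - spec.age_mean)
        + truth.female_effect_lnvitd * (female - spec.prop_female)
        + truth.confounder_effect_vitd * confounder
        + e_v
    )
    b_dev = (z_b + truth.delta_vitd_to_bmi * z_v) / det
    v_dev = (z_v + truth.gamma_bmi_to_vitd * z_b) / det

    ln_bmi = truth.intercept_lnbmi + spec.lnbmi_offset + b_dev
    ln_vitd = truth.intercept_lnvitd + spec.lnvitd_offset + v_dev

    table = pd.DataFrame(
        {
            "iid": [f"{spec.name}_{i:06d}" for i in range(n)],
            "age": age,
            "sex": np.where(female > 0.5, "F", "M"),
            "month": month,
        }
    )
    for k in range(spec.n_pcs):
        table[f"pc{k + 1}"] = pcs[:, k]
    table["bmi"] = np.exp(ln_bmi)
    table["vitd"] = np.exp(ln_vitd)
    table["ln_bmi"] = ln_bmi
    table["ln_vitd"] = ln_vitd
    for j, snp in enumerate(panel):
        col = genotypes[:, j].copy()
        if snp.rsid in spec.missing_snps:
            col[:] = np.nan
        table[snp.rsid] = col
    return table


def simulate_collaboration(
    specs: list[CohortSpec],
    panel: list[SnpDef],
    truth: TrueModel,
    seed,
) -> list[pd.DataFrame]:
    """Simulate independent cohorts with per-cohort seeds spawned from ``seed``."""
    if len(specs) < 2:
        raise ConfigurationError("a collaboration needs at least 2 cohorts")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigurationError(f"duplicate cohort names: {dupes}")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(len(specs))
    return [
        simulate_cohort(spec, panel, truth, child)
        for spec, child in zip(specs, children)
    ]


def write_cohort_table(table: pd.DataFrame, path) -> None:
    """Write a cohort table as TSV (UTF-8, header row, empty cells for NaN)."""
    table.to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort_table(path) -> pd.DataFrame:
    """Read a cohort TSV with the header contract of :func:`simulate_cohort`."""
    return pd.read_csv(path, sep="\t")
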