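"""Instrument panel construction and weight calibration.

The panel holds 12 BMI-raising SNPs and 4 vitamin-D-lowering SNPs (two acting
on 25(OH)D synthesis, two on its transport/clearance).  Allele frequencies for
the default panel are drawn uniformly from a configurable common-variant range;
relative per-SNP weight magnitudes are drawn once and then rescaled per axis so
that each allele score explains a target fraction of its phenotype's variance
under the default generator conditions (0.97% for the weighted BMI score,
0.64% for the synthesis score, 1.26% for the metabolism score).

Calibration solves the variance budget exactly.  Writing V0 for the genetic
variance contributed by an axis at unit scale and K for all non-genetic
variance of the phenotype, the marginal score R^2 equals c^2*V0 / (c^2*V0 + K),
so the axis scale c satisfies c^2*V0 = t/(1-t) * K for target t.  The two
vitamin D axes share one phenotype and are solved jointly.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .model import CohortSpec, SnpDef, TrueModel

BMI_SNPS = (
    ("rs9939609", "FTO"),
    ("rs17782313", "MC4R"),
    ("rs2867125", "TMEM18"),
    ("rs7498665", "SH2B1"),
    ("rs4074134", "BDNF"),
    ("rs29941", "KCTD15"),
    ("rs7647305", "ETV5"),
    ("rs10913469", "SEC16B"),
    ("rs7138803", "FAIM2"),
    ("rs3101336", "NEGR1"),
    ("rs10838738", "MTCH2"),
    ("rs10938397", "GNPDA2"),
)
VITD_SYNTHESIS_SNPS = (("rs12785878", "DHCR7"), ("rs10741657", "CYP2R1"))
VITD_METABOLISM_SNPS = (("rs2282679", "GC"), ("rs6013897", "CYP24A1"))

#: Target marginal variance explained by each allele score in its phenotype.
R2_TARGETS = {"bmi": 0.0097, "vitd_synthesis": 0.0064, "vitd_metabolism": 0.0126}

#: Reference age SD / female proportion used when budgeting covariate variance.
_REF_AGE_SD = 10.0
_REF_PROP_FEMALE = 0.5


def _axis_unit_variance(freqs: np.ndarray, magnitudes: np.ndarray) -> float:
    """Genetic variance of sum(w/100 * g) for unit-scale weights w."""
    return float(np.sum((magnitudes / 100.0) ** 2 * 2.0 * freqs * (1.0 - freqs)))


def calibrate_axis_scales(
    freqs: dict[str, np.ndarray],
    magnitudes: dict[str, np.ndarray],
    truth: TrueModel,
    resid_sd_lnbmi: float,
    resid_sd_lnvitd: float,
    month_amplitude: float,
    r2_targets: dict[str, float] | None = None,
) -> dict[str, float]:
    """Per-axis multiplicative weight scales hitting the R^2 targets.

    Derivation assumes the default one-directional truth (delta = 0); with a
    nonzero reverse effect the realised R^2 deviates mildly from target.
    """
    t = dict(R2_TARGETS if r2_targets is None else r2_targets)
    for axis, val in t.items():
        if not 0.0 < val < 0.5:
            raise ConfigurationError(f"R^2 target for {axis} out of range: {val}")

    pf = _REF_PROP_FEMALE
    var_cov_b = (truth.age_effect_lnbmi * _REF_AGE_SD) ** 2 + (
        truth.female_effect_lnbmi**2
    ) * pf * (1 - pf)
    var_cov_v = (truth.age_effect_lnvitd * _REF_AGE_SD) ** 2 + (
        truth.female_effect_lnvitd**2
    ) * pf * (1 - pf)
    cov_zb_zv = (
        truth.confounder_effect_bmi * truth.confounder_effect_vitd
        + truth.age_effect_lnbmi * truth.age_effect_lnvitd * _REF_AGE_SD**2
        + truth.female_effect_lnbmi * truth.female_effect_lnvitd * pf * (1 - pf)
    )

    v0 = {ax: _axis_unit_variance(freqs[ax], magnitudes[ax]) for ax in t}

    # BMI phenotype: non-genetic variance K_b, then D_b = var(ln BMI).
    k_b = truth.confounder_effect_bmi**2 + resid_sd_lnbmi**2 + var_cov_b
    tb = t["bmi"]
    c_b = math.sqrt(tb / (1.0 - tb) * k_b / v0["bmi"])
    d_b = k_b / (1.0 - tb)

    # 25(OH)D phenotype: gamma couples the whole ln BMI variance in, the
    # seasonal cosine over uniform months contributes amplitude^2/2.
    gamma = truth.gamma_bmi_to_vitd
    k_v = (
        gamma**2 * d_b
        + 2.0 * gamma * cov_zb_zv
        + truth.confounder_effect_vitd**2
        + month_amplitude**2 / 2.0
        + resid_sd_lnvitd**2
        + var_cov_v
    )
    ts, tm = t["vitd_synthesis"], t["vitd_metabolism"]
    d_v = k_v / (1.0 - ts - tm)
    c_s = math.sqrt(ts * d_v / v0["vitd_synthesis"])
    c_m = math.sqrt(tm * d_v / v0["vitd_metabolism"])
    return {"bmi": c_b, "vitd_synthesis": c_s, "vitd_metabolism": c_m}


def make_snp_panel(
    seed: int,
    freq_range: tuple[float, float] = (0.2, 0.5),
    truth: TrueModel | None = None,
    resid_sd_lnbmi: float | None = None,
    resid_sd_lnvitd: float | None = None,
    month_amplitude: float | None = None,
    r2_targets: dict[str, float] | None = None,
) -> list[SnpDef]:
    """Build the 16-SNP instrument panel, deterministic given ``seed``.

    Frequencies are drawn uniformly from ``freq_range``; relative weight
    magnitudes uniformly from [0.5, 1.5) before per-axis calibration.
    """
    lo, hi = freq_range
    if not (0.05 < lo < hi < 0.95):
        raise ConfigurationError(
            f"freq_range must lie strictly inside (0.05, 0.95): {freq_range}"
        )
    truth = truth if truth is not None else TrueModel()
    defaults = CohortSpec(name="_ref", n=1000)
    resid_sd_lnbmi = (
        defaults.resid_sd_lnbmi if resid_sd_lnbmi is None else resid_sd_lnbmi
    )
    resid_sd_lnvitd = (
        defaults.resid_sd_lnvitd if resid_sd_lnvitd is None else resid_sd_lnvitd
    )
    month_amplitude = (
        defaults.month_amplitude if month_amplitude is None else month_amplitude
    )

    rng = np.random.default_rng(seed)
    groups = {
        "bmi": BMI_SNPS,
        "vitd_synthesis": VITD_SYNTHESIS_SNPS,
        "vitd_metabolism": VITD_METABOLISM_SNPS,
    }
    freqs = {ax: rng.uniform(lo, hi, size=len(snps)) for ax, snps in groups.items()}
    mags = {ax: rng.uniform(0.5, 1.5, size=len(snps)) for ax, snps in groups.items()}
    scales = calibrate_axis_scales(
        freqs, mags, truth, resid_sd_lnbmi, resid_sd_lnvitd, month_amplitude,
        r2_targets,
    )

    panel: list[SnpDef] = []
    for axis, snps in groups.items():
        sign = 1.0 if axis == "bmi" else -1.0
        for j, (rsid, gene) in enumerate(snps):
            panel.append(
                SnpDef(
                    rsid=rsid,
                    gene_label=gene,
                    trait_axis=axis,
                    effect_allele_freq=float(freqs[axis][j]),
                    weight=float(sign * scales[axis] * mags[axis][j]),
                )
            )
    return panel


def panel_axis(panel: list[SnpDef], axis: str) -> list[SnpDef]:
    """SNPs of one trait axis, in panel order."""
    return [s for s in panel if s.trait_axis == axis]


def write_panel(panel: list[SnpDef], path) -> None:
    """Write the panel as TSV: rsid, gene, axis, eaf, weight."""
    df = pd.DataFrame(
        {
            "rsid": [s.rsid for s in panel],
            "gene": [s.gene_label for s in panel],
            "axis": [s.trait_axis for s in panel],
            "eaf": [s.effect_allele_freq for s in panel],
            "weight": [s.weight for s in panel],
        }
    )
    # %.17g keeps the read/write roundtrip exact in double precision
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_panel(path) -> list[SnpDef]:
    """Read a panel TSV written by :func:`write_panel`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        SnpDef(
            rsid=row.rsid,
            gene_label=row.gene,
            trait_axis=row.axis,
            effect_allele_freq=float(row.eaf),
            weight=float(row.weight),
        )
        for row in df.itertuples()
    ]
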