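"""Bundled simulation scenarios.

``dcardia21`` mirrors the design of a 21-cohort North American / European
collaboration totalling 42,024 subjects: heterogeneous sizes, sex mixes, age
distributions, phenotype means, assay platforms, and cohort-level missing-SNP
patterns (five cohorts lack one to three BMI SNPs; one cohort lacks a
synthesis SNP; one lacks one SNP from each vitamin D score).
"""

from __future__ import annotations

import math

from .model import CohortSpec, TrueModel

# name, n, prop-female numerator/denominator via counts, age mean, age sd,
# continent, assay, geometric-mean BMI, geometric-mean 25(OH)D, missing SNPs
_DCARDIA_ROWS = [
    ("B58C", 3711, 3703, 45.2, 0.4, "europe", "elisa", 26.9, 52.1, ()),
    ("NFBC1966", 2192, 2261, 31.1, 0.4, "europe", "ms", 24.3, 63.2, ()),
    ("FHS", 2678, 2978, 46.6, 13.1, "north_america", "ria", 26.8, 69.7,
     ("rs29941",)),
    ("LURIC", 2299, 999, 62.6, 10.6, "europe", "ria", 27.2, 37.3,
     ("rs12785878",)),
    ("HCS", 586, 624, 65.0, 2.6, "europe", "ria", 26.9, 41.7,
     ("rs7647305", "rs10913469", "rs29941")),
    ("UKBS", 1310, 1298, 43.8, 12.2, "europe", "elisa", 26.1, 52.5, ()),
    ("YoungFinns", 907, 1077, 37.6, 5.0, "europe", "ria", 25.5, 56.3, ()),
    ("CaMos", 709, 1588, 64.3, 16.6, "north_america", "ria", 26.8, 64.1, ()),
    ("TwinsUK", 176, 1754, 51.2, 13.2, "europe", "elisa", 25.3, 68.0, ()),
    ("HealthABC", 829, 729, 74.8, 2.9, "north_america", "ria", 26.3, 67.7, ()),
    ("HPFS", 1245, 0, 63.8, 8.6, "north_america", "ria", 25.5, 56.8, ()),
    ("InCHIANTI", 496, 598, 68.3, 15.5, "europe", "ria", 26.8, 43.4,
     ("rs4074134", "rs29941")),
    ("ULSAM", 1194, 0, 71.0, 0.6, "europe", "ms", 26.1, 65.8,
     ("rs2867125", "rs7498665", "rs29941")),
    ("PIVUS", 500, 499, 70.2, 0.2, "europe", "ms", 26.7, 54.3,
     ("rs7498665", "rs7647305")),
    ("GOOD", 921, 0, 18.9, 0.6, "europe", "ria", 22.1, 61.8, ()),
    ("NHS-CGEMS", 0, 870, 59.6, 5.8, "north_america", "ria", 25.0, 74.4, ()),
    ("GENMETS", 397, 424, 50.7, 11.1, "europe", "ria", 25.0, 44.7, ()),
    ("MRCEly", 323, 435, 53.5, 7.7, "europe", "elisa", 25.5, 53.2,
     ("rs10741657", "rs6013897")),
    ("SOCCS", 336, 328, 51.2, 5.1, "europe", "elisa", 26.8, 34.3, ()),
    ("NHS-T2D", 0, 720, 56.5, 6.9, "north_america", "ria", 27.1, 53.5, ()),
    ("AFOS", 141, 189, 49.0, 13.9, "north_america", "ria", 26.8, 53.8, ()),
]


def default_truth() -> TrueModel:
    """Default structural truth: gamma = -0.42, delta = 0, confounding 0.3."""
    return TrueModel()


def dcardia21_specs(truth: TrueModel | None = None) -> list[CohortSpec]:
    """Cohort specs for the bundled 21-cohort scenario (total n = 42,024)."""
    truth = truth if truth is not None else default_truth()
    specs = []
    for (name, n_m, n_w, age_m, age_sd, continent, assay, gm_bmi, gm_vitd,
         missing) in _DCARDIA_ROWS:
        n = n_m + n_w
        specs.append(
            CohortSpec(
                name=name,
                n=n,
                prop_female=n_w / n,
                age_mean=age_m,
                age_sd=max(age_sd, 0.2),
                continent=continent,
                assay_label=assay,
                missing_snps=frozenset(missing),
                lnbmi_offset=math.log(gm_bmi) - truth.intercept_lnbmi,
                lnvitd_offset=math.log(gm_vitd) - truth.intercept_lnvitd,
            )
        )
    return specs


def small_specs(
    n_cohorts: int = 5,
    n_per_cohort: int = 4000,
    truth: TrueModel | None = None,
) -> list[CohortSpec]:
    """A scaled-down collaboration cycling through the large scenario's rows.

    Used for repeated-simulation studies (e.g. coverage experiments at
    5 cohorts x 4,000 subjects) where the full 42,024-subject design would be
    needlessly slow.
    """
    base = dcardia21_specs(truth)
    specs = []
    for i in range(n_cohorts):
        tmpl = base[i % len(base)]
        specs.append(
            CohortSpec(
                name=f"sim{i + 1}",
                n=n_per_cohort,
                prop_female=tmpl.prop_female,
                age_mean=tmpl.age_mean,
                age_sd=tmpl.age_sd,
                continent=tmpl.continent,
                assay_label=tmpl.assay_label,
                missing_snps=frozenset(),
                lnbmi_offset=tmpl.lnbmi_offset,
                lnvitd_offset=tmpl.lnvitd_offset,
            )
        )
    return specs
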