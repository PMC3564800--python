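"""Allele-score construction.

The weighted score rescales the weighted allele count over the sum of weights
for the SNPs the cohort actually has, so it always reads as an average allele
dose on the 0-2 scale regardless of how many SNPs are available.  Unweighted
scores are plain risk-allele counts and are only formed when every constituent
SNP is present — a cohort missing any constituent skips that score rather than
imputing it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ScoreUndefinedError
from .model import SnpDef
from .panel import panel_axis


@dataclass(frozen=True)
class ScoreDef:
    name: str
    rsids: tuple[str, ...]
    weights: tuple[float, ...]
    weighted: bool

    def __post_init__(self):
        if len(self.rsids) != len(self.weights):
            raise ConfigurationError(
                f"{self.name}: weights and rsids must have equal length"
            )
        if any(w <= 0 for w in self.weights):
            raise ConfigurationError(f"{self.name}: score weights must be > 0")


def default_scores(panel: list[SnpDef]) -> dict[str, ScoreDef]:
    """The three analysis scores from a 16-SNP panel.

    The BMI score is weighted by the per-allele effect magnitudes; the two
    vitamin D scores are unweighted counts of 25(OH)D-lowering alleles.
    """
    bmi = panel_axis(panel, "bmi")
    syn = panel_axis(panel, "vitd_synthesis")
    met = panel_axis(panel, "vitd_metabolism")
    return {
        "bmi_score": ScoreDef(
            name="bmi_score",
            rsids=tuple(s.rsid for s in bmi),
            weights=tuple(abs(s.weight) for s in bmi),
            weighted=True,
        ),
        "synthesis_score": ScoreDef(
            name="synthesis_score",
            rsids=tuple(s.rsid for s in syn),
            weights=tuple(1.0 for _ in syn),
            weighted=False,
        ),
        "metabolism_score": ScoreDef(
            name="metabolism_score",
            rsids=tuple(s.rsid for s in met),
            weights=tuple(1.0 for _ in met),
            weighted=False,
        ),
    }


def _available_rsids(genotypes: pd.DataFrame, rsids) -> list[str]:
    """Score SNPs present in the table with at least one non-missing call."""
    return [
        r
        for r in rsids
        if r in genotypes.columns and genotypes[r].notna().any()
    ]


def weighted_allele_score(genotypes: pd.DataFrame, score: ScoreDef) -> pd.Series:
    """S = sum(w_i g_i) / sum(w_i) over the SNPs available in this cohort.

    SNPs absent from the table (or entirely missing) are dropped from both
    sums; the result stays on the 0-2 average-dose scale.
    """
    avail = _available_rsids(genotypes, score.rsids)
    if not avail:
        raise ScoreUndefinedError(
            f"{score.name}: no constituent SNPs available in this cohort"
        )
    w = np.array([score.weights[score.rsids.index(r)] for r in avail])
    values = genotypes[avail].to_numpy(dtype=float) @ w / w.sum()
    return pd.Series(values, index=genotypes.index, name=score.name)


def unweighted_allele_score(genotypes: pd.DataFrame, score: ScoreDef) -> pd.Series:
    """S = sum(g_i); requires every constituent SNP to be present."""
    avail = _available_rsids(genotypes, score.rsids)
    missing = [r for r in score.rsids if r not in avail]
    if missing:
        raise ScoreUndefinedError(
            f"{score.name}: constituent SNPs missing in this cohort: {missing}"
        )
    values = genotypes[list(score.rsids)].to_numpy(dtype=float).sum(axis=1)
    return pd.Series(values, index=genotypes.index, name=score.name)


def allele_score(genotypes: pd.DataFrame, score: ScoreDef) -> pd.Series:
    """Dispatch to the weighted or unweighted rule of ``score``."""
    if score.weighted:
        return weighted_allele_score(genotypes, score)
    return unweighted_allele_score(genotypes, score)
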