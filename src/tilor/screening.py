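"""Univariate odds-ratio screening of a SNP panel.

Each SNP is reduced to a 2×2 allele-count table (case/control ×
variant/reference allele, two alleles per subject) and tested with a
two-sided Wald z-test on the log allelic odds ratio.  SNPs with p-value
at or below the chosen significance level form the regressor set handed
to the threshold index model.  No multiple-testing correction is applied:
the screen runs at the raw per-SNP level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["ScreenResult", "allele_table", "or_screen", "screen_to_frame"]


@dataclass
class ScreenResult:
    snp_id: str
    odds_ratio: float
    p_value: float
    selected: bool


def allele_table(genotypes: np.ndarray, phenotype: np.ndarray) -> np.ndarray:
    """2×2 allele counts: rows (case, control), columns (variant, reference).

    Each subject contributes two alleles, so the table total is 2n.
    """
    g = np.asarray(genotypes)
    y = np.asarray(phenotype)
    if g.shape != y.shape or g.ndim != 1:
        raise ValueError("genotypes and phenotype must be 1-D vectors of equal length")
    case = y == 1
    a = int(g[case].sum())           # case, variant
    b = int((2 - g[case]).sum())     # case, reference
    c = int(g[~case].sum())          # control, variant
    d = int((2 - g[~case]).sum())    # control, reference
    return np.array([[a, b], [c, d]])


def _wald_or(table: np.ndarray) -> tuple[float, float]:
    """Allelic OR and two-sided Wald p; Haldane-Anscombe 0.5 on any zero cell."""
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = np.log(or_) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(or_), float(p)


def or_screen(data: GenotypeMatrix, alpha_level: float) -> list[ScreenResult]:
    """Screen every SNP by allelic OR; select those with p <= alpha_level.

    Monomorphic SNPs (all subjects share one genotype) have an undefined OR
    and are reported with NaN statistics, never selected.  Results are
    ordered by ascending p-value, ties broken by snp_id, undefined last.
    """
    if not 0 < alpha_level < 1:
        raise ValueError("alpha_level must be in (0, 1)")
    data._require_phenotype()
    results = []
    for j, snp in enumerate(data.snp_ids):
        g = data.genotypes[:, j]
        # monomorphic = one allele fixed in the sample; no allelic contrast
        if g.sum() == 0 or (2 - g).sum() == 0:
            logger.info("SNP %s is monomorphic; OR undefined, not selected", snp)
            results.append(ScreenResult(snp, float("nan"), float("nan"), False))
            continue
        or_, p = _wald_or(allele_table(g, data.phenotype))
        results.append(ScreenResult(snp, or_, p, p <= alpha_level))
    results.sort(key=lambda r: (np.isnan(r.p_value), r.p_value, r.snp_id))
    return results


def screen_to_frame(results: list[ScreenResult]):
    """Screening report as a DataFrame (snp_id, odds_ratio, p_value, selected)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "selected": [r.selected for r in results],
        }
    )
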