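"""Genotype-by-phenotype association: dominance-aware phenotype scoring and
the chi-squared linear trend test with Bonferroni control.

Phenotypes on each patterning axis are coded 0.0 / 0.5 / 1.0.  The trend
statistic is chi^2 = N * r^2 with r the Pearson correlation between allele
dosage and phenotype score over complete pairs, referred to a 1-df
chi-square; when the phenotype takes only the three coded levels this is
exactly the Cochran-Armitage trend test.  Every common site is tested on
both axes; multi-allelic sites get one test per common allele with a
within-site Bonferroni factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NoTestError
from .io import SampleMeta
from .variants import (
    ASSOC_STATUSES,
    MERGED_MINOR,
    STATUS_EXCLUDED,
    GenotypeMatrix,
    dosage_vector,
)


def phenotype_scores(
    samples: list[SampleMeta],
    axis: str,
    cr_sensitivity_recode: bool = False,
) -> np.ndarray:
    """Per-individual phenotype score vector for one axis ('D' or 'Cr').

    The Cr axis carries the dominance ambiguity: emma-type individuals on
    both axes cannot be genotyped at Cr from phenotype alone and are coded
    0.5.  ``cr_sensitivity_recode`` recodes those ambiguous 0.5 values to
    1.0 to probe the sensitivity of that convention.
    """
    if axis == "D":
        return np.array([s.d_score for s in samples])
    if axis != "Cr":
        raise NoTestError(f"unknown phenotype axis {axis!r}")
    scores = np.array([s.cr_score for s in samples])
    if cr_sensitivity_recode:
        ambiguous = np.array([s.cr_dominant_ambiguous for s in samples])
        scores = np.where(ambiguous, 1.0, scores)
    return scores


def trend_test(
    dosage: np.ndarray, phenotype: np.ndarray, min_n: int = 10
) -> tuple[float, float]:
    """Chi-squared linear trend test of dosage against phenotype score.

    chi^2 = N * r^2 on complete pairs, p from the 1-df chi-square upper
    tail.  Raises :class:`NoTestError` for constant vectors or fewer than
    ``min_n`` complete pairs.
    """
    x = np.asarray(dosage, float)
    y = np.asarray(phenotype, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < min_n:
        raise NoTestError(f"only {n} complete pairs (< min_n={min_n})")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise NoTestError("constant vector; trend test undefined")
    r = np.corrcoef(x, y)[0, 1]
    chi2 = float(n * r * r)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


@dataclass
class AssocResult:
    site_index: int
    site: str
    locus_name: str
    interval: str
    interval_coordinate: int
    phenotype_axis: str
    tested_allele: str
    chi2: float
    p: float
    minus_log10_p: float
    bonferroni_significant: bool
    n_used: int


def association_scan(
    gm: GenotypeMatrix,
    samples: list[SampleMeta],
    alpha: float = 0.05,
    maf_threshold: float = 0.05,
    min_n: int = 10,
    cr_sensitivity_recode: bool = False,
) -> pd.DataFrame:
    """Trend-test every common SNP against both phenotype axes.

    Bi-allelic and condensed sites are tested on their minor (or merged
    minor) allele.  Multi-allelic excluded sites are tested once per allele
    with frequency >= ``maf_threshold``; the site-level p is the smallest
    per-allele p times the number of alleles tested (within-site
    Bonferroni), capped at 1.  The genome-wide Bonferroni threshold is
    alpha divided by the number of sites actually tested on the axis.
    """
    order = [s.individual_id for s in samples]
    idx = gm.individual_indices(order)
    results: list[AssocResult] = []
    for axis in ("D", "Cr"):
        pheno = phenotype_scores(samples, axis, cr_sensitivity_recode)
        axis_rows: list[AssocResult] = []
        for si, site in enumerate(gm.sites):
            if site.status not in ASSOC_STATUSES:
                continue
            if site.status == STATUS_EXCLUDED:
                alleles = [
                    a
                    for a in sorted(site.allele_counts)
                    if site.allele_frequency(a) >= maf_threshold
                ]
            elif site.minor_class:
                alleles = [MERGED_MINOR]
            else:
                alleles = [site.minor_alleles[0]]
            per_allele = []
            for allele in alleles:
                dos = dosage_vector(gm, si, allele)[idx]
                try:
                    chi2, p = trend_test(dos, pheno, min_n=min_n)
                except NoTestError:
                    continue
                n_used = int(np.sum(~np.isnan(dos)))
                per_allele.append((p, chi2, allele, n_used))
            if not per_allele:
                continue
            per_allele.sort()
            best_p, best_chi2, best_allele, n_used = per_allele[0]
            p_site = min(1.0, best_p * len(per_allele))
            axis_rows.append(
                AssocResult(
                    site_index=si,
                    site=f"{site.locus_name}:{site.offset}",
                    locus_name=site.locus_name,
                    interval=site.interval,
                    interval_coordinate=site.interval_coordinate,
                    phenotype_axis=axis,
                    tested_allele=best_allele,
                    chi2=best_chi2,
                    p=p_site,
                    minus_log10_p=float(-np.log10(p_site)) if p_site > 0 else np.inf,
                    bonferroni_significant=False,  # set below
                    n_used=n_used,
                )
            )
        n_tests = len(axis_rows)
        if n_tests:
            threshold = alpha / n_tests
            for row in axis_rows:
                row.bonferroni_significant = row.p < threshold
        results.extend(axis_rows)

    df = pd.DataFrame([vars(r) for r in results])
    if not df.empty:
        df = df.sort_values(
            ["phenotype_axis", "interval", "interval_coordinate", "site"]
        ).reset_index(drop=True)
    return df
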