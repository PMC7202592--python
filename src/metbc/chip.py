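"""Clonal-hematopoiesis (CHIP) diagnostics: age trends in rate and VAF.

A gene whose mutations come from expanding blood-cell clones rather than
the tumor shows two signatures in tumor-only panel sequencing: the
mutation rate rises with patient age, and the variant allele fraction
(VAF) of those mutations falls with age (blood-derived reads dilute as the
clone is sampled against an unrelated tumor). DNMT3A is the canonical CHIP
gene; PIK3CA and TP53 serve as age-flat tumor controls.

``age_normalized_rates`` bins the cohort by age and normalizes each bin's
mutation prevalence to the 20-39 reference bin; ``vaf_age_trend`` fits an
ordinary least-squares line of VAF on age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_AGE_BINS = ((20, 39), (40, 49), (50, 59), (60, 69), (70, 120))


@dataclass
class AgeTrendResult:
    gene: str
    bins: tuple
    n_per_bin: np.ndarray
    rate_per_bin: np.ndarray
    normalized_rate: np.ndarray
    rate_se: np.ndarray
    vaf_slope: float | None = None
    vaf_slope_se: float | None = None
    vaf_slope_p: float | None = None


def _mutated_ids(cohort, gene: str) -> set:
    alts = cohort.alterations
    sub = alts[(alts["gene"] == gene) & (alts["alteration_class"] == "short_variant")]
    return set(sub["sample_id"])


def age_normalized_rates(cohort, gene: str,
                         bins: tuple = DEFAULT_AGE_BINS) -> AgeTrendResult:
    """Per-age-bin mutation prevalence, normalized to the first bin.

    The reference (first) bin must be non-empty; samples with unknown age
    are excluded. Binomial SE is reported per bin.
    """
    s = cohort.samples
    ages = pd.to_numeric(s["age_years"], errors="coerce")
    mutated = s["sample_id"].isin(_mutated_ids(cohort, gene))
    n_bin, rate, se = [], [], []
    for lo, hi in bins:
        mask = (ages >= lo) & (ages <= hi)
        n = int(mask.sum())
        n_bin.append(n)
        r = float(mutated[mask].mean()) if n else np.nan
        rate.append(r)
        se.append(np.sqrt(r * (1 - r) / n) if n and not np.isnan(r) else np.nan)
    if n_bin[0] == 0:
        raise ValueError("empty reference age bin")
    rate = np.array(rate)
    ref = rate[0]
    norm = rate / ref if ref > 0 else np.full_like(rate, np.nan)
    if ref > 0:
        norm[0] = 1.0
    return AgeTrendResult(gene=gene, bins=bins, n_per_bin=np.array(n_bin),
                          rate_per_bin=rate, normalized_rate=norm,
                          rate_se=np.array(se))


def vaf_age_trend(cohort, gene: str) -> dict:
    """OLS slope of VAF on age for one gene's short variants.

    Returns slope, SE and the two-sided normal-approximation p; NA when
    fewer than 3 (age, VAF) points are available.
    """
    alts = cohort.alterations
    sub = alts[(alts["gene"] == gene) & (alts["alteration_class"] == "short_variant")]
    sub = sub.dropna(subset=["vaf"])
    merged = sub.merge(cohort.samples[["sample_id", "age_years"]], on="sample_id")
    merged["age_years"] = pd.to_numeric(merged["age_years"], errors="coerce")
    merged = merged.dropna(subset=["age_years"])
    if len(merged) < 3:
        return {"gene": gene, "slope": np.nan, "se": np.nan, "p": np.nan,
                "n": len(merged), "note": "fewer than 3 points"}
    if merged["age_years"].nunique() < 2:
        return {"gene": gene, "slope": np.nan, "se": np.nan, "p": np.nan,
                "n": len(merged), "note": "no age variation"}
    res = stats.linregress(merged["age_years"], merged["vaf"])
    return {"gene": gene, "slope": float(res.slope), "se": float(res.stderr),
            "p": float(res.pvalue), "n": len(merged), "note": ""}


def chip_report(cohort, genes=("DNMT3A", "PIK3CA", "TP53"),
                bins: tuple = DEFAULT_AGE_BINS) -> pd.DataFrame:
    """Rate and VAF age trends for the CHIP candidate and control genes."""
    rows = []
    for g in genes:
        trend = age_normalized_rates(cohort, g, bins)
        vaf = vaf_age_trend(cohort, g)
        rows.append({
            "gene": g,
            "rate_ref_bin": trend.rate_per_bin[0],
            "normalized_rate_last_bin": trend.normalized_rate[-1],
            "vaf_slope": vaf["slope"], "vaf_slope_p": vaf["p"],
            "n_vaf_points": vaf["n"],
        })
    return pd.DataFrame(rows)
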