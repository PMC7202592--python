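"""ESR1 variant classification and hotspot / long-tail analyses.

ESR1 resistance mutations cluster in the receptor's ligand-binding domain
(LBD, residues 311-547 by default). Recurrent exact protein changes get a
named hotspot label (D538G, Y537S, Y537N, Y537C, E380Q, L536H, V422del);
everything else is pooled by in-cohort recurrence: mutations seen 2-3
times, and mutations seen once, each form their own analysis category.

The module builds the hotspot-by-site (or -histology) contingency table
with an r x c Fisher test, contrasts D538G vs other hotspots between
visceral sites and bone, and runs covariate-adjusted enrichment of the
recurrence-defined long-tail sets (seen-once LBD vs seen-once non-LBD),
testing the between-set contrast as a Wald test on the difference of the
two carrier coefficients in a joint logistic model.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import config as cfg
from .enrichment import fisher_exact_2x2, fisher_exact_rxc, fit_logistic

logger = logging.getLogger("metbc")

_SUB_RE = re.compile(r"^([A-Z])(\d+)(del|dup|[A-Z*])$")

HOTSPOT_LABELS = list(cfg.ESR1_HOTSPOTS) + ["pooled_2_3", "pooled_1", "other"]


@dataclass
class Esr1Variant:
    sample_id: str
    protein_change: str
    position: int | None
    hotspot_label: str
    in_lbd: bool
    recurrence: int


def classify_esr1_variant(
    protein_change: str,
    recurrence: int,
    lbd_interval: tuple[int, int] = cfg.ESR1_LBD_INTERVAL,
) -> tuple[str, bool, int | None]:
    """(hotspot_label, in_lbd, position) for one protein change.

    Named hotspots keep their label at any recurrence; other changes pool
    by in-cohort recurrence (>=4 -> other, 2-3 -> pooled_2_3, 1 ->
    pooled_1). Unparseable strings classify as ``other`` with a warning,
    never dropped.
    """
    change = str(protein_change).strip()
    if change in cfg.ESR1_HOTSPOTS:
        m = _SUB_RE.match(change)
        pos = int(m.group(2))
        return change, lbd_interval[0] <= pos <= lbd_interval[1], pos
    m = _SUB_RE.match(change)
    if not m:
        logger.warning("unparseable ESR1 protein change %r -> other", protein_change)
        return "other", False, None
    pos = int(m.group(2))
    in_lbd = lbd_interval[0] <= pos <= lbd_interval[1]
    if recurrence >= 4:
        label = "other"
    elif recurrence >= 2:
        label = "pooled_2_3"
    else:
        label = "pooled_1"
    return label, in_lbd, pos


def collect_esr1_variants(
    cohort,
    lbd_interval: tuple[int, int] = cfg.ESR1_LBD_INTERVAL,
) -> pd.DataFrame:
    """All ESR1 short variants with cohort-wide recurrence and labels.

    Recurrence is counted over the full analyzed cohort before any
    grouping, so pooling is stable under sample reordering.
    """
    alts = cohort.alterations
    sub = alts[(alts["gene"] == "ESR1")
               & (alts["alteration_class"] == "short_variant")].copy()
    if sub.empty:
        return pd.DataFrame(columns=["sample_id", "protein_change", "position",
                                     "hotspot_label", "in_lbd", "recurrence"])
    counts = sub["protein_change"].value_counts()
    rows = []
    for _, r in sub.iterrows():
        rec = int(counts.get(r["protein_change"], 0))
        label, in_lbd, pos = classify_esr1_variant(r["protein_change"], rec, lbd_interval)
        rows.append({"sample_id": r["sample_id"], "protein_change": r["protein_change"],
                     "position": pos, "hotspot_label": label, "in_lbd": in_lbd,
                     "recurrence": rec})
    return pd.DataFrame(rows)


def hotspot_site_table(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    stratifier: str = "site",
    min_stratum_variants: int = 1,
    seed: int = 0,
) -> dict:
    """Hotspot-by-stratum contingency table with Fisher p.

    Rows are strata (biopsy sites or histologies); columns hotspot labels.
    ``percentages`` holds each cell as the share of that stratum's ESR1
    mutations (rows sum to 100); ``carrier_fraction`` is the fraction of
    the stratum's samples carrying any ESR1 mutation.
    """
    if variants.empty:
        raise ValueError("no ESR1 variants")
    col = {"site": "biopsy_site", "histology": "histology"}[stratifier]
    merged = variants.merge(samples[["sample_id", col]], on="sample_id")
    table = pd.crosstab(merged[col], merged["hotspot_label"])
    table = table[[c for c in HOTSPOT_LABELS if c in table.columns]]
    table = table[table.sum(axis=1) >= min_stratum_variants]
    pct = table.div(table.sum(axis=1), axis=0) * 100

    carriers = merged.drop_duplicates(["sample_id"])[["sample_id", col]]
    denom = samples.groupby(col)["sample_id"].nunique()
    num = carriers.groupby(col)["sample_id"].nunique()
    carrier_frac = (num / denom).reindex(table.index).fillna(0.0)

    if table.shape[0] >= 2 and table.shape[1] >= 2:
        p = fisher_exact_rxc(table.to_numpy(), seed=seed)
    else:
        p = np.nan
    return {"counts": table, "percentages": pct,
            "carrier_fraction": carrier_frac, "fisher_p": p}


def visceral_hotspot_test(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    visceral_sites: tuple[str, ...] = cfg.VISCERAL_SITES,
    comparator_site: str = "bone",
) -> dict:
    """D538G vs other named hotspots, visceral sites vs bone (Fisher 2x2)."""
    merged = variants.merge(samples[["sample_id", "biopsy_site"]], on="sample_id")
    named = merged[merged["hotspot_label"].isin(cfg.ESR1_HOTSPOTS)]
    visc = named["biopsy_site"].isin(visceral_sites)
    comp = named["biopsy_site"].eq(comparator_site)
    d538 = named["hotspot_label"].eq("D538G")
    table = np.array([
        [int((visc & d538).sum()), int((visc & ~d538).sum())],
        [int((comp & d538).sum()), int((comp & ~d538).sum())],
    ])
    p = fisher_exact_2x2(table)
    return {"table": table, "p": p,
            "d538g_fraction_visceral": table[0, 0] / max(table[0].sum(), 1),
            "d538g_fraction_comparator": table[1, 0] / max(table[1].sum(), 1)}


def long_tail_enrichment(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Covariate-adjusted metastatic enrichment of recurrence-defined sets.

    Sets: seen-once, seen-twice, seen-once-LBD, seen-once-nonLBD. Each is a
    per-sample carrier indicator modelled as
    ``metastasis ~ carrier + covariates``; the LBD vs non-LBD seen-once
    contrast is a Wald test on the coefficient difference in a joint model
    (reported as set ``once_lbd_vs_nonlbd``, construction flagged in the
    ``note`` column).
    """
    s = samples.reset_index(drop=True)
    analyzed = s["group"].isin(["local", "metastasis"])
    s = s[analyzed].reset_index(drop=True)
    covs = covariates.reset_index(drop=True)[analyzed.values].reset_index(drop=True)
    y = s["group"].eq("metastasis").astype(float).to_numpy()

    def carrier(mask: pd.Series) -> np.ndarray:
        ids = set(variants.loc[mask.values, "sample_id"])
        return s["sample_id"].isin(ids).astype(float).to_numpy()

    sets = {
        "once": variants["recurrence"].eq(1),
        "twice": variants["recurrence"].eq(2),
        "once_lbd": variants["recurrence"].eq(1) & variants["in_lbd"],
        "once_nonlbd": variants["recurrence"].eq(1) & ~variants["in_lbd"],
        "all": variants["recurrence"].ge(1),
    }
    rows = []
    ind = {}
    for name, mask in sets.items():
        x = carrier(mask)
        ind[name] = x
        if x.sum() == 0:
            rows.append({"set": name, "n_carriers": 0, "odds_ratio": np.nan,
                         "z": np.nan, "p": np.nan, "note": "no carriers"})
            continue
        X = pd.DataFrame({"intercept": 1.0, "carrier": x})
        X = pd.concat([X, covs], axis=1)
        fit = fit_logistic(y, X)
        se = fit.se()["carrier"]
        z = fit.params["carrier"] / se
        rows.append({"set": name, "n_carriers": int(x.sum()),
                     "odds_ratio": float(np.exp(fit.params["carrier"])),
                     "z": float(z), "p": float(2 * stats.norm.sf(abs(z))),
                     "note": "penalized" if fit.penalized else ""})

    # between-set contrast: joint model with both indicators
    if ind["once_lbd"].sum() > 0 and ind["once_nonlbd"].sum() > 0:
        X = pd.DataFrame({"intercept": 1.0, "once_lbd": ind["once_lbd"],
                          "once_nonlbd": ind["once_nonlbd"]})
        X = pd.concat([X, covs], axis=1)
        fit = fit_logistic(y, X)
        c = np.zeros(len(fit.params))
        c[list(fit.params.index).index("once_lbd")] = 1.0
        c[list(fit.params.index).index("once_nonlbd")] = -1.0
        var = float(c @ fit.cov.to_numpy() @ c)
        diff = float(c @ fit.params.to_numpy())
        z = diff / np.sqrt(var)
        rows.append({"set": "once_lbd_vs_nonlbd",
                     "n_carriers": int(ind["once_lbd"].sum() + ind["once_nonlbd"].sum()),
                     "odds_ratio": float(np.exp(diff)), "z": float(z),
                     "p": float(2 * stats.norm.sf(abs(z))),
                     "note": "Wald on coefficient difference (set x carrier interaction)"})
    else:
        rows.append({"set": "once_lbd_vs_nonlbd", "n_carriers": 0,
                     "odds_ratio": np.nan, "z": np.nan, "p": np.nan,
                     "note": "empty set"})
    return pd.DataFrame(rows)
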