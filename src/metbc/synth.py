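"""Synthetic panel-sequencing cohort generator with planted effects.

The real clinical cohort behind this analysis is not publicly deposited, so
every statistical procedure in this package is exercised on cohorts drawn
from this generator. The default configuration plants the published
prevalences and effect sizes as generative parameters:

* group sizes 4,512 local / 1,357 lymph-node / 5,034 metastatic
  (+713 ambiguous),
* ESR1 short-variant prevalence 18.3% in metastases vs 2.2% in local
  disease, peaking at 44% in ER+ liver metastases,
* CTCF mutations 2.0% vs 0.9%, CDKN1B amplification 1.3% vs 3.6%,
* ER+/HER2- fraction 64% among metastases vs 48% in local disease,
* the ESR1 hotspot mixture (D538G 33.2%, Y537S 21.4%, E380Q 8.5%, ...),
  with visceral sites tilted toward D538G and bone toward Y537S,
* site-specific enrichments (NOTCH1 in skin, ASXL1/PTEN in brain,
  DNMT3A in bone, the KRAS/KEAP1/STK11/EGFR quartet in lung),
* a lung-like contaminant mixture among lung-site "metastases" carrying
  the co-occurring KRAS/KEAP1/STK11 triplet,
* age-increasing DNMT3A clonal hematopoiesis with VAF decreasing in age,
* pathology-report text with positive/negative wording and negation.

Sampling is hierarchical: group -> site -> subtype/histology/age ->
per-feature Bernoulli alteration vector (enrichments applied on the logit
scale) -> ESR1 hotspot assignment -> contaminant substitution -> CHIP
injection. Given the same (config, seed) the output is reproducible.
Ground truth per sample is returned alongside the cohort for recovery
tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import config as cfg
from .cohort import ALTERATION_COLUMNS, SAMPLE_COLUMNS, Cohort

logger = logging.getLogger("metbc")

# Genes that carry named rates or planted effects; the rest of the panel is
# synthetic filler carrying the background mutation load.
NAMED_GENES = [
    "TP53", "PIK3CA", "CDH1", "GATA3", "ESR1", "KMT2D", "MYC", "CCND1",
    "ERBB2", "PTEN", "CDKN2A", "CDKN2B", "RB1", "FGFR1", "BRCA1", "BRCA2",
    "CTCF", "CDKN1B", "FGF3", "FGF4", "FGF19", "KRAS", "NF1", "ASXL1",
    "DNMT3A", "NOTCH1", "KEAP1", "STK11", "EGFR", "LRP1B", "BRAF", "NRAS",
]

MET_SITES = {
    "liver": 0.28, "bone": 0.18, "lung": 0.12, "brain": 0.08, "skin": 0.07,
    "pleura": 0.05, "pleural fluid": 0.04, "soft tissue": 0.08,
    "ovary": 0.04, "GI": 0.06,
}

HOTSPOT_CATEGORIES = [
    "D538G", "Y537S", "E380Q", "Y537N", "Y537C", "L536H", "V422del",
    "pooled_2_3", "pooled_1_lbd", "pooled_1_nonlbd",
]


def default_panel(n_genes: int = 287) -> list[str]:
    """Named genes plus synthetic filler genes up to the panel size."""
    if n_genes < len(NAMED_GENES):
        return list(NAMED_GENES[:n_genes])
    filler = [f"SYN{i:03d}" for i in range(1, n_genes - len(NAMED_GENES) + 1)]
    return list(NAMED_GENES) + filler


@dataclass
class RateSpec:
    """Per-feature Bernoulli rate with contextual overrides.

    Resolution order: (group, er) override > group override > base rate;
    site odds multipliers are then applied on the logit scale, so planted
    probabilities stay in (0, 1).
    """

    base: float
    by_group: dict = field(default_factory=dict)          # group -> rate
    by_group_er: dict = field(default_factory=dict)       # (group, "positive"/"negative") -> rate
    by_site_er: dict = field(default_factory=dict)        # (site, er) -> rate (metastases)
    site_odds: dict = field(default_factory=dict)         # site -> odds multiplier


@dataclass
class Esr1Model:
    rate: RateSpec
    base_mixture: dict            # category -> probability, sums to 1
    site_delta: dict              # site -> {category: additive tilt}
    histology_delta: dict         # histology -> {category: additive tilt}
    local_mixture: dict           # mixture for local / lymph-node carriers
    multi_mutation_prob: float = 0.089

    def mixture_for(self, site: str | None, histology: str | None, group: str = "metastasis") -> dict:
        """Site/histology-specific category mixture (renormalized)."""
        base = self.local_mixture if group in ("local", "lymph_node") else self.base_mixture
        mix = dict(base)
        for delta in (self.site_delta.get(site, {}), self.histology_delta.get(histology, {})):
            for k, v in delta.items():
                mix[k] = mix.get(k, 0.0) + v
        arr = np.array([max(mix[k], 0.0) for k in HOTSPOT_CATEGORIES])
        total = arr.sum()
        if not total > 0:
            raise ValueError("degenerate hotspot mixture")
        return dict(zip(HOTSPOT_CATEGORIES, arr / total))


@dataclass
class ChipModel:
    """Age-dependent DNMT3A clonal-hematopoiesis injection."""

    max_prob: float = 0.12        # asymptotic CHIP probability at high age
    age_mid: float = 70.0         # logistic midpoint in years
    age_scale: float = 8.0
    vaf_mean_at_40: float = 0.22
    vaf_slope_per_year: float = -0.0022
    vaf_concentration: float = 25.0

    def prob(self, age):
        return self.max_prob * expit((np.asarray(age, float) - self.age_mid) / self.age_scale)

    def vaf_mean(self, age):
        return np.clip(
            self.vaf_mean_at_40 + self.vaf_slope_per_year * (np.asarray(age, float) - 40.0),
            0.03, 0.5,
        )


@dataclass
class ContaminantModel:
    """Misdiagnosed lung primaries among lung-site 'metastases'."""

    fraction_of_lung_mets: float = 0.08
    esr1_rate: float = 0.005


@dataclass
class TmbModel:
    mean_mutations_local: float = 5.6
    mean_mutations_met: float = 6.7
    mean_mutations_lymph: float = 6.0
    dispersion_shape: float = 8.0       # gamma shape of the per-sample load factor
    hypermutated_fraction: float = 0.01
    hypermutated_filler_rate: float = 0.13


@dataclass
class GeneratorConfig:
    n_local: int = 4512
    n_lymph: int = 1357
    n_met: int = 5034
    n_ambiguous: int = 713
    panel: list = field(default_factory=default_panel)
    site_freqs: dict = field(default_factory=lambda: dict(MET_SITES))
    er_pos_by_site: dict = field(default_factory=dict)    # site -> P(ER+)
    er_pos_local: float = 0.526
    er_pos_lymph: float = 0.60
    her2_by_site: dict = field(default_factory=dict)      # site -> P(HER2 amp)
    her2_local: float = 0.087
    her2_lymph: float = 0.09
    histology_probs: dict = field(default_factory=lambda: {"IDC": 0.78, "ILC": 0.12, "other": 0.10})
    age_mean: float = 55.0
    age_sd: float = 12.0
    er_known_fraction: float = 0.12
    rates: dict = field(default_factory=dict)             # (gene, class) -> RateSpec
    filler_rate_by_group: dict = field(default_factory=dict)
    functional_probs: tuple = (0.45, 0.25, 0.30)          # known / likely / VUS
    tumor_vaf_mean: float = 0.30
    tumor_vaf_concentration: float = 10.0
    esr1_model: Esr1Model | None = None
    contaminant_model: ContaminantModel = field(default_factory=ContaminantModel)
    chip_model: ChipModel = field(default_factory=ChipModel)
    tmb_model: TmbModel = field(default_factory=TmbModel)
    tissue_profiles: dict = field(default_factory=dict)   # tissue -> {(gene, class): rate}
    report_templates: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for n in (self.n_local, self.n_lymph, self.n_met, self.n_ambiguous):
            if n < 0:
                raise ValueError("group sizes must be nonnegative")
        if abs(sum(self.site_freqs.values()) - 1.0) > 1e-9:
            raise ValueError("metastatic site frequencies must sum to 1")
        for p in list(self.er_pos_by_site.values()) + list(self.her2_by_site.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        for spec in self.rates.values():
            for r in [spec.base, *spec.by_group.values(), *spec.by_group_er.values(),
                      *spec.by_site_er.values()]:
                if not 0.0 <= r <= 1.0:
                    raise ValueError("rates must lie in [0,1]")
            for m in spec.site_odds.values():
                if m <= 0:
                    raise ValueError("odds multipliers must be positive")
        if self.esr1_model is not None:
            for mix in (self.esr1_model.base_mixture, self.esr1_model.local_mixture):
                if abs(sum(mix.values()) - 1.0) > 1e-9:
                    raise ValueError("hotspot mixture must sum to 1")


# --------------------------------------------------------- default config


def _logit_shift_to_target(raw: dict, weights: dict, cotarget: dict, target: float) -> dict:
    """Shift site probabilities on the logit scale so the weighted mean of
    p_s * cotarget_s hits ``target``. Deterministic (Brent root find)."""

    sites = list(raw)

    def f(delta):
        return sum(
            weights[s] * expit(logit(raw[s]) + delta) * cotarget[s] for s in sites
        ) - target

    delta = brentq(f, -5.0, 5.0, xtol=1e-12)
    return {s: float(expit(logit(raw[s]) + delta)) for s in sites}


def default_config_from_paper(n_genes: int = 287) -> GeneratorConfig:
    """Generator configuration whose planted parameters equal the published
    prevalences and effect sizes (see module docstring)."""

    panel = default_panel(n_genes)
    w = dict(MET_SITES)

    # HER2 amplification: 9.4% overall among metastases, elevated in brain.
    her2 = {s: 0.0 for s in w}
    her2["brain"] = 0.18
    rest = (0.094 - w["brain"] * her2["brain"]) / (1.0 - w["brain"])
    for s in w:
        if s != "brain":
            her2[s] = rest

    # ER positivity by metastatic site: raw pattern (liver/bone high,
    # brain/lung low), logit-shifted so the overall ER+/HER2- fraction among
    # metastases equals the published 64%.
    er_raw = {
        "liver": 0.80, "bone": 0.78, "lung": 0.60, "brain": 0.45,
        "skin": 0.70, "pleura": 0.72, "pleural fluid": 0.72,
        "soft tissue": 0.70, "ovary": 0.70, "GI": 0.65,
    }
    er_pos = _logit_shift_to_target(er_raw, w, {s: 1.0 - her2[s] for s in w}, 0.64)

    # --- named per-feature rates -----------------------------------------
    R: dict[tuple, RateSpec] = {}

    def mut(gene, base, **kw):
        R[(gene, "short_variant")] = RateSpec(base, **kw)

    mut("TP53", 0.559, by_group_er={("metastasis", "negative"): 0.75,
                                    ("metastasis", "positive"): 0.48,
                                    ("local", "negative"): 0.72,
                                    ("local", "positive"): 0.42})
    mut("PIK3CA", 0.324)
    mut("CDH1", 0.11)
    mut("GATA3", 0.109, by_group_er={("metastasis", "positive"): 0.155,
                                     ("metastasis", "negative"): 0.02,
                                     ("local", "positive"): 0.145,
                                     ("local", "negative"): 0.02})
    mut("KMT2D", 0.095)
    mut("BRCA1", 0.056)
    mut("BRCA2", 0.072)
    mut("CTCF", 0.009, by_group={"metastasis": 0.020, "local": 0.009, "lymph_node": 0.014})
    mut("CDKN1B", 0.011, by_group={"metastasis": 0.019, "local": 0.011})
    mut("KRAS", 0.021, by_group={"metastasis": 0.026, "local": 0.021})
    mut("NF1", 0.033, by_group={"metastasis": 0.047, "local": 0.033})
    mut("DNMT3A", 0.012, site_odds={"bone": 2.6})
    mut("NOTCH1", 0.045, site_odds={"skin": 2.05})       # 8.8% at skin vs 4.5% local
    mut("KEAP1", 0.010)
    mut("STK11", 0.010)
    mut("EGFR", 0.012)
    mut("LRP1B", 0.082)
    mut("BRAF", 0.015)
    mut("NRAS", 0.010)
    mut("ASXL1", 0.020)

    R[("MYC", "amplification")] = RateSpec(0.228)
    R[("CCND1", "amplification")] = RateSpec(0.174, by_group_er={
        ("metastasis", "positive"): 0.22, ("metastasis", "negative"): 0.07,
        ("local", "positive"): 0.21, ("local", "negative"): 0.07})
    R[("ERBB2", "amplification")] = RateSpec(0.0)        # driven by her2_amplified flag
    R[("CDKN1B", "amplification")] = RateSpec(0.036, by_group={"metastasis": 0.013, "local": 0.036})
    R[("ASXL1", "amplification")] = RateSpec(0.008, site_odds={"brain": 5.5})  # 4.2% brain vs 0.8%
    fgf = {("metastasis", "positive"): 0.27, ("metastasis", "negative"): 0.13,
           ("local", "positive"): 0.17, ("local", "negative"): 0.04}
    for g in ("FGF3", "FGF4", "FGF19"):
        R[(g, "amplification")] = RateSpec(0.12, by_group_er=dict(fgf))
    R[("PTEN", "deletion")] = RateSpec(0.050, site_odds={"brain": 2.55})       # 11.8% brain vs 5.0%
    R[("CDKN2A", "deletion")] = RateSpec(0.045)
    R[("CDKN2B", "deletion")] = RateSpec(0.043)
    R[("RB1", "deletion")] = RateSpec(0.025)
    R[("CDKN1B", "deletion")] = RateSpec(0.001, by_group={"metastasis": 0.002, "local": 0.001})
    R[("ERBB2", "rearrangement")] = RateSpec(0.015)
    R[("FGFR1", "rearrangement")] = RateSpec(0.013)

    # --- ESR1 model -------------------------------------------------------
    contam = ContaminantModel()
    esr1_er_pos = {"liver": 0.44, "pleura": 0.25, "pleural fluid": 0.25,
                   "lung": 0.24, "bone": 0.20, "brain": 0.20}
    esr1_er_neg_rate = 0.02
    # Solve the ESR1 rate x of the unprinted ER+ met sites so the overall
    # metastatic prevalence equals 18.3%, accounting for contaminant
    # dilution among lung-site metastases.
    open_sites = [s for s in w if s not in esr1_er_pos]
    known = 0.0
    for s in w:
        scale = 1.0 - contam.fraction_of_lung_mets if s == "lung" else 1.0
        if s in esr1_er_pos:
            known += w[s] * scale * (er_pos[s] * esr1_er_pos[s] + (1 - er_pos[s]) * esr1_er_neg_rate)
        else:
            known += w[s] * scale * (1 - er_pos[s]) * esr1_er_neg_rate
    known += MET_SITES["lung"] * contam.fraction_of_lung_mets * contam.esr1_rate
    mass = sum(w[s] * er_pos[s] for s in open_sites)
    x = (0.183 - known) / mass
    if not 0.0 < x < 1.0:
        raise RuntimeError("ESR1 calibration failed")
    by_site_er = {(s, "positive"): esr1_er_pos.get(s, x) for s in w}
    by_site_er.update({(s, "negative"): esr1_er_neg_rate for s in w})
    esr1_rate = RateSpec(
        base=0.022,
        by_group={"local": 0.022, "lymph_node": 0.06},
        by_site_er=by_site_er,
    )

    base_mix = {
        "D538G": 0.332, "Y537S": 0.214, "E380Q": 0.085, "Y537N": 0.080,
        "Y537C": 0.043, "L536H": 0.019, "V422del": 0.014,
        "pooled_2_3": 0.073, "pooled_1_lbd": 0.100, "pooled_1_nonlbd": 0.040,
    }
    local_mix = {
        "D538G": 0.15, "Y537S": 0.10, "E380Q": 0.06, "Y537N": 0.04,
        "Y537C": 0.02, "L536H": 0.01, "V422del": 0.01,
        "pooled_2_3": 0.09, "pooled_1_lbd": 0.22, "pooled_1_nonlbd": 0.30,
    }
    # Visceral sites tilt toward D538G; bone toward Y537S (29% vs 22%).
    site_delta = {s: {"D538G": 0.08, "Y537S": -0.08} for s in cfg.VISCERAL_SITES}
    site_delta["bone"] = {"D538G": -0.112, "Y537S": 0.076, "pooled_1_lbd": 0.036}
    histology_delta = {"ILC": {"E380Q": 0.10, "D538G": -0.10}}
    esr1_model = Esr1Model(esr1_rate, base_mix, site_delta, histology_delta, local_mix)

    # --- background mutation load ----------------------------------------
    # Filler-gene rates are set so the expected distinct-gene mutation count
    # matches the printed group means (6.7 met / 5.6 local).
    n_filler = sum(1 for g in panel if g.startswith("SYN"))
    tmb = TmbModel()

    def named_mut_mean(group):
        total = 0.0
        er_frac = 0.64 / (1 - 0.094) if group == "metastasis" else (
            0.526 if group == "local" else 0.60)
        for (g, c), spec in R.items():
            if c != "short_variant":
                continue
            if (group, "positive") in spec.by_group_er:
                r = er_frac * spec.by_group_er[(group, "positive")] + \
                    (1 - er_frac) * spec.by_group_er[(group, "negative")]
            else:
                r = spec.by_group.get(group, spec.base)
            total += r
        esr1 = {"metastasis": 0.183, "local": 0.022, "lymph_node": 0.06}[group]
        return total + esr1

    filler_rate = {}
    for group, mean in [("local", tmb.mean_mutations_local),
                        ("metastasis", tmb.mean_mutations_met),
                        ("lymph_node", tmb.mean_mutations_lymph),
                        ("ambiguous", tmb.mean_mutations_local)]:
        g = group if group != "ambiguous" else "local"
        filler_rate[group] = max(mean - named_mut_mean(g), 0.1) / max(n_filler, 1)

    # --- other-tissue generative profiles (tissue-of-origin training) ----
    tissue_profiles = {
        "lung": {
            ("KRAS", "short_variant"): 0.30, ("KEAP1", "short_variant"): 0.20,
            ("STK11", "short_variant"): 0.17, ("EGFR", "short_variant"): 0.14,
            ("TP53", "short_variant"): 0.65, ("LRP1B", "short_variant"): 0.30,
            ("CDKN2A", "deletion"): 0.20, ("CDKN2B", "deletion"): 0.18,
            ("PIK3CA", "short_variant"): 0.07, ("NF1", "short_variant"): 0.08,
            ("__filler__", "short_variant"): 0.030,
        },
        "skin": {
            ("BRAF", "short_variant"): 0.45, ("NRAS", "short_variant"): 0.20,
            ("NOTCH1", "short_variant"): 0.35, ("TP53", "short_variant"): 0.50,
            ("CDKN2A", "deletion"): 0.30, ("CDKN2B", "deletion"): 0.25,
            ("LRP1B", "short_variant"): 0.25,
            ("__filler__", "short_variant"): 0.045,
        },
        "brain": {
            ("PTEN", "deletion"): 0.25, ("EGFR", "amplification"): 0.35,
            ("EGFR", "short_variant"): 0.12, ("CDKN2A", "deletion"): 0.45,
            ("CDKN2B", "deletion"): 0.40, ("TP53", "short_variant"): 0.30,
            ("NF1", "short_variant"): 0.10,
            ("__filler__", "short_variant"): 0.012,
        },
        "bone": {
            ("TP53", "short_variant"): 0.40, ("RB1", "deletion"): 0.15,
            ("MYC", "amplification"): 0.10, ("CDKN2A", "deletion"): 0.10,
            ("PIK3CA", "short_variant"): 0.05,
            ("__filler__", "short_variant"): 0.010,
        },
    }

    return GeneratorConfig(
        panel=panel,
        er_pos_by_site=er_pos,
        her2_by_site=her2,
        rates=R,
        filler_rate_by_group=filler_rate,
        esr1_model=esr1_model,
        contaminant_model=contam,
        tmb_model=tmb,
        tissue_profiles=tissue_profiles,
        report_templates=default_report_templates(),
    )


def null_config(n_genes: int = 100, n_local: int = 1000, n_met: int = 1000,
                gene_rate: float = 0.05) -> GeneratorConfig:
    """Global-null configuration: every feature has the same rate in every
    group and site. Used by the family-wise-error simulations."""
    panel = default_panel(n_genes)
    rates = {(g, "short_variant"): RateSpec(gene_rate) for g in panel if not g.startswith("SYN")}
    esr1 = Esr1Model(
        RateSpec(gene_rate),
        base_mixture={k: (1.0 if k == "D538G" else 0.0) for k in HOTSPOT_CATEGORIES},
        site_delta={}, histology_delta={},
        local_mixture={k: (1.0 if k == "D538G" else 0.0) for k in HOTSPOT_CATEGORIES},
        multi_mutation_prob=0.0,
    )
    return GeneratorConfig(
        n_local=n_local, n_lymph=0, n_met=n_met, n_ambiguous=0,
        panel=panel,
        er_pos_by_site={s: 0.6 for s in MET_SITES}, er_pos_local=0.6, er_pos_lymph=0.6,
        her2_by_site={s: 0.09 for s in MET_SITES}, her2_local=0.09,
        rates=rates,
        filler_rate_by_group={g: gene_rate for g in cfg.GROUPS},
        esr1_model=esr1,
        contaminant_model=ContaminantModel(fraction_of_lung_mets=0.0),
        chip_model=ChipModel(max_prob=0.0),
        tmb_model=TmbModel(hypermutated_fraction=0.0),
        report_templates=default_report_templates(),
    )


# --------------------------------------------------------------- sampling


def _resolve_rates(spec: RateSpec, group: np.ndarray, site: np.ndarray,
                   er: np.ndarray) -> np.ndarray:
    """Vectorized rate lookup for one feature over all samples."""
    p = np.full(len(group), spec.base)
    for g, r in spec.by_group.items():
        p[group == g] = r
    for (g, e), r in spec.by_group_er.items():
        p[(group == g) & (er == e)] = r
    for (s, e), r in spec.by_site_er.items():
        p[(group == "metastasis") & (site == s) & (er == e)] = r
    if spec.site_odds:
        lo = logit(np.clip(p, 1e-12, 1 - 1e-12))
        for s, m in spec.site_odds.items():
            mask = site == s
            lo[mask] += math.log(m)
        p = expit(lo)
    return p


AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_change(rng, lo, hi):
    pos = int(rng.integers(lo, hi + 1))
    a, b = rng.choice(list(AA), size=2, replace=True)
    return f"{a}{pos}{b}"


def simulate_esr1_variants(
    rng: np.random.Generator,
    esr1_model: Esr1Model,
    site: str | None = None,
    histology: str | None = None,
    group: str = "metastasis",
    n: int = 1,
) -> list[dict]:
    """Draw ESR1 mutation events for ``n`` carrier samples.

    Each carrier gets one category draw from the site/histology-specific
    mixture (``site=None`` uses the unconditional default mixture); with the
    configured multi-mutation probability a second, independent draw is
    added. Returns one dict per event with ``category`` and a concrete
    ``protein_change`` string.
    """
    mix = esr1_model.mixture_for(site, histology, group)
    cats = list(mix)
    probs = np.array([mix[c] for c in cats])
    lbd_lo, lbd_hi = cfg.ESR1_LBD_INTERVAL
    out = []
    for i in range(n):
        k = 1 + (rng.random() < esr1_model.multi_mutation_prob)
        for cat in rng.choice(cats, size=k, p=probs):
            if cat == "pooled_2_3":
                change = _random_change(rng, lbd_lo, lbd_hi)
            elif cat == "pooled_1_lbd":
                change = _random_change(rng, lbd_lo, lbd_hi)
            elif cat == "pooled_1_nonlbd":
                change = _random_change(rng, 5, lbd_lo - 1)
            else:
                change = cat
            out.append({"carrier": i, "category": str(cat), "protein_change": change})
    return out


def simulate_chip_vaf(age_years: float, chip_model: ChipModel,
                      rng: np.random.Generator) -> float:
    """One CHIP variant-allele fraction; the mean decreases with age."""
    m = float(chip_model.vaf_mean(age_years))
    k = chip_model.vaf_concentration
    return float(rng.beta(m * k, (1 - m) * k))


# ------------------------------------------------------- pathology reports

_BOILERPLATE = (
    "Interpretation guide: positive denotes nuclear staining in >1% of tumor "
    "cells; see reference manual for scoring details.\n"
)


def default_report_templates() -> dict:
    return {
        "positive": [
            "ER staining was detected",
            "Estrogen receptor: positive",
            "Immunohistochemistry shows strong ER expression in tumor cells",
            "The tumor is positive for ER",
        ],
        "negative": [
            "ER staining was not detected",
            "Estrogen receptor: negative",
            "No ER expression identified",
            "Tumor cells are negative for ER",
        ],
        "boilerplate": [_BOILERPLATE],
    }


def simulate_pathology_report(
    er_status: str,
    rng: np.random.Generator,
    templates: dict | None = None,
    template_id: int | None = None,
    with_boilerplate: bool = True,
) -> str:
    """One synthetic pathology-report snippet carrying the given ER status.

    Negative reports include negated-positive phrasings ("ER staining was
    not detected"); boilerplate distractor text is prepended to exercise the
    parser's filtering.
    """
    templates = templates or default_report_templates()
    if er_status not in ("positive", "negative"):
        raise ValueError("er_status must be positive or negative")
    pool = templates[er_status]
    if not pool:
        raise ValueError("empty template set")
    idx = int(rng.integers(len(pool))) if template_id is None else template_id % len(pool)
    body = pool[idx]
    parts = []
    if with_boilerplate and templates.get("boilerplate"):
        parts.append(templates["boilerplate"][0])
    parts.append("Specimen: breast, core biopsy.\n")
    parts.append(body + ".\n")
    parts.append("HER2 evaluation pending.\n")
    return "".join(parts)


# ----------------------------------------------------------- tissue draws


def _draw_profile_calls(rng, profile: dict, panel: list[str], sample_ids: list[str],
                        filler_rate_key: str = "__filler__") -> list[dict]:
    """Bernoulli alteration calls for a non-breast tissue profile."""
    n = len(sample_ids)
    rows = []
    filler_rate = profile.get((filler_rate_key, "short_variant"), 0.0)
    for gene in panel:
        for klass in cfg.ALTERATION_CLASSES:
            r = profile.get((gene, klass))
            if r is None:
                r = filler_rate if (klass == "short_variant" and gene.startswith("SYN")) else 0.0
            if r <= 0:
                continue
            hits = np.nonzero(rng.random(n) < r)[0]
            for i in hits:
                rows.append({
                    "sample_id": sample_ids[i], "gene": gene, "alteration_class": klass,
                    "protein_change": None, "functional_status": "VUS",
                    "vaf": float(np.clip(rng.beta(3, 7), 0.01, 0.99))
                    if klass == "short_variant" else None,
                })
    return rows


def simulate_tissue_cohort(tissue: str, n: int, config: GeneratorConfig,
                           seed: int) -> Cohort:
    """A cohort of ``n`` primary tumors of another indication (lung, skin,
    brain or bone), used to train tissue-of-origin classifiers.

    The lung profile draws the KRAS/KEAP1/STK11 triplet from a latent
    co-occurrence factor, mimicking the smoking-associated genotype."""
    if tissue not in config.tissue_profiles:
        raise ValueError(f"no tissue profile for {tissue!r}")
    rng = np.random.default_rng(seed)
    ids = [f"{tissue.upper()}{i:05d}" for i in range(n)]
    profile = dict(config.tissue_profiles[tissue])
    rows = []
    if tissue == "lung":
        triplet = [("KRAS", "short_variant"), ("KEAP1", "short_variant"),
                   ("STK11", "short_variant")]
        z = rng.random(n) < 0.5
        hi = {("KRAS", "short_variant"): 0.50, ("KEAP1", "short_variant"): 0.36,
              ("STK11", "short_variant"): 0.32}
        lo = {("KRAS", "short_variant"): 0.10, ("KEAP1", "short_variant"): 0.04,
              ("STK11", "short_variant"): 0.02}
        for key in triplet:
            p = np.where(z, hi[key], lo[key])
            for i in np.nonzero(rng.random(n) < p)[0]:
                rows.append({"sample_id": ids[i], "gene": key[0],
                             "alteration_class": key[1], "protein_change": None,
                             "functional_status": "known",
                             "vaf": float(np.clip(rng.beta(3, 7), 0.01, 0.99))})
            profile.pop(key, None)
    rows += _draw_profile_calls(rng, profile, config.panel, ids)
    ages = np.clip(rng.normal(63, 11, n).round(), 25, 92).astype(int)
    samples = pd.DataFrame({
        "sample_id": ids, "biopsy_site": tissue, "group": "metastasis",
        "er_status": "unknown", "er_source": "unknown", "er_prob": np.nan,
        "her2_amplified": False, "histology": "other", "age_years": ages,
    })[SAMPLE_COLUMNS]
    alts = pd.DataFrame(rows, columns=ALTERATION_COLUMNS)
    return Cohort(samples, alts, list(config.panel))


# ------------------------------------------------------------- main driver


def simulate_cohort(config: GeneratorConfig, seed: int) -> tuple[Cohort, pd.DataFrame]:
    """Draw a full cohort plus its per-sample ground truth.

    Truth columns: group, site, true_er, her2, histology, age,
    is_contaminant, has_chip, hypermutated, esr1_mut.
    """
    config.validate()
    rng = np.random.default_rng(seed)

    groups = (["local"] * config.n_local + ["lymph_node"] * config.n_lymph
              + ["metastasis"] * config.n_met + ["ambiguous"] * config.n_ambiguous)
    n = len(groups)
    group = np.array(groups)

    # --- sites ---
    site = np.empty(n, dtype=object)
    site[group == "local"] = rng.choice(["breast", "chest wall"], p=[0.96, 0.04],
                                        size=(group == "local").sum())
    site[group == "lymph_node"] = "lymph node"
    met_sites = list(config.site_freqs)
    met_probs = np.array([config.site_freqs[s] for s in met_sites])
    site[group == "metastasis"] = rng.choice(met_sites, p=met_probs,
                                             size=(group == "metastasis").sum())
    site[group == "ambiguous"] = rng.choice(["other", "unknown"],
                                            size=(group == "ambiguous").sum())

    # --- subtype / histology / age ---
    p_er = np.full(n, config.er_pos_local)
    p_her2 = np.full(n, config.her2_local)
    p_er[group == "lymph_node"] = config.er_pos_lymph
    p_her2[group == "lymph_node"] = config.her2_lymph
    for s in met_sites:
        mask = (group == "metastasis") & (site == s)
        p_er[mask] = config.er_pos_by_site.get(s, 0.6)
        p_her2[mask] = config.her2_by_site.get(s, 0.09)
    er = np.where(rng.random(n) < p_er, "positive", "negative")
    her2 = rng.random(n) < p_her2
    hist_names = list(config.histology_probs)
    hist_p = np.array([config.histology_probs[h] for h in hist_names])
    histology = rng.choice(hist_names, p=hist_p / hist_p.sum(), size=n)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n).round(), 22, 92).astype(int)

    ids = np.array([f"S{i:06d}" for i in range(n)])

    # --- alteration vectors -----------------------------------------------
    tmbm = config.tmb_model
    hyper = rng.random(n) < tmbm.hypermutated_fraction
    load = rng.gamma(tmbm.dispersion_shape, 1.0 / tmbm.dispersion_shape, n)

    rows: list[dict] = []
    fstat_p = np.array(config.functional_probs, float)
    fstat_p = fstat_p / fstat_p.sum()

    vaf_a = config.tumor_vaf_mean * config.tumor_vaf_concentration
    vaf_b = (1 - config.tumor_vaf_mean) * config.tumor_vaf_concentration

    def add_calls(gene, klass, mask_idx, known_status=False):
        k = len(mask_idx)
        if k == 0:
            return
        if klass == "short_variant":
            fs = (np.full(k, "known") if known_status
                  else rng.choice(cfg.FUNCTIONAL_STATUSES, p=fstat_p, size=k))
            vafs = np.clip(rng.beta(vaf_a, vaf_b, size=k), 0.01, 0.99)
            for j, i in enumerate(mask_idx):
                rows.append({"sample_id": ids[i], "gene": gene,
                             "alteration_class": klass, "protein_change": None,
                             "functional_status": str(fs[j]), "vaf": float(vafs[j])})
        else:
            for i in mask_idx:
                rows.append({"sample_id": ids[i], "gene": gene,
                             "alteration_class": klass, "protein_change": None,
                             "functional_status": None, "vaf": None})

    for (gene, klass), spec in config.rates.items():
        if gene == "ESR1" and klass == "short_variant":
            continue
        p = _resolve_rates(spec, group, site, er)
        hits = np.nonzero(rng.random(n) < p)[0]
        add_calls(gene, klass, hits)

    # HER2 amplification calls mirror the subtype flag.
    add_calls("ERBB2", "amplification", np.nonzero(her2)[0])

    # Filler genes: group-dependent background with per-sample load factor;
    # hypermutated samples get an elevated flat rate.
    filler_genes = [g for g in config.panel if g.startswith("SYN")]
    base_rate = np.zeros(n)
    for g, r in config.filler_rate_by_group.items():
        base_rate[group == g] = r
    p_filler = np.clip(base_rate * load, 0.0, 0.95)
    p_filler[hyper] = tmbm.hypermutated_filler_rate
    for gene in filler_genes:
        hits = np.nonzero(rng.random(n) < p_filler)[0]
        add_calls(gene, "short_variant", hits)

    # --- ESR1 -------------------------------------------------------------
    esr1 = config.esr1_model
    esr1_flag = np.zeros(n, dtype=bool)
    if esr1 is not None:
        p_esr1 = _resolve_rates(esr1.rate, group, site, er)
        esr1_flag = rng.random(n) < p_esr1
        for i in np.nonzero(esr1_flag)[0]:
            events = simulate_esr1_variants(
                rng, esr1, site=site[i], histology=histology[i], group=group[i], n=1)
            for ev in events:
                rows.append({
                    "sample_id": ids[i], "gene": "ESR1",
                    "alteration_class": "short_variant",
                    "protein_change": ev["protein_change"],
                    "functional_status": "known" if ev["category"] in cfg.ESR1_HOTSPOTS
                    else ("likely" if "lbd" in ev["category"] or ev["category"] == "pooled_2_3"
                          else "VUS"),
                    "vaf": float(np.clip(rng.beta(3, 7), 0.01, 0.99)),
                })

    alts = pd.DataFrame(rows, columns=ALTERATION_COLUMNS)

    # --- contaminant substitution ----------------------------------------
    cm = config.contaminant_model
    contaminant = np.zeros(n, dtype=bool)
    lung_mask = (group == "metastasis") & (site == "lung")
    if cm.fraction_of_lung_mets > 0 and lung_mask.any() and "lung" in config.tissue_profiles:
        pick = np.nonzero(lung_mask)[0]
        chosen = pick[rng.random(len(pick)) < cm.fraction_of_lung_mets]
        contaminant[chosen] = True
        if len(chosen):
            sub = simulate_tissue_cohort("lung", len(chosen), config,
                                         seed=int(rng.integers(2**31)))
            repl = sub.alterations.copy()
            id_map = dict(zip(sub.samples["sample_id"], ids[chosen]))
            repl["sample_id"] = repl["sample_id"].map(id_map)
            if cm.esr1_rate > 0:
                keep_esr1 = rng.random(len(chosen)) < cm.esr1_rate
                esr1_rows = [{"sample_id": ids[c], "gene": "ESR1",
                              "alteration_class": "short_variant",
                              "protein_change": "D538G", "functional_status": "known",
                              "vaf": 0.3}
                             for c, k in zip(chosen, keep_esr1) if k]
                if esr1_rows:
                    repl = pd.concat([repl, pd.DataFrame(esr1_rows)], ignore_index=True)
            alts = alts[~alts["sample_id"].isin(set(ids[chosen]))]
            alts = pd.concat([alts, repl], ignore_index=True)
            esr1_flag[chosen] = np.isin(ids[chosen],
                                        repl.loc[repl["gene"] == "ESR1", "sample_id"])

    # --- CHIP injection ---------------------------------------------------
    chm = config.chip_model
    has_chip = rng.random(n) < chm.prob(age)
    chip_rows = []
    for i in np.nonzero(has_chip)[0]:
        chip_rows.append({
            "sample_id": ids[i], "gene": "DNMT3A", "alteration_class": "short_variant",
            "protein_change": None, "functional_status": "likely",
            "vaf": simulate_chip_vaf(age[i], chm, rng),
        })
    if chip_rows:
        alts = pd.concat([alts, pd.DataFrame(chip_rows)], ignore_index=True)

    # --- assemble ---------------------------------------------------------
    er_known = rng.random(n) < config.er_known_fraction
    samples = pd.DataFrame({
        "sample_id": ids,
        "biopsy_site": site,
        "group": group,
        "er_status": np.where(er_known, er, "unknown"),
        "er_source": np.where(er_known, "pathology_report", "unknown"),
        "er_prob": np.nan,
        "her2_amplified": her2,
        "histology": histology,
        "age_years": age,
    })[SAMPLE_COLUMNS]

    truth = pd.DataFrame({
        "sample_id": ids, "group": group, "site": site, "true_er": er,
        "her2": her2, "histology": histology, "age": age,
        "is_contaminant": contaminant, "has_chip": has_chip,
        "hypermutated": hyper, "esr1_mut": esr1_flag,
    })
    cohort = Cohort(samples, alts.reset_index(drop=True), list(config.panel))
    return cohort, truth
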