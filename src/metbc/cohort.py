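"""Cohort data model, tabular I/O, group assignment, feature matrices.

A :class:`Cohort` bundles a sample-metadata table, an alteration-call table
(MAF-like: one row per called event), and the ordered gene panel. Both
tables are held as :class:`pandas.DataFrame` objects; the record dataclasses
below document the per-row schema and are used for validation and
programmatic construction.

Files are UTF-8 tab-separated with ``.`` for missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import config as cfg

logger = logging.getLogger("metbc")

SAMPLE_COLUMNS = [
    "sample_id",
    "biopsy_site",
    "group",
    "er_status",
    "er_source",
    "er_prob",
    "her2_amplified",
    "histology",
    "age_years",
]
REQUIRED_SAMPLE_COLUMNS = ["sample_id", "biopsy_site"]

ALTERATION_COLUMNS = [
    "sample_id",
    "gene",
    "alteration_class",
    "protein_change",
    "functional_status",
    "vaf",
]
REQUIRED_ALTERATION_COLUMNS = ["sample_id", "gene", "alteration_class"]


@dataclass
class SampleRecord:
    """One sequenced tumor sample."""

    sample_id: str
    biopsy_site: str
    group: str = ""
    er_status: str = "unknown"
    er_source: str = "unknown"
    er_prob: float | None = None
    her2_amplified: bool = False
    histology: str = "unknown"
    age_years: int | None = None

    def __post_init__(self):
        if not self.group:
            self.group = assign_group(self.biopsy_site)
        if self.er_prob is not None and not 0.0 <= self.er_prob <= 1.0:
            raise ValueError(f"er_prob out of [0,1]: {self.er_prob}")


@dataclass
class AlterationCall:
    """One called genomic alteration in one sample."""

    sample_id: str
    gene: str
    alteration_class: str
    protein_change: str | None = None
    functional_status: str = "VUS"
    vaf: float | None = None

    def __post_init__(self):
        if self.alteration_class not in cfg.ALTERATION_CLASSES:
            raise ValueError(f"unknown alteration_class: {self.alteration_class!r}")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if self.protein_change and self.alteration_class != "short_variant":
            raise ValueError("protein_change only valid for short variants")


@dataclass
class Cohort:
    """Sample metadata + alteration calls + ordered gene panel."""

    samples: pd.DataFrame
    alterations: pd.DataFrame
    panel: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.samples["sample_id"].duplicated().any():
            dups = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample_id: {sorted(set(dups))}")
        if len(set(self.panel)) != len(self.panel):
            raise ValueError("panel contains duplicate genes")
        unknown = set(self.alterations["sample_id"]) - set(self.samples["sample_id"])
        if unknown:
            raise ValueError(
                f"{len(unknown)} alteration rows reference unknown sample_ids"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @classmethod
    def from_records(
        cls,
        samples: Iterable[SampleRecord],
        alterations: Iterable[AlterationCall],
        panel: Sequence[str],
    ) -> "Cohort":
        sdf = pd.DataFrame([vars(s) for s in samples], columns=SAMPLE_COLUMNS)
        adf = pd.DataFrame([vars(a) for a in alterations], columns=ALTERATION_COLUMNS)
        return cls(sdf, adf, list(panel))

    def subset(self, mask: pd.Series) -> "Cohort":
        keep = self.samples.loc[mask.values if hasattr(mask, "values") else mask]
        alts = self.alterations[self.alterations["sample_id"].isin(keep["sample_id"])]
        return Cohort(keep.reset_index(drop=True), alts.reset_index(drop=True), list(self.panel))


@dataclass
class FeatureMatrix:
    """Samples x binary alteration features, plus mutation load per Mb.

    ``X`` is indexed by sample_id with values in {0, 1}; ``tmb_per_mb`` is
    the short-variant count divided by the panel footprint in Mb;
    ``hypermutated`` flags samples mutated in more than 25 distinct genes.
    """

    X: pd.DataFrame
    tmb_per_mb: pd.Series
    hypermutated: pd.Series

    def __post_init__(self):
        vals = self.X.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("feature matrix entries must be 0/1")
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature columns")
        if (self.tmb_per_mb < 0).any():
            raise ValueError("tmb_per_mb must be nonnegative")

    @property
    def frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out["tmb_per_mb"] = self.tmb_per_mb
        out["hypermutated"] = self.hypermutated.astype(int)
        return out


# ------------------------------------------------------------------ grouping


def assign_group(biopsy_site: str) -> str:
    """Map a biopsy site onto local / lymph_node / metastasis / ambiguous.

    Total and deterministic: unrecognized sites map to ``ambiguous``.
    """
    site = str(biopsy_site)
    if site not in cfg.SITE_GROUP:
        site = site.strip().lower().replace("_", " ")
        if site == "gi":
            site = "GI"
    return cfg.SITE_GROUP.get(site, "ambiguous")


def _assign_group_simple(site: str) -> str:
    return cfg.SITE_GROUP.get(site, "ambiguous")


# --------------------------------------------------------------------- I/O


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, na_values=[cfg.MISSING], keep_default_na=False)


def read_sample_table(path) -> Cohort:
    """Read ``samples.tsv`` into a Cohort with an empty alteration table.

    Missing groups are filled from the site mapping; malformed enum values
    are coerced to ``unknown`` with a logged warning.
    """
    df = _read_tsv(path)
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"samples table is missing required column(s): {missing}")
    for col in SAMPLE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[SAMPLE_COLUMNS].copy()
    if df["sample_id"].duplicated().any():
        dups = sorted(set(df.loc[df["sample_id"].duplicated(), "sample_id"]))
        raise ValueError(f"duplicate sample_id: {dups}")

    df["group"] = df["group"].where(
        df["group"].isin(cfg.GROUPS), df["biopsy_site"].map(_assign_group_simple)
    )
    for col, allowed, fallback in [
        ("er_status", cfg.ER_STATUSES, "unknown"),
        ("er_source", cfg.ER_SOURCES, "unknown"),
        ("histology", cfg.HISTOLOGIES, "unknown"),
    ]:
        bad = df[col].notna() & ~df[col].isin(allowed)
        if bad.any():
            logger.warning("%d malformed %s values mapped to %s", bad.sum(), col, fallback)
        df[col] = df[col].where(df[col].isin(allowed), fallback)
    df["er_prob"] = pd.to_numeric(df["er_prob"], errors="coerce")
    if ((df["er_prob"] < 0) | (df["er_prob"] > 1)).any():
        raise ValueError("er_prob outside [0,1]")
    df["her2_amplified"] = (
        df["her2_amplified"].fillna("0").astype(str).str.lower().isin(["1", "true", "yes"])
    )
    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
    return Cohort(df.reset_index(drop=True), pd.DataFrame(columns=ALTERATION_COLUMNS), [])


def read_alteration_table(path, cohort: Cohort, panel: Sequence[str] | None = None) -> Cohort:
    """Attach an alteration-call table to an existing cohort.

    Calls whose sample_id is not in the cohort are dropped with their count
    reported; an unknown alteration class or an out-of-range VAF is a hard
    error.
    """
    df = _read_tsv(path)
    missing = [c for c in REQUIRED_ALTERATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"alterations table is missing required column(s): {missing}")
    for col in ALTERATION_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[ALTERATION_COLUMNS].copy()
    bad_class = ~df["alteration_class"].isin(cfg.ALTERATION_CLASSES)
    if bad_class.any():
        raise ValueError(
            f"unknown alteration_class values: {sorted(set(df.loc[bad_class, 'alteration_class']))}"
        )
    df["vaf"] = pd.to_numeric(df["vaf"], errors="coerce")
    if ((df["vaf"] < 0) | (df["vaf"] > 1)).any():
        raise ValueError("vaf outside [0,1]")
    known = df["sample_id"].isin(set(cohort.samples["sample_id"]))
    if (~known).any():
        logger.warning("rejected %d calls for unknown sample_ids", (~known).sum())
    df = df[known].reset_index(drop=True)
    genes = list(panel) if panel is not None else sorted(set(df["gene"]))
    return Cohort(cohort.samples, df, genes)


def write_cohort(cohort: Cohort, samples_path, alterations_path) -> None:
    """Write both tables as UTF-8 TSV with '.' for missing."""
    s = cohort.samples.copy()
    s["her2_amplified"] = s["her2_amplified"].astype(int)
    s.to_csv(samples_path, sep="\t", index=False, na_rep=cfg.MISSING)
    cohort.alterations.to_csv(alterations_path, sep="\t", index=False, na_rep=cfg.MISSING)


# ----------------------------------------------------------- feature matrix


def build_feature_matrix(
    cohort: Cohort,
    granularity: str = "gene_by_class",
    variant_filter: str = "all_variants",
    panel_mb: float = cfg.PANEL_MB,
) -> FeatureMatrix:
    """Binarize alteration calls into a samples x features matrix.

    ``granularity="gene"`` gives one mutation column per panel gene (short
    variants only); ``"gene_by_class"`` additionally gives amplification /
    deletion / rearrangement columns per gene. Under
    ``variant_filter="known_likely_only"`` VUS short variants contribute
    neither to the flags nor to the mutation load.
    """
    if not cohort.panel:
        raise ValueError("cohort has an empty gene panel")
    if granularity not in ("gene", "gene_by_class"):
        raise ValueError(f"unknown granularity {granularity!r}")
    if variant_filter not in ("all_variants", "known_likely_only"):
        raise ValueError(f"unknown variant filter {variant_filter!r}")

    ids = cohort.samples["sample_id"]
    alts = cohort.alterations
    alts = alts[alts["gene"].isin(set(cohort.panel))]
    if variant_filter == "known_likely_only":
        drop = (alts["alteration_class"] == "short_variant") & ~alts[
            "functional_status"
        ].isin(["known", "likely"])
        alts = alts[~drop]

    classes = (
        ["short_variant"]
        if granularity == "gene"
        else list(cfg.ALTERATION_CLASSES)
    )
    columns = [
        f"{g}_{cfg.CLASS_SUFFIX[c]}" for g in cohort.panel for c in classes
    ]
    X = pd.DataFrame(0, index=ids, columns=columns, dtype=np.int8)
    sub = alts[alts["alteration_class"].isin(classes)]
    if len(sub):
        colname = sub["gene"] + "_" + sub["alteration_class"].map(cfg.CLASS_SUFFIX)
        flags = pd.crosstab(sub["sample_id"], colname).clip(upper=1)
        X.loc[flags.index, flags.columns] = flags.astype(np.int8)

    sv = alts[alts["alteration_class"] == "short_variant"]
    counts = sv.groupby("sample_id").size().reindex(ids, fill_value=0)
    tmb = counts / panel_mb
    tmb.name = "tmb_per_mb"
    distinct = (
        sv.drop_duplicates(["sample_id", "gene"]).groupby("sample_id").size().reindex(ids, fill_value=0)
    )
    hyper = distinct > cfg.HYPERMUTATION_GENE_THRESHOLD
    hyper.name = "hypermutated"
    return FeatureMatrix(X, tmb.astype(float), hyper)


# ------------------------------------------------------------------ summary


def summarize_cohort(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Prevalence tables: subtype by site, histology by site, group counts,
    alteration prevalence ranked descending.

    Rows of the compositional tables sum to 1.
    """
    if cohort.n_samples == 0:
        raise ValueError("empty cohort")
    s = cohort.samples

    subtype = np.where(
        s["er_status"].eq("positive") & ~s["her2_amplified"], "ER+/HER2-",
        np.where(s["her2_amplified"], "HER2+",
                 np.where(s["er_status"].eq("negative"), "ER-/HER2-", "unknown")),
    )
    subtype_by_site = pd.crosstab(s["biopsy_site"], subtype, normalize="index")
    histology_by_site = pd.crosstab(s["biopsy_site"], s["histology"], normalize="index")

    groups = s["group"].value_counts()
    group_counts = pd.DataFrame({"n": groups, "fraction": groups / len(s)})

    prev = pd.DataFrame()
    if cohort.panel:
        fm = build_feature_matrix(cohort)
        rates = fm.X.mean(axis=0).sort_values(ascending=False)
        prev = rates.to_frame("prevalence")
    return {
        "subtype_by_site": subtype_by_site,
        "histology_by_site": histology_by_site,
        "group_counts": group_counts,
        "alteration_prevalence": prev,
    }
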