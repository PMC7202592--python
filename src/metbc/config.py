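"""Shared controlled vocabularies and analysis constants.

Everything here is overridable at call sites; these are the documented
defaults the rest of the package assumes.
"""

from __future__ import annotations

# ---------------------------------------------------------------- vocabularies

GROUPS = ("local", "lymph_node", "metastasis", "ambiguous")

SITES = (
    "breast",
    "lymph node",
    "liver",
    "bone",
    "lung",
    "brain",
    "skin",
    "pleura",
    "pleural fluid",
    "chest wall",
    "soft tissue",
    "ovary",
    "GI",
    "other",
    "unknown",
)

#: Biopsy site -> local / lymph_node / metastasis group. Breast biopsies and
#: chest-wall recurrences count as local disease; distant organs as
#: metastases; anything unrecognized is ambiguous and excluded from the
#: enrichment analyses by default.
SITE_GROUP = {
    "breast": "local",
    "chest wall": "local",
    "lymph node": "lymph_node",
    "liver": "metastasis",
    "bone": "metastasis",
    "lung": "metastasis",
    "brain": "metastasis",
    "skin": "metastasis",
    "pleura": "metastasis",
    "pleural fluid": "metastasis",
    "soft tissue": "metastasis",
    "ovary": "metastasis",
    "GI": "metastasis",
    "other": "ambiguous",
    "unknown": "ambiguous",
}

#: Metastatic sites draining to internal organs; used by the ESR1
#: hotspot-by-site contrast (bone is the non-visceral comparator).
VISCERAL_SITES = ("liver", "pleura", "pleural fluid", "brain", "lung")

ALTERATION_CLASSES = ("short_variant", "amplification", "deletion", "rearrangement")
FUNCTIONAL_STATUSES = ("known", "likely", "VUS")
ER_STATUSES = ("positive", "negative", "unknown")
ER_SOURCES = ("pathology_report", "imputed", "unknown")
HISTOLOGIES = ("IDC", "ILC", "other", "unknown")

# ---------------------------------------------------------------- constants

#: Effective panel footprint in megabases used to scale short-variant counts
#: into a mutation load per Mb. Any positive constant only rescales the
#: covariate; 1.1 Mb is a typical targeted-panel coding footprint.
PANEL_MB = 1.1

#: A sample mutated in more than this many distinct genes is called
#: hypermutated.
HYPERMUTATION_GENE_THRESHOLD = 25

#: ESR1 ligand-binding domain, in protein residues (inclusive).
ESR1_LBD_INTERVAL = (311, 547)

#: Recurrent ESR1 protein changes given a named hotspot label.
ESR1_HOTSPOTS = ("D538G", "Y537S", "Y537N", "Y537C", "E380Q", "L536H", "V422del")

#: Column-name separators for gene-by-class feature columns.
CLASS_SUFFIX = {
    "short_variant": "mut",
    "amplification": "amp",
    "deletion": "del",
    "rearrangement": "rearr",
}

MISSING = "."
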