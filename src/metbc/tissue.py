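"""Gene-masked tissue-of-origin classifiers and misdiagnosis inference.

To ask whether metastases carrying a site-enriched alteration are actually
misdiagnosed primaries of that site, a balanced random forest is trained
to separate breast tumors from primaries of the other tissue — with the
enriched genes masked (all their feature columns removed, and mutation
load excluded), so the classifier cannot trivially key on the alteration
used to stratify patients. The classifier is then applied to metastatic
breast tumors, and the score distribution of the carrier stratum is
compared with the background stratum by a two-sample Kolmogorov-Smirnov
test plus the fraction classified as the other tissue at the majority-vote
threshold. A beta regression on the (shrunken) scores tests the stratum
effect while controlling for subtype and mutation-load covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.othermod.betareg import BetaModel

from .ensemble import EnsembleConfig, EnsembleModel, train_ensemble

logger = logging.getLogger("metbc")


@dataclass
class TooModel:
    other_tissue: str
    masked_genes: list[str]
    model: EnsembleModel
    n_breast: int
    n_other: int
    held_out: dict = field(default_factory=dict)


@dataclass
class TooScoreSet:
    probs: np.ndarray            # P(other tissue) per sample
    stratum: np.ndarray          # "carrier" / "background"
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        if ((self.probs < 0) | (self.probs > 1)).any():
            raise ValueError("probabilities out of [0,1]")


def mask_columns(features: pd.DataFrame, masked_genes: list[str],
                 drop_tmb: bool = True) -> pd.DataFrame:
    """Drop every feature column of the masked genes (and mutation load)."""
    drop = [c for c in features.columns
            if any(c == g or c.startswith(g + "_") for g in masked_genes)]
    if drop_tmb:
        drop += [c for c in features.columns if c == "tmb_per_mb"]
    return features.drop(columns=drop)


def train_too_classifier(
    breast_features: pd.DataFrame,
    other_features: pd.DataFrame,
    other_tissue: str,
    masked_genes: list[str],
    config: EnsembleConfig | None = None,
    seed: int = 0,
) -> TooModel:
    """Breast-vs-other ensemble with the enriched genes masked.

    The positive class is the other tissue (labels sort breast < tissue
    except for "bone"/"brain"; the wrapper fixes orientation explicitly).
    Masked genes absent from the panel only warn. Held-out performance is
    the out-of-bag accuracy of the balanced forest.
    """
    if len(breast_features) == 0 or len(other_features) == 0:
        raise ValueError("both classes must be non-empty")
    present = set()
    for c in breast_features.columns:
        present.add(c.split("_")[0])
    for g in masked_genes:
        if g not in present:
            logger.warning("masked gene %s not in panel", g)
    Xb = mask_columns(breast_features, masked_genes)
    Xo = mask_columns(other_features, masked_genes)
    Xo = Xo[Xb.columns]
    X = pd.concat([Xb, Xo], axis=0, ignore_index=True)
    y = np.array([0] * len(Xb) + [1] * len(Xo))
    model = train_ensemble(X, y, target=f"{other_tissue}_vs_breast",
                           config=config, seed=seed)
    return TooModel(
        other_tissue=other_tissue, masked_genes=list(masked_genes), model=model,
        n_breast=len(Xb), n_other=len(Xo),
        held_out={"oob_accuracy": model.oob_accuracy},
    )


def score_samples(
    too: TooModel,
    features: pd.DataFrame,
    stratum: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
) -> TooScoreSet:
    """Other-tissue vote fraction per sample, tagged with its stratum."""
    X = mask_columns(features, too.masked_genes)
    X = X[too.model.feature_names]
    probs = too.model.predict_proba(X)
    return TooScoreSet(probs=probs, stratum=np.asarray(stratum, dtype=object),
                       covariates=covariates)


def misdiagnosis_test(scores: TooScoreSet, threshold: float = 0.5) -> dict:
    """KS comparison of carrier vs background score distributions.

    Also reports the fraction of each stratum classified as the other
    tissue at the majority-vote threshold.
    """
    a = scores.probs[scores.stratum == "carrier"]
    b = scores.probs[scores.stratum == "background"]
    if len(a) < 2 or len(b) < 2:
        return {"ks_stat": np.nan, "ks_p": np.nan,
                "frac_carrier": np.nan, "frac_background": np.nan,
                "note": "stratum of size < 2"}
    res = stats.ks_2samp(a, b)
    return {
        "ks_stat": float(res.statistic), "ks_p": float(res.pvalue),
        "frac_carrier": float((a > threshold).mean()),
        "frac_background": float((b > threshold).mean()),
        "n_carrier": int(len(a)), "n_background": int(len(b)),
        "note": "",
    }


def covariate_adjusted_comparison(scores: TooScoreSet,
                                  covariates: pd.DataFrame | None = None) -> dict:
    """Beta regression of scores on the stratum indicator plus covariates.

    Vote fractions hit 0 and 1, so scores are shrunk to the open interval
    by (p * (n - 1) + 0.5) / n before fitting; the reported z and p are the
    Wald test on the stratum coefficient (logit mean link).
    """
    covariates = covariates if covariates is not None else scores.covariates
    n = len(scores.probs)
    y = (scores.probs * (n - 1) + 0.5) / n
    X = pd.DataFrame({
        "const": 1.0,
        "stratum": (scores.stratum == "carrier").astype(float),
    })
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    try:
        res = BetaModel(y, X).fit(disp=False)
    except Exception as err:  # non-convergence etc.
        return {"z": np.nan, "p": np.nan, "converged": False, "note": str(err)}
    z = float(res.params["stratum"] / res.bse["stratum"])
    p = float(2 * stats.norm.sf(abs(z)))
    return {"z": z, "p": p, "coef": float(res.params["stratum"]),
            "converged": bool(res.mle_retvals.get("converged", True)
                              if hasattr(res, "mle_retvals") else True),
            "note": ""}
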