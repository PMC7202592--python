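"""ER-status (and histology) imputation from genomic features.

A class-balanced random forest is trained on the samples whose ER status is
known from pathology reports; the fraction of tree votes for the positive
class is the imputed probability of ER positivity. Samples that were part
of the training set receive their out-of-bag vote fraction (honest, not
resubstitution); unlabelled samples receive the full-ensemble vote
fraction. The imputed probability is the ER covariate used by the
enrichment models downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ensemble import (EnsembleConfig, EnsembleModel, evaluate_classifier,
                       permutation_importance, train_ensemble)

__all__ = [
    "train_subtype_classifier", "impute_er", "permutation_importance",
    "evaluate_classifier", "EnsembleConfig", "EnsembleModel",
]


def train_subtype_classifier(
    features: pd.DataFrame,
    labels,
    target: str = "er_status",
    config: EnsembleConfig | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Train the ensemble on labelled samples (binary target).

    mtry is selected by stratified 10-fold CV by default and the final
    model is refit on all labelled data with per-tree class-stratified
    bootstraps; OOB vote fractions populate ``model.oob_probs``.
    """
    return train_ensemble(features, labels, target=target, config=config, seed=seed)


def impute_er(
    model: EnsembleModel,
    features: pd.DataFrame,
    labelled_mask: np.ndarray | pd.Series | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-sample probability of the positive class plus a hard label.

    ``labelled_mask`` marks rows that were in the training set in the same
    order the model was trained on; those receive OOB probabilities.
    """
    probs = model.predict_proba(features)
    if labelled_mask is not None:
        labelled_mask = np.asarray(labelled_mask, bool)
        if labelled_mask.sum() != len(model.oob_probs):
            raise ValueError(
                "labelled_mask marks a different number of samples than the "
                "model was trained on")
        oob = model.oob_probs
        probs = probs.copy()
        probs[labelled_mask] = np.where(np.isnan(oob), probs[labelled_mask], oob)
    hard = np.where(probs > threshold, model.classes[1], model.classes[0])
    return pd.DataFrame({
        "er_prob": probs,
        "er_label": hard,
    }, index=features.index)
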