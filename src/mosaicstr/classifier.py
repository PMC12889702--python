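"""Random-forest artifact classification of candidate mosaic STR calls.

Two forests are trained — one with phasing-derived features for phaseable
sites, one without for genome-wide use — each predicting five classes:
amplification error, sequencing error, repeat (stutter), heterozygous, and
mosaic.  Training and evaluation follow a leave-one-donor-out scheme so a
donor's own cells never inform its predictions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import LeaveOneGroupOut

CLASSES = ("amp_error", "seq_error", "repeat", "het", "mosaic")
MISSING = -1.0

FEATURE_NAMES = (
    "cell_depth", "bulk_depth", "mean_cell_depth",
    "vaf_mutant_cell", "mosaic_posterior", "mu",
    "stutter_u", "stutter_d", "stutter_rho",
    "segmentation_hmm_frac", "viterbi_loglik_margin",
    "allele_pool_size", "motif_length", "ref_tract_length",
    "gc_flanks", "n_supporting_cells",
    "d_bulk", "d_sc", "d_amp", "d_k",            # phase mode only
    "local_af_pred", "local_af_usable",
    "strand_balance", "mean_baseq_mutant", "mapq_mean",
    "alt_reads", "bulk_alt_reads", "bulk_vaf",
    "mutation_size", "mutation_is_insertion",
)

PHASE_FEATURES = frozenset({"d_bulk", "d_sc", "d_amp", "d_k"})


def extract_features(context: Dict[str, float], mode: str = "phase") -> np.ndarray:
    """Deterministic fixed-order feature vector from a call context.

    Missing values — and every phasing feature in nophase mode — are
    encoded as the sentinel -1.
    """
    out = np.empty(len(FEATURE_NAMES))
    for i, name in enumerate(FEATURE_NAMES):
        if mode == "nophase" and name in PHASE_FEATURES:
            out[i] = MISSING
            continue
        v = context.get(name)
        out[i] = MISSING if v is None else float(v)
    return out


@dataclass
class ClassifierModel:
    """A trained five-class forest plus its mode and held-out provenance."""

    mode: str
    forest: RandomForestClassifier
    classes: tuple = CLASSES
    heldout_metrics: Optional[Dict[str, float]] = None


def train_classifier(X: np.ndarray, y: Sequence[str], donors: Sequence[str],
                     mode: str = "phase", seed: int = 0,
                     n_estimators: int = 500) -> ClassifierModel:
    """Train one forest per mode with leave-one-donor-out evaluation.

    Returns the model fitted on all donors, with per-donor held-out
    accuracies recorded in ``heldout_metrics``.
    """
    X = np.asarray(X, dtype=float)
    y_idx = np.array([CLASSES.index(c) for c in y])
    donors = np.asarray(donors)
    unique_donors = np.unique(donors)
    if len(unique_donors) < 2:
        raise ValueError("leave-one-donor-out requires >= 2 donors")

    def make_forest():
        return RandomForestClassifier(n_estimators=n_estimators,
                                      max_features="sqrt", random_state=seed,
                                      n_jobs=1)

    metrics: Dict[str, float] = {}
    logo = LeaveOneGroupOut()
    for train_idx, test_idx in logo.split(X, y_idx, groups=donors):
        held = str(donors[test_idx][0])
        clf = make_forest()
        clf.fit(X[train_idx], y_idx[train_idx])
        metrics[held] = float(np.mean(clf.predict(X[test_idx]) == y_idx[test_idx]))

    final = make_forest()
    final.fit(X, y_idx)
    return ClassifierModel(mode=mode, forest=final, heldout_metrics=metrics)


def class_probabilities(model: ClassifierModel, features: np.ndarray) -> np.ndarray:
    """Probability vector over the five classes in fixed order."""
    features = np.asarray(features, dtype=float).reshape(1, -1)
    if features.shape[1] != len(FEATURE_NAMES):
        raise ValueError(
            f"expected {len(FEATURE_NAMES)} features, got {features.shape[1]}")
    raw = model.forest.predict_proba(features)[0]
    probs = np.zeros(len(CLASSES))
    for cls_idx, p in zip(model.forest.classes_, raw):
        probs[int(cls_idx)] = p
    return probs


def classify_call(model: ClassifierModel, features: np.ndarray):
    """Argmax class (ties broken toward the lowest class index, so a tie
    never yields mosaic); a call is mosaic iff the mosaic class wins."""
    probs = class_probabilities(model, features)
    idx = int(np.argmax(probs))
    return CLASSES[idx], probs
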