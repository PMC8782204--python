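"""Scoring against ground truth: contact recovery and SOZ ROC/AUC.

AUC is computed by all-pairs concordance (the probability that a random
positive channel outranks a random negative one, ties counting 1/2), which
equals trapezoidal integration of the tie-handled ROC curve; the curve
points themselves come from scikit-learn.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import SingleClassError
from .synth import GroundTruth


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class RecoveryReport:
    n_true: int
    n_found: int
    n_matched: int
    errors_mm: np.ndarray                 # per matched pair
    unmatched_truth: List[int] = field(default_factory=list)
    unmatched_found: List[int] = field(default_factory=list)


def localization_batch(seeds: Sequence[int], n_electrodes: int = 8) -> dict:
    """Geometric-QC summary over a batch of synthetic localization runs.

    For each seed, a skull-stripped CT-like volume with ``n_electrodes``
    straight electrodes (default geometry, default noise) is generated and
    the full localization pipeline is run with default configuration; the
    per-contact axis distances and adjacent contact distances are pooled.
    """
    from .electrodes import ElectrodeLocator
    from .synth import ElectrodeSpec, make_volume

    axis_d, adj_d = [], []
    n_true = 0
    for seed in seeds:
        vol, truth = make_volume(ElectrodeSpec(n_electrodes=n_electrodes), seed=seed)
        loc = ElectrodeLocator().fit(vol)
        axis_d.append(loc.qc_.axis_contact_distances)
        adj_d.append(loc.qc_.adjacent_distances)
        n_true += truth.n_contacts
    axis_d = np.concatenate(axis_d)
    adj_d = np.concatenate(adj_d)
    return {
        "axis_contact_distances": axis_d,
        "adjacent_distances": adj_d,
        "n_contacts": int(axis_d.size),
        "n_pairs": int(adj_d.size),
        "n_true_contacts": int(n_true),
    }


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve and concordance AUC of per-channel scores vs binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if not labels.any() or labels.all():
        raise SingleClassError("labels must contain a positive and a negative")
    pos = scores[labels]
    neg = scores[~labels]
    diff = pos[:, None] - neg[None, :]
    auc = float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)
    fpr, tpr, thr = _sk_roc_curve(labels.astype(int), scores)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def match_contacts(
    found: Sequence[np.ndarray] | np.ndarray,
    truth: GroundTruth | Sequence[np.ndarray] | np.ndarray,
    tol_mm: float = 1.75,
) -> RecoveryReport:
    """Greedy nearest-pair one-to-one matching of found vs true contacts.

    ``found`` may be an array of mm coordinates, a list of per-electrode
    arrays, or a list of ContactSet-like objects with a ``contacts``
    attribute; ``truth`` may be a GroundTruth or coordinates in the same
    forms.  The default tolerance is half the standard 3.5 mm pitch, so a
    found contact can never be credited to a neighboring true contact.
    """

    def _stack(obj) -> np.ndarray:
        if isinstance(obj, GroundTruth):
            parts = obj.contacts
        elif isinstance(obj, np.ndarray):
            return obj.reshape(-1, 3)
        else:
            parts = [getattr(p, "contacts", p) for p in obj]
        if not parts:
            return np.zeros((0, 3))
        return np.concatenate([np.asarray(p).reshape(-1, 3) for p in parts])

    f = _stack(found)
    t = _stack(truth)
    if f.size == 0 or t.size == 0:
        return RecoveryReport(
            n_true=len(t), n_found=len(f), n_matched=0, errors_mm=np.zeros(0),
            unmatched_truth=list(range(len(t))), unmatched_found=list(range(len(f))),
        )
    d = cdist(f, t)
    free_f = np.ones(len(f), dtype=bool)
    free_t = np.ones(len(t), dtype=bool)
    pairs: List[Tuple[int, int]] = []
    order = np.argsort(d, axis=None)
    for flat in order:
        i, j = np.unravel_index(flat, d.shape)
        if d[i, j] > tol_mm:
            break
        if free_f[i] and free_t[j]:
            pairs.append((i, j))
            free_f[i] = False
            free_t[j] = False
    errors = np.array([d[i, j] for i, j in pairs])
    return RecoveryReport(
        n_true=len(t),
        n_found=len(f),
        n_matched=len(pairs),
        errors_mm=errors,
        unmatched_truth=list(np.flatnonzero(free_t)),
        unmatched_found=list(np.flatnonzero(free_f)),
    )
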