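"""Deletion genotyping from SNP-array Log R Ratio intensities.

A heterozygous deletion halves the DNA copy number at the markers it spans,
depressing their Log R Ratio (LRR).  Carriers are therefore separable from
non-carriers with a small logistic classifier over the per-marker LRR values
at the four chip markers inside the deletion plus their mean (5 features).

The logistic fit minimizes the mean negative log-likelihood plus an L2 ridge
on the slope weights (intercept unpenalized) by Newton iterations.  The
per-observation scaling of the likelihood makes the fit invariant to
duplicating the training set, and the ridge keeps the near-separable
carrier/non-carrier clusters from driving the MLE to infinity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_DELETION_MARKERS = 4
HOMOZYGOUS_LRR_CUTOFF = -2.0  # mean LRR below this flags a del/del animal


@dataclass
class LRRFeatures:
    animal: str
    lrr: np.ndarray          # the 4 per-marker LRR values, stated order
    mean_lrr: float
    complete: bool = True    # False when any marker LRR was missing

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.lrr, [self.mean_lrr]])


@dataclass
class CnvModel:
    weights: np.ndarray       # 5 slopes, feature order = 4 markers then mean
    intercept: float
    ridge_penalty: float
    threshold: float = 0.5
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.intercept):
            raise ValueError("non-finite model weights")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "ridge_penalty": self.ridge_penalty,
            "threshold": self.threshold,
            "feature_names": self.feature_names,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CnvModel":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["weights"], dtype=float), d["intercept"],
                   d["ridge_penalty"], d["threshold"], d["feature_names"])


def extract_features(lrr_matrix: pd.DataFrame,
                     deletion_markers: list[str]) -> list[LRRFeatures]:
    """Build the 5-feature vectors (4 marker LRRs + their mean) from an
    animals x markers LRR matrix."""
    if len(deletion_markers) != N_DELETION_MARKERS:
        raise ValueError(f"expected {N_DELETION_MARKERS} deletion markers")
    for m in deletion_markers:
        if m not in lrr_matrix.columns:
            raise KeyError(f"marker {m} missing from LRR matrix")
    sub = lrr_matrix[deletion_markers]
    out = []
    for animal, row in zip(sub.index, sub.to_numpy(dtype=float)):
        complete = bool(np.all(np.isfinite(row)))
        out.append(LRRFeatures(str(animal), row,
                               float(np.nanmean(row)), complete))
    return out


def _feature_matrix(features: list[LRRFeatures]) -> np.ndarray:
    return np.array([f.vector for f in features], dtype=float)


def train_classifier(features: list[LRRFeatures],
                     labels,
                     ridge_penalty: float = 1e-3,
                     max_iter: int = 200,
                     tol: float = 1e-10) -> CnvModel:
    """Fit the penalized logistic carrier classifier.

    ``labels`` are 'carrier'/'non_carrier' strings or a 0/1 array (1 =
    carrier).  Objective: mean cross-entropy + (ridge_penalty/2)*||w||^2 on
    the slopes.  Converges when the gradient infinity-norm drops below
    ``tol``; the fit is deterministic.
    """
    X = _feature_matrix(features)
    y = np.asarray([
        1.0 if (lab == "carrier" or lab == 1) else 0.0 for lab in labels])
    if len(y) != len(X):
        raise ValueError("labels/features length mismatch")
    if len(y) < 10:
        raise ValueError("need at least 10 training animals")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contain a single class")
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen = np.concatenate([[0.0], np.full(p, ridge_penalty)])  # no intercept pen
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = Xd.T @ (mu - y) / n + pen * beta
        if np.max(np.abs(grad)) < tol:
            break
        w = np.clip(mu * (1 - mu), 1e-10, None)
        hess = (Xd.T * w) @ Xd / n + np.diag(pen)
        step = np.linalg.solve(hess, grad)
        # halving line search on the penalized objective
        def obj(b):
            e = Xd @ b
            return (np.logaddexp(0, e).sum() - y @ e) / n + 0.5 * (pen * b * b).sum()
        f0, scale = obj(beta), 1.0
        while obj(beta - scale * step) > f0 and scale > 1e-8:
            scale *= 0.5
        beta = beta - scale * step
    return CnvModel(beta[1:].copy(), float(beta[0]), ridge_penalty,
                    feature_names=[f"lrr_{i+1}" for i in range(4)] + ["mean_lrr"])


def predict_carrier(features, model: CnvModel):
    """Carrier probability and status call for one LRRFeatures or a list.

    Status is 'carrier' when the logistic probability is at or above the
    model threshold; animals with mean LRR below the homozygous cutoff are
    additionally flagged 'deldel' (a putative fresh-born homozygote).
    """
    single = isinstance(features, LRRFeatures)
    feats = [features] if single else list(features)
    X = _feature_matrix(feats)
    if X.shape[1] != len(model.weights):
        raise ValueError(
            f"feature length {X.shape[1]} != model size {len(model.weights)}")
    prob = 1.0 / (1.0 + np.exp(-(X @ model.weights + model.intercept)))
    out = []
    for f, p in zip(feats, prob):
        if f.mean_lrr < HOMOZYGOUS_LRR_CUTOFF:
            status = "deldel"
        elif p >= model.threshold:
            status = "carrier"
        else:
            status = "non_carrier"
        out.append((float(p), status))
    return out[0] if single else out
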