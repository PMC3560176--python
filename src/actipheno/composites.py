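"""Weighted composite scores over standardized feature blocks.

The commercial instruments emulated here ship fixed composite scores
(activity severity, distraction severity, CPT confidence index) whose
coefficients are proprietary.  This package re-fits each composite on a
synthetic calibration cohort: features are standardized against control
reference statistics and combined by logistic regression of diagnostic
group on the block, so the score is the fitted linear predictor and higher
values are more ADHD-like.  Models serialize to plain JSON so a composite
fit once can be applied to any later cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression


@dataclass
class CompositeModel:
    """Standardization statistics plus logistic weights for one composite."""

    name: str
    feature_keys: list[str]
    ref_mean: np.ndarray        # control means used for standardization
    ref_sd: np.ndarray
    coef: np.ndarray
    intercept: float

    def score(self, features: pd.DataFrame) -> np.ndarray:
        """Linear predictor for each row; higher = more ADHD-like."""
        X = features[self.feature_keys].to_numpy(dtype=float)
        Z = (X - self.ref_mean) / self.ref_sd
        return Z @ self.coef + self.intercept

    def to_json(self) -> str:
        return json.dumps({
            "name": self.name,
            "feature_keys": self.feature_keys,
            "ref_mean": self.ref_mean.tolist(),
            "ref_sd": self.ref_sd.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CompositeModel":
        d = json.loads(text)
        return cls(d["name"], d["feature_keys"], np.asarray(d["ref_mean"]),
                   np.asarray(d["ref_sd"]), np.asarray(d["coef"]),
                   float(d["intercept"]))


def fit_composite(features: pd.DataFrame, is_case: np.ndarray,
                  feature_keys: list[str], name: str = "composite",
                  C: float = 1.0) -> CompositeModel:
    """Fit a composite on a calibration cohort containing both groups.

    `is_case` is 1 for the clinical group.  An L2 penalty (inverse strength
    `C`) keeps the fit defined under complete separation.
    """
    y = np.asarray(is_case).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("calibration cohort must contain both groups")
    missing = [k for k in feature_keys if k not in features.columns]
    if missing:
        raise ValueError(f"missing composite features: {missing}")
    X = features[feature_keys].to_numpy(dtype=float)
    ctrl = X[y == 0]
    ref_mean = ctrl.mean(axis=0)
    ref_sd = ctrl.std(axis=0, ddof=1)
    ref_sd = np.where(ref_sd > 0, ref_sd, 1.0)
    Z = (X - ref_mean) / ref_sd
    clf = LogisticRegression(C=C, max_iter=5000)
    clf.fit(Z, y)
    return CompositeModel(name, list(feature_keys), ref_mean, ref_sd,
                          clf.coef_.ravel().copy(), float(clf.intercept_[0]))
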