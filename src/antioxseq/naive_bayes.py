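"""Naive Bayes log-odds classifier over composition features.

The model assumes features independent given the class and scores a
protein by its log posterior-odds

    s(x) = log P(C=1)/P(C=0) + sum_i log p_i(x_i | C=1)/p_i(x_i | C=0),

declaring it positive (antioxidant) when s(x) >= theta. The threshold
theta trades sensitivity against specificity; theta = 0 is the plain
maximum-posterior decision.

Class-conditional densities are per-feature Gaussians by default (means
and variances estimated per class, variances floored to keep log-ratios
finite on near-constant composition features). A discretized multinomial
variant -- supervised MDL binning with Laplace-smoothed per-class bin
probabilities -- is available via ``density="multinomial"`` for
sensitivity analysis.

Organized as a model/results pair: :class:`GaussianNaiveBayes` holds the
data, ``fit()`` returns a :class:`NaiveBayesResults` carrying estimates,
scoring, threshold tuning, a ``summary()`` table and JSON round-tripping.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cfs import apply_cuts, mdl_discretize
from .features import FeatureMatrix

_LOG2PI = math.log(2.0 * math.pi)
_VAR_FLOOR_ABS = 1e-9
#: relative precision used for the variance floor: (0.01 * feature range)^2
_VAR_FLOOR_REL = 0.01


class ModelError(ValueError):
    """Raised on unfittable data or feature-name mismatches at scoring."""


def _as_matrix(
    X, feature_names: tuple[str, ...] | None = None
) -> tuple[np.ndarray, tuple[str, ...] | None, tuple[str, ...] | None]:
    """Coerce FeatureMatrix / DataFrame / ndarray to (values, names, ids)."""
    if isinstance(X, FeatureMatrix):
        return X.values, X.feature_names, X.sample_ids
    if isinstance(X, pd.DataFrame):
        return (
            X.to_numpy(dtype=float),
            tuple(map(str, X.columns)),
            tuple(map(str, X.index)),
        )
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr, feature_names, None


def tune_theta(
    scores: np.ndarray,
    labels: np.ndarray,
    objective: Literal["accuracy", "youden"] = "accuracy",
) -> float:
    """Pick the decision threshold maximizing accuracy or Youden's J.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted scores plus sentinels below the minimum and above the maximum
    (all-positive and all-negative decisions). Ties in the objective are
    broken toward the smallest theta.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to tune theta")
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best_theta, best_obj = None, -np.inf
    for theta in candidates:  # ascending, so first max wins -> smallest theta
        pred = scores >= theta
        tp = int(np.sum(pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        if objective == "accuracy":
            obj = (tp + tn) / len(labels)
        elif objective == "youden":
            obj = tp / n_pos + tn / n_neg - 1.0
        else:
            raise ValueError(f"unknown objective {objective!r}")
        if obj > best_obj + 1e-12:
            best_theta, best_obj = float(theta), obj
    return best_theta


class GaussianNaiveBayes:
    """Naive Bayes model over a named feature matrix with binary labels.

    Parameters
    ----------
    features
        FeatureMatrix, DataFrame (columns = feature names) or 2-D array.
    labels
        Binary labels aligned with the rows; 1 = positive class.
    density
        "gaussian" (default) or "multinomial" (MDL-discretized bins).
    theta
        Default decision threshold carried into the results.
    """

    def __init__(
        self,
        features,
        labels,
        feature_names: Sequence[str] | None = None,
        density: Literal["gaussian", "multinomial"] = "gaussian",
        theta: float = 0.0,
    ) -> None:
        values, names, ids = _as_matrix(features)
        if names is None:
            if feature_names is not None:
                names = tuple(feature_names)
            else:
                names = tuple(f"f{i}" for i in range(values.shape[1]))
        if len(names) != values.shape[1]:
            raise ModelError("feature_names length mismatch")
        if density not in ("gaussian", "multinomial"):
            raise ModelError(f"unknown density family {density!r}")
        labels = np.asarray(labels, dtype=int)
        if len(labels) != values.shape[0]:
            raise ModelError("labels length mismatch")
        if len(labels) and not np.isin(labels, (0, 1)).all():
            raise ModelError("labels must be binary (0/1)")
        self.exog = values
        self.labels = labels
        self.feature_names = tuple(names)
        self.sample_ids = ids
        self.density = density
        self.theta = float(theta)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "label", **kwargs
    ) -> "GaussianNaiveBayes":
        if label_col not in df.columns:
            raise ModelError(f"no {label_col!r} column in dataframe")
        return cls(
            df.drop(columns=[label_col]), df[label_col].to_numpy(), **kwargs
        )

    def fit(self) -> "NaiveBayesResults":
        """Estimate priors and class-conditional densities.

        Priors are Laplace-smoothed class frequencies (n_c + 1)/(N + 2).
        Gaussian family: per class/feature sample mean and unbiased
        variance, floored at max(1e-9, (0.01 * feature range)^2) so a
        feature constant within a class cannot blow up the log-ratio.
        Requires at least two samples per class.
        """
        y = self.labels
        n0 = int((y == 0).sum())
        n1 = int((y == 1).sum())
        if n0 < 2 or n1 < 2:
            raise ModelError(
                f"need >= 2 samples per class, got neg={n0}, pos={n1}"
            )
        n = n0 + n1
        prior_pos = (n1 + 1.0) / (n + 2.0)
        if self.density == "gaussian":
            means = np.empty((2, len(self.feature_names)))
            variances = np.empty_like(means)
            col_range = self.exog.max(axis=0) - self.exog.min(axis=0)
            floor = np.maximum(
                _VAR_FLOOR_ABS, (_VAR_FLOOR_REL * col_range) ** 2
            )
            for cls in (0, 1):
                block = self.exog[y == cls]
                means[cls] = block.mean(axis=0)
                variances[cls] = np.maximum(block.var(axis=0, ddof=1), floor)
            return NaiveBayesResults(
                feature_names=self.feature_names,
                prior_pos=prior_pos,
                density="gaussian",
                means=means,
                variances=variances,
                theta=self.theta,
                model=self,
            )
        # multinomial: supervised MDL bins, Laplace-smoothed bin probabilities
        cuts: list[list[float]] = []
        log_probs: list[np.ndarray] = []
        for i in range(len(self.feature_names)):
            col = self.exog[:, i]
            c = mdl_discretize(col, y)
            codes = apply_cuts(col, c)
            n_bins = len(c) + 1
            table = np.empty((2, n_bins))
            for cls in (0, 1):
                counts = np.bincount(codes[y == cls], minlength=n_bins)
                table[cls] = np.log(
                    (counts + 1.0) / (counts.sum() + n_bins)
                )
            cuts.append(list(c))
            log_probs.append(table)
        return NaiveBayesResults(
            feature_names=self.feature_names,
            prior_pos=prior_pos,
            density="multinomial",
            cuts=cuts,
            log_probs=log_probs,
            theta=self.theta,
            model=self,
        )


class NaiveBayesResults:
    """Fitted Naive Bayes parameters with scoring and reporting.

    Carries the class priors, the per-class per-feature density
    parameters, the decision threshold, and the feature-name contract
    every scored input must satisfy.
    """

    def __init__(
        self,
        feature_names: Sequence[str],
        prior_pos: float,
        density: str,
        means: np.ndarray | None = None,
        variances: np.ndarray | None = None,
        cuts: list[list[float]] | None = None,
        log_probs: list[np.ndarray] | None = None,
        theta: float = 0.0,
        model: GaussianNaiveBayes | None = None,
    ) -> None:
        if not 0.0 < prior_pos < 1.0:
            raise ModelError("prior_pos must lie strictly in (0, 1)")
        self.feature_names = tuple(feature_names)
        self.prior_pos = float(prior_pos)
        self.prior_neg = 1.0 - self.prior_pos
        self.density = density
        self.means = means
        self.variances = variances
        if variances is not None and np.any(variances < _VAR_FLOOR_ABS):
            raise ModelError("variances below the admissible floor")
        self.cuts = cuts
        self.log_probs = log_probs
        self.theta = float(theta)
        self.model = model

    # -- scoring -----------------------------------------------------------

    def _coerce(self, X) -> tuple[np.ndarray, tuple[str, ...] | None]:
        values, names, ids = _as_matrix(X)
        if names is not None and names != self.feature_names:
            raise ModelError(
                "feature names/order do not match the fitted model"
            )
        if values.shape[1] != len(self.feature_names):
            raise ModelError(
                f"expected {len(self.feature_names)} features, "
                f"got {values.shape[1]}"
            )
        return values, ids

    def log_odds(self, X) -> np.ndarray:
        """Log posterior-odds score for each row of X (finite for finite X)."""
        values, _ = self._coerce(X)
        prior_term = math.log(self.prior_pos / self.prior_neg)
        if self.density == "gaussian":
            ll = []
            for cls in (0, 1):
                m, v = self.means[cls], self.variances[cls]
                ll.append(
                    -0.5
                    * (np.log(v) + _LOG2PI + (values - m) ** 2 / v).sum(axis=1)
                )
            return prior_term + ll[1] - ll[0]
        scores = np.full(values.shape[0], prior_term)
        for i in range(len(self.feature_names)):
            codes = apply_cuts(values[:, i], self.cuts[i])
            table = self.log_probs[i]
            scores += table[1][codes] - table[0][codes]
        return scores

    def predict(self, X, theta: float | None = None):
        """Classify rows of X: 1 iff log-odds >= theta (ties go positive).

        Returns ``(classes, scores)``.
        """
        theta = self.theta if theta is None else float(theta)
        scores = self.log_odds(X)
        return (scores >= theta).astype(int), scores

    def tune_theta(
        self,
        scores: np.ndarray | None = None,
        labels: np.ndarray | None = None,
        objective: Literal["accuracy", "youden"] = "accuracy",
    ) -> float:
        """Tune theta on given (scores, labels), or on the training data."""
        if scores is None or labels is None:
            if self.model is None:
                raise ModelError(
                    "no training data attached; pass scores and labels"
                )
            scores = self.log_odds(self.model.exog)
            labels = self.model.labels
        return tune_theta(scores, labels, objective)

    # -- reporting ---------------------------------------------------------

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary with the most discriminative features."""
        lines = [
            "Naive Bayes log-odds classifier",
            "=" * 47,
            f"density family:   {self.density}",
            f"features:         {len(self.feature_names)}",
            f"prior P(C=1):     {self.prior_pos:.4f}",
            f"prior P(C=0):     {self.prior_neg:.4f}",
            f"threshold theta:  {self.theta:g}",
        ]
        if self.model is not None:
            n1 = int((self.model.labels == 1).sum())
            n0 = int((self.model.labels == 0).sum())
            lines.insert(2, f"n samples:        {n0 + n1} ({n1} pos, {n0} neg)")
        if self.density == "gaussian":
            sd = np.sqrt(self.variances)
            pooled = np.sqrt((self.variances[0] + self.variances[1]) / 2.0)
            effect = (self.means[1] - self.means[0]) / pooled
            order = np.argsort(-np.abs(effect))[:top]
            table = pd.DataFrame(
                {
                    "mean_pos": self.means[1][order],
                    "sd_pos": sd[1][order],
                    "mean_neg": self.means[0][order],
                    "sd_neg": sd[0][order],
                    "std_diff": effect[order],
                },
                index=[self.feature_names[i] for i in order],
            )
            lines += [
                "",
                f"top {len(order)} features by standardized class difference:",
                table.to_string(float_format=lambda v: f"{v:9.4f}"),
            ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        payload = {
            "density_family": self.density,
            "feature_names": list(self.feature_names),
            "prior_pos": self.prior_pos,
            "prior_neg": self.prior_neg,
            "theta": self.theta,
        }
        if self.density == "gaussian":
            payload["means"] = {
                "neg": self.means[0].tolist(),
                "pos": self.means[1].tolist(),
            }
            payload["variances"] = {
                "neg": self.variances[0].tolist(),
                "pos": self.variances[1].tolist(),
            }
        else:
            payload["cuts"] = self.cuts
            payload["log_probs"] = {
                "neg": [t[0].tolist() for t in self.log_probs],
                "pos": [t[1].tolist() for t in self.log_probs],
            }
        return payload

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, payload: dict) -> "NaiveBayesResults":
        density = payload["density_family"]
        kwargs = dict(
            feature_names=payload["feature_names"],
            prior_pos=payload["prior_pos"],
            density=density,
            theta=payload.get("theta", 0.0),
        )
        if density == "gaussian":
            kwargs["means"] = np.array(
                [payload["means"]["neg"], payload["means"]["pos"]]
            )
            kwargs["variances"] = np.array(
                [payload["variances"]["neg"], payload["variances"]["pos"]]
            )
        else:
            kwargs["cuts"] = payload["cuts"]
            kwargs["log_probs"] = [
                np.array([neg, pos])
                for neg, pos in zip(
                    payload["log_probs"]["neg"], payload["log_probs"]["pos"]
                )
            ]
        return cls(**kwargs)

    @classmethod
    def from_json(cls, source: str | Path) -> "NaiveBayesResults":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        return cls.from_dict(json.loads(text))
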