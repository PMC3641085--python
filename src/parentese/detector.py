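"""Two-stream GMM parentese detector with weighted score fusion.

One diagonal-covariance Gaussian mixture is trained per class and per
feature stream: the segmental stream models pooled MFCC frames (M = 12
components by default), the supra-segmental stream models the utterance's
prosodic-statistics vector (M = 15).  At test time each stream scores an
utterance under both class models — the segmental score is the *mean*
per-frame log-likelihood so the two streams are on comparable, duration-free
scales — the per-stream scores are softmax-normalised into class posteriors,
and the posteriors are fused convexly:

    P(c) = lambda * P_segmental(c) + (1 - lambda) * P_suprasegmental(c)

with lambda = 0.4 by default.  The predicted label is the argmax; an exact
tie resolves to other speech.  Evaluation reports accuracy, positive and
negative predictive value with two-sided exact (Clopper–Pearson) binomial
95% confidence intervals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import log_softmax
from scipy.stats import binomtest
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .acoustics import extract_segmental, extract_suprasegmental
from .synth.audio import OTHER_SPEECH, PARENTESE

CLASSES = (PARENTESE, OTHER_SPEECH)
STREAMS = ("segmental", "suprasegmental")


@dataclass(frozen=True)
class FusionConfig:
    """Fusion weight and mixture sizes of the detector."""

    fusion_lambda: float = 0.4
    m_segmental: int = 12
    m_suprasegmental: int = 15

    def __post_init__(self) -> None:
        if not 0.0 <= self.fusion_lambda <= 1.0:
            raise ValueError("fusion lambda must lie in [0, 1]")
        if self.m_segmental < 1 or self.m_suprasegmental < 1:
            raise ValueError("mixture sizes must be >= 1")


@dataclass
class GmmModel:
    """Diagonal-covariance Gaussian mixture for one class and stream."""

    weights: np.ndarray
    means: np.ndarray  # (M, d)
    variances: np.ndarray  # (M, d) diagonal
    class_label: str = ""
    loglik_trace: list[float] = field(default_factory=list, repr=False)

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def is_loglik_monotone(self, tol: float = 1e-5) -> bool:
        """Whether the recorded EM trace is non-decreasing.

        Exact EM never decreases the likelihood; the variance floor
        (``reg_covar``) is re-added at every M-step, which can perturb the
        mean per-sample log-likelihood at up to roughly the floor's scale,
        hence the small absolute tolerance.
        """
        return bool(np.all(np.diff(self.loglik_trace) >= -tol))

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        """Log-density of each row of ``x`` under the mixture."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.dim:
            raise ValueError(
                f"feature dimension {x.shape[1]} does not match model dimension {self.dim}"
            )
        # (n, M) component log-densities
        diff = x[:, None, :] - self.means[None, :, :]
        comp = -0.5 * (
            np.sum(diff**2 / self.variances[None, :, :], axis=2)
            + np.sum(np.log(2 * np.pi * self.variances), axis=1)[None, :]
        )
        comp = comp + np.log(self.weights)[None, :]
        m = comp.max(axis=1)
        return m + np.log(np.sum(np.exp(comp - m[:, None]), axis=1))

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "class_label": self.class_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GmmModel":
        return cls(
            weights=np.asarray(d["weights"]),
            means=np.asarray(d["means"]),
            variances=np.asarray(d["variances"]),
            class_label=d.get("class_label", ""),
        )


def fit_gmm(
    features: np.ndarray,
    n_components: int,
    seed: int = 0,
    class_label: str = "",
    tol: float = 1e-4,
    max_iter: int = 200,
    var_floor: float = 1e-6,
) -> GmmModel:
    """EM fit of a diagonal GMM with k-means initialisation.

    The fit is stepped one EM iteration at a time so the training
    log-likelihood trace is recorded; EM guarantees it is non-decreasing,
    and the trace is kept on the model for auditing.  Stops on relative
    improvement < ``tol`` (on the mean per-sample log-likelihood, sklearn's
    convention) or ``max_iter`` iterations.
    """
    x = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if not np.all(np.isfinite(x)):
        raise ValueError("training features must be finite")
    if x.shape[0] < n_components:
        raise ValueError(
            f"need at least {n_components} training vectors, got {x.shape[0]}"
        )
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="diag",
        reg_covar=var_floor,
        tol=0.0,  # convergence is managed by the stepping loop below
        max_iter=1,
        init_params="kmeans",
        random_state=seed,
        warm_start=True,
    )
    trace: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(max_iter):
            gm.fit(x)
            trace.append(float(gm.lower_bound_))
            if len(trace) >= 2:
                prev, cur = trace[-2], trace[-1]
                if abs(cur - prev) < tol * max(1.0, abs(prev)):
                    break
    return GmmModel(
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        variances=gm.covariances_.copy(),
        class_label=class_label,
        loglik_trace=trace,
    )


class ParenteseDetector:
    """Train / apply the fused two-stream parentese vs other-speech detector."""

    def __init__(self, config: FusionConfig | None = None):
        self.config = config or FusionConfig()
        self.models: dict[str, dict[str, GmmModel]] = {}

    # -- training -----------------------------------------------------------

    def fit(self, utterances, labels=None, seed: int = 0) -> "ParenteseDetector":
        """Train all four stream x class mixtures.

        ``labels`` defaults to each utterance's own ``label`` attribute.
        Utterances without any voiced frame contribute to the segmental
        stream only.
        """
        if labels is None:
            labels = [u.label for u in utterances]
        labels = list(labels)
        if set(labels) - set(CLASSES):
            raise ValueError(f"labels must be among {CLASSES}")
        seg_feats = {c: [] for c in CLASSES}
        sup_feats = {c: [] for c in CLASSES}
        for u, lab in zip(utterances, labels):
            seg_feats[lab].append(extract_segmental(u).features)
            sup = extract_suprasegmental(u)
            if sup.has_voicing:
                sup_feats[lab].append(sup.vector)
            else:
                warnings.warn(
                    "utterance with no voiced frames: excluded from the "
                    "supra-segmental stream"
                )
        self.models = {"segmental": {}, "suprasegmental": {}}
        for i, c in enumerate(CLASSES):
            self.models["segmental"][c] = fit_gmm(
                np.vstack(seg_feats[c]), self.config.m_segmental,
                seed=seed + i, class_label=c,
            )
            self.models["suprasegmental"][c] = fit_gmm(
                np.vstack(sup_feats[c]), self.config.m_suprasegmental,
                seed=seed + 10 + i, class_label=c,
            )
        return self

    # -- scoring ------------------------------------------------------------

    def score_streams(self, utterance) -> dict[str, dict[str, float]]:
        """Per-stream, per-class scores for one utterance.

        Segmental: mean per-frame log-likelihood (duration-normalised).
        Supra-segmental: log-likelihood of the statistics vector, or None
        for utterances with no voiced frame (prior fallback at fusion).
        """
        if not self.models:
            raise RuntimeError("detector is not trained")
        seg = extract_segmental(utterance).features
        sup = extract_suprasegmental(utterance)
        out: dict[str, dict[str, float]] = {"segmental": {}, "suprasegmental": {}}
        for c in CLASSES:
            out["segmental"][c] = float(
                np.mean(self.models["segmental"][c].logpdf(seg))
            )
            out["suprasegmental"][c] = (
                float(self.models["suprasegmental"][c].logpdf(sup.vector[None, :])[0])
                if sup.has_voicing
                else None
            )
        return out

    def predict(self, utterances) -> list[str]:
        return [self.classify(u)[0] for u in utterances]

    def classify(self, utterance) -> tuple[str, float]:
        """(label, fused parentese posterior) for one utterance."""
        scores = self.score_streams(utterance)
        return fuse_and_classify(scores, self.config)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "config": {
                "fusion_lambda": self.config.fusion_lambda,
                "m_segmental": self.config.m_segmental,
                "m_suprasegmental": self.config.m_suprasegmental,
            },
            "models": {
                s: {c: m.to_dict() for c, m in per_class.items()}
                for s, per_class in self.models.items()
            },
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "ParenteseDetector":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        det = cls(FusionConfig(**payload["config"]))
        det.models = {
            s: {c: GmmModel.from_dict(m) for c, m in per_class.items()}
            for s, per_class in payload["models"].items()
        }
        return det


def _stream_posteriors(class_scores: dict[str, float | None]) -> np.ndarray:
    """Softmax class posteriors for one stream (uniform priors).

    A stream with missing scores (no voiced frames) contributes the prior.
    """
    vals = [class_scores[c] for c in CLASSES]
    if any(v is None for v in vals):
        return np.full(len(CLASSES), 1.0 / len(CLASSES))
    return np.exp(log_softmax(np.asarray(vals, dtype=np.float64)))


def fuse_and_classify(
    stream_scores: dict[str, dict[str, float | None]],
    config: FusionConfig | None = None,
) -> tuple[str, float]:
    """Convex posterior fusion of the two streams; returns (label, P(parentese)).

    Ties resolve to other speech (the negative class).
    """
    config = config or FusionConfig()
    lam = config.fusion_lambda
    p_seg = _stream_posteriors(stream_scores["segmental"])
    p_sup = _stream_posteriors(stream_scores["suprasegmental"])
    fused = lam * p_seg + (1.0 - lam) * p_sup
    p_parentese = float(fused[CLASSES.index(PARENTESE)])
    label = PARENTESE if p_parentese > 0.5 else OTHER_SPEECH
    return label, p_parentese


def fuse_posteriors(
    p_seg_parentese: float, p_sup_parentese: float, fusion_lambda: float = 0.4
) -> tuple[str, float]:
    """Fusion directly from per-stream parentese posteriors."""
    if not 0.0 <= fusion_lambda <= 1.0:
        raise ValueError("fusion lambda must lie in [0, 1]")
    fused = fusion_lambda * p_seg_parentese + (1 - fusion_lambda) * p_sup_parentese
    return (PARENTESE if fused > 0.5 else OTHER_SPEECH), fused


# -- evaluation -------------------------------------------------------------


def _exact_ci(k: int, n: int) -> tuple[float, float]:
    ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return 100.0 * ci.low, 100.0 * ci.high


@dataclass
class EvalReport:
    tp: int
    fn: int
    fp: int
    tn: int
    metrics: dict[str, float] = field(default_factory=dict)  # % values
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def to_dict(self) -> dict:
        return {
            "confusion": {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn},
            "metrics_pct": self.metrics,
            "ci95_pct": {k: list(v) for k, v in self.intervals.items()},
        }

    def summary(self) -> str:
        lines = [f"n = {self.n}  (TP={self.tp} FN={self.fn} FP={self.fp} TN={self.tn})"]
        for name, val in self.metrics.items():
            lo, hi = self.intervals[name]
            lines.append(f"{name:>9s} = {val:6.2f}%  (95% CI {lo:.2f}-{hi:.2f}%)")
        return "\n".join(lines)


def evaluate_confusion(tp: int, fn: int, fp: int, tn: int) -> EvalReport:
    """Metrics and exact binomial CIs from confusion counts.

    Accuracy = (TP+TN)/n, PPV = TP/(TP+FP), NPV = TN/(TN+FN), each with a
    two-sided Clopper–Pearson 95% interval on its own numerator/denominator.
    Metrics with a zero denominator are omitted from the report.
    """
    n = tp + fn + fp + tn
    if n == 0:
        raise ValueError("empty evaluation")
    report = EvalReport(tp=tp, fn=fn, fp=fp, tn=tn)
    cells = {
        "accuracy": (tp + tn, n),
        "ppv": (tp, tp + fp),
        "npv": (tn, tn + fn),
    }
    for name, (k, denom) in cells.items():
        if denom == 0:
            continue
        report.metrics[name] = 100.0 * k / denom
        report.intervals[name] = _exact_ci(k, denom)
    return report


def evaluate(true_labels, predicted_labels, positive: str = PARENTESE) -> EvalReport:
    """EvalReport from parallel label sequences (positive class: parentese)."""
    y = list(true_labels)
    yhat = list(predicted_labels)
    if len(y) != len(yhat):
        raise ValueError("label sequences must have equal length")
    if len(y) == 0:
        raise ValueError("empty evaluation")
    tp = sum(1 for a, b in zip(y, yhat) if a == positive and b == positive)
    fn = sum(1 for a, b in zip(y, yhat) if a == positive and b != positive)
    fp = sum(1 for a, b in zip(y, yhat) if a != positive and b == positive)
    tn = sum(1 for a, b in zip(y, yhat) if a != positive and b != positive)
    return evaluate_confusion(tp, fn, fp, tn)
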