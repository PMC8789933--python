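"""Gaussian-mixture / Mahalanobis-distance diagnosis in the 3-D feature space.

A K=7 full-covariance Gaussian mixture is fitted to the diagnostic features
[gamma1, gamma2, gamma3] by EM (diagonal regularization 0.01, as in the
MATLAB ``fitgmdist`` convention).  For a Gaussian component the squared
Mahalanobis distance d2 = (x-mu)' Sigma^-1 (x-mu) follows a chi-square
distribution with 3 degrees of freedom, so the chi2(3) quantile at a
confidence level beta_k bounds a confidence ellipsoid (threshold MDC_k).
A sample is assigned to the class whose ellipsoid contains it, or "unknown"
when none does; with multiple containing ellipsoids, the class minimizing
the normalized distance d2_k / MDC_k wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2
from sklearn.mixture import GaussianMixture

from .errors import DataError, PackagingError, ParameterError
from .spectral import PcaModel

UNKNOWN = "unknown"

#: Confidence-level sweep grid: 0.63 to 0.97 in steps of 0.02.
DEFAULT_BETA_GRID = np.round(np.linspace(0.63, 0.97, 18), 10)


@dataclass(frozen=True)
class GaussianComponent:
    """One mixture component (pi, mu, Sigma) tagged with its disease class."""

    pi: float
    mu: np.ndarray
    sigma: np.ndarray
    label: str

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if not (0.0 < self.pi <= 1.0):
            raise ParameterError(f"mixing weight must lie in (0, 1], got {self.pi}")
        if sigma.shape != (mu.size, mu.size):
            raise ParameterError("covariance shape does not match the mean")
        if not np.allclose(sigma, sigma.T, atol=1e-8):
            raise ParameterError(f"covariance of {self.label!r} is not symmetric")
        if np.linalg.eigvalsh(sigma).min() <= 0:
            raise ParameterError(f"covariance of {self.label!r} is not positive-definite")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)


def chi2_inverse(beta: float, dof: int = 3) -> float:
    """chi-square quantile at probability ``beta`` (the MDC threshold)."""
    if not (0.0 <= beta < 1.0):
        raise ParameterError(f"confidence level must lie in [0, 1), got {beta}")
    return float(chi2.ppf(beta, dof))


def mahalanobis_sq(x, comp: GaussianComponent) -> float:
    """Squared Mahalanobis distance (x-mu)' Sigma^-1 (x-mu) to one component."""
    diff = np.asarray(x, dtype=float) - comp.mu
    return float(diff @ np.linalg.solve(comp.sigma, diff))


@dataclass
class ClassifierModel:
    """K Gaussian components with per-class confidence levels and thresholds.

    Carries the PCA/standardization constants needed to score a raw
    8-feature vector, when available.
    """

    components: list[GaussianComponent]
    beta: np.ndarray
    mdc: np.ndarray
    pca: PcaModel | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.mdc = np.asarray(self.mdc, dtype=float)
        k = len(self.components)
        if self.beta.size != k or self.mdc.size != k:
            raise ParameterError("beta/mdc length must match the component count")
        total = sum(c.pi for c in self.components)
        if abs(total - 1.0) > 1e-4:
            raise ParameterError(f"mixing weights sum to {total}, expected 1")

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.components]

    def with_beta(self, beta) -> "ClassifierModel":
        """Same components, new confidence levels (thresholds recomputed)."""
        beta = np.asarray(beta, dtype=float)
        mdc = np.array([chi2_inverse(b) for b in beta])
        return ClassifierModel(self.components, beta, mdc, self.pca, dict(self.metadata))

    def distances(self, x) -> np.ndarray:
        return np.array([mahalanobis_sq(x, c) for c in self.components])

    def to_dict(self) -> dict:
        return {
            "components": [
                {
                    "label": c.label,
                    "pi": c.pi,
                    "mu": c.mu.tolist(),
                    "sigma": c.sigma.tolist(),
                }
                for c in self.components
            ],
            "beta": self.beta.tolist(),
            "mdc": self.mdc.tolist(),
            "pca": None if self.pca is None else self.pca.to_dict(),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierModel":
        comps = [
            GaussianComponent(pi=c["pi"], mu=c["mu"], sigma=c["sigma"], label=c["label"])
            for c in d["components"]
        ]
        pca = None if d.get("pca") is None else PcaModel.from_dict(d["pca"])
        return cls(comps, d["beta"], d["mdc"], pca, d.get("metadata", {}))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_gmm(
    features,
    k: int = 7,
    regularization: float = 0.01,
    max_iter: int = 1000,
    seed: int | None = 0,
    labels=None,
    n_init: int = 4,
) -> list[GaussianComponent]:
    """EM-fit a K-component full-covariance Gaussian mixture.

    ``regularization`` is added to every covariance diagonal in each M step.
    When ``labels`` are supplied and their class count equals ``k``, EM is
    initialized from the per-class moments (and refined unsupervised from
    there); otherwise k-means initialization with ``n_init`` restarts is
    used.  Fitted components are then named by optimal assignment against
    the labels of the points they claim (highest posterior), or
    component_0..component_{K-1} without labels.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise DataError("features must be an n-by-d matrix")
    if not np.isfinite(x).all():
        raise DataError("features contain non-finite values")
    if x.shape[0] < 10 * k:
        raise DataError(f"need at least {10 * k} samples to fit {k} components")
    kwargs = {}
    if labels is not None:
        lab = np.asarray(labels)
        if lab.size != x.shape[0]:
            raise DataError("labels length must match the feature rows")
        classes = sorted(set(lab.tolist()))
        if len(classes) == k:
            kwargs["means_init"] = np.stack([x[lab == c].mean(axis=0) for c in classes])
            kwargs["weights_init"] = np.array(
                [np.mean(lab == c) for c in classes]
            )
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=regularization,
        max_iter=max_iter,
        tol=1e-8,
        random_state=seed,
        init_params="kmeans",
        n_init=1 if "means_init" in kwargs else n_init,
        **kwargs,
    )
    assignment = gm.fit_predict(x)
    if labels is not None:
        labels = np.asarray(labels)
        if labels.size != x.shape[0]:
            raise DataError("labels length must match the feature rows")
        classes = sorted(set(labels.tolist()))
        counts = np.zeros((len(classes), k))
        for ci, cls_ in enumerate(classes):
            member = assignment[labels == cls_]
            for comp in member:
                counts[ci, comp] += 1
        rows, cols = linear_sum_assignment(-counts)
        names = {int(c): classes[int(r)] for r, c in zip(rows, cols)}
        comp_labels = [names.get(i, f"component_{i}") for i in range(k)]
    else:
        comp_labels = [f"component_{i}" for i in range(k)]
    return [
        GaussianComponent(
            pi=float(gm.weights_[i]),
            mu=gm.means_[i],
            sigma=gm.covariances_[i],
            label=comp_labels[i],
        )
        for i in range(k)
    ]


def classify(x, model: ClassifierModel) -> str:
    """Assign x to the class whose confidence ellipsoid contains it.

    No containing ellipsoid -> "unknown"; several -> smallest d2/MDC ratio.
    """
    d2 = model.distances(x)
    eligible = np.flatnonzero(d2 <= model.mdc)
    if eligible.size == 0:
        return UNKNOWN
    ratios = d2[eligible] / model.mdc[eligible]
    return model.components[eligible[np.argmin(ratios)]].label


def classify_batch(features, model: ClassifierModel) -> np.ndarray:
    x = np.atleast_2d(np.asarray(features, dtype=float))
    return np.array([classify(row, model) for row in x], dtype=object)


def select_beta(
    model: ClassifierModel,
    features,
    labels,
    grid=DEFAULT_BETA_GRID,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-class confidence-level sweep.

    For each class k, one-vs-rest accuracy is evaluated over the grid with
    the binary rule "inside ellipsoid k at level beta <=> predicted k"; the
    selected beta_k is the largest grid value whose accuracy ties (within
    1e-9) the class maximum, i.e. the largest ellipsoid among the most
    accurate ones.  Returns (beta per component, accuracy table with one
    column per class and one row per grid value).
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    missing = set(model.labels) - set(labels.tolist())
    if missing:
        raise DataError(f"labelled features miss class(es): {sorted(missing)}")
    grid = np.asarray(grid, dtype=float)
    d2 = np.array([[mahalanobis_sq(row, c) for c in model.components] for row in x])
    table = pd.DataFrame(index=np.round(grid, 4), columns=model.labels, dtype=float)
    table.index.name = "beta"
    chosen = np.empty(len(model.components))
    for ki, comp in enumerate(model.components):
        truth = labels == comp.label
        accs = np.array(
            [np.mean((d2[:, ki] <= chi2_inverse(b)) == truth) for b in grid]
        )
        table[comp.label] = 100.0 * accs
        best = accs.max()
        chosen[ki] = grid[np.flatnonzero(accs >= best - 1e-9)[-1]]
    return chosen, table


@dataclass(frozen=True)
class Metrics:
    """One-vs-rest confusion counts and the derived percentages."""

    tp: int
    fp: int
    tn: int
    fn: int
    ca: float
    se: float
    sp: float


def evaluate(predicted, true, positive_class) -> Metrics:
    """One-vs-rest accuracy/sensitivity/specificity for one class, in percent."""
    predicted = np.asarray(predicted, dtype=object)
    true = np.asarray(true, dtype=object)
    if predicted.size != true.size:
        raise DataError("prediction and truth label sequences differ in length")
    pos_pred = predicted == positive_class
    pos_true = true == positive_class
    tp = int(np.sum(pos_pred & pos_true))
    fp = int(np.sum(pos_pred & ~pos_true))
    fn = int(np.sum(~pos_pred & pos_true))
    tn = int(np.sum(~pos_pred & ~pos_true))
    if tp + fn == 0:
        raise DataError(f"sensitivity undefined: no true {positive_class!r} samples")
    if fp + tn == 0:
        raise DataError(f"specificity undefined: only {positive_class!r} samples")
    total = tp + fp + fn + tn
    return Metrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        ca=100.0 * (tp + tn) / total,
        se=100.0 * tp / (tp + fn),
        sp=100.0 * tn / (fp + tn),
    )


def evaluate_all(predicted, true, classes=None) -> pd.DataFrame:
    """Per-class one-vs-rest metrics as a table (rows = classes)."""
    if classes is None:
        classes = sorted(set(np.asarray(true, dtype=object).tolist()))
    rows = {}
    for cls_ in classes:
        m = evaluate(predicted, true, cls_)
        rows[cls_] = {
            "TP": m.tp, "FP": m.fp, "TN": m.tn, "FN": m.fn,
            "CA": m.ca, "Se": m.se, "Sp": m.sp,
        }
    out = pd.DataFrame(rows).T
    out.index.name = "class"
    return out


def bundled_reference_model() -> ClassifierModel:
    """The packaged seven-class reference model.

    Mixture parameters, feature statistics, and the PCA eigensystem come from
    the packaged resource; the MDC thresholds are recomputed from the stored
    confidence levels and checked against the stored 4-decimal values.
    """
    try:
        text = resources.files("heartsound.data").joinpath("reference_model.json").read_text()
        doc = json.loads(text)
        comps = [
            GaussianComponent(pi=c["pi"], mu=c["mu"], sigma=c["sigma"], label=c["label"])
            for c in doc["gmm"]["components"]
        ]
        beta = np.asarray(doc["gmm"]["beta"], dtype=float)
        stored_mdc = np.asarray(doc["gmm"]["mdc"], dtype=float)
        pca = PcaModel.from_dict({
            "mu_ff": doc["pca"]["mu_ff"],
            "sigma_ff": doc["pca"]["sigma_ff"],
            "eigenvectors": doc["pca"]["eigenvectors"],
            "eigenvalues": doc["pca"]["eigenvalues"],
        })
    except (KeyError, FileNotFoundError, json.JSONDecodeError) as exc:
        raise PackagingError(f"reference model resource is missing or corrupt: {exc}")
    mdc = np.array([chi2_inverse(b) for b in beta])
    if not np.allclose(np.round(mdc, 4), stored_mdc):
        raise PackagingError("recomputed MDC thresholds disagree with the stored values")
    return ClassifierModel(
        comps, beta, mdc, pca, metadata={"source": "bundled reference", "version": doc["version"]}
    )
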