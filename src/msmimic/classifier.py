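"""Subgroup classification with missing-locus tolerance.

Two support-vector-machine models are trained on the same cohort: a
genome-scale model on the 10,000 most variably methylated loci, and the
deployable minimal-signature model on the 17 signature loci.  The signature
model carries the machinery needed for degraded single samples:

* EM imputation of missing signature loci under a multivariate-normal model
  of logit-transformed training β-values;
* a maximum tolerated number of missing loci (shipped default 6 of 17);
* a classification-confidence threshold (shipped default 0.69) below which a
  sample is non-classifiable (NC).

Classification of a sample runs a fixed QC cascade: bisulfite-conversion
control, missing-locus count, imputation, probability threshold.
"""

from __future__ import annotations

import json
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC


@contextmanager
def _quiet_svc():
    # SVC(probability=True) is the pairwise-coupled probability calibration
    # this model is built on; silence scikit-learn's migration notice.
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")
        yield

from .matrix import BetaMatrix
from .signature import SignatureDefinition

__all__ = [
    "ClassifierModel",
    "ClassificationResult",
    "LocusQCError",
    "train_models",
    "impute_missing_em",
    "calibrate_missing_threshold",
    "calibrate_probability_threshold",
    "classify_sample",
    "classify_cohort",
]

#: Shipped defaults: tolerate at most 6 missing of 17 signature loci, and
#: require a maximum class probability of at least 0.69 for a confident call.
DEFAULT_MAX_MISSING = 6
DEFAULT_PROBABILITY_THRESHOLD = 0.69

_BETA_CLIP = (0.01, 0.99)


class LocusQCError(ValueError):
    """Too many missing signature loci for imputation."""


def _logit2(beta: np.ndarray) -> np.ndarray:
    b = np.clip(beta, *_BETA_CLIP)
    return np.log2(b / (1.0 - b))


def _inv_logit2(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp2(-z))


# ---------------------------------------------------------------------------
# Model container and JSON serialization

# Fitted-SVC attributes required to reconstruct predict_proba without
# refitting.  Tied to the scikit-learn version recorded in the JSON payload.
_SVC_ATTRS = [
    "support_",
    "support_vectors_",
    "_n_support",
    "_dual_coef_",
    "_intercept_",
    "_probA",
    "_probB",
    "_num_iter",
    "classes_",
    "class_weight_",
    "_gamma",
    "shape_fit_",
    "fit_status_",
    "_sparse",
    "n_features_in_",
]


def _svc_to_dict(svc: SVC) -> dict:
    import sklearn

    payload: dict = {"params": svc.get_params(), "sklearn_version": sklearn.__version__}
    attrs = {}
    for name in _SVC_ATTRS:
        if not hasattr(svc, name):
            continue
        try:
            value = getattr(svc, name)
        except AttributeError:  # properties on unfitted aspects
            continue
        if isinstance(value, np.ndarray):
            attrs[name] = {"__ndarray__": value.tolist(), "dtype": str(value.dtype)}
        elif isinstance(value, (np.integer, np.floating)):
            attrs[name] = value.item()
        else:
            attrs[name] = value
    payload["attrs"] = attrs
    return payload


def _svc_from_dict(payload: dict) -> SVC:
    svc = SVC(**payload["params"])
    for name, value in payload["attrs"].items():
        if isinstance(value, dict) and "__ndarray__" in value:
            value = np.asarray(value["__ndarray__"], dtype=value["dtype"])
        try:
            setattr(svc, name, value)
        except AttributeError:
            continue  # read-only property backed by a stored private attr
    return svc


@dataclass
class ClassifierModel:
    """A trained subgroup classifier plus imputation statistics and thresholds."""

    model_kind: str  # "full_450k" or "signature"
    loci: list[str]
    svc: SVC = field(repr=False)
    classes: list[str]
    feature_means: np.ndarray = field(repr=False)
    covariance: np.ndarray | None = field(repr=False, default=None)
    medians: np.ndarray | None = field(repr=False, default=None)
    max_missing_loci: int = DEFAULT_MAX_MISSING
    probability_threshold: float = DEFAULT_PROBABILITY_THRESHOLD
    class_conditional: dict | None = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not 0.0 < self.probability_threshold < 1.0:
            raise ValueError("probability_threshold must be in (0, 1)")
        if self.max_missing_loci >= len(self.loci):
            raise ValueError("max_missing_loci must be smaller than the locus panel")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        with _quiet_svc():
            proba = self.svc.predict_proba(np.atleast_2d(X))
        # svc.classes_ ordering → model class ordering
        order = [list(self.svc.classes_).index(c) for c in self.classes]
        return proba[:, order]

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "msmimic-model/1",
            "model_kind": self.model_kind,
            "loci": self.loci,
            "classes": self.classes,
            "max_missing_loci": self.max_missing_loci,
            "probability_threshold": self.probability_threshold,
            "feature_means": self.feature_means.tolist(),
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "medians": None if self.medians is None else self.medians.tolist(),
            "svc": _svc_to_dict(self.svc),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            model_kind=payload["model_kind"],
            loci=payload["loci"],
            svc=_svc_from_dict(payload["svc"]),
            classes=payload["classes"],
            feature_means=np.asarray(payload["feature_means"]),
            covariance=(
                None if payload["covariance"] is None else np.asarray(payload["covariance"])
            ),
            medians=None if payload["medians"] is None else np.asarray(payload["medians"]),
            max_missing_loci=payload["max_missing_loci"],
            probability_threshold=payload["probability_threshold"],
        )


@dataclass
class ClassificationResult:
    """A single-sample call with its QC disposition."""

    sample_id: str
    call: str  # subgroup, "NC" or "FAIL"
    probabilities: dict[str, float] | None
    n_missing_loci: int
    qc_code: str  # PASS, BISULFITE_FAIL, LOCUS_QC_FAIL, BELOW_THRESHOLD
    probability: float | None

    def __post_init__(self) -> None:
        if self.call == "FAIL" and self.qc_code not in ("BISULFITE_FAIL", "LOCUS_QC_FAIL"):
            raise ValueError("FAIL requires a QC failure code")
        if (self.call == "NC") != (self.qc_code == "BELOW_THRESHOLD"):
            raise ValueError("NC if and only if BELOW_THRESHOLD")
        if self.call != "FAIL" and self.probabilities is None:
            raise ValueError("non-FAIL results must carry probabilities")


# ---------------------------------------------------------------------------
# Training


def train_models(
    training_beta: BetaMatrix,
    labels: pd.Series | Sequence[str],
    signature: SignatureDefinition,
    seed: int = 0,
    n_top: int = 10000,
    ridge: float = 1e-3,
    classes: Sequence[str] | None = None,
) -> tuple[ClassifierModel, ClassifierModel]:
    """Train the genome-scale and minimal-signature SVM models.

    Both use a linear kernel with one-vs-one decision and pairwise-coupled
    probability calibration.  The signature model additionally stores the
    mean and ridge-regularized covariance of logit₂-transformed training
    β-values for EM imputation; the genome-scale model stores per-locus
    medians and imputes by median instead.
    """
    y = pd.Series(list(labels), index=training_beta.sample_ids)
    class_list = sorted(y.unique(), key=str) if classes is None else list(classes)
    missing_classes = set(class_list) - set(y.unique())
    if missing_classes:
        raise ValueError(f"classes absent from training labels: {sorted(missing_classes)}")
    if len(class_list) < 2:
        raise ValueError("need at least two classes")
    absent = [l for l in signature.locus_ids if l not in training_beta.values.columns]
    if absent:
        raise ValueError(f"signature loci absent from training matrix: {absent[:5]}")

    filled = training_beta.fill_median()

    top = filled.top_variable_loci(n_top)
    X_full = filled.values.loc[:, top].to_numpy()
    with _quiet_svc():
        svc_full = SVC(kernel="linear", C=1.0, probability=True, random_state=seed)
        svc_full.fit(X_full, y.to_numpy())
    full_model = ClassifierModel(
        model_kind="full_450k",
        loci=top,
        svc=svc_full,
        classes=class_list,
        feature_means=X_full.mean(axis=0),
        medians=np.median(X_full, axis=0),
    )

    sig_loci = signature.locus_ids
    X_sig = filled.values.loc[:, sig_loci].to_numpy()
    with _quiet_svc():
        svc_sig = SVC(kernel="linear", C=1.0, probability=True, random_state=seed)
        svc_sig.fit(X_sig, y.to_numpy())
    Z = _logit2(X_sig)
    cov = np.cov(Z, rowvar=False) + ridge * np.eye(len(sig_loci))
    by_class = {}
    for c in class_list:
        Zc = Z[(y == c).to_numpy()]
        by_class[c] = {
            "mean": Zc.mean(axis=0).tolist(),
            "cov": (np.cov(Zc, rowvar=False) + ridge * np.eye(len(sig_loci))).tolist(),
        }
    sig_model = ClassifierModel(
        model_kind="signature",
        loci=sig_loci,
        svc=svc_sig,
        classes=class_list,
        feature_means=Z.mean(axis=0),
        covariance=cov,
        class_conditional=by_class,
    )
    return full_model, sig_model


# ---------------------------------------------------------------------------
# EM imputation


def impute_missing_em(
    x: np.ndarray | pd.Series,
    model: ClassifierModel,
    max_iter: int = 200,
    tol: float = 1e-10,
    class_label: str | None = None,
) -> np.ndarray:
    """Impute missing signature loci by expectation maximisation.

    Missing coordinates of the logit₂-transformed vector are iteratively
    replaced by their conditional expectation under the multivariate-normal
    training model (Gauss–Seidel sweeps on the precision matrix, which
    converge to the joint Gaussian conditional mean).  Observed entries are
    returned untouched; imputed entries are back-transformed into [0, 1].

    The default model is pooled over classes; pass ``class_label`` to use
    the class-conditional Gaussian instead (when the model stores one).
    """
    if isinstance(x, pd.Series):
        x = x.reindex(model.loci).to_numpy(dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    if x.shape != (len(model.loci),):
        raise ValueError(
            f"vector length {x.shape} does not match signature size {len(model.loci)}"
        )
    miss = np.isnan(x)
    n_missing = int(miss.sum())
    if n_missing == 0:
        return x.copy()
    if n_missing > model.max_missing_loci:
        raise LocusQCError(
            f"{n_missing} missing loci exceed the tolerated maximum "
            f"{model.max_missing_loci}"
        )
    if model.covariance is None:
        # Genome-scale model: median imputation.
        out = x.copy()
        out[miss] = model.medians[miss]
        return out

    if class_label is not None:
        if not model.class_conditional or class_label not in model.class_conditional:
            raise ValueError(f"no class-conditional statistics for {class_label!r}")
        cc = model.class_conditional[class_label]
        mu = np.asarray(cc["mean"])
        Lam = np.linalg.inv(np.asarray(cc["cov"]))
    else:
        mu = model.feature_means
        Lam = np.linalg.inv(model.covariance)
    z = np.empty_like(x)
    z[~miss] = _logit2(x[~miss])
    z[miss] = mu[miss]  # E-step initialization at the marginal mean

    m_idx = np.flatnonzero(miss)
    o_idx = np.flatnonzero(~miss)
    rhs = -Lam[np.ix_(m_idx, o_idx)] @ (z[o_idx] - mu[o_idx])
    Lmm = Lam[np.ix_(m_idx, m_idx)]
    w = z[m_idx] - mu[m_idx]
    for _ in range(max_iter):
        w_old = w.copy()
        for a in range(len(m_idx)):  # Gauss–Seidel sweep
            r = rhs[a] - Lmm[a] @ w + Lmm[a, a] * w[a]
            w[a] = r / Lmm[a, a]
        if np.max(np.abs(w - w_old)) < tol:
            break
    z[m_idx] = mu[m_idx] + w

    out = x.copy()
    out[m_idx] = _inv_logit2(z[m_idx])
    return out


# ---------------------------------------------------------------------------
# Threshold calibration


def calibrate_missing_threshold(
    model: ClassifierModel,
    validation_beta: BetaMatrix,
    n_boot: int = 10000,
    tolerance: float = 0.99,
    seed: int = 0,
) -> int:
    """Bootstrap the maximum tolerable number of missing signature loci.

    For each mask size j, bootstrap-resampled validation samples have j
    random loci masked, imputed and classified; the threshold is the largest
    j whose agreement with the complete-data calls stays at or above
    ``tolerance`` (agreement curve monotonized by a running minimum first).
    ``n_boot`` is the total number of bootstrap classifications, spread
    evenly over mask sizes.
    """
    if validation_beta.n_samples == 0:
        raise ValueError("empty validation set")
    p = len(model.loci)
    X = validation_beta.fill_median().subset_loci(model.loci).to_numpy()
    complete_calls = np.asarray(model.classes)[
        model.predict_proba(X).argmax(axis=1)
    ]
    rng = np.random.default_rng(seed)
    relaxed = _with_max_missing(model, p - 1)
    per_j = max(1, n_boot // p)
    agreement = np.ones(p)
    for j in range(1, p):
        hits = 0
        for _ in range(per_j):
            i = int(rng.integers(validation_beta.n_samples))
            vec = X[i].copy()
            vec[rng.choice(p, size=j, replace=False)] = np.nan
            filled = impute_missing_em(vec, relaxed)
            call = model.classes[int(model.predict_proba(filled).argmax())]
            hits += call == complete_calls[i]
        agreement[j] = hits / per_j
    smoothed = np.minimum.accumulate(agreement)
    ok = np.flatnonzero(smoothed >= tolerance)
    return int(ok.max()) if ok.size else 0


def _with_max_missing(model: ClassifierModel, max_missing: int) -> ClassifierModel:
    return ClassifierModel(
        model_kind=model.model_kind,
        loci=model.loci,
        svc=model.svc,
        classes=model.classes,
        feature_means=model.feature_means,
        covariance=model.covariance,
        medians=model.medians,
        max_missing_loci=max_missing,
        probability_threshold=model.probability_threshold,
    )


def calibrate_probability_threshold(
    probabilities: np.ndarray | pd.DataFrame,
    truth: Sequence[str],
    classes: Sequence[str] | None = None,
    grid_step: float = 0.01,
    tolerance: float = 0.0,
) -> float:
    """Smallest grid threshold whose retained calls are (near-)error-free.

    Scans t = 0, grid_step, …, 1; among samples whose maximum class
    probability is ≥ t, the misclassification rate must be ≤ ``tolerance``.
    Raises if every grid point leaves no sample retained or too many errors.
    """
    if isinstance(probabilities, pd.DataFrame):
        classes = list(probabilities.columns)
        P = probabilities.to_numpy()
    else:
        P = np.asarray(probabilities, dtype=float)
        if classes is None:
            raise ValueError("classes required with an array of probabilities")
    truth_arr = np.asarray(list(truth))
    pred = np.asarray(list(classes))[P.argmax(axis=1)]
    maxp = P.max(axis=1)
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    for t in grid:
        kept = maxp >= t
        if not kept.any():
            break
        if (pred[kept] != truth_arr[kept]).mean() <= tolerance:
            return float(t)
    raise ValueError("no grid threshold satisfies the error tolerance with samples retained")


# ---------------------------------------------------------------------------
# Single-sample classification


def classify_sample(
    x,
    model: ClassifierModel,
    sample_id: str | None = None,
    conversion_cutoff: float = 0.1,
) -> ClassificationResult:
    """Classify one sample through the full QC cascade.

    ``x`` may be a partial β vector aligned to the signature (array or
    Series indexed by locus) or an :class:`~msmimic.assay.AssayRecord`.  The
    cascade, in order: bisulfite-conversion control (FAIL/BISULFITE_FAIL),
    missing-locus count vs the tolerated maximum (FAIL/LOCUS_QC_FAIL), EM
    imputation, probability threshold (NC/BELOW_THRESHOLD), else the argmax
    subgroup.  Deterministic given model and input.
    """
    from .assay import AssayRecord, conversion_control_check

    if isinstance(x, AssayRecord):
        sample_id = sample_id or x.sample_id
        if not conversion_control_check(x, cutoff=conversion_cutoff):
            return ClassificationResult(
                sample_id=sample_id,
                call="FAIL",
                probabilities=None,
                n_missing_loci=x.n_failed(model.loci),
                qc_code="BISULFITE_FAIL",
                probability=None,
            )
        vec = x.beta_vector(model.loci)
    elif isinstance(x, pd.Series):
        vec = x.reindex(model.loci).to_numpy(dtype=float)
    else:
        vec = np.asarray(x, dtype=float)
        if vec.shape != (len(model.loci),):
            raise ValueError("input vector is not aligned to the signature loci")
    sample_id = sample_id or "sample"

    n_missing = int(np.isnan(vec).sum())
    if n_missing > model.max_missing_loci:
        return ClassificationResult(
            sample_id=sample_id,
            call="FAIL",
            probabilities=None,
            n_missing_loci=n_missing,
            qc_code="LOCUS_QC_FAIL",
            probability=None,
        )
    filled = impute_missing_em(vec, model)
    proba = model.predict_proba(filled)[0]
    probs = {c: float(p) for c, p in zip(model.classes, proba)}
    best = int(proba.argmax())
    if proba[best] < model.probability_threshold:
        return ClassificationResult(
            sample_id=sample_id,
            call="NC",
            probabilities=probs,
            n_missing_loci=n_missing,
            qc_code="BELOW_THRESHOLD",
            probability=float(proba[best]),
        )
    return ClassificationResult(
        sample_id=sample_id,
        call=model.classes[best],
        probabilities=probs,
        n_missing_loci=n_missing,
        qc_code="PASS",
        probability=float(proba[best]),
    )


def classify_cohort(
    inputs,
    model: ClassifierModel,
    conversion_cutoff: float = 0.1,
) -> pd.DataFrame:
    """Classify many samples; accepts a BetaMatrix or a list of AssayRecords.

    Returns a calls table (sample_id, call, probability, n_missing, qc_code).
    """
    results = []
    if isinstance(inputs, BetaMatrix):
        for sid in inputs.sample_ids:
            res = classify_sample(
                inputs.values.loc[sid], model, sample_id=sid,
                conversion_cutoff=conversion_cutoff,
            )
            results.append(res)
    else:
        for rec in inputs:
            results.append(
                classify_sample(rec, model, conversion_cutoff=conversion_cutoff)
            )
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "call": [r.call for r in results],
            "probability": [np.nan if r.probability is None else r.probability for r in results],
            "n_missing": [r.n_missing_loci for r in results],
            "qc_code": [r.qc_code for r in results],
        }
    )
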