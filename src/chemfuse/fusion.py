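"""Low-, mid- and high-level fusion of IMS and GC-QEPAS data.

LLDF concatenates the preprocessed blocks (autoscaled IMS | SNV IR spectra |
raw retention time) into one matrix and trains a one-class SVM on the target
analyte.  MLDF first compresses each preprocessed block by PCA, keeping the
smallest number of components reaching 99% cumulative explained variance,
and concatenates the scores with the raw retention times before the one-class
SVM.  HLDF fuses at the decision level: a one-class verdict on the raw IMS
plasmagram and a SIMCA verdict on the GC-QEPAS channel are combined by a
safety-oriented rule.

The one-class SVM is consumed from scikit-learn with the canonical parameter
set (linear kernel, coef0=0, degree=3, gamma="auto", tol=1e-3, cache 200,
no iteration cap); the classification rule replaces the native sign test
with an analyte-specific decision threshold tau: positive iff f(x) >= tau.
SIMCA is implemented here from scratch: a per-class PCA, with new samples
accepted when both the Euclidean and the per-component-standardized
(Mahalanobis, diagonal in score space) distances to the class centroid stay
below their limits (defaults 5.5 and 6.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import OneClassSVM

from .core import FeatureBlock, LabelledDataset, Sample, ValidationError, assemble_dataset
from .positioning import (
    DEFAULT_CUTOFF_M,
    DEFAULT_TIME_WINDOW_S,
    GateDecision,
    GateRefusalError,
    require_fusable,
)
from .preprocess import autoscale_apply, autoscale_fit, extract_rt, snv_block

__all__ = [
    "lldf_assemble",
    "PCABlockModel",
    "pca_blocks_fit",
    "pca_blocks_transform",
    "mldf_assemble",
    "OneClassModel",
    "ocsvm_fit",
    "ocsvm_classify",
    "SimcaClassModel",
    "simca_fit",
    "simca_classify",
    "hldf_combine",
    "FusionVerdict",
    "LLDFPipeline",
    "MLDFPipeline",
    "IMSOneClassPipeline",
    "SimcaPipeline",
    "HLDFPipeline",
    "build_fusion_dataset",
    "fuse",
    "save_pipeline",
    "load_pipeline",
]

#: Canonical one-class SVM hyperparameters (kernel choice exposed separately).
OCSVM_DEFAULTS = {
    "cache_size": 200,
    "coef0": 0.0,
    "degree": 3,
    "gamma": "auto",
    "max_iter": -1,
    "tol": 0.001,
}

#: Upper bound on the fraction of training samples rejected by the fitted
#: boundary.  Kept small: in a safety application the boundary must enclose
#: essentially all confirmed target samples so that the decision-threshold
#: override, not the nu-rejection, governs false negatives.
DEFAULT_NU = 0.02

EV_CRITERION = 0.99  # cumulative explained-variance criterion


def _matrix(features) -> np.ndarray:
    if isinstance(features, FeatureBlock):
        return features.matrix
    return np.asarray(features, dtype=float)


# ---------------------------------------------------------------------------
# Block assembly
# ---------------------------------------------------------------------------

def _require_step(block: FeatureBlock, step_prefix: str):
    if not any(p.startswith(step_prefix) for p in block.provenance):
        raise ValidationError(
            f"block {block.name!r} lacks required preprocessing step "
            f"{step_prefix!r} in its provenance {block.provenance}"
        )


def lldf_assemble(ims_block: FeatureBlock, qepas_block: FeatureBlock, rt) -> FeatureBlock:
    """Column-wise concatenation [autoscaled IMS | SNV spectra | raw RT].

    Provenance is enforced: the IMS block must have been autoscaled and the
    spectra SNV-normalized; retention times enter as one raw trailing column.
    """
    _require_step(ims_block, "autoscale")
    _require_step(qepas_block, "snv")
    rt = np.asarray(rt, dtype=float).reshape(-1, 1)
    if not (ims_block.n_samples == qepas_block.n_samples == rt.shape[0]):
        raise ValidationError(
            f"row counts differ: ims={ims_block.n_samples}, "
            f"qepas={qepas_block.n_samples}, rt={rt.shape[0]}"
        )
    matrix = np.hstack([ims_block.matrix, qepas_block.matrix, rt])
    provenance = (
        tuple(f"ims:{p}" for p in ims_block.provenance)
        + tuple(f"qepas:{p}" for p in qepas_block.provenance)
        + ("rt:raw", "concat(ims|qepas|rt)")
    )
    return FeatureBlock("lldf", matrix, provenance=provenance)


@dataclass(frozen=True)
class _BlockPCA:
    mean: np.ndarray
    components: np.ndarray  # n_retained x n_variables, orthonormal rows
    explained_variance_ratio: np.ndarray
    n_retained: int
    # training-score standard deviations; when set, scores are standardized
    # to unit variance (soft block scaling) so no single block or component
    # dominates the concatenated feature vector
    score_sds: np.ndarray = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.mean.size:
            raise ValidationError(
                f"PCA model expects {self.mean.size} variables, got {X.shape[1]}"
            )
        scores = (X - self.mean) @ self.components.T
        if self.score_sds is not None:
            scores = scores / self.score_sds
        return scores


@dataclass(frozen=True)
class PCABlockModel:
    """Per-block PCA models retaining >= ``ev`` cumulative explained variance."""

    blocks: dict
    ev: float


def _fit_pca(
    X: np.ndarray, ev: float, n_components: int = None, scale_scores: bool = False
) -> _BlockPCA:
    est = PCA(svd_solver="full")
    est.fit(X)
    evr = est.explained_variance_ratio_
    if n_components is None:
        cum = np.cumsum(evr)
        m = int(np.searchsorted(cum, ev - 1e-12) + 1)
    else:
        if n_components > evr.size:
            raise ValidationError(
                f"requested {n_components} components but only {evr.size} available"
            )
        m = int(n_components)
    score_sds = None
    if scale_scores:
        scores = (X - est.mean_) @ est.components_[:m].T
        total_var = float(scores.var(axis=0, ddof=1).sum())
        if not total_var > 0:
            raise ValidationError("retained components must have score variance > 0")
        # one scalar per block (not per component): dividing by the square
        # root of the total retained variance equalizes the blocks while
        # preserving the relative weights of the components within a block;
        # per-component whitening would inflate minor noise components
        score_sds = np.full(m, np.sqrt(total_var))
    return _BlockPCA(
        mean=est.mean_,
        components=est.components_[:m],
        explained_variance_ratio=evr,
        n_retained=m,
        score_sds=score_sds,
    )


def pca_blocks_fit(
    blocks, ev: float = EV_CRITERION, scale_scores: bool = True
) -> PCABlockModel:
    """Fit one PCA per named (already preprocessed, training-only) block.

    Each block's scores are scaled to unit total training variance by
    default (block scaling): retained components of a high-dimensional
    block would otherwise carry that block's full variance into the
    concatenated mid-level feature vector and swamp the other blocks.
    """
    if not 0 < ev <= 1:
        raise ValidationError("ev must be in (0, 1]")
    fitted = {}
    for name, block in blocks.items():
        X = _matrix(block)
        if X.shape[0] < 2:
            raise ValidationError(f"block {name!r}: PCA needs at least 2 samples")
        fitted[name] = _fit_pca(X, ev, scale_scores=scale_scores)
    return PCABlockModel(blocks=fitted, ev=ev)


def pca_blocks_transform(model: PCABlockModel, blocks) -> dict:
    return {name: model.blocks[name].transform(_matrix(b)) for name, b in blocks.items()}


def mldf_assemble(
    ims_block: FeatureBlock,
    qepas_block: FeatureBlock,
    rt,
    pca: PCABlockModel,
) -> FeatureBlock:
    """Concatenate per-block PCA scores with the raw retention times."""
    _require_step(ims_block, "autoscale")
    _require_step(qepas_block, "snv")
    rt = np.asarray(rt, dtype=float).reshape(-1, 1)
    scores = pca_blocks_transform(pca, {"ims": ims_block, "qepas": qepas_block})
    if not (scores["ims"].shape[0] == scores["qepas"].shape[0] == rt.shape[0]):
        raise ValidationError("row counts differ between blocks and rt")
    matrix = np.hstack([scores["ims"], scores["qepas"], rt])
    provenance = (
        f"ims:pca(m={pca.blocks['ims'].n_retained},ev>={pca.ev})",
        f"qepas:pca(m={pca.blocks['qepas'].n_retained},ev>={pca.ev})",
        "rt:raw",
        "concat(scores|rt)",
    )
    return FeatureBlock("mldf", matrix, provenance=provenance)


# ---------------------------------------------------------------------------
# One-class SVM with decision-threshold override
# ---------------------------------------------------------------------------

@dataclass
class OneClassModel:
    """Fitted one-class boundary plus the decision threshold tau.

    ``training_decisions`` stores the decision-function values of the
    training rows so that re-applying the model to its own training data is
    checkable exactly.
    """

    estimator: OneClassSVM
    threshold: float
    kernel: str
    nu: float
    params: dict
    n_features: int
    training_decisions: np.ndarray


KERNELS = ("linear", "poly", "sigmoid", "rbf")


def ocsvm_fit(
    features,
    kernel: str = "linear",
    nu: float = DEFAULT_NU,
    threshold: float = 0.0,
    **param_overrides,
) -> OneClassModel:
    """Train the one-class SVM on target-class rows only."""
    X = _matrix(features)
    if kernel not in KERNELS:
        raise ValidationError(f"kernel must be one of {KERNELS}, got {kernel!r}")
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("one-class training needs a 2-D matrix with >= 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValidationError("training features contain non-finite values")
    params = dict(OCSVM_DEFAULTS, **param_overrides)
    est = OneClassSVM(kernel=kernel, nu=nu, **params)
    est.fit(X)
    return OneClassModel(
        estimator=est,
        threshold=float(threshold),
        kernel=kernel,
        nu=float(nu),
        params=params,
        n_features=X.shape[1],
        training_decisions=est.decision_function(X),
    )


def ocsvm_classify(model: OneClassModel, features):
    """(decision value f, inlier) with the threshold rule f >= tau.

    Accepts a single sample (1-D) or a batch (2-D); returns scalars or
    arrays accordingly.
    """
    X = np.asarray(_matrix(features), dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"feature width {X.shape[1]} != training width {model.n_features}"
        )
    f = model.estimator.decision_function(X)
    inlier = f >= model.threshold
    if single:
        return float(f[0]), bool(inlier[0])
    return f, inlier


# ---------------------------------------------------------------------------
# SIMCA (from scratch)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimcaClassModel:
    """Per-class PCA model with score-space distance limits.

    The centroid is the mean training score vector -- the origin by PCA
    construction, stored explicitly.  The Mahalanobis distance uses the
    per-component training-score standard deviations, which is the exact
    (diagonal) covariance in PCA score space.
    """

    label: str
    mean: np.ndarray
    loadings: np.ndarray          # n_components x n_variables
    score_sds: np.ndarray
    centroid: np.ndarray
    explained_variance_ratio: np.ndarray
    dE_max: float = 5.5
    dM_max: float = 6.5

    def __post_init__(self):
        if not (self.dE_max > 0 and self.dM_max > 0):
            raise ValidationError("distance limits must be > 0")
        if np.any(self.score_sds <= 0):
            raise ValidationError("per-component score sds must be > 0")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def simca_fit(
    data,
    class_label: str = None,
    block_names=("qepas", "rt"),
    n_components: int = None,
    ev: float = EV_CRITERION,
    dE_max: float = 5.5,
    dM_max: float = 6.5,
) -> SimcaClassModel:
    """Fit the class PCA sub-model on (preprocessed) target-class data.

    ``data`` is either a plain matrix of class rows, or a
    :class:`LabelledDataset`, in which case rows with ``label ==
    class_label`` are selected and the named blocks concatenated.
    """
    if isinstance(data, LabelledDataset):
        if class_label is None:
            raise ValidationError("class_label required with a LabelledDataset")
        idx = np.flatnonzero(data.labels.astype(str) == class_label)
        X = np.hstack([data.blocks[b].matrix for b in block_names])[idx]
    else:
        X = _matrix(data)
    if X.shape[0] < 3:
        raise ValidationError("SIMCA needs at least 3 class samples")
    max_comps = min(X.shape[0] - 1, X.shape[1])
    if n_components is not None and n_components > max_comps:
        raise ValidationError(
            f"requested {n_components} components but only {max_comps} supportable"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    total = var.sum()
    if total <= 0:
        raise ValidationError("class data has zero variance; SIMCA undefined")
    evr = var / total
    if n_components is None:
        cum = np.cumsum(evr)
        m = int(np.searchsorted(cum, ev - 1e-12) + 1)
        m = min(m, max_comps)
    else:
        m = int(n_components)
    scores = U[:, :m] * s[:m]
    sds = scores.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        raise ValidationError(
            "a retained component has zero score variance; reduce n_components"
        )
    return SimcaClassModel(
        label=class_label if class_label is not None else "",
        mean=mean,
        loadings=Vt[:m],
        score_sds=sds,
        centroid=np.zeros(m),
        explained_variance_ratio=evr,
        dE_max=dE_max,
        dM_max=dM_max,
    )


def simca_classify(model: SimcaClassModel, features):
    """(dE, dM, positive): score-space distances to the class centroid.

    positive iff dE <= dE_max and dM <= dM_max (closed limits).  Accepts a
    single sample or a batch.
    """
    X = np.asarray(_matrix(features), dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.mean.size:
        raise ValidationError(
            f"feature width {X.shape[1]} != training width {model.mean.size}"
        )
    t = (X - model.mean) @ model.loadings.T - model.centroid
    dE = np.sqrt(np.sum(t**2, axis=1))
    dM = np.sqrt(np.sum((t / model.score_sds) ** 2, axis=1))
    positive = (dE <= model.dE_max) & (dM <= model.dM_max)
    if single:
        return float(dE[0]), float(dM[0]), bool(positive[0])
    return dE, dM, positive


# ---------------------------------------------------------------------------
# Decision-level combination and verdicts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FusionVerdict:
    """Per-analyte fusion decision with the evidence that produced it."""

    analyte: str
    level: str
    positive: bool
    evidence: dict
    gate: GateDecision = None


def hldf_combine(ims_verdict, gc_verdict, rule: str = "any", analyte: str = "") -> FusionVerdict:
    """Combine the per-sensor verdicts at the decision level.

    ``ims_verdict`` is ``(f, inlier)`` from :func:`ocsvm_classify`;
    ``gc_verdict`` is ``(dE, dM, positive)`` from :func:`simca_classify`.
    ``rule="any"`` (default, safety alarm) flags when either sensor is
    positive; ``rule="all"`` requires confirmation by both.
    """
    if rule not in ("any", "all"):
        raise ValidationError(f"rule must be 'any' or 'all', got {rule!r}")
    if ims_verdict is None or gc_verdict is None:
        raise ValidationError("both sensor verdicts are required")
    f, ims_positive = ims_verdict
    dE, dM, gc_positive = gc_verdict
    combine = any if rule == "any" else all
    positive = combine([bool(ims_positive), bool(gc_positive)])
    return FusionVerdict(
        analyte=analyte,
        level="HLDF",
        positive=positive,
        evidence={
            "ims_decision_function": f,
            "ims_positive": bool(ims_positive),
            "gc_dE": dE,
            "gc_dM": dM,
            "gc_positive": bool(gc_positive),
            "rule": rule,
        },
    )


# ---------------------------------------------------------------------------
# Trained pipelines (fit on a training corpus, apply to new data)
# ---------------------------------------------------------------------------

def build_fusion_dataset(samples) -> LabelledDataset:
    """Assemble the standard three blocks (ims, qepas, rt) from samples."""
    return assemble_dataset(
        samples,
        {
            "ims": "ims",
            "qepas": "spectrum",
            "rt": lambda s: [extract_rt(s.reading("GCQEPAS").payload.chromatogram)],
        },
    )


def _target_rows(dataset: LabelledDataset, analyte: str) -> LabelledDataset:
    idx = np.flatnonzero(dataset.labels.astype(str) == analyte)
    if idx.size < 2:
        raise ValidationError(
            f"training corpus holds {idx.size} rows labelled {analyte!r}; need >= 2"
        )
    return dataset.subset(idx)


class LLDFPipeline:
    """Low-level fusion: preprocess, concatenate, one-class SVM."""

    level = "LLDF"

    def __init__(self, analyte: str, threshold: float = 0.0,
                 kernel: str = "linear", nu: float = DEFAULT_NU):
        self.analyte = analyte
        self.threshold = threshold
        self.kernel = kernel
        self.nu = nu
        self.autoscale_ = None
        self.model_ = None

    def fit(self, dataset: LabelledDataset):
        train = _target_rows(dataset, self.analyte)
        self.autoscale_ = autoscale_fit(train.blocks["ims"])
        features = self._features(train)
        self.model_ = ocsvm_fit(
            features, kernel=self.kernel, nu=self.nu, threshold=self.threshold
        )
        return self

    def _features(self, dataset: LabelledDataset) -> FeatureBlock:
        ims = autoscale_apply(dataset.blocks["ims"], self.autoscale_)
        qepas = snv_block(dataset.blocks["qepas"])
        return lldf_assemble(ims, qepas, dataset.blocks["rt"].matrix[:, 0])

    def decision(self, dataset: LabelledDataset) -> np.ndarray:
        if self.model_ is None:
            raise ValidationError("pipeline is not fitted")
        f, _ = ocsvm_classify(self.model_, self._features(dataset))
        return f

    def predict(self, dataset: LabelledDataset):
        f = self.decision(dataset)
        return f >= self.model_.threshold, {"decision_function": f}


class MLDFPipeline(LLDFPipeline):
    """Mid-level fusion: per-block PCA scores + RT, one-class SVM."""

    level = "MLDF"

    def __init__(self, analyte: str, threshold: float = 0.0, kernel: str = "linear",
                 nu: float = DEFAULT_NU, ev: float = EV_CRITERION):
        super().__init__(analyte, threshold=threshold, kernel=kernel, nu=nu)
        self.ev = ev
        self.pca_ = None

    def fit(self, dataset: LabelledDataset):
        train = _target_rows(dataset, self.analyte)
        self.autoscale_ = autoscale_fit(train.blocks["ims"])
        ims = autoscale_apply(train.blocks["ims"], self.autoscale_)
        qepas = snv_block(train.blocks["qepas"])
        self.pca_ = pca_blocks_fit({"ims": ims, "qepas": qepas}, ev=self.ev)
        features = self._features(train)
        self.model_ = ocsvm_fit(
            features, kernel=self.kernel, nu=self.nu, threshold=self.threshold
        )
        return self

    def _features(self, dataset: LabelledDataset) -> FeatureBlock:
        ims = autoscale_apply(dataset.blocks["ims"], self.autoscale_)
        qepas = snv_block(dataset.blocks["qepas"])
        return mldf_assemble(ims, qepas, dataset.blocks["rt"].matrix[:, 0], self.pca_)


class IMSOneClassPipeline:
    """HLDF IMS branch: one-class SVM on plasmagram vectors.

    Raw currents by default: the plasmagram cloud then sits away from the
    origin, which a linear one-class boundary needs; column autoscaling is
    available but centres the training block exactly and degenerates the
    linear decision function.
    """

    level = "HLDF-IMS"

    def __init__(self, analyte: str, threshold: float = 0.0, kernel: str = "linear",
                 nu: float = DEFAULT_NU, autoscale: bool = False):
        self.analyte = analyte
        self.threshold = threshold
        self.kernel = kernel
        self.nu = nu
        self.autoscale = autoscale
        self.autoscale_ = None
        self.model_ = None

    def fit(self, dataset: LabelledDataset):
        train = _target_rows(dataset, self.analyte)
        block = train.blocks["ims"]
        if self.autoscale:
            self.autoscale_ = autoscale_fit(block)
            block = autoscale_apply(block, self.autoscale_)
        self.model_ = ocsvm_fit(
            block, kernel=self.kernel, nu=self.nu, threshold=self.threshold
        )
        return self

    def _features(self, dataset: LabelledDataset):
        block = dataset.blocks["ims"]
        if self.autoscale_ is not None:
            block = autoscale_apply(block, self.autoscale_)
        return block

    def decision(self, dataset: LabelledDataset) -> np.ndarray:
        if self.model_ is None:
            raise ValidationError("pipeline is not fitted")
        f, _ = ocsvm_classify(self.model_, self._features(dataset))
        return f

    def predict(self, dataset: LabelledDataset):
        f = self.decision(dataset)
        return f >= self.model_.threshold, {"decision_function": f}


class SimcaPipeline:
    """HLDF GC-QEPAS branch: SIMCA on [SNV spectra | raw RT]."""

    level = "HLDF-GC"

    def __init__(self, analyte: str, dE_max: float = 5.5, dM_max: float = 6.5,
                 ev: float = EV_CRITERION, n_components: int = None):
        self.analyte = analyte
        self.dE_max = dE_max
        self.dM_max = dM_max
        self.ev = ev
        self.n_components = n_components
        self.model_ = None

    def _features(self, dataset: LabelledDataset) -> np.ndarray:
        qepas = snv_block(dataset.blocks["qepas"])
        rt = dataset.blocks["rt"].matrix
        return np.hstack([qepas.matrix, rt])

    def fit(self, dataset: LabelledDataset):
        train = _target_rows(dataset, self.analyte)
        self.model_ = simca_fit(
            self._features(train),
            class_label=self.analyte,
            n_components=self.n_components,
            ev=self.ev,
            dE_max=self.dE_max,
            dM_max=self.dM_max,
        )
        return self

    def predict(self, dataset: LabelledDataset):
        if self.model_ is None:
            raise ValidationError("pipeline is not fitted")
        dE, dM, positive = simca_classify(self.model_, self._features(dataset))
        return positive, {"dE": dE, "dM": dM}


class HLDFPipeline:
    """Decision-level fusion of the IMS and GC-QEPAS branch verdicts."""

    level = "HLDF"

    def __init__(self, analyte: str, rule: str = "any",
                 ims: IMSOneClassPipeline = None, gc: SimcaPipeline = None):
        if rule not in ("any", "all"):
            raise ValidationError(f"rule must be 'any' or 'all', got {rule!r}")
        self.analyte = analyte
        self.rule = rule
        self.ims = ims or IMSOneClassPipeline(analyte)
        self.gc = gc or SimcaPipeline(analyte)

    def fit(self, dataset: LabelledDataset):
        self.ims.fit(dataset)
        self.gc.fit(dataset)
        return self

    def predict(self, dataset: LabelledDataset):
        ims_pos, ims_ev = self.ims.predict(dataset)
        gc_pos, gc_ev = self.gc.predict(dataset)
        combine = np.logical_or if self.rule == "any" else np.logical_and
        positive = combine(ims_pos, gc_pos)
        evidence = {
            "ims_decision_function": ims_ev["decision_function"],
            "ims_positive": ims_pos,
            "gc_dE": gc_ev["dE"],
            "gc_dM": gc_ev["dM"],
            "gc_positive": gc_pos,
            "rule": self.rule,
        }
        return positive, evidence


# ---------------------------------------------------------------------------
# End-to-end fusion of a co-located reading pair
# ---------------------------------------------------------------------------

def fuse(
    ims_reading,
    gc_reading,
    pipeline,
    cutoff: float = DEFAULT_CUTOFF_M,
    mode: str = "per_axis",
    time_window_s: float = DEFAULT_TIME_WINDOW_S,
) -> FusionVerdict:
    """Run a fitted pipeline on one reading pair, behind the co-location gate.

    Raises :class:`GateRefusalError` (carrying the gate decision) when the
    readings are not co-located; no classification is computed in that case.
    """
    decision = require_fusable(
        ims_reading, gc_reading, cutoff=cutoff, mode=mode, time_window_s=time_window_s
    )
    if not decision.fused:
        raise GateRefusalError(decision)
    sample = Sample(readings=(ims_reading, gc_reading))
    dataset = build_fusion_dataset([sample])
    positive, evidence = pipeline.predict(dataset)
    evidence = {
        k: (v[0] if isinstance(v, np.ndarray) else v) for k, v in evidence.items()
    }
    return FusionVerdict(
        analyte=pipeline.analyte,
        level=pipeline.level,
        positive=bool(np.atleast_1d(positive)[0]),
        evidence=evidence,
        gate=decision,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_ARCHIVE_VERSION = 1


def save_pipeline(pipeline, path) -> None:
    """Persist a fitted pipeline (preprocessing stats, PCA loadings, SVM
    state, SIMCA models, thresholds) as one versioned archive."""
    joblib.dump({"format_version": _ARCHIVE_VERSION, "pipeline": pipeline}, path)


def load_pipeline(path):
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != _ARCHIVE_VERSION:
        raise ValidationError(f"unsupported pipeline archive version {version!r}")
    return payload["pipeline"]
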