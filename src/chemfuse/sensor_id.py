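"""Single-sensor identification baselines.

The IMS side identifies a compound when a sufficiently intense plasmagram
peak falls inside a multiplicative reduced-mobility window (default +-2%
around the library K0, 1 nA intensity floor).  The GC-QEPAS side screens by
a retention-time window (mu +- k*sigma) and confirms by Pearson correlation
of the SNV-normalized IR spectrum against a reference; the sequential
combination requires both.  A multiclass LDA on concatenated feature blocks
serves as the machine-learning comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .core import IRSpectrum, LabelledDataset, ValidationError
from .preprocess import snv

__all__ = [
    "RMLibraryEntry",
    "RTModel",
    "SpectralReference",
    "rm_identify",
    "rt_detect",
    "pearson_match",
    "LDAModel",
    "lda_fit",
    "lda_predict",
    "gcqepas_sequential_id",
    "rt_model_from_values",
    "reference_from_spectra",
]


@dataclass(frozen=True)
class RMLibraryEntry:
    """Library reduced mobility with its acceptance window.

    ``matched`` requires at least ``required_peaks`` detected peaks, each with
    intensity above ``min_intensity``, inside the analyte's K0 window(s)
    [K0*(1-tolerance), K0*(1+tolerance)].
    """

    analyte: str
    K0: float
    tolerance: float = 0.02
    min_intensity: float = 1.0
    required_peaks: int = 1

    def __post_init__(self):
        if not self.K0 > 0:
            raise ValidationError("K0 must be > 0")
        if not 0 < self.tolerance < 1:
            raise ValidationError("tolerance must be in (0, 1)")
        if self.required_peaks < 1:
            raise ValidationError("required_peaks must be >= 1")

    @property
    def window(self) -> tuple:
        return (self.K0 * (1.0 - self.tolerance), self.K0 * (1.0 + self.tolerance))

    def accepts(self, peak) -> bool:
        lo, hi = self.window
        return peak.intensity > self.min_intensity and lo <= peak.reduced_mobility <= hi


@dataclass(frozen=True)
class RTModel:
    """Retention-time acceptance window mu +- k*sigma (closed interval)."""

    analyte: str
    mu: float
    sigma: float
    k: float = 3.0

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValidationError("sigma must be > 0")
        if not self.k > 0:
            raise ValidationError("k must be > 0")


@dataclass(frozen=True)
class SpectralReference:
    """SNV-normalized reference spectrum with a correlation threshold."""

    analyte: str
    spectrum: IRSpectrum
    r_min: float = 0.95

    def __post_init__(self):
        if not -1.0 <= self.r_min <= 1.0:
            raise ValidationError("r_min must be in [-1, 1]")


def rm_identify(peaks, library) -> list:
    """Per-analyte reduced-mobility identification.

    Library entries are grouped by analyte; an analyte is matched when the
    number of distinct detected peaks falling in any of its windows (and above
    the intensity floor) reaches the analyte's required peak count.
    """
    library = list(library)
    if not library:
        raise ValidationError("reduced-mobility library must be nonempty")
    analytes = []
    for entry in library:
        if entry.analyte not in analytes:
            analytes.append(entry.analyte)
    results = []
    for analyte in analytes:
        entries = [e for e in library if e.analyte == analyte]
        required = max(e.required_peaks for e in entries)
        n_hits = sum(1 for p in peaks if any(e.accepts(p) for e in entries))
        results.append((analyte, n_hits >= required))
    return results


def rt_detect(rt: float, model: RTModel) -> bool:
    """True iff |rt - mu| <= k*sigma (closed on the boundary)."""
    return abs(rt - model.mu) <= model.k * model.sigma


def pearson_match(spectrum: IRSpectrum, ref: SpectralReference):
    """(r, matched) from Pearson correlation of SNV-normalized spectra.

    Both spectra are passed through SNV (idempotent), so the score is
    invariant to positive affine rescaling of either input.  The spectrum
    must already live on the reference grid; resample first otherwise.
    """
    if spectrum.wavelength != ref.spectrum.wavelength:
        raise ValidationError("spectrum and reference grids differ; resample first")
    a = snv(spectrum.signal)
    b = snv(ref.spectrum.signal)
    # both have zero mean and unit sample sd, so r is the scaled dot product
    r = float(a @ b / (a.size - 1))
    return r, r >= ref.r_min


def rt_model_from_values(analyte: str, rts, k: float = 3.0) -> RTModel:
    """Estimate an RT window from training retention times."""
    rts = np.asarray(rts, dtype=float)
    if rts.size < 2:
        raise ValidationError("need at least 2 retention times to fit an RT model")
    sigma = float(rts.std(ddof=1))
    if sigma <= 0:
        raise ValidationError("retention times are constant; sigma undefined")
    return RTModel(analyte=analyte, mu=float(rts.mean()), sigma=sigma, k=k)


def reference_from_spectra(analyte: str, spectra, r_min: float = 0.95) -> SpectralReference:
    """Class-mean of SNV spectra as the library reference."""
    spectra = list(spectra)
    if not spectra:
        raise ValidationError("need at least one spectrum")
    grid = spectra[0].wavelength
    rows = []
    for s in spectra:
        if s.wavelength != grid:
            raise ValidationError("reference spectra must share a grid")
        rows.append(snv(s.signal))
    return SpectralReference(
        analyte=analyte, spectrum=IRSpectrum(grid, np.mean(rows, axis=0)), r_min=r_min
    )


@dataclass(frozen=True)
class LDAModel:
    estimator: LinearDiscriminantAnalysis
    block_names: tuple
    n_features: int


def _concat_blocks(dataset: LabelledDataset, block_names) -> np.ndarray:
    missing = [b for b in block_names if b not in dataset.blocks]
    if missing:
        raise ValidationError(f"dataset lacks blocks {missing}")
    return np.hstack([dataset.blocks[b].matrix for b in block_names])


def lda_fit(dataset: LabelledDataset, block_names) -> LDAModel:
    """Multiclass linear discriminant baseline on concatenated blocks."""
    block_names = tuple(block_names)
    X = _concat_blocks(dataset, block_names)
    y = dataset.labels.astype(str)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("LDA needs at least 2 classes")
    if counts.min() < 2:
        raise ValidationError("every class needs at least 2 samples")
    est = LinearDiscriminantAnalysis(solver="svd")
    try:
        est.fit(X, y)
    except np.linalg.LinAlgError as e:
        raise ValidationError(
            "singular within-class scatter; reduce dimensionality (e.g. PCA) first"
        ) from e
    return LDAModel(estimator=est, block_names=block_names, n_features=X.shape[1])


def lda_predict(model: LDAModel, features) -> np.ndarray:
    """Predicted analyte labels for feature rows (order as at fit time)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"feature width {X.shape[1]} != training width {model.n_features}"
        )
    return model.estimator.predict(X)


def gcqepas_sequential_id(rt: float, spectrum: IRSpectrum, rt_models, references) -> list:
    """Sequential GC-QEPAS identification: RT window screens, spectrum confirms.

    ``rt_models`` and ``references`` are mappings analyte -> RTModel /
    SpectralReference over the same analyte name-space.
    """
    if set(rt_models) != set(references):
        only_rt = sorted(set(rt_models) - set(references))
        only_ref = sorted(set(references) - set(rt_models))
        raise ValidationError(
            f"analyte name-spaces differ (RT only: {only_rt}, reference only: {only_ref})"
        )
    results = []
    for analyte in rt_models:
        if not rt_detect(rt, rt_models[analyte]):
            results.append((analyte, False))
            continue
        _, matched = pearson_match(spectrum, references[analyte])
        results.append((analyte, matched))
    return results
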