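"""Spectral preprocessing: saturation masking, linear baseline correction, mean centering.

The pipeline order is fixed — mask -> baseline -> center — and is recorded in
the result's provenance.  Minimal preprocessing keeps loadings interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessedSpectra",
    "mask_saturated",
    "baseline_correct",
    "mean_center",
    "preprocess",
    "SATURATION_THRESHOLD",
]

#: Absorbance above which a transmission NIR detector leaves its linear range.
SATURATION_THRESHOLD = 2.5


class AllChannelsSaturatedError(ValueError):
    """Every channel's mean absorbance exceeds the saturation threshold."""


@dataclass
class PreprocessedSpectra:
    """Analysis-ready matrix: masked, detrended, centered.

    ``matrix`` holds the centered absorbances (rows = samples, columns =
    retained wavenumbers); ``grand_mean`` is the mean spectrum subtracted
    during centering, so ``matrix + grand_mean`` restores the
    baseline-corrected data exactly.
    """

    matrix: pd.DataFrame
    grand_mean: pd.Series
    provenance: list = field(default_factory=list)

    @property
    def retained_wavenumbers(self) -> np.ndarray:
        return self.matrix.columns.to_numpy(float)

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(float)


def mask_saturated(spectra: pd.DataFrame, threshold: float = SATURATION_THRESHOLD) -> pd.DataFrame:
    """Drop every channel whose mean absorbance exceeds ``threshold``.

    Masking is decided on the mean spectrum so all rows keep one shared grid;
    rows are never removed.  Idempotent.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    keep = spectra.mean(axis=0).to_numpy(float) <= threshold
    if not keep.any():
        raise AllChannelsSaturatedError(
            f"all {spectra.shape[1]} channels exceed {threshold} AU"
        )
    return spectra.loc[:, keep]


def baseline_correct(spectra: pd.DataFrame) -> pd.DataFrame:
    """Subtract each spectrum's least-squares straight line in wavenumber.

    Removes the additive offset + tilt that residual turbidity produces in
    transmission spectra; any affine-in-wavenumber contamination is removed
    exactly, so the output has zero linear trend per row.
    """
    if spectra.shape[1] < 2:
        raise ValueError("baseline correction needs >= 2 channels")
    nu = spectra.columns.to_numpy(float)
    # Orthonormal (constant, linear) design for a stable per-row projection.
    basis = np.ones((len(nu), 2))
    basis[:, 1] = nu - nu.mean()
    q, _ = np.linalg.qr(basis)
    X = spectra.to_numpy(float)
    detrended = X - (X @ q) @ q.T
    return pd.DataFrame(detrended, index=spectra.index, columns=spectra.columns)


def mean_center(spectra: pd.DataFrame) -> PreprocessedSpectra:
    """Subtract the grand-mean spectrum; column means of the result are ~0."""
    if len(spectra) < 1:
        raise ValueError("need at least one spectrum")
    mu = spectra.mean(axis=0)
    return PreprocessedSpectra(
        matrix=spectra - mu, grand_mean=mu, provenance=["mean_center"]
    )


def preprocess(
    spectra: pd.DataFrame, threshold: float = SATURATION_THRESHOLD
) -> PreprocessedSpectra:
    """Full pipeline in fixed order: mask saturated -> baseline -> center."""
    masked = mask_saturated(spectra, threshold)
    corrected = baseline_correct(masked)
    out = mean_center(corrected)
    out.provenance = [f"mask_saturated(threshold={threshold})", "baseline_correct", "mean_center"]
    return out
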