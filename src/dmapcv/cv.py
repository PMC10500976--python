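"""Candidate collective variables and their correlation with diffusion coordinates.

Candidate CVs come from two families: internal coordinates themselves, and
coefficients of principal components of the (mean-subtracted) feature matrix.
A CV is judged by the absolute Pearson correlation of its per-frame series
with the leading nontrivial diffusion coordinates DC2 and DC3: a CV that
tracks the slow dynamics correlates strongly with the slow eigenvectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coordinates import FeatureSeries, wrap_angle

__all__ = [
    "PCAModel",
    "pca_fit",
    "pc_coefficients",
    "pearson_correlation",
    "correlation_table",
    "rank_cvs",
    "singular_value_decay_report",
    "unwrap_angular_features",
]


@dataclass
class PCAModel:
    """Mean-subtracted SVD of a feature matrix.

    ``components`` has orthonormal PCs as columns (right-singular vectors of
    ``X - mean``); ``singular_values`` are descending.  Sign convention: the
    largest-magnitude loading of each PC is positive, so refitting the same
    data reproduces identical components.
    """

    mean: np.ndarray
    components: np.ndarray
    singular_values: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def unwrap_angular_features(features: FeatureSeries) -> np.ndarray:
    """Map angular dimensions to ``(-pi, pi]`` about their circular mean.

    PCA treats angles as plain real numbers; re-centering each angular
    dimension about its circular mean keeps a tight angular distribution
    contiguous even when it straddles the branch cut.
    """
    X = features.values.copy()
    for k in np.nonzero(features.is_angular)[0]:
        theta = X[:, k]
        mu = np.arctan2(np.mean(np.sin(theta)), np.mean(np.cos(theta)))
        X[:, k] = np.asarray(wrap_angle(theta - mu)) + mu
    return X


def pca_fit(X: FeatureSeries | np.ndarray, standardize: bool = False) -> PCAModel:
    """Principal components as right-singular vectors of the centered data.

    ``standardize=True`` additionally z-scores each column before the SVD
    (off by default: mixed-unit internal coordinates are analyzed in their
    native units).  Constant data yields all-zero singular values with a
    warning.
    """
    if isinstance(X, FeatureSeries):
        M = unwrap_angular_features(X)
    else:
        M = np.atleast_2d(np.asarray(X, dtype=float))
    if M.shape[0] < 2:
        raise ValueError("PCA requires at least 2 frames")
    mean = M.mean(axis=0)
    C = M - mean
    if standardize:
        sd = C.std(axis=0, ddof=1)
        C = C / np.where(sd > 0, sd, 1.0)
    _, s, Vt = np.linalg.svd(C, full_matrices=False)
    if np.allclose(s, 0.0):
        warnings.warn("constant data: all singular values are zero", RuntimeWarning, stacklevel=2)
    V = Vt.T
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
    V = V * np.where(flip == 0, 1.0, flip)
    return PCAModel(mean=mean, components=V, singular_values=s)


def pc_coefficients(X: FeatureSeries | np.ndarray, model: PCAModel, j: int) -> np.ndarray:
    """Per-frame coefficient of PC ``j`` (0-based): projection of centered rows."""
    if isinstance(X, FeatureSeries):
        M = unwrap_angular_features(X)
    else:
        M = np.atleast_2d(np.asarray(X, dtype=float))
    if M.shape[1] != model.components.shape[0]:
        raise ValueError("feature dimension does not match the fitted model")
    if not 0 <= j < model.n_components:
        raise IndexError(f"PC index {j} out of range [0, {model.n_components})")
    return (M - model.mean) @ model.components[:, j]


def pearson_correlation(C: np.ndarray, D: np.ndarray) -> float:
    """Pearson correlation ``cov(C, D) / (sigma_C sigma_D)`` in [-1, 1]."""
    C = np.asarray(C, dtype=float).reshape(-1)
    D = np.asarray(D, dtype=float).reshape(-1)
    if C.shape != D.shape or len(C) < 2:
        raise ValueError("series must share length >= 2")
    sc, sd = C.std(), D.std()
    if sc == 0.0 or sd == 0.0:
        raise ValueError("zero-variance series: correlation undefined")
    rho = float(np.mean((C - C.mean()) * (D - D.mean())) / (sc * sd))
    return float(np.clip(rho, -1.0, 1.0))


def correlation_table(
    cvs: dict[str, np.ndarray], dcs: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Absolute Pearson correlations: rows = CVs, columns = DC labels.

    Zero-variance CVs are reported as NaN with a warning instead of failing
    the whole table.
    """
    lengths = {len(np.asarray(v).reshape(-1)) for v in [*cvs.values(), *dcs.values()]}
    if len(lengths) != 1:
        raise ValueError("all CV and DC series must share the same length")
    rows = {}
    for name, series in cvs.items():
        entries = {}
        for dc_label, dc in dcs.items():
            try:
                entries[dc_label] = abs(pearson_correlation(series, dc))
            except ValueError:
                warnings.warn(
                    f"CV {name!r} has zero variance; reported as NaN", RuntimeWarning, stacklevel=2
                )
                entries[dc_label] = np.nan
        rows[name] = entries
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(dcs.keys()))


def rank_cvs(table: pd.DataFrame, dc: str = "DC2", threshold: float = 0.7) -> pd.DataFrame:
    """Rank CVs by |rho| against one DC; flag candidates above ``threshold``.

    Ties preserve the declaration order of the table's rows (stable sort).
    """
    out = table[[dc]].copy()
    out["flagged"] = out[dc] >= threshold
    return out.sort_values(dc, ascending=False, kind="stable")


def singular_value_decay_report(
    X_a: FeatureSeries | np.ndarray, X_b: FeatureSeries | np.ndarray
) -> dict[str, np.ndarray]:
    """Normalized singular-value spectra of two sample sets.

    Each spectrum is divided by its own largest singular value (first entry
    1 by construction).  A sample set hugging a low-dimensional curve (e.g.
    a minimum-energy path) decays much faster than a thermally spread basin
    cloud; the returned spectra make that comparison directly.
    """
    spectra = {}
    for key, X in (("a", X_a), ("b", X_b)):
        s = pca_fit(X).singular_values
        if s[0] <= 0:
            raise ValueError("zero leading singular value")
        spectra[key] = s / s[0]
    return spectra
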