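"""Essential dynamics: PCA of Cartesian coordinate fluctuations.

Every frame is superposed onto a reference structure on a chosen atom
selection (Calpha by default), the 3N x 3N covariance matrix of the
coordinate deviations from the ensemble mean is built, and its
eigendecomposition yields collective motions (eigenvectors) with
amplitudes (eigenvalues, A^2).  Projections of frames onto the leading
modes quantify how far the ensemble explores each collective motion; the
per-mode standard deviation of the projections ("spread") is the scalar
used to rank the flexibility of two variants in a shared basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble_io import EnsembleError, Frame, Selection, StructureEnsemble, select_atoms
from .geometry import superpose_ensemble_coords

__all__ = [
    "CovarianceModel",
    "ModeProjection",
    "build_covariance",
    "project",
    "variance_fraction",
    "spread",
    "write_eigenvalues_tsv",
    "write_projections_tsv",
]


@dataclass
class CovarianceModel:
    """Superposition reference, mean, covariance and its eigensystem."""

    mean: np.ndarray  # (3N,)
    covariance: np.ndarray  # (3N, 3N)
    eigenvalues: np.ndarray  # (3N,) descending, A^2
    eigenvectors: np.ndarray  # (3N, 3N), column k = mode k
    reference_coords: np.ndarray  # (N, 3) superposition target
    selection: Selection
    n_frames: int

    @property
    def n_atoms(self) -> int:
        return self.reference_coords.shape[0]


@dataclass
class ModeProjection:
    """Per-frame scalar projections (A) onto selected modes."""

    values: np.ndarray  # (n_frames, n_modes)
    modes: list[int]  # 0-based mode indices
    label: str
    times_ps: np.ndarray
    replica_ids: list[str]


def _fix_eigenvector_signs(vecs: np.ndarray) -> np.ndarray:
    # Deterministic orientation: the largest-magnitude component is positive.
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def build_covariance(
    ensemble: StructureEnsemble,
    selection: Selection | None = None,
    reference: Frame | np.ndarray | str = "mean",
) -> CovarianceModel:
    """Superpose, then build and diagonalise the coordinate covariance.

    ``reference="mean"`` iterates fit -> mean -> refit twice (same
    convention as the RMSF computation); an explicit frame fixes the
    superposition target.  The covariance uses the 1/F normalisation so
    that the eigenvalue of a mode equals the variance of the ensemble's
    own projections onto it.
    """
    if ensemble.n_frames < 2:
        raise EnsembleError("covariance needs at least 2 frames")
    sel = selection if selection is not None else Selection.calpha()
    sub = select_atoms(ensemble, sel)
    if sub.n_atoms < 3:
        raise EnsembleError("selection must contain at least 3 atoms")
    ref = reference.coordinates if isinstance(reference, Frame) else reference
    fitted, ref_used = superpose_ensemble_coords(sub.coords, ref)
    X = fitted.reshape(fitted.shape[0], -1)
    mean = X.mean(axis=0)
    D = X - mean
    cov = D.T @ D / D.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = _fix_eigenvector_signs(evecs[:, order])
    return CovarianceModel(mean, cov, evals, evecs, ref_used, sel, ensemble.n_frames)


def project(
    model: CovarianceModel,
    ensemble: StructureEnsemble,
    modes: list[int] | None = None,
) -> ModeProjection:
    """Project an ensemble onto the model's modes (dot with eigenvectors).

    Frames are superposed onto the model's stored reference with the
    model's selection, mean-centred with the model's mean, then projected.
    """
    if modes is None:
        modes = [0, 1]
    dim = model.eigenvectors.shape[1]
    for m in modes:
        if not 0 <= m < dim:
            raise IndexError(f"mode index {m} out of range (0..{dim - 1})")
    sub = select_atoms(ensemble, model.selection)
    if sub.n_atoms != model.n_atoms:
        raise EnsembleError("ensemble selection does not match the covariance model")
    fitted, _ = superpose_ensemble_coords(sub.coords, model.reference_coords)
    D = fitted.reshape(fitted.shape[0], -1) - model.mean
    values = D @ model.eigenvectors[:, modes]
    return ModeProjection(values, list(modes), ensemble.label, ensemble.times_ps, ensemble.replica_ids)


def variance_fraction(model: CovarianceModel, k: int) -> float:
    """Fraction of total positional variance carried by the first k modes."""
    if not 1 <= k <= len(model.eigenvalues):
        raise ValueError(f"k must be in 1..{len(model.eigenvalues)}")
    total = model.eigenvalues.sum()
    if total <= 0:
        raise EnsembleError("degenerate all-zero spectrum")
    return float(model.eigenvalues[:k].sum() / total)


def spread(projection: ModeProjection) -> np.ndarray:
    """Per-mode standard deviation (A) of the projections."""
    if projection.values.shape[0] < 2:
        raise EnsembleError("spread needs at least 2 frames")
    return projection.values.std(axis=0)


def write_eigenvalues_tsv(model: CovarianceModel, path) -> None:
    pd.DataFrame(
        {
            "mode": np.arange(1, len(model.eigenvalues) + 1),
            "eigenvalue_A2": model.eigenvalues,
        }
    ).to_csv(path, sep="\t", index=False)


def write_projections_tsv(projection: ModeProjection, path) -> None:
    df = pd.DataFrame(
        projection.values, columns=[f"mode{m + 1}" for m in projection.modes]
    )
    df.insert(0, "time_ps", projection.times_ps)
    df.insert(0, "replica_id", projection.replica_ids)
    df.to_csv(path, sep="\t", index=False)
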