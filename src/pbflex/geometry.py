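"""Backbone geometry of conformational ensembles.

Torsion angles, optimal rigid-body superposition (Kabsch), per-frame RMSD
and per-residue RMSF, mass-weighted centres of mass and their distances,
and residue contact counts from Calpha distances.

Angles are degrees in the half-open interval (-180, 180], following the
IUPAC sign convention for torsions (an ideal right-handed alpha helix has
phi ~ -57 deg, psi ~ -47 deg).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .ensemble_io import (
    EnsembleError,
    Frame,
    Selection,
    SelectionError,
    StructureEnsemble,
    TopologyError,
    select_atoms,
)

__all__ = [
    "DihedralSeries",
    "ContactSeries",
    "DistanceSeries",
    "wrap_angle",
    "dihedral_angle",
    "backbone_dihedrals",
    "kabsch_superpose",
    "superpose_ensemble_coords",
    "rmsd_series",
    "rmsf_profile",
    "center_of_mass",
    "com_distance_series",
    "contact_counts",
    "contacts_by_partner_domain",
    "write_rmsd_tsv",
    "write_rmsf_tsv",
    "write_contacts_tsv",
    "write_distance_tsv",
]


def wrap_angle(deg):
    """Wrap angles (degrees) into (-180, 180]."""
    deg = np.asarray(deg, dtype=float)
    wrapped = ((deg + 180.0) % 360.0) - 180.0
    wrapped = np.where(np.isclose(wrapped, -180.0), 180.0, wrapped)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


@dataclass
class DihedralSeries:
    """Per-frame, per-residue backbone phi/psi angles in degrees.

    Undefined angles (phi of the first residue, psi of the last, or any
    angle involving a missing atom) are NaN.
    """

    residue_numbers: np.ndarray  # (n_res,)
    phi_deg: np.ndarray  # (n_frames, n_res)
    psi_deg: np.ndarray  # (n_frames, n_res)

    @property
    def n_frames(self) -> int:
        return self.phi_deg.shape[0]

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)


@dataclass
class ContactSeries:
    """Per-frame, per-residue Calpha contact counts."""

    residue_numbers: np.ndarray  # (n_res,)
    counts: np.ndarray  # (n_frames, n_res) int
    cutoff_A: float
    exclusion: int
    times_ps: np.ndarray
    replica_ids: list[str]


@dataclass
class DistanceSeries:
    """Per-frame distance (Angstrom) between two centre-of-mass selections."""

    values_A: np.ndarray  # (n_frames,)
    label_a: str
    label_b: str
    times_ps: np.ndarray
    replica_ids: list[str]


# ---------------------------------------------------------------------------
# Torsions
# ---------------------------------------------------------------------------

def _dihedral_batch(p1, p2, p3, p4) -> np.ndarray:
    """Signed torsion (degrees) for stacked coordinate quadruples.

    Returns NaN where a bounding plane is degenerate (collinear points).
    """
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.sum(n1 * n2, axis=-1)
        y = np.sum(np.cross(n1, n2) * (b2 / b2n[..., None]), axis=-1)
        ang = np.degrees(np.arctan2(y, x))
    bad = (np.linalg.norm(n1, axis=-1) < 1e-9) | (np.linalg.norm(n2, axis=-1) < 1e-9)
    ang = np.where(bad, np.nan, ang)
    return wrap_angle(ang)


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle about the p2-p3 axis, degrees in (-180, 180].

    IUPAC convention: positive when, looking from p2 towards p3, the far
    bond p3-p4 is rotated clockwise from the near bond p2-p1.
    """
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(np.asarray(b, float) - np.asarray(a, float)) < 1e-12:
            raise ValueError("consecutive torsion points coincide")
    ang = _dihedral_batch(
        np.asarray(p1, float), np.asarray(p2, float), np.asarray(p3, float), np.asarray(p4, float)
    )
    if np.isnan(ang):
        raise ValueError("undefined torsion: three consecutive points are collinear")
    return float(ang)


def _backbone_coords(ensemble: StructureEnsemble):
    """Per-residue N/CA/C coordinate stacks, shape (n_frames, n_res, 3) each."""
    residues = ensemble.residue_numbers
    index: dict[tuple[int, str], int] = {}
    for i, a in enumerate(ensemble.topology):
        index.setdefault((a.residue_number, a.atom_name), i)
    cols = {}
    for name in ("N", "CA", "C"):
        idx = []
        for r in residues:
            try:
                idx.append(index[(int(r), name)])
            except KeyError:
                raise TopologyError(f"residue {r} is missing backbone atom {name}") from None
        cols[name] = np.array(idx)
    coords = ensemble.coords
    return residues, {k: coords[:, v, :] for k, v in cols.items()}


def backbone_dihedrals(ensemble: StructureEnsemble) -> DihedralSeries:
    """phi/psi series for every residue of every frame.

    phi(i) is the C(i-1)-N(i)-CA(i)-C(i) torsion, psi(i) the
    N(i)-CA(i)-C(i)-N(i+1) torsion; chain termini are NaN.
    """
    residues, bb = _backbone_coords(ensemble)
    n_frames = ensemble.n_frames
    n_res = len(residues)
    phi = np.full((n_frames, n_res), np.nan)
    psi = np.full((n_frames, n_res), np.nan)
    if n_res >= 2:
        phi[:, 1:] = _dihedral_batch(
            bb["C"][:, :-1], bb["N"][:, 1:], bb["CA"][:, 1:], bb["C"][:, 1:]
        )
        psi[:, :-1] = _dihedral_batch(
            bb["N"][:, :-1], bb["CA"][:, :-1], bb["C"][:, :-1], bb["N"][:, 1:]
        )
    return DihedralSeries(residues, phi, psi)


# ---------------------------------------------------------------------------
# Superposition, RMSD, RMSF
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd_A)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference``; the
    rotation is proper (det +1) and the RMSD is the post-fit value.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must both have shape (n, 3)")
    if P.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.ones(P.shape[0])
    else:
        w = np.asarray(weights, float)
        if w.shape != (P.shape[0],) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    cp = w @ P
    cq = w @ Q
    Pc = P - cp
    Qc = Q - cq
    H = (Pc * w[:, None]).T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    fitted = Pc @ R.T + cq
    rmsd = float(np.sqrt(np.sum(w * np.sum((fitted - Q) ** 2, axis=1))))
    return R, t, rmsd


def _fit_coords(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Superpose every frame of ``coords`` (F, N, 3) onto ``reference`` (N, 3)."""
    out = np.empty_like(coords)
    for i in range(coords.shape[0]):
        R, t, _ = kabsch_superpose(coords[i], reference)
        out[i] = coords[i] @ R.T + t
    return out


def superpose_ensemble_coords(
    coords: np.ndarray,
    reference: np.ndarray | str = "mean",
    n_iter: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose stacked frames onto a reference, shape (F, N, 3).

    ``reference="mean"`` iterates fit -> mean -> refit ``n_iter`` times,
    starting from the first frame; an explicit (N, 3) array is used as-is.
    Returns ``(superposed, reference_used)``.
    """
    coords = np.asarray(coords, float)
    if isinstance(reference, str):
        if reference == "first":
            ref = coords[0]
            return _fit_coords(coords, ref), ref
        if reference != "mean":
            raise ValueError("reference must be 'mean', 'first' or an (N, 3) array")
        ref = coords[0]
        fitted = coords
        for _ in range(max(1, n_iter)):
            fitted = _fit_coords(coords, ref)
            ref = fitted.mean(axis=0)
        return fitted, ref
    ref = np.asarray(reference, float)
    return _fit_coords(coords, ref), ref


def rmsd_series(
    ensemble: StructureEnsemble,
    reference: Frame | np.ndarray,
    selection: Selection | None = None,
) -> np.ndarray:
    """Per-frame post-fit RMSD (Angstrom) to a reference structure.

    The fit and the measurement use the same selection (Calpha by default).
    """
    sel = selection if selection is not None else Selection.calpha()
    sub = select_atoms(ensemble, sel)
    mask = sel.mask(ensemble.topology)
    ref_coords = reference.coordinates if isinstance(reference, Frame) else np.asarray(reference, float)
    if ref_coords.shape[0] == ensemble.n_atoms:
        ref_coords = ref_coords[mask]
    if ref_coords.shape[0] != sub.n_atoms:
        raise SelectionError("reference does not match the selection size")
    return np.array([kabsch_superpose(f.coordinates, ref_coords)[2] for f in sub.frames])


def rmsf_profile(
    ensemble: StructureEnsemble,
    selection: Selection | None = None,
    reference: str = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue RMSF (Angstrom) about the mean structure.

    Frames are superposed onto the iterated mean structure (two fit/mean
    rounds by default; ``reference="first"`` fits to the first frame), then
    RMSF(i) = sqrt(mean_frames |x_i - <x_i>|^2).  Returns
    ``(residue_numbers, rmsf)``.
    """
    if ensemble.n_frames < 2:
        raise EnsembleError("RMSF needs at least 2 frames")
    sel = selection if selection is not None else Selection.calpha()
    sub = select_atoms(ensemble, sel)
    fitted, _ = superpose_ensemble_coords(sub.coords, reference)
    mean = fitted.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
    return np.array([a.residue_number for a in sub.topology]), rmsf


# ---------------------------------------------------------------------------
# Centres of mass and distances
# ---------------------------------------------------------------------------

def center_of_mass(
    frame: Frame | np.ndarray,
    selection: Selection,
    topology: Sequence,
) -> np.ndarray:
    """Mass-weighted mean position (Angstrom) of the selected atoms."""
    mask = selection.mask(topology)
    if not mask.any():
        raise SelectionError(f"selection {selection} matches no atom")
    coords = frame.coordinates if isinstance(frame, Frame) else np.asarray(frame, float)
    masses = np.array([topology[i].mass for i in np.flatnonzero(mask)])
    return masses @ coords[mask] / masses.sum()


def com_distance_series(
    ensemble: StructureEnsemble,
    selection_a: Selection,
    selection_b: Selection,
    label_a: str = "A",
    label_b: str = "B",
) -> DistanceSeries:
    """Per-frame Euclidean distance between two centres of mass."""
    mask_a = selection_a.mask(ensemble.topology)
    mask_b = selection_b.mask(ensemble.topology)
    if not mask_a.any():
        raise SelectionError(f"selection {selection_a} matches no atom")
    if not mask_b.any():
        raise SelectionError(f"selection {selection_b} matches no atom")
    masses = ensemble.masses
    wa = masses[mask_a] / masses[mask_a].sum()
    wb = masses[mask_b] / masses[mask_b].sum()
    coords = ensemble.coords
    com_a = np.einsum("i,fij->fj", wa, coords[:, mask_a, :])
    com_b = np.einsum("i,fij->fj", wb, coords[:, mask_b, :])
    values = np.linalg.norm(com_a - com_b, axis=1)
    return DistanceSeries(values, label_a, label_b, ensemble.times_ps, ensemble.replica_ids)


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def _calpha_subensemble(ensemble: StructureEnsemble) -> StructureEnsemble:
    residues = set(int(r) for r in ensemble.residue_numbers)
    have_ca = {a.residue_number for a in ensemble.topology if a.atom_name == "CA"}
    missing = sorted(residues - have_ca)
    if missing:
        raise TopologyError(f"residue {missing[0]} has no CA atom")
    return select_atoms(ensemble, Selection.calpha())


def contact_counts(
    ensemble: StructureEnsemble,
    cutoff_A: float = 8.0,
    exclusion: int = 0,
) -> ContactSeries:
    """Residue contact counts from Calpha distances.

    Residues i and j are in contact when d(CA_i, CA_j) <= cutoff_A
    (boundary inclusive) and |i - j| > exclusion in residue numbering;
    ``exclusion=0`` counts sequence neighbours.
    """
    ca = _calpha_subensemble(ensemble)
    residues = np.array([a.residue_number for a in ca.topology])
    sep = np.abs(residues[:, None] - residues[None, :])
    allowed = sep > exclusion
    counts = np.empty((ca.n_frames, len(residues)), dtype=int)
    for fi, frame in enumerate(ca.frames):
        d = cdist(frame.coordinates, frame.coordinates)
        counts[fi] = np.sum((d <= cutoff_A) & allowed, axis=1)
    return ContactSeries(residues, counts, cutoff_A, exclusion, ca.times_ps, ca.replica_ids)


def _validate_domains(domains: Mapping[str, tuple[int, int]]) -> None:
    items = list(domains.items())
    for i, (na, (a_lo, a_hi)) in enumerate(items):
        if a_lo > a_hi:
            raise ValueError(f"domain {na} has an empty range {a_lo}-{a_hi}")
        for nb, (b_lo, b_hi) in items[i + 1 :]:
            if a_lo <= b_hi and b_lo <= a_hi:
                raise ValueError(f"domains {na} and {nb} overlap")


def contacts_by_partner_domain(
    ensemble: StructureEnsemble,
    residue: int,
    domains: Mapping[str, tuple[int, int]],
    cutoff_A: float = 8.0,
    exclusion: int = 0,
) -> dict[str, np.ndarray]:
    """Per-frame contact counts of one residue, split by partner domain.

    Domain ranges are inclusive and must not overlap; partners outside all
    domains are not counted in any split (the per-domain counts sum to the
    total count restricted to domain members).
    """
    _validate_domains(domains)
    ca = _calpha_subensemble(ensemble)
    residues = np.array([a.residue_number for a in ca.topology])
    try:
        ri = int(np.flatnonzero(residues == residue)[0])
    except IndexError:
        raise SelectionError(f"residue {residue} not in ensemble") from None
    allowed = np.abs(residues - residue) > exclusion
    coords = ca.coords
    d = np.linalg.norm(coords - coords[:, ri : ri + 1, :], axis=2)
    contact = (d <= cutoff_A) & allowed
    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in domains.items():
        member = (residues >= lo) & (residues <= hi)
        out[name] = np.sum(contact & member, axis=1)
    return out


# ---------------------------------------------------------------------------
# TSV writers
# ---------------------------------------------------------------------------

def _series_frame(ensemble_like, values, column: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "replica_id": ensemble_like.replica_ids,
            "time_ps": ensemble_like.times_ps,
            column: values,
        }
    )


def write_rmsd_tsv(ensemble: StructureEnsemble, rmsd_A: np.ndarray, path) -> None:
    _series_frame(ensemble, rmsd_A, "rmsd_A").to_csv(path, sep="\t", index=False)


def write_rmsf_tsv(residue_numbers: np.ndarray, rmsf_A: np.ndarray, path) -> None:
    pd.DataFrame({"residue_number": residue_numbers, "rmsf_A": rmsf_A}).to_csv(
        path, sep="\t", index=False
    )


def write_contacts_tsv(series: ContactSeries, path) -> None:
    df = pd.DataFrame(series.counts, columns=[str(r) for r in series.residue_numbers])
    df.insert(0, "time_ps", series.times_ps)
    df.insert(0, "replica_id", series.replica_ids)
    df.to_csv(path, sep="\t", index=False)


def write_distance_tsv(series: DistanceSeries, path) -> None:
    pd.DataFrame(
        {
            "replica_id": series.replica_ids,
            "time_ps": series.times_ps,
            f"dist_{series.label_a}_{series.label_b}_A": series.values_A,
        }
    ).to_csv(path, sep="\t", index=False)
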