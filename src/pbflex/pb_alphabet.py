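"""Protein Blocks structural alphabet and the Neq flexibility statistic.

Protein Blocks (PBs) are 16 local-backbone prototypes labelled ``a``-``p``,
each defined by 8 reference dihedral angles spanning five consecutive
residues (psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i), phi(i+1),
psi(i+1), phi(i+2)).  Assigning a PB letter to every residue of every
snapshot coarse-grains an ensemble into strings; per-residue letter
frequencies then yield Neq, the exponential of the Shannon entropy of the
PB distribution: Neq = 1 means a single conformation (rigid), Neq = 16 a
uniform spread over the whole alphabet.

Two ensembles are compared through dNeq = |Neq_A - Neq_B|; a residue is
flagged as significantly altered when dNeq > 1.5 and at least one of the
two Neq values is below 2.5 (both inequalities strict).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import DihedralSeries, wrap_angle

__all__ = [
    "PB_LABELS",
    "PBPrototypeTable",
    "PBAssignmentSet",
    "PBProfile",
    "NeqProfile",
    "DeltaNeqReport",
    "rmsda",
    "assign_window",
    "assign_ensemble",
    "pb_profile",
    "neq",
    "neq_profile",
    "delta_neq",
    "write_pb_fasta",
    "write_delta_neq_tsv",
]

PB_LABELS = "abcdefghijklmnop"
UNASSIGNED = "Z"

#: Window angle slots relative to the centre residue i:
#: psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i), phi(i+1), psi(i+1), phi(i+2)
WINDOW_OFFSETS = ((-2, "psi"), (-1, "phi"), (-1, "psi"), (0, "phi"),
                  (0, "psi"), (1, "phi"), (1, "psi"), (2, "phi"))


@dataclass(frozen=True)
class PBPrototypeTable:
    """The 16 x 8 reference dihedral table of the PB alphabet."""

    labels: str
    angles: np.ndarray  # (16, 8) degrees
    version: str

    def __post_init__(self):
        if self.labels != PB_LABELS:
            raise ValueError("prototype table must carry the 16 labels a..p")
        a = np.asarray(self.angles, float)
        if a.shape != (16, 8) or not np.all(np.isfinite(a)):
            raise ValueError("prototype table must be a finite 16x8 angle array")
        if np.any(a <= -180) or np.any(a > 180):
            raise ValueError("prototype angles must lie in (-180, 180]")

    def prototype(self, label: str) -> np.ndarray:
        return self.angles[PB_LABELS.index(label)]

    @classmethod
    def load_default(cls) -> "PBPrototypeTable":
        with resources.files("pbflex.data").joinpath("pb_prototypes.json").open() as fh:
            data = json.load(fh)
        payload = json.dumps(data["prototypes"], sort_keys=True).encode()
        digest = hashlib.sha256(payload).hexdigest()
        if digest != data["checksum_sha256"]:
            raise ValueError("PB prototype data file failed its checksum")
        angles = np.array([data["prototypes"][c] for c in PB_LABELS])
        return cls(PB_LABELS, angles, f"{data['name']}/{data['version']}")


@dataclass
class PBAssignmentSet:
    """Per-frame PB strings over a..p plus Z for unassignable positions."""

    residue_numbers: np.ndarray
    frames: list[str]
    table_version: str = ""
    times_ps: np.ndarray | None = None
    replica_ids: list[str] | None = None

    def __post_init__(self):
        n = len(self.residue_numbers)
        for s in self.frames:
            if len(s) != n:
                raise ValueError("assignment string length must equal residue count")


@dataclass
class PBProfile:
    """Per-residue PB letter frequencies over frames (Z excluded).

    Rows of residues that are never assignable are NaN.
    """

    residue_numbers: np.ndarray
    frequencies: np.ndarray  # (n_res, 16)
    n_frames: int

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.frequencies[:, 0])


@dataclass
class NeqProfile:
    """Per-residue equivalent number of PBs; NaN where undefined."""

    residue_numbers: np.ndarray
    values: np.ndarray
    label: str = ""


@dataclass
class DeltaNeqReport:
    """Per-residue Neq comparison of two ensembles with significance flags."""

    residue_numbers: np.ndarray
    neq_a: np.ndarray
    neq_b: np.ndarray
    delta: np.ndarray
    significant: np.ndarray  # bool
    label_a: str = "A"
    label_b: str = "B"

    def significant_residues(self) -> list[int]:
        return [int(r) for r in self.residue_numbers[self.significant]]


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def rmsda(window, prototype) -> float:
    """Root mean square deviation of angles between a window and a prototype.

    Differences are wrapped to the shortest arc before squaring.
    """
    w = np.asarray(window, float)
    p = np.asarray(prototype, float)
    if w.shape != (8,) or p.shape != (8,):
        raise ValueError("window and prototype must each hold 8 angles")
    if not np.all(np.isfinite(w)):
        raise ValueError("window contains undefined angles")
    d = wrap_angle(w - p)
    return float(np.sqrt(np.mean(np.square(d))))


def assign_window(window, table: PBPrototypeTable | None = None) -> str:
    """PB letter whose prototype minimises the RMSDA to the window.

    Ties are broken alphabetically (the first minimal label wins).
    """
    table = table or PBPrototypeTable.load_default()
    w = np.asarray(window, float)
    if not np.all(np.isfinite(w)):
        raise ValueError("window contains undefined angles")
    d = wrap_angle(w[None, :] - table.angles)
    scores = np.sqrt(np.mean(np.square(d), axis=1))
    return PB_LABELS[int(np.argmin(scores))]


def _windows(dihedrals: DihedralSeries) -> np.ndarray:
    """Stack the 8-angle windows, shape (n_frames, n_res, 8); NaN where undefined."""
    n_frames, n_res = dihedrals.phi_deg.shape
    out = np.full((n_frames, n_res, 8), np.nan)
    src = {"phi": dihedrals.phi_deg, "psi": dihedrals.psi_deg}
    for k, (off, kind) in enumerate(WINDOW_OFFSETS):
        lo = max(0, -off)
        hi = n_res - max(0, off)
        if hi > lo:
            out[:, lo:hi, k] = src[kind][:, lo + off : hi + off]
    return out


def assign_ensemble(
    dihedrals: DihedralSeries,
    table: PBPrototypeTable | None = None,
    chunk: int = 256,
) -> PBAssignmentSet:
    """Assign a PB letter to every residue of every frame.

    Position i uses the window psi(i-2)..phi(i+2); positions whose window
    contains an undefined angle (always the two first and two last
    residues) are marked ``Z``.
    """
    if dihedrals.n_residues < 5:
        raise ValueError("PB assignment needs at least 5 residues")
    table = table or PBPrototypeTable.load_default()
    windows = _windows(dihedrals)
    n_frames, n_res, _ = windows.shape
    defined = np.all(np.isfinite(windows), axis=2)
    letters = np.full((n_frames, n_res), UNASSIGNED, dtype="U1")
    label_arr = np.array(list(PB_LABELS))
    for start in range(0, n_frames, chunk):
        sl = slice(start, min(start + chunk, n_frames))
        w = windows[sl]
        best = np.full(w.shape[:2], np.inf)
        best_idx = np.zeros(w.shape[:2], dtype=int)
        for pi in range(16):
            d = wrap_angle(w - table.angles[pi])
            score = np.mean(np.square(d), axis=2)
            better = score < best  # strict: earlier (alphabetical) label wins ties
            best = np.where(better, score, best)
            best_idx = np.where(better, pi, best_idx)
        lets = label_arr[best_idx]
        lets[~defined[sl]] = UNASSIGNED
        letters[sl] = lets
    return PBAssignmentSet(
        residue_numbers=np.asarray(dihedrals.residue_numbers),
        frames=["".join(row) for row in letters],
        table_version=table.version,
    )


# ---------------------------------------------------------------------------
# Profiles and Neq
# ---------------------------------------------------------------------------

def pb_profile(assignments: PBAssignmentSet) -> PBProfile:
    """Per-residue relative PB letter frequencies over all frames.

    Z assignments are excluded from the tally; residues with no non-Z
    assignment in any frame get a NaN row.
    """
    if not assignments.frames:
        raise ValueError("no frames to profile")
    mat = np.array([list(s) for s in assignments.frames])
    n_res = mat.shape[1]
    freq = np.full((n_res, 16), np.nan)
    for r in range(n_res):
        col = mat[:, r]
        ok = col != UNASSIGNED
        total = int(ok.sum())
        if total == 0:
            continue
        counts = np.array([(col == c).sum() for c in PB_LABELS], dtype=float)
        freq[r] = counts / total
    return PBProfile(assignments.residue_numbers, freq, len(assignments.frames))


def neq(frequencies) -> float:
    """Equivalent number of PBs: exp of the Shannon entropy of ``frequencies``.

    Uses the 0 ln 0 = 0 convention; the input must be a normalised
    probability vector over the 16 letters.
    """
    f = np.asarray(frequencies, float)
    if np.any(f < 0):
        raise ValueError("PB frequencies must be non-negative")
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError(f"PB frequencies must sum to 1 (got {f.sum():.8f})")
    nz = f[f > 0]
    return float(np.exp(-np.sum(nz * np.log(nz))))


def neq_profile(profile: PBProfile, label: str = "") -> NeqProfile:
    """Per-residue Neq values from a PB frequency profile (NaN where undefined)."""
    values = np.full(len(profile.residue_numbers), np.nan)
    for i, row in enumerate(profile.frequencies):
        if not np.isnan(row[0]):
            values[i] = neq(row)
    return NeqProfile(profile.residue_numbers, values, label)


def delta_neq(
    profile_a: NeqProfile,
    profile_b: NeqProfile,
    delta_threshold: float = 1.5,
    rigid_threshold: float = 2.5,
) -> DeltaNeqReport:
    """Absolute Neq difference per residue with significance flags.

    A residue is significant when delta > ``delta_threshold`` and
    min(Neq_A, Neq_B) < ``rigid_threshold`` (both strict).  Residues
    undefined in either profile are never significant.
    """
    if len(profile_a.residue_numbers) != len(profile_b.residue_numbers) or np.any(
        np.asarray(profile_a.residue_numbers) != np.asarray(profile_b.residue_numbers)
    ):
        raise ValueError("Neq profiles cover different residue sets")
    a = np.asarray(profile_a.values, float)
    b = np.asarray(profile_b.values, float)
    delta = np.abs(a - b)
    with np.errstate(invalid="ignore"):
        significant = (delta > delta_threshold) & (np.fmin(a, b) < rigid_threshold)
    significant &= np.isfinite(delta)
    return DeltaNeqReport(
        np.asarray(profile_a.residue_numbers),
        a,
        b,
        delta,
        significant,
        profile_a.label or "A",
        profile_b.label or "B",
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_pb_fasta(assignments: PBAssignmentSet, path) -> None:
    """Write per-frame PB strings in a FASTA-like text format."""
    times = assignments.times_ps
    reps = assignments.replica_ids
    with open(path, "w") as fh:
        for i, s in enumerate(assignments.frames):
            rep = reps[i] if reps is not None else "r?"
            t = f"{times[i]:g}" if times is not None else str(i)
            fh.write(f">{rep} t={t}ps\n{s}\n")


def write_delta_neq_tsv(report: DeltaNeqReport, path) -> None:
    pd.DataFrame(
        {
            "residue_number": report.residue_numbers,
            f"neq_{report.label_a}": report.neq_a,
            f"neq_{report.label_b}": report.neq_b,
            "delta": report.delta,
            "significant": report.significant,
        }
    ).to_csv(path, sep="\t", index=False)
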