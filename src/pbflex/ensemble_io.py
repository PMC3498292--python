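"""Reading, writing and slicing of conformational ensembles stored as multi-model PDB.

An ensemble is a set of coordinate frames (snapshots of one protein chain)
sharing a single atom topology.  Frames carry a simulation time in
picoseconds and a replica label so that several independent simulations of
the same molecule can be pooled and filtered consistently.

Multi-model PDB parsing and writing are delegated to :mod:`biotite`; this
module adds the ensemble bookkeeping (times, replicas, equilibration
filtering, pooling, atom selection) on top of it.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "ATOMIC_MASSES",
    "AtomRecord",
    "Frame",
    "StructureEnsemble",
    "Selection",
    "EnsembleError",
    "TopologyError",
    "PDBParseError",
    "SelectionError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "discard_equilibration",
    "pool_replicas",
    "select_atoms",
]

# Standard atomic masses (u) for heavy-atom centre-of-mass computations.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}


class EnsembleError(ValueError):
    """Invalid ensemble content or operation."""


class TopologyError(EnsembleError):
    """Atom topology inconsistent across models or ensembles."""


class PDBParseError(EnsembleError):
    """Malformed PDB content."""


class SelectionError(EnsembleError):
    """Atom selection empty or invalid."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology (author residue numbering)."""

    serial: int
    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    element: str

    @property
    def mass(self) -> float:
        try:
            return ATOMIC_MASSES[self.element]
        except KeyError:
            raise TopologyError(
                f"no atomic mass for element {self.element!r} "
                f"(atom {self.atom_name} of residue {self.residue_number})"
            ) from None


@dataclass
class Frame:
    """One snapshot: coordinates for every topology atom, in Angstrom."""

    coordinates: np.ndarray  # (n_atoms, 3) float
    time_ps: float
    replica_id: str

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise EnsembleError("frame coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise EnsembleError("frame contains non-finite coordinates")
        if self.time_ps < 0:
            raise EnsembleError("frame time_ps must be >= 0")


@dataclass
class StructureEnsemble:
    """Ordered frames over one shared single-chain topology.

    Frames are kept sorted by ``(replica_id, time_ps)``; construction sorts
    stably, so already-ordered input keeps its order.
    """

    topology: list[AtomRecord]
    frames: list[Frame]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.topology:
            raise EnsembleError("empty topology")
        if not self.frames:
            raise EnsembleError("ensemble must contain at least one frame")
        chains = {a.chain_id for a in self.topology}
        if len(chains) > 1:
            raise TopologyError(f"only single-chain ensembles are supported, got chains {sorted(chains)}")
        res = [a.residue_number for a in self.topology]
        if any(b < a for a, b in zip(res, res[1:])):
            raise TopologyError("residue numbers must be non-decreasing along the topology")
        n = len(self.topology)
        for i, f in enumerate(self.frames):
            if f.coordinates.shape[0] != n:
                raise TopologyError(
                    f"frame {i} has {f.coordinates.shape[0]} atoms, topology has {n}"
                )
        self.frames = sorted(self.frames, key=lambda f: (f.replica_id, f.time_ps))

    # -- convenience views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def coords(self) -> np.ndarray:
        """Stacked coordinates, shape ``(n_frames, n_atoms, 3)``."""
        return np.stack([f.coordinates for f in self.frames])

    @property
    def times_ps(self) -> np.ndarray:
        return np.array([f.time_ps for f in self.frames])

    @property
    def replica_ids(self) -> list[str]:
        return [f.replica_id for f in self.frames]

    @property
    def residue_numbers(self) -> np.ndarray:
        """Unique residue numbers in topology order."""
        seen: dict[int, None] = {}
        for a in self.topology:
            seen.setdefault(a.residue_number, None)
        return np.array(list(seen), dtype=int)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.topology])

    def residue_names(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for a in self.topology:
            out.setdefault(a.residue_number, a.residue_name)
        return out

    def subset_frames(self, indices: Sequence[int], label: str | None = None) -> "StructureEnsemble":
        frames = [self.frames[i] for i in indices]
        if not frames:
            raise EnsembleError("frame subset is empty")
        return StructureEnsemble(self.topology, frames, self.label if label is None else label)


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection over a topology.

    Any combination of atom names, an inclusive residue-number range,
    explicit residue numbers, and residue names; unset criteria match
    everything.
    """

    atom_names: tuple[str, ...] | None = None
    residue_range: tuple[int, int] | None = None
    residue_numbers: tuple[int, ...] | None = None
    residue_names: tuple[str, ...] | None = None

    @classmethod
    def calpha(cls, residue_range: tuple[int, int] | None = None) -> "Selection":
        return cls(atom_names=("CA",), residue_range=residue_range)

    @classmethod
    def residues(cls, numbers: Iterable[int]) -> "Selection":
        return cls(residue_numbers=tuple(int(n) for n in numbers))

    def mask(self, topology: Sequence[AtomRecord]) -> np.ndarray:
        m = np.ones(len(topology), dtype=bool)
        if self.atom_names is not None:
            names = set(self.atom_names)
            m &= np.array([a.atom_name in names for a in topology])
        if self.residue_range is not None:
            lo, hi = self.residue_range
            m &= np.array([lo <= a.residue_number <= hi for a in topology])
        if self.residue_numbers is not None:
            nums = set(self.residue_numbers)
            m &= np.array([a.residue_number in nums for a in topology])
        if self.residue_names is not None:
            rnames = set(self.residue_names)
            m &= np.array([a.residue_name in rnames for a in topology])
        return m

    def __str__(self) -> str:  # used in report provenance
        parts = []
        if self.atom_names:
            parts.append("name=" + ",".join(self.atom_names))
        if self.residue_range:
            parts.append(f"resid={self.residue_range[0]}-{self.residue_range[1]}")
        if self.residue_numbers:
            parts.append("resid=" + ",".join(map(str, self.residue_numbers)))
        if self.residue_names:
            parts.append("resname=" + ",".join(self.residue_names))
        return " and ".join(parts) or "all"


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_TIME_REMARK = "REMARK 250 PBFLEX FRAME"


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if path.suffix == ".gz" or magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def _prescan(lines: list[str]) -> list[int]:
    """Validate ATOM records and return per-model atom counts.

    Raises :class:`PDBParseError` with a line number for malformed ATOM
    lines and :class:`TopologyError` naming the model whose atom count
    differs from model 1.
    """
    counts: list[int] = []
    in_model = False
    saw_model_record = False
    current = 0
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if in_model:
                raise PDBParseError(f"line {lineno}: nested MODEL record")
            in_model = True
            saw_model_record = True
            current = 0
        elif rec == "ENDMDL":
            if not in_model:
                raise PDBParseError(f"line {lineno}: ENDMDL without MODEL")
            in_model = False
            counts.append(current)
        elif rec in ("ATOM", "HETATM"):
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"line {lineno}: truncated ATOM record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                int(line[22:26])
            except ValueError:
                raise PDBParseError(f"line {lineno}: unparsable ATOM record") from None
            current += 1
    if in_model:
        raise PDBParseError("file ends inside a MODEL block")
    if not saw_model_record:
        counts = [current]
    if not counts or counts[0] == 0:
        raise PDBParseError("no ATOM records found")
    for i, c in enumerate(counts[1:], start=2):
        if c != counts[0]:
            raise TopologyError(
                f"model {i} has {c} atoms, model 1 has {counts[0]}"
            )
    return counts


def _parse_time_remarks(lines: list[str]) -> dict[int, tuple[float, str]]:
    """Parse per-frame time/replica remarks written by :func:`write_multimodel_pdb`."""
    out: dict[int, tuple[float, str]] = {}
    for line in lines:
        if line.startswith(_TIME_REMARK):
            try:
                _, _, _, _, idx, t, rep = line.split()
                out[int(idx)] = (float(t), rep)
            except ValueError:
                continue
    return out


def read_multimodel_pdb(
    path: str | Path,
    default_time_step_ps: float = 100.0,
    replica_id: str = "r1",
    label: str = "",
) -> StructureEnsemble:
    """Read a (possibly gzipped) multi-model PDB file into an ensemble.

    Frame times come from ``REMARK 250 PBFLEX FRAME`` records when present
    (written by :func:`write_multimodel_pdb`); otherwise frame *i* (0-based,
    file order) gets ``i * default_time_step_ps``.
    """
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    _prescan(lines)
    times = _parse_time_remarks(lines)

    pdb = PDBFile.read(io.StringIO("\n".join(lines) + "\n"))
    atoms = pdb.get_structure(model=None)  # AtomArrayStack
    arr0 = atoms[0]
    topology = [
        AtomRecord(
            serial=i + 1,
            atom_name=str(arr0.atom_name[i]),
            residue_name=str(arr0.res_name[i]),
            residue_number=int(arr0.res_id[i]),
            chain_id=str(arr0.chain_id[i]) or "A",
            element=str(arr0.element[i]) or str(arr0.atom_name[i])[0],
        )
        for i in range(arr0.array_length())
    ]
    frames = []
    for i in range(atoms.stack_depth()):
        t, rep = times.get(i, (i * default_time_step_ps, replica_id))
        frames.append(Frame(np.asarray(atoms.coord[i], dtype=float), t, rep))
    return StructureEnsemble(topology, frames, label=label)


def write_multimodel_pdb(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as multi-model PDB (gzipped if the path ends in .gz).

    Per-frame times and replica labels are preserved in header remarks so
    that a read/write round trip is lossless apart from the fixed-width
    3-decimal coordinate precision of the PDB format.
    """
    n = ensemble.n_atoms
    template = struc.AtomArray(n)
    for i, a in enumerate(ensemble.topology):
        template.chain_id[i] = a.chain_id
        template.res_id[i] = a.residue_number
        template.res_name[i] = a.residue_name
        template.atom_name[i] = a.atom_name
        template.element[i] = a.element
        template.hetero[i] = False
    stack = struc.from_template(template, ensemble.coords)
    pdb = PDBFile()
    pdb.set_structure(stack)
    remarks = [
        f"{_TIME_REMARK} {i} {f.time_ps:.6g} {f.replica_id}"
        for i, f in enumerate(ensemble.frames)
    ]
    pdb.lines = remarks + pdb.lines
    path = Path(path)
    try:
        if path.suffix == ".gz":
            with gzip.open(path, "wt") as fh:
                fh.write("\n".join(pdb.lines) + "\n")
        else:
            pdb.write(path)
    except OSError as exc:
        raise IOError(f"cannot write ensemble to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Ensemble operations
# ---------------------------------------------------------------------------

def discard_equilibration(ensemble: StructureEnsemble, cutoff_ps: float) -> StructureEnsemble:
    """Drop the equilibration phase: keep frames with ``time_ps > cutoff_ps``.

    The strict inequality makes the boundary deterministic; the filter acts
    on each replica independently (times are per-replica clocks).
    """
    if cutoff_ps < 0:
        raise EnsembleError("cutoff_ps must be >= 0")
    keep = [i for i, f in enumerate(ensemble.frames) if f.time_ps > cutoff_ps]
    if not keep:
        raise EnsembleError(
            f"discarding t <= {cutoff_ps} ps removes every frame of {ensemble.label or 'ensemble'}"
        )
    return ensemble.subset_frames(keep)


def pool_replicas(ensembles: Sequence[StructureEnsemble]) -> StructureEnsemble:
    """Concatenate replicate ensembles sharing an identical topology."""
    if not ensembles:
        raise EnsembleError("nothing to pool")
    first = ensembles[0]
    for e in ensembles[1:]:
        if len(e.topology) != len(first.topology):
            raise TopologyError(
                f"cannot pool: {e.label or 'ensemble'} has {len(e.topology)} atoms, "
                f"expected {len(first.topology)}"
            )
        for i, (a, b) in enumerate(zip(first.topology, e.topology)):
            if (a.atom_name, a.residue_name, a.residue_number) != (
                b.atom_name,
                b.residue_name,
                b.residue_number,
            ):
                raise TopologyError(
                    f"cannot pool: topologies differ at atom {i} "
                    f"({a.residue_name}{a.residue_number}/{a.atom_name} vs "
                    f"{b.residue_name}{b.residue_number}/{b.atom_name})"
                )
    frames = [f for e in ensembles for f in e.frames]
    return StructureEnsemble(first.topology, frames, label=first.label)


def select_atoms(ensemble: StructureEnsemble, selection: Selection) -> StructureEnsemble:
    """Restrict an ensemble to the atoms matched by ``selection``."""
    mask = selection.mask(ensemble.topology)
    if not mask.any():
        raise SelectionError(f"selection {selection} matches no atom")
    idx = np.flatnonzero(mask)
    topology = [ensemble.topology[i] for i in idx]
    frames = [
        Frame(f.coordinates[idx], f.time_ps, f.replica_id) for f in ensemble.frames
    ]
    return StructureEnsemble(topology, frames, label=ensemble.label)
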