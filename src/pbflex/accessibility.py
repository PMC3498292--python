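"""Solvent accessible surface area (Shrake-Rupley) and relative ASA.

The absolute ASA of an atom is estimated by placing a deterministic
golden-spiral point set on its probe-expanded sphere and counting the
points not buried inside any neighbouring expanded sphere.  Residue ASA is
the sum over member atoms; the relative ASA (rASA, percent) normalises a
residue's ASA by the same residue type's ASA in an extended Ala-X-Ala
tripeptide, so values above 100% are possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .ensemble_io import Frame, StructureEnsemble, TopologyError

__all__ = [
    "RadiiSet",
    "ReferenceASATable",
    "AccessibilitySeries",
    "golden_spiral_points",
    "shrake_rupley_asa",
    "residue_asa",
    "relative_asa",
    "accessibility_series",
    "write_accessibility_tsv",
]


@dataclass(frozen=True)
class RadiiSet:
    """Van der Waals radii per element plus the solvent probe radius."""

    radii: dict
    probe_radius_A: float = 1.4
    name: str = "custom"

    def __post_init__(self):
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("all van der Waals radii must be positive")
        if self.probe_radius_A < 0:
            raise ValueError("probe radius must be >= 0")

    def radius(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise TopologyError(f"no van der Waals radius for element {element!r}") from None

    @classmethod
    def load_default(cls) -> "RadiiSet":
        with resources.files("pbflex.data").joinpath("vdw_radii.json").open() as fh:
            data = json.load(fh)
        return cls(dict(data["radii"]), data["probe_radius_A"], f"{data['name']}/{data['version']}")


@dataclass(frozen=True)
class ReferenceASATable:
    """Extended Ala-X-Ala reference accessibilities (A^2) per residue type."""

    values: dict
    name: str = "custom"

    def __post_init__(self):
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("reference ASA values must be positive")

    def reference(self, residue_name: str) -> float:
        try:
            return self.values[residue_name]
        except KeyError:
            raise KeyError(f"no reference ASA for residue type {residue_name!r}") from None

    @classmethod
    def load_default(cls) -> "ReferenceASATable":
        with resources.files("pbflex.data").joinpath("asa_reference.json").open() as fh:
            data = json.load(fh)
        return cls(dict(data["values"]), f"{data['name']}/{data['version']}")


@dataclass
class AccessibilitySeries:
    """Per-frame per-residue absolute (A^2) and relative (%) ASA."""

    residue_numbers: np.ndarray
    asa_A2: np.ndarray  # (n_frames, n_res)
    rasa_pct: np.ndarray  # (n_frames, n_res)
    times_ps: np.ndarray
    replica_ids: list[str]
    reference_name: str


def golden_spiral_points(n: int) -> np.ndarray:
    """Near-uniform deterministic point set on the unit sphere (n, 3)."""
    if n < 1:
        raise ValueError("need at least one quadrature point")
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley_asa(
    frame: Frame | np.ndarray,
    topology: Sequence,
    radii: RadiiSet | None = None,
    n_points: int = 960,
    atom_indices: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-atom solvent accessible surface area in A^2.

    For each atom the fraction of quadrature points on its probe-expanded
    sphere that fall outside every other atom's expanded sphere is
    multiplied by the full sphere area 4 pi (r + probe)^2.  All atoms act
    as occluders; ``atom_indices`` limits which atoms get a value (the
    rest are NaN), which makes single-residue series cheap.
    """
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    radii = radii or RadiiSet.load_default()
    coords = frame.coordinates if isinstance(frame, Frame) else np.asarray(frame, float)
    n = coords.shape[0]
    if len(topology) != n:
        raise TopologyError("topology and coordinates disagree on atom count")
    r = np.array([radii.radius(a.element) for a in topology]) + radii.probe_radius_A
    pts = golden_spiral_points(n_points)
    targets = np.arange(n) if atom_indices is None else np.asarray(atom_indices, int)
    tree = cKDTree(coords)
    rmax = r.max()
    out = np.full(n, np.nan)
    for i in targets:
        neigh = [j for j in tree.query_ball_point(coords[i], r[i] + rmax) if j != i]
        sphere = coords[i] + r[i] * pts
        if neigh:
            d2 = np.sum((sphere[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (r[neigh] ** 2)[None, :], axis=1)
            accessible = n_points - int(buried.sum())
        else:
            accessible = n_points
        out[i] = 4.0 * np.pi * r[i] ** 2 * accessible / n_points
    return out


def residue_asa(atom_values: np.ndarray, topology: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Sum per-atom ASA into per-residue ASA; returns (residue_numbers, asa)."""
    atom_values = np.asarray(atom_values, float)
    order: dict[int, float] = {}
    for v, a in zip(atom_values, topology):
        order[a.residue_number] = order.get(a.residue_number, 0.0) + v
    residues = np.array(list(order), dtype=int)
    return residues, np.array(list(order.values()))


def relative_asa(
    asa_A2: np.ndarray,
    residue_names: Sequence[str],
    reference: ReferenceASATable | None = None,
) -> np.ndarray:
    """rASA in percent: 100 x absolute / reference ASA of the residue type."""
    reference = reference or ReferenceASATable.load_default()
    refs = np.array([reference.reference(nm) for nm in residue_names])
    return 100.0 * np.asarray(asa_A2, float) / refs


def accessibility_series(
    ensemble: StructureEnsemble,
    residue_numbers: Sequence[int] | None = None,
    radii: RadiiSet | None = None,
    reference: ReferenceASATable | None = None,
    n_points: int = 960,
) -> AccessibilitySeries:
    """Per-frame residue ASA/rASA over an ensemble.

    Restricting ``residue_numbers`` computes quadrature only for the atoms
    of those residues (all atoms still occlude).
    """
    radii = radii or RadiiSet.load_default()
    reference = reference or ReferenceASATable.load_default()
    all_res = ensemble.residue_numbers
    wanted = all_res if residue_numbers is None else np.asarray(residue_numbers, int)
    wanted_set = set(int(x) for x in wanted)
    atom_idx = [i for i, a in enumerate(ensemble.topology) if a.residue_number in wanted_set]
    if not atom_idx:
        raise ValueError("no atoms in the requested residues")
    names = ensemble.residue_names()
    res_names = [names[int(r)] for r in wanted]
    asa = np.empty((ensemble.n_frames, len(wanted)))
    for fi, f in enumerate(ensemble.frames):
        per_atom = shrake_rupley_asa(f, ensemble.topology, radii, n_points, atom_idx)
        sums = {int(r): 0.0 for r in wanted}
        for i in atom_idx:
            sums[ensemble.topology[i].residue_number] += per_atom[i]
        asa[fi] = [sums[int(r)] for r in wanted]
    rasa = relative_asa(asa, res_names, reference)
    return AccessibilitySeries(
        wanted, asa, rasa, ensemble.times_ps, ensemble.replica_ids, reference.name
    )


def write_accessibility_tsv(series: AccessibilitySeries, path) -> None:
    rows = []
    for fi in range(series.asa_A2.shape[0]):
        for ri, r in enumerate(series.residue_numbers):
            rows.append(
                {
                    "replica_id": series.replica_ids[fi],
                    "time_ps": series.times_ps[fi],
                    "residue_number": int(r),
                    "asa_A2": series.asa_A2[fi, ri],
                    "rasa_pct": series.rasa_pct[fi, ri],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
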