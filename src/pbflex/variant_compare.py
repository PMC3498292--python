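"""End-to-end two-variant ensemble comparison.

Given two conformational ensembles of the same chain differing at one
variant residue (e.g. Leu33 vs Pro33 of integrin beta3), this module runs
the full analysis battery — per-residue RMSF, pooled essential-dynamics
projections, the variant residue's relative solvent accessibility,
contact-count and centre-of-mass-distance distributions against named
domains, and the Protein Blocks Neq/dNeq flexibility comparison — and
collects everything into a single report with deterministic, exportable
tables plus representative snapshots picked from the jointly most
frequent (rASA bin, contact count) class.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .accessibility import (
    AccessibilitySeries,
    RadiiSet,
    ReferenceASATable,
    accessibility_series,
    write_accessibility_tsv,
)
from .ensemble_io import (
    EnsembleError,
    Selection,
    StructureEnsemble,
    discard_equilibration,
    pool_replicas,
    select_atoms,
    write_multimodel_pdb,
)
from .essential_dynamics import (
    CovarianceModel,
    ModeProjection,
    build_covariance,
    project,
    spread,
    variance_fraction,
    write_eigenvalues_tsv,
    write_projections_tsv,
)
from .geometry import (
    ContactSeries,
    DistanceSeries,
    backbone_dihedrals,
    com_distance_series,
    contact_counts,
    contacts_by_partner_domain,
    rmsf_profile,
    write_distance_tsv,
    write_rmsf_tsv,
)
from .pb_alphabet import (
    DeltaNeqReport,
    NeqProfile,
    PBProfile,
    PBPrototypeTable,
    assign_ensemble,
    delta_neq,
    neq_profile,
    pb_profile,
    write_delta_neq_tsv,
    write_pb_fasta,
)

__all__ = [
    "DomainDefinition",
    "ComparisonConfig",
    "Histogram",
    "VariantReport",
    "histogram",
    "select_representatives",
    "run_comparison",
    "export_report",
]


@dataclass(frozen=True)
class DomainDefinition:
    """Named inclusive residue ranges plus the variant residue position.

    Defaults are the integrin beta3 knee: PSI 1-56, I-EGF-1 434-472,
    I-EGF-2 473-522, variant residue 33 (mature-sequence numbering).
    """

    domains: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "PSI": (1, 56),
            "I-EGF-1": (434, 472),
            "I-EGF-2": (473, 522),
        }
    )
    variant_residue: int = 33

    def __post_init__(self):
        items = list(self.domains.items())
        if not items:
            raise ValueError("at least one domain must be defined")
        for i, (na, (lo, hi)) in enumerate(items):
            if lo > hi:
                raise ValueError(f"domain {na} has an empty range")
            for nb, (blo, bhi) in items[i + 1 :]:
                if lo <= bhi and blo <= hi:
                    raise ValueError(f"domains {na} and {nb} overlap")
        hosts = [n for n, (lo, hi) in items if lo <= self.variant_residue <= hi]
        if len(hosts) != 1:
            raise ValueError(
                f"variant residue {self.variant_residue} must fall in exactly one domain "
                f"(found {hosts or 'none'})"
            )

    @property
    def host_domain(self) -> str:
        for n, (lo, hi) in self.domains.items():
            if lo <= self.variant_residue <= hi:
                return n
        raise AssertionError

    @property
    def partner_domains(self) -> list[str]:
        return [n for n in self.domains if n != self.host_domain]


@dataclass(frozen=True)
class ComparisonConfig:
    """Tunable thresholds and binning of the comparison pipeline."""

    equilibration_cutoff_ps: float = 5000.0
    contact_cutoff_A: float = 8.0
    contact_exclusion: int = 0
    rasa_bin_width_pct: float = 5.0
    contact_bin_width: float = 1.0
    com_bin_width_A: float = 1.0
    delta_neq_threshold: float = 1.5
    neq_rigid_threshold: float = 2.5
    n_representatives: int = 3
    sasa_n_points: int = 960
    pca_modes: tuple[int, int] = (0, 1)
    seed: int = 0

    def __post_init__(self):
        for name in ("contact_cutoff_A", "rasa_bin_width_pct", "contact_bin_width", "com_bin_width_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.equilibration_cutoff_ps < 0:
            raise ValueError("equilibration_cutoff_ps must be >= 0")
        if self.n_representatives < 1:
            raise ValueError("n_representatives must be >= 1")


@dataclass
class Histogram:
    """Left-closed right-open bins with relative frequencies summing to 1."""

    edges: np.ndarray  # (n_bins + 1,)
    frequencies: np.ndarray  # (n_bins,)

    def modal_bin(self) -> int:
        return int(np.argmax(self.frequencies))


def histogram(values, bin_width: float, value_range: tuple[float, float] | None = None) -> Histogram:
    """Relative-frequency histogram with fixed-width [lo, hi) bins."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("cannot histogram an empty series")
    if value_range is None:
        lo = np.floor(v.min() / bin_width) * bin_width
        hi = v.max()
    else:
        lo, hi = value_range
        if np.any(v < lo) or np.any(v >= hi + bin_width):
            raise ValueError("values fall outside the requested range")
    n_bins = int(np.floor((hi - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    return Histogram(edges, counts / v.size)


@dataclass
class VariantReport:
    """Everything the two-variant comparison produces."""

    label_a: str
    label_b: str
    # flexibility profiles
    rmsf_residues: np.ndarray
    rmsf_a: np.ndarray
    rmsf_b: np.ndarray
    # essential dynamics in the pooled basis
    eigenvalues: np.ndarray
    variance_fractions: tuple[float, float]
    projections_a: ModeProjection
    projections_b: ModeProjection
    spread_a: np.ndarray
    spread_b: np.ndarray
    # variant-residue exposure / packing
    rasa_a: AccessibilitySeries
    rasa_b: AccessibilitySeries
    rasa_hist_a: Histogram
    rasa_hist_b: Histogram
    contacts_a: np.ndarray
    contacts_b: np.ndarray
    contact_hist_a: Histogram
    contact_hist_b: Histogram
    contacts_by_domain_a: dict[str, np.ndarray]
    contacts_by_domain_b: dict[str, np.ndarray]
    com_a: dict[str, DistanceSeries]
    com_b: dict[str, DistanceSeries]
    com_hist_a: dict[str, Histogram]
    com_hist_b: dict[str, Histogram]
    # Protein Blocks statistics
    pb_profile_a: PBProfile
    pb_profile_b: PBProfile
    neq_a: NeqProfile
    neq_b: NeqProfile
    delta_neq_report: DeltaNeqReport
    # representatives (frame index, replica_id, time_ps) into the pooled ensembles
    representatives_a: list[tuple[int, str, float]]
    representatives_b: list[tuple[int, str, float]]
    # the pooled post-equilibration ensembles the report was computed on
    ensemble_a: StructureEnsemble
    ensemble_b: StructureEnsemble
    provenance: dict

    @property
    def significant_residues(self) -> list[int]:
        return self.delta_neq_report.significant_residues()


def select_representatives(
    ensemble: StructureEnsemble,
    rasa_values: np.ndarray,
    contact_values: np.ndarray,
    k: int = 3,
    rasa_bin_width: float = 5.0,
    contact_bin_width: float = 1.0,
) -> list[tuple[int, str, float]]:
    """Pick up to k frames from the jointly most frequent structural class.

    The modal bin of the variant residue's rASA histogram and the modal
    contact count define the target class; frames falling in both are
    returned in time order.  If fewer than k qualify, the class is relaxed
    to nearest-neighbour bins, widening the contact class before the rASA
    class, until k frames are found or the ensemble is exhausted.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rasa_values = np.asarray(rasa_values, float)
    contact_values = np.asarray(contact_values, float)
    if len(rasa_values) != ensemble.n_frames or len(contact_values) != ensemble.n_frames:
        raise EnsembleError("series are not aligned with the ensemble frames")
    rasa_hist = histogram(rasa_values, rasa_bin_width)
    cont_hist = histogram(contact_values, contact_bin_width)
    rasa_bins = np.clip(
        ((rasa_values - rasa_hist.edges[0]) // rasa_bin_width).astype(int),
        0,
        len(rasa_hist.frequencies) - 1,
    )
    cont_bins = np.clip(
        ((contact_values - cont_hist.edges[0]) // contact_bin_width).astype(int),
        0,
        len(cont_hist.frequencies) - 1,
    )
    modal_rasa = rasa_hist.modal_bin()
    modal_cont = cont_hist.modal_bin()
    times = ensemble.times_ps
    reps = ensemble.replica_ids
    order = sorted(range(ensemble.n_frames), key=lambda i: (times[i], reps[i]))

    max_rc = max(modal_cont, len(cont_hist.frequencies) - 1 - modal_cont)
    max_ra = max(modal_rasa, len(rasa_hist.frequencies) - 1 - modal_rasa)
    # Relaxation schedule: smallest total widening first; on ties widen the
    # contact class before the rASA class.
    schedule = sorted(
        ((rc, ra) for rc in range(max_rc + 1) for ra in range(max_ra + 1)),
        key=lambda p: (p[0] + p[1], p[1]),
    )
    chosen: list[int] = []
    seen: set[int] = set()
    for rc, ra in schedule:
        for i in order:
            if i in seen:
                continue
            if abs(cont_bins[i] - modal_cont) <= rc and abs(rasa_bins[i] - modal_rasa) <= ra:
                chosen.append(i)
                seen.add(i)
        if len(chosen) >= k:
            break
    chosen = chosen[:k]
    return [(i, reps[i], float(times[i])) for i in chosen]


def _prepare(
    ensemble: StructureEnsemble | Sequence[StructureEnsemble],
    cutoff_ps: float,
) -> StructureEnsemble:
    if isinstance(ensemble, StructureEnsemble):
        pooled = ensemble
    else:
        pooled = pool_replicas(list(ensemble))
    if cutoff_ps > 0 and any(f.time_ps <= cutoff_ps for f in pooled.frames):
        pooled = discard_equilibration(pooled, cutoff_ps)
    return pooled


def _check_residue_sets(a: StructureEnsemble, b: StructureEnsemble, variant: int) -> None:
    ra, rb = a.residue_numbers, b.residue_numbers
    if len(ra) != len(rb) or np.any(ra != rb):
        raise EnsembleError("ensembles cover different residue sets")
    if variant not in set(int(r) for r in ra):
        raise EnsembleError(f"variant residue {variant} absent from the ensembles")
    na, nb = a.residue_names(), b.residue_names()
    diff = [r for r in na if na[r] != nb[r] and r != variant]
    if diff:
        raise EnsembleError(
            f"residue types differ away from the variant position: {diff[:5]}"
        )


def _pooled_ca_ensemble(a: StructureEnsemble, b: StructureEnsemble) -> StructureEnsemble:
    """CA frames of both variants over one topology, for a shared PCA basis."""
    ca_a = select_atoms(a, Selection.calpha())
    ca_b = select_atoms(b, Selection.calpha())
    frames = []
    # Prefix with the variant's own label so the pooled frame order (and
    # hence the PCA basis) is invariant under swapping the two arguments.
    for sub in (ca_a, ca_b):
        prefix = (sub.label or "ens") + ":"
        for f in sub.frames:
            frames.append(dataclasses.replace(f, replica_id=prefix + f.replica_id))
    return StructureEnsemble(ca_a.topology, frames, label="pooled")


def run_comparison(
    ensemble_a: StructureEnsemble | Sequence[StructureEnsemble],
    ensemble_b: StructureEnsemble | Sequence[StructureEnsemble],
    domains: DomainDefinition | None = None,
    config: ComparisonConfig | None = None,
    radii: RadiiSet | None = None,
    asa_reference: ReferenceASATable | None = None,
) -> VariantReport:
    """Run the full two-variant analysis and assemble the report.

    Each input may be a single ensemble or a list of replicas to pool.
    The pipeline is deterministic given the inputs and the configuration.
    """
    domains = domains or DomainDefinition()
    config = config or ComparisonConfig()
    table = PBPrototypeTable.load_default()
    radii = radii or RadiiSet.load_default()
    asa_reference = asa_reference or ReferenceASATable.load_default()

    ens_a = _prepare(ensemble_a, config.equilibration_cutoff_ps)
    ens_b = _prepare(ensemble_b, config.equilibration_cutoff_ps)
    _check_residue_sets(ens_a, ens_b, domains.variant_residue)
    label_a = ens_a.label or "A"
    label_b = ens_b.label or "B"
    variant = domains.variant_residue

    # Per-residue fluctuation profiles (Calpha).
    res_a, rmsf_a = rmsf_profile(ens_a)
    _, rmsf_b = rmsf_profile(ens_b)

    # Essential dynamics in a common basis built on the pooled ensembles.
    pooled = _pooled_ca_ensemble(ens_a, ens_b)
    model = build_covariance(pooled)
    modes = list(config.pca_modes)
    proj_a = project(model, select_atoms(ens_a, Selection.calpha()), modes)
    proj_a.label = label_a
    proj_b = project(model, select_atoms(ens_b, Selection.calpha()), modes)
    proj_b.label = label_b

    # Variant-residue exposure.
    rasa_a = accessibility_series(
        ens_a, [variant], radii, asa_reference, config.sasa_n_points
    )
    rasa_b = accessibility_series(
        ens_b, [variant], radii, asa_reference, config.sasa_n_points
    )
    rasa_hist_a = histogram(rasa_a.rasa_pct[:, 0], config.rasa_bin_width_pct)
    rasa_hist_b = histogram(rasa_b.rasa_pct[:, 0], config.rasa_bin_width_pct)

    # Variant-residue contacts, total and split by partner domain.
    def _variant_contacts(ens):
        series = contact_counts(ens, config.contact_cutoff_A, config.contact_exclusion)
        col = int(np.flatnonzero(series.residue_numbers == variant)[0])
        total = series.counts[:, col]
        by_dom = contacts_by_partner_domain(
            ens, variant, dict(domains.domains), config.contact_cutoff_A, config.contact_exclusion
        )
        return total, by_dom

    contacts_a, by_dom_a = _variant_contacts(ens_a)
    contacts_b, by_dom_b = _variant_contacts(ens_b)
    cont_hist_a = histogram(contacts_a, config.contact_bin_width)
    cont_hist_b = histogram(contacts_b, config.contact_bin_width)

    # Centre-of-mass distances to every non-host domain.
    var_sel = Selection.residues([variant])
    com_a: dict[str, DistanceSeries] = {}
    com_b: dict[str, DistanceSeries] = {}
    com_hist_a: dict[str, Histogram] = {}
    com_hist_b: dict[str, Histogram] = {}
    for dom in domains.partner_domains:
        dom_sel = Selection(residue_range=domains.domains[dom])
        com_a[dom] = com_distance_series(ens_a, var_sel, dom_sel, f"res{variant}", dom)
        com_b[dom] = com_distance_series(ens_b, var_sel, dom_sel, f"res{variant}", dom)
        com_hist_a[dom] = histogram(com_a[dom].values_A, config.com_bin_width_A)
        com_hist_b[dom] = histogram(com_b[dom].values_A, config.com_bin_width_A)

    # Protein Blocks flexibility statistics.
    def _neq(ens, label):
        assignments = assign_ensemble(backbone_dihedrals(ens), table)
        assignments.times_ps = ens.times_ps
        assignments.replica_ids = ens.replica_ids
        profile = pb_profile(assignments)
        return assignments, profile, neq_profile(profile, label)

    asg_a, prof_a, neq_a = _neq(ens_a, label_a)
    asg_b, prof_b, neq_b = _neq(ens_b, label_b)
    report = delta_neq(neq_a, neq_b, config.delta_neq_threshold, config.neq_rigid_threshold)

    reps_a = select_representatives(
        ens_a, rasa_a.rasa_pct[:, 0], contacts_a, config.n_representatives,
        config.rasa_bin_width_pct, config.contact_bin_width,
    )
    reps_b = select_representatives(
        ens_b, rasa_b.rasa_pct[:, 0], contacts_b, config.n_representatives,
        config.rasa_bin_width_pct, config.contact_bin_width,
    )

    provenance = {
        "pbflex_version": _pkg_version,
        "pb_table": table.version,
        "radii_set": radii.name,
        "asa_reference": asa_reference.name,
        "config": dataclasses.asdict(config),
        "domains": {k: list(v) for k, v in domains.domains.items()},
        "variant_residue": variant,
        "n_frames_a": ens_a.n_frames,
        "n_frames_b": ens_b.n_frames,
        "label_a": label_a,
        "label_b": label_b,
        "pca_note": "covariance built on the pooled variants, both projected in one basis",
    }
    return VariantReport(
        label_a=label_a,
        label_b=label_b,
        rmsf_residues=res_a,
        rmsf_a=rmsf_a,
        rmsf_b=rmsf_b,
        eigenvalues=model.eigenvalues,
        variance_fractions=(
            variance_fraction(model, 1),
            variance_fraction(model, 2) - variance_fraction(model, 1),
        ),
        projections_a=proj_a,
        projections_b=proj_b,
        spread_a=spread(proj_a),
        spread_b=spread(proj_b),
        rasa_a=rasa_a,
        rasa_b=rasa_b,
        rasa_hist_a=rasa_hist_a,
        rasa_hist_b=rasa_hist_b,
        contacts_a=contacts_a,
        contacts_b=contacts_b,
        contact_hist_a=cont_hist_a,
        contact_hist_b=cont_hist_b,
        contacts_by_domain_a=by_dom_a,
        contacts_by_domain_b=by_dom_b,
        com_a=com_a,
        com_b=com_b,
        com_hist_a=com_hist_a,
        com_hist_b=com_hist_b,
        pb_profile_a=prof_a,
        pb_profile_b=prof_b,
        neq_a=neq_a,
        neq_b=neq_b,
        delta_neq_report=report,
        representatives_a=reps_a,
        representatives_b=reps_b,
        ensemble_a=ens_a,
        ensemble_b=ens_b,
        provenance=provenance,
    )


def _write_histogram_tsv(hist: Histogram, path) -> None:
    pd.DataFrame(
        {
            "bin_left": hist.edges[:-1],
            "bin_right": hist.edges[1:],
            "frequency": hist.frequencies,
        }
    ).to_csv(path, sep="\t", index=False)


def export_report(report: VariantReport, out_dir) -> list[Path]:
    """Write every profile, distribution and summary of a report to disk.

    Produces TSV tables, a flat key-value summary, and multi-model PDB
    files holding the representative frames of each variant.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(name, writer, *args):
        path = out / name
        writer(*args, path)
        written.append(path)

    la, lb = report.label_a, report.label_b
    rmsf_df = pd.DataFrame(
        {
            "residue_number": report.rmsf_residues,
            f"rmsf_{la}_A": report.rmsf_a,
            f"rmsf_{lb}_A": report.rmsf_b,
        }
    )
    path = out / "rmsf.tsv"
    rmsf_df.to_csv(path, sep="\t", index=False)
    written.append(path)

    _w("delta_neq.tsv", write_delta_neq_tsv, report.delta_neq_report)
    _w(f"projections_{la}.tsv", write_projections_tsv, report.projections_a)
    _w(f"projections_{lb}.tsv", write_projections_tsv, report.projections_b)
    _w(f"rasa_{la}.tsv", write_accessibility_tsv, report.rasa_a)
    _w(f"rasa_{lb}.tsv", write_accessibility_tsv, report.rasa_b)
    _w(f"rasa_hist_{la}.tsv", _write_histogram_tsv, report.rasa_hist_a)
    _w(f"rasa_hist_{lb}.tsv", _write_histogram_tsv, report.rasa_hist_b)
    _w(f"contact_hist_{la}.tsv", _write_histogram_tsv, report.contact_hist_a)
    _w(f"contact_hist_{lb}.tsv", _write_histogram_tsv, report.contact_hist_b)
    for dom in report.com_a:
        safe = dom.replace("/", "_")
        _w(f"com_{safe}_{la}.tsv", write_distance_tsv, report.com_a[dom])
        _w(f"com_{safe}_{lb}.tsv", write_distance_tsv, report.com_b[dom])
        _w(f"com_hist_{safe}_{la}.tsv", _write_histogram_tsv, report.com_hist_a[dom])
        _w(f"com_hist_{safe}_{lb}.tsv", _write_histogram_tsv, report.com_hist_b[dom])

    for label, ens, reps in (
        (la, report.ensemble_a, report.representatives_a),
        (lb, report.ensemble_b, report.representatives_b),
    ):
        if reps:
            sub = ens.subset_frames([i for i, _, _ in reps])
            path = out / f"representatives_{label}.pdb"
            write_multimodel_pdb(sub, path)
            written.append(path)

    path = out / "summary.txt"
    with open(path, "w") as fh:
        fh.write(f"label_a\t{la}\nlabel_b\t{lb}\n")
        fh.write(
            "significant_residues\t"
            + ",".join(map(str, report.significant_residues))
            + "\n"
        )
        fh.write(f"mode1_spread_{la}_A\t{report.spread_a[0]:.6g}\n")
        fh.write(f"mode1_spread_{lb}_A\t{report.spread_b[0]:.6g}\n")
        fh.write(f"mode1_variance_fraction\t{report.variance_fractions[0]:.6g}\n")
        fh.write(f"mode2_variance_fraction\t{report.variance_fractions[1]:.6g}\n")
        for key, value in report.provenance.items():
            fh.write(f"provenance.{key}\t{value}\n")
    written.append(path)
    return written
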