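# Methods

## Problem setting

Point variants such as the Leu33Pro (HPA-1a/HPA-1b) polymorphism of the
integrin β3 subunit can change a protein's behaviour without changing its
average structure: the variants differ in how the conformational *ensemble*
is distributed.  `pbflex` implements the ensemble-comparison toolbox used
to characterise such contrasts: a structural-alphabet description of local
backbone conformation with an entropy-based flexibility statistic, plus
the classical geometric descriptors (RMSD/RMSF, contacts, solvent
accessibility, centre-of-mass distances, essential dynamics) computed
per frame over multi-model PDB ensembles.

## Protein Blocks and Neq

Local backbone conformation is coarse-grained with the 16-letter Protein
Blocks (PB) alphabet.  Each letter `a`–`p` is a prototype of 8 dihedral
angles spanning five consecutive residues, ordered
ψ(i−2), φ(i−1), ψ(i−1), φ(i), ψ(i), φ(i+1), ψ(i+1), φ(i+2).  The 16×8
reference table is shipped as a versioned JSON data file
(`pbflex/data/pb_prototypes.json`) with provenance metadata and a SHA-256
checksum over the angle payload; the loader refuses a corrupted file.

Assignment: for each residue of each frame the observed window is compared
to all 16 prototypes with the RMSDA metric,

    rmsda(w, p) = sqrt( (1/8) Σ_k wrap(w_k − p_k)² ),

where `wrap` maps angle differences to the shortest arc in (−180°, 180°].
The letter with the minimal RMSDA wins; exact ties break alphabetically
(deterministic and order-independent).  Positions whose window contains an
undefined angle — always the two first and two last residues — are marked
`Z` and excluded from all statistics (no imputation).

Per-residue PB frequencies `f` over the frames give the equivalent number
of PBs,

    Neq = exp( − Σ_x f_x ln f_x ),      0·ln 0 ≡ 0,

which ranges from 1 (one conformation, rigid) to 16 (uniform over the
alphabet).  Two ensembles A and B are compared through
ΔNeq = |Neq_A − Neq_B| per residue; a residue is flagged *significant*
when ΔNeq > 1.5 **and** min(Neq_A, Neq_B) < 2.5, both inequalities strict.
The thresholds are configurable (`ComparisonConfig.delta_neq_threshold`,
`.neq_rigid_threshold`) but the defaults are the standard rule.

## Geometric descriptors

* **Torsions** follow the IUPAC sign convention (right-handed α-helix:
  φ ≈ −57°, ψ ≈ −47°); all angles are reported in (−180°, 180°].
* **Superposition** is a weighted Kabsch fit (SVD, proper rotation
  enforced).  RMSD series are post-fit values on the measured selection
  (Cα by default).  RMSF uses an iterated mean reference: frames are
  fitted to the first frame, a mean structure is formed, and the
  fit→mean cycle is run twice; `reference="first"` is available.  The
  same superposition convention backs the PCA, so Σ RMSF² equals the
  covariance trace exactly.
* **Contacts**: residues i, j are in contact when d(Cα_i, Cα_j) ≤ 8 Å,
  boundary inclusive.  The sequence-neighbour exclusion defaults to 0
  (|i−j| > 0, i.e. neighbours count), so an interior residue of an ideal
  extended chain has 4 contacts; the exclusion is configurable because
  published contact definitions differ on this point.
* **Centres of mass** are heavy-atom mass-weighted means (standard
  element masses; ensembles carry no hydrogens).
* **Essential dynamics**: frames are superposed (iterated-mean reference
  by default), the 3N×3N covariance of Cα coordinates is built with the
  1/F normalisation and diagonalised.  Eigenvalue k therefore equals the
  variance of the ensemble's own projections on mode k.  Eigenvector
  orientation is fixed by making the largest-magnitude component
  positive.  PCA is mass-unweighted.  When two variants are compared,
  the covariance is built on the **pooled** ensembles so both project
  into one basis; pooled frames are ordered by variant label, making the
  basis invariant under swapping the two inputs.  The report's
  provenance block records this pooling choice.

## Solvent accessibility

ASA uses the Shrake–Rupley construction with a deterministic
golden-spiral quadrature (default 960 points) on each atom's
probe-expanded sphere (probe 1.4 Å); a point is accessible when it lies
outside every other atom's expanded sphere.  Van der Waals radii are an
element-class united-heavy-atom set shipped as a versioned data file and
fully configurable.  The deterministic point set makes results
bit-reproducible across runs and platforms; against closed forms the
quadrature is within 1% for an isolated sphere and 1.5% for two
overlapping spheres at 960 points.

Relative ASA divides a residue's ASA by the same residue type's ASA in an
extended Ala-X-Ala tripeptide (Leu 183 Å², Pro 142 Å²; the remaining
types follow the Miller et al. 1987 tripeptide table) and is reported in
percent, values above 100% being possible.  When only the variant
residue's series is needed, quadrature is restricted to its atoms while
all atoms still occlude, making per-frame series cheap.

## Ensemble handling

Multi-model PDB files (optionally gzipped) are parsed and written through
biotite; a pre-scan produces model-numbered topology errors and
line-numbered parse errors.  The PDB format carries no time field, so
frame times default to model-order × a configurable step (100 ps);
files written by this package embed per-frame time/replica remarks that
survive a round trip.  Author residue numbering is authoritative and
never remapped.  Only single-chain ensembles are accepted.

Equilibration discard keeps frames with `time_ps > cutoff` (strict, per
replica); the default cutoff is 5 000 ps.  Under this convention a
sampling campaign of four 50 ns replicas plus one 100 ns replica at
100 ps spacing retains 2 750 frames.  (Published analyses of such a
campaign sometimes quote 2 749; no endpoint convention reproduces that
count exactly, so the package fixes its own and documents it here.)

## Synthetic ensembles

The generator draws, per frame, a full-length PB "recipe" from a weighted
mixture, sets each residue's (φ, ψ) to the *central* angle pair of its
letter's prototype, adds independent wrapped-normal noise (σ in degrees,
scalar or per residue), and rebuilds the backbone with NeRF chain
building from ideal peptide geometry (N–Cα 1.458 Å, Cα–C 1.525 Å,
C–N 1.329 Å; N–Cα–C 111.0°, Cα–C–N 116.5°, C–N–Cα 121.5°; ω = 180°).
Carbonyl O is placed in the peptide plane anti to the next amide N and an
ideal Cβ is added with L-amino-acid chirality (C–N–Cα–Cβ = −122.5°);
hydrogens are omitted.  Rebuilt chains reproduce their input torsions to
< 1e-6°, and the construction is deterministic and byte-identical for a
given seed.

Because a residue's angles come from its own letter only, a run of
identical letters gives a window exactly consistent with overlapping
five-residue windows; recovery guarantees therefore apply at positions
whose ±2 window is homogeneous.  Only the structurally repetitive letters
`d` (extended) and `m` (helix) are fixed points of this construction —
homogeneous runs of the cap/turn letters assign to other letters (e.g. a
run of `i` central angles assigns to `n`, `j` to `e`).  Mixture tests
exploit this: equal mixtures of `d`/`m`/`i`/`j` runs produce exactly k
distinct assigned states, so Neq measures k.

Wrapped-normal (rather than von Mises) noise was chosen for exact
circular-SD control and trivial seeding.

### What the generator does and does not emulate

It reproduces the statistical structure the analyses assume — per-residue
local-conformation mixtures, tunable angular noise, replicas, frame
times — with exact ground truth.  It has no physics: no sterics beyond
ideal geometry, no side chains beyond Cβ, no solvent, no correlation
between frames (frames are i.i.d. draws, not a dynamical trajectory).
Passing tests therefore validate the *analysis machinery* (assignment,
statistics, geometry, accounting), not any claim about real protein
energetics or about reproducing molecular-dynamics observables.

### The packaged two-variant scenario

`two_variant_scenario(seed, n_frames=2000, n_residues=60)` builds a
60-residue chain of three 20-residue "domains" with the variant residue
at position 10.  Variant A (Leu-like) is the base recipe — extended with
a helical insert in the third quarter — at σ = 5°.  Variant B (Pro-like)
is identical except inside the 5-residue window around the variant
residue: a helical recipe is mixed in with weight 0.5 and 40° of extra
angular noise is added in quadrature.  The mixture doubles the local PB
states and the noise scatters window assignments into further letters,
driving the window Neq past the 2.5/1.5 significance rule, while the
intermittent helical kink bends the chain so the variant residue packs
against downstream residues (more contacts, shorter centre-of-mass
distances) — the qualitative signature of a flexibility-gaining variant.
These generator settings are the packaged study conditions; tests run the
scenario over 20 seeds at 400 frames per variant and require 18/20
successes for each contrast, and the full-size run (2 × 2000 frames)
completes in well under a minute.

## Representative-frame selection

For each variant the modal bin of the variant residue's rASA histogram
(default width 5%) and the modal contact count (width 1) define the most
frequent structural class; up to k frames (default 3) falling in *both*
modal classes are returned in time order.  If fewer than k qualify, the
class is widened to nearest-neighbour bins, contacts before rASA — the
joint-modal rule and the relaxation order are this package's own
conventions, since "most frequent structures" admits several readings.

## Numerical choices and degenerate inputs

* Angle wrapping maps to (−180°, 180]; −180° inputs normalise to +180°.
* `neq` rejects frequency vectors whose sum deviates from 1 by more than
  1e-6; Neq is clamped by construction to [1, 16].
* Superposition requires ≥3 points; collinear torsion reference points
  raise rather than return an arbitrary value.
* Histograms are left-closed right-open with an edge grid anchored at a
  bin-width multiple, so equal inputs land in identical bins across runs.
* Empty ensembles, empty selections, all-discarded equilibration filters
  and residue-set mismatches raise typed errors early.
* Covariance eigenvalues are clipped only by an assertion tolerance
  (−1e-8) — no silent flooring.

## Known limitations

* PB assignment fidelity is only guaranteed at homogeneous-window
  positions of synthetic recipes; real ensembles have no such guarantee
  (nor do they need one — assignment is still well defined everywhere).
* The SASA radii set is element-class based; per-atom-class radii (e.g.
  distinguishing carbonyl from aliphatic carbon) can be supplied but are
  not the default.
* The equilibration filter trusts frame times; files without time
  remarks get model-order times, which is only correct for uniformly
  sampled trajectories.
* Multi-chain ensembles and binary trajectory formats are out of scope.
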