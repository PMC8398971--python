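# Methods

## The model

`frdex` computes electronic circular dichroism (ECD) and absorption spectra
of closely stacked multichromophore assemblies — G-quadruplexes (GQs) being
the flagship case — from an excitonic Hamiltonian that includes
charge-transfer (CT) basis states alongside the local excitations (LEs).

An excitonic state is expanded as

    |Psi_k> = sum_{m,alpha} C_{m alpha,k} |L_alpha^m>
            + sum_{m != n, gamma} C_{mn gamma,k} |CT_gamma^{m->n}>

where m runs over the chromophores (here: nucleobases reduced to their ring
+ exocyclic heavy atoms), alpha over the LEs of each base (for guanine the
two pi-pi* states La and Lb), and gamma over the CT transitions moving an
electron from donor m to acceptor n.  The Hamiltonian splits into an
intra-molecular part (per-site LE energies and same-site La-Lb couplings,
both "dressed" by the environment) and an inter-molecular part (cross-site
LE-LE couplings, CT energies, LE-CT couplings on the hole and electron
side, and CT-CT couplings in the same and opposite direction).

### Fragment diabatization

All of these energies and couplings are obtained by diabatizing the
adiabatic states of small supramolecular complexes (SCs — pairs, strands or
tetrads of bases).  Given the overlap matrix `S = <R_frags | a_SC>` between
reference fragment states and the SC adiabats, the diabatizing transform is
the Loewdin / symmetric-orthogonalization solution

    D = S^T (S S^T)^(-1/2),      H_d = D^T H_a D,

with `H_a` the diagonal matrix of adiabatic energies.  `D` is computed from
the SVD `S = U diag(s) V^T` as `D = V U^T`, which is simultaneously the
column-orthonormal matrix closest to `S^T` in Frobenius norm (orthogonal
Procrustes).  Transition properties transform by the same columns of `D`.
Singular values of `S` below 1e-6 (configurable) raise an error naming the
offending reference state rather than silently dropping it; reference-state
completeness (row norm of `S`) below 0.5 triggers a warning, since an
incomplete projection is the main practical failure mode when geometry
fluctuations destabilize the CT states.

Adiabatic and reference phases are arbitrary; each adiabatic column of `S`
is sign-fixed so its largest-magnitude entry is positive (ties resolved by
the lowest reference index), and the same signs are applied to the
adiabatic property vectors.  `H_d` itself is invariant under any sign
pattern; the convention only pins down `D` and the diabatic property
vectors reproducibly.

### Hamiltonian assembly

Inter-molecular blocks come from pair SCs over a nearest-neighbour graph
with three pair classes: *stacked* (consecutive bases along a strand, in
adjacent tetrads), *hbonded* (cyclic Hoogsteen partners within a tetrad)
and *diagonal* (a base paired with the H-bond neighbours of its stacking
partner).  Intra-molecular parameters come either from averaging the
already-diabatized pairs over each base (`pair_averaged`, unweighted mean
of energies and of same-site La-Lb couplings — the averaging rule for the
couplings mirrors the one for energies) or from an LE-only diabatization of
a strand or tetrad SC (which by default updates both the site energies and
the same-site couplings).  CT basis states are attached to every
nearest-neighbour pair class by default; a `ct_policy="stacked"` switch
restricts them to the physically dominant stacked pairs.

The LE-only Frenkel/Coulombic baseline (FHC) uses isolated-monomer site
energies and electrostatic couplings, either point-dipole or atomic
transition charges (`V = sum_ab q_a q_b / r_ab`); since the Coulomb
interaction is long-range, FHC couples all pairs by default, with an option
to truncate to the diabatized model's connectivity for controlled
comparisons.

Units: Hamiltonians in eV, transition dipoles in atomic units, coordinates
in Angstrom; every conversion goes through `frdex.constants`.

### Rotational strengths

The per-state velocity-gauge rotational strength is evaluated as

    R_k = sum_i C_ik^2 Im(mu_i . m_i)
        - sum_{i<j} C_ik C_jk (E_ref / 2c) (r_i - r_j) . (mu_i x mu_j)

(atomic units; `c` the speed of light, 137.036).  The first term is the
intrinsic site contribution; the second is the extrinsic coupled-oscillator
term.  Two structural choices matter:

* only coordinate *differences* enter, so every `R_k` is exactly invariant
  under rigid translations (and, with the dipoles co-rotated, rotations);
* the extrinsic prefactor `E_ref/(2c)` is *state-independent* — `E_ref` is
  the mean LE site energy — so eigenvector orthonormality makes the
  extrinsic part cancel exactly in `sum_k R_k`, which therefore equals the
  intrinsic total (zero when intrinsic magnetic moments vanish: the CD of
  an electric-dipole exciton system is conservative).  Using per-state
  energies in the prefactor would break this sum rule and would let
  high-lying basis states (e.g. artificially decoupled CT states) leak
  intensity through negligible admixtures.  Across the 4.9-5.3 eV band the
  approximation error of a common prefactor is a few percent, well below
  the other model uncertainties.

The sign convention is fixed by the expression above; only relative signs
(couplet structure) are meaningful.  Rotational strengths are reported in
the customary 1e-40 cgs units (1 a.u. = 471.4436e-40 cgs) with an `au`
toggle.  Oscillator strengths are `f_k = (2/3) E_k |sum_i C_ik mu_i|^2`.
CT basis states carry their diabatized electric/magnetic dipoles; if a
parametrization provides none, CT states contribute intensity only through
mixing with the LEs.  Velocity-gauge electric dipoles are preferred and the
gauge provenance is carried as a flag; length-gauge input is accepted and
used as-is (exact for complete bases), flagged in the output metadata.

### Spectra

Stick spectra are broadened with unit-area Gaussians in the energy domain
(default sigma 0.21 eV), red-shifted by a constant (default -0.85 eV, the
empirical shift aligning the computed guanine monomer spectrum with
experiment), and sampled on a wavelength grid (default 220-340 nm at
0.5 nm).  The shift applies to stick energies only, after diagonalization.
Snapshot ensembles are averaged pointwise.  Peak normalization scales a
curve so its lowest-energy extremum matches a reference (scalar or another
curve) and stores the factor so sibling curves can reuse it without each
being forced to peak 1 (intensities are in arbitrary units, because
experimental nucleobase concentrations are themselves uncertain).

## Geometry

Structures are read from (multi-model) PDB files; each nucleobase residue
is reduced to a whitelist of base heavy atoms (purines: the 9 ring atoms
plus O6/N2 or N6; thymine: the 6 ring atoms plus O2/O4/C7), discarding
backbone, hydrogens, ions and solvent.  Base internal geometries can be
idealized by rigidly superposing an optimized template (Kabsch, via SVD;
hydrogens excluded; atom correspondence by canonical atom name), which
replaces each base's internal geometry exactly while preserving its pose.

Stacking overlap areas project both bases' ring + exocyclic atoms onto a
single common plane and intersect the convex hulls of the projections
(exact polygon clipping).  The common plane passes through the midpoint of
the two ring centroids with its normal along the *bisector* of the two
per-base mean-plane normals.  A plane fitted to the union of the two atom
sets — the obvious alternative — fails for cofacial pairs: at a 3.4 A
stacking separation the union cloud has *less* variance along the stack
axis than along the ring's minor in-plane axis, so the least-squares plane
flips into the ring plane and the projected polygons become slivers.  The
bisector construction is symmetric in the pair and agrees with the union
fit in the near-coplanar regime.  Whether "exocyclic" includes only the
O6/N2-type substituents or more atoms is controlled by the per-base atom
table.  Mean planes are least-squares fits with the normal sign fixed
toward positive z (then x, then y).

Neighbour classification prefers an explicit topology file (tetrads as
cyclically ordered id lists, strands as stacking-ordered lists); geometric
inference is provided for structures without one, with config-exposed
cutoffs: stacked if COM distance < 5.0 A and inter-plane angle < 30
degrees; hbonded if near-coplanar (angle < 30 degrees, COM < 9 A) with at
least two donor-acceptor heavy-atom contacts < 3.5 A; diagonal pairs are
composed from the other two classes (stacked-then-hbonded), since no
single-pair cutoff characterizes them.  On idealized structures the
geometric mode reproduces the topology mode exactly.

## The synthetic generator

The generator replaces the electronic-structure upstream so the entire
pipeline is testable offline, by *parameter recovery*: it builds a known
"true" diabatic Hamiltonian plus properties, diagonalizes it, and emits the
eigenvector matrix as the reference/adiabatic overlap together with the
adiabatic energies and transformed properties — so an untruncated
diabatization must reproduce the truth to machine precision.  Controlled
degradation (truncation of high adiabats, Givens-rotation mixing with
out-of-reference spectator states) produces monotone error growth for
robustness tests.

Geometries are idealized G-tetrad stacks: one guanine pose within a
C4-symmetric tetrad is solved once by least squares against Hoogsteen
targets (N1->O6 and N2->N7 at 2.90 A to the 90-degree neighbour, O6 at
2.30 A from the central axis, the cation-coordination distance), then
replicated by the tetrad's four-fold rotation and stacked with
configurable rise (default 3.4 A), twist (default 30 degrees) and slide
(default 0).  Base templates are idealized planar standard-frame
geometries.  MD-like snapshot series perturb the per-interface helical
parameters and apply small per-base rigid jitters from a single seeded
random stream.

Electronic settings are documented placeholders, *not* quantum-chemistry
results: La at 4.95 eV with |mu| = 1.1 a.u., Lb at 5.25 eV with 0.75 a.u.,
in-plane dipole directions at 35 and 125 degrees from the base-frame x
axis, intrinsic magnetic moments zero by default, same-site La-Lb coupling
0.02 eV.  Atomic transition charges are the minimum-norm solution
reproducing the requested dipole with zero total charge, so
transition-charge Coulomb couplings are exact for the stated dipole by
construction.  Cross-site LE-LE couplings in the "true" pair Hamiltonians
are genuine transition-charge Coulomb couplings at the actual geometry.
The CT ladder is deliberately simple: for stacked pairs
`eps_CT(R) = 5.6 eV + 0.5 eV/A * (R - 3.4 A)` (R the donor-acceptor COM
distance) with a 0.3 eV spacing between orbital-pair channels; non-stacked
pairs sit at 7.5 eV.  LE-CT couplings decay exponentially with R from
0.12 eV with fixed per-channel scale factors; CT-CT couplings are 0.05 /
0.03 eV (same / opposite direction); CT electric dipoles are 0.08 a.u.
along the donor->acceptor axis.  The linear distance dependence makes
tighter stacking stabilize the CT states, reproducing qualitatively the
mechanism by which inter-tetrad overlap modulates CT involvement at the
bottom of the exciton bands — which is exactly what the correlation
analysis is designed to display.

What the generator does *not* emulate: real TD-DFT energetics and
couplings, vibronic structure, polarizable embedding, loop-base chemistry,
and genuine MD force-field fluctuations.  Passing the recovery and
mechanism tests therefore demonstrates that the *machinery* (diabatization,
assembly, spectra, analysis) is correct and internally consistent, not
that any specific synthetic spectrum matches a measured one.

Note one geometric subtlety the synthetic world makes visible: for exactly
parallel tetrad planes, the projected overlap area is independent of the
rise, so a pure-rise series changes CT stabilization without changing
overlap.  Series meant to co-vary both (as real thermal fluctuations do)
reduce rise and twist together ("tighter stacking").

## Numerical choices

* Eigenproblems via LAPACK (`scipy.linalg.eigh`); eigenvector sign fixed by
  making the largest-magnitude coefficient positive; degenerate states
  ordered by the basis index of that coefficient.
* Basis ordering is deterministic (LE block by site then alpha, CT block by
  donor, acceptor, channel), so eigenvector files are comparable across
  runs.
* Hamiltonian symmetry is asserted at 1e-10; transform orthonormality at
  1e-8.
* Degenerate geometry (collinear point sets, sub-3-point superpositions,
  flat curves, empty stick lists) raises or warns explicitly rather than
  returning silently wrong numbers.
* All randomness in the generator flows from one `numpy` Generator seeded
  by the spec; identical specs give bitwise-identical outputs.

## Problem sizes

The default synthetic system is a 3-tetrad, 12-guanine stack: 24 LE basis
states, 36 nearest-neighbour pairs (8 stacked, 12 hbonded, 16 diagonal),
and 168 basis states with 4 CT states on every pair class (56 with CT on
stacked pairs only).  These sizes exercise every code path while keeping
the full test suite and the reproduction script in the seconds range.

## Known limitations

* The rotational-strength expression uses a common extrinsic prefactor (see
  above); per-state gauge refinements are out of scope.
* No vibronic lineshapes, temperature-dependent broadening, or magnetic CD.
* Geometric neighbour inference is tuned for idealized quadruplex
  geometries; heavily distorted MD snapshots should supply a topology file.
* PDB is the only structure dialect (models double as NMR/MD snapshots);
  trajectory formats are out of scope.
* The CLI's `analyze` correlation table requires a topology file (interface
  overlap totals are defined per tetrad interface).
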