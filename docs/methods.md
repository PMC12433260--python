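# Methods

This note records the models, parameter choices and numerical decisions
behind `poremode`, and what the synthetic ground truth does and does not
establish about real data.

## Elastic network and normal modes

The protein is reduced to one bead per residue (the Cα) and modelled as an
anisotropic network: every bead pair within a cutoff is joined by a
harmonic spring acting along the inter-bead axis. Two parametrizations are
built in:

| parameter | default | meaning |
|---|---|---|
| `cutoff` | 15 Å | contact distance; 12–15 Å is the conventional ANM range for Cα networks |
| `gamma` | 1.0 (arbitrary) | uniform spring constant; only relative amplitudes matter, so the energy unit is left arbitrary |
| `spring_model` | `uniform_cutoff` | Atilgan-style ANM; `inverse_square_weighted` (k = γ/d²) is the parameter-free alternative |

Per-contact spring constants can be rescaled after construction, which is
how the synthetic dimer softens its interface. Masses are uniform (no
mass-weighting): the target quantities are mode geometry and relative
amplitude, not absolute frequencies.

Trivial (rigid-body) modes are removed by an eigenvalue tolerance,
λ < 10⁻⁶ λ_max, rather than by dropping a fixed count of six: a collinear
body has five zero modes and near-degenerate structures can blur the gap,
so the count is reported and a warning raised when it differs from six.
Mode numbering is 1-based over the *non-trivial* spectrum (mode 1 =
softest); the mapping to raw spectrum indices is kept on the `ModeSet`
because external tools may count differently — published mode labels from
other pipelines cannot be assumed to share an origin or a force field, so
no attempt is made to reproduce literal mode indices from elsewhere.

Eigenproblems up to 3n = 3000 use the dense symmetric solver; larger ones
use shift-invert Lanczos with the shift placed well below the spectrum
(a shift near zero would sit on the rigid-body null space and destroy the
factorization's conditioning) followed by a Rayleigh–Ritz refinement in
the converged subspace, which brings the two paths into 10⁻⁸ relative
agreement on overlap sizes.

## The gating screen

Each screened mode displaces the structure by x → x₀ ± s·v_k with
s = RMSD·√n, so the displacement RMSD equals the target exactly (the
eigenvector is unit-norm). Defaults follow the protocol the package
implements: 100 modes, 2 Å RMSD, 0.5 Å opening threshold. Choices that
were genuinely open:

* **Selection quantifier.** "The gating pairs widen" can mean all pairs
  together or any pair. Both rules are implemented
  (`all_pairs_one_sense`, default, and `any_pair_any_sense`); the report
  stores every (mode, sense, pair) distance change so either rule can be
  recomputed from the artifact.
* **Endpoint vs path.** The threshold is evaluated at the full-RMSD
  endpoint: the displacement is linear, so intermediate amplitudes scale
  proportionally and the endpoint is the maximal, sufficient check.
* **Distance atoms.** Gating distances default to Cα–Cα (the network has
  no other atoms); a named-atom mode exists for all-atom structures.
  Side-chain-terminus distances would differ; no claim is made about
  which convention external figures use.
* **Observation pairs.** Extra pairs (e.g. acidic-pocket residues) can be
  tracked in the report without influencing selection.

Displacement senses are antisymmetric only to first order: a mode that
moves a pair transversely lengthens it in *both* senses by ≈ s²|Δv⊥|²/2d.
This second-order term is real geometry, not error — the tests verify the
first-order antisymmetry by its scaling (halving the amplitude halves the
antisymmetric part and quarters the symmetric remainder) rather than by a
fixed bound, which no amplitude makes universally valid.

Visualization trajectories oscillate one full sine period about x₀ with
peak RMSD = magnification × base amplitude. The base amplitude is 0.1 Å
RMSD, chosen so the conventional 15× magnification yields a clearly
visible 1.5 Å peak; 34 frames ≈ 10.6° phase steps (cosmetic). Energetic
viability of displaced conformers is explicitly out of scope: large-
amplitude harmonic extrapolations need not be physically reachable.

## Trajectory statistics

* **Superposition** is a proper-rotation least-squares (Kabsch) fit;
  RMSF and DCCM use a two-pass scheme (fit to frame 0, recompute the mean,
  refit to the mean). Collinear fit sets are rejected — they leave a free
  rotation axis. The fit selection defaults to all Cα.
* **RDF**: g(r) = ⟨n(r, r+dr)⟩ / (ρ 4πr² dr) with ρ the instantaneous
  per-frame bulk density N/V (correct for NPT-like inputs), minimum-image
  distances, self-pairs excluded on overlapping sets, and r_max capped at
  half the smallest box edge. Mass balance (Σ g ρ 4πr²dr = mean in-sphere
  count) is exact up to binning and is asserted at 1%.
* **PBC** is orthorhombic minimum-image only; triclinic input is an
  explicit unsupported error.
* **Hydrogen bonds** are geometric: donor–acceptor distance ≤ 3.5 Å, plus
  D–H···A angle ≥ 150° when hydrogens are supplied (heavy-atom mode uses
  distance alone).
* **Mixture decomposition**: own 1-D EM (tolerance 10⁻⁸ on the
  log-likelihood, ≤ 500 iterations, k-means++-style restarts, 5 by
  default), model selection by BIC over k = 1..k_max with ties broken
  toward smaller k. The EM log-likelihood trace is retained on the result
  so its monotonicity is checkable; zero-variance input is a degenerate-
  data error. An independent library implementation serves as a
  cross-check in the tests, never as the implementation.
* **Units**: Å everywhere internally; user-facing distance tables are in
  nm (× 0.1) to match the field's plotting convention.

## Synthetic ground truth

`synthetic_data` generates every input class with known answers; all
generators are pure functions of their spec (seed included).

* **Helical dimer** (default 5 helices × 25 residues per protomer, ideal
  α-helix Cα geometry: 1.5 Å rise, 100°/residue, 2.3 Å radius; protomer
  axes 24 Å apart, C2 symmetry about the pore axis, 0.05 Å seeded jitter
  to lift symmetry degeneracies). Down-weighting inter-protomer springs
  (scale 0.05) makes the protomers near-rigid bodies with a soft
  separation mode that widens every gating pair — the planted positive
  control. Because ANM springs are central forces, inter-protomer shear
  and twist are generically *softer* than separation, so the planted mode
  is identified by overlap with the ideal separation pattern rather than
  assumed to be mode 1; its selection is stable across cutoffs 12/13/15 Å
  and thresholds 0.3/0.5 Å. With uniform springs (scale 1) no such
  guarantee exists and none is asserted. The dimer has no sequence
  realism (ALA everywhere, LEU at gating positions): every in-scope
  computation is geometric.
* **Harmonic ensembles** draw exactly from the Gaussian measure of a mode
  subset, Δx = Σ_k √(kT/λ_k) z_k v_k, so RMSF and DCCM have closed forms.
  kT is in the network's arbitrary energy unit; tests use values giving
  sub-Å fluctuations, inside the regime where superposition corrections
  are negligible.
* **Solvent boxes** are iid uniform points (ideal gas, g ≡ 1) or
  rejection-sampled outside an exclusion sphere (g ≡ 0 below the radius),
  with a fixed reference pseudo-atom at the box center.
* **Mixture samples** carry their component labels for recovery scoring.

What passing these tests shows: the estimators implement their
definitions correctly and converge at the expected statistical rates.
What it does not show: anything about force-field quality, sampling
adequacy, or water structure in real simulations — the synthetic solvent
has no correlations and the synthetic ensembles are exactly harmonic.

## Problem sizes

The test suite and acceptance script use 30–500-site structures, 5 000–
20 000-frame ensembles, and 10⁴-sample mixtures; these sizes put the
statistical checks (5% RMSF, 0.05–0.1 DCCM, ±0.05 g(r)) comfortably past
their convergence knees while keeping a full run to a couple of minutes.

## Known limitations

* No mmCIF, bond perception, hydrogen placement, or trajectory unwrapping;
  PDB (including multi-model) is the interchange format, with fixed-width
  precision (10⁻³ Å) as its floor.
* The ENM is Cα-uniform: no all-atom force field, mass weighting, or
  solvent damping; absolute frequencies/amplitudes are defined only up to
  the spring-unit scale.
* Mode labels are not comparable across ENM parametrizations; any
  comparison to externally published mode indices requires the same force
  field and numbering origin.
* EM mixture fitting assumes Gaussian components; heavy-tailed or skewed
  distance distributions will inflate k.
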