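"""Synthetic structures, ensembles, solvent boxes and distance samples
with closed-form ground truth.

Every generator here is a pure, seeded function of its spec, so each
analysis stage in the package can be validated against known answers
without microsecond MD data:

* :func:`make_helical_dimer` — a two-protomer Cα helical bundle with a
  *planted* soft pore-opening mode: inter-protomer elastic contacts are
  down-weighted, so the protomers behave as near-rigid bodies whose
  relative separation along the interface normal is a soft mode that
  widens every gating pair. A positive control for the mode screen.
* :func:`sample_harmonic_ensemble` — exact draws from the Gaussian
  ensemble of a mode set (Δx = Σ_k √(kT/λ_k) z_k v_k), giving RMSF and
  cross-correlation closed forms.
* :func:`make_solvent_box` — ideal-gas or hard-exclusion point solvent
  with known g(r).
* :func:`sample_mixture_series` — labelled draws from a 1-D Gaussian
  mixture for decomposition-recovery tests.

The dimer makes no attempt at sequence realism: every residue is ALA
except gating residues, named LEU for readability. Geometry, not
chemistry, drives all the analyses tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .enm import ElasticNetwork, ModeSet, build_network
from .mode_screen import GatingPairSet
from .structure_io import AtomRecord, ResidueKey, StructureModel, Trajectory

__all__ = [
    "BundleSpec",
    "EnsembleSpec",
    "SolventSpec",
    "MixtureSpec",
    "make_helical_dimer",
    "dimer_network",
    "opening_pattern",
    "find_opening_mode",
    "sample_harmonic_ensemble",
    "make_solvent_box",
    "sample_mixture_series",
]

# ideal alpha-helix Calpha trace parameters
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å


@dataclass
class BundleSpec:
    """Geometry and softness of the synthetic two-protomer helix bundle."""

    n_helices_per_protomer: int = 5
    residues_per_helix: int = 25
    pore_radius: float = 5.0  # Å, protomer-axis to helix inner surface
    protomer_separation: float = 24.0  # Å between protomer axes
    interface_spring_scale: float = 0.05  # (0, 1]; 1 = uniform network
    gating_pair_positions: tuple[float, ...] = (0.35, 0.5, 0.65)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.interface_spring_scale <= 1:
            raise ValueError("interface_spring_scale must be in (0, 1]")
        for p in (self.pore_radius, self.protomer_separation):
            if p <= 0:
                raise ValueError("geometric parameters must be positive")
        if not self.gating_pair_positions:
            raise ValueError("need at least one gating pair position")


@dataclass
class EnsembleSpec:
    """Harmonic-ensemble sampling parameters over a mode set."""

    modes: ModeSet
    k_set: list[int] = field(default_factory=list)  # empty = all modes
    kT: float = 1.0  # spring units · Å²
    n_frames: int = 1000
    seed: int = 0


@dataclass
class SolventSpec:
    """Point-solvent box: ideal gas, or hard exclusion around a reference."""

    box: tuple[float, float, float] = (40.0, 40.0, 40.0)  # Å
    n_particles: int = 500
    exclusion_radius: float = 0.0  # Å; 0 = ideal gas
    reference_point: tuple[float, float, float] | None = None  # default box center
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.exclusion_radius >= 0.5 * min(self.box):
            raise ValueError("exclusion_radius must be < half the min box edge")


@dataclass
class MixtureSpec:
    """1-D Gaussian mixture: (mean, sd, weight) components."""

    components: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(8.0, 0.5, 0.6), (11.0, 0.5, 0.4)]
    )
    n_samples: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(c[2] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1 (got {w})")
        if any(c[1] <= 0 for c in self.components):
            raise ValueError("component SDs must be positive")


# ---------------------------------------------------------------------------
# Helical dimer with a planted opening mode
# ---------------------------------------------------------------------------

def _protomer_coords(spec: BundleSpec) -> np.ndarray:
    """Cα trace of one protomer, axis along z at x = -separation/2."""
    n_res = spec.residues_per_helix
    length = (n_res - 1) * HELIX_RISE
    ring_r = spec.pore_radius + HELIX_RADIUS
    coords = []
    for h in range(spec.n_helices_per_protomer):
        theta = 2.0 * np.pi * h / spec.n_helices_per_protomer
        cx = -0.5 * spec.protomer_separation + ring_r * np.cos(theta)
        cy = ring_r * np.sin(theta)
        phase = np.radians(40.0 * h)  # stagger phases between helices
        for r in range(n_res):
            phi = np.radians(HELIX_TWIST * r) + phase
            coords.append(
                [
                    cx + HELIX_RADIUS * np.cos(phi),
                    cy + HELIX_RADIUS * np.sin(phi),
                    r * HELIX_RISE - 0.5 * length,
                ]
            )
    return np.asarray(coords)


def make_helical_dimer(
    spec: BundleSpec | None = None,
) -> tuple[StructureModel, GatingPairSet, dict]:
    """Build the synthetic two-chain helix bundle with a planted soft mode.

    Chain B is the 180°-about-z image of chain A (C2 symmetry about the
    pore axis). Gating pairs sit at the requested fractional heights along
    the pore axis, chosen as the chain-A Cα nearest the axis at each height
    together with its C2 partner in chain B; those residues are renamed LEU
    (the rest ALA). A small seeded coordinate jitter (0.05 Å) breaks exact
    symmetry degeneracies in the mode spectrum.

    Returns the structure, the gating pair set, and a description of the
    planted opening mode holding the expected displacement ``pattern``
    (protomers separating along x) for identification via
    :func:`find_opening_mode`.
    """
    spec = spec or BundleSpec()
    rng = np.random.default_rng(spec.seed)
    A = _protomer_coords(spec)
    B = A @ np.diag([-1.0, -1.0, 1.0])  # rotate 180 deg about z
    coords = np.vstack([A, B]) + rng.normal(0.0, 0.05, (2 * A.shape[0], 3))

    n_per_chain = A.shape[0]
    min_interchain = cdist(coords[:n_per_chain], coords[n_per_chain:]).min()
    if min_interchain < 2.0:
        raise ValueError(
            f"protomers overlap (min inter-chain distance {min_interchain:.2f} Å < 2 Å); "
            "increase protomer_separation"
        )

    length = (spec.residues_per_helix - 1) * HELIX_RISE
    gating_resids = []
    for f in spec.gating_pair_positions:
        z = (f - 0.5) * length
        axis_dist = np.hypot(coords[:n_per_chain, 0], coords[:n_per_chain, 1])
        score = axis_dist + np.abs(coords[:n_per_chain, 2] - z) * 2.0
        idx = int(np.argmin(score))
        if idx + 1 not in gating_resids:
            gating_resids.append(idx + 1)

    atoms = []
    for chain, offset in (("A", 0), ("B", n_per_chain)):
        for i in range(n_per_chain):
            resid = i + 1
            atoms.append(
                AtomRecord(
                    serial=offset + i + 1,
                    name="CA",
                    resname="LEU" if resid in gating_resids else "ALA",
                    chain=chain,
                    resid=resid,
                    coords=coords[offset + i].copy(),
                    element="C",
                )
            )
    structure = StructureModel(atoms)

    pairs = [
        (ResidueKey("A", r), ResidueKey("B", r)) for r in sorted(gating_resids)
    ]
    gating = GatingPairSet(pairs=pairs, distance_atoms="CA")

    pattern = opening_pattern(structure)
    description = {
        "kind": "inter-protomer separation along x",
        "pattern": pattern,
        "interface_spring_scale": spec.interface_spring_scale,
    }
    return structure, gating, description


def opening_pattern(structure: StructureModel) -> np.ndarray:
    """Unit (n, 3) displacement pattern of the protomers separating.

    Chain A moves along −x, chain B along +x, equal magnitude: the
    idealized pore-opening motion of the synthetic dimer, used to identify
    the planted mode among the computed ones by overlap.
    """
    chains = [a.chain for a in structure.atoms]
    uniq = sorted(set(chains))
    if len(uniq) != 2:
        raise ValueError("opening pattern needs exactly 2 chains")
    sign = np.array([-1.0 if c == uniq[0] else 1.0 for c in chains])
    pat = np.zeros((len(chains), 3))
    pat[:, 0] = sign
    return pat / np.linalg.norm(pat)


def find_opening_mode(modes: ModeSet, pattern: np.ndarray) -> tuple[int, float]:
    """Mode (1-based) with maximal |overlap| against a displacement pattern."""
    p = np.asarray(pattern, dtype=float).ravel()
    p = p / np.linalg.norm(p)
    overlaps = np.abs(modes.eigenvectors.T @ p)
    k = int(np.argmax(overlaps)) + 1
    return k, float(overlaps[k - 1])


def dimer_network(
    structure: StructureModel,
    interface_spring_scale: float,
    cutoff: float = 15.0,
    gamma: float = 1.0,
) -> ElasticNetwork:
    """Elastic network of the dimer with inter-chain springs down-weighted.

    With ``interface_spring_scale`` well below 1 the protomers act as stiff
    bodies coupled by a soft interface, planting soft inter-protomer modes
    — among them the separation (opening) mode the screen must find.
    """
    net = build_network(structure, cutoff=cutoff, gamma=gamma)
    chains = np.array([a.chain for a in structure.atoms])
    inter = chains[net.contacts[:, 0]] != chains[net.contacts[:, 1]]
    factor = np.where(inter, interface_spring_scale, 1.0)
    return net.rescale_springs(factor)


# ---------------------------------------------------------------------------
# Harmonic ensembles
# ---------------------------------------------------------------------------

def sample_harmonic_ensemble(spec: EnsembleSpec, base_coords: np.ndarray) -> Trajectory:
    """Draw frames from the Gaussian ensemble of a mode subset.

    Each frame is base + Σ_k √(kT/λ_k) z_k v_k with z_k iid standard
    normal; the sample covariance converges to kT Σ_k λ_k⁻¹ v_k v_kᵀ, so
    RMSF and DCCM have closed-form targets. Requires a topology-bearing
    base: pass the coordinates of the structure the modes were computed on.
    """
    base = np.asarray(base_coords, dtype=float)
    modes = spec.modes
    k_set = list(spec.k_set) if spec.k_set else list(range(1, modes.n_modes + 1))
    idx = np.asarray(k_set, dtype=int) - 1
    lam = modes.eigenvalues[idx]
    if np.any(lam <= 0):
        raise ValueError("all eigenvalues in k_set must be positive")
    V = modes.eigenvectors[:, idx]  # (3n, m)
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, idx.size))
    disp = (z * np.sqrt(spec.kT / lam)) @ V.T  # (n_frames, 3n)
    frames = base[None, :, :] + disp.reshape(spec.n_frames, -1, 3)
    # topology: bare Cα pseudo-structure matching the mode sites
    topo = _bare_topology(base, modes)
    return Trajectory(frames=frames, topology=topo)


def _bare_topology(base: np.ndarray, modes: ModeSet) -> StructureModel:
    keys = modes.site_keys or [ResidueKey("A", i + 1) for i in range(base.shape[0])]
    atoms = [
        AtomRecord(
            serial=i + 1,
            name="CA",
            resname="ALA",
            chain=k.chain,
            resid=k.resid,
            insertion_code=k.insertion_code,
            coords=base[i].copy(),
            element="C",
        )
        for i, k in enumerate(keys)
    ]
    return StructureModel(atoms)


# ---------------------------------------------------------------------------
# Solvent boxes with known g(r)
# ---------------------------------------------------------------------------

def make_solvent_box(spec: SolventSpec) -> Trajectory:
    """Point-solvent frames with known radial structure.

    Atom 0 is a fixed reference pseudo-atom (name ``REF``) at the reference
    point (box center by default); atoms 1..n are solvent points, uniform
    iid per frame (ideal gas) or rejection-sampled outside the exclusion
    radius of the reference. g(r) around atom 0 is 1 for an ideal gas and 0
    below the exclusion radius by construction.
    """
    box = np.asarray(spec.box, dtype=float)
    ref = (
        0.5 * box
        if spec.reference_point is None
        else np.asarray(spec.reference_point, dtype=float)
    )
    a = spec.exclusion_radius
    accept_frac = 1.0 - (4.0 / 3.0) * np.pi * a**3 / np.prod(box)
    if accept_frac < 0.01:
        raise ValueError("exclusion sphere fills > 99% of the box; infeasible spec")
    rng = np.random.default_rng(spec.seed)
    frames = np.empty((spec.n_frames, spec.n_particles + 1, 3))
    frames[:, 0, :] = ref
    for f in range(spec.n_frames):
        got = 0
        pts = np.empty((spec.n_particles, 3))
        while got < spec.n_particles:
            batch = rng.uniform(0.0, 1.0, (max(spec.n_particles, 64), 3)) * box
            if a > 0:
                d = batch - ref
                d -= box * np.round(d / box)  # exclusion is periodic, like rdf
                batch = batch[np.sqrt((d**2).sum(axis=1)) >= a]
            take = min(batch.shape[0], spec.n_particles - got)
            pts[got : got + take] = batch[:take]
            got += take
        frames[f, 1:, :] = pts

    atoms = [
        AtomRecord(serial=1, name="REF", resname="REF", chain="R", resid=1,
                   coords=ref.copy(), element="X", het=True)
    ]
    for i in range(spec.n_particles):
        atoms.append(
            AtomRecord(
                serial=i + 2,
                name="O",
                resname="HOH",
                chain="W",
                resid=i + 1,
                coords=frames[0, i + 1].copy(),
                element="O",
                het=True,
            )
        )
    return Trajectory(frames=frames, topology=StructureModel(atoms), box=box)


# ---------------------------------------------------------------------------
# Mixture samples
# ---------------------------------------------------------------------------

def sample_mixture_series(spec: MixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw labelled samples from a 1-D Gaussian mixture.

    Returns (samples, labels); labels index the spec's component list so
    recovery by :func:`poremode.traj_analysis.fit_mixture_1d` can be scored
    against the generating truth.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c[2] for c in spec.components])
    labels = rng.choice(len(spec.components), size=spec.n_samples, p=weights)
    means = np.array([c[0] for c in spec.components])
    sds = np.array([c[1] for c in spec.components])
    samples = rng.normal(means[labels], sds[labels])
    return samples, labels
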