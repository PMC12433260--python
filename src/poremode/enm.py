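"""Cα elastic-network (anisotropic network model) normal-mode analysis.

The protein is reduced to its alpha carbons and modelled as a network of
harmonic springs connecting every Cα pair within a distance cutoff. The
quadratic energy around the input conformation gives a 3n × 3n Hessian whose
low-frequency eigenvectors are the collective motions of interest: each mode
is a harmonic oscillator with amplitude proportional to 1/λ, so the softest
non-trivial modes carry the largest, most collective displacements (domain
motions, pore opening), while stiff modes are local.

Spring models
-------------
``uniform_cutoff``
    Atilgan-style ANM: every contact within the cutoff gets the same spring
    constant ``gamma``. Default cutoff 15 Å, gamma 1.0 (spring units are
    arbitrary; mode shapes and relative amplitudes are what matter).
``inverse_square_weighted``
    k_ij = gamma / d_ij², a parameter-free distance weighting.

Per-contact spring constants may also be supplied or rescaled directly
(used e.g. to soften an interface and plant a known soft mode).

Trivial (rigid-body) modes are removed by an eigenvalue tolerance relative
to the largest eigenvalue, never by assuming a fixed count of six; a
collinear body has five. Mode numbering: k = 1 is the softest non-trivial
mode, and the mapping to raw eigenvalue indices (trivial modes included) is
always retained on the :class:`ModeSet`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from scipy.spatial.distance import pdist, squareform

from .structure_io import ResidueKey, StructureModel

__all__ = [
    "ElasticNetwork",
    "ModeSet",
    "CorrelationMap",
    "build_network",
    "hessian",
    "compute_modes",
    "mode_correlation",
    "dccm_from_modes",
    "mode_fluctuations",
]

TRIVIAL_TOL = 1e-6  # eigenvalue threshold relative to lambda_max
DENSE_LIMIT = 3000  # largest 3n solved with the dense symmetric path


@dataclass
class ElasticNetwork:
    """A Cα harmonic network: sites, contacts and spring constants."""

    sites: np.ndarray  # (n, 3) [Å]
    site_keys: list[ResidueKey]
    cutoff: float
    gamma: float
    contacts: np.ndarray  # (m, 2) int, i < j
    distances: np.ndarray  # (m,) [Å]
    spring_constants: np.ndarray  # (m,)
    spring_model: str = "uniform_cutoff"
    connected: bool = True

    @property
    def n_sites(self) -> int:
        return self.sites.shape[0]

    def rescale_springs(self, factor: np.ndarray | float) -> "ElasticNetwork":
        """Copy of the network with per-contact spring constants multiplied."""
        k = self.spring_constants * np.asarray(factor, dtype=float)
        if np.any(k <= 0):
            raise ValueError("spring constants must stay positive")
        return ElasticNetwork(
            sites=self.sites,
            site_keys=self.site_keys,
            cutoff=self.cutoff,
            gamma=self.gamma,
            contacts=self.contacts,
            distances=self.distances,
            spring_constants=k,
            spring_model=self.spring_model,
            connected=self.connected,
        )


@dataclass
class ModeSet:
    """Non-trivial normal modes, ascending by eigenvalue.

    ``eigenvectors[:, k]`` is the unit 3n-vector of mode ``k`` (0-based in
    storage; user-facing mode numbers are 1-based, 1 = softest non-trivial).
    ``raw_indices[k]`` maps to the index in the full spectrum including the
    removed trivial modes.
    """

    eigenvalues: np.ndarray  # (m,) ascending, > 0
    eigenvectors: np.ndarray  # (3n, m), orthonormal columns
    n_trivial_removed: int
    raw_indices: np.ndarray  # (m,) int
    site_keys: list[ResidueKey] = field(default_factory=list)

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def n_sites(self) -> int:
        return self.eigenvectors.shape[0] // 3

    def mode_vector(self, k: int) -> np.ndarray:
        """Mode k (1-based) reshaped to per-site (n, 3) displacements."""
        self._check_k(k)
        return self.eigenvectors[:, k - 1].reshape(-1, 3)

    def _check_k(self, k: int) -> None:
        if not 1 <= k <= self.n_modes:
            raise IndexError(f"mode index {k} out of range 1..{self.n_modes}")

    # -- plain-text serialization ------------------------------------------
    def to_csv_bundle(self, directory: str | Path) -> None:
        """Write eigenvalues and eigenvectors as two CSV files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "mode": np.arange(1, self.n_modes + 1),
                "raw_index": self.raw_indices,
                "eigenvalue": self.eigenvalues,
            }
        ).to_csv(directory / "eigenvalues.csv", index=False)
        cols = {f"mode_{k}": self.eigenvectors[:, k - 1] for k in range(1, self.n_modes + 1)}
        pd.DataFrame(cols).to_csv(directory / "eigenvectors.csv", index=False)


@dataclass
class CorrelationMap:
    """Normalized per-site displacement correlations in [-1, 1]."""

    values: np.ndarray  # (n, n)
    site_keys: list[ResidueKey]
    source: str

    def to_csv(self, path: str | Path) -> None:
        labels = [str(k) for k in self.site_keys]
        pd.DataFrame(self.values, index=labels, columns=labels).to_csv(path)


# ---------------------------------------------------------------------------
# Network construction and Hessian
# ---------------------------------------------------------------------------

def build_network(
    calpha_structure: StructureModel,
    cutoff: float = 15.0,
    gamma: float = 1.0,
    spring_model: str = "uniform_cutoff",
) -> ElasticNetwork:
    """Build the elastic network over a Cα structure.

    Contacts are exactly the site pairs with d_ij ≤ cutoff (i < j stored
    once). A disconnected network is flagged with a warning, not an error.
    """
    if spring_model not in ("uniform_cutoff", "inverse_square_weighted"):
        raise ValueError(f"unknown spring_model {spring_model!r}")
    if cutoff <= 0 or gamma <= 0:
        raise ValueError("cutoff and gamma must be positive")
    sites = calpha_structure.coords
    n = sites.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sites to build a network")
    dmat = squareform(pdist(sites))
    iu, ju = np.triu_indices(n, k=1)
    mask = dmat[iu, ju] <= cutoff
    contacts = np.stack([iu[mask], ju[mask]], axis=1)
    dists = dmat[iu, ju][mask]
    if np.any(dists <= 0):
        raise ValueError("coincident sites (zero contact distance)")
    if spring_model == "uniform_cutoff":
        springs = np.full(contacts.shape[0], gamma, dtype=float)
    else:
        springs = gamma / dists**2

    connected = True
    if contacts.shape[0] == 0:
        connected = False
    else:
        adj = csr_matrix(
            (np.ones(contacts.shape[0]), (contacts[:, 0], contacts[:, 1])), shape=(n, n)
        )
        ncomp, _ = connected_components(adj, directed=False)
        connected = ncomp == 1
    if not connected:
        warnings.warn(
            f"elastic network is disconnected at cutoff {cutoff} Å",
            stacklevel=2,
        )
    return ElasticNetwork(
        sites=sites,
        site_keys=calpha_structure.residue_keys(),
        cutoff=cutoff,
        gamma=gamma,
        contacts=contacts,
        distances=dists,
        spring_constants=springs,
        spring_model=spring_model,
        connected=connected,
    )


def hessian(network: ElasticNetwork) -> np.ndarray:
    """Assemble the 3n × 3n ANM Hessian.

    Off-diagonal block for contact (i, j): −(k_ij / d_ij²) (r_j − r_i)(r_j − r_i)ᵀ;
    each diagonal block is minus the sum of its row's off-diagonal blocks, so
    uniform translations are annihilated exactly.
    """
    n = network.n_sites
    H = np.zeros((3 * n, 3 * n))
    rij = network.sites[network.contacts[:, 1]] - network.sites[network.contacts[:, 0]]
    # (m, 3, 3) per-contact projector blocks scaled by k_ij
    # outer product first: r_a·r_b is exactly commutative, so the scaled
    # blocks (and hence H) are exactly symmetric in floating point
    outer = rij[:, :, None] * rij[:, None, :]
    blocks = -(network.spring_constants / network.distances**2)[:, None, None] * outer
    for (i, j), B in zip(network.contacts, blocks):
        H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] += B
        H[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] += B
        H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= B
        H[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= B
    return H


# ---------------------------------------------------------------------------
# Eigenproblem
# ---------------------------------------------------------------------------

def compute_modes(network: ElasticNetwork, n_modes: int = 100) -> ModeSet:
    """The ``n_modes`` softest non-trivial normal modes of the network.

    Trivial (rigid-body) modes are identified by λ < 1e-6 · λ_max and
    removed; a warning is issued when their count differs from 6 for what
    should be a 3-D structure (collinear or degenerate input). Dense
    symmetric eigensolve for 3n ≤ 3000, iterative smallest-eigenpair path
    above (both paths agree to 1e-8 on overlap sizes).
    """
    H = hessian(network)
    dim = H.shape[0]
    if dim <= DENSE_LIMIT:
        vals, vecs = eigh(H)
        lam_max = vals[-1]
    else:
        # smallest eigenpairs via shift-invert around zero
        k = min(n_modes + 12, dim - 1)
        # shift well below the spectrum: H - sigma*I stays well-conditioned
        # (a shift at ~0 would sit on the rigid-body null space)
        lam_scale = float(np.abs(np.diag(H)).max())
        vals, vecs = eigsh(csr_matrix(H), k=k, sigma=-0.1 * lam_scale, which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
        # Rayleigh-Ritz refinement in the converged subspace: eigenvalue
        # error drops to the square of the iterative residual, matching the
        # dense path on overlap sizes
        Q, _ = np.linalg.qr(vecs)
        small_vals, small_vecs = eigh(Q.T @ (H @ Q))
        vals = small_vals
        vecs = Q @ small_vecs
        lam_max = eigsh(csr_matrix(H), k=1, which="LA", return_eigenvectors=False)[0]
    if lam_max <= 0:
        raise ValueError("Hessian has no positive eigenvalue; degenerate network")
    trivial = vals < TRIVIAL_TOL * lam_max
    n_trivial = int(np.sum(trivial))
    if n_trivial != 6:
        warnings.warn(
            f"{n_trivial} trivial modes removed (expected 6 for a 3-D "
            "non-collinear structure); possible degeneracy",
            stacklevel=2,
        )
    keep = np.flatnonzero(~trivial)
    if n_modes > keep.size:
        raise ValueError(
            f"requested {n_modes} modes but only {keep.size} non-trivial modes exist"
        )
    keep = keep[:n_modes]
    return ModeSet(
        eigenvalues=vals[keep].copy(),
        eigenvectors=vecs[:, keep].copy(),
        n_trivial_removed=n_trivial,
        raw_indices=keep.copy(),
        site_keys=list(network.site_keys),
    )


# ---------------------------------------------------------------------------
# Mode-derived statistics
# ---------------------------------------------------------------------------

def mode_correlation(modes: ModeSet, k: int) -> CorrelationMap:
    """Single-mode orientational correlation map.

    c_ij = (v_i · v_j) / (|v_i| |v_j|) over the per-site 3-vectors of mode
    k. Sites with |v_i| = 0 get correlation 0 by convention (their motion
    has no direction), including the diagonal entry.
    """
    V = modes.mode_vector(k)  # (n, 3)
    norms = np.linalg.norm(V, axis=1)
    dots = V @ V.T
    with np.errstate(invalid="ignore", divide="ignore"):
        C = dots / np.outer(norms, norms)
    C[~np.isfinite(C)] = 0.0
    np.clip(C, -1.0, 1.0, out=C)
    return CorrelationMap(values=C, site_keys=list(modes.site_keys), source=f"single_mode({k})")


def _mode_covariance(modes: ModeSet, k_set: list[int] | np.ndarray) -> np.ndarray:
    """(n, n) trace-of-3×3-block covariance  C_ij = Σ_k λ_k⁻¹ v_ik · v_jk."""
    k_set = np.asarray(list(k_set), dtype=int)
    if k_set.size == 0:
        raise ValueError("k_set must be non-empty")
    for k in k_set:
        modes._check_k(int(k))
    lam = modes.eigenvalues[k_set - 1]
    if np.any(lam <= 0):
        raise ValueError("all eigenvalues in k_set must be positive")
    W = modes.eigenvectors[:, k_set - 1] / np.sqrt(lam)  # (3n, m)
    n = modes.n_sites
    Wr = W.reshape(n, 3, -1)
    return np.einsum("iak,jak->ij", Wr, Wr)


def dccm_from_modes(modes: ModeSet, k_set) -> CorrelationMap:
    """Ensemble cross-correlation map over a mode subset.

    C_ij = Σ_k λ_k⁻¹ v_ik · v_jk, normalized by √(C_ii C_jj). With a single
    mode this reduces to :func:`mode_correlation`.
    """
    cov = _mode_covariance(modes, k_set)
    d = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = cov / np.outer(d, d)
    C[~np.isfinite(C)] = 0.0
    np.clip(C, -1.0, 1.0, out=C)
    ks = ",".join(str(int(k)) for k in k_set)
    return CorrelationMap(values=C, site_keys=list(modes.site_keys), source=f"modes({ks})")


def mode_fluctuations(modes: ModeSet, k_set) -> np.ndarray:
    """Per-site mean-square fluctuation MSF_i = Σ_k λ_k⁻¹ |v_ik|².

    Units are Å² up to the arbitrary spring-unit energy scale (multiply by
    kT in spring units·Å² for absolute fluctuations).
    """
    return np.diag(_mode_covariance(modes, k_set)).copy()
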