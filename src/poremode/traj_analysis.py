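"""Trajectory statistics: superposition, RMSF, distances, RDF, DCCM,
hydrogen bonds and Gaussian-mixture decomposition of distance series.

These are the analyses run on conformational ensembles (MD-style
multi-model trajectories or harmonic-ensemble samples): least-squares
superposition and per-residue RMSF, residue-pair and nearest-ion distance
series, radial distribution functions g(r) relative to an ideal gas at the
bulk density, trajectory cross-correlation maps, geometric hydrogen-bond
counting, and EM/BIC decomposition of multimodal 1-D distance
distributions into Gaussian components (mean, SD, weight per component).

Internal units are Å throughout; reporting layers convert to nm (× 0.1)
where that is the field's plotting convention. Periodic boundaries are
orthorhombic minimum-image only; triclinic boxes are rejected explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation
from scipy.special import logsumexp

from .enm import CorrelationMap
from .structure_io import ResidueKey, Trajectory

__all__ = [
    "DistanceSeries",
    "RDFProfile",
    "RMSFProfile",
    "MixtureFit",
    "kabsch_superpose",
    "rmsf",
    "distance_series",
    "nearest_ion_series",
    "rdf",
    "dccm_from_traj",
    "hbond_series",
    "fit_mixture_1d",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class DistanceSeries:
    """Per-frame distances [Å] for one labelled pair of atom sets."""

    values: np.ndarray
    label: str
    frame_times: np.ndarray | None = None  # [ns]

    def in_nm(self) -> np.ndarray:
        """The series converted to nm for reporting (internal unit is Å)."""
        return self.values * 0.1


@dataclass
class RDFProfile:
    """Radial distribution function g(r) relative to an ideal gas."""

    r_centers: np.ndarray  # [Å]
    g: np.ndarray
    bin_width: float  # [Å]
    n_ref: int
    n_target: int
    bulk_density: float  # [Å^-3], averaged over frames
    mean_pair_count: float  # mean per-frame (ref, target) pairs within r_max

    def mass_balance(self) -> float:
        """Σ g(r) ρ 4πr² dr — should equal mean in-sphere count per reference."""
        shell = 4.0 * np.pi * self.r_centers**2 * self.bin_width
        return float(np.sum(self.g * self.bulk_density * shell))


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation [Å] after superposition."""

    values: np.ndarray
    residue_keys: list[ResidueKey]
    fit_selection: str = "all"


@dataclass
class MixtureFit:
    """A 1-D Gaussian mixture decomposition chosen by BIC.

    ``components`` is a list of (mean, sd, weight) sorted by mean; ``bic``
    maps each candidate component count to its BIC; ``loglik_trace`` is the
    EM log-likelihood path of the winning fit (non-decreasing).
    """

    k: int
    components: list[tuple[float, float, float]]
    bic: dict[int, float]
    converged: bool
    seed: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[2] for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])


# ---------------------------------------------------------------------------
# Superposition and RMSF
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | list[int] | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The optimal proper rotation is found on the fit atoms (all atoms when
    ``fit_indices`` is None) and applied to every atom; returns the rotated
    coordinates and the RMSD over the fit atoms. Degenerate (collinear) fit
    sets are rejected — they leave a free rotation axis.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have identical shapes")
    idx = np.arange(mobile.shape[0]) if fit_indices is None else np.asarray(fit_indices)
    if idx.size < 3:
        raise ValueError("need at least 3 fit atoms")
    mob_fit = mobile[idx]
    ref_fit = reference[idx]
    mob_c = mob_fit.mean(axis=0)
    ref_c = ref_fit.mean(axis=0)
    A = mob_fit - mob_c
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[1] <= 1e-10 * max(sv[0], 1.0):
        raise ValueError("fit atoms are collinear/degenerate; rotation underdetermined")
    rot, _ = Rotation.align_vectors(ref_fit - ref_c, A)
    rotated = rot.apply(mobile - mob_c) + ref_c
    rmsd_val = float(np.sqrt(np.mean(np.sum((rotated[idx] - ref_fit) ** 2, axis=1))))
    return rotated, rmsd_val


def _superpose_frames(
    frames: np.ndarray, reference: np.ndarray, fit_indices
) -> np.ndarray:
    return np.stack([kabsch_superpose(f, reference, fit_indices)[0] for f in frames])


def rmsf(
    traj: Trajectory,
    selection: np.ndarray | list[int] | None = None,
    fit_indices: np.ndarray | list[int] | None = None,
) -> RMSFProfile:
    """Per-atom RMSF after two-pass superposition.

    Every frame is first fit to frame 0, the mean structure is computed,
    every frame is refit onto that mean, and RMSF_i = √⟨|x_i − ⟨x_i⟩|²⟩ is
    taken over the refit frames. Rigid-body motion common to all frames is
    removed by the fit and does not contribute.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    frames = traj.frames
    pass1 = _superpose_frames(frames, frames[0], fit_indices)
    mean1 = pass1.mean(axis=0)
    pass2 = _superpose_frames(frames, mean1, fit_indices)
    mean2 = pass2.mean(axis=0)
    msf = np.mean(np.sum((pass2 - mean2) ** 2, axis=2), axis=0)
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    keys = traj.topology.residue_keys()
    return RMSFProfile(
        values=np.sqrt(msf[sel]),
        residue_keys=[keys[i] for i in sel],
        fit_selection="all" if fit_indices is None else "custom",
    )


# ---------------------------------------------------------------------------
# Distance series
# ---------------------------------------------------------------------------

def _min_image_diff(diff: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return diff
    return diff - box * np.round(diff / box)


def distance_series(
    traj: Trajectory,
    pair: tuple[np.ndarray | list[int], np.ndarray | list[int]],
    metric: str = "single_atom",
    label: str = "",
) -> DistanceSeries:
    """Per-frame distance between two atom sets.

    ``single_atom`` requires singleton sets; ``min`` takes the minimum
    cross-set pair distance; ``center`` the distance between set centroids.
    Symmetric in the order of the two sets.
    """
    ia = np.asarray(pair[0], dtype=int)
    ib = np.asarray(pair[1], dtype=int)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("atom sets must be non-empty")
    if metric == "single_atom":
        if ia.size != 1 or ib.size != 1:
            raise ValueError("single_atom metric requires singleton sets")
        diff = traj.frames[:, ia[0], :] - traj.frames[:, ib[0], :]
        vals = np.linalg.norm(diff, axis=1)
    elif metric == "center":
        diff = traj.frames[:, ia, :].mean(axis=1) - traj.frames[:, ib, :].mean(axis=1)
        vals = np.linalg.norm(diff, axis=1)
    elif metric == "min":
        vals = np.empty(traj.n_frames)
        for f in range(traj.n_frames):
            vals[f] = cdist(traj.frames[f, ia], traj.frames[f, ib]).min()
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceSeries(values=vals, label=label or metric, frame_times=traj.frame_times)


def nearest_ion_series(
    traj: Trajectory,
    residue_atoms: np.ndarray | list[int],
    ion_indices: np.ndarray | list[int],
    label: str = "nearest_ion",
) -> DistanceSeries:
    """Per-frame distance from a residue to its nearest ion.

    Minimum over ions of the minimum over the residue's atoms of the
    pairwise distance; minimum-image convention applies when the trajectory
    carries a box.
    """
    ir = np.asarray(residue_atoms, dtype=int)
    ii = np.asarray(ion_indices, dtype=int)
    if ii.size == 0:
        raise ValueError("need at least one ion index")
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        diff = traj.frames[f][ir][:, None, :] - traj.frames[f][ii][None, :, :]
        box = traj.box[f] if traj.box is not None else None
        diff = _min_image_diff(diff, box)
        vals[f] = np.sqrt(np.sum(diff**2, axis=2)).min()
    return DistanceSeries(values=vals, label=label, frame_times=traj.frame_times)


# ---------------------------------------------------------------------------
# Radial distribution function
# ---------------------------------------------------------------------------

def rdf(
    traj: Trajectory,
    ref_indices: np.ndarray | list[int],
    target_indices: np.ndarray | list[int],
    r_max: float,
    bin_width: float = 0.1,
    bulk_density: float | None = None,
) -> RDFProfile:
    """g(r): target density around the references relative to an ideal gas.

    g(r) = ⟨n(r, r+dr)⟩ / (ρ 4πr² dr) with ρ the bulk target density,
    N_target / V_box per frame (instantaneous volume, so NPT-like inputs
    normalize correctly) or an explicit ``bulk_density`` [Å⁻³] for
    non-periodic data. Minimum-image distances; self-pairs are excluded
    when the reference and target sets overlap; ``r_max`` may not exceed
    half the smallest box edge.
    """
    ir = np.asarray(ref_indices, dtype=int)
    it = np.asarray(target_indices, dtype=int)
    if ir.size == 0 or it.size == 0:
        raise ValueError("reference and target sets must be non-empty")
    if traj.box is None and bulk_density is None:
        raise ValueError("rdf needs a periodic box or an explicit bulk_density")
    if traj.box is not None and r_max > 0.5 * traj.box.min():
        raise ValueError(
            f"r_max {r_max} Å exceeds half the smallest box edge "
            f"({0.5 * traj.box.min():.3f} Å)"
        )
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * centers**2 * bin_width

    overlap = np.intersect1d(ir, it).size > 0
    acc = np.zeros(n_bins)
    rho_sum = 0.0
    pair_count = 0.0
    for f in range(traj.n_frames):
        box = traj.box[f] if traj.box is not None else None
        diff = traj.frames[f][ir][:, None, :] - traj.frames[f][it][None, :, :]
        diff = _min_image_diff(diff, box)
        d = np.sqrt(np.sum(diff**2, axis=2))
        if overlap:
            same = ir[:, None] == it[None, :]
            d = d[~same]
        d = d.ravel()
        d = d[d < r_max]
        counts, _ = np.histogram(d, bins=edges)
        rho = bulk_density if box is None else it.size / float(np.prod(box))
        acc += counts / (ir.size * rho * shell)
        rho_sum += rho
        pair_count += d.size / ir.size
    g = acc / traj.n_frames
    return RDFProfile(
        r_centers=centers,
        g=g,
        bin_width=bin_width,
        n_ref=ir.size,
        n_target=it.size,
        bulk_density=rho_sum / traj.n_frames,
        mean_pair_count=pair_count / traj.n_frames,
    )


# ---------------------------------------------------------------------------
# Trajectory cross-correlation
# ---------------------------------------------------------------------------

def dccm_from_traj(
    traj: Trajectory,
    selection: np.ndarray | list[int] | None = None,
    fit_indices: np.ndarray | list[int] | None = None,
) -> CorrelationMap:
    """Dynamical cross-correlation map from a trajectory.

    After superposing every frame onto the mean structure (two-pass, as in
    :func:`rmsf`), C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩) over the selected
    atoms. Zero-variance sites get correlation 0 by convention.
    """
    if traj.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    frames = traj.frames
    pass1 = _superpose_frames(frames, frames[0], fit_indices)
    mean1 = pass1.mean(axis=0)
    pass2 = _superpose_frames(frames, mean1, fit_indices)
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    dx = pass2[:, sel, :] - pass2[:, sel, :].mean(axis=0, keepdims=True)
    cov = np.einsum("fia,fja->ij", dx, dx) / dx.shape[0]
    var = np.diag(cov)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = cov / np.sqrt(np.outer(var, var))
    C[~np.isfinite(C)] = 0.0
    np.clip(C, -1.0, 1.0, out=C)
    keys = traj.topology.residue_keys()
    return CorrelationMap(
        values=C, site_keys=[keys[i] for i in sel], source="trajectory"
    )


# ---------------------------------------------------------------------------
# Hydrogen bonds (geometric criterion)
# ---------------------------------------------------------------------------

def hbond_series(
    traj: Trajectory,
    donors: np.ndarray | list[int],
    hydrogens: np.ndarray | list[int] | None,
    acceptors: np.ndarray | list[int],
    d_max: float = 3.5,
    angle_min: float = 150.0,
) -> tuple[np.ndarray, dict[tuple[int, int], float]]:
    """Geometric hydrogen-bond counting along a trajectory.

    A donor–acceptor pair is bonded in a frame when their distance is
    ≤ ``d_max`` and, if ``hydrogens`` is given (one hydrogen index per
    donor, parallel lists), the D–H···A angle is ≥ ``angle_min`` degrees;
    with no hydrogens the heavy-atom distance criterion alone applies.
    Returns the per-frame bond count and per-(donor, acceptor) occupancy
    (fraction of frames bonded).
    """
    dn = np.asarray(donors, dtype=int)
    ac = np.asarray(acceptors, dtype=int)
    if dn.size == 0 or ac.size == 0:
        raise ValueError("donor and acceptor sets must be non-empty")
    hy = None
    if hydrogens is not None:
        hy = np.asarray(hydrogens, dtype=int)
        if hy.size != dn.size:
            raise ValueError("hydrogens must parallel donors (one H per donor)")
    counts = np.zeros(traj.n_frames, dtype=int)
    bonded_frames = np.zeros((dn.size, ac.size), dtype=int)
    for f in range(traj.n_frames):
        pos = traj.frames[f]
        d = cdist(pos[dn], pos[ac])
        ok = d <= d_max
        ok &= dn[:, None] != ac[None, :]  # a heavy atom never bonds itself
        if hy is not None:
            v1 = pos[dn] - pos[hy]  # H->D
            v2 = pos[ac][None, :, :] - pos[hy][:, None, :]  # H->A
            cosang = np.einsum("ia,ija->ij", v1, v2) / (
                np.linalg.norm(v1, axis=1)[:, None] * np.linalg.norm(v2, axis=2) + 1e-30
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            ok &= ang >= angle_min
        counts[f] = int(ok.sum())
        bonded_frames += ok
    occupancy = {
        (int(dn[i]), int(ac[j])): bonded_frames[i, j] / traj.n_frames
        for i in range(dn.size)
        for j in range(ac.size)
        if bonded_frames[i, j] > 0
    }
    return counts, occupancy


# ---------------------------------------------------------------------------
# 1-D Gaussian mixture decomposition (EM + BIC)
# ---------------------------------------------------------------------------

def _kmeanspp_centers(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [x[rng.integers(x.size)]]
    for _ in range(1, k):
        d2 = np.min((x[:, None] - np.array(centers)[None, :]) ** 2, axis=1)
        p = d2 / d2.sum() if d2.sum() > 0 else None
        centers.append(x[rng.choice(x.size, p=p)])
    return np.array(centers)


def _em_1d(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    tol: float = 1e-8,
    max_iter: int = 500,
):
    """One EM run; returns (loglik, means, sds, weights, trace, converged)."""
    n = x.size
    mu = _kmeanspp_centers(x, k, rng)
    sd = np.full(k, x.std() / max(k, 1) + 1e-12)
    w = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    trace = []
    converged = False
    var_floor = max(1e-10 * x.var(), 1e-300)
    for _ in range(max_iter):
        log_pdf = (
            -0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
            - np.log(sd[None, :])
            - 0.5 * np.log(2 * np.pi)
            + np.log(w[None, :])
        )
        ll_per = logsumexp(log_pdf, axis=1)
        ll = float(ll_per.sum())
        trace.append(ll)
        resp = np.exp(log_pdf - ll_per[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):  # empty component: failed start
            return -np.inf, mu, sd, w, np.array(trace), False
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, var_floor))
        if ll - prev_ll < tol * max(1.0, abs(ll)) and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
    return ll, mu, sd, w, np.array(trace), converged


def fit_mixture_1d(
    samples: np.ndarray,
    k_max: int = 3,
    n_starts: int = 5,
    seed: int = 0,
) -> MixtureFit:
    """Decompose a 1-D sample into Gaussian components, choosing k by BIC.

    EM is restarted ``n_starts`` times per candidate k from k-means++-style
    seeds; the component count minimizing BIC wins, ties broken toward the
    smaller k (parsimony). Deterministic for a given seed. The winning
    fit's log-likelihood trace is retained (non-decreasing by construction
    of EM).
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 10 * k_max:
        raise ValueError(f"need at least {10 * k_max} samples for k_max={k_max}")
    if x.std() == 0:
        raise ValueError("degenerate data: all samples identical (zero variance)")
    rng = np.random.default_rng(seed)
    bics: dict[int, float] = {}
    best = None  # (bic, k, mu, sd, w, trace, converged)
    for k in range(1, k_max + 1):
        best_ll = -np.inf
        best_run = None
        for _ in range(n_starts):
            ll, mu, sd, w, trace, conv = _em_1d(x, k, rng)
            if ll > best_ll:
                best_ll = ll
                best_run = (mu, sd, w, trace, conv)
        if best_run is None or not np.isfinite(best_ll):
            bics[k] = np.inf
            continue
        p = 3 * k - 1
        bic = p * np.log(x.size) - 2.0 * best_ll
        bics[k] = float(bic)
        # strict < keeps the smaller k on ties
        if best is None or bic < best[0] - 1e-12:
            best = (bic, k, *best_run)
    if best is None:
        raise RuntimeError("all EM runs failed")
    _, k, mu, sd, w, trace, conv = best
    order = np.argsort(mu)
    components = [(float(mu[i]), float(sd[i]), float(w[i])) for i in order]
    return MixtureFit(
        k=k,
        components=components,
        bic=bics,
        converged=bool(conv),
        seed=seed,
        loglik_trace=trace,
    )
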