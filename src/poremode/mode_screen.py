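"""Pore-gating mode screening.

The screening protocol asks which soft normal modes open a pore occluded by
a stack of gating residue pairs. Each of the first ``n_modes`` non-trivial
modes is used to displace the Cα structure in both senses up to a target
RMSD (default 2 Å); for every gating pair the change in pair distance
Δd = d(displaced) − d(original) is recorded, and a mode is *selected* when
it widens the gate beyond a threshold (default 0.5 Å). Two quantifiers are
implemented because "widening the pairs" is ambiguous:

``all_pairs_one_sense`` (default)
    there is one displacement sense in which every gating pair widens by at
    least the threshold simultaneously;
``any_pair_any_sense``
    some pair widens by at least the threshold in some sense.

The report stores Δd for every (mode, sense, pair) so either rule can be
re-derived after the fact. Additional observation pairs can be tracked
(recorded in the report, never used for selection).

For each selected mode a per-residue correlation profile (mean correlation
of the gating residues with every residue) and a magnified oscillating
trajectory for visualization can be produced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enm import ModeSet, mode_correlation
from .structure_io import ResidueKey, StructureModel, Trajectory, resolve_residue

__all__ = [
    "GatingPairSet",
    "ScreenConfig",
    "ModeScreenReport",
    "displace_along_mode",
    "pair_distance",
    "screen_modes",
    "gating_correlation_profile",
    "mode_trajectory",
]


@dataclass
class GatingPairSet:
    """Residue pairs defining the gate, and which atom measures distance.

    ``distance_atoms="CA"`` measures between alpha carbons (the only atoms
    present in a Cα network); any other atom name selects that named atom in
    each residue of the pair.
    """

    pairs: list[tuple[ResidueKey, ResidueKey]]
    distance_atoms: str = "CA"

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("gating pair set must be non-empty")

    def validate(self, structure: StructureModel) -> None:
        """Fail fast if any pair member is absent from the structure."""
        for a, b in self.pairs:
            resolve_residue(structure, a, self.distance_atoms)
            resolve_residue(structure, b, self.distance_atoms)


@dataclass
class ScreenConfig:
    """Parameters of the screening protocol (defaults: 100 modes, 2 Å RMSD
    displacement, 0.5 Å opening threshold, magnification 15 for the
    visualization trajectories)."""

    n_modes: int = 100
    rmsd_target: float = 2.0
    open_threshold: float = 0.5
    selection_rule: str = "all_pairs_one_sense"
    magnification: float = 15.0
    traj_frames: int = 34

    def __post_init__(self) -> None:
        if self.rmsd_target <= 0:
            raise ValueError("rmsd_target must be > 0")
        if self.open_threshold < 0:
            raise ValueError("open_threshold must be >= 0")
        if self.selection_rule not in ("all_pairs_one_sense", "any_pair_any_sense"):
            raise ValueError(f"unknown selection_rule {self.selection_rule!r}")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")

    def to_dict(self) -> dict:
        return {
            "n_modes": self.n_modes,
            "rmsd_target": self.rmsd_target,
            "open_threshold": self.open_threshold,
            "selection_rule": self.selection_rule,
            "magnification": self.magnification,
            "traj_frames": self.traj_frames,
        }


@dataclass
class ModeScreenReport:
    """Per-mode, per-sense, per-pair distance changes plus the selection."""

    records: pd.DataFrame  # columns: mode, sense, pair, role, d0, d, delta
    selected_modes: list[int]
    config: ScreenConfig
    structure_fingerprint: str

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "selected_modes": self.selected_modes,
            "config": self.config.to_dict(),
            "structure_fingerprint": self.structure_fingerprint,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def displace_along_mode(
    coords: np.ndarray,
    modes: ModeSet,
    k: int,
    rmsd_target: float = 2.0,
    sense: int = 1,
) -> np.ndarray:
    """Displace coordinates along mode k to an exact RMSD from the input.

    For a unit 3n eigenvector the step is coords + sense·s·v_k with
    s = rmsd_target·√n, which gives RMSD(out, in) = rmsd_target exactly.
    """
    if sense not in (1, -1):
        raise ValueError("sense must be +1 or -1")
    if rmsd_target <= 0:
        raise ValueError("rmsd_target must be > 0")
    coords = np.asarray(coords, dtype=float)
    V = modes.mode_vector(k)  # errors if k out of range
    if coords.shape != V.shape:
        raise ValueError(f"coords shape {coords.shape} incompatible with mode shape {V.shape}")
    n = coords.shape[0]
    s = rmsd_target * np.sqrt(n)
    return coords + sense * s * V


def pair_distance(
    coords: np.ndarray,
    structure: StructureModel,
    pair: tuple[ResidueKey, ResidueKey],
    distance_atoms: str = "CA",
) -> float:
    """Euclidean distance [Å] between the designated atoms of a residue pair."""
    coords = np.asarray(coords, dtype=float)
    ia = resolve_residue(structure, pair[0], distance_atoms)[0]
    ib = resolve_residue(structure, pair[1], distance_atoms)[0]
    return float(np.linalg.norm(coords[ia] - coords[ib]))


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def screen_modes(
    structure: StructureModel,
    modes: ModeSet,
    gating: GatingPairSet,
    config: ScreenConfig | None = None,
    observation_pairs: list[tuple[ResidueKey, ResidueKey]] | None = None,
) -> ModeScreenReport:
    """Displace along every mode in both senses and select opening modes.

    ``observation_pairs`` are measured and reported alongside the gating
    pairs but never influence selection (e.g. acidic-pocket pairs watched
    while the apolar seal pairs are the criterion).
    """
    config = config or ScreenConfig()
    gating.validate(structure)
    observation_pairs = observation_pairs or []
    for a, b in observation_pairs:
        resolve_residue(structure, a, gating.distance_atoms)
        resolve_residue(structure, b, gating.distance_atoms)

    coords0 = structure.coords
    if modes.n_sites * 3 != coords0.size:
        raise ValueError("mode set and structure have different site counts")
    n_screen = min(config.n_modes, modes.n_modes)

    all_pairs = [(p, "gating") for p in gating.pairs] + [
        (p, "observation") for p in observation_pairs
    ]
    d0 = {
        _pair_label(p): pair_distance(coords0, structure, p, gating.distance_atoms)
        for p, _ in all_pairs
    }

    rows = []
    gate_delta: dict[tuple[int, int], list[float]] = {}
    for k in range(1, n_screen + 1):
        for sense in (1, -1):
            disp = displace_along_mode(coords0, modes, k, config.rmsd_target, sense)
            deltas_g = []
            for p, role in all_pairs:
                label = _pair_label(p)
                d = pair_distance(disp, structure, p, gating.distance_atoms)
                rows.append(
                    {
                        "mode": k,
                        "sense": sense,
                        "pair": label,
                        "role": role,
                        "d0": d0[label],
                        "d": d,
                        "delta": d - d0[label],
                    }
                )
                if role == "gating":
                    deltas_g.append(d - d0[label])
            gate_delta[(k, sense)] = deltas_g

    selected = []
    thr = config.open_threshold
    for k in range(1, n_screen + 1):
        if config.selection_rule == "all_pairs_one_sense":
            hit = any(
                all(dd >= thr for dd in gate_delta[(k, s)]) for s in (1, -1)
            )
        else:  # any_pair_any_sense
            hit = any(
                any(dd >= thr for dd in gate_delta[(k, s)]) for s in (1, -1)
            )
        if hit:
            selected.append(k)

    records = pd.DataFrame(rows)
    fingerprint = _structure_fingerprint(coords0)
    return ModeScreenReport(
        records=records,
        selected_modes=selected,
        config=config,
        structure_fingerprint=fingerprint,
    )


def _pair_label(pair: tuple[ResidueKey, ResidueKey]) -> str:
    return f"{pair[0]}-{pair[1]}"


def _structure_fingerprint(coords: np.ndarray) -> str:
    import hashlib

    return hashlib.sha256(np.ascontiguousarray(np.round(coords, 6)).tobytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Profiles and visualization trajectories
# ---------------------------------------------------------------------------

def gating_correlation_profile(
    modes: ModeSet, k: int, gating_residues: list[ResidueKey]
) -> np.ndarray:
    """Mean single-mode correlation of the gating residues with every site.

    profile[j] = mean over gating residues g of c_gj for mode k; length is
    the number of network sites, values in [-1, 1].
    """
    if not gating_residues:
        raise ValueError("gating residue list must be non-empty")
    cmap = mode_correlation(modes, k)
    key_index = {key: i for i, key in enumerate(cmap.site_keys)}
    rows = []
    for g in gating_residues:
        if g not in key_index:
            raise KeyError(f"gating residue {g} not among network sites")
        rows.append(cmap.values[key_index[g]])
    return np.mean(rows, axis=0)


def mode_trajectory(
    structure: StructureModel,
    modes: ModeSet,
    k: int,
    magnification: float = 15.0,
    n_frames: int = 34,
    base_amplitude: float = 0.1,
) -> Trajectory:
    """Oscillating displacement along one mode for visualization.

    Frame t holds x₀ + magnification·sin(2πt/n_frames)·√n·base_amplitude·v_k,
    so frame 0 equals the input and the peak RMSD from the input is
    magnification·base_amplitude (1.5 Å with the defaults: base amplitude
    0.1 Å RMSD magnified 15×). One full period over ``n_frames`` frames.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    coords0 = structure.coords
    V = modes.mode_vector(k)
    n = coords0.shape[0]
    amp = magnification * base_amplitude * np.sqrt(n)
    phases = np.sin(2.0 * np.pi * np.arange(n_frames) / n_frames)
    frames = coords0[None, :, :] + amp * phases[:, None, None] * V[None, :, :]
    return Trajectory(frames=frames, topology=structure)
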