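"""End-to-end pipelines with strict config validation and run manifests.

Two orchestrations cover the full workflow:

* :func:`run_screen_pipeline` — structure → Cα subset → elastic network →
  normal modes → gating-pair mode screen → per-selected-mode correlation
  profiles and magnified visualization trajectories.
* :func:`run_traj_pipeline` — trajectory → any configured subset of
  distance series, nearest-ion series, RDF, RMSF, cross-correlation map,
  hydrogen bonds and mixture decomposition.

Configs are flat YAML; unknown keys are *errors*, not warnings, so a typo
in a parameter name (``treshold``) can never silently fall back to a
default. All randomness derives from the single top-level seed. Each run
writes a manifest (config echo, input content hashes, package version,
per-stage outputs and wall-clock) sufficient to re-run deterministic
stages bit-identically. User-facing distance tables report nm (× 0.1 from
the internal Å).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enm import build_network, compute_modes
from .mode_screen import (
    GatingPairSet,
    ModeScreenReport,
    ScreenConfig,
    gating_correlation_profile,
    mode_trajectory,
    screen_modes,
)
from .structure_io import ResidueKey, calpha_subset, read_pdb, select_atoms, write_pdb
from .traj_analysis import (
    dccm_from_traj,
    distance_series,
    fit_mixture_1d,
    hbond_series,
    nearest_ion_series,
    rdf,
    rmsf,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "ConfigError",
    "load_config",
    "run_screen_pipeline",
    "run_traj_pipeline",
]

log = logging.getLogger("poremode")


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


_TOP_KEYS = {
    "input", "output_dir", "seed", "log_level", "screen", "analyses", "pairs_file",
}
_SCREEN_KEYS = {
    "cutoff", "gamma", "spring_model", "n_modes", "rmsd_target", "open_threshold",
    "selection_rule", "magnification", "traj_frames", "pairs", "observation_pairs",
    "distance_atoms", "write_mode_trajectories",
}
_ANALYSIS_KEYS = {
    "dist": {"pairs", "metric", "atom_names", "mixture", "k_max", "n_starts"},
    "iondist": {"residue", "atom_names", "ion_resnames"},
    "rdf": {"ref", "target_resnames", "r_max", "bin_width", "bulk_density"},
    "rmsf": {"fit", "selection"},
    "dccm": {"fit", "selection"},
    "hbond": {"donor_names", "acceptor_names", "d_max", "angle_min"},
    "mix": {"series_csv", "column", "k_max", "n_starts"},
}


@dataclass
class RunConfig:
    """Validated run configuration (see module docstring for the format)."""

    input: str
    output_dir: str
    seed: int = 0
    log_level: str = "INFO"
    screen: dict = field(default_factory=dict)
    analyses: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "input" not in raw or "output_dir" not in raw:
            raise ConfigError("config requires 'input' and 'output_dir'")
        screen = raw.get("screen") or {}
        bad = set(screen) - _SCREEN_KEYS
        if bad:
            raise ConfigError(f"unknown screen keys: {sorted(bad)}")
        analyses = raw.get("analyses") or {}
        for name, params in analyses.items():
            if name not in _ANALYSIS_KEYS:
                raise ConfigError(f"unknown analysis {name!r}")
            bad = set(params or {}) - _ANALYSIS_KEYS[name]
            if bad:
                raise ConfigError(f"unknown {name} keys: {sorted(bad)}")
        return cls(
            input=str(raw["input"]),
            output_dir=str(raw["output_dir"]),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
            screen=screen,
            analyses=analyses,
        )

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "log_level": self.log_level,
            "screen": self.screen,
            "analyses": self.analyses,
        }


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(raw)


@dataclass
class RunManifest:
    """Everything needed to audit and re-run a pipeline invocation."""

    config: dict
    input_sha256: str
    package_version: str
    outputs: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    failed_stage: str | None = None

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _parse_pairs(entries) -> list[tuple[ResidueKey, ResidueKey]]:
    pairs = []
    for e in entries:
        if len(e) != 4:
            raise ConfigError(f"pair entry must be [chainA, residA, chainB, residB]: {e}")
        pairs.append((ResidueKey(str(e[0]), int(e[1])), ResidueKey(str(e[2]), int(e[3]))))
    return pairs


class _Stage:
    """Context helper recording wall-clock and failure attribution."""

    def __init__(self, manifest: RunManifest, name: str):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest.stage_seconds[self.name] = round(time.perf_counter() - self.t0, 4)
        if exc is not None:
            self.manifest.failed_stage = self.name
            log.error("stage %s failed: %s", self.name, exc)
        return False


# ---------------------------------------------------------------------------
# Screen pipeline
# ---------------------------------------------------------------------------

def run_screen_pipeline(config: RunConfig) -> RunManifest:
    """Structure → ENM → mode screen → profiles and mode trajectories."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sc = config.screen
    if not sc.get("pairs"):
        raise ConfigError("screen.pairs is required for the screen pipeline")
    screen_cfg = ScreenConfig(
        n_modes=int(sc.get("n_modes", 100)),
        rmsd_target=float(sc.get("rmsd_target", 2.0)),
        open_threshold=float(sc.get("open_threshold", 0.5)),
        selection_rule=sc.get("selection_rule", "all_pairs_one_sense"),
        magnification=float(sc.get("magnification", 15.0)),
        traj_frames=int(sc.get("traj_frames", 34)),
    )
    manifest = RunManifest(
        config=config.to_dict(),
        input_sha256=_sha256(config.input),
        package_version=__version__,
    )

    with _Stage(manifest, "read_structure"):
        structure = read_pdb(config.input, model_policy="first")
    with _Stage(manifest, "calpha_subset"):
        ca = calpha_subset(structure)
    with _Stage(manifest, "build_network"):
        net = build_network(
            ca,
            cutoff=float(sc.get("cutoff", 15.0)),
            gamma=float(sc.get("gamma", 1.0)),
            spring_model=sc.get("spring_model", "uniform_cutoff"),
        )
    with _Stage(manifest, "compute_modes"):
        n_modes = min(screen_cfg.n_modes, 3 * net.n_sites - 6)
        modes = compute_modes(net, n_modes=n_modes)
    with _Stage(manifest, "screen_modes"):
        gating = GatingPairSet(
            pairs=_parse_pairs(sc["pairs"]),
            distance_atoms=sc.get("distance_atoms", "CA"),
        )
        obs = _parse_pairs(sc.get("observation_pairs", []))
        report = screen_modes(ca, modes, gating, screen_cfg, observation_pairs=obs)
        report_tsv = out / "screen_report.tsv"
        report.to_tsv(report_tsv)
        report.to_json(out / "screen_report.json")
        manifest.outputs["screen_report_tsv"] = str(report_tsv)
        manifest.outputs["screen_report_json"] = str(out / "screen_report.json")
    with _Stage(manifest, "profiles_and_trajectories"):
        gating_res = sorted(
            {k for p in gating.pairs for k in p}, key=lambda k: (k.chain, k.resid)
        )
        for k in report.selected_modes:
            prof = gating_correlation_profile(modes, k, gating_res)
            pf = out / f"profile_mode{k}.csv"
            pd.DataFrame(
                {"site": [str(s) for s in modes.site_keys], "mean_correlation": prof}
            ).to_csv(pf, index=False)
            manifest.outputs[f"profile_mode{k}"] = str(pf)
            if sc.get("write_mode_trajectories", True):
                mt = mode_trajectory(
                    ca, modes, k,
                    magnification=screen_cfg.magnification,
                    n_frames=screen_cfg.traj_frames,
                )
                tf = out / f"mode{k}_trajectory.pdb"
                write_pdb(mt, tf)
                manifest.outputs[f"mode{k}_trajectory"] = str(tf)

    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Trajectory pipeline
# ---------------------------------------------------------------------------

def run_traj_pipeline(config: RunConfig) -> RunManifest:
    """Trajectory → any configured subset of the statistics operations."""
    logging.basicConfig(level=config.log_level)
    if not config.analyses:
        raise ConfigError("analyses block is empty: nothing to compute")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        input_sha256=_sha256(config.input),
        package_version=__version__,
    )
    with _Stage(manifest, "read_trajectory"):
        traj = read_pdb(config.input, model_policy="all")
    topo = traj.topology

    def _sidecar(name: str, payload: dict) -> None:
        p = out / f"{name}.json"
        payload = {"seed": config.seed, **payload}
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        manifest.outputs[f"{name}_json"] = str(p)

    for name, params in config.analyses.items():
        params = params or {}
        with _Stage(manifest, name):
            if name == "dist":
                atom = params.get("atom_names", "CA")
                rows = {}
                for e in params["pairs"]:
                    a = select_atoms(topo, chain=str(e[0]), resids={int(e[1])}, names={atom})
                    b = select_atoms(topo, chain=str(e[2]), resids={int(e[3])}, names={atom})
                    lab = f"{e[0]}{e[1]}-{e[2]}{e[3]}"
                    s = distance_series(traj, (a[:1], b[:1]), metric="single_atom", label=lab)
                    rows[lab] = s.in_nm()
                df = pd.DataFrame(rows)
                df.insert(0, "frame", np.arange(traj.n_frames))
                p = out / "distances_nm.csv"
                df.to_csv(p, index=False)
                manifest.outputs["distances_csv"] = str(p)
                _sidecar("dist", {"params": params, "unit": "nm"})
                if params.get("mixture"):
                    for lab, vals in rows.items():
                        fit = fit_mixture_1d(
                            np.asarray(vals),
                            k_max=int(params.get("k_max", 3)),
                            n_starts=int(params.get("n_starts", 5)),
                            seed=config.seed,
                        )
                        _sidecar(
                            f"mixture_{lab}",
                            {
                                "k": fit.k,
                                "components_mean_sd_weight": fit.components,
                                "bic": fit.bic,
                                "unit": "nm",
                            },
                        )
            elif name == "iondist":
                res = params["residue"]  # [chain, resid]
                ra = select_atoms(topo, chain=str(res[0]), resids={int(res[1])})
                ion_resnames = set(params.get("ion_resnames", ["NA", "SOD"]))
                ions = [i for i, a in enumerate(topo.atoms) if a.resname in ion_resnames]
                s = nearest_ion_series(traj, ra, ions)
                p = out / "nearest_ion_nm.csv"
                pd.DataFrame({"frame": np.arange(traj.n_frames), "d_nm": s.in_nm()}).to_csv(
                    p, index=False
                )
                manifest.outputs["nearest_ion_csv"] = str(p)
                _sidecar("iondist", {"params": params, "unit": "nm"})
            elif name == "rdf":
                ref = params["ref"]  # [chain, resid] or atom name
                if isinstance(ref, list):
                    ri = select_atoms(topo, chain=str(ref[0]), resids={int(ref[1])})
                else:
                    ri = select_atoms(topo, names={str(ref)})
                tnames = set(params.get("target_resnames", ["HOH"]))
                ti = [i for i, a in enumerate(topo.atoms) if a.resname in tnames]
                prof = rdf(
                    traj, ri, ti,
                    r_max=float(params.get("r_max", 10.0)),
                    bin_width=float(params.get("bin_width", 0.1)),
                    bulk_density=params.get("bulk_density"),
                )
                p = out / "rdf.csv"
                pd.DataFrame({"r_A": prof.r_centers, "g": prof.g}).to_csv(p, index=False)
                manifest.outputs["rdf_csv"] = str(p)
                _sidecar("rdf", {"params": params, "bulk_density_A3": prof.bulk_density})
            elif name == "rmsf":
                fit_idx = _fit_indices(topo, params.get("fit", "CA"))
                prof = rmsf(traj, fit_indices=fit_idx)
                p = out / "rmsf.csv"
                pd.DataFrame(
                    {"site": [str(k) for k in prof.residue_keys], "rmsf_A": prof.values}
                ).to_csv(p, index=False)
                manifest.outputs["rmsf_csv"] = str(p)
                _sidecar("rmsf", {"params": params, "unit": "Å"})
            elif name == "dccm":
                fit_idx = _fit_indices(topo, params.get("fit", "CA"))
                cmap = dccm_from_traj(traj, fit_indices=fit_idx)
                p = out / "dccm.csv"
                cmap.to_csv(p)
                manifest.outputs["dccm_csv"] = str(p)
                _sidecar("dccm", {"params": params})
            elif name == "hbond":
                dn = select_atoms(topo, names=set(params["donor_names"]))
                ac = select_atoms(topo, names=set(params["acceptor_names"]))
                counts, occ = hbond_series(
                    traj, dn, None, ac,
                    d_max=float(params.get("d_max", 3.5)),
                    angle_min=float(params.get("angle_min", 150.0)),
                )
                p = out / "hbond_counts.csv"
                pd.DataFrame({"frame": np.arange(traj.n_frames), "n_bonds": counts}).to_csv(
                    p, index=False
                )
                manifest.outputs["hbond_csv"] = str(p)
                _sidecar(
                    "hbond",
                    {"params": params, "occupancy": {f"{d}-{a}": v for (d, a), v in occ.items()}},
                )
            elif name == "mix":
                df = pd.read_csv(params["series_csv"])
                col = params.get("column", df.columns[-1])
                fit = fit_mixture_1d(
                    df[col].to_numpy(),
                    k_max=int(params.get("k_max", 3)),
                    n_starts=int(params.get("n_starts", 5)),
                    seed=config.seed,
                )
                _sidecar(
                    "mix",
                    {
                        "k": fit.k,
                        "components_mean_sd_weight": fit.components,
                        "bic": fit.bic,
                        "converged": fit.converged,
                    },
                )

    manifest.write(out / "manifest.json")
    return manifest


def _fit_indices(topo, fit: str):
    if fit == "all":
        return None
    idx = select_atoms(topo, names={fit})
    if len(idx) < 3:
        raise ConfigError(f"fit selection {fit!r} matches fewer than 3 atoms")
    return idx
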