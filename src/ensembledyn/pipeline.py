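"""Config-driven analysis pipeline with a reproducible report bundle.

A single YAML config names the input trajectories, the residue selections
and the analyses to run (RMSD pivots, msf, correlation maps and windows,
bond autocorrelations, distances, clustering, PCA).  ``run_pipeline``
executes the requested stages in dependency order and writes a bundle of
labelled CSV files plus a machine-readable manifest recording the package
version, the config hash, all seeds and a checksum per output — rerunning
an identical config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import SelectionMask, Topology, Trajectory
from .correlations import bond_autocorrelation, cross_correlation_matrix, windowed_correlations
from .ensemble import cluster_conformations, pca_fit, pca_project
from .fluctuations import distance_timeseries, mean_square_fluctuations
from .io import (
    read_reference_structure,
    read_trajectory,
    topology_from_frame_table,
    write_results,
    write_structures_pdb,
)
from .superpose import rmsd_timeseries

__all__ = ["AnalysisConfig", "validate_config", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = (
    "rmsd",
    "msf",
    "distance",
    "correlation",
    "bond_autocorrelation",
    "clustering",
    "pca",
)


@dataclass
class AnalysisConfig:
    """Validated pipeline configuration."""

    raw: dict
    path: Path | None
    reference: Path | None
    inputs: list[dict]
    selections: dict[str, dict]
    analyses: dict[str, list[dict]]
    output_dir: Path
    warnings: list[str] = field(default_factory=list)

    def sha256(self) -> str:
        blob = yaml.safe_dump(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _check_selection_def(name: str, sel: dict, errors: list[str]) -> None:
    if not isinstance(sel, dict):
        errors.append(f"selections.{name}: must be a mapping")
        return
    keys = set(sel)
    if not keys & {"chain", "chains", "residues", "indices"}:
        errors.append(
            f"selections.{name}: needs 'chain(s)', 'residues' or 'indices'"
        )
    if "residues" in sel:
        r = sel["residues"]
        if not (isinstance(r, (list, tuple)) and len(r) == 2):
            errors.append(f"selections.{name}.residues: expected [first, last]")
        if "chain" not in sel:
            errors.append(f"selections.{name}: 'residues' requires 'chain'")


def validate_config(path_or_dict: str | Path | dict) -> AnalysisConfig:
    """Parse and validate a pipeline config; raise with ALL errors listed.

    Schema violations are collected exhaustively and reported together.
    Suspicious-but-legal values (e.g. an autocorrelation delay beyond half
    the trajectory span) become warnings on the returned config.
    """
    if isinstance(path_or_dict, dict):
        raw, path = path_or_dict, None
    else:
        path = Path(path_or_dict)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    errors: list[str] = []
    warnings: list[str] = []

    inputs = raw.get("inputs") or []
    if not inputs:
        errors.append("inputs: at least one trajectory is required")
    names = set()
    for i, inp in enumerate(inputs):
        where = f"inputs[{i}]"
        if "name" not in inp:
            errors.append(f"{where}: missing 'name'")
        elif inp["name"] in names:
            errors.append(f"{where}: duplicate name {inp['name']!r}")
        else:
            names.add(inp["name"])
        if "path" not in inp:
            errors.append(f"{where}: missing 'path'")
        elif path is not None and not (path.parent / inp["path"]).exists() \
                and not Path(inp["path"]).exists():
            errors.append(f"{where}: file not found: {inp['path']}")
        if inp.get("stride", 1) < 1:
            errors.append(f"{where}.stride: must be a positive integer")
        if inp.get("frame_interval_ns", 1.0) <= 0:
            errors.append(f"{where}.frame_interval_ns: must be positive")
        if inp.get("equilibration_end_ns", 0.0) < 0:
            errors.append(f"{where}.equilibration_end_ns: must be >= 0")

    selections = raw.get("selections") or {}
    for name, sel in selections.items():
        _check_selection_def(name, sel, errors)

    def known_selection(ref, where):
        if ref not in (None, "all") and ref not in selections:
            errors.append(f"{where}: undefined selection {ref!r}")

    def known_input(ref, where):
        if ref not in names:
            errors.append(f"{where}: undefined trajectory {ref!r}")

    analyses = raw.get("analyses") or {}
    for stage in analyses:
        if stage not in STAGES:
            errors.append(f"analyses.{stage}: unknown stage (choose from {STAGES})")
    for stage, entries in analyses.items():
        if stage not in STAGES:
            continue
        if not isinstance(entries, list):
            errors.append(f"analyses.{stage}: must be a list of entries")
            continue
        for j, entry in enumerate(entries):
            where = f"analyses.{stage}[{j}]"
            if stage in {"rmsd", "msf", "distance", "correlation", "bond_autocorrelation"}:
                known_input(entry.get("trajectory"), f"{where}.trajectory")
            if stage in {"clustering", "pca"}:
                for t in entry.get("trajectories", []):
                    known_input(t, f"{where}.trajectories")
                if not entry.get("trajectories"):
                    errors.append(f"{where}.trajectories: at least one required")
            for key in ("fit", "measure", "selection", "exclude"):
                if key in entry:
                    known_selection(entry[key], f"{where}.{key}")
            if stage == "distance":
                for key in ("a", "b"):
                    known_selection(entry.get(key), f"{where}.{key}")
                if entry.get("mode", "calpha") not in {"calpha", "centroid"}:
                    errors.append(f"{where}.mode: must be 'calpha' or 'centroid'")
            if stage == "clustering" and entry.get("radius", 1.7) <= 0:
                errors.append(f"{where}.radius: must be positive")
            if stage == "bond_autocorrelation":
                delays = entry.get("delays_ns", [])
                if not delays:
                    errors.append(f"{where}.delays_ns: required")
                elif any(d < 0 for d in delays):
                    errors.append(f"{where}.delays_ns: delays must be nonnegative")
            if stage == "correlation":
                for w in entry.get("windows") or []:
                    if not (isinstance(w, (list, tuple)) and len(w) == 2 and w[1] > w[0]):
                        errors.append(f"{where}.windows: bad window {w!r}")

    if errors:
        raise ValueError(
            "invalid config:\n" + "\n".join(f"  - {e}" for e in errors)
        )
    return AnalysisConfig(
        raw=raw,
        path=path,
        reference=Path(raw["reference"]) if raw.get("reference") else None,
        inputs=inputs,
        selections=selections,
        analyses=analyses,
        output_dir=Path(raw.get("output_dir", "ensembledyn_out")),
        warnings=warnings,
    )


def _resolve(base: Path | None, p: str | Path) -> Path:
    p = Path(p)
    if p.exists() or base is None:
        return p
    return base / p


def _build_mask(topology: Topology, name: str | None, selections: dict) -> SelectionMask | None:
    if name in (None, "all"):
        return None
    sel = selections[name]
    chains = sel.get("chains") or ([sel["chain"]] if "chain" in sel else [])
    if "indices" in sel:
        return SelectionMask(topology, sel["indices"])
    if "residues" in sel:
        first, last = sel["residues"]
        return SelectionMask.from_residue_range(topology, sel["chain"], first, last)
    return SelectionMask.from_chain(topology, *chains)


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: AnalysisConfig,
    out_dir: str | Path | None = None,
    stages: list[str] | None = None,
    verbose: bool = False,
) -> dict:
    """Execute the configured analyses and write the report bundle.

    Returns the manifest dict (also written as ``manifest.json``).  Any
    stage error aborts the run; outputs written so far are listed in the
    manifest as incomplete.
    """
    out = Path(out_dir) if out_dir is not None else config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ensembledyn")
    root.addHandler(handler)
    root.setLevel(logging.DEBUG if verbose else logging.INFO)
    manifest: dict = {
        "package": "ensembledyn",
        "version": __version__,
        "config_sha256": config.sha256(),
        "seeds": {},
        "outputs": {},
        "complete": False,
    }
    base = config.path.parent if config.path else None
    requested = list(stages) if stages else list(STAGES)
    bad = [s for s in requested if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stage(s): {bad}")

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"][name] = _sha256_file(path)
        logger.info("wrote %s", path)

    try:
        # --- input stage -------------------------------------------------
        if config.reference is not None:
            topology, ref_coords = read_reference_structure(
                _resolve(base, config.reference)
            )
        else:
            first = _resolve(base, config.inputs[0]["path"])
            topology = topology_from_frame_table(first)
            ref_coords = None
        trajs: dict[str, Trajectory] = {}
        for inp in config.inputs:
            traj = read_trajectory(
                _resolve(base, inp["path"]),
                topology,
                stride=inp.get("stride", 1),
                frame_interval_ns=inp.get("frame_interval_ns", 1.0),
                equilibration_end=inp.get("equilibration_end_ns", 0.0),
            )
            trajs[inp["name"]] = traj
            logger.info(
                "loaded %s: %d frames, %d residues", inp["name"], traj.n_frames,
                traj.n_residues,
            )
        if ref_coords is None:
            ref_coords = trajs[config.inputs[0]["name"]].coordinates[0]

        def mask(name):
            return _build_mask(topology, name, config.selections)

        # --- analysis stages ---------------------------------------------
        for j, entry in enumerate(_entries(config, "rmsd", requested)):
            traj = trajs[entry["trajectory"]]
            series = rmsd_timeseries(
                traj, ref_coords, mask(entry.get("fit")), mask(entry.get("measure"))
            )
            name = entry.get("name", f"rmsd_{j}")
            df = pd.DataFrame({"time_ns": traj.frame_times, "rmsd_A": series})
            emit(f"{name}.csv", lambda p, df=df: df.to_csv(p, index=False, float_format="%.12g"))

        for j, entry in enumerate(_entries(config, "msf", requested)):
            traj = trajs[entry["trajectory"]]
            prof = mean_square_fluctuations(
                traj,
                mask(entry.get("fit")),
                mask(entry.get("measure")),
                exclude_mask=mask(entry.get("exclude")),
            )
            name = entry.get("name", f"msf_{j}")
            df = pd.DataFrame({"residue": prof.labels, "msf_A2": prof.values})
            emit(f"{name}.csv", lambda p, df=df: df.to_csv(p, index=False, float_format="%.12g"))

        for j, entry in enumerate(_entries(config, "distance", requested)):
            traj = trajs[entry["trajectory"]]
            a, b = mask(entry["a"]), mask(entry["b"])
            series, mean = distance_timeseries(
                traj, a, b, mode=entry.get("mode", "calpha")
            )
            name = entry.get("name", f"distance_{j}")
            use = traj.usable()
            df = pd.DataFrame({"time_ns": traj.frame_times[use], "distance_A": series})
            emit(f"{name}.csv", lambda p, df=df: df.to_csv(p, index=False, float_format="%.12g"))
            logger.info("%s: mean distance %.3f A", name, mean)

        for j, entry in enumerate(_entries(config, "correlation", requested)):
            traj = trajs[entry["trajectory"]]
            name = entry.get("name", f"correlation_{j}")
            windows = entry.get("windows")
            if windows:
                mats, diffs = windowed_correlations(
                    traj,
                    [tuple(w) for w in windows],
                    mask(entry.get("fit")),
                    mask(entry.get("measure")),
                )
                for k, mat in enumerate(mats):
                    emit(
                        f"{name}_window{k}.csv",
                        lambda p, m=mat: write_results(m.values, p, labels=m.labels),
                    )
                if diffs:
                    df = pd.DataFrame(
                        [(i, k, v) for (i, k), v in diffs.items()],
                        columns=["window_i", "window_j", "mean_abs_difference"],
                    )
                    emit(f"{name}_window_contrasts.csv",
                         lambda p, df=df: df.to_csv(p, index=False, float_format="%.12g"))
            else:
                mat = cross_correlation_matrix(
                    traj, mask(entry.get("fit")), mask(entry.get("measure"))
                )
                emit(f"{name}.csv",
                     lambda p, m=mat: write_results(m.values, p, labels=m.labels))

        for j, entry in enumerate(_entries(config, "bond_autocorrelation", requested)):
            traj = trajs[entry["trajectory"]]
            span = traj.frame_times[-1] - traj.frame_times[0]
            for d in entry["delays_ns"]:
                if d > span / 2:
                    logger.warning(
                        "delay %.3g ns exceeds half the trajectory span (%.3g ns)",
                        d, span,
                    )
            prof = bond_autocorrelation(traj, entry["delays_ns"])
            name = entry.get("name", f"bond_autocorrelation_{j}")
            rows = [
                (prof.bond_labels[b], float(tau), prof.values[b, k])
                for b in range(prof.values.shape[0])
                for k, tau in enumerate(prof.delays)
            ]
            df = pd.DataFrame(rows, columns=["bond", "delay_ns", "autocorrelation"])
            emit(f"{name}.csv", lambda p, df=df: df.to_csv(p, index=False, float_format="%.12g"))

        for j, entry in enumerate(_entries(config, "clustering", requested)):
            members = [trajs[t] for t in entry["trajectories"]]
            seed = int(entry.get("seed", 0))
            manifest["seeds"][f"clustering_{j}"] = seed
            model = cluster_conformations(
                members,
                ref_coords,
                mask(entry.get("fit")),
                radius=float(entry.get("radius", 1.7)),
                seed=seed,
                selection=mask(entry.get("selection")),
                source_labels=list(entry["trajectories"]),
            )
            name = entry.get("name", f"clustering_{j}")
            emit(f"{name}_occupancy.csv",
                 lambda p, m=model: m.occupancy.to_csv(p, float_format="%.12g"))
            for t_label, tl in zip(entry["trajectories"], model.timelines()):
                emit(f"{name}_timeline_{t_label}.csv",
                     lambda p, tl=tl: tl.to_csv(p, index=False, float_format="%.12g"))
            emit(f"{name}_centroids.pdb",
                 lambda p, m=model: write_structures_pdb(topology, _pad_centroids(m, topology), p))

        for j, entry in enumerate(_entries(config, "pca", requested)):
            members = [trajs[t] for t in entry["trajectories"]]
            model = pca_fit(
                members,
                ref_coords,
                mask(entry.get("fit")),
                selection=mask(entry.get("selection")),
            )
            name = entry.get("name", f"pca_{j}")
            df = pd.DataFrame(
                {
                    "eigenvalue_A2": model.eigenvalues,
                    "proportion": model.proportions,
                    "cumulative": model.cumulative,
                }
            )
            emit(f"{name}_eigenvalues.csv",
                 lambda p, df=df: df.to_csv(p, index=False, float_format="%.12g"))
            n_comp = int(entry.get("components", 2))
            for t_label in entry["trajectories"]:
                proj = pca_project(trajs[t_label], model, list(range(n_comp)))
                pdf = pd.DataFrame(proj, columns=[f"PC{c+1}_A" for c in range(n_comp)])
                emit(f"{name}_projection_{t_label}.csv",
                     lambda p, pdf=pdf: pdf.to_csv(p, index=False, float_format="%.12g"))

        manifest["complete"] = True
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        root.removeHandler(handler)
        handler.close()
    return manifest


def _entries(config: AnalysisConfig, stage: str, requested: list[str]) -> list[dict]:
    if stage not in requested:
        return []
    return config.analyses.get(stage, [])


def _pad_centroids(model, topology: Topology) -> np.ndarray:
    """Embed selected-coordinate centroids into full-topology frames."""
    k = model.centroids.shape[0]
    frames = np.zeros((k, len(topology), 3))
    frames[:, model.selection_indices] = model.centroids
    return frames
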