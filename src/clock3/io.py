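"""File round-tripping: parameter sets, condition registries, trajectories,
run manifests.  Plain-text first (TSV/CSV/YAML); trajectories can also go to
an HDF5 container."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .integrators import Trajectory
from .network import ClockNetwork, ParameterSet
from .perturbations import Condition, EditOp, Expectation, Perturbation

__all__ = [
    "read_parameter_set", "write_parameter_set",
    "conditions_to_yaml", "conditions_from_yaml",
    "write_trajectory_tsv", "write_trajectory_h5",
    "write_network_yaml", "write_manifest",
]


def read_parameter_set(path: str | Path) -> ParameterSet:
    return ParameterSet.from_text(Path(path).read_text())


def write_parameter_set(params: ParameterSet, path: str | Path) -> None:
    Path(path).write_text(params.to_text())


def conditions_to_yaml(conditions: Sequence[Condition]) -> str:
    docs = []
    for c in conditions:
        docs.append({
            "id": c.id,
            "perturbation": {
                "name": c.perturbation.name,
                "edits": [[p, op.value, f] for p, op, f in c.perturbation.edits],
            },
            "expected": c.expected.value,
            "marker": c.marker,
            "band_pct": list(c.band_pct) if c.band_pct else None,
            "source": c.source,
            "canonical": c.canonical,
        })
    return yaml.safe_dump(docs, sort_keys=False)


def conditions_from_yaml(text: str) -> list[Condition]:
    out = []
    for d in yaml.safe_load(text):
        pert = Perturbation(d["perturbation"]["name"],
                            tuple((p, EditOp(op), float(f))
                                  for p, op, f in d["perturbation"]["edits"]))
        out.append(Condition(
            id=d["id"], perturbation=pert,
            expected=Expectation(d["expected"]), marker=d.get("marker", "MnB"),
            band_pct=tuple(d["band_pct"]) if d.get("band_pct") else None,
            source=d.get("source", ""), canonical=d.get("canonical", True)))
    return out


def write_trajectory_tsv(traj: Trajectory, path: str | Path) -> None:
    Path(path).write_text(traj.to_tsv())


def write_trajectory_h5(traj: Trajectory, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("states", data=traj.states, compression="gzip")
        f.create_dataset("species",
                         data=np.array(traj.species_order, dtype="S"))
        f.attrs["dt"] = traj.config.dt
        f.attrs["t_end"] = traj.config.t_end
        f.attrs["solver"] = traj.config.solver


def write_network_yaml(network: ClockNetwork, params: ParameterSet,
                       path: str | Path) -> None:
    """Structured-text network definition: species, parameters with ranges,
    reactions."""
    doc = {
        "genes": list(network.genes),
        "species": [s.label for s in network.species],
        "parameters": {p: [params[p], *params.ranges[p]]
                       for p in network.parameters},
        # compact reaction strings: "rate | kind | A + B -> C + D"
        "reactions": [
            f"{r.name} | {r.term_kind.value} | "
            f"{' + '.join(r.reactants) or '0'} -> "
            f"{' + '.join(r.products) or '0'}"
            for r in network.reactions],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False,
                                         default_flow_style=None, width=100))


def write_manifest(out_dir: str | Path, seed: int, config: dict) -> Path:
    """Record seed, config hash and environment versions next to the outputs
    so a run can be reproduced bit-for-bit on the deterministic paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
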