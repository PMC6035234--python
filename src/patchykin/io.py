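"""File formats: TSV tables, extended-XYZ snapshots, TOML configs, JSON results.

All floating-point output uses 17 significant digits, so write -> read is
bit-exact.  Snapshot files follow an extended-XYZ dialect: the comment line
carries the box, reduced time, extent of reaction and current barrier;
columns are species label, center, quaternion (w x y z), velocity and
angular momentum.  Unknown extra columns in foreign files are preserved
opaquely and re-emitted on write.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .geometry import BoxSpec
from .observables import ClusterDistribution, KineticCurve
from .state import BondRegistry, InteractionParams, SimulationConfig, SystemState

__all__ = [
    "write_kinetic_curve", "read_kinetic_curve",
    "write_snapshot", "read_snapshot",
    "write_distribution", "read_distribution",
    "read_config", "write_params", "read_params",
    "RunManifest",
]

_FMT = "%.17g"


class ParseError(ValueError):
    def __init__(self, path, line, msg):
        super().__init__(f"{path}:{line}: {msg}")


def _fmt(x: float) -> str:
    return _FMT % x


def write_kinetic_curve(path, curve: KineticCurve) -> None:
    with open(path, "w") as fh:
        cols = "t\tp" + ("\tsem" if curve.sem is not None else "")
        fh.write(f"# patchykin kinetic curve v1; replicas={curve.n_replicas}\n")
        fh.write(f"# columns: {cols}\n")
        for k in range(len(curve.times)):
            row = [_fmt(curve.times[k]), _fmt(curve.p[k])]
            if curve.sem is not None:
                row.append(_fmt(curve.sem[k]))
            fh.write("\t".join(row) + "\n")


def read_kinetic_curve(path) -> KineticCurve:
    times, ps, sems = [], [], []
    n_replicas = 1
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "patchykin kinetic curve" in line and "v1" not in line:
                    raise ParseError(
                        path, ln, "unsupported curve-format version; this "
                        "build reads v1 -- regenerate or convert the file")
                if "replicas=" in line:
                    n_replicas = int(line.split("replicas=")[1].split(";")[0])
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(path, ln, "expected at least 2 columns")
            try:
                vals = [float(v) for v in parts[:3]]
            except ValueError as exc:
                raise ParseError(path, ln, f"bad number: {exc}") from exc
            times.append(vals[0])
            ps.append(vals[1])
            if len(vals) > 2:
                sems.append(vals[2])
    t = np.array(times)
    if np.any(np.diff(t) <= 0):
        raise ParseError(path, 0, "time column must be strictly increasing")
    return KineticCurve(times=t, p=np.array(ps),
                        sem=np.array(sems) if sems else None,
                        n_replicas=n_replicas)


def write_distribution(path, dist: ClusterDistribution,
                       source: str = "simulation") -> None:
    with open(path, "w") as fh:
        fh.write(f"# patchykin cluster distribution v1; p={_fmt(dist.p)}; "
                 f"N={dist.n_particles}; source={source}\n")
        fh.write("# columns: s\tn_s  (raw counts; normalize by N if needed)\n")
        for s, c in zip(dist.sizes, dist.counts):
            fh.write(f"{int(s)}\t{_fmt(c)}\n")


def read_distribution(path) -> ClusterDistribution:
    sizes, counts = [], []
    p, n_part = 0.0, 0
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split(";"):
                    tok = tok.strip()
                    if tok.startswith("p="):
                        p = float(tok[2:])
                    elif tok.startswith("N="):
                        n_part = int(tok[2:])
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(path, ln, "expected 2 columns (s, n_s)")
            sizes.append(int(parts[0]))
            counts.append(float(parts[1]))
    return ClusterDistribution(sizes=np.array(sizes), counts=np.array(counts),
                               n_particles=n_part, p=p)


_SPECIES_LABEL = {0: "A", 1: "B"}
_LABEL_SPECIES = {"A": 0, "B": 1}


def write_snapshot(path, state: SystemState) -> None:
    extras = getattr(state, "xyz_extras", None)
    with open(path, "w") as fh:
        fh.write(f"{state.n_particles}\n")
        box = " ".join(_fmt(e) for e in state.box.edges)
        bonds = ";".join(f"{a},{b}" for a, b in state.registry.pairs)
        fh.write(f'box="{box}" time={_fmt(state.time)} p={_fmt(state.p)} '
                 f'dU={_fmt(state.dU)} bonds="{bonds}" '
                 f'columns=species:pos:quat:vel:angmom\n')
        wrapped = state.wrapped_positions()
        for i in range(state.n_particles):
            row = [_SPECIES_LABEL[int(state.species_id[i])]]
            row += [_fmt(v) for v in wrapped[i]]
            row += [_fmt(v) for v in state.quat[i]]
            row += [_fmt(v) for v in state.vel[i]]
            row += [_fmt(v) for v in state.angmom[i]]
            if extras is not None:
                row += list(extras[i])
            fh.write(" ".join(row) + "\n")


def read_snapshot(path) -> SystemState:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise ParseError(path, 1, "truncated snapshot")
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise ParseError(path, 1, "first line must be the particle count") \
            from exc
    header = lines[1]
    fields = {}
    key = None
    # simple key=value / key="quoted value" scanner
    import re
    for m in re.finditer(r'(\w+)=("[^"]*"|\S+)', header):
        key, val = m.group(1), m.group(2).strip('"')
        fields[key] = val
    if "box" not in fields:
        raise ParseError(path, 2, "missing box specification in header")
    edges = np.array([float(v) for v in fields["box"].split()])
    pos = np.empty((n, 3))
    quat = np.empty((n, 4))
    vel = np.empty((n, 3))
    ang = np.empty((n, 3))
    species = np.empty(n, dtype=np.int8)
    extras = []
    for i in range(n):
        parts = lines[2 + i].split()
        if len(parts) < 14:
            raise ParseError(path, 3 + i, "expected >= 14 columns")
        if parts[0] not in _LABEL_SPECIES:
            raise ParseError(path, 3 + i, f"unknown species {parts[0]!r}")
        species[i] = _LABEL_SPECIES[parts[0]]
        vals = [float(v) for v in parts[1:14]]
        pos[i] = vals[0:3]
        quat[i] = vals[3:7]
        vel[i] = vals[7:10]
        ang[i] = vals[10:13]
        extras.append(parts[14:])
    state = SystemState(pos=pos, quat=quat, vel=vel, angmom=ang,
                        species_id=species, box=BoxSpec(edges),
                        time=float(fields.get("time", 0.0)),
                        dU=float(fields.get("dU", 0.0)))
    bonds = fields.get("bonds", "")
    if bonds:
        for pair in bonds.split(";"):
            a, b = pair.split(",")
            state.registry.add(int(a), int(b))
    if any(e for e in extras):
        state.xyz_extras = extras
    return state


def read_config(path) -> tuple[SimulationConfig, InteractionParams]:
    """Load a TOML run configuration ([run] and [interaction] tables)."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    run = doc.get("run", {})
    inter = doc.get("interaction", {})
    return SimulationConfig(**run), InteractionParams(**inter)


def write_params(path, obj) -> None:
    """Serialize a parameter dataclass (JSON dialect)."""
    d = asdict(obj)
    d = {k: v for k, v in d.items()
         if isinstance(v, (int, float, str, bool, type(None)))}
    d["_type"] = type(obj).__name__
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_params(path, cls=None):
    with open(path) as fh:
        d = json.load(fh)
    tname = d.pop("_type", None)
    if cls is None:
        from . import fitting, meanfield
        registry = {
            "MeanFieldRateParams": meanfield.MeanFieldRateParams,
            "KamalParams": meanfield.KamalParams,
            "EpoxyFitParams": fitting.EpoxyFitParams,
            "InteractionParams": InteractionParams,
        }
        if tname not in registry:
            raise ValueError(f"cannot infer parameter type {tname!r}")
        cls = registry[tname]
    return cls(**d)


@dataclass
class RunManifest:
    """Audit record of a multi-replica run: seeds, files, checksums."""

    config: dict
    seed: int
    files: dict = field(default_factory=dict)  # path -> sha256

    def add(self, path) -> None:
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.files[str(path)] = h

    def verify(self) -> bool:
        for path, digest in self.files.items():
            if not Path(path).exists():
                return False
            if hashlib.sha256(Path(path).read_bytes()).hexdigest() != digest:
                return False
        return True

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "seed": self.seed,
                       "files": self.files}, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(config=d["config"], seed=d["seed"], files=d["files"])
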