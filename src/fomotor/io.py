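"""Configuration files, trajectory/event readers and writers, manifests.

Configs are TOML or JSON with sections [geometry], [energetics],
[environment], [mutations], [transfer] and [run]; every model default can
be overridden and unknown keys are rejected.  Trajectories and event logs
are CSV with a ``#``-prefixed metadata header; writers and readers
round-trip exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import EVENT_COLUMNS, FRAME_COLUMNS, SimConfig, Trajectory
from .mc import TransferParams
from .model import (
    ConfigurationError, EnergeticsParams, EnvConditions, FoModel,
    RotorGeometry, apply_mutations, build_geometry,
)

_SECTION_FIELDS = {
    "geometry": {f.name for f in dataclasses.fields(RotorGeometry)},
    "energetics": {f.name for f in dataclasses.fields(EnergeticsParams)},
    "environment": {f.name for f in dataclasses.fields(EnvConditions)},
    "transfer": {f.name for f in dataclasses.fields(TransferParams)},
    "mutations": {"pattern", "relay_pKa_ims", "relay_pKa_matrix", "A_ASP",
                  "r0_ASP", "pKa_ASP", "A_GLU", "r0_GLU", "pKa_GLU",
                  "max_mutations"},
    "run": {f.name for f in dataclasses.fields(SimConfig)} | {"desk"},
}


class ConfigFileError(ConfigurationError):
    """Raised for unparsable or schema-violating configuration files."""


def _parse_config_text(text: str, suffix: str) -> dict:
    if suffix == ".json":
        return json.loads(text)
    try:
        return tomllib.loads(text)
    except tomllib.TOMLDecodeError:
        try:
            return json.loads(text)
        except json.JSONDecodeError:
            raise ConfigFileError("config is neither valid TOML nor JSON")


def load_config(path: str | Path) -> dict:
    """Load and validate a configuration file; fill all defaults.

    Returns a dict with keys ``model`` (FoModel), ``tparams``
    (TransferParams), ``sim`` (SimConfig) and ``raw`` (the echo of the
    file contents).
    """
    path = Path(path)
    raw = _parse_config_text(path.read_text(), path.suffix.lower())
    if not isinstance(raw, dict):
        raise ConfigFileError("top level of config must be a table")
    bad_sections = set(raw) - set(_SECTION_FIELDS)
    if bad_sections:
        raise ConfigFileError(f"unknown config section(s): "
                              f"{sorted(bad_sections)}")
    for sec, content in raw.items():
        if not isinstance(content, dict):
            raise ConfigFileError(f"section [{sec}] must be a table")
        bad = set(content) - _SECTION_FIELDS[sec]
        if bad:
            raise ConfigFileError(
                f"unknown key(s) in [{sec}]: {sorted(bad)}")
    mut = dict(raw.get("mutations", {}))
    pattern = mut.pop("pattern", "")
    relay_kw = {}
    if "relay_pKa_ims" in mut:
        relay_kw["relay_pKa_ims"] = mut.pop("relay_pKa_ims")
    if "relay_pKa_matrix" in mut:
        relay_kw["relay_pKa_matrix"] = mut.pop("relay_pKa_matrix")
    max_mut = mut.pop("max_mutations", 2)
    override_map = {"A": "decay_A", "r0": "r0", "pKa": "pKa"}
    asp_over = {override_map[k[:-4]]: v
                for k, v in mut.items() if k.endswith("_ASP")}
    glu_over = {override_map[k[:-4]]: v
                for k, v in mut.items() if k.endswith("_GLU")}
    try:
        geometry = build_geometry(raw.get("geometry"))
        model = FoModel(
            geometry=geometry,
            sites=tuple(apply_mutations(
                pattern, max_mutations=max_mut, asp_overrides=asp_over,
                glu_overrides=glu_over, **relay_kw)),
            env=EnvConditions(**raw.get("environment", {})),
            energetics=EnergeticsParams(**raw.get("energetics", {})),
        )
        tparams = TransferParams(**raw.get("transfer", {}))
        run = dict(raw.get("run", {}))
        desk = run.pop("desk", False)
        run.setdefault("mutant", pattern)
        sim = SimConfig.desk(**run) if desk else SimConfig(**run)
    except TypeError as exc:
        raise ConfigFileError(str(exc)) from exc
    return {"model": model, "tparams": tparams, "sim": sim, "raw": raw}


# ---------------------------------------------------------------------------
# trajectory / event CSV


class FormatError(ValueError):
    """Raised for malformed trajectory or event files."""


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# fomotor trajectory v1\n")
        fh.write(f"# config: {json.dumps(traj.config.to_dict())}\n")
        fh.write(f"# seed: {traj.seed_label}\n")
        traj.frames.to_csv(fh, index=False)


def read_trajectory(path: str | Path,
                    events_path: str | Path | None = None) -> Trajectory:
    path = Path(path)
    header = {}
    n_meta = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            if ":" in line:
                key, _, val = line[1:].partition(":")
                header[key.strip()] = val.strip()
    frames = pd.read_csv(path, skiprows=n_meta, dtype={"occupancy": str})
    missing = set(FRAME_COLUMNS) - set(frames.columns)
    if missing:
        raise FormatError(f"trajectory file lacks column(s) {sorted(missing)}")
    frames = frames[FRAME_COLUMNS]
    occ = frames["occupancy"].astype(str)
    bad = occ.str.len() != 12
    if bad.any():
        line_no = int(np.nonzero(bad.to_numpy())[0][0]) + n_meta + 2
        raise FormatError(
            f"occupancy string not length 12 at line {line_no}")
    frames = frames.assign(occupancy=occ)
    if not frames["md_step"].is_monotonic_increasing:
        raise FormatError("md_step must be strictly increasing")
    cfg = SimConfig(**json.loads(header["config"])) if "config" in header \
        else SimConfig(rounds=max(1, len(frames) // 10))
    events = read_events(events_path) if events_path else \
        pd.DataFrame(columns=EVENT_COLUMNS)
    return Trajectory(frames, events, cfg, header.get("seed", ""))


def write_events(traj_or_df, path: str | Path) -> None:
    df = traj_or_df.events if isinstance(traj_or_df, Trajectory) \
        else traj_or_df
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"event file lacks column(s) {sorted(missing)}")
    if len(df):
        df["subunit"] = df["subunit"].fillna("").astype(str)
        if (df["md_step"].diff().dropna() < 0).any():
            raise FormatError("event md_step must be non-decreasing")
    return df[EVENT_COLUMNS]


# ---------------------------------------------------------------------------
# run manifest


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, config: dict | None,
                   seeds: list, outputs: list[str | Path]) -> dict:
    """Write a JSON run manifest (config echo, seeds, version, checksums)."""
    manifest = {
        "package": "fomotor",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seeds": list(seeds),
        "config": config or {},
        "outputs": {str(p): file_checksum(p) for p in outputs},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
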