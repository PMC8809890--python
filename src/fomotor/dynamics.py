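"""Hybrid MC/Langevin driver producing trajectories and ensembles.

Each round consists of one MC sweep over all proton-transfer channels
followed by ``md_steps_per_round`` overdamped Langevin steps of the ring
angle; frames (cumulative angle + protonation snapshot + cumulative
reservoir counts) are sampled at fixed stride.  The default profile mirrors
the production protocol (6000 rounds x 1e5 MD steps, 10 frames per round =
60,000 frames); the desk profile is a scaled variant (1000 rounds x 1e4 MD
steps with rescaled dt) that completes several net turns in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel
from .mc import (
    OUTCOME_SUCCESS, RESERVOIR_IMS, RESERVOIR_MATRIX, TransferEvent,
    TransferParams, mc_sweep,
)
from .model import (
    ConfigurationError, FoModel, ProtonState, build_model, initial_state,
)

EVENT_COLUMNS = ["md_step", "channel_kind", "subunit", "outcome",
                 "delta_energy", "donor", "acceptor"]
FRAME_COLUMNS = ["frame", "md_step", "phi_deg_cum", "occupancy",
                 "n_ims_in", "n_matrix_out"]

#: default rotational diffusion coefficient (rad^2 per MD step, dt = 1)
DEFAULT_D_ROT = 6.0e-9
#: dt rescaling of the desk profile (same D_rot, 10x fewer/shorter rounds)
DESK_DT = 240.0


@dataclass(frozen=True)
class SimConfig:
    """Run-length, integrator and mutation settings of one simulation."""

    rounds: int = 6000
    md_steps_per_round: int = 100_000
    frames_per_round: int = 10
    dt: float = 1.0
    D_rot: float = DEFAULT_D_ROT
    seed: int = 0
    mutant: str = ""
    desk_profile: bool = False

    def __post_init__(self) -> None:
        if self.rounds <= 0 or self.md_steps_per_round <= 0:
            raise ConfigurationError("rounds and md_steps_per_round > 0")
        if self.md_steps_per_round % self.frames_per_round:
            raise ConfigurationError(
                "frames_per_round must divide md_steps_per_round")
        if self.D_rot <= 0 or self.dt <= 0:
            raise ConfigurationError("D_rot and dt must be positive")

    @classmethod
    def desk(cls, **overrides) -> "SimConfig":
        """Scaled desk profile: 1000 rounds x 1e4 steps, rescaled dt."""
        base = dict(rounds=1000, md_steps_per_round=10_000,
                    frames_per_round=10, dt=DESK_DT, desk_profile=True)
        base.update(overrides)
        return cls(**base)

    @property
    def total_md_steps(self) -> int:
        return self.rounds * self.md_steps_per_round

    @property
    def n_frames(self) -> int:
        return self.rounds * self.frames_per_round

    @property
    def steps_per_frame(self) -> int:
        return self.md_steps_per_round // self.frames_per_round

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "rounds", "md_steps_per_round", "frames_per_round", "dt",
            "D_rot", "seed", "mutant", "desk_profile")}


@dataclass
class Trajectory:
    """Frames, event log and metadata of one simulation run."""

    frames: pd.DataFrame
    events: pd.DataFrame
    config: SimConfig
    seed_label: str = ""

    @property
    def steps_per_frame(self) -> int:
        return self.config.steps_per_frame

    def final_angle(self) -> float:
        return float(self.frames["phi_deg_cum"].iloc[-1])


def langevin_step(phi: float, torque: float, dt: float, D_rot: float,
                  rng: np.random.Generator, kT: float = 1.0) -> float:
    """One overdamped Euler step of the ring angle (radians).

    phi' = phi + (D/kT) * torque * dt + sqrt(2*D*dt) * xi.
    """
    if D_rot <= 0:
        raise ConfigurationError("D_rot must be positive")
    return (phi + (D_rot / kT) * torque * dt
            + math.sqrt(2.0 * D_rot * dt) * rng.standard_normal())


def _kernel_args(model: FoModel, state: ProtonState):
    g, en = model.geometry, model.energetics
    q = model.site_charges(state)
    c_offsets = np.deg2rad(g.site_offsets)
    c_charges = q[:g.n_subunits].astype(np.float64)
    stator_angles = np.deg2rad(
        [g.angle_aE223, g.angle_aE162, g.angle_aR176])
    stator_charges = np.array([q[g.n_subunits], q[g.n_subunits + 1], 1.0])
    return (c_offsets, c_charges, stator_angles, stator_charges,
            g.c_radius, g.a_radius, en.coulomb_B, en.debye_length,
            en.distance_floor, en.eps_mem,
            math.radians(g.window_half_width),
            math.radians(en.edge_width_deg / 2.0),
            math.radians(g.angle_aR176),
            en.background_amplitude, float(en.background_periodicity))


def kernel_torque(phi_rad: float, state: ProtonState, model: FoModel) -> float:
    """Torque (kT/rad) from the compiled kernel (for cross-checks)."""
    return float(_kernel.rotor_torque(phi_rad, *_kernel_args(model, state)))


def run_round(phi_rad: float, state: ProtonState, model: FoModel,
              tparams: TransferParams, config: SimConfig,
              rng: np.random.Generator, md_step0: int = 0
              ) -> tuple[float, ProtonState, np.ndarray, list[TransferEvent]]:
    """One MC sweep followed by one MD leg; returns sampled frame angles."""
    state, events = mc_sweep(model, tparams, state,
                             math.degrees(phi_rad), rng, md_step=md_step0)
    noise = rng.standard_normal(config.md_steps_per_round)
    out_frames = np.empty(config.frames_per_round)
    drift = config.D_rot * config.dt / model.env.kT
    sigma = math.sqrt(2.0 * config.D_rot * config.dt)
    phi_rad = _kernel.langevin_rotor(
        phi_rad, noise, drift, sigma, *_kernel_args(model, state),
        config.steps_per_frame, out_frames)
    return phi_rad, state, out_frames, events


def run_trajectory(config: SimConfig, model: FoModel | None = None,
                   tparams: TransferParams | None = None,
                   rng: np.random.Generator | None = None,
                   state: ProtonState | None = None,
                   seed_label: str = "") -> Trajectory:
    """Full hybrid MC/MD run under ``config``.

    The initial occupancy protonates every c-site outside the a-facing
    cleft; phi starts at 0.  Identical config + seed gives a bit-identical
    trajectory.
    """
    if model is None:
        model = build_model(config.mutant or None)
    if tparams is None:
        tparams = TransferParams()
    if rng is None:
        rng = np.random.default_rng(config.seed)
        seed_label = seed_label or str(config.seed)
    if state is None:
        state = initial_state(model)
    phi = 0.0
    n_ims_in = n_matrix_out = 0
    frame_rows: list[tuple] = []
    all_events: list[TransferEvent] = []
    spf = config.steps_per_frame
    for r in range(config.rounds):
        md0 = r * config.md_steps_per_round
        phi, state, phis, events = run_round(
            phi, state, model, tparams, config, rng, md_step0=md0)
        for ev in events:
            if ev.outcome == OUTCOME_SUCCESS:
                if ev.donor == RESERVOIR_IMS:
                    n_ims_in += 1
                elif ev.acceptor == RESERVOIR_MATRIX:
                    n_matrix_out += 1
        all_events.extend(events)
        occ = state.to_string()
        base = r * config.frames_per_round
        for k in range(config.frames_per_round):
            frame_rows.append((base + k, md0 + (k + 1) * spf,
                               math.degrees(phis[k]), occ,
                               n_ims_in, n_matrix_out))
    frames = pd.DataFrame(frame_rows, columns=FRAME_COLUMNS)
    events_df = pd.DataFrame(
        [(e.md_step, e.channel_kind, e.subunit, e.outcome, e.delta_energy,
          e.donor, e.acceptor) for e in all_events], columns=EVENT_COLUMNS)
    return Trajectory(frames, events_df, config, seed_label)


def run_ensemble(config: SimConfig, n_replicates: int = 10,
                 model: FoModel | None = None,
                 tparams: TransferParams | None = None) -> list[Trajectory]:
    """n independent runs with replicate seeds derived from config.seed."""
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    if n_replicates == 1:
        return [run_trajectory(config, model=model, tparams=tparams)]
    children = np.random.SeedSequence(config.seed).spawn(n_replicates)
    out = []
    for k, ss in enumerate(children):
        out.append(run_trajectory(
            config, model=model, tparams=tparams,
            rng=np.random.default_rng(ss),
            seed_label=f"{config.seed}.{k}"))
    return out
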