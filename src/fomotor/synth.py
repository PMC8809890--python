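"""Synthetic inputs with known ground truth for every pipeline stage.

Replicate activity tables emulate the published per-mutant summaries
(Gaussian noise around a configured mean/SD with the published replicate
counts); luminescence traces emulate the luciferase assay record (baseline
drift, post-NADH synthesis slope, four stepwise ATP-calibration additions
at 20-s intervals); ACMA traces emulate the proton-pump assay (exponential
quench after ATP, recovery after FCCP).  A static fixture carries the
PROPKA-predicted pKa table of the ten c-ring carboxylates.  Scripted event
logs give the trajectory analyses exactly known inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biochem import TraceSeries
from .dynamics import EVENT_COLUMNS, FRAME_COLUMNS, SimConfig, Trajectory

#: published per-mutant ATP-synthesis activity summaries
#: (% of fusion-control activity): label -> (mean, sd, n)
PRINTED_ACTIVITY_SUMMARIES = {
    "e": (35.6, 8.8, 9),
    "ef": (22.3, 9.3, 10),
    "eg": (18.8, 8.8, 9),
    "eh": (13.0, 8.9, 10),
    "ei": (14.4, 6.7, 10),
    "ej": (12.0, 4.7, 8),
}

#: membrane ATPase activity (umol/min/mg) without / with 50 uM DCCD
PRINTED_ATPASE_DCCD = {
    "WT": (0.23, 0.076),
    "c10": (0.15, 0.067),
    "e": (0.087, 0.076),
    "ef": (0.090, 0.065),
    "eg": (0.078, 0.070),
    "eh": (0.086, 0.073),
    "ei": (0.088, 0.080),
    "ej": (0.083, 0.068),
}

_TABLE3_CHAINS = tuple("abcdefghij")
_TABLE3 = {
    "cE59": (7.40, 6.10, 5.89, 5.89, 5.89, 5.89, 5.89, 6.73, 8.03, 7.34),
    "cE59D": (6.49, 5.37, 5.16, 5.16, 5.16, 5.16, 5.16, 5.85, 7.08, 6.54),
}


def table3_fixture() -> pd.DataFrame:
    """PROPKA-predicted pKa of the c-ring carboxylates, Glu and Asp rows.

    Static fixture of published predictions (rows cE59/cE59D, chains a-j);
    not recomputed here.
    """
    return pd.DataFrame(_TABLE3, index=list(_TABLE3_CHAINS)).T


@dataclass(frozen=True)
class ActivityGeneratorSpec:
    """Ground truth for replicate activity tables.

    ``summaries`` maps mutant label to (true mean %, true SD %, n).
    """

    summaries: dict = field(
        default_factory=lambda: dict(PRINTED_ACTIVITY_SUMMARIES))
    seed: int = 0
    distribution: str = "gaussian"     # or "lognormal"

    def __post_init__(self) -> None:
        for lab, (mean, sd, n) in self.summaries.items():
            if sd < 0 or n < 2:
                raise ValueError(f"bad summary for {lab!r}: sd>=0, n>=2")
        if self.distribution not in ("gaussian", "lognormal"):
            raise ValueError("distribution must be gaussian or lognormal")


def gen_activity_replicates(spec: ActivityGeneratorSpec | None = None
                            ) -> pd.DataFrame:
    """Seeded replicate table with columns label, replicate, activity."""
    spec = spec or ActivityGeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for lab, (mean, sd, n) in spec.summaries.items():
        if spec.distribution == "gaussian" or sd == 0:
            vals = mean + sd * rng.standard_normal(n)
        else:
            var = sd ** 2
            mu = np.log(mean ** 2 / np.sqrt(var + mean ** 2))
            s = np.sqrt(np.log(1.0 + var / mean ** 2))
            vals = rng.lognormal(mu, s, n)
        rows.extend((lab, k, float(v)) for k, v in enumerate(vals))
    return pd.DataFrame(rows, columns=["label", "replicate", "activity"])


@dataclass(frozen=True)
class TraceGeneratorSpec:
    """Ground truth for a luciferase luminescence trace.

    The record runs from t=0: baseline of slope ``baseline_slope`` until
    the NADH addition, then slope ``baseline_slope + synthesis_slope``
    until the uncoupler (FCCP) stops synthesis ``post_span`` seconds later;
    the signal is then steady while four ATP-calibration steps of height
    ``step_height`` (per ``atp_amount``) are added at 20-s intervals.
    Gaussian noise of SD ``noise_sd`` throughout.
    """

    baseline_slope: float = 1.0        # units/s before NADH
    synthesis_slope: float = 5.0       # extra units/s after NADH
    nadh_time: float = 100.0           # s
    post_span: float = 60.0            # s of synthesis phase generated
    step_height: float = 200.0         # units per calibration addition
    atp_amount: float = 1.0            # amount per addition
    step_interval: float = 20.0        # s between additions
    noise_sd: float = 0.0
    sample_dt: float = 0.5             # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.sample_dt <= 0:
            raise ValueError("noise_sd >= 0 and sample_dt > 0 required")
        if self.nadh_time < 90.0:
            raise ValueError("need >= 90 s of baseline before NADH")


def gen_luminescence_trace(spec: TraceGeneratorSpec | None = None
                           ) -> TraceSeries:
    """Piecewise-linear luciferase trace with annotations NADH and ATP."""
    spec = spec or TraceGeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    t_fccp = spec.nadh_time + spec.post_span
    t_steps = t_fccp + spec.step_interval * np.arange(1, 5)
    t_end = t_steps[-1] + spec.step_interval
    t = np.arange(0.0, t_end + spec.sample_dt / 2, spec.sample_dt)
    # piecewise slopes: baseline / synthesis / steady calibration regime
    y = spec.baseline_slope * np.minimum(t, t_fccp)
    y += np.where(t > spec.nadh_time,
                  spec.synthesis_slope
                  * (np.minimum(t, t_fccp) - spec.nadh_time), 0.0)
    for ts in t_steps:
        y += np.where(t > ts, spec.step_height, 0.0)
    if spec.noise_sd > 0:
        y = y + spec.noise_sd * rng.standard_normal(len(t))
    return TraceSeries(t, y, {"NADH": spec.nadh_time, "FCCP": t_fccp,
                              "ATP": list(t_steps)})


@dataclass(frozen=True)
class AcmaGeneratorSpec:
    """Ground truth for an ACMA proton-pump fluorescence trace.

    ATP addition triggers an exponential quench to ``quench_depth`` (as a
    fraction of the FCCP plateau, reached with time constant ``tau_s``);
    FCCP addition recovers the signal to ``plateau``.
    """

    plateau: float = 100.0
    quench_depth: float = 0.4          # fraction of plateau quenched
    tau_s: float = 15.0
    atp_time: float = 60.0
    fccp_time: float = 360.0           # 5 min after ATP
    recovery_tau_s: float = 10.0
    total_time: float = 460.0
    noise_sd: float = 0.0
    sample_dt: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.quench_depth <= 1.0:
            raise ValueError("quench_depth must lie in [0, 1]")
        if not self.atp_time < self.fccp_time < self.total_time:
            raise ValueError("annotation times must be ordered")


def gen_acma_trace(spec: AcmaGeneratorSpec | None = None) -> TraceSeries:
    """ACMA trace with ATP-induced quench and FCCP recovery."""
    spec = spec or AcmaGeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.total_time + spec.sample_dt / 2, spec.sample_dt)
    y = np.full_like(t, spec.plateau)
    quench = spec.plateau * spec.quench_depth
    in_q = (t > spec.atp_time) & (t <= spec.fccp_time)
    y[in_q] -= quench * (1.0 - np.exp(-(t[in_q] - spec.atp_time) / spec.tau_s))
    after = t > spec.fccp_time
    level_at_fccp = spec.plateau - quench * (
        1.0 - np.exp(-(spec.fccp_time - spec.atp_time) / spec.tau_s))
    y[after] = spec.plateau + (level_at_fccp - spec.plateau) * np.exp(
        -(t[after] - spec.fccp_time) / spec.recovery_tau_s)
    if spec.noise_sd > 0:
        y = y + spec.noise_sd * rng.standard_normal(len(t))
    return TraceSeries(t, y, {"ATP": spec.atp_time, "FCCP": spec.fccp_time})


def gen_event_log(script: list[dict],
                  angle_waypoints: list[tuple[int, float]] | None = None,
                  steps_per_frame: int = 10,
                  total_steps: int | None = None) -> Trajectory:
    """Minimal trajectory encoding a scripted event list exactly.

    ``script`` rows carry md_step, channel_kind, subunit, outcome and
    optionally donor/acceptor/delta_energy; ``angle_waypoints`` is a list
    of (md_step, phi_deg) pairs interpolated linearly onto the frame grid.
    The script must be ordered by md_step.
    """
    steps = [int(ev["md_step"]) for ev in script]
    if any(b < a for a, b in zip(steps, steps[1:])):
        raise ValueError("script events must be ordered by md_step")
    rows = []
    for ev in script:
        kind = ev["channel_kind"]
        sub = ev.get("subunit", "")
        donor = ev.get("donor")
        acceptor = ev.get("acceptor")
        if donor is None or acceptor is None:
            # forward transport direction by default
            if kind == "release":
                donor, acceptor = sub, "aE162"
            elif kind == "uptake":
                donor, acceptor = "aE223", sub
            elif kind == "relay_ims":
                donor, acceptor = "IMS", "aE223"
            else:
                donor, acceptor = "aE162", "matrix"
        rows.append((int(ev["md_step"]), kind, sub, ev["outcome"],
                     float(ev.get("delta_energy", 0.0)), donor, acceptor))
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if total_steps is None:
        total_steps = max(steps, default=0)
        if angle_waypoints:
            total_steps = max(total_steps,
                              max(s for s, _ in angle_waypoints))
        total_steps = max(total_steps, steps_per_frame)
    n_frames = max(1, int(total_steps) // steps_per_frame)
    md = steps_per_frame * np.arange(1, n_frames + 1)
    if angle_waypoints:
        wp = sorted(angle_waypoints)
        phi = np.interp(md, [s for s, _ in wp], [a for _, a in wp])
    else:
        phi = np.zeros(n_frames)
    frames = pd.DataFrame({
        "frame": np.arange(n_frames), "md_step": md, "phi_deg_cum": phi,
        "occupancy": "1" * 12, "n_ims_in": 0, "n_matrix_out": 0,
    })[FRAME_COLUMNS]
    rounds = max(1, int(total_steps) // (steps_per_frame * 10))
    cfg = SimConfig(rounds=rounds, md_steps_per_round=steps_per_frame * 10,
                    frames_per_round=10)
    return Trajectory(frames, events, cfg, seed_label="scripted")
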