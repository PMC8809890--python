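"""Trajectory observables: velocity, proton flux, stage durations, sharing.

The rotational velocity follows the last-return convention: the cumulative
angle is divided by the time of the last visit to a nonzero multiple of
360 deg, so partial turns at the end of a run (which would bias asymmetric
mutants) are excluded.  Per-subunit transport cycles are decomposed into
stage 1 (proton release: first release trial -> release success), stage 2
(deprotonated rotation: release success -> first uptake trial) and stage 3
(proton uptake: first uptake trial -> uptake success), the remainder being
resting time.  Sharing of two subunits' uptake waits is quantified as the
overlapped stage-3 time normalized by the smaller stage-3 total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mc import (
    CHANNEL_RELEASE, CHANNEL_UPTAKE, OUTCOME_SUCCESS, OUTCOME_TRIAL,
)
from .model import C_LABELS, RESERVOIR_IMS, RESERVOIR_MATRIX
from .dynamics import Trajectory


# ---------------------------------------------------------------------------
# angle handling and velocity


def unwrap_cumulative_angle(angles_deg) -> np.ndarray:
    """Continuous cumulative angle from a possibly wrapped series.

    Identity for already-cumulative input; warns when successive gaps
    exceed 120 deg (undersampled for unambiguous unwrapping).
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        return a
    out = np.degrees(np.unwrap(np.radians(a)))
    gaps = np.abs(np.diff(out))
    if (gaps > 120.0).any():
        warnings.warn("angle gaps > 120 deg between frames; "
                      "series may be undersampled", stacklevel=2)
    return out


@dataclass(frozen=True)
class VelocityEstimate:
    """Last-return velocity of one trajectory."""

    cumulative_angle: float        # deg at the last 360-multiple return
    t_last_return: float           # MD steps
    defined: bool

    @property
    def deg_per_step(self) -> float:
        return self.cumulative_angle / self.t_last_return

    @property
    def deg_per_megastep(self) -> float:
        """Velocity in deg per 1e6 MD steps."""
        return 1e6 * self.deg_per_step

    @property
    def net_turns(self) -> float:
        return self.cumulative_angle / 360.0


def rotational_velocity(traj: Trajectory | pd.DataFrame) -> VelocityEstimate:
    """Cumulative angle over the time of the last full-turn return.

    Scans for the last time the cumulative angle equals a nonzero multiple
    of 360 deg (linearly interpolated between frames).  A trajectory that
    never completes a full turn yields an undefined estimate, not an error.
    """
    frames = traj.frames if isinstance(traj, Trajectory) else traj
    t = frames["md_step"].to_numpy(dtype=float)
    phi = unwrap_cumulative_angle(frames["phi_deg_cum"].to_numpy(dtype=float))
    m = phi / 360.0
    best_t, best_k = -np.inf, 0
    for i in range(len(m) - 1, 0, -1):
        m0, m1 = m[i - 1], m[i]
        lo, hi = (m0, m1) if m0 <= m1 else (m1, m0)
        ks = np.arange(np.ceil(lo), np.floor(hi) + 1, dtype=float)
        ks = ks[ks != 0.0]
        if ks.size == 0:
            continue
        # the multiple crossed last within this segment
        k = ks.max() if m1 >= m0 else ks.min()
        if m1 == m0:
            tc = t[i]
        else:
            tc = t[i - 1] + (k - m0) / (m1 - m0) * (t[i] - t[i - 1])
        best_t, best_k = tc, k
        break
    if not np.isfinite(best_t) or best_t <= 0:
        return VelocityEstimate(np.nan, np.nan, False)
    return VelocityEstimate(360.0 * best_k, best_t, True)


def drift_rate(traj: Trajectory | pd.DataFrame) -> float:
    """Plain net rotation rate (deg per MD step) over the whole run."""
    frames = traj.frames if isinstance(traj, Trajectory) else traj
    t = frames["md_step"].to_numpy(dtype=float)
    phi = frames["phi_deg_cum"].to_numpy(dtype=float)
    return float((phi[-1] - phi[0]) / (t[-1] - t[0]))


# ---------------------------------------------------------------------------
# proton bookkeeping


def net_proton_count(traj: Trajectory | pd.DataFrame,
                     up_to_step: float | None = None
                     ) -> tuple[int, int, int]:
    """(ims_in, matrix_out, net) successful reservoir transfers.

    ``ims_in`` counts protons entering at the IMS relay, ``matrix_out``
    protons delivered to the matrix; ``net`` is matrix_out minus matrix
    backflow.  ``up_to_step`` restricts counting to events at or before
    that MD step.
    """
    ev = traj.events if isinstance(traj, Trajectory) else traj
    if len(ev) == 0:
        return (0, 0, 0)
    ok = ev["outcome"] == OUTCOME_SUCCESS
    if up_to_step is not None:
        ok &= ev["md_step"] <= up_to_step
    ims_in = int((ok & (ev["donor"] == RESERVOIR_IMS)).sum())
    matrix_out = int((ok & (ev["acceptor"] == RESERVOIR_MATRIX)).sum())
    matrix_in = int((ok & (ev["donor"] == RESERVOIR_MATRIX)).sum())
    return (ims_in, matrix_out, matrix_out - matrix_in)


def protons_per_turn(traj: Trajectory) -> float:
    """Net matrix-delivered protons per net full turn (last-return)."""
    vel = rotational_velocity(traj)
    if not vel.defined or vel.net_turns == 0:
        return np.nan
    _, _, net = net_proton_count(traj, up_to_step=vel.t_last_return)
    return net / vel.net_turns


# ---------------------------------------------------------------------------
# stage-duration decomposition


@dataclass(frozen=True)
class TransportCycle:
    """One complete release/rotation/uptake cycle of a single subunit.

    Durations in frames; the absolute boundaries (MD steps) are kept for
    interval arithmetic.
    """

    t_release_trial: float
    t_release_success: float
    t_uptake_trial: float
    t_uptake_success: float
    steps_per_frame: float

    @property
    def release(self) -> float:          # stage 1
        return (self.t_release_success - self.t_release_trial) \
            / self.steps_per_frame

    @property
    def deprot_rotation(self) -> float:  # stage 2
        return (self.t_uptake_trial - self.t_release_success) \
            / self.steps_per_frame

    @property
    def uptake(self) -> float:           # stage 3
        return (self.t_uptake_success - self.t_uptake_trial) \
            / self.steps_per_frame


@dataclass
class StageDurations:
    """All completed cycles of one subunit plus the resting total."""

    subunit: str
    cycles: list = field(default_factory=list)
    resting: float = 0.0                 # frames
    dropped: int = 0                     # truncated cycles at run end

    def stage_totals(self) -> tuple[float, float, float]:
        return (sum(c.release for c in self.cycles),
                sum(c.deprot_rotation for c in self.cycles),
                sum(c.uptake for c in self.cycles))

    def stage_means(self) -> tuple[float, float, float]:
        n = len(self.cycles)
        if n == 0:
            return (np.nan, np.nan, np.nan)
        tot = self.stage_totals()
        return tuple(x / n for x in tot)

    def uptake_intervals(self) -> list[tuple[float, float]]:
        """Stage-3 intervals in MD steps, for overlap analysis."""
        return [(c.t_uptake_trial, c.t_uptake_success) for c in self.cycles]


_RESTING, _RELEASING, _DEPROT, _UPTAKING = range(4)


def stage_durations(traj: Trajectory | pd.DataFrame,
                    steps_per_frame: float | None = None,
                    total_steps: float | None = None
                    ) -> dict[str, StageDurations]:
    """Per-subunit stage decomposition from the trial/success event log.

    "Arrival at the uptake angle" is operationalized as the first uptake
    trial (the first MC attempt admissible under the arginine gate).
    Cycles truncated by the end of the run are dropped and counted.
    Backflow events (reverse hops) abort the cycle in progress.
    """
    if isinstance(traj, Trajectory):
        ev = traj.events
        spf = traj.steps_per_frame if steps_per_frame is None \
            else steps_per_frame
        total = traj.config.total_md_steps if total_steps is None \
            else total_steps
    else:
        ev = traj
        spf = 1.0 if steps_per_frame is None else steps_per_frame
        total = float(ev["md_step"].max()) if total_steps is None and len(ev) \
            else (total_steps or 0.0)
    result: dict[str, StageDurations] = {}
    for lab in C_LABELS:
        sd = StageDurations(lab)
        sub = ev[ev["subunit"] == lab] if len(ev) else ev
        phase = _RESTING
        t_rt = t_rs = t_ut = None
        rest_since = 0.0
        for row in sub.itertuples(index=False):
            t = float(row.md_step)
            fwd_release = (row.channel_kind == CHANNEL_RELEASE
                           and row.donor == lab)
            fwd_uptake = (row.channel_kind == CHANNEL_UPTAKE
                          and row.acceptor == lab)
            success = row.outcome == OUTCOME_SUCCESS
            if phase == _RESTING:
                if fwd_release and row.outcome == OUTCOME_TRIAL:
                    t_rt, phase = t, _RELEASING
                    sd.resting += (t - rest_since) / spf
            if phase == _RELEASING:
                if fwd_release and success:
                    t_rs, phase = t, _DEPROT
                elif success and not fwd_release:
                    phase = _RESTING          # e.g. backflow to aE223
                    rest_since = t
                continue
            if phase == _DEPROT:
                if fwd_uptake and row.outcome == OUTCOME_TRIAL:
                    t_ut, phase = t, _UPTAKING
                elif success and not fwd_uptake:
                    phase = _RESTING          # re-protonated by backflow
                    rest_since = t
                    continue
            if phase == _UPTAKING:
                if fwd_uptake and success:
                    sd.cycles.append(TransportCycle(t_rt, t_rs, t_ut, t, spf))
                    phase = _RESTING
                    rest_since = t
                elif success and not fwd_uptake:
                    phase = _RESTING
                    rest_since = t
        if phase == _RESTING:
            sd.resting += (total - rest_since) / spf
        else:
            sd.dropped += 1
        result[lab] = sd
    return result


def _merge_intervals(ivals):
    ivals = sorted((a, b) for a, b in ivals if b > a)
    merged = []
    for a, b in ivals:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def duration_overlap(dur_a: StageDurations | list,
                     dur_b: StageDurations | list) -> float:
    """Shared stage-3 time normalized by the smaller stage-3 total.

    Symmetric and scale-free: |A intersect B| / min(|A|, |B|); 0 when
    either subunit never waits for uptake.
    """
    ia = dur_a.uptake_intervals() if isinstance(dur_a, StageDurations) \
        else list(dur_a)
    ib = dur_b.uptake_intervals() if isinstance(dur_b, StageDurations) \
        else list(dur_b)
    ia, ib = _merge_intervals(ia), _merge_intervals(ib)
    tot_a = sum(b - a for a, b in ia)
    tot_b = sum(b - a for a, b in ib)
    if tot_a == 0.0 or tot_b == 0.0:
        return 0.0
    shared = 0.0
    j = 0
    for a0, a1 in ia:
        for b0, b1 in ib:
            lo, hi = max(a0, b0), min(a1, b1)
            if hi > lo:
                shared += hi - lo
    return shared / min(tot_a, tot_b)


# ---------------------------------------------------------------------------
# ensemble summaries


def mean_se(values) -> tuple[float, float]:
    """Mean and standard error of a 1-d sample."""
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    if v.size == 0:
        return (np.nan, np.nan)
    if v.size == 1:
        return (float(v[0]), np.nan)
    return (float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size)))


def ensemble_summary(trajectories: list[Trajectory],
                     overlap_pair: tuple[str, str] | None = None) -> dict:
    """Across-replicate mean +- SE of velocity, stage durations, overlap.

    Undefined velocities (no completed turn) are excluded, with the count
    reported.  Stage durations are per-subunit means of per-cycle
    durations, averaged across replicates.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories")
    vels = [rotational_velocity(t) for t in trajectories]
    vel_vals = [v.deg_per_megastep for v in vels if v.defined]
    v_mean, v_se = mean_se(vel_vals)
    out = {
        "n_replicates": len(trajectories),
        "velocity_mean": v_mean,
        "velocity_se": v_se,
        "velocity_undefined": sum(not v.defined for v in vels),
        "drift_mean": mean_se([drift_rate(t) for t in trajectories])[0],
    }
    per_sub: dict[str, list] = {lab: [] for lab in C_LABELS}
    overlaps = []
    for t in trajectories:
        durs = stage_durations(t)
        for lab in C_LABELS:
            per_sub[lab].append(durs[lab].stage_means())
        if overlap_pair is not None:
            overlaps.append(duration_overlap(durs[overlap_pair[0]],
                                             durs[overlap_pair[1]]))
    stage_stats = {}
    for lab in C_LABELS:
        arr = np.asarray(per_sub[lab], dtype=float)
        stage_stats[lab] = {
            "release": mean_se(arr[:, 0]),
            "deprot_rotation": mean_se(arr[:, 1]),
            "uptake": mean_se(arr[:, 2]),
        }
    out["stage_durations"] = stage_stats
    if overlap_pair is not None:
        om, ose = mean_se(overlaps)
        out["overlap_mean"], out["overlap_se"] = om, ose
        out["overlap_values"] = overlaps
    return out
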