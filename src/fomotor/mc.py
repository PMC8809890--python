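"""Monte-Carlo proton-transfer engine.

Protons hop between the c-ring carboxylates and the two stator relays, and
the relays exchange protons with the bulk reservoirs (aE223 with the IMS,
aE162 with the matrix).  Direct c-site/c-site hops have no channel.  Each
site-relay hop is attempted with probability

    w = f(r) * g(theta) * h(R176)

where f is the exponential distance factor of the carrier, g a Gaussian
sidechain-orientation factor and h the hard arginine gate that blocks leak
between the half-channels; attempted moves are accepted by the Metropolis
rule on the total-energy change.  w is evaluated identically for the forward
and reverse hop of a pair, so the chain satisfies detailed balance and the
only source of net flux is the proton motive force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import (
    C_LABELS, IDX_AE162, IDX_AE223, N_C_SITES, RESERVOIR_IMS,
    RESERVOIR_MATRIX, ConfigurationError, FoModel, ProtonState, SiteParams,
    total_energy, wrap_deg,
)

CHANNEL_RELEASE = "release"          # c-site <-> aE162 (matrix half-channel)
CHANNEL_UPTAKE = "uptake"            # c-site <-> aE223 (IMS half-channel)
CHANNEL_RELAY_IMS = "relay_ims"      # IMS <-> aE223
CHANNEL_RELAY_MATRIX = "relay_matrix"  # aE162 <-> matrix

OUTCOME_TRIAL = "trial"
OUTCOME_SUCCESS = "success"


@dataclass(frozen=True)
class TransferChannel:
    """A proton-exchange pathway (site pair or site-reservoir pair)."""

    kind: str
    c_index: int | None = None   # c-subunit involved, if any

    @property
    def subunit(self) -> str:
        return C_LABELS[self.c_index] if self.c_index is not None else ""


@dataclass(frozen=True)
class TransferEvent:
    """One logged trial or success of a proton move."""

    md_step: int
    channel_kind: str
    subunit: str
    outcome: str
    delta_energy: float
    donor: str
    acceptor: str


@dataclass(frozen=True)
class TransferParams:
    """Attempt-weight parameters.

    ``g_theta0_deg``/``g_sigma_deg`` are the mean and width of the Gaussian
    orientation factor; the cryo-EM-derived values of the antecedent model
    are unpublished, so the peak sits at perfect alignment with a 30 deg
    width.  ``reservoir_weight`` is the constant attempt probability of the
    relay-reservoir exchanges.  ``gate_width_deg`` > 0 softens the arginine
    gate into a logistic of that angular scale.
    """

    g_theta0_deg: float = 0.0
    g_sigma_deg: float = 30.0
    reservoir_weight: float = 1.0
    gate_width_deg: float = 0.0
    gate_margin_deg: float = 4.5

    def __post_init__(self) -> None:
        if self.g_sigma_deg <= 0:
            raise ConfigurationError("g_sigma_deg must be positive")
        if not 0.0 <= self.reservoir_weight <= 1.0:
            raise ConfigurationError("reservoir_weight must lie in [0, 1]")
        if not 0.0 <= self.gate_margin_deg < 10.0:
            raise ConfigurationError("gate_margin_deg must lie in [0, 10)")


def all_channels(n_subunits: int = N_C_SITES) -> list[TransferChannel]:
    """Every admissible pathway of the model."""
    chans = []
    for i in range(n_subunits):
        chans.append(TransferChannel(CHANNEL_RELEASE, i))
        chans.append(TransferChannel(CHANNEL_UPTAKE, i))
    chans.append(TransferChannel(CHANNEL_RELAY_IMS))
    chans.append(TransferChannel(CHANNEL_RELAY_MATRIX))
    return chans


def distance_factor(r: float, params: SiteParams) -> float:
    """min(1, exp(-A*(r - r0))): unit attempt weight at closest approach."""
    if r < 0:
        raise ValueError("distance must be non-negative")
    return min(1.0, math.exp(-params.decay_A * (r - params.r0)))


def orientation_factor(theta_deg: float, theta0_deg: float = 0.0,
                       sigma_deg: float = 30.0) -> float:
    """Gaussian sidechain-orientation factor exp(-(theta-theta0)^2/2sigma^2)."""
    if sigma_deg <= 0:
        raise ConfigurationError("sigma must be positive")
    return math.exp(-((theta_deg - theta0_deg) ** 2) / (2.0 * sigma_deg ** 2))


def arg_gate(site_angle_deg: float, channel_kind: str,
             model: FoModel, gate_width_deg: float = 0.0,
             gate_margin_deg: float = 0.0) -> float:
    """Arginine gate blocking proton leak between the half-channels.

    A c-site may exchange with aE162 only on the matrix side of aR176 and
    with aE223 only on the IMS side; relay-reservoir exchanges are ungated.
    ``gate_margin_deg`` additionally excludes a dead zone around the
    arginine itself (its positive charge displaces transferable protons
    from its immediate vicinity, the structural basis of leak blocking);
    ``gate_width_deg`` > 0 softens the boundary into a logistic.
    """
    if channel_kind in (CHANNEL_RELAY_IMS, CHANNEL_RELAY_MATRIX):
        return 1.0
    rel = float(wrap_deg(site_angle_deg - model.geometry.angle_aR176))
    # matrix relay sits at negative relative angles, IMS relay at positive
    side = -1.0 if channel_kind == CHANNEL_RELEASE else 1.0
    if gate_width_deg > 0.0:
        x = side * rel - gate_margin_deg
        x = max(-60.0, min(60.0, x / gate_width_deg))
        return 1.0 / (1.0 + math.exp(-x))
    return 1.0 if side * rel > gate_margin_deg else 0.0


def _orientation_angle(model: FoModel, site_index: int, phi_deg: float,
                       relay_index: int) -> float:
    """Angle (deg) between the site's outward radial direction and the
    site->relay direction."""
    g = model.geometry
    p = g.site_positions(phi_deg)[site_index]
    relay_pos = g.stator_positions()[0 if relay_index == IDX_AE223 else 1]
    v = relay_pos - p
    nv = np.linalg.norm(v)
    if nv == 0.0:
        return 0.0
    cosang = float(np.dot(p / np.linalg.norm(p), v / nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def transfer_weight(channel: TransferChannel, phi_deg: float,
                    model: FoModel, tparams: TransferParams) -> float:
    """Attempt probability of a channel at ring angle phi.

    Symmetric in the hop direction: distance and the c-site's sidechain
    orientation do not depend on which partner currently holds the proton.
    """
    if channel.kind in (CHANNEL_RELAY_IMS, CHANNEL_RELAY_MATRIX):
        return tparams.reservoir_weight
    g = model.geometry
    i = channel.c_index
    relay_idx = IDX_AE162 if channel.kind == CHANNEL_RELEASE else IDX_AE223
    relay_angle = (g.angle_aE162 if channel.kind == CHANNEL_RELEASE
                   else g.angle_aE223)
    site_angle = g.site_angles(phi_deg)[i]
    h = arg_gate(site_angle, channel.kind, model, tparams.gate_width_deg,
                 tparams.gate_margin_deg)
    if h == 0.0:
        return 0.0
    r = g.site_relay_distance(site_angle, relay_angle)
    f = distance_factor(r, model.sites[i])
    gth = orientation_factor(
        _orientation_angle(model, i, phi_deg, relay_idx),
        tparams.g_theta0_deg, tparams.g_sigma_deg)
    return f * gth * h


def metropolis_acceptance(delta_energy: float, kT: float = 1.0) -> float:
    """min(1, exp(-dV/kT))."""
    if not math.isfinite(delta_energy):
        raise ValueError("delta_energy must be finite")
    if delta_energy <= 0.0:
        return 1.0
    return math.exp(-delta_energy / kT)


def _resolve_move(channel: TransferChannel, state: ProtonState):
    """Donor/acceptor of a channel under the occupancy constraints, or None.

    Returns (donor_label, acceptor_label, from_index, to_index) where a
    reservoir endpoint has index None.
    """
    occ = state.occupancy
    if channel.kind == CHANNEL_RELEASE:
        i, r = channel.c_index, IDX_AE162
        if occ[i] == 1 and occ[r] == 0:
            return (C_LABELS[i], "aE162", i, r)
        if occ[i] == 0 and occ[r] == 1:
            return ("aE162", C_LABELS[i], r, i)
        return None
    if channel.kind == CHANNEL_UPTAKE:
        i, r = channel.c_index, IDX_AE223
        if occ[r] == 1 and occ[i] == 0:
            return ("aE223", C_LABELS[i], r, i)
        if occ[r] == 0 and occ[i] == 1:
            return (C_LABELS[i], "aE223", i, r)
        return None
    if channel.kind == CHANNEL_RELAY_IMS:
        if occ[IDX_AE223] == 0:
            return (RESERVOIR_IMS, "aE223", None, IDX_AE223)
        return ("aE223", RESERVOIR_IMS, IDX_AE223, None)
    if channel.kind == CHANNEL_RELAY_MATRIX:
        if occ[IDX_AE162] == 1:
            return ("aE162", RESERVOIR_MATRIX, IDX_AE162, None)
        return (RESERVOIR_MATRIX, "aE162", None, IDX_AE162)
    raise ValueError(f"unknown channel kind {channel.kind!r}")


def transfer_delta_energy(model: FoModel, state: ProtonState, phi_deg: float,
                          from_index: int | None, to_index: int | None,
                          reservoir: str | None = None) -> float:
    """Total free-energy change (kT) of moving one proton.

    For reservoir exchanges the bulk chemical potential of the proton is
    added/removed alongside the configurational energy change.
    """
    new = state.copy()
    if from_index is not None:
        new.occupancy[from_index] = 0
    if to_index is not None:
        new.occupancy[to_index] = 1
    dv = total_energy(new, phi_deg, model).total \
        - total_energy(state, phi_deg, model).total
    if reservoir is not None:
        mu = model.env.reservoir_chemical_potential(reservoir)
        if from_index is None:      # proton taken from the reservoir
            dv -= mu
        else:                       # proton delivered to the reservoir
            dv += mu
    return dv


def mc_sweep(model: FoModel, tparams: TransferParams, state: ProtonState,
             phi_deg: float, rng: np.random.Generator,
             md_step: int = 0) -> tuple[ProtonState, list[TransferEvent]]:
    """One MC phase: attempt every admissible channel once, random order.

    Returns the updated state and the list of trial/success events.  Proton
    number changes only through the reservoir channels.
    """
    channels = all_channels(model.geometry.n_subunits)
    order = rng.permutation(len(channels))
    state = state.copy()
    events: list[TransferEvent] = []
    for k in order:
        chan = channels[k]
        move = _resolve_move(chan, state)
        if move is None:
            continue
        w = transfer_weight(chan, phi_deg, model, tparams)
        if w <= 0.0 or rng.random() >= w:
            continue
        donor, acceptor, i_from, i_to = move
        reservoir = None
        if donor in (RESERVOIR_IMS, RESERVOIR_MATRIX):
            reservoir = donor
        elif acceptor in (RESERVOIR_IMS, RESERVOIR_MATRIX):
            reservoir = acceptor
        dv = transfer_delta_energy(model, state, phi_deg, i_from, i_to,
                                   reservoir)
        events.append(TransferEvent(md_step, chan.kind, chan.subunit,
                                    OUTCOME_TRIAL, dv, donor, acceptor))
        if rng.random() < metropolis_acceptance(dv, model.env.kT):
            if i_from is not None:
                state.occupancy[i_from] = 0
            if i_to is not None:
                state.occupancy[i_to] = 1
            events.append(TransferEvent(md_step, chan.kind, chan.subunit,
                                        OUTCOME_SUCCESS, dv, donor, acceptor))
    return state, events
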