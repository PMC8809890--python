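"""Reduced-coordinate model of the Fo proton motor.

The membrane-embedded Fo motor is modelled as a rigid c10-ring with a single
rotational degree of freedom ``phi`` turning against a fixed stator
(a-subunit).  Each c-subunit carries one protonatable carboxylate (Glu in the
wild type, Asp in E->D mutants) on a circle of radius ``c_radius``; the stator
carries the two proton-relaying carboxylates aE223 (IMS half-channel) and
aE162 (matrix half-channel) and the essential arginine aR176 on a circle of
radius ``a_radius``.  aR176 defines the x-axis; counterclockwise rotation
(increasing phi) is the ATP-synthesis direction.

The configurational energy is

    V_total = V_background + V_coulomb + V_mem + V_pka

with a Debye-Hueckel screened Coulomb term over all charged beads, a membrane
penalty ``eps_mem`` for every deprotonated c-site outside the a-facing window,
and a protonation term combining the intrinsic pKa of each site with the
electrostatic work of carrying a proton to the site's depth along the
membrane-potential profile.  Energies are in units of kT (T = 298 K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

KT_PER_MV = 1.0 / 25.693       # kT per mV at 298 K (kT/e = 25.693 mV)
MV_PER_KT = 25.693
LN10 = math.log(10.0)

#: fixed site order: c-subunits a..j, then aE223, then aE162
C_LABELS = tuple("abcdefghij")
SITE_LABELS = C_LABELS + ("aE223", "aE162")
N_C_SITES = 10
IDX_AE223 = 10
IDX_AE162 = 11
N_SITES = 12

RESERVOIR_IMS = "IMS"
RESERVOIR_MATRIX = "matrix"


class ConfigurationError(ValueError):
    """Raised for physically inadmissible model configuration."""


def wrap_deg(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle (deg) to (-180, 180]."""
    return -((-np.asarray(angle) + 180.0) % 360.0 - 180.0)


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class RotorGeometry:
    """Angular layout of the ring and stator.

    Angles in degrees, radii in nm.  With the defaults the aligned
    site-relay distance is ``a_radius - c_radius = 0.8 nm``, the closest
    approach of a carrier to a relay.
    """

    n_subunits: int = 10
    c_radius: float = 1.2
    a_radius: float = 2.0
    angle_aR176: float = 0.0
    angle_aE162: float = -36.0
    angle_aE223: float = 36.0
    window_half_width: float = 72.0
    synthesis_sign: int = +1

    def __post_init__(self) -> None:
        if self.n_subunits < 3:
            raise ConfigurationError("n_subunits must be >= 3")
        if self.c_radius <= 0 or self.a_radius <= 0:
            raise ConfigurationError("radii must be positive")
        if not (self.angle_aE162 < self.angle_aR176 < self.angle_aE223):
            raise ConfigurationError(
                "require angle_aE162 < angle_aR176 < angle_aE223")
        if self.window_half_width < max(abs(self.angle_aE162),
                                        abs(self.angle_aE223)):
            raise ConfigurationError("window must cover both relays")

    @property
    def site_offsets(self) -> np.ndarray:
        """Offsets (deg) of subunits a..j relative to the ring angle."""
        return 360.0 * np.arange(self.n_subunits) / self.n_subunits

    def site_angles(self, phi_deg: float) -> np.ndarray:
        """Absolute (unwrapped) angles of the c-sites at ring angle phi."""
        return phi_deg + self.site_offsets

    def site_positions(self, phi_deg: float) -> np.ndarray:
        """(n_subunits, 2) xy positions of the c-site carboxylates, nm."""
        a = np.deg2rad(self.site_angles(phi_deg))
        return self.c_radius * np.column_stack([np.cos(a), np.sin(a)])

    def stator_positions(self) -> np.ndarray:
        """(3, 2) xy positions of aE223, aE162, aR176, nm."""
        a = np.deg2rad([self.angle_aE223, self.angle_aE162, self.angle_aR176])
        return self.a_radius * np.column_stack([np.cos(a), np.sin(a)])

    def site_relay_distance(self, site_angle_deg: float,
                            relay_angle_deg: float) -> float:
        """Planar distance (nm) between a c-site and a stator bead."""
        d2 = (self.c_radius ** 2 + self.a_radius ** 2
              - 2.0 * self.c_radius * self.a_radius
              * math.cos(math.radians(site_angle_deg - relay_angle_deg)))
        return math.sqrt(max(d2, 0.0))


def build_geometry(config: dict | None = None) -> RotorGeometry:
    """Build a :class:`RotorGeometry` from a mapping of overrides."""
    return RotorGeometry(**(config or {}))


# ---------------------------------------------------------------------------
# per-site parameters and mutations

GLU = "GLU"
ASP = "ASP"

_DEFAULT_SITE_PARAMS = {
    GLU: dict(decay_A=2.5, r0=0.8, pKa=8.0),
    ASP: dict(decay_A=9.0, r0=0.6, pKa=7.0),
}


@dataclass(frozen=True)
class SiteParams:
    """Proton-transfer parameters of one protonatable carboxylate.

    ``decay_A`` (1/nm) and ``r0`` (nm) parameterize the distance factor of
    the hop attempt weight; ``pKa`` sets the protonation free energy.  The
    carboxylate is neutral when protonated and carries -1 e when
    deprotonated.
    """

    residue_kind: str
    decay_A: float
    r0: float
    pKa: float
    charge_protonated: float = 0.0
    charge_deprotonated: float = -1.0

    def __post_init__(self) -> None:
        if self.decay_A <= 0 or self.r0 <= 0:
            raise ConfigurationError("decay_A and r0 must be positive")


def make_site_params(residue_kind: str, **overrides: float) -> SiteParams:
    """Default Glu/Asp parameter bundle, with optional overrides.

    Overrides support the sensitivity variants (e.g. ``decay_A=2.5`` or
    ``pKa=7.8`` for Asp).
    """
    if residue_kind not in _DEFAULT_SITE_PARAMS:
        raise ConfigurationError(f"unknown residue kind: {residue_kind!r}")
    params = dict(_DEFAULT_SITE_PARAMS[residue_kind])
    unknown = set(overrides) - set(params)
    if unknown:
        raise ConfigurationError(f"unknown site parameter(s): {sorted(unknown)}")
    params.update(overrides)
    return SiteParams(residue_kind=residue_kind, **params)


@dataclass(frozen=True)
class MutationPattern:
    """Set of c-subunits carrying the E->D substitution.

    ``name`` is the compact label used throughout ("", "e", "ef", ... "ej").
    For double mutants ``separation`` is the minimal number of c-subunits
    between the two mutated chains along the ring (ef=1 ... ej=5).
    """

    mutated_labels: frozenset = frozenset()
    name: str = ""

    @classmethod
    def from_name(cls, name: str | None) -> "MutationPattern":
        name = (name or "").strip()
        if name.upper() in ("", "WT"):
            return cls(frozenset(), "")
        labels = frozenset(name)
        if not labels <= set(C_LABELS):
            raise ConfigurationError(f"unknown c-subunit label in {name!r}")
        return cls(labels, name)

    def __post_init__(self) -> None:
        if not self.mutated_labels <= set(C_LABELS):
            raise ConfigurationError("mutated labels must be c-subunits a..j")

    @property
    def separation(self) -> int:
        """Minimal ring distance between the two mutations (0 for <2)."""
        if len(self.mutated_labels) < 2:
            return 0
        idx = sorted(C_LABELS.index(l) for l in self.mutated_labels)
        gap = idx[1] - idx[0]
        return min(gap, N_C_SITES - gap)


#: default relay pKa values: the IMS relay (aE223) holds its proton
#: tightly, making the final handover to the ring carboxylate slightly
#: uphill and hence acceptance-limited; the matrix relay releases freely.
RELAY_PKA_IMS = 8.5
RELAY_PKA_MATRIX = 7.0


def apply_mutations(pattern: MutationPattern | str | None,
                    relay_pKa_ims: float = RELAY_PKA_IMS,
                    relay_pKa_matrix: float = RELAY_PKA_MATRIX,
                    max_mutations: int | None = 2,
                    asp_overrides: dict | None = None,
                    glu_overrides: dict | None = None) -> list[SiteParams]:
    """Per-site parameter map for the 12 protonatable sites.

    Mutated c-subunits get Asp parameters, the rest Glu.  The two stator
    relays are glutamates whose pKa values are not experimentally pinned;
    the defaults make proton uptake from the loaded IMS relay mildly
    endergonic (so uptake takes several Metropolis trials, more for the
    lower-pKa Asp) while the matrix relay never traps protons.
    """
    if not isinstance(pattern, MutationPattern):
        pattern = MutationPattern.from_name(pattern)
    if max_mutations is not None and len(pattern.mutated_labels) > max_mutations:
        raise ConfigurationError(
            f"pattern {pattern.name!r} has more than {max_mutations} mutations")
    glu = make_site_params(GLU, **(glu_overrides or {}))
    asp = make_site_params(ASP, **(asp_overrides or {}))
    sites = [asp if lab in pattern.mutated_labels else glu for lab in C_LABELS]
    return sites + [make_site_params(GLU, pKa=relay_pKa_ims),
                    make_site_params(GLU, pKa=relay_pKa_matrix)]


# ---------------------------------------------------------------------------
# protonation state


class ProtonState:
    """Occupancy flags of the 12 protonatable sites (houses the protons).

    Order: c-subunits a..j, then aE223, then aE162.  1 = protonated
    (neutral carboxylic acid), 0 = deprotonated (charged carboxylate).
    """

    __slots__ = ("occupancy",)

    def __init__(self, occupancy) -> None:
        occ = np.asarray(occupancy, dtype=np.int8)
        if occ.shape != (N_SITES,):
            raise ValueError(f"occupancy must have length {N_SITES}")
        if not np.isin(occ, (0, 1)).all():
            raise ValueError("occupancy flags must be 0 or 1")
        self.occupancy = occ

    @classmethod
    def from_string(cls, bits: str) -> "ProtonState":
        return cls([int(ch) for ch in bits])

    def to_string(self) -> str:
        return "".join(str(int(b)) for b in self.occupancy)

    def copy(self) -> "ProtonState":
        return ProtonState(self.occupancy.copy())

    @property
    def n_protons(self) -> int:
        return int(self.occupancy.sum())

    def __eq__(self, other) -> bool:
        return isinstance(other, ProtonState) and bool(
            np.array_equal(self.occupancy, other.occupancy))

    def __repr__(self) -> str:
        return f"ProtonState('{self.to_string()}')"


# ---------------------------------------------------------------------------
# environment


@dataclass(frozen=True)
class EnvConditions:
    """Bulk conditions driving the motor.

    ``delta_psi_mV`` is the membrane potential, IMS side positive.  The
    proton-carrying depth of each site along the potential profile is a
    fraction s in [0, 1] from the IMS (s=0) to the matrix (s=1): the c-ring
    carboxylates sit at ``psi_fraction_at_ring`` and the two relays part-way
    down their half-channels.
    """

    pH_IMS: float = 7.0
    pH_matrix: float = 8.0
    delta_psi_mV: float = 150.0
    kT: float = 1.0
    psi_fraction_at_ring: float = 0.5
    psi_fraction_ims_relay: float = 0.25
    psi_fraction_matrix_relay: float = 0.75

    def __post_init__(self) -> None:
        if self.pH_IMS <= 0 or self.pH_matrix <= 0:
            raise ConfigurationError("pH values must be positive")
        for f in (self.psi_fraction_at_ring, self.psi_fraction_ims_relay,
                  self.psi_fraction_matrix_relay):
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError("psi fractions must lie in [0, 1]")

    @property
    def psi_kT(self) -> float:
        """Full trans-membrane electrostatic energy of one proton, kT."""
        return self.delta_psi_mV * KT_PER_MV * self.kT

    def proton_potential(self, s: float) -> float:
        """Electrostatic energy (kT) of a proton at depth fraction s."""
        return (1.0 - s) * self.psi_kT

    def site_depth(self, site_index: int) -> float:
        if site_index == IDX_AE223:
            return self.psi_fraction_ims_relay
        if site_index == IDX_AE162:
            return self.psi_fraction_matrix_relay
        return self.psi_fraction_at_ring

    def reservoir_depth(self, reservoir: str) -> float:
        if reservoir == RESERVOIR_IMS:
            return 0.0
        if reservoir == RESERVOIR_MATRIX:
            return 1.0
        raise ValueError(f"unknown reservoir {reservoir!r}")

    def reservoir_pH(self, reservoir: str) -> float:
        return self.pH_IMS if reservoir == RESERVOIR_IMS else self.pH_matrix

    def reservoir_chemical_potential(self, reservoir: str) -> float:
        """Free energy (kT) of one proton in a bulk reservoir."""
        return (-LN10 * self.kT * self.reservoir_pH(reservoir)
                + self.proton_potential(self.reservoir_depth(reservoir)))


def protonation_free_energy(site: SiteParams, env: EnvConditions,
                            reservoir: str, site_depth: float | None = None
                            ) -> float:
    """Free energy (kT) of protonating ``site`` from ``reservoir``.

    ln(10)*kT*(pH_res - pKa) plus the electrostatic work of moving the
    proton from the reservoir to the site's depth along the potential
    profile.  Zero when pH equals pKa and the membrane potential vanishes.
    """
    s = env.psi_fraction_at_ring if site_depth is None else site_depth
    chem = LN10 * env.kT * (env.reservoir_pH(reservoir) - site.pKa)
    elec = env.proton_potential(s) - env.proton_potential(
        env.reservoir_depth(reservoir))
    return chem + elec


# ---------------------------------------------------------------------------
# energetics


@dataclass(frozen=True)
class EnergeticsParams:
    """Electrostatics, membrane-penalty, and background-term parameters.

    ``coulomb_B`` (kT*nm) is the Coulomb coupling strength, ``debye_length``
    (nm) the screening length, ``distance_floor`` (nm) a lower distance bound
    preventing singularities.  ``eps_mem`` (kT) penalizes each deprotonated
    c-site outside the a-facing window; the window edge is smoothed over
    ``edge_width_deg`` so the torque exists everywhere.  The optional smooth
    periodic background stands in for the non-electrostatic protein energy
    (identically zero by default).
    """

    coulomb_B: float = 2.0
    debye_length: float = 1.0
    distance_floor: float = 0.3
    eps_mem: float = 8.0
    edge_width_deg: float = 2.0
    background_amplitude: float = 0.0
    background_periodicity: int = 10

    def __post_init__(self) -> None:
        if self.eps_mem < 0:
            raise ConfigurationError("eps_mem must be >= 0")
        if self.debye_length <= 0 or self.distance_floor <= 0:
            raise ConfigurationError("lengths must be positive")
        if self.edge_width_deg <= 0:
            raise ConfigurationError("edge_width_deg must be positive")


@dataclass(frozen=True)
class EnergyBreakdown:
    v_coulomb: float
    v_mem: float
    v_pka: float
    v_background: float

    @property
    def total(self) -> float:
        return self.v_coulomb + self.v_mem + self.v_pka + self.v_background


@dataclass(frozen=True)
class FoModel:
    """Complete parameterization of the reduced Fo model."""

    geometry: RotorGeometry = field(default_factory=RotorGeometry)
    sites: tuple = field(
        default_factory=lambda: tuple(apply_mutations(None)))
    env: EnvConditions = field(default_factory=EnvConditions)
    energetics: EnergeticsParams = field(default_factory=EnergeticsParams)

    def __post_init__(self) -> None:
        if len(self.sites) != self.geometry.n_subunits + 2:
            raise ConfigurationError(
                "need one SiteParams per c-subunit plus the two relays")

    def site_charges(self, state: ProtonState) -> np.ndarray:
        """Charge (e) of each protonatable site under ``state``."""
        occ = state.occupancy
        return np.array([
            s.charge_protonated if occ[i] else s.charge_deprotonated
            for i, s in enumerate(self.sites)])


def build_model(mutant: MutationPattern | str | None = None,
                geometry: dict | None = None,
                env: dict | None = None,
                energetics: dict | None = None,
                relay_pKa_ims: float = RELAY_PKA_IMS,
                relay_pKa_matrix: float = RELAY_PKA_MATRIX,
                asp_overrides: dict | None = None,
                glu_overrides: dict | None = None) -> FoModel:
    """Convenience constructor from plain mappings of overrides."""
    return FoModel(
        geometry=build_geometry(geometry),
        sites=tuple(apply_mutations(mutant,
                                    relay_pKa_ims=relay_pKa_ims,
                                    relay_pKa_matrix=relay_pKa_matrix,
                                    asp_overrides=asp_overrides,
                                    glu_overrides=glu_overrides)),
        env=EnvConditions(**(env or {})),
        energetics=EnergeticsParams(**(energetics or {})),
    )


def _charged_bead_layout(model: FoModel, state: ProtonState, phi_deg: float):
    """Positions (nm) and charges (e) of all beads: 10 c-sites, aE223,
    aE162, aR176 (always +1)."""
    g = model.geometry
    pos_c = g.site_positions(phi_deg)
    pos_stator = g.stator_positions()           # aE223, aE162, aR176
    q = model.site_charges(state)
    charges = np.concatenate([q[:N_C_SITES], [q[IDX_AE223], q[IDX_AE162], 1.0]])
    positions = np.vstack([pos_c, pos_stator])
    return positions, charges


def coulomb_energy(state: ProtonState, phi_deg: float,
                   model: FoModel) -> float:
    """Screened pairwise Coulomb energy (kT) over all charged beads."""
    en = model.energetics
    positions, charges = _charged_bead_layout(model, state, phi_deg)
    idx = np.nonzero(charges)[0]
    if idx.size < 2:
        return 0.0
    p = positions[idx]
    q = charges[idx]
    diff = p[:, None, :] - p[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    iu = np.triu_indices(len(idx), k=1)
    d = np.maximum(d[iu], en.distance_floor)
    qq = (q[:, None] * q[None, :])[iu]
    return float(np.sum(qq * en.coulomb_B * np.exp(-d / en.debye_length) / d))


def _membrane_indicator(wrapped_deg: np.ndarray, half_width: float,
                        edge_width: float) -> np.ndarray:
    """Smooth 0/1 indicator of the membrane sector (outside the window)."""
    x = (np.abs(wrapped_deg) - half_width) / (edge_width / 2.0)
    x = np.clip(x, -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(-x))


def membrane_penalty(state: ProtonState, phi_deg: float, model: FoModel,
                     eps_mem: float | None = None) -> float:
    """Penalty (kT) for deprotonated c-sites in the membrane sector."""
    g, en = model.geometry, model.energetics
    eps = en.eps_mem if eps_mem is None else eps_mem
    deprot = state.occupancy[:N_C_SITES] == 0
    if not deprot.any():
        return 0.0
    ang = wrap_deg(g.site_angles(phi_deg) - g.angle_aR176)[deprot]
    return float(eps * _membrane_indicator(
        ang, g.window_half_width, en.edge_width_deg).sum())


def pka_energy(state: ProtonState, model: FoModel) -> float:
    """Protonation term: sum over occupied sites of -ln10*kT*pKa + U(s)."""
    env = model.env
    total = 0.0
    for i, s in enumerate(model.sites):
        if state.occupancy[i]:
            total += (-LN10 * env.kT * s.pKa
                      + env.proton_potential(env.site_depth(i)))
    return total


def background_energy(phi_deg: float, model: FoModel) -> float:
    en = model.energetics
    if en.background_amplitude == 0.0:
        return 0.0
    return en.background_amplitude * 0.5 * (
        1.0 - math.cos(math.radians(phi_deg) * en.background_periodicity))


def total_energy(state: ProtonState, phi_deg: float,
                 model: FoModel) -> EnergyBreakdown:
    """All energy components (kT) at ring angle phi under ``state``."""
    return EnergyBreakdown(
        v_coulomb=coulomb_energy(state, phi_deg, model),
        v_mem=membrane_penalty(state, phi_deg, model),
        v_pka=pka_energy(state, model),
        v_background=background_energy(phi_deg, model),
    )


def torque(phi_deg: float, state: ProtonState, model: FoModel) -> float:
    """Generalized force -dV_total/dphi on the ring angle, kT/rad.

    Analytic: only the c-site/stator Coulomb pairs, the membrane edges and
    the background term depend on phi (c-c and stator-stator distances are
    rigid).
    """
    g, en = model.geometry, model.energetics
    q = model.site_charges(state)
    qc = q[:N_C_SITES]
    stator_angles = np.array([g.angle_aE223, g.angle_aE162, g.angle_aR176])
    stator_q = np.array([q[IDX_AE223], q[IDX_AE162], 1.0])
    site_ang = g.site_angles(phi_deg)
    tau = 0.0
    rc, ra = g.c_radius, g.a_radius
    for i in range(g.n_subunits):
        qi = qc[i]
        if qi == 0.0:
            continue
        for j in range(3):
            qj = stator_q[j]
            if qj == 0.0:
                continue
            da = math.radians(site_ang[i] - stator_angles[j])
            d2 = rc * rc + ra * ra - 2.0 * rc * ra * math.cos(da)
            d = math.sqrt(d2)
            if d <= en.distance_floor:
                continue  # flat (floored) region: no force
            dV_dd = (-en.coulomb_B * qi * qj * math.exp(-d / en.debye_length)
                     * (1.0 / (en.debye_length * d) + 1.0 / d2))
            dd_da = rc * ra * math.sin(da) / d
            tau -= dV_dd * dd_da
        # membrane edge force (deprotonated sites only)
        aw = float(wrap_deg(site_ang[i] - g.angle_aR176))
        delta = en.edge_width_deg / 2.0
        x = (abs(aw) - g.window_half_width) / delta
        if -60.0 < x < 60.0:
            sgm = 1.0 / (1.0 + math.exp(-x))
            dV_da = en.eps_mem * sgm * (1.0 - sgm) / math.radians(delta)
            tau -= dV_da * (1.0 if aw > 0 else -1.0)
    if en.background_amplitude != 0.0:
        n = en.background_periodicity
        tau -= (en.background_amplitude * 0.5 * n
                * math.sin(math.radians(phi_deg) * n))
    return tau


def initial_state(model: FoModel) -> ProtonState:
    """Default initial occupancy at phi = 0.

    All c-sites protonated except those between the two relays (facing the
    hydrated a-subunit cleft); the IMS relay starts loaded, the matrix relay
    empty.
    """
    g = model.geometry
    ang = wrap_deg(g.site_angles(0.0) - g.angle_aR176)
    occ = np.ones(N_SITES, dtype=np.int8)
    inside = (ang > g.angle_aE162) & (ang < g.angle_aE223)
    occ[:N_C_SITES][inside] = 0
    occ[IDX_AE223] = 1
    occ[IDX_AE162] = 0
    return ProtonState(occ)
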