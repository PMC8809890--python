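"""Compiled inner loop of the overdamped Langevin integrator.

Within one MC/MD round the protonation state is frozen, so the torque is a
smooth function of the ring angle determined by a fixed set of bead charges;
this lets the 10^4-10^5 MD steps of a round run inside one numba kernel.
The torque expression here must match :func:`fomotor.model.torque` exactly
(a unit test enforces this).
"""

from __future__ import annotations

import math

from numba import njit

TWO_PI = 2.0 * math.pi


@njit(cache=True, fastmath=False)
def rotor_torque(phi, c_offsets, c_charges, stator_angles, stator_charges,
                 r_c, r_a, coulomb_B, debye_length, distance_floor,
                 eps_mem, window_half_width, edge_delta, arg_angle,
                 bg_amplitude, bg_periodicity):
    """Torque (kT/rad) at ring angle ``phi`` (rad); angles in rad."""
    tau = 0.0
    for i in range(c_offsets.shape[0]):
        qi = c_charges[i]
        if qi == 0.0:
            continue
        a = phi + c_offsets[i]
        for j in range(stator_angles.shape[0]):
            qj = stator_charges[j]
            if qj == 0.0:
                continue
            da = a - stator_angles[j]
            d2 = r_c * r_c + r_a * r_a - 2.0 * r_c * r_a * math.cos(da)
            d = math.sqrt(d2)
            if d <= distance_floor:
                continue
            dV_dd = (-coulomb_B * qi * qj * math.exp(-d / debye_length)
                     * (1.0 / (debye_length * d) + 1.0 / d2))
            dd_da = r_c * r_a * math.sin(da) / d
            tau -= dV_dd * dd_da
        # membrane edge force on deprotonated sites
        rel = a - arg_angle
        aw = rel - TWO_PI * math.floor(rel / TWO_PI + 0.5)
        x = (abs(aw) - window_half_width) / edge_delta
        if -60.0 < x < 60.0:
            s = 1.0 / (1.0 + math.exp(-x))
            dV_da = eps_mem * s * (1.0 - s) / edge_delta
            if aw > 0.0:
                tau -= dV_da
            else:
                tau += dV_da
    if bg_amplitude != 0.0:
        tau -= bg_amplitude * 0.5 * bg_periodicity * math.sin(
            phi * bg_periodicity)
    return tau


@njit(cache=True, fastmath=False)
def langevin_rotor(phi0, noise, drift_coeff, noise_coeff,
                   c_offsets, c_charges, stator_angles, stator_charges,
                   r_c, r_a, coulomb_B, debye_length, distance_floor,
                   eps_mem, window_half_width, edge_delta, arg_angle,
                   bg_amplitude, bg_periodicity,
                   frame_stride, out_frames):
    """Integrate ``noise.size`` overdamped Euler steps; returns final phi.

    phi' = phi + drift_coeff * torque(phi) + noise_coeff * xi with
    drift_coeff = D*dt/kT and noise_coeff = sqrt(2*D*dt).  Every
    ``frame_stride`` steps the cumulative (unwrapped) angle is written to
    ``out_frames``.
    """
    phi = phi0
    k = 0
    for t in range(noise.shape[0]):
        tau = rotor_torque(phi, c_offsets, c_charges, stator_angles,
                           stator_charges, r_c, r_a, coulomb_B, debye_length,
                           distance_floor, eps_mem, window_half_width,
                           edge_delta, arg_angle, bg_amplitude,
                           bg_periodicity)
        phi = phi + drift_coeff * tau + noise_coeff * noise[t]
        if (t + 1) % frame_stride == 0:
            out_frames[k] = phi
            k += 1
    return phi
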