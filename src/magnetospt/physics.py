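"""Physical constants, the needle force field and drift-diffusion kinematics.

Everything downstream works in a single unit system: lengths in micrometres,
times in seconds, forces in femtonewtons, temperatures in kelvin. The one
conversion that matters — turning a force acting on a membrane-bound particle
into a drift velocity — is Einstein's relation ``v = F * D / (k_B * T)``,
which is also the relation the force estimator inverts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Boltzmann constant, J / K (exact, SI 2019).
BOLTZMANN_J_PER_K = 1.380649e-23

#: femtonewtons per newton
FN_PER_N = 1e15

#: metres per micrometre
M_PER_UM = 1e-6


@dataclass(frozen=True)
class PhysicalParams:
    """Thermal context of an experiment.

    Parameters
    ----------
    temperature_K : float
        Absolute temperature. Defaults to 298 K (room temperature, where
        membrane experiments of this kind are carried out).
    """

    temperature_K: float = 298.0

    def __post_init__(self) -> None:
        if not self.temperature_K > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature_K}")

    @property
    def kB(self) -> float:
        """Boltzmann constant in J/K."""
        return BOLTZMANN_J_PER_K

    @property
    def thermal_energy_J(self) -> float:
        """k_B * T in joules (~4.11e-21 J at 298 K)."""
        return BOLTZMANN_J_PER_K * self.temperature_K


@dataclass(frozen=True)
class NeedleGeometry:
    """A magnetized needle tip and its attractive force field.

    The field magnitude follows a configurable power-law decay

        ``F(d) = F0 * (d0 / d) ** p``

    pointing from the particle toward the tip. The power law is a model
    choice: any monotone decay reproduces the qualitative behaviour of a
    sharp magnetized tip (strong pull nearby, noise-dominated far away), and
    ``p = 0`` gives a spatially constant force, convenient for calibration
    studies.

    Parameters
    ----------
    tip_um : tuple of float
        Tip position (x, y) in micrometres.
    F0_fN : float
        Force magnitude at the reference distance, femtonewtons.
    d0_um : float
        Reference distance, micrometres.
    p : float
        Decay exponent (0 = constant force, 1 = inverse distance, ...).
    """

    tip_um: tuple[float, float] = (0.0, 0.0)
    F0_fN: float = 13.4
    d0_um: float = 50.0
    p: float = 1.0

    def __post_init__(self) -> None:
        if self.F0_fN < 0:
            raise ValueError("F0_fN must be >= 0")
        if not self.d0_um > 0:
            raise ValueError("d0_um must be > 0")
        if self.p < 0:
            raise ValueError("decay exponent p must be >= 0")

    @property
    def tip(self) -> np.ndarray:
        return np.asarray(self.tip_um, dtype=float)


def force_field(needle: NeedleGeometry, pos_um: np.ndarray) -> np.ndarray:
    """Force vector(s) in fN exerted by the needle at position(s) ``pos_um``.

    Parameters
    ----------
    needle : NeedleGeometry
    pos_um : array-like, shape (2,) or (N, 2)
        Particle position(s) in micrometres.

    Returns
    -------
    ndarray with the same shape as ``pos_um``: force vectors in fN, pointing
    from each position toward the tip, magnitude ``F0 * (d0 / d) ** p``.

    Raises
    ------
    ZeroDivisionError
        If any position coincides with the tip (the field is singular there).
    """
    pos = np.asarray(pos_um, dtype=float)
    single = pos.ndim == 1
    pos2 = np.atleast_2d(pos)
    delta = needle.tip[None, :] - pos2
    d = np.hypot(delta[:, 0], delta[:, 1])
    if np.any(d == 0.0):
        raise ZeroDivisionError("force field is singular at the needle tip")
    mag = needle.F0_fN * (needle.d0_um / d) ** needle.p
    vec = delta * (mag / d)[:, None]
    return vec[0] if single else vec


def drift_velocity(force_fN: np.ndarray, D_um2_s: float, phys: PhysicalParams) -> np.ndarray:
    """Drift velocity (μm/s) of a particle with diffusivity D under a force.

    Einstein relation ``v = F D / (k_B T)``; with F in fN and D in μm²/s the
    result is in μm/s.
    """
    force = np.asarray(force_fN, dtype=float)
    # F[N] * D[m^2/s] / kT -> m/s, then m -> um
    return (force / FN_PER_N) * (D_um2_s * M_PER_UM**2) / phys.thermal_energy_J / M_PER_UM


def force_from_velocity(v_um_s: float, D_um2_s: float, phys: PhysicalParams) -> float:
    """Invert the Einstein relation: F (fN) from drift velocity and D.

    This is the core calibration formula ``F = k_B T v / D`` evaluated in
    μm-fN units.
    """
    if D_um2_s == 0:
        raise ZeroDivisionError("force undefined for zero diffusion coefficient")
    return phys.thermal_energy_J * (v_um_s * M_PER_UM) / (D_um2_s * M_PER_UM**2) * FN_PER_N
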