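"""Forces and time integration for the immersed elastic network.

The equation of motion of particle *i* is

    m d2r_i/dt2 = -grad U_i - gamma |v_i|^alpha v_hat_i

with the interaction potential

    U_i = (k/2) sum_j (r_ij - ell)^2 + eps [sigma / (r_is - (sigma_s - sigma)/2)]^xi

where the sum runs over bonded neighbors and the second term is the
hard-core repulsion from the rigid spherical indenter (xi = 400 keeps
the contact stiff and short-ranged).  The drag term models the
interaction of each particle with the surrounding fluid: alpha = 1 is
Stokes drag, alpha = 0 a velocity-independent frictional force, and
alpha < 1 the sublinear regime associated with deformable bodies.

This module provides plain-numpy force evaluations (the reference
implementation used by the tests) and a single-step velocity Verlet
update; long runs go through the fused numba kernels in
:mod:`viscnet._kernels` via :mod:`viscnet.indentation`.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .lattice import Network

__all__ = [
    "DragLaw",
    "Indenter",
    "StepperState",
    "spring_force",
    "spring_energy",
    "indenter_force",
    "indenter_energy",
    "drag_force",
    "verlet_step",
    "kinetic_energy",
    "suggest_dt",
]


@dataclasses.dataclass(frozen=True)
class DragLaw:
    """Generalized drag  F = -gamma |v|^alpha v_hat.

    ``v_eps`` regularizes the force evaluation: below this speed the law
    is linearized with matched magnitude at ``v_eps`` so the drag force
    stays finite for alpha < 1 (where |v|^(alpha-1) diverges as v -> 0).
    The time stepper does not need the regularization — it advances the
    drag by its exact closed-form solution — but force inspection and
    external integrators do.
    """

    gamma: float
    alpha: float
    v_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.v_eps <= 0:
            raise ValueError(f"v_eps must be > 0, got {self.v_eps}")


@dataclasses.dataclass
class Indenter:
    """Rigid spherical punch.

    ``diameter`` is sigma_s in units of sigma; ``epsilon`` the energy
    scale and ``xi`` the stiffness exponent of the hard-core potential;
    ``center`` the sphere center; ``speed`` the descent rate during the
    loading stage (sigma per time unit, positive number).
    """

    diameter: float
    epsilon: float = 1.0
    xi: float = 400.0
    center: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))
    speed: float = 0.0

    def __post_init__(self) -> None:
        if self.xi < 1:
            raise ValueError(f"xi must be >= 1, got {self.xi}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        self.center = np.asarray(self.center, dtype=float)

    def core_radius(self, sigma: float) -> float:
        return 0.5 * (self.diameter - sigma)


@dataclasses.dataclass
class StepperState:
    """Bundle advanced by :func:`verlet_step`."""

    time: float
    net: Network
    indenter: Indenter | None
    drag: DragLaw
    dt: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")


def _min_image(d: np.ndarray, box) -> np.ndarray:
    Lx, Ly = box[0], box[1]
    d = d.copy()
    d[..., 0] -= Lx * np.round(d[..., 0] / Lx)
    d[..., 1] -= Ly * np.round(d[..., 1] / Ly)
    return d


def spring_force(net: Network) -> np.ndarray:
    """Harmonic bond forces, (N, 3); minimum image across x/y."""
    i, j = net.bonds[:, 0], net.bonds[:, 1]
    d = _min_image(net.positions[i] - net.positions[j], net.box)
    r = np.linalg.norm(d, axis=1)
    if np.any(r == 0):
        raise FloatingPointError("coincident bonded particles (r_ij = 0)")
    fm = -net.k * (r - net.ell) / r
    fvec = fm[:, None] * d
    F = np.zeros_like(net.positions)
    np.add.at(F, i, fvec)
    np.add.at(F, j, -fvec)
    return F


def spring_energy(net: Network) -> float:
    i, j = net.bonds[:, 0], net.bonds[:, 1]
    d = _min_image(net.positions[i] - net.positions[j], net.box)
    r = np.linalg.norm(d, axis=1)
    return float(0.5 * net.k * np.sum((r - net.ell) ** 2))


def _indenter_terms(net: Network, ind: Indenter):
    d = _min_image(net.positions - ind.center[None, :], net.box)
    r = np.linalg.norm(d, axis=1)
    core = ind.core_radius(net.sigma)
    if np.any(r <= core):
        raise FloatingPointError(
            "particle center inside the indenter hard core (r_is <= (sigma_s - sigma)/2)"
        )
    return d, r, core


def indenter_force(net: Network, ind: Indenter) -> tuple[np.ndarray, np.ndarray]:
    """Hard-core repulsion from the indenter.

    Returns ``(F, reaction)``: per-particle forces (radial, repulsive)
    and the 3-vector reaction on the indenter (minus their sum).  The
    z-component of the reaction is the recorded contact force.
    """
    d, r, core = _indenter_terms(net, ind)
    x = r - core
    # F = xi * eps * sigma^xi / x^(xi+1), evaluated in log space to avoid
    # overflow; negligible beyond ~1.15 sigma outside the core.
    with np.errstate(over="ignore"):
        mag = ind.xi * ind.epsilon / net.sigma * np.exp(
            (ind.xi + 1.0) * np.log(net.sigma / x)
        )
    mag[net.sigma / x < 0.85] = 0.0
    F = mag[:, None] * d / r[:, None]
    return F, -F.sum(axis=0)


def indenter_energy(net: Network, ind: Indenter) -> float:
    d, r, core = _indenter_terms(net, ind)
    with np.errstate(over="ignore"):
        u = ind.epsilon * np.exp(ind.xi * np.log(net.sigma / (r - core)))
    u[net.sigma / (r - core) < 0.85] = 0.0
    return float(u.sum())


def drag_force(v: np.ndarray, law: DragLaw) -> np.ndarray:
    """Generalized drag force for velocity array ``v`` (… , 3).

    -gamma |v|^alpha v_hat for |v| >= v_eps; linearized with matched
    magnitude below v_eps; exactly zero at v = 0.
    """
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    vv = np.atleast_2d(v)
    s = np.linalg.norm(vv, axis=-1)
    mag = np.zeros_like(s)
    fast = s >= law.v_eps
    mag[fast] = law.gamma * s[fast] ** law.alpha
    slow = (~fast) & (s > 0)
    mag[slow] = law.gamma * law.v_eps ** (law.alpha - 1.0) * s[slow]
    with np.errstate(invalid="ignore", divide="ignore"):
        F = -np.where(s[:, None] > 0, mag[:, None] / s[:, None], 0.0) * vv
    return F[0] if single else F


def kinetic_energy(net: Network) -> float:
    return float(0.5 * net.mass * np.sum(net.velocities ** 2))


def total_force(net: Network, ind: Indenter | None) -> np.ndarray:
    F = spring_force(net)
    if ind is not None:
        Fi, _ = indenter_force(net, ind)
        F = F + Fi
    return F


def _drag_half_kick(vel: np.ndarray, F: np.ndarray, bottom: np.ndarray,
                    law: DragLaw, h: float, m: float) -> np.ndarray:
    """Half-kick with conservative force + explicit drag.

    The drag force is evaluated at the velocity entering the half-kick
    (the previous half-step velocity); below ``law.v_eps`` the law is
    linearized with matched magnitude so the force stays continuous.
    """
    v = vel + (h / m) * (F + drag_force(vel, law))
    v[bottom, 2] = 0.0
    return v


def verlet_step(state: StepperState) -> StepperState:
    """One velocity Verlet step with explicit-drag half-kicks.

    Bottom-layer particles keep z and v_z fixed but slide freely in the
    plane (drag still acts on that in-plane motion).  If the indenter
    has a nonzero ``speed`` its center moves down by ``speed * dt``
    during the step.
    """
    net = state.net.copy()
    ind = state.indenter
    drag = state.drag
    dt = state.dt
    m = net.mass
    bottom = net.bottom_mask
    F = total_force(net, ind)
    net.velocities = _drag_half_kick(net.velocities, F, bottom, drag, 0.5 * dt, m)
    net.positions += dt * net.velocities
    net.positions[:, 0] %= net.box[0]
    net.positions[:, 1] %= net.box[1]
    if ind is not None and ind.speed != 0.0:
        ind = dataclasses.replace(ind, center=ind.center - np.array([0.0, 0.0, ind.speed * dt]))
    F = total_force(net, ind)
    net.velocities = _drag_half_kick(net.velocities, F, bottom, drag, 0.5 * dt, m)
    if not np.all(np.isfinite(net.positions)):
        raise FloatingPointError(
            f"non-finite coordinates after step (dt={dt}, k={net.k}, "
            f"gamma={drag.gamma}, alpha={drag.alpha}); reduce dt"
        )
    return StepperState(time=state.time + dt, net=net, indenter=ind, drag=drag, dt=dt)


def integrate(net: Network, drag: DragLaw, dt: float, n_steps: int,
              indenter: Indenter | None = None) -> Network:
    """Advance the network ``n_steps`` with the fused numba kernel.

    The indenter (if any) is held fixed.  Returns an advanced copy;
    equivalent to repeated :func:`verlet_step` but orders of magnitude
    faster for long runs.
    """
    from . import _kernels

    net = net.copy()
    pos = np.ascontiguousarray(net.positions)
    vel = np.ascontiguousarray(net.velocities)
    F = np.zeros_like(pos)
    bonds = np.ascontiguousarray(net.bonds, dtype=np.int64)
    bottom = np.ascontiguousarray(net.bottom_mask, dtype=np.bool_)
    Lx, Ly, _ = net.box
    if indenter is not None:
        xc, yc, zc = indenter.center
        sig_s, eps, xi = indenter.diameter, indenter.epsilon, indenter.xi
    else:
        xc = yc = zc = 0.0
        sig_s = eps = xi = 0.0
    _, status = _kernels.compute_forces(pos, bonds, net.k, net.ell, Lx, Ly,
                                        zc, xc, yc, sig_s, eps, xi, net.sigma, F)
    out = np.zeros(2)
    ns, _, status = _kernels.run_segment(
        pos, vel, F, bonds, bottom, net.k, net.ell, Lx, Ly, net.mass,
        drag.gamma, drag.alpha, drag.v_eps, zc, 0.0, xc, yc, sig_s, eps, xi,
        net.sigma,
        dt, n_steps, max(n_steps, 1), out, out.copy())
    if status != _kernels.STATUS_OK:
        raise FloatingPointError(
            f"integration unstable (dt={dt}, k={net.k}, gamma={drag.gamma}, "
            f"alpha={drag.alpha})")
    net.positions = pos
    net.velocities = vel
    return net


def suggest_dt(k: float, mass: float = 1.0, factor: float = 0.05) -> float:
    """Default integration step, scaled to the stiffest spring period.

    ``factor / sqrt(k/m)`` keeps ``omega_max * dt`` well below the
    Verlet stability bound for the FCC bond topology and resolves the
    xi = 400 contact at the force levels reached in indentation runs.
    """
    return factor / np.sqrt(k / mass)
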