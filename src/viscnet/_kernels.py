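"""Numba kernels for the inner integration loop.

The time stepper is velocity Verlet with the generalized drag force
``-gamma |v|^alpha v_hat`` evaluated explicitly: each half-kick adds the
drag computed from the velocity entering that half-kick (the previous
half-step velocity), alongside the conservative spring + indenter
forces.  Below the regularization speed ``v_eps`` the law is linearized
with matched magnitude, keeping the force continuous at v = 0.

For alpha < 1 the slope of the drag law diverges as v -> 0, so at very
small speeds the explicit update alternates the velocity sign around a
bounded floor ~ (gamma dt / 2m)^(1/(1-alpha)).  This micro-chatter is
the standard behavior of explicitly integrated friction-like laws; it
sets the residual agitation scale of the nearly arrested network and
makes the time step an effective regularization parameter of the model
(see the methods note).  The recorded contact force is averaged over
each sampling window, which filters both elastic ringing and chatter
from the curve without biasing the slow relaxation.
"""

import numba as nb
import numpy as np

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_OVERLAP = 2


@nb.njit(cache=True, fastmath=True, inline="always")
def _drag_xyz(vx, vy, vz, gamma, alpha, v_eps):
    """Drag force components for one particle velocity."""
    s2 = vx * vx + vy * vy + vz * vz
    if s2 <= 0.0:
        return 0.0, 0.0, 0.0
    s = np.sqrt(s2)
    if s >= v_eps:
        mag = gamma * s ** alpha
    else:
        mag = gamma * v_eps ** (alpha - 1.0) * s
    f = -mag / s
    return f * vx, f * vy, f * vz


@nb.njit(cache=True, fastmath=True)
def compute_forces(pos, bonds, k, ell, Lx, Ly, zc, xc, yc,
                   sig_s, eps, xi, sigma, F):
    """Spring + indenter forces; returns (reaction_z, status).

    ``reaction_z`` is the z-component of the total reaction exerted by
    the particles on the indenter (positive = pushing the indenter up).
    """
    N = pos.shape[0]
    for i in range(N):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    hx = 0.5 * Lx
    hy = 0.5 * Ly
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx > hx:
            dx -= Lx
        elif dx < -hx:
            dx += Lx
        if dy > hy:
            dy -= Ly
        elif dy < -hy:
            dy += Ly
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r <= 0.0:
            return 0.0, STATUS_NONFINITE
        fm = -k * (r - ell) / r
        fx = fm * dx
        fy = fm * dy
        fz = fm * dz
        F[i, 0] += fx
        F[i, 1] += fy
        F[i, 2] += fz
        F[j, 0] -= fx
        F[j, 1] -= fy
        F[j, 2] -= fz
    reaction = 0.0
    if eps > 0.0 and sig_s > 0.0:
        core = 0.5 * (sig_s - sigma)
        # beyond ~1.15 sigma outside the core the xi=400 repulsion is
        # below 1e-10 and is treated as zero
        rcut = core + 1.15 * sigma
        zmin = zc - rcut
        for i in range(N):
            if pos[i, 2] < zmin:
                continue
            dx = pos[i, 0] - xc
            dy = pos[i, 1] - yc
            dz = pos[i, 2] - zc
            if dx > hx:
                dx -= Lx
            elif dx < -hx:
                dx += Lx
            if dy > hy:
                dy -= Ly
            elif dy < -hy:
                dy += Ly
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r >= rcut:
                continue
            if r <= core:
                return 0.0, STATUS_OVERLAP
            br = sigma / (r - core)
            fm = xi * eps * (br ** xi) / ((r - core) * r)
            F[i, 0] += fm * dx
            F[i, 1] += fm * dy
            F[i, 2] += fm * dz
            reaction -= fm * dz
    return reaction, STATUS_OK


@nb.njit(cache=True, fastmath=True)
def run_segment(pos, vel, F, bonds, bottom, k, ell, Lx, Ly, m,
                gamma, alpha, v_eps, zc0, vzc, xc, yc, sig_s, eps, xi, sigma,
                dt, n_steps, stride, out_f, out_z):
    """Advance ``n_steps``; record window-averaged contact force.

    ``F`` must hold the conservative forces for the entering
    configuration.  ``bottom`` marks particles whose z coordinate is
    frozen (v_z pinned to zero, x/y free — drag still acts on their
    in-plane motion).  Returns (n_samples, zc_end, status).
    """
    N = pos.shape[0]
    zc = zc0
    ns = 0
    hdt = 0.5 * dt
    im = 1.0 / m
    acc_f = 0.0
    n_acc = 0
    for step in range(n_steps):
        for i in range(N):
            gx, gy, gz = _drag_xyz(vel[i, 0], vel[i, 1], vel[i, 2],
                                   gamma, alpha, v_eps)
            vel[i, 0] += hdt * (F[i, 0] + gx) * im
            vel[i, 1] += hdt * (F[i, 1] + gy) * im
            if not bottom[i]:
                vel[i, 2] += hdt * (F[i, 2] + gz) * im
            else:
                vel[i, 2] = 0.0
            x = pos[i, 0] + dt * vel[i, 0]
            y = pos[i, 1] + dt * vel[i, 1]
            if x >= Lx:
                x -= Lx
            elif x < 0.0:
                x += Lx
            if y >= Ly:
                y -= Ly
            elif y < 0.0:
                y += Ly
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] += dt * vel[i, 2]
        zc += vzc * dt
        fz, status = compute_forces(pos, bonds, k, ell, Lx, Ly, zc, xc, yc,
                                    sig_s, eps, xi, sigma, F)
        if status != STATUS_OK:
            return ns, zc, status
        for i in range(N):
            gx, gy, gz = _drag_xyz(vel[i, 0], vel[i, 1], vel[i, 2],
                                   gamma, alpha, v_eps)
            vel[i, 0] += hdt * (F[i, 0] + gx) * im
            vel[i, 1] += hdt * (F[i, 1] + gy) * im
            if not bottom[i]:
                vel[i, 2] += hdt * (F[i, 2] + gz) * im
            else:
                vel[i, 2] = 0.0
        acc_f += fz
        n_acc += 1
        if (step + 1) % stride == 0:
            out_f[ns] = acc_f / n_acc
            out_z[ns] = zc
            ns += 1
            acc_f = 0.0
            n_acc = 0
        v2 = vel[0, 0] * vel[0, 0] + vel[0, 1] * vel[0, 1] + vel[0, 2] * vel[0, 2]
        if not np.isfinite(pos[0, 0] + pos[0, 2] + v2) or v2 > 1e24:
            return ns, zc, STATUS_NONFINITE
    return ns, zc, STATUS_OK
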