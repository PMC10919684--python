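"""Two-stage computational indentation assay.

A rigid spherical punch descends onto the network at constant rate
until a maximum depth ``delta_max`` is reached (*loading* stage, duration
``tau_l``), then is held fixed while the network relaxes (*dwell*
stage).  The recorded observable is the z-component of the reaction
force on the indenter ("the sum of all collisions on the indenter"),
sampled as a window average every ``sample_stride`` steps.

Depth convention: ``delta = 0`` at geometric contact, i.e. when the gap
between the indenter surface and the top-layer particle surfaces is
zero.  The short approach from the initial standoff is simulated but
not recorded.  Time is measured from first contact, so the dwell stage
covers ``t in (tau_l, tau_l + dwell_time]`` — the clock shared by both
relaxation models.
"""

from __future__ import annotations

import dataclasses
import io
import json
from pathlib import Path

import numpy as np

from . import _kernels
from .dynamics import DragLaw, Indenter, suggest_dt
from .lattice import Network

__all__ = ["IndentationProtocol", "ForceCurve", "run_assay", "normalize",
           "hertz_constant", "write_curve", "read_curve"]

#: Poisson coefficient of the normalization constant
NU_DEFAULT = 0.5

#: initial indenter standoff above geometric contact (units of sigma);
#: the xi = 400 repulsion is ~1e-17 at this gap
STANDOFF = 0.1


@dataclasses.dataclass
class IndentationProtocol:
    """Displacement-controlled ramp-and-hold protocol.

    Parameters
    ----------
    delta_max : maximum indentation depth (units of sigma).  Must stay
        below 10% of the network height to avoid finite-size effects.
    tau_l : loading duration; the descent rate is ``delta_max / tau_l``.
    dwell_time : duration of the hold stage.
    dt : integration step; ``None`` selects ``suggest_dt(k)`` of the
        network being indented.
    sample_stride : integration steps per recorded force sample.
    early_stop : stop the dwell stage once the force has changed by
        less than ``early_stop_rtol`` (relative) over the trailing 10%
        of recorded samples.  Deterministic: depends only on the curve.
    """

    delta_max: float = 0.8
    tau_l: float = 16.0
    dwell_time: float = 32.0
    dt: float | None = None
    sample_stride: int = 100
    early_stop: bool = False
    early_stop_rtol: float = 1e-3

    def __post_init__(self) -> None:
        if self.delta_max <= 0:
            raise ValueError(f"delta_max must be > 0, got {self.delta_max}")
        if self.tau_l <= 0:
            raise ValueError(f"tau_l must be > 0, got {self.tau_l}")
        if self.dwell_time < 0:
            raise ValueError(f"dwell_time must be >= 0, got {self.dwell_time}")
        if self.sample_stride < 1:
            raise ValueError(f"sample_stride must be >= 1, got {self.sample_stride}")

    @property
    def speed(self) -> float:
        return self.delta_max / self.tau_l


@dataclasses.dataclass
class ForceCurve:
    """Sampled (t, delta, F) record of one assay.

    ``f_raw`` is the contact force; ``f_norm`` is ``f_raw`` divided by
    the spherical-punch normalization ``4 sqrt(sigma_s) delta_max^(3/2)
    / (3 (1 - nu^2))`` with nu = 0.5, which maps the dwell force onto
    the scale of the relaxation modulus.
    """

    t: np.ndarray
    delta: np.ndarray
    f_raw: np.ndarray
    f_norm: np.ndarray
    tau_l: float
    meta: dict = dataclasses.field(default_factory=dict)

    @property
    def dwell_mask(self) -> np.ndarray:
        return self.t > self.tau_l

    def dwell(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.dwell_mask
        return self.t[m], self.f_norm[m]


def hertz_constant(sigma_s: float, delta_max: float, nu: float = NU_DEFAULT) -> float:
    """Spherical-punch normalization constant 4 sqrt(sigma_s) delta_max^1.5 / (3 (1 - nu^2))."""
    if sigma_s <= 0 or delta_max <= 0:
        raise ValueError("sigma_s and delta_max must be > 0")
    if not 0 <= nu < 1:
        raise ValueError(f"Poisson coefficient must satisfy 0 <= nu < 1, got {nu}")
    return 4.0 * np.sqrt(sigma_s) * delta_max ** 1.5 / (3.0 * (1.0 - nu ** 2))


def normalize(curve: ForceCurve, nu: float = NU_DEFAULT) -> ForceCurve:
    """Recompute ``f_norm`` from ``f_raw`` (idempotent)."""
    sigma_s = curve.meta["sigma_s"]
    delta_max = curve.meta["delta_max"]
    const = hertz_constant(sigma_s, delta_max, nu)
    meta = dict(curve.meta)
    meta["nu"] = nu
    return dataclasses.replace(curve, f_norm=curve.f_raw / const, meta=meta)


def run_assay(
    net: Network,
    ind: Indenter,
    drag: DragLaw,
    proto: IndentationProtocol,
) -> ForceCurve:
    """Run the loading + dwell assay and return the force curve.

    The indenter axis is placed over the box center; its center height
    follows ``z0 - (delta_max / tau_l) t`` for ``t <= tau_l`` and is
    constant afterwards.
    """
    if proto.delta_max > 0.1 * net.sigma * net.H:
        raise ValueError(
            f"delta_max={proto.delta_max} exceeds 10% of the network height "
            f"{net.sigma * net.H}"
        )
    net = net.copy()
    dt = proto.dt if proto.dt is not None else suggest_dt(net.k, net.mass)
    stride = int(proto.sample_stride)
    Lx, Ly, _ = net.box
    xc, yc = 0.5 * Lx, 0.5 * Ly
    z_top = float(net.positions[:, 2].max())
    contact_z = z_top + 0.5 * (net.sigma + ind.diameter)
    speed = proto.speed

    pos = np.ascontiguousarray(net.positions)
    vel = np.ascontiguousarray(net.velocities)
    F = np.zeros_like(pos)
    bonds = np.ascontiguousarray(net.bonds, dtype=np.int64)
    bottom = np.ascontiguousarray(net.bottom_mask, dtype=np.bool_)

    args = (bonds, bottom, net.k, net.ell, Lx, Ly, net.mass,
            drag.gamma, drag.alpha, drag.v_eps)
    ind_args = (ind.diameter, ind.epsilon, ind.xi, net.sigma)

    def _segment(zc0, vzc, n_steps, out_f, out_z):
        _, status = _kernels.compute_forces(
            pos, bonds, net.k, net.ell, Lx, Ly, zc0, xc, yc, *ind_args, F)
        if status != _kernels.STATUS_OK:
            _raise_status(status, net, drag, dt)
        ns, zc, status = _kernels.run_segment(
            pos, vel, F, *args, zc0, vzc, xc, yc, *ind_args,
            dt, n_steps, stride, out_f, out_z)
        if status != _kernels.STATUS_OK:
            _raise_status(status, net, drag, dt)
        return ns, zc

    # approach from standoff (not recorded)
    n_pre = int(np.ceil(STANDOFF * net.sigma / (speed * dt)))
    zc = contact_z + n_pre * speed * dt
    scratch_f = np.zeros(n_pre // stride + 2)
    scratch_z = np.zeros_like(scratch_f)
    _, zc = _segment(zc, -speed, n_pre, scratch_f, scratch_z)

    # loading: contact -> delta_max
    n_load = int(round(proto.tau_l / dt))
    n_load -= n_load % stride
    cap_f: list[np.ndarray] = []
    out_f = np.zeros(n_load // stride + 1)
    out_z = np.zeros_like(out_f)
    ns, zc = _segment(zc, -speed, n_load, out_f, out_z)
    cap_f.append(out_f[:ns])
    t_load = ns * stride * dt

    # dwell: chunked, optional early stop on force stagnation
    n_dwell = int(round(proto.dwell_time / dt))
    n_dwell -= n_dwell % stride
    chunk = max(stride, (n_dwell // 10) - (n_dwell // 10) % stride)
    done = 0
    dwell_f: list[np.ndarray] = []
    while done < n_dwell:
        n = min(chunk, n_dwell - done)
        out_f = np.zeros(n // stride + 1)
        out_z = np.zeros_like(out_f)
        ns, zc = _segment(zc, 0.0, n, out_f, out_z)
        dwell_f.append(out_f[:ns])
        done += n
        if proto.early_stop and done < n_dwell:
            f_all = np.concatenate(dwell_f)
            n_tail = max(2, len(f_all) // 10)
            tail = f_all[-n_tail:]
            scale = max(abs(f_all).max(), 1e-300)
            if (tail.max() - tail.min()) / scale < proto.early_stop_rtol:
                break

    f_raw = np.concatenate(cap_f + dwell_f)
    t = (np.arange(len(f_raw)) + 1) * stride * dt
    delta = np.minimum(speed * t, proto.delta_max)
    delta[t > t_load] = proto.delta_max

    net.positions = pos
    net.velocities = vel
    meta = {
        "k": net.k, "gamma": drag.gamma, "alpha": drag.alpha,
        "H": net.H, "sigma_s": ind.diameter, "epsilon": ind.epsilon,
        "xi": ind.xi, "nu": NU_DEFAULT, "tau_l": t_load,
        "delta_max": proto.delta_max, "dt": dt, "sample_stride": stride,
        "n_particles": net.n_particles,
    }
    curve = ForceCurve(
        t=t, delta=delta, f_raw=f_raw, f_norm=np.zeros_like(f_raw),
        tau_l=t_load, meta=meta,
    )
    return normalize(curve)


def _raise_status(status: int, net: Network, drag: DragLaw, dt: float):
    if status == _kernels.STATUS_OVERLAP:
        raise FloatingPointError(
            "particle center entered the indenter hard core; "
            f"dt={dt} too large for k={net.k}, gamma={drag.gamma}, alpha={drag.alpha}"
        )
    raise FloatingPointError(
        f"non-finite state during integration (dt={dt}, k={net.k}, "
        f"gamma={drag.gamma}, alpha={drag.alpha}); reduce dt"
    )


# ------------------------------------------------------------------ I/O

def write_curve(curve: ForceCurve, path: str | Path) -> None:
    """Delimited text: JSON metadata block in the header, then TSV columns."""
    buf = io.StringIO()
    buf.write("# meta: " + json.dumps({**curve.meta, "tau_l": curve.tau_l}) + "\n")
    buf.write("t\tdelta\tf_raw\tf_norm\n")
    for row in zip(curve.t, curve.delta, curve.f_raw, curve.f_norm):
        buf.write("\t".join(f"{v:.10g}" for v in row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_curve(path: str | Path) -> ForceCurve:
    """Read the :func:`write_curve` format.

    Also accepts plain two-column (time, force) text without metadata —
    e.g. an exported experimental curve — in which case ``tau_l`` must
    be present as a ``# tau_l:`` comment or supplied downstream via
    ``meta``.
    """
    meta: dict = {}
    rows = []
    header: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("meta:"):
                meta = json.loads(body[5:])
            elif body.startswith("tau_l:"):
                meta["tau_l"] = float(body[6:])
            continue
        parts = line.split()
        if header is None and any(not _is_float(p) for p in parts):
            header = parts
            continue
        rows.append([float(p) for p in parts])
    data = np.asarray(rows, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"no force samples found in {path}")
    tau_l = float(meta.get("tau_l", 0.0))
    if data.shape[1] >= 4:
        t, delta, f_raw, f_norm = data[:, 0], data[:, 1], data[:, 2], data[:, 3]
    else:
        t, f_raw = data[:, 0], data[:, 1]
        delta = np.full_like(t, meta.get("delta_max", np.nan))
        f_norm = f_raw.copy()
    return ForceCurve(t=t, delta=delta, f_raw=f_raw, f_norm=f_norm,
                      tau_l=tau_l, meta=meta)


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
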