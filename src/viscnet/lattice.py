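"""FCC particle networks for mesoscale viscoelasticity simulations.

The simulated material is a close-packed (FCC) arrangement of spherical
particles of diameter ``sigma`` connected to their twelve nearest
neighbors by harmonic springs.  The simulation box is
``(sigma*H*sin(pi/3))**2 x sigma*H`` where ``H`` counts lattice layers
in units of ``sigma``; the horizontal plane is periodic, the vertical
direction is open (bottom layer supported, top layer free).

All quantities are in reduced units: particle diameter ``sigma = 1``,
particle mass ``m = 1``, and the time unit is ``sqrt(m sigma^2 / k0)``
with the reference stiffness ``k0 = 1``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["Network", "build_fcc", "neighbor_check", "write_xyz"]

#: relative tolerance used when matching bonded-pair distances to ``ell``
BOND_TOL = 1e-6


@dataclasses.dataclass
class Network:
    """Particle network state and material parameters.

    Attributes
    ----------
    positions, velocities : (N, 3) float arrays, reduced units.
    bonds : (M, 2) int array of particle index pairs, each pair once,
        ``bonds[:, 0] < bonds[:, 1]``.
    layer_index : (N,) int array; 0 is the bottom (supported) layer.
    box : (Lx, Ly, Lz); x and y are periodic, z is open.
    sigma, mass, k, ell, H : material/geometry parameters.  ``k`` is the
        spring constant shared by every bond and ``ell`` the common rest
        length.
    """

    positions: np.ndarray
    velocities: np.ndarray
    bonds: np.ndarray
    layer_index: np.ndarray
    box: tuple[float, float, float]
    sigma: float
    mass: float
    k: float
    ell: float
    H: int

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def bottom_mask(self) -> np.ndarray:
        return self.layer_index == 0

    @property
    def n_layers(self) -> int:
        return int(self.layer_index.max()) + 1

    def copy(self) -> "Network":
        return Network(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            bonds=self.bonds.copy(),
            layer_index=self.layer_index.copy(),
            box=self.box,
            sigma=self.sigma,
            mass=self.mass,
            k=self.k,
            ell=self.ell,
            H=self.H,
        )

    # ---------------------------------------------------------------- I/O
    def to_dict(self) -> dict:
        return {
            "positions": self.positions.tolist(),
            "velocities": self.velocities.tolist(),
            "bonds": self.bonds.tolist(),
            "layer_index": self.layer_index.tolist(),
            "box": list(self.box),
            "sigma": self.sigma,
            "mass": self.mass,
            "k": self.k,
            "ell": self.ell,
            "H": self.H,
        }

    def save(self, path: str | Path) -> None:
        """Serialize to a single JSON container."""
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        d = json.loads(Path(path).read_text())
        return cls(
            positions=np.asarray(d["positions"], dtype=float),
            velocities=np.asarray(d["velocities"], dtype=float),
            bonds=np.asarray(d["bonds"], dtype=np.int64),
            layer_index=np.asarray(d["layer_index"], dtype=np.int64),
            box=tuple(d["box"]),
            sigma=d["sigma"],
            mass=d["mass"],
            k=d["k"],
            ell=d["ell"],
            H=d["H"],
        )


def _layer_points(H: int, ell: float, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Close-packed (111-oriented) layers clipped to the periodic box.

    Layers are stacked along z with ABC offsets so every interior
    particle sits at distance ``ell`` from 6 in-plane, 3 upper and 3
    lower neighbors.  A lattice site is kept when its (x, y) coordinates
    fall in ``[0, L)``; the half-open interval prevents a site from
    coinciding with its own periodic image.  The box is generally
    incommensurate with the lattice, so the exact particle count is
    specific to this clipping rule (counts shift by a fraction of a
    percent under a different rule).
    """
    L = sigma * H * np.sin(np.pi / 3.0)
    a = ell                        # in-plane nearest-neighbor spacing
    b = a * np.sqrt(3.0) / 2.0     # in-plane row spacing
    dz = a * np.sqrt(2.0 / 3.0)    # inter-layer spacing
    # ABC stacking: B sits over the centroids of A triangles, C over the
    # complementary centroids.
    offsets = [(0.0, 0.0), (a / 2.0, b / 3.0), (0.0, 2.0 * b / 3.0)]
    tol = 1e-9
    # nearest-integer number of close-packed layers filling the height
    # sigma*H (17 layers for H = 15, ell = 1.1; a single layer for H = 1)
    n_layers = max(1, int(round(sigma * H / dz)))
    pts: list[tuple[float, float, float]] = []
    layer: list[int] = []
    for iz in range(n_layers):
        ox, oy = offsets[iz % 3]
        z = iz * dz
        j_hi = int(np.ceil(L / b)) + 2
        for j in range(j_hi):
            y = oy + j * b
            if y < -tol or y >= L - tol:
                continue
            x0 = (ox + j * (a / 2.0)) % a
            n_x = int(np.floor((L - tol - x0) / a)) + 1
            for i in range(n_x):
                pts.append((x0 + i * a, y, z))
                layer.append(iz)
    return np.asarray(pts, dtype=float), np.asarray(layer, dtype=np.int64)


def _find_bonds(positions: np.ndarray, ell: float, box: tuple[float, float, float]) -> np.ndarray:
    """All particle pairs at distance ``ell`` (minimum image in x, y)."""
    Lx, Ly, Lz = box
    # cKDTree handles the horizontal periodicity; the z period is padded
    # far beyond any bond length so no pair is matched through the z wrap.
    pad = Lz + 10.0 * ell
    pts = positions.copy()
    pts[:, 0] %= Lx
    pts[:, 1] %= Ly
    tree = cKDTree(pts, boxsize=[Lx, Ly, pad])
    pairs = tree.query_pairs(r=ell * (1.0 + BOND_TOL), output_type="ndarray")
    if pairs.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    d = pts[pairs[:, 0]] - pts[pairs[:, 1]]
    d[:, 0] -= Lx * np.round(d[:, 0] / Lx)
    d[:, 1] -= Ly * np.round(d[:, 1] / Ly)
    r = np.sqrt((d * d).sum(axis=1))
    keep = np.abs(r - ell) <= ell * BOND_TOL
    bonds = np.sort(pairs[keep], axis=1).astype(np.int64)
    order = np.lexsort((bonds[:, 1], bonds[:, 0]))
    return bonds[order]


def build_fcc(
    H: int,
    ell: float = 1.1,
    sigma: float = 1.0,
    k: float = 1.0,
    mass: float = 1.0,
) -> Network:
    """Construct the FCC network filling the standard simulation box.

    Parameters
    ----------
    H : number of layers (in units of ``sigma``) defining the box height
        ``sigma * H``; as many close-packed layers as fit are stacked.
    ell : spring rest length = nearest-neighbor spacing, in ``sigma``.
    sigma : particle diameter (1 in reduced units).
    k : spring constant assigned to every bond.
    mass : particle mass.

    Returns
    -------
    Network with zero velocities, all bonded pairs at distance ``ell``.
    """
    if H < 1:
        raise ValueError(f"H must be >= 1, got {H}")
    if ell <= 0:
        raise ValueError(f"ell must be > 0, got {ell}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    positions, layer = _layer_points(int(H), float(ell), float(sigma))
    L = sigma * H * np.sin(np.pi / 3.0)
    box = (float(L), float(L), float(sigma * H))
    bonds = _find_bonds(positions, ell, box)
    return Network(
        positions=positions,
        velocities=np.zeros_like(positions),
        bonds=bonds,
        layer_index=layer,
        box=box,
        sigma=float(sigma),
        mass=float(mass),
        k=float(k),
        ell=float(ell),
        H=int(H),
    )


def neighbor_check(net: Network) -> dict:
    """Per-particle bond counts and a flag for under-coordinated interior sites.

    Interior particles (not in the top or bottom layer and farther than
    one bond length from the open lateral clipping seam) must have
    exactly 12 bonds in a defect-free FCC network.
    """
    counts = np.zeros(net.n_particles, dtype=np.int64)
    for col in (0, 1):
        np.add.at(counts, net.bonds[:, col], 1)
    top = net.layer_index == net.layer_index.max()
    bottom = net.layer_index == 0
    # The box is generally incommensurate with the lattice, so particles
    # within ~ell of the periodic seam can miss lateral neighbors; they
    # are surface-like and excluded from the interior criterion.
    Lx, Ly, _ = net.box
    x, y = net.positions[:, 0], net.positions[:, 1]
    near_seam = (
        (x < net.ell) | (x > Lx - net.ell) | (y < net.ell) | (y > Ly - net.ell)
    )
    interior = ~(top | bottom | near_seam)
    flagged = np.flatnonzero(interior & (counts != 12))
    return {"counts": counts, "interior": interior, "flagged": flagged}


def write_xyz(net: Network, path: str | Path, comment: str = "", append: bool = False) -> None:
    """Write one XYZ-format snapshot; the comment line carries the box."""
    Lx, Ly, Lz = net.box
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{net.n_particles}\n")
        fh.write(f"box {Lx:.9g} {Ly:.9g} {Lz:.9g} {comment}\n")
        for p in net.positions:
            fh.write(f"P {p[0]:.9f} {p[1]:.9f} {p[2]:.9f}\n")
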