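"""EEG forward model: dipole potentials in a three-shell spherical head.

The head is three concentric homogeneous conductors (brain, skull, scalp)
with an insulating exterior.  For a current dipole inside the innermost
shell the potential separates into spherical harmonics; per degree ``n``
the radial profile in each shell is ``A r^n + B r^-(n+1)``, and matching
potential and radial current at the two interfaces plus the zero-current
scalp boundary fixes the coefficients.  The per-degree surface response is
obtained by solving that small linear system numerically, which keeps the
implementation transparent and reduces exactly to the homogeneous-sphere
solution when all conductivities are equal (the closed form of which is
also provided, as an independent check).

Geometry convention: the outer scalp radius is normalized to 1 and
electrodes sit on it; lead-field columns are average-referenced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Montage
from .mesh import CorticalMesh

__all__ = [
    "SphereHeadModel",
    "LeadField",
    "build_sphere_leadfield",
    "dipole_potential_series",
    "homogeneous_dipole_potential",
]


@dataclass(frozen=True)
class SphereHeadModel:
    """Radii (brain, skull, scalp; outer normalized to 1) and
    conductivities (S/m) of the three shells, plus the series truncation."""

    radii: tuple[float, float, float] = (0.87, 0.92, 1.0)
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)
    n_terms: int = 80

    def __post_init__(self):
        r1, r2, r3 = self.radii
        if not (0 < r1 < r2 < r3):
            raise ValueError("radii must be increasing and positive")
        if any(c <= 0 for c in self.conductivities):
            raise ValueError("conductivities must be positive")
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")


@dataclass
class LeadField:
    """Electrode x vertex gain matrix (potential per unit dipole moment),
    average-referenced columns."""

    gain: np.ndarray  # (E, V)
    montage: Montage
    head: SphereHeadModel | None = None

    def __post_init__(self):
        g = np.asarray(self.gain, dtype=float)
        if not np.all(np.isfinite(g)):
            raise ValueError("non-finite lead-field entries")
        self.gain = g

    @property
    def n_electrodes(self) -> int:
        return self.gain.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.gain.shape[1]


def _shell_response(head: SphereHeadModel, n_max: int) -> np.ndarray:
    """Surface response k_n: potential at the scalp surface produced by the
    degree-n source multipole of unit strength (coefficient of r^-(n+1) in
    the innermost shell's particular solution).

    Unknowns per degree: A1 (brain homogeneous part), A2, B2 (skull),
    A3, B3 (scalp).  Equations: continuity of V and of sigma dV/dr at the
    brain/skull and skull/scalp interfaces, zero radial current at the
    scalp surface.
    """
    r1, r2, r3 = head.radii
    s1, s2, s3 = head.conductivities
    ks = np.empty(n_max + 1)
    ks[0] = 0.0
    for n in range(1, n_max + 1):
        # column order: A1, A2, B2, A3, B3
        m = np.zeros((5, 5))
        rhs = np.zeros(5)
        # interface r1: V continuous
        m[0] = [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0, 0]
        rhs[0] = -(r1 ** -(n + 1))
        # interface r1: sigma dV/dr continuous
        m[1] = [
            s1 * n * r1 ** (n - 1),
            -s2 * n * r1 ** (n - 1),
            s2 * (n + 1) * r1 ** -(n + 2),
            0,
            0,
        ]
        rhs[1] = s1 * (n + 1) * r1 ** -(n + 2)
        # interface r2: V continuous
        m[2] = [0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))]
        # interface r2: sigma dV/dr continuous
        m[3] = [
            0,
            s2 * n * r2 ** (n - 1),
            -s2 * (n + 1) * r2 ** -(n + 2),
            -s3 * n * r2 ** (n - 1),
            s3 * (n + 1) * r2 ** -(n + 2),
        ]
        # scalp surface r3: radial current vanishes
        m[4] = [0, 0, 0, n * r3 ** (n - 1), -(n + 1) * r3 ** -(n + 2)]
        sol = np.linalg.solve(m, rhs)
        a3, b3 = sol[3], sol[4]
        ks[n] = a3 * r3**n + b3 * r3 ** -(n + 1)
    return ks


def dipole_potential_series(
    head: SphereHeadModel,
    electrodes: np.ndarray,
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
) -> np.ndarray:
    """Potential at surface electrodes from dipoles inside the brain shell.

    ``electrodes`` (E, 3) on the outer sphere; ``dipole_pos`` and
    ``dipole_moment`` (V, 3).  Returns (E, V) potentials, not yet
    average-referenced.  The infinite-medium dipole expansion (degree-n
    source coefficient ``b^(n-1) [n m_r P_n + m_t . e_t P_n']``) is scaled
    per degree by the shell response.
    """
    r1 = head.radii[0]
    s1 = head.conductivities[0]
    e = np.asarray(electrodes, dtype=float)
    p = np.atleast_2d(np.asarray(dipole_pos, dtype=float))
    q = np.atleast_2d(np.asarray(dipole_moment, dtype=float))
    b = np.linalg.norm(p, axis=1)
    if np.any(b >= r1):
        raise ValueError("dipole outside the innermost shell")
    e_hat = e / np.linalg.norm(e, axis=1, keepdims=True)

    # handle dipoles at the exact centre: direction is arbitrary, b=0 kills
    # all but the n=1 term through b^(n-1) with 0^0 := 1
    b_safe = np.where(b > 0, b, 1.0)
    p_hat = np.where(b[:, None] > 0, p / b_safe[:, None], np.array([0.0, 0.0, 1.0]))

    cosg = e_hat @ p_hat.T  # (E, V)
    m_r = np.einsum("vi,vi->v", q, p_hat)  # radial moment
    m_t = q - m_r[:, None] * p_hat  # tangential moment vector
    # m_t . (e_hat - cosg p_hat) == (m_t . e_t) sin(gamma); absorbs the
    # sin factor of the associated Legendre term and is stable at sin -> 0
    tang = np.einsum("vi,evi->ev", m_t, e_hat[:, None, :] - cosg[..., None] * p_hat[None, :, :])

    ks = _shell_response(head, head.n_terms)
    # Legendre recurrences for P_n(cosg) and P_n'(cosg)
    x = np.clip(cosg, -1.0, 1.0)
    p_nm1 = np.ones_like(x)  # P_0
    p_n = x.copy()  # P_1
    dp_nm1 = np.zeros_like(x)  # P_0'
    dp_n = np.ones_like(x)  # P_1'
    bpow = np.ones_like(b)  # b^(n-1), n = 1
    v = np.zeros_like(x)
    for n in range(1, head.n_terms + 1):
        v += ks[n] * bpow[None, :] * (n * m_r[None, :] * p_n + tang * dp_n)
        # advance recurrences to degree n+1
        p_np1 = ((2 * n + 1) * x * p_n - n * p_nm1) / (n + 1)
        dp_np1 = dp_nm1 + (2 * n + 1) * p_n
        p_nm1, p_n = p_n, p_np1
        dp_nm1, dp_n = dp_n, dp_np1
        bpow = bpow * b
    return v / (4.0 * np.pi * s1)


def homogeneous_dipole_potential(
    sigma: float,
    radius: float,
    electrodes: np.ndarray,
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
) -> np.ndarray:
    """Closed-form surface potential for a dipole in a homogeneous
    conducting sphere with insulating exterior.

    Obtained by summing the Legendre series analytically (generating-
    function identities), giving for f = b/R, c = cos(gamma),
    g = sqrt(1 - 2 f c + f^2), h = 1 - f c + g:

    radial sum      S_r = 2 (c - f) / g^3 + (1/g - 1) / f
    tangential sum  S_t = 2 / g^3 + (g + 1) / (g h)

    and V = [m_r S_r + (m_t . e_t sin(gamma)) S_t] / (4 pi sigma R^2).
    """
    e = np.asarray(electrodes, dtype=float)
    p = np.atleast_2d(np.asarray(dipole_pos, dtype=float))
    q = np.atleast_2d(np.asarray(dipole_moment, dtype=float))
    b = np.linalg.norm(p, axis=1)
    if np.any(b >= radius):
        raise ValueError("dipole outside the sphere")
    e_hat = e / np.linalg.norm(e, axis=1, keepdims=True)
    b_safe = np.where(b > 0, b, 1.0)
    p_hat = np.where(b[:, None] > 0, p / b_safe[:, None], np.array([0.0, 0.0, 1.0]))
    c = np.clip(e_hat @ p_hat.T, -1.0, 1.0)  # (E, V)
    m_r = np.einsum("vi,vi->v", q, p_hat)
    m_t = q - m_r[:, None] * p_hat
    tang = np.einsum("vi,evi->ev", m_t, e_hat[:, None, :] - c[..., None] * p_hat[None, :, :])

    f = (b / radius)[None, :]
    g = np.sqrt(1.0 - 2.0 * f * c + f**2)
    h = 1.0 - f * c + g
    with np.errstate(divide="ignore", invalid="ignore"):
        s_r = 2.0 * (c - f) / g**3 + np.where(f > 0, (1.0 / g - 1.0) / np.where(f > 0, f, 1.0), c)
    s_t = 2.0 / g**3 + (g + 1.0) / (g * h)
    v = m_r[None, :] * s_r + tang * s_t
    return v / (4.0 * np.pi * sigma * radius**2)


def build_sphere_leadfield(
    head: SphereHeadModel,
    montage: Montage,
    mesh: CorticalMesh,
) -> LeadField:
    """Lead field of unit dipoles along the mesh normals, seen at the
    montage electrodes on the scalp sphere; columns are re-referenced to
    the common average."""
    r_outer = head.radii[2]
    if np.any(np.linalg.norm(mesh.vertices, axis=1) >= head.radii[0]):
        raise ValueError("mesh vertices must lie strictly inside the brain shell")
    electrodes = montage.positions * r_outer
    gain = dipole_potential_series(head, electrodes, mesh.vertices, mesh.normals)
    gain = gain - gain.mean(axis=0, keepdims=True)
    return LeadField(gain=gain, montage=montage, head=head)
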