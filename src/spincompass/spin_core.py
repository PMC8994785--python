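"""Spin algebra and Hamiltonian construction for radical-pair systems.

A radical pair consists of two radicals, each carrying one unpaired electron
(spin 1/2) coupled to a set of magnetic nuclei (protons, s = 1/2, or
nitrogens, s = 1) through 3x3 hyperfine tensors.  Each radical evolves under
its local Hamiltonian

    H_i = sum_j S_i . A_ij . I_ij + omega . S_i ,      omega = -gamma B,

i.e. anisotropic hyperfine couplings plus the electron Zeeman interaction.
Inter-radical couplings (exchange, dipolar) and nuclear Zeeman terms are
neglected, which renders the pair dynamics separable radical by radical.

Units
-----
Hyperfine tensors are given in MHz and interpreted as frequencies
(A/2pi); magnetic fields in microtesla; time in microseconds; rates in
inverse microseconds.  Internally all Hamiltonians are expressed as angular
frequencies in rad/us, with the single MHz -> rad/us conversion happening
in :func:`build_radical_hamiltonian`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GAMMA_E",
    "NucleusSpec",
    "RadicalSpec",
    "EulerOrientation",
    "RadicalPairSpec",
    "FieldDirection",
    "DensityOperator",
    "spin_matrices",
    "spin_vector_operators",
    "build_radical_hamiltonian",
    "rotation_matrix",
    "rotate_tensor",
    "singlet_projector",
    "pair_hamiltonian",
]

#: Free-electron gyromagnetic ratio in rad us^-1 uT^-1 (gamma/2pi =
#: 28.024951 GHz/T).  Negative sign: the electron magnetic moment is
#: antiparallel to its spin, so the Larmor frequency omega = -gamma*B > 0.
GAMMA_E = -2.0 * np.pi * 28.024951e-3

_SUPPORTED_SPINS = (0.5, 1.0)


class UnsupportedSpinError(ValueError):
    """Raised for nuclear spin quantum numbers other than 1/2 or 1."""


@dataclass(frozen=True)
class NucleusSpec:
    """One magnetic nucleus: spin quantum number and hyperfine tensor (MHz).

    The tensor is expressed in the radical's own molecular frame and is used
    as given (no symmetrization); only finiteness is validated.
    """

    label: str
    spin: float
    tensor: np.ndarray

    def __post_init__(self):
        if float(self.spin) not in _SUPPORTED_SPINS:
            raise UnsupportedSpinError(
                f"nucleus {self.label!r}: spin {self.spin} unsupported "
                f"(supported: 1/2, 1)"
            )
        t = np.asarray(self.tensor, dtype=float)
        if t.shape != (3, 3):
            raise ValueError(f"nucleus {self.label!r}: tensor must be 3x3")
        if not np.all(np.isfinite(t)):
            raise ValueError(f"nucleus {self.label!r}: non-finite tensor entries")
        object.__setattr__(self, "tensor", t)

    @property
    def multiplicity(self) -> int:
        return int(round(2 * self.spin + 1))


@dataclass(frozen=True)
class RadicalSpec:
    """A radical: one unpaired electron plus an ordered list of nuclei."""

    name: str
    nuclei: tuple[NucleusSpec, ...] = ()
    gamma: float = GAMMA_E  # electron gyromagnetic ratio, rad us^-1 uT^-1

    def __post_init__(self):
        object.__setattr__(self, "nuclei", tuple(self.nuclei))

    @property
    def z(self) -> int:
        """Nuclear Hilbert-space dimension Z = prod_j (2 s_j + 1)."""
        z = 1
        for n in self.nuclei:
            z *= n.multiplicity
        return z

    @property
    def dim(self) -> int:
        """Total radical dimension 2 Z (electron times nuclei)."""
        return 2 * self.z

    @property
    def dims_layout(self) -> tuple[int, ...]:
        """Site dimensions, electron first."""
        return (2,) + tuple(n.multiplicity for n in self.nuclei)

    def rotated(self, orientation: "EulerOrientation") -> "RadicalSpec":
        """Radical with all hyperfine tensors rotated, A -> R A R^T."""
        rot = rotation_matrix(orientation)
        nuclei = tuple(
            replace(n, tensor=rot @ n.tensor @ rot.T) for n in self.nuclei
        )
        return replace(self, nuclei=nuclei)


@dataclass(frozen=True)
class EulerOrientation:
    """Intrinsic ZYZ Euler angles in degrees (active rotation).

    alpha, gamma in [0, 360); beta in [0, 180].
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0


@dataclass(frozen=True)
class RadicalPairSpec:
    """Two radicals, a mutual orientation, field magnitude and rate constant.

    ``orientation`` is applied to ``radical_a`` (the flavin by convention);
    ``radical_b`` defines the reference frame.  Recombination proceeds with
    equal singlet and triplet rate constants k_S = k_T = k, under which the
    Haberkorn reaction operator reduces to uniform exponential decay.
    """

    radical_a: RadicalSpec
    radical_b: RadicalSpec
    orientation: EulerOrientation = EulerOrientation()
    b0: float = 50.0  # uT
    k: float = 1.0  # us^-1

    def __post_init__(self):
        if not self.k > 0:
            raise ValueError("rate constant k must be positive")
        if self.b0 < 0:
            raise ValueError("field magnitude b0 must be non-negative")

    @property
    def dim(self) -> int:
        return self.radical_a.dim * self.radical_b.dim

    def oriented_radical_a(self) -> RadicalSpec:
        return self.radical_a.rotated(self.orientation)

    def with_orientation(self, orientation: EulerOrientation) -> "RadicalPairSpec":
        return replace(self, orientation=orientation)


@dataclass(frozen=True)
class FieldDirection:
    """Unit direction of the applied field, spherical angles in radians."""

    theta: float
    phi: float

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "FieldDirection":
        v = np.asarray(v, dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("zero vector has no direction")
        v = v / n
        return cls(theta=float(np.arccos(np.clip(v[2], -1, 1))),
                   phi=float(np.arctan2(v[1], v[0])))

    @property
    def unit(self) -> np.ndarray:
        st = np.sin(self.theta)
        return np.array(
            [st * np.cos(self.phi), st * np.sin(self.phi), np.cos(self.theta)]
        )


@dataclass
class DensityOperator:
    """A (possibly trace-decaying) density matrix with a time stamp in us."""

    matrix: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=complex)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("density operator must be square")
        self.matrix = m

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    @property
    def trace(self) -> float:
        return float(np.trace(self.matrix).real)

    def validate(self, tol: float = 1e-10) -> None:
        m = self.matrix
        if not np.allclose(m, m.conj().T, atol=tol):
            raise ValueError("density operator not Hermitian")
        ev = np.linalg.eigvalsh(m)
        if ev.min() < -tol:
            raise ValueError(f"density operator not PSD (min eig {ev.min():.2e})")
        tr = self.trace
        if not (0 < tr <= 1 + tol):
            raise ValueError(f"trace {tr} outside (0, 1]")


# ---------------------------------------------------------------------------
# spin matrices and operator embedding


def spin_matrices(s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Angular-momentum matrices (Sx, Sy, Sz) for spin quantum number s.

    Basis ordered by decreasing magnetic quantum number m = s, ..., -s.
    """
    if float(s) not in _SUPPORTED_SPINS:
        raise UnsupportedSpinError(f"spin {s} unsupported (supported: 1/2, 1)")
    d = int(round(2 * s + 1))
    m = s - np.arange(d)
    sz = np.diag(m).astype(complex)
    # ladder operator S+ |s,m> = sqrt(s(s+1) - m(m+1)) |s,m+1>
    sp = np.zeros((d, d), dtype=complex)
    for i in range(1, d):
        sp[i - 1, i] = np.sqrt(s * (s + 1) - m[i] * (m[i] + 1))
    sx = (sp + sp.conj().T) / 2
    sy = (sp - sp.conj().T) / (2j)
    return sx, sy, sz


def _embed(op: np.ndarray, site: int, dims: Sequence[int]) -> np.ndarray:
    """Embed a single-site operator into the tensor-product space."""
    out = np.array([[1.0 + 0j]])
    for i, d in enumerate(dims):
        factor = op if i == site else np.eye(d, dtype=complex)
        out = np.kron(out, factor)
    return out


def spin_vector_operators(
    s: float, site_index: int, dims_layout: Sequence[int]
) -> np.ndarray:
    """(Sx, Sy, Sz) for one site, embedded in the full product space.

    Returns an array of shape (3, D, D) with D = prod(dims_layout).
    """
    dims = tuple(dims_layout)
    if not 0 <= site_index < len(dims):
        raise ValueError(f"site_index {site_index} out of range for {dims}")
    expected = int(round(2 * s + 1))
    if dims[site_index] != expected:
        raise ValueError(
            f"site {site_index} has dimension {dims[site_index]}, "
            f"expected {expected} for spin {s}"
        )
    return np.stack(
        [_embed(op, site_index, dims) for op in spin_matrices(s)]
    )


def electron_spin_ops(radical: RadicalSpec) -> np.ndarray:
    """Electron (Sx, Sy, Sz) on the full radical space, shape (3, 2Z, 2Z)."""
    return spin_vector_operators(0.5, 0, radical.dims_layout)


def build_radical_hamiltonian(
    radical: RadicalSpec, field_uT: Sequence[float]
) -> np.ndarray:
    """Local radical Hamiltonian in rad/us on the 2Z-dimensional space.

    H = sum_j S.A_j.I_j + omega.S with omega = -gamma B.  Hyperfine tensors
    (MHz, i.e. frequency units) are converted to angular frequency here.
    """
    field = np.asarray(field_uT, dtype=float)
    if field.shape != (3,) or not np.all(np.isfinite(field)):
        raise ValueError("field must be a finite 3-vector in uT")
    dims = radical.dims_layout
    dim = radical.dim
    s_el = electron_spin_ops(radical)  # (3, dim, dim)

    h = np.zeros((dim, dim), dtype=complex)
    for j, nuc in enumerate(radical.nuclei):
        i_ops = spin_vector_operators(nuc.spin, j + 1, dims)
        a_ang = 2.0 * np.pi * nuc.tensor  # MHz -> rad/us
        for a in range(3):
            for b in range(3):
                if a_ang[a, b] != 0.0:
                    h += a_ang[a, b] * (s_el[a] @ i_ops[b])
    omega = -radical.gamma * field  # rad/us
    for a in range(3):
        if omega[a] != 0.0:
            h += omega[a] * s_el[a]
    return h


# ---------------------------------------------------------------------------
# rotations


def rotation_matrix(orientation: EulerOrientation) -> np.ndarray:
    """Proper rotation matrix for intrinsic ZYZ Euler angles (degrees)."""
    a, b, g = np.deg2rad([orientation.alpha, orientation.beta, orientation.gamma])

    def rz(t):
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def ry(t):
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    return rz(a) @ ry(b) @ rz(g)


def rotate_tensor(tensor: np.ndarray, orientation: EulerOrientation) -> np.ndarray:
    """Rotate a 3x3 interaction tensor: A' = R A R^T."""
    r = rotation_matrix(orientation)
    return r @ np.asarray(tensor, dtype=float) @ r.T


# ---------------------------------------------------------------------------
# pair-space operators

def _pair_electron_ops(z_a: int, z_b: int) -> tuple[np.ndarray, np.ndarray]:
    """Electron spin vectors of radicals A and B on the joint space.

    Layout: (electron_A x nuclei_A) x (electron_B x nuclei_B).
    """
    sa = spin_vector_operators(0.5, 0, (2, z_a, 2, z_b))
    sb = spin_vector_operators(0.5, 2, (2, z_a, 2, z_b))
    return sa, sb


def singlet_projector(z_a: int = 1, z_b: int = 1) -> np.ndarray:
    """Projector onto the electronic singlet, P_S = 1/4 - S_A . S_B.

    Acts on the 4*z_a*z_b-dimensional pair space (identity on the nuclei);
    Tr P_S = z_a * z_b.
    """
    if z_a < 1 or z_b < 1:
        raise ValueError("nuclear dimensions must be >= 1")
    dim = 4 * z_a * z_b
    sa, sb = _pair_electron_ops(z_a, z_b)
    p = 0.25 * np.eye(dim, dtype=complex)
    for a in range(3):
        p -= sa[a] @ sb[a]
    return p


def pair_hamiltonian(pair: RadicalPairSpec, field_uT: Sequence[float]) -> np.ndarray:
    """Joint Hamiltonian H_A (x) 1 + 1 (x) H_B with radical A rotated."""
    ha = build_radical_hamiltonian(pair.oriented_radical_a(), field_uT)
    hb = build_radical_hamiltonian(pair.radical_b, field_uT)
    return (
        np.kron(ha, np.eye(pair.radical_b.dim))
        + np.kron(np.eye(pair.radical_a.dim), hb)
    )
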