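"""Rigid-body superposition, inter-atom distances, helix-orientation angle.

The orientation of the mobile helix (normalized residues 167-181) is
summarized per frame as the signed angle between the X-Z-plane
projection of its Calpha167 -> Calpha181 vector and the +X axis of an
X-aligned reference structure. Frames are first superposed per monomer
onto that reference so the angle reflects internal motion only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InputError, MissingAtomError
from .structure_io import AtomRef, ConformerEnsemble

__all__ = [
    "HELIX_SPAN",
    "Superposition",
    "DistanceSeries",
    "superpose",
    "rotation_about_axis",
    "align_reference_to_x",
    "helix_angle",
    "helix_angles",
    "distance_series",
    "dihedral",
]

HELIX_SPAN = (167, 181)


@dataclass(frozen=True)
class Superposition:
    """Least-squares rigid fit: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame Euclidean distance between two resolved atoms (Angstrom)."""

    a: AtomRef
    b: AtomRef
    values: np.ndarray

    @property
    def label(self) -> str:
        return f"{self.a}-{self.b}"


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> Superposition:
    """Optimal proper-rotation rigid fit of ``mobile`` onto ``reference``.

    Closed-form Kabsch solution with the reflection branch corrected so
    the returned rotation always has det = +1, even for chirally flipped
    inputs (which then simply fit with a larger rmsd).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise InputError(f"point sets must share shape (n, 3); got {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 points to superpose, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w < 0).any() or w.sum() <= 0:
            raise InputError("weights must be non-negative with positive sum")
        w = w / w.sum()

    cm = w @ P
    cr = w @ Q
    Pc = P - cm
    Qc = Q - cr
    C = (Pc * w[:, None]).T @ Qc
    U, S, Vt = np.linalg.svd(C)
    if S[1] <= 1e-10 * max(S[0], 1e-300):
        raise DegenerateGeometryError(
            "point set is (near-)collinear; rotation is under-determined"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    delta = Pc @ R.T - Qc
    rmsd = float(np.sqrt(np.sum(w[:, None] * delta**2)))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues formula)."""
    u = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise InputError("zero rotation axis")
    u = u / norm
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def _helix_vector(ens: ConformerEnsemble, chain: str, frame: int) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = HELIX_SPAN
    p0 = ens.coordinates(AtomRef(chain, lo, "CA"), frame)
    p1 = ens.coordinates(AtomRef(chain, hi, "CA"), frame)
    return p0, p1 - p0


def align_reference_to_x(
    reference: ConformerEnsemble,
    chain: str,
    frame: int = 0,
) -> ConformerEnsemble:
    """Rigidly transform a reference frame so its helix vector lies on +X.

    The Calpha at position 167 is moved to the origin and the
    167 -> 181 vector rotated onto the +X unit direction. Returns a new
    single-frame ensemble; numbering maps are carried over.
    """
    ref = reference.frame(frame)
    ref.residue_maps = dict(reference.residue_maps)
    p0, v = _helix_vector(ref, chain, 0)
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise DegenerateGeometryError("helix endpoints coincide")
    u = v / norm
    x = np.array([1.0, 0.0, 0.0])
    c = float(np.clip(u @ x, -1.0, 1.0))
    axis = np.cross(u, x)
    if np.linalg.norm(axis) < 1e-12:
        R = np.eye(3) if c > 0 else rotation_about_axis([0.0, 1.0, 0.0], 180.0)
    else:
        R = rotation_about_axis(axis, np.degrees(np.arccos(c)))
    out = ref.transformed(R, -R @ p0)
    out.residue_maps = dict(reference.residue_maps)
    return out


def _matched_calpha(
    ens: ConformerEnsemble,
    chain: str,
    reference: ConformerEnsemble,
    ref_chain: str,
    exclude_helix: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of CA atoms shared (by normalized number) by frame and reference."""
    if chain not in ens.residue_maps or ref_chain not in reference.residue_maps:
        raise InputError("both ensembles need residue maps attached")
    common = sorted(
        set(ens.residue_maps[chain]) & set(reference.residue_maps[ref_chain])
    )
    if exclude_helix:
        lo, hi = HELIX_SPAN
        common = [n for n in common if not lo <= n <= hi]
    mob_idx, ref_idx = [], []
    for nnum in common:
        try:
            mob_idx.append(ens.atom_index(AtomRef(chain, nnum, "CA")))
            ref_idx.append(reference.atom_index(AtomRef(ref_chain, nnum, "CA")))
        except MissingAtomError:
            continue  # dropped pairwise
    if len(mob_idx) < 3:
        raise DegenerateGeometryError(
            f"fewer than 3 shared Calpha atoms between chain {chain} and reference"
        )
    return np.array(mob_idx), np.array(ref_idx)


def helix_angle(
    ensemble: ConformerEnsemble,
    frame: int,
    chain: str,
    reference: ConformerEnsemble,
    fit: str | None = "calpha",
    ref_chain: str | None = None,
) -> float:
    """Signed helix-orientation angle (degrees) of one frame vs the reference.

    ``fit`` selects the per-monomer superposition atoms: "calpha" (all
    shared Calphas, the default), "non_helix" (shared Calphas outside
    the 167-181 span, which recovers planted helix-only rotations
    exactly), or None to skip fitting. Positive angles have a positive
    Z-component of the projected helix vector.
    """
    ref_chain = chain if ref_chain is None else ref_chain
    p0, v = _helix_vector(ensemble, chain, frame)
    if fit is not None:
        if fit not in {"calpha", "non_helix"}:
            raise InputError(f"unknown fit selection: {fit!r}")
        mob_idx, ref_idx = _matched_calpha(
            ensemble, chain, reference, ref_chain, exclude_helix=(fit == "non_helix")
        )
        sup = superpose(ensemble.coords[frame, mob_idx], reference.coords[0, ref_idx])
        v = sup.rotation @ v
    vx, vz = v[0], v[2]
    proj_norm = np.hypot(vx, vz)
    if proj_norm < 1e-9 * np.linalg.norm(v):
        raise DegenerateGeometryError(
            "helix vector is perpendicular to the X-Z plane; angle undefined"
        )
    return float(np.degrees(np.arctan2(vz, vx)))


def helix_angles(
    ensemble: ConformerEnsemble,
    chain: str,
    reference: ConformerEnsemble,
    fit: str | None = "calpha",
    ref_chain: str | None = None,
) -> np.ndarray:
    """``helix_angle`` evaluated for every frame (degrees)."""
    return np.array(
        [
            helix_angle(ensemble, f, chain, reference, fit=fit, ref_chain=ref_chain)
            for f in range(ensemble.n_frames)
        ]
    )


def distance_series(
    ensemble: ConformerEnsemble,
    a: AtomRef,
    b: AtomRef,
) -> DistanceSeries:
    """Per-frame Euclidean distance between two atoms (cross-chain allowed)."""
    try:
        ia = ensemble.atom_index(a)
        ib = ensemble.atom_index(b)
    except (MissingAtomError, InputError) as exc:
        raise type(exc)(f"{exc} (while resolving pair at frame 0)") from exc
    values = np.linalg.norm(ensemble.coords[:, ia] - ensemble.coords[:, ib], axis=1)
    return DistanceSeries(a=a, b=b, values=values)


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees, IUPAC sign convention, range (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-9:
        raise DegenerateGeometryError("central dihedral bond has zero length")
    b1 = b1 / nb1
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return float(np.degrees(np.arctan2(y, x)))
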