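"""Conformational-landscape result objects built from geometry series.

Turns raw distance/angle series into: empirical distance distributions
with detected peaks, 2D (helix angle, proxy distance) landscapes with
R-like/T-like calls, side-chain (chi1, chi2) substate assignments for
position 250, and the open/closed state of the mobile active-site loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks
from scipy.stats import gaussian_kde

from .errors import ConfigError, UnsupportedResidueError
from .geometry import dihedral, distance_series, helix_angles
from .structure_io import AtomRef, ConformerEnsemble

__all__ = [
    "DistanceDistribution",
    "StateThresholds",
    "LoopThresholds",
    "SubstateAssignment",
    "make_distribution",
    "find_peaks",
    "classify_state",
    "landscape",
    "sidechain_substates",
    "loop_state",
]

R_LIKE = "R_like"
T_LIKE = "T_like"
INTERMEDIATE = "intermediate"


# ---------------------------------------------------------------------------
# distance distributions and peaks
# ---------------------------------------------------------------------------

@dataclass
class DistanceDistribution:
    """KDE of an inter-atom distance with detected peaks.

    ``peaks`` holds (location Angstrom, height, prominence) sorted by
    location; ``degenerate`` marks an (all-)constant input series whose
    density is a delta-like spike with no peak search performed.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    degenerate: bool = False

    @property
    def peak_locations(self) -> list[float]:
        return [p[0] for p in self.peaks]

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def make_distribution(
    series,
    bandwidth: float = 0.3,
    grid_step: float = 0.05,
    min_prominence: float = 0.05,
    min_separation: float = 1.0,
    min_n: int = 50,
) -> DistanceDistribution:
    """Gaussian-KDE probability density of a distance series.

    Accepts a DistanceSeries or a plain array. The density is
    renormalized on its grid so it integrates to 1. Peaks are filled in
    via :func:`find_peaks` unless the series is constant (degenerate).
    """
    values = np.asarray(getattr(series, "values", series), dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ConfigError("series must be a non-empty 1-D array of distances")
    if values.size < min_n:
        warnings.warn(
            f"only {values.size} samples (< {min_n}); density may be unreliable",
            stacklevel=2,
        )
    spread = values.std()
    if spread < 1e-12:
        center = float(values[0])
        grid = np.linspace(center - 1.0, center + 1.0, 41)
        density = np.zeros_like(grid)
        density[np.argmin(np.abs(grid - center))] = 1.0 / (grid[1] - grid[0])
        return DistanceDistribution(
            grid=grid, density=density, bandwidth=bandwidth, degenerate=True
        )
    kde = gaussian_kde(values, bw_method=bandwidth / spread)
    lo = values.min() - 4 * bandwidth
    hi = values.max() + 4 * bandwidth
    grid = np.arange(lo, hi + grid_step, grid_step)
    density = kde(grid)
    density = density / np.trapezoid(density, grid)
    dist = DistanceDistribution(grid=grid, density=density, bandwidth=bandwidth)
    dist.peaks = find_peaks(dist, min_prominence, min_separation)
    return dist


def find_peaks(
    dist: DistanceDistribution,
    min_prominence: float = 0.05,
    min_separation: float = 1.0,
) -> list[tuple[float, float, float]]:
    """Local density maxima passing prominence and separation filters.

    ``min_prominence`` is a fraction of the maximum density;
    ``min_separation`` is in Angstroms. Returns (location, height,
    prominence) sorted by location; an empty list is a valid outcome.
    """
    if dist.degenerate:
        return []
    step = float(dist.grid[1] - dist.grid[0])
    idx, props = _scipy_find_peaks(
        dist.density,
        prominence=min_prominence * dist.density.max(),
        distance=max(1, int(round(min_separation / step))),
    )
    return [
        (float(dist.grid[i]), float(dist.density[i]), float(p))
        for i, p in sorted(zip(idx, props["prominences"]))
    ]


# ---------------------------------------------------------------------------
# R-like / T-like classification and the 2D landscape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateThresholds:
    """Heuristic (theta, distance) bands for R-like/T-like calls.

    Declared heuristics, not literature-stated boundaries: anchored
    loosely to the reported out-state distance peaks (17 and 20 A)
    versus in-state geometry. Always embed these in run metadata.
    """

    d_R: float = 16.0
    d_T: float = 18.0
    theta_R: float = 4.0
    theta_T: float = 8.0

    def __post_init__(self) -> None:
        if not (self.d_R < self.d_T):
            raise ConfigError(f"require d_R < d_T, got {self.d_R} >= {self.d_T}")
        if not (self.theta_R < self.theta_T):
            raise ConfigError(
                f"require theta_R < theta_T, got {self.theta_R} >= {self.theta_T}"
            )

    def as_dict(self) -> dict:
        return asdict(self)


def classify_state(
    theta: float, d: float, thresholds: StateThresholds | None = None
) -> str:
    """Label a (helix angle, R171-P141 distance) point.

    T_like iff d >= d_T and |theta| >= theta_T; R_like iff d <= d_R and
    |theta| <= theta_R; otherwise intermediate. The three labels
    partition the plane.
    """
    t = thresholds or StateThresholds()
    if d >= t.d_T and abs(theta) >= t.theta_T:
        return T_LIKE
    if d <= t.d_R and abs(theta) <= t.theta_R:
        return R_LIKE
    return INTERMEDIATE


def landscape(
    ensemble: ConformerEnsemble,
    chain: str,
    reference: ConformerEnsemble,
    thresholds: StateThresholds | None = None,
    fit: str | None = "calpha",
) -> pd.DataFrame:
    """Per-frame (theta, d(R171 CG - P141 CA)) points with state labels.

    ``reference`` must be X-aligned (see geometry.align_reference_to_x)
    and both ensembles must have numbering attached.
    """
    t = thresholds or StateThresholds()
    theta = helix_angles(ensemble, chain, reference, fit=fit)
    d = distance_series(
        ensemble, AtomRef(chain, 171, "CG"), AtomRef(chain, 141, "CA")
    ).values
    labels = [classify_state(th, dd, t) for th, dd in zip(theta, d)]
    return pd.DataFrame(
        {
            "frame": np.arange(ensemble.n_frames),
            "chain": chain,
            "theta_deg": theta,
            "distance_A": d,
            "label": labels,
        }
    )


# ---------------------------------------------------------------------------
# side-chain substates (chi1/chi2 clustering on the torus)
# ---------------------------------------------------------------------------

@dataclass
class SubstateAssignment:
    """Cluster assignment of per-frame (chi1, chi2) side-chain dihedrals.

    Clusters are labelled Cs1..Csk by descending occupancy; occupancies
    sum to 1 and every frame is assigned.
    """

    table: pd.DataFrame  # frame, chain, chi1, chi2, substate
    occupancies: dict[str, float]
    k: int
    silhouette: float | None

    def __post_init__(self) -> None:
        total = sum(self.occupancies.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"occupancies sum to {total}, not 1")


_CHI_ATOMS = {
    "chi1": ("N", "CA", "CB", ("CG1", "CG")),
    "chi2": ("CA", "CB", ("CG1", "CG"), ("CD1", "CD")),
}


def _chi_atom_names(ensemble, chain, resid) -> tuple[list[str], str]:
    sub = ensemble.atoms[
        (ensemble.atoms["chain"] == chain) & (ensemble.atoms["resid"] == resid)
    ]
    names = set(sub["atom"])
    resname = sub["resname"].iloc[0] if len(sub) else "?"
    order = []
    for want in ("N", "CA", "CB", ("CG1", "CG"), ("CD1", "CD")):
        cands = (want,) if isinstance(want, str) else want
        hit = next((c for c in cands if c in names), None)
        if hit is None:
            raise UnsupportedResidueError(
                f"residue {resname} {chain}/{resid} lacks {'/'.join(cands)}; "
                "chi1/chi2 substate analysis unsupported"
                + (" (proline chi2 is undefined)" if resname == "PRO" else "")
            )
        order.append(hit)
    return order, resname


def sidechain_substates(
    ensemble: ConformerEnsemble,
    chain: str,
    normalized: int = 250,
    k_range: tuple[int, int] = (1, 5),
    seed: int = 0,
    min_silhouette: float = 0.5,
) -> SubstateAssignment:
    """Cluster the (chi1, chi2) dihedrals of one residue across frames.

    Angles are embedded as (cos, sin) pairs so clustering respects the
    +-180 degree wrap; k is selected in ``k_range`` by silhouette score,
    falling back to a single substate when no split scores at least
    ``min_silhouette``.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    if chain not in ensemble.residue_maps:
        raise ConfigError(f"chain {chain} has no residue map attached")
    resid = ensemble._resid_for(chain, normalized)
    names, resname = _chi_atom_names(ensemble, chain, resid)
    if resname == "PRO":
        raise UnsupportedResidueError(
            f"proline at normalized {normalized}: chi2 undefined, substate "
            "clustering unsupported"
        )
    idx = [ensemble._index[(chain, resid, n)] for n in names]
    P = ensemble.coords[:, idx, :]  # (F, 5, 3): N CA CB CG(1) CD(1)
    chi1 = np.array([dihedral(*p[:4]) for p in P])
    chi2 = np.array([dihedral(*p[1:5]) for p in P])

    ang = np.deg2rad(np.column_stack([chi1, chi2]))
    X = np.concatenate([np.cos(ang), np.sin(ang)], axis=1)

    k_lo, k_hi = k_range
    if not 1 <= k_lo <= k_hi:
        raise ConfigError(f"invalid k range {k_range}")
    k_hi = min(k_hi, len(X) - 1)
    best_k, best_sil, best_labels = 1, None, np.zeros(len(X), dtype=int)
    for k in range(max(2, k_lo), k_hi + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_score(X, labels)
        if best_sil is None or sil > best_sil:
            best_k, best_sil, best_labels = k, sil, labels
    if k_lo == 1 and (best_sil is None or best_sil < min_silhouette):
        best_k, best_sil, best_labels = 1, best_sil, np.zeros(len(X), dtype=int)

    # relabel clusters Cs1..Csk by descending occupancy
    counts = pd.Series(best_labels).value_counts()
    rank = {orig: i + 1 for i, orig in enumerate(counts.index)}
    substates = [f"Cs{rank[l]}" for l in best_labels]
    occ = {
        f"Cs{i + 1}": float(c) / len(X) for i, c in enumerate(counts.to_numpy())
    }
    table = pd.DataFrame(
        {
            "frame": np.arange(len(X)),
            "chain": chain,
            "chi1": chi1,
            "chi2": chi2,
            "substate": substates,
        }
    )
    return SubstateAssignment(
        table=table, occupancies=occ, k=best_k, silhouette=best_sil
    )


# ---------------------------------------------------------------------------
# mobile-loop open/closed state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoopThresholds:
    """Open/closed bands anchored to printed crystal exemplars.

    Closed exemplar (Holo): d102 = 13.1 A, d109 = 9.6 A; open exemplar
    (Apo): both distances above 20 A. The mid-band stays intermediate.
    """

    closed_d102: float = 15.0
    closed_d109: float = 12.0
    open_d102: float = 20.0
    open_d109: float = 15.0

    def __post_init__(self) -> None:
        if self.closed_d102 >= self.open_d102 or self.closed_d109 >= self.open_d109:
            raise ConfigError("closed thresholds must lie below open thresholds")

    def classify(self, d102: float, d109: float) -> str:
        if d102 <= self.closed_d102 and d109 <= self.closed_d109:
            return "closed"
        if d102 >= self.open_d102 and d109 >= self.open_d109:
            return "open"
        return INTERMEDIATE

    def as_dict(self) -> dict:
        return asdict(self)


def loop_state(
    ensemble: ConformerEnsemble,
    chain: str,
    thresholds: LoopThresholds | None = None,
) -> pd.DataFrame:
    """Per-frame loop distances to L167 CA and the open/closed call."""
    t = thresholds or LoopThresholds()
    anchor = AtomRef(chain, 167, "CA")
    d102 = distance_series(ensemble, anchor, AtomRef(chain, 102, "CG")).values
    d109 = distance_series(ensemble, anchor, AtomRef(chain, 109, "CG")).values
    states = [t.classify(a, b) for a, b in zip(d102, d109)]
    return pd.DataFrame(
        {
            "frame": np.arange(ensemble.n_frames),
            "chain": chain,
            "d102_A": d102,
            "d109_A": d109,
            "state": states,
        }
    )
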