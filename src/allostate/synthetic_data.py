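"""Ground-truth generators for every input the pipeline consumes.

Emits (a) dimeric pseudo-protein conformer ensembles with planted
R-in/T-out side-chain positions, helix rotations, loop states and
chi1/chi2 substates, (b) saturation curves from the three rate laws with
multiplicative noise, and (c) toy family FASTA/Newick fixtures with
planted signature residues. Every generator is seeded and writes a
sidecar truth record; tests read truth only from there.

Only the atoms the analyses touch are emitted (CA everywhere; side-chain
atoms at the addressed positions), spaced on an idealized backbone so
superposition is well-conditioned. The contract is geometric, not
chemical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .geometry import rotation_about_axis
from .kinetics import MODELS, SaturationDataset, rate
from .numbering import ReferenceProfile, load_reference
from .signatures import SIGNATURE_POSITIONS
from .structure_io import ConformerEnsemble, attach_identity_numbering, write_ensemble

__all__ = [
    "EnsembleSpec",
    "KineticsSpec",
    "make_ensemble",
    "make_saturation",
    "make_family_fixture",
]

R_LIKE, T_LIKE, INTERMEDIATE = "R_like", "T_like", "intermediate"

RESID_RANGE = (60, 260)
HELIX_LO, HELIX_HI = 167, 181
_RISE = 1.5  # A per residue along the idealized helix


# ---------------------------------------------------------------------------
# small geometric helpers
# ---------------------------------------------------------------------------

def _sphere_intersection(c1, r1, c2, r2) -> np.ndarray:
    """A deterministic point at distance r1 from c1 and r2 from c2."""
    c1 = np.asarray(c1, float)
    c2 = np.asarray(c2, float)
    d = float(np.linalg.norm(c2 - c1))
    if d < 1e-9 or d > r1 + r2 or d < abs(r1 - r2):
        raise ConfigError(
            f"planted distances infeasible: centers {d:.2f} A apart cannot "
            f"carry radii {r1:.2f} and {r2:.2f}"
        )
    u = (c2 - c1) / d
    a = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h2 = r1 * r1 - a * a
    h = np.sqrt(max(h2, 0.0))
    v = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(v) < 1e-6:
        v = np.cross(u, [0.0, 1.0, 0.0])
    v = v / np.linalg.norm(v)
    return c1 + a * u + h * v


def _nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from internal coordinates so dihedral(a,b,c,D)=torsion."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [-bond * np.cos(theta), bond * np.sin(theta) * np.cos(phi), bond * np.sin(theta) * np.sin(phi)]
    )
    return c + np.column_stack([bc, m, n]) @ d2


def _wrap_deg(x: np.ndarray) -> np.ndarray:
    return (np.asarray(x) + 180.0) % 360.0 - 180.0


def _exact_partition(labels, fractions, n, rng) -> np.ndarray:
    """Shuffled label vector with counts as close to n*fraction as possible."""
    counts = [int(round(f * n)) for f in fractions]
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n:
        counts[int(np.argmax(fractions))] += 1
    out = np.repeat(labels, counts)
    return out[rng.permutation(n)]


# ---------------------------------------------------------------------------
# ensemble spec and generator
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSpec:
    """Planted ground truth for a synthetic dimeric conformer ensemble.

    Distance anchors follow the printed family values: out-state
    R171-P141 peaks near 17 and 20 A with mirror R171-N181 peaks near 13
    and 11 A, closed-loop exemplar (13.1, 9.6) A, open (22, 21) A.
    """

    seed: int
    n_frames: int = 500
    fractions: dict = field(
        default_factory=lambda: {R_LIKE: 0.7, T_LIKE: 0.3, INTERMEDIATE: 0.0}
    )
    # d(R171 CG - P141 CA) per state: list of (mean A, sd A, weight)
    r_distance_modes: tuple = ((15.0, 0.30, 1.0),)
    t_distance_modes: tuple = ((20.0, 0.35, 1.0),)
    i_distance_modes: tuple = ((17.0, 0.25, 1.0),)
    # mirror law: d(R171-N181) = intercept - slope * d(R171-P141) + noise
    mirror_slope: float = 0.6
    mirror_intercept: float = 23.0
    mirror_noise_sd: float = 0.10
    # helix angle theta per state: (mean deg, sd deg)
    r_theta: tuple = (0.0, 1.5)
    t_theta: tuple = (12.0, 1.5)
    i_theta: tuple = (6.0, 1.0)
    # mobile loop
    loop_fractions: dict = field(
        default_factory=lambda: {"closed": 1.0, "open": 0.0, "intermediate": 0.0}
    )
    loop_closed: tuple = (13.1, 9.6)
    loop_open: tuple = (22.0, 21.0)
    loop_intermediate: tuple = (17.0, 13.0)
    loop_sd: float = 0.15
    # residue-250 side-chain substates: (chi1 deg, chi2 deg, occupancy)
    chi_modes: tuple = ((-60.0, 170.0, 0.5), (65.0, -60.0, 0.3), (180.0, 60.0, 0.2))
    chi_sd: float = 8.0
    residue102: str = "ARG"
    residue250: str = "ILE"
    noise_sd: float = 0.0
    frame_dt_ps: float = 100.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for name, frs in (("fractions", self.fractions), ("loop_fractions", self.loop_fractions)):
            if abs(sum(frs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1, got {sum(frs.values())}")
            if any(f < 0 for f in frs.values()):
                raise ConfigError(f"negative fraction in {name}")
        occ = sum(m[2] for m in self.chi_modes)
        if abs(occ - 1.0) > 1e-9:
            raise ConfigError(f"chi mode occupancies must sum to 1, got {occ}")
        for modes in (self.r_distance_modes, self.t_distance_modes, self.i_distance_modes):
            if any(sd < 0 for _, sd, _ in modes):
                raise ConfigError("distance mode SDs must be >= 0")
        if self.noise_sd < 0 or self.chi_sd < 0 or self.loop_sd < 0:
            raise ConfigError("SDs must be >= 0")
        if self.n_frames < 1:
            raise ConfigError("need at least one frame")
        if self.residue250 not in {"ILE", "PRO"}:
            raise ConfigError("residue250 must be ILE or PRO")
        if self.residue102 not in {"ARG", "GLN"}:
            raise ConfigError("residue102 must be ARG or GLN")


_SPECIAL_RESNAMES = {
    68: "HIS", 109: "ARG", 141: "PRO", 167: "LEU", 171: "ARG",
    181: "ASN", 195: "HIS", 199: "ASP", 246: "THR", 251: "GLY",
}


def _canonical_monomer() -> dict:
    """Static scaffold for one monomer: CA curve plus anchor geometry."""
    lo, hi = RESID_RANGE
    ca = {}
    for i in range(lo, hi + 1):
        ca[i] = np.array([8.0 * np.cos(0.5 * i), 8.0 * np.sin(0.5 * i), 0.8 * i])
    p167 = ca[167].copy()
    for j in range(HELIX_LO, HELIX_HI + 1):
        ca[j] = p167 + np.array([_RISE * (j - HELIX_LO), 0.0, 0.0])
    ca[141] = p167 + np.array([5.0, -18.0, 2.0])
    return {
        "ca": ca,
        "p167": p167,
        "loop_dir_102": np.array([-0.30, 0.80, 0.52]) / np.linalg.norm([-0.30, 0.80, 0.52]),
        "loop_dir_109": np.array([-0.50, -0.60, 0.62]) / np.linalg.norm([-0.50, -0.60, 0.62]),
    }


def _atom_layout(spec: EnsembleSpec) -> list[tuple[str, int, str, str]]:
    """(chain, resid, resname, atom) rows, identical ordering every frame."""
    lo, hi = RESID_RANGE
    resnames = dict(_SPECIAL_RESNAMES)
    resnames[102] = spec.residue102
    resnames[250] = spec.residue250
    rows = []
    for chain in ("A", "B"):
        for i in range(lo, hi + 1):
            resname = resnames.get(i, "ALA")
            if i == 250:
                rows.append((chain, i, resname, "N"))
            rows.append((chain, i, resname, "CA"))
            if i in (68, 102, 109, 171):
                rows.append((chain, i, resname, "CG"))
            if i == 250 and spec.residue250 == "ILE":
                rows.extend(
                    [(chain, i, resname, "CB"), (chain, i, resname, "CG1"), (chain, i, resname, "CD1")]
                )
            elif i == 250:
                rows.append((chain, i, resname, "CB"))
    return rows


def _chain_truth(spec: EnsembleSpec, rng: np.random.Generator) -> dict:
    """Draw all planted per-frame quantities for one monomer."""
    n = spec.n_frames
    states = _exact_partition(
        list(spec.fractions), list(spec.fractions.values()), n, rng
    )
    mode_sets = {
        R_LIKE: spec.r_distance_modes,
        T_LIKE: spec.t_distance_modes,
        INTERMEDIATE: spec.i_distance_modes,
    }
    theta_par = {R_LIKE: spec.r_theta, T_LIKE: spec.t_theta, INTERMEDIATE: spec.i_theta}
    d1 = np.empty(n)
    theta = np.empty(n)
    for s in spec.fractions:
        idx = np.flatnonzero(states == s)
        if idx.size == 0:
            continue
        modes = mode_sets[s]
        weights = np.array([m[2] for m in modes], float)
        weights = weights / weights.sum()
        comp = _exact_partition(np.arange(len(modes)), weights, idx.size, rng)
        means = np.array([modes[c][0] for c in comp])
        sds = np.array([modes[c][1] for c in comp])
        d1[idx] = rng.normal(means, sds)
        mu, sd = theta_par[s]
        theta[idx] = rng.normal(mu, sd, idx.size)
    d2 = spec.mirror_intercept - spec.mirror_slope * d1 + rng.normal(
        0.0, spec.mirror_noise_sd, n
    )

    loop_states = _exact_partition(
        list(spec.loop_fractions), list(spec.loop_fractions.values()), n, rng
    )
    loop_means = {
        "closed": spec.loop_closed,
        "open": spec.loop_open,
        "intermediate": spec.loop_intermediate,
    }
    d102 = np.array([rng.normal(loop_means[s][0], spec.loop_sd) for s in loop_states])
    d109 = np.array([rng.normal(loop_means[s][1], spec.loop_sd) for s in loop_states])

    occ = [m[2] for m in spec.chi_modes]
    chi_mode = _exact_partition(np.arange(len(spec.chi_modes)), occ, n, rng)
    chi1 = _wrap_deg(
        np.array([spec.chi_modes[m][0] for m in chi_mode]) + rng.normal(0, spec.chi_sd, n)
    )
    chi2 = _wrap_deg(
        np.array([spec.chi_modes[m][1] for m in chi_mode]) + rng.normal(0, spec.chi_sd, n)
    )
    return {
        "state": states.tolist(),
        "theta_deg": theta.tolist(),
        "d_r171_p141": d1.tolist(),
        "d_r171_n181": d2.tolist(),
        "loop_state": loop_states.tolist(),
        "d102": d102.tolist(),
        "d109": d109.tolist(),
        "chi_mode": chi_mode.tolist(),
        "chi1": chi1.tolist(),
        "chi2": chi2.tolist(),
    }


def _monomer_frame(spec: EnsembleSpec, scaffold: dict, truth: dict, f: int) -> dict:
    """Coordinates {(resid, atom): xyz} of one monomer in one frame."""
    ca = {i: p.copy() for i, p in scaffold["ca"].items()}
    p167 = scaffold["p167"]
    theta = truth["theta_deg"][f]
    R = rotation_about_axis([0.0, -1.0, 0.0], theta)
    for j in range(HELIX_LO, HELIX_HI + 1):
        ca[j] = p167 + R @ (ca[j] - p167) if j > HELIX_LO else ca[j]

    coords = {(i, "CA"): p for i, p in ca.items()}
    coords[(171, "CG")] = _sphere_intersection(
        ca[141], truth["d_r171_p141"][f], ca[181], truth["d_r171_n181"][f]
    )
    coords[(102, "CG")] = ca[167] + truth["d102"][f] * scaffold["loop_dir_102"]
    coords[(109, "CG")] = ca[167] + truth["d109"][f] * scaffold["loop_dir_109"]
    coords[(68, "CG")] = ca[68] + np.array([1.0, 1.0, 0.5])

    n250 = ca[250] + 1.46 * (ca[249] - ca[250]) / np.linalg.norm(ca[249] - ca[250])
    coords[(250, "N")] = n250
    cb = _nerf(ca[251], n250, ca[250], 1.53, 110.5, -122.0)
    coords[(250, "CB")] = cb
    if spec.residue250 == "ILE":
        cg1 = _nerf(n250, ca[250], cb, 1.53, 114.0, truth["chi1"][f])
        coords[(250, "CG1")] = cg1
        coords[(250, "CD1")] = _nerf(ca[250], cb, cg1, 1.53, 113.0, truth["chi2"][f])
    return coords


def make_ensemble(
    spec: EnsembleSpec, out_dir: str | Path | None = None
) -> tuple[ConformerEnsemble, dict]:
    """Build the dimer ensemble carrying every planted quantity.

    Returns the ensemble (identity numbering attached) and the truth
    record; when ``out_dir`` is given, writes ``ensemble.pdb`` and
    ``ensemble.truth.json`` there.
    """
    rng = np.random.default_rng(spec.seed)
    scaffold = _canonical_monomer()
    layout = _atom_layout(spec)
    truth_chains = {"A": _chain_truth(spec, rng), "B": _chain_truth(spec, rng)}

    # static placement transform of monomer B; a Y-axis rotation keeps the
    # signed helix-angle convention identical in both monomers
    Rb = rotation_about_axis([0.0, 1.0, 0.0], 180.0)
    tb = np.array([60.0, 5.0, 0.0])

    per_chain_rows = {
        c: [(r, a) for ch, r, _, a in layout if ch == c] for c in ("A", "B")
    }
    coords = np.empty((spec.n_frames, len(layout), 3))
    for f in range(spec.n_frames):
        frame_coords = []
        for chain in ("A", "B"):
            mono = _monomer_frame(spec, scaffold, truth_chains[chain], f)
            pts = np.array([mono[key] for key in per_chain_rows[chain]])
            if chain == "B":
                pts = pts @ Rb.T + tb
            frame_coords.append(pts)
        coords[f] = np.vstack(frame_coords)
    if spec.noise_sd > 0:
        coords = coords + rng.normal(0.0, spec.noise_sd, coords.shape)

    atoms = pd.DataFrame(layout, columns=["chain", "resid", "resname", "atom"])
    ensemble = ConformerEnsemble(
        atoms=atoms,
        coords=coords,
        frame_times=np.arange(spec.n_frames) * spec.frame_dt_ps,
    )
    attach_identity_numbering(ensemble)
    truth = {"spec": asdict(spec), "chains": truth_chains}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_ensemble(ensemble, out_dir / "ensemble.pdb")
        (out_dir / "ensemble.truth.json").write_text(json.dumps(truth, indent=1))
    return ensemble, truth


def reference_ensemble(spec: EnsembleSpec) -> ConformerEnsemble:
    """The noise-free, R-state, theta=0 single-frame reference structure."""
    ref_spec = EnsembleSpec(
        seed=spec.seed,
        n_frames=1,
        fractions={R_LIKE: 1.0, T_LIKE: 0.0, INTERMEDIATE: 0.0},
        r_distance_modes=((spec.r_distance_modes[0][0], 0.0, 1.0),),
        r_theta=(0.0, 0.0),
        mirror_noise_sd=0.0,
        loop_fractions=dict(spec.loop_fractions),
        loop_sd=0.0,
        chi_modes=((spec.chi_modes[0][0], spec.chi_modes[0][1], 1.0),),
        chi_sd=0.0,
        residue102=spec.residue102,
        residue250=spec.residue250,
        noise_sd=0.0,
    )
    ens, _ = make_ensemble(ref_spec)
    return ens


# ---------------------------------------------------------------------------
# saturation curves
# ---------------------------------------------------------------------------

@dataclass
class KineticsSpec:
    """Planted rate law, parameters, concentration grid and noise model."""

    seed: int
    model: str = "michaelis_menten"
    params: dict = field(default_factory=lambda: {"Vmax": 40.0, "Km": 5.6})
    n_concentrations: int = 12
    span: tuple = (0.2, 10.0)  # multiples of the half-saturation parameter
    grid_mM: tuple | None = None  # explicit grid overrides span
    replicates: int = 3
    cv: float = 0.05
    substrate: str = "other"

    def half_saturation(self) -> float:
        key = "S05" if self.model == "allosteric_sigmoidal" else "Km"
        return float(self.params[key])

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.model not in MODELS:
            raise ConfigError(f"unknown model {self.model!r}")
        missing = set(MODELS[self.model]["params"]) - set(self.params)
        if missing:
            raise ConfigError(f"missing parameters for {self.model}: {sorted(missing)}")
        if self.cv < 0:
            raise ConfigError("cv must be >= 0")
        k = self.half_saturation()
        if self.grid_mM is not None:
            lo, hi = min(self.grid_mM), max(self.grid_mM)
        else:
            lo, hi = self.span[0] * k, self.span[1] * k
        if lo > 0.2 * k + 1e-12 or hi < 5.0 * k - 1e-9:
            raise ConfigError(
                f"grid [{lo:g}, {hi:g}] mM must span at least 0.2x-5x the "
                f"half-saturation parameter ({k:g} mM)"
            )


def make_saturation(spec: KineticsSpec) -> tuple[SaturationDataset, dict]:
    """Noisy saturation dataset: v = rate(S) * exp(eps), eps ~ N(0, cv^2)."""
    rng = np.random.default_rng(spec.seed)
    if spec.grid_mM is not None:
        grid = np.asarray(spec.grid_mM, float)
    else:
        k = spec.half_saturation()
        grid = np.geomspace(spec.span[0] * k, spec.span[1] * k, spec.n_concentrations)
    S = np.tile(grid, spec.replicates)
    reps = np.repeat(np.arange(1, spec.replicates + 1), len(grid))
    v_true = rate(spec.model, S, spec.params)
    v = v_true * np.exp(rng.normal(0.0, spec.cv, S.shape))
    dataset = SaturationDataset(
        substrate_mM=S, rates=v, substrate=spec.substrate, replicate=reps
    )
    truth = {"spec": asdict(spec), "grid_mM": grid.tolist()}
    return dataset, truth


# ---------------------------------------------------------------------------
# toy family fixtures
# ---------------------------------------------------------------------------

def _balanced_newick(ids: list[str]) -> str:
    def build(sub):
        if len(sub) == 1:
            return f"{sub[0]}:0.1"
        mid = len(sub) // 2
        return f"({build(sub[:mid])},{build(sub[mid:])}):0.1"

    return build(ids) + ";"


def make_family_fixture(
    n_leaves: int,
    assignments: dict[str, dict[int, str]] | None = None,
    seed: int = 0,
    n_neutral_mutations: int = 0,
    reference: ReferenceProfile | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[str, str]], str, dict]:
    """Sequences = packaged reference with planted signature substitutions.

    ``assignments`` maps leaf id -> {normalized position: amino acid};
    leaves without an entry keep the reference signature. Optional
    neutral mutations are placed away from the signature positions.
    Returns (records, newick, truth); writes family.fa / family.nwk /
    family.truth.json under ``out_dir`` when given.
    """
    rng = np.random.default_rng(seed)
    ref = reference or load_reference()
    assignments = assignments or {}
    ids = list(assignments) or [f"leaf{i + 1}" for i in range(n_leaves)]
    if len(ids) < n_leaves:
        ids += [f"leaf{i + 1}" for i in range(len(ids), n_leaves)]
    pos_of = {n: i for i, n in enumerate(ref.normalized_numbers)}
    forbidden = {pos_of[p] for p in SIGNATURE_POSITIONS if p in pos_of}
    records = []
    truth: dict = {"seed": seed, "leaves": {}}
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    for leaf in ids:
        seq = list(ref.sequence)
        planted = assignments.get(leaf, {})
        for p, aa in planted.items():
            if p not in SIGNATURE_POSITIONS:
                raise ConfigError(
                    f"{leaf}: {p} is not a signature position {SIGNATURE_POSITIONS}"
                )
            seq[pos_of[p]] = aa.upper()
        mutated = []
        if n_neutral_mutations:
            candidates = [i for i in range(len(seq)) if i not in forbidden]
            for i in rng.choice(candidates, size=n_neutral_mutations, replace=False):
                choices = [a for a in alphabet if a != seq[i]]
                seq[i] = str(rng.choice(choices))
                mutated.append(int(i) + 1)
        records.append((leaf, "".join(seq)))
        truth["leaves"][leaf] = {
            "planted": {int(p): aa for p, aa in planted.items()},
            "neutral_sites": mutated,
        }
    newick = _balanced_newick(ids)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "family.fa", "w") as fh:
            for leaf, seq in records:
                fh.write(f">{leaf}\n{seq}\n")
        (out_dir / "family.nwk").write_text(newick + "\n")
        (out_dir / "family.truth.json").write_text(json.dumps(truth, indent=1))
    return records, newick, truth
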