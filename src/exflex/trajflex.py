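"""Conformational flexibility of ensembles: superposition, RMSD clustering,
cluster-probability conformational entropy, and per-atom RMSF.

The flexibility measure follows the cluster-counting convention: snapshots are
clustered at an RMSD cutoff (2 A by default) and the cluster probability
distribution p yields the conformational entropy, reported as the
temperature-weighted quantity

    S_conf = -R T sum_i p_i ln p_i        [kcal/mol, T = 300 K default]

so a single rigid conformation scores 0 and m equiprobable conformations score
R T ln m.  RMSF is the per-atom root mean square fluctuation about the mean
position after rigid-body superposition; for ligand atoms the superposition
frame is the receptor selection, so ligand RMSF measures motion relative to
the receptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .binding import R_KCAL_PER_MOL_K

DEFAULT_CLUSTER_CUTOFF_A = 2.0
DEFAULT_ENTROPY_TEMPERATURE_K = 300.0
DEFAULT_FRAME_INTERVAL_PS = 20.0

MAIN_CHAIN_NAMES = ("N", "CA", "C", "O")
GROUPS = ("ligand", "receptor", "crosslink")


@dataclass
class ConformerTrajectory:
    """Frames x atoms x 3 coordinates (A) with atom names and group labels."""

    coords: np.ndarray
    atom_names: np.ndarray
    atom_groups: np.ndarray  # each in {"ligand", "receptor", "crosslink"}
    frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.atom_groups = np.asarray(self.atom_groups, dtype=object)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("trajectory needs >= 2 frames")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.atom_names.shape[0] != self.n_atoms or self.atom_groups.shape[0] != self.n_atoms:
            raise ValueError("atom_names/atom_groups length must match atom count")
        bad = set(self.atom_groups) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown atom groups: {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(
        self,
        groups: Sequence[str] | None = None,
        names: Sequence[str] | None = None,
    ) -> np.ndarray:
        """Atom indices matching any of ``groups`` and (if given) any of ``names``."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if groups is not None:
            mask &= np.isin(self.atom_groups, list(groups))
        if names is not None:
            mask &= np.isin(self.atom_names, list(names))
        return np.nonzero(mask)[0]


@dataclass
class ClusterResult:
    """Frame->cluster assignment with cluster populations."""

    labels: np.ndarray  # cluster id per frame, 0-based, ordered by discovery
    populations: np.ndarray
    n_clusters: int
    cutoff: float
    selection: np.ndarray  # atom indices used for the distance
    method: str
    seeds: np.ndarray | None = None  # seed frame index per cluster (leader only)

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.populations)) - 1.0) > 1e-9:
            raise ValueError("cluster populations must sum to 1")


@dataclass
class FlexReport:
    """Entropy decomposition and per-atom RMSF for one complex."""

    S_conf_total: float  # kcal/mol
    S_conf_ligand: float
    S_conf_receptor: float
    temperature: float
    rmsf: np.ndarray  # A, per RMSF-selected atom
    rmsf_atoms: np.ndarray  # indices of those atoms
    cutoff: float
    clusters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "S_conf_total": self.S_conf_total,
            "S_conf_ligand": self.S_conf_ligand,
            "S_conf_receptor": self.S_conf_receptor,
            "temperature_K": self.temperature,
            "cutoff_A": self.cutoff,
            "rmsf_A": [float(v) for v in self.rmsf],
            "rmsf_atom_indices": [int(i) for i in self.rmsf_atoms],
            "populations": {
                key: [float(p) for p in res.populations]
                for key, res in self.clusters.items()
            },
        }


# ---------------------------------------------------------------------------
# Rigid-body superposition (Kabsch), batched over frames


def _kabsch_rotations(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimal rotations aligning each centred frame in ``mobile`` onto centred
    ``ref``.  mobile: (n_frames, n_atoms, 3), ref: (n_atoms, 3); both centred.
    Returns (n_frames, 3, 3) proper rotation matrices."""
    cov = np.einsum("fai,aj->fij", mobile, ref)
    u, _, vt = np.linalg.svd(cov)
    det = np.linalg.det(np.einsum("fij,fjk->fik", u, vt))
    d = np.ones_like(u[:, :, 0])
    d[:, -1] = np.sign(det)
    return np.einsum("fij,fj,fjk->fik", u, d, vt).transpose(0, 2, 1)


def _align_frames(coords: np.ndarray, idx: np.ndarray, ref_sel: np.ndarray):
    """Rigid-transform every frame so its ``idx`` selection best fits
    ``ref_sel`` (already centred at origin).  Returns transformed coords."""
    sel = coords[:, idx, :]
    cent = sel.mean(axis=1, keepdims=True)
    rot = _kabsch_rotations(sel - cent, ref_sel)
    return np.einsum("fai,fij->faj", coords - cent, rot.transpose(0, 2, 1))


def superpose(traj: ConformerTrajectory, selection: np.ndarray | None = None) -> ConformerTrajectory:
    """Superpose all frames onto the iteratively refined mean structure.

    Each frame is rigid-body transformed (Kabsch rotation + centroid shift) to
    minimize RMSD of ``selection`` to the running mean; the mean is recomputed
    and the procedure iterated until it moves by < 1e-6 A RMSD.
    """
    if selection is None:
        selection = np.arange(traj.n_atoms)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("selection is empty")
    if selection.size >= 3:
        probe = traj.coords[0, selection, :]
        if np.linalg.matrix_rank(probe - probe.mean(axis=0)) < 2:
            raise ValueError("degenerate selection: atoms are collinear")
    else:
        raise ValueError("selection needs >= 3 non-collinear atoms")

    coords = traj.coords.copy()
    ref = coords[0, selection, :]
    ref = ref - ref.mean(axis=0)
    for _ in range(50):
        coords = _align_frames(coords, selection, ref)
        new_ref = coords[:, selection, :].mean(axis=0)
        new_ref = new_ref - new_ref.mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_ref - ref) ** 2, axis=1)))
        ref = new_ref
        if shift < 1e-6:
            break
    return replace(traj, coords=coords, meta=dict(traj.meta, superposed_on=selection))


def rmsd_to_reference(
    coords: np.ndarray, ref: np.ndarray, superimpose: bool = True
) -> np.ndarray:
    """Minimum RMSD (A) of each frame in ``coords`` (f, a, 3) to ``ref`` (a, 3)."""
    ref_c = ref - ref.mean(axis=0)
    sel = coords - coords.mean(axis=1, keepdims=True)
    if superimpose:
        rot = _kabsch_rotations(sel, ref_c)
        sel = np.einsum("fai,fij->faj", sel, rot.transpose(0, 2, 1))
    return np.sqrt(np.mean(np.sum((sel - ref_c) ** 2, axis=2), axis=1))


def pairwise_rmsd(traj: ConformerTrajectory, selection: np.ndarray | None = None) -> np.ndarray:
    """Symmetric matrix of pair-optimal RMSD (A) between all frames."""
    if selection is None:
        selection = np.arange(traj.n_atoms)
    sel = traj.coords[:, np.asarray(selection, dtype=int), :]
    n = sel.shape[0]
    out = np.zeros((n, n))
    for i in range(n - 1):
        out[i, i + 1 :] = rmsd_to_reference(sel[i + 1 :], sel[i])
    return out + out.T


# ---------------------------------------------------------------------------
# Clustering and entropy


def cluster(
    traj: ConformerTrajectory,
    cutoff: float = DEFAULT_CLUSTER_CUTOFF_A,
    selection: np.ndarray | None = None,
    method: str = "leader",
) -> ClusterResult:
    """Cluster frames at an RMSD ``cutoff`` on ``selection``.

    leader (default): the first frame seeds cluster 0; each subsequent frame
    joins the lowest-id cluster whose *seed* is within the cutoff, else seeds
    a new cluster.  Implemented as equivalent vectorized sweeps: all frames
    within the cutoff of seed 0 are assigned to it, the first remaining frame
    seeds the next cluster, and so on — identical assignment, O(n_frames x
    n_clusters).  single/average: agglomerative linkage on the pairwise RMSD
    matrix cut at the cutoff (O(n^2) memory; small ensembles only).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if selection is None:
        selection = np.arange(traj.n_atoms)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("selection is empty")
    sel = traj.coords[:, selection, :]
    n = sel.shape[0]

    if method == "leader":
        labels = np.full(n, -1, dtype=int)
        seeds: list[int] = []
        remaining = np.arange(n)
        while remaining.size:
            seed = int(remaining[0])
            cid = len(seeds)
            seeds.append(seed)
            d = rmsd_to_reference(sel[remaining], sel[seed])
            hit = d <= cutoff
            labels[remaining[hit]] = cid
            remaining = remaining[~hit]
        seeds_arr = np.asarray(seeds)
    elif method in ("single", "average"):
        dm = pairwise_rmsd(traj, selection)
        link = hierarchy.linkage(squareform(dm, checks=False), method=method)
        raw = hierarchy.fcluster(link, t=cutoff, criterion="distance")
        # renumber by first appearance so labels are deterministic in frame order
        _, labels = np.unique(raw, return_inverse=True)
        order = {}
        labels2 = np.empty_like(labels)
        for i, lab in enumerate(labels):
            if lab not in order:
                order[lab] = len(order)
            labels2[i] = order[lab]
        labels = labels2
        seeds_arr = None
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    n_clusters = int(labels.max()) + 1
    populations = np.bincount(labels, minlength=n_clusters) / n
    return ClusterResult(
        labels=labels,
        populations=populations,
        n_clusters=n_clusters,
        cutoff=float(cutoff),
        selection=selection,
        method=method,
        seeds=seeds_arr,
    )


def conf_entropy(
    populations, temperature: float = DEFAULT_ENTROPY_TEMPERATURE_K
) -> float:
    """Conformational entropy S_conf = -R T sum p ln p (kcal/mol), 0 ln 0 := 0."""
    p = np.asarray(populations, dtype=float)
    if np.any(p < 0):
        raise ValueError("populations must be >= 0")
    if abs(float(p.sum()) - 1.0) > 1e-6:
        raise ValueError(f"populations must sum to 1, got {p.sum()}")
    nz = p[p > 0]
    return float(-R_KCAL_PER_MOL_K * temperature * np.sum(nz * np.log(nz)))


def rmsf(traj: ConformerTrajectory, selection: np.ndarray | None = None) -> np.ndarray:
    """Per-atom RMSF (A): sqrt(mean_t |r_a(t) - <r_a>|^2).

    Assumes the trajectory has already been superposed (rigid-body motion
    removed); otherwise translations/rotations inflate the result.
    """
    if selection is None:
        selection = np.arange(traj.n_atoms)
    sel = traj.coords[:, np.asarray(selection, dtype=int), :]
    mean = sel.mean(axis=0, keepdims=True)
    return np.sqrt(np.mean(np.sum((sel - mean) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# Report assembly


def _distance_selection(traj: ConformerTrajectory, part: str) -> np.ndarray:
    """Atoms defining the clustering distance for a selection.

    Ligand: main-chain atoms plus crosslink carbons; receptor: CA atoms;
    complex: union.  Falls back to all atoms of the group when none of the
    conventional names are present (e.g. coarse synthetic ensembles).
    """
    def _named(groups, names):
        idx = traj.select(groups=groups, names=names)
        return idx if idx.size else traj.select(groups=groups)

    if part == "ligand":
        main = _named(("ligand",), MAIN_CHAIN_NAMES)
        xlink = traj.select(groups=("crosslink",))
        if xlink.size:
            carbons = [i for i in xlink if str(traj.atom_names[i]).startswith("C")]
            xlink = np.asarray(carbons, dtype=int) if carbons else xlink
        return np.union1d(main, xlink)
    if part == "receptor":
        return _named(("receptor",), ("CA",))
    if part == "complex":
        return np.union1d(_distance_selection(traj, "ligand"), _distance_selection(traj, "receptor"))
    raise ValueError(f"unknown part {part!r}")


def flex_report(
    traj: ConformerTrajectory,
    cutoff: float = DEFAULT_CLUSTER_CUTOFF_A,
    temperature: float = DEFAULT_ENTROPY_TEMPERATURE_K,
    method: str = "leader",
) -> FlexReport:
    """Full flexibility analysis of one ligand-receptor ensemble.

    Three independent clustering+entropy computations (complex = ligand union
    receptor, ligand only, receptor only), plus RMSF of ligand main-chain
    atoms and crosslink carbons after superposition on the receptor selection.
    """
    for grp in ("ligand", "receptor"):
        if traj.select(groups=(grp,)).size == 0:
            raise ValueError(f"trajectory has no atoms in group {grp!r}")

    entropies = {}
    clusters = {}
    for part in ("complex", "ligand", "receptor"):
        res = cluster(traj, cutoff=cutoff, selection=_distance_selection(traj, part), method=method)
        clusters[part] = res
        entropies[part] = conf_entropy(res.populations, temperature)

    rec_sel = _distance_selection(traj, "receptor")
    aligned = superpose(traj, rec_sel)
    rmsf_atoms = _distance_selection(traj, "ligand")
    rmsf_vals = rmsf(aligned, rmsf_atoms)

    return FlexReport(
        S_conf_total=entropies["complex"],
        S_conf_ligand=entropies["ligand"],
        S_conf_receptor=entropies["receptor"],
        temperature=temperature,
        rmsf=rmsf_vals,
        rmsf_atoms=rmsf_atoms,
        cutoff=cutoff,
        clusters=clusters,
    )
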