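"""CheA P4 "dipping" switch analysis for MD-style trajectories.

The kinase domain (P4) of a CheA dimer can swing between an "undipped" and a
"dipped" conformation through rotations about the P3-P4 and P4-P5 flexible
linkers.  This module defines the reaction coordinate and detection pipeline:

1. align every frame to a reference on a rigid subset (the P5 domains,
   residues 543-671);
2. PCA on the alpha carbons of the P4 domains (residues 352-542) of a
   dip-exhibiting dimer to obtain the dipping mode (PC1);
3. project trajectories onto PC1 and detect extended (>10 ns) dip events
   with a two-component-mixture threshold and hysteresis;
4. cluster conformations by pairwise RMSD with UPGMC (centroid) linkage and
   report state populations;
5. measure salt-bridge occupancy for the stabilizing contact pairs
   (dipped: R297/E397, E390/R379; undipped: D333/K390, D345/R379) and
   annotate dip events with whether the stabilizing contact formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError, NumericError, ValidationError

__all__ = [
    "DOMAIN_RANGES",
    "TM_TO_ECOLI",
    "Trajectory",
    "SelectionSpec",
    "PCAModel",
    "ProjectionSeries",
    "DipEvent",
    "RMSDMatrix",
    "ClusterResult",
    "ContactPair",
    "ContactSeries",
    "superpose",
    "align_trajectory",
    "fit_pca",
    "project",
    "detect_dips",
    "rmsd_matrix",
    "cluster_conformations",
    "contact_occupancy",
    "annotate_events",
]

#: CheA domain boundaries (T. maritima author numbering, inclusive).
DOMAIN_RANGES: dict[str, tuple[int, int]] = {
    "P3": (290, 351),
    "P4": (352, 542),
    "P5": (543, 671),
}

#: T. maritima -> E. coli residue correspondences for the contact pairs
#: (static homology table; not computed by alignment).
TM_TO_ECOLI: dict[str, str] = {
    "R297": "R265",
    "E397": "E368",
    "E390": "E361",
    "R379": "R394",
    "D333": "I304",
    "K390": "N405",
    "D345": "D316",
    "E387": "E402",
    "R389": "R404",
    "E351": "D363",
    "R403": "R415",
}


@dataclass
class Trajectory:
    """Time-resolved coordinates plus a per-atom table.

    coordinates : (n_frames, n_atoms, 3) Angstrom.
    atoms       : DataFrame with columns chain, resid, name, domain.
    frame_interval : ns between stored frames.
    """

    coordinates: np.ndarray
    atoms: pd.DataFrame
    frame_interval: float
    label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValidationError("coordinates must be (frames, atoms, 3)")
        if len(self.atoms) != self.coordinates.shape[1]:
            raise ValidationError("atom table does not match coordinate array")
        if not self.frame_interval > 0:
            raise ValidationError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def copy(self) -> "Trajectory":
        return Trajectory(
            self.coordinates.copy(), self.atoms.copy(), self.frame_interval, self.label
        )

    # -- I/O (MDAnalysis) ------------------------------------------------

    def write(self, topology_path, trajectory_path=None) -> None:
        """Write a PDB topology plus DCD trajectory (or multi-model PDB)."""
        import MDAnalysis as mda

        n = self.n_atoms
        u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                               trajectory=True)
        u.add_TopologyAttr("names", self.atoms["name"].to_numpy(dtype=object))
        u.add_TopologyAttr("resids", self.atoms["resid"].to_numpy(dtype=int))
        u.add_TopologyAttr(
            "chainIDs", self.atoms["chain"].to_numpy(dtype=object)
        )
        u.add_TopologyAttr(
            "segids", np.array(["SYS"], dtype=object)
        )
        u.atoms.positions = self.coordinates[0].astype(np.float32)
        u.atoms.write(str(topology_path))
        if trajectory_path is not None:
            with mda.Writer(str(trajectory_path), n) as w:
                for f in range(self.n_frames):
                    u.atoms.positions = self.coordinates[f].astype(np.float32)
                    w.write(u.atoms)

    @classmethod
    def read(
        cls,
        topology_path,
        trajectory_path=None,
        frame_interval: float = 1.0,
        domain_ranges: dict[str, tuple[int, int]] | None = None,
        receptor_chains: tuple[str, ...] = ("R", "S"),
    ) -> "Trajectory":
        """Load DCD + PDB topology (or a multi-model PDB alone).

        Domain tags are reattached from residue ranges (default: the CheA
        P3/P4/P5 boundaries); atoms on ``receptor_chains`` are tagged RCPT
        instead, since receptor residue numbers overlap the CheA ranges.
        ``frame_interval`` must be supplied because neither format stores it
        reliably.
        """
        import MDAnalysis as mda

        args = (str(topology_path),) if trajectory_path is None else (
            str(topology_path), str(trajectory_path))
        u = mda.Universe(*args)
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory])
        ranges = DOMAIN_RANGES if domain_ranges is None else domain_ranges

        def tag(resid: int) -> str:
            for dom, (lo, hi) in ranges.items():
                if lo <= resid <= hi:
                    return dom
            return ""

        try:
            chains = u.atoms.chainIDs
        except (mda.exceptions.NoDataError, AttributeError):
            chains = np.array([""] * len(u.atoms))
        atoms = pd.DataFrame(
            {
                "chain": chains,
                "resid": u.atoms.resids,
                "name": u.atoms.names,
                "domain": [
                    "RCPT" if c in receptor_chains else tag(r)
                    for c, r in zip(chains, u.atoms.resids)
                ],
            }
        )
        return cls(coords, atoms, frame_interval)


@dataclass
class SelectionSpec:
    """Atom selection by domain tag, chain, residue range and/or atom name.

    ``resid_range`` is inclusive on both ends (543-671 includes both).
    """

    domain: str | None = None
    chain: str | None = None
    resid_range: tuple[int, int] | None = None
    atom_name: str | None = None

    def resolve(self, atoms: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(atoms), dtype=bool)
        if self.domain is not None:
            mask &= (atoms["domain"] == self.domain).to_numpy()
        if self.chain is not None:
            mask &= (atoms["chain"] == self.chain).to_numpy()
        if self.resid_range is not None:
            lo, hi = self.resid_range
            r = atoms["resid"].to_numpy()
            mask &= (r >= lo) & (r <= hi)
        if self.atom_name is not None:
            mask &= (atoms["name"] == self.atom_name).to_numpy()
        return np.nonzero(mask)[0]


#: default alignment / PCA selections.  The P4 selection filters on the
#: domain tag as well: receptor anchor beads carry receptor residue numbers
#: (379, 390) that fall inside the P4 residue range.
P5_ALIGN = SelectionSpec(resid_range=DOMAIN_RANGES["P5"])
P4_CA = SelectionSpec(domain="P4", resid_range=DOMAIN_RANGES["P4"], atom_name="CA")


def _check_selection(idx: np.ndarray, minimum: int = 3) -> None:
    if len(idx) < minimum:
        raise ValidationError(f"selection resolves to {len(idx)} atoms (< {minimum})")


def superpose(
    mobile: np.ndarray, reference: np.ndarray, selection: np.ndarray | None = None
) -> tuple[Rotation, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) over a selection.

    Returns (rotation, translation, RMSD) such that
    ``rotation.apply(mobile) + translation`` minimizes the RMSD to the
    reference over the selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValidationError("mobile and reference shapes differ")
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    _check_selection(sel)
    m = mobile[sel]
    r = reference[sel]
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    m0, r0 = m - mc, r - rc
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2:
        raise NumericError("degenerate (collinear or coincident) selection")
    R, _ = Rotation.align_vectors(r0, m0)
    t = rc - R.apply(mc)
    rmsd = float(np.sqrt(np.mean(np.sum((R.apply(m) + t - r) ** 2, axis=1))))
    return R, t, rmsd


def align_trajectory(
    traj: Trajectory, reference: np.ndarray, selection: SelectionSpec | np.ndarray
) -> Trajectory:
    """Superpose every frame onto the reference using the alignment selection.

    The whole frame is transformed by the selection-optimal rigid transform
    (the canonical "align on P5, watch P4 move" workflow).
    """
    idx = (
        selection.resolve(traj.atoms)
        if isinstance(selection, SelectionSpec)
        else np.asarray(selection)
    )
    _check_selection(idx)
    # batched Kabsch over all frames
    mob = traj.coordinates[:, idx, :]  # (F, m, 3)
    ref = np.asarray(reference, dtype=float)[idx]
    mc = mob.mean(axis=1, keepdims=True)
    rc = ref.mean(axis=0)
    H = np.einsum("fmi,mj->fij", mob - mc, ref - rc)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("fij,fjk->fik", U, Vt))
    D = np.repeat(np.eye(3)[None], traj.n_frames, axis=0)
    D[:, 2, 2] = np.sign(det)
    # rotation acting on row vectors: x' = x @ Rm with Rm = U D Vt
    Rm = np.einsum("fij,fjk,fkl->fil", U, D, Vt)
    out = traj.copy()
    out.coordinates = (
        np.einsum("fmi,fij->fmj", traj.coordinates - mc, Rm) + rc
    )
    return out


@dataclass
class PCAModel:
    mean: np.ndarray  # (3m,) mean coordinates over the PCA selection
    components: np.ndarray  # (k, 3m) orthonormal rows, descending variance
    eigenvalues: np.ndarray  # (k,)
    fractional_variances: np.ndarray  # (n_total,) sums to 1
    selection_index: np.ndarray  # atom indices the model was fitted on

    def __post_init__(self) -> None:
        G = self.components @ self.components.T
        if not np.allclose(G, np.eye(len(self.components)), atol=1e-8):
            raise ValidationError("PCA components are not orthonormal")


def fit_pca(
    traj: Trajectory,
    selection: SelectionSpec | np.ndarray = P4_CA,
    n_components: int = 10,
) -> PCAModel:
    """PCA of the coordinate covariance over a selection of an aligned trajectory.

    Components are ordered by eigenvalue; each retained component's sign is
    oriented so that its projection distribution has non-negative skewness,
    which puts a minority (e.g. dipped) state on the positive side.
    """
    idx = (
        selection.resolve(traj.atoms)
        if isinstance(selection, SelectionSpec)
        else np.asarray(selection)
    )
    if len(idx) == 0:
        raise ValidationError("empty PCA selection")
    if traj.n_frames < 2:
        raise ValidationError("PCA requires at least two frames")
    X = traj.coordinates[:, idx, :].reshape(traj.n_frames, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD: eigenvalues of the covariance are s^2 / (F - 1)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (traj.n_frames - 1)
    total = eigvals.sum()
    frac = eigvals / total if total > 0 else np.zeros_like(eigvals)
    k = min(n_components, len(s))
    comps = Vt[:k].copy()
    for c in range(k):
        proj = Xc @ comps[c]
        if np.mean(proj**3) < 0:
            comps[c] = -comps[c]
    return PCAModel(
        mean=mean,
        components=comps,
        eigenvalues=eigvals[:k],
        fractional_variances=frac,
        selection_index=idx,
    )


@dataclass
class ProjectionSeries:
    time: np.ndarray  # ns
    value: np.ndarray  # Angstrom along the principal component
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape:
            raise ValidationError("time and value lengths differ")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.time, "value_A": self.value,
                             "label": self.label})


def project(
    traj: Trajectory, model: PCAModel, component: int = 1, label: str = ""
) -> ProjectionSeries:
    """Per-frame mean-centered projection onto a principal component (1-based)."""
    if not 1 <= component <= len(model.components):
        raise ValidationError(f"component {component} not in model")
    idx = model.selection_index
    if idx.max() >= traj.n_atoms:
        raise ValidationError("trajectory does not contain the model's atoms")
    X = traj.coordinates[:, idx, :].reshape(traj.n_frames, -1)
    if X.shape[1] != model.mean.shape[0]:
        raise ValidationError("selection size mismatch with PCA model")
    vals = (X - model.mean) @ model.components[component - 1]
    return ProjectionSeries(traj.times, vals, label or traj.label)


@dataclass
class DipEvent:
    start: float  # ns
    end: float  # ns
    duration: float  # ns
    peak_amplitude: float
    extended: bool
    stabilizing_contact_formed: bool | None = None

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValidationError("event end must be after start")


def fit_dip_threshold(
    values: np.ndarray, seed: int = 0, min_separation: float = 3.0
) -> tuple[float, float]:
    """Two-component Gaussian-mixture threshold and hysteresis half-width.

    Returns (threshold, hysteresis): the midpoint of the two component means
    and half the mean component standard deviation (a +-0.5 sigma band).
    If the fitted components are not separated by at least
    ``min_separation`` pooled sigmas the series is treated as unimodal
    (no dipped state visited) and a one-sided guard threshold of
    mean + 5 sigma is returned, so pure-noise series yield no events.
    """
    from sklearn.mixture import GaussianMixture

    v = np.asarray(values, dtype=float).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3).fit(v)
    means = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_.ravel())
    separation = abs(means[1] - means[0]) / max(sigmas.mean(), 1e-12)
    if separation < min_separation:
        return float(v.mean() + 5.0 * v.std()), float(0.5 * v.std())
    threshold = float(means.mean())
    hysteresis = float(0.5 * sigmas.mean())
    return threshold, hysteresis


def detect_dips(
    series: ProjectionSeries,
    threshold: float | None = None,
    min_duration: float = 10.0,
    hysteresis: float | None = None,
) -> list[DipEvent]:
    """Detect dip events as maximal runs on the dipped (positive) side.

    Frame states follow a Schmitt trigger: a frame enters the dipped state
    when the projection exceeds ``threshold + hysteresis`` and leaves it when
    the projection drops below ``threshold - hysteresis``.  Events lasting
    longer than ``min_duration`` ns (default 10) are flagged extended.  When
    no threshold is given, a two-component Gaussian mixture fitted to the
    series supplies threshold and hysteresis.
    """
    if len(series.value) == 0:
        raise ValidationError("empty projection series")
    if np.any(np.diff(series.time) <= 0):
        raise ValidationError("series time must be strictly increasing")
    if threshold is None:
        threshold, hyst = fit_dip_threshold(series.value)
        if hysteresis is None:
            hysteresis = hyst
    if hysteresis is None:
        hysteresis = 0.0
    v = series.value
    t = series.time
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    hi, lo = threshold + hysteresis, threshold - hysteresis
    state = bool(v[0] > threshold)
    states = np.empty(len(v), dtype=bool)
    for i, x in enumerate(v):
        if state and x < lo:
            state = False
        elif not state and x > hi:
            state = True
        states[i] = state

    events: list[DipEvent] = []
    i = 0
    n = len(v)
    while i < n:
        if states[i]:
            j = i
            while j + 1 < n and states[j + 1]:
                j += 1
            duration = (j - i + 1) * dt
            events.append(
                DipEvent(
                    start=float(t[i]),
                    end=float(t[i]) + duration,
                    duration=duration,
                    peak_amplitude=float(v[i : j + 1].max()),
                    extended=duration > min_duration,
                )
            )
            i = j + 1
        else:
            i += 1
    return events


@dataclass
class RMSDMatrix:
    matrix: np.ndarray
    frame_index: np.ndarray  # original frame indices
    subsample: int = 1
    labels: np.ndarray | None = None  # provenance (unit label per frame)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("RMSD matrix must be square")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValidationError("RMSD matrix must be symmetric")
        if np.any(np.abs(np.diag(m)) > 1e-9) or np.any(m < -1e-12):
            raise ValidationError("RMSD matrix must be non-negative, zero diagonal")


def rmsd_matrix(
    traj: Trajectory | np.ndarray,
    selection: SelectionSpec | np.ndarray | None = None,
    subsample: int = 1,
    labels: np.ndarray | None = None,
) -> RMSDMatrix:
    """Pairwise coordinate RMSD over a selection of pre-aligned frames.

    Frames are assumed aligned to a common reference (no per-pair
    re-superposition), so ``rmsd_ij = |X_i - X_j| / sqrt(m)`` is a Euclidean
    metric, as required for centroid-linkage clustering.
    """
    if isinstance(traj, Trajectory):
        coords = traj.coordinates
        atoms = traj.atoms
    else:
        coords = np.asarray(traj, dtype=float)
        atoms = None
    if selection is None:
        idx = np.arange(coords.shape[1])
    elif isinstance(selection, SelectionSpec):
        if atoms is None:
            raise ValidationError("SelectionSpec needs a Trajectory input")
        idx = selection.resolve(atoms)
    else:
        idx = np.asarray(selection)
    if len(idx) == 0:
        raise ValidationError("empty selection for rmsd_matrix")
    frame_index = np.arange(coords.shape[0])[::subsample]
    X = coords[frame_index][:, idx, :].reshape(len(frame_index), -1)
    sq = np.sum(X**2, axis=1)
    G = X @ X.T
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * G, 0.0)
    m = len(idx)
    mat = np.sqrt(d2 / m)
    mat = 0.5 * (mat + mat.T)
    np.fill_diagonal(mat, 0.0)
    sub_labels = None if labels is None else np.asarray(labels)[frame_index]
    return RMSDMatrix(mat, frame_index, subsample, sub_labels)


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-frame cluster ids, 0-based, ordered by population
    populations: np.ndarray  # descending fractions, sum to 1
    linkage_method: str
    cut: float | int
    linkage_matrix: np.ndarray

    def dendrogram_newick(self) -> str:
        """The merge dendrogram as a Newick string (leaves f<frame index>)."""
        tree = to_tree(self.linkage_matrix)

        def rec(node, parent_dist) -> str:
            if node.is_leaf():
                return f"f{node.id}:{max(parent_dist, 0.0):.6g}"
            length = max(parent_dist - node.dist, 0.0) if parent_dist is not None else 0.0
            inner = f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
            return f"{inner}:{length:.6g}" if parent_dist is not None else f"{inner};"

        return rec(tree, None)


def cluster_conformations(
    matrix: RMSDMatrix,
    method: str = "centroid",
    n_clusters: int | None = None,
    cut_height: float | None = None,
) -> ClusterResult:
    """Agglomerative clustering of conformations on the pairwise RMSD matrix.

    The default "centroid" linkage is UPGMC.  Exactly one of ``n_clusters``
    or ``cut_height`` selects the cut.  Cluster ids are relabelled by
    descending population (0 = most populated).
    """
    if (n_clusters is None) == (cut_height is None):
        raise ValidationError("give exactly one of n_clusters / cut_height")
    n = matrix.matrix.shape[0]
    if n_clusters is not None and not 1 <= n_clusters <= n:
        raise ValidationError(f"n_clusters must be in [1, {n}]")
    Z = linkage(squareform(matrix.matrix, checks=False), method=method)
    if n_clusters is not None:
        raw = fcluster(Z, t=n_clusters, criterion="maxclust")
        cut: float | int = n_clusters
    else:
        raw = fcluster(Z, t=cut_height, criterion="distance")
        cut = cut_height
    ids, counts = np.unique(raw, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    remap = {int(ids[o]): rank for rank, o in enumerate(order)}
    labels = np.array([remap[int(r)] for r in raw])
    populations = counts[order] / n
    return ClusterResult(labels, populations, method, cut, Z)


@dataclass
class ContactPair:
    """A candidate salt bridge between two residue atom sets."""

    a: SelectionSpec
    b: SelectionSpec
    cutoff: float = 4.5
    name: str = ""
    species_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValidationError("contact cutoff must be positive")


@dataclass
class ContactSeries:
    pair: ContactPair
    time: np.ndarray
    min_distance: np.ndarray
    bound: np.ndarray
    occupancy: float


def contact_occupancy(
    traj: Trajectory, pairs: list[ContactPair]
) -> list[ContactSeries]:
    """Per-frame minimum distance and bound fraction for each contact pair."""
    out = []
    for pair in pairs:
        ia = pair.a.resolve(traj.atoms)
        ib = pair.b.resolve(traj.atoms)
        if len(ia) == 0 or len(ib) == 0:
            raise ConfigurationError(
                f"contact pair {pair.name or pair} does not resolve "
                f"(A: {len(ia)} atoms, B: {len(ib)} atoms)"
            )
        A = traj.coordinates[:, ia, :]
        B = traj.coordinates[:, ib, :]
        d = np.linalg.norm(A[:, :, None, :] - B[:, None, :, :], axis=-1)
        mind = d.reshape(traj.n_frames, -1).min(axis=1)
        bound = mind <= pair.cutoff
        out.append(
            ContactSeries(
                pair=pair,
                time=traj.times,
                min_distance=mind,
                bound=bound,
                occupancy=float(bound.mean()),
            )
        )
    return out


def annotate_events(
    events: list[DipEvent],
    contact: ContactSeries,
    bound_fraction: float = 0.5,
) -> list[DipEvent]:
    """Set ``stabilizing_contact_formed`` on each event.

    An event carries the stabilizing contact when the pair is bound for at
    least ``bound_fraction`` of the event's frames.
    """
    out = []
    for ev in events:
        in_event = (contact.time >= ev.start - 1e-9) & (contact.time < ev.end - 1e-9)
        if not in_event.any():
            raise ValidationError(
                f"event [{ev.start}, {ev.end}) ns shares no frames with the "
                "contact series"
            )
        formed = bool(contact.bound[in_event].mean() >= bound_fraction)
        out.append(
            DipEvent(
                ev.start, ev.end, ev.duration, ev.peak_amplitude, ev.extended, formed
            )
        )
    return out
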