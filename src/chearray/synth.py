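"""Synthetic data generators with ground truth for every pipeline stage.

Everything the analysis modules consume can be generated here with known
truth: a labelled toy CheA-dimer/receptor bead model whose P4 domain switches
between an undipped and a dipped pose about the P3-P4 hinge (two-state Markov
dynamics with Gaussian thermal noise and state-linked contact formation),
half-map pairs with controlled isotropic or direction-attenuated noise for
FSC validation, multi-state conformational ensembles for clustering, and
rigid-fit ensembles concentrated around planted poses.

The toy dimer is schematic: one bead per residue with the real CheA domain
boundaries (P3 290-351, P4 352-542, P5 543-671, two chains) and contact-proxy
beads for the stabilizing salt bridges, but no physical force field and no
claim about real T. maritima geometry beyond labelled topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ValidationError
from .maps import DensityMap, simulate_map
from .docking import RigidFit, Template
from .switch import (
    DOMAIN_RANGES,
    ContactPair,
    DipEvent,
    SelectionSpec,
    Trajectory,
)

__all__ = [
    "ToyDimerModel",
    "SwitchingParams",
    "SwitchingTruth",
    "HalfMapTruth",
    "FitEnsembleTruth",
    "EnsembleTruth",
    "make_toy_dimer",
    "generate_switching_trajectory",
    "generate_state_ensemble",
    "generate_half_maps",
    "generate_fit_ensemble",
    "toy_contact_pairs",
]


def _blob(n: int, center, radii, phase: float = 0.0) -> np.ndarray:
    """Deterministic quasi-uniform bead cloud (Fibonacci spiral shells)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - 2.0 * (i + 0.5) / n
    r_xy = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    theta = 2.0 * np.pi * i / golden + phase
    pts = np.stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z], axis=1)
    # fill the volume, not just the surface
    shell = ((i * 7919) % 97 / 97.0) ** (1.0 / 3.0)
    pts *= shell[:, None]
    return pts * np.asarray(radii, dtype=float) + np.asarray(center, dtype=float)


@dataclass
class ToyDimerModel:
    """Labelled bead model of a CheA dimer plus receptor anchor beads.

    ``coords`` are the undipped reference positions.  The dip of chain A's
    P4 domain is a rotation of ``dip_angle`` degrees about the P3-P4 hinge
    (``hinge_point``, ``hinge_axis``) combined with a rigid shift of the
    lower P3 bundle (residues >= 320) that breaks the undipped P3/receptor
    contacts.  ``mutant`` marks an R297A-like model whose 297 proxy bead is
    displaced so the dipped-state R297/E397 contact cannot form.
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    hinge_point: np.ndarray
    hinge_axis: np.ndarray
    p3_shift: np.ndarray
    mutant: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.hinge_axis = np.asarray(self.hinge_axis, dtype=float)
        self.hinge_axis = self.hinge_axis / np.linalg.norm(self.hinge_axis)

    def index_of(self, chain: str, resid: int) -> int:
        m = (self.atoms["chain"] == chain) & (self.atoms["resid"] == resid)
        idx = np.nonzero(m.to_numpy())[0]
        if len(idx) != 1:
            raise ValidationError(f"bead {chain}:{resid} not unique in model")
        return int(idx[0])

    @property
    def dip_mask(self) -> np.ndarray:
        """Beads moved by the dip: chain A P4 plus the lower P3 bundle."""
        a = self.atoms
        p4 = ((a["chain"] == "A") & (a["domain"] == "P4")).to_numpy()
        return p4

    @property
    def p3_mobile_mask(self) -> np.ndarray:
        a = self.atoms
        return (
            (a["chain"] == "A") & (a["domain"] == "P3") & (a["resid"] >= 320)
        ).to_numpy()

    def dip_rotation(self, dip_angle: float) -> Rotation:
        return Rotation.from_rotvec(np.deg2rad(dip_angle) * self.hinge_axis)

    def dipped_coords(self, dip_angle: float) -> np.ndarray:
        """Reference coordinates with chain A's P4 dipped by ``dip_angle`` deg."""
        out = self.coords.copy()
        R = self.dip_rotation(dip_angle)
        m = self.dip_mask
        out[m] = R.apply(out[m] - self.hinge_point) + self.hinge_point
        out[self.p3_mobile_mask] += self.p3_shift
        return out

    def p4_template(self) -> Template:
        """Chain A's P4 beads (undipped) as a rigid docking template."""
        sel = ((self.atoms["chain"] == "A") & (self.atoms["domain"] == "P4")).to_numpy()
        idx = np.nonzero(sel)[0]
        coords = self.coords[idx]
        resids = self.atoms["resid"].to_numpy()[idx]
        labels = {
            "N": int(np.nonzero(resids == DOMAIN_RANGES["P4"][0])[0][0]),
            "C": int(np.nonzero(resids == DOMAIN_RANGES["P4"][1])[0][0]),
        }
        return Template(coords=coords, labels=labels)


_DIP_ANGLE_DEFAULT = 25.0


def make_toy_dimer(
    dip_angle: float = _DIP_ANGLE_DEFAULT,
    contact_gap: float = 2.5,
    mutant: bool = False,
) -> ToyDimerModel:
    """Build the deterministic toy CheA dimer with receptor anchor beads.

    One bead per residue on two chains A/B (P3 290-351, P4 352-542,
    P5 543-671); chain A's P4 is a mirror-asymmetric two-lobe cluster so its
    docking orientation is identifiable.  Receptor anchor beads:

    * chain R (adjacent receptor): K390 and R379 proxies sit ``contact_gap``
      Angstrom from the undipped positions of the P3 beads D333 and D345 -
      the undipped contacts, broken when the lower P3 bundle shifts;
    * chain S (receptor tip): an R379 proxy sits ``contact_gap`` Angstrom
      from the *dipped* position of the P4 bead E390, so the E390/R379
      bridge can only form in the dipped pose.

    The P3 bead R297 is placed near the dipped position of the P4 bead E397
    (the dipped-state P3/P4 bridge); ``mutant=True`` (R297A-like) displaces
    it so that bridge cannot form.
    """
    rows: list[dict] = []
    coords: list[np.ndarray] = []

    def add(chain: str, resid: int, domain: str, xyz) -> None:
        rows.append({"chain": chain, "resid": resid, "name": "CA", "domain": domain})
        coords.append(np.asarray(xyz, dtype=float))

    # --- P3 dimerization bundle: two strands along z near the center ----
    lo3, hi3 = DOMAIN_RANGES["P3"]
    n3 = hi3 - lo3 + 1
    for k, resid in enumerate(range(lo3, hi3 + 1)):
        t = k / (n3 - 1)
        z = 45.0 - 37.0 * t  # 45 -> 8 A
        wob = 1.2 * np.sin(2.0 * np.pi * 3.0 * t)
        add("A", resid, "P3", (-2.5, wob, z))
    # --- P4 kinase domain, chain A: asymmetric two-lobe cluster ---------
    lo4, hi4 = DOMAIN_RANGES["P4"]
    # three well-separated sub-lobes in a chiral tripod: the docking
    # orientation is identifiable even at ~8 A simulated resolution
    lobe1 = _blob(120, center=(-18.0, 0.0, 22.0), radii=(6.0, 4.5, 5.0))
    lobe2 = _blob(47, center=(-7.0, 6.0, 14.0), radii=(3.5, 3.0, 3.5), phase=1.3)
    lobe3 = _blob(24, center=(-10.0, -6.0, 28.0), radii=(3.0, 3.0, 3.0), phase=2.1)
    p4_pts = np.vstack([lobe1, lobe2, lobe3])
    for k, resid in enumerate(range(lo4, hi4 + 1)):
        add("A", resid, "P4", p4_pts[k])
    # --- P5 regulatory domain, chain A ----------------------------------
    lo5, hi5 = DOMAIN_RANGES["P5"]
    p5_pts = _blob(hi5 - lo5 + 1, center=(-27.0, 0.0, 45.0), radii=(8.0, 6.0, 5.0),
                   phase=0.7)
    for k, resid in enumerate(range(lo5, hi5 + 1)):
        add("A", resid, "P5", p5_pts[k])
    # --- chain B: chain A mirrored in x ----------------------------------
    nA = len(coords)
    for row, xyz in list(zip(rows[:nA], coords[:nA])):
        add("B", row["resid"], row["domain"], xyz * np.array([-1.0, 1.0, 1.0]))

    atoms = pd.DataFrame(rows)
    X = np.array(coords)

    hinge_point = np.array([-3.0, 0.0, 10.0])
    hinge_axis = np.array([0.0, -1.0, 0.0])  # positive dip swings P4-A downward
    p3_shift = np.array([5.0, 0.0, 0.0])
    R_dip = Rotation.from_rotvec(np.deg2rad(dip_angle) * hinge_axis)

    def a_idx(resid: int) -> int:
        return int(
            np.nonzero(((atoms["chain"] == "A") & (atoms["resid"] == resid)).to_numpy())[0][0]
        )

    # long-lever overrides for the dipped-contact beads (far from the hinge
    # so the dip moves them by ~10 A, well beyond the 4.5 A contact cutoff)
    X[a_idx(397)] = np.array([-26.0, 2.0, 18.0])
    X[a_idx(390)] = np.array([-24.0, -2.0, 15.0])
    e397_dipped = R_dip.apply(X[a_idx(397)] - hinge_point) + hinge_point
    e390_dipped = R_dip.apply(X[a_idx(390)] - hinge_point) + hinge_point

    # R297 (P3, static): near the dipped E397 position
    r297 = e397_dipped + np.array([0.0, contact_gap, 0.0])
    if mutant:
        r297 = r297 + np.array([0.0, 8.0, 6.0])  # side chain removed: no bridge
    X[a_idx(297)] = r297

    # receptor anchor beads
    extra_rows = [
        # adjacent receptor (undipped partners of the P3 bundle)
        {"chain": "R", "resid": 390, "name": "CA", "domain": "RCPT"},
        {"chain": "R", "resid": 379, "name": "CA", "domain": "RCPT"},
        # receptor tip (dipped partner of P4 E390)
        {"chain": "S", "resid": 379, "name": "CA", "domain": "RCPT"},
    ]
    extra_coords = np.array(
        [
            X[a_idx(333)] + np.array([0.0, contact_gap, 0.0]),
            X[a_idx(345)] + np.array([0.0, -contact_gap, 0.0]),
            e390_dipped + np.array([0.0, -contact_gap, 0.0]),
        ]
    )
    atoms = pd.concat([atoms, pd.DataFrame(extra_rows)], ignore_index=True)
    X = np.vstack([X, extra_coords])

    return ToyDimerModel(
        coords=X,
        atoms=atoms,
        hinge_point=hinge_point,
        hinge_axis=hinge_axis,
        p3_shift=p3_shift,
        mutant=mutant,
    )


def toy_contact_pairs(cutoff: float = 4.5) -> dict[str, ContactPair]:
    """The stabilizing / broken salt-bridge proxies of the toy model."""

    def bead(chain: str, resid: int) -> SelectionSpec:
        return SelectionSpec(chain=chain, resid_range=(resid, resid))

    return {
        "R297/E397": ContactPair(
            bead("A", 297), bead("A", 397), cutoff, name="R297/E397",
            species_tags={"T.maritima": "R297/E397", "E.coli": "R265/E368"},
        ),
        "E390/R379": ContactPair(
            bead("A", 390), bead("S", 379), cutoff, name="E390/R379",
            species_tags={"T.maritima": "E390/R379", "E.coli": "E361/R394"},
        ),
        "D333/K390": ContactPair(
            bead("A", 333), bead("R", 390), cutoff, name="D333/K390",
            species_tags={"T.maritima": "D333/K390", "E.coli": "I304/N405"},
        ),
        "D345/R379": ContactPair(
            bead("A", 345), bead("R", 379), cutoff, name="D345/R379",
            species_tags={"T.maritima": "D345/R379", "E.coli": "D316/R394"},
        ),
    }


@dataclass(frozen=True)
class SwitchingParams:
    """Two-state Markov hinge-switching parameters.

    Rates are per ns; per-frame transition probabilities are
    ``1 - exp(-k * dt)``.  ``mutant`` multiplies the undip rate by
    ``mutant_undip_factor`` (the R297A-like destabilized dipped state) and
    disables formation of the R297/E397 proxy contact.
    """

    k_dip: float = 0.02
    k_undip: float = 0.05
    dip_angle: float = _DIP_ANGLE_DEFAULT
    noise_sigma: float = 0.5
    frame_interval: float = 0.02
    n_frames: int = 10_000
    seed: int = 0
    mutant: bool = False
    mutant_undip_factor: float = 5.0
    drift_sigma: float = 0.0
    start_dipped: bool = False

    def __post_init__(self) -> None:
        if self.k_dip < 0 or self.k_undip < 0:
            raise ValidationError("rates must be non-negative")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be positive")


@dataclass
class SwitchingTruth:
    states: np.ndarray  # bool per frame, True = dipped
    events: list[DipEvent]  # maximal dipped runs with extended flags
    contact_intervals: list[tuple[float, float]]  # ns, R297/E397 formed
    stationary_dipped: float
    params: SwitchingParams
    drift: np.ndarray | None = None


def _events_from_states(
    states: np.ndarray, dt: float, min_duration: float = 10.0
) -> list[DipEvent]:
    events = []
    i, n = 0, len(states)
    while i < n:
        if states[i]:
            j = i
            while j + 1 < n and states[j + 1]:
                j += 1
            dur = (j - i + 1) * dt
            events.append(
                DipEvent(
                    start=i * dt,
                    end=i * dt + dur,
                    duration=dur,
                    peak_amplitude=float("nan"),
                    extended=dur > min_duration,
                )
            )
            i = j + 1
        else:
            i += 1
    return events


def generate_switching_trajectory(
    model: ToyDimerModel, params: SwitchingParams
) -> tuple[Trajectory, SwitchingTruth]:
    """Simulate the two-state Markov dipping dynamics of the toy dimer.

    Dipped frames carry chain A's P4 rotated by ``dip_angle`` about the
    P3-P4 hinge and the lower P3 bundle shifted (undipped contacts broken,
    dipped proxies formed unless the model is mutant); all beads receive
    i.i.d. Gaussian noise of ``noise_sigma`` Angstrom, plus an optional
    rigid random-walk drift shared by all beads.
    """
    if model.mutant != params.mutant:
        model = make_toy_dimer(dip_angle=params.dip_angle, mutant=params.mutant)
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval
    k_undip = params.k_undip * (params.mutant_undip_factor if params.mutant else 1.0)
    p_dip = 1.0 - np.exp(-params.k_dip * dt)
    p_undip = 1.0 - np.exp(-k_undip * dt)

    n = params.n_frames
    states = np.empty(n, dtype=bool)
    s = params.start_dipped
    u = rng.random(n)
    for i in range(n):
        if s:
            if u[i] < p_undip:
                s = False
        else:
            if u[i] < p_dip:
                s = True
        states[i] = s

    undipped = model.coords
    dipped = model.dipped_coords(params.dip_angle)
    coords = np.where(states[:, None, None], dipped[None], undipped[None]).astype(float)
    if params.noise_sigma > 0:
        coords += rng.normal(0.0, params.noise_sigma, size=coords.shape)
    drift = None
    if params.drift_sigma > 0:
        drift = np.cumsum(rng.normal(0.0, params.drift_sigma, size=(n, 3)), axis=0)
        coords += drift[:, None, :]

    traj = Trajectory(
        coords, model.atoms.copy(), dt,
        label="mutant" if params.mutant else "wt",
    )
    events = _events_from_states(states, dt)
    contacts = (
        [] if params.mutant else [(e.start, e.end) for e in events]
    )
    k_tot = params.k_dip + k_undip
    truth = SwitchingTruth(
        states=states,
        events=events,
        contact_intervals=contacts,
        stationary_dipped=params.k_dip / k_tot if k_tot > 0 else 0.0,
        params=params,
        drift=drift,
    )
    return traj, truth


@dataclass
class EnsembleTruth:
    labels: np.ndarray  # planted state per frame (0-based)
    populations: np.ndarray
    state_angles: np.ndarray


def generate_state_ensemble(
    model: ToyDimerModel,
    populations: tuple[float, ...] = (0.80, 0.10, 0.08, 0.02),
    state_angles: tuple[float, ...] | None = None,
    n_frames: int = 2_000,
    noise_sigma: float = 0.3,
    frame_interval: float = 0.02,
    seed: int = 0,
) -> tuple[Trajectory, EnsembleTruth]:
    """Draw frames i.i.d. from a multi-state conformational mixture.

    State 0 is undipped, state 1 fully dipped, further states interpolate the
    hinge angle (intermediates).  Intra-state spread (``noise_sigma``) is far
    below the inter-state separation at the defaults, the regime in which
    centroid-linkage clustering must recover the planted populations.
    """
    populations_arr = np.asarray(populations, dtype=float)
    if abs(populations_arr.sum() - 1.0) > 1e-9 or np.any(populations_arr < 0):
        raise ValidationError("populations must be non-negative and sum to 1")
    k = len(populations_arr)
    if state_angles is None:
        if k == 1:
            angles = np.array([0.0])
        else:
            # 0, full dip, then evenly spaced intermediates
            inter = np.linspace(0.0, _DIP_ANGLE_DEFAULT, k)[1:-1]
            angles = np.concatenate([[0.0, _DIP_ANGLE_DEFAULT], inter])
    else:
        angles = np.asarray(state_angles, dtype=float)
        if len(angles) != k:
            raise ValidationError("state_angles length must match populations")
    rng = np.random.default_rng(seed)
    labels = rng.choice(k, size=n_frames, p=populations_arr)
    conformers = np.stack(
        [model.coords if a == 0 else model.dipped_coords(a) for a in angles]
    )
    coords = conformers[labels]
    if noise_sigma > 0:
        coords = coords + rng.normal(0.0, noise_sigma, size=coords.shape)
    traj = Trajectory(coords, model.atoms.copy(), frame_interval, label="ensemble")
    return traj, EnsembleTruth(labels, populations_arr, angles)


@dataclass
class HalfMapTruth:
    reference: DensityMap  # noise-free signal
    snr: float
    noise_mode: str
    anisotropy: tuple[np.ndarray, float] | None  # (axis, amplitude factor)


def _shell_ids(shape, voxel_size):
    from .maps import _shell_indices

    shell, dk, nyq, kmag = _shell_indices(shape, voxel_size)
    return shell, kmag


def generate_half_maps(
    coords: np.ndarray,
    resolution: float = 10.0,
    snr: float = 1.0,
    voxel_size: float = 2.0,
    padding: float = 12.0,
    noise_mode: str = "shell",
    anisotropy: tuple[np.ndarray, float] | None = None,
    half_angle: float = 42.0,
    seed: int = 0,
    grid: DensityMap | None = None,
) -> tuple[DensityMap, DensityMap, HalfMapTruth]:
    """Half-map pair: shared noise-free signal plus independent noise.

    ``noise_mode='shell'`` shapes each half's Fourier noise power to
    ``signal shell power / snr`` (constant per-shell SNR, so the expected
    FSC is snr/(snr+1) in every signal-bearing shell); ``'white'`` adds flat
    Gaussian noise with real-space variance ``var(signal)/snr`` (per-shell
    SNR then decays with frequency like the kernel envelope, giving
    realistic falling FSC curves).  ``anisotropy=(axis, factor)`` multiplies
    the noiseless signal amplitudes of BOTH halves by ``factor`` inside the
    double cone of ``half_angle`` degrees about the axis, degrading the
    directional SNR and hence the conical resolution along that axis.
    ``snr=inf`` returns two identical noise-free halves.
    """
    if not snr > 0:
        raise ValidationError("snr must be positive (may be inf)")
    signal = simulate_map(coords, resolution=resolution, voxel_size=voxel_size,
                          padding=padding, grid=grid)
    F = np.fft.fftn(signal.values.astype(np.float64))
    if anisotropy is not None:
        axis = np.asarray(anisotropy[0], dtype=float)
        axis = axis / np.linalg.norm(axis)
        factor = float(anisotropy[1])
        shell, kmag = _shell_ids(signal.dims, voxel_size)
        from .maps import _freq_grids

        gx, gy, gz = _freq_grids(signal.dims, voxel_size)
        with np.errstate(invalid="ignore", divide="ignore"):
            inv = np.where(kmag > 0, 1.0 / np.where(kmag > 0, kmag, 1.0), 0.0)
        cosang = np.abs(gx * axis[0] + gy * axis[1] + gz * axis[2]) * inv
        cone = cosang >= np.cos(np.deg2rad(half_angle))
        F = np.where(cone, F * factor, F)
    clean = np.fft.ifftn(F).real
    ref = DensityMap(clean, voxel_size, signal.origin.copy())
    if np.isinf(snr):
        return ref.copy(), ref.copy(), HalfMapTruth(ref, snr, noise_mode, anisotropy)

    rng = np.random.default_rng(seed)
    halves = []
    if noise_mode == "shell":
        shell, _ = _shell_ids(signal.dims, voxel_size)
        n_shells = shell.max() + 1
        psig = np.bincount(
            shell.ravel(), weights=(np.abs(F) ** 2).ravel(), minlength=n_shells
        ) / np.bincount(shell.ravel(), minlength=n_shells)
        nvox = clean.size
        amp = np.sqrt(psig[shell] / (snr * nvox))
        for _ in range(2):
            W = np.fft.fftn(rng.normal(size=clean.shape))
            noise = np.fft.ifftn(W * amp).real
            halves.append(DensityMap(clean + noise, voxel_size, signal.origin.copy()))
    elif noise_mode == "white":
        sigma_n = np.sqrt(np.var(clean) / snr)
        for _ in range(2):
            noise = rng.normal(0.0, sigma_n, size=clean.shape)
            halves.append(DensityMap(clean + noise, voxel_size, signal.origin.copy()))
    else:
        raise ValidationError(f"unknown noise_mode {noise_mode!r}")
    return halves[0], halves[1], HalfMapTruth(ref, snr, noise_mode, anisotropy)


@dataclass
class FitEnsembleTruth:
    poses: list[tuple[np.ndarray, np.ndarray]]  # planted (quat, translation)
    weights: np.ndarray
    labels: np.ndarray  # planted component per fit


def generate_fit_ensemble(
    poses: list[tuple[np.ndarray, np.ndarray]],
    weights: np.ndarray | list[float],
    n: int = 1000,
    angle_jitter: float = 1.0,
    shift_jitter: float = 1.0,
    seed: int = 0,
) -> tuple[list[RigidFit], FitEnsembleTruth]:
    """Draw rigid fits from a mixture of planted poses with Gaussian jitter.

    Jitter magnitudes are half-normal: the rotation offset angle is
    ``|N(0, angle_jitter)|`` degrees about a uniformly random axis and the
    shift offset is ``|N(0, shift_jitter)|`` Angstrom along a uniformly
    random direction, so the sigmas bound the total pose displacement
    directly.  Scores decrease with distance from the planted pose, so
    score-ordered clustering visits near-planted fits first.
    """
    weights_arr = np.asarray(weights, dtype=float)
    if abs(weights_arr.sum() - 1.0) > 1e-9:
        raise ValidationError("pose weights must sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(poses), size=n, p=weights_arr)
    fits = []
    for lab in labels:
        q0, t0 = poses[lab]
        R0 = Rotation.from_quat(np.asarray(q0, dtype=float))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang_off = abs(rng.normal(0.0, angle_jitter))
        R = Rotation.from_rotvec(np.deg2rad(ang_off) * axis) * R0
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        shift_off = abs(rng.normal(0.0, shift_jitter))
        t = np.asarray(t0, dtype=float) + shift_off * direction
        score = float(np.clip(1.0 - ang_off / 90.0 - shift_off / 60.0, -1.0, 1.0))
        fits.append(RigidFit(R.as_quat(), t, score, converged=True))
    return fits, FitEnsembleTruth(
        poses=[(np.asarray(q), np.asarray(t)) for q, t in poses],
        weights=weights_arr,
        labels=labels,
    )
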