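"""Structural statistics over MD trajectories.

Implements the analyses used to compare protein conformational dynamics at
different temperatures and solvent compositions: RMSD after optimal (Kabsch)
superposition, radius of gyration, Shrake-Rupley solvent-accessible surface
area, per-residue RMSF and its temperature difference dRMSF, profile
correlation, the minimum-distance distribution function (MDDF) of a cosolvent
around a solute selection, and per-residue cosolvent density maps.

Coordinates are in angstroms; residue ids are 1-based (PDB convention).
Distances in a cubic periodic box use the minimum-image convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Mobile-loop residue ranges of the luciferase alpha-subunit (inclusive)
MOBILE_LOOP = {"V.harveyi": (262, 291), "P.leiognathi": (261, 290)}

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class Structure:
    """Labelled atomic reference coordinates.

    Per-atom records: name, element, residue id, residue name, chain id,
    coordinates (angstrom), mass (Da), van der Waals radius (angstrom).
    """

    name: np.ndarray
    element: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    coords: np.ndarray
    mass: np.ndarray
    radius: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError("structure needs at least one atom")
        for attr in ("name", "element", "res_id", "res_name", "chain_id", "mass", "radius"):
            arr = np.asarray(getattr(self, attr))
            if arr.shape[0] != n:
                raise ValueError(f"{attr} length does not match coordinates")
            setattr(self, attr, arr)
        if np.any(self.radius <= 0):
            raise ValueError("van der Waals radii must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def selection_mask(self, selection: str) -> np.ndarray:
        """Boolean atom mask for 'all', 'backbone', 'CA' or an atom name."""
        if selection == "all":
            return np.ones(self.n_atoms, dtype=bool)
        if selection == "backbone":
            return np.isin(self.name, BACKBONE_NAMES)
        return self.name == selection


@dataclass
class FluctuationProfile:
    """Per-residue RMSF (or dRMSF) values."""

    residue_ids: np.ndarray
    rmsf: np.ndarray
    selection: str = "CA"
    label: str | None = None


@dataclass
class MDDFProfile:
    """Minimum-distance distribution of a cosolvent around a solute."""

    r: np.ndarray  # bin centers, angstrom
    mddf: np.ndarray  # normalized; -> 1 for uniform cosolvent at large r
    counts: np.ndarray  # raw minimum-distance counts per bin (all frames)


@dataclass
class Trajectory:
    """Frames of coordinates over a reference :class:`Structure`.

    ``cosolvent`` holds per-frame cosolvent atom coordinates of shape
    (n_frames, n_cos_atoms, 3); ``cosolvent_mol`` assigns each cosolvent atom
    to a molecule (point-particle cosolvents have one atom per molecule).
    ``box`` is the cubic box edge in angstrom (None = non-periodic).
    """

    reference: Structure
    frames: np.ndarray
    frame_times: np.ndarray | None = None
    cosolvent: np.ndarray | None = None
    cosolvent_mol: np.ndarray | None = None
    box: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.reference.n_atoms, 3):
            raise ValueError("frames must be (n_frames, n_atoms, 3) congruent with reference")
        if self.cosolvent is not None:
            self.cosolvent = np.asarray(self.cosolvent, dtype=float)
            if self.cosolvent.ndim != 3 or self.cosolvent.shape[0] != self.n_frames:
                raise ValueError("cosolvent must be (n_frames, n_cos_atoms, 3)")
            if self.cosolvent_mol is None:
                self.cosolvent_mol = np.arange(self.cosolvent.shape[1])
            self.cosolvent_mol = np.asarray(self.cosolvent_mol)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# superposition


def kabsch_superpose(
    moving: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t minimizing weighted RMSD.

    Applying ``x @ R.T + t`` to ``moving`` best superposes it on ``target``.
    The reflection branch of the SVD solution is corrected so det(R) = +1.
    Raises on degenerate (collinear or coincident) point sets.
    """
    moving = np.asarray(moving, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if moving.shape != target.shape or moving.shape[0] < 3:
        raise ValueError("need congruent sets of at least 3 points")
    if weights is None:
        w = np.ones(moving.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()

    mc = (w[:, None] * moving).sum(axis=0)
    tc = (w[:, None] * target).sum(axis=0)
    a = moving - mc
    b = target - tc
    h = (w[:, None] * a).T @ b
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate point set: collinear or coincident points")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tc - rot @ mc
    moved = a @ rot.T
    rmsd = float(np.sqrt((w[:, None] * (moved - b) ** 2).sum()))
    return rot, trans, rmsd


def rmsd_series(traj: Trajectory, selection: str = "backbone") -> np.ndarray:
    """Per-frame RMSD (angstrom) after superposing each frame on the reference.

    Superposition and RMSD are both evaluated on the selection, as is standard
    for backbone-RMSD stability monitoring.
    """
    mask = traj.reference.selection_mask(selection)
    if not mask.any():
        raise ValueError(f"selection {selection!r} matches no atoms")
    ref = traj.reference.coords[mask]
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        _, _, out[i] = kabsch_superpose(frame[mask], ref)
    return out


def tail_mean(values: np.ndarray, frac: float = 0.1) -> float:
    """Mean over the trailing ``frac`` of a series (the equilibrated tail)."""
    values = np.asarray(values, dtype=float)
    n = max(int(round(frac * values.size)), 1)
    return float(values[-n:].mean())


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted RMS distance from the center of mass (angstrom)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (masses[:, None] * coords).sum(axis=0) / total
    return float(np.sqrt((masses * ((coords - com) ** 2).sum(axis=1)).sum() / total))


# ---------------------------------------------------------------------------
# solvent-accessible surface area


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 256,
    coords: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom's accessible sphere of radius r_i + probe is sampled with a
    deterministic Fibonacci point lattice; test points buried inside any
    neighbour's inflated sphere are discarded.  Returns (total, per-atom)
    areas in angstrom^2; the per-atom values sum exactly to the total.
    """
    if n_points < 32:
        raise ValueError("n_points < 32 is below the accuracy floor")
    xyz = structure.coords if coords is None else np.asarray(coords, float).reshape(-1, 3)
    radii = structure.radius + probe
    n = xyz.shape[0]
    sphere = _fibonacci_sphere(n_points)
    per_atom = np.empty(n)
    d2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=-1)
    for i in range(n):
        pts = xyz[i] + radii[i] * sphere
        cutoff2 = (radii[i] + radii) ** 2
        neighbours = np.nonzero((d2[i] < cutoff2) & (np.arange(n) != i))[0]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbours:
            exposed &= ((pts - xyz[j]) ** 2).sum(axis=1) > radii[j] ** 2
        per_atom[i] = exposed.mean() * 4.0 * np.pi * radii[i] ** 2
    return float(per_atom.sum()), per_atom


# ---------------------------------------------------------------------------
# fluctuations


def rmsf(traj: Trajectory, selection: str = "CA") -> FluctuationProfile:
    """Per-residue RMSF about the mean structure.

    Frames are superposed on the running mean structure in two passes (the
    first pass aligns on the reference), which removes rigid-body drift
    before the fluctuation statistics are taken.  The second pass weights
    each atom by the inverse variance estimated in the first pass, so highly
    mobile atoms do not drag the fit and leak their fluctuation into rigid
    ones.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for fluctuation statistics")
    mask = traj.reference.selection_mask(selection)
    if not mask.any():
        raise ValueError(f"selection {selection!r} matches no atoms")
    sel = [frame[mask] for frame in traj.frames]
    target = traj.reference.coords[mask]
    weights = None
    for _ in range(2):
        aligned = []
        for x in sel:
            rot, trans, _ = kabsch_superpose(x, target, weights=weights)
            aligned.append(x @ rot.T + trans)
        stack = np.asarray(aligned)
        target = stack.mean(axis=0)
        fluct = np.sqrt(((stack - target) ** 2).sum(axis=-1).mean(axis=0))
        var = fluct**2
        weights = 1.0 / (var + 0.05 * var.mean() + 1e-12)
    return FluctuationProfile(
        residue_ids=traj.reference.res_id[mask].astype(int),
        rmsf=fluct,
        selection=selection,
    )


def delta_rmsf(p_t: FluctuationProfile, p_ref: FluctuationProfile) -> FluctuationProfile:
    """Flexibility change dRMSF = RMSF_T - RMSF_ref, elementwise per residue.

    Positive values mark segments more flexible than in the reference
    condition; negative values mark rigidified segments.
    """
    if not np.array_equal(p_t.residue_ids, p_ref.residue_ids):
        raise ValueError("profiles cover different residues")
    return FluctuationProfile(
        residue_ids=p_t.residue_ids.copy(),
        rmsf=p_t.rmsf - p_ref.rmsf,
        selection=p_t.selection,
        label="delta",
    )


def profile_correlation(
    p: FluctuationProfile,
    q: FluctuationProfile,
    window: tuple[int, int] | None = None,
) -> float:
    """Pearson correlation of two per-residue profiles over a residue window.

    ``window`` is an inclusive (first_res, last_res) id range applied to each
    profile independently, so profiles of homologous proteins with offset
    numbering can be compared position-by-position.
    """
    from scipy.stats import pearsonr

    a, b = p.rmsf, q.rmsf
    if window is not None:
        a = p.rmsf[(p.residue_ids >= window[0]) & (p.residue_ids <= window[1])]
        b = q.rmsf[(q.residue_ids >= window[0]) & (q.residue_ids <= window[1])]
    if a.size != b.size:
        raise ValueError("windows select unequal numbers of residues")
    if a.size < 3:
        raise ValueError("need at least 3 residues for a correlation")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a profile window")
    return float(pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# cosolvent solvation statistics


def _min_image(diff: np.ndarray, box: float | None) -> np.ndarray:
    if box is not None:
        diff = diff - box * np.round(diff / box)
    return diff


def _min_mol_distances(
    cos_xyz: np.ndarray,
    mol_ids: np.ndarray,
    solute_xyz: np.ndarray,
    box: float | None,
) -> np.ndarray:
    """Minimum atom-pair distance of each cosolvent molecule to the solute."""
    diff = _min_image(cos_xyz[:, None, :] - solute_xyz[None, :, :], box)
    d_atom = np.sqrt((diff**2).sum(axis=-1)).min(axis=1)
    order = np.argsort(mol_ids, kind="stable")
    sorted_ids = mol_ids[order]
    starts = np.nonzero(np.r_[True, sorted_ids[1:] != sorted_ids[:-1]])[0]
    return np.minimum.reduceat(d_atom[order], starts)


def mddf(
    traj: Trajectory,
    solute_selection: str = "all",
    bin_width: float = 0.1,
    r_max: float = 10.0,
    oversample: int = 10,
    seed: int = 0,
) -> MDDFProfile:
    """Minimum-distance distribution function of the cosolvent.

    For every frame and cosolvent molecule the minimum atom-pair distance to
    the solute selection is histogrammed; bins are normalized by the expected
    count for the same number of molecules placed uniformly in the box,
    estimated by seeded random insertion with ``oversample``-fold
    oversampling.  A uniformly distributed cosolvent therefore gives 1.
    """
    if traj.cosolvent is None or traj.cosolvent.shape[1] == 0:
        raise ValueError("trajectory carries no cosolvent")
    if traj.box is not None and r_max > traj.box / 2.0:
        raise ValueError("r_max exceeds half the box edge (minimum image ambiguous)")
    mask = traj.reference.selection_mask(solute_selection)
    if not mask.any():
        raise ValueError(f"selection {solute_selection!r} matches no atoms")

    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    counts = np.zeros(edges.size - 1)
    expected = np.zeros_like(counts)
    rng = np.random.default_rng(seed)
    mol_ids = traj.cosolvent_mol
    n_mol = np.unique(mol_ids).size
    box = traj.box if traj.box is not None else _bounding_edge(traj)

    for frame, cos in zip(traj.frames, traj.cosolvent):
        solute = frame[mask]
        d = _min_mol_distances(cos, mol_ids, solute, traj.box)
        counts += np.histogram(d, bins=edges)[0]
        ins = rng.uniform(0.0, box, size=(n_mol * oversample, 3))
        d_ins = _min_mol_distances(ins, np.arange(ins.shape[0]), solute, traj.box)
        expected += np.histogram(d_ins, bins=edges)[0] / oversample

    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return MDDFProfile(r=centers, mddf=g, counts=counts)


def _bounding_edge(traj: Trajectory) -> float:
    span = traj.frames.max(axis=(0, 1)) - traj.frames.min(axis=(0, 1))
    return float(span.max() + 20.0)


def residue_density_map(
    traj: Trajectory,
    residues: np.ndarray,
    r_range: tuple[float, float] = (1.5, 3.5),
    bin_width: float = 0.25,
) -> np.ndarray:
    """Per-residue cosolvent contact probabilities over distance bins.

    Entry (i, b) is the fraction of frames in which at least one cosolvent
    molecule's minimum distance to residue ``residues[i]`` falls inside
    distance bin b of ``r_range``.  Being a frequency, the expectation does
    not change with the number of frames.
    """
    residues = np.asarray(residues, dtype=int)
    if residues.size == 0:
        raise ValueError("empty residue list")
    res_ids = traj.reference.res_id.astype(int)
    missing = np.setdiff1d(residues, res_ids)
    if missing.size:
        raise ValueError(f"residues absent from structure: {missing.tolist()}")
    edges = np.arange(r_range[0], r_range[1] + bin_width / 2, bin_width)
    n_bins = edges.size - 1
    dens = np.zeros((residues.size, n_bins))
    if traj.cosolvent is None:
        return dens
    mol_ids = traj.cosolvent_mol
    masks = [res_ids == r for r in residues]
    for frame, cos in zip(traj.frames, traj.cosolvent):
        for i, m in enumerate(masks):
            d = _min_mol_distances(cos, mol_ids, frame[m], traj.box)
            hist = np.histogram(d, bins=edges)[0]
            dens[i] += (hist > 0)
    return dens / traj.n_frames
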