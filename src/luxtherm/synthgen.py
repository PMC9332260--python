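"""Synthetic instrument and simulation outputs with known ground truth.

Every analysis input the package consumes can be generated here with stated
parameters, so parameter-recovery tests and round-trip I/O tests need no
external data:

* flash-shaped single-turnover bioluminescence traces (rise/decay
  two-exponential model plus additive Gaussian noise),
* remaining-activity time courses with an induction lag and an optional late
  plateau (multiplicative Gaussian noise, so R(0) stays at 100%),
* two-state excess-heat-capacity peaks on sloping instrument baselines
  (van't Hoff equilibrium form, additive Gaussian noise),
* harmonic-fluctuation trajectories with optional rigid-body motion and
  residue-targeted cosolvent enrichment.

All randomness flows from one explicit integer seed per generator call;
identical parameters and seed give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dsc import R_GAS, Thermogram
from .flashkin import KineticTrace
from .inactivation import ActivitySeries
from .trajstat import Structure, Trajectory


# ---------------------------------------------------------------------------
# flash traces


@dataclass
class FlashModelParams:
    """Two-exponential flash model I(t) = A*(exp(-k_decay t) - exp(-k_rise t)).

    ``noise_sd`` is additive Gaussian noise expressed as a fraction of the
    noise-free peak intensity.
    """

    amplitude: float = 1.0
    k_rise: float = 10.0  # s^-1
    k_decay: float = 0.32  # s^-1
    noise_sd: float = 0.02
    dt: float = 0.01  # s
    duration: float = 20.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_decay <= 0 or self.k_rise <= self.k_decay:
            raise ValueError("flash model requires k_rise > k_decay > 0")
        if self.dt <= 0 or self.duration <= 0 or self.noise_sd < 0:
            raise ValueError("dt, duration must be positive; noise_sd non-negative")

    @property
    def t_peak(self) -> float:
        """Closed-form peak time ln(k_rise/k_decay)/(k_rise - k_decay)."""
        return float(np.log(self.k_rise / self.k_decay) / (self.k_rise - self.k_decay))


def gen_flash_trace(p: FlashModelParams) -> KineticTrace:
    """Sample a flash trace on a uniform grid.

    The noise-free trace is non-negative with a single interior maximum at
    ``p.t_peak``; its integral is amplitude*(1/k_decay - 1/k_rise).
    """
    t = np.arange(0.0, p.duration + p.dt / 2, p.dt)
    clean = p.amplitude * (np.exp(-p.k_decay * t) - np.exp(-p.k_rise * t))
    if p.noise_sd > 0 and p.amplitude != 0:
        rng = np.random.default_rng(p.seed)
        peak = p.amplitude * (
            np.exp(-p.k_decay * p.t_peak) - np.exp(-p.k_rise * p.t_peak)
        )
        clean = clean + rng.normal(0.0, p.noise_sd * peak, t.size)
    return KineticTrace(times=t, intensities=clean)


# ---------------------------------------------------------------------------
# inactivation courses


@dataclass
class InactivationModelParams:
    """First-order inactivation with an induction lag and optional plateau.

    R(t) = 100 for t <= t_lag;
    R(t) = (100 - plateau)*exp(-k (t - t_lag)) + plateau otherwise,
    with multiplicative Gaussian noise of relative sd ``noise_sd``.
    The plateau emulates the aggregation-limited slow phase seen at 50 C.
    """

    k: float = 1.36  # min^-1
    t_lag: float = 1.0  # min
    plateau_frac: float = 0.0  # fraction of initial activity
    noise_sd: float = 0.02
    times: np.ndarray = field(default_factory=lambda: np.arange(0.0, 4.01, 1.0 / 3.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0 or self.t_lag < 0:
            raise ValueError("k must be positive and t_lag non-negative")
        if not 0 <= self.plateau_frac < 1:
            raise ValueError("plateau_frac must lie in [0, 1)")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size == 0:
            raise ValueError("times must not be empty")


def gen_inactivation_series(p: InactivationModelParams) -> ActivitySeries:
    """Sample a remaining-activity course; R(0) = 100 up to noise."""
    t = p.times
    plateau = 100.0 * p.plateau_frac
    r = np.where(
        t <= p.t_lag,
        100.0,
        (100.0 - plateau) * np.exp(-p.k * np.maximum(t - p.t_lag, 0.0)) + plateau,
    )
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        r = r * (1.0 + rng.normal(0.0, p.noise_sd, t.size))
    return ActivitySeries(times=t, R=np.clip(r, 0.0, None))


# ---------------------------------------------------------------------------
# thermograms


@dataclass
class ThermogramModelParams:
    """Two-state van't Hoff excess heat capacity on linear baselines.

    K(T) = exp[(dH_vH/R)(1/T_m - 1/T)] and the excess term is
    C_exc = dH_cal*dH_vH*K / (R T^2 (1+K)^2), whose integral over the full
    transition equals dH_cal.  Baselines are (intercept, slope) pairs in
    kJ/(K mol) and kJ/(K^2 mol), blended by the progress alpha = K/(1+K).
    ``skew`` adds a linear temperature dependence to dH_vH (fractional change
    per kelvin around T_m), producing the asymmetric, irreversible-looking
    peaks real scans show; it is off by default.
    """

    T_m: float = 318.5  # K
    dH_cal: float = 997.0  # kJ/mol
    dH_vH: float = 500.0  # kJ/mol
    native_baseline: tuple[float, float] = (0.0, 0.0)
    denatured_baseline: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.0  # kJ/(K mol), additive
    T_grid: np.ndarray = field(default_factory=lambda: np.arange(290.0, 350.0, 0.05))
    skew: float = 0.0  # fractional dH_vH change per K
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dH_cal <= 0 or self.dH_vH <= 0:
            raise ValueError("enthalpies must be positive")
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        if self.T_grid.size < 50 or not np.all(np.diff(self.T_grid) > 0):
            raise ValueError("T_grid must be strictly increasing with >= 50 samples")


def two_state_excess(p: ThermogramModelParams) -> np.ndarray:
    """Noise-free excess heat capacity term on the parameter grid (kJ/(K mol))."""
    T = p.T_grid
    dh_vh = p.dH_vH * 1000.0 * (1.0 + p.skew * (T - p.T_m))  # J/mol
    k_eq = np.exp((dh_vh / R_GAS) * (1.0 / p.T_m - 1.0 / T))
    c_exc = (p.dH_cal * 1000.0) * dh_vh * k_eq / (R_GAS * T**2 * (1.0 + k_eq) ** 2)
    return c_exc / 1000.0  # kJ/(K mol)


def gen_thermogram(p: ThermogramModelParams) -> Thermogram:
    """Sample a molar thermogram: baselines + two-state excess + noise.

    Warns when the temperature grid does not bracket T_m (the peak would be
    truncated and the calorimetric enthalpy underestimated).
    """
    T = p.T_grid
    if not (T[0] < p.T_m < T[-1]):
        import warnings

        warnings.warn("T_grid does not bracket T_m: generated peak is truncated")
    k_eq = np.exp((p.dH_vH * 1000.0 / R_GAS) * (1.0 / p.T_m - 1.0 / T))
    alpha = k_eq / (1.0 + k_eq)
    bn = p.native_baseline[0] + p.native_baseline[1] * T
    bd = p.denatured_baseline[0] + p.denatured_baseline[1] * T
    cp = (1.0 - alpha) * bn + alpha * bd + two_state_excess(p)
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        cp = cp + rng.normal(0.0, p.noise_sd, T.size)
    return Thermogram(T=T, Cp=cp, units="molar", meta={"synthetic": True})


def vant_hoff_from_fwhm(t_m: float, dt_half: float) -> float:
    """van't Hoff enthalpy (kJ/mol) giving a two-state peak of width dt_half.

    From the half-maximum condition K^2 - 6K + 1 = 0 (ln K = +/-1.7627),
    FWHM = 3.5255*R*T_m^2/dH_vH to first order in (T - T_m).
    """
    return 3.5255 * R_GAS * t_m**2 / dt_half / 1000.0


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class TrajectoryModelParams:
    """Harmonic-fluctuation trajectory model around a reference structure.

    Per-frame atom positions are the reference plus isotropic Gaussian
    displacements with per-coordinate sd rmsf_target/sqrt(3) (so the sampled
    RMSF converges to the target), optionally composed with a random proper
    rotation and translation of the whole frame.  Cosolvent particles are
    placed uniformly in the cubic box except for a fraction placed in
    1.5-3.5 A shells of enriched residues, proportional to enrichment-1.
    """

    reference: Structure = None  # type: ignore[assignment]
    rmsf_targets: np.ndarray = None  # type: ignore[assignment]
    n_frames: int = 100
    rigid_motion: bool = False
    cosolvent_count: int = 0
    enrichment: dict[int, float] = field(default_factory=dict)
    box: float = 60.0  # angstrom
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference is None:
            raise ValueError("a reference structure is required")
        if self.rmsf_targets is None:
            self.rmsf_targets = np.zeros(self.reference.n_atoms)
        self.rmsf_targets = np.asarray(self.rmsf_targets, dtype=float)
        if self.rmsf_targets.size != self.reference.n_atoms:
            raise ValueError("rmsf_targets must have one value per atom")
        if np.any(self.rmsf_targets < 0):
            raise ValueError("rmsf_targets must be non-negative")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if any(f < 1 for f in self.enrichment.values()):
            raise ValueError("enrichment factors must be >= 1")


def toy_chain(n_residues: int = 30, spacing: float = 3.8) -> Structure:
    """Deterministic CA-only helical chain used as a small test solute.

    One carbon pseudo-atom per residue on an ideal helix with the given
    CA-CA spacing; residue ids are 1-based.
    """
    i = np.arange(n_residues)
    turn = 100.0 * np.pi / 180.0  # helical twist per residue
    radius, rise = 2.3, 1.5
    coords = np.column_stack(
        [radius * np.cos(i * turn), radius * np.sin(i * turn), rise * i]
    )
    # rescale consecutive distances to the requested spacing
    if n_residues > 1:
        d = np.linalg.norm(np.diff(coords, axis=0), axis=1).mean()
        coords *= spacing / d
    return Structure(
        name=np.full(n_residues, "CA"),
        element=np.full(n_residues, "C"),
        res_id=i + 1,
        res_name=np.full(n_residues, "GLY"),
        chain_id=np.full(n_residues, "A"),
        coords=coords,
        mass=np.full(n_residues, 12.011),
        radius=np.full(n_residues, 1.7),
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def gen_trajectory(p: TrajectoryModelParams) -> Trajectory:
    """Generate harmonic-fluctuation frames (no cosolvent)."""
    rng = np.random.default_rng(p.seed)
    ref = p.reference.coords
    sd = p.rmsf_targets / np.sqrt(3.0)
    frames = np.empty((p.n_frames, ref.shape[0], 3))
    for i in range(p.n_frames):
        frame = ref + rng.normal(size=ref.shape) * sd[:, None]
        if p.rigid_motion:
            rot = _random_rotation(rng)
            trans = rng.uniform(-p.box / 10.0, p.box / 10.0, 3)
            frame = frame @ rot.T + trans
        frames[i] = frame
    return Trajectory(
        reference=p.reference,
        frames=frames,
        frame_times=np.arange(p.n_frames, dtype=float),
        box=p.box,
    )


SHELL_RANGE = (1.5, 3.5)  # angstrom, first-solvation-shell placement band


def gen_solvated_frames(p: TrajectoryModelParams) -> Trajectory:
    """Generate frames plus point-particle cosolvent with residue enrichment.

    Each cosolvent particle is placed uniformly in the box, except with
    probability (enrichment-1)*V_shell/V_box per enriched residue it is
    placed in that residue's 1.5-3.5 A shell instead; counts near an
    enriched residue therefore exceed the uniform expectation by the
    enrichment factor.  Rigid-body motion is not applied so the box frame
    stays meaningful for the solvent statistics.
    """
    if p.cosolvent_count <= 0:
        raise ValueError("cosolvent_count must be positive")
    ref = p.reference.coords
    extent = ref.max(axis=0) - ref.min(axis=0)
    if np.any(extent + 2 * SHELL_RANGE[1] >= p.box):
        raise ValueError("box too small to hold the solute and its shells")

    rng = np.random.default_rng(p.seed)
    centered = Structure(
        name=p.reference.name,
        element=p.reference.element,
        res_id=p.reference.res_id,
        res_name=p.reference.res_name,
        chain_id=p.reference.chain_id,
        coords=ref - ref.mean(axis=0) + p.box / 2.0,
        mass=p.reference.mass,
        radius=p.reference.radius,
    )
    solute = TrajectoryModelParams(
        reference=centered,
        rmsf_targets=p.rmsf_targets,
        n_frames=p.n_frames,
        rigid_motion=False,
        box=p.box,
        seed=int(rng.integers(2**31)),
    )
    traj = gen_trajectory(solute)

    res_ids = centered.res_id.astype(int)
    enriched = sorted(p.enrichment)
    v_shell = 4.0 / 3.0 * np.pi * (SHELL_RANGE[1] ** 3 - SHELL_RANGE[0] ** 3)
    p_shell = np.array(
        [(p.enrichment[r] - 1.0) * v_shell / p.box**3 for r in enriched]
    )

    cos = np.empty((p.n_frames, p.cosolvent_count, 3))
    for f in range(p.n_frames):
        frame = traj.frames[f]
        anchors = [frame[res_ids == r].mean(axis=0) for r in enriched]
        for m in range(p.cosolvent_count):
            u = rng.random()
            placed = False
            acc = 0.0
            for a, prob in zip(anchors, p_shell):
                acc += prob
                if u < acc:
                    cos[f, m] = a + _shell_point(rng)
                    placed = True
                    break
            if not placed:
                cos[f, m] = rng.uniform(0.0, p.box, 3)
    return Trajectory(
        reference=centered,
        frames=traj.frames,
        frame_times=traj.frame_times,
        cosolvent=cos,
        cosolvent_mol=np.arange(p.cosolvent_count),
        box=p.box,
    )


def _shell_point(rng: np.random.Generator) -> np.ndarray:
    """Uniform point in the spherical shell between the shell radii."""
    r3 = rng.uniform(SHELL_RANGE[0] ** 3, SHELL_RANGE[1] ** 3)
    r = r3 ** (1.0 / 3.0)
    v = rng.normal(size=3)
    return r * v / np.linalg.norm(v)
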