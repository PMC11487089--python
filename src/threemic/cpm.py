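"""Two-cell-type cellular Potts model of ischemic tumor-cell dispersal.

A spheroid is modeled as ~100 cells on a square lattice: an inner *core* of
ischemic cells (type C1) surrounded by a *cortex* of well-nurtured cells
(type C2), embedded in ECM/medium (type M, spin 0). Cells are spin domains;
dynamics are Metropolis-accepted spin-copy attempts that minimize a
Graner–Glazier Hamiltonian

    H = Σ_contacts J(τ_i, τ_j)·[σ_i ≠ σ_j]  +  λ Σ_cells (v - V_T)²

with contact energies J per type pair and a quadratic volume constraint.

The biology enters through inequalities on J. Reduced epithelial adhesion in
ischemic cells is modeled as J_C1,C1 > J_C1,C2 > J_C2,C2 (core–core contacts
are the least stable); increased ECM invasion as J_C1,M < J_C2,M (core cells
have the higher ECM affinity). Four presets — baseline, low_adhesion,
invasion, combined — apply neither, one, or both rules. Only these orderings
are mechanistic claims; the absolute J, λ, V_T, and temperature values are
implementation choices that realize them with mid-range contrast, and the
qualitative outcomes are robust to ±25% perturbation of the J table.

The Metropolis loop is compiled with numba; one Monte Carlo step is
accounted as one copy attempt by default (a sweep accounting — lattice-size
attempts per step — is available via ``mcs_as_sweeps``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.ndimage import binary_dilation

from .core import Track, TrackSet
from .errors import ConfigError, FitError
from .trackstats import MSDFit, fit_msd_exponent, msd

TYPE_M, TYPE_C1, TYPE_C2 = 0, 1, 2

CONDITIONS = ("baseline", "low_adhesion", "invasion", "combined")

_MOORE = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)
_VON_NEUMANN = np.array([(-1, 0), (0, -1), (0, 1), (1, 0)], dtype=np.int64)


# ---------------------------------------------------------------------------
# parameters and state
# ---------------------------------------------------------------------------


@dataclass
class CPMParams:
    """Lattice, energy table, and schedule of one simulation run."""

    grid: tuple[int, int] = (200, 200)
    n_cells: int = 100
    core_fraction: float = 0.5
    J: np.ndarray = field(default_factory=lambda: _j_table(8, 8, 8, 16, 16))
    lambda_volume: float = 2.0
    v_target: float = 60.0
    temperature: float = 9.0
    n_mcs: int = 128_000_000
    record_every: int = 1_280_000
    neighborhood: int = 8
    seed: int = 0
    mcs_as_sweeps: bool = False
    condition: str = ""

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        if self.J.shape != (3, 3):
            raise ConfigError("J must be a 3x3 type-pair table (M, C1, C2)")
        if not np.allclose(self.J, self.J.T):
            raise ConfigError("J must be symmetric")
        if not np.all(np.isfinite(self.J)):
            raise ConfigError("J entries must be finite")
        if self.lambda_volume < 0:
            raise ConfigError("lambda_volume must be >= 0")
        if self.neighborhood not in (4, 8):
            raise ConfigError("neighborhood must be 4 or 8")
        if not (0 < self.core_fraction < 1):
            raise ConfigError("core_fraction must lie in (0, 1)")

    @property
    def total_attempts(self) -> int:
        n = int(self.n_mcs)
        if self.mcs_as_sweeps:
            n *= self.grid[0] * self.grid[1]
        return n

    @property
    def offsets(self) -> np.ndarray:
        return _MOORE if self.neighborhood == 8 else _VON_NEUMANN


def _j_table(j11: float, j12: float, j22: float, j1m: float, j2m: float) -> np.ndarray:
    J = np.zeros((3, 3))
    J[TYPE_C1, TYPE_C1] = j11
    J[TYPE_C1, TYPE_C2] = J[TYPE_C2, TYPE_C1] = j12
    J[TYPE_C2, TYPE_C2] = j22
    J[TYPE_M, TYPE_C1] = J[TYPE_C1, TYPE_M] = j1m
    J[TYPE_M, TYPE_C2] = J[TYPE_C2, TYPE_M] = j2m
    return J


#: frozen contact-energy presets (J_C1C1, J_C1C2, J_C2C2, J_C1M, J_C2M).
#:
#: baseline: one cohesive tissue, equal ECM affinity — nothing sorts or
#:   invades. low_adhesion: core-core contacts destabilized with
#:   cross-contacts favored over the mean (J_C1C2 < (J_C1C1+J_C2C2)/2),
#:   so core cells intermingle with the cortex but stay in the cluster.
#: invasion: core cells gain ECM affinity (J_C1M far below J_C2M) with
#:   uniform cell-cell adhesion — a moderate surface-protrusion trend.
#: combined: strong core-core destabilization with cross-contacts *above*
#:   the mixing threshold and J_C1C2 ≈ J_C1M + J_C2M (detachment is not
#:   undone by re-adhesion), so the only relaxation channel is sustained
#:   outward expulsion of core cells into the ECM.
_PRESET_J = {
    "baseline": (8.0, 8.0, 8.0, 16.0, 16.0),
    "low_adhesion": (20.0, 10.0, 6.0, 16.0, 16.0),
    "invasion": (8.0, 8.0, 8.0, 4.0, 16.0),
    "combined": (30.0, 20.0, 6.0, 4.0, 16.0),
}


def condition_params(name: str, scale: str = "full", seed: int = 0) -> CPMParams:
    """Preset parameters for one of the four experimental conditions.

    ``scale='full'`` is the published geometry (200×200 lattice, 100 cells,
    1.28×10⁸ copy attempts); ``scale='desk'`` is a down-scaled preset
    (100×100, 25 cells, 2×10⁶ attempts) that preserves the qualitative
    outcomes and runs in seconds.
    """
    if name not in CONDITIONS:
        raise ConfigError(f"unknown condition {name!r}; use one of {CONDITIONS}")
    if scale == "full":
        kw = dict(grid=(200, 200), n_cells=100, n_mcs=128_000_000,
                  record_every=1_280_000)
    elif scale == "desk":
        kw = dict(grid=(100, 100), n_cells=25, n_mcs=2_000_000,
                  record_every=20_000)
    else:
        raise ConfigError(f"unknown scale {scale!r}; use 'full' or 'desk'")
    p = CPMParams(J=_j_table(*_PRESET_J[name]), seed=seed, condition=name, **kw)
    _check_preset_invariants(p)
    return p


def _check_preset_invariants(p: CPMParams) -> None:
    J = p.J
    name = p.condition
    if name in ("low_adhesion", "combined"):
        if not (J[1, 1] > J[1, 2] > J[2, 2]):
            raise ConfigError(f"{name}: requires J_C1C1 > J_C1C2 > J_C2C2")
    if name in ("invasion", "combined"):
        if not (J[1, 0] < J[2, 0]):
            raise ConfigError(f"{name}: requires J_C1,M < J_C2,M")


@dataclass
class CPMState:
    """Spin field, cell-type map, and cached per-cell volumes."""

    sigma: np.ndarray        # (H, W) int32 spin field; 0 = ECM/medium
    cell_types: np.ndarray   # (n_cells+1,) int8; index 0 is medium
    volumes: np.ndarray      # (n_cells+1,) int64 cached site counts
    elapsed_attempts: int = 0

    def recount_volumes(self) -> np.ndarray:
        return np.bincount(self.sigma.ravel(), minlength=len(self.cell_types)).astype(
            np.int64
        )

    def copy(self) -> "CPMState":
        return CPMState(self.sigma.copy(), self.cell_types.copy(),
                        self.volumes.copy(), self.elapsed_attempts)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def init_state(params: CPMParams) -> CPMState:
    """Circular cluster of cells centered on the grid, core inside cortex.

    Cell seed points follow a sunflower spiral (near-uniform Voronoi areas);
    lattice sites within the cluster disk are assigned to the nearest seed.
    Cells are ordered by seed radius and the innermost ``core_fraction`` are
    typed C1 (ischemic core), the rest C2 (well-nurtured cortex); all other
    sites are ECM/medium.
    """
    H, W = params.grid
    n = params.n_cells
    cluster_area = n * params.v_target
    radius = math.sqrt(cluster_area / math.pi)
    if 2 * radius > min(H, W) - 20:
        raise ConfigError(
            f"cluster diameter {2 * radius:.0f} leaves <10-site margin on "
            f"a {H}x{W} grid"
        )
    golden = math.pi * (3 - math.sqrt(5))
    i = np.arange(n)
    r_seed = radius * np.sqrt((i + 0.5) / n)
    th = i * golden
    cy = (H - 1) / 2.0 + r_seed * np.sin(th)
    cx = (W - 1) / 2.0 + r_seed * np.cos(th)
    # order cells by distance from center: inner cells get the low ids
    order = np.argsort(r_seed, kind="stable")
    cy, cx = cy[order], cx[order]

    rows, cols = np.mgrid[0:H, 0:W]
    rho = np.hypot(rows - (H - 1) / 2.0, cols - (W - 1) / 2.0)
    in_disk = rho <= radius
    site_r = rows[in_disk].astype(float)
    site_c = cols[in_disk].astype(float)
    d2 = (site_r[:, None] - cy[None, :]) ** 2 + (site_c[:, None] - cx[None, :]) ** 2
    # balance volumes with a power diagram: adjust per-seed weights until
    # every cell holds ~its quota of sites. Power cells are convex, so the
    # partition stays contiguous (plain Voronoi rim cells deviate by ±40%).
    n_sites = len(site_r)
    quota = np.full(n, n_sites / n)
    w = np.zeros(n)
    assign = np.argmin(d2, axis=1)
    best_assign, best_err = assign, np.inf
    for it in range(600):
        assign = np.argmin(d2 - w[None, :], axis=1)
        v = np.bincount(assign, minlength=n)
        err = quota - v
        worst = float(np.abs(err).max())
        if worst < best_err:
            best_assign, best_err = assign, worst
        if worst <= max(2.0, 0.08 * params.v_target):
            break
        w += (0.3 / (1.0 + it / 200.0)) * err
    assign = best_assign
    sigma0 = np.zeros((H, W), dtype=np.int32)
    sigma0[in_disk] = assign.astype(np.int32) + 1

    # type by realized centroid radius so every core centroid lies strictly
    # inside every cortical one; relabel ids in that radial order
    cr = np.array([site_r[assign == k].mean() for k in range(n)])
    cc = np.array([site_c[assign == k].mean() for k in range(n)])
    cent_r = np.hypot(cr - (H - 1) / 2.0, cc - (W - 1) / 2.0)
    radial = np.argsort(cent_r, kind="stable")
    relabel = np.empty(n + 1, dtype=np.int32)
    relabel[0] = 0
    relabel[radial + 1] = np.arange(1, n + 1)
    sigma = relabel[sigma0]

    n_core = int(round(params.core_fraction * n))
    n_core = min(max(n_core, 1), n - 1)
    cell_types = np.zeros(n + 1, dtype=np.int8)
    cell_types[1 : n_core + 1] = TYPE_C1
    cell_types[n_core + 1 :] = TYPE_C2
    state = CPMState(sigma, cell_types, None, 0)
    state.volumes = state.recount_volumes()
    return state


def initial_cluster_mask(state: CPMState) -> np.ndarray:
    """Boolean footprint of the cluster (all cell sites) at a given state."""
    return state.sigma > 0


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------


def hamiltonian(state: CPMState, params: CPMParams) -> float:
    """Total contact energy plus the volume-constraint term.

    Each unordered neighbor pair with differing spins contributes
    J(τ_a, τ_b) once; contacts are counted over the configured neighborhood
    (8-neighbor Moore by default, which reduces lattice anisotropy).
    """
    sigma = state.sigma
    tmap = state.cell_types[sigma]
    offs = [(0, 1), (1, 0)]
    if params.neighborhood == 8:
        offs += [(1, 1), (1, -1)]
    E = 0.0
    for dr, dc in offs:
        r0, r1 = max(0, -dr), sigma.shape[0] - max(0, dr)
        c0, c1 = max(0, -dc), sigma.shape[1] - max(0, dc)
        a = sigma[r0:r1, c0:c1]
        b = sigma[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ta = tmap[r0:r1, c0:c1]
        tb = tmap[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        diff = a != b
        E += params.J[ta[diff], tb[diff]].sum()
    v = state.recount_volumes()[1:]
    E += params.lambda_volume * np.sum((v - params.v_target) ** 2)
    return float(E)


def delta_energy(
    state: CPMState, params: CPMParams, r: int, c: int, new_spin: int
) -> float:
    """Local energy change of copying ``new_spin`` into site (r, c)."""
    old_spin = int(state.sigma[r, c])
    J = params.J
    ct = state.cell_types
    t_new, t_old = ct[new_spin], ct[old_spin]
    dE = 0.0
    for dr, dc in params.offsets:
        s_n = int(state.sigma[r + dr, c + dc])
        t_n = ct[s_n]
        if s_n != new_spin:
            dE += J[t_new, t_n]
        if s_n != old_spin:
            dE -= J[t_old, t_n]
    lam, vt = params.lambda_volume, params.v_target
    if new_spin != 0:
        v = state.volumes[new_spin]
        dE += lam * ((v + 1 - vt) ** 2 - (v - vt) ** 2)
    if old_spin != 0:
        v = state.volumes[old_spin]
        dE += lam * ((v - 1 - vt) ** 2 - (v - vt) ** 2)
    return float(dE)


def attempt_copy(
    state: CPMState, params: CPMParams, rng: np.random.Generator
) -> tuple[bool, float]:
    """One Metropolis copy attempt (reference kinetics, used for audits).

    Picks a random interior target site and a random neighbor source, and
    accepts the copy with probability min(1, exp(-ΔE/T)); at T = 0 only
    strictly energy-lowering moves are accepted. Returns (accepted, ΔE).
    The compiled kernel in :func:`run` implements identical physics.
    """
    H, W = state.sigma.shape
    offs = params.offsets
    while True:  # rejection-sample a boundary (target, source) pair
        r = int(rng.integers(1, H - 1))
        c = int(rng.integers(1, W - 1))
        dr, dc = offs[int(rng.integers(0, len(offs)))]
        new_spin = int(state.sigma[r + dr, c + dc])
        old_spin = int(state.sigma[r, c])
        if new_spin != old_spin:
            break
    state.elapsed_attempts += 1
    dE = delta_energy(state, params, r, c, new_spin)
    if dE <= 0:
        accept = True
    elif params.temperature <= 0:
        accept = False
    else:
        accept = rng.random() < math.exp(-dE / params.temperature)
    if accept:
        state.sigma[r, c] = new_spin
        state.volumes[new_spin] += 1
        state.volumes[old_spin] -= 1
    return accept, dE


# ---------------------------------------------------------------------------
# compiled kernel
# ---------------------------------------------------------------------------


@njit(cache=False)
def _seed_kernel(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=False)
def _run_chunk(sigma, cell_types, J, lam, vt, T, volumes, offsets, n_attempts):
    """Metropolis copy attempts, in place; returns number accepted."""
    H, W = sigma.shape
    n_off = offsets.shape[0]
    accepted = 0
    for _ in range(n_attempts):
        # rejection-sample a boundary (target, source) pair: spins must differ
        tries = 0
        found = False
        while tries < 10_000_000:
            tries += 1
            r = 1 + int(np.random.random() * (H - 2))
            c = 1 + int(np.random.random() * (W - 2))
            k = int(np.random.random() * n_off)
            new_spin = sigma[r + offsets[k, 0], c + offsets[k, 1]]
            old_spin = sigma[r, c]
            if new_spin != old_spin:
                found = True
                break
        if not found:  # uniform lattice: nothing can move
            break
        t_new = cell_types[new_spin]
        t_old = cell_types[old_spin]
        dE = 0.0
        for kk in range(n_off):
            s_n = sigma[r + offsets[kk, 0], c + offsets[kk, 1]]
            t_n = cell_types[s_n]
            if s_n != new_spin:
                dE += J[t_new, t_n]
            if s_n != old_spin:
                dE -= J[t_old, t_n]
        if new_spin != 0:
            v = volumes[new_spin]
            dE += lam * ((v + 1 - vt) ** 2 - (v - vt) ** 2)
        if old_spin != 0:
            v = volumes[old_spin]
            dE += lam * ((v - 1 - vt) ** 2 - (v - vt) ** 2)
        if dE <= 0:
            acc = True
        elif T <= 0.0:
            acc = False
        else:
            acc = np.random.random() < np.exp(-dE / T)
        if acc:
            sigma[r, c] = new_spin
            volumes[new_spin] += 1
            volumes[old_spin] -= 1
            accepted += 1
    return accepted


# ---------------------------------------------------------------------------
# running and metrics
# ---------------------------------------------------------------------------


@dataclass
class CPMResult:
    """Snapshots and derived time series of one simulation run."""

    params: CPMParams
    snapshots: np.ndarray        # (n_snap, H, W) spin fields
    attempts: np.ndarray         # (n_snap,) elapsed attempts per snapshot
    cell_types: np.ndarray
    initial_mask: np.ndarray     # cluster footprint at t = 0
    final_state: CPMState
    #: a dispersing cell reached the fixed wall; its late track is reflected
    border_contact: bool = False

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    def state_at(self, i: int) -> CPMState:
        s = CPMState(self.snapshots[i].copy(), self.cell_types.copy(), None,
                     int(self.attempts[i]))
        s.volumes = s.recount_volumes()
        return s

    def centroid_tracks(self, cell_type: int | None = None) -> TrackSet:
        """Per-cell centroid positions over snapshots as a track ensemble.

        Time is reported in snapshot units (one frame per recorded
        snapshot); MSD exponents are invariant to this choice. A cell that
        momentarily vanishes keeps its last known centroid.
        """
        n_ids = len(self.cell_types)
        n_snap = self.n_snapshots
        cy = np.zeros((n_snap, n_ids))
        cx = np.zeros((n_snap, n_ids))
        for s, sigma in enumerate(self.snapshots):
            flat = sigma.ravel()
            counts = np.bincount(flat, minlength=n_ids).astype(float)
            H, W = sigma.shape
            rows = np.repeat(np.arange(H), W)
            cols = np.tile(np.arange(W), H)
            sum_r = np.bincount(flat, weights=rows, minlength=n_ids)
            sum_c = np.bincount(flat, weights=cols, minlength=n_ids)
            with np.errstate(invalid="ignore", divide="ignore"):
                cy[s] = sum_r / counts
                cx[s] = sum_c / counts
        ids = np.arange(1, n_ids)
        if cell_type is not None:
            ids = ids[self.cell_types[ids] == cell_type]
        t = np.arange(n_snap, dtype=float)
        tracks = []
        for cid in ids:
            y = cy[:, cid].copy()
            x = cx[:, cid].copy()
            for s in range(1, n_snap):  # carry last position through gaps
                if not np.isfinite(x[s]):
                    x[s], y[s] = x[s - 1], y[s - 1]
            if np.isfinite(x).all():
                tracks.append(Track(int(cid), t, x, y))
        return TrackSet(tracks, condition=self.params.condition)

    def metrics(self) -> dict[str, np.ndarray]:
        """Energy, mixing index, and per-type ECM-invasion time series."""
        energy = np.empty(self.n_snapshots)
        mixing = np.empty(self.n_snapshots)
        inv1 = np.empty(self.n_snapshots)
        inv2 = np.empty(self.n_snapshots)
        for i in range(self.n_snapshots):
            st = self.state_at(i)
            energy[i] = hamiltonian(st, self.params)
            mixing[i] = mixing_index(st)
            frac = ecm_invasion_fraction(st, self.initial_mask)
            inv1[i], inv2[i] = frac[TYPE_C1], frac[TYPE_C2]
        return {
            "attempt": self.attempts.astype(float),
            "energy": energy,
            "mixing_index": mixing,
            "invasion_C1": inv1,
            "invasion_C2": inv2,
        }


def _touches_border(sigma: np.ndarray) -> bool:
    """True when any cell occupies a site adjacent to the fixed lattice wall."""
    ring = np.concatenate([sigma[0], sigma[-1], sigma[:, 0], sigma[:, -1],
                           sigma[1], sigma[-2], sigma[1:-1, 1], sigma[1:-1, -2]])
    return bool(np.any(ring != 0))


def run(params: CPMParams) -> CPMResult:
    """Execute a full simulation: seeded, snapshot-recorded, reproducible.

    Records ``floor(n_attempts / record_every) + 1`` snapshots including the
    initial state. Identical params (including seed) give bit-identical
    results. The lattice boundary is fixed (no wrap); sites on the outermost
    ring never change, acting as a hard wall. When a dispersing cell reaches
    the wall the run continues (the wall is valid no-flux physics) but
    ``border_contact`` is flagged, since that cell's subsequent displacement
    statistics are reflected.
    """
    state = init_state(params)
    init_mask = initial_cluster_mask(state)
    total = params.total_attempts
    every = int(params.record_every)
    n_chunks = total // every if every > 0 else 0
    remainder = total - n_chunks * every
    snapshots = [state.sigma.copy()]
    attempts = [0]
    _seed_kernel(params.seed % (2**31))
    offsets = params.offsets
    done = 0
    border = False
    for _ in range(n_chunks):
        _run_chunk(state.sigma, state.cell_types, params.J,
                   params.lambda_volume, params.v_target, params.temperature,
                   state.volumes, offsets, every)
        done += every
        snapshots.append(state.sigma.copy())
        attempts.append(done)
        border = border or _touches_border(state.sigma)
    if remainder:
        _run_chunk(state.sigma, state.cell_types, params.J,
                   params.lambda_volume, params.v_target, params.temperature,
                   state.volumes, offsets, remainder)
        done += remainder
        snapshots.append(state.sigma.copy())
        attempts.append(done)
        border = border or _touches_border(state.sigma)
    state.elapsed_attempts = done
    if not np.array_equal(state.volumes, state.recount_volumes()):
        raise RuntimeError("volume cache diverged from spin field")
    return CPMResult(
        params=params,
        snapshots=np.stack(snapshots),
        attempts=np.array(attempts),
        cell_types=state.cell_types.copy(),
        initial_mask=init_mask,
        final_state=state,
        border_contact=border,
    )


# ---------------------------------------------------------------------------
# mixing and invasion metrics
# ---------------------------------------------------------------------------


def mixing_index(state: CPMState) -> float:
    """Heterotypic contact fraction normalized by the random expectation.

    Counts cell–cell contacts between distinct cells over the Moore
    neighborhood; the fraction that is C1–C2 is divided by the expected
    fraction were cell types assigned at random (2·n1·n2 / n(n-1) over live
    cells). ~1 for randomly mixed types, below 1 for sorted layouts, above 1
    for alternating (checkerboard) layouts. NaN when a type is absent.
    """
    sigma = state.sigma
    ct = state.cell_types
    tmap = ct[sigma]
    het = 0
    tot = 0
    for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:
        r0, r1 = max(0, -dr), sigma.shape[0] - max(0, dr)
        c0, c1 = max(0, -dc), sigma.shape[1] - max(0, dc)
        a = sigma[r0:r1, c0:c1]
        b = sigma[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ta = tmap[r0:r1, c0:c1]
        tb = tmap[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        cc = (a != b) & (a > 0) & (b > 0)
        tot += int(cc.sum())
        het += int((cc & (ta != tb)).sum())
    live = state.recount_volumes()[1:] > 0
    types_live = ct[1:][live]
    n1 = int((types_live == TYPE_C1).sum())
    n2 = int((types_live == TYPE_C2).sum())
    n = n1 + n2
    if n1 == 0 or n2 == 0 or tot == 0:
        return float("nan")
    expected = 2.0 * n1 * n2 / (n * (n - 1))
    return (het / tot) / expected


def ecm_invasion_fraction(
    state: CPMState, initial_mask: np.ndarray, dilate: int = 2
) -> dict[int, float]:
    """Fraction of each type's volume outside the initial cluster footprint.

    The footprint is dilated by ``dilate`` sites (8-connected) so that
    boundary jitter does not count as invasion.
    """
    inside = binary_dilation(
        initial_mask, structure=np.ones((3, 3), bool), iterations=dilate
    )
    out = {}
    tmap = state.cell_types[state.sigma]
    for t in (TYPE_C1, TYPE_C2):
        sites = tmap == t
        n = int(sites.sum())
        out[t] = float((sites & ~inside).sum() / n) if n else 0.0
    return out


def run_replicates(
    name: str, seeds, scale: str = "desk"
) -> list[CPMResult]:
    """Run one condition at several seeds (replicate simulated spheroids)."""
    return [run(condition_params(name, scale=scale, seed=int(s))) for s in seeds]


def pooled_msd_fit(
    results: list[CPMResult],
    cell_type: int = TYPE_C1,
    seed: int = 0,
    n_boot: int = 400,
) -> MSDFit:
    """MSD exponent of one cell type pooled across replicate runs.

    Mirrors how experimental track analyses pool cells across spheroids:
    centroid tracks from every replicate enter one time-averaged pooled MSD,
    and the bootstrap resamples cells. Pooling averages over the
    run-to-run variability of when dispersal nucleates.
    """
    tracks = []
    for i, res in enumerate(results):
        for t in res.centroid_tracks(cell_type):
            t.track_id = t.track_id + 10_000 * i
            tracks.append(t)
    ts = TrackSet(tracks, condition=results[0].params.condition if results else None)
    curve = msd(ts)
    return fit_msd_exponent(curve, trackset=ts, seed=seed, n_boot=n_boot)


def simulated_msd(
    result: CPMResult, cell_type: int = TYPE_C1, seed: int = 0, n_boot: int = 500
) -> MSDFit:
    """MSD exponent of pooled centroid tracks of one cell type.

    Delegates to the track-statistics module: time-averaged pooled MSD over
    the cells' centroid tracks, log-log fit over the first quarter of lags,
    bootstrap-over-cells confidence interval.
    """
    if result.n_snapshots < 20:
        raise ConfigError("need >= 20 snapshots for an MSD fit")
    ts = result.centroid_tracks(cell_type)
    curve = msd(ts)
    # sub-half-site displacement is lattice jitter, not kinetics
    if curve.msd_um2.max() < 0.25:
        raise FitError("insufficient displacement for an exponent fit "
                       "(frozen dynamics)")
    return fit_msd_exponent(curve, trackset=ts, seed=seed, n_boot=n_boot)
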