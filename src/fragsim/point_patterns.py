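"""Spatial point-process generators for species distributions.

Every point represents one individual in a continuous landscape (the unit
square by default). Three processes are implemented:

* complete spatial randomness (CSR, homogeneous Poisson with conditioned n);
* the Thomas cluster process (aggregation): cluster centres uniform, offspring
  displaced by an isotropic bivariate Gaussian with per-axis standard
  deviation sigma;
* the Strauss inhibition process (regularity): fixed-n Gibbs density
  proportional to gamma**s(x), where s(x) counts point pairs closer than the
  interaction radius r, sampled by single-point Metropolis-Hastings.

Thomas offspring falling outside the window are wrapped toroidally, which
keeps the intensity spatially uniform. In "conditioned" mode the total
abundance is fixed exactly (offspring allocated to centres by an
equal-probability multinomial); in "poisson" mode both the number of centres
and the offspring counts are Poisson, matching the assumptions of the
analytic survival solution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from fragsim.window import Window

__all__ = [
    "PointPattern",
    "ThomasParams",
    "StraussParams",
    "FeasibilityError",
    "simulate_csr",
    "simulate_thomas",
    "simulate_strauss",
    "nn_distances",
    "pair_count",
    "write_pattern",
    "read_pattern",
]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


class FeasibilityError(RuntimeError):
    """A hard-core configuration with the requested n and r is unreachable."""


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PointPattern:
    """A finite set of individual coordinates with its generating context.

    Attributes
    ----------
    points : (n, 2) float array
        Coordinates, all inside ``window``.
    window : Window
    process_label : {"csr", "thomas", "strauss", "external"}
    seed : int or None
        Seed used by the generator; None for external data.
    """

    points: np.ndarray
    window: Window = field(default_factory=Window)
    process_label: str = "external"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if pts.size and not np.all(self.window.contains(pts[:, 0], pts[:, 1])):
            raise ValueError("all points must lie inside the window")

    @property
    def n(self) -> int:
        """Abundance (number of individuals)."""
        return self.points.shape[0]

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class ThomasParams:
    """Parameters of the Thomas cluster process.

    n_points is the (expected) total abundance n_P, n_clusters the (expected)
    number of cluster centres n_C, sigma the per-axis standard deviation of
    the Gaussian offspring displacement. Derived quantities: mu = n_P/n_C
    individuals per cluster, rho = n_C/A centre intensity.
    """

    n_points: int
    n_clusters: int
    sigma: float
    mode: str = "conditioned"

    def __post_init__(self) -> None:
        if self.n_points < 0:
            raise ValueError("n_points must be >= 0")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.mode not in ("conditioned", "poisson"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def mu(self) -> float:
        """Mean number of individuals per cluster."""
        return self.n_points / self.n_clusters

    def rho(self, window: Window) -> float:
        """Cluster-centre intensity for a given window."""
        return self.n_clusters / window.area


@dataclass(frozen=True)
class StraussParams:
    """Parameters of the fixed-n Strauss process.

    gamma in [0, 1] is the pairwise inhibition strength (gamma=1 is CSR,
    gamma=0 a hard core). The interaction radius r defaults to 1/sqrt(n),
    the lattice spacing at which n points tile the unit landscape.
    n_sweeps counts single-point Metropolis-Hastings updates; burn_in
    updates are discarded before the returned state is considered a draw.
    """

    n_points: int
    gamma: float
    r: Optional[float] = None
    n_sweeps: int = 100_000
    burn_in: int = 50_000

    def __post_init__(self) -> None:
        if self.n_points < 0:
            raise ValueError("n_points must be >= 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.r is not None and not self.r > 0:
            raise ValueError("r must be > 0")
        if not self.n_sweeps > self.burn_in >= 0:
            raise ValueError("need n_sweeps > burn_in >= 0")

    def radius(self) -> float:
        if self.r is not None:
            return self.r
        if self.n_points == 0:
            return 1.0
        return 1.0 / math.sqrt(self.n_points)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_csr(n: int, window: Window = Window(), seed: SeedLike = 0) -> PointPattern:
    """Simulate n uniform independent points (complete spatial randomness)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _rng(seed)
    x = rng.uniform(window.x_min, window.x_max, size=n)
    y = rng.uniform(window.y_min, window.y_max, size=n)
    return PointPattern(np.column_stack([x, y]), window, "csr",
                        seed if isinstance(seed, int) else None)


def simulate_thomas(params: ThomasParams, window: Window = Window(),
                    seed: SeedLike = 0) -> PointPattern:
    """Simulate a Thomas cluster process realization.

    Conditioned mode fixes both the number of centres and the total
    abundance; poisson mode draws both from Poisson distributions
    (centres ~ Poisson(n_clusters), offspring per centre ~ Poisson(mu)).
    Offspring are wrapped toroidally into the window.
    """
    rng = _rng(seed)
    if params.mode == "conditioned":
        n_centres = params.n_clusters
        n_total = params.n_points
        cx = rng.uniform(window.x_min, window.x_max, size=n_centres)
        cy = rng.uniform(window.y_min, window.y_max, size=n_centres)
        # equal-probability multinomial allocation of offspring to centres
        assign = rng.integers(0, n_centres, size=n_total)
    else:
        n_centres = rng.poisson(params.n_clusters)
        cx = rng.uniform(window.x_min, window.x_max, size=n_centres)
        cy = rng.uniform(window.y_min, window.y_max, size=n_centres)
        counts = rng.poisson(params.mu, size=n_centres) if n_centres else np.empty(0, int)
        assign = np.repeat(np.arange(n_centres), counts)
        n_total = assign.size
    offsets = rng.normal(0.0, params.sigma, size=(n_total, 2))
    if n_total:
        x = cx[assign] + offsets[:, 0]
        y = cy[assign] + offsets[:, 1]
        x, y = window.wrap(x, y)
    else:
        x = np.empty(0)
        y = np.empty(0)
    return PointPattern(np.column_stack([x, y]), window, "thomas",
                        seed if isinstance(seed, int) else None)


# Pairs are "close" when d < r strictly; a distance equal to r does not
# count. Comparisons use a tiny relative guard band so that configurations
# whose closest pairs sit mathematically AT r (e.g. optimal packings reached
# when r equals the packing bound) are not miscounted through float roundoff.
# For continuous random configurations the band is hit with probability ~0.
_STRICT = 1.0 - 1e-9


@njit(cache=True)
def _local_pairs(xy, i, x, y, r, width, height, toroidal):
    """Number of points j != i strictly closer than r to (x, y)."""
    t = 0
    r2 = r * r * _STRICT
    for j in range(xy.shape[0]):
        if j == i:
            continue
        dx = abs(xy[j, 0] - x)
        dy = abs(xy[j, 1] - y)
        if toroidal:
            if dx > 0.5 * width:
                dx = width - dx
            if dy > 0.5 * height:
                dy = height - dy
        if dx * dx + dy * dy < r2:
            t += 1
    return t


@njit(cache=True)
def _mh_strauss(xy, gamma, r, width, height, toroidal,
                idx, u_kind, ux, uy, gx, gy, u_acc, s0):
    """Single-point Metropolis-Hastings chain for the fixed-n Strauss density.

    Proposals mix a fresh uniform location (prob 1/2) with a Gaussian jitter
    of scale r/2. Acceptance ratio gamma**(delta s); for gamma=0 a move is
    accepted iff the moved point has no neighbour within r afterwards
    (the 0**0 = 1 convention).
    Returns the trace of s (pair count) after every proposal.
    """
    n_steps = idx.shape[0]
    s = s0
    trace = np.empty(n_steps, dtype=np.int64)
    jitter = 0.5 * r
    for t in range(n_steps):
        i = idx[t]
        ox = xy[i, 0]
        oy = xy[i, 1]
        if u_kind[t] < 0.5:
            nx = ux[t] * width
            ny = uy[t] * height
        else:
            nx = ox + jitter * gx[t]
            ny = oy + jitter * gy[t]
            nx = nx % width
            ny = ny % height
        t_old = _local_pairs(xy, i, ox, oy, r, width, height, toroidal)
        t_new = _local_pairs(xy, i, nx, ny, r, width, height, toroidal)
        if gamma > 0.0:
            d = t_new - t_old
            accept = d <= 0 or u_acc[t] < gamma ** d
        else:
            accept = t_new == 0
        if accept:
            xy[i, 0] = nx
            xy[i, 1] = ny
            s += t_new - t_old
        trace[t] = s
    return trace


def _shear_lattice_search(n: int, r_rel: float):
    """Best sheared lattice of n points on the unit torus.

    Candidates are the finite subgroups of the torus of order n: R rows of C
    columns (n = R*C) with a per-row shear delta = j/n. Returns
    (min_distance, R, C, delta) for the candidate with the largest minimum
    pairwise distance, or None if none reaches r_rel (distances in units of
    the window side). Includes the rotated square lattices that achieve the
    exact packing bound min_distance = 1/sqrt(n) when n is a sum of two
    squares.
    """
    best = None
    tol = r_rel * _STRICT
    for C in range(1, n + 1):
        if n % C:
            continue
        R = n // C
        if 1.0 / C < tol:
            continue
        for j in range(0, n // 2 + 1):
            delta = j / n
            dmin = 1.0 / C
            feasible = True
            for b in range(1, R):
                vert = min(b / R, 1.0 - b / R)
                if vert >= dmin:
                    continue
                h = (b * delta) % (1.0 / C)
                h = min(h, 1.0 / C - h)
                d = math.hypot(h, vert)
                if d < dmin:
                    dmin = d
                if dmin < tol:
                    feasible = False
                    break
            if feasible and (best is None or dmin > best[0]):
                best = (dmin, R, C, delta)
    return best


def _build_shear_lattice(n: int, R: int, C: int, delta: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Realize a sheared lattice with a random torus isometry applied."""
    i = np.repeat(np.arange(R), C)
    j = np.tile(np.arange(C), R)
    x = (j / C + i * delta) % 1.0
    y = (i + 0.5) / R
    xy = np.column_stack([x, y])
    if rng.random() < 0.5:  # axis swap
        xy = xy[:, ::-1]
    for axis in (0, 1):  # reflections
        if rng.random() < 0.5:
            xy[:, axis] = (1.0 - xy[:, axis]) % 1.0
    xy = (xy + rng.random(2)) % 1.0  # uniform translation
    return xy


def _rsa_pack(n: int, r_rel: float, rng: np.random.Generator,
              max_darts: int) -> Optional[np.ndarray]:
    """Random sequential adsorption; succeeds at low disk coverage."""
    pts = np.empty((n, 2))
    k = 0
    r2 = r_rel * r_rel * _STRICT
    for _ in range(max_darts):
        cand = rng.random(2)
        d = pts[:k] - cand
        d = np.abs(d)
        d = np.minimum(d, 1.0 - d)
        if k == 0 or np.all(d[:, 0] ** 2 + d[:, 1] ** 2 >= r2):
            pts[k] = cand
            k += 1
            if k == n:
                return pts
    return None


def _penalty_pack(n: int, r_rel: float, rng: np.random.Generator,
                  tries: int) -> Optional[np.ndarray]:
    """Overlap-penalty minimization from random starts (dense packings)."""
    from scipy.optimize import minimize

    target = r_rel * 1.03

    def energy_grad(x):
        xy = x.reshape(n, 2)
        diff = xy[:, None, :] - xy[None, :, :]
        diff -= np.round(diff)  # shortest toroidal displacement
        d = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(d, np.inf)
        pen = np.maximum(0.0, target - d)
        e = 0.5 * float((pen ** 2).sum())  # each pair counted twice -> x0.5
        with np.errstate(invalid="ignore"):
            coef = np.where(pen > 0.0, -2.0 * pen / d, 0.0)
        grad = 0.5 * 2.0 * (coef[..., None] * diff).sum(axis=1)
        return e, grad.ravel()

    for _ in range(tries):
        res = minimize(energy_grad, rng.random(2 * n), jac=True,
                       method="L-BFGS-B", options={"maxiter": 500})
        xy = res.x.reshape(n, 2) % 1.0
        d = _pair_count_xy(np.ascontiguousarray(xy), r_rel, 1.0, 1.0, True)
        if d == 0:
            return xy
    return None


def _hardcore_init(n: int, r: float, window: Window,
                   rng: np.random.Generator) -> np.ndarray:
    """A configuration of n points with no pair strictly closer than r.

    Works in window-relative units on the torus. Strategy: random sequential
    adsorption when the disk coverage is low; otherwise the densest sheared
    torus lattice (randomly translated/reflected so replicates differ);
    otherwise bounded overlap-penalty optimization. Raises FeasibilityError
    when all bounded attempts fail (the requested coverage is at or beyond
    the packing limit).
    """
    if n == 1:
        return np.array([[window.x_min + rng.random() * window.width,
                          window.y_min + rng.random() * window.height]])
    side = min(window.width, window.height)
    if abs(window.width - window.height) > 1e-12 * side:
        # conservative: treat the rectangle via its shorter side
        side = min(window.width, window.height)
    r_rel = r / side
    coverage = n * math.pi * (0.5 * r_rel) ** 2
    if coverage > math.pi / math.sqrt(12.0):
        # beyond the hexagonal packing bound: provably infeasible
        raise FeasibilityError(
            f"n={n} points with hard-core distance r={r:.4g} exceed the "
            f"packing bound (disk coverage {coverage:.2f} > 0.9069)")
    xy = None
    if coverage < 0.4:
        xy = _rsa_pack(n, r_rel, rng, max_darts=500 * n)
    if xy is None:
        found = _shear_lattice_search(n, r_rel)
        if found is not None:
            xy = _build_shear_lattice(n, found[1], found[2], found[3], rng)
    if xy is None:
        xy = _penalty_pack(n, r_rel, rng, tries=60)
    if xy is None:
        raise FeasibilityError(
            f"could not place n={n} points with hard-core distance r={r:.4g} "
            f"(disk coverage {coverage:.2f} of window area)")
    out = np.empty_like(xy)
    out[:, 0] = window.x_min + xy[:, 0] * window.width
    out[:, 1] = window.y_min + xy[:, 1] * window.height
    return out


def simulate_strauss(params: StraussParams, window: Window = Window(),
                     seed: SeedLike = 0, return_s_trace: bool = False):
    """Sample the fixed-n Strauss process by Metropolis-Hastings.

    gamma=1 reduces exactly to CSR (sampled directly); gamma=0 yields a
    hard-core pattern with no pair closer than r. Initialization is a
    relaxed lattice for gamma=0 and CSR otherwise.

    With ``return_s_trace=True`` also returns the trace of the pair
    statistic s after every update (used for convergence diagnostics).
    """
    rng = _rng(seed)
    n = params.n_points
    r = params.radius()
    seed_int = seed if isinstance(seed, int) else None
    if n == 0:
        pat = PointPattern(np.empty((0, 2)), window, "strauss", seed_int)
        return (pat, np.empty(0, dtype=np.int64)) if return_s_trace else pat
    if params.gamma == 1.0:
        # the Strauss density is uniform: draw CSR directly
        pat = simulate_csr(n, window, rng)
        pat = PointPattern(pat.points, window, "strauss", seed_int)
        if return_s_trace:
            s = pair_count(pat, r)
            return pat, np.full(params.n_sweeps, s, dtype=np.int64)
        return pat

    if params.gamma == 0.0:
        xy = _hardcore_init(n, r, window, rng)
    else:
        xy = simulate_csr(n, window, rng).points.copy()
    # local frame for the kernel: origin at window corner
    xy = xy - [window.x_min, window.y_min]

    n_steps = params.n_sweeps
    idx = rng.integers(0, n, size=n_steps)
    u_kind = rng.random(n_steps)
    ux = rng.random(n_steps)
    uy = rng.random(n_steps)
    gxy = rng.normal(0.0, 1.0, size=(n_steps, 2))
    u_acc = rng.random(n_steps)

    toroidal = window.topology == "toroidal"
    s0 = _pair_count_xy(xy, r, window.width, window.height, toroidal)
    trace = _mh_strauss(xy, float(params.gamma), float(r),
                        window.width, window.height, toroidal,
                        idx, u_kind, ux, uy, gxy[:, 0], gxy[:, 1], u_acc, s0)
    xy = xy + [window.x_min, window.y_min]
    # wrapping can land exactly on the upper bound in floating point
    np.clip(xy[:, 0], window.x_min, window.x_max, out=xy[:, 0])
    np.clip(xy[:, 1], window.y_min, window.y_max, out=xy[:, 1])
    pat = PointPattern(xy, window, "strauss", seed_int)
    return (pat, trace) if return_s_trace else pat


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def nn_distances(pattern: PointPattern) -> np.ndarray:
    """Distance from each point to its nearest neighbour.

    Respects the window topology (toroidal distances wrap around edges).
    Requires at least two points.
    """
    if pattern.n < 2:
        raise ValueError("nearest-neighbour distances need at least 2 points")
    w = pattern.window
    pts = pattern.points - [w.x_min, w.y_min]
    if w.topology == "toroidal":
        # guard against coordinates exactly on the upper boundary
        pts = np.mod(pts, [w.width, w.height])
        tree = cKDTree(pts, boxsize=[w.width, w.height])
    else:
        tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1]


def _pairs_within(pattern: PointPattern, r: float) -> np.ndarray:
    """Index pairs strictly closer than r (respecting topology)."""
    w = pattern.window
    pts = pattern.points - [w.x_min, w.y_min]
    if w.topology == "toroidal":
        pts = np.mod(pts, [w.width, w.height])
        tree = cKDTree(pts, boxsize=[w.width, w.height])
    else:
        tree = cKDTree(pts)
    pairs = tree.query_pairs(r, output_type="ndarray")
    if pairs.size == 0:
        return pairs.reshape(0, 2)
    a = pts[pairs[:, 0]]
    b = pts[pairs[:, 1]]
    dx = np.abs(a[:, 0] - b[:, 0])
    dy = np.abs(a[:, 1] - b[:, 1])
    if w.topology == "toroidal":
        dx = np.minimum(dx, w.width - dx)
        dy = np.minimum(dy, w.height - dy)
    # query_pairs includes distance == r; keep strictly-closer pairs only,
    # with the same roundoff guard as the sampler
    strict = np.hypot(dx, dy) ** 2 < r * r * _STRICT
    return pairs[strict]


def pair_count(pattern: PointPattern, r: float) -> int:
    """Number of unordered point pairs strictly closer than r.

    This is the Strauss sufficient statistic s(x).
    """
    if not r > 0:
        raise ValueError("r must be > 0")
    if pattern.n < 2:
        return 0
    return int(_pairs_within(pattern, r).shape[0])


@njit(cache=True)
def _pair_count_xy(xy, r, width, height, toroidal):
    s = 0
    n = xy.shape[0]
    r2 = r * r * _STRICT
    for i in range(n):
        for j in range(i + 1, n):
            dx = abs(xy[j, 0] - xy[i, 0])
            dy = abs(xy[j, 1] - xy[i, 1])
            if toroidal:
                if dx > 0.5 * width:
                    dx = width - dx
                if dy > 0.5 * height:
                    dy = height - dy
            if dx * dx + dy * dy < r2:
                s += 1
    return s


# ---------------------------------------------------------------------------
# I/O: CSV of coordinates plus a JSON metadata sidecar
# ---------------------------------------------------------------------------

def write_pattern(pattern: PointPattern, path: Union[str, Path],
                  params: Optional[dict] = None) -> None:
    """Write a pattern as CSV (header x,y) with a JSON metadata sidecar."""
    path = Path(path)
    header = "x,y"
    np.savetxt(path, pattern.points, delimiter=",", header=header, comments="")
    meta = {
        "process": pattern.process_label,
        "seed": pattern.seed,
        "window": [pattern.window.x_min, pattern.window.y_min,
                   pattern.window.x_max, pattern.window.y_max],
        "topology": pattern.window.topology,
        "params": params or {},
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_pattern(path: Union[str, Path],
                 window: Optional[Window] = None) -> PointPattern:
    """Read a pattern written by :func:`write_pattern` (or any x,y CSV)."""
    path = Path(path)
    pts = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if pts.size == 0:
        pts = np.empty((0, 2))
    label = "external"
    seed = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label = meta.get("process", "external")
        seed = meta.get("seed")
        if window is None and "window" in meta:
            x0, y0, x1, y1 = meta["window"]
            window = Window(x0, y0, x1, y1, meta.get("topology", "toroidal"))
    return PointPattern(pts, window or Window(), label, seed)
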