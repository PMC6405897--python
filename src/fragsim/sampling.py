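"""Cookie-cutter overlay and Monte-Carlo survival estimation.

Overlaying a species point pattern on a habitat map labels every individual
in a habitat cell (or disk) as a survivor and removes every individual in
the matrix. Landscape-scale survival means at least one survivor. For each
scenario (species parameters x landscape parameters), replicate simulations
redraw BOTH the point pattern and the landscape from deterministic child
seeds and record the surviving abundance; summaries are the mean abundance,
the coefficient of variation of abundance (sd/mean), and the survival
probability with a binomial standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from fragsim.window import Window
from fragsim.point_patterns import (
    PointPattern, StraussParams, ThomasParams,
    simulate_csr, simulate_strauss, simulate_thomas,
)
from fragsim.landscapes import (
    DiskLandscape, HabitatMap,
    is_habitat, make_disk_landscape, midpoint_displacement, threshold_to_habitat,
)

__all__ = [
    "OverlayResult",
    "SurvivalEstimate",
    "SpeciesSpec",
    "LandscapeSpec",
    "overlay",
    "estimate_survival",
    "run_scenario_cell",
    "RESULT_COLUMNS",
]


@dataclass(frozen=True)
class OverlayResult:
    """Survivors of one cookie-cutter overlay."""

    survivors: PointPattern
    abundance: int
    survived: bool


@dataclass(frozen=True)
class SurvivalEstimate:
    """Monte-Carlo summaries over replicate overlays.

    cv_abundance is NaN when the mean abundance is zero (undefined, not 0).
    se_survival is the binomial standard error sqrt(q(1-q)/n_reps).
    """

    n_reps: int
    mean_abundance: float
    cv_abundance: float
    survival_prob: float
    se_survival: float
    se_mean_abundance: float
    abundances: Optional[np.ndarray] = None

    def wilson_interval(self, z: float = 1.96) -> tuple:
        """Wilson score interval for the survival probability."""
        n, q = self.n_reps, self.survival_prob
        denom = 1 + z ** 2 / n
        centre = (q + z ** 2 / (2 * n)) / denom
        half = z * math.sqrt(q * (1 - q) / n + z ** 2 / (4 * n ** 2)) / denom
        return centre - half, centre + half


@dataclass(frozen=True)
class SpeciesSpec:
    """Species side of a scenario: process and its parameters.

    process: "csr" (n_points), "thomas" (n_points, n_clusters, sigma, mode)
    or "strauss" (n_points, gamma, optional r, n_sweeps, burn_in).
    """

    process: str
    n_points: int
    n_clusters: Optional[int] = None
    sigma: Optional[float] = None
    mode: str = "conditioned"
    gamma: Optional[float] = None
    r: Optional[float] = None
    n_sweeps: int = 100_000
    burn_in: int = 50_000

    def __post_init__(self) -> None:
        if self.process not in ("csr", "thomas", "strauss"):
            raise ValueError(f"unknown process {self.process!r}")
        if self.process == "thomas" and (self.n_clusters is None or self.sigma is None):
            raise ValueError("thomas spec needs n_clusters and sigma")
        if self.process == "strauss" and self.gamma is None:
            raise ValueError("strauss spec needs gamma")

    def draw(self, window: Window, seed) -> PointPattern:
        if self.process == "csr":
            return simulate_csr(self.n_points, window, seed)
        if self.process == "thomas":
            params = ThomasParams(self.n_points, self.n_clusters,
                                  self.sigma, self.mode)
            return simulate_thomas(params, window, seed)
        params = StraussParams(self.n_points, self.gamma, self.r,
                               self.n_sweeps, self.burn_in)
        return simulate_strauss(params, window, seed)


@dataclass(frozen=True)
class LandscapeSpec:
    """Landscape side of a scenario.

    kind="fractal": midpoint-displacement surface (hurst, levels) thresholded
    to habitat_amount. kind="disks": n_disks equal circular fragments with
    nominal coverage habitat_amount.
    """

    habitat_amount: float
    kind: str = "fractal"
    hurst: Optional[float] = None
    levels: int = 7
    n_disks: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("fractal", "disks"):
            raise ValueError(f"unknown landscape kind {self.kind!r}")
        if self.kind == "fractal" and self.hurst is None:
            raise ValueError("fractal landscape needs hurst")
        if self.kind == "disks" and self.n_disks is None:
            raise ValueError("disk landscape needs n_disks")

    def draw(self, window: Window, seed) -> Union[HabitatMap, DiskLandscape]:
        rng = np.random.default_rng(seed)
        if self.kind == "fractal":
            if self.habitat_amount == 0.0:
                side = 2 ** self.levels + 1
                return HabitatMap(np.zeros((side, side), bool), 0.0, window)
            surface = midpoint_displacement(self.hurst, self.levels, rng)
            m = threshold_to_habitat(surface, self.habitat_amount, rng)
            return replace(m, window=window)
        return make_disk_landscape(self.n_disks, self.habitat_amount, window, rng)


def overlay(pattern: PointPattern,
            landscape: Union[HabitatMap, DiskLandscape]) -> OverlayResult:
    """Apply the cookie-cutter: keep individuals in habitat, drop the rest."""
    w1, w2 = pattern.window, landscape.window
    if (w1.x_min, w1.y_min, w1.x_max, w1.y_max) != (w2.x_min, w2.y_min,
                                                    w2.x_max, w2.y_max):
        raise ValueError("pattern and landscape windows do not match")
    if pattern.n == 0:
        keep = np.zeros(0, dtype=bool)
    else:
        keep = is_habitat(landscape, pattern.points[:, 0], pattern.points[:, 1])
    survivors = PointPattern(pattern.points[keep], pattern.window,
                             pattern.process_label, pattern.seed)
    return OverlayResult(survivors, survivors.n, survivors.n > 0)


def _child_seeds(master_seed: int, n: int):
    """Deterministic per-replicate seed sequences from one master seed."""
    return np.random.SeedSequence(master_seed).spawn(n)


def estimate_survival(species_spec: SpeciesSpec, landscape_spec: LandscapeSpec,
                      n_reps: int = 1000, master_seed: int = 0,
                      window: Window = Window(),
                      keep_abundances: bool = False) -> SurvivalEstimate:
    """Monte-Carlo estimate of abundance statistics and survival probability.

    Each replicate draws a fresh point pattern AND a fresh landscape from
    deterministic child seeds of master_seed, overlays them, and records the
    surviving abundance. Both sources of randomness are therefore averaged
    over, as the reported quantities require.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    abundances = np.empty(n_reps, dtype=np.int64)
    for i, child in enumerate(_child_seeds(master_seed, n_reps)):
        s_species, s_land = child.spawn(2)
        pattern = species_spec.draw(window, np.random.default_rng(s_species))
        landscape = landscape_spec.draw(window, np.random.default_rng(s_land))
        abundances[i] = overlay(pattern, landscape).abundance
    mean_ab = float(abundances.mean())
    if n_reps >= 2:
        sd = float(abundances.std(ddof=1))
        cv = sd / mean_ab if mean_ab > 0 else float("nan")
        se_mean = sd / math.sqrt(n_reps)
    else:
        cv = float("nan")
        se_mean = float("nan")
    q = float((abundances > 0).mean())
    se_q = math.sqrt(q * (1.0 - q) / n_reps)
    return SurvivalEstimate(
        n_reps=n_reps,
        mean_abundance=mean_ab,
        cv_abundance=cv,
        survival_prob=q,
        se_survival=se_q,
        se_mean_abundance=se_mean,
        abundances=abundances if keep_abundances else None,
    )


RESULT_COLUMNS = [
    "process", "n_P", "n_C", "sigma", "gamma", "r", "landscape",
    "habitat_amount", "hurst", "n_disks", "n_reps", "master_seed",
    "mean_abundance", "cv_abundance", "survival_prob", "se_survival",
    "se_mean_abundance",
]


def run_scenario_cell(species_spec: SpeciesSpec, landscape_spec: LandscapeSpec,
                      n_reps: int = 1000, master_seed: int = 0,
                      window: Window = Window()) -> dict:
    """One cell of a factorial design: estimate plus a flat metadata row."""
    est = estimate_survival(species_spec, landscape_spec, n_reps,
                            master_seed, window)
    r_eff = None
    if species_spec.process == "strauss":
        r_eff = species_spec.r or 1.0 / math.sqrt(max(species_spec.n_points, 1))
    return {
        "process": species_spec.process,
        "n_P": species_spec.n_points,
        "n_C": species_spec.n_clusters,
        "sigma": species_spec.sigma,
        "gamma": species_spec.gamma,
        "r": r_eff,
        "landscape": landscape_spec.kind,
        "habitat_amount": landscape_spec.habitat_amount,
        "hurst": landscape_spec.hurst,
        "n_disks": landscape_spec.n_disks,
        "n_reps": n_reps,
        "master_seed": master_seed,
        "mean_abundance": est.mean_abundance,
        "cv_abundance": est.cv_abundance,
        "survival_prob": est.survival_prob,
        "se_survival": est.se_survival,
        "se_mean_abundance": est.se_mean_abundance,
    }
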