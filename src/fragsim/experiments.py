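"""Factorial scenario grids, the experiment runner, and figure output.

A ScenarioConfig describes one factorial design: a point process with grids
over its parameters, crossed with grids over habitat amount and Hurst factor
(or disk landscapes). run_experiment iterates all cells, estimates survival
statistics for each, and writes a long-format CSV incrementally; re-running
the same config reproduces the CSV byte for byte.
"""

from __future__ import annotations

import itertools
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from fragsim.sampling import (
    LandscapeSpec, SpeciesSpec, RESULT_COLUMNS, run_scenario_cell,
)

__all__ = [
    "ScenarioConfig",
    "default_grids",
    "load_config",
    "save_config",
    "run_experiment",
    "plot_survival_curves",
]

logger = logging.getLogger("fragsim")

# Habitat-amount and Hurst grids used throughout. The habitat range 0.01-0.5
# is covered with a roughly log-spaced ladder; H spans 0.1 (high
# fragmentation per se) to 0.9 (low fragmentation per se).
DEFAULT_HABITAT_GRID = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5)
DEFAULT_HURST_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class ScenarioConfig:
    """One factorial design: species grids x landscape grids x replication."""

    process: str
    n_points_grid: Sequence[int] = (10, 100, 1000)
    n_clusters_grid: Sequence[int] = ()
    sigma_grid: Sequence[float] = ()
    gamma_grid: Sequence[float] = ()
    habitat_grid: Sequence[float] = DEFAULT_HABITAT_GRID
    hurst_grid: Sequence[float] = DEFAULT_HURST_GRID
    landscape_type: str = "fractal"
    n_disks_grid: Sequence[int] = ()
    levels: int = 7
    n_reps: int = 1000
    master_seed: int = 0
    n_sweeps: int = 100_000
    output: Optional[str] = None

    def species_cells(self) -> List[SpeciesSpec]:
        if self.process == "csr":
            return [SpeciesSpec("csr", n) for n in self.n_points_grid]
        if self.process == "thomas":
            return [
                SpeciesSpec("thomas", n, n_clusters=nc, sigma=s)
                for n, nc, s in itertools.product(
                    self.n_points_grid, self.n_clusters_grid, self.sigma_grid)
            ]
        if self.process == "strauss":
            return [
                SpeciesSpec("strauss", n, gamma=g, n_sweeps=self.n_sweeps,
                            burn_in=self.n_sweeps // 2)
                for n, g in itertools.product(self.n_points_grid,
                                              self.gamma_grid)
            ]
        raise ValueError(f"unknown process {self.process!r}")

    def landscape_cells(self) -> List[LandscapeSpec]:
        if self.landscape_type == "fractal":
            return [
                LandscapeSpec(p, "fractal", hurst=h, levels=self.levels)
                for p, h in itertools.product(self.habitat_grid,
                                              self.hurst_grid)
            ]
        return [
            LandscapeSpec(p, "disks", n_disks=nd)
            for p, nd in itertools.product(self.habitat_grid,
                                           self.n_disks_grid)
        ]


def default_grids() -> dict:
    """The three factorial designs over species parameters.

    CSR: abundance 10/100/1000 (3 cells). Thomas: abundance x number of
    clusters {1,2,5,10} x cluster size sigma {0.01,0.02,0.05,0.1} (48 cells).
    Strauss: abundance x inhibition strength gamma {0,0.01,0.1,1} (12 cells).
    Each is crossed with the habitat-amount and Hurst grids at run time.
    """
    return {
        "csr": ScenarioConfig("csr"),
        "thomas": ScenarioConfig(
            "thomas",
            n_clusters_grid=(1, 2, 5, 10),
            sigma_grid=(0.01, 0.02, 0.05, 0.1),
        ),
        "strauss": ScenarioConfig(
            "strauss",
            gamma_grid=(0.0, 0.01, 0.1, 1.0),
        ),
    }


def save_config(config: ScenarioConfig, path: Union[str, Path]) -> None:
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path: Union[str, Path]) -> ScenarioConfig:
    data = yaml.safe_load(Path(path).read_text())
    return ScenarioConfig(**data)


def run_experiment(config: ScenarioConfig,
                   output: Optional[Union[str, Path]] = None) -> pd.DataFrame:
    """Run every cell of a factorial design and return the results table.

    The long-format CSV (one row per scenario cell) is written incrementally
    when an output path is given, and the resolved config is saved next to
    it. Per-cell seeds are derived deterministically from the master seed,
    keyed by cell index, so a re-run reproduces the CSV exactly. A failing
    cell is logged and recorded with NaN statistics rather than aborting
    the run.
    """
    out_path = Path(output) if output else (
        Path(config.output) if config.output else None)
    species = config.species_cells()
    lands = config.landscape_cells()
    rows = []
    fh = None
    if out_path is not None:
        out_path.parent.mkdir(parents=True, exist_ok=True)
        save_config(config, out_path.with_suffix(".config.yml"))
        fh = open(out_path, "w")
        fh.write(",".join(RESULT_COLUMNS) + "\n")
    ss = np.random.SeedSequence(config.master_seed)
    cell_seeds = ss.generate_state(len(species) * len(lands)) >> 1  # < 2^31
    try:
        for idx, (sp, ls) in enumerate(itertools.product(species, lands)):
            seed = int(cell_seeds[idx])
            t0 = time.perf_counter()
            logger.info("cell %d/%d process=%s p=%s H=%s seed=%d",
                        idx + 1, len(species) * len(lands), sp.process,
                        ls.habitat_amount, ls.hurst, seed)
            try:
                row = run_scenario_cell(sp, ls, config.n_reps, seed)
            except Exception:  # pragma: no cover - partial-failure policy
                logger.exception("cell %d failed", idx + 1)
                row = {c: None for c in RESULT_COLUMNS}
                row.update(process=sp.process, n_P=sp.n_points,
                           habitat_amount=ls.habitat_amount, hurst=ls.hurst,
                           n_reps=config.n_reps, master_seed=seed)
            logger.info("cell %d done in %.2fs", idx + 1,
                        time.perf_counter() - t0)
            rows.append(row)
            if fh is not None:
                fh.write(",".join(
                    "" if row[c] is None else repr(row[c])
                    if isinstance(row[c], float) else str(row[c])
                    for c in RESULT_COLUMNS) + "\n")
                fh.flush()
    finally:
        if fh is not None:
            fh.close()
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def plot_survival_curves(results: pd.DataFrame,
                         out_dir: Union[str, Path],
                         value: str = "survival_prob",
                         row_var: Optional[str] = None,
                         col_var: Optional[str] = None,
                         fmt: str = "png") -> List[Path]:
    """Panel figures: survival (or another statistic) vs fragmentation.

    The x-axis runs from low fragmentation per se (H = 0.9) to high
    (H = 0.1); one line per habitat amount. Panels are laid out on a grid of
    row_var x col_var (for example sigma x n_C for the aggregated design, or
    n_P x gamma for the regular one). One figure per point process found in
    the table; returns the written paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    required = {"process", "habitat_amount", "hurst", value}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table is missing columns: {sorted(missing)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    if results.empty:
        logger.warning("empty results table: no figures written")
        return written
    for process, sub in results.groupby("process"):
        rows = sorted(sub[row_var].dropna().unique()) if row_var else [None]
        cols = sorted(sub[col_var].dropna().unique()) if col_var else [None]
        fig, axes = plt.subplots(len(rows), len(cols),
                                 figsize=(3.2 * len(cols), 2.8 * len(rows)),
                                 squeeze=False, sharex=True, sharey=True)
        cmap = plt.get_cmap("viridis")
        p_values = sorted(sub["habitat_amount"].unique())
        for i, rv in enumerate(rows):
            for j, cv in enumerate(cols):
                ax = axes[i][j]
                panel = sub
                if rv is not None:
                    panel = panel[panel[row_var] == rv]
                if cv is not None:
                    panel = panel[panel[col_var] == cv]
                for k, p in enumerate(p_values):
                    line = panel[panel["habitat_amount"] == p].sort_values(
                        "hurst", ascending=False)
                    ax.plot(line["hurst"], line[value], "o-",
                            color=cmap(k / max(len(p_values) - 1, 1)),
                            label=f"p={p:g}")
                ax.invert_xaxis()  # low fragmentation (H=0.9) on the left
                title = []
                if rv is not None:
                    title.append(f"{row_var}={rv:g}")
                if cv is not None:
                    title.append(f"{col_var}={cv:g}")
                ax.set_title(", ".join(title), fontsize=8)
        axes[-1][0].set_xlabel("Hurst factor H (fragmentation per se →)")
        axes[0][0].set_ylabel(value)
        axes[0][0].legend(fontsize=6)
        fig.tight_layout()
        path = out_dir / f"{value}_{process}.{fmt}"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
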