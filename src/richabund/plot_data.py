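"""Tree-level inventory tables and plot-level derived variables.

A forest region is sampled with fixed-size plots; every stem above the
inventory's diameter-at-breast-height (DBH) threshold is measured and
identified to species or morphospecies.  Plot-level variables derived here
are the ones the per-region structural models consume:

* ``S``  species richness  — number of distinct species labels per plot
* ``A``  abundance         — number of standing trees per plot
* ``D``  mean tree size    — arithmetic mean DBH per plot (cm)
* ``E``  elevation         — plot elevation (m)

Richness and abundance are natural-log transformed before model fitting
(``logS``, ``logA``); mean size is left untransformed, since logging
abundance alone already linearizes the negative size–density relationship.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TreeRecord",
    "PlotRecord",
    "RegionDataset",
    "aggregate_trees",
    "log_transform",
    "read_tree_table",
    "plots_to_frame",
    "frame_to_plots",
    "read_plot_table",
    "write_plot_table",
    "write_region_results",
    "read_region_results",
]

TREE_COLUMNS = ["region_code", "plot_id", "species", "dbh_cm", "elevation_m"]
PLOT_COLUMNS = [
    "region_code",
    "plot_id",
    "cluster_id",
    "elevation",
    "richness",
    "abundance",
    "mean_dbh",
    "log_richness",
    "log_abundance",
]


@dataclass(frozen=True)
class TreeRecord:
    """One measured stem."""

    region_code: str
    plot_id: str
    species: str
    dbh: float  # cm
    elevation: float  # m
    cluster_id: str | None = None

    def __post_init__(self):
        if not (self.dbh > 0):
            raise ValueError(f"dbh must be positive, got {self.dbh} (plot {self.plot_id})")
        if not str(self.species).strip():
            raise ValueError(f"empty species label in plot {self.plot_id}")


@dataclass
class PlotRecord:
    """Derived variables for one plot."""

    plot_id: str
    elevation: float
    richness: int
    abundance: int
    mean_dbh: float
    cluster_id: str | None = None
    region_code: str = ""
    log_richness: float | None = None
    log_abundance: float | None = None

    def __post_init__(self):
        if self.richness < 1 or self.abundance < 1:
            raise ValueError(f"plot {self.plot_id}: counts must be >= 1")
        if self.richness > self.abundance:
            raise ValueError(
                f"plot {self.plot_id}: richness {self.richness} exceeds abundance {self.abundance}"
            )
        if not (self.mean_dbh > 0):
            raise ValueError(f"plot {self.plot_id}: mean_dbh must be positive")


@dataclass
class RegionDataset:
    """All plots of one forest region, plus sampling metadata."""

    region_code: str
    plots: list[PlotRecord]
    plot_size: float | None = None  # m²
    dbh_threshold: float | None = None  # cm
    dropped_plots: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.plots) < 3:
            raise ValueError(
                f"region {self.region_code}: at least 3 plots required, got {len(self.plots)}"
            )
        for p in self.plots:
            if p.region_code and p.region_code != self.region_code:
                raise ValueError(
                    f"plot {p.plot_id} has region {p.region_code!r}, expected {self.region_code!r}"
                )

    @property
    def clustered(self) -> bool:
        return any(p.cluster_id is not None for p in self.plots)

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    def to_frame(self) -> pd.DataFrame:
        return plots_to_frame(self.plots, region_code=self.region_code)


def aggregate_trees(
    trees: list[TreeRecord],
    dbh_threshold: float,
    inclusive: bool = True,
) -> tuple[list[PlotRecord], list[str]]:
    """Filter stems by the DBH threshold and aggregate to plot records.

    Stems with ``dbh >= dbh_threshold`` are kept (``>`` when
    ``inclusive=False``; inventories phrase their thresholds ambiguously,
    so the convention is exposed).  Plots left empty by the filter are
    dropped and their ids returned in the second element.

    Raises if a plot carries inconsistent elevation values.
    """
    if not trees:
        raise ValueError("no trees supplied")
    if dbh_threshold < 0:
        raise ValueError("dbh_threshold must be >= 0")

    by_plot: dict[tuple[str, str], list[TreeRecord]] = {}
    order: list[tuple[str, str]] = []
    for t in trees:
        key = (t.region_code, t.plot_id)
        if key not in by_plot:
            by_plot[key] = []
            order.append(key)
        by_plot[key].append(t)

    plots: list[PlotRecord] = []
    dropped: list[str] = []
    for key in sorted(order):
        group = by_plot[key]
        elevations = {t.elevation for t in group}
        if len(elevations) > 1:
            raise ValueError(
                f"plot {key[1]}: inconsistent elevation values {sorted(elevations)}"
            )
        clusters = {t.cluster_id for t in group}
        if len(clusters) > 1:
            raise ValueError(f"plot {key[1]}: inconsistent cluster ids {sorted(map(str, clusters))}")
        if inclusive:
            kept = [t for t in group if t.dbh >= dbh_threshold]
        else:
            kept = [t for t in group if t.dbh > dbh_threshold]
        if not kept:
            dropped.append(key[1])
            continue
        species = {t.species.strip() for t in kept}
        # sorted before averaging so the result is bitwise permutation-invariant
        dbh = np.sort(np.array([t.dbh for t in kept], dtype=float))
        plots.append(
            PlotRecord(
                plot_id=key[1],
                region_code=key[0],
                cluster_id=next(iter(clusters)),
                elevation=float(group[0].elevation),
                richness=len(species),
                abundance=len(kept),
                mean_dbh=float(dbh.mean()),
            )
        )
    return plots, dropped


def log_transform(plots: list[PlotRecord]) -> list[PlotRecord]:
    """Populate natural-log richness and abundance in place; returns the list."""
    for p in plots:
        if p.richness < 1 or p.abundance < 1:
            raise ValueError(f"plot {p.plot_id}: cannot log-transform zero counts")
        p.log_richness = math.log(p.richness)
        p.log_abundance = math.log(p.abundance)
    return plots


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_tree_table(path, sep: str = ",") -> list[TreeRecord]:
    """Read a delimited tree table; requires the columns
    region_code, plot_id, species, dbh_cm, elevation_m (cluster_id optional)."""
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in TREE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tree table {path} missing required columns: {missing}")
    has_cluster = "cluster_id" in df.columns
    records = []
    for row in df.itertuples(index=False):
        cluster = getattr(row, "cluster_id", None) if has_cluster else None
        if cluster is not None and (pd.isna(cluster) or str(cluster) == ""):
            cluster = None
        records.append(
            TreeRecord(
                region_code=str(row.region_code),
                plot_id=str(row.plot_id),
                species=str(row.species),
                dbh=float(row.dbh_cm),
                elevation=float(row.elevation_m),
                cluster_id=None if cluster is None else str(cluster),
            )
        )
    return records


def plots_to_frame(plots: list[PlotRecord], region_code: str | None = None) -> pd.DataFrame:
    rows = []
    for p in plots:
        rows.append(
            {
                "region_code": p.region_code or region_code or "",
                "plot_id": p.plot_id,
                "cluster_id": p.cluster_id,
                "elevation": p.elevation,
                "richness": p.richness,
                "abundance": p.abundance,
                "mean_dbh": p.mean_dbh,
                "log_richness": p.log_richness,
                "log_abundance": p.log_abundance,
            }
        )
    return pd.DataFrame(rows, columns=PLOT_COLUMNS)


def frame_to_plots(df: pd.DataFrame) -> list[PlotRecord]:
    required = {"plot_id", "elevation", "richness", "abundance", "mean_dbh"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"plot table missing required columns: {missing}")
    plots = []
    for row in df.itertuples(index=False):
        cluster = getattr(row, "cluster_id", None)
        if cluster is not None and (pd.isna(cluster) or str(cluster) == ""):
            cluster = None
        p = PlotRecord(
            plot_id=str(row.plot_id),
            region_code=str(getattr(row, "region_code", "") or ""),
            cluster_id=None if cluster is None else str(cluster),
            elevation=float(row.elevation),
            richness=int(row.richness),
            abundance=int(row.abundance),
            mean_dbh=float(row.mean_dbh),
        )
        plots.append(p)
    return log_transform(plots)


def read_plot_table(path, sep: str = ",") -> list[PlotRecord]:
    """Read a plot table with precomputed S, A, D, E columns."""
    return frame_to_plots(pd.read_csv(path, sep=sep, comment="#"))


def write_plot_table(plots: list[PlotRecord], path, sep: str = ",") -> None:
    plots_to_frame(plots).to_csv(path, sep=sep, index=False)


def write_region_results(results: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a per-region results table (one row per region)."""
    results.to_csv(path, sep=sep, index=False, float_format="%.6f")


def read_region_results(path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")
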