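"""Static trajectory plotting with configuration overlays and observed data.

Stands in for the original interactive Visualizer: up to eight variables are
assigned to compass quadrants (NW, N, NE, W, E, SW, S, SE), up to four
configurations are drawn per panel in the fixed colour order black, blue,
green, red, and observed data points can be superimposed on the panels of
the variables they measure.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .model import ModelSpec
from .simulate import SimulationResult

QUADRANTS = ("NW", "N", "NE", "W", "E", "SW", "S", "SE")
CONFIG_COLOURS = ("black", "blue", "green", "red")

# quadrant -> (row, col) on a 3x3 grid whose centre stays empty
_GRID_POS = {
    "NW": (0, 0), "N": (0, 1), "NE": (0, 2),
    "W": (1, 0), "E": (1, 2),
    "SW": (2, 0), "S": (2, 1), "SE": (2, 2),
}


class PlotError(ValueError):
    pass


@dataclass
class Observations:
    """External data points to superimpose: a time vector plus one series
    per observed variable (NaN marks an absent point)."""

    times: np.ndarray
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise PlotError("observation times must be strictly increasing")
        for name, series in self.values.items():
            series = np.asarray(series, dtype=float)
            if len(series) != len(self.times):
                raise PlotError(
                    f"series '{name}' length {len(series)} does not match "
                    f"{len(self.times)} time points"
                )
            self.values[name] = series


def load_observations(path) -> Observations:
    """Read a headered CSV with a ``time`` column plus one column per
    observed variable; blank cells become absent (NaN) points."""
    import csv

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise PlotError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    lowered = [h.lower() for h in header]
    if "time" not in lowered:
        raise PlotError(f"{path}: no 'time' column in header {header}")
    t_idx = lowered.index("time")

    def cell(row_cells, idx, rownum, col):
        if idx >= len(row_cells) or row_cells[idx].strip() == "":
            return np.nan
        try:
            return float(row_cells[idx])
        except ValueError:
            raise PlotError(
                f"{path}: row {rownum}, column '{col}': "
                f"cannot parse {row_cells[idx]!r} as a number"
            )

    times = []
    series: dict[str, list[float]] = {h: [] for i, h in enumerate(header) if i != t_idx}
    for rownum, row in enumerate(rows[1:], start=2):
        if not any(c.strip() for c in row):
            continue
        tval = cell(row, t_idx, rownum, header[t_idx])
        if np.isnan(tval):
            raise PlotError(f"{path}: row {rownum}: missing time value")
        times.append(tval)
        for i, h in enumerate(header):
            if i != t_idx:
                series[h].append(cell(row, i, rownum, h))
    return Observations(
        times=np.asarray(times), values={k: np.asarray(v) for k, v in series.items()}
    )


@dataclass
class PlotLayout:
    """Quadrant assignment plus the configurations (and colours) shown."""

    assignments: dict[str, str] = field(default_factory=dict)  # variable -> quadrant
    configurations_shown: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        used: dict[str, str] = {}
        for var, quad in self.assignments.items():
            if quad not in QUADRANTS:
                raise PlotError(f"unknown quadrant '{quad}' (use one of {QUADRANTS})")
            if quad in used:
                raise PlotError(f"quadrant {quad} assigned to both '{used[quad]}' and '{var}'")
            used[quad] = var
        if len(self.configurations_shown) > len(CONFIG_COLOURS):
            raise PlotError(
                f"at most {len(CONFIG_COLOURS)} configurations can be shown"
            )


def default_layout(spec: ModelSpec, configurations: list[str]) -> PlotLayout:
    """Quadrants filled in order with the GeneralControls display variables
    (all state variables when none are declared)."""
    names = spec.general_controls.default_display_variables or [
        v.name for v in spec.state_variables
    ]
    assignments = {name: QUADRANTS[i] for i, name in enumerate(names[: len(QUADRANTS)])}
    shown = [(c, CONFIG_COLOURS[i]) for i, c in enumerate(configurations)]
    return PlotLayout(assignments=assignments, configurations_shown=shown)


def build_figure(
    results: list[SimulationResult],
    layout: PlotLayout,
    observations: Observations | None = None,
):
    """Build (without saving) the multi-panel overlay figure; the returned
    figure's visible axes are one per assigned quadrant."""
    if len(results) > len(CONFIG_COLOURS):
        raise PlotError(f"at most {len(CONFIG_COLOURS)} results can be overlaid")
    if not results:
        raise PlotError("no simulation results to plot")
    for var in layout.assignments:
        for res in results:
            if var not in res.variable_names:
                raise PlotError(
                    f"variable '{var}' is missing from the result for "
                    f"configuration '{res.configuration}'"
                )

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colours = dict(layout.configurations_shown)
    fig, axes = plt.subplots(3, 3, figsize=(12, 9))
    for ax in axes.flat:
        ax.set_visible(False)
    for var, quad in layout.assignments.items():
        r, c = _GRID_POS[quad]
        ax = axes[r][c]
        ax.set_visible(True)
        for i, res in enumerate(results):
            colour = colours.get(res.configuration, CONFIG_COLOURS[i])
            ax.plot(res.times, res.trajectory(var), color=colour, label=res.configuration)
        if observations is not None and var in observations.values:
            ax.scatter(
                observations.times, observations.values[var],
                marker="o", facecolors="none", edgecolors="dimgray", zorder=3,
                label="observed",
            )
        ax.set_title(f"{var} ({quad})")
        ax.set_xlabel("time")
        if len(results) > 1 or observations is not None:
            ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_result(
    results: list[SimulationResult],
    layout: PlotLayout,
    observations: Observations | None = None,
    out_path="trajectories.png",
) -> str:
    """Write a multi-panel figure: one panel per assigned quadrant, one
    curve per result (colour-coded by configuration), observed points
    overlaid where a variable has a series.  The file format follows the
    extension of ``out_path``."""
    import matplotlib.pyplot as plt

    fig = build_figure(results, layout, observations)
    fig.savefig(out_path)
    plt.close(fig)
    return str(out_path)


def plot_scan(
    spec_results: list[tuple[float, SimulationResult]],
    variable: str,
    parameter: str,
    out_path="scan.png",
) -> str:
    """Overlay one variable's trajectory across a parameter sweep."""
    if not spec_results:
        raise PlotError("no scan results to plot")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import cm

    fig, ax = plt.subplots(figsize=(8, 5))
    values = [v for v, _ in spec_results]
    vmin, vmax = min(values), max(values)
    span = (vmax - vmin) or 1.0
    for value, res in spec_results:
        ax.plot(
            res.times, res.trajectory(variable),
            color=cm.viridis((value - vmin) / span),
            label=f"{parameter}={value:g}",
        )
    ax.set_xlabel("time")
    ax.set_ylabel(variable)
    ax.set_title(f"{variable} under a sweep of {parameter}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return str(out_path)
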