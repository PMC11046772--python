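"""Optional PNG output: per-place evolution plots and grid heatmap frames.

Requires matplotlib; everything else in the package works without it.
"""
from __future__ import annotations

from pathlib import Path

from ..compiler import CompiledModel
from ..simulator import Trace


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_evolution(trace: Trace, out_dir: str | Path, mode: str = "exploration") -> list[Path]:
    """One PNG per observed scope: token counts over ticks for every place.

    ``mode='exploration'`` lets each panel scale to its own value range;
    ``'fixed-axes'`` shares the y-axis across scopes.
    """
    plt = _pyplot()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = trace.to_frame()
    ymax = df["count"].max() if mode == "fixed-axes" else None
    written = []
    for scope, group in df.groupby("scope"):
        fig, ax = plt.subplots(figsize=(7, 4))
        for place, series in group.groupby("place"):
            ax.plot(series["tick"], series["count"], label=place, linewidth=1)
        ax.set_xlabel("tick")
        ax.set_ylabel("tokens")
        ax.set_title(scope)
        if ymax is not None:
            ax.set_ylim(0, ymax * 1.05 + 1)
        ax.legend(fontsize=6, ncol=2)
        path = out_dir / f"evolution_{scope}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written


def plot_grid_frames(
    trace: Trace,
    model: CompiledModel,
    place: str,
    ticks: list[int],
    out_dir: str | Path,
) -> list[Path]:
    """Tick-stamped heatmaps of one entity's counts across the spatial grid."""
    import numpy as np

    plt = _pyplot()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(x for x, _ in model.coords.values()) + 1
    height = max(y for _, y in model.coords.values()) + 1
    df = trace.to_frame()
    written = []
    for tick in ticks:
        grid = np.zeros((height, width))
        frame = df[(df["tick"] == tick) & (df["place"] == place)]
        for _, row in frame.iterrows():
            if row["scope"] in model.coords:
                x, y = model.coords[row["scope"]]
                grid[y, x] = row["count"]
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(grid, cmap="viridis", origin="upper")
        ax.set_title(f"{place}  t={tick}")
        fig.colorbar(im, ax=ax, shrink=0.8)
        path = out_dir / f"grid_{place}_t{tick:04d}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written
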