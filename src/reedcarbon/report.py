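"""Figures and a markdown summary for simulation and scenario outputs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def plot_trajectory(trajectory: pd.DataFrame, path: str | Path) -> None:
    """Two stacked time-series panels: shoot and rhizome carbon stock."""
    if trajectory.empty:
        raise ValueError("trajectory is empty")
    dates = pd.to_datetime(trajectory["date"])
    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    axes[0].plot(dates, trajectory["pac_gc_m2"], color="forestgreen")
    axes[0].set_ylabel("aboveground C (gC m$^{-2}$)")
    axes[1].plot(dates, trajectory["pbc_gc_m2"], color="saddlebrown")
    axes[1].set_ylabel("belowground C (gC m$^{-2}$)")
    axes[1].set_xlabel("date")
    fig.suptitle("Reed carbon stocks over the growing season")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scenario_windows(daily: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """One percent-change panel per scenario window.

    ``daily`` is the long-format scenario table (scenario, window, date,
    pct_pac, pct_pbc).  Returns the files written, one per window.
    """
    if daily.empty:
        raise ValueError("scenario daily table is empty")
    outdir = Path(outdir)
    written: list[Path] = []
    for window in sorted(daily["window"].unique()):
        sub = daily[daily["window"] == window]
        fig, ax = plt.subplots(figsize=(8, 4.5))
        for name, grp in sub.groupby("scenario"):
            ax.plot(pd.to_datetime(grp["date"]), grp["pct_pac"], label=name, lw=1)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylabel("aboveground stock change vs baseline (%)")
        ax.set_title(f"{window} window water-transfer scenarios")
        ax.legend(fontsize=6, ncol=2)
        fig.tight_layout()
        path = outdir / f"scenario_{window}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def render_report(
    outdir: str | Path,
    trajectory: pd.DataFrame | None = None,
    scenario_daily: pd.DataFrame | None = None,
    scenario_summary: pd.DataFrame | None = None,
    seed: int | None = None,
) -> Path:
    """Write plots and a deterministic markdown summary into ``outdir``.

    Re-running on identical inputs reproduces the markdown byte-for-byte.
    """
    if trajectory is None and scenario_daily is None:
        raise ValueError("nothing to report: no trajectory or scenario input")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["# reedcarbon run report", ""]
    if seed is not None:
        lines += [f"seed: {seed}", ""]
    if trajectory is not None:
        plot_trajectory(trajectory, outdir / "trajectory.png")
        dates = pd.to_datetime(trajectory["date"])
        peak_a = dates.iloc[trajectory["pac_gc_m2"].idxmax()]
        peak_b = dates.iloc[trajectory["pbc_gc_m2"].idxmax()]
        lines += [
            "## Trajectory",
            "",
            f"- days simulated: {len(trajectory)}",
            f"- aboveground stock peak: {trajectory['pac_gc_m2'].max():.1f} "
            f"gC m-2 on {peak_a.date()}",
            f"- belowground stock peak: {trajectory['pbc_gc_m2'].max():.1f} "
            f"gC m-2 on {peak_b.date()}",
            f"- end-of-season stocks: {trajectory['pac_gc_m2'].iloc[-1]:.1f} / "
            f"{trajectory['pbc_gc_m2'].iloc[-1]:.1f} gC m-2",
            "",
            "![trajectory](trajectory.png)",
            "",
        ]
    if scenario_daily is not None:
        files = plot_scenario_windows(scenario_daily, outdir)
        lines += ["## Scenarios", ""]
        if scenario_summary is not None:
            worst = scenario_summary.loc[scenario_summary["max_loss_pac_pct"].idxmin()]
            lines += [
                f"- scenarios run: {len(scenario_summary)}",
                f"- largest aboveground loss: {worst['max_loss_pac_pct']:.1f}% "
                f"({worst['scenario']})",
                "",
            ]
        lines += [f"![{p.stem}]({p.name})" for p in files] + [""]
    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
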