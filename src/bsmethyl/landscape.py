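"""Chromosome-scale methylation summaries: fixed windows and per-site tracks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WindowProfile", "window_profile", "compare_samples", "site_track"]

DEFAULT_WINDOW = 250_000


@dataclass(frozen=True)
class WindowProfile:
    """Non-overlapping windows tiling [0, genome_length)."""

    window_size: int
    genome_length: int
    table: pd.DataFrame  # columns: start, end, n_called, mean_beta

    def same_grid(self, other: "WindowProfile") -> bool:
        return (
            self.window_size == other.window_size
            and self.genome_length == other.genome_length
        )


def window_profile(
    calls: pd.DataFrame,
    genome_length: int,
    window: int = DEFAULT_WINDOW,
) -> WindowProfile:
    """Bin call positions into floor(pos / window) tiles.

    Every input row counts as one called site; pass the called subset.
    The last window may be short; empty windows have mean_beta = NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    n_windows = -(-genome_length // window)
    starts = np.arange(n_windows, dtype=np.int64) * window
    ends = np.minimum(starts + window, genome_length)
    n_called = np.zeros(n_windows, dtype=np.int64)
    mean_beta = np.full(n_windows, np.nan)
    if not calls.empty:
        pos = calls["pos"].to_numpy(dtype=np.int64)
        if pos.min() < 0 or pos.max() >= genome_length:
            raise ValueError("call position outside [0, genome_length)")
        widx = pos // window
        np.add.at(n_called, widx, 1)
        if "beta" in calls.columns:
            beta_sum = np.zeros(n_windows)
            np.add.at(beta_sum, widx, calls["beta"].to_numpy(dtype=float))
            nz = n_called > 0
            mean_beta[nz] = beta_sum[nz] / n_called[nz]
    table = pd.DataFrame(
        {"start": starts, "end": ends, "n_called": n_called, "mean_beta": mean_beta}
    )
    return WindowProfile(window_size=window, genome_length=genome_length, table=table)


def compare_samples(a: WindowProfile, b: WindowProfile) -> pd.DataFrame:
    """Per-window deltas (A minus B); requires identical window grids."""
    if not a.same_grid(b):
        raise ValueError("window grids differ between profiles")
    return pd.DataFrame(
        {
            "start": a.table["start"],
            "end": a.table["end"],
            "delta_n_called": a.table["n_called"] - b.table["n_called"],
            "delta_mean_beta": a.table["mean_beta"] - b.table["mean_beta"],
        }
    )


def site_track(calls: pd.DataFrame, track_name: str = "methylated_sites") -> pd.DataFrame:
    """BED6 table of called sites (0-based half-open, one bp per record)."""
    if calls.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "name", "score", "strand"]
        )
    pos = calls["pos"].to_numpy(dtype=np.int64)
    score = (
        np.rint(1000 * calls["beta"].to_numpy(dtype=float)).astype(int)
        if "beta" in calls.columns
        else np.zeros(len(calls), dtype=int)
    )
    return pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start": pos,
            "end": pos + 1,
            "name": [f"{track_name}_{i}" for i in range(len(calls))],
            "score": np.clip(score, 0, 1000),
            "strand": calls["strand"],
        }
    )


def plot_profiles(profiles, labels, path, ylabel: str = "n_called") -> None:
    """Overlay window tracks (one line per profile) and save the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    colors = ["red", "green", "blue", "orange"]
    for profile, label, color in zip(profiles, labels, colors):
        mid = (profile.table["start"] + profile.table["end"]) / 2
        ax.plot(mid / 1e6, profile.table[ylabel], label=label, color=color, lw=1)
    ax.set_xlabel("chromosome position (Mbp)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": "bsmethyl"})
    plt.close(fig)


def plot_site_track(bed: pd.DataFrame, path) -> None:
    """Genome-coordinate scatter of called sites, one row per strand."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 2))
    if not bed.empty:
        y = np.where(bed["strand"].to_numpy() == "+", 1.0, 0.0)
        ax.scatter(bed["start"].to_numpy() / 1e6, y, s=4, marker="|", color="black")
    ax.set_yticks([0, 1], ["-", "+"])
    ax.set_ylim(-0.5, 1.5)
    ax.set_xlabel("chromosome position (Mbp)")
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": "bsmethyl"})
    plt.close(fig)
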