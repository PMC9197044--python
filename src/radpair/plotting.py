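"""Optional figure rendering for scans (heatmaps, contours, field sweeps)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

from .scans import AgreementBand, RatioMap, agreement_region

__all__ = ["plot_ratio_map", "plot_field_sweep"]


def plot_ratio_map(
    ratio_map: RatioMap,
    band: AgreementBand | None = None,
    out_path: str | Path | None = None,
):
    """Heatmap of the k–r yield-ratio map, with optional band contours."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    mesh = ax.pcolormesh(
        ratio_map.k_grid_per_s,
        ratio_map.r_grid_per_s,
        ratio_map.ratio,
        shading="nearest",
        cmap="viridis",
    )
    fig.colorbar(mesh, ax=ax, label="triplet yield ratio")
    if band is not None:
        _, contours = agreement_region(ratio_map, band)
        for poly in contours:
            ax.plot(poly[:, 0], poly[:, 1], color="black", lw=1.2)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"reaction rate $k$ (s$^{-1}$)")
    ax.set_ylabel(r"relaxation rate $r$ (s$^{-1}$)")
    ax.set_title(f"{ratio_map.born}-born pair")
    if out_path is not None:
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_field_sweep(sweep: pd.DataFrame, out_path: str | Path | None = None):
    """Triplet yield versus static field magnitude."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.plot(sweep["b_ut"], sweep["phi_t"], lw=1.5)
    ax.set_xlabel(r"magnetic field $B$ ($\mu$T)")
    ax.set_ylabel(r"triplet yield $\Phi_T$")
    if out_path is not None:
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
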