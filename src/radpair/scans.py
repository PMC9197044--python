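"""Parameter scans: k–r yield-ratio maps, field sweeps, agreement regions.

The k–r map evaluates the triplet-yield ratio between two fields on a
grid of kinetics parameters.  Because the eigensystem depends only on
the field, the spectral ingredients (overlap weights and beat
frequencies) are computed once per field and the Lorentzian sum is then
broadcast over the whole grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import find_contours

from .constants import GMF_UT, HMF_UT, K_DEFAULT, R_DEFAULT
from .spin import EigenSystem, RadicalPairSystem
from .yields import Born, KineticsParams, triplet_yield

__all__ = [
    "RatioMap",
    "AgreementBand",
    "default_k_grid",
    "default_r_grid",
    "kr_ratio_map",
    "field_sweep",
    "agreement_region",
]


def default_k_grid(n: int = 60) -> np.ndarray:
    """Logarithmic reaction-rate grid, 10³–10⁷ s⁻¹.

    The upper end stays an order of magnitude below the hyperfine
    frequency scale of the default pair (|a₁|γ_e ≈ 1.4×10⁸ rad/s):
    beyond that the pair reacts before completing a single coherent
    singlet–triplet oscillation and the model leaves the regime it is
    meant to describe.
    """
    return np.logspace(3, 7, n)


def default_r_grid(n: int = 60) -> np.ndarray:
    """Logarithmic relaxation-rate grid, 10³–10⁷ s⁻¹."""
    return np.logspace(3, 7, n)


@dataclass(frozen=True)
class AgreementBand:
    """An experimental target interval, center ± half_width."""

    center: float
    half_width: float

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be non-negative")

    @property
    def lower(self) -> float:
        return self.center - self.half_width

    @property
    def upper(self) -> float:
        return self.center + self.half_width

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class RatioMap:
    """Yield ratio (B_numerator to B_denominator) over the k–r plane.

    ``ratio`` has shape (len(r_grid), len(k_grid)): rows index r, columns
    index k.
    """

    k_grid_per_s: np.ndarray
    r_grid_per_s: np.ndarray
    ratio: np.ndarray
    born: Born
    metadata: dict = field(default_factory=dict)

    def at(self, k_per_s: float, r_per_s: float) -> float:
        """Ratio at the grid cell nearest to (k, r)."""
        i = int(np.argmin(np.abs(self.r_grid_per_s - r_per_s)))
        j = int(np.argmin(np.abs(self.k_grid_per_s - k_per_s)))
        return float(self.ratio[i, j])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns k_per_s, r_per_s, ratio."""
        kk, rr = np.meshgrid(self.k_grid_per_s, self.r_grid_per_s)
        return pd.DataFrame(
            {"k_per_s": kk.ravel(), "r_per_s": rr.ravel(), "ratio": self.ratio.ravel()}
        )

    def save(self, csv_path: str | Path) -> None:
        """Write the long-format CSV plus a JSON metadata sidecar."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        sidecar = csv_path.with_suffix(".meta.json")
        sidecar.write_text(json.dumps({"born": self.born, **self.metadata}, indent=2))


def _phi_grid(
    eig: EigenSystem, k_grid: np.ndarray, r_grid: np.ndarray, born: Born
) -> np.ndarray:
    """Φ_T over the (r, k) grid from one precomputed eigensystem."""
    w, delta = eig.singlet_overlap_weights()
    w_flat = w.ravel()
    keep = w_flat > 1e-18
    w_flat = w_flat[keep]
    d2 = delta.ravel()[keep] ** 2
    m = eig.n_nuclear_configs

    kk = k_grid[None, :]
    rr = r_grid[:, None]
    kr = kk + rr
    out = np.empty((r_grid.size, k_grid.size))
    # chunk over rows to keep the (cells × pairs) temporary modest
    for i0 in range(0, r_grid.size, 8):
        sl = slice(i0, min(i0 + 8, r_grid.size))
        s = kr[sl][..., None]
        f = (w_flat / (s**2 + d2)).sum(axis=-1)
        out[sl] = kk * kr[sl] * f / m  # Σ W·L / M on this block
    if born == "singlet":
        return 0.75 + kk / (4 * kr) - out
    return 0.75 - kk / (12 * kr) + out / 3


def kr_ratio_map(
    system: RadicalPairSystem,
    b_numerator_ut: float = GMF_UT,
    b_denominator_ut: float = HMF_UT,
    k_grid_per_s: Sequence[float] | None = None,
    r_grid_per_s: Sequence[float] | None = None,
    born: Born = "singlet",
) -> RatioMap:
    """Triplet-yield ratio map over the k–r plane.

    Raises
    ------
    FloatingPointError
        If any cell evaluates non-finite or non-positive, naming the
        offending (k, r).
    """
    k_grid = np.asarray(default_k_grid() if k_grid_per_s is None else k_grid_per_s, float)
    r_grid = np.asarray(default_r_grid() if r_grid_per_s is None else r_grid_per_s, float)
    if (k_grid <= 0).any() or (np.diff(k_grid) <= 0).any():
        raise ValueError("k grid must be strictly positive and sorted ascending")
    if (r_grid <= 0).any() or (np.diff(r_grid) <= 0).any():
        raise ValueError("r grid must be strictly positive and sorted ascending")

    eig_num = system.with_field(b_numerator_ut).eigensystem()
    eig_den = system.with_field(b_denominator_ut).eigensystem()
    ratio = _phi_grid(eig_num, k_grid, r_grid, born) / _phi_grid(eig_den, k_grid, r_grid, born)

    bad = ~np.isfinite(ratio) | (ratio <= 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FloatingPointError(
            f"non-finite/non-positive ratio at k={k_grid[j]:.4g}, r={r_grid[i]:.4g}"
        )
    meta = {
        "b_numerator_ut": b_numerator_ut,
        "b_denominator_ut": b_denominator_ut,
        "gamma_e": system.gamma_e,
        "nuclei": [
            {"label": n.label, "spin": n.spin, "hfcc_ut": n.hfcc_ut, "electron": n.electron}
            for n in system.nuclei
        ],
    }
    return RatioMap(k_grid, r_grid, ratio, born, meta)


def field_sweep(
    system: RadicalPairSystem,
    b_values_ut: Sequence[float] | None = None,
    kin: KineticsParams | None = None,
    born: Born = "singlet",
) -> pd.DataFrame:
    """Φ_T as a function of the static field at fixed kinetics.

    Returns a DataFrame with columns ``b_ut`` and ``phi_t``, one row per
    requested field value.  Defaults: 0–1000 μT in 201 points, and
    (k, r) = (2×10⁶, 2×10⁵) s⁻¹.
    """
    if b_values_ut is None:
        b_values_ut = np.linspace(0.0, 1000.0, 201)
    b_values = np.asarray(b_values_ut, dtype=float)
    if (b_values < 0).any():
        raise ValueError("field values must be non-negative")
    kin = kin or KineticsParams(K_DEFAULT, R_DEFAULT)
    phi = [
        triplet_yield(system.with_field(b).eigensystem(), kin, born).phi_t for b in b_values
    ]
    return pd.DataFrame({"b_ut": b_values, "phi_t": phi})


def agreement_region(
    ratio_map: RatioMap, band: AgreementBand
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Cells of a ratio map lying inside an experimental band.

    Returns the boolean mask (same shape as the map) and contour
    polylines at the two band edges as (k, r) coordinate arrays.
    Contours are traced by marching squares on log(ratio) over the
    log-log grid, i.e. linear interpolation in the logarithms.  An empty
    region is a valid scientific outcome, not an error.
    """
    mask = (ratio_map.ratio >= band.lower) & (ratio_map.ratio <= band.upper)
    log_ratio = np.log(ratio_map.ratio)
    log_k = np.log10(ratio_map.k_grid_per_s)
    log_r = np.log10(ratio_map.r_grid_per_s)
    contours: list[np.ndarray] = []
    for edge in (band.lower, band.upper):
        if edge <= 0:
            continue
        for poly in find_contours(log_ratio, np.log(edge)):
            # poly columns are fractional (row, col) = (r-index, k-index)
            k_coords = 10 ** np.interp(poly[:, 1], np.arange(log_k.size), log_k)
            r_coords = 10 ** np.interp(poly[:, 0], np.arange(log_r.size), log_r)
            contours.append(np.column_stack([k_coords, r_coords]))
    return mask, contours
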