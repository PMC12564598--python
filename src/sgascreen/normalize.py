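"""Removal of technical variation from raw colony sizes.

Colony areas on arrayed plates carry multiplicative technical effects:
plate-to-plate pinning differences, smooth within-plate gradients (agar
thickness, temperature, scanner shading), discrete row/column geometry
artifacts, and edge enhancement from reduced nutrient competition.  All
corrections here are therefore multiplicative — ratios to medians — which
keeps the downstream interaction score a clean log-ratio.

The pipeline order is: small/absent-colony QC -> plate-to-plate scaling to
a reference median -> 2-D moving-median spatial smoothing -> row-column
median normalization.  The smooth trend is removed before the discrete
row/column factors are estimated so edge gradients do not contaminate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .plate_io import PlateGrid, REASON_SMALL, logger


@dataclass
class NormalizeConfig:
    """Tunable QC and normalization parameters.

    min_colony_size
        Colonies below this pixel area are masked (strict ``<``); default 50.
    smooth_window
        Odd edge length of the square moving-median window; default 9.
    reference_median
        Target plate median for plate-to-plate scaling, or ``"auto"`` to use
        the grand median of all control-background plates in the batch.
    """

    min_colony_size: int = 50
    smooth_window: int = 9
    reference_median: float | str = "auto"
    flag_exclusions: tuple[str, ...] = ()


@dataclass
class NormalizationResult:
    """A normalized plate together with every correction component.

    The corrected value at any unmasked position is reproducible from the
    stored pieces::

        corrected = raw * scale_factor / (surface_ratio * row_factor * col_factor)

    where ``surface_ratio = surface / smooth_reference``.
    """

    corrected: PlateGrid
    raw: PlateGrid
    surface: np.ndarray
    smooth_reference: float
    scale_factor: float
    row_factors: np.ndarray
    col_factors: np.ndarray

    def reconstruct(self) -> np.ndarray:
        """Recompute corrected sizes from the stored components."""
        surface_ratio = self.surface / self.smooth_reference
        denom = (
            surface_ratio
            * self.row_factors[:, None]
            * self.col_factors[None, :]
        )
        return self.raw.size * self.scale_factor / denom


def filter_small_colonies(grid: PlateGrid, min_size: int = 50) -> PlateGrid:
    """Mask colonies smaller than ``min_size`` pixels (strict ``<``).

    Absent positions keep their reason; newly masked positions gain reason
    ``small``.  Raises ValueError if ``min_size <= 0``.
    """
    if min_size <= 0:
        raise ValueError("min_size must be positive")
    out = grid.copy()
    small = (~out.mask) & (out.size < min_size)
    out.mask |= small
    out.mask_reason[small] = REASON_SMALL
    return out


def scale_plate(grid: PlateGrid, reference_median: float) -> PlateGrid:
    """Rescale all unmasked sizes so the plate median equals the reference."""
    if reference_median <= 0:
        raise ValueError("reference_median must be positive")
    values = grid.unmasked_values()
    if values.size == 0:
        raise ValueError(f"plate {grid.plate_id}: no unmasked positions to scale")
    factor = reference_median / float(np.median(values))
    out = grid.copy()
    out.size[~out.mask] *= factor
    return out


def median_smooth(
    grid: PlateGrid, window: int = 9
) -> tuple[PlateGrid, np.ndarray, float]:
    """Estimate and divide out a smooth spatial trend via moving medians.

    ``surface[r, c]`` is the median of unmasked sizes in the ``window`` x
    ``window`` neighborhood of (r, c), truncated at plate borders (no
    padding — padding would fabricate data at the edge, exactly where the
    bias is strongest).  Corrected sizes are ``size * plate_median /
    surface``; a neighborhood with no unmasked positions falls back to the
    plate median (logged).

    Returns
    -------
    (corrected_grid, surface, plate_median)
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if window > min(grid.n_rows, grid.n_cols):
        raise ValueError("window exceeds the plate format")
    values = grid.unmasked_values()
    if values.size == 0:
        raise ValueError(f"plate {grid.plate_id}: no unmasked positions")
    plate_median = float(np.median(values))

    half = window // 2
    nr, nc = grid.n_rows, grid.n_cols
    surface = np.empty((nr, nc))
    n_empty = 0
    size, mask = grid.size, grid.mask
    for r in range(nr):
        r0, r1 = max(0, r - half), min(nr, r + half + 1)
        for c in range(nc):
            c0, c1 = max(0, c - half), min(nc, c + half + 1)
            win = size[r0:r1, c0:c1][~mask[r0:r1, c0:c1]]
            if win.size == 0:
                surface[r, c] = plate_median
                n_empty += 1
            else:
                surface[r, c] = np.median(win)
    if n_empty:
        logger.warning(
            "plate %s: %d fully masked neighborhoods fell back to the plate "
            "median", grid.plate_id, n_empty,
        )

    out = grid.copy()
    unm = ~out.mask
    out.size[unm] = size[unm] * plate_median / surface[unm]
    return out, surface, plate_median


def rowcol_median_normalize(
    grid: PlateGrid,
) -> tuple[PlateGrid, np.ndarray, np.ndarray]:
    """Divide out per-row then per-column median factors.

    Row factors are medians of each row relative to the plate median,
    applied first; column factors are then recomputed on the row-corrected
    plate.  A fully masked row or column gets factor 1 with a warning.

    Returns
    -------
    (corrected_grid, row_factors, col_factors)
    """
    out = grid.copy()
    unm = ~out.mask
    if unm.sum() == 0:
        raise ValueError(f"plate {grid.plate_id}: no unmasked positions")

    plate_median = float(np.median(out.size[unm]))
    row_factors = np.ones(grid.n_rows)
    for r in range(grid.n_rows):
        vals = out.size[r][unm[r]]
        if vals.size == 0:
            logger.warning("plate %s: row %d fully masked, factor 1",
                           grid.plate_id, r + 1)
            continue
        row_factors[r] = np.median(vals) / plate_median
    out.size[unm] = (out.size / row_factors[:, None])[unm]

    plate_median2 = float(np.median(out.size[unm]))
    col_factors = np.ones(grid.n_cols)
    for c in range(grid.n_cols):
        vals = out.size[:, c][unm[:, c]]
        if vals.size == 0:
            logger.warning("plate %s: column %d fully masked, factor 1",
                           grid.plate_id, c + 1)
            continue
        col_factors[c] = np.median(vals) / plate_median2
    out.size[unm] = (out.size / col_factors[None, :])[unm]

    return out, row_factors, col_factors


def normalize_plate(
    grid: PlateGrid,
    config: NormalizeConfig | None = None,
    reference_median: float | None = None,
) -> NormalizationResult:
    """Full spatial normalization of one QC-filtered plate.

    Applies plate scaling, moving-median smoothing, and row-column median
    normalization, in that order, and records every component so the
    corrected values can be reconstructed exactly.

    Parameters
    ----------
    grid
        A QC-filtered plate (absent/small positions already masked).
    config
        Normalization parameters; defaults used when None.
    reference_median
        Overrides ``config.reference_median``; ``None`` with config
        ``"auto"`` scales the plate to its own median (factor 1 only when
        the plate median already equals it).
    """
    config = config or NormalizeConfig()
    if reference_median is None:
        ref = config.reference_median
        if ref == "auto":
            vals = grid.unmasked_values()
            if vals.size == 0:
                raise ValueError(f"plate {grid.plate_id}: no unmasked positions")
            reference_median = float(np.median(vals))
        else:
            reference_median = float(ref)

    scaled = scale_plate(grid, reference_median)
    scale_factor = reference_median / float(np.median(grid.unmasked_values()))
    smoothed, surface, smooth_ref = median_smooth(scaled, config.smooth_window)
    corrected, row_f, col_f = rowcol_median_normalize(smoothed)

    return NormalizationResult(
        corrected=corrected,
        raw=grid,
        surface=surface,
        smooth_reference=smooth_ref,
        scale_factor=scale_factor,
        row_factors=row_f,
        col_factors=col_f,
    )


def batch_reference_median(grids) -> float:
    """Grand median of unmasked sizes across all control-background plates.

    Falls back to all plates when none is labelled ``control``.
    """
    control = [g for g in grids if g.background == "control"]
    pool = control if control else list(grids)
    values = np.concatenate([g.unmasked_values() for g in pool])
    if values.size == 0:
        raise ValueError("no unmasked positions in the batch")
    return float(np.median(values))
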