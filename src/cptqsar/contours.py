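"""stdev*coeff contour volumes and favored/disfavored region extraction.

After the final PLS fit, each retained grid column gets the score
sd(column) * coefficient — the classic "stdev*coeff" field used to draw
CoMFA contour maps.  Regions where the score is high favor the property the
column measures (bulk for the steric field, positive charge for the
electrostatic field with a +1 probe); low-score regions disfavor it.
Contour levels are set at percentiles of the signed score distribution over
the retained points; the conventional display uses the 80th percentile for
favored and the 20th for disfavored regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError
from .fields import GridSpec
from .pls import PLSModel

__all__ = [
    "ContourVolume",
    "ContourSet",
    "stdev_coeff_volume",
    "percentile_contours",
    "write_dx",
    "write_contour_csv",
    "write_contour_pdb",
]


@dataclass
class ContourVolume:
    """Per-grid-point stdev*coeff scores for one field block.

    ``values`` has one entry per grid point; points whose column was dropped
    by the minimum-sigma filter carry NaN.
    """

    grid: GridSpec
    field_kind: str
    values: np.ndarray

    @property
    def retained(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class ContourSet:
    """Grid points above/below the contribution-percentile thresholds."""

    field_kind: str
    levels: tuple[float, float]  # (high %, low %)
    favored_threshold: float
    disfavored_threshold: float
    favored_points: np.ndarray  # (k, 3) coordinates
    disfavored_points: np.ndarray
    favored_scores: np.ndarray
    disfavored_scores: np.ndarray


def stdev_coeff_volume(
    model: PLSModel, field_kind: str, grid: GridSpec | None = None
) -> ContourVolume:
    """Map sd * coefficient of each retained column back onto the grid.

    The standard deviation is that of the scaled training column, the
    coefficient the fitted PLS coefficient in the same space, so the score
    reflects each point's share of the explained activity variation.
    """
    blocks = model.design.blocks
    known = set(str(b) for b in np.unique(blocks))
    if field_kind not in known:
        raise SchemaError(f"unknown field kind {field_kind!r}; have {sorted(known)}")
    # field-matrix columns are [steric block | electrostatic block] of equal
    # length; a generic single-block design maps one-to-one
    if field_kind in ("steric", "electrostatic"):
        n_points = model.design.n_original_columns // 2
        offset = 0 if field_kind == "steric" else n_points
    else:
        n_points = model.design.n_original_columns
        offset = 0
    values = np.full(n_points, np.nan)
    sd = model.design.X.std(axis=0, ddof=1)
    score = sd * model.coefficients
    for j, col in enumerate(model.design.kept):
        if str(blocks[j]) != field_kind:
            continue
        values[col - offset] = score[j]
    return ContourVolume(grid=grid, field_kind=field_kind, values=values)


def percentile_contours(
    volume: ContourVolume, high: float = 80.0, low: float = 20.0
) -> ContourSet:
    """Extract favored/disfavored point sets at signed-score percentiles.

    Thresholds are the ``high`` and ``low`` percentiles of the score
    distribution over retained points; points strictly above the high
    threshold are favored, strictly below the low threshold disfavored
    (strict inequalities keep a constant volume from producing spurious
    contours).
    """
    if not 0 <= low < high <= 100:
        raise ValueError("need 0 <= low < high <= 100")
    mask = volume.retained
    scores = volume.values[mask]
    if scores.size == 0:
        raise SchemaError("volume has no retained points")
    hi_thr = float(np.percentile(scores, high))
    lo_thr = float(np.percentile(scores, low))
    if volume.grid is not None:
        pts = volume.grid.points()
    else:
        pts = np.full((volume.values.size, 3), np.nan)
    fav = mask & (volume.values > hi_thr)
    dis = mask & (volume.values < lo_thr)
    return ContourSet(
        field_kind=volume.field_kind,
        levels=(high, low),
        favored_threshold=hi_thr,
        disfavored_threshold=lo_thr,
        favored_points=pts[fav],
        disfavored_points=pts[dis],
        favored_scores=volume.values[fav],
        disfavored_scores=volume.values[dis],
    )


# ---------------------------------------------------------------------------
# exports for standard volumetric viewers


def write_dx(volume: ContourVolume, path) -> None:
    """OpenDX scalar-field export (dropped points written as 0)."""
    grid = volume.grid
    if grid is None:
        raise SchemaError("volume has no grid attached")
    nx, ny, nz = grid.shape
    vals = np.where(np.isfinite(volume.values), volume.values, 0.0)
    ax = np.asarray(grid.axes) * grid.spacing
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*grid.origin))
        for row in ax:
            fh.write("delta {:.6f} {:.6f} {:.6f}\n".format(*row))
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {vals.size} data follows\n"
        )
        for i in range(0, vals.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in vals[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def write_contour_csv(contours: ContourSet, path) -> None:
    rows = []
    for cls, pts, scores in (
        ("favored", contours.favored_points, contours.favored_scores),
        ("disfavored", contours.disfavored_points, contours.disfavored_scores),
    ):
        for p, s in zip(pts, scores):
            rows.append(
                {"x": p[0], "y": p[1], "z": p[2], "score": s, "class": cls}
            )
    pd.DataFrame(rows, columns=["x", "y", "z", "score", "class"]).to_csv(
        path, index=False
    )


def write_contour_pdb(contours: ContourSet, path) -> None:
    """Pseudo-atom export: He for favored points, Ne for disfavored."""
    with open(path, "w") as fh:
        serial = 1
        for elem, pts in (
            ("HE", contours.favored_points),
            ("NE", contours.disfavored_points),
        ):
            for p in pts:
                fh.write(
                    f"HETATM{serial:>5} {elem:<3} CNT A{serial % 9999:>4}    "
                    f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00          "
                    f"{elem:>2}\n"
                )
                serial += 1
        fh.write("END\n")
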