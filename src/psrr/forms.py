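"""Relationship-form maps and productivity-by-form summaries.

A location's productivity-richness relationship form is read off the 95%
credible interval of the local slope: ``positive`` if the interval lies
above zero, ``negative`` if below, otherwise ``non-existent``.  The overlap
rule is inclusive — an interval touching zero counts as non-existent — and a
cell is "statistically important" exactly when its form is not non-existent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .grids import RasterGrid
from .svc import SVCPosterior, predict_coefficients

__all__ = [
    "classify_form",
    "FormGrid",
    "build_form_grid",
    "summarize_by_form",
    "FORM_CODES",
]

FORM_CODES = {"negative": -1, "non-existent": 0, "positive": 1}


def classify_form(q025, q975):
    """Classify a slope's form from its 95% credible bounds.

    Vectorized; returns a string for scalars, an object array otherwise.
    """
    lo = np.asarray(q025, dtype=float)
    hi = np.asarray(q975, dtype=float)
    if np.any(lo > hi):
        raise ValueError("credible bounds out of order (q2.5 > q97.5)")
    out = np.full(lo.shape, "non-existent", dtype=object)
    out[lo > 0] = "positive"
    out[hi < 0] = "negative"
    return out if out.ndim else str(out)


@dataclass
class FormGrid:
    """Regular grid of slope posteriors and form labels."""

    table: pd.DataFrame  # x_km, y_km, beta_median, beta_q025, beta_q975, form, important
    resolution_km: float
    origin: tuple[float, float]
    shape: tuple[int, int]
    valid_mask: np.ndarray  # (rows, cols) bool, True where the cell is classified

    def raster(self, column: str) -> RasterGrid:
        """Render a column back onto the grid (NaN outside the study area)."""
        arr = np.full(self.shape, np.nan)
        rows = self.table["_row"].to_numpy()
        cols = self.table["_col"].to_numpy()
        if column == "form":
            vals = self.table["form"].map(FORM_CODES).to_numpy(dtype=float)
        else:
            vals = self.table[column].to_numpy(dtype=float)
        arr[rows, cols] = vals
        return RasterGrid(arr, self.resolution_km, self.origin)

    def check_invariants(self) -> None:
        t = self.table
        if not ((t["form"] != "non-existent") == t["important"]).all():
            raise AssertionError("importance flag inconsistent with form")
        pos = t["form"] == "positive"
        neg = t["form"] == "negative"
        if not (t.loc[pos, "beta_q025"] > 0).all():
            raise AssertionError("positive cell with lower bound <= 0")
        if not (t.loc[neg, "beta_q975"] < 0).all():
            raise AssertionError("negative cell with upper bound >= 0")


def build_form_grid(
    fit: SVCPosterior,
    resolution_km: float = 40.0,
    extent: Polygon | None = None,
) -> FormGrid:
    """Classify slope posteriors on a regular grid over the study area.

    Cell centers outside the study polygon (default: the mesh's interior
    hull) or outside the mesh extension are masked out.
    """
    poly = extent if extent is not None else fit.mesh.interior_boundary
    minx, miny, maxx, maxy = poly.bounds
    origin = (minx, miny)
    n_cols = max(int(np.ceil((maxx - minx) / resolution_km)), 1)
    n_rows = max(int(np.ceil((maxy - miny) / resolution_km)), 1)
    xs = minx + (np.arange(n_cols) + 0.5) * resolution_km
    ys = miny + (np.arange(n_rows) + 0.5) * resolution_km
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel())
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside &= fit.mesh.contains(pts)
    valid = inside.reshape(n_rows, n_cols)
    sel = pts[inside]
    pred = predict_coefficients(fit, sel)
    form = classify_form(pred["beta_q025"], pred["beta_q975"])
    rows, cols = np.nonzero(valid)
    table = pd.DataFrame(
        {
            "x_km": sel[:, 0],
            "y_km": sel[:, 1],
            "beta_median": pred["beta_median"],
            "beta_q025": pred["beta_q025"],
            "beta_q975": pred["beta_q975"],
            "form": form,
            "important": form != "non-existent",
            "_row": rows,
            "_col": cols,
        }
    )
    grid = FormGrid(
        table=table,
        resolution_km=resolution_km,
        origin=origin,
        shape=(n_rows, n_cols),
        valid_mask=valid,
    )
    grid.check_invariants()
    return grid


def summarize_by_form(
    measure: RasterGrid,
    fit: SVCPosterior,
    form_grid: FormGrid | None = None,
) -> pd.DataFrame:
    """Boxplot statistics of a productivity measure by relationship form.

    Every valid measure cell (non-nodata, inside the mesh extension) is
    classified at its center — directly from the posterior projector, or by
    nearest-cell lookup in ``form_grid`` when one is given — and per-form
    five-number summaries are computed.  Whiskers use the 1.5*IQR
    convention; values beyond them are counted as outliers but remain in
    ``n``, so per-form counts partition the valid cells.
    """
    xx, yy = measure.center_mesh()
    vals = measure.values
    finite = np.isfinite(vals)
    pts = np.column_stack([xx[finite], yy[finite]])
    v = vals[finite]
    in_mesh = fit.mesh.contains(pts)
    pts, v = pts[in_mesh], v[in_mesh]
    if form_grid is not None:
        col = np.clip(
            ((pts[:, 0] - form_grid.origin[0]) / form_grid.resolution_km).astype(int),
            0,
            form_grid.shape[1] - 1,
        )
        row = np.clip(
            ((pts[:, 1] - form_grid.origin[1]) / form_grid.resolution_km).astype(int),
            0,
            form_grid.shape[0] - 1,
        )
        code = form_grid.raster("form").values[row, col]
        keep = np.isfinite(code)
        pts, v, code = pts[keep], v[keep], code[keep]
        inv = {c: f for f, c in FORM_CODES.items()}
        forms = np.array([inv[int(c)] for c in code], dtype=object)
    else:
        pred = predict_coefficients(fit, pts)
        forms = classify_form(pred["beta_q025"], pred["beta_q975"])
    rows = []
    for form in ("negative", "non-existent", "positive"):
        sel = v[forms == form]
        if sel.size == 0:
            rows.append(
                dict(form=form, n=0, min=np.nan, q25=np.nan, median=np.nan,
                     q75=np.nan, max=np.nan, n_outliers=0)
            )
            continue
        q25, med, q75 = np.quantile(sel, [0.25, 0.5, 0.75])
        iqr = q75 - q25
        outliers = (sel < q25 - 1.5 * iqr) | (sel > q75 + 1.5 * iqr)
        rows.append(
            dict(
                form=form,
                n=int(sel.size),
                min=float(sel.min()),
                q25=float(q25),
                median=float(med),
                q75=float(q75),
                max=float(sel.max()),
                n_outliers=int(outliers.sum()),
            )
        )
    return pd.DataFrame(rows)
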