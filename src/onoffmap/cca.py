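"""Canonical correlation alignment of cortical (3-D) and visual (2-D)
coordinates, and the cortical-visual fluctuation-map correlation test.

CCA finds centered projections ``xhat = (x - xbar) A`` (3 -> 2) and
``yhat = (y - ybar) B`` (2 -> 2) such that matching canonical coordinates are
maximally correlated, non-matching pairs are uncorrelated, and every
canonical variable has unit sample variance.  The cortical depth coordinate
is included so the projection can compensate for a slight tilt of the imaging
plane relative to the cortical surface.  Solved via the whitened
cross-covariance SVD; sign convention: all canonical correlations >= 0,
ordered descending.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .domains import (Grid, _difference_values, _kernel_rows, _rowwise_corr,
                      canonical_grid, field_correlation, SIGMA_CANONICAL)
from .errors import ParameterError


@dataclass
class CcaModel:
    """Fitted CCA: centering vectors, projections and canonical correlations."""

    mean_x: np.ndarray           # (3,) um
    mean_y: np.ndarray           # (2,) deg
    A: np.ndarray                # (3, 2) cortical -> canonical
    B: np.ndarray                # (2, 2) visual -> canonical
    rho: np.ndarray              # (2,), descending, >= 0
    n_cells: int

    def to_json(self, path) -> None:
        obj = dict(format_version=1, mean_x=self.mean_x.tolist(),
                   mean_y=self.mean_y.tolist(), A=self.A.tolist(),
                   B=self.B.tolist(), rho=self.rho.tolist(),
                   n_cells=self.n_cells)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CcaModel":
        with open(path) as fh:
            obj = json.load(fh)
        if obj.get("format_version") != 1:
            raise ParameterError("unknown CCA model format version")
        return cls(mean_x=np.array(obj["mean_x"]), mean_y=np.array(obj["mean_y"]),
                   A=np.array(obj["A"]), B=np.array(obj["B"]),
                   rho=np.array(obj["rho"]), n_cells=int(obj["n_cells"]))


def _check_full_rank(m: np.ndarray, name: str) -> None:
    c = m - m.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[-1] < 1e-10 * max(s[0], 1.0):
        # name the degenerate direction by the dominant coefficient
        _, _, vt = np.linalg.svd(c)
        col = int(np.argmax(np.abs(vt[-1])))
        raise ParameterError(
            f"{name} coordinates are rank deficient (column {col} is "
            "linearly dependent on the others)")


def fit_cca(cortical_xyz: np.ndarray, visual_yy: np.ndarray) -> CcaModel:
    """Fit CCA between (n, 3) cortical and (n, 2) visual coordinates.

    Deterministic for fixed input.  Canonical coordinates computed on the
    fitting data have unit sample variance (``ddof=1``) and the non-matching
    pairs are uncorrelated to numerical precision.
    """
    X = np.asarray(cortical_xyz, dtype=float)
    Y = np.asarray(visual_yy, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ParameterError("cortical coordinates must be (n, 3)")
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise ParameterError("visual coordinates must be (n, 2)")
    n = len(X)
    if len(Y) != n:
        raise ParameterError("cortical and visual tables differ in length")
    if n < 10:
        raise ParameterError("CCA requires at least 10 cells")
    _check_full_rank(X, "cortical")
    _check_full_rank(Y, "visual")

    mean_x = X.mean(axis=0)
    mean_y = Y.mean(axis=0)
    Xc = X - mean_x
    Yc = Y - mean_y
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    # whitening by inverse matrix square roots (symmetric)
    Wx = linalg.inv(linalg.sqrtm(Sxx).real)
    Wy = linalg.inv(linalg.sqrtm(Syy).real)
    U, s, Vt = np.linalg.svd(Wx @ Sxy @ Wy)
    k = 2
    A = Wx @ U[:, :k]
    B = Wy @ Vt.T[:, :k]
    rho = np.clip(s[:k], 0.0, 1.0)
    return CcaModel(mean_x=mean_x, mean_y=mean_y, A=A, B=B, rho=rho, n_cells=n)


def transform(points: np.ndarray, model: CcaModel, which: str) -> np.ndarray:
    """Project points into canonical coordinates: ``(p - mean) @ A`` or ``B``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if which == "cortical":
        if pts.shape[1] != 3:
            raise ParameterError("cortical points must have 3 columns")
        return (pts - model.mean_x) @ model.A
    if which == "visual":
        if pts.shape[1] != 2:
            raise ParameterError("visual points must have 2 columns")
        return (pts - model.mean_y) @ model.B
    raise ParameterError("which must be 'cortical' or 'visual'")


@dataclass
class MapCorrelation:
    """Cortical-visual fluctuation correlation in canonical space."""

    r: float
    p_value: float
    values_cortical: np.ndarray
    values_visual: np.ndarray
    grid: Grid
    n_shuffles: int


def map_correlation(labels: np.ndarray,
                    xhat: np.ndarray,
                    yhat: np.ndarray,
                    sigma: float = SIGMA_CANONICAL,
                    grid: Grid | None = None,
                    n_shuffles: int = 1000,
                    seed: int = 0) -> MapCorrelation:
    """Correlation between cortical and visual ON/OFF fluctuation maps.

    ``labels`` is boolean (True = ON) over mono-contrast cells; ``xhat`` and
    ``yhat`` are their canonical cortical and visual coordinates.  The null
    distribution jointly shuffles the labels (each cell keeps both coordinate
    pairs) and recomputes both maps; p is the fraction of null |r| at least
    the observed |r|.
    """
    lab = np.asarray(labels, dtype=bool)
    n_on, n_off = int(lab.sum()), int((~lab).sum())
    if n_on == 0 or n_off == 0:
        raise ParameterError("need both ON and OFF cells for a fluctuation map")
    if grid is None:
        grid = canonical_grid()
    rows_x = _kernel_rows(np.asarray(xhat, dtype=float), sigma, grid)
    rows_y = _kernel_rows(np.asarray(yhat, dtype=float), sigma, grid)
    w = np.where(lab, 1.0 / n_on, -1.0 / n_off)
    vx = _difference_values(w, rows_x)
    vy = _difference_values(w, rows_y)
    r = field_correlation(vx, vy)

    rng = np.random.default_rng(seed)
    W = np.stack([w[rng.permutation(len(w))] for _ in range(n_shuffles)])
    r_null = _rowwise_corr(W @ rows_x, W @ rows_y)
    p = (1.0 + np.sum(np.abs(r_null) >= abs(r))) / (n_shuffles + 1.0)
    return MapCorrelation(r=r, p_value=float(p),
                          values_cortical=vx.reshape(grid.shape),
                          values_visual=vy.reshape(grid.shape),
                          grid=grid, n_shuffles=n_shuffles)


def polarity_cca(cells: pd.DataFrame) -> dict:
    """Fit CCA separately on mono ON and mono OFF cells of one dataset.

    ``cells`` needs ``cell_class, x1, x2, x3`` and per-polarity centres
    ``on_y1, on_y2`` / ``off_y1, off_y2``.  Returns ``{"ON": rho, "OFF": rho}``
    (each a length-2 array).  A polarity with fewer than 10 cells is skipped.
    """
    out = {}
    for cls, c1, c2 in (("ON", "on_y1", "on_y2"), ("OFF", "off_y1", "off_y2")):
        sub = cells[cells.cell_class == cls]
        if len(sub) < 10:
            continue
        model = fit_cca(sub[["x1", "x2", "x3"]].to_numpy(),
                        sub[[c1, c2]].to_numpy())
        out[cls] = model.rho
    return out


def polarity_cca_comparison(datasets: list[pd.DataFrame]) -> dict:
    """Per-polarity canonical correlations across datasets, with a paired
    sign-rank comparison of OFF vs ON (pairing each dataset's rho1 and rho2).

    Datasets where either polarity has fewer than 10 cells are excluded.
    """
    on_rhos, off_rhos = [], []
    n_excluded = 0
    for df in datasets:
        res = polarity_cca(df)
        if "ON" not in res or "OFF" not in res:
            n_excluded += 1
            continue
        on_rhos.append(res["ON"])
        off_rhos.append(res["OFF"])
    if not on_rhos:
        raise ParameterError("no dataset has enough cells of both polarities")
    on_arr = np.vstack(on_rhos)
    off_arr = np.vstack(off_rhos)
    diffs = (off_arr - on_arr).ravel()
    if np.allclose(diffs, 0.0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diffs).pvalue)
    return dict(rho_on=on_arr, rho_off=off_arr, p_value=p,
                n_datasets=len(on_rhos), n_excluded=n_excluded)
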