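"""Reverse-correlation kernel estimation, Gaussian fits and cell classification.

The ON kernel of a cell at delay ``t`` is the average response ``t`` frames
after onset of presentations in which a given tile was bright; the OFF kernel
conditions on dark tiles.  Kernels are summarised by the normalised norm curve
``S(t) = ||K(t)|| / ||K(0)||`` (Frobenius norm); a polarity is significant
when the curve peaks above ``norm_threshold`` and a 2-D Gaussian fit of the
peak-delay map explains at least ``ve_threshold`` of its variance.  Cells with
both significant polarities split into simple and complex by the normalised
distance between the fitted centres.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DegenerateBaselineError, ParameterError
from .synthetic import ResponseMatrix, StimulusEnsemble

log = logging.getLogger(__name__)

POLARITIES = ("ON", "OFF")


@dataclass
class KernelStack:
    """Per-cell, per-polarity response-average maps across delays."""

    cell_id: int
    polarity: str
    maps: np.ndarray             # (max_delay + 1, n_rows, n_cols)

    @property
    def max_delay(self) -> int:
        return self.maps.shape[0] - 1

    @property
    def peak_delay(self) -> int:
        return norm_curve(self)[1]

    @property
    def peak_map(self) -> np.ndarray:
        return self.maps[self.peak_delay]


@dataclass
class KernelSet:
    """Dense container of ON and OFF kernel stacks for a whole population."""

    on: np.ndarray               # (n_cells, max_delay + 1, n_rows, n_cols)
    off: np.ndarray
    tile_deg: float

    @property
    def n_cells(self) -> int:
        return self.on.shape[0]

    def stack(self, cell: int, polarity: str) -> KernelStack:
        if polarity not in POLARITIES:
            raise ParameterError(f"polarity must be one of {POLARITIES}")
        maps = self.on[cell] if polarity == "ON" else self.off[cell]
        return KernelStack(cell_id=cell, polarity=polarity, maps=maps)


def estimate_kernels(responses: ResponseMatrix,
                     stimulus: StimulusEnsemble,
                     max_delay: int = 15) -> KernelSet:
    """Event-triggered averages over the ``max_delay`` frames following onset.

    ``maps[t, i, j]`` is the mean activity at ``onset + t`` over presentations
    whose tile (i, j) was bright (ON) or dark (OFF).  Tiles never flashed in a
    state are flagged with a warning and imputed as 0.
    """
    onsets = np.asarray(stimulus.onset_frame_index)
    if onsets[-1] + max_delay >= responses.n_frames:
        raise ParameterError(
            "response record too short: last onset plus max_delay exceeds "
            f"{responses.n_frames} frames")
    T = stimulus.n_stimuli
    delays = np.arange(max_delay + 1)
    # (cells, T, delays)
    r = responses.activity[:, onsets[:, None] + delays[None, :]]
    out = {}
    for pol, state in (("ON", 1), ("OFF", -1)):
        mask = (stimulus.frames == state).reshape(T, -1).astype(float)
        counts = mask.sum(axis=0)
        if np.any(counts == 0):
            warnings.warn(
                f"{int((counts == 0).sum())} tile(s) never flashed "
                f"{'bright' if state == 1 else 'dark'}; kernel entries imputed as 0")
        safe = np.maximum(counts, 1.0)
        maps = np.einsum("ctd,tp->cdp", r, mask) / safe
        maps[:, :, counts == 0] = 0.0
        out[pol] = maps.reshape(responses.n_cells, max_delay + 1,
                                stimulus.n_rows, stimulus.n_cols)
    return KernelSet(on=out["ON"], off=out["OFF"], tile_deg=stimulus.tile_deg)


def norm_curve(stack: KernelStack) -> tuple[np.ndarray, int]:
    """Normalised norm curve ``S(t) = ||K(t)|| / ||K(0)||`` and its argmax.

    Ties in the argmax break toward the smaller delay.  A zero norm at delay
    zero with signal elsewhere is floored at a machine-epsilon scale of the
    largest norm (a situation only noiseless simulations produce); a stack
    that is zero everywhere raises :class:`DegenerateBaselineError`.
    """
    norms = np.linalg.norm(stack.maps.reshape(stack.maps.shape[0], -1), axis=1)
    n0 = norms[0]
    if n0 == 0.0:
        if norms.max() == 0.0:
            raise DegenerateBaselineError(
                f"cell {stack.cell_id} {stack.polarity}: kernel stack is zero everywhere")
        n0 = np.finfo(float).eps * norms.max()
        log.info("cell %s %s: ||K(0)|| = 0, floored at %.3g",
                 stack.cell_id, stack.polarity, n0)
    s = norms / n0
    return s, int(np.argmax(s))


def delay_to_ms(frames: float, frame_rate: float) -> float:
    """Convert a delay in microscope frames to milliseconds."""
    return 1000.0 * frames / frame_rate


@dataclass
class Gauss2D:
    """Elliptical 2-D Gaussian fit of a kernel map, in tile coordinates.

    ``center`` is (col, row) in continuous tile units; multiply by the tile
    size (and add half a tile) to obtain degrees.  ``sigmas`` are the two
    principal standard deviations, also in tiles.
    """

    center: tuple[float, float]
    sigmas: tuple[float, float]
    orientation: float
    amplitude: float
    offset: float
    variance_explained: float
    success: bool = True

    @property
    def mean_sigma(self) -> float:
        return 0.5 * (self.sigmas[0] + self.sigmas[1])

    def center_deg(self, tile_deg: float) -> tuple[float, float]:
        """(y1, y2) = (azimuth, elevation) of the centre in degrees."""
        return ((self.center[0] + 0.5) * tile_deg,
                (self.center[1] + 0.5) * tile_deg)


def _gauss_model(params: np.ndarray, jj: np.ndarray, ii: np.ndarray) -> np.ndarray:
    amp, x0, y0, sx, sy, theta, off = params
    ct, st = np.cos(theta), np.sin(theta)
    u = (jj - x0) * ct + (ii - y0) * st
    v = -(jj - x0) * st + (ii - y0) * ct
    return off + amp * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))


def _gauss_jac(params: np.ndarray, jj: np.ndarray, ii: np.ndarray) -> np.ndarray:
    amp, x0, y0, sx, sy, theta, _off = params
    ct, st = np.cos(theta), np.sin(theta)
    u = (jj - x0) * ct + (ii - y0) * st
    v = -(jj - x0) * st + (ii - y0) * ct
    E = np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))
    aE = amp * E
    cols = [
        E,                                               # d/d amp
        aE * ((u / sx ** 2) * ct - (v / sy ** 2) * st),  # d/d x0
        aE * ((u / sx ** 2) * st + (v / sy ** 2) * ct),  # d/d y0
        aE * u ** 2 / sx ** 3,                           # d/d sx
        aE * v ** 2 / sy ** 3,                           # d/d sy
        aE * u * v * (1.0 / sy ** 2 - 1.0 / sx ** 2),    # d/d theta
        np.ones_like(E),                                 # d/d offset
    ]
    return np.column_stack([c.ravel() for c in cols])


def fit_gauss2d(map2d: np.ndarray,
                allow_rotation: bool = True,
                with_offset: bool = True) -> Gauss2D:
    """Least-squares elliptical Gaussian (with constant offset) fit of a map.

    Initialised from image moments; the centre is bounded within one tile
    beyond the grid.  Non-convergence returns a fit marked failed with
    ``variance_explained = 0``.
    """
    m = np.asarray(map2d, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ParameterError("map contains non-finite values")
    if np.ptp(m) == 0.0:
        raise ParameterError("map is constant; Gaussian fit undefined")
    n_rows, n_cols = m.shape
    ii, jj = np.mgrid[0:n_rows, 0:n_cols].astype(float)

    off0 = float(np.median(m)) if with_offset else 0.0
    r = m - off0
    peak = r.flat[np.argmax(np.abs(r))]
    w = np.clip(np.sign(peak) * r, 0.0, None)
    wsum = w.sum()
    if wsum == 0:
        w = np.abs(r)
        wsum = w.sum()
    x0 = float((w * jj).sum() / wsum)
    y0 = float((w * ii).sum() / wsum)
    sx = float(np.sqrt(max((w * (jj - x0) ** 2).sum() / wsum, 0.25)))
    sy = float(np.sqrt(max((w * (ii - y0) ** 2).sum() / wsum, 0.25)))
    p0 = np.array([peak, x0, y0, sx, sy, 0.0, off0])

    smax = float(max(n_rows, n_cols))
    lo = [-np.inf, -1.0, -1.0, 0.2, 0.2, -np.pi, -np.inf]
    hi = [np.inf, n_cols, n_rows, smax, smax, np.pi, np.inf]
    if not allow_rotation:
        lo[5], hi[5], p0[5] = -1e-9, 1e-9, 0.0
    if not with_offset:
        lo[6], hi[6], p0[6] = -1e-9, 1e-9, 0.0
    p0 = np.clip(p0, lo, hi)

    def resid(p):
        return (_gauss_model(p, jj, ii) - m).ravel()

    try:
        sol = optimize.least_squares(resid, p0, bounds=(lo, hi), method="trf",
                                     jac=lambda p: _gauss_jac(p, jj, ii),
                                     max_nfev=200)
        success = sol.success
        p = sol.x
    except Exception:      # pragma: no cover - defensive
        success = False
        p = p0
    ss_tot = float(((m - m.mean()) ** 2).sum())
    ss_res = float((resid(p) ** 2).sum())
    ve = max(0.0, 1.0 - ss_res / ss_tot) if success else 0.0
    return Gauss2D(center=(float(p[1]), float(p[2])),
                   sigmas=(abs(float(p[3])), abs(float(p[4]))),
                   orientation=float(p[5]), amplitude=float(p[0]),
                   offset=float(p[6]), variance_explained=min(ve, 1.0),
                   success=bool(success))


CLASS_NONE = "NONE"


@dataclass
class CellClassification:
    """Outcome of the significance rule and the simple/complex split."""

    cell_id: int
    has_on: bool
    has_off: bool
    cell_class: str              # ON, OFF, SIMPLE, COMPLEX or NONE
    normalized_distance: float = np.nan
    s_max_on: float = np.nan
    s_max_off: float = np.nan
    peak_delay_on: int = -1
    peak_delay_off: int = -1


def _polarity_significant(stack: KernelStack | None, fit: Gauss2D | None,
                          norm_threshold: float, ve_threshold: float
                          ) -> tuple[bool, float, int]:
    if stack is None:
        return False, np.nan, -1
    try:
        s, peak = norm_curve(stack)
    except DegenerateBaselineError:
        return False, np.nan, -1
    s_max = float(s.max())
    ok = (s_max > norm_threshold
          and fit is not None and fit.success
          and fit.variance_explained >= ve_threshold)
    return ok, s_max, peak


def classify_cell(on_stack: KernelStack | None,
                  on_fit: Gauss2D | None,
                  off_stack: KernelStack | None,
                  off_fit: Gauss2D | None,
                  norm_threshold: float = 5.0,
                  ve_threshold: float = 0.5,
                  simple_threshold: float = 0.5) -> CellClassification:
    """Apply the significance rule per polarity and split dual cells.

    A polarity is significant when its norm curve peaks above
    ``norm_threshold`` and the Gaussian fit of the peak-delay map explains at
    least ``ve_threshold`` of the variance.  Dual cells are SIMPLE when the
    normalised distance between centres (distance divided by the mean of the
    two fits' average sigmas) exceeds ``simple_threshold``, COMPLEX otherwise.
    """
    has_on, s_on, pk_on = _polarity_significant(on_stack, on_fit,
                                                norm_threshold, ve_threshold)
    has_off, s_off, pk_off = _polarity_significant(off_stack, off_fit,
                                                   norm_threshold, ve_threshold)
    cid = next((s.cell_id for s in (on_stack, off_stack) if s is not None), -1)
    nd = np.nan
    if has_on and has_off:
        d = float(np.hypot(on_fit.center[0] - off_fit.center[0],
                           on_fit.center[1] - off_fit.center[1]))
        sbar = 0.5 * (on_fit.mean_sigma + off_fit.mean_sigma)
        nd = d / sbar
        cls = "SIMPLE" if nd > simple_threshold else "COMPLEX"
    elif has_on:
        cls = "ON"
    elif has_off:
        cls = "OFF"
    else:
        cls = CLASS_NONE
    return CellClassification(cell_id=cid, has_on=has_on, has_off=has_off,
                              cell_class=cls, normalized_distance=nd,
                              s_max_on=s_on, s_max_off=s_off,
                              peak_delay_on=pk_on, peak_delay_off=pk_off)


def simple_rf(on_stack: KernelStack, off_stack: KernelStack) -> np.ndarray:
    """Signed receptive field: peak-delay ON map minus peak-delay OFF map."""
    if on_stack is None or off_stack is None:
        raise ParameterError("simple_rf requires both an ON and an OFF stack")
    return on_stack.peak_map - off_stack.peak_map


def classify_population(responses: ResponseMatrix,
                        stimulus: StimulusEnsemble,
                        max_delay: int = 15,
                        norm_threshold: float = 5.0,
                        ve_threshold: float = 0.5,
                        simple_threshold: float = 0.5,
                        cortical: pd.DataFrame | None = None
                        ) -> tuple[pd.DataFrame, KernelSet]:
    """Estimate kernels, fit Gaussians and classify every cell.

    Returns the cell table (one row per neuron; centres and sigmas in
    degrees, NaN where a polarity is not significant) and the kernel set.
    If ``cortical`` is given (columns ``cell_id, x1, x2, x3``) it is merged
    into the table.
    """
    kset = estimate_kernels(responses, stimulus, max_delay=max_delay)
    td = kset.tile_deg
    rows = []
    n_excluded = 0
    for c in range(kset.n_cells):
        fits = {}
        stacks = {}
        for pol in POLARITIES:
            st = kset.stack(c, pol)
            stacks[pol] = st
            try:
                s, peak = norm_curve(st)
                # a polarity that fails the norm test cannot become
                # significant, so its Gaussian fit is not needed
                if s.max() > norm_threshold:
                    fits[pol] = fit_gauss2d(st.maps[peak])
                else:
                    fits[pol] = None
            except (DegenerateBaselineError, ParameterError):
                fits[pol] = None
        cl = classify_cell(stacks["ON"], fits["ON"], stacks["OFF"], fits["OFF"],
                           norm_threshold, ve_threshold, simple_threshold)
        row = dict(cell_id=c, cell_class=cl.cell_class,
                   has_on=cl.has_on, has_off=cl.has_off,
                   s_max_on=cl.s_max_on, s_max_off=cl.s_max_off,
                   peak_delay_on=cl.peak_delay_on, peak_delay_off=cl.peak_delay_off,
                   normalized_distance=cl.normalized_distance)
        for pol, pref in (("ON", "on"), ("OFF", "off")):
            f = fits[pol]
            sig = cl.has_on if pol == "ON" else cl.has_off
            if sig and f is not None:
                y1, y2 = f.center_deg(td)
                row[f"{pref}_y1"], row[f"{pref}_y2"] = y1, y2
                row[f"sigma_{pref}_deg"] = f.mean_sigma * td
                row[f"ve_{pref}"] = f.variance_explained
            else:
                row[f"{pref}_y1"] = row[f"{pref}_y2"] = np.nan
                row[f"sigma_{pref}_deg"] = np.nan
                row[f"ve_{pref}"] = (f.variance_explained
                                     if f is not None else np.nan)
        if cl.cell_class == CLASS_NONE:
            n_excluded += 1
        rows.append(row)
    table = pd.DataFrame(rows)
    if n_excluded:
        log.info("classification: %d of %d cells have no significant kernel "
                 "and are excluded downstream", n_excluded, kset.n_cells)
    if cortical is not None:
        missing = {"cell_id", "x1", "x2", "x3"} - set(cortical.columns)
        if missing:
            raise ParameterError(f"cortical table lacks columns {sorted(missing)}")
        table = table.merge(cortical[["cell_id", "x1", "x2", "x3"]], on="cell_id")
    return table, kset


def aggregate_retinotopy(sector_signals: np.ndarray,
                         probe_positions: np.ndarray,
                         probe_grid_shape: tuple[int, int]) -> np.ndarray:
    """Coarse retinotopy from a 3 x 3 sectorisation of the field of view.

    ``sector_signals`` is (9, n_trials): the average evoked signal of each
    sector on each probe trial.  ``probe_positions`` is (n_trials, 2) integer
    (row, col) probe locations on a probe grid.  Each sector's aggregate map
    is the trial-triggered average per probe location; its centre is the
    centroid of the map thresholded at half its maximum.  Returns an array of
    shape (3, 3, 2) with (row, col) centres, NaN where the aggregate map is
    flat.
    """
    sig = np.asarray(sector_signals, dtype=float)
    pos = np.asarray(probe_positions, dtype=int)
    if sig.shape[0] != 9:
        raise ParameterError("sector_signals must have 9 rows (3 x 3 sectors)")
    if pos.shape != (sig.shape[1], 2):
        raise ParameterError("probe_positions must be (n_trials, 2)")
    nr, nc = probe_grid_shape
    centers = np.full((3, 3, 2), np.nan)
    flat_idx = pos[:, 0] * nc + pos[:, 1]
    for s in range(9):
        sums = np.bincount(flat_idx, weights=sig[s], minlength=nr * nc)
        counts = np.bincount(flat_idx, minlength=nr * nc)
        with np.errstate(invalid="ignore"):
            amap = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        amap = amap.reshape(nr, nc)
        if np.ptp(amap) == 0.0:
            continue
        thr = 0.5 * amap.max()
        mask = amap >= thr
        w = amap * mask
        ii, jj = np.mgrid[0:nr, 0:nc]
        centers[s // 3, s % 3] = [(w * ii).sum() / w.sum(),
                                  (w * jj).sum() / w.sum()]
    return centers
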