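"""Synthetic ground truth: bias fields, retinotopy, virtual cell populations,
sparse-noise stimuli and linear-nonlinear-Poisson responses.

The generator emulates the statistical structure a volumetric two-photon
experiment in mouse V1 delivers to the analysis: a smooth ON/OFF bias over the
visual field, an affine retinotopy with per-cell scatter (larger for ON than
OFF cells), mono-contrast / simple / complex receptive fields, ternary
sparse-noise stimulation, and event-like responses at a fixed delay after
stimulus onset.

Geometry conventions (used everywhere in the package):

* Stimulus tiles are indexed ``(row, col)`` = (elevation, azimuth), row-major,
  0-based, azimuth increasing rightward.  The tile centre in degrees is
  ``y1 = (col + 0.5) * tile_deg`` (azimuth) and ``y2 = (row + 0.5) * tile_deg``
  (elevation).
* Visual coordinates ``(y1, y2)`` are degrees of visual angle; cortical
  coordinates ``(x1, x2, x3)`` are micrometres, ``x3`` being depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError

# Stimulus grid geometry: 18 x 8 tiles of ~8 deg each.
N_ROWS = 8
N_COLS = 18
TILE_DEG = 8.0
FRAME_RATE = 15.6  # microscope frames per second
FOV_UM = (900.0, 540.0)  # imaged field of view, (x1, x2) in um

#: Visual extent of the stimulated field, (y1_min, y1_max, y2_min, y2_max) deg.
VISUAL_EXTENT = (0.0, N_COLS * TILE_DEG, 0.0, N_ROWS * TILE_DEG)

CLASS_ON = "ON"
CLASS_OFF = "OFF"
CLASS_SIMPLE = "SIMPLE"
CLASS_COMPLEX = "COMPLEX"


def tile_centers_deg(n_rows: int = N_ROWS, n_cols: int = N_COLS,
                     tile_deg: float = TILE_DEG) -> tuple[np.ndarray, np.ndarray]:
    """Return (Y1, Y2) arrays of shape (n_rows, n_cols) with tile centres in deg."""
    cols = (np.arange(n_cols) + 0.5) * tile_deg
    rows = (np.arange(n_rows) + 0.5) * tile_deg
    y1, y2 = np.meshgrid(cols, rows)
    return y1, y2


@dataclass(frozen=True)
class BiasField:
    """Smooth scalar field b(y1, y2) in [-1, 1] over the visual field.

    b > 0 marks ON-dominant regions, b < 0 OFF-dominant ones.  The field is a
    sum of signed Gaussian bumps plus a constant global imbalance, clipped to
    [-1, 1].
    """

    extent: tuple[float, float, float, float]
    centers: np.ndarray          # (n_bumps, 2) degrees
    heights: np.ndarray          # (n_bumps,), signed
    length_scale: float          # degrees
    imbalance: float = 0.0

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the field at ``points`` of shape (..., 2)."""
        pts = np.asarray(points, dtype=float)
        out = np.full(pts.shape[:-1], self.imbalance, dtype=float)
        for c, h in zip(self.centers, self.heights):
            d2 = np.sum((pts - c) ** 2, axis=-1)
            out += h * np.exp(-0.5 * d2 / self.length_scale ** 2)
        return np.clip(out, -1.0, 1.0)

    def values(self, spacing: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sample the field on a regular grid; returns (y1_nodes, y2_nodes, b)."""
        y1 = np.arange(self.extent[0], self.extent[1] + 0.5 * spacing, spacing)
        y2 = np.arange(self.extent[2], self.extent[3] + 0.5 * spacing, spacing)
        g1, g2 = np.meshgrid(y1, y2, indexing="ij")
        pts = np.stack([g1, g2], axis=-1)
        return y1, y2, self.evaluate(pts)


def make_bias_field(extent: tuple[float, float, float, float] = VISUAL_EXTENT,
                    n_blobs: int = 6,
                    amplitude: float = 0.5,
                    length_scale: float = 20.0,
                    seed: int = 0,
                    imbalance: float = 0.0) -> BiasField:
    """Draw a random ON/OFF bias field as a sum of signed Gaussian bumps.

    Parameters
    ----------
    extent:
        (y1_min, y1_max, y2_min, y2_max) rectangle in degrees.
    n_blobs:
        Number of bumps.  Signs alternate between +1 and -1 in random order so
        the expected spatial mean stays near ``imbalance``.
    amplitude:
        Peak height of each bump, in [0, 1].  ``amplitude=0`` yields the
        uniform field ``b == imbalance`` (zero by default).
    length_scale:
        Gaussian width of the bumps, degrees.  Must be positive.
    """
    if length_scale <= 0:
        raise ParameterError("length_scale must be positive")
    if not 0.0 <= amplitude <= 1.0:
        raise ParameterError("amplitude must lie in [0, 1]")
    if extent[1] <= extent[0] or extent[3] <= extent[2]:
        raise ParameterError("extent is degenerate")
    rng = np.random.default_rng(seed)
    centers = np.column_stack([
        rng.uniform(extent[0], extent[1], size=n_blobs),
        rng.uniform(extent[2], extent[3], size=n_blobs),
    ])
    signs = np.ones(n_blobs)
    signs[1::2] = -1.0
    rng.shuffle(signs)
    heights = amplitude * signs
    if amplitude == 0.0:
        heights = np.zeros(n_blobs)
    return BiasField(extent=tuple(extent), centers=centers, heights=heights,
                     length_scale=float(length_scale), imbalance=float(imbalance))


@dataclass(frozen=True)
class RetinotopyModel:
    """Affine map from visual degrees to cortical micrometres with scatter.

    ``cortical = visual @ affine + offset`` (row-vector convention), then
    class-specific Gaussian scatter is added in (x1, x2) and a depth plane is
    drawn uniformly from ``depth_planes``.
    """

    affine: np.ndarray            # (2, 2), deg -> um
    offset: np.ndarray            # (2,), um
    scatter_sigma_on: float       # um
    scatter_sigma_off: float      # um
    depth_planes: np.ndarray      # um, >= 1 plane

    def __post_init__(self):
        a = np.asarray(self.affine, dtype=float)
        if a.shape != (2, 2) or abs(np.linalg.det(a)) < 1e-12:
            raise ParameterError("retinotopy affine must be an invertible 2x2 matrix")
        if self.scatter_sigma_on < self.scatter_sigma_off:
            raise ParameterError(
                "scatter_sigma_on must be >= scatter_sigma_off "
                "(ON cells have the larger retinotopic scatter)")
        if len(np.atleast_1d(self.depth_planes)) < 1:
            raise ParameterError("at least one depth plane is required")

    def visual_to_cortical(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.affine + self.offset


def default_retinotopy(scatter_sigma_on: float = 40.0,
                       scatter_sigma_off: float = 25.0,
                       n_planes: int = 6,
                       plane_spacing_um: float = 30.0,
                       top_depth_um: float = 150.0) -> RetinotopyModel:
    """Retinotopy matching the imaging geometry: the 144 x 64 deg stimulated
    field maps onto a 900 x 540 um field of view; planes every 30 um."""
    affine = np.diag([FOV_UM[0] / (VISUAL_EXTENT[1] - VISUAL_EXTENT[0]),
                      FOV_UM[1] / (VISUAL_EXTENT[3] - VISUAL_EXTENT[2])])
    planes = top_depth_um + plane_spacing_um * np.arange(n_planes)
    return RetinotopyModel(affine=affine, offset=np.zeros(2),
                           scatter_sigma_on=scatter_sigma_on,
                           scatter_sigma_off=scatter_sigma_off,
                           depth_planes=planes)


def gaussian_rf_map(center_deg: np.ndarray, sigma_deg: float,
                    n_rows: int = N_ROWS, n_cols: int = N_COLS,
                    tile_deg: float = TILE_DEG) -> np.ndarray:
    """Isotropic Gaussian receptive-field map sampled at tile centres, peak 1."""
    y1, y2 = tile_centers_deg(n_rows, n_cols, tile_deg)
    d2 = (y1 - center_deg[0]) ** 2 + (y2 - center_deg[1]) ** 2
    return np.exp(-0.5 * d2 / sigma_deg ** 2)


@dataclass
class GroundTruthPopulation:
    """A virtual population with known classes, maps, centres and wiring.

    ``cells`` has one row per neuron with columns ``cell_id``, ``true_class``,
    ``x1``, ``x2``, ``x3`` (um), and per-polarity true centres
    ``on_y1, on_y2, off_y1, off_y2`` in degrees (NaN where the polarity is
    absent).  ``on_maps`` / ``off_maps`` hold the true per-polarity spatial
    maps on the stimulus grid (zero where absent).  ``mixing`` records, for
    composite (simple) cells, the mono-contrast component ids and weights.
    """

    cells: pd.DataFrame
    on_maps: np.ndarray          # (n_cells, n_rows, n_cols)
    off_maps: np.ndarray
    mixing: dict = field(default_factory=dict)   # cell_id -> {"on": [(id, w)], "off": [...]}
    bias_field: BiasField | None = None
    retinotopy: RetinotopyModel | None = None
    rf_sigma_deg: float = 6.0
    seed: int | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def signed_rf(self, index: int) -> np.ndarray:
        """True signed receptive field (ON map minus OFF map) of one cell."""
        return self.on_maps[index] - self.off_maps[index]


def _sample_biased_centers(bias: BiasField, sign: int, n: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample RF centres with density proportional to (1 + sign*b)."""
    if n == 0:
        return np.empty((0, 2))
    e = bias.extent
    spacing = max(min(bias.length_scale / 5.0, 4.0), 0.5)
    _, _, b = bias.values(spacing=spacing)
    g = 1.0 + sign * b
    g_max = float(g.max())
    if g_max <= 1e-9:
        pol = "ON" if sign > 0 else "OFF"
        raise GenerationError(
            f"{pol} sampling density vanishes everywhere (bias saturated "
            f"at {-sign:+.0f}); the requested density is unnormalizable")
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(4 * (n - len(out)), 64)
        cand = np.column_stack([rng.uniform(e[0], e[1], m),
                                rng.uniform(e[2], e[3], m)])
        accept = rng.random(m) < (1.0 + sign * bias.evaluate(cand)) / g_max
        out = np.vstack([out, cand[accept]])
    return out[:n]


def sample_population(bias: BiasField,
                      retinotopy: RetinotopyModel,
                      n_on: int = 450,
                      n_off: int = 900,
                      n_simple: int = 150,
                      n_complex: int = 150,
                      seed: int = 0,
                      rf_sigma_deg: float = 6.0,
                      max_components: int = 3,
                      weight_concentration: float = 0.3,
                      min_separation: float = 0.9,
                      max_attempts: int = 200) -> GroundTruthPopulation:
    """Draw a ground-truth population under a bias field and retinotopy.

    Mono-contrast ON / OFF receptive-field centres are drawn with density
    proportional to ``1 + b`` and ``1 - b`` respectively; cortical positions
    are the affine image of the centre plus class-specific scatter and a
    random depth plane.  Simple cells are non-negative combinations of at most
    ``max_components`` nearby mono ON and OFF cells (weights from a sparse
    Dirichlet prior), constrained to have their ON and OFF sub-region
    centroids separated by at least ``min_separation`` times the component
    sigma.  Complex cells carry co-centred ON and OFF Gaussians (separation
    zero).
    """
    for name, v in [("n_on", n_on), ("n_off", n_off),
                    ("n_simple", n_simple), ("n_complex", n_complex)]:
        if v < 0:
            raise ParameterError(f"{name} must be >= 0")
    if n_simple > 0 and (n_on < 1 or n_off < 1):
        raise GenerationError(
            "simple cells require at least one mono ON and one mono OFF cell "
            f"(got n_on={n_on}, n_off={n_off})")
    rng = np.random.default_rng(seed)
    e = bias.extent
    planes = np.atleast_1d(retinotopy.depth_planes)
    scatter_mix = 0.5 * (retinotopy.scatter_sigma_on + retinotopy.scatter_sigma_off)

    rows: list[dict] = []
    on_maps: list[np.ndarray] = []
    off_maps: list[np.ndarray] = []
    mixing: dict[int, dict] = {}
    zero_map = np.zeros((N_ROWS, N_COLS))
    next_id = 0

    def cortical(center: np.ndarray, sigma: float) -> np.ndarray:
        xy = retinotopy.visual_to_cortical(center)[0] + rng.normal(0.0, sigma, 2)
        return np.array([xy[0], xy[1], rng.choice(planes)])

    # --- mono-contrast cells ---------------------------------------------
    for sign, n_req, cls, sigma in [(+1, n_on, CLASS_ON, retinotopy.scatter_sigma_on),
                                    (-1, n_off, CLASS_OFF, retinotopy.scatter_sigma_off)]:
        centers = _sample_biased_centers(bias, sign, n_req, rng)
        for c in centers:
            x = cortical(c, sigma)
            m = gaussian_rf_map(c, rf_sigma_deg)
            is_on = cls == CLASS_ON
            rows.append(dict(cell_id=next_id, true_class=cls,
                             x1=x[0], x2=x[1], x3=x[2],
                             on_y1=c[0] if is_on else np.nan,
                             on_y2=c[1] if is_on else np.nan,
                             off_y1=np.nan if is_on else c[0],
                             off_y2=np.nan if is_on else c[1]))
            on_maps.append(m if is_on else zero_map)
            off_maps.append(zero_map if is_on else m)
            next_id += 1

    mono = pd.DataFrame(rows)
    mono_on = mono[mono.true_class == CLASS_ON]
    mono_off = mono[mono.true_class == CLASS_OFF]

    # --- simple cells: sparse pooling of nearby mono components ----------
    for _ in range(n_simple):
        ok = False
        for _attempt in range(max_attempts):
            center = np.array([rng.uniform(e[0], e[1]), rng.uniform(e[2], e[3])])
            x = cortical(center, scatter_mix)
            comp = {}
            cent = {}
            for pol, pool in (("on", mono_on), ("off", mono_off)):
                d = np.sqrt((pool.x1 - x[0]) ** 2 + (pool.x2 - x[1]) ** 2
                            + (pool.x3 - x[2]) ** 2)
                m = min(max_components, len(pool))
                idx = np.lexsort((pool.cell_id.to_numpy(), d.to_numpy()))[:m]
                sub = pool.iloc[idx]
                w = rng.dirichlet(np.full(m, weight_concentration))
                comp[pol] = list(zip(sub.cell_id.to_numpy(), w))
                cc = sub[[f"{pol}_y1", f"{pol}_y2"]].to_numpy()
                cent[pol] = w @ cc
            sep = np.linalg.norm(cent["on"] - cent["off"]) / rf_sigma_deg
            if sep >= min_separation:
                ok = True
                break
        if not ok:
            raise GenerationError(
                "could not construct a simple cell with the required ON/OFF "
                f"sub-region separation after {max_attempts} attempts")
        om = sum(w * np.asarray(on_maps[int(i)]) for i, w in comp["on"])
        fm = sum(w * np.asarray(off_maps[int(i)]) for i, w in comp["off"])
        rows.append(dict(cell_id=next_id, true_class=CLASS_SIMPLE,
                         x1=x[0], x2=x[1], x3=x[2],
                         on_y1=cent["on"][0], on_y2=cent["on"][1],
                         off_y1=cent["off"][0], off_y2=cent["off"][1]))
        on_maps.append(om)
        off_maps.append(fm)
        mixing[next_id] = comp
        next_id += 1

    # --- complex cells: co-centred ON and OFF Gaussians -------------------
    for _ in range(n_complex):
        center = np.array([rng.uniform(e[0], e[1]), rng.uniform(e[2], e[3])])
        x = cortical(center, scatter_mix)
        m = gaussian_rf_map(center, rf_sigma_deg)
        rows.append(dict(cell_id=next_id, true_class=CLASS_COMPLEX,
                         x1=x[0], x2=x[1], x3=x[2],
                         on_y1=center[0], on_y2=center[1],
                         off_y1=center[0], off_y2=center[1]))
        on_maps.append(m)
        off_maps.append(m)
        next_id += 1

    cells = pd.DataFrame(rows)
    return GroundTruthPopulation(
        cells=cells,
        on_maps=np.stack(on_maps) if on_maps else np.zeros((0, N_ROWS, N_COLS)),
        off_maps=np.stack(off_maps) if off_maps else np.zeros((0, N_ROWS, N_COLS)),
        mixing=mixing, bias_field=bias, retinotopy=retinotopy,
        rf_sigma_deg=rf_sigma_deg, seed=seed)


@dataclass(frozen=True)
class StimulusEnsemble:
    """Ternary sparse-noise ensemble, one frame row per flashed image.

    ``frames[t, i, j]`` in {-1, 0, +1} is the luminance state of tile (i, j)
    during presentation ``t``; ``onset_frame_index[t]`` is the microscope
    frame at which that presentation began.  The 166 ms flash is collapsed to
    its onset frame; kernels are indexed by delay from onset.
    """

    frames: np.ndarray               # (T, n_rows, n_cols) int8
    onset_frame_index: np.ndarray    # (T,) int
    frame_rate: float = FRAME_RATE
    tile_deg: float = TILE_DEG
    p_bright: float = 0.1
    p_dark: float = 0.1
    flash_duration_ms: float = 166.0
    presentation_rate: float = 1.0

    @property
    def n_stimuli(self) -> int:
        return self.frames.shape[0]

    @property
    def n_rows(self) -> int:
        return self.frames.shape[1]

    @property
    def n_cols(self) -> int:
        return self.frames.shape[2]

    def scalar_metadata(self) -> dict:
        return dict(frame_rate=self.frame_rate, tile_deg=self.tile_deg,
                    p_bright=self.p_bright, p_dark=self.p_dark,
                    flash_duration_ms=self.flash_duration_ms,
                    presentation_rate=self.presentation_rate)


def make_stimulus(n_stimuli: int = 1500,
                  p_bright: float = 0.1,
                  p_dark: float = 0.1,
                  frame_rate: float = FRAME_RATE,
                  seed: int = 0,
                  presentation_rate: float = 1.0,
                  n_rows: int = N_ROWS,
                  n_cols: int = N_COLS) -> StimulusEnsemble:
    """Draw i.i.d. ternary frames: bright/dark with the given probabilities,
    gray otherwise, independent across tiles and presentations."""
    if p_bright < 0 or p_dark < 0 or p_bright + p_dark > 1:
        raise ParameterError("need p_bright, p_dark >= 0 and p_bright + p_dark <= 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n_stimuli, n_rows, n_cols))
    frames = np.zeros((n_stimuli, n_rows, n_cols), dtype=np.int8)
    frames[u < p_bright] = 1
    frames[(u >= p_bright) & (u < p_bright + p_dark)] = -1
    spacing = int(round(frame_rate / presentation_rate))
    onsets = spacing * np.arange(n_stimuli)
    return StimulusEnsemble(frames=frames, onset_frame_index=onsets,
                            frame_rate=frame_rate, p_bright=p_bright,
                            p_dark=p_dark, presentation_rate=presentation_rate)


def expected_tile_statistics(n_stimuli: int, p: float) -> tuple[float, float]:
    """Binomial mean and SD of the per-tile count of one luminance state."""
    return n_stimuli * p, float(np.sqrt(n_stimuli * p * (1.0 - p)))


def session_presentations(duration_min: float, rate_per_s: float = 1.0) -> int:
    """Number of presentations in a session of the given length."""
    return int(round(duration_min * 60.0 * rate_per_s))


@dataclass(frozen=True)
class ResponseMatrix:
    """Deconvolved-style activity: non-negative event rates, cells x frames."""

    activity: np.ndarray         # (n_cells, n_frames), >= 0
    frame_rate: float = FRAME_RATE

    def __post_init__(self):
        a = np.asarray(self.activity)
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ParameterError("activity must be finite and non-negative")

    @property
    def n_cells(self) -> int:
        return self.activity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.activity.shape[1]


def stimulus_drive(population: GroundTruthPopulation,
                   stimulus: StimulusEnsemble) -> np.ndarray:
    """Per-cell, per-presentation drive of the LN front end.

    Linear cells (ON, OFF, SIMPLE) half-rectify the summed overlap of their
    ON map with bright tiles and OFF map with dark tiles; complex cells sum
    two separately rectified subunits.
    """
    if population.on_maps.shape[1:] != stimulus.frames.shape[1:]:
        raise ParameterError(
            f"population RF grid {population.on_maps.shape[1:]} does not match "
            f"stimulus grid {stimulus.frames.shape[1:]}")
    bright = (stimulus.frames == 1).reshape(stimulus.n_stimuli, -1).astype(float)
    dark = (stimulus.frames == -1).reshape(stimulus.n_stimuli, -1).astype(float)
    on_flat = population.on_maps.reshape(population.n_cells, -1)
    off_flat = population.off_maps.reshape(population.n_cells, -1)
    on_drive = on_flat @ bright.T          # (cells, T)
    off_drive = off_flat @ dark.T
    is_complex = (population.cells.true_class == CLASS_COMPLEX).to_numpy()
    drive = np.maximum(on_drive + off_drive, 0.0)
    drive[is_complex] = (np.maximum(on_drive[is_complex], 0.0)
                         + np.maximum(off_drive[is_complex], 0.0))
    return drive


def simulate_responses(population: GroundTruthPopulation,
                       stimulus: StimulusEnsemble,
                       gain: float = 2.0,
                       baseline: float = 0.08,
                       delay_frames: int = 5,
                       delay_jitter: int = 0,
                       noise_model: str = "poisson",
                       seed: int = 0) -> ResponseMatrix:
    """Simulate event-like activity with a fixed response delay.

    Each presentation contributes Poisson(gain * drive) events placed
    ``delay_frames`` after its onset (plus an integer jitter drawn uniformly
    from [-delay_jitter, delay_jitter]); every frame additionally carries
    Poisson(``baseline``) noise.  ``noise_model='none'`` replaces both draws
    with their deterministic expectations, which is useful for impulse-style
    checks.
    """
    if delay_frames < 0:
        raise ParameterError("delay_frames must be >= 0")
    if gain < 0:
        raise ParameterError("gain must be >= 0")
    if noise_model not in ("poisson", "none"):
        raise ParameterError(f"unknown noise_model {noise_model!r}")
    drive = stimulus_drive(population, stimulus)
    rng = np.random.default_rng(seed)
    spacing = int(round(stimulus.frame_rate / stimulus.presentation_rate))
    n_frames = int(stimulus.onset_frame_index[-1]) + spacing + delay_frames + 1
    n_cells = population.n_cells

    if noise_model == "poisson":
        activity = rng.poisson(baseline, size=(n_cells, n_frames)).astype(float)
        evoked = rng.poisson(gain * drive).astype(float)
    else:
        activity = np.full((n_cells, n_frames), baseline, dtype=float)
        evoked = gain * drive

    t_idx = stimulus.onset_frame_index + delay_frames
    if delay_jitter > 0:
        t_idx = t_idx + rng.integers(-delay_jitter, delay_jitter + 1,
                                     size=stimulus.n_stimuli)
        t_idx = np.clip(t_idx, 0, n_frames - 1)
    np.add.at(activity, (slice(None), t_idx), evoked)
    return ResponseMatrix(activity=activity, frame_rate=stimulus.frame_rate)
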