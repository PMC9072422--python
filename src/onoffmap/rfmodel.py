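"""Receptive-field structure analyses: population composition, mean-RF
comparison, per-cell diversity, and the non-negative k-nearest-neighbour
model of simple-cell receptive fields.

The neighbourhood model regresses each simple cell's signed receptive field
(ON kernel minus OFF kernel) on the receptive fields of its k nearest mono
ON and k nearest mono OFF cells, with non-negative weights.  ON neighbour
maps enter the design with a positive sign and OFF maps with a negative
sign, so non-negative weights build an ON-minus-OFF field.  Weights are
solved by active-set non-negative least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ParameterError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# population composition
# ---------------------------------------------------------------------------

@dataclass
class CompositionSummary:
    """Pooled counts and whole-percent fractions of cell classes."""

    n_on: int
    n_off: int
    n_dual: int
    n_simple: int
    n_complex: int

    @property
    def n_total(self) -> int:
        return self.n_on + self.n_off + self.n_dual

    @property
    def pct_on(self) -> int:
        return round(100.0 * self.n_on / self.n_total)

    @property
    def pct_off(self) -> int:
        return round(100.0 * self.n_off / self.n_total)

    @property
    def pct_dual(self) -> int:
        return round(100.0 * self.n_dual / self.n_total)

    @property
    def pct_simple_of_dual(self) -> float:
        return 100.0 * self.n_simple / self.n_dual if self.n_dual else np.nan

    def fractions(self) -> dict:
        t = self.n_total
        return dict(on=self.n_on / t, off=self.n_off / t, dual=self.n_dual / t)


def population_composition(table: pd.DataFrame) -> CompositionSummary:
    """Pool per-dataset class counts into one composition summary.

    ``table`` needs columns ``n_on, n_off, n_dual`` and optionally
    ``n_simple, n_complex``.  Counts must be non-negative integers.
    """
    if len(table) == 0:
        raise ParameterError("empty count table")
    cols = ["n_on", "n_off", "n_dual"]
    missing = set(cols) - set(table.columns)
    if missing:
        raise ParameterError(f"count table lacks columns {sorted(missing)}")
    opt = [c for c in ("n_simple", "n_complex") if c in table.columns]
    counts = table[cols + opt]
    if (counts.to_numpy() < 0).any():
        raise ParameterError("counts must be non-negative")
    tot = counts.sum()
    return CompositionSummary(
        n_on=int(tot["n_on"]), n_off=int(tot["n_off"]), n_dual=int(tot["n_dual"]),
        n_simple=int(tot.get("n_simple", 0)), n_complex=int(tot.get("n_complex", 0)))


def composition_from_cells(cells: pd.DataFrame) -> CompositionSummary:
    """Composition of a classified cell table (column ``cell_class``)."""
    vc = cells.cell_class.value_counts()
    n_simple = int(vc.get("SIMPLE", 0))
    n_complex = int(vc.get("COMPLEX", 0))
    return CompositionSummary(n_on=int(vc.get("ON", 0)),
                              n_off=int(vc.get("OFF", 0)),
                              n_dual=n_simple + n_complex,
                              n_simple=n_simple, n_complex=n_complex)


# ---------------------------------------------------------------------------
# mean receptive-field comparison and diversity
# ---------------------------------------------------------------------------

def _map_corr(a: np.ndarray, b: np.ndarray) -> float:
    av, bv = np.ravel(a), np.ravel(b)
    if np.std(av) == 0 or np.std(bv) == 0:
        raise ParameterError("correlation undefined for a constant map")
    return float(np.corrcoef(av, bv)[0, 1])


@dataclass
class MeanRfSummary:
    """Population-mean maps and the mu_on - mu_off vs mu_s correlation."""

    mu_on: np.ndarray
    mu_off: np.ndarray
    mu_s: np.ndarray
    r_mean: float
    p_value: float


def mean_rf_comparison(on_maps: np.ndarray,
                       off_maps: np.ndarray,
                       simple_rfs: np.ndarray,
                       n_permutations: int = 1000,
                       seed: int = 0) -> MeanRfSummary:
    """Correlate the mean simple-cell RF with the mean ON minus mean OFF map.

    The permutation p recomputes the correlation after randomly reassigning
    the pooled per-cell maps to the three groups with group sizes fixed.
    """
    for name, arr in (("on_maps", on_maps), ("off_maps", off_maps),
                      ("simple_rfs", simple_rfs)):
        if len(arr) == 0:
            raise ParameterError(f"{name} is empty")
    mu_on = np.mean(on_maps, axis=0)
    mu_off = np.mean(off_maps, axis=0)
    mu_s = np.mean(simple_rfs, axis=0)
    r = _map_corr(mu_on - mu_off, mu_s)

    pool = np.concatenate([on_maps, off_maps, simple_rfs], axis=0)
    n1, n2 = len(on_maps), len(off_maps)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(pool))
        a = pool[perm[:n1]].mean(axis=0)
        b = pool[perm[n1:n1 + n2]].mean(axis=0)
        s = pool[perm[n1 + n2:]].mean(axis=0)
        try:
            rp = _map_corr(a - b, s)
        except ParameterError:
            continue
        if abs(rp) >= abs(r):
            count += 1
    p = (1.0 + count) / (n_permutations + 1.0)
    return MeanRfSummary(mu_on=mu_on, mu_off=mu_off, mu_s=mu_s,
                         r_mean=r, p_value=float(p))


@dataclass
class RfDiversity:
    """Per-cell correlations against the mean simple-cell RF."""

    correlations: np.ndarray
    p_signrank: float
    excluded: int

    @property
    def corr_range(self) -> tuple[float, float]:
        return float(self.correlations.min()), float(self.correlations.max())


def rf_diversity(simple_rfs: np.ndarray, mu_s: np.ndarray) -> RfDiversity:
    """Distribution of per-cell Pearson correlations vs the population mean,
    with a two-tailed one-sample sign-rank test of median > 0."""
    if len(simple_rfs) < 2:
        raise ParameterError("need at least 2 simple cells")
    rs = []
    excluded = 0
    for m in simple_rfs:
        try:
            rs.append(_map_corr(m, mu_s))
        except ParameterError:
            excluded += 1
            log.info("rf_diversity: constant RF map excluded")
    rs = np.asarray(rs)
    if np.allclose(rs, 0.0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(rs).pvalue)
    return RfDiversity(correlations=rs, p_signrank=p, excluded=excluded)


# ---------------------------------------------------------------------------
# k-nearest-neighbour non-negative model
# ---------------------------------------------------------------------------

def knn_neighbors(target_xyz: np.ndarray,
                  mono_cells: pd.DataFrame,
                  k: int) -> dict:
    """k nearest mono ON and k nearest mono OFF cells by 3-D Euclidean
    distance in cortical micrometres; ties break by cell id.

    ``mono_cells`` needs columns ``cell_id, cell_class, x1, x2, x3``.
    Returns ``{"ON": (ids, distances), "OFF": (ids, distances)}``.
    """
    t = np.asarray(target_xyz, dtype=float)
    out = {}
    for pol in ("ON", "OFF"):
        pool = mono_cells[mono_cells.cell_class == pol]
        if len(pool) < k:
            raise ParameterError(
                f"need {k} mono {pol} cells, only {len(pool)} available")
        xyz = pool[["x1", "x2", "x3"]].to_numpy()
        d = np.sqrt(((xyz - t) ** 2).sum(axis=1))
        ids = pool.cell_id.to_numpy()
        order = np.lexsort((ids, d))[:k]
        out[pol] = (ids[order], d[order])
    return out


@dataclass
class NeighborhoodFit:
    """NNLS decomposition of one simple cell's RF over its neighbourhood."""

    cell_id: int
    k: int
    neighbor_ids: dict           # {"ON": ids, "OFF": ids}
    distances: dict              # {"ON": um, "OFF": um}
    weights: dict                # {"ON": w, "OFF": w}, non-negative
    fit_corr: float
    model_rf: np.ndarray

    def normalized_weights(self, polarity: str) -> np.ndarray:
        """Same-polarity weights sorted descending, normalised to sum 1."""
        w = np.sort(self.weights[polarity])[::-1]
        s = w.sum()
        return w / s if s > 0 else w

    def n90(self, polarity: str) -> int:
        """Smallest count of same-polarity neighbours whose normalised
        weights sum to at least 0.9."""
        nw = self.normalized_weights(polarity)
        if nw.sum() == 0:
            return 0
        return int(np.searchsorted(np.cumsum(nw), 0.9 - 1e-12) + 1)


def nnls_fit(target_rf: np.ndarray,
             on_neighbor_maps: np.ndarray,
             off_neighbor_maps: np.ndarray,
             cell_id: int = -1,
             neighbor_ids: dict | None = None,
             distances: dict | None = None) -> NeighborhoodFit:
    """Non-negative least squares over signed neighbour maps.

    Design columns are the flattened ON maps (positive sign) and negated OFF
    maps, so the non-negative solution builds an ON-minus-OFF receptive
    field.  ``fit_corr`` is the Pearson correlation between the model and
    measured RF (NaN for an all-zero target).
    """
    n_on = len(on_neighbor_maps)
    n_off = len(off_neighbor_maps)
    if n_on + n_off == 0:
        raise ParameterError("at least one neighbour map is required")
    t = np.ravel(np.asarray(target_rf, dtype=float))
    cols = [np.asarray(m, dtype=float).ravel() for m in on_neighbor_maps]
    cols += [-np.asarray(m, dtype=float).ravel() for m in off_neighbor_maps]
    A = np.column_stack(cols)
    if A.shape[0] != t.size:
        raise ParameterError("neighbour maps and target differ in grid shape")
    if np.all(t == 0.0):
        w = np.zeros(A.shape[1])
    else:
        w, _ = optimize.nnls(A, t)
    model = A @ w
    try:
        fc = _map_corr(model, t)
    except ParameterError:
        fc = np.nan
    k = max(n_on, n_off)
    return NeighborhoodFit(
        cell_id=cell_id, k=k,
        neighbor_ids=neighbor_ids or {"ON": np.arange(n_on),
                                      "OFF": np.arange(n_off)},
        distances=distances or {"ON": np.full(n_on, np.nan),
                                "OFF": np.full(n_off, np.nan)},
        weights={"ON": w[:n_on], "OFF": w[n_on:]},
        fit_corr=fc,
        model_rf=model.reshape(np.asarray(target_rf).shape))


def fit_neighborhood_model(simple_cells: pd.DataFrame,
                           simple_rfs: dict,
                           mono_cells: pd.DataFrame,
                           mono_maps: dict,
                           k: int = 5) -> list[NeighborhoodFit]:
    """Fit the k-NN non-negative model for every simple cell.

    ``simple_rfs`` maps cell_id -> signed RF map; ``mono_maps`` maps mono
    cell_id -> peak-delay map of its significant polarity.
    """
    fits = []
    for _, row in simple_cells.iterrows():
        nb = knn_neighbors(np.array([row.x1, row.x2, row.x3]), mono_cells, k)
        on_maps = np.stack([mono_maps[i] for i in nb["ON"][0]])
        off_maps = np.stack([mono_maps[i] for i in nb["OFF"][0]])
        fits.append(nnls_fit(simple_rfs[row.cell_id], on_maps, off_maps,
                             cell_id=int(row.cell_id),
                             neighbor_ids={"ON": nb["ON"][0], "OFF": nb["OFF"][0]},
                             distances={"ON": nb["ON"][1], "OFF": nb["OFF"][1]}))
    return fits


def sweep_k(simple_cells: pd.DataFrame,
            simple_rfs: dict,
            mono_cells: pd.DataFrame,
            mono_maps: dict,
            k_range=range(1, 9),
            saturation_eps: float = 0.02) -> dict:
    """Median and quartiles of fit quality per neighbourhood size.

    Returns a dict with a per-k summary table and the smallest k whose median
    fit correlation is within ``saturation_eps`` of the maximum over the
    range.
    """
    ks = list(k_range)
    if not ks:
        raise ParameterError("k_range is empty")
    rows = []
    for k in ks:
        fits = fit_neighborhood_model(simple_cells, simple_rfs,
                                      mono_cells, mono_maps, k=k)
        fc = np.array([f.fit_corr for f in fits])
        fc = fc[np.isfinite(fc)]
        rows.append(dict(k=k, median=float(np.median(fc)),
                         q25=float(np.percentile(fc, 25)),
                         q75=float(np.percentile(fc, 75)), n=len(fc)))
    summary = pd.DataFrame(rows)
    best = summary["median"].max()
    sat = summary[summary["median"] >= best - saturation_eps].k.min()
    return dict(summary=summary, saturation_k=int(sat))


def weight_sparsity(fits: list[NeighborhoodFit]) -> dict:
    """Rank-ordered mean normalised weights, mean cumulative curves and the
    distribution of n90, per polarity.  Fits with zero total weight in a
    polarity are excluded from that polarity's summary."""
    out = {}
    for pol in ("ON", "OFF"):
        curves = []
        n90s = []
        skipped = 0
        for f in fits:
            nw = f.normalized_weights(pol)
            if nw.sum() <= 0:
                skipped += 1
                continue
            curves.append(nw)
            n90s.append(f.n90(pol))
        if not curves:
            raise ParameterError(f"no fit has positive total {pol} weight")
        if skipped:
            log.info("weight_sparsity: %d all-zero %s-weight fits excluded",
                     skipped, pol)
        kmax = max(len(c) for c in curves)
        padded = np.zeros((len(curves), kmax))
        for i, c in enumerate(curves):
            padded[i, :len(c)] = c
        mean_w = padded.mean(axis=0)
        out[pol] = dict(mean_normalized_weights=mean_w,
                        mean_cumulative=np.cumsum(mean_w),
                        n90=np.asarray(n90s))
    return out


def neighbor_distance_comparison(fits: list[NeighborhoodFit],
                                 used_only: bool = False) -> dict:
    """ON vs OFF neighbour-distance distributions with a two-sided rank-sum
    test.  With ``used_only`` the comparison keeps only neighbours with
    nonzero weight."""
    if len(fits) < 10:
        raise ParameterError("need at least 10 fits")
    d_on, d_off = [], []
    for f in fits:
        for pol, acc in (("ON", d_on), ("OFF", d_off)):
            d = np.asarray(f.distances[pol], dtype=float)
            if used_only:
                d = d[np.asarray(f.weights[pol]) > 0]
            acc.extend(d.tolist())
    d_on = np.asarray(d_on)
    d_off = np.asarray(d_off)
    if d_on.std() == 0 and d_off.std() == 0 and np.all(d_on == 0) and np.all(d_off == 0):
        p = 1.0
    else:
        p = float(stats.ranksums(d_on, d_off).pvalue)
    return dict(distances_on=d_on, distances_off=d_off, p_value=p,
                median_on=float(np.median(d_on)) if len(d_on) else np.nan,
                median_off=float(np.median(d_off)) if len(d_off) else np.nan)
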