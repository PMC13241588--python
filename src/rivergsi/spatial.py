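"""Spatial diagnostics: network distances, semivariograms, latitude trends.

After the contribution model absorbs covariate effects, each source
population keeps a random intercept (its mean contribution relative to
expectation).  These values are screened for spatial structure with
empirical semivariograms over Euclidean and watercourse (flow-line)
distances, a linear latitude trend, and per-region summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


# --------------------------------------------------------------- distances --
def watercourse_distance(net, a: str, b: str) -> float:
    """Flow-line distance (km) along the unique tree path between two
    network nodes."""
    try:
        return float(nx.shortest_path_length(net.graph, a, b, weight="length"))
    except nx.NetworkXNoPath as err:  # pragma: no cover - tree invariant
        raise ValueError(f"nodes {a!r} and {b!r} are in different components") from err


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    metric: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def distance_matrix(net, nodes: list[str], metric: str = "watercourse") -> np.ndarray:
    """Pairwise distances between network nodes.

    ``metric``: "watercourse" (along the tree) or "euclidean" (planar node
    coordinates)."""
    n = len(nodes)
    D = np.zeros((n, n))
    if metric == "watercourse":
        for i, a in enumerate(nodes):
            lengths = nx.single_source_dijkstra_path_length(net.graph, a, weight="length")
            for j, b in enumerate(nodes):
                D[i, j] = lengths[b]
        D = (D + D.T) / 2  # exact symmetry against float jitter
    elif metric == "euclidean":
        xy = np.array([net.node_xy(v) for v in nodes])
        diff = xy[:, None, :] - xy[None, :, :]
        D = np.sqrt((diff**2).sum(axis=-1))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    return D


# ----------------------------------------------------------- semivariogram --
@dataclass
class SemivariogramEstimate:
    bins: pd.DataFrame  # lower, upper, mean_distance, gamma, n_pairs, low_support
    metric: str
    smoothed: pd.DataFrame | None = None  # distance, gamma_smooth
    span: float = 0.7


def empirical_semivariogram(
    values: np.ndarray,
    D: np.ndarray,
    n_bins: int = 20,
    min_pairs: int = 21,
    metric: str = "watercourse",
    binning: str = "equal_width",
    smooth: bool = True,
    span: float = 0.7,
) -> SemivariogramEstimate:
    """Empirical semivariance gamma(h) = (1 / 2 N_h) sum (v_i - v_j)^2 over
    pairs whose separation falls in bin h.

    Bins span (0, max distance]; bins supported by fewer than ``min_pairs``
    pairs are retained but flagged ``low_support``.  An optional
    locally-weighted (lowess) smooth over bin midpoints is attached.
    ``binning``: "equal_width" or "equal_count".
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least two points")
    iu = np.triu_indices(n, k=1)
    d = np.asarray(D)[iu]
    sq = (values[iu[0]] - values[iu[1]]) ** 2
    dmax = d.max()
    if binning == "equal_width":
        edges = np.linspace(0.0, dmax, n_bins + 1)
    elif binning == "equal_count":
        edges = np.quantile(d, np.linspace(0, 1, n_bins + 1))
        edges[0], edges[-1] = 0.0, dmax
    else:
        raise ValueError(f"unknown binning {binning!r}")
    which = np.clip(np.searchsorted(edges, d, side="left") - 1, 0, n_bins - 1)
    rows = []
    for h in range(n_bins):
        m = which == h
        npairs = int(m.sum())
        gamma = float(sq[m].sum() / (2 * npairs)) if npairs else np.nan
        rows.append({
            "lower": edges[h], "upper": edges[h + 1],
            "mean_distance": float(d[m].mean()) if npairs else np.nan,
            "gamma": gamma, "n_pairs": npairs,
            "low_support": npairs < min_pairs,
        })
    bins = pd.DataFrame(rows)
    smoothed = None
    if smooth:
        ok = bins["n_pairs"] > 0
        if ok.sum() >= 3:
            from statsmodels.nonparametric.smoothers_lowess import lowess

            sm = lowess(bins.loc[ok, "gamma"], bins.loc[ok, "mean_distance"],
                        frac=span, return_sorted=True)
            smoothed = pd.DataFrame(sm, columns=["distance", "gamma_smooth"])
    return SemivariogramEstimate(bins, metric, smoothed, span)


def inflection_scale(est: SemivariogramEstimate, span: float = 0.35) -> float | None:
    """Distance at which the smoothed semivariogram's slope first drops
    below half its initial value — a proxy for the fine-scale range
    (patchiness).  Returns None when the curve keeps climbing (pure
    gradient).

    The diagnostic recomputes its own locally weighted smooth with a
    lighter span than the display curve: the wide display smooth is meant
    for plotting and flattens exactly the short-range curvature this proxy
    looks for."""
    ok = est.bins["n_pairs"] > 0
    if ok.sum() < 4:
        return None
    from statsmodels.nonparametric.smoothers_lowess import lowess

    sm = lowess(est.bins.loc[ok, "gamma"], est.bins.loc[ok, "mean_distance"],
                frac=span, return_sorted=True)
    g = sm[:, 1]
    x = sm[:, 0]
    slopes = np.diff(g) / np.maximum(np.diff(x), 1e-12)
    first = slopes[0]
    if first <= 0:
        return float(x[1])
    below = np.flatnonzero(slopes < 0.5 * first)
    if below.size == 0:
        return None
    return float(x[below[0] + 1])


# ------------------------------------------------------------ trend/region --
def latitude_trend(intercepts: np.ndarray, latitude: np.ndarray):
    """OLS of random intercepts on a latitude proxy.  Returns (slope,
    intercept, (lo, hi) 95% CI on the slope)."""
    import statsmodels.api as sm

    intercepts = np.asarray(intercepts, float)
    latitude = np.asarray(latitude, float)
    if intercepts.size < 3:
        raise ValueError("need at least three units")
    if np.ptp(latitude) == 0:
        raise ValueError("latitude proxy has zero variance")
    X = sm.add_constant(latitude)
    res = sm.OLS(intercepts, X).fit()
    lo, hi = res.conf_int(alpha=0.05)[1]
    return float(res.params[1]), float(res.params[0]), (float(lo), float(hi))


def region_summary(
    intercepts: np.ndarray, region_ids, latitude: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-region count/mean/sd of random intercepts, ordered north to south
    by region centroid latitude when available."""
    df = pd.DataFrame({"region": list(region_ids), "value": np.asarray(intercepts, float)})
    if latitude is not None:
        df["lat"] = np.asarray(latitude, float)
    g = df.groupby("region")["value"].agg(n="count", mean="mean", sd="std")
    if latitude is not None:
        g["centroid_latitude"] = df.groupby("region")["lat"].mean()
        g = g.sort_values("centroid_latitude", ascending=False)
    return g.reset_index()
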