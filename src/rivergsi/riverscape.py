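"""Synthetic riverscape generator.

Emulates the study system end-to-end so every downstream stage is testable
without field data: a dendritic stream network whose main stem is divided
into sampling sections, tributary source populations with covariates
(flow-line distance to each section midpoint, catchment area, groundwater
index with a north--south gradient plus regional patches, connectivity
category), Balding--Nichols structured allele frequencies at a target global
FST, baseline collections with full-sib families and within-stream replicate
collections, true per-section contributions drawn from the zero-inflated
beta forward model, and main-stem mixture samples with known origins.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .zib_model import (
    CONNECTIVITY_LEVELS,
    ZIBCoefficients,
    linear_predictors,
    standardize_covariates,
)

_SECTION_NAMES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

#: connectivity category frequencies used when counts are not given explicitly
_CONN_DEFAULT_PROPS = {"connected": 0.75, "culvert_diversion": 0.06,
                       "low_flow": 0.13, "waterfall": 0.06}
#: study-condition counts for the default 52-population riverscape
_CONN_52 = {"connected": 39, "culvert_diversion": 3, "low_flow": 7, "waterfall": 3}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic riverscape (defaults emulate the
    real system: 52 tributary source populations genotyped at 266 SNPs with
    global FST ~ 0.04, a six-section main stem sampled for three years at
    ~500 adults per year)."""

    seed: int = 0
    n_populations: int = 52
    n_loci: int = 266
    theta_fst: float = 0.04
    theta_within: float = 0.003  # drift between same-stream replicate collections
    n_per_collection: tuple[int, int] = (25, 45)
    sib_family_rate: float = 0.15
    sib_family_size: tuple[int, int] = (3, 5)
    n_sections: int = 6
    section_length_km: float = 20.0
    n_years: int = 3
    first_year: int = 2020
    mixture_size_per_year: int = 500
    missing_rate: float = 0.02
    n_split_populations: int = 11   # populations sampled as two collections
    n_small_collections: int = 6    # tiny unaggregatable collections (n <= 5)
    small_collection_size: tuple[int, int] = (3, 5)
    missing_source_fraction: float = 0.05  # mixture fish from unsampled sources
    connectivity_counts: dict[str, int] | None = None
    zib_coefficients: ZIBCoefficients = field(default_factory=ZIBCoefficients)
    lat_effect: float = -0.5   # south-high latitudinal gradient in true logit-mu
    region_sd: float = 0.4     # regional patchiness in true logit-mu
    n_regions: int = 8
    sampling_offset_range_km: tuple[float, float] = (1.0, 8.0)
    year_mode: str = "constant"  # contributions constant across years
    skip_first_stratum: bool = False  # emulate the unsampled section-year

    def resolved_connectivity_counts(self) -> dict[str, int]:
        if self.connectivity_counts is not None:
            counts = dict(self.connectivity_counts)
            if sum(counts.values()) != self.n_populations:
                raise ValueError("connectivity_counts must sum to n_populations")
            return counts
        if self.n_populations == 52:
            return dict(_CONN_52)
        counts = {k: int(round(v * self.n_populations))
                  for k, v in _CONN_DEFAULT_PROPS.items()}
        counts["connected"] += self.n_populations - sum(counts.values())
        return counts

    def pop_ids(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_populations)]

    def section_ids(self) -> list[str]:
        return list(_SECTION_NAMES[: self.n_sections])


# ----------------------------------------------------------------- network --
@dataclass
class StreamNetwork:
    """Dendritic (tree) stream network with a sectioned main stem.

    Every point of interest (section midpoints, tributary sampling points,
    confluences) is a graph node; edges carry a ``length`` (km) attribute and
    nodes carry planar ``x``/``y`` coordinates (km; y is northing)."""

    graph: nx.Graph
    main_stem: list[str]                 # node path, upstream -> outlet
    sections: list[str]
    section_midpoints: dict[str, str]
    tributary_mouths: dict[str, str]     # population -> sampling-point node
    confluences: dict[str, str]          # population -> confluence node

    def __post_init__(self) -> None:
        if not nx.is_tree(self.graph):
            raise ValueError("stream network must be a tree")

    def node_xy(self, node: str) -> tuple[float, float]:
        d = self.graph.nodes[node]
        return d["x"], d["y"]

    def distance(self, a: str, b: str) -> float:
        from .spatial import watercourse_distance

        return watercourse_distance(self, a, b)


def generate_network(cfg: SimulationConfig, seed=None) -> StreamNetwork:
    """Main stem of ``n_sections`` equal sections running north to south with
    one tributary per source population, attached at a uniform position."""
    if cfg.n_populations < 1 or cfg.n_sections < 1:
        raise ValueError("need at least one population and one section")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    L = cfg.n_sections * cfg.section_length_km
    sections = cfg.section_ids()
    pops = cfg.pop_ids()

    # positions along the main stem, measured from the upstream (north) end
    points: list[tuple[float, str]] = [(0.0, "ms_top"), (L, "ms_outlet")]
    for i, s in enumerate(sections):
        points.append(((i + 1) * cfg.section_length_km, f"ms_b{i + 1}"))
        points.append(((i + 0.5) * cfg.section_length_km, f"mid_{s}"))
    conf_pos = rng.uniform(0.5, L - 0.5, size=cfg.n_populations)
    for pop, pos in zip(pops, conf_pos):
        points.append((float(pos), f"conf_{pop}"))
    # deduplicate positions (keep named nodes distinct)
    points = sorted(set(points))

    g = nx.Graph()
    prev = None
    for pos, name in points:
        x = 6.0 * np.sin(pos / 17.0)
        g.add_node(name, x=x, y=L - pos, pos=pos)
        if prev is not None:
            plen = pos - prev[0]
            if plen > 0:
                g.add_edge(prev[1], name, length=plen)
            else:  # coincident positions: zero-length tie (should not happen)
                g.add_edge(prev[1], name, length=1e-9)
        prev = (pos, name)

    mouths, confs = {}, {}
    offsets = rng.uniform(*cfg.sampling_offset_range_km, size=cfg.n_populations)
    sides = rng.choice([-1.0, 1.0], size=cfg.n_populations)
    angles = rng.uniform(np.pi / 6, np.pi / 2.2, size=cfg.n_populations)
    for k, pop in enumerate(pops):
        conf = f"conf_{pop}"
        node = f"pop_{pop}"
        cx, cy = g.nodes[conf]["x"], g.nodes[conf]["y"]
        g.add_node(node,
                   x=cx + sides[k] * offsets[k] * np.cos(angles[k]),
                   y=cy + offsets[k] * np.sin(angles[k]),
                   pos=np.nan)
        g.add_edge(conf, node, length=float(offsets[k]))
        mouths[pop] = node
        confs[pop] = conf

    main_stem = [name for _, name in points]
    midpoints = {s: f"mid_{s}" for s in sections}
    return StreamNetwork(g, main_stem, sections, midpoints, mouths, confs)


# --------------------------------------------------------------- covariates --
def generate_covariates(net: StreamNetwork, cfg: SimulationConfig, seed=None) -> pd.DataFrame:
    """Per-population covariates: latitude proxy (northing of the sampling
    point), region id (north->south bands), catchment area (lognormal, km^2),
    groundwater index in (0, 1) with a northward gradient plus regional
    patches, and the connectivity category."""
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    pops = list(net.tributary_mouths)
    lat = np.array([net.node_xy(net.tributary_mouths[p])[1] for p in pops])

    # regions: equal latitude bands, ordered north -> south
    order = np.argsort(-lat)
    region = np.empty(len(pops), dtype=int)
    for rank, idx in enumerate(order):
        region[idx] = min(rank * cfg.n_regions // len(pops), cfg.n_regions - 1)
    region_ids = np.array([f"R{i + 1}" for i in region])

    area = rng.lognormal(mean=np.log(30.0), sigma=0.8, size=len(pops))
    lat01 = (lat - lat.min()) / max(lat.max() - lat.min(), 1e-9)
    reg_eff = rng.normal(0, 0.10, cfg.n_regions)
    gw = 0.15 + 0.6 * lat01 + reg_eff[region] + rng.normal(0, 0.08, len(pops))
    gw = np.clip(gw, 0.01, 0.99)

    counts = cfg.resolved_connectivity_counts()
    cats = np.concatenate([[lev] * n for lev, n in counts.items()])
    rng.shuffle(cats)

    return pd.DataFrame({
        "population": pops,
        "latitude_proxy": lat,
        "region": region_ids,
        "A": area,
        "G": gw,
        "C": cats,
    }).set_index("population")


# --------------------------------------------------------- allele frequencies --
def generate_allele_frequencies(
    cfg: SimulationConfig, seed=None, n_populations: int | None = None,
) -> np.ndarray:
    """Balding--Nichols population allele frequencies: ancestral frequency
    p_l ~ Uniform(0.05, 0.95) per locus, then per population
    p_kl ~ Beta(p_l (1-theta)/theta, (1-p_l)(1-theta)/theta), whose mean is
    p_l and variance theta * p_l (1 - p_l).  Clipped 1e-4 away from {0, 1}."""
    theta = cfg.theta_fst
    if not 0 < theta < 1:
        raise ValueError("theta_fst must lie in (0, 1)")
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    K = cfg.n_populations if n_populations is None else n_populations
    anc = rng.uniform(0.05, 0.95, size=cfg.n_loci)
    scale = (1.0 - theta) / theta
    freqs = rng.beta(anc * scale, (1.0 - anc) * scale, size=(K, cfg.n_loci))
    return np.clip(freqs, 1e-4, 1 - 1e-4)


def drift_frequencies(freqs: np.ndarray, theta: float, rng) -> np.ndarray:
    """Daughter frequencies drifted from ``freqs`` by a small F (used for
    replicate collections within one tributary)."""
    scale = (1.0 - theta) / theta
    return np.clip(rng.beta(freqs * scale, (1.0 - freqs) * scale), 1e-4, 1 - 1e-4)


# ---------------------------------------------------------------- genotypes --
def _hwe_genotypes(p: np.ndarray, n: int, rng) -> np.ndarray:
    """(n, L) alt-allele dosages under Hardy--Weinberg."""
    return (rng.random((n, p.size)) < p).astype(np.int8) + (
        rng.random((n, p.size)) < p
    ).astype(np.int8)


def _mendelian_child(pa: np.ndarray, pb: np.ndarray, rng) -> np.ndarray:
    """One offspring dosage from two parental dosage vectors."""
    def gamete(par):
        # transmit one of two alleles: hom -> deterministic, het -> coin flip
        return np.where(par == 1, (rng.random(par.size) < 0.5).astype(np.int8),
                        (par // 2).astype(np.int8))
    return gamete(pa) + gamete(pb)


def _codes_to_alleles(codes: np.ndarray, missing_mask: np.ndarray) -> np.ndarray:
    """Dosage (n, L) -> allele-string array (n, L, 2) with codes '1'/'2'."""
    n, L = codes.shape
    a = np.empty((n, L, 2), dtype=object)
    a[:, :, 0] = np.where(codes >= 1, "2", "1")
    a[:, :, 1] = np.where(codes == 2, "2", "1")
    a[missing_mask] = MISSING
    return a


def simulate_collection(
    p: np.ndarray, n: int, cfg: SimulationConfig, rng,
    collection_id: str,
) -> tuple[np.ndarray, dict[int, str]]:
    """Dosage matrix for one baseline collection; a configured fraction of
    individuals belongs to simulated full-sib families (two Hardy--Weinberg
    parents, Mendelian offspring).  Returns (codes, row -> family id)."""
    target_sibs = int(round(cfg.sib_family_rate * n))
    fams: dict[int, str] = {}
    rows = []
    fam_no = 0
    while target_sibs - len(fams) >= 2 and len(rows) < n:
        size = int(rng.integers(cfg.sib_family_size[0], cfg.sib_family_size[1] + 1))
        size = min(size, n - len(rows), target_sibs - len(fams) + 1)
        if size < 2:
            break
        fam_no += 1
        pa, pb = _hwe_genotypes(p, 2, rng)
        for _ in range(size):
            fams[len(rows)] = f"{collection_id}_fam{fam_no}"
            rows.append(_mendelian_child(pa, pb, rng))
    n_rest = n - len(rows)
    if n_rest:
        rows.append(_hwe_genotypes(p, n_rest, rng))
        codes = np.vstack([np.atleast_2d(r) for r in rows])
    else:
        codes = np.vstack(rows)
    return codes.astype(np.int8), fams


def simulate_baseline(
    freqs: np.ndarray, cfg: SimulationConfig, seed=None,
    small_freqs: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Baseline genotype matrix across collections.

    The first ``n_split_populations`` populations are sampled as two
    collections at different positions along the same stream (frequencies
    drifted apart by ``theta_within``); the rest as one collection.  If
    ``small_freqs`` is given, that many additional tiny collections (n <= 5,
    from populations otherwise absent from the riverscape) are appended.

    Returns the matrix and a collection table (collection, population,
    stream, n, plus sib-family labels per individual in a companion column
    of the returned frame's attrs)."""
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    pops = [f"P{i + 1:02d}" for i in range(freqs.shape[0])]
    split = set(pops[: cfg.n_split_populations])
    metas, blocks, crows = [], [], []
    family_of: dict[str, str] = {}
    for k, pop in enumerate(pops):
        coll_specs = []
        if pop in split:
            n_tot = int(rng.integers(*cfg.n_per_collection))
            n_a = max(6, n_tot // 2)
            fa = drift_frequencies(freqs[k], cfg.theta_within, rng)
            fb = drift_frequencies(freqs[k], cfg.theta_within, rng)
            coll_specs = [(f"{pop}a", fa, n_a), (f"{pop}b", fb, n_tot - n_a + 6)]
        else:
            n_tot = int(rng.integers(*cfg.n_per_collection))
            coll_specs = [(pop, freqs[k], n_tot)]
        for cid, f, n in coll_specs:
            codes, fams = simulate_collection(f, n, cfg, rng, cid)
            miss = rng.random(codes.shape) < cfg.missing_rate
            ids = [f"{cid}_{i + 1:03d}" for i in range(n)]
            for row, fam in fams.items():
                family_of[ids[row]] = fam
            metas.append(pd.DataFrame({
                "individual_id": ids, "collection_id": cid, "role": "baseline",
                "section": "", "year": pd.array([pd.NA] * n, dtype="Int64"),
            }))
            blocks.append(_codes_to_alleles(codes, miss))
            crows.append({"collection": cid, "population": pop, "stream": pop, "n": n})
    if small_freqs is not None:
        for j in range(small_freqs.shape[0]):
            cid = f"X{j + 1}"
            n = int(rng.integers(cfg.small_collection_size[0],
                                 cfg.small_collection_size[1] + 1))
            codes = _hwe_genotypes(small_freqs[j], n, rng)
            miss = rng.random(codes.shape) < cfg.missing_rate
            ids = [f"{cid}_{i + 1:03d}" for i in range(n)]
            metas.append(pd.DataFrame({
                "individual_id": ids, "collection_id": cid, "role": "baseline",
                "section": "", "year": pd.array([pd.NA] * n, dtype="Int64"),
            }))
            blocks.append(_codes_to_alleles(codes, miss))
            crows.append({"collection": cid, "population": cid, "stream": cid, "n": n})
    loci = [f"L{i + 1:03d}" for i in range(cfg.n_loci)]
    G = GenotypeMatrix(pd.concat(metas, ignore_index=True),
                       np.concatenate(blocks, axis=0), loci)
    table = pd.DataFrame(crows)
    table.attrs["family_of"] = family_of
    return G, table


# ------------------------------------------------------------ contributions --
def section_distance_table(net: StreamNetwork, covariates: pd.DataFrame) -> pd.DataFrame:
    """Long (r, s) covariate table with flow-line distances D (km) from each
    population's sampling point to each section midpoint."""
    from .spatial import distance_matrix

    pops = list(covariates.index)
    pts = [net.tributary_mouths[p] for p in pops] + [
        net.section_midpoints[s] for s in net.sections
    ]
    D = distance_matrix(net, pts)
    rows = []
    for i, r in enumerate(pops):
        for j, s in enumerate(net.sections):
            rows.append({
                "r": r, "s": s,
                "D": D[i, len(pops) + j],
                "A": covariates.loc[r, "A"],
                "G": covariates.loc[r, "G"],
                "C": covariates.loc[r, "C"],
            })
    return pd.DataFrame(rows)


def simulate_true_contributions(
    covariates: pd.DataFrame,
    net: StreamNetwork,
    cfg: SimulationConfig,
    seed=None,
    coef: ZIBCoefficients | None = None,
) -> pd.DataFrame:
    """Forward-simulate true contributions per (population, section).

    Draws the zero-inflated beta forward model on the (r, s) covariate table;
    the latitudinal gradient and regional patches configured in ``cfg`` enter
    the logit-mean as unit-level offsets (they are *not* covariates of the
    fitted model, so they surface later as spatially structured random
    intercepts).  Nonzero draws are renormalized within each section to give
    simplex contribution vectors; the raw draws are kept as the regression
    truth.  Returns columns r, s, mu, omega, p_raw, contribution."""
    rng = np.random.default_rng(cfg.seed + 4 if seed is None else seed)
    coef = coef or cfg.zib_coefficients
    longtab = section_distance_table(net, covariates)
    df, _ = standardize_covariates(longtab)
    sections = net.sections
    pops = list(covariates.index)
    lat = covariates["latitude_proxy"].to_numpy(float)
    lat_z = (lat - lat.mean()) / max(lat.std(), 1e-9)
    regions = sorted(covariates["region"].unique())
    reg_eff = rng.normal(0, cfg.region_sd, len(regions))
    reg_of = covariates["region"].map({g: i for i, g in enumerate(regions)}).to_numpy()
    unit_extra = cfg.lat_effect * lat_z + reg_eff[reg_of]
    a_s = rng.normal(0, coef.sigma_section, len(sections))
    a_r = rng.normal(0, coef.sigma_unit, len(pops)) + unit_extra
    # linear_predictors sorts unit levels; align our arrays to that order
    unit_levels = sorted(pops)
    sec_levels = sorted(sections)
    a_r_sorted = a_r[[pops.index(u) for u in unit_levels]]
    a_s_sorted = a_s[[sections.index(s) for s in sec_levels]]
    omega, mu, phi = linear_predictors(df, coef, sec_levels, unit_levels,
                                       a_s_sorted, a_r_sorted)
    df = df.assign(omega=omega, mu=mu, phi=phi)
    for attempt in range(100):
        zero = rng.random(len(df)) < df["omega"].to_numpy()
        p = rng.beta(df["mu"] * df["phi"], (1 - df["mu"]) * df["phi"])
        p_raw = np.where(zero, 0.0, np.clip(p, 1e-9, 1 - 1e-6))
        sums = pd.Series(p_raw).groupby(df["s"].values).transform("sum").to_numpy()
        if (sums > 0).all():
            break
        warnings.warn("a section drew all-zero contributions; resampling")
    df["p_raw"] = p_raw
    df["contribution"] = np.where(sums > 0, p_raw / sums, 0.0)
    df.attrs["unit_extra_logit"] = dict(zip(pops, unit_extra))
    return df


def simulate_mixture(
    contributions: pd.DataFrame,
    freqs: np.ndarray,
    cfg: SimulationConfig,
    seed=None,
    ghost_freqs: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Main-stem mixture genotypes with known origins.

    Per section-year stratum, origins are multinomial in the section's true
    contribution vector; a configured fraction of fish instead comes from
    "ghost" populations absent from the baseline (emulating incompleteness).
    Genotypes are Hardy--Weinberg draws from the origin's frequencies."""
    rng = np.random.default_rng(cfg.seed + 5 if seed is None else seed)
    pops = sorted(contributions["r"].unique())
    sections = sorted(contributions["s"].unique())
    pi = contributions.pivot_table(index="s", columns="r", values="contribution")
    pi = pi.reindex(index=sections, columns=pops).fillna(0.0)
    per_section = int(round(cfg.mixture_size_per_year / len(sections)))
    metas, blocks, labels = [], [], []
    loci = [f"L{i + 1:03d}" for i in range(cfg.n_loci)]
    ghost_n = 0 if ghost_freqs is None else ghost_freqs.shape[0]
    for t in range(cfg.n_years):
        year = cfg.first_year + t
        for si, s in enumerate(sections):
            if cfg.skip_first_stratum and t == 0 and si == 0:
                continue
            n = per_section
            pvec = pi.loc[s].to_numpy(float)
            pvec = pvec / pvec.sum()
            origin_idx = rng.choice(len(pops), size=n, p=pvec)
            origins = np.array(pops, dtype=object)[origin_idx]
            if ghost_n and cfg.missing_source_fraction > 0:
                is_ghost = rng.random(n) < cfg.missing_source_fraction
                gidx = rng.integers(0, ghost_n, size=n)
                origins = np.where(is_ghost,
                                   np.array([f"X{j + 1}" for j in gidx], dtype=object),
                                   origins)
                origin_idx = np.where(is_ghost, -1 - gidx, origin_idx)
            codes = np.empty((n, cfg.n_loci), dtype=np.int8)
            for i in range(n):
                oi = origin_idx[i]
                f = freqs[oi] if oi >= 0 else ghost_freqs[-1 - oi]
                codes[i] = _hwe_genotypes(f, 1, rng)[0]
            miss = rng.random(codes.shape) < cfg.missing_rate
            ids = [f"M{year}{s}_{i + 1:04d}" for i in range(n)]
            metas.append(pd.DataFrame({
                "individual_id": ids, "collection_id": "", "role": "mixture",
                "section": s, "year": pd.array([year] * n, dtype="Int64"),
            }))
            blocks.append(_codes_to_alleles(codes, miss))
            labels.append(pd.DataFrame({
                "individual_id": ids, "origin": origins, "section": s, "year": year,
            }))
    G = GenotypeMatrix(pd.concat(metas, ignore_index=True),
                       np.concatenate(blocks, axis=0), loci)
    return G, pd.concat(labels, ignore_index=True)


# --------------------------------------------------------------- top level --
@dataclass
class SyntheticRiverscape:
    cfg: SimulationConfig
    network: StreamNetwork
    covariates: pd.DataFrame
    freqs: np.ndarray
    ghost_freqs: np.ndarray
    baseline: GenotypeMatrix
    collections: pd.DataFrame
    contributions: pd.DataFrame
    mixture: GenotypeMatrix
    labels: pd.DataFrame

    @property
    def family_of(self) -> dict[str, str]:
        return self.collections.attrs.get("family_of", {})

    def stream_of_collection(self) -> dict[str, str]:
        return dict(zip(self.collections["collection"], self.collections["stream"]))

    def population_of_collection(self) -> dict[str, str]:
        return dict(zip(self.collections["collection"], self.collections["population"]))


def simulate_riverscape(cfg: SimulationConfig | None = None, seed=None) -> SyntheticRiverscape:
    """Generate the full synthetic study: network, covariates, frequencies,
    baseline and mixture genotypes, and truth tables."""
    cfg = cfg or SimulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    net = generate_network(cfg)
    cov = generate_covariates(net, cfg)
    # ghost populations (tiny excluded collections / unsampled mixture sources)
    # come from the same ancestral frequency field as the baseline populations
    n_ghost = max(cfg.n_small_collections, 1)
    allf = generate_allele_frequencies(cfg, n_populations=cfg.n_populations + n_ghost)
    freqs, ghost = allf[: cfg.n_populations], allf[cfg.n_populations:]
    baseline, collections = simulate_baseline(
        freqs, cfg, small_freqs=ghost[: cfg.n_small_collections] if cfg.n_small_collections else None)
    contributions = simulate_true_contributions(cov, net, cfg)
    mixture, labels = simulate_mixture(contributions, freqs, cfg,
                                       ghost_freqs=ghost if cfg.missing_source_fraction else None)
    return SyntheticRiverscape(cfg, net, cov, freqs, ghost, baseline, collections,
                               contributions, mixture, labels)
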