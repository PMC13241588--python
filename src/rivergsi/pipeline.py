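"""End-to-end pipeline: QC -> relatedness -> baseline -> GSI -> models -> spatial.

`run_pipeline` executes the full inference chain on either a synthetic
riverscape (simulation config) or user-supplied tables, with every
threshold, sampler setting and seed recorded in a run report.  Stage
functions are importable individually; the numbered analysis scripts and
the acceptance script drive them directly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baseline as bl
from . import gsi, relatedness, spatial
from .genotypes import GenotypeMatrix, drop_loci, filter_by_call_rate, write_genotype_table
from .riverscape import SimulationConfig, SyntheticRiverscape, simulate_riverscape
from .zib_model import fit_zib, posterior_predictive_check


@dataclass
class Thresholds:
    call_rate: float = 0.85
    sib_relatedness: float = 0.4
    self_assignment: float = 0.7
    fst_merge: float = 0.01
    assignment_prob: float = 0.7
    small_collection: int = 5

    def validate(self) -> None:
        for name in ("call_rate", "sib_relatedness", "self_assignment",
                     "fst_merge", "assignment_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"threshold {name}={v} outside [0, 1]")


@dataclass
class SamplerSettings:
    gsi_sweeps: int = 2000
    gsi_burn: int = 500
    bootstrap_reps: int = 100
    bootstrap_sweeps: int = 500
    bootstrap_burn: int = 150
    zib_chains: int = 4
    zib_warmup: int = 2000
    zib_iterations: int = 2000
    dirichlet_chains: int = 3
    dirichlet_warmup: int = 2000
    dirichlet_iterations: int = 2000
    dirichlet_top_k: int | None = None  # collapse minor units into "other"
    run_dirichlet_loo: bool = True


@dataclass
class PipelineConfig:
    seed: int = 0
    simulation: SimulationConfig | None = None
    genotypes_path: str | None = None
    covariates_path: str | None = None
    network_nodes_path: str | None = None
    network_edges_path: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    outdir: str | None = None

    def validate(self) -> None:
        paths = [self.genotypes_path, self.covariates_path,
                 self.network_nodes_path, self.network_edges_path]
        has_paths = any(p is not None for p in paths)
        if has_paths and self.simulation is not None:
            raise ValueError("config must give either input paths or a "
                             "simulation block, not both")
        if not has_paths and self.simulation is None:
            raise ValueError("config needs input paths or a simulation block")
        if has_paths and not all(p is not None for p in paths):
            raise ValueError("path mode needs genotypes, covariates and network files")
        self.thresholds.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        thr = raw.pop("thresholds", {})
        smp = raw.pop("sampler", {})
        cfg = cls(
            simulation=SimulationConfig(**sim) if sim is not None else None,
            thresholds=Thresholds(**thr),
            sampler=SamplerSettings(**smp),
            **raw,
        )
        cfg.validate()
        return cfg


# ------------------------------------------------------------- data loading --
def load_network(nodes_path, edges_path):
    """Build a stream network from nodes (node, x, y) and edges (a, b,
    length) tables.  Section midpoints must be nodes named ``mid_<section>``
    and tributary sampling points ``pop_<population>``."""
    import networkx as nx

    from .riverscape import StreamNetwork

    nodes = pd.read_csv(nodes_path)
    edges = pd.read_csv(edges_path)
    g = nx.Graph()
    for t in nodes.itertuples():
        g.add_node(t.node, x=float(t.x), y=float(t.y))
    for t in edges.itertuples():
        g.add_edge(t.a, t.b, length=float(t.length))
    sections = sorted(n[4:] for n in g.nodes if str(n).startswith("mid_"))
    mouths = {str(n)[4:]: n for n in g.nodes if str(n).startswith("pop_")}
    return StreamNetwork(g, [], sections, {s: f"mid_{s}" for s in sections},
                         mouths, {})


# ------------------------------------------------------------------ stages --
def qc_stage(G: GenotypeMatrix, thresholds: Thresholds, panel=None):
    """Call-rate filter (individuals) then locus screening (flagged and
    invariant loci, assessed over the union of retained individuals)."""
    filtered = filter_by_call_rate(G, thresholds.call_rate)
    pruned, removed = drop_loci(filtered, panel)
    return pruned, removed


def composition_table(fits: list[gsi.MixtureFit]) -> pd.DataFrame:
    """Strata x units table of zero-adjusted contributions."""
    rows = {}
    for fit in fits:
        rows[fit.stratum] = gsi.zero_adjusted_contributions(fit)
    df = pd.DataFrame(rows).T
    df.index = pd.MultiIndex.from_tuples(df.index, names=["section", "year"])
    return df.fillna(0.0)


def collapse_minor_units(Y: pd.DataFrame, top_k: int) -> pd.DataFrame:
    """Keep the ``top_k`` units with the largest overall contribution and
    pool the remainder into an "other" component (compositional lumping)."""
    totals = Y.sum(axis=0).sort_values(ascending=False)
    major = list(totals.index[:top_k])
    out = Y[major].copy()
    out["other"] = Y.drop(columns=major).sum(axis=1)
    return out


def contribution_long_table(
    composition: pd.DataFrame, covariates: pd.DataFrame, net,
) -> pd.DataFrame:
    """Long (r, s, y, p, D, A, G, C) table joining GSI output to tributary
    covariates and network distances."""
    from .riverscape import section_distance_table

    longcov = section_distance_table(net, covariates)
    key = longcov.set_index(["r", "s"])
    rows = []
    for (section, year), comp in composition.iterrows():
        for r, p in comp.items():
            if r not in covariates.index:
                continue
            cv = key.loc[(r, section)]
            rows.append({"r": r, "s": section, "y": year, "p": float(p),
                         "D": cv["D"], "A": cv["A"], "G": cv["G"], "C": cv["C"]})
    return pd.DataFrame(rows)


def report_composition(
    fits: list[gsi.MixtureFit], covariates: pd.DataFrame,
    gw_bands=(0.33, 0.66),
) -> pd.DataFrame:
    """Per-section mean contribution per unit across years (with min/max),
    plus each section's aggregate share from low/mid/high-groundwater
    tributaries."""
    comp = composition_table(fits)
    mean = comp.groupby(level="section").mean()
    cmin = comp.groupby(level="section").min()
    cmax = comp.groupby(level="section").max()
    rows = []
    gw = covariates["G"] if "G" in covariates else pd.Series(dtype=float)
    for section in mean.index:
        for unit in mean.columns:
            g = gw.get(unit, np.nan)
            band = ("unknown" if pd.isna(g) else
                    "low" if g < gw_bands[0] else
                    "mid" if g < gw_bands[1] else "high")
            rows.append({"section": section, "unit": unit,
                         "mean": mean.loc[section, unit],
                         "min": cmin.loc[section, unit],
                         "max": cmax.loc[section, unit],
                         "groundwater_band": band})
    return pd.DataFrame(rows)


# -------------------------------------------------------------- run report --
@dataclass
class RunReport:
    seeds: dict
    thresholds: dict
    sampler: dict
    stage_counts: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def add_file(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.manifest[str(path)] = digest

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


@dataclass
class RunResult:
    config: PipelineConfig
    report: RunReport
    riverscape: SyntheticRiverscape | None
    units: list
    fst: bl.FstMatrix
    confusion: bl.ConfusionMatrix
    fits: list
    composition: pd.DataFrame
    zib_fit: object
    ppc: pd.DataFrame
    random_intercepts: pd.DataFrame
    semivariograms: dict
    latitude: tuple
    dirichlet_table: pd.DataFrame | None
    zscores: pd.DataFrame
    dispersal: gsi.DispersalSummary | None


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full chain; see module docstring.  Strata with zero
    retained individuals are skipped and recorded."""
    config.validate()
    thr, smp = config.thresholds, config.sampler
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2**31 - 1))
             for k in ("gsi", "bootstrap", "zib", "dirichlet", "assess")}
    report = RunReport(seeds={"root": config.seed, **seeds},
                       thresholds=asdict(thr), sampler=asdict(smp))
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # ---- inputs ---------------------------------------------------------
    rs = None
    if config.simulation is not None:
        rs = simulate_riverscape(config.simulation)
        G_all = rs.baseline.concat(rs.mixture)
        covariates = rs.covariates
        net = rs.network
        stream_of = rs.stream_of_collection()
        pop_of = rs.population_of_collection()
        network_point_of = {c: f"pop_{p}" for c, p in pop_of.items()
                            if p in rs.network.tributary_mouths}
    else:
        from .genotypes import read_genotype_table

        G_all = read_genotype_table(config.genotypes_path)
        covariates = pd.read_csv(config.covariates_path, index_col=0)
        net = load_network(config.network_nodes_path, config.network_edges_path)
        stream_of = covariates.get("stream", pd.Series(dtype=str)).to_dict()
        network_point_of = {p: f"pop_{p}" for p in covariates.index
                            if f"pop_{p}" in net.graph}
    report.stage_counts["input_individuals"] = G_all.n_individuals
    report.stage_counts["input_loci"] = G_all.n_loci

    # ---- qc -------------------------------------------------------------
    G_all, removed_loci = qc_stage(G_all, thr)
    report.stage_counts["post_qc_individuals"] = G_all.n_individuals
    report.stage_counts["post_qc_loci"] = G_all.n_loci
    report.exclusions["removed_loci"] = len(removed_loci)
    allele_codes = G_all.locus_allele_codes()
    is_base = (G_all.meta["role"] == "baseline").to_numpy()
    G_base = G_all.take_individuals(np.flatnonzero(is_base))
    G_mix = G_all.take_individuals(np.flatnonzero(~is_base))

    # ---- relatedness ----------------------------------------------------
    G_base, pair_table, fam_table = relatedness.sibling_filter(
        G_base, thr.sib_relatedness)
    report.stage_counts["post_sib_individuals"] = G_base.n_individuals
    report.exclusions["sib_pruned"] = int((~fam_table["retained"]).sum()) if len(fam_table) else 0

    # ---- baseline -------------------------------------------------------
    grouping, merge_log = bl.aggregate_collections(
        G_base, stream_of, thr.self_assignment, thr.fst_merge)
    units = bl.build_units(G_base, grouping, stream_of, network_point_of)
    units, excl = bl.exclude_small_collections(units, thr.small_collection)
    if rs is not None:
        # relabel units by their source population where unambiguous, so
        # downstream covariate joins use population ids
        proposed = {}
        for u in units:
            pops = {pop_of[c] for c in u.collection_ids if c in pop_of}
            proposed[u.unit_id] = pops.pop() if len(pops) == 1 else u.unit_id
        counts = pd.Series(list(proposed.values())).value_counts()
        for u in units:
            new = proposed[u.unit_id]
            if counts[new] == 1:
                for c in u.collection_ids:
                    grouping[c] = new
                u.unit_id = new
    keep_colls = {c for u in units for c in u.collection_ids}
    G_base = G_base.take_individuals(np.flatnonzero(
        G_base.meta["collection_id"].isin(keep_colls).to_numpy()))
    unit_of = {c: u.unit_id for u in units for c in u.collection_ids}
    post, confusion = bl.self_assignment_loo(G_base, unit_of)
    fst = bl.weir_cockerham_fst(G_base, unit_of)
    report.stage_counts["n_collections"] = len(unit_of)
    report.stage_counts["n_units"] = len(units)
    report.exclusions["small_collections"] = len(excl)
    report.diagnostics["weighted_mean_self_assignment"] = confusion.weighted_mean_self_rate(
        {u.unit_id: u.n_individuals for u in units})
    report.diagnostics["global_fst"] = fst.global_theta

    # ---- mixtures -------------------------------------------------------
    fits, zrows = [], []
    strata = sorted({(s, int(y)) for s, y in
                     zip(G_mix.meta["section"], G_mix.meta["year"])})
    skipped = []
    for section, year in strata:
        sel = ((G_mix.meta["section"] == section)
               & (G_mix.meta["year"] == year)).to_numpy()
        if sel.sum() == 0:
            skipped.append((section, year))
            continue
        stratum = G_mix.take_individuals(np.flatnonzero(sel))
        fit = gsi.fit_mixture(units, stratum, smp.gsi_sweeps, smp.gsi_burn,
                              seed=seeds["gsi"] + len(fits),
                              allele_codes=allele_codes)
        gsi.bootstrap_correct(fit, units, smp.bootstrap_reps,
                              seed=seeds["bootstrap"] + len(fits),
                              sweeps=smp.bootstrap_sweeps, burn=smp.bootstrap_burn)
        z = gsi.z_scores(fit, units, stratum, allele_codes=allele_codes)
        z["section"], z["year"] = section, year
        zrows.append(z)
        fits.append(fit)
    report.stage_counts["n_strata"] = len(fits)
    report.exclusions["skipped_strata"] = skipped
    zscores = pd.concat(zrows, ignore_index=True) if zrows else pd.DataFrame()
    if len(zscores):
        report.diagnostics["zscore_flag_rate"] = float(
            zscores["flagged_missing_source"].mean())
    composition = composition_table(fits)
    dispersal = gsi.dispersal_summary(fits, units, net, thr.assignment_prob) \
        if net is not None else None
    if dispersal is not None:
        report.diagnostics["median_dispersal_km"] = dispersal.median_km
        report.diagnostics["max_dispersal_km"] = dispersal.max_km

    # ---- composition models --------------------------------------------
    dirichlet_table = None
    if smp.run_dirichlet_loo:
        from .dirichlet_model import loo_compare

        Y = composition
        if smp.dirichlet_top_k:
            Y = collapse_minor_units(Y, smp.dirichlet_top_k)
        obs = Y.index.to_frame(index=False)
        dirichlet_table = loo_compare(
            obs, Y.to_numpy(), seed=seeds["dirichlet"],
            chains=smp.dirichlet_chains, warmup=smp.dirichlet_warmup,
            iterations=smp.dirichlet_iterations)
        report.diagnostics["dirichlet_best_model"] = str(
            dirichlet_table.iloc[0]["model"])

    # ---- covariate model ------------------------------------------------
    long_table = contribution_long_table(composition, covariates, net)
    zib = fit_zib(long_table, chains=smp.zib_chains, warmup=smp.zib_warmup,
                  iterations=smp.zib_iterations, seed=seeds["zib"])
    ppc = posterior_predictive_check(zib, seed=seeds["zib"] + 1)
    intercepts = zib.random_intercepts()
    intercepts = intercepts.merge(
        covariates[["latitude_proxy", "region"]], left_on="unit",
        right_index=True, how="left")
    report.diagnostics["zib_rhat"] = zib.rhat
    report.diagnostics["zib_converged"] = bool(zib.converged)

    # ---- spatial --------------------------------------------------------
    pts = [f"pop_{u}" for u in intercepts["unit"]]
    vals = intercepts["alpha_r_mean"].to_numpy()
    on_net = [p in net.graph for p in pts]
    pts_ok = [p for p, ok in zip(pts, on_net) if ok]
    vals_ok = vals[np.array(on_net, bool)]
    semis = {}
    for metric in ("watercourse", "euclidean"):
        D = spatial.distance_matrix(net, pts_ok, metric)
        semis[metric] = spatial.empirical_semivariogram(
            vals_ok, D, metric=metric)
    lat = intercepts["latitude_proxy"].to_numpy(float)
    trend = spatial.latitude_trend(vals, lat)
    report.diagnostics["latitude_slope"] = trend[0]
    report.diagnostics["latitude_slope_ci"] = trend[2]

    # ---- outputs --------------------------------------------------------
    if outdir:
        _write_outputs(outdir, report, rs, composition, fst, confusion,
                       zscores, dispersal, dirichlet_table, zib, ppc,
                       intercepts, semis)
    return RunResult(config, report, rs, units, fst, confusion, fits,
                     composition, zib, ppc, intercepts, semis, trend,
                     dirichlet_table, zscores, dispersal)


def _write_outputs(outdir, report, rs, composition, fst, confusion, zscores,
                   dispersal, dirichlet_table, zib, ppc, intercepts, semis):
    outdir = Path(outdir)
    def save(df, name):
        path = outdir / name
        df.to_csv(path)
        report.add_file(path)
    save(composition, "composition.csv")
    save(fst.as_frame() if hasattr(fst, "as_frame")
         else pd.DataFrame(fst.matrix, index=fst.ids, columns=fst.ids), "fst.csv")
    save(confusion.probabilities, "confusion.csv")
    if len(zscores):
        save(zscores, "zscores.csv")
    if dispersal is not None:
        save(dispersal.distances, "dispersal.csv")
    if dirichlet_table is not None:
        save(dirichlet_table, "composition_model_selection.csv")
    save(zib.summary(), "zib_posterior_summary.csv")
    save(ppc, "zib_ppc.csv")
    save(intercepts, "random_intercepts.csv")
    for metric, est in semis.items():
        save(est.bins, f"semivariogram_{metric}.csv")
    if rs is not None:
        write_genotype_table(rs.baseline, outdir / "baseline_genotypes.csv")
        report.add_file(outdir / "baseline_genotypes.csv")
    (outdir / "run_report.json").write_text(report.to_json())
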