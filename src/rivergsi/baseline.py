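"""Baseline construction: differentiation, self-assignment, aggregation.

Collections of juveniles sampled in tributaries are screened into reporting
units ("source populations") that the mixture model can tell apart:

* pairwise and global Weir--Cockerham theta (variance-components FST,
  ratio-of-sums across loci);
* leave-one-out self-assignment under the Hardy--Weinberg genotype
  likelihood with Dirichlet-posterior allele frequencies (each individual's
  own alleles removed from its group's counts before evaluation);
* iterative aggregation of confusable pairs (self-assignment rate below a
  threshold with the largest misassignment flowing to the partner, pairwise
  theta below a threshold, and both collections on the same stream);
* exclusion of tiny unmergeable collections;
* a simulation-based accuracy assessment that repeatedly gene-drops
  mixtures from the baseline allele pools and measures the bias of
  re-estimated mixing proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

DEFAULT_PRIOR = 0.5  # per-allele Dirichlet prior: 1 / (number of alleles)


# ---------------------------------------------------------------- counting --
def allele_counts(codes: np.ndarray, groups: np.ndarray, n_groups: int):
    """Alt-allele and total-allele counts per group and locus.

    ``codes``: (n, L) alt dosages, -1 missing.  Returns (alt, tot), each
    (n_groups, L); tot = 2 * called individuals.
    """
    called = codes >= 0
    L = codes.shape[1]
    alt = np.zeros((n_groups, L))
    tot = np.zeros((n_groups, L))
    for g in range(n_groups):
        sel = groups == g
        alt[g] = np.where(called[sel], codes[sel], 0).sum(axis=0)
        tot[g] = 2.0 * called[sel].sum(axis=0)
    return alt, tot


@dataclass
class BaselineUnit:
    """A reporting unit: one or more aggregated collections."""

    unit_id: str
    collection_ids: list[str]
    allele_counts: np.ndarray  # (L, 2): [ref, alt]
    n_individuals: int
    stream_id: str = ""
    network_point: str | None = None

    @property
    def alt(self) -> np.ndarray:
        return self.allele_counts[:, 1]

    @property
    def tot(self) -> np.ndarray:
        return self.allele_counts.sum(axis=1)


def build_units(
    G: GenotypeMatrix,
    grouping: dict[str, str] | None = None,
    stream_of: dict[str, str] | None = None,
    network_point_of: dict[str, str] | None = None,
) -> list[BaselineUnit]:
    """Construct units from a baseline matrix.  ``grouping`` maps collection
    id -> unit id (default: one unit per collection)."""
    colls = G.meta["collection_id"]
    grouping = grouping or {c: c for c in colls.unique()}
    unit_ids = sorted(set(grouping.values()))
    codes = G.to_codes()
    units = []
    for uid in unit_ids:
        members = sorted(c for c, u in grouping.items() if u == uid)
        sel = colls.isin(members).to_numpy()
        sub = codes[sel]
        called = sub >= 0
        alt = np.where(called, sub, 0).sum(axis=0).astype(float)
        tot = 2.0 * called.sum(axis=0)
        counts = np.stack([tot - alt, alt], axis=1)
        stream = ""
        if stream_of:
            streams = {stream_of.get(c, "") for c in members}
            stream = streams.pop() if len(streams) == 1 else "+".join(sorted(streams))
        npoint = network_point_of.get(members[0]) if network_point_of else None
        units.append(BaselineUnit(uid, members, counts, int(sel.sum()), stream, npoint))
    return units


# --------------------------------------------------------------------- fst --
@dataclass
class FstMatrix:
    ids: list[str]
    matrix: np.ndarray
    global_theta: float

    def pair(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


def _wc_components(codes: np.ndarray, groups: np.ndarray, n_groups: int):
    """Per-locus Weir--Cockerham variance components (a, b, c) for the
    alternate allele, vectorized across loci.  Loci where any group has no
    called individual, or with fewer than two gene copies overall, are
    masked out (returned as zeros)."""
    r = n_groups
    called = codes >= 0
    het = codes == 1
    L = codes.shape[1]
    n = np.zeros((r, L))
    p = np.zeros((r, L))
    h = np.zeros((r, L))
    for g in range(r):
        sel = groups == g
        cg = called[sel]
        n[g] = cg.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[g] = np.where(n[g] > 0, np.where(cg, codes[sel], 0).sum(axis=0) / (2 * np.maximum(n[g], 1)), 0.0)
            h[g] = np.where(n[g] > 0, (het[sel] & cg).sum(axis=0) / np.maximum(n[g], 1), 0.0)
    valid = (n > 0).all(axis=0)
    nsum = n.sum(axis=0)
    nbar = nsum / r
    valid &= nbar > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n * p).sum(axis=0) / nsum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / nsum
        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4
        a = (nbar / nc) * (s2 - inner / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    a = np.where(valid, a, 0.0)
    b = np.where(valid, b, 0.0)
    c = np.where(valid, c, 0.0)
    return a, b, c, valid


def weir_cockerham_fst(
    G: GenotypeMatrix, grouping: dict[str, str] | None = None, by: str = "collection_id",
) -> FstMatrix:
    """Pairwise and global Weir--Cockerham theta across groups.

    Variance components are summed over loci (ratio of sums); invariant loci
    contribute components without producing NaNs.
    """
    labels = G.meta[by]
    if grouping:
        labels = labels.map(lambda c: grouping.get(c, c))
    ids = sorted(labels.unique())
    gmap = {g: i for i, g in enumerate(ids)}
    gi = labels.map(gmap).to_numpy()
    if len(ids) < 2:
        raise ValueError("need at least two groups")
    codes = G.to_codes()
    a, b, c, valid = _wc_components(codes, gi, len(ids))
    if not valid.any():
        raise ValueError("no locus with called individuals in every group")
    denom = (a + b + c).sum()
    global_theta = float(a.sum() / denom) if denom != 0 else 0.0
    M = np.zeros((len(ids), len(ids)))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            sel = (gi == i) | (gi == j)
            sub_groups = (gi[sel] == j).astype(int)
            ap, bp, cp, v = _wc_components(codes[sel], sub_groups, 2)
            den = (ap + bp + cp).sum()
            M[i, j] = M[j, i] = ap.sum() / den if den != 0 else 0.0
    return FstMatrix(ids, M, global_theta)


# ----------------------------------------------------------- self-assignment --
@dataclass
class ConfusionMatrix:
    ids: list[str]
    probabilities: pd.DataFrame  # mean assignment probability, rows = true
    argmax_rates: pd.DataFrame

    def self_rates(self) -> pd.Series:
        return pd.Series(np.diag(self.probabilities.to_numpy()),
                         index=self.ids, name="self_assignment")

    def weighted_mean_self_rate(self, weights: dict[str, float] | None = None) -> float:
        r = self.self_rates()
        if weights is None:
            return float(r.mean())
        w = np.array([weights[i] for i in self.ids], dtype=float)
        return float((r.to_numpy() * w).sum() / w.sum())


def _log_freqs(alt, tot, prior=DEFAULT_PRIOR):
    p = (alt + prior) / (tot + 2 * prior)
    return np.log(p), np.log1p(-p)


def _loglik_rows(codes: np.ndarray, logp: np.ndarray, log1mp: np.ndarray) -> np.ndarray:
    """(n, G) HWE genotype log-likelihood of each row against each group.

    ``logp``/``log1mp``: (G, L) log allele frequencies."""
    i0 = (codes == 0).astype(float)
    i1 = (codes == 1).astype(float)
    i2 = (codes == 2).astype(float)
    ll = (i0 @ (2 * log1mp).T
          + i1 @ (np.log(2.0) + logp + log1mp).T
          + i2 @ (2 * logp).T)
    return ll


def self_assignment_loo(
    G: GenotypeMatrix,
    grouping: dict[str, str] | None = None,
    prior: float = DEFAULT_PRIOR,
) -> tuple[pd.DataFrame, ConfusionMatrix]:
    """Leave-one-out self-assignment of every baseline individual.

    Each individual's own alleles are subtracted from its group's counts
    before its genotype likelihood for that group is computed; posteriors
    use a uniform prior over groups.  Returns the per-individual posterior
    table and the confusion matrix (rows sum to 1).
    """
    labels = G.meta["collection_id"]
    if grouping:
        labels = labels.map(lambda c: grouping.get(c, c))
    ids = sorted(labels.unique())
    gmap = {g: i for i, g in enumerate(ids)}
    gi = labels.map(gmap).to_numpy()
    codes = G.to_codes()
    alt, tot = allele_counts(codes, gi, len(ids))
    logp, log1mp = _log_freqs(alt, tot, prior)
    ll = _loglik_rows(codes, logp, log1mp)
    # leave-one-out correction of the own-group column
    called = codes >= 0
    for i in range(codes.shape[0]):
        g = gi[i]
        own_alt = alt[g] - np.where(called[i], codes[i], 0)
        own_tot = tot[g] - 2.0 * called[i]
        if not np.any(own_tot > 0):
            warnings.warn(f"group {ids[g]!r} has a single member; "
                          "leave-one-out falls back to the prior mean")
        lp, l1p = _log_freqs(own_alt, own_tot, prior)
        c = codes[i]
        ll[i, g] = np.where(c == 0, 2 * l1p,
                            np.where(c == 1, np.log(2.0) + lp + l1p,
                                     np.where(c == 2, 2 * lp, 0.0))).sum()
    post = np.exp(ll - ll.max(axis=1, keepdims=True))
    post /= post.sum(axis=1, keepdims=True)
    post_df = pd.DataFrame(post, columns=ids)
    post_df.insert(0, "individual_id", G.meta["individual_id"].to_numpy())
    post_df.insert(1, "true_group", [ids[g] for g in gi])
    conf = post_df.groupby("true_group")[ids].mean().reindex(ids)
    am = pd.get_dummies(pd.Series([ids[k] for k in post.argmax(axis=1)]))
    am = am.reindex(columns=ids, fill_value=0).astype(float)
    am.insert(0, "true_group", [ids[g] for g in gi])
    conf_am = am.groupby("true_group")[ids].mean().reindex(ids)
    return post_df, ConfusionMatrix(ids, conf, conf_am)


# -------------------------------------------------------------- aggregation --
def aggregate_collections(
    G: GenotypeMatrix,
    stream_of: dict[str, str],
    self_rate_threshold: float = 0.7,
    fst_threshold: float = 0.01,
    max_iter: int = 100,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Iteratively merge confusable same-stream collection pairs.

    A pair qualifies when (i) one member's self-assignment rate is below
    ``self_rate_threshold`` and its largest off-diagonal assignment mass
    flows to the other, (ii) pairwise theta is below ``fst_threshold``
    (strict), and (iii) both lie on the same stream.  The lowest-theta
    qualifying pair is merged first; confusion and theta are recomputed
    after every merge.  Returns (collection -> unit mapping, merge log).
    """
    grouping = {c: c for c in G.meta["collection_id"].unique()}
    log_rows = []
    for it in range(max_iter):
        _, conf = self_assignment_loo(G, grouping)
        fst = weir_cockerham_fst(G, grouping)
        ids = conf.ids
        rates = conf.self_rates()
        P = conf.probabilities.to_numpy()
        streams = {}
        for uid in ids:
            ss = {stream_of.get(c, "") for c, u in grouping.items() if u == uid}
            streams[uid] = ss.pop() if len(ss) == 1 else None
        candidates = []
        for i, u in enumerate(ids):
            if rates[u] >= self_rate_threshold:
                continue
            off = P[i].copy()
            off[i] = -np.inf
            j = int(np.argmax(off))
            v = ids[j]
            theta = fst.pair(u, v)
            if theta < fst_threshold and streams[u] is not None and streams[u] == streams[v]:
                candidates.append((theta, u, v))
        if not candidates:
            break
        theta, u, v = min(candidates)
        new_id = "+".join(sorted(set(u.split("+")) | set(v.split("+"))))
        for c, g in grouping.items():
            if g in (u, v):
                grouping[c] = new_id
        log_rows.append({"iteration": it, "merged_a": u, "merged_b": v,
                         "theta": theta, "unit": new_id,
                         "self_rate_a": rates[u], "self_rate_b": rates[v]})
    return grouping, pd.DataFrame(
        log_rows, columns=["iteration", "merged_a", "merged_b", "theta",
                           "unit", "self_rate_a", "self_rate_b"])


def exclude_small_collections(
    units: list[BaselineUnit], max_n: int = 5,
) -> tuple[list[BaselineUnit], pd.DataFrame]:
    """Drop un-aggregated units (single collection) with n <= ``max_n``."""
    kept, rows = [], []
    for u in units:
        if len(u.collection_ids) == 1 and u.n_individuals <= max_n:
            rows.append({"collection": u.collection_ids[0], "n": u.n_individuals,
                         "reason": f"n <= {max_n} and aggregation not feasible"})
        else:
            kept.append(u)
    return kept, pd.DataFrame(rows, columns=["collection", "n", "reason"])


# ---------------------------------------------------------- bias assessment --
def assess_reference_loo(
    units: list[BaselineUnit],
    n_sims: int = 500,
    mixture_size: int = 1000,
    seed: int | np.random.Generator = 0,
    sweeps: int = 400,
    burn: int = 100,
) -> pd.DataFrame:
    """Simulation assessment of baseline accuracy.

    Each replicate draws true mixing proportions from Dirichlet(1), builds a
    mixture by gene-dropping (each simulated fish's two alleles per locus
    sampled without replacement from its unit's observed allele pool, and
    removed from that unit's counts when its own likelihood is evaluated),
    re-estimates proportions with the mixture engine, and records
    residuals (true - estimated).  Returns a per-unit summary with the mean
    and SD of residuals and whether mean +/- SD overlaps zero.
    """
    from .gsi import gibbs_mixture, unit_log_freqs

    if len(units) < 2:
        raise ValueError("need at least two units")
    rng = np.random.default_rng(seed)
    U = len(units)
    L = units[0].allele_counts.shape[0]
    logp, log1mp = unit_log_freqs(units)
    residuals = np.zeros((n_sims, U))
    alt_pool = np.array([np.round(u.alt) for u in units]).astype(np.int64)
    tot_pool = np.array([np.round(u.tot) for u in units]).astype(np.int64)
    # degenerate loci with <2 observed gene copies fall back to a 50:50 pool
    thin = tot_pool < 2
    alt_pool[thin], tot_pool[thin] = 1, 2
    for sim in range(n_sims):
        pi = rng.dirichlet(np.ones(U))
        n_u = rng.multinomial(mixture_size, pi)
        blocks = []
        for k, u in enumerate(units):
            if n_u[k] == 0:
                continue
            x = rng.hypergeometric(alt_pool[k], tot_pool[k] - alt_pool[k], 2,
                                   size=(n_u[k], L))
            blocks.append((k, x))
        codes = np.concatenate([x for _, x in blocks], axis=0).astype(np.int8)
        ll = _loglik_rows(codes, logp, log1mp)
        row = 0
        for k, x in blocks:
            # leave-one-out: the fish's own two gene copies leave the pool
            alt_adj = alt_pool[k] - x
            tot_adj = tot_pool[k] - 2.0
            lp, l1p = _log_freqs(alt_adj, tot_adj)
            own = np.where(x == 0, 2 * l1p,
                           np.where(x == 1, np.log(2.0) + lp + l1p, 2 * lp)).sum(axis=1)
            ll[row:row + len(x), k] = own
            row += len(x)
        pi_hat, _, _ = gibbs_mixture(ll, sweeps=sweeps, burn=burn, rng=rng)
        residuals[sim] = pi - pi_hat
    mean = residuals.mean(axis=0)
    sd = residuals.std(axis=0, ddof=1)
    return pd.DataFrame({
        "unit": [u.unit_id for u in units],
        "mean_residual": mean,
        "sd_residual": sd,
        "overlaps_zero": np.abs(mean) <= sd,
    })
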