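"""Pairwise relatedness, full-sibling classification and family pruning.

Baseline collections are screened for close kin because full-sib families
distort collection allele-frequency estimates and downstream assignment.
The pairwise estimator is the moment estimator built on genotype-similarity
categories: for a pair of diploid genotypes at one locus the observable
outcome is (1) identical genotypes, (2) one homozygote and one heterozygote
sharing an allele, (3) both heterozygous sharing exactly one allele, or (4)
no allele in common.  The category probabilities are polynomial in the
population allele frequencies and linear in the pair's IBD coefficients
(phi = P(one pair of genes IBD), Delta = P(both pairs IBD)); inverting the
moment equations gives phi and Delta, and relatedness r = phi/2 + Delta.

For strictly biallelic markers category (3) is impossible (it needs three
distinct alleles), so the system reduces to two equations in two unknowns
and is solved exactly, with per-locus information weights w_l proportional
to 1/u_l, u_l = 2*a2 - a3 (a_m the m-th power sums of allele frequencies).
Loci with a missing call in either individual, or monomorphic in the
reference frequencies, are skipped and excluded from n_loci_used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


@dataclass(frozen=True)
class RelatednessPair:
    individual_a: str
    individual_b: str
    r_wang: float
    n_loci_used: int


@dataclass
class SibFamily:
    member_ids: frozenset[str]
    retained_ids: frozenset[str] = frozenset()


def _locus_coefficients(p: np.ndarray):
    """Per-locus category-probability coefficients from alt-allele freq p."""
    q = 1.0 - p
    a2 = p**2 + q**2
    a3 = p**3 + q**3
    a4 = p**4 + q**4
    b = 2 * a2**2 - a4          # P(identical | unrelated)
    c = a2 - 2 * a2**2 + a4     # P(identical | 1 IBD) - b
    d = 4 * (a3 - a4)           # P(hom-het share | unrelated)
    e = 2 * (a2 - 3 * a3 + 2 * a4)  # P(hom-het share | 1 IBD) - d
    u = 2 * a2 - a3
    return b, c, d, e, u


def wang_relatedness_matrix(
    codes: np.ndarray, freqs: np.ndarray, ids: list[str] | None = None,
) -> list[RelatednessPair]:
    """All within-group pairs from a dosage matrix.

    ``codes``: (n, L) alt-allele dosages with -1 missing; ``freqs``: per-locus
    alt-allele frequencies of the reference (collection) sample.
    """
    n, L = codes.shape
    ids = ids or [str(i) for i in range(n)]
    poly = (freqs > 1e-9) & (freqs < 1 - 1e-9)
    b, c, d, e, u = _locus_coefficients(freqs)
    w_raw = np.where(poly, 1.0 / u, 0.0)
    het = codes == 1
    called = codes >= 0
    out = []
    for i, j in combinations(range(n), 2):
        use = called[i] & called[j] & poly
        nl = int(use.sum())
        if nl == 0:
            raise ValueError(f"no usable loci for pair ({ids[i]}, {ids[j]})")
        w = w_raw[use]
        w = w / w.sum()
        gi, gj = codes[i, use], codes[j, use]
        s1 = gi == gj                                     # identical genotypes
        s2 = (het[i, use] != het[j, use]) & (np.abs(gi - gj) == 1)  # hom-het sharing
        P1 = float(w @ s1)
        P2 = float(w @ s2)
        bb, cc, dd, ee = (float(w @ x[use]) for x in (b, c, d, e))
        y1, y2 = P1 - bb, P2 - dd
        det = cc * dd + ee * (1.0 - bb)
        phi = (dd * y1 + (1.0 - bb) * y2) / det
        delta = (ee * y1 - cc * y2) / det
        out.append(RelatednessPair(ids[i], ids[j], phi / 2.0 + delta, nl))
    return out


def wang_relatedness(
    a: np.ndarray, b: np.ndarray, freqs: np.ndarray,
    id_a: str = "a", id_b: str = "b",
) -> RelatednessPair:
    """Relatedness for one pair of dosage vectors (see module docstring)."""
    pair = wang_relatedness_matrix(np.vstack([a, b]), freqs, [id_a, id_b])
    return pair[0]


def pairwise_within_collections(
    G: GenotypeMatrix,
) -> pd.DataFrame:
    """Wang relatedness for every pair within each baseline collection,
    using collection-level allele frequencies (all its individuals)."""
    codes = G.to_codes()
    rows = []
    for coll, idx in G.meta.groupby("collection_id").groups.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            continue
        sub = codes[idx]
        called = sub >= 0
        n_called = called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            freqs = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), 0.0)
        ids = G.meta["individual_id"].iloc[idx].tolist()
        for pr in wang_relatedness_matrix(sub, freqs, ids):
            rows.append({"collection": coll, "a": pr.individual_a, "b": pr.individual_b,
                         "r": pr.r_wang, "n_loci": pr.n_loci_used})
    return pd.DataFrame(rows, columns=["collection", "a", "b", "r", "n_loci"])


def build_sib_families(pairs, threshold: float = 0.4) -> list[SibFamily]:
    """Connected components of the graph whose edges are pairs with
    r strictly greater than ``threshold``; singletons are their own family.

    ``pairs`` is a list of RelatednessPair or a DataFrame with columns
    a, b, r (pairs from a single collection)."""
    if isinstance(pairs, pd.DataFrame):
        items = [(r.a, r.b, r.r) for r in pairs.itertuples()]
    else:
        items = [(p.individual_a, p.individual_b, p.r_wang) for p in pairs]
    import networkx as nx

    g = nx.Graph()
    for a, b, r in items:
        g.add_node(a)
        g.add_node(b)
        if r > threshold:
            g.add_edge(a, b)
    return [SibFamily(frozenset(comp)) for comp in nx.connected_components(g)]


def prune_families(
    families: list[SibFamily], G: GenotypeMatrix, keep: int = 2,
) -> set[str]:
    """Retain at most ``keep`` members per family: highest call rate first,
    ties broken by lexicographically smallest id.  Returns the retained id
    set (and records it on each family)."""
    rate = dict(zip(G.meta["individual_id"], G.call_rate()))
    retained: set[str] = set()
    for fam in families:
        members = sorted(fam.member_ids, key=lambda i: (-rate.get(i, 0.0), i))
        kept = frozenset(members[:keep])
        fam.retained_ids = kept
        retained |= kept
    return retained


def sibling_filter(
    G: GenotypeMatrix, threshold: float = 0.4,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Full screening pass over all baseline collections: estimate pairwise
    relatedness, classify full-sib families (r > threshold), keep two per
    family, and subset the matrix.  Returns (filtered matrix, pair table,
    family table)."""
    pairs = pairwise_within_collections(G)
    retained_all: set[str] = set(G.meta["individual_id"])
    fam_rows = []
    for coll, sub in pairs.groupby("collection"):
        fams = build_sib_families(sub, threshold)
        retained = prune_families(fams, G)
        ids_in_coll = set(sub["a"]) | set(sub["b"])
        retained_all -= ids_in_coll - retained
        for k, fam in enumerate(f for f in fams if len(f.member_ids) > 1):
            for m in sorted(fam.member_ids):
                fam_rows.append({"collection": coll, "family": f"{coll}_F{k + 1}",
                                 "individual_id": m,
                                 "retained": m in fam.retained_ids})
    fam_table = pd.DataFrame(fam_rows,
                             columns=["collection", "family", "individual_id", "retained"])
    return G.subset_ids(retained_all), pairs, fam_table
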