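"""Genotype tables, metadata, and quality-control filters.

Diploid SNP genotypes are held as an individuals x loci x 2 array of allele
codes (strings, preserved verbatim), with a single internal missing marker
``""``.  Baseline individuals carry a collection id; mixture individuals carry
the main-stem section and sampling year they were captured in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = ""
#: markers normalized to :data:`MISSING` on read
_MISSING_INPUT = {"", "0", "NA", "na", "NaN", "nan", "-"}

META_COLUMNS = ["individual_id", "collection_id", "role", "section", "year"]


@dataclass
class LocusPanel:
    """Per-locus screening metadata."""

    locus_name: str
    flagged_class: str = "none"  # none | species_diagnostic | mitochondrial
    n_alleles_observed: int = 2

    def __post_init__(self) -> None:
        if self.flagged_class not in {"none", "species_diagnostic", "mitochondrial"}:
            raise ValueError(f"unknown flagged_class {self.flagged_class!r}")


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid calls plus sample metadata.

    ``meta`` has columns ``individual_id, collection_id, role, section, year``
    (unused fields empty / NA).  ``alleles`` has shape ``(n, L, 2)`` with
    string allele codes and :data:`MISSING` for no-calls; a call is missing
    all-or-nothing within a locus.
    """

    meta: pd.DataFrame
    alleles: np.ndarray
    locus_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.meta = self.meta.reset_index(drop=True)
        self.alleles = np.asarray(self.alleles, dtype=object).reshape(
            len(self.meta), len(self.locus_names), 2
        )
        if len(set(self.locus_names)) != len(self.locus_names):
            raise ValueError("duplicate locus names")
        ids = self.meta["individual_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate individual_id {dup!r}")
        # enforce all-or-nothing missingness within a locus call
        a = self.alleles
        half = (a[:, :, 0] == MISSING) != (a[:, :, 1] == MISSING)
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing call at individual {ids.iloc[i]!r}, locus {self.locus_names[l]!r}"
            )

    # ------------------------------------------------------------------ basic
    @property
    def n_individuals(self) -> int:
        return len(self.meta)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def called_mask(self) -> np.ndarray:
        """Boolean (n, L): genotype called at locus."""
        return self.alleles[:, :, 0] != MISSING

    def call_rate(self) -> np.ndarray:
        """Fraction of loci called, per individual."""
        return self.called_mask().mean(axis=1)

    def take_individuals(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.meta.iloc[list(index)], self.alleles[list(index)],
                              list(self.locus_names))

    def take_loci(self, index: list[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.meta, self.alleles[:, list(index), :],
                              [self.locus_names[i] for i in index])

    def subset_ids(self, ids) -> "GenotypeMatrix":
        keep = self.meta["individual_id"].isin(set(ids)).to_numpy()
        return self.take_individuals(np.flatnonzero(keep))

    def locus_allele_codes(self) -> list[list[str]]:
        """Sorted distinct allele codes observed at each locus."""
        out = []
        for l in range(self.n_loci):
            col = self.alleles[:, l, :].ravel()
            out.append(sorted({c for c in col if c != MISSING}))
        return out

    def to_codes(self, allele_codes: list[list[str]] | None = None) -> np.ndarray:
        """Encode as alt-allele dosage: 0/1/2 copies of the last allele code,
        -1 for missing.  Monomorphic loci encode as all zeros."""
        if allele_codes is None:
            allele_codes = self.locus_allele_codes()
        n, L = self.n_individuals, self.n_loci
        codes = np.full((n, L), -1, dtype=np.int8)
        called = self.called_mask()
        for l in range(L):
            if not allele_codes[l]:
                continue
            alt = allele_codes[l][-1]
            dose = (self.alleles[:, l, 0] == alt).astype(np.int8) + (
                self.alleles[:, l, 1] == alt
            ).astype(np.int8)
            codes[:, l] = np.where(called[:, l], dose, -1)
        return codes

    def concat(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if self.locus_names != other.locus_names:
            raise ValueError("locus panels differ")
        return GenotypeMatrix(
            pd.concat([self.meta, other.meta], ignore_index=True),
            np.concatenate([self.alleles, other.alleles], axis=0),
            list(self.locus_names),
        )


# ---------------------------------------------------------------------- io --
def _detect_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_genotype_table(path, sep: str | None = None) -> GenotypeMatrix:
    """Read a genotype table: metadata columns then two columns per locus
    (``<locus>`` and ``<locus>.1``).  Missing alleles (empty, ``0`` or ``NA``)
    are normalized to the single internal missing code."""
    if sep is None:
        sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    if "individual_id" not in meta_cols:
        raise ValueError("genotype table lacks an individual_id column")
    allele_cols = [c for c in df.columns if c not in META_COLUMNS]
    if len(allele_cols) % 2:
        raise ValueError(
            f"odd number of allele columns ({len(allele_cols)}); "
            "expected two columns per locus"
        )
    locus_names = []
    for i in range(0, len(allele_cols), 2):
        a, b = allele_cols[i], allele_cols[i + 1]
        if b != a + ".1":
            raise ValueError(f"allele columns {a!r}/{b!r} are not a <locus>/<locus>.1 pair")
        locus_names.append(a)
    meta = df[meta_cols].copy()
    for c in META_COLUMNS:
        if c not in meta.columns:
            meta[c] = ""
    meta = meta[META_COLUMNS]
    meta["year"] = pd.to_numeric(meta["year"], errors="coerce").astype("Int64")
    raw = df[allele_cols].to_numpy(dtype=object)
    norm = np.where(np.isin(raw, list(_MISSING_INPUT)), MISSING, raw)
    # all-or-nothing: one missing allele blanks the whole call
    norm = norm.reshape(len(df), len(locus_names), 2)
    any_missing = (norm == MISSING).any(axis=2)
    norm[any_missing] = MISSING
    return GenotypeMatrix(meta, norm, locus_names)


def write_genotype_table(G: GenotypeMatrix, path, sep: str = ",") -> None:
    """Inverse of :func:`read_genotype_table`; missing alleles written as 0."""
    meta = G.meta.copy()
    meta["year"] = meta["year"].astype(object).where(meta["year"].notna(), "")
    flat = G.alleles.reshape(G.n_individuals, 2 * G.n_loci)
    flat = np.where(flat == MISSING, "0", flat)
    cols = []
    for name in G.locus_names:
        cols.extend([name, name + ".1"])
    out = pd.concat([meta, pd.DataFrame(flat, columns=cols)], axis=1)
    out.to_csv(path, sep=sep, index=False)


# ----------------------------------------------------------------- filters --
def filter_by_call_rate(G: GenotypeMatrix, min_rate: float = 0.85) -> GenotypeMatrix:
    """Retain individuals genotyped at >= ``min_rate`` of loci (order kept)."""
    if not (0 <= min_rate <= 1):
        raise ValueError("min_rate must be in [0, 1]")
    keep = np.flatnonzero(G.call_rate() >= min_rate)
    if keep.size == 0:
        warnings.warn("call-rate filter removed every individual")
    return G.take_individuals(keep)


def drop_loci(
    G: GenotypeMatrix, panel: list[LocusPanel] | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove flagged (species-diagnostic / mitochondrial) and invariant loci.

    Invariance is assessed on the individuals present in ``G`` (after any
    individual filtering).  Returns the pruned matrix and a removal report
    with one row per dropped locus and its reason.
    """
    flags = {p.locus_name: p.flagged_class for p in panel or []}
    unknown = set(flags) - set(G.locus_names)
    if unknown:
        raise ValueError(f"panel names absent from matrix: {sorted(unknown)[:5]}")
    codes_per_locus = G.locus_allele_codes()
    rows = []
    keep = []
    for l, name in enumerate(G.locus_names):
        flag = flags.get(name, "none")
        if flag != "none":
            rows.append({"locus": name, "reason": flag})
        elif len(codes_per_locus[l]) <= 1:
            rows.append({"locus": name, "reason": "invariant"})
        else:
            keep.append(l)
    return G.take_loci(keep), pd.DataFrame(rows, columns=["locus", "reason"])


def exclude_individuals(G: GenotypeMatrix, exclude_ids) -> GenotypeMatrix:
    """Drop a pre-specified exclusion list (e.g. known hybrids)."""
    keep = ~G.meta["individual_id"].isin(set(exclude_ids)).to_numpy()
    return G.take_individuals(np.flatnonzero(keep))
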