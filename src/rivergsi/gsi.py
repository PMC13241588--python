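"""Bayesian genetic stock identification for main-stem mixtures.

Conditional GSI: reporting-unit allele frequencies are fixed at their
Dirichlet-posterior means (baseline counts plus a 1/(number of alleles)
prior per allele) and each section-year mixture is decomposed by a Gibbs
sampler that alternates latent origins z_i ~ Categorical(pi_u L_iu / sum)
with mixing proportions pi ~ Dirichlet(1/U + assignment counts).

Also provides the parametric-bootstrap bias correction of the estimated
proportions, the z-score check for individuals from sources missing from
the baseline, and flow-line dispersal-distance summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline import DEFAULT_PRIOR, BaselineUnit, _log_freqs, _loglik_rows
from .genotypes import GenotypeMatrix


# ------------------------------------------------------------- likelihoods --
def unit_posterior_freqs(unit: BaselineUnit, prior: float = DEFAULT_PRIOR) -> np.ndarray:
    """Posterior-mean alternate-allele frequency per locus:
    (count + prior) / (total + 2 * prior)."""
    return (unit.alt + prior) / (unit.tot + 2 * prior)


def unit_log_freqs(units: list[BaselineUnit], prior: float = DEFAULT_PRIOR):
    """(U, L) log p and log(1-p) arrays over units."""
    alt = np.array([u.alt for u in units])
    tot = np.array([u.tot for u in units])
    return _log_freqs(alt, tot, prior)


def genotype_loglik(codes_row: np.ndarray, freqs: np.ndarray) -> float:
    """Log HWE genotype probability of one dosage row (missing = -1 skipped)
    at the given alt-allele frequencies."""
    called = codes_row >= 0
    if not called.any():
        raise ValueError("all loci missing")
    c = codes_row[called]
    p = freqs[called]
    ll = np.where(c == 0, 2 * np.log1p(-p),
                  np.where(c == 1, np.log(2.0) + np.log(p) + np.log1p(-p),
                           2 * np.log(p)))
    return float(ll.sum())


def loglik_matrix(codes: np.ndarray, units: list[BaselineUnit],
                  prior: float = DEFAULT_PRIOR) -> np.ndarray:
    """(N, U) genotype log-likelihoods of mixture rows against every unit."""
    logp, log1mp = unit_log_freqs(units, prior)
    ll = _loglik_rows(codes, logp, log1mp)
    if not np.all(np.isfinite(ll)):
        i, u = np.argwhere(~np.isfinite(ll))[0]
        raise ValueError(f"non-finite likelihood for individual row {i}, unit {u}")
    return ll


# ------------------------------------------------------------------- gibbs --
def gibbs_mixture(
    logL: np.ndarray,
    sweeps: int = 2000,
    burn: int = 500,
    rng: np.random.Generator | int = 0,
    prior_alpha: float | None = None,
):
    """Gibbs sampler for mixing proportions given a fixed (N, U) genotype
    log-likelihood matrix.  Returns (pi posterior mean, pi draws after
    burn-in, mean responsibilities)."""
    rng = np.random.default_rng(rng)
    N, U = logL.shape
    alpha = 1.0 / U if prior_alpha is None else prior_alpha
    L = np.exp(logL - logL.max(axis=1, keepdims=True))
    pi = np.full(U, 1.0 / U)
    keep = sweeps - burn
    pi_draws = np.empty((keep, U))
    resp_sum = np.zeros((N, U))
    for t in range(sweeps):
        probs = L * pi
        probs /= probs.sum(axis=1, keepdims=True)
        # vectorized categorical draw per row
        z = (probs.cumsum(axis=1) < rng.random((N, 1))).sum(axis=1)
        counts = np.bincount(z, minlength=U)
        pi = rng.dirichlet(alpha + counts)
        if t >= burn:
            pi_draws[t - burn] = pi
            resp_sum += probs
    resp = resp_sum / keep
    return pi_draws.mean(axis=0), pi_draws, resp


@dataclass
class MixtureFit:
    stratum: tuple
    unit_ids: list[str]
    pi_posterior_mean: np.ndarray
    pi_draws: np.ndarray
    individual_posteriors: pd.DataFrame  # index individual_id, columns units
    pi_bootstrap_corrected: np.ndarray | None = None
    sampler_meta: dict = field(default_factory=dict)

    def assignments(self) -> pd.DataFrame:
        """Maximum-posterior unit and its probability per individual."""
        P = self.individual_posteriors[self.unit_ids].to_numpy()
        best = P.argmax(axis=1)
        return pd.DataFrame({
            "individual_id": self.individual_posteriors.index,
            "assigned_unit": [self.unit_ids[k] for k in best],
            "probability": P[np.arange(len(P)), best],
        })


def fit_mixture(
    units: list[BaselineUnit],
    mixture: GenotypeMatrix,
    sweeps: int = 2000,
    burn: int = 500,
    seed: int | np.random.Generator = 0,
    stratum: tuple | None = None,
    allele_codes: list[list[str]] | None = None,
) -> MixtureFit:
    """Fit one section-year mixture stratum.

    ``allele_codes`` fixes the per-locus allele ordering used to encode the
    mixture genotypes; it must match the ordering the unit allele counts
    were built with (pass the baseline matrix's ordering when allele sets
    differ between baseline and mixture)."""
    if len(units) < 2:
        raise ValueError("need at least two units")
    if mixture.n_individuals == 0:
        raise ValueError("empty mixture stratum")
    rng = np.random.default_rng(seed)
    codes = mixture.to_codes(allele_codes)
    ll = loglik_matrix(codes, units)
    pi_mean, pi_draws, resp = gibbs_mixture(ll, sweeps, burn, rng)
    post = pd.DataFrame(resp, columns=[u.unit_id for u in units],
                        index=pd.Index(mixture.meta["individual_id"], name="individual_id"))
    if stratum is None:
        sec = mixture.meta["section"].iloc[0]
        yr = mixture.meta["year"].iloc[0]
        stratum = (sec, int(yr) if pd.notna(yr) else None)
    return MixtureFit(
        stratum=stratum,
        unit_ids=[u.unit_id for u in units],
        pi_posterior_mean=pi_mean,
        pi_draws=pi_draws,
        individual_posteriors=post,
        sampler_meta={"sweeps": sweeps, "burn": burn},
    )


# --------------------------------------------------------------- bootstrap --
def _gene_drop_mixture(units, pi, n, rng):
    """Simulate a mixture by gene-dropping from unit allele pools."""
    U = len(units)
    L = units[0].allele_counts.shape[0]
    alt = np.array([np.round(u.alt) for u in units]).astype(np.int64)
    tot = np.array([np.round(u.tot) for u in units]).astype(np.int64)
    thin = tot < 2
    alt[thin], tot[thin] = 1, 2
    n_u = rng.multinomial(n, pi)
    blocks = [rng.hypergeometric(alt[k], tot[k] - alt[k], 2, size=(n_u[k], L))
              for k in range(U) if n_u[k] > 0]
    return np.concatenate(blocks, axis=0).astype(np.int8)


def bootstrap_correct(
    fit: MixtureFit,
    units: list[BaselineUnit],
    B: int = 100,
    seed: int | np.random.Generator = 0,
    sweeps: int = 500,
    burn: int = 150,
) -> np.ndarray:
    """Parametric-bootstrap bias correction of the mixing proportions.

    B mixtures of the stratum's size are gene-dropped with true proportions
    equal to the fitted posterior mean, re-estimated, and the mean bias is
    subtracted; the corrected vector is clipped at zero and renormalized.
    """
    rng = np.random.default_rng(seed)
    n = len(fit.individual_posteriors)
    pi0 = fit.pi_posterior_mean
    est = np.zeros((B, len(units)))
    for b in range(B):
        codes = _gene_drop_mixture(units, pi0, n, rng)
        ll = loglik_matrix(codes, units)
        est[b], _, _ = gibbs_mixture(ll, sweeps, burn, rng)
    bias = est.mean(axis=0) - pi0
    corrected = np.clip(pi0 - bias, 0.0, None)
    corrected /= corrected.sum()
    fit.pi_bootstrap_corrected = corrected
    return corrected


def zero_adjusted_contributions(fit: MixtureFit) -> pd.Series:
    """Per-unit contribution with an explicit exact-zero convention: a unit
    contributes 0 when no fish in the stratum has it as maximum-posterior
    assignment AND its corrected proportion is below 1/(2 n); otherwise the
    bootstrap-corrected (or raw posterior-mean) proportion is used, with the
    vector renormalized."""
    pi = (fit.pi_bootstrap_corrected if fit.pi_bootstrap_corrected is not None
          else fit.pi_posterior_mean).copy()
    n = len(fit.individual_posteriors)
    amax = set(fit.assignments()["assigned_unit"])
    for k, u in enumerate(fit.unit_ids):
        if u not in amax and pi[k] < 1.0 / (2 * n):
            pi[k] = 0.0
    s = pi.sum()
    if s > 0:
        pi = pi / s
    return pd.Series(pi, index=fit.unit_ids, name="contribution")


# ---------------------------------------------------------------- z-scores --
@dataclass
class ZScoreResult:
    individual_id: str
    z: float
    flagged_missing_source: bool


def z_scores(
    fit: MixtureFit,
    units: list[BaselineUnit],
    mixture: GenotypeMatrix,
    prior: float = DEFAULT_PRIOR,
    allele_codes: list[list[str]] | None = None,
) -> pd.DataFrame:
    """Standardized genotype log-likelihood under each fish's assigned unit.

    z = (logL - mu) / sigma where mu and sigma^2 sum the per-locus mean and
    variance of the log genotype probability under Hardy--Weinberg at the
    assigned unit's posterior frequencies, over the fish's called loci.
    Individuals with |z - mean(z)| > 2 SD(z) (within the mixture) are
    flagged as potentially from a source missing from the baseline.
    """
    codes = mixture.to_codes(allele_codes)
    unit_index = {u.unit_id: k for k, u in enumerate(units)}
    freqs = np.array([unit_posterior_freqs(u, prior) for u in units])
    assigned = fit.assignments()["assigned_unit"].map(unit_index).to_numpy()
    zs = np.empty(len(codes))
    for i in range(len(codes)):
        p = freqs[assigned[i]]
        called = codes[i] >= 0
        pc, c = p[called], codes[i][called]
        l0 = 2 * np.log1p(-pc)
        l1 = np.log(2.0) + np.log(pc) + np.log1p(-pc)
        l2 = 2 * np.log(pc)
        w0, w1, w2 = (1 - pc) ** 2, 2 * pc * (1 - pc), pc**2
        mu_l = w0 * l0 + w1 * l1 + w2 * l2
        var_l = w0 * l0**2 + w1 * l1**2 + w2 * l2**2 - mu_l**2
        obs = np.where(c == 0, l0, np.where(c == 1, l1, l2)).sum()
        sig = np.sqrt(var_l.sum())
        if sig == 0:
            warnings.warn("z-score undefined (all assigned loci fixed)")
            zs[i] = np.nan
            continue
        zs[i] = (obs - mu_l.sum()) / sig
    m, s = np.nanmean(zs), np.nanstd(zs)
    flagged = np.abs(zs - m) > 2 * s
    flagged &= ~np.isnan(zs)
    return pd.DataFrame({
        "individual_id": mixture.meta["individual_id"],
        "z": zs,
        "flagged_missing_source": flagged,
    })


# ---------------------------------------------------------------- dispersal --
@dataclass
class DispersalSummary:
    distances: pd.DataFrame
    median_km: float
    max_km: float
    prob_threshold: float


def dispersal_summary(
    fits: list[MixtureFit],
    units: list[BaselineUnit],
    net,
    prob_threshold: float = 0.7,
) -> DispersalSummary:
    """Flow-line distance between each fish's section midpoint of capture and
    its origin unit's network point, over fish assigned to a single unit with
    posterior above ``prob_threshold``."""
    from .spatial import watercourse_distance

    point_of = {u.unit_id: u.network_point for u in units}
    cache: dict[tuple, float] = {}
    rows = []
    for fit in fits:
        section = fit.stratum[0]
        mid = net.section_midpoints.get(section)
        asg = fit.assignments()
        for t in asg.itertuples():
            if t.probability <= prob_threshold:
                continue
            pt = point_of.get(t.assigned_unit)
            if pt is None:
                warnings.warn(f"unit {t.assigned_unit!r} has no network point; skipped")
                continue
            key = (mid, pt)
            if key not in cache:
                cache[key] = watercourse_distance(net, mid, pt)
            rows.append({"individual_id": t.individual_id, "section": section,
                         "year": fit.stratum[1], "unit": t.assigned_unit,
                         "probability": t.probability, "distance_km": cache[key]})
    df = pd.DataFrame(rows, columns=["individual_id", "section", "year", "unit",
                                     "probability", "distance_km"])
    med = float(df["distance_km"].median()) if len(df) else float("nan")
    mx = float(df["distance_km"].max()) if len(df) else float("nan")
    return DispersalSummary(df, med, mx, prob_threshold)
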