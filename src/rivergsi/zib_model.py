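"""Zero-inflated beta regression of tributary contributions.

The contribution p_rsy of source population r to main-stem section s in year
y is modelled as a two-part mixture: with probability omega_rsy the
contribution is a structural zero; otherwise p follows a Beta distribution in
mean--precision form, Beta(mu*phi, (1-mu)*phi).  The three distribution
parameters are linked to tributary covariates:

    logit mu_rsy  = a' + a'_s + a'_r + b1'*D_rs + b2'*A_r + b3'_s*G_r + b4'[C_r]
    logit om_rsy  = a'' + b1''*D + b2''*A + b3''*G + b4''[C]
    log   phi_rsy = a''' + b1'''*D + b2'''*A + b3'''*G + b4'''[C]

where D is flow-line distance to the section midpoint (km), A catchment area
(km^2), G the groundwater index and C the connectivity category (reference
level "connected").  a'_s and a'_r are hierarchical (random) intercepts for
section and source population; the groundwater slope b3'_s varies by section.
Neither the zero model nor the precision model carries random effects, and
there is no year intercept.  Continuous covariates are z-score standardized
over the dataset before entering the predictors.

The posterior is sampled by Hamiltonian Monte Carlo with analytic gradients
(:mod:`rivergsi.mcmc`); random intercepts use a non-centered
parameterization.  Priors are weakly informative: normal(0, 5) on intercepts
and slopes, half-normal(0, 2) on the random-effect standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, digamma, expit, gammaln

from . import mcmc

CONNECTIVITY_LEVELS = ["connected", "culvert_diversion", "low_flow", "waterfall"]

_N05 = 5.0  # prior sd for coefficients
_HN = 2.0  # half-normal prior scale for random-effect sds


# --------------------------------------------------------------- densities --
def zib_density(p, omega, mu, phi):
    """Density of the zero-inflated beta: omega at p == 0, else
    (1-omega) * Beta(p; mu*phi, (1-mu)*phi)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("p must lie in [0, 1)")
    a, b = mu * phi, (1.0 - mu) * phi
    interior = np.exp((a - 1) * np.log(np.where(p > 0, p, 0.5))
                      + (b - 1) * np.log1p(-p) - betaln(a, b))
    out = np.where(p == 0, omega, (1.0 - omega) * interior)
    return out if out.ndim else float(out)


def zib_loglik(p, omega, mu, phi):
    """Vectorized log-density (p may contain exact zeros)."""
    p = np.asarray(p, dtype=float)
    zero = p == 0
    a, b = mu * phi, (1.0 - mu) * phi
    safe_p = np.where(zero, 0.5, p)
    ll_beta = (a - 1) * np.log(safe_p) + (b - 1) * np.log1p(-safe_p) - betaln(a, b)
    return np.where(zero, np.log(omega), np.log1p(-omega) + ll_beta)


# ------------------------------------------------------------ coefficients --
def _zero_conn() -> dict[str, float]:
    return {lev: 0.0 for lev in CONNECTIVITY_LEVELS[1:]}


@dataclass
class ZIBCoefficients:
    """Fixed-effect coefficients (standardized-covariate scale) plus the
    random-effect scales of the contribution model; the defaults are the
    synthetic riverscape's generating values."""

    alpha_mu: float = -3.2
    beta_mu_distance: float = -0.8
    beta_mu_area: float = 0.5
    beta_mu_groundwater: float | np.ndarray = 0.3  # scalar or per-section
    beta_mu_connectivity: dict[str, float] = field(
        default_factory=lambda: {
            "culvert_diversion": -1.0, "low_flow": -0.8, "waterfall": -1.6,
        }
    )
    sigma_section: float = 0.3
    sigma_unit: float = 0.5

    alpha_omega: float = -1.0
    beta_omega_distance: float = 0.8
    beta_omega_area: float = -0.5
    beta_omega_groundwater: float = 0.0
    beta_omega_connectivity: dict[str, float] = field(default_factory=_zero_conn)

    alpha_phi: float = 3.2
    beta_phi_distance: float = 0.3
    beta_phi_area: float = -0.2
    beta_phi_groundwater: float = -0.1
    beta_phi_connectivity: dict[str, float] = field(
        default_factory=lambda: {
            "culvert_diversion": 0.3, "low_flow": 0.3, "waterfall": 0.5,
        }
    )

    def groundwater_slope(self, section_index: np.ndarray, n_sections: int) -> np.ndarray:
        b = np.asarray(self.beta_mu_groundwater, dtype=float)
        if b.ndim == 0:
            b = np.full(n_sections, float(b))
        return b[section_index]


# ------------------------------------------------------------ observations --
def standardize_covariates(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Z-score D, A, G over the dataset; returns the augmented frame and the
    (mean, sd) pairs used, for back-transforming coefficients."""
    out = df.copy()
    stats = {}
    for col in ["D", "A", "G"]:
        m, s = float(df[col].mean()), float(df[col].std(ddof=0))
        if s == 0:
            s = 1.0
        out[col + "_z"] = (df[col] - m) / s
        stats[col] = (m, s)
    return out, stats


def linear_predictors(
    df: pd.DataFrame,
    coef: ZIBCoefficients,
    section_levels: list | None = None,
    unit_levels: list | None = None,
    alpha_section: np.ndarray | None = None,
    alpha_unit: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate (omega, mu, phi) for each row of a covariate table with
    columns r, s, D_z, A_z, G_z, C.  Random intercepts default to zero."""
    section_levels = section_levels or sorted(df["s"].unique())
    unit_levels = unit_levels or sorted(df["r"].unique())
    s_idx = df["s"].map({v: i for i, v in enumerate(section_levels)}).to_numpy()
    r_idx = df["r"].map({v: i for i, v in enumerate(unit_levels)}).to_numpy()
    if df["C"].isin(CONNECTIVITY_LEVELS).sum() != len(df):
        bad = sorted(set(df["C"]) - set(CONNECTIVITY_LEVELS))
        raise ValueError(f"unknown connectivity level(s): {bad}")
    D, A, G = (df[c].to_numpy(float) for c in ["D_z", "A_z", "G_z"])
    conn_mu = df["C"].map(lambda c: coef.beta_mu_connectivity.get(c, 0.0)).to_numpy(float)
    conn_om = df["C"].map(lambda c: coef.beta_omega_connectivity.get(c, 0.0)).to_numpy(float)
    conn_ph = df["C"].map(lambda c: coef.beta_phi_connectivity.get(c, 0.0)).to_numpy(float)
    a_s = np.zeros(len(section_levels)) if alpha_section is None else alpha_section
    a_r = np.zeros(len(unit_levels)) if alpha_unit is None else alpha_unit
    gw = coef.groundwater_slope(s_idx, len(section_levels))

    eta_mu = (coef.alpha_mu + a_s[s_idx] + a_r[r_idx]
              + coef.beta_mu_distance * D + coef.beta_mu_area * A + gw * G + conn_mu)
    eta_om = (coef.alpha_omega + coef.beta_omega_distance * D
              + coef.beta_omega_area * A + coef.beta_omega_groundwater * G + conn_om)
    eta_ph = (coef.alpha_phi + coef.beta_phi_distance * D
              + coef.beta_phi_area * A + coef.beta_phi_groundwater * G + conn_ph)
    return expit(eta_om), expit(eta_mu), np.exp(eta_ph)


def simulate_zib_dataset(
    covariates: pd.DataFrame,
    coef: ZIBCoefficients,
    n_years: int = 3,
    seed: int | np.random.Generator = 0,
    extra_unit_logit: dict | None = None,
    year_mode: str = "iid",
) -> pd.DataFrame:
    """Draw a long-format contribution table (r, s, y, p, D, A, G, C) from
    the generative model.  ``covariates`` has one row per (r, s) with columns
    r, s, D, A, G, C.  Random intercepts are drawn N(0, sigma) per section and
    unit; ``extra_unit_logit`` adds fixed unit-level logit offsets (used by the
    riverscape generator to inject spatially structured signal).
    ``year_mode``: "iid" draws p independently each year; "constant" draws
    once and repeats it."""
    rng = np.random.default_rng(seed)
    df, _ = standardize_covariates(covariates)
    section_levels = sorted(df["s"].unique())
    unit_levels = sorted(df["r"].unique())
    a_s = rng.normal(0, coef.sigma_section, len(section_levels))
    a_r = rng.normal(0, coef.sigma_unit, len(unit_levels))
    if extra_unit_logit:
        a_r = a_r + np.array([extra_unit_logit.get(u, 0.0) for u in unit_levels])
    omega, mu, phi = linear_predictors(df, coef, section_levels, unit_levels, a_s, a_r)

    def draw():
        zero = rng.random(len(df)) < omega
        p = rng.beta(mu * phi, (1 - mu) * phi)
        p = np.clip(p, 1e-9, 1 - 1e-6)
        return np.where(zero, 0.0, p)

    rows = []
    p_const = draw() if year_mode == "constant" else None
    for y in range(n_years):
        p = p_const if p_const is not None else draw()
        block = df[["r", "s", "D", "A", "G", "C"]].copy()
        block["y"] = y
        block["p"] = p
        rows.append(block)
    out = pd.concat(rows, ignore_index=True)
    out.attrs["alpha_section"] = dict(zip(section_levels, a_s))
    out.attrs["alpha_unit"] = dict(zip(unit_levels, a_r))
    return out


# -------------------------------------------------------------------- model --
class _ZIBModel:
    """Log-posterior with analytic gradients, on a packed parameter vector.

    Packing order:
      [alpha_mu, bD', bA', bG'_s (S), bC' (len conn), eta_s (S), eta_r (R),
       log sig_s, log sig_r,
       alpha_om, bD'', bA'', bG'', bC'' (conn),
       alpha_ph, bD''', bA''', bG''', bC''' (conn)]
    """

    def __init__(self, data: pd.DataFrame):
        need = {"r", "s", "y", "p", "D", "A", "G", "C"}
        missing = need - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (data["p"] >= 1).any():
            warnings.warn("contribution equal to 1 squeezed to 1 - 1e-6")
            data = data.copy()
            data.loc[data["p"] >= 1, "p"] = 1 - 1e-6
        df, self.cov_stats = standardize_covariates(data)
        self.section_levels = sorted(df["s"].unique())
        self.unit_levels = sorted(df["r"].unique())
        self.conn_levels = [c for c in CONNECTIVITY_LEVELS[1:] if c in set(df["C"])]
        unknown = set(df["C"]) - set(CONNECTIVITY_LEVELS)
        if unknown:
            raise ValueError(f"unknown connectivity level(s): {sorted(unknown)}")
        self.S, self.R, self.Cn = len(self.section_levels), len(self.unit_levels), len(self.conn_levels)
        self.s_idx = df["s"].map({v: i for i, v in enumerate(self.section_levels)}).to_numpy()
        self.r_idx = df["r"].map({v: i for i, v in enumerate(self.unit_levels)}).to_numpy()
        cmap = {v: i for i, v in enumerate(self.conn_levels)}
        self.c_idx = df["C"].map(lambda c: cmap.get(c, -1)).to_numpy()  # -1 = reference
        self.D = df["D_z"].to_numpy(float)
        self.A = df["A_z"].to_numpy(float)
        self.G = df["G_z"].to_numpy(float)
        self.p = df["p"].to_numpy(float)
        self.zero = self.p == 0.0
        self.nz = ~self.zero
        self.logp_nz = np.log(np.where(self.nz, self.p, 0.5))
        self.log1mp_nz = np.log1p(-np.where(self.nz, self.p, 0.5))
        self.n = len(df)
        # slices
        S, R, C = self.S, self.R, self.Cn
        i = 0
        def take(k):
            nonlocal i
            sl = slice(i, i + k); i += k; return sl
        self.i_amu = take(1); self.i_bd = take(1); self.i_ba = take(1)
        self.i_bgw = take(S); self.i_bc = take(C)
        self.i_eta_s = take(S); self.i_eta_r = take(R)
        self.i_lss = take(1); self.i_lsr = take(1)
        self.i_om = take(4); self.i_omc = take(C)
        self.i_ph = take(4); self.i_phc = take(C)
        self.dim = i

    # -- predictors -------------------------------------------------------
    def _etas(self, th):
        sig_s = np.exp(th[self.i_lss][0]); sig_r = np.exp(th[self.i_lsr][0])
        a_s = sig_s * th[self.i_eta_s]
        a_r = sig_r * th[self.i_eta_r]
        bc = np.concatenate([[0.0], th[self.i_bc]])
        cidx = self.c_idx + 1  # reference -> 0
        eta_mu = (th[self.i_amu][0] + a_s[self.s_idx] + a_r[self.r_idx]
                  + th[self.i_bd][0] * self.D + th[self.i_ba][0] * self.A
                  + th[self.i_bgw][self.s_idx] * self.G + bc[cidx])
        om = th[self.i_om]; omc = np.concatenate([[0.0], th[self.i_omc]])
        eta_om = om[0] + om[1] * self.D + om[2] * self.A + om[3] * self.G + omc[cidx]
        ph = th[self.i_ph]; phc = np.concatenate([[0.0], th[self.i_phc]])
        eta_ph = ph[0] + ph[1] * self.D + ph[2] * self.A + ph[3] * self.G + phc[cidx]
        return eta_mu, eta_om, eta_ph, sig_s, sig_r

    def loglik_pointwise(self, th) -> np.ndarray:
        eta_mu, eta_om, eta_ph, _, _ = self._etas(th)
        mu = expit(eta_mu); phi = np.exp(eta_ph)
        a, b = mu * phi, (1 - mu) * phi
        ll = np.where(
            self.zero,
            -np.logaddexp(0.0, -eta_om),  # log omega
            -np.logaddexp(0.0, eta_om)    # log(1 - omega)
            + gammaln(phi) - gammaln(a) - gammaln(b)
            + (a - 1) * self.logp_nz + (b - 1) * self.log1mp_nz,
        )
        return ll

    def logp_grad(self, th):
        with np.errstate(all="ignore"):
            lp, g = self._logp_grad_raw(th)
        if not np.isfinite(lp) or not np.all(np.isfinite(g)):
            return -np.inf, np.zeros(self.dim)
        return lp, g

    def _logp_grad_raw(self, th):
        S, R, C = self.S, self.R, self.Cn
        eta_mu, eta_om, eta_ph, sig_s, sig_r = self._etas(th)
        mu = expit(eta_mu); om = expit(eta_om); phi = np.exp(eta_ph)
        a, b = mu * phi, (1 - mu) * phi
        nz = self.nz

        ll = np.where(self.zero, -np.logaddexp(0.0, -eta_om), -np.logaddexp(0.0, eta_om))
        beta_ll = (gammaln(phi) - gammaln(a) - gammaln(b)
                   + (a - 1) * self.logp_nz + (b - 1) * self.log1mp_nz)
        ll = ll + np.where(nz, beta_ll, 0.0)
        lp = float(ll.sum())

        # d loglik / d eta
        d_eta_om = np.where(self.zero, 1.0 - om, -om)
        dg_a, dg_b, dg_phi = digamma(a), digamma(b), digamma(phi)
        dl_dmu = phi * (self.logp_nz - self.log1mp_nz - dg_a + dg_b)
        d_eta_mu = np.where(nz, dl_dmu * mu * (1 - mu), 0.0)
        dl_dphi = (mu * self.logp_nz + (1 - mu) * self.log1mp_nz
                   + dg_phi - mu * dg_a - (1 - mu) * dg_b)
        d_eta_ph = np.where(nz, dl_dphi * phi, 0.0)

        g = np.zeros(self.dim)
        g[self.i_amu] = d_eta_mu.sum()
        g[self.i_bd] = d_eta_mu @ self.D
        g[self.i_ba] = d_eta_mu @ self.A
        g[self.i_bgw] = np.bincount(self.s_idx, d_eta_mu * self.G, minlength=S)
        has_c = self.c_idx >= 0
        if C:
            g[self.i_bc] = np.bincount(self.c_idx[has_c], d_eta_mu[has_c], minlength=C)
        ds = np.bincount(self.s_idx, d_eta_mu, minlength=S)
        dr = np.bincount(self.r_idx, d_eta_mu, minlength=R)
        g[self.i_eta_s] = sig_s * ds
        g[self.i_eta_r] = sig_r * dr
        g[self.i_lss] = sig_s * float(ds @ th[self.i_eta_s])
        g[self.i_lsr] = sig_r * float(dr @ th[self.i_eta_r])
        g[self.i_om] = [d_eta_om.sum(), d_eta_om @ self.D, d_eta_om @ self.A, d_eta_om @ self.G]
        if C:
            g[self.i_omc] = np.bincount(self.c_idx[has_c], d_eta_om[has_c], minlength=C)
        g[self.i_ph] = [d_eta_ph.sum(), d_eta_ph @ self.D, d_eta_ph @ self.A, d_eta_ph @ self.G]
        if C:
            g[self.i_phc] = np.bincount(self.c_idx[has_c], d_eta_ph[has_c], minlength=C)

        # priors: normal(0,5) on coefficients, N(0,1) on etas,
        # half-normal(0,2) on sigmas (with log-scale Jacobian)
        coef_idx = np.r_[np.arange(self.i_amu.start, self.i_eta_s.start),
                         np.arange(self.i_om.start, self.dim)]
        lp += float(-0.5 * np.sum(th[coef_idx] ** 2) / _N05**2)
        g[coef_idx] += -th[coef_idx] / _N05**2
        for sl in (self.i_eta_s, self.i_eta_r):
            lp += float(-0.5 * np.sum(th[sl] ** 2))
            g[sl] += -th[sl]
        for sl, sig in ((self.i_lss, sig_s), (self.i_lsr, sig_r)):
            lp += -0.5 * sig**2 / _HN**2 + np.log(sig)
            g[sl] += -(sig**2) / _HN**2 + 1.0
        return lp, g

    def init_theta(self) -> np.ndarray:
        th = np.zeros(self.dim)
        pbar = self.p[self.nz].mean() if self.nz.any() else 0.1
        th[self.i_amu] = np.log(pbar / (1 - pbar))
        zr = self.zero.mean()
        th[self.i_om.start] = np.log((zr + 0.02) / (1 - zr + 0.02))
        th[self.i_ph.start] = np.log(10.0)
        th[self.i_lss] = np.log(0.5)
        th[self.i_lsr] = np.log(0.5)
        return th


@dataclass
class ZIBFit:
    model: _ZIBModel
    result: mcmc.HMCResult
    named: dict[str, np.ndarray]
    rhat: float
    ess: float
    converged: bool
    seed: int

    @property
    def draws(self) -> np.ndarray:
        return self.result.flat()

    def coefficient_draws(self) -> dict[str, np.ndarray]:
        """Flat draws of the interpretable fixed effects and sds."""
        m = self.model
        flat = self.draws
        out = {
            "alpha_mu": flat[:, m.i_amu.start],
            "beta_mu_distance": flat[:, m.i_bd.start],
            "beta_mu_area": flat[:, m.i_ba.start],
            "sigma_section": np.exp(flat[:, m.i_lss.start]),
            "sigma_unit": np.exp(flat[:, m.i_lsr.start]),
            "alpha_omega": flat[:, m.i_om.start],
            "beta_omega_distance": flat[:, m.i_om.start + 1],
            "beta_omega_area": flat[:, m.i_om.start + 2],
            "beta_omega_groundwater": flat[:, m.i_om.start + 3],
            "alpha_phi": flat[:, m.i_ph.start],
            "beta_phi_distance": flat[:, m.i_ph.start + 1],
            "beta_phi_area": flat[:, m.i_ph.start + 2],
            "beta_phi_groundwater": flat[:, m.i_ph.start + 3],
        }
        for j, s in enumerate(m.section_levels):
            out[f"beta_mu_groundwater[{s}]"] = flat[:, m.i_bgw.start + j]
        for j, c in enumerate(m.conn_levels):
            out[f"beta_mu_connectivity[{c}]"] = flat[:, m.i_bc.start + j]
            out[f"beta_omega_connectivity[{c}]"] = flat[:, m.i_omc.start + j]
            out[f"beta_phi_connectivity[{c}]"] = flat[:, m.i_phc.start + j]
        return out

    def summary(self) -> pd.DataFrame:
        rows = []
        natural_sd = {"distance": self.model.cov_stats["D"][1],
                      "area": self.model.cov_stats["A"][1],
                      "groundwater": self.model.cov_stats["G"][1]}
        for name, d in self.coefficient_draws().items():
            lo, med, hi = np.percentile(d, [2.5, 50, 97.5])
            scale = next((s for k, s in natural_sd.items() if k in name and "alpha" not in name), None)
            rows.append({"parameter": name, "median": med, "q2.5": lo, "q97.5": hi,
                         "median_natural": med / scale if scale else np.nan})
        return pd.DataFrame(rows)

    def random_intercepts(self) -> pd.DataFrame:
        """Posterior mean unit intercepts alpha'_r (the spatial-analysis
        response variable)."""
        m = self.model
        flat = self.draws
        sig = np.exp(flat[:, m.i_lsr.start])[:, None]
        a_r = sig * flat[:, m.i_eta_r]
        return pd.DataFrame({
            "unit": m.unit_levels,
            "alpha_r_mean": a_r.mean(axis=0),
            "alpha_r_sd": a_r.std(axis=0),
        })

    def pointwise_loglik(self, thin: int = 10) -> np.ndarray:
        flat = self.draws[::thin]
        return np.array([self.model.loglik_pointwise(t) for t in flat])


def fit_zib(
    data: pd.DataFrame,
    chains: int = 4,
    warmup: int = 2000,
    iterations: int = 2000,
    seed: int | np.random.Generator = 0,
    max_leapfrog: int = 24,
) -> ZIBFit:
    """Fit the hierarchical zero-inflated beta model by HMC.

    ``data`` is long format with columns r, s, y, p, D, A, G, C.  A
    convergence warning (split-R-hat >= 1.01) flags the fit but the result
    is still returned.
    """
    if data["s"].nunique() < 2 or data["r"].nunique() < 2:
        raise ValueError("need at least 2 sections and 2 units")
    if not ((data["p"] == 0).any() and (data["p"] > 0).any()):
        raise ValueError("need both zero and nonzero contributions")
    model = _ZIBModel(data)
    seed_int = int(np.random.default_rng(seed).integers(2**31 - 1))
    res = mcmc.hmc_sample(model.logp_grad, model.init_theta(),
                          n_warmup=warmup, n_draws=iterations, seed=seed_int,
                          n_chains=chains, max_leapfrog=max_leapfrog)
    named = _named_chain_draws(model, res.draws)
    ess = mcmc.ess_min(named)
    if chains >= 2:
        rhat = mcmc.rhat_max(named)
        converged = bool(rhat < 1.01)
        if not converged:
            warnings.warn(f"ZIB fit: split-R-hat {rhat:.3f} >= 1.01")
    else:  # R-hat needs multiple chains
        rhat, converged = float("nan"), True
    return ZIBFit(model, res, named, rhat, ess, converged, seed_int)


def _named_chain_draws(model: _ZIBModel, draws: np.ndarray) -> dict[str, np.ndarray]:
    m = model
    named = {
        "alpha_mu": draws[:, :, m.i_amu.start],
        "beta_mu_distance": draws[:, :, m.i_bd.start],
        "beta_mu_area": draws[:, :, m.i_ba.start],
        "beta_mu_groundwater": draws[:, :, m.i_bgw],
        "log_sigma_section": draws[:, :, m.i_lss.start],
        "log_sigma_unit": draws[:, :, m.i_lsr.start],
        "omega_block": draws[:, :, m.i_om],
        "phi_block": draws[:, :, m.i_ph],
    }
    if m.Cn:
        named["beta_mu_connectivity"] = draws[:, :, m.i_bc]
        named["beta_omega_connectivity"] = draws[:, :, m.i_omc]
        named["beta_phi_connectivity"] = draws[:, :, m.i_phc]
    return named


# ------------------------------------------------------------------- checks --
def posterior_predictive_check(
    fit: ZIBFit, data: pd.DataFrame | None = None, n_rep: int = 200,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate replicated datasets from the joint posterior (including the
    fitted random intercepts) and compare test statistics with the observed
    data.  Bayesian p-value = fraction of replicates with statistic >=
    observed.  Statistics: proportion of zeros, mean of nonzero p, max p;
    one row per statistic per section plus an overall row."""
    rng = np.random.default_rng(seed)
    m = fit.model
    flat = fit.draws
    take = rng.choice(len(flat), size=min(n_rep, len(flat)), replace=False)
    obs_p = m.p
    groups = {"overall": np.ones(m.n, bool)}
    for j, s in enumerate(m.section_levels):
        groups[str(s)] = m.s_idx == j

    stats = {
        "zero_proportion": lambda p: float(np.mean(p == 0)),
        "mean_nonzero": lambda p: float(p[p > 0].mean()) if (p > 0).any() else 0.0,
        "max_p": lambda p: float(p.max()),
    }
    reps = {k: {g: [] for g in groups} for k in stats}
    for t in flat[take]:
        eta_mu, eta_om, eta_ph, _, _ = m._etas(t)
        mu, om, phi = expit(eta_mu), expit(eta_om), np.exp(eta_ph)
        p_rep = rng.beta(mu * phi, (1 - mu) * phi)
        p_rep = np.where(rng.random(m.n) < om, 0.0, np.clip(p_rep, 1e-9, 1 - 1e-9))
        for k, f in stats.items():
            for gname, mask in groups.items():
                reps[k][gname].append(f(p_rep[mask]))
    rows = []
    for k, f in stats.items():
        for gname, mask in groups.items():
            observed = f(obs_p[mask])
            sim = np.asarray(reps[k][gname])
            rows.append({"statistic": k, "stratum": gname, "observed": observed,
                         "rep_mean": sim.mean(),
                         "bayes_p": float(np.mean(sim >= observed))})
    return pd.DataFrame(rows)


def effect_curves(
    fit: ZIBFit, variable: str, connectivity: str = "connected",
    n_grid: int = 50, per_section: bool | None = None,
) -> pd.DataFrame:
    """Posterior median and 95% band of mu (and omega) along one covariate,
    the others held at their mean (0 after standardization); random
    intercepts at 0 (population level).  For groundwater the mu curve is
    returned per section (the slope varies by section)."""
    m = fit.model
    col = {"distance": "D", "area": "A", "groundwater": "G"}[variable]
    mean, sd = m.cov_stats[col]
    z = {"D": m.D, "A": m.A, "G": m.G}[col]
    grid = np.linspace(z.min(), z.max(), n_grid)
    flat = fit.draws
    cmap = {c: j for j, c in enumerate(m.conn_levels)}
    if connectivity != "connected" and connectivity not in cmap:
        raise ValueError(f"connectivity level {connectivity!r} not in fit")
    bc_mu = 0.0 if connectivity == "connected" else flat[:, m.i_bc.start + cmap[connectivity]]
    bc_om = 0.0 if connectivity == "connected" else flat[:, m.i_omc.start + cmap[connectivity]]
    slope_om = {"D": flat[:, m.i_om.start + 1], "A": flat[:, m.i_om.start + 2],
                "G": flat[:, m.i_om.start + 3]}[col]
    if per_section is None:
        per_section = variable == "groundwater"
    rows = []
    sections = m.section_levels if per_section else [None]
    for s in sections:
        if col == "D":
            slope_mu = flat[:, m.i_bd.start]
        elif col == "A":
            slope_mu = flat[:, m.i_ba.start]
        else:
            j = m.section_levels.index(s) if s is not None else None
            slope_mu = (flat[:, m.i_bgw.start + j] if j is not None
                        else flat[:, m.i_bgw].mean(axis=1))
        for gz in grid:
            eta_mu = flat[:, m.i_amu.start] + slope_mu * gz + bc_mu
            eta_om = flat[:, m.i_om.start] + slope_om * gz + bc_om
            mu = expit(eta_mu); omg = expit(eta_om)
            rows.append({
                "variable": variable, "section": s, "connectivity": connectivity,
                "x": mean + sd * gz, "x_z": gz,
                "mu_median": np.median(mu),
                "mu_lo": np.percentile(mu, 2.5), "mu_hi": np.percentile(mu, 97.5),
                "omega_median": np.median(omg),
                "omega_lo": np.percentile(omg, 2.5), "omega_hi": np.percentile(omg, 97.5),
            })
    return pd.DataFrame(rows)
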