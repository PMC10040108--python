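"""Maximum-likelihood estimation of mixture cure models.

`MixtureCureModel` is built from either individual records (a
:class:`~curecorrect.cohort.Cohort`) or a grouped
:class:`~curecorrect.lifetable.LifeTable`, together with a
population-mortality source, and fitted by quasi-Newton maximisation of
the appropriate log-likelihood.

Individual data: each record contributes

    d_i * ln( h_c(t_i, x_i) + alpha * h*(age_i + t_i) )
        + ln RS(t_i, x_i) + alpha * ln S*(t_i | age_i),

the standard form ``d ln h_O + ln S_O`` of the observed-hazard
likelihood.  With ``alpha = 1`` (conventional variant) the expected
survival term is a constant; a flag controls whether it is kept so that
likelihood values remain comparable across variants.

Grouped data: each life-table cell (stratum k, interval j) contributes a
binomial term ``d ln(1 - p) + (l - d) ln p`` where the predicted
conditional interval observed survival is, under the default "exact"
dialect,

    p_jk = [RS(t_j; x_k) / RS(t_{j-1}; x_k)] * s_exp_jk ** alpha,

with s_exp the Ederer II expected interval survival.  The
"printed_first_order" dialect uses the additive first-order form
``r_jk + alpha * ln s_exp_jk`` instead.

Optimisation runs on a working scale — ``ln alpha``, ``ln lambda``,
``ln gamma`` unconstrained, the link-scale parameters untransformed —
with standard errors from the inverse numerical Hessian and 95% Wald
intervals back-transformed to the natural scale (the cure fraction
``pi_60`` and its interval by inverse-logit of the intercept interval).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess

from .cohort import Cohort
from .lifetable import LifeTable, build_life_table, relative_survival_table
from .model import cure_fraction, net_survival, uncured_survival
from .params import CureParams

__all__ = ["MixtureCureModel", "MixtureCureResults", "fit", "initial_values"]

_Z95 = stats.norm.ppf(0.975)
_T_FLOOR = 0.5 / 365.25  # events at t = 0 are shifted to half a day
_PENALTY = 1e6


def _working_names(variant, link):
    names = []
    if variant != "corrected_no_cure":
        names += ["beta0", "beta"]
    names += ["log_lambda", "log_gamma", "delta"]
    if variant != "conventional":
        names += ["log_alpha"]
    return names


class MixtureCureModel:
    """(Corrected) mixture cure model for net-survival estimation.

    Parameters
    ----------
    data : Cohort or LifeTable
        Individual records, or a grouped life table with Ederer II
        expected interval survival filled in.
    pop : PopulationMortality
        Expected-mortality source (required for individual data; used
        with grouped data only to fill a missing ``s_exp``).
    variant : {"corrected", "conventional", "corrected_no_cure"}
        ``corrected`` estimates the excess non-cancer mortality factor
        alpha; ``conventional`` fixes alpha = 1; ``corrected_no_cure``
        keeps alpha free but drops the cured component (pi = 0).
    link : {"logistic", "identity"}
        Link for the cure fraction.
    dialect : {"exact", "printed_first_order"}
        Grouped-likelihood form (see module docstring).
    keep_constant_terms : bool
        Keep the expected-survival term in the conventional individual
        likelihood (a constant) so values are comparable with the
        corrected variant.
    """

    def __init__(self, data, pop=None, variant="corrected", link="logistic",
                 dialect="exact", keep_constant_terms=True):
        if variant not in ("corrected", "conventional", "corrected_no_cure"):
            raise ValueError(f"unknown variant {variant!r}")
        if link not in ("logistic", "identity"):
            raise ValueError(f"unknown link {link!r}")
        if dialect not in ("exact", "printed_first_order"):
            raise ValueError(f"unknown dialect {dialect!r}")
        self.variant = variant
        self.link = link
        self.dialect = dialect
        self.keep_constant_terms = keep_constant_terms
        self.pop = pop
        self.param_names = _working_names(variant, link)
        self.k_params = len(self.param_names)

        if isinstance(data, LifeTable):
            self.grouped = True
            self.life_table = data
            self._setup_grouped(data)
        else:
            if not isinstance(data, Cohort):
                data = Cohort(data)
            if pop is None:
                raise ValueError("individual-data fits require pop")
            self.grouped = False
            self.cohort = data
            self._setup_individual(data, pop)

    # ------------------------------------------------------------------
    def _setup_individual(self, cohort, pop):
        t = cohort.time.copy()
        d = cohort.event
        t[(d == 1) & (t <= 0)] = _T_FLOOR
        self._t = t
        self._d = d.astype(bool)
        self._x = cohort.x
        self._ln_sstar = np.log(pop.survival(cohort.age, t))
        self._hstar = pop.hazard(cohort.age, t)
        self.nobs = len(cohort)

    def _setup_grouped(self, lt):
        df = lt.data
        if df["s_exp"].isna().any():
            raise ValueError(
                "life table lacks s_exp; compute it via ederer2_expected "
                "(pass pop when building the table)")
        self._g_d = df["d"].to_numpy(float)
        self._g_l = df["l"].to_numpy(float)
        self._g_x = df["x"].to_numpy(float)
        self._g_t0 = df["t_start"].to_numpy(float)
        self._g_t1 = df["t_end"].to_numpy(float)
        self._g_sexp = df["s_exp"].to_numpy(float)
        self._g_ln_sexp = np.log(self._g_sexp)
        self.nobs = len(df)

    # ------------------------------------------------------------------
    # parameter bookkeeping
    # ------------------------------------------------------------------
    def _unpack(self, w):
        """Working vector -> (pi-part, lambda, gamma, delta, alpha)."""
        i = 0
        if self.variant != "corrected_no_cure":
            beta0, beta = w[0], w[1]
            i = 2
        else:
            beta0 = beta = 0.0
        lam, gam, delta = np.exp(w[i]), np.exp(w[i + 1]), w[i + 2]
        alpha = 1.0 if self.variant == "conventional" else np.exp(w[i + 3])
        return beta0, beta, lam, gam, delta, alpha

    def working_from_params(self, params: CureParams):
        w = []
        if self.variant != "corrected_no_cure":
            w += [params.beta0, params.beta]
        w += [np.log(params.lambda_), np.log(params.gamma_), params.delta]
        if self.variant != "conventional":
            w += [np.log(params.alpha)]
        return np.asarray(w, dtype=float)

    def params_from_working(self, w):
        beta0, beta, lam, gam, delta, alpha = self._unpack(w)
        return CureParams(alpha=float(alpha), beta0=float(beta0),
                          beta=float(beta), lambda_=float(lam),
                          gamma_=float(gam), delta=float(delta),
                          link=self.link, variant=self.variant)

    def _pi(self, beta0, beta, x):
        if self.variant == "corrected_no_cure":
            return np.zeros_like(x)
        eta = beta0 + beta * x
        if self.link == "logistic":
            return special.expit(eta)
        return eta  # identity link; validity handled by the caller

    # ------------------------------------------------------------------
    # log-likelihoods
    # ------------------------------------------------------------------
    def loglike(self, w):
        """Log-likelihood at a working-scale parameter vector."""
        if self.grouped:
            return self._loglike_grouped(w)
        return self._loglike_individual(w)

    def _identity_penalty(self, pi):
        lo = np.minimum(pi, 0.0)
        hi = np.maximum(pi - 1.0, 0.0)
        return _PENALTY * float(np.sum(lo ** 2 + hi ** 2) + np.sum((lo != 0) | (hi != 0)))

    def _loglike_individual(self, w):
        beta0, beta, lam, gam, delta, alpha = self._unpack(w)
        x, t, d = self._x, self._t, self._d
        pi = self._pi(beta0, beta, x)
        penalty = 0.0
        if self.link == "identity" and self.variant != "corrected_no_cure":
            penalty = self._identity_penalty(pi)
            pi = np.clip(pi, 0.0, 1.0)
        age_mult = np.exp(-delta * x)
        su = np.exp(-lam * t ** gam * age_mult)
        rs = pi + (1.0 - pi) * su
        hu = gam * lam * t[d] ** (gam - 1.0) * age_mult[d]
        hc = (1.0 - pi[d]) * su[d] * hu / rs[d]
        h_obs = hc + alpha * self._hstar[d]
        if np.any(h_obs <= 0) or np.any(rs <= 0):
            return -np.inf
        ll = float(np.sum(np.log(h_obs)) + np.sum(np.log(rs)))
        if self.variant != "conventional" or self.keep_constant_terms:
            ll += float(alpha * np.sum(self._ln_sstar))
        if not np.isfinite(ll):
            bad = np.flatnonzero(~np.isfinite(np.log(rs)))
            raise FloatingPointError(
                f"non-finite individual likelihood (first record {bad[:1]})")
        return ll - penalty

    def _loglike_grouped(self, w):
        beta0, beta, lam, gam, delta, alpha = self._unpack(w)
        x = self._g_x
        pi = self._pi(beta0, beta, x)
        penalty = 0.0
        if self.link == "identity" and self.variant != "corrected_no_cure":
            penalty = self._identity_penalty(pi)
            pi = np.clip(pi, 0.0, 1.0)
        age_mult = np.exp(-delta * x)
        rs1 = pi + (1.0 - pi) * np.exp(-lam * self._g_t1 ** gam * age_mult)
        rs0 = pi + (1.0 - pi) * np.exp(-lam * self._g_t0 ** gam * age_mult)
        r = rs1 / rs0
        if self.dialect == "exact":
            p = r * self._g_sexp ** alpha
        else:
            p = r + alpha * self._g_ln_sexp
        # optimizer-safe: cells pushed outside (0, 1) contribute a smooth
        # penalty instead of NaN
        bad_lo = np.minimum(p - 1e-12, 0.0)
        bad_hi = np.maximum(p - (1.0 - 1e-12), 0.0)
        penalty += _PENALTY * float(np.sum(bad_lo ** 2 + bad_hi ** 2)
                                    + np.sum((bad_lo != 0) | (bad_hi != 0)))
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        ll = float(np.sum(self._g_d * np.log1p(-p)
                          + (self._g_l - self._g_d) * np.log(p)))
        return ll - penalty

    # ------------------------------------------------------------------
    def fit(self, start_params=None, maxiter=500, gtol=1e-6, restarts=3):
        """Maximise the log-likelihood.

        Up to ``restarts`` jittered restarts (deterministically seeded
        from the data) are attempted on non-convergence; a fit that
        still fails is returned with ``converged = False`` rather than
        raising.
        """
        if start_params is None:
            start = self.working_from_params(self._initial_params())
        elif isinstance(start_params, CureParams):
            start = self.working_from_params(start_params)
        else:
            start = np.asarray(start_params, dtype=float)

        def nll(w):
            return -self.loglike(w)

        seed = self._data_seed()
        best = None
        w0 = start
        for attempt in range(restarts + 1):
            res = optimize.minimize(nll, w0, method="BFGS",
                                    options={"maxiter": maxiter, "gtol": gtol})
            grad_ok = np.all(np.abs(res.jac) < 1e-3 * max(1.0, abs(res.fun)))
            converged = bool(res.success or grad_ok)
            if best is None or res.fun < best[0].fun:
                best = (res, converged)
            if converged:
                best = (res, True)
                break
            rng = np.random.default_rng((seed + 7919 * (attempt + 1)) % 2**31)
            w0 = start + rng.normal(0.0, 0.2, size=start.size)
        res, converged = best

        hess = approx_hess(res.x, nll)
        vcov = self._safe_inverse(hess)
        return MixtureCureResults(self, res.x, float(-res.fun), vcov,
                                  converged, diagnostics={
                                      "nit": int(res.nit),
                                      "message": str(res.message),
                                      "grad_norm": float(np.max(np.abs(res.jac))),
                                  })

    @staticmethod
    def _safe_inverse(hess):
        try:
            vcov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(hess)
        diag = np.diag(vcov)
        if np.any(diag < 0):
            vcov = np.linalg.pinv(hess)
        return vcov

    def _data_seed(self):
        if self.grouped:
            basis = float(np.sum(self._g_d) + np.sum(self._g_l))
        else:
            basis = float(np.sum(self._t) + np.sum(self._d))
        return int(abs(basis) * 1000) % 2**31

    def _initial_params(self):
        if self.grouped:
            return initial_values(self.life_table, variant=self.variant,
                                  link=self.link)
        lt = build_life_table(self.cohort, max_followup=np.ceil(
            max(self.cohort.time.max(), 1.0)), pop=self.pop,
            age_breaks=self._cohort_breaks())
        return initial_values(lt, variant=self.variant, link=self.link)

    def _cohort_breaks(self):
        lo = np.floor(self.cohort.age.min())
        hi = np.ceil(self.cohort.age.max()) + 1.0
        return (lo, hi)


def initial_values(life_table, variant="corrected", link="logistic"):
    """Deterministic starting values from a grouped life table.

    alpha starts at 1; the cure fraction at the empirical
    relative-survival plateau (size-weighted last-interval cumulative
    relative survival, clamped to [0.05, 0.95]); the Weibull rate and
    shape from a least-squares line on the complementary-log-log of the
    early relative survival; the two age trends at 0.
    """
    lt = life_table if isinstance(life_table, LifeTable) else LifeTable(life_table)
    if lt.data["d"].sum() == 0:
        raise ValueError("cannot initialise from data with no deaths")
    rs = relative_survival_table(lt)
    rs = rs.merge(lt.data[["stratum", "t_start", "t_end", "n"]],
                  on=["stratum", "t_start", "t_end"])
    last = rs.sort_values("t_end").groupby("stratum", sort=False).tail(1)
    plateau = float(np.average(last["rs"], weights=last["n"]))
    pi0 = float(np.clip(plateau, 0.05, 0.95))

    # pooled cumulative RS by interval end, weighted by numbers at risk
    pooled = rs.groupby("t_end").apply(
        lambda g: np.average(g["rs"], weights=g["n"]),
        include_groups=False)
    t = pooled.index.to_numpy(float)
    su = (pooled.to_numpy(float) - pi0) / max(1.0 - pi0, 1e-6)
    mask = (su > 0.02) & (su < 0.98) & (t > 0)
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(np.log(t[mask]),
                                      np.log(-np.log(su[mask])), 1)
        gamma0 = float(np.clip(slope, 0.2, 5.0))
        lambda0 = float(np.clip(np.exp(intercept), 1e-3, 10.0))
    else:
        gamma0, lambda0 = 1.0, 0.3
    if link == "identity":
        beta0 = pi0
    else:
        beta0 = float(special.logit(pi0))
    alpha0 = 1.0
    if variant == "conventional":
        alpha0 = 1.0
    return CureParams(alpha=alpha0, beta0=beta0, beta=0.0, lambda_=lambda0,
                      gamma_=gamma0, delta=0.0, link=link,
                      variant=variant if variant != "conventional" else "conventional")


class MixtureCureResults:
    """Fit results: estimates, uncertainties and diagnostics.

    Natural-scale estimates are exposed through :attr:`params` (a
    :class:`CureParams`), :meth:`conf_int` and :meth:`summary`; the
    derived cure fraction ``pi_60`` and its interval are obtained by
    inverse-logit of the intercept interval under the logistic link.
    """

    def __init__(self, model, working, llf, vcov, converged, diagnostics):
        self.model = model
        self.working = np.asarray(working, dtype=float)
        self.llf = llf
        self.vcov = np.asarray(vcov, dtype=float)
        self.converged = converged
        self.diagnostics = diagnostics
        self.params = model.params_from_working(self.working)
        self.nobs = model.nobs
        with np.errstate(invalid="ignore"):
            self.bse_working = np.sqrt(np.diag(self.vcov))

    # ------------------------------------------------------------------
    @property
    def param_names(self):
        return self.model.param_names

    def _working_table(self):
        return pd.DataFrame({
            "estimate": self.working,
            "se": self.bse_working,
        }, index=self.param_names)

    def conf_int(self, alpha_level=0.05):
        """Natural-scale estimates, SEs and Wald intervals.

        Rows: the model's reported parameters (``alpha``, ``pi_60``,
        ``lambda``, ``gamma``, ``beta``, ``delta`` as applicable).
        Positive parameters use Wald intervals on the log scale,
        back-transformed; ``pi_60`` uses the inverse-logit of the
        intercept interval.  SEs are delta-method on the natural scale.
        """
        z = stats.norm.ppf(1.0 - alpha_level / 2.0)
        wt = self._working_table()
        rows = {}

        def log_scale(name, label):
            est_w, se_w = wt.loc[name, "estimate"], wt.loc[name, "se"]
            est = np.exp(est_w)
            rows[label] = (est, est * se_w,
                           np.exp(est_w - z * se_w), np.exp(est_w + z * se_w))

        def plain(name, label):
            est, se = wt.loc[name, "estimate"], wt.loc[name, "se"]
            rows[label] = (est, se, est - z * se, est + z * se)

        if self.model.variant != "conventional":
            log_scale("log_alpha", "alpha")
        if self.model.variant != "corrected_no_cure":
            b0, se0 = wt.loc["beta0", "estimate"], wt.loc["beta0", "se"]
            if self.model.link == "logistic":
                pi = special.expit(b0)
                rows["pi_60"] = (pi, pi * (1 - pi) * se0,
                                 special.expit(b0 - z * se0),
                                 special.expit(b0 + z * se0))
            else:
                rows["pi_60"] = (b0, se0, b0 - z * se0, b0 + z * se0)
            plain("beta", "beta")
        log_scale("log_lambda", "lambda")
        log_scale("log_gamma", "gamma")
        plain("delta", "delta")
        out = pd.DataFrame(rows, index=["estimate", "se", "lower", "upper"]).T
        order = [n for n in ("alpha", "pi_60", "lambda", "gamma", "beta",
                             "delta") if n in out.index]
        return out.loc[order]

    def summary(self):
        """Human-readable fit summary."""
        ci = self.conf_int()
        lines = [
            "Mixture cure model" + (" (corrected)" if
                                    self.model.variant != "conventional"
                                    else " (conventional)"),
            f"  variant: {self.model.variant}   link: {self.model.link}   "
            f"data: {'grouped' if self.model.grouped else 'individual'}",
            f"  n {'cells' if self.model.grouped else 'records'}: "
            f"{self.nobs}   log-likelihood: {self.llf:.4f}   "
            f"converged: {self.converged}",
            "",
            f"  {'param':<8}{'estimate':>10}{'se':>10}{'95% CI':>22}",
        ]
        for name, row in ci.iterrows():
            lines.append(f"  {name:<8}{row['estimate']:>10.4f}"
                         f"{row['se']:>10.4f}"
                         f"   [{row['lower']:.4f}, {row['upper']:.4f}]")
        return "\n".join(lines)

    def predict_summary(self, ages=(40, 50, 60, 70), horizons=(1, 5, 10, 15)):
        from .model import predict_summary
        return predict_summary(self.params, ages=ages, horizons=horizons)

    def to_dict(self):
        ci = self.conf_int()
        return {
            "variant": self.model.variant,
            "link": self.model.link,
            "grouped": self.model.grouped,
            "converged": self.converged,
            "loglik": self.llf,
            "n_used": int(self.nobs),
            "params": self.params.to_dict(),
            "table": {name: {k: float(v) for k, v in row.items()}
                      for name, row in ci.iterrows()},
            "diagnostics": self.diagnostics,
        }


def fit(data, pop=None, variant="corrected", link="logistic", dialect="exact",
        init=None, **options):
    """One-call fit: build a :class:`MixtureCureModel` and maximise it."""
    model = MixtureCureModel(data, pop=pop, variant=variant, link=link,
                             dialect=dialect)
    return model.fit(start_params=init, **options)
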