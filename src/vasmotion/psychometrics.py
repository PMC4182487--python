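"""Psychometric-function fitting and within-subject inference.

The 2AFC judgment ("which modality leads?") as a function of the signed
audio-visual spatial offset mu (degrees, positive = auditory lag) is
modelled as a cumulative Gaussian with a symmetric lapse rate:

    psi(mu) = lambda + (1 - 2 lambda) Phi((mu - PSE) / beta)

PSE is the offset at the inflection (the point of subjective equality) and
beta is the spread (standard deviation) of the underlying Gaussian --
larger beta means a shallower function and greater judgment uncertainty.
The lapse rate is capped at 0.06.  beta is reported in degrees; its square
is exported alongside for readers who prefer the variance parameterisation.

Fitting is constrained maximum likelihood over binomial per-offset counts
with multiple deterministic restarts; confidence limits come from a
parametric bootstrap (refitting data resampled from the fitted psi); group
comparisons use a two-way repeated-measures ANOVA in which every effect is
tested against its own subject-by-factor interaction error term (no
sphericity correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, ndtr, ndtri

__all__ = [
    "LAPSE_MAX",
    "PsychometricFit",
    "psychometric_function",
    "neg_log_lik",
    "fit_pf",
    "bootstrap_ci",
    "rm_anova",
    "summarize_group",
]

LAPSE_MAX = 0.06
_PCLIP = 1e-12


def psychometric_function(mu, pse: float, beta: float, lapse: float):
    """psi(mu) = lambda + (1 - 2 lambda) Phi((mu - pse) / beta)."""
    return lapse + (1.0 - 2.0 * lapse) * ndtr((np.asarray(mu, float) - pse) / beta)


@dataclass
class PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit of one 90-trial block."""

    pse: float
    beta: float
    lapse: float
    neg_log_likelihood: float
    ci95_pse: tuple[float, float] | None = None
    ci95_beta: tuple[float, float] | None = None
    n_bootstrap: int = 0
    converged: bool = True
    flagged: bool = False

    @property
    def beta_sq(self) -> float:
        """Variance parameterisation of the spread."""
        return self.beta**2


def _as_counts(data) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coerce per-offset response counts to (mu, n, k) arrays.

    Accepts a DataFrame with columns (offset_deg, n_trials,
    n_vision_leads) or a triple of array-likes.
    """
    if isinstance(data, pd.DataFrame):
        mu = data["offset_deg"].to_numpy(float)
        n = data["n_trials"].to_numpy(float)
        k = data["n_vision_leads"].to_numpy(float)
    else:
        mu, n, k = (np.asarray(a, float) for a in data)
    if not (mu.shape == n.shape == k.shape):
        raise ValueError("offsets, totals and counts must align")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("counts must satisfy 0 <= k <= n")
    return mu, n, k


def neg_log_lik(params, data) -> float:
    """Negative binomial log likelihood of (pse, beta, lapse) in nats."""
    pse, beta, lapse = params
    if beta <= 0 or not 0.0 <= lapse <= LAPSE_MAX:
        raise ValueError("invalid parameters: need beta > 0, 0 <= lapse <= 0.06")
    mu, n, k = _as_counts(data)
    psi = np.clip(psychometric_function(mu, pse, beta, lapse), _PCLIP, 1 - _PCLIP)
    coef = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float(-np.sum(coef + k * np.log(psi) + (n - k) * np.log1p(-psi)))


def _nll_and_grad(params, mu, n, k, coef_sum):
    """Objective and analytic gradient for the bounded optimizer."""
    pse, beta, lapse = params
    z = (mu - pse) / beta
    cdf = ndtr(z)
    psi = np.clip(lapse + (1.0 - 2.0 * lapse) * cdf, _PCLIP, 1 - _PCLIP)
    nll = -(coef_sum + np.sum(k * np.log(psi) + (n - k) * np.log1p(-psi)))
    dldpsi = -(k / psi - (n - k) / (1.0 - psi))
    pdf = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
    scale = (1.0 - 2.0 * lapse) * pdf / beta
    g_pse = np.sum(dldpsi * -scale)
    g_beta = np.sum(dldpsi * -scale * z)
    g_lapse = np.sum(dldpsi * (1.0 - 2.0 * cdf))
    return float(nll), np.array([g_pse, g_beta, g_lapse])


def _moment_init(mu, n, k) -> tuple[float, float]:
    """Probit-regression starting values for (pse, beta)."""
    p = np.clip(k / np.maximum(n, 1.0), 0.02, 0.98)
    z = ndtri(p)
    try:
        slope, icpt = np.polyfit(mu, z, 1, w=np.sqrt(np.maximum(n, 1.0)))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate design
        slope, icpt = 0.0, 0.0
    span = max(mu.max() - mu.min(), 1.0)
    if slope <= 1e-6:
        return float(np.mean(mu)), span / 3.0
    beta0 = float(np.clip(1.0 / slope, 1e-2, 5.0 * span))
    return float(np.clip(-icpt * beta0, mu.min(), mu.max())), beta0


def fit_pf(data, beta_min: float = 1e-2, starts=None) -> PsychometricFit:
    """Constrained MLE of (PSE, beta, lapse) from per-offset counts.

    Requires at least three distinct offsets and at least one response in
    each category overall.  Five deterministic restarts around a
    moment-based initialiser (override with ``starts``); ties break toward
    the smaller lapse.  Perfectly separated data drive beta to the
    optimizer's lower bound and are returned flagged rather than rejected.
    """
    mu, n, k = _as_counts(data)
    if np.unique(mu).size < 3:
        raise ValueError("need at least 3 distinct offsets to fit")
    if k.sum() == 0 or k.sum() == n.sum():
        raise ValueError("need at least one response in each category overall")

    span = max(mu.max() - mu.min(), 1.0)
    bounds = [
        (mu.min() - span, mu.max() + span),
        (beta_min, 5.0 * span),
        (0.0, LAPSE_MAX),
    ]
    if starts is None:
        pse0, beta0 = _moment_init(mu, n, k)
        starts = [
            (pse0, beta0, 0.02),
            (pse0, min(2.0 * beta0, 5.0 * span), 0.0),
            (pse0, max(0.5 * beta0, beta_min), 0.04),
            (float(np.mean(mu)), span / 3.0, 0.01),
            (pse0 + 0.25 * span, beta0, 0.02),
        ]

    coef_sum = float(np.sum(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)))
    best = None
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            _nll_and_grad, x0, args=(mu, n, k, coef_sum),
            method="L-BFGS-B", jac=True, bounds=bounds,
        )
        key = (round(res.fun, 9), res.x[2])
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    pse, beta, lapse = res.x
    separated = bool(np.all((k == 0) | (k == n)))
    flagged = separated or bool(beta <= beta_min * 1.5) or not res.success
    return PsychometricFit(
        pse=float(pse),
        beta=float(beta),
        lapse=float(lapse),
        neg_log_likelihood=float(res.fun),
        converged=bool(res.success),
        flagged=flagged,
    )


def bootstrap_ci(
    fit: PsychometricFit, data, n_boot: int = 1000, seed: int = 0
) -> PsychometricFit:
    """Parametric-bootstrap 95% confidence limits for PSE and beta.

    Draws ``n_boot`` synthetic datasets from the fitted psi at the observed
    offsets and trial counts, refits each, and takes percentile 2.5/97.5
    intervals.  A refit failure rate above 5% attaches a warning.  With
    ``n_boot=0`` the fit is returned unchanged.
    """
    if n_boot == 0:
        return fit
    mu, n, k = _as_counts(data)
    rng = np.random.default_rng(seed)
    psi = psychometric_function(mu, fit.pse, fit.beta, fit.lapse)
    parent = (fit.pse, fit.beta, fit.lapse)
    pses, betas, failures = [], [], 0
    for _ in range(n_boot):
        kb = rng.binomial(n.astype(int), psi)
        if kb.sum() == 0 or kb.sum() == n.sum():
            failures += 1
            continue
        refit = fit_pf((mu, n, kb), starts=[parent, _moment_init(mu, n, kb) + (0.02,)])
        if not refit.converged:
            failures += 1
            continue
        pses.append(refit.pse)
        betas.append(refit.beta)
    if failures > 0.05 * n_boot:
        warnings.warn(
            f"bootstrap refit failure rate {failures / n_boot:.1%} exceeds 5%",
            stacklevel=2,
        )
    if not pses:
        return replace(fit, n_bootstrap=n_boot, flagged=True)
    lo_p, hi_p = np.percentile(pses, [2.5, 97.5])
    lo_b, hi_b = np.percentile(betas, [2.5, 97.5])
    return replace(
        fit,
        ci95_pse=(min(lo_p, fit.pse), max(hi_p, fit.pse)),
        ci95_beta=(min(lo_b, fit.beta), max(hi_b, fit.beta)),
        n_bootstrap=n_boot,
    )


def _as_cube(table, factor_a: str, factor_b: str, value: str, subject: str):
    """Coerce a subjects x A x B design to a 3-D array plus level labels."""
    if isinstance(table, pd.DataFrame):
        wide = table.pivot_table(index=subject, columns=[factor_a, factor_b],
                                 values=value, sort=True)
        if wide.isna().any().any():
            raise ValueError("design has missing cells")
        a_levels = wide.columns.get_level_values(0).unique()
        b_levels = wide.columns.get_level_values(1).unique()
        cube = wide.to_numpy().reshape(wide.shape[0], a_levels.size, b_levels.size)
        return cube, list(a_levels), list(b_levels)
    cube = np.asarray(table, float)
    if cube.ndim != 3:
        raise ValueError("expected a subjects x A x B array")
    return cube, list(range(cube.shape[1])), list(range(cube.shape[2]))


def rm_anova(
    table,
    factor_a: str = "condition",
    factor_b: str = "velocity",
    value: str = "value",
    subject: str = "subject",
) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA (both factors within subject).

    ``table`` is either a complete balanced long DataFrame or a 3-D array
    (subjects x A-levels x B-levels, one measure per cell).  Each effect's
    F statistic uses its own subject-interaction mean square as the error
    term; cells with zero effect variance report F = 0, p = 1.  Returns a
    DataFrame with rows for A, B and A x B.
    """
    cube, a_levels, b_levels = _as_cube(table, factor_a, factor_b, value, subject)
    ns, na, nb = cube.shape
    if ns < 2:
        raise ValueError("need at least 2 subjects")
    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)
    m_ab = cube.mean(axis=0)

    ss_a = ns * nb * np.sum((m_a - grand) ** 2)
    ss_b = ns * na * np.sum((m_b - grand) ** 2)
    ss_ab = ns * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = nb * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = na * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        cube
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_sab = np.sum(resid**2)

    total_ss = np.sum((cube - grand) ** 2)
    tiny = 1e-12 * max(total_ss, 1.0)

    rows = []
    for name, ss_eff, df_eff, ss_err, df_err in [
        (factor_a, ss_a, na - 1, ss_sa, (na - 1) * (ns - 1)),
        (factor_b, ss_b, nb - 1, ss_sb, (nb - 1) * (ns - 1)),
        (f"{factor_a}:{factor_b}", ss_ab, (na - 1) * (nb - 1), ss_sab,
         (na - 1) * (nb - 1) * (ns - 1)),
    ]:
        if ss_eff <= tiny:
            f_val, p = 0.0, 1.0
        elif ss_err <= tiny:
            f_val, p = np.inf, 0.0
        else:
            f_val = (ss_eff / df_eff) / (ss_err / df_err)
            p = float(stats.f.sf(f_val, df_eff, df_err))
        rows.append(
            dict(effect=name, F=f_val, p=p, df_num=df_eff, df_den=df_err,
                 ss_effect=ss_eff, ss_error=ss_err)
        )
    return pd.DataFrame(rows)


def summarize_group(fits: pd.DataFrame, measures=("pse", "beta")) -> pd.DataFrame:
    """Group means and between-participants standard errors per cell.

    ``fits`` needs columns subject, condition, velocity and the requested
    measures; SE is sd(ddof=1)/sqrt(n) across subjects.
    """
    out = []
    for (cond, vel), cell in fits.groupby(["condition", "velocity"]):
        if len(cell) < 2:
            raise ValueError("need at least 2 subjects per cell")
        row = dict(condition=cond, velocity=vel, n_subjects=len(cell))
        for m in measures:
            vals = cell[m].to_numpy(float)
            row[f"{m}_mean"] = vals.mean()
            row[f"{m}_se"] = vals.std(ddof=1) / np.sqrt(len(vals))
        out.append(row)
    return pd.DataFrame(out)
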