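"""Empirical-Bayes moderated t-statistics and q-values for two-group designs.

Per gene g with pooled residual variance :math:`s_g^2` on :math:`d_g`
degrees of freedom, the prior :math:`(d_0, s_0^2)` is fitted by matching
the moments of :math:`\\log s_g^2` to a scaled-F model, the posterior
variance is the precision-weighted blend

.. math:: \\tilde s_g^2 = \\frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g},

and the moderated statistic is
:math:`t_g = \\mathrm{logFC}_g / (\\tilde s_g \\sqrt{1/n_1 + 1/n_2})` with a
t reference distribution on :math:`d_0 + d_g` degrees of freedom
(:math:`d_0` may be infinite, in which case the reference is normal).
Only the two-group contrast is supported; logFC is case minus control.

FDR control uses q-values: :math:`\\pi_0` is estimated from the flat tail
of the p-value histogram over a :math:`\\lambda` grid and
:math:`q_i = \\min_{j: p_j \\ge p_i} \\pi_0 m p_j / \\mathrm{rank}(p_j)`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix

__all__ = [
    "moderated_t_test",
    "estimate_qvalues",
    "fit_variance_prior",
    "trigamma_inverse",
    "write_de_table",
]


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma_inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of the prior df d0 and prior variance s0^2.

    Matches mean and variance of log(s2) to the log of a scaled F
    distribution with (df, d0) degrees of freedom.  Genes with zero sample
    variance are excluded from the fit.  Returns ``(d0, s0_2)``; ``d0`` is
    ``inf`` when the observed spread of log-variances is no larger than
    expected under a single common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise ValueError("all gene variances are zero; cannot fit a variance prior")
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) if e.size > 1 else 0.0
    evar = evar - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        # spread of log-variances no larger than chi-square sampling noise:
        # infinite prior df, common variance = mean observed variance
        d0 = np.inf
        s0_2 = float(np.asarray(s2, dtype=float).mean())
    if not np.isfinite(s0_2) or s0_2 <= 0:
        warnings.warn("degenerate variance-prior fit; falling back to full shrinkage")
        d0, s0_2 = np.inf, float(pos.mean())
    return float(d0), float(s0_2)


def moderated_t_test(
    expr: ExpressionMatrix,
    prior_df: float | None = None,
    prior_var: float | None = None,
    qvalue_pi0: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t-test of case vs control.

    Parameters
    ----------
    expr : ExpressionMatrix
        log2 expression with group labels; >= 2 samples per group.
    prior_df : float, optional
        Fix the prior degrees of freedom instead of fitting them.  0 gives
        the ordinary pooled t-test, ``inf`` full shrinkage to the common
        variance.
    prior_var : float, optional
        Fix the prior variance s0^2 (only used when shrinkage is active).
    qvalue_pi0 : float, optional
        Fix pi0 for the q-value step (1.0 reproduces Benjamini-Hochberg).

    Returns
    -------
    DataFrame indexed by gene with columns ``avexp_control``,
    ``avexp_case``, ``logfc``, ``t``, ``p``, ``q``.
    """
    case = expr.case_samples()
    ctrl = expr.control_samples()
    n1, n2 = len(case), len(ctrl)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >=2 samples per group, got {n1} cases / {n2} controls")
    xc = expr.values[case].to_numpy(dtype=float)
    xk = expr.values[ctrl].to_numpy(dtype=float)
    if not (np.isfinite(xc).all() and np.isfinite(xk).all()):
        raise ValueError("expression matrix contains non-finite values")

    mean_case = xc.mean(axis=1)
    mean_ctrl = xk.mean(axis=1)
    logfc = mean_case - mean_ctrl
    df_resid = n1 + n2 - 2
    rss = ((xc - mean_case[:, None]) ** 2).sum(axis=1) + ((xk - mean_ctrl[:, None]) ** 2).sum(axis=1)
    s2 = rss / df_resid

    if prior_df is None:
        d0, s0_2 = fit_variance_prior(s2, df_resid)
        if prior_var is not None:
            s0_2 = float(prior_var)
    else:
        d0 = float(prior_df)
        if d0 < 0:
            raise ValueError("prior_df must be >= 0")
        s0_2 = float(prior_var) if prior_var is not None else (
            fit_variance_prior(s2, df_resid)[1] if d0 > 0 else 0.0
        )

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(logfc == 0.0, 0.0, logfc / se)
    t = np.where(np.isnan(t), 0.0, t)  # 0/0 only when logfc == 0
    p = 2.0 * stats.t.sf(np.abs(t), df_total)

    out = pd.DataFrame(
        {
            "avexp_control": mean_ctrl,
            "avexp_case": mean_case,
            "logfc": logfc,
            "t": t,
            "p": p,
        },
        index=expr.genes.rename("gene_id"),
    )
    out["q"] = estimate_qvalues(out["p"].to_numpy(), pi0=qvalue_pi0)
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_2
    out.attrs["df_resid"] = df_resid
    return out


def estimate_qvalues(
    p: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    pi0: float | None = None,
) -> np.ndarray:
    """q-values with tail-based pi0 estimation.

    pi0 is estimated as a running-mean smooth of
    ``#{p > lambda} / (m (1 - lambda))`` over the lambda grid, evaluated at
    the largest lambda; when the smoother degenerates (non-positive or
    non-finite) the most conservative grid point is used instead.  Pass
    ``pi0=1`` for plain Benjamini-Hochberg.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size

    if pi0 is None:
        grid = np.arange(0.0, 0.95, 0.05) if lambda_grid is None else np.asarray(lambda_grid, float)
        grid = np.sort(grid)
        raw = np.array([(p > lam).mean() / (1.0 - lam) for lam in grid])
        smooth = np.array(
            [raw[max(0, i - 1): i + 2].mean() for i in range(raw.size)]
        )
        pi0_est = smooth[-1]
        if not np.isfinite(pi0_est) or pi0_est <= 0:
            pi0_est = raw.max()  # most conservative grid point
        if pi0_est <= 0:
            pi0_est = 1.0 / m
        pi0 = min(1.0, float(pi0_est))
    else:
        if not 0.0 < pi0 <= 1.0:
            raise ValueError("pi0 must be in (0, 1]")

    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def write_de_table(de: pd.DataFrame, path, float_format: str | None = "%.6g") -> None:
    """Tab-separated table mirroring the standard report layout."""
    table = de.rename(
        columns={
            "avexp_control": "AvExp(Control)",
            "avexp_case": "AvExp(Case)",
            "logfc": "logFC",
            "t": "t",
            "p": "P-value",
            "q": "q-value",
        }
    )
    table.to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)
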