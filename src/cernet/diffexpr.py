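"""Two-group differential expression with an empirical-Bayes moderated t.

Per-gene residual variances are shrunk toward a common prior estimated by
the method of moments on log variances (Smyth's hierarchical model): the
sample variances are modelled as scaled chi-square draws

    s_g^2 | sigma_g^2  ~  sigma_g^2 * chisq(df) / df
    1 / sigma_g^2      ~  chisq(d0) / (d0 * s0^2)

which makes e_g = log(s_g^2) a shifted log-chi-square whose mean and
variance identify the prior degrees of freedom d0 and prior variance s0^2.
The moderated t uses the posterior variance (d0*s0^2 + df*s_g^2)/(d0+df)
and gains df, giving substantially better ranking than the ordinary t in
small microarray cohorts.  The same machinery serves mRNA and miRNA tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PriorEstimate:
    """Shrinkage hyperparameters: prior df ``d0`` (may be ``inf``) and prior
    variance ``s0_2``."""

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and self.s0_2 > 0):
            raise ValueError(f"invalid prior {self}")


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return special.polygamma(1, x)


def trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by monotone Newton iteration.

    Uses the Newton step on 1/trigamma (nearly linear in x), which converges
    monotonically from the starting value 0.5 + 1/y.
    """
    if y <= 0:
        return math.inf
    if y > 1e7:  # trigamma(x) ~ 1/x^2 for small x
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(_trigamma(x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> PriorEstimate:
    """Method-of-moments estimate of (d0, s0^2) from per-gene variances.

    Works on e_g = log(s2_g) - digamma(df/2) + log(df/2); the excess of
    var(e) over trigamma(df/2) identifies trigamma(d0/2).  When the observed
    spread is no larger than the chi-square sampling spread the prior df is
    infinite (complete shrinkage to s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all variances are zero; cannot estimate a prior")
    if positive.size < 10:
        logger.warning("only %d positive variances; prior estimate is crude",
                       positive.size)
    e = np.log(positive) - special.digamma(df / 2.0) + math.log(df / 2.0)
    n = e.size
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=0)) * n / (n - 1) if n > 1 else 0.0
    target = e_var - float(_trigamma(df / 2.0))
    if target <= 0:
        if e_var < 1e-15:
            # literally no spread: the data shows no chi-square sampling at
            # all, so shrink to the common observed variance itself — this
            # keeps the moderated t identical to the pooled t
            s0_2 = float(np.exp(np.mean(np.log(positive))))
        else:
            # spread within chi-square sampling noise: infinite prior df
            # with the log-bias-adjusted common variance (e is already
            # offset by log(df/2) - digamma(df/2))
            s0_2 = math.exp(e_mean)
        return PriorEstimate(d0=math.inf, s0_2=s0_2)
    d0 = 2.0 * trigamma_inverse(target)
    s0_2 = math.exp(e_mean + float(special.digamma(d0 / 2.0))
                    - math.log(d0 / 2.0))
    return PriorEstimate(d0=d0, s0_2=s0_2)


def moderated_t_test(m: ExpressionMatrix,
                     prior: PriorEstimate | None = None) -> pd.DataFrame:
    """Per-gene moderated t test of case vs control.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (mean(case)
    - mean(control)), ``t_mod``, ``p`` (two-sided), ``s2`` (pooled residual
    variance) and ``df_resid``.  When ``prior`` is omitted it is estimated
    from the data.  Genes with zero posterior variance cannot be tested and
    get p = 1.
    """
    case = m.values[m.samples_in_group("case")].to_numpy()
    ctrl = m.values[m.samples_in_group("control")].to_numpy()
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 samples per group, got {n1} case, {n2} control")
    df = n1 + n2 - 2
    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    s2 = ((n1 - 1) * case.var(axis=1, ddof=1)
          + (n2 - 1) * ctrl.var(axis=1, ddof=1)) / df
    if prior is None:
        prior = estimate_variance_prior(s2, df)
    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_2)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_2 + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, lfc / se, 0.0)
    if (se == 0).any():
        logger.warning("%d genes have zero posterior variance; p set to 1",
                       int((se == 0).sum()))
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.where(se > 0, np.clip(p, np.finfo(float).tiny, 1.0), 1.0)
    return pd.DataFrame(
        {"log2fc": lfc, "t_mod": t_mod, "p": p, "s2": s2,
         "df_resid": float(df)},
        index=pd.Index(m.feature_ids, name="gene"),
    )


def filter_degs(table: pd.DataFrame, lfc: float = 0.5,
                alpha: float = 0.05) -> tuple[list[str], list[str]]:
    """Split a DE table into (up, down) gene lists at strict cutoffs.

    A gene is up when p < alpha and log2fc > lfc, down when p < alpha and
    log2fc < -lfc.  Each list is ordered by |log2fc| descending, ties broken
    by symbol ascending — the ordering later consumed by rank aggregation.
    """
    sig = table[table["p"] < alpha]

    def ordered(sub: pd.DataFrame) -> list[str]:
        tmp = pd.DataFrame({"_abs": sub["log2fc"].abs(),
                            "_sym": sub.index.astype(str)})
        tmp = tmp.sort_values(["_abs", "_sym"], ascending=[False, True])
        return list(tmp["_sym"])

    up = sig[sig["log2fc"] > lfc]
    down = sig[sig["log2fc"] < -lfc]
    return ordered(up), ordered(down)
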