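"""Empirical-Bayes moderated differential methylation on M-values.

For each probe g a two-group contrast is fitted on the M scale (paired
design: one-sample location model on within-pair differences; unpaired:
two-sample pooled-variance contrast). Residual variances are shrunk
toward a common prior by the standard hierarchical model

    s2_g | sigma2_g ~ sigma2_g * chi2(d_g) / d_g
    1/sigma2_g      ~ chi2(d0) / (d0 * s02)

giving the posterior variance

    s2_post = (d0*s02 + d_g*s2_g) / (d0 + d_g)

and the moderated t-statistic t_mod = coef / sqrt(s2_post * v_g) on
d0 + d_g degrees of freedom, where v_g is the unscaled coefficient
variance (1/n for paired, 1/n1 + 1/n2 for unpaired). The prior degrees
of freedom d0 and prior variance s02 are estimated from the observed
log variances by digamma/trigamma moment matching.

With shrinkage disabled (d0 = 0) the statistic reduces exactly to the
classical paired / two-sample t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import BetaMatrix, DMSSet, ValidationError
from .preprocess import MMatrix, beta_to_m

logger = logging.getLogger(__name__)

_S2_ZERO_GUARD = 1e-8  # fraction of the smallest positive variance used for s2_g == 0


def bh_adjust(p_values) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sort ascending; q_(i) = min_{j >= i} p_(j) * m / j, capped at 1;
    result returned in the original order. Accepts array-likes or a
    pandas Series (index preserved).
    """
    if isinstance(p_values, pd.Series):
        adj = bh_adjust(p_values.to_numpy())
        return pd.Series(adj, index=p_values.index)
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise ValidationError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s02) from residual variances.

    Works on z_g = log(s2_g): E[z_g] and Var[z_g] under the hierarchical
    model involve digamma/trigamma of d_g/2 and d0/2; matching the sample
    moments yields d0 (possibly infinite) and s02.
    """
    ok = df > 0
    s2, df = np.asarray(s2, float)[ok], np.asarray(df, float)[ok]
    if s2.size < 2:
        raise ValidationError("need at least 2 probes with positive residual df to estimate the prior")
    pos = s2[s2 > 0]
    guard = (pos.min() if pos.size else 1.0) * _S2_ZERO_GUARD
    s2 = np.maximum(s2, guard)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = np.sum((e - emean) ** 2) / (n - 1) - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


@dataclass
class _ContrastFit:
    coef: np.ndarray  # group effect on the M scale
    s2: np.ndarray  # residual variance per probe
    df: np.ndarray  # residual df per probe
    v_unscaled: np.ndarray  # unscaled variance of coef


class DifferentialMethylationModel:
    """Two-group differential methylation model on M-values.

    Parameters
    ----------
    m
        :class:`~cpgdiff.preprocess.MMatrix` whose metadata carries ``group``
        (tumor/control) and, for the paired design, ``pair_id``.
    design
        ``"paired"`` — one-sample location model on within-pair
        tumor-minus-control M differences; ``"unpaired"`` — two-group
        mean contrast with pooled variance.

    Examples
    --------
    >>> model = DifferentialMethylationModel(m, design="paired")
    >>> res = model.fit()
    >>> dms = res.call_dms(beta, alpha=0.05)
    """

    def __init__(self, m: MMatrix, design: str = "paired"):
        if design not in ("paired", "unpaired"):
            raise ValidationError(f"design must be 'paired' or 'unpaired', got {design!r}")
        self.m = m
        self.design = design
        self._prepare()

    @classmethod
    def from_beta(cls, beta: BetaMatrix, design: str = "paired", epsilon: float = 1e-3) -> "DifferentialMethylationModel":
        model = cls(beta_to_m(beta, epsilon=epsilon), design=design)
        model._beta = beta
        return model

    # -- design preparation -------------------------------------------------

    def _prepare(self) -> None:
        md = self.m.metadata
        if self.design == "paired":
            pseudo = BetaMatrix.__new__(BetaMatrix)  # reuse pairing validation without beta checks
            pseudo.metadata = md
            pairs = BetaMatrix.validate_pairing(pseudo)
            if len(pairs) < 2:
                raise ValidationError(f"paired design needs >=2 complete pairs, got {len(pairs)}")
            self.pairs = pairs
            self.tumor_samples = list(pairs["tumor"])
            self.control_samples = list(pairs["control"])
        else:
            self.tumor_samples = list(md.index[md["group"] == "tumor"])
            self.control_samples = list(md.index[md["group"] == "control"])
            if len(self.tumor_samples) < 2 or len(self.control_samples) < 2:
                raise ValidationError(
                    "unpaired design needs >=2 samples per group "
                    f"(tumor={len(self.tumor_samples)}, control={len(self.control_samples)})"
                )

    def _contrast_fit(self) -> _ContrastFit:
        vals = self.m.values
        if self.design == "paired":
            diff = vals[self.tumor_samples].to_numpy() - vals[self.control_samples].to_numpy()
            n_valid = np.sum(~np.isnan(diff), axis=1)
            with np.errstate(invalid="ignore"):
                coef = np.nanmean(diff, axis=1)
                s2 = np.nanvar(diff, axis=1, ddof=1)
            df = n_valid - 1.0
            v = np.where(n_valid > 0, 1.0 / np.maximum(n_valid, 1), np.nan)
            return _ContrastFit(coef, s2, df, v)
        t = vals[self.tumor_samples].to_numpy()
        c = vals[self.control_samples].to_numpy()
        n1 = np.sum(~np.isnan(t), axis=1).astype(float)
        n2 = np.sum(~np.isnan(c), axis=1).astype(float)
        with np.errstate(invalid="ignore"):
            coef = np.nanmean(t, axis=1) - np.nanmean(c, axis=1)
            var1 = np.nanvar(t, axis=1, ddof=1)
            var2 = np.nanvar(c, axis=1, ddof=1)
        df = n1 + n2 - 2.0
        s2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / np.where(df > 0, df, np.nan)
        v = 1.0 / n1 + 1.0 / n2
        return _ContrastFit(coef, s2, df, v)

    # -- fitting ------------------------------------------------------------

    def fit(self, shrink: bool = True, prior_df: float | None = None) -> "DifferentialMethylationResults":
        """Fit the contrast and apply empirical-Bayes variance shrinkage.

        Parameters
        ----------
        shrink
            If False, d0 is forced to 0 and the statistic equals the
            classical t-test.
        prior_df
            Override the estimated prior degrees of freedom (``np.inf``
            shrinks every variance fully to the prior s02).
        """
        cf = self._contrast_fit()
        if not shrink:
            d0, s02 = 0.0, np.nan
        elif prior_df is not None:
            _, s02 = estimate_prior(cf.s2, cf.df)
            d0 = float(prior_df)
        else:
            d0, s02 = estimate_prior(cf.s2, cf.df)

        if d0 == 0.0:
            s2_post = cf.s2.copy()
        elif np.isinf(d0):
            s2_post = np.full_like(cf.s2, s02)
        else:
            s2_post = (d0 * s02 + cf.df * cf.s2) / (d0 + cf.df)

        df_total = d0 + cf.df
        with np.errstate(invalid="ignore", divide="ignore"):
            t_mod = cf.coef / np.sqrt(s2_post * cf.v_unscaled)
            p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
        p = np.where(np.isnan(p), 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
        return DifferentialMethylationResults(
            model=self,
            coef=pd.Series(cf.coef, index=self.m.probe_ids, name="coef"),
            sigma2=pd.Series(cf.s2, index=self.m.probe_ids, name="s2"),
            df_residual=pd.Series(cf.df, index=self.m.probe_ids, name="df_residual"),
            df_prior=d0,
            s2_prior=s02,
            s2_post=pd.Series(s2_post, index=self.m.probe_ids, name="s2_post"),
            tvalues=pd.Series(t_mod, index=self.m.probe_ids, name="t_mod"),
            pvalues=pd.Series(p, index=self.m.probe_ids, name="p_value"),
        )


class DifferentialMethylationResults:
    """Fitted moderated-model results.

    Attributes mirror statsmodels results objects: ``coef`` (group effect
    on the M scale), ``tvalues``, ``pvalues``, ``adj_pvalues`` (BH),
    shrinkage hyperparameters ``df_prior`` (d0) and ``s2_prior`` (s02),
    and the posterior variances ``s2_post``.
    """

    def __init__(self, model, coef, sigma2, df_residual, df_prior, s2_prior, s2_post, tvalues, pvalues):
        self.model = model
        self.coef = coef
        self.sigma2 = sigma2
        self.df_residual = df_residual
        self.df_prior = df_prior
        self.s2_prior = s2_prior
        self.s2_post = s2_post
        self.tvalues = tvalues
        self.pvalues = pvalues
        self.adj_pvalues = bh_adjust(pvalues)

    @property
    def n_tested(self) -> int:
        return len(self.pvalues)

    def delta_beta(self, beta: BetaMatrix) -> pd.Series:
        """Effect size on the beta scale: mean beta(tumor) - mean beta(control).

        Under the paired design this is the mean of per-pair differences
        (identical to the difference of group means when data are complete).
        """
        if list(beta.probe_ids) != list(self.model.m.probe_ids):
            raise ValidationError("beta matrix probes do not match the fitted model")
        vals = beta.values
        if self.model.design == "paired":
            diff = vals[self.model.tumor_samples].to_numpy() - vals[self.model.control_samples].to_numpy()
            with np.errstate(invalid="ignore"):
                db = np.nanmean(diff, axis=1)
        else:
            with np.errstate(invalid="ignore"):
                db = np.nanmean(vals[self.model.tumor_samples].to_numpy(), axis=1) - np.nanmean(
                    vals[self.model.control_samples].to_numpy(), axis=1
                )
        return pd.Series(db, index=beta.probe_ids, name="delta_beta")

    def call_dms(self, beta: BetaMatrix, alpha: float = 0.05) -> DMSSet:
        """Call differentially methylated sites at BH-adjusted p < alpha.

        Direction is hypo iff delta_beta < 0; probes whose delta_beta sign
        disagrees with the M-scale coefficient (possible very near zero
        because the beta->M map is probe-specifically nonlinear) are
        resolved by delta_beta and logged.
        """
        if not 0 < alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {alpha}")
        db = self.delta_beta(beta)
        sig = self.adj_pvalues < alpha
        discordant = sig & (np.sign(db) != np.sign(self.coef)) & (db != 0)
        if discordant.any():
            logger.warning(
                "%d significant probes have delta_beta sign discordant with the M-scale "
                "coefficient; direction assigned from delta_beta",
                int(discordant.sum()),
            )
        records = pd.DataFrame(
            {
                "delta_beta": db[sig],
                "t_mod": self.tvalues[sig],
                "p_value": self.pvalues[sig],
                "adj_p": self.adj_pvalues[sig],
                "direction": np.where(db[sig] < 0, "hypo", "hyper"),
            }
        )
        return DMSSet(records=records, alpha=alpha, design=self.model.design, n_tested=self.n_tested)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "s2": self.sigma2,
                "s2_post": self.s2_post,
                "t_mod": self.tvalues,
                "p_value": self.pvalues,
                "adj_p": self.adj_pvalues,
            }
        )

    def summary(self, top: int = 10) -> str:
        """Text summary: design, cohort sizes, shrinkage prior, top probes by p."""
        frame = self.summary_frame().sort_values("p_value").head(top)
        lines = [
            "Differential methylation (empirical-Bayes moderated t)",
            "=" * 58,
            f"design:        {self.model.design}",
            f"probes tested: {self.n_tested}",
            f"tumor n:       {len(self.model.tumor_samples)}",
            f"control n:     {len(self.model.control_samples)}",
            f"prior df (d0): {self.df_prior:.4g}",
            f"prior var s02: {self.s2_prior:.4g}" if np.isfinite(self.s2_prior) else "prior var s02: n/a (shrinkage off)",
            "-" * 58,
            frame.to_string(float_format=lambda x: f"{x:.4g}"),
        ]
        return "\n".join(lines)

    def plot_volcano(self, beta: BetaMatrix, alpha: float = 0.05, ax=None):
        """Volcano plot of delta_beta vs -log10 adjusted p (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        db = self.delta_beta(beta)
        y = -np.log10(self.adj_pvalues)
        sig = self.adj_pvalues < alpha
        ax.scatter(db[~sig], y[~sig], s=4, c="grey", alpha=0.5)
        ax.scatter(db[sig], y[sig], s=6, c="crimson")
        ax.axhline(-np.log10(alpha), color="black", lw=0.8)
        ax.set_xlabel("delta beta (tumor - control)")
        ax.set_ylabel("-log10 adjP")
        return ax
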