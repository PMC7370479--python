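"""Model-style interface for estimating a prevalence from count data.

The observed data are three binomial counts: ``x`` positives among ``n``
tested individuals, plus the results of the diagnostic test's validation
studies -- ``x_se`` true positives among ``n_se`` known-diseased and ``x_sp``
true negatives among ``n_sp`` known-healthy samples.

    >>> m = PrevalenceModel(x=129, n=323, x_se=74, n_se=100, x_sp=193, n_sp=200)
    >>> res = m.fit(method="lang_reiczigel")
    >>> round(res.point, 4), [round(v, 4) for v in res.conf_int()]

``fit`` dispatches to any of the frequentist interval constructions or to the
Bayesian Gibbs sampler; ``fit_all`` collects every method into one table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import frequentist as fq
from . import gibbs
from .datasim import MLEstimates, classify

__all__ = ["PrevalenceModel", "PrevalenceResults", "ALL_METHODS"]

ALL_METHODS = fq.FREQUENTIST_METHODS + ("bayes_hdi",)


@dataclass
class PrevalenceResults:
    """Estimate of a true prevalence with its 95% interval.

    ``point`` is the truncated Rogan-Gladen estimate for frequentist methods
    and the posterior mean for ``bayes_hdi``; ``point_raw`` keeps the
    non-truncated Rogan-Gladen value (NaN for the Bayesian fit).
    """

    model: "PrevalenceModel"
    method: str
    point: float
    point_raw: float
    lower: float
    upper: float
    level: float
    psrf: float = float("nan")
    ess: float = float("nan")
    converged: bool = True
    draws: gibbs.PosteriorDraws | None = None

    def conf_int(self) -> tuple[float, float]:
        return (self.lower, self.upper)

    @property
    def length(self) -> float:
        return self.upper - self.lower

    def summary(self) -> str:
        m = self.model
        lines = [
            "Prevalence estimate adjusted for misclassification",
            "=" * 52,
            f"method:           {self.method}",
            f"data:             x={m.x}/{m.n}, x_se={m.x_se}/{m.n_se}, x_sp={m.x_sp}/{m.n_sp}",
            f"MLEs:             Se_hat={m.mle.se_hat:.6g}, Sp_hat={m.mle.sp_hat:.6g}, AP_hat={m.mle.ap_hat:.6g}",
            f"point estimate:   {self.point:.6f}",
            f"{int(self.level*100)}% interval:     [{self.lower:.6f}, {self.upper:.6f}]",
        ]
        if not np.isnan(self.point_raw):
            lines.append(f"raw Rogan-Gladen: {self.point_raw:.6f}")
        if self.method == "bayes_hdi":
            lines.append(f"PSRF: {self.psrf:.4f}   ESS: {self.ess:.0f}   converged: {self.converged}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "method": self.method, "point_raw": self.point_raw, "point": self.point,
                "lower": self.lower, "upper": self.upper, "length": self.length,
            }]
        )


class PrevalenceModel:
    """True-prevalence model for one application of an imperfect test."""

    def __init__(self, x: int, n: int, x_se: int, n_se: int, x_sp: int, n_sp: int):
        for count, size, name in ((x, n, "x"), (x_se, n_se, "x_se"), (x_sp, n_sp, "x_sp")):
            if size < 1 or not 0 <= count <= size:
                raise ValueError(f"invalid counts: 0 <= {name} <= size required")
        self.x, self.n = int(x), int(n)
        self.x_se, self.n_se = int(x_se), int(n_se)
        self.x_sp, self.n_sp = int(x_sp), int(n_sp)
        self.mle = MLEstimates(self.x_se / self.n_se, self.x_sp / self.n_sp, self.x / self.n)
        self.case = classify(self.mle)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PrevalenceModel":
        """Build from a one-row table with columns x, n, x_se, n_se, x_sp, n_sp."""
        if len(df) != 1:
            raise ValueError("expected exactly one row of counts")
        r = df.iloc[0]
        return cls(r["x"], r["n"], r["x_se"], r["n_se"], r["x_sp"], r["n_sp"])

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (self.n, self.n_se, self.n_sp)

    def _require_adjustable(self) -> None:
        if self.case == "excluded":
            raise ValueError(
                "the estimated test does not discriminate better than chance "
                "(1 - Sp_hat >= Se_hat); refrain from adjusting for "
                "misclassification until the test's accuracy data are clarified"
            )

    def fit(self, method: str = "bayes_hdi", level: float = 0.95,
            prior: gibbs.PriorSpec | None = None,
            mcmc: gibbs.McmcConfig | None = None,
            lr_adjustment: fq.LangReiczigelAdjustment = fq.LangReiczigelAdjustment(),
            ) -> PrevalenceResults:
        """Fit one estimation method; returns a :class:`PrevalenceResults`."""
        if method not in ALL_METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {ALL_METHODS}")
        self._require_adjustable()
        if method == "bayes_hdi":
            cfg = mcmc or gibbs.McmcConfig()
            draws = gibbs.gibbs_sample(self, self.sizes, prior, cfg)
            s = gibbs.summarize(draws, cfg)
            return PrevalenceResults(
                self, method, s.mean_pi, float("nan"), s.hdi_low, s.hdi_high,
                0.95, s.psrf_pi, s.ess_pi, s.converged, draws,
            )
        raw = fq.rogan_gladen(self.mle.ap_hat, self.mle.se_hat, self.mle.sp_hat)
        point = fq.truncate_unit(raw)
        if method in ("clopper_pearson", "sterne", "blaker"):
            ci_ap = fq.exact_binomial_ci(self.x, self.n, level, method)
            est = fq.transform_ap_interval(ci_ap, self.mle.se_hat, self.mle.sp_hat,
                                           level, method, raw)
        elif method == "wald_rogan_gladen":
            est = fq.wald_rogan_gladen_ci(self.mle, self.sizes, level)
        else:  # lang_reiczigel
            est = fq.lang_reiczigel_ci(self, self.sizes, level, lr_adjustment)
        return PrevalenceResults(self, method, point, raw, est.lower, est.upper, level)

    def fit_all(self, methods=ALL_METHODS, level: float = 0.95,
                mcmc: gibbs.McmcConfig | None = None) -> pd.DataFrame:
        """Fit several methods; returns one table row per method."""
        frames = [self.fit(m, level=level, mcmc=mcmc).to_frame() for m in methods]
        return pd.concat(frames, ignore_index=True)
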