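"""Model/Results interface over the threshold index logistic machinery.

`ThresholdIndexLogit` is constructed from data (arrays or a DataFrame) in
the style of the classic regression packages; `fit()` runs the
multi-start simplex maximization and returns a results object carrying
the canonical estimates, optional bootstrap standard errors, diagnostics
and a `summary()` table.
"""

from __future__ import annotations

import io as _io

import numpy as np
import pandas as pd

from .estimation import BootstrapConfig, FitResult, bootstrap_sd, fit_mle
from .model import (
    FitConfig,
    GenotypeMatrix,
    TILoRParams,
    below_threshold_fractions,
    case_probability,
    eval_threshold_link,
)

__all__ = ["ThresholdIndexLogit", "ThresholdIndexLogitResults"]


class ThresholdIndexLogit:
    """Additive threshold index logistic regression model.

    Parameters
    ----------
    endog : (n,) array of 0/1 phenotypes (1 = case)
    exog : (n, p) array of genotype codes in {0, 1, 2}
    snp_ids, subject_ids : optional labels
    """

    def __init__(self, endog, exog, snp_ids=None, subject_ids=None):
        self.data = GenotypeMatrix(
            np.asarray(exog),
            np.asarray(endog),
            list(snp_ids) if snp_ids is not None else [],
            list(subject_ids) if subject_ids is not None else [],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, phenotype: str = "phenotype"):
        """Build the model from a subjects × (SNPs + phenotype) DataFrame."""
        if phenotype not in df.columns:
            raise ValueError(f"phenotype column {phenotype!r} not found")
        snp_cols = [c for c in df.columns if c != phenotype]
        return cls(
            df[phenotype].to_numpy(),
            df[snp_cols].to_numpy(),
            snp_ids=snp_cols,
            subject_ids=[str(i) for i in df.index],
        )

    @property
    def endog(self) -> np.ndarray:
        return self.data.phenotype

    @property
    def exog(self) -> np.ndarray:
        return self.data.genotypes

    def predict(self, params: TILoRParams, exog=None) -> np.ndarray:
        X = self.data.genotypes if exog is None else np.asarray(exog)
        return case_probability(params, X)

    def loglike(self, params: TILoRParams) -> float:
        from .model import log_likelihood

        return log_likelihood(params, self.data)

    def fit(
        self,
        config: FitConfig | None = None,
        **kwargs,
    ) -> "ThresholdIndexLogitResults":
        """Multi-start downhill-simplex penalized MLE.

        Keyword arguments (``n_restarts``, ``seed``, ...) override fields of
        a default :class:`FitConfig` when ``config`` is not given.
        """
        if config is None:
            config = FitConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either config or keyword overrides, not both")
        return ThresholdIndexLogitResults(self, fit_mle(self.data, config), config)


class ThresholdIndexLogitResults:
    """Fitted threshold index logistic model."""

    def __init__(self, model: ThresholdIndexLogit, fit_result: FitResult, config: FitConfig):
        self.model = model
        self.fit_result = fit_result
        self.config = config

    # -- estimates ----------------------------------------------------------
    @property
    def params(self) -> TILoRParams:
        return self.fit_result.theta_hat

    @property
    def llf(self) -> float:
        return self.fit_result.loglik

    @property
    def objective(self) -> float:
        return self.fit_result.objective

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @property
    def bse(self) -> TILoRParams | None:
        """Bootstrap standard errors, once :meth:`bootstrap_sd` has run."""
        return self.fit_result.sd

    def bootstrap_sd(
        self,
        config: BootstrapConfig | None = None,
        fit_config: FitConfig | None = None,
    ) -> TILoRParams:
        """Parametric-bootstrap standard errors; stored on the result."""
        sd = bootstrap_sd(
            self.params, self.model.data, config, fit_config or self.config
        )
        self.fit_result.sd = sd
        return sd

    def predict(self, exog=None) -> np.ndarray:
        return self.model.predict(self.params, exog)

    # -- descriptive summaries ---------------------------------------------
    def below_threshold_fractions(self) -> tuple[float, float]:
        """Fraction of subjects whose alpha- and beta-indices are <= c1, c2."""
        return below_threshold_fractions(self.params, self.model.data)

    def index_coefficients(self) -> pd.DataFrame:
        """Per-SNP alpha and beta loadings (with bootstrap sds if available)."""
        t = self.params
        frame = {"snp_id": self.model.data.snp_ids, "alpha": t.alpha, "beta": t.beta}
        if self.bse is not None:
            frame["alpha_sd"] = self.bse.alpha
            frame["beta_sd"] = self.bse.beta
        return pd.DataFrame(frame)

    def link_coefficients(self) -> pd.DataFrame:
        """Regime coefficients and thresholds of g1, g2 (Table-style layout)."""
        t = self.params
        rows = []
        for name, link in (("g1", t.g1), ("g2", t.g2)):
            rows.append(
                {"link": name, "b1": link.b1, "b2": link.b2, "b3": link.b3,
                 "b4": link.b4, "c": link.c}
            )
        if self.bse is not None:
            for row, link in zip(rows, (self.bse.g1, self.bse.g2)):
                row.update(
                    {"b1_sd": link.b1, "b2_sd": link.b2, "b3_sd": link.b3,
                     "b4_sd": link.b4, "c_sd": link.c}
                )
        return pd.DataFrame(rows)

    def link_curve_table(self, n_points: int = 201) -> pd.DataFrame:
        """g1 and g2 evaluated on a grid spanning the observed index values."""
        t = self.params
        X = np.asarray(self.model.data.genotypes, dtype=float)
        out = {}
        for name, vec, link in (("g1", t.alpha, t.g1), ("g2", t.beta, t.g2)):
            u = X @ vec
            grid = np.linspace(u.min(), u.max(), n_points)
            out[f"u_{name}"] = grid
            out[name] = eval_threshold_link(link, grid)
        return pd.DataFrame(out)

    def plot_links(self, ax=None):
        """Plot the two fitted threshold link functions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.link_curve_table()
        for name in ("g1", "g2"):
            ax.plot(tab[f"u_{name}"], tab[name], label=name)
        for c, ls in ((self.params.g1.c, "--"), (self.params.g2.c, ":")):
            ax.axvline(c, linestyle=ls, color="grey", linewidth=0.8)
        ax.set_xlabel("index value u")
        ax.set_ylabel("g(u)")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Text summary: fit diagnostics, link coefficients, index loadings."""
        fr = self.fit_result
        data = self.model.data
        buf = _io.StringIO()
        buf.write("Threshold Index Logistic Regression Results\n")
        buf.write("=" * 60 + "\n")
        buf.write(
            f"No. observations: {data.n} ({data.n_cases} cases, "
            f"{data.n_controls} controls)   No. SNPs: {data.p}\n"
        )
        buf.write(
            f"Log-likelihood: {fr.loglik:.4f}   Penalized objective: "
            f"{fr.objective:.4f}\n"
        )
        buf.write(
            f"Restarts: {fr.n_restarts_run} (best: {fr.best_restart_index})   "
            f"Converged: {fr.converged}   Seed: {fr.seed}\n"
        )
        f1, f2 = self.below_threshold_fractions()
        buf.write(
            f"P(alpha'x <= c1) = {100 * f1:.2f}%   "
            f"P(beta'x <= c2) = {100 * f2:.2f}%\n"
        )
        buf.write("-" * 60 + "\n")
        buf.write(self.link_coefficients().to_string(index=False, float_format="%.4f"))
        buf.write("\n" + "-" * 60 + "\n")
        buf.write(
            self.index_coefficients().to_string(index=False, float_format="%.4f")
        )
        buf.write("\n")
        return buf.getvalue()
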