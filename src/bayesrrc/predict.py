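"""Posterior-predictive genomic prediction and individual-level uncertainty.

A genetic value draw for individual i is g_i = sum_j x_ij beta_j^(draw) with
the new cohort standardized using the TRAINING means and SDs, so effect sizes
transfer on the scale they were estimated on. The full set of draws gives a
posterior predictive distribution per individual, from which accuracy,
coverage, and percentile-of-risk (PCF) metrics are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "PredictiveDistribution",
    "posterior_predictive",
    "accuracy",
    "coverage_probability",
    "pcf_probability",
    "group_partial_correlations",
    "expected_ridge_r2",
]


@dataclass
class PredictiveDistribution:
    """Per-individual genetic-value draws, one per retained posterior sample.

    ``draws`` is (n_draws, n_individuals); ``mean`` averages over draws.
    """

    draws: np.ndarray
    individual_ids: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.draws.shape[1]

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def quantiles(self, q=(0.025, 0.975)) -> np.ndarray:
        return np.quantile(self.draws, q, axis=0)

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.quantiles()
        ids = (self.individual_ids if self.individual_ids is not None
               else np.arange(self.n_individuals))
        return pd.DataFrame({"id": ids, "mean": self.mean, "q2.5": lo, "q97.5": hi})


def _standardize_with_training(new_panel, training, marker_subset=None):
    """Standardize a new panel's columns with the training means/sds.

    Markers present in the training scaling but absent from the new panel are
    dropped (and counted in the log); new-panel order follows training order.
    """
    new_ids = {str(m): i for i, m in enumerate(new_panel.marker_ids)}
    train_ids = [str(m) for m in training.marker_ids]
    cols_train, cols_new = [], []
    for tj, mid in enumerate(train_ids):
        if marker_subset is not None and tj not in marker_subset:
            continue
        if mid in new_ids:
            cols_train.append(tj)
            cols_new.append(new_ids[mid])
    dropped = (len(train_ids) if marker_subset is None else len(marker_subset)) - len(cols_train)
    if dropped:
        logger.warning("%d training markers absent from the new panel were dropped", dropped)
    g = new_panel.genotypes[:, cols_new].astype(float)
    miss = g < 0
    if miss.any():
        g[miss] = np.nan
        g = np.where(np.isnan(g), training.means[cols_train], g)
    x = (g - training.means[cols_train]) / training.sds[cols_train]
    return x, np.asarray(cols_train, dtype=int), dropped


def posterior_predictive(samples, new_panel, training, marker_subset=None
                         ) -> PredictiveDistribution:
    """Genetic-value draws for new individuals from the stored effect draws.

    ``training`` is the :class:`~bayesrrc.model.StandardizedGenotypes` of the
    fitting cohort (its means/sds standardize the new panel). An optional
    ``marker_subset`` (training marker indices) restricts the predictor, e.g.
    to one annotation group.
    """
    x, cols_train, _ = _standardize_with_training(new_panel, training, marker_subset)
    col_pos = np.full(len(training.marker_ids), -1, dtype=np.int64)
    col_pos[cols_train] = np.arange(len(cols_train))
    n = x.shape[0]
    out = np.zeros((samples.n_draws, n))
    for d in range(samples.n_draws):
        idx, val, _ = samples.draw_effects(d)
        pos = col_pos[idx]
        keep = pos >= 0
        if keep.any():
            out[d] = x[:, pos[keep]] @ val[keep]
    return PredictiveDistribution(out)


def accuracy(pred: PredictiveDistribution, phenotype) -> dict:
    """Correlation and R^2 of the posterior-mean predictor; AUC if binary.

    AUC uses the rank-sum (Mann-Whitney) identity with ties mid-ranked.
    Constant predictors yield NaN correlation, reported as such.
    """
    y = np.asarray(phenotype, dtype=float)
    g = pred.mean
    if len(y) != len(g):
        raise ValueError("phenotype and prediction must align")
    if g.std() == 0 or y.std() == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(g, y)[0, 1])
    out = {"correlation": r, "r2": r**2 if np.isfinite(r) else np.nan}
    uniq = np.unique(y)
    if len(uniq) == 2 and set(uniq) <= {0.0, 1.0}:
        ranks = rankdata(g)
        n1 = int(y.sum())
        n0 = len(y) - n1
        out["auc"] = float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
    return out


def coverage_probability(pred: PredictiveDistribution, phenotype,
                         width: float = 1.0) -> np.ndarray:
    """Per-individual fraction of draws with |g_draw - y| below ``width``."""
    y = np.asarray(phenotype, dtype=float)
    return (np.abs(pred.draws - y[None, :]) < width).mean(axis=0)


def pcf_probability(pred: PredictiveDistribution, percentile: float = 0.25,
                    population_reference=None, case_labels=None) -> dict:
    """Probability of sitting in the top-``percentile`` of genetic risk.

    The cutoff is the (1 - percentile) quantile of the population reference
    distribution (by default the cohort's own posterior-mean predictors); the
    per-individual probability is the fraction of that individual's draws
    above the cutoff. With ``case_labels``, a 2x2 odds ratio contrasts the
    >= 0.9 and <= 0.1 probability strata.
    """
    ref = (np.asarray(population_reference, dtype=float)
           if population_reference is not None else pred.mean)
    cutoff = np.quantile(ref, 1.0 - percentile)
    prob = (pred.draws > cutoff).mean(axis=0)
    out = {"probability": prob, "cutoff": float(cutoff)}
    if case_labels is not None:
        y = np.asarray(case_labels).astype(bool)
        hi, lo = prob >= 0.9, prob <= 0.1
        if hi.any() and lo.any() and y[hi].any() and (~y[hi]).any() \
                and y[lo].any() and (~y[lo]).any():
            a, b = int(y[hi].sum()), int((~y[hi]).sum())
            c, d = int(y[lo].sum()), int((~y[lo]).sum())
            out["odds_ratio"] = (a / b) / (c / d)
            out["case_rate_high"] = a / (a + b)
            out["case_rate_low"] = c / (c + d)
        else:
            out["odds_ratio"] = np.nan  # empty stratum
    return out


def group_partial_correlations(group_preds: dict, phenotype) -> pd.DataFrame:
    """Partial correlation of each group predictor with y, given the others.

    ``group_preds`` maps group name -> PredictiveDistribution (one predictor
    per annotation group per draw). Per draw the partial correlations are
    read off the inverse of the correlation matrix of [y, g_1, ..., g_K];
    draws with singular (collinear) correlation matrices are flagged and
    skipped. Pairwise correlations among the posterior-mean group predictors
    are reported alongside.
    """
    names = list(group_preds)
    y = np.asarray(phenotype, dtype=float)
    first = group_preds[names[0]]
    if len(names) == 1:
        r = np.corrcoef(first.mean, y)[0, 1]
        return pd.DataFrame([{"group": names[0], "partial_mean": r,
                              "partial_ci_low": np.nan, "partial_ci_high": np.nan,
                              "flagged_draws": 0}])
    n_draws = first.n_draws
    partials = np.full((n_draws, len(names)), np.nan)
    flagged = 0
    for d in range(n_draws):
        mat = np.column_stack([y] + [group_preds[nm].draws[d] for nm in names])
        if np.any(mat.std(axis=0) == 0):
            flagged += 1
            continue
        corr = np.corrcoef(mat, rowvar=False)
        try:
            prec = np.linalg.inv(corr)
        except np.linalg.LinAlgError:
            flagged += 1
            continue
        diag = np.sqrt(np.outer(np.diag(prec), np.diag(prec)))
        partial = -prec / diag
        partials[d] = partial[0, 1:]
    rows = []
    for i, nm in enumerate(names):
        col = partials[:, i]
        col = col[np.isfinite(col)]
        rows.append({"group": nm,
                     "partial_mean": col.mean() if len(col) else np.nan,
                     "partial_ci_low": np.quantile(col, 0.025) if len(col) else np.nan,
                     "partial_ci_high": np.quantile(col, 0.975) if len(col) else np.nan,
                     "flagged_draws": flagged})
    return pd.DataFrame(rows)


def expected_ridge_r2(n: float, m_causal: float, h2: float) -> float:
    """Expected prediction R^2 under ridge-regression theory.

    R^2 = h2 / (1 + m / (n h2)) with the marker count m set to the number of
    causal variants; the expected correlation is its square root.
    """
    if n <= 0 or m_causal < 0 or not (0 <= h2 <= 1):
        raise ValueError("need n > 0, m_causal >= 0, h2 in [0, 1]")
    if h2 == 0:
        return 0.0
    return h2 / (1.0 + m_causal / (n * h2))
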