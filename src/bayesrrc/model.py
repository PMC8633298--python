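"""The grouped Dirac spike-and-slab whole-genome regression model.

The model of a phenotype vector y over N individuals and p standardized SNP
markers split into groups phi = 1..G is

    y = 1 mu + sum_phi X_phi beta_phi + eps,     eps ~ N(0, I sigma2_eps)

with each marker effect drawn from a group-specific mixture of a point mass
at zero (the Dirac spike) and L Gaussian slab components whose variances are
the group variance sigma2_G[phi] scaled by fixed mixture constants C_l:

    beta_j ~ pi_0 delta_0 + sum_l pi_l N(0, sigma2_G[phi] * C_l)

Mixture proportions pi_phi, group variances sigma2_G[phi] and the residual
variance are all estimated by Gibbs sampling with conjugate updates
(Dirichlet for pi, scaled inverse chi-square for the variances) and sparse
residual updating for the marker sweep.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from . import _gibbs
from .annotate import MarkerGrouping
from .samples import PosteriorSamples

logger = logging.getLogger(__name__)

__all__ = ["MixtureSpec", "ChainConfig", "StandardizedGenotypes", "standardize", "BayesRRC"]

#: slab variance multipliers; the zero spike is handled separately
DEFAULT_MIXTURE = (0.0001, 0.001, 0.01, 0.1)


@dataclass(frozen=True)
class MixtureSpec:
    """Ordered slab mixture constants C_1 < ... < C_L (all > 0)."""

    constants: tuple = DEFAULT_MIXTURE

    def __post_init__(self) -> None:
        c = np.asarray(self.constants, dtype=float)
        if len(c) == 0 or np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("mixture constants must be strictly increasing and > 0")

    @property
    def n_components(self) -> int:
        return len(self.constants)


@dataclass(frozen=True)
class ChainConfig:
    """Gibbs chain settings and hyperprior constants.

    ``nu0`` and the scale parameters define the scaled inverse chi-square
    hyperpriors: s0^2 = Var(y) / (2 G) for each group variance and Var(y) / 2
    for the residual variance. The Dirichlet prior on the mixture proportions
    is spike-favoring: concentration ``dirichlet_alpha_spike`` on the zero
    component and ``dirichlet_alpha`` on each slab component. Keeping the
    spike pseudo-count at least 1 while the slab concentrations are small
    protects the sparse regime the model is designed to explore: with a
    symmetric concentration the per-group mixture proportions perform a
    near-neutral random walk (the average Bayes factor of a null marker is
    exactly 1 for every slab variance) whose dense corner is absorbing in
    small marker groups.
    """

    n_iter: int = 2500
    burn_in: int = 500
    thin: int = 1
    n_chains: int = 1
    seed: int = 0
    dirichlet_alpha: float = 0.05
    dirichlet_alpha_spike: float = 5.0
    nu0: float = 4.0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class StandardizedGenotypes:
    """Marker-major standardized genotypes plus the training scaling.

    ``xt`` is (p, N) float32 with rows of mean 0 / variance 1 (denominator N,
    missing genotypes mean-imputed before scaling); ``means`` / ``sds`` are
    the 0/1/2-scale column statistics needed to standardize a new cohort with
    the training scaling; ``xx`` holds the exact per-row sums of squares used
    by the sampler in place of N.
    """

    xt: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    xx: np.ndarray
    marker_ids: np.ndarray

    @property
    def n_markers(self) -> int:
        return self.xt.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.xt.shape[1]


def standardize(panel) -> StandardizedGenotypes:
    """Centre and scale a genotype panel to per-marker unit variance.

    Missing calls (-1) are mean-imputed, which after centring contributes
    exact zeros — the algebra the sparse residual update relies on.
    Monomorphic markers are rejected by name.
    """
    g = panel.genotypes
    n, p = g.shape
    xt = np.empty((p, n), dtype=np.float32)
    means = np.empty(p)
    sds = np.empty(p)
    bad = []
    for j in range(p):
        col = g[:, j].astype(np.float64)
        miss = col < 0
        if miss.any():
            mu_obs = col[~miss].mean() if (~miss).any() else 0.0
            col[miss] = mu_obs
        mu = col.mean()
        sd = col.std()
        if sd == 0.0:
            bad.append(str(panel.marker_ids[j]))
            sd = 1.0
        means[j] = mu
        sds[j] = sd
        xt[j] = ((col - mu) / sd).astype(np.float32)
    if bad:
        raise ValueError(f"monomorphic markers cannot be standardized: {bad}")
    xx = np.einsum("ij,ij->i", xt.astype(np.float64), xt.astype(np.float64))
    return StandardizedGenotypes(xt, means, sds, xx, np.asarray(panel.marker_ids))


class BayesRRC:
    """Grouped spike-and-slab regression of a phenotype on SNP markers.

    Parameters
    ----------
    y : (N,) array
        Phenotype, continuous or 0/1 (binary traits are modelled on the
        observed scale as a linear model).
    genotypes : GenotypePanel or StandardizedGenotypes
        Raw panel (standardized internally) or pre-standardized matrix.
    grouping : MarkerGrouping, optional
        Marker partition; defaults to a single group, which reduces the model
        to plain (ungrouped) BayesR.
    mixture : MixtureSpec, optional
        Slab mixture constants, default (0.0001, 0.001, 0.01, 0.1).

    Examples
    --------
    >>> model = BayesRRC(y, panel, grouping=groups)
    >>> res = model.fit(n_iter=3000, burn_in=1000, seed=7)
    >>> res.variance_partition().head()
    """

    def __init__(self, y, genotypes, grouping: MarkerGrouping | None = None,
                 mixture: MixtureSpec | None = None):
        if isinstance(genotypes, StandardizedGenotypes):
            self.data = genotypes
        else:
            self.data = standardize(genotypes)
        self.y = np.asarray(y, dtype=np.float64)
        if len(self.y) != self.data.n_individuals:
            raise ValueError("phenotype length does not match the genotype panel")
        p = self.data.n_markers
        self.grouping = grouping if grouping is not None else MarkerGrouping.single_group(p)
        if len(self.grouping.group_index) != p:
            raise ValueError("grouping does not cover all markers")
        if self.grouping.group_index.min() < 0:
            raise ValueError("grouping leaves markers unassigned")
        self.mixture = mixture if mixture is not None else MixtureSpec()

    @classmethod
    def from_simulation(cls, config, grouping=None):
        """Build model and truth from a :class:`~bayesrrc.simulate.SimConfig`."""
        from .annotate import build_groups, compute_ld_scores
        from .simulate import simulate_dataset

        panel, y, truth, categories = simulate_dataset(config)
        if grouping is None:
            ld = compute_ld_scores(panel)
            grouping = build_groups(categories, panel.realized_maf(), ld)
        model = cls(y, panel, grouping=grouping)
        model.panel = panel
        model.truth = truth
        return model

    @classmethod
    def from_plink(cls, bed_path, pheno_path, groups_path=None, **kwargs):
        """Construct from PLINK bed/bim/fam plus phenotype (and group) files."""
        from .io import read_groups, read_phenotype
        from .plink import read_plink

        panel = read_plink(bed_path)
        y = read_phenotype(pheno_path)
        grouping = None
        if groups_path is not None:
            grouping = read_groups(groups_path, panel.marker_ids)
        model = cls(y, panel, grouping=grouping, **kwargs)
        model.panel = panel
        return model

    # ------------------------------------------------------------------ fit

    def fit(self, config: ChainConfig | None = None, *, use_numba: bool = True,
            **kwargs):
        """Run the Gibbs sampler and return a results object.

        Keyword arguments (``n_iter``, ``burn_in``, ``thin``, ``n_chains``,
        ``seed``, ...) override :class:`ChainConfig` defaults. Chains run
        sequentially from per-chain seeds spawned from ``seed``; the result
        is deterministic given the configuration.
        """
        from .results import BayesRRCResults

        if config is None:
            config = ChainConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either a ChainConfig or keyword overrides, not both")
        chains = []
        for c in range(config.n_chains):
            rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), c]))
            chains.append(self._run_single_chain(c, rng, config, use_numba))
        samples = PosteriorSamples.from_chains(
            chains, self.grouping, self.mixture, self.data.marker_ids, self.data.sds
        )
        return BayesRRCResults(self, samples, config)

    def _run_single_chain(self, chain_id: int, rng, config: ChainConfig,
                          use_numba: bool) -> dict:
        data, y = self.data, self.y
        p, n = data.n_markers, data.n_individuals
        group_of = np.ascontiguousarray(self.grouping.group_index, dtype=np.int64)
        n_groups = self.grouping.n_groups
        consts = np.asarray(self.mixture.constants)
        n_slab = len(consts)
        var_y = y.var()
        s0_group = var_y / (2.0 * n_groups)
        s0_eps = var_y / 2.0
        eps_floor = 1e-6 * max(var_y, 1e-12)
        nu0 = config.nu0
        alpha_vec = np.concatenate([[config.dirichlet_alpha_spike],
                                    np.full(n_slab, config.dirichlet_alpha)])
        sweep = _gibbs.sweep_markers_numba if use_numba else _gibbs.sweep_markers_numpy

        # initial state: sparse mixture proportions (pi_0 = 0.99 with the
        # slab remainder split geometrically towards the small components),
        # matching the sparse regime the model is designed to explore
        mu = float(y.mean())
        beta = np.zeros(p)
        gamma = np.zeros(p, dtype=np.int64)
        sigma2_G = np.full(n_groups, s0_group)
        sigma2_eps = max(0.5 * var_y, eps_floor)
        slab_init = 0.5 ** np.arange(1, n_slab + 1)
        pi = np.tile(np.concatenate([[0.99], 0.01 * slab_init / slab_init.sum()]),
                     (n_groups, 1))
        resid = y - mu

        stored = {
            "mu": [], "sigma2_eps": [], "sigma2_G": [], "pi": [],
            "beta_idx": [], "beta_val": [], "beta_comp": [], "iteration": [],
        }
        t0 = time.perf_counter()
        n_divergent = 0
        for it in range(config.n_iter):
            # intercept (conjugate normal)
            mu_new = rng.normal(mu + resid.mean(), np.sqrt(sigma2_eps / n))
            resid += mu - mu_new
            mu = float(mu_new)

            # marker sweep in a fresh random permutation
            comp_var = sigma2_G[:, None] * consts[None, :]
            with np.errstate(divide="ignore"):
                log_pi = np.log(pi)
            order = rng.permutation(p).astype(np.int64)
            u_comp = rng.random(p)
            z_norm = rng.standard_normal(p)
            sweep(data.xt, data.xx, resid, beta, gamma, group_of, comp_var,
                  log_pi, sigma2_eps, order, u_comp, z_norm)
            if not np.isfinite(resid[0]):
                raise FloatingPointError(
                    f"non-finite residual at iteration {it} (chain {chain_id})"
                )

            # mixture proportions: Dirichlet(alpha + occupancy), spike included
            counts = np.bincount(group_of * (n_slab + 1) + gamma,
                                 minlength=n_groups * (n_slab + 1)
                                 ).reshape(n_groups, n_slab + 1)
            pi = rng.gamma(alpha_vec[None, :] + counts)
            pi /= pi.sum(axis=1, keepdims=True)

            # group variances: scaled inverse chi-square given sum beta^2 / C
            in_model = gamma > 0
            ssq = np.zeros(n_groups)
            if in_model.any():
                contrib = beta[in_model] ** 2 / consts[gamma[in_model] - 1]
                np.add.at(ssq, group_of[in_model], contrib)
            m_g = counts[:, 1:].sum(axis=1)
            sigma2_G = (nu0 * s0_group + ssq) / rng.chisquare(nu0 + m_g)
            if np.any(sigma2_G > 10.0 * var_y):
                n_divergent += 1
                if n_divergent == 1:
                    logger.warning("divergent group variance at iteration %d; "
                                   "prior will pull back (reported once)", it)

            # residual variance
            sigma2_eps = float((nu0 * s0_eps + resid @ resid) / rng.chisquare(nu0 + n))
            sigma2_eps = max(sigma2_eps, eps_floor)

            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                nz = np.flatnonzero(gamma)
                stored["iteration"].append(it)
                stored["mu"].append(mu)
                stored["sigma2_eps"].append(sigma2_eps)
                stored["sigma2_G"].append(sigma2_G.copy())
                stored["pi"].append(pi.copy())
                stored["beta_idx"].append(nz.astype(np.int32))
                stored["beta_val"].append(beta[nz].copy())
                stored["beta_comp"].append(gamma[nz].astype(np.int8))
        stored["chain_id"] = chain_id
        stored["runtime_s"] = time.perf_counter() - t0
        stored["final_resid"] = resid.copy()
        stored["final_beta"] = beta.copy()
        stored["final_mu"] = mu
        return stored

    def recompute_residual(self, beta: np.ndarray, mu: float) -> np.ndarray:
        """Residual rebuilt from scratch, for bookkeeping checks."""
        nz = np.flatnonzero(beta)
        fitted = np.zeros(self.data.n_individuals)
        for j in nz:
            fitted += self.data.xt[j].astype(np.float64) * beta[j]
        return self.y - mu - fitted
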