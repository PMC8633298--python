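"""Genotype-phenotype simulation with known truth.

Generates LD-blocked hard-called genotypes over a configurable MAF spectrum,
selects causal markers (at random among LD-independent markers, or the
highest-MAF marker per LD block), samples effect sizes whose prior variance
scales as ``w**a * (p*(1-p))**b`` (``w`` the LD score, ``p`` the minor allele
frequency), partitions genetic variance across annotation categories in the
"enriched" setting, and builds phenotypes with optional two-population
stratification and family common-environment effects.

Genotypes are produced by thresholding a latent Gaussian with exchangeable
within-block correlation at MAF-derived quantiles, independently for two
haplotypes, which gives tunable LD and exact Hardy-Weinberg proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotate import ENRICHED_H2_SHARES

__all__ = [
    "SimConfig",
    "SimTruth",
    "GenotypePanel",
    "simulate_genotypes",
    "simulate_structured_genotypes",
    "select_causal_markers",
    "sample_effect_sizes",
    "build_phenotype",
    "simulate_dataset",
]


@dataclass
class GenotypePanel:
    """Hard-called 0/1/2 genotypes with per-marker metadata.

    ``genotypes`` is an N x p int8 matrix (-1 encodes missing). ``positions``
    are 0-based base-pair coordinates; ``maf`` is the realized minor allele
    frequency; ``block`` the LD-block index each marker was generated in
    (-1 when unknown, e.g. data read from disk).
    """

    genotypes: np.ndarray
    marker_ids: np.ndarray
    positions: np.ndarray
    chromosomes: np.ndarray
    maf: np.ndarray
    block: np.ndarray

    def __post_init__(self) -> None:
        n, p = self.genotypes.shape
        for name in ("marker_ids", "positions", "chromosomes", "maf", "block"):
            if len(getattr(self, name)) != p:
                raise ValueError(f"{name} length {len(getattr(self, name))} != p={p}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def realized_maf(self) -> np.ndarray:
        """Minor allele frequency from the genotype calls, ignoring missing."""
        g = np.ma.masked_equal(self.genotypes, -1)
        freq = g.mean(axis=0).filled(0.0) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated genetic architecture.

    Defaults follow the simulation design the package is validated against:
    unit-variance phenotypes, LD blocks of 10 markers, MAF-dependent effect
    sizes with exponent -0.25, and the enriched setting partitioning h2 over
    the 13 annotation categories with shares (1/6 exon, 1/3 intron, 1/12
    promoter, 1/24 each for 1-10kb enh/tfbs, 1/12 each for distal enh/tfbs,
    0 elsewhere).
    """

    n_individuals: int = 5000
    n_markers: int = 5000
    maf_range: tuple[float, float] = (0.01, 0.5)
    ld_block_size: int = 10
    within_block_corr: float = 0.7
    n_causal: int = 50
    causal_mode: str = "random"  # or "high_maf_per_block"
    ld_r2_threshold: float = 0.1
    effect_exponents: tuple[float, float] = (0.0, -0.25)  # (a, b) on (w, p(1-p))
    h2: float = 0.6
    enrichment_setting: str = "random"  # or "enriched"
    group_h2_shares: dict = field(default_factory=lambda: dict(ENRICHED_H2_SHARES))
    bp_per_marker: int = 2500
    fst: float = 0.0
    pop_mean_shift: float = 0.0
    n_families: int = 0
    common_env_var: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.within_block_corr < 1.0):
            raise ValueError("within_block_corr must be in [0, 1)")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must be in [0, 1]")
        if not (0.0 <= self.common_env_var < 1.0):
            raise ValueError("common_env_var must be in [0, 1)")
        if self.h2 + self.common_env_var >= 1.0 + 1e-12 and (self.h2 + self.common_env_var) != 1.0:
            if self.h2 + self.common_env_var > 1.0:
                raise ValueError("h2 + common_env_var must be < 1")
        if self.n_causal > self.n_markers:
            raise ValueError("n_causal cannot exceed n_markers")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must be in [0, 1)")
        if self.causal_mode not in ("random", "high_maf_per_block"):
            raise ValueError(f"unknown causal_mode {self.causal_mode!r}")
        if self.enrichment_setting not in ("random", "enriched"):
            raise ValueError(f"unknown enrichment_setting {self.enrichment_setting!r}")
        if self.enrichment_setting == "enriched":
            total = sum(self.group_h2_shares.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"group_h2_shares must sum to 1, got {total}")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset (standardized-marker scale)."""

    causal_indices: np.ndarray
    true_effects: np.ndarray
    true_group_variances: dict
    genetic_values: np.ndarray
    variance_components: dict
    population_labels: np.ndarray | None = None
    family_labels: np.ndarray | None = None
    categories: np.ndarray | None = None

    def to_frame(self, marker_ids: np.ndarray) -> pd.DataFrame:
        causal = np.zeros(len(self.true_effects), dtype=bool)
        causal[self.causal_indices] = True
        cats = self.categories if self.categories is not None else np.full(len(causal), ".")
        return pd.DataFrame(
            {
                "marker_id": marker_ids,
                "category": cats,
                "true_beta": self.true_effects,
                "causal": causal.astype(int),
            }
        )


def _threshold_haplotypes(latent1, latent2, maf):
    """Two latent Gaussian haplotypes -> 0/1/2 genotype by MAF quantile cut."""
    cut = norm.ppf(1.0 - maf)  # per-marker threshold: P(latent > cut) = maf
    return (latent1 > cut).astype(np.int8) + (latent2 > cut).astype(np.int8)


def _block_latent(rng, n, sizes, rho):
    """Latent Gaussian with exchangeable correlation rho inside each block."""
    p = int(np.sum(sizes))
    out = np.empty((n, p))
    col = 0
    sq_shared = np.sqrt(rho)
    sq_own = np.sqrt(1.0 - rho)
    for size in sizes:
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, size))
        out[:, col : col + size] = sq_shared * shared + sq_own * own
        col += size
    return out


def _block_sizes(n_markers: int, block_size: int) -> np.ndarray:
    n_full, rem = divmod(n_markers, block_size)
    sizes = [block_size] * n_full + ([rem] if rem else [])
    return np.asarray(sizes, dtype=int)


def _panel_from_genotypes(g, maf, config, chrom=1):
    p = config.n_markers
    sizes = _block_sizes(p, config.ld_block_size)
    block = np.repeat(np.arange(len(sizes)), sizes)
    positions = np.arange(p, dtype=np.int64) * config.bp_per_marker
    return GenotypePanel(
        genotypes=g,
        marker_ids=np.array([f"snp{j}" for j in range(p)]),
        positions=positions,
        chromosomes=np.full(p, chrom, dtype=np.int64),
        maf=maf,
        block=block,
    )


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Simulate an LD-blocked 0/1/2 genotype panel.

    Markers come in consecutive blocks of ``ld_block_size`` with exchangeable
    latent correlation ``within_block_corr`` within a block and independence
    across blocks. Per-marker MAFs are drawn uniformly over ``maf_range``.
    Deterministic given ``config.seed``.
    """
    rng = config.rng(1)
    n, p = config.n_individuals, config.n_markers
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)
    sizes = _block_sizes(p, config.ld_block_size)
    h1 = _block_latent(rng, n, sizes, config.within_block_corr)
    h2 = _block_latent(rng, n, sizes, config.within_block_corr)
    g = _threshold_haplotypes(h1, h2, maf)
    return _panel_from_genotypes(g, maf, config)


def simulate_structured_genotypes(config: SimConfig):
    """Two-population panel under a Balding-Nichols allele-frequency model.

    Subpopulation allele frequencies are Beta-distributed around an ancestral
    frequency with variance ``fst * p * (1 - p)``. Returns the panel and a
    0/1 population label per individual (population sizes N/2 each).
    """
    if not (0.0 < config.fst < 1.0):
        raise ValueError("simulate_structured_genotypes requires 0 < fst < 1")
    rng = config.rng(2)
    n, p = config.n_individuals, config.n_markers
    anc = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)
    shape = (1.0 - config.fst) / config.fst
    sub_freq = np.empty((2, p))
    for k in range(2):
        sub_freq[k] = rng.beta(anc * shape, (1.0 - anc) * shape)
    sub_freq = np.clip(sub_freq, 1e-4, 1 - 1e-4)

    sizes = _block_sizes(p, config.ld_block_size)
    n0 = n // 2
    labels = np.zeros(n, dtype=int)
    labels[n0:] = 1
    g = np.empty((n, p), dtype=np.int8)
    for k, (lo, hi) in enumerate([(0, n0), (n0, n)]):
        nk = hi - lo
        h1 = _block_latent(rng, nk, sizes, config.within_block_corr)
        h2 = _block_latent(rng, nk, sizes, config.within_block_corr)
        g[lo:hi] = _threshold_haplotypes(h1, h2, sub_freq[k])
    freq = g.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    panel = _panel_from_genotypes(g, maf, config)
    return panel, labels


def _empirical_block_r2(panel: GenotypePanel, block_idx: np.ndarray) -> np.ndarray:
    g = panel.genotypes[:, block_idx].astype(float)
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    corr = (g / sd).T @ (g / sd) / g.shape[0]
    return corr**2


def select_causal_markers(panel: GenotypePanel, config: SimConfig) -> np.ndarray:
    """Pick the causal marker set.

    random mode: a random LD-independent subset — markers are visited in
    random order and accepted only if their empirical R^2 with every already
    accepted marker in the same LD block stays below ``ld_r2_threshold``
    (cross-block correlation is zero by construction).

    high_maf_per_block mode: ``n_causal`` blocks are chosen at random and the
    highest-MAF marker of each contributes, so no two causal markers share a
    block.
    """
    rng = config.rng(3)
    m = config.n_causal
    if m == 0:
        return np.empty(0, dtype=int)
    if config.causal_mode == "high_maf_per_block":
        blocks = np.unique(panel.block)
        if len(blocks) < m:
            raise ValueError(
                f"high_maf_per_block needs >= n_causal blocks: {len(blocks)} < {m}"
            )
        chosen_blocks = rng.choice(blocks, size=m, replace=False)
        maf = panel.realized_maf()
        picks = []
        for b in chosen_blocks:
            members = np.flatnonzero(panel.block == b)
            picks.append(members[np.argmax(maf[members])])
        return np.sort(np.asarray(picks, dtype=int))

    order = rng.permutation(panel.n_markers)
    accepted: list[int] = []
    accepted_by_block: dict[int, list[int]] = {}
    r2_cache: dict[int, np.ndarray] = {}
    for j in order:
        b = int(panel.block[j])
        peers = accepted_by_block.get(b, [])
        if peers:
            if b not in r2_cache:
                members = np.flatnonzero(panel.block == b)
                r2_cache[b] = _empirical_block_r2(panel, members)
                r2_cache[f"_idx{b}"] = {int(g): i for i, g in enumerate(members)}
            idx = r2_cache[f"_idx{b}"]
            r2 = r2_cache[b]
            if any(r2[idx[j], idx[k]] >= config.ld_r2_threshold for k in peers):
                continue
        accepted.append(int(j))
        accepted_by_block.setdefault(b, []).append(int(j))
        if len(accepted) == m:
            return np.sort(np.asarray(accepted, dtype=int))
    raise ValueError(
        f"could only place {len(accepted)} of {m} LD-independent causal markers"
    )


def sample_effect_sizes(
    mafs: np.ndarray,
    ld_scores: np.ndarray,
    causal: np.ndarray,
    config: SimConfig,
    categories: np.ndarray | None = None,
) -> np.ndarray:
    """Draw standardized-marker effect sizes for the causal set.

    beta_j ~ N(0, c * w_j**a * (p_j (1-p_j))**b) for causal j and 0 otherwise.
    The overall constant c is fixed by the h2 rescaling done in
    :func:`build_phenotype`; here the relative weights are what matter. In the
    enriched setting the per-category standard deviations are pre-scaled so
    the expected per-category variance budget follows ``group_h2_shares``
    before the MAF/LD weighting.
    """
    rng = config.rng(4)
    p = len(mafs)
    beta = np.zeros(p)
    causal = np.asarray(causal, dtype=int)
    if len(causal) == 0:
        if config.h2 > 0:
            raise ValueError("h2 > 0 requires a non-empty causal set")
        return beta
    if config.h2 == 0:
        return beta
    a, b = config.effect_exponents
    w = np.asarray(ld_scores, dtype=float)[causal]
    if np.any(w < 1.0 - 1e-9):
        raise ValueError("ld_scores must be >= 1 (self-score included)")
    pq = mafs[causal] * (1.0 - mafs[causal])
    var = np.power(w, a) * np.power(pq, b)
    raw = rng.standard_normal(len(causal)) * np.sqrt(var)

    if config.enrichment_setting == "enriched":
        if categories is None:
            raise ValueError("enriched setting requires per-marker categories")
        cats = np.asarray(categories)[causal]
        for cat in np.unique(cats):
            members = cats == cat
            share = config.group_h2_shares.get(cat, 0.0)
            if share == 0.0:
                raw[members] = 0.0
                continue
            # expected variance contributed by this category under unit total
            ev = np.sum(var[members])
            raw[members] *= np.sqrt(share / ev * np.sum(var))
    beta[causal] = raw
    return beta


def build_phenotype(
    panel: GenotypePanel,
    effects: np.ndarray,
    config: SimConfig,
    population_labels: np.ndarray | None = None,
    categories: np.ndarray | None = None,
):
    """Assemble the phenotype and the ground-truth record.

    y = g + population mean shift + family common environment + residual,
    finally standardized to zero mean, unit variance. The genetic values are
    rescaled so Var(g) = h2 exactly (the rescaling factor is folded into the
    returned true effects); per-replicate realized variance therefore matches
    the configured h2 rather than fluctuating around it.
    """
    if len(effects) != panel.n_markers:
        raise ValueError("effects length must equal the number of markers")
    rng = config.rng(5)
    n = panel.n_individuals
    strat_var = 0.0
    if population_labels is not None and config.pop_mean_shift != 0.0:
        frac = population_labels.mean()
        strat_var = config.pop_mean_shift**2 * frac * (1 - frac)
    total = config.h2 + config.common_env_var + strat_var
    if total > 1.0 + 1e-9:
        raise ValueError(f"variance components sum to {total} > 1")

    effects = np.asarray(effects, dtype=float).copy()
    causal = np.flatnonzero(effects)
    if len(causal) and config.h2 > 0:
        x = standardize_columns(panel, causal)
        g = x @ effects[causal]
        scale = np.sqrt(config.h2 / g.var())
        g *= scale
        effects[causal] *= scale
    else:
        g = np.zeros(n)

    y = g.copy()
    if population_labels is not None and config.pop_mean_shift != 0.0:
        y = y + config.pop_mean_shift * (population_labels - population_labels.mean())

    family = None
    if config.n_families > 0 and config.common_env_var > 0.0:
        family = rng.integers(0, config.n_families, size=n)
        fam_eff = rng.normal(0.0, np.sqrt(config.common_env_var), size=config.n_families)
        y = y + fam_eff[family]

    resid_var = max(1.0 - total, 0.0)
    if resid_var > 0:
        y = y + rng.normal(0.0, np.sqrt(resid_var), size=n)
    sd = y.std()
    y = (y - y.mean()) / (sd if sd > 0 else 1.0)

    group_var: dict[str, float] = {}
    if categories is not None and len(causal):
        for cat in np.unique(np.asarray(categories)[causal]):
            members = causal[np.asarray(categories)[causal] == cat]
            xg = standardize_columns(panel, members)
            group_var[str(cat)] = float((xg @ effects[members]).var())
    truth = SimTruth(
        causal_indices=causal,
        true_effects=effects,
        true_group_variances=group_var,
        genetic_values=g,
        variance_components={
            "h2": config.h2,
            "common_env": config.common_env_var,
            "stratification": strat_var,
            "residual": resid_var,
        },
        population_labels=population_labels,
        family_labels=family,
        categories=None if categories is None else np.asarray(categories),
    )
    return y, truth


def standardize_columns(panel: GenotypePanel, cols: np.ndarray) -> np.ndarray:
    """Mean-imputed, zero-mean, unit-variance genotype columns (float64)."""
    g = panel.genotypes[:, cols].astype(float)
    miss = g < 0
    if miss.any():
        g[miss] = np.nan
        g = np.where(np.isnan(g), np.nanmean(g, axis=0), g)
    mu = g.mean(axis=0)
    sd = g.std(axis=0)
    if np.any(sd == 0):
        bad = np.asarray(cols)[sd == 0]
        raise ValueError(f"monomorphic markers cannot be standardized: {bad.tolist()}")
    return (g - mu) / sd


def simulate_dataset(config: SimConfig, categories: np.ndarray | None = None):
    """One-call simulation: panel, phenotype, truth (and categories used).

    When ``categories`` is omitted they are assigned to contiguous marker
    index ranges in proportion to a default 13-category layout (see
    :func:`bayesrrc.annotate.default_category_layout`).
    """
    from .annotate import compute_ld_scores, default_category_layout

    if config.fst > 0:
        panel, labels = simulate_structured_genotypes(config)
    else:
        panel = simulate_genotypes(config)
        labels = None
    if categories is None:
        categories = default_category_layout(panel.n_markers)
    causal = select_causal_markers(panel, config)
    ld = compute_ld_scores(panel)
    beta = sample_effect_sizes(panel.realized_maf(), ld, causal, config, categories)
    y, truth = build_phenotype(panel, beta, config, labels, categories)
    return panel, y, truth, categories
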