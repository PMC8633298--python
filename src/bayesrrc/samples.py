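"""Posterior sample container and convergence diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["PosteriorSamples", "split_rhat", "convergence_diagnostics"]


class PosteriorSamples:
    """Thinned post-burn-in Gibbs draws.

    Marker effects are stored sparsely (most draws put most markers in the
    spike): ``beta_idx`` / ``beta_val`` / ``beta_comp`` are flat arrays over
    all draws, delimited by ``indptr`` (draw d owns the slice
    ``indptr[d]:indptr[d+1]``). Hyperparameter draws live in dense arrays
    aligned with the same draw order; ``chain`` and ``iteration`` identify
    each draw's origin.
    """

    def __init__(self, chain, iteration, mu, sigma2_eps, sigma2_G, pi,
                 beta_idx, beta_val, beta_comp, indptr,
                 grouping=None, mixture=None, marker_ids=None, marker_sds=None):
        self.chain = np.asarray(chain)
        self.iteration = np.asarray(iteration)
        self.mu = np.asarray(mu)
        self.sigma2_eps = np.asarray(sigma2_eps)
        self.sigma2_G = np.asarray(sigma2_G)
        self.pi = np.asarray(pi)
        self.beta_idx = np.asarray(beta_idx, dtype=np.int32)
        self.beta_val = np.asarray(beta_val, dtype=np.float64)
        self.beta_comp = np.asarray(beta_comp, dtype=np.int8)
        self.indptr = np.asarray(indptr, dtype=np.int64)
        self.grouping = grouping
        self.mixture = mixture
        self.marker_ids = None if marker_ids is None else np.asarray(marker_ids)
        self.marker_sds = None if marker_sds is None else np.asarray(marker_sds)
        if len(self.indptr) != self.n_draws + 1:
            raise ValueError("indptr length must be n_draws + 1")

    # ------------------------------------------------------------ basics

    @property
    def n_draws(self) -> int:
        return len(self.sigma2_eps)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids) if self.marker_ids is not None else int(self.beta_idx.max(initial=-1)) + 1

    @property
    def n_groups(self) -> int:
        return self.sigma2_G.shape[1]

    @property
    def chain_ids(self) -> np.ndarray:
        return np.unique(self.chain)

    def draw_effects(self, d: int):
        """(marker indices, effects, components) of draw ``d``."""
        s, e = self.indptr[d], self.indptr[d + 1]
        return self.beta_idx[s:e], self.beta_val[s:e], self.beta_comp[s:e]

    def beta_matrix(self) -> np.ndarray:
        """Dense (n_draws, p) effect matrix — small problems only."""
        out = np.zeros((self.n_draws, self.n_markers))
        for d in range(self.n_draws):
            idx, val, _ = self.draw_effects(d)
            out[d, idx] = val
        return out

    def beta_mean(self) -> np.ndarray:
        """Posterior mean effect per marker (zeros included)."""
        out = np.zeros(self.n_markers)
        np.add.at(out, self.beta_idx, self.beta_val)
        return out / self.n_draws

    def hyperparameters(self) -> pd.DataFrame:
        """Flat table of hyperparameter draws (one row per draw)."""
        cols = {"chain": self.chain, "iteration": self.iteration, "mu": self.mu,
                "sigma2_eps": self.sigma2_eps}
        cols.update({f"sigma2_G{g}": self.sigma2_G[:, g]
                     for g in range(self.n_groups)})
        cols.update({f"pi_g{g}_c{l}": self.pi[:, g, l]
                     for g in range(self.n_groups)
                     for l in range(self.pi.shape[2])})
        return pd.DataFrame(cols)

    # ------------------------------------------------------------ assembly

    @classmethod
    def from_chains(cls, chains, grouping, mixture, marker_ids, marker_sds):
        chain_col, iteration, mu, s2e, s2g, pi = [], [], [], [], [], []
        bidx, bval, bcomp = [], [], []
        for ch in chains:
            k = len(ch["iteration"])
            chain_col.extend([ch["chain_id"]] * k)
            iteration.extend(ch["iteration"])
            mu.extend(ch["mu"])
            s2e.extend(ch["sigma2_eps"])
            s2g.extend(ch["sigma2_G"])
            pi.extend(ch["pi"])
            bidx.extend(ch["beta_idx"])
            bval.extend(ch["beta_val"])
            bcomp.extend(ch["beta_comp"])
        if not iteration:
            raise ValueError("no stored draws: check n_iter / burn_in / thin")
        lengths = np.array([len(a) for a in bidx], dtype=np.int64)
        indptr = np.concatenate([[0], np.cumsum(lengths)])
        cat = lambda parts, dt: (np.concatenate(parts) if lengths.sum() else np.empty(0, dt))
        return cls(
            chain_col, iteration, mu, s2e, np.asarray(s2g), np.asarray(pi),
            cat(bidx, np.int32), cat(bval, np.float64), cat(bcomp, np.int8), indptr,
            grouping=grouping, mixture=mixture, marker_ids=marker_ids,
            marker_sds=marker_sds,
        )

    # ------------------------------------------------------------ storage

    def save(self, path) -> None:
        """Write the container to HDF5."""
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("chain", "iteration", "mu", "sigma2_eps", "sigma2_G",
                         "pi", "beta_idx", "beta_val", "beta_comp", "indptr"):
                f.create_dataset(name, data=getattr(self, name))
            if self.marker_ids is not None:
                f.create_dataset("marker_ids", data=self.marker_ids.astype("S"))
            if self.marker_sds is not None:
                f.create_dataset("marker_sds", data=self.marker_sds)
            if self.mixture is not None:
                f.attrs["mixture_constants"] = list(self.mixture.constants)
            if self.grouping is not None:
                f.create_dataset("group_index", data=self.grouping.group_index)

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        import h5py

        from .annotate import MarkerGrouping
        from .model import MixtureSpec

        with h5py.File(path, "r") as f:
            kw = {name: f[name][...] for name in
                  ("chain", "iteration", "mu", "sigma2_eps", "sigma2_G",
                   "pi", "beta_idx", "beta_val", "beta_comp", "indptr")}
            marker_ids = f["marker_ids"][...].astype(str) if "marker_ids" in f else None
            marker_sds = f["marker_sds"][...] if "marker_sds" in f else None
            mixture = (MixtureSpec(tuple(f.attrs["mixture_constants"]))
                       if "mixture_constants" in f.attrs else None)
            grouping = None
            if "group_index" in f:
                gi = f["group_index"][...]
                g = MarkerGrouping.single_group(len(gi))
                g.group_index = gi
                g.group_labels = [("g", "g", "g")] * (int(gi.max()) + 1)
                grouping = g
        return cls(marker_ids=marker_ids, marker_sds=marker_sds,
                   mixture=mixture, grouping=grouping, **kw)


def split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``draws`` is (n_chains, n_iterations); each chain is split in half and
    the classic between/within variance ratio is computed over the halves.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    n = draws.shape[1] // 2
    halves = np.concatenate([draws[:, :n], draws[:, n : 2 * n]], axis=0)
    m = halves.shape[0]
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def convergence_diagnostics(samples: PosteriorSamples, flag_threshold: float = 1.1) -> pd.DataFrame:
    """Split-R-hat and effective sample size for the variance parameters.

    Covers sigma2_eps, every group variance, and the genome-wide h2 proxy
    (total sigma2_G). R-hat needs >= 2 chains and is NaN otherwise; ESS
    (via arviz) is always reported. Parameters with R-hat above
    ``flag_threshold`` are flagged.
    """
    import arviz as az

    chains = samples.chain_ids
    per_chain = [samples.chain == c for c in chains]
    n_min = min(int(m.sum()) for m in per_chain)

    def stack(values: np.ndarray) -> np.ndarray:
        return np.stack([values[m][:n_min] for m in per_chain])

    params = {"sigma2_eps": samples.sigma2_eps,
              "h2_total": samples.sigma2_G.sum(axis=1)}
    for g in range(samples.n_groups):
        params[f"sigma2_G{g}"] = samples.sigma2_G[:, g]

    rows = []
    for name, values in params.items():
        arr = stack(values)
        rhat = split_rhat(arr) if len(chains) >= 2 else np.nan
        ess = float(az.ess(arr))
        rows.append({"parameter": name, "rhat": rhat, "ess": ess,
                     "flagged": bool(rhat > flag_threshold) if np.isfinite(rhat) else False})
    return pd.DataFrame(rows)
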