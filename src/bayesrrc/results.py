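"""Posterior inference: heritability partition, enrichment, PPWV, fine-mapping.

All quantities are computed per retained draw and summarised as posterior
means with equal-tail credible intervals. Region variance follows the
summed-squared-coefficient convention: at each iteration the variance a
region contributes is the sum of squared standardized effects of its in-model
markers, and its share divides by the total over all markers that iteration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotate import RegionSet
from .samples import PosteriorSamples, convergence_diagnostics

__all__ = ["BayesRRCResults", "region_variance_shares", "ppwv", "evaluate_calls"]


class BayesRRCResults:
    """Fitted grouped spike-and-slab regression.

    Wraps the posterior draws with the summaries used for inference:
    per-group SNP heritability, enrichment, marker inclusion probabilities,
    region variance shares and PPWV calls, credible sets, allele-scale
    effects, and posterior-predictive prediction for new cohorts.
    """

    def __init__(self, model, samples: PosteriorSamples, config):
        self.model = model
        self.samples = samples
        self.config = config

    # ------------------------------------------------------- heritability

    def h2_draws(self, basis: str = "beta") -> np.ndarray:
        """Genome-wide h2 per draw.

        basis "beta": realized sum of squared standardized effects (primary);
        basis "sigma2G": sum of the sampled group variances (secondary).
        """
        s = self.samples
        if basis == "sigma2G":
            return s.sigma2_G.sum(axis=1)
        out = np.zeros(s.n_draws)
        np.add.at(out, np.repeat(np.arange(s.n_draws), np.diff(s.indptr)),
                  s.beta_val**2)
        return out

    def variance_partition(self, by: str = "group") -> pd.DataFrame:
        """Posterior of the variance attributable to each marker group.

        ``by`` is "group" (dense group index), "category" (the 13 location/
        functional classes) or "component" (slab mixture component). Shares
        are computed per draw as sum(beta^2) within the unit, reported with
        the sigma2_G-draw counterpart where applicable.
        """
        s = self.samples
        draw_of = np.repeat(np.arange(s.n_draws), np.diff(s.indptr))
        if by == "component":
            keys = s.beta_comp.astype(int) - 1
            names = [f"C{c}" for c in self.model.mixture.constants]
        elif by == "category":
            cats = np.asarray(s.grouping.category)
            uniq = list(dict.fromkeys(cats))  # preserve order
            lookup = {c: i for i, c in enumerate(uniq)}
            keys = np.array([lookup[c] for c in cats[s.beta_idx]], dtype=int)
            names = uniq
        elif by == "group":
            keys = s.grouping.group_index[s.beta_idx]
            names = [f"{c}|{m}|{l}" for c, m, l in s.grouping.group_labels]
        else:
            raise ValueError(f"unknown by={by!r}")
        k = len(names)
        per_draw = np.zeros((s.n_draws, k))
        np.add.at(per_draw, (draw_of, keys), s.beta_val**2)
        rows = []
        for i, name in enumerate(names):
            d = per_draw[:, i]
            row = {"unit": name, "mean": d.mean(),
                   "ci_low": np.quantile(d, 0.025), "ci_high": np.quantile(d, 0.975)}
            if by == "group":
                # median: the inverse-chi-square draws of near-empty groups
                # are heavy-tailed and make the mean unrepresentative
                row["sigma2_G_median"] = np.median(s.sigma2_G[:, i])
            rows.append(row)
        total = per_draw.sum(axis=1)
        rows.append({"unit": "total", "mean": total.mean(),
                     "ci_low": np.quantile(total, 0.025),
                     "ci_high": np.quantile(total, 0.975),
                     **({"sigma2_G_median": float(np.median(s.sigma2_G.sum(axis=1)))}
                        if by == "group" else {})})
        return pd.DataFrame(rows)

    def per_draw_category_shares(self) -> tuple[list, np.ndarray]:
        """Per-draw share of total sum(beta^2) by annotation category."""
        s = self.samples
        draw_of = np.repeat(np.arange(s.n_draws), np.diff(s.indptr))
        cats = np.asarray(s.grouping.category)
        uniq = list(dict.fromkeys(cats))
        lookup = {c: i for i, c in enumerate(uniq)}
        keys = np.array([lookup[c] for c in cats[s.beta_idx]], dtype=int) if len(s.beta_idx) else np.empty(0, int)
        per_draw = np.zeros((s.n_draws, len(uniq)))
        if len(keys):
            np.add.at(per_draw, (draw_of, keys), s.beta_val**2)
        total = per_draw.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return uniq, per_draw / total

    # --------------------------------------------------------- enrichment

    def enrichment(self, by: str = "category") -> pd.DataFrame:
        """Sparse-model enrichment posterior per annotation unit.

        Per draw: (unit share of sum beta^2) / (unit share of in-model marker
        count). The classical definition (denominator = unit share of all
        markers) is reported alongside. Draws with zero in-model markers are
        skipped and counted.
        """
        s = self.samples
        draw_of = np.repeat(np.arange(s.n_draws), np.diff(s.indptr))
        if by == "category":
            labels = np.asarray(s.grouping.category)
        elif by == "group":
            labels = np.array([f"{c}|{m}|{l}" for c, m, l in
                               np.asarray(s.grouping.group_labels)[s.grouping.group_index]])
        else:
            raise ValueError(f"unknown by={by!r}")
        uniq = list(dict.fromkeys(labels))
        lookup = {c: i for i, c in enumerate(uniq)}
        keys = np.array([lookup[c] for c in labels[s.beta_idx]], dtype=int) if len(s.beta_idx) else np.empty(0, int)
        k = len(uniq)

        var_draw = np.zeros((s.n_draws, k))
        cnt_draw = np.zeros((s.n_draws, k))
        if len(keys):
            np.add.at(var_draw, (draw_of, keys), s.beta_val**2)
            np.add.at(cnt_draw, (draw_of, keys), 1.0)
        tot_var = var_draw.sum(axis=1)
        tot_cnt = cnt_draw.sum(axis=1)
        ok = (tot_var > 0) & (tot_cnt > 0)
        n_skipped = int((~ok).sum())

        marker_share = np.array([np.mean(labels == u) for u in uniq])
        rows = []
        for i, u in enumerate(uniq):
            with np.errstate(divide="ignore", invalid="ignore"):
                vshare = var_draw[ok, i] / tot_var[ok]
                mshare = cnt_draw[ok, i] / tot_cnt[ok]
                enr = np.where(mshare > 0, vshare / np.where(mshare > 0, mshare, 1.0), np.nan)
                enr_classic = vshare / marker_share[i]
            enr = enr[np.isfinite(enr)]
            rows.append({
                "unit": u,
                "enrichment_mean": enr.mean() if len(enr) else np.nan,
                "enrichment_ci_low": np.quantile(enr, 0.025) if len(enr) else np.nan,
                "enrichment_ci_high": np.quantile(enr, 0.975) if len(enr) else np.nan,
                "classic_enrichment_mean": np.nanmean(enr_classic) if ok.any() else np.nan,
                "marker_share": marker_share[i],
                "draws_skipped": n_skipped,
            })
        return pd.DataFrame(rows)

    # ---------------------------------------------------------------- PIP

    def pip(self, pooled: bool = True, level: float | None = None):
        """Posterior inclusion probability per marker.

        ``pooled=True`` concatenates all chains; otherwise a (n_chains, p)
        matrix of per-chain PIPs is returned. When ``level`` is given, also
        returns the boolean all-chains flag (per-chain PIP exceeds ``level``
        in every chain).
        """
        s = self.samples
        p = s.n_markers
        draw_of = np.repeat(np.arange(s.n_draws), np.diff(s.indptr))
        chains = s.chain_ids
        per_chain = np.zeros((len(chains), p))
        for ci, c in enumerate(chains):
            in_chain = (s.chain == c)[draw_of]
            cnt = np.bincount(s.beta_idx[in_chain], minlength=p)
            per_chain[ci] = cnt / max(int((s.chain == c).sum()), 1)
        pooled_pip = np.bincount(s.beta_idx, minlength=p) / s.n_draws
        if level is not None:
            return pooled_pip, (per_chain > level).all(axis=0)
        return pooled_pip if pooled else per_chain

    # ------------------------------------------------------------- regions

    def region_shares(self, regions: RegionSet, base: str = "snp") -> np.ndarray:
        """(n_draws, n_regions) per-iteration region variance shares."""
        return region_variance_shares(self.samples, regions, base=base)

    def ppwv(self, regions: RegionSet, theta: float = 1e-5,
             levels=(0.8, 0.9, 0.95), base: str = "snp") -> pd.DataFrame:
        """Posterior probability of window variance per region."""
        shares = self.region_shares(regions, base=base)
        return ppwv(shares, regions, theta=theta, levels=levels)

    def credible_set(self, regions: RegionSet, region_id: str,
                     purity_r2: float = 0.9) -> pd.DataFrame:
        """Purity-pruned credible set within an associated region.

        Keeps the connected component (edges: pairwise R^2 >= ``purity_r2``)
        containing the region's top-PIP marker; if no pair meets the purity
        bound the set is that single marker. Members are reported with PIPs.
        """
        from .simulate import standardize_columns

        idx = regions.region_ids.index(region_id)
        members = np.asarray(regions.members[idx], dtype=int)
        pip = self.pip()[members]
        top = members[np.argmax(pip)]
        if len(members) == 1:
            keep = members
        else:
            panel = getattr(self.model, "panel", None)
            if panel is None:
                raise ValueError("credible sets need the genotype panel on the model")
            x = standardize_columns(panel, members)
            r2 = (x.T @ x / x.shape[0]) ** 2
            adj = r2 >= purity_r2
            # connected component containing the top-PIP marker
            pos = {m: i for i, m in enumerate(members)}
            seen = {pos[top]}
            frontier = [pos[top]]
            while frontier:
                i = frontier.pop()
                for k in np.flatnonzero(adj[i]):
                    if k not in seen:
                        seen.add(int(k))
                        frontier.append(int(k))
            keep = members[sorted(seen)]
        full_pip = self.pip()
        return pd.DataFrame({"marker": keep,
                             "marker_id": self.samples.marker_ids[keep],
                             "pip": full_pip[keep],
                             "is_top": keep == top}).sort_values(
                                 "pip", ascending=False, ignore_index=True)

    # ------------------------------------------------------------- effects

    def allele_effects(self) -> pd.DataFrame:
        """Posterior mean effects on the allele-substitution scale.

        Standardized effects divided by each marker's 0/1/2 genotype SD.
        """
        s = self.samples
        mean_std = s.beta_mean()
        return pd.DataFrame({
            "marker_id": s.marker_ids,
            "beta_std": mean_std,
            "beta_allele": mean_std / s.marker_sds,
            "pip": self.pip(),
        })

    # ---------------------------------------------------------- prediction

    def predict(self, new_panel, marker_subset=None):
        """Posterior predictive genetic values for a new cohort."""
        from .predict import posterior_predictive

        return posterior_predictive(self.samples, new_panel,
                                    self.model.data, marker_subset=marker_subset)

    # ------------------------------------------------------------- summary

    def diagnostics(self) -> pd.DataFrame:
        return convergence_diagnostics(self.samples)

    def summary(self) -> str:
        """Plain-text overview of the fit."""
        s = self.samples
        h2 = self.h2_draws()
        vp = self.variance_partition("category")
        lines = [
            "Grouped spike-and-slab whole-genome regression (BayesRR-RC)",
            "=" * 59,
            f"draws: {s.n_draws}  chains: {len(s.chain_ids)}  markers: {s.n_markers}  groups: {s.n_groups}",
            f"h2 (sum beta^2):   {h2.mean():.4f}  [{np.quantile(h2, 0.025):.4f}, {np.quantile(h2, 0.975):.4f}]",
            f"sigma2_eps:        {s.sigma2_eps.mean():.4f}",
            f"in-model markers per draw (mean): {np.diff(s.indptr).mean():.1f}",
            "",
            "Variance by annotation category:",
        ]
        for _, row in vp.iterrows():
            lines.append(f"  {row['unit']:<16} {row['mean']:.4f}  "
                         f"[{row['ci_low']:.4f}, {row['ci_high']:.4f}]")
        return "\n".join(lines)


def region_variance_shares(samples: PosteriorSamples, regions: RegionSet,
                           base: str = "snp") -> np.ndarray:
    """Per-draw, per-region variance shares.

    Region variance at one iteration is the sum of squared in-model
    standardized effects of the region's markers. base "snp" divides by the
    total sum(beta^2) of that iteration (share of the variance attributed to
    all SNP markers); base "phenotypic" leaves the sums unnormalized.
    Markers may appear in several regions (e.g. gene cis sets); shares over a
    disjoint tiling sum to 1.
    """
    n_draws = samples.n_draws
    p = samples.n_markers
    region_of = np.full(p, -1, dtype=np.int64)
    overlapping = False
    for r, members in enumerate(regions.members):
        m = np.asarray(members, dtype=int)
        if np.any(region_of[m] >= 0):
            overlapping = True
            break
        region_of[m] = r

    draw_of = np.repeat(np.arange(n_draws), np.diff(samples.indptr))
    sq = samples.beta_val**2
    out = np.zeros((n_draws, len(regions)))
    if not overlapping:
        reg = region_of[samples.beta_idx]
        keep = reg >= 0
        np.add.at(out, (draw_of[keep], reg[keep]), sq[keep])
    else:
        member_of = [np.asarray(m, dtype=int) for m in regions.members]
        dense = np.zeros((n_draws, p))
        np.add.at(dense, (draw_of, samples.beta_idx), sq)
        for r, m in enumerate(member_of):
            out[:, r] = dense[:, m].sum(axis=1)
    if base == "phenotypic":
        return out
    total = np.zeros(n_draws)
    np.add.at(total, draw_of, sq)
    total[total == 0] = np.inf  # empty-model draws contribute zero shares
    return out / total[:, None]


def ppwv(shares: np.ndarray, regions: RegionSet, theta: float = 1e-5,
         levels=(0.8, 0.9, 0.95)) -> pd.DataFrame:
    """Fraction of draws in which each region's share reaches ``theta``.

    ``theta`` defaults to 1e-5, i.e. 0.001% of the variance attributed to the
    SNP markers; a region is called associated at probability ``level`` when
    its PPWV is at least that level.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    prob = (shares >= theta).mean(axis=0)
    df = pd.DataFrame({
        "region_id": regions.region_ids,
        "kind": regions.kind,
        "n_markers": [len(m) for m in regions.members],
        "mean_share": shares.mean(axis=0),
        "ci_low": np.quantile(shares, 0.025, axis=0),
        "ci_high": np.quantile(shares, 0.975, axis=0),
        "ppwv": prob,
    })
    for lv in levels:
        df[f"called_{lv:g}"] = prob >= lv
    return df


def evaluate_calls(ppwv_table: pd.DataFrame, regions: RegionSet,
                   causal_indices, shares: np.ndarray | None = None,
                   true_region_variance: np.ndarray | None = None,
                   level: float = 0.95) -> dict:
    """Score PPWV calls against simulation truth.

    FDR is the fraction of called regions (PPWV >= ``level``) containing no
    causal marker. The precision-recall curve sweeps the PPWV threshold over
    the observed values; AUPRC integrates it with the trapezoid rule over
    recall. When per-draw ``shares`` and the true per-region variances are
    supplied, per-region z-scores (posterior mean - truth) / posterior SD are
    included.
    """
    causal = set(int(c) for c in np.asarray(causal_indices).ravel())
    has_causal = np.array([bool(causal.intersection(m)) for m in regions.members])
    prob = ppwv_table["ppwv"].to_numpy()

    called = prob >= level
    n_called = int(called.sum())
    fdr = float((called & ~has_causal).sum() / n_called) if n_called else 0.0

    order = np.argsort(-prob, kind="stable")
    tp = np.cumsum(has_causal[order])
    fp = np.cumsum(~has_causal[order])
    precision = tp / np.maximum(tp + fp, 1)
    n_pos = int(has_causal.sum())
    result = {"fdr": fdr, "n_called": n_called, "level": level}
    if n_pos:
        recall = tp / n_pos
        rec = np.concatenate([[0.0], recall])
        prec = np.concatenate([[1.0], precision])
        result["auprc"] = float(np.trapezoid(prec, rec))
        result["precision"] = precision
        result["recall"] = recall
    else:
        result["auprc"] = np.nan
        result["recall_undefined"] = True
    if shares is not None and true_region_variance is not None:
        mean = shares.mean(axis=0)
        sd = shares.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        result["z_scores"] = (mean - np.asarray(true_region_variance)) / sd
    return result
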