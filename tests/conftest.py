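import numpy as np
import pytest

import bayesrrc as b


@pytest.fixture(scope="session")
def small_panel():
    """LD-blocked panel: 3 blocks of 5 markers, strong within-block LD."""
    cfg = b.SimConfig(n_individuals=2000, n_markers=15, ld_block_size=5,
                      within_block_corr=0.9, n_causal=0, h2=0.0,
                      maf_range=(0.2, 0.4), seed=7)
    return b.simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def fitted_small():
    """A fitted model on a small simulated dataset with known truth."""
    cfg = b.SimConfig(n_individuals=1500, n_markers=300, n_causal=10, h2=0.5,
                      ld_block_size=10, within_block_corr=0.5, seed=42)
    panel, y, truth, cats = b.simulate_dataset(cfg)
    grouping = b.build_groups(cats, panel.realized_maf(), b.compute_ld_scores(panel))
    model = b.BayesRRC(y, panel, grouping=grouping)
    model.panel = panel
    res = model.fit(n_iter=1200, burn_in=400, seed=43, n_chains=2)
    return {"panel": panel, "y": y, "truth": truth, "categories": cats,
            "grouping": grouping, "model": model, "res": res, "config": cfg}


def grid_panel_frame(n_per_cell: int = 4, seed: int = 0):
    """Synthetic marker table populating all 13 x 3 x 2 grouping cells."""
    rng = np.random.default_rng(seed)
    cats, mafs, lds = [], [], []
    maf_rep = {"rare": (0.002, 0.01), "low": (0.02, 0.05), "common": (0.1, 0.5)}
    for cat in b.CATEGORIES:
        for mc, (lo, hi) in maf_rep.items():
            for half, ld_base in ((0, 1.0), (1, 10.0)):
                for _ in range(n_per_cell):
                    cats.append(cat)
                    mafs.append(rng.uniform(lo, hi))
                    lds.append(ld_base + rng.uniform(0, 0.5))
    return np.array(cats), np.array(mafs), np.array(lds)
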