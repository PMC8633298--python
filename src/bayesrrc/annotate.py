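"""Marker annotation, MAF/LD grouping and region construction.

Markers are partitioned into 13 location/functional categories (exon, intron,
1 kb promoter, then 1-10 kb / 10-500 kb / 500 kb-1 Mb upstream bands each split
into enhancer / TFBS / other, plus a residual "others" class), crossed with
three minor-allele-frequency classes (rare <= 0.01, low 0.01-0.05,
common > 0.05) and a within-cell median LD-score split. With every cell
populated this yields 13 x 3 x 2 = 78 non-overlapping marker groups, each of
which receives its own mixture prior in the regression model.

Region sets for window-variance inference: 50 kb tiles, greedily clumped LD
blocks, and gene-anchored sets (exon / intron / promoter / cis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: location/functional categories in assignment-priority order
CATEGORIES = (
    "exon",
    "intron",
    "1kb_promoter",
    "1-10kb_enh",
    "1-10kb_tfbs",
    "1-10kb_other",
    "10-500kb_enh",
    "10-500kb_tfbs",
    "10-500kb_other",
    "500kb-1Mb_enh",
    "500kb-1Mb_tfbs",
    "500kb-1Mb_other",
    "others",
)

MAF_CLASSES = ("rare", "low", "common")
LD_CLASSES = ("low", "high")

#: per-category genetic-variance shares of the enriched simulation setting
#: (exact fractions whose decimal roundings are 0.167, 0.334, 0.0835, 0.04175)
ENRICHED_H2_SHARES = {
    "exon": float(Fraction(1, 6)),
    "intron": float(Fraction(1, 3)),
    "1kb_promoter": float(Fraction(1, 12)),
    "1-10kb_enh": float(Fraction(1, 24)),
    "1-10kb_tfbs": float(Fraction(1, 24)),
    "1-10kb_other": 0.0,
    "10-500kb_enh": float(Fraction(1, 12)),
    "10-500kb_tfbs": float(Fraction(1, 12)),
    "10-500kb_other": 0.0,
    "500kb-1Mb_enh": float(Fraction(1, 12)),
    "500kb-1Mb_tfbs": float(Fraction(1, 12)),
    "500kb-1Mb_other": 0.0,
    "others": 0.0,
}

#: marker-count proportions used when assigning categories to simulated
#: markers by contiguous index ranges (exons sparse, introns and distal
#: regions dense, mirroring genome-wide annotation density)
DEFAULT_CATEGORY_PROPORTIONS = {
    "exon": 0.04,
    "intron": 0.30,
    "1kb_promoter": 0.02,
    "1-10kb_enh": 0.03,
    "1-10kb_tfbs": 0.03,
    "1-10kb_other": 0.04,
    "10-500kb_enh": 0.08,
    "10-500kb_tfbs": 0.08,
    "10-500kb_other": 0.14,
    "500kb-1Mb_enh": 0.05,
    "500kb-1Mb_tfbs": 0.05,
    "500kb-1Mb_other": 0.06,
    "others": 0.08,
}


@dataclass
class MarkerGrouping:
    """Per-marker category / MAF class / LD class and the dense group index.

    ``group_index`` densely enumerates the populated
    (category, maf_class, ld_class) triples; ``n_groups`` is the number of
    populated triples (78 when every cell is populated).
    """

    category: np.ndarray
    maf_class: np.ndarray
    ld_class: np.ndarray
    group_index: np.ndarray
    group_labels: list

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    def to_frame(self, marker_ids: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": marker_ids,
                "category": self.category,
                "maf_class": self.maf_class,
                "ld_class": self.ld_class,
                "group_index": self.group_index,
            }
        )

    @classmethod
    def single_group(cls, p: int) -> "MarkerGrouping":
        """One group covering all markers (plain, ungrouped BayesR)."""
        filler = np.full(p, "all")
        return cls(filler, filler, filler, np.zeros(p, dtype=int), [("all", "all", "all")])


@dataclass
class RegionSet:
    """Named marker index sets of one kind (50 kb windows, LD blocks, genes)."""

    region_ids: list
    members: list
    kind: str
    provenance: dict

    def __len__(self) -> int:
        return len(self.region_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "kind": self.kind,
                "marker_indices": [",".join(map(str, m)) for m in self.members],
            }
        )


def maf_class(maf) -> np.ndarray:
    """Classify minor allele frequencies: rare (<=0.01), low (0.01-0.05], common.

    Scalar in, scalar out; array in, array out. Frequencies outside (0, 0.5]
    are rejected.
    """
    arr = np.atleast_1d(np.asarray(maf, dtype=float))
    if np.any(arr <= 0) or np.any(arr > 0.5):
        raise ValueError("MAF must be in (0, 0.5]")
    out = np.where(arr <= 0.01, "rare", np.where(arr <= 0.05, "low", "common"))
    return out if np.ndim(maf) else out[0]


def default_category_layout(p: int) -> np.ndarray:
    """Assign the 13 categories to contiguous marker index ranges.

    Range lengths follow :data:`DEFAULT_CATEGORY_PROPORTIONS`; the last
    category absorbs rounding remainders.
    """
    cats = np.empty(p, dtype=object)
    start = 0
    items = list(DEFAULT_CATEGORY_PROPORTIONS.items())
    for i, (cat, frac) in enumerate(items):
        stop = p if i == len(items) - 1 else min(p, start + int(round(frac * p)))
        cats[start:stop] = cat
        start = stop
    cats[start:] = items[-1][0]
    return cats.astype(str)


def assign_location_category(
    positions: np.ndarray,
    chromosomes: np.ndarray,
    marker_ids: np.ndarray,
    gene_intervals: pd.DataFrame,
    promoter_set: set | None = None,
    enhancer_set: set | None = None,
    tfbs_set: set | None = None,
) -> np.ndarray:
    """Assign each marker to one of the 13 location/functional categories.

    Priority: exon > intron > 1 kb upstream > 1-10 kb > 10-500 kb >
    500 kb-1 Mb > others. Upstream distance is measured strand-aware to the
    nearest gene start (TSS); markers downstream of every gene are never
    claimed by a distance band. All 1 kb-band markers are promoters; the wider
    bands are sub-labelled enh if the marker id is in ``enhancer_set``, else
    tfbs if in ``tfbs_set``, else ``*_other``.

    ``gene_intervals`` columns: chrom, start, end, strand, gene_id, feature
    (feature in {exon, intron}; gene body = union of its intervals).
    0-based half-open coordinates.
    """
    enhancer_set = enhancer_set or set()
    tfbs_set = tfbs_set or set()
    p = len(positions)
    out = np.full(p, "others", dtype=object)
    known_chroms = set(gene_intervals["chrom"].unique())

    # per-gene body span and TSS
    genes = gene_intervals.groupby("gene_id").agg(
        chrom=("chrom", "first"),
        start=("start", "min"),
        end=("end", "max"),
        strand=("strand", "first"),
    )
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"])

    exons = gene_intervals[gene_intervals["feature"] == "exon"]
    for j in range(p):
        pos, chrom = positions[j], chromosomes[j]
        if chrom not in known_chroms:
            logger.warning("marker %s on unknown chromosome %s -> others", marker_ids[j], chrom)
            continue
        ex = exons[(exons["chrom"] == chrom) & (exons["start"] <= pos) & (pos < exons["end"])]
        if len(ex):
            out[j] = "exon"
            continue
        gb = genes[(genes["chrom"] == chrom) & (genes["start"] <= pos) & (pos < genes["end"])]
        if len(gb):
            out[j] = "intron"
            continue
        gc = genes[genes["chrom"] == chrom]
        # strand-aware upstream distance: + strand genes upstream of pos means
        # pos < tss with distance tss - pos; - strand means pos > tss.
        up_plus = gc[(gc["strand"] == "+") & (gc["tss"] > pos)]["tss"] - pos
        up_minus = pos - gc[(gc["strand"] == "-") & (gc["tss"] < pos)]["tss"]
        dists = pd.concat([up_plus, up_minus])
        if len(dists) == 0:
            continue
        d = int(dists.min())
        mid = marker_ids[j]
        if d <= 1_000:
            out[j] = "1kb_promoter"
        elif d <= 10_000:
            out[j] = _functional_sublabel("1-10kb", mid, enhancer_set, tfbs_set)
        elif d <= 500_000:
            out[j] = _functional_sublabel("10-500kb", mid, enhancer_set, tfbs_set)
        elif d <= 1_000_000:
            out[j] = _functional_sublabel("500kb-1Mb", mid, enhancer_set, tfbs_set)
    return out.astype(str)


def _functional_sublabel(band, marker_id, enhancer_set, tfbs_set):
    if marker_id in enhancer_set:
        return f"{band}_enh"
    if marker_id in tfbs_set:
        return f"{band}_tfbs"
    return f"{band}_other"


def compute_ld_scores(panel, window_kb: float = 1000.0) -> np.ndarray:
    """LD score w_j = sum of R^2 with markers within ``window_kb``, self included.

    Computed per chromosome on standardized genotypes; w_j >= 1 always.
    """
    from .simulate import standardize_columns

    p = panel.n_markers
    w = np.zeros(p)
    window = window_kb * 1000.0
    for chrom in np.unique(panel.chromosomes):
        idx = np.flatnonzero(panel.chromosomes == chrom)
        x = standardize_columns(panel, idx)
        n = x.shape[0]
        pos = panel.positions[idx]
        # banded computation in column chunks
        chunk = 512
        for s in range(0, len(idx), chunk):
            e = min(s + chunk, len(idx))
            r = (x.T @ x[:, s:e]) / n  # (p_c, chunk)
            r2 = r**2
            in_win = np.abs(pos[:, None] - pos[None, s:e]) <= window
            w[idx[s:e]] = np.sum(r2 * in_win, axis=0)
    return np.maximum(w, 1.0)


def build_groups(categories, mafs, ld_scores) -> MarkerGrouping:
    """Cross categories with MAF classes and a within-cell median LD split.

    The LD split is nested: within each (category, MAF class) cell markers at
    or below the cell's median LD score are "low", the rest "high". Populated
    triples are densely enumerated in (category, MAF, LD) order; empty triples
    are dropped.
    """
    categories = np.asarray(categories)
    mafs = np.asarray(mafs, dtype=float)
    ld_scores = np.asarray(ld_scores, dtype=float)
    if not (len(categories) == len(mafs) == len(ld_scores)):
        raise ValueError("categories, mafs and ld_scores must be aligned")
    mclass = maf_class(mafs)
    ldclass = np.empty(len(mafs), dtype=object)
    for cat in np.unique(categories):
        for mc in MAF_CLASSES:
            cell = (categories == cat) & (mclass == mc)
            if not cell.any():
                continue
            med = np.median(ld_scores[cell])
            ldclass[cell] = np.where(ld_scores[cell] <= med, "low", "high")
    ldclass = ldclass.astype(str)

    labels = []
    index = np.full(len(mafs), -1, dtype=int)
    for cat in CATEGORIES:
        for mc in MAF_CLASSES:
            for lc in LD_CLASSES:
                mask = (categories == cat) & (mclass == mc) & (ldclass == lc)
                if mask.any():
                    index[mask] = len(labels)
                    labels.append((cat, mc, lc))
    # categories outside the canonical 13 (e.g. a custom scheme) appended last
    for cat in sorted(set(np.unique(categories)) - set(CATEGORIES)):
        for mc in MAF_CLASSES:
            for lc in LD_CLASSES:
                mask = (categories == cat) & (mclass == mc) & (ldclass == lc)
                if mask.any():
                    index[mask] = len(labels)
                    labels.append((cat, mc, lc))
    return MarkerGrouping(categories, mclass, ldclass, index, labels)


def define_regions(panel, mode: str, window_kb: float = 50.0,
                   r2_threshold: float = 0.1,
                   gene_intervals: pd.DataFrame | None = None,
                   cis_kb: float = 50.0) -> RegionSet:
    """Build a region set for window-variance inference.

    mode "window50kb": half-open non-overlapping tiles of ``window_kb`` per
    chromosome. mode "ld_block": greedy clumping — markers ranked by MAF
    descending (the most common marker seeds each block, index tie-break);
    the seed absorbs every unassigned marker with R^2 > ``r2_threshold``.
    mode "gene": marker sets per gene body plus a cis set (gene span extended
    by ``cis_kb`` on both sides).
    """
    if mode == "window50kb":
        ids, members = [], []
        width = int(window_kb * 1000)
        for chrom in np.unique(panel.chromosomes):
            idx = np.flatnonzero(panel.chromosomes == chrom)
            win = panel.positions[idx] // width
            for wv in np.unique(win):
                ids.append(f"chr{chrom}:{wv * width}-{(wv + 1) * width}")
                members.append(idx[win == wv].tolist())
        return RegionSet(ids, members, "window50kb", {"window_kb": window_kb})

    if mode == "ld_block":
        from .simulate import standardize_columns

        maf = panel.realized_maf()
        order = np.lexsort((np.arange(panel.n_markers), -maf))
        assigned = np.zeros(panel.n_markers, dtype=bool)
        ids, members = [], []
        x = standardize_columns(panel, np.arange(panel.n_markers))
        n = x.shape[0]
        for seed in order:
            if assigned[seed]:
                continue
            r2 = (x.T @ x[:, seed] / n) ** 2
            block = np.flatnonzero((~assigned) & ((r2 > r2_threshold) | (np.arange(len(r2)) == seed)))
            assigned[block] = True
            ids.append(f"ldblock_{panel.marker_ids[seed]}")
            members.append(block.tolist())
        return RegionSet(ids, members, "ld_block", {"r2_threshold": r2_threshold})

    if mode == "gene":
        if gene_intervals is None:
            raise ValueError("gene mode requires gene_intervals")
        genes = gene_intervals.groupby("gene_id").agg(
            chrom=("chrom", "first"), start=("start", "min"), end=("end", "max")
        )
        ids, members = [], []
        pad = int(cis_kb * 1000)
        for gid, row in genes.iterrows():
            on_chr = panel.chromosomes == row["chrom"]
            body = np.flatnonzero(on_chr & (panel.positions >= row["start"]) & (panel.positions < row["end"]))
            cis = np.flatnonzero(
                on_chr & (panel.positions >= row["start"] - pad) & (panel.positions < row["end"] + pad)
            )
            ids.extend([f"{gid}_body", f"{gid}_cis"])
            members.extend([body.tolist(), cis.tolist()])
        return RegionSet(ids, members, "gene", {"cis_kb": cis_kb})

    raise ValueError(f"unknown region mode {mode!r}")
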