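"""PLINK v1 bed/bim/fam reading and writing (SNP-major layout).

The bed codec packs four genotypes per byte, low bits first. With A1-allele
counting (the PLINK convention) the 2-bit codes decode as:

    00 -> 2 copies of A1 (homozygous A1)
    01 -> missing
    10 -> 1 copy (heterozygous)
    11 -> 0 copies (homozygous A2)

``count_a2=True`` flips the counting; effect signs depend on this choice.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_plink", "write_plink", "read_bim", "read_fam"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# code -> genotype lookup under A1 counting; -1 encodes missing
_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)
_ENCODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}


def _paths(prefix):
    prefix = Path(prefix)
    if prefix.suffix == ".bed":
        prefix = prefix.with_suffix("")
    return (prefix.with_suffix(".bed"), prefix.with_suffix(".bim"),
            prefix.with_suffix(".fam"))


def read_bim(path) -> pd.DataFrame:
    bim = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["chrom", "marker_id", "cm", "pos", "a1", "a2"])
    return bim


def read_fam(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", header=None,
                       names=["fid", "iid", "father", "mother", "sex", "pheno"])


def read_plink(prefix, count_a2: bool = False):
    """Read bed/bim/fam into a :class:`~bayesrrc.simulate.GenotypePanel`.

    Rejects individual-major files and truncated payloads with the offending
    byte offset. bim positions are 1-based on disk and converted to the
    package's 0-based convention.
    """
    from .simulate import GenotypePanel

    bed_path, bim_path, fam_path = _paths(prefix)
    bim = read_bim(bim_path)
    fam = read_fam(fam_path)
    n, p = len(fam), len(bim)

    raw = Path(bed_path).read_bytes()
    if raw[:2] != _MAGIC[:2]:
        raise ValueError(f"bad magic bytes {raw[:2]!r} at offset 0: not a PLINK bed file")
    if raw[2:3] != _MAGIC[2:3]:
        raise ValueError("individual-major bed files (third byte 0x00) are not supported")
    bytes_per_marker = (n + 3) // 4
    expected = 3 + bytes_per_marker * p
    if len(raw) != expected:
        raise ValueError(
            f"truncated or oversized bed: expected {expected} bytes, got {len(raw)} "
            f"(mismatch from offset {min(expected, len(raw))})"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(p, bytes_per_marker)
    # unpack two-bit codes, low bits first
    codes = np.empty((p, bytes_per_marker * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (data >> (2 * k)) & 0b11
    geno = _DECODE[codes[:, :n]].T.copy()  # (n, p)
    if count_a2:
        flip = geno >= 0
        geno[flip] = 2 - geno[flip]

    freq = np.array([g[g >= 0].mean() / 2 if (g >= 0).any() else 0.0 for g in geno.T])
    maf = np.minimum(freq, 1 - freq)
    return GenotypePanel(
        genotypes=geno,
        marker_ids=bim["marker_id"].to_numpy(str),
        positions=bim["pos"].to_numpy(np.int64) - 1,
        chromosomes=bim["chrom"].to_numpy(),
        maf=maf,
        block=np.full(p, -1, dtype=np.int64),
    )


def write_plink(panel, prefix, individual_ids=None, phenotypes=None) -> None:
    """Write a panel as bed/bim/fam (A/B placeholder alleles, 1-based bim)."""
    bed_path, bim_path, fam_path = _paths(prefix)
    n, p = panel.genotypes.shape
    bytes_per_marker = (n + 3) // 4

    geno = panel.genotypes.T  # (p, n)
    codes = np.empty((p, bytes_per_marker * 4), dtype=np.uint8)
    codes[:] = 0
    # map genotype value (-1,0,1,2) -> code
    mapped = np.where(geno < 0, _ENCODE[-1],
                      np.where(geno == 0, _ENCODE[0],
                               np.where(geno == 1, _ENCODE[1], _ENCODE[2])))
    codes[:, :n] = mapped
    packed = np.zeros((p, bytes_per_marker), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4].astype(np.uint8) << (2 * k)
    with open(bed_path, "wb") as f:
        f.write(_MAGIC)
        f.write(packed.tobytes())

    bim = pd.DataFrame({
        "chrom": panel.chromosomes,
        "marker_id": panel.marker_ids,
        "cm": 0,
        "pos": np.asarray(panel.positions) + 1,
        "a1": "A",
        "a2": "B",
    })
    bim.to_csv(bim_path, sep="\t", header=False, index=False)

    ids = individual_ids if individual_ids is not None else [f"ind{i}" for i in range(n)]
    fam = pd.DataFrame({
        "fid": ids, "iid": ids, "father": 0, "mother": 0, "sex": 0,
        "pheno": phenotypes if phenotypes is not None else -9,
    })
    fam.to_csv(fam_path, sep="\t", header=False, index=False)
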