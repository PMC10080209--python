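"""Genotype file I/O: PLINK .bed/.bim/.fam triplets and dosage CSV.

The PLINK codec implements the v1.00 binary layout directly (magic bytes
0x6c 0x1b, mode byte 0x01 = SNP-major, two bits per genotype packed
little-endian within each byte). Dosages count copies of the A1 allele:
bit pair 00 -> 2, 10 -> 1, 11 -> 0. The pair 01 encodes a missing
genotype, which is rejected — missingness is unsupported throughout.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

__all__ = ["read_genotypes", "write_genotypes", "FormatError"]

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# bit-pair -> A1 dosage; 3 marks the missing code 0b01
_PAIR_TO_DOSAGE = np.array([2, 3, 1, 0], dtype=np.int8)
_DOSAGE_TO_PAIR = {2: 0b00, 1: 0b10, 0: 0b11}


class FormatError(ValueError):
    """Malformed genotype file."""


class MissingGenotypeError(ValueError):
    """File contains missing genotype codes (unsupported)."""


def _strip_ext(path: str) -> str:
    base, ext = os.path.splitext(path)
    return base if ext in {".bed", ".bim", ".fam"} else path


def _read_plink(prefix: str) -> GenotypeMatrix:
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] != 6 or bim.shape[1] != 6:
        raise FormatError(".fam and .bim must each have 6 columns")
    n, p = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        header = fh.read(3)
        if len(header) != 3 or header[:2] != _BED_MAGIC:
            raise FormatError("bad .bed magic bytes")
        if header[2] != _SNP_MAJOR:
            raise FormatError("only SNP-major .bed files are supported")
        body = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if body.size != bytes_per_snp * p:
        raise FormatError(
            f".bed payload has {body.size} bytes, expected {bytes_per_snp * p} "
            f"for n={n}, p={p}"
        )
    blocks = body.reshape(p, bytes_per_snp)
    # unpack two-bit genotype codes, sample-within-byte little-endian
    pairs = np.stack(
        [(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(p, -1)[:, :n]
    dosages = _PAIR_TO_DOSAGE[pairs].T
    if (dosages == 3).any():
        raise MissingGenotypeError("missing genotypes are not supported")
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=fam[1].to_numpy(dtype=object),
        marker_ids=bim[1].to_numpy(dtype=object),
        chromosome=bim[0].to_numpy(dtype=object),
        position_bp=bim[3].astype(np.int64).to_numpy(),
    )


def _write_plink(G: GenotypeMatrix, prefix: str) -> None:
    n, p = G.shape
    codes = np.empty((p, n), dtype=np.uint8)
    for dosage, pair in _DOSAGE_TO_PAIR.items():
        codes[G.dosages.T == dosage] = pair
    pad = (-n) % 4
    if pad:
        # pad with hom-A2 (dosage 0) pairs; ignored on read
        codes = np.hstack([codes, np.full((p, pad), 0b11, dtype=np.uint8)])
    quads = codes.reshape(p, -1, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())
    fam = pd.DataFrame(
        {
            0: G.sample_ids,
            1: G.sample_ids,
            2: "0",
            3: "0",
            4: "0",
            5: "-9",
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {
            0: G.chromosome,
            1: G.marker_ids,
            2: "0",
            3: G.position_bp,
            4: "A",
            5: "B",
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)


def _read_dosage_csv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy()
    if pd.isna(values).any():
        raise MissingGenotypeError("missing genotypes are not supported")
    dosages = values.astype(np.int8)
    if not np.isin(dosages, (0, 1, 2)).all():
        raise FormatError("dosage CSV cells must be integers in {0, 1, 2}")
    p = df.shape[1]
    from .core import _default_marker_map

    _, chrom, pos = _default_marker_map(p)
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=df.index.to_numpy(dtype=object).astype(str),
        marker_ids=df.columns.to_numpy(dtype=object).astype(str),
        chromosome=chrom,
        position_bp=pos,
    )


def _write_dosage_csv(G: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(G.dosages, index=G.sample_ids, columns=G.marker_ids)
    df.index.name = "sample_id"
    df.to_csv(path)


def read_genotypes(path: str, format: str = "plink-bed") -> GenotypeMatrix:
    """Read a genotype matrix (``plink-bed`` prefix/path or ``dosage-csv``)."""
    if format == "plink-bed":
        return _read_plink(_strip_ext(path))
    if format == "dosage-csv":
        return _read_dosage_csv(path)
    raise ValueError(f"unknown format {format!r}")


def write_genotypes(G: GenotypeMatrix, path: str, format: str = "plink-bed") -> None:
    """Write a genotype matrix in the given format (round-trip exact)."""
    if format == "plink-bed":
        _write_plink(G, _strip_ext(path))
    elif format == "dosage-csv":
        _write_dosage_csv(G, path)
    else:
        raise ValueError(f"unknown format {format!r}")
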