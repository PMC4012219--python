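"""Genotype and phenotype I/O, allele-frequency estimation, standardization.

Genotypes are reference-allele counts in {0, 1, 2}; missing calls are coded
as -1 internally.  PLINK binary filesets (.bed/.bim/.fam, v1.00 SNP-major)
and a plain whitespace-delimited 0/1/2 dosage matrix are supported.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

PLINK_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01


class GenotypeFormatError(ValueError):
    """Raised on malformed or unsupported genotype files."""


@dataclass(frozen=True)
class LocusInfo:
    """Metadata for one biallelic locus.

    ``p`` is the frequency of the counted (reference) allele; the
    alternative-allele frequency is ``1 - p``.
    """

    id: str
    chrom: str = "1"
    pos: int = 0
    ref_allele: str = "A"
    alt_allele: str = "a"
    p: float = float("nan")

    @property
    def q(self) -> float:
        return 1.0 - self.p


@dataclass
class GenotypeMatrix:
    """N x M reference-allele counts with per-locus metadata.

    ``calls`` is an int8 array with values in {0, 1, 2, MISSING}.
    """

    samples: list[tuple[str, str]]
    loci: list[LocusInfo]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        n, m = self.calls.shape
        if n != len(self.samples) or m != len(self.loci):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(f"invalid genotype call at row {bad[0]}, column {bad[1]}")

    @property
    def n(self) -> int:
        return self.calls.shape[0]

    @property
    def m(self) -> int:
        return self.calls.shape[1]

    def flipped(self) -> "GenotypeMatrix":
        """Return a copy counting the other allele (2 - x, missing preserved)."""
        calls = self.calls.copy()
        obs = calls != MISSING
        calls[obs] = 2 - calls[obs]
        loci = [
            LocusInfo(l.id, l.chrom, l.pos, l.alt_allele, l.ref_allele,
                      1.0 - l.p if np.isfinite(l.p) else float("nan"))
            for l in self.loci
        ]
        return GenotypeMatrix(list(self.samples), loci, calls)

    def subset_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            list(self.samples),
            [self.loci[int(i)] for i in idx],
            self.calls[:, idx],
        )


@dataclass
class StandardizedMatrix:
    """Centered/scaled genotypes s_ik = (x_ik - 2 p_k) / sqrt(2 p_k q_k).

    ``mask`` marks originally observed entries (True = observed); under the
    default mean-imputation policy missing entries are filled with 0, which
    is the per-locus mean on the standardized scale.
    """

    values: np.ndarray
    freqs: np.ndarray
    missing_policy: str = "mean"
    mask: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# PLINK binary filesets


def read_plink_bed(prefix: str | os.PathLike, a1_as_reference: bool = True) -> GenotypeMatrix:
    """Read a PLINK v1.00 SNP-major .bed/.bim/.fam fileset.

    2-bit codes per sample: 00 = homozygous A1, 01 = missing, 10 = het,
    11 = homozygous A2.  With ``a1_as_reference`` (default) the .bim A1
    allele is the counted allele, so 00 decodes to 2 copies.
    """
    prefix = os.fspath(prefix)
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None, dtype=str)
    samples = list(zip(fam[0], fam[1]))
    loci = [
        LocusInfo(id=row[1], chrom=row[0], pos=int(row[3]),
                  ref_allele=row[4], alt_allele=row[5])
        for row in bim.itertuples(index=False)
    ]
    n, m = len(samples), len(loci)

    with open(prefix + ".bed", "rb") as fh:
        raw = fh.read()
    if raw[:2] != PLINK_MAGIC:
        raise GenotypeFormatError(
            f"{prefix}.bed: bad magic bytes {raw[:2]!r}; not a PLINK v1.00 .bed file"
        )
    if len(raw) < 3 or raw[2] != _SNP_MAJOR:
        raise GenotypeFormatError(f"{prefix}.bed: only SNP-major mode (0x01) is supported")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise GenotypeFormatError(
            f"{prefix}.bed: expected {bytes_per_snp * m} data bytes for "
            f"N={n}, M={m}, found {body.size}"
        )
    # unpack 2-bit fields, little-endian within byte
    codes = body.reshape(m, bytes_per_snp)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (codes[:, :, None] >> shifts) & 0b11  # (m, bytes, 4)
    two_bit = two_bit.reshape(m, bytes_per_snp * 4)[:, :n]
    # 00 -> 2 copies of A1, 01 -> missing, 10 -> 1, 11 -> 0 copies of A1
    decode = np.array([2, MISSING, 1, 0], dtype=np.int8)
    calls = decode[two_bit].T.copy()  # (n, m)
    G = GenotypeMatrix(samples, loci, calls)
    return G if a1_as_reference else G.flipped()


def write_plink_bed(G: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write a PLINK v1.00 SNP-major fileset; round-trips with read_plink_bed."""
    prefix = os.fspath(prefix)
    with open(prefix + ".fam", "w") as fh:
        for fid, iid in G.samples:
            fh.write(f"{fid} {iid} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for l in G.loci:
            fh.write(f"{l.chrom} {l.id} 0 {l.pos} {l.ref_allele} {l.alt_allele}\n")
    n, m = G.n, G.m
    # inverse of the read decode: counts of A1 -> 2-bit codes
    encode = np.zeros(4, dtype=np.uint8)
    encode[2], encode[1], encode[0] = 0b00, 0b10, 0b11
    codes = np.where(G.calls == MISSING, 0b01, encode[np.clip(G.calls, 0, 2)]).astype(np.uint8)
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded.reshape(m, bytes_per_snp, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(PLINK_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Text formats


def read_text_genotypes(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a whitespace-delimited dosage matrix, one individual per row.

    Entries must be 0, 1, 2 or NA.  Synthetic sample/locus metadata is
    attached (individuals ``ind1..``, loci ``snp1..``).
    """
    rows: list[list[int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            row = []
            for col_no, tok in enumerate(tokens, start=1):
                if tok.upper() in ("NA", "."):
                    row.append(MISSING)
                elif tok in ("0", "1", "2"):
                    row.append(int(tok))
                else:
                    raise GenotypeFormatError(
                        f"{path}: invalid genotype {tok!r} at row {line_no}, column {col_no}"
                    )
            rows.append(row)
    if not rows:
        raise GenotypeFormatError(f"{path}: empty genotype file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise GenotypeFormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    m = widths.pop()
    samples = [("F" + str(i + 1), "ind" + str(i + 1)) for i in range(len(rows))]
    loci = [LocusInfo(id=f"snp{k + 1}", pos=k + 1) for k in range(m)]
    return GenotypeMatrix(samples, loci, np.array(rows, dtype=np.int8))


def read_phenotype(path: str | os.PathLike) -> pd.DataFrame:
    """Read a 'FID IID value' phenotype file; NA becomes NaN.

    Returns a DataFrame with columns fid, iid, value.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise GenotypeFormatError(f"{path}: phenotype file needs FID IID value columns")
    out = df.iloc[:, :3].copy()
    out.columns = ["fid", "iid", "value"]
    out["value"] = pd.to_numeric(out["value"].replace({"NA": np.nan, "-9": np.nan}),
                                 errors="coerce")
    return out


def write_phenotype(path: str | os.PathLike,
                    samples: Sequence[tuple[str, str]],
                    values: np.ndarray) -> None:
    with open(path, "w") as fh:
        for (fid, iid), v in zip(samples, values):
            fh.write(f"{fid} {iid} {'NA' if not np.isfinite(v) else repr(float(v))}\n")


# ---------------------------------------------------------------------------
# Frequencies and standardization


def estimate_allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Reference-allele frequency per locus from non-missing calls only."""
    calls = G.calls
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        bad = [G.loci[int(k)].id for k in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"all calls missing at loci: {', '.join(bad)}")
    totals = np.where(obs, calls, 0).sum(axis=0)
    return totals / (2.0 * n_obs)


def polymorphic_index(freqs: np.ndarray, maf_min: float = 0.01) -> np.ndarray:
    """Indices of loci with minor-allele frequency >= maf_min."""
    freqs = np.asarray(freqs, dtype=float)
    maf = np.minimum(freqs, 1.0 - freqs)
    return np.flatnonzero(maf >= maf_min)


def standardize(G: GenotypeMatrix,
                freqs: np.ndarray | None = None,
                missing_policy: str = "mean") -> StandardizedMatrix:
    """Standardize calls: s_ik = (x_ik - 2 p_k) / sqrt(2 p_k q_k).

    Monomorphic loci (p in {0, 1}) are rejected; exclude them first with
    :func:`polymorphic_index`.  ``missing_policy``:

    * ``"mean"`` — missing entries set to 0 (the standardized mean);
    * ``"pairwise"`` — same fill, but the observation mask is retained so the
      relatedness step can use per-pair complete-marker denominators.
    """
    if missing_policy not in ("mean", "pairwise"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    if freqs is None:
        freqs = estimate_allele_frequencies(G)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (G.m,):
        raise ValueError("frequency vector length mismatch")
    mono = (freqs <= 0.0) | (freqs >= 1.0)
    if mono.any():
        bad = [G.loci[int(k)].id for k in np.flatnonzero(mono)]
        raise ValueError(
            f"monomorphic loci cannot be standardized (p in {{0,1}}): {', '.join(bad)}"
        )
    denom = np.sqrt(2.0 * freqs * (1.0 - freqs))
    obs = G.calls != MISSING
    s = (G.calls.astype(float) - 2.0 * freqs) / denom
    s[~obs] = 0.0
    mask = obs if missing_policy == "pairwise" or not obs.all() else None
    return StandardizedMatrix(values=s, freqs=freqs, missing_policy=missing_policy,
                              mask=mask)
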