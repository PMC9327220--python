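"""PLINK1 bed/bim/fam filesets and the dosage-preserving VCF output.

The PLINK1 binary fileset stores hard genotype calls: a ``.bed`` file packs
two bits per sample in SNP-major order behind a three-byte magic
(``6C 1B 01``), while ``.bim`` and ``.fam`` are six-column text tables for
variants and samples.  Dosages lose their fractional information at this
step: each dosage is *hard-called* to the nearest integer genotype when it
lies within a threshold of that integer, and set missing otherwise.

Because the hard call discards imputation uncertainty, a parallel
dosage-preserving path writes a VCF with a ``DS`` FORMAT field carrying the
allele-1 dosage at fixed decimal precision alongside the hard-called ``GT``.

Genotype codes used in memory (dosage counts allele A1):

====  =============  ==========
code  genotype       dosage
====  =============  ==========
0     hom A1/A1      ~2
1     het A1/A2      ~1
2     hom A2/A2      ~0
-1    missing        elsewhere
====  =============  ==========
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import FileIOError, FormatError
from .mach_io import SampleId, format_dosage

BED_MAGIC = b"\x6c\x1b\x01"
MISSING = -1  # in-memory missing genotype code

#: Chromosome codes eligible for ``chr:pos`` variant-ID repair.
CHROM_CODES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "XY", "MT"])

_CHROM_POS_RE = re.compile(r"^(?:chr)?([0-9XYMT]{1,2}):(\d+)(?::\S+)?$", re.IGNORECASE)

# internal code (-1..2, offset by +1) -> 2-bit bed value
_CODE_TO_BITS = np.array([0b01, 0b00, 0b10, 0b11], dtype=np.uint8)
# 2-bit bed value -> internal code
_BITS_TO_CODE = np.array([0, MISSING, 1, 2], dtype=np.int8)


def parse_chrom_pos(variant_id: str) -> tuple[str, int] | None:
    """Extract ``(chrom, pos)`` from a ``chr:pos[:ref:alt]`` variant ID.

    Returns ``None`` for IDs (e.g. rs numbers) that do not follow the
    convention, or whose chromosome token is not a recognised code.
    """
    m = _CHROM_POS_RE.match(variant_id)
    if not m:
        return None
    chrom = m.group(1).upper()
    pos = int(m.group(2))
    if chrom not in CHROM_CODES or pos <= 0:
        return None
    return chrom, pos


@dataclass(frozen=True)
class BimRecord:
    """One ``.bim`` row: chromosome, variant ID, cM, bp position, alleles."""

    chrom: str
    id: str
    cm: float
    pos: int
    a1: str
    a2: str

    def __post_init__(self):
        if self.pos < 0:
            raise FormatError(f"variant {self.id}: negative position {self.pos}")
        if self.a1 == self.a2:
            raise FormatError(f"variant {self.id}: identical alleles {self.a1}")


@dataclass(frozen=True)
class FamRecord:
    """One ``.fam`` row. sex: 0 unknown / 1 male / 2 female; pheno -9 missing."""

    fid: str
    iid: str
    pid: str = "0"
    mid: str = "0"
    sex: int = 0
    pheno: str = "-9"

    def __post_init__(self):
        if self.sex not in (0, 1, 2):
            raise FormatError(f"sample {self.fid} {self.iid}: sex must be 0/1/2, got {self.sex}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.fid, self.iid)


@dataclass
class BedSet:
    """A PLINK1 fileset in memory: variants, samples, SNP-major genotypes.

    ``genotypes`` is int8 with shape ``(n_variants, n_samples)`` using the
    module's genotype codes (-1 missing).
    """

    bim: list[BimRecord]
    fam: list[FamRecord]
    genotypes: np.ndarray

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.bim), len(self.fam)):
            raise FormatError(
                f"genotype matrix shape {self.genotypes.shape} != "
                f"({len(self.bim)} variants, {len(self.fam)} samples)"
            )
        vals = np.unique(self.genotypes)
        if not np.all(np.isin(vals, [-1, 0, 1, 2])):
            raise FormatError(f"invalid genotype codes {vals}")

    @property
    def n_variants(self) -> int:
        return len(self.bim)

    @property
    def n_samples(self) -> int:
        return len(self.fam)


# ---------------------------------------------------------------------------
# hard calling


def hard_call_dosages(dosages: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """Hard-call a dosage array (any shape) to genotype codes.

    A dosage within ``threshold`` (inclusive) of an integer r in {0, 1, 2}
    becomes the code for r (dosage 2 -> hom A1 = code 0, 1 -> het, 0 -> hom
    A2 = code 2); everything else, including NaN, becomes missing.  The
    threshold must be < 0.5 so the nearest integer is unique.
    """
    if not 0 <= threshold < 0.5:
        raise FormatError(f"hard-call threshold must be in [0, 0.5), got {threshold}")
    d = np.asarray(dosages, dtype=np.float64)
    nearest = np.clip(np.rint(d), 0, 2)
    # small slack keeps the boundary inclusive under binary float rounding
    # (|1.9 - 2| evaluates a hair above 0.1)
    with np.errstate(invalid="ignore"):
        ok = np.abs(d - nearest) <= threshold + 1e-9
    ok &= np.isfinite(d)
    codes = np.where(ok, 2 - nearest, MISSING).astype(np.int8)
    return codes


def hard_call(dosage: float, threshold: float = 0.1) -> int:
    """Scalar convenience wrapper around :func:`hard_call_dosages`."""
    return int(hard_call_dosages(np.array([dosage]), threshold)[0])


# ---------------------------------------------------------------------------
# bed/bim/fam writing and reading


def write_bim(records: Sequence[BimRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.chrom, r.id, r.cm, r.pos, r.a1, r.a2) for r in records]
    ).to_csv(path, sep="\t", header=False, index=False)


def read_bim(path: str | Path) -> list[BimRecord]:
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 6:
        raise FormatError(f"{path}: expected 6 bim columns, found {df.shape[1]}")
    return [
        BimRecord(chrom=r[0], id=r[1], cm=float(r[2]), pos=int(r[3]), a1=r[4], a2=r[5])
        for r in df.itertuples(index=False)
    ]


def write_fam(records: Sequence[FamRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.fid, r.iid, r.pid, r.mid, r.sex, r.pheno) for r in records]
    ).to_csv(path, sep="\t", header=False, index=False)


def read_fam(path: str | Path) -> list[FamRecord]:
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 6:
        raise FormatError(f"{path}: expected 6 fam columns, found {df.shape[1]}")
    return [
        FamRecord(fid=r[0], iid=r[1], pid=r[2], mid=r[3], sex=int(r[4]), pheno=r[5])
        for r in df.itertuples(index=False)
    ]


def pack_genotypes(genotypes: np.ndarray) -> bytes:
    """Pack a (variants x samples) code matrix into SNP-major .bed bytes.

    Per variant, sample k occupies bits (2k mod 8)..(2k mod 8)+1 of byte
    floor(k/4); trailing pad bits in the last byte are zero.
    """
    g = np.asarray(genotypes, dtype=np.int8)
    m, n = g.shape
    n4 = -(-n // 4) * 4
    padded = np.zeros((m, n4), dtype=np.int8)  # pad code 0 -> bits 00
    padded[:, :n] = g
    bits = _CODE_TO_BITS[padded + 1].reshape(m, n4 // 4, 4)
    packed = (
        bits[:, :, 0] | (bits[:, :, 1] << 2) | (bits[:, :, 2] << 4) | (bits[:, :, 3] << 6)
    ).astype(np.uint8)
    return packed.tobytes()


def unpack_genotypes(body: bytes, n_variants: int, n_samples: int) -> np.ndarray:
    """Inverse of :func:`pack_genotypes`."""
    bpv = -(-n_samples // 4)  # bytes per variant
    raw = np.frombuffer(body, dtype=np.uint8).reshape(n_variants, bpv)
    codes = np.empty((n_variants, bpv * 4), dtype=np.int8)
    for k in range(4):
        codes[:, k::4] = _BITS_TO_CODE[(raw >> (2 * k)) & 0b11]
    return codes[:, :n_samples]


def write_bedset(bs: BedSet, prefix: str | Path) -> dict[str, Path]:
    """Write a fileset as ``prefix.bed``/``.bim``/``.fam``; returns the paths."""
    prefix = Path(prefix)
    paths = {ext: prefix.with_suffix(prefix.suffix + "." + ext) for ext in ("bed", "bim", "fam")}
    try:
        with open(paths["bed"], "wb") as fh:
            fh.write(BED_MAGIC)
            fh.write(pack_genotypes(bs.genotypes))
    except OSError as exc:
        raise FileIOError(f"cannot write {paths['bed']}: {exc}") from exc
    write_bim(bs.bim, paths["bim"])
    write_fam(bs.fam, paths["fam"])
    return paths


def read_bedset(prefix: str | Path) -> BedSet:
    """Read ``prefix.bed``/``.bim``/``.fam`` back into a :class:`BedSet`."""
    prefix = Path(prefix)
    bim = read_bim(prefix.with_suffix(prefix.suffix + ".bim"))
    fam = read_fam(prefix.with_suffix(prefix.suffix + ".fam"))
    bed_path = prefix.with_suffix(prefix.suffix + ".bed")
    try:
        data = bed_path.read_bytes()
    except OSError as exc:
        raise FileIOError(f"cannot read {bed_path}: {exc}") from exc
    if len(data) < 3 or data[:2] != BED_MAGIC[:2]:
        raise FormatError(f"{bed_path}: not a PLINK .bed file (bad magic)")
    if data[2] != 0x01:
        raise FormatError(f"{bed_path}: only SNP-major .bed (mode 0x01) is supported, got {data[2]:#04x}")
    expected = 3 + (-(-len(fam) // 4)) * len(bim)
    if len(data) != expected:
        raise FormatError(f"{bed_path}: expected {expected} bytes for {len(bim)} variants x {len(fam)} samples, found {len(data)} (truncated or corrupt)")
    genotypes = (
        unpack_genotypes(data[3:], len(bim), len(fam))
        if bim and fam
        else np.empty((len(bim), len(fam)), dtype=np.int8)
    )
    return BedSet(bim=bim, fam=fam, genotypes=genotypes)


# ---------------------------------------------------------------------------
# pdat -> BedSet, VCF output


def samples_to_fam(samples: Sequence[SampleId]) -> list[FamRecord]:
    """Default fam roster: founders, unknown sex, missing phenotype."""
    return [FamRecord(fid=s.family_id, iid=s.individual_id) for s in samples]


def pdat_to_bedset(pdat, threshold: float = 0.1) -> BedSet:
    """Hard-call a SNP-major dosage table into a PLINK1 fileset.

    Chromosome and position are written as 0 — the conversion does not retain
    them; the correction stage restores both from ``chr:pos`` variant IDs.
    """
    bim = [
        BimRecord(chrom="0", id=name, cm=0.0, pos=0, a1=a1, a2=a2)
        for name, a1, a2 in zip(pdat.names, pdat.al1, pdat.al2)
    ]
    fam = samples_to_fam(pdat.samples)
    return BedSet(bim=bim, fam=fam, genotypes=hard_call_dosages(pdat.dosages, threshold))


_CHROM_SORT = {c: i for i, c in enumerate([str(i) for i in range(1, 23)] + ["X", "Y", "XY", "MT"])}

_GT_BY_CODE = {0: "1/1", 1: "0/1", 2: "0/0", MISSING: "./."}


def write_dosage_vcf(
    pdat,
    path: str | Path,
    decimals: int = 4,
    threshold: float = 0.1,
) -> None:
    """Write the dosage-preserving VCF: ``GT:DS`` per sample, REF=A2, ALT=A1.

    DS carries the allele-A1 (ALT) dosage at ``decimals`` fixed decimal
    places; GT is the hard call at ``threshold``.  Records are sorted by
    (chromosome, position) parsed from ``chr:pos`` IDs; unparseable IDs get
    chromosome "." and position 0 (with a warning) and sort last.  Output is
    BGZF-compressed when the path ends in ``.gz``.
    """
    path = Path(path)
    entries = []
    n_unparsed = 0
    for j, (name, a1, a2) in enumerate(zip(pdat.names, pdat.al1, pdat.al2)):
        cp = parse_chrom_pos(name)
        if cp is None:
            n_unparsed += 1
            cp = (".", 0)
        entries.append((cp[0], cp[1], j, name, a1, a2))
    if n_unparsed:
        warnings.warn(
            f"{n_unparsed} variant IDs not in chr:pos form; written with CHROM='.' POS=0",
            stacklevel=2,
        )
    entries.sort(key=lambda e: (_CHROM_SORT.get(e[0], len(_CHROM_SORT)), e[1], e[2]))

    calls = hard_call_dosages(pdat.dosages, threshold)
    lines = ["##fileformat=VCFv4.2", "##source=machkit"]
    for chrom in dict.fromkeys(e[0] for e in entries):
        if chrom != ".":
            lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Hard-called genotype">')
    lines.append(
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Allele-1 (ALT) dosage in [0,2]">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(s.raw for s in pdat.samples)
    )
    for chrom, pos, j, name, a1, a2 in entries:
        fields = [chrom, str(pos), name, a2, a1, ".", ".", ".", "GT:DS"]
        row = pdat.dosages[j]
        fields.extend(
            f"{_GT_BY_CODE[int(calls[j, i])]}:{format_dosage(row[i], decimals).replace('NA', '.')}"
            for i in range(row.size)
        )
        lines.append("\t".join(fields))
    text = "\n".join(lines) + "\n"
    try:
        if path.suffix == ".gz":
            with pysam.BGZFile(str(path), "wb") as fh:
                fh.write(text.encode())
        else:
            path.write_text(text)
    except OSError as exc:
        raise FileIOError(f"cannot write {path}: {exc}") from exc
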