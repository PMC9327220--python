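"""Readers and writers for MaCH/minimac mldose and mlinfo filesets.

MaCH and minimac store imputation output per chromosome as a pair of files:

* ``.mlinfo`` / ``.info`` — one header line, then one row per SNP with the
  variant name (conventionally ``chr:pos``), the two alleles, the frequency of
  allele 1, the minor-allele frequency, and two imputation quality metrics.
* ``.mldose`` / ``.dose`` — sample-major matrix: one row per individual with a
  sample-ID token, a mode token (``ML_DOSE``/``DOSE``), and then one dosage
  per SNP in the info file.

A dosage is the expected count of allele ``Al1`` — a real number in [0, 2]
reflecting imputation uncertainty.  All readers here accept plain or
gzip-compressed input, detected from the file's magic bytes rather than its
extension.
"""

from __future__ import annotations

import gzip
import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import DimensionError, FileIOError, FormatError

#: Conventional mlinfo header (MaCH).  Columns are matched by position; a
#: differing header only triggers a warning so minimac variants still parse.
MLINFO_COLUMNS = ("SNP", "Al1", "Al2", "Freq1", "MAF", "Quality", "Rsq")

#: Tokens interpreted as a missing dosage or missing metric value.
MISSING_TOKENS = frozenset({"NA", "-9", ".", "-", "nan", "NaN"})

#: Dosages may stray outside [0, 2] by at most this much (float formatting).
DOSE_RANGE_TOL = 1e-6


def open_text(path: str | Path, mode: str = "rt"):
    """Open ``path`` for text I/O, transparently handling gzip.

    Reading sniffs the two gzip magic bytes (``1f 8b``) so a mis-named file
    still parses; writing compresses iff the path ends in ``.gz``.
    """
    path = Path(path)
    if "r" in mode:
        try:
            with open(path, "rb") as fh:
                magic = fh.read(2)
        except OSError as exc:
            raise FileIOError(f"cannot read {path}: {exc}") from exc
        if magic == b"\x1f\x8b":
            return io.TextIOWrapper(gzip.open(path, "rb"), newline=None)
        return open(path, "rt", newline=None)
    try:
        if path.suffix == ".gz":
            return io.TextIOWrapper(gzip.open(path, mode.replace("t", "") + "b"))
        return open(path, mode)
    except OSError as exc:
        raise FileIOError(f"cannot write {path}: {exc}") from exc


@dataclass(frozen=True)
class SampleId:
    """One individual, parsed from the dose file's first-column token.

    MaCH writes ``FID->IID``; tokens without the ``->`` separator are used as
    both family and individual ID.
    """

    family_id: str
    individual_id: str
    raw: str

    @classmethod
    def from_token(cls, token: str) -> "SampleId":
        if not token or any(c.isspace() for c in token):
            raise FormatError(f"invalid sample token {token!r}")
        if "->" in token:
            fid, iid = token.split("->", 1)
            return cls(fid, iid, token)
        return cls(token, token, token)

    @property
    def key(self) -> tuple[str, str]:
        return (self.family_id, self.individual_id)


def parse_sample_token(token: str) -> SampleId:
    """Split a ``FID->IID`` token on its *first* ``->`` separator."""
    return SampleId.from_token(token)


@dataclass(frozen=True)
class SnpInfoRecord:
    """One mlinfo row: variant name, alleles, frequency and quality metrics.

    Numeric metrics are ``None`` when the file marks them missing.
    """

    name: str
    al1: str
    al2: str
    freq1: float | None = None
    maf: float | None = None
    quality: float | None = None
    rsq: float | None = None

    def __post_init__(self):
        if not self.name:
            raise FormatError("SNP name must be non-empty")
        if self.al1 == self.al2:
            raise FormatError(f"SNP {self.name}: alleles must differ, got {self.al1}/{self.al2}")
        if self.maf is not None and self.maf > 0.5 + 1e-9:
            raise FormatError(f"SNP {self.name}: MAF {self.maf} exceeds 0.5")


@dataclass
class DoseBlock:
    """Sample-major dosage matrix for one chromosome.

    ``dosages`` is ``float64`` with shape ``(n_samples, m_snps)``; missing
    values are NaN.  ``mode_tokens`` preserves the second dose-file column
    verbatim for round-tripping.
    """

    samples: list[SampleId]
    snps: list[SnpInfoRecord]
    dosages: np.ndarray
    chrom_label: str = ""
    mode_tokens: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise DimensionError(
                f"dosage matrix shape {self.dosages.shape} != "
                f"({len(self.samples)} samples, {len(self.snps)} SNPs)"
            )
        if not self.mode_tokens:
            self.mode_tokens = ["ML_DOSE"] * len(self.samples)
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < -DOSE_RANGE_TOL or finite.max() > 2 + DOSE_RANGE_TOL):
            raise FormatError("dosages must lie in [0, 2]")
        raws = [s.raw for s in self.samples]
        if len(set(raws)) != len(raws):
            raise FormatError("duplicate sample IDs within one dose block")
        names = [s.name for s in self.snps]
        if len(set(names)) != len(names):
            raise FormatError("duplicate SNP names within one block")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def m_snps(self) -> int:
        return len(self.snps)


def _parse_metric(token: str, what: str, line_no: int) -> float | None:
    if token in MISSING_TOKENS:
        return None
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"line {line_no}: cannot parse {what} value {token!r}") from None


def read_mlinfo(path: str | Path) -> list[SnpInfoRecord]:
    """Parse an mlinfo file into records, preserving file order.

    The first line is treated as a header; columns are matched by position
    against the MaCH convention ``SNP Al1 Al2 Freq1 MAF Quality Rsq`` with a
    warning (not an error) when the names differ, so minimac files with extra
    trailing columns still parse.
    """
    records: list[SnpInfoRecord] = []
    with open_text(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: missing mlinfo header line")
        head_cols = header.split()
        if len(head_cols) < 7:
            raise FormatError(f"{path}: line 1: expected >=7 header columns, found {len(head_cols)}")
        if tuple(c.lower() for c in head_cols[:7]) != tuple(c.lower() for c in MLINFO_COLUMNS):
            warnings.warn(
                f"{path}: unexpected mlinfo header {head_cols[:7]}; "
                f"columns are taken by position as {MLINFO_COLUMNS}",
                stacklevel=2,
            )
        for line_no, line in enumerate(fh, start=2):
            cols = line.split()
            if not cols:
                continue
            if len(cols) < 7:
                raise FormatError(f"{path}: line {line_no}: expected >=7 columns, found {len(cols)}")
            records.append(
                SnpInfoRecord(
                    name=cols[0],
                    al1=cols[1],
                    al2=cols[2],
                    freq1=_parse_metric(cols[3], "Freq1", line_no),
                    maf=_parse_metric(cols[4], "MAF", line_no),
                    quality=_parse_metric(cols[5], "Quality", line_no),
                    rsq=_parse_metric(cols[6], "Rsq", line_no),
                )
            )
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise FormatError(f"{path}: duplicate SNP name {dup!r}")
    return records


def iter_mldose_rows(path: str | Path) -> Iterator[tuple[SampleId, str, np.ndarray]]:
    """Stream an mldose file row by row.

    Yields ``(sample, mode_token, dosage_vector)`` per individual; dosage
    vectors are float64 with NaN for missing.  Validates the [0, 2] range and
    that every row has the same number of columns as the first.
    """
    expected_m: int | None = None
    with open_text(path) as fh:
        for row_idx, line in enumerate(fh):
            cols = line.split()
            if not cols:
                continue
            if len(cols) < 2:
                raise FormatError(f"{path}: row {row_idx}: expected sample ID and mode token")
            sample = SampleId.from_token(cols[0])
            mode = cols[1]
            values = np.array(
                [math.nan if c in MISSING_TOKENS else float(c) for c in cols[2:]],
                dtype=np.float64,
            )
            if expected_m is None:
                expected_m = values.size
            elif values.size != expected_m:
                raise FormatError(
                    f"{path}: row {row_idx}: {values.size} dosages, expected {expected_m} (ragged file)"
                )
            finite = values[np.isfinite(values)]
            if finite.size and (finite.min() < -DOSE_RANGE_TOL or finite.max() > 2 + DOSE_RANGE_TOL):
                bad = finite[(finite < -DOSE_RANGE_TOL) | (finite > 2 + DOSE_RANGE_TOL)][0]
                raise FormatError(f"{path}: row {row_idx}: dosage {bad} outside [0, 2]")
            yield sample, mode, values


def read_mldose(
    path: str | Path,
    expected_snps: Sequence[SnpInfoRecord] | None = None,
    chrom_label: str = "",
) -> DoseBlock:
    """Read a whole mldose file into a :class:`DoseBlock`.

    When ``expected_snps`` is given (the companion mlinfo records), the number
    of dosage columns must equal its length.
    """
    samples: list[SampleId] = []
    modes: list[str] = []
    rows: list[np.ndarray] = []
    for sample, mode, values in iter_mldose_rows(path):
        if expected_snps is not None and values.size != len(expected_snps):
            raise DimensionError(
                f"{path}: row {len(rows)}: {values.size} dosages but mlinfo lists "
                f"{len(expected_snps)} SNPs"
            )
        samples.append(sample)
        modes.append(mode)
        rows.append(values)
    m = rows[0].size if rows else (len(expected_snps) if expected_snps else 0)
    dosages = np.vstack(rows) if rows else np.empty((0, m))
    snps = (
        list(expected_snps)
        if expected_snps is not None
        else [SnpInfoRecord(name=f"snp{j}", al1="A", al2="B") for j in range(m)]
    )
    return DoseBlock(samples=samples, snps=snps, dosages=dosages, chrom_label=chrom_label, mode_tokens=modes)


def format_dosage(value: float, decimals: int) -> str:
    """Fixed-decimal dosage text; NaN renders as ``NA``."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{value:.{decimals}f}"


def write_mldose(block: DoseBlock, path: str | Path, decimals: int = 4) -> None:
    """Write a :class:`DoseBlock` as an mldose file (gzip iff path ends .gz).

    Round-tripping through :func:`read_mldose` reproduces every dosage within
    ``0.5 * 10**-decimals``.
    """
    with open_text(path, "wt") as fh:
        for i, sample in enumerate(block.samples):
            vals = " ".join(format_dosage(v, decimals) for v in block.dosages[i])
            fh.write(f"{sample.raw} {block.mode_tokens[i]}" + (" " + vals if vals else "") + "\n")


def write_mlinfo(records: Sequence[SnpInfoRecord], path: str | Path) -> None:
    """Write mlinfo records with the conventional MaCH header."""

    def fmt(v: float | None) -> str:
        return "-" if v is None else f"{v:.4f}"

    with open_text(path, "wt") as fh:
        fh.write("\t".join(MLINFO_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.name}\t{r.al1}\t{r.al2}\t{fmt(r.freq1)}\t{fmt(r.maf)}\t"
                f"{fmt(r.quality)}\t{fmt(r.rsq)}\n"
            )
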