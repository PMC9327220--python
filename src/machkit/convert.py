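"""The convert pipeline: consent groups -> QC -> pdat/pfam -> PLINK outputs.

dbGaP cohorts such as the Women's Health Initiative distribute imputed
genotypes split by *consent group*: each chromosome's dose file is sharded
across groups while the per-chromosome info file is shared.  Analysis needs
the whole cohort back together, so the pipeline

1. concatenates each chromosome's group dose files row-wise (samples) and
   carries over the shared info file,
2. runs a structural QC check — the dose file must have exactly one more
   column than the info file has lines (ID + mode columns on the dose side
   versus the single header line on the info side),
3. transposes the sample-major dose matrix to the SNP-major ``pdat`` table
   with its companion ``pfam`` sample roster,
4. concatenates the per-chromosome pdat tables genome-wide (all chromosomes
   must carry the identical sample roster; this is verified, not assumed),
5. emits the PLINK1 hard-called bed/bim/fam fileset and the
   dosage-preserving VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import plink_io
from .errors import ArgumentError, FileIOError, FormatError, HarmonizationError, IdentityError, QcError
from .mach_io import (
    DoseBlock,
    SampleId,
    SnpInfoRecord,
    format_dosage,
    open_text,
    read_mldose,
    read_mlinfo,
)

logger = logging.getLogger("machkit")


@dataclass
class QcReport:
    """Result of the structural consistency check on a (dose, info) pair.

    ``passed`` is true iff the dose column count equals the info line count
    plus one and every dose row has the same number of columns.
    """

    info_line_count: int
    dose_column_count: int
    passed: bool
    messages: list[str] = field(default_factory=list)
    per_file_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [
            f"info lines (incl. header): {self.info_line_count}",
            f"dose columns:              {self.dose_column_count}",
            f"expected dose columns:     info lines + 1 = {self.info_line_count + 1}",
            f"result: {'PASS' if self.passed else 'FAIL'}",
        ]
        for path, (rows, cols) in self.per_file_counts.items():
            lines.append(f"  {path}: {rows} rows x {cols} columns")
        lines.extend("  " + m for m in self.messages)
        return "\n".join(lines) + "\n"


@dataclass
class PdatSet:
    """SNP-major dosage table plus its companion sample roster.

    ``dosages`` has shape ``(m_snps, n_samples)``; row j holds variant
    ``names[j]`` with alleles ``al1[j]``/``al2[j]`` (the dosage counts al1).
    """

    names: list[str]
    al1: list[str]
    al2: list[str]
    dosages: np.ndarray
    samples: list[SampleId]
    source_chroms: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.names), len(self.samples)):
            raise FormatError(
                f"pdat matrix shape {self.dosages.shape} != "
                f"({len(self.names)} SNPs, {len(self.samples)} samples)"
            )
        if len(set(self.names)) != len(self.names):
            dup = next(n for n in self.names if self.names.count(n) > 1)
            raise FormatError(f"duplicate SNP name {dup!r} in pdat set")

    @property
    def m_snps(self) -> int:
        return len(self.names)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# stage 1: consent-group combination


def _check_info_concordance(reference: list[SnpInfoRecord], other: list[SnpInfoRecord], ref_path, other_path) -> None:
    if len(reference) != len(other):
        raise HarmonizationError(
            f"{other_path}: {len(other)} SNPs but {ref_path} has {len(reference)}"
        )
    for j, (a, b) in enumerate(zip(reference, other)):
        if a.name != b.name or a.al1 != b.al1 or a.al2 != b.al2:
            raise HarmonizationError(
                f"{other_path}: SNP {j} is {b.name} {b.al1}/{b.al2} but "
                f"{ref_path} has {a.name} {a.al1}/{a.al2}"
            )


def combine_consent_groups(
    dose_paths: Sequence[str | Path],
    info_paths: Sequence[str | Path],
    out_dose: str | Path,
    out_info: str | Path,
) -> QcReport:
    """Row-concatenate per-group dose files for one chromosome.

    All groups' info files must describe the identical SNP list (name, order,
    alleles) — this is verified before any dose row is written, because a
    silent misalignment would corrupt every downstream dosage.  Sample IDs
    must be unique across groups.  The combined info file is the first
    group's, re-written uncompressed.  Returns the QC report for the combined
    pair (see :func:`qc_check`).
    """
    if len(dose_paths) < 1:
        raise ArgumentError("at least one consent group is required")
    if len(dose_paths) != len(info_paths):
        raise ArgumentError(
            f"{len(dose_paths)} dose files but {len(info_paths)} info files"
        )
    reference = read_mlinfo(info_paths[0])
    for p in info_paths[1:]:
        _check_info_concordance(reference, read_mlinfo(p), info_paths[0], p)

    seen: set[str] = set()
    with open_text(out_dose, "wt") as out:
        for dose_path in dose_paths:
            with open_text(dose_path) as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    token = line.split(None, 1)[0]
                    if token in seen:
                        raise IdentityError(
                            f"{dose_path}: sample {token!r} already present in an earlier group"
                        )
                    seen.add(token)
                    out.write(line.rstrip("\r\n") + "\n")
    # combined info == group-1 info, uncompressed
    with open_text(info_paths[0]) as src, open_text(out_info, "wt") as dst:
        for line in src:
            dst.write(line.rstrip("\r\n") + "\n")
    return qc_check(out_dose, out_info)


# ---------------------------------------------------------------------------
# stage 2: structural QC


def qc_check(
    dose_path: str | Path,
    info_path: str | Path,
    report_path: str | Path | None = None,
) -> QcReport:
    """Compare dose column count against info line count.

    With n SNPs the info file has n + 1 lines (header included) and each dose
    row has n + 2 columns (sample ID + mode token + n dosages), so the dose
    file must show exactly one more column than the info file has lines.  The
    column count is taken from the first dose row and verified constant; a
    ragged file produces a failed report (not an exception).  When
    ``report_path`` is given the report text is also written there.
    """
    with open_text(info_path) as fh:
        info_lines = sum(1 for line in fh if line.strip())
    messages: list[str] = []
    dose_cols = 0
    dose_rows = 0
    with open_text(dose_path) as fh:
        for idx, line in enumerate(fh):
            cols = len(line.split())
            if cols == 0:
                continue
            if dose_rows == 0:
                dose_cols = cols
            elif cols != dose_cols:
                messages.append(f"row {idx}: {cols} columns, expected {dose_cols}")
            dose_rows += 1
    passed = not messages and dose_cols == info_lines + 1
    if dose_cols != info_lines + 1:
        messages.append(
            f"dose has {dose_cols} columns; expected info lines + 1 = {info_lines + 1}"
        )
    report = QcReport(
        info_line_count=info_lines,
        dose_column_count=dose_cols,
        passed=passed,
        messages=messages,
        per_file_counts={
            str(dose_path): (dose_rows, dose_cols),
            str(info_path): (info_lines, 7),
        },
    )
    if report_path is not None:
        with open(report_path, "at") as fh:
            fh.write(f"== QC: {dose_path} vs {info_path} ==\n")
            fh.write(report.to_text())
    return report


# ---------------------------------------------------------------------------
# stage 3: transposition


def dose_to_pdat(block: DoseBlock) -> PdatSet:
    """Transpose a sample-major :class:`DoseBlock` to the SNP-major pdat form.

    Exact transposition — no precision is lost in memory; the sample roster
    preserves input order and A1/A2 carry over from the info records.
    """
    return PdatSet(
        names=[s.name for s in block.snps],
        al1=[s.al1 for s in block.snps],
        al2=[s.al2 for s in block.snps],
        dosages=block.dosages.T.copy(),
        samples=list(block.samples),
        source_chroms=[block.chrom_label] if block.chrom_label else [],
    )


def concat_pdats(per_chrom: Sequence[PdatSet]) -> PdatSet:
    """Concatenate per-chromosome pdat tables genome-wide.

    Every input must carry the identical sample roster (same raw IDs, same
    order) — each chromosome of a cohort contains the same participants, and
    the shared-roster assumption behind reusing one pfam file is checked
    here rather than trusted.
    """
    if not per_chrom:
        raise ArgumentError("no pdat sets to concatenate")
    first = per_chrom[0]
    roster = [s.raw for s in first.samples]
    for k, p in enumerate(per_chrom[1:], start=1):
        other = [s.raw for s in p.samples]
        if other != roster:
            pos = next(
                (i for i, (a, b) in enumerate(zip(roster, other)) if a != b),
                min(len(roster), len(other)),
            )
            raise HarmonizationError(
                f"pdat set {k}: sample roster differs from set 0 at position {pos}"
            )
    names = [n for p in per_chrom for n in p.names]
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise HarmonizationError(f"SNP {dup!r} appears on more than one chromosome")
    return PdatSet(
        names=names,
        al1=[a for p in per_chrom for a in p.al1],
        al2=[a for p in per_chrom for a in p.al2],
        dosages=np.vstack([p.dosages for p in per_chrom]),
        samples=list(first.samples),
        source_chroms=[c for p in per_chrom for c in p.source_chroms],
    )


# ---------------------------------------------------------------------------
# pdat / pfam file formats


def write_pdat(pdat: PdatSet, path: str | Path, decimals: int = 2) -> None:
    """Write the SNP-major dosage table.

    Header ``SNP A1 A2`` followed by one FID->IID token per sample, then one
    row per SNP: name, alleles, and one fixed-decimal dosage per sample.  Two
    decimal places by default (the precision PLINK1's dosage path retains).
    """
    with open_text(path, "wt") as fh:
        fh.write("SNP A1 A2 " + " ".join(s.raw for s in pdat.samples) + "\n")
        for j in range(pdat.m_snps):
            vals = " ".join(format_dosage(v, decimals) for v in pdat.dosages[j])
            fh.write(f"{pdat.names[j]} {pdat.al1[j]} {pdat.al2[j]} {vals}\n")


def read_pdat(path: str | Path) -> PdatSet:
    """Read a pdat file back; sample IDs are taken from the header."""
    names: list[str] = []
    al1: list[str] = []
    al2: list[str] = []
    rows: list[np.ndarray] = []
    with open_text(path) as fh:
        header = fh.readline().split()
        if header[:3] != ["SNP", "A1", "A2"]:
            raise FormatError(f"{path}: pdat header must start 'SNP A1 A2', got {header[:3]}")
        samples = [SampleId.from_token(t) for t in header[3:]]
        for line_no, line in enumerate(fh, start=2):
            cols = line.split()
            if not cols:
                continue
            if len(cols) != 3 + len(samples):
                raise FormatError(
                    f"{path}: line {line_no}: {len(cols)} columns, expected {3 + len(samples)}"
                )
            names.append(cols[0])
            al1.append(cols[1])
            al2.append(cols[2])
            rows.append(
                np.array([np.nan if c == "NA" else float(c) for c in cols[3:]], dtype=np.float64)
            )
    dosages = np.vstack(rows) if rows else np.empty((0, len(samples)))
    return PdatSet(names=names, al1=al1, al2=al2, dosages=dosages, samples=samples)


def write_pfam(samples: Sequence[SampleId], path: str | Path) -> None:
    """Write the sample roster: ``FID IID 0 0 0 -9`` per sample."""
    with open_text(path, "wt") as fh:
        for s in samples:
            fh.write(f"{s.family_id} {s.individual_id} 0 0 0 -9\n")


def read_pfam(path: str | Path) -> list[SampleId]:
    samples = []
    with open_text(path) as fh:
        for line in fh:
            cols = line.split()
            if not cols:
                continue
            if len(cols) != 6:
                raise FormatError(f"{path}: pfam rows need 6 columns, found {len(cols)}")
            fid, iid = cols[0], cols[1]
            raw = fid if fid == iid else f"{fid}->{iid}"
            samples.append(SampleId(fid, iid, raw))
    return samples


# ---------------------------------------------------------------------------
# full pipeline


_DOSE_SUFFIXES = (".mldose", ".dose", ".mldose.gz", ".dose.gz")
_INFO_SUFFIXES = (".mlinfo", ".info", ".mlinfo.gz", ".info.gz")


def find_chrom_file(directory: str | Path, pattern: str, chrom: str, kind: str) -> Path:
    """Locate the dose or info file for one chromosome.

    ``pattern`` is a filename stem template with a ``{chrom}`` placeholder
    (default ``chr{chrom}``); the stem is tried with each conventional
    extension, plain then gzipped.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileIOError(f"not a readable directory: {directory}")
    stem = pattern.format(chrom=chrom)
    suffixes = _DOSE_SUFFIXES if kind == "dose" else _INFO_SUFFIXES
    for suffix in suffixes:
        candidate = directory / (stem + suffix)
        if candidate.exists():
            return candidate
    raise FileIOError(
        f"no {kind} file for chromosome {chrom} in {directory} (tried {stem}{{{','.join(suffixes)}}})"
    )


def detect_chroms(directory: str | Path, pattern: str = "chr{chrom}") -> list[str]:
    """Chromosomes (1..22 in natural order, then X/Y if present) with a dose file."""
    found = []
    for chrom in [str(i) for i in range(1, 23)] + ["X", "Y"]:
        try:
            find_chrom_file(directory, pattern, chrom, "dose")
        except FileIOError:
            continue
        found.append(chrom)
    return found


def run_convert_mac(
    groups: Sequence[tuple[str | Path, str | Path]],
    project: str,
    out_dir: str | Path,
    pattern: str = "chr{chrom}",
    chroms: Sequence[str] | None = None,
    hard_call_threshold: float = 0.1,
    decimals_pdat: int = 2,
    decimals_vcf: int = 4,
) -> dict[str, object]:
    """Run the whole conversion for a multi-group, multi-chromosome cohort.

    ``groups`` is an ordered list of ``(dose_dir, info_dir)`` pairs, one per
    consent group.  When ``chroms`` is None the chromosomes are detected from
    the first group's dose directory.  Produces, under ``out_dir``:
    per-chromosome combined dose/info files, the QC report, the genome-wide
    ``<project>.pdat``/``.pfam``, the hard-called ``<project>.bed/.bim/.fam``
    and the dosage-preserving ``<project>.dose.vcf.gz``.  Raises
    :class:`QcError` (and the run aborts) if any chromosome fails QC.
    """
    if not groups:
        raise ArgumentError("at least one consent group is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / f"{project}.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        if chroms is None:
            chroms = detect_chroms(groups[0][0], pattern)
            if not chroms:
                raise FileIOError(f"no dose files matching {pattern!r} found in {groups[0][0]}")
        logger.info("convert: project=%s groups=%d chroms=%s", project, len(groups), list(chroms))

        qc_path = out_dir / f"{project}.qc.txt"
        qc_path.unlink(missing_ok=True)
        qc_reports: dict[str, QcReport] = {}
        pdats: list[PdatSet] = []
        for chrom in chroms:
            dose_paths = [find_chrom_file(d, pattern, chrom, "dose") for d, _ in groups]
            info_paths = [find_chrom_file(i, pattern, chrom, "info") for _, i in groups]
            combined_dose = out_dir / f"{project}.chr{chrom}.dose"
            combined_info = out_dir / f"{project}.chr{chrom}.info"
            logger.info("chr%s: combining %d consent group(s)", chrom, len(groups))
            combine_consent_groups(dose_paths, info_paths, combined_dose, combined_info)
            report = qc_check(combined_dose, combined_info, report_path=qc_path)
            qc_reports[chrom] = report
            if not report.passed:
                raise QcError(
                    f"QC failed for chromosome {chrom}: " + "; ".join(report.messages)
                )
            logger.info(
                "chr%s: QC pass (%d info lines, %d dose columns)",
                chrom, report.info_line_count, report.dose_column_count,
            )
            snps = read_mlinfo(combined_info)
            block = read_mldose(combined_dose, expected_snps=snps, chrom_label=str(chrom))
            pdats.append(dose_to_pdat(block))

        genome = concat_pdats(pdats)
        logger.info("genome-wide: %d SNPs x %d samples", genome.m_snps, genome.n_samples)
        pdat_path = out_dir / f"{project}.pdat"
        pfam_path = out_dir / f"{project}.pfam"
        write_pdat(genome, pdat_path, decimals=decimals_pdat)
        write_pfam(genome.samples, pfam_path)

        bedset = plink_io.pdat_to_bedset(genome, threshold=hard_call_threshold)
        bed_paths = plink_io.write_bedset(bedset, out_dir / project)
        vcf_path = out_dir / f"{project}.dose.vcf.gz"
        plink_io.write_dosage_vcf(genome, vcf_path, decimals=decimals_vcf, threshold=hard_call_threshold)
        logger.info("wrote %s, %s, %s, %s", pdat_path, pfam_path, bed_paths["bed"], vcf_path)
        return {
            "pdat": pdat_path,
            "pfam": pfam_path,
            "qc": qc_path,
            "qc_reports": qc_reports,
            "log": log_path,
            "vcf": vcf_path,
            "pdat_set": genome,
            "bedset": bedset,
            **bed_paths,
        }
    finally:
        logger.removeHandler(handler)
        handler.close()
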