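"""Post-conversion repair: restore chrom/pos metadata and update sample sex.

Converting a dosage fileset to PLINK loses the chromosome and base-pair
position — the bim rows come out with chromosome 0 and position 0.  Because
imputed variants are conventionally named ``chr:pos`` (optionally
``chr:pos:ref:alt``), both fields can be recovered from the variant ID
itself.  IDs that do not follow the convention (e.g. rs numbers) are left
untouched and counted, never guessed at.

Sex is similarly absent after conversion (fam sex code 0 = unknown) and is
filled in from an external ``FID IID SEX`` table, the same shape PLINK's
``--update-sex`` consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from .errors import FormatError
from .plink_io import BedSet, BimRecord, FamRecord, parse_chrom_pos, read_bedset, write_bedset


@dataclass
class CorrectionReport:
    total: int = 0
    corrected: int = 0
    already_correct: int = 0
    unparseable: int = 0
    messages: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        return (
            f"variants examined:   {self.total}\n"
            f"chrom/pos corrected: {self.corrected}\n"
            f"already correct:     {self.already_correct}\n"
            f"unparseable IDs:     {self.unparseable}\n"
            + "".join("  " + m + "\n" for m in self.messages)
        )


def correct_bim(records: Sequence[BimRecord]) -> tuple[list[BimRecord], CorrectionReport]:
    """Overwrite chrom/pos from ``chr:pos``-style variant IDs.

    Idempotent; record count, order and alleles are never altered.  IDs not
    matching the convention are reported in ``unparseable``.
    """
    report = CorrectionReport(total=len(records))
    out: list[BimRecord] = []
    for rec in records:
        cp = parse_chrom_pos(rec.id)
        if cp is None:
            report.unparseable += 1
            report.messages.append(f"cannot parse chrom:pos from ID {rec.id!r}; left unchanged")
            out.append(rec)
            continue
        chrom, pos = cp
        if rec.chrom == chrom and rec.pos == pos:
            report.already_correct += 1
            out.append(rec)
        else:
            report.corrected += 1
            out.append(replace(rec, chrom=chrom, pos=pos))
    return out, report


_SEX_TOKENS = {"0": 0, "1": 1, "2": 2, "M": 1, "F": 2, "m": 1, "f": 2}


def parse_sex_token(token: str) -> int:
    if token not in _SEX_TOKENS:
        raise FormatError(f"invalid sex token {token!r} (expected 0/1/2 or M/F)")
    return _SEX_TOKENS[token]


@dataclass
class SexUpdateReport:
    updated: int = 0
    unmatched: list[tuple[str, str]] = field(default_factory=list)

    def to_text(self) -> str:
        text = f"samples updated: {self.updated}\n"
        for fid, iid in self.unmatched:
            text += f"  no fam match for {fid} {iid}\n"
        return text


def update_sex(
    fam: Sequence[FamRecord],
    sex_map: Mapping[tuple[str, str], int | str],
) -> tuple[list[FamRecord], SexUpdateReport]:
    """Apply a ``(FID, IID) -> sex`` mapping to a fam roster.

    Unmatched fam rows pass through untouched; map entries with no fam match
    are listed in the report rather than raising.
    """
    codes = {key: parse_sex_token(str(v)) for key, v in sex_map.items()}
    report = SexUpdateReport()
    out: list[FamRecord] = []
    matched: set[tuple[str, str]] = set()
    for rec in fam:
        if rec.key in codes:
            out.append(replace(rec, sex=codes[rec.key]))
            matched.add(rec.key)
            report.updated += 1
        else:
            out.append(rec)
    report.unmatched = [k for k in codes if k not in matched]
    return out, report


def read_sex_file(path: str | Path) -> dict[tuple[str, str], str]:
    """Read a whitespace-delimited ``FID IID SEX`` file."""
    mapping: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            cols = line.split()
            if not cols:
                continue
            if len(cols) != 3:
                raise FormatError(f"{path}: line {line_no}: expected 'FID IID SEX', found {len(cols)} columns")
            mapping[(cols[0], cols[1])] = cols[2]
    return mapping


def run_correct_files(
    bfile: str | Path,
    out_prefix: str | Path,
    sex_file: str | Path | None = None,
) -> tuple[CorrectionReport, SexUpdateReport | None]:
    """Correct a bed/bim/fam fileset on disk and write it under ``out_prefix``."""
    bs = read_bedset(bfile)
    bim, bim_report = correct_bim(bs.bim)
    fam = bs.fam
    sex_report = None
    if sex_file is not None:
        fam, sex_report = update_sex(fam, read_sex_file(sex_file))
    write_bedset(BedSet(bim=bim, fam=fam, genotypes=bs.genotypes), out_prefix)
    report_path = Path(str(out_prefix) + ".correction.txt")
    with open(report_path, "wt") as fh:
        fh.write(bim_report.to_text())
        if sex_report is not None:
            fh.write(sex_report.to_text())
    return bim_report, sex_report
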