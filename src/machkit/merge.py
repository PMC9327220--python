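"""Combine already-harmonized PLINK1 filesets on their common SNPs.

Multi-cohort GWAS needs the sub-studies (e.g. the imputation sub-studies of
a large cohort) in one fileset.  This stage intersects the variant lists of
all inputs, verifies that every shared variant carries identical chromosome,
position and allele orientation, and stacks the samples.  No harmonization
is performed — allele flips or strand swaps are treated as user errors, not
repaired silently.  Inputs are assumed straight out of the conversion stage,
so chrom/pos repair is applied to each before intersecting.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .correct import correct_bim
from .errors import ArgumentError, EmptyIntersectionError, HarmonizationError, IdentityError
from .plink_io import BedSet, BimRecord, read_bedset, write_bedset


def common_snps(
    bims: Sequence[Sequence[BimRecord]],
    out_path: str | Path | None = None,
) -> list[str]:
    """Variant IDs present in every dataset, in first-dataset order.

    Refuses an empty intersection — merging zero SNPs is never intended.
    When ``out_path`` is given the list is also written one ID per line
    (consumable by PLINK ``--extract``).
    """
    if len(bims) < 2:
        raise ArgumentError(f"need at least 2 datasets to intersect, got {len(bims)}")
    shared = set(r.id for r in bims[0])
    for bim in bims[1:]:
        shared &= {r.id for r in bim}
    ordered = [r.id for r in bims[0] if r.id in shared]
    if not ordered:
        raise EmptyIntersectionError("no SNP is common to all datasets")
    if out_path is not None:
        Path(out_path).write_text("\n".join(ordered) + "\n")
    return ordered


def merge_bedsets(sets: Sequence[BedSet]) -> BedSet:
    """Merge filesets on their common SNPs; samples are concatenated.

    Every common SNP must agree on chromosome, position and the (a1, a2)
    pair with identical orientation across all inputs; sample identities
    must be disjoint.  Genotypes are copied block-wise with no recoding.
    """
    ids = common_snps([s.bim for s in sets])
    seen: set[tuple[str, str]] = set()
    for s in sets:
        for rec in s.fam:
            if rec.key in seen:
                raise IdentityError(f"sample {rec.key} occurs in more than one dataset")
            seen.add(rec.key)

    by_id = [{r.id: j for j, r in enumerate(s.bim)} for s in sets]
    reference = {r.id: r for r in sets[0].bim}
    for k, s in enumerate(sets[1:], start=1):
        for vid in ids:
            a, b = reference[vid], s.bim[by_id[k][vid]]
            if (a.chrom, a.pos) != (b.chrom, b.pos):
                raise HarmonizationError(
                    f"SNP {vid}: chrom/pos {b.chrom}:{b.pos} in dataset {k} "
                    f"differs from {a.chrom}:{a.pos} in dataset 0"
                )
            if (a.a1, a.a2) != (b.a1, b.a2):
                raise HarmonizationError(
                    f"SNP {vid}: alleles {b.a1}/{b.a2} in dataset {k} differ in "
                    f"orientation from {a.a1}/{a.a2} in dataset 0 (no silent flip is applied)"
                )

    bim = [reference[vid] for vid in ids]
    fam = [rec for s in sets for rec in s.fam]
    blocks = [s.genotypes[[by_id[k][vid] for vid in ids], :] for k, s in enumerate(sets)]
    return BedSet(bim=bim, fam=fam, genotypes=np.hstack(blocks))


def run_combine_datasets(
    dataset_prefixes: Sequence[str | Path],
    project: str,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Read, chrom/pos-correct, intersect and merge filesets on disk.

    Writes ``<project>.bed/.bim/.fam``, the common-SNP list and a merge
    report under ``out_dir``.
    """
    if len(dataset_prefixes) < 2:
        raise ArgumentError(f"need at least 2 datasets to combine, got {len(dataset_prefixes)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sets = []
    for prefix in dataset_prefixes:
        bs = read_bedset(prefix)
        bim, _ = correct_bim(bs.bim)
        sets.append(BedSet(bim=bim, fam=bs.fam, genotypes=bs.genotypes))
    snp_list = out_dir / f"{project}.common_snps.txt"
    ids = common_snps([s.bim for s in sets], out_path=snp_list)
    merged = merge_bedsets(sets)
    paths = write_bedset(merged, out_dir / project)
    report = out_dir / f"{project}.merge.txt"
    with open(report, "wt") as fh:
        fh.write(f"datasets merged: {len(sets)}\n")
        for prefix, s in zip(dataset_prefixes, sets):
            fh.write(f"  {prefix}: {s.n_variants} SNPs x {s.n_samples} samples\n")
        fh.write(f"common SNPs: {len(ids)}\n")
        fh.write(f"merged: {merged.n_variants} SNPs x {merged.n_samples} samples\n")
    return {"snp_list": snp_list, "report": report, **paths}
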