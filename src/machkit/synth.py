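"""Synthetic MaCH fileset generator with known ground truth.

Real cohort dosage data is access-controlled, so every pipeline stage is
exercised against generated filesets instead.  The generator emulates the
distribution layout of an imputed dbGaP cohort: per-chromosome,
per-consent-group mldose files plus one shared mlinfo file per chromosome,
with variants named ``chrom:pos``.

Generative model, per SNP j and sample i:

* allele-1 frequency  f_j ~ Uniform(0.05, 0.95)   (monomorphic SNPs avoided)
* true genotype       g_ij ~ Binomial(2, f_j)      (count of allele 1)
* dosage              d_ij = clip(g_ij + Normal(0, noise_sd), 0, 2)

The truncated-Gaussian dosage noise mimics imputation uncertainty and makes
the hard-call error rate analytically tractable: a call at threshold t is
wrong-or-missing roughly when |Normal(0, sd)| > t (edge genotypes clip, so
the observed rate sits slightly below 2*(1 - Phi(t/sd))).

Everything is reproducible from the integer seed; the same call writes
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ArgumentError
from .mach_io import DoseBlock, SampleId, SnpInfoRecord, write_mldose, write_mlinfo

_ALLELES = np.array(list("ACGT"))


@dataclass
class SynthTruth:
    """Ground truth behind one generated dataset."""

    true_genotypes: np.ndarray  # (n_samples, total_snps), allele-1 counts
    allele_freqs: np.ndarray  # per-SNP allele-1 frequency used for simulation
    noise_sd: float
    group_assignment: list[int]  # sample index -> consent group index
    snp_table: list[tuple[str, int, str, str]]  # (chrom, pos, al1, al2)
    seed: int

    def to_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "group_assignment": self.group_assignment,
            "allele_freqs": [round(float(f), 6) for f in self.allele_freqs],
            "snp_table": [list(row) for row in self.snp_table],
            "true_genotypes": self.true_genotypes.astype(int).tolist(),
        }


def generate_dataset(
    n_samples: int = 8,
    m_snps_per_chrom: int = 5,
    n_chroms: int = 2,
    n_groups: int = 2,
    noise_sd: float = 0.05,
    seed: int = 1,
    out_dir: str | Path = ".",
    decimals: int = 4,
    compress: bool = False,
    sample_prefix: str = "",
) -> tuple[dict, SynthTruth]:
    """Write a conformant multi-chromosome, multi-group MaCH fileset.

    Layout under ``out_dir``: ``group<g>/chr<c>.mldose[.gz]`` per chromosome
    per consent group, ``info/chr<c>.mlinfo[.gz]`` per chromosome (identical
    across groups), and ``truth.json`` with the generating parameters and
    genotypes.  Returns ``(paths, truth)`` where ``paths["groups"]`` is the
    ``(dose_dir, info_dir)`` list that feeds straight into the converter.

    SNP names are ``chrom:pos`` with strictly increasing positions per
    chromosome (drawn without replacement from 1..10*m).  The mlinfo Freq1
    and MAF columns are computed from the generated dosages; Quality and Rsq
    are drawn Uniform(0.3, 1) as plausible imputation metrics.
    ``sample_prefix`` prefixes every FID/IID, letting two generated studies
    carry disjoint sample rosters for merge testing.
    """
    if min(n_samples, m_snps_per_chrom, n_chroms, n_groups) < 1:
        raise ArgumentError("all counts must be >= 1")
    if n_groups > n_samples:
        raise ArgumentError(f"{n_groups} groups but only {n_samples} samples")
    if noise_sd < 0:
        raise ArgumentError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    ext = ".gz" if compress else ""

    samples = [
        SampleId.from_token(f"{sample_prefix}F{i:04d}->{sample_prefix}I{i:04d}")
        for i in range(n_samples)
    ]
    # contiguous near-even split into consent groups
    bounds = np.linspace(0, n_samples, n_groups + 1).astype(int)
    group_of = [int(np.searchsorted(bounds[1:], i, side="right")) for i in range(n_samples)]

    info_dir = out_dir / "info"
    info_dir.mkdir(parents=True, exist_ok=True)
    group_dirs = []
    for g in range(n_groups):
        d = out_dir / f"group{g + 1}"
        d.mkdir(parents=True, exist_ok=True)
        group_dirs.append(d)

    all_genotypes = []
    all_freqs = []
    snp_table: list[tuple[str, int, str, str]] = []
    paths: dict = {"dose": {}, "info": {}, "groups": [(d, info_dir) for d in group_dirs]}

    for c in range(1, n_chroms + 1):
        chrom = str(c)
        positions = np.sort(
            rng.choice(np.arange(1, 10 * m_snps_per_chrom + 1), size=m_snps_per_chrom, replace=False)
        )
        freqs = rng.uniform(0.05, 0.95, size=m_snps_per_chrom)
        allele_idx = np.array(
            [rng.choice(4, size=2, replace=False) for _ in range(m_snps_per_chrom)]
        )
        genotypes = rng.binomial(2, freqs, size=(n_samples, m_snps_per_chrom)).astype(np.int8)
        noise = rng.normal(0.0, noise_sd, size=genotypes.shape) if noise_sd > 0 else 0.0
        dosages = np.clip(genotypes + noise, 0.0, 2.0)

        snps = []
        for j in range(m_snps_per_chrom):
            al1, al2 = _ALLELES[allele_idx[j, 0]], _ALLELES[allele_idx[j, 1]]
            freq1 = float(dosages[:, j].mean() / 2.0)
            snps.append(
                SnpInfoRecord(
                    name=f"{chrom}:{positions[j]}",
                    al1=str(al1),
                    al2=str(al2),
                    freq1=freq1,
                    maf=min(freq1, 1.0 - freq1),
                    quality=float(rng.uniform(0.3, 1.0)),
                    rsq=float(rng.uniform(0.3, 1.0)),
                )
            )
            snp_table.append((chrom, int(positions[j]), str(al1), str(al2)))

        info_path = info_dir / f"chr{chrom}.mlinfo{ext}"
        write_mlinfo(snps, info_path)
        paths["info"][chrom] = info_path

        for g in range(n_groups):
            rows = [i for i in range(n_samples) if group_of[i] == g]
            block = DoseBlock(
                samples=[samples[i] for i in rows],
                snps=snps,
                dosages=dosages[rows, :],
                chrom_label=chrom,
            )
            dose_path = group_dirs[g] / f"chr{chrom}.mldose{ext}"
            write_mldose(block, dose_path, decimals=decimals)
            paths["dose"][(chrom, g)] = dose_path

        all_genotypes.append(genotypes)
        all_freqs.append(freqs)

    truth = SynthTruth(
        true_genotypes=np.hstack(all_genotypes),
        allele_freqs=np.concatenate(all_freqs),
        noise_sd=noise_sd,
        group_assignment=group_of,
        snp_table=snp_table,
        seed=seed,
    )
    manifest = out_dir / "truth.json"
    manifest.write_text(json.dumps(truth.to_manifest(), indent=1))
    paths["manifest"] = manifest
    return paths, truth
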