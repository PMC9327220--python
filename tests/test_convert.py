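"""Consent-group combination, structural QC, transposition, concatenation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from machkit.convert import (
    combine_consent_groups,
    concat_pdats,
    dose_to_pdat,
    qc_check,
    read_pdat,
    read_pfam,
    run_convert_mac,
    write_pdat,
    write_pfam,
)
from machkit.errors import HarmonizationError, IdentityError, QcError
from machkit.mach_io import DoseBlock, SampleId, read_mldose, read_mlinfo, write_mldose, write_mlinfo

from conftest import make_block, make_snps


def _write_groups(tmp_path, sizes, m=4, chrom="1"):
    """Per-group dose files sharing one info file; returns (dose_paths, info_paths)."""
    snps = make_snps(m, chrom)
    info = tmp_path / "g.info"
    write_mlinfo(snps, info)
    dose_paths = []
    offset = 0
    rng = np.random.default_rng(7)
    for k, n in enumerate(sizes):
        samples = [SampleId.from_token(f"F{offset + i}->I{offset + i}") for i in range(n)]
        offset += n
        block = DoseBlock(samples=samples, snps=snps, dosages=rng.uniform(0, 2, (n, m)))
        p = tmp_path / f"group{k}.dose"
        write_mldose(block, p)
        dose_paths.append(p)
    return dose_paths, [info] * len(sizes), snps


class TestCombineConsentGroups:
    def test_row_concatenation_counts(self, tmp_path):
        dose_paths, info_paths, _ = _write_groups(tmp_path, [2, 3], m=4)
        out_d, out_i = tmp_path / "c.dose", tmp_path / "c.info"
        report = combine_consent_groups(dose_paths, info_paths, out_d, out_i)
        assert report.passed
        assert len(out_d.read_text().splitlines()) == 5
        assert len(out_i.read_text().splitlines()) == 5  # header + 4 SNPs

    def test_single_group_is_identity(self, tmp_path):
        dose_paths, info_paths, _ = _write_groups(tmp_path, [3], m=2)
        out_d, out_i = tmp_path / "c.dose", tmp_path / "c.info"
        combine_consent_groups(dose_paths, info_paths, out_d, out_i)
        assert out_d.read_text() == dose_paths[0].read_text()
        assert out_i.read_text() == info_paths[0].read_text()

    def test_info_order_mismatch_rejected(self, tmp_path):
        dose_paths, info_paths, snps = _write_groups(tmp_path, [2, 2], m=3)
        swapped = tmp_path / "swapped.info"
        write_mlinfo([snps[1], snps[0], snps[2]], swapped)
        with pytest.raises(HarmonizationError, match="1:200"):
            combine_consent_groups(
                dose_paths, [info_paths[0], swapped], tmp_path / "c.dose", tmp_path / "c.info"
            )

    def test_duplicate_sample_across_groups_rejected(self, tmp_path):
        dose_paths, info_paths, _ = _write_groups(tmp_path, [2, 2], m=3)
        # second group re-uses the first group's rows
        with pytest.raises(IdentityError):
            combine_consent_groups(
                [dose_paths[0], dose_paths[0]], info_paths,
                tmp_path / "c.dose", tmp_path / "c.info",
            )


class TestQcCheck:
    def _write_pair(self, tmp_path, n_snps, dose_rows):
        info = tmp_path / "q.info"
        write_mlinfo(make_snps(n_snps), info)
        dose = tmp_path / "q.dose"
        dose.write_text("".join(r + "\n" for r in dose_rows))
        return dose, info

    def test_offset_of_one_passes(self, tmp_path):
        dose, info = self._write_pair(
            tmp_path, 3, ["F1->I1 ML_DOSE 1.0 0.5 0.2", "F2->I2 ML_DOSE 0.1 1.9 1.0"]
        )
        report = qc_check(dose, info)
        assert report.passed
        assert report.dose_column_count - report.info_line_count == 1

    def test_extra_column_fails(self, tmp_path):
        dose, info = self._write_pair(tmp_path, 3, ["F1->I1 ML_DOSE 1.0 0.5 0.2 0.7"])
        assert not qc_check(dose, info).passed

    def test_ragged_row_fails_and_is_named(self, tmp_path):
        dose, info = self._write_pair(
            tmp_path, 2,
            ["F1->I1 ML_DOSE 1.0 0.5", "F2->I2 ML_DOSE 0.1 1.9", "F3->I3 ML_DOSE 0.1"],
        )
        report = qc_check(dose, info)
        assert not report.passed
        assert any("row 2" in m for m in report.messages)

    def test_report_written_to_file(self, tmp_path):
        dose, info = self._write_pair(tmp_path, 2, ["F1->I1 ML_DOSE 1.0 0.5"])
        out = tmp_path / "qc.txt"
        qc_check(dose, info, report_path=out)
        assert "PASS" in out.read_text()


class TestTransposition:
    def test_worked_example(self):
        block = make_block(2, 2, dosages=np.array([[1.98, 0.02], [1.00, 2.00]]))
        pdat = dose_to_pdat(block)
        np.testing.assert_array_equal(pdat.dosages, [[1.98, 1.00], [0.02, 2.00]])
        assert pdat.names == ["1:100", "1:200"]
        assert (pdat.al1[0], pdat.al2[0]) == ("A", "G")
        assert [s.raw for s in pdat.samples] == ["F0->I0", "F1->I1"]

    def test_single_cell(self):
        pdat = dose_to_pdat(make_block(1, 1, dosages=np.array([[0.5]])))
        assert pdat.dosages.shape == (1, 1) and pdat.dosages[0, 0] == 0.5

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_involution(self, seed):
        """Transposing twice recovers the original matrix exactly."""
        block = make_block(20, 50, np.random.default_rng(seed))
        np.testing.assert_array_equal(dose_to_pdat(block).dosages.T, block.dosages)


class TestConcatPdats:
    def test_chromosome_concatenation(self, rng):
        p1 = dose_to_pdat(make_block(4, 3, rng, chrom="1"))
        p2 = dose_to_pdat(make_block(4, 2, rng, chrom="2"))
        genome = concat_pdats([p1, p2])
        assert genome.m_snps == 5 and genome.n_samples == 4
        assert genome.source_chroms == ["1", "2"]
        np.testing.assert_array_equal(genome.dosages[:3], p1.dosages)

    def test_single_input_identity(self, rng):
        p1 = dose_to_pdat(make_block(3, 3, rng))
        out = concat_pdats([p1])
        assert out.names == p1.names
        np.testing.assert_array_equal(out.dosages, p1.dosages)

    def test_roster_mismatch_rejected(self, rng):
        p1 = dose_to_pdat(make_block(4, 3, rng, chrom="1"))
        p2 = dose_to_pdat(make_block(4, 2, rng, chrom="2"))
        p2.samples = list(reversed(p2.samples))
        with pytest.raises(HarmonizationError, match="position 0"):
            concat_pdats([p1, p2])

    def test_duplicate_snp_names_rejected(self, rng):
        p1 = dose_to_pdat(make_block(2, 2, rng, chrom="1"))
        p2 = dose_to_pdat(make_block(2, 2, rng, chrom="1"))
        with pytest.raises(HarmonizationError, match="appears"):
            concat_pdats([p1, p2])


def test_pdat_round_trip(tmp_path, rng):
    pdat = dose_to_pdat(make_block(5, 7, rng))
    path = tmp_path / "x.pdat.gz"
    write_pdat(pdat, path, decimals=3)
    back = read_pdat(path)
    assert back.names == pdat.names
    assert [s.raw for s in back.samples] == [s.raw for s in pdat.samples]
    assert np.max(np.abs(back.dosages - pdat.dosages)) <= 0.5e-3


def test_pfam_round_trip(tmp_path):
    samples = [SampleId.from_token(t) for t in ["F1->I1", "SOLO", "F2->I2"]]
    path = tmp_path / "x.pfam"
    write_pfam(samples, path)
    line = path.read_text().splitlines()[0].split()
    assert line == ["F1", "I1", "0", "0", "0", "-9"]
    assert [s.key for s in read_pfam(path)] == [s.key for s in samples]


class TestRunConvertMac:
    def test_pipeline_outputs(self, tmp_path):
        from machkit.synth import generate_dataset

        paths, _ = generate_dataset(out_dir=tmp_path / "in", seed=3)
        out = run_convert_mac(paths["groups"], "proj", tmp_path / "out")
        for key in ("pdat", "pfam", "bed", "bim", "fam", "vcf", "qc", "log"):
            assert out[key].exists(), key
        assert all(r.passed for r in out["qc_reports"].values())

    def test_corrupted_dose_row_fails_qc(self, tmp_path):
        from machkit.synth import generate_dataset

        paths, _ = generate_dataset(out_dir=tmp_path / "in", seed=3)
        dose = paths["dose"][("1", 0)]
        lines = dose.read_text().splitlines()
        dose.write_text("\n".join(lines[:-1] + [lines[-1] + " 0.50"]) + "\n")
        with pytest.raises(QcError, match="chromosome 1"):
            run_convert_mac(paths["groups"], "proj", tmp_path / "out")

    def test_matches_manual_stage_composition(self, tmp_path):
        """Single group, single chromosome: pipeline == stages run by hand."""
        from machkit.plink_io import pdat_to_bedset
        from machkit.synth import generate_dataset

        paths, _ = generate_dataset(
            n_samples=6, m_snps_per_chrom=8, n_chroms=1, n_groups=1,
            noise_sd=0.05, seed=11, out_dir=tmp_path / "in",
        )
        out = run_convert_mac(paths["groups"], "proj", tmp_path / "out")
        snps = read_mlinfo(paths["info"]["1"])
        block = read_mldose(paths["dose"][("1", 0)], expected_snps=snps, chrom_label="1")
        manual = pdat_to_bedset(dose_to_pdat(block), threshold=0.1)
        np.testing.assert_array_equal(out["bedset"].genotypes, manual.genotypes)
        assert [r.id for r in out["bedset"].bim] == [r.id for r in manual.bim]
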