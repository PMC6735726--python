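"""Fragment coverage, efficiency/recovery arithmetic, and error profiling."""

import numpy as np
import pysam
import pytest

from duplexsc.bamio import make_header, write_records_bam, _segment
from duplexsc.metrics import (
    dcs_recovery,
    efficiency,
    error_report,
    fragment_coverage,
    gt_ca_imbalance,
    read_panel,
)


def _write_bam(path, header, specs):
    """specs: (qname, pos1based, length, seq) pairs of forward/reverse mates."""
    records = []
    for qname, pos, length, seq, mate_pos in specs:
        records.append(
            _segment(header, qname, "toy1", pos, f"{length}M", False, True,
                     seq, np.full(length, 37, np.uint8), True, "toy1", mate_pos, 0)
        )
    return write_records_bam(str(path), records, header)


class TestFragmentCoverage:
    def test_overlapping_mates_count_once(self, toy_reference, tmp_path):
        header = make_header(toy_reference)
        # one pair: mates overlap by 50 bp within a 100 bp panel target
        bed = tmp_path / "t.bed"
        bed.write_text("toy1\t2000\t2100\n")
        records = []
        for pos, rev, r1 in ((2001, False, True), (2051, True, False)):
            records.append(
                _segment(header, "frag|AAAA", "toy1", pos, "50M", rev, not rev,
                         "A" * 50, np.full(50, 37, np.uint8), r1, "toy1", 2001, 0)
            )
        bam = write_records_bam(str(tmp_path / "o.bam"), records, header)
        assert fragment_coverage(bam, str(bed)) == pytest.approx(1.0)

    def test_two_templates_give_depth_two(self, toy_reference, tmp_path):
        header = make_header(toy_reference)
        bed = tmp_path / "t.bed"
        bed.write_text("toy1\t2000\t2100\n")
        bam = _write_bam(
            tmp_path / "o.bam", header,
            [("a|AAAA", 2001, 100, "A" * 100, 2001), ("b|AAAA", 2001, 100, "A" * 100, 2001)],
        )
        assert fragment_coverage(bam, str(bed)) == pytest.approx(2.0)

    def test_empty_panel_is_an_error(self, toy_reference, tmp_path):
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        with pytest.raises(ValueError):
            read_panel(str(bed))

    def test_contig_mismatch_lists_offenders(self, sim_factory, tmp_path):
        res, _ = sim_factory("cm", n_molecules=5, per_strand_reads="fixed:1", seed=50)
        bed = tmp_path / "bad.bed"
        bed.write_text("chrUnknown\t0\t100\n")
        with pytest.raises(ValueError, match="chrUnknown"):
            fragment_coverage(res.bam, str(bed))

    def test_matches_brute_force_template_counting(self, sim_factory, small_panel):
        res, _ = sim_factory(
            "brute", panel=small_panel, n_molecules=30,
            per_strand_reads="ztpoisson:1.5", seed=51,
        )
        fast = fragment_coverage(res.bam, small_panel)
        assert fast == pytest.approx(_brute_force_coverage(res.bam, small_panel))


def _brute_force_coverage(bam_path, bed_path):
    """Direct definition: per position, count templates with a base there."""
    panel = read_panel(bed_path)
    depths = []
    with pysam.AlignmentFile(bam_path) as bam:
        for row in panel.itertuples():
            for pos in range(row.start, row.end):
                names = set()
                for rec in bam.fetch(row.contig, pos, pos + 1):
                    for s, e in rec.get_blocks():
                        if s <= pos < e:
                            names.add(rec.query_name)
                depths.append(len(names))
    return float(np.mean(depths))


class TestRatios:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(250.0, 1000.0, 0.25), (1000.0, 1000.0, 1.0), (0.0, 1000.0, 0.0)],
    )
    def test_efficiency(self, num, den, expected):
        assert efficiency(num, den) == pytest.approx(expected)

    def test_efficiency_zero_denominator_is_missing(self):
        assert efficiency(1.0, 0.0) is None

    def test_dcs_recovery(self):
        assert dcs_recovery(15.0, 200.0) == pytest.approx(0.15)
        assert dcs_recovery(100.0, 200.0) == pytest.approx(1.0)
        assert dcs_recovery(1.0, 0.0) is None


class TestErrorReport:
    def test_error_free_bam(self, sim_factory, toy_reference, toy_panel):
        res, _ = sim_factory("clean_err", n_molecules=60, per_strand_reads="fixed:1", seed=52)
        rep = error_report(res.bam, toy_reference, toy_panel)
        assert rep.error_rate == 0.0
        assert rep.error_free_positions == 1.0
        assert sum(rep.substitution_counts.values()) == rep.nonref_bases == 0

    def test_single_error_counted_and_classified(self, toy_reference, tmp_path):
        import pyfaidx

        header = make_header(toy_reference)
        bed = tmp_path / "t.bed"
        bed.write_text("toy1\t2000\t2100\n")
        ref = str(pyfaidx.Fasta(toy_reference)["toy1"][2000:2100]).upper()
        # 30 clean templates plus one carrying a substitution at offset 10
        specs = [(f"c{i}|AAAA", 2001, 100, ref, 2001) for i in range(30)]
        mutated = ref[:10] + ("A" if ref[10] != "A" else "G") + ref[11:]
        specs.append(("err|AAAA", 2001, 100, mutated, 2001))
        bam = _write_bam(tmp_path / "o.bam", header, specs)
        rep = error_report(bam, toy_reference, str(bed))
        assert rep.nonref_bases == 1
        assert rep.total_bases == 3100
        assert rep.error_rate == pytest.approx(1 / 3100)
        cls = f"{ref[10]}>{'A' if ref[10] != 'A' else 'G'}"
        assert rep.substitution_counts[cls] == 1
        assert rep.error_free_positions == pytest.approx(99 / 100)

    def test_high_frequency_allele_treated_as_variant(self, toy_reference, tmp_path):
        import pyfaidx

        header = make_header(toy_reference)
        bed = tmp_path / "t.bed"
        bed.write_text("toy1\t2000\t2100\n")
        ref = str(pyfaidx.Fasta(toy_reference)["toy1"][2000:2100]).upper()
        alt = "A" if ref[10] != "A" else "G"
        mutated = ref[:10] + alt + ref[11:]
        # 10/20 reads carry the allele: 50% AF, excluded from error numerator
        specs = [(f"c{i}|AAAA", 2001, 100, ref, 2001) for i in range(10)]
        specs += [(f"v{i}|AAAA", 2001, 100, mutated, 2001) for i in range(10)]
        bam = _write_bam(tmp_path / "o.bam", header, specs)
        rep = error_report(bam, toy_reference, str(bed))
        assert rep.nonref_bases == 0
        assert rep.error_rate == 0.0

    def test_n_bases_excluded_from_both_sides(self, toy_reference, tmp_path):
        import pyfaidx

        header = make_header(toy_reference)
        bed = tmp_path / "t.bed"
        bed.write_text("toy1\t2000\t2100\n")
        ref = str(pyfaidx.Fasta(toy_reference)["toy1"][2000:2100]).upper()
        masked = "N" * 10 + ref[10:]
        bam = _write_bam(tmp_path / "o.bam", header, [("n|AAAA", 2001, 100, masked, 2001)])
        rep = error_report(bam, toy_reference, str(bed))
        assert rep.total_bases == 90
        assert rep.nonref_bases == 0

    def test_invariant_to_record_order(self, sim_factory, toy_reference, toy_panel, tmp_path):
        res, _ = sim_factory(
            "ord", n_molecules=50, per_strand_reads="fixed:1",
            seq_error_rate=0.01, seed=53,
        )
        a = error_report(res.bam, toy_reference, toy_panel)
        # rewrite with reversed record order per contig chunk, then re-sort:
        # coordinate sorting is canonical, so shuffling qname suffixes suffices
        shuffled = str(tmp_path / "shuf.bam")
        with pysam.AlignmentFile(res.bam) as src:
            recs = list(src.fetch(until_eof=True))
            header = src.header
        recs = recs[::-1]
        recs.sort(key=lambda r: (r.reference_id, r.reference_start))
        with pysam.AlignmentFile(shuffled, "wb", header=header) as out:
            for r in recs:
                out.write(r)
        pysam.index(shuffled)
        b = error_report(shuffled, toy_reference, toy_panel)
        assert a.error_rate == b.error_rate
        assert a.substitution_counts == b.substitution_counts


def test_gt_ca_imbalance_statistic():
    from duplexsc.metrics import ErrorReport, SUBSTITUTION_CLASSES

    counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    counts["G>T"], counts["C>A"] = 99, 9
    rep = ErrorReport(0.0, counts, 1.0, 0, 0)
    assert gt_ca_imbalance(rep) == pytest.approx(99.5 / 9.5)
    counts["G>T"], counts["C>A"] = 0, 0
    assert gt_ca_imbalance(rep) == 1.0
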