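"""VCF ingestion, SNP filters, windows, and functional classification."""

import numpy as np
import pytest
from Bio.Seq import Seq

import peachpop as pp
from peachpop.cohort_io import cds_sequence, nonsyn_syn_ratio

from conftest import make_matrix

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=t1,length=200>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsA\tsB\n"
)


def _write_vcf(path, body_lines):
    path.write_text(VCF_HEADER + "".join(l + "\n" for l in body_lines))
    return path


def _write_groups(path, rows=(("sA", "W", "wild"), ("sB", "W", "wild"))):
    path.write_text(
        "sample_id\tsubgroup\trole\n" + "".join("\t".join(r) + "\n" for r in rows)
    )
    return path


class TestReadCohort:
    def test_drops_indels_and_multiallelics_keeps_snp(self, tmp_path):
        vcf = _write_vcf(
            tmp_path / "a.vcf",
            [
                "t1\t5\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/0",
                "t1\t8\t.\tAT\tA\t.\tPASS\t.\tGT\t0/0\t0/1",
                "t1\t12\t.\tC\tG,T\t.\tPASS\t.\tGT\t0/1\t0/0",
                "t1\t20\t.\tG\tC\t.\tPASS\t.\tGT\t./.\t1/1",
            ],
        )
        groups = _write_groups(tmp_path / "g.tsv")
        matrix, _ = pp.read_cohort(vcf, groups)
        assert matrix.n_sites == 2
        assert list(matrix.sites["pos"]) == [5, 20]
        # 0/1 and 1/0 both code 1; ./. codes missing; 1/1 codes 2
        assert matrix.codes[:, 0].tolist() == [1, 1]
        assert matrix.codes[:, 1].tolist() == [-1, 2]

    def test_unassigned_vcf_sample_is_an_error(self, tmp_path):
        vcf = _write_vcf(tmp_path / "a.vcf", ["t1\t5\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0"])
        groups = _write_groups(tmp_path / "g.tsv", rows=(("sA", "W", "wild"),))
        with pytest.raises(ValueError, match="sB"):
            pp.read_cohort(vcf, groups)

    def test_no_usable_records_is_an_error(self, tmp_path):
        vcf = _write_vcf(tmp_path / "a.vcf", ["t1\t8\t.\tAT\tA\t.\tPASS\t.\tGT\t0/0\t0/1"])
        groups = _write_groups(tmp_path / "g.tsv")
        with pytest.raises(ValueError, match="no usable"):
            pp.read_cohort(vcf, groups)

    def test_synthetic_cohort_dimensions(self, small_cohort, small_matrix):
        spec, paths = small_cohort
        matrix, _ = small_matrix
        n_records = sum(
            1
            for ln in paths["vcf"].read_text().splitlines()
            if ln and not ln.startswith("#")
        )
        assert matrix.n_samples == sum(sg.n_accessions for sg in spec.subgroups)
        assert matrix.n_sites == n_records


class TestFilters:
    def test_no_thresholds_is_identity(self):
        m = make_matrix([[0, 1, -1], [2, 1, -1]])
        out = pp.filter_population_snps(m, 0.0, 0.0)
        assert out.n_sites == 2  # all-missing site has no defined MAF

    def test_all_missing_site_dropped_at_half_call_rate(self):
        m = make_matrix([[0, -1], [1, -1], [2, -1], [0, -1]])
        out = pp.filter_population_snps(m, 0.5, 0.0)
        assert out.n_sites == 1

    def test_maf_threshold_counts_alleles(self):
        # 10 samples: nine hom-ref, one het -> MAF 1/20 = 0.05 < 0.1
        col = [[0]] * 9 + [[1]]
        m = make_matrix(col)
        assert pp.filter_population_snps(m, 0.0, 0.1).n_sites == 0
        assert pp.filter_population_snps(m, 0.0, 0.05).n_sites == 1


class TestIterWindows:
    def test_exact_tiling(self):
        assert len(pp.iter_windows([("c", 30_000)], 10_000)) == 3

    def test_sliding_with_partial_tail(self):
        wins = pp.iter_windows([("c", 25_000)], 10_000, 5_000)
        assert [w[1] for w in wins] == [0, 5_000, 10_000, 15_000, 20_000]
        assert wins[-1] == ("c", 20_000, 25_000)
        assert wins[-2] == ("c", 15_000, 25_000)

    def test_empty_contigs(self):
        assert pp.iter_windows([], 10_000) == []

    def test_rejects_bad_step(self):
        with pytest.raises(ValueError):
            pp.iter_windows([("c", 100)], 10, 20)


# ---------------------------------------------------------------------------
# hand-built two-gene annotation (one strand each) for classification


@pytest.fixture(scope="module")
def toy_annotation(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("toyann")
    seq = list("A" * 200)
    seq[16:19] = "GCT"  # first codon of the plus-strand CDS
    fasta = tmp / "t.fa"
    fasta.write_text(">t1\n" + "".join(seq) + "\n")
    gff = tmp / "t.gff3"
    gff.write_text(
        "##gff-version 3\n"
        # plus-strand gene: exons [10,40)+[60,100), CDS [16,40)+[60,87)
        "t1\ttest\tgene\t11\t100\t.\t+\t.\tID=gplus\n"
        "t1\ttest\tmRNA\t11\t100\t.\t+\t.\tID=gplus.t1;Parent=gplus\n"
        "t1\ttest\texon\t11\t40\t.\t+\t.\tID=e1;Parent=gplus.t1\n"
        "t1\ttest\texon\t61\t100\t.\t+\t.\tID=e2;Parent=gplus.t1\n"
        "t1\ttest\tfive_prime_UTR\t11\t16\t.\t+\t.\tID=u5;Parent=gplus.t1\n"
        "t1\ttest\tCDS\t17\t40\t.\t+\t0\tID=c1;Parent=gplus.t1\n"
        "t1\ttest\tCDS\t61\t87\t.\t+\t0\tID=c2;Parent=gplus.t1\n"
        "t1\ttest\tthree_prime_UTR\t88\t100\t.\t+\t.\tID=u3;Parent=gplus.t1\n"
        # minus-strand gene: exons [120,150)+[170,190)
        "t1\ttest\tgene\t121\t190\t.\t-\t.\tID=gminus\n"
        "t1\ttest\tmRNA\t121\t190\t.\t-\t.\tID=gminus.t1;Parent=gminus\n"
        "t1\ttest\texon\t121\t150\t.\t-\t.\tID=me1;Parent=gminus.t1\n"
        "t1\ttest\texon\t171\t190\t.\t-\t.\tID=me2;Parent=gminus.t1\n"
        "t1\ttest\tfive_prime_UTR\t186\t190\t.\t-\t.\tID=mu5;Parent=gminus.t1\n"
        "t1\ttest\tCDS\t130\t150\t.\t-\t.\tID=mc1;Parent=gminus.t1\n"
        "t1\ttest\tCDS\t171\t185\t.\t-\t0\tID=mc2;Parent=gminus.t1\n"
        "t1\ttest\tthree_prime_UTR\t121\t129\t.\t-\t.\tID=mu3;Parent=gminus.t1\n"
    )
    return pp.GenomeAnnotation.from_files(fasta, gff)


class TestClassifySite:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (5, "intergenic"),      # before any gene
            (110, "intergenic"),    # between genes
            (13, "UTR5"),           # plus-strand 5' UTR
            (50, "intronic"),       # plus-strand intron
            (30, "CDS"),            # plus-strand CDS
            (95, "UTR3"),           # plus-strand 3' UTR
            (188, "UTR5"),          # minus-strand 5' UTR (genomic right end)
            (125, "UTR3"),          # minus-strand 3' UTR (genomic left end)
            (160, "intronic"),      # minus-strand intron
            (140, "CDS"),           # minus-strand CDS
        ],
    )
    def test_contexts(self, toy_annotation, pos, expected):
        assert pp.classify_site("t1", pos, toy_annotation) == expected

    def test_unknown_contig_is_an_error(self, toy_annotation):
        with pytest.raises(KeyError):
            pp.classify_site("nope", 5, toy_annotation)

    def test_longest_transcript_rule(self, tmp_path):
        # two transcripts of one gene disagree: position is CDS in the short
        # one but intronic in the longer one -> longest transcript wins
        fasta = tmp_path / "t.fa"
        fasta.write_text(">t1\n" + "A" * 100 + "\n")
        gff = tmp_path / "t.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "t1\ttest\tgene\t1\t100\t.\t+\t.\tID=g\n"
            "t1\ttest\tmRNA\t1\t100\t.\t+\t.\tID=g.long;Parent=g\n"
            "t1\ttest\texon\t1\t30\t.\t+\t.\tID=le1;Parent=g.long\n"
            "t1\ttest\texon\t61\t99\t.\t+\t.\tID=le2;Parent=g.long\n"
            "t1\ttest\tCDS\t1\t30\t.\t+\t0\tID=lc1;Parent=g.long\n"
            "t1\ttest\tCDS\t61\t99\t.\t+\t0\tID=lc2;Parent=g.long\n"
            "t1\ttest\tmRNA\t1\t100\t.\t+\t.\tID=g.short;Parent=g\n"
            "t1\ttest\texon\t31\t60\t.\t+\t.\tID=se1;Parent=g.short\n"
            "t1\ttest\tCDS\t31\t60\t.\t+\t0\tID=sc1;Parent=g.short\n"
        )
        ann = pp.GenomeAnnotation.from_files(fasta, gff)
        assert ann.genes["g"].representative_transcript().tid == "g.long"
        assert pp.classify_site("t1", 45, ann) == "intronic"


class TestCdsEffect:
    def test_synonymous_third_position(self, toy_annotation):
        # GCT -> GCC, Ala -> Ala (position 19 is the codon's third base)
        assert (
            pp.classify_cds_effect("t1", 19, "T", "C", toy_annotation) == "synonymous"
        )

    def test_nonsynonymous_second_position(self, toy_annotation):
        # GCT -> GAT, Ala -> Asp
        assert (
            pp.classify_cds_effect("t1", 18, "C", "A", toy_annotation)
            == "nonsynonymous"
        )

    def test_reference_mismatch_is_an_error(self, toy_annotation):
        with pytest.raises(ValueError, match="disagrees"):
            pp.classify_cds_effect("t1", 19, "G", "C", toy_annotation)

    def test_minus_strand_agrees_with_full_translation_oracle(self, toy_annotation):
        # brute force: rebuild the mutant genome, re-splice, re-translate
        gene = toy_annotation.genes["gminus"]
        tx = gene.representative_transcript()
        for s, e in tx.cds:
            for pos0 in range(s, e):
                ref = toy_annotation.sequences["t1"][pos0]
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    got = pp.classify_cds_effect("t1", pos0 + 1, ref, alt, toy_annotation)
                    assert got == _oracle_effect(toy_annotation, tx, pos0, alt)


def _oracle_effect(annotation, tx, pos0, alt):
    """Independent effect call: mutate the contig, rebuild the spliced CDS,
    translate the whole protein, and compare."""
    wild = Seq(cds_sequence(tx, annotation)).translate()
    seq = annotation.sequences[tx.contig]
    mutated = dict(annotation.sequences)
    mutated[tx.contig] = seq[:pos0] + alt + seq[pos0 + 1 :]

    class _Mut:
        sequences = mutated

    mut = Seq(cds_sequence(tx, _Mut)).translate()
    return "synonymous" if wild == mut else "nonsynonymous"


class TestSummarize:
    def test_ratio_arithmetic(self):
        assert nonsyn_syn_ratio(258_902, 198_230) == 1.31
        assert nonsyn_syn_ratio(190_986, 157_316) == 1.21
        assert np.isnan(nonsyn_syn_ratio(0, 0))

    def test_class_partition_identity(self, small_matrix, small_annotation):
        matrix, groups = small_matrix
        summary = pp.summarize_variants(matrix, groups, small_annotation)
        t = summary.table
        assert (
            t["intergenic"] + t["UTR5"] + t["UTR3"] + t["intronic"] + t["CDS"]
        ).tolist() == t["total"].tolist()
        assert (t["nonsynonymous"] + t["synonymous"]).tolist() == t["CDS"].tolist()
        # group totals cannot exceed the cohort total
        all_total = t.loc[t["group"] == "all", "total"].iloc[0]
        assert (t["total"] <= all_total).all()

    def test_effect_calls_match_oracle_on_toy_transcriptome(
        self, small_matrix, small_annotation
    ):
        matrix, _ = small_matrix
        checked = 0
        for row in matrix.sites.itertuples():
            if pp.classify_site(row.contig, row.pos, small_annotation) != "CDS":
                continue
            pos0 = row.pos - 1
            for gene in small_annotation.genes_overlapping(row.contig, pos0, pos0 + 1):
                tx = gene.representative_transcript()
                if any(s <= pos0 < e for s, e in tx.cds):
                    expected = _oracle_effect(small_annotation, tx, pos0, row.alt)
                    got = pp.classify_cds_effect(
                        row.contig, row.pos, row.ref, row.alt, small_annotation
                    )
                    assert got == expected
                    checked += 1
                    break
        assert checked > 20
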