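"""Catalogue parsing, allele normalization, DBS merging, partitioning."""
from collections import Counter

import pytest

from mutmat import variant_io as vio
from mutmat.variant_io import (
    MutationRecord,
    make_record,
    merge_adjacent_sbs,
    normalize_alleles,
    partition_by_chromosome,
    read_catalogue,
    read_partition,
)


@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ("C", "A", vio.SBS),
        ("CT", "AA", vio.DBS),
        ("TT", "AC", vio.DBS),
        ("", "ACA", vio.ID_INS),
        ("ACA", "", vio.ID_DEL),
        ("CC", "AAA", vio.COMPLEX),
    ],
)
def test_event_classification(ref, alt, expected):
    assert vio.classify_event(ref, alt) == expected


@pytest.mark.parametrize(
    "pos,ref,alt,expected",
    [
        (10, "ATT", "A", (11, "TT", "")),      # anchored deletion
        (10, "A", "ATT", (10, "", "TT")),      # anchored insertion
        (10, "ATCCG", "ATAAAG", (12, "CC", "AAA")),  # complex: del CC + ins AAA
        (10, "AT", "AC", (11, "T", "C")),      # disguised SBS
        (10, "C", "A", (10, "C", "A")),
    ],
)
def test_allele_normalization(pos, ref, alt, expected):
    assert normalize_alleles(pos, ref, alt) == expected


def test_maf_dash_allele_convention():
    rec = make_record("s", "chr1", 100, "-", "ACA")
    assert (rec.position, rec.ref, rec.alt, rec.event_class) == (100, "", "ACA", vio.ID_INS)
    rec = make_record("s", "1", 100, "ACA", "-")
    assert (rec.position, rec.ref, rec.alt, rec.event_class) == (100, "ACA", "", vio.ID_DEL)


def test_non_mutation_is_rejected():
    with pytest.raises(ValueError):
        make_record("s", "1", 5, "T", "T")


class TestMergeAdjacentSbs:
    def _sbs(self, sample, pos, ref="C", alt="A"):
        return MutationRecord(sample, "1", pos, ref, alt, vio.SBS)

    def test_consecutive_pair_becomes_one_doublet(self):
        out = merge_adjacent_sbs([self._sbs("S", 10), self._sbs("S", 11, "T", "A")])
        assert len(out) == 1
        assert out[0] == MutationRecord("S", "1", 10, "CT", "AA", vio.DBS)

    def test_same_positions_in_different_samples_not_merged(self):
        out = merge_adjacent_sbs([self._sbs("S1", 10), self._sbs("S2", 11)])
        assert len(out) == 2
        assert all(r.event_class == vio.SBS for r in out)

    def test_run_of_three_left_unmerged(self):
        stats = Counter()
        out = merge_adjacent_sbs(
            [self._sbs("S", 10), self._sbs("S", 11), self._sbs("S", 12)],
            stats=stats,
        )
        assert len(out) == 3
        assert all(r.event_class == vio.SBS for r in out)
        assert stats["adjacent_run_unmerged"] == 1

    def test_merging_can_be_disabled(self):
        recs = [self._sbs("S", 10), self._sbs("S", 11)]
        assert merge_adjacent_sbs(recs, enabled=False) == recs

    def test_non_adjacent_untouched(self):
        recs = [self._sbs("S", 10), self._sbs("S", 12)]
        assert merge_adjacent_sbs(recs) == recs


def _write_vcf(path, body, contigs=("1", "2"), samples=()):
    header = ["##fileformat=VCFv4.2"]
    header += [f"##contig=<ID={c},length=1000>" for c in contigs]
    if samples:
        header.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        cols += "\tFORMAT\t" + "\t".join(samples)
    path.write_text("\n".join(header + [cols] + body) + "\n")


def test_vcf_per_file_sample_and_multiallelic_split(tmp_path):
    """One-file-per-sample mode: sample from file name; ALT alleles split."""
    vcf = tmp_path / "tumorA.vcf"
    _write_vcf(vcf, ["1\t100\t.\tC\tA,T\t.\t.\t.", "2\t50\t.\tGT\tG\t.\t.\t."])
    stats = Counter()
    recs = read_catalogue([vcf], stats=stats)
    assert {r.sample for r in recs} == {"tumorA"}
    assert [(r.chromosome, r.position, r.ref, r.alt) for r in recs] == [
        ("1", 100, "C", "A"),
        ("1", 100, "C", "T"),
        ("2", 51, "T", ""),
    ]
    assert stats["read"] == 3


def test_multisample_vcf_assigns_by_genotype(tmp_path):
    vcf = tmp_path / "cohort.vcf"
    _write_vcf(
        vcf,
        ["1\t100\t.\tC\tA\t.\t.\t.\tGT\t0/1\t0/0"],
        samples=("P1", "P2"),
    )
    recs = read_catalogue([vcf])
    assert [(r.sample, r.ref, r.alt) for r in recs] == [("P1", "C", "A")]


def test_duplicate_records_counted_once(tmp_path):
    vcf = tmp_path / "s.vcf"
    _write_vcf(vcf, ["1\t100\t.\tC\tA\t.\t.\t.", "1\t100\t.\tC\tA\t.\t.\t."])
    stats = Counter()
    recs = read_catalogue([vcf], stats=stats)
    assert len(recs) == 1
    assert stats["duplicate"] == 1


def test_maf_reading(tmp_path):
    maf = tmp_path / "cohort.maf"
    maf.write_text(
        "Chromosome\tStart_Position\tReference_Allele\tTumor_Seq_Allele2\t"
        "Tumor_Sample_Barcode\tVariant_Type\n"
        "chr1\t100\tC\tA\tP1\tSNP\n"
        "1\t200\tACA\t-\tP2\tDEL\n"
    )
    recs = read_catalogue([maf])
    assert [(r.sample, r.chromosome, r.event_class) for r in recs] == [
        ("P1", "1", vio.SBS),
        ("P2", "1", vio.ID_DEL),
    ]


class TestPartition:
    def _records(self):
        return [
            MutationRecord("S", "2", 30, "C", "A", vio.SBS),
            MutationRecord("S", "1", 20, "C", "A", vio.SBS),
            MutationRecord("S", "1", 10, "T", "G", vio.SBS),
            MutationRecord("S", "99", 5, "C", "A", vio.SBS),  # unknown chrom
        ]

    def test_files_sorted_and_in_manifest_order(self, world, tmp_path):
        stats = Counter()
        paths = partition_by_chromosome(self._records(), world.build, tmp_path, stats)
        assert [p.stem for p in paths] == ["1", "2"]
        recs1 = read_partition(paths[0])
        assert [r.position for r in recs1] == [10, 20]
        assert stats["unknown_chromosome"] == 1

    def test_partition_roundtrip_preserves_records(self, world, tmp_path):
        paths = partition_by_chromosome(self._records(), world.build, tmp_path)
        back = [r for p in paths for r in read_partition(p)]
        kept = sorted(
            (r for r in self._records() if r.chromosome != "99"),
            key=lambda r: (r.chromosome, r.position),
        )
        assert back == kept

    def test_idempotent_on_sorted_input(self, world, tmp_path):
        paths = partition_by_chromosome(self._records(), world.build, tmp_path / "a")
        texts = [p.read_text() for p in paths]
        again = partition_by_chromosome(
            [r for p in paths for r in read_partition(p)],
            world.build,
            tmp_path / "b",
        )
        assert [p.read_text() for p in again] == texts

    def test_empty_input_gives_zero_files(self, world, tmp_path):
        assert partition_by_chromosome([], world.build, tmp_path) == []

    def test_human_layout_gives_25_intermediate_files(self, tmp_path):
        """A human-layout build with >= 1 mutation per chromosome produces
        one intermediate file per chromosome: 25 in total."""
        from mutmat import FixtureSpec, encode_genome, make_genome

        spec = FixtureSpec.human_layout(seed=2, length=1200)
        g = make_genome(spec, tmp_path / "g")
        build = encode_genome(g["fasta"], g["annotation"], tmp_path / "b")
        records = [
            MutationRecord("S", chrom, 300, build.load_chromosome(chrom).base(300), "", vio.ID_DEL)
            for chrom, _ in build.chromosomes
        ]
        paths = partition_by_chromosome(records, build, tmp_path / "w")
        assert len(paths) == 25


def test_event_count_conservation(world):
    """Records in == records kept + records dropped, all causes counted."""
    stats = Counter()
    recs = read_catalogue(world.catalogue["vcfs"], stats=stats)
    assert stats["read"] == len(recs)
    merged = merge_adjacent_sbs(recs, stats=stats)
    assert len(merged) == len(recs) - stats["sbs_pairs_merged"]
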