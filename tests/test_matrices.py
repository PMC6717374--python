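"""Accumulation, collapse chains, region subsetting, strand-bias testing."""
import math
from collections import Counter

import pandas as pd
import pytest

from mutmat import generate_matrices
from mutmat.matrices import (
    SCHEMES,
    channels,
    collapse,
    counts_to_matrix,
    empty_matrix,
    read_bed,
    strand_bias_test,
    subset_records,
)


def _tiny_run(write_build, tmp_path, vcf_body, **kwargs):
    build, _, _ = write_build(
        {"1": "AGTTCCAGGACCAATTACAACAGGCGC"},
        annotation=[("1", "+", 9, 14, "", "")],
    )
    vcf = tmp_path / "s1.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n##contig=<ID=1,length=27>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n" + vcf_body
    )
    return build, generate_matrices("t", [vcf], build, tmp_path / "out", **kwargs)


def test_one_of_each_event_lands_in_each_finest_matrix(write_build, tmp_path):
    body = (
        "1\t5\t.\tC\tT\t.\t.\t.\n"        # SBS
        "1\t11\t.\tCC\tTT\t.\t.\t.\n"     # DBS (inside the + gene footprint)
        "1\t16\t.\tTACA\tT\t.\t.\t.\n"    # deletion of ACA from the 2-copy tract
    )
    _, res = _tiny_run(write_build, tmp_path, body)
    m = res["matrices"]
    assert m["SBS6144"].to_numpy().sum() == 1
    assert m["DBS2976"].to_numpy().sum() == 1
    assert m["ID415"].to_numpy().sum() == 1
    assert m["SBS6144"].loc["N:TT[C>T]CA", "s1"] == 1
    assert m["DBS2976"].loc["U:ACCA>ATTA", "s1"] == 1
    assert m["ID415"].loc["N:3:Del:R:2", "s1"] == 1
    assert m["ID83"].loc["3:Del:R:2", "s1"] == 1


def test_default_run_emits_fourteen_matrix_files(write_build, tmp_path):
    _, res = _tiny_run(write_build, tmp_path, "1\t5\t.\tC\tT\t.\t.\t.\n")
    assert len(res["paths"]) == 14
    names = {p.name.split(".")[1] for p in res["paths"]}
    assert names == set(SCHEMES)


def test_collapse_sums_strand_labels():
    df = empty_matrix("SBS6144", ["s"])
    core = "AA[C>A]GG"
    for strand, n in zip("TUBN", (1, 2, 3, 4)):
        df.loc[f"{strand}:{core}", "s"] = n
    out = collapse(df, "SBS6144", "SBS1536")
    assert out.loc[core, "s"] == 10
    assert out.to_numpy().sum() == 10


def test_collapse_chain_conserves_column_sums(world, tmp_path):
    res = generate_matrices(
        "w", world.catalogue["vcfs"], world.build, tmp_path / "out"
    )
    m = res["matrices"]
    for fine, coarse in [
        ("SBS6144", "SBS1536"), ("SBS1536", "SBS96"), ("SBS96", "SBS6"),
        ("SBS6144", "SBS384"), ("SBS24", "SBS6"),
        ("DBS2976", "DBS1248"), ("DBS186", "DBS78"),
        ("ID415", "ID83"), ("ID83", "ID28"), ("ID8628", "ID83"),
    ]:
        assert (
            collapse(m[fine], fine, coarse).sum().equals(m[coarse].sum())
        ), (fine, coarse)
    # the two SBS-6 routes agree
    assert collapse(m["SBS96"], "SBS96", "SBS6").sum().equals(
        collapse(m["SBS24"], "SBS24", "SBS6").sum()
    )


def test_edge_events_are_excluded_with_ledger(write_build, tmp_path):
    """An SBS at position 1 lacks context: counted in SBS-24/6, excluded
    from the context matrices, and recorded in the run log."""
    body = "1\t1\t.\tA\tT\t.\t.\t.\n1\t5\t.\tC\tT\t.\t.\t.\n"
    _, res = _tiny_run(write_build, tmp_path, body)
    m = res["matrices"]
    assert m["SBS6144"].to_numpy().sum() == 1
    assert m["SBS96"].to_numpy().sum() == 1
    assert m["SBS24"].to_numpy().sum() == 2
    assert m["SBS6"].to_numpy().sum() == 2
    assert res["stats"]["sbs_context_unavailable"] == 1


def test_undefined_collapse_is_hard_error():
    df = empty_matrix("SBS96", ["s"])
    with pytest.raises(KeyError):
        collapse(df, "SBS96", "ID83")


def test_ref_mismatch_dropped_and_logged(write_build, tmp_path):
    body = "1\t5\t.\tG\tT\t.\t.\t.\n"  # reference has C at position 5
    _, res = _tiny_run(write_build, tmp_path, body)
    assert res["matrices"]["SBS6"].to_numpy().sum() == 0
    assert res["stats"]["ref_mismatch"] == 1


def test_additivity_across_chromosome_split(world, tmp_path):
    """Per-chromosome matrix sets sum to the whole-genome matrices."""
    res = generate_matrices(
        "w", world.catalogue["vcfs"], world.build, tmp_path / "out",
        per_chromosome=True,
    )
    per = res["per_chromosome"]
    for scheme in ("SBS6144", "DBS2976", "ID415", "SBS96", "ID28"):
        total = sum(mats[scheme] for mats in per.values())
        pd.testing.assert_frame_equal(total, res["matrices"][scheme])


def test_determinism_byte_identical_outputs(world, tmp_path):
    r1 = generate_matrices("w", world.catalogue["vcfs"], world.build, tmp_path / "a")
    r2 = generate_matrices("w", world.catalogue["vcfs"], world.build, tmp_path / "b")
    for p1, p2 in zip(r1["paths"], r2["paths"]):
        assert p1.read_bytes() == p2.read_bytes()


class TestRegions:
    def test_bed_subsetting_keeps_covered_mutations(self, write_build, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("1\t4\t5\n")  # 0-based half-open: only position 5
        body = "1\t5\t.\tC\tT\t.\t.\t.\n1\t21\t.\tC\tA\t.\t.\t.\n1\t24\t.\tG\tC\t.\t.\t.\n"
        _, res = _tiny_run(write_build, tmp_path, body, bed=bed)
        assert res["matrices"]["SBS6"].to_numpy().sum() == 1
        assert res["stats"]["outside_region"] == 2

    def test_bed_unknown_chromosome_ignored(self, world, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("1\t0\t100\nUn_random\t0\t50\n")
        trees = read_bed(bed, world.build)
        assert set(trees) == {"1"}

    def test_exome_mode_keeps_exonic_only(self, tmp_path, write_build):
        """One exonic and one intronic SBS: exome mode keeps the exonic one,
        matching a direct interval check."""
        build, _, _ = write_build(
            {"1": "AGTTCCAGGACCAATTACAACAGGCGC"},
            annotation=[("1", "+", 2, 24, "2,20", "8,24")],
        )
        vcf = tmp_path / "s.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1,length=27>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t5\t.\tC\tT\t.\t.\t.\n"   # inside exon 3-8
            "1\t12\t.\tC\tA\t.\t.\t.\n"  # intronic
        )
        res = generate_matrices("t", [vcf], build, tmp_path / "out", exome=True)
        assert res["matrices"]["SBS6"].to_numpy().sum() == 1
        ex = build.exon_intervals()["1"]
        assert any(s <= 5 <= e for s, e in ex)
        assert not any(s <= 12 <= e for s, e in ex)

    def test_exome_without_exons_is_an_error(self, write_build, tmp_path):
        with pytest.raises(ValueError):
            _tiny_run(write_build, tmp_path, "1\t5\t.\tC\tT\t.\t.\t.\n", exome=True)


class TestStrandBias:
    def _matrices(self, t, u):
        df = empty_matrix("SBS384", ["s"])
        df.loc["T:A[C>A]A", "s"] = t
        df.loc["U:A[C>A]A", "s"] = u
        return {"SBS384": df}

    def test_symmetric_counts_give_p_one(self):
        res = strand_bias_test(self._matrices(5, 5))
        row = res[res.channel == "A[C>A]A"].iloc[0]
        assert row.transcribed == 5 and row.untranscribed == 5
        assert row.p_value == pytest.approx(1.0)

    def test_one_sided_counts_match_exact_binomial_tail(self):
        """P(all 10 on one strand) enumerated directly: 2 * (1/2)^10."""
        res = strand_bias_test(self._matrices(10, 0))
        row = res[res.channel == "A[C>A]A"].iloc[0]
        exact = 2 * sum(
            math.comb(10, k) for k in (0, 10)
        ) * 0.5**10 / 2  # = 2 * 0.5**10
        assert row.p_value == pytest.approx(2 * 0.5**10)
        assert row.p_value == pytest.approx(exact)

    def test_zero_total_channels_skipped(self):
        res = strand_bias_test(self._matrices(0, 0))
        assert res.empty

    def test_bh_adjustment_properties(self, world, tmp_path):
        res = generate_matrices(
            "w", world.catalogue["vcfs"], world.build, tmp_path / "out",
            tsb_test=True,
        )
        sb = res["strand_bias"]
        assert not sb.empty
        assert (sb.q_value >= sb.p_value - 1e-12).all()
        assert (sb.q_value <= 1.0).all() and (sb.p_value >= 0).all()
        for _, grp in sb.groupby(["sample", "scheme"]):
            grp = grp.sort_values("p_value")
            # BH q-values are monotone nondecreasing in ranked p
            assert (grp.q_value.diff().dropna() >= -1e-12).all()
        assert (tmp_path / "out" / "TSB" / "w.strand_bias.tsv").exists()


def test_scheme_cardinalities():
    expected = {
        "SBS6": 6, "SBS24": 24, "SBS96": 96, "SBS384": 384,
        "SBS1536": 1536, "SBS6144": 6144,
        "DBS78": 78, "DBS1248": 1248,
        "ID83": 83, "ID415": 415, "ID28": 28,
    }
    for scheme, n in expected.items():
        assert len(channels(scheme)) == n
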