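"""HGVS parsing, record merging, carrier/frequency conventions, table I/O."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sorlvar.ingest import (
    AA1,
    ChangeKind,
    Cohort,
    CohortIndividual,
    HgvsParseError,
    ProteinChange,
    VariantRecord,
    carrier_set,
    effective_maf,
    format_hgvs_p,
    merge_cis_adjacent,
    parse_hgvs_p,
    read_cohort_tsv,
    read_variant_tsv,
    write_variant_tsv,
)


@pytest.mark.parametrize(
    "text, ref, pos, alt, kind",
    [
        ("p.Y391C", "Y", 391, "C", ChangeKind.MISSENSE),
        ("p.R866X", "R", 866, "*", ChangeKind.NONSENSE),
        ("p.R744X", "R", 744, "*", ChangeKind.NONSENSE),
        ("p.D1261G", "D", 1261, "G", ChangeKind.MISSENSE),
        ("Y391C", "Y", 391, "C", ChangeKind.MISSENSE),
        ("p.Trp1673Ter", "W", 1673, "*", ChangeKind.NONSENSE),
        ("p.Arg953His", "R", 953, "H", ChangeKind.MISSENSE),
        ("p.R1303fs", "R", 1303, "R", ChangeKind.FRAMESHIFT),
        ("p.Gly511Argfs*12", "G", 511, "G", ChangeKind.FRAMESHIFT),
    ],
)
def test_parse_hgvs_examples(text, ref, pos, alt, kind):
    pc = parse_hgvs_p(text)
    assert (pc.ref_aa, pc.position, pc.alt_aa, pc.kind) == (ref, pos, alt, kind)


@pytest.mark.parametrize("bad", ["p.Q12?", "", "p.", "12A", "p.A0G", "p.BxxC"])
def test_parse_hgvs_rejects_malformed(bad):
    with pytest.raises(HgvsParseError):
        parse_hgvs_p(bad)


def test_parse_double_substitution():
    pc = parse_hgvs_p("p.Y100_D101delinsCG")
    assert pc.second_change == ("D", "G")
    assert pc.positions == (100, 101)
    assert pc.substitutions() == [("Y", 100, "C"), ("D", 101, "G")]


_aa = st.sampled_from(list(AA1))
_pos = st.integers(min_value=1, max_value=2214)


@given(ref=_aa, pos=_pos, alt=_aa, kind=st.sampled_from(["mis", "non", "fs"]))
def test_format_parse_round_trip(ref, pos, alt, kind):
    if kind == "mis":
        if ref == alt:
            return
        pc = ProteinChange(ref, pos, alt, ChangeKind.MISSENSE)
    elif kind == "non":
        pc = ProteinChange(ref, pos, "*", ChangeKind.NONSENSE)
    else:
        pc = ProteinChange(ref, pos, ref, ChangeKind.FRAMESHIFT)
    assert parse_hgvs_p(format_hgvs_p(pc)) == pc


def _missense_record(vid, ref, pos, alt, revel=None, carriers=None, maf=None):
    return VariantRecord(
        variant_id=vid,
        hgvs_p=ProteinChange(ref, pos, alt, ChangeKind.MISSENSE),
        consequence="missense_variant",
        revel=revel,
        gnomad_nonneuro_popmax_maf=maf,
        carriers=carriers or {},
    )


class TestMergeCisAdjacent:
    def test_cis_pair_merged_with_lowest_revel(self):
        a = _missense_record("11:100:A>G", "Y", 100, "C", revel=0.8,
                             carriers={"A": 1.0})
        b = _missense_record("11:103:C>T", "D", 101, "G", revel=0.3,
                             carriers={"A": 1.0})
        out = merge_cis_adjacent(
            [a, b], {frozenset({"11:100:A>G", "11:103:C>T"}): "cis"}
        )
        assert len(out) == 1
        merged = out[0]
        assert merged.revel == 0.3
        assert merged.hgvs_p.second_change == ("D", "G")
        assert "merged_cis" in merged.flags

    def test_unknown_phase_left_unmerged_and_flagged(self):
        a = _missense_record("11:100:A>G", "Y", 100, "C", carriers={"A": 1.0})
        b = _missense_record("11:103:C>T", "D", 101, "G", carriers={"A": 1.0})
        out = merge_cis_adjacent([a, b])
        assert len(out) == 2
        assert all("phase_unknown" in r.flags for r in out)

    def test_single_record_unchanged(self):
        a = _missense_record("11:100:A>G", "Y", 100, "C")
        assert merge_cis_adjacent([a]) == [a]

    def test_merging_preserves_carriers_of_affected_loci(self):
        a = _missense_record("11:100:A>G", "Y", 100, "C",
                             carriers={"A": 1.0, "B": 1.0})
        b = _missense_record("11:103:C>T", "D", 101, "G",
                             carriers={"A": 1.0, "B": 1.0})
        out = merge_cis_adjacent(
            [a, b], {frozenset({"11:100:A>G", "11:103:C>T"}): "cis"}
        )
        assert carrier_set(out[0]) == {"A", "B"}


class TestCarrierSet:
    def test_strictly_above_threshold(self):
        rec = _missense_record("v", "Y", 1, "C", carriers={"A": 0.9, "B": 0.4})
        assert carrier_set(rec) == {"A"}

    def test_empty(self):
        assert carrier_set(_missense_record("v", "Y", 1, "C")) == set()

    def test_boundary_dosage_excluded(self):
        rec = _missense_record("v", "Y", 1, "C", carriers={"A": 0.5})
        assert carrier_set(rec) == set()


def _cohort_of_size(n):
    inds = [CohortIndividual(f"I{k}", "control", 70.0) for k in range(n)]
    return Cohort(individuals=inds)


class TestEffectiveMaf:
    def test_gnomad_passthrough(self):
        rec = _missense_record("v", "Y", 100, "C", maf=0.002)
        maf, source = effective_maf(rec, _cohort_of_size(10))
        assert (maf, source) == (0.002, "gnomad")

    def test_sample_fallback_21_carriers_crosses_threshold(self):
        cohort = _cohort_of_size(40852)
        rec = _missense_record(
            "v", "Y", 100, "C",
            carriers={f"I{k}": 1.0 for k in range(21)},
        )
        maf, source = effective_maf(rec, cohort)
        assert source == "sample"
        assert maf == pytest.approx(21 / 40852)
        assert maf > 0.0005  # at least 21 carriers => no longer rare

    def test_sample_fallback_singleton_is_rare(self):
        cohort = _cohort_of_size(40852)
        rec = _missense_record("v", "Y", 100, "C", carriers={"I0": 1.0})
        maf, source = effective_maf(rec, cohort)
        assert maf == pytest.approx(1 / 40852)
        assert maf < 0.0005

    def test_monotone_in_carrier_count(self):
        cohort = _cohort_of_size(1000)
        prev = -1.0
        for k in (0, 1, 5, 50):
            rec = _missense_record(
                "v", "Y", 100, "C", carriers={f"I{j}": 1.0 for j in range(k)}
            )
            maf, _ = effective_maf(rec, cohort)
            assert maf > prev
            prev = maf


def test_cohort_rejects_unknown_carrier_ids():
    rec = _missense_record("v", "Y", 100, "C", carriers={"ghost": 1.0})
    with pytest.raises(ValueError, match="carriers not in the cohort"):
        Cohort(individuals=[CohortIndividual("I0", "case", 70.0)],
               variants=[rec])


def test_cohort_tsv_round_trip_and_age_coercion(tmp_path):
    path = tmp_path / "cohort.tsv"
    path.write_text(
        "id\tstatus\taao_or_age\tapoe_e4\tapoe_e2\t"
        "pc1\tpc2\tpc3\tpc4\tpc5\tpc6\tcohort\n"
        "A\tcase\t64\t1\t0\t0.1\t0.2\t0.3\t0.4\t0.5\t0.6\tstudy1\n"
        "B\tcontrol\t> 89\t\t\t\t\t\t\t\t\tstudy2\n"
    )
    inds = read_cohort_tsv(path)
    assert inds[0].aao_or_age == 64.0 and inds[0].apoe_e4_count == 1
    assert inds[0].pcs == (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    assert inds[1].aao_or_age == 90.0  # "> 89" stored as 90
    assert inds[1].apoe_e4_count is None and inds[1].pcs is None


def test_variant_tsv_round_trip(tmp_path, arch, rules, variant_table):
    variants, _ = variant_table
    path = tmp_path / "variants.tsv"
    write_variant_tsv(variants, path)
    back = read_variant_tsv(path)
    assert len(back) == len(variants)
    for orig, rt in zip(variants, back):
        assert rt.variant_id == orig.variant_id
        assert rt.hgvs_p == orig.hgvs_p
        assert rt.loftee_flag == orig.loftee_flag
        assert rt.revel == pytest.approx(orig.revel) if orig.revel is not None \
            else rt.revel is None


def test_vcf_ingestion(tmp_path):
    vcf = tmp_path / "variants.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=HGVSP,Number=1,Type=String,Description="HGVS protein">\n'
        '##INFO=<ID=REVEL,Number=1,Type=Float,Description="REVEL score">\n'
        '##INFO=<ID=LOFTEE,Number=1,Type=Integer,Description="LoF flag">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n'
        "##contig=<ID=11>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        "11\t121350000\t.\tA\tG\t.\t.\tHGVSP=p.Y391C;REVEL=0.7;LOFTEE=0\t"
        "GT:DS\t0/1:0.98\t0/0:0.01\n"
        "11\t121400000\t.\tC\tT\t.\t.\tHGVSP=p.R866X;LOFTEE=1\t"
        "GT\t0/0\t0/1\n"
    )
    records = read_variant_vcf_checked(vcf)
    assert records[0].variant_id == "11:121350000:A>G"
    assert records[0].hgvs_p.kind is ChangeKind.MISSENSE
    assert records[0].revel == pytest.approx(0.7)
    assert carrier_set(records[0]) == {"S1"}
    assert records[1].loftee_flag == 1
    assert carrier_set(records[1]) == {"S2"}


def read_variant_vcf_checked(path):
    from sorlvar.ingest import read_variant_vcf

    return read_variant_vcf(path)
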