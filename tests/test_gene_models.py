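import numpy as np
import pytest

from conftest import KAA_DNA, RAA_DNA, TAA_DNA, TPA_DNA, region_from_units
from oracles import orf_spans_repeats

from afgpkit.gene_models import (
    MassModel,
    assign_isoform_bin,
    classify_gene,
    digest_polyprotein,
    family_summary,
    find_cleavage_sites,
    isoform_from_repeats,
    isoform_table,
    peptide_mass,
)
from afgpkit.repeat_scanner import find_repeat_region
from afgpkit.seqio import GeneRecord


def make_gene(units_dna, stub_codons=12, indel=None, insertion=None,
              truncate=False):
    """Assemble a synthetic gene: flanks + ATG + stub + tract + stop."""
    stub = "ATG" + "GAAGTT" * (stub_codons // 2)
    if truncate:
        stub = stub[-12:]
    if indel is not None:
        pos, delta = indel
        stub = stub[:pos] + ("C" * delta if delta > 0 else "") + stub[pos - delta if delta < 0 else pos:]
    tract = "".join(units_dna)
    if insertion is not None:
        at, seq = insertion
        tract = tract[: 9 * at] + seq + tract[9 * at :]
    cds = stub + tract + "TGA"
    flank5, flank3 = "C" * 40, "G" * 40
    seq = flank5 + cds + flank3
    return GeneRecord("g1", "sp", seq, len(flank5), len(flank5) + len(cds))


class TestClassifyGene:
    def test_intact_gene_is_functional(self):
        rec = make_gene([TAA_DNA] * 20)
        assert classify_gene(rec).status == "functional"

    def test_single_deletion_upstream_is_frameshift(self):
        rec = make_gene([TAA_DNA] * 20, indel=(10, -1))
        cls = classify_gene(rec)
        assert (cls.status, cls.pseudogene_reason) == (
            "pseudogene", "frameshift_indel",
        )

    def test_long_insertion_in_tract(self):
        rng = np.random.default_rng(3)
        ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=650))
        rec = make_gene([TAA_DNA] * 20, insertion=(10, ins))
        cls = classify_gene(rec)
        assert (cls.status, cls.pseudogene_reason) == (
            "pseudogene", "coding_insertion",
        )

    def test_five_prime_truncation(self):
        rec = make_gene([TAA_DNA] * 20, truncate=True)
        cls = classify_gene(rec)
        assert (cls.status, cls.pseudogene_reason) == (
            "pseudogene", "five_prime_truncated",
        )

    def test_no_repeats_reported_as_non_afgp(self):
        seq = "ATG" + "GAAGTT" * 20 + "TGA"
        rec = GeneRecord("g", "sp", seq, 0, len(seq))
        assert classify_gene(rec).status == "non_afgp"

    def test_agrees_with_orf_oracle_on_variants(self, rng):
        # intact genes and 1-2 nt indel variants, checked against a
        # first-principles ORF scan
        for _ in range(30):
            n_units = int(rng.integers(6, 25))
            if rng.random() < 0.5:
                rec = make_gene([TAA_DNA] * n_units)
            else:
                delta = int(rng.integers(1, 3)) * (1 if rng.random() < 0.5 else -1)
                rec = make_gene([TAA_DNA] * n_units, indel=(9, delta))
            region = find_repeat_region(rec.cds)
            expected_functional = orf_spans_repeats(
                rec.cds, region.cds_offset_start, region.cds_offset_end
            )
            got = classify_gene(rec).status == "functional"
            assert got == expected_functional


class TestCleavageSites:
    def test_single_lys_site(self):
        region = region_from_units([TAA_DNA] * 4 + [KAA_DNA] + [TAA_DNA] * 5)
        sites = find_cleavage_sites(region)
        assert [(s.unit_index, s.site_type) for s in sites] == [(4, "single_Lys")]

    def test_raar_spans_unit_boundary(self):
        region = region_from_units(
            [TAA_DNA] * 3 + [RAA_DNA, RAA_DNA] + [TAA_DNA] * 2
        )
        sites = find_cleavage_sites(region)
        assert [(s.unit_index, s.site_type, s.residue_span) for s in sites] == [
            (3, "RAAR", 4)
        ]

    def test_lone_arg_is_single_arg(self):
        region = region_from_units([TAA_DNA] * 3 + [RAA_DNA] + [TAA_DNA] * 3)
        sites = find_cleavage_sites(region)
        assert [(s.unit_index, s.site_type) for s in sites] == [(3, "single_Arg")]

    def test_all_taa_has_no_sites(self):
        region = region_from_units([TAA_DNA] * 8)
        assert find_cleavage_sites(region) == []

    def test_every_kaa_maps_to_one_site(self, rng):
        for _ in range(30):
            pool = [TAA_DNA, TPA_DNA, KAA_DNA]
            dnas = [pool[i] for i in rng.integers(0, 3, size=int(rng.integers(4, 30)))]
            region = region_from_units(dnas)
            sites = find_cleavage_sites(region)
            n_kaa = sum(d == KAA_DNA for d in dnas)
            assert sum(s.site_type == "single_Lys" for s in sites) == n_kaa


class TestDigestion:
    def test_lys_split_four_five(self):
        region = region_from_units([TAA_DNA] * 4 + [KAA_DNA] + [TAA_DNA] * 5)
        isos = digest_polyprotein(region)
        assert [i.n_repeats for i in isos] == [4, 5]
        assert [i.size_bin for i in isos] == ["AFGP8", "AFGP7"]

    def test_no_sites_single_product(self):
        region = region_from_units([TAA_DNA] * 7)
        isos = digest_polyprotein(region)
        assert len(isos) == 1 and isos[0].n_repeats == 7

    def test_unit_conservation_on_random_regions(self, rng):
        pool = [TAA_DNA, TPA_DNA, RAA_DNA, KAA_DNA]
        for _ in range(50):
            dnas = [pool[i] for i in rng.integers(0, 4, size=int(rng.integers(4, 40)))]
            region = region_from_units(dnas)
            sites = find_cleavage_sites(region)
            isos = digest_polyprotein(region, sites, min_repeats=0)
            linker_units = set()
            for s in sites:
                linker_units.add(s.unit_index)
                if s.site_type == "RAAR":
                    linker_units.add(s.unit_index + 1)
            product_units = sum(len(i.unit_indices) for i in isos)
            assert product_units + len(linker_units) == region.n_units

    def test_small_fragments_reported_as_sub_afgp(self):
        region = region_from_units(
            [TAA_DNA] * 2 + [KAA_DNA] + [TAA_DNA] * 6
        )
        isos = digest_polyprotein(region)
        assert [(i.n_repeats, i.size_bin) for i in isos] == [
            (2, "sub_AFGP"), (6, "AFGP6_group"),
        ]

    def test_removing_all_spacers_leaves_one_product(self):
        region = region_from_units([TAA_DNA] * 6)
        assert len(digest_polyprotein(region)) == 1


class TestPeptideMass:
    # frozen from an independent sum of standard average residue masses:
    # n*(101.10 + 2*71.08) + 18.02 + n*365.33
    @pytest.mark.parametrize(
        "n,expected",
        [(4, 2452.38), (9, 5495.33), (33, 20101.49), (53, 32273.29)],
    )
    def test_taa_isoform_masses(self, n, expected):
        iso = isoform_from_repeats(n)
        assert iso.mass_da == pytest.approx(expected, abs=0.01)

    def test_empty_peptide_is_water(self):
        iso = isoform_from_repeats(0)
        assert iso.mass_da == pytest.approx(18.02)

    def test_mass_additivity(self):
        a, b = isoform_from_repeats(4), isoform_from_repeats(9)
        ab = isoform_from_repeats(13)
        assert ab.mass_da == pytest.approx(a.mass_da + b.mass_da - 18.02)

    def test_unknown_residue_rejected(self):
        iso = isoform_from_repeats(2)
        iso.residue_composition["Z"] = 1
        with pytest.raises(KeyError):
            peptide_mass(iso)

    def test_mass_strictly_increases_with_repeats(self):
        masses = [isoform_from_repeats(n).mass_da for n in range(1, 20)]
        assert all(b > a for a, b in zip(masses, masses[1:]))


class TestIsoformBins:
    @pytest.mark.parametrize(
        "n,expected",
        [(4, "AFGP8"), (5, "AFGP7"), (2, "sub_AFGP"),
         (9, "AFGP6_group"), (33, "AFGP1_5_group")],
    )
    def test_bins_from_repeat_count(self, n, expected):
        iso = isoform_from_repeats(n)
        assert iso.size_bin == expected


class TestFamilySummary:
    def test_hand_built_family(self):
        dnas = [TAA_DNA] * 4 + [KAA_DNA] + [TAA_DNA] * 6
        rec = make_gene(dnas)
        region = find_repeat_region(rec.cds)
        isos = digest_polyprotein(region, source_gene=rec.id)
        df = family_summary([rec], {rec.id: region}, {rec.id: isos})
        row = df.iloc[0]
        assert row["n_genes"] == 1
        assert row["n_isoforms"] == 2
        assert (row["repeats_min"], row["repeats_max"]) == (4, 6)
        # 11 units = 33 residues: 10 T, 22 A, 1 K
        assert row["pct_T"] == pytest.approx(100 * 10 / 33)
        assert row["pct_K"] == pytest.approx(100 * 1 / 33)

    def test_zero_genes_zero_rows(self):
        assert family_summary([], {}, {}).empty

    def test_isoform_table_columns(self):
        region = region_from_units([TAA_DNA] * 5)
        isos = digest_polyprotein(region, source_gene="g")
        df = isoform_table({"g": isos})
        assert list(df["n_repeats"]) == [5]
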