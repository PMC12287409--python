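import logging

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from knockoutkit.io_catalog import CatalogError, ProteinRecord
from knockoutkit.ptm_constraint import (
    PTMSite,
    ProteinVariant,
    align_orthologs,
    build_residue_track,
    classify_sites,
    export_track,
    parse_site_label,
    read_track,
    validate_sites,
)


def mkvar(pos, ref, alt, cons="missense", ac=1, an=10000, nhom=0, pid="P1"):
    return ProteinVariant(
        protein_id=pid, position=pos, ref_residue=ref, alt_residue=alt,
        consequence=cons, allele_count=ac, allele_number=an,
        homozygote_count=nhom,
    )


@pytest.fixture()
def protein():
    # 12 residues; positions referenced below are 1-based
    return ProteinRecord(protein_id="P1", sequence="MSTAYKLSPQRV")


class TestResidueTrack:
    def test_no_variants_all_zero(self, protein):
        track = build_residue_track(protein, [])
        assert track.missense_count.sum() == 0
        assert track.cumulative_af.sum() == 0.0

    def test_hand_summed_aggregation(self, protein):
        # two missense at position 10 (AF 1e-4 and 2e-4) plus one synonymous
        variants = [
            mkvar(10, "Q", "H", ac=1, an=10000),       # AF 1e-4
            mkvar(10, "Q", "R", ac=2, an=10000),       # AF 2e-4
            mkvar(10, "Q", "Q", cons="synonymous", ac=5, an=10000),
        ]
        track = build_residue_track(protein, variants)
        assert track.missense_count[9] == 2
        assert track.cumulative_af[9] == pytest.approx(3e-4, rel=1e-12)

    def test_ref_mismatch_rejected(self, protein, caplog):
        # sequence has T at position 3, variant claims S
        with caplog.at_level(logging.WARNING, logger="knockoutkit"):
            track = build_residue_track(protein, [mkvar(3, "S", "A")])
        assert track.missense_count.sum() == 0
        assert track.n_rejected == 1

    def test_out_of_range_rejected(self, protein):
        track = build_residue_track(protein, [mkvar(99, "Q", "H")])
        assert track.n_rejected == 1

    def test_other_protein_ignored_not_rejected(self, protein):
        track = build_residue_track(protein, [mkvar(1, "X", "Y", pid="OTHER")])
        assert track.n_rejected == 0 and track.missense_count.sum() == 0

    def test_conservation_of_mass(self, protein):
        rng = np.random.default_rng(2)
        variants = []
        for _ in range(40):
            pos = int(rng.integers(1, len(protein) + 1))
            ref = protein.sequence[pos - 1]
            alt = "W" if ref != "W" else "Y"
            variants.append(mkvar(pos, ref, alt, ac=int(rng.integers(1, 50))))
        track = build_residue_track(protein, variants)
        assert track.cumulative_af.sum() == pytest.approx(
            sum(v.allele_frequency for v in variants), rel=1e-12
        )

    def test_homozygote_flag_carried(self, protein):
        track = build_residue_track(protein, [mkvar(5, "Y", "F", ac=4, nhom=1)])
        assert bool(track.any_homozygote[4])


class TestVariantValidation:
    def test_af_must_match_ac_an(self):
        with pytest.raises(CatalogError):
            ProteinVariant(
                protein_id="P1", position=1, ref_residue="M", alt_residue="V",
                consequence="missense", allele_count=1, allele_number=1000,
                allele_frequency=0.5,
            )

    def test_homozygotes_bounded_by_half_ac(self):
        with pytest.raises(CatalogError):
            mkvar(1, "M", "V", ac=3, nhom=2)

    def test_unknown_consequence(self):
        with pytest.raises(CatalogError):
            mkvar(1, "M", "V", cons="weird")


class TestAlignment:
    def test_identical_sequences_gapless(self):
        aln = align_orthologs("MKTAYW", "MKTAYW")
        assert aln.aligned_a == aln.aligned_b == "MKTAYW"
        assert aln.column_map == [1, 2, 3, 4, 5, 6]

    def test_hand_dp_substitution(self):
        # 3x3 DP by hand with BLOSUM62: M/M=5, K/R=2, T/T=5 -> 12, gapless
        aln = align_orthologs("MKT", "MRT")
        assert (aln.aligned_a, aln.aligned_b) == ("MKT", "MRT")
        assert aln.score == 12.0

    def test_hand_dp_single_gap(self):
        # deleting T costs the open penalty: 5+5-10+4+4 = 8
        aln = align_orthologs("MKTLV", "MKLV")
        assert aln.aligned_b == "MK-LV"
        assert aln.score == 8.0
        assert aln.column_map == [1, 2, None, 3, 4]

    def test_degapping_reproduces_inputs(self):
        a, b = "MKTAYWCC", "MKAYW"
        aln = align_orthologs(a, b)
        assert aln.seq_a == a and aln.seq_b == b

    @pytest.mark.parametrize("seed", range(6))
    def test_score_matches_reference_aligner(self, seed):
        # independent oracle: Biopython's global affine-gap aligner with the
        # same matrix and penalties must produce the same optimal score
        rng = np.random.default_rng(seed)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(aas[i] for i in rng.integers(20, size=int(rng.integers(5, 40))))
        b = "".join(aas[i] for i in rng.integers(20, size=int(rng.integers(5, 40))))
        ref = PairwiseAligner()
        ref.mode = "global"
        ref.substitution_matrix = substitution_matrices.load("BLOSUM62")
        ref.open_gap_score = -10
        ref.extend_gap_score = -1
        assert align_orthologs(a, b).score == pytest.approx(ref.score(a, b))

    def test_gapless_symmetry(self):
        a, b = "MKTAY", "MRTSY"
        fwd = align_orthologs(a, b)
        rev = align_orthologs(b, a)
        assert fwd.score == rev.score
        assert fwd.aligned_a == rev.aligned_b and fwd.aligned_b == rev.aligned_a

    def test_empty_sequence_fatal(self):
        with pytest.raises(CatalogError):
            align_orthologs("", "MKT")


class TestClassifySites:
    def site(self, pos, res, pid="P1"):
        return PTMSite(protein_id=pid, position=pos, residue=res, mod_type="phospho")

    def test_mutated_beats_conservation(self, protein):
        track = build_residue_track(protein, [mkvar(2, "S", "A")])
        aln = align_orthologs(protein.sequence, protein.sequence)
        calls = classify_sites([self.site(2, "S")], track, aln)
        assert calls[0].status == "MUTATED"

    def test_conserved_when_identical(self, protein):
        track = build_residue_track(protein, [])
        aln = align_orthologs(protein.sequence, protein.sequence)
        calls = classify_sites([self.site(2, "S")], track, aln)
        assert calls[0].status == "CONSTRAINED_CONSERVED"
        assert calls[0].ortholog_residue == "S"

    def test_not_conserved_on_substitution(self, protein):
        ortho = protein.sequence.replace("S", "A")
        track = build_residue_track(protein, [])
        aln = align_orthologs(protein.sequence, ortho)
        calls = classify_sites([self.site(2, "S")], track, aln)
        assert calls[0].status == "CONSTRAINED_NOT_CONSERVED"

    def test_unaligned_without_alignment(self, protein):
        track = build_residue_track(protein, [])
        calls = classify_sites([self.site(2, "S")], track, None)
        assert calls[0].status == "CONSTRAINED_UNALIGNED"

    def test_gap_yields_unaligned(self):
        protein = ProteinRecord(protein_id="P1", sequence="MKTLV")
        track = build_residue_track(protein, [])
        aln = align_orthologs(protein.sequence, "MKLV")
        calls = classify_sites([PTMSite(protein_id="P1", position=3,
                                        residue="T", mod_type="phospho")],
                               track, aln)
        assert calls[0].status == "CONSTRAINED_UNALIGNED"

    def test_allow_similar_uses_matrix_sign(self, protein):
        # K->R scores +2 in BLOSUM62: similar, not identical
        ortho = protein.sequence.replace("K", "R")
        track = build_residue_track(protein, [])
        aln = align_orthologs(protein.sequence, ortho)
        site = self.site(6, "K")
        strict = classify_sites([site], track, aln)[0]
        relaxed = classify_sites([site], track, aln, allow_similar=True)[0]
        assert strict.status == "CONSTRAINED_NOT_CONSERVED"
        assert relaxed.status == "CONSTRAINED_CONSERVED"

    def test_statuses_partition_sites(self, ikba):
        track = build_residue_track(ikba.protein, ikba.variants)
        calls = classify_sites(ikba.sites, track, ikba.alignment())
        assert len(calls) == len(ikba.sites)
        for c in calls:
            assert (c.status == "MUTATED") == (c.missense_count > 0)

    def test_site_outside_track_fatal(self, protein):
        track = build_residue_track(protein, [])
        with pytest.raises(CatalogError):
            classify_sites([self.site(99, "S")], track, None)


class TestSiteParsing:
    def test_label_round(self):
        assert parse_site_label("S32") == ("S", 32)
        assert parse_site_label(" k67 ") == ("K", 67)

    def test_bad_label(self):
        with pytest.raises(CatalogError):
            parse_site_label("32S")

    def test_validation_against_sequence(self, protein):
        good = PTMSite(protein_id="P1", position=2, residue="S")
        assert validate_sites([good], protein) == [good]
        with pytest.raises(CatalogError):
            validate_sites(
                [PTMSite(protein_id="P1", position=2, residue="T")], protein
            )


class TestExportTrack:
    def test_rows_and_ptm_flag(self, tmp_path):
        protein = ProteinRecord(protein_id="P1", sequence="MST")
        track = build_residue_track(protein, [])
        sites = [PTMSite(protein_id="P1", position=2, residue="S",
                         mod_type="phospho")]
        df = export_track(protein, track, sites, [], tmp_path / "t.tsv")
        assert len(df) == 3
        assert df.loc[1, "is_ptm"] == 1 and df.loc[0, "is_ptm"] == 0

    def test_round_trip_bit_exact(self, tmp_path, ikba):
        track = build_residue_track(ikba.protein, ikba.variants)
        out = tmp_path / "track.tsv"
        export_track(ikba.protein, track, ikba.sites, [], out)
        back = read_track(out, protein_id=ikba.protein.protein_id)
        assert np.array_equal(back.missense_count, track.missense_count)
        assert np.array_equal(back.cumulative_af, track.cumulative_af)
        assert np.array_equal(back.any_homozygote, track.any_homozygote)

    def test_length_mismatch_fatal(self, tmp_path):
        protein = ProteinRecord(protein_id="P1", sequence="MST")
        other = ProteinRecord(protein_id="P1", sequence="MSTA")
        track = build_residue_track(other, [])
        with pytest.raises(CatalogError):
            export_track(protein, track, [], [], tmp_path / "t.tsv")

    def test_svg_written(self, tmp_path, ikba):
        track = build_residue_track(ikba.protein, ikba.variants)
        calls = classify_sites(ikba.sites, track, ikba.alignment())
        svg = tmp_path / "t.svg"
        export_track(ikba.protein, track, ikba.sites, calls,
                     tmp_path / "t.tsv", svg_path=svg)
        assert svg.stat().st_size > 0
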