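import numpy as np
import pytest
from scipy import stats

from knockoutkit.compendium import build_compendium, overlap_summary
from knockoutkit.io_catalog import CatalogError
from knockoutkit.ptm_constraint import align_orthologs, build_residue_track
from knockoutkit.synthetic_data import (
    OrthologSpec,
    StudyListSpec,
    VariantTableSpec,
    gen_concordance,
    gen_ortholog,
    gen_shet_groups,
    gen_study_lists,
    gen_variant_table,
    ikba_demo,
)

ABC_MATRIX = {
    "g1": {"A"},
    "g2": {"A", "B"},
    "g3": {"A", "B", "C"},
    "g4": {"B"},
}


class TestStudyListGenerator:
    def test_explicit_matrix_reproduced(self):
        lists, truth = gen_study_lists(StudyListSpec(membership=ABC_MATRIX))
        assert lists == {
            "A": {"g1", "g2", "g3"},
            "B": {"g2", "g3", "g4"},
            "C": {"g3"},
        }
        assert truth.count_by_n_studies == {1: 2, 2: 1, 3: 1}

    def test_probability_one_puts_every_gene_everywhere(self):
        spec = StudyListSpec(
            n_genes_universe=20,
            inclusion_probability={"A": 1.0, "B": 1.0, "C": 1.0},
            seed=1,
        )
        lists, truth = gen_study_lists(spec)
        assert all(len(g) == 20 for g in lists.values())
        assert truth.count_by_n_studies == {3: 20}

    def test_half_probability_within_binomial_bounds(self):
        # exactly-one expectation: 3 * 100 * 0.5 * 0.25 = 37.5
        spec = StudyListSpec(
            n_genes_universe=100,
            inclusion_probability={"A": 0.5, "B": 0.5, "C": 0.5},
            seed=11,
        )
        _, truth = gen_study_lists(spec)
        n, p = 100, 3 * 0.5 * 0.25
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
        assert lo <= truth.count_by_n_studies.get(1, 0) <= hi

    def test_same_seed_same_output(self):
        spec = dict(n_genes_universe=50,
                    inclusion_probability={"A": 0.3, "B": 0.6}, seed=4)
        a, _ = gen_study_lists(StudyListSpec(**spec))
        b, _ = gen_study_lists(StudyListSpec(**spec))
        assert a == b

    def test_truth_matches_recomputation(self):
        spec = StudyListSpec(
            n_genes_universe=80,
            inclusion_probability={"A": 0.4, "B": 0.4, "C": 0.2},
            seed=9,
        )
        lists, truth = gen_study_lists(spec)
        recomputed = overlap_summary(build_compendium(lists))
        assert recomputed.count_by_n_studies == truth.count_by_n_studies
        assert recomputed.exclusive_by_study == truth.exclusive_by_study

    def test_ambiguous_spec_rejected(self):
        with pytest.raises(CatalogError):
            StudyListSpec(membership=ABC_MATRIX, inclusion_probability={"A": 1.0})


class TestVariantGenerator:
    def make_protein(self, length=100, seed=5):
        from knockoutkit.io_catalog import ProteinRecord
        from knockoutkit.synthetic_data import AMINO_ACIDS

        rng = np.random.default_rng(seed)
        return ProteinRecord(
            protein_id="SYN",
            sequence="".join(
                AMINO_ACIDS[int(i)] for i in rng.integers(20, size=length)
            ),
        )

    def test_zero_rate_empty_table(self):
        protein = self.make_protein()
        assert gen_variant_table(VariantTableSpec(missense_rate=0.0), protein) == []

    def test_protected_positions_hard_guarantee(self):
        protein = self.make_protein(length=317)
        spec = VariantTableSpec(
            missense_rate=0.5, protected_positions=frozenset({32, 36}), seed=3
        )
        track = build_residue_track(protein, gen_variant_table(spec, protein))
        assert track.missense_count[31] == 0 and track.missense_count[35] == 0

    def test_total_count_within_poisson_bounds(self):
        protein = self.make_protein(length=100)
        spec = VariantTableSpec(missense_rate=1.0, synonymous_fraction=0.0, seed=5)
        variants = gen_variant_table(spec, protein)
        n_missense = sum(1 for v in variants if v.consequence == "missense")
        lo, hi = stats.poisson.ppf([0.005, 0.995], 100)
        assert lo <= n_missense <= hi

    def test_refs_match_sequence_and_af_consistent(self):
        protein = self.make_protein()
        for v in gen_variant_table(VariantTableSpec(seed=8), protein):
            assert protein.sequence[v.position - 1] == v.ref_residue
            assert v.allele_frequency == pytest.approx(
                v.allele_count / v.allele_number
            )


class TestOrthologGenerator:
    BASE = "MSTAYKLSPQRVMSTAYKLSPQRV"

    def test_zero_rates_identical(self):
        seq, pmap = gen_ortholog(OrthologSpec(base_sequence=self.BASE,
                                              substitution_prob=0.0))
        assert seq == self.BASE
        assert all(pmap[i] == i for i in range(1, len(self.BASE) + 1))

    def test_full_substitution_outside_conserved(self):
        spec = OrthologSpec(
            base_sequence=self.BASE,
            substitution_prob=1.0,
            conserved_positions=frozenset({1, 2, 3, 4, 5}),
            seed=2,
        )
        seq, _ = gen_ortholog(spec)
        assert seq[:5] == self.BASE[:5]
        assert all(seq[i] != self.BASE[i] for i in range(5, len(self.BASE)))

    def test_position_map_is_alignment_oracle(self):
        # with indels present, the aligner must still map every conserved
        # base position onto an identical ortholog residue
        rng = np.random.default_rng(9)
        from knockoutkit.synthetic_data import AMINO_ACIDS

        base = "".join(AMINO_ACIDS[int(i)] for i in rng.integers(20, size=300))
        conserved = frozenset({10, 50, 100, 150, 200, 250, 299})
        spec = OrthologSpec(
            base_sequence=base,
            substitution_prob=0.05,
            indel_prob=0.02,
            conserved_positions=conserved,
            seed=9,
        )
        seq, pmap = gen_ortholog(spec)
        aln = align_orthologs(base, seq)
        for pos in conserved:
            assert seq[pmap[pos] - 1] == base[pos - 1]
            assert aln.ortholog_residue(pos) == base[pos - 1]

    def test_determinism(self):
        spec = dict(base_sequence=self.BASE, substitution_prob=0.3,
                    indel_prob=0.1, seed=6)
        assert gen_ortholog(OrthologSpec(**spec)) == gen_ortholog(OrthologSpec(**spec))


class TestShetGenerator:
    def test_tiny_sigma_concentrates(self):
        table, sets = gen_shet_groups([("grp", 50, float(np.log(0.1)), 1e-8)], seed=1)
        values = [table.scores[g] for g in sets[0].members]
        assert all(abs(v - 0.1) < 1e-6 for v in values)

    def test_zero_n_group_empty_with_warning(self, caplog):
        table, sets = gen_shet_groups([("empty", 0, -3.0, 1.0)], seed=1)
        assert len(sets[0].members) == 0 and len(table) == 0

    def test_sigma_must_be_positive(self):
        with pytest.raises(CatalogError):
            gen_shet_groups([("bad", 10, -3.0, 0.0)], seed=1)


class TestConcordanceGenerator:
    def test_truth_matches_membership(self):
        demo = gen_concordance(n_pairs=200, shared_fraction=0.5, seed=1)
        planted = sum(
            1 for i in range(1, 201) if f"HUM{i:05d}" in demo.nonessential_a
        )
        assert planted == demo.n_shared_truth

    def test_decoys_present(self):
        demo = gen_concordance(n_pairs=100, n_nonviable=10, n_non_one_to_one=5,
                               seed=2)
        calls = set(demo.viability_b.calls.values())
        assert {"lethal", "subviable"} <= calls
        assert any(not o for _, _, o in demo.ortholog_map.pairs)


class TestIkbaDemo:
    def test_site_residues_forced(self):
        demo = ikba_demo(seed=3)
        for site in demo.sites:
            assert demo.protein.residue(site.position) == site.residue

    def test_determinism(self):
        a, b = ikba_demo(seed=3), ikba_demo(seed=3)
        assert a.protein.sequence == b.protein.sequence
        assert a.ortholog_seq == b.ortholog_seq
        assert [
            (v.position, v.alt_residue, v.allele_count) for v in a.variants
        ] == [(v.position, v.alt_residue, v.allele_count) for v in b.variants]
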