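"""Seeded generators for every input the pipeline consumes.

Each generator plants a known ground truth (overlap structure, protected
residues, conserved positions, group location shifts, shared ortholog
fractions) so that every downstream stage can be tested for exact recovery
without any external download.  All randomness flows from one explicit seed
per call through :func:`numpy.random.default_rng`; no global state.  Hard
guarantees (protected positions carry zero variants, conserved positions
are never substituted, explicit membership matrices are reproduced
verbatim) hold with probability one.

The flagship fixture :func:`ikba_demo` emulates the classic IκBα story:
a synthetic 317-residue sequence carrying phospho-degron serines at
positions 32/36, the tyrosine 42 alternative-activation site and the
ubiquitin-acceptor lysine 67, a variant table that leaves those residues
untouched, and a diverged ortholog that conserves them.  The residue
numbering mirrors the real protein; the sequence itself is synthetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .compendium import OverlapSummary, build_compendium, overlap_summary
from .constraint_sets import OrthologMap, ShetTable, ViabilityTable
from .io_catalog import CatalogError, GeneSet, ProteinRecord, StudySource
from .ptm_constraint import (
    PairwiseAlignment,
    PTMSite,
    ProteinVariant,
    align_orthologs,
)

logger = logging.getLogger("knockoutkit")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# study lists
# ---------------------------------------------------------------------------

@dataclass
class StudyListSpec:
    """Design for synthetic per-study knockout gene lists.

    Exactly one of ``membership`` (explicit gene -> set of study_ids, fully
    deterministic) or ``inclusion_probability`` (study_id -> Bernoulli
    inclusion probability per gene, seeded) must be given.
    """

    n_genes_universe: int = 0
    membership: Optional[Mapping[str, set[str]]] = None
    inclusion_probability: Optional[Mapping[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.membership is None) == (self.inclusion_probability is None):
            raise CatalogError(
                "give exactly one of membership or inclusion_probability"
            )
        if self.inclusion_probability is not None:
            if self.n_genes_universe <= 0:
                raise CatalogError("probabilistic design needs n_genes_universe > 0")
            for s, p in self.inclusion_probability.items():
                if not 0.0 <= p <= 1.0:
                    raise CatalogError(f"inclusion probability for {s} outside [0,1]")


def gen_study_lists(
    spec: StudyListSpec,
) -> tuple[dict[str, set[str]], OverlapSummary]:
    """Materialize study gene lists plus their exact ground-truth overlap.

    With an explicit membership design the ground truth equals the matrix's
    column sums; with a probabilistic design the truth is computed from the
    realized draws (still exact for the generated lists).  Same spec and
    seed give identical output.
    """
    if spec.membership is not None:
        studies = sorted({s for ss in spec.membership.values() for s in ss})
        lists: dict[str, set[str]] = {s: set() for s in studies}
        for gene, ss in spec.membership.items():
            if not ss:
                raise CatalogError(f"gene {gene!r} in no study")
            for s in ss:
                lists[s].add(gene)
    else:
        rng = np.random.default_rng(spec.seed)
        genes = [f"G{i:05d}" for i in range(1, spec.n_genes_universe + 1)]
        lists = {}
        for study in sorted(spec.inclusion_probability):
            p = spec.inclusion_probability[study]
            draw = rng.random(len(genes)) < p
            lists[study] = {g for g, hit in zip(genes, draw) if hit}
    catalog = [StudySource(study_id=s) for s in sorted(lists)]
    truth = overlap_summary(build_compendium(lists, catalog))
    return lists, truth


# Table-style nine-study design: per-study knockout list sizes from the
# large published sequencing efforts, largest (the million-exome project)
# last.  Used by :func:`gen_compendium_demo`.
NINE_STUDY_SIZES: dict[str, int] = {
    "macarthur2012": 98,
    "lim2014": 80,
    "decode": 1171,
    "exac": 1775,
    "elgh": 781,
    "promis": 1317,
    "gnomad": 1815,
    "rausell2020": 166,
    "rgcme": 4848,
}

#: planted compendium marginals: union, single-study, largest-study-exclusive
#: and multi-study gene counts of the published nine-study compilation
COMPENDIUM_MARGINALS = {
    "union": 6689,
    "single_study": 3895,
    "largest_exclusive": 2736,
    "multi_study": 2794,
}


@dataclass
class CompendiumDemo:
    """A nine-study synthetic compendium design with planted marginals."""

    membership: dict[str, set[str]]
    catalog: list[StudySource]
    pathway_set: GeneSet
    n_pathway_knockouts: int

    @property
    def study_lists(self) -> dict[str, set[str]]:
        lists: dict[str, set[str]] = {s.study_id: set() for s in self.catalog}
        for gene, ss in self.membership.items():
            for s in ss:
                lists[s].add(gene)
        return lists


def gen_compendium_demo(
    seed: int = 0, n_pathway_knockouts: int = 28, n_pathway_extra: int = 47
) -> CompendiumDemo:
    """Build an explicit nine-study membership matrix whose marginals match
    the published compilation: 6689 genes in total, 3895 seen in a single
    study (2736 of them exclusive to the largest, million-exome study) and
    2794 seen in two or more studies.

    The matrix is synthetic — gene identities are placeholders — but the
    marginal counts are planted exactly, so the compendium stage can be
    exercised at full scale and must recover them.  A pathway gene set with
    ``n_pathway_knockouts`` members inside the compendium and
    ``n_pathway_extra`` members outside it is returned alongside (mirroring
    a curated signaling-pathway regulator list whose knockout overlap is
    counted).
    """
    rng = np.random.default_rng(seed)
    studies = list(NINE_STUDY_SIZES)
    largest = max(NINE_STUDY_SIZES, key=NINE_STUDY_SIZES.get)
    others = [s for s in studies if s != largest]
    m = COMPENDIUM_MARGINALS
    genes = [f"G{i:05d}" for i in range(1, m["union"] + 1)]
    membership: dict[str, set[str]] = {}

    # single-study genes: largest-study exclusives first, the rest spread
    # over the other eight studies proportionally to their list sizes
    singles = genes[: m["single_study"]]
    for g in singles[: m["largest_exclusive"]]:
        membership[g] = {largest}
    rest = singles[m["largest_exclusive"]:]
    weights = np.array([NINE_STUDY_SIZES[s] for s in others], dtype=float)
    share = np.floor(weights / weights.sum() * len(rest)).astype(int)
    share[0] += len(rest) - int(share.sum())
    cursor = 0
    for study, k in zip(others, share):
        for g in rest[cursor : cursor + int(k)]:
            membership[g] = {study}
        cursor += int(k)

    # multi-study genes: 2..9 studies each, smaller overlaps more common,
    # studies drawn weighted by list size
    multi = genes[m["single_study"]:]
    assert len(multi) == m["multi_study"]
    k_choices = np.arange(2, 10)
    k_probs = np.array([0.52, 0.24, 0.10, 0.06, 0.04, 0.02, 0.01, 0.01])
    all_weights = np.array([NINE_STUDY_SIZES[s] for s in studies], dtype=float)
    all_weights /= all_weights.sum()
    ks = rng.choice(k_choices, size=len(multi), p=k_probs)
    for g, k in zip(multi, ks):
        chosen = rng.choice(studies, size=int(k), replace=False, p=all_weights)
        membership[g] = set(chosen.tolist())

    # pathway gene set: planted knockout members drawn across the compendium,
    # plus pathway genes with no knockout at all
    ko_members = rng.choice(genes, size=n_pathway_knockouts, replace=False)
    extra = [f"P{i:04d}" for i in range(1, n_pathway_extra + 1)]
    pathway = GeneSet(
        name="pathway_regulators",
        description="synthetic curated signaling-pathway gene list",
        members=frozenset(ko_members.tolist()) | frozenset(extra),
    )
    catalog = [
        StudySource(study_id=s, n_individuals=None, label=s)
        for s in studies
    ]
    return CompendiumDemo(
        membership=membership,
        catalog=catalog,
        pathway_set=pathway,
        n_pathway_knockouts=n_pathway_knockouts,
    )


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

@dataclass
class VariantTableSpec:
    """Design for a synthetic protein-level variant table.

    ``missense_rate`` is the Poisson mean number of missense variants per
    residue; allele frequencies are log-uniform on [af_min, af_max];
    ``protected_positions`` carry no variants at all (hard guarantee);
    a ``synonymous_fraction`` of additional same-residue records is mixed
    in so that consequence filtering is exercised.
    """

    missense_rate: float = 0.3
    af_min: float = 1e-6
    af_max: float = 1e-3
    allele_number: int = 1_000_000
    protected_positions: frozenset[int] = frozenset()
    synonymous_fraction: float = 0.2
    homozygote_probability: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.af_min <= 0 or self.af_max < self.af_min:
            raise CatalogError("need 0 < af_min <= af_max")
        if self.missense_rate < 0:
            raise CatalogError("missense rate must be >= 0")
        self.protected_positions = frozenset(self.protected_positions)


def gen_variant_table(
    spec: VariantTableSpec, protein: ProteinRecord
) -> list[ProteinVariant]:
    """Generate a seeded variant table for one protein.

    Protected positions receive zero variants of any consequence; every
    ref residue matches the sequence; AC/AN/AF are mutually consistent.
    """
    bad = {p for p in spec.protected_positions if not 1 <= p <= len(protein)}
    if bad:
        raise CatalogError(f"protected positions outside protein: {sorted(bad)}")
    rng = np.random.default_rng(spec.seed)
    variants: list[ProteinVariant] = []
    for pos in range(1, len(protein) + 1):
        if pos in spec.protected_positions:
            continue
        ref = protein.sequence[pos - 1]
        n_missense = rng.poisson(spec.missense_rate)
        n_syn = rng.poisson(spec.missense_rate * spec.synonymous_fraction)
        for kind, count in (("missense", n_missense), ("synonymous", n_syn)):
            for _ in range(int(count)):
                if kind == "missense":
                    alt = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
                    while alt == ref:
                        alt = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
                else:
                    alt = ref
                log_af = rng.uniform(np.log(spec.af_min), np.log(spec.af_max))
                ac = max(1, int(round(np.exp(log_af) * spec.allele_number)))
                nhom = 0
                if ac >= 2 and rng.random() < spec.homozygote_probability:
                    nhom = 1
                variants.append(
                    ProteinVariant(
                        protein_id=protein.protein_id,
                        position=pos,
                        ref_residue=ref,
                        alt_residue=alt,
                        consequence=kind,
                        allele_count=ac,
                        allele_number=spec.allele_number,
                        homozygote_count=nhom,
                    )
                )
    for v in variants:  # hard guarantee, asserted on every run
        assert v.position not in spec.protected_positions
        assert protein.sequence[v.position - 1] == v.ref_residue
    return variants


def forced_missense(
    protein: ProteinRecord,
    positions: Sequence[int],
    allele_number: int = 1_000_000,
    allele_count: int = 5,
    seed: int = 0,
) -> list[ProteinVariant]:
    """Deliberately place one missense variant at each given position."""
    rng = np.random.default_rng(seed)
    out = []
    for pos in positions:
        ref = protein.residue(pos)
        alt = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
        while alt == ref:
            alt = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
        out.append(
            ProteinVariant(
                protein_id=protein.protein_id,
                position=pos,
                ref_residue=ref,
                alt_residue=alt,
                consequence="missense",
                allele_count=allele_count,
                allele_number=allele_number,
            )
        )
    return out


# ---------------------------------------------------------------------------
# ortholog sequences
# ---------------------------------------------------------------------------

@dataclass
class OrthologSpec:
    """Design for a diverged ortholog of a base protein sequence.

    Substitutions hit non-conserved positions with ``substitution_prob``;
    short indels occur between positions with ``indel_prob``; conserved
    positions are never substituted or deleted (hard guarantee).
    """

    base_sequence: str
    substitution_prob: float = 0.08
    indel_prob: float = 0.0
    max_indel_length: int = 3
    conserved_positions: frozenset[int] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        self.conserved_positions = frozenset(self.conserved_positions)
        bad = {
            p for p in self.conserved_positions
            if not 1 <= p <= len(self.base_sequence)
        }
        if bad:
            raise CatalogError(f"conserved positions outside sequence: {sorted(bad)}")
        if not 0 <= self.substitution_prob <= 1 or not 0 <= self.indel_prob <= 1:
            raise CatalogError("probabilities must lie in [0,1]")


def gen_ortholog(spec: OrthologSpec) -> tuple[str, dict[int, Optional[int]]]:
    """Generate a diverged ortholog plus a base->ortholog position map.

    The map sends each 1-based base position to its 1-based position in the
    ortholog, or None when the residue was deleted.  Conserved positions
    always map to an identical residue.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[str] = []
    position_map: dict[int, Optional[int]] = {}
    for pos in range(1, len(spec.base_sequence) + 1):
        ref = spec.base_sequence[pos - 1]
        conserved = pos in spec.conserved_positions
        # deletion / insertion events between residues
        if not conserved and rng.random() < spec.indel_prob:
            if rng.random() < 0.5:
                position_map[pos] = None  # delete this residue
                continue
            for _ in range(int(rng.integers(1, spec.max_indel_length + 1))):
                out.append(AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))])
        if not conserved and rng.random() < spec.substitution_prob:
            alt = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
            while alt == ref:
                alt = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
            out.append(alt)
        else:
            out.append(ref)
        position_map[pos] = len(out)
    for pos in spec.conserved_positions:  # hard guarantee
        mapped = position_map[pos]
        assert mapped is not None
        assert out[mapped - 1] == spec.base_sequence[pos - 1]
    return "".join(out), position_map


# ---------------------------------------------------------------------------
# S_het groups
# ---------------------------------------------------------------------------

def gen_shet_groups(
    group_specs: Sequence[tuple[str, int, float, float]],
    seed: int = 0,
) -> tuple[ShetTable, list[GeneSet]]:
    """Generate log-normal S_het scores for named gene groups.

    Each spec is (name, n_genes, lognormal mu, lognormal sigma); sigma must
    be positive.  Gene names carry the group name so planted groups are
    recoverable by eye.  An n = 0 group yields an empty set with a warning.
    """
    rng = np.random.default_rng(seed)
    scores: dict[str, float] = {}
    sets: list[GeneSet] = []
    for name, n, mu, sigma in group_specs:
        if sigma <= 0:
            raise CatalogError(f"group {name}: sigma must be > 0")
        if n == 0:
            logger.warning("group %s: n = 0, empty gene set", name)
            sets.append(
                GeneSet(name=name, description="synthetic empty group",
                        members=frozenset())
            )
            continue
        genes = [f"{name.upper()}{i:04d}" for i in range(1, n + 1)]
        values = rng.lognormal(mean=mu, sigma=sigma, size=n)
        for g, v in zip(genes, values):
            scores[g] = float(v)
        sets.append(
            GeneSet(
                name=name,
                description=f"synthetic S_het group (lognormal mu={mu}, sigma={sigma})",
                members=frozenset(genes),
            )
        )
    return ShetTable(scores=scores), sets


# ---------------------------------------------------------------------------
# ortholog map / concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceDemo:
    """Synthetic cross-species concordance inputs with planted truth."""

    nonessential_a: set[str]
    viability_b: ViabilityTable
    ortholog_map: OrthologMap
    n_shared_truth: int
    n_comparable: int


def gen_concordance(
    n_pairs: int = 1000,
    shared_fraction: float = 0.38,
    n_nonviable: int = 100,
    n_non_one_to_one: int = 50,
    seed: int = 7,
) -> ConcordanceDemo:
    """Generate ortholog pairs with a planted shared-nonessential fraction.

    ``n_pairs`` one-to-one pairs of viable mouse knockouts are created; for
    each, the human ortholog enters the human non-essential set with
    probability ``shared_fraction``.  Non-viable pairs and non-one-to-one
    pairs are mixed in to exercise both filters; their human genes are
    forced into the human set so any filter leak changes the counts.
    """
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str, bool]] = []
    calls: dict[str, str] = {}
    nonessential_a: set[str] = set()
    n_shared = 0
    for i in range(1, n_pairs + 1):
        a, b = f"HUM{i:05d}", f"MUS{i:05d}"
        pairs.append((a, b, True))
        calls[b] = "viable"
        if rng.random() < shared_fraction:
            nonessential_a.add(a)
            n_shared += 1
    for i in range(1, n_nonviable + 1):
        a, b = f"HUMNV{i:04d}", f"MUSNV{i:04d}"
        pairs.append((a, b, True))
        calls[b] = "lethal" if i % 2 else "subviable"
        nonessential_a.add(a)  # must be excluded by the viability filter
    for i in range(1, n_non_one_to_one + 1):
        a, b = f"HUMP{i:04d}", f"MUSP{i:04d}"
        pairs.append((a, b, False))
        calls[b] = "viable"
        nonessential_a.add(a)  # must be excluded by the one-to-one filter
    return ConcordanceDemo(
        nonessential_a=nonessential_a,
        viability_b=ViabilityTable(calls=calls),
        ortholog_map=OrthologMap(pairs=pairs),
        n_shared_truth=n_shared,
        n_comparable=n_pairs,
    )


# ---------------------------------------------------------------------------
# the flagship PTM fixture
# ---------------------------------------------------------------------------

@dataclass
class IkbaDemo:
    """The IκBα-style demonstration fixture (synthetic sequence).

    Planted truth per PTM position: 32/36/42/67 variant-free and conserved;
    100/150 deliberately hit by missense; 200 variant-free but substituted
    in the ortholog; 250 variant-free but deleted in the ortholog.
    """

    protein: ProteinRecord
    sites: list[PTMSite]
    variants: list[ProteinVariant]
    ortholog_seq: str
    position_map: dict[int, Optional[int]]
    expected_status: dict[int, str]

    def alignment(self) -> PairwiseAlignment:
        return align_orthologs(self.protein.sequence, self.ortholog_seq)


def write_ikba_inputs(demo: "IkbaDemo", outdir) -> dict[str, str]:
    """Materialize the demo fixture as the TSV/FASTA dialects the readers
    consume; returns the path of each written file by role."""
    import pandas as pd
    from pathlib import Path

    from .io_catalog import write_fasta
    from .ptm_constraint import write_variant_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "protein.fa",
        "ortholog": outdir / "ortholog.fa",
        "ptm": outdir / "ptm_sites.tsv",
        "variants": outdir / "variants.tsv",
        "domains": outdir / "domains.tsv",
    }
    write_fasta([demo.protein], paths["fasta"])
    write_fasta(
        [ProteinRecord(protein_id="ORTHOLOG_SYN", sequence=demo.ortholog_seq)],
        paths["ortholog"],
    )
    pd.DataFrame(
        [
            {"protein_id": s.protein_id, "site": s.label, "mod_type": s.mod_type}
            for s in demo.sites
        ]
    ).to_csv(paths["ptm"], sep="\t", index=False)
    write_variant_tsv(demo.variants, paths["variants"])
    pd.DataFrame(
        [
            {"protein_id": demo.protein.protein_id, "start": a, "end": b, "label": lab}
            for a, b, lab in demo.protein.domains
        ]
    ).to_csv(paths["domains"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


#: (position, residue, modification) of the planted PTM sites
IKBA_DEMO_SITES: list[tuple[int, str, str]] = [
    (32, "S", "phospho"),
    (36, "S", "phospho"),
    (42, "Y", "phospho"),
    (67, "K", "ubiquitin"),
    (100, "S", "phospho"),
    (150, "T", "phospho"),
    (200, "K", "ubiquitin"),
    (250, "S", "phospho"),
]

IKBA_LENGTH = 317
_IKBA_PROTECTED = frozenset({32, 36, 42, 67, 200, 250})
_IKBA_HIT = (100, 150)
_IKBA_DELETED = range(246, 256)  # ortholog lacks this loop, includes 250


def ikba_demo(seed: int = 3) -> IkbaDemo:
    """Build the 317-residue demonstration protein with planted site fates.

    The sequence is random but seeded; residue identities at the planted
    PTM positions are forced (Ser32, Ser36, Tyr42, Lys67, ...).  Domains
    mimic the ankyrin-repeat region (73-280) and the C-terminal PEST
    segment (281-317) so track rendering has realistic annotation.
    """
    rng = np.random.default_rng(seed)
    seq = [AMINO_ACIDS[int(i)] for i in rng.integers(len(AMINO_ACIDS), size=IKBA_LENGTH)]
    for pos, res, _ in IKBA_DEMO_SITES:
        seq[pos - 1] = res
    sequence = "".join(seq)
    protein = ProteinRecord(
        protein_id="IKBA_DEMO",
        symbol="NFKBIA",
        sequence=sequence,
        domains=[(73, 280, "ankyrin repeats"), (281, 317, "PEST")],
    )
    sites = [
        PTMSite(protein_id="IKBA_DEMO", position=p, residue=r, mod_type=m,
                source="synthetic")
        for p, r, m in IKBA_DEMO_SITES
    ]

    var_spec = VariantTableSpec(
        missense_rate=0.3,
        protected_positions=_IKBA_PROTECTED,
        seed=seed + 1,
    )
    variants = gen_variant_table(var_spec, protein)
    variants += forced_missense(protein, _IKBA_HIT, seed=seed + 2)

    # ortholog: substituted at 200, one deleted loop covering 250, ~8%
    # background substitutions elsewhere, conserved at 32/36/42/67
    ortho: list[str] = []
    position_map: dict[int, Optional[int]] = {}
    conserved = {32, 36, 42, 67}
    rng2 = np.random.default_rng(seed + 3)
    for pos in range(1, IKBA_LENGTH + 1):
        ref = sequence[pos - 1]
        if pos in _IKBA_DELETED:
            position_map[pos] = None
            continue
        if pos == 200 or (pos not in conserved and rng2.random() < 0.08):
            alt = AMINO_ACIDS[int(rng2.integers(len(AMINO_ACIDS)))]
            while alt == ref:
                alt = AMINO_ACIDS[int(rng2.integers(len(AMINO_ACIDS)))]
            ortho.append(alt)
        else:
            ortho.append(ref)
        position_map[pos] = len(ortho)

    expected = {
        32: "CONSTRAINED_CONSERVED",
        36: "CONSTRAINED_CONSERVED",
        42: "CONSTRAINED_CONSERVED",
        67: "CONSTRAINED_CONSERVED",
        100: "MUTATED",
        150: "MUTATED",
        200: "CONSTRAINED_NOT_CONSERVED",
        250: "CONSTRAINED_UNALIGNED",
    }
    return IkbaDemo(
        protein=protein,
        sites=sites,
        variants=variants,
        ortholog_seq="".join(ortho),
        position_map=position_map,
        expected_status=expected,
    )
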