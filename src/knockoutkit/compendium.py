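"""Non-redundant knockout compendium: union with provenance, overlap
statistics, Venn regions, and over-representation analysis (ORA).

The compendium treats "non-redundant" as "distinct canonical symbols": a
gene appearing in several study lists is a single entry whose provenance
records every study that reported it.  Overlap statistics (how many genes
were seen in exactly one study, two studies, three or more) summarize the
agreement between studies; ORA asks whether a gene list overlaps a gene set
more than expected by chance, given a stated universe, using the
hypergeometric upper tail with Benjamini–Hochberg correction across the
tested sets.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_catalog import CatalogError, GeneSet, StudySource

logger = logging.getLogger("knockoutkit")


@dataclass
class KnockoutCompendium:
    """Gene -> set of source studies, plus the study catalog."""

    membership: dict[str, frozenset[str]]
    catalog: list[StudySource] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = {s.study_id for s in self.catalog}
        for gene, studies in self.membership.items():
            studies = frozenset(studies)
            if not studies:
                raise CatalogError(f"gene {gene!r} has empty study provenance")
            if known and not studies <= known:
                raise CatalogError(
                    f"gene {gene!r} cites unknown studies {sorted(studies - known)}"
                )
            self.membership[gene] = studies

    @property
    def genes(self) -> set[str]:
        return set(self.membership)

    def __len__(self) -> int:
        return len(self.membership)

    def __contains__(self, gene: str) -> bool:
        return gene in self.membership

    def study_list(self, study_id: str) -> set[str]:
        """Genes attributed to one study."""
        return {g for g, studies in self.membership.items() if study_id in studies}

    # -- TSV round-trip ----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "gene": gene,
                "n_studies": len(studies),
                "studies": ";".join(sorted(studies)),
            }
            for gene, studies in sorted(self.membership.items())
        ]
        pd.DataFrame(rows, columns=["gene", "n_studies", "studies"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(
        cls, path: str | Path, catalog: Optional[list[StudySource]] = None
    ) -> "KnockoutCompendium":
        df = pd.read_csv(path, sep="\t", dtype=str)
        membership = {
            row["gene"]: frozenset(row["studies"].split(";"))
            for _, row in df.iterrows()
        }
        if catalog is None:  # reconstruct from provenance
            studies = sorted({s for ss in membership.values() for s in ss})
            catalog = [StudySource(study_id=s) for s in studies]
        return cls(membership=membership, catalog=catalog)


@dataclass
class OverlapSummary:
    """How many genes were seen in exactly k studies, and per-study
    exclusives.  ``binned`` is the 3-bin partition (1 / 2 / >=3 studies)."""

    union_size: int
    count_by_n_studies: dict[int, int]
    exclusive_by_study: dict[str, int]

    def __post_init__(self) -> None:
        if sum(self.count_by_n_studies.values()) != self.union_size:
            raise CatalogError("overlap counts do not sum to the union size")
        if self.count_by_n_studies.get(1, 0) != sum(self.exclusive_by_study.values()):
            raise CatalogError("exclusive counts do not sum to the k=1 bin")

    @property
    def binned(self) -> dict[str, int]:
        return {
            "1": self.count_by_n_studies.get(1, 0),
            "2": self.count_by_n_studies.get(2, 0),
            "3+": sum(v for k, v in self.count_by_n_studies.items() if k >= 3),
        }

    @property
    def multi_study(self) -> int:
        """Genes found in two or more studies."""
        return sum(v for k, v in self.count_by_n_studies.items() if k >= 2)


@dataclass
class OraResult:
    """One gene set's over-representation test result."""

    set_name: str
    universe_size: int
    set_size: int
    query_size: int
    overlap: int
    p_value: float
    q_value: float
    overlap_genes: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_compendium(
    study_lists: Mapping[str, Iterable[str]],
    catalog: Optional[Sequence[StudySource]] = None,
) -> KnockoutCompendium:
    """Union the per-study gene lists into a compendium with provenance.

    The result is independent of study and gene ordering.  Symbols are
    assumed canonical already (see :func:`knockoutkit.io_catalog.read_study_lists`).
    An unknown study_id (absent from the catalog) is fatal.
    """
    catalog = list(catalog) if catalog else [
        StudySource(study_id=s) for s in sorted(study_lists)
    ]
    known = {s.study_id for s in catalog}
    unknown = set(study_lists) - known
    if unknown:
        raise CatalogError(f"study lists cite unknown studies {sorted(unknown)}")
    membership: dict[str, set[str]] = {}
    for study_id, genes in study_lists.items():
        for gene in genes:
            membership.setdefault(gene, set()).add(study_id)
    return KnockoutCompendium(
        membership={g: frozenset(s) for g, s in membership.items()},
        catalog=catalog,
    )


def overlap_summary(compendium: KnockoutCompendium) -> OverlapSummary:
    """Count genes by the number of studies that reported them."""
    if not compendium.membership:
        raise CatalogError("cannot summarize an empty compendium")
    count_by_n: Counter[int] = Counter(
        len(studies) for studies in compendium.membership.values()
    )
    exclusive: Counter[str] = Counter()
    for studies in compendium.membership.values():
        if len(studies) == 1:
            (only,) = studies
            exclusive[only] += 1
    all_studies = {s.study_id for s in compendium.catalog} or {
        sid for studies in compendium.membership.values() for sid in studies
    }
    return OverlapSummary(
        union_size=len(compendium),
        count_by_n_studies=dict(sorted(count_by_n.items())),
        exclusive_by_study={s: exclusive.get(s, 0) for s in sorted(all_studies)},
    )


def venn_regions(
    compendium: KnockoutCompendium, studies: Sequence[str]
) -> dict[tuple[str, ...], int]:
    """Counts for every non-empty region of the Venn diagram over 2-5 studies.

    Keys are sorted tuples of the studies a region belongs to; a gene counts
    toward the region given by its provenance restricted to the selected
    studies.  Genes seen only in unselected studies are ignored.  All
    2^s - 1 regions are reported, including zeros.
    """
    studies = list(studies)
    if not 2 <= len(studies) <= 5:
        raise CatalogError(f"venn supports 2-5 studies, got {len(studies)}")
    if len(set(studies)) != len(studies):
        raise CatalogError("duplicate study_id in venn selection")
    known = {s.study_id for s in compendium.catalog}
    missing = set(studies) - known
    if missing:
        raise CatalogError(f"unknown studies in venn selection: {sorted(missing)}")

    from itertools import combinations

    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(studies) + 1):
        for combo in combinations(studies, r):
            regions[tuple(sorted(combo))] = 0
    selected = set(studies)
    for studies_of_gene in compendium.membership.values():
        sig = tuple(sorted(studies_of_gene & selected))
        if sig:
            regions[sig] += 1
    return regions


def intersect_with_geneset(
    compendium: KnockoutCompendium, gene_set: GeneSet
) -> dict[str, frozenset[str]]:
    """Compendium genes that belong to a gene set, provenance retained."""
    return {
        gene: studies
        for gene, studies in compendium.membership.items()
        if gene in gene_set.members
    }


def ora(
    query: Iterable[str],
    gene_sets: Sequence[GeneSet],
    universe: Iterable[str],
) -> list[OraResult]:
    """Over-representation analysis of a gene list against gene sets.

    For each set, the hypergeometric upper tail P(X >= k) with
    N = |universe|, K = |set ∩ universe|, n = |query ∩ universe|,
    k = |query ∩ set ∩ universe|.  q-values are Benjamini–Hochberg across
    all sets tested in this call.  Query genes outside the universe are
    dropped with a warning; sets with zero overlap are still reported.
    """
    universe = set(universe)
    if not universe:
        raise CatalogError("ORA universe is empty")
    query = set(query)
    outside = query - universe
    if outside:
        logger.warning(
            "ORA: dropping %d query genes outside the universe", len(outside)
        )
    query &= universe
    if not query:
        raise CatalogError("ORA query is empty after restriction to the universe")

    N, n = len(universe), len(query)
    results: list[OraResult] = []
    pvals: list[float] = []
    for gs in gene_sets:
        members = gs.members & universe
        K = len(members)
        hits = query & members
        k = len(hits)
        # P(X >= k); survival function is P(X > k-1)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        p = min(max(p, 0.0), 1.0) or 1.0
        pvals.append(p)
        results.append(
            OraResult(
                set_name=gs.name,
                universe_size=N,
                set_size=K,
                query_size=n,
                overlap=k,
                p_value=p,
                q_value=float("nan"),
                overlap_genes=frozenset(hits),
            )
        )
    if results:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for res, q in zip(results, qvals):
            res.q_value = float(q)
    return results


def ora_to_frame(results: Sequence[OraResult]) -> pd.DataFrame:
    """Tabulate ORA results, ordered by p-value."""
    df = pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "universe_size": r.universe_size,
                "set_size": r.set_size,
                "query_size": r.query_size,
                "overlap": r.overlap,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "overlap_genes": ";".join(sorted(r.overlap_genes)),
            }
            for r in results
        ]
    )
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
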