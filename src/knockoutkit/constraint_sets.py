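"""Gene-set essentiality via S_het, human-mouse essentiality concordance,
and the Hardy-Weinberg homozygosity calculator.

S_het is the selection coefficient against heterozygous loss of function:
higher values mean stronger constraint, i.e. a more essential gene.  Scores
are consumed as annotation (one score per gene from a user-supplied table),
never recomputed.  Group summaries are descriptive by default (median and
interquartile range against a stated background universe); a two-sided
rank-sum comparison against the background is opt-in, because a location
test is an inferential claim the descriptive figure-style output does not
itself make.

The concordance operation compares a set of human non-essential genes with
mouse knockout viability calls (viable / subviable / lethal), restricted to
one-to-one orthologs.  Subviable is treated as non-viable and excluded.
Because the natural denominator of "fraction shared" is ambiguous (mouse
side, human side, or the union), all three fractions are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io_catalog import CatalogError, GeneSet

logger = logging.getLogger("knockoutkit")

VIABILITY_CALLS = frozenset({"viable", "subviable", "lethal"})


# ---------------------------------------------------------------------------
# S_het
# ---------------------------------------------------------------------------

@dataclass
class ShetTable:
    """Gene -> S_het score (non-negative selection coefficient)."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        for gene, s in self.scores.items():
            if not math.isfinite(s) or s < 0:
                raise CatalogError(f"S_het for {gene!r} must be finite and >= 0, got {s}")

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, gene: str) -> bool:
        return gene in self.scores

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ShetTable":
        """Read an S_het TSV with columns ``gene`` and ``s_het``."""
        df = pd.read_csv(path, sep="\t")
        if not {"gene", "s_het"}.issubset(df.columns):
            raise CatalogError(f"{path}: S_het TSV needs columns gene, s_het")
        scores: dict[str, float] = {}
        for _, row in df.iterrows():
            gene = str(row["gene"]).strip().upper()
            if gene in scores:
                raise CatalogError(f"{path}: duplicate S_het entry for {gene}")
            scores[gene] = float(row["s_het"])
        return cls(scores=scores)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.scores.items()), columns=["gene", "s_het"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class GroupShetSummary:
    """Descriptive S_het summary for one gene group, optionally with a
    rank-sum comparison against the background."""

    group_name: str
    n_mapped: int
    n_unmapped: int
    median: Optional[float]
    q1: Optional[float]
    q3: Optional[float]
    compare_to_background: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.median is not None and not (self.q1 <= self.median <= self.q3):
            raise CatalogError("quartiles out of order")


def summarize_group_shet(
    group: GeneSet,
    shet: ShetTable,
    background: Iterable[str],
    rank_sum: bool = False,
) -> GroupShetSummary:
    """Summarize a gene group's S_het distribution against a background.

    Genes without an S_het score are excluded from the statistics but
    counted as unmapped.  With ``rank_sum=True``, a two-sided Mann-Whitney
    rank-sum test compares the group's mapped scores against the mapped
    background scores.
    """
    background = set(background)
    mapped = sorted(g for g in group.members if g in shet)
    n_unmapped = len(group.members) - len(mapped)
    if not mapped:
        logger.warning("group %s: no genes with an S_het score", group.name)
        return GroupShetSummary(
            group_name=group.name,
            n_mapped=0,
            n_unmapped=n_unmapped,
            median=None,
            q1=None,
            q3=None,
        )
    values = np.array([shet.scores[g] for g in mapped], dtype=float)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    compare = None
    if rank_sum:
        bg_values = np.array(
            [shet.scores[g] for g in background if g in shet], dtype=float
        )
        if bg_values.size == 0:
            logger.warning("group %s: background has no mapped scores", group.name)
        else:
            stat, p = mannwhitneyu(values, bg_values, alternative="two-sided")
            compare = {"statistic": float(stat), "p_value": float(p)}
    return GroupShetSummary(
        group_name=group.name,
        n_mapped=len(mapped),
        n_unmapped=n_unmapped,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        compare_to_background=compare,
    )


def summaries_to_frame(summaries: Iterable[GroupShetSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "group": s.group_name,
            "n_mapped": s.n_mapped,
            "n_unmapped": s.n_unmapped,
            "median": s.median,
            "q1": s.q1,
            "q3": s.q3,
        }
        if s.compare_to_background:
            row["ranksum_statistic"] = s.compare_to_background["statistic"]
            row["ranksum_p"] = s.compare_to_background["p_value"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# viability + orthologs + concordance
# ---------------------------------------------------------------------------

@dataclass
class ViabilityTable:
    """Mouse gene -> knockout viability call (viable / subviable / lethal)."""

    calls: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.calls.values() if c not in VIABILITY_CALLS}
        if bad:
            raise CatalogError(
                f"unknown viability calls {sorted(bad)}; "
                f"allowed: {sorted(VIABILITY_CALLS)}"
            )

    def viable_genes(self) -> set[str]:
        return {g for g, c in self.calls.items() if c == "viable"}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ViabilityTable":
        """Read a viability TSV with columns ``gene`` and ``call``."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"gene", "call"}.issubset(df.columns):
            raise CatalogError(f"{path}: viability TSV needs columns gene, call")
        return cls(
            calls={
                str(r["gene"]).strip().upper(): str(r["call"]).strip().lower()
                for _, r in df.iterrows()
            }
        )


@dataclass
class OrthologMap:
    """Ortholog pairs (gene_a, gene_b, one_to_one flag) between two species.

    Species A is the namespace of the non-essential set (human); species B
    the namespace of the viability calls (mouse).  A gene participating in
    more than one pair flagged one-to-one is a conflict: such pairs are
    excluded with a log entry rather than trusted.
    """

    pairs: list[tuple[str, str, bool]]
    n_conflicting: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        seen_a: dict[str, int] = {}
        seen_b: dict[str, int] = {}
        for a, b, one2one in self.pairs:
            if one2one:
                seen_a[a] = seen_a.get(a, 0) + 1
                seen_b[b] = seen_b.get(b, 0) + 1
        conflicted_a = {g for g, n in seen_a.items() if n > 1}
        conflicted_b = {g for g, n in seen_b.items() if n > 1}
        if conflicted_a or conflicted_b:
            kept = []
            dropped = 0
            for a, b, one2one in self.pairs:
                if one2one and (a in conflicted_a or b in conflicted_b):
                    dropped += 1
                else:
                    kept.append((a, b, one2one))
            logger.warning(
                "ortholog map: excluded %d pairs with conflicting one-to-one flags",
                dropped,
            )
            self.pairs = kept
            self.n_conflicting = dropped

    def one_to_one(self) -> dict[str, str]:
        """Mapping gene_b -> gene_a over one-to-one pairs only."""
        return {b: a for a, b, one2one in self.pairs if one2one}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologMap":
        """Read an ortholog TSV with columns ``gene_a``, ``gene_b``,
        ``one_to_one`` (0/1)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"gene_a", "gene_b", "one_to_one"}.issubset(df.columns):
            raise CatalogError(
                f"{path}: ortholog TSV needs columns gene_a, gene_b, one_to_one"
            )
        return cls(
            pairs=[
                (
                    str(r["gene_a"]).strip().upper(),
                    str(r["gene_b"]).strip().upper(),
                    str(r["one_to_one"]).strip() in {"1", "true", "True"},
                )
                for _, r in df.iterrows()
            ]
        )


@dataclass
class ConcordanceResult:
    """Cross-species overlap of non-essential genes over one-to-one orthologs.

    All counts are in species-A (human) namespace after translation.  Three
    denominators are exposed because "fraction shared" is ambiguous:
    ``fraction_of_a`` (shared / A-side filtered), ``fraction_of_b``
    (shared / B-side filtered) and ``jaccard`` (shared / union).
    """

    n_a_filtered: int
    n_b_filtered: int
    n_shared: int
    shared: frozenset[str]
    a_only: frozenset[str]
    b_only: frozenset[str]

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_a_filtered, self.n_b_filtered):
            raise CatalogError("shared count exceeds a filtered set size")

    @property
    def fraction_of_a(self) -> float:
        return self.n_shared / self.n_a_filtered if self.n_a_filtered else 0.0

    @property
    def fraction_of_b(self) -> float:
        return self.n_shared / self.n_b_filtered if self.n_b_filtered else 0.0

    @property
    def jaccard(self) -> float:
        union = self.n_a_filtered + self.n_b_filtered - self.n_shared
        return self.n_shared / union if union else 0.0


def concordance(
    nonessential_a: Iterable[str],
    viability_b: ViabilityTable,
    ortholog_map: OrthologMap,
) -> ConcordanceResult:
    """Overlap of species-A non-essential genes with species-B viable knockouts.

    Pipeline order is fixed: (1) keep B genes whose knockout call is
    ``viable`` (subviable and lethal are excluded); (2) keep one-to-one
    ortholog pairs only; (3) translate the B set into A's namespace;
    (4) restrict A's non-essential set to genes that appear in one-to-one
    pairs, then intersect.
    """
    nonessential_a = set(nonessential_a)
    viable_b = viability_b.viable_genes()
    b_to_a = ortholog_map.one_to_one()
    comparable_a = set(b_to_a.values())

    b_translated = {b_to_a[b] for b in viable_b if b in b_to_a}
    a_filtered = nonessential_a & comparable_a
    shared = a_filtered & b_translated
    logger.info(
        "concordance: %d A-side, %d B-side comparable genes, %d shared",
        len(a_filtered), len(b_translated), len(shared),
    )
    return ConcordanceResult(
        n_a_filtered=len(a_filtered),
        n_b_filtered=len(b_translated),
        n_shared=len(shared),
        shared=frozenset(shared),
        a_only=frozenset(a_filtered - b_translated),
        b_only=frozenset(b_translated - a_filtered),
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

@dataclass
class HWEResult:
    """Homozygote frequency implied by a heterozygote frequency under
    Hardy-Weinberg equilibrium."""

    het_freq: float
    allele_freq: float
    homozygote_freq: float
    individuals_per_homozygote: float

    def __post_init__(self) -> None:
        q = self.allele_freq
        if abs(2.0 * (1.0 - q) * q - self.het_freq) > 1e-12:
            raise CatalogError("allele frequency inconsistent with heterozygote frequency")


def hwe_individuals_per_homozygote(het_freq: float) -> HWEResult:
    """How many individuals per homozygote, given a heterozygote frequency.

    Solves 2(1-q)q = h for the minor allele frequency q (the smaller root
    of the quadratic, q = (1 - sqrt(1 - 2h)) / 2), then reports q, the
    homozygote frequency q^2, and its reciprocal.  h must lie in (0, 0.5]:
    2pq attains its maximum 0.5 at q = 0.5.

    A heterozygote frequency of 1 per mille yields roughly one homozygote
    in four million individuals.
    """
    if not (0.0 < het_freq <= 0.5):
        raise CatalogError(
            f"heterozygote frequency must be in (0, 0.5], got {het_freq}; "
            "2(1-q)q cannot exceed 0.5"
        )
    q = (1.0 - math.sqrt(1.0 - 2.0 * het_freq)) / 2.0
    return HWEResult(
        het_freq=het_freq,
        allele_freq=q,
        homozygote_freq=q * q,
        individuals_per_homozygote=1.0 / (q * q),
    )
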