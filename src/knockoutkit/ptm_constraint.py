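"""Per-residue missense constraint tracks, ortholog alignment, and
dual-criterion classification of post-translational-modification sites.

A residue is *constrained* when population sequencing shows zero missense
variants at that position; nonsense and synonymous variants never count.
A constrained PTM site is additionally *conserved* when the residue at its
globally aligned position in an ortholog sequence is identical.  Sites are
therefore called one of:

* ``MUTATED`` — at least one missense variant hits the residue;
* ``CONSTRAINED_CONSERVED`` — variant-free and identical in the ortholog;
* ``CONSTRAINED_NOT_CONSERVED`` — variant-free, ortholog residue differs;
* ``CONSTRAINED_UNALIGNED`` — variant-free, aligned to a gap (or no
  ortholog supplied).

Conservation demands residue identity by default, the strictest defensible
reading; ``allow_similar=True`` relaxes it to a positive substitution-matrix
score.  The cumulative allele frequency per residue (the sum of the allele
frequencies of all missense variants mapping to it) is carried along as a
per-residue mutation-rate proxy.  Homozygote counts are reported but play
no role in the constraint call — population missense variants at these
sites are typically monoallelic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .io_catalog import CatalogError, ProteinRecord

logger = logging.getLogger("knockoutkit")

CONSEQUENCES = frozenset({"missense", "synonymous", "nonsense", "other"})

STATUS_MUTATED = "MUTATED"
STATUS_CONSERVED = "CONSTRAINED_CONSERVED"
STATUS_NOT_CONSERVED = "CONSTRAINED_NOT_CONSERVED"
STATUS_UNALIGNED = "CONSTRAINED_UNALIGNED"

_SITE_RE = re.compile(r"^([A-Z])(\d+)$")


# ---------------------------------------------------------------------------
# PTM sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PTMSite:
    """One modified residue: protein, 1-based position, residue letter,
    modification type (phospho, ubiquitin, acetyl, ...)."""

    protein_id: str
    position: int
    residue: str
    mod_type: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise CatalogError(f"PTM position must be >= 1, got {self.position}")
        if len(self.residue) != 1 or not self.residue.isalpha():
            raise CatalogError(f"PTM residue must be one letter, got {self.residue!r}")

    @property
    def label(self) -> str:
        return f"{self.residue}{self.position}"


def parse_site_label(label: str) -> tuple[str, int]:
    """Parse a ``S32``-style site label into (residue, position)."""
    m = _SITE_RE.match(label.strip().upper())
    if not m:
        raise CatalogError(f"cannot parse site label {label!r} (expected e.g. 'S32')")
    return m.group(1), int(m.group(2))


def read_ptm_sites(
    path: str | Path, protein: Optional[ProteinRecord] = None
) -> list[PTMSite]:
    """Read a PTM-site TSV.

    Accepts either a ``site`` column with letter+position labels ("S32") or
    split ``position`` / ``residue`` columns; ``protein_id`` and ``mod_type``
    are expected, ``source`` optional.  When a protein record is supplied,
    each site's residue is validated against the sequence (fatal mismatch).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "protein_id" not in df.columns:
        raise CatalogError(f"{path}: PTM TSV needs a protein_id column")
    sites: list[PTMSite] = []
    for idx, row in df.iterrows():
        if "site" in df.columns and str(row["site"]).strip():
            residue, position = parse_site_label(str(row["site"]))
        elif {"position", "residue"}.issubset(df.columns):
            residue = str(row["residue"]).strip().upper()
            position = int(row["position"])
        else:
            raise CatalogError(
                f"{path}: PTM TSV needs a 'site' column or 'position'/'residue'"
            )
        site = PTMSite(
            protein_id=str(row["protein_id"]).strip(),
            position=position,
            residue=residue,
            mod_type=str(row.get("mod_type", "")).strip(),
            source=str(row.get("source", "")).strip(),
        )
        if protein is not None and site.protein_id == protein.protein_id:
            if protein.residue(site.position) != site.residue:
                raise CatalogError(
                    f"{path}: row {idx}: site {site.label} does not match "
                    f"sequence residue {protein.residue(site.position)!r}"
                )
        sites.append(site)
    return sites


def validate_sites(sites: Iterable[PTMSite], protein: ProteinRecord) -> list[PTMSite]:
    """Check every site against the protein sequence; fatal on mismatch."""
    out = []
    for site in sites:
        if site.protein_id != protein.protein_id:
            raise CatalogError(
                f"site {site.label} belongs to {site.protein_id!r}, "
                f"not {protein.protein_id!r}"
            )
        actual = protein.residue(site.position)
        if actual != site.residue:
            raise CatalogError(
                f"site {site.label}: sequence has {actual!r} at position "
                f"{site.position} of {protein.protein_id}"
            )
        out.append(site)
    return out


# ---------------------------------------------------------------------------
# protein-level variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinVariant:
    """One protein-level variant record with allele counts.

    AF defaults to AC/AN when not given; when given, it must agree with
    AC/AN to 1e-9.  The homozygote count can never exceed floor(AC/2).
    """

    protein_id: str
    position: int
    ref_residue: str
    alt_residue: str
    consequence: str
    allele_count: int
    allele_number: int
    allele_frequency: float = -1.0
    homozygote_count: int = 0

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise CatalogError(
                f"unknown consequence {self.consequence!r}; "
                f"allowed: {sorted(CONSEQUENCES)}"
            )
        if self.allele_count < 0 or self.allele_number <= 0:
            raise CatalogError("need AC >= 0 and AN > 0")
        if self.allele_frequency < 0:
            object.__setattr__(
                self, "allele_frequency", self.allele_count / self.allele_number
            )
        else:
            implied = self.allele_count / self.allele_number
            if abs(self.allele_frequency - implied) > 1e-9:
                raise CatalogError(
                    f"AF {self.allele_frequency} inconsistent with "
                    f"AC/AN = {implied} at {self.protein_id}:{self.position}"
                )
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise CatalogError("AF outside [0, 1]")
        if self.homozygote_count > self.allele_count // 2:
            raise CatalogError(
                f"homozygote count {self.homozygote_count} exceeds AC/2 "
                f"at {self.protein_id}:{self.position}"
            )


def read_variant_tsv(path: str | Path) -> list[ProteinVariant]:
    """Read a protein-level variant TSV (population-database export dialect).

    Columns: ``protein_id``, ``position``, ``ref``, ``alt``, ``consequence``,
    ``AC``, ``AN``, ``nhomalt``; ``AF`` optional (derived from AC/AN when
    absent).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    needed = {"protein_id", "position", "ref", "alt", "consequence", "AC", "AN"}
    if not needed.issubset(df.columns):
        raise CatalogError(f"{path}: variant TSV needs columns {sorted(needed)}")
    out: list[ProteinVariant] = []
    for _, row in df.iterrows():
        af = float(row["AF"]) if "AF" in df.columns and str(row["AF"]).strip() else -1.0
        out.append(
            ProteinVariant(
                protein_id=str(row["protein_id"]).strip(),
                position=int(row["position"]),
                ref_residue=str(row["ref"]).strip().upper(),
                alt_residue=str(row["alt"]).strip().upper(),
                consequence=str(row["consequence"]).strip().lower(),
                allele_count=int(row["AC"]),
                allele_number=int(row["AN"]),
                allele_frequency=af,
                homozygote_count=int(row["nhomalt"]) if str(row.get("nhomalt", "")).strip() else 0,
            )
        )
    return out


def write_variant_tsv(variants: Sequence[ProteinVariant], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": v.protein_id,
                "position": v.position,
                "ref": v.ref_residue,
                "alt": v.alt_residue,
                "consequence": v.consequence,
                "AC": v.allele_count,
                "AN": v.allele_number,
                "AF": v.allele_frequency,
                "nhomalt": v.homozygote_count,
            }
            for v in variants
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# residue constraint track
# ---------------------------------------------------------------------------

@dataclass
class ResidueConstraintTrack:
    """Per-residue missense count, cumulative allele frequency, and an
    any-homozygote flag, over residues 1..len(protein)."""

    protein_id: str
    missense_count: np.ndarray
    cumulative_af: np.ndarray
    any_homozygote: np.ndarray
    n_rejected: int = 0

    def __post_init__(self) -> None:
        n = len(self.missense_count)
        if len(self.cumulative_af) != n or len(self.any_homozygote) != n:
            raise CatalogError("track arrays must share one length")
        if np.any((self.missense_count == 0) & (self.cumulative_af != 0)):
            raise CatalogError("cumulative AF nonzero at a variant-free residue")

    def __len__(self) -> int:
        return len(self.missense_count)

    def is_constrained(self, position: int) -> bool:
        """True when no missense variant maps to the 1-based position."""
        return int(self.missense_count[position - 1]) == 0


def build_residue_track(
    protein: ProteinRecord, variants: Sequence[ProteinVariant]
) -> ResidueConstraintTrack:
    """Aggregate variants into a per-residue constraint track.

    Only missense consequences contribute counts and allele frequency;
    synonymous/nonsense/other records are validated but ignored.  Records
    for other proteins, positions outside the sequence, or with a ref
    residue that disagrees with the sequence are rejected and logged; more
    than 5% rejections triggers a hard warning (the usual cause is a
    variant table annotated on a different isoform).
    """
    n = len(protein)
    counts = np.zeros(n, dtype=int)
    caf = np.zeros(n, dtype=float)
    hom = np.zeros(n, dtype=bool)
    n_rejected = 0
    n_seen = 0
    for v in variants:
        if v.protein_id != protein.protein_id:
            continue
        n_seen += 1
        if not 1 <= v.position <= n:
            logger.info(
                "rejecting variant at %s:%d: outside 1..%d",
                v.protein_id, v.position, n,
            )
            n_rejected += 1
            continue
        if protein.sequence[v.position - 1] != v.ref_residue:
            logger.info(
                "rejecting variant at %s:%d: ref %r does not match sequence %r",
                v.protein_id, v.position, v.ref_residue,
                protein.sequence[v.position - 1],
            )
            n_rejected += 1
            continue
        if v.consequence != "missense":
            continue
        i = v.position - 1
        counts[i] += 1
        caf[i] += v.allele_frequency
        if v.homozygote_count > 0:
            hom[i] = True
    if n_seen and n_rejected / n_seen > 0.05:
        logger.warning(
            "%s: %d/%d variants rejected (>5%%) — wrong isoform for the "
            "variant table?", protein.protein_id, n_rejected, n_seen,
        )
    return ResidueConstraintTrack(
        protein_id=protein.protein_id,
        missense_count=counts,
        cumulative_af=caf,
        any_homozygote=hom,
        n_rejected=n_rejected,
    )


# ---------------------------------------------------------------------------
# global pairwise alignment (Gotoh, affine gaps, fixed tie-breaking)
# ---------------------------------------------------------------------------

@dataclass
class PairwiseAlignment:
    """A global alignment of two sequences with affine gap scoring.

    ``column_map[i-1]`` gives, for each 1-based position i of sequence A,
    the aligned 1-based position in sequence B, or None when A's residue
    sits opposite a gap.
    """

    aligned_a: str
    aligned_b: str
    score: float
    column_map: list[Optional[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise CatalogError("aligned strings differ in length")
        if not self.column_map:
            self.column_map = self._derive_column_map()

    def _derive_column_map(self) -> list[Optional[int]]:
        cmap: list[Optional[int]] = []
        bpos = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if cb != "-":
                bpos += 1
            if ca != "-":
                cmap.append(bpos if cb != "-" else None)
        return cmap

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace("-", "")

    def ortholog_residue(self, position_a: int) -> Optional[str]:
        """Residue of B aligned to a 1-based position of A, or None (gap)."""
        bpos = self.column_map[position_a - 1]
        return None if bpos is None else self.seq_b[bpos - 1]


_M, _X, _Y = 0, 1, 2  # DP states: match/mismatch, gap in B (up), gap in A (left)


def align_orthologs(
    seq_a: str,
    seq_b: str,
    substitution_matrix: str | object = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Needleman–Wunsch global alignment with affine gaps (Gotoh).

    The first residue of a gap scores ``gap_open``, each further residue
    ``gap_extend``.  Terminal gaps are charged like any other (no free end
    gaps).  Ties in the traceback resolve deterministically: diagonal
    (match state) first, then up (gap in B), then left (gap in A), so the
    same pair of sequences always yields the same alignment string.
    """
    if not seq_a or not seq_b:
        raise CatalogError("cannot align an empty sequence")
    if isinstance(substitution_matrix, str):
        matrix = substitution_matrices.load(substitution_matrix)
    else:
        matrix = substitution_matrix

    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    n, m = len(seq_a), len(seq_b)
    NEG = float("-inf")

    score = np.full((3, n + 1, m + 1), NEG)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)  # predecessor state

    score[_M, 0, 0] = 0.0
    for i in range(1, n + 1):
        score[_X, i, 0] = gap_open + (i - 1) * gap_extend
        ptr[_X, i, 0] = _X if i > 1 else _M
    for j in range(1, m + 1):
        score[_Y, 0, j] = gap_open + (j - 1) * gap_extend
        ptr[_Y, 0, j] = _Y if j > 1 else _M

    def best(candidates: list[tuple[float, int]]) -> tuple[float, int]:
        # deterministic: first state in M, X, Y order wins ties
        top, state = candidates[0]
        for s, st in candidates[1:]:
            if s > top:
                top, state = s, st
        return top, state

    for i in range(1, n + 1):
        ca = seq_a[i - 1]
        for j in range(1, m + 1):
            sub = float(matrix[ca, seq_b[j - 1]])
            s, st = best(
                [
                    (score[_M, i - 1, j - 1], _M),
                    (score[_X, i - 1, j - 1], _X),
                    (score[_Y, i - 1, j - 1], _Y),
                ]
            )
            score[_M, i, j] = sub + s
            ptr[_M, i, j] = st
            s, st = best(
                [
                    (score[_M, i - 1, j] + gap_open, _M),
                    (score[_X, i - 1, j] + gap_extend, _X),
                    (score[_Y, i - 1, j] + gap_open, _Y),
                ]
            )
            score[_X, i, j] = s
            ptr[_X, i, j] = st
            s, st = best(
                [
                    (score[_M, i, j - 1] + gap_open, _M),
                    (score[_X, i, j - 1] + gap_open, _X),
                    (score[_Y, i, j - 1] + gap_extend, _Y),
                ]
            )
            score[_Y, i, j] = s
            ptr[_Y, i, j] = st

    final, state = best(
        [(score[_M, n, m], _M), (score[_X, n, m], _X), (score[_Y, n, m], _Y)]
    )

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        prev = int(ptr[state, i, j])
        if state == _M:
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i, j = i - 1, j - 1
        elif state == _X:
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            j -= 1
        state = prev

    return PairwiseAlignment(
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=float(final),
    )


# ---------------------------------------------------------------------------
# site classification
# ---------------------------------------------------------------------------

@dataclass
class SiteCall:
    """One PTM site's constraint/conservation status."""

    site: PTMSite
    status: str
    missense_count: int
    cumulative_af: float
    ortholog_residue: Optional[str] = None  # None encodes "gap"/no ortholog

    def __post_init__(self) -> None:
        if (self.status == STATUS_MUTATED) != (self.missense_count > 0):
            raise CatalogError("MUTATED status must match missense_count > 0")
        if self.status == STATUS_CONSERVED and (
            self.ortholog_residue != self.site.residue
        ):
            raise CatalogError("conserved call with a differing ortholog residue")


def classify_sites(
    sites: Sequence[PTMSite],
    track: ResidueConstraintTrack,
    alignment: Optional[PairwiseAlignment] = None,
    ortholog_seq: Optional[str] = None,
    allow_similar: bool = False,
    substitution_matrix: str | object = "BLOSUM62",
) -> list[SiteCall]:
    """Classify PTM sites by population constraint and ortholog conservation.

    A site with any missense variant is MUTATED regardless of conservation.
    A variant-free site is CONSTRAINED_CONSERVED when the aligned ortholog
    residue is identical (or scores positively when ``allow_similar``),
    CONSTRAINED_NOT_CONSERVED when it differs, CONSTRAINED_UNALIGNED when
    it faces a gap or no alignment was supplied.
    """
    if alignment is not None and ortholog_seq is not None:
        if alignment.seq_b != ortholog_seq.upper():
            raise CatalogError("alignment does not belong to the given ortholog")
    matrix = None
    if allow_similar:
        matrix = (
            substitution_matrices.load(substitution_matrix)
            if isinstance(substitution_matrix, str)
            else substitution_matrix
        )
    calls: list[SiteCall] = []
    for site in sites:
        if not 1 <= site.position <= len(track):
            raise CatalogError(
                f"site {site.label} outside track 1..{len(track)}"
            )
        i = site.position - 1
        count = int(track.missense_count[i])
        caf = float(track.cumulative_af[i])
        ortho = alignment.ortholog_residue(site.position) if alignment else None
        if count > 0:
            status = STATUS_MUTATED
        elif alignment is None or ortho is None:
            status = STATUS_UNALIGNED
        elif ortho == site.residue or (
            allow_similar and float(matrix[site.residue, ortho]) > 0
        ):
            status = STATUS_CONSERVED
            ortho = site.residue if allow_similar else ortho
        else:
            status = STATUS_NOT_CONSERVED
        calls.append(
            SiteCall(
                site=site,
                status=status,
                missense_count=count,
                cumulative_af=caf,
                ortholog_residue=ortho,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# track export
# ---------------------------------------------------------------------------

def export_track(
    protein: ProteinRecord,
    track: ResidueConstraintTrack,
    sites: Sequence[PTMSite] = (),
    calls: Sequence[SiteCall] = (),
    out_path: str | Path = "track.tsv",
    svg_path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Write the per-residue track as TSV (one row per residue), optionally
    with an SVG rendering: allele-frequency bars on top, PTM tick marks
    below, constrained-and-conserved sites in red, domains as colored bands.

    The TSV round-trips: :func:`read_track` reconstructs the numeric track
    bit-exactly.
    """
    if len(track) != len(protein):
        raise CatalogError(
            f"track length {len(track)} != protein length {len(protein)}"
        )
    by_pos_sites: dict[int, list[PTMSite]] = {}
    for s in sites:
        by_pos_sites.setdefault(s.position, []).append(s)
    by_pos_status: dict[int, str] = {}
    for c in calls:
        by_pos_status[c.site.position] = c.status

    def domain_label(pos: int) -> str:
        labels = [lab for start, end, lab in protein.domains if start <= pos <= end]
        return ";".join(labels)

    rows = []
    for pos in range(1, len(protein) + 1):
        here = by_pos_sites.get(pos, [])
        rows.append(
            {
                "position": pos,
                "residue": protein.sequence[pos - 1],
                "missense_count": int(track.missense_count[pos - 1]),
                "cumulative_af": float(track.cumulative_af[pos - 1]),
                "any_homozygote": int(track.any_homozygote[pos - 1]),
                "is_ptm": int(bool(here)),
                "mod_types": ";".join(sorted({s.mod_type for s in here if s.mod_type})),
                "status": by_pos_status.get(pos, ""),
                "domain_label": domain_label(pos),
            }
        )
    df = pd.DataFrame(rows)
    # %.17g preserves every float64 exactly, so re-reading is bit-exact
    df.to_csv(out_path, sep="\t", index=False, float_format="%.17g")
    if svg_path is not None:
        _render_track_svg(protein, track, sites, calls, svg_path)
    return df


def read_track(path: str | Path, protein_id: str = "") -> ResidueConstraintTrack:
    """Reconstruct a ResidueConstraintTrack from an exported TSV."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return ResidueConstraintTrack(
        protein_id=protein_id,
        missense_count=df["missense_count"].to_numpy(dtype=int),
        cumulative_af=df["cumulative_af"].to_numpy(dtype=float),
        any_homozygote=df["any_homozygote"].to_numpy(dtype=bool),
    )


_DOMAIN_COLORS = {"ankyrin": "#4472c4", "pest": "#ffd966"}


def _render_track_svg(protein, track, sites, calls, svg_path) -> None:
    # layout: AF bars above, PTM ticks below, conserved+constrained in red
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(protein)
    fig, ax = plt.subplots(figsize=(max(6.0, n / 40.0), 3.0))
    ax.bar(
        np.arange(1, n + 1),
        track.cumulative_af,
        width=1.0,
        color="#666666",
        label="cumulative AF",
    )
    top = float(track.cumulative_af.max()) or 1.0
    for start, end, label in protein.domains:
        color = _DOMAIN_COLORS.get(label.lower().split()[0], "#cccccc")
        ax.axvspan(start - 0.5, end + 0.5, ymin=0.0, ymax=0.06, color=color)
    conserved = {c.site.position for c in calls if c.status == STATUS_CONSERVED}
    for s in sites:
        color = "red" if s.position in conserved else "black"
        ax.vlines(s.position, -0.22 * top, -0.08 * top, color=color, linewidth=1.2)
    ax.set_xlim(0, n + 1)
    ax.set_ylim(-0.25 * top, 1.05 * top)
    ax.set_xlabel(f"{protein.protein_id} residue")
    ax.set_ylabel("cumulative allele frequency")
    ax.spines[["top", "right"]].set_visible(False)
    fig.tight_layout()
    fig.savefig(svg_path, format="svg")
    plt.close(fig)
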