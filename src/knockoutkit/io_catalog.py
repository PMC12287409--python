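"""Readers, writers and validation for the text formats the pipeline consumes.

Gene identity throughout the package is the canonical gene symbol: an
uppercased, whitespace-stripped string, optionally remapped through a
two-column alias table (``alias`` -> ``canonical``).  No online lookup is
ever performed; the alias table is the only remapping mechanism, which keeps
every downstream count deterministic and auditable.

All residue and domain coordinates are 1-based inclusive, matching the
field's customary "Ser32" / "Lys67" notation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger("knockoutkit")

_STUDY_ID_RE = re.compile(r"^[A-Za-z0-9_-]+$")

#: amino-acid letters accepted in protein sequences (X = unknown)
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: ambiguous / non-standard letters silently mapped to X (with a warning)
AMBIGUOUS_RESIDUES = frozenset("UBZJ")


class CatalogError(ValueError):
    """Fatal problem in an input file (malformed line, unknown id, ...)."""


# ---------------------------------------------------------------------------
# symbol canonicalization
# ---------------------------------------------------------------------------

def normalize_symbol(raw: str, alias_table: Optional[Mapping[str, str]] = None) -> str:
    """Canonicalize one gene symbol: strip, uppercase, then alias-remap.

    Aliases are matched after case-folding, so ``nemo`` and ``NEMO`` hit the
    same alias entry.  Idempotent: applying twice equals applying once.
    Returns the empty string for blank input (callers skip those).
    """
    sym = raw.strip().upper()
    if not sym:
        return ""
    if alias_table:
        sym = alias_table.get(sym, sym)
    return sym


def canonicalize_symbols(
    raw: Iterable[str], alias_table: Optional[Mapping[str, str]] = None
) -> set[str]:
    """Canonicalize an iterable of symbols into a deduplicated set.

    Blank entries are dropped.
    """
    out: set[str] = set()
    for raw_sym in raw:
        sym = normalize_symbol(raw_sym, alias_table)
        if sym:
            out.add(sym)
    return out


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``alias<TAB>canonical`` into a mapping.

    Both columns are uppercased.  A header line ``alias\tcanonical`` is
    recognized and skipped.
    """
    path = Path(path)
    table: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise CatalogError(
                    f"{path}:{lineno}: alias table needs 2 tab-separated columns"
                )
            a, c = parts[0].strip().upper(), parts[1].strip().upper()
            if lineno == 1 and (a, c) == ("ALIAS", "CANONICAL"):
                continue
            if a:
                table[a] = c
    return table


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudySource:
    """One sequencing study contributing a knockout gene list."""

    study_id: str
    label: str = ""
    n_individuals: Optional[int] = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not _STUDY_ID_RE.match(self.study_id):
            raise CatalogError(
                f"study_id {self.study_id!r} must match [A-Za-z0-9_-]+"
            )
        if self.n_individuals is not None and self.n_individuals < 0:
            raise CatalogError("n_individuals must be non-negative")


@dataclass
class GeneSet:
    """A named gene set (GMT line): name, free-text description, members."""

    name: str
    description: str = ""
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ProteinRecord:
    """A protein sequence with optional domain annotation.

    Residues are numbered 1..len(sequence); domains are (start, end, label)
    inclusive 1-based intervals.
    """

    protein_id: str
    symbol: str = ""
    sequence: str = ""
    domains: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise CatalogError(f"protein {self.protein_id!r} has an empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise CatalogError(
                f"protein {self.protein_id!r} contains invalid residues {sorted(bad)}"
            )
        for start, end, label in self.domains:
            if not (1 <= start <= end <= len(self.sequence)):
                raise CatalogError(
                    f"domain {label!r} [{start},{end}] outside 1..{len(self.sequence)}"
                    f" for protein {self.protein_id!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise CatalogError(
                f"position {position} outside 1..{len(self.sequence)} "
                f"for protein {self.protein_id!r}"
            )
        return self.sequence[position - 1]


# ---------------------------------------------------------------------------
# study catalog + study gene lists
# ---------------------------------------------------------------------------

def read_catalog(path: str | Path) -> list[StudySource]:
    """Read a study catalog TSV with columns ``study_id``, ``label``,
    ``n_individuals``, ``notes`` (all but study_id optional)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "study_id" not in df.columns:
        raise CatalogError(f"{path}: catalog needs a 'study_id' column")
    out = []
    for _, row in df.iterrows():
        n_raw = str(row.get("n_individuals", "")).strip()
        out.append(
            StudySource(
                study_id=row["study_id"].strip(),
                label=str(row.get("label", "")),
                n_individuals=int(n_raw) if n_raw else None,
                notes=str(row.get("notes", "")),
            )
        )
    ids = [s.study_id for s in out]
    if len(ids) != len(set(ids)):
        raise CatalogError(f"{path}: duplicate study_id in catalog")
    return out


def read_gene_list(
    path: str | Path, alias_table: Optional[Mapping[str, str]] = None
) -> set[str]:
    """Read one knockout gene list.

    Accepts either a headerless one-symbol-per-line file or a TSV whose
    header names a ``gene`` column.  Symbols are canonicalized; blank lines
    are skipped; duplicates collapse.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        return set()
    header = lines[0].split("\t")
    lowered = [h.strip().lower() for h in header]
    if "gene" in lowered:
        col = lowered.index("gene")
        raw = [
            line.split("\t")[col]
            for line in lines[1:]
            if len(line.split("\t")) > col
        ]
    else:
        raw = [line.split("\t")[0] for line in lines]
    return canonicalize_symbols(raw, alias_table)


def read_study_lists(
    path_per_study: Mapping[str, str | Path],
    alias_table: Optional[Mapping[str, str]] = None,
) -> dict[str, set[str]]:
    """Read one gene list per study and canonicalize every symbol.

    Per-study counts are reported through the package logger (the load log).
    An empty study list is retained as an empty set with a warning; an
    unreadable file is fatal.
    """
    lists: dict[str, set[str]] = {}
    for study_id, path in path_per_study.items():
        try:
            genes = read_gene_list(path, alias_table)
        except OSError as exc:
            raise CatalogError(f"cannot read study list for {study_id!r}: {exc}")
        if not genes:
            logger.warning("study %s: empty gene list", study_id)
        logger.info("study %s: %d genes after canonicalization", study_id, len(genes))
        lists[study_id] = genes
    return lists


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(
    path: str | Path, alias_table: Optional[Mapping[str, str]] = None
) -> list[GeneSet]:
    """Read gene sets from GMT (``name<TAB>description<TAB>member...``).

    Members are canonicalized exactly like study lists; duplicate members
    collapse with a warning.  A line with fewer than three fields is fatal.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CatalogError(
                    f"{path}:{lineno}: GMT line has {len(parts)} fields, needs >= 3"
                )
            name, desc = parts[0], parts[1]
            raw_members = parts[2:]
            members = canonicalize_symbols(raw_members, alias_table)
            if len(members) < len([m for m in raw_members if m.strip()]):
                logger.warning(
                    "%s:%d: gene set %s contains duplicate members", path, lineno, name
                )
            sets.append(GeneSet(name=name, description=desc, members=members))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: str | Path) -> None:
    """Write gene sets to GMT.  Members are sorted so output is deterministic
    and round-trips through :func:`read_gmt` exactly."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# FASTA + domain annotation
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    symbols: Optional[Mapping[str, str]] = None,
    domains: Optional[Mapping[str, list[tuple[int, int, str]]]] = None,
) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    The header token up to the first whitespace is the protein_id.
    Sequences are uppercased; the ambiguous letters U/B/Z/J are mapped to X
    with a warning.  An empty sequence is fatal.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise CatalogError(f"{path}: record {rec.id!r} has an empty sequence")
        ambiguous = set(seq) & AMBIGUOUS_RESIDUES
        if ambiguous:
            logger.warning(
                "%s: record %s: mapping ambiguous residues %s to X",
                path, rec.id, sorted(ambiguous),
            )
            for ch in ambiguous:
                seq = seq.replace(ch, "X")
        records.append(
            ProteinRecord(
                protein_id=rec.id,
                symbol=(symbols or {}).get(rec.id, ""),
                sequence=seq,
                domains=list((domains or {}).get(rec.id, [])),
            )
        )
    if not records:
        raise CatalogError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_domains(path: str | Path) -> dict[str, list[tuple[int, int, str]]]:
    """Read a domain annotation TSV: ``protein_id``, ``start``, ``end``,
    ``label`` (1-based inclusive)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "label": str})
    needed = {"protein_id", "start", "end", "label"}
    if not needed.issubset(df.columns):
        raise CatalogError(f"{path}: domain TSV needs columns {sorted(needed)}")
    out: dict[str, list[tuple[int, int, str]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["protein_id"]), []).append(
            (int(row["start"]), int(row["end"]), str(row["label"]))
        )
    return out
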