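"""Readers and writers for the plain-text formats the pipeline touches.

Sequences come in as FASTA (miRNAs and transcripts in separate files), known
miRNA-target associations as a two-column TSV of identifiers, predicted
association scores go out as a ranked three-column TSV and evaluation metrics
as a flat JSON document.

All sequences are normalised to an RNA alphabet: DNA input is accepted and
transcribed (T -> U), case is folded to upper. Characters outside
{A, C, G, U, T, N} are hard errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SequenceRecord",
    "AssociationList",
    "FastaParseError",
    "ValidationError",
    "normalize_sequence",
    "read_fasta",
    "write_fasta",
    "read_associations",
    "write_associations",
    "write_scores",
    "read_scores",
    "write_metrics_json",
]

_ALLOWED_RAW = set("ACGUTN")
_NORMALIZED = set("ACGUN")


class FastaParseError(ValueError):
    """Malformed FASTA syntax; the message names the offending line."""


class ValidationError(ValueError):
    """Input that parses but violates a contract (duplicate ids, bad alphabet, ...)."""


def normalize_sequence(raw: str) -> str:
    """Upper-case and transcribe a nucleotide string to the RNA alphabet.

    Idempotent: normalising an already-normalised sequence is the identity.
    Raises :class:`ValidationError` on any character outside {A,C,G,U,T,N}
    (either case).
    """
    up = raw.upper()
    bad = set(up) - _ALLOWED_RAW
    if bad:
        raise ValidationError(
            f"illegal sequence character(s) {sorted(bad)!r}; allowed: A,C,G,U,T,N"
        )
    return up.replace("T", "U")


@dataclass(frozen=True)
class SequenceRecord:
    """A single named sequence with its role in the bipartite problem.

    Parameters
    ----------
    id : str
        Unique (within its role) non-empty identifier.
    sequence : str
        Normalised RNA sequence over {A,C,G,U,N}.
    role : str
        Either ``"miRNA"`` or ``"target"``.
    """

    id: str
    sequence: str
    role: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("empty sequence id")
        if self.role not in ("miRNA", "target"):
            raise ValidationError(f"unknown role {self.role!r}")
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _NORMALIZED
        if bad:
            raise ValidationError(
                f"record {self.id!r}: non-normalised character(s) {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_ambiguous(self) -> bool:
        """True if the sequence contains N (flagged, still usable)."""
        return "N" in self.sequence


@dataclass
class AssociationList:
    """Deduplicated set of known (miRNA_id, target_id) pairs.

    ``pairs`` preserves first-seen order for reproducibility; membership is
    checked against the set view.
    """

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        deduped = []
        for p in self.pairs:
            if p not in seen:
                seen.add(p)
                deduped.append(tuple(p))
        self.pairs = deduped

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pair_set

    @property
    def pair_set(self) -> frozenset:
        return frozenset(self.pairs)


def read_fasta(path: str | Path, role: str) -> list[SequenceRecord]:
    """Parse a (possibly line-wrapped) multi-record FASTA file.

    Sequences are normalised (T->U, upper case); records are returned in file
    order. Duplicate ids and empty sequences are rejected.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    ids_seen: set[str] = set()
    cur_id: str | None = None
    cur_parts: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal cur_id, cur_parts
        if cur_id is None:
            return
        seq = "".join(cur_parts)
        if not seq:
            raise ValidationError(f"{path}: record {cur_id!r} has an empty sequence")
        try:
            norm = normalize_sequence(seq)
        except ValidationError as e:
            raise ValidationError(f"{path}: record {cur_id!r}: {e}") from None
        records.append(SequenceRecord(id=cur_id, sequence=norm, role=role))
        cur_id, cur_parts = None, []

    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaParseError(f"{path}:{line_no}: empty FASTA header")
                if header in ids_seen:
                    raise ValidationError(
                        f"{path}:{line_no}: duplicate sequence id {header!r}"
                    )
                ids_seen.add(header)
                cur_id = header
            else:
                if cur_id is None:
                    raise FastaParseError(
                        f"{path}:{line_no}: sequence data before first '>' header"
                    )
                cur_parts.append(line)
    flush(-1)
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_associations(
    path: str | Path,
    mirnas: Sequence[SequenceRecord],
    targets: Sequence[SequenceRecord],
    header: bool = False,
) -> AssociationList:
    """Read a two-column (miRNA_id <tab> target_id) TSV of known associations.

    Rows are deduplicated. Every id must resolve to a loaded record; unknown
    ids raise :class:`ValidationError` naming all offenders. ``header=True``
    skips the first line.
    """
    path = Path(path)
    mirna_ids = {r.id for r in mirnas}
    target_ids = {r.id for r in targets}
    pairs: list[tuple[str, str]] = []
    unknown: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    if header:
        lines = lines[1:]
    n_rows = 0
    for line_no, line in enumerate(lines, start=2 if header else 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise ValidationError(
                f"{path}:{line_no}: expected >=2 tab-separated columns, got {len(cols)}"
            )
        m, t = cols[0].strip(), cols[1].strip()
        n_rows += 1
        if m not in mirna_ids:
            unknown.append(f"miRNA {m!r} (line {line_no})")
            continue
        if t not in target_ids:
            unknown.append(f"target {t!r} (line {line_no})")
            continue
        pairs.append((m, t))
    if unknown:
        raise ValidationError(f"{path}: unresolvable id(s): " + "; ".join(unknown))
    if n_rows == 0:
        raise ValidationError(f"{path}: association file contains no pairs")
    return AssociationList(pairs=pairs)


def write_associations(assoc: AssociationList, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for m, t in assoc:
            fh.write(f"{m}\t{t}\n")


def write_scores(
    scores: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    """Write ranked association scores as a three-column TSV.

    Rows are sorted by probability descending; ties break lexicographically on
    (miRNA_id, target_id) so output is deterministic. Probabilities outside
    [0, 1] are rejected.
    """
    rows = list(scores)
    for m, t, p in rows:
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"score for ({m}, {t}) is {p}, outside [0, 1]")
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    path = Path(path)
    with open(path, "w") as fh:
        for m, t, p in rows:
            fh.write(f"{m}\t{t}\t{p:.6f}\n")


def read_scores(path: str | Path) -> list[tuple[str, str, float]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            m, t, p = line.rstrip("\n").split("\t")
            rows.append((m, t, float(p)))
    return rows


def write_metrics_json(metrics: dict, path: str | Path) -> None:
    """Serialise a metrics report (per-fold + aggregate) as flat JSON."""
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")
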