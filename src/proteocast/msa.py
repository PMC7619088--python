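"""Reading, normalising and summarising multiple sequence alignments.

Three input dialects are accepted, all FASTA-shaped:

* **A3M** — lowercase letters are insertions relative to the query and are
  removed; rows need not share a length before normalisation.
* **A2M** — like A3M, but insert-state gaps are written as ``.``; lowercase
  letters and dots are removed.
* **aligned FASTA** — uppercase letters and gap characters only; all rows
  must already share one length.

After normalisation every row has exactly the query length and gaps are
``-``. The first record is the query and must be ungapped — that convention
is enforced, not repaired. All user-facing positions are 1-based; internal
arrays are 0-based.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import AA_SET
from .errors import (
    EmptyMsaError,
    GappedQueryError,
    RaggedAlignmentError,
    UnknownDialectError,
)

_DIALECTS = ("a2m", "a3m", "fasta", "auto")


@dataclass(frozen=True)
class Msa:
    """A normalised alignment: equal-length rows, ungapped query first."""

    query_id: str
    query_seq: str
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.query_seq)

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def __post_init__(self) -> None:
        if self.rows and self.rows[0] != self.query_seq:
            raise RaggedAlignmentError("first row must equal the query sequence")


@dataclass(frozen=True)
class ColumnStats:
    """Per-column summary used for residue-level confidence flags.

    ``n_substitutions_sampled`` counts the distinct non-gap, non-wild-type
    amino acids observed in the column (at most 19). ``conservation`` is the
    modal non-gap amino-acid frequency, a tree-free conservation proxy.
    """

    position: int  # 1-based
    gap_fraction: float
    n_substitutions_sampled: int
    conservation: float


@dataclass(frozen=True)
class SequenceSimilarity:
    row_index: int
    identity_to_query: float


def _normalise_record(seq: str, dialect: str) -> str:
    if dialect in ("a3m", "a2m"):
        # lowercase = insertion relative to the query; '.' = gap in an
        # insert column (A2M). Both are columns the query does not own.
        seq = "".join(c for c in seq if not (c.islower() or c == "."))
    else:  # aligned fasta
        if any(c.islower() for c in seq):
            raise UnknownDialectError(
                "lowercase letters are not valid in aligned FASTA; "
                "use dialect='a3m' or 'a2m' for insertion-annotated alignments"
            )
        seq = seq.replace(".", "-")
    for c in seq:
        if c != "-" and not c.isalpha():
            raise UnknownDialectError(f"invalid alignment character {c!r}")
    return seq


def _sniff_dialect(raw_seqs: list[str]) -> str:
    for s in raw_seqs:
        if any(c.islower() for c in s):
            return "a2m" if "." in s else "a3m"
    if any("." in s for s in raw_seqs):
        return "a2m"
    return "fasta"


def read_msa(path: str | Path, dialect: str = "auto") -> Msa:
    """Parse an alignment file into a normalised :class:`Msa`.

    Raises a named error for each failure mode: empty file, gapped query,
    ragged rows after normalisation, unknown dialect/characters.
    """
    if dialect not in _DIALECTS:
        raise UnknownDialectError(
            f"unknown dialect {dialect!r}; expected one of {_DIALECTS}"
        )
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyMsaError(f"no sequence records in {path}")
    raw = [str(r.seq) for r in records]
    if dialect == "auto":
        dialect = _sniff_dialect(raw)
    rows = [_normalise_record(s, dialect) for s in raw]
    query = rows[0].upper()
    if "-" in query:
        raise GappedQueryError(
            "first record (the query) contains gaps after normalisation"
        )
    L = len(query)
    if L == 0:
        raise EmptyMsaError("query sequence is empty")
    bad = {c for c in query if c not in AA_SET and c != "X"}
    if bad:
        raise UnknownDialectError(
            f"query contains non-amino-acid letters: {sorted(bad)}"
        )
    norm = []
    for i, row in enumerate(rows):
        row = row.upper()
        if len(row) != L:
            raise RaggedAlignmentError(
                f"row {i} ({records[i].id}) has length {len(row)} after "
                f"normalisation, expected {L}"
            )
        norm.append(row)
    return Msa(
        query_id=records[0].id,
        query_seq=query,
        ids=tuple(r.id for r in records),
        rows=tuple(norm),
    )


def write_msa(msa: Msa, path: str | Path) -> None:
    """Write the normalised alignment as aligned FASTA."""
    with open(path, "w") as fh:
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")


def _is_gap_like(c: str) -> bool:
    return c not in AA_SET  # '-', '.', 'X', B/Z/U/O/J ... all gap-like


def column_stats(msa: Msa) -> list[ColumnStats]:
    """One :class:`ColumnStats` per query position.

    Conservation is computed over non-gap standard letters only; an empty
    (all-gap) column yields gap_fraction 1 and conservation 0.
    """
    out = []
    n = msa.n_sequences
    for j in range(msa.length):
        wt = msa.query_seq[j]
        counts: Counter[str] = Counter()
        n_gap = 0
        for row in msa.rows:
            c = row[j]
            if _is_gap_like(c):
                n_gap += 1
            else:
                counts[c] += 1
        n_aa = n - n_gap
        conservation = max(counts.values()) / n_aa if n_aa else 0.0
        n_subs = sum(1 for aa in counts if aa != wt)
        out.append(
            ColumnStats(
                position=j + 1,
                gap_fraction=n_gap / n,
                n_substitutions_sampled=n_subs,
                conservation=conservation,
            )
        )
    return out


def column_stats_frame(msa: Msa) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in column_stats(msa)])


def similarity_to_query(msa: Msa) -> list[SequenceSimilarity]:
    """Identity of each row to the query over the query's positions.

    The query is ungapped, so the denominator is the full query length
    (query-coverage identity); an all-gap row scores 0.
    """
    q = np.frombuffer(msa.query_seq.encode(), dtype="S1")
    out = []
    for i, row in enumerate(msa.rows):
        r = np.frombuffer(row.encode(), dtype="S1")
        out.append(
            SequenceSimilarity(
                row_index=i,
                identity_to_query=float((q == r).sum()) / msa.length,
            )
        )
    return out
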