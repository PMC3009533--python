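"""Sequence I/O, redundancy reduction and PU dataset assembly.

FASTA reading/writing is delegated to Biopython; this module adds the
validation contracts (duplicate ids, alphabet checks) and the greedy
identity-based redundancy reducer used as a desk-scale stand-in for
CD-HIT-style clustering.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: ambiguity codes tolerated on ingest; excluded from feature counts downstream
AMBIGUOUS_AA = "BZXUO"
ALLOWED_AA = frozenset(STANDARD_AA + AMBIGUOUS_AA)


@dataclass(frozen=True)
class SequenceRecord:
    """An identifier plus an amino-acid string; the atomic input unit."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id {self.id!r}: empty or contains whitespace")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PUDataset:
    """A positive set P and an unlabeled set U, optionally with synthetic truth.

    ``truth`` maps every id in U to ``"positive"`` or ``"negative"``; it exists
    only for synthetic benchmarks where the hidden labels are known.
    """

    P: list[SequenceRecord]
    U: list[SequenceRecord]
    truth: dict[str, str] | None = None

    def __post_init__(self) -> None:
        p_ids = {r.id for r in self.P}
        u_ids = {r.id for r in self.U}
        if len(p_ids) != len(self.P) or len(u_ids) != len(self.U):
            raise ValueError("duplicate ids within P or U")
        overlap = p_ids & u_ids
        if overlap:
            raise ValueError(f"P and U share ids: {sorted(overlap)[:5]}")
        if self.truth is not None:
            missing = u_ids - set(self.truth)
            if missing:
                raise ValueError(f"truth map missing ids: {sorted(missing)[:5]}")
            bad = set(self.truth.values()) - {"positive", "negative"}
            if bad:
                raise ValueError(f"truth labels must be positive/negative, got {bad}")


def _validate_seq(rec_id: str, raw: str) -> str:
    seq = "".join(raw.split()).upper()
    if not seq:
        raise ValueError(f"record {rec_id!r}: no sequences")
    for pos, ch in enumerate(seq):
        if ch not in ALLOWED_AA:
            raise ValueError(
                f"record {rec_id!r}: illegal character {ch!r} at position {pos + 1}"
            )
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Multi-line sequences are concatenated and upper-cased; the id is the
    header token before the first space. Raises ``ValueError`` on an empty
    file, duplicate ids, or characters outside the tolerated alphabet.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate id {entry.id}")
        seen.add(entry.id)
        records.append(SequenceRecord(entry.id, _validate_seq(entry.id, str(entry.seq))))
    if not records:
        raise ValueError(f"{path}: no sequences")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned positions under global alignment.

    Scoring: match=1, mismatch=0, gap=-1 (end gaps included). The identity
    denominator is the length of the shorter sequence, matching the usual
    clustering convention.
    """
    if a == b:
        return 1.0
    aligner = _make_aligner()
    alignment = aligner.align(a, b)[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))


def greedy_identity_reduce(
    records: Sequence[SequenceRecord], max_identity: float
) -> list[SequenceRecord]:
    """Greedy longest-first redundancy reduction.

    Sorts by descending length (ties broken by lexicographic id) and keeps a
    record iff its pairwise identity to every already-kept record is at most
    ``max_identity``.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if not (0 < max_identity <= 1):
        raise ValueError(f"max_identity must be in (0, 1], got {max_identity}")
    ordered = sorted(records, key=lambda r: (-len(r.seq), r.id))
    kept: list[SequenceRecord] = []
    for rec in ordered:
        if all(pairwise_identity(rec.seq, k.seq) <= max_identity for k in kept):
            kept.append(rec)
    return kept


def holdout_split(
    P: Sequence[SequenceRecord], n_holdout: int, seed: int
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split positives into (train, holdout) uniformly at random, seeded.

    Original input order is preserved within each part.
    """
    if not (0 < n_holdout < len(P)):
        raise ValueError(
            f"n_holdout must be in (0, {len(P)}), got {n_holdout} for |P|={len(P)}"
        )
    rng = np.random.default_rng(seed)
    holdout_idx = set(rng.choice(len(P), size=n_holdout, replace=False).tolist())
    train = [r for i, r in enumerate(P) if i not in holdout_idx]
    holdout = [r for i, r in enumerate(P) if i in holdout_idx]
    return train, holdout


def write_manifest(
    path: str | Path,
    memberships: dict[str, str],
) -> None:
    """Write a TSV manifest mapping id -> set membership (P/U/holdout/RN/Q)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "set"])
        for rec_id, membership in memberships.items():
            writer.writerow([rec_id, membership])
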