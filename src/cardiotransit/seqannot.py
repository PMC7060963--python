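"""Sequence utilities: exon-skip consequence prediction and windowed
percent identity between protein sequences.

The transcript model carries coding lengths per exon only, so frame
consequences are genome-build independent: skipping exons removes their
combined coding length, and the deletion is in frame iff that length is a
multiple of three.  The aligner is a global (Needleman-Wunsch) dynamic
program with configurable scoring and a deterministic traceback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "TranscriptModel",
    "SkipEffect",
    "AlignmentWindow",
    "Alignment",
    "predict_exon_skip_effect",
    "global_align",
    "signature_identity",
    "read_fasta",
    "load_transcript_model",
    "crispld1_transcript",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered exons with coding lengths in nucleotides."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]  # (exon_number, coding_length_nt)
    cds_frame_offset: int = 0

    def __post_init__(self) -> None:
        numbers = [n for n, _ in self.exons]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError("exon numbers must be strictly increasing")
        if any(length < 0 for _, length in self.exons):
            raise ValueError("coding lengths must be >= 0")
        if self.cds_frame_offset not in (0, 1, 2):
            raise ValueError("cds_frame_offset must be 0, 1 or 2")

    def coding_length(self, exon_number: int) -> int:
        for n, length in self.exons:
            if n == exon_number:
                return length
        raise KeyError(f"exon {exon_number} not in transcript {self.transcript_id!r}")


@dataclass(frozen=True)
class SkipEffect:
    """Consequence of skipping exons on the coding sequence."""

    nt_removed: int
    in_frame: bool
    aa_removed: int | None  # defined iff in frame
    frameshift_position: int | None  # 1-based codon index, iff frameshifted

    def __post_init__(self) -> None:
        if self.in_frame != (self.nt_removed % 3 == 0):
            raise ValueError("in_frame must equal (nt_removed % 3 == 0)")
        if self.in_frame and self.aa_removed != self.nt_removed // 3:
            raise ValueError("aa_removed must be nt_removed / 3 when in frame")


def predict_exon_skip_effect(
    model: TranscriptModel, skipped_exon_numbers: Iterable[int]
) -> SkipEffect:
    """Frame and protein consequence of skipping the given exons.

    An in-frame skip removes nt/3 amino acids; otherwise the frameshift
    begins at the codon following the last intact upstream codon.
    """
    skipped = sorted(set(skipped_exon_numbers))
    nt_removed = sum(model.coding_length(n) for n in skipped)
    in_frame = nt_removed % 3 == 0
    if in_frame:
        return SkipEffect(nt_removed, True, nt_removed // 3, None)
    first_skipped = skipped[0]
    preceding_nt = model.cds_frame_offset + sum(
        length for n, length in model.exons if n < first_skipped
    )
    frameshift_codon = preceding_nt // 3 + 1
    return SkipEffect(nt_removed, False, None, frameshift_codon)


# ---------------------------------------------------------------------------
# Global alignment

@dataclass(frozen=True)
class Alignment:
    """A gapped global alignment of two protein sequences."""

    query: str  # with '-' gaps
    subject: str
    score: float

    def __post_init__(self) -> None:
        if len(self.query) != len(self.subject):
            raise ValueError("aligned strings must have equal length")


def _validate_protein(seq: str, name: str) -> str:
    seq = seq.upper()
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"illegal characters in {name}: {sorted(bad)}")
    return seq


def global_align(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
    substitution: dict[tuple[str, str], float] | None = None,
) -> Alignment:
    """Needleman-Wunsch global alignment with linear gap penalty.

    Pair scores come from ``substitution`` when given (e.g. a BLOSUM
    matrix), else match/mismatch.  Traceback ties prefer diagonal, then up
    (gap in B), then left (gap in A), making the alignment deterministic.
    """
    a = _validate_protein(seq_a, "seq_a")
    b = _validate_protein(seq_b, "seq_b")
    la, lb = len(a), len(b)

    def pair(x: str, y: str) -> float:
        if substitution is not None:
            return substitution.get((x, y), substitution.get((y, x)))
        return match if x == y else mismatch

    score = np.zeros((la + 1, lb + 1))
    score[:, 0] = gap * np.arange(la + 1)
    score[0, :] = gap * np.arange(lb + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            score[i, j] = max(
                score[i - 1, j - 1] + pair(a[i - 1], b[j - 1]),
                score[i - 1, j] + gap,
                score[i, j - 1] + gap,
            )

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and score[i, j] == score[i - 1, j - 1] + pair(a[i - 1], b[j - 1])
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return Alignment(
        query="".join(reversed(out_a)),
        subject="".join(reversed(out_b)),
        score=float(score[la, lb]),
    )


@dataclass(frozen=True)
class AlignmentWindow:
    """1-based inclusive residue window on the query sequence."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError("window must satisfy 1 <= start <= end")


def signature_identity(alignment: Alignment, window: AlignmentWindow) -> int:
    """Percent identity over alignment columns whose query residue lies in
    the window, rounded to the nearest integer."""
    query_pos = 0
    matches = 0
    columns = 0
    max_query = sum(1 for c in alignment.query if c != "-")
    if window.end > max_query:
        raise ValueError(
            f"window end {window.end} beyond query length {max_query}"
        )
    for qc, sc in zip(alignment.query, alignment.subject):
        if qc == "-":
            continue
        query_pos += 1
        if window.start <= query_pos <= window.end:
            columns += 1
            if qc == sc:
                matches += 1
    return int(round(100.0 * matches / columns))


# ---------------------------------------------------------------------------
# I/O and packaged fixture

def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_transcript_model(path: str | Path) -> TranscriptModel:
    data = json.loads(Path(path).read_text())
    return TranscriptModel(
        transcript_id=data["transcript_id"],
        exons=tuple((int(n), int(l)) for n, l in data["exons"]),
        cds_frame_offset=int(data.get("cds_frame_offset", 0)),
    )


def crispld1_transcript() -> TranscriptModel:
    """Packaged CRISPLD1-like transcript model.

    Exons 6-8 jointly carry 303 coding nucleotides (the skipped block whose
    loss is in frame, removing 101 amino acids); the per-exon split and the
    flanking exon lengths are synthetic placeholders.
    """
    ref = resources.files("cardiotransit.data").joinpath(
        "crispld1_transcript_synthetic.json"
    )
    data = json.loads(ref.read_text())
    return TranscriptModel(
        transcript_id=data["transcript_id"],
        exons=tuple((int(n), int(l)) for n, l in data["exons"]),
        cds_frame_offset=int(data.get("cds_frame_offset", 0)),
    )
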