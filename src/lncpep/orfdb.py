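"""Putative microprotein database construction from lncRNA transcripts.

Long noncoding RNAs carry no annotated protein-coding ORF, yet many harbour
small ORFs (smORFs) whose translated products ("microproteins") are detectable
by shotgun MS. Because these products are absent from reference proteomes, a
custom search database must be built directly from the transcript sequences.

Two complementary scans are combined, mirroring the ORFfinder + six-frame
strategy used for proteogenomic smORF discovery:

* AUG-initiated ORFs: every in-frame ATG (optionally restricted to a relaxed
  Kozak context) extended to the first in-frame stop codon.
* Stop-to-stop intervals: maximal codon runs bounded by stop codons in each of
  the six reading frames, capturing products whose true initiator is unknown
  or non-AUG.

Each candidate is classified by its first codon as ``AUG``, ``NEAR_COGNATE``
(one of the nine single-mismatch variants of ATG) or ``UNKNOWN``. For known
starts the product length is the predicted smORF length; for unknown starts it
is the stop-to-stop interval length — both reduce to ``len(aa_seq)`` of the
emitted record.

Coordinates are 0-based half-open on the strand-oriented sequence: plus-strand
coordinates index the transcript itself, minus-strand coordinates index its
reverse complement. A minus-strand interval ``[s, e)`` maps back to transcript
positions ``[L - e, L - s)`` for a transcript of length ``L``. When an ORF is
closed by a stop codon, the stop codon is included in the nucleotide interval
but never in ``aa_seq``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .errors import InputError, ParameterError

__all__ = [
    "StartClass",
    "Transcript",
    "SmOrf",
    "MicroproteinRecord",
    "NEAR_COGNATE_CODONS",
    "normalize_transcript",
    "reverse_complement",
    "translate_frame",
    "six_frame_translate",
    "classify_start",
    "find_aug_smorfs",
    "find_stop_to_stop_orfs",
    "build_database",
]

_STANDARD_TABLE = unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

#: The nine codons differing from ATG at exactly one position; all have been
#: observed to initiate translation in vivo.
NEAR_COGNATE_CODONS = frozenset(
    {"CTG", "GTG", "TTG", "ATA", "ATT", "ATC", "ACG", "AAG", "AGG"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID_ALPHABET = frozenset("ACGTN")


class StartClass(str, Enum):
    """Initiator-codon class of a candidate microprotein."""

    AUG = "AUG"
    NEAR_COGNATE = "NEAR_COGNATE"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class Transcript:
    """A normalized lncRNA transcript (DNA alphabet, uppercase)."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"transcript {self.accession!r}: empty sequence")
        bad = set(self.sequence) - _VALID_ALPHABET
        if bad:
            raise InputError(
                f"transcript {self.accession!r}: illegal characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class SmOrf:
    """A candidate small ORF on a strand-oriented transcript.

    ``nt_start``/``nt_end`` are 0-based half-open on the oriented sequence
    (the reverse complement for strand ``-``). A closing stop codon, when
    present, is inside the interval; ``aa_seq`` never contains ``*``.
    """

    transcript_accession: str
    strand: str
    frame: int
    nt_start: int
    nt_end: int
    start_class: StartClass
    nt_seq: str
    aa_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError(f"invalid strand {self.strand!r}")
        if not 0 <= self.frame <= 2:
            raise InputError(f"invalid frame {self.frame}")
        span = self.nt_end - self.nt_start
        if span <= 0 or span % 3:
            raise InputError(f"ORF span {span} not a positive multiple of 3")
        if "*" in self.aa_seq:
            raise InputError("aa_seq contains an internal stop")
        n_codons = span // 3
        if len(self.aa_seq) not in (n_codons, n_codons - 1):
            raise InputError(
                f"aa_seq length {len(self.aa_seq)} inconsistent with span {span}"
            )
        if self.start_class is StartClass.AUG and not self.nt_seq.startswith("ATG"):
            raise InputError("AUG-class ORF does not begin with ATG")

    @property
    def has_trailing_stop(self) -> bool:
        return len(self.aa_seq) == (self.nt_end - self.nt_start) // 3 - 1


@dataclass(frozen=True)
class MicroproteinRecord:
    """A database entry: one translated product with its genomic provenance.

    ``length`` always equals ``len(aa_seq)``; for AUG/near-cognate starts this
    is the predicted smORF length, for unknown starts the stop-to-stop
    interval length.
    """

    id: str
    aa_seq: str
    length: int
    start_class: StartClass
    provenance: tuple[tuple[str, str, int, int, int], ...]

    def __post_init__(self) -> None:
        if self.length != len(self.aa_seq):
            raise InputError(
                f"record {self.id}: length {self.length} != len(aa_seq) "
                f"{len(self.aa_seq)}"
            )
        if not self.aa_seq:
            raise InputError(f"record {self.id}: empty product")


def normalize_transcript(
    accession: str, raw_sequence: str, description: str = ""
) -> Transcript:
    """Normalize raw sequence text into a :class:`Transcript`.

    Whitespace is removed, the sequence uppercased and RNA ``U`` mapped to
    ``T``. Characters outside ``{A, C, G, T, N}`` raise :class:`InputError`
    naming the offending 1-based position.
    """
    seq = "".join(raw_sequence.split()).upper().replace("U", "T")
    if not seq:
        raise InputError(f"transcript {accession!r}: empty sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _VALID_ALPHABET:
            raise InputError(
                f"transcript {accession!r}: illegal character {ch!r} at "
                f"position {pos}"
            )
    return Transcript(accession=accession, sequence=seq, description=description)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate_codon(codon: str) -> str:
    """Standard-table translation; codons containing N give 'X'."""
    return _CODON_TO_AA.get(codon, "X")


def translate_frame(seq: str, frame: int) -> str:
    """Translate one reading frame of an oriented sequence ('*' = stop)."""
    return "".join(
        _translate_codon(seq[i : i + 3]) for i in range(frame, len(seq) - 2, 3)
    )


def oriented_sequence(t: Transcript, strand: str) -> str:
    return t.sequence if strand == "+" else reverse_complement(t.sequence)


def six_frame_translate(t: Transcript) -> list[tuple[str, int, str]]:
    """All six frame translations as ``(strand, frame, aa_string)`` tuples.

    Reverse frames are computed on the reverse complement, so frame ``f`` on
    strand ``-`` starts at position ``f`` of the reverse-complemented
    transcript.
    """
    out = []
    for strand in "+-":
        seq = oriented_sequence(t, strand)
        for frame in range(3):
            out.append((strand, frame, translate_frame(seq, frame)))
    return out


def classify_start(nt_seq: str) -> StartClass:
    """Classify an ORF by its first codon."""
    first = nt_seq[:3]
    if first == "ATG":
        return StartClass.AUG
    if first in NEAR_COGNATE_CODONS:
        return StartClass.NEAR_COGNATE
    return StartClass.UNKNOWN


def _kozak_ok(seq: str, atg_pos: int) -> bool:
    # Relaxed Kozak (gccRccATGG): purine at -3 or G at +4.
    if atg_pos >= 3 and seq[atg_pos - 3] in "AG":
        return True
    return atg_pos + 3 < len(seq) and seq[atg_pos + 3] == "G"


def find_aug_smorfs(
    t: Transcript,
    min_aa: int = 7,
    require_kozak: bool = False,
    allow_open_ended: bool = False,
) -> list[SmOrf]:
    """All ATG-initiated ORFs of at least ``min_aa`` residues.

    Every ATG in every frame on both strands is extended codon by codon to
    the first in-frame stop. ORFs truncated by the transcript end or by an
    ambiguous (N-containing) codon lack a bounding stop and are kept only
    when ``allow_open_ended`` is set.
    """
    if min_aa < 1:
        raise ParameterError(f"min_aa must be >= 1, got {min_aa}")
    orfs: list[SmOrf] = []
    for strand in "+-":
        seq = oriented_sequence(t, strand)
        for pos in range(len(seq) - 2):
            if seq[pos : pos + 3] != "ATG":
                continue
            if require_kozak and not _kozak_ok(seq, pos):
                continue
            aa = ["M"]
            end = pos + 3
            closed = False
            q = pos + 3
            while q + 3 <= len(seq):
                residue = _translate_codon(seq[q : q + 3])
                if residue == "*":
                    closed = True
                    end = q + 3
                    break
                if residue == "X":
                    # ambiguous codon terminates extension without a stop
                    break
                aa.append(residue)
                end = q + 3
                q += 3
            if not closed and not allow_open_ended:
                continue
            if len(aa) < min_aa:
                continue
            orfs.append(
                SmOrf(
                    transcript_accession=t.accession,
                    strand=strand,
                    frame=pos % 3,
                    nt_start=pos,
                    nt_end=end,
                    start_class=StartClass.AUG,
                    nt_seq=seq[pos:end],
                    aa_seq="".join(aa),
                )
            )
    return orfs


def find_stop_to_stop_orfs(
    t: Transcript,
    min_aa: int = 7,
    require_bounding_stops: bool = True,
) -> list[SmOrf]:
    """Maximal stop-bounded codon runs in all six frames.

    Each run between two in-frame stop codons (exclusive of the opening stop,
    inclusive of the closing one in the nucleotide interval) is emitted with
    its start class resolved from the first codon. Runs truncated by the
    transcript end or by an ambiguous codon are kept only when
    ``require_bounding_stops`` is off.
    """
    if min_aa < 1:
        raise ParameterError(f"min_aa must be >= 1, got {min_aa}")
    orfs: list[SmOrf] = []
    for strand in "+-":
        seq = oriented_sequence(t, strand)
        for frame in range(3):
            run_start: int | None = None
            left_bounded = False
            run_aa: list[str] = []

            def emit(end: int, right_bounded: bool, *, _s=strand, _f=frame) -> None:
                if run_start is None or not run_aa:
                    return
                if require_bounding_stops and not (left_bounded and right_bounded):
                    return
                if len(run_aa) < min_aa:
                    return
                nt_seq = seq[run_start:end]
                orfs.append(
                    SmOrf(
                        transcript_accession=t.accession,
                        strand=_s,
                        frame=_f,
                        nt_start=run_start,
                        nt_end=end,
                        start_class=classify_start(nt_seq),
                        nt_seq=nt_seq,
                        aa_seq="".join(run_aa),
                    )
                )

            pos = frame
            while pos + 3 <= len(seq):
                residue = _translate_codon(seq[pos : pos + 3])
                if residue == "*":
                    emit(pos + 3, right_bounded=True)
                    run_start, run_aa, left_bounded = None, [], True
                elif residue == "X":
                    # ambiguous codon breaks the run without a bounding stop
                    emit(pos, right_bounded=False)
                    run_start, run_aa, left_bounded = None, [], False
                else:
                    if run_start is None:
                        run_start = pos
                        run_aa = []
                    run_aa.append(residue)
                pos += 3
            emit(pos, right_bounded=False)
    return orfs


def _record_id(orf: SmOrf) -> str:
    return (
        f"{orf.transcript_accession}|{orf.strand}{orf.frame}"
        f"|{orf.nt_start}-{orf.nt_end}"
    )


_CLASS_PRECEDENCE = {
    StartClass.AUG: 0,
    StartClass.NEAR_COGNATE: 1,
    StartClass.UNKNOWN: 2,
}


def build_database(
    transcripts: Sequence[Transcript],
    min_aa: int = 7,
    require_kozak: bool = False,
    dedup: bool = True,
    allow_open_ended: bool = False,
) -> list[MicroproteinRecord]:
    """Union of AUG-initiated and stop-to-stop ORFs over all transcripts.

    Candidates identical by (accession, strand, frame, coordinates) are
    merged first; with ``dedup`` on, records sharing an amino-acid sequence
    are collapsed into one entry whose provenance lists every source ORF and
    whose start class is the most informative one observed
    (AUG > near-cognate > unknown). Record order is deterministic:
    by accession, strand, frame, then start coordinate.
    """
    if not transcripts:
        raise InputError("build_database requires at least one transcript")
    seen: dict[tuple[str, str, int, int, int], SmOrf] = {}
    for t in transcripts:
        found = find_aug_smorfs(
            t, min_aa=min_aa, require_kozak=require_kozak,
            allow_open_ended=allow_open_ended,
        ) + find_stop_to_stop_orfs(
            t, min_aa=min_aa, require_bounding_stops=not allow_open_ended,
        )
        for orf in found:
            key = (orf.transcript_accession, orf.strand, orf.frame,
                   orf.nt_start, orf.nt_end)
            prev = seen.get(key)
            if prev is None or (
                _CLASS_PRECEDENCE[orf.start_class]
                < _CLASS_PRECEDENCE[prev.start_class]
            ):
                seen[key] = orf

    ordered = sorted(
        seen.values(),
        key=lambda o: (o.transcript_accession, o.strand, o.frame, o.nt_start),
    )
    if not dedup:
        return [
            MicroproteinRecord(
                id=_record_id(o),
                aa_seq=o.aa_seq,
                length=len(o.aa_seq),
                start_class=o.start_class,
                provenance=(
                    (o.transcript_accession, o.strand, o.frame,
                     o.nt_start, o.nt_end),
                ),
            )
            for o in ordered
        ]

    by_seq: dict[str, list[SmOrf]] = {}
    for o in ordered:
        by_seq.setdefault(o.aa_seq, []).append(o)
    records = []
    for aa_seq, group in by_seq.items():
        lead = group[0]
        best_class = min(
            (o.start_class for o in group), key=_CLASS_PRECEDENCE.__getitem__
        )
        records.append(
            MicroproteinRecord(
                id=_record_id(lead),
                aa_seq=aa_seq,
                length=len(aa_seq),
                start_class=best_class,
                provenance=tuple(
                    (o.transcript_accession, o.strand, o.frame,
                     o.nt_start, o.nt_end)
                    for o in group
                ),
            )
        )
    records.sort(key=lambda r: (r.provenance[0][0], r.provenance[0][1],
                                r.provenance[0][2], r.provenance[0][3]))
    return records
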