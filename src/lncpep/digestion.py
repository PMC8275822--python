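"""In-silico tryptic digestion and peptide novelty against an annotated proteome.

A microprotein identification is only credible when it rests on peptides that
(a) could arise from a tryptic digest of the candidate and (b) do not occur
anywhere in the annotated reference proteome — otherwise the spectrum is
explained by a known protein. This module provides the digest, the novelty
check and the unique-peptide-to-microprotein assignment.

Trypsin cleaves C-terminal to K or R; by default cleavage is suppressed when
the following residue is proline, matching the convention of mainstream
search engines. Because collision-induced dissociation cannot distinguish
leucine from isoleucine, the novelty check collapses I and L by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import InputError, ParameterError
from .orfdb import MicroproteinRecord

__all__ = [
    "Peptide",
    "ProteomeIndex",
    "PeptideAssignment",
    "tryptic_digest",
    "is_novel_peptide",
    "assign_peptides",
    "min_length_filter",
]

_IL_COLLAPSE = str.maketrans("L", "I")


@dataclass(frozen=True)
class Peptide:
    """A peptide with its missed-cleavage count and modifications.

    Modifications are ``(site, name, monoisotopic_delta_da)`` with 1-based
    sites into ``sequence``.
    """

    sequence: str
    missed_cleavages: int = 0
    modifications: tuple[tuple[int, str, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError("empty peptide sequence")
        if self.missed_cleavages < 0:
            raise InputError("negative missed-cleavage count")
        for site, name, _delta in self.modifications:
            if not 1 <= site <= len(self.sequence):
                raise InputError(
                    f"modification {name!r} site {site} outside peptide "
                    f"of length {len(self.sequence)}"
                )

    def __len__(self) -> int:  # convenience for filters
        return len(self.sequence)


def _cleavage_sites(sequence: str, exclude_before_proline: bool) -> list[int]:
    """Positions after which trypsin cuts (1-based boundaries)."""
    sites = []
    for i, ch in enumerate(sequence[:-1]):
        if ch in "KR":
            if exclude_before_proline and sequence[i + 1] == "P":
                continue
            sites.append(i + 1)
    return sites


def tryptic_digest(
    protein: str,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 50,
    exclude_before_proline: bool = True,
) -> list[Peptide]:
    """Fully tryptic peptides of ``protein`` with up to ``max_missed`` missed
    cleavage sites and length within ``[min_len, max_len]``.

    Peptides are returned in order of their start position, then missed-
    cleavage count, each annotated with its missed-cleavage count.
    """
    if not protein:
        raise InputError("empty protein sequence")
    if max_missed < 0:
        raise ParameterError(f"max_missed must be >= 0, got {max_missed}")
    if min_len < 1 or max_len < min_len:
        raise ParameterError(
            f"invalid length window [{min_len}, {max_len}]"
        )
    boundaries = [0] + _cleavage_sites(protein, exclude_before_proline) + [
        len(protein)
    ]
    peptides = []
    n_frag = len(boundaries) - 1
    for i in range(n_frag):
        for j in range(i + 1, min(i + max_missed + 2, n_frag + 1)):
            seq = protein[boundaries[i] : boundaries[j]]
            if min_len <= len(seq) <= max_len:
                peptides.append(Peptide(sequence=seq, missed_cleavages=j - i - 1))
    return peptides


class ProteomeIndex:
    """Exact-substring membership over an annotated protein collection.

    With ``il_equivalent`` (default) isoleucine and leucine are treated as the
    same residue on both sides of the query, since MS2 fragmentation cannot
    tell them apart.
    """

    def __init__(self, sequences: Iterable[str], il_equivalent: bool = True):
        self.il_equivalent = il_equivalent
        seqs = [s.upper() for s in sequences]
        if il_equivalent:
            seqs = [s.translate(_IL_COLLAPSE) for s in seqs]
        self._sequences = seqs
        # '|' never occurs in amino-acid sequences, so a single joined string
        # gives substring search without false positives across boundaries.
        self._text = "|".join(seqs)
        self.n_proteins = len(seqs)

    def __contains__(self, peptide_sequence: str) -> bool:
        q = peptide_sequence.upper()
        if self.il_equivalent:
            q = q.translate(_IL_COLLAPSE)
        return q in self._text


def is_novel_peptide(p: Peptide | str, idx: ProteomeIndex) -> bool:
    """True iff the peptide occurs nowhere in the annotated proteome."""
    seq = p if isinstance(p, str) else p.sequence
    return seq not in idx


@dataclass(frozen=True)
class PeptideAssignment:
    """Which microprotein(s) a peptide maps to; unique iff exactly one."""

    peptide: str
    record_ids: tuple[str, ...]

    @property
    def is_unique(self) -> bool:
        return len(self.record_ids) == 1

    @property
    def unique_to(self) -> str | None:
        return self.record_ids[0] if self.is_unique else None


def assign_peptides(
    peptides: Iterable[Peptide | str],
    db: Sequence[MicroproteinRecord],
) -> dict[str, PeptideAssignment]:
    """Map each peptide to the deduplicated microprotein sequences containing it.

    A peptide is *unique* when it occurs in exactly one distinct microprotein
    sequence; only unique peptides validate a specific microprotein.
    """
    if not db:
        raise InputError("assign_peptides requires a nonempty database")
    # collapse identical sequences: uniqueness is at the sequence level
    seq_to_ids: dict[str, list[str]] = {}
    for rec in db:
        seq_to_ids.setdefault(rec.aa_seq, []).append(rec.id)
    out: dict[str, PeptideAssignment] = {}
    for p in peptides:
        seq = p if isinstance(p, str) else p.sequence
        hits = tuple(
            ids[0] for aa, ids in seq_to_ids.items() if seq in aa
        )
        out[seq] = PeptideAssignment(peptide=seq, record_ids=hits)
    return out


def min_length_filter(
    peptides: Iterable[Peptide], min_len: int = 6
) -> list[Peptide]:
    """Retain peptides of at least ``min_len`` residues (default 6)."""
    return [p for p in peptides if len(p.sequence) >= min_len]
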