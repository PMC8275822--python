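"""Readers and writers for the pipeline's external formats.

Supported formats: multi-FASTA (transcripts, proteomes, microprotein
databases), MGF peak lists, tab-separated PSM tables, tab-separated
intensity/detection matrices with a sample-to-group file, and the packaged
reference table of microproteins identified specifically in plasma EVs of
glioma patients.

All tabular formats are UTF-8, tab-separated with a header row. Readers
validate rather than coerce: malformed records raise :class:`FormatError`
(or :class:`IntegrityError` for the packaged reference data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .digestion import Peptide
from .errors import FormatError, IntegrityError
from .orfdb import MicroproteinRecord, StartClass, Transcript, normalize_transcript
from .quantify import DetectionMatrix
from .spectral import Ms2Spectrum, Psm

__all__ = [
    "FastaRecord",
    "read_fasta",
    "write_fasta",
    "read_transcripts",
    "read_proteome",
    "write_database",
    "read_mgf",
    "write_mgf",
    "read_psm_table",
    "write_psm_table",
    "read_matrix",
    "write_matrix",
    "load_reference_microproteins",
    "load_reference_records",
    "REFERENCE_SET_SIZE",
]

logger = logging.getLogger(__name__)

#: Number of microproteins in the packaged glioma-EV reference list.
REFERENCE_SET_SIZE = 19

_REFERENCE_RESOURCE = "glioma_ev_microproteins.tsv"


@dataclass(frozen=True)
class FastaRecord:
    id: str
    description: str
    sequence: str


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read a multi-FASTA file; the first whitespace token of each header is
    the accession. An empty file yields an empty list (with a warning); a
    file whose first non-blank line is not a header raises
    :class:`FormatError` with the line number.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    first_content = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            first_content = (lineno, line)
            break
    if first_content is None:
        logger.warning("FASTA file %s is empty", path)
        return []
    if not first_content[1].lstrip().startswith(">"):
        raise FormatError(
            f"{path}: line {first_content[0]}: expected '>' header, got "
            f"{first_content[1][:30]!r}"
        )
    records = []
    from io import StringIO

    for rec in SeqIO.parse(StringIO(text), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(
            FastaRecord(id=rec.id, description=desc, sequence=str(rec.seq))
        )
    return records


def write_fasta(
    records: Iterable[FastaRecord | tuple[str, str, str]],
    path: str | Path,
    wrap: int = 60,
) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                rec = FastaRecord(*rec)
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            seq = rec.sequence
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def read_transcripts(path: str | Path) -> list[Transcript]:
    """Read lncRNA transcripts, normalizing to the DNA alphabet."""
    return [
        normalize_transcript(r.id, r.sequence, r.description)
        for r in read_fasta(path)
    ]


def read_proteome(path: str | Path) -> list[str]:
    """Annotated protein sequences from FASTA (UniProt-style headers
    tolerated; only sequences are needed for the novelty index)."""
    return [r.sequence.upper() for r in read_fasta(path)]


def _provenance_str(rec: MicroproteinRecord) -> str:
    return ";".join(
        f"{acc}:{strand}{frame}:{start}-{end}"
        for acc, strand, frame, start, end in rec.provenance
    )


def write_database(
    records: Sequence[MicroproteinRecord],
    fasta_path: str | Path,
    table_path: str | Path | None = None,
) -> None:
    """Write a microprotein database as FASTA plus an optional metadata table.

    FASTA headers are ``id|start_class|length|provenance``.
    """
    write_fasta(
        (
            FastaRecord(
                id=rec.id,
                description=f"{rec.start_class.value}|{rec.length}|"
                f"{_provenance_str(rec)}",
                sequence=rec.aa_seq,
            )
            for rec in records
        ),
        fasta_path,
    )
    if table_path is not None:
        pd.DataFrame(
            {
                "id": [r.id for r in records],
                "start_class": [r.start_class.value for r in records],
                "length_aa": [r.length for r in records],
                "provenance": [_provenance_str(r) for r in records],
                "sequence": [r.aa_seq for r in records],
            }
        ).to_csv(table_path, sep="\t", index=False)


def read_mgf(path: str | Path) -> list[Ms2Spectrum]:
    """Read MGF spectra: TITLE becomes the spectrum id, peaks are sorted
    ascending, blocks without peaks are dropped with a warning, and a missing
    CHARGE line leaves the precursor charge unknown."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    begins = sum(1 for ln in lines if ln.strip() == "BEGIN IONS")
    ends = sum(1 for ln in lines if ln.strip() == "END IONS")
    if begins != ends:
        raise FormatError(
            f"{path}: unbalanced BEGIN IONS/END IONS ({begins} vs {ends})"
        )
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            title = str(params.get("title", f"spectrum_{i}"))
            mz = np.asarray(entry.get("m/z array", []), dtype=float)
            inten = np.asarray(entry.get("intensity array", []), dtype=float)
            if mz.size == 0:
                logger.warning("%s: spectrum %r has no peaks; dropped", path, title)
                continue
            pepmass = params.get("pepmass", (0.0,))
            precursor_mz = float(pepmass[0]) if pepmass and pepmass[0] else 0.0
            charge_field = params.get("charge")
            charge = int(charge_field[0]) if charge_field else None
            spectra.append(
                Ms2Spectrum(
                    spectrum_id=title,
                    precursor_mz=precursor_mz,
                    precursor_charge=charge,
                    mz=mz,
                    intensity=inten,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Ms2Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        params = {"title": s.spectrum_id, "pepmass": s.precursor_mz}
        if s.precursor_charge is not None:
            params["charge"] = s.precursor_charge
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": params,
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


_PSM_COLUMNS = [
    "spectrum_id", "peptide", "modifications", "charge", "score",
    "source_ids", "is_decoy",
]


def _parse_mods(text: str) -> tuple[tuple[int, str, float], ...]:
    if not text or text in ("-", "nan"):
        return ()
    mods = []
    for part in text.split(";"):
        site, name, delta = part.split(":")
        mods.append((int(site), name, float(delta)))
    return tuple(mods)


def read_psm_table(path: str | Path) -> list[Psm]:
    """Tab-separated PSM table with documented header.

    Columns: ``spectrum_id, peptide, modifications, charge, score,
    source_ids, is_decoy``; modifications encoded ``site:name:delta`` joined
    by ';' (empty for none), source ids joined by ';'. Exports from vendor
    search engines (e.g. Proteome Discoverer PSM exports) can be converted by
    renaming columns to this schema and re-encoding modification strings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _PSM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing PSM columns {missing}")
    psms = []
    for row in df.itertuples(index=False):
        psms.append(
            Psm(
                spectrum_id=row.spectrum_id,
                peptide=Peptide(
                    sequence=row.peptide,
                    modifications=_parse_mods(row.modifications),
                ),
                charge=int(row.charge),
                engine_score=float(row.score),
                source_ids=tuple(
                    s for s in str(row.source_ids).split(";") if s
                ),
                is_decoy=str(row.is_decoy).strip().lower()
                in ("1", "true", "yes"),
            )
        )
    return psms


def write_psm_table(psms: Sequence[Psm], path: str | Path) -> None:
    pd.DataFrame(
        {
            "spectrum_id": [p.spectrum_id for p in psms],
            "peptide": [p.peptide.sequence for p in psms],
            "modifications": [
                ";".join(
                    f"{site}:{name}:{delta}" for site, name, delta
                    in p.peptide.modifications
                )
                for p in psms
            ],
            "charge": [p.charge for p in psms],
            "score": [p.engine_score for p in psms],
            "source_ids": [";".join(p.source_ids) for p in psms],
            "is_decoy": [int(p.is_decoy) for p in psms],
            "q_value": [
                "" if p.q_value is None else p.q_value for p in psms
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def read_matrix(
    matrix_path: str | Path, groups_path: str | Path
) -> DetectionMatrix:
    """Intensity matrix (first column microprotein id, one column per sample)
    plus a two-column ``sample<TAB>group`` file. Duplicated sample columns
    are rejected."""
    matrix_path = Path(matrix_path)
    with open(matrix_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise FormatError(f"{matrix_path}: duplicated sample columns {dupes}")
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    gdf = pd.read_csv(groups_path, sep="\t", dtype=str)
    if list(gdf.columns[:2]) != ["sample", "group"]:
        raise FormatError(
            f"{groups_path}: expected header 'sample<TAB>group'"
        )
    groups = dict(zip(gdf["sample"], gdf["group"]))
    return DetectionMatrix(values, groups)


def write_matrix(m: DetectionMatrix, matrix_path: str | Path,
                 groups_path: str | Path | None = None) -> None:
    m.values.to_csv(matrix_path, sep="\t", index_label="id")
    if groups_path is not None:
        m.groups.rename_axis("sample").reset_index().to_csv(
            groups_path, sep="\t", index=False
        )


def load_reference_microproteins() -> pd.DataFrame:
    """The packaged reference list of 19 microproteins identified specifically
    in plasma EVs of glioma patients.

    Columns: id, chromosome, strand, strand_printed (the typographic strand
    symbol as originally printed), genomic_start, genomic_end (1-based
    inclusive, spliced spans — never used for arithmetic), length_aa,
    sequence. Integrity is validated on every load: exactly
    ``REFERENCE_SET_SIZE`` rows, unique ids, and sequence length equal to the
    printed length.
    """
    with resources.files("lncpep.data").joinpath(_REFERENCE_RESOURCE).open(
        encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh, sep="\t")
    if len(df) != REFERENCE_SET_SIZE:
        raise IntegrityError(
            f"reference table has {len(df)} rows, expected {REFERENCE_SET_SIZE}"
        )
    if df["id"].duplicated().any():
        raise IntegrityError("reference table contains duplicated ids")
    for row in df.itertuples(index=False):
        if len(row.sequence) != row.length_aa:
            raise IntegrityError(
                f"reference row {row.id}: sequence length "
                f"{len(row.sequence)} != printed length {row.length_aa}"
            )
        if row.strand not in "+-":
            raise IntegrityError(f"reference row {row.id}: bad strand")
    return df


def load_reference_records() -> list[MicroproteinRecord]:
    """Reference rows as validated :class:`MicroproteinRecord` objects.

    Start class is inferred from the product (initial Met implies an AUG
    start; otherwise the initiator is unknown at the protein level), and the
    printed genomic span is carried as provenance with frame 0 — genomic
    coordinates are spliced and never used for arithmetic here.
    """
    df = load_reference_microproteins()
    records = []
    for row in df.itertuples(index=False):
        records.append(
            MicroproteinRecord(
                id=row.id,
                aa_seq=row.sequence,
                length=int(row.length_aa),
                start_class=(
                    StartClass.AUG if row.sequence.startswith("M")
                    else StartClass.UNKNOWN
                ),
                provenance=(
                    (row.id, row.strand, 0, int(row.genomic_start),
                     int(row.genomic_end)),
                ),
            )
        )
    return records
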