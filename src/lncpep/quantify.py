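"""Downstream characterization and cohort statistics for detected microproteins.

Label-free microprotein evidence is sparse: most candidates are seen in only
some samples, so cohort comparison works on presence/absence at the group
level, while intensity-based analysis (PCA) uses total-area-sum normalization
restricted to reproducibly detected microproteins.

The central container is :class:`DetectionMatrix`: microproteins x samples,
``NaN`` meaning "not detected", with a group label per sample (e.g. healthy
donors vs glioma patients).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .digestion import Peptide
from .errors import InputError, ParameterError
from .orfdb import MicroproteinRecord, StartClass

__all__ = [
    "DetectionMatrix",
    "GroupComparison",
    "PcaResult",
    "CharacteristicsSummary",
    "sequence_coverage",
    "replicate_consistency",
    "presence_compare",
    "tas_normalize",
    "pca_scores",
    "summarize_characteristics",
]


class DetectionMatrix:
    """Raw area intensities of microproteins across samples, with group labels.

    ``values`` is a DataFrame indexed by microprotein id with one column per
    sample; absent detections are ``NaN``. ``groups`` maps every sample to a
    cohort group.
    """

    def __init__(self, values: pd.DataFrame, groups: Mapping[str, str]):
        if values.index.has_duplicates:
            raise InputError("duplicated microprotein ids in matrix")
        if values.columns.has_duplicates:
            raise InputError("duplicated sample columns in matrix")
        vals = values.astype(float)
        if (vals.to_numpy() < 0).any():
            raise InputError("negative intensities in detection matrix")
        missing = [s for s in vals.columns if s not in groups]
        if missing:
            raise InputError(f"samples without group label: {missing}")
        self.values = vals
        self.groups = pd.Series(
            {s: groups[s] for s in vals.columns}, name="group"
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def microprotein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def group_names(self) -> list[str]:
        return sorted(self.groups.unique())

    def samples_of(self, group: str) -> list[str]:
        if group not in set(self.groups):
            raise InputError(f"unknown group {group!r}")
        return list(self.groups.index[self.groups == group])

    def detected(self) -> pd.DataFrame:
        """Boolean presence per cell."""
        return self.values.notna()


@dataclass(frozen=True)
class GroupComparison:
    """Group-level detection divergence between two cohorts."""

    group_a: str
    group_b: str
    detected_a: frozenset[str]
    detected_b: frozenset[str]

    @property
    def missing_in_b(self) -> frozenset[str]:
        return self.detected_a - self.detected_b

    @property
    def new_in_b(self) -> frozenset[str]:
        return self.detected_b - self.detected_a

    @property
    def shared(self) -> frozenset[str]:
        return self.detected_a & self.detected_b


def sequence_coverage(
    record: MicroproteinRecord | str,
    peptides: Iterable[Peptide | str],
) -> float:
    """Fraction of residues covered by the union of peptide occurrences.

    Every occurrence of every peptide counts; a peptide that is not a
    substring of the microprotein raises :class:`InputError`.
    """
    protein = record if isinstance(record, str) else record.aa_seq
    covered = np.zeros(len(protein), dtype=bool)
    for p in peptides:
        seq = p if isinstance(p, str) else p.sequence
        start = protein.find(seq)
        if start < 0:
            raise InputError(
                f"peptide {seq!r} is not a substring of the microprotein"
            )
        while start >= 0:
            covered[start : start + len(seq)] = True
            start = protein.find(seq, start + 1)
    return float(covered.mean())


def replicate_consistency(
    m: DetectionMatrix, group: str, k: int = 2
) -> tuple[int, list[str]]:
    """Microproteins detected in at least ``k`` samples of ``group``.

    Returns the count together with the ids so that every headline number is
    auditable.
    """
    samples = m.samples_of(group)
    if k > len(samples):
        raise ParameterError(
            f"k={k} exceeds group {group!r} size {len(samples)}"
        )
    hits = m.detected()[samples].sum(axis=1)
    ids = sorted(hits.index[hits >= k])
    return len(ids), ids


def presence_compare(
    m: DetectionMatrix,
    group_a: str,
    group_b: str,
    min_samples: int = 1,
) -> GroupComparison:
    """Presence/absence divergence between two groups.

    A microprotein counts as detected in a group when it is present in at
    least ``min_samples`` of that group's samples (default: union over
    samples).
    """
    det = m.detected()

    def group_set(group: str) -> frozenset[str]:
        samples = m.samples_of(group)
        hits = det[samples].sum(axis=1)
        return frozenset(hits.index[hits >= min_samples])

    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        detected_a=group_set(group_a),
        detected_b=group_set(group_b),
    )


def tas_normalize(
    m: DetectionMatrix, min_group_detections: int = 2
) -> DetectionMatrix:
    """Total-area-sum normalization over reproducibly detected microproteins.

    Microproteins detected fewer than ``min_group_detections`` times in any
    group are dropped; each remaining intensity is divided by its sample's
    total over the retained microproteins, so present values in a sample sum
    to 1. Absent cells stay ``NaN`` (imputation, if any, is the consumer's
    choice — PCA imputes zero).
    """
    det = m.detected()
    keep = pd.Series(True, index=m.values.index)
    for group in m.group_names:
        samples = m.samples_of(group)
        keep &= det[samples].sum(axis=1) >= min_group_detections
    retained = m.values.loc[keep]
    if retained.empty:
        raise InputError(
            "no microprotein passes the per-group detection filter"
        )
    totals = retained.sum(axis=0, skipna=True)
    dead = [s for s in retained.columns if not totals[s] > 0]
    if dead:
        raise InputError(f"samples with no retained detections: {dead}")
    return DetectionMatrix(retained.div(totals, axis=1), dict(m.groups))


@dataclass(frozen=True)
class PcaResult:
    """Sample scores and explained-variance fractions."""

    scores: pd.DataFrame              # samples x components
    explained_variance_ratio: np.ndarray

    def pc(self, i: int) -> pd.Series:
        return self.scores.iloc[:, i - 1]


def pca_scores(m: DetectionMatrix, n_components: int = 2) -> PcaResult:
    """PCA of samples on mean-centered (unscaled) normalized intensities.

    Absent values are imputed as zero — not detected is read as zero area
    intensity. Input is typically the output of :func:`tas_normalize`. A
    matrix with zero total variance yields all-zero scores and variance
    fractions.
    """
    X = m.values.T.fillna(0.0).to_numpy()  # samples x microproteins
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ParameterError("PCA requires >= 2 samples and >= 2 microproteins")
    k = min(n_components, X.shape[0], X.shape[1])
    centered = X - X.mean(axis=0)
    if not np.any(np.abs(centered) > 0):
        scores = np.zeros((X.shape[0], k))
        evr = np.zeros(k)
    else:
        model = PCA(n_components=k)
        scores = model.fit_transform(X)
        evr = model.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=m.values.columns, columns=cols),
        explained_variance_ratio=np.asarray(evr),
    )


@dataclass(frozen=True)
class CharacteristicsSummary:
    """Length, start-codon-usage and coverage summaries of a microprotein set."""

    length_histogram: dict[int, int]          # bin lower edge -> count
    start_class_fractions: dict[StartClass, float]
    coverages: dict[str, float]               # record id -> coverage
    mean_coverage: float | None


def summarize_characteristics(
    records: Sequence[MicroproteinRecord],
    peptides_by_record: Mapping[str, Sequence[Peptide | str]] | None = None,
    length_bin: int = 20,
) -> CharacteristicsSummary:
    """Binned length counts, start-class fractions and sequence coverages.

    Lengths are binned in ``length_bin``-residue bins starting at 0; the
    start-class fractions sum to 1 over a nonempty record set. Coverage is
    reported for records with assigned peptides.
    """
    if length_bin < 1:
        raise ParameterError("length_bin must be >= 1")
    hist: dict[int, int] = {}
    class_counts: dict[StartClass, int] = {}
    for rec in records:
        edge = (rec.length // length_bin) * length_bin
        hist[edge] = hist.get(edge, 0) + 1
        class_counts[rec.start_class] = class_counts.get(rec.start_class, 0) + 1
    n = len(records)
    fractions = {c: count / n for c, count in class_counts.items()} if n else {}
    coverages: dict[str, float] = {}
    if peptides_by_record:
        by_id = {rec.id: rec for rec in records}
        for rec_id, peps in peptides_by_record.items():
            if rec_id not in by_id:
                raise InputError(f"unknown record id {rec_id!r}")
            coverages[rec_id] = sequence_coverage(by_id[rec_id], peps)
    mean_cov = (
        float(np.mean(list(coverages.values()))) if coverages else None
    )
    return CharacteristicsSummary(
        length_histogram=dict(sorted(hist.items())),
        start_class_fractions=fractions,
        coverages=coverages,
        mean_coverage=mean_cov,
    )
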