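"""Sequence and manifest I/O plus reference-anchored coordinate mapping.

All downstream SNP lookups are expressed in 1-based coordinates of a locus
reference sequence; :func:`align_to_reference` produces the reference->query
position map via a global pairwise alignment with affine gap costs (gap open
10, gap extension 1, matching the alignment costs used to build the panel;
match/mismatch default to +1/-1).  Partial amplicons (e.g. an rbcLa-only read
against the full rbcL reference) simply pay for a terminal gap; uncovered
reference positions come back as gaps and are reported as missing by the
profile extractor.

No multiple sequence alignment is performed anywhere in the package: every
coordinate question is pairwise-to-reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .panel import IUPAC_CODES

__all__ = [
    "SeqRecord",
    "CoordinateMap",
    "WrongLocusError",
    "read_fasta",
    "write_fasta",
    "align_to_reference",
    "base_at",
    "reference_anchored_rows",
    "read_manifest",
]

logger = logging.getLogger(__name__)

GAP = "-"
_ALPHABET = "".join(sorted(IUPAC_CODES))


class WrongLocusError(ValueError):
    """Alignment identity fell below the floor: query is not this locus."""


@dataclass(frozen=True)
class SeqRecord:
    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CoordinateMap:
    """Mapping from 1-based reference positions to 1-based query positions.

    ``ref_to_query[i]`` holds the query position aligned to reference position
    ``i + 1``, or ``0`` where the reference base is deleted from the query
    (including uncovered reference ends).
    """

    query_id: str
    reference_id: str
    ref_to_query: np.ndarray  # int32, len == len(reference)
    score: float
    identity: float

    def query_position(self, position: int) -> int | None:
        """1-based query position aligned to the reference position, or None."""
        if not 1 <= position <= len(self.ref_to_query):
            raise IndexError(
                f"position {position} outside reference 1..{len(self.ref_to_query)}"
            )
        q = int(self.ref_to_query[position - 1])
        return q if q > 0 else None


def _normalize(seq: str, rec_id: str) -> str:
    seq = seq.upper()
    if GAP in seq or "." in seq:
        logger.warning("record %s: stripping gap characters from input sequence", rec_id)
        seq = seq.replace(GAP, "").replace(".", "")
    bad = set(seq) - set(_ALPHABET)
    if bad:
        logger.warning(
            "record %s: replacing non-IUPAC characters %s with N", rec_id, sorted(bad)
        )
        seq = "".join(c if c in _ALPHABET else "N" for c in seq)
    return seq


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into uppercase, gap-free records (order preserved).

    Duplicate ids are kept but deduplicated with a numeric suffix, with a
    logged warning.
    """
    records: list[SeqRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}_{seen[rid]}"
            logger.warning("duplicate FASTA id %s renamed to %s", rid, new_id)
            rid = new_id
        else:
            seen[rid] = 1
        records.append(
            SeqRecord(id=rid, seq=_normalize(str(rec.seq), rid), description=rec.description)
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SeqRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _iupac_matrix(match: float, mismatch: float) -> substitution_matrices.Array:
    """Score +match when the two IUPAC sets intersect, mismatch otherwise."""
    m = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            m[a, b] = match if IUPAC_CODES[a] & IUPAC_CODES[b] else mismatch
    return m


def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _iupac_matrix(match, mismatch)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


_DEFAULT_ALIGNER = None


def _default_aligner() -> PairwiseAligner:
    global _DEFAULT_ALIGNER
    if _DEFAULT_ALIGNER is None:
        _DEFAULT_ALIGNER = _make_aligner(1.0, -1.0, 10.0, 1.0)
    return _DEFAULT_ALIGNER


def align_to_reference(
    query: SeqRecord,
    reference: SeqRecord,
    *,
    min_identity: float = 0.70,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> CoordinateMap:
    """Globally align ``query`` to ``reference`` and return the coordinate map.

    Identity is computed over aligned (non-gap) columns; below ``min_identity``
    a :class:`WrongLocusError` is raised.
    """
    if (match, mismatch, gap_open, gap_extend) == (1.0, -1.0, 10.0, 1.0):
        aligner = _default_aligner()
    else:
        aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    alignment = aligner.align(reference.seq, query.seq)[0]

    ref_to_query = np.zeros(len(reference.seq), dtype=np.int32)
    matches = 0
    aligned_cols = 0
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        ref_to_query[t0:t1] = np.arange(q0 + 1, q1 + 1, dtype=np.int32)
        aligned_cols += t1 - t0
        rblock = reference.seq[t0:t1]
        qblock = query.seq[q0:q1]
        matches += sum(
            1 for r, q in zip(rblock, qblock) if IUPAC_CODES[r] & IUPAC_CODES[q]
        )
    identity = matches / aligned_cols if aligned_cols else 0.0
    if identity < min_identity:
        raise WrongLocusError(
            f"{query.id} vs {reference.id}: identity {identity:.2f} below "
            f"floor {min_identity:.2f} (wrong locus?)"
        )
    return CoordinateMap(
        query_id=query.id,
        reference_id=reference.id,
        ref_to_query=ref_to_query,
        score=float(alignment.score),
        identity=identity,
    )


def base_at(coord_map: CoordinateMap, query: SeqRecord, position: int) -> str:
    """Query base aligned to the 1-based reference ``position`` (GAP if deleted)."""
    q = coord_map.query_position(position)
    if q is None:
        return GAP
    return query.seq[q - 1]


def reference_anchored_rows(
    records: Sequence[SeqRecord],
    reference: SeqRecord,
    *,
    min_identity: float = 0.70,
) -> dict[str, str]:
    """Project each record onto the reference columns (a pseudo-alignment).

    Every output row has length ``len(reference)``; insertions relative to the
    reference are dropped, deletions/uncovered ends become gaps.  This gives a
    common coordinate frame for distance computation without a full MSA.
    """
    rows: dict[str, str] = {}
    for rec in records:
        cmap = align_to_reference(rec, reference, min_identity=min_identity)
        chars = []
        for q in cmap.ref_to_query:
            chars.append(rec.seq[q - 1] if q > 0 else GAP)
        rows[rec.id] = "".join(chars)
    return rows


def read_manifest(path):
    """Read a tab-separated collection manifest into a pandas DataFrame.

    Requires at least ``accession_id`` and ``original_label`` columns; extra
    columns (truth fields of synthetic manifests) are passed through.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"accession_id", "original_label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    if df["accession_id"].duplicated().any():
        dups = df.loc[df["accession_id"].duplicated(), "accession_id"].tolist()
        raise ValueError(f"{path}: duplicate accession ids {dups}")
    return df
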