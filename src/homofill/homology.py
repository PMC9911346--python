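"""Sequence-based donor search: local alignments as HSPs, E-value ordered.

Each donor chain is aligned to the query with a gapped Smith-Waterman
(BLOSUM62, gap open 11 / extend 1, via Bio.Align.PairwiseAligner) and the
resulting high-scoring segment pairs are assigned E-values with standard
Karlin-Altschul statistics for those gapped parameters, including the
usual edge-effect length correction.  A chain can contribute several HSPs
(e.g. permuted or repeated domains): after each alignment the matched donor
segment is masked out and the chain is re-aligned until the score drops
below significance.

Hits are sorted ascending by E-value — this single ordering captures both
similarity and alignment length and later fixes which donor wins a
deduplication race.  Filtering keeps HSPs with identity >= 25% over an
aligned length >= 85 residues (both bounds inclusive); the identity
denominator is the alignment length including gap columns, the usual
convention for reported BLAST identities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .structure import Structure, extract_sequence

__all__ = [
    "Hsp",
    "SequenceDatabase",
    "build_donor_db",
    "find_homologs",
    "filter_hits",
    "read_fasta_db",
    "write_fasta_db",
]

# Gapped Karlin-Altschul parameters for BLOSUM62 with open 11 / extend 1.
_LAMBDA = 0.267
_K = 0.041
_H = 0.14
_MAX_EVALUE = 10.0       # significance cutoff for reporting an HSP
_MAX_HSPS_PER_CHAIN = 8  # masking iterations per donor chain
_MASK_CHAR = "*"         # scores -4 against everything in BLOSUM62


@dataclass(frozen=True)
class Hsp:
    """One local-alignment segment pair between query and a donor chain."""

    donor_entry: str
    donor_chain: str
    query_range: tuple[int, int]      # 1-based closed
    donor_range: tuple[int, int]      # 1-based closed
    aligned_pairs: tuple[tuple[int, int], ...]  # (query_seq_id, donor_seq_id), non-gap columns
    alignment_length: int             # columns including gaps
    identities: int
    score: float
    evalue: float

    @property
    def identity_fraction(self) -> float:
        return self.identities / self.alignment_length

    def donor_to_query(self) -> dict[int, int]:
        return {d: q for q, d in self.aligned_pairs}


@dataclass
class SequenceDatabase:
    records: list[tuple[str, str, str]] = field(default_factory=list)  # (entry, chain, sequence)

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, _, seq in self.records)

    def __len__(self) -> int:
        return len(self.records)


def build_donor_db(structures: Iterable[Structure]) -> SequenceDatabase:
    """One database record per (entry, polymer chain)."""
    db = SequenceDatabase()
    for s in structures:
        for chain in s.polymer_chains:
            db.records.append((s.entry_id, chain.id, extract_sequence(s, chain.id)))
    return db


def write_fasta_db(db: SequenceDatabase, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{entry}_{chain}", description="")
        for entry, chain, seq in db.records
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_db(path: str | Path) -> SequenceDatabase:
    db = SequenceDatabase()
    for rec in SeqIO.parse(str(path), "fasta"):
        entry, _, chain = rec.id.rpartition("_")
        db.records.append((entry or rec.id, chain if entry else "A", str(rec.seq)))
    return db


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _evalue(score: float, query_len: int, db: SequenceDatabase) -> float:
    """Karlin-Altschul expectation with edge-effect length adjustment."""
    n_total = max(db.total_length, 1)
    ell = math.log(_K * query_len * n_total) / _H if query_len * n_total > 0 else 0.0
    m_eff = max(query_len - ell, 1.0 / _K)
    n_eff = max(n_total - len(db) * ell, 1.0 / _K)
    return _K * m_eff * n_eff * math.exp(-_LAMBDA * score)


def _extract_hsp(alignment, entry: str, chain: str, evalue: float) -> Hsp:
    q_blocks, t_blocks = (
        [(int(a), int(b)) for a, b in blocks] for blocks in alignment.aligned
    )  # target=query, query=donor in our call order
    pairs: list[tuple[int, int]] = []
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        pairs.extend((q + 1, t + 1) for q, t in zip(range(qs, qe), range(ts, te)))
    qseq = alignment.target
    tseq = alignment.query
    identities = sum(1 for q, t in pairs if qseq[q - 1] == tseq[t - 1])
    # columns including gaps: span covered in each sequence plus the other's gaps
    q_span = q_blocks[-1][1] - q_blocks[0][0]
    t_span = t_blocks[-1][1] - t_blocks[0][0]
    n_pairs = len(pairs)
    alignment_length = n_pairs + (q_span - n_pairs) + (t_span - n_pairs)
    return Hsp(
        donor_entry=entry,
        donor_chain=chain,
        query_range=(q_blocks[0][0] + 1, q_blocks[-1][1]),
        donor_range=(t_blocks[0][0] + 1, t_blocks[-1][1]),
        aligned_pairs=tuple(pairs),
        alignment_length=alignment_length,
        identities=identities,
        score=float(alignment.score),
        evalue=evalue,
    )


def find_homologs(query: str, db: SequenceDatabase, max_hits: int = 250) -> list[Hsp]:
    """All significant HSPs of the query against every database record.

    Returns at most ``max_hits`` HSPs sorted ascending by E-value; ties break
    on higher identity fraction, then lexicographic (entry, chain).
    """
    if not query:
        raise ValueError("query sequence is empty")
    aligner = _make_aligner()
    hsps: list[Hsp] = []
    for entry, chain, seq in db.records:
        masked = list(seq)
        for _ in range(_MAX_HSPS_PER_CHAIN):
            target = "".join(masked)
            if not target.strip(_MASK_CHAR):
                break
            alignments = aligner.align(query, target)
            try:
                best = alignments[0]
            except (IndexError, ValueError):
                break
            if best.score <= 0:
                break
            ev = _evalue(best.score, len(query), db)
            if ev > _MAX_EVALUE:
                break
            hsp = _extract_hsp(best, entry, chain, ev)
            hsps.append(hsp)
            d0, d1 = hsp.donor_range
            for i in range(d0 - 1, d1):
                masked[i] = _MASK_CHAR
    hsps.sort(key=lambda h: (h.evalue, -h.identity_fraction, h.donor_entry, h.donor_chain))
    return hsps[:max_hits]


def filter_hits(hsps: Sequence[Hsp], min_identity: float = 0.25, min_length: int = 85) -> list[Hsp]:
    """Keep HSPs with identity_fraction >= min_identity and alignment_length
    >= min_length (both inclusive); input order is preserved."""
    return [h for h in hsps if h.identity_fraction >= min_identity and h.alignment_length >= min_length]
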