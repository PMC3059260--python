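"""Matching of small-RNA reads to element sequences, the 18-27 nt length
histogram, and TPQ (occurrences per quarter million) normalization.

Element-derived small RNAs in plants are processed from retrotransposon
transcripts by the RNAi machinery; their hallmark is an 18-27 nt length
range with a 24 nt mode. Matching is exact by default (mismatches are
exposed as a flag), against both strands of the element. Distinct-read
counting de-duplicates identical read sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ._util import revcomp
from .seqio import GenomicSequence


@dataclass
class ReadMatch:
    read_id: str
    position: int
    strand: str
    length: int


@dataclass
class SmallRNAMatchSet:
    element_id: str
    matches: list[ReadMatch] = field(default_factory=list)
    length_histogram: dict[int, int] = field(default_factory=dict)
    distinct_matching_reads: int = 0
    library_total: int = 0
    tpq: float = 0.0


def tpq(matched: int, library_total: int) -> float:
    """Occurrences per quarter million: matched / library_total x 250,000."""
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    if matched > library_total:
        raise ValueError("matched count exceeds library size")
    return matched / library_total * 250_000


def _find_exact(read: str, targets: dict[str, str]) -> list[tuple[int, str]]:
    out = []
    for strand, seq in targets.items():
        i = seq.find(read)
        while i != -1:
            pos = i if strand == "+" else len(seq) - i - len(read)
            out.append((pos, strand))
            i = seq.find(read, i + 1)
    return out


def _find_mismatch(read: str, targets: dict[str, str], max_mm: int) -> list[tuple[int, str]]:
    out = []
    k = len(read)
    for strand, seq in targets.items():
        for i in range(len(seq) - k + 1):
            mm = 0
            for a, b in zip(read, seq[i:i + k]):
                if a != b:
                    mm += 1
                    if mm > max_mm:
                        break
            else:
                pos = i if strand == "+" else len(seq) - i - k
                out.append((pos, strand))
    return out


def match_small_rna(
    reads: Sequence[tuple[str, str]],
    element_seq: GenomicSequence | str,
    max_mismatch: int = 0,
    len_min: int = 18,
    len_max: int = 27,
    library_total: int | None = None,
) -> SmallRNAMatchSet:
    """Match a small-RNA library against one element sequence.

    ``reads`` are (read_id, sequence) pairs; RNA input (U) is accepted and
    converted. Reads outside [len_min, len_max] are skipped; surviving reads
    are matched against both strands of the element allowing at most
    ``max_mismatch`` substitutions. Match positions are reported on the
    forward strand of the element. The length histogram and the TPQ count
    are over distinct matching read sequences; ``library_total`` defaults to
    the number of reads supplied.
    """
    if not reads:
        raise ValueError("empty read set")
    if isinstance(element_seq, GenomicSequence):
        element_id, elem = element_seq.id, element_seq.residues
    else:
        element_id, elem = "element", element_seq.upper()
    targets = {"+": elem, "-": revcomp(elem)}
    total = library_total if library_total is not None else len(reads)

    result = SmallRNAMatchSet(element_id=element_id, library_total=total)
    matched_seqs: set[str] = set()
    for read_id, raw in reads:
        read = raw.upper().replace("U", "T")
        if not (len_min <= len(read) <= len_max):
            continue
        if max_mismatch == 0:
            hits = _find_exact(read, targets)
        else:
            hits = _find_mismatch(read, targets, max_mismatch)
        for pos, strand in hits:
            result.matches.append(
                ReadMatch(read_id=read_id, position=pos, strand=strand, length=len(read))
            )
        if hits and read not in matched_seqs:
            matched_seqs.add(read)
            result.length_histogram[len(read)] = (
                result.length_histogram.get(len(read), 0) + 1
            )
    result.distinct_matching_reads = len(matched_seqs)
    result.tpq = tpq(result.distinct_matching_reads, total)
    return result


def read_small_rna_library(path) -> list[tuple[str, str]]:
    """Read a FASTA or FASTQ small-RNA library into (id, sequence) pairs."""
    from Bio import SeqIO

    path = str(path)
    fmt = "fastq" if path.endswith((".fq", ".fastq")) else "fasta"
    reads = [(r.id, str(r.seq)) for r in SeqIO.parse(path, fmt)]
    if not reads:
        raise ValueError(f"no reads in {path}")
    return reads
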