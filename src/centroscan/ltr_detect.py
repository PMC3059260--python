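"""De novo detection of candidate full-length LTR retrotransposon insertions.

The detector looks for aged direct-repeat pairs (the two LTRs of an element
diverge after insertion, so exact-repeat finders are not enough) by a
seed-chain-extend strategy: exact k-mer seeds shared by two forward-strand
positions at a plausible element-scale separation are grouped per diagonal,
chained into runs, extended by ungapped X-drop alignment, and the resulting
repeat pair is refined so the element starts with TG and ends with CA
(with a scoring bonus for the full TGATG...CATCA terminal motif). Both
strands are scanned; overlaps are resolved by detection score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import revcomp
from .seqio import GenomicSequence

_MOTIF_5P = "TGATG"
_MOTIF_3P = "CATCA"


@dataclass
class DetectionConfig:
    """Tunable bounds for LTR pair detection.

    The length defaults quote the observed survey ranges for CRM elements
    (elements ~5.1-10.2 kbp flanked by 299-1,225 bp LTRs); they are soft,
    fully user-configurable bounds, not hard biological limits.
    """

    min_ltr_len: int = 299
    max_ltr_len: int = 1225
    min_element_len: int = 5100
    max_element_len: int = 10200
    min_ltr_identity: float = 0.80
    seed_k: int = 13
    terminal_motif_5p: str = _MOTIF_5P
    terminal_motif_3p: str = _MOTIF_3P
    require_tg_ca: bool = True

    def __post_init__(self):
        if not self.min_ltr_len < self.max_ltr_len:
            raise ValueError("min_ltr_len must be < max_ltr_len")
        if not self.min_element_len < self.max_element_len:
            raise ValueError("min_element_len must be < max_element_len")
        if not 0 < self.min_ltr_identity <= 1:
            raise ValueError("min_ltr_identity must be in (0, 1]")


@dataclass
class LTRCandidate:
    """One candidate full-length insertion, in forward coordinates."""

    seq_id: str
    strand: str
    start: int
    end: int
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    ltr_identity: float
    terminal_motif_score: int
    detection_score: float
    attributes: dict = field(default_factory=dict)

    @property
    def element_length(self) -> int:
        return self.end - self.start

    @property
    def ltr_length(self) -> int:
        return self.ltr5_end - self.ltr5_start


# ungapped X-drop extension parameters
_MATCH, _MISMATCH, _XDROP = 1, -2, 20
_MAX_KMER_OCC = 50  # skip hyper-repetitive seeds
_CHAIN_GAP = 400  # max gap between chained seeds on one diagonal
_REFINE_WINDOW = 25  # boundary search radius for terminal motifs


def _motif_matches(observed: str, motif: str) -> int:
    return sum(a == b for a, b in zip(observed, motif))


def _extend(seq: str, d: int, s: int, e: int) -> tuple[int, int]:
    """Extend the repeat run [s, e) (first copy; second copy at +d) by
    ungapped X-drop in both directions; returns the extended interval."""
    n = len(seq)
    # leftwards
    best, score, best_i = 0.0, 0.0, s
    i = s - 1
    while i >= 0 and i + d < n:
        score += _MATCH if seq[i] == seq[i + d] else _MISMATCH
        if score > best:
            best, best_i = score, i
        if score < best - _XDROP:
            break
        i -= 1
    left = best_i
    # rightwards (second copy must stay in bounds)
    best, score, best_j = 0.0, 0.0, e
    j = e
    while j + d < n and j < s + d:  # copies must not overlap
        score += _MATCH if seq[j] == seq[j + d] else _MISMATCH
        if score > best:
            best, best_j = score, j + 1
        if score < best - _XDROP:
            break
        j += 1
    return left, best_j


def _ungapped_identity(seq: str, a: int, d: int, length: int) -> float:
    m = sum(seq[a + i] == seq[a + d + i] for i in range(length))
    return m / length if length else 0.0


def _refine(seq: str, d: int, a: int, b: int, cfg: DetectionConfig):
    """Refine element boundaries to maximize terminal motif match.

    The repeat pair is copies [a,b) and [a+d,b+d); the element spans
    [start, end) = [ltr5_start, ltr3_end). Returns (start, end, motif_score)
    or None if require_tg_ca cannot be satisfied.
    """
    n = len(seq)
    approx_start, approx_end = a, b + d
    starts = []
    for p in range(max(0, approx_start - _REFINE_WINDOW), min(n - 1, approx_start + _REFINE_WINDOW) + 1):
        if not cfg.require_tg_ca or seq[p:p + 2] == "TG":
            starts.append(p)
    ends = []
    for q in range(max(2, approx_end - _REFINE_WINDOW), min(n, approx_end + _REFINE_WINDOW) + 1):
        if not cfg.require_tg_ca or seq[q - 2:q] == "CA":
            ends.append(q)
    best = None
    for p in starts:
        for q in ends:
            ltr_len = (q - d) - p
            if not (cfg.min_ltr_len <= ltr_len <= cfg.max_ltr_len):
                continue
            if not (cfg.min_element_len <= q - p <= cfg.max_element_len):
                continue
            if p + ltr_len > p + d or q > n:
                continue
            motif = _motif_matches(seq[p:p + 5], cfg.terminal_motif_5p) + _motif_matches(
                seq[q - 5:q], cfg.terminal_motif_3p
            )
            ident = _ungapped_identity(seq, p, d, ltr_len)
            key = (motif, ident, -p)
            if best is None or key > best[0]:
                best = (key, p, q, motif, ident)
    if best is None:
        return None
    _, p, q, motif, ident = best
    return p, q, motif, ident


def _scan_strand(seq: str, cfg: DetectionConfig) -> list[dict]:
    n = len(seq)
    k = cfg.seed_k
    d_min = cfg.min_element_len - cfg.max_ltr_len
    d_max = cfg.max_element_len
    kmers: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        w = seq[i:i + k]
        if "N" in w:
            continue
        kmers.setdefault(w, []).append(i)

    diagonals: dict[int, list[int]] = {}
    for positions in kmers.values():
        if len(positions) < 2 or len(positions) > _MAX_KMER_OCC:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                d = positions[bi] - positions[ai]
                if d_min <= d <= d_max:
                    diagonals.setdefault(d, []).append(positions[ai])

    raw = []
    for d, starts in diagonals.items():
        starts.sort()
        run_start = prev = starts[0]
        runs = []
        for s in starts[1:]:
            if s - prev > _CHAIN_GAP:
                runs.append((run_start, prev + k))
                run_start = s
            prev = s
        runs.append((run_start, prev + k))
        for s, e in runs:
            a, b = _extend(seq, d, s, e)
            if b - a < cfg.min_ltr_len // 2:
                continue
            refined = _refine(seq, d, a, b, cfg)
            if refined is None:
                continue
            p, q, motif, ident = refined
            if ident < cfg.min_ltr_identity:
                continue
            ltr_len = (q - d) - p
            score = ident * ltr_len + 10.0 * motif
            raw.append(
                dict(start=p, end=q, ltr_len=ltr_len, d=d, identity=ident,
                     motif=motif, score=score)
            )
    return raw


def find_ltr_pairs(seq: GenomicSequence, config: DetectionConfig | None = None) -> list[LTRCandidate]:
    """Detect candidate full-length LTR retrotransposon insertions.

    Scans both strands; results are reported in forward coordinates with the
    strand set, overlapping candidates resolved by best detection score, and
    output sorted by element start. Degenerate inputs yield an empty list.
    """
    cfg = config or DetectionConfig()
    n = len(seq)
    if n < cfg.min_element_len:
        return []

    found: list[tuple[float, int, str, dict]] = []
    for strand, s in (("+", seq.residues), ("-", revcomp(seq.residues))):
        for c in _scan_strand(s, cfg):
            if strand == "-":
                start, end = n - c["end"], n - c["start"]
            else:
                start, end = c["start"], c["end"]
            found.append((c["score"], 0 if strand == "+" else 1, strand,
                          {**c, "fstart": start, "fend": end}))

    # overlap resolution: greedy by (score desc, + strand first, leftmost)
    found.sort(key=lambda t: (-t[0], t[1], t[3]["fstart"]))
    kept: list[dict] = []
    kept_meta: list[tuple[str, float]] = []
    for score, _sord, strand, c in found:
        if any(c["fstart"] < k["fend"] and k["fstart"] < c["fend"] for k in kept):
            continue
        kept.append(c)
        kept_meta.append((strand, score))

    out = []
    for (strand, score), c in zip(kept_meta, kept):
        start, end, ltr_len = c["fstart"], c["fend"], c["ltr_len"]
        # forward-coordinate convention: ltr5 is the left repeat copy,
        # ltr3 the right one, regardless of strand (so ltr5_end <= ltr3_start)
        l5s, l5e = start, start + ltr_len
        l3s, l3e = end - ltr_len, end
        out.append(
            LTRCandidate(
                seq_id=seq.id,
                strand=strand,
                start=start,
                end=end,
                ltr5_start=l5s,
                ltr5_end=l5e,
                ltr3_start=l3s,
                ltr3_end=l3e,
                ltr_identity=c["identity"],
                terminal_motif_score=c["motif"],
                detection_score=score,
            )
        )
    out.sort(key=lambda c: c.start)
    return out
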