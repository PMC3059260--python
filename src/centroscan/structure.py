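"""Internal anatomy of a candidate element: TSD, PBS, PPT, A-rich stretch,
polyprotein domain cassette, and the coding-into-3'-LTR flag.

All detectors operate in the element's own 5'->3' orientation (minus-strand
candidates are handled through coordinate reflection) and report intervals in
forward genome coordinates. Search windows are anchored on the LTRs: the
primer binding site abuts the 5' LTR, the polypurine tract abuts the 3' LTR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from . import panels
from ._util import revcomp, translate
from .ltr_detect import LTRCandidate
from .ptd import Profile
from .seqio import GenomicSequence


@dataclass
class StructureConfig:
    """Windows and thresholds for the structural detectors.

    TSD length 5 bp, PBS complementarity 12-18 nt against the tRNA-Met 3'
    terminus and a PPT of at least 4 bp reflect the observed CRM ranges; the
    30/40 bp search windows and the A-rich operationalization (>= 70% A over
    >= 20 bp) are this package's conventions.
    """

    tsd_len: int = 5
    tsd_max_mismatch: int = 0
    pbs_min_match: int = 12
    pbs_max_match: int = 18
    pbs_window: int = 30
    ppt_min_len: int = 4
    ppt_window: int = 40
    a_rich_min_len: int = 20
    a_rich_min_frac: float = 0.70
    trna_met_3prime: str = panels.TRNA_MET_3PRIME

    def __post_init__(self):
        if not self.pbs_min_match <= self.pbs_max_match <= len(self.trna_met_3prime):
            raise ValueError(
                "need pbs_min_match <= pbs_max_match <= len(trna_met_3prime)"
            )


@dataclass
class TSD:
    sequence: str
    left: tuple[int, int]
    right: tuple[int, int]
    mismatches: int


@dataclass
class PBS:
    start: int
    end: int
    sequence: str
    matched_len: int
    offset: int  # distance from the 5' LTR end


@dataclass
class PPT:
    start: int
    end: int
    sequence: str


@dataclass
class ARichRegion:
    start: int
    end: int
    a_fraction: float


@dataclass
class DomainHit:
    domain: str
    start: int  # nt, forward genome coordinates
    end: int
    frame: int
    score: float
    disruptions: int
    aa_start: int = 0
    aa_end: int = 0


class _Oriented:
    """Element-strand view of a genome: plus candidates map 1:1; minus
    candidates are reflected through the reverse complement."""

    def __init__(self, genome: GenomicSequence, cand: LTRCandidate):
        self.n = len(genome)
        self.strand = cand.strand
        if cand.strand == "+":
            self.seq = genome.residues
            self.start, self.end = cand.start, cand.end
            self.ltr5 = (cand.ltr5_start, cand.ltr5_end)
            self.ltr3 = (cand.ltr3_start, cand.ltr3_end)
        else:
            self.seq = revcomp(genome.residues)
            self.start, self.end = self.n - cand.end, self.n - cand.start
            # the forward-left repeat copy becomes the element's 3' LTR
            self.ltr5 = (self.n - cand.ltr3_end, self.n - cand.ltr3_start)
            self.ltr3 = (self.n - cand.ltr5_end, self.n - cand.ltr5_start)

    def back(self, s: int, e: int) -> tuple[int, int]:
        """Map an oriented interval back to forward genome coordinates."""
        if self.strand == "+":
            return s, e
        return self.n - e, self.n - s


def detect_tsd(
    genome: GenomicSequence, cand: LTRCandidate, cfg: StructureConfig | None = None
) -> TSD | None:
    """The target site duplication flanking the element, if present.

    Compares the ``tsd_len`` bp immediately 5' of the element with the
    ``tsd_len`` bp immediately 3' of it (on the element's strand); returns
    None when the flanks differ beyond ``tsd_max_mismatch`` or are
    unavailable because the element abuts a sequence end.
    """
    cfg = cfg or StructureConfig()
    ori = _Oriented(genome, cand)
    k = cfg.tsd_len
    if ori.start - k < 0 or ori.end + k > ori.n:
        return None  # flank unavailable
    left = ori.seq[ori.start - k:ori.start]
    right = ori.seq[ori.end:ori.end + k]
    mismatches = sum(a != b for a, b in zip(left, right))
    if mismatches > cfg.tsd_max_mismatch:
        return None
    return TSD(
        sequence=left,
        left=ori.back(ori.start - k, ori.start),
        right=ori.back(ori.end, ori.end + k),
        mismatches=mismatches,
    )


def detect_pbs(
    genome: GenomicSequence, cand: LTRCandidate, cfg: StructureConfig | None = None
) -> PBS | None:
    """Primer binding site: the longest stretch within ``pbs_window`` bp
    downstream of the 5' LTR that is the reverse complement of a 3'-terminal
    segment of the tRNA-Met sequence; reported iff >= ``pbs_min_match`` nt.
    Ties on length go to the smallest offset from the LTR."""
    cfg = cfg or StructureConfig()
    ori = _Oriented(genome, cand)
    w_start = ori.ltr5[1]
    window = ori.seq[w_start:min(w_start + cfg.pbs_window, ori.end)]
    trna = cfg.trna_met_3prime.upper()
    best: tuple[int, int] | None = None  # (length, offset)
    for off in range(0, max(0, len(window) - cfg.pbs_min_match) + 1):
        max_l = min(cfg.pbs_max_match, len(window) - off)
        for length in range(max_l, cfg.pbs_min_match - 1, -1):
            if window[off:off + length] == revcomp(trna[-length:]):
                if best is None or (length, -off) > (best[0], -best[1]):
                    best = (length, off)
                break
    if best is None:
        return None
    length, off = best
    s, e = w_start + off, w_start + off + length
    fs, fe = ori.back(s, e)
    return PBS(start=fs, end=fe, sequence=ori.seq[s:e], matched_len=length, offset=off)


def detect_ppt(
    genome: GenomicSequence, cand: LTRCandidate, cfg: StructureConfig | None = None
) -> PPT | None:
    """Polypurine tract: longest unbroken purine (A/G) run on the element
    strand within ``ppt_window`` bp immediately upstream of the 3' LTR; ties
    broken by proximity to the LTR. Reported iff >= ``ppt_min_len`` bp."""
    cfg = cfg or StructureConfig()
    ori = _Oriented(genome, cand)
    w_end = ori.ltr3[0]
    w_start = max(ori.start, w_end - cfg.ppt_window)
    window = ori.seq[w_start:w_end]
    best: tuple[int, int] | None = None  # (length, end) -- later end wins ties
    run = 0
    for i, b in enumerate(window):
        run = run + 1 if b in "AG" else 0
        if run >= cfg.ppt_min_len:
            if best is None or (run, i + 1) >= best:
                best = (run, i + 1)
    if best is None:
        return None
    length, end = best
    s, e = w_start + end - length, w_start + end
    fs, fe = ori.back(s, e)
    return PPT(start=fs, end=fe, sequence=ori.seq[s:e])


def detect_a_rich(
    genome: GenomicSequence,
    cand: LTRCandidate,
    cfg: StructureConfig | None = None,
    region_start: int | None = None,
    region_end: int | None = None,
) -> ARichRegion | None:
    """A-rich stretch in the 5' UTR: the longest window of length
    >= ``a_rich_min_len`` whose A fraction is >= ``a_rich_min_frac``.

    ``region_start``/``region_end`` bound the search in oriented coordinates
    (defaults: end of the 5' LTR or of the PBS, and start of the 3' LTR /
    first domain hit when the caller knows it).
    """
    cfg = cfg or StructureConfig()
    ori = _Oriented(genome, cand)
    if region_start is None:
        pbs = detect_pbs(genome, cand, cfg)
        region_start = pbs.end if (pbs and ori.strand == "+") else ori.ltr5[1]
        if pbs and ori.strand == "-":
            region_start = ori.n - pbs.start
    if region_end is None:
        region_end = ori.ltr3[0]
    region = ori.seq[region_start:region_end]
    n = len(region)
    if n < cfg.a_rich_min_len:
        return None
    # longest interval with mean(is_A) >= threshold, via shifted prefix sums
    thr = cfg.a_rich_min_frac
    prefix = [0.0] * (n + 1)
    for i, b in enumerate(region):
        prefix[i + 1] = prefix[i] + ((1.0 if b == "A" else 0.0) - thr)
    # candidate left endpoints: strictly decreasing prefix values
    stack = [0]
    for i in range(1, n + 1):
        if prefix[i] < prefix[stack[-1]]:
            stack.append(i)
    best_len, best_start = 0, 0
    for j in range(n, 0, -1):
        while stack and prefix[j] >= prefix[stack[-1]] - 1e-12:
            i = stack.pop()
            if j - i > best_len:
                best_len, best_start = j - i, i
    if best_len < cfg.a_rich_min_len:
        return None
    s, e = region_start + best_start, region_start + best_start + best_len
    # trim non-A edges (the longest qualifying window can carry ~30% padding)
    while e - s > cfg.a_rich_min_len and ori.seq[s] != "A":
        s += 1
    while e - s > cfg.a_rich_min_len and ori.seq[e - 1] != "A":
        e -= 1
    frac = ori.seq[s:e].count("A") / (e - s)
    fs, fe = ori.back(s, e)
    return ARichRegion(start=fs, end=fe, a_fraction=frac)


@dataclass
class DomainAnnotation:
    hits: list[DomainHit] = field(default_factory=list)
    intact_orf: bool = False
    coding_into_3ltr: bool = False
    orf_end: int | None = None  # oriented-forward nt coordinate of the ORF end


def annotate_domains(
    genome: GenomicSequence,
    cand: LTRCandidate,
    domain_profiles: Mapping[str, Profile] | None = None,
) -> DomainAnnotation:
    """Scan the internal region (plus the 3' LTR) for the GAG-PRO-RT-RH-INT
    cassette in all three forward reading frames.

    Per domain, the best-scoring window above the profile's threshold is
    reported with its stop-codon disruption count. ``intact_orf`` is set iff
    all five domains occur in cassette order in a single frame with zero
    disruptions; ``coding_into_3ltr`` iff the integrase reading frame,
    continued to its stop codon, ends past the 3' LTR start (the group A
    signature).
    """
    domain_profiles = domain_profiles or panels.default_domain_profiles()
    missing = [d for d in panels.DOMAIN_ORDER if d not in domain_profiles]
    if missing:
        raise ValueError(f"missing domain profile(s): {', '.join(missing)}")

    ori = _Oriented(genome, cand)
    region_start = ori.ltr5[1]
    region = ori.seq[region_start:ori.end]  # includes the 3' LTR
    translations = [translate(region[f:]) for f in range(3)]

    hits: list[DomainHit] = []
    for name in panels.DOMAIN_ORDER:
        prof = domain_profiles[name]
        best = None
        for frame, aa in enumerate(translations):
            score, start = prof.scan(aa)
            if start is None or score < prof.score_threshold:
                continue
            if best is None or score > best[0]:
                best = (score, frame, start)
        if best is None:
            continue
        score, frame, aa_start = best
        aa_end = aa_start + prof.n_positions
        disruptions = translations[frame][aa_start:aa_end].count("*")
        nt_start = region_start + frame + 3 * aa_start
        nt_end = region_start + frame + 3 * aa_end
        fs, fe = ori.back(nt_start, nt_end)
        hits.append(
            DomainHit(
                domain=name, start=fs, end=fe, frame=frame, score=score,
                disruptions=disruptions, aa_start=aa_start, aa_end=aa_end,
            )
        )

    ann = DomainAnnotation(hits=hits)
    by_name = {h.domain: h for h in hits}
    if len(hits) == 5:
        frames = {h.frame for h in hits}
        ordered = all(
            by_name[a].aa_end <= by_name[b].aa_start
            for a, b in zip(panels.DOMAIN_ORDER, panels.DOMAIN_ORDER[1:])
        )
        ann.intact_orf = (
            len(frames) == 1 and ordered and all(h.disruptions == 0 for h in hits)
        )

    if "INT" in by_name:
        h = by_name["INT"]
        aa = translations[h.frame]
        stop = aa.find("*", h.aa_end)
        orf_aa_end = stop if stop != -1 else len(aa)
        orf_end = region_start + h.frame + 3 * orf_aa_end
        ann.orf_end = orf_end
        ann.coding_into_3ltr = orf_end > ori.ltr3[0]
    return ann


def integrase_tail(
    genome: GenomicSequence, cand: LTRCandidate, annotation: DomainAnnotation
) -> str | None:
    """Translated region from the end of the integrase core to the reading
    frame's stop codon (the input to PTD classification)."""
    by_name = {h.domain: h for h in annotation.hits}
    if "INT" not in by_name:
        return None
    ori = _Oriented(genome, cand)
    region = ori.seq[ori.ltr5[1]:ori.end]
    h = by_name["INT"]
    aa = translate(region[h.frame:])
    stop = aa.find("*", h.aa_end)
    return aa[h.aa_end:stop if stop != -1 else len(aa)]
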