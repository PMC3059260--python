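"""Position-specific scoring profiles and integrase C-terminus classification.

The centromeric (CRM) clade of plant chromoviruses is heterogeneous at the
integrase C-terminus: downstream of the conserved GPY/F motif an element may
carry a CR motif (group A, genuinely centromeric), no putative targeting
domain at all (group B), or a type II chromodomain (group C, dispersed).
This module materializes those distinctions as log-odds profiles built from
protein alignments, classifies integrase tails into the three groups, and
screens reverse-transcriptase domains against reference panels to separate
CRM-clade elements from other chromovirus clades (Tekay, Reina, Galadriel).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_GPYF_RE = re.compile(r"GP[YF]")

#: fraction of gaps above which an alignment column is dropped
MAX_GAP_FRACTION = 0.5


class Profile:
    """A position-specific log2-odds scoring matrix over the 20 amino acids.

    ``position_scores[i][aa]`` is the log2 odds of observing ``aa`` at
    position ``i`` relative to the background. ``frequencies`` holds the
    pseudocount-smoothed per-position frequency distributions (summing to 1),
    used for information-content computation.
    """

    def __init__(
        self,
        name: str,
        position_scores: Sequence[Mapping[str, float]],
        frequencies: Sequence[Mapping[str, float]],
        background: Mapping[str, float],
        pseudocount: float,
        score_threshold: float,
    ):
        self.name = name
        self.position_scores = [dict(p) for p in position_scores]
        self.frequencies = [dict(p) for p in frequencies]
        self.background = dict(background)
        self.pseudocount = pseudocount
        self.score_threshold = score_threshold
        for pos in self.position_scores:
            for a, s in pos.items():
                if not math.isfinite(s):
                    raise ValueError(f"non-finite score for {a} in profile {name}")

    @property
    def n_positions(self) -> int:
        return len(self.position_scores)

    def __len__(self) -> int:
        return self.n_positions

    @cached_property
    def _matrix(self) -> np.ndarray:
        """(n_positions, 21) score matrix; column 20 scores unknown residues
        ('X', '*', gaps) with the per-position minimum."""
        m = np.empty((self.n_positions, 21))
        for i, pos in enumerate(self.position_scores):
            row = [pos[a] for a in AMINO_ACIDS]
            m[i, :20] = row
            m[i, 20] = min(row)
        return m

    def _encode(self, seq: str) -> np.ndarray:
        return np.fromiter((_AA_INDEX.get(c, 20) for c in seq.upper()), dtype=np.intp, count=len(seq))

    def window_score(self, window: str) -> float:
        """Score a window of exactly ``n_positions`` residues."""
        if len(window) != self.n_positions:
            raise ValueError(f"window length {len(window)} != profile length {self.n_positions}")
        codes = self._encode(window)
        return float(self._matrix[np.arange(self.n_positions), codes].sum())

    def scan(self, seq: str) -> tuple[float, int | None]:
        """Best-scoring window over ``seq``; (-inf, None) if seq is too short."""
        n = self.n_positions
        if len(seq) < n:
            return (-math.inf, None)
        codes = self._encode(seq)
        k = len(seq) - n + 1
        scores = np.zeros(k)
        m = self._matrix
        for j in range(n):
            scores += m[j, codes[j:j + k]]
        best = int(np.argmax(scores))
        return (float(scores[best]), best)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "name": self.name,
                    "position_scores": self.position_scores,
                    "frequencies": self.frequencies,
                    "background": self.background,
                    "pseudocount": self.pseudocount,
                    "score_threshold": self.score_threshold,
                },
                fh,
            )

    @classmethod
    def load(cls, path: str | Path) -> "Profile":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def build_profile(
    alignment: Sequence[str],
    pseudocount: float = 0.5,
    background: Mapping[str, float] | None = None,
    name: str = "profile",
) -> Profile:
    """Build a log2-odds profile from an aligned set of protein sequences.

    Per kept column, frequencies are ``(count + pseudocount*bg) / (n + pseudocount)``
    where ``n`` is the number of non-gap residues in the column; scores are
    ``log2(freq / bg)``. Columns with more than 50% gaps are dropped. The
    score threshold is calibrated from the training members themselves as
    (mean member score - 2 SD).
    """
    seqs = [s.upper() for s in alignment]
    if len(seqs) < 2:
        raise ValueError("profile construction requires at least 2 sequences")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("ragged alignment: sequences differ in aligned length")
    if not pseudocount > 0:
        raise ValueError("pseudocount must be > 0")
    if background is None:
        background = {a: 1.0 / 20.0 for a in AMINO_ACIDS}

    kept_cols = []
    for c in range(width):
        col = [s[c] for s in seqs]
        gap_frac = sum(r not in _AA_INDEX for r in col) / len(col)
        if gap_frac <= MAX_GAP_FRACTION:
            kept_cols.append(c)

    position_scores: list[dict[str, float]] = []
    frequencies: list[dict[str, float]] = []
    for c in kept_cols:
        col = [s[c] for s in seqs if s[c] in _AA_INDEX]
        n = len(col)
        freqs = {}
        scores = {}
        for a in AMINO_ACIDS:
            f = (col.count(a) + pseudocount * background[a]) / (n + pseudocount)
            freqs[a] = f
            scores[a] = math.log2(f / background[a])
        frequencies.append(freqs)
        position_scores.append(scores)

    member_scores = []
    for s in seqs:
        total = 0.0
        for i, c in enumerate(kept_cols):
            if s[c] in _AA_INDEX:
                total += position_scores[i][s[c]]
        member_scores.append(total)
    mean = float(np.mean(member_scores))
    sd = float(np.std(member_scores))
    threshold = mean - 2.0 * sd

    return Profile(
        name=name,
        position_scores=position_scores,
        frequencies=frequencies,
        background=background,
        pseudocount=pseudocount,
        score_threshold=threshold,
    )


def profile_information(profile: Profile) -> tuple[list[float], float]:
    """Per-position information content in bits (log2(20) - Shannon entropy)
    plus the total, as displayed by sequence-logo plots."""
    max_bits = math.log2(20)
    bits = []
    for freqs in profile.frequencies:
        entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        bits.append(max_bits - entropy)
    return bits, float(sum(bits))


def locate_gpyf(integrase_tail: str) -> int | None:
    """Index of the first GPY or GPF motif (the integrase GPY/F anchor)."""
    if not integrase_tail:
        raise ValueError("empty integrase tail")
    m = _GPYF_RE.search(integrase_tail.upper())
    return m.start() if m else None


@dataclass
class PTDCall:
    """Classification of one integrase C-terminus.

    group A <-> CR motif; group B <-> no putative targeting domain;
    group C <-> type II chromodomain.
    """

    ptd_type: str  # CR_MOTIF | CHROMODOMAIN_II | NONE
    group: str  # A | B | C
    cr_score: float
    chd2_score: float
    gpyf_position: int | None
    tail_length_aa: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        expected = {"CR_MOTIF": "A", "NONE": "B", "CHROMODOMAIN_II": "C"}
        if expected.get(self.ptd_type) != self.group:
            raise ValueError(f"inconsistent ptd_type {self.ptd_type} / group {self.group}")


def classify_ptd(
    integrase_tail: str,
    cr_profile: Profile,
    chd2_profile: Profile,
    none_max_tail_aa: int = 40,
) -> PTDCall:
    """Classify the integrase tail downstream of the GPY/F anchor.

    The tail is the translated region from the end of the integrase core to
    the reading frame's stop codon. The region after GPY/F is scanned with
    both the CR-motif and type II chromodomain profiles; a hit above a
    profile's own threshold (and above the competing profile's score) gives
    group A or C, while the absence of any hit over a short tail gives
    group B. A long tail with no hit is still called group B, with a
    low-confidence warning.
    """
    warnings: list[str] = []
    gpyf = locate_gpyf(integrase_tail)
    if gpyf is None:
        warnings.append("no GPY/F anchor found; classified on the whole tail")
        region = integrase_tail
    else:
        region = integrase_tail[gpyf + 3:]
    tail_len = len(region)

    cr_score, _ = cr_profile.scan(region)
    chd2_score, _ = chd2_profile.scan(region)
    cr_hit = cr_score >= cr_profile.score_threshold
    chd2_hit = chd2_score >= chd2_profile.score_threshold

    if cr_hit and (not chd2_hit or cr_score >= chd2_score):
        ptd_type, group = "CR_MOTIF", "A"
    elif chd2_hit:
        ptd_type, group = "CHROMODOMAIN_II", "C"
    else:
        ptd_type, group = "NONE", "B"
        if tail_len > none_max_tail_aa:
            warnings.append(
                f"tail of {tail_len} aa without a PTD hit exceeds the "
                f"{none_max_tail_aa} aa bound for a confident group B call"
            )

    return PTDCall(
        ptd_type=ptd_type,
        group=group,
        cr_score=cr_score if math.isfinite(cr_score) else -math.inf,
        chd2_score=chd2_score if math.isfinite(chd2_score) else -math.inf,
        gpyf_position=gpyf,
        tail_length_aa=tail_len,
        warnings=warnings,
    )


def _clade_aligner():
    from Bio.Align import PairwiseAligner, substitution_matrices

    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def assign_clade(
    rt_domain: str,
    panels: Mapping[str, Sequence[tuple[str, str]]],
) -> tuple[str, float]:
    """Best-hit clade screen of an RT domain against reference panels.

    ``panels`` maps a clade name (e.g. CRM, Tekay) to reference RT sequences
    as (name, sequence) pairs. Returns the clade of the best local-alignment
    score (BLOSUM62) and the margin over the best competing clade. Ties are
    broken alphabetically by clade name, so the result does not depend on
    panel ordering or duplicated entries.
    """
    rt = re.sub(r"[^A-Z]", "", rt_domain.upper().replace("*", ""))
    if not rt:
        raise ValueError("empty RT domain")
    if not panels:
        raise ValueError("no reference panels supplied")
    aligner = _clade_aligner()
    best_per_clade: dict[str, float] = {}
    for clade in panels:
        scores = [float(aligner.score(rt, seq)) for _name, seq in panels[clade]]
        if scores:
            best_per_clade[clade] = max(scores)
    ordered = sorted(best_per_clade.items(), key=lambda kv: (-kv[1], kv[0]))
    best_clade, best_score = ordered[0]
    margin = best_score - ordered[1][1] if len(ordered) > 1 else math.inf
    return best_clade, margin
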