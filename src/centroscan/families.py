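"""Family assignment by LTR similarity and insertion dating from 5'/3' LTR
divergence.

Retrotransposon families follow the survey rule: elements from different
species, elements that cannot be aligned over most of their LTR length, and
elements sharing less than 70% LTR identity form distinct families.
Insertion ages use the LTR pair as a molecular clock: the two LTRs are
identical at insertion, so their corrected divergence K divided by twice the
substitution rate estimates the time since insertion, T = K / (2r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from Bio.Align import PairwiseAligner

from ._util import PURINES, PYRIMIDINES, is_transition

#: default substitution rate, substitutions/site/year (the rate convention of
#: the LTR-dating literature for plant nuclear sequences); configurable.
DEFAULT_RATE = 1.3e-8


def _aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -5
    a.extend_gap_score = -1
    return a


_ALIGNER = _aligner()


def _align_pair(a: str, b: str):
    """Best global alignment; returns the two gapped row strings."""
    aln = _ALIGNER.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def ltr_identity(ltr_a: str, ltr_b: str) -> tuple[float, float]:
    """Global-alignment percent identity between two LTR sequences.

    Returns (identity %, coverage), where identity = matches / alignment
    columns x 100 and coverage = columns where both sequences are aligned
    (non-gap) / max(sequence length). Scoring: match +1, mismatch -1, gap
    open -5, gap extend -1.
    """
    if not ltr_a or not ltr_b:
        raise ValueError("empty LTR sequence")
    row_a, row_b = _align_pair(ltr_a, ltr_b)
    columns = len(row_a)
    matches = sum(x == y and x != "-" for x, y in zip(row_a, row_b))
    aligned_cols = sum(x != "-" and y != "-" for x, y in zip(row_a, row_b))
    identity = matches / columns * 100.0
    coverage = aligned_cols / max(len(ltr_a), len(ltr_b))
    return identity, coverage


@dataclass
class Family:
    family_id: str
    species: str
    members: list[str]
    representative: str  # longest member


@dataclass
class FamilyInput:
    """What assign_families needs to know about one element."""

    element_id: str
    species: str
    ltr5_seq: str | None
    length: int = 0


def assign_families(
    elements: Sequence[FamilyInput],
    threshold_pct: float = 70.0,
    coverage_min: float = 0.8,
) -> tuple[list[Family], list[str]]:
    """Partition elements into families by the LTR-similarity rule.

    Elements are partitioned by species first; within a species,
    single-linkage clustering joins pairs with LTR identity >=
    ``threshold_pct`` AND alignment coverage >= ``coverage_min``. Family ids
    are deterministic (species label + ordinal by first-seen member).
    Elements lacking an LTR sequence are excluded; their ids are returned as
    warnings alongside the family list.
    """
    warnings = []
    usable = []
    for e in elements:
        if not e.ltr5_seq:
            warnings.append(f"element {e.element_id} lacks an LTR sequence; excluded")
        else:
            usable.append(e)

    parent = {e.element_id: e.element_id for e in usable}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    by_species: dict[str, list[FamilyInput]] = {}
    for e in usable:
        by_species.setdefault(e.species, []).append(e)

    for species_elements in by_species.values():
        for i in range(len(species_elements)):
            for j in range(i + 1, len(species_elements)):
                a, b = species_elements[i], species_elements[j]
                ident, cov = ltr_identity(a.ltr5_seq, b.ltr5_seq)
                if ident >= threshold_pct and cov >= coverage_min:
                    union(a.element_id, b.element_id)

    clusters: dict[str, list[FamilyInput]] = {}
    order: list[str] = []
    for e in usable:  # input order fixes the ordinal, not cluster content
        root = find(e.element_id)
        if root not in clusters:
            clusters[root] = []
            order.append(root)
        clusters[root].append(e)

    species_counter: dict[str, int] = {}
    families = []
    for root in order:
        members = clusters[root]
        species = members[0].species
        species_counter[species] = species_counter.get(species, 0) + 1
        label = species.replace(" ", "_") if species else "unknown"
        rep = max(members, key=lambda e: (e.length, e.element_id))
        families.append(
            Family(
                family_id=f"{label}_fam{species_counter[species]}",
                species=species,
                members=[m.element_id for m in members],
                representative=rep.element_id,
            )
        )
    return families, warnings


@dataclass
class AgeEstimate:
    """Insertion age from 5'/3' LTR divergence, T = K / (2r)."""

    p_distance: float
    transitions: float  # P, per comparable site
    transversions: float  # Q, per comparable site
    k: float  # corrected substitutions/site
    rate: float
    age_years: float
    sites_compared: int
    correction: str


def estimate_age(
    ltr5: str,
    ltr3: str,
    rate: float = DEFAULT_RATE,
    correction: str = "K2P",
) -> AgeEstimate:
    """Date an insertion from the divergence of its two LTRs.

    The LTRs are globally aligned; transition (P) and transversion (Q)
    fractions are counted over ungapped columns. With the Kimura
    two-parameter correction, K = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q); with
    ``correction="raw"``, K = P + Q. The age is T = K / (2 rate) years.
    Raises on saturated divergence (correction undefined) and on
    unalignable pairs (coverage < 0.5).
    """
    if rate <= 0:
        raise ValueError("substitution rate must be > 0")
    if correction not in ("K2P", "raw"):
        raise ValueError(f"unknown correction {correction!r}")
    row_a, row_b = _align_pair(ltr5, ltr3)
    aligned_cols = sum(x != "-" and y != "-" for x, y in zip(row_a, row_b))
    if aligned_cols / max(len(ltr5), len(ltr3)) < 0.5:
        raise ValueError("LTRs not alignable: coverage < 0.5")
    ti = tv = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-" or x == y:
            continue
        if is_transition(x, y):
            ti += 1
        elif (x in PURINES or x in PYRIMIDINES) and (y in PURINES or y in PYRIMIDINES):
            tv += 1
    p = ti / aligned_cols
    q = tv / aligned_cols
    if correction == "K2P":
        if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
            raise ValueError("saturation: correction undefined")
        k = -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)
        k += 0.0  # normalize IEEE -0.0 for the identical-LTR case
    else:
        k = p + q
    return AgeEstimate(
        p_distance=p + q,
        transitions=p,
        transversions=q,
        k=k,
        rate=rate,
        age_years=k / (2 * rate),
        sites_compared=aligned_cols,
        correction=correction,
    )
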