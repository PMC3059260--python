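"""Synthetic-data generator: genomes with implanted, structurally faithful,
group-labeled CRM-like retrotransposon insertions plus ground-truth manifests.

Each synthetic element follows the canonical CRM architecture: a 5' LTR with
TGATG...CATCA termini, a primer binding site complementary to a 12-18 nt
suffix of the tRNA-Met 3' terminus, an optional A-rich stretch in the 5' UTR,
a single ORF encoding GAG-PRO-RT-RH-INT, a group-specific integrase tail
downstream of the GPY/F anchor (CR motif for group A with the reading frame
running into the 3' LTR; nothing for group B; a type II chromodomain for
group C ending before the 3' LTR), a 4-13 bp polypurine tract abutting the
3' LTR, and a 3' LTR born identical to the 5' one. Aging mutates the two
LTRs independently (transition-biased substitutions at rate x age expected
divergence per copy); integration duplicates 5 bp of host sequence on both
flanks. A manifest records the ground truth of every feature, which is the
acceptance surface for all recovery tests.
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass, field, replace
from typing import Sequence

from . import panels
from ._util import GENETIC_CODE, revcomp
from .seqio import AnnotationRecord, GenomicSequence

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

#: residues of group A coding that run into the 3' LTR before the stop codon
EXT_AA = 15

#: default per-group probability of an A-rich 5' UTR stretch (common in
#: group A, absent from most group B/C members)
A_RICH_PROB_BY_GROUP = {"A": 0.8, "B": 0.1, "C": 0.1}

#: read-length weights for synthetic small-RNA libraries (mode at 24 nt)
READ_LENGTH_WEIGHTS = {18: 3, 19: 4, 20: 6, 21: 8, 22: 10, 23: 13,
                       24: 30, 25: 12, 26: 8, 27: 6}

#: spacing used by generate_benchmark between implants. Family members carry
#: near-identical LTRs, so a cross-element LTR pair at a separation inside
#: the detector's element-length range would be an irreducible false direct
#: repeat; a gap above max_element_len keeps every cross-element pair out of
#: that range.
BENCHMARK_SPACING = 9500


@dataclass
class SimConfig:
    """Generator settings; the defaults are the observed CRM survey ranges."""

    ltr_len_range: tuple[int, int] = (299, 1225)
    element_len_range: tuple[int, int] = (5100, 10200)
    tsd_len: int = 5
    pbs_len_range: tuple[int, int] = (12, 18)
    ppt_len_range: tuple[int, int] = (4, 13)
    a_rich_prob: float | None = None  # None -> per-group defaults
    group: str | dict = field(default_factory=lambda: {"A": 9, "B": 8, "C": 8})
    age_years: float | tuple[float, float] = (0.0, 3.0e6)
    subst_rate: float = 1.3e-8
    ti_tv_ratio: float = 2.0
    internal_divergence: float = 0.0
    host_len: int | None = None
    n_elements: int = 25
    trna_met_3prime: str = panels.TRNA_MET_3PRIME

    def __post_init__(self):
        for lo, hi in (self.ltr_len_range, self.element_len_range,
                       self.pbs_len_range, self.ppt_len_range):
            if lo > hi:
                raise ValueError("invalid range in SimConfig")
        if isinstance(self.group, str) and self.group not in "ABC":
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class ElementTruth:
    """Ground truth for one implanted element (absolute coordinates after
    implantation; element-relative before)."""

    element_id: str
    group: str
    family_id: str
    start: int
    end: int
    strand: str = "+"
    ltr5: tuple[int, int] = (0, 0)
    ltr3: tuple[int, int] = (0, 0)
    tsd_seq: str = ""
    tsd_left: tuple[int, int] | None = None
    tsd_right: tuple[int, int] | None = None
    pbs: tuple[int, int] = (0, 0)
    pbs_seq: str = ""
    ppt: tuple[int, int] = (0, 0)
    ppt_seq: str = ""
    a_rich: tuple[int, int] | None = None
    age_years: float = 0.0
    ltr5_subs: int = 0
    ltr3_subs: int = 0
    orf_start: int = 0
    domains: dict = field(default_factory=dict)  # name -> (start, end) nt
    ptd_interval: tuple[int, int] | None = None
    clade: str = "CRM"
    proteins: dict = field(default_factory=dict)

    def shifted(self, offset: int) -> "ElementTruth":
        t = copy.deepcopy(self)

        def mv(iv):
            return None if iv is None else (iv[0] + offset, iv[1] + offset)

        t.start += offset
        t.end += offset
        t.ltr5 = mv(t.ltr5)
        t.ltr3 = mv(t.ltr3)
        t.pbs = mv(t.pbs)
        t.ppt = mv(t.ppt)
        t.a_rich = mv(t.a_rich)
        t.tsd_left = mv(t.tsd_left)
        t.tsd_right = mv(t.tsd_right)
        t.orf_start += offset
        t.domains = {k: mv(v) for k, v in t.domains.items()}
        t.ptd_interval = mv(t.ptd_interval)
        return t


@dataclass
class SimManifest:
    """Ground truth for a simulated genome."""

    genome_id: str
    host_len: int
    tsd_len: int
    elements: list[ElementTruth] = field(default_factory=list)

    def to_records(self) -> list[AnnotationRecord]:
        out = []
        for t in self.elements:
            eid = t.element_id
            out.append(AnnotationRecord(
                self.genome_id, "element", t.start, t.end, t.strand,
                feature_id=eid,
                attributes={"group": t.group, "family": t.family_id,
                            "age_years": f"{t.age_years:.0f}", "clade": t.clade},
            ))
            for kind, iv in (("LTR5", t.ltr5), ("LTR3", t.ltr3),
                             ("PBS", t.pbs), ("PPT", t.ppt), ("A_rich", t.a_rich)):
                if iv is not None:
                    out.append(AnnotationRecord(
                        self.genome_id, kind, iv[0], iv[1], t.strand,
                        feature_id=f"{eid}_{kind}", parent=eid))
            for name, iv in t.domains.items():
                out.append(AnnotationRecord(
                    self.genome_id, "domain", iv[0], iv[1], t.strand,
                    feature_id=f"{eid}_{name}", parent=eid,
                    attributes={"domain": name}))
        return out

    def to_rows(self) -> list[dict]:
        return [
            {
                "element_id": t.element_id, "seq_id": self.genome_id,
                "family": t.family_id, "group": t.group, "clade": t.clade,
                "start": t.start, "end": t.end,
                "element_length": t.end - t.start,
                "ltr_length": t.ltr5[1] - t.ltr5[0],
                "tsd": t.tsd_seq, "pbs_length": t.pbs[1] - t.pbs[0],
                "ppt_length": t.ppt[1] - t.ppt[0],
                "age_my": t.age_years / 1e6,
            }
            for t in self.elements
        ]


def _filler(rng: random.Random, n: int) -> str:
    """Random host-like DNA with a cap on accidental A-rich 20-mers."""
    out = [rng.choice(_BASES) for _ in range(n)]
    if n >= 20:
        acount = sum(1 for b in out[:20] if b == "A")
        i = 0
        while True:
            if acount >= 14:
                for j in range(i, i + 20):
                    if out[j] == "A":
                        out[j] = rng.choice("CGT")
                        acount -= 1
                        break
                continue
            if i + 20 >= n:
                break
            acount += (out[i + 20] == "A") - (out[i] == "A")
            i += 1
    return "".join(out)


def _capped_filler(rng: random.Random, n: int, max_purine_run: int) -> str:
    """Random DNA whose purine runs never exceed ``max_purine_run``; starts
    and ends with a pyrimidine."""
    out = []
    run = 0
    for i in range(n):
        if i == 0 or i == n - 1 or run >= max_purine_run:
            b = rng.choice("CT")
        else:
            b = rng.choice(_BASES)
        run = run + 1 if b in "AG" else 0
        out.append(b)
    return "".join(out)


def _make_ltr(rng: random.Random, length: int) -> str:
    """An LTR with TGATG...CATCA termini, its interior arranged so a reading
    frame entering one base after the LTR start stays open for EXT_AA codons
    and then terminates (shared by all groups; only group A uses it)."""
    if length < 5 + 3 * (EXT_AA + 1) + 1 + 5:
        raise ValueError(f"LTR length {length} too short")
    inner = list(_filler(rng, length - 10))
    ltr = list("TGATG" + "".join(inner) + "CATCA")
    for k in range(EXT_AA):
        codon = "".join(ltr[1 + 3 * k:4 + 3 * k])
        if GENETIC_CODE.get(codon) == "*":
            ltr[1 + 3 * k] = "C"
    ltr[1 + 3 * EXT_AA:4 + 3 * EXT_AA] = list("TAA")
    return "".join(ltr)


def _draw(rng: random.Random, value):
    if isinstance(value, (tuple, list)):
        return rng.uniform(value[0], value[1])
    return float(value)


def _pick_group(cfg: SimConfig, rng: random.Random) -> str:
    if isinstance(cfg.group, str):
        return cfg.group
    groups = sorted(cfg.group)
    weights = [cfg.group[g] for g in groups]
    return rng.choices(groups, weights=weights)[0]


def generate_element(
    cfg: SimConfig,
    rng: random.Random,
    group: str | None = None,
    rt_protein: str | None = None,
    clade: str = "CRM",
    apply_age: bool = True,
) -> tuple[str, ElementTruth]:
    """Assemble one pristine element and optionally age its LTR pair.

    Returns the element sequence (without TSDs; implantation adds those from
    the host) and its ground-truth entry with element-relative coordinates.
    ``rt_protein`` substitutes the RT domain (used for non-CRM decoys).
    """
    group = group or _pick_group(cfg, rng)
    L = rng.randint(*cfg.ltr_len_range)
    p = rng.randint(*cfg.pbs_len_range)
    p2 = rng.randint(*cfg.ppt_len_range)
    age = _draw(rng, cfg.age_years) if apply_age else 0.0
    a_prob = cfg.a_rich_prob if cfg.a_rich_prob is not None else A_RICH_PROB_BY_GROUP[group]
    has_a_rich = rng.random() < a_prob

    proteins = dict(panels.CASSETTE_PROTEINS)
    dna = dict(panels.CASSETTE_DNA)
    if rt_protein is not None:
        proteins["RT"] = rt_protein
        dna["RT"] = panels.reverse_translate(rt_protein, rng)

    ltr = _make_ltr(rng, L)
    trna = cfg.trna_met_3prime.upper()
    pbs_seq = revcomp(trna[-p:])
    if p < len(trna):
        blocked = revcomp(trna[-(p + 1):])[-1]  # base that would extend the match
        guard = rng.choice([b for b in _BASES if b != blocked])
    else:
        guard = rng.choice(_BASES)

    cassette_dna = "".join(dna[d] for d in panels.DOMAIN_ORDER)
    orf_core = "ATG" + cassette_dna + dna["ANCHOR"]

    if group == "A":
        tail_dna = dna["CR"]
        m = next(x for x in (2, 3, 4) if (p2 + x) % 3 == 2)
        j = max(2, -(-(42 - p2 - m) // 3))
        ppt_region = "C" * (3 * j) + "".join(rng.choice("AG") for _ in range(p2)) + "C" * m
        orf_internal = orf_core + tail_dna + ppt_region
        suffix = ""  # coding runs straight into the 3' LTR
        ppt_from_ltr = (m + p2, m)  # distances back from the LTR start
    else:
        tail_dna = dna["TAIL_B"] if group == "B" else dna["CHD2"]
        orf_internal = orf_core + tail_dna + "TAA"
        g = rng.randint(2, 6)
        prefix_len = 40 - p2 - g
        window = (
            _capped_filler(rng, prefix_len, min(3, p2 - 1))
            + "".join(rng.choice("AG") for _ in range(p2))
            + "".join(rng.choice("CT") for _ in range(g))
        )
        suffix = window
        ppt_from_ltr = (g + p2, g)

    target_len = rng.randint(*cfg.element_len_range)
    fixed = L + p + 1 + len(orf_internal) + len(suffix) + L
    a_len = rng.randint(22, 36) if has_a_rich else 0
    u1_min = a_len + 30 if has_a_rich else 20
    slack = target_len - fixed
    if group == "A":
        u1 = max(u1_min, slack)
    else:
        u2_min = 6
        if slack < u1_min + u2_min:
            u1, u2 = u1_min, u2_min
        else:
            u1 = u1_min + rng.randint(0, slack - u1_min - u2_min)
            u2 = slack - u1
        suffix = _filler(rng, u2) + suffix
    if fixed + u1 + (0 if group == "A" else u2) > cfg.element_len_range[1] + 600:
        raise ValueError("infeasible length combination for SimConfig")

    utr5 = _filler(rng, u1)
    a_iv = None
    if has_a_rich:
        stretch = "".join("A" if rng.random() < 0.85 else rng.choice("CGT") for _ in range(a_len))
        while stretch.count("A") / a_len < 0.75:
            stretch = "".join("A" if rng.random() < 0.85 else rng.choice("CGT") for _ in range(a_len))
        off = rng.randint(5, u1 - a_len - 5)
        utr5 = utr5[:off] + stretch + utr5[off + a_len:]
        a_iv = (L + p + 1 + off, L + p + 1 + off + a_len)

    element = ltr + pbs_seq + guard + utr5 + orf_internal + suffix + ltr
    E = len(element)
    orf_start = L + p + 1 + u1
    ltr3_start = E - L

    pos = orf_start + 3
    domains = {}
    for d in panels.DOMAIN_ORDER:
        domains[d] = (pos, pos + len(dna[d]))
        pos += len(dna[d])
    anchor_end = pos + len(dna["ANCHOR"])
    if group == "A":
        ptd_iv = (anchor_end, ltr3_start + 1 + 3 * (EXT_AA + 1))
    elif group == "C":
        ptd_iv = (anchor_end, anchor_end + len(tail_dna))
    else:
        ptd_iv = None

    truth = ElementTruth(
        element_id="", group=group, family_id="", start=0, end=E,
        ltr5=(0, L), ltr3=(ltr3_start, E),
        pbs=(L, L + p), pbs_seq=pbs_seq,
        ppt=(ltr3_start - ppt_from_ltr[0], ltr3_start - ppt_from_ltr[1]),
        ppt_seq=element[ltr3_start - ppt_from_ltr[0]:ltr3_start - ppt_from_ltr[1]],
        a_rich=a_iv, age_years=age, orf_start=orf_start,
        domains=domains, ptd_interval=ptd_iv, clade=clade,
        proteins={**{d: proteins[d] for d in panels.DOMAIN_ORDER},
                  "TAIL": {"A": panels.CR_CONSENSUS, "B": panels.TAIL_B_CONSENSUS,
                           "C": panels.CHD2_CONSENSUS}[group]},
    )

    if cfg.internal_divergence > 0:
        orf_end = min(orf_start + len(orf_internal), ltr3_start)
        element = _mutate_orf(element, orf_start, orf_end, cfg.internal_divergence, rng)
    if apply_age and age > 0:
        element, truth = age_element(element, truth, age, cfg, rng)
    else:
        truth.age_years = age
    return element, truth


def _mutate_orf(element: str, start: int, end: int, rate: float, rng: random.Random) -> str:
    """Codon-aware substitution of the internal ORF region (stop-creating
    substitutions are vetoed, emulating purifying selection on the cassette)."""
    seq = list(element)
    for i in range(start, end):
        if rng.random() >= rate:
            continue
        new = rng.choice([b for b in _BASES if b != seq[i]])
        c0 = start + 3 * ((i - start) // 3)
        codon = seq[c0:c0 + 3]
        codon[i - c0] = new
        if GENETIC_CODE.get("".join(codon)) == "*":
            continue
        seq[i] = new
    return "".join(seq)


def _mutate_interval(seq: list, start: int, end: int, prob: float,
                     ti_tv_ratio: float, rng: random.Random) -> int:
    p_ti = ti_tv_ratio / (ti_tv_ratio + 1.0)
    count = 0
    for i in range(start, end):
        if rng.random() < prob:
            b = seq[i]
            if b not in _TRANSITION:
                continue
            seq[i] = _TRANSITION[b] if rng.random() < p_ti else rng.choice(_TRANSVERSIONS[b])
            count += 1
    return count


def age_element(
    element: str, truth: ElementTruth, age: float, cfg: SimConfig, rng: random.Random
) -> tuple[str, ElementTruth]:
    """Mutate the two LTR copies independently at ``subst_rate x age``
    expected substitutions per site each (transition-biased)."""
    seq = list(element)
    prob = cfg.subst_rate * age
    n5 = _mutate_interval(seq, *truth.ltr5, prob, cfg.ti_tv_ratio, rng)
    n3 = _mutate_interval(seq, *truth.ltr3, prob, cfg.ti_tv_ratio, rng)
    truth = replace(truth, age_years=age, ltr5_subs=n5, ltr3_subs=n3)
    return "".join(seq), truth


def implant_elements(
    host_len: int,
    elements: Sequence[tuple[str, ElementTruth]],
    tsd_len: int = 5,
    rng: random.Random | None = None,
    min_gap: int = 1000,
    genome_id: str = "synth_genome",
    species: str = "Hostia synthetica",
) -> tuple[GenomicSequence, SimManifest]:
    """Implant elements into an i.i.d.-random host with target-site
    duplications: at each insertion site the ``tsd_len`` bp 3' of the cut are
    duplicated to flank the element. Sites are non-overlapping with at least
    ``min_gap`` bp between them; manifest coordinates are final."""
    rng = rng or random.Random(0)
    n = len(elements)
    if host_len < (n + 1) * min_gap + n * tsd_len:
        raise ValueError("host too small for the requested elements and spacing")
    host = "".join(rng.choice(_BASES) for _ in range(host_len))

    extras = host_len - (n + 1) * min_gap
    weights = [rng.random() + 1e-9 for _ in range(n + 1)]
    wsum = sum(weights)
    gaps = [min_gap + int(extras * w / wsum) for w in weights]
    sites = []
    x = 0
    for i in range(n):
        x += gaps[i]
        sites.append(x)

    pieces = []
    manifest = SimManifest(genome_id=genome_id, host_len=host_len, tsd_len=tsd_len)
    pos = 0
    out_len = 0
    for i, (eseq, truth) in enumerate(elements):
        x = sites[i]
        chunk = host[pos:x]
        pieces.append(chunk)
        out_len += len(chunk)
        tsd = host[x:x + tsd_len]
        pieces.append(tsd)
        left_iv = (out_len, out_len + tsd_len)
        out_len += tsd_len
        t = truth.shifted(out_len)
        t.element_id = truth.element_id or f"elem{i + 1:03d}"
        t.tsd_seq = tsd
        t.tsd_left = left_iv
        pieces.append(eseq)
        out_len += len(eseq)
        t.tsd_right = (out_len, out_len + tsd_len)
        manifest.elements.append(t)
        pos = x
    pieces.append(host[pos:])
    genome = GenomicSequence(
        id=genome_id, residues="".join(pieces), species=species,
        description=f"synthetic genome, {n} implanted elements",
    )
    return genome, manifest


@dataclass
class Benchmark:
    genome: GenomicSequence
    manifest: SimManifest
    reads: list[tuple[str, str]]
    library_total: int


def generate_benchmark(
    cfg: SimConfig | None = None,
    seed: int = 0,
    include_decoy: bool = True,
    n_element_reads: int = 500,
    n_background_reads: int = 700,
) -> Benchmark:
    """End-to-end fixture: a genome with a group A/B/C element mixture in
    families, one non-CRM decoy (chromodomain-II tail, Tekay-like RT) for
    the clade screen, and a synthetic small-RNA library with the
    characteristic 24 nt length mode."""
    cfg = cfg or SimConfig()
    rng = random.Random(seed)

    if isinstance(cfg.group, str):
        labels = [cfg.group] * cfg.n_elements
    else:
        groups = sorted(cfg.group)
        weights = [cfg.group[g] for g in groups]
        total_w = sum(weights)
        counts = [int(cfg.n_elements * w / total_w) for w in weights]
        i = 0
        while sum(counts) < cfg.n_elements:
            counts[i % len(counts)] += 1
            i += 1
        labels = [g for g, c in zip(groups, counts) for _ in range(c)]

    elements: list[tuple[str, ElementTruth]] = []
    fam_no = 0
    idx = 0
    while idx < len(labels):
        group = labels[idx]
        same_run = 1
        while idx + same_run < len(labels) and labels[idx + same_run] == group:
            same_run += 1
        size = min(rng.choice([1, 1, 2, 3]), same_run)
        fam_no += 1
        fam_id = f"fam{fam_no:02d}"
        template_seq, template_truth = generate_element(
            cfg, rng, group=group, apply_age=False
        )
        for _ in range(size):
            age = _draw(rng, cfg.age_years)
            eseq, truth = age_element(template_seq, template_truth, age, cfg, rng)
            truth.family_id = fam_id
            elements.append((eseq, truth))
            idx += 1

    if include_decoy:
        fam_no += 1
        tekay_rt = panels.rt_reference_panels()["Tekay"][0][1]
        dseq, dtruth = generate_element(
            cfg, rng, group="C", rt_protein=tekay_rt, clade="Tekay"
        )
        dtruth.family_id = f"fam{fam_no:02d}"
        elements.append((dseq, dtruth))

    rng.shuffle(elements)
    # the host carries only the inter-element gaps; elements add their own
    # length on insertion
    host_len = cfg.host_len or (
        (len(elements) + 1) * BENCHMARK_SPACING
        + len(elements) * cfg.tsd_len + 2000
    )
    genome, manifest = implant_elements(
        host_len, elements, tsd_len=cfg.tsd_len, rng=rng,
        min_gap=BENCHMARK_SPACING,
    )

    lengths = sorted(READ_LENGTH_WEIGHTS)
    weights = [READ_LENGTH_WEIGHTS[l] for l in lengths]
    reads: list[tuple[str, str]] = []
    for i in range(n_element_reads):
        t = rng.choice(manifest.elements)
        length = rng.choices(lengths, weights=weights)[0]
        pos = rng.randint(t.start, t.end - length)
        frag = genome.residues[pos:pos + length]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        reads.append((f"sr{i + 1:04d}", frag))
    for i in range(n_background_reads):
        length = rng.choices(lengths, weights=weights)[0]
        reads.append((
            f"bg{i + 1:04d}",
            "".join(rng.choice(_BASES) for _ in range(length)),
        ))
    rng.shuffle(reads)
    return Benchmark(genome=genome, manifest=manifest, reads=reads,
                     library_total=len(reads))
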