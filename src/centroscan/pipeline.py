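"""The chained analysis: scan -> annotate -> classify -> families -> date.

This is the library entry point the CLI wraps; the output is one GFF3-ready
feature hierarchy plus a per-element summary table (family, group, clade,
element/LTR lengths, TSD, PBS/PPT lengths, insertion age in My).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import panels
from ._util import translate, revcomp
from .families import DEFAULT_RATE, FamilyInput, assign_families, estimate_age
from .ltr_detect import DetectionConfig, LTRCandidate, find_ltr_pairs
from .ptd import PTDCall, Profile, assign_clade, classify_ptd
from .seqio import AnnotationRecord, GenomicSequence, read_fasta, write_element_table, write_gff3
from .structure import (
    PBS, PPT, ARichRegion, DomainAnnotation, StructureConfig, TSD,
    annotate_domains, detect_a_rich, detect_pbs, detect_ppt, detect_tsd,
    integrase_tail,
)


@dataclass
class PipelineConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    structure: StructureConfig = field(default_factory=StructureConfig)
    family_threshold_pct: float = 70.0
    family_coverage_min: float = 0.8
    rate: float = DEFAULT_RATE
    correction: str = "K2P"
    none_max_tail_aa: int = 40


@dataclass
class ElementReport:
    element_id: str
    seq_id: str
    species: str
    candidate: LTRCandidate
    tsd: TSD | None = None
    pbs: PBS | None = None
    ppt: PPT | None = None
    a_rich: ARichRegion | None = None
    domains: DomainAnnotation = field(default_factory=DomainAnnotation)
    ptd_call: PTDCall | None = None
    clade: str | None = None
    clade_margin: float | None = None
    family_id: str | None = None
    age_my: float | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def group(self) -> str | None:
        return self.ptd_call.group if self.ptd_call else None


@dataclass
class PipelineResult:
    reports: list[ElementReport]
    records: list[AnnotationRecord]
    rows: list[dict]


def _rt_query(genome, cand, domains: DomainAnnotation, rt_profile: Profile) -> str | None:
    """Protein query for the clade screen: the RT hit if one was annotated,
    else the best RT-profile window in any frame regardless of threshold
    (the screen itself decides CRM vs non-CRM, so a diverged RT must still
    be queried rather than silently dropped)."""
    rt_hit = next((h for h in domains.hits if h.domain == "RT"), None)
    if rt_hit is not None:
        rt_nt = genome.residues[rt_hit.start:rt_hit.end]
        if cand.strand == "-":
            rt_nt = revcomp(rt_nt)
        return translate(rt_nt)
    region = genome.residues[cand.start:cand.end]
    if cand.strand == "-":
        region = revcomp(region)
    best = None
    for f in range(3):
        aa = translate(region[f:])
        score, start = rt_profile.scan(aa)
        if start is not None and (best is None or score > best[0]):
            best = (score, aa[start:start + rt_profile.n_positions])
    return best[1] if best else None


def _ltr_seqs(genome: GenomicSequence, cand: LTRCandidate) -> tuple[str, str]:
    """(5' LTR, 3' LTR) on the element's strand."""
    left = genome.residues[cand.ltr5_start:cand.ltr5_end]
    right = genome.residues[cand.ltr3_start:cand.ltr3_end]
    if cand.strand == "+":
        return left, right
    return revcomp(right), revcomp(left)


def analyze_sequences(
    sequences: Sequence[GenomicSequence],
    config: PipelineConfig | None = None,
    cr_profile: Profile | None = None,
    chd2_profile: Profile | None = None,
    domain_profiles: Mapping[str, Profile] | None = None,
    rt_panels: Mapping | None = None,
) -> PipelineResult:
    """Run the full chain on in-memory sequences and return reports,
    GFF3-ready records and summary-table rows."""
    cfg = config or PipelineConfig()
    cr_profile = cr_profile or panels.default_cr_profile()
    chd2_profile = chd2_profile or panels.default_chd2_profile()
    domain_profiles = domain_profiles or panels.default_domain_profiles()
    rt_panels = rt_panels or panels.rt_reference_panels()

    reports: list[ElementReport] = []
    counter = 0
    for genome in sequences:
        for cand in find_ltr_pairs(genome, cfg.detection):
            counter += 1
            rep = ElementReport(
                element_id=f"{genome.id}_e{counter:03d}",
                seq_id=genome.id,
                species=genome.species,
                candidate=cand,
            )
            rep.tsd = detect_tsd(genome, cand, cfg.structure)
            rep.pbs = detect_pbs(genome, cand, cfg.structure)
            rep.ppt = detect_ppt(genome, cand, cfg.structure)
            rep.domains = annotate_domains(genome, cand, domain_profiles)
            rep.a_rich = detect_a_rich(genome, cand, cfg.structure)
            tail = integrase_tail(genome, cand, rep.domains)
            if tail:
                rep.ptd_call = classify_ptd(
                    tail, cr_profile, chd2_profile, cfg.none_max_tail_aa
                )
                rep.warnings.extend(rep.ptd_call.warnings)
            else:
                rep.warnings.append("no integrase hit; PTD classification skipped")
            rt_query = _rt_query(genome, cand, rep.domains, domain_profiles["RT"])
            if rt_query:
                try:
                    rep.clade, rep.clade_margin = assign_clade(rt_query, rt_panels)
                except ValueError as exc:
                    rep.warnings.append(f"clade screen failed: {exc}")
            else:
                rep.warnings.append("no RT-like region; clade screen skipped")
            ltr5, ltr3 = _ltr_seqs(genome, cand)
            try:
                rep.age_my = estimate_age(
                    ltr5, ltr3, rate=cfg.rate, correction=cfg.correction
                ).age_years / 1e6
            except ValueError as exc:
                rep.warnings.append(f"dating failed: {exc}")
            reports.append(rep)

    fam_inputs = [
        FamilyInput(
            element_id=r.element_id,
            species=r.species,
            ltr5_seq=_ltr_seqs(next(s for s in sequences if s.id == r.seq_id), r.candidate)[0],
            length=r.candidate.element_length,
        )
        for r in reports
    ]
    families, fam_warnings = assign_families(
        fam_inputs, cfg.family_threshold_pct, cfg.family_coverage_min
    )
    fam_of = {m: f.family_id for f in families for m in f.members}
    for r in reports:
        r.family_id = fam_of.get(r.element_id)

    records = _to_records(reports)
    rows = _to_rows(reports)
    return PipelineResult(reports=reports, records=records, rows=rows)


def _to_records(reports: Sequence[ElementReport]) -> list[AnnotationRecord]:
    out = []
    for r in reports:
        c = r.candidate
        attrs = {
            "ltr_identity": f"{c.ltr_identity:.4f}",
            "motif_score": c.terminal_motif_score,
        }
        if r.group:
            attrs["group"] = r.group
        if r.clade:
            attrs["clade"] = r.clade
        if r.family_id:
            attrs["family"] = r.family_id
        if r.age_my is not None:
            attrs["age_my"] = f"{r.age_my:.4f}"
        out.append(AnnotationRecord(
            r.seq_id, "element", c.start, c.end, c.strand,
            score=c.detection_score, feature_id=r.element_id, attributes=attrs,
        ))
        out.append(AnnotationRecord(
            r.seq_id, "LTR5", c.ltr5_start, c.ltr5_end, c.strand,
            feature_id=f"{r.element_id}_LTR5", parent=r.element_id))
        out.append(AnnotationRecord(
            r.seq_id, "LTR3", c.ltr3_start, c.ltr3_end, c.strand,
            feature_id=f"{r.element_id}_LTR3", parent=r.element_id))
        if r.tsd:
            for side, iv in (("L", r.tsd.left), ("R", r.tsd.right)):
                out.append(AnnotationRecord(
                    r.seq_id, "TSD", iv[0], iv[1], c.strand,
                    feature_id=f"{r.element_id}_TSD{side}", parent=r.element_id,
                    attributes={"sequence": r.tsd.sequence}))
        if r.pbs:
            out.append(AnnotationRecord(
                r.seq_id, "PBS", r.pbs.start, r.pbs.end, c.strand,
                feature_id=f"{r.element_id}_PBS", parent=r.element_id,
                attributes={"matched_len": r.pbs.matched_len}))
        if r.ppt:
            out.append(AnnotationRecord(
                r.seq_id, "PPT", r.ppt.start, r.ppt.end, c.strand,
                feature_id=f"{r.element_id}_PPT", parent=r.element_id))
        if r.a_rich:
            out.append(AnnotationRecord(
                r.seq_id, "A_rich", r.a_rich.start, r.a_rich.end, c.strand,
                feature_id=f"{r.element_id}_Arich", parent=r.element_id,
                attributes={"a_fraction": f"{r.a_rich.a_fraction:.3f}"}))
        for h in r.domains.hits:
            out.append(AnnotationRecord(
                r.seq_id, "domain", h.start, h.end, c.strand,
                score=h.score, feature_id=f"{r.element_id}_{h.domain}",
                parent=r.element_id,
                attributes={"domain": h.domain, "disruptions": h.disruptions}))
    return out


def _to_rows(reports: Sequence[ElementReport]) -> list[dict]:
    rows = []
    for r in reports:
        c = r.candidate
        rows.append({
            "element_id": r.element_id,
            "seq_id": r.seq_id,
            "species": r.species,
            "family": r.family_id or "",
            "group": r.group or "",
            "clade": r.clade or "",
            "start": c.start,
            "end": c.end,
            "strand": c.strand,
            "element_length": c.element_length,
            "ltr_length": c.ltr_length,
            "tsd": r.tsd.sequence if r.tsd else "",
            "pbs_length": r.pbs.matched_len if r.pbs else 0,
            "ppt_length": (r.ppt.end - r.ppt.start) if r.ppt else 0,
            "age_my": round(r.age_my, 4) if r.age_my is not None else "",
            "intact_orf": r.domains.intact_orf,
            "coding_into_3ltr": r.domains.coding_into_3ltr,
            "warnings": "; ".join(r.warnings),
        })
    return rows


def run_pipeline(
    fasta_path,
    out_gff3=None,
    out_tsv=None,
    config: PipelineConfig | None = None,
    **profile_kwargs,
) -> PipelineResult:
    """File-level wrapper: read a FASTA, run the chain, optionally write the
    GFF3 feature hierarchy and the per-element summary TSV."""
    sequences = read_fasta(fasta_path)
    result = analyze_sequences(sequences, config=config, **profile_kwargs)
    lengths = {s.id: len(s) for s in sequences}
    if out_gff3:
        write_gff3(result.records, out_gff3, seq_lengths=lengths)
    if out_tsv:
        write_element_table(result.rows, out_tsv)
    return result
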