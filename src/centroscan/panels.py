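"""Packaged synthetic reference material: the coding cassette, PTD consensus
sequences, training alignments, RT clade panels and the tRNA-Met default.

Everything here is synthetic, designed once and reproduced deterministically
at import from a fixed internal seed (python's version-stable Mersenne
Twister), so the repository ships no downloaded sequence data. The cassette
emulates the GAG-PRO-RT-RH-INT polyprotein layout of CRM-clade chromoviruses;
the CR motif and type II chromodomain consensus sequences are unrelated
random proteins, mirroring the fact that the real CR motif shares no sequence
similarity with true chromodomains. Reference RT panels for the Tekay, Reina
and Galadriel clades are ~30%-diverged relatives of the CRM reference,
which is ample separation for a best-hit screen.

Users can rebuild any profile from their own alignments with
:func:`centroscan.ptd.build_profile`; the tRNA-Met 3' terminus is a
configurable parameter of the structure detectors.
"""

from __future__ import annotations

import random
import re
from functools import lru_cache

from .ptd import AMINO_ACIDS, Profile, build_profile

_PANEL_SEED = 715231

#: 3' terminus (5'->3', DNA alphabet) of a plant initiator tRNA-Met; the PBS
#: of a CRM element is the reverse complement of a 12-18 nt suffix of this.
TRNA_MET_3PRIME = "CGCAGGGCTCTGATACCA"

#: sense-codon table used for deterministic reverse translation
CODONS = {
    "A": ["GCT", "GCC", "GCA"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["CTT", "CTC", "CTG"], "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCA", "CCG"], "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "AGA"],
    "S": ["TCT", "TCC", "AGC"], "T": ["ACT", "ACC", "ACA"],
    "V": ["GTT", "GTC", "GTA"], "W": ["TGG"], "Y": ["TAT", "TAC"],
}

_GPYF_RE = re.compile(r"GP[YF]")

#: residues after the integrase core: the conserved GPY/F anchor
TAIL_ANCHOR = "DSSAKGPY"

DOMAIN_ORDER = ["GAG", "PRO", "RT", "RH", "INT"]
_DOMAIN_LENGTHS = {"GAG": 100, "PRO": 70, "RT": 160, "RH": 90, "INT": 140}


def _random_protein(rng: random.Random, n: int) -> str:
    """A random protein free of GPY/GPF (that anchor must be unique)."""
    while True:
        s = "".join(rng.choice(AMINO_ACIDS) for _ in range(n))
        if not _GPYF_RE.search(s):
            return s


def mutate_protein(seq: str, rate: float, rng: random.Random) -> str:
    """Substitute each residue with probability ``rate`` (GPY/F-free)."""
    while True:
        out = []
        for a in seq:
            if rng.random() < rate:
                out.append(rng.choice([b for b in AMINO_ACIDS if b != a]))
            else:
                out.append(a)
        s = "".join(out)
        if not _GPYF_RE.search(s):
            return s


def reverse_translate(protein: str, rng: random.Random) -> str:
    return "".join(rng.choice(CODONS[a]) for a in protein)


def _build():
    rng = random.Random(_PANEL_SEED)
    proteins = {name: _random_protein(rng, n) for name, n in _DOMAIN_LENGTHS.items()}
    cr = _random_protein(rng, 45)
    chd2 = _random_protein(rng, 50)
    tail_b = _random_protein(rng, 8)

    # training members span close to distant relatives (5-25% divergence),
    # as a real family alignment would; the mean-2SD threshold rule then
    # inherits a realistic score spread
    variant_rates = [0.05, 0.10, 0.15, 0.20, 0.25] * 2
    training = {}
    for name, base in {**proteins, "CR": cr, "CHD2": chd2}.items():
        training[name] = [base] + [mutate_protein(base, r, rng) for r in variant_rates]

    # RT clade panels: other chromovirus clades as ~30%-diverged RT relatives
    rt_panels = {"CRM": [("CRM_ref1", proteins["RT"])]}
    for i, clade in enumerate(["Tekay", "Reina", "Galadriel"]):
        crng = random.Random(_PANEL_SEED + 101 + i)
        base = mutate_protein(proteins["RT"], 0.30, crng)
        rt_panels[clade] = [(f"{clade}_ref1", base)] + [
            (f"{clade}_ref{j + 2}", mutate_protein(base, 0.10, crng)) for j in range(2)
        ]
    crng = random.Random(_PANEL_SEED + 100)
    rt_panels["CRM"] += [
        (f"CRM_ref{j + 2}", mutate_protein(proteins["RT"], 0.10, crng)) for j in range(2)
    ]

    dna_rng = random.Random(_PANEL_SEED + 999)
    dna = {name: reverse_translate(proteins[name], dna_rng) for name in DOMAIN_ORDER}
    dna["ANCHOR"] = reverse_translate(TAIL_ANCHOR, dna_rng)
    dna["CR"] = reverse_translate(cr, dna_rng)
    dna["CHD2"] = reverse_translate(chd2, dna_rng)
    dna["TAIL_B"] = reverse_translate(tail_b, dna_rng)
    return proteins, cr, chd2, tail_b, training, rt_panels, dna


(
    CASSETTE_PROTEINS,
    CR_CONSENSUS,
    CHD2_CONSENSUS,
    TAIL_B_CONSENSUS,
    _TRAINING,
    _RT_PANELS,
    CASSETTE_DNA,
) = _build()


def training_alignment(name: str) -> list[str]:
    """The packaged (gap-free) training alignment for one profile.

    ``name`` is one of GAG, PRO, RT, RH, INT, CR, CHD2.
    """
    return list(_TRAINING[name])


@lru_cache(maxsize=None)
def default_cr_profile() -> Profile:
    return build_profile(training_alignment("CR"), pseudocount=0.5, name="CR_motif")


@lru_cache(maxsize=None)
def default_chd2_profile() -> Profile:
    return build_profile(training_alignment("CHD2"), pseudocount=0.5, name="chromodomain_II")


@lru_cache(maxsize=None)
def default_domain_profiles() -> dict[str, Profile]:
    """One profile per polyprotein domain (GAG, PRO, RT, RH, INT)."""
    return {
        name: build_profile(training_alignment(name), pseudocount=0.5, name=name)
        for name in DOMAIN_ORDER
    }


def rt_reference_panels() -> dict[str, list[tuple[str, str]]]:
    """Reference RT panels per clade for the best-hit clade screen."""
    return {clade: list(members) for clade, members in _RT_PANELS.items()}
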