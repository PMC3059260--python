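"""Classify integrase C-termini into groups A/B/C and screen RT clades.

Scores synthetic integrase tails with the packaged CR-motif and type II
chromodomain profiles, and screens an RT domain against the clade panels.
"""

from centroscan import assign_clade, classify_ptd
from centroscan.panels import (
    CHD2_CONSENSUS, CR_CONSENSUS, default_chd2_profile, default_cr_profile,
    rt_reference_panels,
)

cr_prof = default_cr_profile()
chd2_prof = default_chd2_profile()

tails = {
    "CR-motif tail": "DSSAKGPY" + CR_CONSENSUS,
    "bare tail": "DSSAKGPYLWDNRTQSIE",
    "chromodomain-II tail": "DSSAKGPF" + CHD2_CONSENSUS,
}
for name, tail in tails.items():
    call = classify_ptd(tail, cr_prof, chd2_prof)
    print(f"{name}: group {call.group} ({call.ptd_type}), "
          f"CR score {call.cr_score:.1f}, CHDII score {call.chd2_score:.1f}, "
          f"tail {call.tail_length_aa} aa after GPY/F")

panels = rt_reference_panels()
for clade in ("CRM", "Tekay"):
    rt = panels[clade][0][1]
    best, margin = assign_clade(rt, panels)
    print(f"RT from {clade} panel -> clade {best} (margin {margin:.0f})")

# Group A = CR motif (centromere-targeted), B = no targeting domain,
# C = type II chromodomain (dispersed). The clade screen keeps only elements
# whose best RT hit is a CRM reference, as the survey's best-hit rule does.
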