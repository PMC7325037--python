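"""Classify transposases by their DDD/E catalytic signature.

Builds a small synthetic transposase family with a planted D-D-E triad
(34 residues between the second and third positions, the classic Tc1-like
architecture), aligns each sequence to the family's seed profile and
reads the signature back.
"""

from tcmariner.alignment import SeedProfile, align_to_profile
from tcmariner.motif import assign_family, detect_motif
from tcmariner.synthetic_data import FamilySpec, sim_family

records, truth = sim_family(FamilySpec(n=5, spacing=34, res3="E", divergence=0.12), seed=42)
profile = SeedProfile(["ancestor"], [truth.ancestor], truth.positions)

print("id        signature  spacing  candidate families")
for rec in records:
    aligned = align_to_profile(rec.id, rec.residues, profile)
    call = detect_motif(aligned, profile)
    fam = assign_family(call.signature)
    print(f"{rec.id}   {call.signature}      {call.spacing}       {sorted(fam.candidate_families)}")

# The signature DD34E is shared by the Tc1, Tec, TBE and HvSm families --
# the candidate set stays ambiguous on purpose; only clade membership in a
# phylogeny can separate them.
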