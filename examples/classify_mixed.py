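"""Intra- vs inter-monomeric classification by 14N/15N mixed labeling.

For the crosslink MQDQR(N-terminus) x TKVER(K173) the four combination
masses of a 1:1 mix of unlabeled and 15N-labeled oligomers are computed
from the peptides' nitrogen counts.  A crosslink formed *within* one
monomer shows only the outer 14N-14N / 15N-15N pair; one formed *between*
monomers also shows the two mixed combinations.
"""

from xlscreen import (
    classify_pattern,
    combination_masses,
    enumerate_type2,
    simulate_mixed_pattern,
)
from xlscreen.digestion import Peptide

pep_a = Peptide("hsp", 1, 5, "MQDQR", 0, frozenset(), is_protein_nterm=True)
pep_b = Peptide("hsp", 172, 176, "TKVER", 1)
candidate = next(
    c for c in enumerate_type2([pep_a, pep_b])
    if {p.sequence for p in c.peptides} == {"MQDQR", "TKVER"}
)

pattern = combination_masses(candidate)
print(f"crosslink: {candidate.label}")
print(f"nitrogens: {pattern.n_a} (MQDQR) + {pattern.n_b} (TKVER)")
print("combination MH+ (Da):")
for name, mass in (("14N-14N", pattern.mass_aa), ("14N-15N", pattern.mass_ab),
                   ("15N-14N", pattern.mass_ba), ("15N-15N", pattern.mass_bb)):
    print(f"  {name}: {mass:.2f}")

masses = (pattern.mass_aa, pattern.mass_ab, pattern.mass_ba, pattern.mass_bb)
for truth in ("intra", "inter"):
    peaks = simulate_mixed_pattern(masses, truth, rng_seed=0)
    verdict = classify_pattern(pattern, peaks).verdict
    print(f"planted {truth} pattern -> classified {verdict}")
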