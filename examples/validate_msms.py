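"""MSMS-mode validation of one inter-subunit crosslink.

Builds the published inter-subunit crosslink of the Clp protease core
(IEKDTDR x AKEVLANK, light MH+ 1886), simulates a fragment spectrum and
matches it against the theoretical singly charged b/y ions.  Fragments
spanning the crosslinked lysine keep the linker and the intact partner
peptide attached and therefore appear as light/heavy doublets 12.0757 Da
apart - the decisive evidence for a genuine crosslink.
"""

from xlscreen import (
    clp_protease_peptides,
    enumerate_type2,
    match_fragments,
    simulate_msms,
    theoretical_fragments,
)

pep_p, pep_r = clp_protease_peptides()
candidate = next(
    c
    for c in enumerate_type2([pep_p, pep_r])
    if {p.protein_id for p in c.peptides} == {"ClpP3", "ClpR"}
    and {s.residue_index for s in c.sites} == {171, 165}
)
print(f"candidate: {candidate.label}")
print(f"precursor MH+ light/heavy: {candidate.mh_light:.2f} / {candidate.mh_heavy:.2f}")

fragments = theoretical_fragments(candidate)
carriers = [f for f in fragments if f.carries_crosslinker]
print(f"theoretical b/y ions: {len(fragments)}, crosslinker-carrying doublets: {len(carriers)}")

spectrum = simulate_msms(candidate, completeness=0.8, rng_seed=1, noise_peaks=10)
report = match_fragments(spectrum, fragments, frag_tol_da=0.3, candidate=candidate)
print(
    f"matched {report.matched_fragments}/{report.total_theoretical} fragments, "
    f"{report.matched_doublets} doublets -> validated: {report.validated}"
)
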