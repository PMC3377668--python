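"""Enumerate the theoretical crosslink space of one protein.

Digests the bundled synthetic small heat-shock protein construct,
enumerates dead-end (type 0), loop-link (type 1) and inter-peptide
(type 2) BS3 species in the 600-5000 Da window, and prints the counts
plus a few benchmark masses.  The type-2 count dwarfs the linear classes
because it grows quadratically with the number of crosslinkable sites.
"""

from xlscreen import SYNTHETIC_SHSP_CONSTRUCT, enumerate_candidates

candidates = enumerate_candidates([SYNTHETIC_SHSP_CONSTRUCT])
by_type = {t: [c for c in candidates if c.xtype == t] for t in ("type0", "type1", "type2")}

print(f"protein: {SYNTHETIC_SHSP_CONSTRUCT.id}, {len(SYNTHETIC_SHSP_CONSTRUCT.sequence)} residues")
for xtype, group in by_type.items():
    print(f"{xtype}: {len(group)} candidates")

print("\nselected type-2 light/heavy MH+ (Da):")
for c in by_type["type2"]:
    if round(c.mh_light, 2) in (1272.75, 1446.74, 1712.00):
        print(f"  {c.label}:  {c.mh_light:.2f} / {c.mh_heavy:.2f}")
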