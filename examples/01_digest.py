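"""In-silico limited proteolysis of a small protein.

Detects tryptic cleavage sites, enumerates every partial-digest fragment
(all boundary pairs, not just fully digested peptides) with its
monoisotopic mass, and reports the footprinting coverage gained by adding
more proteases.
"""

import footprintdock as fd

seq = fd.ProteinSequence("demo", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")

sites = fd.cleavage_sites(seq, fd.TRYPSIN)
print(f"tryptic sites (P1 residue numbers): {[s.position for s in sites]}")

frags = fd.digest(seq, fd.TRYPSIN)
print(f"{len(frags)} partial-digest fragments; five lightest:")
for f in sorted(frags, key=lambda f: f.mass)[:5]:
    print(f"  {f.start:>3}-{f.end:<3} {seq.subsequence(f.start, f.end):<12} "
          f"{f.mass:9.4f} Da")

for rules, label in [
    ([fd.TRYPSIN], "trypsin"),
    ([fd.TRYPSIN, fd.CHYMOTRYPSIN], "+ chymotrypsin"),
    ([fd.TRYPSIN, fd.CHYMOTRYPSIN, fd.V8], "+ V8"),
]:
    cov = fd.multi_protease_coverage(seq, rules)
    print(f"coverage {label:>15}: {cov:.0%}")
# Coverage is the fraction of residues any chosen protease can report on —
# the ceiling on how much of an interface this experiment could see.
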