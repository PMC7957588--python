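"""Predict miRNA target sites with the six complementarity rules.

Sites are ungapped antiparallel duplexes scored position by position
from the miRNA 5' end; G-U wobbles count half a mismatch toward the
numeric totals but are non-matches for the adjacency and central-
position rules.  Rule 6 requires the duplex MFE to reach 75% of the
perfect-complement duplex.
"""

from heatmir._seq import revcomp
from heatmir.targets import alignment_strings, evaluate_site, scan

mirna = "TGGAGCTCCCTTCATTCCAAT"
site = revcomp(mirna)
# a transcript with one perfect site and one site mismatched at 10-11
damaged = site[:9] + "TT" + site[11:]
transcript = "ACGA" * 10 + site + "CTTG" * 10 + damaged + "AACG" * 10

hits = scan([("miR-example", mirna)], {"tx1": transcript})
print(f"accepted sites: {len(hits)}")
for h in hits:
    print(f"  window {h.start}-{h.end}: score={h.total_score}, "
          f"positions 1-12 score={h.window_1_12_score}, "
          f"MFE ratio={h.mfe_ratio:.2f}")

rejected = evaluate_site(
    "miR-example", mirna, "tx1", transcript, 102
)
print(f"damaged window at 102 verdicts: {rejected.rule_verdicts}")
mir_str, pairing, site_rev = alignment_strings(
    mirna, transcript[101 : 101 + len(mirna)]
)
print(f"  miRNA 5'->3'  {mir_str}")
print(f"                {pairing}")
print(f"  site  3'->5'  {site_rev}")
# '|' = Watson-Crick pair, 'o' = G-U wobble, '.' = mismatch.  The
# damaged site mismatches miRNA positions 11-12: adjacent non-matches
# inside positions 2-12 (rule 3) and a central mismatch (rule 4), so
# scan() reports only the perfect window.
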