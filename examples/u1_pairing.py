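"""Score donor sites against the U1 snRNA 5' recognition element.

U1's element (ACTTAC in DNA alphabet) pairs antiparallel with the donor
site, so the perfectly complementary donor is GTAAGT. Each donor position
is a match iff it Watson-Crick pairs with its U1 partner; pairing may also
slide up to 3 nt into the exon tail.
"""

import splicecons as sc

for hexamer in ("GTAAGT", "GTGAGT", "GTTTCG"):
    res = sc.u1_match_vector(hexamer)
    marks = "".join("|" if m else "." for m in res.matches)
    print(f"{hexamer}  {marks}  {res.n_matches}/6 matched")

# a perfect donor buried two positions into the exon side: best register -2
best = sc.u1_best_register("CGT", "AAGTCC")
print(f"exon CGT + donor AAGTCC: best register {best.register_shift}, "
      f"{best.n_matches}/6 matched")

cfg = sc.GeneratorConfig(n_pairs=1000, seed=4, intron_length_range=(12, 12))
pairs, _ = sc.generate_pairs(cfg)
hex5, _ = sc.extract_all_hexes(pairs)
agg = sc.u1_aggregate(hex5)
rates = agg["per_position"]["pooled"]
print("pooled per-position match rates:",
      " ".join(f"{p}:{rates[p - 1]:.2f}" for p in range(1, 7)))
print(f"mean over variable positions: {agg['mean_variable']['pooled']:.2f}; "
      f"perfect sites: {100 * agg['perfect_fraction']['pooled']:.1f}%")
# positions 1-2 always match (canonical GT); variable-position rates track
# how often the population uses the GTAAGT-complementary bases
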