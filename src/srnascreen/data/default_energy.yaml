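# srnascreen default nearest-neighbour parameter set, version 1.
#
# Self-contained energy model: a 6x6 stacking table over the canonical pair
# set plus affine loop penalties.  The stack table is generated from a
# per-pair strength rule  E_stack(p1, p2) = -(s(p1) + s(p2)) / 2  with
# strengths s(GC) = s(CG) = 2.9, s(AU) = s(UA) = 1.1, s(GU) = s(UG) = 0.8
# kcal/mol, which makes the table symmetric under strand reversal by
# construction.  All values in kcal/mol; temperature in Kelvin.
version: 1
temperature: 310.15
canonical_pairs: [AU, UA, GC, CG, GU, UG]
pair_strength:
  AU: 1.1
  UA: 1.1
  GC: 2.9
  CG: 2.9
  GU: 0.8
  UG: 0.8
# hairpin_penalty(size) = hairpin_a + hairpin_b * size   (size >= 3, else forbidden)
hairpin_a: 4.8
hairpin_b: 0.10
# Loop interruption penalties are set so that breaking a helix costs about
# what 2-3 average stacks gain; weaker penalties let spurious chained
# micro-helices outcompete genuine contiguous duplexes.
# bulge_penalty(size) = bulge_a + bulge_b * size         (one side unpaired)
bulge_a: 5.0
bulge_b: 0.5
# interior_penalty(l1, l2) = interior_a + interior_b * (l1 + l2)   (both sides > 0)
interior_a: 4.6
interior_b: 0.5
# multiloop = ml_a + ml_b * branches (closing helix included) + ml_c * unpaired
ml_a: 3.8
ml_b: 0.4
ml_c: 0.1
# intermolecular duplex initiation
duplex_init: 4.1
# interior/bulge loops larger than this per side are assigned infinite energy
max_interior: 10
# minimum hairpin loop size
min_hairpin: 3
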