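# Bioenergetic complex definitions, v1.
#
# Each complex lists the COG families of its subunits, the subset whose
# distinct presence is counted toward the call, and the minimum number of
# distinct countable families required for a genome to be called positive.
#
# cNDH: canonical 14-subunit proton-pumping NADH:ubiquinone oxidoreductase,
#   nuoA-N. nuoM (COG1008) and nuoN (COG1007) are often encoded far from
#   the main gene cluster, so they are listed but not counted; the call
#   requires at least 6 of the 12 nuoA-L families.
# nNDH: noncanonical NDH variant lacking the nuoD-F NADH-oxidising module.
#   Its orthologous groups are distinct from the canonical complex, so its
#   families live in a separate namespace (the canonical COG id suffixed
#   with "_n"); the call requires at least 5 of the 8 nuoABCGHIJK families.
# NQR: Na+-translocating NADH:quinone oxidoreductase (nqrA-F); the call
#   requires at least 3 of the 6 listed families.
version: 1
complexes:
  cNDH:
    all_families:
      [COG0838, COG0377, COG0852, COG0649, COG1905, COG1894, COG1034,
       COG1005, COG1143, COG0839, COG0713, COG1009, COG1008, COG1007]
    countable_families:
      [COG0838, COG0377, COG0852, COG0649, COG1905, COG1894, COG1034,
       COG1005, COG1143, COG0839, COG0713, COG1009]
    min_present: 6
  nNDH:
    all_families:
      [COG0838_n, COG0377_n, COG0852_n, COG1034_n, COG1005_n, COG1143_n,
       COG0839_n, COG0713_n]
    countable_families:
      [COG0838_n, COG0377_n, COG0852_n, COG1034_n, COG1005_n, COG1143_n,
       COG0839_n, COG0713_n]
    min_present: 5
  NQR:
    all_families:
      [COG1726, COG1805, COG2869, COG1347, COG2209, COG2871]
    countable_families:
      [COG1726, COG1805, COG2869, COG1347, COG2209, COG2871]
    min_present: 3
markers:
  photolyase: COG0415
  proteorhodopsin: ENOG4111G9N
  NarG: COG5013
  NarH: COG1140
  NuoH: COG1005
  NqrA: COG1726
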