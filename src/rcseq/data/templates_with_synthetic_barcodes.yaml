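# Built-in template/product definitions for the barcoded one-pot and
# branched rolling-circle experiments.
#
# Geometry: 36-nt circles primed with the 9-nt primer P9_1 (GAAGAACTG),
# i.e. 12 triplet slots per circle period, full length after 9
# incorporations.  Extension positions are 1-based from the first triplet
# after the primer; the primer itself occupies slots 10-12 of the period,
# so position 12 expects the primer's final triplet (CTG) and position 15
# repeats position 3.
#
# One-pot templates A-D carry identifying barcode triplets at positions
# 3, 6 and 9.  The position-3 barcodes (ATA/AAA/TTA/ATC) are the published
# classification triplets.  The position-6 and position-9 barcodes below
# are SYNTHETIC placeholders chosen from the 14-triplet alphabet with the
# documented character (position 6 mixed GC, position 9 G/C-rich); the real
# identities live in a supplementary oligo table not reproduced here and
# are configurable per run.
#
# The branched circle sc8211 carries two identical primer sites, giving two
# phase-shifted products I and II.  The third substrate triplet is recorded
# as CGC, following the 14-triplet alphabet (the experiment description
# also mentions GCG once; CGC is used consistently here).
alphabet: [CTG, ATA, CCA, CCC, AAA, CAC, GGG, TTA, TCC, GGC, ATC, GAT, CGC, GAA]
primer: GAAGAACTG
adapter: GTCGAATAT
templates:
  A_circular:
    topology: circular
    circle_len_nt: 36
    primer: GAAGAACTG
    expected: [GAA, GAA, ATA, GAA, GAA, GAT, GAA, GAA, GGG, GAA, GAA, CTG]
    barcodes: {3: ATA, 6: GAT, 9: GGG}
  B_circular:
    topology: circular
    circle_len_nt: 36
    primer: GAAGAACTG
    expected: [GAA, GAA, AAA, GAA, GAA, ATC, GAA, GAA, CCC, GAA, GAA, CTG]
    barcodes: {3: AAA, 6: ATC, 9: CCC}
  C_circular:
    topology: circular
    circle_len_nt: 36
    primer: GAAGAACTG
    expected: [GAA, GAA, TTA, GAA, GAA, TCC, GAA, GAA, GGC, GAA, GAA, CTG]
    barcodes: {3: TTA, 6: TCC, 9: GGC}
  D_circular:
    topology: circular
    circle_len_nt: 36
    primer: GAAGAACTG
    expected: [GAA, GAA, ATC, GAA, GAA, CAC, GAA, GAA, CGC, GAA, GAA, CTG]
    barcodes: {3: ATC, 6: CAC, 9: CGC}
  A_linear:
    topology: linear
    primer: GAAGAACTG
    expected: [GAA, GAA, ATA, GAA, GAA, GAT, GAA, GAA, GGG]
    barcodes: {3: ATA, 6: GAT, 9: GGG}
  B_linear:
    topology: linear
    primer: GAAGAACTG
    expected: [GAA, GAA, AAA, GAA, GAA, ATC, GAA, GAA, CCC]
    barcodes: {3: AAA, 6: ATC, 9: CCC}
  C_linear:
    topology: linear
    primer: GAAGAACTG
    expected: [GAA, GAA, TTA, GAA, GAA, TCC, GAA, GAA, GGC]
    barcodes: {3: TTA, 6: TCC, 9: GGC}
  D_linear:
    topology: linear
    primer: GAAGAACTG
    expected: [GAA, GAA, ATC, GAA, GAA, CAC, GAA, GAA, CGC]
    barcodes: {3: ATC, 6: CAC, 9: CGC}
products:
  I:
    topology: circular
    circle_len_nt: 36
    primer: GAAGAACTG
    expected: [GAA, GAA, ATA, GAA, GAA, CTG, GAA, GAA, CGC, GAA, GAA, CTG]
    barcodes: {3: ATA}
  II:
    topology: circular
    circle_len_nt: 36
    primer: GAAGAACTG
    expected: [GAA, GAA, CGC, GAA, GAA, CTG, GAA, GAA, ATA, GAA, GAA, CTG]
    barcodes: {3: CGC}
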