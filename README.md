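# rcseq

Quantitative analysis of RNA-catalyzed rolling circle synthesis (RCS).

A triplet polymerase ribozyme can extend an RNA primer around a small
circular RNA template (34–58 nt) in steps of three nucleotides, continuing
past full-length circle synthesis by displacing the nascent strand's 5′
end and yielding concatemeric products. Quantifying that process means
answering, from deep-sequencing reads and gel densitometry:

* which triplet was incorporated at each position, with what fidelity, on
  which template;
* how far templated synthesis proceeds, and how much better a circular
  template sustains it past full length than a linear one;
* how long the fully correct concatemer products get;
* how efficient each ligation junction is on the gel, and whether that
  efficiency oscillates with the helical pitch of A-form dsRNA
  (11.3 bp/turn) as inside-facing junctions become less accessible.

`rcseq` implements this pipeline as a reusable library plus CLI, together
with a seeded synthetic-read/lane generator carrying ground truth, so that
every statistic can be validated end to end by round-trip and
parameter-recovery tests.

## The statistics

Reads have the layout `[sample barcode] + primer + triplet extension +
3′ adapter`. After demultiplexing, the primer (`GAAGAACTG`) anchors a
non-overlapping triplet frame and the first adapter occurrence
(`GTCGAATAT…`) marks the product end. Reads are attributed to templates
A–D by the identifying barcode triplet at position 3. Per-position
incorporation fidelity over the 14-triplet substrate alphabet is

```
F(a, xxx, Y) = 100 · n(xxx, a, Y) / Σ_XXX n(XXX, a, Y)
```

with counting *prefix-conditional*: a read is counted at position `a` only
if positions `1..a−1` are all correct for template `Y`. The product of
correct-triplet fidelities from position 3 through `X` then telescopes
exactly to the fraction of classified reads fully correct through `X` —
the cumulative probability of templated synthesis — and the
circular/linear ratio of those probabilities is the fold advantage of the
circular topology. Cells with `n ≤ 5` are masked as unreliable.

From gel band intensities `I_0..I_n` (band 0 = unextended primer) the
per-junction extension efficiency is

```
E_b = Σ_{i=b..n} I_i / Σ_{i=b−1..n} I_i
```

whose running product is the band-`b` survival fraction. A joint
sinusoid-plus-baseline fit over the efficiency series (band `b` at `3b`
nt) recovers the dominant helical period.

For branched RCS (two primer sites on one circle, products I/II), the
concatemer spectrum counts reads that are *complete, fully correct*
products: exactly `k` triplets, all matching the product's expectation,
ending in the 3′ adapter on frame; each `k` maps to product length
(`9 + 3k` nt) and circle coverage.

## Worked example

```python
import rcseq
from rcseq import (SimConfig, fidelity_profile, fixed_termination,
                   simulate_dataset, decode_reads, count_conditional,
                   fidelity, cumulative_correct)

coll = rcseq.builtin_templates()
A = coll.templates["A_circular"]          # 36-nt circle, 12 triplet slots

cfg = SimConfig(seed=7, n_reads=10_000, template=A,
                p_correct=fidelity_profile(12),   # plateau 0.90, dip 0.11 at 10
                termination=fixed_termination(12))
reads, truth = simulate_dataset(cfg)

result = decode_reads(reads, coll.primer, adapter_seq=coll.adapter)
bmap = coll.barcode_map()                 # position-3 barcode -> template
specs = {lab: coll.templates[lab + "_circular"] for lab in bmap.values()}
cm = count_conditional(result.decoded, specs, bmap, positions=range(3, 13))
fm = fidelity(cm)

for a in (9, 10, 11):
    exp = rcseq.expected_triplet(A, a)
    print(f"F({a}) = {fm.value(a, exp, 'A'):.1f}%  (n = {cm.total(a, 'A')})")
print("P(correct through 10) =", round(cumulative_correct(fm, 'A', 10)[0], 4))
```

prints

```
F(9) = 89.2%  (n = 4377)
F(10) = 10.6%  (n = 3905)
F(11) = 46.1%  (n = 414)
P(correct through 10) = 0.057
```

— the estimated fidelities recover the generating probabilities (0.90 at
the full-length plateau, the sharp 0.11 dip at the strand-invasion
position 10, 0.50 recovery beyond), and the cumulative probability is the
exact fully-correct read fraction. The same round trip works for the gel:
a noiseless lane simulated with helically modulated junction efficiencies
returns its pitch,

```python
from rcseq import LaneSimConfig, simulate_lane, extension_efficiency, periodicity
lane = simulate_lane(LaneSimConfig(n_junctions=12, e0=0.8, modulation_amplitude=0.5))
print(periodicity(extension_efficiency(lane)))   # -> (11.3, 1.0)
```

The same stages are available as CLI subcommands (`rcseq simulate`,
`decode`, `fidelity`, `concatemers`, `gel`, `report`); every run logs its
effective configuration and discard counts to stderr, and all positions in
outputs are 1-based.

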