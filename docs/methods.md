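# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `rcseq`.

## Coordinate conventions

Triplet positions are 1-based, counted from the first extension triplet
after the primer. On a circular template of `C` nt the expectation wraps
with period `P = C/3` triplet slots; because the primer anneals to part of
the circle, the last `len(primer)/3` slots of one period are the primer's
own triplets (position 12 of the built-in 36-nt circles expects the
primer's final triplet, and position 15 repeats position 3). Full length —
one complete circle — is `(C − primer)/3` incorporations (9 for a 36-nt
circle and 9-nt primer); the position immediately beyond is the
strand-invasion position. Linear templates give no instruction past their
end: incorporation there is non-templated (terminal-transferase, TT,
regime).

The experimental circle series includes sizes not divisible by 3. Rather
than silently rounding, such templates carry an explicit
`full_circle_override` and no per-position expectation list; the geometry
arithmetic stays exact for in-frame circles.

All sequence handling is on the DNA alphabet (reads are sequenced cDNA);
RNA input is normalized one-way with U→T at ingest. Quality strings are
ignored throughout — the analysis is sequence-only — and the simulator
writes a constant `I`.

## Built-in templates

The bundled collection defines the four barcoded one-pot templates (A–D,
circular and linear) and the two phase-shifted products (I/II) of the
doubly-primed branched circle. The position-3 barcodes are the published
classification triplets (ATA/AAA/TTA/ATC). The position-6 and position-9
barcodes are synthetic placeholders with the documented character (mixed
GC at 6, G/C-rich at 9), chosen from the 14-triplet alphabet and distinct
within each position; real analyses should supply the true identities via
their own template YAML. The branched products' third substrate triplet is
recorded as CGC, following the 14-triplet substrate alphabet; one place in
the experimental description names GCG instead, and the collection flags
this by comment rather than guessing both.

## Decoding

Matching is exact (no mismatches) for primer and adapter, mirroring the
exact-substring counting the fidelity statistics are defined over; sample
barcodes accept an optional Hamming tolerance (default 0). Reads are
processed in the deposited product-strand orientation; reverse-complement
search is opt-in. The first primer occurrence anchors the frame (reads
with additional internal occurrences are logged), and the first adapter
occurrence ends the product. A read whose adapter falls off the triplet
frame cannot be assigned positions; it is flagged (`frame_ok = False`),
reported, and excluded from fidelity counting. Reads without an adapter
keep `frame_ok = True` (the frame is not contradicted) and their 0–2
residual letters are recorded as trailing bases.

## Fidelity statistics

Counting is prefix-conditional by default: a read is counted at position
`a` for template `Y` only if positions `1..a−1` all match `Y`'s
expectation. This is the only conditioning under which the cumulative
product of correct-triplet fidelities telescopes exactly to the
fully-correct read fraction, and it matches the published position-4
counting construction (primer + two correct GAA + barcode + query
triplet); whether the original counting lists for positions ≥ 5
conditioned on the full prefix is not stated, so an `unconditional` mode
is exposed for sensitivity analysis. Observed triplets outside the
14-member substrate alphabet are tallied as "other" and excluded from the
Eq.-style denominator (which sums over the offered alphabet), so no read
is silently dropped. The low-`n` mask threshold defaults to `n ≤ 5`,
configurable. Percentages are reported at full double precision;
display rounding to 0.1% is left to output formatting.

`CountMatrix.cumulative_correct_exact` evaluates the telescoping product
in rational arithmetic (`fractions.Fraction`) so the identity with the
direct count is exact, not approximate; the float path through the
fidelity matrix agrees to 1e-9 relative. The exactness of the identity
requires every counted read to reach the queried position (guaranteed in
the validation datasets by fixed termination); in real data with
variable-length reads the product is still the correct chained conditional
probability, but no longer literally a ratio of two counts.

The circular/linear fold difference divides cumulative probabilities; a
zero or undefined linear probability yields an inf/NaN sentinel rather
than an exception, since downstream reporting must still show the cell.

## Concatemer spectrum

A product of length `k` is counted only as a complete exact match: `k`
triplets, all equal to the product's expectation, adapter found on frame.
Both products are tested independently against every read; reads matching
more than one product (possible where expected prefixes coincide) are
counted for each and tallied as ambiguous. Lengths map to `9 + 3k` nt and
coverage to `length / 36`.

## Densitometry

`E_b` with a zero denominator (no molecules reached junction `b−1`) is
reported as missing (NaN), never as 0 or 1 — absence of signal is not
inefficiency. "Mean extension efficiency" is the arithmetic mean of
`E_1..E_through` (the conventional reading); a geometric option exists
since its `k`-th power is the survival fraction. Band positions map to
nucleotides as `3b` from the primer junction (one triplet = 3 bp of new
duplex).

The periodicity estimator fits, at each candidate period, a sine/cosine
pair *jointly* with a linear baseline by least squares and scores variance
explained beyond the baseline-only fit; fitting the baseline jointly
avoids the small period bias that pre-detrending a finite window of a
sinusoid introduces. Candidate periods below twice the band spacing
(2 × 3 bp) are skipped: they are beyond the Nyquist limit of a
once-per-triplet-sampled series and indistinguishable from their aliases.
The default scan is 2–20 bp in 0.1-bp steps; series whose residual
variance is at floating-point rounding level, or whose best fit explains
less than R² = 0.2, report "no significant period". Noiseless recovery is
exact to the grid step for periods 8–15 bp on 9+ bands.

Band-formation velocities are OLS slopes of a band's *fraction of lane
total* against time — fractions rather than absolute intensities remove
lane-loading variation. The circular-vs-linear parity size extrapolates an
OLS line through (circle size, mean efficiency) points to the linear
reference level, flagging crossings outside the observed size range.

## Synthetic data generator

The read generator is the inverse of the decoder: reads are
`[barcode] + primer + triplets + [adapter + filler]`, with the triplet at
each templated position correct with probability `p_correct(a)` and
otherwise drawn from an error distribution over the alphabet (default:
uniform excluding the expected triplet); past a linear template's end,
triplets come from a TT distribution (default: uniform over the alphabet).
The default fidelity profile mirrors the measured circular-template shape:
plateau 0.90 up to full length, 0.11 at the invasion position, 0.50
recovery beyond — these are configuration values, not constants, since the
experiments measure data rather than prescribe a generative law. The
number of incorporated triplets is drawn from an explicit termination
distribution; adapter presence and primer presence are Bernoulli.
The adapter filler after `GTCGAATAT` is the fixed documented suffix
`AGATCGGAAGAGC` (only the adapter prefix is analytically meaningful).

One top-level seed drives everything; each read uses a substream derived
from (seed, read index), so output is byte-identical across runs and
independent of chunking. Gzipped FASTQ output pins the archive mtime and
name so identical inputs give identical bytes.

The lane generator modulates junction efficiencies as
`e_b = e0·(1 − A·(1 + cos(2π(3b + φ)/pitch))/2)` — inside-facing junctions
(cosine peak) least efficient — with pitch defaulting to the A-form dsRNA
constant 11.3 bp/turn, and converts them to band intensities by survival
arithmetic; noiseless lanes conserve molecules exactly. Noise, when
enabled, is multiplicative log-normal per band.

What the generator deliberately does not model: instrument sequencing
errors (substitutions/indels) beyond the biochemical error draws, RT-PCR
chimeras and the blunt-end ligation artifacts occasionally seen on linear
templates, per-read quality variation, and any dependence of TT activity
on position. Passing round-trip tests therefore validates the counting and
estimation machinery, not robustness to those artifacts in real data.

Notably, reads can legitimately contain a second primer occurrence — a
fully correct read through the primer-site slots (positions 10–12)
recreates the primer — so grep-style substring counting and anchored
decoding agree structurally only on reads that stop short of those slots
with error draws that cannot spell the primer (the test fixtures enforce
both); on long reads first-occurrence anchoring is the deliberate,
logged behaviour.

## Validation scales

The validation suite runs at the scales its claims need and nothing more:
exact identities on small integer lanes and 2,000-read sets; statistical
parameter recovery at 10,000 reads (3 binomial SEs); oracle equivalence at
1,200 reads; periodicity recovery on 9–12-junction lanes. The whole suite
completes in well under a minute.

## Interfaces

The library is the primary interface; the `rcseq` CLI wraps it thinly for
shell pipelines (simulate / decode / fidelity / concatemers / gel /
report), reading YAML configs with command-line overrides and echoing the
effective configuration to stderr for provenance. Plotting is out of
scope; all outputs are TSV/JSON designed to drop into standard tooling.
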