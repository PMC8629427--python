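# Methods

## The decoding model

For each codon Z the data are the N profile consensus columns C₁…C_N
aligned to genomic instances of Z after filtering. The generative model
imagines each column drawn from the pool of all aligned columns by a
codon translated as an unknown amino acid A, with affinity proportional
to the column's emission probability for A:

    P(Cᵢ | A) = P(A | Cᵢ) · P(Cᵢ) / P(A).

P(A|Cᵢ) is the column's emission probability; P(A) is the average
emission over the pool, taken to be all columns aligned to the target
genome so that genome-specific amino acid usage is reflected. Columns
are treated as independent — a simplifying approximation, since columns
of one domain hit are not independent in reality. Twenty-one decoding
models are scored: one per amino acid, plus a nonspecific model `?`
whose likelihood is ∏ᵢ P(Cᵢ) (columns drawn at random). With a uniform
prior over models, both the prior and the common ∏ᵢ P(Cᵢ) factor cancel
in the posterior, so the implementation computes

    log L(a) = Σᵢ [log P(a|Cᵢ) − log P(a)],   log L(?) = 0,

and softmax-normalizes over the 21 models. The cancelled form is
verified in the test suite against a brute-force evaluator that keeps
the P(Cᵢ) factors explicitly (uniform over a finite pool); agreement is
required to 1e-9 relative on 1,000 random instances.

An amino acid is assigned only when its posterior exceeds the decoding
threshold; otherwise the codon is `?`, including when the nonspecific
model itself is the winner. Because the threshold exceeds 0.5 and the
posterior sums to 1, at most one model can pass, so assignment is
unambiguous. No stop-codon, ambiguous-translation, noncanonical amino
acid, or context-dependent readthrough model is included: stop codons
are expected to surface as `?` through having few or no aligned columns.

## Parameters and defaults

| parameter | default | role |
|---|---|---|
| `evalue_max` | 1e-10 | per-domain ("independent") E-value cutoff, strict `<` |
| `pp_min` | 0.95 | per-residue alignment posterior cutoff; with hmmscan's pp codes only `*` (>0.95) passes |
| `cap_fraction` | 0.01 | no single column may exceed this fraction of a codon's set |
| `threshold` | 0.9999 | decoding probability required to assign an amino acid |
| `chunk_len` | 100,000 nt | input chunking before six-frame translation |
| emission clamp ε | 1e-6 | floor applied to every emission and background vector |

The per-domain (rather than full-sequence) E-value is thresholded because
the filter acts on domain hits; a switch on the parsed hits exposes the
full-sequence statistic as well. The pp-code digit d is interpreted as
the midpoint of its interval ((d−0.5)/10, (d+0.5)/10], `*` as 1.0, so at
`pp_min = 0.95` exactly the `*`-annotated columns survive; the cutoff is
configurable.

## Filtering and downsampling

The 1% cap mitigates repetitive artifacts (e.g. a pseudogene family
aligning one column to hundreds of codon instances). The cap is computed
from the *pre*-downsampling total with `floor()`, a computed cap of 0 is
raised to 1 so a legitimately aligned column always keeps one vote, and
a set whose original total is below 100 reduces every unique column to a
single occurrence (a total of exactly 100 yields cap = 1 by either
rule). Because occurrences of the same (domain, column) key are
exchangeable after aggregation, removing the excess "uniformly at
random" is identical to truncating the count; the run seed is recorded
for provenance but cannot influence this step. Storing the original
total on the association set makes downsampling idempotent.

Background frequencies P(A) are computed after filtering and
downsampling by default (occurrence-weighted over all 64 sets), with a
`pre_downsample` switch, since either reading of "all aligned columns"
is defensible. The ε = 1e-6 clamp on emissions and background bounds any
single column's log-ratio contribution to roughly ±14 nats, keeping
degenerate or synthetic profiles finite.

## Coordinates and translation

Coordinates are 0-based, half-open, always on the forward strand; a
codon is (record id, start, strand), with `start` the 5'-most
forward-strand base. Reverse-frame peptide positions map back through
this convention, and a round-trip property test asserts that re-reading
3 nt at each recorded start reproduces the translated residue. Codons
straddling 100 kb chunk boundaries are dropped (at most two per boundary
per frame) — chunking happens before translation and chunks are not
stitched. IUPAC ambiguity codes are legal input; any codon containing
one translates to `X` and is excluded from association sets, because the
model requires an unambiguous 64-way codon identity. A final partial
chunk shorter than 3 nt yields empty translations.

## Profile databases

Profiles are read from HMMER3 ASCII files via pyhmmer; stored match
emission scores (−ln p) are converted to probabilities, `*` (impossible)
entries become 0 and are then clamped. Entropy-weighting-off databases
(`hmmbuild --enone`) are recommended because their emissions approximate
raw alignment frequencies, which is what the generative model assumes.
The excluded-model list ships as an editable text file of accessions and
name globs; the five excluded classes are known (mitochondrial, viral,
selenoprotein, pyrrolysine, mobile-element models) but no canonical
accession list exists, so the default file is a documented best effort
and tests use synthetic accessions.

## The synthetic-data generator

The generator emulates exactly the structure the decoder assumes, which
is both its point and its limitation. Consensus columns are drawn from a
two-component mixture: with probability 0.8 a Dirichlet concentrating a
mean emission of 0.6 on a designated amino acid (concentration 30), and
with probability 0.2 a flat Dirichlet (weakly conserved column). Genes
are sampled paths through a domain's columns; each column emits an amino
acid from its own emission vector, encoded as a codon drawn from the
configured usage (uniform within synonym groups by default) under the
ground-truth code; genes are placed on random strands between random
intergenic spacers with configurable GC content and terminated by a stop
codon. The alignment emulator replays the ground-truth codon↔column
pairs with fixed significance (E = 1e-20, pp `*`) and can corrupt a
configurable fraction by random column substitution to emulate
pseudogene-style misalignment. No attempt is made to simulate the search
program's E-value distribution, sequencing error, frameshifts, or
horizontally transferred material — so passing the recovery tests shows
the inference machinery is correct under its own model, not that real
genomes are this clean. One seed drives named substreams (profiles /
genome / noise / subsampling), making every artifact reproducible.

Two profile serializers exist because handcrafted HMMs carry no E-value
calibration and are invisible to hmmscan's reporting thresholds: a
direct writer with exact emission control (consumed by the parser and
the emulator path), and an `hmmbuild --enone --pnone --wnone` route that
expands each domain into an ungapped count-matched alignment and builds
a calibrated, hmmscan-searchable database. The integration tests run
the real hmmscan on the latter.

## Subsampling benchmark

For each sense codon a pool of conserved columns is built (2,000 per
codon at the defaults above); at every size in {1..50, 100, 500}, 1,000
subsamples are drawn with replacement (a without-replacement switch
exists for pools that allow it), decoded, and classified as true /
false / uninferred against the codon's known amino acid. Error is
F/(T+F+U), power is T/(T+F+U); a `?` outcome counts toward neither.
With 1,000 replicates per cell the smallest nonzero error rate is
0.001, so the expected benchmark outcome under these pool conditions is
exactly zero false assignments, with power reaching 1.0 well before 34
columns for every codon. The benchmark table reports all cells; the
summary reports the maximum error over all cells and the minimum
per-codon power at 34 columns.

## tRNA isotype classification

The classifier consumes tRNAscan-SE-style sequence/structure pairs and
resolves numbered positions by walking the cloverleaf: acceptor stem
(pairs 1:72, 2:71, 3:70), D-stem (N10), D-loop, anticodon loop
(anticodon 34–36, N35, N37, N38), variable loop length, and the
discriminator N73 preceding the 3' CCA. Because the D-loop tolerates
insertions and deletions (17/17a, 20a/20b), N20 cannot be numbered by
offset alone; it is located relative to the conserved G18-G19
dinucleotide, and a loop where that anchor is absent or ambiguous is
flagged unusual, which blocks any ruleset that depends on N20 from
assigning an identity.

Rulesets are declarative (required vs. support elements as
position→allowed-base maps, extendable from YAML without code changes):

- **bacterial_arg_met** — Arg: A20 and A/G73. Met: A73 and not A20;
  support G2:C71 and C3:G70. The published acceptor-stem support pairs
  appear in one place with shifted numbering (2:70/3:69); the
  structure-figure numbering (2:71/3:70) is used here.
- **bacterial_trp** — Trp: G73 and not A20; support A/G1:U72.
- **bacterial_gln** — Gln: weak 1:72 pair (anything but G:C/C:G), A37,
  A/G73, not A20; support G2:C71, G3:C70, G38, G10.
- **bacterial_gly** — G1:C72, C2:G71, G3:C70, U73.
- **yeast_ser_leu** — requires a long (>12 nt) variable loop; Leu on
  A73 + A35 + G37, otherwise Ser (G73 is typical for serine but any
  discriminator is tolerated; non-G73 serine calls are flagged).

Within a ruleset the required elements are mutually exclusive (asserted
by exhaustive enumeration for Arg/Met); an unknown base at any required
position yields `unassigned`, never a guess. The D-loop gate applies
only to rulesets that reference N20 — the yeast Ser/Leu rules target
type-II tRNAs whose D-loops are frequently nonstandard and do not use
N20.

## Problem sizes and numerical notes

The default test and benchmark sizes — 2,000-column pools, 1,000
replicates, 20 domains × 200 columns × 200 genes (≈40,000 codons) for
recovery — were chosen as the smallest sizes at which every sense codon
is decisively supported under the generator's defaults; the benchmark
evaluates ~3.2 million subsample decodings in well under a minute via
vectorized log-ratio accumulation. Thresholding is done in log-odds
space (posterior > t ⟺ best-logit − logsumexp(rest) > logit(t)) to
avoid overflow at large set sizes. Posteriors are validated to sum to 1
within 1e-9; the empty set yields exactly 1/21 per model.

## Known limitations

Ambiguous decoding (e.g. CUG read as both Ser and Leu in some yeasts)
is not modelled and surfaces as `?`; start/stop codon usage is not
modelled; noncanonical amino acids (Sec, Pyl) cannot be predicted;
heavily pseudogenized or contaminated assemblies can produce spurious
stop-codon signals, which the 1% cap only partially mitigates; and the
tRNA cloverleaf walk targets canonical secondary structures — heavily
degenerate tRNAs (e.g. some mitochondrial ones) will fail to parse
rather than misparse.
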