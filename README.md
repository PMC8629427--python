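# decodon

Genetic code inference from nucleotide sequence.

Most organisms use the standard genetic code, but dozens of lineages —
*Mycoplasma*, *Candida* yeasts, many mitochondria, several uncultivated
bacterial clades — have reassigned one or more of the 64 codons to a
different amino acid, or recruited a stop codon into coding use. `decodon`
predicts the amino acid translation of each of the 64 codons directly from
genomic (or transcriptomic) nucleotide sequence, with no gene annotation
required, by comparing how each codon's genomic contexts align to
conserved protein-domain profiles.

It is aimed at anyone screening assemblies for non-standard translation:
microbial genomicists triaging metagenome-assembled genomes, curators
validating translation tables, and students of genetic-code evolution.

## How it works

1. **Six-frame translation.** The input FASTA is split into 100 kb chunks
   and translated in all six frames under the standard code, stop codons
   rendered as `X` (an unknown residue to the search program). Exact
   coordinate maps link every peptide position back to its genomic codon.
2. **Profile search.** The translation is searched against a database of
   protein-domain profile HMMs (HMMER3 format; ideally built with entropy
   weighting off, so match emissions approximate raw alignment
   frequencies). Domain hits with E-value < 1e-10 are kept, columns whose
   per-residue alignment posterior is below 95% are dropped, and hits to
   excluded model classes (mobile elements, viral and mitochondrial
   proteins, selenoproteins, pyrrolysine proteins) are removed.
3. **Association sets.** For each codon Z, the consensus columns aligned
   to its genomic instances form the multiset C→Z of size N. No single
   column may contribute more than 1% of a codon's total (sets under 100
   columns are reduced to one occurrence per unique column).
4. **Bayesian decoding.** Each column C carries emission probabilities
   P(A|C) over the 20 amino acids. Under the generative model, a column
   associates with a codon translated as A with probability
   P(C|A) = P(A|C)·P(C)/P(A), where P(A) is the average emission over all
   columns aligned to this genome. For each of 21 decoding models
   M ∈ {Ala, …, Tyr, ?} the likelihood of C→Z is

       P(C→Z | M) = ∏ᵢ P(A=M|Cᵢ)·P(Cᵢ)/P(A=M)   for an amino acid model,
       P(C→Z | M) = ∏ᵢ P(Cᵢ)                      for the nonspecific '?',

   and with a uniform prior the posterior P(M|C→Z) follows by
   normalization (computed in log space; the P(Cᵢ) factors cancel). A
   codon is assigned an amino acid only if its posterior exceeds 0.9999;
   otherwise it is reported as `?` — the expected outcome for stop
   codons, rare codons, and ambiguously translated codons.

The package also ships a synthetic-data subsystem (profile, genome and
alignment emulation under arbitrary genetic codes), a subsampling
error/power benchmark, and a rule-based tRNA isotype classifier that
reads tRNAscan-SE-style secondary structures and applies identity-element
rules (discriminator base N73, D-loop N20, acceptor-stem pairs,
anticodon-loop positions) for Arg/Met/Trp/Gln/Gly and the yeast Ser/Leu
distinction.

## Worked example

Infer the code of a synthetic genome emitted under a CUG→Ser variant
(200 genes sampled through 20 domain profiles of 200 columns):

```sh
$ cat sim.yaml
n_domains: 20
cols_per_domain: 200
n_genes: 200
seed: 11
code:
  CTG: S

$ decodon infer --backend emulator --sim-config sim.yaml --out-prefix run
FFLLSSSSYY??CC?WLLLSPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG
```

The 64-character string lists the inferred translation in TTT, TTC, TTA,
TTG, TCT, … GGG order (each base cycling T, C, A, G). Positions 17–20
(CTT, CTC, CTA, CTG) read `LLLS`: the pipeline recovered the CUG→Ser
reassignment, while the three standard stop codons (TAA, TAG, TGA) are
`?`. The per-codon table shows the evidence behind each call:

```
$ head -8 run.codons.tsv
codon	n_columns	inferred	p_inferred	p_nonspecific
TTT	1011	F	1.0	0.0
TTC	1022	F	1.0	0.0
TTA	354	L	1.0	6.056711516440882e-174
TTG	400	L	1.0	1.2332634341454161e-211
TCT	270	S	1.0	1.189657428833042e-140
TCC	278	S	1.0	4.233804921517684e-150
TCA	291	S	1.0	1.4309218436611125e-133
```

`n_columns` is N, the size of the codon's association set;
`p_inferred` is the decoding probability of the winning model and
`p_nonspecific` that of the `?` model. A JSON run report
(`run.report.json`) records every parameter and seed.

The subsampling benchmark measures how many aligned columns a codon
needs for reliable inference:

```
$ decodon benchmark --sizes 1:50,100,500 --reps 1000 --n-columns 2000 --seed 2063 --out bench.tsv
{"max_error_rate": 0.0, "power_at": 34, "min_power_percent": 100.0}
```

Across 1,000 subsamples per codon per size, no subsample ever assigned a
wrong amino acid (error 0.0), and every sense codon reached full power by
34 columns.

To run on real data, point `infer` at a genome and a profile database:

```sh
decodon infer --genome genome.fa.gz --db pfam_enone.hmm --out-prefix mygenome
```

(The database should be built from seed alignments with
`hmmbuild --enone` so emissions reflect raw alignment frequencies.)

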