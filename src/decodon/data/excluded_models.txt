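# Excluded profile models: hits to these are dropped before building the
# per-codon association sets. Five classes are excluded because their
# amino acid usage violates the decoding model's assumptions:
# mitochondrial proteins (organellar codes differ), viral proteins,
# selenoproteins (U at UGA), pyrrolysine-containing proteins (O at UAG),
# and transposon / mobile-element proteins (pseudogene-prone).
# One accession or shell-style name glob per line; edit freely.
#
# -- transposons and other mobile genetic elements --
Transposase*
DDE_Tnp*
Tnp_*
rve
rve_*
Integrase*
Phage_integrase
Retrotrans_gag
RVT_*
Recombinase
#
# -- viral proteins --
Phage_*
Viral_*
Gag_*
Capsid*
#
# -- mitochondrial proteins --
Oxidored_q*
COX*
Cytochrom_B*
NADHdh*
ATP-synt_8
#
# -- selenoproteins --
GSHPx
SelP*
Sel1
#
# -- pyrrolysine-containing proteins --
MtmB
MttB
PylS*
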