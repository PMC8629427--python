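"""Codon tables and the genetic-code container.

The 64 codons are ordered with the first, second and third base each cycling
T, C, A, G (TTT, TTC, TTA, TTG, TCT, ..., GGG), the order used by standard
translation-table listings. Amino acids are always indexed in the canonical
alphabetical one-letter order ``ACDEFGHIKLMNPQRSTVWY``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: Number of decoding models: the 20 amino acids plus the nonspecific '?'.
N_MODELS = 21

_BASES = "TCAG"
CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

STANDARD_STOPS = ("TAA", "TAG", "TGA")

# Standard genetic code; '*' marks stop codons. Used for the preliminary
# six-frame translation, where stops are emitted as 'X'.
_STANDARD_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIIMTTTTNNKKSRR"  # placeholder, replaced below
)
# Spell the table out explicitly to avoid transcription slips.
STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
del _STANDARD_AA

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneticCode:
    """Amino acid translation of each of the 64 codons.

    Each codon maps to one of the 20 amino acid letters or to ``'?'``, the
    nonspecific meaning used both for codons inferred not to encode a single
    amino acid (e.g. stop codons) and for codons where no decoding reached
    the probability threshold.
    """

    table: dict[str, str]
    threshold: float | None = None
    posteriors: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if set(self.table) != set(CODONS):
            raise ValueError("genetic code table must have exactly the 64 codons")
        allowed = set(AA_ORDER) | {"?"}
        bad = {v for v in self.table.values() if v not in allowed}
        if bad:
            raise ValueError(f"invalid code characters: {sorted(bad)}")

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard code with the three stop codons mapped to '?'."""
        return cls({c: ("?" if aa == "*" else aa) for c, aa in STANDARD_TABLE.items()})

    def with_reassignments(self, changes: dict[str, str]) -> "GeneticCode":
        """Return a copy with the given codon→amino-acid changes applied."""
        table = dict(self.table)
        for codon, aa in changes.items():
            codon = codon.upper().replace("U", "T")
            if codon not in table:
                raise KeyError(f"not a codon: {codon}")
            table[codon] = aa
        return GeneticCode(table)

    @classmethod
    def from_string(cls, s: str) -> "GeneticCode":
        if len(s) != 64:
            raise ValueError("code string must have 64 characters")
        return cls(dict(zip(CODONS, s)))

    def code_string(self, rna: bool = False) -> str:
        """64-character code string in TTT..GGG (T,C,A,G-cycling) order."""
        return "".join(self.table[c] for c in CODONS)

    def codons_display(self, rna: bool = False) -> list[str]:
        return [c.replace("T", "U") if rna else c for c in CODONS]

    def stop_codons(self) -> tuple[str, ...]:
        """Standard stop codons that this code has not reassigned to an
        amino acid (a '?' at a standard stop keeps it as a stop)."""
        return tuple(c for c in STANDARD_STOPS if self.table[c] == "?")

    def sense_codons(self) -> list[str]:
        return [c for c in CODONS if c not in self.stop_codons()]

    def __getitem__(self, codon: str) -> str:
        return self.table[codon]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneticCode):
            return NotImplemented
        return self.table == other.table
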