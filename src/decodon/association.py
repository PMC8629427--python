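"""Per-codon association sets: the multiset of consensus columns aligned
to each codon across the whole input, with the downsampling cap that
mitigates repetitive-family artifacts (e.g. pseudogene families aligning
one column to many codon instances).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path

from .codons import CODONS

#: Default cap: no single column may account for more than 1% of a codon's
#: aligned columns.
DEFAULT_CAP_FRACTION = 0.01

#: Below this many total aligned columns, every unique column is
#: downsampled to a single occurrence instead.
SMALL_SET_TOTAL = 100


@dataclass
class AssociationSet:
    """The C→Z multiset for one codon Z.

    ``columns`` maps (domain accession, consensus column index) to its
    occurrence count; ``n_original`` remembers the pre-downsampling total
    so that the 1% cap is computed from the original set size and
    downsampling is idempotent.
    """

    codon: str
    columns: Counter = field(default_factory=Counter)
    n_original: int | None = None

    def __post_init__(self) -> None:
        if self.n_original is None:
            self.n_original = self.n_total

    @property
    def n_total(self) -> int:
        return sum(self.columns.values())


def build_association_sets(pairs) -> dict[str, AssociationSet]:
    """Aggregate filtered aligned pairs into 64 per-codon sets.

    Every pair contributes exactly one occurrence to exactly one codon's
    multiset; codons with no pairs get an empty set.
    """
    sets = {c: AssociationSet(c) for c in CODONS}
    for p in pairs:
        sets[p.codon].columns[(p.domain_acc, p.col_index)] += 1
    for s in sets.values():
        s.n_original = s.n_total
    return sets


def downsample(
    aset: AssociationSet,
    cap_fraction: float = DEFAULT_CAP_FRACTION,
    rng_seed: int | None = None,
) -> AssociationSet:
    """Cap each unique column's occurrence count.

    If the original set held at least 100 columns, no column may exceed
    ``floor(cap_fraction * original total)`` occurrences (a computed cap of
    0 is raised to 1 so a column that legitimately aligned retains a vote);
    below 100 columns every unique column is reduced to one occurrence.

    Occurrences of the same (domain, column) key are exchangeable once
    aggregated, so removing the excess "uniformly at random" is equivalent
    to truncating the count; ``rng_seed`` is accepted for reproducibility
    bookkeeping but does not influence the result.
    """
    if not (0 < cap_fraction <= 1):
        raise ValueError("cap_fraction must be in (0, 1]")
    n0 = aset.n_original if aset.n_original is not None else aset.n_total
    if n0 >= SMALL_SET_TOTAL:
        cap = max(1, math.floor(cap_fraction * n0))
    else:
        cap = 1
    capped = Counter(
        {key: min(cnt, cap) for key, cnt in aset.columns.items() if cnt > 0}
    )
    return AssociationSet(aset.codon, capped, n_original=n0)


def write_association_tsv(
    sets: dict[str, AssociationSet], path: str | Path
) -> None:
    """Serialize association sets for inspection or replay without
    re-running the homology search."""
    with open(path, "w") as fh:
        fh.write("codon\tdomain_acc\tcol_index\tcount\n")
        for codon in CODONS:
            for (acc, col), cnt in sorted(sets[codon].columns.items()):
                fh.write(f"{codon}\t{acc}\t{col}\t{cnt}\n")


def read_association_tsv(path: str | Path) -> dict[str, AssociationSet]:
    sets = {c: AssociationSet(c) for c in CODONS}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("codon\t"):
            raise ValueError(f"{path}: not an association TSV")
        for line in fh:
            codon, acc, col, cnt = line.rstrip("\n").split("\t")
            sets[codon].columns[(acc, int(col))] += int(cnt)
    for s in sets.values():
        s.n_original = s.n_total
    return sets
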