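"""Profile database: per-domain consensus-column emission vectors.

Profiles are read from HMMER3 ASCII files (possibly a concatenation of
many profiles). Match-state emission scores stored in the file as negative
natural-log probabilities are converted back to probabilities; '*' entries
(impossible emissions) become probability 0 and are then clamped. Every
column's 20-vector is clamped at a floor of 1e-6 and renormalized so that
no log of zero can occur downstream. Amino acids are indexed in the
canonical order ACDEFGHIKLMNPQRSTVWY throughout.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pyhmmer

from .codons import AA_ORDER

#: Emission clamp floor applied before renormalization.
EMISSION_FLOOR = 1e-6


def clamp_normalize(v: np.ndarray, floor: float = EMISSION_FLOOR) -> np.ndarray:
    """Clamp a probability vector at ``floor`` and renormalize to sum 1."""
    v = np.maximum(np.asarray(v, dtype=float), floor)
    return v / v.sum()


@dataclass
class ConsensusColumn:
    """A profile match column with its amino acid emission distribution."""

    domain_acc: str
    col_index: int  # 1-based consensus column number
    emissions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.col_index < 1:
            raise ValueError("col_index is 1-based")
        if self.emissions.shape != (len(AA_ORDER),):
            raise ValueError("emissions must be a 20-vector")


@dataclass
class ProfileDomain:
    """A protein-domain profile reduced to its consensus columns."""

    acc: str
    name: str
    length: int
    columns: list[ConsensusColumn]

    def __post_init__(self) -> None:
        if len(self.columns) != self.length:
            raise ValueError("column count must equal profile length")

    @property
    def emission_matrix(self) -> np.ndarray:
        return np.stack([c.emissions for c in self.columns])


class ProfileDB:
    """A parsed profile database with fast (accession, column) lookup."""

    def __init__(self, domains: dict[str, ProfileDomain]):
        self.domains = domains
        self._names = {d.name: acc for acc, d in domains.items()}
        # stacked emission matrix with a row index per (acc, col)
        self._row: dict[tuple[str, int], int] = {}
        mats = []
        r = 0
        for acc, dom in domains.items():
            mats.append(dom.emission_matrix)
            for col in dom.columns:
                self._row[(acc, col.col_index)] = r
                r += 1
        self.matrix = (
            np.vstack(mats) if mats else np.empty((0, len(AA_ORDER)))
        )
        self._keys = list(self._row)

    def __len__(self) -> int:
        return len(self.domains)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[0]

    def emissions(self, acc: str, col_index: int) -> np.ndarray:
        return self.matrix[self._row[(acc, col_index)]]

    def row_index(self, acc: str, col_index: int) -> int:
        return self._row[(acc, col_index)]

    def column_keys(self) -> list[tuple[str, int]]:
        return self._keys

    def resolve_name(self, name_or_acc: str) -> str | None:
        if name_or_acc in self.domains:
            return name_or_acc
        return self._names.get(name_or_acc)

    # -- full-precision tabular sidecar -----------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Serialize column emissions to a full-precision TSV sidecar."""
        with open(path, "w") as fh:
            fh.write("acc\tname\tcol\t" + "\t".join(AA_ORDER) + "\n")
            for acc, dom in self.domains.items():
                for col in dom.columns:
                    vals = "\t".join(format(x, ".17g") for x in col.emissions)
                    fh.write(f"{acc}\t{dom.name}\t{col.col_index}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileDB":
        domains: dict[str, ProfileDomain] = {}
        rows: dict[str, list[tuple[str, int, np.ndarray]]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("acc\t"):
                raise ValueError(f"{path}: not an emissions TSV")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                acc, name, col = parts[0], parts[1], int(parts[2])
                v = np.array([float(x) for x in parts[3:]])
                rows.setdefault(acc, []).append((name, col, v))
        for acc, cols in rows.items():
            cols.sort(key=lambda t: t[1])
            name = cols[0][0]
            columns = [
                ConsensusColumn(acc, c, v) for (_, c, v) in cols
            ]
            domains[acc] = ProfileDomain(acc, name, len(columns), columns)
        return cls(domains)


def parse_profile_db(path: str | Path) -> ProfileDB:
    """Parse a HMMER3 ASCII profile database into a :class:`ProfileDB`.

    Raises ``ValueError`` on malformed input (naming the offending profile
    where known) and on duplicate accessions.
    """
    domains: dict[str, ProfileDomain] = {}
    try:
        with pyhmmer.plan7.HMMFile(str(path)) as hf:
            for hmm in hf:
                name = hmm.name if isinstance(hmm.name, str) else hmm.name.decode()
                acc = hmm.accession
                acc = (
                    name
                    if not acc
                    else (acc if isinstance(acc, str) else acc.decode())
                )
                if acc in domains:
                    raise ValueError(f"{path}: duplicate accession {acc!r}")
                me = np.asarray(hmm.match_emissions, dtype=float)[1:]  # drop node 0
                columns = [
                    ConsensusColumn(acc, k + 1, clamp_normalize(me[k]))
                    for k in range(hmm.M)
                ]
                domains[acc] = ProfileDomain(acc, name, hmm.M, columns)
    except (pyhmmer.errors.EaselError, EOFError, OSError) as exc:
        raise ValueError(f"{path}: malformed profile database ({exc})") from exc
    if not domains:
        raise ValueError(f"{path}: no profiles found")
    return ProfileDB(domains)


def load_exclusion_list(path: str | Path) -> set[str]:
    """Load excluded-model accessions/name globs, one per line.

    '#' starts a comment; an empty file yields the empty set. The default
    list shipped with the package is a best-effort stand-in for the five
    excluded model classes (mitochondrial, viral, selenoprotein,
    pyrrolysine-containing, and mobile-element proteins).
    """
    patterns: set[str] = set()
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                patterns.add(entry)
    return patterns


def is_excluded(acc: str, name: str | None, excluded: set[str]) -> bool:
    """True if the accession or domain name matches any exclusion pattern.

    Patterns are matched as shell-style globs (``Transposase*`` matches a
    domain named ``Transposase_21``) and literally.
    """
    for pat in excluded:
        if fnmatch.fnmatchcase(acc, pat):
            return True
        if name is not None and fnmatch.fnmatchcase(name, pat):
            return True
    return False


def default_exclusion_path() -> Path:
    return Path(__file__).parent / "data" / "excluded_models.txt"
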