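"""Homology search layer: obtain profile alignments of the six-frame
translation and convert them to codon↔consensus-column pairs.

Three routes produce the same AlignedPair stream: invoking hmmscan
(``run_search`` + ``parse_search_output``), parsing a pre-computed hmmscan
text output, or the alignment emulator in :mod:`decodon.simulate` which
bypasses the external program entirely.

Per-residue alignment posteriors are carried as hmmscan's one-character
codes: digit d covers the interval ((d-0.5)/10, (d+0.5)/10] and '*' means
above 0.95. With the default 95% cutoff only '*'-annotated columns pass.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

from .profile_db import is_excluded

DEFAULT_EVALUE_MAX = 1e-10
DEFAULT_PP_MIN = 0.95


@dataclass
class AlignedPair:
    """One association between a genomic codon instance and a profile
    consensus column, with the alignment quality metadata used for
    filtering."""

    codon: str
    domain_acc: str
    col_index: int
    evalue: float
    pp_class: str  # '0'-'9' or '*'
    record_id: str = ""
    start: int = 0
    strand: str = "+"
    domain_name: str | None = None

    def __post_init__(self) -> None:
        if any(b not in "ACGT" for b in self.codon) or len(self.codon) != 3:
            raise ValueError(f"codon must be 3 unambiguous bases, got {self.codon!r}")
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")


@dataclass
class DomainHit:
    """A parsed per-domain alignment: query peptide positions matched to
    profile consensus columns, with per-position posterior codes."""

    query_id: str
    domain_name: str
    domain_acc: str
    i_evalue: float
    full_evalue: float
    # (1-based peptide position, 1-based consensus column, pp code)
    aligned: list[tuple[int, int, str]] = field(default_factory=list)


def pp_value(code: str) -> float:
    """Numeric alignment posterior for a one-character pp code.

    Digits map to the midpoint of their bin (d ↦ d/10); '*' maps to 1.0.
    """
    if code == "*":
        return 1.0
    if code.isdigit():
        return int(code) / 10.0
    raise ValueError(f"invalid posterior code {code!r}")


def run_search(
    peptides: str | Path,
    db: str | Path,
    workdir: str | Path,
    hmmscan: str = "hmmscan",
) -> Path:
    """Run hmmscan on a peptide FASTA, returning the alignment text output.

    The profile database is pressed first if its binary index is missing.
    Raises ``RuntimeError`` with guidance if the executable is absent, or
    with the captured output tail on a nonzero exit.
    """
    db = Path(db)
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if shutil.which(hmmscan) is None:
        raise RuntimeError(
            f"{hmmscan!r} not found on PATH. Install HMMER (http://hmmer.org) "
            "or use the emulator backend, which needs no external program."
        )
    if not db.with_suffix(db.suffix + ".h3m").exists():
        press = subprocess.run(
            ["hmmpress", "-f", str(db)], capture_output=True, text=True
        )
        if press.returncode != 0:
            raise RuntimeError(
                f"hmmpress failed on {db}: ...{press.stderr[-500:]}"
            )
    out = workdir / "hmmscan.out"
    proc = subprocess.run(
        [hmmscan, "--notextw", "-o", str(out), str(db), str(peptides)],
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        tail = (proc.stderr or proc.stdout)[-500:]
        raise RuntimeError(f"hmmscan exited with {proc.returncode}: ...{tail}")
    return out


_QUERY_RE = re.compile(r"^Query:\s+(\S+)")
_TARGET_RE = re.compile(r"^>> (\S+)")
_DOMLINE_RE = re.compile(
    r"^\s*(\d+)\s+[!?]\s+(\S+)\s+(\S+)\s+(\S+)\s+(\S+)\s+"
    r"(\d+)\s+(\d+)\s+\S+\s+(\d+)\s+(\d+)"
)
_ALI_HEAD_RE = re.compile(r"^\s*== domain (\d+)")
_SCORE_ROW_RE = re.compile(
    r"^\s+([\d.eE+-]+)\s+-?[\d.]+\s+[\d.]+\s+[\d.eE+-]+\s+-?[\d.]+\s+"
    r"[\d.]+\s+[\d.]+\s+\d+\s+(\S+)"
)
_SEQLINE_RE = re.compile(r"^(\s*)(\S+)(\s+)(\d+)( )(\S+)( )(\d+)\s*$")


def parse_search_output(stream) -> list[DomainHit]:
    """Parse hmmscan's human-readable output into per-domain alignments.

    For each reported domain the per-position correspondence between query
    peptide positions and profile consensus columns is recovered, skipping
    insert states ('.' in the model line) and query deletions ('-' in the
    query line); the per-position posterior code and the domain's
    independent ("i-Evalue") and full-sequence E-values are attached.
    Raises ``ValueError`` on a stream truncated mid-record.
    """
    hits: list[DomainHit] = []
    query = None
    target = None
    # per-target per-domain-number (i_evalue, full placeholder)
    dom_evalues: dict[tuple[str, int], float] = {}
    full_evalues: dict[str, float] = {}
    cur: DomainHit | None = None
    pending: list[str] | None = None  # model/query/pp lines of one block
    saw_ok = False

    def close_current():
        nonlocal cur
        if cur is not None:
            hits.append(cur)
            cur = None

    lines = iter(stream)
    for line in lines:
        line = line.rstrip("\n")
        m = _QUERY_RE.match(line)
        if m:
            close_current()
            query = m.group(1)
            target = None
            continue
        if query is None:
            continue
        if target is None and cur is None:
            ms = _SCORE_ROW_RE.match(line)
            if ms:
                full_evalues[ms.group(2)] = float(ms.group(1))
        m = _TARGET_RE.match(line)
        if m:
            close_current()
            target = m.group(1)
            continue
        if target is not None and cur is None:
            m = _DOMLINE_RE.match(line)
            if m:
                # domain summary table row: number, c-Evalue, i-Evalue at
                # fields 4 and 5 (score, bias precede them)
                num = int(m.group(1))
                i_evalue = float(m.group(5))
                dom_evalues[(target, num)] = i_evalue
                continue
        m = _ALI_HEAD_RE.match(line)
        if m and target is not None:
            close_current()
            num = int(m.group(1))
            cur = DomainHit(
                query_id=query,
                domain_name=target,
                domain_acc=target,
                i_evalue=dom_evalues.get((target, num), float("nan")),
                full_evalue=full_evalues.get(target, float("nan")),
            )
            pending = None
            continue
        if cur is not None:
            stripped = line.strip()
            if stripped.endswith(" PP") or stripped == "PP":
                # posterior line closes a 4-line block (model/match/query/PP)
                if pending is None or len(pending) < 2:
                    raise ValueError(
                        f"truncated alignment block in domain of {cur.domain_name!r} "
                        f"(query {cur.query_id!r})"
                    )
                model_line, query_line = pending[0], pending[-1]
                _consume_block(cur, model_line, query_line, line)
                pending = None
                continue
            msl = _SEQLINE_RE.match(line)
            if msl is not None and msl.group(2) in (cur.domain_name, cur.query_id):
                if pending is None:
                    pending = [line]
                else:
                    pending.append(line)
                continue
        if line.startswith("//") or line == "[ok]":
            close_current()
            if line == "[ok]":
                saw_ok = True
            continue
    close_current()
    if query is not None and not saw_ok:
        last = hits[-1].domain_name if hits else "(none)"
        raise ValueError(
            f"truncated hmmscan output: no [ok] terminator; last complete "
            f"domain record: {last}"
        )
    return hits


def _consume_block(hit: DomainHit, model_line: str, query_line: str, pp_line: str):
    """Walk one aligned segment (model seq / query seq / PP string)."""
    mm = _SEQLINE_RE.match(model_line)
    mq = _SEQLINE_RE.match(query_line)
    if mm is None or mq is None:
        raise ValueError(
            f"unparseable alignment block for domain {hit.domain_name!r}"
        )
    model_seq = mm.group(6)
    query_seq = mq.group(6)
    # the PP string occupies the same columns as the query sequence
    q_start_col = sum(len(mq.group(i)) for i in range(1, 6))
    pp_seq = pp_line[q_start_col : q_start_col + len(query_seq)]
    if len(model_seq) != len(query_seq) or len(pp_seq) != len(query_seq):
        raise ValueError(
            f"misaligned block for domain {hit.domain_name!r} "
            f"(query {hit.query_id!r})"
        )
    hmm_pos = int(mm.group(4))  # 1-based first consensus column of segment
    q_pos = int(mq.group(4))  # 1-based first peptide position of segment
    for mc, qc, pc in zip(model_seq, query_seq, pp_seq):
        if mc == ".":  # insert state: query residue, no consensus column
            q_pos += 1
            continue
        if qc == "-":  # deletion: consensus column, no query residue
            hmm_pos += 1
            continue
        hit.aligned.append((q_pos, hmm_pos, pc))
        q_pos += 1
        hmm_pos += 1


def attach_accessions(hits: list[DomainHit], db) -> None:
    """Replace hit domain names with database accessions where known."""
    for h in hits:
        acc = db.resolve_name(h.domain_name)
        if acc is not None:
            h.domain_acc = acc


def pairs_from_hits(hits: list[DomainHit], index) -> list[AlignedPair]:
    """Convert parsed domain hits to genomic codon↔column pairs.

    Each aligned peptide position is resolved through the six-frame
    coordinate index; pairs whose codon contains a non-ACGT base (an 'X'
    produced by an ambiguity code) are dropped. A TGA-encoded 'X' inside a
    domain alignment is retained as codon "TGA". Raises ``KeyError`` for a
    query id with no coordinate map.
    """
    pairs: list[AlignedPair] = []
    for h in hits:
        for pep_pos, col, pp in h.aligned:
            codon, rec_id, start, strand = index.codon_at(h.query_id, pep_pos - 1)
            if any(b not in "ACGT" for b in codon):
                continue
            pairs.append(
                AlignedPair(
                    codon=codon,
                    domain_acc=h.domain_acc,
                    col_index=col,
                    evalue=h.i_evalue,
                    pp_class=pp,
                    record_id=rec_id,
                    start=start,
                    strand=strand,
                    domain_name=h.domain_name,
                )
            )
    return pairs


def filter_pairs(
    pairs,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    pp_min: float = DEFAULT_PP_MIN,
    excluded: set[str] | None = None,
) -> list[AlignedPair]:
    """Keep pairs with E-value strictly below ``evalue_max``, alignment
    posterior meeting ``pp_min``, and a domain not on the exclusion list.

    A pure, order-preserving, idempotent filter. Overlapping hits are not
    deduplicated: a codon instance aligned by several domains contributes
    one pair per domain alignment.
    """
    excluded = excluded or set()
    return [
        p
        for p in pairs
        if p.evalue < evalue_max
        and pp_value(p.pp_class) >= pp_min
        and not is_excluded(p.domain_acc, p.domain_name, excluded)
    ]
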