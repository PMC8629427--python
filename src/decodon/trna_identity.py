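"""Rule-based tRNA isotype classification from sequence identity elements.

Aminoacyl-tRNA synthetases recognize their cognate tRNAs largely through a
small set of identity elements: the discriminator base N73 (the unpaired
nucleotide preceding the 3' CCA), position N20 in the D-loop, acceptor-stem
base pairs, and anticodon-loop positions. Nucleotide numbering follows the
standard cloverleaf convention (acceptor stem 1-7/66-72, D-stem from
position 10, D-loop 14-21, anticodon 34-36, variable loop 44-48, N73).

Rulesets are clade-specific and declarative: each isotype lists required
elements (all must be satisfied) and support elements (reported, never
required). A record that fits no pattern — or whose D-loop is too unusual
to locate N20 when a rule needs it — is left unassigned rather than
guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

WATSON_CRICK = {("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")}
STRONG_PAIRS = {("G", "C"), ("C", "G")}


@dataclass
class TRNARecord:
    """Numbered positions of one tRNA, resolved from its cloverleaf.

    Base-pair fields hold (5' base, 3' base) tuples; single positions hold
    a base or ``None`` when the position could not be resolved.
    """

    id: str
    n1_72: tuple[str, str] | None = None
    n2_71: tuple[str, str] | None = None
    n3_70: tuple[str, str] | None = None
    n10: str | None = None
    n20: str | None = None
    anticodon: str | None = None
    n35: str | None = None
    n37: str | None = None
    n38: str | None = None
    n73: str | None = None
    var_loop_len: int = 0
    d_loop_usual: bool = True


@dataclass
class IsotypeCall:
    """Result of classifying one tRNA record under one ruleset."""

    isotype: str  # amino acid 3-letter name or "unassigned"
    required_met: bool
    support_met: list[str] = field(default_factory=list)
    ruleset: str = ""
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# cloverleaf parsing


def _stems(structure: str) -> list[list[tuple[int, int]]]:
    """Base-pair stems from '>'/'<' bracket notation, in 5'→3' order of
    their opening strand. A stem is a maximal run of nested adjacent
    pairs."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == ">":
            stack.append(i)
        elif ch == "<":
            if not stack:
                raise ValueError("unbalanced secondary structure string")
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced secondary structure string")
    pairs.sort()
    stems: list[list[tuple[int, int]]] = []
    for p in pairs:
        if stems and p[0] == stems[-1][-1][0] + 1 and p[1] == stems[-1][-1][1] - 1:
            stems[-1].append(p)
        else:
            stems.append([p])
    return stems


def _locate_n20(d_loop: str) -> tuple[str | None, bool]:
    """N20 from the D-loop via the conserved G18-G19 anchor.

    The D-loop spans positions 14-21 with optional 17/17a and 20a/20b
    insertions, so a fixed offset cannot number it; instead the conserved
    G18G19 dinucleotide is located and N20 is the base that follows. If
    the anchor is absent or its placement is ambiguous, which nucleotide
    is N20 is unclear and the loop is flagged unusual.
    """
    L = len(d_loop)
    candidates = []
    for o in range(L - 1):
        if d_loop[o : o + 2] == "GG":
            before = o  # bases 14..17(,17a)
            after = L - (o + 2)  # N20(,20a,20b) and 21
            if 2 <= before <= 5 and 2 <= after <= 4:
                candidates.append(o)
    if len(candidates) != 1:
        return None, False
    o = candidates[0]
    return d_loop[o + 2], True


def parse_trna_record(seq: str, structure: str, id: str = "") -> TRNARecord:
    """Resolve numbered tRNA positions by walking the cloverleaf.

    ``structure`` uses the '>'/'<'/'.' bracket notation of tRNAscan-SE
    secondary-structure output and must align 1:1 with ``seq``. The
    expected arms, 5'→3', are the acceptor stem (~7 bp), D-arm,
    anticodon arm, an optional variable arm, and the T-arm.
    """
    seq = seq.upper().replace("T", "U")
    if len(seq) != len(structure):
        raise ValueError(f"{id}: sequence and structure lengths differ")
    stems = _stems(structure)
    if len(stems) < 4:
        raise ValueError(f"{id}: fewer than four stems; cannot walk cloverleaf")
    acceptor, d_stem, ac_stem = stems[0], stems[1], stems[2]
    t_stem = stems[-1]
    if len(acceptor) < 3:
        raise ValueError(f"{id}: acceptor stem too short to read pairs 1-3")

    rec = TRNARecord(id=id)
    rec.n1_72 = (seq[acceptor[0][0]], seq[acceptor[0][1]])
    rec.n2_71 = (seq[acceptor[1][0]], seq[acceptor[1][1]])
    rec.n3_70 = (seq[acceptor[2][0]], seq[acceptor[2][1]])

    rec.n10 = seq[d_stem[0][0]]
    d5_end = d_stem[-1][0]
    d3_start = d_stem[-1][1]
    d_loop = seq[d5_end + 1 : d3_start]
    rec.n20, rec.d_loop_usual = _locate_n20(d_loop)

    ac5_end = ac_stem[-1][0]
    ac3_start = ac_stem[-1][1]
    ac_loop = seq[ac5_end + 1 : ac3_start]
    if len(ac_loop) != 7:
        raise ValueError(
            f"{id}: anticodon loop of {len(ac_loop)} nt (expected 7)"
        )
    rec.anticodon = ac_loop[2:5]
    rec.n35 = ac_loop[3]
    rec.n37 = ac_loop[5]
    rec.n38 = ac_loop[6]

    # variable region: between the anticodon stem 3' side and the T-stem
    ac_stem_3end = ac_stem[0][1]
    t5_start = t_stem[0][0]
    rec.var_loop_len = t5_start - ac_stem_3end - 1

    acc_3end = acceptor[0][1]
    rec.n73 = seq[acc_3end + 1] if acc_3end + 1 < len(seq) else None
    return rec


# ---------------------------------------------------------------------------
# rulesets

# Element grammar: "N<pos>=X" (base, '/' for alternatives), "N<pos>!=X",
# "P<a>:<b>=X:Y" (ordered base pair), "P1:72=weak" (not G:C/C:G),
# "VARLOOP>n". An element against an unresolved position is unsatisfied.
RULESETS: dict[str, dict] = {
    "bacterial_arg_met": {
        "uses_n20": True,
        "isotypes": [
            {"isotype": "Arg", "required": ["N20=A", "N73=A/G"], "support": []},
            {
                "isotype": "Met",
                "required": ["N73=A", "N20!=A"],
                "support": ["P2:71=G:C", "P3:70=C:G"],
            },
        ],
    },
    "bacterial_trp": {
        "uses_n20": True,
        "isotypes": [
            {"isotype": "Arg", "required": ["N20=A", "N73=A/G"], "support": []},
            {
                "isotype": "Trp",
                "required": ["N73=G", "N20!=A"],
                "support": ["P1:72=A:U", "P1:72=G:U"],
            },
        ],
    },
    "bacterial_gln": {
        "uses_n20": True,
        "isotypes": [
            {"isotype": "Arg", "required": ["N20=A", "N73=A/G"], "support": []},
            {
                "isotype": "Gln",
                "required": ["P1:72=weak", "N37=A", "N73=A/G", "N20!=A"],
                "support": ["P2:71=G:C", "P3:70=G:C", "N38=G", "N10=G"],
            },
        ],
    },
    "bacterial_gly": {
        "uses_n20": False,
        "isotypes": [
            {
                "isotype": "Gly",
                "required": ["P1:72=G:C", "P2:71=C:G", "P3:70=G:C", "N73=U"],
                "support": [],
            },
        ],
    },
    "yeast_ser_leu": {
        "uses_n20": False,
        "isotypes": [
            {
                "isotype": "Leu",
                "required": ["VARLOOP>12", "N73=A", "N35=A", "N37=G"],
                "support": [],
            },
            # Ser typically carries G73 but tolerates any nucleotide, so a
            # long-variable-loop tRNA failing the Leu elements is called
            # Ser, flagged when N73 is not G.
            {"isotype": "Ser", "required": ["VARLOOP>12"], "support": ["N73=G"]},
        ],
    },
}

_PAIR_FIELDS = {"1:72": "n1_72", "2:71": "n2_71", "3:70": "n3_70"}
_POS_FIELDS = {"10": "n10", "20": "n20", "35": "n35", "37": "n37", "38": "n38", "73": "n73"}


def _element_satisfied(rec: TRNARecord, element: str) -> bool:
    if element.startswith("VARLOOP>"):
        return rec.var_loop_len > int(element[len("VARLOOP>"):])
    if element.startswith("P"):
        pos, want = element[1:].split("=")
        pair = getattr(rec, _PAIR_FIELDS[pos])
        if pair is None or None in pair:
            return False
        if want == "weak":
            return tuple(pair) not in STRONG_PAIRS
        a, b = want.split(":")
        return pair == (a, b)
    if "!=" in element:
        pos, bad = element[1:].split("!=")
        base = getattr(rec, _POS_FIELDS[pos])
        return base is not None and base not in bad.split("/")
    pos, want = element[1:].split("=")
    base = getattr(rec, _POS_FIELDS[pos])
    return base is not None and base in want.split("/")


def classify_isotype(rec: TRNARecord, ruleset: str) -> IsotypeCall:
    """Classify a tRNA's amino acid identity under a clade-specific
    ruleset.

    The first isotype whose required elements are all satisfied is
    returned, with its satisfied support elements listed (support is
    reported, never required). Records that fit no pattern are
    unassigned, as are records whose D-loop was too unusual to place N20
    when the ruleset depends on it.
    """
    try:
        rules = RULESETS[ruleset]
    except KeyError:
        raise ValueError(
            f"unknown ruleset {ruleset!r}; available: {sorted(RULESETS)}"
        ) from None
    if rules.get("uses_n20") and not rec.d_loop_usual:
        return IsotypeCall(
            "unassigned", False, ruleset=ruleset, flags=["unusual_d_loop"]
        )
    for iso in rules["isotypes"]:
        if all(_element_satisfied(rec, e) for e in iso["required"]):
            support = [e for e in iso["support"] if _element_satisfied(rec, e)]
            flags = []
            if (
                ruleset == "yeast_ser_leu"
                and iso["isotype"] == "Ser"
                and rec.n73 != "G"
            ):
                flags.append("non_G73_serine")
            return IsotypeCall(
                iso["isotype"], True, support, ruleset, flags
            )
    return IsotypeCall("unassigned", False, ruleset=ruleset)


def load_ruleset_yaml(path: str | Path) -> None:
    """Merge user-defined rulesets (same schema as ``RULESETS``) from a
    YAML file, so new clade rules can be added without code changes."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of ruleset names")
    RULESETS.update(data)


# ---------------------------------------------------------------------------
# tRNAscan-SE style input


def read_trnascan_ss(path: str | Path) -> list[tuple[str, str, str]]:
    """Read (id, sequence, structure) triples from tRNAscan-SE style
    secondary-structure output (blocks with ``Seq:`` and ``Str:`` lines)."""
    out = []
    cur_id, cur_seq, cur_str = None, None, None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("Seq:"):
                cur_seq = line.split(":", 1)[1].strip()
            elif line.startswith("Str:"):
                cur_str = line.split(":", 1)[1].strip()
            elif line.strip() and not line.startswith(("Type:", "Possible", "HMM", "Pre:", "PRE:", "*")):
                if cur_id is None or (cur_seq and cur_str):
                    if cur_id and cur_seq and cur_str:
                        out.append((cur_id, cur_seq, cur_str))
                    cur_id = line.split()[0]
                    cur_seq = cur_str = None
        if cur_id and cur_seq and cur_str:
            out.append((cur_id, cur_seq, cur_str))
    return out
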