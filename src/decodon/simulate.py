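"""Synthetic data generation and the subsampling error/power benchmark.

The generator emulates the statistical structure the decoder assumes:
protein-domain profiles whose consensus columns carry amino acid emission
distributions of tunable conservation, genomes whose genes are sampled
paths through those columns encoded under an arbitrary genetic code with
tunable codon usage and GC bias, and the resulting ground-truth
codon↔column association stream that stands in for an external homology
search. All randomness flows from a single seed through named substreams
(profiles / genome / noise / subsampling).

Column conservation is modelled as a two-component mixture: with
probability ``1 - weak_fraction`` a column is drawn from a Dirichlet whose
mean concentrates ``mean_emission`` of the mass on a designated amino
acid, and otherwise from a flat Dirichlet (a weakly conserved column).
"""

from __future__ import annotations

import subprocess
import tempfile
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pyhmmer

from .codons import AA_ORDER, CODONS, GeneticCode
from .profile_db import (
    ConsensusColumn,
    ProfileDB,
    ProfileDomain,
    clamp_normalize,
)
from .alignment_layer import AlignedPair
from .association import AssociationSet
from .decode import DEFAULT_THRESHOLD

#: Emulated significance attached to true pairs; the emulator makes no
#: attempt to model the search program's E-value distribution.
EMULATED_EVALUE = 1e-20

DEFAULT_SEED = 2063


def substream(seed: int, *names: str) -> np.random.Generator:
    """A named, reproducible child RNG derived from the run seed."""
    key = tuple(zlib.crc32(n.encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass
class SimConfig:
    """Parameters of the synthetic data generator.

    ``codon_usage`` gives relative weights for the 64 codons in TTT..GGG
    order (None = uniform over the code's sense codons; zero weight means
    the codon is never used). ``mean_emission`` and ``concentration``
    parameterize the conserved Dirichlet component; ``weak_fraction`` is
    the weakly conserved admixture.
    """

    n_domains: int = 20
    cols_per_domain: int = 200
    mean_emission: float = 0.6
    concentration: float = 30.0
    weak_fraction: float = 0.2
    code: GeneticCode = field(default_factory=GeneticCode.standard)
    n_genes: int = 200
    codon_usage: np.ndarray | None = None
    gc_bias: float = 0.5
    intergenic_len: tuple[int, int] = (60, 140)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.codon_usage is not None:
            u = np.asarray(self.codon_usage, dtype=float)
            if u.shape != (64,) or (u < 0).any():
                raise ValueError("codon_usage must be 64 nonnegative weights")
            self.codon_usage = u


def _draw_column(
    rng: np.random.Generator,
    target: int,
    mean_emission: float,
    concentration: float,
    weak_fraction: float,
) -> np.ndarray:
    if rng.random() < weak_fraction:
        v = rng.dirichlet(np.ones(len(AA_ORDER)))
    else:
        alpha = np.full(len(AA_ORDER), (1 - mean_emission) / 19 * concentration)
        alpha[target] = mean_emission * concentration
        v = rng.dirichlet(alpha)
    return clamp_normalize(v)


def make_profiles(cfg: SimConfig) -> tuple[ProfileDB, dict[str, np.ndarray]]:
    """Generate a synthetic profile database.

    Returns the database and, per domain accession, the designated
    ("target") amino acid index of each column — the identity a strongly
    conserved column concentrates its emissions on.
    """
    rng = substream(cfg.seed, "profiles")
    domains: dict[str, ProfileDomain] = {}
    targets: dict[str, np.ndarray] = {}
    for d in range(cfg.n_domains):
        acc = f"SY{d:05d}"
        name = f"simdom_{d}"
        tgt = rng.integers(0, len(AA_ORDER), size=cfg.cols_per_domain)
        cols = [
            ConsensusColumn(
                acc,
                k + 1,
                _draw_column(
                    rng, tgt[k], cfg.mean_emission, cfg.concentration,
                    cfg.weak_fraction,
                ),
            )
            for k in range(cfg.cols_per_domain)
        ]
        domains[acc] = ProfileDomain(acc, name, cfg.cols_per_domain, cols)
        targets[acc] = tgt
    return ProfileDB(domains), targets


# ---------------------------------------------------------------------------
# profile serialization

_ALPHABET = pyhmmer.easel.Alphabet.amino()


def _to_hmm(dom: ProfileDomain) -> pyhmmer.plan7.HMM:
    M = dom.length
    hmm = pyhmmer.plan7.HMM(_ALPHABET, M, dom.name)
    hmm.accession = dom.acc.encode()
    hmm.match_emissions[0, 0] = 1.0
    for a in range(1, 20):
        hmm.match_emissions[0, a] = 0.0
    for k, col in enumerate(dom.columns, start=1):
        for a in range(20):
            hmm.match_emissions[k, a] = float(col.emissions[a])
    for k in range(M + 1):
        for a in range(20):
            hmm.insert_emissions[k, a] = 1 / 20
        last = k == M
        hmm.transition_probabilities[k, 0] = 0.99  # m->m
        hmm.transition_probabilities[k, 1] = 0.01 if last else 0.005
        hmm.transition_probabilities[k, 2] = 0.0 if last else 0.005
        hmm.transition_probabilities[k, 3] = 0.5
        hmm.transition_probabilities[k, 4] = 0.5
        hmm.transition_probabilities[k, 5] = 1.0 if last else 0.995
        hmm.transition_probabilities[k, 6] = 0.0 if last else 0.005
    hmm.validate(tolerance=1e-4)
    hmm.set_consensus()
    hmm.set_composition()
    return hmm


def write_profile_db(db: ProfileDB, path: str | Path) -> None:
    """Serialize a profile database as HMMER3 ASCII.

    The output is parseable by :func:`decodon.profile_db.parse_profile_db`
    (emissions round-trip to the text format's precision) and is
    byte-identical across runs for identical inputs.
    """
    with open(path, "wb") as fh:
        for dom in db.domains.values():
            _to_hmm(dom).write(fh, binary=False)


def _counts_msa(emissions: np.ndarray, rows: int) -> np.ndarray:
    """Residue columns whose empirical frequencies match ``emissions`` as
    closely as ``rows`` sequences allow (largest-remainder rounding)."""
    M = emissions.shape[0]
    msa = np.empty((rows, M), dtype="U1")
    for k in range(M):
        p = emissions[k]
        c = np.floor(p * rows).astype(int)
        short = rows - c.sum()
        order = np.argsort(-(p * rows - c))
        c[order[:short]] += 1
        col = np.repeat(list(AA_ORDER), c)
        msa[:, k] = col
    return msa


def build_calibrated_db(
    db: ProfileDB,
    path: str | Path,
    rows: int = 400,
    hmmbuild: str = "hmmbuild",
) -> Path:
    """Serialize profiles through ``hmmbuild --enone --pnone --wnone`` so
    the resulting database carries E-value calibration and can be searched
    with hmmscan.

    Each domain is expanded into an ungapped alignment whose column
    frequencies match its emissions (to 1/rows resolution), then built
    with entropy weighting, priors and sequence weighting all off — the
    emission estimates are the raw alignment frequencies.
    """
    path = Path(path)
    with tempfile.TemporaryDirectory(prefix="decodon_hmmbuild_") as td:
        td = Path(td)
        parts = []
        for acc, dom in db.domains.items():
            msa = _counts_msa(dom.emission_matrix, rows)
            sto = td / f"{acc}.sto"
            with open(sto, "w") as fh:
                fh.write("# STOCKHOLM 1.0\n")
                fh.write(f"#=GF ID {dom.name}\n#=GF AC {acc}\n")
                for i in range(rows):
                    fh.write(f"seq{i} {''.join(msa[i])}\n")
                fh.write("//\n")
            out = td / f"{acc}.hmm"
            proc = subprocess.run(
                [
                    hmmbuild, "--amino", "--enone", "--pnone", "--wnone",
                    "-n", dom.name, str(out), str(sto),
                ],
                capture_output=True,
                text=True,
            )
            if proc.returncode != 0:
                raise RuntimeError(
                    f"hmmbuild failed for {acc}: ...{proc.stderr[-400:]}"
                )
            parts.append(out.read_bytes())
    with open(path, "wb") as fh:
        for blob in parts:
            fh.write(blob)
    return path


# ---------------------------------------------------------------------------
# genome emission

def _codon_samplers(cfg: SimConfig):
    """Per-amino-acid codon lists and sampling probabilities under the
    configured code and codon usage."""
    usage = cfg.codon_usage
    if usage is None:
        usage = np.array(
            [1.0 if cfg.code[c] != "?" else 0.0 for c in CODONS]
        )
    samplers: dict[int, tuple[list[str], np.ndarray]] = {}
    for a, aa in enumerate(AA_ORDER):
        codons = [
            c for i, c in enumerate(CODONS)
            if cfg.code[c] == aa and usage[i] > 0
        ]
        w = np.array([usage[CODONS.index(c)] for c in codons], dtype=float)
        if not codons or w.sum() <= 0:
            raise ValueError(
                f"amino acid {aa!r} has zero total codon weight under the code"
            )
        samplers[a] = (codons, w / w.sum())
    return samplers


def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ATGC"))[rng.choice(4, size=n, p=p)])


def make_genome(
    cfg: SimConfig, db: ProfileDB
) -> tuple[list, list[AlignedPair]]:
    """Emit a synthetic genome of genes sampled through profile columns.

    Each gene walks one domain's columns; every column emits an amino acid
    from its emission vector, which is encoded as a codon drawn from the
    configured usage restricted to that amino acid under the ground-truth
    code. Genes are placed on random strands separated by random
    intergenic sequence with the configured GC bias, and each gene is
    terminated by a stop codon. The returned ground truth records every
    (codon instance, consensus column) association.
    """
    from .genome_io import NucleotideSequence

    rng = substream(cfg.seed, "genome")
    samplers = _codon_samplers(cfg)
    accs = list(db.domains)
    stops = cfg.code.stop_codons()
    parts: list[str] = []
    truth: list[AlignedPair] = []
    pos = 0
    rec_id = "sim_genome"

    def spacer() -> None:
        nonlocal pos
        n = int(rng.integers(*cfg.intergenic_len))
        parts.append(_random_nt(rng, n, cfg.gc_bias))
        pos += n

    spacer()
    for _ in range(cfg.n_genes):
        acc = accs[rng.integers(len(accs))]
        mat = db.domains[acc].emission_matrix
        cum = mat.cumsum(axis=1)
        aas = (rng.random(mat.shape[0])[:, None] > cum).sum(axis=1)
        codons = []
        for k, a in enumerate(aas):
            clist, w = samplers[int(a)]
            codons.append(clist[rng.choice(len(clist), p=w)])
        strand = "+" if rng.random() < 0.5 else "-"
        gene_nt = "".join(codons)
        if stops:
            gene_nt += stops[rng.integers(len(stops))]
        L = len(gene_nt)
        if strand == "+":
            starts = [pos + 3 * k for k in range(len(codons))]
            parts.append(gene_nt)
        else:
            from .codons import revcomp

            starts = [pos + L - 3 * k - 3 for k in range(len(codons))]
            parts.append(revcomp(gene_nt))
        for k, codon in enumerate(codons):
            truth.append(
                AlignedPair(
                    codon=codon,
                    domain_acc=acc,
                    col_index=k + 1,
                    evalue=EMULATED_EVALUE,
                    pp_class="*",
                    record_id=rec_id,
                    start=starts[k],
                    strand=strand,
                    domain_name=db.domains[acc].name,
                )
            )
        pos += L
        spacer()
    genome = NucleotideSequence(id=rec_id, seq="".join(parts))
    return [genome], truth


def emulate_associations(
    truth: list[AlignedPair],
    noise: float = 0.0,
    db: ProfileDB | None = None,
    seed: int = DEFAULT_SEED,
) -> list[AlignedPair]:
    """Emit the ground-truth pair stream as an external search would,
    optionally corrupting a ``noise`` fraction of pairs by substituting a
    random consensus column (emulating pseudogene/misalignment artifacts).
    """
    if not 0 <= noise < 1:
        raise ValueError("noise must be in [0, 1)")
    if noise == 0:
        return list(truth)
    if db is None:
        raise ValueError("db is required when noise > 0")
    rng = substream(seed, "noise")
    keys = db.column_keys()
    out = []
    corrupt = rng.random(len(truth)) < noise
    for p, bad in zip(truth, corrupt):
        if bad:
            acc, col = keys[rng.integers(len(keys))]
            p = replace(p, domain_acc=acc, col_index=col,
                        domain_name=db.domains[acc].name)
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# subsampling error/power benchmark

@dataclass
class BenchmarkPools:
    """Per-codon pools of consensus-column emission vectors, with the true
    amino acid of each codon and the pool background."""

    emissions: dict[str, np.ndarray]  # codon -> (n_cols, 20)
    truth: dict[str, str]  # codon -> amino acid letter
    bg: np.ndarray  # pooled background P(A)


def make_benchmark_pools(
    n_columns: int = 2000,
    mean_emission: float = 0.6,
    concentration: float = 30.0,
    weak_fraction: float = 0.2,
    code: GeneticCode | None = None,
    seed: int = DEFAULT_SEED,
) -> BenchmarkPools:
    """Synthetic per-codon column pools for the subsampling benchmark.

    For every sense codon, ``n_columns`` emission vectors are drawn from
    the conserved/weak Dirichlet mixture with the codon's true amino acid
    as the conserved target. The background is the occurrence-weighted
    mean over all pools, as in the full pipeline.
    """
    code = code or GeneticCode.standard()
    rng = substream(seed, "benchmark_pools")
    pools: dict[str, np.ndarray] = {}
    truth: dict[str, str] = {}
    total = np.zeros(len(AA_ORDER))
    n = 0
    for codon in code.sense_codons():
        aa = code[codon]
        t = AA_ORDER.index(aa)
        rows = np.stack(
            [
                _draw_column(rng, t, mean_emission, concentration, weak_fraction)
                for _ in range(n_columns)
            ]
        )
        pools[codon] = rows
        truth[codon] = aa
        total += rows.sum(axis=0)
        n += n_columns
    bg = clamp_normalize(total / n)
    return BenchmarkPools(pools, truth, bg)


def pools_from_sets(
    sets: dict[str, AssociationSet], db: ProfileDB, code: GeneticCode
) -> BenchmarkPools:
    """Benchmark pools taken from a pipeline run's post-filter association
    sets (each occurrence contributes one pool entry)."""
    from .decode import background_freqs

    pools = {}
    truth = {}
    for codon, aset in sets.items():
        if code[codon] == "?" or aset.n_total == 0:
            continue
        rows = []
        for (acc, col), cnt in aset.columns.items():
            rows.extend([db.emissions(acc, col)] * cnt)
        pools[codon] = np.stack(rows)
        truth[codon] = code[codon]
    bg = background_freqs(sets, db).p
    return BenchmarkPools(pools, truth, bg)


DEFAULT_SIZES = list(range(1, 51)) + [100, 500]


def subsample_experiment(
    pools: BenchmarkPools,
    sizes: list[int] | None = None,
    n_reps: int = 1000,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = DEFAULT_SEED,
    with_replacement: bool = True,
) -> pd.DataFrame:
    """Per-codon error rate and power as a function of C→Z set size.

    For each codon and size, ``n_reps`` random subsamples of columns are
    drawn from the codon's pool, decoded, and thresholded. A replicate is
    'true' (T) if the correct amino acid is assigned, 'false' (F) if an
    incorrect one is, and 'uninferred' (U) otherwise; error = F/(T+F+U)
    and power = T/(T+F+U). Sampling is with replacement by default
    (without-replacement is available when the pool size permits).
    """
    sizes = DEFAULT_SIZES if sizes is None else sizes
    rng = substream(seed, "subsampling")
    log_bg = np.log(pools.bg)
    log_thr_odds = np.log(threshold) - np.log1p(-threshold)
    rows = []
    for codon in pools.emissions:
        E = pools.emissions[codon]
        L = np.log(E) - log_bg  # (n_cols, 20) per-column log ratios
        n_cols = L.shape[0]
        true_idx = AA_ORDER.index(pools.truth[codon])
        for s in sizes:
            if s == 0:
                rows.append((codon, 0, n_reps, 0, 0, n_reps, 0.0, 0.0))
                continue
            if with_replacement:
                idx = rng.integers(0, n_cols, size=(n_reps, s))
            else:
                if s > n_cols:
                    raise ValueError(
                        f"size {s} exceeds pool of {n_cols} columns"
                    )
                idx = np.stack(
                    [rng.permutation(n_cols)[:s] for _ in range(n_reps)]
                )
            S = L[idx].sum(axis=1)  # (n_reps, 20) amino acid logits; '?' at 0
            best = np.argmax(S, axis=1)
            best_val = np.take_along_axis(S, best[:, None], 1)[:, 0]
            # posterior(best) > thr  <=>  best_val - lse(others) > logit(thr)
            rest = S.copy()
            np.put_along_axis(rest, best[:, None], -np.inf, axis=1)
            m = np.maximum(rest.max(axis=1), 0.0)
            others = np.exp(rest - m[:, None]).sum(axis=1) + np.exp(-m)
            lse_others = m + np.log(others)
            assigned = (best_val - lse_others) > log_thr_odds
            n_true = int((assigned & (best == true_idx)).sum())
            n_false = int((assigned & (best != true_idx)).sum())
            n_un = n_reps - n_true - n_false
            rows.append(
                (
                    codon, s, n_reps, n_true, n_false, n_un,
                    n_false / n_reps, n_true / n_reps,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "codon", "set_size", "n_reps", "n_true", "n_false",
            "n_uninferred", "error_rate", "power",
        ],
    )


def benchmark_summary(table: pd.DataFrame, power_at: int = 34) -> dict:
    """Headline numbers of an error/power table: the maximum per-codon
    error over all sizes and the minimum per-codon power at ``power_at``
    columns (as a percentage)."""
    max_error = float(table["error_rate"].max())
    at = table[table["set_size"] == power_at]
    min_power = float(at["power"].min()) if len(at) else float("nan")
    return {
        "max_error_rate": max_error,
        "power_at": power_at,
        "min_power_percent": 100.0 * min_power,
    }


def run_emulated_pipeline(
    cfg: SimConfig, noise: float = 0.0, **infer_kwargs
):
    """Full parameter-recovery pipeline on emulated alignments.

    Generates profiles and a genome under ``cfg``, emits the emulated
    pair stream, and runs the decoder. Returns (inferred code, report,
    profile db, ground-truth pairs).
    """
    from .decode import infer_code_from_pairs

    db, _targets = make_profiles(cfg)
    _genome, truth = make_genome(cfg, db)
    pairs = emulate_associations(truth, noise=noise, db=db, seed=cfg.seed)
    code, report = infer_code_from_pairs(pairs, db, **infer_kwargs)
    return code, report, db, truth
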