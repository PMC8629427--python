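"""The decoding model: Bayesian inference of each codon's amino acid.

For codon Z, the data are the N consensus columns C_i aligned to Z. Under
the generative model, a column associates with a codon translated as amino
acid A with probability P(C_i | A) = P(A | C_i) P(C_i) / P(A), where
P(A | C_i) is the column's emission probability and P(A) is the average
emission over the pool of aligned columns (computed from the target
genome itself, to reflect genome-specific amino acid usage). There are 21
decoding models M: the 20 amino acids, plus the nonspecific model '?'
which draws columns at random (likelihood ∏ P(C_i)).

With a uniform prior over M, both the prior and the common factor
∏ P(C_i) cancel in the posterior, so

    P(M=a | data) ∝ exp( Σ_i [log P(a|C_i) − log P(a)] ),
    P(M='?' | data) ∝ 1,

normalized over the 21 models. Computation is done in log space; the
cancelled form is verified against a brute-force evaluation that keeps the
∏ P(C_i) factors explicitly. An amino acid is assigned only if its
posterior exceeds the decoding threshold (default 0.9999); otherwise the
codon is reported as '?', including when the nonspecific model itself is
the high-probability one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codons import AA_ORDER, CODONS, N_MODELS, GeneticCode
from .profile_db import EMISSION_FLOOR, ProfileDB, clamp_normalize
from .association import AssociationSet

DEFAULT_THRESHOLD = 0.9999


@dataclass
class BackgroundFreqs:
    """Pool-average emission probabilities P(A), canonical amino acid order."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(AA_ORDER),):
            raise ValueError("background must be a 20-vector")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        if self.p.min() < EMISSION_FLOOR / 2:
            raise ValueError("background entries must respect the clamp floor")


@dataclass
class DecodingPosterior:
    """Posterior over the 21 decoding models for one codon."""

    codon: str
    posterior: np.ndarray  # length 21: 20 amino acids then '?'
    n_columns: int
    log_likelihoods: np.ndarray = field(repr=False)  # unnormalized, length 21

    MODELS = tuple(AA_ORDER) + ("?",)

    def __post_init__(self) -> None:
        if self.posterior.shape != (N_MODELS,):
            raise ValueError("posterior must have 21 entries")

    @property
    def top_model(self) -> str:
        return self.MODELS[int(np.argmax(self.posterior))]

    @property
    def top_probability(self) -> float:
        return float(self.posterior.max())

    @property
    def p_nonspecific(self) -> float:
        return float(self.posterior[-1])


def background_freqs(
    sets: dict[str, AssociationSet], db: ProfileDB
) -> BackgroundFreqs:
    """Occurrence-weighted mean emission over every column occurrence in
    every codon's set, clamped and renormalized.

    By default the sets passed here are the post-filter, post-downsample
    sets (configurable upstream); a column counted k times contributes k
    times its emission vector.
    """
    total = np.zeros(len(AA_ORDER))
    n = 0
    for aset in sets.values():
        for (acc, col), cnt in aset.columns.items():
            total += cnt * db.emissions(acc, col)
            n += cnt
    if n == 0:
        raise ValueError("no aligned columns; cannot infer a genetic code")
    return BackgroundFreqs(clamp_normalize(total / n))


def decoding_posterior(
    aset: AssociationSet, db: ProfileDB, bg: BackgroundFreqs
) -> DecodingPosterior:
    """Posterior P(M | C→Z) over the 21 decoding models for one codon."""
    log_bg = np.log(bg.p)
    ll = np.zeros(N_MODELS)
    n = 0
    for (acc, col), cnt in aset.columns.items():
        e = db.emissions(acc, col)
        ll[:-1] += cnt * (np.log(e) - log_bg)
        n += cnt
    # '?' model: all shared factors cancel, leaving log-likelihood 0.
    post = np.exp(ll - ll.max())
    post /= post.sum()
    return DecodingPosterior(aset.codon, post, n, ll)


def posterior_from_logits(codon: str, logits: np.ndarray, n: int) -> DecodingPosterior:
    """Build a posterior from precomputed per-amino-acid log-likelihood
    ratios (the '?' model is appended at 0). Used by vectorized callers."""
    ll = np.append(logits, 0.0)
    post = np.exp(ll - ll.max())
    post /= post.sum()
    return DecodingPosterior(codon, post, n, ll)


def assign_codon(dp: DecodingPosterior, threshold: float = DEFAULT_THRESHOLD) -> str:
    """The amino acid whose posterior exceeds the threshold, else '?'.

    A threshold above 0.5 guarantees at most one model can exceed it, so
    the assignment is unambiguous. A high-probability nonspecific model
    also yields '?'.
    """
    if not (0.5 < threshold <= 1):
        raise ValueError("threshold must be in (0.5, 1]")
    amino = dp.posterior[:-1]
    i = int(np.argmax(amino))
    return AA_ORDER[i] if amino[i] > threshold else "?"


def infer_code_from_sets(
    sets: dict[str, AssociationSet],
    db: ProfileDB,
    threshold: float = DEFAULT_THRESHOLD,
    cap_fraction: float = 0.01,
    background_mode: str = "post_downsample",
    rng_seed: int | None = None,
) -> tuple[GeneticCode, dict]:
    """Downsample, compute the background and posteriors, and assemble the
    64-codon genetic code. Returns the code and a per-codon report."""
    from .association import downsample

    if background_mode not in ("post_downsample", "pre_downsample"):
        raise ValueError(f"unknown background_mode {background_mode!r}")
    down = {c: downsample(s, cap_fraction, rng_seed) for c, s in sets.items()}
    bg_sets = down if background_mode == "post_downsample" else sets
    bg = background_freqs(bg_sets, db)
    table: dict[str, str] = {}
    percodon: dict[str, dict] = {}
    posteriors: dict[str, DecodingPosterior] = {}
    for codon in CODONS:
        dp = decoding_posterior(down[codon], db, bg)
        aa = assign_codon(dp, threshold)
        table[codon] = aa
        posteriors[codon] = dp
        percodon[codon] = {
            "n_columns": dp.n_columns,
            "inferred": aa,
            "top_model": dp.top_model,
            "p_top": dp.top_probability,
            "p_nonspecific": dp.p_nonspecific,
        }
    code = GeneticCode(table, threshold=threshold, posteriors=posteriors)
    report = {
        "threshold": threshold,
        "cap_fraction": cap_fraction,
        "background_mode": background_mode,
        "background": {a: float(x) for a, x in zip(AA_ORDER, bg.p)},
        "per_codon": percodon,
    }
    return code, report


def infer_code_from_pairs(
    pairs,
    db: ProfileDB,
    evalue_max: float = 1e-10,
    pp_min: float = 0.95,
    excluded: set[str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    cap_fraction: float = 0.01,
    background_mode: str = "post_downsample",
    rng_seed: int | None = None,
) -> tuple[GeneticCode, dict]:
    """Filter aligned pairs and run the full decoding for all 64 codons."""
    from .alignment_layer import filter_pairs
    from .association import build_association_sets

    kept = filter_pairs(pairs, evalue_max, pp_min, excluded or set())
    sets = build_association_sets(kept)
    if all(s.n_total == 0 for s in sets.values()):
        # zero significant hits: every codon is uninferred
        import warnings

        warnings.warn("no aligned columns passed the filters; all codons '?'")
        table = {c: "?" for c in CODONS}
        return GeneticCode(table, threshold=threshold), {
            "threshold": threshold,
            "per_codon": {c: {"n_columns": 0, "inferred": "?"} for c in CODONS},
        }
    code, report = infer_code_from_sets(
        sets, db, threshold, cap_fraction, background_mode, rng_seed
    )
    report["filters"] = {
        "evalue_max": evalue_max,
        "pp_min": pp_min,
        "n_pairs_in": len(pairs) if hasattr(pairs, "__len__") else None,
        "n_pairs_kept": len(kept),
    }
    return code, report


def infer_code(
    genome_fasta,
    db_path,
    workdir=None,
    backend: str = "external_search",
    search_output=None,
    chunk_len: int = 100_000,
    evalue_max: float = 1e-10,
    pp_min: float = 0.95,
    exclusion_list=None,
    threshold: float = DEFAULT_THRESHOLD,
    cap_fraction: float = 0.01,
    background_mode: str = "post_downsample",
    rng_seed: int = 2063,
) -> tuple[GeneticCode, dict]:
    """End-to-end inference from a genome FASTA and a profile database.

    ``backend`` selects how alignments are obtained: ``external_search``
    invokes hmmscan; ``precomputed`` parses an existing hmmscan output
    given as ``search_output``.
    """
    import tempfile
    from pathlib import Path

    from . import alignment_layer, genome_io
    from .profile_db import load_exclusion_list, parse_profile_db

    records = genome_io.read_fasta(genome_fasta)
    peptides, index = genome_io.translate_genome(records, chunk_len)
    db = parse_profile_db(db_path)
    excluded = load_exclusion_list(exclusion_list) if exclusion_list else set()

    if backend == "precomputed":
        if search_output is None:
            raise ValueError("precomputed backend requires search_output")
        with open(search_output) as fh:
            hits = alignment_layer.parse_search_output(fh)
    elif backend == "external_search":
        wd = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="decodon_"))
        wd.mkdir(parents=True, exist_ok=True)
        pep_fa = wd / "six_frame.faa"
        genome_io.write_peptides(peptides, pep_fa)
        out = alignment_layer.run_search(pep_fa, db_path, wd)
        with open(out) as fh:
            hits = alignment_layer.parse_search_output(fh)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    alignment_layer.attach_accessions(hits, db)
    pairs = alignment_layer.pairs_from_hits(hits, index)
    code, report = infer_code_from_pairs(
        pairs,
        db,
        evalue_max=evalue_max,
        pp_min=pp_min,
        excluded=excluded,
        threshold=threshold,
        cap_fraction=cap_fraction,
        background_mode=background_mode,
        rng_seed=rng_seed,
    )
    report["config"] = {
        "backend": backend,
        "chunk_len": chunk_len,
        "evalue_max": evalue_max,
        "pp_min": pp_min,
        "threshold": threshold,
        "cap_fraction": cap_fraction,
        "background_mode": background_mode,
        "rng_seed": rng_seed,
    }
    return code, report
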