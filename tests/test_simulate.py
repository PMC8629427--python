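import numpy as np
import pytest
from scipy import stats

from decodon.codons import AA_ORDER, CODONS, GeneticCode
from decodon.decode import infer_code_from_pairs
from decodon.profile_db import parse_profile_db
from decodon.simulate import (
    BenchmarkPools,
    SimConfig,
    emulate_associations,
    make_benchmark_pools,
    make_genome,
    make_profiles,
    run_emulated_pipeline,
    subsample_experiment,
    write_profile_db,
)


class TestMakeProfiles:
    def test_conserved_columns_argmax_matches_target(self):
        """At mean emission 0.9 the designated amino acid dominates almost
        every conserved column."""
        cfg = SimConfig(
            n_domains=5, cols_per_domain=200, mean_emission=0.9,
            weak_fraction=0.0, seed=17,
        )
        db, targets = make_profiles(cfg)
        hit = total = 0
        for acc, dom in db.domains.items():
            am = dom.emission_matrix.argmax(axis=1)
            hit += (am == targets[acc]).sum()
            total += len(am)
        assert hit / total >= 0.95

    def test_deterministic_serialization(self, tmp_path):
        cfg = SimConfig(n_domains=3, cols_per_domain=20, seed=99)
        p1, p2 = tmp_path / "a.hmm", tmp_path / "b.hmm"
        db1, _ = make_profiles(cfg)
        db2, _ = make_profiles(cfg)
        write_profile_db(db1, p1)
        write_profile_db(db2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_zero_domains_gives_empty_db_and_all_uninferred(self):
        cfg = SimConfig(n_domains=0, n_genes=0)
        db, targets = make_profiles(cfg)
        assert len(db) == 0 and targets == {}
        with pytest.warns(UserWarning):
            code, _ = infer_code_from_pairs([], db)
        assert set(code.table.values()) == {"?"}


class TestMakeGenome:
    def test_codon_usage_matches_uniform_within_synonyms(self):
        """Within each amino acid's synonymous codon group, usage is
        uniform up to multinomial sampling noise (~50,000 codons)."""
        cfg = SimConfig(n_domains=10, cols_per_domain=250, n_genes=200, seed=3)
        db, _ = make_profiles(cfg)
        _, truth = make_genome(cfg, db)
        counts = {c: 0 for c in CODONS}
        for p in truth:
            counts[p.codon] += 1
        assert sum(counts.values()) == 200 * 250
        code = cfg.code
        chi2 = 0.0
        dof = 0
        for aa in AA_ORDER:
            group = [c for c in CODONS if code[c] == aa]
            obs = np.array([counts[c] for c in group])
            if len(group) < 2 or obs.sum() < 50:
                continue
            chi2 += stats.chisquare(obs).statistic
            dof += len(group) - 1
        p = stats.chi2.sf(chi2, dof)
        assert p > 1e-4

    def test_stop_codons_never_inside_genes(self):
        cfg = SimConfig(n_domains=5, cols_per_domain=100, n_genes=50, seed=3)
        db, _ = make_profiles(cfg)
        _, truth = make_genome(cfg, db)
        stops = set(cfg.code.stop_codons())
        assert not any(p.codon in stops for p in truth)

    def test_reassigned_codon_appears_at_its_new_amino_acids_columns(self):
        code = GeneticCode.standard().with_reassignments({"CTG": "S"})
        cfg = SimConfig(
            n_domains=5, cols_per_domain=100, n_genes=50, code=code, seed=4,
        )
        db, targets = make_profiles(cfg)
        _, truth = make_genome(cfg, db)
        ser = AA_ORDER.index("S")
        ctg = [p for p in truth if p.codon == "CTG"]
        assert ctg, "CTG should be used under the reassigned code"
        for p in ctg:
            e = db.emissions(p.domain_acc, p.col_index)
            # the emitting column put nontrivial mass on serine
            assert e[ser] > 1e-4

    def test_truth_coordinates_recover_codons_from_genome(self):
        from decodon.genome_io import codon_at

        cfg = SimConfig(n_domains=4, cols_per_domain=60, n_genes=20, seed=8)
        db, _ = make_profiles(cfg)
        genome, truth = make_genome(cfg, db)
        rec = genome[0]
        for p in truth[::7]:
            assert codon_at(rec, p.start, p.strand) == p.codon

    def test_unencodable_amino_acid_errors(self):
        usage = np.ones(64)
        for i, c in enumerate(CODONS):
            if GeneticCode.standard()[c] == "W":
                usage[i] = 0.0  # tryptophan becomes unencodable
        cfg = SimConfig(n_domains=2, cols_per_domain=30, n_genes=5,
                        codon_usage=usage, seed=1)
        db, _ = make_profiles(cfg)
        with pytest.raises(ValueError, match="zero total codon weight"):
            make_genome(cfg, db)


class TestEmulator:
    def _setup(self, seed=21):
        cfg = SimConfig(n_domains=5, cols_per_domain=100, n_genes=60, seed=seed)
        db, _ = make_profiles(cfg)
        _, truth = make_genome(cfg, db)
        return cfg, db, truth

    def test_zero_noise_is_identity(self):
        cfg, db, truth = self._setup()
        assert emulate_associations(truth, 0.0) == truth

    def test_noise_fraction_binomial(self):
        cfg, db, truth = self._setup()
        pairs = emulate_associations(truth, 0.05, db=db, seed=cfg.seed)
        changed = sum(
            1 for a, b in zip(truth, pairs)
            if (a.domain_acc, a.col_index) != (b.domain_acc, b.col_index)
        )
        n = len(truth)
        # within 5 sigma of Binomial(n, ~0.05); corrupted pairs may rarely
        # redraw the original column, hence the slight downward allowance
        sd = np.sqrt(n * 0.05 * 0.95)
        assert 0.05 * n - 5 * sd <= changed <= 0.05 * n + 5 * sd

    def test_noise_degrades_true_posterior_on_average(self):
        cfg, db, truth = self._setup()
        code = cfg.code

        def mean_true_posterior(noise):
            pairs = emulate_associations(truth, noise, db=db, seed=cfg.seed)
            inferred, report = infer_code_from_pairs(pairs, db)
            vals = []
            for codon, row in report["per_codon"].items():
                if code[codon] != "?" and row["n_columns"] > 0:
                    dp = inferred.posteriors[codon]
                    vals.append(dp.posterior[AA_ORDER.index(code[codon])])
            return np.mean(vals)

        p0, p3, p6 = (mean_true_posterior(x) for x in (0.0, 0.3, 0.6))
        assert p0 >= p3 >= p6


class TestSubsampleExperiment:
    def _perfect_pools(self, n=50):
        """Columns exactly conserved (clamped) for the true amino acid,
        uniform background: likelihood ratio ~20 per column."""
        from decodon.profile_db import clamp_normalize

        pools, truth = {}, {}
        for codon, aa in (("TGG", "W"), ("ATG", "M")):
            t = AA_ORDER.index(aa)
            row = np.zeros(20)
            row[t] = 1.0
            pools[codon] = np.tile(clamp_normalize(row), (n, 1))
            truth[codon] = aa
        return BenchmarkPools(pools, truth, np.full(20, 0.05))

    def test_accounting_exact(self):
        pools = make_benchmark_pools(n_columns=60, seed=5)
        table = subsample_experiment(pools, sizes=[1, 5, 10], n_reps=50, seed=5)
        assert (
            table.n_true + table.n_false + table.n_uninferred == table.n_reps
        ).all()
        np.testing.assert_allclose(table.error_rate, table.n_false / table.n_reps)
        np.testing.assert_allclose(table.power, table.n_true / table.n_reps)

    def test_size_zero_is_all_uninferred(self):
        table = subsample_experiment(
            self._perfect_pools(), sizes=[0], n_reps=20, seed=1
        )
        assert (table.power == 0).all() and (table.error_rate == 0).all()

    def test_four_perfect_ratio20_columns_give_full_power(self):
        # 20^4/(20^4+1) > 0.9999 while 20^3/(20^3+1) is not enough
        table = subsample_experiment(
            self._perfect_pools(), sizes=[3, 4], n_reps=50, seed=1
        )
        at3 = table[table.set_size == 3]
        at4 = table[table.set_size == 4]
        assert (at3.power == 0.0).all()
        assert (at4.power == 1.0).all()

    def test_power_nondecreasing_in_size(self):
        pools = make_benchmark_pools(n_columns=300, seed=9)
        sizes = [1, 2, 4, 8, 16, 32]
        table = subsample_experiment(pools, sizes=sizes, n_reps=200, seed=9)
        for codon, grp in table.groupby("codon"):
            p = grp.sort_values("set_size").power.to_numpy()
            assert (np.diff(p) >= -0.05).all()  # Monte-Carlo tolerance

    def test_deterministic_given_seed(self):
        pools = make_benchmark_pools(n_columns=40, seed=2)
        t1 = subsample_experiment(pools, sizes=[5], n_reps=30, seed=2)
        t2 = subsample_experiment(pools, sizes=[5], n_reps=30, seed=2)
        assert t1.equals(t2)

    def test_without_replacement_requires_capacity(self):
        pools = self._perfect_pools(n=10)
        with pytest.raises(ValueError, match="exceeds pool"):
            subsample_experiment(
                pools, sizes=[11], n_reps=5, seed=1, with_replacement=False
            )


class TestFullRecovery:
    def test_emulated_pipeline_recovers_code_and_stops(self):
        cfg = SimConfig(n_domains=10, cols_per_domain=120, n_genes=80, seed=31)
        code, report, db, truth = run_emulated_pipeline(cfg)
        for codon in CODONS:
            if report["per_codon"][codon]["n_columns"] >= 20:
                assert code[codon] == cfg.code[codon]
        for stop in ("TAA", "TAG", "TGA"):
            assert code[stop] == "?"
            assert report["per_codon"][stop]["n_columns"] == 0
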