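import numpy as np
import pytest

import repliq as rq
from repliq.alphabet import ALPHABET

from conftest import make_constant_table, make_delta_table, make_random_table

LN4 = np.log(4.0)


class TestChainEnergy:
    def test_single_site_uses_pair_energy(self, table):
        t = rq.TemplateSequence("C")
        eps0 = rq.derive_pair_energies(table)
        assert rq.chain_energy("G", t, table) == pytest.approx(
            eps0[ALPHABET.index("C"), ALPHABET.index("G")]
        )

    def test_constant_energies_sum(self):
        t = rq.make_template("random", 12, seed=4)
        table = make_constant_table(0.25)
        y = rq.make_template("random", 12, seed=5).symbols
        assert rq.chain_energy(y, t, table) == pytest.approx(12 * 0.25, abs=1e-12)

    def test_four_mer_hand_summation(self, table):
        """Energy of the all-WC copy of ACGT, summed term by term from the table."""
        t = rq.TemplateSequence("ACGT")
        eps0 = rq.derive_pair_energies(table)
        hand = (
            eps0[ALPHABET.index("A"), ALPHABET.index("T")]
            + table.nn_energy("AT", "CG")
            + table.nn_energy("CG", "GC")
            + table.nn_energy("GC", "TA")
        )
        assert rq.chain_energy("TGCA", t, table) == pytest.approx(hand, abs=1e-12)
        assert hand == pytest.approx(-5.036894375, abs=1e-9)

    def test_length_mismatch_rejected(self, table):
        with pytest.raises(ValueError, match="length"):
            rq.chain_energy("AC", rq.TemplateSequence("ACG"), table)


class TestIsingEnsemble:
    def test_single_site_reduces_to_incorporation_column(self, table, thermo):
        t = rq.TemplateSequence("G")
        ens = rq.ising_ensemble(t, table, thermo)
        eps0 = rq.derive_pair_energies(table)
        col = eps0[ALPHABET.index("G")]
        log_z = np.log(np.exp(-thermo.beta * col).sum())
        assert ens.log_partition == pytest.approx(log_z, rel=1e-12)
        m = rq.incorporation_matrix(eps0, thermo)
        np.testing.assert_allclose(ens.site_marginals[0], m.column("G"), rtol=1e-12)

    def test_uniform_energies_closed_form(self, thermo):
        c = -0.8
        t = rq.make_template("random", 30, seed=6)
        ens = rq.ising_ensemble(t, make_constant_table(c), thermo)
        assert ens.log_partition == pytest.approx(30 * LN4 - thermo.beta * 30 * c, rel=1e-12)
        np.testing.assert_allclose(ens.site_marginals, 0.25, atol=1e-12)

    def test_marginal_normalization(self, table):
        ens = rq.ising_ensemble(rq.make_template("random", 15, seed=7), table)
        np.testing.assert_allclose(ens.site_marginals.sum(axis=1), 1.0, atol=1e-10)
        for i, joint in enumerate(ens.pair_marginals):
            np.testing.assert_allclose(joint.sum(axis=1), ens.site_marginals[i], atol=1e-10)
            np.testing.assert_allclose(joint.sum(axis=0), ens.site_marginals[i + 1], atol=1e-10)


class TestAgainstEnumeration:
    @pytest.mark.parametrize("seed", range(6))
    def test_random_table_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(2, 9))
        table = make_random_table(rng)
        t = rq.make_template("random", n, seed=200 + seed)
        ens = rq.ising_ensemble(t, table)
        enum = rq.enumerate_exact(t, table)
        assert ens.log_partition == pytest.approx(enum.log_partition, rel=1e-10, abs=1e-10)
        np.testing.assert_allclose(ens.site_marginals, enum.site_marginals, atol=1e-10)
        assert ens.internal_energy == pytest.approx(enum.internal_energy, rel=1e-10, abs=1e-10)
        # S from (U - F)/T agrees with -sum p ln p over all 4^n strands
        assert ens.entropy_nats == pytest.approx(enum.entropy_nats, abs=1e-9)

    def test_enumeration_against_independent_summation_order(self, table, thermo):
        """The oracle itself cross-checked: per-strand loop in pure Python."""
        import itertools

        t = rq.make_template("random", 5, seed=11)
        enum = rq.enumerate_exact(t, table)
        eps0 = rq.derive_pair_energies(table)
        xs = t.indices()
        zs = 0.0
        for combo in itertools.product(range(4), repeat=5):
            e = eps0[xs[0], combo[0]]
            for i in range(1, 5):
                e += table.nn[xs[i - 1], combo[i - 1], xs[i], combo[i]]
            zs += np.exp(-thermo.beta * e)
        assert enum.log_partition == pytest.approx(np.log(zs), rel=1e-12)

    def test_conditional_matches_enumeration(self, table):
        t = rq.make_template("random", 6, seed=12)
        ens = rq.ising_ensemble(t, table)
        enum = rq.enumerate_exact(t, table)
        for i in (2, 4, 6):
            joint = enum.pair_marginal(i - 1)
            for prev in range(4):
                expected = joint[prev] / joint[prev].sum()
                got = rq.ising_conditional(ens, i, prev)
                np.testing.assert_allclose(got, expected, atol=1e-10)
                assert got.sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_site_conditional_closed_form(self, thermo):
        rng = np.random.default_rng(13)
        table = make_random_table(rng)
        t = rq.TemplateSequence("AG")
        ens = rq.ising_ensemble(t, table)
        xs = t.indices()
        prev = 2
        w = np.exp(-thermo.beta * table.nn[xs[0], prev, xs[1], :])
        np.testing.assert_allclose(
            rq.ising_conditional(ens, 2, prev), w / w.sum(), rtol=1e-10
        )

    def test_conditional_position_range(self, table):
        ens = rq.ising_ensemble(rq.TemplateSequence("ACG"), table)
        with pytest.raises(ValueError):
            rq.ising_conditional(ens, 1, 0)
        with pytest.raises(ValueError):
            rq.ising_conditional(ens, 4, 0)

    def test_enumeration_length_cap(self, table):
        with pytest.raises(ValueError, match="N <= 10"):
            rq.enumerate_exact(rq.make_template("polyA", 11), table)


class TestIsingThermo:
    def test_delta_limit_entropy_vanishes(self):
        t = rq.make_template("random", 40, seed=14)
        res = rq.IsingReplication(t, table=make_delta_table()).fit()
        assert (res.per_prefix["s_per_nt_nats"].abs() < 1e-10).all()

    def test_uniform_energies_max_entropy(self):
        t = rq.make_template("random", 40, seed=15)
        res = rq.IsingReplication(t, table=make_constant_table(1.0)).fit()
        np.testing.assert_allclose(res.per_prefix["s_per_nt_nats"], LN4, atol=1e-12)

    def test_free_energy_identity_per_prefix(self, table, thermo):
        res = rq.IsingReplication(rq.make_template("random", 30, seed=16), table=table).fit()
        pp = res.per_prefix
        f_check = pp["U_total_kcal_mol"] - thermo.temperature * thermo.gas_constant * pp["S_total_nats"]
        np.testing.assert_allclose(pp["F_total_kcal_mol"], f_check, atol=1e-8)

    def test_finite_size_effect(self, table):
        """Per-nucleotide quantities at a fixed prefix depend on total length."""
        t20 = rq.make_template("random", 20, seed=17)
        t10 = rq.TemplateSequence(t20.symbols[:10], label="prefix10")
        full = rq.IsingReplication(t20, table=table).fit()
        short = rq.IsingReplication(t10, table=table).fit()
        # the length-10 chain is not the first 10 rows of the length-20 chain,
        # but the final row of the prefix run must equal the dedicated run
        assert full.per_prefix["s_per_nt_nats"].iloc[9] == pytest.approx(
            short.per_prefix["s_per_nt_nats"].iloc[9], rel=1e-10
        )
        marg_full = rq.ising_ensemble(t20, table).site_marginals[5]
        marg_short = rq.ising_ensemble(t10, table).site_marginals[5]
        assert np.abs(marg_full - marg_short).max() > 1e-8
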