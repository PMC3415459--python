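import numpy as np
import pytest

import repliq as rq
from repliq.alphabet import ALPHABET, WC_INDEX
from repliq.energy import DEFAULT_FILLED, MEASURED, _mirror

from conftest import make_constant_table


class TestThermoConditions:
    def test_beta_at_reference(self):
        th = rq.ThermoConditions()
        assert th.temperature == 310.15
        assert th.beta == pytest.approx(1.0 / (1.98720425e-3 * 310.15), rel=1e-12)

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            rq.ThermoConditions(temperature=0.0)


class TestBuiltinTable:
    def test_complete_with_measured_wc_stacks(self, table):
        assert table.is_complete
        assert table.n_entries() == 256
        wc_vals = {
            round(table.nn[x1, WC_INDEX[x1], x2, WC_INDEX[x2]], 6)
            for x1 in range(4)
            for x2 in range(4)
        }
        assert len(wc_vals) >= 10  # the ten unique published WC stacks

    def test_provenance_accounting(self, table):
        counts = table.provenance_counts()
        assert sum(counts.values()) == 256
        assert counts[MEASURED] >= 26  # 10 WC + >=16 mismatch stacks measured
        assert counts.get(DEFAULT_FILLED, 0) > 0

    def test_matches_published_dh_ds_at_37C(self, table):
        """The shipped dG37 values re-derive from the published dH/dS sets."""
        from Bio.SeqUtils import MeltingTemp as mt

        checked = 0
        for source in (mt.DNA_NN3, mt.DNA_IMM1):
            for key, (dh, ds) in source.items():
                if "/" not in key or "init" in key or key == "sym" or "I" in key:
                    continue
                top, bottom = key.split("/")
                expected = dh - 310.15 * ds / 1000.0
                # top strand is the copy read 5'->3', bottom the template 3'->5'
                got = table.nn_energy(bottom[0] + top[0], bottom[1] + top[1])
                assert got == pytest.approx(expected, abs=1e-9)
                checked += 1
        assert checked == 61

    def test_wc_pair_is_most_stable_per_template_symbol(self, table):
        for context in ("all_contexts", "wc_contexts"):
            eps0 = rq.derive_pair_energies(table, context=context)
            assert np.array_equal(eps0.argmin(axis=1), WC_INDEX)


class TestLoadAndExport:
    def test_duplicate_key_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text(
            "prev_x\tprev_y\tcur_x\tcur_y\tdG_kcal_mol\n"
            "A\tT\tC\tG\t-1.0\nA\tT\tC\tG\t-1.1\n"
        )
        with pytest.raises(ValueError, match="duplicate key"):
            rq.load_nn_table(str(p))

    def test_non_numeric_energy_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("prev_x\tprev_y\tcur_x\tcur_y\tdG_kcal_mol\nA\tT\tC\tG\tok\n")
        with pytest.raises(ValueError, match="non-numeric"):
            rq.load_nn_table(str(p))

    def test_export_load_roundtrip(self, table, tmp_path):
        p = tmp_path / "table.tsv"
        rq.export_table(table, str(p))
        back = rq.load_nn_table(str(p))
        assert back.n_entries() == 256
        np.testing.assert_allclose(back.nn, table.nn, rtol=0, atol=1e-9)
        assert (back.provenance == table.provenance).all()


class TestCompleteTable:
    def test_full_table_is_noop(self):
        t = make_constant_table(0.5)
        out = rq.complete_table(t)
        np.testing.assert_array_equal(out.nn, t.nn)
        assert DEFAULT_FILLED not in out.provenance_counts()

    def test_double_mismatch_fill_flagged(self):
        t = make_constant_table(-1.0)
        wc = set(zip(range(4), WC_INDEX))
        for px in range(4):
            for py in range(4):
                for cx in range(4):
                    for cy in range(4):
                        if (px, py) not in wc and (cx, cy) not in wc:
                            t.nn[px, py, cx, cy] = np.nan
                            t.provenance[px, py, cx, cy] = ""
        out = rq.complete_table(t, fill_value=1.0)
        assert out.is_complete
        filled = out.provenance == DEFAULT_FILLED
        assert np.all(out.nn[filled] == 1.0)
        assert filled.sum() == 144

    def test_symmetry_conflict_names_both_keys(self):
        t = make_constant_table(0.0)
        t.nn[0, 0, 1, 1] = 0.0
        t.nn[_mirror(0, 0, 1, 1)] = 0.5
        with pytest.raises(ValueError, match=r"prev=\(A·A\) cur=\(C·C\)"):
            rq.complete_table(t)


class TestValidateSymmetry:
    def test_builtin_is_symmetric(self, table):
        assert rq.validate_symmetry(table) == []

    def test_perturbation_reports_exactly_its_orbit(self, table):
        t = table.copy()
        key = (0, 1, 2, 3)  # prev A·C, cur G·T — not self-symmetric
        t.nn[key] += 0.1
        report = rq.validate_symmetry(t)
        assert len(report) == 1
        assert report[0]["key"] == "prev=(A·C) cur=(G·T)"
        assert report[0]["delta_kcal_mol"] == pytest.approx(0.1, abs=1e-9)

    def test_tiny_perturbation_within_tolerance(self, table):
        t = table.copy()
        t.nn[0, 1, 2, 3] += 1e-12
        assert rq.validate_symmetry(t) == []


class TestPairEnergies:
    def test_constant_table_gives_constant(self):
        t = make_constant_table(0.7)
        for context in ("all_contexts", "wc_contexts"):
            np.testing.assert_allclose(rq.derive_pair_energies(t, context), 0.7)

    def test_wc_context_mean_matches_hand_sum(self, table):
        # the four WC-context stacks under current pair (template C, copy G)
        listed = [table.nn_energy(p, "CG") for p in ("AT", "CG", "GC", "TA")]
        hand_mean = sum(listed) / 4.0
        eps0 = rq.derive_pair_energies(table, "wc_contexts")
        assert eps0[ALPHABET.index("C"), ALPHABET.index("G")] == pytest.approx(
            hand_mean, abs=1e-12
        )
        assert hand_mean == pytest.approx(-1.684595, abs=1e-6)

    def test_unknown_context_rejected(self, table):
        with pytest.raises(ValueError, match="context"):
            rq.derive_pair_energies(table, "sideways")
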