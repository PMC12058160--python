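import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

import methdriver as md
from methdriver import io, primary


def _tumor_cohort(n):
    t = tuple(f"T{i:03d}" for i in range(n))
    return md.AlignedCohort(samples=t, tumor=t, normal=())


def _deg_table(genes, flags=None, lfc=None):
    flags = flags if flags is not None else [True] * len(genes)
    lfc = lfc if lfc is not None else [1.0] * len(genes)
    return pd.DataFrame({
        "gene_symbol": genes, "log2fc": lfc, "p_value": 0.001, "fdr": 0.01,
        "direction": ["up" if x > 0 else "down" for x in lfc],
        "is_deg": flags})


class TestMutualInformation:
    @given(hnp.arrays(np.float64, 40,
                      elements=st.floats(-5, 5, allow_nan=False)))
    def test_symmetric(self, x):
        rng = np.random.default_rng(0)
        y = rng.normal(size=40)
        assert abs(primary.mutual_information(x, y)
                   - primary.mutual_information(y, x)) < 1e-12

    def test_self_information_is_maximal(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        mi_xx = primary.mutual_information(x, x)
        for _ in range(10):
            y = rng.normal(size=60)
            assert mi_xx >= primary.mutual_information(x, y)

    def test_constant_gene_has_zero_mi(self):
        x = np.full(30, 0.7)
        y = np.random.default_rng(2).normal(size=30)
        assert primary.mutual_information(x, y) == 0.0


class TestBuildGrn:
    def _expr_pair(self, x, y):
        cohort = _tumor_cohort(len(x))
        expr = pd.DataFrame([x, y], index=["X", "Y"],
                            columns=list(cohort.tumor))
        return expr, cohort

    def test_independent_edge_rejected_in_most_repetitions(self):
        rejected = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            expr, cohort = self._expr_pair(rng.uniform(size=200),
                                           rng.uniform(size=200))
            regs = primary.build_grn(expr, _deg_table(["X"]).pipe(
                lambda d: pd.concat([d, _deg_table(["Y"], [False])])
            ), cohort, seed=rep)
            reg = next(r for r in regs if r.regulator == "X")
            rejected += "Y" not in reg.targets
        assert rejected >= 0.9 * n_rep

    def test_identical_gene_edge_retained(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=200)
        expr, cohort = self._expr_pair(x, x.copy())
        regs = primary.build_grn(expr, _deg_table(["X", "Y"], [True, False]),
                                 cohort, seed=0)
        reg = next(r for r in regs if r.regulator == "X")
        assert "Y" in reg.targets

    def test_requires_eight_samples(self):
        rng = np.random.default_rng(4)
        expr, cohort = self._expr_pair(rng.uniform(size=5), rng.uniform(size=5))
        with pytest.raises(ValueError, match="8 samples"):
            primary.build_grn(expr, _deg_table(["X"]), cohort, seed=0)

    def test_no_self_target(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(size=100)
        expr, cohort = self._expr_pair(x, x + rng.normal(0, 0.01, 100))
        regs = primary.build_grn(expr, _deg_table(["X", "Y"]), cohort, seed=0)
        for r in regs:
            assert r.regulator not in r.targets


class TestRunUra:
    def _sigs(self, entries):
        return io.SignatureSet(processes=entries)

    def test_empty_intersection_scores_zero(self):
        regs = [md.Regulon("R", {"A": 1.0})]
        sigs = self._sigs({"proliferation": {"Z": "increase"}})
        ura = primary.run_ura(regs, _deg_table(["R", "A"]), sigs)
        assert ura.loc["R", "proliferation"] == 0.0

    def test_all_concordant_z(self):
        # 4 up-regulated targets, all expected to increase: z = 4/sqrt(4)
        regs = [md.Regulon("R", {f"A{i}": 1.0 for i in range(4)})]
        sigs = self._sigs({"proliferation": {f"A{i}": "increase"
                                             for i in range(4)}})
        degs = _deg_table(["R"] + [f"A{i}" for i in range(4)])
        ura = primary.run_ura(regs, degs, sigs)
        assert ura.loc["R", "proliferation"] == pytest.approx(2.0)

    def test_three_concordant_one_discordant_z(self):
        # s = (+1, +1, +1, -1): z = 2/sqrt(4) = 1.0
        regs = [md.Regulon("R", {f"A{i}": 1.0 for i in range(4)})]
        sigs = self._sigs({"proliferation": {f"A{i}": "increase"
                                             for i in range(4)}})
        degs = _deg_table(["R"] + [f"A{i}" for i in range(4)],
                          lfc=[1.0, 1.0, 1.0, 1.0, -1.0])
        ura = primary.run_ura(regs, degs, sigs)
        assert ura.loc["R", "proliferation"] == pytest.approx(1.0)

    def test_target_absent_from_deg_table_skipped(self):
        regs = [md.Regulon("R", {"A": 1.0, "GHOST": 1.0})]
        sigs = self._sigs({"proliferation": {"A": "increase",
                                             "GHOST": "increase"}})
        ura = primary.run_ura(regs, _deg_table(["R", "A"]), sigs)
        assert ura.loc["R", "proliferation"] == pytest.approx(1.0)


class TestRunPra:
    def _ura(self, zp, za):
        return pd.DataFrame({"proliferation": [zp], "apoptosis": [za]},
                            index=["G"])

    @pytest.mark.parametrize("zp,za,role", [
        (3.0, -3.0, "putative_OCG"),   # growth up, apoptosis down
        (-3.0, 3.0, "putative_TSG"),   # the mirrored pattern
    ])
    def test_role_patterns(self, zp, za, role):
        med = primary.run_pra(self._ura(zp, za), "proliferation", "apoptosis")
        assert list(med.putative_role) == [role]

    @pytest.mark.parametrize("zp,za", [(0.0, 0.0), (2.0, 2.0), (0.5, -0.5)])
    def test_non_mediator_patterns_excluded(self, zp, za):
        med = primary.run_pra(self._ura(zp, za), "proliferation", "apoptosis")
        assert med.empty

    def test_missing_process_is_error(self):
        with pytest.raises(KeyError):
            primary.run_pra(self._ura(1, -1), "proliferation", "autophagy")

    def test_no_gene_is_both_roles(self, default_run):
        med = default_run.primary.mediators
        assert not med.gene_symbol.duplicated().any()

    def test_recovers_planted_mediators(self, default_run, default_sim):
        """The URA/PRA chain recovers ≥80% of planted drivers as mediators
        with the correct putative role on the reference cohort."""
        med = default_run.primary.mediators.set_index("gene_symbol")
        truth = default_sim.truth
        planted = truth[truth.is_driver]
        correct = sum(
            1 for g, role in zip(planted.gene_symbol, planted.role)
            if g in med.index and med.loc[g, "putative_role"] == role)
        assert correct >= 0.8 * len(planted)


class TestLoadPra:
    def test_aliases(self, tmp_path):
        p = tmp_path / "pra.tsv"
        p.write_text("gene\trole\nBRCA1\tTSG\nMYC\tocg\n")
        med = primary.load_pra(p)
        assert list(med.putative_role) == ["putative_TSG", "putative_OCG"]

    def test_unknown_role_rejected(self, tmp_path):
        p = tmp_path / "pra.tsv"
        p.write_text("gene\trole\nX\toncogene?\n")
        with pytest.raises(io.FormatError):
            primary.load_pra(p)

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        p = tmp_path / "pra.tsv"
        p.write_text("")
        med = primary.load_pra(p)
        assert med.empty
        assert list(med.columns) == list(primary.MEDIATOR_COLUMNS)
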