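"""geNorm, the NormFinder-style index and set comparison against explicit-loop oracles."""

import numpy as np
import pandas as pd
import pytest

import refpick as rp
from tests.conftest import make_tpm


def brute_force_genorm_m(logexpr: pd.DataFrame, genes) -> dict[str, float]:
    """O(I^2 n) double loop over gene pairs with a hand-rolled n-1 SD."""
    out = {}
    for i in genes:
        vs = []
        for k in genes:
            if k == i:
                continue
            diff = [
                logexpr.loc[i, s] - logexpr.loc[k, s] for s in logexpr.columns
            ]
            m = sum(diff) / len(diff)
            sd = (sum((d - m) ** 2 for d in diff) / (len(diff) - 1)) ** 0.5
            vs.append(sd)
        out[i] = sum(vs) / len(vs)
    return out


def brute_force_normfinder(logexpr, genes, groups):
    """Explicit-loop two-way decomposition mirroring the documented contract."""
    genes = list(genes)
    I = len(genes)
    labels = sorted(set(groups[s] for s in logexpr.columns))
    by_group = {g: [s for s in logexpr.columns if groups[s] == g] for g in labels}
    var_shrunk, d_raw, n_g = {}, {}, {}
    for g in labels:
        ss = by_group[g]
        n = len(ss)
        n_g[g] = n
        raw = {}
        for i in genes:
            gene_mean = sum(logexpr.loc[i, s] for s in ss) / n
            acc = 0.0
            for s in ss:
                sample_mean = sum(logexpr.loc[k, s] for k in genes) / I
                grand = sum(logexpr.loc[k, t] for k in genes for t in ss) / (I * n)
                r = logexpr.loc[i, s] - gene_mean - sample_mean + grand
                acc += r * r
            raw[i] = acc / (n - 1)
        avg = sum(raw.values()) / I
        for i in genes:
            var_shrunk[(i, g)] = max(0.0, raw[i] - avg / (I - 1))
    all_samples = list(logexpr.columns)
    grand_all = sum(logexpr.loc[k, s] for k in genes for s in all_samples) / (
        I * len(all_samples)
    )
    for i in genes:
        overall_i = sum(logexpr.loc[i, s] for s in all_samples) / len(all_samples)
        for g in labels:
            ss = by_group[g]
            mean_ig = sum(logexpr.loc[i, s] for s in ss) / len(ss)
            mean_g = sum(logexpr.loc[k, s] for k in genes for s in ss) / (I * len(ss))
            d_raw[(i, g)] = (mean_ig - overall_i) - (mean_g - grand_all)
    rho = {}
    for i in genes:
        ds = [d_raw[(i, g)] for g in labels]
        sv = sum(var_shrunk[(i, g)] / n_g[g] for g in labels) / len(labels)
        mean_d = sum(ds) / len(ds)
        var_d = sum((d - mean_d) ** 2 for d in ds) / (len(ds) - 1)
        tau2 = max(0.0, var_d - sv)
        gamma = tau2 / (tau2 + sv) if (tau2 + sv) > 0 else 0.0
        rho[i] = sum(
            abs(d_raw[(i, g)] * gamma) + (var_shrunk[(i, g)] / n_g[g]) ** 0.5
            for g in labels
        ) / len(labels)
    return var_shrunk, d_raw, rho


class TestGenormM:
    def test_constant_offsets_give_zero(self):
        base = np.array([1.0, 3.0, 2.0, 4.0])
        logexpr = pd.DataFrame(
            {"s%d" % j: [base[j], base[j] + 2, base[j] - 1] for j in range(4)},
            index=["g1", "g2", "g3"],
        )
        M = rp.genorm_m(logexpr, ["g1", "g2", "g3"])
        np.testing.assert_allclose(M, 0.0, atol=1e-12)

    def test_hand_computed_three_gene_instance(self):
        logexpr = pd.DataFrame(
            [[1.0, 2.0], [2.0, 1.0], [0.0, 0.0]],
            index=["i", "k", "j"],
            columns=["s1", "s2"],
        )
        M = rp.genorm_m(logexpr, ["i", "k", "j"])
        # V_ik = SD(-1, 1) = sqrt(2); V_ij = SD(1, 2) = 0.7071...
        assert M["i"] == pytest.approx((np.sqrt(2) + np.sqrt(0.5)) / 2)
        assert M["i"] == pytest.approx(1.0606601717798212)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        logexpr = pd.DataFrame(
            rng.normal(5, 1, size=(10, 6)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(6)],
        )
        M = rp.genorm_m(logexpr, list(logexpr.index))
        oracle = brute_force_genorm_m(logexpr, list(logexpr.index))
        for g, val in oracle.items():
            assert M[g] == pytest.approx(val, rel=1e-12)

    def test_nonfinite_entry_named(self):
        logexpr = pd.DataFrame(
            [[1.0, 2.0], [np.nan, 1.0], [0.0, 0.0]],
            index=["a", "b", "c"],
            columns=["s1", "s2"],
        )
        with pytest.raises(ValueError, match="'b'.*'s1'"):
            rp.genorm_m(logexpr, ["a", "b", "c"])


class TestGenormRank:
    @staticmethod
    def _matrix(seed=0, shift_gene=None, shift=3.0):
        rng = np.random.default_rng(seed)
        logexpr = pd.DataFrame(
            rng.normal(6, 0.05, size=(4, 8)),
            index=["g1", "g2", "g3", "g4"],
            columns=[f"s{j}" for j in range(8)],
        )
        if shift_gene:
            logexpr.loc[shift_gene, logexpr.columns[4:]] += shift
        return logexpr

    def test_planted_shift_removed_first(self):
        logexpr = self._matrix(seed=1, shift_gene="g3")
        ranks, _ = rp.genorm_rank(logexpr, list(logexpr.index))
        assert ranks["g3"] == 4  # worst rank = removed first
        # oracle: its M on the full set is the largest by far
        M = rp.genorm_m(logexpr, list(logexpr.index))
        assert M["g3"] == M.max() and M["g3"] > 2 * M.drop("g3").max()

    def test_scalar_multiples_tie_break_lexicographic(self):
        base = np.array([1.0, 2.0, 4.0, 8.0])
        logexpr = pd.DataFrame(
            {f"s{j}": np.log2(base[j]) + np.array([0.0, 1.0, 2.0, 3.0]) for j in range(4)},
            index=["gA", "gB", "gC", "gD"],
        )
        ranks, v = rp.genorm_rank(logexpr, list(logexpr.index))
        # all ratios constant: removal order is purely lexicographic
        assert ranks["gA"] == 4 and ranks["gB"] == 3
        assert ranks["gC"] == 1 and ranks["gD"] == 1  # terminal pair shares rank
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_v_series_length(self):
        logexpr = self._matrix(seed=2)
        ranks, v = rp.genorm_rank(logexpr, list(logexpr.index))
        assert len(v) == len(logexpr) - 2
        assert sorted(ranks) == [1, 1, 3, 4]

    def test_sample_permutation_invariance(self):
        logexpr = self._matrix(seed=3, shift_gene="g2", shift=1.0)
        perm = ["s5", "s0", "s7", "s2", "s1", "s6", "s3", "s4"]
        r1, v1 = rp.genorm_rank(logexpr, list(logexpr.index))
        r2, v2 = rp.genorm_rank(logexpr[perm], list(logexpr.index))
        pd.testing.assert_series_equal(r1, r2)
        np.testing.assert_allclose(v1, v2, rtol=1e-12)


class TestNormfinder:
    GROUPS6 = {f"s{j}": ("A" if j < 3 else "B") for j in range(6)}

    def test_constant_genes_perfectly_stable(self):
        logexpr = pd.DataFrame(
            np.tile([[5.0], [6.0], [7.0]], (1, 6)),
            index=["g1", "g2", "g3"],
            columns=[f"s{j}" for j in range(6)],
        )
        comp = rp.normfinder_stability(logexpr, list(logexpr.index), self.GROUPS6)
        np.testing.assert_allclose(comp["stability"], 0.0, atol=1e-12)

    def test_sample_mean_gene_has_zero_intra_variance(self):
        rng = np.random.default_rng(5)
        base = pd.DataFrame(
            rng.normal(5, 1, size=(4, 6)),
            index=["g1", "g2", "g3", "g4"],
            columns=[f"s{j}" for j in range(6)],
        )
        base.loc["gmean"] = base.mean(axis=0)  # equals the all-gene sample mean
        comp = rp.normfinder_stability(base, list(base.index), self.GROUPS6)
        for col in ("intra_sd:A", "intra_sd:B"):
            assert comp.loc["gmean", col] == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(9)
        logexpr = pd.DataFrame(
            rng.normal(6, 0.5, size=(5, 6)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(6)],
        )
        comp = rp.normfinder_stability(logexpr, list(logexpr.index), self.GROUPS6)
        var_o, d_o, rho_o = brute_force_normfinder(
            logexpr, list(logexpr.index), self.GROUPS6
        )
        for i in logexpr.index:
            assert comp.loc[i, "intra_sd:A"] ** 2 == pytest.approx(
                var_o[(i, "A")], abs=1e-12
            )
            assert comp.loc[i, "intra_sd:B"] ** 2 == pytest.approx(
                var_o[(i, "B")], abs=1e-12
            )
            assert comp.loc[i, "stability"] == pytest.approx(rho_o[i], rel=1e-10)

    def test_single_group_reduces_to_intra_sd(self):
        rng = np.random.default_rng(4)
        logexpr = pd.DataFrame(
            rng.normal(5, 0.3, size=(4, 4)),
            index=["g1", "g2", "g3", "g4"],
            columns=[f"s{j}" for j in range(4)],
        )
        groups = {s: "only" for s in logexpr.columns}
        comp = rp.normfinder_stability(logexpr, list(logexpr.index), groups)
        np.testing.assert_allclose(
            comp["stability"], comp["intra_sd:only"], rtol=1e-12
        )

    def test_small_group_rejected(self):
        logexpr = pd.DataFrame(
            np.ones((3, 3)), index=["a", "b", "c"], columns=["s0", "s1", "s2"]
        )
        groups = {"s0": "A", "s1": "A", "s2": "B"}
        with pytest.raises(ValueError, match="fewer than 2"):
            rp.normfinder_stability(logexpr, ["a", "b", "c"], groups)

    def test_planted_group_shift_is_least_stable(self):
        """A gene shifted >=1 log2 unit between groups gets the worst rho and
        geNorm rank in >=19/20 seeded replicates."""
        hits_rho = hits_rank = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            logexpr = pd.DataFrame(
                rng.normal(6, 0.05, size=(8, 8)),
                index=[f"g{i}" for i in range(8)],
                columns=[f"s{j}" for j in range(8)],
            )
            logexpr.loc["g0", logexpr.columns[4:]] += 1.0
            groups = {f"s{j}": ("A" if j < 4 else "B") for j in range(8)}
            comp = rp.normfinder_stability(logexpr, list(logexpr.index), groups)
            ranks, _ = rp.genorm_rank(logexpr, list(logexpr.index))
            hits_rho += comp["stability"].idxmax() == "g0"
            hits_rank += ranks["g0"] == ranks.max()
        assert hits_rho >= 19
        assert hits_rank >= 19


class TestNormalizationInvariance:
    def test_sample_constant_shift_leaves_m_and_rho_unchanged(self):
        rng = np.random.default_rng(8)
        logexpr = pd.DataFrame(
            rng.normal(5, 0.4, size=(5, 6)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(6)],
        )
        shifts = rng.normal(0, 2, size=6)
        shifted = logexpr + shifts[None, :]
        groups = {f"s{j}": ("A" if j < 3 else "B") for j in range(6)}
        np.testing.assert_allclose(
            rp.genorm_m(logexpr, list(logexpr.index)),
            rp.genorm_m(shifted, list(logexpr.index)),
            rtol=1e-9,
        )
        c1 = rp.normfinder_stability(logexpr, list(logexpr.index), groups)
        c2 = rp.normfinder_stability(shifted, list(logexpr.index), groups)
        np.testing.assert_allclose(c1["stability"], c2["stability"], rtol=1e-8, atol=1e-12)


class TestCompareReferenceSets:
    def test_custom_set_beats_background_panel(self, sim42, tpm42, refs42):
        _, _, truth = sim42
        rng = np.random.default_rng(0)
        bg = truth.genes.index[truth.genes["label"] == "background"]
        panel = rp.GeneList("panel", list(rng.choice(bg, size=14, replace=False)))
        reports = rp.compare_reference_sets(
            tpm42, truth.groups, [panel], custom=refs42
        )
        assert (
            reports["custom"].summary["stability_median"]
            < reports["panel"].summary["stability_median"]
        )
        assert (
            reports["custom"].summary["cv_median"]
            < reports["panel"].summary["cv_median"]
        )

    def test_zero_count_gene_kept_only_in_cv_block(self):
        rng = np.random.default_rng(2)
        tpm = pd.DataFrame(
            rng.uniform(10, 100, size=(6, 6)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(6)],
        )
        tpm.loc["g5", "s0"] = 0.0
        groups = {f"s{j}": ("A" if j < 3 else "B") for j in range(6)}
        with pytest.warns(UserWarning, match="zeros"):
            reports = rp.compare_reference_sets(
                tpm, groups, [rp.GeneList("demo", list(tpm.index))]
            )
        row = reports["demo"].table.loc["g5"]
        assert np.isfinite(row["cv_percent"])
        assert np.isnan(row["stability"]) and np.isnan(row["genorm_m"])

    def test_identical_sets_identical_reports(self, sim42, tpm42, refs42):
        _, _, truth = sim42
        ids = refs42.gene_ids[:10]
        s1, s2 = rp.GeneList("one", list(ids)), rp.GeneList("two", list(ids))
        reports = rp.compare_reference_sets(tpm42, truth.groups, [s1, s2])
        pd.testing.assert_frame_equal(reports["one"].table, reports["two"].table)
        assert reports["one"].pairwise_variation == reports["two"].pairwise_variation

    def test_tiny_set_skipped_with_warning(self):
        rng = np.random.default_rng(1)
        tpm = pd.DataFrame(
            rng.uniform(10, 100, size=(3, 4)),
            index=["a", "b", "c"],
            columns=[f"s{j}" for j in range(4)],
        )
        tpm.loc["b", "s0"] = 0.0
        tpm.loc["c", "s1"] = 0.0
        groups = {f"s{j}": ("A" if j < 2 else "B") for j in range(4)}
        with pytest.warns(UserWarning, match="fewer than 3 usable"):
            reports = rp.compare_reference_sets(
                tpm, groups, [rp.GeneList("tiny", ["a", "b", "c"])]
            )
        assert reports["tiny"].table["stability"].isna().all()

    def test_unknown_gene_rejected(self, tpm42, sim42):
        _, _, truth = sim42
        with pytest.raises(KeyError, match="nope"):
            rp.compare_reference_sets(
                tpm42, truth.groups, [rp.GeneList("bad", ["nope", "x", "y"])]
            )
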