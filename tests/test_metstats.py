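"""Turnover, screens, Spearman/FDR machinery vs independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ulvaphen.metstats import (
    MetstatsError,
    adjust_fdr,
    biomarker_screen,
    night_consumption_screen,
    significance_tier,
    spearman,
    spearman_matrix,
    turnover,
    turnover_table,
)
from ulvaphen.synthetic import MetaboliteConfig, SimConfig, simulate_metabolite_matrix


def rank_pearson_oracle(x, y):
    """Brute-force Spearman: Pearson on explicitly averaged ranks."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


class TestTurnover:
    def test_consumed_positive(self):
        assert turnover(10.0, 4.0) == 6.0

    def test_balanced_zero(self):
        assert turnover(3.3, 3.3) == 0.0

    @given(a=st.floats(0, 1e6), b=st.floats(0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, a, b):
        assert turnover(a, b) == -turnover(b, a)

    def test_missing_pairs_excluded_with_note(self):
        matrix = pd.DataFrame(
            {
                "strain_id": ["s0", "s0", "s1"],
                "metabolite": ["glycine", "glycine", "glycine"],
                "timepoint": ["EOD", "EON", "EOD"],
                "value": [5.0, 2.0, 4.0],
            }
        )
        table, notes = turnover_table(matrix)
        assert table.loc["s0", "glycine"] == 3.0
        assert any("missing a pair" in n for n in notes)


class TestNightConsumptionScreen:
    @staticmethod
    def _long(values):
        rows = []
        for met, (eod, eon) in values.items():
            for s, (a, b) in enumerate(zip(eod, eon)):
                rows.append({"strain_id": f"s{s}", "metabolite": met, "timepoint": "EOD", "value": a})
                rows.append({"strain_id": f"s{s}", "metabolite": met, "timepoint": "EON", "value": b})
        return pd.DataFrame(rows)

    def test_fourfold_drop_included(self):
        m = self._long({"glucose": ([8.0, 8.0], [2.0, 2.0]), "proline": ([5.0, 5.0], [5.0, 5.0])})
        screen, _ = night_consumption_screen(m)
        by = screen.set_index("metabolite")
        assert by.loc["glucose", "log2fc"] == pytest.approx(2.0)
        assert bool(by.loc["glucose", "consumed"])
        assert not bool(by.loc["proline", "consumed"])

    def test_all_zero_metabolite_excluded(self):
        m = self._long({"ribose": ([0.0, 0.0], [0.0, 0.0])})
        screen, notes = night_consumption_screen(m)
        assert screen.empty
        assert any("all-zero" in n for n in notes)

    def test_zero_mean_offset_keeps_screen_defined(self):
        m = self._long({"xylose": ([4.0, 4.0], [0.0, 0.0])})
        screen, _ = night_consumption_screen(m)
        # EON offset by half the smallest nonzero value (2.0): log2(4/2)=1
        assert screen["log2fc"].iloc[0] == pytest.approx(1.0)

    def test_planted_17_recovered_noiselessly(self):
        cfg = SimConfig(seed=2, n_strains=16, metabolites=MetaboliteConfig(abundance_sigma=0.0))
        matrix, gt = simulate_metabolite_matrix(cfg, np.linspace(0.1, 0.3, 16))
        screen, _ = night_consumption_screen(matrix)
        hits = set(screen.loc[screen["consumed"], "metabolite"])
        assert hits == set(gt.night_consumed)
        assert len(hits) == 17

    def test_monotone_transform_invariance_of_rank_screens(self):
        cfg = SimConfig(seed=4, n_strains=16)
        rgr = np.linspace(0.1, 0.3, 16)
        matrix, _ = simulate_metabolite_matrix(cfg, rgr)
        res1 = biomarker_screen(matrix, pd.Series(rgr, index=[f"strain{i:02d}" for i in range(16)]))
        matrix2 = matrix.assign(value=np.log1p(matrix["value"]))
        res2 = biomarker_screen(matrix2, pd.Series(rgr, index=[f"strain{i:02d}" for i in range(16)]))
        eod = res1["family"] != "diff"
        # EOD/EON decisions are rank-based, hence invariant; the diff
        # family is computed on raw differences and may change
        assert np.allclose(
            res1.loc[eod, "rho"].to_numpy(), res2.loc[eod, "rho"].to_numpy(), equal_nan=True
        )


class TestSpearman:
    def test_monotone_invariance_rho_one(self):
        x = np.array([0.1, 0.5, 1.2, 2.0, 3.3, 4.0])
        rho, p, n = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert n == 6

    def test_reversal_rho_minus_one(self):
        x = np.arange(6.0)
        rho, _, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_constant_variable_undefined(self):
        rho, p, _ = spearman(np.ones(6), np.arange(6.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_pairwise_complete(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([2.0, 3.0, 9.0, 5.0, np.nan, 7.0])
        rho, _, n = spearman(x, y)
        assert n == 4 and rho == pytest.approx(1.0)

    def test_matches_rank_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            n = rng.integers(4, 9)
            x = rng.integers(0, 4, n).astype(float)  # heavy ties
            y = rng.normal(size=n) + x
            if np.all(x == x[0]):
                continue
            rho, _, _ = spearman(x, y)
            assert rho == pytest.approx(rank_pearson_oracle(x, y), abs=1e-12)


class TestFDR:
    def test_bh_hand_computed_step_up(self):
        q = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.all(adjust_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_monotone_and_order_invariant(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        q = adjust_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        perm = rng.permutation(50)
        assert np.allclose(adjust_fdr(p[perm]), q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(MetstatsError):
            adjust_fdr([0.5, 1.5])

    def test_storey_no_larger_than_bh(self):
        rng = np.random.default_rng(6)
        p = np.concatenate([rng.uniform(0, 0.01, 20), rng.uniform(size=80)])
        q_bh = adjust_fdr(p, "bh")
        q_st = adjust_fdr(p, "storey")
        assert np.all(q_st <= q_bh + 1e-12)

    def test_nan_propagates(self):
        q = adjust_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_tiers(self):
        assert significance_tier(0.0005) == "***"
        assert significance_tier(0.005) == "**"
        assert significance_tier(0.02) == "*"
        assert significance_tier(0.2) == ""


class TestSpearmanMatrix:
    def test_all_pairs_emitted_with_family_fdr(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        out = spearman_matrix(table)
        assert len(out) == 10  # 5 choose 2
        assert {"rho", "p", "q", "tier"}.issubset(out.columns)

    def test_constant_column_reported_undefined(self):
        table = pd.DataFrame({"a": np.arange(6.0), "b": np.ones(6)})
        out = spearman_matrix(table)
        assert np.isnan(out["rho"].iloc[0])


class TestBiomarkerScreen:
    @staticmethod
    def _run(seed, planted=True, n_strains=16):
        met = MetaboliteConfig() if planted else MetaboliteConfig(planted_eod={}, planted_eon={})
        cfg = SimConfig(seed=seed, n_strains=n_strains, metabolites=met)
        rng = np.random.default_rng(seed + 10_000)
        rgr = rng.normal(0.209, 0.062, n_strains).clip(0.05, 0.45)
        matrix, gt = simulate_metabolite_matrix(cfg, rgr)
        res = biomarker_screen(matrix, pd.Series(rgr, index=[f"strain{i:02d}" for i in range(n_strains)]))
        return res, gt

    def test_planted_biomarkers_recovered_with_signs(self):
        res, gt = self._run(seed=17)
        sig = res[res["significant"]]
        for _, eff in gt.metabolite_effects.iterrows():
            hit = sig[(sig["metabolite"] == eff["metabolite"]) & (sig["family"] == eff["timepoint"])]
            assert len(hit) == 1
            assert np.sign(hit["rho"].iloc[0]) == eff["sign"]

    def test_null_matrix_mostly_clean(self):
        flagged = 0
        for seed in range(40, 60):
            res, _ = self._run(seed=seed, planted=False)
            flagged += int(res["significant"].sum())
        # BH at 5% over 20 null screens of 3 families: expect ~0-3 total
        assert flagged <= 10

    def test_turnover_family_present(self):
        res, _ = self._run(seed=99)
        assert set(res["family"]) == {"EOD", "EON", "diff"}
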