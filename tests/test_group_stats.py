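"""Rank-sum tests, BH FDR, region-pair screening and biomarker selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import eegspatcorr as esc
from eegspatcorr.group_stats import fdr_bh, ranksum_one_tailed


def exact_ranksum_oracle(x, y, direction="less"):
    """Brute-force permutation enumeration of the one-sided rank-sum p."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    n1 = len(x)
    obs = ranks[:n1].sum()
    count = total = 0
    for subset in itertools.combinations(range(len(combined)), n1):
        s = ranks[list(subset)].sum()
        total += 1
        if direction == "less":
            count += s <= obs
        else:
            count += s >= obs
    return count / total


def bh_oracle(pvalues, q):
    """Literal step-up definition of Benjamini-Hochberg rejection."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = -1
    for k in range(m):
        if p[order[k]] <= (k + 1) / m * q:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    if k_max >= 0:
        reject[order[: k_max + 1]] = True
    return reject


class TestRankSum:
    @pytest.mark.parametrize("direction", ["less", "greater"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_matches_enumeration_oracle(self, direction, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.0, 1.0, 5)
        y = rng.normal(0.5, 1.0, 7)
        ours = ranksum_one_tailed(x, y, direction)
        assert ours == pytest.approx(exact_ranksum_oracle(x, y, direction), abs=1e-12)

    def test_shifted_sample_is_detected(self):
        rng = np.random.default_rng(42)
        x = rng.normal(-1.0, 0.3, 8)
        y = rng.normal(1.0, 0.3, 8)
        assert ranksum_one_tailed(x, y, "less") < 0.001
        assert ranksum_one_tailed(x, y, "greater") > 0.999

    def test_one_sided_directions_complementary(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 6)
        y = rng.normal(0, 1, 6)
        p_lo = ranksum_one_tailed(x, y, "less")
        p_hi = ranksum_one_tailed(x, y, "greater")
        # exact one-sided p-values overlap only at the observed statistic
        assert p_lo + p_hi > 1.0
        assert p_lo + p_hi < 1.1

    def test_degenerate_identical_samples(self):
        with pytest.warns(UserWarning, match="identical"):
            p = ranksum_one_tailed([1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 0.5

    def test_ties_use_corrected_asymptotic(self):
        # ties force the tie-corrected normal approximation; p stays in (0, 1)
        x = [1.0, 2.0, 2.0, 3.0, 7.0]
        y = [2.0, 3.0, 3.0, 4.0, 9.0]
        p = ranksum_one_tailed(x, y, "less")
        assert 0.0 < p < 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            ranksum_one_tailed([], [1.0])

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            ranksum_one_tailed([1.0], [2.0], "two-sided")


class TestFdrBH:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 40) ** 2
        np.testing.assert_array_equal(fdr_bh(p, 0.05), bh_oracle(p, 0.05))

    def test_textbook_example(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205])
        # k/m * q thresholds at q=0.05: 0.00625, 0.0125, ... 0.05; largest k
        # with p_(k) <= threshold is k=5 (0.042 <= 0.03125? no; check oracle)
        np.testing.assert_array_equal(fdr_bh(p, 0.05), bh_oracle(p, 0.05))

    def test_all_null_rejects_nothing(self):
        p = np.linspace(0.2, 0.9, 20)
        assert not fdr_bh(p, 0.05).any()

    def test_empty_family(self):
        assert fdr_bh([], 0.05).size == 0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.1, 1.2], 0.05)


def _toy_montage():
    """Two 2-channel regions on the unit sphere (positions arbitrary)."""
    angles = {"A1": 0.0, "A2": 0.5, "B1": 1.5, "B2": 2.0}
    positions = {
        ch: np.array([np.cos(a), np.sin(a), 0.0]) for ch, a in angles.items()
    }
    return esc.Montage(positions, {"front": ("A1", "A2"), "back": ("B1", "B2")})


def _toy_table(exp_shift=0.0, n_exp=5, n_ctrl=5, seed=0):
    """Pair table for the toy montage; experimental group shifted by exp_shift."""
    rng = np.random.default_rng(seed)
    montage = _toy_montage()
    pairs = esc.region_channel_pairs(montage, "front", "back")
    rows = []
    for i in range(n_exp + n_ctrl):
        pid = f"s{i + 1}"
        is_exp = i < n_exp
        for a, b in pairs:
            for condition in ("eyes_closed", "eyes_open"):
                base = 0.8 + 0.05 * rng.standard_normal()
                if is_exp and condition == "eyes_closed":
                    base += exp_shift
                rows.append(
                    {
                        "participant": pid,
                        "channel_a": a,
                        "channel_b": b,
                        "carrier_band": "theta",
                        "envelope_band": "infraslow",
                        "condition": condition,
                        "m_psi": float(np.clip(base, 0, 1)),
                        "n_samples": 100,
                    }
                )
    groups = {
        f"s{i + 1}": ("Exp" if i < n_exp else "Ctrl") for i in range(n_exp + n_ctrl)
    }
    return montage, pd.DataFrame(rows), groups


class TestRegionPairScreen:
    def test_planted_decrease_is_found(self):
        montage, table, groups = _toy_table(exp_shift=-0.3)
        comps = esc.region_pair_screen(table, montage, groups, ("Exp", "Ctrl"))
        cells = {(c.carrier_band, c.condition): c for c in comps}
        hit = cells[("theta", "eyes_closed")]
        assert hit.frac_lower == 1.0
        assert cells[("theta", "eyes_open")].frac_lower == 0.0

    def test_null_table_mostly_quiet(self):
        montage, table, groups = _toy_table(exp_shift=0.0)
        comps = esc.region_pair_screen(table, montage, groups, ("Exp", "Ctrl"))
        total_flags = sum(
            c.flags_lower.sum() + c.flags_higher.sum() for c in comps
        )
        assert total_flags == 0

    def test_too_small_group_rejected(self):
        montage, table, groups = _toy_table()
        groups = dict(groups)
        lone = {k: v for k, v in groups.items() if v == "Ctrl" or k == "s1"}
        with pytest.raises(ValueError, match=">= 2"):
            esc.region_pair_screen(table, montage, lone, ("Exp", "Ctrl"))

    def test_missing_rows_reported(self):
        montage, table, groups = _toy_table()
        broken = table[table["participant"] != "s3"]
        with pytest.raises(ValueError, match="missing|no M_psi"):
            esc.region_pair_screen(broken, montage, groups, ("Exp", "Ctrl"))

    def test_global_family_is_stricter_or_equal(self):
        montage, table, groups = _toy_table(exp_shift=-0.12, seed=3)
        per_cell = esc.region_pair_screen(
            table, montage, groups, ("Exp", "Ctrl"), family="region_pair"
        )
        pooled = esc.region_pair_screen(
            table, montage, groups, ("Exp", "Ctrl"), family="global"
        )
        n_cell = sum(c.flags_lower.sum() for c in per_cell)
        n_pool = sum(c.flags_lower.sum() for c in pooled)
        # pooling dilutes a localized effect across many null tests
        assert n_pool <= n_cell


class TestSelectBiomarker:
    def test_winner_has_smallest_p_in_best_cell(self):
        montage, table, groups = _toy_table(exp_shift=-0.3)
        comps = esc.region_pair_screen(table, montage, groups, ("Exp", "Ctrl"))
        sel = esc.select_biomarker(comps)
        assert sel.found
        assert sel.condition == "eyes_closed"
        assert sel.region_pair == ("front", "back")
        best = [c for c in comps if c.condition == "eyes_closed"][0]
        assert sel.p_value == pytest.approx(best.min_p_lower)
        assert sel.channel_pair in best.pairs

    def test_nothing_significant_returns_not_found(self):
        montage, table, groups = _toy_table(exp_shift=0.0)
        comps = esc.region_pair_screen(table, montage, groups, ("Exp", "Ctrl"))
        sel = esc.select_biomarker(comps)
        assert not sel.found

    def test_direction_higher(self):
        montage, table, groups = _toy_table(exp_shift=-0.3)
        comps = esc.region_pair_screen(table, montage, groups, ("Exp", "Ctrl"))
        sel = esc.select_biomarker(comps, direction="higher")
        # the planted effect is a decrease; the increase direction finds nothing
        assert not sel.found
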