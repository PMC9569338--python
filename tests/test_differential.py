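import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kinoscope import differential as d, preprocess as pp, simulate as sim
from kinoscope.errors import ValidationError

from conftest import matrix_from_values, run_to_log2fc, make_config


def exact_signed_rank_p(diffs) -> float:
    """Independent oracle: exhaustive enumeration over all 2^n sign patterns.

    Assumes no zero differences. Two-sided p = fraction of sign patterns whose
    W+ is at least as far from the null mean n(n+1)/4 as the observed one.
    """
    diffs = np.asarray(diffs, dtype=float)
    assert np.all(diffs != 0)
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    center = n * (n + 1) / 4.0
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if abs(w - center) >= abs(w_obs - center) - 1e-12:
            count += 1
    return count / 2.0**n


class TestLog2FC:
    def test_exact_doubling(self):
        m = matrix_from_values(
            {
                ("case", "c1"): [2.0], ("case", "c2"): [2.0], ("case", "c3"): [2.0],
                ("ctrl", "c1"): [1.0], ("ctrl", "c2"): [1.0], ("ctrl", "c3"): [1.0],
            }
        )
        lfc = d.log2fc(m, "case", "ctrl")
        row = lfc.iloc[0]
        for chip in ("c1", "c2", "c3"):
            assert row[f"log2fc_{chip}"] == pytest.approx(1.0)
        assert row["mean_log2fc"] == pytest.approx(1.0)
        assert row["classification"] == "up"

    def test_identity_unchanged(self):
        m = matrix_from_values(
            {("case", "c1"): [3.0, 1.0], ("ctrl", "c1"): [3.0, 1.0]}
        )
        lfc = d.log2fc(m, "case", "ctrl")
        assert (lfc["mean_log2fc"] == 0).all()
        assert (lfc["classification"] == "unchanged").all()

    def test_mean_is_mean_of_chips(self):
        m = matrix_from_values(
            {
                ("case", "c1"): [2.0], ("case", "c2"): [3.0],
                ("ctrl", "c1"): [1.0], ("ctrl", "c2"): [1.0],
            }
        )
        lfc = d.log2fc(m, "case", "ctrl").iloc[0]
        assert lfc["mean_log2fc"] == pytest.approx((1.0 + 2.0) / 2)

    def test_chip_missing_one_group_warns_and_omits(self):
        m = matrix_from_values(
            {
                ("case", "c1"): [2.0], ("case", "c2"): [5.0],
                ("ctrl", "c1"): [1.0],
            }
        )
        with pytest.warns(UserWarning, match="omitted"):
            lfc = d.log2fc(m, "case", "ctrl")
        assert list(c for c in lfc.columns if c.startswith("log2fc_")) == ["log2fc_c1"]

    def test_group_absent_everywhere_errors(self):
        m = matrix_from_values({("case", "c1"): [2.0], ("ctrl", "c1"): [1.0]})
        with pytest.raises(ValidationError, match="absent"):
            d.log2fc(m, "case", "nosuch")

    def test_synthetic_multiplier_propagates(self):
        mult = 2.0 ** 0.3
        cfg = make_config(noise_cv=0.0, n_low_signal_peptides=0, seed=19,
                          active_kinases={"synaptosomal": {"KIN01": mult}})
        out = run_to_log2fc(cfg)
        kmap = out["kmap"]
        k1 = set(kmap[kmap["kinase"] == "KIN01"]["peptide_id"])
        others = set(kmap[kmap["kinase"] != "KIN01"]["peptide_id"])
        exclusive = sorted(k1 - others)
        assert exclusive  # scenario must exercise the claim
        lfc = out["lfc"].set_index("peptide_id")
        assert np.allclose(lfc.loc[exclusive, "mean_log2fc"], 0.3, atol=1e-9)
        assert (lfc.loc[exclusive, "classification"] == "up").all()

    def test_antisymmetry(self):
        cfg = make_config(seed=29)
        out = run_to_log2fc(cfg)
        fwd = out["lfc"].set_index("peptide_id")
        rev = d.log2fc(out["matrix"], "nuclear", "synaptosomal").set_index("peptide_id")
        cols = [c for c in fwd.columns if c.startswith("log2fc_")] + ["mean_log2fc"]
        for c in cols:
            assert np.allclose(fwd[c], -rev[c], atol=0)
        up_fwd = set(fwd.index[fwd["classification"] == "up"])
        down_rev = set(rev.index[rev["classification"] == "down"])
        assert up_fwd == down_rev

    def test_scale_invariance(self):
        cfg = make_config(seed=37, n_low_signal_peptides=0)
        out = run_to_log2fc(cfg)
        kmap = out["kmap"]
        scaled = out["series"].assign(intensity=out["series"]["intensity"] * 10)
        slopes = pp.fit_slopes(scaled)
        qc = pp.apply_qc(slopes)
        m2 = pp.build_signal_matrix(slopes, qc.keep)
        lfc2 = d.log2fc(m2, "synaptosomal", "nuclear")
        pd.testing.assert_frame_equal(out["lfc"], lfc2, atol=1e-9, rtol=0)

    def test_reclassify(self):
        lfc = pd.DataFrame({"peptide_id": ["p1", "p2"], "mean_log2fc": [0.18, 0.25],
                            "classification": ["up", "up"]})
        re = d.log2fc_reclassify(lfc, 0.2)
        assert re["classification"].tolist() == ["unchanged", "up"]


class TestGlobalTest:
    def test_identical_paired_p_is_one(self):
        m = matrix_from_values({("A", "c1"): [1.0, 2.0, 3.0], ("B", "c1"): [1.0, 2.0, 3.0]})
        res = d.global_test(m, ("A", "B"), paired=True)
        assert res.test == "signed_rank"
        assert res.p_value == 1.0

    def test_all_positive_n10_exact(self):
        vals = np.arange(1.0, 11.0)
        m = matrix_from_values({("A", "c1"): list(vals + 0.5), ("B", "c1"): list(vals)})
        res = d.global_test(m, ("A", "B"), paired=True)
        assert res.p_value == pytest.approx(2 / 1024)

    @pytest.mark.parametrize("n", [4, 6, 8, 10, 12])
    def test_signed_rank_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        diffs = rng.normal(size=n)
        diffs[diffs == 0] = 0.1
        base = rng.uniform(1, 5, size=n)
        m = matrix_from_values({("A", "c1"): list(base + diffs), ("B", "c1"): list(base)})
        res = d.global_test(m, ("A", "B"), paired=True)
        assert res.p_value == pytest.approx(exact_signed_rank_p(diffs), abs=1e-12)

    def test_too_few_pairs(self):
        m = matrix_from_values({("A", "c1"): [1.0, 2.0], ("B", "c1"): [2.0, 1.0]})
        with pytest.raises(ValidationError, match=">= 3"):
            d.global_test(m, ("A", "B"), paired=True)

    def test_rank_sum_type_one_error(self):
        # Monte-Carlo calibration at alpha = 0.05
        rng = np.random.default_rng(123)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            xa = rng.normal(size=30)
            xb = rng.normal(size=30)
            m = matrix_from_values({("A", "c1"): list(xa), ("B", "c1"): list(xb)})
            res = d.global_test(m, ("A", "B"), paired=False)
            if res.p_value < 0.05:
                rejections += 1
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)

    def test_rank_sum_reports_group_means(self):
        m = matrix_from_values({("A", "c1"): [1.0, 3.0], ("B", "c1"): [2.0, 6.0]})
        res = d.global_test(m, ("A", "B"), paired=False)
        assert res.group_means == {"A": 2.0, "B": 4.0}


class TestCVReport:
    def slopes(self, signals_by_chip, group="A", peptide="p1"):
        rows = [
            (peptide, group, f"c{i + 1}", s / 100, 0.0, 1.0, "", 300.0, float(s))
            for i, s in enumerate(signals_by_chip)
        ]
        return pd.DataFrame(
            rows,
            columns=["peptide_id", "group", "chip", "slope", "intercept",
                     "r_squared", "fit_flag", "signal_at_max_exposure", "signal"],
        )

    def test_constant_cv_zero(self):
        per, med = d.cv_report(self.slopes([10, 10, 10]))
        assert per["cv_pct"].iloc[0] == 0.0
        assert med["median_cv_pct"].iloc[0] == 0.0

    def test_hand_computed_cv(self):
        per, _ = d.cv_report(self.slopes([9, 10, 11]))
        assert per["cv_pct"].iloc[0] == pytest.approx(10.0)

    def test_zero_mean_excluded_with_warning(self):
        frame = pd.concat([self.slopes([0, 0, 0]), self.slopes([9, 10, 11], peptide="p2")])
        with pytest.warns(UserWarning, match="CV undefined"):
            per, _ = d.cv_report(frame)
        assert per["peptide_id"].tolist() == ["p2"]

    def test_single_chip_rejected(self):
        with pytest.raises(ValidationError, match=">= 2 chips"):
            d.cv_report(self.slopes([10]))

    def test_synthetic_median_cv_tracks_noise(self):
        medians = []
        for seed in range(20):
            cfg = make_config(seed=seed, active_kinases={})
            kmap = sim.generate_kinase_map(cfg)
            series, _ = sim.simulate_exposure_series(cfg, kmap)
            slopes = pp.fit_slopes(series)
            qc = pp.apply_qc(slopes)
            _, med = d.cv_report(slopes, keep=qc.keep)
            medians.extend(med["median_cv_pct"])
        grand = float(np.median(medians))
        assert 4.0 <= grand <= 6.0


class TestDifferentialPeptides:
    def test_direction_selection(self):
        lfc = pd.DataFrame(
            {
                "peptide_id": ["p1", "p2", "p3"],
                "mean_log2fc": [0.3, -0.3, 0.0],
                "classification": ["up", "down", "unchanged"],
            }
        )
        assert d.differential_peptides(lfc, "both") == ["p1", "p2"]
        assert d.differential_peptides(lfc, "up") == ["p1"]
        assert d.differential_peptides(lfc, "down") == ["p2"]
        with pytest.raises(ValidationError):
            d.differential_peptides(lfc, "sideways")
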