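"""PSM filtering, rollup, normalization and QC gates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import miproteo as mp
from miproteo.matrix import QuantMatrix


def make_psms(rows):
    base = {
        "psm_id": [f"PSM{i}" for i in range(len(rows))],
        "plex": ["plex1"] * len(rows),
        "feature_id": ["F1"] * len(rows),
    }
    return pd.DataFrame({**base, **pd.DataFrame(rows).to_dict(orient="list")})


class TestFilterPsms:
    @pytest.mark.parametrize(
        "label, purity, delta, kept",
        [
            ("full", 0.49, 1.0, False),   # strict < 50% excluded
            ("full", 0.50, 1.0, True),    # boundary retained
            ("full", 0.80, -0.01, False), # negative delta excluded
            ("full", 0.80, 0.0, True),    # zero delta retained
            ("none", 0.80, 1.0, False),   # unlabeled excluded
            ("partial", 0.80, 1.0, True),
        ],
    )
    def test_rule_boundaries(self, label, purity, delta, kept):
        psms = make_psms(
            [{"label_state": label, "precursor_purity": purity, "delta_fr_score": delta}]
        )
        assert (len(mp.filter_psms(psms)) == 1) is kept

    def test_compliant_table_unchanged_and_idempotent(self):
        rng = np.random.default_rng(0)
        psms = make_psms(
            [
                {
                    "label_state": "full",
                    "precursor_purity": float(rng.uniform(0.5, 1)),
                    "delta_fr_score": float(rng.uniform(0, 2)),
                }
                for _ in range(40)
            ]
        )
        out = mp.filter_psms(psms)
        pd.testing.assert_frame_equal(out, psms)
        pd.testing.assert_frame_equal(mp.filter_psms(out), out)

    def test_survivor_count_matches_per_rule_recount(self):
        rng = np.random.default_rng(42)
        rows = []
        for _ in range(200):
            rows.append(
                {
                    "label_state": rng.choice(["none", "partial", "full"], p=[0.1, 0.2, 0.7]),
                    "precursor_purity": float(rng.uniform(0, 1)),
                    "delta_fr_score": float(rng.normal(0.5, 1.0)),
                }
            )
        psms = make_psms(rows)
        # independent recount, one rule at a time
        expected = sum(
            1
            for r in rows
            if r["label_state"] != "none"
            and not r["precursor_purity"] < 0.5
            and not r["delta_fr_score"] < 0
        )
        assert len(mp.filter_psms(psms)) == expected


def toy_manifest(cores_channels, plex="plex1", cr="131N"):
    return pd.DataFrame(
        {
            "core_id": [c for c, _ in cores_channels],
            "patient_id": [c.split("_")[0] for c, _ in cores_channels],
            "timepoint": ["pre"] * len(cores_channels),
            "plex": [plex] * len(cores_channels),
            "channel": [ch for _, ch in cores_channels],
            "cr_channel": [cr] * len(cores_channels),
        }
    )


class TestRollup:
    def test_single_psm_twice_cr(self):
        psms = pd.DataFrame(
            {"psm_id": ["a"], "plex": ["plex1"], "feature_id": ["F1"],
             "intensity_126": [200.0], "intensity_131N": [100.0]}
        )
        man = toy_manifest([("S1_pre1", "126")])
        out = mp.rollup_psms(psms, man)
        assert out.data.at["F1", "S1_pre1"] == pytest.approx(1.0)

    def test_median_of_linear_ratios(self):
        # three PSMs with ratios 1, 2, 4 -> median 2 -> log2 = 1
        psms = pd.DataFrame(
            {"psm_id": list("abc"), "plex": ["plex1"] * 3, "feature_id": ["F1"] * 3,
             "intensity_126": [100.0, 200.0, 400.0], "intensity_131N": [100.0] * 3}
        )
        man = toy_manifest([("S1_pre1", "126")])
        out = mp.rollup_psms(psms, man)
        assert out.data.at["F1", "S1_pre1"] == pytest.approx(1.0)

    def test_matches_groupby_median_oracle_and_permutation_invariance(self):
        rng = np.random.default_rng(1)
        n = 120
        feats = rng.choice([f"F{i}" for i in range(8)], size=n)
        psms = pd.DataFrame(
            {
                "psm_id": [f"p{i}" for i in range(n)],
                "plex": ["plex1"] * n,
                "feature_id": feats,
                "intensity_126": rng.lognormal(10, 1, n),
                "intensity_127N": rng.lognormal(10, 1, n),
                "intensity_131N": rng.lognormal(10, 1, n),
            }
        )
        man = toy_manifest([("S1_pre1", "126"), ("S2_pre1", "127N")])
        out = mp.rollup_psms(psms, man)
        # brute-force oracle
        for core, channel in [("S1_pre1", "126"), ("S2_pre1", "127N")]:
            for f in np.unique(feats):
                sub = psms[psms.feature_id == f]
                expected = np.log2(
                    np.median(sub[f"intensity_{channel}"] / sub["intensity_131N"])
                )
                assert out.data.at[f, core] == pytest.approx(expected)
        shuffled = psms.sample(frac=1, random_state=2).reset_index(drop=True)
        out2 = mp.rollup_psms(shuffled, man)
        pd.testing.assert_frame_equal(out.data, out2.data)

    def test_feature_absent_from_plex_is_missing(self):
        psms = pd.DataFrame(
            {"psm_id": ["a"], "plex": ["plex1"], "feature_id": ["F1"],
             "intensity_126": [100.0], "intensity_131N": [100.0]}
        )
        man = pd.concat(
            [toy_manifest([("S1_pre1", "126")]),
             toy_manifest([("S2_pre1", "126")], plex="plex2")]
        )
        out = mp.rollup_psms(psms, man)
        assert np.isnan(out.data.at["F1", "S2_pre1"])


class TestReferenceNormalize:
    def test_basic_ratios(self):
        assert mp.reference_normalize(100.0, 100.0) == pytest.approx(0.0)
        assert mp.reference_normalize(200.0, 100.0) == pytest.approx(1.0)

    def test_zero_or_bad_inputs_become_missing_not_inf(self):
        assert np.isnan(mp.reference_normalize(0.0, 100.0))
        assert np.isnan(mp.reference_normalize(100.0, 0.0))
        assert np.isnan(mp.reference_normalize(100.0, float("nan")))


class TestCenterScale:
    def test_postconditions_and_idempotence(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(2, 3, (200, 5)), columns=list("abcde"))
        data.iloc[::7, 2] = np.nan
        m = QuantMatrix(data, "protein")
        out = mp.center_scale(m)
        for col in out.data.columns:
            x = out.data[col].dropna()
            assert abs(x.median()) < 1e-9
            assert abs(1.4826 * (x - x.median()).abs().median() - 1.0) < 1e-9
        out2 = mp.center_scale(out)
        pd.testing.assert_frame_equal(out.data, out2.data)

    def test_recovers_planted_shift_and_scale(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, (500, 3))
        shifts, scales = np.array([1.0, -2.0, 5.0]), np.array([0.5, 2.0, 3.0])
        data = pd.DataFrame(base * scales + shifts, columns=list("xyz"))
        m = QuantMatrix(data, "protein")
        out = mp.center_scale(m)
        for j, col in enumerate(data.columns):
            med = data[col].median()
            mad = 1.4826 * (data[col] - med).abs().median()
            expected = (data[col] - med) / mad
            np.testing.assert_allclose(out.data[col], expected)

    def test_preserves_rank_order(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        out = mp.center_scale(QuantMatrix(data, "protein"))
        for col in data.columns:
            assert (data[col].rank() == out.data[col].rank()).all()

    def test_zero_mad_column_raises_with_name(self):
        data = pd.DataFrame({"good": [1.0, 2, 3, 4], "flat": [1.0, 1, 1, 1]})
        with pytest.raises(ValueError, match="flat"):
            mp.center_scale(QuantMatrix(data, "protein"))


class TestUpperQuartile:
    def test_all_zero_gene_removed_zeros_missing(self):
        counts = pd.DataFrame(
            {"s1": [0, 10, 0], "s2": [0, 20, 5]}, index=["dead", "g1", "g2"]
        )
        out = mp.upper_quartile_normalize(counts)
        assert "dead" not in out.data.index
        assert np.isnan(out.data.at["g2", "s1"])

    def test_constant_column_normalizes_to_constant(self):
        counts = pd.DataFrame({"s1": [7, 7, 7, 7]}, index=list("abcd"))
        out = mp.upper_quartile_normalize(counts, scale=1000.0)
        np.testing.assert_allclose(out.data["s1"], np.log2(1000.0))

    def test_matches_percentile_oracle(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(40, 4)),
            index=[f"g{i}" for i in range(40)],
            columns=list("abcd"),
        )
        counts.iloc[0] = 0  # all-zero gene
        out = mp.upper_quartile_normalize(counts)
        for col in counts.columns:
            vals = counts[col].astype(float)
            nz = vals[vals > 0]
            uq = np.percentile(nz, 75)
            expected = np.log2(vals.where(vals > 0) / uq * 1000.0)
            got = out.data[col].reindex(expected.index)
            np.testing.assert_allclose(
                got.dropna(), expected.dropna().loc[got.dropna().index]
            )

    def test_column_without_counts_raises(self):
        counts = pd.DataFrame({"s1": [1, 2], "empty": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="empty"):
            mp.upper_quartile_normalize(counts)


class TestTumorContentGate:
    def test_boundary_average_of_50_passes(self):
        avg, ok = mp.gate_tumor_content([60, 60, 40, 40])
        assert avg == pytest.approx(50.0) and ok

    def test_all_zero_fails(self):
        _, ok = mp.gate_tumor_content([0, 0, 0])
        assert not ok

    def test_cohort_gate_keeps_14_of_19(self):
        rng = np.random.default_rng(8)
        avgs = list(rng.uniform(55, 90, 14)) + list(rng.uniform(10, 45, 5))
        passed = sum(mp.gate_tumor_content([a])[1] for a in avgs)
        assert passed == 14

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mp.gate_tumor_content([])


class TestLabelingQc:
    def _psms(self, n, partial_pct, full_pct, channel_factor=1.0):
        n_full = int(round(n * full_pct / 100))
        n_none = n - int(round(n * partial_pct / 100))
        labels = (
            ["full"] * n_full
            + ["none"] * n_none
            + ["partial"] * (n - n_full - n_none)
        )
        rng = np.random.default_rng(9)
        cr = rng.lognormal(10, 0.5, n)
        return pd.DataFrame(
            {
                "psm_id": [f"p{i}" for i in range(n)],
                "plex": ["plex1"] * n,
                "feature_id": ["F1"] * n,
                "label_state": labels,
                "precursor_purity": 0.9,
                "delta_fr_score": 1.0,
                "intensity_126": cr * channel_factor,
                "intensity_131N": cr,
            }
        )

    def test_passing_plex(self):
        man = toy_manifest([("S1_pre1", "126")])
        rep = mp.check_labeling_qc(self._psms(1000, 99.5, 95.0, 1.10), man)[0]
        assert rep.passed and rep.mixing_deviation_pct["126"] == pytest.approx(10.0)

    def test_partial_exactly_99_fails(self):
        man = toy_manifest([("S1_pre1", "126")])
        rep = mp.check_labeling_qc(self._psms(1000, 99.0, 95.0), man)[0]
        assert not rep.partial_pass and not rep.passed

    def test_mixing_violation_names_channel(self):
        man = toy_manifest([("S1_pre1", "126")])
        rep = mp.check_labeling_qc(self._psms(1000, 99.5, 95.0, 0.80), man)[0]
        assert not rep.mixing_pass and rep.failing_channels == ["126"]

    def test_generated_bundle_with_zero_violations_passes(self):
        cfg = mp.CohortConfig(
            n_genes=300, n_phosphosites=50, n_psm_features=300,
            psm_violation_rates={"unlabeled": 0.0, "low_purity": 0.0, "negative_delta": 0.0},
            seed=13,
        )
        bundle = mp.generate_cohort(cfg)
        reports = mp.check_labeling_qc(bundle.psms, bundle.manifest)
        assert all(r.passed for r in reports)
        assert all(len(mp.filter_psms(bundle.psms)) == len(bundle.psms) for _ in [0])
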