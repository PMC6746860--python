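import numpy as np
import pandas as pd
import pytest

from epicube.facs import (
    OutlierConfig,
    allele_enrichment,
    apply_pseudocounts,
    combine_channels,
    enrichment_to_landscape,
    fit_power_transform,
    iterative_enrichment,
    normalize_channels,
    validate_segment_barcode,
    zscore_outlier_filter,
)
from epicube.operators import Form, Landscape, inverse_fast_transform


def counts_df(rows):
    return pd.DataFrame(
        rows, columns=["allele_barcode", "uniqueness_barcode", "channel", "n_in", "n_out"]
    )


class TestAlleleEnrichment:
    def test_single_barcode(self):
        enr = allele_enrichment(counts_df([("01", "b1", "blue", 100, 50)]))
        assert enr["enrichment"].iloc[0] == 0.5

    def test_pooled_ratio_of_two_barcodes(self):
        enr = allele_enrichment(
            counts_df([("01", "b1", "blue", 100, 50), ("01", "b2", "blue", 300, 150)])
        )
        assert enr["enrichment"].iloc[0] == 0.5

    def test_sum_of_ratios_mode_differs(self):
        df = counts_df([("01", "b1", "blue", 100, 100), ("01", "b2", "blue", 400, 100)])
        pooled = allele_enrichment(df, pooled=True)["enrichment"].iloc[0]
        per_bc = allele_enrichment(df, pooled=False)["enrichment"].iloc[0]
        assert pooled == pytest.approx(0.4)
        assert per_bc == pytest.approx(0.625)

    def test_known_enrichment_within_bootstrap_sd(self):
        rng = np.random.default_rng(0)
        n_in = rng.poisson(200, 20)
        n_out = rng.poisson(2.0 * n_in)
        df = counts_df(
            [("0", f"b{k}", "blue", int(n_in[k]), int(n_out[k])) for k in range(20)]
        )
        enr = allele_enrichment(df, seed=1)
        e, sd = enr["enrichment"].iloc[0], enr["sd"].iloc[0]
        assert abs(e - 2.0) < 3 * max(sd, 1e-6)

    def test_zero_input_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            allele_enrichment(counts_df([("01", "b1", "blue", 0, 5)]))

    def test_duplicate_rows_rejected(self):
        df = counts_df([("0", "b1", "blue", 1, 1), ("0", "b1", "blue", 2, 2)])
        with pytest.raises(ValueError, match="duplicate"):
            allele_enrichment(df)


class TestOutlierFilter:
    def test_z_score_value_and_retention(self):
        # n_in=100, E=2, n_out=260: Z = 60 / 200**0.35 ~ 9.39 -> retained
        beta = 1 / 0.35
        z = (260 - 2 * 100) / (2 * 100) ** (1 / beta)
        assert z == pytest.approx(9.39, abs=0.01)
        rows = [("0", f"b{k}", "blue", 100, 200) for k in range(9)]
        rows.append(("0", "b9", "blue", 100, 260))
        filtered, log = zscore_outlier_filter(counts_df(rows))
        assert len(log) == 0
        assert len(filtered) == 10

    def test_massive_outlier_rejected_first_round(self):
        rows = [("0", f"b{k}", "blue", 100, 200) for k in range(19)]
        rows.append(("0", "b19", "blue", 100, 20_000))  # 100x expectation
        filtered, log = zscore_outlier_filter(counts_df(rows))
        assert list(log["uniqueness_barcode"]) == ["b19"]
        assert log["round"].iloc[0] == 1

    def test_masked_outlier_does_not_swamp_clean_barcodes(self):
        # one extreme barcode must not drag the rate and reject the rest
        rng = np.random.default_rng(5)
        rows = [
            ("0", f"b{k}", "blue", 100, int(rng.poisson(500))) for k in range(19)
        ]
        rows.append(("0", "b19", "blue", 100, 50_000))
        filtered, log = zscore_outlier_filter(counts_df(rows))
        assert set(log["uniqueness_barcode"]) == {"b19"}

    def test_clean_poisson_counts_rarely_rejected(self):
        rng = np.random.default_rng(1)
        rows = []
        for a in range(20):
            n_in = rng.poisson(200, 20)
            n_out = rng.poisson(1.5 * n_in)
            rows += [
                (f"a{a}", f"b{k}", "blue", int(n_in[k]), int(n_out[k]))
                for k in range(20)
            ]
        _, log = zscore_outlier_filter(counts_df(rows))
        assert len(log) / len(rows) < 0.05

    def test_config_validation(self):
        with pytest.raises(ValueError):
            OutlierConfig(beta=-1.0)


class TestNormalizeChannels:
    def make_enr(self):
        return pd.DataFrame(
            {
                "allele_barcode": ["00", "00", "11", "11", "01", "01"],
                "channel": ["blue", "red"] * 3,
                "enrichment": [10.0, 0.5, 0.2, 8.0, 5.0, 5.0],
                "sd": [0.1] * 6,
            }
        )

    def test_printed_constants(self):
        _, cal = normalize_channels(self.make_enr(), "00", "11")
        assert round(cal["brightness_ratio"], 3) == 0.772
        assert cal["target_ratio"] == pytest.approx(0.172, abs=1e-3)

    def test_parental_ratio_enforced(self):
        out, cal = normalize_channels(self.make_enr(), "00", "11")
        keyed = out.set_index(["allele_barcode", "channel"])["enrichment"]
        assert keyed[("11", "red")] / keyed[("00", "blue")] == pytest.approx(
            cal["target_ratio"]
        )

    def test_identity_when_already_calibrated(self):
        enr = self.make_enr()
        keyed = enr.set_index(["allele_barcode", "channel"])["enrichment"]
        # equal brightness, attenuation 1, red parent already at blue level
        enr.loc[
            (enr.allele_barcode == "11") & (enr.channel == "red"), "enrichment"
        ] = keyed[("00", "blue")]
        out, cal = normalize_channels(
            enr, "00", "11", brightness_red=1.0, brightness_blue=1.0, red_attenuation=1.0
        )
        assert cal["red_scale_factor"] == pytest.approx(1.0)
        assert np.allclose(out["enrichment"], enr["enrichment"])

    def test_rank_order_preserved_within_channel(self):
        out, _ = normalize_channels(self.make_enr(), "00", "11")
        for ch in ("blue", "red"):
            a = self.make_enr().query("channel == @ch")["enrichment"].rank()
            b = out.query("channel == @ch")["enrichment"].rank()
            assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_missing_parent_errors(self):
        with pytest.raises(ValueError, match="parental"):
            normalize_channels(self.make_enr(), "10", "11")


class TestCombineChannels:
    @pytest.mark.parametrize(
        "b, r, expected", [(3.0, 4.0, 5.0), (0.0, 2.0, 2.0), (1.0, 1.0, np.sqrt(2))]
    )
    def test_values(self, b, r, expected):
        assert combine_channels(b, r) == pytest.approx(expected)

    def test_symmetric_and_homogeneous(self):
        rng = np.random.default_rng(0)
        b, r = rng.uniform(0, 10, 2)
        assert combine_channels(b, r) == combine_channels(r, b)
        assert combine_channels(3 * b, 3 * r) == pytest.approx(3 * combine_channels(b, r))
        assert combine_channels(b, r) >= max(b, r)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            combine_channels(-1.0, 2.0)


class TestPowerTransform:
    def _curved_landscape(self, alpha_true, seed, noise=0.0):
        n = 8
        rng = np.random.default_rng(seed)
        from epicube.genotype_space import order_of_index

        o = order_of_index(np.arange(1 << n))
        terms = np.zeros(1 << n)
        low = np.flatnonzero((o >= 1) & (o <= 2))
        terms[rng.choice(low, 12, replace=False)] = rng.normal(0, 0.3, 12)
        y_true = inverse_fast_transform(terms, n, Form.BACKGROUND_AVERAGED)
        y_true = y_true - y_true.min() + 0.2
        x = y_true ** (1.0 / alpha_true)
        if noise:
            x = x * np.exp(rng.normal(0, noise, x.size))
        return Landscape(n, x)

    @pytest.mark.parametrize("alpha_true", [0.5, 1.0])
    def test_alpha_recovery(self, alpha_true):
        for seed in range(10):
            pt, transformed = fit_power_transform(
                self._curved_landscape(alpha_true, seed, noise=0.01)
            )
            assert abs(pt.alpha - alpha_true) < 0.05

    def test_objective_improves_over_identity(self):
        L = self._curved_landscape(0.5, 3)
        pt, _ = fit_power_transform(L)
        # objective at alpha=1 computed directly
        from epicube.operators import fast_transform
        from epicube.genotype_space import order_of_index

        f = L.phenotypes
        terms = fast_transform(f, L.n_positions, Form.BACKGROUND_AVERAGED)
        o = order_of_index(np.arange(L.size))
        terms[o > 2] = 0.0
        recon = inverse_fast_transform(terms, L.n_positions, Form.BACKGROUND_AVERAGED)
        obj_identity = np.sum((f - recon) ** 2) / f.var()
        assert pt.objective_value <= obj_identity

    def test_negative_phenotypes_rejected(self):
        with pytest.raises(ValueError):
            fit_power_transform(Landscape(2, [-0.1, 0.2, 0.3, 0.4]))


class TestPseudocounts:
    def test_above_floor_unchanged(self):
        L = Landscape(2, [0.2, 0.3, 0.4, 0.5])
        out = apply_pseudocounts(L, 0.1)
        assert np.array_equal(out.phenotypes, L.phenotypes)

    def test_below_floor_clamped(self):
        out = apply_pseudocounts(Landscape(2, [0.0, 0.01, 0.5, 0.9]), 0.05)
        assert np.array_equal(out.phenotypes, [0.05, 0.05, 0.5, 0.9])

    def test_monotone_never_decreases(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 1, 16)
        out = apply_pseudocounts(Landscape(4, y), 0.3)
        assert (out.phenotypes >= y).all()
        above = y > 0.3
        assert np.array_equal(out.phenotypes[above], y[above])


class TestSegmentBarcode:
    def test_all_a_valid(self):
        assert validate_segment_barcode("AAAA")

    def test_acgt_parity(self):
        assert validate_segment_barcode("ACGT")  # 0+1+2 = 3 -> T

    def test_single_substitutions_detected(self):
        base = "ACGT"
        for pos in range(4):
            for sub in "ACGT":
                if sub == base[pos]:
                    continue
                mutated = base[:pos] + sub + base[pos + 1 :]
                assert not validate_segment_barcode(mutated)

    def test_bad_characters_rejected(self):
        with pytest.raises(ValueError):
            validate_segment_barcode("ACGN")
        with pytest.raises(ValueError):
            validate_segment_barcode("ACG")
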