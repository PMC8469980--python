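"""Latent-factor cohort simulator: marginals, determinism, coupling structure."""

import numpy as np
import pytest
from scipy import stats

from frailtykit import reference
from frailtykit.association import pearson_r
from frailtykit.scales import ZFS_ITEMS, cohort_scores
from frailtykit.simulate import (
    ItemSpec,
    SimSpec,
    TwinPair,
    calibrate_threshold,
    default_spec,
    generate_cohort,
    load_spec_config,
)


class TestCalibrateThreshold:
    def test_half_prevalence_is_zero(self):
        assert calibrate_threshold(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_inverse_normal_value(self):
        assert calibrate_threshold(0.44) == pytest.approx(stats.norm.isf(0.44), abs=1e-12)
        assert calibrate_threshold(0.44) == pytest.approx(0.1510, abs=5e-4)

    @pytest.mark.parametrize("p", [0.05, 0.2, 0.44, 0.9])
    def test_antisymmetry(self, p):
        assert calibrate_threshold(p) == pytest.approx(-calibrate_threshold(1 - p))

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 2.0])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            calibrate_threshold(p)


class TestSpecValidation:
    def test_default_spec_validates(self):
        default_spec().validate()

    def test_coupling_variance_budget_enforced(self):
        items = (ItemSpec("a", "zfs", "binary", 0.3, 0.9),
                 ItemSpec("b", "msega", "binary", 0.3, 0.2))
        spec = SimSpec(n=10, seed=0, items=items,
                       twin_pairs=(TwinPair("a", "b", rho=0.6),))
        with pytest.raises(ValueError, match="loading\\^2 \\+ rho\\^2"):
            spec.validate()

    def test_ordinal_probabilities_must_sum_to_one(self):
        item = ItemSpec("a", "msega", "ordinal3", (0.5, 0.3, 0.3), 0.2)
        with pytest.raises(ValueError, match="sum to 1"):
            item.validate()


class TestGenerateCohort:
    def test_seed_determinism_byte_exact(self):
        spec = default_spec(n=300, seed=17)
        a = generate_cohort(spec).to_csv(index=False).encode()
        b = generate_cohort(spec).to_csv(index=False).encode()
        assert a == b

    def test_different_seeds_differ(self):
        a = generate_cohort(default_spec(n=300, seed=1))
        b = generate_cohort(default_spec(n=300, seed=2))
        assert not a.equals(b)

    def test_zero_loadings_give_independent_items(self):
        """With no factor and no coupling, item correlations sit at Monte-Carlo zero."""
        n = 10_000
        items = tuple(
            ItemSpec(name, "zfs", "binary", 0.4, 0.0) for name in ZFS_ITEMS
        )
        spec = SimSpec(n=n, seed=5, items=items)
        df = generate_cohort(spec)
        cols = [f"zfs_{name}" for name in ZFS_ITEMS]
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                r = pearson_r(df[a].to_numpy(), df[b].to_numpy())
                assert abs(r) < 3 / np.sqrt(n)

    def test_default_prevalences_recovered(self):
        """Every published item prevalence is recovered within 3 binomial SEs at n=10^4."""
        n = 10_000
        df = generate_cohort(default_spec(n=n, seed=23))
        for name, count in reference.item_prevalences().items():
            p = count / reference.COHORT_N
            phat = df[f"zfs_{name}"].mean()
            assert abs(phat - p) < 3 * np.sqrt(p * (1 - p) / n), name

    def test_twin_coupling_monotone_in_rho(self):
        """Raising a pair's residual coupling strictly raises its empirical phi."""
        n = 10_000
        phis = []
        for rho in (0.0, 0.3, 0.6, 0.9):
            items = (ItemSpec("a", "zfs", "binary", 0.3, 0.3),
                     ItemSpec("b", "msega", "binary", 0.4, 0.3))
            spec = SimSpec(n=n, seed=99, items=items,
                           twin_pairs=(TwinPair("a", "b", rho=rho),))
            df = generate_cohort(spec)
            phis.append(pearson_r(df["zfs_a"].to_numpy(), df["msega_b"].to_numpy()))
        assert phis == sorted(phis)
        assert phis[-1] - phis[0] > 0.2

    def test_appending_an_item_preserves_earlier_columns(self):
        base = default_spec(n=200, seed=4)
        extended = SimSpec(
            n=base.n, seed=base.seed,
            items=base.items + (ItemSpec("extra_item", "zfs", "binary", 0.2, 0.1),),
            twin_pairs=base.twin_pairs, demographics=base.demographics,
            age_loading=base.age_loading, sex_female_p=base.sex_female_p,
        )
        a = generate_cohort(base)
        b = generate_cohort(extended)
        assert a.equals(b[a.columns])

    def test_calibrated_cohort_level_targets(self):
        """Totals correlation near 0.81 and mSEGA-frail prevalence near 19.6%."""
        df = generate_cohort(default_spec(n=5000, seed=31))
        sc = cohort_scores(df.to_dict("records"))
        r = float(np.corrcoef(sc.zfs_score, sc.msega_total)[0, 1])
        assert abs(r - 0.81) < 0.08
        assert abs(sc.msega_frail.mean() - 0.196) < 0.05

    def test_age_rises_with_frailty(self):
        df = generate_cohort(default_spec(n=5000, seed=8))
        sc = cohort_scores(df.to_dict("records"))
        assert df.loc[sc.msega_frail, "age"].mean() > df.loc[~sc.msega_frail, "age"].mean()


class TestSpecConfig:
    def test_round_trip_overrides(self, tmp_path):
        cfg = tmp_path / "spec.cfg"
        cfg.write_text(
            "# synthetic cohort overrides\n"
            "n = 50\nseed = 9\n"
            "loading.lives_alone = 0.2\n"
            "marginal.lives_alone = 0.3\n"
            "marginal.age = 0.5,0.3,0.2\n"
            "rho.memory_complaint = 0.5\n"
            "demographic.age = 80,6\n",
            encoding="utf-8",
        )
        spec = load_spec_config(cfg)
        assert spec.n == 50 and spec.seed == 9
        items = {it.name: it for it in spec.items}
        assert items["lives_alone"].loading == 0.2
        assert items["lives_alone"].marginal == 0.3
        assert items["age"].marginal == (0.5, 0.3, 0.2)
        assert {p.zfs_item: p.rho for p in spec.twin_pairs}["memory_complaint"] == 0.5
        assert spec.demographics["age"] == (80.0, 6.0)

    def test_unknown_key_rejected(self, tmp_path):
        cfg = tmp_path / "bad.cfg"
        cfg.write_text("frobnicate = 3\n", encoding="utf-8")
        with pytest.raises(ValueError, match="frobnicate"):
            load_spec_config(cfg)
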