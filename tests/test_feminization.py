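"""Female-bias, ovary-dominance and gametolog profile statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from zwstrata import feminization as fem
from zwstrata import simdata


def tpm_frame(rows, cols=None):
    cols = cols or [f"{t}_{s}" for t in fem.TISSUES for s in ("F", "M")]
    return pd.DataFrame(rows, columns=cols)


class TestFilterExpressed:
    def test_low_expression_removed(self):
        df = pd.DataFrame({"liver_F": [0.5, 1.0], "liver_M": [0.5, 1.0]}, index=["lo", "ok"])
        kept = fem.filter_expressed(df, ["liver_F", "liver_M"])
        assert list(kept.index) == ["ok"]  # boundary 1.0 retained, strict < removal

    def test_all_below_threshold(self):
        df = pd.DataFrame({"liver_F": [0.1], "liver_M": [0.2]})
        assert fem.filter_expressed(df, ["liver_F", "liver_M"]).empty

    def test_per_comparison_semantics(self):
        df = pd.DataFrame({"liver_F": [5.0], "liver_M": [0.2], "brain_F": [5.0], "brain_M": [5.0]})
        assert fem.filter_expressed(df, ["liver_F", "liver_M"]).empty
        assert len(fem.filter_expressed(df, ["brain_F", "brain_M"])) == 1


class TestFemaleBias:
    @pytest.mark.parametrize("f,m,ratio,biased", [(4, 1, 4.0, True), (2, 1, 2.0, False), (1, 4, 0.25, False)])
    def test_fold_change_rule(self, f, m, ratio, biased):
        call = fem.female_bias_call("g", "liver", f, m)
        assert call.f_over_m == pytest.approx(ratio)
        assert call.female_biased is biased

    def test_reciprocal_ratios(self):
        a = fem.female_bias_call("g", "t", 3.0, 7.0).f_over_m
        b = fem.female_bias_call("g", "t", 7.0, 3.0).f_over_m
        assert a * b == pytest.approx(1.0)


class TestOvaryDominance:
    def _row(self, ovary, each_other):
        cols = [f"{t}_{s}" for t in fem.TISSUES for s in ("F", "M")]
        row = pd.Series(each_other, index=cols, dtype=float)
        row["gonad_F"] = ovary
        return row

    def test_dominant(self):
        r, dom = fem.ovary_dominance(self._row(10, 40 / 9))
        assert r == pytest.approx(0.25) and dom

    def test_boundary_not_dominant(self):
        r, dom = fem.ovary_dominance(self._row(10, 50 / 9))
        assert r == pytest.approx(0.20) and not dom

    def test_zero_ovary(self):
        r, dom = fem.ovary_dominance(self._row(0, 5))
        assert r == 0.0 and not dom

    def test_scale_invariance(self):
        row = self._row(10, 3)
        r1, _ = fem.ovary_dominance(row)
        r2, _ = fem.ovary_dominance(row * 17.0)
        assert r1 == pytest.approx(r2)

    def test_all_denominator_variant(self):
        row = self._row(10, 40 / 9)
        r_other, _ = fem.ovary_dominance(row, denominator="other")
        r_all, _ = fem.ovary_dominance(row, denominator="all")
        assert r_other == pytest.approx(0.25)
        assert r_all == pytest.approx(10 / 50)

    def test_zero_denominator_flagged(self):
        row = self._row(0, 0)
        r, dom = fem.ovary_dominance(row)
        assert math.isnan(r) and not dom


class TestProfileCompare:
    def _pair(self, factor):
        cols = [f"{t}_{s}" for t in fem.TISSUES for s in ("F", "M")]
        z = pd.Series(np.arange(1.0, 11.0), index=cols)
        w = z.copy()
        for c in cols:
            w[c] = 0.0 if c.endswith("_M") else z[c] * factor
        return z, w

    def test_half_expression(self):
        z, w = self._pair(0.5)
        _, rho, ratio = fem.gametolog_profile_compare(z, w)
        assert rho == pytest.approx(1.0) and ratio == pytest.approx(0.5)

    def test_identity_when_factor_one(self):
        z, w = self._pair(1.0)
        _, rho, ratio = fem.gametolog_profile_compare(z, w)
        assert rho == 1.0 and ratio == 1.0

    def test_all_zero_w(self):
        z, w = self._pair(0.0)
        _, rho, ratio = fem.gametolog_profile_compare(z, w)
        assert math.isnan(rho) and ratio == 0.0

    def test_simulated_downregulation_recovery(self):
        spec = simdata.ExpressionSpec(
            n_genes=300, n_gametolog_pairs=120, w_downregulation_factor=0.5, noise_sd=0.1
        )
        cfg = simdata.SimulationConfig(seed=6, expression=spec)
        df, truth = simdata.simulate_expression(cfg)
        ratios = []
        for zg, wg in truth.gametolog_pairs:
            _, _, ratio = fem.gametolog_profile_compare(df.loc[zg], df.loc[wg])
            ratios.append(ratio)
        assert np.median(ratios) == pytest.approx(0.5, abs=0.05)


class TestEnrichmentAndReplicates:
    def test_all_biased_retained(self):
        calls = [fem.BiasCall(f"g{i}", "liver", 4.0, True) for i in range(5)]
        calls += [fem.BiasCall(f"h{i}", "liver", 1.0, False) for i in range(5)]
        status = {f"g{i}": "retained" for i in range(5)}
        status.update({f"h{i}": "lost" for i in range(5)})
        out = fem.feminization_enrichment(calls, status, tissues=("liver",))
        assert out["liver"]["p"] == pytest.approx(2 / 252, abs=1e-12)

    def test_no_biased_genes_notice(self):
        calls = [fem.BiasCall("g0", "liver", 1.0, False), fem.BiasCall("g1", "liver", 1.0, False)]
        out = fem.feminization_enrichment(calls, {"g0": "retained", "g1": "lost"}, tissues=("liver",))
        assert out["liver"]["p"] == 1.0 and "notice" in out["liver"]

    def test_null_pvalues_not_skewed(self):
        """With no planted retention/bias association, Fisher p-values over
        seeds should not pile up near 0 (KS sanity check against uniform
        dominance)."""
        from scipy import stats

        rng = np.random.default_rng(42)
        ps = []
        for _ in range(200):
            biased = rng.random(40) < 0.3
            retained = rng.random(40) < 0.5
            calls = [fem.BiasCall(f"g{i}", "liver", 4.0 if b else 1.0, bool(b)) for i, b in enumerate(biased)]
            status = {f"g{i}": ("retained" if r else "lost") for i, r in enumerate(retained)}
            out = fem.feminization_enrichment(calls, status, tissues=("liver",))
            ps.append(out["liver"]["p"])
        # discrete p-values are super-uniform; only check there is no excess of small p
        assert np.mean(np.array(ps) < 0.05) < 0.08

    def test_replicate_averaging(self):
        df = pd.DataFrame(
            {"liver_F_r1": [2.0], "liver_F_r2": [4.0], "liver_M": [1.0]}, index=["g"]
        )
        avg = fem.mean_over_replicates(df)
        assert avg.loc["g", "liver_F"] == pytest.approx(3.0)
        assert avg.loc["g", "liver_M"] == 1.0
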