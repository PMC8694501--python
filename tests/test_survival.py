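"""Survival statistics: KM/log-rank, Cox adjustment, mutation enrichment."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from moclust.io import OmicsLayer
from moclust.simulate import SimulationConfig, simulate_multiomics, simulate_survival
from moclust.survival import (
    cox_multivariable,
    exact_kx2_test,
    km_logrank,
    mutation_stats,
)
from tests.conftest import small_layer_specs


def logrank_by_hand(time, event, group):
    """Independent two-group log-rank tabulation over event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    g1 = np.unique(group)[0]
    O_minus_E = 0.0
    V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == g1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == g1)).sum()
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O_minus_E ** 2 / V


class TestKMLogrank:
    def test_identical_groups_give_null_statistic(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 40)
        e = np.ones(40, dtype=int)
        time = np.concatenate([t, t])
        event = np.concatenate([e, e])
        group = np.array([1] * 40 + [2] * 40)
        res = km_logrank(time, event, group)
        assert res.chi_square == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_toy_two_group_matches_hand_tabulation(self):
        time = [1.0, 2.0, 3.0, 4.0]
        event = [1, 1, 1, 1]
        group = ["A", "A", "B", "B"]
        res = km_logrank(time, event, group)
        assert res.chi_square == pytest.approx(logrank_by_hand(time, event, group), rel=1e-9)

    def test_random_data_matches_hand_tabulation(self):
        rng = np.random.default_rng(1)
        time = rng.exponential(5, 60)
        event = rng.integers(0, 2, 60)
        event[0] = 1
        group = rng.choice(["A", "B"], 60)
        res = km_logrank(time, event, group)
        assert res.chi_square == pytest.approx(logrank_by_hand(time, event, group), rel=1e-6)

    def test_km_curve_properties(self):
        rng = np.random.default_rng(2)
        time = rng.exponential(10, 50)
        event = np.ones(50, dtype=int)
        res = km_logrank(np.concatenate([time, time * 2]), np.concatenate([event, event]),
                         [1] * 50 + [2] * 50)
        for curve in res.curves.values():
            surv = curve.iloc[:, 0].to_numpy()
            assert surv[0] == 1.0
            assert (np.diff(surv) <= 1e-12).all()
        # no censoring: KM equals the empirical survival function
        km1 = res.curves[1].iloc[:, 0]
        for t in np.quantile(time, [0.25, 0.5, 0.75]):
            emp = (time > t).mean()
            km_at = km1[km1.index <= t].iloc[-1]
            assert km_at == pytest.approx(emp, abs=1e-9)

    def test_planted_hazards_power(self):
        """Hazards (0.08, 0.02, 0.01) at n=300 give overwhelming log-rank evidence."""
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, layer_specs=small_layer_specs())
            rng = np.random.default_rng(seed + 50_000)
            labels = rng.choice(3, 300, p=cfg.proportions) + 1
            surv = simulate_survival(labels, cfg, rng)
            res = km_logrank(surv["rfs_months"], surv["rfs_event"], labels)
            hits += res.p_value < 0.01
        assert hits / n_seeds >= 0.95

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2, 3, 4], [0, 0, 0, 0], [1, 1, 2, 2])


class TestCox:
    @staticmethod
    def _two_group(n, hr, seed, censor=None):
        rng = np.random.default_rng(seed)
        group = rng.integers(0, 2, n)
        lam = 0.02 * hr ** group
        t = rng.exponential(1 / lam)
        if censor is None:
            event = np.ones(n, dtype=int)
        else:
            c = rng.uniform(0, censor, n)
            event = (t <= c).astype(int)
            t = np.minimum(t, c)
        return pd.DataFrame({"rfs_months": t, "rfs_event": event, "grp": group.astype(float)})

    def test_recovers_true_hazard_ratio(self):
        tab = self._two_group(400, hr=4.0, seed=0)
        fit = cox_multivariable(tab, ["grp"])
        assert fit.converged
        assert 3.2 <= fit.summary.loc["grp", "HR"] <= 5.0
        lo, hi = fit.summary.loc["grp", ["ci_low", "ci_high"]]
        assert lo < fit.summary.loc["grp", "HR"] < hi

    def test_null_covariate_ci_covers_one(self):
        cover = 0
        n_seeds = 40
        for seed in range(n_seeds):
            tab = self._two_group(150, hr=1.0, seed=seed)
            fit = cox_multivariable(tab, ["grp"])
            lo, hi = fit.summary.loc["grp", ["ci_low", "ci_high"]]
            cover += lo <= 1.0 <= hi
        assert cover / n_seeds >= 0.85  # nominal 95% coverage within MC error

    def test_separation_flagged(self):
        tab = pd.DataFrame({"rfs_months": [1.0, 2.0], "rfs_event": [1, 0], "x": [1.0, 0.0]})
        fit = cox_multivariable(tab, ["x"])
        assert not fit.converged
        assert fit.message

    def test_categorical_references_respected(self):
        cfg = SimulationConfig(n_samples=200, layer_specs=small_layer_specs(), seed=13)
        ds, gt = simulate_multiomics(cfg)
        tab = ds.clinical.copy()
        tab["subtype"] = gt.true_labels
        fit = cox_multivariable(tab, ["subtype", "age"], references={"subtype": 3})
        assert "subtype_3" not in fit.summary.index
        assert {"subtype_1", "subtype_2"} <= set(fit.summary.index)
        # subtype 1 has the largest planted hazard (0.08 vs reference 0.01)
        assert fit.summary.loc["subtype_1", "HR"] > fit.summary.loc["subtype_2", "HR"] > 1.0


def fisher_by_enumeration(a, b, c, d):
    """Two-sided Fisher p for [[a, b], [c, d]] by hypergeometric enumeration."""
    m = a + c
    row1 = a + b
    n = a + b + c + d

    def prob(x):
        return comb(row1, x) * comb(n - row1, m - x) / comb(n, m)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, m - (n - row1)), min(row1, m) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestMutationStats:
    def _layer(self, X, samples=None):
        samples = samples or [f"S{i}" for i in range(X.shape[1])]
        df = pd.DataFrame(X.astype(float), index=[f"gene{i}" for i in range(X.shape[0])],
                          columns=samples)
        return OmicsLayer(name="mutation", kind="binary", values=df)

    def test_fisher_matches_hypergeometric_enumeration(self):
        """Contingency (9/38 vs 2/50): scipy Fisher, our exact k x 2 test, and a
        direct hypergeometric enumeration all agree."""
        p_scipy = stats.fisher_exact([[9, 29], [2, 48]])[1]
        p_enum = fisher_by_enumeration(9, 29, 2, 48)
        p_ours = exact_kx2_test(np.array([9, 2]), np.array([38, 50]))
        assert p_scipy == pytest.approx(p_enum, rel=1e-9)
        assert p_ours == pytest.approx(p_enum, rel=1e-9)

    def test_exact_3x2_sums_to_one_over_extremes(self):
        # all allocations enumerated: p of the most extreme table <= 1
        p = exact_kx2_test(np.array([10, 0, 0]), np.array([10, 10, 10]))
        assert 0 < p < 0.01

    def test_universally_mutated_gene_degenerate(self):
        X = np.ones((1, 30), dtype=int)
        summary = mutation_stats(self._layer(X), [1] * 15 + [2] * 15)
        assert summary.per_gene["p_value"].iloc[0] == 1.0
        assert (summary.per_gene.filter(like="fraction_").iloc[0] == 1.0).all()

    def test_tmb_counts(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(20, 10))
        summary = mutation_stats(self._layer(X), [1] * 5 + [2] * 5)
        assert (summary.tmb.to_numpy() == X.sum(axis=0)).all()

    def test_planted_enrichment_detected(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SimulationConfig(n_samples=150, layer_specs=small_layer_specs(), seed=seed)
            ds, gt = simulate_multiomics(cfg)
            summary = mutation_stats(ds.layer("mutation"), gt.true_labels)
            planted = [g for s in (1, 2, 3) for g in gt.informative_features["mutation"][s]]
            sig = summary.per_gene.loc[planted, "fdr"] < 0.05
            hits += sig.mean() >= 0.8
        assert hits >= 8

    def test_non_binary_layer_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 4)),
                          index=["a", "b", "c"], columns=list("wxyz"))
        layer = OmicsLayer(name="x", kind="gaussian", values=df)
        with pytest.raises(TypeError):
            mutation_stats(layer, [1, 1, 2, 2])
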