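"""Deregression, the relationship matrix, and the weighted REML association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mendelbalance import simdata
from mendelbalance.assoc import (
    DEBVRecord, _deregress_one, a_matrix, association_table, deregress,
    fit_association,
)


def ped_frame(rows):
    return pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex",
                                       "birth_date"])


class TestDeregression:
    def test_weight_formula_direct_evaluation(self):
        # h2=0.5, r2_debv=0.5, c=0.5 -> w = 0.5 / ((0.5 + 1) * 0.5) = 2/3
        h2, rel_debv, c = 0.5, 0.5, 0.5
        w = (1 - h2) / ((c + (1 - rel_debv) / rel_debv) * h2)
        assert w == pytest.approx(2 / 3)
        # with c = 0 the weight is the additive-to-residual variance ratio
        # scaled by the record's information odds r2/(1-r2)
        r2 = 0.8
        w0 = (1 - 0.3) / ((0.0 + (1 - r2) / r2) * 0.3)
        assert w0 == pytest.approx((1 - 0.3) / 0.3 * r2 / (1 - r2))

    def test_solved_information_reproduces_reliabilities(self):
        # invert the construction: the coefficient matrix built from the
        # solved Z'Z terms must return the input prediction error variances
        for rel, rel_pa, h2 in [(0.7, 0.25, 0.4), (0.5, 0.15, 0.25),
                                (0.9, 0.45, 0.6), (0.3, 0.05, 0.1)]:
            lam = (1 - h2) / h2
            debv, rel_debv, w = _deregress_one(1.0, 0.0, rel, rel_pa, h2, 0.5)
            A = (0.5 - rel_pa) / lam
            B = (1 - rel) / lam
            u = (1 + np.sqrt(1 + 16 * A * B * lam * lam)) / (2 * A)
            v = 4 * A * lam * lam / (A * u - 1)
            C = np.array([[u, -2 * lam], [-2 * lam, v]])
            Cinv = np.linalg.inv(C)
            assert Cinv[0, 0] * lam == pytest.approx(0.5 - rel_pa, rel=1e-9)
            assert Cinv[1, 1] * lam == pytest.approx(1 - rel, rel=1e-9)
            assert 0 < rel_debv < 1 and w > 0

    def test_low_information_record_not_retained(self):
        rec = pd.DataFrame([{"animal": "x", "trait": "T", "ebv": 1.0,
                             "rel": 0.25, "rel_pa": 0.20, "h2": 0.3,
                             "ebv_pa": 0.0}])
        out, = deregress(rec)
        assert out.rel_debv < 0.20
        assert not out.retained

    def test_parent_average_reliability_cap(self):
        rec = pd.DataFrame([{"animal": "x", "trait": "T", "ebv": 1.0,
                             "rel": 0.7, "rel_pa": 0.55, "h2": 0.3,
                             "ebv_pa": 0.0}])
        with pytest.raises(ValueError, match="0.5"):
            deregress(rec)

    def test_uninformative_record_flagged_not_deregressed(self):
        rec = pd.DataFrame([{"animal": "x", "trait": "T", "ebv": 1.0,
                             "rel": 0.2, "rel_pa": 0.3, "h2": 0.3,
                             "ebv_pa": 0.0}])
        out, = deregress(rec)
        assert out.flagged == "rel<=rel_pa"
        assert not out.retained and np.isnan(out.debv)

    def test_inverts_forward_simulated_evaluation(self, small_bundle):
        # the generator runs the PA/individual equations forward; the
        # deregression must recover the individual pseudo-record exactly
        b = small_bundle
        debvs = deregress(b.ebv, c=0.5)
        truth = b.truth.debv_true.set_index(["animal", "trait"])["y_i"]
        checked = 0
        for r in debvs:
            if r.retained:
                assert r.debv == pytest.approx(truth.loc[(r.animal, r.trait)],
                                               abs=1e-8)
                checked += 1
        assert checked > 1000


class TestAMatrix:
    def test_unrelated_founders_identity(self):
        ped = ped_frame([("A", np.nan, np.nan, "m", "2006-01-01"),
                         ("B", np.nan, np.nan, "f", "2006-01-01")])
        A, order = a_matrix(ped)
        np.testing.assert_array_equal(A, np.eye(2))

    def test_full_sibs_and_parent_offspring(self):
        ped = ped_frame([("S", np.nan, np.nan, "m", "2006-01-01"),
                         ("D", np.nan, np.nan, "f", "2006-01-01"),
                         ("K1", "S", "D", "m", "2007-01-01"),
                         ("K2", "S", "D", "f", "2007-01-01")])
        A, order = a_matrix(ped)
        i = {a: k for k, a in enumerate(order)}
        assert A[i["K1"], i["K2"]] == pytest.approx(0.5)
        assert A[i["S"], i["K1"]] == pytest.approx(0.5)
        assert A[i["K1"], i["K1"]] == pytest.approx(1.0)

    def test_offspring_of_half_sibs_is_inbred(self):
        ped = ped_frame([("S", np.nan, np.nan, "m", "2006-01-01"),
                         ("D1", np.nan, np.nan, "f", "2006-01-01"),
                         ("D2", np.nan, np.nan, "f", "2006-01-01"),
                         ("H1", "S", "D1", "m", "2007-01-01"),
                         ("H2", "S", "D2", "f", "2007-01-01"),
                         ("X", "H1", "H2", "m", "2008-01-01")])
        A, order = a_matrix(ped)
        i = {a: k for k, a in enumerate(order)}
        assert A[i["H1"], i["H2"]] == pytest.approx(0.25)
        assert A[i["X"], i["X"]] == pytest.approx(1.125)  # F = 0.125

    def test_row_order_invariance_and_psd(self):
        rng = np.random.default_rng(0)
        b = simdata.generate_population(simdata.SimConfig(
            seed=3, n_founders=40, n_generations=2, n_dams=15, n_sires=5,
            tnb_mean=4.0))
        ped = b.pedigree
        A1, order1 = a_matrix(ped)
        shuffled = ped.sample(frac=1.0, random_state=1).reset_index(drop=True)
        A2, order2 = a_matrix(shuffled)
        i2 = {a: k for k, a in enumerate(order2)}
        perm = [i2[a] for a in order1]
        np.testing.assert_allclose(A1, A2[np.ix_(perm, perm)], atol=1e-12)
        assert np.linalg.eigvalsh(A1).min() > -1e-10


def _fit_inputs(bundle, trait):
    debvs = deregress(bundle.ebv, c=0.5)
    status = {a: int(c >= 1) for a, c in bundle.truth.copies.items()}
    return debvs, status


@pytest.fixture(scope="module")
def tiny():
    cfg = simdata.SimConfig(seed=21, n_founders=100, n_generations=2,
                            n_dams=40, n_sires=12, tnb_mean=8.0)
    return simdata.generate_population(cfg)


class TestREMLAssociation:
    def test_no_polygenic_variance_collapses_to_wls(self, tiny):
        debvs, status = _fit_inputs(tiny, "GROWTH")
        res = fit_association(debvs, status, tiny.pedigree, trait="GROWTH",
                              sigma_a2_zero=True)
        recs = [r for r in debvs if r.retained and r.trait == "GROWTH"]
        y = np.array([r.debv for r in recs])
        w = np.array([r.weight for r in recs])
        x = np.array([status[r.animal] for r in recs], dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * y))
        assert res.effect == pytest.approx(beta[1], rel=1e-9)

    def test_reml_optimum_matches_grid_search(self, tiny):
        from mendelbalance.assoc import _reml_profile, a_matrix as build_a
        debvs, status = _fit_inputs(tiny, "GROWTH")
        res = fit_association(debvs, status, tiny.pedigree, trait="GROWTH")
        recs = [r for r in debvs if r.retained and r.trait == "GROWTH"
                and r.animal in status]
        A, order = build_a(tiny.pedigree)
        pos = {a: i for i, a in enumerate(order)}
        idx = [pos[r.animal] for r in recs]
        y = np.array([r.debv for r in recs])
        w = np.array([r.weight for r in recs])
        x = np.array([status[r.animal] for r in recs], dtype=float)
        sw = np.sqrt(w)
        M = (A[np.ix_(idx, idx)] * sw[:, None]) * sw[None, :]
        S, U = np.linalg.eigh(M)
        S = np.clip(S, 0, None)
        X = np.column_stack([np.ones_like(x), x])
        zt, Xt = U.T @ (sw * y), U.T @ (sw[:, None] * X)
        grid = np.linspace(-12, 12, 4001)
        vals = [_reml_profile(ll, S, Xt, zt, len(y), 2)[0] for ll in grid]
        best = grid[int(np.argmin(vals))]
        lam_grid = np.exp(best)
        lam_fit = res.sigma_e2 / res.sigma_a2
        assert lam_fit == pytest.approx(lam_grid, rel=5e-3)

    def test_animal_order_invariance(self, tiny):
        debvs, status = _fit_inputs(tiny, "TSI")
        recs = [r for r in debvs if r.trait == "TSI"]
        rng = np.random.default_rng(0)
        shuffled = [recs[i] for i in rng.permutation(len(recs))]
        r1 = fit_association(recs, status, tiny.pedigree, trait="TSI")
        r2 = fit_association(shuffled, status, tiny.pedigree, trait="TSI")
        assert r1.effect == pytest.approx(r2.effect, rel=1e-8)
        assert r1.se == pytest.approx(r2.se, rel=1e-6)
        assert r1.p == pytest.approx(r2.p, rel=1e-6)

    def test_recovers_injected_shift_across_seeds(self):
        hits = 0
        for seed in range(10):
            cfg = simdata.SimConfig(seed=300 + seed, n_founders=100,
                                    n_generations=2, n_dams=40, n_sires=12,
                                    tnb_mean=8.0)
            b = simdata.generate_population(cfg)
            debvs, status = _fit_inputs(b, "GROWTH")
            res = fit_association(debvs, status, b.pedigree, trait="GROWTH")
            hits += abs(res.effect - 12.4) <= 2 * res.se
        assert hits >= 8

    def test_null_trait_p_values_uniform(self):
        # no injected shift: association p-values across replicates should be
        # uniform (Kolmogorov-Smirnov)
        ps = []
        for seed in range(60):
            cfg = simdata.SimConfig(seed=700 + seed, n_founders=60,
                                    n_generations=1, n_dams=25, n_sires=8,
                                    tnb_mean=7.0, carrier_tsi_shift_pct=0.0)
            b = simdata.generate_population(cfg)
            debvs, status = _fit_inputs(b, "TSI")
            res = fit_association(debvs, status, b.pedigree, trait="TSI")
            ps.append(res.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_carriers_rejected(self, tiny):
        debvs, _ = _fit_inputs(tiny, "TSI")
        status = {r.animal: 0 for r in debvs}
        status[debvs[0].animal] = 1
        with pytest.raises(ValueError, match="carrier"):
            fit_association(debvs, status, tiny.pedigree, trait="TSI")

    def test_association_table_layout(self, tiny):
        debvs, status = _fit_inputs(tiny, None)
        table = association_table(debvs, status, tiny.pedigree)
        assert set(table["trait"]) == {"GROWTH", "LBW", "TSI"}
        assert {"n_noncarrier", "n_carrier", "P", "-log10P", "effect",
                "se"} <= set(table.columns)
        growth = table.set_index("trait").loc["GROWTH"]
        assert growth["effect"] > 0 and growth["P"] < 0.05
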