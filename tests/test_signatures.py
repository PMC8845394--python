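"""Refitting (plain / strict / bootstrapped), merging and NMF extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import lsq_linear

from mutpat import (
    ChannelMismatchError,
    MutationCountMatrix,
    MutpatError,
    SignatureMatrix,
    bootstrap_correlation,
    extract_signatures,
    filter_low_contribution,
    fit_bootstrapped,
    fit_strict,
    fit_to_signatures,
    get_known_signatures,
    merge_signatures,
    rank_survey,
    rename_extracted,
)
from mutpat.context_engine import sbs_channels
from mutpat.signatures import backwards_elimination_path, select_from_path


@pytest.fixture(scope="module")
def catalog():
    return get_known_signatures("snv", "COSMIC_v3.1")


def _mcm(values: dict) -> MutationCountMatrix:
    df = pd.DataFrame(values, index=sbs_channels(1))
    return MutationCountMatrix(df.round().astype(int), "sbs_ext1")


class TestFitToSignatures:
    def test_pure_signature_recovered_exactly(self, catalog):
        m = _mcm({"s": 500 * catalog["SBS1"].to_numpy()})
        r = fit_to_signatures(m, catalog)
        c = r.contribution["s"]
        assert c["SBS1"] == pytest.approx(m.totals()["s"], rel=0.02)
        assert (c.drop("SBS1") < 1e-6 * c["SBS1"] + 2).all()
        assert r.cosine["s"] > 0.999

    def test_noiseless_two_signature_mixture_solved_analytically(self):
        # two linearly independent signatures; y = 60 a + 40 b exactly,
        # so the (unconstrained) least-squares solution is (60, 40) and it
        # is feasible, hence NNLS must return it
        channels = sbs_channels(1)
        a = np.zeros(96)
        a[:4] = [0.4, 0.3, 0.2, 0.1]
        b = np.zeros(96)
        b[2:6] = [0.1, 0.2, 0.3, 0.4]
        S = SignatureMatrix(pd.DataFrame({"a": a, "b": b}, index=channels))
        y = 60 * a + 40 * b
        m = MutationCountMatrix(
            pd.DataFrame({"s": y}, index=channels), "sbs_ext1"
        )
        r = fit_to_signatures(m, S)
        assert r.contribution.loc["a", "s"] == pytest.approx(60, abs=1e-8)
        assert r.contribution.loc["b", "s"] == pytest.approx(40, abs=1e-8)
        np.testing.assert_allclose(
            r.reconstructed["s"], S.values.to_numpy() @ r.contribution["s"], atol=1e-9
        )

    def test_residual_beats_random_search(self, catalog, rng):
        m = _mcm({"s": rng.integers(0, 30, 96).astype(float)})
        r = fit_to_signatures(m, catalog)
        Sv = catalog.values.to_numpy()
        y = m.counts["s"].to_numpy(float)
        best = np.linalg.norm(y - Sv @ r.contribution["s"].to_numpy())
        scale = y.sum() / len(catalog.signatures)
        for _ in range(1000):
            c = rng.uniform(0, 2 * scale, size=Sv.shape[1])
            assert np.linalg.norm(y - Sv @ c) >= best - 1e-9

    def test_nnls_residual_matches_independent_solver(self, catalog, rng):
        # independent oracle: bounded least squares via a different algorithm
        Sv = catalog.values.to_numpy()
        for _ in range(50):
            y = rng.integers(0, 25, 96).astype(float)
            m = _mcm({"s": y})
            r = fit_to_signatures(m, catalog)
            res_pkg = np.linalg.norm(y - Sv @ r.contribution["s"].to_numpy())
            oracle = lsq_linear(Sv, y, bounds=(0, np.inf), tol=1e-14)
            res_oracle = np.linalg.norm(y - Sv @ oracle.x)
            assert res_pkg <= res_oracle + 1e-9

    def test_channel_mismatch_errors(self, catalog):
        df = pd.DataFrame({"s": [1, 2]}, index=["x", "y"])
        with pytest.raises(ChannelMismatchError):
            fit_to_signatures(MutationCountMatrix(df, "sbs_ext1"), catalog)


class TestFilterLowContribution:
    def _small(self):
        channels = sbs_channels(1)
        a = np.zeros(96)
        a[:2] = [0.5, 0.5]
        b = np.zeros(96)
        b[4:6] = [0.5, 0.5]
        c = np.zeros(96)
        c[8:10] = [0.5, 0.5]
        S = SignatureMatrix(pd.DataFrame({"a": a, "b": b, "c": c}, index=channels))
        y = 120 * a + 9 * b  # b sits under the 10-mutation default threshold
        m = MutationCountMatrix(pd.DataFrame({"s": y}, index=channels), "sbs_ext1")
        return m, S

    def test_under_threshold_signature_dropped_then_refit(self):
        m, S = self._small()
        r = filter_low_contribution(fit_to_signatures(m, S))
        c = r.contribution["s"]
        assert c["a"] > 0 and c["b"] == 0 and c["c"] == 0

    def test_idempotent_when_all_clear_threshold(self, catalog, rng):
        m = _mcm({"s": 300 * catalog["SBS1"] + 300 * catalog["SBS13"]})
        first = filter_low_contribution(fit_to_signatures(m, catalog))
        second = filter_low_contribution(first)
        pd.testing.assert_frame_equal(first.contribution, second.contribution)

    def test_zero_threshold_is_identity(self):
        m, S = self._small()
        r = fit_to_signatures(m, S)
        r0 = filter_low_contribution(r, min_mutations=0)
        pd.testing.assert_frame_equal(r0.contribution, r.contribution)


class TestFitStrict:
    def test_pure_signature_yields_single_signature(self, catalog):
        m = _mcm({"s": 1000 * catalog["SBS2"].to_numpy()})
        r = fit_strict(m, catalog, max_delta=0.004)
        support = r.contribution["s"][r.contribution["s"] > 0]
        assert list(support.index) == ["SBS2"]

    def test_max_delta_validated(self, catalog):
        m = _mcm({"s": np.ones(96)})
        with pytest.raises(MutpatError):
            fit_strict(m, catalog, max_delta=0)

    def test_support_subset_of_plain_fit_and_cosine_bound(self, catalog, rng):
        pool = catalog.select(catalog.signatures[:12])
        max_delta = 0.01
        for _ in range(5):
            sigs = rng.choice(pool.signatures, 3, replace=False)
            y = np.zeros(96)
            for s in sigs:
                y += rng.multinomial(300, pool[s].to_numpy())
            m = _mcm({"s": y})
            plain = fit_to_signatures(m, pool)
            strict = fit_strict(m, pool, max_delta=max_delta)
            sup_plain = set(plain.contribution["s"][plain.contribution["s"] > 0].index)
            sup_strict = set(
                strict.contribution["s"][strict.contribution["s"] > 0].index
            )
            assert sup_strict <= sup_plain
            n_dropped = len(pool.signatures) - len(sup_strict)
            assert strict.cosine["s"] >= plain.cosine["s"] - n_dropped * max_delta

    def test_stop_returns_fit_before_the_break(self, catalog, rng):
        # walking the elimination path by hand must give the same selection
        pool = catalog.select(catalog.signatures[:8])
        y = (
            400 * pool["SBS1"].to_numpy() + 300 * pool["SBS4"].to_numpy()
        ).round()
        path = backwards_elimination_path(y, pool.values)
        max_delta = 0.01
        chosen = path[0]
        for nxt in path[1:]:
            if chosen[2] - nxt[2] > max_delta:
                break
            chosen = nxt
        names, _, _ = select_from_path(path, max_delta)
        assert names == chosen[0]

    def test_best_subset_matches_or_beats_backwards_cosine(self, catalog, rng):
        pool = catalog.select(catalog.signatures[:6])
        y = rng.multinomial(500, (pool.values.to_numpy() @ np.full(6, 1 / 6)))
        m = _mcm({"s": y.astype(float)})
        back = fit_strict(m, pool, max_delta=0.004, method="backwards")
        best = fit_strict(m, pool, max_delta=0.004, method="best_subset")
        assert best.cosine["s"] >= back.cosine["s"] - 1e-9

    def test_best_subset_refuses_large_catalogs(self, catalog):
        m = _mcm({"s": np.ones(96)})
        with pytest.raises(MutpatError, match="force"):
            fit_strict(m, catalog, method="best_subset")


class TestBootstrap:
    def test_pure_signature_always_present(self, catalog):
        pool = catalog.select(catalog.signatures[:10])
        m = _mcm({"s": 2000 * pool["SBS2"].to_numpy()})
        b = fit_bootstrapped(m, pool, n_boot=30, method="strict", seed=1)
        assert b.presence_fraction.loc["SBS2", "s"] == pytest.approx(1.0)
        assert b.mean_nonzero_contribution.loc["SBS2", "s"] > 1000

    def test_seeded_determinism(self, catalog):
        pool = catalog.select(catalog.signatures[:6])
        m = _mcm({"s": 200 * pool["SBS1"] + 200 * pool["SBS4"]})
        b1 = fit_bootstrapped(m, pool, n_boot=10, seed=42)
        b2 = fit_bootstrapped(m, pool, n_boot=10, seed=42)
        np.testing.assert_array_equal(b1.iterations, b2.iterations)

    def test_near_collinear_signatures_anticorrelate(self, rng):
        channels = sbs_channels(1)
        base = rng.dirichlet(np.full(96, 0.2))
        twin = 0.97 * base + 0.03 * rng.dirichlet(np.full(96, 0.2))
        other = rng.dirichlet(np.full(96, 0.2))
        S = SignatureMatrix(
            pd.DataFrame(
                {"t1": base, "t2": twin / twin.sum(), "bg": other}, index=channels
            )
        )
        y = rng.multinomial(3000, (0.5 * base + 0.5 * twin / twin.sum()))
        m = _mcm({"s": y.astype(float)})
        b = fit_bootstrapped(m, S, n_boot=100, seed=3)
        corr = bootstrap_correlation(b, "s")
        assert corr.loc["t1", "t2"] < -0.5

    def test_correlation_matches_manual_pearson_and_is_symmetric(self, catalog):
        pool = catalog.select(catalog.signatures[:5])
        m = _mcm({"s": 300 * pool["SBS1"] + 300 * pool["SBS5"]})
        b = fit_bootstrapped(m, pool, n_boot=50, seed=9)
        corr = bootstrap_correlation(b, "s")
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-12)
        data = b.iterations[:, [b.signatures.index(s) for s in corr.index], 0]
        manual = np.corrcoef(data, rowvar=False)
        np.testing.assert_allclose(corr.to_numpy(), manual, atol=1e-12)

    def test_too_few_iterations_rejected(self, catalog):
        pool = catalog.select(catalog.signatures[:3])
        m = _mcm({"s": 100 * pool["SBS1"].to_numpy()})
        b = fit_bootstrapped(m, pool, n_boot=2, seed=0)
        with pytest.raises(MutpatError):
            bootstrap_correlation(b, "s")


class TestMergeSignatures:
    def test_duplicate_columns_merge_into_original(self, catalog):
        df = pd.DataFrame(
            {"X": catalog["SBS1"], "Y": catalog["SBS1"], "Z": catalog["SBS10a"]}
        )
        merged = merge_signatures(SignatureMatrix(df), cos_cutoff=0.95)
        assert "X;Y" in merged.signatures and len(merged.signatures) == 2
        np.testing.assert_allclose(merged["X;Y"], catalog["SBS1"], atol=1e-12)

    def test_no_similar_pair_is_identity(self, catalog):
        sub = catalog.select(["SBS2", "SBS10a"])
        merged = merge_signatures(sub, cos_cutoff=0.99)
        assert merged.signatures == sub.signatures

    def test_merged_columns_sum_to_one(self, catalog, rng):
        sub = catalog.select(list(rng.choice(catalog.signatures, 8, replace=False)))
        merged = merge_signatures(sub, cos_cutoff=0.5)
        np.testing.assert_allclose(merged.values.sum(axis=0), 1.0, atol=1e-9)


class TestNmf:
    def _mix(self, catalog, rng, n_samples=30):
        a = catalog["SBS2"].to_numpy()  # concentrated, well separated pair
        b = catalog["SBS10a"].to_numpy()
        cols = {}
        for i in range(n_samples):
            # weights spanning the whole simplex (near-pure samples included)
            # keep the rank-2 factorization identifiable
            w = rng.uniform(0.0, 1.0)
            cols[f"s{i}"] = rng.multinomial(2000, w * a + (1 - w) * b)
        df = pd.DataFrame(cols, index=catalog.channels)
        return MutationCountMatrix(df, "sbs_ext1")

    def test_two_signature_recovery(self, catalog, rng):
        m = self._mix(catalog, rng)
        res = extract_signatures(m, rank=2, n_runs=5, seed=11)
        from mutpat import cos_sim_matrix

        sims = cos_sim_matrix(res.signatures, catalog.select(["SBS2", "SBS10a"]))
        # each truth signature matched by a distinct extracted column
        assert sims.max(axis=0).min() > 0.95
        assert sims.values.argmax(axis=0)[0] != sims.values.argmax(axis=0)[1]

    def test_reconstruction_error_non_increasing_in_rank(self, catalog, rng):
        m = self._mix(catalog, rng)
        survey = rank_survey(m, ranks=[1, 2, 3], n_runs=4, seed=5)
        errs = survey["reconstruction_error"].to_numpy()
        assert errs[0] >= errs[1] >= errs[2] - 1e-6

    def test_rename_identical_column_gets_like_suffix(self, catalog):
        from mutpat.signatures import NmfResult

        sigs = catalog.select(["SBS1", "SBS2"]).values.copy()
        sigs.columns = ["A", "B"]
        res = NmfResult(
            sigs,
            pd.DataFrame(np.ones((2, 1)), index=["A", "B"], columns=["s"]),
            0.0,
            2,
            1,
            None,
        )
        renamed = rename_extracted(res, catalog, cos_cutoff=0.85)
        assert list(renamed.signatures.columns) == ["SBS1-like", "SBS2-like"]

    def test_bad_rank_rejected(self, catalog, rng):
        m = self._mix(catalog, rng, n_samples=5)
        with pytest.raises(MutpatError):
            extract_signatures(m, rank=0)
        with pytest.raises(MutpatError):
            extract_signatures(m, rank=5)
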