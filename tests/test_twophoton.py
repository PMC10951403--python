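"""Two-photon preprocessing, responsiveness screening, d' and the encoding
model (ridge, permutation threshold, weight sums, unique EV)."""

import numpy as np
import pandas as pd
import pytest

from texgeom import twophoton as tp
from texgeom.synth import make_trial_schedule

GROUPS = ("marginal", "spectral", "linear_cc", "energy_cc")
GB = {g: slice(2 * i, 2 * i + 2) for i, g in enumerate(GROUPS)}


class TestPreprocess:
    def test_zero_neuropil_leaves_soma(self):
        rng = np.random.default_rng(0)
        soma = 100.0 + rng.random((3, 200))
        tr = tp.preprocess_traces(soma, np.zeros_like(soma), rate_hz=10.0)
        assert np.array_equal(tr.corrected, soma)

    def test_pure_linear_drift_maps_to_zero_dff(self):
        t = np.arange(300, dtype=float)
        soma = 200.0 - 0.1 * t
        tr = tp.preprocess_traces(soma[None], np.zeros((1, 300)), rate_hz=10.0)
        assert np.allclose(tr.dff_pct, 0.0, atol=1e-9)

    def test_nonpositive_baseline_masked(self):
        soma = np.vstack([np.full(100, -5.0), np.full(100, 50.0) + np.arange(100) * 0.01])
        with pytest.warns(UserWarning, match="masked"):
            tr = tp.preprocess_traces(soma, np.zeros_like(soma), rate_hz=10.0)
        assert np.isnan(tr.dff_pct[0]).all()
        assert np.isfinite(tr.dff_pct[1]).all()


def _mini_schedule():
    return make_trial_schedule(
        "twophoton", 0, families=("a",), n_exemplars=2, n_repeats=3, n_blanks=4,
        rotations=(0,),
    )


class TestFrameZero:
    def test_constant_trace_gives_zero_trials(self):
        sch = _mini_schedule()
        rate = 10.0
        dff = np.full((2, int(sch.duration_s * rate) + 1), 3.3)
        trials = tp.frame_zero_tensor(dff, sch, rate_hz=rate)
        assert np.allclose(trials.stim, 0.0)
        assert np.allclose(trials.blanks, 0.0)
        assert trials.blanks.shape[0] == 4

    def test_step_at_onset_has_preserved_height(self):
        sch = _mini_schedule()
        rate = 10.0
        n = int(sch.duration_s * rate) + 1
        dff = np.zeros((1, n))
        onsets = sch.onset_frames(rate)
        stim_rows = np.flatnonzero(~sch.trials.is_blank.to_numpy())
        for i in onsets[stim_rows]:
            dff[0, i : i + 3] = 5.0  # 300 ms step from onset
        trials = tp.frame_zero_tensor(dff, sch, rate_hz=rate)
        i0 = np.flatnonzero(trials.time_ms == 0.0)[0]
        assert np.allclose(trials.stim[:, 0, i0], 5.0)


def _trial_responses(resp_by_exemplar, blanks, window_frames=3):
    """Build a TrialResponses with constant within-window responses."""
    rows, segs = [], []
    time_ms = np.array([-250.0, 0.0, 250.0, 375.0, 500.0])
    for key, reps in resp_by_exemplar.items():
        for r_i, val in enumerate(reps):
            seg = np.zeros((val.shape[0] if val.ndim else 1, len(time_ms)))
            seg[:, 2:] = np.asarray(val)[:, None]
            rows.append((*key, r_i))
            segs.append(seg)
    blank_segs = []
    for val in blanks:
        seg = np.zeros((np.asarray(val).shape[0], len(time_ms)))
        seg[:, 2:] = np.asarray(val)[:, None]
        blank_segs.append(seg)
    return tp.TrialResponses(
        stim=np.array(segs),
        index=pd.DataFrame(
            rows, columns=["family", "stim_class", "exemplar_id", "rotation_deg", "repeat"]
        ),
        blanks=np.array(blank_segs),
        time_ms=time_ms,
        rate_hz=4.0,
    )


class TestSelectResponsive:
    def test_dprime_stim_arithmetic(self):
        # mu_stim 2 (sd 1), mu_blank 0 (sd 1) -> d'_stim = (2-0)/(1+1) = 1.0
        trials = _trial_responses(
            {("a", "texture", 0, 0): [np.array([1.0, 10.0]), np.array([3.0, 10.0])]},
            blanks=[np.array([-1.0, 0.0]), np.array([1.0, 0.0])],
        )
        mask, dp = tp.select_responsive(trials, d_min=1.0, dff_min_pct=1.0)
        assert dp[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert mask[0]

    def test_blank_identical_cell_excluded(self):
        trials = _trial_responses(
            {("a", "texture", 0, 0): [np.array([1.0]), np.array([3.0])]},
            blanks=[np.array([1.0]), np.array([3.0])],
        )
        mask, dp = tp.select_responsive(trials)
        assert not mask[0]
        assert dp[0, 0] == 0.0


class TestTexScrDprime:
    @staticmethod
    def _table(values, stim):
        return tp.CellResponseTable(values=values, stimuli=stim)

    def _random_table(self, rng, n_cells=7, n_ex=10):
        rows = [
            (fam, cls, e, rot)
            for fam in ("a", "b")
            for cls in ("texture", "scramble")
            for e in range(n_ex)
            for rot in (0, 90)
        ]
        stim = pd.DataFrame(rows, columns=["family", "stim_class", "exemplar_id", "rotation_deg"])
        vals = rng.standard_normal((n_cells, len(rows)))
        return self._table(vals, stim)

    def test_matches_straight_formula_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            table = self._random_table(rng)
            got = tp.cell_texscr_dprime(table)
            is_tex = (table.stimuli.stim_class == "texture").to_numpy()
            a, b = table.values[:, is_tex], table.values[:, ~is_tex]
            expect = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(
                (a.var(axis=1) + b.var(axis=1)) / 2
            )
            assert np.allclose(got, expect, atol=1e-12)

    def test_swapping_classes_flips_sign(self):
        rng = np.random.default_rng(1)
        table = self._random_table(rng)
        d = tp.cell_texscr_dprime(table)
        swapped = table.stimuli.copy()
        swapped["stim_class"] = swapped.stim_class.map(
            {"texture": "scramble", "scramble": "texture"}
        )
        d2 = tp.cell_texscr_dprime(self._table(table.values, swapped))
        assert np.allclose(d, -d2, atol=1e-12)

    def test_per_family_columns(self):
        rng = np.random.default_rng(2)
        table = self._random_table(rng)
        df = tp.cell_texscr_dprime(table, per_family=True)
        assert list(df.columns) == ["a", "b"]
        assert len(df) == table.n_cells


class TestRidge:
    def test_closed_form_matches_sklearn(self):
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 8))
        y = rng.standard_normal(40)
        for lam in (0.1, 1.0, 100.0):
            W, b = tp.ridge_weights(X, y[:, None], lam)
            sk = Ridge(alpha=lam).fit(X, y)
            assert np.allclose(W[:, 0], sk.coef_, atol=1e-10)
            assert b[0] == pytest.approx(sk.intercept_, abs=1e-10)

    def test_three_stimulus_toy_matches_formula(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = np.array([1.0, 2.0, 2.5])
        lam = 0.5
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        expect = np.linalg.solve(Xc.T @ Xc + lam * np.eye(2), Xc.T @ yc)
        W, _ = tp.ridge_weights(X, y[:, None], lam)
        assert np.allclose(W[:, 0], expect, atol=1e-14)

    def test_noiseless_linear_cell_fully_explained(self):
        rng = np.random.default_rng(4)
        rows = [
            (fam, cls, e, 0)
            for fam in ("a", "b")
            for cls in ("texture", "scramble")
            for e in range(10)
        ]
        stim = pd.DataFrame(rows, columns=["family", "stim_class", "exemplar_id", "rotation_deg"])
        X = rng.standard_normal((len(rows), 8))
        w_true = rng.standard_normal(8)
        table = tp.CellResponseTable((X @ w_true)[None, :], stim)
        fit = tp.fit_encoding_model(table, X, rng_seed=0)
        assert fit.cv_ev_pct[0] > 99.0
        w = fit.weights[0]
        assert np.dot(w, w_true) / (np.linalg.norm(w) * np.linalg.norm(w_true)) > 0.999

    def test_rank_deficient_features_rejected(self):
        stim = pd.DataFrame(
            [("a", "texture", e, 0) for e in range(6)],
            columns=["family", "stim_class", "exemplar_id", "rotation_deg"],
        )
        X = np.ones((6, 2))
        with pytest.raises(ValueError, match="degenerate"):
            tp.fit_encoding_model(tp.CellResponseTable(np.zeros((1, 6)), stim), X)


class TestPermutationThreshold:
    @pytest.fixture(scope="class")
    def noise_table(self):
        rng = np.random.default_rng(5)
        rows = [
            (fam, cls, e, rot)
            for fam in ("a", "b")
            for cls in ("texture", "scramble")
            for e in range(8)
            for rot in (0, 90)
        ]
        stim = pd.DataFrame(rows, columns=["family", "stim_class", "exemplar_id", "rotation_deg"])
        X = rng.standard_normal((len(rows), 8))
        Y = rng.standard_normal((30, len(rows)))
        return tp.CellResponseTable(Y, stim), X

    def test_alpha_one_returns_distribution_maximum(self, noise_table):
        table, X = noise_table
        res = tp.permutation_ev_threshold(table, X, n_perm=5, alpha=1.0, rng_seed=0)
        assert res["threshold_pct"] == pytest.approx(res["null_ev_pct"].min())
        res95 = tp.permutation_ev_threshold(table, X, n_perm=5, alpha=0.0, rng_seed=0)
        assert res95["threshold_pct"] == pytest.approx(res95["null_ev_pct"].max())

    def test_seeded_threshold_reproducible(self, noise_table):
        table, X = noise_table
        a = tp.permutation_ev_threshold(table, X, n_perm=5, rng_seed=3)
        b = tp.permutation_ev_threshold(table, X, n_perm=5, rng_seed=3)
        assert a["threshold_pct"] == b["threshold_pct"]


class TestWeightAnalysis:
    def test_group_sums(self):
        fit = tp.EncodingModelFit(
            weights=np.array([[0.0, 0.0, 1.0, -2.0, 0.5, 0.5, 3.0, -3.0]]),
            intercepts=np.zeros(1), lambdas=np.ones(1), cv_ev_pct=np.zeros(1),
            lambda_grid=np.ones(1), folds=[], group_blocks=GB,
        )
        W = tp.group_weight_sums(fit)
        assert W.loc[0, "marginal"] == 0.0
        assert W.loc[0, "spectral"] == 3.0
        assert W.loc[0, "energy_cc"] == 6.0
        fit.weights = fit.weights * 2.5
        assert tp.group_weight_sums(fit).loc[0, "spectral"] == 7.5

    def test_unique_ev_zero_for_irrelevant_group(self):
        rng = np.random.default_rng(6)
        rows = [
            (fam, cls, e, rot)
            for fam in ("a", "b")
            for cls in ("texture", "scramble")
            for e in range(8)
            for rot in (0, 90)
        ]
        stim = pd.DataFrame(rows, columns=["family", "stim_class", "exemplar_id", "rotation_deg"])
        X = rng.standard_normal((len(rows), 8))
        w = np.zeros(8)
        w[GB["energy_cc"]] = [2.0, -1.5]  # cells driven only by energy columns
        y = X @ w + 0.05 * rng.standard_normal(len(rows))
        table = tp.CellResponseTable(np.tile(y, (5, 1)), stim)
        res = tp.unique_ev(table, X, GB, rng_seed=0)
        assert len(res.cell_indices) == 5
        assert (res.delta_ev_pct["energy_cc"] > 50).all()
        assert np.abs(res.delta_ev_pct["marginal"]).max() < 5.0
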