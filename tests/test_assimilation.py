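import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grouplearn import (
    DesignConfig,
    assimilation_series,
    condition_difference_series,
    fit_log_regression,
    kde_scott,
    last_trial_test,
    wilcoxon_signed_rank,
)
from grouplearn.simulate import cohort_designs
from tests.conftest import make_records


def _records_from_sequences(seqs, designs):
    """Trial table where agent -> list of predicted vases (presentation
    order)."""
    rows, t = [], 0
    cond_of = {a.agent_id: a.condition for a in designs[0]}
    for aid, seq in seqs.items():
        for i, v in enumerate(seq, start=1):
            t += 1
            rows.append(
                {
                    "participant_id": 0,
                    "block": 1,
                    "global_trial_index": t,
                    "agent_id": aid,
                    "condition": cond_of[aid],
                    "presentation_index": i,
                    "predicted_vase": v,
                    "actual_choice": 0,
                    "missed": False,
                }
            )
    df = pd.DataFrame(rows)
    df["predicted_vase"] = df["predicted_vase"].astype("Int64")
    return df


def test_identical_predictions_give_zero_dispersion():
    designs = cohort_designs(1, DesignConfig())
    seqs = {aid: [0, 1, 2, 0, 1] for aid in
            ["L1", "L2", "L3", "L4", "N1", "N2", "N3", "N4"]}
    rec = _records_from_sequences(seqs, designs)
    series = assimilation_series(rec, designs)
    assert np.allclose(series["dispersion_bits"], 0.0, atol=1e-12)
    assert len(series) == 2 * 5  # 2 conditions x 5 presentation indices


def test_first_presentation_dispersion_hand_value():
    """At k=1 with the four agents predicting vases 0..3, every smoothed
    distribution is a permutation of (2/5, 1/5, 1/5, 1/5), the mean is
    uniform, and all four Jeffreys divergences from the mean are equal."""
    designs = cohort_designs(1, DesignConfig())
    seqs = {"L1": [0], "L2": [1], "L3": [2], "L4": [3],
            "N1": [0], "N2": [1], "N3": [2], "N4": [3]}
    rec = _records_from_sequences(seqs, designs)
    series = assimilation_series(rec, designs)
    p = np.array([2 / 5, 1 / 5, 1 / 5, 1 / 5])
    q = np.full(4, 0.25)
    expected = math.fsum(pi * math.log2(pi / qi) for pi, qi in zip(p, q))
    expected += math.fsum(qi * math.log2(qi / pi) for pi, qi in zip(p, q))
    assert np.allclose(series["dispersion_bits"], expected, atol=1e-12)


def test_dispersion_invariant_under_agent_and_vase_relabeling():
    designs = cohort_designs(1, DesignConfig())
    rng = np.random.default_rng(0)
    aids = ["L1", "L2", "L3", "L4"]
    seqs = {aid: rng.integers(0, 4, size=8).tolist() for aid in aids}
    seqs.update({f"N{i}": [0] * 8 for i in range(1, 5)})
    base = assimilation_series(_records_from_sequences(seqs, designs), designs)

    # permute which agent carries which sequence
    perm = {"L1": "L3", "L2": "L4", "L3": "L1", "L4": "L2"}
    seqs_a = {perm.get(k, k): v for k, v in seqs.items()}
    relabeled = assimilation_series(_records_from_sequences(seqs_a, designs), designs)
    logo = lambda s: s[s["condition"] == "Logo"].sort_values("k")["dispersion_bits"]
    assert np.allclose(logo(base), logo(relabeled), atol=1e-12)

    # permute the vase labels consistently across all sequences
    vperm = [2, 0, 3, 1]
    seqs_b = {k: [vperm[v] for v in vs] for k, vs in seqs.items()}
    revased = assimilation_series(_records_from_sequences(seqs_b, designs), designs)
    assert np.allclose(logo(base), logo(revased), atol=1e-12)


def test_requested_k_beyond_schedule_rejected():
    designs = cohort_designs(1, DesignConfig())
    seqs = {aid: [0, 1] for aid in ["L1", "L2", "L3", "L4", "N1", "N2", "N3", "N4"]}
    rec = _records_from_sequences(seqs, designs)
    with pytest.raises(ValueError, match="exceeds"):
        assimilation_series(rec, designs, ks=[5])


def test_wilcoxon_exact_all_positive_small_n():
    """Six positive differences: one-sided exact p is 1/2^6 = 1/64."""
    res = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6], method="exact",
                               alternative="greater")
    assert res.p == pytest.approx(1 / 64, abs=1e-12)
    assert res.statistic == 21.0


def test_wilcoxon_exact_matches_scipy():
    rng = np.random.default_rng(1)
    for _ in range(10):
        d = rng.normal(0.2, 1.0, size=12)
        mine = wilcoxon_signed_rank(d, method="exact")
        ref = stats.wilcoxon(d, method="exact")
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)


def test_wilcoxon_exact_agrees_with_approximation_at_n26():
    rng = np.random.default_rng(7)
    for _ in range(10):
        d = rng.normal(0.1, 1.0, size=26)
        exact = wilcoxon_signed_rank(d, method="exact")
        approx = wilcoxon_signed_rank(d, method="approx")
        assert abs(exact.p - approx.p) < 0.01


def test_wilcoxon_zero_and_tie_conventions():
    res = wilcoxon_signed_rank([0.0, 0.0, 1.0, -2.0, 3.0])
    assert res.n == 3  # zeros discarded
    with pytest.raises(ValueError, match="untied"):
        wilcoxon_signed_rank([1.0, 1.0, 2.0], method="exact")
    degen = wilcoxon_signed_rank([0.0, 0.0])
    assert degen.degenerate


def test_last_trial_test_identical_conditions_degenerate():
    designs = cohort_designs(2, DesignConfig())
    frames = []
    for pid in (0, 1):
        seqs = {aid: [0, 1, 2, 3] for aid in
                ["L1", "L2", "L3", "L4", "N1", "N2", "N3", "N4"]}
        rec = _records_from_sequences(seqs, designs)
        rec["participant_id"] = pid
        frames.append(rec)
    series = assimilation_series(pd.concat(frames, ignore_index=True), designs)
    res = last_trial_test(series)
    assert res.degenerate


def test_condition_difference_series_sign_and_constant_offset():
    k = np.arange(1, 11)
    rows = []
    for pid in range(3):
        for kk in k:
            rows.append({"participant_id": pid, "condition": "Logo", "k": kk,
                         "dispersion_bits": 0.5})
            rows.append({"participant_id": pid, "condition": "NoLogo", "k": kk,
                         "dispersion_bits": 0.7})
    diff = condition_difference_series(pd.DataFrame(rows))
    # NoLogo - Logo: positive when Logo dispersion is lower
    assert np.allclose(diff["mean_diff_bits"], 0.2)
    assert len(diff) == 10


def test_log_regression_noiseless_recovery_and_oracle():
    k = np.arange(1, 51)
    y = 0.5 + 0.2 * np.log(k)
    res = fit_log_regression(pd.DataFrame({"k": k, "mean_diff_bits": y}))
    assert res.beta1 == pytest.approx(0.2, abs=1e-10)
    assert res.beta0 == pytest.approx(0.5, abs=1e-10)
    assert res.r_sq == pytest.approx(1.0, abs=1e-10)
    assert res.df_den == 48

    flat = fit_log_regression(pd.DataFrame({"k": k, "mean_diff_bits": np.ones(50)}))
    assert flat.beta1 == pytest.approx(0.0, abs=1e-12)
    assert flat.r_sq == pytest.approx(0.0, abs=1e-12)

    # normal-equations oracle on random data
    rng = np.random.default_rng(5)
    y = rng.normal(size=50)
    res = fit_log_regression(pd.DataFrame({"k": k, "mean_diff_bits": y}))
    x = np.log(k)
    X = np.column_stack([np.ones(50), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
    assert res.beta0 == pytest.approx(beta[0], abs=1e-10)
    assert res.beta1 == pytest.approx(beta[1], abs=1e-10)
    assert res.r_sq == pytest.approx(r2, abs=1e-10)
    assert res.F == pytest.approx(res.t_beta1**2, abs=1e-8)


def test_log_regression_input_validation():
    with pytest.raises(ValueError):
        fit_log_regression(pd.DataFrame({"k": [1, 2], "mean_diff_bits": [0.1, 0.2]}))
    with pytest.raises(ValueError, match="constant predictor"):
        fit_log_regression(
            pd.DataFrame({"k": [1, 1, 1], "mean_diff_bits": [0.1, 0.2, 0.3]})
        )


def test_kde_scott_bandwidth_and_normalization():
    rng = np.random.default_rng(11)
    x = rng.normal(size=100)
    grid, dens, bw = kde_scott(x, grid_size=400)
    assert bw[0] == pytest.approx(100 ** (-1 / 5) * x.std(ddof=1), rel=1e-12)
    integral = np.trapezoid(dens, grid)
    assert integral == pytest.approx(1.0, abs=0.01)
    # unimodal around a tight cluster
    tight = rng.normal(3.0, 0.05, size=50)
    g2, d2, _ = kde_scott(tight)
    assert abs(g2[np.argmax(d2)] - 3.0) < 0.1

    xy = rng.normal(size=(200, 2))
    (gx, gy), dens2, bw2 = kde_scott(xy, grid_size=120)
    assert bw2 == pytest.approx(200 ** (-1 / 6) * xy.std(axis=0, ddof=1), rel=1e-12)
    cell = (gx[0, 1] - gx[0, 0]) * (gy[1, 0] - gy[0, 0])
    assert dens2.sum() * cell == pytest.approx(1.0, abs=0.01)

    with pytest.raises(ValueError, match="zero variance"):
        kde_scott(np.ones(10))
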