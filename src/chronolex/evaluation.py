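"""Reproducibility studies: recovery, calibration, and oracle agreement.

Each function here runs one self-contained simulation study over the
package's own generators and analyses and returns summary numbers: can
the weighting-hypothesis comparison recover a planted hypothesis, do the
simulated cohort-by-decade patterns peak where the hypotheses predict, is
decade ablation sensitive and calibrated, are the ordinal fits and the
closed-form walk/alignment/correlation routines exact against independent
oracles.  The study sizes are chosen to give stable rates on a single
CPU in minutes; all randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .ablation import (
    ablate_linear,
    ablate_ordinal,
    f_test_nested,
    fit_linear,
    fit_ordinal,
)
from .assoc_graph import WalkParams, katz_walk
from .embeddings import RSM, DecadeEmbeddings, procrustes_align
from .hypotheses import hypothesis_rsa, simulate_hypothesis_pattern
from .rsa import rsa_spearman, temporal_permutation_test, upper_triangle_values
from .stimuli import build_counterbalance_lists, build_stimulus_set
from .synthetic import (
    CohortSimConfig,
    DriftConfig,
    changed_words,
    decade_rsms,
    default_cohort_exposures,
    simulate_cohort_rsm,
    simulate_diachronic_embeddings,
)

HYPS = ("early", "uniform", "recent")


def hypothesis_recovery_rates(
    seed: int = 0,
    n_seeds: int = 50,
    n_words: int = 100,
    n_decades: int = 10,
    noise_sd: float = 0.05,
) -> dict[str, float]:
    """Fraction of cohort-runs whose generating hypothesis is identified.

    Per seed: one drifting decade series, three cohorts with the default
    exposure windows, a cohort RSM generated under each hypothesis, and
    `hypothesis_rsa` (restricted to the cohort's experienced decades)
    asked to pick the generator.
    """
    hits = {h: 0 for h in HYPS}
    total = {h: 0 for h in HYPS}
    for s in range(n_seeds):
        cfg = DriftConfig(
            n_words=n_words, n_changed=n_words // 2, n_decades=n_decades,
            seed=seed * 100_000 + s,
        )
        series = simulate_diachronic_embeddings(cfg)
        rsms = decade_rsms(series)
        cohorts = default_cohort_exposures([d for d, _ in rsms])
        for hyp in HYPS:
            for ci, exp in enumerate(cohorts):
                sim_cfg = CohortSimConfig(
                    exp.label, exp.experienced_decades, hypothesis=hyp,
                    rsm_noise_sd=noise_sd, seed=seed * 100_000 + s * 10 + ci,
                )
                rsm, label = simulate_cohort_rsm(series, sim_cfg)
                res = hypothesis_rsa(rsm, rsms, exposures=exp)
                total[hyp] += 1
                hits[hyp] += res.best == (label,)
    return {h: hits[h] / total[h] for h in HYPS}


def pattern_peak_rates(
    seed: int = 0, n_seeds: int = 50, n_words: int = 100, noise_sd: float = 0.05
) -> dict[str, float]:
    """Qualitative cohort-by-decade pattern checks.

    Under the recent-weighted hypothesis every cohort's decade-correlation
    curve should peak at the most recent decade; under the early-weighted
    hypothesis the oldest cohort should peak at its earliest experienced
    decade.
    """
    recent_ok = early_ok = 0
    for s in range(n_seeds):
        series = simulate_diachronic_embeddings(
            DriftConfig(n_words=n_words, n_changed=n_words // 2, seed=seed * 100_000 + s)
        )
        rsms = decade_rsms(series)
        cohorts = default_cohort_exposures([d for d, _ in rsms])
        latest = rsms[-1][0]
        pat = simulate_hypothesis_pattern(
            rsms, cohorts, "recent", noise_sd, seed=seed * 100_000 + s
        )
        recent_ok += all(pat.loc[c.label].idxmax() == latest for c in cohorts)
        pat = simulate_hypothesis_pattern(
            rsms, cohorts, "early", noise_sd, seed=seed * 100_000 + s + 1
        )
        oldest = cohorts[-1]
        early_ok += pat.loc[oldest.label].idxmax() == oldest.experienced_decades[0]
    return {
        "recent_all_cohorts_peak_latest": recent_ok / n_seeds,
        "early_oldest_peaks_earliest": early_ok / n_seeds,
    }


def katz_walk_oracle_max_error(seed: int = 0, n_cases: int = 100) -> float:
    """Max |closed form - truncated series| over random small graphs.

    Decay values stay below 0.6 so the 50-term series itself is converged
    far beyond the comparison tolerance.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        n = int(rng.integers(2, 13))
        m = rng.uniform(0, 1, size=(n, n)) * (rng.random((n, n)) > 0.3)
        sums = m.sum(axis=1, keepdims=True)
        P = np.divide(m, sums, out=np.zeros_like(m), where=sums > 0)
        alpha = float(rng.uniform(0.1, 0.6))
        params = WalkParams(alpha=alpha, max_terms=50)
        closed = katz_walk(P, params)
        series_sum = np.zeros_like(P)
        term = np.eye(n)
        for _ in range(params.max_terms + 1):
            series_sum += term
            term = alpha * term @ P
        worst = max(worst, float(np.max(np.abs(closed - series_sum))))
    return worst


def procrustes_oracle_errors(seed: int = 0, n_cases: int = 100) -> dict[str, float]:
    """Exact-rotation residual and worst residual gap vs the SVD closed form."""
    rng = np.random.default_rng(seed)
    exact_worst = 0.0
    random_worst = 0.0
    for _ in range(n_cases):
        n, d = int(rng.integers(5, 30)), int(rng.integers(2, 8))
        vocab = [f"w{i}" for i in range(n)]
        a = rng.normal(size=(n, d))
        q, _ = np.linalg.qr(rng.normal(size=(d, d)))
        src = DecadeEmbeddings(1900, vocab, a)
        _, rotated = procrustes_align(src, DecadeEmbeddings(1990, vocab, a @ q))
        exact_worst = max(exact_worst, float(np.linalg.norm(rotated.vectors - a @ q)))

        b = rng.normal(size=(n, d))
        _, rotated = procrustes_align(src, DecadeEmbeddings(1990, vocab, b))
        u, _, vt = np.linalg.svd(a.T @ b)
        oracle = float(np.linalg.norm(a @ (u @ vt) - b))
        random_worst = max(
            random_worst, abs(float(np.linalg.norm(rotated.vectors - b)) - oracle)
        )
    return {"exact_rotation_residual": exact_worst, "svd_oracle_gap": random_worst}


def _random_rsm(v: int, rng: np.random.Generator) -> RSM:
    m = rng.uniform(-1, 1, size=(v, v))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return RSM([f"w{i:02d}" for i in range(v)], m)


def rsa_oracle_max_error(seed: int = 0, n_cases: int = 100) -> float:
    """Worst |rsa_spearman - naive rank-then-Pearson| over random pairs."""

    def naive(x, y):
        def ranks(vals):
            r = np.empty(len(vals))
            for i, vi in enumerate(vals):
                less = np.sum(vals < vi)
                equal = np.sum(vals == vi)
                r[i] = less + (equal + 1) / 2.0
            return r

        return float(np.corrcoef(ranks(x), ranks(y))[0, 1])

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        v = int(rng.integers(4, 16))
        a, b = _random_rsm(v, rng), _random_rsm(v, rng)
        got = rsa_spearman(a, b).rho
        want = naive(upper_triangle_values(a), upper_triangle_values(b))
        worst = max(worst, abs(got - want))
    return worst


def _decade_predictors(seed: int, n_words: int = 25) -> pd.DataFrame:
    series = simulate_diachronic_embeddings(
        DriftConfig(n_words=n_words, n_changed=n_words // 2, seed=seed)
    )
    return pd.DataFrame(
        {f"sim_{d}": upper_triangle_values(r) for d, r in decade_rsms(series)}
    )


def linear_ablation_signal_rate(seed: int = 0, n_runs: int = 100) -> float:
    """How often ablating a planted decade is the top, significant hit.

    The target is the 1990s decade-RSM cells plus N(0, 0.01^2) noise;
    success requires the 1990 column to have both the largest mean
    held-out delta-R^2 and a significant full-data F-test.
    """
    ok = 0
    for run in range(n_runs):
        rng = np.random.default_rng(seed * 100_000 + run)
        X = _decade_predictors(seed * 100_000 + run)
        y = X["sim_1990"] + rng.normal(0, 0.01, size=len(X))
        results = ablate_linear(y, X, folds=5, seed=seed * 100_000 + run)
        by_r2 = max((r for r in results if r.ablated != "none"), key=lambda r: r.delta_r2)
        sig = next(r for r in results if r.ablated == "sim_1990")
        ok += (by_r2.ablated == "sim_1990") and (sig.p_value < 0.05)
    return ok / n_runs


def linear_ablation_null_rates(seed: int = 0, n_runs: int = 1000) -> pd.Series:
    """Per-decade F-test rejection rates when the target is pure noise."""
    rej = None
    for run in range(n_runs):
        rng = np.random.default_rng(seed * 100_000 + run)
        X = _decade_predictors(seed * 100_000 + run)
        y = rng.normal(size=len(X))
        full = fit_linear(y, X)
        p_values = {}
        for col in X.columns:
            reduced = fit_linear(y, X.drop(columns=[col]))
            _, p = f_test_nested(full, reduced)
            p_values[col] = p < 0.05
        row = pd.Series(p_values, dtype=float)
        rej = row if rej is None else rej + row
    return rej / n_runs


def ordinal_recovery_errors(seed: int = 0, n: int = 20_000) -> dict[str, float]:
    """Slope-recovery error at large n and the binary-collapse oracle gap."""
    rng = np.random.default_rng(seed)
    betas = np.array([1.5, -0.5])
    X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["x0", "x1"])
    latent = X.to_numpy() @ betas + rng.logistic(size=n)
    cuts = np.quantile(latent, np.linspace(0, 1, 8)[1:-1])
    y = np.searchsorted(cuts, latent)
    fit = fit_ordinal(y, X)
    max_err = float(np.max(np.abs(fit.betas.to_numpy() - betas)))

    from sklearn.linear_model import LogisticRegression

    y2 = (y >= 4).astype(int)
    collapse = fit_ordinal(y2, X)
    oracle = LogisticRegression(penalty=None, tol=1e-12, max_iter=5000)
    oracle.fit(X.to_numpy(), y2)
    collapse_gap = float(np.max(np.abs(collapse.betas.to_numpy() - oracle.coef_[0])))
    return {"slope_recovery_error": max_err, "binary_collapse_gap": collapse_gap}


def elpd_flag_rates(seed: int = 0, n_runs: int = 20, n: int = 2500) -> dict[str, float]:
    """Calibration of the |ELPD difference| < 4 negligibility rule.

    One strong planted predictor (slope 2) and one null predictor per
    run; the null ablation should be flagged negligible, the strong one
    should exceed twice its standard error.
    """
    null_negligible = strong_detected = 0
    for run in range(n_runs):
        rng = np.random.default_rng(seed * 100_000 + run)
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["strong", "null"])
        latent = 2.0 * X["strong"].to_numpy() + rng.logistic(size=n)
        cuts = np.quantile(latent, np.linspace(0, 1, 8)[1:-1])
        y = np.searchsorted(cuts, latent)
        results = {r.ablated: r for r in ablate_ordinal(y, X, folds=5, seed=run)}
        null_negligible += bool(results["null"].negligible)
        strong = results["strong"]
        strong_detected += abs(strong.elpd_diff) > 2 * strong.elpd_se
    return {
        "null_negligible_rate": null_negligible / n_runs,
        "strong_detected_rate": strong_detected / n_runs,
    }


def stimulus_audit(seed: int = 0) -> dict[str, float]:
    """Full-scale stimulus build and counterbalance audit.

    A 1950-1990 drift axis with a 450-word candidate pool (200 planted
    changed) supports selecting 150 changed + 150 unchanged targets; the
    120-list design is then audited: 75 pairs and 25 targets per list,
    12 or 13 changed targets, per-target inventory of 20 neighbor + 10
    non-neighbor pairs, and full coverage of every pair by some list.
    """
    series = simulate_diachronic_embeddings(
        DriftConfig(n_words=450, n_changed=200, first_decade=1950, n_decades=5,
                    seed=seed)
    )
    stim = build_stimulus_set(series, t1=1950, t2=1990, seed=seed)
    inventory_ok = all(
        len(by_type["n1950"]) == 10
        and len(by_type["n1990"]) == 10
        and len(by_type["non_neighbor"]) == 10
        for by_type in stim.pairs.values()
    )
    lists = build_counterbalance_lists(stim, n_lists=120, seed=seed)
    per_list = lists.groupby("list_id").agg(
        n_pairs=("partner", "size"), n_targets=("target", "nunique")
    )
    changed_per_list = (
        lists[lists.change_status == "changed"].groupby("list_id")["target"].nunique()
    )
    coverage = lists.groupby(["target", "pair_type"])["partner"].nunique()
    return {
        "n_lists": float(lists["list_id"].nunique()),
        "pairs_per_list_ok": float((per_list["n_pairs"] == 75).all()),
        "targets_per_list_ok": float((per_list["n_targets"] == 25).all()),
        "changed_split_ok": float(changed_per_list.isin([12, 13]).all()),
        "inventory_ok": float(inventory_ok),
        "coverage_ok": float((coverage == 10).all()),
    }


def simulator_calibration(seed: int = 0, n_seeds: int = 5) -> dict[str, float]:
    """Mean first-last self-cosines of the two planted word classes."""
    sims_c, sims_u = [], []
    for s in range(n_seeds):
        cfg = DriftConfig(n_words=300, n_changed=150, seed=seed * 100_000 + s)
        series = simulate_diachronic_embeddings(cfg)
        cw = set(changed_words(cfg))
        first, last = series.decade_labels[0], series.decade_labels[-1]
        normed = {
            d: series.get(d).vectors for d in (first, last)
        }
        cos = np.sum(normed[first] * normed[last], axis=1)
        mask = np.array([w in cw for w in series.vocabulary])
        sims_c.extend(cos[mask])
        sims_u.extend(cos[~mask])
    return {
        "changed_mean_self_similarity": float(np.mean(sims_c)),
        "unchanged_mean_self_similarity": float(np.mean(sims_u)),
    }


def temporal_decay_detection_rate(
    seed: int = 0, n_seeds: int = 20, n_perm: int = 300
) -> float:
    """How often the distance-decay permutation test fires on drifted data."""
    hits = 0
    for s in range(n_seeds):
        series = simulate_diachronic_embeddings(
            DriftConfig(n_words=60, n_changed=25, seed=seed * 100_000 + s)
        )
        res = temporal_permutation_test(
            decade_rsms(series), n_perm=n_perm, seed=seed * 100_000 + s
        )
        hits += res.outside_null and res.rho_obs > 0
    return hits / n_seeds
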