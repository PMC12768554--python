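"""Synthetic generators for every input of the pipeline.

Drifting diachronic embeddings, cohort semantic spaces built under a known
weighting hypothesis, association responses sampled from a planted
similarity structure, and ordinal relatedness ratings produced through
monotone thresholds — all pure functions of a config plus seed, with the
ground truth recoverable, so the full analysis chain can be exercised and
its recovery behavior measured without any external downloads.

The drift model keeps word vectors on the unit sphere and separates two
noise sources.  A *cumulative* latent walk carries genuine semantic
change: decade 0 vectors are isotropic Gaussian directions, each
subsequent latent state adds Gaussian jitter (and, for changed words, a
pull toward a fresh random anchor) before re-normalizing.  On top of
that, each decade's *observed* vectors add non-cumulative observation
noise standing in for decade-specific corpus sampling variability —
without it, consecutive decade RSMs would correlate far more strongly
than decade-trained embedding spaces actually do.  Three anchors drive
calibration: the expected observed first-to-last self-cosine of changed
words (0.21), of unchanged words (0.71), and the adjacent-decade RSM
Spearman correlation (0.70).  Calibration is 1-D root finding on fixed
inner-seed Monte-Carlo estimates, alternated to a joint fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .assoc_graph import RECORD_COLUMNS, CohortSpec
from .embeddings import AlignedSeries, DecadeEmbeddings, RSM, cosine_rsm
from .hypotheses import CohortExposure, compute_weights, weighted_mean_rsm, _symmetric_noise

__all__ = [
    "DriftConfig",
    "CohortSimConfig",
    "ResponseSimConfig",
    "RatingSimConfig",
    "simulate_diachronic_embeddings",
    "changed_words",
    "simulate_cohort_rsm",
    "simulate_association_responses",
    "simulate_ratings",
    "default_cohort_exposures",
    "decade_rsms",
]

_CALIBRATION_WORDS = 256
_CALIBRATION_SEED = 12345


@dataclass(frozen=True)
class DriftConfig:
    """Configuration of the diachronic drift generator.

    ``base_drift_sd=None`` calibrates the per-decade cumulative jitter so
    that unchanged words land at ``stable_target_sim``; an explicit value
    (e.g. 0) is used as-is.  ``obs_noise_sd=None`` likewise calibrates the
    per-decade observation noise to ``adjacent_rsm_target`` — unless
    ``base_drift_sd`` was given explicitly, in which case it defaults to 0
    so that zero-drift configs yield literally identical decades.
    """

    n_words: int = 300
    dim: int = 50
    n_decades: int = 10
    base_drift_sd: float | None = None
    obs_noise_sd: float | None = None
    n_changed: int = 150
    change_target_sim: float = 0.21
    stable_target_sim: float = 0.71
    adjacent_rsm_target: float = 0.70
    seed: int = 0
    first_decade: int = 1900
    decade_step: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.n_changed <= self.n_words:
            raise ValueError("n_changed must be in [0, n_words]")
        for t in (self.change_target_sim, self.stable_target_sim):
            if not -1.0 < t < 1.0:
                raise ValueError(f"target similarity {t} outside (-1, 1)")
        if self.n_decades < 1:
            raise ValueError("need at least one decade")

    @property
    def decades(self) -> tuple[int, ...]:
        return tuple(
            self.first_decade + i * self.decade_step for i in range(self.n_decades)
        )


@dataclass(frozen=True)
class CohortSimConfig:
    """One simulated cohort: exposure window, weighting hypothesis, noise."""

    label: str
    experienced_decades: tuple[int, ...]
    hypothesis: str = "recent"
    base: float = 0.5
    rsm_noise_sd: float = 0.05
    seed: int = 0


@dataclass(frozen=True)
class ResponseSimConfig:
    """Softmax association-response sampler settings.

    ``temperature`` controls response concentration: responses are drawn
    without replacement with probability proportional to
    ``exp(similarity / temperature)`` over non-cue words.  The softmax
    sampler is a modelling convenience, not an empirically fitted process.
    """

    responses_per_cue: int = 50
    temperature: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.responses_per_cue < 1:
            raise ValueError("responses_per_cue must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class RatingSimConfig:
    """Ordinal rating generator: latent relatedness through thresholds.

    The latent value is ``intercept + slope * similarity`` plus Gaussian
    noise; the 0-6 rating counts how many of the six ordered thresholds
    lie below it.  Defaults map similarity -1..1 onto a latent -3..3
    spanning the threshold grid.
    """

    thresholds: tuple[float, ...] = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)
    latent_noise_sd: float = 0.75
    raters_per_pair_per_cohort: int = 5
    latent_slope: float = 3.0
    latent_intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if self.raters_per_pair_per_cohort < 1:
            raise ValueError("raters_per_pair_per_cohort must be >= 1")


# ---------------------------------------------------------------------------
# Drift calibration
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _walk_cosine(
    dim: int, steps: int, sigma: float, tau: float, rate: float, seed: int
) -> float:
    """MC expected observed first-to-last cosine under the drift model.

    Latent walk with jitter ``sigma`` (and anchor pull ``rate``); both
    endpoint observations perturbed by observation noise ``tau``.
    """
    rng = np.random.default_rng(seed)
    v0 = _unit(rng.standard_normal((_CALIBRATION_WORDS, dim)))
    anchors = _unit(rng.standard_normal((_CALIBRATION_WORDS, dim)))
    v = v0.copy()
    for _ in range(steps):
        v = (1.0 - rate) * v + rate * anchors + sigma * rng.standard_normal(v.shape)
        v = _unit(v)
    obs0 = _unit(v0 + tau * rng.standard_normal(v0.shape))
    obsT = _unit(v + tau * rng.standard_normal(v.shape))
    return float(np.mean(np.sum(obs0 * obsT, axis=1)))


def _adjacent_rsm_rho(dim: int, steps: int, sigma: float, tau: float, seed: int) -> float:
    """MC mean Spearman between adjacent observed decade RSMs (stable walk)."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    m = 40
    v = _unit(rng.standard_normal((m, dim)))
    iu = np.triu_indices(m, k=1)
    triangles = []
    for _ in range(steps + 1):
        obs = _unit(v + tau * rng.standard_normal(v.shape))
        triangles.append((obs @ obs.T)[iu])
        v = _unit(v + sigma * rng.standard_normal(v.shape))
    rhos = [
        stats.spearmanr(triangles[i], triangles[i + 1]).statistic
        for i in range(len(triangles) - 1)
    ]
    return float(np.mean(rhos))


def _solve(f, lo: float, hi: float, what: str) -> float:
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(f"cannot calibrate {what}: no sign change in [{lo}, {hi}]")
    return float(brentq(f, lo, hi, xtol=1e-5))


@lru_cache(maxsize=32)
def _calibrated_drift(
    dim: int,
    steps: int,
    stable_target: float,
    change_target: float | None,
    adjacent_target: float | None,
    fixed_sigma: float | None,
    fixed_tau: float | None,
) -> tuple[float, float, float]:
    """Calibrate (sigma, tau, rate) to the anchors, honoring fixed values.

    sigma: cumulative jitter -> observed first-last cosine of stable words;
    tau: observation noise -> adjacent-decade RSM correlation;
    rate: anchor pull -> observed first-last cosine of changed words.
    sigma and tau interact, so when both are free their 1-D solves are
    alternated to a fixed point.
    """
    if steps == 0:
        return fixed_sigma or 0.0, fixed_tau or 0.0, 0.0
    tau = fixed_tau if fixed_tau is not None else 0.0
    sigma = fixed_sigma if fixed_sigma is not None else 0.05
    for _ in range(3):
        if fixed_sigma is None:
            sigma = _solve(
                lambda s: _walk_cosine(dim, steps, s, tau, 0.0, _CALIBRATION_SEED)
                - stable_target,
                1e-9, 5.0, "cumulative jitter",
            )
        if fixed_tau is not None or adjacent_target is None:
            break
        tau = _solve(
            lambda t: _adjacent_rsm_rho(dim, steps, sigma, t, _CALIBRATION_SEED)
            - adjacent_target,
            0.0, 5.0, "observation noise",
        )
        if fixed_sigma is not None:
            break
    rate = 0.0
    if change_target is not None:
        f = lambda r: (
            _walk_cosine(dim, steps, sigma, tau, r, _CALIBRATION_SEED) - change_target
        )
        if f(0.0) < 0:
            raise ValueError(
                f"change target {change_target} not below what jitter alone produces"
            )
        if f(0.999) > 0:
            raise ValueError(f"change target {change_target} unreachable by anchor pull")
        rate = float(brentq(f, 0.0, 0.999, xtol=1e-6))
    return sigma, tau, rate


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def changed_words(cfg: DriftConfig) -> list[str]:
    """The planted changed-word list implied by a drift config."""
    width = max(4, len(str(cfg.n_words - 1)))
    return [f"w{i:0{width}d}" for i in range(cfg.n_changed)]


def simulate_diachronic_embeddings(cfg: DriftConfig) -> AlignedSeries:
    """Generate a drifting, already-aligned decade series.

    All decades live in one common frame by construction, so the returned
    series is marked aligned.  The first ``cfg.n_changed`` words are the
    changed class.
    """
    if cfg.n_changed and not cfg.change_target_sim < cfg.stable_target_sim:
        raise ValueError("change_target_sim must be below stable_target_sim")
    steps = cfg.n_decades - 1
    fixed_tau = cfg.obs_noise_sd
    if fixed_tau is None and cfg.base_drift_sd is not None:
        # explicit drift scale implies a fully explicit noise model
        fixed_tau = 0.0
    sigma, tau, rate = _calibrated_drift(
        cfg.dim,
        steps,
        round(cfg.stable_target_sim, 6),
        round(cfg.change_target_sim, 6) if cfg.n_changed and steps > 0 else None,
        round(cfg.adjacent_rsm_target, 6),
        None if cfg.base_drift_sd is None else round(float(cfg.base_drift_sd), 9),
        None if fixed_tau is None else round(float(fixed_tau), 9),
    )

    width = max(4, len(str(cfg.n_words - 1)))
    vocab = [f"w{i:0{width}d}" for i in range(cfg.n_words)]
    rng = np.random.default_rng(cfg.seed)
    v = _unit(rng.standard_normal((cfg.n_words, cfg.dim)))
    anchors = _unit(rng.standard_normal((cfg.n_words, cfg.dim)))
    rates = np.zeros(cfg.n_words)
    rates[: cfg.n_changed] = rate

    def observe(latent: np.ndarray) -> np.ndarray:
        if tau == 0.0:
            return latent.copy()
        return _unit(latent + tau * rng.standard_normal(latent.shape))

    decades = [DecadeEmbeddings(cfg.decades[0], vocab, observe(v))]
    for label in cfg.decades[1:]:
        v = (1.0 - rates[:, None]) * v + rates[:, None] * anchors
        v = _unit(v + sigma * rng.standard_normal(v.shape))
        decades.append(DecadeEmbeddings(label, vocab, observe(v)))
    return AlignedSeries(decades, aligned=True, reference_decade=cfg.decades[-1])


def decade_rsms(series: AlignedSeries) -> list[tuple[int, RSM]]:
    """Convenience: cosine RSM for every decade of a series."""
    return [(emb.decade, cosine_rsm(emb)) for emb in series.decades]


def default_cohort_exposures(decade_labels: list[int]) -> list[CohortExposure]:
    """Three cohorts on the decade axis, in the spirit of a 20-35 / 35-50 /
    50-90 age split observed at the end of the axis: the youngest has
    experienced the last 4 decades, the middle the last 6, the oldest all
    of them."""
    d = list(decade_labels)
    return [
        CohortExposure("young", tuple(d[-4:])),
        CohortExposure("middle", tuple(d[-6:])),
        CohortExposure("old", tuple(d)),
    ]


def simulate_cohort_rsm(
    series: AlignedSeries, cfg: CohortSimConfig
) -> tuple[RSM, str]:
    """A cohort's semantic RSM under a known weighting hypothesis.

    Weighted mean of the cohort's experienced-decade RSMs plus symmetric
    cellwise Gaussian noise (diagonal reset to 1).  Returns the RSM and
    the generating hypothesis label (the recovery ground truth).
    """
    wanted = set(cfg.experienced_decades)
    sub = [(d, r) for d, r in decade_rsms(series) if d in wanted]
    if len(sub) != len(wanted):
        have = {d for d, _ in sub}
        raise KeyError(f"series lacks decades {sorted(wanted - have)}")
    w = compute_weights(cfg.hypothesis, [d for d, _ in sub], cfg.base)
    combo = weighted_mean_rsm([r for _, r in sub], w)
    rng = np.random.default_rng(cfg.seed)
    matrix = combo.matrix + _symmetric_noise(combo.n_words, cfg.rsm_noise_sd, rng)
    np.fill_diagonal(matrix, 1.0)
    return RSM(combo.vocabulary, matrix, source=f"cohort:{cfg.label}"), cfg.hypothesis


def simulate_association_responses(
    agent_rsm: RSM,
    cues: list[str],
    cfg: ResponseSimConfig,
    cohort: CohortSpec | None = None,
) -> pd.DataFrame:
    """Sample SWOW-style cue-response records from a planted RSM.

    Each synthetic participant gives three distinct responses per cue,
    drawn without replacement with probability proportional to
    ``exp(similarity / temperature)`` over non-cue words (Gumbel top-k).
    Enough participants are created to reach ``responses_per_cue``
    records per cue; ages are uniform within the cohort window.
    """
    index = {w: i for i, w in enumerate(agent_rsm.vocabulary)}
    missing = [c for c in cues if c not in index]
    if missing:
        raise KeyError(f"cues not in RSM vocabulary: {missing[:5]}")
    if cohort is None:
        cohort = CohortSpec("all", 18, 90)
    n_participants = math.ceil(cfg.responses_per_cue / 3)
    rng = np.random.default_rng(cfg.seed)
    ages = rng.integers(cohort.min_age, cohort.max_age, size=n_participants)
    vocab = np.asarray(agent_rsm.vocabulary, dtype=object)

    frames = []
    for cue in cues:
        i = index[cue]
        logits = agent_rsm.matrix[i] / cfg.temperature
        logits[i] = -np.inf  # never respond with the cue itself
        gumbel = rng.gumbel(size=(n_participants, len(vocab)))
        top3 = np.argsort(logits[None, :] + gumbel, axis=1)[:, -3:][:, ::-1]
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(
                        [f"{cohort.label}-p{j}" for j in range(n_participants)], 3
                    ),
                    "age": np.repeat(ages, 3),
                    "cue": cue,
                    "response": vocab[top3.ravel()],
                    "position": np.tile([1, 2, 3], n_participants),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[RECORD_COLUMNS]


def simulate_ratings(
    agent_rsm: RSM,
    pairs: pd.DataFrame,
    cfg: RatingSimConfig,
    cohort: str = "YA",
    n_violators: int = 0,
) -> pd.DataFrame:
    """Ordinal relatedness ratings for stimulus pairs, one cohort.

    Latent relatedness is an affine map of the planted similarity plus
    Gaussian noise; the 0-6 rating counts thresholds below the latent
    value.  If the pair table has a ``list_id`` column each (list,
    replicate) is one participant rating that list's pairs; otherwise each
    replicate rates every pair.  Generated keepers have a perfect catch
    score and plausible durations; ``n_violators`` extra participants with
    failing catch scores or too-short durations can be planted to exercise
    the cleaning filter.
    """
    if cohort not in ("YA", "OA"):
        raise ValueError("cohort must be 'YA' or 'OA'")
    age_lo, age_hi = (18, 34) if cohort == "YA" else (63, 93)
    index = {w: i for i, w in enumerate(agent_rsm.vocabulary)}
    for col in ("target", "partner"):
        missing = set(pairs[col]) - set(index)
        if missing:
            raise KeyError(f"pair words not in RSM vocabulary: {sorted(missing)[:5]}")
    rng = np.random.default_rng(cfg.seed)
    thresholds = np.asarray(cfg.thresholds)

    if "list_id" in pairs.columns:
        groups = [(lid, g) for lid, g in pairs.groupby("list_id")]
    else:
        groups = [(0, pairs)]

    frames = []
    for lid, g in groups:
        sims = np.array(
            [agent_rsm.matrix[index[t], index[p]] for t, p in zip(g["target"], g["partner"])]
        )
        for r in range(cfg.raters_per_pair_per_cohort):
            pid = f"{cohort}-l{lid}-r{r}"
            latent = (
                cfg.latent_intercept
                + cfg.latent_slope * sims
                + rng.normal(0.0, cfg.latent_noise_sd, size=len(sims))
            )
            ratings = np.searchsorted(thresholds, latent)
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "age": int(rng.integers(age_lo, age_hi)),
                        "cohort": cohort,
                        "target": g["target"].to_numpy(),
                        "partner": g["partner"].to_numpy(),
                        "pair_type": g["pair_type"].to_numpy(),
                        "change_status": g.get(
                            "change_status", pd.Series(["unchanged"] * len(g))
                        ).to_numpy(),
                        "rating": ratings,
                        "unknown_flag": False,
                        "catch_score": 5,
                        "duration": float(rng.uniform(8.0, 20.0)),
                        "list_id": lid,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)

    if n_violators:
        lid, g = groups[0]
        sims = np.array(
            [agent_rsm.matrix[index[t], index[p]] for t, p in zip(g["target"], g["partner"])]
        )
        for v in range(n_violators):
            fail_catch = v % 2 == 0
            latent = cfg.latent_intercept + cfg.latent_slope * sims + rng.normal(
                0.0, cfg.latent_noise_sd, size=len(sims)
            )
            frames_v = pd.DataFrame(
                {
                    "participant_id": f"{cohort}-violator{v}",
                    "age": int(rng.integers(age_lo, age_hi)),
                    "cohort": cohort,
                    "target": g["target"].to_numpy(),
                    "partner": g["partner"].to_numpy(),
                    "pair_type": g["pair_type"].to_numpy(),
                    "change_status": g.get(
                        "change_status", pd.Series(["unchanged"] * len(g))
                    ).to_numpy(),
                    "rating": np.searchsorted(thresholds, latent),
                    "unknown_flag": False,
                    "catch_score": int(rng.integers(0, 5)) if fail_catch else 5,
                    "duration": 4.0 if not fail_catch else float(rng.uniform(8.0, 20.0)),
                    "list_id": lid,
                }
            )
            out = pd.concat([out, frames_v], ignore_index=True)
    return out
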