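"""Three-tier variant classification from a Gaussian mixture of raw scores.

The pooled finite scores of a landscape are modelled as a mixture of three
Gaussians. The component with the most negative mean captures impactful
substitutions, the middle one mild effects, and the upper one neutral
variation. Two thresholds — the weighted-density crossovers between adjacent
components — cut the score axis into the three classes. Residues are then
called tolerant when at least 10 of their 19 substitutions are neutral
(strictly more than half), sensitive otherwise.

A residue-level confidence flag marks positions whose scores carry little
evolutionary information: low score dispersion at a poorly conserved
position whose alignment column is highly gapped or samples few of the 19
possible substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .alphabet import AA_INDEX, AA_ORDER
from .errors import GmmDegenerateError, InsufficientScoresError
from .landscape import MutationalLandscape

VARIANT_CLASSES = ("impactful", "mild", "neutral", "unscored")

_MIN_SCORES = 30
_VARIANCE_FLOOR = 1e-8
_EM_TOL = 1e-6
_EM_MAX_ITER = 500
_N_RESTARTS = 10


@dataclass
class GmmFit:
    """Sorted three-component fit plus the derived class thresholds."""

    weights: np.ndarray  # (3,), sums to 1
    means: np.ndarray  # (3,), ascending
    variances: np.ndarray  # (3,), positive
    seed: int
    log_likelihood: float
    n_scores: int
    threshold_low: float = float("nan")
    threshold_high: float = float("nan")
    threshold_fallback: list[str] = field(default_factory=list)
    init: str = "quantile"

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "threshold_low": self.threshold_low,
            "threshold_high": self.threshold_high,
            "threshold_fallback": list(self.threshold_fallback),
            "threshold_rule": "weighted-density crossover, midpoint fallback",
            "seed": self.seed,
            "log_likelihood": self.log_likelihood,
            "n_scores": self.n_scores,
            "init": self.init,
        }


@dataclass(frozen=True)
class ConfidenceConfig:
    """Thresholds of the non-confidence rule; all four are tunable."""

    d_min: float = 0.2  # score-dispersion floor
    c_min: float = 0.3  # conservation floor
    g_max: float = 0.5  # gap-fraction ceiling
    s_min: int = 5  # minimum distinct substitutions sampled


def _fit_once(x: np.ndarray, gm_kwargs: dict) -> GaussianMixture:
    gm = GaussianMixture(
        n_components=3,
        covariance_type="full",
        tol=_EM_TOL,
        max_iter=_EM_MAX_ITER,
        reg_covar=1e-10,
        **gm_kwargs,
    )
    gm.fit(x)
    return gm


def _is_degenerate(gm: GaussianMixture) -> bool:
    return bool((gm.covariances_.ravel() < _VARIANCE_FLOOR).any())


def fit_gmm3(scores: np.ndarray, seed: int = 0) -> GmmFit:
    """Fit the three-component Gaussian mixture to pooled raw scores.

    Initialisation places the component means at the 1/6, 1/2 and 5/6
    quantiles of the data with uniform weights, which makes the fit
    deterministic (the seed only drives the fallback random restarts used
    if that fit collapses). Components are reported sorted by mean.
    """
    x = np.asarray(scores, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < _MIN_SCORES:
        raise InsufficientScoresError(
            f"{x.size} finite scores; need at least {_MIN_SCORES} for a "
            "3-component fit"
        )
    X = x.reshape(-1, 1)
    var0 = max(x.var(), _VARIANCE_FLOOR)
    quantile_init = dict(
        weights_init=np.full(3, 1 / 3),
        means_init=np.quantile(x, [1 / 6, 1 / 2, 5 / 6]).reshape(-1, 1),
        precisions_init=np.full((3, 1, 1), 1.0 / var0),
        init="quantile",
    )
    attempts = [quantile_init] + [
        dict(init_params="random", random_state=int(seed) + r, init=f"random-{r}")
        for r in range(_N_RESTARTS)
    ]
    gm = None
    init_used = ""
    for kw in attempts:
        kw = dict(kw)
        init_used = kw.pop("init")
        candidate = _fit_once(X, kw)
        if not _is_degenerate(candidate):
            gm = candidate
            break
    if gm is None:
        raise GmmDegenerateError(
            "EM collapsed (component variance below floor) on the quantile "
            f"initialisation and all {_N_RESTARTS} random restarts"
        )
    order = np.argsort(gm.means_.ravel())
    fit = GmmFit(
        weights=gm.weights_[order].copy(),
        means=gm.means_.ravel()[order].copy(),
        variances=gm.covariances_.ravel()[order].copy(),
        seed=int(seed),
        log_likelihood=float(gm.score(X) * x.size),
        n_scores=int(x.size),
        init=init_used,
    )
    derive_thresholds(fit)
    return fit


def _crossover(w1, m1, v1, w2, m2, v2) -> tuple[float, bool]:
    """Score between m1 < m2 where the weighted component densities match.

    Returns (threshold, fallback_used). Falls back to the midpoint when the
    densities do not cross in the open interval (pathological overlap).
    """
    mid = 0.5 * (m1 + m2)
    if not m1 < m2:
        return mid, True

    def diff(t: float) -> float:
        return (np.log(w1) + norm.logpdf(t, m1, np.sqrt(v1))) - (
            np.log(w2) + norm.logpdf(t, m2, np.sqrt(v2))
        )

    eps = 1e-9 * max(1.0, abs(m1), abs(m2))
    lo, hi = m1 + eps, m2 - eps
    if lo >= hi or diff(lo) * diff(hi) > 0:
        return mid, True
    return float(brentq(diff, lo, hi, xtol=1e-12)), False


def derive_thresholds(fit: GmmFit) -> tuple[float, float]:
    """Set the impactful/mild and mild/neutral boundaries on the fit."""
    w, m, v = fit.weights, fit.means, fit.variances
    t_low, fb_low = _crossover(w[0], m[0], v[0], w[1], m[1], v[1])
    t_high, fb_high = _crossover(w[1], m[1], v[1], w[2], m[2], v[2])
    fit.threshold_low = t_low
    fit.threshold_high = t_high
    fit.threshold_fallback = (["low"] if fb_low else []) + (
        ["high"] if fb_high else []
    )
    return t_low, t_high


def classify_scores(scores: np.ndarray, fit: GmmFit) -> np.ndarray:
    """Vectorised class labels; a score equal to a threshold takes the
    milder class (conservative tie-break)."""
    scores = np.asarray(scores, dtype=float)
    return np.select(
        [
            ~np.isfinite(scores),
            scores < fit.threshold_low,
            scores < fit.threshold_high,
        ],
        ["unscored", "impactful", "mild"],
        default="neutral",
    )


def classify_variants(landscape: MutationalLandscape, fit: GmmFit) -> pd.DataFrame:
    """Long-form variant table with columns position, wt, mut, raw_score,
    variant_class (19 rows per position)."""
    df = landscape.to_long_frame()
    df["variant_class"] = classify_scores(df["raw_score"].to_numpy(), fit)
    return df


def classify_residues(variants: pd.DataFrame) -> pd.DataFrame:
    """Tolerant/sensitive call per residue.

    Tolerant requires strictly more than half of the 19 possible
    substitutions to be neutral, i.e. n_neutral >= 10; unscored
    substitutions count as non-neutral (absence of evidence does not
    manufacture tolerance).
    """
    n_neutral = (
        variants.assign(is_neutral=variants["variant_class"].eq("neutral"))
        .groupby("position", sort=True)["is_neutral"]
        .sum()
        .astype(int)
    )
    out = n_neutral.reset_index().rename(columns={"is_neutral": "n_neutral"})
    out["residue_class"] = np.where(
        out["n_neutral"] >= 10, "tolerant", "sensitive"
    )
    return out


def residue_confidence(
    stats: pd.DataFrame,
    dispersion: np.ndarray,
    config: ConfidenceConfig = ConfidenceConfig(),
) -> pd.DataFrame:
    """Flag positions whose predictions rest on weak evolutionary signal.

    A position is non-confident iff its score dispersion is low AND it is
    poorly conserved AND (its column is highly gapped OR few distinct
    substitutions were sampled). ``reasons`` lists the clauses that fired
    and is empty exactly when the position is confident.
    """
    stats = stats.sort_values("position").reset_index(drop=True)
    if len(stats) != len(dispersion):
        raise ValueError("column stats and dispersion cover different positions")
    disp = np.asarray(dispersion, dtype=float)
    low_disp = disp < config.d_min
    poor_cons = stats["conservation"].to_numpy() < config.c_min
    gappy = stats["gap_fraction"].to_numpy() > config.g_max
    few_subs = stats["n_substitutions_sampled"].to_numpy() < config.s_min
    non_confident = low_disp & poor_cons & (gappy | few_subs)
    reasons = []
    for i, bad in enumerate(non_confident):
        if not bad:
            reasons.append("")
            continue
        r = ["low_dispersion", "poorly_conserved"]
        if gappy[i]:
            r.append("highly_gapped")
        if few_subs[i]:
            r.append("few_substitutions")
        reasons.append(";".join(r))
    return pd.DataFrame(
        {
            "position": stats["position"],
            "score_dispersion": disp,
            "confident": ~non_confident,
            "reasons": reasons,
        }
    )
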