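"""Cue measurement, a synthetic observer, and the statistical battery.

The observer operationalises the three part-structure cues that separate
plants from animals -- asymmetry of limb pairs, straightness of limbs, and
the prominence of sprouting (second-order) limbs -- and maps them through a
noisy logistic decision rule onto 2-AFC plant choices or continuous
animal--plant slider ratings.  Evidence is pooled additively over parts, so
shapes with more limbs produce stronger categorical signals; this is what
lets psychometric slopes grow with limb count.

The statistics here (exact binomial test, one-way ANOVA, Tukey HSD,
one-sample t, JZS Bayes factor, psychometric fits) mirror the analyses a
2-AFC / rating study of these stimuli calls for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats
from scipy.special import expit

from .part_manipulation import CURVED_ANGLE_RANGE_DEG, DISPLACEMENT_LEVELS
from .skeleton_core import Shape

__all__ = [
    "CueVector",
    "ObserverModel",
    "PsychometricFit",
    "measure_cues",
    "cue_features",
    "simulate_2afc",
    "simulate_slider",
    "recover_observer_weights",
    "binomial_preference",
    "one_way_anova",
    "tukey_posthoc",
    "one_sample_t",
    "jzs_bayes_factor",
    "fit_psychometric",
    "analyze_2afc",
    "analyze_slider",
]

#: Normalisers that bring the three cue features to order 1: the largest
#: displacement level, the upper end of the curved turning-angle range, and
#: a typical full-grown sprout area fraction.
_ASYM_NORM = DISPLACEMENT_LEVELS[-1]
_CURV_NORM = CURVED_ANGLE_RANGE_DEG[1]
_SPROUT_NORM = 0.2


# --------------------------------------------------------------------------
# cue measurement

@dataclass(frozen=True)
class CueVector:
    """Measured part-structure cues of a composed shape.

    ``asymmetry`` is the mean attachment offset of nominal limb pairs from
    perfect mirror positions, as a perimeter fraction (NaN when the shape
    has no nominal pairs); ``curvedness`` the mean unsigned turning angle in
    degrees over first-order limbs; ``sprout_prominence`` the summed
    silhouette area of order-2 parts divided by the total silhouette area.
    """

    asymmetry: float
    curvedness: float
    sprout_prominence: float


def _pair_offsets(shape: Shape) -> list[float]:
    groups: dict[int, list[float]] = {}
    for p in shape.parts:
        if p.order == 1 and p.pair_id is not None:
            groups.setdefault(p.pair_id, []).append(p.attach_t)
    offsets = []
    for ts in groups.values():
        if len(ts) == 2:
            # a mirror-symmetric pair satisfies t_left + t_right = 1 (mod 1)
            v = (ts[0] + ts[1] - 1.0) % 1.0
            offsets.append(min(v, 1.0 - v))
    return offsets


def measure_cues(shape: Shape) -> CueVector:
    """Deterministically measure the three cues on a composed shape."""
    offsets = _pair_offsets(shape)
    asym = float(np.mean(offsets)) if offsets else float("nan")

    angles = [
        np.abs(p.path.turning_angles_deg)
        for p in shape.parts
        if p.order == 1 and p.path.n_joints >= 3
    ]
    curv = float(np.mean(np.concatenate(angles))) if angles else 0.0

    total = shape.silhouette.area
    sprout_area = sum(
        poly.area
        for p, poly in zip(shape.parts, shape.part_polygons)
        if p.order == 2 and poly is not None
    )
    return CueVector(
        asymmetry=asym,
        curvedness=curv,
        sprout_prominence=float(sprout_area / total) if total > 0 else 0.0,
    )


def cue_features(shape: Shape) -> np.ndarray:
    """Extensive (part-summed) plant-evidence features ``[asym, straight, sprout]``.

    Each limb pair contributes its normalised attachment offset; each
    first-order limb its normalised straightness (1 = straight, 0 = fully
    curved); sprouts contribute their normalised silhouette-area fraction.
    Summing rather than averaging makes the total evidence grow with the
    number of parts carrying it.
    """
    offsets = _pair_offsets(shape)
    f_asym = float(np.sum(offsets)) / _ASYM_NORM if offsets else 0.0

    f_straight = 0.0
    for p in shape.parts:
        if p.order == 1 and p.path.n_joints >= 3:
            mean_abs = float(np.mean(np.abs(p.path.turning_angles_deg)))
            f_straight += max(0.0, 1.0 - mean_abs / _CURV_NORM)

    cues = measure_cues(shape)
    f_sprout = cues.sprout_prominence / _SPROUT_NORM
    return np.array([f_asym, f_straight, f_sprout])


# --------------------------------------------------------------------------
# observer model

@dataclass(frozen=True)
class ObserverModel:
    """A synthetic observer weighing the three cues toward 'plant'.

    The decision variable for a single shape is
    ``s = w · f(shape) - reference_per_limb · n_first_order + bias``
    where ``f`` are the part-summed features of :func:`cue_features`; the
    per-limb reference term centres the evidence so that mid-morph shapes
    are ambiguous regardless of limb count.  Ratings pass ``s`` plus
    Gaussian noise through a logistic squash; 2-AFC choices use the signal
    difference between the pair members (the reference terms cancel).
    """

    weights: tuple[float, float, float] = (1.0, 1.0, 1.5)
    bias: float = 0.3
    reference_per_limb: float = 0.9
    noise: float = 0.8
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if not (0.0 <= self.lapse < 0.5):
            raise ValueError("lapse must lie in [0, 0.5)")

    def signal(self, shape: Shape, features: Optional[np.ndarray] = None) -> float:
        f = cue_features(shape) if features is None else features
        n1 = sum(1 for p in shape.parts if p.order == 1)
        return float(np.dot(self.weights, f) - self.reference_per_limb * n1 + self.bias)


def simulate_2afc(
    pairs: Sequence,
    model: ObserverModel,
    n_participants: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate 2-AFC "pick the plant" choices over a list of shape pairs.

    Each pair carries a reference member ``a`` and a manipulated member
    ``b`` (see :mod:`partmorph.experiment_designs`).  Per trial, the
    probability of choosing ``b`` is the lapse-adjusted logistic of the
    weighted cue difference; choices are sampled independently across
    participants and trials.
    """
    rows = []
    feats = [(cue_features(p.a), cue_features(p.b)) for p in pairs]
    for part_id in range(n_participants):
        for pair, (fa, fb) in zip(pairs, feats):
            delta = np.asarray(fb) - np.asarray(fa)
            drive = float(np.dot(model.weights, delta))
            scale = model.noise if model.noise > 0 else 1e-9
            p_b = model.lapse / 2.0 + (1.0 - model.lapse) * expit(drive / scale)
            chose_b = int(rng.random() < p_b)
            rows.append(
                {
                    "participant": part_id,
                    "pair_id": pair.pair_id,
                    "condition": pair.condition,
                    "level": pair.level,
                    "n_limbs": pair.n_limbs,
                    "d_asym": delta[0],
                    "d_straight": delta[1],
                    "d_sprout": delta[2],
                    "chose_manipulated": chose_b,
                    "choice": (
                        ("left" if pair.placement_swapped else "right")
                        if chose_b
                        else ("right" if pair.placement_swapped else "left")
                    ),
                }
            )
    return pd.DataFrame(rows)


def simulate_slider(
    shapes: Sequence[Shape],
    model: ObserverModel,
    n_participants: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate animal--plant slider ratings in [0, 1] for single shapes.

    The rating is the logistic squash of the cue signal plus Gaussian noise
    on the logit, so ratings always land in (0, 1); zero noise makes them
    deterministic.
    """
    rows = []
    sigs = [model.signal(s) for s in shapes]
    for part_id in range(n_participants):
        eps = rng.normal(0.0, model.noise, size=len(shapes))
        for (shape, s0), e in zip(zip(shapes, sigs), eps):
            rating = float(expit(s0 + e))
            rows.append(
                {
                    "participant": part_id,
                    "shape_id": shape.meta.get("shape_id", ""),
                    "sequence_id": shape.meta.get("sequence_id", ""),
                    "step": shape.meta.get("step"),
                    "condition": shape.meta.get("condition", ""),
                    "n_limbs": shape.meta.get("n_first_order"),
                    "rating": min(1.0, max(0.0, rating)),
                }
            )
    return pd.DataFrame(rows)


def recover_observer_weights(responses: pd.DataFrame) -> np.ndarray:
    """Maximum-likelihood recovery of observer cue weights from 2-AFC data.

    Fits a logistic regression of ``chose_manipulated`` on the three cue
    differences (no intercept: the task is symmetric).  The recovered
    coefficients estimate ``weights / noise``; a non-zero lapse rate
    shrinks them slightly toward zero.  Cues with no variation in the
    design are unidentifiable and come back as NaN.
    """
    import statsmodels.api as sm

    X = responses[["d_asym", "d_straight", "d_sprout"]].to_numpy()
    y = responses["chose_manipulated"].to_numpy()
    active = np.ptp(X, axis=0) > 1e-12
    fit = sm.Logit(y, X[:, active]).fit(disp=False)
    out = np.full(X.shape[1], np.nan)
    out[active] = np.asarray(fit.params)
    return out


# --------------------------------------------------------------------------
# statistics

def binomial_preference(K: int, N: int, p0: float = 0.5) -> tuple[float, float]:
    """Proportion and one-sided (upper-tail) exact binomial p-value."""
    if N <= 0:
        raise ValueError("N must be positive")
    if not (0 <= K <= N):
        raise ValueError("K must lie in [0, N]")
    res = stats.binomtest(K, N, p0, alternative="greater")
    return K / N, float(res.pvalue)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Standard one-way ANOVA over ``groups`` of observations."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        raise ValueError("degenerate data: zero variance overall")
    F, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return AnovaResult(float(F), k - 1, n - k, float(p))


def tukey_posthoc(
    groups: Sequence[Sequence[float]], labels: Optional[Sequence] = None
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (studentized-range based)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = list(range(len(groups)))
    res = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            lo, hi = res.confidence_interval().low[i, j], res.confidence_interval().high[i, j]
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                    "p": float(res.pvalue[i, j]),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    return pd.DataFrame(rows)


def one_sample_t(values: Sequence[float], mu0: float) -> tuple[float, int, float]:
    """One-sample t-test; returns (t, df, two-sided p)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    if np.std(v) == 0:
        raise ValueError("degenerate data: zero variance")
    res = stats.ttest_1samp(v, mu0)
    return float(res.statistic), v.size - 1, float(res.pvalue)


def jzs_bayes_factor(t: float, n: int, scale: float = 0.707) -> float:
    """JZS Bayes factor BF10 for a one-sample t statistic.

    Uses the Jeffreys–Zellner–Siow setup: a Cauchy prior with the given
    scale on standardised effect size, marginalised by numerical
    integration over the Zellner g mixture.  BF10 > 1 favours a non-zero
    effect; values below 1 favour the null.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    nu = n - 1
    t2 = float(t) * float(t)
    r2 = scale * scale

    def integrand(g: float) -> float:
        c = 1.0 + n * g * r2
        return (
            c**-0.5
            * (1.0 + t2 / (c * nu)) ** (-(nu + 1) / 2.0)
            * (2.0 * np.pi) ** -0.5
            * g**-1.5
            * np.exp(-1.0 / (2.0 * g))
        )

    num, err = integrate.quad(integrand, 0.0, np.inf, limit=400)
    if not np.isfinite(num) or (num > 0 and err / num > 1e-6):
        raise RuntimeError("JZS integration did not converge")
    den = (1.0 + t2 / nu) ** (-(nu + 1) / 2.0)
    if den == 0.0:
        # extreme t: fall back to log-space evaluation of the ratio
        log_den = -(nu + 1) / 2.0 * np.log1p(t2 / nu)
        return float(np.exp(np.log(num) - log_den))
    return float(num / den)


# --------------------------------------------------------------------------
# psychometric fitting

@dataclass(frozen=True)
class PsychometricFit:
    """A four-parameter logistic psychometric function.

    ``psi(x) = guess + (1 - guess - lapse) / (1 + exp(-slope * (x - location)))``
    fitted over (stimulus level, response) points by bounded maximum
    likelihood (Gaussian residuals for ratings, Bernoulli for choices).
    """

    location: float
    slope: float
    lapse: float
    guess: float
    converged: bool
    flat_warning: bool
    residual: float = float("nan")

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.guess + (1.0 - self.guess - self.lapse) * expit(
            self.slope * (x - self.location)
        )


def fit_psychometric(
    step_values: Sequence[float],
    responses: Sequence[float],
    binary: bool = False,
) -> PsychometricFit:
    """Fit the lapse-bounded logistic sigmoid to (level, response) data.

    Requires at least 5 points over at least 2 distinct levels.  Flat data
    (essentially constant responses) yields a near-zero slope with
    ``flat_warning`` set rather than an error.
    """
    x = np.asarray(step_values, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size or x.size < 5 or np.unique(x).size < 2:
        raise ValueError("need >= 5 points spanning >= 2 distinct levels")

    span = np.ptp(x)
    if np.std(y) < 1e-6:
        return PsychometricFit(
            location=float(np.mean(x)),
            slope=0.0,
            lapse=0.0,
            guess=float(np.clip(np.mean(y), 0, 1)),
            converged=True,
            flat_warning=True,
            residual=0.0,
        )

    def psi(theta, xv):
        loc, slope, lapse, guess = theta
        return guess + (1.0 - guess - lapse) * expit(slope * (xv - loc))

    def negloglik(theta):
        p = np.clip(psi(theta, x), 1e-9, 1.0 - 1e-9)
        if binary:
            return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        return float(np.sum((y - p) ** 2))

    x0 = np.array([float(np.mean(x)), 4.0 / max(span, 1e-6), 0.02, 0.02])
    bounds = [
        (x.min() - 2 * span, x.max() + 2 * span),
        (0.0, 200.0 / max(span, 1e-6)),
        (0.0, 0.499),
        (0.0, 0.499),
    ]
    best = None
    for slope0 in (x0[1] * 0.25, x0[1], x0[1] * 4.0):
        res = optimize.minimize(
            negloglik,
            np.array([x0[0], slope0, x0[2], x0[3]]),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    loc, slope, lapse, guess = best.x
    flat = slope < 1e-3
    if not best.success:
        warnings.warn("psychometric fit did not fully converge", RuntimeWarning)
    return PsychometricFit(
        location=float(loc),
        slope=float(slope),
        lapse=float(lapse),
        guess=float(guess),
        converged=bool(best.success),
        flat_warning=bool(flat),
        residual=float(best.fun),
    )


# --------------------------------------------------------------------------
# report-level analyses

def analyze_2afc(responses: pd.DataFrame) -> dict:
    """Per-participant and pooled binomial tests, plus a level-wise ANOVA.

    The ANOVA units are per-pair choice proportions (across participants),
    grouped by manipulation level, mirroring the design structure of a
    2-AFC preference study.
    """
    out: dict = {"participants": {}}
    for pid, grp in responses.groupby("participant"):
        k = int(grp["chose_manipulated"].sum())
        n = int(len(grp))
        prop, p = binomial_preference(k, n)
        out["participants"][int(pid)] = {"K": k, "N": n, "proportion": prop, "p": p}
    K = int(responses["chose_manipulated"].sum())
    N = int(len(responses))
    prop, p = binomial_preference(K, N)
    out["pooled"] = {"K": K, "N": N, "proportion": prop, "p": p}

    if responses["level"].nunique() > 1:
        per_pair = (
            responses.groupby(["level", "pair_id"])["chose_manipulated"]
            .mean()
            .reset_index()
        )
        groups = [
            g["chose_manipulated"].to_numpy()
            for _, g in per_pair.groupby("level")
        ]
        try:
            anova = one_way_anova(groups)
            out["anova"] = {
                "F": anova.F,
                "df": [anova.df_between, anova.df_within],
                "p": anova.p,
            }
            out["tukey"] = tukey_posthoc(
                groups, labels=sorted(per_pair["level"].unique())
            ).to_dict("records")
            out["per_level_proportion"] = {
                str(lvl): float(g["chose_manipulated"].mean())
                for lvl, g in per_pair.groupby("level")
            }
        except ValueError:
            out["anova"] = None
    return out


def analyze_slider(responses: pd.DataFrame) -> dict:
    """Slider-rating battery: plant bias, sprouting-style contrast, and
    psychometric fits by condition and limb count."""
    out: dict = {}
    vals = responses["rating"].to_numpy()
    t, df, p = one_sample_t(vals, 0.5)
    out["bias"] = {"mean": float(vals.mean()), "t": t, "df": df, "p": p}

    by_seq = responses.groupby(["sequence_id", "condition"])["rating"].mean().reset_index()
    conds = [g["rating"].to_numpy() for _, g in by_seq.groupby("condition")]
    if len(conds) == 2:
        anova = one_way_anova(conds)
        tt = stats.ttest_ind(conds[0], conds[1])
        out["sprouting_style"] = {
            "F": anova.F,
            "df": [anova.df_between, anova.df_within],
            "p": anova.p,
            "BF10": jzs_bayes_factor(
                float(tt.statistic), min(len(conds[0]), len(conds[1]))
            ),
        }

    out["fits"] = {}
    fit_all = fit_psychometric(responses["step"], responses["rating"])
    out["fits"]["all"] = {"location": fit_all.location, "slope": fit_all.slope}
    for key, grp in responses.groupby("condition"):
        f = fit_psychometric(grp["step"], grp["rating"])
        out["fits"][f"condition:{key}"] = {"location": f.location, "slope": f.slope}
    for key, grp in responses.groupby("n_limbs"):
        f = fit_psychometric(grp["step"], grp["rating"])
        out["fits"][f"limbs:{key}"] = {"location": f.location, "slope": f.slope}
    odd = responses[responses["n_limbs"] % 2 == 1]
    even = responses[responses["n_limbs"] % 2 == 0]
    for name, grp in (("odd", odd), ("even", even)):
        if len(grp) >= 5 and grp["step"].nunique() >= 2:
            f = fit_psychometric(grp["step"], grp["rating"])
            out["fits"][f"parity:{name}"] = {"location": f.location, "slope": f.slope}
    return out
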