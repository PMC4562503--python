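"""Statistical pipeline: synchrony estimates, repeated-measures ANOVA with
Greenhouse-Geisser correction, within-subject confidence intervals, drift QC,
and the filling-in regression.

E is the adjusted delay Δt at perceived onset-onset synchrony and D the delay
at perceived onset-offset synchrony; VP = D - E estimates the duration of the
fading percept with the unknown perceptual latencies cancelled.

The repeated-measures ANOVA is a fully-within factorial decomposition: every
effect is tested against its own subject-by-effect interaction.  For effects
with more than one degree of freedom the Greenhouse-Geisser epsilon is
computed from the covariance of orthonormalized effect contrasts, and the
corrected p-value is adopted when Mauchly's test rejects sphericity at
alpha = 0.05 (or cannot be computed).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import FillInFeatures

__all__ = [
    "SynchronyEstimate",
    "RegressionFit",
    "synchrony_estimates",
    "rm_anova",
    "within_subject_ci",
    "drift_check",
    "linear_fit",
    "fillin_regression",
    "cross_predict",
    "speed_from_slope",
]

logger = logging.getLogger(__name__)

#: trial-record columns that never define a condition cell
_META_COLS = frozenset({
    "subject", "experiment", "trial_index", "task", "delta_t_ms",
    "n_reps", "converged", "seed", "direction_rad",
})


@dataclass(frozen=True)
class SynchronyEstimate:
    """Per subject x condition synchrony settings (all times in ms)."""

    subject: str
    condition: tuple
    E: float
    D_off: float
    VP: float
    sd_on: float
    sd_off: float
    n_on: int
    n_off: int


def condition_columns(records: pd.DataFrame) -> List[str]:
    """Columns that define a condition cell (everything non-standard)."""
    return [c for c in records.columns if c not in _META_COLS]


def synchrony_estimates(
    records: pd.DataFrame,
    condition_cols: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Collapse trial records to per-(subject, condition) E, D and VP = D - E.

    E (D_off) is the mean final Δt over onset (offset) trials; sd_on/sd_off
    are the standard deviations over trial repetitions.  Cells missing either
    task are marked incomplete (``complete = False``), logged, and should be
    excluded downstream.
    """
    if condition_cols is None:
        condition_cols = condition_columns(records)
    required = {"subject", "task", "delta_t_ms"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing required columns: {sorted(missing)}")

    rows = []
    keys = ["subject"] + list(condition_cols)
    for key, grp in records.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        on = grp.loc[grp["task"] == "onset", "delta_t_ms"]
        off = grp.loc[grp["task"] == "offset", "delta_t_ms"]
        complete = len(on) > 0 and len(off) > 0
        if not complete:
            logger.warning("incomplete cell %s: n_on=%d n_off=%d",
                           dict(zip(keys, key)), len(on), len(off))
        row = dict(zip(keys, key))
        row.update(
            E=on.mean() if len(on) else np.nan,
            D_off=off.mean() if len(off) else np.nan,
            sd_on=on.std(ddof=1) if len(on) > 1 else (0.0 if len(on) else np.nan),
            sd_off=off.std(ddof=1) if len(off) > 1 else (0.0 if len(off) else np.nan),
            n_on=len(on), n_off=len(off), complete=complete,
        )
        row["VP"] = row["D_off"] - row["E"]
        rows.append(row)
    out = pd.DataFrame(rows)
    order = keys + ["E", "D_off", "VP", "sd_on", "sd_off", "n_on", "n_off",
                    "complete"]
    return out[order]


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _data_cube(df: pd.DataFrame, dv: str, within: Sequence[str],
               subject: str) -> Tuple[np.ndarray, List[str], List[list]]:
    """subjects x levels... array of cell values (replicates averaged),
    erroring on missing cells."""
    subjects = sorted(df[subject].unique())
    levels = [sorted(df[f].unique()) for f in within]
    shape = (len(subjects),) + tuple(len(l) for l in levels)
    cube = np.full(shape, np.nan)
    means = df.groupby([subject] + list(within), sort=True)[dv].mean()
    subj_idx = {s: i for i, s in enumerate(subjects)}
    level_idx = [{v: i for i, v in enumerate(l)} for l in levels]
    for key, val in means.items():
        key = key if isinstance(key, tuple) else (key,)
        idx = (subj_idx[key[0]],) + tuple(level_idx[j][key[j + 1]]
                                          for j in range(len(within)))
        cube[idx] = val
    if np.isnan(cube).any():
        missing = []
        it = np.argwhere(np.isnan(cube))
        for idx in it[:20]:
            cell = {subject: subjects[idx[0]]}
            cell.update({within[j]: levels[j][idx[j + 1]]
                         for j in range(len(within))})
            missing.append(cell)
        raise ValueError(f"unbalanced design, missing cells (first 20): {missing}")
    return cube, subjects, levels


def _center(arr: np.ndarray, axes: Sequence[int]) -> np.ndarray:
    for ax in axes:
        arr = arr - arr.mean(axis=ax, keepdims=True)
    return arr


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) matrix of orthonormal contrasts spanning the centered space."""
    m = np.eye(k) - np.full((k, k), 1.0 / k)
    q, r = np.linalg.qr(m)
    # keep the k-1 columns with non-negligible diagonal in R
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep][:, : k - 1]


def rm_anova(
    df: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "subject",
    *,
    alpha_sphericity: float = 0.05,
) -> pd.DataFrame:
    """Fully-within factorial repeated-measures ANOVA.

    Returns one row per effect (main effects and all interactions) with the F
    statistic, uncorrected degrees of freedom and p, the Greenhouse-Geisser
    epsilon, Mauchly's W and p, the GG-corrected p, and ``p`` -- the corrected
    value when sphericity is rejected (or untestable) and the effect has more
    than one degree of freedom, the uncorrected one otherwise.
    """
    within = list(within)
    cube, subjects, levels = _data_cube(df, dv, within, subject)
    n_subj = len(subjects)
    if n_subj < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 subjects")
    n_levels = [len(l) for l in levels]
    k = len(within)
    grand = cube.mean(axis=0)  # cell means over subjects

    rows = []
    for r in range(1, k + 1):
        for combo in itertools.combinations(range(k), r):
            in_axes = combo
            out_axes = tuple(j for j in range(k) if j not in combo)
            df1 = int(np.prod([n_levels[j] - 1 for j in in_axes]))
            mult_out = int(np.prod([n_levels[j] for j in out_axes])) if out_axes else 1

            # effect term on the grand cell-mean table
            m = grand.mean(axis=out_axes) if out_axes else grand
            term = _center(m, range(m.ndim))
            ss_effect = n_subj * mult_out * float((term ** 2).sum())

            # subject x effect interaction as the error term
            axes_in_cube = tuple(a + 1 for a in out_axes)
            z = cube.mean(axis=axes_in_cube) if out_axes else cube
            z_eff = _center(z, range(1, z.ndim))          # effect per subject
            resid = z_eff - z_eff.mean(axis=0, keepdims=True)
            ss_err = mult_out * float((resid ** 2).sum())
            df2 = (n_subj - 1) * df1

            ms_effect = ss_effect / df1
            ms_err = ss_err / df2
            if ms_effect == 0.0:
                f_stat = 0.0
            elif ms_err > 0:
                f_stat = ms_effect / ms_err
            else:
                f_stat = np.inf
            p_unc = float(stats.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0

            # Greenhouse-Geisser epsilon from orthonormal effect contrasts
            if df1 == 1:
                eps, w, p_sph = 1.0, 1.0, 1.0
            else:
                zmat = z.reshape(n_subj, -1)
                c = _orthonormal_contrasts(n_levels[in_axes[0]])
                for j in in_axes[1:]:
                    c = np.kron(c, _orthonormal_contrasts(n_levels[j]))
                y = zmat @ c
                v = np.cov(y, rowvar=False)
                v = np.atleast_2d(v)
                d = v.shape[0]
                tr = np.trace(v)
                eps = float(tr ** 2 / (d * np.trace(v @ v))) if tr > 0 else 1.0
                eps = float(np.clip(eps, 1.0 / d, 1.0))
                w, p_sph = _mauchly(v, n_subj)
            p_gg = float(stats.f.sf(f_stat, df1 * eps, df2 * eps)) \
                if np.isfinite(f_stat) else 0.0
            use_gg = df1 > 1 and (not np.isfinite(p_sph) or p_sph < alpha_sphericity)
            rows.append({
                "effect": ":".join(within[j] for j in in_axes),
                "F": f_stat, "df1": df1, "df2": df2, "p_unc": p_unc,
                "eps_gg": eps, "mauchly_W": w, "mauchly_p": p_sph,
                "p_gg": p_gg, "p": p_gg if use_gg else p_unc,
                "gg_applied": bool(use_gg),
                "SS_effect": ss_effect, "SS_error": ss_err,
            })
    return pd.DataFrame(rows).set_index("effect")


def _mauchly(v: np.ndarray, n_subj: int) -> Tuple[float, float]:
    """Mauchly's sphericity test on the contrast covariance matrix."""
    d = v.shape[0]
    if d < 2:
        return 1.0, 1.0
    sign, logdet = np.linalg.slogdet(v)
    if sign <= 0 or n_subj - 1 < d:
        return np.nan, np.nan  # singular: too few subjects for the test
    log_w = logdet - d * math.log(np.trace(v) / d)
    w = math.exp(log_w)
    f_corr = (2 * d ** 2 + d + 2) / (6.0 * d * (n_subj - 1))
    chi2 = -(1 - f_corr) * (n_subj - 1) * log_w
    df = d * (d + 1) // 2 - 1
    return w, float(stats.chi2.sf(chi2, df))


def within_subject_ci(
    df: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "subject",
    level: float = 0.95,
) -> float:
    """Loftus-Masson within-subject confidence-interval half-width.

    Treats the full crossing of ``within`` as one condition factor with k
    cells: half-width = t_{(n-1)(k-1)} * sqrt(MS_{subject x condition} / n),
    identical across conditions.
    """
    cube, subjects, levels = _data_cube(df, dv, list(within), subject)
    n = len(subjects)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    y = cube.reshape(n, -1)
    k = y.shape[1]
    resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) \
        + y.mean()
    dof = (n - 1) * (k - 1)
    ms_sc = float((resid ** 2).sum()) / dof
    t_crit = stats.t.ppf(1 - (1 - level) / 2, dof)
    return float(t_crit * math.sqrt(ms_sc / n))


def drift_check(
    records: pd.DataFrame,
    *,
    min_trials: int = 10,
    rho_threshold: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag subjects whose offset settings drift upward over the session.

    Computes the Spearman rank correlation between offset-trial Δt and trial
    order per subject; a subject is flagged when rho > ``rho_threshold`` with
    p < ``alpha`` (the pattern of a subject who starts with very low offset
    settings that then rise monotonically, suggesting a misunderstood task).
    """
    off = records[records["task"] == "offset"]
    rows = []
    order_col = "trial_index" if "trial_index" in off.columns else None
    for subj, grp in off.groupby("subject"):
        if order_col:
            grp = grp.sort_values(order_col)
        if len(grp) < min_trials:
            raise ValueError(
                f"subject {subj!r} has only {len(grp)} offset trials "
                f"(need >= {min_trials})")
        x = np.arange(len(grp))
        y = grp["delta_t_ms"].to_numpy()
        if np.ptp(y) == 0:
            rho, p = 0.0, 1.0
        else:
            rho, p = stats.spearmanr(x, y)
        rows.append({"subject": subj, "rho": float(rho), "p": float(p),
                     "flagged": bool(rho > rho_threshold and p < alpha)})
    return pd.DataFrame(rows)


def linear_fit(x, y) -> Tuple[float, float, float]:
    """Ordinary least-squares line; returns (slope, intercept, Pearson r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct predictor values")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


@dataclass(frozen=True)
class RegressionFit:
    """Coefficients of VP = b0 + b1*C + b2*D_fill and the fit correlation."""

    b0: float
    b1: float
    b2: float
    r: float

    def __post_init__(self) -> None:
        if not np.isnan(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| cannot exceed 1")

    def predict(self, features: Sequence[FillInFeatures]) -> np.ndarray:
        c = np.array([f.contour_len_px for f in features])
        d = np.array([f.fill_dist_px for f in features])
        return self.b0 + self.b1 * c + self.b2 * d


def fillin_regression(
    vp_means: Sequence[float],
    features: Sequence[FillInFeatures],
) -> RegressionFit:
    """Least-squares fit of per-condition VP on contour length and filling-in
    distance (both in pixels); r is the correlation of fitted vs observed."""
    vp = np.asarray(vp_means, dtype=float)
    if len(vp) != len(features):
        raise ValueError("vp_means and features must have equal length")
    if len(vp) < 3:
        raise ValueError("need at least 3 conditions for the 3-parameter fit")
    x = np.column_stack([
        np.ones(len(vp)),
        [f.contour_len_px for f in features],
        [f.fill_dist_px for f in features],
    ])
    if np.linalg.matrix_rank(x) < 3:
        raise ValueError("feature matrix is rank-deficient (collinear C and D)")
    beta, *_ = np.linalg.lstsq(x, vp, rcond=None)
    fitted = x @ beta
    r = _safe_pearson(fitted, vp)
    return RegressionFit(float(beta[0]), float(beta[1]), float(beta[2]), r)


def cross_predict(
    fit: RegressionFit,
    features: Sequence[FillInFeatures],
    observed: Optional[Sequence[float]] = None,
) -> Tuple[np.ndarray, Optional[float]]:
    """Apply fitted coefficients to new features; if observed values are given,
    also return the Pearson correlation of predicted vs observed."""
    pred = fit.predict(features)
    r = None
    if observed is not None:
        r = _safe_pearson(pred, np.asarray(observed, dtype=float))
    return pred, r


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def speed_from_slope(slope_ms_per_deg: float) -> float:
    """Convert a VP-vs-diameter slope (ms per degree of diameter) into a
    filling-in speed in degrees of radius per second: 1000 / (2 * slope)."""
    if slope_ms_per_deg <= 0:
        raise ValueError("slope must be positive")
    return 1000.0 / (2.0 * slope_ms_per_deg)
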