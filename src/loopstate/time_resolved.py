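"""Decamer vs. filament particle-fraction quantification over a reaction
time course.

Each time-resolved dataset contributes counts of particles assigned to
decamer or filament 2D classes (plus unassignable picks, which are excluded
from the denominator).  The filament fraction per dataset is tested for a
linear trend against reaction quench time.  Because such experiments have
very few datasets (typically five), inference is by permutation of the time
labels and bootstrap resampling of rows rather than parametric OLS t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as st

__all__ = [
    "ParticleCountTable",
    "FractionSeries",
    "TrendResult",
    "read_counts",
    "compute_fractions",
    "linear_trend",
    "compare_modes",
]

_COLUMNS = ["dataset_id", "time_s", "n_decamer", "n_filament", "n_unassigned"]


class CountsError(ValueError):
    """Raised for invalid particle-count inputs."""


@dataclass
class ParticleCountTable:
    """Per-dataset particle class counts with quench times.

    ``mode`` records whether datasets were 2D-classified independently or
    pooled before class assignment.
    """

    data: pd.DataFrame
    mode: str = "independent"

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise CountsError(f"missing columns {missing}")
        counts = df[["n_decamer", "n_filament", "n_unassigned"]]
        if (counts < 0).any().any() or not np.allclose(
            counts, counts.round()
        ):
            raise CountsError("counts must be non-negative integers")
        if (df["time_s"] <= 0).any():
            raise CountsError("quench times must be positive")
        assigned = df["n_decamer"] + df["n_filament"]
        if (assigned < 1).any():
            bad = df.loc[assigned < 1, "dataset_id"].tolist()
            raise CountsError(f"no assigned particles in dataset(s) {bad}")
        if self.mode not in ("independent", "pooled"):
            raise CountsError("mode must be 'independent' or 'pooled'")


def read_counts(path, mode: str | None = None) -> ParticleCountTable:
    """Read a particle-count CSV (columns dataset_id, time_s, n_decamer,
    n_filament, n_unassigned[, mode])."""
    df = pd.read_csv(Path(path))
    if mode is None:
        mode = str(df["mode"].iloc[0]) if "mode" in df.columns else "independent"
    return ParticleCountTable(data=df[_COLUMNS].copy(), mode=mode)


@dataclass
class FractionSeries:
    """Per-dataset filament/decamer fractions with binomial SEs."""

    dataset_id: np.ndarray
    time_s: np.ndarray
    filament_fraction: np.ndarray
    decamer_fraction: np.ndarray
    assigned_total: np.ndarray
    se: np.ndarray


def compute_fractions(table: ParticleCountTable) -> FractionSeries:
    """Filament fraction per dataset: filament / (filament + decamer).

    Unassigned picks are excluded from the denominator.  The per-row
    binomial standard error is sqrt(f(1-f)/n_assigned).
    """
    df = table.data
    assigned = (df["n_decamer"] + df["n_filament"]).to_numpy(float)
    f = df["n_filament"].to_numpy(float) / assigned
    se = np.sqrt(f * (1 - f) / assigned)
    return FractionSeries(
        dataset_id=df["dataset_id"].to_numpy(),
        time_s=df["time_s"].to_numpy(float),
        filament_fraction=f,
        decamer_fraction=1.0 - f,
        assigned_total=assigned,
        se=se,
    )


@dataclass
class TrendResult:
    """OLS trend with permutation p-value and bootstrap CI."""

    slope: float
    intercept: float
    pearson_r: float
    p_permutation: float
    ci_low: float
    ci_high: float
    n_perm: int
    n_boot: int
    seed: int
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise CountsError("Pearson r out of range")


def _ols(t: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    tbar, fbar = t.mean(), f.mean()
    stt = np.sum((t - tbar) ** 2)
    slope = float(np.sum((t - tbar) * (f - fbar)) / stt)
    return slope, float(fbar - slope * tbar)


def linear_trend(
    series: FractionSeries,
    n_perm: int = 10000,
    n_boot: int = 10000,
    seed: int = 0,
    weighted: bool = False,
) -> TrendResult:
    """Linear trend of filament fraction vs. quench time.

    Ordinary least squares gives the slope (fraction per second) and
    intercept; significance is a two-sided permutation test shuffling the
    time labels (test statistic |Pearson r|), and the slope's 95% CI comes
    from bootstrap resampling of rows with replacement.  Datasets are
    unweighted by default (each is one point on the trend plot);
    ``weighted=True`` applies inverse-variance weights from the binomial
    SEs.
    """
    t = np.asarray(series.time_s, float)
    f = np.asarray(series.filament_fraction, float)
    if len(t) < 3:
        raise CountsError("need at least 3 time points")
    if len(np.unique(t)) < 2:
        raise CountsError("all quench times identical")
    if weighted:
        w = 1.0 / np.maximum(series.se, 1e-12) ** 2
        w = w / w.sum() * len(w)
        # weighted OLS via sqrt-weight transform of both variables
        sw = np.sqrt(w)
        X = np.column_stack([t * sw, sw])
        beta, *_ = np.linalg.lstsq(X, f * sw, rcond=None)
        slope, intercept = float(beta[0]), float(beta[1])
    else:
        slope, intercept = _ols(t, f)
    sf = f.std()
    r = 0.0 if sf == 0 else float(np.corrcoef(t, f)[0, 1])

    rng = np.random.default_rng(seed)
    # permutation p: shuffle time labels, two-sided on |r|
    if sf == 0:
        p = 1.0
    else:
        obs = abs(r)
        count = 0
        for _ in range(n_perm):
            rp = np.corrcoef(rng.permutation(t), f)[0, 1]
            if abs(rp) >= obs - 1e-15:
                count += 1
        p = (count + 1) / (n_perm + 1)

    # bootstrap CI for the slope: resample rows with replacement.  With the
    # handful of datasets a time-resolved series has, plain percentile
    # intervals are systematically narrow, so the expanded percentile
    # interval (Hesterberg) is used: the outer quantiles are widened by the
    # normal-vs-t small-sample factor while the nominal level stays 95%.
    n = len(t)
    slopes = np.empty(n_boot)
    filled = 0
    while filled < n_boot:
        idx = rng.integers(0, n, size=n)
        tb = t[idx]
        if np.ptp(tb) == 0:
            continue  # degenerate resample carries no slope information
        slopes[filled], _ = _ols(tb, f[idx])
        filled += 1
    z_exp = np.sqrt(n / (n - 1)) * st.t.ppf(0.975, n - 1)
    alpha_exp = st.norm.cdf(-z_exp)
    ci_low, ci_high = np.quantile(slopes, [alpha_exp, 1 - alpha_exp])
    return TrendResult(
        slope=slope,
        intercept=intercept,
        pearson_r=r,
        p_permutation=float(p),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_perm=n_perm,
        n_boot=n_boot,
        seed=seed,
        flags={"weighted": weighted},
    )


def compare_modes(
    independent: ParticleCountTable, pooled: ParticleCountTable
) -> pd.DataFrame:
    """Per-dataset filament-fraction difference between processing modes.

    Returns a frame keyed by dataset id with the fraction under each mode,
    their difference (independent minus pooled) and a combined binomial SE.
    """
    fi = compute_fractions(independent)
    fp = compute_fractions(pooled)
    ids_i = list(fi.dataset_id)
    ids_p = list(fp.dataset_id)
    if sorted(map(str, ids_i)) != sorted(map(str, ids_p)):
        raise CountsError(
            f"dataset ids differ: {sorted(set(map(str, ids_i)) ^ set(map(str, ids_p)))}"
        )
    dfi = pd.DataFrame(
        {"dataset_id": fi.dataset_id, "f_independent": fi.filament_fraction,
         "se_i": fi.se, "time_s": fi.time_s}
    )
    dfp = pd.DataFrame(
        {"dataset_id": fp.dataset_id, "f_pooled": fp.filament_fraction,
         "se_p": fp.se}
    )
    out = dfi.merge(dfp, on="dataset_id")
    out["delta"] = out["f_independent"] - out["f_pooled"]
    out["delta_se"] = np.sqrt(out["se_i"] ** 2 + out["se_p"] ** 2)
    return out[["dataset_id", "time_s", "f_independent", "f_pooled",
                "delta", "delta_se"]]
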