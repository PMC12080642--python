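"""Spline smoothing of periodograms and pointwise functional group tests.

Each participant's periodogram is projected onto a cubic B-spline basis with
equally spaced interior knots (default 44, giving 48 basis functions) and
evaluated on a common frequency grid spanning the intersection of all
participants' grids. Group differences are then located by a pointwise
F-test of the group factor in a power ~ group + age + sex regression at
every grid frequency, with significant bands read off as maximal contiguous
runs above the critical F; pairwise differences use pointwise t-tests with
uncorrected and Bonferroni-corrected critical lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline, make_lsq_spline

from cptspect.spectral import Periodogram

SPLINE_ORDER = 4  # cubic
DEFAULT_N_INTERIOR_KNOTS = 44
DEFAULT_N_EVAL = 200
DEFAULT_ALPHA = 0.05
DEFAULT_BONFERRONI_M = 6


@dataclass
class SmoothedSpectrum:
    participant_id: str
    spline: BSpline
    f_min: float
    f_max: float
    n_basis: int
    n_interior_knots: int
    reduced: bool = False

    def evaluate(self, frequencies: np.ndarray) -> np.ndarray:
        return self.spline(np.asarray(frequencies, dtype=float))


def smooth_spectrum(
    pg: Periodogram,
    n_interior_knots: int = DEFAULT_N_INTERIOR_KNOTS,
) -> SmoothedSpectrum:
    """Least-squares cubic B-spline fit to one periodogram.

    Interior knots are equally spaced over the participant's frequency
    range; the basis size is ``n_interior_knots + 4``. If the periodogram
    has fewer points than basis functions the knot count is reduced
    automatically (with a warning) until the least-squares problem is
    well posed.
    """
    x = np.asarray(pg.frequencies, dtype=float)
    y = np.asarray(pg.power, dtype=float)
    n = x.size
    requested = n_interior_knots
    k = SPLINE_ORDER - 1
    n_int = min(n_interior_knots, max(0, n - SPLINE_ORDER - 1))
    while True:
        t_int = np.linspace(x[0], x[-1], n_int + 2)[1:-1]
        t = np.r_[[x[0]] * SPLINE_ORDER, t_int, [x[-1]] * SPLINE_ORDER]
        try:
            spl = make_lsq_spline(x, y, t, k=k)
            break
        except (ValueError, np.linalg.LinAlgError):
            if n_int == 0:
                raise
            n_int -= 1
    if n_int < requested:
        warnings.warn(
            f"{pg.participant_id}: reduced interior knots {requested} -> {n_int} "
            f"({n} periodogram points)",
            stacklevel=2,
        )
    return SmoothedSpectrum(
        participant_id=pg.participant_id,
        spline=spl,
        f_min=float(x[0]),
        f_max=float(x[-1]),
        n_basis=n_int + SPLINE_ORDER,
        n_interior_knots=n_int,
        reduced=n_int < requested,
    )


def common_grid(
    spectra: list[SmoothedSpectrum] | list[Periodogram],
    n_points: int = DEFAULT_N_EVAL,
) -> np.ndarray:
    """Equally spaced frequencies over the intersection of all ranges."""
    lo = max(s.f_min for s in spectra)
    hi = min(s.f_max for s in spectra)
    if hi <= lo:
        raise ValueError("participant frequency ranges do not overlap")
    return np.linspace(lo, hi, n_points)


def evaluate_matrix(
    spectra: list[SmoothedSpectrum], grid: np.ndarray
) -> pd.DataFrame:
    """Participants × frequencies matrix of smoothed power."""
    return pd.DataFrame(
        {s.participant_id: s.evaluate(grid) for s in spectra},
        index=grid,
    ).T


@dataclass
class BandTestResult:
    """Pointwise F curve, critical value, detected bands, and t-test curves."""

    frequencies: np.ndarray
    f_stat: np.ndarray
    f_crit: float
    df_num: int
    df_den: int
    alpha: float
    bands: list[tuple[float, float]] = field(default_factory=list)
    t_tests: dict = field(default_factory=dict)
    band_group_means: pd.DataFrame | None = None

    @property
    def significant(self) -> np.ndarray:
        return self.f_stat > self.f_crit

    def band_periods(self) -> list[tuple[float, float]]:
        """Band endpoints as oscillation periods in seconds (slow, fast)."""
        return [(1.0 / lo, 1.0 / hi) for lo, hi in self.bands]


def _covariate_design(cov: pd.DataFrame, groups: list[str]):
    n = len(cov)
    cols = [np.ones(n)]
    names = ["Intercept"]
    gvals = cov["group"].astype(str).to_numpy()
    for g in groups[1:]:
        cols.append((gvals == g).astype(float))
        names.append(f"group[{g}]")
    cols.append(cov["age"].to_numpy(dtype=float))
    names.append("age")
    sex = cov["sex"].astype(str).to_numpy()
    levels = sorted(pd.unique(sex))
    if len(levels) > 1:
        cols.append((sex == levels[1]).astype(float))
        names.append(f"sex[{levels[1]}]")
    return np.column_stack(cols), names


def _rss_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Column-wise residual sums of squares of Y regressed on X."""
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    return np.einsum("ij,ij->j", resid, resid)


def pointwise_group_ftest(
    spectra: list[SmoothedSpectrum],
    covariates: pd.DataFrame,
    grid: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> BandTestResult:
    """Covariate-adjusted pointwise F-test for the group factor.

    At each common-grid frequency, ``power ~ group + age + sex`` is fit
    across participants and the partial F for the group dummies is compared
    with the central F critical value at ``alpha``. ``covariates`` needs
    ``participant_id, group, age, sex``; rows are matched to spectra by id.
    """
    if grid is None:
        grid = common_grid(spectra)
    cov = covariates.set_index("participant_id").loc[
        [s.participant_id for s in spectra]
    ]
    groups = sorted(cov["group"].astype(str).unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    Y = np.vstack([s.evaluate(grid) for s in spectra])  # participants × freqs

    X_full, names = _covariate_design(cov, groups)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError(
            "rank-deficient design (e.g. a single-sex or constant-age group)"
        )
    group_cols = [i for i, nm in enumerate(names) if nm.startswith("group[")]
    X_red = np.delete(X_full, group_cols, axis=1)

    n, p = X_full.shape
    q = len(group_cols)
    rss_full = _rss_matrix(X_full, Y)
    rss_red = _rss_matrix(X_red, Y)
    df_den = n - p
    if df_den <= 0:
        raise ValueError("not enough participants for the covariate model")
    F = ((rss_red - rss_full) / q) / (rss_full / df_den)
    crit = float(stats.f.ppf(1.0 - alpha, q, df_den))

    bands = _runs_to_bands(grid, F > crit)
    return BandTestResult(
        frequencies=grid,
        f_stat=F,
        f_crit=crit,
        df_num=q,
        df_den=df_den,
        alpha=alpha,
        bands=bands,
    )


def _runs_to_bands(grid: np.ndarray, flag: np.ndarray) -> list[tuple[float, float]]:
    bands = []
    in_run = False
    start = 0
    for i, on in enumerate(flag):
        if on and not in_run:
            in_run, start = True, i
        elif not on and in_run:
            bands.append((float(grid[start]), float(grid[i - 1])))
            in_run = False
    if in_run:
        bands.append((float(grid[start]), float(grid[-1])))
    return bands


def primary_band(result: BandTestResult) -> tuple[float, float] | None:
    """The significant band containing the largest F value, if any."""
    if not result.bands:
        return None
    f_peak = result.frequencies[np.argmax(result.f_stat)]
    for lo, hi in result.bands:
        if lo <= f_peak <= hi:
            return (lo, hi)
    # peak not significant (cannot happen when bands exist, but be safe)
    return max(result.bands, key=lambda b: b[1] - b[0])


def pairwise_pointwise_ttest(
    spectra: list[SmoothedSpectrum],
    covariates: pd.DataFrame,
    pair: tuple[str, str],
    band: tuple[float, float] | None = None,
    grid: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
    n_comparisons: int = DEFAULT_BONFERRONI_M,
) -> dict:
    """Pointwise t-test for one group pair, within a band or over the grid.

    Fits ``power ~ group + age + sex`` on the two groups' participants at
    each frequency; returns the t curve, the uncorrected critical t at
    ``alpha`` and the Bonferroni critical t at ``alpha / n_comparisons``.
    """
    if grid is None:
        grid = common_grid(spectra)
    ga, gb = pair
    cov = covariates.set_index("participant_id").loc[
        [s.participant_id for s in spectra]
    ]
    mask = cov["group"].astype(str).isin([ga, gb]).to_numpy()
    if cov["group"].astype(str).eq(ga).sum() == 0 or cov["group"].astype(str).eq(gb).sum() == 0:
        raise ValueError(f"pair {pair} not present in data")
    sub_spectra = [s for s, m in zip(spectra, mask) if m]
    sub_cov = cov[mask]

    freqs = grid
    if band is not None:
        lo, hi = band
        sel = (grid >= lo) & (grid <= hi)
        if not sel.any():
            raise ValueError("band does not intersect the evaluation grid")
        freqs = grid[sel]

    pair_groups = sorted([ga, gb])
    X, names = _covariate_design(sub_cov.reset_index(), pair_groups)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design within pair")
    Y = np.vstack([s.evaluate(freqs) for s in sub_spectra])
    n, p = X.shape
    df = n - p
    gcol = names.index(f"group[{pair_groups[1]}]")

    XtX_inv = np.linalg.inv(X.T @ X)
    betas = XtX_inv @ X.T @ Y
    rss = _rss_matrix(X, Y)
    sigma2 = rss / df
    se = np.sqrt(sigma2 * XtX_inv[gcol, gcol])
    tcurve = betas[gcol] / se
    if pair_groups[1] != ga:
        # sign convention: positive t means the first-named group is higher
        tcurve = -tcurve

    crit_unc = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    crit_bonf = float(stats.t.ppf(1.0 - alpha / (2.0 * n_comparisons), df))
    return {
        "pair": (ga, gb),
        "frequencies": freqs,
        "t": tcurve,
        "df": df,
        "crit_uncorrected": crit_unc,
        "crit_bonferroni": crit_bonf,
        "alpha": alpha,
        "n_comparisons": n_comparisons,
    }


def summarize_band(
    result: BandTestResult,
    spectra: list[SmoothedSpectrum],
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Per-group mean smoothed power within each significant band.

    Returns an empty frame when no band was detected. Band endpoints are
    reported in Hz and as periods (seconds, reciprocal of frequency).
    """
    if not result.bands:
        return pd.DataFrame(
            columns=["band_lo_hz", "band_hi_hz", "period_lo_s", "period_hi_s", "group", "mean_power"]
        )
    cov = covariates.set_index("participant_id").loc[
        [s.participant_id for s in spectra]
    ]
    rows = []
    for lo, hi in result.bands:
        sel = (result.frequencies >= lo) & (result.frequencies <= hi)
        freqs = result.frequencies[sel]
        Y = np.vstack([s.evaluate(freqs) for s in spectra])
        mean_per_participant = Y.mean(axis=1)
        for g in sorted(cov["group"].astype(str).unique()):
            m = cov["group"].astype(str).eq(g).to_numpy()
            rows.append(
                {
                    "band_lo_hz": lo,
                    "band_hi_hz": hi,
                    "period_lo_s": 1.0 / hi,
                    "period_hi_s": 1.0 / lo,
                    "group": g,
                    "mean_power": float(mean_per_participant[m].mean()),
                }
            )
    return pd.DataFrame(rows)


def freq_period_convert(x: float) -> float:
    """Reciprocal conversion between frequency (Hz) and period (s)."""
    if np.any(np.asarray(x) <= 0):
        raise ValueError("frequency/period must be positive")
    return 1.0 / x
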