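"""Block-wise RT coefficient of variation and the group × block mixed model.

The time-on-task analysis partitions each session into 8 blocks of 60
trials, computes the coefficient of variation (sample SD / mean) of the hit
RTs per block, and fits

    cov ~ group * block_centered + age + sex  +  (block_centered | participant)

by REML with treatment coding against a reference group. Omnibus F-tests and
all contrasts use Satterthwaite-approximated denominator degrees of freedom;
pairwise group contrasts are Tukey-adjusted via the studentized range.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

from cptspect.preprocess import SessionResult

DEFAULT_N_BLOCKS = 8
DEFAULT_BLOCK_SIZE = 60
MIN_RT_PER_BLOCK = 3


def compute_block_cov(
    session: SessionResult,
    n_blocks: int = DEFAULT_N_BLOCKS,
    block_size: int = DEFAULT_BLOCK_SIZE,
    min_rt_per_block: int = MIN_RT_PER_BLOCK,
) -> pd.DataFrame:
    """Coefficient of variation of hit RTs per trial block.

    Blocks partition trials by index into ``n_blocks`` runs of
    ``block_size``. A block emits a row only when it holds at least
    ``min_rt_per_block`` hit RTs (sample SD needs n >= 2; the default of 3
    adds stability). ``block_centered`` is ``block - (n_blocks + 1) / 2``
    so that a complete participant's centered blocks sum to zero.
    """
    rows = []
    center = (n_blocks + 1) / 2.0
    s = session.rt_series
    block_of = s["trial_index"].to_numpy() // block_size + 1
    for b in range(1, n_blocks + 1):
        rt = s["rt_ms"].to_numpy()[block_of == b]
        if rt.size < max(min_rt_per_block, 2):
            continue
        rows.append(
            {
                "participant_id": session.participant_id,
                "group": session.group,
                "age": session.age,
                "sex": session.sex,
                "block": b,
                "block_centered": b - center,
                "cov": float(np.std(rt, ddof=1) / np.mean(rt)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "group",
            "age",
            "sex",
            "block",
            "block_centered",
            "cov",
        ],
    )


def build_cov_table(
    sessions: list[SessionResult],
    n_blocks: int = DEFAULT_N_BLOCKS,
    block_size: int = DEFAULT_BLOCK_SIZE,
    min_rt_per_block: int = MIN_RT_PER_BLOCK,
) -> pd.DataFrame:
    """Stack per-participant block CoV rows into one long table."""
    frames = [
        compute_block_cov(s, n_blocks, block_size, min_rt_per_block)
        for s in sessions
    ]
    frames = [f for f in frames if len(f)]
    if not frames:
        raise ValueError("no usable CoV rows; are the sessions empty?")
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Satterthwaite machinery
#
# For a contrast L the denominator df is  2 (L C L')^2 / (g' A g)  where
# C(theta) = (sum_i X_i' V_i^-1 X_i)^-1 is the fixed-effect covariance as a
# function of the variance parameters theta = (vech(G), sigma^2), g is the
# finite-difference gradient of L C(theta) L' at the REML estimate, and A is
# the inverse observed information of the REML log-likelihood in theta.
# Multi-row L combines per-eigenvector one-df approximations into an F
# denominator df in the usual way.
# --------------------------------------------------------------------------


class _SattEngine:
    def __init__(self, X, y, Z, group_codes, G, sigma2, correlated=True):
        self.X = X
        self.y = y
        self.Z = Z
        self.p = X.shape[1]
        self.n = X.shape[0]
        self.correlated = correlated
        order = np.argsort(group_codes, kind="stable")
        codes = group_codes[order]
        bounds = np.flatnonzero(np.r_[1, np.diff(codes)])
        self._chunks = []
        for a, b in zip(bounds, np.r_[bounds[1:], codes.size]):
            rows = order[a:b]
            self._chunks.append((X[rows], Z[rows], y[rows]))
        self.theta_hat = self._pack(G, sigma2)
        self._A = None

    def _pack(self, G, sigma2):
        if self.correlated:
            return np.array([G[0, 0], G[1, 0], G[1, 1], sigma2])
        return np.array([G[0, 0], G[1, 1], sigma2])

    def _unpack(self, theta):
        if self.correlated:
            G = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
            return G, theta[3]
        G = np.diag(theta[:2])
        return G, theta[2]

    def _steps(self):
        scale = max(self.theta_hat[-1], 1e-10)
        return 1e-3 * np.maximum(np.abs(self.theta_hat), 1e-2 * scale)

    def beta_cov(self, theta):
        G, s2 = self._unpack(theta)
        p = self.p
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        for Xi, Zi, yi in self._chunks:
            Vi = Zi @ G @ Zi.T + s2 * np.eye(Zi.shape[0])
            Wi = np.linalg.solve(Vi, np.c_[Xi, yi])
            XtVX += Xi.T @ Wi[:, :p]
            XtVy += Xi.T @ Wi[:, p]
        C = np.linalg.inv(XtVX)
        return C @ XtVy, C

    def reml_ll(self, theta):
        G, s2 = self._unpack(theta)
        p = self.p
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        quad = 0.0
        logdet = 0.0
        pieces = []
        for Xi, Zi, yi in self._chunks:
            Vi = Zi @ G @ Zi.T + s2 * np.eye(Zi.shape[0])
            sign, ld = np.linalg.slogdet(Vi)
            if sign <= 0:
                return -np.inf
            logdet += ld
            Wi = np.linalg.solve(Vi, np.c_[Xi, yi])
            XtVX += Xi.T @ Wi[:, :p]
            XtVy += Xi.T @ Wi[:, p]
            pieces.append((Xi, yi, Wi))
        try:
            C = np.linalg.inv(XtVX)
        except np.linalg.LinAlgError:
            return -np.inf
        beta = C @ XtVy
        for Xi, yi, Wi in pieces:
            ri = yi - Xi @ beta
            quad += ri @ (Wi[:, self.p] - Wi[:, : self.p] @ beta)
        sign, ld_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return -np.inf
        return -0.5 * (logdet + quad + ld_x)

    def theta_vcov(self):
        """Inverse observed information of the REML criterion at theta_hat."""
        if self._A is not None:
            return self._A
        t0 = self.theta_hat
        h = self._steps()
        k = t0.size
        H = np.zeros((k, k))
        f0 = self.reml_ll(t0)
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h[i]
            fpp = self.reml_ll(t0 + ei)
            fmm = self.reml_ll(t0 - ei)
            H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k)
                ej[j] = h[j]
                fp = self.reml_ll(t0 + ei + ej)
                fm = self.reml_ll(t0 - ei - ej)
                fpm = self.reml_ll(t0 + ei - ej)
                fmp = self.reml_ll(t0 - ei + ej)
                H[i, j] = H[j, i] = (fp - fpm - fmp + fm) / (4 * h[i] * h[j])
        info = -H
        try:
            A = np.linalg.inv(info)
            if np.any(np.diag(A) < 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            A = np.linalg.pinv((info + info.T) / 2)
            A = np.abs(A)  # boundary fits: keep df finite rather than negative
        self._A = A
        return A

    def _grad_vcov_quad(self, L):
        """Gradient of f(theta) = L C(theta) L' (L a vector) at theta_hat."""
        t0 = self.theta_hat
        h = self._steps()
        g = np.zeros(t0.size)
        for i in range(t0.size):
            ei = np.zeros(t0.size)
            ei[i] = h[i]
            _, Cp = self.beta_cov(t0 + ei)
            _, Cm = self.beta_cov(t0 - ei)
            g[i] = (L @ Cp @ L - L @ Cm @ L) / (2 * h[i])
        return g

    def _one_df(self, L, C):
        var = float(L @ C @ L)
        g = self._grad_vcov_quad(L)
        A = self.theta_vcov()
        denom = float(g @ A @ g)
        if denom <= 0:
            return float(self.n - self.p)
        df = 2.0 * var**2 / denom
        return float(np.clip(df, 1.0, self.n - self.p))

    def t_contrast(self, L, beta, C):
        est = float(L @ beta)
        se = float(np.sqrt(L @ C @ L))
        df = self._one_df(L, C)
        t = est / se if se > 0 else np.nan
        p = 2.0 * stats.t.sf(abs(t), df)
        return est, se, df, t, p

    def f_test(self, Lmat, beta, C):
        Lmat = np.atleast_2d(Lmat)
        q = np.linalg.matrix_rank(Lmat)
        M = Lmat @ C @ Lmat.T
        Fstat = float(
            (Lmat @ beta) @ np.linalg.solve(M, Lmat @ beta) / q
        )
        evals, evecs = np.linalg.eigh(M)
        keep = evals > max(evals.max(), 0) * 1e-10
        nus = []
        for lam, u in zip(evals[keep], evecs[:, keep].T):
            Lu = u @ Lmat
            g = self._grad_vcov_quad(Lu)
            A = self.theta_vcov()
            denom = float(g @ A @ g)
            if denom <= 0:
                nus.append(float(self.n - self.p))
            else:
                nus.append(float(np.clip(2.0 * lam**2 / denom, 1.0, self.n - self.p)))
        E = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
        if E > q:
            df_den = 2.0 * E / (E - q)
        else:
            df_den = float(self.n - self.p)
        df_den = float(np.clip(df_den, 1.0, self.n - self.p))
        p = stats.f.sf(Fstat, q, df_den)
        return Fstat, q, df_den, p


@dataclass
class VigilanceFit:
    """Mixed-model results for the block-wise CoV analysis."""

    fixed_effects: pd.DataFrame
    omnibus: pd.DataFrame
    simple_slopes: pd.DataFrame
    intercept_contrasts: pd.DataFrame
    slope_contrasts: pd.DataFrame
    r2_marginal: float
    r2_conditional: float
    groups: list[str] = field(default_factory=list)
    reference_group: str = "HC"
    singular: bool = False
    converged: bool = True
    random_effects_cov: np.ndarray | None = None
    residual_var: float = float("nan")


def _design(table: pd.DataFrame, reference_group: str):
    groups = sorted(table["group"].unique())
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not in data")
    others = [g for g in groups if g != reference_group]
    n = len(table)
    cols = {"Intercept": np.ones(n)}
    gvals = table["group"].to_numpy()
    for g in others:
        cols[f"group[{g}]"] = (gvals == g).astype(float)
    bc = table["block_centered"].to_numpy(dtype=float)
    cols["block_centered"] = bc
    cols["age"] = table["age"].to_numpy(dtype=float)
    sex = table["sex"].to_numpy()
    levels = sorted(pd.unique(sex).astype(str))
    if len(levels) > 1:
        cols[f"sex[{levels[1]}]"] = (sex.astype(str) == levels[1]).astype(float)
    for g in others:
        cols[f"group[{g}]:block_centered"] = cols[f"group[{g}]"] * bc
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    return X, names, [reference_group] + others


def fit_vigilance_model(
    table: pd.DataFrame,
    reference_group: str = "HC",
) -> VigilanceFit:
    """Fit the group × centered-block mixed model to a long CoV table.

    ``table`` needs columns ``participant_id, group, age, sex, block_centered,
    cov``. The model has participant-level random intercepts and slopes on
    centered block; if the random-effects covariance is (near-)singular the
    model is refit with uncorrelated random effects and flagged.
    Raises on fewer than two groups, on groups with a single participant,
    and on optimizer non-convergence.
    """
    counts = table.groupby("group")["participant_id"].nunique()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(
            f"groups with a single participant are not identifiable: "
            f"{list(thin.index)}"
        )
    blocks_per = table.groupby("participant_id")["block_centered"].nunique()
    if blocks_per.max() < 2:
        raise ValueError("need >= 2 blocks per participant for a random slope")

    X, names, groups = _design(table, reference_group)
    y = table["cov"].to_numpy(dtype=float)
    bc = table["block_centered"].to_numpy(dtype=float)
    Z = np.column_stack([np.ones(len(table)), bc])
    pid_codes = pd.factorize(table["participant_id"])[0]

    def _fit(free=None):
        model = MixedLM(y, X, groups=pid_codes, exog_re=Z)
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "bfgs", "powell"):
                res = model.fit(reml=True, method=method, maxiter=500, free=free)
                if res.converged:
                    break
        return model, res

    def _at_boundary(res):
        # variance component pinned at (near) zero: optimizer reports
        # non-convergence although the REML criterion is maximized there
        d = np.diag(np.asarray(res.cov_re, dtype=float))
        return bool(np.min(d) < 1e-6 * max(float(res.scale), 1e-12))

    model, res = _fit()
    G = np.asarray(res.cov_re, dtype=float)
    sigma2 = float(res.scale)
    evals = np.linalg.eigvalsh(G)
    singular = bool(evals.min() < 1e-8 * max(evals.max(), 1e-12))
    correlated = True
    if singular or not res.converged:
        free = MixedLMParams.from_components(
            fe_params=np.ones(X.shape[1]), cov_re=np.eye(2)
        )
        model, res = _fit(free=free)
        G = np.asarray(res.cov_re, dtype=float)
        sigma2 = float(res.scale)
        correlated = False
        singular = True
    if not res.converged and not _at_boundary(res):
        raise RuntimeError(
            "mixed model failed to converge; "
            f"random-effects covariance:\n{G}\nresidual variance: {sigma2}"
        )

    engine = _SattEngine(X, y, Z, pid_codes, G, sigma2, correlated=correlated)
    beta, C = engine.beta_cov(engine.theta_hat)
    p = len(names)
    name_idx = {nm: i for i, nm in enumerate(names)}

    fe_rows = []
    for nm in names:
        L = np.zeros(p)
        L[name_idx[nm]] = 1.0
        est, se, df, t, pv = engine.t_contrast(L, beta, C)
        fe_rows.append(
            {"term": nm, "estimate": est, "se": se, "df": df, "t": t, "p": pv}
        )
    fixed_effects = pd.DataFrame(fe_rows)

    others = groups[1:]
    dummy_idx = {g: name_idx[f"group[{g}]"] for g in others}
    inter_idx = {g: name_idx[f"group[{g}]:block_centered"] for g in others}
    bc_idx = name_idx["block_centered"]

    omni_rows = []
    Ldiag = np.zeros((len(others), p))
    for r, g in enumerate(others):
        Ldiag[r, dummy_idx[g]] = 1.0
    F, dfn, dfd, pv = engine.f_test(Ldiag, beta, C)
    omni_rows.append({"effect": "group", "F": F, "df_num": dfn, "df_den": dfd, "p": pv})
    Lb = np.zeros(p)
    Lb[bc_idx] = 1.0
    F, dfn, dfd, pv = engine.f_test(Lb, beta, C)
    omni_rows.append({"effect": "block", "F": F, "df_num": dfn, "df_den": dfd, "p": pv})
    Lint = np.zeros((len(others), p))
    for r, g in enumerate(others):
        Lint[r, inter_idx[g]] = 1.0
    F, dfn, dfd, pv = engine.f_test(Lint, beta, C)
    omni_rows.append(
        {"effect": "group:block", "F": F, "df_num": dfn, "df_den": dfd, "p": pv}
    )
    omnibus = pd.DataFrame(omni_rows)

    slope_rows = []
    for g in groups:
        L = np.zeros(p)
        L[bc_idx] = 1.0
        if g != reference_group:
            L[inter_idx[g]] = 1.0
        est, se, df, t, pv = engine.t_contrast(L, beta, C)
        slope_rows.append(
            {"group": g, "slope": est, "se": se, "df": df, "t": t, "p": pv}
        )
    simple_slopes = pd.DataFrame(slope_rows)

    k = len(groups)
    ic_rows, sc_rows = [], []
    for ga, gb in itertools.combinations(groups, 2):
        Li = np.zeros(p)
        Ls = np.zeros(p)
        if ga != reference_group:
            Li[dummy_idx[ga]] += 1.0
            Ls[inter_idx[ga]] += 1.0
        if gb != reference_group:
            Li[dummy_idx[gb]] -= 1.0
            Ls[inter_idx[gb]] -= 1.0
        for L, rows, what in ((Li, ic_rows, "level"), (Ls, sc_rows, "slope")):
            est, se, df, t, pv = engine.t_contrast(L, beta, C)
            p_tukey = float(
                stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df)
            )
            rows.append(
                {
                    "contrast": f"{ga} - {gb}",
                    "estimate": est,
                    "se": se,
                    "df": df,
                    "t": t,
                    "p_unadjusted": pv,
                    "p_tukey": p_tukey,
                }
            )
    intercept_contrasts = pd.DataFrame(ic_rows)
    slope_contrasts = pd.DataFrame(sc_rows)

    # Nakagawa-style R2 with random-slope contribution averaged over rows
    var_f = float(np.var(X @ beta))
    var_re = float(np.mean(np.einsum("ij,jk,ik->i", Z, G, Z)))
    total = var_f + var_re + sigma2
    r2m = var_f / total
    r2c = (var_f + var_re) / total

    return VigilanceFit(
        fixed_effects=fixed_effects,
        omnibus=omnibus,
        simple_slopes=simple_slopes,
        intercept_contrasts=intercept_contrasts,
        slope_contrasts=slope_contrasts,
        r2_marginal=r2m,
        r2_conditional=r2c,
        groups=groups,
        reference_group=reference_group,
        singular=singular,
        converged=bool(res.converged),
        random_effects_cov=G,
        residual_var=sigma2,
    )
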