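"""Bayesian dynamic linear model for gap-filling weekly series.

The model is the conjugate Gaussian state-space form

    y_t     = F' theta_t + v_t,        v_t ~ N(0, V)
    theta_t = G  theta_{t-1} + w_t,    w_t ~ N(0, W_t)

with a local-linear-trend block (level + slope) and a trigonometric seasonal
block (h harmonics of period 52).  The observation variance V is either known
or learned conjugately (normal-inverse-gamma: degrees of freedom n_t and
scale S_t); the evolution covariances W_t come from block discount factors.
Missing weeks propagate through the evolution only, so the filter, smoother
and forward-filtering-backward-sampling (FFBS) algorithm deliver exact
posterior and posterior-predictive inference at the gaps — including
multi-year block gaps, whose wider predictive spread emerges naturally.

FFBS draws complete chlorophyll sequences from the posterior predictive:
observed weeks are kept verbatim (imputation only fills gaps); at missing
weeks each sampled state path emits an observation draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .core import WEEKS_PER_YEAR, EnvironmentalPanel, WeekIndex, WeeklySeries


@dataclass
class DLMSpec:
    """Model structure, priors and variance handling for one series."""

    trend: str = "local-linear"      # "local-linear" | "level"
    harmonics: int = 3               # trigonometric seasonal harmonics, 1..26
    period: int = WEEKS_PER_YEAR
    discount_trend: float = 0.98
    discount_seasonal: float = 0.98
    obs_variance: float | None = None   # None -> conjugate unknown-variance
    prior_df: float = 1.0               # n_0
    prior_scale: float = 1.0            # S_0
    prior_mean: np.ndarray | None = None
    prior_cov: np.ndarray | None = None  # default: diffuse diag(1e6)
    state_cov: np.ndarray | None = None  # fixed W (requires obs_variance)
    transform: str = "log"               # "log" | "raw"; recorded in outputs

    def __post_init__(self) -> None:
        if self.trend not in ("local-linear", "level"):
            raise ValueError("trend must be 'local-linear' or 'level'")
        if self.harmonics and not 1 <= self.harmonics <= self.period // 2:
            raise ValueError(f"harmonics must be in 1..{self.period // 2}")
        for d in (self.discount_trend, self.discount_seasonal):
            if not 0 < d <= 1:
                raise ValueError("discount factors must be in (0, 1]")
        if self.state_cov is not None and self.obs_variance is None:
            raise ValueError("fixed state_cov requires a known obs_variance")
        if self.transform not in ("log", "raw"):
            raise ValueError("transform must be 'log' or 'raw'")

    # -- structure ---------------------------------------------------------

    @property
    def n_trend(self) -> int:
        return 2 if self.trend == "local-linear" else 1

    @property
    def n_seasonal(self) -> int:
        if self.harmonics == 0:
            return 0
        full = min(self.harmonics, self.period // 2 - 1) if self.period % 2 == 0 else self.harmonics
        nyquist = 1 if (self.period % 2 == 0 and self.harmonics == self.period // 2) else 0
        return 2 * full + nyquist

    @property
    def dim(self) -> int:
        return self.n_trend + self.n_seasonal

    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Observation vector F and evolution matrix G."""
        d = self.dim
        F = np.zeros(d)
        G = np.zeros((d, d))
        if self.trend == "local-linear":
            G[:2, :2] = [[1.0, 1.0], [0.0, 1.0]]
        else:
            G[0, 0] = 1.0
        F[0] = 1.0
        k = self.n_trend
        for j in range(1, self.harmonics + 1):
            w = 2 * np.pi * j / self.period
            if self.period % 2 == 0 and j == self.period // 2:
                G[k, k] = -1.0   # Nyquist harmonic
                F[k] = 1.0
                k += 1
            else:
                c, s = np.cos(w), np.sin(w)
                G[k : k + 2, k : k + 2] = [[c, s], [-s, c]]
                F[k] = 1.0
                k += 2
        return F, G

    def seasonal_obs_indices(self) -> np.ndarray:
        """State indices that contribute to the seasonal part of F'theta."""
        F, _ = self.matrices()
        idx = np.flatnonzero(F) if self.harmonics else np.array([], int)
        return idx[idx >= self.n_trend]

    def discount_vector(self) -> np.ndarray:
        d = np.empty(self.dim)
        d[: self.n_trend] = self.discount_trend
        d[self.n_trend :] = self.discount_seasonal
        return d

    def priors(self, series: "WeeklySeries | None" = None) -> tuple[np.ndarray, np.ndarray]:
        """Prior state moments.

        When not set explicitly, the prior is weakly informative on the data
        scale (mean level = observed mean, covariance 25x the observed
        variance): vague enough to let the data dominate within a few weeks,
        but bounded so the smoother stays well conditioned at discount
        factors near 1.
        """
        m0 = np.zeros(self.dim)
        scale = 1e6
        if series is not None:
            obs = series.values[series.mask]
            if obs.size:
                m0[0] = obs.mean()
                scale = 25.0 * max(float(obs.var()), 1e-4)
        if self.prior_mean is not None:
            m0 = np.asarray(self.prior_mean, float)
        C0 = (
            np.eye(self.dim) * scale
            if self.prior_cov is None
            else np.asarray(self.prior_cov, float)
        )
        if m0.shape != (self.dim,) or C0.shape != (self.dim, self.dim):
            raise ValueError("prior dimensions inconsistent with model structure")
        return m0, C0


@dataclass
class StateMoments:
    """Filtered/smoothed state moments and one-step forecasts on the grid."""

    spec: DLMSpec
    mask: np.ndarray
    pred_means: np.ndarray       # a_t
    pred_covs: np.ndarray        # R_t
    filtered_means: np.ndarray   # m_t
    filtered_covs: np.ndarray    # C_t
    forecast_means: np.ndarray   # f_t
    forecast_vars: np.ndarray    # q_t
    df: np.ndarray               # n_t
    scale: np.ndarray            # S_t (== obs_variance when known)
    loglik: float
    smoothed_means: np.ndarray | None = None
    smoothed_covs: np.ndarray | None = None

    @property
    def n_weeks(self) -> int:
        return len(self.forecast_means)

    def smoothed_observation(self) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and predictive variance of y on the grid."""
        if self.smoothed_means is None:
            raise ValueError("run kalman_smooth first")
        F, _ = self.spec.matrices()
        mean = self.smoothed_means @ F
        var = np.einsum("i,tij,j->t", F, self.smoothed_covs, F) + self.scale[-1]
        return mean, var


@dataclass
class ImputationEnsemble:
    """M complete series sampled from the posterior predictive."""

    name: str
    members: np.ndarray          # (M, T), data scale
    mask: np.ndarray             # observed flags of the input series
    start: WeekIndex
    seed: int
    spec: DLMSpec

    def __post_init__(self) -> None:
        if self.members.ndim != 2 or self.members.shape[0] < 1:
            raise ValueError("members must be (M, T) with M >= 1")

    @property
    def m(self) -> int:
        return self.members.shape[0]

    @property
    def n_weeks(self) -> int:
        return self.members.shape[1]

    def mean_series(self) -> np.ndarray:
        return self.members.mean(axis=0)


def _symmetrize(A: np.ndarray) -> np.ndarray:
    return (A + A.T) / 2


def kalman_filter(spec: DLMSpec, series: WeeklySeries) -> StateMoments:
    """Forward recursion; missing weeks update through the evolution only.

    Returns the predictive log-likelihood of the observed points (Student-t
    one-step densities in the unknown-variance case, Gaussian otherwise).
    """
    y = np.asarray(series.values, float)
    mask = np.asarray(series.mask, bool)
    T = len(y)
    if not mask.any():
        raise ValueError("all-missing series: nothing to filter")

    F, G = spec.matrices()
    d = spec.dim
    m, C = spec.priors(series)
    known_v = spec.obs_variance is not None
    S = spec.obs_variance if known_v else spec.prior_scale
    n = np.inf if known_v else spec.prior_df
    # block-diagonal discounting: W_ii = P_ii (1 - delta_i) / delta_i per
    # component block, zero across blocks (keeps the implied W PSD)
    kt = spec.n_trend
    w_trend = (1.0 - spec.discount_trend) / spec.discount_trend
    w_seas = (1.0 - spec.discount_seasonal) / spec.discount_seasonal

    out = {k: np.empty((T, d)) for k in ("a", "m")}
    covs = {k: np.empty((T, d, d)) for k in ("R", "C")}
    f = np.empty(T)
    q = np.empty(T)
    dfs = np.empty(T)
    scales = np.empty(T)
    loglik = 0.0

    for t in range(T):
        a = G @ m
        P = _symmetrize(G @ C @ G.T)
        if spec.state_cov is not None:
            R = P + spec.state_cov
        else:
            R = P.copy()
            R[:kt, :kt] += P[:kt, :kt] * w_trend
            R[kt:, kt:] += P[kt:, kt:] * w_seas
        R = _symmetrize(R)
        ft = float(F @ a)
        qt = float(F @ R @ F) + S
        if mask[t]:
            e = y[t] - ft
            A = (R @ F) / qt
            m = a + A * e
            if known_v:
                C = _symmetrize(R - np.outer(A, A) * qt)
                loglik += stats.norm.logpdf(e, scale=np.sqrt(qt))
            else:
                n_new = n + 1.0
                S_new = S + (S / n_new) * (e * e / qt - 1.0)
                C = _symmetrize((S_new / S) * (R - np.outer(A, A) * qt))
                loglik += stats.t.logpdf(e / np.sqrt(qt), df=n) - 0.5 * np.log(qt)
                n, S = n_new, S_new
        else:
            m, C = a, R
        out["a"][t], out["m"][t] = a, m
        covs["R"][t], covs["C"][t] = R, C
        f[t], q[t] = ft, qt
        dfs[t] = n
        scales[t] = S

    return StateMoments(
        spec=spec, mask=mask,
        pred_means=out["a"], pred_covs=covs["R"],
        filtered_means=out["m"], filtered_covs=covs["C"],
        forecast_means=f, forecast_vars=q,
        df=dfs, scale=scales, loglik=float(loglik),
    )


def _backward_gains(spec: DLMSpec, mom: StateMoments):
    """Smoother gains B_t and conditional covariances H_t, shared by
    smoothing and FFBS.  H_t = C_t - B_t R_{t+1} B_t' (scale handled by
    callers in the unknown-variance case)."""
    _, G = spec.matrices()
    T = mom.n_weeks
    B = np.empty((T - 1, spec.dim, spec.dim))
    H = np.empty((T - 1, spec.dim, spec.dim))
    for t in range(T - 1):
        R_next = mom.pred_covs[t + 1]
        C = mom.filtered_covs[t]
        B[t] = np.linalg.solve(R_next, G @ C).T
        H[t] = _symmetrize(C - B[t] @ R_next @ B[t].T)
    return B, H


def kalman_smooth(spec: DLMSpec, moments: StateMoments) -> StateMoments:
    """Backward recursion; fills smoothed means/covariances in a copy."""
    T = moments.n_weeks
    B, _ = _backward_gains(spec, moments)
    s = np.empty_like(moments.filtered_means)
    Ssm = np.empty_like(moments.filtered_covs)
    s[-1] = moments.filtered_means[-1]
    Ssm[-1] = moments.filtered_covs[-1]
    for t in range(T - 2, -1, -1):
        s[t] = moments.filtered_means[t] + B[t] @ (s[t + 1] - moments.pred_means[t + 1])
        Ssm[t] = _symmetrize(
            moments.filtered_covs[t]
            - B[t] @ (moments.pred_covs[t + 1] - Ssm[t + 1]) @ B[t].T
        )
    if spec.obs_variance is None:
        # retrospective scale update: calibrate to the final variance estimate
        Ssm = Ssm * (moments.scale[-1] / moments.scale)[:, None, None]
    return replace(moments, smoothed_means=s, smoothed_covs=Ssm)


def ffbs_sample(
    spec: DLMSpec, series: WeeklySeries, M: int = 100, seed: int = 0
) -> ImputationEnsemble:
    """Draw M complete sequences from the posterior predictive.

    Observed weeks are emitted verbatim; missing weeks get a state draw plus
    observation noise.  Deterministic given the seed.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    mom = kalman_filter(spec, series)
    F, _ = spec.matrices()
    T = mom.n_weeks
    d = spec.dim
    B, H = _backward_gains(spec, mom)

    # draw the observation variance per member
    if spec.obs_variance is not None:
        V = np.full(M, float(spec.obs_variance))
        c = np.ones(M)                      # covariance scale factor V / S_t
        c_t = None
    else:
        nT, ST = mom.df[-1], mom.scale[-1]
        V = nT * ST / rng.chisquare(nT, size=M)
        c_t = V[:, None] / mom.scale[None, :]   # (M, T)

    def chol(Ai: np.ndarray) -> np.ndarray:
        A = _symmetrize(Ai)
        jitter = 1e-12 * max(np.trace(A) / d, 1e-300)
        for _ in range(6):
            try:
                return np.linalg.cholesky(A + jitter * np.eye(d))
            except np.linalg.LinAlgError:
                jitter *= 100
        # fall back to eigendecomposition for a PSD square root
        w, U = np.linalg.eigh(A)
        return U * np.sqrt(np.clip(w, 0, None))

    theta = np.empty((M, T, d))
    sc = np.sqrt(c_t[:, -1] if c_t is not None else c)
    theta[:, -1] = mom.filtered_means[-1] + (rng.standard_normal((M, d)) @ chol(
        mom.filtered_covs[-1]).T) * sc[:, None]
    for t in range(T - 2, -1, -1):
        h = mom.filtered_means[t] + (theta[:, t + 1] - mom.pred_means[t + 1]) @ B[t].T
        sc = np.sqrt(c_t[:, t] if c_t is not None else c)
        theta[:, t] = h + (rng.standard_normal((M, d)) @ chol(H[t]).T) * sc[:, None]

    members = theta @ F
    members += rng.standard_normal((M, T)) * np.sqrt(V)[:, None]
    members[:, mom.mask] = series.values[mom.mask]
    return ImputationEnsemble(
        name=series.name, members=members, mask=mom.mask.copy(),
        start=series.start, seed=seed, spec=spec,
    )


def decompose(
    spec: DLMSpec, series: WeeklySeries
) -> tuple[np.ndarray, np.ndarray, dict[int, float]]:
    """Smoothed trend and seasonal components plus the per-year seasonal mean.

    The trend component is the smoothed level; the seasonal component is the
    smoothed sum of the harmonic states entering the observation equation.
    """
    if spec.harmonics < 1:
        raise ValueError("decompose requires a seasonal block")
    mom = kalman_smooth(spec, kalman_filter(spec, series))
    trend = mom.smoothed_means[:, 0]
    seasonal = mom.smoothed_means[:, spec.seasonal_obs_indices()].sum(axis=1)
    years, _ = series.week_grid()
    annual_mean = {
        int(y): float(seasonal[years == y].mean()) for y in np.unique(years)
    }
    return trend, seasonal, annual_mean


# ---------------------------------------------------------------------------
# Panel-level imputation


def _transform_series(series: WeeklySeries, transform: str) -> WeeklySeries:
    if transform == "raw":
        return series
    obs = series.values[series.mask]
    if np.any(obs <= 0):
        raise ValueError(f"{series.name}: log transform requires positive values")
    vals = np.where(series.mask, np.maximum(series.values, 1e-300), 1.0)
    # renamed so the nonnegativity check on concentration variables does not
    # fire on (legitimately negative) log values
    return WeeklySeries(
        f"log_{series.name}",
        np.where(series.mask, np.log(vals), np.nan),
        series.mask, series.start, unit=series.unit,
    )


def default_spec_for(series: WeeklySeries) -> DLMSpec:
    """Log transform whenever the observed values are strictly positive."""
    obs = series.values[series.mask]
    transform = "log" if obs.size and np.all(obs > 0) else "raw"
    return DLMSpec(transform=transform)


def impute_panel(
    panel: EnvironmentalPanel,
    specs: dict[str, DLMSpec] | None = None,
    M: int = 100,
    seed: int = 0,
    chl_var: str = "chl",
) -> tuple[ImputationEnsemble, EnvironmentalPanel]:
    """Ensemble-impute chlorophyll; mean-impute every other variable.

    Chlorophyll gets M posterior-predictive sequences (back-transformed to the
    raw scale when fit on logs, with observed weeks exact).  Each driver is
    completed with its smoothed posterior-mean observation.  The returned
    panel is fully observed, with chlorophyll filled by the ensemble mean.
    """
    if chl_var not in panel:
        raise ValueError(f"panel has no {chl_var!r} series")
    specs = dict(specs or {})
    completed: dict[str, WeeklySeries] = {}
    ensemble: ImputationEnsemble | None = None

    for name, s in panel.series.items():
        spec = specs.get(name, default_spec_for(s))
        n_obs = int(s.mask.sum())
        if n_obs < 2 * WEEKS_PER_YEAR:
            warnings.warn(
                f"{name}: only {n_obs} observed weeks; using the diffuse default prior",
                stacklevel=2,
            )
            spec = replace(spec, prior_mean=None, prior_cov=None)
        ts = _transform_series(s, spec.transform)
        if name == chl_var:
            ens = ffbs_sample(spec, ts, M=M, seed=seed)
            members = np.exp(ens.members) if spec.transform == "log" else ens.members
            members[:, s.mask] = s.values[s.mask]
            ensemble = ImputationEnsemble(
                name=name, members=members, mask=s.mask.copy(),
                start=s.start, seed=seed, spec=spec,
            )
            filled = members.mean(axis=0)
        else:
            mom = kalman_smooth(spec, kalman_filter(spec, ts))
            mean, _ = mom.smoothed_observation()
            filled = np.exp(mean) if spec.transform == "log" else mean
        vals = np.where(s.mask, s.values, filled)
        if s.name in ("chl",) or name in ("no32", "nh4", "po4", "sio4"):
            vals = np.maximum(vals, 0.0)
        completed[name] = WeeklySeries(
            name, vals, np.ones(len(s), bool), s.start, unit=s.unit
        )

    assert ensemble is not None
    return ensemble, EnvironmentalPanel(completed, dict(panel.annual_covariates))
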