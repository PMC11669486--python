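"""Hierarchical smooth model of migration distance versus days.

Along-river distance since the start of upriver migration is modelled as

    d_ij = f(t_ij) + a_i + c_i * t_ij + e_ij,

with ``f`` a penalized cubic B-spline population smooth, ``(a_i, c_i)``
independent per-fish random intercepts and slopes (fish share a release
point but differ mainly in speed), and ``e_ij`` first-order autoregressive
within-fish residuals with lag-1 coefficient ``phi`` (daily surveys make
consecutive positional errors dependent).

Estimation alternates (i) profiled REML over the variance ratios of the
smooth and the random effects given ``phi`` — the smooth's wiggly part is
treated as a random effect, so its penalty weight is estimated with the
variance components — with (ii) a moment update of ``phi`` from the lag-1
autocorrelation of within-fish residuals, iterating to a relative
tolerance.  Uniform (unclamped) knots are used so the penalty null space
corresponds exactly to straight lines: as the smoothing variance goes to
zero the fitted curve collapses to a line.

The module also implements the data-filtering rules applied before
fitting: fixes after tracking gaps longer than 3 days are dropped, the
initial stay at the release site is removed (time is rebased to the start
of upriver movement), and fish spawning in the lower basin (<30 km), fish
whose tag surfaced there, and fish left with two or fewer points are
excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.interpolate import BSpline

from .fates import LOCATED, NOT_LOCATED, FateRecord, _find_stop

__all__ = [
    "TrajectoryData",
    "TrajectoryModel",
    "TrajectoryResults",
    "filter_tracking_data",
    "fit_trajectory_model",
    "compare_ar_structures",
]


# ---------------------------------------------------------------------------
# data filtering
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryData:
    """Filtered distance-time observations with per-row exclusion reasons."""

    frame: pd.DataFrame  # fish_id, t, d, retained, reason

    @property
    def retained(self) -> pd.DataFrame:
        return self.frame[self.frame["retained"]].reset_index(drop=True)

    @property
    def n_fish(self) -> int:
        return self.retained["fish_id"].nunique()

    def exclusion_log(self) -> pd.DataFrame:
        dropped = self.frame[~self.frame["retained"]]
        return dropped.groupby(["fish_id", "reason"]).size().rename("n").reset_index()


def filter_tracking_data(
    tracks: pd.DataFrame,
    fates: Mapping[str, FateRecord] | list[FateRecord] | None = None,
    max_gap_days: float = 3.0,
    movement_threshold_km: float = 1.0,
    min_points: int = 3,
    lower_basin_km: float = 30.0,
) -> TrajectoryData:
    """Apply the pre-fit filtering rules to a projected-track table.

    ``tracks`` needs columns fish_id, day, chainage_km.  With ``fates``
    supplied, not-located fish, lower-basin spawners and tags surfaced in
    the lower basin are excluded, and located fish are truncated at their
    stop day (station-keeping at the spawning site is not migration).
    """
    if isinstance(fates, list):
        fates = {r.fish_id: r for r in fates}
    rows = []
    for fish_id, sub in tracks.groupby("fish_id", sort=True):
        sub = sub.sort_values("day")
        day = sub["day"].to_numpy(float)
        chain = sub["chainage_km"].to_numpy(float)
        reason = np.array([""] * len(day), dtype=object)
        keep = np.ones(len(day), dtype=bool)

        fate = fates.get(fish_id) if fates else None
        if fate is not None:
            if fate.category == NOT_LOCATED:
                keep[:] = False
                reason[:] = "not_located"
            elif fate.last_chainage_km < lower_basin_km and (
                fate.category == LOCATED or fate.subcategory.startswith("Scheduled")
                or fate.subcategory.startswith("Premature")
            ):
                keep[:] = False
                reason[:] = (
                    "lower_basin_spawner" if fate.category == LOCATED
                    else "tag_surfaced_lower_basin"
                )
            elif fate.category == LOCATED:
                # migration ended during the interval before the stop fix, so
                # the at-site fix itself is station-keeping, not migration
                post = day > fate.last_day - 1e-9
                keep[post] = False
                reason[post] = "post_arrival"

        if keep.any():
            # terminal station-keeping that the fate label missed (e.g. a
            # noisy plateau classified as censoring) is not migration either;
            # the wider radius tolerates positional noise around the site
            stop = _find_stop(day[keep], chain[keep], 2.0, 2.0, movement_threshold_km)
            if stop is not None:
                post = keep & (day > stop[0] - 1e-9)
                keep[post] = False
                reason[post] = "post_arrival"

        if keep.any():
            kd = day[keep]
            gaps = np.diff(kd)
            big = np.nonzero(gaps > max_gap_days)[0]
            if big.size:
                cut = kd[big[0] + 1]
                late = keep & (day >= cut)
                keep[late] = False
                reason[late] = "long_gap"

        if keep.any():
            moved = keep & (chain >= movement_threshold_km)
            if not moved.any():
                reason[keep] = "no_movement"
                keep[:] = False
            else:
                first_move = np.nonzero(moved)[0][0]
                kept_before = np.nonzero(keep[:first_move])[0]
                origin = kept_before[-1] if kept_before.size else first_move
                stay = keep & (np.arange(len(day)) < origin)
                keep[stay] = False
                reason[stay] = "initial_stay"

        if keep.sum() < min_points:
            reason[keep] = "too_few_points"
            keep[:] = False

        t0 = day[keep][0] if keep.any() else 0.0
        for j in range(len(day)):
            rows.append(
                {
                    "fish_id": fish_id,
                    "t": day[j] - t0,
                    "d": chain[j] - (chain[keep][0] if keep.any() else 0.0),
                    "retained": bool(keep[j]),
                    "reason": reason[j],
                }
            )
    return TrajectoryData(frame=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class TrajectoryModel:
    """Population smooth + per-fish random intercept/slope + AR(1) residuals.

    Parameters
    ----------
    data : TrajectoryData or DataFrame
        Retained observations with columns fish_id, t, d.
    n_knots : int
        Interior knots of the cubic B-spline smooth (uniform spacing).
    extrapolation_factor : float
        The basis (and hence the predictable range) extends to this
        multiple of the largest observed t.
    """

    def __init__(self, data, n_knots: int = 8, extrapolation_factor: float = 1.5):
        df = data.retained if isinstance(data, TrajectoryData) else pd.DataFrame(data)
        df = df.sort_values(["fish_id", "t"]).reset_index(drop=True)
        counts = df.groupby("fish_id").size()
        if len(counts) < 5:
            raise ValueError("at least 5 fish are required")
        if (counts >= 4).sum() < 5:
            raise ValueError("at least 5 fish need 4 or more points")
        if (counts < 3).any():
            raise ValueError("each fish needs at least 3 points (filter the data first)")
        if (df.groupby("fish_id")["t"].apply(lambda s: np.any(np.diff(s) <= 0))).any():
            raise ValueError("within-fish t must be strictly increasing")
        if (df["t"] < 0).any():
            raise ValueError("t must be non-negative")

        self.df = df
        self.fish_ids = list(counts.index)
        self.t = df["t"].to_numpy(float)
        self.y = df["d"].to_numpy(float)
        self.groups = df["fish_id"].to_numpy()
        self.t_max = float(self.t.max())
        self.t_hi = extrapolation_factor * self.t_max
        self.n_knots = n_knots

        n_seg = n_knots + 1
        h = self.t_hi / n_seg
        self.knots = np.arange(-3, n_seg + 4) * h
        self.p_basis = n_seg + 3

        B = BSpline.design_matrix(self.t, self.knots, 3).toarray()
        D = np.diff(np.eye(self.p_basis), n=2, axis=0)
        vals, vecs = np.linalg.eigh(D.T @ D)
        self._U0 = vecs[:, :2]              # penalty null space: straight lines
        self._Up = vecs[:, 2:] / np.sqrt(vals[2:])
        self.X = B @ self._U0               # fixed: line
        self.Zs = B @ self._Up              # smooth deviations, unit prior
        self.q_smooth = self.Zs.shape[1]

        # per-fish random intercept/slope design (block diagonal)
        m = len(self.fish_ids)
        self.Zf = np.zeros((len(self.t), 2 * m))
        self._fish_slices = {}
        for k, fid in enumerate(self.fish_ids):
            idx = np.nonzero(self.groups == fid)[0]
            self.Zf[idx, 2 * k] = 1.0
            self.Zf[idx, 2 * k + 1] = self.t[idx]
            self._fish_slices[fid] = idx
        self.n_fish = m
        self.n_obs = len(self.t)

        # covariance building blocks, fixed across the optimisation
        self._Ss = self.Zs @ self.Zs.T
        self._A0 = (self.Zf[:, 0::2]) @ (self.Zf[:, 0::2]).T
        self._A1 = (self.Zf[:, 1::2]) @ (self.Zf[:, 1::2]).T

    # -- internals -----------------------------------------------------------

    def _corr_blocks(self, phi: float) -> np.ndarray:
        """Within-fish AR(1) correlation matrix of the residuals (N x N)."""
        R = np.eye(self.n_obs)
        if phi == 0.0:
            return R
        s, a = np.sign(phi), abs(phi)
        for idx in self._fish_slices.values():
            dt = np.abs(self.t[idx][:, None] - self.t[idx][None, :])
            R[np.ix_(idx, idx)] = np.power(s, np.round(dt)) * np.power(a, dt)
        return R

    def _v0(self, ratios: np.ndarray, R: np.ndarray) -> np.ndarray:
        gs, g0, g1 = ratios
        return R + gs * self._Ss + g0 * self._A0 + g1 * self._A1

    def _profiled_reml(self, log_ratios: np.ndarray, R: np.ndarray) -> float:
        try:
            V0 = self._v0(np.exp(log_ratios), R)
            c, low = linalg.cho_factor(V0, lower=True)
        except (np.linalg.LinAlgError, ValueError):
            return 1e12
        logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
        Vy = linalg.cho_solve((c, low), self.y)
        VX = linalg.cho_solve((c, low), self.X)
        A = self.X.T @ VX
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e12
        beta = np.linalg.solve(A, self.X.T @ Vy)
        r = self.y - self.X @ beta
        quad = float(r @ linalg.cho_solve((c, low), r))
        dof = self.n_obs - self.X.shape[1]
        if quad <= 0:
            return 1e12
        sigma2 = quad / dof
        return 0.5 * (logdetV + logdetA + dof * (math.log(sigma2) + 1.0))

    def fit(
        self,
        fix_phi: float | None = None,
        max_outer: int = 100,
        tol: float = 1e-6,
        fixed_ratios: Mapping[str, float] | None = None,
    ) -> "TrajectoryResults":
        """Profiled-REML estimation of variance ratios and the AR coefficient.

        The residual variance is profiled out analytically; the smoothing,
        random-intercept and random-slope variance ratios (log scale) and
        ``phi`` (Fisher-z scale) are maximised jointly by Nelder-Mead,
        initialised from an independent-residual fit plus the lag-1
        moment autocorrelation of its within-fish residuals.  A moment
        fixed-point update of ``phi`` alone is biased towards zero because
        the BLUPs absorb part of the correlated noise, so the criterion
        itself decides ``phi``.

        ``fix_phi`` pins the AR coefficient (e.g. 0 for independent
        residuals); ``fixed_ratios`` pins variance-to-residual ratios by
        name ("smooth", "intercept", "slope") — useful for forcing the
        smooth to a straight line (``{"smooth": 1e-8}``).
        """
        fixed_ratios = dict(fixed_ratios or {})
        names = ["smooth", "intercept", "slope"]
        free = [i for i, nm in enumerate(names) if nm not in fixed_ratios]
        base = np.log(np.array([1.0, 1.0, 1.0]))
        for i, nm in enumerate(names):
            if nm in fixed_ratios:
                base[i] = math.log(max(fixed_ratios[nm], 1e-12))

        def neg_reml_at(log_ratios: np.ndarray, phi: float) -> float:
            return self._profiled_reml(log_ratios, self._corr_blocks(phi))

        nm_opts = {"xatol": 1e-4, "fatol": 1e-7}

        # stage 1: independent residuals, giving a warm start for the ratios
        def obj_ratios(x):
            full = base.copy()
            full[free] = x
            return neg_reml_at(full, 0.0 if fix_phi is None else fix_phi)

        log_ratios = base.copy()
        if free:
            best = None
            for x0 in (np.zeros(len(free)), np.array([1.0, -2.0, 1.0])[: len(free)]):
                res = optimize.minimize(
                    obj_ratios, x0, method="Nelder-Mead",
                    options={**nm_opts, "maxiter": 250 * len(free)},
                )
                if best is None or res.fun < best.fun:
                    best = res
            log_ratios[free] = best.x

        n_eval = 0
        if fix_phi is not None:
            phi = float(fix_phi)
            neg_reml = neg_reml_at(log_ratios, phi)
            converged = True
        else:
            phi0 = self._phi_moment(np.exp(log_ratios), self._corr_blocks(0.0))

            def obj_joint(x):
                full = base.copy()
                if free:
                    full[free] = x[:-1]
                return neg_reml_at(full, math.tanh(x[-1]))

            best = None
            for z0 in (float(np.arctanh(np.clip(phi0, -0.9, 0.9))), 0.5):
                x0 = np.concatenate([log_ratios[free], [z0]])
                res = optimize.minimize(
                    obj_joint, x0, method="Nelder-Mead",
                    options={**nm_opts, "maxiter": max_outer * (len(free) + 1) * 3},
                )
                if best is None or res.fun < best.fun:
                    best = res
            if free:
                log_ratios[free] = best.x[:-1]
            phi = float(math.tanh(best.x[-1]))
            neg_reml = best.fun
            converged = bool(best.success)
            n_eval = int(best.nit)
        if not converged:
            warnings.warn("trajectory model: REML optimisation did not converge")
        n_outer = n_eval

        return self._assemble_results(np.exp(log_ratios), phi, -neg_reml, converged,
                                      fix_phi is not None, n_outer)

    def _solve_blups(self, ratios: np.ndarray, R: np.ndarray):
        V0 = self._v0(ratios, R)
        c, low = linalg.cho_factor(V0, lower=True)
        Vy = linalg.cho_solve((c, low), self.y)
        VX = linalg.cho_solve((c, low), self.X)
        A = self.X.T @ VX
        beta = np.linalg.solve(A, self.X.T @ Vy)
        r = self.y - self.X @ beta
        Vr = linalg.cho_solve((c, low), r)
        gs, g0, g1 = ratios
        u_s = gs * (self.Zs.T @ Vr)
        gf = np.tile([g0, g1], self.n_fish)
        u_f = gf * (self.Zf.T @ Vr)
        sigma2 = float(r @ Vr) / (self.n_obs - self.X.shape[1])
        return beta, u_s, u_f, sigma2, r

    def _phi_moment(self, ratios: np.ndarray, R: np.ndarray) -> float:
        beta, u_s, u_f, _, r = self._solve_blups(ratios, R)
        e = r - self.Zs @ u_s - self.Zf @ u_f
        num = den_a = den_b = 0.0
        for idx in self._fish_slices.values():
            ti, ei = self.t[idx], e[idx]
            lag1 = np.isclose(np.diff(ti), 1.0)
            a, b = ei[1:][lag1], ei[:-1][lag1]
            num += float(a @ b)
            den_a += float(a @ a)
            den_b += float(b @ b)
        if den_a <= 0 or den_b <= 0:
            return 0.0
        return float(np.clip(num / math.sqrt(den_a * den_b), -0.95, 0.95))

    def _assemble_results(self, ratios, phi, reml_loglik, converged, phi_fixed, n_outer):
        R = self._corr_blocks(phi)
        beta, u_s, u_f, sigma2, _ = self._solve_blups(ratios, R)

        # Bayesian posterior covariance of all coefficients, for CIs.
        C = np.hstack([self.X, self.Zs, self.Zf])
        gs, g0, g1 = np.maximum(ratios, 1e-10)
        prior = np.concatenate(
            [np.zeros(2), np.full(self.q_smooth, 1.0 / gs), np.tile([1.0 / g0, 1.0 / g1], self.n_fish)]
        )
        Rinv_C = np.linalg.solve(R, C)
        H = C.T @ Rinv_C + np.diag(prior)
        cov = sigma2 * np.linalg.inv(H)

        blups = pd.DataFrame(
            {
                "fish_id": self.fish_ids,
                "intercept": u_f[0::2],
                "slope": u_f[1::2],
            }
        )
        k_var = 1 + len(ratios) + (0 if phi_fixed else 1)
        aic = -2.0 * reml_loglik + 2.0 * k_var
        bic = -2.0 * reml_loglik + k_var * math.log(self.n_obs)
        return TrajectoryResults(
            model=self,
            beta=beta,
            u_smooth=u_s,
            blups=blups,
            phi=float(phi),
            phi_fixed=phi_fixed,
            sigma2=sigma2,
            tau2_smooth=gs * sigma2,
            var_intercept=g0 * sigma2,
            var_slope=g1 * sigma2,
            cov_mean=cov[: 2 + self.q_smooth, : 2 + self.q_smooth],
            reml_loglik=reml_loglik,
            aic=aic,
            bic=bic,
            converged=converged,
            n_outer=n_outer,
        )

    def _mean_design(self, t: np.ndarray) -> np.ndarray:
        B = BSpline.design_matrix(t, self.knots, 3).toarray()
        return np.hstack([B @ self._U0, B @ self._Up])


@dataclass
class TrajectoryResults:
    """Fitted hierarchical trajectory model."""

    model: TrajectoryModel = field(repr=False)
    beta: np.ndarray
    u_smooth: np.ndarray
    blups: pd.DataFrame
    phi: float
    phi_fixed: bool
    sigma2: float
    tau2_smooth: float
    var_intercept: float
    var_slope: float
    cov_mean: np.ndarray
    reml_loglik: float
    aic: float
    bic: float
    converged: bool
    n_outer: int

    @property
    def sd_intercept(self) -> float:
        return math.sqrt(self.var_intercept)

    @property
    def sd_slope(self) -> float:
        return math.sqrt(self.var_slope)

    def predict(self, t, with_ci: bool = False, isotonic: bool = False, z: float = 1.959963984540054):
        """Population-mean distance at ``t`` days since migration start.

        Pointwise intervals come from the coefficient posterior covariance
        and widen beyond the observed range.  ``isotonic`` projects the
        mean onto non-decreasing curves (pool-adjacent-violators via
        cumulative maximum), for inverse queries.
        """
        scalar = np.isscalar(t)
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < 0) or np.any(t > self.model.t_hi + 1e-9):
            raise ValueError(
                f"t outside the predictable range [0, {self.model.t_hi:.2f}] days"
            )
        A = self.model._mean_design(t)
        coefs = np.concatenate([self.beta, self.u_smooth])
        mean = A @ coefs
        if isotonic:
            order = np.argsort(t)
            mean[order] = np.maximum.accumulate(mean[order])
        if not with_ci:
            return mean[0] if scalar else mean
        var = np.einsum("ij,jk,ik->i", A, self.cov_mean, A)
        se = np.sqrt(np.clip(var, 0.0, None))
        lo, hi = mean - z * se, mean + z * se
        if scalar:
            return mean[0], lo[0], hi[0]
        return mean, lo, hi

    def predict_fish(self, fish_id: str, t) -> np.ndarray:
        """Individual prediction including the fish's BLUPs."""
        row = self.blups.set_index("fish_id").loc[fish_id]
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return self.predict(t) + row["intercept"] + row["slope"] * t

    def time_to_chainage(self, target_km: float, resolution: float = 0.01,
                         isotonic: bool = True) -> float:
        """Smallest t (days) with predicted distance >= ``target_km``."""
        if target_km <= 0:
            return 0.0
        grid = np.arange(0.0, self.model.t_hi + resolution / 2.0, resolution)
        pred = self.predict(grid, isotonic=isotonic)
        hit = np.nonzero(pred >= target_km)[0]
        if hit.size == 0:
            raise ValueError(
                f"target {target_km} km is never reached on the predictable range"
            )
        return float(grid[hit[0]])

    def summary(self) -> pd.DataFrame:
        rows = [
            ("phi (AR1)", self.phi),
            ("sigma (residual, km)", math.sqrt(self.sigma2)),
            ("sd intercept (km)", self.sd_intercept),
            ("sd slope (km/day)", self.sd_slope),
            ("tau (smooth, km)", math.sqrt(self.tau2_smooth)),
            ("REML loglik", self.reml_loglik),
            ("AIC", self.aic),
            ("BIC", self.bic),
        ]
        return pd.DataFrame(rows, columns=["parameter", "value"])

    def plot(self, ax=None):  # pragma: no cover - convenience only
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(0.0, self.model.t_hi, 200)
        mean, lo, hi = self.predict(grid, with_ci=True)
        ax.plot(grid, mean, label="population mean")
        ax.fill_between(grid, lo, hi, alpha=0.2)
        for fid, idx in self.model._fish_slices.items():
            ax.plot(self.model.t[idx], self.model.y[idx], ".", ms=4)
        ax.set_xlabel("days since start of upriver migration")
        ax.set_ylabel("distance from release (km)")
        return ax


def fit_trajectory_model(data, **kwargs) -> TrajectoryResults:
    """Build and fit the trajectory model in one call."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("fix_phi", "max_outer", "tol", "fixed_ratios")
                  if k in kwargs}
    return TrajectoryModel(data, **kwargs).fit(**fit_kwargs)


def compare_ar_structures(data, **kwargs) -> pd.DataFrame:
    """Information-criterion comparison: AR(1) residuals vs independent."""
    model = TrajectoryModel(data, **kwargs)
    free = model.fit()
    indep = model.fit(fix_phi=0.0)
    return pd.DataFrame(
        {
            "structure": ["AR1", "independent"],
            "phi": [free.phi, 0.0],
            "reml_loglik": [free.reml_loglik, indep.reml_loglik],
            "aic": [free.aic, indep.aic],
            "bic": [free.bic, indep.bic],
        }
    )
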