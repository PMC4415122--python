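"""Gaussian-process factor analysis of binned spike counts.

The model: square-rooted spike counts ``y_t`` (n_units) in 20 ms bins relate
to a low-dimensional latent state ``x_t`` (n_latents) through

    y_t = C x_t + d + eps_t,      eps_t ~ N(0, R),  R diagonal,

with each latent dimension an independent zero-mean Gaussian process over
the trial's bins, squared-exponential kernel

    K_i(t, s) = (1 - sigma_n) exp(-(t - s)^2 / (2 tau_i^2)) + sigma_n delta_ts.

Fitting is by EM: the E-step computes the exact Gaussian posterior of the
latents per trial (trials of equal length share all expensive factors); the
M-step updates ``C, d, R`` in closed form and each timescale ``tau_i`` by
bounded scalar maximisation of its expected complete-data log-likelihood
term (a generalised M-step, so the data log-likelihood never decreases).
Variable trial lengths are handled by per-length kernel matrices on the
shared bin grid; no padding.

The posterior mean trajectory is a *linear* function of the centred
observations for a fixed model, which is what makes the full decode value an
affine function of the binned counts.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg, optimize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FactorAnalysis


def se_kernel(n_bins: int, tau: float, bin_width: float, gp_noise: float) -> np.ndarray:
    """Squared-exponential kernel on a regular grid of ``n_bins`` bins."""
    t = bin_width * np.arange(n_bins)
    d2 = (t[:, None] - t[None, :]) ** 2
    return (1.0 - gp_noise) * np.exp(-d2 / (2.0 * tau**2)) + gp_noise * np.eye(n_bins)


def _chol_logdet(A: np.ndarray) -> Tuple[np.ndarray, float]:
    c = linalg.cholesky(A, lower=True)
    return c, 2.0 * float(np.sum(np.log(np.diag(c))))


class GPFA(TransformerMixin, BaseEstimator):
    """GPFA estimator over lists of per-trial count matrices.

    Parameters
    ----------
    n_latents : int
        Latent dimensionality (default 12).
    bin_width : float
        Bin width in ms; sets the kernel's time axis (default 20).
    sqrt_transform : bool
        Apply a square-root transform to counts before fitting (default
        True; stabilises Poisson variance).
    tol : float
        Relative log-likelihood convergence tolerance (default 1e-8).
    max_iter : int
        EM iteration cap (default 500).
    tau_init : float
        Initial GP timescale, ms (default 100).
    gp_noise : float
        Fixed GP noise fraction ``sigma_n`` (default 1e-3).
    update_tau : bool
        Learn timescales in the M-step (default True).
    init : {"fa", "random"}
        Initialise from a static factor analysis, or randomly.
    random_state : int or None
        Seed for random initialisation.

    Attributes
    ----------
    C_ : (n_units, n_latents) loading matrix.
    d_ : (n_units,) offsets.
    R_ : (n_units,) diagonal observation noise variances.
    taus_ : (n_latents,) GP timescales, ms.
    loglik_history_ : data log-likelihood at the start of each EM iteration.
    """

    def __init__(
        self,
        n_latents: int = 12,
        bin_width: float = 20.0,
        sqrt_transform: bool = True,
        tol: float = 1e-8,
        max_iter: int = 500,
        tau_init: float = 100.0,
        gp_noise: float = 1e-3,
        update_tau: bool = True,
        init: str = "fa",
        random_state: Optional[int] = None,
        min_var: float = 1e-6,
        tau_bounds: Tuple[float, float] = (10.0, 1500.0),
    ):
        self.n_latents = n_latents
        self.bin_width = bin_width
        self.sqrt_transform = sqrt_transform
        self.tol = tol
        self.max_iter = max_iter
        self.tau_init = tau_init
        self.gp_noise = gp_noise
        self.update_tau = update_tau
        self.init = init
        self.random_state = random_state
        self.min_var = min_var
        self.tau_bounds = tau_bounds

    # -- helpers ------------------------------------------------------------

    def _prepare(self, X: Sequence[np.ndarray]) -> List[np.ndarray]:
        out = []
        for i, Y in enumerate(X):
            Y = np.asarray(Y, dtype=float)
            if Y.ndim != 2:
                raise ValueError(f"trial {i}: expected a (bins, units) matrix")
            if self.sqrt_transform:
                if np.any(Y < 0):
                    raise ValueError(f"trial {i}: negative counts")
                Y = np.sqrt(Y)
            out.append(Y)
        n_units = {Y.shape[1] for Y in out}
        if len(n_units) != 1:
            raise ValueError(f"inconsistent unit counts across trials: {n_units}")
        return out

    def _kernels(self, T: int, taus: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
        """Per-latent kernels for a trial length: (Kinv stack, chols, logdetK)."""
        q = self.n_latents
        Kinv = np.empty((q, T, T))
        logdet = 0.0
        for i in range(q):
            K = se_kernel(T, taus[i], self.bin_width, self.gp_noise)
            c, ld = _chol_logdet(K)
            Kinv[i] = linalg.cho_solve((c, True), np.eye(T))
            logdet += ld
        return Kinv, logdet

    def _estep(
        self,
        by_len: Dict[int, List[np.ndarray]],
        C: np.ndarray,
        d: np.ndarray,
        R: np.ndarray,
        taus: np.ndarray,
        want_stats: bool = True,
    ):
        """Exact posterior per trial; returns loglik, means, and M-step stats."""
        q = self.n_latents
        n = C.shape[0]
        Rinv_C = C / R[:, None]                    # (n, q)
        W = C.T @ Rinv_C                           # (q, q)
        log_R = float(np.sum(np.log(R)))

        loglik = 0.0
        means: Dict[int, List[np.ndarray]] = {}
        if want_stats:
            S_xx = np.zeros((q, q))
            S_x = np.zeros(q)
            S_yx = np.zeros((n, q))
            S_y = np.zeros(n)
            S_yy = np.zeros(n)
            N = 0
            S_lat: Dict[int, np.ndarray] = {}      # T -> (q, T, T)

        for T, Ys in by_len.items():
            m = len(Ys)
            Kinv, logdetK = self._kernels(T, taus)
            # M = K^{-1} + I_T (x) W, time-major ordering
            M4 = np.zeros((T, q, T, q))
            for i in range(q):
                M4[:, i, :, i] = Kinv[i]
            idx = np.arange(T)
            M4[idx, :, idx, :] += W
            M = M4.reshape(T * q, T * q)
            cM, logdetM = _chol_logdet(M)
            Sigma = linalg.cho_solve((cM, True), np.eye(T * q))

            Ydiff = np.stack(Ys) - d               # (m, T, n)
            B = Ydiff @ Rinv_C                     # (m, T, q)
            Bf = B.reshape(m, T * q)
            Mu = Bf @ Sigma                        # posterior means, (m, Tq)
            quad_y = np.einsum("mtn,n->m", Ydiff**2, 1.0 / R)
            quad_b = np.einsum("mk,mk->m", Bf, Mu)
            const = n * T * math.log(2.0 * math.pi)
            ll_trials = -0.5 * (
                const + T * log_R + logdetK + logdetM + quad_y - quad_b
            )
            loglik += float(np.sum(ll_trials))
            Mu3 = Mu.reshape(m, T, q)
            means[T] = [Mu3[j] for j in range(m)]

            if want_stats:
                Sigma4 = Sigma.reshape(T, q, T, q)
                cov_tt = Sigma4[idx, :, idx, :]    # (T, q, q)
                S_xx += m * cov_tt.sum(axis=0) + np.einsum("mtq,mtr->qr", Mu3, Mu3)
                S_x += Mu3.sum(axis=(0, 1))
                Yall = np.stack(Ys)                # (m, T, n)
                S_yx += np.einsum("mtn,mtq->nq", Yall, Mu3)
                S_y += Yall.sum(axis=(0, 1))
                S_yy += np.einsum("mtn,mtn->n", Yall, Yall)
                N += m * T
                lat = np.empty((q, T, T))
                for i in range(q):
                    lat[i] = m * Sigma4[:, i, :, i] + np.einsum(
                        "mt,ms->ts", Mu3[:, :, i], Mu3[:, :, i]
                    )
                S_lat[T] = lat

        if want_stats:
            stats = dict(
                S_xx=S_xx, S_x=S_x, S_yx=S_yx, S_y=S_y, S_yy=S_yy, N=N, S_lat=S_lat
            )
            return loglik, means, stats
        return loglik, means, None

    def _tau_objective(self, tau: float, i: int, S_lat: Dict[int, np.ndarray], counts: Dict[int, int]) -> float:
        f = 0.0
        for T, lat in S_lat.items():
            K = se_kernel(T, tau, self.bin_width, self.gp_noise)
            c, ld = _chol_logdet(K)
            Kinv_S = linalg.cho_solve((c, True), lat[i])
            f += counts[T] * ld + float(np.trace(Kinv_S))
        return 0.5 * f  # negative of the tau-dependent part of Q

    # -- estimator API ------------------------------------------------------

    def fit(self, X: Sequence[np.ndarray], y=None) -> "GPFA":
        """Fit by EM on a list of (bins, units) count matrices."""
        Ys = self._prepare(X)
        n = Ys[0].shape[1]
        q = self.n_latents
        if n < q:
            raise ValueError(f"need at least {q} units to fit {q} latents, got {n}")

        by_len: Dict[int, List[np.ndarray]] = {}
        for Y in Ys:
            by_len.setdefault(Y.shape[0], []).append(Y)
        counts = {T: len(v) for T, v in by_len.items()}

        pooled = np.concatenate(Ys, axis=0)
        if self.init == "fa":
            fa = FactorAnalysis(n_components=q, random_state=0)
            fa.fit(pooled)
            C = fa.components_.T.copy()
            d = fa.mean_.copy()
            R = np.maximum(fa.noise_variance_, self.min_var)
        elif self.init == "random":
            rng = np.random.default_rng(self.random_state)
            scale = float(np.std(pooled)) or 1.0
            C = rng.normal(0.0, scale / math.sqrt(q), size=(n, q))
            d = pooled.mean(axis=0)
            R = np.maximum(pooled.var(axis=0), self.min_var)
        else:
            raise ValueError(f"unknown init {self.init!r}")
        taus = np.full(q, float(self.tau_init))

        history: List[float] = []
        for it in range(self.max_iter):
            loglik, _, stats = self._estep(by_len, C, d, R, taus, want_stats=True)
            if not np.isfinite(loglik):
                raise FloatingPointError(
                    f"non-finite log-likelihood at EM iteration {it}"
                )
            history.append(loglik)
            if it >= 1:
                rel = (history[-1] - history[-2]) / max(abs(history[-2]), 1.0)
                if abs(rel) < self.tol:
                    break

            # M-step: closed-form C, d, R
            G = np.empty((q + 1, q + 1))
            G[:q, :q] = stats["S_xx"]
            G[:q, q] = stats["S_x"]
            G[q, :q] = stats["S_x"]
            G[q, q] = stats["N"]
            Syx_aug = np.concatenate([stats["S_yx"], stats["S_y"][:, None]], axis=1)
            CD = np.linalg.solve(G, Syx_aug.T).T       # (n, q+1)
            C = CD[:, :q]
            d = CD[:, q]
            R = np.maximum(
                (stats["S_yy"] - np.einsum("nk,nk->n", CD, Syx_aug)) / stats["N"],
                self.min_var,
            )

            # generalised M-step on timescales (accept only improvements)
            if self.update_tau:
                for i in range(q):
                    f_old = self._tau_objective(taus[i], i, stats["S_lat"], counts)
                    res = optimize.minimize_scalar(
                        self._tau_objective,
                        args=(i, stats["S_lat"], counts),
                        bounds=self.tau_bounds,
                        method="bounded",
                        options={"xatol": 1.0},
                    )
                    if res.fun < f_old:
                        taus[i] = float(res.x)

        self.C_ = C
        self.d_ = d
        self.R_ = R
        self.taus_ = taus
        self.n_units_ = n
        self.loglik_history_ = history
        return self

    def loglik(self, X: Sequence[np.ndarray]) -> float:
        """Data log-likelihood of trials under the fitted model."""
        self._check_fitted()
        Ys = self._prepare(X)
        by_len: Dict[int, List[np.ndarray]] = {}
        for Y in Ys:
            by_len.setdefault(Y.shape[0], []).append(Y)
        ll, _, _ = self._estep(
            by_len, self.C_, self.d_, self.R_, self.taus_, want_stats=False
        )
        return ll

    def transform(self, X: Sequence[np.ndarray]) -> List[np.ndarray]:
        """Posterior-mean latent trajectories, one (bins, n_latents) per trial."""
        self._check_fitted()
        Ys = self._prepare(X)
        if Ys and Ys[0].shape[1] != self.n_units_:
            raise ValueError(
                f"model was fit on {self.n_units_} units, got {Ys[0].shape[1]}"
            )
        by_len: Dict[int, List[int]] = {}
        mats: Dict[int, List[np.ndarray]] = {}
        for j, Y in enumerate(Ys):
            by_len.setdefault(Y.shape[0], []).append(j)
            mats.setdefault(Y.shape[0], []).append(Y)
        _, means, _ = self._estep(
            mats, self.C_, self.d_, self.R_, self.taus_, want_stats=False
        )
        out: List[Optional[np.ndarray]] = [None] * len(Ys)
        for T, idxs in by_len.items():
            for j, mu in zip(idxs, means[T]):
                out[j] = mu
        return out  # type: ignore[return-value]

    def _check_fitted(self) -> None:
        if not hasattr(self, "C_"):
            raise RuntimeError("GPFA instance is not fitted yet")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "params": self.get_params(),
            "C": self.C_.tolist(),
            "d": self.d_.tolist(),
            "R": self.R_.tolist(),
            "taus": self.taus_.tolist(),
            "loglik_history": list(self.loglik_history_),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPFA":
        params = dict(d["params"])
        params["tau_bounds"] = tuple(params.get("tau_bounds", (10.0, 1500.0)))
        model = cls(**params)
        model.C_ = np.asarray(d["C"], dtype=float)
        model.d_ = np.asarray(d["d"], dtype=float)
        model.R_ = np.asarray(d["R"], dtype=float)
        model.taus_ = np.asarray(d["taus"], dtype=float)
        model.n_units_ = model.C_.shape[0]
        model.loglik_history_ = list(d.get("loglik_history", []))
        return model
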