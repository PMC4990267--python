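"""Conditional logit engine for the two-stage location choice models.

The systematic utility of region r on occasion n is

    V[n, r] = sum_k X[n, r, k] beta_k + sum_j Z[n, j] theta[j, r]

where X are region-varying features sharing one coefficient per feature
and Z are decision-invariant features whose effect is allowed to differ by
region (the Kronecker Z (x) I structure).  Identification requires a base
alternative: theta[:, base] = 0, so each theta[j, r] measures the effect
of Z_j on choosing region r relative to the base region.  The extreme-value
error is never materialized; it is integrated out in the logit choice
probabilities.

Estimation is maximum likelihood by Newton iteration with the analytic
gradient and Hessian (the conditional-logit log likelihood is globally
concave).  A normal-mixing random-coefficient extension is available as an
optional mode (:class:`MixedLogit`), off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import ChoiceOccasion

#: |coefficient| beyond which a fit is flagged as (quasi-)separated: on the
#: log-odds scale such magnitudes indicate a diverging parameter.
SEPARATION_BOUND = 30.0

SIZE_CLASS_NAMES = ("small", "medium", "large", "xlarge")
#: Half-open carrying-capacity bins (t); the upper edge of the last class
#: is inclusive.
SIZE_CLASS_BOUNDS = (363.0, 700.0, 1050.0, 1250.0, 1800.0)


def size_class(capacity_t: float) -> str:
    """Vessel size class from fish carrying capacity in tonnes.

    Classes are half-open [363,700), [700,1050), [1050,1250), [1250,1800];
    a capacity on a shared edge belongs to the larger class.
    """
    c = float(capacity_t)
    if not SIZE_CLASS_BOUNDS[0] <= c <= SIZE_CLASS_BOUNDS[-1]:
        raise ValueError(f"capacity {c} t outside [363, 1800]")
    for name, lo, hi in zip(SIZE_CLASS_NAMES, SIZE_CLASS_BOUNDS, SIZE_CLASS_BOUNDS[1:]):
        if lo <= c < hi:
            return name
    return SIZE_CLASS_NAMES[-1]  # c == 1800


@dataclass
class CoefficientSet:
    """Shared beta over X features plus region-specific theta over Z.

    ``theta`` is (J, R) with the base-alternative column identically zero.
    """

    beta: np.ndarray
    theta: np.ndarray
    base_alt: int  # region id (1-based); default: last region
    x_names: tuple[str, ...] = ()
    z_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        if self.theta.size and not np.all(self.theta[:, self.base_alt - 1] == 0.0):
            raise ValueError("theta column for the base alternative must be zero")

    @property
    def K(self) -> int:
        return self.beta.shape[0]

    @property
    def J(self) -> int:
        return self.theta.shape[0] if self.theta.size else 0

    @property
    def R(self) -> int:
        return self.theta.shape[1]

    def pack(self) -> np.ndarray:
        """Stack (beta, vec theta excluding the base column)."""
        free = np.delete(self.theta, self.base_alt - 1, axis=1) if self.theta.size else np.empty((0, 0))
        return np.concatenate([self.beta, free.ravel()])

    @classmethod
    def unpack(
        cls,
        params: np.ndarray,
        K: int,
        J: int,
        R: int,
        base_alt: int,
        x_names: tuple[str, ...] = (),
        z_names: tuple[str, ...] = (),
    ) -> "CoefficientSet":
        params = np.asarray(params, dtype=float)
        beta = params[:K]
        theta = np.zeros((J, R))
        if J:
            free = params[K:].reshape(J, R - 1)
            cols = [r for r in range(R) if r != base_alt - 1]
            theta[:, cols] = free
        return cls(beta=beta, theta=theta, base_alt=base_alt,
                   x_names=tuple(x_names), z_names=tuple(z_names))


def build_design(occ: ChoiceOccasion, base_alt: int) -> np.ndarray:
    """Explicit (R, K + J*(R-1)) design matrix for one occasion.

    X columns come first in declared order; then, for each Z feature j and
    each non-base region r (ascending), a column carrying Z_j in row r and
    zero elsewhere.  The base alternative's row of the Z block is all
    zeros.
    """
    X, Z = occ.X, occ.Z
    R, K = X.shape
    J = Z.shape[0]
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(Z)):
        bad = occ.x_names if not np.all(np.isfinite(X)) else occ.z_names
        raise ValueError(f"occasion {occ.occasion_id}: non-finite covariates in {bad}")
    out = np.zeros((R, K + J * (R - 1)))
    out[:, :K] = X
    col = K
    nonbase = [r for r in range(R) if r != base_alt - 1]
    for j in range(J):
        for r in nonbase:
            out[r, col] = Z[j]
            col += 1
    return out


def utility(d: np.ndarray, c: CoefficientSet) -> np.ndarray:
    """Systematic utility V (length R) from a design matrix."""
    params = c.pack()
    if d.shape[1] != params.shape[0]:
        raise ValueError(
            f"design has {d.shape[1]} columns but coefficient set packs to {params.shape[0]}"
        )
    return d @ params


def choice_probabilities(V: np.ndarray) -> np.ndarray:
    """Logit choice probabilities with max-subtraction overflow safety."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite utilities")
    e = np.exp(V - V.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _stack(occasions: Sequence[ChoiceOccasion]):
    o0 = occasions[0]
    R, K = o0.X.shape
    J = o0.Z.shape[0]
    for o in occasions:
        if o.X.shape != (R, K) or o.Z.shape != (J,):
            raise ValueError(f"occasion {o.occasion_id}: inconsistent covariate shapes")
        if not (1 <= o.chosen <= R):
            raise ValueError(f"occasion {o.occasion_id}: chosen region {o.chosen} not in 1..{R}")
    X = np.array([o.X for o in occasions], dtype=float)
    Z = np.array([o.Z for o in occasions], dtype=float)
    y = np.array([o.chosen - 1 for o in occasions], dtype=int)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(Z)):
        raise ValueError("non-finite covariates in occasion set")
    return X, Z, y


class ConditionalLogit:
    """Conditional logit model over a set of choice occasions.

    Parameters
    ----------
    occasions : sequence of ChoiceOccasion
        All occasions must share the same feature lists and R.
    base_alt : int, optional
        Region id of the base alternative (theta fixed at zero); defaults
        to the last region.
    """

    def __init__(self, occasions: Sequence[ChoiceOccasion], base_alt: Optional[int] = None):
        if len(occasions) == 0:
            raise ValueError("need at least one occasion")
        self.occasions = list(occasions)
        self.X, self.Z, self.y = _stack(self.occasions)
        self.N, self.R, self.K = self.X.shape
        self.J = self.Z.shape[1]
        self.base_alt = int(base_alt) if base_alt is not None else self.R
        if not 1 <= self.base_alt <= self.R:
            raise ValueError(f"base_alt {self.base_alt} not in 1..{self.R}")
        self.x_names = tuple(occasions[0].x_names)
        self.z_names = tuple(occasions[0].z_names)
        self.nparams = self.K + self.J * (self.R - 1)
        self._free_cols = [r for r in range(self.R) if r != self.base_alt - 1]

    # -- parameter plumbing -------------------------------------------------

    def coefficients(self, params: np.ndarray) -> CoefficientSet:
        return CoefficientSet.unpack(
            params, self.K, self.J, self.R, self.base_alt, self.x_names, self.z_names
        )

    def _theta(self, params: np.ndarray) -> np.ndarray:
        theta = np.zeros((self.J, self.R))
        if self.J:
            theta[:, self._free_cols] = params[self.K:].reshape(self.J, self.R - 1)
        return theta

    # -- likelihood ---------------------------------------------------------

    def utilities(self, params: np.ndarray) -> np.ndarray:
        V = np.einsum("nrk,k->nr", self.X, params[: self.K])
        if self.J:
            V = V + self.Z @ self._theta(params)
        return V

    def probabilities(self, params: np.ndarray) -> np.ndarray:
        return choice_probabilities(self.utilities(params))

    def loglike(self, params: np.ndarray) -> float:
        V = self.utilities(params)
        Vmax = V.max(axis=1)
        lse = Vmax + np.log(np.exp(V - Vmax[:, None]).sum(axis=1))
        return float((V[np.arange(self.N), self.y] - lse).sum())

    def score(self, params: np.ndarray) -> np.ndarray:
        p = self.probabilities(params)
        resid = -p
        resid[np.arange(self.N), self.y] += 1.0
        g_beta = np.einsum("nr,nrk->k", resid, self.X)
        if not self.J:
            return g_beta
        g_theta = self.Z.T @ resid  # (J, R)
        return np.concatenate([g_beta, g_theta[:, self._free_cols].ravel()])

    def hessian(self, params: np.ndarray) -> np.ndarray:
        """Analytic Hessian of the log likelihood (negative semidefinite)."""
        p = self.probabilities(params)
        N, R, K, J = self.N, self.R, self.K, self.J
        xbar = np.einsum("nr,nrk->nk", p, self.X)
        Xc = self.X - xbar[:, None, :]
        H = np.zeros((self.nparams, self.nparams))
        H[:K, :K] = -np.einsum("nr,nrk,nrl->kl", p, Xc, Xc)
        if J:
            free = self._free_cols
            # beta-theta block: -sum_n Z_nj p_ns Xc[n,s,k]
            bt = -np.einsum("nj,ns,nsk->kjs", self.Z, p, Xc)  # (K, J, R)
            H[:K, K:] = bt[:, :, free].reshape(K, J * (R - 1))
            H[K:, :K] = H[:K, K:].T
            # theta-theta block
            M = (self.Z[:, :, None] * p[:, None, :]).reshape(N, J * R)
            B = M.T @ M  # sum_n (Z_j p_r)(Z_j' p_r')
            A = np.empty((J, J, R))
            for r in range(R):
                A[:, :, r] = (self.Z * p[:, r : r + 1]).T @ self.Z
            Htt = B.reshape(J, R, J, R).copy()
            for r in range(R):
                Htt[:, r, :, r] -= A[:, :, r]
            Htt = Htt[:, free][:, :, :, free]
            H[K:, K:] = Htt.transpose(0, 1, 2, 3).reshape(
                J * (R - 1), J * (R - 1)
            )
        return H

    def loglike_null(self) -> float:
        """Zero-parameter equal-share null: N * ln(1/R)."""
        return self.N * np.log(1.0 / self.R)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        start_params: Optional[np.ndarray] = None,
        tol: float = 1e-6,
        maxiter: int = 100,
        stratum: Optional[tuple] = None,
        stage: Optional[str] = None,
    ) -> "ConditionalLogitResults":
        """Maximize the log likelihood by damped Newton iteration.

        Convergence is declared at gradient max-norm < ``tol``.  Singular
        information (collinear design columns) falls back to
        pseudo-inverse steps and is reported in the diagnostics.
        """
        params = (
            np.zeros(self.nparams)
            if start_params is None
            else np.asarray(start_params, dtype=float).copy()
        )
        if params.shape != (self.nparams,):
            raise ValueError(f"start_params must have shape ({self.nparams},)")
        ll = self.loglike(params)
        converged = False
        singular = False
        niter = 0
        for niter in range(1, maxiter + 1):
            g = self.score(params)
            if np.max(np.abs(g)) < tol:
                converged = True
                break
            H = self.hessian(params)
            try:
                step = np.linalg.solve(-H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.pinv(-H) @ g
                singular = True
            if not np.all(np.isfinite(step)):
                step = np.linalg.pinv(-H) @ g
                singular = True
            # damped step: halve until the likelihood does not decrease
            lam = 1.0
            for _ in range(40):
                cand = params + lam * step
                ll_new = self.loglike(cand)
                if ll_new >= ll - 1e-12:
                    break
                lam *= 0.5
            else:
                break  # no uphill step found: numerically at the optimum
            if abs(ll_new - ll) < 1e-13 * max(1.0, abs(ll)) and lam == 1.0:
                params, ll = cand, ll_new
                g = self.score(params)
                converged = bool(np.max(np.abs(g)) < tol)
                break
            params, ll = cand, ll_new
        else:
            g = self.score(params)
            converged = bool(np.max(np.abs(g)) < tol)
        separation = bool(np.any(np.abs(params) > SEPARATION_BOUND))
        if separation:
            warnings.warn(
                "possible perfect separation: |coefficient| exceeds "
                f"{SEPARATION_BOUND} on the log-odds scale"
            )
        if not converged:
            warnings.warn(f"fit did not reach gradient tolerance {tol} in {niter} iterations")
        H = self.hessian(params)
        info = -H
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
            singular = True
        bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
        return ConditionalLogitResults(
            model=self,
            params=params,
            cov_params=cov,
            bse=bse,
            llf=self.loglike(params),
            llnull=self.loglike_null(),
            nobs=self.N,
            niter=niter,
            converged=converged,
            separation=separation,
            singular_information=singular,
            stratum=stratum,
            stage=stage or (self.occasions[0].stage if self.occasions else None),
        )


@dataclass
class ConditionalLogitResults:
    """MLE results: estimates, uncertainties, fit measures, predictions."""

    model: ConditionalLogit
    params: np.ndarray
    cov_params: np.ndarray
    bse: np.ndarray
    llf: float
    llnull: float
    nobs: int
    niter: int
    converged: bool
    separation: bool
    singular_information: bool
    stratum: Optional[tuple] = None
    stage: Optional[str] = None

    @property
    def estimates(self) -> CoefficientSet:
        return self.model.coefficients(self.params)

    @property
    def std_errors(self) -> CoefficientSet:
        return self.model.coefficients(self.bse)

    @property
    def df_model(self) -> int:
        return self.model.nparams

    @property
    def prsquared(self) -> float:
        """McFadden's likelihood ratio index."""
        from .fit_eval import mcfadden_lri

        return mcfadden_lri(self.llf, self.llnull)

    @property
    def aldrich_nelson(self) -> float:
        from .fit_eval import aldrich_nelson

        return aldrich_nelson(self.llf, self.llnull, self.nobs)

    @property
    def estrella(self) -> float:
        from .fit_eval import estrella

        return estrella(self.llf, self.llnull, self.nobs)

    def predict(self, occasions: Optional[Sequence[ChoiceOccasion]] = None) -> np.ndarray:
        """(N, R) choice probabilities for fitted or new occasions."""
        if occasions is None:
            return self.model.probabilities(self.params)
        other = ConditionalLogit(occasions, base_alt=self.model.base_alt)
        return other.probabilities(self.params)

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table: one row per parameter with estimate, SE, z."""
        est, se = self.estimates, self.std_errors
        rows = []
        strat = "|".join(str(s) for s in self.stratum) if self.stratum else ""
        for k, name in enumerate(self.model.x_names):
            rows.append((strat, self.stage, name, "shared", est.beta[k], se.beta[k]))
        for j, name in enumerate(self.model.z_names):
            for r in range(self.model.R):
                if r == self.model.base_alt - 1:
                    continue
                rows.append(
                    (strat, self.stage, name, f"region_{r + 1}", est.theta[j, r], se.theta[j, r])
                )
        df = pd.DataFrame(
            rows,
            columns=["stratum", "stage", "feature", "region_or_shared", "estimate", "se"],
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            df["z"] = df["estimate"] / df["se"]
        return df

    def summary(self) -> str:
        lines = [
            "Conditional logit results",
            "=" * 70,
            f"Stage: {self.stage}   Stratum: {self.stratum}",
            f"N occasions: {self.nobs}   Alternatives: {self.model.R}   "
            f"Parameters: {self.df_model}",
            f"lnL: {self.llf:.3f}   lnL0: {self.llnull:.3f}",
            f"McFadden LRI: {self.prsquared:.4f}   "
            f"Aldrich-Nelson: {self.aldrich_nelson:.4f}   "
            f"Estrella: {self.estrella:.4f}",
            f"Converged: {self.converged} ({self.niter} iterations)"
            + ("   [separation flagged]" if self.separation else ""),
            "-" * 70,
            f"{'feature':<18}{'alt':<12}{'estimate':>12}{'SE':>12}{'z':>10}",
        ]
        df = self.to_frame()
        for _, row in df.iterrows():
            lines.append(
                f"{row['feature']:<18}{row['region_or_shared']:<12}"
                f"{row['estimate']:>12.4f}{row['se']:>12.4f}{row['z']:>10.2f}"
            )
        return "\n".join(lines)


def log_likelihood(
    c: CoefficientSet, occs: Sequence[ChoiceOccasion]
) -> tuple[float, np.ndarray]:
    """(lnL, analytic gradient) of a coefficient set on a set of occasions."""
    model = ConditionalLogit(occs, base_alt=c.base_alt)
    params = c.pack()
    return model.loglike(params), model.score(params)


def fit_conditional_logit(
    occs: Sequence[ChoiceOccasion],
    init: Optional[np.ndarray] = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    base_alt: Optional[int] = None,
) -> ConditionalLogitResults:
    """Convenience wrapper: build a ConditionalLogit and fit it."""
    return ConditionalLogit(occs, base_alt=base_alt).fit(
        start_params=init, tol=tol, maxiter=max_iter
    )


# ---------------------------------------------------------------------------
# Stratified fitting: DML x vessel size x stage
# ---------------------------------------------------------------------------


@dataclass
class StratifiedFit:
    """Per-stratum fit results over the full DML x size x stage grid."""

    results: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)  # stratum -> n occasions

    @property
    def n_models(self) -> int:
        return len(self.results)

    def to_frame(self) -> pd.DataFrame:
        frames = [res.to_frame() for res in self.results.values()]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def fit_stratified(
    occs: Sequence[ChoiceOccasion],
    registry: pd.DataFrame,
    min_occasions: int = 20,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> StratifiedFit:
    """Fit independent models per (DML, size class, stage) stratum.

    ``registry`` needs columns vessel_id, capacity_t, dml.  Every vessel
    appearing in the occasions must be registered.  Strata with fewer than
    ``min_occasions`` occasions are reported as skipped; a full fleet
    yields 2 x 4 x 2 = 16 models.
    """
    reg = registry.set_index(registry["vessel_id"].astype(str))
    strata: dict[tuple, list[ChoiceOccasion]] = {}
    for occ in occs:
        if occ.vessel_id not in reg.index:
            raise KeyError(f"vessel {occ.vessel_id} not in registry")
        row = reg.loc[occ.vessel_id]
        key = (int(row["dml"]), size_class(row["capacity_t"]), occ.stage)
        strata.setdefault(key, []).append(occ)
    out = StratifiedFit()
    for dml in (0, 1):
        for size in SIZE_CLASS_NAMES:
            for stage in ("first", "switch"):
                key = (dml, size, stage)
                group = strata.get(key, [])
                if len(group) < min_occasions:
                    out.skipped[key] = len(group)
                    continue
                out.results[key] = ConditionalLogit(group).fit(
                    tol=tol, maxiter=max_iter, stratum=(dml, size), stage=stage
                )
    return out


# ---------------------------------------------------------------------------
# Optional random-coefficient (mixed logit) mode
# ---------------------------------------------------------------------------


class MixedLogit(ConditionalLogit):
    """Normal-mixing random-coefficient extension (simulated ML).

    Selected X coefficients are treated as normally distributed across
    occasions; the simulated likelihood averages conditional-logit
    probabilities over scrambled-Halton draws.  Off by default and
    intended for small models: the gradient is numerical.
    """

    def __init__(
        self,
        occasions: Sequence[ChoiceOccasion],
        random_features: Sequence[str],
        n_draws: int = 64,
        seed: int = 0,
        base_alt: Optional[int] = None,
    ):
        super().__init__(occasions, base_alt=base_alt)
        self.random_idx = [self.x_names.index(f) for f in random_features]
        if not self.random_idx:
            raise ValueError("no random features specified")
        from scipy.stats import norm, qmc

        sampler = qmc.Halton(d=len(self.random_idx), scramble=True, seed=seed)
        u = sampler.random(n_draws)
        self.draws = norm.ppf(u)  # (n_draws, n_random)
        self.n_draws = n_draws
        self.nparams_mixed = self.nparams + len(self.random_idx)

    def simulated_loglike(self, params: np.ndarray) -> float:
        base = params[: self.nparams]
        sds = np.abs(params[self.nparams :])
        probs = np.zeros(self.N)
        for d in range(self.n_draws):
            p = base.copy()
            for i, k in enumerate(self.random_idx):
                p[k] = base[k] + sds[i] * self.draws[d, i]
            pr = self.probabilities(p)
            probs += pr[np.arange(self.N), self.y]
        probs /= self.n_draws
        return float(np.log(np.maximum(probs, 1e-300)).sum())

    def fit_mixed(self, start_params: Optional[np.ndarray] = None, maxiter: int = 200):
        from scipy.optimize import minimize

        x0 = (
            np.zeros(self.nparams_mixed)
            if start_params is None
            else np.asarray(start_params, dtype=float)
        )
        res = minimize(
            lambda p: -self.simulated_loglike(p),
            x0,
            method="L-BFGS-B",
            options={"maxiter": maxiter},
        )
        return res
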