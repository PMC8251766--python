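"""Random-effects meta-regression of log response ratios on moderators.

The model is

    L_i ~ N(x_iᵀ β,  v_i + τ²)

where v_i is the known (or imputed) sampling variance of study i's log
response ratio and τ² is the between-study variance of true effects beyond
sampling error.  Moderators are the log VPD ratio, daytime temperature,
treatment duration, plant age (continuous) and irrigation frequency and
soil type (categorical, dummy-coded against a reference level); single-
factor analyses use the plant-grouping labels instead.

τ² is estimated by REML (Fisher scoring with non-negativity projection;
DerSimonian–Laird method-of-moments available as an option).  Inference on
β is by normal-theory Wald z tests, with the Knapp–Hartung small-sample
adjustment (t reference, scaled covariance) as an option.  The omnibus
moderator statistic QM is the Wald chi-square over all non-intercept
coefficients.

Model selection follows backward elimination to a minimal adequate model:
each round refits and removes the single moderator with the largest
p-value above alpha (categorical moderators tested and removed as whole
blocks via their omnibus p) until only significant moderators remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .effects import EffectEstimate

CONTINUOUS_MODERATORS = ("log_vpd_ratio", "day_temp", "treatment_duration",
                         "plant_age")
CATEGORICAL_REFERENCES = {"irrigation": "hydroponic_or_daily",
                          "soil_type": "artificial"}
GROUPING_FACTORS = ("evolutionary_history", "growth_habit",
                    "growth_duration", "end_use")

#: gates: moderator meta-regression needs n > 20 studies, grouping analyses
#: need N > 20 species
MIN_STUDIES_METAREG = 21
MIN_SPECIES_GROUPING = 21


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


class UnderDeterminedError(ValueError):
    pass


@dataclass
class DesignSpec:
    """Which moderators enter the meta-regression, and their coding."""
    continuous: tuple[str, ...] = CONTINUOUS_MODERATORS
    categorical: dict[str, str] = field(
        default_factory=lambda: dict(CATEGORICAL_REFERENCES))
    intercept: bool = True

    def moderators(self) -> list[str]:
        return list(self.continuous) + list(self.categorical)

    def drop(self, moderator: str) -> "DesignSpec":
        if moderator in self.continuous:
            return replace(self, continuous=tuple(
                m for m in self.continuous if m != moderator))
        cats = {k: v for k, v in self.categorical.items() if k != moderator}
        return replace(self, categorical=cats)


def _value(e: EffectEstimate, name: str):
    if name == "log_vpd_ratio":
        return e.log_vpd_ratio
    return e.moderators.get(name)


@dataclass
class Design:
    L: np.ndarray
    v: np.ndarray
    X: np.ndarray
    names: list[str]
    blocks: dict[str, list[int]]        # moderator -> column indices
    used: list[str]                     # study_ids in row order
    dropped: dict[str, str]             # study_id -> reason
    pruned_levels: dict[str, list[str]] = field(default_factory=dict)


def build_design(estimates: Sequence[EffectEstimate], spec: DesignSpec,
                 min_level_count: int = 1) -> Design:
    """Assemble (L, v, X) for the meta-regression.

    Rows with a missing required moderator or no variance are dropped and
    listed; categorical levels absent from the data (or with fewer than
    ``min_level_count`` rows) are pruned.  The reference level is the
    configured one if present, else the first remaining level.
    """
    if len(estimates) == 0:
        raise ValueError("no estimates")
    dropped: dict[str, str] = {}
    rows: list[EffectEstimate] = []
    for e in estimates:
        if e.v_source == "unit_weight" or e.v is None:
            dropped[e.study_id] = "no variance (unit-weight study)"
            continue
        missing = [m for m in spec.moderators() if _value(e, m) is None]
        if missing:
            dropped[e.study_id] = f"missing moderator(s): {', '.join(missing)}"
            continue
        rows.append(e)

    pruned: dict[str, list[str]] = {}
    # level census for categorical moderators, then prune sparse levels
    level_keep: dict[str, list[str]] = {}
    for mod in spec.categorical:
        counts: dict[str, int] = {}
        for e in rows:
            counts[_value(e, mod)] = counts.get(_value(e, mod), 0) + 1
        keep = sorted(lv for lv, c in counts.items() if c >= min_level_count)
        pruned[mod] = sorted(lv for lv in counts if lv not in keep)
        level_keep[mod] = keep
    if any(pruned.values()):
        keep_rows = []
        for e in rows:
            bad = [m for m in spec.categorical
                   if _value(e, m) not in level_keep[m]]
            if bad:
                dropped[e.study_id] = (
                    "pruned level of " + ", ".join(bad))
            else:
                keep_rows.append(e)
        rows = keep_rows

    cols: list[np.ndarray] = []
    names: list[str] = []
    blocks: dict[str, list[int]] = {}
    if spec.intercept:
        cols.append(np.ones(len(rows)))
        names.append("intercept")
    for mod in spec.continuous:
        blocks[mod] = [len(cols)]
        cols.append(np.array([float(_value(e, mod)) for e in rows]))
        names.append(mod)
    for mod, ref in spec.categorical.items():
        levels = level_keep[mod]
        if ref in levels:
            nonref = [lv for lv in levels if lv != ref]
        else:
            nonref = levels[1:]  # first remaining level becomes the reference
        blocks[mod] = []
        for lv in nonref:
            blocks[mod].append(len(cols))
            cols.append(np.array([1.0 if _value(e, mod) == lv else 0.0
                                  for e in rows]))
            names.append(f"{mod}[{lv}]")
        if not nonref:
            blocks[mod] = []  # single level: no columns, moderator inert
    X = np.column_stack(cols) if cols else np.empty((len(rows), 0))
    k, p = X.shape
    if k < p + 2:
        raise UnderDeterminedError(
            f"{k} usable studies for {p} coefficients")
    if p and np.linalg.matrix_rank(X) < p:
        raise UnderDeterminedError("design matrix is rank deficient")
    L = np.array([e.L for e in rows])
    v = np.array([e.v for e in rows])
    return Design(L=L, v=v, X=X, names=names, blocks=blocks,
                  used=[e.study_id for e in rows], dropped=dropped,
                  pruned_levels=pruned)


# ---------------------------------------------------------------------------
# tau^2 estimation


def _projection(v: np.ndarray, X: np.ndarray, tau2: float) -> np.ndarray:
    w = 1.0 / (v + tau2)
    W = np.diag(w)
    WX = w[:, None] * X
    XtWX_inv = np.linalg.inv(X.T @ WX)
    return W - WX @ XtWX_inv @ WX.T


def restricted_loglik(tau2: float, L: np.ndarray, v: np.ndarray,
                      X: np.ndarray) -> float:
    """Restricted log-likelihood of the mixed meta-regression at tau2."""
    w = 1.0 / (v + tau2)
    WX = w[:, None] * X
    XtWX = X.T @ WX
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    P = _projection(v, X, tau2)
    return -0.5 * (np.sum(np.log(v + tau2)) + logdet + float(L @ P @ L))


def dersimonian_laird_tau2(L: np.ndarray, v: np.ndarray,
                           X: np.ndarray) -> float:
    """Method-of-moments (DerSimonian–Laird) heterogeneity estimate."""
    w = 1.0 / v
    WX = w[:, None] * X
    XtWX_inv = np.linalg.inv(X.T @ WX)
    H = X @ XtWX_inv @ WX.T
    resid = L - H @ L
    Q = float(np.sum(w * resid ** 2))
    k, p = X.shape
    trW = np.sum(w)
    trHW = float(np.trace(XtWX_inv @ (X.T @ (w[:, None] ** 2 * X))))
    denom = trW - trHW
    if denom <= 0:
        return 0.0
    return max(0.0, (Q - (k - p)) / denom)


def reml_tau2(L: np.ndarray, v: np.ndarray, X: np.ndarray,
              tol: float = 1e-8, max_iter: int = 100) -> float:
    """REML estimate of tau^2 by Fisher scoring, projected to tau^2 >= 0.

    The score is  -0.5 tr(P) + 0.5 LᵀP²L  and the expected information
    0.5 tr(P²), with P the REML projection at the current tau^2.  Iteration
    starts from the DerSimonian–Laird value and stops when the step falls
    below ``tol``; a boundary solution at 0 with non-positive score is a
    valid convergence point.
    """
    L = np.asarray(L, float)
    v = np.asarray(v, float)
    X = np.asarray(X, float)
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")
    tau2 = dersimonian_laird_tau2(L, v, X)
    trace = [tau2]
    for _ in range(max_iter):
        P = _projection(v, X, tau2)
        PL = P @ L
        score = -0.5 * float(np.trace(P)) + 0.5 * float(PL @ PL)
        info = 0.5 * float(np.trace(P @ P))
        if tau2 == 0.0 and score <= 0.0:
            return 0.0
        step = score / info
        new = max(0.0, tau2 + step)
        trace.append(new)
        if abs(new - tau2) < tol * (1.0 + tau2):
            return new
        tau2 = new
    raise ConvergenceError(
        f"REML did not converge in {max_iter} iterations", trace)


# ---------------------------------------------------------------------------
# model / results


@dataclass
class MetaRegressionResults:
    """Weighted least-squares fit of the random-effects meta-regression."""
    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    cov_params: np.ndarray
    tau2: float
    k: int
    qm: float
    qm_df: int
    qm_pvalue: float
    loglike_reml: float
    converged: bool
    blocks: dict[str, list[int]]
    dropped: dict[str, str]
    inference: str = "z"

    def block_test(self, moderator: str) -> tuple[float, int, float]:
        """Omnibus Wald chi-square for one moderator's coefficient block."""
        idx = self.blocks.get(moderator)
        if not idx:
            raise KeyError(f"moderator {moderator!r} has no columns in fit")
        b = self.params[idx]
        C = self.cov_params[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(C, b))
        df = len(idx)
        return stat, df, float(stats.chi2.sf(stat, df))

    def moderator_pvalues(self) -> dict[str, float]:
        """Block omnibus p per moderator (equals the Wald p for 1-df blocks)."""
        return {m: self.block_test(m)[2] for m, idx in self.blocks.items()
                if idx}

    def summary(self) -> str:
        lines = [
            f"Random-effects meta-regression  (k={self.k}, "
            f"tau^2={self.tau2:.5f}, REML logLik={self.loglike_reml:.3f})",
            f"Omnibus moderator test: QM={self.qm:.3f} "
            f"(df={self.qm_df}), p={self.qm_pvalue:.4g}",
            f"{'coef':<34}{'estimate':>10}{'se':>10}"
            f"{'z':>8}{'p':>10}",
        ]
        for i, name in enumerate(self.names):
            lines.append(f"{name:<34}{self.params[i]:>10.4f}"
                         f"{self.bse[i]:>10.4f}{self.zvalues[i]:>8.2f}"
                         f"{self.pvalues[i]:>10.4g}")
        return "\n".join(lines)


class MetaRegression:
    """Mixed-model meta-regression  L ~ N(Xβ, diag(v) + τ²I).

    Construct from arrays or via :meth:`from_estimates` with a
    :class:`DesignSpec`; ``fit`` estimates τ² (REML by default), then β by
    weighted least squares with weights 1/(v_i + τ̂²).
    """

    def __init__(self, L: np.ndarray, v: np.ndarray, X: np.ndarray,
                 names: Optional[list[str]] = None,
                 blocks: Optional[dict[str, list[int]]] = None,
                 dropped: Optional[dict[str, str]] = None):
        self.L = np.asarray(L, float)
        self.v = np.asarray(v, float)
        self.X = np.asarray(X, float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        p = self.X.shape[1]
        self.names = names if names is not None else [f"x{j}" for j in range(p)]
        if blocks is None:
            blocks = {n: [j] for j, n in enumerate(self.names)
                      if n != "intercept"}
        self.blocks = blocks
        self.dropped = dropped or {}

    @classmethod
    def from_estimates(cls, estimates: Sequence[EffectEstimate],
                       spec: Optional[DesignSpec] = None,
                       min_level_count: int = 1) -> "MetaRegression":
        spec = spec if spec is not None else DesignSpec()
        d = build_design(estimates, spec, min_level_count=min_level_count)
        return cls(d.L, d.v, d.X, names=d.names, blocks=d.blocks,
                   dropped=d.dropped)

    def fit(self, method: str = "reml", tau2: Optional[float] = None,
            inference: str = "z") -> MetaRegressionResults:
        L, v, X = self.L, self.v, self.X
        k, p = X.shape
        converged = True
        if tau2 is None:
            if method == "reml":
                tau2 = reml_tau2(L, v, X)
            elif method == "dl":
                tau2 = dersimonian_laird_tau2(L, v, X)
            else:
                raise ValueError(f"unknown tau^2 estimator {method!r}")
        w = 1.0 / (v + tau2)
        WX = w[:, None] * X
        XtWX = X.T @ WX
        cond = np.linalg.cond(XtWX)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"singular normal matrix (columns: {self.names})")
        cov = np.linalg.inv(XtWX)
        beta = cov @ (WX.T @ L)
        resid = L - X @ beta
        if inference == "knha":
            s2 = float(np.sum(w * resid ** 2)) / (k - p)
            cov = cov * s2
            bse = np.sqrt(np.diag(cov))
            tvals = beta / bse
            pvals = 2.0 * stats.t.sf(np.abs(tvals), df=k - p)
        elif inference == "z":
            bse = np.sqrt(np.diag(cov))
            tvals = beta / bse
            pvals = 2.0 * stats.norm.sf(np.abs(tvals))
        else:
            raise ValueError(f"unknown inference variant {inference!r}")
        # omnibus over all non-intercept coefficients
        mod_idx = [j for j, n in enumerate(self.names) if n != "intercept"]
        if mod_idx:
            bm = beta[mod_idx]
            Cm = cov[np.ix_(mod_idx, mod_idx)]
            qm = float(bm @ np.linalg.solve(Cm, bm))
            qm_df = len(mod_idx)
            if inference == "knha":
                qm_p = float(stats.f.sf(qm / qm_df, qm_df, k - p))
            else:
                qm_p = float(stats.chi2.sf(qm, qm_df))
        else:
            qm, qm_df, qm_p = 0.0, 0, 1.0
        return MetaRegressionResults(
            names=list(self.names), params=beta, bse=bse, zvalues=tvals,
            pvalues=pvals, cov_params=cov, tau2=tau2, k=k,
            qm=qm, qm_df=qm_df, qm_pvalue=qm_p,
            loglike_reml=restricted_loglik(tau2, L, v, X),
            converged=converged, blocks=dict(self.blocks),
            dropped=dict(self.dropped), inference=inference)


# ---------------------------------------------------------------------------
# model selection


@dataclass
class EliminationRound:
    round: int
    removed: str
    pvalue: float
    remaining: list[str]


def minimal_adequate_model(estimates: Sequence[EffectEstimate],
                           spec: Optional[DesignSpec] = None,
                           alpha: float = 0.05,
                           min_studies: int = MIN_STUDIES_METAREG,
                           method: str = "reml", inference: str = "z"
                           ) -> tuple[MetaRegressionResults,
                                      list[EliminationRound]]:
    """Backward elimination to the minimal adequate meta-regression.

    Starting from the full moderator set, each round removes the single
    moderator with the largest p-value exceeding ``alpha`` (categorical
    moderators judged and removed as whole blocks) and refits, until every
    remaining moderator is significant or none remain.  p-value ties are
    broken by removing the later-listed moderator.
    """
    spec = spec if spec is not None else DesignSpec()
    usable = [e for e in estimates if e.v is not None]
    if len(usable) < min_studies:
        raise ValueError(
            f"{len(usable)} usable studies; moderator analysis requires "
            f">= {min_studies}")
    trace: list[EliminationRound] = []
    current = spec
    rnd = 0
    while True:
        fit = MetaRegression.from_estimates(estimates, current).fit(
            method=method, inference=inference)
        pvals = {m: fit.block_test(m)[2]
                 for m, idx in fit.blocks.items() if idx}
        offenders = {m: p for m, p in pvals.items() if p > alpha}
        if not offenders:
            return fit, trace
        worst_p = max(offenders.values())
        # later-listed moderator wins ties
        order = current.moderators()
        worst = max((m for m, p in offenders.items() if p == worst_p),
                    key=order.index)
        rnd += 1
        current = current.drop(worst)
        trace.append(EliminationRound(
            round=rnd, removed=worst, pvalue=worst_p,
            remaining=current.moderators()))
        if not current.moderators():
            final = MetaRegression.from_estimates(estimates, current).fit(
                method=method, inference=inference)
            return final, trace


def single_factor_analysis(estimates: Sequence[EffectEstimate],
                           grouping: str,
                           min_species: int = MIN_SPECIES_GROUPING,
                           min_level_count: int = 2,
                           method: str = "reml", inference: str = "z"
                           ) -> MetaRegressionResults:
    """Meta-regression of L on a single plant-grouping factor.

    Used for the plant groupings (evolutionary history, growth habit,
    growth duration, end use) one at a time, since several groupings jointly
    would introduce redundant dummies.  Levels carried by fewer than
    ``min_level_count`` studies are pruned; the species gate requires more
    than ``min_species - 1`` distinct species.
    """
    usable = [e for e in estimates
              if e.v is not None and _value(e, grouping) is not None]
    n_species = len({e.species.strip().casefold() for e in usable})
    if n_species < min_species:
        raise ValueError(
            f"{n_species} species; grouping analysis requires >= {min_species}")
    levels = {_value(e, grouping) for e in usable}
    if len(levels) < 2:
        raise ValueError(f"factor {grouping!r} has one level")
    spec = DesignSpec(continuous=(), categorical={grouping: ""})
    model = MetaRegression.from_estimates(usable, spec,
                                          min_level_count=min_level_count)
    if not model.blocks.get(grouping):
        raise ValueError(
            f"factor {grouping!r} has one level after pruning sparse levels")
    return model.fit(method=method, inference=inference)
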