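"""SNP-heritability from unrelated individuals.

GRM construction with the centered-and-scaled estimator, greedy relatedness
pruning, single-component REML (EM warm start + average-information updates
on the eigenbasis of the GRM), and the boundary likelihood-ratio test.

The restricted log-likelihood convention used throughout (and by the
grid-search oracle in the test-suite) is

    logL = -1/2 [ (N - p) log 2*pi + log|V| + log|X' V^-1 X| + y' P y ]

with V = vg * A + ve * I and P the usual REML projection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genio import GenotypeMatrix

logger = logging.getLogger(__name__)


class GremlError(ValueError):
    pass


@dataclass
class Grm:
    """Symmetric genomic-relatedness matrix over retained samples."""

    sample_id: list[str]
    A: np.ndarray
    n_snps: int

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.sample_id)
        if self.A.shape != (n, n):
            raise GremlError("GRM shape does not match sample ids")

    @property
    def n(self) -> int:
        return len(self.sample_id)


@dataclass
class RemlResult:
    """Variance components and the boundary LRT (one genetic component)."""

    vg: float
    ve: float
    vp: float
    h2: float
    se_h2: float
    logL: float
    logL0: float
    lrt: float
    p_value: float
    n_iterations: int
    converged: bool
    n: int
    se_vg: float = np.nan
    se_ve: float = np.nan


def compute_grm(genotypes: GenotypeMatrix) -> Grm:
    """Centered-scaled relatedness estimates.

    Off-diagonal:  A_jk = (1/M) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2p_i(1-p_i))
    Diagonal:      A_jj = 1 + (1/M) sum_i (x_ij^2 - (1+2p_i)x_ij + 2p_i^2)
                                           / (2p_i(1-p_i))
    """
    if genotypes.n < 2 or genotypes.m < 1:
        raise GremlError("need at least 2 samples and 1 SNP")
    p = genotypes.ensure_freq()
    if np.any(p <= 0) or np.any(p >= 1):
        bad = [genotypes.panel.snp_id[i]
               for i in np.flatnonzero((p <= 0) | (p >= 1))[:5]]
        raise GremlError(f"monomorphic SNPs reached the GRM stage: {bad}")
    x = genotypes.imputed_dosage()
    m = genotypes.m
    denom = 2.0 * p * (1.0 - p)
    z = (x - 2.0 * p) / np.sqrt(denom)
    A = (z @ z.T) / m
    diag = 1.0 + np.sum((x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom, axis=1) / m
    np.fill_diagonal(A, diag)
    return Grm(sample_id=list(genotypes.sample_id), A=A, n_snps=m)


def filter_relatedness(
    grm: Grm, cutoff: float = 0.025
) -> tuple[Grm, list[str]]:
    """Greedy pruning until no off-diagonal entry is >= cutoff.

    While any violating pair exists, the individual participating in the most
    violating pairs is dropped (ties broken toward the lexicographically
    smaller id).  Returns the reduced GRM and the drop list.
    """
    if cutoff <= 0:
        raise GremlError("cutoff must be positive")
    n = grm.n
    viol = grm.A >= cutoff
    np.fill_diagonal(viol, False)
    keep = np.ones(n, dtype=bool)
    ids = np.asarray(grm.sample_id, dtype=object)
    order = np.argsort(ids)  # lexicographic tie-break: smaller id drops first
    dropped: list[str] = []
    while True:
        deg = (viol[:, keep].sum(axis=1)) * keep
        mx = deg.max()
        if mx == 0:
            break
        cand = np.flatnonzero(deg == mx)
        drop = min(cand, key=lambda i: str(ids[i]))
        keep[drop] = False
        dropped.append(str(ids[drop]))
    if not keep.any():
        raise GremlError("relatedness filter dropped every individual")
    kept_idx = np.flatnonzero(keep)
    out = Grm(
        sample_id=[grm.sample_id[i] for i in kept_idx],
        A=grm.A[np.ix_(kept_idx, kept_idx)],
        n_snps=grm.n_snps,
    )
    return out, dropped


@dataclass
class RemlOptions:
    max_iter: int = 100
    tol: float = 1e-8
    n_em: int = 3  # EM warm-start iterations before AI updates


def _rotated_quantities(vg, ve, d, Xs, ys):
    """Everything REML needs, on the eigenbasis where V is diagonal."""
    v = vg * d + ve
    if np.any(v <= 0):
        return None
    Wx = Xs / v[:, None]
    B = Xs.T @ Wx
    try:
        cB = np.linalg.cholesky(B)
    except np.linalg.LinAlgError:
        return None
    b = Wx.T @ ys
    beta = np.linalg.solve(B, b)
    r = ys - Xs @ beta
    u = r / v  # u = P y
    yPy = float(ys @ u)
    logdetV = float(np.sum(np.log(v)))
    logdetB = float(2.0 * np.sum(np.log(np.diag(cB))))
    n, p = Xs.shape
    logL = -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetB + yPy)
    return {"v": v, "B": B, "u": u, "yPy": yPy, "logL": logL, "Wx": Wx}


def _P_apply(w, v, Xs, B):
    """P w  =  V^-1 w - V^-1 X (X'V^-1 X)^-1 X' V^-1 w  (rotated basis)."""
    Ww = w / v
    return Ww - (Xs / v[:, None]) @ np.linalg.solve(B, Xs.T @ Ww)


def _trace_PA(v, Xs, B, d):
    """tr(P diag(d)) without forming P."""
    Wx = Xs / v[:, None]
    C = Xs.T @ (Wx * (d / v)[:, None])
    return float(np.sum(d / v) - np.trace(np.linalg.solve(B, C)))


def reml_fit(
    y: np.ndarray,
    X: np.ndarray | None,
    grm: Grm,
    options: RemlOptions | None = None,
) -> RemlResult:
    """Single-component REML of y = X b + g + e, g ~ (0, A vg), e ~ (0, I ve).

    EM warm start, then average-information updates with step halving; vg is
    clamped at zero (active set) when updates push it negative.  The null
    (vg = 0) restricted likelihood has the OLS closed form; the LRT p-value
    uses the 50:50 boundary mixture.
    """
    opts = options or RemlOptions()
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n != grm.n:
        raise GremlError("phenotype length does not match GRM")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise GremlError("fixed-effect design is rank deficient")
    if n < 30:
        warnings.warn(f"REML with N={n} < 30 is unreliable", stacklevel=2)

    d, U = np.linalg.eigh(grm.A)
    Xs = U.T @ X
    ys = U.T @ y

    # null model: V = ve I; REML closed form
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta0) ** 2))
    ve0 = rss / (n - p)
    sign, logdetXX = np.linalg.slogdet(X.T @ X)
    logL0 = -0.5 * ((n - p) * (np.log(2 * np.pi) + np.log(ve0) + 1.0) + logdetXX)

    vp0 = float(np.var(y, ddof=1))
    vg, ve = 0.5 * vp0, 0.5 * vp0
    floor = 1e-10 * vp0
    q = _rotated_quantities(vg, ve, d, Xs, ys)
    logL = q["logL"]
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        u, v, B = q["u"], q["v"], q["B"]
        Du = d * u
        dL_g = -0.5 * (_trace_PA(v, Xs, B, d) - float(u @ Du))
        dL_e = -0.5 * (_trace_PA(v, Xs, B, np.ones(n)) - float(u @ u))
        grad = np.array([dL_g, dL_e])

        em_step = np.array(
            [
                vg**2 * (float(u @ Du) - _trace_PA(v, Xs, B, d)) / n,
                ve**2 * (float(u @ u) - _trace_PA(v, Xs, B, np.ones(n))) / n,
            ]
        )
        if it <= opts.n_em:
            step = em_step
        else:
            PDu = _P_apply(Du, v, Xs, B)
            Pu = _P_apply(u, v, Xs, B)
            AI = 0.5 * np.array(
                [
                    [float(Du @ PDu), float(Du @ Pu)],
                    [float(u @ PDu), float(u @ Pu)],
                ]
            )
            try:
                step = np.linalg.solve(AI, grad)
            except np.linalg.LinAlgError:
                step = em_step

        accepted = False
        for attempt in range(30):  # step halving; fall back to EM once stuck
            cand_vg = max(vg + step[0], 0.0)  # active-set clamp at the boundary
            cand_ve = max(ve + step[1], floor)
            qc = _rotated_quantities(cand_vg, cand_ve, d, Xs, ys)
            if qc is not None and (qc["logL"] >= logL - 1e-10 or it <= opts.n_em):
                accepted = True
                break
            if attempt == 15 and not np.array_equal(step, em_step):
                step = em_step.copy()  # AI direction failed; try EM
            else:
                step = step / 2.0
        if not accepted:
            break
        delta = qc["logL"] - logL
        vg, ve, q, logL = max(cand_vg, 0.0), cand_ve, qc, qc["logL"]
        if abs(delta) < opts.tol and it > opts.n_em:
            converged = True
            break

    # the null (vg = 0) is inside the parameter space: if the iterate ended
    # below it, the optimum sits on the boundary
    if logL < logL0:
        vg, ve = 0.0, ve0
        q = _rotated_quantities(vg, ve, d, Xs, ys)
        logL = q["logL"]
        converged = True
    if not converged:
        logger.warning("REML did not converge in %d iterations", it)

    # SEs from the inverse AI matrix at the optimum; delta method for h2
    u, v, B = q["u"], q["v"], q["B"]
    Du = d * u
    PDu = _P_apply(Du, v, Xs, B)
    Pu = _P_apply(u, v, Xs, B)
    AI = 0.5 * np.array(
        [[float(Du @ PDu), float(Du @ Pu)], [float(u @ PDu), float(u @ Pu)]]
    )
    vp = vg + ve
    try:
        cov = np.linalg.inv(AI)
        se_vg, se_ve = np.sqrt(np.maximum(np.diag(cov), 0.0))
        gradient = np.array([ve, -vg]) / vp**2
        se_h2 = float(np.sqrt(max(gradient @ cov @ gradient, 0.0)))
    except np.linalg.LinAlgError:
        se_vg = se_ve = se_h2 = np.nan

    lrt = 2.0 * (logL - logL0)
    if lrt < -1e-6:
        logger.warning("LRT %.3g below zero beyond slack; clamping", lrt)
    lrt = max(lrt, 0.0)
    return RemlResult(
        vg=vg,
        ve=ve,
        vp=vp,
        h2=vg / vp,
        se_h2=se_h2,
        logL=logL,
        logL0=logL0,
        lrt=lrt,
        p_value=lrt_boundary_pvalue(lrt),
        n_iterations=it,
        converged=converged,
        n=n,
        se_vg=se_vg,
        se_ve=se_ve,
    )


def lrt_boundary_pvalue(lrt: float) -> float:
    """p = 0.5 * Pr(chi2_1 >= lrt): the 50:50 point-mass/chi-square mixture
    for a single variance component tested on its boundary."""
    if lrt < -1e-6:
        raise GremlError(f"negative LRT statistic: {lrt}")
    lrt = max(lrt, 0.0)
    return float(0.5 * stats.chi2.sf(lrt, df=1))
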