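"""Genetic share of the parent-child education association.

The headline statistic converts the attenuation of the parental-education
coefficient (when the offspring's polygenic score is added as a control)
into the share of the intergenerational association attributable to genes:

    share% = attenuation% * (h2 / R2_score) * relatedness

The h2 / R2_score factor de-attenuates the noisy score up to the assumed
true heritability; relatedness (default 0.5 for parent-child pairs) scales
for shared genes.  Both published groupings of the multiplier - a single
combined "scaling factor", or heritability factor times relatedness - are
views of this one computation.

The coefficient-difference ("Hausman-style") test is a cluster bootstrap:
the classical Hausman variance formula is invalid here because neither
estimator is efficient, so families are resampled with replacement and the
difference is referred to its bootstrap standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grm_greml import RemlResult
from .regress import ModelFit, ModelSpec, fit_ols_clustered


class MediationError(ValueError):
    pass


@dataclass
class MediationResult:
    beta_raw: float  # parental-education coefficient, score not controlled
    beta_adj: float  # same, offspring score controlled
    attenuation_pct: float
    r2_score: float  # score-alone R^2
    h2: float
    relatedness: float
    scale_factor: float  # h2 / r2_score
    genetic_share_pct: float
    diff_test_stat: float | None = None
    diff_test_p: float | None = None
    fit_raw: ModelFit | None = None
    fit_adj: ModelFit | None = None

    def combined_multiplier(self) -> float:
        return self.scale_factor * self.relatedness


def attenuation(beta_raw: float, beta_adj: float) -> float:
    """100 * (beta_raw - beta_adj) / beta_raw; negative means it grew."""
    if beta_raw == 0:
        raise MediationError("beta_raw is zero; attenuation undefined")
    return 100.0 * (beta_raw - beta_adj) / beta_raw


def genetic_share(
    attenuation_pct: float,
    h2: float,
    r2_score: float,
    relatedness: float = 0.5,
) -> float:
    """attenuation% * (h2 / r2_score) * relatedness, in percent."""
    if not (0 < r2_score <= h2 <= 1):
        raise MediationError(
            f"need 0 < r2_score <= h2 <= 1, got r2_score={r2_score}, h2={h2}: "
            "a scaling factor below 1 is inconsistent with the model"
        )
    if not (0 < relatedness <= 1):
        raise MediationError("relatedness must lie in (0, 1]")
    return attenuation_pct * (h2 / r2_score) * relatedness


def coefficient_difference_test(
    data: pd.DataFrame,
    spec_raw: ModelSpec,
    spec_adj: ModelSpec,
    term: str,
    n_boot: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Cluster bootstrap of Delta = beta_raw(term) - beta_adj(term).

    Families are resampled with replacement; stat = Delta / SE_boot with a
    normal reference.  Point estimates come from the full sample.
    """
    for s in (spec_raw, spec_adj):
        if term not in s.terms:
            raise MediationError(f"term {term!r} missing from spec {s.name or s.terms}")
    if spec_raw.outcome != spec_adj.outcome or spec_raw.cluster != spec_adj.cluster:
        raise MediationError("specs must share outcome and cluster variable")
    need = sorted(spec_raw.columns_needed() | spec_adj.columns_needed())
    df = data.dropna(subset=[c for c in need if c in data.columns])
    df = df.reset_index(drop=True)

    from .regress import build_design

    X_raw, y, _ = build_design(df, spec_raw)
    X_adj, y_adj, clusters = build_design(df, spec_adj)
    if not y.index.equals(y_adj.index):
        raise MediationError("specs must resolve to the same sample")
    Xr, Xa = X_raw.to_numpy(float), X_adj.to_numpy(float)
    yv = y.to_numpy(float)
    jr = list(X_raw.columns).index(term)
    ja = list(X_adj.columns).index(term)

    def delta_for(rows: np.ndarray) -> float:
        br = np.linalg.lstsq(Xr[rows], yv[rows], rcond=None)[0][jr]
        ba = np.linalg.lstsq(Xa[rows], yv[rows], rcond=None)[0][ja]
        return float(br - ba)

    all_rows = np.arange(len(yv))
    delta = delta_for(all_rows)

    fam_rows: dict = {}
    for i, f in enumerate(clusters.to_numpy()):
        fam_rows.setdefault(f, []).append(i)
    blocks = [np.asarray(fam_rows[f]) for f in sorted(fam_rows, key=str)]
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        draw = rng.integers(0, len(blocks), size=len(blocks))
        rows = np.concatenate([blocks[i] for i in draw])
        try:
            deltas[b] = delta_for(rows)
        except np.linalg.LinAlgError:
            deltas[b] = np.nan
    se = float(np.nanstd(deltas, ddof=1))
    if se == 0:
        return 0.0, 1.0
    from scipy import stats

    stat = delta / se
    p = float(2 * stats.norm.sf(abs(stat)))
    return stat, p


def end_to_end_mediation(
    data: pd.DataFrame,
    h2_source: float | RemlResult,
    relatedness: float = 0.5,
    parent_term: str = "mother_edu",
    score_term: str = "score",
    covariates: list[str] | None = None,
    n_boot: int = 0,
    seed: int = 0,
) -> MediationResult:
    """Fit raw and score-adjusted models, then scale the attenuation.

    ``data`` is a child-level analysis frame (see
    :func:`polytrans.frames.cohort_frame`).  ``h2_source`` is either an
    assumed heritability or a fitted :class:`RemlResult`.
    """
    h2 = h2_source.h2 if isinstance(h2_source, RemlResult) else float(h2_source)
    if covariates is None:
        covariates = [c for c in ("female", "age", "survey_year")
                      if c in data.columns]
    spec_raw = ModelSpec("edu_years", covariates + [parent_term], name="raw")
    spec_adj = ModelSpec(
        "edu_years", covariates + [parent_term, score_term],
        score_term=score_term, name="adjusted",
    )
    fit_raw = fit_ols_clustered(data, spec_raw)
    fit_adj = fit_ols_clustered(data, spec_adj)
    beta_raw = float(fit_raw.params[parent_term])
    beta_adj = float(fit_adj.params[parent_term])
    att = attenuation(beta_raw, beta_adj)
    r2_score = float(fit_adj.r2_score_alone)
    share = genetic_share(att, h2, r2_score, relatedness)

    stat = p = None
    if n_boot > 0:
        stat, p = coefficient_difference_test(
            data, spec_raw, spec_adj, parent_term, n_boot=n_boot, seed=seed
        )
    return MediationResult(
        beta_raw=beta_raw,
        beta_adj=beta_adj,
        attenuation_pct=att,
        r2_score=r2_score,
        h2=h2,
        relatedness=relatedness,
        scale_factor=h2 / r2_score,
        genetic_share_pct=share,
        diff_test_stat=stat,
        diff_test_p=p,
        fit_raw=fit_raw,
        fit_adj=fit_adj,
    )
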