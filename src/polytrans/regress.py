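"""OLS model suites with family-cluster-robust standard errors.

Point estimates are ordinary least squares; the covariance is the CR1
cluster sandwich

    c * (X'X)^-1 [ sum_g X_g' u_g u_g' X_g ] (X'X)^-1,
    c = G/(G-1) * (N-1)/(N-K),

the common statistical-package default.  Interaction terms are written
``a:b`` and are formed as elementwise products of (already constructed)
columns; interaction models include all constituent main effects unless the
spec explicitly omits them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class RegressionError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Declarative model: outcome, additive/product terms, cluster variable."""

    outcome: str
    terms: list[str]
    cluster: str = "family_id"
    sample_filter: str | None = None  # pandas query string
    add_intercept: bool = True
    score_term: str | None = None  # term whose score-alone R^2 is reported
    name: str = ""

    def columns_needed(self) -> set[str]:
        cols = {self.outcome, self.cluster}
        for t in self.terms:
            cols.update(t.split(":"))
        return cols


@dataclass
class ModelFit:
    """Coefficients, cluster-robust SEs and fit statistics."""

    params: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    r2: float
    r2_score_alone: float | None
    n_obs: int
    n_clusters: int
    spec: ModelSpec

    def tvalues(self) -> pd.Series:
        return self.params / self.se

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.se,
                             "t": self.tvalues()})


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Materialize the design matrix, outcome and cluster ids.

    Listwise deletion on the model variables; product terms are formed after
    deletion so both routes see the same sample.
    """
    need = spec.columns_needed()
    missing = need - set(data.columns)
    if missing:
        raise RegressionError(f"terms reference absent columns: {sorted(missing)}")
    df = data.query(spec.sample_filter) if spec.sample_filter else data
    df = df.dropna(subset=sorted(need))
    cols = {}
    for t in spec.terms:
        parts = t.split(":")
        col = df[parts[0]].to_numpy(float).copy()
        for q in parts[1:]:
            col = col * df[q].to_numpy(float)
        cols[t] = col
    X = pd.DataFrame(cols, index=df.index)
    if spec.add_intercept:
        X.insert(0, "const", 1.0)
    return X, df[spec.outcome].astype(float), df[spec.cluster]


def fit_ols_clustered(
    data: pd.DataFrame, spec: ModelSpec, cov_type: str = "CR1"
) -> ModelFit:
    """OLS with the CR1 (default) or CR0 cluster sandwich covariance."""
    X, y, clusters = build_design(data, spec)
    n, k = X.shape
    if n < k:
        raise RegressionError(f"n={n} observations for k={k} parameters")
    Xm = X.to_numpy(float)
    rank = np.linalg.matrix_rank(Xm)
    if rank < k:
        # name the collinear terms via incremental rank
        collinear, cum = [], []
        for j, name in enumerate(X.columns):
            cum.append(j)
            if np.linalg.matrix_rank(Xm[:, cum]) < len(cum):
                collinear.append(name)
                cum.pop()
        raise RegressionError(f"singular design; collinear terms: {collinear}")
    groups = clusters.to_numpy()
    uniq = pd.unique(groups)
    G = len(uniq)
    if G < 2:
        raise RegressionError("cluster-robust covariance needs >= 2 clusters")

    XtX = Xm.T @ Xm
    beta = np.linalg.solve(XtX, Xm.T @ y.to_numpy(float))
    resid = y.to_numpy(float) - Xm @ beta
    # meat: sum over clusters of (X_g' u_g)(X_g' u_g)'
    scores = Xm * resid[:, None]
    score_by_g = (
        pd.DataFrame(scores, index=pd.Index(groups, name="g"))
        .groupby("g", sort=False)
        .sum()
        .to_numpy()
    )
    meat = score_by_g.T @ score_by_g
    bread = np.linalg.inv(XtX)
    if cov_type == "CR1":
        c = (G / (G - 1)) * ((n - 1) / (n - k)) if n > k else np.nan
    elif cov_type == "CR0":
        c = 1.0
    else:
        raise RegressionError(f"unknown cov_type {cov_type!r}")
    cov = c * bread @ meat @ bread

    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum(resid**2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan

    r2_alone = None
    if spec.score_term is not None and spec.score_term in X.columns:
        xs = X[spec.score_term].to_numpy(float)
        Z = np.column_stack([np.ones(n), xs])
        b = np.linalg.lstsq(Z, y.to_numpy(float), rcond=None)[0]
        r2_alone = 1.0 - float(np.sum((y.to_numpy(float) - Z @ b) ** 2)) / tss

    names = list(X.columns)
    return ModelFit(
        params=pd.Series(beta, index=names),
        se=pd.Series(np.sqrt(np.diag(cov)), index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        r2=r2,
        r2_score_alone=r2_alone,
        n_obs=n,
        n_clusters=G,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# fixed model catalogs

def _suite_specs(suite: str, columns: set[str],
                 omit_maternal_score_main: bool = False) -> list[ModelSpec]:
    """Model catalogs mirroring the published table layouts."""
    have_mom_score = "mother_score" in columns
    have_dad = "father_edu" in columns
    base = ["female", "age"] + (["survey_year"] if "survey_year" in columns else [])
    specs: list[ModelSpec] = []
    if suite == "table4":
        specs = [
            ModelSpec("edu_years", base + ["mother_edu"], name="m1_mother_edu"),
            ModelSpec("edu_years", base + ["score"], score_term="score",
                      name="m2_score"),
            ModelSpec("edu_years", base + ["mother_edu", "score"],
                      score_term="score", name="m3_both"),
        ]
        if have_mom_score:
            specs += [
                ModelSpec("edu_years", base + ["mother_score"],
                          score_term="mother_score", name="m4_mother_score"),
                ModelSpec("edu_years", base + ["mother_edu", "mother_score"],
                          name="m5_mother_edu_mother_score"),
                ModelSpec("edu_years",
                          base + ["mother_edu", "score", "mother_score"],
                          name="m6_all"),
            ]
    elif suite == "table5":
        specs = [
            ModelSpec("edu_years", base + ["mother_edu", "score"],
                      score_term="score", name="m1_base"),
            ModelSpec("edu_years",
                      base + ["mother_edu", "score", "score:mother_edu"],
                      name="m2_gxe"),
        ]
        if have_mom_score:
            gxg_terms = base + ["mother_edu", "score"]
            if not omit_maternal_score_main:
                gxg_terms = gxg_terms + ["mother_score"]
            specs.append(
                ModelSpec("edu_years", gxg_terms + ["score:mother_score"],
                          name="m3_gxg")
            )
    elif suite == "table7":
        if not have_dad:
            raise RegressionError("table7 suite needs father_edu")
        specs = [
            ModelSpec("edu_years", base + ["mother_edu", "father_edu"],
                      name="m1_both_parents"),
            ModelSpec(
                "edu_years",
                base + ["mother_edu", "father_edu", "score"]
                + (["mother_score", "father_score"]
                   if "father_score" in columns else []),
                score_term="score",
                name="m2_with_scores",
            ),
        ]
    else:
        raise RegressionError(f"unknown suite {suite!r}")
    return specs


def run_model_suite(
    data: pd.DataFrame, suite: str, omit_maternal_score_main: bool = False
) -> list[ModelFit]:
    """Fit the fixed catalog of specifications for one published table."""
    specs = _suite_specs(suite, set(data.columns), omit_maternal_score_main)
    return [fit_ols_clustered(data, s) for s in specs]


def render_table(fits: list[ModelFit]) -> str:
    """Publication-style text table: coefficient (SE) per model column."""
    terms: list[str] = []
    for f in fits:
        for t in f.params.index:
            if t not in terms:
                terms.append(t)
    width = max(len(t) for t in terms) + 2
    lines = ["".ljust(width) + "".join(f"({i + 1})".rjust(18) for i in range(len(fits)))]
    for t in terms:
        row = t.ljust(width)
        for f in fits:
            if t in f.params.index:
                row += f"{f.params[t]:9.3f} ({f.se[t]:.3f})".rjust(18)
            else:
                row += "".rjust(18)
        lines.append(row)
    lines.append("R2".ljust(width)
                 + "".join(f"{f.r2:9.3f}".rjust(18) for f in fits))
    lines.append(
        "R2 score alone".ljust(width)
        + "".join(
            (f"{f.r2_score_alone:9.3f}" if f.r2_score_alone is not None else "")
            .rjust(18)
            for f in fits
        )
    )
    lines.append("N".ljust(width) + "".join(f"{f.n_obs:9d}".rjust(18) for f in fits))
    lines.append("Families".ljust(width)
                 + "".join(f"{f.n_clusters:9d}".rjust(18) for f in fits))
    return "\n".join(lines)


def predict_interaction_advantage(
    fit: ModelFit,
    z_child: float,
    z_mother: float,
    score_term: str = "score",
    interaction_term: str = "score:mother_score",
) -> float:
    """Predicted schooling advantage (years) of a child at z_child SDs of the
    score with a mother at z_mother SDs, holding everything else fixed:

        beta_score * z_child + beta_interaction * z_child * z_mother
    """
    for t in (score_term, interaction_term):
        if t not in fit.params.index:
            raise RegressionError(f"fit lacks required term {t!r}")
    return float(
        fit.params[score_term] * z_child
        + fit.params[interaction_term] * z_child * z_mother
    )
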