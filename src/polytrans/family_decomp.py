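"""Within-family / between-family regression decomposition and sibling ICCs.

The within fit regresses the outcome on family-demeaned regressors (families
with one genotyped member contribute nothing to the slopes); the between fit
uses one row of unweighted family means per family; the total fit is pooled
OLS.  For a single regressor with no covariates the pooled slope decomposes
exactly as

    total = w * within + (1 - w) * between_weighted,
    w = within-x sum of squares / total-x sum of squares,

where ``between_weighted`` is the family-size-weighted means regression; the
(unweighted) reported between fit coincides with it for balanced families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regress import ModelFit, ModelSpec, RegressionError, fit_ols_clustered


class DecompositionError(ValueError):
    pass


@dataclass
class DecompResult:
    within: ModelFit
    between: ModelFit
    total: ModelFit
    between_weighted_slopes: pd.Series
    variance_shares: pd.DataFrame  # per regressor: within / between share of SS
    n_families: int
    n_sibling_pairs: int

    def decomposition_weight(self, term: str) -> float:
        return float(self.variance_shares.loc[term, "within_share"])


def within_between_decompose(data: pd.DataFrame, spec: ModelSpec) -> DecompResult:
    """Split the regression of ``spec`` into within/between/total components."""
    need = sorted(spec.columns_needed())
    df = data.dropna(subset=need).copy()
    fam = df[spec.cluster]
    sizes = fam.map(fam.value_counts())
    multi = df[sizes >= 2]
    if multi[spec.cluster].nunique() < 2:
        raise DecompositionError(
            "within component needs >= 2 families with >= 2 members"
        )

    terms = [t for t in spec.terms if ":" not in t]
    if len(terms) != len(spec.terms):
        raise DecompositionError("decomposition supports main effects only")

    # --- within: demean outcome and regressors inside each family
    demeaned = multi.copy()
    grp = multi.groupby(spec.cluster)
    for col in [spec.outcome] + terms:
        vals = multi[col].to_numpy(float)
        demeaned[col] = vals - grp[col].transform("mean").to_numpy(float)
    for col in terms:
        if np.allclose(demeaned[col].to_numpy(float), 0.0):
            raise DecompositionError(
                f"regressor {col!r} is constant within every family: "
                "within slope undefined"
            )
    within_spec = ModelSpec(
        spec.outcome, terms, cluster=spec.cluster, add_intercept=False,
        score_term=spec.score_term, name="within",
    )
    within = fit_ols_clustered(demeaned, within_spec)

    # --- between: unweighted family means, one row per family
    means = df.groupby(spec.cluster, as_index=False)[[spec.outcome] + terms].mean()
    means[spec.cluster] = means[spec.cluster].astype(str)
    between_spec = ModelSpec(
        spec.outcome, terms, cluster=spec.cluster,
        score_term=spec.score_term, name="between",
    )
    between = fit_ols_clustered(means, between_spec)

    # --- weighted between (used by the exact decomposition identity)
    fam_mean = grp_mean_matrix(df, spec.cluster, terms)
    y_mean = grp_mean_matrix(df, spec.cluster, [spec.outcome]).ravel()
    Zw = np.column_stack([np.ones(fam_mean.shape[0]), fam_mean])
    nw = df.groupby(spec.cluster).size().to_numpy(float)
    W = np.diag(nw)
    bw = np.linalg.solve(Zw.T @ W @ Zw, Zw.T @ W @ y_mean)
    between_weighted = pd.Series(bw[1:], index=terms)

    # --- total
    total_spec = ModelSpec(
        spec.outcome, terms, cluster=spec.cluster,
        score_term=spec.score_term, name="total",
    )
    total = fit_ols_clustered(df, total_spec)

    # --- variance shares
    shares = {}
    for col in terms:
        x = df[col].to_numpy(float)
        fm = df.groupby(spec.cluster)[col].transform("mean").to_numpy(float)
        ssw = float(np.sum((x - fm) ** 2))
        sst = float(np.sum((x - x.mean()) ** 2))
        shares[col] = {"within_share": ssw / sst if sst else np.nan,
                       "between_share": 1 - ssw / sst if sst else np.nan}
    counts = df.groupby(spec.cluster).size()
    return DecompResult(
        within=within,
        between=between,
        total=total,
        between_weighted_slopes=between_weighted,
        variance_shares=pd.DataFrame(shares).T,
        n_families=int(fam.nunique()),
        n_sibling_pairs=int((counts * (counts - 1) // 2).sum()),
    )


def grp_mean_matrix(df: pd.DataFrame, cluster: str, cols: list[str]) -> np.ndarray:
    return df.groupby(cluster)[cols].mean().to_numpy(float)


def intraclass_correlation(
    values, family_ids, method: str = "anova"
) -> float:
    """Sibling intraclass correlation.

    ``anova``: one-way ANOVA ICC(1), (MSB - MSW) / (MSB + (k0 - 1) MSW) with
    the unbalanced-design mean family size k0 = (N - sum n_g^2 / N)/(G - 1).
    ``pairwise``: Pearson correlation over all ordered within-family pairs.
    """
    s = pd.Series(np.asarray(values, dtype=float),
                  index=pd.Index(family_ids, name="family_id"))
    counts = s.groupby(level=0).size()
    multi = counts[counts >= 2]
    if len(multi) < 2:
        raise DecompositionError("ICC needs >= 2 families with >= 2 members")
    s = s[s.index.isin(multi.index)]
    if method == "pairwise":
        a, b = [], []
        for _, grp in s.groupby(level=0):
            v = grp.to_numpy()
            for i in range(len(v)):
                for j in range(len(v)):
                    if i != j:
                        a.append(v[i])
                        b.append(v[j])
        return float(np.corrcoef(a, b)[0, 1])
    if method != "anova":
        raise DecompositionError(f"unknown ICC method {method!r}")
    n = len(s)
    g = len(multi)
    grand = s.mean()
    grp_means = s.groupby(level=0).mean()
    grp_sizes = s.groupby(level=0).size()
    ssb = float((grp_sizes * (grp_means - grand) ** 2).sum())
    ssw = float(((s - grp_means.reindex(s.index)) ** 2).sum())
    msb = ssb / (g - 1)
    msw = ssw / (n - g)
    k0 = (n - float((grp_sizes**2).sum()) / n) / (g - 1)
    return float((msb - msw) / (msb + (k0 - 1) * msw))
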