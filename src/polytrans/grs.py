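"""Polygenic score construction and standardization.

A score is a weighted sum of effect-allele counts over the SNPs shared
between the genotype panel and the weight table.  Standardization uses the
sample standard deviation (n-1 denominator) over a reference set, by default
all scored persons; analyses that mix generations should standardize within
generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, WeightTable

logger = logging.getLogger(__name__)


class ScoreError(ValueError):
    pass


@dataclass
class ScoreVector:
    """Raw (years-of-schooling scale) and standardized scores per person."""

    table: pd.DataFrame  # person_id, raw_score, std_score (NaN until standardized)
    n_snps_used: int

    def raw(self) -> pd.Series:
        return self.table.set_index("person_id")["raw_score"]

    def std(self) -> pd.Series:
        return self.table.set_index("person_id")["std_score"]


def compute_score(
    genotypes: GenotypeMatrix, weights: WeightTable, allow_flip: bool = True
) -> ScoreVector:
    """raw_score_j = sum_i w_i x_ij over the shared SNPs.

    Weight-table rows whose effect allele differs from the genotype panel's
    counted allele are harmonized by flipping the dosage (x -> 2 - x), with a
    logged warning; pass ``allow_flip=False`` to make that a hard error.
    Missing dosages are mean-imputed at 2 p_i.
    """
    panel = genotypes.panel
    pos = {s: i for i, s in enumerate(panel.snp_id)}
    wt = weights.table
    shared = [s for s in wt["snp_id"] if s in pos]
    if not shared:
        raise ScoreError("no SNPs shared between weight table and genotype panel")
    cols = np.array([pos[s] for s in shared])
    w = wt.set_index("snp_id").loc[shared, "weight"].to_numpy(float)
    a1 = wt.set_index("snp_id").loc[shared, "effect_allele"].to_numpy()
    panel_allele = np.array([panel.effect_allele[c] for c in cols])

    flip = panel_allele != a1
    if flip.any():
        if not allow_flip:
            bad = [shared[i] for i in np.flatnonzero(flip)[:5]]
            raise ScoreError(f"allele-code mismatch at {bad}")
        logger.warning("flipping %d SNPs whose counted allele differs from "
                       "the weight table", int(flip.sum()))
    dosage = genotypes.imputed_dosage()[:, cols]
    # flip: count the weight table's allele -> dosage 2 - x
    raw = dosage @ w - 2.0 * (dosage[:, flip] @ w[flip]) + 2.0 * w[flip].sum()
    table = pd.DataFrame(
        {"person_id": genotypes.sample_id, "raw_score": raw, "std_score": np.nan}
    )
    return ScoreVector(table=table, n_snps_used=len(shared))


def standardize_score(
    score: ScoreVector, reference_ids: list[str] | None = None
) -> ScoreVector:
    """(x - mean) / SD with moments taken from the reference set.

    Default reference: all scored persons.  Sample SD (ddof=1).  Applying the
    function to an already standardized vector is idempotent when the same
    reference is used.
    """
    t = score.table.copy()
    ref = t if reference_ids is None else t[t["person_id"].isin(set(reference_ids))]
    if ref.empty:
        raise ScoreError("empty reference set")
    mu = ref["raw_score"].mean()
    sd = ref["raw_score"].std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ScoreError("zero score variance in reference set")
    t["std_score"] = (t["raw_score"] - mu) / sd
    return ScoreVector(table=t, n_snps_used=score.n_snps_used)
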