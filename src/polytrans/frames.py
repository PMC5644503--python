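"""Child-level analysis frame assembly shared by the regression stages."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import grs
from .genio import GenotypeMatrix, Pedigree, PhenotypeTable, WeightTable


def cohort_frame(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    phenotypes: PhenotypeTable,
    weights: WeightTable,
) -> pd.DataFrame:
    """One row per offspring with standardized scores and parental columns.

    Scores are standardized within generation (parents and offspring
    separately).  Columns: person_id, family_id, edu_years, female, age,
    survey_year, score, mother_edu, father_edu, mother_score, father_score.
    """
    ped = pedigree.table
    phen = phenotypes.table.set_index("person_id")
    score = grs.compute_score(genotypes, weights)

    parent_ids = ped.loc[ped["generation"] == "parent", "person_id"]
    child_ids = ped.loc[ped["generation"] == "offspring", "person_id"]
    scored = set(score.table["person_id"])
    z_par = grs.standardize_score(
        score, [p for p in parent_ids if p in scored]
    ).std() if any(p in scored for p in parent_ids) else pd.Series(dtype=float)
    z_child = grs.standardize_score(
        score, [c for c in child_ids if c in scored]
    ).std()

    off = ped[ped["generation"] == "offspring"]
    rows = pd.DataFrame(
        {
            "person_id": off["person_id"].to_numpy(),
            "family_id": off["family_id"].to_numpy(),
            "mother_id": off["mother_id"].to_numpy(),
            "father_id": off["father_id"].to_numpy(),
        }
    )
    rows["edu_years"] = phen.reindex(rows["person_id"])["edu_years"].to_numpy()
    rows["female"] = (
        phen.reindex(rows["person_id"])["sex"].to_numpy() == "female"
    ).astype(float)
    rows["age"] = phen.reindex(rows["person_id"])["age"].to_numpy()
    if "survey_year" in phen.columns:
        rows["survey_year"] = phen.reindex(rows["person_id"])["survey_year"].to_numpy()
    rows["score"] = z_child.reindex(rows["person_id"]).to_numpy()
    rows["mother_edu"] = phen.reindex(rows["mother_id"])["edu_years"].to_numpy()
    rows["father_edu"] = phen.reindex(rows["father_id"])["edu_years"].to_numpy()
    if not z_par.empty:
        rows["mother_score"] = z_par.reindex(rows["mother_id"]).to_numpy()
        rows["father_score"] = z_par.reindex(rows["father_id"]).to_numpy()
    return rows.drop(columns=["mother_id", "father_id"])
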