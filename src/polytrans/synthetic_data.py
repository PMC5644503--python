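"""Forward simulator for a two-generation cohort with assortative mating.

The generator produces couples plus 1-3 children per family whose moments are
calibrated to measured targets: spousal education correlation, spousal
polygenic-score correlation, SNP-heritability, score predictive R^2, sibling
score intraclass correlation, and unequal within-/between-family score
effects.

Design notes
------------
* Loci are unlinked and unphased; each parent transmits one allele per locus
  with probability ``dosage / 2``.  For unlinked loci this reproduces the
  first two moments of true meiosis exactly, including cross-locus gametic
  disequilibrium built up by assortative mating.
* Spousal correlations are matched by a two-stage noisy rank matching:
  couples are first rank-paired on a noisy education index, then re-matched
  on a noisy score index inside small blocks of adjacent couples.  The two
  noise scales are calibrated by bisection against the realized correlations
  of the actual draw, so targets are hit almost exactly.  The block stage is
  what lets the spousal score correlation exceed the value implied by
  education matching alone; set ``assort_on_phenotype_only=True`` to disable
  it.
* Sibling score correlations approach the equilibrium value (1 + r_spouse)/2
  only after several generations of assortment, so the simulator runs
  ``n_burnin`` generations of mating before the final cohort is emitted.
* One RNG stream per stage, derived from the master seed by stage name.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import (
    GenotypeMatrix,
    Pedigree,
    PhenotypeTable,
    SnpPanel,
    WeightTable,
    write_genotypes_tsv,
    write_pedigree,
    write_phenotypes,
    write_weights,
)


class SimulationError(ValueError):
    pass


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for one pipeline stage."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed), zlib.crc32(stage.encode())))
    )


@dataclass
class SimConfig:
    """Generative targets for the synthetic cohort.

    The structural coefficients are calibration targets taken from fitted
    regression tables, not asserted mechanisms.  ``gamma_within`` /
    ``gamma_between`` act on the regressor named by ``genetic_regressor``
    ("score": the standardized noisy polygenic score, so fitted score slopes
    recover them; "true_g": the standardized true genetic value).
    """

    n_families: int = 2000
    m_snps: int = 400
    freq_range: tuple[float, float] = (0.05, 0.95)
    h2_true: float = 0.20
    var_p: float = 6.10  # target phenotypic variance (years^2)
    r_spouse_edu: float = 0.61
    r_spouse_grs: float = 0.22
    b_mother: float = 0.30
    b_father: float = 0.0
    gamma_within: float = 0.32
    gamma_between: float = 0.27
    theta_gxg: float = 0.15
    r2_score_target: float = 0.026
    sibs_per_family: dict = field(default_factory=lambda: {1: 0.25, 2: 0.5, 3: 0.25})
    seed: int = 0
    n_burnin: int = 8
    mu_edu_parent: float = 12.0
    mu_edu_child: float = 13.4
    genetic_regressor: str = "score"
    assort_on_phenotype_only: bool = False
    match_block: int = 20
    spouse_tol: float = 0.02

    def __post_init__(self) -> None:
        lo, hi = self.freq_range
        if not (0 < lo < hi < 1):
            raise SimulationError(f"degenerate freq_range {self.freq_range}")
        if not 0 <= self.h2_true <= 1:
            raise SimulationError("h2_true must lie in [0, 1]")
        if self.r2_score_target > self.h2_true + 1e-12:
            raise SimulationError(
                f"r2_score_target={self.r2_score_target} exceeds "
                f"h2_true={self.h2_true}: a score cannot out-predict heritability"
            )
        if not np.isfinite([self.gamma_within, self.gamma_between]).all():
            raise SimulationError("gamma coefficients must be finite")
        probs = np.array(list(self.sibs_per_family.values()), dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1) > 1e-9:
            raise SimulationError("sibs_per_family must be a probability distribution")
        if self.genetic_regressor not in ("score", "true_g"):
            raise SimulationError("genetic_regressor must be 'score' or 'true_g'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["freq_range"] = list(d["freq_range"])
        d["sibs_per_family"] = {str(k): v for k, v in d["sibs_per_family"].items()}
        return d

    def manifest_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class CohortBundle:
    """Everything the downstream analysis stages need, in memory."""

    genotypes: GenotypeMatrix  # parents + offspring
    pedigree: Pedigree
    phenotypes: PhenotypeTable | None
    true_effects: WeightTable
    noisy_weights: WeightTable
    true_genetic_value: pd.Series  # g, years scale, indexed by person_id
    z_genetic_value: pd.Series  # z(g), standardized within generation
    parent_edu: pd.Series | None = None
    config: SimConfig | None = None

    def people(self, generation: str) -> list[str]:
        t = self.pedigree.table
        return t.loc[t["generation"] == generation, "person_id"].tolist()


# ---------------------------------------------------------------------------
# founders and effects

def draw_founder_genotypes(
    config: SimConfig,
    seed: int,
    n_samples: int | None = None,
    id_prefix: str = "G0",
) -> GenotypeMatrix:
    """Unrelated founders in Hardy-Weinberg and linkage equilibrium."""
    if config.m_snps < 1:
        raise SimulationError("m_snps must be >= 1")
    rng = stage_rng(seed, "founders")
    n = 2 * config.n_families if n_samples is None else n_samples
    p = rng.uniform(*config.freq_range, size=config.m_snps)
    dosage = rng.binomial(2, p, size=(n, config.m_snps)).astype(float)
    ids = [f"{id_prefix}_{i:06d}" for i in range(n)]
    panel = SnpPanel(
        [f"snp{i:06d}" for i in range(config.m_snps)],
        ["A"] * config.m_snps,
        allele_freq=p,
    )
    return GenotypeMatrix(ids, panel, dosage)


def make_true_effects(panel: SnpPanel, config: SimConfig, seed: int) -> WeightTable:
    """I.i.d. normal per-SNP effects rescaled to the genic variance target.

    The rescaling enforces sum_i 2 p_i (1 - p_i) beta_i^2 =
    ``h2_true * var_p`` exactly.
    """
    rng = stage_rng(seed, "effects")
    p = panel.allele_freq
    beta = rng.standard_normal(panel.m)
    target = config.h2_true * config.var_p
    if target == 0:
        beta = np.zeros(panel.m)
    else:
        beta *= np.sqrt(target / np.sum(2 * p * (1 - p) * beta**2))
    return WeightTable(
        pd.DataFrame(
            {"snp_id": panel.snp_id, "effect_allele": panel.effect_allele,
             "weight": beta}
        )
    )


def make_noisy_weights(
    true_effects: WeightTable, panel: SnpPanel, config: SimConfig, seed: int
) -> WeightTable:
    """Add estimation noise so cor^2(score, g) = r2_score_target / h2_true.

    With per-SNP noise variance tau^2, the score's non-genetic variance is
    tau^2 * sum 2p(1-p), so tau is solved from the correlation target; the
    score-on-phenotype R^2 then lands near ``r2_score_target``.
    """
    if config.r2_score_target > config.h2_true + 1e-12:
        raise SimulationError("r2_score_target > h2_true")
    rng = stage_rng(seed, "score_noise")
    beta = true_effects.table["weight"].to_numpy(float)
    if config.r2_score_target == 0 or config.h2_true == 0:
        noisy = beta.copy()
    else:
        p = panel.allele_freq
        s2 = np.sum(2 * p * (1 - p))
        vg = np.sum(2 * p * (1 - p) * beta**2)
        tau2 = vg * (config.h2_true / config.r2_score_target - 1.0) / s2
        noisy = beta + np.sqrt(tau2) * rng.standard_normal(beta.size)
    out = true_effects.table.copy()
    out["weight"] = noisy
    return WeightTable(out)


# ---------------------------------------------------------------------------
# couple matching

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise SimulationError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def _bisect_noise(fn, target: float, lo: float = 0.0, hi: float = 80.0,
                  n_iter: int = 40) -> float:
    """Find noise scale s with fn(s) = target; fn is decreasing in s."""
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if fn(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _match_couples(
    ze_m: np.ndarray, ze_f: np.ndarray,
    zs_m: np.ndarray, zs_f: np.ndarray,
    config: SimConfig, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (mother_order, father_order): mothers[i]'s spouse is fathers[i].

    Stage 1 rank-pairs on a noisy education index; stage 2 re-matches fathers
    inside blocks of ``match_block`` adjacent couples on a noisy score index.
    Both noise scales are bisected against realized correlations.
    """
    n = ze_m.size
    if ze_f.size != n:
        raise SimulationError("equal numbers of prospective mothers and fathers required")
    eps_m = rng.standard_normal(n)
    eps_f = rng.standard_normal(n)
    eta_m = rng.standard_normal(n)
    eta_f = rng.standard_normal(n)
    # cap the re-match block so it stays local in the education ranking
    K = max(2, min(config.match_block, n // 10))

    def stage1(sig_e: float) -> tuple[np.ndarray, np.ndarray]:
        om = np.argsort(ze_m + sig_e * eps_m, kind="stable")
        of = np.argsort(ze_f + sig_e * eps_f, kind="stable")
        return om, of

    def stage2(om: np.ndarray, of: np.ndarray, sig_s: float) -> np.ndarray:
        of2 = of.copy()
        for start in range(0, n, K):
            bm = om[start:start + K]
            bf = of[start:start + K]
            sm = zs_m[bm] + sig_s * eta_m[bm]
            sf = zs_f[bf] + sig_s * eta_f[bf]
            reordered = np.empty_like(bf)
            reordered[np.argsort(sm, kind="stable")] = bf[np.argsort(sf, kind="stable")]
            of2[start:start + K] = reordered
        return of2

    pure_random = config.r_spouse_edu <= 0.005 and (
        config.r_spouse_grs <= 0.005 or config.assort_on_phenotype_only
    )
    if pure_random:
        return np.arange(n), rng.permutation(n)

    sig_s = 1.0
    use_stage2 = not config.assort_on_phenotype_only
    for _ in range(3):
        def realized_e(sig_e: float) -> float:
            om, of = stage1(sig_e)
            of2 = stage2(om, of, sig_s) if use_stage2 else of
            return float(np.corrcoef(ze_m[om], ze_f[of2])[0, 1])

        om0, of0 = stage1(0.0)
        stage1_max = float(np.corrcoef(ze_m[om0], ze_f[of0])[0, 1])
        if stage1_max < config.r_spouse_edu - config.spouse_tol:
            raise SimulationError(
                f"spousal education target {config.r_spouse_edu} not attainable "
                f"(max realized {stage1_max:.3f})"
            )
        sig_e = _bisect_noise(realized_e, config.r_spouse_edu)
        om, of = stage1(sig_e)
        if not use_stage2:
            break

        def realized_s(sig: float) -> float:
            of2 = stage2(om, of, sig)
            return float(np.corrcoef(zs_m[om], zs_f[of2])[0, 1])

        hi_val, lo_val = realized_s(0.0), realized_s(80.0)
        if config.r_spouse_grs > hi_val + config.spouse_tol:
            raise SimulationError(
                f"spousal score target {config.r_spouse_grs} not attainable: "
                f"max realized {hi_val:.3f} at zero matching noise"
            )
        if config.r_spouse_grs < lo_val - config.spouse_tol:
            raise SimulationError(
                f"spousal score target {config.r_spouse_grs} below the "
                f"{lo_val:.3f} induced by education matching alone"
            )
        sig_s = _bisect_noise(realized_s, config.r_spouse_grs)
    of_final = stage2(om, of, sig_s) if use_stage2 else of
    return om, of_final


def assign_couples(
    founder_phenotypes: PhenotypeTable,
    founder_scores: pd.Series,
    config: SimConfig,
    seed: int,
) -> Pedigree:
    """Pair founders into couples via the calibrated noisy mating index.

    ``founder_scores`` is indexed by person_id.  Returns a parent-generation
    pedigree whose family_id groups each couple.
    """
    rng = stage_rng(seed, "mating")
    phen = founder_phenotypes.table
    mothers = phen[phen["sex"] == "female"].reset_index(drop=True)
    fathers = phen[phen["sex"] == "male"].reset_index(drop=True)
    if len(mothers) != len(fathers):
        raise SimulationError(
            f"{len(mothers)} mothers vs {len(fathers)} fathers: counts must match"
        )
    ze_m = _zscore(mothers["edu_years"].to_numpy(float))
    ze_f = _zscore(fathers["edu_years"].to_numpy(float))
    zs_m = _zscore(founder_scores.loc[mothers["person_id"]].to_numpy(float))
    zs_f = _zscore(founder_scores.loc[fathers["person_id"]].to_numpy(float))
    om, of = _match_couples(ze_m, ze_f, zs_m, zs_f, config, rng)

    rows = []
    for fam_idx, (im, if_) in enumerate(zip(om, of)):
        fam = f"FAM{fam_idx:06d}"
        rows.append((mothers.loc[im, "person_id"], fam, None, None, "female", "parent"))
        rows.append((fathers.loc[if_, "person_id"], fam, None, None, "male", "parent"))
    table = pd.DataFrame(
        rows,
        columns=["person_id", "family_id", "mother_id", "father_id", "sex",
                 "generation"],
    )
    return Pedigree(table)


# ---------------------------------------------------------------------------
# transmission

def transmit_genotypes(
    parent_genotypes: GenotypeMatrix, pedigree: Pedigree, seed: int
) -> GenotypeMatrix:
    """Mendelian transmission: one allele per parent, Bernoulli(dosage / 2).

    Loci are treated as unlinked; draws are independent across loci and
    children.
    """
    rng = stage_rng(seed, "meiosis")
    off = pedigree.offspring
    idx = {s: i for i, s in enumerate(parent_genotypes.sample_id)}
    for col in ("mother_id", "father_id"):
        missing = [p for p in off[col] if p is None or p not in idx]
        if missing:
            raise SimulationError(f"offspring with ungenotyped parent: {missing[:5]}")
    dm = parent_genotypes.dosage[[idx[p] for p in off["mother_id"]]]
    df_ = parent_genotypes.dosage[[idx[p] for p in off["father_id"]]]
    if np.isnan(dm).any() or np.isnan(df_).any():
        raise SimulationError("parental dosages must be complete for transmission")
    child = rng.binomial(1, dm / 2.0) + rng.binomial(1, df_ / 2.0)
    return GenotypeMatrix(
        off["person_id"].tolist(), parent_genotypes.panel, child.astype(float)
    )


# ---------------------------------------------------------------------------
# phenotypes

def _genetic_values(dosage: np.ndarray, weights: np.ndarray) -> np.ndarray:
    return dosage @ weights


def simulate_phenotypes(bundle: CohortBundle, config: SimConfig, seed: int) -> PhenotypeTable:
    """Generate education, age and sex for everyone in the bundle.

    Parent education is ``mu_par + g + e`` with the residual variance chosen
    so the parent-generation heritability equals ``h2_true`` exactly for the
    realized var(g).  Child education follows the structural equation with
    parental-education main effects, within- and between-family genetic
    effects, and a child-by-mother genetic interaction; the residual variance
    is set to hit ``var_p``.
    """
    rng = stage_rng(seed, "phenotypes")
    ped = bundle.pedigree.table
    g = bundle.true_genetic_value

    parent_ids = ped.loc[ped["generation"] == "parent", "person_id"].tolist()
    child_rows = ped[ped["generation"] == "offspring"]
    child_ids = child_rows["person_id"].tolist()

    # --- parents
    if bundle.parent_edu is not None:
        edu_par = bundle.parent_edu.loc[parent_ids]
    else:
        edu_par = _draw_parent_edu(g.loc[parent_ids], config, rng)

    # --- children: standardized genetic regressor, within generation
    from . import grs as _grs  # deferred to avoid import cycle at module load

    if config.genetic_regressor == "score":
        sc = _grs.compute_score(bundle.genotypes, bundle.noisy_weights)
        raw = sc.table.set_index("person_id")["raw_score"]
    else:
        raw = g
    x_child = pd.Series(_zscore(raw.loc[child_ids].to_numpy(float)), index=child_ids)
    score_all = _grs.compute_score(bundle.genotypes, bundle.noisy_weights)
    s_raw = score_all.table.set_index("person_id")["raw_score"]
    z_s_parent = pd.Series(
        _zscore(s_raw.loc[parent_ids].to_numpy(float)), index=parent_ids
    )

    fam_mean = x_child.groupby(child_rows.set_index("person_id")["family_id"]).mean()
    xbar = child_rows["family_id"].map(fam_mean).to_numpy(float)
    x = x_child.to_numpy(float)
    edu_mom = edu_par.loc[child_rows["mother_id"]].to_numpy(float)
    edu_dad = edu_par.loc[child_rows["father_id"]].to_numpy(float)
    z_s_mom = z_s_parent.loc[child_rows["mother_id"]].to_numpy(float)

    struct = (
        config.b_mother * edu_mom
        + config.b_father * edu_dad
        + config.gamma_between * xbar
        + config.gamma_within * (x - xbar)
        + config.theta_gxg * x * z_s_mom
    )
    var_struct = float(np.var(struct))
    resid_var = config.var_p - var_struct
    if resid_var <= 0:
        raise SimulationError(
            "negative implied residual variance: structural variance "
            f"{var_struct:.3f} exceeds var_p={config.var_p:.3f} "
            f"(budget: b_mother*edu_mom etc.)"
        )
    edu_child = (
        config.mu_edu_child
        + struct
        - struct.mean()
        + rng.normal(0.0, np.sqrt(resid_var), size=len(child_ids))
    )

    sex_map = ped.set_index("person_id")["sex"]
    age = pd.concat(
        [
            pd.Series(rng.normal(68.0, 8.0, len(parent_ids)), index=parent_ids),
            pd.Series(rng.normal(39.0, 7.0, len(child_ids)), index=child_ids),
        ]
    ).round(1)
    survey_year = pd.Series(
        rng.integers(2002, 2013, size=len(parent_ids) + len(child_ids)),
        index=parent_ids + child_ids,
    )
    edu = pd.concat([edu_par, pd.Series(edu_child, index=child_ids)])
    ids = parent_ids + child_ids
    table = pd.DataFrame(
        {
            "person_id": ids,
            "edu_years": edu.loc[ids].to_numpy(float),
            "age": age.loc[ids].to_numpy(float),
            "sex": sex_map.loc[ids].to_numpy(),
            "survey_year": survey_year.loc[ids].to_numpy(),
        }
    )
    return PhenotypeTable(table)


def _draw_parent_edu(
    g_par: pd.Series, config: SimConfig, rng: np.random.Generator
) -> pd.Series:
    var_g = float(np.var(g_par.to_numpy(float)))
    if config.h2_true == 0:
        resid = config.var_p
    else:
        resid = var_g * (1.0 - config.h2_true) / config.h2_true
    e = rng.normal(0.0, np.sqrt(resid), size=g_par.size)
    vals = config.mu_edu_parent + g_par.to_numpy(float) - g_par.mean() + e
    return pd.Series(vals, index=g_par.index)


# ---------------------------------------------------------------------------
# orchestrator

def simulate_cohort(config: SimConfig, out_dir: str | Path | None = None) -> CohortBundle:
    """Run burn-in, mate the final parents, transmit, and phenotype."""
    seed = config.seed
    founders = draw_founder_genotypes(config, seed)
    panel = founders.panel
    effects = make_true_effects(panel, config, seed)
    noisy = make_noisy_weights(effects, panel, config, seed)
    beta = effects.table["weight"].to_numpy(float)
    w = noisy.table["weight"].to_numpy(float)

    n = config.n_families
    dosage = founders.dosage
    burn_rng = stage_rng(seed, "burnin")
    for t in range(config.n_burnin):
        dosage = _burnin_generation(dosage, beta, w, config, burn_rng)

    parent_ids = [f"P_{i:06d}" for i in range(2 * n)]
    parents = GenotypeMatrix(parent_ids, panel, dosage)
    # first half mothers, second half fathers (burn-in preserves this split)
    sexes = ["female"] * n + ["male"] * n

    g_par = pd.Series(_genetic_values(dosage, beta), index=parent_ids)
    s_par = pd.Series(_genetic_values(dosage, w), index=parent_ids)
    pheno_rng = stage_rng(seed, "parent_edu")
    edu_par = _draw_parent_edu(g_par, config, pheno_rng)
    parent_phen = PhenotypeTable(
        pd.DataFrame(
            {
                "person_id": parent_ids,
                "edu_years": edu_par.to_numpy(float),
                "age": 0.0,
                "sex": sexes,
            }
        )
    )
    parent_ped = assign_couples(parent_phen, s_par, config, seed)

    # children per family
    fam_rng = stage_rng(seed, "families")
    sizes = np.array(list(config.sibs_per_family.keys()), dtype=int)
    probs = np.array(list(config.sibs_per_family.values()), dtype=float)
    fams = parent_ped.table.groupby("family_id", sort=True)
    child_rows = []
    counts = fam_rng.choice(sizes, size=fams.ngroups, p=probs)
    for (fam, grp), k in zip(fams, counts):
        mother = grp.loc[grp["sex"] == "female", "person_id"].iloc[0]
        father = grp.loc[grp["sex"] == "male", "person_id"].iloc[0]
        for j in range(k):
            sex = "female" if fam_rng.random() < 0.5 else "male"
            child_rows.append(
                (f"C_{fam[3:]}_{j}", fam, mother, father, sex, "offspring")
            )
    ped_table = pd.concat(
        [
            parent_ped.table,
            pd.DataFrame(child_rows, columns=parent_ped.table.columns),
        ],
        ignore_index=True,
    )
    pedigree = Pedigree(ped_table)

    children = transmit_genotypes(parents, pedigree, seed)
    all_geno = GenotypeMatrix(
        parent_ids + children.sample_id,
        panel,
        np.vstack([parents.dosage, children.dosage]),
    )
    g_child = pd.Series(_genetic_values(children.dosage, beta), index=children.sample_id)
    g_all = pd.concat([g_par, g_child])
    z_g = pd.concat(
        [
            pd.Series(_zscore(g_par.to_numpy(float)), index=g_par.index)
            if g_par.std() > 0 else g_par * 0.0,
            pd.Series(_zscore(g_child.to_numpy(float)), index=g_child.index)
            if g_child.std() > 0 else g_child * 0.0,
        ]
    )

    bundle = CohortBundle(
        genotypes=all_geno,
        pedigree=pedigree,
        phenotypes=None,
        true_effects=effects,
        noisy_weights=noisy,
        true_genetic_value=g_all,
        z_genetic_value=z_g,
        parent_edu=edu_par,
        config=config,
    )
    bundle.phenotypes = simulate_phenotypes(bundle, config, seed)

    if out_dir is not None:
        write_cohort(bundle, out_dir)
    return bundle


def _burnin_generation(
    dosage: np.ndarray,
    beta: np.ndarray,
    w: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One generation of assortative mating; returns the next population.

    The population is kept at n mothers followed by n fathers; each couple
    contributes one daughter and one son.
    """
    n = dosage.shape[0] // 2
    g = _genetic_values(dosage, beta)
    s = _genetic_values(dosage, w)
    var_g = g.var()
    if config.h2_true > 0 and var_g > 0:
        resid = var_g * (1 - config.h2_true) / config.h2_true
    else:
        resid = config.var_p
    edu = g + rng.normal(0.0, np.sqrt(resid), size=2 * n)

    ze_m, ze_f = _zscore(edu[:n]), _zscore(edu[n:])
    zs_m, zs_f = _zscore(s[:n]), _zscore(s[n:])
    om, of = _match_couples(ze_m, ze_f, zs_m, zs_f, config, rng)
    dm = dosage[:n][om]
    df_ = dosage[n:][of]
    daughters = rng.binomial(1, dm / 2.0) + rng.binomial(1, df_ / 2.0)
    sons = rng.binomial(1, dm / 2.0) + rng.binomial(1, df_ / 2.0)
    return np.vstack([daughters, sons]).astype(float)


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> dict:
    """Write cohort files in genio formats plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genotypes_tsv(bundle.genotypes, out / "genotypes.tsv")
    write_pedigree(bundle.pedigree, out / "pedigree.tsv")
    write_phenotypes(bundle.phenotypes, out / "phenotypes.tsv")
    write_weights(bundle.noisy_weights, out / "weights.tsv")
    write_weights(bundle.true_effects, out / "true_effects.tsv")
    bundle.true_genetic_value.rename("g").rename_axis("person_id").to_csv(
        out / "true_genetic_value.tsv", sep="\t", float_format="%.17g"
    )
    manifest = {
        "config": bundle.config.to_dict() if bundle.config else None,
        "seed": bundle.config.seed if bundle.config else None,
        "config_hash": bundle.config.manifest_hash() if bundle.config else None,
        "n_people": bundle.genotypes.n,
        "n_snps": bundle.genotypes.m,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
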