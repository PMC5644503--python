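import numpy as np
import pandas as pd
import pytest

from polytrans import grs
from polytrans.genio import PhenotypeTable
from polytrans.regress import ModelSpec, fit_ols_clustered
from polytrans.synthetic_data import (
    CohortBundle,
    SimConfig,
    SimulationError,
    assign_couples,
    draw_founder_genotypes,
    make_noisy_weights,
    make_true_effects,
    simulate_cohort,
    stage_rng,
    transmit_genotypes,
)
from polytrans import frames


def _founder_scores(cfg, seed):
    geno = draw_founder_genotypes(cfg, seed)
    eff = make_true_effects(geno.panel, cfg, seed)
    noisy = make_noisy_weights(eff, geno.panel, cfg, seed)
    g = geno.dosage @ eff.table["weight"].to_numpy()
    s = geno.dosage @ noisy.table["weight"].to_numpy()
    return geno, g, s


# ---------------------------------------------------------------------------
# founders


def test_founder_moments_half_frequency():
    cfg = SimConfig(n_families=10_000, m_snps=5, freq_range=(0.499, 0.501), seed=0)
    geno = draw_founder_genotypes(cfg, 0)
    assert abs(geno.dosage.mean() - 1.0) < 0.02
    assert abs(geno.dosage.var() - 0.5) < 0.02


def test_founder_determinism():
    cfg = SimConfig(n_families=50, m_snps=20, seed=9)
    a = draw_founder_genotypes(cfg, 9)
    b = draw_founder_genotypes(cfg, 9)
    np.testing.assert_array_equal(a.dosage, b.dosage)


def test_founder_frequencies_match_draw():
    # empirical p-hat vs drawn p at N=5,000: deviations within binomial SE
    cfg = SimConfig(n_families=2500, m_snps=300, seed=2)
    geno = draw_founder_genotypes(cfg, 2)
    p = geno.panel.allele_freq
    phat = geno.dosage.mean(0) / 2
    se = np.sqrt(p * (1 - p) / (2 * geno.n))
    assert np.max(np.abs(phat - p) / se) < 5.0


def test_degenerate_freq_range_rejected():
    with pytest.raises(SimulationError, match="freq_range"):
        SimConfig(freq_range=(0.5, 0.5))


# ---------------------------------------------------------------------------
# effects and noisy weights


def test_zero_heritability_zero_weights():
    cfg = SimConfig(n_families=20, m_snps=30, h2_true=0.0, r2_score_target=0.0)
    geno = draw_founder_genotypes(cfg, 1)
    eff = make_true_effects(geno.panel, cfg, 1)
    assert (eff.table["weight"] == 0).all()


def test_effect_scaling_hits_genic_variance_target():
    # h2 = 1.20/6.10, var_p = 6.10 -> sum 2p(1-p) beta^2 = 1.20
    cfg = SimConfig(n_families=100, m_snps=400, h2_true=1.20 / 6.10, var_p=6.10)
    geno = draw_founder_genotypes(cfg, 3)
    eff = make_true_effects(geno.panel, cfg, 3)
    p = geno.panel.allele_freq
    b = eff.table["weight"].to_numpy()
    assert np.sum(2 * p * (1 - p) * b**2) == pytest.approx(1.20, abs=1e-10)


def test_founder_genetic_variance_near_target():
    cfg = SimConfig(n_families=4000, m_snps=500, h2_true=1.20 / 6.10,
                    var_p=6.10, seed=7)
    geno, g, _ = _founder_scores(cfg, 7)
    assert g.var() == pytest.approx(1.20, abs=0.10)


def test_noiseless_weights_identity():
    cfg = SimConfig(n_families=50, m_snps=40, h2_true=0.2, r2_score_target=0.2)
    geno = draw_founder_genotypes(cfg, 4)
    eff = make_true_effects(geno.panel, cfg, 4)
    noisy = make_noisy_weights(eff, geno.panel, cfg, 4)
    np.testing.assert_allclose(
        noisy.table["weight"].to_numpy(), eff.table["weight"].to_numpy()
    )


def test_score_cannot_outpredict_heritability():
    with pytest.raises(SimulationError, match="out-predict"):
        SimConfig(h2_true=0.1, r2_score_target=0.2)


def test_score_g_correlation_matches_closed_form():
    # realized cor^2(score, g) vs r2/h2 across seeds, within 2 SE of the mean
    vals = []
    for seed in range(10):
        _, g, s = _founder_scores(
            SimConfig(n_families=1500, m_snps=250, h2_true=0.2,
                      r2_score_target=0.026, seed=seed),
            seed,
        )
        vals.append(np.corrcoef(s, g)[0, 1] ** 2)
    vals = np.array(vals)
    target = 0.026 / 0.2
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - target) < 2 * se + 0.01


# ---------------------------------------------------------------------------
# mating


def _phen_for(geno, g, cfg, seed):
    n = geno.n // 2
    rng = stage_rng(seed, "test_edu")
    resid = g.var() * (1 - cfg.h2_true) / cfg.h2_true
    edu = 13 + g - g.mean() + rng.normal(0, np.sqrt(resid), geno.n)
    return PhenotypeTable(
        pd.DataFrame(
            {
                "person_id": geno.sample_id,
                "edu_years": edu,
                "age": 40.0,
                "sex": ["female"] * n + ["male"] * n,
            }
        )
    )


def _spouse_corrs(cfg, seed):
    geno, g, s = _founder_scores(cfg, seed)
    phen = _phen_for(geno, g, cfg, seed)
    scores = pd.Series(s, index=geno.sample_id)
    ped = assign_couples(phen, scores, cfg, seed)
    t = ped.table.set_index("person_id")
    phe = phen.table.set_index("person_id")
    moms = t[t["sex"] == "female"].reset_index().set_index("family_id")["person_id"]
    dads = t[t["sex"] == "male"].reset_index().set_index("family_id")["person_id"]
    fams = moms.index
    e = np.corrcoef(
        phe.loc[moms[fams], "edu_years"], phe.loc[dads[fams], "edu_years"]
    )[0, 1]
    sc = np.corrcoef(scores[moms[fams]], scores[dads[fams]])[0, 1]
    return e, sc


def test_zero_assortment_gives_null_correlations():
    cfg = SimConfig(n_families=2000, m_snps=150, r_spouse_edu=0.0,
                    r_spouse_grs=0.0, seed=21)
    e, s = _spouse_corrs(cfg, 21)
    assert abs(e) < 0.05 and abs(s) < 0.05


@pytest.mark.parametrize("target_edu", [0.53, 0.61])
def test_spousal_targets_hit(target_edu):
    cfg = SimConfig(n_families=3000, m_snps=150, r_spouse_edu=target_edu,
                    r_spouse_grs=0.22, seed=22)
    e, s = _spouse_corrs(cfg, 22)
    assert e == pytest.approx(target_edu, abs=0.02)
    assert s == pytest.approx(0.22, abs=0.02)


def test_infeasible_spousal_score_target_errors():
    cfg = SimConfig(n_families=400, m_snps=100, r_spouse_edu=0.5,
                    r_spouse_grs=0.99, seed=23)
    with pytest.raises(SimulationError, match="not attainable"):
        _spouse_corrs(cfg, 23)


def test_unequal_sex_counts_error():
    cfg = SimConfig(n_families=10, m_snps=20, seed=1)
    geno, g, s = _founder_scores(cfg, 1)
    phen = _phen_for(geno, g, cfg, 1)
    phen.table.loc[0, "sex"] = "male"
    with pytest.raises(SimulationError, match="counts must match"):
        assign_couples(phen, pd.Series(s, index=geno.sample_id), cfg, 1)


# ---------------------------------------------------------------------------
# transmission


def _mini_pedigree(children):
    rows = [
        ("m", "f1", None, None, "female", "parent"),
        ("d", "f1", None, None, "male", "parent"),
    ]
    rows += [(c, "f1", "m", "d", "female", "offspring") for c in children]
    from polytrans.genio import Pedigree

    return Pedigree(
        pd.DataFrame(
            rows,
            columns=["person_id", "family_id", "mother_id", "father_id",
                     "sex", "generation"],
        )
    )


def _parents_with_dosage(dm, dd):
    from polytrans.genio import GenotypeMatrix, SnpPanel

    panel = SnpPanel(["rs1"], ["A"], allele_freq=np.array([0.5]))
    return GenotypeMatrix(["m", "d"], panel, np.array([[dm], [dd]], float))


def test_homozygote_parents_transmit_deterministically():
    ped = _mini_pedigree([f"c{i}" for i in range(50)])
    geno = _parents_with_dosage(2.0, 2.0)
    child = transmit_genotypes(geno, ped, 0)
    assert (child.dosage == 2.0).all()


def test_het_parents_mendelian_ratios():
    ped = _mini_pedigree([f"c{i}" for i in range(4000)])
    geno = _parents_with_dosage(1.0, 1.0)
    child = transmit_genotypes(geno, ped, 0)
    counts = np.bincount(child.dosage[:, 0].astype(int), minlength=3) / 4000
    np.testing.assert_allclose(counts, [0.25, 0.5, 0.25], atol=0.03)


def test_missing_parent_dosage_errors():
    ped = _mini_pedigree(["c1"])
    geno = _parents_with_dosage(np.nan, 1.0)
    with pytest.raises(SimulationError, match="complete"):
        transmit_genotypes(geno, ped, 0)


def test_random_mating_relative_correlations_half():
    # sibling and parent-offspring correlation of true genetic value ~ 0.5
    cfg = SimConfig(
        n_families=5000, m_snps=200, r_spouse_edu=0.0, r_spouse_grs=0.0,
        n_burnin=0, sibs_per_family={2: 1.0}, seed=31,
    )
    b = simulate_cohort(cfg)
    g = b.true_genetic_value
    off = b.pedigree.offspring
    sib = off.groupby("family_id")["person_id"].apply(list)
    pairs = np.array([(g[a], g[c]) for a, c in sib])
    r_sib = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
    po = np.array([(g[m], g[c]) for c, m in zip(off["person_id"], off["mother_id"])])
    r_po = np.corrcoef(po[:, 0], po[:, 1])[0, 1]
    se = 1.0 / np.sqrt(len(pairs))
    assert abs(r_sib - 0.5) < 3 * se + 0.01
    assert abs(r_po - 0.5) < 3 * se + 0.01


def test_offspring_alleles_consistent_with_parents(small_cohort):
    b = small_cohort
    idx = {s: i for i, s in enumerate(b.genotypes.sample_id)}
    off = b.pedigree.offspring
    D = b.genotypes.dosage
    dm = D[[idx[m] for m in off["mother_id"]]]
    dd = D[[idx[f] for f in off["father_id"]]]
    dc = D[[idx[c] for c in off["person_id"]]]
    # a child cannot carry more copies than its parents can transmit
    assert np.all(dc <= (dm > 0).astype(int) + (dd > 0).astype(int))
    assert np.all(dc >= (dm == 2).astype(int) + (dd == 2).astype(int))


# ---------------------------------------------------------------------------
# phenotypes and orchestration


def test_cohort_determinism():
    cfg = SimConfig(n_families=60, m_snps=30, n_burnin=2, seed=42)
    a = simulate_cohort(cfg)
    b = simulate_cohort(cfg)
    np.testing.assert_array_equal(a.genotypes.dosage, b.genotypes.dosage)
    np.testing.assert_array_equal(
        a.phenotypes.table["edu_years"].to_numpy(),
        b.phenotypes.table["edu_years"].to_numpy(),
    )
    assert a.config.manifest_hash() == b.config.manifest_hash()


def test_negative_residual_budget_errors():
    cfg = SimConfig(n_families=100, m_snps=40, var_p=0.2, b_mother=2.0,
                    n_burnin=0, seed=2)
    with pytest.raises(SimulationError, match="residual variance"):
        simulate_cohort(cfg)


def test_null_genetic_effects_give_null_score_coefficient():
    cfg = SimConfig(
        n_families=2500, m_snps=150, gamma_within=0.0, gamma_between=0.0,
        theta_gxg=0.0, n_burnin=2, seed=43,
    )
    b = simulate_cohort(cfg)
    d = frames.cohort_frame(b.genotypes, b.pedigree, b.phenotypes, b.noisy_weights)
    fit = fit_ols_clustered(
        d, ModelSpec("edu_years", ["mother_edu", "father_edu", "score"])
    )
    assert abs(fit.params["score"]) < 3 * fit.se["score"]


def test_founder_h2_within_tolerance(calibrated_cohort):
    b = calibrated_cohort
    parents = b.people("parent")
    g = b.true_genetic_value[parents]
    edu = b.phenotypes.table.set_index("person_id").loc[parents, "edu_years"]
    h2 = g.var() / edu.var()
    assert h2 == pytest.approx(b.config.h2_true, abs=0.02)


def test_sibling_score_icc_matches_equilibrium(calibrated_frame, calibrated_cohort):
    from polytrans.family_decomp import intraclass_correlation

    icc = intraclass_correlation(
        calibrated_frame["score"], calibrated_frame["family_id"]
    )
    target = (1 + calibrated_cohort.config.r_spouse_grs) / 2
    assert icc == pytest.approx(target, abs=0.03)
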