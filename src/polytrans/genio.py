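"""Readers and writers for genotypes, weights, pedigrees, phenotypes and GRMs.

All downstream modules consume only the in-memory containers defined here.
Text formats are tab-delimited with a header row; identifiers are opaque
strings.  Genotype columns are headed ``<snp_id>:<effect_allele>`` so that the
allele being counted travels with the dosages.  The GRM writer/reader speak
the de-facto GCTA text layout (``<prefix>.grm`` lower-triangle triplets plus
``<prefix>.grm.id``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEX_CODES = {"1": "male", "2": "female", "male": "male", "female": "female"}
MISSING_PARENT = "0"


class GenioError(ValueError):
    """Raised on malformed or inconsistent input files."""


@dataclass
class SnpPanel:
    """SNP identifiers, counted (effect) alleles and allele frequencies."""

    snp_id: list[str]
    effect_allele: list[str]
    allele_freq: np.ndarray | None = None  # effect-allele frequency p_i

    def __post_init__(self) -> None:
        if len(set(self.snp_id)) != len(self.snp_id):
            dupes = pd.Index(self.snp_id)
            raise GenioError(
                f"duplicate SNP ids: {sorted(dupes[dupes.duplicated()])[:5]}"
            )
        if len(self.effect_allele) != len(self.snp_id):
            raise GenioError("snp_id and effect_allele length mismatch")
        if self.allele_freq is not None:
            self.allele_freq = np.asarray(self.allele_freq, dtype=float)
            if self.allele_freq.shape != (len(self.snp_id),):
                raise GenioError("allele_freq length mismatch")

    @property
    def m(self) -> int:
        return len(self.snp_id)

    def require_polymorphic(self) -> None:
        """Check 0 < p_i < 1 for every SNP (needed for GRM/score work)."""
        if self.allele_freq is None:
            raise GenioError("allele frequencies not set")
        bad = np.flatnonzero((self.allele_freq <= 0) | (self.allele_freq >= 1))
        if bad.size:
            ids = [self.snp_id[i] for i in bad[:5]]
            raise GenioError(f"monomorphic or out-of-range frequency at {ids}")


@dataclass
class GenotypeMatrix:
    """N x M additive dosages (effect-allele counts); NaN marks missing."""

    sample_id: list[str]
    panel: SnpPanel
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if len(set(self.sample_id)) != len(self.sample_id):
            ids = pd.Index(self.sample_id)
            raise GenioError(
                f"duplicate sample ids: {sorted(ids[ids.duplicated()])[:5]}"
            )
        if self.dosage.shape != (len(self.sample_id), self.panel.m):
            raise GenioError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_id)} samples x {self.panel.m} SNPs"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if np.nanmin(self.dosage, initial=0) < 0 or np.nanmax(
                self.dosage, initial=0
            ) > 2:
                raise GenioError("dosages must lie in [0, 2]")

    @property
    def n(self) -> int:
        return len(self.sample_id)

    @property
    def m(self) -> int:
        return self.panel.m

    def allele_freq_from_data(self) -> np.ndarray:
        """Per-SNP effect-allele frequency: column mean of dosage / 2."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    def ensure_freq(self) -> np.ndarray:
        if self.panel.allele_freq is None:
            self.panel.allele_freq = self.allele_freq_from_data()
        return self.panel.allele_freq

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=1)

    def imputed_dosage(self) -> np.ndarray:
        """Dosages with missing entries replaced by their expectation 2 p_i."""
        if not np.isnan(self.dosage).any():
            return self.dosage
        p = self.ensure_freq()
        out = self.dosage.copy()
        r, c = np.nonzero(np.isnan(out))
        out[r, c] = 2.0 * p[c]
        return out

    def drop_high_missing(self, max_missing: float = 0.10) -> "GenotypeMatrix":
        """Drop persons with more than ``max_missing`` missing SNPs."""
        keep = self.missing_rate() <= max_missing
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning("dropping %d samples with >%.0f%% missing dosages",
                           n_drop, 100 * max_missing)
        return GenotypeMatrix(
            [s for s, k in zip(self.sample_id, keep) if k],
            self.panel,
            self.dosage[keep],
        )

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_id)}
        rows = [index[s] for s in ids]
        return GenotypeMatrix(list(ids), self.panel, self.dosage[rows])


@dataclass
class Pedigree:
    """Family structure linking children to parents and sibling groups.

    ``table`` columns: person_id, family_id, mother_id, father_id, sex,
    generation.  Parent ids are ``None`` for founders.
    """

    table: pd.DataFrame

    REQUIRED = ("person_id", "family_id", "mother_id", "father_id", "sex",
                "generation")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise GenioError(f"pedigree missing columns {sorted(missing)}")
        if self.table["person_id"].duplicated().any():
            d = self.table.loc[self.table["person_id"].duplicated(), "person_id"]
            raise GenioError(f"duplicate person ids: {sorted(d)[:5]}")
        self.validate()

    def validate(self) -> None:
        t = self.table
        present = set(t["person_id"])
        for _, row in t.iterrows():
            for parent in (row["mother_id"], row["father_id"]):
                if parent is not None and parent == row["person_id"]:
                    raise GenioError(f"{row['person_id']} is its own ancestor")
                if parent is not None and parent not in present:
                    # explicitly flagged external parent is allowed
                    if not str(parent).startswith("ext:"):
                        raise GenioError(
                            f"parent {parent} of {row['person_id']} absent "
                            "from pedigree (prefix with 'ext:' if external)"
                        )

    @property
    def offspring(self) -> pd.DataFrame:
        return self.table[self.table["generation"] == "offspring"]

    @property
    def parents(self) -> pd.DataFrame:
        return self.table[self.table["generation"] == "parent"]

    def sibling_groups(self) -> dict[str, list[str]]:
        off = self.offspring
        return {f: g["person_id"].tolist() for f, g in off.groupby("family_id")}


@dataclass
class PhenotypeTable:
    """One row per person: edu_years, age, sex, survey_year (nullable)."""

    table: pd.DataFrame

    REQUIRED = ("person_id", "edu_years", "age", "sex")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise GenioError(f"phenotype table missing columns {sorted(missing)}")
        if self.table["person_id"].duplicated().any():
            raise GenioError("duplicate person ids in phenotype table")
        if not np.isfinite(self.table["edu_years"].to_numpy(float)).all():
            raise GenioError("edu_years must be finite")
        if "survey_year" not in self.table.columns:
            self.table = self.table.assign(survey_year=np.nan)


@dataclass
class WeightTable:
    """GWAS weight table: snp_id, effect_allele, per-allele weight."""

    table: pd.DataFrame

    REQUIRED = ("snp_id", "effect_allele", "weight")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise GenioError(f"weight table missing columns {sorted(missing)}")
        if self.table["snp_id"].duplicated().any():
            raise GenioError("duplicate SNP ids in weight table")
        if not np.isfinite(self.table["weight"].to_numpy(float)).all():
            raise GenioError("weights must be finite")


# ---------------------------------------------------------------------------
# genotype TSV / VCF

def write_genotypes_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    header = ["sample_id"] + [
        f"{s}:{a}" for s, a in zip(geno.panel.snp_id, geno.panel.effect_allele)
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for sid, row in zip(geno.sample_id, geno.dosage):
            vals = ["NA" if np.isnan(v) else repr(int(v)) if v == int(v) else repr(v)
                    for v in row]
            fh.write(sid + "\t" + "\t".join(vals) + "\n")


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA"],
                     float_precision="round_trip")
    cols = list(df.columns[1:])
    snp_id, allele = [], []
    for c in cols:
        if ":" not in c:
            raise GenioError(f"genotype column {c!r} lacks ':<effect_allele>'")
        s, a = c.rsplit(":", 1)
        snp_id.append(s)
        allele.append(a)
    panel = SnpPanel(snp_id, allele)
    geno = GenotypeMatrix(df.iloc[:, 0].tolist(), panel, df[cols].to_numpy(float))
    geno.ensure_freq()
    return geno


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a (single-ALT, diploid) VCF; dosage counts the ALT allele."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise GenioError("cyvcf2 is required for VCF input") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_id, allele, rows = [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GenioError(f"multi-allelic record at {rec.ID or rec.POS}")
        snp_id.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        allele.append(rec.ALT[0])
        gt = np.asarray(rec.genotype.array())[:, :2].astype(float)
        gt[gt < 0] = np.nan
        rows.append(gt.sum(axis=1))
    dosage = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    geno = GenotypeMatrix(samples, SnpPanel(snp_id, allele), dosage)
    geno.ensure_freq()
    return geno


# ---------------------------------------------------------------------------
# pedigree (FAM-like), phenotypes, weights

def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    t = ped.table
    out = pd.DataFrame(
        {
            "FID": t["family_id"],
            "IID": t["person_id"],
            "PAT": [p if p is not None else MISSING_PARENT for p in t["father_id"]],
            "MAT": [p if p is not None else MISSING_PARENT for p in t["mother_id"]],
            "SEX": ["2" if s == "female" else "1" for s in t["sex"]],
            "GEN": t["generation"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"FID", "IID", "PAT", "MAT", "SEX"}
    if not need.issubset(df.columns):
        raise GenioError(f"pedigree file must have columns {sorted(need)}")
    sex = df["SEX"].map(SEX_CODES)
    if sex.isna().any():
        raise GenioError("SEX codes must be 1/2 or male/female")
    gen = (
        df["GEN"]
        if "GEN" in df.columns
        else np.where((df["PAT"] == MISSING_PARENT) & (df["MAT"] == MISSING_PARENT),
                      "parent", "offspring")
    )
    table = pd.DataFrame(
        {
            "person_id": df["IID"],
            "family_id": df["FID"],
            "mother_id": [None if p == MISSING_PARENT else p for p in df["MAT"]],
            "father_id": [None if p == MISSING_PARENT else p for p in df["PAT"]],
            "sex": sex,
            "generation": gen,
        }
    )
    return Pedigree(table)


def write_phenotypes(phen: PhenotypeTable, path: str | Path) -> None:
    # %.17g guarantees float64 round-trip
    phen.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"person_id": str},
                     float_precision="round_trip")
    return PhenotypeTable(df)


def write_weights(weights: WeightTable, path: str | Path) -> None:
    out = weights.table.rename(
        columns={"snp_id": "SNP", "effect_allele": "A1", "weight": "WEIGHT"}
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_weights(path: str | Path) -> WeightTable:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str},
                     float_precision="round_trip")
    need = {"SNP", "A1", "WEIGHT"}
    if not need.issubset(df.columns):
        raise GenioError(f"weight file must have columns {sorted(need)}")
    return WeightTable(
        df.rename(columns={"SNP": "snp_id", "A1": "effect_allele",
                           "WEIGHT": "weight"})
    )


# ---------------------------------------------------------------------------
# cohort loader

def load_cohort(
    genotype_path: str | Path,
    pedigree_path: str | Path,
    phenotype_path: str | Path,
    weights_path: str | Path | None = None,
    genotype_format: str = "tsv",
    max_missing: float = 0.10,
):
    """Load and cross-reference a cohort.

    Persons present in the phenotype table but absent from the genotype file
    are retained (their genotype is simply missing).  Allele frequencies are
    computed from non-missing dosages when not supplied.  A weight table, if
    given, is checked for allele-code agreement against the genotype panel; a
    mismatch is a hard error naming the SNP (use :func:`polytrans.grs.
    compute_score` with ``allow_flip=True`` to instead flip dosages).
    """
    if genotype_format == "vcf":
        geno = read_genotypes_vcf(genotype_path)
    else:
        geno = read_genotypes_tsv(genotype_path)
    geno = geno.drop_high_missing(max_missing)
    ped = read_pedigree(pedigree_path)
    phen = read_phenotypes(phenotype_path)

    genotyped = set(geno.sample_id)
    n_ungeno = sum(1 for p in phen.table["person_id"] if p not in genotyped)
    if n_ungeno:
        logger.info("%d phenotyped persons lack genotypes", n_ungeno)
    phen.table = phen.table.assign(
        has_genotype=[p in genotyped for p in phen.table["person_id"]]
    )

    if weights_path is not None:
        w = read_weights(weights_path)
        alleles = dict(zip(geno.panel.snp_id, geno.panel.effect_allele))
        for snp, a1 in zip(w.table["snp_id"], w.table["effect_allele"]):
            if snp in alleles and alleles[snp] != a1:
                raise GenioError(
                    f"allele-code mismatch for SNP {snp}: genotype file counts "
                    f"{alleles[snp]!r}, weight table names {a1!r}"
                )
    return geno, ped, phen


# ---------------------------------------------------------------------------
# GCTA-style text GRM

def write_grm_gcta(grm, prefix: str | Path) -> None:
    """Write lower-triangle triplets to ``<prefix>.grm`` + ``<prefix>.grm.id``.

    Triplet lines are ``index_j  index_k  n_snps  A_jk`` for k <= j, 1-based,
    matching the GCTA text-GRM layout.
    """
    A = np.asarray(grm.A, dtype=float)
    if not np.isfinite(A).all():
        raise GenioError("GRM contains non-finite entries")
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise GenioError("GRM must be square and symmetric")
    prefix = str(prefix)
    n = A.shape[0]
    n_snps = np.asarray(grm.n_snps) * np.ones((n, n), dtype=int)
    with open(prefix + ".grm", "w") as fh:
        for j in range(n):
            for k in range(j + 1):
                fh.write(f"{j + 1}\t{k + 1}\t{n_snps[j, k]}\t{float(A[j, k])!r}\n")
    with open(prefix + ".grm.id", "w") as fh:
        for sid in grm.sample_id:
            fam = getattr(grm, "family_id", None)
            fh.write(f"{fam[sid] if fam else sid}\t{sid}\n")


def read_grm_gcta(prefix: str | Path):
    """Reconstruct a dense symmetric :class:`~polytrans.grm_greml.Grm`."""
    from .grm_greml import Grm  # deferred: grm_greml does not import genio

    prefix = str(prefix)
    ids = [line.split("\t")[1].strip()
           for line in open(prefix + ".grm.id") if line.strip()]
    n = len(ids)
    A = np.full((n, n), np.nan)
    n_snps = 0
    for line in open(prefix + ".grm"):
        j, k, m, a = line.split("\t")
        j, k = int(j) - 1, int(k) - 1
        A[j, k] = A[k, j] = float(a)
        n_snps = int(m)
    missing = [(j + 1, k + 1) for j in range(n) for k in range(j + 1)
               if np.isnan(A[j, k])]
    if missing:
        raise GenioError(f"missing lower-triangle entries: {missing[:10]}")
    return Grm(sample_id=ids, A=A, n_snps=n_snps)
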