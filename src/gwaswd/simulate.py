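"""Synthetic case-control genotype cohorts with known ground truth.

The generator emulates the kind of cohort a small GWAS classification
study works with: a diploid biallelic map with local linkage
disequilibrium, a handful of planted causal SNPs acting through a
logistic liability, case-control ascertainment to exact quotas, and
injectable data defects (missingness, Hardy-Weinberg violations,
related pairs, sex-labelling errors) for exercising the QC cascade.

Haplotypes are first-order Markov chains along the map: the latent
uniform behind allele ``j`` copies its left neighbour's with
probability ``ld_rho`` and is otherwise redrawn, so adjacent SNPs are
correlated while every site keeps its drawn allele frequency exactly.
A1 in the emitted .bim is the minor allele, so dosage counts
minor-allele copies.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .plink import CASE, CONTROL, MISSING, GenotypeMatrix, write_plink

__all__ = [
    "SimulationConfig", "CausalTruth", "simulate_cohort", "write_cohort",
    "planted_cohort_config",
]

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    ``causal_spec`` lists (variant index, per-allele odds ratio) pairs;
    indices refer to the emitted map order.  ``ld_rho`` is the
    probability that a haplotype allele copies its left neighbour on the
    same chromosome.  Defect counts plant QC-detectable artefacts after
    genotypes are drawn.
    """

    n_cases: int = 174
    n_controls: int = 214
    n_snps_per_chrom: dict[int, int] = dataclasses.field(
        default_factory=lambda: {c: 50 for c in range(1, 11)}
    )
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.2
    causal_spec: list[tuple[int, float]] = dataclasses.field(default_factory=list)
    target_prevalence: float = 0.15
    snp_missing_rate: float = 0.005
    n_hwe_violators: int = 0
    n_related_pairs: int = 0
    n_sex_errors: int = 0
    n_high_missing_snps: int = 0
    high_missing_snp_rate: float = 0.10
    n_high_missing_samples: int = 0
    high_missing_sample_rate: float = 0.30
    causal_maf_range: tuple[float, float] = (0.2, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if any(orr <= 0 for _, orr in self.causal_spec):
            raise ValueError("odds ratios must be positive")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie in (0, 1)")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def n_snps(self) -> int:
        return sum(self.n_snps_per_chrom.values())


@dataclasses.dataclass
class CausalTruth:
    """Ground truth emitted beside a simulated cohort."""

    causal: list[tuple[str, float]]  # (snp id, log-odds per allele)
    intercept: float
    hwe_violators: list[str]
    related_pairs: list[tuple[str, str]]
    sex_errors: list[str]
    high_missing_snps: list[str]
    high_missing_samples: list[str]

    @property
    def causal_ids(self) -> list[str]:
        return [snp for snp, _ in self.causal]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CausalTruth":
        d = json.loads(text)
        d["causal"] = [tuple(x) for x in d["causal"]]
        d["related_pairs"] = [tuple(x) for x in d["related_pairs"]]
        return cls(**d)


def planted_cohort_config(
    seed: int, *, n_snps: int = 5000, n_chrom: int = 20, n_causal: int = 10,
    or_range: tuple[float, float] = (2.0, 3.0), with_defects: bool = False,
    n_x_snps: int = 0,
) -> SimulationConfig:
    """The standard planted-signal study conditions.

    A 174-case / 214-control cohort over ``n_snps`` autosomal SNPs with
    ``n_causal`` planted causal SNPs whose per-allele odds ratios are
    evenly spaced across ``or_range``, placed evenly across the map away
    from chromosome edges.  ``with_defects`` additionally plants every
    QC-detectable artefact class (and an X chromosome for the sex check).
    """
    per = n_snps // n_chrom
    chrom_map = {c: per for c in range(1, n_chrom + 1)}
    chrom_map[n_chrom] += n_snps - per * n_chrom
    if n_x_snps or with_defects:
        chrom_map[23] = max(n_x_snps, 200)
    ors = np.linspace(*or_range, n_causal)
    # even placement, offset into the chromosome interior
    idx = (np.arange(n_causal) * (n_snps // n_causal) + per // 3).astype(int)
    defects = dict(
        n_hwe_violators=5, n_related_pairs=3, n_sex_errors=2,
        n_high_missing_snps=10, n_high_missing_samples=2,
    ) if with_defects else {}
    return SimulationConfig(
        n_cases=174, n_controls=214, n_snps_per_chrom=chrom_map,
        causal_spec=[(int(i), float(r)) for i, r in zip(idx, ors)],
        seed=seed, **defects,
    )


def _build_map(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom in sorted(cfg.n_snps_per_chrom):
        m = cfg.n_snps_per_chrom[chrom]
        pos = np.cumsum(rng.integers(500, 20_000, size=m))
        for k in range(m):
            a1, a2 = rng.choice(4, size=2, replace=False)
            rows.append((chrom, f"rs{chrom}_{k}", 0.0, int(pos[k]),
                         _BASES[a1], _BASES[a2]))
    return pd.DataFrame(rows, columns=["chrom", "snp", "cm", "pos", "a1", "a2"])


def _draw_haplotypes(
    maf: np.ndarray, chrom: np.ndarray, n_hap: int, ld_rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Markov haplotypes with exact per-site allele frequencies.

    A latent uniform runs down each chromosome, copied from the left
    neighbour with probability ``ld_rho`` and redrawn otherwise; the
    allele is the indicator ``U < maf``.  Copying the latent uniform
    (rather than the allele itself) keeps every site's marginal
    frequency exactly at its drawn MAF while still inducing
    positive allele correlation between map neighbours.
    """
    m = len(maf)
    U = np.empty((n_hap, m))
    fresh = rng.random((n_hap, m))
    copy = rng.random((n_hap, m)) < ld_rho
    U[:, 0] = fresh[:, 0]
    for j in range(1, m):
        if chrom[j] == chrom[j - 1]:
            U[:, j] = np.where(copy[:, j], U[:, j - 1], fresh[:, j])
        else:
            U[:, j] = fresh[:, j]
    return (U < maf[None, :]).astype(np.int8)


def _solve_intercept(
    scores: np.ndarray, target: float, limit: float = 50.0
) -> float:
    """Bisect alpha so mean(expit(alpha + score)) hits the target prevalence."""
    lo, hi = -limit, limit
    if expit(lo + scores).mean() > target or expit(hi + scores).mean() < target:
        raise ValueError("effect sizes inconsistent with prevalence")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(mid + scores).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(cfg: SimulationConfig) -> tuple[GenotypeMatrix, CausalTruth]:
    """Draw a cohort with exact case/control quotas and inject defects.

    Disease status follows ``logit P(case) = alpha + sum_j beta_j g_j``
    with the intercept solved for the target population prevalence;
    cases and controls are then accumulated by rejection sampling, so
    the emitted cohort is ascertained (case-enriched) the way a
    case-control study is.
    """
    rng = np.random.default_rng(cfg.seed)
    variants = _build_map(cfg, rng)
    chrom = variants["chrom"].to_numpy()
    m = len(variants)
    maf = rng.uniform(*cfg.maf_range, size=m)
    causal_idx = np.array([i for i, _ in cfg.causal_spec], dtype=int)
    if len(causal_idx):
        if causal_idx.max() >= m:
            raise ValueError("causal index beyond map")
        maf[causal_idx] = rng.uniform(*cfg.causal_maf_range, size=len(causal_idx))
    beta = np.zeros(m)
    for i, orr in cfg.causal_spec:
        beta[i] = np.log(orr)

    # sex: one X chromosome for males; X stored as homozygous diploid codes
    is_x = chrom == 23
    sex = rng.integers(1, 3, size=cfg.n_samples)  # 1 male, 2 female

    def draw_batch(k: int) -> np.ndarray:
        h1 = _draw_haplotypes(maf, chrom, k, cfg.ld_rho, rng)
        h2 = _draw_haplotypes(maf, chrom, k, cfg.ld_rho, rng)
        return (h1 + h2).astype(np.int8)

    # intercept from a pre-drawn candidate pool (population, not ascertained)
    pool = draw_batch(max(4096, cfg.n_samples))
    alpha = _solve_intercept(pool @ beta, cfg.target_prevalence)

    need = {CASE: cfg.n_cases, CONTROL: cfg.n_controls}
    got = {CASE: 0, CONTROL: 0}
    geno = np.empty((cfg.n_samples, m), dtype=np.int8)
    pheno = np.empty(cfg.n_samples, dtype=int)
    filled = 0
    batch = pool
    while filled < cfg.n_samples:
        if batch is None:
            batch = draw_batch(2048)
        is_case = rng.random(len(batch)) < expit(alpha + batch @ beta)
        for row, case in zip(batch, is_case):
            label = CASE if case else CONTROL
            if got[label] < need[label]:
                geno[filled] = row
                pheno[filled] = label
                got[label] += 1
                filled += 1
                if filled == cfg.n_samples:
                    break
        batch = None

    # interleave cases/controls in fam order deterministically
    order = rng.permutation(cfg.n_samples)
    geno, pheno = geno[order], pheno[order]

    # X hemizygosity: males get a single haplotype, stored 0/2
    if is_x.any():
        male = sex == 1
        if male.any():
            hap = _draw_haplotypes(maf[is_x], chrom[is_x], int(male.sum()), cfg.ld_rho, rng)
            geno[np.ix_(male, is_x)] = (2 * hap).astype(np.int8)

    samples = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(cfg.n_samples)],
            "iid": [f"I{i:04d}" for i in range(cfg.n_samples)],
            "father": "0",
            "mother": "0",
            "sex": sex,
            "phenotype": pheno,
        }
    )

    # ---- defect injection -------------------------------------------------
    snp_ids = variants["snp"].to_numpy()
    autosomal_noncausal = np.flatnonzero((chrom <= 22) & (beta == 0.0))
    rng_defect = np.random.default_rng(rng.integers(2**31))

    hwe_violators: list[str] = []
    if cfg.n_hwe_violators:
        chosen = rng_defect.choice(autosomal_noncausal, cfg.n_hwe_violators, replace=False)
        for j in chosen:
            # violators must be common: at ~200 controls the exact test only
            # reaches p < 1e-6 for F = -0.5 when MAF is ~0.3 or higher
            p = max(0.35, maf[j])
            probs = np.array([
                max(0.0, (1 - p) ** 2 + -0.5 * p * (1 - p)),  # hom A2, F=-0.5
                2 * p * (1 - p) * 1.5,                        # het excess
                max(0.0, p**2 + -0.5 * p * (1 - p)),          # hom A1
            ])
            probs /= probs.sum()
            geno[:, j] = rng_defect.choice(
                np.array([0, 1, 2], dtype=np.int8), size=cfg.n_samples, p=probs
            )
        hwe_violators = [str(s) for s in snp_ids[chosen]]
        autosomal_noncausal = np.setdiff1d(autosomal_noncausal, chosen)

    high_missing_snps: list[str] = []
    if cfg.n_high_missing_snps:
        chosen = rng_defect.choice(autosomal_noncausal, cfg.n_high_missing_snps, replace=False)
        for j in chosen:
            mask = rng_defect.random(cfg.n_samples) < cfg.high_missing_snp_rate
            geno[mask, j] = MISSING
        high_missing_snps = [str(s) for s in snp_ids[chosen]]

    related_pairs: list[tuple[str, str]] = []
    sample_pool = list(range(cfg.n_samples))
    if cfg.n_related_pairs:
        chosen = rng_defect.choice(sample_pool, 2 * cfg.n_related_pairs, replace=False)
        for k in range(cfg.n_related_pairs):
            a, b = int(chosen[2 * k]), int(chosen[2 * k + 1])
            geno[b] = geno[a]
            redraw = rng_defect.random(m) < 0.01  # 1% per-site redraw
            geno[b, redraw] = rng_defect.integers(0, 3, size=int(redraw.sum()), dtype=np.int8)
            sex[b] = sex[a]  # keep X coherent with the copied genotypes
            samples.loc[b, "sex"] = sex[a]
            related_pairs.append((samples["iid"].iloc[a], samples["iid"].iloc[b]))
        sample_pool = [s for s in sample_pool if s not in set(map(int, chosen))]

    sex_errors: list[str] = []
    if cfg.n_sex_errors:
        chosen = rng_defect.choice(sample_pool, cfg.n_sex_errors, replace=False)
        for s in chosen:
            samples.loc[int(s), "sex"] = 3 - int(samples.loc[int(s), "sex"])
        sex_errors = samples["iid"].iloc[sorted(map(int, chosen))].tolist()
        sample_pool = [s for s in sample_pool if s not in set(map(int, chosen))]

    high_missing_samples: list[str] = []
    if cfg.n_high_missing_samples:
        chosen = rng_defect.choice(sample_pool, cfg.n_high_missing_samples, replace=False)
        for s in chosen:
            mask = rng_defect.random(m) < cfg.high_missing_sample_rate
            geno[int(s), mask] = MISSING
        high_missing_samples = samples["iid"].iloc[sorted(map(int, chosen))].tolist()

    # background MCAR missingness everywhere else
    if cfg.snp_missing_rate > 0:
        mcar = rng_defect.random(geno.shape) < cfg.snp_missing_rate
        geno[mcar] = MISSING

    G = GenotypeMatrix(geno, variants, samples)
    truth = CausalTruth(
        causal=[(str(snp_ids[i]), float(np.log(orr))) for i, orr in cfg.causal_spec],
        intercept=float(alpha),
        hwe_violators=hwe_violators,
        related_pairs=related_pairs,
        sex_errors=sex_errors,
        high_missing_snps=high_missing_snps,
        high_missing_samples=high_missing_samples,
    )
    return G, truth


def write_cohort(G: GenotypeMatrix, truth: CausalTruth, prefix) -> None:
    """Write the PLINK triplet, the truth JSON and a per-SNP summary TSV."""
    prefix = Path(prefix)
    write_plink(G, prefix)
    (prefix.parent / f"{prefix.name}.truth.json").write_text(truth.to_json())
    valid = G.dosages != MISSING
    from .qc import minor_allele_frequency

    summary = pd.DataFrame(
        {
            "snp": G.variants["snp"],
            "chrom": G.variants["chrom"],
            "pos": G.variants["pos"],
            "maf": minor_allele_frequency(G),
            "call_rate": valid.mean(axis=0),
        }
    )
    summary.to_csv(prefix.parent / f"{prefix.name}.snpsummary.tsv", sep="\t", index=False)
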