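"""Quality control for case-control genotype cohorts.

The cascade applies, in a fixed order: SNP missingness, sample
missingness, sex check against X-chromosome homozygosity, autosome
restriction, minor-allele-frequency filter, Hardy-Weinberg exact test
(controls then cases), relatedness (pi-hat, lowest-call-rate member
removed), and an optional ethnicity/stratification filter driven by a
sample-metadata table.  Each step records what it removed in a
:class:`QCReport`, whose totals always reconcile with the dimension
change of the matrix.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd

from .plink import MISSING, GenotypeMatrix

__all__ = [
    "QCThresholds", "QCReport", "SexCheckResult", "RelatednessEstimate",
    "hwe_exact_test", "filter_snp_missingness", "filter_sample_missingness",
    "sex_check", "filter_sex_discrepancy", "filter_autosomes", "filter_maf",
    "filter_hwe", "estimate_pi_hat", "pairwise_pi_hat", "filter_related",
    "filter_ethnicity", "run_qc",
]


@dataclasses.dataclass
class QCThresholds:
    """Thresholds of the QC cascade (defaults follow common GWAS practice)."""

    snp_missing_max: float = 0.02
    sample_missing_max: float = 0.2
    maf_min: float = 0.05
    hwe_controls_p: float = 1e-6
    hwe_cases_p: float = 1e-10
    f_male_min: float = 0.8
    f_female_max: float = 0.2
    pihat_max: float = 0.2
    allowed_ethnicities: frozenset | None = None
    remove_sex_discrepant: bool = True

    def __post_init__(self) -> None:
        for name in ("snp_missing_max", "sample_missing_max", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("hwe_controls_p", "hwe_cases_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")


@dataclasses.dataclass
class QCStep:
    name: str
    axis: str  # "variant" or "sample"
    removed_ids: list[str]

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)


@dataclasses.dataclass
class QCReport:
    """Per-step removal record for one cascade run."""

    steps: list[QCStep] = dataclasses.field(default_factory=list)
    n_samples_in: int = 0
    n_variants_in: int = 0
    n_samples_out: int = 0
    n_variants_out: int = 0

    def add(self, name: str, axis: str, removed_ids) -> None:
        self.steps.append(QCStep(name, axis, list(map(str, removed_ids))))

    def removed_total(self, axis: str) -> int:
        return sum(s.n_removed for s in self.steps if s.axis == axis)

    def reconciles(self) -> bool:
        return (
            self.removed_total("variant") == self.n_variants_in - self.n_variants_out
            and self.removed_total("sample") == self.n_samples_in - self.n_samples_out
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "dimensions": {
                    "in": [self.n_samples_in, self.n_variants_in],
                    "out": [self.n_samples_out, self.n_variants_out],
                },
                "steps": [
                    {"name": s.name, "axis": s.axis, "n_removed": s.n_removed,
                     "removed_ids": s.removed_ids}
                    for s in self.steps
                ],
            },
            indent=2,
        )


@dataclasses.dataclass
class SexCheckResult:
    iid: str
    f_coefficient: float
    inferred_sex: int  # 0 undetermined, 1 male, 2 female
    reported_sex: int
    discrepant: bool


@dataclasses.dataclass
class RelatednessEstimate:
    iid1: str
    iid2: str
    pi_hat: float
    ibd_probs: tuple[float, float, float]


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided HWE p-value conditional on the allele counts.

    Sums the conditional probabilities of every heterozygote count (of the
    same parity as the observed one) that is no more probable than the
    observed count.  Probabilities follow the standard recurrence in the
    heterozygote count; no mid-p correction is applied.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one genotype required")
    rare = 2 * min(n_hom1, n_hom2) + n_het  # rare-allele copies
    # attainable het counts share the parity of `rare`
    het_min = rare % 2
    het_max = min(rare, 2 * n - rare)
    n_configs = (het_max - het_min) // 2 + 1
    if n_configs == 1:
        return 1.0

    probs = np.zeros(n_configs)
    # start from the largest het count and recur downward:
    # P(het-2) / P(het) = het*(het-1) / (4*(hom1+1)*(hom2+1))
    probs[-1] = 1.0
    het = het_max
    hom_rare = (rare - het) // 2
    hom_common = n - het - hom_rare
    for i in range(n_configs - 2, -1, -1):
        probs[i] = probs[i + 1] * het * (het - 1) / (
            4.0 * (hom_rare + 1) * (hom_common + 1)
        )
        het -= 2
        hom_rare += 1
        hom_common += 1
    probs /= probs.sum()
    p_obs = probs[(n_het - het_min) // 2]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _genotype_counts(dosages_col: np.ndarray) -> tuple[int, int, int]:
    obs = dosages_col[dosages_col != MISSING]
    return int((obs == 2).sum()), int((obs == 1).sum()), int((obs == 0).sum())


# ---------------------------------------------------------------------------
# Single filters
# ---------------------------------------------------------------------------

def filter_snp_missingness(
    G: GenotypeMatrix, max_rate: float = 0.02
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop variants whose missing-call fraction exceeds ``max_rate``."""
    miss = (G.dosages == MISSING).mean(axis=0)
    keep = miss <= max_rate
    removed = G.variants.loc[~keep, "snp"].tolist()
    return G.take_variants(np.flatnonzero(keep)), removed


def filter_sample_missingness(
    G: GenotypeMatrix, max_rate: float = 0.2
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop samples whose missing-call fraction exceeds ``max_rate``."""
    miss = (G.dosages == MISSING).mean(axis=1)
    keep = miss <= max_rate
    removed = G.samples.loc[~keep, "iid"].tolist()
    return G.take_samples(np.flatnonzero(keep)), removed


def sex_check(
    G: GenotypeMatrix, f_male_min: float = 0.8, f_female_max: float = 0.2
) -> list[SexCheckResult]:
    """Infer sex from X-chromosome homozygosity.

    Per sample, ``F = (obs_hom - exp_hom) / (n_used - exp_hom)`` over
    non-missing X genotypes, with the expected homozygosity ``1 - 2pq``
    accumulated from pooled X allele frequencies.  Males (one X) appear
    fully homozygous (F near 1); females at Hardy-Weinberg proportions
    give F near 0.
    """
    on_x = G.variants["chrom"].to_numpy() == 23
    if not on_x.any():
        warnings.warn("sex check skipped: no X-chromosome variants")
        return []
    X = G.dosages[:, on_x]
    valid = X != MISSING
    with np.errstate(invalid="ignore"):
        p = np.where(
            valid.sum(axis=0) > 0,
            np.where(valid, X, 0).sum(axis=0) / np.maximum(2 * valid.sum(axis=0), 1),
            0.5,
        )
    exp_het = 2.0 * p * (1.0 - p)
    obs_hom = ((X == 0) | (X == 2)).sum(axis=1)
    n_used = valid.sum(axis=1)
    exp_hom = np.where(valid, 1.0 - exp_het[None, :], 0.0).sum(axis=1)

    results = []
    for i in range(G.n_samples):
        denom = n_used[i] - exp_hom[i]
        f = float((obs_hom[i] - exp_hom[i]) / denom) if denom > 0 else 0.0
        inferred = 1 if f > f_male_min else (2 if f < f_female_max else 0)
        reported = int(G.samples["sex"].iloc[i])
        discrepant = inferred != 0 and reported in (1, 2) and inferred != reported
        results.append(
            SexCheckResult(str(G.samples["iid"].iloc[i]), f, inferred, reported, discrepant)
        )
    return results


def filter_sex_discrepancy(
    G: GenotypeMatrix, f_male_min: float = 0.8, f_female_max: float = 0.2
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove samples whose reported sex conflicts with the X-based inference."""
    results = sex_check(G, f_male_min, f_female_max)
    if not results:
        return G, []
    bad = {r.iid for r in results if r.discrepant}
    keep = ~G.samples["iid"].astype(str).isin(bad).to_numpy()
    return G.take_samples(np.flatnonzero(keep)), sorted(bad)


def filter_autosomes(G: GenotypeMatrix) -> GenotypeMatrix:
    """Keep chromosomes 1-22 only."""
    keep = G.variants["chrom"].between(1, 22).to_numpy()
    return G.take_variants(np.flatnonzero(keep))


def minor_allele_frequency(G: GenotypeMatrix) -> np.ndarray:
    """Per-variant MAF over non-missing calls (NaN when fully missing)."""
    valid = G.dosages != MISSING
    n_alleles = 2 * valid.sum(axis=0)
    a1 = np.where(valid, G.dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, a1 / np.maximum(n_alleles, 1), np.nan)
    return np.minimum(freq, 1.0 - freq)


def filter_maf(
    G: GenotypeMatrix, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop variants with MAF below ``min_maf`` (boundary retained)."""
    maf = minor_allele_frequency(G)
    keep = maf >= min_maf  # NaN compares False -> fully-missing variants dropped
    removed = G.variants.loc[~keep, "snp"].tolist()
    return G.take_variants(np.flatnonzero(keep)), removed


def _hwe_pass(G: GenotypeMatrix, sample_mask: np.ndarray, alpha: float) -> np.ndarray:
    sub = G.dosages[sample_mask]
    keep = np.ones(G.n_variants, dtype=bool)
    for j in range(G.n_variants):
        counts = _genotype_counts(sub[:, j])
        if sum(counts) == 0:
            continue
        if hwe_exact_test(*counts) < alpha:
            keep[j] = False
    return keep


def filter_hwe(
    G: GenotypeMatrix, controls_p: float = 1e-6, cases_p: float = 1e-10
) -> tuple[GenotypeMatrix, list[str]]:
    """Two sequential HWE passes: controls at ``controls_p``, then cases."""
    removed: list[str] = []
    controls = G.control_mask()
    if controls.any():
        keep = _hwe_pass(G, controls, controls_p)
        removed += G.variants.loc[~keep, "snp"].tolist()
        G = G.take_variants(np.flatnonzero(keep))
    else:
        warnings.warn("controls pass skipped: no controls present")
    cases = G.case_mask()
    if cases.any():
        keep = _hwe_pass(G, cases, cases_p)
        removed += G.variants.loc[~keep, "snp"].tolist()
        G = G.take_variants(np.flatnonzero(keep))
    return G, removed


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------

def _ibd_expectations(p: np.ndarray) -> tuple[float, float, float, float, float]:
    """Per-site IBS-class probabilities under IBD 0/1, summed over sites."""
    q = 1.0 - p
    e_ibs0_ibd0 = float((2 * p**2 * q**2).sum())
    e_ibs1_ibd0 = float((4 * p**3 * q + 4 * p * q**3).sum())
    e_ibs2_ibd0 = float((p**4 + q**4 + 4 * p**2 * q**2).sum())
    e_ibs1_ibd1 = float((2 * p**2 * q + 2 * p * q**2).sum())
    e_ibs2_ibd1 = float((p**2 + q**2).sum())
    return e_ibs0_ibd0, e_ibs1_ibd0, e_ibs2_ibd0, e_ibs1_ibd1, e_ibs2_ibd1


def _pi_hat_from_ibs(n0, n1, n2, n_valid, expectations, m_total) -> tuple[float, tuple]:
    e00, e10, e20, e11, e21 = (e * (n_valid / m_total) for e in expectations)
    p0 = n0 / e00 if e00 > 0 else 0.0
    p1 = (n1 - p0 * e10) / e11 if e11 > 0 else 0.0
    p2 = (n2 - p0 * e20 - p1 * e21) / n_valid if n_valid > 0 else 0.0
    # clip to the probability simplex
    p0, p1, p2 = (max(0.0, v) for v in (p0, p1, p2))
    total = p0 + p1 + p2
    if total > 0:
        p0, p1, p2 = p0 / total, p1 / total, p2 / total
    pi_hat = min(1.0, max(0.0, p1 / 2.0 + p2))
    return pi_hat, (p0, p1, p2)


def _autosomal_freq_and_masks(G: GenotypeMatrix):
    auto = G.variants["chrom"].between(1, 22).to_numpy()
    D = G.dosages[:, auto]
    valid = D != MISSING
    denom = np.maximum(2 * valid.sum(axis=0), 1)
    p = np.where(valid, D, 0).sum(axis=0) / denom
    informative = (p > 0) & (p < 1)
    return D[:, informative], valid[:, informative], p[informative]


def estimate_pi_hat(G: GenotypeMatrix, i: int, j: int) -> RelatednessEstimate | None:
    """PLINK-style method-of-moments IBD estimate for one sample pair.

    IBS 0/1/2 site counts are converted into IBD-state probabilities
    using allele-frequency expectations (frequencies estimated from the
    full matrix, no finite-sample correction), clipped to the simplex;
    ``pi_hat = P(IBD=1)/2 + P(IBD=2)``.
    """
    D, valid, p = _autosomal_freq_and_masks(G)
    both = valid[i] & valid[j]
    n_valid = int(both.sum())
    if n_valid < 100:
        warnings.warn(f"pair ({i}, {j}) skipped: only {n_valid} overlapping calls")
        return None
    diff = np.abs(D[i, both].astype(int) - D[j, both].astype(int))
    n0, n1, n2 = int((diff == 2).sum()), int((diff == 1).sum()), int((diff == 0).sum())
    pi_hat, probs = _pi_hat_from_ibs(
        n0, n1, n2, n_valid, _ibd_expectations(p), D.shape[1]
    )
    return RelatednessEstimate(
        str(G.samples["iid"].iloc[i]), str(G.samples["iid"].iloc[j]), pi_hat, probs
    )


def pairwise_pi_hat(G: GenotypeMatrix, sample_index: np.ndarray | None = None) -> pd.DataFrame:
    """pi-hat for every sample pair (vectorised over indicator matmuls)."""
    D, valid, p = _autosomal_freq_and_masks(G)
    if sample_index is None:
        sample_index = np.arange(G.n_samples)
    D = D[sample_index]
    valid = valid[sample_index]
    expectations = _ibd_expectations(p)
    m_total = D.shape[1]

    ind = [(valid & (D == d)).astype(np.float32) for d in (0, 1, 2)]
    n_valid = valid.astype(np.float32) @ valid.astype(np.float32).T
    ibs0 = ind[0] @ ind[2].T + ind[2] @ ind[0].T
    ibs2 = sum(a @ a.T for a in ind)
    ibs1 = n_valid - ibs0 - ibs2

    rows = []
    iids = G.samples["iid"].astype(str).to_numpy()[sample_index]
    k = len(sample_index)
    for a in range(k):
        for b in range(a + 1, k):
            nv = n_valid[a, b]
            if nv < 100:
                continue
            pi_hat, probs = _pi_hat_from_ibs(
                ibs0[a, b], ibs1[a, b], ibs2[a, b], nv, expectations, m_total
            )
            rows.append((iids[a], iids[b], int(sample_index[a]), int(sample_index[b]), pi_hat))
    return pd.DataFrame(rows, columns=["iid1", "iid2", "idx1", "idx2", "pi_hat"])


def filter_related(
    G: GenotypeMatrix, pihat_max: float = 0.2
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove one member of each related founder pair (pi-hat above threshold).

    Only founders (father and mother ids "0") are considered.  The member
    with the lower call rate is removed; ties break toward the
    lexicographically larger individual id so the outcome is deterministic.
    """
    founders = (
        (G.samples["father"].astype(str) == "0")
        & (G.samples["mother"].astype(str) == "0")
    ).to_numpy()
    idx = np.flatnonzero(founders)
    if len(idx) < 2:
        return G, []
    pairs = pairwise_pi_hat(G, idx)
    flagged = pairs[pairs["pi_hat"] > pihat_max]
    if flagged.empty:
        return G, []
    call_rate = (G.dosages != MISSING).mean(axis=1)
    iids = G.samples["iid"].astype(str)
    to_remove: set[str] = set()
    for _, row in flagged.iterrows():
        i, j = int(row["idx1"]), int(row["idx2"])
        if iids.iloc[i] in to_remove or iids.iloc[j] in to_remove:
            continue
        if call_rate[i] < call_rate[j]:
            victim = i
        elif call_rate[j] < call_rate[i]:
            victim = j
        else:
            victim = i if iids.iloc[i] > iids.iloc[j] else j
        to_remove.add(iids.iloc[victim])
    keep = ~iids.isin(to_remove).to_numpy()
    return G.take_samples(np.flatnonzero(keep)), sorted(to_remove)


def filter_ethnicity(
    G: GenotypeMatrix, metadata: pd.DataFrame | None, allowed: set | frozenset | None
) -> tuple[GenotypeMatrix, list[str]]:
    """Keep samples whose metadata ethnicity label is in ``allowed``.

    ``metadata`` maps individual id to an ethnicity label (columns ``iid``,
    ``ethnicity``).  With no metadata or no allowed set the step is a no-op.
    """
    if metadata is None or allowed is None:
        return G, []
    labels = metadata.set_index(metadata["iid"].astype(str))["ethnicity"]
    iids = G.samples["iid"].astype(str)
    unlabelled = [s for s in iids if s not in labels.index]
    if unlabelled:
        raise ValueError(f"unlabelled sample(s): {unlabelled[:5]}")
    keep = iids.map(labels).isin(set(allowed)).to_numpy()
    removed = iids[~keep].tolist()
    return G.take_samples(np.flatnonzero(keep)), removed


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def run_qc(
    G: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    metadata: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the full QC cascade in its fixed order and report every removal."""
    t = thresholds or QCThresholds()
    report = QCReport(
        n_samples_in=G.n_samples, n_variants_in=G.n_variants
    )

    G, removed = filter_snp_missingness(G, t.snp_missing_max)
    report.add("snp_missingness", "variant", removed)

    G, removed = filter_sample_missingness(G, t.sample_missing_max)
    report.add("sample_missingness", "sample", removed)

    if t.remove_sex_discrepant:
        G, removed = filter_sex_discrepancy(G, t.f_male_min, t.f_female_max)
        report.add("sex_discrepancy", "sample", removed)

    before = G.variants["snp"].tolist()
    G = filter_autosomes(G)
    report.add("autosomes", "variant", sorted(set(before) - set(G.variants["snp"]))
               if len(before) != G.n_variants else [])

    G, removed = filter_maf(G, t.maf_min)
    report.add("maf", "variant", removed)

    G, removed = filter_hwe(G, t.hwe_controls_p, t.hwe_cases_p)
    report.add("hwe", "variant", removed)

    G, removed = filter_related(G, t.pihat_max)
    report.add("relatedness", "sample", removed)

    G, removed = filter_ethnicity(G, metadata, t.allowed_ethnicities)
    report.add("ethnicity", "sample", removed)

    report.n_samples_out, report.n_variants_out = G.n_samples, G.n_variants
    if G.n_samples == 0 or G.n_variants == 0:
        raise ValueError("QC removed all data")
    assert report.reconciles()
    return G, report
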