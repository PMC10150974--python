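"""QC cascade: exact HWE test, filters, sex check, relatedness."""

import numpy as np
import pytest
from scipy.special import gammaln

import gwaswd.qc as qc
from gwaswd import GenotypeMatrix, SimulationConfig, hwe_exact_test, simulate_cohort

from conftest import make_matrix


# ---------------------------------------------------------------------------
# HWE exact test vs a direct-enumeration oracle
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_hom1, n_het, n_hom2):
    """Full enumeration with log-factorial probabilities (independent path)."""
    n = n_hom1 + n_het + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het
    common = 2 * n - rare

    def log_prob(het):
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            gammaln(n + 1)
            - gammaln(hom_rare + 1) - gammaln(het + 1) - gammaln(hom_common + 1)
            + het * np.log(2)
            + gammaln(rare + 1) + gammaln(common + 1) - gammaln(2 * n + 1)
        )

    hets = np.arange(rare % 2, min(rare, common) + 1, 2)
    logp = np.array([log_prob(h) for h in hets])
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[list(hets).index(n_het)]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


@pytest.mark.parametrize(
    "counts",
    [(0, 0, 100), (25, 50, 25), (50, 0, 50), (3, 4, 5), (0, 11, 0), (1, 0, 1)],
)
def test_hwe_matches_enumeration_spot(counts):
    assert hwe_exact_test(*counts) == pytest.approx(
        hwe_enumeration_oracle(*counts), abs=1e-12
    )


def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(0, 0, 100) == 1.0
    assert hwe_exact_test(42, 0, 0) == 1.0


def test_hwe_extreme_hom_split_tiny_p():
    assert hwe_exact_test(50, 0, 50) < 1e-20


def test_hwe_sweep_small_totals():
    for total in range(1, 26):
        for a in range(total + 1):
            for b in range(total - a + 1):
                c = total - a - b
                assert hwe_exact_test(a, b, c) == pytest.approx(
                    hwe_enumeration_oracle(a, b, c), abs=1e-10
                )


def test_hwe_invalid_counts():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 0, 1)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


# ---------------------------------------------------------------------------
# Missingness / MAF filters
# ---------------------------------------------------------------------------

def test_snp_missingness_counts():
    # 10 variants with 0..9 missing calls among 100 samples, threshold 0.02
    d = np.ones((100, 10), dtype=np.int8)
    for j in range(10):
        d[:j, j] = -1
    d[:, 0] = [0, 1] * 50  # keep some variation
    G = make_matrix(d)
    G2, removed = qc.filter_snp_missingness(G, 0.02)
    assert len(removed) == 7  # 3% .. 9% missing all exceed 2%
    assert G2.n_variants == 3


def test_snp_missingness_threshold_one_keeps_all(rng):
    from conftest import random_matrix

    G = random_matrix(rng, 20, 10, missing_rate=0.5)
    G2, removed = qc.filter_snp_missingness(G, 1.0)
    assert removed == [] and G2.n_variants == 10


def test_sample_missingness_rates():
    d = np.ones((4, 100), dtype=np.int8)
    for i, rate in enumerate([0.1, 0.19, 0.21, 0.5]):
        d[i, : int(rate * 100)] = -1
    G = make_matrix(d)
    G2, removed = qc.filter_sample_missingness(G, 0.2)
    assert len(removed) == 2
    assert G2.n_samples == 2


def test_filter_idempotent(rng):
    from conftest import random_matrix

    G = random_matrix(rng, 30, 20, missing_rate=0.15)
    once, _ = qc.filter_snp_missingness(G, 0.1)
    twice, removed = qc.filter_snp_missingness(once, 0.1)
    assert removed == [] and twice == once


def test_maf_boundary_retained():
    # 10 copies of A1 out of 200 alleles -> MAF exactly 0.05, kept at 0.05
    d = np.zeros((100, 1), dtype=np.int8)
    d[:10, 0] = 1
    G = make_matrix(d)
    G2, removed = qc.filter_maf(G, 0.05)
    assert removed == [] and G2.n_variants == 1


def test_maf_monomorphic_removed():
    G = make_matrix(np.zeros((50, 1), dtype=np.int8))
    _, removed = qc.filter_maf(G, 0.01)
    assert removed == ["rs0"]


def test_maf_monotone(rng):
    from conftest import random_matrix

    G = random_matrix(rng, 50, 30, missing_rate=0.0)
    removed_counts = [len(qc.filter_maf(G, t)[1]) for t in (0.01, 0.05, 0.1, 0.2)]
    assert removed_counts == sorted(removed_counts)


def test_autosome_filter():
    d = np.ones((4, 4), dtype=np.int8)
    G = make_matrix(d, chrom=[1, 22, 23, 26])
    G2 = qc.filter_autosomes(G)
    assert G2.variants["chrom"].tolist() == [1, 22]
    all_x = qc.filter_autosomes(make_matrix(d, chrom=[23] * 4))
    assert all_x.n_variants == 0


# ---------------------------------------------------------------------------
# Sex check
# ---------------------------------------------------------------------------

def test_sex_check_male_all_homozygous(rng):
    m = 60
    d = rng.choice([0, 2], size=(1, m)).astype(np.int8)
    female_rows = rng.integers(0, 3, size=(20, m)).astype(np.int8)
    G = make_matrix(
        np.vstack([d, female_rows]), chrom=[23] * m,
        sex=[2] + [2] * 20,  # reported female, genotypes say male
    )
    res = qc.sex_check(G)
    assert res[0].f_coefficient > 0.8
    assert res[0].inferred_sex == 1
    assert res[0].discrepant


def test_sex_check_female_hwe_proportions(rng):
    m, n = 500, 30
    p = rng.uniform(0.2, 0.5, size=m)
    h1 = (rng.random((n, m)) < p).astype(np.int8)
    h2 = (rng.random((n, m)) < p).astype(np.int8)
    G = make_matrix(h1 + h2, chrom=[23] * m, sex=[2] * n)
    res = qc.sex_check(G)
    for r in res:
        assert -0.2 < r.f_coefficient < 0.2
        assert r.inferred_sex == 2 and not r.discrepant


def test_sex_check_no_x_warns(rng):
    from conftest import random_matrix

    G = random_matrix(rng, 5, 5)
    with pytest.warns(UserWarning, match="sex check skipped"):
        assert qc.sex_check(G) == []


# ---------------------------------------------------------------------------
# HWE filter passes
# ---------------------------------------------------------------------------

def _two_group_matrix(controls, cases, rng, m=5):
    d = rng.integers(0, 3, size=(controls + cases, m)).astype(np.int8)
    phen = [1] * controls + [2] * cases
    return d, phen


def test_hwe_filter_case_only_moderate_violation_retained(rng):
    # a SNP whose case-group p sits between 1e-10 and 1e-6 survives the
    # case pass (threshold 1e-10) after passing the control pass
    controls, cases = 200, 200
    case_counts = (30, 140, 30)  # het excess at allele freq 0.5
    case_p = hwe_exact_test(*case_counts)
    assert 1e-10 < case_p < 1e-6  # fixture sits in the intended window
    d, phen = _two_group_matrix(controls, cases, rng)
    clean = rng.binomial(2, 0.5, size=controls).astype(np.int8)
    case_col = np.repeat([2, 1, 0], case_counts).astype(np.int8)
    d[:, 0] = np.concatenate([clean, case_col])
    G = make_matrix(d, phenotype=phen)
    _, removed = qc.filter_hwe(G, 1e-6, 1e-10)
    assert "rs0" not in removed


def test_hwe_filter_control_violator_removed(rng):
    controls, cases = 200, 100
    d, phen = _two_group_matrix(controls, cases, rng)
    d[:controls, 0] = np.array([1] * controls, dtype=np.int8)  # all het
    G = make_matrix(d, phenotype=phen)
    _, removed = qc.filter_hwe(G, 1e-6, 1e-10)
    assert "rs0" in removed


def test_hwe_filter_no_controls_warns(rng):
    d, _ = _two_group_matrix(0, 50, rng)
    G = make_matrix(d, phenotype=[2] * 50)
    with pytest.warns(UserWarning, match="controls pass skipped"):
        qc.filter_hwe(G, 1e-6, 1e-10)


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------

def _cohort_for_ibd(rng, n=40, m=2000):
    p = rng.uniform(0.1, 0.5, size=m)
    h = lambda k: (rng.random((k, m)) < p).astype(np.int8)
    return p, h


def test_pi_hat_duplicate_and_unrelated(rng):
    p, h = _cohort_for_ibd(rng, m=5000)
    g = h(40) + h(40)
    g[1] = g[0]  # duplicate pair
    G = make_matrix(g)
    dup = qc.estimate_pi_hat(G, 0, 1)
    assert dup.pi_hat >= 0.95
    unrelated = qc.estimate_pi_hat(G, 2, 3)
    assert unrelated.pi_hat < 0.05


def test_pi_hat_parent_child(rng):
    p, h = _cohort_for_ibd(rng, m=3000)
    shared = h(1)
    parent = (shared + h(1)).astype(np.int8)
    child = (shared + h(1)).astype(np.int8)
    others = (h(20) + h(20)).astype(np.int8)
    G = make_matrix(np.vstack([parent, child, others]))
    est = qc.estimate_pi_hat(G, 0, 1)
    assert 0.4 <= est.pi_hat <= 0.6


def test_pi_hat_insufficient_overlap_warns(rng):
    g = rng.integers(0, 3, size=(4, 150)).astype(np.int8)
    g[0, 80:] = -1
    g[1, :80] = -1
    G = make_matrix(g)
    with pytest.warns(UserWarning, match="skipped"):
        assert qc.estimate_pi_hat(G, 0, 1) is None


def test_filter_related_removes_lower_call_rate_member(rng):
    p, h = _cohort_for_ibd(rng)
    g = (h(30) + h(30)).astype(np.int8)
    g[5] = g[4]
    g[5, rng.choice(2000, 100, replace=False)] = -1  # sample 5: lower call rate
    G = make_matrix(g)
    G2, removed = qc.filter_related(G, 0.2)
    assert removed == ["I005"]
    assert G2.n_samples == 29


def test_filter_related_noop_when_unrelated(rng):
    p, h = _cohort_for_ibd(rng, n=20)
    G = make_matrix((h(20) + h(20)).astype(np.int8))
    G2, removed = qc.filter_related(G, 0.2)
    assert removed == [] and G2.n_samples == 20


# ---------------------------------------------------------------------------
# Ethnicity and full cascade
# ---------------------------------------------------------------------------

def test_ethnicity_filter(rng):
    import pandas as pd
    from conftest import random_matrix

    G = random_matrix(rng, 10, 5, missing_rate=0.0)
    meta = pd.DataFrame(
        {"iid": [f"I{i:03d}" for i in range(10)],
         "ethnicity": ["eur"] * 8 + ["other"] * 2}
    )
    G2, removed = qc.filter_ethnicity(G, meta, {"eur"})
    assert len(removed) == 2 and G2.n_samples == 8

    same, removed = qc.filter_ethnicity(G, None, None)  # no metadata: no-op
    assert removed == [] and same.n_samples == 10

    with pytest.raises(ValueError, match="unlabelled"):
        qc.filter_ethnicity(G, meta.iloc[:5], {"eur"})


def test_run_qc_clean_cohort_no_removals():
    cfg = SimulationConfig(
        n_cases=30, n_controls=30, n_snps_per_chrom={1: 1000, 2: 1000},
        maf_range=(0.15, 0.5), snp_missing_rate=0.0, seed=5,
    )
    G, _ = simulate_cohort(cfg)
    G2, report = qc.run_qc(G)
    assert report.reconciles()
    assert all(s.n_removed == 0 for s in report.steps)


def test_run_qc_report_reconciles(small_cohort):
    G, _ = small_cohort
    with pytest.warns(UserWarning):
        G2, report = qc.run_qc(G)
    assert report.reconciles()
    assert report.removed_total("variant") == report.n_variants_in - report.n_variants_out
    assert report.removed_total("sample") == report.n_samples_in - report.n_samples_out


def test_hwe_type1_rate(rng):
    # HWE-consistent SNPs at 200 controls: essentially none below 1e-6
    n, m = 200, 4000
    p = rng.uniform(0.05, 0.5, size=m)
    g = (rng.random((n, m)) < p).astype(np.int8) + (rng.random((n, m)) < p).astype(
        np.int8
    )
    n_reject = 0
    for j in range(m):
        col = g[:, j]
        pval = hwe_exact_test(
            int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())
        )
        n_reject += pval < 1e-6
    assert n_reject <= 3
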