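import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from snpmeta import (GenotypeCounts, allele_counts, contrast_table,
                     hwe_chi_square)
from snpmeta.errors import ValidationError

genotypes = st.tuples(st.integers(0, 500), st.integers(0, 500),
                      st.integers(0, 500)).filter(lambda t: sum(t) >= 1)


@pytest.mark.parametrize("counts, expected", [
    ((0, 0, 10), (0, 20)),
    ((10, 20, 30), (40, 80)),
    ((16, 48, 36), (80, 120)),
])
def test_allele_counts(counts, expected):
    assert allele_counts(GenotypeCounts(*counts)) == expected


@pytest.mark.parametrize("model, expected", [
    ("allelic", (40, 80, 35, 105)),
    ("homozygote", (10, 30, 5, 40)),
    ("heterozygote", (20, 30, 25, 40)),
    ("dominant", (30, 30, 30, 40)),
    ("recessive", (10, 50, 5, 65)),
])
def test_contrast_tables_from_hand_collapsed_classes(model, expected):
    t = contrast_table(GenotypeCounts(10, 20, 30), GenotypeCounts(5, 25, 40),
                       model)
    assert (t.a, t.b, t.c, t.d) == expected


def test_unknown_model_is_usage_error():
    with pytest.raises(ValidationError, match="model"):
        contrast_table(GenotypeCounts(1, 1, 1), GenotypeCounts(1, 1, 1),
                       "additive")


@given(cases=genotypes, controls=genotypes)
@settings(derandomize=True, max_examples=100)
def test_count_conservation_and_allele_doubling(cases, controls):
    ca, co = GenotypeCounts(*cases), GenotypeCounts(*controls)
    dom = contrast_table(ca, co, "dominant")
    rec = contrast_table(ca, co, "recessive")
    allelic = contrast_table(ca, co, "allelic")
    assert dom.a + dom.b == rec.a + rec.b == ca.total
    assert dom.c + dom.d == rec.c + rec.d == co.total
    assert allelic.a + allelic.b == 2 * ca.total
    assert allelic.c + allelic.d == 2 * co.total


@given(cases=genotypes, controls=genotypes)
@settings(derandomize=True, max_examples=100)
def test_allele_relabelling_swaps_dominant_and_recessive(cases, controls):
    """Relabelling M <-> W reverses genotype order; dominant becomes
    recessive with exposure classes swapped, homozygote flips a/b and c/d."""
    ca, co = GenotypeCounts(*cases), GenotypeCounts(*controls)
    ca_r = GenotypeCounts(*cases[::-1])
    co_r = GenotypeCounts(*controls[::-1])
    dom = contrast_table(ca, co, "dominant")
    rec_r = contrast_table(ca_r, co_r, "recessive")
    assert (dom.a, dom.b, dom.c, dom.d) == (rec_r.b, rec_r.a, rec_r.d, rec_r.c)
    hom = contrast_table(ca, co, "homozygote")
    hom_r = contrast_table(ca_r, co_r, "homozygote")
    assert (hom.a, hom.b, hom.c, hom.d) == (hom_r.b, hom_r.a, hom_r.d, hom_r.c)


@pytest.mark.parametrize("counts, chi2, p, mono", [
    ((16, 48, 36), 0.0, 1.0, False),   # exact HWE at allele freq 0.4
    ((30, 40, 30), 4.0, 0.0455, False),
    ((0, 0, 50), 0.0, 1.0, True),
    ((50, 0, 0), 0.0, 1.0, True),
])
def test_hwe_chi_square_hand_cases(counts, chi2, p, mono):
    res = hwe_chi_square(GenotypeCounts(*counts))
    assert res.chi2 == pytest.approx(chi2, abs=1e-12)
    assert res.p == pytest.approx(p, abs=5e-4)
    assert res.monomorphic is mono


@given(controls=genotypes)
@settings(derandomize=True, max_examples=150)
def test_hwe_matches_brute_force_pearson(controls):
    """Oracle: scipy's one-way chi-square on observed vs HWE-expected
    three-class vectors, with 1 df (one estimated parameter)."""
    g = GenotypeCounts(*controls)
    res = hwe_chi_square(g)
    n = g.total
    n_m = 2 * g.n_MM + g.n_MW
    p_hat = n_m / (2 * n)
    if p_hat in (0.0, 1.0):
        assert res.monomorphic
        return
    expected = np.array([n * p_hat**2, 2 * n * p_hat * (1 - p_hat),
                         n * (1 - p_hat) ** 2])
    chi2_ref = stats.chisquare(np.array(controls), expected,
                               ddof=1).statistic
    assert res.chi2 == pytest.approx(float(chi2_ref), rel=1e-10)
    assert res.p == pytest.approx(float(stats.chi2.sf(chi2_ref, 1)), rel=1e-10)
    assert res.chi2 >= 0
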