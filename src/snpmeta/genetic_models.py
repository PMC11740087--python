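"""Genetic-model contrast tables and the Hardy-Weinberg chi-square test.

Five standard ways of collapsing genotype counts (MM/MW/WW, M = variant
allele) into a 2x2 case-control exposure table:

================  =========================  =========================
model             exposed                    unexposed
================  =========================  =========================
allelic           M alleles                  W alleles
homozygote        MM                         WW   (MW excluded)
heterozygote      MW                         WW   (MM excluded)
dominant          MM + MW                    WW
recessive         MM                         MW + WW
================  =========================  =========================
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .errors import ValidationError
from .study_io import GenotypeCounts

#: Canonical model order, as presented in stratified report grids.
MODELS = ("allelic", "homozygote", "heterozygote", "dominant", "recessive")


@dataclass(frozen=True)
class ContrastTable:
    """2x2 exposure table (a, b | c, d) under one genetic model.

    a/b are exposed/unexposed counts in cases, c/d in controls.
    """

    model: str
    a: int
    b: int
    c: int
    d: int


@dataclass(frozen=True)
class HweResult:
    chi2: float
    p: float
    monomorphic: bool = False


def allele_counts(g: GenotypeCounts) -> tuple[int, int]:
    """Return (M allele count, W allele count): each genotype carries two."""
    return (2 * g.n_MM + g.n_MW, 2 * g.n_WW + g.n_MW)


def contrast_table(cases: GenotypeCounts, controls: GenotypeCounts,
                   model: str) -> ContrastTable:
    """Collapse genotype counts of both arms into a 2x2 exposure table."""
    if model == "allelic":
        a, b = allele_counts(cases)
        c, d = allele_counts(controls)
    elif model == "homozygote":
        a, b, c, d = cases.n_MM, cases.n_WW, controls.n_MM, controls.n_WW
    elif model == "heterozygote":
        a, b, c, d = cases.n_MW, cases.n_WW, controls.n_MW, controls.n_WW
    elif model == "dominant":
        a, b = cases.n_MM + cases.n_MW, cases.n_WW
        c, d = controls.n_MM + controls.n_MW, controls.n_WW
    elif model == "recessive":
        a, b = cases.n_MM, cases.n_MW + cases.n_WW
        c, d = controls.n_MM, controls.n_MW + controls.n_WW
    else:
        raise ValidationError(
            f"unknown genetic model {model!r} (expected one of {MODELS})")
    return ContrastTable(model=model, a=a, b=b, c=c, d=d)


def hwe_chi_square(controls: GenotypeCounts) -> HweResult:
    """Pearson chi-square goodness-of-fit test for Hardy-Weinberg equilibrium.

    The variant-allele frequency is estimated from the data, so the test has
    3 - 1 - 1 = 1 degree of freedom.  No continuity correction.  Monomorphic
    samples carry no information about HWE and return chi2 = 0, p = 1 with
    the ``monomorphic`` flag set.
    """
    n = controls.total
    if n < 1:
        raise ValidationError("control arm must contain at least one genotype")
    n_m, n_w = allele_counts(controls)
    p_hat = n_m / (2 * n)
    if p_hat == 0.0 or p_hat == 1.0:
        return HweResult(chi2=0.0, p=1.0, monomorphic=True)
    expected = (n * p_hat ** 2,
                2 * n * p_hat * (1 - p_hat),
                n * (1 - p_hat) ** 2)
    observed = controls.as_tuple()
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return HweResult(chi2=chi2, p=float(stats.chi2.sf(chi2, df=1)))
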