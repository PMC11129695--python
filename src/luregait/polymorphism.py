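"""Morph-ratio stability tests and exact Mendelian segregation tests.

Two small count-table analyses:

* temporal stability of the darter:leech lure ratio in a population, from a
  2×2 table of counts (time period × morph): the Pearson chi-square without
  continuity correction and the two-sided Fisher exact test are both
  reported, clearly labeled;
* exact binomial segregation tests of a brood's phenotype counts against the
  Mendelian expectation of a specified single-locus dominance model.  Unknown
  (possibly multiple) sires are modeled through a sire dominant-allele
  frequency rather than explicit sire genotypes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .events import Morph


class DamGenotype(str, enum.Enum):
    HOMOZYGOUS_DOMINANT = "homozygous_dominant"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS_RECESSIVE = "homozygous_recessive"


@dataclass(frozen=True)
class PhenotypeTable:
    """Counts of lure morphs per time period or sample (rows × morphs)."""

    row_labels: tuple[str, ...]
    column_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("phenotype table needs at least 2 rows and 2 columns")
        if (arr < 0).any():
            raise ValueError("phenotype counts must be non-negative")
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise ValueError("phenotype table has an all-zero margin")
        if len(self.row_labels) != arr.shape[0] or len(self.column_labels) != arr.shape[1]:
            raise ValueError("label lengths do not match the count matrix")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)


@dataclass(frozen=True)
class BroodCounts:
    """Phenotype counts of one brood, with the dam's own morph."""

    n_darter: int
    n_leech: int
    dam_morph: Morph

    def __post_init__(self) -> None:
        if self.n_darter < 0 or self.n_leech < 0:
            raise ValueError("brood counts must be non-negative")
        if self.dam_morph not in (Morph.DARTER, Morph.LEECH):
            raise ValueError("dam morph must be darter or leech")

    @property
    def total(self) -> int:
        return self.n_darter + self.n_leech

    def count(self, morph: Morph) -> int:
        return self.n_darter if morph == Morph.DARTER else self.n_leech


@dataclass(frozen=True)
class GeneticModel:
    """Single-locus, two-allele dominance model for the lure polymorphism.

    ``sire_dominant_freq`` is the frequency of the dominant allele among the
    (unknown, possibly multiple) sires' successful gametes.
    """

    dominant_morph: Morph
    dam_genotype: DamGenotype
    sire_dominant_freq: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sire_dominant_freq <= 1.0:
            raise ValueError("sire_dominant_freq must be in [0, 1]")
        if self.dominant_morph not in (Morph.DARTER, Morph.LEECH):
            raise ValueError("dominant morph must be darter or leech")

    @property
    def recessive_morph(self) -> Morph:
        return Morph.LEECH if self.dominant_morph == Morph.DARTER else Morph.DARTER

    def dam_morph(self) -> Morph:
        """Phenotype the dam genotype implies under this dominance relation."""
        if self.dam_genotype == DamGenotype.HOMOZYGOUS_RECESSIVE:
            return self.recessive_morph
        return self.dominant_morph

    def validate_against_dam(self, dam_morph: Morph) -> None:
        if self.dam_morph() != dam_morph:
            raise ValueError(
                f"dam genotype {self.dam_genotype.value} implies a "
                f"{self.dam_morph().value} phenotype, but the dam is "
                f"{dam_morph.value}"
            )


def phenotype_percentages(counts: tuple[int, ...] | np.ndarray) -> tuple[float, ...]:
    """Percent of each morph in one table row, rounded to one decimal."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("cannot compute percentages of a zero-total row")
    return tuple(round(100.0 * c / total, 1) for c in arr)


@dataclass
class StabilityTestResult:
    chi2: float
    chi2_p: float
    fisher_p: float
    dof: int = 1


def ratio_stability_test(table: PhenotypeTable) -> StabilityTestResult:
    """Chi-square (no continuity correction) and Fisher exact test of a 2×2 table.

    Both statistics are reported because small-sample practice varies; the
    chi-square is uncorrected, which is what reproduces published values
    computed with ``chisq.test(correct = FALSE)``-style conventions.
    """
    arr = table.array
    if arr.shape != (2, 2):
        raise ValueError(f"stability test needs a 2×2 table, got {arr.shape}")
    chi2, chi2_p, dof, _ = stats.chi2_contingency(arr, correction=False)
    _, fisher_p = stats.fisher_exact(arr, alternative="two-sided")
    return StabilityTestResult(
        chi2=float(chi2), chi2_p=float(chi2_p), fisher_p=float(fisher_p), dof=dof
    )


def _dam_dominant_gamete_prob(genotype: DamGenotype) -> float:
    return {
        DamGenotype.HOMOZYGOUS_DOMINANT: 1.0,
        DamGenotype.HETEROZYGOUS: 0.5,
        DamGenotype.HOMOZYGOUS_RECESSIVE: 0.0,
    }[genotype]


def expected_offspring_proportions(model: GeneticModel) -> dict[Morph, float]:
    """Mendelian expectation of each morph under random union of gametes.

    An offspring shows the recessive morph iff it receives a recessive allele
    from both the dam and the sire pool.
    """
    p_dam_dom = _dam_dominant_gamete_prob(model.dam_genotype)
    p_recessive = (1.0 - p_dam_dom) * (1.0 - model.sire_dominant_freq)
    return {
        model.dominant_morph: 1.0 - p_recessive,
        model.recessive_morph: p_recessive,
    }


@dataclass
class SegregationTestResult:
    expected_maternal_proportion: float
    observed_maternal_count: int
    n: int
    p_one_sided: float
    p_two_sided: float
    alpha: float
    verdict: str  # "rejected" | "not rejected" | "impossible under model"


def segregation_test(
    brood: BroodCounts,
    model: GeneticModel,
    alpha: float = 0.05,
) -> SegregationTestResult:
    """Exact binomial test of the maternal-morph count against the model.

    The one-sided p is the tail toward the observed deviation; the two-sided
    p sums all outcome probabilities not exceeding the observed outcome's
    (the mode-symmetric convention of standard exact-test routines).  A model
    expecting proportion 0 or 1 that the observations contradict returns
    p = 0 and the verdict ``"impossible under model"``.
    """
    if brood.total == 0:
        raise ValueError("brood has no offspring to test")
    model.validate_against_dam(brood.dam_morph)
    expected = expected_offspring_proportions(model)[brood.dam_morph]
    k, n = brood.count(brood.dam_morph), brood.total

    if (expected == 0.0 and k > 0) or (expected == 1.0 and k < n):
        return SegregationTestResult(
            expected_maternal_proportion=expected, observed_maternal_count=k,
            n=n, p_one_sided=0.0, p_two_sided=0.0, alpha=alpha,
            verdict="impossible under model",
        )

    if k / n <= expected:
        p_one = float(stats.binom.cdf(k, n, expected))
    else:
        p_one = float(stats.binom.sf(k - 1, n, expected))
    p_two = float(stats.binomtest(k, n, expected, alternative="two-sided").pvalue)
    verdict = "rejected" if p_one < alpha else "not rejected"
    return SegregationTestResult(
        expected_maternal_proportion=expected, observed_maternal_count=k,
        n=n, p_one_sided=p_one, p_two_sided=p_two, alpha=alpha, verdict=verdict,
    )
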