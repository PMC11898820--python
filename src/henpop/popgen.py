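"""Per-population SNP diversity statistics: allele frequencies, PIC, H_E, HWE.

For a biallelic locus with ref-allele frequency p (q = 1 - p):

* allele frequencies by gene counting, p = (2*n_refref + n_refalt) / (2n) —
  the maximum-likelihood estimator for a codominant marker;
* expected heterozygosity H_E = 1 - p^2 - q^2 = 2pq (no small-sample
  correction);
* polymorphism information content, biallelic Botstein form
  PIC = 1 - (p^2 + q^2) - 2 p^2 q^2 = H_E - 2 p^2 q^2, maximum 0.375 at
  p = 0.5;
* Hardy-Weinberg chi-square goodness of fit of observed genotype counts
  against expected (p^2 n, 2pq n, q^2 n), no continuity correction.

Two degrees-of-freedom conventions are supported for the HWE test:
``alleles_based`` (df = 1: three genotype classes minus one minus one
estimated allele frequency — the statistically standard choice) and
``classes_minus_1`` (df = 2, i.e. a 5.99 critical value at alpha = 0.05,
which some livestock diversity reports use).

Intermediate arithmetic uses exact rationals, so two-decimal report rounding
(half away from zero) is free of binary-float boundary artifacts.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd
from scipy import stats

from .core_data import GenotypeTable, LocusDef

__all__ = [
    "GenotypeCounts",
    "AlleleFreqs",
    "DiversityStats",
    "DegenerateInputError",
    "genotype_counts",
    "allele_frequencies",
    "expected_heterozygosity",
    "pic",
    "hwe_chisq",
    "HweResult",
    "diversity_table",
    "round_half_up",
    "pic_informativeness",
    "render_markdown",
]

ALL_POPULATIONS = "All"


class DegenerateInputError(ValueError):
    """No data left to compute a statistic (empty population, n = 0)."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Non-missing genotype counts at one locus in one population."""

    n_refref: int
    n_refalt: int
    n_altalt: int

    def __post_init__(self) -> None:
        if min(self.n_refref, self.n_refalt, self.n_altalt) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_refref + self.n_refalt + self.n_altalt

    @property
    def is_monomorphic(self) -> bool:
        p = Fraction(2 * self.n_refref + self.n_refalt, 2 * self.n)
        return p in (0, 1)


@dataclass(frozen=True)
class AlleleFreqs:
    """Ref/alt allele frequencies; exact rationals when gene-counted."""

    p: Fraction
    q: Fraction

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 and 0 <= self.q <= 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if abs(self.p + self.q - 1) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")


@dataclass(frozen=True)
class HweResult:
    chi2: float
    df: int
    p_value: float
    in_hwe: bool
    monomorphic: bool = False


@dataclass(frozen=True)
class DiversityStats:
    """One row of the diversity report: locus x population."""

    locus_id: str
    population: str
    counts: GenotypeCounts
    freqs: AlleleFreqs
    pic: float
    he: float
    hwe: HweResult


def genotype_counts(table: GenotypeTable, locus: LocusDef, population: str = ALL_POPULATIONS) -> GenotypeCounts:
    """Count non-missing ref-hom / het / alt-hom calls for one population.

    ``population`` is a breed label, or ``"All"`` to pool every breed.
    """
    if population == ALL_POPULATIONS:
        samples = table.samples
    else:
        samples = table.subset(population)
    if not samples:
        raise DegenerateInputError(f"no samples in population {population!r}")
    rr = ra = aa = 0
    hom_ref = (locus.ref_allele, locus.ref_allele)
    hom_alt = (locus.alt_allele, locus.alt_allele)
    for s in samples:
        call = s.calls.get(locus.locus_id)
        if call is None or call.is_missing:
            continue
        if call.alleles == hom_ref:
            rr += 1
        elif call.alleles == hom_alt:
            aa += 1
        else:
            ra += 1
    counts = GenotypeCounts(rr, ra, aa)
    if counts.n == 0:
        raise DegenerateInputError(
            f"no non-missing calls at {locus.locus_id} in population {population!r}"
        )
    return counts


def allele_frequencies(counts: GenotypeCounts) -> AlleleFreqs:
    """Gene-counting (ML) allele frequencies from genotype counts."""
    if counts.n == 0:
        raise DegenerateInputError("cannot estimate allele frequencies with n = 0")
    p = Fraction(2 * counts.n_refref + counts.n_refalt, 2 * counts.n)
    return AlleleFreqs(p, 1 - p)


def expected_heterozygosity(freqs: AlleleFreqs) -> Fraction:
    """H_E = 1 - p^2 - q^2 (= 2pq for two alleles), uncorrected."""
    return 1 - freqs.p * freqs.p - freqs.q * freqs.q


def pic(freqs: AlleleFreqs) -> Fraction:
    """Biallelic polymorphism information content, 1-(p^2+q^2)-2p^2q^2."""
    p2, q2 = freqs.p * freqs.p, freqs.q * freqs.q
    return 1 - (p2 + q2) - 2 * p2 * q2


def hwe_chisq(counts: GenotypeCounts, df_convention: str = "alleles_based") -> HweResult:
    """Hardy-Weinberg chi-square goodness-of-fit test.

    Expected counts are p^2 n, 2pq n, q^2 n with p gene-counted from the
    observed genotypes; the statistic is the plain Pearson sum over the three
    genotype classes (no continuity correction). A monomorphic locus returns
    chi2 = 0 with df = 0, flagged, and counts as "in HWE".
    """
    if df_convention not in ("alleles_based", "classes_minus_1"):
        raise ValueError(f"unknown df convention {df_convention!r}")
    if counts.n == 0:
        raise DegenerateInputError("cannot test HWE with n = 0")
    freqs = allele_frequencies(counts)
    if freqs.p in (0, 1):
        return HweResult(0.0, 0, 1.0, True, monomorphic=True)
    n = counts.n
    expected = (freqs.p**2 * n, 2 * freqs.p * freqs.q * n, freqs.q**2 * n)
    observed = (counts.n_refref, counts.n_refalt, counts.n_altalt)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    df = 1 if df_convention == "alleles_based" else 2
    p_value = float(stats.chi2.sf(float(chi2), df))
    return HweResult(float(chi2), df, p_value, p_value >= 0.05)


def diversity_table(
    table: GenotypeTable,
    populations=None,
    df_convention: str = "alleles_based",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full diversity report: one row per locus x population (+ pooled "All").

    Rows are ordered by locus (table order), then populations in the given
    order with the pooled "All" row last. Columns mirror the conventional
    genotype-and-allele-frequency report (genotype frequencies with counts,
    p, q, PIC, H_E, chi2) plus df, p_value and the HWE flag.
    """
    if populations is None:
        populations = table.breeds
    pops = list(populations) + [ALL_POPULATIONS]
    rows = []
    for locus in table.loci:
        for popn in pops:
            counts = genotype_counts(table, locus, popn)
            freqs = allele_frequencies(counts)
            he = expected_heterozygosity(freqs)
            pic_v = pic(freqs)
            hwe = hwe_chisq(counts, df_convention)
            in_hwe = hwe.monomorphic or hwe.p_value >= alpha
            n = counts.n
            rows.append(
                {
                    "locus": locus.locus_id,
                    "site": locus.display_name,
                    "population": popn,
                    "n": n,
                    "n_refref": counts.n_refref,
                    "n_refalt": counts.n_refalt,
                    "n_altalt": counts.n_altalt,
                    "freq_refref": counts.n_refref / n,
                    "freq_refalt": counts.n_refalt / n,
                    "freq_altalt": counts.n_altalt / n,
                    "p": float(freqs.p),
                    "q": float(freqs.q),
                    "pic": float(pic_v),
                    "he": float(he),
                    "pic_class": pic_informativeness(float(pic_v)),
                    "chi2": hwe.chi2,
                    "df": hwe.df,
                    "p_value": hwe.p_value,
                    "in_hwe": in_hwe,
                    "monomorphic": hwe.monomorphic,
                }
            )
    return pd.DataFrame(rows)


def round_half_up(value, ndigits: int = 2) -> float:
    """Round half away from zero, exactly, for Fractions and floats.

    Report tables round through :class:`fractions.Fraction` so values that
    sit exactly on a rounding boundary (e.g. 0.255) round the way a desk
    calculation would, not the way binary floats happen to fall.
    """
    frac = value if isinstance(value, Fraction) else Fraction(value).limit_denominator(10**12)
    d = decimal.Decimal(frac.numerator) / decimal.Decimal(frac.denominator)
    return float(d.quantize(decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP))


def pic_informativeness(pic_value: float) -> str:
    """Conventional marker-informativeness label for a PIC value."""
    if pic_value < 0.25:
        return "modest"
    if pic_value < 0.50:
        return "reasonable"
    return "high"


def render_markdown(report: pd.DataFrame) -> str:
    """Human-readable markdown rendering of a diversity report."""
    df = report.copy()
    for col in ("freq_refref", "freq_refalt", "freq_altalt", "p", "q", "pic", "he", "chi2"):
        df[col] = df[col].map(lambda v: f"{round_half_up(v):.2f}")
    df["p_value"] = df["p_value"].map(lambda v: f"{v:.4f}")
    cols = [
        "locus", "site", "population", "n",
        "freq_refref", "freq_refalt", "freq_altalt",
        "p", "q", "pic", "he", "chi2", "df", "p_value", "in_hwe",
    ]
    return df[cols].to_markdown(index=False)
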