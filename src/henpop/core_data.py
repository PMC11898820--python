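"""Domain types and delimited-text I/O for SNP genotype and trait tables.

The central containers are :class:`GenotypeTable` (samples x biallelic loci,
with breed labels) and :class:`TraitTable` (quantitative traits per sample).
Files are plain UTF-8 delimited text (tab by default), hand-editable, with
``#``-prefixed comment lines ignored. Genotype cells are two adjacent allele
characters ("AG"); missing calls are "." or "NA". A minimal VCF 4.2 export is
provided for interoperability with standard variant tooling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "LocusDef",
    "GenotypeCall",
    "MISSING_CALL",
    "SampleRecord",
    "GenotypeTable",
    "TraitDef",
    "TraitTable",
    "STUDY_TRAITS",
    "FormatError",
    "ValidationError",
    "read_genotype_table",
    "write_genotype_table",
    "read_trait_table",
    "write_trait_table",
    "export_vcf",
]

_NUCLEOTIDES = frozenset("ACGT")
_MISSING_TOKENS = frozenset({".", "NA", ""})


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Table contents violate a domain invariant (e.g. foreign allele)."""


@dataclass(frozen=True)
class LocusDef:
    """A biallelic SNP locus on the reference coding sequence.

    ``position`` is the 1-based offset into the ungapped reference coding
    sequence, matching the conventional "g.<pos> <ref>><alt>" site naming
    (e.g. "g.130 A>G").
    """

    locus_id: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele not in _NUCLEOTIDES or self.alt_allele not in _NUCLEOTIDES:
            raise ValidationError(
                f"{self.locus_id}: alleles must be single unambiguous nucleotides, "
                f"got {self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"{self.locus_id}: ref and alt alleles must differ")
        if self.position < 1:
            raise ValidationError(f"{self.locus_id}: position must be >= 1")

    @property
    def display_name(self) -> str:
        """Site label in "g.<pos> <ref>><alt>" form."""
        return f"g.{self.position} {self.ref_allele}>{self.alt_allele}"

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.ref_allele, self.alt_allele))


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered diploid allele pair, or a missing call.

    Storage is normalized: the two allele characters are sorted, so "GA" and
    "AG" compare equal. ``alleles`` is ``None`` for missing calls.
    """

    alleles: tuple | None = None

    @classmethod
    def from_string(cls, text: str) -> "GenotypeCall":
        text = text.strip()
        if text.upper() in _MISSING_TOKENS:
            return MISSING_CALL
        if len(text) != 2:
            raise ValidationError(f"genotype call must be two allele characters, got {text!r}")
        a, b = sorted(text.upper())
        if a not in _NUCLEOTIDES or b not in _NUCLEOTIDES:
            raise ValidationError(f"genotype call contains non-nucleotide characters: {text!r}")
        return cls((a, b))

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def is_hom(self) -> bool:
        return self.alleles is not None and self.alleles[0] == self.alleles[1]

    def to_string(self) -> str:
        return "." if self.alleles is None else "".join(self.alleles)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


MISSING_CALL = GenotypeCall(None)


@dataclass
class SampleRecord:
    """One individual: id, breed label, genotype calls and trait values."""

    sample_id: str
    breed: str
    calls: dict = field(default_factory=dict)
    traits: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TraitDef:
    name: str
    units: str = ""


#: The eight egg-production traits of the four-breed laying-hen study design:
#: age at first egg (days), first egg weight (g), egg weight at 9/12 months of
#: lay (g), cumulative egg number at 9/12 months, eggs per month, and egg mass
#: (g per hen per day).
STUDY_TRAITS = (
    TraitDef("AFEP", "day"),
    TraitDef("FEW", "g"),
    TraitDef("EW_9M", "g"),
    TraitDef("EW_12M", "g"),
    TraitDef("NE_9M", "egg"),
    TraitDef("NE_12M", "egg"),
    TraitDef("EperM", "egg"),
    TraitDef("EMs", "g/hen/day"),
)


@dataclass
class GenotypeTable:
    """Samples x loci matrix of genotype calls with breed labels."""

    loci: list
    samples: list

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen = set()
        by_id = {l.locus_id: l for l in self.loci}
        if len(by_id) != len(self.loci):
            raise ValidationError("duplicate locus ids")
        for s in self.samples:
            if s.sample_id in seen:
                raise ValidationError(f"duplicate sample id {s.sample_id!r}")
            seen.add(s.sample_id)
            if not s.breed:
                raise ValidationError(f"sample {s.sample_id!r} has an empty breed label")
            for locus_id, call in s.calls.items():
                if locus_id not in by_id:
                    raise ValidationError(
                        f"sample {s.sample_id!r} has a call at unknown locus {locus_id!r}"
                    )
                if call.is_missing:
                    continue
                locus = by_id[locus_id]
                foreign = set(call.alleles) - locus.alleles
                if foreign:
                    raise ValidationError(
                        f"sample {s.sample_id!r}, locus {locus_id!r}: allele(s) "
                        f"{''.join(sorted(foreign))!r} outside locus alphabet "
                        f"{{{locus.ref_allele},{locus.alt_allele}}}"
                    )

    @property
    def breeds(self) -> list:
        """Breed labels in order of first appearance."""
        out = []
        for s in self.samples:
            if s.breed not in out:
                out.append(s.breed)
        return out

    def breed_counts(self) -> dict:
        counts: dict = {}
        for s in self.samples:
            counts[s.breed] = counts.get(s.breed, 0) + 1
        return counts

    def locus(self, locus_id: str) -> LocusDef:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)

    def subset(self, breed: str) -> list:
        return [s for s in self.samples if s.breed == breed]


@dataclass
class TraitTable:
    """Per-sample quantitative trait values with trait definitions.

    Values are finite non-negative reals; ``None`` marks a missing
    measurement and is preserved on round trip.
    """

    traits: tuple = STUDY_TRAITS
    values: dict = field(default_factory=dict)  # sample_id -> {trait: float|None}

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = {t.name for t in self.traits}
        for sample_id, row in self.values.items():
            for trait, value in row.items():
                if trait not in names:
                    raise ValidationError(
                        f"sample {sample_id!r}: unknown trait {trait!r}"
                    )
                if value is None:
                    continue
                v = float(value)
                if not (v == v) or v in (float("inf"), float("-inf")) or v < 0:
                    raise ValidationError(
                        f"sample {sample_id!r}, trait {trait}: value must be a "
                        f"finite non-negative number, got {value!r}"
                    )

    def trait_names(self) -> list:
        return [t.name for t in self.traits]


# ---------------------------------------------------------------------------
# Delimited-text I/O


def _read_delimited(path, delimiter: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=delimiter, comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    return df


def read_genotype_table(path, loci=None, delimiter: str = "\t") -> GenotypeTable:
    """Read a genotype table from delimited text.

    The header must name ``sample_id`` and ``breed``; every remaining column
    up to the first trait-like column is a locus. When ``loci`` (a list of
    :class:`LocusDef`) is given, locus columns are validated against it;
    otherwise locus definitions are inferred from a ``#locus`` comment line
    written by :func:`write_genotype_table`.
    """
    header_loci = loci
    if header_loci is None:
        header_loci = _read_locus_comments(path)
        if not header_loci:
            raise FormatError(
                f"{path}: no locus definitions; pass loci= or use a file with "
                "#locus comment lines"
            )
    df = _read_delimited(path, delimiter)
    for col in ("sample_id", "breed"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    locus_ids = [l.locus_id for l in header_loci]
    missing_cols = [lid for lid in locus_ids if lid not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing locus column(s) {missing_cols}")
    samples = []
    for _, row in df.iterrows():
        calls = {lid: GenotypeCall.from_string(row[lid]) for lid in locus_ids}
        samples.append(SampleRecord(str(row["sample_id"]), str(row["breed"]), calls))
    return GenotypeTable(list(header_loci), samples)


def _read_locus_comments(path) -> list:
    loci = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("#locus\t"):
                _, locus_id, pos, ref, alt = line.rstrip("\n").split("\t")
                loci.append(LocusDef(locus_id, int(pos), ref, alt))
    return loci


def write_genotype_table(table: GenotypeTable, path, delimiter: str = "\t") -> None:
    """Write a genotype table as delimited text (byte-stable column order).

    Locus definitions are embedded as ``#locus`` comment lines so the file is
    self-describing for :func:`read_genotype_table`.
    """
    table.validate()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for l in table.loci:
            fh.write(f"#locus\t{l.locus_id}\t{l.position}\t{l.ref_allele}\t{l.alt_allele}\n")
        cols = ["sample_id", "breed"] + [l.locus_id for l in table.loci]
        fh.write(delimiter.join(cols) + "\n")
        for s in table.samples:
            cells = [s.sample_id, s.breed]
            cells += [s.calls.get(l.locus_id, MISSING_CALL).to_string() for l in table.loci]
            fh.write(delimiter.join(cells) + "\n")


def read_trait_table(path, traits=STUDY_TRAITS, delimiter: str = "\t") -> TraitTable:
    """Read a per-sample trait table; "." / "NA" cells become missing."""
    df = _read_delimited(path, delimiter)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    known = {t.name for t in traits}
    trait_cols = [c for c in df.columns if c in known]
    if not trait_cols:
        raise FormatError(f"{path}: no recognized trait columns (expected any of {sorted(known)})")
    values: dict = {}
    for _, row in df.iterrows():
        rec = {}
        for c in trait_cols:
            cell = str(row[c]).strip()
            rec[c] = None if cell.upper() in _MISSING_TOKENS else float(cell)
        values[str(row["sample_id"])] = rec
    return TraitTable(tuple(traits), values)


def write_trait_table(table: TraitTable, path, delimiter: str = "\t") -> None:
    """Write a trait table; trait columns in alphabetical order."""
    table.validate()
    trait_cols = sorted(table.trait_names())
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(delimiter.join(["sample_id"] + trait_cols) + "\n")
        for sample_id in table.values:
            row = table.values[sample_id]
            cells = [sample_id]
            for c in trait_cols:
                v = row.get(c)
                cells.append("." if v is None else format(v, "g"))
            fh.write(delimiter.join(cells) + "\n")


# ---------------------------------------------------------------------------
# VCF export


def export_vcf(table: GenotypeTable, reference_name: str, path) -> None:
    """Write a minimal VCF 4.2 file: one record per locus, GT-only samples.

    Positions are the loci's 1-based coding-sequence coordinates on
    ``reference_name``; genotypes are encoded 0/0, 0/1, 1/1 or ./. .
    """
    table.validate()
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write(f"##contig=<ID={reference_name}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    sample_ids = [s.sample_id for s in table.samples]
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
    for locus in table.loci:
        gts = []
        for s in table.samples:
            call = s.calls.get(locus.locus_id, MISSING_CALL)
            if call.is_missing:
                gts.append("./.")
            else:
                codes = sorted(0 if a == locus.ref_allele else 1 for a in call.alleles)
                gts.append(f"{codes[0]}/{codes[1]}")
        buf.write(
            f"{reference_name}\t{locus.position}\t{locus.locus_id}\t"
            f"{locus.ref_allele}\t{locus.alt_allele}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())
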