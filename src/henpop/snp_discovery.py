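"""Variant-site discovery from a multiple sequence alignment.

Scans the columns of an aligned FASTA of the candidate-gene coding region
and catalogues biallelic substitution sites in "g.<pos> <ref>><alt>" form,
where <pos> is the 1-based position on the *ungapped* reference sequence.
Heterozygotes follow the Sanger direct-sequencing convention: a two-base
IUPAC ambiguity code (R, Y, S, W, K, M) in a consensus read denotes a
heterozygous diploid call. Three/four-base codes (B, D, H, V, N) and gaps
are treated as missing. No indel or multi-nucleotide calling is attempted;
columns with more than two segregating alleles are reported separately and
excluded from the biallelic catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

from .core_data import GenotypeCall, GenotypeTable, LocusDef, MISSING_CALL, SampleRecord

__all__ = [
    "AlignedSequences",
    "VariantSite",
    "AlignmentError",
    "read_alignment",
    "call_variant_sites",
    "sites_to_genotype_table",
    "write_site_catalogue",
]

IUPAC_HET = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}
_BASES = frozenset("ACGT")


class AlignmentError(ValueError):
    """The alignment is malformed (ragged rows, missing reference, ...)."""


@dataclass
class AlignedSequences:
    """An equal-length alignment with a designated reference sequence."""

    reference_id: str
    sequences: dict  # sample_id -> aligned string

    def __post_init__(self) -> None:
        if self.reference_id not in self.sequences:
            raise AlignmentError(f"reference id {self.reference_id!r} not in alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise AlignmentError(f"aligned sequences have unequal lengths: {sorted(lengths)}")
        ref = self.sequences[self.reference_id].upper()
        bad = set(ref) - _BASES - {"-"}
        if bad:
            raise AlignmentError(
                f"reference sequence contains ambiguity codes: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def sample_ids(self) -> list:
        """Non-reference sample ids, in alignment order."""
        return [sid for sid in self.sequences if sid != self.reference_id]


@dataclass
class VariantSite:
    """One biallelic substitution site with per-sample diploid calls."""

    position: int  # 1-based ungapped reference coordinate
    ref_allele: str
    alt_allele: str
    calls: dict  # sample_id -> GenotypeCall
    ref_is_major_fallback: bool = False  # set when the reference base was absent
    locus_id: str = ""

    @property
    def display_name(self) -> str:
        return f"g.{self.position} {self.ref_allele}>{self.alt_allele}"


@dataclass
class MultiallelicSite:
    """A column with > 2 segregating alleles, excluded from the catalogue."""

    position: int
    ref_allele: str
    alleles: tuple


@dataclass
class DiscoveryResult:
    sites: list = field(default_factory=list)
    multiallelic: list = field(default_factory=list)


def read_alignment(path, reference_id: str) -> AlignedSequences:
    """Load an aligned FASTA (equal-length records) via Biopython."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise AlignmentError(f"{path}: no FASTA records")
    return AlignedSequences(reference_id, seqs)


def _column_genotype(char: str):
    """Expand one aligned character into an allele pair, or None if missing."""
    if char in _BASES:
        return (char, char)
    if char in IUPAC_HET:
        pair = tuple(sorted(IUPAC_HET[char]))
        return pair
    return None  # gap, N, three/four-base codes -> missing


def call_variant_sites(aln: AlignedSequences) -> DiscoveryResult:
    """Scan alignment columns for biallelic substitution sites.

    Columns where the reference holds a gap belong to insertions relative to
    the reference: they are skipped and do not advance the reference
    coordinate. A sample gap at a scanned column makes that sample missing at
    the site. The reference base is the ref allele; a column where every
    called sample carries one identical non-reference base is still a
    ref>alt site (a substitution fixed among the samples). When two alleles
    segregate among the samples and neither is the reference base, the major
    sample allele is used as ref and the site is flagged
    (``ref_is_major_fallback``). "Multiallelic" means more than two distinct
    alleles among the samples themselves.
    """
    ref_seq = aln.sequences[aln.reference_id]
    sample_ids = aln.sample_ids
    result = DiscoveryResult()
    ref_pos = 0
    for col in range(aln.length):
        ref_char = ref_seq[col]
        if ref_char == "-":
            continue
        ref_pos += 1
        column = {}
        allele_counts: dict = {}
        for sid in sample_ids:
            g = _column_genotype(aln.sequences[sid][col])
            column[sid] = g
            if g is not None:
                for a in g:
                    allele_counts[a] = allele_counts.get(a, 0) + 1
        segregating = sorted(allele_counts)
        if not segregating or segregating == [ref_char]:
            continue
        if len(segregating) > 2:
            result.multiallelic.append(
                MultiallelicSite(ref_pos, ref_char, tuple(segregating))
            )
            continue
        if len(segregating) == 1:
            # every called sample carries the same non-reference base: a
            # substitution fixed among the samples, still a ref>alt site
            ref_allele, alt_allele = ref_char, segregating[0]
            fallback = False
        elif ref_char in segregating:
            ref_allele = ref_char
            alt_allele = next(a for a in segregating if a != ref_char)
            fallback = False
        else:
            # reference base absent: polarize by the major sample allele
            ref_allele = max(segregating, key=lambda a: (allele_counts[a], a))
            alt_allele = next(a for a in segregating if a != ref_allele)
            fallback = True
        valid = {ref_allele, alt_allele}
        calls = {}
        for sid in sample_ids:
            g = column[sid]
            if g is None or not set(g) <= valid:
                calls[sid] = MISSING_CALL
            else:
                calls[sid] = GenotypeCall(tuple(sorted(g)))
        result.sites.append(
            VariantSite(ref_pos, ref_allele, alt_allele, calls, fallback)
        )
    for i, site in enumerate(result.sites, start=1):
        site.locus_id = f"SNP{i}"
    return result


def sites_to_genotype_table(result: DiscoveryResult, breed_of=None, default_breed: str = "unknown") -> GenotypeTable:
    """Convert discovered sites to a :class:`GenotypeTable`.

    ``breed_of`` optionally maps sample_id -> breed; unmapped samples get
    ``default_breed``.
    """
    loci = [
        LocusDef(site.locus_id, site.position, site.ref_allele, site.alt_allele)
        for site in result.sites
    ]
    sample_ids: list = []
    for site in result.sites:
        for sid in site.calls:
            if sid not in sample_ids:
                sample_ids.append(sid)
    samples = []
    for sid in sample_ids:
        breed = (breed_of or {}).get(sid, default_breed)
        calls = {site.locus_id: site.calls[sid] for site in result.sites}
        samples.append(SampleRecord(sid, breed, calls))
    return GenotypeTable(loci, samples)


def write_site_catalogue(result: DiscoveryResult, path) -> None:
    """Write the site catalogue TSV: locus_id, position, ref, alt, site, flag."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("locus_id\tposition\tref\talt\tsite\tref_is_major_fallback\n")
        for site in result.sites:
            fh.write(
                f"{site.locus_id}\t{site.position}\t{site.ref_allele}\t"
                f"{site.alt_allele}\t{site.display_name}\t"
                f"{str(site.ref_is_major_fallback).lower()}\n"
            )
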