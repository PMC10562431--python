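"""Reading and normalising direct-to-consumer (DTC) raw genotype exports.

Consumer genealogy services let customers download their raw array calls as
plain text.  Two dialects are supported:

* 23andMe style — tab-separated ``rsid  chromosome  position  genotype`` where
  the genotype column holds both alleles as a two-character string (``AT``),
  with ``#``-prefixed comment headers.
* AncestryDNA style — ``rsid  chromosome  position  allele1  allele2`` with an
  uncommented ``rsid ...`` header line in addition to ``#`` comments.

Calls are keyed on rsID only; chromosome and position are carried as opaque
labels (no genome-build validation, no liftover).  Arrays report alleles on
mixed strands, so :func:`normalize_alleles` orients an observed pair onto a
locus definition via Watson-Crick complementation, flagging strand-ambiguous
(A/T, C/G) loci that cannot be oriented from the data alone.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "Dialect",
    "SnpDefinition",
    "GenotypeRecord",
    "GenotypeTable",
    "MISSING_SENTINELS",
    "ParseError",
    "ConflictError",
    "AlleleMismatchError",
    "parse_dtc_table",
    "write_dtc_table",
    "extract_panel",
    "normalize_alleles",
    "complement",
]

#: Tokens that DTC exports use for a no-call (or indel call, which the panel
#: does not use): double-dash, double-zero, deletion/insertion codes, blanks.
MISSING_SENTINELS = {"--", "00", "0", "DD", "II", "D", "I", ""}

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


class Dialect(str, Enum):
    """Raw-export file dialects."""

    TWENTYTHREE_AND_ME = "23andme"
    ANCESTRY = "ancestry"


class ParseError(ValueError):
    """Malformed DTC export line (reports the 1-based line number)."""


class ConflictError(ValueError):
    """The same rsID appears more than once with discordant calls."""


class AlleleMismatchError(ValueError):
    """Observed alleles match a locus definition on neither strand."""


def complement(alleles: Iterable[str]) -> frozenset[str]:
    """Watson-Crick complement of a set of bases."""
    return frozenset(_COMPLEMENT[a] for a in alleles)


@dataclass(frozen=True)
class SnpDefinition:
    """A panel locus: rsID, the two expected alleles, and chromosome label.

    ``ambiguous_strand`` is true for A/T and C/G loci, whose allele pair is its
    own complement: observed calls there cannot be strand-checked.
    """

    rsid: str
    chromosome: str
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        pair = set(self.alleles)
        if not pair <= _BASES or len(pair) != 2:
            raise ValueError(
                f"{self.rsid}: locus must define exactly two distinct bases "
                f"from A/C/G/T, got {self.alleles!r}"
            )

    @property
    def ambiguous_strand(self) -> bool:
        return set(self.alleles) in _AMBIGUOUS_PAIRS

    def genotypes(self) -> list[str]:
        """The three diploid genotypes of the allele pair, canonically sorted."""
        a, b = sorted(self.alleles)
        return [a + a, a + b, b + b]


@dataclass(frozen=True)
class GenotypeRecord:
    """One variant call: an unordered allele pair, or a missing call.

    ``alleles`` is a frozenset of one (homozygous) or two bases; ``None``
    denotes a missing call.  AT and TA compare equal by construction.
    """

    rsid: str
    alleles: frozenset[str] | None

    def __post_init__(self) -> None:
        if self.alleles is not None and (
            not self.alleles <= _BASES or not 1 <= len(self.alleles) <= 2
        ):
            raise ValueError(f"{self.rsid}: bad allele set {set(self.alleles)!r}")

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    def genotype_string(self) -> str:
        """Canonical two-character genotype (``'AT'``), or ``'--'`` if missing."""
        if self.alleles is None:
            return "--"
        a = sorted(self.alleles)
        return a[0] + a[-1]  # homozygous sets have one element


def _record_from_alleles(rsid: str, raw: Iterable[str]) -> GenotypeRecord:
    calls = [a for a in raw if a not in MISSING_SENTINELS]
    if not calls:
        return GenotypeRecord(rsid, None)
    if len(calls) == 1:
        # hemizygous (X/Y/MT) call: duplicate to a homozygous pair
        calls = calls * 2
    return GenotypeRecord(rsid, frozenset(calls))


@dataclass
class GenotypeTable:
    """All calls from one subject's raw export, keyed by rsID.

    Lookup is total: :meth:`get` returns a missing record for absent rsIDs.
    Duplicate lines with identical calls are collapsed silently; discordant
    duplicates are remembered and raised on access by :func:`extract_panel`.
    """

    subject_id: str
    records: dict[str, GenotypeRecord] = field(default_factory=dict)
    source_dialect: Dialect | None = None
    conflicts: set[str] = field(default_factory=set)

    def add(self, record: GenotypeRecord) -> None:
        prior = self.records.get(record.rsid)
        if prior is not None and prior.alleles != record.alleles:
            self.conflicts.add(record.rsid)
        self.records[record.rsid] = record

    def get(self, rsid: str) -> GenotypeRecord:
        return self.records.get(rsid, GenotypeRecord(rsid, None))

    def __len__(self) -> int:
        return len(self.records)


def parse_dtc_table(text: str, dialect: Dialect, subject_id: str = "subject") -> GenotypeTable:
    """Parse a raw DTC export into a :class:`GenotypeTable`.

    Lines beginning with ``#`` and an Ancestry-style ``rsid ...`` header line
    are skipped.  Fields may be tab- or comma-separated.

    Raises
    ------
    ParseError
        If a data line has the wrong column count for the dialect.
    """
    dialect = Dialect(dialect)
    table = GenotypeTable(subject_id=subject_id, source_dialect=dialect)
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        sep = "\t" if "\t" in line else ","
        fields = [f.strip() for f in line.split(sep)]
        if fields[0].lower() == "rsid":  # uncommented header line
            continue
        if dialect is Dialect.TWENTYTHREE_AND_ME:
            if len(fields) != 4:
                raise ParseError(
                    f"line {lineno}: expected 4 columns for 23andMe dialect, got {len(fields)}"
                )
            rsid, _chrom, _pos, genotype = fields
            table.add(_record_from_alleles(rsid, genotype if genotype not in MISSING_SENTINELS else []))
        else:
            if len(fields) != 5:
                raise ParseError(
                    f"line {lineno}: expected 5 columns for Ancestry dialect, got {len(fields)}"
                )
            rsid, _chrom, _pos, a1, a2 = fields
            table.add(_record_from_alleles(rsid, [a1, a2]))
    return table


def write_dtc_table(
    table: GenotypeTable,
    dialect: Dialect,
    positions: Mapping[str, tuple[str, str]] | None = None,
) -> str:
    """Serialise a table back to a raw-export dialect (round-trips with parse).

    ``positions`` optionally maps rsid -> (chromosome, position); absent
    entries are written with placeholder ``0`` labels, which the parser carries
    opaquely.
    """
    dialect = Dialect(dialect)
    lines = [f"# raw genotype data for {table.subject_id}"]
    if dialect is Dialect.ANCESTRY:
        lines.append("rsid\tchromosome\tposition\tallele1\tallele2")
    for rsid in sorted(table.records):
        rec = table.records[rsid]
        chrom, pos = (positions or {}).get(rsid, ("0", "0"))
        if dialect is Dialect.TWENTYTHREE_AND_ME:
            lines.append(f"{rsid}\t{chrom}\t{pos}\t{rec.genotype_string()}")
        else:
            g = rec.genotype_string()
            a1, a2 = ("0", "0") if rec.is_missing else (g[0], g[1])
            lines.append(f"{rsid}\t{chrom}\t{pos}\t{a1}\t{a2}")
    return "\n".join(lines) + "\n"


def extract_panel(
    table: GenotypeTable, panel: list[SnpDefinition]
) -> tuple[dict[str, GenotypeRecord], int]:
    """Pull the panel loci out of a subject's table.

    Returns one record per panel SNP (missing record for absent rsIDs) and the
    count of panel SNPs without a call.

    Raises
    ------
    ConflictError
        If a panel rsID appeared in the source file with discordant calls.
    ValueError
        If the panel is empty or contains duplicate rsIDs.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    rsids = [s.rsid for s in panel]
    if len(set(rsids)) != len(rsids):
        raise ValueError("panel contains duplicate rsIDs")
    clash = sorted(set(rsids) & table.conflicts)
    if clash:
        raise ConflictError(
            f"subject {table.subject_id}: discordant duplicate calls at {', '.join(clash)}"
        )
    out = {rsid: table.get(rsid) for rsid in rsids}
    missing = sum(rec.is_missing for rec in out.values())
    return out, missing


def normalize_alleles(
    observed: frozenset[str] | Iterable[str], snp: SnpDefinition
) -> tuple[frozenset[str], bool, bool]:
    """Orient an observed allele pair onto a locus definition.

    Returns ``(oriented_alleles, strand_flipped, ambiguous_strand)``.  If the
    observed alleles already lie within the locus alleles they are returned
    unchanged; otherwise the Watson-Crick complement is tried and
    ``strand_flipped`` set.  At strand-ambiguous loci (A/T or C/G definitions)
    the call is accepted as-is and flagged, since flipping is undetectable.

    Raises
    ------
    AlleleMismatchError
        If neither the observed pair nor its complement fits the definition.
    """
    obs = frozenset(observed)
    if not obs or obs == frozenset({None}):
        raise ValueError("observed alleles must be non-missing")
    ref = frozenset(snp.alleles)
    if snp.ambiguous_strand:
        if obs <= ref:
            return obs, False, True
        raise AlleleMismatchError(
            f"{snp.rsid}: observed {sorted(obs)} not within ambiguous locus {snp.alleles}"
        )
    if obs <= ref:
        return obs, False, False
    comp = complement(obs)
    if comp <= ref:
        return comp, True, False
    raise AlleleMismatchError(
        f"{snp.rsid}: observed {sorted(obs)} matches locus {snp.alleles} on neither strand"
    )


def table_to_tsv(table: GenotypeTable) -> str:
    """Canonical TSV serialisation: subject_id, rsid, allele1, allele2."""
    lines = ["subject_id\trsid\tallele1\tallele2"]
    for rsid in sorted(table.records):
        g = table.records[rsid].genotype_string()
        lines.append(f"{table.subject_id}\t{rsid}\t{g[0]}\t{g[1]}")
    return "\n".join(lines) + "\n"
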