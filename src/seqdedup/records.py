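"""Parse and write GenBank flat-file nucleotide records.

The feature extractor consumes a small slice of a GenBank record: the
DEFINITION line, the REFERENCE blocks (literature citations and the
"Direct Submission" block that names the submitters), the ORIGIN sequence,
and CDS features with their protein translations.  This module maps
GenBank flat files onto that record model and back, delegating the flat-file
dialect itself to Biopython.

Coordinates are stored 0-based half-open internally; the 1-based inclusive
GenBank convention is converted at the parser boundary.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import Reference, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "LiteratureRef",
    "CdsRegion",
    "SequenceRecord",
    "RecordPair",
    "GenBankParseError",
    "parse_genbank",
    "write_genbank",
    "first_cds",
    "normalize_author",
    "split_author_list",
]

DIRECT_SUBMISSION = "Direct Submission"


class GenBankParseError(ValueError):
    """Raised when a record block cannot be mapped onto the record model."""


def normalize_author(name: str) -> str:
    """Canonicalize one author name to lowercase ``surname,i.`` form.

    Database submissions render the same person inconsistently
    ("Smith, J.", "SMITH J.", "Smith,J"); names are compared as set
    elements, so a deterministic canonical form is required.
    """
    name = name.strip().lower()
    name = re.sub(r"\s+", "", name)
    # keep letters, hyphens, the surname/initials comma and initial dots
    name = re.sub(r"[^a-z\-,.]", "", name)
    if "," not in name and "." in name:
        # "smithj." style: split before first initial-dot group
        m = re.match(r"([a-z\-]+?)((?:[a-z]\.)+)$", name)
        if m:
            name = f"{m.group(1)},{m.group(2)}"
    if "," in name:
        surname, initials = name.split(",", 1)
        initials = re.sub(r"\.+", ".", initials)
        if initials and not initials.endswith("."):
            initials += "."
        name = f"{surname},{initials}"
    return name


def split_author_list(authors: str) -> set[str]:
    """Split a GenBank AUTHORS string into a set of normalized names.

    GenBank separates authors with ``", "`` and a final ``" and "``, while
    surname/initials are joined by a comma without a space.
    """
    if not authors:
        return set()
    parts: list[str] = []
    for chunk in authors.replace(" and ", ", ").split(", "):
        chunk = chunk.strip().rstrip(",")
        if chunk and chunk != ".":
            parts.append(chunk)
    return {normalize_author(p) for p in parts if normalize_author(p)}


@dataclass(frozen=True)
class LiteratureRef:
    """One literature citation from a REFERENCE block.

    Direct-submission blocks (title ``"Direct Submission"``) are modelled
    separately as record submitters and never appear in ``references``.
    """

    pubmed_id: Optional[str] = None
    journal: Optional[str] = None
    title: Optional[str] = None
    authors: frozenset[str] = frozenset()
    is_direct_submission: bool = False

    def __post_init__(self) -> None:
        if not (self.pubmed_id or self.journal or self.title or self.authors):
            raise ValueError("LiteratureRef must populate at least one field")


@dataclass(frozen=True)
class CdsRegion:
    """A coding-sequence region on the record sequence.

    ``start``/``end`` give the 0-based half-open span on the forward strand.
    For simple forward locations ``nucleotide_seq`` equals the sequence slice
    ``[start, end)``; for joined or complement locations it is the
    concatenated (and reverse-complemented) exonic sequence, which is what
    alignment consumes.
    """

    start: int
    end: int
    nucleotide_seq: str
    translation: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid CDS span [{self.start}, {self.end})")


@dataclass(frozen=True)
class SequenceRecord:
    """One parsed nucleotide record."""

    accession: str
    organism: str
    description: str
    sequence: str
    references: tuple[LiteratureRef, ...] = ()
    submitters: Optional[frozenset[str]] = None
    cds_regions: tuple[CdsRegion, ...] = ()

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        for cds in self.cds_regions:
            if cds.end > len(self.sequence):
                raise ValueError(
                    f"{self.accession}: CDS [{cds.start}, {cds.end}) exceeds "
                    f"sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RecordPair:
    """Two records under comparison, optionally with a known label."""

    record_a: SequenceRecord
    record_b: SequenceRecord
    label: Optional["PairLabel"] = None  # noqa: F821 - forward ref to labeling

    def __post_init__(self) -> None:
        if self.record_a.accession == self.record_b.accession:
            raise ValueError(
                f"pair members share accession {self.record_a.accession}"
            )


def first_cds(record: SequenceRecord) -> Optional[tuple[str, Optional[str]]]:
    """Return the first CDS (nucleotide sequence, translation), or None.

    Records commonly carry several CDS features; only the first one in
    record order is used for coding-region comparison.
    """
    if not record.cds_regions:
        return None
    cds = record.cds_regions[0]
    return cds.nucleotide_seq, cds.translation


def _is_direct_submission(ref: Reference) -> bool:
    title = (ref.title or "").strip()
    journal = (ref.journal or "").strip()
    return title == DIRECT_SUBMISSION or journal.startswith("Submitted (")


def _convert_record(rec: SeqRecord) -> SequenceRecord:
    sequence = str(rec.seq).upper()
    if not sequence or set(sequence) == {"N"} and not rec.seq.defined:  # pragma: no cover
        raise GenBankParseError(f"record {rec.id}: no ORIGIN sequence")

    references: list[LiteratureRef] = []
    submitters: Optional[frozenset[str]] = None
    for ref in rec.annotations.get("references", []):
        authors = frozenset(split_author_list(ref.authors or ""))
        if _is_direct_submission(ref):
            if submitters is None:
                submitters = authors
            else:
                submitters = submitters | authors
            continue
        if not (ref.pubmed_id or ref.journal or ref.title or authors):
            continue
        references.append(
            LiteratureRef(
                pubmed_id=ref.pubmed_id or None,
                journal=ref.journal or None,
                title=ref.title or None,
                authors=authors,
            )
        )

    cds_regions: list[CdsRegion] = []
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        start = int(feat.location.start)
        end = int(feat.location.end)
        nt = str(feat.extract(rec.seq)).upper()
        translations = feat.qualifiers.get("translation", [])
        translation = translations[0] if translations else None
        cds_regions.append(
            CdsRegion(start=start, end=end, nucleotide_seq=nt, translation=translation)
        )

    accession = rec.annotations.get("accessions", [rec.id])[0] or rec.id
    return SequenceRecord(
        accession=accession,
        organism=rec.annotations.get("organism", ""),
        description=rec.description or "",
        sequence=sequence,
        references=tuple(references),
        submitters=submitters,
        cds_regions=tuple(cds_regions),
    )


def parse_genbank(
    source: Union[str, Path, TextIO],
) -> list[SequenceRecord]:
    """Parse GenBank flat-file records from a path, string, or handle.

    Empty input yields an empty list.  A block without a LOCUS line or
    without an ORIGIN sequence raises :class:`GenBankParseError` naming the
    offending block.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and source.strip() and "\n" not in source
    ):
        handle: TextIO = open(source)
        close = True
    elif isinstance(source, str):
        handle = io.StringIO(source)
        close = False
    else:
        handle = source
        close = False

    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    if not text.strip():
        return []
    if not text.lstrip().startswith("LOCUS"):
        head = text.lstrip().splitlines()[0][:60]
        raise GenBankParseError(f"block does not start with LOCUS: {head!r}")

    out: list[SequenceRecord] = []
    try:
        for rec in SeqIO.parse(io.StringIO(text), "genbank"):
            if len(rec.seq) == 0 or not rec.seq.defined:
                raise GenBankParseError(f"record {rec.id}: missing ORIGIN sequence")
            out.append(_convert_record(rec))
    except GenBankParseError:
        raise
    except ValueError as exc:
        raise GenBankParseError(str(exc)) from exc
    return out


def _to_biopython(record: SequenceRecord) -> SeqRecord:
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.accession,
        name=record.accession,
        description=record.description,
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["date"] = "01-JAN-2016"  # fixed: corpora must be byte-stable
    rec.annotations["organism"] = record.organism
    rec.annotations["source"] = record.organism
    rec.annotations["accessions"] = [record.accession]
    refs = []
    for lit in record.references:
        ref = Reference()
        ref.authors = ", ".join(sorted(lit.authors))
        ref.title = lit.title or ""
        ref.journal = lit.journal or ""
        ref.pubmed_id = lit.pubmed_id or ""
        refs.append(ref)
    if record.submitters is not None:
        sub = Reference()
        sub.authors = ", ".join(sorted(record.submitters))
        sub.title = DIRECT_SUBMISSION
        sub.journal = "Submitted (01-JAN-2016) to the INSDC"
        refs.append(sub)
    rec.annotations["references"] = refs
    for cds in record.cds_regions:
        qualifiers = {"codon_start": ["1"]}
        if cds.translation is not None:
            qualifiers["translation"] = [cds.translation]
        rec.features.append(
            SeqFeature(
                SimpleLocation(cds.start, cds.end, strand=1),
                type="CDS",
                qualifiers=qualifiers,
            )
        )
    return rec


def write_genbank(
    records: Iterable[SequenceRecord], dest: Union[str, Path, TextIO]
) -> None:
    """Write records as GenBank flat-file blocks (round-trips with the parser)."""
    recs = [_to_biopython(r) for r in records]
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as handle:
            SeqIO.write(recs, handle, "genbank")
    else:
        SeqIO.write(recs, dest, "genbank")
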