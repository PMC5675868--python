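"""Annotated-replicon I/O and coordinate conventions.

A replicon is a DNA sequence (plasmid or chromosome) plus an ordered list of
CDS features.  Internally all intervals are 0-based half-open; everything the
user sees (GFF3, TSV reports, function arguments documented as "positions")
is 1-based inclusive, the GFF3 convention.  The two views round-trip
losslessly.

Printed coordinate ranges in the literature are not always 1-based inclusive:
a range whose stated length is one short of ``end - start + 1`` is treated as
start-inclusive / end-exclusive.  :func:`extract_segment` therefore takes an
explicit ``convention`` flag, and reports record which convention was used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.Data.CodonTable import TranslationError

from .errors import CoordinateError, FormatError, UndefinedContentError
from ._util import round_half_away

#: NCBI genetic code used for all translations (bacterial/plastid).
TRANSLATION_TABLE = 11

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """A located, stranded CDS with its translated protein.

    ``start``/``end`` are 1-based inclusive (external convention);
    ``start0``/``end0`` give the 0-based half-open view used internally.
    ``protein`` is ``None`` when the CDS could not be translated (e.g. its
    length is not a multiple of 3); such features carry ``in_frame=False``
    but are kept.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    phase: int = 0
    protein: str | None = None
    in_frame: bool = True

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise CoordinateError(
                f"{self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: invalid strand {self.strand!r}")

    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def end0(self) -> int:
        return self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class RepliconAnnotation:
    """A replicon sequence with its CDS features, sorted by start."""

    replicon_id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"{self.replicon_id}: ambiguity codes other than N are not "
                f"supported: {sorted(bad)}")
        for f in self.features:
            if f.start < 1 or f.end > len(self.sequence):
                raise CoordinateError(
                    f"{f.gene_id}: [{f.start}, {f.end}] outside replicon of "
                    f"length {len(self.sequence)}")
        self.features.sort(key=lambda f: (f.start, f.end, f.gene_id))

    def feature(self, gene_id: str) -> GeneFeature:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise KeyError(gene_id)

    def __len__(self) -> int:
        return len(self.sequence)


def translate_feature(annotation: RepliconAnnotation, feat: GeneFeature) -> str | None:
    """Translate a CDS feature with the bacterial genetic code.

    Alternative start codons (GTG, TTG, ...) are translated as M, and the
    trailing stop codon is dropped.  Returns ``None`` for CDSs whose length
    (after the phase offset) is not a multiple of 3.
    """
    dna = annotation.sequence[feat.start0:feat.end0]
    if feat.strand == "-":
        dna = reverse_complement(dna)
    dna = dna[feat.phase:]
    if len(dna) % 3 != 0 or len(dna) < 6:
        return None
    try:
        return str(Seq(dna).translate(table=TRANSLATION_TABLE, cds=True))
    except TranslationError:
        # no canonical start/stop: fall back to a plain frame translation
        prot = str(Seq(dna).translate(table=TRANSLATION_TABLE))
        return prot[:-1] if prot.endswith("*") else prot


def read_annotation(gff3_path: str | Path, fasta_path: str | Path) -> RepliconAnnotation:
    """Parse a GFF3 + genome FASTA pair into a :class:`RepliconAnnotation`.

    All CDS features are read with strand and phase, and translated with the
    bacterial genetic code.  A CDS whose length is not divisible by 3 is kept
    with ``protein=None`` and ``in_frame=False``.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise FormatError(f"{fasta_path}: expected exactly one FASTA record")
    rec = records[0]
    sequence = str(rec.seq).upper()

    db = gffutils.create_db(str(gff3_path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    features: list[GeneFeature] = []
    for cds in db.features_of_type("CDS", order_by="start"):
        if cds.seqid != rec.id:
            raise FormatError(
                f"{gff3_path}: unknown replicon id {cds.seqid!r} "
                f"(FASTA has {rec.id!r})")
        phase = int(cds.frame) if cds.frame not in (None, ".") else 0
        gene_id = cds.attributes.get("ID", [cds.id])[0]
        feat = GeneFeature(gene_id=gene_id, start=cds.start, end=cds.end,
                           strand=cds.strand, phase=phase)
        annotation_stub = RepliconAnnotation(rec.id, sequence, [])
        prot = translate_feature(annotation_stub, feat)
        feat.protein = prot
        feat.in_frame = prot is not None
        features.append(feat)
    return RepliconAnnotation(rec.id, sequence, features)


def write_annotation(annotation: RepliconAnnotation, gff3_path: str | Path,
                     fasta_path: str | Path) -> None:
    """Write the canonical GFF3 + FASTA pair (byte-stable round trip)."""
    lines = ["##gff-version 3",
             f"##sequence-region {annotation.replicon_id} 1 {len(annotation)}"]
    for f in annotation.features:
        lines.append("\t".join([
            annotation.replicon_id, "relaxkit", "CDS", str(f.start),
            str(f.end), ".", f.strand, str(f.phase), f"ID={f.gene_id}",
        ]))
    Path(gff3_path).write_text("\n".join(lines) + "\n")

    wrapped = "\n".join(annotation.sequence[i:i + 60]
                        for i in range(0, len(annotation.sequence), 60))
    Path(fasta_path).write_text(f">{annotation.replicon_id}\n{wrapped}\n")


def extract_segment(annotation: RepliconAnnotation, start: int, end: int,
                    convention: str = "inclusive") -> str:
    """Extract a sub-sequence under an explicit coordinate convention.

    ``inclusive``      -> bases ``start..end`` (length ``end - start + 1``)
    ``end_exclusive``  -> bases ``start..end-1`` (length ``end - start``)
    """
    if convention not in ("inclusive", "end_exclusive"):
        raise ValueError(f"unknown convention {convention!r}")
    stop0 = end if convention == "inclusive" else end - 1
    if start < 1 or stop0 > len(annotation) or stop0 < start:
        raise CoordinateError(
            f"[{start}, {end}] ({convention}) outside replicon of length "
            f"{len(annotation)}")
    return annotation.sequence[start - 1:stop0]


def at_content(seq: str) -> float:
    """AT content in percent, to one decimal; N bases are excluded entirely."""
    a = seq.count("A") + seq.count("T")
    total = a + seq.count("C") + seq.count("G")
    if total == 0:
        raise UndefinedContentError("AT content undefined for empty/all-N input")
    return round_half_away(100.0 * a / total, 1)


def reverse_complement_annotation(annotation: RepliconAnnotation) -> RepliconAnnotation:
    """Map an annotation onto the reverse-complement strand.

    Coordinates are mirrored, strands flipped; stored proteins are unchanged
    (translation is strand-symmetric).
    """
    L = len(annotation)
    feats = [dataclasses.replace(f,
                                 start=L - f.end + 1, end=L - f.start + 1,
                                 strand="-" if f.strand == "+" else "+")
             for f in annotation.features]
    return RepliconAnnotation(annotation.replicon_id,
                              reverse_complement(annotation.sequence), feats)
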