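"""Annotated-genome model and GenBank/FASTA input-output.

All coordinates inside the package are 0-based half-open; the GenBank
boundary (1-based inclusive) is converted exactly once, here.  Only CDS
features are retained: the downstream analyses work on proteins.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X")

#: fixed LOCUS date so written files are byte-stable across runs
_GENBANK_DATE = "01-JAN-2024"


@dataclasses.dataclass(frozen=True)
class GeneFeature:
    """One CDS on a genome, 0-based half-open coordinates."""

    locus_tag: str
    start: int
    end: int
    strand: str  # "+" or "-"
    gene_name: str | None = None
    translation: str | None = None
    product: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"feature {self.locus_tag}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"feature {self.locus_tag}: bad strand {self.strand!r}")
        if self.translation is not None:
            bad = set(self.translation) - AA_ALPHABET
            if bad:
                raise ValidationError(
                    f"feature {self.locus_tag}: non-canonical residues {sorted(bad)}"
                )
            if self.end - self.start < 3:
                raise ValidationError(
                    f"feature {self.locus_tag}: translated CDS shorter than one codon"
                )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class GenomeRecord:
    """An annotated genome: sequence plus its CDS features, sorted by start."""

    id: str
    length: int
    features: list[GeneFeature]
    sequence: str | None = None
    topology: str = "linear"  # or "circular"
    source_taxon: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"genome {self.id}: non-positive length {self.length}")
        if self.topology not in ("linear", "circular"):
            raise ValidationError(f"genome {self.id}: bad topology {self.topology!r}")
        for f in self.features:
            if f.end > self.length:
                raise ValidationError(
                    f"genome {self.id}: feature {f.locus_tag} end {f.end} exceeds "
                    f"genome length {self.length}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)


def _translate_cds(nt: str, strand: str) -> str:
    seq = Seq(nt)
    if strand == "-":
        seq = seq.reverse_complement()
    aa = str(seq.translate(table=11))
    return aa[:-1] if aa.endswith("*") else aa


def read_genbank(path) -> GenomeRecord:
    """Parse a GenBank flat file into a :class:`GenomeRecord`.

    CDS coordinates are converted from GenBank's 1-based inclusive form to
    0-based half-open; ``complement()`` maps to strand ``-``.  A CDS without
    a ``/translation`` qualifier is translated from the nucleotide span with
    translation table 11 (terminal stop stripped).  Origin-spanning CDS on
    circular records are rejected.
    """
    try:
        rec: SeqRecord = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise ParseError(f"cannot parse GenBank file {path}: {exc}") from exc

    length = len(rec.seq)
    if length == 0:
        raise ParseError(f"{path}: record {rec.id} has no sequence/length")
    topology = rec.annotations.get("topology", "linear")
    features: list[GeneFeature] = []
    for i, feat in enumerate(rec.features):
        if feat.type != "CDS":
            continue
        if len(feat.location.parts) > 1:
            raise ParseError(
                f"{path}: CDS #{i} has a compound location "
                f"(origin-spanning or joined CDS are not supported)"
            )
        start, end = int(feat.location.start), int(feat.location.end)
        if end > length:
            raise ValidationError(
                f"{path}: CDS #{i} end {end} beyond LOCUS length {length}"
            )
        strand = "-" if feat.location.strand == -1 else "+"
        quals = feat.qualifiers
        translation = quals.get("translation", [None])[0]
        if translation is None:
            translation = _translate_cds(str(rec.seq[start:end]), strand)
        features.append(
            GeneFeature(
                locus_tag=quals.get("locus_tag", [f"CDS_{i:04d}"])[0],
                gene_name=quals.get("gene", [None])[0],
                start=start,
                end=end,
                strand=strand,
                translation=translation,
                product=quals.get("product", [None])[0],
            )
        )
    taxon = rec.annotations.get("organism") or None
    return GenomeRecord(
        id=rec.id or rec.name,
        length=length,
        features=features,
        sequence=str(rec.seq),
        topology=topology,
        source_taxon=taxon,
    )


def write_genbank(record: GenomeRecord, path) -> None:
    """Write a :class:`GenomeRecord` as a GenBank flat file.

    The output is deterministic (fixed LOCUS date) and round-trips through
    :func:`read_genbank` with all modelled fields preserved.
    """
    if record.sequence is None:
        raise ValidationError(f"genome {record.id}: no sequence to write")
    if len(record.sequence) != record.length:
        raise ValidationError(
            f"genome {record.id}: sequence length {len(record.sequence)} != {record.length}"
        )
    rec = SeqRecord(Seq(record.sequence), id=record.id, name=record.id.split(".")[0])
    rec.description = ""
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = record.topology
    rec.annotations["date"] = _GENBANK_DATE
    rec.annotations["data_file_division"] = "BCT"
    if record.source_taxon:
        rec.annotations["organism"] = record.source_taxon
        rec.annotations["source"] = record.source_taxon
    for f in record.features:
        quals: dict[str, list[str]] = {"locus_tag": [f.locus_tag]}
        if f.gene_name:
            quals["gene"] = [f.gene_name]
        if f.product:
            quals["product"] = [f.product]
        if f.translation:
            quals["translation"] = [f.translation]
        loc = FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1)
        rec.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def extract_proteins(record: GenomeRecord) -> dict[str, str]:
    """Return ``locus_tag -> amino-acid string`` for every translated CDS.

    Order follows genome order; CDS without a translation are skipped.
    """
    out: dict[str, str] = {}
    for f in record.features:
        if f.translation:
            out[f.locus_tag] = f.translation
    return out


def read_fasta(path) -> dict[str, str]:
    """Plain multi-FASTA into an ordered ``name -> sequence`` mapping
    (name = first whitespace-delimited token of the header)."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_protein_fasta(record: GenomeRecord, path) -> None:
    """Export translated CDS as multi-FASTA, header ``record|locus_tag|gene``."""
    with open(path, "w") as fh:
        for f in record.features:
            if not f.translation:
                continue
            header = f"{record.id}|{f.locus_tag}|{f.gene_name or ''}"
            fh.write(f">{header}\n")
            for i in range(0, len(f.translation), 60):
                fh.write(f.translation[i : i + 60] + "\n")
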