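"""Readers and writers for the external formats the pipeline touches.

This is the single module where on-disk coordinate conventions are fixed:
GFF3 is 1-based inclusive on disk and stays 1-based inclusive in
:class:`GeneModel` (the rest of the package only ever consumes intron
counts, never raw coordinates). All text I/O is UTF-8 with LF endings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

_DNA_CHARS = set("ACGTNRYSWKMBDHV")
_PROTEIN_CHARS = set("ARNDCQEGHILKMFPSTWYVBZX*")


@dataclass
class SequenceRecord:
    """A named sequence with an explicit molecule type."""

    id: str
    seq: str
    moltype: str = "protein"  # "protein" | "dna"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        allowed = _DNA_CHARS if self.moltype == "dna" else _PROTEIN_CHARS
        bad = set(self.seq) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} not valid for moltype {self.moltype}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """Gene structure needed for intron evidence.

    ``cds_segments`` maps transcript id -> list of (start, end) pairs,
    1-based inclusive (GFF3 convention), sorted 5'->3' (descending start on
    the minus strand). ``intron_known`` is False for genes whose annotation
    carries no CDS features — the intron criterion then cannot be applied.
    """

    gene_id: str
    transcript_ids: list[str] = field(default_factory=list)
    strand: str = "+"
    cds_segments: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    intron_known: bool = True

    def intron_count(self, transcript_id: str) -> int:
        return len(self.cds_segments[transcript_id]) - 1

    def representative_transcript(self) -> str | None:
        """Transcript with the longest CDS; ties -> lexicographically smallest id.

        Mirrors the removal of predicted alternative splice variants: one
        transcript stands for the locus.
        """
        if not self.cds_segments:
            return None
        def cds_len(tid: str) -> int:
            return sum(e - s + 1 for s, e in self.cds_segments[tid])
        return min(self.cds_segments, key=lambda t: (-cds_len(t), t))

    @property
    def representative_intron_count(self) -> int | None:
        tid = self.representative_transcript()
        if tid is None or not self.intron_known:
            return None
        return self.intron_count(tid)


@dataclass
class ExpressionMatrix:
    """Genes x tissues expression values, linear scale on input."""

    gene_ids: list[str]
    tissue_labels: list[str]
    values: "object"  # numpy array, shape (genes, tissues)

    def __post_init__(self) -> None:
        import numpy as np

        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.tissue_labels)):
            raise ValueError("expression matrix not rectangular with its labels")
        if any(not t for t in self.tissue_labels):
            raise ValueError("missing tissue label")
        if (self.values < 0).any():
            raise ValueError("negative expression values")


def read_fasta(path: str | Path, moltype: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Sequences are uppercased; duplicate IDs and empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq), moltype))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [_BioRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def _parse_attributes(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in raw.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[key] = value
    return out


def read_gff3_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Parse gene/mRNA/CDS features from a GFF3 file into GeneModels.

    Intron counts are CDS-only (UTR introns are ignored): per transcript,
    intron_count = number of CDS segments - 1. Genes annotated without any
    CDS feature get ``intron_known = False``. Malformed lines raise with
    their line number; CDS features with an unknown parent are skipped with
    a warning.
    """
    genes: dict[str, GeneModel] = {}
    transcript_to_gene: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 line ({len(cols)} columns)")
            _, _, ftype, start_s, end_s, _, strand, _, attrs_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid coordinate range {start}-{end}")
            attrs = _parse_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: gene feature without ID")
                genes.setdefault(gid, GeneModel(gene_id=gid, strand=strand))
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid is None or parent is None:
                    raise ValueError(f"{path}:{lineno}: mRNA feature missing ID or Parent")
                gene = genes.setdefault(parent, GeneModel(gene_id=parent, strand=strand))
                if tid not in gene.transcript_ids:
                    gene.transcript_ids.append(tid)
                transcript_to_gene[tid] = parent
            elif ftype == "CDS":
                parent = attrs.get("Parent")
                if parent is None or parent not in transcript_to_gene:
                    warnings.warn(f"{path}:{lineno}: CDS without known parent, skipped")
                    continue
                gene = genes[transcript_to_gene[parent]]
                gene.cds_segments.setdefault(parent, []).append((start, end))
    for gene in genes.values():
        if not gene.cds_segments:
            gene.intron_known = False
            continue
        reverse = gene.strand == "-"
        for tid, segs in gene.cds_segments.items():
            segs.sort(key=lambda se: se[0], reverse=reverse)
            for a, b in zip(segs, segs[1:]):
                lo_a, hi_a = min(a), max(a)
                lo_b, hi_b = min(b), max(b)
                if not (hi_a < lo_b or hi_b < lo_a):
                    raise ValueError(f"gene {gene.gene_id}: overlapping CDS segments in {tid}")
    return genes


# Report columns, fixed order. ``calls`` are classify.VariantCall objects
# (duck-typed here to keep this module import-light).
_REPORT_COLUMNS = [
    "gene_id",
    "class",
    "signature",
    "intron_count",
    "evidence",
    "k4_state",
    "k9_state",
    "k27_state",
    "k36_state",
    "conflicts",
    "confidence",
]


def write_variant_report(calls, path: str | Path) -> None:
    """Write classification calls as a deterministic TSV report.

    One row per gene, ordered lexicographically by gene_id; byte-identical
    output for identical input.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no variant calls to write")
    rows = []
    for c in sorted(calls, key=lambda c: c.gene_id):
        sig = c.signature
        conflicts = ";".join(sorted(f for f in c.evidence if "conflict" in f)) or "."
        evidence = ";".join(sorted(c.evidence)) or "."
        rows.append(
            [
                c.gene_id,
                c.variant_class,
                "".join(sig.signature_residues()),
                "NA" if c.intron_count is None else str(c.intron_count),
                evidence,
                sig.k4,
                sig.k9,
                sig.k27,
                sig.k36,
                conflicts,
                c.confidence,
            ]
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-tissues TSV (header = tissue labels, first column = gene id)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float))


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.tissue_labels)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", lineterminator="\n")
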