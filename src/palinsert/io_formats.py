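"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open.  On-disk reports follow the
convention of their format (GFF3 is 1-based inclusive); the converters at the
reporting boundary are inverse bijections.  Readers reject malformed input
rather than silently repairing it.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import yaml
from Bio import SeqIO, motifs

DNA_ALPHABET = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Malformed input file."""


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, T, N}."""


def normalize_sequence(seq: str, *, context: str = "") -> str:
    """Uppercase a DNA string and enforce the {A,C,G,T,N} alphabet.

    ``U`` is rejected rather than converted: this is a DNA-only analysis.
    """
    s = seq.upper()
    bad = set(s) - DNA_ALPHABET
    if bad:
        where = f" in {context}" if context else ""
        raise AlphabetError(
            f"non-DNA characters {sorted(bad)}{where}; alphabet is A/C/G/T/N"
        )
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclasses.dataclass
class SequenceRecord:
    """One named DNA sequence."""

    identifier: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"empty sequence for record {self.identifier!r}")
        self.sequence = normalize_sequence(self.sequence, context=self.identifier)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass
class AnnotationRecord:
    """A located feature on a sequence, 0-based half-open internally."""

    sequence_id: str
    start: int
    end: int
    strand: str
    feature_type: str
    attributes: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for "
                f"{self.feature_type} on {self.sequence_id}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Records are returned in file order with sequences uppercased.  Malformed
    headers or empty sequences raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header: str | None = None
    desc = ""
    chunks: list[str] = []
    header_line = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if header is not None:
                    if not chunks:
                        raise ParseError(
                            f"{path}:{header_line}: record {header!r} has no sequence"
                        )
                    records.append(SequenceRecord(header, "".join(chunks), desc))
                fields = line[1:].split(None, 1)
                if not fields:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                header = fields[0]
                desc = fields[1] if len(fields) > 1 else ""
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                try:
                    chunks.append(normalize_sequence(line.strip(), context=header))
                except AlphabetError as exc:
                    raise AlphabetError(f"{path}:{lineno}: {exc}") from None
    if header is None:
        raise ParseError(f"{path}: no FASTA records found")
    if not chunks:
        raise ParseError(f"{path}:{header_line}: record {header!r} has no sequence")
    records.append(SequenceRecord(header, "".join(chunks), desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            head = rec.identifier
            if rec.description:
                head += f" {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def write_gff(annotations: Iterable[AnnotationRecord], path, source: str = "palinsert") -> None:
    """Write annotations as GFF3 (columns 4/5 are 1-based inclusive)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            attrs = ";".join(f"{k}={v}" for k, v in ann.attributes.items()) or "."
            fh.write(
                "\t".join(
                    [
                        ann.sequence_id,
                        source,
                        ann.feature_type,
                        str(ann.start + 1),
                        str(ann.end),
                        ".",
                        ann.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff(path) -> list[AnnotationRecord]:
    """Read a GFF3 file back into 0-based half-open annotations."""
    path = Path(path)
    out: list[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _source, ftype, start1, end1, _score, strand, _frame, attrs = cols
            try:
                start = int(start1) - 1
                end = int(end1)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            attributes = {}
            if attrs not in {".", ""}:
                for item in attrs.split(";"):
                    if not item:
                        continue
                    if "=" not in item:
                        raise ParseError(f"{path}:{lineno}: malformed attribute {item!r}")
                    k, v = item.split("=", 1)
                    attributes[k] = v
            out.append(AnnotationRecord(seqid, start, end, strand, ftype, attributes))
    return out


# ---------------------------------------------------------------------------
# Newick


def read_newick(path) -> dendropy.Tree:
    """Read a rooted newick tree with unique leaf labels (polytomies allowed)."""
    path = Path(path)
    text = path.read_text()
    return parse_newick(text, source=str(path))


def parse_newick(text: str, source: str = "<string>") -> dendropy.Tree:
    if text.count("(") != text.count(")"):
        raise ParseError(f"{source}: unbalanced parentheses in newick")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise ParseError(f"{source}: newick parse failure: {exc}") from None
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ParseError(f"{source}: duplicate leaf labels {dupes}")
    return tree


# ---------------------------------------------------------------------------
# JASPAR motifs


@dataclasses.dataclass
class CountMatrix:
    """A motif as base counts, rows A/C/G/T, one column per position."""

    motif_id: str
    counts: np.ndarray  # shape (4, width)

    @property
    def width(self) -> int:
        return self.counts.shape[1]


def read_jaspar(path) -> list[CountMatrix]:
    """Read JASPAR-format count matrices (4 rows A/C/G/T per motif)."""
    path = Path(path)
    with open(path) as fh:
        try:
            parsed = motifs.parse(fh, "jaspar")
        except Exception as exc:
            raise ParseError(f"{path}: JASPAR parse failure: {exc}") from None
    out: list[CountMatrix] = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        if counts.shape[1] < 4:
            raise ParseError(
                f"{path}: motif {m.matrix_id or m.name}: width {counts.shape[1]} < 4"
            )
        if (counts < 0).any():
            raise ParseError(f"{path}: motif {m.matrix_id or m.name}: negative count")
        widths = {len(m.counts[b]) for b in "ACGT"}
        if len(widths) != 1:
            raise ParseError(f"{path}: motif {m.matrix_id or m.name}: row-length mismatch")
        out.append(CountMatrix(m.matrix_id or m.name, counts))
    if not out:
        raise ParseError(f"{path}: no motifs found")
    return out


# ---------------------------------------------------------------------------
# YAML configuration


def load_yaml(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: top-level YAML must be a mapping")
    return data


def dump_yaml(data: dict, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
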