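"""Readers and writers for FASTA, Newick, GenBank CDS features and TSV tables.

Conventions used throughout the package:

* residues are upper-cased on read, ``U`` is mapped to ``T``, and ambiguity
  codes other than ``N`` are mapped to ``N`` with a warning;
* GenBank feature coordinates are 1-based inclusive on disk; every internal
  coordinate is 0-based half-open; user-facing reports are 1-based;
* an "absent" gene (no feature in the annotation) is represented by an
  explicit :class:`SequenceRecord` with empty residues, never by a missing
  dictionary key.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
from Bio import SeqIO

logger = logging.getLogger("plastevo")

_VALID = set("ACGTN-")
_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


class ParseError(ValueError):
    """Raised for malformed FASTA/Newick/GenBank input."""


class CoordinateError(ValueError):
    """Raised when an annotated feature lies outside its source sequence."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N,-}.

    Empty ``residues`` are allowed only as an explicit absent-gene
    placeholder.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        self.residues = normalize_residues(self.residues)

    @property
    def is_absent(self) -> bool:
        return len(self.residues) == 0

    def degapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class CdsFeature:
    """A CDS annotation: ordered exon segments on the source sequence.

    Segments are 0-based half-open ``(start, end, strand)`` with strand
    +1/-1; for minus-strand features the segments are still stored in file
    order and the spliced product is reverse-complemented as a whole.
    """

    gene: str
    segments: list[tuple[int, int, int]] = field(default_factory=list)
    pseudo_flag: bool = False


def normalize_residues(s: str) -> str:
    """Upper-case, map U->T and non-N ambiguity codes to N."""
    s = s.upper().replace("U", "T")
    if not set(s) <= _VALID:
        bad = sorted(set(s) - _VALID)
        logger.warning("ambiguity codes %s mapped to N", "".join(bad))
        s = re.sub(r"[^ACGTN\-]", "N", s)
    return s


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file, preserving record order.

    Raises :class:`ParseError` for an empty file or for sequence data
    appearing before the first header.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header, got {stripped[:30]!r}"
                )
            break
        else:
            raise ParseError(f"{path}: line 1: empty FASTA file")
    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq), description=rec.description)
        for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise ParseError(f"{path}: line 1: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            seq = rec.residues
            for i in range(0, max(len(seq), 1), 70):
                fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted dendropy tree.

    Leaf labels must be unique; negative branch lengths and unbalanced
    parentheses raise :class:`ParseError`.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"invalid Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ParseError(f"duplicate leaf labels in Newick: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ParseError(f"negative branch length {edge.length}")
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True)
    )


# ---------------------------------------------------------------------------
# GenBank CDS extraction
# ---------------------------------------------------------------------------

#: trans-spliced across distant loci; the simple exon-splicing model below
#: cannot represent it, so it is skipped with a warning.
TRANS_SPLICED_GENES = {"rps12"}


def list_cds_features(gb_record) -> list[CdsFeature]:
    """All CDS features of a parsed GenBank record, in file order."""
    feats = []
    for feat in gb_record.features:
        if feat.type != "CDS":
            continue
        gene = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
        segments = []
        for part in feat.location.parts:
            segments.append((int(part.start), int(part.end),
                             1 if part.strand in (1, None) else -1))
        feats.append(CdsFeature(gene=gene, segments=segments,
                                pseudo_flag="pseudo" in feat.qualifiers
                                or "pseudogene" in feat.qualifiers))
    return feats


def splice_feature(source: str, feature: CdsFeature) -> str:
    """Concatenate a feature's exon segments; reverse-complement minus strand.

    Minus-strand joins are stored 5'->3' of the gene after complementing the
    whole spliced product, matching GenBank ``complement(join(...))``
    semantics for features contained on one strand.
    """
    n = len(source)
    parts = []
    strands = {s for _, _, s in feature.segments}
    for start, end, _strand in feature.segments:
        if start < 0 or end > n or start > end:
            raise CoordinateError(
                f"{feature.gene}: segment [{start}, {end}) outside sequence of length {n}"
            )
        parts.append(source[start:end])
    if strands == {-1}:
        return reverse_complement("".join(parts))
    if len(strands) > 1:
        raise CoordinateError(f"{feature.gene}: mixed-strand join unsupported")
    return "".join(parts)


def extract_cds(flatfile: str | Path, wanted_genes: Iterable[str]) -> dict[str, SequenceRecord]:
    """Extract spliced CDS sequences for ``wanted_genes`` from one GenBank file.

    Returns a mapping gene -> :class:`SequenceRecord` whose id is the taxon
    (record) name.  Genes with no CDS feature come back as explicit absent
    placeholders (empty residues).  Duplicate features for a gene (inverted
    repeat copies) resolve to the first feature in file order, logged.
    """
    flatfile = Path(flatfile)
    try:
        gb = next(SeqIO.parse(flatfile, "genbank"))
    except StopIteration:
        raise ParseError(f"{flatfile}: no GenBank record found") from None
    taxon = gb.annotations.get("organism", gb.id).replace(" ", "_")
    source = normalize_residues(str(gb.seq))
    features = list_cds_features(gb)
    by_gene: dict[str, CdsFeature] = {}
    for feat in features:
        if feat.gene in by_gene:
            logger.warning("%s: duplicate CDS feature for %s; keeping first",
                           flatfile.name, feat.gene)
            continue
        by_gene[feat.gene] = feat
    out: dict[str, SequenceRecord] = {}
    for gene in wanted_genes:
        if gene in TRANS_SPLICED_GENES:
            logger.warning("%s: trans-spliced gene %s skipped", flatfile.name, gene)
            continue
        feat = by_gene.get(gene)
        if feat is None:
            out[gene] = SequenceRecord(id=taxon, residues="",
                                       description=f"{gene} absent")
        else:
            out[gene] = SequenceRecord(id=taxon, residues=splice_feature(source, feat),
                                       description=gene)
    return out


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def write_tsv(df, path: str | Path) -> None:
    """Write a DataFrame as a TSV with header row (the package's table format)."""
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
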