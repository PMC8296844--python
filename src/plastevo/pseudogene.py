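"""Pseudogene lesion calling and the gene x taxon status matrix.

Each (gene, taxon) CDS is aligned against an intact reference and walked in
the reference reading frame; the first of the following events is recorded:

* **frameshift** — the cumulative net indel length modulo 3 becomes nonzero
  and stays nonzero for at least ``F`` reference codons.  A compensated pair
  of indels restoring the frame within fewer than ``F`` codons is treated as
  evidence of a functional gene, not a lesion;
* **premature stop** — an in-frame stop codon strictly before the terminal
  reference codon (a stop falling in the final 5% of codons is tolerated
  with a warning);
* **truncation** — an alignment deletion running to the query 5' or 3' end
  and covering at least fraction ``T`` of the reference.

``intact_fraction`` — the preserved fraction of the reading frame before the
first lesion — drives the shading categories of the status heatmap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .codon_align import GeneAlignment, is_translatable, pairwise_align_nt
from .codons import STOP_CODONS
from .io_formats import SequenceRecord

logger = logging.getLogger("plastevo")

DEFAULT_FRAMESHIFT_PERSISTENCE = 10   # F, in reference codons
DEFAULT_TRUNCATION_FRACTION = 0.05    # T, fraction of reference length
TERMINAL_STOP_TOLERANCE = 0.05        # stops in the last 5% of codons tolerated

#: scanner-specific alignment scores: stiff gap costs suppress spurious
#: compensated indel pairs in divergent regions; genuine lesions (real 1-2 bp
#: indels, large deletions) still align as gaps
SCAN_NT_SCORES = (2.0, -3.0, -20.0, -4.0)

STATUS_CATEGORIES = ("intact", "pseudo_mild", "pseudo_moderate",
                     "pseudo_severe", "absent")


@dataclass
class PseudogeneCall:
    gene: str
    taxon: str
    status: str                      # intact | pseudogene | absent
    lesion_kind: str                 # frameshift | premature_stop | truncation | none
    first_lesion_codon: int | None   # 1-based reference codon
    intact_fraction: float

    def category(self) -> str:
        """Heatmap shading class from the preserved-fragment length."""
        if self.status == "absent":
            return "absent"
        if self.status == "intact":
            return "intact"
        if self.intact_fraction < 0.25:
            return "pseudo_severe"
        if self.intact_fraction <= 0.75:
            return "pseudo_moderate"
        return "pseudo_mild"


def scan_gene(ref_cds: str, query_seq: str, gene: str = "", taxon: str = "",
              frameshift_persistence: int = DEFAULT_FRAMESHIFT_PERSISTENCE,
              truncation_fraction: float = DEFAULT_TRUNCATION_FRACTION,
              ) -> PseudogeneCall:
    """Classify one query CDS against an intact reference CDS.

    The reference must be a clean full-length ORF.  An empty query is the
    explicit whole-gene-deletion case: status ``absent``, reported as a
    truncation from codon 1.
    """
    ref = ref_cds.replace("-", "")
    if not is_translatable(ref):
        raise ValueError(f"{gene}: reference CDS is not a clean ORF")
    n_codons = len(ref) // 3
    query = query_seq.replace("-", "")
    if not query:
        return PseudogeneCall(gene, taxon, "absent", "truncation", 1, 0.0)

    ref_len = len(ref)
    min_trunc_nt = truncation_fraction * ref_len

    def project(ra: str, qa: str):
        """Per reference position: aligned query char and the net indel
        shift of the columns strictly before it; plus terminal gap runs."""
        qchar = [""] * ref_len
        shift_before = [0] * ref_len
        shift = 0
        pos = 0
        for rc, qc in zip(ra, qa):
            if rc == "-":
                shift += 1       # insertion in query
                continue
            shift_before[pos] = shift
            qchar[pos] = qc
            if qc == "-":
                shift -= 1       # deletion in query
            pos += 1
        lead = 0
        while lead < ref_len and qchar[lead] == "-":
            lead += 1
        trail = 0
        while trail < ref_len - lead and qchar[ref_len - 1 - trail] == "-":
            trail += 1
        return qchar, shift_before, lead, trail

    # glocal alignment keeps genuine terminal deletions contiguous; but a
    # small internal indel near an end can masquerade as a free overhang,
    # so when the overhangs are too short to be truncations the walk is
    # redone on a fully global alignment
    ra, qa, _ = pairwise_align_nt(ref, query, scores=SCAN_NT_SCORES,
                                  free_ref_end_gaps=True)
    qchar, shift_before, lead, trail = project(ra, qa)
    if 0 < max(lead, trail) < min_trunc_nt:
        ra, qa, _ = pairwise_align_nt(ref, query, scores=SCAN_NT_SCORES)
        qchar, shift_before, lead, trail = project(ra, qa)

    events: list[tuple[int, int, str]] = []  # (codon 1-based, priority, kind)
    if lead >= min_trunc_nt:
        events.append((1, 0, "truncation"))
    if trail >= min_trunc_nt:
        events.append(((ref_len - trail) // 3 + 1, 0, "truncation"))

    walk_end = ref_len - trail   # trailing deletion handled above

    # frameshift: first out-of-frame position and its persistence in codons
    p = 0
    while p < walk_end:
        if shift_before[p] % 3 != 0:
            onset_codon = p // 3 + 1
            q = p
            while q < walk_end and shift_before[q] % 3 != 0:
                q += 1
            persisted = (q // 3 if q < walk_end else (walk_end + 2) // 3) - (p // 3)
            if persisted >= frameshift_persistence:
                events.append((onset_codon, 1, "frameshift"))
            p = q
        else:
            p += 1

    # premature in-frame stops (reference frame; skip codons broken by indels)
    for c in range(n_codons - 1):        # terminal reference codon never a lesion
        i = 3 * c
        if shift_before[i] % 3 != 0:
            continue
        if not (shift_before[i] == shift_before[i + 1] == shift_before[i + 2]):
            continue
        codon = qchar[i] + qchar[i + 1] + qchar[i + 2]
        if codon in STOP_CODONS:
            if c + 1 > (1.0 - TERMINAL_STOP_TOLERANCE) * n_codons:
                logger.warning("%s/%s: stop at codon %d within terminal %.0f%%"
                               " tolerated", gene, taxon, c + 1,
                               TERMINAL_STOP_TOLERANCE * 100)
                continue
            events.append((c + 1, 2, "premature_stop"))

    if not events:
        return PseudogeneCall(gene, taxon, "intact", "none", None, 1.0)
    codon1, _, kind = min(events)
    return PseudogeneCall(gene, taxon, "pseudogene", kind, codon1,
                          (codon1 - 1) / n_codons)


def scan_alignment(aln: GeneAlignment,
                   ref_id: str | None = None, **kwargs) -> list[PseudogeneCall]:
    """Scan every row of a gene alignment against its frame anchor."""
    ref_id = ref_id or aln.anchor_id
    ref = aln.row(ref_id).replace("-", "")
    return [scan_gene(ref, rec.residues, gene=aln.gene, taxon=rec.id, **kwargs)
            for rec in aln.records]


def scan_records(records: list[SequenceRecord], gene: str = "",
                 ref_id: str | None = None, **kwargs) -> list[PseudogeneCall]:
    """Scan unaligned per-taxon CDS records against a chosen/first clean ORF."""
    ref = None
    if ref_id is not None:
        ref = next(r for r in records if r.id == ref_id).residues
    else:
        # longest clean ORF: a terminal truncation still translates cleanly,
        # so preferring length avoids anchoring on a damaged copy
        candidates = [r for r in records
                      if not r.is_absent and is_translatable(r.residues)]
        if candidates:
            ref = max(candidates, key=lambda r: len(r.residues)).residues
    if ref is None:
        raise ValueError(f"{gene}: no clean ORF available as scan reference")
    return [scan_gene(ref, rec.residues, gene=gene, taxon=rec.id, **kwargs)
            for rec in records]


# ---------------------------------------------------------------------------
# status matrix and masking
# ---------------------------------------------------------------------------

def calls_table(calls: list[PseudogeneCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene, c.taxon, c.status, c.lesion_kind, c.first_lesion_codon,
          round(c.intact_fraction, 6)) for c in calls],
        columns=["gene", "taxon", "status", "lesion_kind",
                 "first_lesion_codon", "intact_fraction"],
    )


def build_status_matrix(calls: list[PseudogeneCall]) -> pd.DataFrame:
    """Gene x taxon category matrix (heatmap classes); missing cells 'absent'."""
    seen = set()
    for c in calls:
        key = (c.gene, c.taxon)
        if key in seen:
            raise ValueError(f"duplicate call for {key}")
        seen.add(key)
    genes = sorted({c.gene for c in calls})
    taxa = sorted({c.taxon for c in calls})
    mat = pd.DataFrame("absent", index=pd.Index(genes, name="gene"),
                       columns=taxa)
    for c in calls:
        mat.loc[c.gene, c.taxon] = c.category()
    return mat


def mask_pseudogenes(gene_alignments: dict[str, GeneAlignment],
                     calls: list[PseudogeneCall],
                     drop_allgap_columns: bool = True) -> dict[str, GeneAlignment]:
    """Replace every non-intact row with gaps of the same length.

    Columns left gap-only by masking (insertions private to masked rows) are
    dropped by default so each gene block keeps a triplet width.
    """
    by_gene: dict[str, dict[str, PseudogeneCall]] = {}
    for c in calls:
        by_gene.setdefault(c.gene, {})[c.taxon] = c
    out: dict[str, GeneAlignment] = {}
    for gene, aln in gene_alignments.items():
        gcalls = by_gene.get(gene, {})
        width = aln.n_cols
        rows = {}
        for rec in aln.records:
            call = gcalls.get(rec.id)
            if call is None:
                raise ValueError(f"no pseudogene call for ({gene}, {rec.id})")
            rows[rec.id] = ("-" * width if call.status != "intact"
                            else rec.residues)
        if drop_allgap_columns:
            keep = [i for i in range(width)
                    if any(rows[t][i] != "-" for t in rows)]
            rows = {t: "".join(s[i] for i in keep) for t, s in rows.items()}
        out[gene] = GeneAlignment(
            gene=gene,
            records=[SequenceRecord(id=r.id, residues=rows[r.id],
                                    description=r.description)
                     for r in aln.records],
            anchor_id=aln.anchor_id,
        )
    return out
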