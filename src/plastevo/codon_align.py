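"""Translation-guided codon-aware alignment.

The aligner exists so the pseudogene scanner and the selection stages can
run without an external binary; aligned FASTA produced by any other tool is
accepted as drop-in input downstream.  The procedure is two-phase:

1. records that translate cleanly are aligned progressively at the amino
   acid level (guide order from k-mer distances, Needleman–Wunsch with
   BLOSUM62) and back-translated, so every amino-acid gap becomes a 3-nt
   gap;
2. records that fail translation — the pseudogene candidates — are added
   one by one by global nucleotide alignment against the frame anchor row,
   which allows non-triplet (frameshift-revealing) gaps.

All dynamic programs use a fixed tie-break (match/mismatch preferred over
gap-in-query over gap-in-ref) so outputs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .codons import translate_codon
from .io_formats import SequenceRecord

DEFAULT_NT_SCORES = (2.0, -3.0, -5.0, -2.0)  # match, mismatch, gap_open, gap_extend

_NEG = -1e30


class FrameError(ValueError):
    """Sequence length is not a multiple of 3 and no trailing policy allows it."""


class AlignError(ValueError):
    pass


def translate(cds: str, table_id: int = 11, allow_trailing: bool = False) -> str:
    """Translate a CDS; stops as '*', codons containing N or '-' as 'X'.

    Only translation table 11 (bacterial/plastid) is supported.  A length
    that is not a multiple of 3 raises :class:`FrameError` unless
    ``allow_trailing`` drops the 1-2 trailing nucleotides.
    """
    if table_id != 11:
        raise ValueError("only translation table 11 is supported")
    if len(cds) % 3 != 0:
        if not allow_trailing:
            raise FrameError(f"CDS length {len(cds)} not a multiple of 3")
        cds = cds[: len(cds) - len(cds) % 3]
    return "".join(translate_codon(cds[i:i + 3]) for i in range(0, len(cds), 3))


def is_translatable(seq: str) -> bool:
    """True when the ungapped sequence is a clean full-length ORF: triplet
    length, no internal stop (a single terminal stop is allowed), no N."""
    s = seq.replace("-", "")
    if not s or len(s) % 3 != 0 or "N" in s:
        return False
    aa = translate(s)
    core = aa[:-1] if aa.endswith("*") else aa
    return "*" not in core


# ---------------------------------------------------------------------------
# pairwise global nucleotide alignment (Gotoh, affine gaps)
# ---------------------------------------------------------------------------

def pairwise_align_nt(ref: str, query: str,
                      scores: tuple[float, float, float, float] = DEFAULT_NT_SCORES,
                      free_ref_end_gaps: bool = False,
                      ) -> tuple[str, str, float]:
    """Affine-gap pairwise alignment; returns (ref_aln, query_aln, score).

    Global by default.  With ``free_ref_end_gaps`` the alignment is glocal:
    reference overhangs at either end cost nothing, so a query covering only
    part of the reference (a truncated gene) aligns compactly instead of
    scattering its terminal residues into a long gap.

    The first residue of a gap costs ``gap_open + gap_extend``; each further
    residue ``gap_extend``.  Traceback prefers match/mismatch, then gap in
    the query, then gap in the ref, making the output deterministic.
    """
    if not ref or not query:
        raise AlignError("pairwise alignment requires non-empty sequences")
    match, mismatch, go, ge = scores
    n, m = len(ref), len(query)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    sub = np.where(r[:, None] == q[None, :], match, mismatch)

    M = np.full((n + 1, m + 1), _NEG)   # ref[i-1] aligned to query[j-1]
    X = np.full((n + 1, m + 1), _NEG)   # gap in query (ref residue vs '-')
    Y = np.full((n + 1, m + 1), _NEG)   # gap in ref
    M[0, 0] = 0.0
    if free_ref_end_gaps:
        X[1:, 0] = 0.0
    else:
        X[1:, 0] = go + ge * np.arange(1, n + 1)
    Y[0, 1:] = go + ge * np.arange(1, m + 1)
    js = np.arange(m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + sub[i - 1]
        X[i, 1:] = np.maximum(np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + go + ge,
                              X[i - 1, 1:] + ge)
        # Y via running max: Y[i,j] = go + ge*j + max_{k<j}(best_mx[i,k] - ge*k)
        best_mx = np.maximum(M[i], X[i])
        run = np.maximum.accumulate(best_mx - ge * js)
        Y[i, 1:] = go + ge * js[1:] + run[:-1]
        Y[i, 0] = _NEG

    out_r: list[str] = []
    out_q: list[str] = []
    eps = 1e-9
    if free_ref_end_gaps:
        ends = np.maximum(M[:, m], Y[:, m])
        i_end = int(np.argmax(ends - 1e-7 * np.arange(n + 1)))  # ties: 5'-anchored
        score = float(ends[i_end])
        for k in range(n, i_end, -1):       # free trailing ref overhang
            out_r.append(ref[k - 1])
            out_q.append("-")
        i, j = i_end, m
        state = "M" if M[i, j] >= Y[i, j] else "Y"
        if i == 0 and j == 0:
            state = "M"
    else:
        score = float(max(M[n, m], X[n, m], Y[n, m]))
        i, j = n, m
        if M[i, j] >= score - eps:
            state = "M"
        elif X[i, j] >= score - eps:
            state = "X"
        else:
            state = "Y"
    while i > 0 or j > 0:
        if free_ref_end_gaps and j == 0:    # free leading ref overhang
            out_r.append(ref[i - 1])
            out_q.append("-")
            i -= 1
            continue
        if state == "M":
            out_r.append(ref[i - 1])
            out_q.append(query[j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if M[i, j] >= target - eps:
                state = "M"
            elif X[i, j] >= target - eps:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            out_r.append(ref[i - 1])
            out_q.append("-")
            cont = X[i - 1, j] + ge          # gap continues upward
            i -= 1
            if i == 0 and j == 0:
                break
            opened = max(M[i, j], Y[i, j]) + go + ge
            # prefer closing the gap (M) when scores tie
            if i >= 0 and opened >= cont - eps:
                state = "M" if M[i, j] >= Y[i, j] else "Y"
            else:
                state = "X"
        else:  # Y
            out_r.append("-")
            out_q.append(query[j - 1])
            target = Y[i, j] - ge
            j -= 1
            if i == 0 and j == 0:
                break
            best_mx = max(M[i, j], X[i, j])
            if best_mx + go >= target - eps:
                state = "M" if M[i, j] >= X[i, j] else "X"
            else:
                state = "Y"
    return "".join(reversed(out_r)), "".join(reversed(out_q)), score


# ---------------------------------------------------------------------------
# progressive amino-acid alignment
# ---------------------------------------------------------------------------

_BLOSUM = substitution_matrices.load("BLOSUM62")
_AA_GAP = -10.0  # per-column gap penalty at the amino-acid level


def _aa_score(a: str, b: str) -> float:
    try:
        return float(_BLOSUM[a, b])
    except (KeyError, IndexError):
        return 0.0


_AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {a: i for i, a in enumerate(_AA_ALPHABET)}
_BLOSUM_ARR = np.array([[_aa_score(a, b) for b in _AA_ALPHABET]
                        for a in _AA_ALPHABET])


def _profile_counts(prof: list[list[str]]) -> np.ndarray:
    """(n_cols, alphabet) residue count matrix of a profile; gaps omitted."""
    counts = np.zeros((len(prof), len(_AA_ALPHABET)))
    for i, col in enumerate(prof):
        for c in col:
            if c != "-":
                counts[i, _AA_INDEX.get(c, _AA_INDEX["X"])] += 1
    return counts


def _nw_profiles(prof_a: list[list[str]], prof_b: list[list[str]]
                 ) -> tuple[list[list[str]], list[list[str]]]:
    """Needleman–Wunsch on two profiles (lists of columns); linear gaps.

    Column score is the mean pairwise BLOSUM62 score over non-gap residue
    pairs; the DP fills row-wise with numpy (the left-move chain folded in
    via a running maximum).  Traceback prefers diagonal, then up, then left.
    """
    n, m = len(prof_a), len(prof_b)
    rows_a = len(prof_a[0]) if n else 1
    rows_b = len(prof_b[0]) if m else 1
    ca = _profile_counts(prof_a)
    cb = _profile_counts(prof_b)
    pairs = np.outer(ca.sum(axis=1), cb.sum(axis=1))
    pairs[pairs == 0] = 1.0
    sub = (ca @ _BLOSUM_ARR @ cb.T) / pairs      # (n, m) column-score matrix

    score = np.empty((n + 1, m + 1))
    score[0] = _AA_GAP * np.arange(m + 1)
    js = np.arange(m + 1)
    for i in range(1, n + 1):
        cand = np.empty(m + 1)
        cand[0] = _AA_GAP * i
        cand[1:] = np.maximum(score[i - 1, :-1] + sub[i - 1],
                              score[i - 1, 1:] + _AA_GAP)
        # fold in left moves: score[i,j] = max_{k<=j} cand[k] + gap*(j-k)
        run = np.maximum.accumulate(cand - _AA_GAP * js)
        score[i] = run + _AA_GAP * js

    cols_a: list[list[str]] = []
    cols_b: list[list[str]] = []
    i, j = n, m
    eps = 1e-9
    while i > 0 or j > 0:
        if (i > 0 and j > 0
                and score[i, j] <= score[i - 1, j - 1] + sub[i - 1, j - 1] + eps):
            cols_a.append(prof_a[i - 1])
            cols_b.append(prof_b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] <= score[i - 1, j] + _AA_GAP + eps:
            cols_a.append(prof_a[i - 1])
            cols_b.append(["-"] * rows_b)
            i -= 1
        else:
            cols_a.append(["-"] * rows_a)
            cols_b.append(prof_b[j - 1])
            j -= 1
    cols_a.reverse()
    cols_b.reverse()
    return cols_a, cols_b


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    sa = {a[i:i + k] for i in range(len(a) - k + 1)}
    sb = {b[i:i + k] for i in range(len(b) - k + 1)}
    inter = len(sa & sb)
    return 1.0 - inter / max(1, min(len(sa), len(sb)))


def _progressive_align_aa(seqs: list[str]) -> list[str]:
    """Align amino-acid sequences; returns gapped rows in input order."""
    n = len(seqs)
    if n == 1:
        return list(seqs)
    # guide: start from the closest pair, then join nearest remaining sequence
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _kmer_distance(seqs[i], seqs[j])
    in_profile = [False] * n
    i0, j0 = min(((i, j) for i in range(n) for j in range(i + 1, n)),
                 key=lambda ij: (dist[ij], ij))
    order = [i0, j0]
    in_profile[i0] = in_profile[j0] = True
    while len(order) < n:
        rest = [k for k in range(n) if not in_profile[k]]
        nxt = min(rest, key=lambda k: (min(dist[k, o] for o in order), k))
        order.append(nxt)
        in_profile[nxt] = True
    profile = [[c] for c in seqs[order[0]]]
    members = [order[0]]
    for k in order[1:]:
        new = [[c] for c in seqs[k]]
        cols_a, cols_b = _nw_profiles(profile, new)
        profile = [ca + cb for ca, cb in zip(cols_a, cols_b)]
        members.append(k)
    rows = {memb: "".join(col[r] for col in profile)
            for r, memb in enumerate(members)}
    return [rows[i] for i in range(n)]


# ---------------------------------------------------------------------------
# multiple codon-aware alignment
# ---------------------------------------------------------------------------

@dataclass
class GeneAlignment:
    """Equal-length gapped nucleotide rows for one gene.

    ``anchor_id`` names the frame anchor: a row whose ungapped length is a
    multiple of 3 and that contains no internal frameshift by construction.
    """

    gene: str
    records: list[SequenceRecord]
    anchor_id: str

    def __post_init__(self) -> None:
        widths = {len(r.residues) for r in self.records}
        if len(widths) > 1:
            raise AlignError(f"{self.gene}: rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.records[0].residues) if self.records else 0

    def rows(self) -> dict[str, str]:
        return {r.id: r.residues for r in self.records}

    def row(self, rec_id: str) -> str:
        for r in self.records:
            if r.id == rec_id:
                return r.residues
        raise KeyError(rec_id)


def anchor_site_map(aln: "GeneAlignment") -> dict[int, int]:
    """Alignment codon site (1-based) -> anchor-sequence codon (1-based).

    Only sites where the anchor row carries a full contiguous codon are
    mapped; sites falling on anchor gaps are omitted.  Used to compare
    per-site results against ground truth stated in anchor coordinates.
    """
    anchor = aln.row(aln.anchor_id)
    out: dict[int, int] = {}
    apos = 0
    for site in range(len(anchor) // 3):
        triplet = anchor[3 * site:3 * site + 3]
        gaps = triplet.count("-")
        if gaps == 0:
            if apos % 3 == 0:
                out[site + 1] = apos // 3 + 1
            apos += 3
        else:
            apos += 3 - gaps
    return out


def _thread_query_onto_anchor(rows: dict[str, str], anchor_id: str,
                              query_id: str, query: str) -> dict[str, str]:
    """Add one (possibly frameshifted) sequence by alignment to the anchor.

    The query is globally aligned against the degapped anchor; query
    insertions become new all-gap columns in every other row, so previously
    aligned rows are only ever widened, never edited.
    """
    anchor_gapped = rows[anchor_id]
    anchor = anchor_gapped.replace("-", "")
    ra, qa, _ = pairwise_align_nt(anchor, query)
    # per anchor position: the query char aligned to it; plus insertions
    # keyed by the anchor position they precede
    sub_char: list[str] = []
    insertions: dict[int, str] = {}
    pos = 0
    pending = ""
    for rc, qc in zip(ra, qa):
        if rc == "-":
            pending += qc
        else:
            if pending:
                insertions[pos] = insertions.get(pos, "") + pending
                pending = ""
            sub_char.append(qc)
            pos += 1
    if pending:
        insertions[pos] = insertions.get(pos, "") + pending

    new_rows = {rid: [] for rid in rows}
    qrow: list[str] = []
    apos = 0  # index into ungapped anchor
    for col, ch in enumerate(anchor_gapped):
        if ch != "-" and apos in insertions:
            ins = insertions.pop(apos)
            for rid in rows:
                new_rows[rid].append("-" * len(ins))
            qrow.append(ins)
        for rid in rows:
            new_rows[rid].append(rows[rid][col])
        qrow.append(sub_char[apos] if ch != "-" else "-")
        if ch != "-":
            apos += 1
    if apos in insertions:  # trailing insertion
        ins = insertions.pop(apos)
        for rid in rows:
            new_rows[rid].append("-" * len(ins))
        qrow.append(ins)
    out = {rid: "".join(v) for rid, v in new_rows.items()}
    out[query_id] = "".join(qrow)
    return out


def align_codon(records: list[SequenceRecord], gene: str = "") -> GeneAlignment:
    """Translation-guided multiple alignment of one gene's CDS set.

    Clean ORFs are aligned at the amino-acid level and back-translated
    (every gap a triplet); untranslatable records — pseudogene candidates
    and absent placeholders — are added by nucleotide alignment to the
    frame anchor, allowing non-triplet gaps.  Degapping any output row
    recovers the input residues exactly.
    """
    if len(records) < 2:
        raise AlignError("need at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise AlignError("duplicate record ids")
    clean = [r for r in records if not r.is_absent and is_translatable(r.residues)]
    dirty = [r for r in records if r not in clean]
    if not clean:
        raise AlignError(
            f"{gene or 'gene'}: no translatable record to anchor the frame; "
            "supply an external intact reference")
    # longest clean ORF anchors the frame (terminal truncations still
    # translate cleanly but would anchor a damaged frame)
    anchor_id = max(clean, key=lambda r: len(r.residues)).id
    aa_seqs = [translate(r.residues.replace("-", "")) for r in clean]
    aa_rows = _progressive_align_aa(aa_seqs)
    rows: dict[str, str] = {}
    for rec, aa_row in zip(clean, aa_rows):
        nt = rec.residues.replace("-", "")
        out = []
        k = 0
        for aa in aa_row:
            if aa == "-":
                out.append("---")
            else:
                out.append(nt[k:k + 3])
                k += 3
        rows[rec.id] = "".join(out)
    for rec in dirty:
        if rec.is_absent:
            continue  # added as all-gap afterwards
        rows = _thread_query_onto_anchor(rows, anchor_id, rec.id,
                                         rec.residues.replace("-", ""))
    width = len(next(iter(rows.values())))
    for rec in dirty:
        if rec.is_absent:
            rows[rec.id] = "-" * width
    out_records = [SequenceRecord(id=r.id, residues=rows[r.id],
                                  description=r.description) for r in records]
    return GeneAlignment(gene=gene, records=out_records, anchor_id=anchor_id)
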