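"""Genetic-code helpers shared by the simulator, aligner and selection scans.

Plastid protein-coding genes use the bacterial/plastid genetic code
(translation table 11), which has the same codon assignments as the standard
code: stops are TAA, TAG, TGA.  The 61 sense codons are the state space of
the codon substitution model; stop codons are excluded from the evolutionary
process (MG94 convention) and can appear in data only through pseudogene
lesions.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCLEOTIDES = "ACGT"
_TABLE11 = unambiguous_dna_by_id[11]

#: codon -> one-letter amino acid, stops as '*'
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
for _stop in _TABLE11.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE11.stop_codons))

#: the 61 sense codons in lexicographic order; index = model state
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in _TABLE11.stop_codons
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)

_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a<->b is a transition (A<->G, C<->T)."""
    return (a in _PURINES) == (b in _PURINES) and a != b


def is_stop(codon: str) -> bool:
    return codon in _TABLE11.stop_codons


def is_sense(codon: str) -> bool:
    return codon in CODON_INDEX


def translate_codon(codon: str) -> str:
    """One codon -> amino acid; stops '*'; anything with non-ACGT -> 'X'."""
    return CODON_TO_AA.get(codon, "X")


def codon_diffs(a: str, b: str) -> list[int]:
    """Positions (0-based within the codon) where two codons differ."""
    return [k for k in range(3) if a[k] != b[k]]


def _single_step_class(src: str, dst: str) -> str:
    """'syn' or 'nonsyn' for a one-nucleotide codon change between sense codons."""
    return "syn" if CODON_TO_AA[src] == CODON_TO_AA[dst] else "nonsyn"


def pathway_counts(a: str, b: str) -> tuple[float, float] | None:
    """Fractional (synonymous, nonsynonymous) difference counts between codons.

    Nei–Gojobori pathway averaging: all orderings of the single-base steps
    from ``a`` to ``b`` are enumerated, orderings passing through a stop codon
    are discarded, and the syn/nonsyn step classes are averaged with equal
    weight over the remaining orderings.  Returns None when either codon is
    not a sense codon or every pathway crosses a stop.
    """
    if not (is_sense(a) and is_sense(b)):
        return None
    diffs = codon_diffs(a, b)
    if not diffs:
        return (0.0, 0.0)
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diffs):
        cur = a
        path_syn = 0
        path_nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if is_stop(nxt):
                ok = False
                break
            if _single_step_class(cur, nxt) == "syn":
                path_syn += 1
            else:
                path_nonsyn += 1
            cur = nxt
        if ok:
            syn_total += path_syn
            nonsyn_total += path_nonsyn
            n_paths += 1
    if n_paths == 0:
        return None
    return (syn_total / n_paths, nonsyn_total / n_paths)


# cache: pathway_counts is called per codon pair per alignment column
_PATHWAY_CACHE: dict[tuple[str, str], tuple[float, float] | None] = {}


def pathway_counts_cached(a: str, b: str) -> tuple[float, float] | None:
    key = (a, b) if a <= b else (b, a)
    try:
        return _PATHWAY_CACHE[key]
    except KeyError:
        val = pathway_counts(key[0], key[1])
        _PATHWAY_CACHE[key] = val
        return val


def mg94_rate_matrix(
    kappa: float = 2.0,
    omega: float = 1.0,
    codon_freqs: np.ndarray | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """61x61 MG94-style codon rate matrix.

    Off-diagonal rate i->j is nonzero only for single-nucleotide changes:
    ``pi_j * kappa^[transition] * omega^[nonsynonymous]``.  With
    ``normalize=True`` the matrix is scaled so that at the supplied
    stationary frequencies the expected number of nucleotide substitutions
    per codon per unit time is 3 under omega=1 (branch lengths are then in
    expected substitutions per nucleotide site for a neutral site).  The
    same scaling constant is applied for every omega so that omega>1 sites
    genuinely evolve faster.
    """
    if codon_freqs is None:
        codon_freqs = np.full(N_SENSE, 1.0 / N_SENSE)
    codon_freqs = np.asarray(codon_freqs, dtype=float)
    if codon_freqs.shape != (N_SENSE,) or np.any(codon_freqs < 0):
        raise ValueError("codon_freqs must be a length-61 nonnegative vector")
    codon_freqs = codon_freqs / codon_freqs.sum()

    def build(om: float) -> np.ndarray:
        q = np.zeros((N_SENSE, N_SENSE))
        for i, ci in enumerate(SENSE_CODONS):
            for k in range(3):
                for nt in NUCLEOTIDES:
                    if nt == ci[k]:
                        continue
                    cj = ci[:k] + nt + ci[k + 1:]
                    j = CODON_INDEX.get(cj)
                    if j is None:
                        continue
                    rate = codon_freqs[j]
                    if is_transition(ci[k], nt):
                        rate *= kappa
                    if CODON_TO_AA[ci] != CODON_TO_AA[cj]:
                        rate *= om
                    q[i, j] = rate
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    q = build(omega)
    if normalize:
        q_neutral = build(1.0)
        mean_rate = -float(codon_freqs @ np.diag(q_neutral))
        q = q * (3.0 / mean_rate)
    return q
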