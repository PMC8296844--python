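"""Fixed-width window tracks over an alignment: GC, gaps, parsimony steps.

Windows are non-overlapping, fixed at alignment coordinates (the last one
may be short).  GC is pooled across all taxa within the window — N and gap
characters are excluded from both numerator and denominator — and the
substitution track is the sum of per-column Fitch parsimony counts on the
fixed input topology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phylo import CompiledTree, Supermatrix, fitch_steps_matrix, leaf_state_masks


def window_stats(rows: dict[str, str], ctree: CompiledTree,
                 width: int = 100) -> pd.DataFrame:
    """Per-window GC, gap fraction and parsimony substitution count.

    Columns: window_index, start, end (0-based half-open alignment
    coordinates), gc, gap_fraction, substitution_count.
    """
    if width <= 0:
        raise ValueError("window width must be >= 1")
    taxa = list(rows)
    if not taxa:
        raise ValueError("empty alignment")
    n_cols = len(rows[taxa[0]])
    arr = np.frombuffer("".join(rows[t] for t in taxa).encode(),
                        dtype=np.uint8).reshape(len(taxa), n_cols)
    is_gap = arr == ord("-")
    is_n = arr == ord("N")
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_base = ~(is_gap | is_n)

    steps = fitch_steps_matrix(ctree, leaf_state_masks(rows, ctree))

    recs = []
    for wi, start in enumerate(range(0, n_cols, width)):
        end = min(start + width, n_cols)
        bases = int(is_base[:, start:end].sum())
        gc = float(is_gc[:, start:end].sum() / bases) if bases else float("nan")
        gap_fraction = float(is_gap[:, start:end].sum()
                             / (len(taxa) * (end - start)))
        recs.append((wi, start, end, gc, gap_fraction,
                     int(steps[start:end].sum())))
    return pd.DataFrame(recs, columns=["window_index", "start", "end", "gc",
                                       "gap_fraction", "substitution_count"])


def per_gene_gc(sm: Supermatrix) -> pd.DataFrame:
    """Pooled GC content of each gene's partition (gaps and N excluded)."""
    recs = []
    for gene in sm.partitions:
        rows = sm.gene_rows(gene)
        joined = "".join(rows.values())
        bases = sum(1 for c in joined if c not in "-N")
        gc = sum(1 for c in joined if c in "GC")
        recs.append((gene, gc / bases if bases else float("nan")))
    return pd.DataFrame(recs, columns=["gene", "gc"])
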