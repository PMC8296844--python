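"""Ground-truth synthetic datasets for the comparative plastome pipeline.

The generator emulates the statistical structure the analysis assumes: a set
of plastid protein-coding genes evolved along one shared tree under an
MG94-style codon model with

* a per-gene rate multiplier scaling every branch length (mean 1),
* a per-site omega (dN/dS) class, with a minority of sites allowed omega>1,
* a transition/transversion ratio kappa and configurable codon frequencies,

followed by injection of pseudogene lesions — premature stop codons, 1-2 bp
frameshift deletions, terminal truncations and whole-gene deletions — on
chosen (gene, taxon) pairs.  Everything injected is recorded in
``truth.json`` so downstream detection stages can be scored exactly.

Indel evolution along the tree is deliberately not simulated: intact
sequences of a gene are equal-length and stop-free, and all gaps seen by
the pipeline originate from lesions or from masking.  Gene names and their
seven functional ontology groups follow the canonical angiosperm plastome
gene complement (78 protein-coding genes once the trans-spliced rps12 is
set aside).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import expm

from . import codons
from .io_formats import SequenceRecord, write_fasta
from .phylo import CompiledTree, compile_tree
from . import io_formats

LESION_KINDS = ("premature_stop", "frameshift", "truncation", "deletion")

_ONTOLOGY_GENES: dict[str, list[str]] = {
    "atp_synthesis": ["atpA", "atpB", "atpE", "atpF", "atpH", "atpI"],
    "cytochrome_electron_transport": ["petA", "petB", "petD", "petG", "petL",
                                      "petN", "ccsA"],
    "ndh_genes": ["ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF", "ndhG",
                  "ndhH", "ndhI", "ndhJ", "ndhK"],
    "photosynthesis": ["psaA", "psaB", "psaC", "psaI", "psaJ", "psbA", "psbB",
                       "psbC", "psbD", "psbE", "psbF", "psbH", "psbI", "psbJ",
                       "psbK", "psbL", "psbM", "psbN", "psbT", "psbZ", "rbcL"],
    "translation": ["rps2", "rps3", "rps4", "rps7", "rps8", "rps11", "rps14",
                    "rps15", "rps16", "rps18", "rps19", "rpl2", "rpl14",
                    "rpl16", "rpl20", "rpl22", "rpl23", "rpl32", "rpl33",
                    "rpl36", "infA"],
    "transcription": ["rpoA", "rpoB", "rpoC1", "rpoC2"],
    "other": ["matK", "accD", "cemA", "clpP", "ycf1", "ycf2", "ycf3", "ycf4"],
}

ONTOLOGIES = tuple(_ONTOLOGY_GENES)


def plastid_gene_catalog() -> list[tuple[str, str]]:
    """(gene, ontology) pairs in round-robin ontology order, 78 genes total.

    Round-robin ordering means any prefix of the catalog spans several
    ontologies, so small simulated datasets still exercise enrichment.
    """
    pools = {k: list(v) for k, v in _ONTOLOGY_GENES.items()}
    out: list[tuple[str, str]] = []
    while any(pools.values()):
        for ont in ONTOLOGIES:
            if pools[ont]:
                out.append((pools[ont].pop(0), ont))
    return out


@dataclass
class SimConfig:
    """Knobs of the generator; defaults emulate a plastome-scale study
    (dozens of genes, a few dozen taxa, mostly purifying selection with a
    small positively selected minority, sparse pseudogene lesions)."""

    seed: int = 0
    n_taxa: int = 20
    n_genes: int = 40
    gene_length_codons: tuple[int, int] = (100, 400)
    tree_newick: str | None = None       # supplied topology+lengths; else Yule
    birth_rate: float = 1.0
    tree_length: float = 2.0             # total branch length after rescaling
    per_gene_rate_multipliers: list[float] | None = None  # default: all 1
    omega_classes: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.3, 0.75), (1.0, 0.2), (5.0, 0.05)])
    kappa: float = 2.0
    codon_frequencies: np.ndarray | None = None   # default uniform over 61
    lesion_plan: list[tuple[str, str, str, float]] = field(default_factory=list)
    # entries: (gene, taxon, lesion_kind, position_fraction)

    def validate(self) -> None:
        props = [p for _, p in self.omega_classes]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("omega_classes proportions must sum to 1")
        if any(w < 0 for w, _ in self.omega_classes):
            raise ValueError("omega values must be >= 0")
        if self.per_gene_rate_multipliers is not None:
            if len(self.per_gene_rate_multipliers) != self.n_genes:
                raise ValueError("need one rate multiplier per gene")
            if any(m <= 0 for m in self.per_gene_rate_multipliers):
                raise ValueError("rate multipliers must be > 0")
        for gene, taxon, kind, frac in self.lesion_plan:
            if kind not in LESION_KINDS:
                raise ValueError(f"unknown lesion kind {kind!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"lesion position fraction {frac} outside [0,1]")


@dataclass
class SimulatedDataset:
    """In-memory result of :func:`simulate_dataset` (also written to disk)."""

    tree: CompiledTree
    tree_newick: str
    genes: dict[str, list[SequenceRecord]]     # post-lesion tip sequences
    pristine: dict[str, list[SequenceRecord]]  # pre-lesion tip sequences
    ontology: dict[str, str]                   # gene -> ontology
    truth: dict


def _yule_newick(n_taxa: int, birth_rate: float, rng: np.random.Generator) -> str:
    """Ultrametric pure-birth Newick string with taxa t01..tNN."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    children: dict[int, tuple[int, int]] = {}
    born: dict[int, float] = {0: 0.0, 1: 0.0}
    active = [0, 1]
    nxt = 2
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        a, b = nxt, nxt + 1
        nxt += 2
        children[node] = (a, b)
        born[a] = born[b] = t
        active.extend([a, b])
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    leaf_names = iter(f"t{i + 1:02d}" for i in range(n_taxa))

    def split_time(node: int) -> float:
        return born[children[node][0]] if node in children else t_end

    def build(node: int) -> str:
        body = (f"({build(children[node][0])},{build(children[node][1])})"
                if node in children else next(leaf_names))
        return f"{body}:{split_time(node) - born[node]:.10f}"

    return f"({build(0)},{build(1)});"


def make_tree(config: SimConfig, rng: np.random.Generator) -> tuple[CompiledTree, str]:
    """Supplied or simulated topology, rescaled to the configured total length."""
    if config.tree_newick is not None:
        tree = io_formats.parse_newick(config.tree_newick)
    else:
        tree = io_formats.parse_newick(_yule_newick(config.n_taxa, config.birth_rate, rng))
    ctree = compile_tree(tree)
    total = float(ctree.lengths.sum())
    if config.tree_length is not None and total > 0:
        ctree = ctree.scaled(config.tree_length / total)
    newick = _compiled_to_newick(ctree)
    return ctree, newick


def _compiled_to_newick(ctree: CompiledTree) -> str:
    def render(i: int) -> str:
        if not ctree.children[i]:
            body = ctree.taxa[i]
        else:
            body = "(" + ",".join(render(c) for c in ctree.children[i]) + ")"
        if ctree.parent[i] >= 0:
            return f"{body}:{ctree.lengths[i]:.10f}"
        return body

    return render(ctree.root) + ";"


# ---------------------------------------------------------------------------
# codon evolution
# ---------------------------------------------------------------------------

def _sample_rows(p_cum: np.ndarray, parents: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Sample one categorical draw per site from row ``parents[i]`` of a
    cumulative transition matrix."""
    u = rng.random(parents.shape[0])
    rows = p_cum[parents]
    return (rows < u[:, None]).sum(axis=1)


def evolve_gene(ctree: CompiledTree, n_codons: int, site_omega: np.ndarray,
                multiplier: float, kappa: float,
                codon_freqs: np.ndarray | None,
                rng: np.random.Generator) -> np.ndarray:
    """Simulate codon states at the tips: (n_leaves, n_codons) int array.

    Exact CTMC sampling: per branch and per omega class the 61x61 transition
    matrix is the matrix exponential of the normalized MG94 generator times
    the (multiplier-scaled) branch length.
    """
    if codon_freqs is None:
        freqs = np.full(codons.N_SENSE, 1.0 / codons.N_SENSE)
    else:
        freqs = np.asarray(codon_freqs, float)
        freqs = freqs / freqs.sum()
    omegas = np.unique(site_omega)
    q_by_omega = {w: codons.mg94_rate_matrix(kappa=kappa, omega=float(w),
                                             codon_freqs=freqs)
                  for w in omegas}
    states = np.empty((ctree.n_nodes, n_codons), dtype=np.int64)
    root = ctree.root
    states[root] = rng.choice(codons.N_SENSE, size=n_codons, p=freqs)
    # preorder = reversed postorder
    for i in reversed(ctree.postorder):
        if i == root:
            continue
        t = ctree.lengths[i] * multiplier
        parent_states = states[ctree.parent[i]]
        child = np.empty(n_codons, dtype=np.int64)
        for w in omegas:
            sel = site_omega == w
            if not sel.any():
                continue
            p = expm(q_by_omega[w] * t)
            np.clip(p, 0.0, None, out=p)
            p_cum = np.cumsum(p / p.sum(axis=1, keepdims=True), axis=1)
            child[sel] = _sample_rows(p_cum, parent_states[sel], rng)
        states[i] = child
    return states[:ctree.n_leaves]


def _codon_states_to_seq(states: np.ndarray) -> str:
    return "".join(codons.SENSE_CODONS[s] for s in states)


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------

def apply_lesion(seq: str, kind: str, frac: float,
                 rng: np.random.Generator) -> tuple[str, dict]:
    """Damage one intact CDS; returns (lesioned sequence, truth details)."""
    n_codons = len(seq) // 3
    if kind == "deletion":
        return "", {"kind": "deletion"}
    if kind == "premature_stop":
        # internal codon strictly before the terminal one
        codon = min(max(1, int(round(frac * n_codons))), n_codons - 2)
        out = seq[:codon * 3] + "TAA" + seq[(codon + 1) * 3:]
        return out, {"kind": "premature_stop", "codon": codon + 1}
    if kind == "frameshift":
        k = int(rng.integers(1, 3))        # delete 1 or 2 bp
        pos = min(max(3, int(round(frac * len(seq)))), len(seq) - 6)
        out = seq[:pos] + seq[pos + k:]
        return out, {"kind": "frameshift", "codon": pos // 3 + 1, "deleted_bp": k}
    if kind == "truncation":
        pos = min(max(3, int(round(frac * len(seq)))), len(seq) - 3)
        pos -= pos % 3                     # cut at a codon boundary
        out = seq[:pos]
        return out, {"kind": "truncation", "codon": pos // 3 + 1}
    raise ValueError(f"unknown lesion kind {kind!r}")


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def default_lesion_plan(config: SimConfig, n_lesions: int,
                        rng: np.random.Generator) -> list[tuple[str, str, str, float]]:
    """Random sparse lesion plan over distinct (gene, taxon) cells."""
    catalog = plastid_gene_catalog()
    gene_names = [g for g, _ in catalog[:config.n_genes]]
    gene_names += [f"gene{i + 1:02d}" for i in range(len(gene_names), config.n_genes)]
    taxa = [f"t{i + 1:02d}" for i in range(config.n_taxa)]
    cells = [(g, t) for g in gene_names for t in taxa]
    picks = rng.choice(len(cells), size=min(n_lesions, len(cells)), replace=False)
    plan = []
    for idx in sorted(picks):
        g, t = cells[idx]
        kind = LESION_KINDS[int(rng.integers(len(LESION_KINDS)))]
        frac = float(rng.uniform(0.2, 0.8))
        plan.append((g, t, kind, frac))
    return plan


def simulate_dataset(config: SimConfig, out_dir: str | Path | None = None) -> SimulatedDataset:
    """Simulate the full dataset; optionally write the on-disk layout.

    On-disk layout: ``tree.nwk``, ``genes/<gene>.fasta`` (unaligned CDS per
    taxon, lesions applied), ``ontology.tsv`` and ``truth.json``.  The same
    config and seed give byte-identical output.
    """
    config.validate()
    master = np.random.default_rng(config.seed)
    ctree, newick = make_tree(config, master)
    taxa = ctree.taxa

    catalog = plastid_gene_catalog()
    gene_names = [g for g, _ in catalog[:config.n_genes]]
    ontology = {g: o for g, o in catalog[:config.n_genes]}
    for i in range(len(gene_names), config.n_genes):
        name = f"gene{i + 1:02d}"
        gene_names.append(name)
        ontology[name] = "other"

    lesions_by_gene: dict[str, list[tuple[str, str, float]]] = {g: [] for g in gene_names}
    for gene, taxon, kind, frac in config.lesion_plan:
        if gene not in lesions_by_gene:
            raise ValueError(f"lesion plan names unknown gene {gene!r}")
        if taxon not in taxa:
            raise ValueError(f"lesion plan names unknown taxon {taxon!r}")
        lesions_by_gene[gene].append((taxon, kind, frac))

    omega_vals = np.array([w for w, _ in config.omega_classes])
    omega_props = np.array([p for _, p in config.omega_classes])

    genes: dict[str, list[SequenceRecord]] = {}
    pristine: dict[str, list[SequenceRecord]] = {}
    truth_genes: dict[str, dict] = {}
    status: dict[str, dict[str, str]] = {}

    for gi, gene in enumerate(gene_names):
        # per-gene stream keyed by (seed, gene index): adding genes later
        # does not perturb earlier genes
        rng = np.random.default_rng([config.seed, gi])
        lo, hi = config.gene_length_codons
        n_codons = int(rng.integers(lo, hi + 1))
        if config.per_gene_rate_multipliers is not None:
            mult = float(config.per_gene_rate_multipliers[gi])
        else:
            mult = 1.0
        site_omega = omega_vals[rng.choice(len(omega_vals), size=n_codons, p=omega_props)]
        tips = evolve_gene(ctree, n_codons, site_omega, mult, config.kappa,
                           config.codon_frequencies, rng)
        seqs = {taxa[i]: _codon_states_to_seq(tips[i]) for i in range(len(taxa))}
        pristine[gene] = [SequenceRecord(id=t, residues=seqs[t]) for t in taxa]
        gene_status = {t: "intact" for t in taxa}
        gene_lesions: dict[str, dict] = {}
        for taxon, kind, frac in lesions_by_gene[gene]:
            damaged, detail = apply_lesion(seqs[taxon], kind, frac, rng)
            seqs[taxon] = damaged
            gene_lesions[taxon] = detail
            gene_status[taxon] = "absent" if kind == "deletion" else "pseudogene"
        genes[gene] = [SequenceRecord(id=t, residues=seqs[t]) for t in taxa]
        status[gene] = gene_status
        truth_genes[gene] = {
            "length_codons": n_codons,
            "rate_multiplier": mult,
            "site_omega": [float(w) for w in site_omega],
            "lesions": gene_lesions,
            "ontology": ontology[gene],
        }

    truth = {
        "seed": config.seed,
        "taxa": list(taxa),
        "genes": truth_genes,
        "status": status,
        "n_pseudogenes": sum(1 for g in status.values()
                             for s in g.values() if s == "pseudogene"),
        "n_absent": sum(1 for g in status.values()
                        for s in g.values() if s == "absent"),
    }

    ds = SimulatedDataset(tree=ctree, tree_newick=newick, genes=genes,
                          pristine=pristine, ontology=ontology, truth=truth)
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "genes").mkdir(parents=True, exist_ok=True)
    (out / "tree.nwk").write_text(ds.tree_newick + "\n")
    for gene in sorted(ds.genes):
        write_fasta(ds.genes[gene], out / "genes" / f"{gene}.fasta")
    with open(out / "ontology.tsv", "w") as fh:
        fh.write("gene\tontology\n")
        for gene in sorted(ds.ontology):
            fh.write(f"{gene}\t{ds.ontology[gene]}\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
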