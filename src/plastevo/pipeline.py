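"""End-to-end orchestration: extract -> align -> pseudogene scan -> mask ->
concatenate -> branch lengths -> windows -> gene rates -> selection ->
consensus -> enrichment, with a machine-readable run report.

Every stage writes plain TSV/JSON into the output directory so any stage
can also be re-run standalone through the CLI; re-running with the same
config and inputs reproduces the outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .codon_align import GeneAlignment, align_codon
from .io_formats import (SequenceRecord, extract_cds, read_fasta, read_newick,
                         read_tsv, write_fasta, write_tsv)
from .phylo import (compile_tree, concatenate, fit_gene_rate,
                    normalize_relative_rates, optimize_branch_lengths)
from .pseudogene import (DEFAULT_FRAMESHIFT_PERSISTENCE,
                         DEFAULT_TRUNCATION_FRACTION, build_status_matrix,
                         calls_table, mask_pseudogenes, scan_records)
from .selection import (METHOD_A_P, METHOD_B_POSTERIOR, codon_columns,
                        consensus_sites, gene_kn_ks, gene_summary_table,
                        branch_kn_ks, ontology_enrichment, site_test_counting,
                        site_test_ebgrid)
from .windows import per_gene_gc, window_stats

logger = logging.getLogger("plastevo")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending item."""


@dataclass
class RunConfig:
    input_mode: str                      # 'genbank' | 'fasta' | 'synthetic'
    input_dir: str
    tree_path: str
    ontology_path: str | None = None
    out_dir: str = "plastevo_out"
    window_width: int = 100
    frameshift_persistence: int = DEFAULT_FRAMESHIFT_PERSISTENCE
    truncation_fraction: float = DEFAULT_TRUNCATION_FRACTION
    methodA_p: float = METHOD_A_P
    methodB_posterior: float = METHOD_B_POSTERIOR
    seed: int = 0
    genes: list[str] = field(default_factory=list)   # genbank mode: which genes

    def validate(self) -> None:
        if self.input_mode not in ("genbank", "fasta", "synthetic"):
            raise PipelineError(f"validate: unknown input mode {self.input_mode!r}")
        if not Path(self.tree_path).exists():
            raise PipelineError(f"validate: tree file {self.tree_path} not found")
        if not Path(self.input_dir).exists():
            raise PipelineError(f"validate: input dir {self.input_dir} not found")
        if self.ontology_path and not Path(self.ontology_path).exists():
            raise PipelineError(f"validate: ontology file {self.ontology_path} not found")
        if self.window_width < 1:
            raise PipelineError("validate: window width must be >= 1")
        if not (0 < self.methodA_p < 1 and 0 < self.methodB_posterior < 1):
            raise PipelineError("validate: thresholds must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Flat ``key = value`` config text; CLI flags override file values."""
        kv: dict[str, object] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise PipelineError(f"config line {lineno}: expected key = value")
            key, val = (x.strip() for x in line.split("=", 1))
            kv[key] = val
        for intkey in ("window_width", "frameshift_persistence", "seed"):
            if intkey in kv:
                kv[intkey] = int(kv[intkey])        # type: ignore[arg-type]
        for fkey in ("truncation_fraction", "methodA_p", "methodB_posterior"):
            if fkey in kv:
                kv[fkey] = float(kv[fkey])          # type: ignore[arg-type]
        if "genes" in kv:
            kv["genes"] = [g for g in str(kv["genes"]).split(",") if g]
        kv.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kv)  # type: ignore[arg-type]


def setup_logging(out_dir: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(out_dir / "run.log", mode="a"))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    root = logging.getLogger("plastevo")
    root.setLevel(logging.INFO)
    root.handlers = []
    for h in handlers:
        h.setFormatter(fmt)
        root.addHandler(h)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(vars(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_gene_records(config: RunConfig) -> dict[str, list[SequenceRecord]]:
    """Per-gene CDS records from GenBank flat files or per-gene FASTA."""
    indir = Path(config.input_dir)
    if config.input_mode == "genbank":
        if not config.genes:
            raise PipelineError("extract: genbank mode needs an explicit gene list")
        genes: dict[str, list[SequenceRecord]] = {g: [] for g in config.genes}
        files = sorted(indir.glob("*.gb")) + sorted(indir.glob("*.gbk"))
        if not files:
            raise PipelineError(f"extract: no GenBank files in {indir}")
        for fl in files:
            per_gene = extract_cds(fl, config.genes)
            for g, rec in per_gene.items():
                genes[g].append(rec)
        return genes
    gene_dir = indir / "genes" if (indir / "genes").is_dir() else indir
    files = sorted(gene_dir.glob("*.fasta")) + sorted(gene_dir.glob("*.fa"))
    if not files:
        raise PipelineError(f"extract: no per-gene FASTA files in {gene_dir}")
    return {fl.stem: read_fasta(fl) for fl in files}


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the report dict (also written as report.json)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(out)
    report: dict = {"version": __version__, "config_hash": _config_hash(config),
                    "config": {k: str(v) for k, v in vars(config).items()},
                    "stages": {}}
    t_start = time.time()

    def stage(name: str):
        logger.info("stage %s", name)
        return name

    try:
        name = stage("extract")
        gene_records = load_gene_records(config)
        ctree = compile_tree(read_newick(config.tree_path))
        report["stages"][name] = {"n_genes": len(gene_records),
                                  "n_taxa": len(ctree.taxa)}

        name = stage("align")
        alignments: dict[str, GeneAlignment] = {}
        for gene in sorted(gene_records):
            try:
                alignments[gene] = align_codon(gene_records[gene], gene=gene)
            except Exception as exc:
                raise PipelineError(f"align: gene {gene}: {exc}") from exc
        aln_dir = out / "alignments"
        aln_dir.mkdir(exist_ok=True)
        for gene, aln in alignments.items():
            write_fasta(aln.records, aln_dir / f"{gene}.fasta")
        report["stages"][name] = {"n_alignments": len(alignments)}

        name = stage("pseudo_scan")
        calls = []
        for gene in sorted(gene_records):
            try:
                calls.extend(scan_records(
                    gene_records[gene], gene=gene,
                    frameshift_persistence=config.frameshift_persistence,
                    truncation_fraction=config.truncation_fraction))
            except Exception as exc:
                raise PipelineError(f"pseudo_scan: gene {gene}: {exc}") from exc
        write_tsv(calls_table(calls), out / "pseudogene_calls.tsv")
        matrix = build_status_matrix(calls)
        matrix.to_csv(out / "status_matrix.tsv", sep="\t")
        n_pseudo = sum(c.status == "pseudogene" for c in calls)
        n_absent = sum(c.status == "absent" for c in calls)
        report["stages"][name] = {"n_calls": len(calls), "n_pseudogene": n_pseudo,
                                  "n_absent": n_absent}

        name = stage("mask_concatenate")
        masked = mask_pseudogenes(alignments, calls)
        sm = concatenate(masked, gene_order=sorted(masked))
        write_tsv(sm.partition_table(), out / "partitions.tsv")
        write_fasta([SequenceRecord(id=t, residues=sm.rows[t]) for t in sm.taxa],
                    out / "concatenate.fasta")
        report["stages"][name] = {"n_columns": sm.n_cols}

        name = stage("branch_lengths")
        ctree = optimize_branch_lengths(ctree, sm.rows)
        report["stages"][name] = {"tree_length": round(float(ctree.lengths.sum()), 6)}

        name = stage("windows")
        wdf = window_stats(sm.rows, ctree, width=config.window_width)
        write_tsv(wdf, out / "window_stats.tsv")
        write_tsv(per_gene_gc(sm), out / "gene_gc.tsv")
        report["stages"][name] = {"n_windows": len(wdf)}

        name = stage("gene_rates")
        rate_results = [fit_gene_rate(ctree, gene, sm.gene_rows(gene))
                        for gene in sorted(sm.partitions)]
        normalize_relative_rates(rate_results)
        rates_df = pd.DataFrame(
            [(r.gene, r.rate_scaler, r.relative_rate, r.parsimony_rate, r.flag)
             for r in rate_results],
            columns=["gene", "rate_scaler", "relative_rate", "parsimony_rate",
                     "flag"])
        write_tsv(rates_df, out / "gene_rates.tsv")
        report["stages"][name] = {"n_genes": len(rate_results)}

        name = stage("selection")
        kn_ks = {}
        per_gene_sites = {}
        branch_rows = []
        for gene, aln in sorted(masked.items()):
            kn_ks[gene] = gene_kn_ks(aln)
            cols = codon_columns(aln)
            if not cols:
                per_gene_sites[gene] = []
                continue
            res_a = site_test_counting(aln, ctree, p_threshold=config.methodA_p,
                                       columns=cols)
            res_b, _fit = site_test_ebgrid(
                aln, ctree, posterior_threshold=config.methodB_posterior,
                columns=cols)
            per_gene_sites[gene] = consensus_sites(res_a, res_b)
            branch_rows.append(branch_kn_ks(aln, ctree, columns=cols))
        summary = gene_summary_table(per_gene_sites, kn_ks)
        write_tsv(summary, out / "gene_summary.tsv")
        branch_df = (pd.concat(branch_rows, ignore_index=True) if branch_rows
                     else pd.DataFrame())
        write_tsv(branch_df, out / "branch_screen.tsv")
        site_rows = [(r.gene, r.site, round(r.s, 4), round(r.n, 4),
                      round(r.p_pos, 6), round(r.p_neg, 6),
                      None if r.posterior_prob_pos is None
                      else round(r.posterior_prob_pos, 6),
                      r.method_a, r.method_b, r.consensus)
                     for sites in per_gene_sites.values() for r in sites]
        write_tsv(pd.DataFrame(site_rows, columns=[
            "gene", "site", "syn", "nonsyn", "p_pos", "p_neg",
            "posterior_prob_pos", "method_a", "method_b", "consensus"]),
            out / "site_selection.tsv")
        report["stages"][name] = {
            "n_sites": int(sum(len(v) for v in per_gene_sites.values())),
            "n_methodA": int(sum(r.method_a for v in per_gene_sites.values()
                                 for r in v)),
            "n_methodB": int(sum(r.method_b for v in per_gene_sites.values()
                                 for r in v)),
            "n_consensus": int(sum(r.consensus for v in per_gene_sites.values()
                                   for r in v)),
        }

        name = stage("enrichment")
        if config.ontology_path:
            ont_df = read_tsv(config.ontology_path)
            ontology_map = dict(zip(ont_df["gene"], ont_df["ontology"]))
            enr = ontology_enrichment(per_gene_sites, ontology_map)
            write_tsv(enr, out / "enrichment.tsv")
            report["stages"][name] = {"n_tests": len(enr)}
        else:
            report["stages"][name] = {"skipped": "no ontology map supplied"}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"{name}: {exc}") from exc

    report["elapsed_s"] = round(time.time() - t_start, 2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %s", out)
    return report
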