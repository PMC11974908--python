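"""End-to-end pipeline orchestration and the Markdown run report.

``run_pipeline`` executes filter -> per-mix medians -> occupancies ->
replicate merge -> summary -> bins -> enrichment, writing every
intermediate table as TSV so each number in the report can be re-derived.
The validated configuration is echoed verbatim into the report for
provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import enrichment, io_model, quantify

log = logging.getLogger("parstoich")


def percent(k: int, n: int, digits: int = 2) -> float:
    """Composition percentage 100*k/n, rounded for presentation."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * k / n, digits)


@dataclass
class RunConfig:
    peptides: str = ""
    design: str = ""
    reference: str = ""
    sites: str | None = None
    fasta: str | None = None
    terms: str | None = None
    out_dir: str = "parstoich_out"
    sn_threshold: float = quantify.DEFAULT_SN_THRESHOLD
    sn_mode: str = "both"
    max_missed: int = 2
    shared_policy: str = "drop"
    alpha: float = enrichment.DEFAULT_ALPHA
    linkage: str = "single"
    ease: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.peptides or not self.design or not self.reference:
            raise ValueError("peptides, design and reference paths are required")
        if self.linkage != "single":
            raise ValueError("only single linkage is supported")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class ReportBundle:
    config: RunConfig
    filter_reports: dict = field(default_factory=dict)  # replicate -> FilterReport
    merged_table: object = None
    overlap: set = field(default_factory=set)
    replicate_r: float | None = None
    summary: object = None
    bins: list = field(default_factory=list)
    cluster: object = None
    out_dir: Path | None = None


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full pipeline per ``config``; writes tables + report.md."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(config=config, out_dir=out)

    mix_points = io_model.read_design(config.design)
    reference = io_model.read_reference(config.reference)
    records = io_model.read_fasta(config.fasta) if config.fasta else None
    sites = (
        io_model.read_sites(config.sites, records) if config.sites else None
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pairs = io_model.read_peptide_table(config.peptides)
    log.info("stage read: %d peptide pairs, %d mix points", len(pairs), len(mix_points))

    if not pairs:
        warnings.warn("empty peptide table: writing empty report", stacklevel=2)
        (out / "report.md").write_text(
            _render_report(bundle), encoding="utf-8"
        )
        return bundle

    by_rep: dict = {}
    for p in pairs:
        by_rep.setdefault(p.replicate_id, []).append(p)

    estimates_by_rep = {}
    for rep in sorted(by_rep):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            retained, report = quantify.filter_peptides(
                by_rep[rep],
                reference,
                sites=sites,
                protein_records=records,
                max_missed=config.max_missed,
                sn_threshold=config.sn_threshold,
                sn_mode=config.sn_mode,
                shared_policy=config.shared_policy,
            )
        bundle.filter_reports[rep] = report
        log.info(
            "stage filter [%s]: %d in -> %d retained", rep, report.n_input, report.n_pass
        )
        ests = quantify.estimate_stoichiometries(retained, mix_points, rep)
        estimates_by_rep[rep] = ests
        log.info("stage quantify [%s]: %d proteins", rep, len(ests))
        quantify.stoich_table_frame(ests, mix_points).to_csv(
            out / f"stoich_{rep}.tsv", sep="\t", index=False
        )

    _write_filter_reports(bundle.filter_reports, out / "filter_report.tsv")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        merged, overlap, r = quantify.merge_replicates(estimates_by_rep)
    bundle.merged_table, bundle.overlap, bundle.replicate_r = merged, overlap, r
    merged_out = merged.copy()
    merged_out.insert(len(merged_out.columns), "stoich_pct", merged_out["stoich"] * 100.0)
    merged_out.to_csv(out / "stoich_merged.tsv", sep="\t")
    log.info(
        "stage merge: %d proteins, overlap %d, r=%s",
        len(merged),
        len(overlap),
        "NA" if r is None else f"{r:.4f}",
    )

    if len(merged):
        bundle.summary = quantify.summarize(merged)
        (out / "summary.json").write_text(
            json.dumps(dataclasses.asdict(bundle.summary), indent=2),
            encoding="utf-8",
        )
        pct = {pid: v * 100.0 for pid, v in merged["stoich"].items()}
        bundle.bins = enrichment.assign_bins(pct)

        if config.terms:
            term_sets = io_model.read_term_sets(config.terms)
            background = set(merged.index)
            terms, matrix, cells = enrichment.enrichment_matrix(
                bundle.bins,
                term_sets,
                background,
                alpha=config.alpha,
                ease=config.ease,
            )
            _write_enrichment(cells, terms, matrix, out)
            if len(terms) >= 2:
                bundle.cluster = enrichment.cluster_terms(terms, matrix)
                _write_merges(bundle.cluster, out / "dendrogram_merges.tsv")
            log.info("stage enrich: %d significant terms", len(terms))

    (out / "report.md").write_text(_render_report(bundle), encoding="utf-8")
    return bundle


def _write_filter_reports(reports: dict, path: Path) -> None:
    cols = [f.name for f in dataclasses.fields(quantify.FilterReport)]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("replicate\t" + "\t".join(cols) + "\n")
        for rep in sorted(reports):
            vals = [str(getattr(reports[rep], c)) for c in cols]
            fh.write(rep + "\t" + "\t".join(vals) + "\n")


def _write_enrichment(cells, terms, matrix, out: Path) -> None:
    with open(out / "enrichment_cells.tsv", "wt", encoding="utf-8") as fh:
        fh.write("term\tbin\tk\tK\tn\tN\tp\tx\n")
        for c in cells:
            fh.write(
                f"{c.term}\t{c.bin}\t{c.k}\t{c.K}\t{c.n}\t{c.N}\t{c.p!r}\t{c.x!r}\n"
            )
    with open(out / "enrichment_matrix.tsv", "wt", encoding="utf-8") as fh:
        fh.write("term\t" + "\t".join(enrichment.BIN_LABELS) + "\n")
        for t, row in zip(terms, matrix):
            fh.write(t + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def _write_merges(cluster, path: Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("cluster_a\tcluster_b\theight\n")
        for a, b, h in cluster.merges:
            fh.write(f"{a}\t{b}\t{h!r}\n")


def _render_report(bundle: ReportBundle) -> str:
    lines = ["# Stoichiometry pipeline report", ""]
    lines += ["## Configuration", "", "```yaml"]
    lines.append(
        yaml.safe_dump(dataclasses.asdict(bundle.config), sort_keys=True).rstrip()
    )
    lines += ["```", ""]

    if bundle.filter_reports:
        lines += ["## Peptide filtering", ""]
        lines.append(
            "| replicate | input | pass | fail S/N | fail reference | "
            "fail site | fail shared |"
        )
        lines.append("|---|---|---|---|---|---|---|")
        for rep, fr in sorted(bundle.filter_reports.items()):
            lines.append(
                f"| {rep} | {fr.n_input} | {fr.n_pass} | {fr.n_fail_sn} | "
                f"{fr.n_fail_reference} | {fr.n_fail_site} | {fr.n_fail_shared} |"
            )
        lines.append("")

    if bundle.merged_table is not None and len(bundle.merged_table):
        n = len(bundle.merged_table)
        lines += ["## Occupancy estimates", ""]
        lines.append(f"- proteins quantified (union of replicates): {n}")
        lines.append(f"- overlap between replicates: {len(bundle.overlap)}")
        if bundle.replicate_r is not None:
            lines.append(
                f"- replicate concordance (Pearson r on log10 occupancy): "
                f"{bundle.replicate_r:.4f}"
            )
        s = bundle.summary
        if s is not None:
            lines += [
                "",
                "## Occupancy distribution",
                "",
                f"- median: {s.median_pct:.3f}%  mean: {s.mean_pct:.3f}%",
                f"- range: {s.min_pct:.3f}% – {s.max_pct:.3f}%",
                f"- proteins > 5%: {s.n_gt_5pct} "
                f"({percent(s.n_gt_5pct, s.n_proteins)}%)",
                f"- proteins < 1%: {s.n_lt_1pct} "
                f"({percent(s.n_lt_1pct, s.n_proteins)}%)",
                "- bin counts: "
                + ", ".join(f"{k}: {v}" for k, v in s.bin_counts.items()),
            ]
        lines.append("")
    else:
        lines += ["## Occupancy estimates", "", "No proteins quantified.", ""]

    if bundle.cluster is not None:
        lines += [
            "## Enrichment clustering",
            "",
            f"- significant terms clustered: {len(bundle.cluster.terms)}",
            f"- leaf order: {', '.join(bundle.cluster.leaf_order)}",
            "",
        ]
    return "\n".join(lines)
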