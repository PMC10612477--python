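"""Pipeline driver: orthology -> alignments -> trees -> model fits -> reports.

Each orthologous gene cluster (OGC) is an independent unit of work, drawn
from a queue by whichever worker is free; per-OGC RNG seeds derive from the
global seed and the cluster id, so results are independent of scheduling
order and result files are byte-identical across thread counts. Branch and
branch-site scans run only for OGCs whose site-model tests show significant
positive-selection signal after FDR (the gate), with every terminal branch
designated foreground in turn. One cluster's optimizer failure marks that
cluster failed and never aborts the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tarfile
import tempfile
import zlib
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .alignment import (
    CodonAlignment, TooShortError, align_proteins, back_translate,
    clean_columns, write_phylip,
)
from .codon_engine import (
    ModelFit, fit_branch_model, fit_branch_site, fit_model, selected_sites,
    site_posteriors,
)
from .gene_tree import (
    GeneTree, emit_nexus, nj_tree, pairwise_distances, parse_newick,
    prune_to_taxa, to_newick, unroot,
)
from .orthology import OGC, ScoringConfig, predict_ogcs, write_orthology_table
from .selection_stats import LRTResult, fdr_adjust, lrt
from .sequence_io import (
    ProteomePair, load_proteomes, write_fasta, write_validation_report,
)

log = logging.getLogger(__name__)

SSM_MODELS = ("M0", "M1a", "M2a", "M3k3", "M7", "M8", "M8a")
SSM_COMPARISONS = ("M0_vs_M3", "M1a_vs_M2a", "M7_vs_M8", "M8a_vs_M8")
GATE_COMPARISONS = ("M1a_vs_M2a", "M7_vs_M8")


@dataclass
class PipelineConfig:
    out_dir: str
    min_species: int = 3
    models: tuple[str, ...] = ("ssm", "branch", "branchsite")
    threads: int = 1
    seed: int = 0
    gap_policy: str = "complete_deletion"
    fdr_pooled: bool = False
    threshold: float = 0.05
    archive: bool = True
    n_starts: int = 2
    freqs_method: str = "F3x4"
    scoring: ScoringConfig = field(default_factory=ScoringConfig)

    def __post_init__(self) -> None:
        if self.threads < 1:
            raise ValueError("thread count must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("significance threshold must lie in (0, 1)")


def ogc_seed(global_seed: int, ogc_id: str) -> int:
    """Stable per-cluster seed, independent of scheduling order."""
    return zlib.crc32(f"{global_seed}:{ogc_id}".encode()) % (2**31)


@dataclass
class OGCResult:
    ogc: OGC
    status: str                       # completed | failed | skipped:<reason>
    tree: GeneTree | None = None
    codon_alignment: CodonAlignment | None = None   # cleaned
    raw_alignment: CodonAlignment | None = None
    protein_rows: dict[str, str] | None = None
    fits: dict[str, ModelFit] = field(default_factory=dict)
    lrts: list[LRTResult] = field(default_factory=list)
    sites: list = field(default_factory=list)
    error: str | None = None


def process_ogc(ogc: OGC, peptides: dict[str, str], cds: dict[str, str],
                config: PipelineConfig) -> OGCResult:
    """Run alignment, tree building, and the site-model schedule for one OGC."""
    seed = ogc_seed(config.seed, ogc.ogc_id)
    try:
        pa = align_proteins(peptides)
        raw_ca = back_translate(pa, cds)
        try:
            ca = clean_columns(raw_ca, config.gap_policy)
        except TooShortError as exc:
            return OGCResult(ogc=ogc, status="skipped:too_short", error=str(exc))
        dist = pairwise_distances(pa.taxa, pa.rows)
        tree = nj_tree(dist, pa.taxa)

        fits: dict[str, ModelFit] = {}
        kw = dict(seed=seed, n_starts=config.n_starts)
        fits["M0"] = fit_model(tree, ca, "M0", **kw)
        fits["M3k3"] = fit_model(tree, ca, "M3k3", warm_start=fits["M0"], **kw)
        fits["M1a"] = fit_model(tree, ca, "M1a", **kw)
        fits["M2a"] = fit_model(tree, ca, "M2a", warm_start=fits["M1a"], **kw)
        fits["M7"] = fit_model(tree, ca, "M7", **kw)
        fits["M8a"] = fit_model(tree, ca, "M8a", warm_start=fits["M7"], **kw)
        fits["M8"] = fit_model(tree, ca, "M8", warm_start=fits["M8a"], **kw)

        lrts = [
            lrt(fits["M0"], fits["M3k3"], "M0_vs_M3", ogc.ogc_id),
            lrt(fits["M1a"], fits["M2a"], "M1a_vs_M2a", ogc.ogc_id),
            lrt(fits["M7"], fits["M8"], "M7_vs_M8", ogc.ogc_id),
            lrt(fits["M8a"], fits["M8"], "M8a_vs_M8", ogc.ogc_id),
        ]
        sites = site_posteriors(fits["M2a"], tree, ca)
        return OGCResult(ogc=ogc, status="completed", tree=tree,
                         codon_alignment=ca, raw_alignment=raw_ca,
                         protein_rows=dict(zip(pa.taxa, pa.rows)),
                         fits=fits, lrts=lrts, sites=sites)
    except Exception as exc:  # failure isolation: never abort the run
        log.exception("OGC %s failed", ogc.ogc_id)
        return OGCResult(ogc=ogc, status="failed", error=f"{type(exc).__name__}: {exc}")


def _process_ogc_star(args) -> OGCResult:
    return process_ogc(*args)


def branch_scan(result: OGCResult, config: PipelineConfig) -> list[LRTResult]:
    """Per-foreground branch and branch-site tests for one gated OGC."""
    seed = ogc_seed(config.seed, result.ogc.ogc_id + ":branch")
    out: list[LRTResult] = []
    tree, ca = result.tree, result.codon_alignment
    for fg in sorted(tree.leaves()):
        if "branch" in config.models:
            try:
                null, alt = fit_branch_model(
                    tree, ca, fg, seed=seed, n_starts=config.n_starts,
                    m0_fit=result.fits.get("M0"))
                out.append(lrt(null, alt, "BR2_vs_M0", result.ogc.ogc_id,
                               foreground=fg))
            except Exception as exc:
                log.warning("%s branch fit failed for %s: %s",
                            result.ogc.ogc_id, fg, exc)
        if "branchsite" in config.models:
            try:
                null, alt = fit_branch_site(
                    tree, ca, fg, seed=seed, n_starts=config.n_starts,
                    m1a_fit=result.fits.get("M1a"))
                out.append(lrt(null, alt, "BSA_vs_BSA0", result.ogc.ogc_id,
                               foreground=fg))
            except Exception as exc:
                log.warning("%s branch-site fit failed for %s: %s",
                            result.ogc.ogc_id, fg, exc)
    return out


def _branch_scan_star(args) -> tuple[str, list[LRTResult]]:
    result, config = args
    return result.ogc.ogc_id, branch_scan(result, config)


def _map(jobs, fn, threads: int):
    if threads == 1 or len(jobs) <= 1:
        return [fn(j) for j in jobs]
    with ProcessPoolExecutor(max_workers=threads) as pool:
        return list(pool.map(fn, jobs))


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def _fmt(x: float | None, digits: int = 6) -> str:
    if x is None:
        return "NA"
    return format(float(x), f".{digits}f")


def _fmt_p(x: float | None) -> str:
    return "NA" if x is None else format(float(x), ".6g")


def write_ssm_csv(results: list[OGCResult], lrt_index: dict, path: Path,
                  threshold: float) -> None:
    cols = ["ogc_id", "n_species", "species"]
    for m in SSM_MODELS:
        cols += [f"{m}_lnL", f"{m}_np", f"{m}_omega"]
    for c in SSM_COMPARISONS:
        cols += [f"{c}_2dlnL", f"{c}_dof", f"{c}_p", f"{c}_q", f"{c}_significant"]
    cols += ["positive_selection_call", "selected_sites"]
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for r in results:
            if r.status != "completed":
                continue
            row = [r.ogc.ogc_id, str(r.ogc.n_species),
                   ";".join(sorted(r.ogc.members))]
            for m in SSM_MODELS:
                f = r.fits[m]
                row += [_fmt(f.lnL), str(f.np_params), _fmt(f.omega_summary(), 4)]
            call = positive_selection_call(r, lrt_index, threshold)
            for c in SSM_COMPARISONS:
                t = lrt_index.get((r.ogc.ogc_id, c, None))
                row += [_fmt(t.two_delta_lnl, 4), str(t.dof),
                        _fmt_p(t.p_value), _fmt_p(t.q_value),
                        "yes" if t.q_value is not None and t.q_value < threshold
                        else "no"]
            sites = selected_sites(r.sites)
            row += ["yes" if call else "no",
                    ";".join(f"{s.site}:{s.posterior:.4f}" for s in sites)]
            fh.write(",".join(row) + "\n")


def write_branch_csv(branch_lrts: list[LRTResult], path: Path,
                     threshold: float) -> None:
    cols = ["ogc_id", "foreground", "comparison", "lnL_null", "lnL_alt",
            "np_null", "np_alt", "2dlnL", "dof", "p", "q", "significant"]
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for t in sorted(branch_lrts,
                        key=lambda x: (x.ogc_id, x.foreground or "", x.comparison)):
            fh.write(",".join([
                t.ogc_id, t.foreground or "", t.comparison,
                _fmt(t.lnl_null), _fmt(t.lnl_alt), str(t.np_null), str(t.np_alt),
                _fmt(t.two_delta_lnl, 4), str(t.dof),
                _fmt_p(t.p_value), _fmt_p(t.q_value),
                "yes" if t.q_value is not None and t.q_value < threshold else "no",
            ]) + "\n")


def positive_selection_call(result: OGCResult, lrt_index: dict,
                            threshold: float) -> bool:
    """Significant M1a-vs-M2a or M7-vs-M8 test AND a positive-class omega > 1."""
    for comp, model, key in (("M1a_vs_M2a", "M2a", "omega2"),
                             ("M7_vs_M8", "M8", "omega_s")):
        t = lrt_index.get((result.ogc.ogc_id, comp, None))
        if t is None or t.q_value is None or t.q_value >= threshold:
            continue
        if result.fits[model].estimates[key] > 1.0 + 1e-6:
            return True
    return False


def archive_ogc(result: OGCResult, results_dir: Path) -> None:
    """Per-OGC tar.gz mirroring the documented manual re-run layout."""
    ogc_id = result.ogc.ogc_id
    with tempfile.TemporaryDirectory() as tmp:
        root = Path(tmp) / "Orthology_Groups"
        root.mkdir()
        write_fasta(zip(result.codon_alignment.taxa, result.codon_alignment.rows),
                    root / f"{ogc_id}.codon.fasta")
        write_fasta(zip(result.raw_alignment.taxa, result.raw_alignment.rows),
                    root / f"{ogc_id}.codon.raw.fasta")
        write_fasta(result.protein_rows.items(), root / f"{ogc_id}.pep.fasta")
        write_phylip(result.codon_alignment, root / f"{ogc_id}.codon.phy")
        (root / f"{ogc_id}.dnd").write_text(to_newick(result.tree) + "\n")
        (root / f"{ogc_id}.dnd.GenTree.nex").write_text(emit_nexus(result.tree))
        fits = {m: f.to_dict() for m, f in result.fits.items()}
        (root / f"{ogc_id}.fits.json").write_text(json.dumps(fits, indent=1))
        ctl = "\n".join([
            f"seqfile = {ogc_id}.codon.phy",
            f"treefile = {ogc_id}.dnd",
            "seqtype = 1", "CodonFreq = 2", "model = 0",
            "NSsites = 0 1 2 3 7 8", "cleandata = 1", ""])
        (root / f"{ogc_id}.ctl").write_text(ctl)
        with tarfile.open(results_dir / f"{ogc_id}.tar.gz", "w:gz") as tar:
            tar.add(root, arcname="Orthology_Groups")


# ---------------------------------------------------------------------------
# top-level entry points
# ---------------------------------------------------------------------------

def run_pipeline(entries: list[tuple[str, Path, Path]],
                 config: PipelineConfig) -> dict:
    """Execute the four workflow steps end to end; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_dir = out / "Results"
    results_dir.mkdir(exist_ok=True)

    proteomes = load_proteomes(entries)
    write_validation_report(proteomes, out / "validation_report.tsv")
    species_ids = [p.species_id for p in proteomes]
    if len(proteomes) < 3:
        log.warning("fewer than 3 species supplied: no OGC can satisfy the "
                    "minimum-three-species rule")
        ogcs: list[OGC] = []
    else:
        ogcs = predict_ogcs(proteomes, config.scoring, config.min_species)
    write_orthology_table(ogcs, species_ids, out / "orthology.tsv")

    records = {p.species_id: p.as_dict() for p in proteomes}
    jobs = []
    for ogc in ogcs:
        peptides = {sp: records[sp][h].peptide for sp, h in ogc.members.items()}
        cds = {sp: records[sp][h].cds for sp, h in ogc.members.items()}
        jobs.append((ogc, peptides, cds, config))
    results: list[OGCResult] = _map(jobs, _process_ogc_star, config.threads)
    results.sort(key=lambda r: r.ogc.ogc_id)

    # FDR across clusters, per comparison family
    ssm_lrts = [t for r in results for t in r.lrts]
    ssm_lrts = fdr_adjust(ssm_lrts, pooled=config.fdr_pooled)
    lrt_index = {(t.ogc_id, t.comparison, t.foreground): t for t in ssm_lrts}
    write_ssm_csv(results, lrt_index, out / "ssm_results.csv", config.threshold)

    # gate, then branch / branch-site scans
    gated = [r for r in results if r.status == "completed" and any(
        (t := lrt_index.get((r.ogc.ogc_id, c, None))) is not None
        and t.q_value is not None and t.q_value < config.threshold
        for c in GATE_COMPARISONS)]
    branch_lrts: list[LRTResult] = []
    if gated and ({"branch", "branchsite"} & set(config.models)):
        scan_out = _map([(r, config) for r in gated], _branch_scan_star,
                        config.threads)
        scan_out.sort(key=lambda x: x[0])
        branch_lrts = [t for _, lrts in scan_out for t in lrts]
        branch_lrts = fdr_adjust(branch_lrts, pooled=config.fdr_pooled)
    write_branch_csv(branch_lrts, out / "branch_results.csv", config.threshold)

    if config.archive:
        for r in results:
            if r.status == "completed":
                archive_ogc(r, results_dir)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "species": species_ids,
        "n_ogcs": len(ogcs),
        "gated_ogcs": [r.ogc.ogc_id for r in gated] if ogcs else [],
        "ogc_status": {r.ogc.ogc_id: r.status for r in results},
        "ogc_errors": {r.ogc.ogc_id: r.error for r in results if r.error},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    return manifest


def rerun_ogc(archive_path: str | Path, species_tree: str | None = None,
              seed: int = 0, n_starts: int = 2) -> dict[str, ModelFit]:
    """Re-fit the site models for one archived OGC, optionally replacing the
    gene tree with a (pruned) species tree — the subgroup-validation workflow."""
    archive_path = Path(archive_path)
    ogc_id = archive_path.name.replace(".tar.gz", "")
    with tempfile.TemporaryDirectory() as tmp:
        with tarfile.open(archive_path) as tar:
            tar.extractall(tmp, filter="data")
        root = Path(tmp) / "Orthology_Groups"
        from .sequence_io import read_fasta
        recs = read_fasta(root / f"{ogc_id}.codon.fasta")
        ca = CodonAlignment(taxa=[h for h, _ in recs], rows=[s for _, s in recs])
        tree = parse_newick((root / f"{ogc_id}.dnd").read_text())
    if species_tree is not None:
        tree = prune_to_taxa(species_tree, ca.taxa)
    tree = unroot(tree)
    fits: dict[str, ModelFit] = {}
    kw = dict(seed=seed, n_starts=n_starts)
    fits["M0"] = fit_model(tree, ca, "M0", **kw)
    fits["M1a"] = fit_model(tree, ca, "M1a", **kw)
    fits["M2a"] = fit_model(tree, ca, "M2a", warm_start=fits["M1a"], **kw)
    return fits
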