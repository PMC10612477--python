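# orthoselect

Genome-scale scans for positive (diversifying) selection over one-to-one
orthologs, with no external alignment/orthology/phylogenetics binaries.

From two FASTA files per species — coding sequences (CDS) and the matching
peptides, with identical headers — the pipeline:

1. predicts **orthologous gene clusters (OGCs)** from all-vs-all
   Smith–Waterman protein similarity and reciprocal-(near-)best-hit
   clustering, keeping only clusters that span at least three species and
   contain exactly one gene per species (clusters with within-species
   paralogs are discarded wholesale);
2. aligns each cluster's peptides, back-translates the protein alignment to
   an in-frame **codon alignment**, and builds a neighbor-joining gene tree;
3. fits **GY94 codon substitution models** by maximum likelihood — the site
   models M0, M1a, M2a, M3 (k=3), M7, M8, M8a, plus branch (two-ratio) and
   branch-site (Model A) models with each terminal branch designated
   foreground in turn;
4. reports **likelihood-ratio tests** (M0 vs M3, M1a vs M2a, M7 vs M8,
   M8a vs M8; branch and branch-site tests per foreground) with
   Benjamini–Hochberg FDR control across clusters, and naive empirical
   Bayes (NEB) posteriors for positively selected sites — all in flat CSV
   tables plus per-cluster archives for manual re-runs.

The statistic of interest is ω = dN/dS, the ratio of nonsynonymous to
synonymous substitution rates: ω > 1 on a site class or branch indicates
positive selection. Substitution rates between sense codons i → j follow
Goldman–Yang: q_ij = π_j · {1, κ, ω, κω} for synonymous/nonsynonymous
transversions/transitions differing at one nucleotide, zero otherwise, with
2ΔlnL between nested models referred to χ² with the schedule's degrees of
freedom (4, 2, 2, 1, 1, 1).

Intended users: comparative genomicists who have per-species proteome +
CDS FASTA files and want a selection scan that runs end to end with default
parameters on a workstation.

## Worked example

Simulate the bundled 3-species example — three 300-codon gene families, one
of them under strong episodic positive selection — then scan it:

```bash
orthoselect simulate --toy --seed 0 --out toy
orthoselect run --cds-dir toy/cds --pep-dir toy/pep --out scan --seed 5
```

The run prints:

```
3 OGCs predicted; 3 analyzed; 1 passed the site-model gate. Results in scan
```

and `scan/ssm_results.csv` holds one row per OGC. For the gated cluster the
relevant columns read (abridged):

```
ogc_id   M1a_lnL       M2a_lnL       M2a_omega  M1a_vs_M2a_2dlnL  M1a_vs_M2a_p  selected_sites
OGC0002  -2167.179713  -2136.917574  5.7222     60.5243           7.19979e-14   22:0.9809;25:0.9901;32:0.9995;...
```

Read this as: the alternative model with an ω > 1 site class (M2a, ω̂₂ ≈ 5.7)
fits this cluster far better than the nearly-neutral null (2ΔlnL ≈ 60.5,
p ≈ 7e-14, q < 0.05 after BH across clusters), so the cluster is called
positively selected and the listed codon sites carry NEB posterior ≥ 0.95 of
belonging to the selected class (coordinates refer to the original codon
alignment). `scan/branch_results.csv` then reports, for gated clusters only,
the branch and branch-site tests with each terminal branch as foreground —
exactly n_species foreground runs per cluster. Per-cluster archives under
`scan/Results/<ogc_id>.tar.gz` contain the alignments (FASTA/PHYLIP), the
gene tree in Newick (`.dnd`) and Nexus (`.dnd.GenTree.nex`) form, and fit
reports; to validate a cluster against a trusted species phylogeny, either
replace the tree file and re-run manually, or use

```bash
orthoselect rerun-ogc scan/Results/OGC0002.tar.gz --tree species.nwk
```

which prunes the species tree to the cluster's taxa and re-fits the site
models.

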