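#!/usr/bin/env python
"""Pathway-level follow-up for the mediator genes found by the screen.

For each mediator gene implicated by 02_mediation_screen.py, test every
gene set containing it: pool the member genes' significant eQTLs, prune
to near-linkage-equilibrium, and rank-correlate |z_eqtl| with |z_gwas|
for the linked trait.  Writes results/pathway_results.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from methmr.ld import LdPanel
from methmr.pathway import pathway_scan
from methmr.sumstats_io import read_gmt, read_gwas_ma, read_qtl_table

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    study = ROOT / "scratch" / f"study_seed{args.seed}"
    passes_path = ROOT / "results" / "mediation_passes.tsv"
    if not study.exists() or not passes_path.exists():
        raise SystemExit("run 01_simulate_study.py and 02_mediation_screen.py first")

    panel = LdPanel.from_tsv(study / "panel_genotypes.tsv",
                             study / "panel_sites.tsv")
    snp_map = panel.snp_map()
    eqtl_store = {p.gene_name: p for p in read_qtl_table(study / "eqtl.tsv")}
    gene_sets = read_gmt(study / "gene_sets.gmt")
    passes = pd.read_csv(passes_path, sep="\t")

    rows = []
    for _, row in passes.iterrows():
        genes = [g for g in str(row.genes).split(";") if g and g != "nan"]
        gwas = read_gwas_ma(study / f"gwas_{row.trait_id}.ma", snp_map=snp_map)
        for gene in genes:
            for res in pathway_scan(gene, gene_sets, eqtl_store, gwas, panel,
                                    trait_id=row.trait_id):
                rows.append({
                    "trait": res.trait_id, "gene_indicator": res.gene_indicator,
                    "set_id": res.set_id, "description": res.description,
                    "n_snps": res.n_snps, "r": res.rho, "p": res.p, "q": res.q,
                })
    out = pd.DataFrame(rows, columns=["trait", "gene_indicator", "set_id",
                                      "description", "n_snps", "r", "p", "q"])
    out.to_csv(ROOT / "results" / "pathway_results.tsv", sep="\t",
               index=False, float_format="%.4g")
    print(out.to_string(index=False) if len(out) else "no pathways tested")


if __name__ == "__main__":
    main()
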