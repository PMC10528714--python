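#!/usr/bin/env python
"""Simulate the reference synthetic study and write its file bundle.

The bundle emulates the inputs of the real screen: an LD reference panel,
an EWAS-style candidate CpG list, two mQTL cohorts (discovery and
replication), an eQTL cohort, three GWAS traits with polygenic
background, gene sets, and a ground-truth manifest.

Writes the (large) bundle under scratch/ and a small design summary under
results/.
"""

import argparse
import shutil
from collections import Counter
from pathlib import Path

import pandas as pd

from methmr.synthetic import ScenarioSpec, emit_study

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    outdir = ROOT / "scratch" / f"study_seed{args.seed}"
    if outdir.exists():
        shutil.rmtree(outdir)
    spec = ScenarioSpec(seed=args.seed)
    bundle = emit_study(spec, outdir)

    topo = Counter(info["topology"] for info in bundle.manifest["cpgs"].values())
    summary = pd.DataFrame([
        {"quantity": "snps", "value": bundle.panel.n_snps},
        {"quantity": "candidate_cpgs", "value": len(bundle.mqtl_disc)},
        {"quantity": "genes", "value": len(bundle.eqtl)},
        {"quantity": "traits", "value": len(bundle.gwas)},
        *({"quantity": f"cpgs_{k}", "value": v} for k, v in sorted(topo.items())),
        {"quantity": "true_cpg_trait_pairs", "value": len(bundle.manifest["true_pairs"])},
    ])
    (ROOT / "results").mkdir(exist_ok=True)
    summary.to_csv(ROOT / "results" / "study_design.tsv", sep="\t", index=False)

    print(f"study bundle written to {outdir}")
    print(summary.to_string(index=False))
    print("\nPlanted mediating CpG-trait pairs:")
    for cpg, trait in bundle.manifest["true_pairs"]:
        print(f"  {cpg} -> {trait}")


if __name__ == "__main__":
    main()
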