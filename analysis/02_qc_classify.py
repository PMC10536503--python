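"""QC-filter the genotypes and classify the cohort into cases, pedigree-
inferred carriers, controls, and excluded relatives.

Reads the dataset written by 01_simulate.py; writes the QC report, the
pairwise IBD (PIHAT) table, and the per-dog status assignment.
"""

import argparse
from pathlib import Path

import pandas as pd

from carriergwas import genio, relatedness
from carriergwas.pedigree import build_pedigree, classify_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results/analysis")
    ap.add_argument("--pihat-cutoff", type=float, default=0.25)
    args = ap.parse_args()
    base = Path(args.out)
    data = base / "data"

    gm = genio.read_ped_map(data / "genotypes.ped", data / "genotypes.map")
    gm, report = genio.qc_filter(gm, mind=0.2, geno=0.25, maf=0.02)
    report.removed_samples.to_csv(base / "qc_removed_samples.tsv", sep="\t", index=False)
    report.removed_variants.to_csv(base / "qc_removed_variants.tsv", sep="\t", index=False)
    print(f"QC: kept {gm.n_samples} dogs x {gm.n_variants} SNPs "
          f"(removed {len(report.removed_samples)} dogs, {len(report.removed_variants)} SNPs)")

    ibd = relatedness.pihat(gm)
    ibd.to_csv(base / "pihat.tsv", sep="\t", index=False, float_format="%.4f")

    ped = build_pedigree(pd.read_csv(data / "pedigree.csv"))
    clinical = pd.read_csv(data / "clinical.csv")
    cases = [str(i) for i in clinical.loc[clinical["affected"] == 1, "id"]]
    diagnoses = {
        str(r["id"]): ("T" if r.get("immunophenotype") == "T" else "confirmed")
        for _, r in clinical.iterrows()
    }
    status = classify_cohort(
        ped, cases, gm.samples, diagnoses=diagnoses, pihat=ibd,
        pihat_cutoff=args.pihat_cutoff,
    )
    status.to_frame().to_csv(base / "status.tsv", sep="\t", index=False)
    counts = status.counts()
    print("cohort classification:", ", ".join(f"{k}={v}" for k, v in sorted(counts.items())))
    reasons = pd.Series(list(status.reason.values())).value_counts()
    print("exclusion/carrier reasons:")
    for r, n in reasons.items():
        print(f"  {n:4d}  {r}")


if __name__ == "__main__":
    main()
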