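"""Simulate the study population: a closed breeding pedigree with a planted
recessive lymphoma-risk locus, and write the genotype/pedigree/clinical/truth
files every later step consumes.

Run:  python analysis/01_simulate.py [--config configs/demo.yaml] [--out results/analysis]
"""

import argparse
from pathlib import Path

import numpy as np

from carriergwas import genio
from carriergwas.pipeline import load_config
from carriergwas.simdata import simulate_dataset, write_dataset


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--config", default="configs/demo.yaml")
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()

    cfg = load_config(args.config)
    sim = cfg.simulation
    ds = simulate_dataset(sim)

    rng = np.random.default_rng(sim.seed + 2)
    cases = list(ds.case_ids)
    rest = [i for i in ds.pedigree.ids if i not in set(cases)]
    n_extra = max(0, cfg.n_genotyped - len(cases))
    genotyped = sorted(
        cases + [str(x) for x in rng.choice(rest, size=min(n_extra, len(rest)), replace=False)]
    )[: cfg.n_genotyped]

    gm = genio.recode_minor(ds.genotypes.subset(samples=genotyped))
    outdir = Path(args.out) / "data"
    write_dataset(
        gm, ds.pedigree,
        ds.clinical[ds.clinical["id"].isin(genotyped)],
        ds.truth[ds.truth["id"].isin(genotyped)],
        outdir, missing_rate=sim.missing_rate,
        rng=np.random.default_rng(sim.seed + 1),
    )

    prev = ds.clinical["affected"].mean()
    n_cases_geno = int(ds.clinical[ds.clinical["id"].isin(genotyped)]["affected"].sum())
    print(f"population: {len(ds.pedigree)} dogs over {sim.n_generations} generations")
    print(f"realized prevalence: {prev:.3f}  ({int(ds.clinical['affected'].sum())} cases)")
    print(f"genotyped cohort: {gm.n_samples} dogs ({n_cases_geno} cases) x {gm.n_variants} SNPs")
    print(f"planted risk locus: {sim.risk_variant_id} (founder freq {sim.risk_locus[2]})")
    print(f"wrote {outdir}/")


if __name__ == "__main__":
    main()
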