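"""REML variance components for the binary phenotype: all autosomes, the
significant chromosomes, and the significant regions, each transformed to
the liability scale at assumed prevalences 0.025, 0.05, and 0.1.
"""

import argparse
import importlib.util
from pathlib import Path

import pandas as pd

from carriergwas import genio, herit

PREVALENCES = (0.025, 0.05, 0.1)

_spec = importlib.util.spec_from_file_location(
    "gwas_driver", Path(__file__).parent / "03_gwas.py"
)
_gwas = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_gwas)
load_status = _gwas.load_status


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()
    base = Path(args.out)
    data = base / "data"

    gm = genio.read_ped_map(data / "genotypes.ped", data / "genotypes.map")
    gm, _ = genio.qc_filter(gm, mind=0.2, geno=0.25, maf=0.02)
    status = load_status(base / "status.tsv")
    pheno = status.binary
    samples = [s for s in gm.samples if s in pheno]
    sub = gm.subset(samples=samples)
    n_cases = sum(pheno[s] for s in samples)

    scan = pd.read_csv(base / "quantitative" / "mlma.tsv", sep="\t", dtype={"Chr": str})
    sig = scan[scan["q_chr"] < 0.1]
    regions = [("all_autosomes", None)]
    for chrom in list(dict.fromkeys(sig["Chr"]))[:2]:
        in_chr = sig[sig["Chr"] == chrom]
        lo, hi = int(in_chr["bp"].min()), int(in_chr["bp"].max())
        regions += [(f"chr{chrom}", chrom), (f"chr{chrom}:{lo}-{hi}", f"{chrom}:{lo}-{hi}")]

    frames = []
    for name, region in regions:
        grm = herit.grm_subset(sub, region)
        try:
            vc = herit.ai_reml(grm, pheno)
        except herit.RemlError as err:
            print(f"{name}: REML failed ({err})")
            continue
        liab = [
            herit.liability_transform(vc.h2_obs, vc.se, K, n_cases, len(samples))
            for K in PREVALENCES
        ]
        frame = vc.to_hsq_frame(liab)
        frame.insert(0, "Region", name)
        frames.append(frame)
        liab_str = ", ".join(
            f"{le.h2_liability*100:.1f}% (K={le.prevalence:g})" for le in liab
        )
        print(f"{name}: V(G)/Vp={vc.h2_obs*100:.1f}% +- {vc.se*100:.1f}% "
              f"(p={vc.p_value:.2e}, M={grm.m}); liability: {liab_str}")
    pd.concat(frames, ignore_index=True).to_csv(
        base / "reml.tsv", sep="\t", index=False, float_format="%.6g"
    )


if __name__ == "__main__":
    main()
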