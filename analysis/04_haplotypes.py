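"""Haplotype-block analysis of the significant chromosomes: Gabriel-style
block detection, EM haplotype frequencies, per-haplotype regression, and the
per-group homozygosity tables for highly significant haplotypes.
"""

import argparse
import importlib.util
from pathlib import Path

import pandas as pd

from carriergwas import genio, hapblock

HAP_P_CUTOFF = 1e-4

_spec = importlib.util.spec_from_file_location(
    "gwas_driver", Path(__file__).parent / "03_gwas.py"
)
_gwas = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_gwas)
load_status = _gwas.load_status


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results/analysis")
    ap.add_argument("--max-chromosomes", type=int, default=2)
    args = ap.parse_args()
    base = Path(args.out)
    data = base / "data"

    gm = genio.read_ped_map(data / "genotypes.ped", data / "genotypes.map")
    gm, _ = genio.qc_filter(gm, mind=0.2, geno=0.25, maf=0.02)
    status = load_status(base / "status.tsv")

    for design, pheno, model, groups in (
        ("quantitative", status.y, "linear", ("case", "carrier", "control")),
        ("binary", status.binary, "logistic", ("case", "control")),
    ):
        ddir = base / design
        scan = pd.read_csv(ddir / "mlma.tsv", sep="\t", dtype={"Chr": str, "SNP": str})
        sig = scan[scan["q_chr"] < 0.1]
        chroms = list(dict.fromkeys(sig["Chr"]))[: args.max_chromosomes]
        samples = [s for s in gm.samples if s in pheno]
        sub = gm.subset(samples=samples)
        rows_b, rows_a, rows_h = [], [], []
        for chrom in chroms:
            for blk in hapblock.find_blocks(sub, chrom):
                rows_b.append(
                    {"chrom": blk.chrom, "bp_start": blk.start_bp, "bp_end": blk.end_bp,
                     "n_snps": blk.n_snps, "snps": ",".join(blk.snp_ids)}
                )
                tab = hapblock.em_hap_freqs(sub, blk)
                ha = hapblock.hap_association(sub, blk, pheno, model=model, table=tab)
                if len(ha):
                    rows_a.append(ha)
                    hits = ha[ha["p"] < HAP_P_CUTOFF]
                    if len(hits):
                        homo = hapblock.hap_homozygosity_by_group(tab, status.status, groups=groups)
                        rows_h.append(homo[homo["haplotype"].isin(hits["haplotype"])])
        pd.DataFrame(rows_b).to_csv(ddir / "blocks.tsv", sep="\t", index=False)
        n_hits = 0
        if rows_a:
            allhap = pd.concat(rows_a, ignore_index=True)
            allhap.to_csv(ddir / "hap_association.tsv", sep="\t", index=False, float_format="%.6g")
            n_hits = int((allhap["p"] < HAP_P_CUTOFF).sum())
        if rows_h:
            pd.concat(rows_h, ignore_index=True).to_csv(
                ddir / "hap_homozygosity.tsv", sep="\t", index=False, float_format="%.6g"
            )
        print(f"[{design}] chromosomes {chroms}: {len(rows_b)} blocks, "
              f"{n_hits} haplotypes with p<{HAP_P_CUTOFF:g}")


if __name__ == "__main__":
    main()
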