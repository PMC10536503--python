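"""End-to-end orchestration: simulate/load -> QC -> classify -> GWAS (both
designs) -> FDR -> haplotypes -> networks -> REML -> report bundle.

All randomness flows from one seed; rerunning the same config reproduces the
output files byte for byte. Every stage failure aborts with the stage name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, genio, hapblock, herit, pedigree as ped_mod, relatedness, simdata

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Either ``simulation`` (a :class:`~carriergwas.simdata.SimConfig`) or
    ``input_dir`` (a directory produced by :func:`simdata.write_dataset`)
    must be set. Thresholds default to the study's analysis settings.
    """

    simulation: simdata.SimConfig | None = None
    input_dir: str | None = None
    outdir: str = "results/pipeline"
    seed: int = 0
    n_genotyped: int = 200
    mind: float = 0.2
    geno: float = 0.25
    maf: float = 0.02
    pihat_cutoff: float = 0.25
    q_cutoff: float = 0.1
    hap_p_cutoff: float = 1e-4
    k_neighbours: int = 10
    top_n_stepwise: int = 100
    prevalences: tuple[float, ...] = (0.025, 0.05, 0.1)
    designs: tuple[str, ...] = ("quantitative", "binary")
    max_block_chromosomes: int = 2

    def __post_init__(self) -> None:
        if not self.designs:
            raise ValueError("at least one design is required")
        for d in self.designs:
            if d not in ("quantitative", "binary"):
                raise ValueError(f"unknown design {d!r}")
        for name in ("mind", "geno", "maf", "pihat_cutoff", "q_cutoff"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if self.simulation is None and self.input_dir is None:
            raise ValueError("either a simulation block or an input_dir is required")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline config; a ``simulation:`` mapping becomes a SimConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulation", None)
    cfg = PipelineConfig(
        simulation=simdata.SimConfig(**sim) if sim is not None else None, **raw
    )
    return cfg


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _select_genotyped(
    ped: ped_mod.Pedigree, n: int, case_ids: list[str], seed: int
) -> list[str]:
    """Genotyped cohort: all cases plus a stratified draw across generations.

    Mirrors opportunistic sampling from a breed-wide database: affected dogs
    are genotyped preferentially, the rest of the cohort is spread over the
    whole pedigree rather than concentrated in the youngest generation.
    """
    rng = np.random.default_rng(seed)
    chosen = [c for c in case_ids if c in ped]
    rest = [i for i in ped.ids if i not in set(chosen)]
    if len(chosen) < n:
        extra = rng.choice(rest, size=min(n - len(chosen), len(rest)), replace=False)
        chosen += [str(x) for x in extra]
    return sorted(chosen[:n])


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full analysis and write the report bundle under ``outdir``.

    Returns a dict of key in-memory results (status assignment, per-design
    MLMA frames, REML tables, network components) for programmatic use.
    """
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "thresholds": {
        "mind": config.mind, "geno": config.geno, "maf": config.maf,
        "pihat_cutoff": config.pihat_cutoff, "q_cutoff": config.q_cutoff,
        "hap_p_cutoff": config.hap_p_cutoff, "k": config.k_neighbours,
        "top_n_stepwise": config.top_n_stepwise,
    }}
    results: dict = {}

    # --- stage: data -------------------------------------------------------
    try:
        if config.simulation is not None:
            sim_cfg = config.simulation
            ds = simdata.simulate_dataset(sim_cfg)
            ped = ds.pedigree
            clinical, truth = ds.clinical, ds.truth
            genotyped = _select_genotyped(
                ped, config.n_genotyped, ds.case_ids, sim_cfg.seed + 2
            )
            gm_raw = ds.genotypes.subset(samples=genotyped)
            gm_raw = genio.recode_minor(gm_raw)
            simdata.write_dataset(
                gm_raw, ped, clinical[clinical["id"].isin(genotyped)],
                truth[truth["id"].isin(genotyped)], out / "data",
                missing_rate=sim_cfg.missing_rate,
                rng=np.random.default_rng(sim_cfg.seed + 1),
            )
            gm = genio.read_ped_map(out / "data" / "genotypes.ped", out / "data" / "genotypes.map")
        else:
            indir = Path(config.input_dir)
            gm = genio.read_ped_map(indir / "genotypes.ped", indir / "genotypes.map")
            ped = ped_mod.build_pedigree(pd.read_csv(indir / "pedigree.csv"))
            clinical = pd.read_csv(indir / "clinical.csv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("data", str(exc)) from exc

    # --- stage: qc ---------------------------------------------------------
    try:
        gm, qc_report = genio.qc_filter(gm, mind=config.mind, geno=config.geno, maf=config.maf)
        _write(qc_report.removed_samples, out / "qc_removed_samples.tsv")
        _write(qc_report.removed_variants, out / "qc_removed_variants.tsv")
        log["qc"] = {
            "samples_removed": len(qc_report.removed_samples),
            "variants_removed": len(qc_report.removed_variants),
            "samples_retained": gm.n_samples,
            "variants_retained": gm.n_variants,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("qc", str(exc)) from exc

    # --- stage: classify ---------------------------------------------------
    try:
        ibd = relatedness.pihat(gm)
        _write(ibd, out / "pihat.tsv")
        case_ids = [str(i) for i in clinical.loc[clinical["affected"] == 1, "id"]]
        diagnoses = {
            str(r["id"]): ("T" if r.get("immunophenotype") == "T" else "confirmed")
            for _, r in clinical.iterrows()
        }
        status = ped_mod.classify_cohort(
            ped, case_ids, gm.samples, diagnoses=diagnoses,
            pihat=ibd, pihat_cutoff=config.pihat_cutoff,
        )
        _write(status.to_frame(), out / "status.tsv")
        log["status_counts"] = status.counts()
        results["status"] = status
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("classify", str(exc)) from exc

    sig_sets: dict[str, set[str]] = {}
    for design in config.designs:
        dd = out / design
        dd.mkdir(exist_ok=True)
        # --- stage: gwas ---------------------------------------------------
        try:
            pheno = status.y if design == "quantitative" else status.binary
            samples = [s for s in gm.samples if s in pheno]
            sub = gm.subset(samples=samples)
            grm = assoc.compute_grm(sub)
            scan = assoc.mlma_scan(sub, grm, pheno)
            scan["q_genomewide"] = assoc.qvalues(scan["p"])
            scan["q_chr"] = assoc.qvalues(scan["p"], strata=scan["Chr"])
            _write(scan.drop(columns=["flagged"]), dd / "mlma.tsv")
            sig = scan[scan["q_chr"] < config.q_cutoff]
            sig_sets[design] = set(sig["SNP"])
            groups = ("case", "carrier", "control") if design == "quantitative" else ("case", "control")
            if len(sig):
                table = genio.genotype_group_table(gm, status.status, list(sig["SNP"]), groups=groups)
                table = sig.merge(table, left_on="SNP", right_on="id")
                _write(table, dd / "significant_snps.tsv")
            log[f"{design}_n_significant_chrwise"] = int(len(sig))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"gwas:{design}", str(exc)) from exc

        # --- stage: stepwise ----------------------------------------------
        try:
            cc = {s: v + 1 for s, v in status.binary.items()}  # 2 case / 1 control
            n_cc = len(cc)
            n_cand = min(config.top_n_stepwise, max(n_cc - 2, 1))
            top = scan.nsmallest(n_cand, "p")["SNP"].tolist()
            sw = assoc.backward_stepwise(gm, cc, top)
            pd.DataFrame(
                {
                    "retained_snp": sw.retained,
                }
            ).to_csv(dd / "stepwise_retained.tsv", sep="\t", index=False)
            log[f"{design}_stepwise"] = {
                "n_retained": len(sw.retained), "rse": sw.rse,
                "df_resid": sw.df_resid, "adj_r2": sw.adj_r2,
                "model_pvalue": sw.model_pvalue,
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stepwise:{design}", str(exc)) from exc

        # --- stage: haplotypes ----------------------------------------------
        try:
            sig_chroms = list(dict.fromkeys(sig["Chr"]))[: config.max_block_chromosomes]
            model = "linear" if design == "quantitative" else "logistic"
            hap_pheno = pheno
            block_rows, assoc_rows, homo_rows = [], [], []
            for chrom in sig_chroms:
                blocks = hapblock.find_blocks(sub, chrom)
                for blk in blocks:
                    block_rows.append(
                        {"chrom": blk.chrom, "bp_start": blk.start_bp,
                         "bp_end": blk.end_bp, "n_snps": blk.n_snps,
                         "snps": ",".join(blk.snp_ids)}
                    )
                    tab = hapblock.em_hap_freqs(sub, blk)
                    ha = hapblock.hap_association(sub, blk, hap_pheno, model=model, table=tab)
                    if len(ha):
                        assoc_rows.append(ha)
                        top_hits = ha[ha["p"] < config.hap_p_cutoff]
                        if len(top_hits):
                            homo = hapblock.hap_homozygosity_by_group(
                                tab, status.status, groups=groups
                            )
                            homo = homo[homo["haplotype"].isin(top_hits["haplotype"])]
                            homo_rows.append(homo)
            _write(pd.DataFrame(block_rows), dd / "blocks.tsv")
            if assoc_rows:
                _write(pd.concat(assoc_rows, ignore_index=True), dd / "hap_association.tsv")
            if homo_rows:
                _write(pd.concat(homo_rows, ignore_index=True), dd / "hap_homozygosity.tsv")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"haplotypes:{design}", str(exc)) from exc

        # --- stage: reml ----------------------------------------------------
        try:
            n_cases = sum(1 for v in status.binary.values() if v == 1)
            n_total = len(pheno)
            regions: list[tuple[str, str | None]] = [("all_autosomes", None)]
            for chrom in sig_chroms:
                regions.append((f"chr{chrom}", str(chrom)))
                in_chr = sig[sig["Chr"] == chrom]
                lo, hi = int(in_chr["bp"].min()), int(in_chr["bp"].max())
                regions.append((f"chr{chrom}:{lo}-{hi}", f"{chrom}:{lo}-{hi}"))
            hsq_frames = []
            for name, region in regions:
                g = herit.grm_subset(sub, region)
                try:
                    vc = herit.ai_reml(g, pheno)
                except herit.RemlError as err:
                    log.setdefault("reml_failures", []).append(f"{design}/{name}: {err}")
                    continue
                liab = [
                    herit.liability_transform(vc.h2_obs, vc.se, K, n_cases, n_total)
                    for K in config.prevalences
                ]
                frame = vc.to_hsq_frame(liab)
                frame.insert(0, "Region", name)
                hsq_frames.append(frame)
            if hsq_frames:
                _write(pd.concat(hsq_frames, ignore_index=True), dd / "reml.tsv")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"reml:{design}", str(exc)) from exc
        results[design] = {"scan": scan, "significant": sig}

    # --- stage: networks ----------------------------------------------------
    try:
        dist = relatedness.ibs_distance_matrix(gm)
        g = relatedness.mknn_graph(dist, k=config.k_neighbours)
        edges = pd.DataFrame(
            [{"ID1": a, "ID2": b, "distance": d["distance"]} for a, b, d in g.edges(data=True)]
        )
        _write(edges, out / "network_edges.tsv")
        import networkx as nx

        comps = [sorted(c) for c in nx.connected_components(g)]
        comps.sort(key=lambda c: (-len(c), c[0]))
        log["network_components"] = [len(c) for c in comps]
        results["network_components"] = comps
        # Pedigree-kinship network for the genotyped dogs.
        A = ped_mod.additive_relationship(ped, gm.samples)
        kin_dist = 1.0 - (A / 2.0)
        np.fill_diagonal(kin_dist.values, 0.0)
        gk = relatedness.mknn_graph(kin_dist, k=config.k_neighbours)
        _write(
            pd.DataFrame(
                [{"ID1": a, "ID2": b, "distance": d["distance"]} for a, b, d in gk.edges(data=True)]
            ),
            out / "network_edges_pedigree.tsv",
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("networks", str(exc)) from exc

    if len(sig_sets) == 2:
        q, b = (sig_sets.get("quantitative", set()), sig_sets.get("binary", set()))
        log["design_overlap"] = {
            "quantitative_only": len(q - b), "binary_only": len(b - q),
            "shared": len(q & b),
        }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    results["log"] = log
    return results
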