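"""End-to-end orchestration: inputs (or a simulated cohort) to a report bundle.

Stages follow the analysis order of the underlying study design: spectra
and mutation load, VAF clonality, mutational signatures, pathway burden
and diversity, then chromosomal copy-number alterations. Every stage is
a pure function of (inputs, config, seed); re-running with the same seed
reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arms, catalog as cat, clonality, pathways as pw, refsigs, sca, signatures as sig, simulate, spectrum as spec, stats

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "spectrum", "clonality", "signatures", "pathways", "sca", "report")


@dataclass
class RunConfig:
    outdir: str = "bemut_out"
    seed: int = 0
    simulate: dict | None = None  # CohortTruth overrides; {} for defaults
    inputs: dict | None = None  # paths: catalog, covariates, pathways, segments, signatures, arm_table
    vaf_thresholds: tuple = clonality.DEFAULT_THRESHOLDS
    vaf_headline: float = 0.3
    fdr_pathway: float = 0.2
    fdr_gene: float = 0.1
    min_snv: int = 50
    weight_floor: float = 0.06
    k_range: tuple = (1, 2, 3)
    n_resamples: int = 15
    n_perm: int = 2000
    focal_amp_margin: int = 4
    focal_max_mb: float = 3.0

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must have exactly one of 'simulate' or 'inputs'")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        d.update(overrides)
        known = cls.__dataclass_fields__
        return cls(**{k: v for k, v in d.items() if k in known})


def _log(fh, stage: str, seed: int, **extra) -> None:
    fh.write(json.dumps({"stage": stage, "seed": seed, "time": time.time(), **extra}) + "\n")
    fh.flush()


def _load_inputs(config: RunConfig):
    paths = config.inputs
    meta = cat.read_meta(paths["covariates"])
    catalog = cat.read_catalog(paths["catalog"], meta)
    pathdb = cat.read_gmt(paths["pathways"])
    segments = (
        pd.read_csv(paths["segments"], sep="\t", dtype={"chrom": str})
        if paths.get("segments")
        else pd.DataFrame(columns=sca.SEG_COLUMNS)
    )
    reference = refsigs.load_reference_signatures(paths.get("signatures"))
    arm_table = (
        arms.read_arm_table(paths["arm_table"]) if paths.get("arm_table") else arms.load_arm_table()
    )
    return catalog, meta, segments, pathdb, reference, arm_table, None


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Run the requested stages (default: all) and write the report bundle.

    Returns the machine-readable summary also written to summary.json.
    """
    stages = set(stages or STAGES)
    unknown = stages - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    log = open(out / "run_log.jsonl", "w")

    reference = refsigs.load_reference_signatures()
    if config.simulate is not None:
        truth = simulate.default_truth(**{**config.simulate, "seed": config.seed})
        gene_model = simulate.synthetic_gene_model()
        pathdb = simulate.synthetic_pathways(gene_model)
        catalog, meta, segments, truth_log = simulate.generate_cohort(
            truth, pathdb, reference, gene_model
        )
        arm_table = arms.load_arm_table()
        cat.write_catalog(catalog, out / "catalog.tsv")
        cat.write_meta(meta, out / "covariates.tsv")
        segments.to_csv(out / "segments_true.tsv", sep="\t", index=False)
        cat.write_gmt(pathdb, out / "pathways.gmt")
        simulate.write_truth(truth_log, out / "truth.json")
        _log(log, "simulate", config.seed, n_mutations=len(catalog))
    else:
        catalog, meta, segments, pathdb, reference, arm_table, truth_log = _load_inputs(config)
        _log(log, "load", config.seed, n_mutations=len(catalog))

    users = meta.loc[meta["nsaid_user"], "patient_id"]
    nonusers = meta.loc[~meta["nsaid_user"], "patient_id"]
    sm = spec.build_spectrum(catalog, meta)

    if "spectrum" in stages:
        sm.write(out / "spectrum.tsv")
        sf = sm.to_frame()
        med_diff = sf.loc[users].median() - sf.loc[nonusers].median()
        sign = stats.sign_test(med_diff.to_numpy())
        load_all = spec.mutation_load(catalog, meta, "all").set_index("patient_id")
        kw_load = stats.kruskal_wallis(
            load_all.loc[users, "count"], load_all.loc[nonusers, "count"]
        )
        density, n_dropped = spec.arm_density_table(catalog, arm_table, meta)
        perm = stats.group_effect_on_arm_density(
            density, meta, n_perm=config.n_perm, seed=config.seed
        )
        covs = meta.set_index("patient_id")[["nsaid_user", "ever_smoker", "tp53_mutant"]]
        lm = stats.multivariable_lm(
            load_all.loc[covs.index, "count"].to_numpy(), covs
        )
        load_all.to_csv(out / "mutation_load.tsv", sep="\t")
        density.to_csv(out / "arm_density.tsv", sep="\t", index=False)
        lm.to_csv(out / "load_regression.tsv", sep="\t", index=False)
        stats.results_to_frame(
            {"sign_96_median_diff": sign, "kw_total_load": kw_load, "perm_arm_density": perm}
        ).to_csv(out / "load_tests.tsv", sep="\t", index=False)
        summary["spectrum"] = {
            "total_snvs": int(sm.counts.sum()),
            "mean_snvs_user": float(sm.counts[[sm.patients.index(p) for p in users]].sum(1).mean()),
            "mean_snvs_nonuser": float(sm.counts[[sm.patients.index(p) for p in nonusers]].sum(1).mean()),
            "median_load_per_mb_user": float(load_all.loc[users, "load_per_mb"].median()),
            "median_load_per_mb_nonuser": float(load_all.loc[nonusers, "load_per_mb"].median()),
            "sign_test": {"p": sign.p_value, **sign.detail},
            "kw_total_load_p": kw_load.p_value,
            "arm_density_perm_p": perm.p_value,
            "nsaid_lm_p": float(lm.set_index("term").loc["nsaid_user", "p"]),
            "arm_unmapped": n_dropped,
        }
        _log(log, "spectrum", config.seed, sign_p=sign.p_value)

    if "clonality" in stages:
        diploid = clonality.filter_diploid(catalog, segments)
        scans = {}
        for which in ("functional", "nonfunctional"):
            scan = clonality.vaf_threshold_scan(
                diploid, meta, config.vaf_thresholds, which=which
            )
            scan.to_csv(out / f"vaf_scan_{which}.tsv", sep="\t", index=False)
            head = scan[np.isclose(scan["threshold"], config.vaf_headline)]
            scans[which] = {
                "headline_threshold": config.vaf_headline,
                "p_raw": float(head["p_raw"].iloc[0]) if len(head) else None,
                "p_proportion": float(head["p_proportion"].iloc[0]) if len(head) else None,
                "n_significant_thresholds": int(scan["significant"].sum()),
            }
        summary["clonality"] = scans
        _log(log, "clonality", config.seed)

    if "signatures" in stages:
        model = sig.extract_signatures_nmf(
            sm, k_range=list(config.k_range), n_resamples=config.n_resamples, seed=config.seed
        )
        pd.DataFrame(model.W, index=list(spec.CHANNELS),
                     columns=[f"E{j+1}" for j in range(model.k)]).to_csv(
            out / "signatures_denovo.tsv", sep="\t"
        )
        model.exposures_frame().to_csv(out / "exposures_denovo.tsv", sep="\t")
        assigned = sig.refit_cohort(
            sm, reference, min_snv=config.min_snv, weight_floor=config.weight_floor
        )
        assigned.to_csv(out / "assigned_counts_refit.tsv", sep="\t")
        top = sig.top_signatures(assigned)
        reg = sig.signature_load_regression(
            assigned[top.index] if len(top) else assigned,
            meta,
            ["nsaid_never_smoker"],
        )
        cos = {
            f"E{j+1}": {
                s: sig.cosine_similarity(model.W[:, j], reference[s]) for s in ("S1", "S17")
            }
            for j in range(model.k)
        }
        summary["signatures"] = {
            "k_selected": model.k,
            "stability": [float(s) for s in model.stability],
            "cosine_to_reference": cos,
            "top_signatures_pct": {s: round(100 * v, 1) for s, v in top.items()},
            "never_smoker_nsaid_p": {
                s: float(t.set_index("term").loc["nsaid_never_smoker", "p"])
                for s, t in reg.items()
            },
        }
        _log(log, "signatures", config.seed, k=model.k)

    if "pathways" in stages:
        burden = pw.assign_mutations_to_pathways(catalog, pathdb, meta=meta)
        ptest = pw.pathway_burden_test(burden, meta, "functional", fdr=config.fdr_pathway)
        ptest_nf = pw.pathway_burden_test(burden, meta, "nonfunctional", fdr=config.fdr_pathway)
        ptest.to_csv(out / "pathway_burden_functional.tsv", sep="\t", index=False)
        ptest_nf.to_csv(out / "pathway_burden_nonfunctional.tsv", sep="\t", index=False)
        sig_pw = ptest.loc[ptest["significant"], "pathway"].tolist()
        table1 = ptest[ptest["significant"]][
            ["pathway", "mean_user", "sem_user", "mean_nonuser", "sem_nonuser",
             "percent_reduction", "p"]
        ]
        table1.to_csv(out / "significant_pathways_summary.tsv", sep="\t", index=False)
        gtest = pw.gene_burden_test(catalog, meta, fdr=config.fdr_gene)
        gtest.to_csv(out / "gene_burden.tsv", sep="\t", index=False)
        div_res = {}
        si_frames = []
        for label, subset in (
            ("significant", sig_pw or None),
            ("remaining", [p for p in pathdb.names if p not in sig_pw] or None),
        ):
            if subset is None:
                continue
            si = pw.diversity_table(burden, subset)
            si_frames.append(si.rename(f"SI_{label}"))
            res = pw.diversity_group_test(si, meta)
            div_res[label] = {"p": res.p_value, **res.detail}
        if si_frames:
            pd.concat(si_frames, axis=1).to_csv(out / "shannon_diversity.tsv", sep="\t")
        summary["pathways"] = {
            "n_significant": len(sig_pw),
            "significant": sig_pw,
            "mean_percent_reduction": float(
                ptest.loc[ptest["significant"], "percent_reduction"].mean()
            ) if sig_pw else None,
            "n_genes_flagged": int(gtest["significant"].sum()) if len(gtest) else 0,
            "diversity": div_res,
        }
        _log(log, "pathways", config.seed, n_significant=len(sig_pw))

    if "sca" in stages:
        load_tab = sca.arm_sca_load(segments, arm_table)
        load_tab.to_csv(out / "sca_arm_load.tsv", sep="\t", index=False)
        wgd = {
            pid: sca.genome_doubling_flag(sub, arm_table)
            for pid, sub in segments.groupby("patient_id")
        }
        wgd_series = pd.Series(
            {p: wgd.get(p, False) for p in meta["patient_id"]}, name="genome_doubled"
        )
        wgd_series.to_csv(out / "genome_doubling.tsv", sep="\t")
        amp_test = sca.focal_amp_prevalence_test(segments, meta)
        mb = load_tab.groupby("patient_id")["mb"].sum()
        mb_u = mb.reindex(users, fill_value=0.0)
        mb_n = mb.reindex(nonusers, fill_value=0.0)
        summary["sca"] = {
            "mean_sca_mb_user": float(mb_u.mean()),
            "mean_sca_mb_nonuser": float(mb_n.mean()),
            "median_sca_mb_user": float(mb_u.median()),
            "median_sca_mb_nonuser": float(mb_n.median()),
            "focal_amp_test": {"p": amp_test.p_value, **amp_test.detail},
            "wgd_user": int(sum(bool(wgd_series[p]) for p in users)),
            "wgd_nonuser": int(sum(bool(wgd_series[p]) for p in nonusers)),
        }
        _log(log, "sca", config.seed, focal_p=amp_test.p_value)

    if "report" in stages:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        _log(log, "report", config.seed)
    log.close()
    return summary
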