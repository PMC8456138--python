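"""End-to-end analysis orchestration.

From one config: normalization -> differential expression (combined and
per-lineage individual sexual-vs-asexual contrasts) -> multi-set overlap
tests -> sex-bias classification in the reference species -> relative-
expression class shifts (female side for all lineages, male side for the
sexual controls) -> conserved-subset re-analysis -> PCA-LDA maleness ->
expression divergence by class -> optional pooled Fst -> masculinization
verdict. Runs on simulated or user data; deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detest, exprnorm, maleness, multiset, poolfst, sexbias, simdata

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Analysis parameters with their defaults.

    reference_sexbias: lineage used to define FBG/MBG/UBG classes and as
    the relative-expression denominator (the outgroup).
    reference_de: sexual lineage the asexuals are contrasted against.
    """

    counts_path: str | None = None
    meta_path: str | None = None
    lengths_path: str | None = None
    allele_table_path: str | None = None
    simulate: dict | None = None  # simdata config overrides; used when no paths
    reference_sexbias: str = "sinica"
    reference_de: str = "kazakhstan"
    alpha: float = 0.05
    min_transcript_len: int = 500
    pseudocount: float = 1.0
    pc_rule: float = 0.9
    diagnosis_tissue: str = "gonad"
    min_maf: float = 0.1
    min_qual: float = 30.0
    depth_range: tuple[int, int] = (10, 100)
    run_fst: bool = False
    seed: int = 0
    outdir: str | None = None


def _samples(meta: pd.DataFrame, **criteria) -> list[str]:
    mask = pd.Series(True, index=meta.index)
    for key, val in criteria.items():
        mask &= meta[key] == val
    return list(meta.index[mask])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report bundle as a dict."""
    report: dict = {"config": {k: v for k, v in vars(config).items()}, "stages": {}}
    counts, meta, lengths, truth = _load_inputs(config)
    exprnorm.validate_counts(counts)
    exprnorm.validate_meta(counts, meta)

    keep = exprnorm.filter_transcripts(lengths, config.min_transcript_len)
    keep = keep.intersection(counts.index)
    if not len(keep):
        raise RuntimeError("reference transcript set is empty after length filter")
    counts = counts.loc[keep]
    lengths = lengths.loc[keep]
    logger.info("reference set: %d transcripts (> %d bp)", len(keep), config.min_transcript_len)

    rpkm = exprnorm.compute_rpkm(counts, lengths)
    norm = exprnorm.quantile_normalize(rpkm, exprnorm.tissue_groups(meta.loc[counts.columns]))
    report["stages"]["normalization"] = {
        "n_genes": int(len(keep)),
        "n_samples": int(counts.shape[1]),
    }

    tissues = sorted(meta["tissue"].unique())
    asex_lineages = sorted(meta.loc[meta["mode"] == "asexual", "lineage"].unique())
    sexual_lineages = sorted(meta.loc[meta["mode"] == "sexual", "lineage"].unique())
    ref_sb, ref_de = config.reference_sexbias, config.reference_de

    de_block = _run_de_and_overlap(counts, meta, config, tissues, asex_lineages)
    report["stages"]["differential_expression"] = de_block["summary"]

    bias_tables: dict[str, dict[str, pd.Series]] = {}
    for tissue in tissues:
        bias_tables[tissue] = {}
        for lin in sexual_lineages:
            males = _samples(meta, lineage=lin, tissue=tissue, sex="M")
            females = _samples(meta, lineage=lin, tissue=tissue, sex="F")
            if len(males) < 2 or len(females) < 2:
                continue
            de = detest.nb_de_test(counts, males, females)
            bias_tables[tissue][lin] = sexbias.classify_sex_bias(de, config.alpha)

    shifts = _run_shifts(norm, meta, config, bias_tables, asex_lineages, sexual_lineages)
    report["stages"]["class_shifts"] = {
        tissue: {
            side: {lin: r.as_dict() for lin, r in by_lin.items()}
            for side, by_lin in sides.items()
        }
        for tissue, sides in shifts.items()
    }

    lda_cmp, lda_model = _run_lda(norm, meta, config)
    if lda_cmp is not None:
        report["stages"]["maleness"] = {
            "p_vs_female": sexbias._jsonable(lda_cmp.p_vs_female),
            "p_vs_male": sexbias._jsonable(lda_cmp.p_vs_male),
            "overlap_female_range": sexbias._jsonable(lda_cmp.overlap_female_range),
            "scores": {k: float(v) for k, v in lda_cmp.scores.items()},
        }

    divergence = _run_divergence(norm, meta, config, bias_tables, asex_lineages, sexual_lineages)
    report["stages"]["divergence"] = divergence["summary"]

    tissue = config.diagnosis_tissue
    diag = sexbias.diagnose_masculinization(
        female_shifts={
            lin: r for lin, r in shifts.get(tissue, {}).get("female_asexual", {}).items()
        },
        male_shifts={lin: r for lin, r in shifts.get(tissue, {}).get("male_control", {}).items()},
        conserved_shifts={
            lin: r for lin, r in shifts.get(tissue, {}).get("conserved_female", {}).items()
        },
        lda=lda_cmp,
        full_shifts_for_conserved={
            lin: r for lin, r in shifts.get(tissue, {}).get("female_asexual", {}).items()
        },
        alpha=config.alpha,
    )
    report["verdict"] = diag["verdict"]
    report["stages"]["diagnosis"] = diag

    if config.run_fst or config.allele_table_path:
        report["stages"]["fst"] = _run_fst(config)

    if truth is not None:
        report["truth_available"] = True

    if config.outdir:
        _write_outputs(config, report, de_block, norm, lda_model)
    return report


def _load_inputs(config: PipelineConfig):
    if config.counts_path:
        counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(config.meta_path, sep="\t", index_col=0)
        gene_meta = pd.read_csv(config.lengths_path, sep="\t", index_col=0)
        lengths = gene_meta["length_bp"]
        return counts, meta, lengths, None
    sim_cfg = simdata.config_from_dict(dict(config.simulate or {}))
    if "seed" not in (config.simulate or {}):
        sim_cfg.seed = config.seed
    counts, meta, gene_meta, truth = simdata.simulate_dataset(sim_cfg)
    return counts, meta, gene_meta["length_bp"], truth


def _run_de_and_overlap(counts, meta, config, tissues, asex_lineages) -> dict:
    """Combined and individual sexual-vs-asexual DE plus overlap tests.

    'Shared' genes must be significant with the same direction in every
    individual contrast; up and down sets are tested separately against the
    exact multi-set null on the universe of genes tested in all contrasts.
    """
    summary: dict = {}
    tables: dict = {}
    for tissue in tissues:
        ref_f = _samples(meta, lineage=config.reference_de, tissue=tissue, sex="F")
        if len(ref_f) < 2:
            continue
        block: dict = {}
        pooled_asex = [
            s for lin in asex_lineages for s in _samples(meta, lineage=lin, tissue=tissue, sex="F")
        ]
        de_combined = detest.nb_de_test(counts, ref_f, pooled_asex)
        up_c, down_c = detest.call_de_sets(de_combined, config.alpha)
        block["combined"] = {"n_up": len(up_c), "n_down": len(down_c)}
        tables[(tissue, "combined")] = de_combined

        up_sets, down_sets, tested_sets = [], [], []
        for lin in asex_lineages:
            tgt = _samples(meta, lineage=lin, tissue=tissue, sex="F")
            de = detest.nb_de_test(counts, ref_f, tgt)
            tables[(tissue, lin)] = de
            up, down = detest.call_de_sets(de, config.alpha)
            up_sets.append(up)
            down_sets.append(down)
            tested_sets.append(set(de.index[de["tested"]]))
            block.setdefault("individual", {})[lin] = {"n_up": len(up), "n_down": len(down)}
        if len(up_sets) >= 2:
            universe = set.intersection(*tested_sets)
            shared_up = set.intersection(*up_sets)
            shared_down = set.intersection(*down_sets)
            block["shared"] = {
                "n_up": len(shared_up),
                "n_down": len(shared_down),
                "overlap_with_combined": len((shared_up | shared_down) & (up_c | down_c)),
            }
            block["overlap_test_up"] = multiset.intersection_test(
                universe, [s & universe for s in up_sets]
            ).as_dict()
            block["overlap_test_down"] = multiset.intersection_test(
                universe, [s & universe for s in down_sets]
            ).as_dict()
        summary[tissue] = block
    return {"summary": summary, "tables": tables}


def _run_shifts(norm, meta, config, bias_tables, asex_lineages, sexual_lineages) -> dict:
    out: dict = {}
    ref = config.reference_sexbias
    for tissue, by_lin in bias_tables.items():
        if ref not in by_lin:
            continue
        bias = by_lin[ref]
        ref_f = _samples(meta, lineage=ref, tissue=tissue, sex="F")
        ref_m = _samples(meta, lineage=ref, tissue=tissue, sex="M")
        block: dict = {
            "female_asexual": {},
            "female_sexual_control": {},
            "male_control": {},
            "conserved_female": {},
        }
        conserved = None
        if len(by_lin) >= 2:
            conserved = sexbias.conserved_sex_bias(list(by_lin.values()))
        for lin in asex_lineages + [l for l in sexual_lineages if l != ref]:
            tgt_f = _samples(meta, lineage=lin, tissue=tissue, sex="F")
            if not tgt_f or not ref_f:
                continue
            ratios = sexbias.relative_log_expression(norm, tgt_f, ref_f, config.pseudocount)
            shift = sexbias.class_shift_test(ratios, bias, config.alpha)
            key = "female_asexual" if lin in asex_lineages else "female_sexual_control"
            block[key][lin] = shift
            if conserved is not None and lin in asex_lineages:
                block["conserved_female"][lin] = sexbias.class_shift_test(
                    ratios, conserved, config.alpha
                )
        for lin in sexual_lineages:
            if lin == ref:
                continue
            tgt_m = _samples(meta, lineage=lin, tissue=tissue, sex="M")
            if not tgt_m or not ref_m:
                continue
            ratios = sexbias.relative_log_expression(norm, tgt_m, ref_m, config.pseudocount)
            block["male_control"][lin] = sexbias.class_shift_test(ratios, bias, config.alpha)
        out[tissue] = block
    return out


def _run_lda(norm, meta, config):
    tissue = config.diagnosis_tissue
    train = meta[(meta["mode"] == "sexual") & (meta["tissue"] == tissue)]
    asex = meta[(meta["mode"] == "asexual") & (meta["tissue"] == tissue)]
    if (train["sex"] == "M").sum() < 2 or (train["sex"] == "F").sum() < 2 or not len(asex):
        logger.warning("too few samples to train the maleness model for tissue %r", tissue)
        return None, None
    model = maleness.fit_maleness_model(
        norm[list(train.index)],
        train["sex"],
        pc_rule=config.pc_rule,
        loo_groups=train["lineage"] + ":" + train["sex"],
    )
    asex_scores = maleness.maleness_scores(model, norm[list(asex.index)])
    # compare against held-out (leave-lineage-out) training scores: the
    # asexuals are out-of-sample, so the reference sexes must be too. The
    # overlap range is the envelope of in-sample and held-out female
    # projections, which bracket where a female-like sample can score.
    train_scores = model.ld1_train_loo if model.ld1_train_loo is not None else model.ld1_train
    f_idx = train.index[train["sex"] == "F"]
    f_all = pd.concat([model.ld1_train[f_idx], train_scores[f_idx]]).dropna()
    cmp = maleness.score_comparison(
        asex_scores,
        train_scores[f_idx],
        train_scores[train.index[train["sex"] == "M"]],
        female_range=(float(f_all.min()), float(f_all.max())),
    )
    return cmp, model


def log_expression_means(norm: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged log2(x+1) expression per (lineage, sex, tissue);
    the input to Euclidean expression divergence."""
    logged = np.log2(norm + 1.0)
    return exprnorm.average_replicates(logged, meta)


def _run_divergence(norm, meta, config, bias_tables, asex_lineages, sexual_lineages) -> dict:
    ref = config.reference_sexbias
    tissue_for_bias = config.diagnosis_tissue
    bias = bias_tables.get(tissue_for_bias, {}).get(ref)
    if bias is None:
        return {"summary": {}}
    means = log_expression_means(norm, meta)
    tissues = sorted(meta["tissue"].unique())
    summary: dict = {}
    tables: dict = {}
    for lin in asex_lineages + [l for l in sexual_lineages if l != ref]:
        female_slots = [
            (t, "F") for t in tissues if (lin, "F", t) in means.columns and (ref, "F", t) in means.columns
        ]
        slots = list(female_slots)
        if lin in sexual_lineages:
            slots += [
                (t, "M")
                for t in tissues
                if (lin, "M", t) in means.columns and (ref, "M", t) in means.columns
            ]
        if not slots:
            continue
        div = sexbias.expression_divergence(means, ref, lin, slots)
        tables[lin] = div
        summary[lin] = {
            "slots": [f"{t}:{s}" for t, s in slots],
            **sexbias.divergence_class_test(div, bias),
        }
    return {"summary": summary, "tables": tables}


def _run_fst(config: PipelineConfig) -> dict:
    if config.allele_table_path:
        path = config.allele_table_path
        if str(path).endswith(".vcf"):
            table = poolfst.read_vcf(path)
        else:
            table = poolfst.read_allele_table_tsv(path)
    else:
        sim_cfg = simdata.config_from_dict(dict(config.simulate or {}))
        if "seed" not in (config.simulate or {}):
            sim_cfg.seed = config.seed
        table, _ = simdata.simulate_allele_counts(sim_cfg)
    mat = poolfst.pairwise_fst(
        table,
        min_maf=config.min_maf,
        min_qual=config.min_qual,
        depth_range=tuple(config.depth_range),
    )
    return {
        "mean_fst": {f"{a}|{b}": sexbias._jsonable(mat.mean_fst.loc[a, b])
                     for a in mat.lineages for b in mat.lineages if a < b},
        "n_sites": {f"{a}|{b}": int(mat.n_sites.loc[a, b])
                    for a in mat.lineages for b in mat.lineages if a < b},
    }


def _write_outputs(config, report, de_block, norm, lda_model) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for (tissue, name), table in de_block["tables"].items():
        table.to_csv(out / f"de_{tissue}_{name}.tsv", sep="\t")
    norm.to_csv(out / "normalized_expression.tsv", sep="\t")
    if lda_model is not None:
        lda_model.to_json(out / "maleness_model.json")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default)
    with open(out / "run_log.txt", "w") as fh:
        fh.write("asexpress pipeline run\n")
        for key, val in report["config"].items():
            fh.write(f"{key} = {val}\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (set, tuple)):
        return sorted(obj) if isinstance(obj, set) else list(obj)
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_scenario(
    masculinization_m: float, turnover_tau: float, seed: int, **sim_overrides
) -> dict:
    """Simulate a dataset under (m, tau) and run the full diagnosis."""
    sim = {
        "masculinization_m": masculinization_m,
        "turnover_tau": turnover_tau,
        "seed": seed,
        **sim_overrides,
    }
    config = PipelineConfig(simulate=sim, seed=seed)
    return run_pipeline(config)
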