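"""End-to-end workflow: simulate -> annotate -> preprocess -> test -> classify -> validate.

:func:`run_pipeline` binds the library stages into the study's training-cohort
workflow on a synthetic cohort (or user-supplied count/metadata tables),
writes every intermediate table with a seed-stamped header, and collects the
differential tables, classifier confusion statistics and PCR validation
statistics into one machine-readable JSON summary. Reruns with the same
configuration and seed produce byte-identical summaries.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import diffabund, io, preprocess, signature, synth, valstats

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("circmir")

MARKER_GENES = ["hsa-miR-375", "hsa-miR-122"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "circmir-run"
    seed: int = 0
    # synthetic-cohort conditions (used when no counts_path is given)
    n_samples: int = 42
    dispersion: float = 0.2
    mean_library_size: int = 500_000
    n_reads: int = 20_000
    pcr_noise_sd: float = 0.5
    # filter thresholds
    min_samples: int = 2
    min_count: int = 50
    min_fraction: float = 0.10
    fdr_threshold: float = 0.1
    # optional external inputs
    counts_path: str | None = None
    metadata_path: str | None = None
    # stage toggles
    run_annotation: bool = True
    run_classification: bool = True
    run_validation: bool = True
    adjust_regimen: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _differential_summary(table: pd.DataFrame, fdr_threshold: float) -> dict:
    hits = table[table["fdr"] < fdr_threshold]
    return {
        "n_genes": int(table.shape[0]),
        "n_significant": int(hits.shape[0]),
        "top": [
            {
                "gene": r.gene,
                "mean_g1": round(float(r.mean_g1), 1),
                "mean_g2": round(float(r.mean_g2), 1),
                "log2_fold": round(float(r.log2_fold), 2),
                "p_value": float(r.p_value),
                "fdr": float(r.fdr),
            }
            for r in table.head(10).itertuples()
        ],
    }


def _classify_block(features: pd.DataFrame, labels: pd.Series) -> dict:
    out = {}
    for name, cols in [
        ("miR-375", [MARKER_GENES[0]]),
        ("miR-122", [MARKER_GENES[1]]),
        ("two-gene", MARKER_GENES),
    ]:
        preds = signature.loocv_classify(features[cols], labels)
        obs = np.where(labels.to_numpy(), valstats.POSITIVE_LABEL, valstats.NEGATIVE_LABEL)
        table = valstats.confusion_from_predictions(preds["predicted"], obs)
        sens, spec = valstats.confusion_metrics(table)
        orr = valstats.odds_ratio(table)
        out[name] = {
            "tp": table.tp, "fn": table.fn, "fp": table.fp, "tn": table.tn,
            "sensitivity_pct": valstats.round_half_up_percent(sens),
            "specificity_pct": valstats.round_half_up_percent(spec),
            "odds_ratio": None if not orr.defined else round(orr.or_value, 2),
        }
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow and return the machine-readable summary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(cfg)
    summary: dict = {"seed": cfg.seed, "config": cfg_dict}
    log.info("pipeline start (seed=%d, outdir=%s)", cfg.seed, outdir)

    # ------------------------------------------------------------- inputs
    ref = synth.make_reference(seed=cfg.seed)
    if cfg.counts_path:
        if not cfg.metadata_path:
            raise ValueError("counts_path requires metadata_path")
        counts = io.read_counts_tsv(cfg.counts_path)
        metadata = io.read_metadata_tsv(cfg.metadata_path)
    else:
        sim_cfg = synth.SimulationConfig(
            n_samples=cfg.n_samples,
            dispersion=cfg.dispersion,
            mean_library_size=cfg.mean_library_size,
            seed=cfg.seed,
        )
        counts, metadata = synth.simulate_cohort(sim_cfg, ref)
        io.write_reference_fasta(ref, outdir / "reference.fasta")
        io.write_counts_tsv(counts, outdir / "counts.tsv", cfg.seed, cfg_dict)
        io.write_metadata_tsv(metadata, outdir / "metadata.tsv", cfg.seed, cfg_dict)

    if cfg.run_classification and "relapse" not in metadata.columns:
        raise ValueError("classification enabled but metadata has no relapse labels")
    io.validate_sample_consistency(counts, metadata)

    # ----------------------------------------------------------- annotate
    if cfg.run_annotation:
        reads = synth.simulate_reads(ref, n_reads=cfg.n_reads, seed=cfg.seed)
        assignments = ann.annotate_sample(reads, ref)
        _, comp = ann.count_sample(assignments)
        comp_df = pd.DataFrame(
            sorted(comp.fractions.items()), columns=["class", "fraction"]
        )
        comp_df.to_csv(outdir / "composition.tsv", sep="\t", index=False)
        summary["composition"] = {
            "n_reads": comp.n_total,
            "n_assigned": comp.n_assigned,
            "fractions": {k: round(v, 4) for k, v in sorted(comp.fractions.items())},
        }
        log.info("annotated %d reads (%d assigned)", comp.n_total, comp.n_assigned)

    # --------------------------------------------------------- preprocess
    detected = preprocess.detectability_filter(counts, cfg.min_samples)
    analysis_set = preprocess.abundance_filter(detected, cfg.min_count, cfg.min_fraction)
    norm = preprocess.quantile_normalize(analysis_set)
    with open(outdir / "normalized.tsv", "w") as fh:
        for line in io._header_lines(cfg.seed, cfg_dict):
            fh.write(line + "\n")
        norm.to_csv(fh, sep="\t", index_label="gene", float_format="%.6g")
    ranking = preprocess.rank_by_abundance(norm)
    ranking.to_csv(outdir / "abundance_ranking.tsv", sep="\t", index_label="gene")
    dendro = preprocess.cluster_samples(norm)
    io.write_newick(dendro.to_newick(), outdir / "dendrogram.nwk")
    summary["preprocess"] = {
        "n_detected": int(detected.shape[0]),
        "n_analysis_set": int(analysis_set.shape[0]),
        "top_abundant": list(ranking.head(5).index),
    }

    # --------------------------------------------------------- differential
    adjust = "regimen" if cfg.adjust_regimen else None
    relapse_table = diffabund.differential_table(
        analysis_set, metadata, contrast="relapse", adjust=adjust
    )
    relapse_table.to_csv(outdir / "differential_relapse.tsv", sep="\t", index=False)
    summary["differential_relapse"] = _differential_summary(relapse_table, cfg.fdr_threshold)

    her2_pos = metadata.index[metadata["her2"] == "+"]
    her2_counts = analysis_set[[s for s in analysis_set.columns if s in set(her2_pos)]]
    pcr_levels = metadata.loc[her2_counts.columns, "pcr_status"]
    if pcr_levels.nunique() == 2 and pcr_levels.value_counts().min() >= 2:
        pcr_table = diffabund.differential_table(
            her2_counts, metadata, contrast="pcr_status"
        )
        pcr_table.to_csv(outdir / "differential_pcr.tsv", sep="\t", index=False)
        summary["differential_pcr_response"] = _differential_summary(
            pcr_table, cfg.fdr_threshold
        )

    # ------------------------------------------------------------ classify
    # marker levels come from the detected (not abundance-thresholded) set so
    # the classifier does not depend on the >min_count analysis filter
    norm_detected = preprocess.quantile_normalize(detected)
    features = norm_detected.loc[
        [g for g in MARKER_GENES if g in norm_detected.index]].T
    if cfg.run_classification:
        if features.shape[1] < 2:
            raise ValueError("marker genes missing from the analysis set")
        labels = metadata.loc[features.index, "relapse"].astype(bool)
        summary["classification"] = _classify_block(features, labels)
        log.info("classification done")

    # ------------------------------------------------------------ validate
    if cfg.run_validation:
        genes = [g for g in MARKER_GENES if g in norm_detected.index]
        genes = [g for g in dict.fromkeys(genes + [synth.PCR_REFERENCE_GENE])
                 if g in norm_detected.index]
        if synth.PCR_REFERENCE_GENE in genes:
            pcr = synth.simulate_pcr(norm_detected, genes,
                                     noise_sd=cfg.pcr_noise_sd, seed=cfg.seed)
            io.write_pcr_tsv(pcr, outdir / "pcr.tsv", cfg.seed, cfg_dict)
            levels = pcr.relative_levels()
            relapse_mask = metadata.loc[levels.index, "relapse"].astype(bool).to_numpy()
            block = {}
            for gene in genes:
                if gene == synth.PCR_REFERENCE_GENE:
                    continue
                log2_levels = np.log2(levels[gene].to_numpy())
                t, p, means, sems = valstats.group_t_test(
                    log2_levels[relapse_mask], log2_levels[~relapse_mask]
                )
                r, rp = valstats.seq_pcr_correlation(
                    norm_detected.loc[gene].to_numpy(), levels[gene].to_numpy()
                )
                block[gene] = {
                    "t": round(t, 3), "p": float(p),
                    "mean_relapsed": round(means[0], 3),
                    "mean_non_relapsed": round(means[1], 3),
                    "seq_pcr_r": round(r, 3), "seq_pcr_p": float(rp),
                }
            summary["pcr_validation"] = block

    io.write_summary_json(summary, outdir / "summary.json")
    log.info("pipeline complete")
    return summary
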