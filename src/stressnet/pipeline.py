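"""End-to-end orchestration: expression -> discrete calls -> [DE,
enrichment, overlap] -> multi-run boosting -> TF significance -> consensus
network, with every artifact written alongside a config snapshot.

Outputs are deterministic functions of (config, inputs): JSON is written
with sorted keys and no timestamps, so reruns with the same seed are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import expression as xp
from . import overlap as ov
from .boosting import PromoterSet, RegulatorPanel, build_examples, extract_kmer_features
from .enrichment import AnnotationMap, enrich_terms
from .expression import DiscreteExpressionMatrix, IntensityMatrix
from .io import (
    PipelineConfig,
    write_de_table,
    write_discrete_tsv,
    write_gene_list,
    write_venn,
)
from .significance import ConsensusReport, export_network, run_protocol

logger = logging.getLogger(__name__)

__all__ = ["PipelineInputs", "run_pipeline"]


@dataclass
class PipelineInputs:
    """Everything the pipeline stages may consume.

    Either supply a replicate-level ``expression`` matrix (with the group
    labels naming ``control_group`` and ``treatment_groups``), or an
    already condition-level ``discrete`` matrix plus a ``panel``.  The
    learner additionally needs ``promoters`` and, when the panel is to be
    carved out of the discrete matrix, ``tf_ids``.
    """

    expression: IntensityMatrix | None = None
    control_group: str | None = None
    treatment_groups: list[str] | None = None
    discrete: DiscreteExpressionMatrix | None = None
    panel: RegulatorPanel | None = None
    promoters: PromoterSet | None = None
    tf_ids: list[str] | None = None
    annotation: AnnotationMap | None = None
    compare_sets: dict[str, set[str]] | None = None


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def _discretize_stage(
    inputs: PipelineInputs, config: PipelineConfig, outdir: Path, counts: dict
) -> tuple[DiscreteExpressionMatrix, RegulatorPanel | None]:
    if inputs.discrete is not None:
        discrete, panel = inputs.discrete, inputs.panel
    else:
        m = inputs.expression
        ref = m.samples_in_group(inputs.control_group)
        fc = xp.median_reference_fold_change(m, ref)
        calls = xp.discretize(fc, config.fc_discrete, -config.fc_discrete)
        replicate_groups: dict[str, list[str]] = {}
        for s in m.sample_ids:
            replicate_groups.setdefault(str(m.groups[s]), []).append(s)
        discrete, dropped = xp.filter_inconsistent_replicates(calls, replicate_groups)
        write_gene_list(dropped, outdir / "dropped_inconsistent_genes.txt")
        counts["genes_dropped_inconsistent"] = len(dropped)
        panel = inputs.panel
        if panel is None and inputs.tf_ids:
            present = [t for t in inputs.tf_ids if t in discrete.calls.index]
            absent = sorted(set(inputs.tf_ids) - set(present))
            if absent:
                logger.info("TFs without consistent calls, excluded from panel: %s", absent)
            panel = RegulatorPanel(discrete.calls.loc[present])
    write_discrete_tsv(discrete, outdir / "discrete_calls.tsv")
    counts["genes_discretized"] = discrete.calls.shape[0]
    return discrete, panel


def run_pipeline(
    config: PipelineConfig, inputs: PipelineInputs, outdir: str | Path
) -> Path:
    """Execute the stages the supplied inputs allow, in pipeline order.

    Raises before any work if a requested stage lacks its inputs.
    Returns the artifact directory.
    """
    if inputs.expression is None and inputs.discrete is None:
        raise ValueError("need an expression matrix or a discrete call matrix")
    if inputs.expression is not None and inputs.control_group is None:
        raise ValueError("expression input requires control_group")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    config.to_yaml(outdir / "config.yaml")

    discrete, panel = _discretize_stage(inputs, config, outdir, counts)

    de_genes: set[str] | None = None
    if inputs.expression is not None and inputs.treatment_groups:
        de = xp.build_de_table(
            inputs.expression,
            inputs.control_group,
            inputs.treatment_groups,
            fc_cut=config.fc_de,
            q_cut=config.q_de,
        )
        write_de_table(de, outdir / "de_table.tsv")
        de_genes = de.de_genes()
        counts["genes_de"] = len(de_genes)

        if inputs.annotation is not None:
            universe = set(inputs.expression.row_ids)
            result = enrich_terms(de_genes, inputs.annotation, universe=universe)
            result.to_csv(outdir / "enrichment.tsv", sep="\t")
            counts["terms_tested"] = len(result)

        if inputs.compare_sets:
            sets = {"this_study": de_genes, **inputs.compare_sets}
            names = list(sets)[:3]
            regions = ov.venn_partition({n: sets[n] for n in names})
            write_venn(regions, outdir / "venn.tsv")
            other = names[1]
            k = len(sets["this_study"] & sets[other])
            p = ov.hypergeometric_overlap(
                len(sets["this_study"]), len(sets[other]), k, config.universe_size
            )
            # the hypergeometric overlap test is an extension of the
            # comparison workflow; labelled as such in the header
            (outdir / "overlap_significance.tsv").write_text(
                "set_a\tset_b\tk_overlap\tuniverse\tp_hypergeometric_extension\n"
                f"this_study\t{other}\t{k}\t{config.universe_size}\t{p:.6g}\n"
            )

    report: ConsensusReport | None = None
    if inputs.promoters is not None and panel is not None:
        features = extract_kmer_features(inputs.promoters, config.k_list)
        targets = [g for g in discrete.calls.index if g in inputs.promoters]
        examples = build_examples(discrete.calls, targets)
        counts["training_examples"] = len(examples)
        report = run_protocol(
            examples,
            features,
            panel,
            rounds=config.rounds,
            n_runs=config.runs,
            base_seed=config.seed,
            k_top=config.k_top,
            min_runs=config.min_runs,
            final_k=config.final_k,
            edge_threshold=config.edge_threshold,
            scoring_conditions=config.scoring_conditions,
            subsample_rate=config.subsample_rate,
        )
        for run in report.runs:
            _json_dump(
                {
                    "run_id": run.run_id,
                    "seed": run.seed,
                    "tf_scores": run.tf_scores,
                    "pair_scores": {f"{t}|{g}": s for (t, g), s in run.pair_scores.items()},
                },
                outdir / f"run_{run.run_id}.json",
            )
            (outdir / f"model_{run.run_id}.json").write_text(run.model.to_json())
        _json_dump(
            {
                "consensus_tfs": report.consensus_tfs,
                "tf_mean_scores": report.tf_mean_scores,
                "support": report.support,
                "edges": [f"{t}|{g}" for t, g in report.edges],
                "parameters": report.parameters,
            },
            outdir / "consensus.json",
        )
        pd.DataFrame(
            {
                "tf": report.consensus_tfs,
                "mean_significance": [report.tf_mean_scores[t] for t in report.consensus_tfs],
                "support": [report.support[t] for t in report.consensus_tfs],
            }
        ).to_csv(outdir / "consensus.tsv", sep="\t", index=False)
        with (outdir / "edges.tsv").open("w") as fh:
            fh.write("tf\tgene\tmean_score\n")
            for t, g in report.edges:
                fh.write(f"{t}\t{g}\t{report.edge_mean_scores[(t, g)]:.6g}\n")
        counts["consensus_tfs"] = len(report.consensus_tfs)
        counts["consensus_edges"] = len(report.edges)

        if report.edges:
            direction = {}
            for gene in discrete.calls.index:
                s = int(discrete.calls.loc[gene].sum())
                direction[gene] = "up" if s > 0 else ("down" if s < 0 else "none")
            export_network(
                report.edges,
                direction,
                outdir / "network.sif",
                outdir / "network_nodes.tsv",
                outdir / "network.graphml",
            )

    _json_dump(counts, outdir / "stage_counts.json")
    return outdir
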