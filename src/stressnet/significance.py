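"""TF-ablation significance scoring and multi-run consensus calling.

A trained boosting model assigns every (gene, condition) example a margin
score F.  The importance of a candidate TF is measured by ablation: drop
every rule whose predicate references the TF (as a bare regulator state
or inside a conjunction) and record how much the mean margin over the
upregulated examples falls.  Because the margin is a sum over rules, the
drop equals the mean summed contribution of the removed rules, which is
what the vectorized implementation computes directly.

The multi-run protocol trains several independently seeded models,
takes each run's top-k TFs by significance, and keeps TFs that make the
top-k in at least ``min_runs`` runs (consensus TFs, ranked by mean
significance over the supporting runs).  TF-gene edges are called the
same way: pair scores at or above a threshold in at least ``min_runs``
runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .boosting import (
    BoostModel,
    KmerFeatures,
    RegulatorPanel,
    TrainingExample,
    boost_train,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunResult",
    "ConsensusReport",
    "geneset_prediction_score",
    "ablate_tf",
    "tf_significance",
    "top_k_tfs",
    "consensus_tfs",
    "tf_gene_scores",
    "consensus_edges",
    "export_network",
    "score_run",
    "run_protocol",
]


@dataclass
class RunResult:
    run_id: int
    seed: int
    model: BoostModel
    tf_scores: dict[str, float]
    pair_scores: dict[tuple[str, str], float]

    def top_tfs(self, k: int = 20) -> list[str]:
        return top_k_tfs(self.tf_scores, k)


@dataclass
class ConsensusReport:
    consensus_tfs: list[str]
    tf_mean_scores: dict[str, float]
    support: dict[str, int]
    edges: list[tuple[str, str]]
    edge_mean_scores: dict[tuple[str, str], float]
    runs: list[RunResult] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)


def _rule_contributions(
    model: BoostModel,
    examples: list[TrainingExample],
    features: KmerFeatures,
    panel: RegulatorPanel,
) -> np.ndarray:
    """(n_rules, n_examples) matrix of per-rule margin contributions."""
    genes = [e.gene for e in examples]
    conds = [e.condition for e in examples]
    g_idx = np.array([features.gene_index[g] for g in genes])
    cond_pos = {c: i for i, c in enumerate(panel.conditions)}
    c_idx = np.array([cond_pos[c] for c in conds])
    states = panel.states.to_numpy(int)
    tf_pos = {t: i for i, t in enumerate(panel.tfs)}
    out = np.empty((len(model.rules), len(examples)))
    for r, rule in enumerate(model.rules):
        cond = rule.condition
        if cond.kind == "motif":
            sat = features.matrix[features.motif_index[cond.motif]][g_idx]
        elif cond.kind == "regulator_state":
            sat = (states[tf_pos[cond.tf]] == cond.state)[c_idx]
        else:
            sat = (
                features.matrix[features.motif_index[cond.motif]][g_idx]
                & (states[tf_pos[cond.tf]] == cond.state)[c_idx]
            )
        out[r] = np.where(sat, rule.alpha_sat, rule.alpha_unsat)
    return out


def geneset_prediction_score(
    model: BoostModel,
    example_set: list[TrainingExample],
    features: KmerFeatures,
    panel: RegulatorPanel,
) -> float:
    """Arithmetic mean margin F over a set of (gene, condition) examples."""
    if not example_set:
        raise ValueError("empty example set")
    if not model.rules:
        return 0.0
    contrib = _rule_contributions(model, example_set, features, panel)
    return float(contrib.sum(axis=0).mean())


def ablate_tf(model: BoostModel, tf: str) -> BoostModel:
    """Copy of the model without any rule referencing ``tf``; motif-only
    rules are retained and the original model is untouched."""
    return model.without_tf(tf)


def tf_significance(
    model: BoostModel,
    tf: str,
    upregulated_examples: list[TrainingExample],
    features: KmerFeatures,
    panel: RegulatorPanel,
) -> float:
    """Drop in mean margin over the upregulated examples after ablating the
    TF (original minus ablated)."""
    full = geneset_prediction_score(model, upregulated_examples, features, panel)
    reduced = geneset_prediction_score(ablate_tf(model, tf), upregulated_examples, features, panel)
    return full - reduced


def top_k_tfs(tf_scores: dict[str, float], k: int = 20) -> list[str]:
    """The k highest-scoring TFs, descending; ties broken by TF id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(tf_scores):
        logger.info("top_k_tfs: only %d TFs available for k=%d", len(tf_scores), k)
    ranked = sorted(tf_scores, key=lambda t: (-tf_scores[t], t))
    return ranked[:k]


def consensus_tfs(
    per_run_top: list[list[str]],
    per_run_scores: list[dict[str, float]],
    min_runs: int = 4,
    final_k: int = 10,
) -> tuple[list[str], dict[str, float], dict[str, int]]:
    """TFs in the per-run top-k lists of at least ``min_runs`` runs, ranked
    by mean significance over the supporting runs, truncated to ``final_k``.

    Returns (ranked consensus list, mean score per qualifying TF, support
    count per TF seen in any run's list).
    """
    if len(per_run_top) < min_runs:
        raise ValueError("fewer runs than min_runs")
    support: dict[str, int] = {}
    for lst in per_run_top:
        for tf in set(lst):
            support[tf] = support.get(tf, 0) + 1
    means = {}
    for tf, count in support.items():
        if count >= min_runs:
            vals = [
                scores[tf]
                for lst, scores in zip(per_run_top, per_run_scores)
                if tf in lst
            ]
            means[tf] = float(np.mean(vals))
    ranked = sorted(means, key=lambda t: (-means[t], t))[:final_k]
    return ranked, means, support


def tf_gene_scores(
    model: BoostModel,
    tf: str,
    examples_by_gene: dict[str, list[TrainingExample]],
    features: KmerFeatures,
    panel: RegulatorPanel,
) -> dict[str, float]:
    """Per-gene ablation score: mean over the gene's supplied examples of
    the margin drop after removing the TF's rules.  Genes with no examples
    are omitted."""
    removed = [r for r in model.rules if r.condition.references_tf(tf)]
    genes = [g for g, exs in examples_by_gene.items() if exs]
    if not removed:
        return {g: 0.0 for g in genes}
    sub = BoostModel(removed, dict(model.config))
    flat: list[TrainingExample] = []
    owner: list[str] = []
    for g in genes:
        flat.extend(examples_by_gene[g])
        owner.extend([g] * len(examples_by_gene[g]))
    contrib = _rule_contributions(sub, flat, features, panel).sum(axis=0)
    frame = pd.DataFrame({"gene": owner, "delta": contrib})
    return frame.groupby("gene")["delta"].mean().to_dict()


def consensus_edges(
    per_run_pair_scores: list[dict[tuple[str, str], float]],
    threshold: float = 1.0,
    min_runs: int = 4,
) -> tuple[list[tuple[str, str]], dict[tuple[str, str], float]]:
    """(tf, gene) pairs scoring >= threshold (inclusive) in >= min_runs runs,
    with the mean score over qualifying runs."""
    if len(per_run_pair_scores) < min_runs:
        raise ValueError("fewer runs than min_runs")
    counts: dict[tuple[str, str], int] = {}
    sums: dict[tuple[str, str], float] = {}
    for run_scores in per_run_pair_scores:
        for pair, score in run_scores.items():
            if score >= threshold:
                counts[pair] = counts.get(pair, 0) + 1
                sums[pair] = sums.get(pair, 0.0) + score
    edges = sorted(pair for pair, c in counts.items() if c >= min_runs)
    means = {pair: sums[pair] / counts[pair] for pair in edges}
    return edges, means


def export_network(
    edges: list[tuple[str, str]],
    expression_direction: dict[str, str],
    sif_path: str | Path,
    attr_path: str | Path,
    graphml_path: str | Path | None = None,
) -> None:
    """Write the TF-gene network as SIF plus a node-attribute table.

    SIF lines read ``tf<TAB>regulates<TAB>gene``.  The attribute table has
    columns node, role (a node that is both a TF and a target is labelled
    tf), direction (up/down/none from ``expression_direction``) and degree
    (incident edge count).  Reading the SIF back reproduces the edge set.
    """
    if not edges:
        raise ValueError("no edges to export")
    sif_path, attr_path = Path(sif_path), Path(attr_path)
    with sif_path.open("w") as fh:
        for tf, gene in edges:
            fh.write(f"{tf}\tregulates\t{gene}\n")
    tfs = {tf for tf, _ in edges}
    degree: dict[str, int] = {}
    for tf, gene in edges:
        degree[tf] = degree.get(tf, 0) + 1
        degree[gene] = degree.get(gene, 0) + 1
    with attr_path.open("w") as fh:
        fh.write("node\trole\tdirection\tdegree\n")
        for node in sorted(degree):
            role = "tf" if node in tfs else "target"
            direction = expression_direction.get(node, "none")
            fh.write(f"{node}\t{role}\t{direction}\t{degree[node]}\n")
    if graphml_path is not None:
        import networkx as nx

        g = nx.DiGraph()
        for node in sorted(degree):
            g.add_node(
                node,
                role="tf" if node in tfs else "target",
                direction=expression_direction.get(node, "none"),
            )
        g.add_edges_from(edges, interaction="regulates")
        nx.write_graphml(g, graphml_path)


def read_sif(path: str | Path) -> list[tuple[str, str]]:
    """Round-trip reader for the SIF writer above."""
    edges = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        tf, _, gene = line.split("\t")
        edges.append((tf, gene))
    return edges


def score_run(
    run_id: int,
    seed: int,
    model: BoostModel,
    examples: list[TrainingExample],
    features: KmerFeatures,
    panel: RegulatorPanel,
    scoring_conditions: list[str] | None = None,
) -> RunResult:
    """Compute per-TF and per-pair ablation scores for one trained model.

    The scoring set is the upregulated (+1-label) examples, optionally
    restricted to the designated experimental condition(s).
    """
    up = [e for e in examples if e.label == 1]
    if scoring_conditions is not None:
        wanted = set(scoring_conditions)
        up = [e for e in up if e.condition in wanted]
    if not up:
        raise ValueError("no upregulated examples in the scoring condition(s)")
    contrib = _rule_contributions(model, up, features, panel)
    owner = np.array([e.gene for e in up])

    tf_scores: dict[str, float] = {}
    pair_scores: dict[tuple[str, str], float] = {}
    rules_by_tf: dict[str, list[int]] = {tf: [] for tf in panel.tfs}
    for r, rule in enumerate(model.rules):
        if rule.condition.tf is not None:
            rules_by_tf[rule.condition.tf].append(r)
    genes = pd.unique(owner)
    for tf in panel.tfs:
        idx = rules_by_tf[tf]
        if not idx:
            tf_scores[tf] = 0.0
            continue
        delta = contrib[idx].sum(axis=0)
        tf_scores[tf] = float(delta.mean())
        per_gene = pd.Series(delta).groupby(owner).mean()
        for g in genes:
            pair_scores[(tf, g)] = float(per_gene[g])
    return RunResult(run_id, seed, model, tf_scores, pair_scores)


def run_protocol(
    examples: list[TrainingExample],
    features: KmerFeatures,
    panel: RegulatorPanel,
    *,
    rounds: int = 100,
    n_runs: int = 5,
    base_seed: int = 0,
    k_top: int = 20,
    min_runs: int = 4,
    final_k: int = 10,
    edge_threshold: float = 1.0,
    scoring_conditions: list[str] | None = None,
    subsample_rate: float = 0.5,
) -> ConsensusReport:
    """The full multi-run significance protocol: train ``n_runs`` models
    with seeds base_seed..base_seed+n_runs-1, score TF and TF-gene
    ablations per run, then call consensus TFs and edges."""
    runs: list[RunResult] = []
    for i in range(n_runs):
        seed = base_seed + i
        model = boost_train(
            examples, features, panel, rounds=rounds, seed=seed, subsample_rate=subsample_rate
        )
        runs.append(
            score_run(i, seed, model, examples, features, panel, scoring_conditions)
        )
    per_run_top = [r.top_tfs(k_top) for r in runs]
    per_run_scores = [r.tf_scores for r in runs]
    ranked, means, support = consensus_tfs(per_run_top, per_run_scores, min_runs, final_k)
    edges, edge_means = consensus_edges(
        [r.pair_scores for r in runs], edge_threshold, min_runs
    )
    return ConsensusReport(
        consensus_tfs=ranked,
        tf_mean_scores=means,
        support=support,
        edges=edges,
        edge_mean_scores=edge_means,
        runs=runs,
        parameters={
            "rounds": rounds,
            "n_runs": n_runs,
            "base_seed": base_seed,
            "k_top": k_top,
            "min_runs": min_runs,
            "final_k": final_k,
            "edge_threshold": edge_threshold,
        },
    )
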