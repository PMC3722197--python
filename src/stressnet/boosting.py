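"""Confidence-rated boosting learner for regulatory-network inference.

The learner predicts the discretized expression call (up/down) of a
target gene in a condition from two feature families:

* ``motif``: presence of an exact k-mer (or its reverse complement) in
  the gene's promoter — a property of the gene only;
* ``regulator_state``: a candidate transcription factor's own discrete
  call in the condition equals a stated direction — a property of the
  condition only;
* ``conjunction``: one motif AND one regulator state, coupling promoter
  sequence to regulator activity (depth is capped at 2).

Each boosting round selects the feature predicate minimizing the
smoothed two-block normalizer

    Z = sum over blocks b in {satisfied, unsatisfied} of
        2 * sqrt((W_b^+ + eps) * (W_b^- + eps)),

assigns each block the confidence-rated weight
``alpha_b = 1/2 * ln((W_b^+ + eps) / (W_b^- + eps))`` and reweights the
examples multiplicatively.  This is the classic domain-partitioning
weak learner of confidence-rated boosting; the stochastic element across
runs is seeded subsampling of the motif-candidate pool each round.

Because every example is a unique (gene, condition) pair, example
weights can be laid out on a gene x condition grid, and the weighted
label masses of every candidate in a family are obtained with one
matrix-vector product against the motif presence matrix or the panel
state mask — which is what keeps hundreds of rounds over thousands of
candidates cheap.
"""

from __future__ import annotations

import json
import logging

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_KIND_RANK = {"regulator_state": 0, "motif": 1, "conjunction": 2}

__all__ = [
    "PromoterSet",
    "RegulatorPanel",
    "KmerFeatures",
    "TrainingExample",
    "Condition",
    "Rule",
    "BoostModel",
    "extract_kmer_features",
    "build_examples",
    "evaluate_condition",
    "best_condition",
    "boost_train",
    "predict_score",
    "reverse_complement",
]


def reverse_complement(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterSet:
    """gene id -> uppercase promoter sequence over {A, C, G, T, N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        clean = {}
        for gene, seq in self.sequences.items():
            s = seq.upper()
            if not s:
                raise ValueError(f"empty promoter for {gene!r}")
            bad = set(s) - set("ACGTN")
            if bad:
                raise ValueError(f"illegal characters {sorted(bad)} in promoter of {gene!r}")
            clean[gene] = s
        self.sequences = clean

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, gene: str) -> bool:
        return gene in self.sequences


@dataclass
class RegulatorPanel:
    """Candidate-TF discrete states: DataFrame of {-1, 0, +1}, rows = TFs,
    columns = conditions."""

    states: pd.DataFrame

    def __post_init__(self) -> None:
        if self.states.isna().any().any():
            raise ValueError("every TF needs a state in every condition")
        if not self.states.isin([-1, 0, 1]).all().all():
            raise ValueError("TF states must lie in {-1, 0, +1}")

    @property
    def tfs(self) -> list[str]:
        return list(self.states.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.states.columns)

    def state(self, tf: str, condition: str) -> int:
        if tf not in self.states.index:
            raise KeyError(f"unknown TF {tf!r}")
        return int(self.states.at[tf, condition])


@dataclass
class KmerFeatures:
    """Exact k-mer presence per gene: boolean matrix motifs x genes."""

    motifs: list[str]
    genes: list[str]
    matrix: np.ndarray  # bool, len(motifs) x len(genes)
    with_revcomp: bool = True

    def __post_init__(self) -> None:
        self.motif_index = {m: i for i, m in enumerate(self.motifs)}
        self.gene_index = {g: j for j, g in enumerate(self.genes)}

    def has(self, gene: str, motif: str) -> bool:
        j = self.gene_index.get(gene)
        if j is None:
            raise KeyError(f"gene {gene!r} has no promoter features")
        key = min(motif, reverse_complement(motif)) if self.with_revcomp else motif
        i = self.motif_index.get(key)
        return bool(self.matrix[i, j]) if i is not None else False

    def gene_mask(self, motif: str) -> np.ndarray:
        return self.matrix[self.motif_index[motif]]


def extract_kmer_features(
    promoters: PromoterSet, k_list: tuple[int, ...] = (5, 6), with_revcomp: bool = True
) -> KmerFeatures:
    """Enumerate every k-mer occurring in at least one promoter.

    A motif is marked present in a gene if the k-mer or (when
    ``with_revcomp``) its reverse complement occurs in the promoter;
    windows containing N never match.  Motifs are canonicalized to the
    lexicographically smaller of the k-mer and its reverse complement so
    each strand-equivalent pair appears once.
    """
    if any(k < 3 for k in k_list):
        raise ValueError("k must be >= 3")
    genes = list(promoters.sequences)
    max_len = max(len(s) for s in promoters.sequences.values())
    if all(k > max_len for k in k_list):
        raise ValueError("every k exceeds the longest promoter")
    per_gene: list[set[str]] = []
    all_motifs: set[str] = set()
    for gene in genes:
        seq = promoters.sequences[gene]
        found: set[str] = set()
        for k in k_list:
            for i in range(len(seq) - k + 1):
                w = seq[i : i + k]
                if "N" in w:
                    continue
                if with_revcomp:
                    w = min(w, reverse_complement(w))
                found.add(w)
        per_gene.append(found)
        all_motifs |= found
    motifs = sorted(all_motifs)
    idx = {m: i for i, m in enumerate(motifs)}
    matrix = np.zeros((len(motifs), len(genes)), dtype=bool)
    for j, found in enumerate(per_gene):
        for m in found:
            matrix[idx[m], j] = True
    return KmerFeatures(motifs, genes, matrix, with_revcomp)


@dataclass(frozen=True)
class Condition:
    """A feature predicate over (gene, condition) examples."""

    kind: str  # motif | regulator_state | conjunction
    motif: str | None = None
    tf: str | None = None
    state: int | None = None

    def sort_key(self) -> tuple:
        return (
            _KIND_RANK[self.kind],
            self.motif or "",
            self.tf or "",
            self.state if self.state is not None else 0,
        )

    def references_tf(self, tf: str) -> bool:
        return self.tf == tf

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.motif is not None:
            d["motif"] = self.motif
        if self.tf is not None:
            d["tf"] = self.tf
            d["state"] = self.state
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Condition":
        return cls(d["kind"], d.get("motif"), d.get("tf"), d.get("state"))


@dataclass(frozen=True)
class TrainingExample:
    gene: str
    condition: str
    label: int  # -1 or +1
    weight: float = 0.0


@dataclass(frozen=True)
class Rule:
    condition: Condition
    alpha_sat: float
    alpha_unsat: float
    round_index: int

    def to_dict(self) -> dict:
        return {
            "condition": self.condition.to_dict(),
            "alpha_sat": self.alpha_sat,
            "alpha_unsat": self.alpha_unsat,
            "round": self.round_index,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Rule":
        return cls(
            Condition.from_dict(d["condition"]), d["alpha_sat"], d["alpha_unsat"], d["round"]
        )


@dataclass
class BoostModel:
    """Ordered weighted-rule list plus the training trace."""

    rules: list[Rule] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    z_trace: list[float] = field(default_factory=list)
    error_trace: list[float] = field(default_factory=list)

    def without_tf(self, tf: str) -> "BoostModel":
        kept = [r for r in self.rules if not r.condition.references_tf(tf)]
        return BoostModel(kept, dict(self.config), list(self.z_trace), list(self.error_trace))

    def referenced_tfs(self) -> set[str]:
        return {r.condition.tf for r in self.rules if r.condition.tf is not None}

    def to_json(self) -> str:
        return json.dumps(
            {
                "rules": [r.to_dict() for r in self.rules],
                "config": self.config,
                "z_trace": self.z_trace,
                "error_trace": self.error_trace,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "BoostModel":
        d = json.loads(text)
        return cls(
            [Rule.from_dict(r) for r in d["rules"]],
            d.get("config", {}),
            d.get("z_trace", []),
            d.get("error_trace", []),
        )


def build_examples(
    calls: pd.DataFrame,
    target_genes: list[str] | None = None,
    conditions: list[str] | None = None,
) -> list[TrainingExample]:
    """One example per (gene, condition) with a nonzero call; label = call,
    weights uniform."""
    genes = list(target_genes) if target_genes is not None else list(calls.index)
    conds = list(conditions) if conditions is not None else list(calls.columns)
    sub = calls.loc[genes, conds]
    examples = [
        TrainingExample(g, c, int(sub.at[g, c]))
        for g in genes
        for c in conds
        if sub.at[g, c] != 0
    ]
    if not examples:
        raise ValueError("nothing to learn: no nonzero calls")
    w = 1.0 / len(examples)
    return [TrainingExample(e.gene, e.condition, e.label, w) for e in examples]


def evaluate_condition(
    cond: Condition,
    example: TrainingExample,
    features: KmerFeatures,
    panel: RegulatorPanel,
) -> bool:
    """Truth value of a feature predicate on one example."""
    if cond.kind == "motif":
        return features.has(example.gene, cond.motif)
    if cond.kind == "regulator_state":
        return panel.state(cond.tf, example.condition) == cond.state
    if cond.kind == "conjunction":
        return features.has(example.gene, cond.motif) and (
            panel.state(cond.tf, example.condition) == cond.state
        )
    raise ValueError(f"unknown condition kind {cond.kind!r}")


class _TrainerState:
    """Vectorized view of the example set on a gene x condition grid."""

    def __init__(
        self,
        examples: list[TrainingExample],
        features: KmerFeatures,
        panel: RegulatorPanel,
    ):
        self.genes = sorted({e.gene for e in examples})
        self.conditions = list(panel.conditions)
        gi = {g: i for i, g in enumerate(self.genes)}
        ci = {c: i for i, c in enumerate(self.conditions)}
        self.g_idx = np.array([gi[e.gene] for e in examples])
        self.c_idx = np.array([ci[e.condition] for e in examples])
        self.y = np.array([e.label for e in examples], dtype=float)
        w = np.array([e.weight for e in examples], dtype=float)
        self.w = w / w.sum()
        missing = [g for g in self.genes if g not in features.gene_index]
        if missing:
            raise ValueError(f"target genes without promoters: {missing}")
        # motif matrix restricted to the target genes, in grid order
        cols = [features.gene_index[g] for g in self.genes]
        self.motif_matrix = features.matrix[:, cols]
        self.motif_matrix_f = self.motif_matrix.astype(float)
        self.motifs = features.motifs
        self.motif_idx = {m: i for i, m in enumerate(self.motifs)}
        self.panel_states = panel.states[self.conditions].to_numpy(int)
        self.tfs = panel.tfs
        # all (tf, state) predicates and their condition masks, columnwise
        self.regstates = [(tf, s) for tf in self.tfs for s in (-1, 1)]
        self.regstate_masks = np.stack(
            [
                (self.panel_states[self.tfs.index(tf)] == s).astype(float)
                for tf, s in self.regstates
            ],
            axis=1,
        )
        self.margins = np.zeros(len(examples))

    def weight_grids(self) -> tuple[np.ndarray, np.ndarray]:
        shape = (len(self.genes), len(self.conditions))
        wp = np.zeros(shape)
        wm = np.zeros(shape)
        pos = self.y > 0
        np.add.at(wp, (self.g_idx[pos], self.c_idx[pos]), self.w[pos])
        np.add.at(wm, (self.g_idx[~pos], self.c_idx[~pos]), self.w[~pos])
        return wp, wm


def _z_and_alphas(
    ws_p: np.ndarray, ws_m: np.ndarray, wt_p: float, wt_m: float, eps: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vector of smoothed Z values plus block alphas for candidate arrays."""
    wu_p = np.maximum(wt_p - ws_p, 0.0)
    wu_m = np.maximum(wt_m - ws_m, 0.0)
    z = 2.0 * (np.sqrt((ws_p + eps) * (ws_m + eps)) + np.sqrt((wu_p + eps) * (wu_m + eps)))
    a_sat = 0.5 * np.log((ws_p + eps) / (ws_m + eps))
    a_unsat = 0.5 * np.log((wu_p + eps) / (wu_m + eps))
    return z, a_sat, a_unsat


def _round_best(
    state: _TrainerState,
    motif_rows: np.ndarray,
    eps: float,
    max_depth: int,
) -> tuple[Condition, float, float] | None:
    """Select the smoothed-Z minimizer among this round's candidates.

    Families scored: every regulator state (tf, +/-1); the subsampled
    motifs; and, when depth 2 is allowed, every (motif, regulator state)
    conjunction over the same subsample.  All weighted label masses come
    from three matrix products against the gene x condition weight grids.
    Ties within numerical tolerance are broken by kind order
    (regulator_state < motif < conjunction) then lexicographically.
    Returns (condition, alpha_sat, alpha_unsat), or None without
    candidates.
    """
    wp, wm = state.weight_grids()
    wt_p, wt_m = wp.sum(), wm.sum()

    # regulator_state: satisfaction depends on the condition only
    s_mask = state.regstate_masks  # (n_conditions, 2 * n_tfs)
    z_reg, as_reg, au_reg = _z_and_alphas(
        wp.sum(axis=0) @ s_mask, wm.sum(axis=0) @ s_mask, wt_p, wt_m, eps
    )

    z_mot = as_mot = au_mot = None
    z_conj = as_conj = au_conj = None
    if motif_rows.size:
        sub = state.motif_matrix_f[motif_rows]
        # motif: satisfaction depends on the gene only
        z_mot, as_mot, au_mot = _z_and_alphas(
            sub @ wp.sum(axis=1), sub @ wm.sum(axis=1), wt_p, wt_m, eps
        )
        if max_depth >= 2:
            z_conj, as_conj, au_conj = _z_and_alphas(
                sub @ (wp @ s_mask), sub @ (wm @ s_mask), wt_p, wt_m, eps
            )

    zmin = z_reg.min()
    for z in (z_mot, z_conj):
        if z is not None:
            zmin = min(zmin, z.min())
    tol = zmin + 1e-12

    candidates: list[tuple[Condition, float, float]] = []
    for j in np.flatnonzero(z_reg <= tol):
        tf, st = state.regstates[j]
        candidates.append(
            (Condition("regulator_state", tf=tf, state=st), float(as_reg[j]), float(au_reg[j]))
        )
    if z_mot is not None:
        for i in np.flatnonzero(z_mot <= tol):
            candidates.append(
                (
                    Condition("motif", motif=state.motifs[motif_rows[i]]),
                    float(as_mot[i]),
                    float(au_mot[i]),
                )
            )
    if z_conj is not None:
        for i, j in zip(*np.nonzero(z_conj <= tol)):
            tf, st = state.regstates[j]
            candidates.append(
                (
                    Condition(
                        "conjunction", motif=state.motifs[motif_rows[i]], tf=tf, state=st
                    ),
                    float(as_conj[i, j]),
                    float(au_conj[i, j]),
                )
            )
    if not candidates:
        return None
    candidates.sort(key=lambda item: item[0].sort_key())
    return candidates[0]


def best_condition(
    candidates: list[Condition],
    examples: list[TrainingExample],
    features: KmerFeatures,
    panel: RegulatorPanel,
    eps: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Condition, float]:
    """Exhaustively score an explicit candidate list; returns the Z-minimizer.

    Ties within numerical tolerance are broken by kind order
    (regulator_state < motif < conjunction) then lexicographically, then —
    should two distinct candidates still compare equal — by a seeded draw.
    """
    if not candidates:
        raise ValueError("no candidates")
    if eps is None:
        eps = 1.0 / (2 * len(examples))
    w = np.array([e.weight for e in examples])
    w = w / w.sum()
    y = np.array([e.label for e in examples])
    scored = []
    for cond in candidates:
        sat = np.array([evaluate_condition(cond, e, features, panel) for e in examples])
        ws_p = w[sat & (y > 0)].sum()
        ws_m = w[sat & (y < 0)].sum()
        z, _, _ = _z_and_alphas(
            np.array(ws_p), np.array(ws_m), w[y > 0].sum(), w[y < 0].sum(), eps
        )
        scored.append((float(z), cond))
    zmin = min(z for z, _ in scored)
    tied = [c for z, c in scored if z <= zmin + 1e-12]
    tied.sort(key=lambda c: c.sort_key())
    best_key = tied[0].sort_key()
    co_best = [c for c in tied if c.sort_key() == best_key]
    if len(co_best) > 1 and rng is not None:
        return co_best[int(rng.integers(len(co_best)))], zmin
    return tied[0], zmin


def boost_train(
    examples: list[TrainingExample],
    features: KmerFeatures,
    panel: RegulatorPanel,
    rounds: int = 100,
    seed: int = 0,
    *,
    subsample_rate: float = 0.5,
    epsilon: float | None = None,
    max_depth: int = 2,
) -> BoostModel:
    """Train a confidence-rated boosting model.

    Per round: the motif-candidate pool is subsampled at ``subsample_rate``
    (seeded; regulator-state candidates are always retained), the smoothed-Z
    minimizer is selected among regulator states, motifs, and conjunctions
    of a subsampled motif with any regulator state, the two block weights
    are set, and example weights are renormalized.  The trace records the
    actual per-round normalizer Z_t and the running training error, which
    satisfies err_t <= prod_{s<=t} Z_s.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if not (0 < subsample_rate <= 1):
        raise ValueError("subsample_rate must be in (0, 1]")
    n = len(examples)
    eps = epsilon if epsilon is not None else 1.0 / (2 * n)
    rng = np.random.default_rng(seed)
    state = _TrainerState(examples, features, panel)
    n_motifs = len(state.motifs)

    model = BoostModel(
        config={
            "rounds": rounds,
            "seed": seed,
            "subsample_rate": subsample_rate,
            "epsilon": eps,
            "max_depth": max_depth,
            "n_examples": n,
        }
    )
    for t in range(rounds):
        motif_rows = np.flatnonzero(rng.random(n_motifs) < subsample_rate)
        picked = _round_best(state, motif_rows, eps, max_depth)
        if picked is None:
            logger.info("round %d: no candidates after subsampling, skipped", t)
            continue
        cond, a_sat, a_unsat = picked

        # apply the rule
        if cond.kind == "motif":
            sat_g = state.motif_matrix[state.motif_idx[cond.motif]]
            sat = sat_g[state.g_idx]
        elif cond.kind == "regulator_state":
            sat_c = state.panel_states[state.tfs.index(cond.tf)] == cond.state
            sat = sat_c[state.c_idx]
        else:
            sat_g = state.motif_matrix[state.motif_idx[cond.motif]]
            sat_c = state.panel_states[state.tfs.index(cond.tf)] == cond.state
            sat = sat_g[state.g_idx] & sat_c[state.c_idx]

        contrib = np.where(sat, a_sat, a_unsat)
        state.margins += contrib
        state.w = state.w * np.exp(-state.y * contrib)
        z_actual = state.w.sum()
        state.w /= z_actual

        model.rules.append(Rule(cond, a_sat, a_unsat, t))
        model.z_trace.append(float(z_actual))
        model.error_trace.append(float(np.mean(state.margins * state.y <= 0)))

    return model


def predict_score(
    model: BoostModel,
    gene: str,
    condition: str,
    features: KmerFeatures,
    panel: RegulatorPanel,
) -> float:
    """Margin score F(gene, condition) = sum of the rule weights the example
    falls under; sign predicts the expression direction."""
    if gene not in features.gene_index:
        raise KeyError(f"unknown gene {gene!r}")
    f = 0.0
    ex = TrainingExample(gene, condition, 1)
    for rule in model.rules:
        f += rule.alpha_sat if evaluate_condition(rule.condition, ex, features, panel) else rule.alpha_unsat
    return f
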