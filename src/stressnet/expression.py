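"""Gene-level expression processing for dose/control microarray designs.

Intensities are assumed to arrive log2-scale and already normalized
(RMA or equivalent is upstream of this package).  Fold changes are
computed on the linear scale after de-logging, and reported with the
signed convention used throughout: a ratio r >= 1 stays r, a ratio
r < 1 becomes -1/r, so the open interval (-1, 1) is unrepresentable
and the sign encodes direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityMatrix",
    "FoldChangeMatrix",
    "DiscreteExpressionMatrix",
    "DeTable",
    "collapse_probesets",
    "signed_fold_change",
    "median_reference_fold_change",
    "discretize",
    "filter_inconsistent_replicates",
    "anova_de",
    "bh_fdr",
    "call_de_genes",
    "delta_delta_ct",
]


@dataclass
class IntensityMatrix:
    """Log-scale intensities, rows = genes or probesets, columns = samples.

    ``groups`` maps each sample id to its treatment group (e.g. control,
    low_dose, high_dose); ``replicates`` tags the replicate within a group.
    """

    values: pd.DataFrame
    groups: pd.Series
    replicates: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("intensity matrix contains missing cells")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass
class FoldChangeMatrix:
    """Signed linear-scale fold changes relative to a reference baseline."""

    values: pd.DataFrame
    reference_samples: list[str]


@dataclass
class DiscreteExpressionMatrix:
    """Genes x conditions of calls in {-1, 0, +1}."""

    calls: pd.DataFrame
    up_threshold: float = 1.5
    down_threshold: float = -1.5

    def __post_init__(self) -> None:
        ok = self.calls.isin([-1, 0, 1]).all().all()
        if not ok:
            raise ValueError("discrete calls must lie in {-1, 0, +1}")


@dataclass
class DeTable:
    """Per-gene DE summary: fold changes, F, p, q and the DE flag."""

    table: pd.DataFrame
    fc_cut: float = 1.2
    q_cut: float = 0.05
    fc_columns: list[str] = field(default_factory=list)

    def de_genes(self) -> set[str]:
        return set(self.table.index[self.table["is_de"]])


def collapse_probesets(m: IntensityMatrix, probe_to_gene: dict[str, str]) -> IntensityMatrix:
    """Collapse a probeset-level matrix to gene level.

    For each gene, the probeset with the highest mean intensity across all
    samples is retained; ties go to the lexicographically smaller probeset
    id.  Probesets absent from the map are dropped (count logged).
    """
    if not probe_to_gene:
        raise ValueError("empty probeset-to-gene map")
    present = [p for p in m.values.index if p in probe_to_gene]
    n_unmapped = len(m.values.index) - len(present)
    if n_unmapped:
        logger.info("collapse_probesets: dropped %d unmapped probesets", n_unmapped)
    if not present:
        raise ValueError("no probeset in the matrix is covered by the map")

    means = m.values.loc[present].mean(axis=1)
    # sort by (gene, -mean, probeset id): first row per gene is the winner
    order = sorted(present, key=lambda p: (probe_to_gene[p], -means[p], p))
    winners: dict[str, str] = {}
    for p in order:
        winners.setdefault(probe_to_gene[p], p)
    genes = list(winners)
    collapsed = m.values.loc[[winners[g] for g in genes]].copy()
    collapsed.index = genes
    return IntensityMatrix(collapsed, m.groups, m.replicates)


def signed_fold_change(x: float, ref: float) -> float:
    """Linear-scale signed fold change of ``x`` against ``ref``.

    Returns x/ref when the ratio is >= 1, else -ref/x (so magnitude is
    always >= 1 and the sign encodes direction).
    """
    if ref == 0:
        raise ValueError("zero reference")
    r = x / ref
    return r if r >= 1 else -1.0 / r


def _signed_fc_array(ratio: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(ratio >= 1, ratio, -1.0 / ratio)


def median_reference_fold_change(
    m: IntensityMatrix,
    reference_samples: list[str],
    *,
    delog_base: float | None = 2.0,
) -> FoldChangeMatrix:
    """Per-cell signed fold change against each gene's median reference level.

    Intensities are de-logged (base ``delog_base``; pass None when the
    matrix is already linear) before taking ratios, since fold changes are
    linear-scale quantities.
    """
    if not reference_samples:
        raise ValueError("need at least one reference sample")
    linear = m.values if delog_base is None else np.power(delog_base, m.values)
    ref_median = linear[reference_samples].median(axis=1)
    zero = ref_median.index[ref_median == 0].tolist()
    if zero:
        raise ValueError(f"zero median reference for genes: {zero}")
    ratio = linear.div(ref_median, axis=0)
    fc = pd.DataFrame(
        _signed_fc_array(ratio.to_numpy(float)),
        index=linear.index,
        columns=linear.columns,
    )
    return FoldChangeMatrix(fc, list(reference_samples))


def discretize(
    fc: FoldChangeMatrix, up: float = 1.5, down: float = -1.5
) -> DiscreteExpressionMatrix:
    """Map signed fold changes to {-1, 0, +1} calls (thresholds inclusive)."""
    if up < 1 or down > -1:
        raise ValueError("thresholds must satisfy up >= 1 and down <= -1")
    v = fc.values.to_numpy(float)
    calls = np.where(v >= up, 1, np.where(v <= down, -1, 0))
    return DiscreteExpressionMatrix(
        pd.DataFrame(calls, index=fc.values.index, columns=fc.values.columns),
        up_threshold=up,
        down_threshold=down,
    )


def filter_inconsistent_replicates(
    d: DiscreteExpressionMatrix,
    replicate_groups: dict[str, list[str]],
) -> tuple[DiscreteExpressionMatrix, list[str]]:
    """Collapse replicate-level calls to condition level, dropping genes
    whose replicates disagree.

    ``replicate_groups`` maps condition -> list of sample (column) ids.
    A gene is retained only if, within every condition, all replicate
    calls are identical; the condition call is then the shared value.
    """
    for cond, cols in replicate_groups.items():
        if not cols:
            raise ValueError(f"condition {cond!r} has zero replicates")
    conditions = list(replicate_groups)
    per_cond = {}
    consistent = pd.Series(True, index=d.calls.index)
    for cond in conditions:
        block = d.calls[replicate_groups[cond]]
        unanimous = block.nunique(axis=1) == 1
        consistent &= unanimous
        per_cond[cond] = block.iloc[:, 0]
    kept = d.calls.index[consistent]
    dropped = d.calls.index[~consistent].tolist()
    out = pd.DataFrame({c: per_cond[c].loc[kept] for c in conditions})
    return (
        DiscreteExpressionMatrix(out, d.up_threshold, d.down_threshold),
        dropped,
    )


def anova_de(m: IntensityMatrix, group_order: list[str] | None = None) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per gene on log-scale intensities.

    Returns a DataFrame indexed by gene with columns F and p (upper tail).
    Rows with zero within-group variance but nonzero between-group variance
    get the smallest representable positive p (logged).
    """
    groups = group_order or list(dict.fromkeys(m.groups[m.sample_ids]))
    cols = {g: m.samples_in_group(g) for g in groups}
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g, c in cols.items():
        if len(c) < 2:
            raise ValueError(f"group {g!r} has fewer than two samples")

    x = m.values.to_numpy(float)
    n_total = sum(len(c) for c in cols.values())
    grand = m.values[[s for c in cols.values() for s in c]].mean(axis=1).to_numpy()

    ss_between = np.zeros(x.shape[0])
    ss_within = np.zeros(x.shape[0])
    for g in groups:
        block = m.values[cols[g]].to_numpy(float)
        gmean = block.mean(axis=1)
        ss_between += len(cols[g]) * (gmean - grand) ** 2
        ss_within += ((block - gmean[:, None]) ** 2).sum(axis=1)

    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ms_between / ms_within
    p = scipy.stats.f.sf(f_stat, df_between, df_within)

    degenerate = (ms_within == 0) & (ms_between > 0)
    if degenerate.any():
        logger.warning(
            "anova_de: %d genes with zero within-group variance; "
            "p set to smallest positive float",
            int(degenerate.sum()),
        )
        f_stat = np.where(degenerate, np.inf, f_stat)
        p = np.where(degenerate, np.finfo(float).tiny, p)
    flat = (ms_within == 0) & (ms_between == 0)
    f_stat = np.where(flat, 0.0, f_stat)
    p = np.where(flat, 1.0, p)

    return pd.DataFrame({"F": f_stat, "p": p}, index=m.values.index)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de_genes(
    table: pd.DataFrame, fc_column: str, fc_cut: float = 1.2, q_cut: float = 0.05
) -> set[str]:
    """Genes with |signed fc| >= fc_cut and q <= q_cut (both inclusive)."""
    if fc_cut < 1:
        raise ValueError("fc_cut must be >= 1")
    mask = (table[fc_column].abs() >= fc_cut) & (table["q"] <= q_cut)
    return set(table.index[mask])


def build_de_table(
    m: IntensityMatrix,
    control_group: str,
    treatment_groups: list[str],
    fc_cut: float = 1.2,
    q_cut: float = 0.05,
    *,
    delog_base: float | None = 2.0,
) -> DeTable:
    """Full DE workflow: ANOVA across all groups, BH correction, per-contrast
    signed fold changes of treatment group means against the control mean
    (on the linear scale), and the inclusive-threshold DE flag on the first
    contrast."""
    stats = anova_de(m, [control_group] + treatment_groups)
    q = bh_fdr(stats["p"].to_numpy())
    linear = m.values if delog_base is None else np.power(delog_base, m.values)
    ctrl_mean = linear[m.samples_in_group(control_group)].mean(axis=1)
    out = pd.DataFrame(index=m.values.index)
    fc_cols = []
    for g in treatment_groups:
        ratio = (linear[m.samples_in_group(g)].mean(axis=1) / ctrl_mean).to_numpy(float)
        col = f"fc_{g}"
        out[col] = _signed_fc_array(ratio)
        fc_cols.append(col)
    out["F"] = stats["F"]
    out["p"] = stats["p"]
    out["q"] = q
    out["is_de"] = (out[fc_cols[0]].abs() >= fc_cut) & (out["q"] <= q_cut)
    return DeTable(out, fc_cut=fc_cut, q_cut=q_cut, fc_columns=fc_cols)


def delta_delta_ct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the comparative Ct (2^-ddCt) method."""
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))
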