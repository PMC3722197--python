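"""Synthetic data generators and packaged worked-example tables.

Two generators cover the two halves of the pipeline:

* ``generate_planted_network`` emulates the regulatory-inference inputs:
  uniform-background promoters with one exact motif planted per regulon
  member, candidate-TF states drawn symmetrically per condition, and
  noisy discrete target calls that follow the owning TF's state with
  probability 1 - eta.  Decoy target genes get symmetric random calls
  (not zeros), so a learner must exploit the features rather than class
  imbalance; decoy candidate TFs carry states but regulate nothing,
  emulating the large candidate panel screened in practice.

* ``generate_expression_experiment`` emulates a two-dose + control
  log2-intensity microarray design with three replicates per group,
  planted fold changes on a subset of genes (the low-dose effect is a
  configurable fraction of the high-dose effect, mirroring a
  dose-response), and i.i.d. Gaussian noise.

Both are pure functions of (parameters, seed).  The packaged tables are
the printed worked-example records (46 doubly-upregulated genes with
high/low-dose fold changes; the oxidative-stress/iron gene classes; the
10 consensus TFs) shipped as TSV with checksum verification.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .boosting import PromoterSet, RegulatorPanel, reverse_complement
from .expression import DiscreteExpressionMatrix, IntensityMatrix

logger = logging.getLogger(__name__)

# checksums of the packaged tables (verbatim printed values)
_FIXTURE_SHA256 = {
    "table1.tsv": "b9efeb412ee336b07202e8b8c2236eb6c99046b6ac2d92c83226155059689c97",
    "table2.tsv": "cebddcf2fc16dcb42dc5abad8b56b900919a592d7803437d40a23249d258097b",
    "table3.tsv": "62c717237e18d9410ba06d448c4a4c42215616b96407048524c77cd43450b855",
}

__all__ = [
    "PlantedNetworkTruth",
    "NetworkSimConfig",
    "ExpressionSimConfig",
    "generate_planted_network",
    "generate_expression_experiment",
    "paper_table_fixtures",
    "load_table",
]


@dataclass
class NetworkSimConfig:
    """Study conditions for the planted-network benchmark.

    The candidate panel holds the ``n_tfs`` planted regulators;
    ``n_decoy_tfs`` extra candidate TFs with random states can be added
    for a harder benchmark, but note that with few conditions random
    decoy state-vectors inevitably include near-copies of planted TF
    states — such decoys are effective co-regulators of the planted
    regulons, not negatives, which is why they are off by default."""

    n_tfs: int = 5
    targets_per_tf: int = 40
    n_decoy_tfs: int = 0
    n_decoy_genes: int = 50
    n_conditions: int = 20
    promoter_len: int = 1000
    motif_len: int = 6
    eta: float = 0.1  # label-noise rate


@dataclass
class PlantedNetworkTruth:
    tfs: list[str]
    motifs: dict[str, str]  # tf -> planted k-mer
    regulons: dict[str, list[str]]  # tf -> member genes
    decoy_tfs: list[str]
    decoy_genes: list[str]
    eta: float
    n_conditions: int


@dataclass
class ExpressionSimConfig:
    """Study conditions for the two-dose microarray simulation."""

    n_genes: int = 1000
    n_planted: int = 100
    replicates: int = 3
    fold_range: tuple[float, float] = (2.0, 8.0)
    low_dose_fraction: float = 0.25
    sigma: float = 0.1  # log2-scale noise sd
    baseline_range: tuple[float, float] = (6.0, 12.0)
    groups: tuple[str, str, str] = ("control", "low_dose", "high_dose")

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per group")
        if self.fold_range[0] < 1:
            raise ValueError("fold range must be >= 1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def generate_planted_network(
    cfg: NetworkSimConfig | None = None, seed: int = 0
) -> tuple[PromoterSet, RegulatorPanel, DiscreteExpressionMatrix, PlantedNetworkTruth]:
    """Draw a planted TF->regulon network with motifs embedded in promoters.

    Promoters are i.i.d. uniform A/C/G/T strings; each regulon member
    receives one planted occurrence of its TF's motif at a uniform
    position.  TF states per condition are uniform +/-1; each target's
    call equals its TF's state with probability 1 - eta.  Fully
    reproducible from (cfg, seed).
    """
    cfg = cfg or NetworkSimConfig()
    if not (0 <= cfg.eta < 0.5):
        raise ValueError("eta must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)

    planted_tfs = [f"tf_{i + 1:03d}" for i in range(cfg.n_tfs)]
    decoy_tfs = [f"tf_{i + 1:03d}" for i in range(cfg.n_tfs, cfg.n_tfs + cfg.n_decoy_tfs)]
    conditions = [f"cond_{j + 1:02d}" for j in range(cfg.n_conditions)]

    # distinct canonical motifs, one per planted TF (regenerate collisions)
    motifs: dict[str, str] = {}
    seen: set[str] = set()
    for tf in planted_tfs:
        while True:
            m = _random_seq(rng, cfg.motif_len)
            canon = min(m, reverse_complement(m))
            if canon not in seen:
                seen.add(canon)
                motifs[tf] = m
                break
            logger.info("motif collision for %s, regenerating", tf)

    regulons: dict[str, list[str]] = {}
    g = 0
    for tf in planted_tfs:
        regulons[tf] = [f"g_{g + i + 1:04d}" for i in range(cfg.targets_per_tf)]
        g += cfg.targets_per_tf
    decoy_genes = [f"g_{g + i + 1:04d}" for i in range(cfg.n_decoy_genes)]
    targets = [m for tf in planted_tfs for m in regulons[tf]]
    all_genes = targets + decoy_genes

    sequences: dict[str, str] = {}
    for tf in planted_tfs:
        for member in regulons[tf]:
            seq = _random_seq(rng, cfg.promoter_len)
            pos = int(rng.integers(0, cfg.promoter_len - cfg.motif_len + 1))
            seq = seq[:pos] + motifs[tf] + seq[pos + cfg.motif_len :]
            sequences[member] = seq
    for gene in decoy_genes:
        sequences[gene] = _random_seq(rng, cfg.promoter_len)

    panel_tfs = planted_tfs + decoy_tfs
    states = rng.choice([-1, 1], size=(len(panel_tfs), cfg.n_conditions))
    panel = RegulatorPanel(pd.DataFrame(states, index=panel_tfs, columns=conditions))

    calls = np.empty((len(all_genes), cfg.n_conditions), dtype=int)
    row = {gene: i for i, gene in enumerate(all_genes)}
    for ti, tf in enumerate(planted_tfs):
        flip = rng.random((cfg.targets_per_tf, cfg.n_conditions)) < cfg.eta
        tf_states = states[ti][None, :]
        member_rows = [row[m] for m in regulons[tf]]
        calls[member_rows] = np.where(flip, -tf_states, tf_states)
    calls[[row[d] for d in decoy_genes]] = rng.choice(
        [-1, 1], size=(len(decoy_genes), cfg.n_conditions)
    )

    dem = DiscreteExpressionMatrix(pd.DataFrame(calls, index=all_genes, columns=conditions))
    truth = PlantedNetworkTruth(
        tfs=planted_tfs,
        motifs=motifs,
        regulons=regulons,
        decoy_tfs=decoy_tfs,
        decoy_genes=decoy_genes,
        eta=cfg.eta,
        n_conditions=cfg.n_conditions,
    )
    return PromoterSet(sequences), panel, dem, truth


def generate_expression_experiment(
    cfg: ExpressionSimConfig | None = None, seed: int = 0
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Simulate a control/low-dose/high-dose log2-intensity matrix.

    Returns the intensity matrix (with group and replicate assignments)
    and a truth table with the planted signed linear fold changes per
    gene and dose.
    """
    cfg = cfg or ExpressionSimConfig()
    rng = np.random.default_rng(seed)
    genes = [f"g_{i + 1:05d}" for i in range(cfg.n_genes)]
    control, low, high = cfg.groups
    samples, group_of, rep_of = [], {}, {}
    for grp in cfg.groups:
        for r in range(cfg.replicates):
            s = f"{grp}_r{r + 1}"
            samples.append(s)
            group_of[s] = grp
            rep_of[s] = f"r{r + 1}"

    baseline = rng.uniform(*cfg.baseline_range, size=cfg.n_genes)
    planted_idx = rng.choice(cfg.n_genes, size=cfg.n_planted, replace=False)
    log2_high = np.zeros(cfg.n_genes)
    magnitudes = np.log2(rng.uniform(*cfg.fold_range, size=cfg.n_planted))
    signs = rng.choice([-1.0, 1.0], size=cfg.n_planted)
    log2_high[planted_idx] = magnitudes * signs
    log2_low = cfg.low_dose_fraction * log2_high

    effect = {control: np.zeros(cfg.n_genes), low: log2_low, high: log2_high}
    data = {}
    for s in samples:
        noise = rng.normal(0.0, cfg.sigma, size=cfg.n_genes)
        data[s] = baseline + effect[group_of[s]] + noise
    values = pd.DataFrame(data, index=genes)

    def signed(log2fc: np.ndarray) -> np.ndarray:
        lin = 2.0 ** log2fc
        return np.where(lin >= 1, lin, -1.0 / lin)

    truth = pd.DataFrame(
        {
            "planted": np.isin(np.arange(cfg.n_genes), planted_idx),
            "fc_high": signed(log2_high),
            "fc_low": signed(log2_low),
        },
        index=genes,
    )
    m = IntensityMatrix(
        values, pd.Series(group_of), pd.Series(rep_of)
    )
    return m, truth


def _fixture_text(name: str) -> str:
    return (resources.files("stressnet") / "data" / name).read_text()


def load_table(name: str, verify: bool = True) -> pd.DataFrame:
    """Read one packaged table, verifying its checksum."""
    text = _fixture_text(name)
    if verify:
        digest = hashlib.sha256(text.encode()).hexdigest()
        expected = _FIXTURE_SHA256[name]
        if digest != expected:
            raise ValueError(f"checksum mismatch for packaged fixture {name}")
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t")
    if name == "table1.tsv":
        df = df.set_index("gene")
    return df


def paper_table_fixtures(verify: bool = True) -> dict[str, pd.DataFrame]:
    """The three packaged worked-example tables.

    table1: the 46 genes upregulated > 4-fold at both doses, with signed
    fold changes and p-values at each dose.  table2: oxidative-stress and
    iron-metabolism gene classes with p and fold change.  table3: the 10
    consensus-significant TFs.
    """
    return {
        "table1": load_table("table1.tsv", verify),
        "table2": load_table("table2.tsv", verify),
        "table3": load_table("table3.tsv", verify),
    }
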