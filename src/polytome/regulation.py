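"""Steady-state mRNA rate decomposition and regulation-pattern clustering.

At (pseudo-)steady state the concentration of an mRNA species is set by the
balance of transcription against degradation and dilution by growth:

    V_T = k_trans * gene_copies = (k_deg + mu) * [mRNA]

with the degradation rate constant obtained from the half-life,
k_deg = ln 2 / t_half, and the dilution rate constant equal to the specific
growth rate mu = (1/X) dX/dt (constant in balanced growth; the biomass X
enters only through this constant). Gene copy numbers are assumed constant
(default 1). All rates are harmonized to min^-1 internally (mu arrives in
h^-1, half-lives in minutes).

For each gene the stress/optimal ratios of k_trans, k_deg, mu and of the two
translational measures (ribosome density, ribosome occupancy) are assembled
into a ratio table — the mu ratio is genome-wide by construction and a
constant reference column of 1 is appended to anchor the colour scale — and
the genes are grouped by Ward hierarchical clustering (Euclidean distance on
the raw ratios) with the tree cut at k clusters (default 6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .simulate import RATIO_COLUMNS
from .translatome import TranslatomeResults

__all__ = [
    "degradation_rate",
    "transcription_rate_constant",
    "rate_constants",
    "build_ratio_table",
    "cluster_patterns",
    "ClusterResult",
    "RegulationModel",
    "RegulationResults",
]

LN2 = float(np.log(2.0))


def degradation_rate(t_half: float) -> float:
    """mRNA degradation rate constant k_deg = ln 2 / t_half (min^-1)."""
    if np.any(np.asarray(t_half) <= 0):
        raise ValueError("half-life must be positive")
    return LN2 / t_half


def transcription_rate_constant(
    mrna_level: float,
    k_deg: float,
    mu_per_min: float,
    gene_copies: int = 1,
) -> float:
    """k_trans from the steady-state balance (per gene copy).

    k_trans = (k_deg + mu) * [mRNA] / gene_copies, all rates in min^-1.
    """
    if np.any(np.asarray(gene_copies) < 1):
        raise ValueError("gene_copies must be >= 1")
    return (k_deg + mu_per_min) * mrna_level / gene_copies


def rate_constants(
    rates: pd.DataFrame, growth_rate_h: float
) -> pd.DataFrame:
    """Full rate-constant set per gene for one condition.

    ``rates`` columns: ``gene_id``, ``half_life_min``, ``mrna_level`` and
    optionally ``gene_copies`` (default 1). ``growth_rate_h`` is mu in h^-1.
    Returns the frame (indexed by gene_id) with ``k_deg``, ``mu`` (both
    min^-1) and ``k_trans`` added.
    """
    out = rates.set_index("gene_id").copy() if "gene_id" in rates else rates.copy()
    if "gene_copies" not in out.columns:
        out["gene_copies"] = 1
    mu_min = growth_rate_h / 60.0
    out["k_deg"] = degradation_rate(out["half_life_min"].to_numpy())
    out["mu"] = mu_min
    out["k_trans"] = transcription_rate_constant(
        out["mrna_level"].to_numpy(),
        out["k_deg"].to_numpy(),
        mu_min,
        out["gene_copies"].to_numpy(),
    )
    return out


def build_ratio_table(
    rates_stress: pd.DataFrame,
    rates_optimal: pd.DataFrame,
    translatome_stress: TranslatomeResults | pd.DataFrame,
    translatome_optimal: TranslatomeResults | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-gene stress/optimal regulation-ratio table.

    Inputs are rate-constant frames from :func:`rate_constants` and fitted
    translatome results (their non-aberrant single-peak subset is used). A
    gene enters the table only with complete values in both conditions;
    excluded genes are returned with a reason. The table's columns are
    k_trans, k_deg, mu, density, occupancy, reference (constant 1).
    """
    ts = (
        translatome_stress.retained()
        if isinstance(translatome_stress, TranslatomeResults)
        else translatome_stress
    )
    to = (
        translatome_optimal.retained()
        if isinstance(translatome_optimal, TranslatomeResults)
        else translatome_optimal
    )
    excluded = []
    rows = []
    candidates = rates_stress.index.union(rates_optimal.index).union(
        ts.index
    ).union(to.index)
    for g in candidates:
        missing = [
            tag
            for tag, frame in (
                ("rates_stress", rates_stress),
                ("rates_optimal", rates_optimal),
                ("translatome_stress", ts),
                ("translatome_optimal", to),
            )
            if g not in frame.index
        ]
        if missing:
            excluded.append({"gene_id": g, "reason": "missing:" + ",".join(missing)})
            continue
        rs, ro = rates_stress.loc[g], rates_optimal.loc[g]
        denom = {
            "k_trans": ro["k_trans"],
            "k_deg": ro["k_deg"],
            "mu": ro["mu"],
            "density": to.loc[g, "density"],
            "occupancy": to.loc[g, "occupancy"],
        }
        if any(v == 0 or not np.isfinite(v) for v in denom.values()):
            excluded.append({"gene_id": g, "reason": "zero_optimal_denominator"})
            continue
        rows.append(
            {
                "gene_id": g,
                "k_trans": rs["k_trans"] / denom["k_trans"],
                "k_deg": rs["k_deg"] / denom["k_deg"],
                "mu": rs["mu"] / denom["mu"],
                "density": ts.loc[g, "density"] / denom["density"],
                "occupancy": ts.loc[g, "occupancy"] / denom["occupancy"],
                "reference": 1.0,
            }
        )
    table = pd.DataFrame(rows, columns=["gene_id", *RATIO_COLUMNS]).set_index(
        "gene_id"
    )
    return table, pd.DataFrame(excluded, columns=["gene_id", "reason"])


@dataclass
class ClusterResult:
    """Ward clustering of the ratio table cut at k clusters.

    ``labels``: gene_id -> cluster 1..k, labels sorted by decreasing cluster
    size; ``linkage_matrix``: the scipy linkage encoding of the tree.
    """

    labels: pd.Series
    linkage_matrix: np.ndarray
    k: int

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def cluster_patterns(
    table: pd.DataFrame,
    k: int = 6,
    seed: int | None = None,
    log2: bool = False,
) -> ClusterResult:
    """Agglomerative Ward clustering of the regulation ratios.

    Euclidean distance on the raw ratio columns (including the reference
    column) as displayed; ``log2=True`` clusters log2 ratios instead (the
    reference column then becomes 0). Deterministic given the input order —
    ``seed`` is accepted for interface symmetry but unused, as Ward
    agglomeration involves no randomness.
    """
    if k > len(table):
        raise ValueError("k must not exceed the number of genes")
    X = table.to_numpy(dtype=float)
    if log2:
        with np.errstate(divide="ignore"):
            X = np.log2(np.clip(X, 1e-12, None))
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel 1..k by decreasing size (ties by first appearance)
    order = (
        pd.Series(raw)
        .value_counts(sort=True)
        .index.to_list()
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series(
        [remap[r] for r in raw], index=table.index, name="cluster"
    )
    return ClusterResult(labels=labels, linkage_matrix=Z, k=int(labels.max()))


class RegulationModel:
    """Regulation-pattern model: rate decomposition + ratio clustering.

    Parameters
    ----------
    rates_stress, rates_optimal : DataFrame
        Per-condition inputs with columns ``gene_id``, ``half_life_min``,
        ``mrna_level`` (and optional ``gene_copies``).
    growth_rate_stress, growth_rate_optimal : float
        Specific growth rates in h^-1.
    translatome_stress, translatome_optimal : TranslatomeResults
        Fitted per-condition translatome tables.
    """

    def __init__(
        self,
        rates_stress: pd.DataFrame,
        rates_optimal: pd.DataFrame,
        growth_rate_stress: float,
        growth_rate_optimal: float,
        translatome_stress: TranslatomeResults,
        translatome_optimal: TranslatomeResults,
    ) -> None:
        self.rates_stress = rate_constants(rates_stress, growth_rate_stress)
        self.rates_optimal = rate_constants(rates_optimal, growth_rate_optimal)
        self.translatome_stress = translatome_stress
        self.translatome_optimal = translatome_optimal

    def fit(self, k: int = 6, log2: bool = False) -> "RegulationResults":
        ratios, excluded = build_ratio_table(
            self.rates_stress,
            self.rates_optimal,
            self.translatome_stress,
            self.translatome_optimal,
        )
        clusters = cluster_patterns(ratios, k=k, log2=log2)
        return RegulationResults(
            ratios=ratios,
            excluded=excluded,
            clusters=clusters,
            rates_stress=self.rates_stress,
            rates_optimal=self.rates_optimal,
        )


@dataclass
class RegulationResults:
    """Ratio table, exclusions and the fitted clustering."""

    ratios: pd.DataFrame
    excluded: pd.DataFrame
    clusters: ClusterResult
    rates_stress: pd.DataFrame
    rates_optimal: pd.DataFrame

    def table(self) -> pd.DataFrame:
        """Ratio table with the cluster label column appended."""
        out = self.ratios.copy()
        out["cluster"] = self.clusters.labels
        return out

    def summary(self) -> str:
        sizes = self.clusters.sizes()
        lines = [
            f"Regulation ratios: {len(self.ratios)} genes, "
            f"{len(self.excluded)} excluded",
            f"  mu ratio (genome-wide): {self.ratios['mu'].iloc[0]:.4f}"
            if len(self.ratios)
            else "  (empty table)",
            f"  Ward clustering, k = {self.clusters.k}: sizes "
            + ", ".join(f"{c}:{n}" for c, n in sizes.items()),
        ]
        return "\n".join(lines)

    def write(self, path) -> None:
        self.table().to_csv(path, sep="\t")

    def plot_heatmap(self, ax=None):
        """Ratio heatmap with genes ordered by cluster, anchored at ratio 1."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 6))
        t = self.table().sort_values("cluster")
        data = t[list(self.ratios.columns)].to_numpy(dtype=float)
        im = ax.imshow(
            data, aspect="auto", cmap="RdBu_r", vmin=0.0, vmax=2.0
        )
        ax.set_xticks(range(data.shape[1]))
        ax.set_xticklabels(self.ratios.columns, rotation=90)
        ax.set_ylabel("genes (by cluster)")
        plt.colorbar(im, ax=ax, label="stress / optimal ratio")
        return ax
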