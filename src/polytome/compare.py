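"""Two-condition comparison and translational-regulation classes.

Occupancy is compared per gene with a two-sample Student test on the
per-series occupancy values (Welch's unequal-variance form by default, n = 5
per condition); a gene is called higher/lower by the direction of the mean
difference when p < alpha, else similar. Ribosome density is discrete given
the fraction -> ribosome calibration, so the density call is an exact
comparison of the peak fractions' mean ribosome counts (the shared CDS length
cancels from the ratio).

The two calls combine into the regulation class of the gene:

====================  =================  ==================
occupancy call        density call       class
====================  =================  ==================
higher / similar      higher             up
lower  / similar      lower              down
higher                lower              antagonistic
lower                 higher             antagonistic
similar               similar            unregulated
higher / lower        similar            occupancy-only
====================  =================  ==================

No multiple-testing correction is applied by default (per-gene p < 0.05);
Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .translatome import TranslatomeResults

__all__ = [
    "HIGHER",
    "LOWER",
    "SIMILAR",
    "compare_occupancy",
    "compare_density",
    "classify",
    "compare_conditions",
    "ComparisonResults",
]

HIGHER = "higher"
LOWER = "lower"
SIMILAR = "similar"

REG_UP = "up"
REG_DOWN = "down"
REG_ANTAGONISTIC = "antagonistic"
REG_UNREGULATED = "unregulated"
REG_OCCUPANCY_ONLY = "occupancy-only"

_CLASS_TABLE = {
    (HIGHER, HIGHER): REG_UP,
    (SIMILAR, HIGHER): REG_UP,
    (LOWER, LOWER): REG_DOWN,
    (SIMILAR, LOWER): REG_DOWN,
    (HIGHER, LOWER): REG_ANTAGONISTIC,
    (LOWER, HIGHER): REG_ANTAGONISTIC,
    (SIMILAR, SIMILAR): REG_UNREGULATED,
    (HIGHER, SIMILAR): REG_OCCUPANCY_ONLY,
    (LOWER, SIMILAR): REG_OCCUPANCY_ONLY,
}


class OccupancyComparison(NamedTuple):
    ratio: float
    p_value: float
    call: str


class DensityComparison(NamedTuple):
    ratio: float
    call: str


def compare_occupancy(
    occ_stress: np.ndarray,
    occ_optimal: np.ndarray,
    alpha: float = 0.05,
    pooled: bool = False,
) -> OccupancyComparison:
    """Student test on per-series occupancies; ratio is stress/optimal means.

    ``pooled=True`` uses the classical equal-variance form instead of
    Welch's. If both samples are degenerate (zero variance), p is 1 for equal
    means and 0 otherwise.
    """
    a = np.asarray(occ_stress, dtype=float)
    b = np.asarray(occ_optimal, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 occupancy values per condition")
    mean_a, mean_b = a.mean(), b.mean()
    # degenerate (zero-variance) samples: decide by the mean difference
    # directly; the 1e-12 floor absorbs float jitter in exact data
    se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    if se < 1e-12:
        p = 1.0 if abs(mean_a - mean_b) <= 1e-12 else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=pooled).pvalue)
    if p < alpha:
        call = HIGHER if mean_a > mean_b else LOWER
    else:
        call = SIMILAR
    ratio = mean_a / mean_b if mean_b != 0 else np.inf
    return OccupancyComparison(ratio=float(ratio), p_value=p, call=call)


def compare_density(
    ribosomes_stress: float, ribosomes_optimal: float
) -> DensityComparison:
    """Density call by exact comparison of peak-fraction ribosome counts.

    Densities of the same gene share its CDS length, so the stress/optimal
    density ratio equals the ribosome-count ratio, and higher/lower/similar
    is decided by exact comparison of the calibrated counts.
    """
    if not (np.isfinite(ribosomes_stress) and np.isfinite(ribosomes_optimal)):
        raise ValueError("both peak ribosome counts must be defined")
    ratio = (
        ribosomes_stress / ribosomes_optimal
        if ribosomes_optimal != 0
        else np.inf
    )
    if ribosomes_stress > ribosomes_optimal:
        call = HIGHER
    elif ribosomes_stress < ribosomes_optimal:
        call = LOWER
    else:
        call = SIMILAR
    return DensityComparison(ratio=float(ratio), call=call)


def classify(occ_call: str, dens_call: str) -> str:
    """Regulation class from the (occupancy, density) call pair."""
    try:
        return _CLASS_TABLE[(occ_call, dens_call)]
    except KeyError:
        raise ValueError(f"invalid call pair: ({occ_call!r}, {dens_call!r})")


@dataclass
class ComparisonResults:
    """Per-gene two-condition comparison table.

    ``table`` (indexed by gene_id): occ_ratio, occ_p, occ_call, dens_ratio,
    dens_call, reg_class. ``excluded``: genes dropped before comparison and
    why (missing in one condition, widened peak, aberrant density).
    """

    table: pd.DataFrame
    excluded: pd.DataFrame
    alpha: float

    def class_counts(self) -> pd.Series:
        return self.table["reg_class"].value_counts()

    def occupancy_call_counts(self) -> pd.Series:
        return self.table["occ_call"].value_counts()

    def density_call_counts(self) -> pd.Series:
        return self.table["dens_call"].value_counts()

    def summary(self) -> str:
        n = len(self.table)
        lines = [
            f"Condition comparison: {n} genes with both measures "
            f"(alpha = {self.alpha})",
            "  occupancy calls: "
            + ", ".join(
                f"{k} {v}" for k, v in self.occupancy_call_counts().items()
            ),
            "  density calls:   "
            + ", ".join(
                f"{k} {v}" for k, v in self.density_call_counts().items()
            ),
            "  regulation classes: "
            + ", ".join(f"{k} {v}" for k, v in self.class_counts().items()),
            f"  excluded: {len(self.excluded)}",
        ]
        return "\n".join(lines)

    def genes_in_class(self, reg_class: str) -> pd.Index:
        return self.table.index[self.table["reg_class"] == reg_class]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def compare_conditions(
    stress: TranslatomeResults,
    optimal: TranslatomeResults,
    alpha: float = 0.05,
    pooled: bool = False,
    fdr: bool = False,
) -> ComparisonResults:
    """Compare two fitted translatome results gene by gene.

    Genes enter the comparison only with a single-fraction, non-aberrant
    peak in both conditions. With ``fdr=True`` the occupancy p-values are
    Benjamini-Hochberg adjusted before calling (off by default).
    """
    excluded = []
    candidates = stress.table.index.union(optimal.table.index)
    usable_s = stress.retained()
    usable_o = optimal.retained()
    shared = usable_s.index.intersection(usable_o.index)
    for g in candidates.difference(shared):
        if g not in stress.table.index or g not in optimal.table.index:
            reason = "missing_in_one_condition"
        else:
            flags = []
            for res in (stress, optimal):
                row = res.table.loc[g]
                if row["widened"]:
                    flags.append(f"widened_{res.condition.name}")
                elif row["aberrant"]:
                    flags.append(f"aberrant_{res.condition.name}")
            reason = ";".join(flags) or "unknown"
        excluded.append({"gene_id": g, "reason": reason})

    rows = []
    for g in shared:
        occ = compare_occupancy(
            stress.occupancy_series[g],
            optimal.occupancy_series[g],
            alpha=alpha,
            pooled=pooled,
        )
        dens = compare_density(
            float(usable_s.loc[g, "ribosomes"]),
            float(usable_o.loc[g, "ribosomes"]),
        )
        rows.append(
            {
                "gene_id": g,
                "occ_ratio": occ.ratio,
                "occ_p": occ.p_value,
                "occ_call": occ.call,
                "dens_ratio": dens.ratio,
                "dens_call": dens.call,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "occ_ratio", "occ_p", "occ_call", "dens_ratio",
            "dens_call",
        ],
    ).set_index("gene_id")
    if fdr and len(table):
        reject, p_adj = _benjamini_hochberg(table["occ_p"].to_numpy(), alpha)
        table["occ_p_adj"] = p_adj
        means_dir = table["occ_ratio"] > 1
        table["occ_call"] = np.where(
            reject, np.where(means_dir, HIGHER, LOWER), SIMILAR
        )
    table["reg_class"] = [
        classify(o, d) for o, d in zip(table["occ_call"], table["dens_call"])
    ]
    return ComparisonResults(
        table=table,
        excluded=pd.DataFrame(excluded, columns=["gene_id", "reason"]),
        alpha=alpha,
    )


def _benjamini_hochberg(p: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj
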