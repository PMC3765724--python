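"""From raw fraction arrays to per-gene loading proportions.

The chain mirrors the macroarray protocol: every array carries each gene in
duplicate plus empty spots; spot values are background-subtracted and the
duplicates averaged; an expression cutoff (mean of the empty spots plus one
standard deviation) selects genes detected on at least one array of a series;
because every array is hybridised with the same RNA mass (5 ug) regardless of
how much RNA the fraction actually contained, intensities are corrected back
to the fraction's total RNA quantity before the per-gene proportions across
fractions are formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import EMPTY_GENE_ID, FractionIntensityTable

__all__ = [
    "background_subtract_and_average",
    "compute_cutoff",
    "select_expressed",
    "proportions",
    "mrna_share",
    "normalize_series",
    "normalize_experiment",
    "NormalizedExperiment",
]


def background_subtract_and_average(table: FractionIntensityTable) -> pd.Series:
    """Per-gene mean of the duplicate spot intensities after background subtraction.

    Negative background-corrected values are clipped at 0. A gene with a
    number of spots other than two is flagged with a warning and reported as
    missing (NaN).
    """
    spots = table.spots
    genes = spots[spots["gene_id"] != EMPTY_GENE_ID]
    corrected = (genes["intensity"] - genes["background"]).clip(lower=0.0)
    grouped = corrected.groupby(genes["gene_id"], sort=True)
    values = grouped.mean()
    counts = grouped.size()
    bad = counts[counts != 2]
    if len(bad):
        warnings.warn(
            f"{len(bad)} gene(s) without exactly 2 spots on "
            f"{table.condition}/{table.fraction_id} series {table.series_id}; "
            "values set to missing",
            stacklevel=2,
        )
        values.loc[bad.index] = np.nan
    values.name = "value"
    return values


def compute_cutoff(empty_intensities: Sequence[float] | np.ndarray) -> float:
    """Expression cutoff of one array: empty-spot mean plus one sample SD."""
    empty = np.asarray(empty_intensities, dtype=float)
    if empty.size < 3:
        raise ValueError("need at least 3 empty spots to compute a cutoff")
    return float(empty.mean() + empty.std(ddof=1))


def select_expressed(
    values: pd.DataFrame, cutoffs: Mapping[str, float] | pd.Series
) -> pd.Index:
    """Genes above the cutoff on at least one array of the series.

    ``values``: genes x arrays (S0..Sk) background-corrected means;
    ``cutoffs``: per-array cutoff. Union semantics: one detection anywhere in
    the series keeps the gene.
    """
    cutoffs = pd.Series(cutoffs)
    missing = [c for c in values.columns if c not in cutoffs.index]
    if missing:
        raise ValueError(f"no cutoff for arrays: {missing}")
    above = values.gt(cutoffs[values.columns], axis=1)
    return values.index[above.any(axis=1)]


def proportions(
    values: pd.DataFrame,
    fraction_rna_totals: Mapping[str, float] | pd.Series,
    loaded_mass: float | Mapping[str, float] = 5.0,
) -> pd.DataFrame:
    """Total-RNA-corrected per-gene proportions across the fractions S1..Sk.

    ``values``: genes x fractions intensity means from arrays each loaded
    with ``loaded_mass`` of RNA. Multiplying by ``rna_total_f / loaded_mass_f``
    undoes the equal-mass loading and recovers quantities proportional to the
    per-fraction mRNA mass of each gene, which are then row-normalized.
    Genes with an all-zero (or any missing) row get NaN proportions.
    """
    totals = pd.Series(fraction_rna_totals).astype(float)
    if isinstance(loaded_mass, (int, float)):
        loaded = pd.Series(loaded_mass, index=values.columns, dtype=float)
    else:
        loaded = pd.Series(loaded_mass).astype(float)
    corrected = values.mul(totals[values.columns] / loaded[values.columns], axis=1)
    row_sum = corrected.sum(axis=1)
    out = corrected.div(row_sum, axis=0)
    bad = (row_sum <= 0) | corrected.isna().any(axis=1)
    out[bad] = np.nan
    return out


def mrna_share(
    spot_sum_stress: float,
    total_rna_stress: float,
    spot_sum_optimal: float,
    total_rna_optimal: float,
) -> float:
    """Stress/optimal ratio of mRNA as a proportion of total RNA.

    The mRNA proportion per condition is estimated as the summed intensity of
    all spots of the unfractionated (S0) arrays over the condition's total
    RNA content (g/100 g cells).
    """
    if total_rna_stress <= 0 or total_rna_optimal <= 0 or spot_sum_optimal == 0:
        raise ValueError("totals and the optimal spot sum must be non-zero")
    return (spot_sum_stress / total_rna_stress) / (
        spot_sum_optimal / total_rna_optimal
    )


def _equalize(values_by_array: dict[str, pd.Series]) -> dict[str, pd.Series]:
    """Scale each array to the series-mean total gene signal (gain correction)."""
    totals = {a: v.sum() for a, v in values_by_array.items()}
    target = np.mean([t for t in totals.values() if t > 0])
    return {
        a: v * (target / totals[a]) if totals[a] > 0 else v
        for a, v in values_by_array.items()
    }


def normalize_series(
    tables: Sequence[FractionIntensityTable],
    equalize_arrays: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Normalize one replicate series (arrays S0..Sk of one condition).

    Returns (proportions genes x S1..Sk, qc dict). Genes kept: above the
    cutoff on at least one array of the series and with a complete,
    non-degenerate fraction profile. ``equalize_arrays`` optionally rescales
    every array to the same total gene signal first (per-array gain
    correction for drifting exposures; off by default, see docs).
    """
    by_frac = {t.fraction_id: t for t in tables}
    frac_ids = sorted(
        (f for f in by_frac if f != "S0"), key=lambda s: int(s[1:])
    )
    if not frac_ids:
        raise ValueError("no fraction arrays (S1..Sk) in series")
    values = {f: background_subtract_and_average(by_frac[f]) for f in by_frac}
    if equalize_arrays:
        values = _equalize(values)
    cutoffs = {
        f: compute_cutoff(
            np.clip(
                by_frac[f].empty_intensities()
                - by_frac[f].spots["background"].iloc[0],
                0.0,
                None,
            )
        )
        for f in by_frac
    }
    value_df = pd.DataFrame(values)
    expressed = select_expressed(value_df, cutoffs)

    rna_totals = {f: by_frac[f].rna_total for f in frac_ids}
    loaded = {f: by_frac[f].rna_mass for f in frac_ids}
    props = proportions(
        value_df.loc[expressed, frac_ids], rna_totals, loaded
    )
    n_degenerate = int(props.isna().any(axis=1).sum())
    props = props.dropna()
    qc = {
        "condition": tables[0].condition,
        "series_id": tables[0].series_id,
        "n_genes": int(len(value_df)),
        "n_expressed": int(len(expressed)),
        "n_retained": int(len(props)),
        "n_degenerate": n_degenerate,
        "cutoffs": {f: float(c) for f, c in cutoffs.items()},
    }
    return props, qc


@dataclass
class NormalizedExperiment:
    """Long-format proportions plus per-series QC for a whole experiment.

    ``profiles`` columns: gene_id, condition, series, fraction, proportion.
    """

    profiles: pd.DataFrame
    qc: list[dict]

    def condition_profiles(self, condition: str) -> pd.DataFrame:
        return self.profiles[self.profiles["condition"] == condition]

    def s0_spot_sum(
        self, tables: Iterable[FractionIntensityTable], condition: str
    ) -> float:
        """Mean summed background-corrected S0 signal for one condition."""
        sums = [
            background_subtract_and_average(t).sum()
            for t in tables
            if t.condition == condition and t.fraction_id == "S0"
        ]
        if not sums:
            raise ValueError(f"no S0 arrays for condition {condition!r}")
        return float(np.mean(sums))

    def write(self, path) -> None:
        self.profiles.to_csv(path, sep="\t", index=False)


def normalize_experiment(
    tables: Sequence[FractionIntensityTable],
    equalize_arrays: bool = False,
) -> NormalizedExperiment:
    """Normalize every (condition, series) group of arrays."""
    groups: dict[tuple[str, int], list[FractionIntensityTable]] = {}
    for t in tables:
        groups.setdefault((t.condition, t.series_id), []).append(t)
    rows = []
    qcs = []
    for (cond, series), group in sorted(groups.items()):
        props, qc = normalize_series(group, equalize_arrays=equalize_arrays)
        qcs.append(qc)
        long = props.stack().rename("proportion").reset_index()
        long.columns = ["gene_id", "fraction", "proportion"]
        long.insert(1, "condition", cond)
        long.insert(2, "series", series)
        rows.append(long)
    return NormalizedExperiment(
        profiles=pd.concat(rows, ignore_index=True), qc=qcs
    )
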