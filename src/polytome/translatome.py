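"""Per-gene translatome variables: ribosome occupancy, peak fraction, density.

Two variables characterise the translational status of each mRNA species:

* **ribosome occupancy** — the fraction of the gene's mRNA molecules engaged
  in translation, i.e. the summed proportions in the monosome and polysome
  fractions S2..Sk (S1 holds free mRNA or mRNA with an incomplete ribosome);
* **ribosome density** — the number of ribosomes bound per 100 nt of coding
  sequence, read off the gene's *peak fraction* (the fraction holding its
  highest translated-mRNA proportion) through the fraction -> ribosome-count
  calibration of the gradient.

The peak fraction is called with a bootstrap on residuals: residuals of each
replicate series from the across-series mean profile are resampled with
replacement (within fraction, across series), added back to the mean, and the
argmax fraction recorded. If the modal argmax frequency reaches the
confidence level the call is a single fraction; otherwise the definition is
widened to two (or more) adjacent fractions until the merged set's frequency
does. Genes whose call widens beyond one fraction have no defined density;
densities above the sterically maximal one (a ribosome footprint every 30 nt,
3.33 ribosomes/100 nt) are flagged aberrant.

:class:`TranslatomeModel` bundles these estimators statsmodels-style: build
it from normalized fraction profiles of one condition and ``fit()`` to get a
:class:`TranslatomeResults` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import ConditionParams, GeneCatalog

__all__ = [
    "PeakCall",
    "occupancy",
    "bootstrap_peak",
    "density",
    "max_density",
    "fraction_engaged_from_trace",
    "TranslatomeModel",
    "TranslatomeResults",
]


@dataclass(frozen=True)
class PeakCall:
    """Bootstrap peak-fraction call for one gene.

    ``fractions`` is the ordered tuple of adjacent fraction labels the call
    covers (a single label when the bootstrap is confident);
    ``modal_frequency`` is the bootstrap frequency of the returned set.
    """

    fractions: tuple[str, ...]
    modal_frequency: float
    n_iterations: int
    seed: int | None = None

    @property
    def widened(self) -> bool:
        return len(self.fractions) > 1

    @property
    def label(self) -> str:
        return "+".join(self.fractions)


def occupancy(profiles: pd.DataFrame | np.ndarray) -> tuple[float, np.ndarray]:
    """Mean ribosome occupancy and the per-series values.

    ``profiles``: series x fractions (S1..Sk) proportion matrix. Occupancy of
    one series is the summed proportion over the translated fractions S2..Sk;
    the reported value is the arithmetic mean over series.
    """
    arr = np.asarray(profiles, dtype=float)
    per_series = arr[:, 1:].sum(axis=1)
    return float(per_series.mean()), per_series


def _call_from_frequencies(
    freq: np.ndarray, fraction_ids: Sequence[str], conf: float
) -> tuple[tuple[int, ...], float]:
    """Widen the peak definition until its bootstrap frequency reaches conf.

    Start from the most frequent fraction (ties to the heavier fraction);
    repeatedly annex the adjacent fraction with the higher frequency (ties to
    the higher index) until the set's cumulative frequency >= conf.
    """
    order = np.lexsort((np.arange(len(freq)), freq))  # ties -> higher index
    start = int(order[-1])
    members = [start]
    while freq[members].sum() < conf and len(members) < len(freq):
        lo, hi = min(members) - 1, max(members) + 1
        candidates = [i for i in (lo, hi) if 0 <= i < len(freq)]
        best = max(candidates, key=lambda i: (freq[i], i))
        members.append(best)
    members = sorted(members)
    return tuple(members), float(freq[members].sum())


def bootstrap_peak(
    profiles: pd.DataFrame | np.ndarray,
    fraction_ids: Sequence[str] | None = None,
    n_iter: int = 10000,
    conf: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> PeakCall:
    """Call the peak fraction of one gene from its translated-fraction profiles.

    ``profiles``: series x translated-fractions (S2..Sk) proportion matrix
    (at least two series). Residuals from the across-series mean profile are
    resampled with replacement within each fraction, added to the mean,
    clipped at 0, and the argmax recorded, ``n_iter`` times.
    """
    arr = np.asarray(profiles, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 series to form residuals")
    n_series, n_frac = arr.shape
    if fraction_ids is None:
        fraction_ids = [f"S{i + 2}" for i in range(n_frac)]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mean = arr.mean(axis=0)
    residuals = arr - mean
    idx = rng.integers(0, n_series, size=(n_iter, n_frac))
    boot = np.clip(mean[None, :] + residuals[idx, np.arange(n_frac)], 0.0, None)
    argmax = boot.argmax(axis=1)
    freq = np.bincount(argmax, minlength=n_frac) / n_iter
    members, total = _call_from_frequencies(freq, fraction_ids, conf)
    return PeakCall(
        fractions=tuple(fraction_ids[i] for i in members),
        modal_frequency=total,
        n_iterations=n_iter,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )


def density(
    peak: PeakCall, condition: ConditionParams, cds_length: float
) -> tuple[float, float]:
    """(ribosomes, density per 100 nt) for a single-fraction peak call.

    Density is the mean ribosome count of the peak fraction normalized to the
    coding-sequence length: ribosomes / cds_length x 100. Widened calls have
    no defined peak ribosome count and raise ``ValueError``.
    """
    if peak.widened:
        raise ValueError(
            f"peak widened to {peak.label}; density requires a single fraction"
        )
    if cds_length <= 0:
        raise ValueError("cds_length must be positive")
    frac = peak.fractions[0]
    ribosomes = float(condition.ribosome_means[condition.fraction_ids.index(frac)])
    return ribosomes, ribosomes / cds_length * 100.0


def max_density(footprint_nt: int = 30) -> float:
    """Maximal sterically possible ribosome density, ribosomes per 100 nt.

    One ribosome footprint covers ``footprint_nt`` nucleotides, so at most
    100/footprint ribosomes fit per 100 nt (3.33 at the default 30-nt
    footprint). Rounded to 2 decimals.
    """
    if footprint_nt <= 0:
        raise ValueError("footprint_nt must be positive")
    return round(100.0 / footprint_nt, 2)


def fraction_engaged_from_trace(
    trace: pd.DataFrame,
    boundaries: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0, 4.5),
        (4.5, np.inf),
    ),
) -> float:
    """Percentage of ribosomal signal engaged in translation, by area.

    Trapezoidal integration of the absorbance trace over the free-subunit
    region and the engaged (monosome + polysome) region; returns
    100 x engaged / (free + engaged).
    """
    (f_lo, f_hi), (e_lo, e_hi) = boundaries
    if f_lo < e_hi and e_lo < f_hi:
        raise ValueError("free and engaged regions must not overlap")
    t = trace["time_min"].to_numpy()
    a = trace["absorbance"].to_numpy()

    def area(lo: float, hi: float) -> float:
        m = (t >= lo) & (t <= hi)
        return float(np.trapezoid(a[m], t[m])) if m.sum() > 1 else 0.0

    free = area(f_lo, f_hi)
    engaged = area(e_lo, min(e_hi, t[-1]))
    if free + engaged <= 0:
        raise ValueError("trace has zero area over the integration regions")
    return 100.0 * engaged / (free + engaged)


class TranslatomeModel:
    """Per-condition translatome estimator.

    Parameters
    ----------
    profiles : DataFrame
        Long-format normalized proportions with columns ``gene_id``,
        ``series``, ``fraction``, ``proportion`` for a single condition.
    condition : ConditionParams
        Gradient geometry: fraction ids and the fraction -> ribosome map.
    cds_lengths : Series or GeneCatalog
        Coding-sequence length (nt) per gene, for the density calculation.
    min_series : int
        Minimum replicate series a gene needs to be summarized (default 3).
    """

    def __init__(
        self,
        profiles: pd.DataFrame,
        condition: ConditionParams,
        cds_lengths: pd.Series | GeneCatalog,
        min_series: int = 3,
    ) -> None:
        if isinstance(cds_lengths, GeneCatalog):
            cds_lengths = cds_lengths.cds_lengths
        self.condition = condition
        self.cds_lengths = cds_lengths
        self.min_series = min_series
        wide = profiles.pivot_table(
            index=["gene_id", "series"],
            columns="fraction",
            values="proportion",
            sort=False,
        )
        order = [f for f in condition.fraction_ids if f in wide.columns]
        self.wide = wide[order].sort_index()

    @classmethod
    def from_experiment(
        cls,
        experiment,
        condition: ConditionParams,
        cds_lengths: pd.Series | GeneCatalog,
        min_series: int = 3,
    ) -> "TranslatomeModel":
        return cls(
            experiment.condition_profiles(condition.name),
            condition,
            cds_lengths,
            min_series,
        )

    def fit(
        self, n_iter: int = 10000, conf: float = 0.95, seed: int = 0,
        chunk_size: int = 512,
    ) -> "TranslatomeResults":
        """Estimate occupancy and call peaks for every eligible gene.

        The bootstrap is vectorised over genes in chunks; genes are grouped
        by their number of complete series so residual matrices stack.
        """
        cond = self.condition
        frac_ids = cond.fraction_ids
        n_frac = cond.n_fractions
        complete = self.wide.dropna()
        counts = complete.groupby(level="gene_id").size()
        eligible = counts[counts >= max(self.min_series, 2)].index

        rng = np.random.default_rng(seed)
        rows = []
        occ_rows = {}
        limit = max_density()
        for n_series, genes in (
            counts.loc[eligible].groupby(counts.loc[eligible]).groups.items()
        ):
            genes = list(genes)
            block = complete.loc[genes]
            arr = block.to_numpy().reshape(len(genes), n_series, n_frac)
            occ_series = arr[:, :, 1:].sum(axis=2)
            trans = arr[:, :, 1:]  # translated fractions S2..Sk
            mean = trans.mean(axis=1)
            residuals = trans - mean[:, None, :]
            nf = n_frac - 1
            for start in range(0, len(genes), chunk_size):
                sl = slice(start, start + chunk_size)
                sub_res = residuals[sl]
                sub_mean = mean[sl]
                g = sub_res.shape[0]
                idx = rng.integers(0, n_series, size=(g, n_iter, nf))
                boot = np.clip(
                    sub_mean[:, None, :]
                    + sub_res[
                        np.arange(g)[:, None, None],
                        idx,
                        np.arange(nf)[None, None, :],
                    ],
                    0.0,
                    None,
                )
                argmax = boot.argmax(axis=2)
                for gi, gene in enumerate(genes[start : start + chunk_size]):
                    freq = np.bincount(argmax[gi], minlength=nf) / n_iter
                    members, total = _call_from_frequencies(freq, frac_ids[1:], conf)
                    call = PeakCall(
                        fractions=tuple(frac_ids[1:][m] for m in members),
                        modal_frequency=total,
                        n_iterations=n_iter,
                        seed=seed,
                    )
                    i_global = start + gi
                    occ_mean = float(occ_series[i_global].mean())
                    occ_rows[gene] = occ_series[i_global]
                    cds = self.cds_lengths.get(gene, np.nan)
                    if call.widened or not np.isfinite(cds):
                        ribos = dens = np.nan
                        reason = (
                            "widened_peak" if call.widened else "no_cds_length"
                        )
                    else:
                        ribos, dens = density(call, cond, float(cds))
                        reason = ""
                    rows.append(
                        {
                            "gene_id": gene,
                            "condition": cond.name,
                            "n_series": int(n_series),
                            "occupancy": occ_mean,
                            "peak_fraction": call.label,
                            "modal_frequency": call.modal_frequency,
                            "widened": call.widened,
                            "ribosomes": ribos,
                            "density": dens,
                            "aberrant": bool(np.isfinite(dens) and dens > limit),
                            "excluded_reason": reason,
                        }
                    )
        table = (
            pd.DataFrame(rows).set_index("gene_id").sort_index()
            if rows
            else pd.DataFrame(
                columns=[
                    "condition", "n_series", "occupancy", "peak_fraction",
                    "modal_frequency", "widened", "ribosomes", "density",
                    "aberrant", "excluded_reason",
                ]
            )
        )
        return TranslatomeResults(
            table=table,
            occupancy_series={g: np.asarray(v) for g, v in occ_rows.items()},
            condition=cond,
            n_iter=n_iter,
            conf=conf,
            seed=seed,
            max_density_value=limit,
        )


@dataclass
class TranslatomeResults:
    """Fitted per-gene translatome table for one condition.

    ``table`` (indexed by gene_id): occupancy, peak call, ribosomes, density,
    aberrant flag. ``occupancy_series`` maps gene_id to the per-series
    occupancy values used for the two-condition test.
    """

    table: pd.DataFrame
    occupancy_series: dict[str, np.ndarray]
    condition: ConditionParams
    n_iter: int
    conf: float
    seed: int
    max_density_value: float

    def single_fraction(self) -> pd.DataFrame:
        return self.table[~self.table["widened"]]

    def retained(self) -> pd.DataFrame:
        """Single-fraction, non-aberrant genes (the density-analysis set)."""
        t = self.table
        return t[~t["widened"] & ~t["aberrant"]]

    def funnel(self) -> dict[str, int]:
        t = self.table
        return {
            "peak_called": int(len(t)),
            "single_fraction": int((~t["widened"]).sum()),
            "non_aberrant": int((~t["widened"] & ~t["aberrant"]).sum()),
        }

    def summary(self) -> str:
        t = self.table
        f = self.funnel()
        lines = [
            f"Translatome results: condition {self.condition.name!r}",
            f"  bootstrap: {self.n_iter} iterations, confidence {self.conf:.2f}, "
            f"seed {self.seed}",
            f"  genes peak-called:      {f['peak_called']}",
            f"  single-fraction peaks:  {f['single_fraction']}",
            f"  non-aberrant densities: {f['non_aberrant']} "
            f"(ceiling {self.max_density_value} ribosomes/100 nt)",
            f"  median occupancy:       {t['occupancy'].median():.3f}",
        ]
        r = self.retained()
        if len(r):
            lines.append(
                f"  median density:         {r['density'].median():.3f} "
                "ribosomes/100 nt"
            )
        return "\n".join(lines)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    def plot_density_histogram(self, ax=None, bins: int = 20):
        """Histogram of non-aberrant ribosome densities."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.retained()["density"].dropna(), bins=bins)
        ax.set_xlabel("ribosome density (ribosomes / 100 nt)")
        ax.set_ylabel("genes")
        ax.set_title(f"Ribosome density, {self.condition.name}")
        return ax
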