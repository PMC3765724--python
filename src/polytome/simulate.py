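"""Synthetic polysome-profiling experiments with known ground truth.

This module emulates the design of a nylon-macroarray translatome study in a
bacterium: mRNA-ribosome complexes from two growth conditions (optimal growth
and amino-acid starvation) are separated on a sucrose gradient, the gradient
is pooled into fractions (7 under optimal growth, 5 under stress), and every
fraction plus an unfractionated reference aliquot (S0) is hybridised to an
array carrying each gene in duplicate. Five independent cultures give five
replicate series of arrays per condition.

The generator plants, per gene and condition, a "loading distribution" — the
probability that one of the gene's mRNA molecules sediments in each fraction —
from which the observable quantities follow:

* ribosome occupancy  = 1 - loading[S1] (S1 holds free mRNA / incomplete
  ribosomes);
* the peak fraction   = the argmax of the loading over the translated
  fractions S2..Sk;
* ribosome density    = ribosomes in the peak fraction / CDS length x 100.

Each gene carries a regulation archetype describing how stress changes its
translation relative to optimal growth:

``up``            peak moves to a heavier fraction (monosome -> polysome);
``down``          peak moves lighter, occupancy essentially unchanged;
``antagonistic``  peak moves lighter but occupancy increases;
``unregulated``   neither measure changes (the monosome-resident case).

Spot intensities are mRNA mass shares of the fraction's total RNA times the
loaded mass, degraded by multiplicative log-normal noise and an additive
array background; empty spots are drawn from the background distribution so
that the downstream cutoff rule (empty mean + 1 SD) behaves realistically.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARCHETYPES",
    "DEFAULT_ARCHETYPE_PROBS",
    "ConditionParams",
    "GeneCatalog",
    "NoiseModel",
    "SyntheticTruth",
    "FractionIntensityTable",
    "stress_condition",
    "optimal_condition",
    "generate_catalog",
    "generate_truth",
    "simulate_arrays",
    "simulate_trace",
    "generate_ratio_archetypes",
]

ARCHETYPES = ("up", "down", "antagonistic", "unregulated")

#: Default archetype frequencies: the regulation-class sizes observed for the
#: 816-gene set analysed in both conditions (39 up, 420 down, 356 antagonistic,
#: 1 unregulated).
DEFAULT_ARCHETYPE_PROBS: dict[str, float] = {
    "up": 39 / 816,
    "down": 420 / 816,
    "antagonistic": 356 / 816,
    "unregulated": 1 / 816,
}

EMPTY_GENE_ID = "EMPTY"

_STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOP_CODONS and a + b + c != "ATG"
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionParams:
    """Growth-condition parameters of one translatome experiment.

    Parameters
    ----------
    name : str
        Condition label (e.g. ``"stress"``, ``"optimal"``).
    growth_rate : float
        Specific growth rate mu in h^-1; doubles as the mRNA dilution rate
        constant.
    n_fractions : int
        Number of pooled gradient fractions S1..Sk.
    total_rna : float
        Total cellular RNA content, g per 100 g cells.
    fraction_ribosome_map : tuple of (mean, low, high)
        Ribosomes per transcript in each fraction: mean and the range it was
        estimated over. Fraction S1 maps to 0 (free mRNA or an incomplete
        ribosome).
    """

    name: str
    growth_rate: float
    n_fractions: int
    total_rna: float
    fraction_ribosome_map: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        if len(self.fraction_ribosome_map) != self.n_fractions:
            raise ValueError(
                "fraction_ribosome_map must have one entry per fraction"
            )
        means = [m for m, _, _ in self.fraction_ribosome_map]
        if means[0] != 0:
            raise ValueError("fraction S1 must map to 0 ribosomes")
        if any(b < a for a, b in zip(means, means[1:])):
            raise ValueError("ribosome means must be monotone non-decreasing")

    @property
    def ribosome_means(self) -> np.ndarray:
        return np.array([m for m, _, _ in self.fraction_ribosome_map])

    @property
    def fraction_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_fractions)]

    @property
    def translated_fractions(self) -> list[str]:
        """Fractions holding mRNA engaged in translation (S2..Sk)."""
        return self.fraction_ids[1:]


def stress_condition() -> ConditionParams:
    """Amino-acid (isoleucine) starvation defaults.

    Residual growth at 0.05 h^-1, total RNA 5.43 g/100 g cells, five pooled
    fractions with ribosome means 0 (S1, free/incomplete), 1 (S2, monosome),
    2.1, 3.9 and 8.4 (polysomes; ranges 1.4-2.9, 2.9-5.1, 5.1-15.1).
    """
    return ConditionParams(
        name="stress",
        growth_rate=0.05,
        n_fractions=5,
        total_rna=5.43,
        fraction_ribosome_map=(
            (0.0, 0.0, 0.0),
            (1.0, 1.0, 1.0),
            (2.1, 1.4, 2.9),
            (3.9, 2.9, 5.1),
            (8.4, 5.1, 15.1),
        ),
    )


def optimal_condition() -> ConditionParams:
    """Optimal-growth defaults: 0.88 h^-1, 9.01 g RNA/100 g, seven fractions.

    The per-fraction ribosome calibration under optimal growth is not printed
    in full anywhere; the map below is a placeholder anchored to the known
    constraints (monosome fraction = 1 ribosome, heaviest fraction averaging
    14 with a maximum of 18) and should be replaced by a measured calibration
    when available.
    """
    return ConditionParams(
        name="optimal",
        growth_rate=0.88,
        n_fractions=7,
        total_rna=9.01,
        fraction_ribosome_map=(
            (0.0, 0.0, 0.0),
            (1.0, 1.0, 1.0),
            (2.0, 1.4, 2.9),
            (4.0, 2.9, 5.1),
            (7.0, 5.1, 9.0),
            (10.0, 9.0, 12.0),
            (14.0, 12.0, 18.0),
        ),
    )


@dataclass
class GeneCatalog:
    """Annotated gene set of the array: id, CDS length, functional category.

    ``table`` columns: ``gene_id``, ``cds_length`` (nt), ``category`` and
    optionally ``cds_sequence`` (a valid CDS of that length).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")
        if ((t["cds_length"] < 90) | (t["cds_length"] > 6000)).any():
            raise ValueError("cds_length must lie in [90, 6000] nt")
        if "cds_sequence" in t.columns and t["cds_sequence"].notna().any():
            lens = t["cds_sequence"].dropna().str.len()
            if not (lens == t.loc[lens.index, "cds_length"]).all():
                raise ValueError("sequence length must equal cds_length")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.table["gene_id"])

    @property
    def cds_lengths(self) -> pd.Series:
        return self.table.set_index("gene_id")["cds_length"]

    @property
    def categories(self) -> pd.Series:
        return self.table.set_index("gene_id")["category"]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneCatalog":
        return cls(pd.read_csv(path, sep="\t"))

    def to_fasta(self, path: str | Path) -> None:
        """Write CDS sequences (where present) as FASTA via Biopython."""
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(row.cds_sequence), id=row.gene_id, description="")
            for row in self.table.itertuples()
            if isinstance(getattr(row, "cds_sequence", None), str)
        ]
        seqio_write(records, str(path), "fasta")

    def sequences(self) -> dict[str, str]:
        if "cds_sequence" not in self.table.columns:
            return {}
        sub = self.table.dropna(subset=["cds_sequence"])
        return dict(zip(sub["gene_id"], sub["cds_sequence"]))


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters of the simulated arrays.

    ``lognormal_sigma`` is the SD of the multiplicative log-normal spot noise;
    background is additive per spot; empty spots are drawn from the
    background distribution (``empty_spot_*`` default to the background
    parameters) so the expression cutoff behaves as on real arrays.
    """

    lognormal_sigma: float = 0.2
    background_mean: float = 2.0
    background_sd: float = 0.5
    empty_spot_mean: float = 2.0
    empty_spot_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")
        if self.background_sd < 0 or self.empty_spot_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseModel":
        """Zero-noise limit: exact intensities, constant background."""
        return cls(
            lognormal_sigma=0.0,
            background_mean=2.0,
            background_sd=0.0,
            empty_spot_mean=2.0,
            empty_spot_sd=0.0,
            seed=seed,
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth of a two-condition synthetic experiment.

    Attributes
    ----------
    catalog : GeneCatalog
    conditions : dict
        Condition name -> :class:`ConditionParams`, in (reference, stress)
        order as passed to :func:`generate_truth`.
    genes : DataFrame
        One row per gene: ``gene_id``, ``archetype``, ``expressed``,
        ``gene_copies``.
    per_condition : DataFrame
        One row per gene x condition: ``gene_id``, ``condition``,
        ``half_life_min``, ``mrna_level``, ``occupancy_true``,
        ``peak_index`` (0-based fraction index), ``peak_fraction`` (label).
    loading : dict
        Condition name -> (n_genes, n_fractions) array of loading
        distributions; rows sum to 1, row order follows the catalog.
    """

    catalog: GeneCatalog
    conditions: dict[str, ConditionParams]
    genes: pd.DataFrame
    per_condition: pd.DataFrame
    loading: dict[str, np.ndarray]

    def loading_frame(self, condition: str) -> pd.DataFrame:
        cond = self.conditions[condition]
        return pd.DataFrame(
            self.loading[condition],
            index=self.catalog.gene_ids,
            columns=cond.fraction_ids,
        )

    def condition_table(self, condition: str) -> pd.DataFrame:
        sub = self.per_condition[self.per_condition["condition"] == condition]
        return sub.set_index("gene_id")

    def expressed_ids(self) -> pd.Index:
        return pd.Index(self.genes.loc[self.genes["expressed"], "gene_id"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.catalog.to_tsv(outdir / "catalog.tsv")
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.per_condition.to_csv(
            outdir / "truth_per_condition.tsv", sep="\t", index=False
        )
        for name in self.conditions:
            self.loading_frame(name).to_csv(
                outdir / f"loading_{name}.tsv", sep="\t"
            )


@dataclass
class FractionIntensityTable:
    """Raw spot intensities of one array (one fraction of one series).

    ``spots`` columns: ``spot_id``, ``gene_id`` (or ``EMPTY``), ``intensity``,
    ``background``. Every gene occurs twice among the non-empty spots.
    ``rna_mass`` is the RNA mass loaded on the array (equal for every array;
    5 ug in the emulated protocol); ``rna_total`` is the total RNA recovered
    in the fraction (arbitrary units, NaN for the unfractionated S0 aliquot)
    and drives the total-RNA correction during normalization.
    """

    condition: str
    series_id: int
    fraction_id: str
    spots: pd.DataFrame
    rna_mass: float = 5.0
    rna_total: float = float("nan")

    def empty_intensities(self) -> np.ndarray:
        s = self.spots
        return s.loc[s["gene_id"] == EMPTY_GENE_ID, "intensity"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# condition\t{self.condition}\n")
            fh.write(f"# series_id\t{self.series_id}\n")
            fh.write(f"# fraction_id\t{self.fraction_id}\n")
            fh.write(f"# rna_mass\t{self.rna_mass!r}\n")
            fh.write(f"# rna_total\t{self.rna_total!r}\n")
            self.spots.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FractionIntensityTable":
        meta: dict[str, str] = {}
        lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("# "):
                    key, _, val = line[2:].rstrip("\n").partition("\t")
                    meta[key] = val
                else:
                    lines.append(line)
        spots = pd.read_csv(io.StringIO("".join(lines)), sep="\t")
        return cls(
            condition=meta["condition"],
            series_id=int(meta["series_id"]),
            fraction_id=meta["fraction_id"],
            spots=spots,
            rna_mass=float(meta["rna_mass"]),
            rna_total=float(meta["rna_total"]),
        )

    def filename(self) -> str:
        return f"{self.condition}_series{self.series_id}_{self.fraction_id}.tsv"


def write_tables(
    tables: Sequence[FractionIntensityTable], outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for t in tables:
        t.to_tsv(outdir / t.filename())


def read_tables(indir: str | Path) -> list[FractionIntensityTable]:
    paths = sorted(Path(indir).glob("*_series*_S*.tsv"))
    return [FractionIntensityTable.from_tsv(p) for p in paths]


# ---------------------------------------------------------------------------
# Catalog generation
# ---------------------------------------------------------------------------

DEFAULT_CATEGORY_WEIGHTS: dict[str, float] = {
    "translation": 0.09,
    "transcription": 0.04,
    "amino acid biosynthesis": 0.06,
    "base metabolism": 0.05,
    "fatty acid and phospholipid metabolism": 0.03,
    "carbohydrate metabolism": 0.08,
    "transport": 0.10,
    "cell envelope": 0.07,
    "energy metabolism": 0.07,
    "prophage": 0.06,
    "regulatory functions": 0.04,
    "replication": 0.04,
    "other": 0.12,
    "unknown": 0.15,
}


def generate_catalog(
    n_genes: int,
    category_weights: Mapping[str, float] | None = None,
    seed: int = 0,
    with_sequences: bool = True,
    median_cds_length: float = 960.0,
) -> GeneCatalog:
    """Generate a gene catalog of ``n_genes`` unique genes.

    CDS lengths are log-normal around ``median_cds_length`` (a typical
    bacterial CDS is just under 1 kb), clipped to [90, 6000] nt and rounded to
    whole codons. Categories are drawn from ``category_weights``. When
    ``with_sequences``, each gene gets a syntactically valid CDS: ATG start,
    random sense codons, one stop codon.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    weights = dict(category_weights or DEFAULT_CATEGORY_WEIGHTS)
    names = list(weights)
    probs = np.array([weights[n] for n in names], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("category weights must be non-negative, not all zero")
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    gene_ids = [f"llg{i + 1:0{width}d}" for i in range(n_genes)]
    lengths = rng.lognormal(mean=np.log(median_cds_length), sigma=0.5, size=n_genes)
    lengths = np.clip(lengths, 90, 6000)
    lengths = (np.round(lengths / 3).astype(int) * 3).clip(90, 6000)
    categories = rng.choice(names, size=n_genes, p=probs)

    table = pd.DataFrame(
        {"gene_id": gene_ids, "cds_length": lengths, "category": categories}
    )
    if with_sequences:
        sense = np.array(_SENSE_CODONS)
        stops = np.array(_STOP_CODONS)
        seqs = []
        for L in lengths:
            n_codon = L // 3
            inner = sense[rng.integers(0, len(sense), size=n_codon - 2)]
            stop = stops[rng.integers(0, len(stops))]
            seqs.append("ATG" + "".join(inner) + stop)
        table["cds_sequence"] = seqs
    return GeneCatalog(table)


# ---------------------------------------------------------------------------
# Ground-truth generation
# ---------------------------------------------------------------------------


def _unimodal_loading(
    peak_index: np.ndarray,
    occupancy: np.ndarray,
    n_fractions: int,
    width: float,
) -> np.ndarray:
    """Discretised truncated normal over the translated fractions.

    S1 receives ``1 - occupancy``; the translated fractions share
    ``occupancy`` with weights exp(-(j - peak)^2 / (2 width^2)).
    """
    j = np.arange(1, n_fractions)[None, :]
    w = np.exp(-((j - peak_index[:, None]) ** 2) / (2 * width**2))
    w = w / w.sum(axis=1, keepdims=True)
    loading = np.empty((len(peak_index), n_fractions))
    loading[:, 0] = 1.0 - occupancy
    loading[:, 1:] = occupancy[:, None] * w
    return loading


def generate_truth(
    catalog: GeneCatalog,
    cond_a: ConditionParams,
    cond_b: ConditionParams,
    archetype_probs: Mapping[str, float] | None = None,
    seed: int = 0,
    frac_silent: float = 0.12,
    loading_width: float = 0.7,
    occupancy_mean: float = 0.68,
    occupancy_sd: float = 0.06,
    half_life_mean_a: float = 6.2,
    half_life_mean_b: float = 12.1,
) -> SyntheticTruth:
    """Plant per-gene loading distributions and rate inputs for two conditions.

    ``cond_a`` is the reference (optimal growth) condition and ``cond_b`` the
    stress condition; archetypes describe the change from a to b. Half-life
    population means default to the printed condition averages (6.2 min under
    optimal growth, 12.1 min under starvation). A fraction ``frac_silent`` of
    genes is silent (mRNA level 0 in both conditions), emulating genes absent
    from the expressed set.
    """
    probs = dict(archetype_probs or DEFAULT_ARCHETYPE_PROBS)
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError("archetype probabilities must sum to 1")
    unknown = set(probs) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    n = len(catalog)
    names = list(probs)
    archetype = rng.choice(names, size=n, p=np.array([probs[a] for a in names]))
    expressed = rng.random(n) >= frac_silent

    means_a = cond_a.ribosome_means
    means_b = cond_b.ribosome_means
    ka, kb = cond_a.n_fractions, cond_b.n_fractions
    mono_a, mono_b = 1, 1  # 0-based index of the monosome fraction (S2)
    top_b = kb - 1

    # Reference-condition peaks: up/unregulated genes sit in the monosome;
    # the rest are heavily loaded (top two fractions, biased to the heaviest,
    # whose mean ribosome count matches the printed 14-ribosome average).
    peak_a = np.where(
        np.isin(archetype, ("up", "unregulated")),
        mono_a,
        rng.choice([ka - 2, ka - 1], size=n, p=[0.25, 0.75]),
    )

    # Stress-condition peaks chosen so the peak ribosome count obeys the
    # archetype: up -> heavier than a, down/antagonistic -> strictly lighter,
    # unregulated -> identical (monosome in both).
    peak_b = np.empty(n, dtype=int)
    lighter_choices = np.arange(1, kb)  # translated fractions of b
    for i in range(n):
        a = archetype[i]
        if a == "up":
            peak_b[i] = top_b
        elif a == "unregulated":
            peak_b[i] = mono_b
        else:  # down / antagonistic: strictly lower ribosome mean than in a
            admissible = lighter_choices[
                means_b[lighter_choices] < means_a[peak_a[i]]
            ]
            if admissible.size == 0:
                raise ValueError(
                    "no stress fraction lighter than the reference peak; "
                    "check the fraction_ribosome_map of the two conditions"
                )
            # geometric bias toward the heaviest admissible fraction
            w = 4.0 ** np.arange(admissible.size)
            peak_b[i] = rng.choice(admissible, p=w / w.sum())

    # Occupancies. "Similar" archetypes change by exactly 0 (inside the
    # |delta| <= 0.02 similarity band); regulated ones shift by 0.08-0.18.
    occ_a = np.clip(rng.normal(occupancy_mean, occupancy_sd, size=n), 0.30, 0.95)
    delta = np.zeros(n)
    shift = rng.uniform(0.08, 0.18, size=n)
    is_ant = archetype == "antagonistic"
    delta[is_ant] = shift[is_ant]
    is_up = archetype == "up"
    up_occ_higher = rng.random(n) < 19 / 39  # the rest change density only
    delta[is_up & up_occ_higher] = shift[is_up & up_occ_higher]
    is_down = archetype == "down"
    down_occ_lower = rng.random(n) < 6 / 420  # the rare both-lower genes
    delta[is_down & down_occ_lower] = -shift[is_down & down_occ_lower]
    occ_b = np.clip(occ_a + delta, 0.02, 0.97)

    loading_a = _unimodal_loading(peak_a, occ_a, ka, loading_width)
    loading_b = _unimodal_loading(peak_b, occ_b, kb, loading_width)

    # Rate inputs: half-lives log-normal with configured population means,
    # stress correlated with optimal; mRNA levels log-normal, lower in stress.
    s_hl, s_ratio, s_mrna, s_mshift = 0.35, 0.25, 0.8, 0.3
    hl_a = rng.lognormal(np.log(half_life_mean_a) - s_hl**2 / 2, s_hl, size=n)
    ratio = rng.lognormal(
        np.log(half_life_mean_b / half_life_mean_a) - s_ratio**2 / 2,
        s_ratio,
        size=n,
    )
    hl_b = hl_a * ratio
    mrna_a = rng.lognormal(0.0, s_mrna, size=n)
    mrna_b = mrna_a * rng.lognormal(np.log(0.6) - s_mshift**2 / 2, s_mshift, size=n)
    mrna_a = np.where(expressed, mrna_a, 0.0)
    mrna_b = np.where(expressed, mrna_b, 0.0)

    gene_ids = catalog.gene_ids.to_numpy()
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "archetype": archetype,
            "expressed": expressed,
            "gene_copies": 1,
        }
    )
    frames = []
    for cond, hl, mrna, occ, peak in (
        (cond_a, hl_a, mrna_a, occ_a, peak_a),
        (cond_b, hl_b, mrna_b, occ_b, peak_b),
    ):
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "condition": cond.name,
                    "half_life_min": hl,
                    "mrna_level": mrna,
                    "occupancy_true": occ,
                    "peak_index": peak,
                    "peak_fraction": [cond.fraction_ids[p] for p in peak],
                }
            )
        )
    per_condition = pd.concat(frames, ignore_index=True)
    return SyntheticTruth(
        catalog=catalog,
        conditions={cond_a.name: cond_a, cond_b.name: cond_b},
        genes=genes,
        per_condition=per_condition,
        loading={cond_a.name: loading_a, cond_b.name: loading_b},
    )


# ---------------------------------------------------------------------------
# Array simulation
# ---------------------------------------------------------------------------


def simulate_arrays(
    truth: SyntheticTruth,
    noise: NoiseModel,
    n_series: int,
    loaded_mass: float = 5.0,
    gain: float = 1e6,
    n_empty: int = 64,
    rrna_per_ribosome: float = 20.0,
) -> list[FractionIntensityTable]:
    """Simulate the full set of arrays: per condition, series and fraction.

    One table per (condition, series, fraction S1..Sk) plus an unfractionated
    reference table S0 per series. Spot intensity is the gene's mRNA mass
    share of the fraction's total RNA (mRNA plus a ribosome-proportional rRNA
    mass, ``rrna_per_ribosome`` units per bound ribosome) times the loaded
    mass and ``gain``, under multiplicative log-normal noise, plus an additive
    background. Each gene appears as two duplicate spots; ``n_empty`` empty
    spots per array are drawn from the background distribution.
    """
    if n_series < 2:
        raise ValueError("n_series must be >= 2")
    rng = np.random.default_rng(noise.seed)
    gene_ids = truth.catalog.gene_ids.to_numpy()
    n_genes = len(gene_ids)
    tables: list[FractionIntensityTable] = []

    for cond_name, cond in truth.conditions.items():
        ct = truth.condition_table(cond_name).loc[gene_ids]
        mrna = ct["mrna_level"].to_numpy()
        loading = truth.loading[cond_name]
        amounts = mrna[:, None] * loading  # (genes, fractions) mRNA mass
        mrna_f = amounts.sum(axis=0)
        rrna_f = (amounts * cond.ribosome_means[None, :]).sum(axis=0) * rrna_per_ribosome
        rna_total_f = mrna_f + rrna_f
        # S0: the unfractionated aliquot of the same lysate.
        amounts_s0 = mrna
        rna_total_s0 = rna_total_f.sum()

        fraction_plan = [("S0", amounts_s0, rna_total_s0)] + [
            (cond.fraction_ids[f], amounts[:, f], rna_total_f[f])
            for f in range(cond.n_fractions)
        ]
        for series in range(n_series):
            for frac_id, amount, rna_total in fraction_plan:
                base = amount / rna_total * loaded_mass * gain
                signal = np.repeat(base, 2)
                if noise.lognormal_sigma > 0:
                    signal = signal * rng.lognormal(
                        0.0, noise.lognormal_sigma, size=signal.size
                    )
                local_bg = np.clip(
                    rng.normal(noise.background_mean, noise.background_sd, signal.size),
                    0.0,
                    None,
                )
                intensity = signal + local_bg
                empty = np.clip(
                    rng.normal(noise.empty_spot_mean, noise.empty_spot_sd, n_empty),
                    0.0,
                    None,
                )
                spots = pd.DataFrame(
                    {
                        "spot_id": [
                            f"{g}_{d}" for g in gene_ids for d in (1, 2)
                        ]
                        + [f"{EMPTY_GENE_ID}_{i + 1}" for i in range(n_empty)],
                        "gene_id": np.concatenate(
                            [np.repeat(gene_ids, 2), [EMPTY_GENE_ID] * n_empty]
                        ),
                        "intensity": np.concatenate([intensity, empty]),
                        "background": noise.background_mean,
                    }
                )
                tables.append(
                    FractionIntensityTable(
                        condition=cond_name,
                        series_id=series + 1,
                        fraction_id=frac_id,
                        spots=spots,
                        rna_mass=loaded_mass,
                        rna_total=float(rna_total),
                    )
                )
    return tables


# ---------------------------------------------------------------------------
# Absorbance trace
# ---------------------------------------------------------------------------


def simulate_trace(
    truth: SyntheticTruth | None,
    cond: ConditionParams,
    engaged_target: float,
    t_max: float = 10.0,
    dt: float = 0.005,
    free_boundary: float = 4.5,
    peak_sigma: float = 0.15,
) -> pd.DataFrame:
    """Synthesize a UV-absorbance polysome profile as a sum of Gaussian peaks.

    A free-subunit peak elutes before ``free_boundary`` minutes; the monosome
    and polysome peaks elute after it, at evenly spaced centres. The area
    share of the engaged (monosome + polysome) peaks equals
    ``engaged_target`` to within 0.01. If ``truth`` is given, the relative
    weights of the engaged peaks follow the fraction mRNA masses; otherwise
    they are equal. Returns a DataFrame with ``time_min``, ``absorbance``.
    """
    if not 0 < engaged_target < 1:
        raise ValueError("engaged_target must lie strictly between 0 and 1")
    n_engaged = cond.n_fractions - 1
    if truth is not None:
        ct = truth.condition_table(cond.name)
        mrna = ct["mrna_level"].to_numpy()
        weights = (mrna[:, None] * truth.loading[cond.name]).sum(axis=0)[1:]
        if weights.sum() <= 0:
            weights = np.ones(n_engaged)
    else:
        weights = np.ones(n_engaged)
    weights = weights / weights.sum() * engaged_target

    time = np.arange(0.0, t_max + dt / 2, dt)
    free_center = free_boundary * 0.6
    centers = np.linspace(free_boundary + 0.5, t_max - 0.5, n_engaged)

    def gaussian(center: float, area: float) -> np.ndarray:
        return (
            area
            / (peak_sigma * np.sqrt(2 * np.pi))
            * np.exp(-((time - center) ** 2) / (2 * peak_sigma**2))
        )

    absorbance = gaussian(free_center, 1.0 - engaged_target)
    for c, w in zip(centers, weights):
        absorbance = absorbance + gaussian(c, w)
    return pd.DataFrame({"time_min": time, "absorbance": absorbance})


# ---------------------------------------------------------------------------
# Ratio-archetype fixture for clustering
# ---------------------------------------------------------------------------

#: Six regulation-pattern archetypes as (k_trans, k_deg, mu, density,
#: occupancy) stress/optimal ratio centres. The mu ratio is shared (growth
#: rate is genome-wide): 0.05/0.88. Patterns 4-6 follow the general trend
#: (all rate constants down, density down) at different transcription
#: magnitudes; 1 and 3 have destabilised mRNA (k_deg ratio > 1); 2 has
#: strongly increased ribosome density.
RATIO_ARCHETYPE_CENTERS: tuple[tuple[float, ...], ...] = (
    (1.6, 2.2, 0.057, 0.60, 1.20),
    (0.9, 0.9, 0.057, 2.50, 1.10),
    (2.3, 1.4, 0.057, 0.50, 1.00),
    (0.25, 0.45, 0.057, 0.55, 1.25),
    (0.85, 0.50, 0.057, 0.60, 1.00),
    (1.3, 0.50, 0.057, 0.35, 1.15),
)

RATIO_COLUMNS = ("k_trans", "k_deg", "mu", "density", "occupancy", "reference")


def generate_ratio_archetypes(
    n_genes: int,
    sigma: float = 0.1,
    seed: int = 0,
    centers: Sequence[Sequence[float]] = RATIO_ARCHETYPE_CENTERS,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Planted regulation-ratio table for clustering benchmarks.

    Genes are assigned to archetypes in equal numbers (remainder spread over
    the first archetypes); each ratio column gets additive Gaussian noise of
    SD ``sigma``, clipped at 0. The reference column is exactly 1. Returns
    (ratio table, true labels 0..k-1).
    """
    k = len(centers)
    if n_genes < k:
        raise ValueError("need at least one gene per archetype")
    rng = np.random.default_rng(seed)
    labels = np.arange(n_genes) % k
    X = np.asarray(centers, dtype=float)[labels]
    if sigma > 0:
        X = np.clip(X + rng.normal(0.0, sigma, size=X.shape), 0.0, None)
    table = pd.DataFrame(X, columns=RATIO_COLUMNS[:-1])
    table.insert(0, "gene_id", [f"g{i + 1:05d}" for i in range(n_genes)])
    table["reference"] = 1.0
    return table, labels
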