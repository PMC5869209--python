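"""Population-genetic summaries: allele frequencies, diversity, and the
probability of identity.

For a locus with allele frequencies :math:`p_i` under Hardy-Weinberg,
expected heterozygosity is :math:`H_E = 1 - \\sum_i p_i^2`, the
inbreeding coefficient :math:`F_{IS} = (H_E - H_O)/H_E`, and the
probability that two random individuals share the single-locus genotype is

.. math:: PI = 2\\Big(\\sum_i p_i^2\\Big)^2 - \\sum_i p_i^4 .

The conservative full-sibling analogue is

.. math:: PI_{sibs} = 0.25 + 0.5\\sum p_i^2 + 0.5\\Big(\\sum p_i^2\\Big)^2
          - 0.25\\sum p_i^4 .

Multilocus values multiply across (assumed independent) loci; the
cumulative product over an ordered locus list shows how many markers a
panel needs before two individuals - or two full sibs - are unlikely to
share a profile, which is what decides whether noninvasively collected
genotypes can individualize animals for mark-recapture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AlleleFrequencies:
    """Per-population, per-locus allele frequency vectors.

    ``freqs`` is a long table (population, locus, allele, freq);
    ``n_typed`` counts genotyped individuals per population x locus.
    """

    freqs: pd.DataFrame
    n_typed: pd.DataFrame

    def vector(self, population: str, locus: str) -> np.ndarray:
        sel = self.freqs[
            (self.freqs["population"] == population) & (self.freqs["locus"] == locus)
        ]
        if sel.empty:
            raise KeyError((population, locus))
        return sel.sort_values("allele")["freq"].to_numpy()

    def loci(self, population: str) -> list[str]:
        return sorted(
            self.freqs.loc[self.freqs["population"] == population, "locus"].unique()
        )

    def support(self, population: str, locus: str) -> set[int]:
        sel = self.freqs[
            (self.freqs["population"] == population)
            & (self.freqs["locus"] == locus)
            & (self.freqs["freq"] > 0)
        ]
        return set(sel["allele"].astype(int))


def allele_frequencies(
    genotypes: pd.DataFrame, by: str = "population"
) -> AlleleFrequencies:
    """Count-based allele frequencies from a genotype table.

    Frequencies are allele counts over 2 x (typed individuals); missing
    genotypes are excluded per locus. Loci with no typed individual in a
    group are dropped with a warning.
    """
    if genotypes.empty or genotypes[by].nunique() == 0:
        raise ValueError("empty genotype table")
    typed = genotypes.dropna(subset=["allele_a", "allele_b"])
    freq_rows, n_rows = [], []
    for (grp, locus), g in genotypes.groupby([by, "locus"], sort=True):
        t = g.dropna(subset=["allele_a", "allele_b"])
        n = len(t)
        n_rows.append((grp, locus, n))
        if n == 0:
            warnings.warn(f"{by}={grp}, locus={locus}: no typed individuals, dropped")
            continue
        counts = pd.concat([t["allele_a"], t["allele_b"]]).astype(int).value_counts()
        for allele, c in counts.sort_index().items():
            freq_rows.append((grp, locus, int(allele), c / (2 * n)))
    return AlleleFrequencies(
        freqs=pd.DataFrame(freq_rows, columns=["population", "locus", "allele", "freq"]),
        n_typed=pd.DataFrame(n_rows, columns=["population", "locus", "n"]),
    )


@dataclass
class DiversityStats:
    """Table-1-style per-population summaries plus per-locus detail."""

    per_population: pd.DataFrame
    per_locus: pd.DataFrame


def diversity_stats(
    af: AlleleFrequencies,
    genotypes: pd.DataFrame,
    by: str = "population",
    unbiased_he: bool = False,
) -> DiversityStats:
    """N, Na, private alleles, He, Ho, and FIS per population.

    He_l = 1 - sum(p_i^2) (optionally the 2N/(2N-1) small-sample
    correction); Ho_l = heterozygotes / typed; FIS_l = (He_l - Ho_l)/He_l
    where He_l > 0, undefined (and excluded from the mean) at monomorphic
    loci. Population values are unweighted means over the loci where each
    quantity is defined. FIS is additionally reported as the
    ratio-of-means (mean He - mean Ho) / mean He, since published tables
    are not always explicit about which estimator they use. Private
    alleles are counted on frequency support: alleles present in exactly
    one population.
    """
    # support -> private alleles
    support_of: dict[tuple[str, str], set[int]] = {}
    pops = sorted(af.freqs["population"].unique())
    for pop in pops:
        for locus in af.loci(pop):
            support_of[(pop, locus)] = af.support(pop, locus)
    loci_all = sorted(af.freqs["locus"].unique())
    private: dict[str, int] = {p: 0 for p in pops}
    for locus in loci_all:
        seen: dict[int, list[str]] = {}
        for pop in pops:
            for a in support_of.get((pop, locus), set()):
                seen.setdefault(a, []).append(pop)
        for a, holders in seen.items():
            if len(holders) == 1:
                private[holders[0]] += 1

    locus_rows = []
    for pop in pops:
        for locus in af.loci(pop):
            p = af.vector(pop, locus)
            n = int(
                af.n_typed.loc[
                    (af.n_typed["population"] == pop) & (af.n_typed["locus"] == locus),
                    "n",
                ].iloc[0]
            )
            he = 1.0 - float(np.sum(p**2))
            if unbiased_he and n > 0:
                he *= 2 * n / (2 * n - 1)
            g = genotypes[(genotypes[by] == pop) & (genotypes["locus"] == locus)]
            t = g.dropna(subset=["allele_a", "allele_b"])
            ho = float((t["allele_a"] != t["allele_b"]).mean()) if len(t) else np.nan
            fis = (he - ho) / he if he > 0 and not np.isnan(ho) else np.nan
            na = int((p > 0).sum())
            locus_rows.append((pop, locus, n, na, he, ho, fis))
    per_locus = pd.DataFrame(
        locus_rows, columns=["population", "locus", "n", "na", "he", "ho", "fis"]
    )

    pop_rows = []
    for pop in pops:
        pl = per_locus[per_locus["population"] == pop]
        n_samples = genotypes.loc[genotypes[by] == pop, "sample"].nunique()
        mean_he, mean_ho = pl["he"].mean(), pl["ho"].mean()
        pop_rows.append(
            {
                "population": pop,
                "n": n_samples,
                "na": pl["na"].mean(),
                "private_alleles": private[pop],
                "he": mean_he,
                "ho": mean_ho,
                "fis_mean_loci": pl["fis"].dropna().mean(),
                "fis_ratio_of_means": (mean_he - mean_ho) / mean_he
                if mean_he > 0
                else np.nan,
            }
        )
    return DiversityStats(
        per_population=pd.DataFrame(pop_rows), per_locus=per_locus
    )


def _check_freq_vector(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("frequency vector must be 1-D and non-empty")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must be non-negative and sum to 1")
    return p


def pi_locus(p: np.ndarray) -> float:
    """Single-locus probability of identity, 2(sum p^2)^2 - sum p^4."""
    p = _check_freq_vector(p)
    s2, s4 = float(np.sum(p**2)), float(np.sum(p**4))
    return 2 * s2**2 - s4


def pisibs_locus(p: np.ndarray) -> float:
    """Single-locus probability of identity between full siblings."""
    p = _check_freq_vector(p)
    s2, s4 = float(np.sum(p**2)), float(np.sum(p**4))
    return 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4


@dataclass
class PIResult:
    """Per-locus and cumulative PI / PIsibs over an ordered locus list."""

    per_locus: pd.DataFrame  # locus, pi, pisibs (in cumulative order)
    cumulative: pd.DataFrame  # k, locus, pi_cum, pisibs_cum

    @property
    def pi_total(self) -> float:
        return float(self.cumulative["pi_cum"].iloc[-1])

    @property
    def pisibs_total(self) -> float:
        return float(self.cumulative["pisibs_cum"].iloc[-1])


def cumulative_pi(
    af: AlleleFrequencies,
    population: str,
    locus_order: list[str] | None = None,
    exclude: tuple[str, ...] | list[str] = (),
    most_informative_first: bool = False,
) -> PIResult:
    """PI and PIsibs per locus plus their cumulative products.

    Loci multiply in `locus_order` (default: the order they appear in the
    frequency table; `most_informative_first` sorts ascending per-locus
    PI instead). `exclude` drops named loci - e.g. the lowest-QI loci of
    a panel, or a locus that fails in one species - before accumulating.
    """
    loci = locus_order if locus_order is not None else af.loci(population)
    loci = [l for l in loci if l not in set(exclude)]
    if not loci:
        raise ValueError("empty locus list after exclusions")
    per = pd.DataFrame(
        {
            "locus": loci,
            "pi": [pi_locus(af.vector(population, l)) for l in loci],
            "pisibs": [pisibs_locus(af.vector(population, l)) for l in loci],
        }
    )
    if most_informative_first:
        per = per.sort_values("pi").reset_index(drop=True)
    cum = pd.DataFrame(
        {
            "k": np.arange(1, len(per) + 1),
            "locus": per["locus"],
            "pi_cum": per["pi"].cumprod(),
            "pisibs_cum": per["pisibs"].cumprod(),
        }
    ).reset_index(drop=True)
    return PIResult(per_locus=per.reset_index(drop=True), cumulative=cum)
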