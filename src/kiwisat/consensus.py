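"""Multi-tube consensus genotyping, quality index, and error rates.

Low-template samples (feces, molted feathers) are amplified in replicate
(typically quadruplicate) because single PCRs suffer allelic dropout and
false alleles. A consensus genotype is called per sample x locus from the
replicate evidence; every replicate is then scored against that consensus
to yield a quality index (QI) and per-locus / per-sample genotyping error
rates, after which sample-level filters remove profiles too incomplete to
analyze.

Calling rules (configurable): a heterozygote A/B is accepted when each
allele appears in at least ``het_min`` positive replicates; a homozygote
A/A when A appears in at least ``hom_min`` positive replicates and no
second allele reaches ``het_min``; anything else is a missing call. When
a reference profile from a high-quality sample of the same individual is
available it overrides the replicate-based call and replicates are scored
against it instead.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


class ConsensusCaller(BaseEstimator):
    """Call consensus genotypes from a replicate table.

    Parameters
    ----------
    het_min : int, default 2
        Positive replicates each allele of a heterozygote must reach.
    hom_min : int, default 3
        Positive replicates the single allele of a homozygote must reach.

    Attributes
    ----------
    consensus_ : pd.DataFrame
        One row per sample x locus with columns sample, population,
        species, locus, allele_a, allele_b (Int64, NA = missing call),
        source ('replicates' or 'reference') and flag ('ok', 'no_call',
        'low_support', 'conflict', 'all_failed', 'reference').
    """

    def __init__(self, het_min: int = 2, hom_min: int = 3):
        self.het_min = het_min
        self.hom_min = hom_min

    def fit(
        self, replicates: pd.DataFrame, reference: pd.DataFrame | None = None
    ) -> "ConsensusCaller":
        if self.het_min < 1 or self.hom_min < 1:
            raise ValueError("het_min and hom_min must be >= 1")
        ref_lookup: dict[tuple[str, str], tuple[int, int]] = {}
        if reference is not None:
            typed = reference.dropna(subset=["allele_a", "allele_b"])
            ref_lookup = {
                (r.sample, r.locus): (int(r.allele_a), int(r.allele_b))
                for r in typed.itertuples()
            }
        rows = []
        for (sample, locus), grp in replicates.groupby(["sample", "locus"], sort=True):
            pop = grp["population"].iloc[0]
            species = grp["species"].iloc[0]
            if (sample, locus) in ref_lookup:
                a, b = ref_lookup[(sample, locus)]
                rows.append((sample, pop, species, locus, a, b, "reference", "reference"))
                continue
            a_b_flag = self._call_one(list(grp["alleles"]))
            rows.append((sample, pop, species, locus, *a_b_flag, "replicates"))
        cons = pd.DataFrame(
            rows,
            columns=["sample", "population", "species", "locus",
                     "allele_a", "allele_b", "flag", "source"],
        )
        cons["allele_a"] = cons["allele_a"].astype("Int64")
        cons["allele_b"] = cons["allele_b"].astype("Int64")
        self.consensus_ = cons[
            ["sample", "population", "species", "locus",
             "allele_a", "allele_b", "source", "flag"]
        ]
        return self

    def _call_one(self, replicate_alleles) -> tuple:
        positive = [r for r in replicate_alleles if len(r) > 0]
        if not positive:
            return (None, None, "all_failed")
        counts = Counter(a for r in positive for a in set(r))
        reaching_het = sorted(a for a, c in counts.items() if c >= self.het_min)
        if len(reaching_het) >= 3:
            # three alleles with real support: irresolvable conflict
            return (None, None, "conflict")
        if len(reaching_het) == 2:
            return (reaching_het[0], reaching_het[1], "ok")
        if len(reaching_het) == 1:
            a = reaching_het[0]
            if counts[a] >= self.hom_min:
                return (a, a, "ok")
            return (None, None, "low_support")
        return (None, None, "no_call")


def call_consensus(
    replicates: pd.DataFrame,
    het_min: int = 2,
    hom_min: int = 3,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Functional wrapper over :class:`ConsensusCaller`."""
    return ConsensusCaller(het_min=het_min, hom_min=hom_min).fit(
        replicates, reference=reference
    ).consensus_


@dataclass
class QIResult:
    """Consensus quality index at locus, sample, and dataset level."""

    per_sample_locus: pd.DataFrame  # sample, locus, qi
    per_sample: pd.Series  # sample -> QI (mean over loci)
    per_locus: pd.Series  # locus -> mean QI over samples
    dataset_mean: float
    dataset_sd: float


def _replicate_matches(obs: tuple, consensus: tuple[int, int] | None) -> int:
    """1 iff the replicate's full genotype equals the consensus.

    A failed amplification never matches; neither does any replicate when
    the consensus is missing. Homozygote consensus A/A matches the single
    observation {A}; heterozygote A/B matches exactly {A, B}.
    """
    if consensus is None or len(obs) == 0:
        return 0
    a, b = consensus
    expected = {a} if a == b else {a, b}
    return int(set(obs) == expected)


def quality_index(replicates: pd.DataFrame, consensus: pd.DataFrame) -> QIResult:
    """Score replicate-to-consensus concordance (Miquel-style QI).

    Each replicate scores 1 when its genotype equals the consensus and 0
    otherwise (failures score 0); QI(sample, locus) is the mean over
    replicates, QI(sample) the mean over loci, and the dataset QI the mean
    and SD over samples. A sample whose consensus is missing at every
    locus has undefined QI (NaN).
    """
    cons_lookup = _consensus_lookup(consensus)
    rows = []
    for (sample, locus), grp in replicates.groupby(["sample", "locus"], sort=True):
        cons = cons_lookup.get((sample, locus))
        scores = [_replicate_matches(obs, cons) for obs in grp["alleles"]]
        rows.append((sample, locus, float(np.mean(scores)), cons is not None))
    psl = pd.DataFrame(rows, columns=["sample", "locus", "qi", "defined"])
    per_sample = psl.groupby("sample").apply(
        lambda g: g["qi"].mean() if g["defined"].any() else np.nan,
        include_groups=False,
    )
    per_sample.name = "qi"
    per_locus = psl.groupby("locus")["qi"].mean()
    vals = per_sample.dropna()
    return QIResult(
        per_sample_locus=psl[["sample", "locus", "qi"]],
        per_sample=per_sample,
        per_locus=per_locus,
        dataset_mean=float(vals.mean()) if len(vals) else float("nan"),
        dataset_sd=float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
    )


def _consensus_lookup(consensus: pd.DataFrame) -> dict:
    lookup = {}
    for r in consensus.itertuples():
        if pd.isna(r.allele_a):
            lookup[(r.sample, r.locus)] = None
        else:
            lookup[(r.sample, r.locus)] = (int(r.allele_a), int(r.allele_b))
    return lookup


@dataclass
class ErrorRates:
    """Replicate-vs-consensus genotyping error rates.

    Rates are fractions in [0, 1]; NaN marks an undefined rate (e.g. ADO
    for a locus with no heterozygous consensus). The across-loci /
    across-samples summaries are unweighted means of the defined per-unit
    rates, matching how multi-tube studies tabulate them.
    """

    amplification_failure: float
    ado_by_locus: pd.Series
    ado_by_sample: pd.Series
    fa_by_locus: pd.Series
    fa_by_sample: pd.Series

    @property
    def ado_across_loci(self) -> float:
        return float(self.ado_by_locus.dropna().mean())

    @property
    def ado_across_samples(self) -> float:
        return float(self.ado_by_sample.dropna().mean())

    @property
    def fa_across_loci(self) -> float:
        return float(self.fa_by_locus.dropna().mean())

    @property
    def fa_across_samples(self) -> float:
        return float(self.fa_by_sample.dropna().mean())

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "amplification_failure": [self.amplification_failure],
                "ado_across_loci": [self.ado_across_loci],
                "ado_across_samples": [self.ado_across_samples],
                "fa_across_loci": [self.fa_across_loci],
                "fa_across_samples": [self.fa_across_samples],
            }
        )


def error_rates(
    replicates: pd.DataFrame,
    consensus: pd.DataFrame,
    fa_denominator: str = "all",
) -> ErrorRates:
    """GIMLET-style dropout / false-allele / failure estimation.

    ADO per locus = positive replicates at heterozygous-consensus
    sample-loci that show exactly one consensus allele and nothing else,
    over all positive replicates at those sample-loci. FA per locus =
    positive replicates containing at least one allele absent from the
    consensus, over positive replicates at consensus-defined sample-loci
    (`fa_denominator='het'` restricts the denominator to heterozygous
    consensus, the convention some tool versions use). Per-sample rates
    are the same ratios within a sample. Amplification failure is the
    fraction of failed replicates overall.
    """
    if fa_denominator not in ("all", "het"):
        raise ValueError("fa_denominator must be 'all' or 'het'")
    cons_lookup = _consensus_lookup(consensus)

    n_total = len(replicates)
    n_failed = int((replicates["alleles"].map(len) == 0).sum())

    recs = []
    for r in replicates.itertuples():
        cons = cons_lookup.get((r.sample, r.locus))
        if cons is None or len(r.alleles) == 0:
            continue
        a, b = cons
        het = a != b
        obs = set(r.alleles)
        ado = het and (obs == {a} or obs == {b})
        fa = bool(obs - {a, b})
        recs.append((r.sample, r.locus, het, ado, fa))
    ev = pd.DataFrame(recs, columns=["sample", "locus", "het", "ado", "fa"])

    def _rates(by: str) -> tuple[pd.Series, pd.Series]:
        if ev.empty:
            empty = pd.Series(dtype=float)
            return empty, empty
        het_ev = ev[ev["het"]]
        ado = het_ev.groupby(by)["ado"].mean()
        fa_ev = ev if fa_denominator == "all" else het_ev
        fa = fa_ev.groupby(by)["fa"].mean()
        # units with no het consensus have undefined ADO, not zero
        all_units = ev[by].unique()
        ado = ado.reindex(all_units)
        fa = fa.reindex(all_units)
        return ado.sort_index(), fa.sort_index()

    ado_locus, fa_locus = _rates("locus")
    ado_sample, fa_sample = _rates("sample")
    return ErrorRates(
        amplification_failure=n_failed / n_total if n_total else float("nan"),
        ado_by_locus=ado_locus,
        ado_by_sample=ado_sample,
        fa_by_locus=fa_locus,
        fa_by_sample=fa_sample,
    )


def filter_samples(consensus: pd.DataFrame, max_failed_loci: int = 2) -> pd.DataFrame:
    """Drop samples whose consensus is missing at more than
    `max_failed_loci` loci; the removal list is logged."""
    missing = consensus["allele_a"].isna().groupby(consensus["sample"]).sum()
    removed = missing[missing > max_failed_loci].index.tolist()
    if removed:
        logger.info(
            "removing %d sample(s) failing > %d loci: %s",
            len(removed), max_failed_loci, ", ".join(map(str, removed)),
        )
    return consensus[~consensus["sample"].isin(removed)].reset_index(drop=True)


def classify_success(
    qi_per_sample: pd.Series, threshold: float = 0.75
) -> tuple[pd.DataFrame, float]:
    """Flag samples whose QI reaches the success threshold (inclusive).

    Returns the per-sample table and the cohort success fraction over
    samples with defined QI.
    """
    flags = pd.DataFrame(
        {"qi": qi_per_sample, "success": qi_per_sample >= threshold}
    ).reset_index(names="sample")
    defined = flags["qi"].notna()
    frac = float(flags.loc[defined, "success"].mean()) if defined.any() else float("nan")
    return flags, frac
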