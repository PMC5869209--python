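"""Individual identification and molecular sexing.

Kiwi, like all birds, are ZW: females are ZW, males ZZ. The sex-linked
microsatellite amplifies a short W fragment and species-specific Z
fragments that differ in length, so a capillary trace showing the W size
identifies a female, while a male call requires the W fragment to be
absent across enough independent positive replicates to make W dropout
unlikely. Dropout in ZW systems fails asymmetrically: it can turn a
female into an apparent male but never the reverse, which is why female
calls accept a single positive replicate and male calls demand several.

Individualization compares multilocus genotypes pairwise and flags pairs
whose mismatch count at shared typed loci falls at or below a threshold
as recaptures of the same individual.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


@dataclass(frozen=True)
class SexMarkerModel:
    """Species-resolved fragment sizes of the ZW sexing locus.

    The W fragment is shared across species; Z fragments are species
    specific, with some alleles further restricted to particular lineages.
    """

    w_size: int = 92
    z_sizes: dict[str, tuple[int, ...]] = field(default_factory=dict)
    #: (species, z size) -> lineages the allele has been observed in
    lineage_restrictions: dict[tuple[str, int], tuple[str, ...]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for sp, sizes in self.z_sizes.items():
            if self.w_size in sizes:
                raise ValueError(f"W size {self.w_size} in Z pool of {sp}")
            if any(s <= 0 for s in sizes):
                raise ValueError(f"non-positive Z size for {sp}")

    def z_pool(self, species: str, lineage: str | None = None) -> tuple[int, ...]:
        """Z fragment sizes admissible for a species (optionally a lineage)."""
        if species not in self.z_sizes:
            raise KeyError(f"unknown species for sex marker model: {species!r}")
        sizes = self.z_sizes[species]
        if lineage is None:
            return sizes
        return tuple(
            s
            for s in sizes
            if (species, s) not in self.lineage_restrictions
            or lineage in self.lineage_restrictions[(species, s)]
        )

    def off_lineage(self, species: str, size: int, lineage: str | None) -> bool:
        """True when a Z allele is valid for the species but outside the
        lineage it has been recorded in."""
        key = (species, size)
        if key not in self.lineage_restrictions or lineage is None:
            return False
        return lineage not in self.lineage_restrictions[key]


#: Fragment-size model for the five kiwi species. ZZ = male, ZW = female.
KIWI_SEX_MODEL = SexMarkerModel(
    w_size=92,
    z_sizes={
        "A. mantelli": (96, 98, 100),
        "A. australis": (96, 98),
        "A. rowi": (96,),
        "A. owenii": (94,),
        "A. haastii": (94,),
    },
    lineage_restrictions={
        ("A. mantelli", 98): ("Eastern", "Western"),
        ("A. mantelli", 100): ("Western",),
        ("A. australis", 98): ("Fiordland",),
    },
)


@dataclass(frozen=True)
class SexCall:
    """Outcome of sexing one sample from replicated sex-locus amplifications."""

    sample: str
    call: str  # female | male | ambiguous | failed
    n_positive: int
    n_with_w: int
    rationale: str
    off_pool_fragments: tuple[int, ...] = ()
    off_lineage_fragments: tuple[int, ...] = ()


def sex_call(
    replicates: list[tuple[int, ...]] | list[frozenset],
    species: str,
    min_pos_male: int = 2,
    model: SexMarkerModel = KIWI_SEX_MODEL,
    lineage: str | None = None,
    sample: str = "",
) -> SexCall:
    """Sex one sample from its replicated sex-locus observations.

    Parameters
    ----------
    replicates : list of allele-size collections
        One entry per PCR replicate; empty = amplification failure.
    species : str
        Needed to interpret the Z fragment sizes.
    min_pos_male : int
        Minimum W-free positive replicates required for a male call; fewer
        positives give ``ambiguous`` since W dropout cannot be excluded.
    """
    pool = model.z_pool(species)  # raises KeyError for unknown species
    positive = [frozenset(r) for r in replicates if len(r) > 0]
    observed = frozenset().union(*positive) if positive else frozenset()
    off_pool = tuple(
        sorted(a for a in observed if a != model.w_size and a not in pool)
    )
    off_lineage = tuple(
        sorted(a for a in observed if model.off_lineage(species, a, lineage))
    )
    n_pos = len(positive)
    n_w = sum(model.w_size in r for r in positive)

    if n_pos == 0:
        call, why = "failed", "no positive replicate"
    elif n_w >= 1:
        call, why = "female", "W fragment observed"
    elif n_pos >= min_pos_male and any(a in pool for a in observed):
        call, why = "male", f"no W fragment in {n_pos} positive replicates"
    else:
        call, why = "ambiguous", (
            f"only {n_pos} positive replicate(s) without W; W dropout possible"
            if n_pos < min_pos_male
            else "no fragment in the species Z pool"
        )
    return SexCall(sample, call, n_pos, n_w, why, off_pool, off_lineage)


class SexCaller(BaseEstimator):
    """Rule-based ZW sex classifier over a replicate table.

    A stateless classifier in the scikit-learn idiom: ``fit`` validates the
    fragment model, ``predict`` maps a replicate table restricted to the sex
    locus to one call per sample.

    Parameters
    ----------
    model : SexMarkerModel
        Species -> fragment-size mapping (default: the kiwi model).
    min_pos_male : int
        W-free positive replicates required to call a male.
    """

    def __init__(
        self, model: SexMarkerModel = KIWI_SEX_MODEL, min_pos_male: int = 2
    ):
        self.model = model
        self.min_pos_male = min_pos_male

    def fit(self, X=None, y=None) -> "SexCaller":
        if not self.model.z_sizes:
            raise ValueError("sex marker model has no species")
        if self.min_pos_male < 1:
            raise ValueError("min_pos_male must be >= 1")
        self.species_ = tuple(sorted(self.model.z_sizes))
        return self

    def predict(self, replicates: pd.DataFrame) -> pd.DataFrame:
        """Call sex for every sample in a sex-locus replicate table.

        `replicates` needs columns sample, species, alleles (tuple per
        replicate row) and optionally lineage.
        """
        if not hasattr(self, "species_"):
            self.fit()
        has_lineage = "lineage" in replicates.columns
        rows = []
        for (sample, species), grp in replicates.groupby(
            ["sample", "species"], sort=True
        ):
            lineage = grp["lineage"].iloc[0] if has_lineage else None
            if pd.isna(lineage) if lineage is not None else False:
                lineage = None
            call = sex_call(
                list(grp["alleles"]),
                species,
                min_pos_male=self.min_pos_male,
                model=self.model,
                lineage=lineage,
                sample=sample,
            )
            rows.append(
                {
                    "sample": call.sample,
                    "species": species,
                    "call": call.call,
                    "n_positive": call.n_positive,
                    "n_with_w": call.n_with_w,
                    "rationale": call.rationale,
                    "off_pool_fragments": ";".join(map(str, call.off_pool_fragments)),
                    "off_lineage_fragments": ";".join(
                        map(str, call.off_lineage_fragments)
                    ),
                }
            )
        return pd.DataFrame(rows)


def match_genotypes(
    genotypes: pd.DataFrame,
    max_mismatch: int = 0,
    min_shared_loci: int = 1,
) -> pd.DataFrame:
    """All-pairs genotype comparison for individualization.

    Compares every sample pair at the loci both have typed; pairs with at
    most `max_mismatch` mismatching loci over at least `min_shared_loci`
    shared loci are flagged as the same individual. Genotypes are compared
    as unordered allele pairs. Samples with zero typed loci are excluded
    with a warning.

    Returns a symmetric-by-construction table of (sample_a, sample_b,
    n_shared, n_mismatch, match) with sample_a < sample_b.
    """
    typed = genotypes.dropna(subset=["allele_a", "allele_b"])
    profiles: dict[str, dict[str, tuple[int, int]]] = {}
    for sample, grp in typed.groupby("sample"):
        profiles[sample] = {
            r.locus: (int(r.allele_a), int(r.allele_b)) for r in grp.itertuples()
        }
    all_samples = genotypes["sample"].unique()
    untyped = sorted(set(all_samples) - set(profiles))
    if untyped:
        warnings.warn(f"samples with zero typed loci excluded: {untyped}")
    if len(profiles) < 2:
        raise ValueError("need at least 2 samples with typed loci")

    rows = []
    for a, b in itertools.combinations(sorted(profiles), 2):
        shared = profiles[a].keys() & profiles[b].keys()
        n_mis = sum(profiles[a][loc] != profiles[b][loc] for loc in shared)
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "n_shared": len(shared),
                "n_mismatch": n_mis,
                "match": n_mis <= max_mismatch and len(shared) >= min_shared_loci,
            }
        )
    return pd.DataFrame(rows)
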